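"""Published Pearson correlation matrices for the 19 bioclimatic variables.

Lower-triangle transcriptions of the pairwise Pearson coefficients among
bio1-bio19 for the two WorldClim baselines (1.4, 1960-1990 and 2.1,
1970-2000) as used in the *Amaranthus palmeri* collinearity screen. Shipped
as in-package text so variable pruning can be regression-tested without any
external download.
"""

from __future__ import annotations

import numpy as np

from .selection import CorrelationMatrix

__all__ = ["worldclim14_matrix", "worldclim21_matrix", "BIOCLIM_VARIABLES"]

BIOCLIM_VARIABLES = [f"bio{i}" for i in range(1, 20)]

# One line per variable bio2..bio19: coefficients against bio1..bio(k-1).
_WORLDCLIM14_LOWER = """
0.110
0.571 0.511
-0.574 0.029 -0.814
0.686 0.545 0.253 0.071
0.888 -0.139 0.631 -0.830 0.323
-0.477 0.476 -0.484 0.884 0.287 -0.813
0.484 0.278 0.177 0.038 0.555 0.204 0.135
0.751 0.227 0.640 -0.629 0.498 0.786 -0.489 0.083
0.817 0.186 0.144 -0.002 0.905 0.504 0.046 0.611 0.499
0.937 0.085 0.749 -0.820 0.461 0.969 -0.698 0.316 0.806 0.573
-0.131 -0.559 -0.374 0.060 -0.334 -0.047 -0.158 -0.107 -0.286 -0.154 -0.142
0.095 -0.407 -0.034 -0.170 -0.232 0.158 -0.302 0.070 -0.111 -0.050 0.109 0.758
-0.279 -0.486 -0.562 0.285 -0.296 -0.234 0.055 -0.173 -0.362 -0.161 -0.332 0.777 0.244
0.370 0.182 0.555 -0.427 0.111 0.380 -0.316 0.170 0.341 0.141 0.434 -0.365 0.266 -0.748
0.066 -0.419 -0.025 -0.198 -0.277 0.156 -0.328 0.012 -0.110 -0.102 0.101 0.799 0.983 0.285 0.215
-0.263 -0.473 -0.554 0.281 -0.273 -0.225 0.060 -0.161 -0.343 -0.144 -0.319 0.783 0.253 0.994 -0.756 0.290
-0.082 -0.293 -0.174 0.068 -0.237 -0.094 -0.051 0.273 -0.367 -0.092 -0.111 0.724 0.804 0.375 0.014 0.801 0.379
-0.071 -0.468 -0.247 -0.071 -0.266 0.120 -0.285 -0.528 0.185 -0.143 -0.022 0.514 0.246 0.520 -0.261 0.291 0.521 -0.074
"""

_WORLDCLIM21_LOWER = """
0.156
0.562 0.553
-0.549 0.004 -0.800
0.691 0.579 0.271 0.082
0.878 -0.112 0.609 -0.818 0.317
-0.434 0.482 -0.434 0.869 0.324 -0.795
0.484 0.329 0.213 0.036 0.556 0.191 0.165
0.753 0.220 0.602 -0.604 0.499 0.788 -0.467 0.072
0.816 0.214 0.133 0.031 0.900 0.489 0.088 0.596 0.503
0.933 0.126 0.741 -0.809 0.463 0.965 -0.666 0.319 0.802 0.562
-0.118 -0.557 -0.348 0.027 -0.350 -0.021 -0.203 -0.098 -0.263 -0.155 -0.120
0.116 -0.388 0.012 -0.223 -0.258 0.190 -0.354 0.087 -0.093 -0.058 0.147 0.753
-0.269 -0.486 -0.545 0.269 -0.290 -0.215 0.029 -0.173 -0.335 -0.150 -0.319 0.770 0.231
0.361 0.213 0.565 -0.440 0.092 0.366 -0.306 0.169 0.327 0.115 0.434 -0.366 0.272 -0.741
0.090 -0.399 0.021 -0.251 -0.295 0.190 -0.379 0.025 -0.085 -0.107 0.142 0.792 0.982 0.269 0.223
-0.264 -0.475 -0.540 0.268 -0.279 -0.213 0.034 -0.167 -0.324 -0.146 -0.314 0.779 0.238 0.994 -0.753 0.274
-0.032 -0.257 -0.101 0.002 -0.221 -0.041 -0.100 0.300 -0.328 -0.072 -0.046 0.718 0.814 0.344 0.038 0.810 0.351
-0.082 -0.489 -0.271 -0.066 -0.287 0.124 -0.307 -0.542 0.206 -0.148 -0.032 0.495 0.215 0.516 -0.264 0.267 0.516 -0.102
"""


def _from_lower(text: str) -> CorrelationMatrix:
    lines = [ln for ln in text.strip().split("\n")]
    k = len(lines) + 1
    r = np.eye(k)
    for i, line in enumerate(lines, start=1):
        vals = [float(t) for t in line.split()]
        if len(vals) != i:
            raise ValueError(f"row {i + 1} of reference matrix has {len(vals)} entries, expected {i}")
        r[i, :i] = vals
        r[:i, i] = vals
    return CorrelationMatrix(variables=list(BIOCLIM_VARIABLES[:k]), r=r, n=0)


def worldclim14_matrix() -> CorrelationMatrix:
    """The 19x19 bioclim correlation matrix for the WorldClim 1.4 baseline."""
    return _from_lower(_WORLDCLIM14_LOWER)


def worldclim21_matrix() -> CorrelationMatrix:
    """The 19x19 bioclim correlation matrix for the WorldClim 2.1 baseline."""
    return _from_lower(_WORLDCLIM21_LOWER)
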