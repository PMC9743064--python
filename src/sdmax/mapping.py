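"""Suitability classification, area accounting, and change-code overlay.

Logistic suitability is reclassified into four classes — unsuitable
[0, 0.1), low [0.1, 0.2), moderate [0.2, 0.4), high [0.4, 1] — coded
1..4. Change between two periods is the two-digit overlay code
10 * class_first + class_second, so the first and second digits read off
the suitability level in each period; the sixteen codes group into six
change categories (unchanged, new, raised, disappeared, dropped,
unsuitable throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_io import GridAlignmentError, RasterGrid
from .maxent import SuitabilityMap

__all__ = [
    "ClassificationScheme",
    "ClassifiedMap",
    "ChangeMap",
    "CHANGE_CATEGORIES",
    "jenks_breaks",
    "classify",
    "area_percentages",
    "overlay_code",
    "change_summary",
]

#: Overlay code -> change category.
CHANGE_CATEGORIES: dict[int, str] = {
    11: "Unsuitable",
    22: "Suitable level remained the same",
    33: "Suitable level remained the same",
    44: "Suitable level remained the same",
    12: "New (unsuitable to suitable)",
    13: "New (unsuitable to suitable)",
    14: "New (unsuitable to suitable)",
    23: "Suitable level raised",
    24: "Suitable level raised",
    34: "Suitable level raised",
    21: "Disappeared (suitable to unsuitable)",
    31: "Disappeared (suitable to unsuitable)",
    41: "Disappeared (suitable to unsuitable)",
    32: "Suitable level dropped",
    42: "Suitable level dropped",
    43: "Suitable level dropped",
}


@dataclass
class ClassificationScheme:
    """Interior thresholds and labels for the four suitability classes."""

    breaks: tuple[float, ...] = (0.1, 0.2, 0.4)
    labels: tuple[str, ...] = ("unsuitable", "low", "moderate", "high")
    codes: tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        b = self.breaks
        if any(not 0.0 < x < 1.0 for x in b) or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"breaks must be strictly increasing within (0,1): {b}")
        if len(self.labels) != len(b) + 1 or len(self.codes) != len(b) + 1:
            raise ValueError("need one more label/code than breaks")


@dataclass
class ClassifiedMap:
    grid: RasterGrid
    scheme: ClassificationScheme = field(default_factory=ClassificationScheme)
    scenario_label: str = ""

    def __post_init__(self) -> None:
        vals = self.grid.values[self.grid.valid_mask()]
        if vals.size and not np.all(np.isin(vals, self.scheme.codes)):
            raise ValueError("classified map contains codes outside the scheme")


@dataclass
class ChangeMap:
    grid: RasterGrid
    categories: dict[int, str] = field(default_factory=lambda: dict(CHANGE_CATEGORIES))


def jenks_breaks(values, k: int, cap: int = 10_000, seed: int = 0) -> list[float]:
    """Jenks natural breaks by exact dynamic programming.

    Minimizes the within-class sum of squared deviations over all ways to
    cut the sorted sample into ``k`` contiguous classes. Returns the k-1
    interior breaks as the upper (maximum) value of each lower class.
    Samples larger than ``cap`` are reduced to a seeded subsample first.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct values, got {np.unique(x).size}")
    if x.size > cap:
        rng = np.random.default_rng(seed)
        x = np.sort(rng.choice(x, size=cap, replace=False))
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:
        # within-class SSD of x[i:j]
        m = j - i
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / m

    # cost[c][j] = best SSD splitting x[:j] into c classes
    cost = np.full((k + 1, n + 1), np.inf)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = np.inf, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + ssd(i, j)
                if v < best - 1e-12:
                    best, arg = v, i
            cost[c, j], cut[c, j] = best, arg
    breaks = []
    j = n
    for c in range(k, 1, -1):
        i = cut[c, j]
        breaks.append(float(x[i - 1]))  # max of the class ending at i-1
        j = i
    return breaks[::-1]


def classify(smap: SuitabilityMap | RasterGrid, scheme: ClassificationScheme | None = None) -> ClassifiedMap:
    """Reclassify logistic suitability into coded classes.

    Classes are left-closed, right-open; the top class is closed at 1.
    """
    scheme = scheme or ClassificationScheme()
    grid = smap.grid if isinstance(smap, SuitabilityMap) else smap
    valid = grid.valid_mask()
    vals = grid.values
    in_range = vals[valid]
    if in_range.size and (in_range.min() < 0 or in_range.max() > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    edges = np.array([0.0, *scheme.breaks, np.nextafter(1.0, 2.0)])
    cls = np.digitize(vals, edges[1:], right=False) + 1  # 1..k
    codes = np.array(scheme.codes)[np.clip(cls, 1, len(scheme.codes)) - 1]
    out = np.where(valid, codes.astype(float), grid.nodata_value)
    label = getattr(smap, "scenario_label", "")
    return ClassifiedMap(grid=grid.with_values(out, variable_name="suitability_class"),
                         scheme=scheme, scenario_label=label)


def area_percentages(
    classified: ClassifiedMap,
    mask: RasterGrid | None = None,
    latitude_weighted: bool = False,
) -> pd.DataFrame:
    """Percentage of valid (optionally masked) cells per suitability class.

    Default accounting is an unweighted cell count (raster-calculator
    convention); ``latitude_weighted`` switches to cos(latitude) weights so
    each cell counts by its approximate geodesic area.
    """
    grid = classified.grid
    valid = grid.valid_mask()
    if mask is not None:
        if not grid.same_header(mask):
            raise GridAlignmentError("mask misaligned with classified map")
        valid &= mask.valid_mask() & (mask.values != 0)
    if not valid.any():
        raise ValueError("no valid cells to account")
    if latitude_weighted:
        w_row = np.cos(np.radians(grid.cell_latitudes()))
        weights = np.broadcast_to(w_row[:, None], grid.values.shape)
    else:
        weights = np.ones_like(grid.values)
    total = weights[valid].sum()
    rows = []
    for code, label in zip(classified.scheme.codes, classified.scheme.labels):
        sel = valid & (grid.values == code)
        rows.append({"class": label, "code": code, "count": int(sel.sum()),
                     "percent": 100.0 * weights[sel].sum() / total})
    return pd.DataFrame(rows)


def overlay_code(layer1: ClassifiedMap, layer2: ClassifiedMap) -> ChangeMap:
    """Two-digit change code 10 * class_first + class_second per cell."""
    g1, g2 = layer1.grid, layer2.grid
    if not g1.same_header(g2):
        raise GridAlignmentError("overlay layers are misaligned")
    if layer1.scheme.codes != layer2.scheme.codes:
        raise ValueError("overlay layers use different classification schemes")
    valid = g1.valid_mask() & g2.valid_mask()
    code = 10.0 * g1.values + g2.values
    out = np.where(valid, code, g1.nodata_value)
    return ChangeMap(grid=g1.with_values(out, variable_name="change_code"))


def change_summary(change: ChangeMap) -> pd.DataFrame:
    """Counts and percentages of valid cells per change category."""
    grid = change.grid
    valid = grid.valid_mask()
    total = int(valid.sum())
    if total == 0:
        return pd.DataFrame(columns=["category", "count", "percent"])
    vals = grid.values[valid].astype(int)
    order = []
    counts: dict[str, int] = {}
    for code in sorted(change.categories):
        cat = change.categories[code]
        if cat not in counts:
            counts[cat] = 0
            order.append(cat)
        counts[cat] += int(np.sum(vals == code))
    unknown = int(np.sum(~np.isin(vals, list(change.categories))))
    if unknown:
        raise ValueError(f"{unknown} cells carry codes outside the category table")
    return pd.DataFrame(
        [{"category": c, "count": counts[c], "percent": 100.0 * counts[c] / total} for c in order]
    )
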