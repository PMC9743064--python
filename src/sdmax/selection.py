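"""Collinearity screening of candidate environmental variables.

Highly correlated bioclim variables inflate variance and confound variable
importance, so before fitting only one member of each |r| >= threshold
cluster is kept. The pruning is a deterministic greedy pass: ecologically
prioritized variables are processed first, then the rest in ascending bio
index; processing a variable keeps it and discards every not-yet-processed
variable correlated with it at or above the threshold.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occurrences import PresenceTable

__all__ = [
    "CorrelationMatrix",
    "SelectionRule",
    "PriorityConflictError",
    "pearson_matrix",
    "greedy_prune",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over named variables."""

    variables: list[str]
    r: np.ndarray
    n: int = 0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variables)
        if self.r.shape != (k, k):
            raise ValueError(f"matrix shape {self.r.shape} does not match {k} variables")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("|r| must not exceed 1")

    def value(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.r[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)


@dataclass
class SelectionRule:
    """Threshold and retention priorities for the greedy prune."""

    threshold: float = 0.8
    priority: list[str] = field(default_factory=lambda: ["bio1", "bio4", "bio13", "bio17"])
    always_keep: list[str] = field(default_factory=lambda: ["elev"])

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        if len(set(self.priority)) != len(self.priority):
            raise ValueError("priority names must be distinct")


class PriorityConflictError(ValueError):
    """Two priority variables are themselves collinear."""


def pearson_matrix(table: PresenceTable | pd.DataFrame, variables: list[str] | None = None) -> CorrelationMatrix:
    """Product-moment correlation among variables at the presence sample.

    A constant column has no defined correlation; its off-diagonal entries
    are set to 0 with a warning so it can never trigger a removal.
    """
    df = table.env if isinstance(table, PresenceTable) else table
    if variables is not None:
        df = df[variables]
    names = list(df.columns)
    if len(df) < 3:
        raise ValueError(f"need at least 3 rows to estimate correlations, got {len(df)}")
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("correlation input contains non-finite values")
    sd = values.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant variables treated as uncorrelated: {[n for n, c in zip(names, constant) if c]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(variables=names, r=r, n=len(df))


def _bio_sort_key(name: str) -> tuple:
    m = re.fullmatch(r"bio(\d+)", name)
    return (0, int(m.group(1)), name) if m else (1, 0, name)


def greedy_prune(corr: CorrelationMatrix, rule: SelectionRule | None = None) -> list[str]:
    """Retain a maximal pairwise-compatible variable set.

    Variables are processed priority-first, then in ascending bio index.
    Each processed variable is retained and removes every not-yet-processed
    variable with |r| >= threshold against it. The returned list preserves
    the original matrix order and never contains a pair at or above the
    threshold.
    """
    rule = rule or SelectionRule()
    missing = [p for p in rule.priority if p not in corr.variables]
    if missing:
        raise ValueError(f"priority variables not in matrix: {missing}")
    for i, a in enumerate(rule.priority):
        for b in rule.priority[i + 1:]:
            if abs(corr.value(a, b)) >= rule.threshold:
                raise PriorityConflictError(
                    f"priority variables {a} and {b} are collinear "
                    f"(|r| = {abs(corr.value(a, b)):.3f} >= {rule.threshold})"
                )
    rest = sorted((v for v in corr.variables if v not in rule.priority), key=_bio_sort_key)
    order = list(rule.priority) + rest
    removed: set[str] = set()
    retained: list[str] = []
    for var in order:
        if var in removed:
            continue
        retained.append(var)
        for other in order:
            if other == var or other in removed or other in retained:
                continue
            if abs(corr.value(var, other)) >= rule.threshold:
                removed.add(other)
    return [v for v in corr.variables if v in set(retained)]
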