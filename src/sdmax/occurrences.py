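"""Occurrence cleaning: deduplication, fishnet thinning, value extraction.

Thinning follows the fishnet rule used in SDM preprocessing: the landscape
is divided into the environmental grid's cells, and each occupied cell
contributes exactly one presence — the single point if the cell holds one,
or the coordinate centroid of all its points otherwise. Because the centroid
of points inside a convex cell stays inside the cell, thinning is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_io import EnvStack, OccurrenceSet, RasterGrid

__all__ = ["PresenceTable", "deduplicate", "fishnet_thin", "extract_presence_values"]


@dataclass
class PresenceTable:
    """Retained presences with one column per environmental variable."""

    data: pd.DataFrame  # columns: lon, lat, <variable...>
    n_raw: int = 0
    n_effective: int = 0
    n_dropped_nodata: int = 0
    n_dropped_outside: int = 0
    variables: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def env(self) -> pd.DataFrame:
        return self.data[self.variables]


def deduplicate(occ: OccurrenceSet) -> tuple[OccurrenceSet, dict]:
    """Collapse exact (lon, lat) duplicates; drop out-of-range rows.

    Coordinate-range rows can only arise from sets built outside the normal
    readers; they are removed defensively. Returns the cleaned set and a
    report with removal counts.
    """
    seen: set[tuple[float, float]] = set()
    kept, n_dup, n_bad = [], 0, 0
    for species, lon, lat in occ.records:
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            n_bad += 1
            continue
        key = (lon, lat)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        kept.append((species, lon, lat))
    report = {"n_input": len(occ), "n_duplicates": n_dup, "n_out_of_range": n_bad, "n_kept": len(kept)}
    return OccurrenceSet(records=kept), report


def fishnet_thin(occ: OccurrenceSet, template: RasterGrid, mode: str = "mean") -> tuple[OccurrenceSet, dict]:
    """One presence per occupied template cell.

    ``mode='mean'`` (default): cells with two or more points are replaced by
    the arithmetic mean of their (lon, lat). ``mode='first'`` keeps the first
    point encountered instead. Points outside the template extent are dropped
    and counted.
    """
    if mode not in ("mean", "first"):
        raise ValueError(f"unknown thinning mode {mode!r}")
    cells: dict[tuple[int, int], list[tuple[str, float, float]]] = {}
    order: list[tuple[int, int]] = []
    n_outside = 0
    for rec in occ.records:
        idx = template.cell_index(rec[1], rec[2])
        if idx is None:
            n_outside += 1
            continue
        if idx not in cells:
            cells[idx] = []
            order.append(idx)
        cells[idx].append(rec)
    kept = []
    for idx in order:
        pts = cells[idx]
        if len(pts) == 1 or mode == "first":
            kept.append(pts[0])
        else:
            lon = float(np.mean([p[1] for p in pts]))
            lat = float(np.mean([p[2] for p in pts]))
            kept.append((pts[0][0], lon, lat))
    report = {
        "n_input": len(occ),
        "n_outside": n_outside,
        "n_occupied_cells": len(cells),
        "n_kept": len(kept),
    }
    return OccurrenceSet(records=kept), report


def extract_presence_values(occ: OccurrenceSet, stack: EnvStack) -> PresenceTable:
    """Look up each layer's value at every presence point's cell.

    Points outside the extent or on a cell that is NODATA in any layer are
    dropped and counted.
    """
    template = stack.template()
    variables = stack.variables
    valid = stack.valid_mask()
    rows_out: list[list[float]] = []
    n_outside = n_nodata = 0
    for _, lon, lat in occ.records:
        idx = template.cell_index(lon, lat)
        if idx is None:
            n_outside += 1
            continue
        r, c = idx
        if not valid[r, c]:
            n_nodata += 1
            continue
        rows_out.append([lon, lat] + [g.values[r, c] for g in stack])
    df = pd.DataFrame(rows_out, columns=["lon", "lat"] + variables)
    return PresenceTable(
        data=df,
        n_raw=len(occ),
        n_effective=len(df),
        n_dropped_nodata=n_nodata,
        n_dropped_outside=n_outside,
        variables=list(variables),
    )
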