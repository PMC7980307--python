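"""Range-change accounting from continuous habitat-suitability maps.

Continuous suitability scores (e.g. from an ecological niche model) are
binarized at the threshold that maximizes sensitivity + specificity over the
presence and background score distributions (the max-SSS rule); suitable-cell
counts per time slice are then turned into per-cent-of-study-area and
per-cent-range-change figures relative to the present-day map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .landscape import RasterGrid

__all__ = [
    "max_sss_threshold",
    "binarize",
    "ensemble_majority",
    "suitable_cells",
    "range_report",
    "range_report_from_counts",
]


def max_sss_threshold(
    presence_scores, background_scores, above_inclusive: bool = True
) -> float:
    """Threshold maximizing sensitivity(t) + specificity(t).

    Candidates are the union of observed scores; sensitivity is the fraction
    of presences at or above the threshold and specificity the fraction of
    background below it (with ``above_inclusive``, the default, boundary
    cells count as suitable). Ties break toward the lowest threshold.
    """
    pres = np.asarray(presence_scores, float)
    back = np.asarray(background_scores, float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("presence and background score lists must be non-empty")
    if np.any((pres < 0) | (pres > 1)) or np.any((back < 0) | (back > 1)):
        raise ValueError("scores must lie in [0, 1]")
    allscores = np.concatenate([pres, back])
    if np.ptp(allscores) == 0:
        raise ValueError("degenerate input: all scores identical")
    candidates = np.unique(allscores)
    best_t = None
    best = -np.inf
    for t in candidates:
        if above_inclusive:
            sens = float(np.mean(pres >= t))
            spec = float(np.mean(back < t))
        else:
            sens = float(np.mean(pres > t))
            spec = float(np.mean(back <= t))
        score = sens + spec
        if score > best + 1e-12:
            best = score
            best_t = float(t)
    return best_t


def binarize(grid: RasterGrid, threshold: float, above_inclusive: bool = True
             ) -> RasterGrid:
    """0/1 suitability map; nodata propagates."""
    v = grid.values
    if above_inclusive:
        out = np.where(np.isnan(v), np.nan, (v >= threshold).astype(float))
    else:
        out = np.where(np.isnan(v), np.nan, (v > threshold).astype(float))
    return grid.like(out)


def ensemble_majority(maps: list[RasterGrid]) -> RasterGrid:
    """Cell-wise majority vote of binary maps (ties count as suitable)."""
    if not maps:
        raise ValueError("no maps")
    stack = np.stack([m.values for m in maps])
    vote = np.nansum(stack, axis=0)
    valid = ~np.all(np.isnan(stack), axis=0)
    out = np.where(valid, (vote >= len(maps) / 2.0).astype(float), np.nan)
    return maps[0].like(out)


def suitable_cells(binary_map: RasterGrid, mask: RasterGrid | None = None) -> int:
    v = binary_map.values
    ok = ~np.isnan(v)
    if mask is not None:
        ok &= ~np.isnan(mask.values)
    return int(np.nansum(v[ok] > 0))


def range_report_from_counts(
    counts: dict[str, int], present: str, study_area_cells: int
) -> pd.DataFrame:
    """Table of suitable cells, % of study area and % range change vs present.

    ``% change = 100 (cells_t - cells_present) / cells_present``; percentages
    are rounded to one decimal place in the report.
    """
    if present not in counts:
        raise ValueError(f"present slice {present!r} missing from counts")
    base = counts[present]
    if base <= 0:
        raise ValueError("zero suitable cells in the present map; change undefined")
    rows = []
    for name, c in counts.items():
        row = {
            "slice": name,
            "suitable_cells": int(c),
            "pct_study_area": round(100.0 * c / study_area_cells, 1),
        }
        if name != present:
            row["pct_range_change"] = round(100.0 * (c - base) / base, 1)
        else:
            row["pct_range_change"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("slice")


def range_report(
    maps: dict[str, RasterGrid],
    present: str,
    mask: RasterGrid | None = None,
) -> pd.DataFrame:
    """Range-change accounting from binary maps per time slice."""
    shapes = {m.values.shape for m in maps.values()}
    if mask is not None:
        shapes.add(mask.values.shape)
    if len(shapes) > 1:
        raise ValueError("maps (and mask) are not congruent")
    counts = {name: suitable_cells(m, mask) for name, m in maps.items()}
    if mask is not None:
        area = int(np.sum(~np.isnan(mask.values)))
    else:
        any_map = next(iter(maps.values()))
        area = int(np.sum(~np.isnan(any_map.values)))
    return range_report_from_counts(counts, present, area)
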