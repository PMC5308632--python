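"""Scratch-wound invasion kinetics: relative wound density and group comparison.

The assay scratches a confluent monolayer (700-800 um wide wound),
optionally sandwiches the cells in Matrigel so that re-population of the
wound requires matrix invasion rather than 2D migration, and images the
well every 2 h for 68 h.  Closure is quantified as *relative wound
density* (RWD):

    rwd(t) = 100 * (w(t) - w(0)) / (c(t) - w(0))

where ``w(t)`` is the cell occupancy inside the wound region (frozen at
t=0) and ``c(t)`` the occupancy of the surrounding cell region.  RWD is
0 at scratch time and 100 when the wound is as dense as the monolayer;
it depends only on occupancy masks, so it is invariant to any uniform
intensity rescaling of the images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class WoundSeries:
    """One well's wound time course.

    ``wound_occupancy`` (w) and ``cell_occupancy`` (c) are cell-covered
    fractions inside / outside the frozen t=0 wound region.
    """

    timepoints: np.ndarray
    wound_occupancy: np.ndarray
    cell_occupancy: np.ndarray
    wound_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.wound_occupancy = np.asarray(self.wound_occupancy, dtype=float)
        self.cell_occupancy = np.asarray(self.cell_occupancy, dtype=float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not (self.timepoints.size == self.wound_occupancy.size == self.cell_occupancy.size):
            raise ValueError("timepoints and occupancies must have equal length")
        for a in (self.wound_occupancy, self.cell_occupancy):
            if np.any((a < -1e-9) | (a > 1 + 1e-9)):
                raise ValueError("occupancies must lie in [0, 1]")
        if self.wound_mask is not None and not np.any(self.wound_mask):
            raise ValueError("wound_mask is empty")


def define_wound(
    frame0: np.ndarray,
    um_per_px: float = 1.0,
    occupancy_threshold: float = 0.5,
    axis: int = 1,
) -> tuple[np.ndarray, float]:
    """Locate the wound band in the t=0 cell mask.

    ``frame0`` is a binary cell mask (or an image already thresholded to
    one).  The wound is the largest contiguous run of low-occupancy
    columns (``axis=1``; rows for ``axis=0``).  Returns the frozen
    boolean wound mask and the band width in microns.
    """
    mask = np.asarray(frame0) > 0
    if mask.ndim != 2:
        raise ValueError("frame0 must be 2-D")
    occ = mask.mean(axis=0 if axis == 1 else 1)
    free = occ < occupancy_threshold * occ.max() if occ.max() > 0 else np.ones_like(occ, bool)
    if not free.any():
        raise ValueError("no cell-free band found: frame is fully confluent")
    # largest run of consecutive free lines
    best_len, best_start, run_len, run_start = 0, 0, 0, 0
    for i, f in enumerate(free):
        if f:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    wound = np.zeros_like(mask)
    sl = slice(best_start, best_start + best_len)
    if axis == 1:
        wound[:, sl] = True
    else:
        wound[sl, :] = True
    return wound, best_len * um_per_px


def occupancy_from_masks(
    cell_masks: Sequence[np.ndarray],
    timepoints: Sequence[float],
    wound_mask: np.ndarray | None = None,
    um_per_px: float = 1.0,
    erode_margin: int = 0,
) -> WoundSeries:
    """Build a WoundSeries from binary cell masks over time.

    The wound region is taken from the first frame unless given; the
    cell region is its complement, optionally eroded by ``erode_margin``
    pixels from the image border to avoid edge effects.
    """
    masks = [np.asarray(m) > 0 for m in cell_masks]
    if wound_mask is None:
        wound_mask, _ = define_wound(masks[0], um_per_px=um_per_px)
    outside = ~wound_mask
    if erode_margin > 0:
        border = np.zeros_like(outside)
        border[erode_margin:-erode_margin, erode_margin:-erode_margin] = True
        outside &= border
    if not outside.any():
        raise ValueError("no cell region left outside the wound mask")
    w = np.array([m[wound_mask].mean() for m in masks])
    c = np.array([m[outside].mean() for m in masks])
    return WoundSeries(np.asarray(timepoints, float), w, c, wound_mask=wound_mask)


def relative_wound_density(series: WoundSeries, overshoot_tolerance: float = 5.0) -> np.ndarray:
    """Percent RWD per timepoint: 100 (w(t) - w(0)) / (c(t) - w(0)).

    Clipped to ``[0, 100 + overshoot_tolerance]``; rwd(0) = 0 by
    construction.  A degenerate denominator (cell region no denser than
    the initial wound) raises.
    """
    w = series.wound_occupancy
    c = series.cell_occupancy
    w0 = w[0]
    denom = c - w0
    if np.any(denom <= 1e-12):
        raise ValueError("degenerate denominator: cell region not denser than initial wound")
    rwd = 100.0 * (w - w0) / denom
    return np.clip(rwd, 0.0, 100.0 + overshoot_tolerance)


def closure_rate_from_rwd(
    timepoints: np.ndarray,
    rwd: np.ndarray,
    t_start: float = 4.0,
    t_end: float = 50.0,
) -> float:
    """(rwd(t_end) - rwd(t_start)) / (t_end - t_start); offset-invariant in rwd."""
    t = np.asarray(timepoints, dtype=float)
    rwd = np.asarray(rwd, dtype=float)
    vals = []
    for tp in (t_start, t_end):
        idx = np.flatnonzero(np.isclose(t, tp))
        if idx.size == 0:
            raise ValueError(f"timepoint {tp} h not present in the series")
        vals.append(rwd[idx[0]])
    return float((vals[1] - vals[0]) / (t_end - t_start))


def closure_rate(
    series: WoundSeries,
    t_start: float = 4.0,
    t_end: float = 50.0,
) -> float:
    """Mean RWD slope (percent/hour) between ``t_start`` and ``t_end``.

    The 4 h start compensates for differences in initial wound size; the
    50 h end precedes the plateau when cells stop increasing closure.
    """
    rwd = relative_wound_density(series)
    return closure_rate_from_rwd(series.timepoints, rwd, t_start, t_end)


def final_closure(series: WoundSeries, t_final: float = 68.0) -> float:
    """RWD (percent) at the endpoint timepoint."""
    rwd = relative_wound_density(series)
    idx = np.flatnonzero(np.isclose(series.timepoints, t_final))
    if idx.size == 0:
        raise ValueError(f"timepoint {t_final} h not present in the series")
    return float(rwd[idx[0]])


def compare_invasion(
    groups: Mapping[str, Sequence[WoundSeries]],
    vector_label: str = "vector",
    alpha: float = 0.05,
    t_start: float = 4.0,
    t_end: float = 50.0,
    t_final: float = 68.0,
) -> pd.DataFrame:
    """Per-group closure kinetics with Tukey HSD significance vs vector.

    Returns one row per group: mean/SD of the 4-50 h closure rate, mean
    final closure at 68 h, and significance flags for each metric from a
    Tukey HSD across all groups (family = all supplied groups).
    """
    from .confirmstats import tukey_hsd

    if vector_label not in groups:
        raise ValueError(f"vector group {vector_label!r} missing")
    for lab, series_list in groups.items():
        if len(series_list) < 2:
            raise ValueError(f"group {lab!r} needs >= 2 replicate wells")
    rates = {lab: np.array(sorted(closure_rate(s, t_start, t_end) for s in ss)) for lab, ss in groups.items()}
    finals = {lab: np.array(sorted(final_closure(s, t_final) for s in ss)) for lab, ss in groups.items()}
    p_rate = tukey_hsd(rates)
    p_final = tukey_hsd(finals)
    rows = []
    for lab in groups:
        rows.append(
            {
                "group": lab,
                "n": len(groups[lab]),
                "closure_rate_mean": rates[lab].mean(),
                "closure_rate_sd": rates[lab].std(ddof=1),
                "final_closure_mean": finals[lab].mean(),
                "final_closure_sd": finals[lab].std(ddof=1),
                "p_rate_vs_vector": 1.0 if lab == vector_label else p_rate[(lab, vector_label)],
                "p_final_vs_vector": 1.0 if lab == vector_label else p_final[(lab, vector_label)],
            }
        )
    df = pd.DataFrame(rows)
    df["rate_significant"] = (df["p_rate_vs_vector"] < alpha) & (df["group"] != vector_label)
    df["final_significant"] = (df["p_final_vs_vector"] < alpha) & (df["group"] != vector_label)
    return df
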