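"""Primary-screen statistics: robust-Z normalization, hit calling and QC.

Each plate is normalized with robust Z-scores computed from its own
sample wells: z = (value - median) / (1.4826 * MAD), where the plate
median and MAD come only from sample wells with more than 100 GFP+
cells.  The 1.4826 consistency constant makes the scaled MAD estimate
the SD under normality, so the z_cut threshold reads in SD-like units.

Hits are called on wells with at least 50 GFP+ cells when any of the
criteria fires (all strict inequalities):

* robust Z of the VIM antibody channel > 15,
* robust Z of the VIM reporter channel > 15,
* raw well mean intensity above 8000 in either channel,
* more than 18% of GFP+ cells VIM+ (antibody channel).

Assay quality is summarized by the Z'-factor and by control-based error
rates: the false-discovery estimate is the fraction of empty-vector
wells that fit hit criteria, the false-negative estimate the fraction of
SNAI2 positive-control wells that do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

MAD_SCALE = 1.4826
CHANNELS = ("vim_a", "vim_r")


@dataclass
class ScreenThresholds:
    """Hit-calling and eligibility cutoffs for the primary screen."""

    z_cut: float = 15.0
    raw_cut: float = 8000.0
    pct_cut: float = 18.0
    min_gfp_cells_score: int = 50
    min_gfp_cells_platestat: int = 100

    def __post_init__(self) -> None:
        for name in ("z_cut", "raw_cut", "pct_cut", "min_gfp_cells_score", "min_gfp_cells_platestat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def scaled_mad(values: np.ndarray) -> float:
    """1.4826 x median absolute deviation from the median."""
    v = np.asarray(values, dtype=float)
    return float(MAD_SCALE * np.median(np.abs(v - np.median(v))))


def plate_stats(
    wells: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
    channels: Sequence[str] = CHANNELS,
) -> pd.DataFrame:
    """Per-plate, per-channel robust location/scale from eligible sample wells.

    Eligible wells are sample wells (controls excluded) with
    ``gfp_pos_count > min_gfp_cells_platestat``.  A plate whose scaled
    MAD is zero, or with no eligible sample wells, is flagged degenerate
    and its wells are excluded from Z-scoring downstream.
    """
    thr = thresholds or ScreenThresholds()
    rows = []
    for plate_id, sub in wells.groupby("plate_id", sort=False):
        eligible = sub[(sub["role"] == "sample") & (sub["gfp_pos_count"] > thr.min_gfp_cells_platestat)]
        row = {"plate_id": plate_id, "n_eligible_wells": len(eligible), "degenerate": len(eligible) == 0}
        for ch in channels:
            col = f"{ch}_well_mean"
            if len(eligible) == 0:
                row[f"{ch}_median"] = np.nan
                row[f"{ch}_scaled_mad"] = np.nan
            else:
                vals = eligible[col].to_numpy(dtype=float)
                row[f"{ch}_median"] = float(np.median(vals))
                row[f"{ch}_scaled_mad"] = scaled_mad(vals)
                if row[f"{ch}_scaled_mad"] == 0.0:
                    row["degenerate"] = True
        rows.append(row)
    return pd.DataFrame(rows).set_index("plate_id")


def robust_z(value, median: float, scale: float):
    """Robust Z-score (value - median) / scaled_mad; NaN when degenerate."""
    if not np.isfinite(scale) or scale <= 0:
        return np.full_like(np.asarray(value, dtype=float), np.nan)
    return (np.asarray(value, dtype=float) - median) / scale


def add_z_scores(
    wells: pd.DataFrame,
    stats: pd.DataFrame,
    channels: Sequence[str] = CHANNELS,
) -> pd.DataFrame:
    """Attach per-channel robust Z columns (``z_a``, ``z_r``) to the well table."""
    out = wells.copy()
    for ch in channels:
        zcol = f"z_{ch[-1]}"
        out[zcol] = np.nan
        for plate_id, sub in out.groupby("plate_id", sort=False):
            if plate_id not in stats.index:
                continue
            st = stats.loc[plate_id]
            if bool(st["degenerate"]):
                continue
            z = robust_z(sub[f"{ch}_well_mean"].to_numpy(), st[f"{ch}_median"], st[f"{ch}_scaled_mad"])
            out.loc[sub.index, zcol] = z
    return out


def zprime_from_stats(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Z'-factor 1 - 3 (sd_pos + sd_neg) / |mu_pos - mu_neg|.

    Equal group means make the statistic undefined; -inf is returned as
    a sentinel (the assay has no separation whatsoever).
    """
    delta = abs(mu_pos - mu_neg)
    if delta == 0:
        return float("-inf")
    return 1.0 - 3.0 * (sd_pos + sd_neg) / delta


def zprime(pos_values: Sequence[float], neg_values: Sequence[float]) -> float:
    """Z'-factor from raw control-well values (sample means and SDs, ddof=1)."""
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 values per group")
    return zprime_from_stats(pos.mean(), pos.std(ddof=1), neg.mean(), neg.std(ddof=1))


def control_zprime(wells: pd.DataFrame, channels: Sequence[str] = CHANNELS) -> dict[str, float]:
    """Per-channel Z'-factor from the positive and vector control wells."""
    out = {}
    pos = wells[wells["role"] == "positive"]
    neg = wells[wells["role"] == "vector"]
    for ch in channels:
        out[ch] = zprime(pos[f"{ch}_well_mean"], neg[f"{ch}_well_mean"])
    return out


def call_hits(
    wells_with_z: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
) -> pd.DataFrame:
    """Apply the four-criterion hit rule to a Z-scored well table.

    A well is eligible when ``gfp_pos_count >= 50``; it is a hit when it
    is eligible and any criterion fires (strict inequalities): z_a > 15,
    z_r > 15, raw mean > 8000 in either channel, or > 18% VIM+ cells in
    the antibody channel.  NaN scores never fire a criterion.
    """
    thr = thresholds or ScreenThresholds()
    out = wells_with_z.copy()
    z_a = out["z_a"].to_numpy(dtype=float)
    z_r = out["z_r"].to_numpy(dtype=float)
    raw_a = out["vim_a_well_mean"].to_numpy(dtype=float)
    raw_r = out["vim_r_well_mean"].to_numpy(dtype=float)
    pct_a = out["pct_vim_pos_a"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out["eligible"] = out["gfp_pos_count"].to_numpy() >= thr.min_gfp_cells_score
        out["za_hit"] = z_a > thr.z_cut
        out["zr_hit"] = z_r > thr.z_cut
        out["raw_hit"] = (raw_a > thr.raw_cut) | (raw_r > thr.raw_cut)
        out["pct_hit"] = pct_a > thr.pct_cut
    out["hit"] = out["eligible"] & (out["za_hit"] | out["zr_hit"] | out["raw_hit"] | out["pct_hit"])
    return out


@dataclass
class QualityMetrics:
    """Control-based screen error rates."""

    fdr_estimate: float
    fnr_estimate: float
    n_neg_flagged: int
    n_neg_total: int
    n_pos_missed: int
    n_pos_total: int


def control_error_rates(hitcalls: pd.DataFrame) -> QualityMetrics:
    """Error rates from control wells of a hit-called table.

    FDR estimate = flagged vector wells / total vector wells (mock wells
    are excluded from the denominator); FNR estimate = positive-control
    wells that do not fit hit criteria / total positive wells.
    """
    neg = hitcalls[hitcalls["role"] == "vector"]
    pos = hitcalls[hitcalls["role"] == "positive"]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("need >= 1 vector and >= 1 positive control well")
    n_neg_flagged = int(neg["hit"].sum())
    n_pos_missed = int((~pos["hit"].astype(bool)).sum())
    return QualityMetrics(
        fdr_estimate=n_neg_flagged / len(neg),
        fnr_estimate=n_pos_missed / len(pos),
        n_neg_flagged=n_neg_flagged,
        n_neg_total=len(neg),
        n_pos_missed=n_pos_missed,
        n_pos_total=len(pos),
    )


def qc_correlations(
    wells: pd.DataFrame,
    score_cols: Sequence[str] = ("z_a", "z_r"),
    count_cols: Sequence[str] = ("cell_count", "gfp_pos_count"),
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman correlation of VIM scores against well cell/transduction counts.

    Permutation p-values (two-sided) guard against distributional
    assumptions; constant columns are flagged with NaN correlation.
    Used to verify that hit scores do not simply track cell number or
    transduction rate.
    """
    if len(wells) < 10:
        raise ValueError("need >= 10 wells")
    rng = np.random.default_rng(seed)
    rows = []
    for sc in score_cols:
        for cc in count_cols:
            sub = wells[[sc, cc]].dropna()
            x = sub[sc].to_numpy(dtype=float)
            y = sub[cc].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"score": sc, "count": cc, "spearman_r": np.nan, "p_perm": np.nan, "constant": True})
                continue
            r_obs = sps.spearmanr(x, y).statistic
            perm = np.empty(n_perm)
            for i in range(n_perm):
                perm[i] = sps.spearmanr(x, rng.permutation(y)).statistic
            p = (1 + np.sum(np.abs(perm) >= abs(r_obs))) / (n_perm + 1)
            rows.append({"score": sc, "count": cc, "spearman_r": float(r_obs), "p_perm": float(p), "constant": False})
    return pd.DataFrame(rows)


def run_primary_screen(
    wells: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, QualityMetrics]:
    """Full primary-screen pass: plate stats -> Z-scores -> hit calls -> QC."""
    thr = thresholds or ScreenThresholds()
    stats = plate_stats(wells, thr)
    scored = add_z_scores(wells, stats)
    hits = call_hits(scored, thr)
    quality = control_error_rates(hits)
    return hits, stats, quality
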