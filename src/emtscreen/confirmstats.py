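"""Confirmation-screen statistics.

The secondary screen re-tests putative hits in triplicate wells and
classifies them against the plate controls:

* ``confirmed.HC`` — triplicate mean significantly different from the
  empty-vector pool (Tukey HSD, p < 0.01) on either readout (well mean
  total VIM antibody intensity, or percent VIM+ cells);
* ``confirmed`` — triplicate mean inside the SNAI2 positive-control
  interval (99.9% by default) with at least 2 of the 3 wells outside the
  same-level vector interval;
* ``not_confirmed`` otherwise.

The "confidence interval" rule tests *individual well values* ("2 out of
3 wells outside"), so it is implemented as a prediction-style interval
mean +/- t * SD * sqrt(1 + 1/n) rather than an interval on the mean.

The module also houses the Tukey HSD surface reused by the MCF10A
VIM-area comparison and the invasion kinetics, and the qPCR delta-Ct
marker-ratio calculation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

CONFIRMED_HC = "confirmed.HC"
CONFIRMED = "confirmed"
NOT_CONFIRMED = "not_confirmed"

MESENCHYMAL_MARKERS = ("CDH2", "SNAI2", "TWIST1", "VIM", "ZEB2")
EPITHELIAL_MARKER = "CDH1"
REFERENCE_GENE = "RPLP0"


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> dict[tuple[str, str], float]:
    """Tukey honest-significant-difference adjusted p-values for all pairs.

    The family is exactly the supplied groups; unequal group sizes use
    the Tukey-Kramer extension.  Returns a dict keyed by both (a, b) and
    (b, a) orderings.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    for lab, a in zip(labels, arrays):
        if a.size < 2:
            raise ValueError(f"group {lab!r} needs >= 2 values")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")
    res = sps.tukey_hsd(*arrays)
    out: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(labels)), 2):
        p = float(res.pvalue[i, j])
        out[(labels[i], labels[j])] = p
        out[(labels[j], labels[i])] = p
    return out


def control_interval(
    control_values: Sequence[float],
    level: float = 0.999,
) -> tuple[float, float]:
    """Prediction-style interval for a single well value from a control pool.

    mean +/- t_{(1+level)/2, n-1} * SD * sqrt(1 + 1/n).  Contains the
    control mean for every level > 0; width is increasing in level.
    """
    x = np.asarray(control_values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 control values")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    m = x.mean()
    sd = x.std(ddof=1)
    half = sps.t.ppf((1.0 + level) / 2.0, x.size - 1) * sd * np.sqrt(1.0 + 1.0 / x.size)
    return float(m - half), float(m + half)


@dataclass
class ConfirmationCall:
    orf_id: str
    cls: str
    tukey_p_vs_vector: float
    within_snai2_interval: bool
    n_wells_outside_vector_interval: int


def classify(
    orf_id: str,
    orf_values: Mapping[str, Sequence[float]],
    vector_values: Mapping[str, Sequence[float]],
    snai2_values: Mapping[str, Sequence[float]],
    interval_level: float = 0.999,
    alpha: float = 0.01,
) -> ConfirmationCall:
    """Classify one ORF's triplicate against the vector and SNAI2 pools.

    ``orf_values`` etc. map metric name -> well values; each metric is
    tested independently and the hit tiers are "and/or" across metrics.
    The Tukey family per metric is {ORF, vector, SNAI2}.
    """
    best_p = 1.0
    within_flag = False
    outside_count = 0
    confirmed_rule = False
    for m in orf_values:
        orf = np.asarray(orf_values[m], dtype=float)
        vec = np.asarray(vector_values[m], dtype=float)
        pos = np.asarray(snai2_values[m], dtype=float)
        if orf.size != 3:
            raise ValueError(f"metric {m!r}: expected exactly 3 triplicate wells, got {orf.size}")
        p = tukey_hsd({"orf": orf, "vector": vec, "snai2": pos})[("orf", "vector")]
        best_p = min(best_p, p)
        lo_s, hi_s = control_interval(pos, interval_level)
        lo_v, hi_v = control_interval(vec, interval_level)
        within = lo_s <= orf.mean() <= hi_s
        outside = int(np.sum((orf < lo_v) | (orf > hi_v)))
        if within and outside >= 2:
            # both parts of the confirmed rule must hold on the same metric
            confirmed_rule = True
            within_flag, outside_count = True, max(outside_count, outside)
        elif not confirmed_rule:
            within_flag = within_flag or within
            outside_count = max(outside_count, outside)
    if best_p < alpha:
        cls = CONFIRMED_HC
    elif confirmed_rule:
        cls = CONFIRMED
    else:
        cls = NOT_CONFIRMED
    return ConfirmationCall(
        orf_id=orf_id,
        cls=cls,
        tukey_p_vs_vector=best_p,
        within_snai2_interval=within_flag,
        n_wells_outside_vector_interval=outside_count,
    )


def classify_screen(
    triplicates: Mapping[str, Mapping[str, Sequence[float]]],
    vector_values: Mapping[str, Sequence[float]],
    snai2_values: Mapping[str, Sequence[float]],
    interval_level: float = 0.999,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Classify every ORF of a confirmation screen; one row per ORF."""
    rows = []
    for orf, vals in triplicates.items():
        call = classify(orf, vals, vector_values, snai2_values, interval_level, alpha)
        rows.append(
            {
                "orf_id": call.orf_id,
                "class": call.cls,
                "tukey_p_vs_vector": call.tukey_p_vs_vector,
                "within_snai2_interval": call.within_snai2_interval,
                "n_wells_outside_vector_interval": call.n_wells_outside_vector_interval,
            }
        )
    return pd.DataFrame(rows)


def vim_area_compare(
    well_areas: Mapping[str, Sequence[float]],
    vector_label: str = "vector",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare per-well mean VIM+ area (GFP+ cells) of each ORF against vector.

    ``well_areas`` maps group label -> per-well mean VIM-positive area
    values (wells with zero GFP+ cells must already be excluded).  Tukey
    HSD across all supplied groups; returns group means and the adjusted
    p / significance flag vs the vector group.
    """
    if vector_label not in well_areas:
        raise ValueError(f"vector group {vector_label!r} missing")
    clean = {}
    for lab, vals in well_areas.items():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 usable wells")
        clean[lab] = v
    p = tukey_hsd(clean)
    rows = []
    for lab, v in clean.items():
        pv = 1.0 if lab == vector_label else p[(lab, vector_label)]
        rows.append(
            {
                "group": lab,
                "n_wells": v.size,
                "mean_vim_area": v.mean(),
                "sd_vim_area": v.std(ddof=1),
                "p_vs_vector": pv,
                "significant": bool(pv < alpha) and lab != vector_label,
            }
        )
    return pd.DataFrame(rows)


def marker_ratio(
    panel: pd.DataFrame,
    reference: str = REFERENCE_GENE,
    epithelial: str = EPITHELIAL_MARKER,
    mesenchymal: Sequence[str] = MESENCHYMAL_MARKERS,
    efficiency: float = 2.0,
    ct_dispersion_guard: float = 1.5,
) -> pd.DataFrame:
    """Relative expression and mesenchymal/epithelial ratios from a qPCR panel.

    ``panel`` has columns ``sample, gene, replicate, ct``.  Per gene and
    sample the relative level is ``efficiency ** -(Ct_gene - Ct_ref)``
    computed per replicate (paired by replicate index) and averaged; the
    mesenchymal/epithelial ratio is relative(marker) / relative(CDH1).
    Ratios are invariant to adding a constant to every Ct of a sample.
    Replicate Cts spreading more than ``ct_dispersion_guard`` cycles
    raise, as such spreads indicate a failed reaction.
    """
    required = {"sample", "gene", "replicate", "ct"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    if (panel["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    rows = []
    for sample, sub in panel.groupby("sample", sort=False):
        genes = sub.pivot_table(index="replicate", columns="gene", values="ct")
        if reference not in genes.columns:
            raise ValueError(f"sample {sample!r}: reference gene {reference!r} missing")
        spread = genes.max() - genes.min()
        if (spread > ct_dispersion_guard).any():
            bad = spread[spread > ct_dispersion_guard].index.tolist()
            raise ValueError(f"sample {sample!r}: replicate Ct spread exceeds guard for {bad}")
        rel = (float(efficiency) ** -(genes.sub(genes[reference], axis=0))).mean()
        if rel.isna().any():
            raise ValueError(f"sample {sample!r}: all replicates failed for some gene")
        for marker in mesenchymal:
            if marker in rel.index and epithelial in rel.index:
                rows.append(
                    {
                        "sample": sample,
                        "marker": marker,
                        "relative_to_reference": rel[marker],
                        "epithelial_relative": rel[epithelial],
                        "mes_epi_ratio": rel[marker] / rel[epithelial],
                    }
                )
    return pd.DataFrame(rows)
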