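"""Expression-matrix analyses for screen hits and EMT markers.

Operates on a genes x samples log-ratio matrix with tumour-subtype
labels (basal, lumA, lumB, HER2, normal-like) plus normal-tissue
controls: per-subtype quantile summaries, the count of tumours whose
expression exceeds the normal-tissue maximum, and Spearman correlation
matrices between screen hits and the canonical EMT marker panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EMT_MARKERS = ("CDH1", "CDH2", "VIM", "SNAI1", "SNAI2", "SOX9", "TCF3", "TCF4", "TWIST1", "ZEB1", "ZEB2")
SUBTYPES = ("basal", "lumA", "lumB", "HER2", "normal-like", "normal")
NORMAL_LABEL = "normal"


@dataclass
class ExpressionSet:
    """A genes x samples matrix with subtype labels per sample."""

    expr: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.expr.columns.equals(self.labels.index):
            if set(self.expr.columns) != set(self.labels.index):
                raise ValueError("labels must cover exactly the matrix samples")
            self.labels = self.labels.loc[self.expr.columns]
        if self.expr.index.duplicated().any():
            raise ValueError("gene identifiers must be unique")


@dataclass
class CorrMatrix:
    """Symmetric Spearman correlation matrix with matching p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def _pairwise_n(x: pd.DataFrame) -> pd.DataFrame:
    present = x.notna().astype(float)
    n = present @ present.T
    return n


def spearman_matrix(
    eset: ExpressionSet,
    genes: Sequence[str],
    tumours_only: bool = False,
) -> CorrMatrix:
    """Spearman correlation over all pairs of ``genes``.

    Ties get average ranks; missing values are pairwise-deleted; the
    two-sided p-value uses the large-sample t approximation
    t = r sqrt((n-2)/(1-r^2)).  Constant genes yield NaN entries.
    """
    missing = [g for g in genes if g not in eset.expr.index]
    if missing:
        raise KeyError(f"genes absent from the matrix: {missing}")
    sub = eset.expr.loc[list(genes)]
    if tumours_only:
        sub = sub.loc[:, (eset.labels != NORMAL_LABEL).to_numpy()]
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    r = sub.T.corr(method="spearman")
    n = _pairwise_n(sub)
    with np.errstate(divide="ignore", invalid="ignore"):
        rv = r.to_numpy(dtype=float)
        nv = n.to_numpy(dtype=float)
        t = rv * np.sqrt((nv - 2.0) / (1.0 - rv**2))
        p = 2.0 * sps.t.sf(np.abs(t), np.maximum(nv - 2.0, 1.0))
        p[np.abs(rv) >= 1.0] = 0.0
    p_df = pd.DataFrame(p, index=r.index, columns=r.columns)
    np.fill_diagonal(p_df.values, 0.0)
    return CorrMatrix(r=r, p=p_df, n=n)


def above_normal_incidence(eset: ExpressionSet, gene: str) -> int:
    """Tumour samples whose expression strictly exceeds the normal-tissue maximum."""
    if gene not in eset.expr.index:
        raise KeyError(f"gene {gene!r} absent")
    normal_mask = (eset.labels == NORMAL_LABEL).to_numpy()
    if not normal_mask.any():
        raise ValueError("no normal samples present")
    vals = eset.expr.loc[gene].to_numpy(dtype=float)
    normal_max = np.nanmax(vals[normal_mask])
    tumour = vals[~normal_mask]
    return int(np.nansum(tumour > normal_max))


def subtype_summary(eset: ExpressionSet, gene: str) -> pd.DataFrame:
    """Median / quartiles / n per subtype label (type-7 linear-interpolation quantiles)."""
    if gene not in eset.expr.index:
        raise KeyError(f"gene {gene!r} absent")
    vals = eset.expr.loc[gene]
    rows = []
    for lab in pd.unique(eset.labels):
        v = vals[(eset.labels == lab).to_numpy()].dropna().to_numpy(dtype=float)
        if v.size == 0:
            rows.append({"subtype": lab, "n": 0, "median": np.nan, "q25": np.nan, "q75": np.nan, "empty": True})
            continue
        rows.append(
            {
                "subtype": lab,
                "n": int(v.size),
                "median": float(np.quantile(v, 0.5)),
                "q25": float(np.quantile(v, 0.25)),
                "q75": float(np.quantile(v, 0.75)),
                "empty": False,
            }
        )
    return pd.DataFrame(rows)


def hit_marker_report(
    corr: CorrMatrix,
    hits: Sequence[str],
    markers: Sequence[str] = EMT_MARKERS,
    r_cut: float = 0.1,
    order_by: str = "VIM",
) -> pd.DataFrame:
    """Per-hit correlation with each EMT marker, ordered by correlation with VIM.

    A hit-marker pair is called ``positive`` when r > r_cut, ``negative``
    when r < -r_cut, else ``none``.  Rows are sorted by the correlation
    with ``order_by`` (descending), so the output order is independent of
    the input gene order.
    """
    for g in list(hits) + list(markers):
        if g not in corr.r.index:
            raise KeyError(f"gene {g!r} absent from the correlation matrix")
    rows = []
    for h in hits:
        row = {"hit": h}
        for m in markers:
            r = float(corr.r.loc[h, m])
            row[f"r_{m}"] = r
            row[f"call_{m}"] = "positive" if r > r_cut else ("negative" if r < -r_cut else "none")
        rows.append(row)
    df = pd.DataFrame(rows)
    if order_by in markers:
        df = df.sort_values(f"r_{order_by}", ascending=False, kind="mergesort").reset_index(drop=True)
    return df
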