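"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written directly from the defining formula and shares no
code with the package path it validates.
"""

import itertools

import numpy as np
from scipy.stats import rankdata, studentized_range, t as t_dist


def spearman_bruteforce(x, y):
    """Spearman r as Pearson on average ranks, from the definitions."""
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def tukey_bruteforce(groups):
    """Tukey(-Kramer) HSD adjusted p-values straight from the q statistic.

    q_ij = |mean_i - mean_j| / sqrt(s2/2 (1/n_i + 1/n_j)); p = SF of the
    studentized range with k groups and N-k error df.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df = n_total - k
    s2 = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        ai, aj = arrays[i], arrays[j]
        se = np.sqrt(s2 / 2.0 * (1.0 / ai.size + 1.0 / aj.size))
        q = abs(ai.mean() - aj.mean()) / se
        p = float(studentized_range.sf(q, k, df))
        out[(labels[i], labels[j])] = p
        out[(labels[j], labels[i])] = p
    return out


def prediction_interval_bruteforce(values, level):
    """mean +/- t-quantile * sd * sqrt(1 + 1/n), computed directly."""
    x = np.asarray(values, dtype=float)
    n = x.size
    q = t_dist.ppf((1.0 + level) / 2.0, n - 1)
    half = q * x.std(ddof=1) * np.sqrt(1.0 + 1.0 / n)
    return x.mean() - half, x.mean() + half


def nearest_region_bruteforce(nuclei, max_radius):
    """Per-pixel nearest-labeled-region assignment by exhaustive search.

    For every background pixel, the Euclidean distance to every pixel of
    every labeled region is examined; the pixel is assigned to the region
    with minimal distance (lowest label on exact ties) if that distance
    is <= max_radius.
    """
    nuclei = np.asarray(nuclei)
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    coords = {lab: np.argwhere(nuclei == lab) for lab in labels}
    out = np.zeros_like(nuclei, dtype=np.int32)
    h, w = nuclei.shape
    for r in range(h):
        for c in range(w):
            if nuclei[r, c] != 0:
                continue
            best_d, best_lab = np.inf, 0
            for lab in labels:  # ascending: strict < keeps lowest label on ties
                pts = coords[lab]
                d = np.sqrt(((pts - (r, c)) ** 2).sum(axis=1).min())
                if d < best_d:
                    best_d, best_lab = d, lab
            if best_d <= max_radius:
                out[r, c] = best_lab
    return out


def delta_ct_bruteforce(panel, reference, marker, epithelial, efficiency=2.0):
    """Mesenchymal/epithelial expression ratio for one sample, from scratch."""
    rel = {}
    for gene in (marker, epithelial):
        ratios = []
        for rep in sorted(panel["replicate"].unique()):
            ct_g = panel[(panel.gene == gene) & (panel.replicate == rep)]["ct"].iloc[0]
            ct_r = panel[(panel.gene == reference) & (panel.replicate == rep)]["ct"].iloc[0]
            ratios.append(efficiency ** (-(ct_g - ct_r)))
        rel[gene] = np.mean(ratios)
    return rel[marker] / rel[epithelial]
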