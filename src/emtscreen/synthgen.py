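"""Synthetic inputs for every stage of the EMT screen pipeline.

Everything the downstream modules consume can be generated here with a
known ground truth: 96-well plate layouts with the standard control
complement (4 empty-vector, 2 mock, 2 SNAI2-positive wells per plate),
per-well screen measurements with heavy-tailed null noise and planted
ORF effects, rendered multichannel field images, block-correlated
expression matrices with tumour-subtype structure, and scratch-wound
occupancy time courses.

Conventions
-----------
* Well-level VIM intensities are drawn as ``location + scale * L`` where
  ``L`` is a standardized lognormal variate (median 0, scaled MAD 1).
  The lognormal choice gives a heavy right tail so that rare bright
  debris-like outliers occur in null wells, which is exactly the failure
  mode robust median/MAD normalization has to absorb.
* Effect sizes are expressed in multiples of the null scale (scaled-MAD
  units), so a planted effect of 20 shifts a well ~20 robust-Z units.
* Every generator is a pure function of its arguments including the
  seed; the same seed gives bit-identical output.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .woundinvasion import WoundSeries

MAD_SCALE = 1.4826

ROWS = "ABCDEFGH"
COLS = range(1, 13)
ROLES = ("sample", "vector", "mock", "positive")
N_VECTOR = 4
N_MOCK = 2
N_POSITIVE = 2
WELLS_PER_PLATE = 96
SAMPLES_PER_PLATE = WELLS_PER_PLATE - N_VECTOR - N_MOCK - N_POSITIVE

CHANNEL_ORDER = ("dna", "gfp", "vim_r", "vim_a")

SUBTYPES = ("basal", "lumA", "lumB", "HER2", "normal-like", "normal")


# ---------------------------------------------------------------------------
# plate layouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Well:
    row: str
    col: int
    role: str
    orf_id: str | None

    @property
    def name(self) -> str:
        return f"{self.row}{self.col:02d}"


@dataclass
class PlateLayout:
    plate_id: str
    wells: list[Well]

    def validate(self) -> None:
        if len(self.wells) != WELLS_PER_PLATE:
            raise ValueError(f"plate {self.plate_id}: {len(self.wells)} wells, expected {WELLS_PER_PLATE}")
        positions = {(w.row, w.col) for w in self.wells}
        if len(positions) != WELLS_PER_PLATE:
            raise ValueError(f"plate {self.plate_id}: duplicate well positions")
        counts = {role: sum(w.role == role for w in self.wells) for role in ROLES}
        expected = {"vector": N_VECTOR, "mock": N_MOCK, "positive": N_POSITIVE, "sample": SAMPLES_PER_PLATE}
        if counts != expected:
            raise ValueError(f"plate {self.plate_id}: role counts {counts} != {expected}")
        for w in self.wells:
            if w.role == "sample" and w.orf_id is None:
                raise ValueError(f"plate {self.plate_id} well {w.name}: sample well without ORF")
            if w.role != "sample" and w.orf_id is not None:
                raise ValueError(f"plate {self.plate_id} well {w.name}: control well with ORF")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plate_id": self.plate_id,
                "well": [w.name for w in self.wells],
                "row": [w.row for w in self.wells],
                "col": [w.col for w in self.wells],
                "role": [w.role for w in self.wells],
                "orf_id": [w.orf_id for w in self.wells],
            }
        )


def make_layouts(
    n_plates: int,
    orf_ids: Sequence[str],
    seed: int,
    recycle: bool = False,
) -> list[PlateLayout]:
    """Build ``n_plates`` 96-well layouts with randomized control positions.

    Each plate carries 4 empty-vector wells, 2 mock wells and 2
    SNAI2-positive wells; the remaining 88 wells receive one ORF each,
    consumed from ``orf_ids`` in order.  When ``recycle`` is true the ORF
    list wraps around instead of raising when exhausted.
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    if len(orf_ids) == 0:
        raise ValueError("orf_ids must be non-empty")
    needed = n_plates * SAMPLES_PER_PLATE
    if len(orf_ids) < needed and not recycle:
        raise ValueError(
            f"need {needed} ORF ids for {n_plates} plates, got {len(orf_ids)} (pass recycle=True to reuse)"
        )
    rng = np.random.default_rng(seed)
    orf_iter = itertools.cycle(orf_ids) if recycle else iter(orf_ids)
    positions = [(r, c) for r in ROWS for c in COLS]
    layouts = []
    for p in range(n_plates):
        order = rng.permutation(WELLS_PER_PLATE)
        control_idx = order[: N_VECTOR + N_MOCK + N_POSITIVE]
        roles = {}
        for i in control_idx[:N_VECTOR]:
            roles[i] = "vector"
        for i in control_idx[N_VECTOR : N_VECTOR + N_MOCK]:
            roles[i] = "mock"
        for i in control_idx[N_VECTOR + N_MOCK :]:
            roles[i] = "positive"
        wells = []
        for i, (r, c) in enumerate(positions):
            role = roles.get(i, "sample")
            orf = next(orf_iter) if role == "sample" else None
            wells.append(Well(r, c, role, orf))
        layout = PlateLayout(plate_id=f"P{p + 1:03d}", wells=wells)
        layout.validate()
        layouts.append(layout)
    return layouts


def layouts_to_frame(layouts: Sequence[PlateLayout]) -> pd.DataFrame:
    return pd.concat([lay.to_frame() for lay in layouts], ignore_index=True)


# ---------------------------------------------------------------------------
# effect model and well-level simulation
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=64)
def lognormal_scaled_mad(sigma: float) -> float:
    """Population scaled MAD (1.4826 x MAD) of ``exp(sigma * Z)`` (median 1)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    f = lambda d: sps.lognorm.cdf(1 + d, sigma) - sps.lognorm.cdf(max(1 - d, 0.0), sigma) - 0.5
    d = optimize.brentq(f, 1e-9, 1e4)
    return MAD_SCALE * d


def lognormal_sd(sigma: float) -> float:
    """Population SD of ``exp(sigma * Z)``."""
    return float(np.sqrt((np.exp(sigma**2) - 1.0) * np.exp(sigma**2)))


@dataclass
class EffectModel:
    """Generative parameters for well-level screen measurements.

    ``effect_size`` maps ORF id -> channel -> shift in multiples of the
    null scale (scaled-MAD units); unlisted ORFs are null.  The vector
    well VIM+ cell fraction is calibrated so that across wells it has
    mean ``vim_pos_fraction_null_mean`` and SD ``vim_pos_fraction_null_sd``
    (defaults 1.7% and 2.5%, the observed null behaviour of the assay).
    """

    null_location: Mapping[str, float] = field(default_factory=lambda: {"vim_a": 2000.0, "vim_r": 1500.0})
    null_scale: Mapping[str, float] = field(default_factory=lambda: {"vim_a": 250.0, "vim_r": 200.0})
    log_sigma: float = 0.9
    effect_size: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    positive_effect: Mapping[str, float] = field(default_factory=lambda: {"vim_a": 25.0, "vim_r": 25.0})
    vim_pos_fraction_null_mean: float = 0.017
    vim_pos_fraction_null_sd: float = 0.025
    vim_pos_fraction_hits: Mapping[str, float] = field(default_factory=dict)
    positive_vim_pos_fraction: float = 0.45
    transduction_rate: float = 0.30
    cells_per_well_mean: float = 1000.0
    count_dispersion: float = 0.20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in [
            ("vim_pos_fraction_null_mean", self.vim_pos_fraction_null_mean),
            ("vim_pos_fraction_null_sd", self.vim_pos_fraction_null_sd),
            ("positive_vim_pos_fraction", self.positive_vim_pos_fraction),
            ("transduction_rate", self.transduction_rate),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name}={frac} outside [0, 1]")
        for frac in self.vim_pos_fraction_hits.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("per-hit vim_pos_fraction outside [0, 1]")
        if any(s <= 0 for s in self.null_scale.values()) or self.log_sigma <= 0:
            raise ValueError("scales must be > 0")
        if self.cells_per_well_mean <= 0:
            raise ValueError("cells_per_well_mean must be > 0")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.null_location)

    @property
    def null_sd_over_mad(self) -> float:
        """Ratio of null SD to null scaled MAD; converts SD-unit effects to scale units."""
        return lognormal_sd(self.log_sigma) / lognormal_scaled_mad(self.log_sigma)

    def with_effects(self, effect_size: Mapping[str, Mapping[str, float]], **fracs) -> "EffectModel":
        return replace(self, effect_size=dict(effect_size), **fracs)


def _standardized_heavy_tail(rng: np.random.Generator, size, sigma: float) -> np.ndarray:
    """Lognormal variate standardized to median 0, scaled MAD 1."""
    return (rng.lognormal(0.0, sigma, size) - 1.0) / lognormal_scaled_mad(sigma)


def _fraction_lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _null_fraction_per_well(model: EffectModel, rng: np.random.Generator, size: int) -> np.ndarray:
    """Per-well latent VIM+ probability for null wells.

    The between-well spread is chosen so that after binomial sampling at
    the expected GFP+ count the observed fraction has the target mean/SD.
    """
    n_gfp = model.cells_per_well_mean * model.transduction_rate
    m = model.vim_pos_fraction_null_mean
    binom_var = m * (1 - m) / max(n_gfp, 1.0)
    between_var = max(model.vim_pos_fraction_null_sd**2 - binom_var, 1e-8)
    mu, sig = _fraction_lognormal_params(m, np.sqrt(between_var))
    return np.clip(rng.lognormal(mu, sig, size), 0.0, 1.0)


def simulate_wells(layouts: Sequence[PlateLayout], model: EffectModel) -> pd.DataFrame:
    """Simulate the per-well screen table for ``layouts`` under ``model``.

    Returns one row per well with cell counts, GFP+ counts, per-channel
    well mean/total VIM intensity, percent VIM+ cells, and the
    ground-truth ``true_hit`` label (sample wells carrying a non-zero
    planted effect).
    """
    frame = layouts_to_frame(layouts)
    n = len(frame)
    rng = np.random.default_rng(model.rng_seed)

    mult = rng.lognormal(0.0, model.count_dispersion, n)
    cell_count = rng.poisson(model.cells_per_well_mean * mult)
    cell_count = np.maximum(cell_count, 1)
    gfp_pos = rng.binomial(cell_count, model.transduction_rate)
    # mock wells carry no GFP construct: a handful of autofluorescent cells only
    is_mock = (frame["role"] == "mock").to_numpy()
    gfp_pos[is_mock] = rng.poisson(2.0, is_mock.sum())

    role = frame["role"].to_numpy()
    orf = frame["orf_id"].to_numpy(dtype=object)

    out = frame.copy()
    out["cell_count"] = cell_count
    out["gfp_pos_count"] = gfp_pos

    true_hit = np.zeros(n, dtype=bool)
    for ch in model.channels:
        loc = model.null_location[ch]
        scale = model.null_scale[ch]
        shift = np.zeros(n)
        for i in range(n):
            if role[i] == "positive":
                shift[i] = model.positive_effect.get(ch, 0.0)
            elif role[i] == "sample" and orf[i] in model.effect_size:
                shift[i] = model.effect_size[orf[i]].get(ch, 0.0)
                if shift[i] != 0.0:
                    true_hit[i] = True
        L = _standardized_heavy_tail(rng, n, model.log_sigma)
        value = loc + scale * (L + shift)
        value = np.maximum(value, 0.0)
        out[f"{ch}_well_mean"] = value
        out[f"{ch}_well_total"] = value * np.maximum(gfp_pos, 1)

        p = _null_fraction_per_well(model, rng, n)
        for i in range(n):
            if role[i] == "positive":
                p[i] = model.positive_vim_pos_fraction
            elif role[i] == "sample" and orf[i] in model.vim_pos_fraction_hits:
                p[i] = model.vim_pos_fraction_hits[orf[i]]
                true_hit[i] = True
        vim_pos = rng.binomial(np.maximum(gfp_pos, 1), np.clip(p, 0, 1))
        pct = np.where(gfp_pos > 0, 100.0 * vim_pos / np.maximum(gfp_pos, 1), np.nan)
        out[f"pct_vim_pos_{ch[-1]}"] = pct

    out["true_hit"] = true_hit
    return out


def simulate_screen(
    n_plates: int = 8,
    n_hits: int = 16,
    effect: float = 20.0,
    effect_channel: str = "vim_a",
    seed: int = 0,
    model: EffectModel | None = None,
) -> tuple[pd.DataFrame, EffectModel]:
    """Convenience wrapper: layouts + planted hits + well table in one call.

    ``effect`` is in null-scale (scaled-MAD) units on ``effect_channel``.
    The planted hit ORFs are spread evenly across plates.
    """
    rng = np.random.default_rng(seed)
    n_orfs = n_plates * SAMPLES_PER_PLATE
    orf_ids = [f"ORF{i:05d}" for i in range(n_orfs)]
    hit_orfs = list(rng.choice(orf_ids, size=n_hits, replace=False)) if n_hits else []
    effects = {o: {effect_channel: effect} for o in hit_orfs}
    base = model if model is not None else EffectModel()
    mdl = replace(base, effect_size=effects, rng_seed=int(rng.integers(2**31 - 1)))
    layouts = make_layouts(n_plates, orf_ids, seed=int(rng.integers(2**31 - 1)))
    wells = simulate_wells(layouts, mdl)
    return wells, mdl


def null_flag_probability(
    model: EffectModel,
    thresholds,
    n_mc: int = 200_000,
    seed: int = 1,
) -> float:
    """Monte-Carlo probability that a null well satisfies the hit criteria.

    Samples the generative null directly (population location/scale, so
    robust Z equals the standardized variate) and applies the screen's
    criteria.  Serves as the independent expectation for the vector-well
    flag rate of a simulated screen.
    """
    rng = np.random.default_rng(seed)
    hit = np.zeros(n_mc, dtype=bool)
    for ch in model.channels:
        L = _standardized_heavy_tail(rng, n_mc, model.log_sigma)
        raw = model.null_location[ch] + model.null_scale[ch] * L
        hit |= L > thresholds.z_cut
        hit |= raw > thresholds.raw_cut
    n_gfp = int(round(model.cells_per_well_mean * model.transduction_rate))
    p = _null_fraction_per_well(model, rng, n_mc)
    vim_pos = rng.binomial(n_gfp, p)
    hit |= 100.0 * vim_pos / n_gfp > thresholds.pct_cut
    return float(hit.mean())


# ---------------------------------------------------------------------------
# field image rendering
# ---------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """Geometry of one microscope field (defaults: 1321 um wide, 20 per well)."""

    field_width_um: float = 1321.0
    pixels: int = 512
    fields_per_well: int = 20
    channel_names: tuple[str, ...] = CHANNEL_ORDER

    def __post_init__(self) -> None:
        if self.field_width_um <= 0 or self.pixels <= 0:
            raise ValueError("field dimensions must be positive")
        if len(self.channel_names) != 4:
            raise ValueError("exactly 4 channels expected (DNA, GFP, VIM.r, VIM.a)")

    @property
    def um_per_px(self) -> float:
        return self.field_width_um / self.pixels


@dataclass
class SimCell:
    """Ground truth for one rendered cell."""

    x: float
    y: float
    r_major: float = 9.0
    r_minor: float = 6.0
    angle: float = 0.0
    transduced: bool = True
    vim_a: bool = False
    vim_r: bool = False


def place_cells(
    n: int,
    spec: FieldSpec,
    seed: int,
    min_sep: float = 28.0,
    transduced_fraction: float = 1.0,
    vim_a_fraction: float = 0.0,
    vim_r_fraction: float = 0.0,
    max_tries: int = 20_000,
) -> list[SimCell]:
    """Sample ``n`` non-overlapping cell positions inside the field."""
    rng = np.random.default_rng(seed)
    margin = 20.0
    cells: list[SimCell] = []
    tries = 0
    while len(cells) < n and tries < max_tries:
        tries += 1
        x = rng.uniform(margin, spec.pixels - margin)
        y = rng.uniform(margin, spec.pixels - margin)
        if any((c.x - x) ** 2 + (c.y - y) ** 2 < min_sep**2 for c in cells):
            continue
        cells.append(
            SimCell(
                x=x,
                y=y,
                r_major=rng.uniform(7.0, 11.0),
                r_minor=rng.uniform(5.0, 8.0),
                angle=rng.uniform(0, np.pi),
                transduced=bool(rng.random() < transduced_fraction),
                vim_a=bool(rng.random() < vim_a_fraction),
                vim_r=bool(rng.random() < vim_r_fraction),
            )
        )
    if len(cells) < n:
        raise ValueError(f"could not place {n} cells with min_sep={min_sep}")
    return cells


def render_field(
    cells: Sequence[SimCell],
    spec: FieldSpec,
    seed: int,
    background: float = 200.0,
    background_noise: float = 20.0,
    nucleus_intensity: float = 12000.0,
    gfp_intensity: float = 6000.0,
    vim_intensity: float = 8000.0,
    cyto_radius: float = 18.0,
    blur_sigma: float = 1.0,
) -> np.ndarray:
    """Render a 4-channel ``(4, H, W)`` uint16 raster for ``cells``.

    DNA channel: bright blurred ellipse per nucleus.  GFP channel: a
    cytoplasmic disc for transduced cells.  VIM channels: cytoplasmic
    signal for cells flagged VIM+ in the respective channel.  Additive
    Gaussian background noise everywhere.
    """
    from skimage.draw import disk, ellipse
    from skimage.filters import gaussian

    h = w = spec.pixels
    if h <= 0:
        raise ValueError("zero-sized field")
    for c in cells:
        if not (0 <= c.x < w and 0 <= c.y < h):
            raise ValueError("cell centroid outside the field")
    rng = np.random.default_rng(seed)
    img = np.zeros((4, h, w), dtype=float)
    for c in cells:
        rr, cc = ellipse(c.y, c.x, c.r_minor, c.r_major, shape=(h, w), rotation=c.angle)
        img[0][rr, cc] = nucleus_intensity
        rr2, cc2 = disk((c.y, c.x), cyto_radius, shape=(h, w))
        if c.transduced:
            img[1][rr2, cc2] += gfp_intensity
        if c.vim_r:
            img[2][rr2, cc2] += vim_intensity
        if c.vim_a:
            img[3][rr2, cc2] += vim_intensity
    for k in range(4):
        if blur_sigma > 0:
            img[k] = gaussian(img[k], sigma=blur_sigma, preserve_range=True)
        img[k] += background + rng.normal(0.0, background_noise, (h, w))
    return np.clip(img, 0, 65535).astype(np.uint16)


def render_mock_field(
    spec: FieldSpec, seed: int, n_cells: int = 40, min_sep: float = 24.0, **kwargs
) -> tuple[np.ndarray, list[SimCell]]:
    """A mock (no construct, antibody omitted) field: nuclei only, background elsewhere."""
    cells = [
        replace(c, transduced=False, vim_a=False, vim_r=False)
        for c in place_cells(n_cells, spec, seed, min_sep=min_sep)
    ]
    return render_field(cells, spec, seed + 1, **kwargs), cells


def write_field_tiff(path, raster: np.ndarray) -> None:
    """Write one field as a multi-page TIFF, one page per channel (DNA/GFP/VIM.r/VIM.a)."""
    import tifffile

    tifffile.imwrite(path, raster, photometric="minisblack")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def simulate_expression(
    n_per_group: Mapping[str, int],
    module_genes: Sequence[str],
    module_corr: float,
    n_noise_genes: int = 50,
    subtype_shifts: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a genes x samples log-ratio matrix with a correlated EMT module.

    Genes in ``module_genes`` share pairwise Spearman correlation
    ``module_corr`` (achieved by targeting the Pearson correlation
    ``2 sin(pi * rho / 6)`` of an equicorrelated Gaussian factor model).
    ``subtype_shifts`` maps gene -> label -> additive location shift; the
    ``normal`` group defines the above-normal reference downstream.
    """
    if not -1.0 <= module_corr <= 1.0:
        raise ValueError("module_corr must be in [-1, 1]")
    for g, k in n_per_group.items():
        if k < 2:
            raise ValueError(f"n_per_group[{g!r}] must be >= 2")
    rng = np.random.default_rng(seed)
    labels = []
    for g, k in n_per_group.items():
        labels.extend([g] * k)
    labels = pd.Series(labels, name="subtype")
    n_samples = len(labels)
    labels.index = [f"S{i:04d}" for i in range(n_samples)]

    # Pearson target that yields the requested Spearman under Gaussianity
    rho_p = float(np.clip(2.0 * np.sin(np.pi * module_corr / 6.0), -1.0, 1.0))
    m = len(module_genes)
    if m > 1 and rho_p < -1.0 / (m - 1):
        raise ValueError(f"pairwise correlation {module_corr} infeasible for {m} genes")
    cov = (1.0 - rho_p) * np.eye(m) + rho_p * np.ones((m, m))
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(m))
    module = chol @ rng.normal(size=(m, n_samples))
    rows = {g: noise_sd * module[i] for i, g in enumerate(module_genes)}
    for i in range(n_noise_genes):
        rows[f"NOISE{i:04d}"] = noise_sd * rng.normal(size=n_samples)
    expr = pd.DataFrame(rows).T
    expr.columns = labels.index
    if subtype_shifts:
        for gene, shifts in subtype_shifts.items():
            if gene not in expr.index:
                raise KeyError(f"shift for unknown gene {gene!r}")
            for lab, delta in shifts.items():
                expr.loc[gene, (labels == lab).to_numpy()] += delta
    return expr, labels


# ---------------------------------------------------------------------------
# triplicate confirmation screen
# ---------------------------------------------------------------------------

def simulate_triplicates(
    n_true: int,
    n_null: int,
    snai2_effect: float = 25.0,
    noise_sd: float = 1.0,
    n_vector: int = 12,
    n_snai2: int = 6,
    seed: int = 0,
    metrics: tuple[str, ...] = ("vim_a_well_mean", "pct_vim_pos_a"),
) -> dict:
    """Simulate a secondary (confirmation) screen with known truth.

    Each ORF gets 3 replicate wells; control pools are ``n_vector``
    vector and ``n_snai2`` SNAI2 wells.  True ORFs sit at the SNAI2
    location (``snai2_effect`` noise-SD units above vector); nulls sit at
    the vector location.  Well noise is Gaussian: secondary-screen values
    are means over hundreds of cells, so the heavy per-cell tail has
    largely averaged out.

    Returns ``{"orfs": {orf: {metric: array(3)}}, "vector": {...},
    "snai2": {...}, "truth": {orf: bool}}``.
    """
    rng = np.random.default_rng(seed)
    base = {"vim_a_well_mean": 2000.0, "pct_vim_pos_a": 2.0}
    scale = {"vim_a_well_mean": 250.0, "pct_vim_pos_a": 3.0}
    out = {"orfs": {}, "vector": {}, "snai2": {}, "truth": {}}
    for m in metrics:
        out["vector"][m] = base[m] + scale[m] * noise_sd * rng.normal(size=n_vector)
        out["snai2"][m] = base[m] + scale[m] * (snai2_effect + noise_sd * rng.normal(size=n_snai2))
    for i in range(n_true + n_null):
        is_true = i < n_true
        orf = f"{'HIT' if is_true else 'NULL'}{i:04d}"
        vals = {}
        for m in metrics:
            shift = snai2_effect if is_true else 0.0
            vals[m] = base[m] + scale[m] * (shift + noise_sd * rng.normal(size=3))
        out["orfs"][orf] = vals
        out["truth"][orf] = is_true
    return out


# ---------------------------------------------------------------------------
# wound time courses
# ---------------------------------------------------------------------------

def linear_profile(t_full: float) -> Callable[[np.ndarray], np.ndarray]:
    """Occupancy ramps linearly from 0 to the cell-region density at ``t_full`` hours."""
    return lambda t: np.clip(np.asarray(t, dtype=float) / t_full, 0.0, 1.0)


def logistic_profile(t_mid: float, rate: float = 0.15) -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: 1.0 / (1.0 + np.exp(-rate * (np.asarray(t, dtype=float) - t_mid)))


def flat_profile() -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: np.zeros_like(np.asarray(t, dtype=float))


def simulate_wound(
    duration_h: float = 68.0,
    interval_h: float = 2.0,
    fill_profile: Callable[[np.ndarray], np.ndarray] | None = None,
    matrigel: bool = False,
    invasive: bool = True,
    cell_density: float = 0.9,
    initial_wound_occupancy: float = 0.02,
    noise_sd: float = 0.01,
    seed: int = 0,
    require_monotone: bool = False,
) -> WoundSeries:
    """Simulate a scratch-wound occupancy series at 2 h cadence.

    ``fill_profile`` maps hours to the fraction of the cell-region
    density reached inside the wound.  With ``matrigel=True`` and
    ``invasive=False`` the wound never fills (non-invasive cells cannot
    cross the matrix), regardless of the supplied profile.
    """
    if duration_h <= 0 or interval_h <= 0:
        raise ValueError("duration and interval must be positive")
    t = np.arange(0.0, duration_h + interval_h / 2, interval_h)
    profile = fill_profile if fill_profile is not None else linear_profile(46.0)
    if matrigel and not invasive:
        profile = flat_profile()
    frac = np.asarray(profile(t), dtype=float)
    if np.any((frac < -1e-9) | (frac > 1 + 1e-9)):
        raise ValueError("fill_profile must map into [0, 1]")
    if require_monotone and np.any(np.diff(frac) < -1e-12):
        raise ValueError("fill_profile is not monotone non-decreasing")
    rng = np.random.default_rng(seed)
    c = np.clip(cell_density + rng.normal(0.0, noise_sd / 2, t.size), 0.0, 1.0)
    w0 = initial_wound_occupancy
    w = w0 + (c - w0) * frac + rng.normal(0.0, noise_sd, t.size)
    w[0] = w0
    w = np.clip(w, 0.0, 1.0)
    return WoundSeries(timepoints=t, wound_occupancy=w, cell_occupancy=c)
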