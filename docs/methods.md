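# Methods

`emtscreen` implements the statistical analysis of an arrayed
gain-of-function screen for drivers of the epithelial-to-mesenchymal
transition (EMT), read out by high-content imaging of vimentin (VIM) in
96-well plates, together with the downstream confirmation,
expression-correlation and invasion analyses. This note documents the
models, the parameters that matter, and the choices made where the
design was genuinely open.

## Screen model and normalization

Each plate carries 88 sample wells (one ORF each, delivered by a
GFP-co-expressing lentiviral vector), 4 empty-vector wells, 2 mock wells
(viral particles without an expression plasmid) and 2 positive-control
wells expressing SNAI2. Two VIM readouts are collected per well: an
antibody immunofluorescence channel (VIM.a, protein level) and a
dsRed promoter-reporter channel (VIM.r, transcriptional activity).

Wells are normalized per plate with robust Z-scores,

    z = (x - median) / (1.4826 * MAD),

where the location and scale are computed only from sample wells with
more than 100 GFP+ cells; control wells never contribute. The 1.4826
consistency constant makes the scaled MAD estimate the standard
deviation under normality, so the hit threshold `z > 15` reads in
SD-like units. Wells with 50–100 GFP+ cells are scored against these
statistics but never contribute to them: the two eligibility cutoffs are
deliberately distinct (scoring needs far fewer cells than stable
scale estimation). A plate whose scaled MAD is zero, or that has no
eligible sample wells, is flagged degenerate and its wells receive no
Z-scores.

A well with at least 50 GFP+ cells is a hit when any of the following
strict inequalities holds: `z_a > 15`, `z_r > 15`, raw well mean
intensity `> 8000` in either channel, or more than 18% of GFP+ cells
VIM+ in the antibody channel (the antibody channel is the primary assay;
the percent rule is applied there). Assay quality is summarized by the
Z'-factor `1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|` and by
control-based error rates: the false-discovery estimate is the fraction
of vector wells fitting hit criteria, the false-negative estimate the
fraction of SNAI2 wells missing them. Mock wells are excluded from both
denominators — they exist to calibrate fluorescence thresholds, not to
estimate error rates. No per-well p-values or multiplicity correction
are used; the design is fixed thresholds plus control-based error
estimation.

## Synthetic data generator

The generator is first-class, tested code: it produces every input the
pipeline consumes, with ground-truth labels attached.

**Well-level null model.** Well intensities are drawn as
`location + scale * L`, where `L = (exp(sigma*Z) - 1) / smad(sigma)` is
a lognormal variate standardized to median 0 and scaled MAD 1
(`smad(sigma)` is the population scaled MAD of `exp(sigma*Z)`, obtained
by root-finding on the lognormal CDF). The lognormal family is a
modelling choice, not something the assay's description pins down: its
heavy right tail produces rare bright debris-like outliers, the failure
mode that median/MAD normalization exists to absorb, so the generator
stresses exactly the robustness the statistics claim. Defaults:
`sigma = 0.9` (SD/scaled-MAD ratio ≈ 2.05), VIM.a location 2000 and
scale 250, VIM.r location 1500 and scale 200, chosen so that the raw
cut 8000 sits ~24 scale units above the null and null wells cross any
hit criterion with probability ≈ 0.7% — rare but non-zero, as control
wells do in practice.

**Effects.** Planted ORF effects and the SNAI2 positive-control effect
are additive location shifts in multiples of the null scale (scaled-MAD
units); biology of specific ORFs is deliberately not modelled. The
positive-control shift defaults to 25 scale units.

**VIM+ cell fractions.** The per-well fraction of VIM+ cells in null
wells follows a lognormal latent probability plus binomial sampling at
the well's GFP+ count. The latent parameters are solved from the target
observed moments — mean 1.7%, SD 2.5% across vector wells, the null
behaviour observed in the assay — after subtracting the expected
binomial component at the mean GFP+ count.

**Cell counts.** Per-well cell counts are Poisson around 1000 with a
lognormal over-dispersion multiplier (sigma 0.20); ~30% of cells are
transduced. Mock wells carry ~Poisson(2) GFP+ cells (no construct), so
they are structurally ineligible for scoring.

**Field images.** Fields default to 1321 µm width (20 per well):
nuclei are blurred filled ellipses in the DNA channel, transduced cells
get a cytoplasmic GFP disc, VIM+ cells get cytoplasmic marker signal,
and Gaussian background noise is added everywhere. Rendering is opt-in
per well; the screen-level fixtures simulate well summaries directly so
the full-pipeline tests run in seconds.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: illumination gradients and focus failures,
plate-position (edge) effects, cross-well contamination, segmentation
artefacts from confluent or apoptotic cells, transgene silencing, and
any correlation between an ORF's effect and cell viability. Tests
against this generator validate the statistical machinery, not the
wet-lab assay.

## Image quantification

Nuclei are segmented on the DNA channel by Gaussian smoothing
(sigma 2 px), Otsu thresholding (with a contrast guard so blank fields
yield zero objects), removal of objects under 30 px, and a
distance-transform watershed seeded at local maxima at least 10 px
apart to split touching nuclei. Cytoplasm is assigned by bounded
nearest-region growth: every background pixel within `max_radius`
(default 18 px ≈ 15 µm per the default field geometry) of a nucleus
belongs to its nearest nucleus, computed with per-label exact Euclidean
distance transforms and a running minimum so that exact distance ties
resolve to the lowest label — deterministically and identically to a
brute-force per-pixel search. Neighbouring cells therefore meet at a
generalized Voronoi frontier and never overlap.

Intensity cuts are the 0.999 quantile of pooled background pixels from
mock wells (no construct, primary antibody omitted), which fixes the
pixel-level false-positive rate at 0.1%. GFP positivity uses the
cell-mean intensity so the gate is independent of cell size. A cell is
VIM+ in a channel when at least `min_vim_area = 5` cytoplasm pixels
exceed the cut (suppressing single-pixel noise). Well summaries (well
mean/total intensity, percent VIM+) are computed over GFP+ cells only;
a well with no GFP+ cells is flagged ineligible rather than zeroed.
Whether the original instrument averaged total intensity over GFP+
cells or all cells is not documented; GFP+ cells are used, consistent
with how the VIM-area figures gate their measurements.

## Confirmation classifier

Putative hits are re-screened in triplicate wells and classified per
ORF and per metric (well mean total VIM.a intensity; percent VIM+
cells):

* **confirmed.HC** — Tukey HSD adjusted p vs the vector pool < 0.01 on
  either metric. The Tukey family is the smallest consistent with the
  question: {ORF, vector, SNAI2} per ORF (an all-ORFs family is
  available via the same function by passing more groups).
* **confirmed** — triplicate mean inside the SNAI2 99.9% interval and
  at least 2 of 3 wells outside the same-level vector interval, both on
  the same metric.
* **not_confirmed** otherwise.

The "confidence interval" is implemented as a prediction-style interval
for a single well value, `mean ± t_{(1+level)/2, n-1} * SD * sqrt(1+1/n)`:
the rule "2 of 3 wells outside" tests individual wells, not means, so a
mean-based interval would be the wrong object. The interval level is a
parameter (`interval_level`, default 0.999; 0.99 is a documented
alternative). Tukey HSD itself is delegated to
`scipy.stats.tukey_hsd` (Tukey–Kramer for unequal group sizes) behind
the module surface.

The confirmation-screen generator draws Gaussian well noise rather than
the heavy-tailed primary-screen null: secondary-screen well values are
means over hundreds of cells, so the per-cell tail has largely averaged
out, and the classifier's stated null error behaviour (α-consistency of
the Tukey test) presumes approximate normality at the well level.

qPCR marker ratios use ΔCt with an amplification efficiency fixed at
2.0 (perfect doubling): relative level = `2^-(Ct_gene - Ct_ref)` per
replicate (paired by replicate index, RPLP0 reference), averaged, then
ratioed mesenchymal/CDH1. Ratios are invariant to adding a constant to
every Ct of a sample. A replicate spread above 1.5 cycles for any gene
aborts the sample (failed-reaction guard).

## Expression correlations

Spearman correlation uses average ranks for ties and pairwise deletion
of missing values, with two-sided p-values from the large-sample t
approximation. "Above-normal incidence" counts tumour samples strictly
above the normal-tissue maximum (ties excluded — a tumour equal to the
normal maximum has not exceeded it). Quantile summaries use linear
interpolation (type 7). Correlations default to all samples
(tumour-only is a flag). The generator's correlated "EMT module"
targets the requested *Spearman* correlation by planting the Pearson
correlation `2 sin(pi*rho/6)` in an equicorrelated Gaussian, the exact
rank-correlation correspondence for Gaussian data.

## Wound invasion

Relative wound density is

    rwd(t) = 100 * (w(t) - w(0)) / (c(t) - w(0)),

with `w` the cell occupancy inside the wound region frozen at t = 0 and
`c` the occupancy of the surrounding cell region; values are clipped to
[0, 105] (noise can push parity slightly past 100). This declared
formula — 0 at scratch time, 100 at parity with the monolayer — is the
contract; the proprietary instrument metric is not reproduced
bit-for-bit. The wound region is the largest contiguous low-occupancy
band at t = 0 (expected 700–800 µm wide); the cell region is its
complement, optionally eroded at the image border. Whether the
instrument normalized against the whole non-wound area or a border band
is unknown; the margin is a parameter. Occupancies come from binary
masks, so the metric is invariant to uniform intensity rescaling.

The closure rate is the RWD slope between 4 h (compensating initial
wound-size differences) and 50 h (before plateau); the endpoint is RWD
at 68 h. Groups of replicate wells (n = 6 by default) are compared
against vector with Tukey HSD on both metrics at α = 0.05. The
Matrigel-sandwich invasion assay and the 2D migration control share the
same code path; `matrigel=True, invasive=False` in the generator forces
a non-filling wound regardless of the supplied profile.

## Problem sizes and numerical conventions

The desk-scale fixtures are 8 plates × 96 wells with 16 planted hits
(primary screen), 48 true + 150 null ORFs (confirmation), 600-sample
expression matrices, and 6-replicate wound groups — large enough for
stable plate statistics and tight recovery checks while keeping the
whole suite and the acceptance script in well under a minute each.
Coordinates are 0-based pixel indices; intensities are unsigned 16-bit;
all generators are pure functions of their arguments including the
seed. Degenerate inputs (zero-MAD plates, equal Z' means, wells without
GFP+ cells, confluent wound frames, constant genes) are flagged or
raised, never silently imputed.

## Known limitations

* Effects are abstract location shifts; no dose-response, silencing or
  viability coupling.
* Segmentation is tuned to the generator's nucleus geometry (7–11 px
  radii at ~2.6 µm/px); other magnifications need `min_area`,
  `min_distance` and `max_radius` re-tuned.
* The per-label exact cytoplasm assignment is O(labels × pixels); for
  very dense fields an approximate single-pass feature transform would
  be faster but could break exact tie reproducibility.
* The confirmation classifier inherits Tukey's equal-variance
  assumption; strong variance heterogeneity between ORF and control
  pools will distort its error rates.
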