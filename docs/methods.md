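# Methods

This note documents the statistical model behind `topolearn`, the
assumptions of each stage, the synthetic-data generator that the tests
run against, and the numerical and design choices that were genuinely
open.

## Behavioural model

Trials are coded by the equal-variance signal-detection contingency
table: target trials answered "yes" are hits, lures answered "yes" are
false alarms; timeouts are excluded from the table. Sensitivity is

    d' = Φ⁻¹(HR) − Φ⁻¹(FAR),   HR = Hit/(Hit+Miss),  FAR = FA/(FA+CR),

with Φ⁻¹ the standard-normal quantile. Rates of exactly 0 or 1 have an
infinite probit; the default policy replaces rate 0 by 1/(2N) and rate 1
by 1 − 1/(2N) on the respective trial count (N). This is the common
half-count adjustment; `correction="none"` and `correction="error"` are
available because the appropriate policy is a judgment call and observed
cohorts with d' well inside (−0.1, 2.4) typically never hit the extremes.

The learning criterion scans trailing windows of 48 trials for a
proportion correct *strictly above* 0.95 (i.e. at least 46/48), counting
timeouts as incorrect (the task's feedback labels slow responses as
failures), and respects a 504-trial session cap. Note that a *static*
observer with a fixed d' almost never attains 95% correct — observed
criterion-attainment rates in real cohorts reflect learning dynamics that
the simulator deliberately does not model (a static observer is enough to
exercise the scoring path); simulated attainment counts are therefore not
comparable to empirical ones.

## ERP assembly

Epoch rejection applies two rules per epoch and channel: any sample
beyond ±80 µV, and a max-minus-min above 200 µV within a sliding window
of ⌊0.200 · sfreq⌋ samples advanced sample by sample (the hop size is a
choice; sample-wise advancement is the most conservative reading of
"within 200 ms"). Note the two rules are nested at the default limits: a
>200 µV swing cannot occur inside ±80 µV bounds, so the peak-to-peak rule
only becomes independently active when limits are changed.

Channel interpolation uses inverse great-circle-distance weights over the
k = 4 nearest good electrodes, normalized to sum to one. This preserves
the locality of neighbour-based spline interpolation while avoiding a
full spherical-spline implementation whose extra fidelity none of the
downstream statistics need; a constant field is reproduced exactly and
interpolated values stay inside the convex hull of the neighbours.

Accepted epochs are averaged and re-referenced to the common average; no
baseline correction is applied. Manual artifact inspection and ocular ICA
are not reproduced — an external bad-epoch/bad-channel hook
(`assemble_subject_erp`) stands in for them.

## Randomization statistics

All three tests share one engine: an observed per-timeframe effect size,
a permutation null, and the tie-inclusive estimate

    p = (1 + #{null ≥ observed}) / (1 + n_perm),

which is valid (super-uniform under the null) and never exactly zero.
Permutations are drawn uniformly and independently (with replacement
across draws); n_perm < 100 is refused unless explicitly overridden.

* **TCT** — effect: GFP of the across-subject mean map. Null: electrode
  values shuffled within each subject before averaging. The shuffle is
  drawn once per subject per permutation and reused across timeframes;
  each frame's p-value is exact on its own, only the joint distribution
  across frames is affected. A single-subject dataset degenerates (the
  effect is that subject's GFP) and is flagged with NaN p-values.
* **TANCOVA** — effect: GFP of the covariance map
  V = Mᵀu/(n−1), with both the potentials M and the covariate u
  mean-centred across subjects (covariance is undefined without
  centring). Maps are amplitude-normalized to GFP = 1 per subject and
  timeframe by default, so the test isolates differences of topographic
  shape; timeframes where any subject has a zero-GFP map are excluded
  rather than dividing by zero. The 1/(n−1) scaling is irrelevant to
  permutation ranks and is kept only so reported map units are
  per-electrode sample covariances (µV per d' unit).
* **GFP covariation** — effect: |covariance| between per-subject GFP and
  the covariate (|correlation| by option; covariance is the default since
  the choice is not dictated by the underlying framework and covariance
  keeps the effect in physical units).

Significant frames are retained only in maximal runs of at least
⌈min_duration · sfreq / 1000⌉ consecutive frames (20 ms default), the
standard guard against isolated false positives. The windowed frame rate
— the fraction of frames covered by retained windows under a null model —
is the quantity this rule reduces, and the validation suite measures it
against the raw per-frame rejection rate.

Long windows are subdivided into ~70 ms sub-windows centred on local
maxima of the effect-size time course ("explained variation" is read as
the observed effect size; a distinct variance-explained statistic would
change only the peak-picking, not the maps). Sub-window maps are
time-averaged covariance maps computed from the raw (unnormalized) data;
adjacent sub-windows merge when their maps correlate at r ≥ 0.9 across
electrodes, a threshold that separates the merge/keep-separate regimes
(≈0.9+ vs ≈0.6–0.7) reported for this kind of data; merged windows span
their members and their map is recomputed over the full span.

Time convention: stimulus onset = 0 ms, frames are half-open
[start, end), all windows reported in ms.

## Forward model and sLORETA

The head is a three-shell concentric sphere (relative radii 0.87 / 0.92 /
1.0; conductivities 1 : 1/80 : 1 for brain, skull, scalp). The scalp
potential of an internal dipole is the classical Legendre series; per
degree n the shell coefficients solve a 5×5 linear system given by
potential and radial-current continuity at the two interfaces and zero
current at the scalp. The solve is performed on radii normalized to the
scalp radius (the r^n / r^−(n+1) terms are otherwise badly scaled in
physical units), with 160 degrees retained — the series decays like
(b/r_brain)^n, below 10⁻⁵ at the maximal source eccentricity used. The
implementation reduces exactly to the homogeneous-sphere closed form for
equal conductivities and agrees with an independent multilayer sphere
implementation to r > 0.999 and ~1% amplitude (both are unit tests).
Sources live on a cubic grid (spacing 0.2 by default, 257 points) kept
strictly inside the brain shell; gains are average-referenced.

sLORETA inverts a scalp map φ by the standardized minimum-norm estimate:
ĵ = Kᵀ(KKᵀ + λH)⁺φ with H the average-reference centering matrix, and
per-point power ĵᵥᵀ[Rᵥᵥ]⁻¹ĵᵥ with Rᵥᵥ the 3×3 diagonal block of the
resolution matrix Kᵀ(KKᵀ + λH)⁺K. Pseudo-inverses handle the rank
deficiency induced by the average reference; numerically singular blocks
are flagged and skipped. This standardization has zero localization error
for noiseless point sources at λ = 0, which the suite verifies
exhaustively over the grid. The default regularization, when requested
("auto"), is λ = 0.05 · trace(KKᵀ)/n_channels; no principled noise model
exists for covariance maps, so λ = 0 is the default for noiseless
validation and "auto" for data. Covariance maps are inverted as
instantaneous scalp fields.

The spherical solution space is a deliberate desk-scale substitute for an
anatomical template: validation is against simulated ground truth, and no
anatomical labels are produced.

## The synthetic cohort generator

A subject's average ERP is a sum of components plus noise:

    x_s(c, t) = Σ_k env_k(t) · (a_k + g_k · d'_s) · T_k(c) + ε_s(c, t),

with each template T_k zero-mean across electrodes at unit GFP, env_k a
unit-peak window over the component's latency range, and ε spatially and
temporally smoothed Gaussian noise re-standardized to a per-channel SD of
1 µV. Covariates d'_s are drawn from a truncated normal (mean 1.19,
SD 0.51, range −0.09..2.32), matching a realistic young-adult cohort.

The default study-scale cohort (38 subjects, 64 channels, 512 Hz,
−100..1000 ms) contains:

* a sustained frontal-negativity background (boxcar, −1.5 µV) plus an
  occipital evoked deflection at 60–300 ms (2 µV) — both independent of
  d', providing the covariate-independent reference topography without
  which shape analyses on normalized maps would have nothing to detect;
* an early component at 126–148 ms whose template (occipital-positive /
  central-negative) is orthogonalized against both background patterns:
  its covariate link changes map *shape* at nearly constant field
  strength;
* a late component at 530–638 ms built as an orthogonal shape part plus
  0.25 of the background-aligned direction: its covariate link changes
  both the topography and the global field power.

Covariate-linked components use boxcar envelopes: the stated latency
window is the component's full-strength support, which makes "the
injected window" a well-defined recovery target. Gains are calibrated so
the peak-electrode voltage–d' correlation is ≈ 0.6, a moderate
single-electrode effect. Noise smoothing scales — 30° FWHM across the
scalp, 12 ms along time — were fixed once as a plausible correlation
structure for average-referenced, band-limited background EEG and give
the calibrated effect its intended detectability; they are deliberate
generator conditions, not estimates of any particular dataset.

What the generator does **not** emulate: learning dynamics (d' is
static), inter-subject topographic variability of the components (every
subject shares the same templates), realistic artifact morphologies,
volume-conduction-accurate noise covariance, and anatomical source
configurations. Passing tests therefore demonstrate that the statistical
machinery is correct and well-calibrated — not that any particular
empirical finding would replicate.

## Validation experiments (scripts/acceptance.py)

All experiments derive their randomness from one seed and regenerate
their data at run time; problem sizes were chosen to keep the full run
around a minute on one CPU:

* SDT recovery: 10⁵ targets + 10⁵ lures per observer at d' ∈
  {0, 0.5, 1.19, 2.32}, criterion d'/2.
* Exhaustive agreement: 6 subjects, 16 channels, 20 frames; 5000
  Monte-Carlo draws against all 720 permutations.
* Type-I calibration: 1000 replicate null cohorts of 16 subjects,
  64 channels, 64 frames at 512 Hz, n_perm = 500.
* Window recovery: the full 38-subject study-scale cohort, n_perm = 1000.
  Detected windows are scored by interval Jaccard against the injected
  windows, counting only detections that overlap the target (spurious
  windows elsewhere are the type-I quantity measured separately).
* Merge dichotomy: two overlapping high-SNR effect humps (noise SD
  0.05 µV) sharing one significant window — distinct templates must
  split, a repeated template must merge.
* sLORETA: all 257 grid points × 3 orientations, λ = 0.

## Interfaces

The library (`src/topolearn/`) is the contract; the numbered scripts
under `analysis/` are thin drivers over it, and
`topolearn.pipeline.run_pipeline(AnalysisConfig)` ties the stages into
the study's order (consistency gate before covariance analyses) with a
JSON manifest recording seed, parameters and version for exact replay.
A shell entry point would add nothing over these two surfaces for an
analysis-shaped package, so none is installed.

## Known limitations

* The peak-to-peak rejection rule is redundant at the canonical limits
  (see above); it matters only for user-supplied limits.
* The TCT null shuffles electrodes within subjects, which destroys
  spatial smoothness as well as consistency; for strongly spatially
  correlated noise the test is mildly anticonservative about "any shared
  structure" versus "a shared *map*". The validation suite checks its
  calibration under the generator's smooth-noise null.
* Interval recovery depends on the duration rule: effects shorter than
  ~20 ms are invisible by design, and a 22 ms window leaves a margin of
  a single frame at 512 Hz.
* The spherical head model localizes on a geometric grid; nothing
  anatomical can be concluded from peak coordinates.
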