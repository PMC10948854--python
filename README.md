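# topolearn

Topographic ERP statistics for individual-differences research: does the
shape or strength of a scalp potential field covary with how well each
person performs a task?

`topolearn` implements the full analysis chain used to link associative-
learning performance to event-related potential (ERP) topographies:

* **Behaviour** — signal-detection scoring of trial-and-error association
  sessions. Sensitivity is the probit difference
  `d' = Φ⁻¹(Hit/(Hit+Miss)) − Φ⁻¹(FA/(FA+CR))`, with timeouts excluded and
  a configurable extreme-rate correction, plus the
  more-than-95%-correct-in-48-trials learning criterion (504-trial cap).
* **ERP assembly** — epoch rejection (±80 µV amplitude; >200 µV
  peak-to-peak within any 200 ms window), neighbour interpolation of bad
  channels, averaging and common-average re-referencing (no baseline
  correction).
* **Topographic consistency test (TCT)** — per timeframe, a randomization
  test (electrode shuffling within subjects) for whether subjects share a
  common map; downstream analyses are restricted to consistent frames.
* **TANCOVA** — per timeframe, the covariance map `V = Mᵀu` between scalp
  potentials `M` (subjects × electrodes, mean-centred) and the covariate
  `u` (d'); its global field power (GFP, the root-mean-square across
  electrodes) is the effect size, tested against a permutation null of
  `u`. Maps are amplitude-normalized to GFP = 1 so the test sees
  topographic *shape* only.
* **GFP covariation** — the complementary strength analysis: covariance
  between per-subject global field power and d', same permutation scheme.
* **Window logic** — significant frames (`p < 0.05`) are retained only in
  runs of at least 20 ms; long windows are subdivided into ~70 ms
  sub-windows at effect-size maxima and merged back when their covariance
  maps are spatially similar (Pearson `r ≥ 0.9`).
* **Sources** — sLORETA (standardized minimum-norm) inversion of window
  covariance maps on an analytic three-shell spherical-head leadfield,
  with exact localization of noiseless point sources at `λ = 0`.
* **Synthesis** — a first-class generator of SDT observers and
  multi-subject ERP cohorts with known covariate-linked components, so
  every stage is testable against generative ground truth without any
  recordings.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (each accepts `--seed`, default 7):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_score_behavior.py
python analysis/04_topographic_statistics.py
python analysis/05_source_localization.py
```

which prints, among other lines:

```
cohort: 38 subjects, 64 channels, 563 timeframes at 512 Hz
injected covariate-linked windows: 126-148 ms, 530-638 ms
estimated d': mean 1.18, sd 0.48, range 0.24..2.29
recovery of generative d': r = 0.967, max |error| = 0.285
TCT: consistent topographies at 100% of timeframes
tancova: significant windows 127-148 ms, 531-617 ms
gfp: significant windows 556-638 ms
map 531-617 ms: max +0.38 at CPz, min -0.19 at AF7 (GFP 0.12)
```

Reading: behavioural scoring recovers each observer's generative
sensitivity almost perfectly (r = 0.97); the TANCOVA finds the two
injected covariate-linked windows and nothing else; the GFP analysis
flags only the late window, whose amplitude was built to scale with d';
the late covariance map peaks at CPz, the centroparietal positivity that
was injected. `analysis/03_assemble_erp_demo.py` shows the epoch-level
path (artifact rejection, interpolation, averaging) on a single subject.

The same workflow is available as a library call:

```python
from topolearn.pipeline import AnalysisConfig, run_pipeline
report = run_pipeline(AnalysisConfig(out_dir="results/run", seed=7))
```

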