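# Methods

`retinasample` asks a question about active vision: when an observer learns a
face by fixating parts of it, how much machine-usable identity information do
those fixations actually acquire — and does *where* skilled observers look
buy them information beyond *how much* of the face they see? The package
simulates the whole measurement chain on synthetic data: gaze-contingent
face-learning trials, fixation detection, foveated reconstruction of the
retinal input, embedding-based identity matching, and mixed-effects analyses
of the resulting accuracy.

## Synthetic stimuli and observers

Stimuli are parametric grayscale face-like layouts, not photographs: an oval
face with shared generic features (eyes, brows, nose, mouth shading and a
common base texture) plus identity-specific band-pass texture patches placed
at 2–4 of the canonical feature sites (eyes, nose, chin, cheeks, forehead).
Identity information is therefore spatially non-uniform and its location
varies by identity, which is exactly the structure a sampling-policy effect
needs. Each identity's *diagnosticity map* is the mixture of Gaussian windows
(σ = 0.06 × image size) over its patch sites, normalized to peak 1. Every
identity has a neutral and a happy stimulus that differ only inside the mouth
and brow region labels (a hard-masked texture swap), so matching across
expressions cannot be solved by raw image comparison. Demographics (2 genders
× 2 ethnicity categories × 3 age bands) are assigned in consecutive pairs so
every identity has at least one peer with identical demographics for
non-match pairing. Default canvas 448 × 448 px; cohort runs use 224 × 224
(see *Problem sizes*).

Observers are sampling policies. A policy draws each fixation target either
from the viewed identity's diagnosticity map (probability = its *targeting
weight*) or from an isotropic Gaussian centered on the face. The three
sources use targeting weights 0 (random), 0.3 (control) and 0.7
(super-recognizer-like), with the isotropic spread matched across sources so
that group differences are attributable to targeting alone; the super group's
empirically broader fixation distribution emerges from targeting patches that
are dispersed over the face. Gaze traces sample at 120 Hz for 5 s per trial:
dwell segments at each target, 30 ms linear saccades between targets, and
smooth AR(1) oculomotor jitter (stationary SD 0.15°, lag-1 correlation 0.9 —
smooth enough that jitter never crosses the saccade threshold at 120 Hz).
Fixation counts are Poisson (mean 10) with truncated-normal dwell durations
(mean 420 ms, SD 120 ms) rescaled to fill the trial.

What the generator does **not** emulate: photorealistic appearance, blinks
and tracker dropout (the detector handles invalid samples, but the default
generator emits none), saccade dynamics (main-sequence velocity profiles),
learning within or across trials, and any recognition-phase behavior.
Passing tests therefore show that the pipeline's machinery is correct and
that the analysis recovers known sampling-policy differences under these
idealized conditions — not that real super-recognizers behave this way.

## Viewing geometry

Pixels convert to visual angle via deg = 2·atan(px·pitch / 2d). The default
geometry places the screen at 600 mm and scales pixel pitch with image size
so the face spans ~8.6° regardless of resolution; detection thresholds and
foveation therefore behave identically at 224 and 448 px.

## Fixation detection

Samples faster than 30°/s are saccadic; contiguous sub-threshold runs of
valid samples become candidate fixations (centroid = mean sample position).
Cleaning follows three rules in order: (a) a greedy left-to-right merge of
candidates closer than 0.5° with an inter-fixation gap ≤ 75 ms (merged
centroid is duration-weighted; merging continues transitively), (b) removal
of fixations shorter than 50 ms, and (c) removal of fixations longer than
3 SD above the mean duration, where mean and SD pool all trials of a
participant — so rule (c) is a dataset-level pass
(`apply_duration_outlier_rule`), separate from per-trace detection. Invalid
samples split runs; speed is computed between consecutive valid samples, the
first valid sample inheriting the second's speed. No speed smoothing is
applied by default (a moving-average window is available but off). Trials
whose fixations are all removed by rule (c) yield no composite and are
skipped with a count.

## Foveated reconstruction

Each fixation produces a foveated view of the stimulus: effective resolution
r(e) = e2/(e2 + e) at eccentricity e, with half-resolution eccentricity
e2 = 28.75/Δ degrees. The default lossy parameter Δ = 25 gives e2 = 1.15°,
at the conservative end of published human E2 estimates for acuity-like
tasks; Δ → 0 disables acuity loss and reproduces the stimulus exactly. The
view is rendered by blending full-resolution Gaussian-pyramid levels (level
k blurred with σ = 2^(k−1)) at per-pixel level −log₂ r, so the fixated pixel
is always unfiltered. A circular spotlight aperture of area
pct/100 × face-bounds area (radius = √(pct·A/100π)) masks each view to the
background value (mid-gray 0.5, configurable); 100% is a no-op; edges are
hard by default with an optional cosine ramp. A trial's views combine into a
composite by keeping, at every pixel, the value from the view with the
highest resolution there (ties break toward the earlier fixation), which
equals nearest-fixation filtering when all fixations share the acuity
profile. Coordinates are 0-based, origin top-left.

## Information proportion

Two bounded terms measure how much of the original face survives in a
composite, both over the face bounds. The *pixel-test term* is the fraction
of face pixels revealed at usable resolution (resolution map > τ = 0.05).
The *structural-similarity term* is the local SSIM map between composite and
original (canonical 11×11 Gaussian-weighted formulation, population
covariances), rescaled from [−1, 1] to [0, 1] and averaged with
revealed-pixel weighting — unrevealed face pixels contribute 0. The
revealed-weighting is this package's combination rule: it makes the term
exactly 0 for an all-background composite and exactly 1 for a full-fidelity
one, and monotone as apertures grow (plain global SSIM satisfies none of
these exactly). The information proportion is the equal-weight mean of the
two terms by default; both components are always exported so either can be
used alone.

## Identity scoring

Composites (probes) are compared against full-resolution gallery originals.
Per probe: one match pair (same identity, other expression) and one
non-match pair (a demographic peer, also in the other expression, chosen by
seeded shuffle when several peers exist) — so match and non-match counts are
balanced by construction. Embeddings come from pluggable backends; the
built-in family resizes to 224 × 224 and concatenates per-cell mean, SD and
four oriented gradient energies over a g × g grid. Three grids (7, 8, 14;
g must divide 224) form the default ensemble standing in for a set of
recognition networks, with gridstats8 (dim 384) as the reference backend.
Euclidean distances are min-max normalized per backend over the experiment's
full distance set and inverted into similarities in [0, 1]; a zero-span
backend degenerates to 0.5 everywhere with a warning. Trial correctness is
the similarity on match trials and its reversal on non-match trials. Per
(backend × source × spotlight) cell, discriminability is the exact tie-aware
Mann–Whitney AUC computed from ranks.

## Mixed-effects analyses

Both outcomes (AUC, correctness) are continuous in [0, 1]. The logit link is
realized by maximum-likelihood linear mixed models (statsmodels MixedLM) on
the logit of the boundary-shrunk response y* = (y(n−1)+0.5)/n. Spotlight
size enters as a continuous covariate scaled to [0, 1] (12% → 0.12); the
source factor is sequence-coded with two columns whose coefficients are
directly the control-vs-random and super-vs-control contrasts, reported as
exp(b) with Wald 95% CIs and one-tailed p-values for those two directional
contrasts only (all other tests two-tailed).

The condition-level model regresses cell AUC on size × source with a backend
random intercept and is fitted in three functional forms — logit link with a
linear size term, identity scale linear, identity scale quadratic — compared
by BIC. BIC is computed as −2ℓ + k·ln(n) with the log-Jacobian of the logit
transform added to the transformed-scale likelihood, so values are
comparable across forms (the change-of-variables correction, as in Box–Cox
comparisons); k counts fixed effects, variance parameters and the residual
variance. The trial-level model regresses correctness on size, source and
information proportion (no interaction) with crossed random intercepts for
backend and trial, implemented exactly via variance components on a single
grouping; because the dummy-coded components grow with trial count, cohort
runs fit this model on a seeded source-stratified subsample (default 150
trials). Term tests are likelihood-ratio χ² against term-deleted refits; a
single-fit Wald χ² equivalent is provided for replicate-heavy calibration
studies. Optimization tries L-BFGS then Nelder–Mead and keeps the best
likelihood; zero-variance boundary estimates are accepted silently.

Calibration, established by the test suite's simulation studies: the source
test holds its nominal level (type-I ≤ 0.075 at α = 0.05, uniform null
p-values) at ≥ 90 trials and ≥ 3 backends; smaller designs make the
asymptotic tests anticonservative, which is why the reduced-scale replicate
studies use 3 backends × 90 trials. Generating-parameter recovery is within
2 SE in ≥ 90% of replicates, and BIC selects the generating logistic form
essentially always at that scale.

## Problem sizes

The cohort used by the heavyweight tests and the acceptance script is 20
identities × 10 observers per source × 6 spotlight sizes (≈ 3600 trials,
≈ 7200 pair scores per backend), generated at 224 × 224 px with geometry
holding the face at ~8.6°; one full run takes a few minutes on one core.
Replicate-based calibration studies use condition tables of 5 backends × 18
cells and trial tables of 3 backends × 90 trials, 200 replicates each. The
demo configuration in `analysis/config.yaml` is smaller (10 identities × 4
observers) so the scripted walkthrough completes in about a minute per
stage.

## Known limitations

* The Δ = 25 parameterization is this package's acuity-decay reinterpretation
  of a retinal-filter convention; only its limiting behavior (Δ → 0 lossless,
  larger Δ faster falloff) and the default's human-plausible e2 are anchored.
* The SSIM/pixel-test combination rule (equal weights, revealed-weighted
  SSIM) is a declared choice, not an estimated one.
* Grid-statistics embeddings are texture detectors, not face-recognition
  networks; absolute AUC levels are not comparable to DNN results, only the
  within-experiment contrasts are meaningful.
* The trial-level model's cohort fit uses a trial subsample; estimates carry
  correspondingly wider intervals than a full-data fit would.
* Yoked region-matched random fixations are implemented and tested but are
  not part of the default cohort grid, whose random source is a
  zero-targeting policy.
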