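# retinasample

Tools for quantifying the computational value of the face information an
observer samples with their eyes. During natural face learning, fixations
determine what the retina actually encodes: high acuity at the fovea, rapid
fall-off with eccentricity, and — in gaze-contingent "spotlight" experiments —
a hard aperture revealing only a fixed percentage of the face around each
fixation. `retinasample` reconstructs that per-trial retinal information as a
composite image, measures how much of the face it preserves, scores how well
identity can be recognized from it, and tests whether *where* an observer
samples matters beyond *how much* they sample.

The package is aimed at researchers studying visual-sampling differences
between observer groups (for example super-recognizers versus typical
viewers) who want a fully synthetic, end-to-end testbed: every stage from
gaze traces to mixed-model inference runs on generated data with known
ground truth.

## The pipeline

1. **Synthesis** — parametric face-like stimuli whose identity-diagnostic
   texture sits at identity-specific locations (a per-identity diagnosticity
   map), two expressions per identity, and observer policies that differ in
   how strongly fixations target diagnostic locations (targeting weights
   0 / 0.3 / 0.7 for random / control / super).
2. **Fixation detection** — angular speed threshold 30°/s; merge of
   fixations within 0.5° and 75 ms; removal of fixations under 50 ms and of
   per-participant 3 SD duration outliers.
3. **Retinal reconstruction** — per fixation, acuity falls off as
   r(e) = e2/(e2+e) with e2 = 28.75/Δ degrees (lossy parameter Δ = 25 by
   default), rendered from a Gaussian pyramid; a circular aperture reveals
   12–100% of the face area; views combine into a composite by per-pixel
   maximum resolution.
4. **Information metrics** — the proportion of the original face preserved:
   a revealed-weighted structural-similarity term and a revealed-pixel term,
   each in [0, 1].
5. **Identity scoring** — each composite is compared with a full gallery
   image of the same identity in the other expression (match) and of a
   demographically matched identity (non-match) via Euclidean distances
   between grid-statistics embeddings, min-max normalized per backend and
   inverted to similarities; per-condition discriminability is the exact
   Mann–Whitney AUC, P(sim_match > sim_nonmatch) + ½P(tie).
6. **Mixed models** — logit-link mixed models of the bounded outcomes:
   AUC ~ spotlight size × source with a backend random intercept (logit vs
   linear vs quadratic forms compared by BIC), and trial-level
   correctness ~ size + source + information proportion with crossed
   backend/trial random intercepts. The second model is the
   quantity-versus-quality test: a surviving source effect means sampling
   *location* carries value beyond information *amount*.

A yoked control is also provided: random fixations matched to a human trial
in count and per-face-region counts (eyes, nose, mouth, chin, cheeks, brow,
forehead), drawn uniformly within each region.

## Worked example

The numbered scripts under `analysis/` run a demo cohort (10 identities,
4 observers per source; `analysis/config.yaml`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_detect_fixations.py
python analysis/03_reconstruct_and_score.py
python analysis/04_fit_models.py
python analysis/05_plot_results.py
```

Stage 02 reports the detector's view of the simulated gaze:

```
720 traces -> 6882 fixations after merge/min-duration, 6773 after the 3 SD outlier rule
per-trial fixation count: mean 9.4 (range 0-20)
fixation duration: mean 468 ms, sd 216 ms
```

Stage 03 shows the two quantities the analysis lives on. Information grows
with the spotlight (more of the face revealed per fixation), and at every
spotlight size accuracy orders super > control > random:

```
mean info proportion by spotlight:
12     0.445
24     0.635
36     0.754
48     0.828
60     0.877
100    0.943
AUC (mean over backends):
source_label   control  random  super
12               0.672   0.632  0.714
...
100              0.793   0.720  0.803
```

Stage 04 fits both models. At the condition level the super-vs-control
contrast is exp(b) = 1.21 [1.10, 1.33] — super-like sampling multiplies the
odds-scale accuracy by ~1.2 — and the source term is significant
(χ²₂ = 18.5, p < 0.001). Critically, in the trial-level model the
super-vs-control effect survives *with the information proportion in the
model* (exp(b) = 1.34, p = 0.03, while information itself dominates with
χ²₁ = 68.2): the super policy's advantage is not just revealing more face,
it is revealing more *diagnostic* face.

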