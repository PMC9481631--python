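# Methods

`gafunc` quantifies the structure–function relationship of geographic
atrophy (GA): it turns per-feature OCT segmentation probability volumes
into comparable, fovea-centred lesion maps, predicts visual function from
them with bootstrapped random-forest regression, and maps where on the
macula — and through which lesion feature — the predictive information
resides. Because clinical GA imaging datasets with paired visual-function
measurements are not redistributable, the package ships a first-class
synthetic-cohort generator with a *known* structure–function law, so every
claim the pipeline makes can be checked against planted ground truth.

## En-face reduction

The pipeline starts from per-feature probability rasters over the
(b-scan × A-scan) grid of a 6 × 6 mm macular volume (at least 25 b-scans;
49 × 49 by default). When per-b-scan pixel masks are supplied instead, each
depth column is collapsed to its **maximum** probability — the reduction
consistent with detecting presence anywhere in depth; a mean reduction
would dilute a thin but definite lesion. Binarization uses the
`>= threshold` convention with a default threshold of 0.5. The optimal
per-feature thresholds of the segmentation models that would produce these
volumes are model-specific and not public, so the threshold is an explicit
configuration field rather than a constant.

RPE-and-outer-retinal atrophy (RORA) is never segmented independently: it
is defined as the per-A-scan co-occurrence of RPE-loss, photoreceptor
degeneration and hypertransmission. Probabilistically we take the
cell-wise **minimum** (fuzzy AND). The minimum is the unique t-norm whose
thresholding commutes with the binary definition: `min(a,b,c) >= t` iff
`a >= t and b >= t and c >= t`, so the derived RORA is a subset of each
constituent at *every* threshold, not just the default one. Lesion areas
are cell counts times cell area (no sub-cell geometry); cell centres sit at
`(i + 0.5) x spacing`.

## Standard grid and ETDRS subfields

Maps are comparable across eyes only after (i) translating the manually
annotated foveal centre to the grid centre and (ii) mirroring left eyes
horizontally so that +x is nasal for every eye. Without the mirroring,
nasal/temporal aggregates would average anatomically opposite retina.
Resampling is bilinear (an interpolation is required, since foveae are
annotated at sub-cell precision); target cells outside the scanned field
receive a configurable fill value (default 0). Numerical note: resampling
uses edge-value extension for the half-cell band at the field border and an
explicit millimetre-based outside mask, which keeps identity resampling
(fovea at centre, matched resolutions) exact to machine precision.

The ETDRS grid partitions the central 6-mm circle at radii 0.5 / 1.5 /
3.0 mm into a foveal disc, four parafoveal and four perifoveal quadrants,
split at the 45° diagonals. Radius bins and sector angles are half-open
(`[45°, 135°)` superior, etc.), so every cell receives exactly one label
and boundary cells are assigned deterministically. Discretized subfield
areas converge to the analytic ring areas (foveal π/4 ≈ 0.785 mm²; inner
quadrants ≈ 1.571 mm²; outer ≈ 5.301 mm²) with < 1 % relative error at
490 × 490. The default standard-grid resolution (49 × 49 over ± 3 mm)
mirrors the b-scan count of the source volumes; it is a configuration
field, not a constraint.

## Synthetic cohorts

The generator emulates a cross-sectional GA cohort; defaults are the
package's study conditions and were fixed once, by calibration against
published cohort statistics, before being frozen:

* **Cohort structure** — 205 patients with 46.5 % contributing both eyes
  (≈ 300 eyes; the published cohort had 476 eyes / 325 patients with the
  same bilateral fraction). Fellow eyes share a lognormal lesion-burden
  random effect (σ_log = 0.25), which is what makes patient-level splits
  meaningfully stricter than eye-level splits.
* **Lesion morphology** — per eye, K ∈ {1..3} seeds are scattered around
  the fovea (Gaussian, SD 1.15 mm — the *sparing-bias knob*); the RPE-loss
  support is a union of radial kernels with a smooth boundary texture,
  converted to probabilities through a 0.06-mm logistic edge. Feature
  areas are drawn lognormally (σ_log = 0.45, shared multiplier across
  features) around the published medians (RPE-loss 7.82, photoreceptor
  degeneration 14.4, hypertransmission 9.23 mm²) and the kernel scale /
  halo width / boundary offset are solved by bisection per eye, so cohort
  medians track the targets (within ± 20 % at ≈ 300 eyes) without any
  hand-tuned intensity constant. Photoreceptor degeneration is a halo
  dilation of the RPE-loss support plus occasional independent patches;
  hypertransmission perturbs the RPE-loss boundary with a smooth random
  field (amplitude 0.35 mm), so the derived RORA loses thin rim regions
  and lands naturally below the RPE-loss area (published median
  6.22 mm²). A boundary perturbation was chosen over multiplicative
  probability noise because only a geometric perturbation can both exceed
  the RPE-loss area on average and carve RORA below it.
* **Foveal sparing** — the Gaussian seed scatter yields roughly 15 % of
  eyes with zero foveal RORA at threshold 0.5, matching the published
  14.7 % rate. Uniform seed placement over the whole 36 mm² field would
  make sparing the rule rather than the exception (≈ 50–60 % for ~1.6-mm
  lesion radii), which is why the scatter is fovea-centred.
* **Outcomes** — VA = clamp(80 − 35·(mean foveal RORA probability)
  − 0.8·(extrafoveal RORA area, mm²) + ε, 0, 100); LLD = clamp(0 +
  38·(mean parafoveal photoreceptor-degeneration probability) + ε′, 0,
  VA); LLVA = VA − LLD, all in ETDRS letters with ε, ε′ ~ N(0, 15²). No
  published effect sizes exist for these relationships; the coefficients
  were calibrated once so the cohort reproduces the published outcome
  moments (VA ≈ 55 ± 21, LLD ≈ 24 ± 16 letters) and so the default
  bootstrap r² lands in the published 0.25–0.46 band (measured: VA
  ≈ 0.34–0.43). They are calibration choices, not estimates.

What the generator does **not** emulate: longitudinal growth, b-scan-level
depth texture (generation happens directly at A-scan resolution),
rotational/torsional misalignment, segmentation-model failure modes, or
measurement artefacts such as floor effects in letter scores. Passing
recovery tests therefore demonstrates that the pipeline's inference
machinery is sound, not that the published clinical effect sizes are
reproduced.

## Prediction and evaluation

The predictor matrix is one row per eye and one column per (feature,
standard-grid cell), feature-major then row-major — 4 × 49 × 49 = 9 604
columns raw, 196 after the default 7 × 7 block-mean downsampling. Eyes
missing the requested outcome are dropped with a logged count.

Evaluation is a 100-replicate bootstrap: each replicate resamples patients
with replacement, partitions the distinct sampled patients 80/20 (eyes
never straddle the split), fits a `RandomForestRegressor` with the
library's default hyperparameters (100 trees, all features per split,
unlimited depth — all settings are logged into the result), and scores the
held-out eyes with r² and MAE. The point r² is the median across
replicates; MAE is reported as median with 25–75 % quartiles. A plain
repeated-split scheme (`scheme="split_only"`) and eye-level splitting are
available for sensitivity analysis, as is a one-eye-per-patient rerun.
Degenerate replicates are handled explicitly: a test side with fewer than
two eyes (r² undefined) is redrawn; a constant training outcome excludes
the replicate from the summary with a logged count.

## Importance maps

Per-predictor impurity importances (normalized variance reduction) are
averaged across replicates *first*, then renormalized and multiplied by
100, giving percentage contributions per (feature, cell) that total 100.
Aggregation sums them over ETDRS subfields into a 9 × 4 matrix; importance
on cells outside the 6-mm circle is reported as an explicit remainder
rather than silently folded into the outer ring, so matrix + remainder =
100 exactly. The foveal share is the foveal row sum and the non-foveal
share its complement to 100. Impurity importance is biased toward
correlated and high-cardinality predictors; this is acceptable here
because conclusions are drawn from coarse aggregates (rows/columns of the
region matrix), and the recovery tests confirm the aggregates rank
planted signals correctly.

## Recovery experiments

`recovery_config()` defines the conditions under which signal recovery is
asserted: VA depends *only* on foveal RORA, LLD only on parafoveal
photoreceptor degeneration, noise 5 letters, and the PDR coefficient (55)
deliberately strong relative to the foveal coefficient (25). The last
choice matters: LLVA = VA − LLD inherits the foveal RORA signal, so with
effect sizes balanced as in the default law, the foveal component would
dominate the LLVA model and the photoreceptor-degeneration column could
not come out on top no matter how well the pipeline worked. A recovery
experiment must plant an unambiguous law; with this one, the VA model's
largest row sum is foveal and largest column sum RORA, and the LLVA
model's largest column sum is photoreceptor degeneration — the qualitative
foveal/extrafoveal contrast the pipeline exists to detect. The companion
null experiment permutes the outcome over eyes: summary r² drops at or
below 0.1 and held-out MAE approaches the outcome's mean absolute
deviation, while the patient-level leakage guard holds on every split.

## Determinism and problem sizes

Every stochastic stage is seeded: one master seed derives per-stage seeds
through a fixed counter scheme (`pipeline.stage_seed`), and within a stage
per-eye / per-replicate streams are spawned from numpy `SeedSequence`
keys, so identical configurations produce byte-identical cohorts, results
and reports. Default experiment sizes — ≈ 300 eyes, 49 × 49 grids,
downsampling factor 7, 100 bootstrap replicates — were chosen so that a
full recovery-plus-null study runs in a few minutes on a single CPU while
keeping the bootstrap summaries stable to well under the margins the
recovery assertions rely on.

## Known limitations

* The pipeline starts from segmentation probabilities; no inference over
  raw OCT, no proprietary scanner formats.
* Registration is translation + mirroring only (no rotation correction).
* No lesion-diameter classification of atrophy stages; RORA is used as a
  continuous variable throughout.
* Impurity importance is reported as-is (see above); no statistical tests
  on importance differences.
* Synthetic outcome laws are linear with additive Gaussian noise; real
  structure–function relationships are unlikely to be either.
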