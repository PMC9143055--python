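# Methods

This note records the models, parameter choices and numerical details behind
`msitma`, and what the synthetic studies do and do not demonstrate.

## Synthetic TMA model

Each dataset is defined by a `SimulationConfig`. A dataset has `n_slides`
runs; slide *s* carries `cores_per_slide` annotated cores plus one kidney
reference core, laid out on a square lattice of discs of radius
`core_radius_px` (pixels; physical pitch `pixel_size_um`, default 85 µm).
Labels are assigned per slide with exactly
`round(tumour_fraction * cores_per_slide)` tumour cores, and consecutive
same-class cores are grouped into patients of 1–4 cores, mirroring how real
TMA blocks gather several cores per case.

Intensities follow a multiplicative log-normal model on positive baselines:

- a per-feature baseline b<sub>j</sub> ~ LogNormal(ln 50, 0.6) over
  `n_features` true peak positions drawn in 100–1000 m/z with ≥ 100 ppm
  separation (so a 10 ppm matching window is unambiguous);
- a tumour template equal to the baseline with `n_markers` randomly chosen
  features multiplied by 2^`marker_log2_effect`; a kidney template obtained
  by an independent per-feature log-normal modulation;
- pixel intensity = template × slide factor × exp(N(0, `noise_sd`)), with
  the slide factor exp(N(0, `slide_batch_sd`)) shared by all pixels of a run;
- background (non-core) pixels drawn i.i.d. Exponential(`snr_floor`) — pure
  noise floor, giving segmentation a real tissue/background contrast;
- the run's mass axis is the true m/z panel shifted by a run-level offset
  drawn N(0, `ppm_jitter_sd`) ppm.

The generator is centroid-level because the downstream pipeline operates on
centroids; `render_profile` renders any peak list into profile mode
(Gaussian peaks) for exercising peak detection. `simulate_core_table`
evaluates the same intensity model directly at core level (one draw per
core, no pixel rendering) for statistical studies where the pixel stage is
irrelevant; the pixel path is what the end-to-end demonstration uses.

**Demo conditions** (the package defaults): 3 slides × 44 cores, tumour
fraction 8/9 (117:15 ≈ 7.8:1, matching the order of imbalance of archival
breast-TMA cohorts where tumour cores outnumber adjacent-normal cores
roughly eightfold), 100 features with 5 markers at 2-fold effect, noise sd
0.3, slide batch sd 0.3, ppm jitter sd 2, radius 3 px. Batch-effect and
jitter magnitudes are not quantities the underlying study reports; they are
free parameters chosen once at plausible instrument-scale values and
documented here as such.

**FFPE simulation.** `simulate_ffpe_from_ff` keeps
`round(retention × n)` of a fresh-frozen peak list (default retention
158/908, the panel shrinkage observed between comparable FF and FFPE
acquisitions), sampling without replacement with lipid-range (600–900 m/z)
peaks down-weighted by 0.3 — FFPE solvent processing preferentially depletes
(phospho)lipids. Depletion is realised through the retention weighting
rather than by rescaling surviving intensities, which keeps the
retention = 1 case an exact identity.

What the generator does *not* emulate: isotope patterns and adducts,
within-run drift, chemical (structured) background, spatial intensity
gradients within cores, and histological heterogeneity inside a core.
Passing tests therefore demonstrate that the pipeline's stages are correct
and well-calibrated under a realistic noise/batch/imbalance structure — not
that the classifier's near-perfect demo metrics would transfer to clinical
spectra, whose effect sizes and artefacts are harsher.

## Pre-processing

- **Noise scale**: 1.4826 × median absolute deviation from the spectrum's
  median, computed over the values at or below that median. Restricting to
  the baseline half keeps genuine peaks out of the estimate; the 1.4826
  factor makes it consistent for Gaussian noise (verified to 2% by Monte
  Carlo in the tests).
- **Peak detection**: local maxima with intensity ≥ `snr_min` × noise
  (default 3 — a conventional choice, exposed in config since no canonical
  value exists); centroids refined by the intensity-weighted mean over the
  contiguous above-half-maximum bins.
- **Common axis**: greedy single-linkage merge over the sorted pooled
  centroids, opening a new cluster when the next centroid exceeds `ppm_tol`
  (default 10 ppm) relative to the running intensity-weighted cluster mean;
  ties break toward lower m/z. O(n log n), deterministic, and invariant to
  run order because pooling precedes clustering.
- **Recalibration**: a single global ppm offset per run, the median relative
  deviation of peaks matched to their nearest axis entry within tolerance;
  fewer than 3 matches ⇒ zero offset with a warning. A mass-dependent
  (e.g. linear-in-m/z) correction was deliberately not fitted: the generator
  and typical short-term drift are well described by a global shift, and the
  median keeps the estimator robust to mismatches.
- **Rasterisation**: nearest-axis-entry assignment within tolerance;
  unmatched peaks dropped, collisions summed.
- **Segmentation**: k-means (scikit-learn, fixed seed, `n_init=10`) on
  spectra normalised to unit TIC; default k = 4 (tumour, stroma, tissue
  background, slide background in stained-section terms), k = 2 suffices for
  plain tissue/background ROI work. Background clusters are those whose mean
  raw TIC falls below 0.2 × the global median pixel TIC; the fraction is
  config-exposed because the rule identifies background reliably only when
  tissue occupies roughly half the raster or more — when it fails (no
  cluster flagged), the pipeline falls back to treating all pixels as
  tissue, which degrades the spatial filter but nothing else.
- **Spatial feature filter**: a feature is kept iff it is non-zero in at
  least `spatial_filter_min_fraction` (default 1%) of tissue pixels *and*
  its mean on-tissue intensity exceeds its mean off-tissue intensity. This
  is a deliberately simplified spatial-coherence filter: two transparent,
  testable rules standing in for the richer statistic sets of dedicated MSI
  filtering packages. Across runs, a feature is retained if it passes on a
  majority of runs.

## Normalisation

- **Reference scaling**: each run is multiplied by one scalar ∝ 1/(median
  TIC over its kidney-reference pixels), with scalars normalised to mean 1
  (equivalently, the common target is the harmonic mean of the per-run
  reference medians — the convention that leaves the dataset's overall scale
  unchanged). After scaling, reference medians agree to machine precision.
  Median TIC of the kidney core was chosen as the anchoring statistic for
  robustness; the pipeline errors out, naming the slide, if any run lacks
  reference pixels.
- **Median fold change**: reference = dataset-wide feature-median spectrum
  (computed over the spectra being normalised); each spectrum is divided by
  the median ratio to the reference over features where both are positive.
  The defining property (post-normalisation median fold change ≡ 1) and
  idempotence are asserted in tests. A spectrum sharing no positive feature
  with the reference keeps factor 1 with a warning. In the pipeline MFC is
  applied to per-core average spectra — the classifier's inputs — rather
  than per pixel; at the pixel level the same operation is available but
  costs more and changes nothing downstream of core averaging in this model.

## Registration

Affine co-registration of binary masks (e.g. a TIC threshold mask against an
optical tissue mask): both masks are Gaussian-smoothed (σ = 2 px) so the
mean-squared-difference loss has usable gradients, and a 2×3 affine map is
fitted by gradient descent from the identity. Gradients are analytic (chain
rule through bilinear sampling of the moving image); the linear-part
gradient is divided by the mean squared centred pixel coordinate so both
parameter blocks live on the same displacement scale, the first step is
scaled to ~`step_size` (1 px) of displacement, and backtracking halving on
any loss increase makes the loss non-increasing over accepted iterations.
Fifty consecutive rejected steps ⇒ identity returned with a warning. The
returned parameters map moving (row, col) coordinates to fixed coordinates.
Tests recover a (5, −3) px translation to ~10⁻³ px and a 10°/1.1× similarity
to Dice 1.0 on an asymmetric blob.

## Classification

- **Weights**: w_c = n/(2 n_c); balanced data gives weight 1 to both classes.
- **Model**: logistic regression maximising the weighted log-likelihood
  minus (λ/2)‖β‖², λ = `regularization_strength` (default 10⁻²). Per-core
  averaged MSI data can be linearly separable, so some penalty is required
  for a finite optimum; the fit itself is delegated to scikit-learn's lbfgs
  solver (C = 1/λ) behind a surface that standardises features internally,
  stores the transform for prediction, and reports the weighted
  log-likelihood and a convergence flag. The fit is deterministic (convex
  objective).
- **Folds**: stratified on class, then repaired greedily (lowest indices
  first, swapping within class) until every test fold spans ≥ 2 slides.
  Patient identifiers are carried through but folds are not patient-grouped;
  with 1–6 cores per patient this is a known source of optimism on real
  data and is flagged as such.
- **Metrics**: TPR, TNR, FPR = 1 − TNR, balanced accuracy = (TPR + TNR)/2,
  F1 = 2TP/(2TP + FP + FN), confusion at threshold 0.5; ROC over all unique
  probability thresholds with trapezoid AUC, which equals the Mann–Whitney
  concordance probability exactly (asserted against a brute-force pairwise
  count).
- **PCA separation**: PCA on mean-centred spectra (full SVD, deterministic);
  per-component two-sided Mann–Whitney tests, exact enumeration for combined
  n ≤ 20 without ties, continuity-corrected normal approximation otherwise.
  U is reported in the min-rank convention, min(U₁, U₂), so complete
  separation gives 0.

Spectra enter the classifier untransformed (no log); the intensity model is
multiplicative, but after MFC normalisation the weighted LR separates the
demo conditions regardless, and the choice is config-free by design —
callers can transform `CoreFeatureTable.X` themselves.

## Feature refinement

- **LRT screen**: per feature, 2·(ℓ₁ − ℓ₀) where ℓ₁ is the maximised
  weighted log-likelihood of intercept + that single (standardised) feature
  and ℓ₀ the intercept-only closed form; p from χ²₁. The single-feature-vs-
  intercept form was chosen over full-model-vs-drop-one because with
  features ≫ cores the multivariable likelihood is penalty-dominated and
  drop-one tests are ill-defined. The solver is a small Newton/IRLS with
  step halving; under complete separation it stops at the iteration cap,
  where the statistic already dwarfs any χ² quantile. The LRT arm is not
  FDR-corrected; multiplicity control enters through the intersection with
  the BH-corrected univariate arm.
- **Univariate screen**: Kruskal–Wallis H with tie correction (χ²₁ p), BH
  step-up q-values (q_(i) = min_{j≥i} m·p_(j)/j, capped at 1).
- **Selection**: features with LRT p < α and BH q < α (α = 0.05 both arms);
  empty intersection raises an error advising a larger α rather than
  silently keeping everything. The reduced model reuses the full model's
  folds, so before/after metrics and ROC curves are directly comparable.
  An importance ranking by |standardised coefficient| of the fitted LR is
  available (`FitResult.feature_ranking`) but plays no part in selection.

Null calibration is tested: LRT and KW p-values are uniform under the null
(KS test over 500 features), KW type-I error is 5% ± 2%, and the no-signal
pipeline's balanced accuracy is 0.5 ± 0.1 over 20 seeds.

## Problem sizes

The bundled demonstration and the test suite run at deliberately modest
scale — 51×51-pixel slides, 100–200 features, 130–150 cores, 10–20 replicate
seeds — chosen so the full simulation-to-metrics loop stays in the
sub-second range per replicate while every estimator operates far from its
small-sample edge. The acceptance study (10 replicates of the demo) reports
the median cross-validated F1 as a percentage.

## Known limitations

- The SNR threshold and the background-TIC fraction are heuristics with
  config escape hatches, not estimated quantities.
- Recalibration is a global shift; strong mass-dependent miscalibration
  would need a lock-mass or polynomial model (out of scope).
- Folds are slide-aware but not patient-grouped (see above).
- The spatial filter is a two-rule simplification of spatial-coherence
  filtering; structured chemical background could defeat it.
- imzML support is read-only; vendor raw formats are not read.
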