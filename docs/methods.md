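# Methods

This note documents the models, conventions and numerical choices behind
`noderad`, and what the synthetic experiments do and do not demonstrate.

## Endpoints and survival model

Two time-to-event endpoints are modelled per patient, in months: local
control (LC; failure = regrowth of the primary tumour) and loco-regional
control (LRC; failure = the earlier of a local and a regional, i.e.
lymph-node, failure).  LRC is a composite: every LC failure is an LRC
failure and LRC failure times never exceed LC failure times.  All models
are Cox proportional-hazards models; a fitted model's linear predictor
Σ βⱼ zⱼ over z-scored features is its *rad score*.

The synthetic outcome generator draws LC times from an exponential
hazard `baseline_lc_rate · exp(lp_PT)` and independent regional failure
times from `baseline_regional_rate · exp(lp_LN)`, with independent
exponential censoring.  Defaults (`0.004`, `0.0035`, censoring `0.013`
per month) were chosen so that an uninformative cohort shows roughly 23%
LC failures, 36% LRC failures and a median follow-up near 4.5 years —
the structure of an advanced node-positive head-and-neck cohort under
definitive radiochemotherapy.  Under this generator the Cox model is
well-specified, which is what makes coefficient/selection recovery a
meaningful test.

## Phantoms

Each phantom patient is a 3-D HU grid with one connected PT blob and 1–5
LN blobs, all superellipsoids `|x/a|^p + |y/b|^p + |z/c|^p ≤ 1` with
random axis ratios (0.7–1), exponents (1.8–3) and rigid rotations, so
shape features vary non-trivially; `blob_shape: ball` produces exact
spheres for analytic checks.  Textures: `uniform`, `smooth-noise`
(Gaussian-filtered noise scaled to a target HU SD) or `two-class`
(blobby bright/dark compartments).  Artifact corruption overwrites
selected axial slices with alternating ±HU streaks and records the
indices.  LN centres are placed at distance ~`ln_spread` from the PT
centre with at least one voxel of clearance between structures, so the
PT∩LN = ∅ and component-labelling invariants hold by construction; a
grid too small for the request raises a placement error rather than
silently overlapping.

What the phantoms do **not** emulate: anatomy (no air/bone interfaces,
no nodal levels), realistic partial-volume effects, scanner-specific
noise spectra, or contrast-phase variability.  Passing tests therefore
demonstrate correctness of the computational chain and its statistical
behaviour under a known model — not clinical performance.

## ROI preparation

* Eligibility: fraction of ROI volume on artifact slices must be
  **strictly less than** 0.5, evaluated on the original masks before
  slice removal, on the combined PT ∪ LN region by default (per-ROI
  evaluation is a config flag).  Contours (not image values) are removed
  from artifact slices.
* Resampling: tri-linear to 3.3 mm cubic voxels (a typical coarsest
  planning-CT voxel); masks tri-linear then re-binarised at 0.5.  On
  convex ROIs a few target voxels across, volume changes stay within
  ~15%.
* HU window [−20, 180] is a **closed** interval applied after resampling
  (a config flag swaps the order); out-of-window ROI voxels are excluded
  from intensity/texture analysis rather than clamped, because clamping
  would inject artificial modes into the histogram.  Shape features
  always use the full mask.
* LN components are labelled with 26-connectivity and merged into one
  ROI for feature extraction; the labels are retained for the
  distribution features.
* Coordinates: arrays are indexed (z, y, x) with the axial axis first;
  physical positions are `index × spacing` in mm.

## Feature panel

285 features per ROI: 18 shape + 17 intensity + 72 texture + 178 wavelet
(the 89 intensity+texture features on the LLL and HHH subbands).

* **Shape**: mesh volume and surface area from marching cubes on the
  mask after a light Gaussian smoothing (σ = 0.8 voxel) — without
  smoothing the staircase surface overestimates a ball's area by ~10%
  and biases every area-derived feature; the smoothing slightly shrinks
  mesh volumes of very small ROIs (a few percent at 10-voxel radius).
  Axis lengths are 4√λ of the voxel-coordinate covariance eigenvalues;
  elongation = √(λ₂/λ₁), flatness = √(λ₃/λ₁).  *Thickness* is the local
  diameter — 2× the Euclidean distance transform sampled on the medial
  skeleton — summarised by mean and population SD; for the merged LN ROI
  the thickness SD measures variability of node diameters.  The skeleton
  algorithm is not exactly symmetric under grid rotations, so thickness
  statistics are only approximately (±10–15%) rotation invariant; all
  other shape features are exact under axis-aligned 90° rotations (mesh
  quantities to ~1%).
* **Discretisation**: fixed bin width 5 HU anchored at −20 for the
  original image (≤ 40 bins over the window; the top edge belongs to the
  last bin).  Wavelet subbands have no HU anchor and use a fixed count
  of 40 bins over their own in-ROI range.
* **Texture**: IBSI formulas.  GLCM uses the 13 unique 3-D directions at
  distance 1, symmetric pairs, per-direction matrices normalised then
  averaged.  GLRLM merges runs over the same 13 directions.  GLSZM zones
  are 26-connected.  NGTDM uses the 26-voxel neighbourhood.  NGLDM uses
  dependence coarseness α = 0 (a neighbour is dependent iff its grey
  level is equal).  Degenerate ROIs (single grey level / single voxel)
  substitute 0 for entropy-type features and the analytic limit for
  ratio-type features (coarseness capped at 10⁶), logged, so constant
  phantoms cannot cascade NaNs into selection.
* **Wavelet**: one-level stationary (undecimated) separable Haar
  transform on the ROI bounding box (padded to even sides; edge
  padding), subbands placed back on the original lattice so masks apply
  unchanged.  The unnormalised convention is used: the LLL DC gain is
  2^{3/2}, and HHH annihilates constants exactly.

## LNPT features

All statistics use the **population** SD so single-node patients give 0
rather than NaN.  The tumour-volume normalisation (item 3) scales the
volume-weighted statistics by Σvᵢ/V_PT, i.e. the mean is Σ dᵢvᵢ / V_PT —
chosen so that the normalisation genuinely changes the value (a
normalisation that cancelled would duplicate item 2).  The MST vertex
set includes the PT; edge weights are the smallest distances between
voxel centres of the two structures (sub-voxel surface meshes would not
change the ordering on phantoms).  The cluster count maximises the
Calinski–Harabasz index over k = 2..6 (k-means, 10 restarts, fixed
internal seed); since CH is undefined at k = 1, a unimodality guard
reports 1 when the best 2-means split has centroids closer than twice
the mean within-cluster RMS radius, and tiny (< 4 voxels) or coincident
point sets also report 1.  All 14 features are invariant to rigid
motions, and the distance features are linear in scale.

## Selection and modelling

* **PCA sizing**: k = smallest number of principal components explaining
  95% of the variance of the z-scored training matrix, computed per
  feature group.  Radiomic panels are strongly inter-correlated, so k is
  typically far below the feature count; this is what makes a top-k
  selection informative.
* **MRMR**: greedy difference form, score = relevance − mean |Spearman
  ρ| to the already-selected set.  Relevance is |c − 0.5| of the
  feature's univariate Harrell c-index against the endpoint (identical
  to the c-index of a univariate Cox fit, since a single-covariate Cox
  linear predictor is monotone in the covariate).  Ties break
  lexicographically and deterministically.  Bootstrap: n patients drawn
  with replacement, event-free resamples redrawn; rate ≥ 0.60 survives.
* **LASSO-Cox**: scikit-survival's Coxnet path (30 penalties,
  `alpha_min_ratio` 0.05) per bootstrap resample; the penalty minimises
  the 5-fold cross-validated Breslow partial likelihood (`1se` rule
  available).  Candidates rank-identical (|Spearman ρ| = 1) to an
  earlier candidate are dropped before fitting to avoid coefficient
  splitting.  Features with ≥ 60% non-zero rate are refit unpenalised
  (lifelines; a small ridge fallback if the refit does not converge).
  An empty final set raises a model-building failure; a mixed model
  whose final set is only the forced LC rad score is returned but
  flagged unsuccessful — it adds nothing beyond the PT information.
* **Evaluation**: Harrell's c-index (ties = 0.5) on 100 bootstrap
  resamples of the validation cohort.  Resamples are drawn once per run
  from the follow-up structure only (resamples without comparable pairs
  are redrawn), so every model is evaluated on the same resamples and
  the Wilcoxon signed-rank comparison is validly paired.  Training
  standardisation is frozen inside each fitted model; validation labels
  are touched only by `evaluate`/`stratify`.
* **Stratification**: the rad-score threshold maximises Youden's J for
  failure by 18 months on the training cohort (patients censored
  event-free before 18 months are excluded from threshold fitting — the
  landmark treatment; counting them as controls is a config flag) and is
  then frozen for the validation split.  Log-rank tests are two-sided.
  An empty risk group is reported as a stratification failure, not an
  exception swallowed.
* The N-stage comparison model encodes N1–N3 ordinally (1–5) and enters
  the LASSO beside the LC rad score.

## Reproducibility experiments and problem sizes

The acceptance-level experiments run at the feature-matrix level (the
planted-effect claims concern selection and modelling; image extraction
has its own oracle tests).  The simulated panel uses a latent-factor
model — 30 noise features driven by 4 shared Gaussian factors plus
independent noise (SD 0.4), planted features independent — reproducing
the low effective dimension of real radiomic panels (PCA-95% k ≈ 7).
Sizes: selection recovery uses 20 replicates of n = 150 with two planted
features at |β| = 1.5 per SD, 200 MRMR and 50 LASSO bootstraps (a
scaled-down analogue of the 1000/100 production settings, which are the
defaults); the mixed-versus-PT study uses 150 training / 100 validation
patients and |β| = 1.2; null calibration pools ten 500-patient null
cohorts (a single cohort's bootstrap distribution centres on that
cohort's point estimate, whose sampling noise ~0.5/√events would
dominate the centring check) and 200 stratification repetitions.

The shipped demo config uses stronger planted effects and higher event
rates than the generator defaults so that all six model variants can
build on a 110-patient cohort; at paper-scale event rates and cohort
sizes, some variants are honestly reported "unsuccessful" when the 60%
rule discards their features — the same behaviour the original analysis
exhibits for its LNPT and N-stage models.

## Known limitations

* Shape thickness relies on a skeletonisation whose exact definition
  differs between radiomics implementations; the local-diameter
  definition here is a documented stand-in.
* Mesh-derived features carry a small size-dependent bias from the
  pre-mesh smoothing (see above).
* The MRMR relevance for survival endpoints is not standardised in the
  literature; the c-index-based choice is scale-free and censoring-aware
  but other choices (Wald z, mutual information) would reorder features
  in borderline cases.
* Whether wavelet subbands should be re-windowed before texture
  computation is unspecified in common practice; here each subband is
  re-discretised over its own range with a fixed bin count.
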