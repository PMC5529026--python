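# Methods

This note records the models glomkit implements, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic-data
generator does and does not emulate.

## Stereology: the Weibel–Gomez chain

The estimator converts planar-section measurements into 3D quantities under
a model-based (not design-based) set of assumptions: particles are convex,
randomly dispersed, and sections are isotropic uniform-random (IUR).

* `N_A = mean(n_WT1) / mean(tuft_area)` — nuclear profiles per unit tuft
  area. Ratio-of-means (equivalently ratio of totals) rather than
  mean-of-ratios: under unequal profile areas the ratio of totals is the
  unbiased estimator of the underlying density, whereas averaging per-profile
  ratios overweights small profiles.
* `A_A = mean(stain_area) / mean(tuft_area)` — the stained areal fraction, a
  dimensionless number in (0, 1]. This follows the original Weibel–Gomez
  definition of an areal *fraction*; the inverse ratio (tuft over stain)
  would be dimensionally inconsistent inside the N_V formula. The package
  computes stain/tuft.
* `N_V = (K/β)·sqrt(N_A³/A_A)` with defaults K = 1.1, β = 1.45 — the
  conventional values for podocyte nuclei, encoding a modestly aspherical
  nuclear shape and a narrow size distribution. `N_A = 0` short-circuits to
  `N_V = 0` (an empty glomerulus has density zero regardless of A_A); a
  positive count with A_A ≤ 0 is a contradiction and raises.
* `V_glom = mean(tuft_area)^1.5 · β/K` with defaults β = 1.38, K = 1.01 —
  the glomerulus treated as a near-sphere.
* `N_pod = N_V · V_glom`; density is reported as podocytes per 10⁶ μm³ (the
  unit is stated in every output header), and mean nuclear size as total
  stain area over total nuclei (reported absent when no nucleus was counted).

For an exact sphere the shape coefficient is β = sqrt(6/π) ≈ 1.382 and K = 1
for monodisperse particles (`SPHERE_COEFFICIENTS`). Two closed-form facts
anchor the test suite:

* the mean section area of a sphere under uniform offsets is (2/3)πR², so
  the volume formula with β = 1.38, K = 1.01 recovers
  1.38/(1.01·1.38199) = 0.9886 of the true volume;
* for monodisperse spherical nuclei, N_A = 2ρN_V and A_A = (4/3)πρ³N_V, so
  the full chain with the conventional coefficients overestimates a
  spherical ground truth by (1.1/1.45)·1.382 × 0.9886 ≈ 1.0366. The
  Monte-Carlo suite reproduces both to within its sampling error.

Per-animal estimates pool that animal's profiles; cohort values are
unweighted means of per-animal estimates (matching the convention of ~44
profiles analysed per animal). No correction is attempted for parietal
epithelial WT-1⁺ cells, and no disector/design-based counting is provided.

## Sectioning simulator

Glomeruli are spheres of radius R with n spherical nuclei of radius ρ whose
centers are uniform in the interior sphere of radius R − ρ; nuclei are never
edge-clipped, which isolates estimator bias from boundary artifacts. Section
planes take a canonical orientation with offsets uniform in (−R, R) — for
spheres this equals IUR sectioning by symmetry. A section yields tuft area
π(R²−h²); a nucleus at height z is counted iff |h − z| < ρ and contributes
π(ρ² − (h−z)²) of stain. Nuclear profile overlap is ignored: at the default
volume fraction (~5%) overlap is second-order, and the approximation is
additionally clamped so stain never exceeds the tuft disc. Profiles below a
configurable fraction of the maximal disc area (`min_rel_area`, default 0 —
how grazing profiles were excluded during manual selection is not
specifiable, so nothing is dropped by default) are dropped, not resampled,
with the dropped count reported and a warning past 50%.

## Endpoint study simulator

The design is terminal-cohort: two groups (lean, obese) × six ages
(12, 20, 24, 29, 34, 41 weeks) × 5 animals, each animal observed once.
Ordinary analytes (BUN, NGAL, Kim-1) are log-normal per group × age with
log-means rising in obese animals — chosen as a realistic order of magnitude
for aged obese rats, not fitted to any dataset. A latent fibrosis severity
`s = trajectory(group, age) + N(0, 0.25²)` drives three observables:

* uC3M (urinary collagen-III breakdown product, ng/mL) = 20 + 30·s + noise,
* microalbumin (μg/dL) = 150 + 900·s + noise,
* trichrome score = 1 + #{thresholds < s}, thresholds (1, 2, 3, 4) —
  equal-width on the latent scale. Pathologist scoring is judged, so only
  monotonicity of the score in severity is contractual.

Both concentrations are floored at 0 (they are concentrations); the default
obese trajectory (0.5 → 4.2) crosses all four trichrome thresholds. Urine
creatinine is log-normal around 60 mg/dL per animal. Limitations worth
naming: couplings are linear, so the simulator does not reproduce the ~90-
fold dynamic range real albuminuria can show (the fold-change benchmark
therefore uses reported cohort means as inputs); severity is the *only*
driver of both urinary markers, so simulated biomarker correlations are
upper bounds on what heterogeneous real animals would show.

## Count simulator

Counts are negative-binomial with `var = m + φ·m²` (gamma–Poisson, default
φ = 0.1 — a typical bulk RNA-seq biological CV of ~32%), over 12,000 genes
(roughly the detectably expressed fraction of a rat annotation) with
log-normal baseline abundances (σ_log = 1.5) normalized to proportions, and
an expected library of 2×10⁷ reads. Obese samples receive programmed
fold-change trajectories; lean samples are baseline. The five podocyte
transcripts (Nphs1, Nphs2, Wt1, Synpo, Ptpro) get a 50× abundance boost
(they are among the most abundant glomerular mRNAs) and a default obese/lean
decline of 1.0, 0.9, 0.8, 0.7, 0.35, 0.25 across the six ages — i.e. a 75%
reduction at the final age. A truth table lists every non-null gene and its
trajectory.

One deliberate consequence of simulating *relative* abundance: strongly
asymmetric programmed changes shift every RPKM through the library size
(compositional coupling). Benchmarks that target a programmed ratio either
keep the perturbed library share small or are read against that expectation.

## Transcriptome stage

* RPKM = counts·10⁹/(length·library), library = raw column sum.
* The DE test is a Welch two-sample t-test on log2(RPKM + 0.25) — the test
  is deliberately simple, deterministic and robust at n = 5; the pseudocount
  (0.25 RPKM) stabilizes low-expression logs and is configurable. Fold
  change uses cohort mean RPKM with the same pseudocount.
* BH adjustment runs across *all* genes within an age (the RPKM > 0.5 rule
  is a DEG criterion, not a test-universe filter). `is_deg` requires all
  three: |log2FC| > 1, mean RPKM > 0.5, adjusted p < 0.05.
* The composite normalizes per-gene cohort geometric means (ε = 0.01 added
  before the log) to age-matched lean and averages the five ratios;
  100 = no reduction. It is a pure ratio statistic — invariant to gene
  length and sample order.
* PCA: genes with overall mean RPKM > 0.5, log2(x+1), gene-centered, full
  SVD; scores and explained-variance fractions are returned.
* Longitudinal classes: *early-sustained* = significant at every age with
  |FC| ≥ 3 throughout; *progressive* = significant from the second age on,
  log2FC sequence monotone over those ages with a per-step tolerance of 0.1
  log2 units (strict monotonicity is fragile under noise; the value is
  configurable), a net direction, and not already early-sustained.
* Over-representation: right-tailed hypergeometric tail P(X ≥ overlap). The
  direction score (n_up − n_down)/sqrt(overlap) is a simple signed
  concordance and is *not* equivalent to any proprietary pathway-activation
  z-score.

The DE test and pseudocount used in the original analyses of such data are
typically unreported, so absolute DEG counts are not comparable across
implementations; the package is instead validated by truth recovery, null
FDP and power on simulated data.

## Endpoint statistics

Urinary analytes are divided by same-sample urine creatinine (missing
creatinine is an error, never a silent drop). Tukey HSD runs over the full
group × age cell family (12 cells): cell means, pooled within-cell MSE, the
Tukey–Kramer studentized-range statistic, and exact p-values from the
studentized-range distribution. Only the two reported families are returned
(obese vs age-matched lean; each obese cohort vs the youngest obese cohort),
but their p-values are adjusted against the full family — the standard
behavior of a two-way-design Tukey test. The implementation is verified
against statsmodels' `pairwise_tukeyhsd` to 10⁻⁸ and computes only the
reported comparisons for speed. Correlations pool lean and obese animals
(per-group regression is available by subsetting); R² is from OLS.

Fold changes are ratios of arithmetic cohort means, reported raw and
rounded to the nearest ten for headline phrasing ("90-fold").

## Benchmark problem sizes

The acceptance scenarios use: 2×10⁵ uniform sections (400 spheres × 500
sections) for the stereology recovery — comfortably above the 10⁴ minimum
needed for the closed-form comparisons; 20 global-null replicates and one
power replicate at 2,000 genes with 300 programmed 4-fold genes (a
late-disease-scale DE fraction of 15%, balanced up/down so compositional
shifts stay small); 5 replicate studies at the full 12,000-gene default for
the composite; 1,000 random p-vectors and every 2×2 table with universe
≤ 30 for the oracle-equivalence checks. The null-FDP quantity scores the DEG
caller's *calls* (all three criteria), since that is the decision the
pipeline reports.

## Known limitations

* Nuclei are equal spheres; ellipsoidal nuclei and edge clipping are not
  modeled (the coefficients' job is precisely to absorb such effects on real
  tissue, so simulated bias factors apply to the spherical idealization
  only).
* No image segmentation: the morphometry stage consumes per-profile
  measurements or binary masks, not slide images.
* The simulator's endpoint distributions are stylized; passing recovery
  tests shows the estimators are correct on data matching their assumptions,
  not that real tissue satisfies those assumptions.
* Trichrome scoring is simulated and validated for rank agreement only.
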