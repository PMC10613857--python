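# Methods

`psdlsm` replicates, end to end, a multivariate lesion–symptom mapping
analysis of post-stroke depression symptom domains: MADRS scoring into
five symptom domains, a data-driven factor corroboration, support-vector
regression lesion–symptom mapping (SVR-LSM) with permutation inference,
and Dice comparison of the resulting significance maps.  Because
patient-level cohorts of this kind are not publicly shareable, the
package ships a synthetic-cohort generator with planted ground truth, and
every claim the test suite makes is a claim about recovering that ground
truth — not about reproducing patient-level results.

## The mapping model

Let `X` be the `n × v` binary matrix of lesion status over the analyzed
voxels (voxels lesioned in at least `min_overlap = 5` patients) and `y`
a behavioural score.  The analysis chain is:

1. **Volume and confound correction.**  Each column of `X` is replaced
   by its OLS residual on `[1, volume]`; `y` by its residual on
   `[1, volume, NIHSS, age, sex]`.  After this step `corr(y_resid,
   volume) = 0` to machine precision, so surviving voxel effects are
   location-specific rather than lesion-size effects.
2. **Model fit.**  An epsilon-SVR with RBF kernel
   `K(x, x') = exp(−γ‖x − x'‖²)` predicts `y_resid` from the rows of the
   residualized lesion matrix.  Patient feature rows are scaled to unit
   Euclidean norm before the kernel, which keeps squared distances in
   `[0, 4]`; this reproduces the geometry that the direct
   total-lesion-volume-control convention gives binary masks, and it is
   the regime in which the toolbox-lineage defaults `C = 30`, `γ = 5`,
   `ε = 0.1` are meaningful.  Defaults are configurable.
3. **Back-projection.**  The voxel statistic is the sensitivity map
   `β_j = Σ_i d_i x_ij` over support vectors with dual coefficients
   `d_i`.
4. **Permutation inference.**  `y_resid` is permuted `B` times (seeded),
   the SVR refitted, and the one-tailed voxel p-value is
   `p_j = (1 + #{β*_j as or more extreme}) / (1 + B)`.  The `+1`
   smoothing never returns zero.  Because only `y` is permuted, the
   kernel is computed once and reused by every refit; this is what makes
   `B = 1000` (desk scale) or `B = 10 000` (cluster scale) cheap.
5. **Thresholding and smoothing.**  Voxels with `p < 0.005` form a
   binary map that is smoothed with an isotropic Gaussian (2 mm FWHM by
   default; `σ = FWHM/2.3548`, with a flag to interpret the width as σ)
   and re-binarized at 0.5.  On a plateau this is the identity; an
   isolated significant voxel at 1 mm voxels is removed — the smooth is a
   despeckler.  Smoothing p-values before thresholding is available as an
   option.  Voxels outside the minimum-overlap set are never significant.

### Permutation scheme

Two schemes are implemented (`perm_scheme`):

* **`freedman_lane`** (default): permute the residualized behaviour
  vector and re-residualize it on the same design before refitting, so
  observed and permuted statistics are both computed on
  volume/confound-orthogonal vectors.  This scheme is *exactly invariant*
  to a pure lesion-volume effect added to behaviour: such an effect lies
  in the span of the nuisance design and is annihilated before the
  permutation ever sees it.  Naively permuting residuals *without*
  re-residualization is measurably conservative (the permuted vector
  regains a nuisance component the lesion columns no longer carry).
* **`manly`**: permute the raw behaviour vector, then residualize.  This
  is exact under a full-independence null, but a strong nuisance signal
  in behaviour survives (permuted) into the permutation distribution and
  costs power, so it is not the default.

### What "calibrated" means here, and its limits

Under the null (behaviour independent of lesions) the marginal
distribution of each voxel's p-value is uniform up to the `+1`
smoothing; across 52 measured null cohorts the grand mean p-value is
≈ 0.503 and rejection at `p < 0.005` occurs at ≈ 0.4–0.5 %.  However,
all voxels of one run share the same permutations and the same fitted
duals, so per-run rejection fractions are heavily overdispersed relative
to a binomial reference (SD ≈ 0.004 instead of 0.0013), and a run's
entire p-map shifts coherently (per-run mean p ranges ≈ 0.40–0.62).  Any
check that treats pooled voxel p-values as independent — a pooled
binomial interval or a large-n KS test — is therefore stricter than the
inference warrants and can fail on some seed batches for a perfectly
valid test.  The substantive guarantee is one-sided: the test is never
anti-conservative.

## The synthetic cohort generator

The generator emulates an acute ischaemic stroke cohort:

* **Lesions** are connected blobs grown by stochastic (Eden-type)
  dilation from a seed voxel until a target volume is reached.  Seed
  voxels fall in the right half-grid with probability 104/185 (emulating
  a 104:81 right:left excess; bilateral lesions arise when growth crosses
  the midline) and are drawn from a Gaussian around the hemisphere centre
  — infarcts cluster in the middle-cerebral-artery territory, and
  uniform seeding would leave cohort-level overlap everywhere below the
  five-lesion analysis threshold.
* **Volumes** are log-normal, moment-matched to a mean of 33.58 cm³ with
  SD 50.91 cm³ and clipped to 0.01–268.11 cm³.  The default grid is 32³
  voxels of 5 mm (a 160 mm box): coarse, but large enough that the
  default cohort's ≈ 2800 analyzed voxels carry a realistic overlap
  profile (peak overlap ≈ 16/200 patients).
* **Behaviour**: the latent score of domain *d* for patient *i* is
  `effect_d · damage_fraction(i, region_d) + volume_effect ·
  volume_i/max(volume) + N(0, noise_sd)` with defaults `effect = 3`,
  `volume_effect = 0.5`, `noise_sd = 1`.  The ten MADRS items are
  `loadings @ latent` (default loadings: each item indicates its domain),
  linearly rescaled from the fixed reference range `(−2, 10)` to `0–6`,
  rounded half-up and clipped.  Items within a domain are therefore
  deterministic functions of the domain's latent score; the sample item
  correlation matrix has rank five exactly, which the factor tests
  exploit as a closed-form expectation (cumulative explained variance at
  five components = 100 %).
* **Covariates**: age uniform 45–90, sex Bernoulli(114/200), NIHSS a
  clipped rounded normal (12.85 ± 4.56, range 0–25) — all independent of
  the latent symptoms, so any downstream association with them is a
  false positive by construction.

All randomness flows from one integer seed through named substreams;
`(spec, seed)` reproduces a cohort bit for bit.

What the generator does **not** emulate: vascular territory anatomy,
haemorrhage, white-matter specificity, scanner noise, segmentation error,
and realistic inter-item noise (items within a domain are perfectly
correlated).  Passing tests therefore demonstrate that the machinery
recovers planted structure under idealized conditions, not that the
emulated study's anatomical claims are correct.

### The planted-recovery benchmark

`recovery_benchmark_spec()` defines a focused power experiment: one
radius-2 critical region (33 voxels) drives the motivational score with
an effect of 8 latent-noise SDs at full damage; lesions are small focal
infarcts (log-normal mean ≈ 22 voxels ≈ 2.8 cm³) seeded tightly around
the region.  The deliberate choice of lesions *commensurate with the
region* matters: with cohort-scale lesions (tens of cm³), every voxel
within a lesion-diameter of a critical region is genuinely
damage-coupled (lesion-status correlation with region damage ≈ 0.5), and
no voxel-wise method can both detect the region and exclude that
neighbourhood — the apparent "false positives" are real associations
created by lesion geometry.  In the commensurate regime the coupling
decays within a voxel or two of the region surface and recovery can be
scored sharply: across held-out seeds the benchmark achieves Dice
0.59–0.84 with the planted region, in-region sensitivity 0.55–0.82, and
false coverage below 0.06 % of out-of-region voxels.  The same geometric
smear is a recognized limitation of lesion–symptom mapping on real
cohorts, where significant clusters extend beyond critical structures.

## Factor analysis

Extraction is principal components of the item correlation matrix (not a
common-factor fit): eigenvalues sum to the number of items.  Five
components are retained (fixed, mirroring the five hypothesized domains)
and rotated with direct oblimin at δ = 0 (quartimin), solved by oblique
gradient projection.  The criterion is non-convex; the iteration is
restarted from the identity plus ten seeded random oblique transforms
and the best solution kept — without restarts the optimizer can stop in
a mixed local optimum.  Correctness is pinned by invariants rather than a
reference library: the rotated pattern satisfies `P Φ Pᵀ = A Aᵀ`
(communality preservation), Φ is a unit-diagonal correlation matrix, and
planted block loadings are recovered with Tucker congruence 1.00 at
n = 2000.  Factor scores use the regression method, `W = R⁺ (P Φ)` on
standardized items (pseudo-inverse because the planted-model correlation
matrix is exactly rank five).  Sign convention: the largest-magnitude
loading of each factor is made positive.  Data-driven factors are paired
with conceptual domains for map comparison by maximum absolute Tucker
congruence (Hungarian assignment) between loading columns and
domain-indicator columns.

## MADRS scoring

Ten items, each 0–6; global sum 0–60.  The five-domain scheme:
motivational = {lassitude, inability to feel}; emotional = {apparent,
reported sadness}; cognitive = {concentration difficulties, pessimistic
thoughts, suicidal thoughts}; somatic = {reduced sleep, reduced
appetite}; anxiety = {inner tension}.  A domain's standardized score is
its raw sum divided by its item count, putting all domains on the same
0–6 scale.  Severity bands default to the conventional MADRS cut-offs
0–6 / 7–19 / 20–34 / ≥ 35 (none / mild / moderate / severe); these are
an assumption — the emulated study cites but does not print its
cut-offs — and are configurable.

## Map comparison and statistics

Dice: `DC = 2|X∩Y| / (|X| + |Y|)`, undefined (an error) for two empty
maps; similarity bands low / low-moderate / moderate / moderate-high /
high at 0.20 steps, applied after rounding to two decimals because the
band edges are printed at two decimals.  Cluster labelling uses
26-connected components against any integer-labelled atlas volume plus a
code→name table; unknown codes are reported as "unlabelled".  Sample
statistics are Spearman correlations (average ranks, t-approximation),
one-way ANOVA across sexes (equal to the squared pooled t for two
groups), and Benjamini–Hochberg FDR over the whole batch of tests as one
family.

## The study replica

One run executes scoring → factor analysis → eleven SVR-LSM analyses
(global sum, five domain scores, five factor scores) → five
domain-vs-matched-factor Dice comparisons → covariate statistics, and
records a manifest (config echo, per-map hashes, Dice rows, digest) that
reruns bit-identically under a fixed seed.  Desk-scale defaults are 1000
permutations per analysis (≈ 30 s for all eleven on one CPU at the
default cohort size); the emulated study's 10 000 permutations are one
config field away.

## Numerical and design choices

* Voxel order in the lesion matrix is lexicographic (x, y, z); voxel
  coordinates are 0-based array indices; world coordinates only through
  the NIfTI affine.  Masks binarize at 0.5 on read.
* Lesions are never flipped across hemispheres.
* The one-tailed direction defaults to "positive": lesion presence
  associated with *higher* symptom scores, the direction in which the
  back-projected betas of a positive-control simulation come out.
* Ties in the permutation count are "as or more extreme" (inclusive).
* `n_permutations ≥ 100` is enforced; the p-value floor is
  `1/(B+1)`, so `p < 0.005` requires `B ≥ 200`.
* Cross-validated prediction (5-fold, seeded) is exposed as a goodness
  check and as an optional `(C, γ)` grid-search tuner.  At the inference
  defaults the RBF kernel is narrow and out-of-fold prediction is weak;
  with tuning enabled, cohorts carrying a strong planted effect predict
  out-of-fold (r ≈ 0.5), while pure-noise cohorts centre on zero.  The
  inference pathway does not depend on predictive tuning.
* Problem sizes in the test suite (200 patients on a 32³ grid, 1000
  permutations, 20 null seeds, n = 2000 for factor recovery) are the
  package's desk-scale study conditions; each is a config field.

## Known limitations

* The adjacency smear discussed under the recovery benchmark: with
  realistically sized lesions, maps necessarily extend beyond critical
  regions.
* Items within a domain are perfectly correlated under the default
  generator, which makes the factor-recovery task easier than real
  MADRS data; cross-loadings and item noise would lower congruence.
* Permutation p-values within one analysis are strongly dependent across
  voxels; voxel-counting checks on one run have far fewer effective
  degrees of freedom than voxels.
* No cluster-extent or family-wise correction is implemented (the
  replicated design thresholds voxel-wise only).
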