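# Methods

This note documents the models and procedures implemented in `itrait`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not show about real greenhouse scans.

## Trait registries

**RGB (67 traits).** A side-view scan is 20 images at 18° turntable steps.
Segmentation thresholds the excess-green index ExG = 2G − R − B with Otsu's
method (ExG is ~0 for gray/white background and large for foliage),
followed by a 3×3 morphological opening and largest-connected-component
selection; degenerate contrast yields an empty mask with a warning rather
than an error. Traits are computed on the view with maximal horizontal
plant extent (ties broken by lowest view index). The registry is 15
geometry/architecture traits (TPA = foreground pixel count × calibrated
pixel area, height, width, height/width ratio, convex-hull area, solidity,
perimeter, bounding-box fill, centroid height fraction, top-half area
fraction, compactness 4πA/P², left/right maximal extents, skeleton length,
stem width as the median row width over the bottom 10% of plant rows), 12
color summaries (mean and sd of R, G, B, hue, saturation, value over plant
pixels) and 40 hue-histogram bin fractions. The geometry/color/histogram
split is this package's concrete realization of a 67-trait registry whose
full original listing lives outside the primary record; the named members
(TPA, height, width) and the cardinality are fixed, the remainder are
standard shape/color descriptors. Units are pixels unless an mm-per-pixel
calibration is supplied.

**HSI (2000 traits).** Band index b ∈ {1..250} maps linearly to wavelength
through the anchors (15 → 434 nm) and (233 → 959 nm), i.e. ~2.41 nm/band
over roughly 400–1000 nm. Over the plant pixels (mask supplied, or an
NDVI-like red/NIR contrast with Otsu threshold when not) each band gets a
total T_b and an average A_b reflectance. Eight families — T, A, lgT, lgA,
dT, dA, ddT, ddA — give 8 × 250 = 2000 traits. The family set is the
symmetric completion forced by the cardinality (2000/250 = 8) that contains
every named family member (T, A, lgA, dT, ddT). Logs are base 10 with
non-positive arguments missing-coded, never clipped. Derivatives are taken
with respect to band index at unit step (central differences inside,
one-sided at the ends); with constant nm spacing this is proportional to
d/dλ, and trait names index bands, so band-step derivatives are the natural
convention. No spectral smoothing is applied.

**CT (100 traits).** A scan is a 360-projection sinogram at 1° steps.
Reconstruction is filtered back-projection (ramp filter by default, Hann
optional; linear interpolation; square output with side = detector-bin
count). The `_700`-style suffix is interpreted as an intensity threshold on
the reconstructed slice; the ladder τ ∈ {100, 200, …, 1000} with 10
measures per threshold (culm diameter = max Feret diameter of the
material+hollow union, hollow/material/total areas, wall thickness = mean
outer-minus-inner radius over 360 rays marched from the ring centroid,
outer perimeter, hollow fraction, eccentricity, mean material intensity,
hollow-centroid offset) reproduces the 100-trait cardinality with the named
members (hollow_area_700, culm_diameter_700). The material mask is the
largest connected component ≥ τ; the hollow is its enclosed sub-threshold
interior. Thresholds with empty segmentation are missing-coded. One
mid-stem slice is analyzed per scan; the default spatial calibration is
36 μm/px.

Over the full design — 10 RGB, 4 HSI and 3 CT time points, each under WW,
DS and the DS/WW ratio view — the assembled table has 67×3×10 +
2000×3×4 + 100×3×3 = 26,910 columns.

## Drought-trait selection

Stages run in fixed order on the assembled table.

1. *3σ outliers.* Values outside mean ± 3 sd of the raw column are
   missing-coded. Statistics are computed once from the raw column (a
   single pass, the standard reading of the PauTa criterion at 99.7%
   normal coverage), not iteratively re-estimated; a frozen-statistics mode
   makes re-application idempotent.
2. *t-test.* Welch's unequal-variance two-sided t-test on accession means
   (replicates averaged) between the WW and DS arms; keep if p < 0.05.
   Welch is the safer default where only "independent-samples t-test" is
   specified; treatments are between-pot, so no pairing is assumed. No
   multiple-testing correction is applied at this stage by design.
3. *MLP importance.* One single-hidden-layer perceptron (64 units, early
   stopping) classifies WW vs DS rows from the standardized traits that
   survived stage 2; per-trait permutation importance is normalized so the
   top trait scores 100%, averaged over 5 independently seeded fits; keep
   if the mean normalized importance ≥ 50%. Normalization-to-max mirrors
   how "normalized importance" is conventionally reported as % of the
   maximum. A low-class-separation flag is raised when the model does no
   better than the majority class.
4. *Heritability.* H² = σ²G/(σ²G + σ²e/r) from a one-way random-effects
   model with accession as the random effect. The ANOVA estimator is used
   (σ̂²e = MS_within, σ̂²G = (MS_between − MS_within)/n₀, negative
   components truncated at zero); for the balanced interior case this
   coincides with REML. H² is estimated per watering condition and the
   trait is kept if it reaches 0.2 in either condition — the combination
   rule across conditions was an open choice; either-condition retention is
   the permissive reading and is configurable.

The final keep flag is the pure conjunction of the stage-2–4 flags after
stage-1 cleaning, so the report is auditable stage by stage.

## Association

Kinship is the VanRaden cross-product K = MMᵀ / (2Σp(1−p)) on
allele-frequency-centered genotypes; population-structure covariates Q are
the first 3 principal components of the centered genotype matrix.

The scan fits y = Qα + u + ε, u ~ N(0, σ²g·K), on replicate-averaged
accession values. The variance ratio is profiled by REML on the eigenbasis
of K (grid search then bounded refinement — exact for a single random
effect at these panel sizes), estimated once on the no-SNP null model and
frozen for every SNP test ("uncompressed P3D": no per-SNP REML, no
compression of individuals). Each SNP is then a generalized-least-squares
Wald test in the whitened space, computed by Frisch–Waugh residualization
so the whole panel is tested with vectorized linear algebra. SNPs with no
variance among phenotyped lines are skipped with a warning. PVE is the
standard fixed-effect form β²·Var(g)/Var(y) × 100. Significance defaults
to the uniform p ≤ 1/n-markers threshold.

QTL merging follows the iterative rule: significant SNPs within 100 kb on
the same chromosome are merged, repeatedly, until closure (on sorted
positions this is chaining of ≤100-kb gaps); each cluster is reported as
[min − 100 kb (floored at 1), max + 100 kb] with supporting traits
unioned. Intervals from distinct clusters separated by 100–200 kb can
overlap after expansion; the merging rule, not interval disjointness, is
the contract. Candidate genes are SNPs falling inside gene spans, 1-based
inclusive at both ends (GFF3/HapMap convention used throughout). LD r² is
the squared Pearson correlation of additive codings with pairwise deletion.

eQTLs: per gene and watering condition the same scan runs on expression
values; if any SNP clears the threshold the most significant one is
recorded. The eQTL is *local* iff that SNP lies within the gene span
± 10 kb (window boundaries inclusive) — this reconciles the "20-kb region"
phrasing (total flank) with the 10-kb per-side rule — and *static* when
the gene is detected under both conditions, *dynamic* under exactly one.
At the permissive 1/n threshold some null gene-condition pairs are
expected to reach significance (roughly 1 − (1 − 1/n)ⁿ ≈ 63% per scan);
recovery experiments therefore use a stringent explicit threshold.

## Prediction

**RR-BLUP.** y = 1μ + Zu with u ~ N(0, σ²u·I); marker columns are centered
on training means (so a zero-variance marker gets exactly zero effect).
λ = σ²e/σ²u is estimated by REML on the eigenbasis of ZZᵀ; effects are
û = Zᵀ(ZZᵀ + λI)⁻¹(y − μ̂), identically the ridge solution
(ZᵀZ + λI)⁻¹Zᵀ(y − μ̂) — the test suite pins this equality to 1e-8 against
a dense solve. With n < m a noiseless marker-generated phenotype is not
identifiable by REML (any y interpolates), so the interpolation limit is
exercised at a fixed small λ.

**Bayes A.** Gibbs sampler with a scaled-inverse-χ² prior per marker
variance: conjugate normal updates for effects, inverse-χ²(df₀+1) updates
for marker variances, plus intercept and residual-variance updates.
Defaults: 5000 iterations, 1000 burn-in, thin 5, prior df 5, scale set so
the prior mode spreads half the phenotypic variance over the markers (an
R² = 0.5 rule). Fully seeded. At large prior df with scale matched to
RR-BLUP's σ²u the sampler collapses to the ridge solution; the tests
require prediction correlation > 0.99 in that limit.

**Gene-set evaluation.** Candidate sets are the top-k genes' best SNPs
(k ∈ {1, 10, 20, 30, 40, 50, 100, all}); random sets are size-matched
draws from non-candidate SNPs (50 redraws by default, cycled over
repeats). Each repeat is a fresh 50/50 train/test split; accuracy is
Pearson r(predicted, observed) on the test half. Candidate vs random is
compared by a one-sided Welch t-test on the accuracy distributions. The
repeat structure (candidate repeats vs random redraws) is configurable
since the original protocol leaves it ambiguous.

**Stepwise markers.** Forward selection with backward elimination on
ratio i-traits against survival rate: entry if the partial-F p < 0.05,
removal if p > 0.10 (the conventional stepwise defaults of the tooling the
procedure implies), stop at 20 steps or no admissible entry; predictors
collinear with the current model (residual variance < 1e-8 relative)
never enter. The cumulative-R² path is reported and is non-decreasing.

**Spectral indexes.** On the average-reflectance spectrum with the band→nm
map: green peak = max A over 500–590 nm, red valley = min A over
620–700 nm, green-peak area = ∫A over 500–590 nm, red-edge area =
∫(dA/dλ) over 680–760 nm (trapezoidal). The windows follow standard
remote-sensing definitions since the indexes are named without formulas.
Being average-based, the indexes are invariant to plant size.

## Synthetic data

The generators define the study conditions: 368 accessions, 2 replicates,
MAF ≥ 0.05, trait H² centered on 0.4, WW/DS arms with ratio traits.

- *Genotypes*: per-SNP Binomial(2, p) with p ~ U(maf_min, 1−maf_min),
  columns redrawn until the realized MAF clears the floor; optional
  k-subpopulation Balding–Nichols divergence (F-model) supplies genuine
  kinship/PC structure for Q+K to absorb. Linkage disequilibrium between
  neighboring SNPs is *not* modelled.
- *Traits*: accession genetic value = planted causal-SNP effects + a
  polygenic deviation, rescaled so the realized genetic variance equals
  σ²G exactly; replicate noise is Gaussian (Student-t optional, to
  exercise the 3σ filter); variance components use the convention σ²G =
  h², σ²e = r(1−h²), under which H² = σ²G/(σ²G + σ²e/r) = h² identically
  for any r. DS values add a treatment shift plus per-causal-SNP
  drought-specific effects so ratio traits carry genetic signal; a
  baseline offset (default 10) keeps ratios well-behaved.
- *Phantoms*: the silhouette is a stem rectangle plus alternating leaf
  ellipses; leaf thickness is binary-searched and the stem locally widened
  so the foreground pixel count equals the requested area *exactly*, giving
  analytic ground truth for TPA/height/width. The leaf spectrum is a
  smooth parametric curve with a green peak (550 nm), chlorophyll-scaled
  red valley (670 nm), red edge (680–760 nm) and a water-scaled 960-nm
  absorption dip, so derivative traits and the four indexes respond in
  known directions. The culm is an annulus of known radii forward-projected
  with the discrete Radon transform at 1° steps; round-trip tests require
  radii recovered within 1 px and hollow area within 2%.
- *Expression*: baseline + planted eQTL genotype effects + Gaussian noise,
  one planted eQTL per gene; local SNPs lie within 10 kb of the gene span,
  distant ones beyond it; dynamic eQTLs activate in exactly one condition.

What passing tests show — and don't. The phantoms have exact geometry, flat
backgrounds, no illumination gradients, no occlusion, no CT beam hardening
or scatter, and the genotype panel has no LD; recovery on these inputs
validates the *algorithms* (segmentation logic, calibration arithmetic,
estimator consistency, solver correctness), not robustness to the noise
structure of real greenhouse imagery or real maize LD patterns. Population
catalogue numbers from the original study (thousands of significant SNPs,
QTLs and candidate genes) require the real panel and are out of scope.

## Problem sizes and numerics

Simulation-based checks run at panel sizes chosen to make each property
measurable with stable statistics on a single CPU: heritability recovery
at 368 accessions × 2 replicates over 50 panels; scan calibration at 200
individuals × 2000 SNPs over 20 null panels (KS uniformity, pooled);
power at 368 × 5000 with a planted 20%-PVE SNP over 50 panels; QTL-merge
agreement on 1000 random configurations against a union-find oracle;
genomic-selection discrimination at 250 × 600 with 30 causal SNPs over
100 split repeats; stepwise recovery at n = 368 with 15 planted ratio
traits among 60. Kinship eigendecompositions are clipped at zero;
REML profiles use a 64-point grid plus bounded refinement; p-values are
floored at the smallest positive float; PVE is clipped to [0, 100];
negative variance components truncate to zero.
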