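# Methods

This note documents the models, defaults and design choices behind
`genoffset`, and what the synthetic study system does and does not
establish about real data.

## The estimation problem

A population locally adapted to its climate carries allele frequencies
tuned to that climate. Under a projected future climate, the frequencies
that *would* be favoured differ from those present; the scalar size of
that difference — the genomic offset — is read as maladaptation risk.
Two estimators are implemented, sharing one upstream model of
genotype–environment association but making different functional
assumptions.

## Latent factor mixed model (GEA stage)

For mean-imputed, column-centered dosages `Y` (n × L) and standardized
climate `E` (n × d, d = 5), the model

    Y = E·B + U·Vᵀ + ε

is fit by (1) ridge regression of `Y` on `E` (penalty λ = 1e-5, chosen
for numerical stability with negligible shrinkage), (2) truncated SVD of
the residual for the K factor scores `U` (randomized SVD, fixed internal
seed; sign convention: each factor's largest-magnitude loading is
positive, making outputs bit-reproducible), (3) re-estimation of `B`
given `U`.

With climate collinear with structure — the central difficulty of
latitudinally structured species — the deflation assigns the shared axis
to `E·B`, not to `U`. Residual confounding therefore survives in the
per-locus tests and is handled downstream: per-variable z-scores are
rescaled by the genomic inflation factor (median z² over the χ²₁
median), after which calibrated p-values on null simulations are
uniform (KS-tested in the suite) and Benjamini–Hochberg selection at
q = 0.01 holds its error rate (realized FDP ≈ 2–3% at nominal 1% in the
planted-locus simulation, power ≈ 100% at β = 1.5 with n = 493).

**Choosing K.** `select_K` masks 5% of dosage entries, reconstructs them
with a rank-K truncated SVD (five imputation sweeps) and picks the K
minimizing held-out RMSE, smallest K on ties. The matrix is left
*uncentered*: K discrete ancestral pools whose admixture weights sum to
one induce a rank-K mean structure uncentered but only rank K−1 after
centering, so a centered selector could never return the pool count.
On demography-only genotypes (2000 loci, 500 trees, three
latitude-ordered pools) the selector returns K = 3 in 10/10 seeds. When
climate-adaptive loci are included the selector returns larger K — that
is correct behaviour, since those loci add genuine low-rank structure;
practitioners likewise choose K from neutral or pruned marker sets.

## Genetic gap

    G(e_cur, e_fut) = Δeᵀ·C_b·Δe,   C_b = B·Bᵀ/L over candidate loci

equals the mean over loci of the squared predicted genotypic change.
Properties relied on by the tests: symmetry in the two climates, zero at
identity, quadratic scaling, and exact agreement (1e-10) with the
per-locus brute-force sum. A prose-literal variant (effect-size-weighted
mean |Δe|) is available as `genetic_gap_literal` for comparison; the
quadratic form is the default everywhere, including spatial projection.

## Gradient forest

Each candidate SNP gets a random regression forest (defaults: 500 trees
for release runs, mtry = ⌈(d+K)/3⌉, min leaf 5, bootstrap with
replacement; scikit-learn forests). Confounder axes U1..UK enter as
predictors, following the wrapper approach of combining latent factors
with gradient forest. Every split's impurity decrease is accrued to its
predictor at the split threshold; a SNP's accrued mass is normalized to
its out-of-bag R² (R² ≤ 0 ⇒ dropped) and accumulated over SNPs onto 201
equal-width bins per predictor spanning the training range. The
cumulative sums are the turnover functions F_p: nondecreasing, F_p = 0
at the training minimum, plateau = total importance at the maximum, and
clamped outside the range (no extrapolation into novel climates). The
offset is the Euclidean distance in F-space over climate predictors
only. A reference-style split-density standardization was prototyped and
did not improve ground-truth tracking on this generator, so the simpler
binned accumulation is kept.

## Synthetic study system

The generator emulates a paired-site design for a montane tree species
along ~15° of southern-hemisphere latitude.

* **Design.** 10 pair locations evenly spaced (jittered) on latitude
  [−54.8, −40.1]; within-pair great-circle distance ~ 0.6 + 1.6·Beta(2, 4.4)
  km (mean 1.1, range 0.6–2.2) and elevation contrast ~ 150 + 170·Beta(2, 2.25)
  m (mean 230, range 150–320); one high and one low member per pair;
  sites numbered north→south; one sampling area per pair. Elevation
  co-varies with latitude (≈ +92 m per degree northward) so northern
  populations sit higher — the confounding the pipeline must handle.
  Longitude scatter and pair-level elevation noise are residualized
  against latitude: with only ten locations, raw random draws routinely
  produce |r(lon, lat)| ≈ 0.3–0.5, which would destroy the design's
  intended quasi-orthogonality of temperature and precipitation
  gradients.
* **Climate.** Five variables as linear functions of latitude,
  longitude and elevation plus smooth field noise and per-tree
  microclimate noise (the split matters: with ~10 effective locations,
  purely field-level noise produces chance inter-variable correlations
  up to 0.9). Defaults (units per degree/metre): bio3 lat 0.45; gst lat
  0.70, lapse −0.0055; scd lat −2.0, elevation 0.025; bio12 lon −380,
  lat −5; bio15 lon 4.5. Max pairwise |Pearson r| at tree positions
  stays below 0.77 (max 0.69 over a 60-seed sweep). Tree values are
  bilinear raster extractions plus a lapse-rate correction for the
  tree-vs-terrain elevation difference, mirroring practice when point
  elevations are better known than the DEM.
* **Scenarios.** Three severities × two periods; shift vectors are one
  base vector times a severity multiplier (1.0/1.15, 1.6/2.6, 2.1/3.6
  for mid/late), so severities are exactly proportional and offset
  monotonicity across scenarios is an exact property. Shifts vary
  spatially: a per-degree latitudinal gradient (warming stronger toward
  the northern trailing edge) and elevation-dependent warming
  (0.0006 °C/m per severity unit). Spatial non-uniformity is essential,
  not cosmetic: under a spatially flat shift the scaled Δe is identical
  for every tree and the genetic gap degenerates to a near-constant,
  unable to rank sites at all.
* **Genotypes.** Neutral loci: Balding–Nichols pool frequencies
  (F = 0.10) around a common ancestral frequency, mixed through
  latitude-Gaussian admixture weights (three pools). Adaptive loci
  (100 of 2000 by default): individual allele frequency
  logit-linear in one standardized driver variable, |β| ~ U(0.5, 1.5),
  random sign. Dosages are binomial(2, freq); no linkage. PC1 of the
  neutral block correlates with latitude at |r| ≈ 0.99.

**What passing tests do not show.** The generator has no linkage
disequilibrium, no isolation-by-distance beyond the admixture cline, no
spatially autocorrelated selection mosaic, binomial (not overdispersed)
sampling, and logit-linear allele-frequency clines that match the
linear-response assumption of both offset statistics. Validity results
here are therefore a best-case calibration of the machinery, not
evidence about any real species.

## Offset validity and the forcing regime

Ground truth for validation is the mean squared change of expected
allele frequency across planted loci (`true_adaptive_mismatch`). In the
mild-forcing regime (optimistic scenario, mid-century) both statistics
rank sites consistently with that truth (Spearman ≈ 0.93 genetic gap,
≈ 0.82 gradient forest at the canonical example seeds) and with each
other (≈ 0.62). Under strong forcing the logistic clines saturate: cold
high-elevation trees sweep through the steep mid-slope while warm sites
plateau, a nonlinearity the gradient forest tracks but a quadratic form
cannot, so the two statistics increasingly disagree and can rank-invert
by the pessimistic late-century scenario. The validity suite therefore
asserts agreement in the mild regime and monotonicity — not agreement —
across severities.

## Numerical and I/O choices

* Rasters: in-memory numpy grids with cell-center WGS84 georeference,
  row 0 north; text I/O via ESRI ASCII grid (square cells). Nodata is
  NaN and propagates (ensemble means, bilinear neighbourhoods); it is
  never imputed.
* Bilinear extraction clamps the four-neighbour stencil in the outer
  half-cell margin; out-of-bounds points yield per-point error records,
  not silent NaN.
* Scaling: per-variable mean/sd (ddof = 1) fit once on the sampled-tree
  current-period table and applied to everything downstream, including
  future tables and raster grids. The scaler also stores the training
  min/max envelope; projection flags any cell whose current or future
  climate leaves it (novelty raster).
* Default projection grid: 120 rows of square cells covering the design
  extent plus a 0.4° margin (~0.13° cells, ~30 columns), ASCII-grid
  compatible.
* Regressions: unweighted OLS of site-mean offset on signed latitude
  (south negative), per elevation class; significance tiers p ≤ 0.05
  (solid), ≤ 0.1 (dashed), else none. Output headers state the sign
  convention.
* Test problem sizes: the suite runs GEA at up to 5000 loci × 493
  trees, gradient forests at 100 trees per SNP on ~90 candidate loci,
  and K-selection at 2000 loci × 10 seeds; release-scale settings
  (500 forest trees) are defaults in the pipeline config.

## Known limitations

* Effect sizes feeding the genetic gap come from the full-matrix fit,
  subset to candidates; loci discovered by a prior study enter only as
  an input list.
* The gradient-forest importance binning (201 bins) is a declared
  simplification of the reference split-density standardization; parity
  with the reference implementation is at the level of invariants and
  rank agreement, not numerical identity.
* Climate novelty flagging is binary (outside the training envelope on
  any variable); no distance-based extrapolation index.
* No confidence intervals on offsets.
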