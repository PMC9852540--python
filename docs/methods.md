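# Methods

This note documents the models, rules and numerical choices behind
`dieldecline`, in the order data flow through the pipeline.

## Trend classification

Each species receives a trend class with an explicit provenance, applied in
strict precedence:

1. a known IUCN trend: decreasing → declining; stable or increasing →
   non-declining (`iucn_trend`);
2. otherwise, a threatened Red List category (NT, VU, EN, CR) → declining
   (`category_rule`). The rule is justified empirically per dataset by
   `category_trend_concordance`: among threatened species whose trend *is*
   known, the fraction decreasing (above 0.91 in the study system);
3. otherwise a literature-derived trend, if present (`literature`);
4. otherwise unclassified.

A known IUCN trend always beats the category rule, so a stable CR species
stays non-declining. Unclassified species remain in denominator-style
summaries (a niche member is a niche member) and are coded 0 in the
decline regressions by default; `unclassified_mode="drop"` removes them
instead. Both modes exist because the source analysis is ambiguous on this
point; code-zero is the default because the full analysis set is described
as entering the decline model.

Threat knowledge is tri-state per species: all ten categories observed
(possibly all absent), or wholly unknown. A mixture of known and unknown
categories for one species is rejected as an ambiguous knowledge state.
Threat counts are defined only for species with known threats; the
contract admits 0–10 although observed counts in study-like data span 0–6.

Reported percentages are rounded half-up to one decimal, matching the
presentation convention of the source tables.

## Phylogenetic covariance and working correlation

`build_vcv` returns the Brownian shared-path covariance C (root-to-MRCA
path length; diagonal = root-to-tip depth). All regressions first divide C
by its maximum depth — a pure reparameterisation that stabilises the
signal-parameter search.

The working correlation for both regression families is the
Ornstein–Uhlenbeck-with-fixed-root form

    R_ij(α) = e^{-α d_ij} (1 − e^{−2α s_ij}) / √((1 − e^{−2α t_i})(1 − e^{−2α t_j}))

with s the shared path, t the depths and d the patristic distance. α → 0
recovers the Brownian correlation; α → ∞ gives independence; a star
phylogeny is exactly independent at every α (s_ij = 0), which pins the
estimator to ordinary penalised logistic regression in that limit.

Numerical constants (all on the unit-depth scale):

* α searched in [1e−4, 1e6] on the log scale. The upper bound must be
  large enough that e^{−αd} vanishes for the shortest cherries in a
  realistic tree; with a bound that is too small, independence is
  unrepresentable and the profile is forced toward spurious correlation.
* between-tip distances floored at 1e−4 (`DIST_FLOOR`): tips joined by
  zero-length branches would otherwise make R exactly singular at every α.
* Cholesky jitter 1e−8 on the diagonal.

α is profiled by minimising the Gaussian quasi-likelihood criterion
n·log(e'R⁻¹e/n) + log|R| over the Pearson residuals e of the current fit,
alternating with the coefficient update until the objective is stable. An
interior α is retained only if it beats the independence end of the range
by 2 quasi-likelihood units (`ALPHA_PENALTY`, an AIC-type margin for the
single correlation parameter). Without the margin, noise-driven working
correlations measurably distort small-sample fits; a stronger (BIC-type)
margin was rejected because it collapses essentially every binary fit to
exact independence, zeroing the across-tree spread that the ensemble
summaries exist to report.

## Logistic MPLE

Coefficients solve the Firth-adjusted GEE score
X'W^{1/2}R⁻¹W^{−1/2}(y − μ + h(1/2 − μ)) = 0 with W = diag(μ(1−μ)) and h
the generalised leverage; with R = I this is exactly Firth's penalised
logistic regression, which keeps estimates finite under the
quasi-separation that small niches invite. Newton steps are halved until
the score norm does not increase; convergence is declared at score norm
below 1e−8. Standard errors are model-based (inverse working
information). A sandwich estimator is undefined here: one phylogeny is one
GEE cluster, so there is no between-cluster variability to estimate.
P-values are two-sided Wald. A constant response returns a flagged no-fit.

## Poisson GEE

Log link; score X'A^{1/2}R⁻¹A^{−1/2}(y − μ) = 0 with A = diag(μ);
dispersion estimated from Pearson residuals; SEs model-based as above.
With the identity working correlation the estimating equations coincide
with the ordinary Poisson GLM score, so that limit is exact. All-zero
counts return a flagged no-fit.

## Pseudo-R²

McFadden by default (1 − ℓ/ℓ₀ on the Bernoulli or Poisson log-likelihood
at the fitted means, against an intercept-only null fitted the same way);
a Nagelkerke-style rescaling is available. Because a GEE fit under a
non-identity working correlation does not maximise the independence
likelihood, ℓ can fall below ℓ₀; deficits are clamped to 0 with a warning.
Values are diagnostics, not fitted quantities.

## Mk model and imputation

Equal-rates (default) or all-rates-different Mk, uniform root frequencies,
likelihood by Felsenstein pruning with per-node rescaling; the equal-rates
transition matrix uses its closed form. The rate is optimised on the log
scale over [1e−6/T, 1e3/T] (T = tree depth). Missing tips enter as
uninformative and receive marginal posteriors from a down-pass; imputation
assigns the maximum-posterior state, with exact ties broken by the fixed
state order (nocturnal, crepuscular, cathemeral, diurnal) and logged.
If all observed tips share one state the process is degenerate: rate 0,
point posteriors, a warning. Imputed species are excluded from every
regression, so imputation only affects the mapped niche compositions.

## Ensemble aggregation

B trees are drawn without replacement (seeded) and every model is refitted
per tree. Reported per term: mean coefficient, sample SD (n−1), fraction
of repetitions with p < 0.01 (over converged fits), and the tier
(≥ 0.90 `###`, ≥ 0.75 `##`, ≥ 0.60 `#`). Non-converged or degenerate fits
are dropped and counted; fewer than B/2 usable fits flags the summary
unreliable. Identical trees are fitted once and reused, which also makes
the degenerate identical-tree ensemble give exactly zero SD. Threat-specific
models are run only for threats affecting at least 50 declining species.

Sensitivity variants re-run the full study on: primates only, non-primates
only, literature-provenance trends reset to unclassified, and a recode
where VU/EN/CR → declining and LC/NT → non-declining (DD/NE become
unclassified, carrying no threat status to recode from).

## Maps

Per cell and niche: denominator = niche richness, numerator = niche
members that are declining, carry the threat, and are not overridden for
the cell's country. The default assumption is that a declining species
declines throughout its range; overrides subtract named (species, country)
pairs from the numerator only. Two masking modes are first-class because
the source describes both: `richness` (default) masks cells with ≤ 5 niche
species; `decliners` masks cells with ≤ 5 species declining from the
threat. Per-threat layers are not additive across threats (species carry
several threats) and must not be summed into a "total declining" layer.
Crepuscular layers are producible but excluded from default reports —
crepuscular richness is ≤ 5 over most cells, so nearly everything would be
masked. Rasters are written as single-band TIFFs with the grid geometry
(equal-area CRS id, cell size, extent) serialised in the description tag
and a companion byte band for the mask reason.

## Synthetic generator

The generator emulates the statistical structure the models assume, with
defaults matching the study system's magnitudes:

* birth–death tree (birth 1.0, death 0.3) conditioned on the species
  count, rescaled to unit depth; a posterior-like ensemble is faked by
  log-normal branch jitter (sd 0.1) and optional NNI moves;
* diel niche evolved by an F81-style Mk process (stationary frequencies
  0.695/0.022/0.105/0.178, switching rate 3 per unit depth — high enough
  that all four niches are represented at desk scale while clades still
  cluster);
* decline ~ Bernoulli(logit⁻¹(intercept + niche effect + latent)) with
  intercept logit(0.40) and niche shifts −0.01 (crepuscular), +0.12
  (cathemeral), +0.49 (diurnal); the latent effect is a threshold-style
  Gaussian with covariance `phylo_signal`·C (default 1.0) rather than the
  exact two-state evolving process — it is a generator, not the estimator,
  and only sign/coverage properties are asserted against it;
* threat draws are independent Bernoulli per category with niche-dependent
  rates dominated by habitat loss (~0.9 of decliners) and harvesting
  (0.25 nocturnal → 0.52 diurnal); non-decliners use the same rates scaled
  by 0.3;
* IUCN fields are drawn consistently with the classification rules
  (42 % unknown trends; threatened categories mostly attached to true
  decliners, with a 1 % leak to non-decliners mirroring the imperfect
  concordance; 64 % of otherwise-unknown trends resolved by "literature"),
  and a ground-truth sidecar records which records remain recoverable;
* ranges are contiguous random blobs (Poisson mean 12 cells) on a 20×20
  equal-area toy grid, with a vertical-band country raster and a few
  (species, country) overrides sampled among occupied countries.

What passing tests on these data do **not** show: realism of mammalian
biogeography or richness gradients, behaviour under taxonomic mismatch
between tree and table, or calibration under strong confounding between
niche and the latent effect — no GEE-type estimator is exactly calibrated
when the predictor and the residual share the phylogeny, so the
calibration suite uses an independence null, and coverage checks use
moderate sample sizes (400 tips, 50–200 replicates) chosen to keep the
default suite fast on one CPU.

## Known limitations

* The logistic estimator is a penalised GEE in the spirit of the
  Ives–Garland binary-trait model, not a line-for-line reimplementation of
  any existing package; α is a working-correlation parameter and its value
  is only loosely comparable across datasets.
* Model-based SEs under an estimated working correlation are mildly
  optimistic (measured 2-SE coverage 0.92–0.97 at 400 tips against a
  nominal 0.954).
* Imputation quality depends on the Mk fit; only max-posterior assignment
  is provided, and the uniform-root assumption is not configurable.
* Raster IO carries grid geometry in TIFF metadata rather than full
  geo-referencing tags; all grids must share one geometry — no
  reprojection is attempted.
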