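# Methods

## Model

`thresholdsire` fits a tri-variate threshold-linear sire model for a
teat-end hyperkeratosis score analysed jointly with daily milk yield (MY)
and somatic cell score (SCS, defined as `log2(SCC/100,000) + 3`).  The teat
score is observed ordinally — the full four classes (trait `TS`) or one of
two binary collapses (`TSa`: class 1 vs 2–4; `TSb`: classes 1–2 vs 3–4) —
and modelled through a latent Gaussian liability λ cut by thresholds.  On
the liability/observed scale,

    y(λ) = X b + Zh h + Zp p + Zs s + e

with

* `b` — fixed effects: a parity-by-stage-of-lactation class (3 parity
  classes × 12 stage bins = 36 classes; lactation months 12–15 pool into
  the final bin) for all three traits, plus hygiene score (4 classes) and
  udder quarter (FL/FR/RL/RR) for the teat trait only;
* `h ~ N(0, I ⊗ H)` — herd effects, `H` a full 3×3 covariance matrix;
* `p ~ N(0, I ⊗ P)` — cow permanent-environment effects;
* `s ~ N(0, A ⊗ S)` — sire transmitting abilities, with `A` the numerator
  relationship matrix of the pedigree.  Under a sire model the sire
  variance is one quarter of the additive variance, hence the factor 4 in
  heritability;
* `e ~ N(0, I ⊗ R)` — residuals.  Teat scores and production records are
  never observed on the same row (teat scoring happens at a dedicated
  herd visit; MY/SCS come from monthly test-day recording), so the
  teat/production residual covariances are structural zeros: `R` holds a
  liability residual variance and a free 2×2 MY/SCS block.

The month-binning rule deserves a note: a 3 × 12 grid closes at 36 classes
while still admitting records through lactation month 15 only if the late
months pool, so months 12–15 share the final stage bin.  This is a
modelling choice, exposed in `parity_stage_class`.

### Identifiability of the liability scale

Binary traits fix the threshold at 0 and the liability residual variance at
1 (the standard probit normalization).  The four-class trait instead pins
the first two thresholds at 0 and 1 and *estimates* the liability residual
variance together with the free third threshold.  The two parameterizations
are equivalent reparameterizations of the same model; the pinned-threshold
variant is used for `TS` because it is the one under which reported
four-class liability residuals carry information (a residual fixed at 1
cannot have a posterior distribution).  The scheme is selectable via the
`scheme` argument (`fixed_residual` / `estimated_residual`).

## Estimation

Gibbs sampling with data augmentation:

1. **Liabilities.**  Each teat row's λ is drawn from a normal centred on
   its linear predictor with the liability residual SD, truncated to the
   threshold interval of its observed category (vectorized inverse-CDF
   draws).
2. **Missing SCS.**  Test-day rows with MY but no usable SCC keep their MY
   information; the missing SCS is imputed from its conditional normal
   given the MY residual.
3. **Location effects.**  Fixed effects are drawn jointly per trait block
   (the teat design uses a corner constraint: one intercept per observed
   parity-stage class, hygiene and quarter offsets against a reference
   level; a singular design raises an error naming the confounded levels).
   Herd and cow effects are conditionally independent across levels given
   the rest, so all levels are drawn in one batched 3×3 operation; the
   sire vector is drawn jointly from its `3·q`-dimensional conditional
   (dense Cholesky) because `A⁻¹` couples sires.  These blocked updates
   are draw-equivalent to single-site Gibbs.
4. **Thresholds.**  The free cut of the four-class trait is uniform between
   the largest liability of the third class and the smallest of the fourth.
   This extreme-order-statistic update is notoriously sticky, so the free
   cut is initialized at its empirical cumulative-frequency position on the
   pinned 0/1 scale, which removes most of the burn-in it would otherwise
   need.
5. **Covariances.**  `H`, `P` from conditional inverse-Wisharts with
   effect crossproducts; `S` with the `A⁻¹`-weighted crossproduct; the
   2×2 production residual block from the production residuals (with
   augmented SCS); the liability residual from a scaled inverse-χ²
   (1-dimensional inverse-Wishart) when the scheme estimates it.  Priors
   are inverse-Wishart with identity scale and minimal proper degrees of
   freedom (dimension + 1); fixed effects are flat.  The identity scale is
   not innocuous: calibration runs showed it nudging small sire variances
   upward (its scale adds a unit to crossproducts of order ten) — but
   near-scale-free alternatives behaved worse, letting weakly informed
   variance chains collapse toward zero, so the identity scale is kept as
   the default and the `prior_*` attributes are exposed for overriding.
   The structural zeros of `R` are never sampled, so the constraint holds
   exactly at every iteration.

The default chain is 300,000 iterations, 50,000 burn-in, thinning every 50
(5,000 stored draws).  All randomness derives from a single seed; equal
seeds give bit-identical chains.  Chains are summarized by the posterior
mean, the 95% highest-probability-density interval (shortest contiguous
window of sorted draws) and Geweke's z (first 10% vs last 50% of the chain,
spectral variances by Bartlett-windowed autocovariance sums).

**Verification.**  Beyond unit oracles (closed-form truncated-normal
moments, GLS for fixed effects at known covariances, REML cross-checks on
Gaussian submodels), the sampler was validated during development against
an independent MCMC implementation of the identical model and priors
(JAGS, binary and four-class cases with estimated residual and free
threshold): posterior quantiles of all variance components, the liability
residual and the free threshold agreed to the third decimal.

### Point estimates

Genetic parameters (heritability `4σs²/(σs²+σp²+σh²+σe²)`, intra-herd
heritability, cow repeatability `σp²/total`, herd repeatability, and
correlations `cov/(sd·sd)`) are computed at every stored draw and then
averaged (mean of ratios).  The ratio of posterior means is a different
estimator — the two differ noticeably for nonlinear functionals such as the
intra-herd heritability — so both are exposed
(`ThresholdSireResults.point_estimates(method=...)`).

Least-squares means of teat fixed effects are formed per draw on the
liability scale (remaining fixed effects averaged over observed class
frequencies; equal weights would be an alternative) and mapped to
probabilities `P(score > k) = 1 − Φ((t_k − η)/σe)`.

## Selection-index response

For an index placing relative emphasis `e`% on MY and `−(100−e)`% on SCS,
the weight vector on the raw sire-covariance scale is
`w = (0, e/100, −(1−e/100))` and the correlated response of the teat trait
is `r = w′g₁ / √(w′Gw)`, divided by the teat sire SD to express it in
genetic standard deviation units.  Two open conventions are handled
explicitly:

* the response denominator (typographically ambiguous in the source
  formula) — the primary normalization is `√(w′Gw)`; `w′Gw` is available
  behind `normalization="wGw"`;
* "genetic SD" may mean the sire SD (`√σs²`, default) or the additive SD
  (twice that) — configurable, affects only the plateau scale.

The break-even emphasis — the smallest `e` with positive response — is
invariant to both conventions and to the never-reported MY–SCS genetic
covariance, because only the sign of `w′g₁ = (e/100)·cov(t,MY) −
(1−e/100)·cov(t,SCS)` matters; in closed form `e* = 100ρ/(1+ρ)` with
`ρ = cov(t,SCS)/cov(t,MY)`.  The high-emphasis plateau of the curve, by
contrast, depends on both conventions and on the unreported correlation,
so the package reports it without asserting any particular value.

## Synthetic data

`simulate_pedigree` builds a three-tier pedigree — paternal grandsires,
sires (half of them sharing grandsires, giving related sire groups), base
dams and cows with skewed (gamma-weighted) sire family sizes; about 10% of
cows re-appear as dams of later cows.  `simulate_records` then draws herd,
permanent-environment and sire effects from the model's own covariance
structures (`s` via the Cholesky factor of the sire block of `A`) and
generates four teat-quarter rows per cow at one scoring visit plus a run of
monthly test-day records (count ≈ N(10, 2.5²), clipped to 3–15).

Default truth is the published posterior-mean covariance set for the
four-class analysis; the MY–SCS correlations inside each random effect are
never reported and default to small values (+0.1 genetic and permanent
environment, −0.1 herd, 0 residual).  The liability intercept is calibrated
so the lowest score class has the published 65.7% share; with the
pinned-threshold parameterization the remaining class shares are then
determined and only the top-class share is additionally set (≈1.6%) via the
free threshold.  SCC is generated by inverting the SCS transform, so the
transform round-trips exactly; negative MY draws are truncated at 0.1 kg
with a logged count.  Fixed-effect truth uses smooth, mild
parity/stage trends, a front-vs-rear quarter excess of 0.2 liability units
and null hygiene effects.

What the generator does *not* emulate: seasonal/calendar effects,
herd-specific lactation-curve shapes, culling and missing-visit patterns,
pathogen dynamics, or any dependence of SCC on the teat score beyond the
modelled covariances.  Passing recovery tests therefore demonstrate that
the estimation machinery is correct under the model's own assumptions, not
that the model is adequate for any particular real herd.

## Problem sizes used in the automated experiments

The full design (48 herds, 2,649 cows, 869 sires, ~41,000 records with a
300,000-iteration chain) is what the package defaults reproduce; the
automated experiments run a scaled-down version chosen as its own
simulation design:

* **Parameter recovery** (20 replicates): 900 cows from 100 sires, 36
  herds, binary teat trait at its published truth column, scoring window
  restricted to lactation months 1–4, chains of 6,000 iterations (1,500
  burn-in, thin 5).  Three design considerations, all verified in pilot
  studies with the sampler cross-checked against an independent MCMC
  implementation: (i) scaling cows down while keeping all 36 parity-stage
  cells leaves far fewer records per cell than the real design and the
  flat-prior fixed effects then absorb a visible share of the between-cow
  dispersion, so the scaled design preserves the real per-cell record
  density; (ii) variance components need adequate level counts, so herds
  scale much less than cows; (iii) at a few hundred cows the frequentist
  coverage of 95% credible intervals at a fixed truth dips below nominal
  for the cow and herd components (the identifiable dispersion genuinely
  fluctuates ~10% between replicates), so the replicate size must be large
  enough for the likelihood to dominate.  The binary trait is used because
  the free-threshold update of the 4-class trait mixes too slowly
  (integrated autocorrelation times of hundreds of iterations) for honest
  HPD intervals at 20×-replicated short-chain budgets; the 4-class
  machinery is recovery-checked on a single 20,000-iteration chain
  (heritability within its 95% HPD) and was verified end-to-end against
  the independent MCMC oracle.
* **Oracle comparisons** run at 60–300 cows where the dense GLS matrices
  remain cheap.

## Known limitations

* O(n²) pedigree algebra (tabular A, dense sire-block inverse): fine to a
  few thousand individuals, not for national evaluations.
* The joint sire draw factorizes a dense 3q × 3q precision each iteration;
  at the full 869-sire scale this dominates runtime (seconds per
  iteration).  A sparse factorization would remove this.
* Single-site threshold updates mix slowly for very large ordinal datasets
  even with the empirical initialization.
* Genetic groups for unknown parents are not implemented; unknown parents
  are unrelated founders.
* The Geweke statistic uses a Bartlett-window spectral estimate; heavily
  autocorrelated short chains can under-estimate its variance.
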