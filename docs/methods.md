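# Methods

`irtval` implements the psychometric validation workflow used for
patient-reported outcome (PRO) item banks: graded response model (GRM)
calibration, the assumption checks that justify it, item-level fit and
differential item functioning (DIF) diagnostics, post-hoc computerized
adaptive testing (CAT) simulation, and the reliability/efficiency/norm
summaries through which such instruments are judged.  This note records
the models, the numerical choices, and what the synthetic data do and do
not establish.

## The measurement model

Responses are ordinal categories 1..K per item.  The GRM specifies, for
item *i* with discrimination `a_i > 0` and strictly ordered thresholds
`b_i1 < ... < b_i,K-1`,

    P(X_i >= k | theta) = logistic(a_i * (theta - b_i,k-1)),

with category probabilities as differences of adjacent cumulative
curves.  `theta` is the latent trait (here: quality of peer
relationships), standardized in the calibration population.  Scores are
reported on the T metric, `T = 50 + 10*theta` (reference mean 50, SD 10).

### Calibration

Marginal maximum likelihood with a standard-normal latent prior, by EM
over a fixed quadrature grid:

* **E-step** — posterior weights for each respondent on the grid, and
  expected category counts per item/node.
* **M-step** — each item's expected complete-data log-likelihood is
  maximized by L-BFGS with analytic gradients on an unconstrained
  reparameterization (`log a`; first threshold free; log-increments for
  the gaps), which enforces `a > 0` and strict threshold ordering.  If
  the optimizer fails to improve the expected log-likelihood the old
  parameters are kept, so the procedure is a generalized EM and the
  marginal log-likelihood is non-decreasing every cycle (asserted in the
  test suite).

Defaults: 49 equally spaced nodes on [-6, 6] with renormalized N(0,1)
weights; convergence when the largest absolute parameter change falls
below 1e-4, capped at 500 cycles.  Both are exposed as parameters.
Declared categories that are never observed are unidentified; they are
collapsed downward before fitting and the full declared-to-fitted
mapping is reported and applied to any data scored with the fitted
model.  Items answered in a single category are rejected by name.
Missing responses are excluded item-wise from all likelihoods.

### Scoring

EAP (posterior mean) with the posterior SD as SE(theta).  The scoring
grid is finer and wider than the calibration grid: 201 nodes on [-8, 8].
The width matters because all-maximum ("ceiling") responders have
posteriors centered near +3 with prior-like tails; truncating at ±6
leaves a ~1e-6 boundary error, while ±8 agrees with a 10,001-point
reference integration to ~1e-12.  Ceiling responders therefore get a
finite, prior-dominated estimate with a large SE — never an error —
which mirrors how such respondents are scored and discussed in practice.
Reverse-worded items are recoded (K+1−x) before any modeling; the recode
is an involution and is exercised as such in the tests.

## Assumption checks

**Polychoric correlations** are two-step ML: thresholds from the
univariate margins, then each pairwise correlation by maximizing the
bivariate-normal likelihood of the contingency table.  The bivariate
normal CDF is computed by 48-node Gauss–Legendre integration of
Plackett's identity (machine precision against an independent
implementation).  The same identity yields the score `dP/drho` as a
difference of bivariate densities, giving each estimate's asymptotic
variance from the pairwise Fisher information.  Non-PSD matrices are
repaired by eigenvalue clipping at 1e-6 with unit-diagonal
renormalization; the repair preserves the ordering of off-diagonal
entries and is reported.

**One-factor fit.**  Loadings are estimated by *unweighted* least
squares on the polychoric matrix; the test statistic is evaluated at
that solution in the DWLS metric, `T = sum residual^2 / avar`, against
the zero-correlation baseline, with `df = p(p+1)/2 - 2p`.  The unusual
split is deliberate: precision weights give a locally *dependent* item
pair the largest weight (its polychoric is the most precisely
estimated), so a purely weighted fit inflates that pair's loadings and
hides exactly the residual the local-independence check needs.  With
clean unidimensional data the two solutions coincide to within sampling
noise.  Mean-and-variance scaling corrections of the WLSMV family are
intentionally not reproduced; the reported CFI/TLI/RMSEA/SRMR are the
plain unscaled indices, exercised against the conventional thresholds
(CFI/TLI > 0.95, RMSEA < 0.08, SRMR < 0.10).

**Local independence**: pairs with |residual correlation| >= 0.20 are
flagged (a residual of 0.19 passes; the boundary is inclusive at 0.20).

**Bifactor fallback.**  When a specific-factor assignment is supplied, an
orthogonal confirmatory bifactor model is fitted by least squares; when
not, an exploratory Schmid–Leiman transformation is used (iterated
principal-axis EFA, varimax, promax(4), a second-order factor on the
factor correlations).  Reported indices: hierarchical omega
`(Σλ_g)² / Var(total)` and explained common variance
`Σλ_g² / (Σλ_g² + ΣΣλ_s²)`, judged against omega_h > 0.80 and
ECV > 0.60.  Note that ECV = 1 is a property of zero specific loadings,
not of estimates: folded estimation noise keeps estimated ECV below 1
even for truly unidimensional data.

**Monotonicity (Mokken).**  Pairwise scalability is the ratio of the
observed covariance to the maximum covariance attainable under the
pair's margins (the comonotone coupling); item and scale coefficients
aggregate numerators and denominators.  This is numerically identical to
the weighted Guttman-error formulation `1 − F/E` over category steps,
which the test suite implements independently and checks to 1e-10, with
the comonotone maximum additionally verified against a linear-programming
transport solution.  Degenerate pairs (zero maximum covariance) are
excluded and reported.  Criteria: all item H >= 0.30 and scale H >= 0.50.

## Item fit

The summed-score statistic compares observed category frequencies within
rest-score groups (the summed score over the *other* items) to their
model-implied expectations, computed exactly by the Lord–Wingersky
recursion integrated over the latent prior (the recursion is checked
against exhaustive response-pattern enumeration to 1e-12).  Collapsing
is deterministic: empty score groups drop; a group's sparse cells merge
with the adjacent category toward the middle until expected counts reach
1.0; still-sparse groups merge toward the center score.  Degrees of
freedom are the retained independent cells, `Σ_g (cells_g − 1)`, minus
the item's parameter count — each group's expectations sum to its size,
so per-group totals are not free.  The misfit criterion is p < 0.001,
reported unadjusted (the stringent level already plays the role of
multiplicity control).  A 200-replicate type-I simulation shows the
statistic is calibrated on average (pooled rate ≈ 0.045 at nominal 0.05)
and conservative for items whose extreme cells collapse heavily — an
expected property of this construction.

Item-fit plots use deciles of the EAP score (stable sort; bins as equal
as possible, sizes differing by at most one), with each bin's observed
mean response set against the model expectation at the bin's mean theta.
Under the study conditions this reproduces the diagnostic signature of a
ceiling-contaminated reverse-worded item: depressed observed means in
the top deciles.

## Differential item functioning

Per item, three proportional-odds (cumulative logit) regressions:
`response ~ theta`, `+ group`, `+ theta x group`, with the matching
theta taken as the EAP score from a pooled calibration.  McFadden's
pseudo-R² is `1 − lnL_model / lnL_null`; the null (intercepts-only)
log-likelihood is available in closed form from the category
proportions.  The R² *changes* between nested models measure uniform
(M1→M2) and non-uniform (M2→M3) DIF; an item is flagged when the total
change (M1→M3) reaches 0.02, and typed non-uniform if the M2→M3 change
alone reaches the criterion, uniform otherwise.  The regressions are fit
in-package by quasi-Newton with analytic gradients (ordered cutpoints
via log-increment reparameterization, gradient tolerance 1e-8); the
statsmodels ordinal model serves as an independent cross-check in the
tests (agreement ~1e-6 in log-likelihood) but is ~100x slower, which
matters at simulation scale.  Purification recomputes the matching score
from non-flagged (anchor) items until the flag set stabilizes; failure
to stabilize within the iteration cap is reported, never silent.

Anchored recalibration links two groups through a fixed-anchor two-stage
design: group A is calibrated fully; group B holds the anchor items at
the group-A estimates while its remaining items and its latent mean and
SD are estimated by EM (latent distribution updated from posterior
moments).  Parameter standard errors for the agreement checks come from
the empirical (outer-product-of-gradients) information of the marginal
likelihood.

## CAT simulation

Post-hoc mode: responses are looked up from the completed matrix, never
generated, so the procedure is fully deterministic.  The first item
maximizes Fisher information at the starting theta (0, the study-sample
mean); subsequent items maximize posterior-weighted information (MPWI),
the expected information under the current EAP posterior (a config
switch selects plain maximum Fisher information at the interim estimate
instead — the two nearly coincide under a standard-normal prior, which
is why the information-at-zero rule is the default for the first item).
Ties break to the lowest item index.  Scoring is EAP after every
administered item; the test stops when SE(theta) < 0.32 (strict,
evaluated after each item, never before the first) or at eight items —
the short form's length; if both trigger at once the stop reason is
recorded as the SE rule.  With `max_items` equal to the bank size and
`se_stop = 0` the CAT degenerates to the full bank and reproduces the
full-bank EAP exactly, which the tests assert.  Short forms are scored
by plain EAP on the fixed 8-item subset; no separate machinery is
needed.

## Score metrics

* Reliability of an estimate: `1 − se²` on the standardized metric
  (se = 0.32 → 0.8976, the conventional "reliability 0.90" cut).  An SE
  above 3 triggers a units warning (T-metric SEs are 10x larger).
* Efficiency per respondent: `(1 − se²) / n_items`, where `n_items` is
  the count actually administered (varies per respondent for CAT).
  Relative efficiency between instruments is the ratio of mean
  efficiencies over the same respondents.  The alternative reading —
  test information divided by items administered — is available through
  the information functions, but the `(1 − se²)/n` form drives all
  reported tables.
* Percent reliably measured uses the strict inequality se < 0.32; a
  respondent at exactly 0.32 does not count.
* Norms: mean and SD of T plus three functioning bands from empirical
  quantiles (linear interpolation): poor `T <= q05`, fair
  `q05 < T <= q25`, good `T > q25`.  Half-open, exhaustive, ordered by
  construction.
* Construct validity: Pearson correlations between the bank T-score and
  each legacy subscale; hypothesis 1 requires the target subscale's
  correlation to *strictly* exceed 0.50, hypotheses 2..4 require the
  target to exceed each other subscale by more than 0.10; validity is
  sufficient when >= 75% of hypotheses hold.
* Legacy (0-100) scoring: category c maps to `(5 − c)·25` — the
  instrument's items are worded as problem frequencies, so reverse
  keying makes higher scores mean better functioning; subscales are item
  means (8/5/5/5) and the total equals the item-count-weighted subscale
  mean to machine precision.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the data structure the analyses assume: a
general-population survey (default n = 527) of a 15-item, 5-category
bank, with latent traits N(0,1), one reverse-worded low-discrimination
item, a 6.3% acquiescent ceiling subgroup, optional two-group designs
with parameter-level DIF (threshold shifts for uniform, discrimination
ratios for non-uniform), and a paired 23-item legacy instrument with
8/5/5/5 subscales.

Key generator decisions:

* **Ceiling subgroup** — drawn from the same normal population and then
  overwritten with the maximum raw category on every item.  This models
  acquiescent responding rather than extreme true traits (the
  interpretation under which such respondents "cannot be measured
  reliably"), and it is one defensible choice among several: nothing in
  the emulated design identifies the subgroup's true latent levels.
  Because the overwrite acts on raw responses, the reverse-worded item
  lands on its *lowest* recoded category — the mechanism behind the
  item-fit plot signature.
* **Reference bank** — discriminations 0.78–3.7 with thresholds spanning
  −3.8 to +2.0, matching the parameter ranges reported for
  well-targeted pediatric social-health banks; most thresholds are
  negative (the population sits above the items' difficulty), which
  produces the ceiling-prone margins these instruments show in general
  populations.
* **Legacy instrument** — each subscale is driven by its own latent
  construct; the social subscale's latent correlates `target_r` (default
  0.8) with the bank trait, and the physical/emotional/school latents
  at 0.50/0.65/0.60 of `target_r`.  A single shared latent would make
  the discriminant hypotheses (Δr > 0.10) unsatisfiable by
  construction, so the graded overlap is a deliberate design choice
  emulating the observed ordering of convergent vs discriminant
  correlations.  Observed-score correlations are attenuated relative to
  the latent targets (a 5-item ordinal subscale caps the attainable
  correlation near 0.89 even at `target_r = 0.99`).
* **DIF injection** modifies parameters before sampling, giving known
  ground truth for the operating-characteristic simulations.
* All items share K = 5 by default (both emulated instruments use five
  categories); per-item K is supported, and degenerate declarations fail
  loudly.

What passing tests show — and what they do not.  The simulations
establish that each procedure recovers the truth under its own
assumptions (correct model family, normal latent, no missing data, no
response styles beyond the ceiling mechanism).  They do not establish
robustness to misspecified latent distributions, multidimensionality
beyond the injected structures, item nonresponse (excluded by design:
the emulated survey logged only complete batteries), or demographic
sampling structure, all of which are out of scope.

## Problem sizes and runtime

Simulation sizes used by the test suite and the acceptance script are
chosen as the smallest that make the operating characteristics stable:
parameter recovery at n = 2000; DIF null/power at n = 1000 per group
with 20 replicates each; the assumption screen at n = 2000 over 20
seeds; type-I calibration of the item-fit statistic at n = 1000 over 200
replicates; study-scale runs at the emulated survey size n = 527.  The
full pipeline on a study-scale dataset runs in a few seconds on one CPU.

## Known limitations

* The unscaled DWLS test statistic is not chi-square calibrated in
  finite samples; the fit indices are exercised as threshold rules, not
  as significance tests.
* The exploratory Schmid–Leiman route inherits the usual instabilities
  of oblique rotation when specific factors are weak; the confirmatory
  route is preferred whenever an assignment is known.
* S-X² is conservative for items whose extreme cells collapse heavily.
* The CAT simulator is post-hoc only: no exposure control, content
  balancing, or live administration.
* Calibration and scoring parameter sets are deliberately decoupled
  (a supplied bank can score data it was not estimated from), so both
  the self-calibrated and the reference-parameter workflows are
  expressible; linking beyond fixed-anchor recalibration is out of
  scope.
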