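# Methods

`misscen` analyzes missing data in observational health cohorts through
missingness graphs (m-graphs). This note records the model, the choices
behind the synthetic cohorts, the numerical conventions, and the limits
of what the tests demonstrate.

## The m-graph model

Each study variable `X_i` is treated as *counterfactual*: the value it
would take were it always available. A binary indicator `R_i` marks
availability, and the observed *proxy* is the deterministic mixture

    X_i* = X_i   if R_i = 1,      X_i* = NaN   if R_i = 0.

An m-graph is a causal DAG over `{X, R, X*}` in which the proxy edges
`X_i -> X_i* <- R_i` are deterministic and proxies have no descendants.
The joint law of `R` — the *availability policy* — is what distinguishes
data collection (`init`), a shifted deployment regime (`new`), and full
availability (`full`). Whole-row omission (selection bias) is modelled by
an extra node `R_dagger` that parents every indicator: rows with
`R_dagger = 0` never appear, so their absence is invisible in the data.

Two structural assumptions are enforced at construction time. Edges from
indicators into counterfactual variables (measurement changing the
patient, e.g. invasive tests) violate the no-direct-effect assumption and
require an explicit `nde_violating` flag; the identification step refuses
such graphs because the counterfactual estimand itself becomes ill-posed.
Proxies may never cause anything: a physician reacting to a recorded
value is modelled as a reaction to the counterfactual parent, not to the
proxy. The field has no settled convention here; we chose the stricter
reading and note it as a modelling decision.

## Identification

The complete-case probability `PS(x) = p(R = 1 | x)` is the IPW
denominator. The engine factorizes it along an ordering of the
indicators; for each factor `p(R_k = 1 | preceding R = 1, X)` it shrinks
the conditioning set to a minimal subset of counterfactual variables by
greedy backward elimination validated with d-separation (deterministic:
elimination proceeds in declared variable order, starting from the full
variable set — starting from ancestors alone is unsound because
conditioning on preceding indicators can open collider paths to
non-ancestors). An ordering is accepted only if every retained variable's
indicator precedes the factor, in which case the variable is replaced by
its proxy and the factor is estimable from `(X*, R)`. The ordering search
is exhaustive up to 6 indicators (the study graphs have 4) and falls back
to a topological-priority ordering with a warning beyond that.

Self-masking (a variable driving its own indicator, directly or through
paths no conditioning can block) makes every ordering fail and is
reported as unidentifiable. A selection node driven by counterfactual
variables is likewise reported as selection bias: `p(R_dagger = 1 | x)`
cannot be estimated from the surviving rows. The pipeline then accepts an
*externally supplied* selection model — in simulation the generating
(oracle) mechanism — mirroring how a domain-informed analysis would
import visit rates from epidemiologic sources.

## Estimation

The IPW estimator is the unnormalized form

    theta_hat = (1/N) * sum_i 1{r_i = 1} * theta(x_i) / PS(x_i),

with `N` the total row count; under an external selection model rows are
additionally weighted by the inverse selection probability and `N` is
replaced by `sum_i 1/s_i`. Propensity factors are fitted as empirical
frequencies (constant factors) or maximum-likelihood logistic regressions
on the stated proxies over the stated subsamples; predicted propensities
are clipped below at `clip_lo = 0.01` with a logged count (weight
stabilization; the choice is ours). Detected separation (coefficients
beyond ±15) triggers a warned L2-regularized refit.

This unnormalized form is deliberately faithful to the printed estimator
and is exactly the complete-case mean whenever the fitted propensity is
constant (the telescoping product of sequential empirical frequencies
equals the joint complete fraction). Its price is variance: for a
location-scale variable like systolic BP (~130 mmHg), relative noise in
`sum 1/PS` maps to absolute error of order 1 mmHg at n = 2000. A
Hajek-normalized variant would be more stable but is a different
estimator and is not provided.

For monotone missingness patterns the propensity is estimated by
sequential hazards: one membership model per non-complete pattern,
fitted among rows still observed at that prefix depth on the covariates
available within the pattern. Pattern probabilities are cascade products
of hazards and sum to one by construction; the completeness probability
is the final survival product. Monotonicity itself is decided exactly:
variables are sorted by count-weighted observed frequency, tied groups
are permuted exhaustively (≤ 8 variables), and each pattern must observe
a prefix of the ordering.

Imputation offers column means and an iterative random-forest scheme
(round-robin re-regression of each incomplete column on the others, 100
trees, seeded, at most 10 rounds, stopping when the total squared change
between rounds stops decreasing and returning the previous round's
values). The classifier used in the deployment estimand is a
maximum-likelihood linear-logistic model; with binary labels and hard
predictions, accuracy and 1 − MSE are the same number, and accuracy is
what is reported.

## Sensitivity analysis

Delta adjustment assumes the unobserved stratum's mean sits `delta` away
from the observed one (additively or multiplicatively), giving the
closed-form pattern-mixture mean; the additive sweep is affine in
`delta` with slope `1 − p_hat`. Exponential tilting multiplies the
per-row odds of *missingness* `O(R|x) = p(R=0|x)/p(R=1|x)` by
`exp(delta * t(x))` and recomputes the propensity. The printed definition
makes `delta` a log odds-ratio of missingness, which inverts the
colloquial "odds of observation" reading; we implement it as printed and
provide an `observation_odds` toggle. The default grid is 21 points on
[−2, 2] log-odds (odds ratios 1/7 to 7). `delta = 0` short-circuits to a
bit-exact identity.

## The synthetic cohorts

The simulation study uses a four-variable cardiovascular cohort with the
shared counterfactual DAG age → BMI, age → BP, BMI → BP, age → CVD,
BMI → CVD, BP → CVD — the minimal epidemiologically standard structure
for baseline variables, a measurement, and a binary outcome. Scales are
clinical: age ~ N(60, 10²) years; BMI linear in age around 27 kg/m²
(slope U(0.02, 0.12), noise SD U(2, 4)); systolic BP linear in age and
BMI around 130 mmHg (coefficients U(0.2, 1.0), noise SD U(5, 15) mmHg);
CVD logistic in all three with standardized coefficient magnitudes
U(0.3, 1.2) and intercept solved by bisection for a prevalence target
drawn U(0.2, 0.4). Each iteration draws all coefficients uniformly from
these bounds and is rejected until every variable's marginal missingness
rate lies in [0.1, 0.6]; target missingness rates are drawn U(0.2, 0.5)
and mechanism intercepts solved numerically against a seeded reference
sample of 4000 rows.

The three cases layer scenarios on this base: exogenous constant
indicators for invalid-entry drops (case 1); additionally an
outcome-driven selection node with visit probabilities U(0.7, 0.95) for
CVD cases and U(0.3, 0.6) for the healthy (case 2); and a diagnostically
driven BP indicator, logistic in age and BMI with standardized slopes
U(0.5, 1.5), while age and BMI keep exogenous recording indicators
(case 3). The outcome label is always observed. Defaults are n = 2000
rows and 20 iterations — sizes chosen for stable Monte-Carlo error at
minutes-scale runtime; the iteration count follows the study design, the
row count is the package's own choice.

Seeding: a master seed spawns per-(case, iteration) child seeds by a
fixed stride (10007); all structural sampling, masking, imputation and
fitting flow from the child seed, so a run is byte-reproducible.

What the generator does *not* emulate: longitudinal visits and follow-up
dropout (the catalog's scenarios 2–3 have only generic templates),
informative interference between patients, measurement error, and
non-linear structural equations. Passing tests therefore demonstrate
correctness of the estimators under the stated linear-Gaussian/logistic
conditions, not robustness on real EHR data.

## Observed behaviour of the bias study

Two qualitative regularities one might expect — IPW attaining the lowest
pooled median bias for the mean-BP estimand, and complete-case analysis
being most biased in the selection case for the accuracy estimand — do
not hold under these defaults, for reasons the tests make visible: the
unnormalized IPW form carries mmHg-scale variance at n = 2000 while the
forest imputation is essentially correctly specified under the linear
DAG (`R_BP` is independent of BP given age and BMI, which the forest
conditions on); and the covariate-driven BP missingness of case 3
distorts complete-case estimates more than the moderate visit-selection
strengths distort case 2. The corresponding assertions are kept in the
acceptance tests and fail openly rather than being weakened; the
study-level magnitudes (mean classifier accuracy, the 0.25 and 0.1
accuracy-bias bounds) hold.

## Degenerate inputs and tie-breaks

Empty fitting subsamples, all-missing columns, single-class targets and
zero observed entries raise informative errors rather than producing
numbers. Ties in the monotonicity search are broken by exhaustive
permutation up to 8 variables, then lexicographically with a warning.
The first indicator ordering (in declared-variable order) that admits an
estimable factorization is returned, making formulas deterministic.
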