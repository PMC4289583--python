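# Methods

`ordmi` implements a workflow for developing a predictive regression model —
including interaction terms that are *not* specified in advance — when the
data table has missing cells. The circularity it resolves: interactions
should be in the imputation model so that imputed data supports the analysis,
but the interactions can only be discovered from (complete) data. The
resolution is to discover them on a single dataset completed by the EM
algorithm, feed them into the imputation model, and then do the final
inference on multiply imputed data pooled with Rubin's rules.

## The data model

Data is a case-by-variable table with a typed schema: each variable is
continuous, binary, nominal or ordinal, carries its ordered category labels
and a reference level, and has a role (predictor, outcome, auxiliary).
Missing cells are NaN; the missingness mask is derived from the values, so
the two can never disagree. The outcome is an ordinal variable and must be
fully observed for analysis; cases without an observed outcome are outside
the package's scope. Category labels remain strings everywhere; numeric
codes exist only inside coding passes.

## Missingness screening

`summarize_missingness` reports exact cell/case/variable missingness counts
and percentages (rounding happens only at presentation) and classifies the
pattern: *monotone* when the per-variable missing sets are nested under
some column ordering (checked by sorting columns by missing count and
verifying consecutive containment), *nonmonotone* otherwise.

`screen_mar` runs, per incomplete variable V, chi-square tests of (a) V's
observed values against every other variable on complete pairs, and (b) an
indicator of V's missingness against every other variable's observed
values — including the outcome. Rejections of (b) are evidence that
missingness depends on observed data, which makes missing-at-random
plausible and identifies variables the imputation model should carry.
Continuous partners are quartile-binned so one test family covers all
pairs. Tests with more than 20% of expected cell counts below 5 are flagged
invalid rather than dropped; degenerate tables are skipped with a note.
The default screening level is 0.05 and configurable — the procedure is a
screen, not a confirmatory test.

## Coding and transform-then-impute

Interactions are treated as variables in their own right *before*
imputation (transform-then-impute). For the multivariate-normal engine,
every k-category variable becomes k−1 reference-omitted indicators and an
interaction of categorical factors with p joint categories becomes p−1
indicators over the joint categories (reference = the joint category of the
factors' references); for the chained-equations engine the interaction is a
single nominal variable whose categories are the joint categories,
integer-labelled in row-major factor order. Interactions involving a
continuous factor become numeric product columns in both modes. A derived
cell is missing iff any factor cell is missing. Passive imputation
(impute-then-transform) is deliberately not offered: it produces
plausible-looking values but biased regression estimates.

After multivariate-normal imputation, continuous values on indicator
columns are mapped back to legal categories by *sensible rounding*: a
single indicator thresholds at 0.5 (a tie rounds to "present"); in a
multi-indicator block the category with the largest indicator wins (ties to
the lowest category index), with the reference as fallback when every
indicator is below 0.5. Only originally missing cells can be non-integral,
so observed cells always decode to their original labels.

## EM for the multivariate normal

`em_fit` computes maximum-likelihood estimates of the mean vector and
covariance matrix under arbitrary nonmonotone missingness. The E-step
groups cases by missingness pattern and computes conditional expectations
via the conditional-normal regression of the missing block on the observed
block (pattern-grouped Cholesky solves; ridge-stabilized with a warning if
an observed block is numerically singular); the M-step uses the ML divisor
n. Initialization is complete-case moments when at least d+1 complete cases
exist, otherwise available-case moments with an eigenvalue-floor PSD
repair. Convergence is a max absolute parameter change below 1e-6 (the
NORM-class convention); the observed-data log-likelihood is recorded per
iteration and is non-decreasing — a property the tests assert. `em_complete`
replaces each missing cell by its conditional mean given the case's
observed cells; the result is the single "EM-completed" development
dataset. Conditional-mean completion has no residual noise, so completed
columns have attenuated variance — which is why this dataset is used for
model *development* only, never for final inference.

## Multivariate-normal imputation (data augmentation)

The DA chain alternates an I-step (draw missing cells from their
conditional normal given the observed cells and current parameters) and a
P-step (draw parameters from the complete-data posterior under the Jeffreys
prior: inverse-Wishart for the covariance with the centered cross-product
matrix as scale, then normal for the mean given the covariance; an optional
ridge inflates the scale's diagonal near singularity). The chain starts at
the EM ML estimates, runs N = m·k iterations and saves the completed
dataset at the end of every k-th cycle, k defaulting to the EM iteration
count with a floor of 10 — DA nearly always mixes in fewer cycles than EM
takes to converge, so the EM count is a conservative cycle length. k is
fixed at imputation start and no further chain diagnostics are applied.

## Chained-equations imputation (FCS)

Each of the m datasets runs an independent chain: place-holder fills drawn
from each variable's observed marginal (normal for continuous, multinomial
for categorical), then n sweeps (default 10) over the incomplete variables
in ascending missing-count order. Per variable, the conditional model is
linear regression (continuous), binary logistic, or multinomial logistic
(3+ categories, including ordinals), fit on the originally observed cells
with all other variables as predictors. Draws are *proper*: linear-model
residual variance from its scaled inverse chi-square and coefficients from
their asymptotic normal, logistic coefficients from their asymptotic
normal, and imputations from the resulting predictive distribution —
without the parameter draws the between-imputation variance in Rubin's
rules would be understated.

One deliberate deviation from the "all other variables" rule: a derived
interaction column is a *deterministic function* of its factors, so leaving
it in its own factor's conditional model (or the factors in the derived
column's model) guarantees perfect separation and would force those
variables to the marginal-draw fallback every sweep. Each variable's model
therefore excludes its deterministic relatives only; everything else,
including the outcome and unrelated interaction columns, stays in. Genuine
separation or non-convergence in a conditional fit still falls back to
observed-proportion draws for that variable that sweep, and every fallback
is logged in the stack's provenance.

## The analysis model

The outcome model is the proportional-odds cumulative-logit model
logit P(Y ≤ j | x) = θ_j − x′β. Fitting is maximum likelihood by L-BFGS-B
with analytic gradients; threshold ordering is enforced through
θ_j = a + Σ_{l≤j} exp(d_l). Standard errors come from the inverse observed
information, obtained by numerically differentiating the analytic score at
the optimum. The intercept-only model uses the closed form (thresholds =
cumulative logits of the outcome marginal). Constant design columns (an
absent category in a given dataset) are dropped before fitting so the
likelihood stays identified. A fit is flagged when the optimizer fails or
any standardized coefficient exceeds 15 in magnitude (suspected
separation); flagged fits are treated as failures by the stepwise driver.
The implementation is cross-checked in the test suite against statsmodels'
OrderedModel and a brute-force likelihood grid on a contingency table.

Interaction terms enter the analysis design as product columns — one per
combination of non-reference categories, (k1−1)(k2−1) for a two-way
categorical pair. When a completed dataset carries an imputed joint
interaction variable, the product columns are read off that variable
(faithful to transform-then-impute, even where the imputed joint value is
inconsistent with the imputed mains); they are recomputed from the factors
only when no derived column is present, e.g. on the EM-completed
development set, where the two constructions coincide.

Term significance for the stepwise stages is the likelihood-ratio test of
the term's full dummy block (df = its column count), which treats
multi-column terms coherently; per-coefficient Wald p-values are exposed
for reporting.

## Model development and the two strategies

Development is three-staged: (1) all schema predictors enter as main
effects; (2) forward selection over candidate interactions (default: all
two-way products of the mains) adds, per step, the candidate with the
smallest LR p-value while it is below 0.05 (ties: larger LR statistic, then
lexicographic name); (3) backward elimination repeatedly removes the term
with the largest LR p-value while it exceeds 0.10. Main effects that parent
a retained interaction are never removable (hierarchy), so retained
interactions always keep their parents even when the parents are
individually non-significant.

* **Strategy 1** runs all three stages on the EM-completed dataset, puts the
  final terms into the imputation model, imputes m datasets, fits each, and
  pools.
* **Strategy 2** stops the single-set development after stage 2, imputes,
  runs backward elimination on *each* imputed dataset, and keeps the terms
  retained in at least a fraction τ (default 0.5) of the datasets; when
  nothing qualifies, τ is relaxed in steps of 0.1 down to a floor of 0.2
  with a warning. The final terms (plus hierarchy-completing parents) are
  refit on every dataset and pooled.

With no missing data both strategies degenerate to identical
single-dataset development, a property the tests assert.

A complete-case analysis (fit, optionally after backward elimination, on
the fully observed cases only) is provided for comparison; under MAR
missingness its standard errors are systematically larger than the pooled
MI standard errors, a directional property checked in the acceptance suite.

## Pooling and diagnostics

Rubin's rules: Q̄ = mean estimate, W = mean squared SE, B = between-imputation
variance (divisor m−1), T = W + (1+1/m)B, and the classic (1987) degrees of
freedom df = (m−1)(1 + W/((1+1/m)B))²; when B = 0 the df is infinite and
inference is normal-based. Inference is t-based on df with 95% intervals by
default. The df doubles as a stability diagnostic: `df_stability` flags
coefficients with df ≥ c·m (default c = 3), reading a large
within/between-variance ratio as "the pooled estimates have stabilized".

`ks_compare` runs a two-sample Kolmogorov–Smirnov test of observed versus
pooled imputed cell values for every variable missing more than a threshold
percentage (default 8%); categorical variables are numeric-coded in schema
order. `recommended_m` is the published step-function lookup from the
missing-information fraction to the advised number of imputations
(≤0.3 → 20, ≤0.5 → 40, ≤0.7 → 100, beyond → open-ended ">100", returned as
100 with a marker).

## The synthetic-data generator

The generator emulates the structure of the motivating study: 382 cases, 21
categorical predictors plus continuous age, a fully observed 3-level
ordinal outcome drawn from a known proportional-odds model, fully observed
gender/area/age, and per-variable MAR missingness rates between 0 and
19.4%. Predictor dependence comes from an equicorrelated Gaussian copula
(ρ = 0.15) thresholded at the marginal probabilities; marginals are chosen
as plausible questionnaire frequencies. The default generating model
carries four main effects and two interactions with substantial
coefficients, so the selection stages have a known answer. Under MAR, each
incomplete variable's missingness is Bernoulli with a logistic probability
in fully observed drivers, the intercept calibrated by root-finding on the
realized sample to hit the target rate; MNAR adds the cell's own
standardized value; MCAR ignores the drivers. Per-variable masks are
independent, so the realized pattern is nonmonotone — like the study's —
but, unlike real questionnaire data, the generator does not produce
block/page missingness, so case-level incompleteness runs higher than the
study's at the same cell-level rate. Passing tests therefore validate the
machinery under independent-mask MAR, not under clustered nonresponse.

## Test and acceptance scale

The simulation studies in the acceptance tests run at reduced, fixed-seed
scales chosen to keep the whole suite within a routine CI budget: the
calibration study uses the compact 8-variable design at n = 500 with ~20%
per-variable MAR missingness, m = 8 imputations and 20 replicates (coverage
counted over all coefficient × replicate × engine triples); the strategy
recovery study uses n = 700, m = 5 and 10 replicates per strategy. The
recovery thresholds (≥ 90%), the coverage band [0.90, 0.98], and all rule
thresholds (0.05 entry, 0.10 removal, τ = 0.5, 8% KS cut, df ≥ 3m) are as
specified for the method itself.

## Known limitations

* The multivariate-normal engine models dummy indicators as jointly normal;
  sensible rounding repairs the margins but the joint distribution of
  high-order categoricals is approximate.
* Imputed joint interaction variables can be inconsistent with the imputed
  mains; this is the accepted cost of transform-then-impute.
* No MNAR sensitivity analysis is provided (the generator can produce MNAR
  data, but the imputation engines assume MAR).
* Stepwise selection inherits the usual stepwise optimism; the EM-completed
  development set has attenuated noise, which can admit extra interactions
  at the entry threshold. Strategy 2's per-dataset elimination is the
  built-in counterweight.
* No survey weights, multilevel structure, partial proportional odds, or
  predictive-mean matching.
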