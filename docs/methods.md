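# Methods

## Setting and notation

For individual i, `D_i` is a vector of m binary outcome indicators and
`r(X_i)` a vector of marginal risk predictions in [0, 1] — one risk per
outcome, with no probabilities for outcome *combinations*. A threshold
vector `t` classifies individual i as high risk for outcome j when
`r_j(X_i) >= t_j`. The inequality is closed, and the same convention is used
in the empirical estimators and in the analytic model, so the two halves of
the package agree on boundary cases.

The package assumes the predictor is at least weakly component-wise
calibrated — `E(D_j | r_j(X) = r*) = r*` for each outcome separately — and
provides a quantile-bin diagnostic for exactly that property
(`component_calibration`). Quantile (equal-count) bins are used rather than
equal-width bins because risk distributions for low-prevalence outcomes are
strongly right-skewed; equal-width bins would leave most bins nearly empty.
Tied risks that collapse bin edges are merged with a warning. The
unobservable true risk vector is never required: calibration is assessed
against observed outcomes, which is the observable implication of the
definition. Missing values are rejected rather than imputed, because every
criterion's denominator presumes complete outcome/risk vectors.

## Four senses of a correct prediction

* **Outcome-wise** — (individual, outcome) cells are the sampling units.
  Sensitivity is the weighted proportion of occurred cells that were flagged;
  it equals the weighted sum of per-outcome sensitivities with weights equal
  to relative outcome probabilities (an identity the tests assert to machine
  precision). An optional positive diagonal weight matrix W expresses
  outcome importance; W enters sensitivity, specificity and relative utility
  as defined, and we extend the same convention to the C-index weights
  `W_jj K_j (1 - K_j)` (the weight choice for the C-index is this package's
  documented convention; the default is W = I).
* **Joint** — predict all outcomes in an individual. The C-index compares
  the *minimum* risk between an "all outcomes" and a "not all outcomes"
  individual.
* **Screening (weak panel-wise)** — predict at least one outcome, whichever
  it is; appropriate when one action covers all outcomes. The C-index
  compares *maximum* risks between "at least one outcome" and "no outcome"
  individuals.
* **Strong panel-wise** — at least one *specific* occurred outcome must be
  flagged; specificity requires that no non-occurred outcome is flagged in
  individuals with at least one non-occurrence. The C-index compares
  `max(D o r)` against `max((1-D) o r)` over ordered pairs *including the
  self-pair* (implemented literally; as a consequence this C-index need not
  be 0.5 under uninformative predictions and the tests only assert the 0.5
  null for the joint and screening senses).

Ties in every concordance count 1/2, which preserves the m = 1 reduction of
all four senses to the classical Mann–Whitney AUC estimator (asserted in the
tests against scikit-learn's implementation).

Relative utility in each sense is `sens - odds(t) * odds(D) * (1 - spec)`,
the expected net benefit of acting on predictions divided by its maximum.
The threshold odds require `Pr(D in event | r(X) = t)`, which is hard to
estimate nonparametrically; by default the estimators use the published
working forms under independence of predictions and outcomes
(outcome-wise `t'W1 / (1-t)'W1`; joint `prod t / (1 - prod t)`; screening
`(1 - prod(1-t)) / prod(1-t)`; panel-wise `(1 - prod(1-t)) / (1 - prod t)`),
and every estimator accepts a caller-supplied conditional odds — typically
the probit model's exact conditional — as `ru_conditional_odds`. Each
record carries a `relevant_region` flag marking whether `t` lies in the
region where "no action" is the rational default, computed from the same
working forms or from a supplied model.

Degenerate conditioning sets (e.g. joint sensitivity with no all-outcome
individual) yield an explicit `None` plus a reason string, never silent NaN
arithmetic.

**Predictive values.** PPV/NPV Bayes-invert each sense's event pair
(screening PPV = `Pr(D != 0 | I != 0)`, joint PPV = `Pr(D = 1 | I = 1)`,
panel-wise PPV = `Pr(D'I != 0 | I != 0)`, and so on). The panel-wise NPV,
`Pr((1-D)'(1-I) != 0 | I != 1)`, is this package's complement-symmetric
reconstruction: no standard reference definition was available for the
panel-wise negative side, so it mirrors the positive side under the
complementation `D -> 1-D, I -> 1-I`.

**Ascertainment.** Case-enriched sampling biases every conditional-on-outcome
estimator. All sense-level proportions are inverse-probability weighted by
per-individual sampling probabilities (weights 1/p), and outcome-wise
sensitivity can alternatively be reweighted by external incidence estimates
via the weighted-sum identity (`incidence_weighted_sensitivity`). C-indices
are left unweighted. Standard errors use effective sample sizes
`(sum w)^2 / sum w^2` for proportions and Hanley–McNeil for concordances.

## The liability probit model

Liabilities `L ~ N(0, Sigma_L)` (unit variances) define outcomes by
`D_j = 1{L_j >= tau_j}`, `tau_j = Phi^-1(1 - K_j)`. The predictor vector X
is jointly Gaussian with L, with cross-covariance `Sigma_LX` and covariance
`Sigma_X` (diagonal in [0, 1): each diagonal entry is the liability variance
explained by the corresponding predictor). The calibrated risk map and the
predictor-scale thresholds are

```
r_j(x)   = 1 - Phi((tau_j - x_j) / sqrt(1 - Sigma_X[jj]))
t~_j     = tau_j - sqrt(1 - Sigma_X[jj]) * Phi^-1(1 - t_j)
```

so `r_j(t~) = t_j` exactly (round-trip tested to 1e-12); `t_j` of 0 or 1 maps
to an infinite predictor threshold and is handled as an open integration
limit.

Sensitivities and specificities in every sense are ratios of rectangle
probabilities of the 2m-dimensional `Sigma` (panel-wise senses additionally
sum over the 2^m - 1 contributing outcome patterns, with coordinates whose
limits are doubly infinite integrated out exactly; the enumeration is capped
at m = 12, beyond which a cohort simulation with reported Monte-Carlo error
is used). Conditional moments come from the Tallis formulas for the
box-truncated multivariate normal (implemented in the doubly-truncated
generalisation of Manjunath & Wilhelm, validated against univariate closed
forms and rejection sampling) and the Pearson–Aitken selection formulae

```
E(X | D=d)   = Sigma_LX Sigma_L^-1 mu_{L|D=d}
var(X | D=d) = Sigma_X - Sigma_LX (Sigma_L^-1 - Sigma_L^-1 Sigma_{L|D=d} Sigma_L^-1) Sigma_LX'
E(L | X=x)   = Sigma_LX Sigma_X^-1 x
var(L | X=x) = Sigma_L - Sigma_LX Sigma_X^-1 Sigma_LX'
```

Moments conditional on the *complement* pattern `D != d` follow from the law
of total expectation and variance; note the covariance correction is
`Pr(d)/(1-Pr(d))^2 * mu mu'` (derived and Monte-Carlo-verified here; a
commonly reprinted variant squares the probability ratio, which fails the
univariate closed form).

**Concordances.** Joint and screening C-indices are estimated by simulation:
draw X conditional on the two composite events as Gaussians with the
Pearson–Aitken moments (the standard approximation — the exact conditional
law of X given a composite event is not Gaussian), convert to risks, and
compare minima (joint) or maxima (screening); the panel-wise C-index
simulates (L, X) jointly, filters the two conditioning groups, and computes
the rank-based concordance over all cross pairs, which automatically includes
self-pairs. The outcome-wise C-index needs no simulation: each per-outcome
AUC is an exact two-dimensional quadrature (conditioning on the two
liabilities leaves the case-control predictor difference Gaussian).

**AUC <-> R² conversion.** Published per-outcome AUCs are converted to
liability variances explained by *self-consistency*: R² is the root at which
a single-outcome model with `Sigma_LX = Sigma_X = R²` reproduces the given
AUC through the package's own exact single-outcome concordance (Brent's
method on a strictly increasing map). This avoids transcribing any specific
approximation formula and is validated by round-trips (1e-6) and by empirical
concordance on a simulated cohort of 10^6 individuals.

**Wilks' Λ.** `1 - Lambda = 1 - det(Sigma_L + Sigma_X - Sigma_LX -
Sigma_LX') / det(Sigma_L)` summarises total liability variance explained;
for m = 1 it reduces to the coefficient of determination.

## Numerical choices

* Rectangle probabilities use scipy's Genz-type quasi-Monte-Carlo integrator
  with requested absolute tolerance 1e-6; the integration stream is pinned so
  repeated evaluations agree. Achieved accuracy at dimension 12 is about
  1e-5, far below every tolerance asserted on these quantities.
* The joint covariance is validated to be PSD at tolerance -1e-8 on the
  smallest eigenvalue (hard error beyond, clip-and-warn within).
* Truncated-moment calculations refuse patterns with probability below
  1e-12 (an effectively empty conditioning cell).
* Simulation seeds: every stochastic routine takes one seed; paired
  conditional samples use independent child streams (`Generator.spawn`) so
  the two arms are uncorrelated but jointly reproducible.
* Monte-Carlo standard errors are binomial for conditional-simulation
  concordances and Hanley–McNeil for cohort-based ones.

## Synthetic data and what the tests show

`simulate_cohort` draws (L, X) from the model's joint normal law, thresholds
L into outcomes and maps X to risks, so simulated risks are weakly
component-wise calibrated *by construction* and every empirical criterion
converges to the generating model's analytic value — the central
cross-module oracle test (N = 10^5, agreement within 3 standard errors in
every sense). The generator reproduces exactly the statistical structure the
analytic engine assumes: Gaussian liabilities and predictors, marginal
probit risks, iid individuals. Real cohorts violate these assumptions in
ways the simulator deliberately does not emulate — miscalibration,
non-Gaussian predictors, time-to-event outcomes, competing risks,
informative missingness — so passing tests certify internal consistency of
the estimators and the model, not robustness to those violations.

The six-disease polygenic-score example (`prs_example`) is built from a
parameter table of per-disease AUC, lifetime prevalence, SNP heritability
and genetic correlations. **The shipped table is a synthetic
reconstruction** assembled once from the 2018–2019 genome-wide PRS and
LD-score-regression literature (bipolar disorder, breast cancer, coronary
artery disease, Crohn's disease, schizophrenia, type-2 diabetes); it is
realistic for that era but is not a transcription of any single published
table, and downstream numbers (e.g. `1 - Lambda = 0.309` current,
`0.739` at SNP heritability, screening sensitivity `0.952` and specificity
`0.077` at thresholds equal to prevalences, as computed by
`scripts/acceptance.py`) characterise this reconstructed panel. The
`snp_h2` scenario replaces each score's R² with the SNP heritability — the
ceiling for genotype-based predictors — keeping all correlations.

Problem sizes used by the packaged checks: concordance simulations use 10^6
pairs (panel-wise: a cohort sized so that at least 10^6 cross pairs exist,
floor 2x10^5 individuals); cross-module oracle cohorts use N = 10^5;
rejection-sampling oracles for the truncated moments use 3-4x10^5 draws.

## Known limitations

* Model parameters (prevalences, covariances) are inputs; the package does
  not estimate Sigma from data.
* Only marginal risk models are supported — no predictors of outcome
  combinations, no survival outcomes, no competing-risks adaptation.
* Relative utility assumes common additive benefits and costs across
  outcomes; the empirical threshold odds default to independence working
  forms.
* The strong panel-wise C-index lacks a discrimination interpretation (an
  individual can be discordant with itself); its null value under
  uninformative predictors depends on the outcome distribution and should be
  obtained by simulation with `Sigma_LX = 0`, as `scripts/acceptance.py`
  does.
* Confidence quantification is limited to simple binomial / Hanley–McNeil
  standard errors.
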