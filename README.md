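# riskpanel

Criteria for evaluating risk prediction models of **multiple dichotomous
outcomes** — for biostatisticians and epidemiologists assessing biomarker
panels, polygenic risk scores or any marginal multi-outcome risk model.

A single blood draw or genotype array can now yield risk predictions for many
diseases at once. Classical sensitivity, specificity, the C-index and
relative utility are defined for one outcome; with a panel of m outcomes the
question "was this prediction right?" has several defensible answers.
`riskpanel` implements four of them, for both empirical cohorts and an
analytic liability model:

| sense | a true positive is ... |
|---|---|
| **outcome-wise** | a flagged (individual, outcome) cell whose outcome occurred — cells are the sampling units |
| **joint** | an individual predicted to develop *all* outcomes, in whom all did occur |
| **screening** (weak panel-wise) | an individual flagged for *at least one* outcome, in whom at least one occurred |
| **panel-wise** (strong) | an individual in whom at least one *specific* occurred outcome was flagged |

Individual i is flagged for outcome j when its risk `r_j(X_i) >= t_j` for a
threshold vector `t`. For each sense the package estimates sensitivity,
specificity, a C-index (joint: comparing minimum risks; screening/panel-wise:
maximum risks, ties counting 1/2), relative utility
`RU(t) = sens - odds(t) * odds(D) * (1 - spec)`, and positive/negative
predictive values, with binomial / Hanley–McNeil standard errors, per-outcome
importance weights and inverse-probability ascertainment correction.

## The liability probit model

The analytic half assumes a latent liability vector `L ~ N(0, Sigma_L)`
(unit diagonal) with outcome j occurring when `L_j >= tau_j`,
`tau_j = Phi^-1(1 - K_j)` for prevalence `K_j`, and a jointly Gaussian
predictor vector `X` with covariance

```
Sigma = [[Sigma_L,   Sigma_LX],
         [Sigma_LX', Sigma_X ]]
```

The calibrated risk is `r_j(x) = 1 - Phi((tau_j - x_j) / sqrt(1 - Sigma_X[jj]))`.
Every criterion above is then a ratio of multivariate-normal rectangle
probabilities on `Sigma` (or a short conditional simulation for the extremum
based C-indices, using Tallis truncated moments and the Pearson–Aitken
selection formulae for `X | D = d`). A one-number summary is the total
liability variance explained,
`1 - Lambda = 1 - det(Sigma_L + Sigma_X - Sigma_LX - Sigma_LX') / det(Sigma_L)`.
Published per-disease AUCs are converted to liability variances explained by
self-consistent root finding against the model's own single-outcome
concordance.

## Worked example

Eight individuals, four outcomes, risks thresholded at 0.5:

```python
import riskpanel as rp

panel, _ = rp.toy_fixture("eight_by_four")
res = rp.MultiOutcomePrediction.from_panel(panel).fit()
print(res.summary())
```

```
Multi-outcome risk prediction evaluation
========================================================================
individuals: 8    outcomes: 4 (y1, y2, y3, y4)
thresholds:  [0.5 0.5 0.5 0.5]
------------------------------------------------------------------------
sense             sens    spec       C      RU     PPV     NPV   region
outcome_wise     0.438   0.812   0.640   0.250   0.700   0.591      yes
joint            0.500   1.000   0.750   0.500   1.000   0.857      yes
screening        0.571   1.000   0.786   0.571   1.000   0.250       no
panel_wise       0.429   0.667   0.548   0.143   0.750   0.714       no
========================================================================
```

Reading the sensitivities: 7 of the 16 occurred (individual, outcome) cells
were flagged (0.438); of the two individuals with all four outcomes, one was
flagged for all four (0.500); of the seven individuals with at least one
outcome, four were flagged for something (0.571) but only three for an
outcome they actually developed (0.429). The `region` column reports whether
the thresholds lie in each sense's *relevant region*, where acting on the
prediction can beat taking no action by default.

The same criteria from a model instead of data — two diseases with AUCs
0.70/0.65, prevalences 0.10/0.20 and correlation 0.3, thresholds at the
prevalences:

```python
m = rp.LiabilityProbitModel.from_auc([0.70, 0.65], [0.10, 0.20],
                                     [[1.0, 0.3], [0.3, 1.0]])
print(round(m.wilks_variance_explained(), 4))          # 0.2142
rec = m.analytic_criteria(m.prevalences, "screening", seed=1)
# sens=0.754 spec=0.422 C=0.634 RU=0.177
```

Screening two diseases flags three-quarters of the individuals who will
develop at least one of them, at the cost of flagging more than half of those
who develop neither.

A `riskpanel` CLI mirrors the library (`evaluate`, `model`, `simulate`,
`calibration` subcommands); cohorts read and write a plain TSV dialect with
`D_<name>`/`r_<name>` column pairs.

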