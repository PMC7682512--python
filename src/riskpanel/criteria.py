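"""Sample estimators of multi-outcome prediction criteria.

Four senses of a "true positive" are supported:

* ``outcome_wise`` — each (individual, outcome) pair is a sampling unit;
* ``joint``        — predicting *all* outcomes to occur in one individual;
* ``screening``    — predicting *at least one* outcome (weak panel-wise);
* ``panel_wise``   — at least one predicted outcome coincides with one that
  occurred (strong panel-wise).

Each estimator honours the panel's per-individual sampling probabilities via
inverse-probability weighting of the conditional-on-outcome proportions, and
the outcome-wise criteria additionally honour the per-outcome importance
weights W.  Degenerate conditioning sets yield an explicit ``None`` with a
reason recorded in ``CriteriaRecord.undefined``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

from .panel import OutcomePanel, high_risk_indicator
from .records import (
    SENSES,
    CriteriaRecord,
    canonical_sense,
    hanley_mcneil_se,
    proportion_se,
)

__all__ = [
    "outcome_wise_criteria",
    "joint_criteria",
    "screening_criteria",
    "panel_wise_criteria",
    "evaluate_panel",
    "predictive_values",
    "per_outcome_criteria",
    "incidence_weighted_sensitivity",
    "apply_ascertainment",
    "relevant_region_check",
    "two_sample_concordance",
]


def apply_ascertainment(sampling_probs) -> np.ndarray:
    """Inverse-probability weights 1/p for ascertainment correction."""
    p = np.asarray(sampling_probs, dtype=float)
    if (p <= 0).any():
        raise ValueError("sampling probabilities must be positive")
    if (p > 1).any():
        raise ValueError("sampling probabilities must be <= 1")
    return 1.0 / p


def two_sample_concordance(pos, neg) -> float | None:
    """P(pos > neg) + P(pos == neg)/2 over all cross pairs (ties count 1/2).

    Computed from average ranks, so it equals the Mann-Whitney AUC estimator.
    Returns ``None`` when either sample is empty.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    n1, n0 = pos.size, neg.size
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _weighted_proportion(event, condition, weights):
    """IPW proportion of `event` among `condition`; (value, se, n_eff)."""
    w = weights[condition]
    if w.size == 0:
        return None, None, 0.0
    p = float(np.sum(w * event[condition]) / np.sum(w))
    n_eff = float(np.sum(w) ** 2 / np.sum(w**2))
    return p, proportion_se(p, n_eff), n_eff


def per_outcome_criteria(panel: OutcomePanel):
    """Classical per-outcome sensitivity, specificity, C-index and prevalence.

    Returns a dict of (m,) arrays; entries are NaN where undefined (an
    all-zero or all-one outcome column).
    """
    D = panel.outcomes
    I = high_risk_indicator(panel)
    w = panel.ascertainment_weights
    m = panel.n_outcomes
    sens = np.full(m, np.nan)
    spec = np.full(m, np.nan)
    auc = np.full(m, np.nan)
    prev = np.empty(m)
    for j in range(m):
        d = D[:, j].astype(bool)
        prev[j] = np.sum(w * d) / np.sum(w)
        if d.any():
            sens[j] = np.sum(w[d] * I[d, j]) / np.sum(w[d])
        if (~d).any():
            spec[j] = np.sum(w[~d] * (1 - I[~d, j])) / np.sum(w[~d])
        if d.any() and (~d).any():
            auc[j] = two_sample_concordance(panel.risks[d, j], panel.risks[~d, j])
    return {"sensitivity": sens, "specificity": spec, "c_index": auc, "prevalence": prev}


def incidence_weighted_sensitivity(per_outcome_sens, incidences) -> float:
    """Outcome-wise sensitivity reweighted to external outcome probabilities.

    The outcome-wise sensitivity is the weighted sum of per-outcome
    sensitivities with weights equal to the relative outcome probabilities,
    so substituting external incidence estimates corrects ascertainment bias
    in case-enriched samples.
    """
    s = np.asarray(per_outcome_sens, dtype=float)
    k = np.asarray(incidences, dtype=float)
    if s.shape != k.shape:
        raise ValueError("sensitivities and incidences must have equal length")
    if (k < 0).any() or k.sum() <= 0:
        raise ValueError("incidences must be non-negative with positive sum")
    return float(np.sum(s * k) / np.sum(k))


def _ru_from_odds(sens, spec, threshold_odds, outcome_odds):
    """RU(t) = sens - threshold_odds * outcome_odds * (1 - spec)."""
    if sens is None or spec is None:
        return None
    return float(sens - threshold_odds * outcome_odds * (1.0 - spec))


def outcome_wise_criteria(panel: OutcomePanel, ru_conditional_odds=None) -> CriteriaRecord:
    """Outcome-wise criteria: (individual, outcome) cells as sampling units.

    Sensitivity and specificity are importance- and IPW-weighted cell
    proportions; the C-index is the weighted sum of per-outcome concordances
    with weights ``W_jj * p_j * (1 - p_j)``; the relative utility uses the
    weighted threshold odds ``t'W1 / (1-t)'W1``.
    """
    D = panel.outcomes.astype(float)
    I = high_risk_indicator(panel).astype(float)
    wj = panel.importance_weights
    wi = panel.ascertainment_weights
    W = wi[:, None] * wj[None, :]
    t = panel.thresholds

    rec = CriteriaRecord(sense="outcome_wise")
    pos_mass = np.sum(W * D)
    neg_mass = np.sum(W * (1 - D))
    if pos_mass > 0:
        rec.sensitivity = float(np.sum(W * D * I) / pos_mass)
        rec.sensitivity_se = proportion_se(rec.sensitivity, pos_mass**2 / np.sum((W * D) ** 2))
    else:
        rec.undefined["sensitivity"] = "no outcome occurrences in sample"
    if neg_mass > 0:
        rec.specificity = float(np.sum(W * (1 - D) * (1 - I)) / neg_mass)
        rec.specificity_se = proportion_se(
            rec.specificity, neg_mass**2 / np.sum((W * (1 - D)) ** 2)
        )
    else:
        rec.undefined["specificity"] = "no outcome non-occurrences in sample"

    per = per_outcome_criteria(panel)
    prev = per["prevalence"]
    auc = per["c_index"]
    cw = wj * prev * (1 - prev)
    ok = ~np.isnan(auc)
    if (~ok).any():
        warnings.warn(
            "outcome columns with undefined C-index excluded from the weighted sum",
            stacklevel=2,
        )
    if ok.any() and cw[ok].sum() > 0:
        rec.c_index = float(np.sum(cw[ok] * auc[ok]) / np.sum(cw[ok]))
        n = panel.n_individuals
        ses = np.array(
            [
                hanley_mcneil_se(auc[j], prev[j] * n, (1 - prev[j]) * n)
                for j in range(panel.n_outcomes)
                if ok[j]
            ]
        )
        rec.c_index_se = float(
            np.sqrt(np.sum((cw[ok] / cw[ok].sum()) ** 2 * ses**2))
        )
    else:
        rec.undefined["c_index"] = "no outcome column with both classes"

    if ru_conditional_odds is None:
        threshold_odds = float(np.sum(t * wj) / np.sum((1 - t) * wj))
    else:
        threshold_odds = float(ru_conditional_odds)
    if pos_mass > 0 and neg_mass > 0:
        rec.relative_utility = _ru_from_odds(
            rec.sensitivity, rec.specificity, threshold_odds, neg_mass / pos_mass
        )
    else:
        rec.undefined["relative_utility"] = "requires occurrences and non-occurrences"
    rec.relevant_region = relevant_region_check(
        t, prev, "outcome_wise", importance_weights=wj
    )
    return rec


def _individual_sense_record(
    panel: OutcomePanel,
    sense: str,
    event_pos,
    event_neg,
    pred_pos_given_pos,
    pred_neg_given_neg,
    score_pos,
    score_neg,
    threshold_odds,
    outcome_odds,
) -> CriteriaRecord:
    """Shared assembly for the three individual-wise senses."""
    wi = panel.ascertainment_weights
    rec = CriteriaRecord(sense=sense)
    rec.sensitivity, rec.sensitivity_se, _ = _weighted_proportion(
        pred_pos_given_pos, event_pos, wi
    )
    if rec.sensitivity is None:
        rec.undefined["sensitivity"] = "empty conditioning set"
    rec.specificity, rec.specificity_se, _ = _weighted_proportion(
        pred_neg_given_neg, event_neg, wi
    )
    if rec.specificity is None:
        rec.undefined["specificity"] = "empty conditioning set"
    c = two_sample_concordance(score_pos, score_neg)
    if c is None:
        rec.undefined["c_index"] = "empty conditioning set"
    else:
        rec.c_index = c
        rec.c_index_se = hanley_mcneil_se(c, len(score_pos), len(score_neg))
    if rec.sensitivity is not None and rec.specificity is not None:
        rec.relative_utility = _ru_from_odds(
            rec.sensitivity, rec.specificity, threshold_odds, outcome_odds
        )
    else:
        rec.undefined["relative_utility"] = "requires sensitivity and specificity"
    return rec


def joint_criteria(panel: OutcomePanel, ru_conditional_odds=None) -> CriteriaRecord:
    """Joint criteria: a true positive predicts *all* outcomes to occur.

    The C-index compares the minimum risk between an all-outcomes individual
    and a not-all-outcomes individual.  The relative utility uses the
    independence working form ``prod(t) / (1 - prod(t))`` for the threshold
    odds unless ``ru_conditional_odds`` supplies a model-based estimate of
    ``Pr(D=1|r(X)=t) / Pr(D!=1|r(X)=t)``.
    """
    D = panel.outcomes
    I = high_risk_indicator(panel)
    t = panel.thresholds
    wi = panel.ascertainment_weights
    all_out = D.all(axis=1)
    all_pred = I.all(axis=1)
    p1 = float(np.sum(wi * all_out) / np.sum(wi))
    if ru_conditional_odds is None:
        pt = float(np.prod(t))
        threshold_odds = pt / (1 - pt) if pt < 1 else np.inf
    else:
        threshold_odds = float(ru_conditional_odds)
    outcome_odds = (1 - p1) / p1 if p1 > 0 else np.inf
    minr = panel.risks.min(axis=1)
    rec = _individual_sense_record(
        panel,
        "joint",
        all_out,
        ~all_out,
        all_pred.astype(float),
        (~all_pred).astype(float),
        minr[all_out],
        minr[~all_out],
        threshold_odds,
        outcome_odds,
    )
    per = per_outcome_criteria(panel)
    rec.relevant_region = relevant_region_check(t, per["prevalence"], "joint")
    return rec


def screening_criteria(panel: OutcomePanel, ru_conditional_odds=None) -> CriteriaRecord:
    """Screening (weak panel-wise) criteria: predict *at least one* outcome.

    The C-index compares the maximum risk between an individual with at least
    one outcome and one with none.  The working threshold odds are
    ``(1 - prod(1-t)) / prod(1-t)``.
    """
    D = panel.outcomes
    I = high_risk_indicator(panel)
    t = panel.thresholds
    wi = panel.ascertainment_weights
    any_out = D.any(axis=1)
    any_pred = I.any(axis=1)
    p_any = float(np.sum(wi * any_out) / np.sum(wi))
    if ru_conditional_odds is None:
        p0t = float(np.prod(1 - t))
        threshold_odds = (1 - p0t) / p0t if p0t > 0 else np.inf
    else:
        threshold_odds = float(ru_conditional_odds)
    outcome_odds = (1 - p_any) / p_any if p_any > 0 else np.inf
    maxr = panel.risks.max(axis=1)
    rec = _individual_sense_record(
        panel,
        "screening",
        any_out,
        ~any_out,
        any_pred.astype(float),
        (~any_pred).astype(float),
        maxr[any_out],
        maxr[~any_out],
        threshold_odds,
        outcome_odds,
    )
    per = per_outcome_criteria(panel)
    rec.relevant_region = relevant_region_check(t, per["prevalence"], "screening")
    return rec


def panel_wise_criteria(panel: OutcomePanel, ru_conditional_odds=None) -> CriteriaRecord:
    """Strong panel-wise criteria: a prediction must name an occurred outcome.

    Sensitivity conditions on individuals with at least one outcome and asks
    whether any *occurred* outcome is flagged; specificity conditions on
    individuals with at least one non-occurrence and asks that no
    *non-occurred* outcome is flagged.  The C-index compares
    ``max(D o r)`` for one individual against ``max((1-D) o r)`` for another,
    over all ordered pairs including the self-pair.
    """
    D = panel.outcomes
    I = high_risk_indicator(panel)
    t = panel.thresholds
    wi = panel.ascertainment_weights
    any_out = D.any(axis=1)
    not_all = ~D.all(axis=1)
    hit = (D & I).any(axis=1)
    false_alarm = ((1 - D) * I).sum(axis=1) > 0
    p_any = float(np.sum(wi * any_out) / np.sum(wi))
    p_notall = float(np.sum(wi * not_all) / np.sum(wi))
    if ru_conditional_odds is None:
        p0t = float(np.prod(1 - t))
        p1t = float(np.prod(t))
        threshold_odds = (1 - p0t) / (1 - p1t) if p1t < 1 else np.inf
    else:
        threshold_odds = float(ru_conditional_odds)
    outcome_odds = p_notall / p_any if p_any > 0 else np.inf
    with np.errstate(invalid="ignore"):
        s_pos = np.where(D, panel.risks, -np.inf).max(axis=1)[any_out]
        s_neg = np.where(1 - D, panel.risks, -np.inf).max(axis=1)[not_all]
    rec = _individual_sense_record(
        panel,
        "panel_wise",
        any_out,
        not_all,
        hit.astype(float),
        (~false_alarm).astype(float),
        s_pos,
        s_neg,
        threshold_odds,
        outcome_odds,
    )
    per = per_outcome_criteria(panel)
    rec.relevant_region = relevant_region_check(t, per["prevalence"], "panel_wise")
    return rec


_SENSE_FUNCS = {
    "outcome_wise": outcome_wise_criteria,
    "joint": joint_criteria,
    "screening": screening_criteria,
    "panel_wise": panel_wise_criteria,
}


def evaluate_panel(panel: OutcomePanel, senses="all", ru_conditional_odds=None) -> dict:
    """Compute criteria records (with predictive values) for requested senses."""
    if senses == "all":
        senses = SENSES
    elif isinstance(senses, str):
        senses = (senses,)
    out = {}
    for sense in senses:
        sense = canonical_sense(sense)
        odds = None
        if isinstance(ru_conditional_odds, dict):
            odds = ru_conditional_odds.get(sense)
        elif ru_conditional_odds is not None:
            odds = ru_conditional_odds
        rec = _SENSE_FUNCS[sense](panel, ru_conditional_odds=odds)
        ppv, npv = predictive_values(panel, sense)
        rec.ppv, rec.npv = ppv, npv
        if ppv is None:
            rec.undefined["ppv"] = "no positive predictions"
        if npv is None:
            rec.undefined["npv"] = "no negative predictions"
        out[sense] = rec
    return out


def predictive_values(panel: OutcomePanel, sense: str):
    """Sense-specific positive and negative predictive values.

    These Bayes-invert each sense's event pair: e.g. screening
    ``PPV = Pr(D != 0 | I != 0)``, joint ``PPV = Pr(D = 1 | I = 1)``,
    panel-wise ``PPV = Pr(D'I != 0 | I != 0)``.  The panel-wise NPV is the
    complement-symmetric reconstruction
    ``Pr((1-D)'(1-I) != 0 | I != 1)``.
    """
    sense = canonical_sense(sense)
    D = panel.outcomes
    I = high_risk_indicator(panel)
    wi = panel.ascertainment_weights
    if sense == "outcome_wise":
        wj = panel.importance_weights
        W = wi[:, None] * wj[None, :]
        pos = np.sum(W * I)
        neg = np.sum(W * (1 - I))
        ppv = float(np.sum(W * D * I) / pos) if pos > 0 else None
        npv = float(np.sum(W * (1 - D) * (1 - I)) / neg) if neg > 0 else None
        return ppv, npv
    if sense == "joint":
        pred_pos = I.all(axis=1)
        event_in_pos = D.all(axis=1)
        pred_neg = ~pred_pos
        event_in_neg = ~D.all(axis=1)
    elif sense == "screening":
        pred_pos = I.any(axis=1)
        event_in_pos = D.any(axis=1)
        pred_neg = ~pred_pos
        event_in_neg = ~D.any(axis=1)
    else:  # panel_wise
        pred_pos = I.any(axis=1)
        event_in_pos = (D & I).any(axis=1)
        pred_neg = ~I.all(axis=1)
        event_in_neg = ((1 - D) * (1 - I)).sum(axis=1) > 0
    ppv, _, _ = _weighted_proportion(event_in_pos.astype(float), pred_pos, wi)
    npv, _, _ = _weighted_proportion(event_in_neg.astype(float), pred_neg, wi)
    return ppv, npv


def relevant_region_check(
    thresholds,
    prevalence_estimates,
    sense: str,
    model=None,
    importance_weights=None,
) -> bool:
    """Whether the thresholds lie in the sense's relevant region.

    The relevant region is the threshold set on which a default of "no
    action" is rational, so that relative utility compares the predictor
    against doing nothing.  For the individual-wise senses the conditional
    outcome probabilities are evaluated under the independence working
    assumption unless a :class:`~riskpanel.probit.LiabilityProbitModel` is
    supplied, in which case the model's conditional liability distribution at
    the threshold point is used.
    """
    sense = canonical_sense(sense)
    t = np.atleast_1d(np.asarray(thresholds, dtype=float))
    k = np.atleast_1d(np.asarray(prevalence_estimates, dtype=float))
    if sense == "outcome_wise":
        w = np.ones_like(t) if importance_weights is None else np.asarray(importance_weights)
        return bool(np.sum(t * w) >= np.sum(k * w))
    if model is not None:
        cond = model.outcome_probabilities_given_risk(t)
        marg = model.pattern_aggregates()
        if sense == "joint":
            return bool(cond["all"] >= marg["all"])
        if sense == "screening":
            return bool(cond["any"] >= marg["any"])
        num = cond["any"] / (1 - cond["all"]) if cond["all"] < 1 else np.inf
        den = marg["any"] / (1 - marg["all"]) if marg["all"] < 1 else np.inf
        return bool(num >= den)
    # independence working forms
    if sense == "joint":
        return bool(np.prod(t) >= np.prod(k))
    if sense == "screening":
        return bool(1 - np.prod(1 - t) >= 1 - np.prod(1 - k))
    p_any_t = 1 - np.prod(1 - t)
    p_notall_t = 1 - np.prod(t)
    p_any_k = 1 - np.prod(1 - k)
    p_notall_k = 1 - np.prod(k)
    return bool(p_any_t / p_notall_t >= p_any_k / p_notall_k)
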