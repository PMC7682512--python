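"""Result container for one sense of multi-outcome prediction criteria."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SENSES = ("outcome_wise", "joint", "screening", "panel_wise")

#: screening == weak panel-wise; panel_wise == strong panel-wise
SENSE_ALIASES = {
    "weak_panel_wise": "screening",
    "strong_panel_wise": "panel_wise",
    "event_wise": "outcome_wise",
}


def canonical_sense(sense: str) -> str:
    sense = str(sense).lower()
    sense = SENSE_ALIASES.get(sense, sense)
    if sense not in SENSES:
        raise ValueError(f"unknown sense {sense!r}; expected one of {SENSES}")
    return sense


@dataclass
class CriteriaRecord:
    """The four criteria (plus predictive values) for one sense of prediction.

    Any criterion whose conditioning set is empty (for example joint
    sensitivity with no individual in which every outcome occurred) is stored
    as ``None`` with a human-readable reason in ``undefined``; it is never
    silently coerced to 0 or NaN.
    """

    sense: str
    sensitivity: float | None = None
    specificity: float | None = None
    c_index: float | None = None
    relative_utility: float | None = None
    ppv: float | None = None
    npv: float | None = None
    sensitivity_se: float | None = None
    specificity_se: float | None = None
    c_index_se: float | None = None
    relevant_region: bool | None = None
    undefined: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sense = canonical_sense(self.sense)
        for name in ("sensitivity", "specificity", "ppv", "npv", "c_index"):
            v = getattr(self, name)
            if v is not None and not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.relative_utility is not None and self.relative_utility > 1 + 1e-9:
            raise ValueError("relative utility cannot exceed 1")

    def to_dict(self) -> dict:
        out = {"sense": self.sense}
        for name in (
            "sensitivity",
            "specificity",
            "c_index",
            "relative_utility",
            "ppv",
            "npv",
            "sensitivity_se",
            "specificity_se",
            "c_index_se",
        ):
            v = getattr(self, name)
            out[name] = None if v is None else float(v)
        out["relevant_region"] = self.relevant_region
        out["undefined"] = dict(self.undefined)
        return out


def proportion_se(p: float, n_eff: float) -> float:
    """Binomial standard error with an effective sample size."""
    if n_eff <= 0:
        return float("nan")
    return float(np.sqrt(max(p * (1.0 - p), 0.0) / n_eff))


def hanley_mcneil_se(auc: float, n_pos: float, n_neg: float) -> float:
    """Hanley & McNeil (1982) standard error of a two-sample concordance."""
    if n_pos <= 0 or n_neg <= 0:
        return float("nan")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))
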