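"""Model/Results interface for evaluating a multi-outcome risk predictor.

``MultiOutcomePrediction`` binds observed outcomes and marginal risk
predictions (statsmodels-style model object); ``fit`` computes the empirical
criteria for the requested senses and returns a ``PredictionEvaluation``
results object with the estimates, their standard errors and a ``summary()``
table.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .criteria import evaluate_panel
from .panel import OutcomePanel, component_calibration, validate_panel
from .records import SENSES, CriteriaRecord

__all__ = ["MultiOutcomePrediction", "PredictionEvaluation"]

_CRITERIA_COLUMNS = (
    "sensitivity",
    "specificity",
    "c_index",
    "relative_utility",
    "ppv",
    "npv",
)


class MultiOutcomePrediction:
    """Paired binary outcomes and marginal risk predictions for N individuals.

    Parameters mirror :func:`riskpanel.panel.validate_panel`; construction
    validates shapes and domains eagerly.
    """

    def __init__(
        self,
        outcomes,
        risks,
        thresholds,
        outcome_names=None,
        importance_weights=None,
        sampling_probs=None,
    ):
        self.panel: OutcomePanel = validate_panel(
            outcomes,
            risks,
            thresholds,
            importance_weights=importance_weights,
            sampling_probs=sampling_probs,
            outcome_names=outcome_names,
        )

    @classmethod
    def from_panel(cls, panel: OutcomePanel):
        obj = cls.__new__(cls)
        obj.panel = panel
        return obj

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, thresholds, importance_weights=None):
        """Build from a tidy frame with ``D_<name>``/``r_<name>`` column pairs.

        An optional ``sampling_prob`` column supplies per-individual sampling
        probabilities; an ``id`` column, if present, must be unique.
        """
        from .io import panel_from_dataframe

        return cls.from_panel(
            panel_from_dataframe(df, thresholds, importance_weights=importance_weights)
        )

    @classmethod
    def from_tsv(cls, path, thresholds, importance_weights=None):
        from .io import read_panel

        return cls.from_panel(
            read_panel(path, thresholds, importance_weights=importance_weights)
        )

    def fit(self, senses="all", ru_conditional_odds=None) -> "PredictionEvaluation":
        """Estimate the criteria for the requested senses."""
        records = evaluate_panel(
            self.panel, senses=senses, ru_conditional_odds=ru_conditional_odds
        )
        return PredictionEvaluation(self, records)

    def calibration(self, n_bins: int = 10):
        """Weak component-wise calibration table (quantile bins)."""
        return component_calibration(self.panel, n_bins=n_bins)


class PredictionEvaluation:
    """Estimated criteria for one panel, one record per sense."""

    def __init__(self, model, records: dict):
        self.model = model
        self.records = records

    def __getitem__(self, sense: str) -> CriteriaRecord:
        return self.records[sense]

    def frame(self) -> pd.DataFrame:
        """Tidy table: one row per sense, one column per criterion."""
        rows = []
        for sense in SENSES:
            if sense not in self.records:
                continue
            rec = self.records[sense]
            row = {"sense": sense}
            for c in _CRITERIA_COLUMNS:
                row[c] = getattr(rec, c)
            row["relevant_region"] = rec.relevant_region
            rows.append(row)
        return pd.DataFrame(rows).set_index("sense")

    def to_dict(self) -> dict:
        return {s: r.to_dict() for s, r in self.records.items()}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def summary(self) -> str:
        """Human-readable summary table."""
        panel = self.model.panel
        lines = [
            "Multi-outcome risk prediction evaluation",
            "=" * 72,
            f"individuals: {panel.n_individuals}    outcomes: {panel.n_outcomes} "
            f"({', '.join(panel.outcome_names)})",
            f"thresholds:  {np.array2string(panel.thresholds, precision=4)}",
            "-" * 72,
            f"{'sense':<14}{'sens':>8}{'spec':>8}{'C':>8}{'RU':>8}{'PPV':>8}{'NPV':>8}"
            f"{'region':>9}",
        ]
        for sense in SENSES:
            if sense not in self.records:
                continue
            rec = self.records[sense]

            def fmt(v):
                return "   --" if v is None else f"{v:8.3f}"

            region = {True: "yes", False: "no", None: "--"}[rec.relevant_region]
            lines.append(
                f"{sense:<14}"
                + "".join(
                    fmt(getattr(rec, c))
                    for c in _CRITERIA_COLUMNS
                )
                + f"{region:>9}"
            )
        if any(r.undefined for r in self.records.values()):
            lines.append("-" * 72)
            for sense, rec in self.records.items():
                for crit, reason in rec.undefined.items():
                    lines.append(f"undefined {sense}.{crit}: {reason}")
        lines.append("=" * 72)
        return "\n".join(lines)
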