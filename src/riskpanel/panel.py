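"""Core data container for multi-outcome risk prediction and calibration checks.

An :class:`OutcomePanel` pairs an N x m binary outcome matrix ``D`` with an
N x m matrix of marginal risk predictions ``r(X)`` in [0, 1], a threshold
vector ``t``, optional per-outcome importance weights (the diagonal of the
weight matrix W) and optional per-individual sampling probabilities used for
ascertainment correction.  Individual i is classified high risk for outcome j
when ``risks[i, j] >= thresholds[j]`` (closed inequality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OutcomePanel",
    "CalibrationTable",
    "PanelValidationError",
    "DimensionMismatchError",
    "OutcomeDomainError",
    "RiskRangeError",
    "ThresholdRangeError",
    "WeightError",
    "SamplingProbabilityError",
    "validate_panel",
    "high_risk_indicator",
    "component_calibration",
]


class PanelValidationError(ValueError):
    """Base class for panel validation failures."""


class DimensionMismatchError(PanelValidationError):
    """Outcome, risk, threshold or weight shapes are inconsistent."""


class OutcomeDomainError(PanelValidationError):
    """Outcome matrix contains entries other than 0 and 1."""


class RiskRangeError(PanelValidationError):
    """Risk matrix contains entries outside [0, 1]."""


class ThresholdRangeError(PanelValidationError):
    """Threshold vector contains entries outside [0, 1]."""


class WeightError(PanelValidationError):
    """Importance weights are not strictly positive."""


class SamplingProbabilityError(PanelValidationError):
    """Sampling probabilities are not in (0, 1]."""


@dataclass(frozen=True)
class OutcomePanel:
    """Validated container of outcomes, risks and classification thresholds.

    Attributes
    ----------
    outcomes : (N, m) int array of {0, 1}
        Binary indicators; outcome j "did occur" in individual i when
        ``outcomes[i, j] == 1``.
    risks : (N, m) float array in [0, 1]
        Marginal risk predictions, one per outcome per individual.
    thresholds : (m,) float array in [0, 1]
        High-risk classification thresholds.
    outcome_names : tuple of str
    importance_weights : (m,) float array, strictly positive
        Diagonal of the importance-weight matrix W (default all ones).
    sampling_probs : (N,) float array in (0, 1]
        Probability with which each individual was sampled into the panel;
        inverse-probability weights ``1/sampling_probs`` correct the
        conditional-on-outcome estimators for ascertainment.
    """

    outcomes: np.ndarray
    risks: np.ndarray
    thresholds: np.ndarray
    outcome_names: tuple = ()
    importance_weights: np.ndarray = field(default=None)
    sampling_probs: np.ndarray = field(default=None)

    @property
    def n_individuals(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_outcomes(self) -> int:
        return self.outcomes.shape[1]

    @property
    def ascertainment_weights(self) -> np.ndarray:
        """Per-individual inverse-probability weights ``1 / sampling_probs``."""
        return 1.0 / self.sampling_probs

    def high_risk(self) -> np.ndarray:
        return high_risk_indicator(self)


def validate_panel(
    outcomes,
    risks,
    thresholds,
    importance_weights=None,
    sampling_probs=None,
    outcome_names=None,
) -> OutcomePanel:
    """Validate inputs and assemble an :class:`OutcomePanel`.

    Defaults: identity importance weights, sampling probability 1 for all
    individuals, outcome names ``y1..ym``.
    """
    outcomes = np.asarray(outcomes)
    risks = np.asarray(risks, dtype=float)
    if outcomes.ndim == 1:
        outcomes = outcomes[:, None]
    if risks.ndim == 1:
        risks = risks[:, None]
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if outcomes.shape != risks.shape:
        raise DimensionMismatchError(
            f"outcomes shape {outcomes.shape} != risks shape {risks.shape}"
        )
    n, m = outcomes.shape
    if thresholds.size == 1 and m > 1:
        thresholds = np.full(m, thresholds[0])
    if thresholds.shape != (m,):
        raise DimensionMismatchError(
            f"thresholds shape {thresholds.shape} incompatible with m={m}"
        )
    if np.isnan(outcomes.astype(float)).any() or np.isnan(risks).any():
        raise PanelValidationError("missing values are not supported")
    if not np.isin(outcomes, (0, 1)).all():
        raise OutcomeDomainError("outcomes must contain only 0 and 1")
    outcomes = outcomes.astype(np.int8)
    if (risks < 0).any() or (risks > 1).any():
        raise RiskRangeError("risks must lie in [0, 1]")
    if (thresholds < 0).any() or (thresholds > 1).any():
        raise ThresholdRangeError("thresholds must lie in [0, 1]")

    if importance_weights is None:
        importance_weights = np.ones(m)
    importance_weights = np.asarray(importance_weights, dtype=float)
    if importance_weights.shape != (m,):
        raise DimensionMismatchError(
            f"importance_weights shape {importance_weights.shape} != ({m},)"
        )
    if (importance_weights <= 0).any():
        raise WeightError("importance weights must be strictly positive")

    if sampling_probs is None:
        sampling_probs = np.ones(n)
    sampling_probs = np.asarray(sampling_probs, dtype=float)
    if sampling_probs.shape != (n,):
        raise DimensionMismatchError(
            f"sampling_probs shape {sampling_probs.shape} != ({n},)"
        )
    if (sampling_probs <= 0).any() or (sampling_probs > 1).any():
        raise SamplingProbabilityError("sampling probabilities must lie in (0, 1]")

    if outcome_names is None:
        outcome_names = tuple(f"y{j + 1}" for j in range(m))
    else:
        outcome_names = tuple(str(s) for s in outcome_names)
        if len(outcome_names) != m:
            raise DimensionMismatchError("outcome_names length mismatch")

    return OutcomePanel(
        outcomes=outcomes,
        risks=risks,
        thresholds=thresholds,
        outcome_names=outcome_names,
        importance_weights=importance_weights,
        sampling_probs=sampling_probs,
    )


def high_risk_indicator(panel: OutcomePanel) -> np.ndarray:
    """Binary N x m matrix: entry (i, j) is 1 iff ``risks[i,j] >= thresholds[j]``."""
    return (panel.risks >= panel.thresholds[None, :]).astype(np.int8)


@dataclass(frozen=True)
class CalibrationTable:
    """Per-outcome, per-quantile-bin comparison of predicted and observed risk.

    ``table`` has one row per (outcome, bin) with columns ``outcome``, ``bin``,
    ``lower``, ``upper``, ``count``, ``mean_risk``, ``obs_freq``.
    ``max_discrepancy`` maps each outcome name to
    ``max_bins |obs_freq - mean_risk|``, a crude weak component-wise
    calibration summary.
    """

    table: pd.DataFrame
    max_discrepancy: dict

    def __str__(self) -> str:  # pragma: no cover - convenience only
        worst = max(self.max_discrepancy.values())
        return f"CalibrationTable({len(self.table)} bins, worst discrepancy {worst:.4f})"


def component_calibration(panel: OutcomePanel, n_bins: int = 10) -> CalibrationTable:
    """Assess weak component-wise calibration with equal-count (quantile) bins.

    For each outcome the risks are grouped into ``n_bins`` quantile bins
    (merged, with a warning, when tied risks leave duplicate bin edges) and
    the mean predicted risk is compared with the observed outcome frequency.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if panel.n_individuals < n_bins:
        raise ValueError("need at least n_bins individuals")
    rows = []
    max_disc = {}
    for j, name in enumerate(panel.outcome_names):
        r = panel.risks[:, j]
        d = panel.outcomes[:, j]
        try:
            binned, edges = pd.qcut(r, n_bins, retbins=True, duplicates="raise")
        except ValueError:
            warnings.warn(
                f"outcome {name!r}: tied risks collapse some quantile bins; merging",
                stacklevel=2,
            )
            binned, edges = pd.qcut(r, n_bins, retbins=True, duplicates="drop")
        codes = binned.codes
        disc = 0.0
        for b in range(codes.max() + 1):
            sel = codes == b
            mean_risk = float(r[sel].mean())
            obs = float(d[sel].mean())
            disc = max(disc, abs(obs - mean_risk))
            rows.append(
                {
                    "outcome": name,
                    "bin": b,
                    "lower": float(edges[b]),
                    "upper": float(edges[b + 1]),
                    "count": int(sel.sum()),
                    "mean_risk": mean_risk,
                    "obs_freq": obs,
                }
            )
        max_disc[name] = disc
    return CalibrationTable(table=pd.DataFrame(rows), max_discrepancy=max_disc)
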