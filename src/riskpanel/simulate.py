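"""Cohort simulation from a liability probit model, plus hand-auditable fixtures.

``simulate_cohort`` draws (liability, predictor) pairs from the model's joint
multivariate normal law, thresholds liabilities into outcomes and converts
predictors into calibrated risks, so every empirical criterion computed on the
cohort converges to the generating model's analytic value.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .panel import OutcomePanel, validate_panel
from .probit import LiabilityProbitModel

__all__ = ["SimulatedCohort", "simulate_cohort", "toy_fixture", "prs_example"]


@dataclass(frozen=True)
class SimulatedCohort:
    """Draws from a liability probit model.

    ``outcomes[i, j] = 1`` iff ``liabilities[i, j] >= tau[j]``; ``risks`` are
    the calibrated per-outcome risks of each predictor row.
    """

    liabilities: np.ndarray
    predictors: np.ndarray
    outcomes: np.ndarray
    risks: np.ndarray
    model: LiabilityProbitModel
    seed: object

    def panel(self, thresholds, importance_weights=None, sampling_probs=None) -> OutcomePanel:
        """Package the cohort as an :class:`OutcomePanel` at given thresholds."""
        return validate_panel(
            self.outcomes,
            self.risks,
            thresholds,
            importance_weights=importance_weights,
            sampling_probs=sampling_probs,
            outcome_names=self.model.names,
        )


def simulate_cohort(model: LiabilityProbitModel, n: int, seed=None) -> SimulatedCohort:
    """Simulate ``n`` iid individuals from the model's joint (L, X) law."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L, X = model._simulate_joint(n, rng)
    D = (L >= model.tau).astype(np.int8)
    R = model.risk_from_predictor(X)
    return SimulatedCohort(
        liabilities=L, predictors=X, outcomes=D, risks=R, model=model, seed=seed
    )


def _indicator_to_risks(ind, hi=0.9, lo=0.1):
    return np.where(np.asarray(ind) == 1, hi, lo)


def toy_fixture(name: str):
    """Small hand-auditable panels with their exactly enumerated criteria.

    Returns ``(panel, expected)`` where ``expected`` maps sense names to
    exact :class:`fractions.Fraction` sensitivities (and, for the 2x2 panel,
    further criteria).  The ``eight_by_four`` panel is built to match the
    published worked example's caption fractions (caption-consistent, not
    figure-identical): joint 1/2, screening 4/7, panel-wise 3/7, outcome-wise
    7/16.
    """
    if name == "two_by_two":
        outcomes = [[1, 0], [0, 1]]
        risks = [[0.9, 0.1], [0.8, 0.2]]
        panel = validate_panel(outcomes, risks, (0.5, 0.5))
        expected = {
            "outcome_wise": {
                "sensitivity": Fraction(1, 2),
                "specificity": Fraction(1, 2),
                "ppv": Fraction(1, 2),
                "npv": Fraction(1, 2),
            },
            "screening": {"sensitivity": Fraction(1, 1)},
            "panel_wise": {
                "sensitivity": Fraction(1, 2),
                "specificity": Fraction(1, 2),
            },
        }
        return panel, expected
    if name == "perfect":
        outcomes = [[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 0]]
        risks = np.asarray(outcomes, dtype=float)
        panel = validate_panel(outcomes, risks, (0.5, 0.5, 0.5))
        expected = {
            s: {"sensitivity": Fraction(1), "specificity": Fraction(1)}
            for s in ("outcome_wise", "screening", "panel_wise")
        }
        return panel, expected
    if name == "eight_by_four":
        outcomes = np.array(
            [
                [1, 1, 1, 1],
                [1, 1, 1, 1],
                [1, 1, 1, 0],
                [1, 1, 0, 0],
                [1, 0, 0, 0],
                [1, 0, 0, 0],
                [1, 0, 0, 0],
                [0, 0, 0, 0],
            ]
        )
        predicted = np.array(
            [
                [1, 1, 1, 1],
                [0, 0, 0, 0],
                [1, 1, 0, 0],
                [0, 0, 1, 1],
                [1, 0, 1, 0],
                [0, 0, 0, 0],
                [0, 0, 0, 0],
                [0, 0, 0, 0],
            ]
        )
        panel = validate_panel(
            outcomes, _indicator_to_risks(predicted), (0.5, 0.5, 0.5, 0.5)
        )
        expected = {
            "outcome_wise": {"sensitivity": Fraction(7, 16)},
            "joint": {"sensitivity": Fraction(1, 2)},
            "screening": {"sensitivity": Fraction(4, 7)},
            "panel_wise": {"sensitivity": Fraction(3, 7)},
        }
        return panel, expected
    raise KeyError(f"unknown fixture {name!r}")


def prs_example(scenario: str = "current") -> LiabilityProbitModel:
    """Six-disease polygenic-risk-score model (reconstructed parameter set).

    ``scenario='current'`` converts each disease's published-era AUC to a
    liability variance explained and sets Sigma_X = Sigma_LX with the genetic
    correlations supplying both Sigma_L and the score correlation structure.
    ``scenario='snp_h2'`` instead sets each score's liability R^2 to the SNP
    heritability, the ceiling for genotype-based predictors.

    The parameter tables are a synthetic reconstruction from the public
    literature (see ``_prs_tables_synthetic``), not a transcription of any
    single published table.
    """
    from . import _prs_tables_synthetic as tab

    corr = np.asarray(tab.GENETIC_CORRELATION, dtype=float)
    prev = np.asarray(tab.PREVALENCE, dtype=float)
    if scenario == "current":
        return LiabilityProbitModel.from_auc(
            np.asarray(tab.AUC, dtype=float), prev, corr, names=tab.DISEASES
        )
    if scenario == "snp_h2":
        r2 = np.asarray(tab.SNP_H2, dtype=float)
        s = np.sqrt(r2)
        sigma_x = corr * np.outer(s, s)
        return LiabilityProbitModel(prev, corr, sigma_x, sigma_x, names=tab.DISEASES)
    raise ValueError("scenario must be 'current' or 'snp_h2'")
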