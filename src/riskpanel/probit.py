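"""Multivariate probit liability model for multi-outcome risk prediction.

Outcome j occurs when a latent standard-normal liability L[j] exceeds a
threshold tau[j] = Phi^-1(1 - prevalence_j).  A normally distributed
predictor vector X is jointly multivariate normal with L:

    (L, X) ~ N(0, Sigma),   Sigma = [[Sigma_L, Sigma_LX], [Sigma_LX', Sigma_X]]

The marginal risk for outcome j given X = x is

    r_j(x) = 1 - Phi( (tau_j - x_j) / sqrt(1 - Sigma_X[jj]) )

which is weakly component-wise calibrated by construction.  From this
covariance specification every criterion — outcome-wise, joint, screening
(weak panel-wise) and strong panel-wise sensitivity, specificity, C-index and
relative utility — can be computed analytically as ratios of multivariate
normal rectangle probabilities, or by conditional simulation for the
concordances that involve extrema of the risk vector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.stats import norm

from ._tmvn import mvn_rectangle, truncated_mvn_moments
from .records import CriteriaRecord, canonical_sense, proportion_se

__all__ = [
    "LiabilityProbitModel",
    "TruncatedMoments",
    "auc_r2_convert",
    "analytic_single_outcome_auc",
]

_PANEL_ENUMERATION_CAP = 12


@dataclass(frozen=True)
class TruncatedMoments:
    """Moments of the liability conditional on the outcome pattern D = d."""

    pattern: np.ndarray
    mean: np.ndarray
    cov: np.ndarray
    probability: float


def analytic_single_outcome_auc(sigma_lx: float, sigma_x: float, prevalence: float) -> float:
    """Exact single-outcome C-index of the liability model by 2-D quadrature.

    AUC = P(X_a > X_b | L_a >= tau, L_b < tau) for independent case/control
    draws; conditioning on the two liabilities leaves X_a - X_b Gaussian, so

        AUC = (1/(K(1-K))) * int_{la>=tau} int_{lb<tau}
                Phi( s_lx (la - lb) / sqrt(2 s_x - 2 s_lx^2) ) phi(la) phi(lb)
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if sigma_x <= 0:
        return 0.5
    tau = norm.ppf(1 - prevalence)
    denom2 = 2.0 * sigma_x - 2.0 * sigma_lx**2
    if denom2 <= 0:
        denom2 = 1e-12
    scale = sigma_lx / np.sqrt(denom2)

    def inner(la):
        f = lambda lb: norm.cdf(scale * (la - lb)) * norm.pdf(lb)
        v, _ = integrate.quad(f, -np.inf, tau, epsabs=1e-12, limit=200)
        return v * norm.pdf(la)

    val, _ = integrate.quad(inner, tau, np.inf, epsabs=1e-12, limit=200)
    return float(val / (prevalence * (1 - prevalence)))


def auc_r2_convert(value: float, prevalence: float, direction: str = "auc_to_r2") -> float:
    """Convert between a single-outcome AUC and the liability variance explained.

    The conversion is defined by self-consistency: R^2 is the value for which
    a single-outcome model with Sigma_LX = Sigma_X = R^2 has exactly the given
    model-implied C-index.  ``direction`` is ``"auc_to_r2"`` or
    ``"r2_to_auc"``.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if direction == "r2_to_auc":
        if not 0 <= value < 1:
            raise ValueError("R2 must be in [0, 1)")
        return analytic_single_outcome_auc(value, value, prevalence)
    if direction != "auc_to_r2":
        raise ValueError("direction must be 'auc_to_r2' or 'r2_to_auc'")
    if value < 0.5:
        raise ValueError("AUC must be >= 0.5 (positively oriented predictor)")
    if value >= 1:
        raise ValueError("AUC must be < 1")
    if value == 0.5:
        return 0.0
    f = lambda r2: analytic_single_outcome_auc(r2, r2, prevalence) - value
    hi = 1 - 1e-9
    if f(hi) < 0:
        raise ValueError(f"AUC {value} not attainable at prevalence {prevalence}")
    return float(brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-12))


class LiabilityProbitModel:
    """Multivariate probit liability-threshold model (tau, Sigma_L, Sigma_X, Sigma_LX)."""

    def __init__(self, prevalences, sigma_L, sigma_X, sigma_LX, names=None):
        prevalences = np.atleast_1d(np.asarray(prevalences, dtype=float))
        m = prevalences.size
        if not np.all((prevalences > 0) & (prevalences < 1)):
            raise ValueError("prevalences must lie in (0, 1)")
        sigma_L = np.atleast_2d(np.asarray(sigma_L, dtype=float))
        sigma_X = np.atleast_2d(np.asarray(sigma_X, dtype=float))
        sigma_LX = np.atleast_2d(np.asarray(sigma_LX, dtype=float))
        for name, mat in (("sigma_L", sigma_L), ("sigma_X", sigma_X), ("sigma_LX", sigma_LX)):
            if mat.shape != (m, m):
                raise ValueError(f"{name} must be {m}x{m}")
        for name, mat in (("sigma_L", sigma_L), ("sigma_X", sigma_X)):
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
        if not np.allclose(np.diag(sigma_L), 1.0, atol=1e-10):
            raise ValueError("sigma_L must have unit diagonal")
        if np.any(np.diag(sigma_X) < 0) or np.any(np.diag(sigma_X) >= 1):
            raise ValueError("diagonal of sigma_X must lie in [0, 1)")

        sigma = np.block([[sigma_L, sigma_LX], [sigma_LX.T, sigma_X]])
        eig = np.linalg.eigvalsh(sigma)
        if eig[0] < -1e-8:
            raise ValueError(
                f"joint covariance is not positive semi-definite "
                f"(smallest eigenvalue {eig[0]:.3g})"
            )
        if eig[0] < 0:
            warnings.warn(
                f"joint covariance has tiny negative eigenvalue {eig[0]:.3g}; "
                "projecting onto the PSD cone",
                stacklevel=2,
            )
            w, v = np.linalg.eigh(sigma)
            sigma = (v * np.clip(w, 0, None)) @ v.T
            sigma = (sigma + sigma.T) / 2.0

        self.m = m
        self.prevalences = prevalences
        self.tau = norm.ppf(1 - prevalences)
        self.sigma_L = sigma_L
        self.sigma_X = sigma_X
        self.sigma_LX = sigma_LX
        self.sigma = sigma
        self.names = (
            tuple(str(s) for s in names)
            if names is not None
            else tuple(f"y{j + 1}" for j in range(m))
        )
        if len(self.names) != m:
            raise ValueError("names length mismatch")

    # ------------------------------------------------------------------ build
    @classmethod
    def from_auc(cls, auc, prevalence, corr=None, names=None):
        """Build the special case Sigma_X = Sigma_LX from per-outcome AUCs.

        Each AUC is converted to a liability variance explained R2_j
        (self-consistent conversion); ``corr`` supplies both the liability
        correlations Sigma_L and the predictor correlation structure, giving
        Sigma_X[jk] = corr[jk] * sqrt(R2_j R2_k) and Sigma_LX = Sigma_X.
        """
        auc = np.atleast_1d(np.asarray(auc, dtype=float))
        prevalence = np.atleast_1d(np.asarray(prevalence, dtype=float))
        m = auc.size
        if corr is None:
            corr = np.eye(m)
        corr = np.atleast_2d(np.asarray(corr, dtype=float))
        r2 = np.array([auc_r2_convert(a, k) for a, k in zip(auc, prevalence)])
        s = np.sqrt(r2)
        sigma_x = corr * np.outer(s, s)
        return cls(prevalence, corr, sigma_x, sigma_x, names=names)

    @classmethod
    def from_config(cls, config):
        """Build from a dict or JSON file path (see the model config schema)."""
        if isinstance(config, (str, bytes)) or hasattr(config, "read"):
            if hasattr(config, "read"):
                config = json.load(config)
            else:
                with open(config) as fh:
                    config = json.load(fh)
        names = config.get("names")
        if "auc" in config:
            return cls.from_auc(
                config["auc"], config["prevalence"], config.get("corr"), names=names
            )
        return cls(
            config["prevalence"],
            config["sigma_L"],
            config["sigma_X"],
            config["sigma_LX"],
            names=names,
        )

    # -------------------------------------------------------------- plumbing
    def risk_from_predictor(self, x) -> np.ndarray:
        """Calibrated risk vector r(x), component-wise (Eq. for r_j above)."""
        x = np.asarray(x, dtype=float)
        resid_sd = np.sqrt(1.0 - np.diag(self.sigma_X))
        if np.any(resid_sd <= 0):
            raise ValueError("sigma_X diagonal of 1 leaves no residual liability variance")
        return 1.0 - norm.cdf((self.tau - x) / resid_sd)

    def predictor_threshold(self, t) -> np.ndarray:
        """Predictor-scale thresholds: r_j(t_tilde) = t_j component-wise."""
        t = np.broadcast_to(np.asarray(t, dtype=float), (self.m,))
        if np.any((t < 0) | (t > 1)):
            raise ValueError("risk thresholds must lie in [0, 1]")
        with np.errstate(divide="ignore"):
            return self.tau - np.sqrt(1.0 - np.diag(self.sigma_X)) * norm.ppf(1.0 - t)

    # ------------------------------------------------------ conditioning laws
    def pattern_probability(self, d) -> float:
        lower, upper = self._liability_box(d)
        return mvn_rectangle(lower, upper, self.sigma_L)

    def _liability_box(self, d):
        d = np.broadcast_to(np.asarray(d, dtype=int), (self.m,))
        lower = np.where(d == 1, self.tau, -np.inf)
        upper = np.where(d == 1, np.inf, self.tau)
        return lower, upper

    def truncated_liability_moments(self, d) -> TruncatedMoments:
        """Tallis moments of L | D = d (liability box-truncated at tau)."""
        d = np.broadcast_to(np.asarray(d, dtype=int), (self.m,)).copy()
        lower, upper = self._liability_box(d)
        mean, cov, prob = truncated_mvn_moments(self.sigma_L, lower, upper)
        return TruncatedMoments(pattern=d, mean=mean, cov=cov, probability=prob)

    def complement_liability_moments(self, d):
        """Moments of L | D != d from the law of total expectation/variance."""
        tm = self.truncated_liability_moments(d)
        p = tm.probability
        if p >= 1 - 1e-12:
            raise ValueError("complement pattern set has negligible probability")
        mean_c = -p / (1 - p) * tm.mean
        cov_c = (
            (self.sigma_L - p * (tm.cov + np.outer(tm.mean, tm.mean))) / (1 - p)
            - np.outer(mean_c, mean_c)
        )
        return mean_c, (cov_c + cov_c.T) / 2.0, 1.0 - p

    def predictor_moments_given_outcomes(self, d, complement: bool = False):
        """Pearson-Aitken moments of X | D = d (or X | D != d)."""
        if complement:
            mu_l, cov_l, _ = self.complement_liability_moments(d)
        else:
            tm = self.truncated_liability_moments(d)
            mu_l, cov_l = tm.mean, tm.cov
        sl_inv = np.linalg.inv(self.sigma_L)
        mean = self.sigma_LX @ sl_inv @ mu_l
        cov = self.sigma_X - self.sigma_LX @ (sl_inv - sl_inv @ cov_l @ sl_inv) @ self.sigma_LX.T
        return mean, (cov + cov.T) / 2.0

    def liability_given_predictor(self, x):
        """Gaussian conditional moments of L | X = x (selection formulae)."""
        x = np.broadcast_to(np.asarray(x, dtype=float), (self.m,))
        sx_inv = np.linalg.inv(self.sigma_X)
        mean = self.sigma_LX @ sx_inv @ x
        cov = self.sigma_L - self.sigma_LX @ sx_inv @ self.sigma_LX.T
        return mean, (cov + cov.T) / 2.0

    # --------------------------------------------------------- aggregates
    def pattern_aggregates(self) -> dict:
        """Marginal probabilities of the composite events D=1, D=0, D!=0, D!=1."""
        p_all = mvn_rectangle(self.tau, np.inf, self.sigma_L)
        p_none = mvn_rectangle(-np.inf, self.tau, self.sigma_L)
        return {"all": p_all, "none": p_none, "any": 1 - p_none, "not_all": 1 - p_all}

    def outcome_probabilities_given_risk(self, t) -> dict:
        """Composite outcome probabilities conditional on r(X) = t (X = t_tilde)."""
        tt = self.predictor_threshold(t)
        # boundary thresholds (risk 0 or 1) condition on an extreme predictor
        tt = np.clip(tt, -40.0, 40.0)
        mu, cov = self.liability_given_predictor(tt)
        p_all = mvn_rectangle(self.tau, np.inf, cov, mean=mu)
        p_none = mvn_rectangle(-np.inf, self.tau, cov, mean=mu)
        return {"all": p_all, "none": p_none, "any": 1 - p_none, "not_all": 1 - p_all}

    def wilks_variance_explained(self) -> float:
        """1 - Wilks' Lambda: total liability variance explained by X."""
        resid = self.sigma_L + self.sigma_X - self.sigma_LX - self.sigma_LX.T
        return float(1.0 - np.linalg.det(resid) / np.linalg.det(self.sigma_L))

    # --------------------------------------------------------- criteria
    def _joint_sens_spec(self, tt):
        agg = self.pattern_aggregates()
        lower = np.concatenate([self.tau, tt])
        p_both = mvn_rectangle(lower, np.inf, self.sigma)
        sens = p_both / agg["all"]
        p_pred_all = mvn_rectangle(tt, np.inf, self.sigma_X)
        spec = 1.0 - (p_pred_all - p_both) / agg["not_all"]
        return sens, spec

    def _screening_sens_spec(self, tt):
        agg = self.pattern_aggregates()
        upper = np.concatenate([self.tau, tt])
        p_both = mvn_rectangle(-np.inf, upper, self.sigma)
        spec = p_both / agg["none"]
        p_pred_none = mvn_rectangle(-np.inf, tt, self.sigma_X)
        sens = 1.0 - (p_pred_none - p_both) / agg["any"]
        return sens, spec

    def _single_outcome_sens_spec(self, tt):
        sens = np.empty(self.m)
        spec = np.empty(self.m)
        for j in range(self.m):
            cov = np.array(
                [[1.0, self.sigma_LX[j, j]], [self.sigma_LX[j, j], self.sigma_X[j, j]]]
            )
            k = self.prevalences[j]
            p11 = mvn_rectangle([self.tau[j], tt[j]], np.inf, cov)
            p00 = mvn_rectangle(-np.inf, [self.tau[j], tt[j]], cov)
            sens[j] = p11 / k
            spec[j] = p00 / (1 - k)
        return sens, spec

    def _panel_sens_spec(self, tt, n_sim=1_000_000, seed=None):
        if self.m > _PANEL_ENUMERATION_CAP:
            return self._panel_sens_spec_simulated(tt, n_sim, seed)
        agg = self.pattern_aggregates()
        sens_sum = 0.0
        spec_sum = 0.0
        for code in range(2**self.m):
            d = np.array([(code >> j) & 1 for j in range(self.m)])
            occ = d == 1
            lo_l, up_l = self._liability_box(d)
            if occ.any():  # patterns d != 0 contribute to the sensitivity sum
                idx = np.concatenate([np.arange(self.m), self.m + np.where(occ)[0]])
                lower = np.concatenate([lo_l, np.full(occ.sum(), -np.inf)])
                upper = np.concatenate([up_l, tt[occ]])
                cov = self.sigma[np.ix_(idx, idx)]
                sens_sum += mvn_rectangle(lower, upper, cov)
            if not occ.all():  # patterns d != 1 contribute to the specificity sum
                non = ~occ
                idx = np.concatenate([np.arange(self.m), self.m + np.where(non)[0]])
                lower = np.concatenate([lo_l, np.full(non.sum(), -np.inf)])
                upper = np.concatenate([up_l, tt[non]])
                cov = self.sigma[np.ix_(idx, idx)]
                spec_sum += mvn_rectangle(lower, upper, cov)
        sens = 1.0 - sens_sum / agg["any"]
        spec = spec_sum / agg["not_all"]
        return sens, spec

    def _panel_sens_spec_simulated(self, tt, n_sim, seed):
        rng = np.random.default_rng(seed)
        L, X = self._simulate_joint(n_sim, rng)
        D = L >= self.tau
        I = X >= tt
        any_out = D.any(axis=1)
        not_all = ~D.all(axis=1)
        sens = float(((D & I).any(axis=1)[any_out]).mean())
        spec = float((~((~D) & I).any(axis=1)[not_all]).mean())
        return sens, spec

    def _simulate_joint(self, n, rng):
        chol = _safe_cholesky(self.sigma)
        z = rng.standard_normal((n, 2 * self.m)) @ chol.T
        return z[:, : self.m], z[:, self.m :]

    def simulated_concordance(self, sense, n_pairs=1_000_000, seed=None):
        """Monte-Carlo C-index for the joint, screening or panel-wise sense.

        Joint and screening senses draw conditional Gaussian predictors with
        Pearson-Aitken moments (X | D=1 vs X | D!=1, and X | D=0 vs X | D!=0)
        and compare the minimum / maximum risks.  The panel-wise sense draws
        (L, X) jointly and compares ``max(D o r)`` against ``max((1-D) o r)``
        over all cross pairs, self-pairs included.  Returns ``(c, se)``.
        """
        sense = canonical_sense(sense)
        if n_pairs < 10_000:
            raise ValueError("n_pairs must be at least 10^4")
        rng = np.random.default_rng(seed)
        if sense == "outcome_wise":
            raise ValueError("outcome-wise concordance is computed analytically")
        if sense in ("joint", "screening"):
            d = np.ones(self.m, dtype=int) if sense == "joint" else np.zeros(self.m, dtype=int)
            mu_c, cov_c = self.predictor_moments_given_outcomes(d)
            mu_n, cov_n = self.predictor_moments_given_outcomes(d, complement=True)
            rng_a, rng_b = rng.spawn(2)
            xa = _sample_gaussian(mu_c, cov_c, n_pairs, rng_a)
            xb = _sample_gaussian(mu_n, cov_n, n_pairs, rng_b)
            ra = self.risk_from_predictor(xa)
            rb = self.risk_from_predictor(xb)
            if sense == "joint":
                sa, sb = ra.min(axis=1), rb.min(axis=1)  # D=1 side vs D!=1 side
            else:
                sa, sb = rb.max(axis=1), ra.max(axis=1)  # D!=0 side vs D=0 side
            c = float(np.mean((sa > sb) + 0.5 * (sa == sb)))
            return c, proportion_se(c, n_pairs)
        # panel-wise: joint simulation with pattern filtering
        agg = self.pattern_aggregates()
        n_cohort = int(np.ceil(np.sqrt(n_pairs / max(agg["any"] * agg["not_all"], 1e-12))))
        n_cohort = max(n_cohort, 200_000)
        L, X = self._simulate_joint(n_cohort, rng)
        D = L >= self.tau
        R = self.risk_from_predictor(X)
        any_out = D.any(axis=1)
        not_all = ~D.all(axis=1)
        if not any_out.any() or not not_all.any():
            raise ValueError(
                "no individual with the required outcome pattern in the simulation "
                "budget; increase n_pairs"
            )
        s1 = np.where(D, R, -np.inf).max(axis=1)[any_out]
        s0 = np.where(~D, R, -np.inf).max(axis=1)[not_all]
        from .criteria import two_sample_concordance

        c = two_sample_concordance(s1, s0)
        return float(c), proportion_se(c, min(s1.size, s0.size))

    def analytic_criteria(
        self,
        thresholds,
        sense,
        n_pairs=1_000_000,
        seed=None,
        importance_weights=None,
        compute_c_index=True,
    ) -> CriteriaRecord:
        """Model-implied criteria for one sense at the given risk thresholds.

        Sensitivity and specificity are ratios of multivariate normal
        rectangle probabilities on the joint (L, X) covariance; relative
        utility uses the model-based conditional outcome probabilities at the
        threshold point; the C-index is analytic for the outcome-wise sense
        and simulated otherwise.
        """
        sense = canonical_sense(sense)
        t = np.broadcast_to(np.asarray(thresholds, dtype=float), (self.m,))
        tt = self.predictor_threshold(t)
        agg = self.pattern_aggregates()
        cond = self.outcome_probabilities_given_risk(t)
        w = (
            np.ones(self.m)
            if importance_weights is None
            else np.asarray(importance_weights, dtype=float)
        )
        k = self.prevalences
        rec = CriteriaRecord(sense=sense)
        if sense == "outcome_wise":
            sens_j, spec_j = self._single_outcome_sens_spec(tt)
            rec.sensitivity = float(np.sum(w * k * sens_j) / np.sum(w * k))
            rec.specificity = float(np.sum(w * (1 - k) * spec_j) / np.sum(w * (1 - k)))
            if compute_c_index:
                auc = np.array(
                    [
                        analytic_single_outcome_auc(
                            self.sigma_LX[j, j], self.sigma_X[j, j], k[j]
                        )
                        for j in range(self.m)
                    ]
                )
                cw = w * k * (1 - k)
                rec.c_index = float(np.sum(cw * auc) / np.sum(cw))
            threshold_odds = float(np.sum(t * w) / np.sum((1 - t) * w))
            outcome_odds = float(np.sum(w * (1 - k)) / np.sum(w * k))
        elif sense == "joint":
            rec.sensitivity, rec.specificity = self._joint_sens_spec(tt)
            threshold_odds = cond["all"] / cond["not_all"] if cond["not_all"] > 0 else np.inf
            outcome_odds = agg["not_all"] / agg["all"]
        elif sense == "screening":
            rec.sensitivity, rec.specificity = self._screening_sens_spec(tt)
            threshold_odds = cond["any"] / cond["none"] if cond["none"] > 0 else np.inf
            outcome_odds = agg["none"] / agg["any"]
        else:
            rec.sensitivity, rec.specificity = self._panel_sens_spec(tt, seed=seed)
            threshold_odds = cond["any"] / cond["not_all"] if cond["not_all"] > 0 else np.inf
            outcome_odds = agg["not_all"] / agg["any"]
        if compute_c_index and sense != "outcome_wise":
            rec.c_index, rec.c_index_se = self.simulated_concordance(
                sense, n_pairs=n_pairs, seed=seed
            )
        rec.relative_utility = float(
            rec.sensitivity - threshold_odds * outcome_odds * (1.0 - rec.specificity)
        )
        from .criteria import relevant_region_check

        rec.relevant_region = relevant_region_check(
            t, k, sense, model=self, importance_weights=w
        )
        return rec

    def evaluate(self, thresholds, senses="all", n_pairs=1_000_000, seed=None):
        """Criteria records for several senses (see ``analytic_criteria``)."""
        from .records import SENSES

        if senses == "all":
            senses = SENSES
        elif isinstance(senses, str):
            senses = (senses,)
        return {
            canonical_sense(s): self.analytic_criteria(
                thresholds, s, n_pairs=n_pairs, seed=seed
            )
            for s in senses
        }

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LiabilityProbitModel(m={self.m}, prevalences={np.round(self.prevalences, 4)}, "
            f"wilks_1mL={self.wilks_variance_explained():.3f})"
        )


def _safe_cholesky(sigma):
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(sigma)
        w = np.clip(w, 0, None)
        return v * np.sqrt(w)


def _sample_gaussian(mean, cov, n, rng):
    chol = _safe_cholesky(cov)
    return mean + rng.standard_normal((n, mean.size)) @ chol.T
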