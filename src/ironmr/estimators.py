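"""Two-sample Mendelian randomization estimators.

All estimators consume a :class:`~ironmr.summary_data.HarmonizedInstrument`
(allele-aligned SNP–exposure betas gamma_j with SE, SNP–outcome betas
Gamma_j with SE) and assume uncorrelated instruments. The per-SNP causal
estimate is the Wald ratio theta_j = Gamma_j / gamma_j with a delta-method
standard error; pooling is by fixed-effect inverse-variance weighting (the
primary analysis), with simple/weighted median estimators (valid when at
least half the weight comes from valid instruments) and Egger regression
(intercept = directional-pleiotropy test) as sensitivity analyses.

The estimators are scikit-learn style: construct with hyper-parameters,
``fit(instrument)``, read fitted attributes (``beta_``, ``se_``,
``pvalue_``, ``or_point_`` ...); thin module-level functions wrap them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .summary_data import DegenerateInstrumentError, HarmonizedInstrument

__all__ = [
    "WaldEstimate",
    "MREstimate",
    "EggerResult",
    "wald_ratio",
    "wald_ratios",
    "to_odds_scale",
    "weighted_median_point",
    "sex_difference_test",
    "IVWEstimator",
    "SimpleMedianEstimator",
    "WeightedMedianEstimator",
    "EggerRegression",
    "ivw_fixed",
    "simple_median",
    "weighted_median",
    "egger",
]

SE_MODES = ("full_delta", "first_order")


class InsufficientInstrumentsError(ValueError):
    """Fewer SNPs than the estimator's degrees of freedom allow."""


@dataclass(frozen=True)
class WaldEstimate:
    """Single-SNP causal estimate: ratio Gamma/gamma with delta-method SE."""

    rsid: str | None
    ratio: float
    se: float


@dataclass(frozen=True)
class MREstimate:
    """One pooled causal estimate with odds-scale transform.

    ``beta`` is on the outcome-beta (log-odds-approximating) scale;
    ``or_point`` = exp(beta) with a level-``level`` Wald confidence interval.
    """

    method: str
    beta: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EggerResult:
    """Egger slope (pleiotropy-adjusted causal estimate) plus intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float
    low_df: bool = False


def _check_se_mode(se_mode: str) -> None:
    if se_mode not in SE_MODES:
        raise ValueError(f"se_mode must be one of {SE_MODES}, got {se_mode!r}")


def wald_ratio(
    gamma: float,
    se_gamma: float,
    Gamma: float,
    se_Gamma: float,
    se_mode: str = "full_delta",
    rsid: str | None = None,
) -> WaldEstimate:
    """Per-SNP Wald ratio Gamma/gamma with a delta-method standard error.

    ``full_delta`` keeps the exposure-side variance term,
    se = sqrt(se_Gamma^2/gamma^2 + Gamma^2 se_gamma^2 / gamma^4);
    ``first_order`` uses se = se_Gamma/|gamma| (exposure treated as known).
    """
    _check_se_mode(se_mode)
    if gamma == 0:
        raise DegenerateInstrumentError(
            f"exposure beta is zero{f' for {rsid}' if rsid else ''}: Wald ratio undefined"
        )
    if se_Gamma <= 0 or se_gamma < 0:
        raise ValueError("standard errors must be positive")
    ratio = Gamma / gamma
    if se_mode == "first_order":
        se = se_Gamma / abs(gamma)
    else:
        se = math.sqrt(se_Gamma**2 / gamma**2 + Gamma**2 * se_gamma**2 / gamma**4)
    return WaldEstimate(rsid, ratio, se)


def wald_ratios(h: HarmonizedInstrument, se_mode: str = "full_delta") -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-SNP ratios and delta-method SEs for an instrument."""
    _check_se_mode(se_mode)
    if np.any(h.gamma == 0):
        zero = [r for r, g in zip(h.rsids, h.gamma) if g == 0]
        raise DegenerateInstrumentError(f"exposure beta is zero for {', '.join(zero)}")
    ratios = h.Gamma / h.gamma
    if se_mode == "first_order":
        ses = h.se_Gamma / np.abs(h.gamma)
    else:
        ses = np.sqrt(h.se_Gamma**2 / h.gamma**2 + h.Gamma**2 * h.se_gamma**2 / h.gamma**4)
    return ratios, ses


def to_odds_scale(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float, float]:
    """Exponentiate a beta into an odds ratio with Wald CI and two-sided p.

    For binary outcomes analysed with linear models (UK-Biobank-style
    releases) the exponentiated beta is only approximately an odds ratio;
    the transform mirrors the field's reporting convention regardless.
    """
    if not (0 < level < 1):
        raise ValueError("confidence level must be in (0, 1)")
    if se <= 0:
        raise ValueError("se must be positive")
    z = float(stats.norm.ppf(0.5 + level / 2))
    pvalue = float(2 * stats.norm.sf(abs(beta / se)))
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se), pvalue


def weighted_median_point(ratios, weights) -> float:
    """Weighted median of per-SNP ratios.

    Sort ratios ascending, normalise weights, form standardised cumulative
    sums s_j = sum_{i<=j} w_i - w_j/2, and linearly interpolate the ratio at
    s = 0.5; if 0.5 falls outside [s_1, s_J] the extreme ratio is returned.
    Equal weights reduce this to the simple median of an interpolated order
    statistic.
    """
    ratios = np.asarray(ratios, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ratios.size == 0:
        raise ValueError("no ratios supplied")
    if ratios.shape != weights.shape:
        raise ValueError("ratios and weights length mismatch")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5, side="right")) - 1
    return float(r[k] + (r[k + 1] - r[k]) * (0.5 - s[k]) / (s[k + 1] - s[k]))


def sex_difference_test(est_a: MREstimate, est_b: MREstimate) -> tuple[float, float]:
    """Two-sample z test for a difference between stratum-specific estimates.

    z = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2), two-sided normal p.
    Exploratory: the strata come from overlapping pipelines and the test is
    not multiplicity-corrected downstream.
    """
    if est_a.method != est_b.method:
        raise ValueError(f"method mismatch: {est_a.method} vs {est_b.method}")
    z = (est_a.beta - est_b.beta) / math.sqrt(est_a.se**2 + est_b.se**2)
    return z, 2 * stats.norm.sf(abs(z))


class _PooledMREstimator(BaseEstimator):
    """Shared fit plumbing: odds-scale transform and MREstimate export."""

    method: str = ""

    def __init__(self, level: float = 0.95):
        self.level = level

    def _finalize(self, beta: float, se: float, n_snps: int, extras: dict | None = None) -> None:
        self.beta_ = float(beta)
        self.se_ = float(se)
        self.n_snps_ = int(n_snps)
        if se > 0:
            self.or_point_, self.ci_low_, self.ci_high_, self.pvalue_ = to_odds_scale(
                beta, se, self.level
            )
        else:  # degenerate noiseless limit
            self.or_point_ = math.exp(beta)
            self.ci_low_ = self.ci_high_ = self.or_point_
            self.pvalue_ = 1.0 if beta == 0 else 0.0
        self.extras_ = extras or {}

    def to_estimate(self) -> MREstimate:
        return MREstimate(
            method=self.method,
            beta=self.beta_,
            se=self.se_,
            or_point=self.or_point_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            pvalue=self.pvalue_,
            n_snps=self.n_snps_,
            extras=dict(self.extras_),
        )


class IVWEstimator(_PooledMREstimator):
    """Fixed-effect inverse-variance-weighted pooling of Wald ratios.

    With w_j = 1/se(theta_j)^2: beta = sum w_j theta_j / sum w_j and
    se = (sum w_j)^(-1/2). Assumes one common causal effect across SNPs
    and uncorrelated instruments.
    """

    method = "ivw_fixed"

    def __init__(self, se_mode: str = "full_delta", level: float = 0.95):
        self.se_mode = se_mode
        self.level = level

    def fit(self, instrument: HarmonizedInstrument) -> "IVWEstimator":
        _check_se_mode(self.se_mode)
        ratios, ses = wald_ratios(instrument, self.se_mode)
        w = 1.0 / ses**2
        beta = float(np.sum(w * ratios) / np.sum(w))
        se = float(np.sum(w) ** -0.5)
        self.ratios_, self.ratio_ses_ = ratios, ses
        self._finalize(beta, se, instrument.n_snps, {"se_mode": self.se_mode})
        return self


class SimpleMedianEstimator(_PooledMREstimator):
    """Simple median of Wald ratios with a parametric-bootstrap SE.

    Consistent when at least 50% of instruments are valid. Each bootstrap
    replicate redraws theta_j* ~ Normal(theta_j, se(theta_j)^2) and takes
    the median; the SE is the SD of the replicate medians.
    """

    method = "simple_median"

    def __init__(self, B: int = 5000, seed: int | None = None,
                 se_mode: str = "full_delta", level: float = 0.95):
        self.B = B
        self.seed = seed
        self.se_mode = se_mode
        self.level = level

    def _validate(self) -> None:
        _check_se_mode(self.se_mode)
        if self.B < 100:
            raise ValueError("bootstrap B must be at least 100")
        if self.seed is None:
            raise ValueError("a bootstrap seed is mandatory for reproducibility")

    def fit(self, instrument: HarmonizedInstrument) -> "SimpleMedianEstimator":
        self._validate()
        ratios, ses = wald_ratios(instrument, self.se_mode)
        beta = float(np.median(ratios))
        rng = np.random.default_rng(self.seed)
        # antithetic pairs (z, -z): lower bootstrap variance, and the SE is
        # exactly invariant under a global sign flip of the outcome betas
        half = (self.B + 1) // 2
        z = rng.standard_normal((half, ratios.size))
        draws = ratios + np.vstack([z, -z])[: self.B] * ses
        meds = np.median(draws, axis=1)
        se = float(np.std(meds, ddof=1))
        self._finalize(beta, se, instrument.n_snps,
                       {"B": self.B, "seed": self.seed, "se_mode": self.se_mode})
        return self


class WeightedMedianEstimator(_PooledMREstimator):
    """Inverse-variance weighted median with parametric-bootstrap SE.

    The point estimate is the weighted median of ratios with weights
    1/se(theta_j)^2. Bootstrap replicates redraw gamma_j* and Gamma_j* from
    their sampling distributions and recompute ratios, delta SEs and hence
    weights per replicate.
    """

    method = "weighted_median"

    def __init__(self, B: int = 5000, seed: int | None = None,
                 se_mode: str = "full_delta", level: float = 0.95):
        self.B = B
        self.seed = seed
        self.se_mode = se_mode
        self.level = level

    def fit(self, instrument: HarmonizedInstrument) -> "WeightedMedianEstimator":
        SimpleMedianEstimator._validate(self)  # same hyper-parameter checks
        ratios, ses = wald_ratios(instrument, self.se_mode)
        beta = weighted_median_point(ratios, 1.0 / ses**2)
        rng = np.random.default_rng(self.seed)
        J = instrument.n_snps
        # outcome-side noise is antithetic so the replicate set mirrors
        # exactly when every Gamma_j changes sign (SEs are sign-invariant)
        half = (self.B + 1) // 2
        zg = rng.standard_normal((half, J))
        zG = rng.standard_normal((half, J))
        g = instrument.gamma + np.vstack([zg, zg])[: self.B] * instrument.se_gamma
        G = instrument.Gamma + np.vstack([zG, -zG])[: self.B] * instrument.se_Gamma
        # guard the rare sign-crossing draw; exposure F >> 10 makes this negligible
        g = np.where(g == 0, np.finfo(float).tiny, g)
        r_star = G / g
        if self.se_mode == "first_order":
            se_star = instrument.se_Gamma / np.abs(g)
        else:
            se_star = np.sqrt(
                instrument.se_Gamma**2 / g**2 + G**2 * instrument.se_gamma**2 / g**4
            )
        reps = np.empty(self.B)
        for b in range(self.B):
            reps[b] = weighted_median_point(r_star[b], 1.0 / se_star[b] ** 2)
        se = float(np.std(reps, ddof=1))
        self._finalize(beta, se, J, {"B": self.B, "seed": self.seed, "se_mode": self.se_mode})
        return self


class EggerRegression(_PooledMREstimator):
    """Egger regression: WLS of Gamma_j on gamma_j with an intercept.

    Weights 1/se(Gamma_j)^2; the slope is the pleiotropy-adjusted causal
    estimate and the intercept estimates the average directional pleiotropic
    effect (zero under balanced or no pleiotropy, given InSIDE). Inference
    uses fixed-effect normal theory: the covariance is (X' W X)^{-1} without
    residual-variance scaling, matching the fixed-effect IVW convention.
    Requires J >= 3 and an instrument oriented so every gamma_j > 0; with
    J = 3 the fit has a single residual degree of freedom and is flagged
    ``low_df``.
    """

    method = "egger_slope"

    def __init__(self, level: float = 0.95):
        self.level = level

    def fit(self, instrument: HarmonizedInstrument) -> "EggerRegression":
        J = instrument.n_snps
        if J < 3:
            raise InsufficientInstrumentsError(
                f"Egger regression needs at least 3 SNPs, got {J}"
            )
        if np.any(instrument.gamma <= 0):
            raise ValueError(
                "Egger regression requires an exposure-increasing orientation "
                "(all gamma > 0); run orient_to_exposure_increasing first"
            )
        X = sm.add_constant(instrument.gamma)
        w = 1.0 / instrument.se_Gamma**2
        fit = sm.WLS(instrument.Gamma, X, weights=w).fit()
        cov = np.asarray(fit.normalized_cov_params)  # (X'WX)^{-1}, unscaled
        intercept, slope = fit.params
        se_int, se_slope = np.sqrt(np.diag(cov))
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(se_int)
        self.intercept_pvalue_ = float(2 * stats.norm.sf(abs(intercept / se_int)))
        self.low_df_ = J == 3
        self._finalize(slope, se_slope, J, {"low_df": self.low_df_})
        return self

    def to_result(self) -> EggerResult:
        return EggerResult(
            slope=self.to_estimate(),
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            intercept_pvalue=self.intercept_pvalue_,
            low_df=self.low_df_,
        )


# ---------------------------------------------------------------------------
# thin functional wrappers

def ivw_fixed(h: HarmonizedInstrument, se_mode: str = "full_delta") -> MREstimate:
    return IVWEstimator(se_mode=se_mode).fit(h).to_estimate()


def simple_median(h: HarmonizedInstrument, B: int = 5000, seed: int | None = None,
                  se_mode: str = "full_delta") -> MREstimate:
    return SimpleMedianEstimator(B=B, seed=seed, se_mode=se_mode).fit(h).to_estimate()


def weighted_median(h: HarmonizedInstrument, B: int = 5000, seed: int | None = None,
                    se_mode: str = "full_delta") -> MREstimate:
    return WeightedMedianEstimator(B=B, seed=seed, se_mode=se_mode).fit(h).to_estimate()


def egger(h: HarmonizedInstrument) -> EggerResult:
    return EggerRegression().fit(h).to_result()
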