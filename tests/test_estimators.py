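"""MR estimator correctness against independent oracles and identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ironmr.estimators import (
    EggerRegression,
    InsufficientInstrumentsError,
    IVWEstimator,
    MREstimate,
    SimpleMedianEstimator,
    WeightedMedianEstimator,
    egger,
    ivw_fixed,
    sex_difference_test,
    simple_median,
    to_odds_scale,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from ironmr.summary_data import DegenerateInstrumentError, HarmonizedInstrument


def _instrument(ratios, ses, gamma=None):
    """Instrument whose first-order Wald ratios/SEs are exactly as given."""
    ratios = np.asarray(ratios, dtype=float)
    ses = np.asarray(ses, dtype=float)
    gamma = np.ones_like(ratios) if gamma is None else np.asarray(gamma, float)
    return HarmonizedInstrument(
        [f"rs{i}" for i in range(len(ratios))],
        gamma,
        np.full_like(ratios, 1e-12),  # negligible exposure noise
        ratios * gamma,
        ses * np.abs(gamma),
    )


# ---------------------------------------------------------------------------
# Wald ratio

def test_wald_ratio_exposure_without_error():
    est = wald_ratio(1.0, 1e-15, 0.5, 0.1, "full_delta")
    assert est.ratio == 0.5
    assert est.se == pytest.approx(0.1)
    assert wald_ratio(1.0, 0.0, 0.5, 0.1, "first_order").se == pytest.approx(0.1)


def test_wald_ratio_zero_numerator():
    est = wald_ratio(0.4, 0.05, 0.0, 0.008)
    assert est.ratio == 0.0
    assert est.se == pytest.approx(0.008 / 0.4)


def test_wald_ratio_zero_gamma_raises():
    with pytest.raises(DegenerateInstrumentError, match="rs855791"):
        wald_ratio(0.0, 0.01, 0.01, 0.004, rsid="rs855791")


def test_wald_full_delta_matches_monte_carlo_sd():
    """Delta-method SE vs the empirical SD of the ratio of independent
    normal draws (strong-instrument regime)."""
    gamma, se_gamma, Gamma, se_Gamma = 0.33, 0.03, 0.02, 0.005
    est = wald_ratio(gamma, se_gamma, Gamma, se_Gamma, "full_delta")
    assert est.se == pytest.approx(0.01612, abs=5e-5)
    rng = np.random.default_rng(7)
    n = 10**6
    draws = (Gamma + se_Gamma * rng.standard_normal(n)) / (
        gamma + se_gamma * rng.standard_normal(n)
    )
    assert est.se == pytest.approx(np.std(draws), rel=0.02)


def test_wald_first_order_drops_exposure_term():
    full = wald_ratio(0.33, 0.03, 0.02, 0.005, "full_delta")
    first = wald_ratio(0.33, 0.03, 0.02, 0.005, "first_order")
    assert first.se == pytest.approx(0.005 / 0.33)
    assert full.se > first.se


# ---------------------------------------------------------------------------
# IVW

def test_ivw_single_snp_reduces_to_wald(three_snp_instrument):
    h = three_snp_instrument
    single = HarmonizedInstrument(h.rsids[:1], h.gamma[:1], h.se_gamma[:1],
                                  h.Gamma[:1], h.se_Gamma[:1])
    w = wald_ratio(h.gamma[0], h.se_gamma[0], h.Gamma[0], h.se_Gamma[0])
    est = ivw_fixed(single)
    assert est.beta == pytest.approx(w.ratio, abs=1e-15)
    assert est.se == pytest.approx(w.se, abs=1e-15)


def test_ivw_equal_weights_is_plain_mean():
    est = ivw_fixed(_instrument([0.1, 0.2, 0.3], [0.1, 0.1, 0.1]))
    assert est.beta == pytest.approx(0.2)
    assert est.se == pytest.approx(0.1 / np.sqrt(3))


def test_ivw_matches_brute_force_weighted_mean_on_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(100):
        J = rng.integers(3, 11)
        ratios = rng.normal(0, 0.5, J)
        ses = rng.uniform(0.01, 0.3, J)
        est = ivw_fixed(_instrument(ratios, ses))
        # brute-force loop, no vectorisation shared with the implementation
        num = den = 0.0
        for r, s in zip(ratios, ses):
            num += r / s**2
            den += 1 / s**2
        assert est.beta == pytest.approx(num / den, abs=1e-12)
        assert est.se == pytest.approx(den**-0.5, abs=1e-12)


def test_ivw_se_never_exceeds_smallest_wald_se(rng):
    for _ in range(50):
        J = rng.integers(1, 8)
        ses = rng.uniform(0.01, 0.5, J)
        est = ivw_fixed(_instrument(rng.normal(size=J), ses))
        assert est.se <= ses.min() + 1e-15


# ---------------------------------------------------------------------------
# medians

def test_simple_median_odd_count():
    est = simple_median(_instrument([3.0, 1.0, 2.0], [0.1, 0.2, 0.3]), B=200, seed=1)
    assert est.beta == 2.0


def test_simple_median_degenerate_tight_ses():
    est = simple_median(_instrument([0.7, 0.7, 0.7], [1e-9, 1e-9, 1e-9]), B=200, seed=1)
    assert est.beta == pytest.approx(0.7)
    assert est.se < 1e-8


def test_median_bootstrap_B_and_seed_validation(three_snp_instrument):
    with pytest.raises(ValueError, match="at least 100"):
        simple_median(three_snp_instrument, B=50, seed=1)
    with pytest.raises(ValueError, match="seed"):
        simple_median(three_snp_instrument, B=500)


def test_simple_median_se_matches_independent_bootstrap():
    """Seeded B=5000 SE within 5% of a from-scratch 50,000-replicate
    bootstrap written directly against the resampling definition."""
    ratios = np.array([0.01, 0.035, 0.02])
    ses = np.array([0.008, 0.012, 0.006])
    est = simple_median(_instrument(ratios, ses), B=5000, seed=3)
    rng = np.random.default_rng(987654)
    meds = [np.median(rng.normal(ratios, ses)) for _ in range(50_000)]
    assert est.se == pytest.approx(np.std(meds, ddof=1), rel=0.05)


def test_bootstrap_reproducibility(three_snp_instrument):
    a = simple_median(three_snp_instrument, B=1000, seed=42)
    b = simple_median(three_snp_instrument, B=1000, seed=42)
    assert a == b
    c = weighted_median(three_snp_instrument, B=1000, seed=42)
    d = weighted_median(three_snp_instrument, B=1000, seed=42)
    assert c == d
    assert simple_median(three_snp_instrument, B=1000, seed=43).se != a.se


def test_weighted_median_point_hand_worked_case():
    # s = (0.2, 0.55, 0.8, 0.95); 0.5 interpolates between ratios 1 and 2
    value = weighted_median_point([1, 2, 3, 10], [0.4, 0.3, 0.2, 0.1])
    assert value == pytest.approx(1 + 0.3 / 0.35)


def test_weighted_median_point_matches_cdf_inversion_on_grid():
    """The estimator is the 0.5 point of the piecewise-linear weighted CDF
    through (ratio_j, s_j); recover it by brute-force grid search on
    |CDF(x) - 0.5| and compare."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        J = int(rng.integers(2, 9))
        r = np.sort(rng.normal(0, 1, J))
        w = rng.uniform(0.1, 1, J)
        point = weighted_median_point(r, w)
        wn = w / w.sum()
        s = np.cumsum(wn) - wn / 2
        grid = np.linspace(r.min(), r.max(), 200_001)
        cdf = np.interp(grid, r, s)
        best = grid[np.argmin(np.abs(cdf - 0.5))]
        step = (r.max() - r.min()) / 200_000
        assert point == pytest.approx(best, abs=2 * step)


def test_weighted_median_point_identity_and_equal_weights():
    assert weighted_median_point([0.37], [2.0]) == 0.37
    assert weighted_median_point([1, 2, 3], [1, 1, 1]) == 2.0
    with pytest.raises(ValueError):
        weighted_median_point([], [])


def test_weighted_median_equal_ses_reduces_to_simple(three_snp_instrument):
    h = _instrument([0.01, 0.03, 0.02], [0.01, 0.01, 0.01])
    wm = weighted_median(h, B=200, seed=1)
    sm = simple_median(h, B=200, seed=1)
    assert wm.beta == pytest.approx(sm.beta)


def test_weighted_median_dominant_weight_limit():
    h = _instrument([0.01, 0.05, 0.09], [1e-7, 0.05, 0.05])
    assert weighted_median(h, B=200, seed=1).beta == pytest.approx(0.01, abs=1e-6)


def test_weighted_median_stays_between_valid_ratios_under_pleiotropy(rng):
    """With 4 of 10 SNPs strongly directionally pleiotropic, the point
    estimate stays inside the valid SNPs' ratio range (100 replicates)."""
    theta = 0.05
    inside = 0
    for _ in range(100):
        gamma = rng.uniform(0.2, 0.4, 10)
        se_g = gamma / 40
        se_G = np.full(10, 0.002)
        alpha = np.zeros(10)
        alpha[:4] = 0.02  # pleiotropy on the outcome scale
        g_hat = rng.normal(gamma, se_g)
        G_hat = rng.normal(theta * gamma + alpha, se_G)
        h = HarmonizedInstrument([f"rs{i}" for i in range(10)], g_hat, se_g, G_hat, se_G)
        est = weighted_median(h, B=100, seed=9)
        valid = (G_hat / g_hat)[4:]
        if valid.min() <= est.beta <= valid.max():
            inside += 1
    assert inside >= 95


@settings(max_examples=60, deadline=None)
@given(
    st.lists(st.tuples(st.floats(-3, 3), st.floats(0.01, 1)), min_size=1, max_size=12)
)
def test_weighted_median_within_ratio_range(pairs):
    ratios = [p[0] for p in pairs]
    weights = [p[1] for p in pairs]
    value = weighted_median_point(ratios, weights)
    assert min(ratios) - 1e-12 <= value <= max(ratios) + 1e-12


# ---------------------------------------------------------------------------
# Egger

def test_egger_recovers_exact_line():
    gamma = np.array([0.1, 0.2, 0.3, 0.4])
    h = HarmonizedInstrument(["a", "b", "c", "d"], gamma, np.full(4, 0.01),
                             0.01 + 0.1 * gamma, np.array([0.004, 0.005, 0.006, 0.007]))
    res = egger(h)
    assert res.intercept == pytest.approx(0.01, abs=1e-12)
    assert res.slope.beta == pytest.approx(0.1, abs=1e-12)


def test_egger_matches_normal_equations_oracle(rng):
    """WLS slope/intercept and fixed-effect SEs vs an explicit
    (X'WX)^{-1}X'Wy solution."""
    for _ in range(100):
        J = rng.integers(3, 11)
        gamma = rng.uniform(0.05, 0.5, J)
        se_G = rng.uniform(0.002, 0.02, J)
        Gamma = rng.normal(0.003 + 0.08 * gamma, se_G)
        h = HarmonizedInstrument([f"rs{i}" for i in range(J)], gamma,
                                 np.full(J, 0.01), Gamma, se_G)
        res = egger(h)
        X = np.column_stack([np.ones(J), gamma])
        W = np.diag(1 / se_G**2)
        XtWX_inv = np.linalg.inv(X.T @ W @ X)
        coef = XtWX_inv @ X.T @ W @ Gamma
        ses = np.sqrt(np.diag(XtWX_inv))
        assert res.intercept == pytest.approx(coef[0], abs=1e-10)
        assert res.slope.beta == pytest.approx(coef[1], abs=1e-10)
        assert res.intercept_se == pytest.approx(ses[0], abs=1e-10)
        assert res.slope.se == pytest.approx(ses[1], abs=1e-10)


def test_egger_requires_three_snps():
    h = HarmonizedInstrument(["a", "b"], [0.1, 0.2], [0.01, 0.01],
                             [0.01, 0.02], [0.004, 0.004])
    with pytest.raises(InsufficientInstrumentsError):
        egger(h)


def test_egger_requires_orientation():
    h = HarmonizedInstrument(["a", "b", "c"], [0.1, -0.2, 0.3], [0.01] * 3,
                             [0.01, 0.02, 0.03], [0.004] * 3)
    with pytest.raises(ValueError, match="orient"):
        egger(h)


def test_egger_low_df_flag(three_snp_instrument):
    assert egger(three_snp_instrument).low_df is True


# ---------------------------------------------------------------------------
# odds scale, sex difference, cross-estimator identities

def test_to_odds_scale_null():
    or_point, lo, hi, p = to_odds_scale(0.0, 0.1)
    assert or_point == 1.0 and p == pytest.approx(1.0)
    assert lo < 1 < hi


def test_to_odds_scale_closed_form():
    or_point, lo, hi, p = to_odds_scale(0.1, 0.05, 0.95)
    assert or_point == pytest.approx(np.exp(0.1))
    assert lo == pytest.approx(1.0018, abs=5e-4)
    assert hi == pytest.approx(1.2193, abs=5e-4)
    assert p == pytest.approx(2 * stats.norm.sf(2))


def test_to_odds_scale_ci_log_symmetry(rng):
    for _ in range(20):
        beta, se = rng.normal(0, 0.3), rng.uniform(0.01, 0.5)
        _, lo, hi, _ = to_odds_scale(beta, se)
        assert lo * hi == pytest.approx(np.exp(2 * beta), rel=1e-12)


def test_to_odds_scale_invalid_level():
    with pytest.raises(ValueError):
        to_odds_scale(0.1, 0.05, level=1.5)


def _mre(method, beta, se):
    from ironmr.estimators import to_odds_scale as t

    or_point, lo, hi, p = t(beta, se)
    return MREstimate(method, beta, se, or_point, lo, hi, p, 3)


def test_sex_difference_identical_estimates():
    est = _mre("ivw_fixed", 0.1, 0.05)
    z, p = sex_difference_test(est, est)
    assert z == 0 and p == pytest.approx(1.0)


def test_sex_difference_closed_form_and_antisymmetry():
    m = _mre("ivw_fixed", 0.2, 0.1)
    f = _mre("ivw_fixed", 0.0, 0.1)
    z, p = sex_difference_test(m, f)
    assert z == pytest.approx(np.sqrt(2))
    assert p == pytest.approx(2 * stats.norm.sf(np.sqrt(2)), rel=1e-12)
    z2, p2 = sex_difference_test(f, m)
    assert z2 == pytest.approx(-z) and p2 == pytest.approx(p)


def test_sex_difference_method_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        sex_difference_test(_mre("ivw_fixed", 0.1, 0.1), _mre("egger_slope", 0.1, 0.1))


def test_all_point_estimators_collapse_at_single_snp():
    h = HarmonizedInstrument(["rs1"], [0.33], [0.009], [0.002], [0.0007])
    w = wald_ratio(0.33, 0.009, 0.002, 0.0007)
    assert ivw_fixed(h).beta == pytest.approx(w.ratio, abs=1e-15)
    assert simple_median(h, B=200, seed=1).beta == pytest.approx(w.ratio, abs=1e-15)
    assert weighted_median(h, B=200, seed=1).beta == pytest.approx(w.ratio, abs=1e-15)


def test_sign_equivariance(three_snp_instrument):
    """Negating every outcome beta negates each estimator's beta and leaves
    SEs and p-values unchanged."""
    h = three_snp_instrument
    neg = HarmonizedInstrument(h.rsids, h.gamma, h.se_gamma, -h.Gamma, h.se_Gamma)
    for fit, fit_neg in [
        (ivw_fixed(h), ivw_fixed(neg)),
        (simple_median(h, B=500, seed=2), simple_median(neg, B=500, seed=2)),
        (weighted_median(h, B=500, seed=2), weighted_median(neg, B=500, seed=2)),
        (egger(h).slope, egger(neg).slope),
    ]:
        assert fit_neg.beta == pytest.approx(-fit.beta, abs=1e-12)
        assert fit_neg.se == pytest.approx(fit.se, rel=1e-9)
        assert fit_neg.pvalue == pytest.approx(fit.pvalue, rel=1e-9)


def test_estimator_sklearn_interface(three_snp_instrument):
    """get_params/set_params round-trip and fitted attributes."""
    est = IVWEstimator(se_mode="first_order")
    assert est.get_params()["se_mode"] == "first_order"
    est.set_params(se_mode="full_delta").fit(three_snp_instrument)
    assert hasattr(est, "beta_") and hasattr(est, "pvalue_")
    assert est.to_estimate().method == "ivw_fixed"
    cloned = EggerRegression(level=0.9)
    assert cloned.get_params() == {"level": 0.9}
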