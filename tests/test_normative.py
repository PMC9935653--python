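"""Quadratic normative model, outlier handling, and the detection rule."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from thalseg import (
    CohortParams,
    NormativeThalamusModel,
    cohort_detection_rate,
    fit_normative,
    make_cohort,
    quadratic_thalv,
)
from thalseg.normative import design_matrix
from thalseg.phantom import DEFAULT_COEFFS


def _cohort(n=400, seed=0, **kw):
    defaults = dict(n_subjects=n, sigma_inter=0.0, sigma_intra=0.0, seed=seed)
    defaults.update(kw)
    return make_cohort(CohortParams(**defaults))


def test_noiseless_cohort_recovers_generating_coefficients():
    df = _cohort(n=200, sigma_between=0.0, seed=1)
    model = fit_normative(df)
    np.testing.assert_allclose(model.coef_, DEFAULT_COEFFS, rtol=1e-6)
    assert model.sigma_ == pytest.approx(0.0, abs=1e-9)
    # (with zero residual spread the Tukey fences collapse to numerical
    # noise, so the outlier count itself is not meaningful here)
    assert model.n_used_ + model.n_outliers_ == len(df)


def test_residuals_zero_on_model_surface():
    df = _cohort(n=100, sigma_between=0.0, seed=2)
    model = fit_normative(df)
    res = model.residuals(df)
    np.testing.assert_allclose(res, 0.0, atol=1e-8)


def test_res_thalv_direct_substitution():
    """All-zero coefficients except f = 10; THALV 12 -> residual 2.0 mL."""
    model = NormativeThalamusModel()
    model.coef_ = np.array([0, 0, 0, 0, 0, 10.0])
    model.sigma_ = 1.0
    model.n_used_, model.n_outliers_ = 0, 0
    model.fence_bounds_ = (0.0, 0.0)
    assert model.res_thalv(tiv=1400.0, age=50.0, thalv=12.0) == pytest.approx(2.0)


def test_res_thalv_is_pure_function_of_model_and_record():
    df = _cohort(n=100, seed=3)
    model = fit_normative(df)
    r1 = model.res_thalv(1400.0, 55.0, 13.0)
    fit_normative(_cohort(n=100, seed=9))  # unrelated fit must not interfere
    r2 = model.res_thalv(1400.0, 55.0, 13.0)
    assert r1 == r2


def test_two_step_fit_flags_injected_outlier():
    df = _cohort(n=300, sigma_between=0.2, seed=4)
    clean_model = fit_normative(df)
    spoiled = df.copy()
    iqr = np.subtract(*np.percentile(clean_model.residuals(df), [75, 25]))
    spoiled.loc[0, "thalv_ml"] += 10 * abs(iqr) + 5.0
    model = fit_normative(spoiled)
    assert model.n_outliers_ >= 1
    assert model.outlier_mask_[0]
    # the quadratic design is collinear, so compare fitted surfaces rather
    # than raw coefficients: the spoiled fit must track the clean one
    diff = model.predict(df) - clean_model.predict(df)
    assert np.abs(diff).max() < 0.25 * df["thalv_ml"].std()


def test_fit2_equals_ols_on_retained_subjects():
    """Second fit equals a direct normal-equations solve over retained rows."""
    df = _cohort(n=80, sigma_between=0.5, seed=5)
    model = fit_normative(df)
    keep = ~model.outlier_mask_
    A = design_matrix(df["tiv_ml"][keep], df["age_years"][keep])
    yv = df["thalv_ml"][keep].to_numpy()
    coef_oracle = np.linalg.solve(A.T @ A, A.T @ yv)
    np.testing.assert_allclose(model.coef_, coef_oracle, rtol=1e-5, atol=1e-9)


def test_rank_deficient_design_raises_named_error():
    df = _cohort(n=50, seed=6)
    df["age_years"] = 50.0  # constant age: age^2 / age columns collapse
    with pytest.raises(np.linalg.LinAlgError):
        fit_normative(df)


def test_minimum_cohort_size_enforced():
    df = _cohort(n=50, seed=7).head(11)
    with pytest.raises(ValueError, match="12"):
        fit_normative(df)


def test_normal_interval_from_sigma():
    model = NormativeThalamusModel()
    model.coef_ = np.zeros(6)
    model.sigma_ = 0.88
    model.n_used_, model.n_outliers_ = 1, 0
    model.fence_bounds_ = (0.0, 0.0)
    lo, hi = model.normal_interval()
    assert lo == pytest.approx(-1.7248)
    assert hi == pytest.approx(+1.7248)
    model.sigma_ = 0.0
    assert model.normal_interval() == (0.0, 0.0)


@pytest.mark.parametrize(
    "res,sigma_scanner,expected",
    [
        (-2.5, 0.28, True),  # -2.5 + 0.5488 = -1.9512 < -1.7248
        (-2.0, 0.28, False),  # -1.4512 > -1.7248
    ],
)
def test_detection_rule_worked_examples(res, sigma_scanner, expected):
    model = NormativeThalamusModel()
    model.coef_ = np.zeros(6)
    model.sigma_ = 0.88
    model.n_used_, model.n_outliers_ = 1, 0
    model.fence_bounds_ = (0.0, 0.0)
    out = model.detect_reduced(res, sigma_scanner)
    assert out.reduced is expected
    assert out.ci_half_width == pytest.approx(1.96 * sigma_scanner)
    assert out.normal_lower_bound == pytest.approx(-1.7248)


def test_detection_boundary_is_strict():
    model = NormativeThalamusModel()
    model.coef_ = np.zeros(6)
    model.sigma_ = 0.88
    model.n_used_, model.n_outliers_ = 1, 0
    model.fence_bounds_ = (0.0, 0.0)
    exactly_at_bound = -1.96 * 0.88
    assert model.detect_reduced(exactly_at_bound, 0.0).reduced is False


def test_detection_monotonicity():
    """Lower residuals never flip reduced -> not reduced; smaller scanner
    noise never flips reduced -> not reduced."""
    model = NormativeThalamusModel()
    model.coef_ = np.zeros(6)
    model.sigma_ = 0.88
    model.n_used_, model.n_outliers_ = 1, 0
    model.fence_bounds_ = (0.0, 0.0)
    rng = np.random.default_rng(8)
    for _ in range(200):
        r = rng.uniform(-4, 1)
        s = rng.uniform(0, 1)
        if model.detect_reduced(r, s).reduced:
            assert model.detect_reduced(r - rng.uniform(0, 2), s).reduced
            assert model.detect_reduced(r, s * rng.random()).reduced


def test_two_sample_rule_more_conservative_than_one_sample():
    model = NormativeThalamusModel()
    model.coef_ = np.zeros(6)
    model.sigma_ = 0.88
    model.n_used_, model.n_outliers_ = 1, 0
    model.fence_bounds_ = (0.0, 0.0)
    rng = np.random.default_rng(9)
    for r in rng.uniform(-4, 0, 100):
        two = model.detect_reduced(r, 0.28).reduced
        one = model.detect_reduced(r, 0.0).reduced
        if two:
            assert one  # two-sample flags only a subset


def test_detection_rate_zero_on_model_surface():
    df = _cohort(n=100, sigma_between=0.5, seed=10)
    model = fit_normative(df)
    on_surface = df.copy()
    on_surface["thalv_ml"] = model.predict(df)
    assert cohort_detection_rate(on_surface, model, 0.28) == 0.0


def test_detection_rate_one_for_extreme_shift():
    df = _cohort(n=100, sigma_between=0.5, seed=11)
    model = fit_normative(df)
    shifted = df.copy()
    shifted["thalv_ml"] = model.predict(df) - 10 * model.sigma_
    assert cohort_detection_rate(shifted, model, 0.28) == 1.0


def test_healthy_detection_rate_matches_gaussian_tail():
    """Unshifted Gaussian cohorts: rate ~ P(Z < -1.96 - 1.96*s/sigma)."""
    sigma, s = 0.88, 0.28
    model = NormativeThalamusModel()
    model.coef_ = np.array(DEFAULT_COEFFS)
    model.sigma_ = sigma
    model.n_used_, model.n_outliers_ = 1, 0
    model.fence_bounds_ = (0.0, 0.0)
    rates = []
    for seed in range(30):
        df = _cohort(n=800, sigma_between=sigma, seed=100 + seed)
        rates.append(cohort_detection_rate(df, model, s))
    expected = norm.cdf(-1.96 - 1.96 * s / sigma)
    assert np.mean(rates) == pytest.approx(expected, rel=0.25, abs=2e-3)


def test_healthy_specificity_bounded():
    """On generator-faithful healthy cohorts the two-sample rule flags at
    most ~2.5% (one-sided tail), averaged over replicates."""
    rates = []
    for seed in range(100):
        df = _cohort(n=200, sigma_between=0.88, seed=200 + seed)
        model = fit_normative(df)
        rates.append(cohort_detection_rate(df, model, 0.28))
    assert np.mean(rates) <= 0.025


def test_model_dict_round_trip():
    df = _cohort(n=100, seed=12)
    model = fit_normative(df)
    back = NormativeThalamusModel.from_dict(model.to_dict())
    np.testing.assert_allclose(back.coef_, model.coef_)
    assert back.sigma_ == model.sigma_
    r = model.residuals(df)
    np.testing.assert_allclose(back.residuals(df), r)
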