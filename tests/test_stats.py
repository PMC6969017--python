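"""Reproducibility, distribution and screened-regression statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from csdi.simulate import ALL_COVARIATES, CohortParams, make_cohort
from csdi.stats import (
    bland_altman,
    icc_absolute_agreement,
    normality_tests,
    one_sample_t,
    reproducibility_report,
    screened_regression,
)


def icc_a1_oracle(r: np.ndarray) -> float:
    """Brute-force ICC(A,1) from explicit two-way ANOVA sums of squares."""
    n, k = r.shape
    grand = r.mean()
    ss_rows = k * ((r.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((r.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((r - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    )


# ---------------------------------------------------------------------------
# ICC


def test_icc_identical_observers_is_one(rng):
    a = rng.normal(300, 60, size=50)
    res = icc_absolute_agreement(np.column_stack([a, a]))
    assert res.icc == pytest.approx(1.0, abs=1e-9)


def test_icc_penalizes_constant_offset(rng):
    a = rng.normal(300, 60, size=50)
    res = icc_absolute_agreement(np.column_stack([a, a + 30.0]))
    assert res.icc < 1.0
    assert res.icc > 0.5  # still strongly correlated


def test_icc_matches_sums_of_squares_oracle(rng):
    for _ in range(50):
        r = rng.normal(300, 50, size=(10, 2)) + rng.normal(0, 10, size=(10, 2))
        res = icc_absolute_agreement(r)
        assert res.icc == pytest.approx(icc_a1_oracle(r), abs=1e-9)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    r=hnp.arrays(
        float,
        st.tuples(st.integers(3, 12), st.just(2)),
        elements=st.floats(0, 500, allow_nan=False, width=32),
    )
)
def test_icc_oracle_property(r):
    if np.var(r) == 0 or not np.isfinite(icc_a1_oracle(r)):
        return
    res = icc_absolute_agreement(r)
    assert res.icc == pytest.approx(icc_a1_oracle(r), abs=1e-6)


def test_icc_affine_invariance(rng):
    r = rng.normal(300, 50, size=(20, 2))
    a = icc_absolute_agreement(r).icc
    b = icc_absolute_agreement(2.5 * r - 40.0).icc
    assert b == pytest.approx(a, abs=1e-9)


def test_icc_degenerate_inputs_rejected(rng):
    with pytest.raises(ValueError, match="zero total variance"):
        icc_absolute_agreement(np.full((10, 2), 7.0))
    with pytest.raises(ValueError, match="at least 3"):
        icc_absolute_agreement(np.array([[1.0, 2.0], [3.0, 4.0]]))
    bad = rng.normal(size=(10, 2))
    bad[3, 1] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        icc_absolute_agreement(bad)


# ---------------------------------------------------------------------------
# Bland-Altman


def test_bland_altman_identical_pairs():
    a = np.linspace(200, 400, 20)
    res = bland_altman(np.column_stack([a, a]))
    assert res.mean_diff == 0 and res.cr == 0
    assert res.loa_low == res.loa_high == 0


def test_bland_altman_constant_difference():
    a = np.linspace(200, 400, 20)
    res = bland_altman(np.column_stack([a, a - 12.0]))
    assert res.mean_diff == pytest.approx(12.0)
    assert res.cr == pytest.approx(0.0, abs=1e-9)
    assert res.loa_low == pytest.approx(res.loa_high)


def test_bland_altman_cr_monte_carlo(rng):
    """d ~ N(0, 9^2), n = 363 -> CR concentrates near 1.96*9 = 17.64 um,
    inside the published 17.47-24.28 um reproducibility band."""
    crs = []
    for _ in range(300):
        d = rng.normal(0, 9.0, size=363)
        a = rng.normal(300, 80, size=363)
        crs.append(bland_altman(np.column_stack([a, a - d])).cr)
    assert np.mean(crs) == pytest.approx(17.64, abs=0.2)
    assert 17.47 <= np.mean(crs) <= 24.28


def test_bland_altman_needs_two_pairs():
    with pytest.raises(ValueError, match="at least 2"):
        bland_altman(np.array([[1.0, 2.0]]))


def test_reproducibility_report_shape(rng):
    rows = []
    for subj in range(12):
        base = rng.normal(300, 70)
        for obs in ("A", "B"):
            for sub in ("C", "SI", "SO"):
                rows.append(
                    {
                        "subject": f"s{subj}",
                        "observer": obs,
                        "subfield": sub,
                        "mean_thickness_um": base + rng.normal(0, 8),
                    }
                )
    rep = reproducibility_report(pd.DataFrame(rows))
    assert list(rep["subfield"]) == ["C", "SI", "SO"]
    assert ((rep["loa_low_um"] <= rep["mean_diff_um"]) & (rep["mean_diff_um"] <= rep["loa_high_um"])).all()
    assert (rep["cr_um"] >= 0).all()


# ---------------------------------------------------------------------------
# one-sample t


def test_t_symmetric_sample_is_zero():
    res = one_sample_t(np.array([-1.0, 0.0, 1.0]), test_value=0.0)
    assert res.t == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_t_matches_closed_form(rng):
    x = rng.normal(0.2, 1.0, size=30)
    res = one_sample_t(x)
    expected_t = x.mean() / (x.std(ddof=1) / math.sqrt(len(x)))
    assert res.t == pytest.approx(expected_t, rel=1e-12)


def test_t_zero_variance_rejected():
    with pytest.raises(ValueError, match="zero-variance"):
        one_sample_t(np.full(10, 3.0))


# ---------------------------------------------------------------------------
# normality


def test_lilliefors_statistic_matches_statsmodels(rng):
    from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

    x = rng.normal(10, 2, size=100)
    res = normality_tests(x, seed=0, n_mc=2000)
    sm_stat, sm_p = sm_lilliefors(x, dist="norm", pvalmethod="table")
    assert res.ks_stat == pytest.approx(sm_stat, abs=1e-10)
    assert res.ks_p == pytest.approx(sm_p, abs=0.1)


def test_lilliefors_null_calibration(rng):
    """Under normal data the Lilliefors p is uniform: ~5% rejections at 0.05."""
    rejections = 0
    pvals = []
    for i in range(150):
        x = rng.normal(0.1, 0.2, size=150)
        res = normality_tests(x, seed=i, n_mc=1000)
        pvals.append(res.ks_p)
        rejections += res.ks_p < 0.05
    assert 0.005 <= rejections / 150 <= 0.11
    assert 0.38 <= np.mean(pvals) <= 0.62


def test_normality_power_against_lognormal(rng):
    """A strongly skewed sample of n = 363 is rejected by both tests."""
    hits_ks = hits_sw = 0
    for i in range(40):
        x = np.exp(rng.normal(0, 0.8, size=363))
        res = normality_tests(x, seed=i, n_mc=1000)
        hits_ks += res.ks_p < 0.01
        hits_sw += res.shapiro_p < 0.01
    assert hits_ks >= 38
    assert hits_sw >= 38


def test_normality_degenerate_inputs():
    with pytest.raises(ValueError, match="constant"):
        normality_tests(np.full(10, 1.0))
    with pytest.raises(ValueError, match="n >= 4"):
        normality_tests(np.array([1.0, 2.0, 3.0]))


def test_plain_ks_available_behind_flag(rng):
    import scipy.stats

    x = rng.normal(5, 1, size=80)
    res = normality_tests(x, lilliefors=False)
    expected = scipy.stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue
    assert res.ks_p == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# screened regression


def test_exact_linear_single_covariate(rng):
    x = rng.normal(0, 1, size=100)
    df = pd.DataFrame({"subject": range(100), "x": x, "y": 3.0 * x})
    rep = screened_regression(df, "y", covariates=["x"])
    row = rep.table.iloc[0]
    assert row["uni_beta"] == pytest.approx(1.0, abs=1e-9)
    assert row["screened"]
    assert row["multi_beta"] == pytest.approx(1.0, abs=1e-9)
    assert row["multi_p"] < 1e-12


def test_screen_membership_rule(rng):
    """A covariate has a multivariable beta iff its univariate p < 0.10."""
    df = make_cohort(CohortParams(n_subjects=200, seed=21))
    rep = screened_regression(
        df, "horizontal_csdi", covariates=list(ALL_COVARIATES)
    )
    for row in rep.table.itertuples(index=False):
        assert row.screened == (row.uni_p < 0.10)
        assert row.screened == np.isfinite(row.multi_beta)


def test_standardized_beta_affine_invariance(rng):
    x = rng.normal(10, 3, size=150)
    y = 0.4 * x + rng.normal(0, 2, size=150)
    df1 = pd.DataFrame({"x": x, "y": y})
    df2 = pd.DataFrame({"x": 100 * x - 7, "y": 0.01 * y + 3})
    b1 = screened_regression(df1, "y", covariates=["x"]).table["uni_beta"][0]
    b2 = screened_regression(df2, "y", covariates=["x"]).table["uni_beta"][0]
    assert b1 == pytest.approx(b2, rel=1e-9)


def test_null_covariates_screened_at_nominal_rate():
    """With all links zero, ~10% of pure-noise covariates pass the screen."""
    flags = []
    for seed in range(100):
        df = make_cohort(
            CohortParams(
                n_subjects=120, seed=seed, vertical_links={}, horizontal_links={}
            )
        )
        for outcome in ("vertical_csdi", "horizontal_csdi"):
            rep = screened_regression(df, outcome, covariates=list(ALL_COVARIATES))
            flags.extend(rep.table["screened"].tolist())
    rate = np.mean(flags)
    assert rate == pytest.approx(0.10, abs=0.03)


def test_parameter_recovery_axial_length():
    """Outcome built as 0.215 z(axial length) + noise: the multivariable
    standardized beta recovers 0.215 on average across replicates."""
    betas = []
    for seed in range(50):
        df = make_cohort(
            CohortParams(
                n_subjects=363,
                seed=seed,
                vertical_links={},
                horizontal_links={"axial_length_mm": 0.215},
            )
        )
        rep = screened_regression(
            df, "horizontal_csdi", covariates=list(ALL_COVARIATES)
        )
        betas.append(rep.reported_beta("axial_length_mm"))
    assert np.mean(betas) == pytest.approx(0.215, abs=0.06)


def test_collinear_screened_set_rejected(rng):
    x = rng.normal(0, 1, size=200)
    df = pd.DataFrame({"x1": x, "x2": x * 2.0, "y": x + rng.normal(0, 0.3, 200)})
    with pytest.raises(ValueError, match="collinear"):
        screened_regression(df, "y", covariates=["x1", "x2"])


def test_few_cases_warns(rng):
    df = pd.DataFrame(
        {
            "x1": rng.normal(size=25),
            "x2": rng.normal(size=25),
            "x3": rng.normal(size=25),
            "y": rng.normal(size=25),
        }
    )
    with pytest.warns(RuntimeWarning, match="complete cases"):
        screened_regression(df, "y", covariates=["x1", "x2", "x3"])
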