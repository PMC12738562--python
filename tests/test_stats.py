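"""Statistical layer tests, each against an independent oracle:
scipy for the t-test, exhaustive pair counting / scipy for Kendall,
normal equations for the ANCOVA, permutations for small-sample ordering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from guancest import stats as st


# -------------------------------------------------------------------- t-test

def test_identical_samples_give_t0_p1():
    a = np.array([1.0, 2.0, 3.0])
    r = st.two_sample_ttest(a, a.copy())
    assert r.t_stat == 0.0 and r.p_two_sided == 1.0
    assert r.df == 4


def test_matches_scipy_student_and_welch():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.normal(0, 1, rng.integers(3, 30))
        b = rng.normal(0.3, 1.5, rng.integers(3, 30))
        mine = st.two_sample_ttest(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert mine.t_stat == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p_two_sided == pytest.approx(ref.pvalue, rel=1e-12)
        mine_w = st.two_sample_ttest(a, b, welch=True)
        ref_w = sps.ttest_ind(a, b, equal_var=False)
        assert mine_w.p_two_sided == pytest.approx(ref_w.pvalue, rel=1e-12)


def test_group_swap_negates_t_preserves_p():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
    r1, r2 = st.two_sample_ttest(a, b), st.two_sample_ttest(b, a)
    assert r1.t_stat == pytest.approx(-r2.t_stat)
    assert r1.p_two_sided == pytest.approx(r2.p_two_sided)


def test_summary_reconstructed_caudate_comparison_is_significant():
    """Samples rebuilt to exactly the reported caudate summaries
    (1.82 +/- 0.16, n=24 vs 1.67 +/- 0.26, n=25) give p just around 0.02."""
    def with_moments(mean, sd, n, seed):
        x = np.random.default_rng(seed).normal(0, 1, n)
        x = (x - x.mean()) / x.std(ddof=1)
        return mean + sd * x
    hc = with_moments(1.82, 0.16, 24, 0)
    pwpd = with_moments(1.67, 0.26, 25, 1)
    r = st.two_sample_ttest(hc, pwpd)
    assert r.p_two_sided < 0.05
    assert 0.005 < r.p_two_sided < 0.05


def test_small_sample_ordering_matches_permutation_oracle():
    """On tiny fixed vectors, the |t|-based ordering of 'more extreme'
    group splits agrees with exhaustive permutation."""
    pooled = np.array([0.1, 0.5, 0.9, 1.4, 2.0, 2.2, 3.1, 3.3])
    observed = st.two_sample_ttest(pooled[:4], pooled[4:]).t_stat
    more_extreme = 0
    total = 0
    for idx in itertools.combinations(range(8), 4):
        a = pooled[list(idx)]
        b = pooled[[i for i in range(8) if i not in idx]]
        t = st.two_sample_ttest(a, b).t_stat
        total += 1
        if abs(t) >= abs(observed) - 1e-12:
            more_extreme += 1
    perm_p = more_extreme / total
    # the parametric p must classify this split as extreme exactly when the
    # permutation distribution does
    r = st.two_sample_ttest(pooled[:4], pooled[4:])
    assert (r.p_two_sided < 0.05) == (perm_p < 0.05)


def test_type_one_error_calibrated_under_null():
    """2000 null replicates at the study sizes: rejection rate within
    binomial 3 SE of 0.05."""
    rng = np.random.default_rng(99)
    n1, n2, reps = 25, 24, 2000
    a = rng.normal(0, 1, (reps, n1))
    b = rng.normal(0, 1, (reps, n2))
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(np.abs(t), n1 + n2 - 2)
    # cross-check the vectorized null against the scalar implementation
    r0 = st.two_sample_ttest(a[0], b[0])
    assert r0.p_two_sided == pytest.approx(p[0], rel=1e-12)
    rate = (p < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) < 3 * se


def test_degenerate_sizes_rejected():
    with pytest.raises(ValueError):
        st.two_sample_ttest([1.0], [1.0, 2.0])


# ------------------------------------------------------------------- Kendall

def test_perfect_monotone_gives_tau_one():
    x = np.arange(10.0)
    r = st.kendall_tau_b(x, x ** 2 + 1)
    assert r.tau_b == 1.0


def test_hand_counted_tied_example():
    # x=(1,2,3,4), y=(1,1,2,2): pairs C=4, D=0, ties in y only = 2
    r = st.kendall_tau_b([1, 2, 3, 4], [1, 1, 2, 2])
    assert (r.concordant, r.discordant) == (4, 0)
    assert r.ties_y == 2 and r.ties_x == 0
    assert r.tau_b == pytest.approx((4 - 0) / np.sqrt(6 * (6 - 2)))


@given(hst.integers(min_value=0, max_value=2 ** 31 - 1),
       hst.integers(min_value=3, max_value=50))
@settings(max_examples=40, deadline=None)
def test_tau_b_matches_scipy_for_tied_data(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 6, n).astype(float)
    y = rng.integers(0, 6, n).astype(float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return
    mine = st.kendall_tau_b(x, y)
    ref = sps.kendalltau(x, y)
    assert mine.tau_b == pytest.approx(ref.statistic, abs=1e-12)
    assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)
    # pair-count bookkeeping covers every pair
    total = mine.concordant + mine.discordant + mine.ties_x + mine.ties_y + mine.ties_xy
    assert total == n * (n - 1) // 2


def test_exact_small_sample_p_matches_scipy():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
    mine = st.kendall_tau_b(x, y)
    ref = sps.kendalltau(x, y, method="exact")
    assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-12)


def test_constant_input_rejected():
    with pytest.raises(ValueError):
        st.kendall_tau_b([1, 1, 1], [1, 2, 3])


def test_copula_cohort_recovers_target_tau():
    """Copula-mode synthetic severity association at the acceptance size."""
    from guancest.reproduce import severity_kendall_experiment
    res = severity_kendall_experiment(seed=7, n_patients=2500)
    assert abs(res["tau_b"] - (-0.44)) < 0.03
    assert res["p"] < 0.05


# -------------------------------------------------------------------- ANCOVA

def test_exact_linear_data_recovered_to_machine_precision():
    sev = np.array([10.0, 20, 30, 40, 50, 25, 35])
    age = np.array([60.0, 61, 62, 63, 64, 65, 66])
    sex = ["F", "M", "F", "M", "F", "M", "F"]
    y = 2.0 - 0.01 * sev
    r = st.ancova_fit(y, sev, age, sex)
    assert r.params["severity"] == pytest.approx(-0.01, abs=1e-12)
    assert r.params["age"] == pytest.approx(0.0, abs=1e-12)
    assert r.params["sex"] == pytest.approx(0.0, abs=1e-12)


def test_coefficients_match_normal_equations_oracle():
    rng = np.random.default_rng(3)
    n = 40
    sev = rng.uniform(0, 60, n)
    age = rng.uniform(55, 80, n)
    sex = rng.integers(0, 2, n).astype(float)
    y = 1.8 - 0.01 * sev + 0.002 * age + 0.05 * sex + rng.normal(0, 0.1, n)
    r = st.ancova_fit(y, sev, age, sex)
    X = np.column_stack([np.ones(n), sev, age, sex])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(r.params.to_numpy(), beta, rtol=1e-10)


def test_fitted_lines_differ_by_sex_coefficient():
    rng = np.random.default_rng(4)
    n = 30
    sev = rng.uniform(0, 60, n)
    age = rng.uniform(55, 80, n)
    sex = rng.integers(0, 2, n).astype(float)
    y = rng.normal(1.7, 0.2, n)
    r = st.ancova_fit(y, sev, age, sex)
    grid = np.linspace(0, 60, 5)
    gap = r.fitted_line("M", grid, 67.7) - r.fitted_line("F", grid, 67.7)
    np.testing.assert_allclose(gap, r.params["sex"])


def test_rank_deficient_design_rejected():
    with pytest.raises(ValueError):
        st.ancova_fit([1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5],
                      [60.0, 61, 62, 63, 64], ["F", "F", "F", "F", "F"])


def test_severity_slope_recovered_from_linear_cohort():
    from guancest.reproduce import ancova_slope_experiment
    res = ancova_slope_experiment(seed=13, n_patients=2000)
    assert res["beta_severity"] == pytest.approx(-0.01, abs=0.002)
    assert res["p_severity"] < 0.05


# -------------------------------------------------------------- descriptives

@pytest.mark.parametrize("values,kind,expected", [
    ([1, 2, 3], "mean_sd", "2 ± 1"),
    ([1, 2, 2, 4], "median_range", "2 (1;4)"),
])
def test_descriptive_formats(values, kind, expected):
    assert st.descriptive_summary(values, kind) == expected


def test_single_value_summary_warns():
    with pytest.warns(UserWarning):
        assert st.descriptive_summary([2.0]) == "2 ± 0"


def test_empty_summary_rejected():
    with pytest.raises(ValueError):
        st.descriptive_summary([])
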