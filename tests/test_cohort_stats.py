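"""Unit, oracle and property tests for the validation statistics."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

import hepascore as h
from hepascore import Contingency2x2


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cells, expected", [
    ((4, 53, 4, 232), 4.38),    # labMELD level 8 vs 6
    ((5, 14, 4, 232), 20.71),   # labMELD level >=15 vs 6
    ((2, 39, 4, 232), 2.97),
    ((4, 24, 4, 232), 9.67),
    ((5, 143, 4, 232), 2.03),
    ((1, 1, 1, 1), 1.0),
])
def test_cross_product_odds_ratio(cells, expected):
    res = h.odds_ratio(Contingency2x2(*cells))
    assert res.value == pytest.approx(expected, abs=0.005)
    assert res.ci_low < res.value < res.ci_high
    assert not res.corrected and not res.undefined


def test_zero_cell_triggers_haldane_correction():
    res = h.odds_ratio(Contingency2x2(0, 10, 3, 7))
    assert res.corrected and not res.undefined
    assert res.value == pytest.approx((0.5 * 7.5) / (10.5 * 3.5))


def test_zero_margin_leaves_or_undefined():
    res = h.odds_ratio(Contingency2x2(0, 10, 0, 7))  # no events anywhere
    assert res.undefined and math.isnan(res.value)


def test_negative_or_fractional_cells_rejected():
    with pytest.raises(h.DomainError):
        Contingency2x2(-1, 2, 3, 4)
    with pytest.raises(h.DomainError):
        Contingency2x2(1.5, 2, 3, 4)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def test_fisher_exact_small_table_full_enumeration():
    # support of a 4/4 x 4/4 table: probabilities 1,16,36,16,1 over 70
    assert h.fisher_exact(Contingency2x2(3, 1, 1, 3)) \
        == pytest.approx(34 / 70, abs=1e-12)


def test_fisher_trisectionectomy_by_death_is_highly_significant():
    assert h.fisher_exact(Contingency2x2(10, 29, 14, 476)) < 1e-4


def test_fisher_zero_margin_gives_p_one():
    assert h.fisher_exact(Contingency2x2(0, 5, 0, 9)) == 1.0
    assert h.fisher_exact(Contingency2x2(3, 0, 4, 0)) == 1.0


def test_fisher_matches_scipy_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(200):
        cells = rng.integers(0, 25, size=4)
        if cells.sum() == 0:
            continue
        ours = h.fisher_exact(Contingency2x2(*map(int, cells)))
        _, ref = scipy.stats.fisher_exact(np.array(cells).reshape(2, 2))
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mann_whitney_tiny_exact_case():
    res = h.mann_whitney_u([1, 2], [3, 4])
    assert res.u == 0
    assert res.p_value == pytest.approx(1 / 3, abs=1e-12)
    assert res.method == "exact"


def test_mann_whitney_identical_samples():
    x = [1.0, 2.0, 3.0]
    res = h.mann_whitney_u(x, x)
    assert res.u == len(x) ** 2 / 2
    with pytest.warns(UserWarning):
        res = h.mann_whitney_u([5.0] * 4, [5.0] * 6)
    assert res.p_value == 1.0


def test_mann_whitney_empty_sample_rejected():
    with pytest.raises(h.StatisticsError):
        h.mann_whitney_u([], [1.0])


def test_mann_whitney_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n, m = rng.integers(2, 15, size=2)
        x = rng.normal(size=n)
        y = rng.normal(0.5, size=m)
        res = h.mann_whitney_u(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact")
        assert res.method == "exact"
        assert res.u == ref.statistic
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_mann_whitney_normal_branch_matches_scipy_with_ties():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 6, size=40).astype(float)
    y = rng.integers(1, 7, size=35).astype(float)
    res = h.mann_whitney_u(x, y)
    ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
    assert res.method == "normal"
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_mann_whitney_p_decreases_with_shift():
    rng = np.random.default_rng(3)
    x = rng.normal(size=60)
    noise = rng.normal(size=60)
    ps = [h.mann_whitney_u(x, noise + shift).p_value for shift in (0.2, 0.8, 1.6)]
    assert ps[0] > ps[1] > ps[2]


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def _expand_2x2(a, b, c, d):
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return y, x


def test_logistic_slope_equals_log_odds_ratio_on_2x2():
    for cells in [(4, 53, 4, 232), (5, 14, 4, 232), (7, 3, 2, 11)]:
        y, x = _expand_2x2(*cells)
        fit = h.fit_logistic(y, x)
        assert fit.converged
        or_ = h.odds_ratio(Contingency2x2(*cells)).value
        assert math.exp(fit.coef[1]) == pytest.approx(or_, rel=1e-6)
        # Wald SE equals the Woolf SE on a saturated 2x2
        woolf = math.sqrt(sum(1 / v for v in cells))
        assert fit.se[1] == pytest.approx(woolf, rel=1e-5)


def test_logistic_rejects_constant_outcome():
    with pytest.raises(h.StatisticsError):
        h.fit_logistic(np.ones(10), np.arange(10.0))


def test_logistic_rejects_collinear_design():
    x = np.arange(20.0)
    y = (x > 9).astype(float)
    y[0], y[-1] = 1, 0
    with pytest.raises(h.StatisticsError):
        h.fit_logistic(y, np.column_stack([x, 2 * x]))


def test_logistic_flags_complete_separation():
    x = np.r_[-np.arange(1, 6.0), np.arange(1, 6.0)]
    y = (x > 0).astype(float)
    fit = h.fit_logistic(y, x)
    assert fit.separated and not fit.converged


def test_logistic_matches_statsmodels():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(300, 2))
    eta = -1.0 + 0.8 * X[:, 0] - 0.5 * X[:, 1]
    y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = h.fit_logistic(y, X)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(fit.coef, ref.params, rtol=1e-6)
    np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)


def test_logistic_recovers_simulation_truth_within_3se():
    rng = np.random.default_rng(5)
    n = 5000
    truth = np.array([-2.0, 1.2, -0.7])
    X = rng.normal(size=(n, 2))
    eta = truth[0] + X @ truth[1:]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = h.fit_logistic(y, X)
    assert np.all(np.abs(fit.coef - truth) < 3 * fit.se)


# ---------------------------------------------------------------------------
# C-index and ROC curves
# ---------------------------------------------------------------------------

def test_c_index_pair_enumeration_example():
    scores = [3, 5, 1, 2, 3]
    deaths = [1, 1, 0, 0, 0]
    assert h.c_index(scores, deaths) == pytest.approx((5 + 0.5) / 6)


def test_c_index_perfect_and_degenerate():
    assert h.c_index([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
    assert math.isnan(h.c_index([1, 2], [1, 1]))  # one class absent


def test_c_index_near_half_for_uninformative_score():
    rng = np.random.default_rng(6)
    scores = rng.normal(size=4000)
    y = (rng.random(4000) < 0.3).astype(int)
    assert h.c_index(scores, y) == pytest.approx(0.5, abs=0.04)


def test_c_index_equals_mann_whitney_identity():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = rng.integers(8, 40)
        scores = np.round(rng.normal(size=n), 1)  # ties on purpose
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            continue
        u = h.mann_whitney_u(scores[y == 1], scores[y == 0]).u
        n1, n0 = y.sum(), n - y.sum()
        assert h.c_index(scores, y) == pytest.approx(u / (n1 * n0), abs=1e-12)


def test_roc_curve_perfect_score_passes_through_0_1():
    roc = h.roc_curve([1, 2, 10, 11], [0, 0, 1, 1])
    pts = roc.points
    assert ((pts["one_minus_specificity"] == 0) & (pts["sensitivity"] == 1)).any()
    assert roc.auc == 1.0


def test_roc_curve_single_valued_score_is_diagonal():
    roc = h.roc_curve([3, 3, 3, 3], [0, 1, 0, 1])
    assert roc.auc == pytest.approx(0.5, abs=1e-12)
    assert len(roc.points) == 2  # (0,0) and (1,1)


def test_roc_trapezoid_area_equals_rank_c_index():
    rng = np.random.default_rng(8)
    for _ in range(30):
        n = rng.integers(10, 200)
        scores = np.round(rng.normal(size=n), 1)
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            continue
        roc = h.roc_curve(scores, y)
        assert roc.auc == pytest.approx(h.c_index(scores, y), abs=1e-12)
        assert roc.points["sensitivity"].is_monotonic_increasing
        assert roc.points["one_minus_specificity"].is_monotonic_increasing


def test_roc_curve_requires_both_classes():
    with pytest.raises(h.StatisticsError):
        h.roc_curve([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------------
# Paired score comparison
# ---------------------------------------------------------------------------

def test_compare_identical_scores_gives_p_one():
    rng = np.random.default_rng(9)
    s = rng.normal(size=100)
    y = (rng.random(100) < 0.4).astype(int)
    res = h.compare_scores(s, s, y)
    assert res.difference == 0 and res.p_value == 1.0


def test_compare_with_permuted_score_detects_informative_one():
    rng = np.random.default_rng(10)
    n = 3000
    y = (rng.random(n) < 0.3).astype(int)
    a = y + rng.normal(scale=0.8, size=n)
    b = rng.permutation(a)
    res = h.compare_scores(a, b, y)
    assert res.auc_b == pytest.approx(0.5, abs=0.03)
    assert res.difference == pytest.approx(res.auc_a - 0.5, abs=0.03)
    assert res.p_value < 1e-6


def test_compare_logistic_wald_alternative_runs():
    rng = np.random.default_rng(11)
    n = 500
    y = (rng.random(n) < 0.3).astype(int)
    a = y + rng.normal(scale=1.0, size=n)
    b = y + rng.normal(scale=3.0, size=n)
    res = h.compare_scores(a, b, y, method="logistic_wald")
    assert res.method == "logistic_wald"
    assert 0 <= res.p_value <= 1
    ident = h.compare_scores(a, a, y, method="logistic_wald")
    assert ident.p_value == 1.0


# ---------------------------------------------------------------------------
# Stratified mortality tables
# ---------------------------------------------------------------------------

def test_stratified_table_reference_row_and_identity_or():
    df = pd.DataFrame({
        "risk_points": [0] * 50 + [2] * 50,
        "death_90d": ([1] * 5 + [0] * 45) * 2,  # identical odds in both strata
    })
    rows = h.stratified_mortality_table(df, h.RISK_SCORE_SCHEME)
    assert rows[0].reference and rows[0].odds_ratio == 1.0
    assert rows[1].odds_ratio == pytest.approx(1.0)


def test_stratified_table_emits_empty_strata_flagged():
    df = pd.DataFrame({"risk_points": [0, 0, 2, 2], "death_90d": [0, 1, 0, 1]})
    rows = h.stratified_mortality_table(df, h.RISK_SCORE_SCHEME)
    assert len(rows) == len(h.RISK_SCORE_SCHEME.strata)
    empty = [r for r in rows if r.n_total == 0]
    assert empty and all(r.or_undefined for r in empty)


def test_stratified_table_requires_complete_outcome():
    df = pd.DataFrame({"risk_points": [0, 2], "death_90d": [1, None]})
    with pytest.raises(h.SchemaError):
        h.stratified_mortality_table(df, h.RISK_SCORE_SCHEME)
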