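"""2x2 diagnostic metrics: published-value checks, CI methods, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.contingency_tables import Table2x2

from chanse import (
    TwoByTwoTable,
    build_two_by_two,
    compute_metrics,
    odds_ratio,
    proportion_ci,
    univariate_compare,
    reference,
)

counts = st.integers(min_value=1, max_value=200)
tables = st.builds(TwoByTwoTable, tp=counts, fp=counts, fn=counts, tn=counts)


def test_build_two_by_two_toy():
    t = build_two_by_two([1, 1, 0], [1, 0, 0])
    assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 0, 1)
    t = build_two_by_two([1, 1, 1], [1, 1, 1])
    assert (t.tp, t.fp, t.fn, t.tn) == (3, 0, 0, 0)


def test_heel_drop_counts_from_published_prevalences():
    t = reference.two_by_two("heel_drop")
    assert (t.tp, t.fn, t.fp, t.tn) == (66, 18, 35, 23)
    assert t.n == 142


def test_published_heel_drop_metrics():
    m = compute_metrics(TwoByTwoTable(tp=66, fp=35, fn=18, tn=23))
    assert round(m.sensitivity.value, 2) == 0.79
    assert round(m.specificity.value, 2) == 0.40
    assert (round(m.sensitivity.ci_low, 2), round(m.sensitivity.ci_high, 2)) == (0.68, 0.87)
    assert round(m.odds_ratio.value, 3) == 2.410


def test_published_nausea_vomiting_metrics():
    m = compute_metrics(TwoByTwoTable(tp=47, fp=8, fn=37, tn=50))
    assert round(m.plr.value, 2) == 4.06
    assert round(m.npv.value, 2) == 0.57
    est, corrected = odds_ratio(m.table)
    assert not corrected
    assert round(est.value, 3) == 7.939
    assert round(est.ci_low, 3) == 3.354
    assert round(est.ci_high, 3) == 18.794


def test_perfect_test_metrics():
    m = compute_metrics(TwoByTwoTable(tp=10, fp=0, fn=0, tn=10))
    assert m.sensitivity.value == 1.0
    assert m.specificity.value == 1.0
    assert m.nlr.value == 0.0
    assert m.plr is None  # sens/(1-spec) undefined at spec=1


def test_point_estimates_inside_their_cis():
    m = compute_metrics(TwoByTwoTable(tp=30, fp=12, fn=9, tn=40))
    for est in (m.sensitivity, m.specificity, m.ppv, m.npv, m.plr, m.nlr,
                m.odds_ratio):
        assert est.ci_low <= est.value <= est.ci_high


def test_symmetric_table_or_is_one():
    est, _ = odds_ratio(TwoByTwoTable(tp=13, fp=13, fn=7, tn=7))
    assert est.value == pytest.approx(1.0)


def test_zero_cell_or_continuity_corrected():
    est, corrected = odds_ratio(TwoByTwoTable(tp=10, fp=0, fn=5, tn=8))
    assert corrected
    assert math.isfinite(est.value) and est.value > 0
    assert est.ci_low > 0 and math.isfinite(est.ci_high)


@settings(max_examples=60, deadline=None)
@given(tables)
def test_or_axis_invariances(t):
    """Transposing axes or relabeling both keeps the OR; relabeling one inverts it."""
    est, _ = odds_ratio(t)
    transposed, _ = odds_ratio(TwoByTwoTable(tp=t.tp, fp=t.fn, fn=t.fp, tn=t.tn))
    one_axis, _ = odds_ratio(TwoByTwoTable(tp=t.fn, fp=t.tn, fn=t.tp, tn=t.fp))
    both_axes, _ = odds_ratio(TwoByTwoTable(tp=t.tn, fp=t.fn, fn=t.fp, tn=t.tp))
    assert est.value == pytest.approx(transposed.value)
    assert est.value == pytest.approx(1.0 / one_axis.value)
    assert est.value == pytest.approx(both_axes.value)


@settings(max_examples=60, deadline=None)
@given(tables)
def test_or_ci_matches_statsmodels(t):
    est, _ = odds_ratio(t)
    sm = Table2x2(np.array([[t.tp, t.fn], [t.fp, t.tn]]))
    lo, hi = sm.oddsratio_confint(0.05)
    assert est.value == pytest.approx(sm.oddsratio)
    assert est.ci_low == pytest.approx(lo)
    assert est.ci_high == pytest.approx(hi)


@settings(max_examples=60, deadline=None)
@given(tables)
def test_lr_identities(t):
    """PLR > 1 <=> sens + spec > 1 <=> NLR < 1, and the defining ratios hold."""
    m = compute_metrics(t)
    sens, spec = m.sensitivity.value, m.specificity.value
    if spec < 1:
        assert m.plr.value == pytest.approx(sens / (1 - spec))
    if spec > 0:
        assert m.nlr.value == pytest.approx((1 - sens) / spec)
    if 0 < spec < 1:
        if sens + spec > 1:
            assert m.plr.value > 1 and m.nlr.value < 1
        elif sens + spec < 1:
            assert m.plr.value < 1 and m.nlr.value > 1


def test_proportion_ci_edges_and_closed_form():
    lo, hi = proportion_ci(0, 10)
    assert lo == 0.0 and hi == pytest.approx(1 - 0.025 ** (1 / 10))
    lo, hi = proportion_ci(10, 10)
    assert hi == 1.0
    # independent closed form: Clopper-Pearson via beta quantiles
    k, n = 66, 84
    lo, hi = proportion_ci(k, n)
    assert lo == pytest.approx(stats.beta.ppf(0.025, k, n - k + 1))
    assert hi == pytest.approx(stats.beta.ppf(0.975, k + 1, n - k))
    assert (round(lo, 2), round(hi, 2)) == (0.68, 0.87)
    with pytest.raises(ValueError):
        proportion_ci(5, 4)


def _toy_cohort(pairs):
    """Build a minimal cohort exposing one binary variable (heel_drop)."""
    import pandas as pd
    from chanse.cohort import Cohort, SCHEMA

    n = len(pairs)
    columns = {}
    for col, kind in SCHEMA.items():
        if kind == "real":
            columns[col] = np.full(n, np.nan)
        elif kind == "bool":
            columns[col] = pd.array([pd.NA] * n, dtype="boolean")
        else:
            columns[col] = pd.array([pd.NA] * n, dtype="string")
    df = pd.DataFrame(columns)
    df["patient_id"] = [f"t{i}" for i in range(n)]
    df["heel_drop"] = pd.array([v for v, _ in pairs], dtype="boolean")
    df["outcome"] = ["uncomplicated" if d else "none" for _, d in pairs]
    return Cohort(df)


def test_identical_group_distributions_give_p_one():
    pairs = [(True, True)] * 5 + [(False, True)] * 5 \
        + [(True, False)] * 5 + [(False, False)] * 5
    r = univariate_compare(_toy_cohort(pairs), "heel_drop")
    assert r.p_value == pytest.approx(1.0)


def test_fisher_chosen_when_expected_cells_small():
    pairs = [(True, True)] * 3 + [(False, True)] * 1 \
        + [(True, False)] * 1 + [(False, False)] * 3
    r = univariate_compare(_toy_cohort(pairs), "heel_drop")
    assert r.test == "Fisher exact"  # all expected cells are 2
    assert 0 <= r.p_value <= 1


def test_published_male_comparison_significant(cohort):
    t = reference.two_by_two("male")
    m = compute_metrics(t)
    assert m.p_value < 0.05
    assert round(m.odds_ratio.value, 3) == 2.302


def test_fisher_p_equals_exact_permutation_p():
    """Fisher's exact p is the exact conditional permutation p (enumerated)."""
    t = TwoByTwoTable(tp=7, fp=2, fn=3, tn=8)
    m, n = t.n_diseased, t.n_not_diseased
    total_pos = t.tp + t.fp
    pmf = {k: stats.hypergeom.pmf(k, m + n, total_pos, m) for k in range(total_pos + 1)}
    obs = pmf[t.tp]
    p_exact = sum(p for p in pmf.values() if p <= obs + 1e-12)
    p_fisher = stats.fisher_exact([[t.tp, t.fn], [t.fp, t.tn]])[1]
    assert p_fisher == pytest.approx(p_exact, abs=1e-10)


def test_chi_square_p_close_to_monte_carlo_permutation_p():
    """Asymptotic chi-square p vs label-permutation mid-p on a moderate table.

    The permutation distribution of the chi-square statistic on a 2x2 table
    is discrete with large point masses, so the asymptotic p approximates
    the mid-p (half credit for permutations tying the observed statistic).
    """
    rng = np.random.default_rng(11)
    test_pos = np.repeat([True, False], [30, 30])
    diseased = np.concatenate([np.repeat(True, 18), np.repeat(False, 12),
                               np.repeat(True, 11), np.repeat(False, 19)])
    t = build_two_by_two(test_pos, diseased)
    m = compute_metrics(t)
    assert "chi-square" in m.methods["p"]

    def chi2_stat(d):
        tt = build_two_by_two(test_pos, d)
        obs = np.array([[tt.tp, tt.fn], [tt.fp, tt.tn]])
        exp = stats.contingency.expected_freq(obs)
        return ((obs - exp) ** 2 / exp).sum()

    observed = chi2_stat(diseased)
    reps = 20_000
    above = ties = 0
    d = diseased.copy()
    for _ in range(reps):
        rng.shuffle(d)
        s = chi2_stat(d)
        if s > observed + 1e-9:
            above += 1
        elif s > observed - 1e-9:
            ties += 1
    p_perm_mid = (above + 0.5 * ties) / reps
    assert abs(m.p_value - p_perm_mid) < 0.03


def test_welch_used_for_continuous_variable(cohort):
    r = univariate_compare(cohort, "wbc_per_ul")
    assert r.test == "Welch t-test"
    assert 0 <= r.p_value <= 1
    assert r.kind == "continuous"
    assert "±" in r.summary_diseased


def test_constant_variable_flagged_undefined():
    pairs = [(True, True)] * 6 + [(True, False)] * 6
    r = univariate_compare(_toy_cohort(pairs), "heel_drop")
    assert math.isnan(r.p_value)
    assert "constant" in r.test
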