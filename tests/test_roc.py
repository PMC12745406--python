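"""ROC/AUC analysis: pair-counting oracle, DeLong machinery, Youden, tables."""

import math
import subprocess
import sys
import textwrap

import numpy as np
import pytest
from scipy import stats

from chanse import (
    empirical_roc,
    delong_variance,
    delong_paired_test,
    youden_cutoff,
    threshold_table,
    build_two_by_two,
    compute_metrics,
    classify,
)

RNG = np.random.default_rng(20240918)


def brute_force_auc(scores, diseased):
    """Probability interpretation: favorable pairs + half the ties."""
    s = np.asarray(scores, dtype=float)
    d = np.asarray(diseased, dtype=bool)
    pos, neg = s[d], s[~d]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def _random_case(rng, n=40, span=6):
    scores = rng.integers(0, span + 1, size=n)
    diseased = rng.random(n) < 0.5
    if diseased.all():
        diseased[0] = False
    if not diseased.any():
        diseased[0] = True
    return scores, diseased


def test_toy_auc_equals_pair_oracle():
    scores = [3, 4, 2, 1, 2, 3]
    diseased = [1, 1, 1, 0, 0, 0]
    r = empirical_roc(scores, diseased)
    assert r.auc == pytest.approx(brute_force_auc(scores, diseased))


def test_auc_equals_pair_oracle_on_random_inputs():
    for _ in range(200):
        scores, diseased = _random_case(RNG)
        r = empirical_roc(scores, diseased)
        assert r.auc == pytest.approx(brute_force_auc(scores, diseased))


def test_perfect_and_constant_scores():
    diseased = np.repeat([True, False], 10)
    perfect = np.repeat([5, 1], 10)
    r = empirical_roc(perfect, diseased)
    assert r.auc == 1.0
    assert delong_variance(perfect, diseased) == 0.0
    cut, j = youden_cutoff(r)
    assert j == pytest.approx(1.0)
    assert 1 < cut <= 5

    constant = np.full(20, 3)
    r = empirical_roc(constant, diseased)
    assert r.auc == pytest.approx(0.5)
    assert youden_cutoff(r)[1] == pytest.approx(0.0)


def test_roc_curve_monotone_with_extreme_endpoints():
    scores, diseased = _random_case(RNG, n=80)
    r = empirical_roc(scores, diseased)
    assert (np.diff(r.sens_at) <= 1e-12).all()
    assert (np.diff(r.spec_at) >= -1e-12).all()
    assert r.sens_at[0] == 1.0 and r.spec_at[0] == 0.0   # cutoff below min
    assert r.sens_at[-1] == 0.0 and r.spec_at[-1] == 1.0  # cutoff above max


def test_auc_invariant_under_increasing_transform():
    scores, diseased = _random_case(RNG, n=60)
    base = empirical_roc(scores, diseased).auc
    assert empirical_roc(3 * scores + 7, diseased).auc == pytest.approx(base)
    assert empirical_roc(scores ** 3, diseased).auc == pytest.approx(base)


def test_single_class_input_rejected():
    with pytest.raises(ValueError, match="both classes"):
        empirical_roc([1, 2, 3], [True, True, True])


def _paired_scores(rng, n=200):
    """Two correlated integer scores driven by a shared latent signal."""
    diseased = np.repeat([True, False], n // 2)
    latent = rng.normal(diseased * 1.2, 1.0)
    a = np.clip(np.round(latent + rng.normal(0, 0.6, n) + 3), 0, 6).astype(int)
    b = np.clip(np.round(latent + rng.normal(0, 0.9, n) + 3), 0, 6).astype(int)
    return a, b, diseased


def test_delong_variance_matches_bootstrap():
    rng = np.random.default_rng(5)
    a, _, diseased = _paired_scores(rng)
    var = delong_variance(a, diseased)
    reps = 2000
    idx_pos = np.flatnonzero(diseased)
    idx_neg = np.flatnonzero(~diseased)
    aucs = np.empty(reps)
    for i in range(reps):
        bi = np.concatenate([rng.choice(idx_pos, len(idx_pos)),
                             rng.choice(idx_neg, len(idx_neg))])
        aucs[i] = empirical_roc(a[bi], diseased[bi]).auc
    boot = aucs.var(ddof=1)
    assert var == pytest.approx(boot, rel=0.15)


def test_delong_variance_decreases_with_sample_size():
    rng = np.random.default_rng(6)
    a, _, diseased = _paired_scores(rng, n=200)
    v1 = delong_variance(a, diseased)
    v2 = delong_variance(np.tile(a, 2), np.tile(diseased, 2))
    assert v2 < v1


def test_identical_scores_give_p_one():
    a, _, diseased = _paired_scores(np.random.default_rng(7))
    cmp_ = delong_paired_test(a, a, diseased)
    assert cmp_.delta == 0.0
    assert cmp_.p_value == 1.0


def test_paired_test_antisymmetric():
    a, b, diseased = _paired_scores(np.random.default_rng(8))
    ab = delong_paired_test(a, b, diseased)
    ba = delong_paired_test(b, a, diseased)
    assert ab.z == pytest.approx(-ba.z)
    assert ab.p_value == pytest.approx(ba.p_value)
    assert ab.delta == pytest.approx(ab.auc_a - ab.auc_b)


def test_paired_test_agrees_with_paired_bootstrap():
    rng = np.random.default_rng(9)
    a, b, diseased = _paired_scores(rng)
    cmp_ = delong_paired_test(a, b, diseased)
    reps = 2000
    idx_pos = np.flatnonzero(diseased)
    idx_neg = np.flatnonzero(~diseased)
    deltas = np.empty(reps)
    for i in range(reps):
        bi = np.concatenate([rng.choice(idx_pos, len(idx_pos)),
                             rng.choice(idx_neg, len(idx_neg))])
        deltas[i] = (empirical_roc(a[bi], diseased[bi]).auc
                     - empirical_roc(b[bi], diseased[bi]).auc)
    se_boot = deltas.std(ddof=1)
    p_boot = 2 * stats.norm.sf(abs(cmp_.delta) / se_boot)
    assert cmp_.p_value == pytest.approx(p_boot, abs=0.05)


def test_independent_scores_have_near_zero_covariance():
    rng = np.random.default_rng(10)
    diseased = np.repeat([True, False], 300)
    covs = []
    for _ in range(30):
        a = np.clip(np.round(rng.normal(diseased * 1.0, 1.0) + 3), 0, 6).astype(int)
        b = np.clip(np.round(rng.normal(diseased * 1.0, 1.0) + 3), 0, 6).astype(int)
        covs.append(delong_paired_test(a, b, diseased).covariance)
    var_scale = delong_variance(a, diseased)
    assert abs(np.mean(covs)) < var_scale / 3


def test_youden_matches_exhaustive_search():
    for _ in range(100):
        scores, diseased = _random_case(RNG, n=60)
        r = empirical_roc(scores, diseased)
        cut, j = youden_cutoff(r)
        best = max(
            (float(((scores[diseased] >= c).mean()
                    + (scores[~diseased] < c).mean() - 1)), -c)
            for c in range(scores.min() - 1, scores.max() + 2)
        )
        assert j == pytest.approx(best[0])
        assert cut == -best[1]  # lowest cutoff among ties


def test_threshold_table_extremes_and_composition():
    scores, diseased = _random_case(RNG, n=50)
    lo, hi = scores.min(), scores.max()
    rows = threshold_table(scores, diseased, [lo - 1, 3, hi + 1])
    m_lo, m_mid, m_hi = (m for _, m in rows)
    assert m_lo.sensitivity.value == 1.0 and m_lo.specificity.value == 0.0
    assert m_hi.sensitivity.value == 0.0 and m_hi.specificity.value == 1.0
    # composition: classify + compute_metrics gives the same row
    direct = compute_metrics(build_two_by_two(classify(scores, 3), diseased))
    assert m_mid == direct


def test_delong_matches_r_proc(tmp_path, cohort):
    """Independent oracle: R pROC's paired DeLong test on the same data."""
    from chanse import score_cohort

    scored = score_cohort(cohort).dropna(subset=["chanse", "pas"])
    csv = tmp_path / "scored.csv"
    scored.assign(disease=scored["diseased"].astype(int)).to_csv(csv, index=False)
    r_script = textwrap.dedent(f"""
        suppressMessages(library(pROC))
        d <- read.csv("{csv}")
        r1 <- roc(d$disease, d$chanse, quiet=TRUE, direction="<")
        r2 <- roc(d$disease, d$pas, quiet=TRUE, direction="<")
        tt <- roc.test(r1, r2, method="delong", paired=TRUE)
        cat(sprintf("%.12f %.12f %.12f\\n", auc(r1), auc(r2), tt$p.value))
    """)
    path = tmp_path / "delong.R"
    path.write_text(r_script)
    out = subprocess.run(["Rscript", str(path)], capture_output=True, text=True,
                         check=True)
    auc1, auc2, p_r = map(float, out.stdout.split())

    cmp_ = delong_paired_test(
        scored["chanse"].to_numpy(int), scored["pas"].to_numpy(int),
        scored["diseased"].to_numpy(bool),
    )
    assert cmp_.auc_a == pytest.approx(auc1, abs=1e-9)
    assert cmp_.auc_b == pytest.approx(auc2, abs=1e-9)
    assert cmp_.p_value == pytest.approx(p_r, abs=1e-9)
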