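"""Empirical ROC analysis for integer-valued clinical scores.

The AUC is the Mann-Whitney statistic with half credit for ties — equal to
the trapezoidal area under the empirical staircase.  Ties matter here:
scores take at most 7 (CHANSE) or 11 (PAS) values.

Variances and the paired comparison of two scores measured on the same
patients use DeLong's structural components (placement values): for
positives i, V10_i = mean_j psi(x_i, y_j) and for negatives j,
V01_j = mean_i psi(x_i, y_j), with psi = 1, 1/2, 0 for x > y, x = y, x < y.
Then var(AUC) = S10/m + S01/n, and for two paired scores
z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov) with a two-sided normal
p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ROCResult:
    """Operating points of the rule "score >= cutoff" across all cutoffs."""

    cutoffs: np.ndarray
    sens_at: np.ndarray
    spec_at: np.ndarray
    auc: float
    auc_var: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class AUCComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p_value: float
    covariance: float
    var_a: float
    var_b: float
    method: str = "DeLong paired z-test (structural components)"


def _check_classes(diseased: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(diseased, dtype=bool)
    if d.ndim != 1:
        raise ValueError("diseased must be 1-D")
    if d.all() or not d.any():
        raise ValueError("both classes (diseased and non-diseased) must be present")
    return d, ~d


def _placements(scores: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values (V10 for positives, V01 for negatives) and AUC.

    Rank-based O(N log N) formulation; midranks implement the half-credit
    tie convention exactly.
    """
    x, y = scores[d], scores[~d]
    m, n = len(x), len(y)
    tz = stats.rankdata(np.concatenate([x, y]))
    tx = stats.rankdata(x)
    ty = stats.rankdata(y)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return v10, v01, float(auc)


def empirical_roc(scores, diseased, level: float = 0.95) -> ROCResult:
    """Empirical ROC of an integer-valued score against disease status.

    One operating point per integer cutoff spanning the observed score range,
    plus sentinels below the minimum (everyone positive: sens 1, spec 0) and
    above the maximum (everyone negative).  The AUC confidence interval is
    normal-approximate with the DeLong standard error, clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    d, nd = _check_classes(np.asarray(diseased))
    if s.shape != d.shape:
        raise ValueError("scores and diseased must have equal length")
    if np.isnan(s).any():
        raise ValueError("scores must be non-missing (drop missing upstream)")
    if not np.allclose(s, np.round(s)):
        raise ValueError("scores must be integer-valued")
    s = np.round(s).astype(int)

    lo, hi = int(s.min()), int(s.max())
    cutoffs = np.arange(lo - 1, hi + 2)
    m, n = int(d.sum()), int(nd.sum())
    sens = np.array([(s[d] >= c).mean() for c in cutoffs])
    spec = np.array([(s[nd] < c).mean() for c in cutoffs])

    v10, v01, auc = _placements(s.astype(float), d)
    var = _delong_var_from_placements(v10, v01)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return ROCResult(cutoffs, sens, spec, auc, var, ci, m, n)


def _delong_var_from_placements(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_variance(scores, diseased) -> float:
    """DeLong variance of the empirical AUC (0 for a perfectly separating score)."""
    s = np.asarray(scores, dtype=float)
    d, _ = _check_classes(np.asarray(diseased))
    v10, v01, _ = _placements(s, d)
    return _delong_var_from_placements(v10, v01)


def delong_paired_test(scores_a, scores_b, diseased) -> AUCComparison:
    """Compare the AUCs of two scores measured on the same patients.

    Two-sided z-test on the AUC difference with the paired (correlated)
    DeLong variance.  Identical scores give delta 0 and p = 1; a degenerate
    zero-variance difference with unequal AUCs raises.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    d, _ = _check_classes(np.asarray(diseased))
    if a.shape != b.shape or a.shape != d.shape:
        raise ValueError("scores_a, scores_b, diseased must have equal length")

    v10a, v01a, auc_a = _placements(a, d)
    v10b, v01b, auc_b = _placements(b, d)
    m, n = len(v10a), len(v01a)
    var_a = _delong_var_from_placements(v10a, v01a)
    var_b = _delong_var_from_placements(v10b, v01b)
    cov = 0.0
    if m > 1:
        cov += float(np.cov(v10a, v10b, ddof=1)[0, 1]) / m
    if n > 1:
        cov += float(np.cov(v01a, v01b, ddof=1)[0, 1]) / n

    delta = auc_a - auc_b
    var_delta = var_a + var_b - 2 * cov
    if var_delta <= 0 or math.isclose(var_delta, 0.0, abs_tol=1e-15):
        if math.isclose(delta, 0.0, abs_tol=1e-12):
            return AUCComparison(auc_a, auc_b, 0.0, 0.0, 1.0, cov, var_a, var_b)
        raise ValueError(
            "degenerate comparison: zero variance of the AUC difference "
            f"with unequal AUCs (delta={delta:g})"
        )
    z = delta / math.sqrt(var_delta)
    p = 2 * stats.norm.sf(abs(z))
    return AUCComparison(auc_a, auc_b, delta, z, float(p), cov, var_a, var_b)


def youden_cutoff(roc: ROCResult) -> tuple[int, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the lowest cutoff (favoring sensitivity).
    """
    j = roc.sens_at + roc.spec_at - 1.0
    # lowest cutoff among maxima; the tolerance keeps 1-ulp float noise from
    # breaking mathematical ties (cutoffs ascend)
    idx = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return int(roc.cutoffs[idx]), float(j[idx])


def threshold_table(scores, diseased, cutoffs) -> list:
    """Per-cutoff diagnostic metrics for the dichotomized score.

    Each row is ``(cutoff, DiagnosticMetrics)`` for the rule "score >= cutoff",
    computed by the same 2x2 engine used for single tests.
    """
    from .metrics import build_two_by_two, compute_metrics

    s = np.asarray(scores)
    d = np.asarray(diseased, dtype=bool)
    rows = []
    for c in cutoffs:
        t = build_two_by_two(s >= c, d)
        rows.append((int(c), compute_metrics(t)))
    return rows
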