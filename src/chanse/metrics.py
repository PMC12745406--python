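"""2x2 diagnostic-accuracy statistics with confidence intervals.

Point estimates follow the standard definitions: sensitivity = TP/(TP+FN),
specificity = TN/(FP+TN), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
PLR = sens/(1-spec), NLR = (1-sens)/spec, OR = (TP*TN)/(FP*FN).

Interval methods (recorded in output metadata):

* proportions (sens/spec/PPV/NPV): Clopper-Pearson exact;
* likelihood ratios: Simel's log method;
* odds ratio: Woolf's log method, with a 0.5 continuity correction applied
  to all cells when any cell is zero (flagged on the result).

Univariate group comparison uses Pearson's chi-square for binary variables
(Fisher's exact test when any expected cell count is < 5) and Welch's t-test
for continuous variables, with complete-case handling per variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort, BOOL_COLUMNS, REAL_COLUMNS

Z_95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class Estimate:
    """Point estimate with a two-sided confidence interval (NaN when undefined)."""

    value: float
    ci_low: float = math.nan
    ci_high: float = math.nan

    def round(self, ndigits: int) -> "Estimate":
        return Estimate(
            round(self.value, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


@dataclass(frozen=True)
class TwoByTwoTable:
    """Cross-counts of a binary test against disease status."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_not_diseased(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_prevalences(cls, pos_diseased: int, n_diseased: int,
                         pos_not_diseased: int, n_not_diseased: int) -> "TwoByTwoTable":
        """Build from per-group positive counts (the form summary tables print)."""
        return cls(
            tp=pos_diseased,
            fn=n_diseased - pos_diseased,
            fp=pos_not_diseased,
            tn=n_not_diseased - pos_not_diseased,
        )


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: Estimate
    specificity: Estimate
    ppv: Optional[Estimate]
    npv: Optional[Estimate]
    plr: Optional[Estimate]
    nlr: Optional[Estimate]
    odds_ratio: Estimate
    or_corrected: bool
    p_value: float
    table: TwoByTwoTable
    methods: dict = field(
        default_factory=lambda: {
            "proportion_ci": "Clopper-Pearson exact",
            "lr_ci": "Simel log method",
            "or_ci": "Woolf log method (0.5 correction on zero cells)",
            "p": "Pearson chi-square (Fisher exact if any expected cell < 5)",
        }
    )


def build_two_by_two(test_positive, diseased) -> TwoByTwoTable:
    """Cross-tabulate paired boolean vectors of equal length (>= 1)."""
    t = np.asarray(test_positive, dtype=bool)
    d = np.asarray(diseased, dtype=bool)
    if t.shape != d.shape or t.ndim != 1 or len(t) == 0:
        raise ValueError("test_positive and diseased must be equal-length 1-D, n >= 1")
    return TwoByTwoTable(
        tp=int(np.sum(t & d)),
        fp=int(np.sum(t & ~d)),
        fn=int(np.sum(~t & d)),
        tn=int(np.sum(~t & ~d)),
    )


def proportion_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact interval for a binomial proportion.

    k=0 gives lower bound 0; k=n gives upper bound 1.
    """
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n, n > 0; got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    return float(lo), float(hi)


def _proportion_estimate(k: int, n: int, level: float) -> Optional[Estimate]:
    if n == 0:
        return None
    lo, hi = proportion_ci(k, n, level)
    return Estimate(k / n, lo, hi)


def likelihood_ratio_cis(
    t: TwoByTwoTable, level: float = 0.95
) -> tuple[Optional[Estimate], Optional[Estimate]]:
    """PLR and NLR with Simel log-method intervals.

    The interval is NaN when the log-method standard error is undefined
    (a zero count in a term); a zero denominator makes the whole ratio
    undefined (None).  A perfect test yields NLR exactly 0 with no interval.
    """
    z = stats.norm.ppf(0.5 + level / 2)
    tp, fp, fn, tn = t.tp, t.fp, t.fn, t.tn
    m, n = t.n_diseased, t.n_not_diseased
    if m == 0 or n == 0:
        return None, None
    sens, spec = tp / m, tn / n

    plr: Optional[Estimate]
    if spec == 1.0:
        plr = None  # denominator 1-spec is zero
    else:
        val = sens / (1 - spec)
        if tp > 0 and fp > 0:
            se = math.sqrt(1 / tp - 1 / m + 1 / fp - 1 / n)
            plr = Estimate(val, val * math.exp(-z * se), val * math.exp(z * se))
        else:
            plr = Estimate(val)

    nlr: Optional[Estimate]
    if spec == 0.0:
        nlr = None
    else:
        val = (1 - sens) / spec
        if fn > 0 and tn > 0:
            se = math.sqrt(1 / fn - 1 / m + 1 / tn - 1 / n)
            nlr = Estimate(val, val * math.exp(-z * se), val * math.exp(z * se))
        else:
            nlr = Estimate(val)
    return plr, nlr


def odds_ratio(t: TwoByTwoTable, level: float = 0.95) -> tuple[Estimate, bool]:
    """Odds ratio with a Woolf (log-method) interval.

    Returns ``(estimate, corrected)``; when any cell is zero a 0.5
    continuity correction is applied to all four cells and flagged.
    """
    z = stats.norm.ppf(0.5 + level / 2)
    cells = [t.tp, t.fp, t.fn, t.tn]
    corrected = any(c == 0 for c in cells)
    a, b, c, d = (x + 0.5 for x in cells) if corrected else cells
    val = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    est = Estimate(val, val * math.exp(-z * se), val * math.exp(z * se))
    return est, corrected


def _two_by_two_p(t: TwoByTwoTable) -> tuple[float, str]:
    obs = np.array([[t.tp, t.fn], [t.fp, t.tn]])
    if obs.sum() == 0 or (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        return math.nan, "undefined (degenerate margins)"
    expected = stats.contingency.expected_freq(obs)
    if (expected < 5).any():
        return float(stats.fisher_exact(obs)[1]), "Fisher exact"
    chi2 = stats.chi2_contingency(obs, correction=False)
    return float(chi2.pvalue), "Pearson chi-square"


def compute_metrics(t: TwoByTwoTable, level: float = 0.95) -> DiagnosticMetrics:
    """All diagnostic-accuracy metrics for one 2x2 table.

    Requires at least one diseased and one non-diseased subject.  Metrics
    whose denominator is zero (PPV with no positives, PLR with perfect
    specificity, ...) come back as None, never fabricated.
    """
    if t.n_diseased == 0 or t.n_not_diseased == 0:
        raise ValueError("need at least one diseased and one non-diseased subject")
    sens = _proportion_estimate(t.tp, t.n_diseased, level)
    spec = _proportion_estimate(t.tn, t.n_not_diseased, level)
    ppv = _proportion_estimate(t.tp, t.tp + t.fp, level) if t.tp + t.fp else None
    npv = _proportion_estimate(t.tn, t.tn + t.fn, level) if t.tn + t.fn else None
    plr, nlr = likelihood_ratio_cis(t, level)
    or_est, corrected = odds_ratio(t, level)
    p, test = _two_by_two_p(t)
    m = DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        plr=plr,
        nlr=nlr,
        odds_ratio=or_est,
        or_corrected=corrected,
        p_value=p,
        table=t,
    )
    m.methods["p"] = test
    return m


@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    kind: str  # "binary" | "continuous"
    n_diseased: int
    n_not_diseased: int
    summary_diseased: str
    summary_not_diseased: str
    p_value: float
    test: str
    odds_ratio: Optional[Estimate] = None
    or_corrected: bool = False


def univariate_compare(
    cohort: Cohort, variable: str, features: Optional[pd.DataFrame] = None
) -> UnivariateResult:
    """Compare one variable between diseased and non-diseased groups.

    Binary variables: n (%) summaries, chi-square/Fisher p, Woolf OR.
    Continuous variables: mean +/- SD summaries, Welch t-test p.
    Complete-case: records missing the variable are dropped; the reported
    group sizes are the n actually used.  ``features`` may supply derived
    binary flags (fever, leukocytosis, ...) not stored on the raw record.
    """
    df = cohort.df
    if variable == "male":
        values = (df["sex"] == "male").mask(df["sex"].isna()).astype("boolean")
        kind = "binary"
    elif variable in BOOL_COLUMNS:
        values = df[variable]
        kind = "binary"
    elif variable in REAL_COLUMNS:
        values = df[variable]
        kind = "continuous"
    elif features is not None and variable in features.columns:
        values = features[variable]
        kind = "binary"
    else:
        raise KeyError(f"unknown variable {variable!r}")

    ok = values.notna()
    diseased = cohort.diseased[ok].to_numpy()
    vals = values[ok]
    n1, n0 = int(diseased.sum()), int((~diseased).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(f"{variable}: one group has no complete cases")

    if kind == "binary":
        v = vals.to_numpy(dtype=bool)
        if v.all() or not v.any():
            # constant variable: association test undefined
            t = build_two_by_two(v, diseased)
            k1, k0 = t.tp, t.fp
            return UnivariateResult(
                variable, kind, n1, n0,
                f"{k1} ({100 * k1 / n1:.1f})", f"{k0} ({100 * k0 / n0:.1f})",
                math.nan, "undefined (constant variable)",
            )
        t = build_two_by_two(v, diseased)
        or_est, corrected = odds_ratio(t)
        p, test = _two_by_two_p(t)
        return UnivariateResult(
            variable, kind, n1, n0,
            f"{t.tp} ({100 * t.tp / n1:.1f})", f"{t.fp} ({100 * t.fp / n0:.1f})",
            p, test, or_est, corrected,
        )

    x1 = vals[diseased].to_numpy(dtype=float)
    x0 = vals[~diseased].to_numpy(dtype=float)
    if np.ptp(vals.to_numpy(dtype=float)) == 0:
        p, test = math.nan, "undefined (constant variable)"
    else:
        p = float(stats.ttest_ind(x1, x0, equal_var=False).pvalue)
        test = "Welch t-test"
    return UnivariateResult(
        variable, kind, n1, n0,
        f"{x1.mean():.1f} ± {x1.std(ddof=1):.1f}",
        f"{x0.mean():.1f} ± {x0.std(ddof=1):.1f}",
        p, test,
    )
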