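"""End-to-end analysis: cohort -> features -> scores -> tables -> ROC comparison.

`run_analysis` produces an :class:`AnalysisReport` mirroring the derivation
study's outputs: a univariate comparison table, per-parameter diagnostic
metrics, score-threshold operating characteristics for CHANSE and PAS, the
paired DeLong AUC comparison with Youden cutoffs, and CHANSE summaries per
severity class.  Everything is deterministic given the input cohort.

`reproduce_printed_tables` recomputes every count-derivable cell of the
published summary tables from the embedded counts and compares it to the
printed value at printed precision (+/- 1 ulp of the last printed digit),
returning a ledger.  Cells catalogued as internally inconsistent in
:mod:`chanse.reference` are reported as skipped with their reason, never
silently passed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import reference
from .cohort import Cohort, read_cohort, derive_features
from .config import Thresholds, DEFAULT_THRESHOLDS
from .metrics import (
    DiagnosticMetrics,
    build_two_by_two,
    compute_metrics,
    odds_ratio,
    univariate_compare,
)
from .roc import empirical_roc, delong_paired_test, youden_cutoff, threshold_table
from .scoring import score_cohort

UNIVARIATE_VARIABLES = (
    "age_years", "male", "body_temp_c", "fever", "pain_duration_h",
    "anorexia", "nausea_or_vomiting", "diarrhea", "migration",
    "wbc_per_ul", "leukocytosis", "neutrophil_pct", "left_shift",
    "crp_mg_dl", "crp_elevated_5", "rlq_tenderness",
    "cough_percussion_hopping", "psoas", "rovsing", "obturator", "heel_drop",
)

PARAMETER_VARIABLES = (
    "migration", "anorexia", "nausea_or_vomiting", "rlq_tenderness",
    "cough_percussion_hopping", "fever", "leukocytosis", "left_shift",
    "crp_elevated_1", "heel_drop",
)

CHANSE_CUTOFFS_DEFAULT = (2, 3, 4)
PAS_CUTOFFS_DEFAULT = (6, 7, 8)


@dataclass
class AnalysisReport:
    table_univariate: pd.DataFrame
    table_parameters: pd.DataFrame
    table_thresholds: pd.DataFrame
    roc: dict
    severity: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "univariate": self.table_univariate.to_dict(orient="records"),
            "parameters": self.table_parameters.to_dict(orient="records"),
            "thresholds": self.table_thresholds.to_dict(orient="records"),
            "roc": self.roc,
            "severity": self.severity.to_dict(orient="records"),
            "metadata": self.metadata,
        }

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True,
                          default=_jsonable)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _metrics_row(label: str, m: DiagnosticMetrics) -> dict:
    def est(e, nd):
        if e is None:
            return {"value": None, "ci_low": None, "ci_high": None}
        return {"value": round(e.value, nd), "ci_low": round(e.ci_low, nd),
                "ci_high": round(e.ci_high, nd)}

    row = {"parameter": label,
           "tp": m.table.tp, "fp": m.table.fp, "fn": m.table.fn, "tn": m.table.tn}
    for name, nd in [("sensitivity", 4), ("specificity", 4), ("ppv", 4),
                     ("npv", 4), ("plr", 4), ("nlr", 4)]:
        e = getattr(m, name)
        for k, v in est(e, nd).items():
            row[f"{name}_{k}" if k != "value" else name] = v
    row["odds_ratio"] = round(m.odds_ratio.value, 4)
    row["or_ci_low"] = round(m.odds_ratio.ci_low, 4)
    row["or_ci_high"] = round(m.odds_ratio.ci_high, 4)
    row["p_value"] = m.p_value
    return row


def run_analysis(
    cohort: Cohort | str | Path,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    chanse_cutoffs=CHANSE_CUTOFFS_DEFAULT,
    pas_cutoffs=PAS_CUTOFFS_DEFAULT,
) -> AnalysisReport:
    """Run the full diagnostic-accuracy analysis on one cohort.

    Raises on single-class cohorts (ROC and 2x2 stages need both classes).
    Complete-case per variable: each output row records the n it used.
    """
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort)
    features = derive_features(cohort, thresholds)
    diseased = cohort.diseased
    if diseased.all() or not diseased.any():
        raise ValueError("cohort has a single outcome class; analysis needs both")

    # univariate comparison (the study's demographic/clinical table)
    uni_rows = []
    for var in UNIVARIATE_VARIABLES:
        r = univariate_compare(cohort, var, features=features)
        row = {
            "variable": r.variable, "kind": r.kind,
            "n_diseased": r.n_diseased, "n_not_diseased": r.n_not_diseased,
            "diseased": r.summary_diseased, "not_diseased": r.summary_not_diseased,
            "p_value": r.p_value, "test": r.test,
        }
        if r.odds_ratio is not None:
            row["odds_ratio"] = round(r.odds_ratio.value, 3)
            row["or_ci_low"] = round(r.odds_ratio.ci_low, 3)
            row["or_ci_high"] = round(r.odds_ratio.ci_high, 3)
            row["or_corrected"] = r.or_corrected
        uni_rows.append(row)
    table_univariate = pd.DataFrame(uni_rows)

    # per-parameter diagnostic metrics (complete cases per parameter)
    param_rows = []
    for var in PARAMETER_VARIABLES:
        vals = features[var]
        ok = vals.notna()
        t = build_two_by_two(vals[ok].to_numpy(dtype=bool), diseased[ok].to_numpy())
        param_rows.append(_metrics_row(var, compute_metrics(t)))
    table_parameters = pd.DataFrame(param_rows)

    # scores: complete cases where BOTH scores exist (paired comparison)
    scored = score_cohort(cohort, thresholds)
    both = scored["chanse"].notna() & scored["pas"].notna()
    chanse = scored.loc[both, "chanse"].to_numpy(dtype=int)
    pas = scored.loc[both, "pas"].to_numpy(dtype=int)
    dis = scored.loc[both, "diseased"].to_numpy(dtype=bool)

    thr_rows = []
    for label, scores, cuts in [("chanse", chanse, chanse_cutoffs),
                                ("pas", pas, pas_cutoffs)]:
        for cut, m in threshold_table(scores, dis, cuts):
            row = _metrics_row(f"{label} >= {cut}", m)
            row["score"], row["cutoff"] = label, cut
            thr_rows.append(row)
    table_thresholds = pd.DataFrame(thr_rows)

    roc_chanse = empirical_roc(chanse, dis)
    roc_pas = empirical_roc(pas, dis)
    comparison = delong_paired_test(chanse, pas, dis)
    yc, jc = youden_cutoff(roc_chanse)
    yp, jp = youden_cutoff(roc_pas)
    roc = {
        "n_used": int(both.sum()),
        "chanse": {
            "auc": roc_chanse.auc, "auc_ci": list(roc_chanse.auc_ci),
            "auc_var": roc_chanse.auc_var,
            "cutoffs": roc_chanse.cutoffs.tolist(),
            "sensitivity": roc_chanse.sens_at.tolist(),
            "specificity": roc_chanse.spec_at.tolist(),
            "youden_cutoff": yc, "youden_j": jc,
        },
        "pas": {
            "auc": roc_pas.auc, "auc_ci": list(roc_pas.auc_ci),
            "auc_var": roc_pas.auc_var,
            "cutoffs": roc_pas.cutoffs.tolist(),
            "sensitivity": roc_pas.sens_at.tolist(),
            "specificity": roc_pas.spec_at.tolist(),
            "youden_cutoff": yp, "youden_j": jp,
        },
        "comparison": {
            "auc_a": comparison.auc_a, "auc_b": comparison.auc_b,
            "delta": comparison.delta, "z": comparison.z,
            "p_value": comparison.p_value, "covariance": comparison.covariance,
            "method": comparison.method,
        },
    }

    sev_rows = []
    for outcome in ("none", "uncomplicated", "complicated"):
        mask = both & (scored["outcome"] == outcome)
        vals = scored.loc[mask, "chanse"].to_numpy(dtype=float)
        sev_rows.append({
            "outcome": outcome, "n": int(mask.sum()),
            "chanse_mean": float(vals.mean()) if len(vals) else math.nan,
            "chanse_sd": float(vals.std(ddof=1)) if len(vals) > 1 else math.nan,
        })
    severity = pd.DataFrame(sev_rows)

    from . import __version__

    metadata = {
        "package_version": __version__,
        "provenance": cohort.provenance,
        "n_total": len(cohort),
        "n_diseased": int(diseased.sum()),
        "n_scored": int(both.sum()),
        "thresholds": thresholds.to_dict(),
        "chanse_cutoffs": list(chanse_cutoffs),
        "pas_cutoffs": list(pas_cutoffs),
        "methods": {
            "proportion_ci": "Clopper-Pearson exact",
            "lr_ci": "Simel log method",
            "or_ci": "Woolf log method",
            "binary_test": "Pearson chi-square; Fisher exact if any expected cell < 5",
            "continuous_test": "Welch t-test",
            "auc": "Mann-Whitney with half credit for ties",
            "auc_comparison": "DeLong paired z-test, two-sided",
            "youden_tiebreak": "lowest qualifying cutoff",
            "missing_data": "complete-case per variable",
        },
    }
    return AnalysisReport(table_univariate, table_parameters, table_thresholds,
                          roc, severity, metadata)


def render_markdown(report: AnalysisReport) -> str:
    """Human-readable summary of an analysis report."""
    lines = ["# CHANSE analysis report", ""]
    md = report.metadata
    lines.append(f"Cohort: {md['provenance']} (n={md['n_total']}, "
                 f"{md['n_diseased']} diseased)")
    lines.append("")
    lines.append("## Univariate comparison")
    lines.append(report.table_univariate.to_markdown(index=False))
    lines.append("")
    lines.append("## Per-parameter diagnostic metrics")
    cols = ["parameter", "sensitivity", "specificity", "ppv", "npv", "plr",
            "nlr", "odds_ratio", "p_value"]
    lines.append(report.table_parameters[cols].to_markdown(index=False))
    lines.append("")
    lines.append("## Score thresholds")
    lines.append(report.table_thresholds[["parameter"] + cols[1:7]].to_markdown(index=False))
    lines.append("")
    c, p, cmp_ = report.roc["chanse"], report.roc["pas"], report.roc["comparison"]
    lines.append("## ROC comparison")
    lines.append(f"CHANSE AUC {c['auc']:.3f} ({c['auc_ci'][0]:.3f}-{c['auc_ci'][1]:.3f}), "
                 f"Youden cutoff >= {c['youden_cutoff']} (J={c['youden_j']:.3f})")
    lines.append(f"PAS    AUC {p['auc']:.3f} ({p['auc_ci'][0]:.3f}-{p['auc_ci'][1]:.3f}), "
                 f"Youden cutoff >= {p['youden_cutoff']} (J={p['youden_j']:.3f})")
    lines.append(f"DeLong paired test: delta={cmp_['delta']:.3f}, z={cmp_['z']:.3f}, "
                 f"p={cmp_['p_value']:.4g}")
    lines.append("")
    lines.append("## CHANSE by severity class")
    lines.append(report.severity.to_markdown(index=False))
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# reproduction of the published tables from the embedded counts


def _cmp(computed: float, printed: float, tol: float) -> str:
    return "match" if abs(computed - printed) <= tol + 1e-12 else "mismatch"


def reproduce_printed_tables() -> pd.DataFrame:
    """Recompute count-derivable published cells and compare at printed precision.

    Returns a ledger with one row per compared (or skipped) cell: columns
    table, variable, cell, computed, printed, tol, status, reason.  Status is
    ``match``/``mismatch``/``skipped``; catalogued internal inconsistencies
    of the published tables are skipped with their reason.
    """
    tables = reference.load_tables()
    known = reference.KNOWN_INCONSISTENCIES
    rows: list[dict] = []

    def add(table, var, cell, computed, printed, tol):
        key = (table, var, cell)
        row_key = (table, var, "*")
        if row_key in known or key in known:
            reason = known.get(key, known.get(row_key))
            rows.append(dict(table=table, variable=var, cell=cell,
                             computed=computed, printed=printed, tol=tol,
                             status="skipped", reason=reason))
            return
        rows.append(dict(table=table, variable=var, cell=cell,
                         computed=computed, printed=printed, tol=tol,
                         status=_cmp(computed, printed, tol), reason=""))

    for var, printed in tables["univariate_printed_or"].items():
        est, _ = odds_ratio(reference.two_by_two(var))
        add("univariate", var, "or", round(est.value, 3), printed["or"], 0.001)
        add("univariate", var, "or_ci_low", round(est.ci_low, 3), printed["ci"][0], 0.01)
        add("univariate", var, "or_ci_high", round(est.ci_high, 3), printed["ci"][1], 0.01)

    for var, printed in tables["parameter_table_printed"].items():
        m = compute_metrics(reference.two_by_two(var))
        for cell in ("sensitivity", "specificity", "ppv", "npv"):
            e = getattr(m, cell)
            pt, lo, hi = printed[cell]
            add("parameters", var, cell, round(e.value, 2), pt, 0.0)
            if cell in ("sensitivity", "specificity"):
                add("parameters", var, f"{cell}_ci_low", round(e.ci_low, 2), lo, 0.01)
                add("parameters", var, f"{cell}_ci_high", round(e.ci_high, 2), hi, 0.01)
            else:
                rows.append(dict(table="parameters", variable=var,
                                 cell=f"{cell}_ci", computed=math.nan,
                                 printed=math.nan, tol=math.nan,
                                 status="skipped",
                                 reason=reference.PPV_NPV_CI_NOTE))
        for cell in ("plr", "nlr"):
            e = getattr(m, cell)
            pt, lo, hi = printed[cell]
            add("parameters", var, cell, round(e.value, 2), pt, 0.01)
            add("parameters", var, f"{cell}_ci_low", round(e.ci_low, 2), lo, 0.02)
            add("parameters", var, f"{cell}_ci_high", round(e.ci_high, 2), hi, 0.02)

    return pd.DataFrame(rows)


def reproduction_ok(ledger: Optional[pd.DataFrame] = None) -> bool:
    """True when no compared cell mismatches (skips are documented, not passes)."""
    if ledger is None:
        ledger = reproduce_printed_tables()
    return not (ledger["status"] == "mismatch").any()
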