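"""Synthetic cohort generator emulating the derivation study's structure.

The derivation study publishes only group-level summaries: per-group sizes
(84 appendicitis / 58 none; 52 uncomplicated / 32 complicated), binary
feature prevalences, and lab means/SDs.  This module simulates patient-level
cohorts with exactly those marginals so every pipeline stage is testable
without patient-level data.

Model
-----
* Binary features are drawn through a latent Gaussian copula: each feature j
  has latent Z_j = sqrt(rho) U + sqrt(1 - rho) E_j (exchangeable scalar rho,
  default 0 = independent Bernoulli) or a user-supplied latent correlation
  matrix; the flag is Z_j <= Phi^{-1}(p_j), so the group-conditional
  prevalence is exactly p_j.
* CRP uses ONE latent with two cutpoints, so the >= 1 and >= 5 mg/dL flags
  are jointly consistent and both match their marginals.
* In the default ``match_marginals`` mode, labs linked to a flag (WBC,
  neutrophil %, CRP, temperature) are drawn from the group normal truncated
  to the interval the flag dictates, so derived flags reproduce the drawn
  flags exactly AND flag marginals match the published prevalences.  In
  ``from_labs`` mode labs are unconditional (truncated-at-zero) normals and
  flags fall where the tails put them.
* Joint dependence is not published; rho is an explicit knob, default 0.

Severity: the published subgroup CHANSE means (3.0 uncomplicated vs 4.6
complicated) are matched by per-subgroup logit shifts of the six CHANSE
component prevalences, fitted in closed form (the mean of a sum of
Bernoullis is free of the copula correlation).

Reproducibility: one master seed; independent sub-streams per (group,
variable), so adding a variable never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .cohort import Cohort
from .config import Thresholds, DEFAULT_THRESHOLDS
from .scoring import CHANSE_COMPONENTS
from . import reference

# symptom/exam flags stored directly on the record
DIRECT_BINARY = (
    "male",
    "anorexia",
    "nausea_or_vomiting",
    "diarrhea",
    "migration",
    "rlq_tenderness",
    "cough_percussion_hopping",
    "psoas",
    "rovsing",
    "obturator",
    "heel_drop",
)

# lab flags realized through the continuous lab value
FLAG_TO_LAB = {
    "fever": "body_temp_c",
    "leukocytosis": "wbc_per_ul",
    "left_shift": "neutrophil_pct",
}

UNLINKED_LABS = ("age_years", "pain_duration_h")

# latent variables, in canonical order (crp carries both CRP flags)
LATENT_VARS = DIRECT_BINARY + ("fever", "leukocytosis", "left_shift", "crp")

_GROUPS = ("not_diseased", "uncomplicated", "complicated")


@dataclass(frozen=True)
class LabParams:
    mean_diseased: float
    sd_diseased: float
    mean_not_diseased: float
    sd_not_diseased: float

    def for_group(self, diseased: bool) -> tuple[float, float]:
        if diseased:
            return self.mean_diseased, self.sd_diseased
        return self.mean_not_diseased, self.sd_not_diseased


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated cohort (defaults = the derivation study)."""

    n_disease: int = 84
    n_no_disease: int = 58
    n_complicated: int = 32
    binary_prevalence: dict[str, tuple[float, float]] = field(default_factory=dict)
    lab_params: dict[str, LabParams] = field(default_factory=dict)
    rho: Union[float, np.ndarray] = 0.0
    severity_logit_shift: tuple[float, float] = (0.0, 0.0)
    lab_flag_mode: str = "match_marginals"  # or "from_labs"
    seed: int = 0

    @property
    def n_uncomplicated(self) -> int:
        return self.n_disease - self.n_complicated

    @property
    def n_total(self) -> int:
        return self.n_disease + self.n_no_disease

    def validate(self) -> None:
        if self.n_disease < 1 or self.n_no_disease < 1:
            raise ValueError("both groups need at least one patient")
        if not 0 <= self.n_complicated <= self.n_disease:
            raise ValueError("n_complicated must lie in [0, n_disease]")
        if self.lab_flag_mode not in ("match_marginals", "from_labs"):
            raise ValueError(f"unknown lab_flag_mode {self.lab_flag_mode!r}")
        for var, (p1, p0) in self.binary_prevalence.items():
            if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
                raise ValueError(f"{var}: prevalences must be in [0, 1]")
        for lab, lp in self.lab_params.items():
            if lp.sd_diseased <= 0 or lp.sd_not_diseased <= 0:
                raise ValueError(f"{lab}: SDs must be positive")
        p1_1, p1_0 = self.binary_prevalence["crp_elevated_1"]
        p5_1, p5_0 = self.binary_prevalence["crp_elevated_5"]
        if p5_1 > p1_1 or p5_0 > p1_0:
            raise ValueError("crp_elevated_5 prevalence exceeds crp_elevated_1")
        if isinstance(self.rho, np.ndarray):
            _validate_corr_matrix(self.rho)
        elif not 0 <= float(self.rho) < 1:
            raise ValueError("scalar (exchangeable) rho must be in [0, 1)")


def _validate_corr_matrix(r: np.ndarray) -> None:
    k = len(LATENT_VARS)
    if r.shape != (k, k):
        raise ValueError(f"correlation matrix must be {k}x{k} over {LATENT_VARS}")
    if not np.allclose(r, r.T):
        raise ValueError("correlation matrix must be symmetric")
    bad = np.abs(r) > 1 + 1e-12
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"infeasible correlation for pair ({LATENT_VARS[i]}, {LATENT_VARS[j]}): "
            f"{r[i, j]}"
        )
    if np.linalg.eigvalsh(r).min() < -1e-8:
        raise ValueError("correlation matrix is not positive semi-definite")


def default_spec() -> CohortSpec:
    """Spec populated with the derivation study's published summaries."""
    counts = reference.binary_counts()
    sizes = reference.group_sizes()
    n1, n0 = sizes["diseased"], sizes["not_diseased"]
    prev = {var: (k1 / n1, k0 / n0) for var, (k1, k0) in counts.items()}
    labs = {
        lab: LabParams(
            row["mean_diseased"], row["sd_diseased"],
            row["mean_not_diseased"], row["sd_not_diseased"],
        )
        for lab, row in reference.load_tables()["continuous_labs"].items()
    }
    return CohortSpec(
        n_disease=n1,
        n_no_disease=n0,
        n_complicated=sizes["complicated"],
        binary_prevalence=prev,
        lab_params=labs,
    )


def _rng(seed: int, group: str, var: str) -> np.random.Generator:
    key = zlib.crc32(f"{group}/{var}".encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, key)))


def _group_prevalence(spec: CohortSpec, group: str) -> dict[str, float]:
    """Group-conditional prevalences, with the severity logit shift applied
    to the six CHANSE components in the diseased subgroups."""
    diseased = group != "not_diseased"
    prev = {v: (p1 if diseased else p0) for v, (p1, p0) in spec.binary_prevalence.items()}
    if diseased:
        shift = spec.severity_logit_shift[0 if group == "uncomplicated" else 1]
        if shift != 0.0:
            for var in CHANSE_COMPONENTS:
                prev[var] = _shifted(prev[var], shift)
            if prev["crp_elevated_5"] > prev["crp_elevated_1"]:
                # keep the CRP cutpoints ordered under extreme negative shifts
                prev["crp_elevated_5"] = prev["crp_elevated_1"]
    return prev


def _shifted(p: float, delta: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return p
    return float(expit(logit(p) + delta))


def _latent_normals(spec: CohortSpec, group: str, n: int) -> dict[str, np.ndarray]:
    if isinstance(spec.rho, np.ndarray):
        # full latent correlation: one group-level stream, Cholesky factor
        rng = _rng(spec.seed, group, "_latent_matrix")
        jitter = np.eye(len(LATENT_VARS)) * 1e-10
        chol = np.linalg.cholesky(spec.rho + jitter)
        z = rng.standard_normal((n, len(LATENT_VARS))) @ chol.T
        return {var: z[:, i] for i, var in enumerate(LATENT_VARS)}
    rho = float(spec.rho)
    u = _rng(spec.seed, group, "_factor").standard_normal(n) if rho > 0 else 0.0
    out = {}
    for var in LATENT_VARS:
        e = _rng(spec.seed, group, var).standard_normal(n)
        out[var] = np.sqrt(rho) * u + np.sqrt(1 - rho) * e if rho > 0 else e
    return out


def _truncnorm_sample(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lab_given_flag(
    rng: np.random.Generator,
    flag: np.ndarray,
    mean: float,
    sd: float,
    threshold: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Draw a lab from its group normal truncated to the side its flag dictates."""
    x = np.empty(len(flag))
    n_t = int(flag.sum())
    if n_t:
        x[flag] = _truncnorm_sample(rng, mean, sd, threshold, hi, n_t)
    if n_t < len(flag):
        below = _truncnorm_sample(rng, mean, sd, lo, threshold, len(flag) - n_t)
        # the false side is the open interval [lo, threshold)
        x[~flag] = np.minimum(below, np.nextafter(threshold, -np.inf))
    return x


def _generate_group(
    spec: CohortSpec, group: str, n: int, thresholds: Thresholds
) -> pd.DataFrame:
    diseased = group != "not_diseased"
    prev = _group_prevalence(spec, group)
    z = _latent_normals(spec, group, n)

    flags = {var: z[var] <= stats.norm.ppf(prev[var]) for var in DIRECT_BINARY}
    df = pd.DataFrame({v: pd.array(flags[v], dtype="boolean") for v in DIRECT_BINARY})

    if spec.lab_flag_mode == "match_marginals":
        lab_flags = {
            var: z[var] <= stats.norm.ppf(prev[var]) for var in FLAG_TO_LAB
        }
        # CRP: one latent, two cutpoints -> jointly consistent flags
        zc = z["crp"]
        crp_ge_5 = zc <= stats.norm.ppf(prev["crp_elevated_5"])
        crp_ge_1 = zc <= stats.norm.ppf(prev["crp_elevated_1"])

        thr = {
            "body_temp_c": thresholds.body_temp_c,
            "wbc_per_ul": thresholds.wbc_per_ul,
            "neutrophil_pct": thresholds.neutrophil_pct,
        }
        bounds = {
            "body_temp_c": (-np.inf, np.inf),
            "wbc_per_ul": (0.0, np.inf),
            "neutrophil_pct": (0.0, 100.0),
        }
        for flag_name, lab in FLAG_TO_LAB.items():
            mean, sd = spec.lab_params[lab].for_group(diseased)
            lo, hi = bounds[lab]
            df[lab] = _lab_given_flag(
                _rng(spec.seed, group, lab), lab_flags[flag_name],
                mean, sd, thr[lab], lo, hi,
            )
        # CRP in three bands: [0, low), [low, high), [high, inf)
        mean, sd = spec.lab_params["crp_mg_dl"].for_group(diseased)
        rng = _rng(spec.seed, group, "crp_mg_dl")
        crp = np.empty(n)
        low, high = thresholds.crp_mg_dl_low, thresholds.crp_mg_dl_high
        band_hi = crp_ge_5
        band_mid = crp_ge_1 & ~crp_ge_5
        band_lo = ~crp_ge_1
        if band_hi.any():
            crp[band_hi] = _truncnorm_sample(rng, mean, sd, high, np.inf, int(band_hi.sum()))
        if band_mid.any():
            x = _truncnorm_sample(rng, mean, sd, low, high, int(band_mid.sum()))
            crp[band_mid] = np.minimum(x, np.nextafter(high, -np.inf))
        if band_lo.any():
            x = _truncnorm_sample(rng, mean, sd, 0.0, low, int(band_lo.sum()))
            crp[band_lo] = np.minimum(x, np.nextafter(low, -np.inf))
        df["crp_mg_dl"] = crp
    else:  # from_labs: unconditional labs, flags fall where the tails put them
        for lab in ("body_temp_c", "wbc_per_ul", "neutrophil_pct", "crp_mg_dl"):
            mean, sd = spec.lab_params[lab].for_group(diseased)
            lo = -np.inf if lab == "body_temp_c" else 0.0
            hi = 100.0 if lab == "neutrophil_pct" else np.inf
            df[lab] = _truncnorm_sample(_rng(spec.seed, group, lab), mean, sd, lo, hi, n)

    for lab in UNLINKED_LABS:
        mean, sd = spec.lab_params[lab].for_group(diseased)
        df[lab] = _truncnorm_sample(_rng(spec.seed, group, lab), mean, sd, 0.0, np.inf, n)

    df["sex"] = pd.array(
        np.where(df["male"].to_numpy(dtype=bool), "male", "female"), dtype="string"
    )
    df = df.drop(columns=["male"])
    df["outcome"] = "none" if not diseased else group
    return df


def generate_cohort(
    spec: CohortSpec,
    seed: int | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> Cohort:
    """Simulate one cohort; fully reproducible from the seed.

    Group sizes are exact; binary features and flag-linked labs follow the
    copula/truncation model in the module docstring.
    """
    if seed is not None:
        spec = replace(spec, seed=seed)
    spec.validate()
    parts = [
        _generate_group(spec, "not_diseased", spec.n_no_disease, thresholds),
        _generate_group(spec, "uncomplicated", spec.n_uncomplicated, thresholds),
        _generate_group(spec, "complicated", spec.n_complicated, thresholds),
    ]
    df = pd.concat([p for p in parts if len(p)], ignore_index=True)
    df.insert(0, "patient_id", [f"S{i:05d}" for i in range(len(df))])
    from .cohort import SCHEMA

    df = df[[c for c in SCHEMA]]
    return Cohort(df, provenance=f"synthetic:seed={spec.seed}")


def expected_chanse_mean(spec: CohortSpec, group: str) -> float:
    """Closed-form mean CHANSE in a group (sum of component prevalences).

    Exact for any copula rho: the expectation of a sum of Bernoullis does
    not depend on their dependence structure.
    """
    prev = _group_prevalence(spec, group)
    return float(sum(prev[v] for v in CHANSE_COMPONENTS))


def _fit_shift(base_prev: dict[str, float], target: float) -> float:
    comps = [base_prev[v] for v in CHANSE_COMPONENTS]
    lo_mean = sum(1.0 for p in comps if p >= 1.0)
    hi_mean = sum(1.0 for p in comps if p > 0.0)
    if not lo_mean < target < hi_mean:
        raise ValueError(
            f"target mean {target} unreachable (attainable open range "
            f"({lo_mean}, {hi_mean}) for these component prevalences)"
        )

    def mean_at(delta: float) -> float:
        return sum(_shifted(p, delta) for p in comps)

    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_severity_shift(
    spec: CohortSpec, target_means: tuple[float, float] = (3.0, 4.6)
) -> CohortSpec:
    """Fit per-subgroup logit shifts so subgroup CHANSE means hit the targets.

    ``target_means`` is (uncomplicated, complicated).  A single shift per
    subgroup is applied to all six CHANSE component prevalences (baseline:
    the pooled diseased prevalences) and fitted by monotone bisection on the
    closed-form mean.  Targets equal to the baseline mean return zero shift.
    """
    spec.validate()
    base = {v: p1 for v, (p1, _) in spec.binary_prevalence.items()}
    shifts = tuple(_fit_shift(base, t) for t in target_means)
    return replace(spec, severity_logit_shift=shifts)
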