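"""The CHANSE score and the comparator Pediatric Appendicitis Score (PAS).

CHANSE: one point each for CRP >= 1 mg/dL, positive heel drop test,
anorexia, nausea or vomiting, shift to the left (PMN >= 75%) and elevated
WBC (>= 10,000/uL); range 0-6, default high-risk cutoff >= 3.

PAS (Samuel 2002): migration 1, anorexia 1, nausea/vomiting 1, RLQ
tenderness 2, cough/percussion/hopping tenderness 2, fever (>= 38.0 C) 1,
leukocytosis 1, neutrophilia 1; range 0-10, default high-risk cutoff >= 7.
The fever threshold follows the derivation cohort's definition (38.0 C).

Both scores propagate missing components: a record missing any component is
scored as missing and excluded from score-based analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .config import Thresholds, DEFAULT_THRESHOLDS
from .cohort import Cohort, derive_features

CHANSE_COMPONENTS = (
    "crp_elevated_1",
    "heel_drop",
    "anorexia",
    "nausea_or_vomiting",
    "left_shift",
    "leukocytosis",
)

PAS_WEIGHTS: dict[str, int] = {
    "migration": 1,
    "anorexia": 1,
    "nausea_or_vomiting": 1,
    "rlq_tenderness": 2,
    "cough_percussion_hopping": 2,
    "fever": 1,
    "leukocytosis": 1,
    "left_shift": 1,
}

CHANSE_CUTOFF_DEFAULT = 3
PAS_CUTOFF_DEFAULT = 7

FeatureVector = Mapping[str, Optional[bool]]


@dataclass(frozen=True)
class ChanseScore:
    value: int
    components: dict[str, bool]

    def __post_init__(self) -> None:
        assert self.value == sum(self.components.values())
        assert 0 <= self.value <= 6


@dataclass(frozen=True)
class PasScore:
    value: int
    components: dict[str, bool]

    def __post_init__(self) -> None:
        assert self.value == sum(
            PAS_WEIGHTS[k] for k, v in self.components.items() if v
        )
        assert 0 <= self.value <= 10


def _get_components(features: FeatureVector, names) -> Optional[dict[str, bool]]:
    comps = {}
    for name in names:
        v = features.get(name) if hasattr(features, "get") else features[name]
        if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
            return None
        comps[name] = bool(v)
    return comps


def chanse_score(features: FeatureVector) -> Optional[ChanseScore]:
    """Score one feature vector; returns None when any component is missing."""
    comps = _get_components(features, CHANSE_COMPONENTS)
    if comps is None:
        return None
    return ChanseScore(value=sum(comps.values()), components=comps)


def pas_score(features: FeatureVector) -> Optional[PasScore]:
    """PAS for one feature vector; returns None when any component is missing."""
    comps = _get_components(features, PAS_WEIGHTS)
    if comps is None:
        return None
    return PasScore(
        value=sum(w for k, w in PAS_WEIGHTS.items() if comps[k]), components=comps
    )


def classify(score, cutoff: int) -> Union[bool, np.ndarray]:
    """Dichotomize a score at an inclusive cutoff: positive iff score >= cutoff."""
    result = np.greater_equal(score, cutoff)
    return bool(result) if np.isscalar(score) or result.ndim == 0 else result


def score_features_frame(features: pd.DataFrame) -> pd.DataFrame:
    """Vectorized CHANSE and PAS over a feature table (nullable Int64 output)."""
    chanse = features[list(CHANSE_COMPONENTS)].astype("boolean")
    chanse_val = chanse.sum(axis=1).astype("Int64")
    chanse_val[chanse.isna().any(axis=1)] = pd.NA

    pas_cols = features[list(PAS_WEIGHTS)].astype("boolean")
    weights = pd.Series(PAS_WEIGHTS)
    pas_val = (pas_cols * weights).sum(axis=1).astype("Int64")
    pas_val[pas_cols.isna().any(axis=1)] = pd.NA
    return pd.DataFrame({"chanse": chanse_val, "pas": pas_val}, index=features.index)


def score_cohort(
    cohort: Cohort, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """One row per patient: patient_id, chanse, pas, diseased, outcome.

    Scores are nullable integers; a record missing any component of a score
    has that score missing.
    """
    features = derive_features(cohort, thresholds)
    scores = score_features_frame(features)
    return pd.DataFrame(
        {
            "patient_id": cohort.df["patient_id"],
            "chanse": scores["chanse"],
            "pas": scores["pas"],
            "diseased": cohort.diseased,
            "outcome": cohort.df["outcome"],
        }
    )
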