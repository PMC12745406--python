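"""Dichotomization thresholds for laboratory and vital-sign features.

Defaults follow the derivation study: leukocytosis WBC >= 10,000/uL,
shift-to-left (neutrophilia) PMN >= 75%, CRP >= 1 mg/dL (the CHANSE
component) and CRP >= 5 mg/dL (the univariate cut), fever >= 38.0 C.
All thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class Thresholds:
    wbc_per_ul: float = 10_000.0
    neutrophil_pct: float = 75.0
    crp_mg_dl_low: float = 1.0
    crp_mg_dl_high: float = 5.0
    body_temp_c: float = 38.0

    def __post_init__(self) -> None:
        if self.crp_mg_dl_low > self.crp_mg_dl_high:
            raise ValueError(
                "crp_mg_dl_low must not exceed crp_mg_dl_high "
                f"({self.crp_mg_dl_low} > {self.crp_mg_dl_high})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        """Load threshold overrides from a YAML mapping; absent keys keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_THRESHOLDS = Thresholds()
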