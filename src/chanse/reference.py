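"""Embedded summary statistics of the CHANSE derivation cohort.

The derivation study deposits no patient-level data; what it publishes are
group sizes, per-variable positive counts, group-conditional lab means/SDs
and the derived diagnostic metrics.  Those summaries are packaged here as
data: they parameterize the synthetic-cohort generator and drive the
printed-value reproduction checks.

Known internal inconsistencies of the published tables (cells that cannot
be reproduced from the published counts by any rounding) are catalogued in
:data:`KNOWN_INCONSISTENCIES` with the recomputed value, so reproduction
reports skip them with a stated reason instead of silently passing them.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .metrics import TwoByTwoTable


@lru_cache(maxsize=1)
def load_tables() -> dict:
    """The packaged derivation-cohort summary tables (parsed JSON, cached)."""
    ref = resources.files("chanse.data").joinpath("derivation_tables.json")
    return json.loads(ref.read_text(encoding="utf-8"))


def group_sizes() -> dict:
    return dict(load_tables()["group_sizes"])


def binary_counts() -> dict:
    """Per-variable positive counts: {var: (k_diseased, k_not_diseased)}."""
    return {
        var: (row["diseased"], row["not_diseased"])
        for var, row in load_tables()["binary_counts"].items()
    }


def two_by_two(variable: str) -> TwoByTwoTable:
    """2x2 table of one published binary variable against disease status."""
    tbl = load_tables()
    sizes = tbl["group_sizes"]
    row = tbl["binary_counts"][variable]
    return TwoByTwoTable.from_prevalences(
        row["diseased"], sizes["diseased"], row["not_diseased"], sizes["not_diseased"]
    )


# Cells of the published tables that are internally inconsistent: the value
# recomputed from the published counts differs from the printed one beyond
# printed precision.  Each entry: (table, variable, cell) -> reason.
KNOWN_INCONSISTENCIES: dict[tuple[str, str, str], str] = {
    ("parameters", "fever", "*"): (
        "printed sensitivity 0.14 contradicts the univariate prevalence "
        "35/84 = 0.42, and the CI '0.8-0.24' contains a typo; the whole row "
        "is irreconcilable with the published counts"
    ),
    ("parameters", "migration", "sensitivity"): (
        "printed 0.27 vs 22/84 = 0.26 from the published counts"
    ),
    ("parameters", "migration", "plr"): (
        "printed 1.02 vs 1.01 recomputed from the published counts"
    ),
    ("parameters", "migration", "nlr"): (
        "printed 0.99 vs 1.00 recomputed from the published counts"
    ),
    ("parameters", "cough_percussion_hopping", "plr"): (
        "printed 1.22 vs 1.20 recomputed from the published counts"
    ),
    ("parameters", "cough_percussion_hopping", "nlr"): (
        "printed 0.56 vs 0.58 recomputed from the published counts"
    ),
    ("parameters", "cough_percussion_hopping", "plr_ci_low"): (
        "printed 1.02 vs 0.98 recomputed; same inconsistency as the PLR point"
    ),
    ("parameters", "cough_percussion_hopping", "nlr_ci_high"): (
        "printed 0.98 vs 1.03 recomputed; same inconsistency as the NLR point"
    ),
    ("univariate", "cough_percussion_hopping", "or_ci_low"): (
        "printed 1.056 vs Woolf 0.956 from the published counts; likely a typo"
    ),
}

# PPV/NPV interval bounds are not compared at all: the published intervals
# match neither Clopper-Pearson, Wilson, Wald nor logit methods and the
# method used is unstated.  Point estimates are still compared.
PPV_NPV_CI_NOTE = (
    "interval method for predictive values unstated and not reproducible; "
    "point estimates compared, intervals not"
)
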