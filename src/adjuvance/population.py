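"""Covariate subgroups of the stage II colon cancer population.

The cohort model distinguishes 216 subgroups formed by the full
cross-product of five prognostic covariates: number of lymph nodes
evaluated (<10 / >=10), T stage (T3 / T4), tumour site (left / right),
age at diagnosis (nine 5-year bins spanning 50-95) and biomarker status
(MSI, MSS without BRAF/KRAS mutation, MSS with mutation).  Population
weights over the grid describe the Dutch stage II case mix; the analysis
itself is restricted to the high-risk (T4 + MSS) cells.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

NODES_LEVELS = ("lt10", "ge10")
T_STAGE_LEVELS = ("T3", "T4")
SITE_LEVELS = ("left", "right")
AGE_LEVELS = tuple(f"{a}-{a + 5}" for a in range(50, 95, 5))  # nine half-open bins [a, a+5)
BIOMARKER_LEVELS = ("MSI", "MSS_no_mutation", "MSS_mutation")
MSS_LEVELS = ("MSS_no_mutation", "MSS_mutation")

COVARIATE_FIELDS = ("nodes_evaluated", "t_stage", "site", "age_category", "biomarker")

#: tolerance for "weights sum to one"
WEIGHT_SUM_TOL = 1e-12


class EmptyCohortError(ValueError):
    """Raised when a selection leaves no population mass."""


@dataclass(frozen=True)
class Subgroup:
    """One cell of the 2 x 2 x 2 x 9 x 3 covariate grid."""

    nodes_evaluated: str
    t_stage: str
    site: str
    age_category: str
    biomarker: str

    def __post_init__(self) -> None:
        checks = (
            (self.nodes_evaluated, NODES_LEVELS),
            (self.t_stage, T_STAGE_LEVELS),
            (self.site, SITE_LEVELS),
            (self.age_category, AGE_LEVELS),
            (self.biomarker, BIOMARKER_LEVELS),
        )
        for value, levels in checks:
            if value not in levels:
                raise ValueError(f"invalid subgroup level {value!r}; expected one of {levels}")

    @property
    def age_index(self) -> int:
        """0-based index of the 5-year age bin (0 for [50, 55), 8 for [90, 95))."""
        return AGE_LEVELS.index(self.age_category)

    @property
    def age_lower(self) -> float:
        return 50.0 + 5.0 * self.age_index

    @property
    def age_midpoint(self) -> float:
        """Midpoint of the half-open age bin, used as the attained-age origin."""
        return self.age_lower + 2.5

    @property
    def is_high_risk(self) -> bool:
        return self.t_stage == "T4" and self.biomarker in MSS_LEVELS

    def as_tuple(self) -> tuple[str, str, str, str, str]:
        return (self.nodes_evaluated, self.t_stage, self.site, self.age_category, self.biomarker)


@functools.lru_cache(maxsize=1)
def enumerate_subgroups() -> tuple[Subgroup, ...]:
    """All 216 subgroups in a fixed lexicographic order.

    The order is the declaration order of the levels above, iterated as
    (nodes, T stage, site, age, biomarker) with biomarker varying fastest,
    so serialized weight tables are reproducible bit for bit.
    """
    return tuple(
        Subgroup(*combo)
        for combo in itertools.product(
            NODES_LEVELS, T_STAGE_LEVELS, SITE_LEVELS, AGE_LEVELS, BIOMARKER_LEVELS
        )
    )


@dataclass(frozen=True)
class WeightValidation:
    """Report-only result of :func:`validate_weights`."""

    negative_cells: tuple[Subgroup, ...] = ()
    missing_cells: tuple[Subgroup, ...] = ()
    sum_deviation: float = 0.0

    @property
    def ok(self) -> bool:
        return (
            not self.negative_cells
            and not self.missing_cells
            and abs(self.sum_deviation) <= WEIGHT_SUM_TOL
        )


@dataclass(frozen=True)
class SubgroupWeights:
    """Probability weights over a set of subgroups (usually all 216)."""

    weights: Mapping[Subgroup, float]

    def __getitem__(self, subgroup: Subgroup) -> float:
        return self.weights[subgroup]

    def __iter__(self):
        return iter(self.weights)

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def subgroups(self) -> tuple[Subgroup, ...]:
        """Subgroups carrying weight, in enumeration order."""
        return tuple(s for s in enumerate_subgroups() if s in self.weights)

    def total(self) -> float:
        return float(sum(self.weights.values()))

    @classmethod
    def uniform(cls, subgroups: Iterable[Subgroup] | None = None) -> "SubgroupWeights":
        cells = tuple(subgroups) if subgroups is not None else enumerate_subgroups()
        w = 1.0 / len(cells)
        return cls({s: w for s in cells})

    def renormalised(self) -> "SubgroupWeights":
        total = self.total()
        if total <= 0.0:
            raise EmptyCohortError("total weight is zero; cannot renormalise")
        return SubgroupWeights({s: w / total for s, w in self.weights.items()})

    # -- flat-table IO ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [(*s.as_tuple(), self.weights[s]) for s in self.subgroups]
        return pd.DataFrame(rows, columns=[*COVARIATE_FIELDS, "weight"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SubgroupWeights":
        missing = (set(COVARIATE_FIELDS) | {"weight"}) - set(frame.columns)
        if missing:
            raise ValueError(f"weight table is missing columns: {sorted(missing)}")
        weights = {
            Subgroup(*(str(row[f]) for f in COVARIATE_FIELDS)): float(row["weight"])
            for _, row in frame.iterrows()
        }
        if len(weights) != len(frame):
            raise ValueError("weight table contains duplicate subgroup rows")
        return cls(weights)

    def to_csv(self, path) -> None:
        # %.17g keeps the text round-trip lossless for float64 weights
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "SubgroupWeights":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


def validate_weights(weights: SubgroupWeights) -> WeightValidation:
    """Report negative weights, missing grid cells and the deviation of the sum from 1."""
    negative = tuple(s for s in weights.subgroups if weights[s] < 0.0)
    missing = tuple(s for s in enumerate_subgroups() if s not in weights.weights)
    deviation = weights.total() - 1.0
    return WeightValidation(negative_cells=negative, missing_cells=missing, sum_deviation=deviation)


def select_high_risk(weights: SubgroupWeights) -> SubgroupWeights:
    """Restrict weights to the T4+MSS cells and renormalise to sum to 1.

    Both MSS biomarker categories (with and without BRAF/KRAS mutation)
    count as MSS: microsatellite stability is the selection criterion and
    mutation status only modifies hazards.  Idempotent.
    """
    selected = {s: w for s, w in weights.weights.items() if s.is_high_risk}
    total = sum(selected.values())
    if total <= 0.0:
        raise EmptyCohortError("no population mass on T4+MSS subgroups")
    return SubgroupWeights({s: w / total for s, w in selected.items()})
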