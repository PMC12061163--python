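"""Feature families, five-level assignments, and wildcard combinations.

Component features are grouped into eight thematic families. For each
patient and family, the *component count* is the number of member features
present in the record (binary: value 1; count: value >= 1; continuous:
non-missing and > 0). The count is expressed as five binary levels:

* ``None``    — no member feature present (count = 0);
* ``NotNone`` — at least one member present;
* ``Few`` / ``Some`` / ``Many`` — the positive count falls in the lower /
  middle / upper band of family-specific cutpoints (tertiles of the
  positive counts by default, fixed once over all patients).

Feature-family *combinations* conjoin one level selector per family, with a
wildcard ``x`` meaning the family's level is irrelevant. ``A1_C0`` is true
for records with Antecedent-family features but none from the Concurrent
family; ``A1_Cx`` drops the Concurrent constraint.
"""
from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FAMILIES, FeatureMatrix

LEVELS = ("None", "NotNone", "Few", "Some", "Many")
LEVEL_CODES = {"None": "0", "NotNone": "1", "Few": "f", "Some": "s", "Many": "m"}
WILDCARD = "x"
# wildcard first: enumeration visits wildcard-heavy combinations earliest
ENUMERATION_ORDER = (WILDCARD,) + LEVELS

FAMILY_LETTERS = {
    "Antecedent": "A",
    "Concurrent": "C",
    "ServiceUse": "S",
    "Treatment": "T",
    "Inconsistency": "I",
    "PatternsOfPrescription": "P",
    "RelevantPrescriptions": "R",
    "AntipsychoticPrescription": "Z",
}


class FamilyConfigError(ValueError):
    pass


class CombinationOverflowError(RuntimeError):
    """Raised when un-pruned enumeration would exceed the cap."""


@dataclass
class FamilySpec:
    family: str
    members: tuple[str, ...]
    cutpoints: tuple[float, float] | None = None  # (q_low, q_high); fitted if None

    def __post_init__(self) -> None:
        if not self.members:
            raise FamilyConfigError(f"family {self.family!r} has no member features")
        if self.cutpoints is not None:
            lo, hi = self.cutpoints
            if not 0 < lo <= hi:
                raise FamilyConfigError(f"invalid cutpoints {self.cutpoints!r}")


def family_specs_from_metadata(metadata: pd.DataFrame) -> list[FamilySpec]:
    specs = []
    for fam in FAMILIES:
        members = tuple(metadata.loc[metadata["family"] == fam, "feature_id"])
        if members:
            specs.append(FamilySpec(fam, members))
    return specs


def presence_matrix(fm: FeatureMatrix) -> pd.DataFrame:
    """0/1 presence of each component feature in each record."""
    types = fm.metadata.set_index("feature_id")["value_type"]
    out = {}
    for col in fm.values.columns:
        v = fm.values[col]
        if types[col] == "binary":
            out[col] = (v == 1).astype(np.int8)
        elif types[col] == "count":
            out[col] = (v >= 1).astype(np.int8)
        else:  # continuous: present when observed and strictly positive
            out[col] = (v.notna() & (v > 0)).astype(np.int8)
    return pd.DataFrame(out, index=fm.values.index)


@dataclass
class FamilyLevelAssignment:
    """Per-family component counts and the five binary level columns."""

    counts: pd.DataFrame           # patients x families, integer counts
    levels: dict[str, pd.DataFrame]  # family -> patients x LEVELS 0/1 table
    cutpoints: dict[str, tuple[float, float]] = field(default_factory=dict)

    def level_column(self, family: str, level: str) -> np.ndarray:
        return self.levels[family][level].to_numpy()

    def as_feature_table(self) -> pd.DataFrame:
        """All 5 x n_families level indicators as one wide 0/1 table."""
        cols = {}
        for fam, tab in self.levels.items():
            for lvl in LEVELS:
                cols[f"fam{FAMILY_LETTERS[fam]}_{lvl}"] = tab[lvl]
        return pd.DataFrame(cols, index=self.counts.index)


def assign_levels(
    fm: FeatureMatrix, specs: list[FamilySpec] | None = None
) -> FamilyLevelAssignment:
    """Compute per-family component counts and level indicators.

    Cutpoints default to the tertiles of the positive counts of each
    family, computed once over all patients before any assignment.
    """
    specs = specs or family_specs_from_metadata(fm.metadata)
    pres = presence_matrix(fm)
    counts = pd.DataFrame(index=fm.values.index)
    levels: dict[str, pd.DataFrame] = {}
    cutpoints: dict[str, tuple[float, float]] = {}
    for spec in specs:
        missing = [m for m in spec.members if m not in pres.columns]
        if missing:
            raise FamilyConfigError(f"{spec.family}: unknown members {missing}")
        c = pres[list(spec.members)].sum(axis=1).to_numpy()
        counts[spec.family] = c
        pos = c[c > 0]
        if spec.cutpoints is not None:
            q_low, q_high = spec.cutpoints
        elif len(pos):
            q_low, q_high = np.quantile(pos, [1 / 3, 2 / 3])
        else:
            q_low = q_high = 1.0
        cutpoints[spec.family] = (float(q_low), float(q_high))
        # Many takes precedence at the upper cutpoint so the maximum
        # observed count always lands in the top band
        many = c >= q_high
        few = ~many & (c >= 1) & (c <= q_low)
        some = ~many & ~few & (c >= 1)
        tab = pd.DataFrame(index=fm.values.index)
        tab["None"] = (c == 0).astype(np.int8)
        tab["NotNone"] = (c >= 1).astype(np.int8)
        tab["Few"] = few.astype(np.int8)
        tab["Some"] = some.astype(np.int8)
        tab["Many"] = many.astype(np.int8)
        levels[spec.family] = tab
    return FamilyLevelAssignment(counts, levels, cutpoints)


@dataclass(frozen=True)
class CombinationSpec:
    """One level selector per family; ``x`` leaves a family unconstrained."""

    selectors: tuple[tuple[str, str], ...]  # ((family, level-or-x), ...)

    def __post_init__(self) -> None:
        if all(lvl == WILDCARD for _, lvl in self.selectors):
            raise ValueError("combination must constrain at least one family")
        for fam, lvl in self.selectors:
            if lvl != WILDCARD and lvl not in LEVELS:
                raise ValueError(f"unknown level {lvl!r} for family {fam!r}")

    @property
    def identifier(self) -> str:
        return "_".join(
            f"{FAMILY_LETTERS.get(fam, fam)}{LEVEL_CODES.get(lvl, WILDCARD)}"
            for fam, lvl in self.selectors
        )


def evaluate_combination(
    spec: CombinationSpec, assignment: FamilyLevelAssignment
) -> np.ndarray:
    """0/1 column: 1 iff every constrained family's level indicator holds."""
    n = len(assignment.counts)
    col = np.ones(n, dtype=bool)
    for fam, lvl in spec.selectors:
        if lvl != WILDCARD:
            col &= assignment.level_column(fam, lvl).astype(bool)
    return col.astype(np.int8)


def enumerate_combinations(
    assignment: FamilyLevelAssignment,
    prune: bool = True,
    cap: int = 1500,
):
    """Lazily enumerate combination specs with their evaluated columns.

    Yields ``(CombinationSpec, column)`` in a deterministic order
    (lexicographic over families, wildcard level first, so wildcard-heavy
    combinations come before fully-constrained ones). With ``prune`` on,
    constant columns (non-informative) and exact duplicates of an already
    yielded column are dropped; the first-seen representative of a
    duplicate group is always the one kept. Stops after ``cap`` emitted
    combinations; with ``prune`` off, exceeding the cap raises instead of
    truncating silently.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    families = list(assignment.levels)
    seen: set[bytes] = set()
    emitted = 0
    for combo in itertools.product(ENUMERATION_ORDER, repeat=len(families)):
        if all(lvl == WILDCARD for lvl in combo):
            continue
        spec = CombinationSpec(tuple(zip(families, combo)))
        col = evaluate_combination(spec, assignment)
        if prune:
            if col.min() == col.max():
                continue
            digest = hashlib.blake2b(np.packbits(col).tobytes(), digest_size=16).digest()
            if digest in seen:
                continue
            seen.add(digest)
        if emitted >= cap:
            if not prune:
                raise CombinationOverflowError(
                    f"enumeration exceeded cap={cap} with pruning disabled"
                )
            return
        emitted += 1
        yield spec, col
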