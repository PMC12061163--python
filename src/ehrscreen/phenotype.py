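"""Study-population filters and the records-based caseness algorithm.

The study population comprises patients aged 18-70 inclusive at the index
date, registered with their practice for at least one year, holding either
any mental-disorder diagnosis code or a prescription for a medication of
interest within the ten-year lookback window, and without any exclusion
(severe-mental-illness / dementia) code.

Within the study population, a *case* is a patient with at least one
inclusion-list diagnosis code at any time up to the index date AND a
prescription for a medication of interest within the lookback window.
Everyone else in the study population is a control.

Date windows are half-open ``(index - lookback, index]``: an event exactly
``lookback`` years before the index date does not qualify. Age is completed
years at the index date under a mid-year (1 July) birthday convention,
because the tables store year of birth only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .synthetic import Cohort
from .vocab import (
    CodeVocabulary,
    CodelistError,
    MEDICATIONS_OF_INTEREST,
    MENTAL_DISORDER_ROOT,
)

logger = logging.getLogger(__name__)

LABEL_COLUMNS = [
    "patient_id",
    "in_study_population",
    "has_inclusion_diagnosis_ever",
    "has_recent_medication",
    "has_exclusion_diagnosis",
    "is_case",
]


@dataclass
class PhenotypeSpec:
    """Parameters of the records-based phenotype."""

    index_date: date = date(2021, 12, 31)
    lookback_years: int = 10
    age_min: int = 18
    age_max: int = 70
    min_registration_days: int = 365
    inclusion_roots: tuple[str, ...] = (
        "33449004",      # personality disorder (subsumes borderline PD)
        "78667006",      # dysthymia
        "1153575004",    # persistent depressive disorder
        "192080009",     # chronic depression
        "313182004",     # chronic PTSD
        "443919007",     # complex PTSD
    )
    exclusion_roots: tuple[str, ...] = ("58214004", "13746004", "MH-DEM")
    mental_disorder_root: str = MENTAL_DISORDER_ROOT
    medications: tuple[str, ...] = field(default_factory=lambda: MEDICATIONS_OF_INTEREST)

    def validate(self) -> None:
        if self.age_min > self.age_max:
            raise ValueError("age_min must be <= age_max")
        if self.lookback_years <= 0:
            raise ValueError("lookback_years must be positive")

    @property
    def lookback_start(self) -> pd.Timestamp:
        """Exclusive lower bound of the medication / recent-code window."""
        return pd.Timestamp(self.index_date) - pd.DateOffset(years=self.lookback_years)


def code_closure(vocab: CodeVocabulary, roots) -> frozenset[str]:
    """Roots plus all transitive descendants (a parent subsumes its children).

    Raises :class:`CodelistError` if a root is not in the vocabulary.
    """
    out: set[str] = set()
    for r in roots:
        out |= vocab.descendants(r)
    return frozenset(out)


def _match_medications(names: pd.Series, medications) -> pd.Series:
    """Case-insensitive substring match of products against the name list."""
    low = names.str.lower()
    hit = pd.Series(False, index=names.index)
    for med in medications:
        hit |= low.str.contains(med.lower(), regex=False)
    return hit


def build_study_population(
    cohort: Cohort,
    spec: PhenotypeSpec | None = None,
    vocab: CodeVocabulary | None = None,
) -> pd.DataFrame:
    """Evaluate eligibility and caseness for every patient.

    Returns one row per patient with the eligibility flags, the component
    caseness criteria and ``is_case``. Patients with missing birth year or
    registration date are excluded from the study population; their number
    is logged.
    """
    from .vocab import default_vocabulary

    spec = spec or PhenotypeSpec()
    spec.validate()
    vocab = vocab or default_vocabulary()
    index = pd.Timestamp(spec.index_date)
    win_lo = spec.lookback_start  # exclusive

    pats = cohort.patients.set_index("patient_id")
    missing = pats["birth_year"].isna() | pats["registration_date"].isna()
    if missing.any():
        logger.warning(
            "%d patients excluded for missing birth year or registration date",
            int(missing.sum()),
        )

    # completed age at index with mid-year (1 July) birthday convention
    before_birthday = (index.month, index.day) < (7, 1)
    age = index.year - pats["birth_year"] - int(before_birthday)
    age_ok = (age >= spec.age_min) & (age <= spec.age_max)
    reg_ok = (index - pats["registration_date"]).dt.days >= spec.min_registration_days

    dx = cohort.diagnoses
    dated_ok = dx["date"] <= index
    incl = code_closure(vocab, spec.inclusion_roots)
    excl = code_closure(vocab, spec.exclusion_roots)
    mental = code_closure(vocab, (spec.mental_disorder_root,))

    def patients_with(mask: pd.Series) -> pd.Index:
        return pd.Index(dx.loc[mask, "patient_id"].unique())

    has_incl_ever = patients_with(dx["code"].isin(incl) & dated_ok)
    has_excl = patients_with(dx["code"].isin(excl) & dated_ok)
    has_mental_recent = patients_with(
        dx["code"].isin(mental) & (dx["date"] > win_lo) & dated_ok
    )

    rx = cohort.prescriptions
    rx_recent = rx[(rx["date"] > win_lo) & (rx["date"] <= index)]
    has_med_recent = pd.Index(
        rx_recent.loc[_match_medications(rx_recent["medication"], spec.medications),
                      "patient_id"].unique()
    )

    out = pd.DataFrame(index=pats.index)
    out["has_inclusion_diagnosis_ever"] = out.index.isin(has_incl_ever)
    out["has_recent_medication"] = out.index.isin(has_med_recent)
    out["has_exclusion_diagnosis"] = out.index.isin(has_excl)
    mh_activity = out.index.isin(has_mental_recent) | out["has_recent_medication"]
    out["in_study_population"] = (
        age_ok.values
        & reg_ok.values
        & ~missing.values
        & mh_activity
        & ~out["has_exclusion_diagnosis"]
    )
    out = assign_caseness(out)
    out["age_at_index"] = age.values
    return out.reset_index().rename(columns={"index": "patient_id"})


def assign_caseness(labels: pd.DataFrame) -> pd.DataFrame:
    """Derive ``is_case`` from the component criteria flags.

    A case is a study-population member with an inclusion diagnosis at any
    time up to the index date and a recent medication of interest; any
    exclusion diagnosis removes the patient regardless of other records.
    """
    labels = labels.copy()
    labels["is_case"] = (
        labels["in_study_population"]
        & labels["has_inclusion_diagnosis_ever"]
        & labels["has_recent_medication"]
        & ~labels["has_exclusion_diagnosis"]
    )
    return labels
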