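"""Component-feature extraction from patient event streams.

Produces the patients x features table screened downstream: binary
code-presence indicators, count features (distinct psychiatric diagnoses,
prescriptions, referrals, aborted medication regimes), medication-presence
indicators, and the temporal entropy features of non-attendance. Every
feature carries metadata (value type, feature family, provenance tag).

Binary features are never missing; entropy features are missing (NaN) for
patients whose attendance history is too short or degenerate for the
measure, and the missingness pattern is part of the matrix's report.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from . import timeseries as ts
from .phenotype import code_closure
from .synthetic import Cohort
from .vocab import CodeVocabulary, MEDICATION_CLASSES, MENTAL_DISORDER_ROOT

FAMILIES = (
    "Antecedent",
    "Concurrent",
    "ServiceUse",
    "Treatment",
    "Inconsistency",
    "PatternsOfPrescription",
    "RelevantPrescriptions",
    "AntipsychoticPrescription",
)

PROVENANCES = ("fs_literature", "fs_interviews", "fs_clinician")


@dataclass
class FeatureMatrix:
    """Wide feature table plus per-feature metadata."""

    values: pd.DataFrame    # index: patient_id; one column per feature
    metadata: pd.DataFrame  # feature_id, value_type, family, provenance

    def __post_init__(self) -> None:
        meta_ids = list(self.metadata["feature_id"])
        if meta_ids != list(self.values.columns):
            raise ValueError("metadata rows must match value columns, in order")
        if len(set(meta_ids)) != len(meta_ids):
            raise ValueError("duplicate feature_id")

    def missingness(self) -> pd.Series:
        """Fraction of patients missing each feature."""
        return self.values.isna().mean()

    def to_files(self, values_path, metadata_path) -> None:
        self.values.to_csv(values_path)
        self.metadata.to_csv(metadata_path, index=False)


@dataclass
class AttendanceSeries:
    """Monthly attendance/non-attendance bins for a set of patients.

    Calendar-month bins covering the ``n_years`` up to the index date;
    ``valid`` masks, per patient, the months from the first full month
    after registration. DNA counts never exceed appointment counts.
    """

    patient_ids: np.ndarray
    month_starts: pd.DatetimeIndex        # chronological, oldest first
    appointments: np.ndarray              # (n_patients, n_months)
    dna: np.ndarray                       # (n_patients, n_months)
    valid: np.ndarray                     # (n_patients, n_months) bool

    @property
    def first_valid(self) -> np.ndarray:
        """Index of each patient's first valid month (n_months if none)."""
        t = self.valid.shape[1]
        return np.where(self.valid.any(axis=1), self.valid.argmax(axis=1), t)


def build_attendance_series(
    cohort: Cohort,
    index_date: date,
    n_years: int = 4,
    patient_ids: np.ndarray | None = None,
) -> AttendanceSeries:
    """Bin appointments into contiguous calendar months up to the index date."""
    if patient_ids is None:
        patient_ids = cohort.patients["patient_id"].to_numpy()
    index = np.datetime64(index_date, "D")
    n_months = n_years * 12
    months = index.astype("datetime64[M]") - np.arange(n_months - 1, -1, -1).astype(
        "timedelta64[M]"
    )
    month_starts = pd.DatetimeIndex(months.astype("datetime64[D]"))

    pid_pos = pd.Series(np.arange(len(patient_ids)), index=patient_ids)
    ap = cohort.appointments
    ap = ap[ap["patient_id"].isin(pid_pos.index) & (ap["date"] <= pd.Timestamp(index))]
    col = (
        ap["date"].to_numpy().astype("datetime64[M]") - months[0]
    ).astype(np.int64)
    in_window = (col >= 0) & (col < n_months)
    rows = pid_pos[ap["patient_id"].to_numpy()[in_window]].to_numpy()
    cols = col[in_window]
    is_dna = (ap["status"].to_numpy()[in_window] == "DNA")

    shape = (len(patient_ids), n_months)
    appt = np.zeros(shape, dtype=np.int64)
    dna = np.zeros(shape, dtype=np.int64)
    np.add.at(appt, (rows, cols), 1)
    np.add.at(dna, (rows[is_dna], cols[is_dna]), 1)

    reg = (
        cohort.patients.set_index("patient_id")
        .loc[patient_ids, "registration_date"]
        .to_numpy()
        .astype("datetime64[D]")
    )
    valid = month_starts.to_numpy().astype("datetime64[D]")[None, :] >= reg[:, None]
    return AttendanceSeries(np.asarray(patient_ids), month_starts, appt, dna, valid)


def extract_binary_code_features(
    diagnoses: pd.DataFrame,
    patient_ids: np.ndarray,
    codes,
    vocab: CodeVocabulary | None = None,
    closure: bool = False,
    prefix: str = "dx_",
) -> pd.DataFrame:
    """One 0/1 column per code: 1 iff the patient ever recorded it.

    With ``closure`` on, an event with any descendant of the code also
    counts (the parent concept subsumes its children).
    """
    codes = list(codes)
    pid_pos = pd.Series(np.arange(len(patient_ids)), index=patient_ids)
    out = np.zeros((len(patient_ids), len(codes)), dtype=np.int8)
    dx = diagnoses[diagnoses["patient_id"].isin(pid_pos.index)]
    for j, code in enumerate(codes):
        members = code_closure(vocab, [code]) if closure else {code}
        hit = dx.loc[dx["code"].isin(members), "patient_id"].unique()
        out[pid_pos[hit].to_numpy(), j] = 1
    return pd.DataFrame(out, index=pd.Index(patient_ids, name="patient_id"),
                        columns=[f"{prefix}{c}" for c in codes])


def count_unique_psychiatric_diagnoses(
    diagnoses: pd.DataFrame,
    patient_ids: np.ndarray,
    vocab: CodeVocabulary,
) -> pd.Series:
    """Distinct codes under the mental-disorder root, ever recorded."""
    psych = code_closure(vocab, [MENTAL_DISORDER_ROOT])
    dx = diagnoses[diagnoses["code"].isin(psych)]
    counts = dx.drop_duplicates(["patient_id", "code"]).groupby("patient_id").size()
    return counts.reindex(patient_ids, fill_value=0).astype(np.int64)


def count_aborted_regimes(
    prescriptions: pd.DataFrame,
    patient_ids: np.ndarray,
    medications,
    index_date: date,
    gap_days: int = 90,
    min_duration_days: int = 84,
) -> pd.Series:
    """Aborted prescription regimes per patient for one medication class.

    Consecutive scripts of the same product at most ``gap_days`` apart form
    one regime; a regime is *aborted* when its span is shorter than
    ``min_duration_days`` and it is not the patient's final regime still
    open at the index date (last script within ``gap_days`` of it).
    """
    meds = {m.lower() for m in medications}
    rx = prescriptions[prescriptions["medication"].str.lower().isin(meds)]
    rx = rx[rx["date"] <= pd.Timestamp(index_date)]
    if rx.empty:
        return pd.Series(0, index=patient_ids, dtype=np.int64)
    rx = rx.sort_values(["patient_id", "medication", "date"], kind="stable")
    same = (
        rx["patient_id"].eq(rx["patient_id"].shift())
        & rx["medication"].eq(rx["medication"].shift())
    )
    gap = rx["date"].diff().dt.days
    new_regime = ~same | (gap > gap_days)
    regime_id = new_regime.cumsum()
    g = rx.groupby(regime_id).agg(
        patient_id=("patient_id", "first"),
        medication=("medication", "first"),
        first=("date", "first"),
        last=("date", "last"),
    )
    span = (g["last"] - g["first"]).dt.days
    is_last = ~g.duplicated(["patient_id", "medication"], keep="last")
    open_at_index = (pd.Timestamp(index_date) - g["last"]).dt.days <= gap_days
    aborted = (span < min_duration_days) & ~(is_last & open_at_index)
    counts = aborted.groupby(g["patient_id"]).sum()
    return counts.reindex(patient_ids, fill_value=0).astype(np.int64)


def _grouped_by_length(series: AttendanceSeries):
    """Yield (row_indices, slice_start) groups sharing a first valid month."""
    fv = series.first_valid
    for start in np.unique(fv):
        if start >= series.valid.shape[1]:
            continue
        yield np.flatnonzero(fv == start), int(start)


def attendance_entropy_features(series: AttendanceSeries) -> pd.DataFrame:
    """The four Inconsistency-family temporal features, plus median DNA.

    Each measure is evaluated on the patient's valid months only; patients
    are batched by series length so the computation stays vectorised.
    """
    n = len(series.patient_ids)
    out = {
        "sample_entropy_appointments": np.full(n, np.nan),
        "spectral_entropy_nonattendance": np.full(n, np.nan),
        "avg_quarterly_entropy_nonattendance": np.full(n, np.nan),
        "active_information_nonattendance": np.full(n, np.nan),
        "median_monthly_dna": np.full(n, np.nan),
    }
    years = series.month_starts.year.to_numpy()
    month_nums = series.month_starts.month.to_numpy()
    quarters = (month_nums - 1) // 3
    full_years = [
        y for y in np.unique(years) if (years == y).sum() == 12
    ]
    for rows, start in _grouped_by_length(series):
        appt = series.appointments[rows, start:]
        dna = series.dna[rows, start:]
        out["sample_entropy_appointments"][rows] = ts.sample_entropy_batch(appt)
        out["spectral_entropy_nonattendance"][rows] = ts.spectral_entropy_batch(dna)
        out["active_information_nonattendance"][rows] = ts.active_information_batch(dna)
        out["median_monthly_dna"][rows] = np.median(dna, axis=1)
        # full calendar years entirely inside this group's valid span
        yrs = [y for y in full_years if (np.flatnonzero(years == y) >= start).all()]
        if yrs:
            q = np.stack(
                [
                    np.stack(
                        [
                            series.dna[rows][:, (years == y) & (quarters == qq)].sum(axis=1)
                            for qq in range(4)
                        ],
                        axis=1,
                    )
                    for y in yrs
                ],
                axis=1,
            )
            out["avg_quarterly_entropy_nonattendance"][rows] = (
                ts.average_quarterly_entropy_batch(q)
            )
    idx = pd.Index(series.patient_ids, name="patient_id")
    return pd.DataFrame(out, index=idx)


def _medication_name_map() -> dict[str, str]:
    return {
        name.lower(): cls for cls, names in MEDICATION_CLASSES.items() for name in names
    }


def extract_features(
    cohort: Cohort,
    vocab: CodeVocabulary,
    index_date: date = date(2021, 12, 31),
    attendance_years: int = 4,
    patient_ids: np.ndarray | None = None,
) -> FeatureMatrix:
    """Extract the full component-feature census for the given patients.

    The census covers the eight feature families; the caseness-defining
    inclusion and exclusion diagnosis codes are deliberately absent from the
    binary code-presence features (a feature must not be the caseness
    definition itself), but they do count toward the distinct-psychiatric-
    diagnosis total, of which they are legitimate members.
    """
    if patient_ids is None:
        patient_ids = cohort.patients["patient_id"].to_numpy()
    patient_ids = np.asarray(patient_ids)
    idx = pd.Index(patient_ids, name="patient_id")
    index = pd.Timestamp(index_date)
    blocks: list[pd.DataFrame] = []
    meta: list[tuple[str, str, str, str]] = []  # id, type, family, provenance

    pats = cohort.patients.set_index("patient_id").loc[patient_ids]
    birth_mid = pd.to_datetime(
        pats["birth_year"].astype(int).astype(str) + "-07-01"
    )
    turn30 = birth_mid + pd.DateOffset(years=30)
    dx = cohort.diagnoses[cohort.diagnoses["date"] <= index]

    # -- binary code presence ------------------------------------------------
    generic = [
        c for c in vocab.codes_with_role("generic_psychiatric") if vocab.codes[c].parents
    ]
    somatic = vocab.codes_with_role("other")
    g = extract_binary_code_features(dx, patient_ids, generic, vocab)
    s = extract_binary_code_features(dx, patient_ids, somatic, vocab)
    blocks += [g, s]
    meta += [(c, "binary", "ServiceUse", "fs_literature") for c in g.columns]
    meta += [(c, "binary", "ServiceUse", "fs_clinician") for c in s.columns]

    # antecedent / concurrent findings are age-conditional: the event must
    # fall before (after) the patient's 30th birthday, mid-year convention
    t30 = turn30.reindex(dx["patient_id"]).to_numpy()
    before30 = dx[dx["date"].to_numpy() < t30]
    after30 = dx[dx["date"].to_numpy() >= t30]
    a = extract_binary_code_features(
        before30, patient_ids, vocab.codes_with_role("antecedent"), vocab, prefix="pre30_"
    )
    c = extract_binary_code_features(
        after30, patient_ids, vocab.codes_with_role("concurrent"), vocab, prefix="post30_"
    )
    blocks += [a, c]
    meta += [(col, "binary", "Antecedent", "fs_interviews") for col in a.columns]
    meta += [(col, "binary", "Concurrent", "fs_interviews") for col in c.columns]

    # -- medication presence -------------------------------------------------
    rx = cohort.prescriptions[cohort.prescriptions["date"] <= index]
    name_map = _medication_name_map()
    rx_named = rx.assign(_name=rx["medication"].str.lower())
    rx_named = rx_named[rx_named["_name"].isin(name_map)]
    med_block = {}
    for cls, names in MEDICATION_CLASSES.items():
        class_hit = pd.Index([])
        for nm in names:
            holders = rx_named.loc[rx_named["_name"] == nm.lower(), "patient_id"].unique()
            med_block[f"rx_{nm.lower()}"] = idx.isin(holders).astype(np.int8)
            class_hit = class_hit.union(pd.Index(holders))
        med_block[f"rx_class_{cls}"] = idx.isin(class_hit).astype(np.int8)
    med = pd.DataFrame(med_block, index=idx)
    blocks.append(med)
    for col in med.columns:
        fam = (
            "AntipsychoticPrescription"
            if col == "rx_class_antipsychotic"
            else "RelevantPrescriptions"
        )
        meta.append((col, "binary", fam, "fs_clinician"))

    # -- counts ---------------------------------------------------------------
    counts = pd.DataFrame(index=idx)
    counts["count_distinct_psych_dx"] = count_unique_psychiatric_diagnoses(
        dx, patient_ids, vocab
    )
    year_ago = index - pd.DateOffset(years=1)
    ap = cohort.appointments
    recent_ap = ap[(ap["date"] > year_ago) & (ap["date"] <= index)]
    counts["appointments_last_year"] = (
        recent_ap.groupby("patient_id").size().reindex(patient_ids, fill_value=0)
    )
    ref = cohort.referrals[cohort.referrals["date"] <= index]
    counts["iapt_referral_count"] = (
        ref[ref["referral_type"] == "IAPT"].groupby("patient_id").size()
        .reindex(patient_ids, fill_value=0)
    )
    counts["repeat_iapt_referrals"] = (counts["iapt_referral_count"] >= 2).astype(np.int8)
    antidep = [m.lower() for m in MEDICATION_CLASSES["antidepressant"]]
    counts["count_antidepressant_rx"] = (
        rx_named[rx_named["_name"].isin(antidep)].groupby("patient_id").size()
        .reindex(patient_ids, fill_value=0)
    )
    counts["count_distinct_medications"] = (
        rx_named.drop_duplicates(["patient_id", "_name"]).groupby("patient_id").size()
        .reindex(patient_ids, fill_value=0)
    )
    counts["aborted_antidepressant_regimes"] = count_aborted_regimes(
        rx, patient_ids, MEDICATION_CLASSES["antidepressant"], index_date
    )
    blocks.append(counts)
    meta += [
        ("count_distinct_psych_dx", "count", "ServiceUse", "fs_literature"),
        ("appointments_last_year", "count", "ServiceUse", "fs_literature"),
        ("iapt_referral_count", "count", "Treatment", "fs_interviews"),
        ("repeat_iapt_referrals", "binary", "Treatment", "fs_interviews"),
        ("count_antidepressant_rx", "count", "PatternsOfPrescription", "fs_literature"),
        ("count_distinct_medications", "count", "PatternsOfPrescription", "fs_clinician"),
        ("aborted_antidepressant_regimes", "count", "PatternsOfPrescription", "fs_interviews"),
    ]

    # -- temporal entropy features -------------------------------------------
    series = build_attendance_series(cohort, index_date, attendance_years, patient_ids)
    ent = attendance_entropy_features(series)
    blocks.append(ent)
    meta += [
        ("sample_entropy_appointments", "continuous", "Inconsistency", "fs_literature"),
        ("spectral_entropy_nonattendance", "continuous", "Inconsistency", "fs_clinician"),
        ("avg_quarterly_entropy_nonattendance", "continuous", "Inconsistency", "fs_clinician"),
        ("active_information_nonattendance", "continuous", "Inconsistency", "fs_clinician"),
        ("median_monthly_dna", "count", "Inconsistency", "fs_clinician"),
    ]

    values = pd.concat(blocks, axis=1)
    metadata = pd.DataFrame(
        meta, columns=["feature_id", "value_type", "family", "provenance"]
    )
    values = values[metadata["feature_id"].tolist()]
    return FeatureMatrix(values, metadata)
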