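"""Eligibility filters and the caseness algorithm on hand-crafted records."""
from datetime import date

import numpy as np
import pandas as pd
import pytest

from ehrscreen.phenotype import PhenotypeSpec, build_study_population
from ehrscreen.synthetic import GeneratorConfig, generate_cohort

from conftest import make_cohort

IDX = "2021-12-31"


def labels_for(cohort, vocab):
    return build_study_population(cohort, vocab=vocab).set_index("patient_id")


def test_age_bounds_exclude_minor_and_elderly(vocab):
    cohort = make_cohort(
        patients=[
            ("P1", 2004, "2010-01-01"),  # 17 at index
            ("P2", 2000, "2010-01-01"),  # 21 at index
            ("P3", 1950, "2010-01-01"),  # 71 at index
        ],
        diagnoses=[(p, "33449004", "2020-06-01") for p in ("P1", "P2", "P3")],
        prescriptions=[(p, "Sertraline", "antidepressant", "2020-06-01")
                       for p in ("P1", "P2", "P3")],
    )
    lab = labels_for(cohort, vocab)
    assert not lab.loc["P1", "in_study_population"]
    assert lab.loc["P2", "is_case"]
    assert not lab.loc["P3", "in_study_population"]


def test_exclusion_code_dominates_qualifying_records(vocab):
    cohort = make_cohort(
        patients=[("P1", 1990, "2010-01-01")],
        diagnoses=[
            ("P1", "33449004", "2020-06-01"),
            ("P1", "58214004", "2015-01-01"),  # schizophrenia
        ],
        prescriptions=[("P1", "Sertraline", "antidepressant", "2020-06-01")],
    )
    lab = labels_for(cohort, vocab)
    assert not lab.loc["P1", "in_study_population"]
    assert not lab.loc["P1", "is_case"]
    assert lab.loc["P1", "has_exclusion_diagnosis"]


def test_child_code_of_exclusion_root_also_excludes(vocab):
    cohort = make_cohort(
        patients=[("P1", 1990, "2010-01-01")],
        diagnoses=[("P1", "MH-SCZ-PAR", "2015-01-01"),
                   ("P1", "MH-GEN-01", "2020-01-01")],
    )
    assert not labels_for(cohort, vocab).loc["P1", "in_study_population"]


def test_medication_window_is_half_open_ten_years(vocab):
    """Diagnosis counts from any time; medication only within ten years."""
    rows = [
        # old diagnosis + old prescription: medication window fails -> control
        ("P1", "2009-06-01", "2010-12-30"),
        # old diagnosis + recent prescription -> case
        ("P2", "2009-06-01", "2019-06-01"),
        # prescription exactly ten years before index is outside (half-open)
        ("P3", "2009-06-01", "2011-12-31"),
        # one day inside the window
        ("P4", "2009-06-01", "2012-01-01"),
    ]
    cohort = make_cohort(
        patients=[(p, 1980, "2005-01-01") for p, *_ in rows],
        diagnoses=[(p, "78667006", dx) for p, dx, _ in rows],
        prescriptions=[(p, "Citalopram", "antidepressant", rx) for p, _, rx in rows],
    )
    lab = labels_for(cohort, vocab)
    assert not lab.loc["P1", "is_case"]
    assert lab.loc["P2", "is_case"]
    assert not lab.loc["P3", "is_case"]
    assert lab.loc["P4", "is_case"]


def test_medication_match_is_case_insensitive_substring(vocab):
    cohort = make_cohort(
        patients=[("P1", 1980, "2005-01-01"), ("P2", 1980, "2005-01-01")],
        diagnoses=[("P1", "78667006", "2019-01-01"), ("P2", "78667006", "2019-01-01")],
        prescriptions=[
            ("P1", "SERTRALINE 50mg tablets", "antidepressant", "2019-06-01"),
            ("P2", "Amoxicillin 500mg", "other", "2019-06-01"),
        ],
    )
    lab = labels_for(cohort, vocab)
    assert lab.loc["P1", "is_case"]
    assert not lab.loc["P2", "is_case"]


def _oracle_label(patient, dx_rows, rx_rows, vocab, spec):
    """Independent per-patient re-evaluation of the phenotype predicate."""
    from ehrscreen.phenotype import code_closure

    index = pd.Timestamp(spec.index_date)
    win_lo = spec.lookback_start
    pid, birth_year, reg = patient
    age = spec.index_date.year - birth_year
    ok_age = spec.age_min <= age <= spec.age_max
    ok_reg = (index - pd.Timestamp(reg)).days >= spec.min_registration_days
    incl = code_closure(vocab, spec.inclusion_roots)
    excl = code_closure(vocab, spec.exclusion_roots)
    mental = code_closure(vocab, [spec.mental_disorder_root])
    has_excl = any(c in excl for p, c, d in dx_rows if p == pid)
    has_incl = any(c in incl for p, c, d in dx_rows if p == pid)
    meds = [m.lower() for m in spec.medications]
    has_med = any(
        any(m in name.lower() for m in meds)
        and win_lo < pd.Timestamp(d) <= index
        for p, name, cls, d in rx_rows
        if p == pid
    )
    recent_mental = any(
        c in mental and win_lo < pd.Timestamp(d) <= index
        for p, c, d in dx_rows
        if p == pid
    )
    in_study = ok_age and ok_reg and (recent_mental or has_med) and not has_excl
    return in_study, in_study and has_incl and has_med


def test_membership_matches_independent_predicate_oracle(vocab):
    """200 random patients agree with a from-scratch predicate evaluation."""
    rng = np.random.default_rng(5)
    all_codes = sorted(vocab.codes)
    meds = ["Sertraline", "Quetiapine", "Diazepam", "Amoxicillin", "Metformin"]
    patients, dx_rows, rx_rows = [], [], []
    for i in range(200):
        pid = f"P{i:03d}"
        birth = int(rng.integers(1935, 2008))
        reg = pd.Timestamp("2021-12-31") - pd.Timedelta(days=int(rng.integers(60, 6000)))
        patients.append((pid, birth, str(reg.date())))
        for _ in range(rng.integers(0, 5)):
            d = reg + pd.Timedelta(days=int(rng.integers(0, (pd.Timestamp(IDX) - reg).days + 1)))
            dx_rows.append((pid, all_codes[rng.integers(len(all_codes))], str(d.date())))
        for _ in range(rng.integers(0, 4)):
            d = reg + pd.Timedelta(days=int(rng.integers(0, (pd.Timestamp(IDX) - reg).days + 1)))
            rx_rows.append((pid, meds[rng.integers(len(meds))], "any", str(d.date())))
    cohort = make_cohort(patients, dx_rows, rx_rows)
    spec = PhenotypeSpec()
    lab = build_study_population(cohort, spec, vocab).set_index("patient_id")
    for patient in patients:
        in_study, is_case = _oracle_label(patient, dx_rows, rx_rows, vocab, spec)
        assert lab.loc[patient[0], "in_study_population"] == in_study, patient[0]
        assert lab.loc[patient[0], "is_case"] == is_case, patient[0]


def test_caseness_monotone_in_qualifying_prescriptions(vocab, small_cohort):
    """Adding a qualifying prescription can never turn a case into a control."""
    base = build_study_population(small_cohort, vocab=vocab)
    extra = pd.DataFrame(
        {
            "patient_id": small_cohort.patients["patient_id"],
            "medication": "Fluoxetine",
            "med_class": "antidepressant",
            "date": pd.Timestamp("2021-06-01"),
        }
    )
    boosted = small_cohort.__class__(
        patients=small_cohort.patients,
        diagnoses=small_cohort.diagnoses,
        prescriptions=pd.concat([small_cohort.prescriptions, extra], ignore_index=True),
        appointments=small_cohort.appointments,
        referrals=small_cohort.referrals,
        truth=small_cohort.truth,
    )
    after = build_study_population(boosted, vocab=vocab)
    was_case = base.set_index("patient_id")["is_case"]
    now_case = after.set_index("patient_id")["is_case"]
    assert (now_case[was_case] | ~was_case[was_case]).all()
    assert now_case.sum() >= was_case.sum()


def test_population_counts_weakly_decreasing(small_labels):
    n_total = len(small_labels)
    n_study = small_labels["in_study_population"].sum()
    n_case = small_labels["is_case"].sum()
    assert n_total >= n_study >= n_case
    assert (small_labels.loc[small_labels["is_case"], "in_study_population"]).all()
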