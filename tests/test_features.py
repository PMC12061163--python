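"""Component-feature extraction against brute-force oracles."""
from datetime import date

import numpy as np
import pandas as pd
import pytest

from ehrscreen.features import (
    build_attendance_series,
    count_aborted_regimes,
    count_unique_psychiatric_diagnoses,
    extract_binary_code_features,
    extract_features,
)
from ehrscreen.phenotype import code_closure

from conftest import make_cohort

INDEX = date(2021, 12, 31)


def test_binary_features_absent_and_idempotent(vocab):
    dx = pd.DataFrame(
        {
            "patient_id": ["P2", "P2"],
            "code": ["MH-GEN-01", "MH-GEN-01"],  # recorded twice -> still 1
            "date": pd.to_datetime(["2020-01-01", "2021-01-01"]),
        }
    )
    out = extract_binary_code_features(dx, np.array(["P1", "P2"]), ["MH-GEN-01", "MH-GEN-02"])
    assert out.loc["P1"].tolist() == [0, 0]
    assert out.loc["P2"].tolist() == [1, 0]


def test_binary_feature_closure_flag_counts_child_codes(vocab):
    dx = pd.DataFrame(
        {
            "patient_id": ["P1"],
            "code": ["20010003"],  # borderline PD, child of personality disorder
            "date": pd.to_datetime(["2020-01-01"]),
        }
    )
    flat = extract_binary_code_features(dx, np.array(["P1"]), ["33449004"], vocab)
    closed = extract_binary_code_features(dx, np.array(["P1"]), ["33449004"], vocab, closure=True)
    assert flat.iloc[0, 0] == 0
    assert closed.iloc[0, 0] == 1
    assert "20010003" in code_closure(vocab, ["33449004"])


def test_count_unique_psychiatric_diagnoses_distinctness(vocab):
    dx = pd.DataFrame(
        {
            "patient_id": ["P1"] * 5 + ["P2"],
            "code": ["MH-GEN-03"] * 5 + ["SOM-01"],  # repeats count once; somatic never
            "date": pd.to_datetime(["2020-01-01"] * 6),
        }
    )
    counts = count_unique_psychiatric_diagnoses(dx, np.array(["P1", "P2", "P3"]), vocab)
    assert counts.tolist() == [1, 0, 0]


def test_count_unique_psychiatric_diagnoses_matches_bruteforce(vocab, small_cohort):
    psych = code_closure(vocab, ["74732009"])
    pids = small_cohort.patients["patient_id"].to_numpy()[:300]
    got = count_unique_psychiatric_diagnoses(small_cohort.diagnoses, pids, vocab)
    dx = small_cohort.diagnoses
    for pid in pids[::23]:
        want = len({c for c in dx.loc[dx["patient_id"] == pid, "code"] if c in psych})
        assert got[pid] == want


# ------------------------------------------------------------ regimes -------
def _regimes_oracle(dates_by_med, index, gap=90, min_dur=84):
    """Brute-force interval grouping over each medication's sorted dates."""
    aborted = 0
    for dates in dates_by_med.values():
        dates = sorted(dates)
        regimes, current = [], [dates[0]]
        for d in dates[1:]:
            if (d - current[-1]).days <= gap:
                current.append(d)
            else:
                regimes.append(current)
                current = [d]
        regimes.append(current)
        for i, regime in enumerate(regimes):
            span = (regime[-1] - regime[0]).days
            is_last_open = i == len(regimes) - 1 and (index - regime[-1]).days <= gap
            if span < min_dur and not is_last_open:
                aborted += 1
    return aborted


def _rx_frame(rows):
    return pd.DataFrame(
        {
            "patient_id": [r[0] for r in rows],
            "medication": [r[1] for r in rows],
            "med_class": "antidepressant",
            "date": pd.to_datetime([r[2] for r in rows]),
        }
    )


def test_single_old_prescription_is_one_aborted_regime():
    rx = _rx_frame([("P1", "Sertraline", "2018-06-01")])
    out = count_aborted_regimes(rx, np.array(["P1"]), ["Sertraline"], INDEX)
    assert out["P1"] == 1


def test_continuous_monthly_prescriptions_are_not_aborted():
    dates = pd.date_range("2019-01-01", periods=24, freq="28D")
    rx = _rx_frame([("P1", "Sertraline", d) for d in dates])
    out = count_aborted_regimes(rx, np.array(["P1"]), ["Sertraline"], INDEX)
    assert out["P1"] == 0


def test_open_final_regime_near_index_is_not_aborted():
    rx = _rx_frame([("P1", "Sertraline", "2021-12-01")])  # still open at index
    out = count_aborted_regimes(rx, np.array(["P1"]), ["Sertraline"], INDEX)
    assert out["P1"] == 0


def test_aborted_regimes_match_bruteforce_on_random_dates():
    rng = np.random.default_rng(8)
    meds = ["Sertraline", "Citalopram"]
    index = pd.Timestamp(INDEX)
    for trial in range(30):
        rows, per_med = [], {}
        for med in meds:
            k = int(rng.integers(1, 12))
            dates = sorted(
                index - pd.Timedelta(days=int(d)) for d in rng.integers(0, 2000, k)
            )
            per_med[med] = dates
            rows += [("P1", med, d) for d in dates]
        got = count_aborted_regimes(_rx_frame(rows), np.array(["P1"]), meds, INDEX)
        assert got["P1"] == _regimes_oracle(per_med, index), trial


# ------------------------------------------------------------ attendance ----
def test_attendance_series_counts_match_bruteforce(small_cohort):
    series = build_attendance_series(small_cohort, INDEX, n_years=4)
    ap = small_cohort.appointments
    months = series.month_starts
    for pi in [0, 17, 123]:
        pid = series.patient_ids[pi]
        rows = ap[ap["patient_id"] == pid]
        for mi_, start in enumerate(months):
            end = (start + pd.offsets.MonthEnd(0)) + pd.Timedelta(days=0)
            in_bin = rows[(rows["date"] >= start) & (rows["date"] <= end)]
            assert series.appointments[pi, mi_] == len(in_bin)
            assert series.dna[pi, mi_] == (in_bin["status"] == "DNA").sum()
            assert series.dna[pi, mi_] <= series.appointments[pi, mi_]


def test_attendance_all_attended_and_all_dna():
    appts = [("P1", f"2021-{m:02d}-10", "attended") for m in range(1, 13)]
    appts += [("P2", f"2021-{m:02d}-10", "DNA") for m in range(1, 13)]
    cohort = make_cohort(
        patients=[("P1", 1980, "2015-01-01"), ("P2", 1980, "2015-01-01")],
        appointments=appts,
    )
    series = build_attendance_series(cohort, INDEX, n_years=2)
    assert series.dna[0].sum() == 0
    assert (series.dna[1][-12:] == 1).all()


def test_extraction_order_invariant_under_row_shuffling(vocab, small_cohort):
    rng = np.random.default_rng(9)
    pids = small_cohort.patients["patient_id"].to_numpy()[:400]
    fm1 = extract_features(small_cohort, vocab, INDEX, patient_ids=pids)
    shuffled = small_cohort.__class__(
        patients=small_cohort.patients,
        diagnoses=small_cohort.diagnoses.sample(frac=1, random_state=1),
        prescriptions=small_cohort.prescriptions.sample(frac=1, random_state=2),
        appointments=small_cohort.appointments.sample(frac=1, random_state=3),
        referrals=small_cohort.referrals.sample(frac=1, random_state=4),
        truth=small_cohort.truth,
    )
    fm2 = extract_features(shuffled, vocab, INDEX, patient_ids=pids)
    pd.testing.assert_frame_equal(fm1.values, fm2.values)


def test_feature_matrix_types_and_missingness(vocab, small_cohort):
    fm = extract_features(small_cohort, vocab, INDEX)
    meta = fm.metadata.set_index("feature_id")
    miss = fm.missingness()
    for fid, row in meta.iterrows():
        if row["value_type"] == "binary":
            assert miss[fid] == 0.0  # binary features are never missing
            assert set(fm.values[fid].unique()) <= {0, 1}
    # entropy features are missing exactly for short/degenerate histories
    assert miss["spectral_entropy_nonattendance"] > 0
    ent = fm.values["avg_quarterly_entropy_nonattendance"].dropna()
    assert ((ent >= 0) & (ent <= 1)).all()
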