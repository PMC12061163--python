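from datetime import date

import numpy as np
import pandas as pd
import pytest

from ehrscreen.phenotype import build_study_population
from ehrscreen.synthetic import Cohort, GeneratorConfig, generate_cohort
from ehrscreen.vocab import default_vocabulary

INDEX = date(2021, 12, 31)


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def small_cohort(vocab):
    """A 2,000-patient synthetic cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(n_patients=2000, seed=42), vocab)


@pytest.fixture(scope="session")
def small_labels(small_cohort, vocab):
    return build_study_population(small_cohort, vocab=vocab)


def make_cohort(patients, diagnoses=(), prescriptions=(), appointments=(), referrals=()):
    """Build a Cohort from plain tuples, for hand-crafted phenotype cases.

    patients: (patient_id, birth_year, registration_date)
    diagnoses: (patient_id, code, date)
    prescriptions: (patient_id, medication, med_class, date)
    appointments: (patient_id, date, status)
    referrals: (patient_id, referral_type, date)
    """

    def df(rows, cols):
        out = pd.DataFrame(list(rows), columns=cols)
        for c in out.columns:
            if c.endswith("date") or c == "date":
                out[c] = pd.to_datetime(out[c])
        return out

    pats = df(patients, ["patient_id", "birth_year", "registration_date"])
    return Cohort(
        patients=pats,
        diagnoses=df(diagnoses, ["patient_id", "code", "date"]),
        prescriptions=df(prescriptions, ["patient_id", "medication", "med_class", "date"]),
        appointments=df(appointments, ["patient_id", "date", "status"]),
        referrals=df(referrals, ["patient_id", "referral_type", "date"]),
        truth=pd.DataFrame(
            {"patient_id": pats["patient_id"], "latent_status": np.zeros(len(pats), int)}
        ),
    )
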