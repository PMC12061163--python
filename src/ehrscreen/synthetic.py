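"""Synthetic primary-care event streams with a planted latent complexity status.

The generator emulates the situation the screen is designed for: a latent
complex-mental-health status at a few percent true prevalence, heavy
under-coding of the defining diagnoses (so observed, records-based caseness
lands near 0.3% of the population), dose-dependent excess of psychiatric
diagnosis codes in latent cases, elevated psychotropic prescribing in cases,
and more irregular non-attendance in cases.

Structure of one synthetic patient, conditional on latent status ``s``:

* age uniform on a configurable range; a small fraction registered with
  their practice for under a year (both feed the eligibility filters);
* medication-class indicators (antidepressant / antipsychotic /
  hypnotic-anxiolytic), Bernoulli with class- and status-specific
  probabilities; prescriptions for a held class are laid down as repeat
  "regimes" of scripts inside the ten-year medication window;
* a count ``G`` of distinct generic psychiatric codes, negative-binomial
  with mean multiplied by ``diagnosis_rate_ratio`` for latent cases, plus
  Poisson "indication coding" extra codes for medicated patients (patients
  prescribed psychotropics nearly always carry mental-health codes);
* an inclusion diagnosis with probability proportional to
  ``min(G + 1, dose_weight_cap)``, normalised so the *marginal* probability
  is exactly ``coding_probability`` for latent cases (and the background
  probability for controls) — recorded caseness is a dose-dependent
  function of coding intensity while P(caseness) keeps a closed form;
* monthly appointment counts Poisson, per-appointment non-attendance
  probability logistic in latent status with a month-level random effect
  whose spread is inflated for cases (tunable non-attendance entropy);
* occasional IAPT-style referrals, somatic diagnoses and unrelated
  prescriptions as noise.

The latent status is emitted only in a separate truth table, never in the
analysis-facing event tables.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import nbinom, poisson

from .vocab import (
    CodeVocabulary,
    MEDICATION_CLASSES,
    OTHER_MEDICATIONS,
    default_vocabulary,
)


class GeneratorConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


def _check_prob(name: str, value: float) -> None:
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise GeneratorConfigError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise GeneratorConfigError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults are calibrated so that, with the default phenotype definition,
    observed caseness is ~0.3% of the total population (about one tenth of
    the true prevalence), the study population is ~14% of the total, and
    roughly 60% of the study population holds a medication of interest.
    """

    n_patients: int = 10_000
    true_prevalence: float = 0.04
    coding_probability: float = 0.10
    background_coding_probability: float = 0.011
    index_date: date = date(2021, 12, 31)
    observation_years: int = 12
    age_range: tuple[int, int] = (16, 90)
    short_registration_probability: float = 0.05
    exclusion_probability: float = 0.01

    # distinct generic psychiatric codes: NB(mean, dispersion), case mean x ratio
    psych_code_mean: float = 0.09
    psych_code_dispersion: float = 0.8
    diagnosis_rate_ratio: float = 12.0
    medication_coding_mean: float = 1.2   # Poisson extra codes if medicated
    dose_weight_cap: float = 8.0          # saturation of dose-dependent coding

    # (control, latent case) probabilities of holding each medication class
    antidepressant_probability: tuple[float, float] = (0.075, 0.75)
    antipsychotic_probability: tuple[float, float] = (0.005, 0.20)
    hypnotic_probability: tuple[float, float] = (0.02, 0.35)
    other_medication_probability: float = 0.30

    # prescription regimes
    regime_churn: tuple[float, float] = (0.2, 1.0)     # extra regimes, Poisson
    scripts_per_regime_mean: tuple[float, float] = (8.0, 4.0)
    script_interval_days: int = 28
    second_antidepressant_probability: float = 0.30    # latent cases only

    # antecedent / concurrent / somatic code probabilities
    antecedent_probability: tuple[float, float] = (0.03, 0.15)
    concurrent_probability: tuple[float, float] = (0.04, 0.20)
    somatic_code_mean: float = 0.8

    # appointments and non-attendance
    appointment_history_years: int = 6
    appointment_rate_per_month: float = 0.30
    appointment_rate_ratio: float = 1.5
    dna_base_logit: float = -2.442347     # logit(0.08)
    dna_case_logit_shift: float = 1.2
    dna_month_sd: float = 0.6
    nonattendance_irregularity_multiplier: float = 2.0

    referral_rate: tuple[float, float] = (0.05, 0.35)

    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 1:
            raise GeneratorConfigError(f"n_patients must be >= 1, got {self.n_patients!r}")
        if self.observation_years < 2:
            raise GeneratorConfigError("observation_years must be >= 2")
        if self.appointment_history_years < 2:
            raise GeneratorConfigError("appointment_history_years must be >= 2")
        for name in (
            "true_prevalence", "coding_probability", "background_coding_probability",
            "short_registration_probability", "exclusion_probability",
            "other_medication_probability", "second_antidepressant_probability",
        ):
            _check_prob(name, getattr(self, name))
        for name in (
            "antidepressant_probability", "antipsychotic_probability",
            "hypnotic_probability", "antecedent_probability", "concurrent_probability",
        ):
            pair = getattr(self, name)
            _check_prob(f"{name}[control]", pair[0])
            _check_prob(f"{name}[case]", pair[1])
        for name in (
            "psych_code_mean", "psych_code_dispersion", "diagnosis_rate_ratio",
            "medication_coding_mean", "somatic_code_mean",
            "appointment_rate_per_month", "appointment_rate_ratio",
            "dna_month_sd", "nonattendance_irregularity_multiplier",
        ):
            _check_nonneg(name, getattr(self, name))
        if self.dose_weight_cap < 1:
            raise GeneratorConfigError("dose_weight_cap must be >= 1")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise GeneratorConfigError(f"invalid age_range {self.age_range!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["index_date"] = self.index_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if isinstance(d.get("index_date"), str):
            d["index_date"] = date.fromisoformat(d["index_date"])
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class Cohort:
    """Analysis-facing event tables for one synthetic population.

    ``truth`` carries the hidden latent status; it is written to a separate
    file and must never be joined into analysis inputs.
    """

    patients: pd.DataFrame       # patient_id, birth_year, registration_date
    diagnoses: pd.DataFrame      # patient_id, code, date
    prescriptions: pd.DataFrame  # patient_id, medication, med_class, date
    appointments: pd.DataFrame   # patient_id, date, status (attended|DNA)
    referrals: pd.DataFrame      # patient_id, referral_type, date
    truth: pd.DataFrame          # patient_id, latent_status

    _TABLES = ("patients", "diagnoses", "prescriptions", "appointments", "referrals")

    def to_dir(self, out_dir: str | Path, write_truth: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        if write_truth:
            self.truth.to_csv(out / "truth.csv", index=False)

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "Cohort":
        p = Path(in_dir)
        frames = {}
        for name in cls._TABLES:
            df = pd.read_csv(p / f"{name}.csv")
            for col in df.columns:
                if col.endswith("date"):
                    df[col] = pd.to_datetime(df[col])
            frames[name] = df
        truth_path = p / "truth.csv"
        truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame(
            columns=["patient_id", "latent_status"]
        )
        return cls(truth=truth, **frames)


def dose_weight_normalisers(config: GeneratorConfig, pool_size: int) -> dict[tuple[int, int], float]:
    """E[min(G+1, cap)] for each (latent, medicated) cell.

    Computed exactly from the truncated NB (+ Poisson) pmf of the distinct
    generic-code count, so that dividing by it keeps the marginal inclusion
    coding probability equal to the configured value.
    """
    w = np.minimum(np.arange(pool_size + 1) + 1.0, config.dose_weight_cap)
    k = config.psych_code_dispersion
    out = {}
    for s in (0, 1):
        mean = config.psych_code_mean * (config.diagnosis_rate_ratio if s else 1.0)
        pmf = nbinom.pmf(np.arange(pool_size + 1), k, k / (k + mean)) if mean > 0 else \
            np.eye(pool_size + 1)[0]
        pmf[-1] += max(0.0, 1 - pmf.sum())
        for m in (0, 1):
            p = pmf
            if m and config.medication_coding_mean > 0:
                extra = poisson.pmf(np.arange(pool_size + 1), config.medication_coding_mean)
                extra[-1] += max(0.0, 1 - extra.sum())
                full = np.convolve(pmf, extra)
                p = full[: pool_size + 1].copy()
                p[-1] += full[pool_size + 1:].sum()
            out[(s, m)] = float((p * w).sum())
    return out


def _uniform_dates(rng, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Uniform datetime64[D] in [start, end] elementwise."""
    span = (end - start).astype("timedelta64[D]").astype(np.int64)
    offs = rng.integers(0, span + 1)
    return start + offs.astype("timedelta64[D]")


def _pick_distinct(rng, pool: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """For each row i, draw counts[i] distinct items from pool; flat result."""
    n, m = len(counts), len(pool)
    order = rng.random((n, m)).argsort(axis=1)
    mask = np.arange(m)[None, :] < counts[:, None]
    return pool[order[mask]]


def generate_cohort(
    config: GeneratorConfig,
    vocab: CodeVocabulary | None = None,
) -> Cohort:
    """Generate one synthetic population; fully reproducible given the seed."""
    config.validate()
    if vocab is None:
        vocab = default_vocabulary()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    index = np.datetime64(config.index_date, "D")
    index_year = config.index_date.year

    pid = np.array([f"P{i:07d}" for i in range(n)])
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, n)
    birth_year = index_year - age
    short = rng.random(n) < config.short_registration_probability
    reg_days = np.where(
        short,
        rng.integers(30, 365, n),
        rng.integers(365, config.observation_years * 365 + 1, n),
    )
    reg = index - reg_days.astype("timedelta64[D]")

    latent = rng.random(n) < config.true_prevalence

    # medication-class indicators
    def bern(pair):
        p = np.where(latent, pair[1], pair[0])
        return rng.random(n) < p

    has_ad = bern(config.antidepressant_probability)
    has_ap = bern(config.antipsychotic_probability)
    has_hy = bern(config.hypnotic_probability)
    has_med = has_ad | has_ap | has_hy

    # distinct generic psychiatric codes with medication indication coding
    generic_pool = np.array(
        [c for c in vocab.codes_with_role("generic_psychiatric") if vocab.codes[c].parents]
    )
    pool_size = len(generic_pool)
    mean = config.psych_code_mean * np.where(latent, config.diagnosis_rate_ratio, 1.0)
    k = config.psych_code_dispersion
    g = rng.negative_binomial(k, k / (k + np.maximum(mean, 1e-12))) if config.psych_code_mean > 0 \
        else np.zeros(n, dtype=np.int64)
    if config.medication_coding_mean > 0:
        g = g + np.where(has_med, rng.poisson(config.medication_coding_mean, n), 0)
    g = np.minimum(g, pool_size)

    # dose-dependent inclusion coding, marginal fixed at the configured value
    norm = dose_weight_normalisers(config, pool_size)
    ew = np.array([[norm[(s, m)] for m in (0, 1)] for s in (0, 1)])
    w = np.minimum(g + 1.0, config.dose_weight_cap)
    q = np.where(latent, config.coding_probability, config.background_coding_probability)
    # dose weighting redistributes coding probability across code counts;
    # q = 1 means certain coding regardless of dose
    p_incl = np.where(
        q >= 1.0,
        1.0,
        np.clip(q * w / ew[latent.astype(int), has_med.astype(int)], 0.0, 1.0),
    )
    has_incl = rng.random(n) < p_incl
    has_excl = rng.random(n) < config.exclusion_probability

    # ---- diagnosis events ----
    dx_pid, dx_code, dx_date = [], [], []

    gen_codes = _pick_distinct(rng, generic_pool, g)
    gen_pid = np.repeat(np.arange(n), g)
    dx_pid.append(gen_pid)
    dx_code.append(gen_codes)
    dx_date.append(_uniform_dates(rng, reg[gen_pid], np.full(g.sum(), index)))

    incl_pool = np.array(vocab.codes_with_role("inclusion"))
    ii = np.flatnonzero(has_incl)
    dx_pid.append(ii)
    dx_code.append(incl_pool[rng.integers(0, len(incl_pool), len(ii))])
    dx_date.append(_uniform_dates(rng, reg[ii], np.full(len(ii), index)))

    excl_pool = np.array(vocab.codes_with_role("exclusion"))
    ee = np.flatnonzero(has_excl)
    dx_pid.append(ee)
    dx_code.append(excl_pool[rng.integers(0, len(excl_pool), len(ee))])
    dx_date.append(_uniform_dates(rng, reg[ee], np.full(len(ee), index)))

    # antecedent (before age 30) and concurrent (after age 30) findings
    mid_birth = np.array(
        [np.datetime64(f"{y}-07-01", "D") for y in range(birth_year.min(), birth_year.max() + 1)]
    )[birth_year - birth_year.min()]
    turn30 = mid_birth + np.timedelta64(30 * 365 + 7, "D")
    for pair, pool_role, before in (
        (config.antecedent_probability, "antecedent", True),
        (config.concurrent_probability, "concurrent", False),
    ):
        pool = np.array(vocab.codes_with_role(pool_role))
        flag = bern(pair)
        if before:
            lo, hi = reg, np.minimum(index, turn30 - np.timedelta64(1, "D"))
        else:
            lo, hi = np.maximum(reg, turn30), np.full(n, index)
        ok = np.flatnonzero(flag & (lo <= hi))
        dx_pid.append(ok)
        dx_code.append(pool[rng.integers(0, len(pool), len(ok))])
        dx_date.append(_uniform_dates(rng, lo[ok], hi[ok]))

    som_pool = np.array(vocab.codes_with_role("other"))
    som_n = np.minimum(rng.poisson(config.somatic_code_mean, n), len(som_pool))
    som_pid = np.repeat(np.arange(n), som_n)
    dx_pid.append(som_pid)
    dx_code.append(_pick_distinct(rng, som_pool, som_n))
    dx_date.append(_uniform_dates(rng, reg[som_pid], np.full(som_n.sum(), index)))

    diagnoses = pd.DataFrame(
        {
            "patient_id": pid[np.concatenate(dx_pid)],
            "code": np.concatenate(dx_code),
            "date": pd.to_datetime(np.concatenate(dx_date)),
        }
    ).sort_values(["patient_id", "date"], kind="stable", ignore_index=True)

    # ---- prescriptions ----
    med_window_start = (
        pd.Timestamp(index) - pd.DateOffset(years=10) + pd.Timedelta(days=1)
    ).to_datetime64().astype("datetime64[D]")

    rx_rows_pid, rx_rows_name, rx_rows_class, rx_rows_date = [], [], [], []
    churn = np.where(latent, config.regime_churn[1], config.regime_churn[0])
    script_mean = np.where(
        latent, config.scripts_per_regime_mean[1], config.scripts_per_regime_mean[0]
    )
    for cls_name, flag in (
        ("antidepressant", has_ad),
        ("antipsychotic", has_ap),
        ("hypnotic_anxiolytic", has_hy),
    ):
        names = np.array(MEDICATION_CLASSES[cls_name])
        holders = np.flatnonzero(flag)
        name_idx = rng.integers(0, len(names), len(holders))
        rows_pid = [holders]
        rows_name = [names[name_idx]]
        if cls_name == "antidepressant":
            swap = rng.random(len(holders)) < (
                config.second_antidepressant_probability * latent[holders]
            )
            extra = np.flatnonzero(swap)
            rows_pid.append(holders[extra])
            rows_name.append(names[(name_idx[extra] + 1) % len(names)])
        hp = np.concatenate(rows_pid)
        hn = np.concatenate(rows_name)
        n_regimes = 1 + rng.poisson(churn[hp])
        reg_pid = np.repeat(hp, n_regimes)
        reg_name = np.repeat(hn, n_regimes)
        n_scripts = rng.geometric(1.0 / script_mean[reg_pid])
        lo = np.maximum(reg[reg_pid], med_window_start)
        starts = _uniform_dates(rng, lo, np.full(len(reg_pid), index))
        ev_pid = np.repeat(reg_pid, n_scripts)
        ev_start = np.repeat(starts, n_scripts)
        within = np.concatenate([np.arange(c) for c in n_scripts]) if len(n_scripts) else \
            np.array([], dtype=np.int64)
        ev_date = ev_start + (within * config.script_interval_days).astype("timedelta64[D]")
        keep = ev_date <= index
        rx_rows_pid.append(ev_pid[keep])
        rx_rows_name.append(np.repeat(reg_name, n_scripts)[keep])
        rx_rows_class.append(np.full(keep.sum(), cls_name))
        rx_rows_date.append(ev_date[keep])

    other_holders = np.flatnonzero(rng.random(n) < config.other_medication_probability)
    other_counts = 1 + rng.poisson(0.5, len(other_holders))
    op = np.repeat(other_holders, other_counts)
    rx_rows_pid.append(op)
    rx_rows_name.append(
        np.array(OTHER_MEDICATIONS)[rng.integers(0, len(OTHER_MEDICATIONS), len(op))]
    )
    rx_rows_class.append(np.full(len(op), "other"))
    rx_rows_date.append(_uniform_dates(rng, reg[op], np.full(len(op), index)))

    prescriptions = pd.DataFrame(
        {
            "patient_id": pid[np.concatenate(rx_rows_pid)],
            "medication": np.concatenate(rx_rows_name),
            "med_class": np.concatenate(rx_rows_class),
            "date": pd.to_datetime(np.concatenate(rx_rows_date)),
        }
    ).sort_values(["patient_id", "date"], kind="stable", ignore_index=True)

    # ---- appointments ----
    n_months = config.appointment_history_years * 12
    index_month = index.astype("datetime64[M]")
    months = index_month - np.arange(n_months - 1, -1, -1).astype("timedelta64[M]")
    month_start = months.astype("datetime64[D]")
    month_days = ((months + np.timedelta64(1, "M")).astype("datetime64[D]") - month_start).astype(
        np.int64
    )
    active = month_start[None, :] >= reg[:, None]
    lam = (
        config.appointment_rate_per_month
        * np.where(latent, config.appointment_rate_ratio, 1.0)[:, None]
        * active
    )
    counts = rng.poisson(lam)
    sd = config.dna_month_sd * np.where(
        latent, config.nonattendance_irregularity_multiplier, 1.0
    )
    logit = (
        config.dna_base_logit
        + config.dna_case_logit_shift * latent[:, None]
        + rng.normal(0.0, 1.0, counts.shape) * sd[:, None]
    )
    p_dna = 1.0 / (1.0 + np.exp(-logit))
    dna = rng.binomial(counts, p_dna)

    ap_pid, ap_month, ap_status = [], [], []
    for status, mat in (("DNA", dna), ("attended", counts - dna)):
        r, c = np.nonzero(mat)
        reps = mat[r, c]
        ap_pid.append(np.repeat(r, reps))
        ap_month.append(np.repeat(c, reps))
        ap_status.append(np.full(reps.sum(), status))
    ap_pid = np.concatenate(ap_pid)
    ap_month = np.concatenate(ap_month)
    day_off = rng.integers(0, month_days[ap_month])
    appointments = pd.DataFrame(
        {
            "patient_id": pid[ap_pid],
            "date": pd.to_datetime(month_start[ap_month] + day_off.astype("timedelta64[D]")),
            "status": np.concatenate(ap_status),
        }
    ).sort_values(["patient_id", "date"], kind="stable", ignore_index=True)

    # ---- referrals ----
    ref_n = rng.poisson(np.where(latent, config.referral_rate[1], config.referral_rate[0]))
    rp = np.repeat(np.arange(n), ref_n)
    referrals = pd.DataFrame(
        {
            "patient_id": pid[rp],
            "referral_type": np.full(len(rp), "IAPT"),
            "date": pd.to_datetime(_uniform_dates(rng, reg[rp], np.full(len(rp), index))),
        }
    ).sort_values(["patient_id", "date"], kind="stable", ignore_index=True)

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "birth_year": birth_year,
            "registration_date": pd.to_datetime(reg),
        }
    )
    truth = pd.DataFrame({"patient_id": pid, "latent_status": latent.astype(int)})
    return Cohort(patients, diagnoses, prescriptions, appointments, referrals, truth)
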