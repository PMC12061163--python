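"""End-to-end orchestration: simulate -> phenotype -> extract -> rank -> evaluate.

One :func:`run_pipeline` call produces, from a config and a master seed,
the labels table, the feature matrix and metadata, the ranked feature-set
table (components, family levels and wildcard combinations), the
evaluation table for binary feature sets, a rank-vs-MI export for
log10-rank plotting, a caseness summary in the layout of a published
cohort breakdown, and a run manifest with per-stage record counts.

The master seed fans out to named sub-seeds (generation; one jitter stream
per continuous feature), so a config plus seed fixes every artifact
byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mi as mi_mod
from .evaluate import disclosure_control, evaluation_table
from .families import (
    FamilyLevelAssignment,
    assign_levels,
    enumerate_combinations,
)
from .features import FeatureMatrix, extract_features
from .phenotype import PhenotypeSpec, build_study_population
from .synthetic import Cohort, GeneratorConfig, generate_cohort
from .vocab import CodeVocabulary, default_vocabulary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one reproducible screening run."""

    out_dir: str = "ehrscreen_run"
    seed: int = 0
    in_dir: str | None = None           # read an existing cohort instead
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    phenotype: PhenotypeSpec = field(default_factory=PhenotypeSpec)
    attendance_years: int = 4
    knn_k: int = 3
    knn_runs: int = 20
    combination_cap: int = 1500
    combination_prune: bool = True
    disclosure_control: bool = True
    continuity_correction: bool = False
    top_k: int = 5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig.from_dict(raw.pop("generator", {}))
        phen = raw.pop("phenotype", {})
        for key in ("inclusion_roots", "exclusion_roots", "medications"):
            if key in phen:
                phen[key] = tuple(phen[key])
        if "index_date" in phen:
            phen["index_date"] = pd.Timestamp(phen["index_date"]).date()
        return cls(generator=gen, phenotype=PhenotypeSpec(**phen), **raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        d["phenotype"]["index_date"] = self.phenotype.index_date.isoformat()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class ScreenResult:
    labels: pd.DataFrame
    features: FeatureMatrix
    assignment: FamilyLevelAssignment
    ranked: pd.DataFrame
    evaluation: pd.DataFrame | None
    combinations: pd.DataFrame
    caseness_entropy: float
    non_informative: dict[str, int]
    skipped_features: list[str]


def _rank_all_feature_sets(
    fm: FeatureMatrix,
    assignment: FamilyLevelAssignment,
    caseness: np.ndarray,
    seed: int,
    knn_k: int,
    knn_runs: int,
    cap: int,
    prune: bool,
):
    """Estimate scaled MI for components, family levels and combinations."""
    y = caseness.astype(np.int8)
    h_case = mi_mod.binary_entropy(float(y.mean()))
    estimates: list[mi_mod.MIEstimate] = []
    types: dict[str, str] = {}
    non_informative = {"component": 0, "family": 0, "combination": 0}
    skipped: list[str] = []

    value_types = fm.metadata.set_index("feature_id")["value_type"]
    binary_cols, binary_ids = [], []

    def add_binary(col: np.ndarray, fid: str, ftype: str) -> None:
        if col.min() == col.max():
            non_informative[ftype] += 1
            return
        binary_cols.append(col)
        binary_ids.append(fid)
        types[fid] = ftype

    for fid in fm.values.columns:
        x = fm.values[fid].to_numpy()
        vt = value_types[fid]
        if vt == "binary":
            add_binary(x.astype(np.int8), fid, "component")
            continue
        obs = x[~pd.isna(x)]
        if len(obs) == 0 or obs.min() == obs.max():
            non_informative["component"] += 1
            continue
        yy = y[~pd.isna(x)]
        if yy.min() == yy.max():  # missingness wiped out one class
            skipped.append(fid)
            continue
        distinct = len(np.unique(obs))
        if vt == "count" and distinct <= mi_mod.DISCRETE_CARDINALITY_LIMIT:
            v = mi_mod.plugin_mi_discrete(obs, yy)
            estimates.append(
                mi_mod.MIEstimate(fid, v, v / h_case, "plugin_discrete", 1, len(obs))
            )
            types[fid] = "component"
        else:
            fid_key = int.from_bytes(
                hashlib.blake2b(fid.encode(), digest_size=4).digest(), "big"
            )
            ss = np.random.SeedSequence([seed, fid_key])
            if min(np.bincount(yy)) <= knn_k:
                skipped.append(fid)
                continue
            est = mi_mod.knn_mixed_mi(
                obs, yy, k=knn_k, n_runs=knn_runs, seed=ss,
                feature_id=fid, caseness_entropy=h_case,
            )
            estimates.append(est)
            types[fid] = "component"

    for fid, col in assignment.as_feature_table().items():
        add_binary(col.to_numpy(), fid, "family")

    combo_rows = []
    for spec, col in enumerate_combinations(assignment, prune=prune, cap=cap):
        add_binary(col, spec.identifier, "combination")
        combo_rows.append((spec.identifier, int(col.sum())))
    combinations = pd.DataFrame(combo_rows, columns=["identifier", "support"])

    if binary_cols:
        X = np.stack(binary_cols, axis=1)
        vals = mi_mod.plugin_mi_binary_many(X, y)
        for fid, v, col in zip(binary_ids, vals, binary_cols):
            estimates.append(
                mi_mod.MIEstimate(fid, float(v), float(v) / h_case,
                                  "plugin_discrete", 1, len(col))
            )

    ranked = mi_mod.rank_feature_sets(estimates)
    ranked["feature_type"] = ranked["feature_id"].map(types)
    binary_table = pd.DataFrame(
        {fid: col for fid, col in zip(binary_ids, binary_cols)},
        index=fm.values.index,
    )
    return ranked, combinations, binary_table, h_case, non_informative, skipped


def screen_cohort(
    cohort: Cohort,
    config: RunConfig,
    vocab: CodeVocabulary | None = None,
    with_evaluation: bool = True,
) -> ScreenResult:
    """Phenotype a cohort and rank every feature set against caseness.

    The analysis population is the study population; caseness entropy, all
    mutual-information estimates and the evaluation statistics are computed
    within it.
    """
    vocab = vocab or default_vocabulary()
    labels = build_study_population(cohort, config.phenotype, vocab)
    study = labels[labels["in_study_population"]]
    fm = extract_features(
        cohort,
        vocab,
        index_date=config.phenotype.index_date,
        attendance_years=config.attendance_years,
        patient_ids=study["patient_id"].to_numpy(),
    )
    caseness = study["is_case"].to_numpy()
    assignment = assign_levels(fm)
    ranked, combinations, binary_table, h_case, non_inf, skipped = _rank_all_feature_sets(
        fm,
        assignment,
        caseness,
        seed=config.seed,
        knn_k=config.knn_k,
        knn_runs=config.knn_runs,
        cap=config.combination_cap,
        prune=config.combination_prune,
    )
    evaluation = None
    if with_evaluation:
        evaluation = evaluation_table(
            binary_table,
            caseness,
            use_controlled=config.disclosure_control,
            continuity_correction=config.continuity_correction,
        )
    return ScreenResult(
        labels=labels,
        features=fm,
        assignment=assignment,
        ranked=ranked,
        evaluation=evaluation,
        combinations=combinations,
        caseness_entropy=h_case,
        non_informative=non_inf,
        skipped_features=skipped,
    )


def _pct(numerator: int | None, denominator: int | None) -> float:
    if not numerator or not denominator:
        return float("nan")
    return round(100.0 * numerator / denominator, 1)


def summarize_from_counts(
    total: int, study: int, cases: int, apply_control: bool = True
) -> dict:
    """Cohort arithmetic on (possibly disclosure-controlled) headline counts."""
    if apply_control:
        total_c, study_c, cases_c = (
            disclosure_control(c) for c in (total, study, cases)
        )
    else:
        total_c, study_c, cases_c = total, study, cases
    return {
        "total_population": total_c,
        "study_population": study_c,
        "cases": cases_c,
        "study_pct_of_total": _pct(study_c, total_c),
        "case_pct_of_total": _pct(cases_c, total_c),
        "case_pct_of_study": _pct(cases_c, study_c),
    }


def summarize_caseness(labels: pd.DataFrame, apply_control: bool = True) -> pd.DataFrame:
    """Caseness breakdown in the layout of a published cohort table.

    Counts pass through disclosure control before the percentages are
    computed; criterion percentages are relative to the study population.
    """
    study = labels[labels["in_study_population"]]
    head = summarize_from_counts(
        len(labels), len(study), int(labels["is_case"].sum()), apply_control
    )
    rows = [
        ("total_population", head["total_population"], float("nan")),
        ("study_population", head["study_population"], head["study_pct_of_total"]),
        ("cases_total_basis", head["cases"], head["case_pct_of_total"]),
        ("cases_study_basis", head["cases"], head["case_pct_of_study"]),
    ]
    denom = head["study_population"]
    for name, flag in [
        ("inclusion_diagnosis_ever", "has_inclusion_diagnosis_ever"),
        ("recent_medication", "has_recent_medication"),
    ]:
        c = int(study[flag].sum())
        c = disclosure_control(c) if apply_control else c
        rows.append((f"study_{name}", c, _pct(c, denom)))
    excl = int(labels["has_exclusion_diagnosis"].sum())
    excl = disclosure_control(excl) if apply_control else excl
    rows.append(("any_exclusion_diagnosis", excl, _pct(excl, head["total_population"])))
    return pd.DataFrame(rows, columns=["group", "count", "percent"])


def run_pipeline(config: RunConfig, vocab: CodeVocabulary | None = None) -> dict:
    """Run every stage, write all artifacts under ``config.out_dir``.

    Returns the manifest (also written as ``manifest.json``). Output files
    are regenerated from scratch on every call.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vocab = vocab or default_vocabulary()

    if config.in_dir:
        cohort = Cohort.from_dir(config.in_dir)
    else:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        cohort = generate_cohort(gen, vocab)
        cohort.to_dir(out / "cohort", write_truth=False)
        cohort.truth.to_csv(out / "truth.csv", index=False)

    res = screen_cohort(cohort, config, vocab)
    res.labels.to_csv(out / "labels.csv", index=False)
    res.features.to_files(out / "features.csv", out / "feature_metadata.csv")
    res.ranked.to_csv(out / "ranked_feature_sets.csv", index=False)
    if res.evaluation is not None:
        res.evaluation.to_csv(out / "evaluation.csv", index=False)

    census = res.combinations.copy()
    census["support_controlled"] = [
        disclosure_control(int(s)) for s in census["support"]
    ]
    census.drop(columns="support").to_csv(out / "combination_census.csv", index=False)

    rank_plot = res.ranked[["rank", "mi_scaled", "feature_type"]].copy()
    rank_plot["log10_rank"] = np.log10(rank_plot["rank"])
    rank_plot["mi_scaled_pct"] = 100 * rank_plot["mi_scaled"]
    rank_plot.to_csv(out / "rank_vs_mi.csv", index=False)

    summary = summarize_caseness(res.labels, apply_control=config.disclosure_control)
    summary.to_csv(out / "caseness_summary.csv", index=False)

    top = res.ranked.head(config.top_k)
    manifest = {
        "seed": config.seed,
        "n_total": int(len(res.labels)),
        "n_study_population": int(res.labels["in_study_population"].sum()),
        "n_cases": int(res.labels["is_case"].sum()),
        "caseness_entropy_nats": res.caseness_entropy,
        "n_component_features": int(len(res.features.metadata)),
        "n_combinations": int(len(res.combinations)),
        "n_ranked_feature_sets": int(len(res.ranked)),
        "non_informative": res.non_informative,
        "skipped_features": res.skipped_features,
        "top_feature_sets": top[["feature_id", "feature_type", "mi_scaled", "rank"]]
        .to_dict("records"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info(
        "pipeline complete: %d patients, %d in study population, %d cases",
        manifest["n_total"], manifest["n_study_population"], manifest["n_cases"],
    )
    return manifest
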