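"""End-to-end orchestration: simulate -> prep -> mine -> factorize ->
represent -> validate -> profile, with one config, one master seed, and a run
manifest hashing every artifact."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import factorization as fz
from . import mining, prep, profiling, representatives, synthetic, validation

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "mine", "factorize", "represent", "validate", "profile")


class ConfigError(ValueError):
    """Invalid run configuration (caught before any stage runs)."""


class StageError(RuntimeError):
    def __init__(self, stage: str, artifact: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {artifact}: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "sanmf_run"
    n_patients: int = 300
    interval: float = 6.0
    min_support: int = 5
    min_size: int = 2
    max_size: int = 6
    clip: int = 4
    k: int = 3
    n_consensus_runs: int = 30
    top_n: int = 100
    threshold: float = 1.0
    split_ratio: float = 0.8
    test_size: float = 0.2
    gbm_estimators: int = 300
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort_dir: str | None = None   # read an existing cohort instead of simulating

    def validate(self) -> None:
        if self.min_support < 1:
            raise ConfigError("min_support must be >= 1")
        if not 1 <= self.min_size <= self.max_size:
            raise ConfigError("need 1 <= min_size <= max_size")
        if self.interval not in (6.0, 24.0):
            raise ConfigError("interval must be 6 or 24 hours")
        if self.k < 2:
            raise ConfigError("k must be >= 2")
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigError("split_ratio must lie in (0, 1)")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def stage_seed(master: int, stage: str) -> int:
    """Named substream per stage derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in order, writing artifacts and a manifest.

    The manifest (config snapshot, per-artifact SHA-256 hashes, stage counts)
    is written even when a stage fails, with the failed stage marked."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "failed_stage": None,
    }
    state: dict[str, Any] = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            t0 = time.time()
            try:
                counts = _STAGE_FNS[stage](config, state, out)
            except Exception as exc:  # noqa: BLE001 - manifest must record failures
                manifest["failed_stage"] = stage
                raise StageError(stage, str(out / stage), exc) from exc
            artifacts = {
                str(p.relative_to(out)): _sha256(p)
                for p in sorted(out.rglob("*"))
                if p.is_file() and p.name != "manifest.json"
            }
            manifest["stages"][stage] = {
                "seconds": round(time.time() - t0, 3),
                "counts": counts,
            }
            manifest["artifact_hashes"] = artifacts
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    manifest["results"] = state
    return manifest


def _stage_simulate(config, state, out):
    if config.cohort_dir:
        cohort = synthetic.read_cohort(config.cohort_dir)
    else:
        spec = synthetic.make_paperlike_spec(
            config.n_patients, seed=stage_seed(config.seed, "simulate")
        )
        cohort = synthetic.generate_cohort(spec)
    synthetic.write_cohort(cohort, out / "cohort")
    state["cohort"] = cohort
    return {"patients": len(cohort.patients), "records": len(cohort.records)}


def _stage_prep(config, state, out):
    cohort = state["cohort"]
    corpora, stats = prep.prepare_corpora(
        cohort.records, interval=config.interval, clip=config.clip
    )
    prep.write_corpora(corpora, out / "corpora.jsonl")
    state["corpora"] = corpora
    state["stats"] = stats
    n_chains = sum(len(c) for c in corpora.values())
    return {"variables": len(stats), "chains": n_chains}


def _stage_mine(config, state, out):
    cohort = state["cohort"]
    matrix = mining.mine_all(
        state["corpora"], config.min_support, config.min_size, config.max_size,
        patients=cohort.patient_ids,
    )
    mining.write_matrix(matrix, out / "matrix")
    state["matrix"] = matrix
    return {"mined": matrix.n_mined, "dropped": matrix.n_dropped,
            "retained": matrix.n_retained}


def _stage_factorize(config, state, out):
    matrix = state["matrix"]
    seed = stage_seed(config.seed, "factorize")
    consensus = fz.consensus_cophenetic(
        matrix.counts, config.k, config.n_consensus_runs, seed
    )
    factors = consensus.best_factors
    labels_by_row, unassigned = fz.assign_membership(factors.W)
    assignment = {matrix.patients[i]: lab for i, lab in labels_by_row.items()}
    np.savetxt(out / "W.csv", factors.W, delimiter=",")
    np.savetxt(out / "H.csv", factors.H, delimiter=",")
    pd.Series(assignment, name="subgroup").rename_axis("patient_id").to_csv(
        out / "assignment.csv"
    )
    state["factors"] = factors
    state["consensus"] = consensus
    state["assignment"] = assignment
    sizes = pd.Series(list(assignment.values())).value_counts().to_dict()
    return {"objective": factors.objective,
            "cophenetic_rho": consensus.cophenetic_rho,
            "unassigned": len(unassigned),
            "subgroup_sizes": {int(k): int(v) for k, v in sizes.items()}}


def _stage_represent(config, state, out):
    matrix = state["matrix"]
    groups = representatives.select_representatives(
        state["factors"].H, matrix.subgraphs,
        top_n=config.top_n, threshold=config.threshold,
    )
    summary = representatives.exclusivity_summary(groups)
    rows = []
    exclusive = set(summary["exclusive_ids"])
    for g in groups:
        for sid, coef in g.members:
            rows.append({"component": g.component, "subgraph_id": sid,
                         "coefficient": coef, "exclusive": sid in exclusive})
    pd.DataFrame(rows).to_csv(out / "representatives.csv", index=False)
    state["trend_groups"] = groups
    state["representative_union"] = representatives.representative_union(groups)
    return {"n_unique": summary["n_unique"], "n_exclusive": summary["n_exclusive"]}


def _stage_validate(config, state, out):
    cohort = state["cohort"]
    matrix = state["matrix"]
    seed = stage_seed(config.seed, "validate")
    params = validation.GBMParams(n_estimators=config.gbm_estimators)

    sub_features = validation.build_features(
        "representative_subgraphs", matrix=matrix,
        representative_ids=state["representative_union"],
    )
    membership = validation.train_membership_classifier(
        sub_features, state["assignment"], test_size=config.test_size,
        seed=seed, params=params,
    )
    mortality = dict(zip(cohort.patients["patient_id"],
                         cohort.patients["mortality_30d"].astype(bool)))
    reports = {}
    shared_split = None
    for name in validation.FEATURE_SETS:
        feats = validation.build_features(
            name, matrix=matrix, representative_ids=state["representative_union"],
            sofa=cohort.sofa, comorbidities=cohort.comorbidities,
        )
        common = [p for p in cohort.patient_ids if p in set(feats.patient_ids)]
        keep = {p: i for i, p in enumerate(feats.patient_ids)}
        feats = validation.FeatureSet(
            name, common, feats.X[[keep[p] for p in common]], feats.feature_names
        )
        if shared_split is None:
            labels = [int(mortality[p]) for p in common]
            shared_split = validation._split_ids(common, labels,
                                                 config.test_size, seed)
        reports[name] = validation.train_mortality_model(
            feats, mortality, seed=seed, params=params, split=shared_split,
        )
    ranking = validation.compare_benchmarks(reports)
    membership.metrics.to_csv(out / "membership_metrics.csv", index=False)
    for name, rep in reports.items():
        rep.metrics.to_csv(out / f"mortality_{name}_metrics.csv", index=False)
    ranking.to_csv(out / "benchmark_ranking.csv", index=False)
    state["membership_report"] = membership
    state["mortality_reports"] = reports
    state["benchmark_ranking"] = ranking
    test_acc = membership.metrics.loc[
        membership.metrics["split"] == "test", "accuracy"].iloc[0]
    return {"membership_test_accuracy": float(test_acc),
            "benchmark_order": list(ranking["feature_set"])}


def _stage_profile(config, state, out):
    cohort = state["cohort"]
    assignment = state["assignment"]
    demo = profiling.demographics_table(cohort.patients, assignment)
    trend = profiling.sofa_trend(cohort.sofa, assignment)
    comorb = profiling.comorbidity_incidence(cohort.comorbidities, assignment)
    tests = profiling.subgroup_tests(cohort.patients, cohort.comorbidities, assignment)
    demo.to_csv(out / "demographics.csv")
    trend.to_csv(out / "sofa_trend.csv", index=False)
    comorb.to_csv(out / "comorbidity_incidence.csv", index=False)
    tests.to_csv(out / "subgroup_tests.csv", index=False)
    state["profile"] = {"demographics": demo, "sofa_trend": trend,
                        "comorbidities": comorb, "tests": tests}
    return {"n_tests": len(tests), "n_rejected": int(tests["reject"].sum())}


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "mine": _stage_mine,
    "factorize": _stage_factorize,
    "represent": _stage_represent,
    "validate": _stage_validate,
    "profile": _stage_profile,
}


def run_in_memory(
    cohort: synthetic.SyntheticCohort,
    interval: float = 6.0,
    min_support: int = 5,
    k: int = 3,
    n_consensus_runs: int = 10,
    clip: int = 4,
    seed: int = 0,
) -> dict:
    """Prep + mine + factorize + assign, without touching disk.

    Returns corpora, the count matrix, the fitted factors, the consensus
    result, and the patient -> subgroup assignment. This is the core path the
    recovery experiments exercise.
    """
    corpora, stats = prep.prepare_corpora(cohort.records, interval=interval, clip=clip)
    matrix = mining.mine_all(corpora, min_support, patients=cohort.patient_ids)
    consensus = fz.consensus_cophenetic(matrix.counts, k, n_consensus_runs, seed)
    factors = consensus.best_factors
    labels_by_row, _ = fz.assign_membership(factors.W)
    assignment = {matrix.patients[i]: lab for i, lab in labels_by_row.items()}
    return {
        "corpora": corpora,
        "stats": stats,
        "matrix": matrix,
        "factors": factors,
        "consensus": consensus,
        "assignment": assignment,
    }
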