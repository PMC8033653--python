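"""Synthetic sepsis cohort generator.

Emulates the statistical structure the phenotyping pipeline assumes in real ICU
data: a small number of latent trend groups, each with its own per-variable
physiological trajectory on the z-scale, irregular and sparse measurement
times, and group-linked outcomes (30-day mortality, 7-day SOFA trajectories,
Elixhauser comorbidity profiles, demographics). Ground-truth group labels are
kept so recovery tests can score the unsupervised pipeline against the planted
partition.

Variables are generated independently given the group; no physiologic coupling
between variables is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .registry import (
    ELIXHAUSER_CATEGORIES,
    ETHNICITIES,
    SOFA_SUBSCORES,
    VAN_WALRAVEN_WEIGHTS,
    VARIABLE_STATS,
    VARIABLES,
)

HORIZON_HOURS = 72.0
N_WINDOWS = 12  # 6-hour windows over 72 h

Archetype = Callable[[float], float]


class SpecValidationError(ValueError):
    """A cohort spec violates one of its invariants."""


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``trend_archetypes`` maps ``(group, variable)`` to a function of the
    window index (0..11) returning the group's mean z-score for that variable
    in that window. Groups are numbered 1..n_groups.
    """

    n_patients: int
    n_groups: int = 3
    group_proportions: tuple[float, ...] = (0.21, 0.35, 0.44)
    trend_archetypes: Mapping[tuple[int, str], Archetype] = field(default_factory=dict)
    noise_sd: float = 0.5
    sampling_rate: float = 24.0           # expected measurements / variable / 72 h
    missing_variable_prob: float = 0.05
    mortality_logit: tuple[float, ...] = (-1.586, -0.925, -2.183)
    sofa_day1_mean: tuple[float, ...] = (6.51, 8.65, 6.50)
    sofa_slope: tuple[float, ...] = (-0.35, -0.05, -0.70)
    sofa_subscore_weights: tuple[tuple[float, ...], ...] = (
        (0.15, 0.10, 0.05, 0.25, 0.10, 0.35),
        (0.15, 0.10, 0.15, 0.25, 0.05, 0.30),
        (0.15, 0.10, 0.05, 0.15, 0.40, 0.15),
    )
    comorbidity_prevalence: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    variable_stats: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(VARIABLE_STATS)
    )
    # demographics, per group
    age_mean: tuple[float, ...] = (73.1, 67.9, 59.9)
    age_sd: tuple[float, ...] = (14.6, 16.3, 18.2)
    male_fraction: tuple[float, ...] = (0.590, 0.603, 0.504)
    weight_mean: tuple[float, ...] = (84.3, 83.0, 79.4)
    weight_sd: tuple[float, ...] = (35.1, 24.3, 25.5)
    bmi_mean: tuple[float, ...] = (29.4, 29.5, 28.4)
    bmi_sd: tuple[float, ...] = (8.7, 8.7, 8.7)
    los_mean: tuple[float, ...] = (3.1, 6.2, 4.2)
    ethnicity_probs: tuple[tuple[float, ...], ...] = (
        (0.024, 0.096, 0.767, 0.014, 0.099),
        (0.030, 0.086, 0.722, 0.031, 0.131),
        (0.036, 0.082, 0.711, 0.043, 0.128),
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise SpecValidationError("n_patients must be a positive integer")
        if self.n_groups < 1:
            raise SpecValidationError("n_groups must be a positive integer")
        props = np.asarray(self.group_proportions, dtype=float)
        if props.size != self.n_groups:
            raise SpecValidationError(
                "group_proportions length must equal n_groups"
            )
        if (props < 0).any():
            raise SpecValidationError("group_proportions entries must be >= 0")
        if abs(props.sum() - 1.0) > 1e-9:
            raise SpecValidationError("group_proportions must sum to 1 within 1e-9")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd must be nonnegative")
        if self.sampling_rate <= 0:
            raise SpecValidationError("sampling_rate must be positive")
        if not 0.0 <= self.missing_variable_prob <= 1.0:
            raise SpecValidationError("missing_variable_prob must lie in [0, 1]")
        if len(self.variable_stats) != len(VARIABLES):
            raise SpecValidationError(
                f"variable registry must have exactly {len(VARIABLES)} entries"
            )
        for name, (_, sd) in self.variable_stats.items():
            if sd <= 0:
                raise SpecValidationError(f"variable {name!r} must have sd > 0")
        for g, table in self.comorbidity_prevalence.items():
            for cat, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise SpecValidationError(
                        f"comorbidity_prevalence[{g}][{cat!r}] must lie in [0, 1]"
                    )
        for name in ("mortality_logit", "sofa_day1_mean", "sofa_slope"):
            if len(getattr(self, name)) != self.n_groups:
                raise SpecValidationError(f"{name} must have one entry per group")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground-truth group labels."""

    records: pd.DataFrame        # patient_id, variable, t_hours, value
    patients: pd.DataFrame       # demographics + outcomes, one row per patient
    sofa: pd.DataFrame           # patient_id, day, 6 subscores, total
    comorbidities: pd.DataFrame  # patient_id + 30 boolean columns
    truth: dict[str, int]        # patient_id -> group label 1..n_groups

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])


# ---------------------------------------------------------------------------
# archetype bank used by make_paperlike_spec


def _flat(level: float) -> Archetype:
    return lambda w: level


def _ramp(start: float, end: float) -> Archetype:
    return lambda w: start + (end - start) * w / (N_WINDOWS - 1)


def _bump(base: float, apex: float) -> Archetype:
    # rises to apex at mid-stay, returns to base
    def f(w: float) -> float:
        half = (N_WINDOWS - 1) / 2
        return apex - (apex - base) * abs(w - half) / half
    return f


_ARCHETYPE_BANK: tuple[Archetype, ...] = (
    _flat(0.0),
    _flat(1.0),
    _flat(-1.0),
    _ramp(-1.0, 1.0),
    _ramp(1.0, -1.0),
    _ramp(0.0, 2.0),
    _ramp(0.0, -2.0),
    _ramp(2.0, 0.0),
    _bump(0.0, 2.0),
    _bump(0.0, -2.0),
)


# Shared-variable allocation for the three group pairs. Each pair of trend
# groups shares its trajectory shape on a subset of variables (phenotypes
# overlap on some physiology); subset sizes are chosen so that, weighted by
# the harmonic group sizes n_a*n_b/(n_a+n_b) at proportions 21/35/44%, the
# cost of collapsing any two groups into one is about the same for all three
# pairs — no pair of planted phenotypes is systematically easier to merge.
_SHARED_PAIR_ALLOCATION: tuple[tuple[int, int], ...] = (
    *(((1, 2),) * 8),
    *(((2, 3),) * 16),
    *(((1, 3),) * 10),
)


def make_paperlike_spec(n_patients: int, seed: int) -> CohortSpec:
    """Spec for a 3-group cohort mirroring the study's group structure.

    Group proportions 21/35/44%, per-group 30-day mortality near 17/28/10%,
    SOFA day-1 means and slopes reflecting slow / no / fast improvement, and
    comorbidity prevalences on the scale of the study's incidence table.

    For each variable, one designated pair of groups shares a trajectory
    shape drawn from a fixed bank of flat/rising/falling/peaked archetypes
    and the remaining group gets a different shape; the shared pair rotates
    over variables with sizes balancing the pairwise phenotype contrasts
    (see ``_SHARED_PAIR_ALLOCATION``), so all three groups are comparably
    distinct from one another.
    """
    if n_patients < 3:
        raise SpecValidationError("n_patients must be at least n_groups (3)")
    rng = np.random.default_rng(seed)
    archetypes: dict[tuple[int, str], Archetype] = {}
    for i, var in enumerate(VARIABLES):
        close = _SHARED_PAIR_ALLOCATION[i]
        far = next(g for g in (1, 2, 3) if g not in close)
        a, b = rng.choice(len(_ARCHETYPE_BANK), size=2, replace=False)
        for g in close:
            archetypes[(g, var)] = _ARCHETYPE_BANK[a]
        archetypes[(far, var)] = _ARCHETYPE_BANK[b]
    return CohortSpec(
        n_patients=n_patients,
        n_groups=3,
        group_proportions=(0.21, 0.35, 0.44),
        trend_archetypes=archetypes,
        comorbidity_prevalence=_paperlike_comorbidity_prevalence(),
        seed=seed,
    )


def _paperlike_comorbidity_prevalence() -> dict[int, dict[str, float]]:
    """Per-group prevalences: the 17 high-incidence categories on the scale of
    the study's incidence table, modest flat rates for the remaining 13."""
    from_table = {
        "hypertension": (0.699, 0.652, 0.486),
        "fluid_electrolyte": (0.421, 0.619, 0.354),
        "cardiac_arrhythmias": (0.386, 0.371, 0.225),
        "congestive_heart_failure": (0.324, 0.306, 0.150),
        "deficiency_anemias": (0.229, 0.290, 0.214),
        "diabetes_uncomplicated": (0.281, 0.257, 0.166),
        "chronic_pulmonary": (0.234, 0.210, 0.205),
        "renal_failure": (0.281, 0.289, 0.068),
        "coagulopathy": (0.099, 0.296, 0.120),
        "other_neurological": (0.151, 0.132, 0.218),
        "hypothyroidism": (0.154, 0.133, 0.107),
        "depression": (0.117, 0.130, 0.140),
        "liver_disease": (0.062, 0.174, 0.095),
        "valvular_disease": (0.118, 0.130, 0.072),
        "alcohol_abuse": (0.061, 0.106, 0.129),
        "peripheral_vascular": (0.113, 0.120, 0.054),
        "pulmonary_circulation": (0.099, 0.111, 0.063),
    }
    background = {
        "paralysis": 0.04, "diabetes_complicated": 0.08, "peptic_ulcer": 0.03,
        "aids": 0.01, "lymphoma": 0.02, "metastatic_cancer": 0.05,
        "solid_tumor": 0.06, "rheumatoid_arthritis": 0.03, "obesity": 0.10,
        "weight_loss": 0.08, "blood_loss_anemia": 0.03, "drug_abuse": 0.05,
        "psychoses": 0.04,
    }
    out: dict[int, dict[str, float]] = {}
    for g in (1, 2, 3):
        table = {}
        for cat in ELIXHAUSER_CATEGORIES:
            if cat in from_table:
                table[cat] = from_table[cat][g - 1]
            else:
                table[cat] = background[cat]
        out[g] = table
    return out


# ---------------------------------------------------------------------------
# generation


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort. Deterministic for a fixed ``spec.seed``."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    rng_assign, rng_records, rng_outcomes, rng_sofa, rng_comorb = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    n = spec.n_patients
    ids = [f"P{i:05d}" for i in range(n)]
    groups = rng_assign.choice(
        np.arange(1, spec.n_groups + 1), size=n, p=np.asarray(spec.group_proportions)
    )
    truth = dict(zip(ids, (int(g) for g in groups)))

    records = _generate_records(spec, ids, groups, rng_records)
    comorb = _generate_comorbidities(spec, ids, groups, rng_comorb)
    sofa = _generate_sofa(spec, ids, groups, rng_sofa)
    patients = _generate_outcomes(spec, ids, groups, sofa, comorb, rng_outcomes)

    # drop SOFA days after death for 30-day non-survivors who die inside day 7
    death_day = dict(zip(patients["patient_id"], patients["_death_day"]))
    sofa = sofa[[pd.isna(death_day[p]) or d <= death_day[p]
                 for p, d in zip(sofa["patient_id"], sofa["day"])]].reset_index(drop=True)
    patients = patients.drop(columns=["_death_day"])

    return SyntheticCohort(records=records, patients=patients, sofa=sofa,
                           comorbidities=comorb, truth=truth)


def _generate_records(spec, ids, groups, rng) -> pd.DataFrame:
    pid_col: list[str] = []
    var_col: list[str] = []
    t_col: list[float] = []
    val_col: list[float] = []
    for pid, g in zip(ids, groups):
        for var in spec.variable_stats:
            if rng.random() < spec.missing_variable_prob:
                continue
            n_obs = rng.poisson(spec.sampling_rate)
            if n_obs == 0:
                continue
            times = np.sort(rng.uniform(0.0, HORIZON_HOURS, size=n_obs))
            arch = spec.trend_archetypes.get((int(g), var))
            windows = np.minimum(times // (HORIZON_HOURS / N_WINDOWS), N_WINDOWS - 1)
            z = np.array([arch(w) for w in windows]) if arch is not None else np.zeros(n_obs)
            if spec.noise_sd > 0:
                z = z + rng.normal(0.0, spec.noise_sd, size=n_obs)
            mean, sd = spec.variable_stats[var]
            pid_col.extend([pid] * n_obs)
            var_col.extend([var] * n_obs)
            t_col.extend(times.tolist())
            val_col.extend((mean + sd * z).tolist())
    return pd.DataFrame(
        {"patient_id": pid_col, "variable": var_col, "t_hours": t_col, "value": val_col}
    )


def _generate_comorbidities(spec, ids, groups, rng) -> pd.DataFrame:
    data = {"patient_id": ids}
    prev = spec.comorbidity_prevalence
    for cat in ELIXHAUSER_CATEGORIES:
        p = np.array([prev.get(int(g), {}).get(cat, 0.0) for g in groups])
        data[cat] = rng.random(len(ids)) < p
    return pd.DataFrame(data)


def _allocate_subscores(total: int, weights: np.ndarray, rng) -> np.ndarray:
    """Split an integer total across 6 subscores, each capped at 4, by largest
    remainder over the weight vector. Feasible whenever total <= 24."""
    ideal = weights * total
    sub = np.floor(ideal).astype(int)
    sub = np.minimum(sub, 4)
    while sub.sum() < total:
        room = sub < 4
        frac = np.where(room, ideal - sub, -np.inf)
        sub[int(np.argmax(frac))] += 1
    return sub


def _generate_sofa(spec, ids, groups, rng) -> pd.DataFrame:
    rows = []
    for pid, g in zip(ids, groups):
        gi = int(g) - 1
        weights = np.asarray(spec.sofa_subscore_weights[gi], dtype=float)
        weights = weights / weights.sum()
        for day in range(1, 8):
            mean_d = max(spec.sofa_day1_mean[gi] + spec.sofa_slope[gi] * (day - 1), 0.0)
            total = int(np.clip(np.rint(rng.normal(mean_d, 2.0)), 0, 24))
            sub = _allocate_subscores(total, weights, rng)
            rows.append((pid, day, *sub.tolist(), int(sub.sum())))
    return pd.DataFrame(rows, columns=["patient_id", "day", *SOFA_SUBSCORES, "total"])


def _generate_outcomes(spec, ids, groups, sofa, comorb, rng) -> pd.DataFrame:
    n = len(ids)
    gi = np.asarray(groups, dtype=int) - 1
    age = np.clip(rng.normal(np.take(spec.age_mean, gi), np.take(spec.age_sd, gi)), 18, 100)
    male = rng.random(n) < np.take(spec.male_fraction, gi)
    weight = np.clip(
        rng.normal(np.take(spec.weight_mean, gi), np.take(spec.weight_sd, gi)), 30, 300
    )
    bmi = np.clip(rng.normal(np.take(spec.bmi_mean, gi), np.take(spec.bmi_sd, gi)), 12, 80)
    los_mean = np.take(spec.los_mean, gi)
    los = rng.gamma(shape=1.5, scale=los_mean / 1.5)
    los = np.maximum(los, 0.25)
    eth_idx = np.array([
        rng.choice(len(ETHNICITIES), p=np.asarray(spec.ethnicity_probs[i]) /
                   np.sum(spec.ethnicity_probs[i]))
        for i in gi
    ])
    p_death = expit(np.take(spec.mortality_logit, gi))
    mort30 = rng.random(n) < p_death
    mort_inhosp = mort30 & (rng.random(n) < 0.75)
    death_day = [int(rng.integers(2, 31)) if m else None for m in mort30]

    day1 = sofa[sofa["day"] == 1].set_index("patient_id")["total"]
    weights = VAN_WALRAVEN_WEIGHTS
    cmat = comorb.set_index("patient_id")[list(ELIXHAUSER_CATEGORIES)]
    elix = cmat @ np.array([weights[c] for c in ELIXHAUSER_CATEGORIES])

    return pd.DataFrame({
        "patient_id": ids,
        "age": np.round(age, 1),
        "sex": np.where(male, "male", "female"),
        "weight": np.round(weight, 1),
        "bmi": np.round(bmi, 1),
        "ethnicity": [ETHNICITIES[i] for i in eth_idx],
        "icu_los": np.round(los, 2),
        "day1_sofa": [int(day1[p]) for p in ids],
        "elixhauser_index": [float(elix[p]) for p in ids],
        "mortality_30d": mort30,
        "mortality_inhosp": mort_inhosp,
        "_death_day": death_day,
    })


# ---------------------------------------------------------------------------
# disk round-trip

_FILES = ("records.csv", "patients.csv", "sofa.csv", "comorbidities.csv", "truth.json")


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> list[Path]:
    """Write the four CSV tables plus the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.records.to_csv(out / "records.csv", index=False)
    cohort.patients.to_csv(out / "patients.csv", index=False)
    cohort.sofa.to_csv(out / "sofa.csv", index=False)
    cohort.comorbidities.to_csv(out / "comorbidities.csv", index=False)
    (out / "truth.json").write_text(json.dumps(cohort.truth, indent=0))
    return [out / f for f in _FILES]


def read_cohort(in_dir: str | Path) -> SyntheticCohort:
    src = Path(in_dir)
    return SyntheticCohort(
        records=pd.read_csv(src / "records.csv"),
        patients=pd.read_csv(src / "patients.csv"),
        sofa=pd.read_csv(src / "sofa.csv"),
        comorbidities=pd.read_csv(src / "comorbidities.csv"),
        truth={k: int(v) for k, v in json.loads((src / "truth.json").read_text()).items()},
    )
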