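"""Phenotype subgroup profiling.

Demographics/outcome tables per subgroup, 7-day SOFA trajectories with organ
subscores, Elixhauser comorbidity incidence tables, and between-subgroup
hypothesis tests (Welch ANOVA plus pairwise Welch t for continuous variables,
chi-square for proportions) at a configurable significance level.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .registry import ELIXHAUSER_CATEGORIES, SOFA_SUBSCORES, VAN_WALRAVEN_WEIGHTS

logger = logging.getLogger(__name__)

BMI_STRATA = (
    ("underweight", -np.inf, 18.5),
    ("healthy", 18.5, 25.0),
    ("overweight", 25.0, 30.0),
    ("obese", 30.0, np.inf),
)

CONTINUOUS_COLUMNS = ("age", "weight", "bmi", "icu_los", "elixhauser_index", "day1_sofa")
PROPORTION_COLUMNS = ("mortality_30d", "mortality_inhosp")


def _assignment_series(assignment: Mapping[str, int]) -> pd.Series:
    return pd.Series(assignment, name="subgroup")


def bmi_stratum(bmi: float) -> str:
    """Strata with the conventional closed-left boundaries:
    underweight < 18.5 <= healthy < 25 <= overweight < 30 <= obese."""
    for name, lo, hi in BMI_STRATA:
        if lo <= bmi < hi:
            return name
    raise ValueError(f"BMI {bmi} outside any stratum")


def demographics_table(outcomes: pd.DataFrame, assignment: Mapping[str, int]) -> pd.DataFrame:
    """Per-subgroup and overall demographics/outcomes.

    Continuous rows report mean and n-1 SD; categorical rows report within-
    subgroup percentages. Raises if a labelled patient has no outcome row.
    """
    out = outcomes.set_index("patient_id")
    missing = sorted(set(assignment) - set(out.index))
    if missing:
        raise KeyError(f"labelled patients missing outcome rows: {missing}")
    df = out.loc[list(assignment)].copy()
    df["subgroup"] = [assignment[p] for p in df.index]
    df["bmi_stratum"] = df["bmi"].map(bmi_stratum)
    subgroups = sorted(set(assignment.values()))

    def block(frame: pd.DataFrame) -> dict[str, float]:
        rec: dict[str, float] = {"n": len(frame)}
        for col in CONTINUOUS_COLUMNS:
            rec[f"{col}_mean"] = frame[col].mean()
            rec[f"{col}_sd"] = frame[col].std(ddof=1)
        for sex in ("male", "female"):
            rec[f"sex_{sex}_pct"] = 100.0 * (frame["sex"] == sex).mean()
        for eth in sorted(df["ethnicity"].unique()):
            rec[f"ethnicity_{eth}_pct"] = 100.0 * (frame["ethnicity"] == eth).mean()
        for name, _, _ in BMI_STRATA:
            rec[f"bmi_{name}_pct"] = 100.0 * (frame["bmi_stratum"] == name).mean()
        for col in PROPORTION_COLUMNS:
            rec[f"{col}_pct"] = 100.0 * frame[col].astype(bool).mean()
        return rec

    table = {g: block(df[df["subgroup"] == g]) for g in subgroups}
    table["overall"] = block(df)
    return pd.DataFrame(table)


def sofa_trend(
    sofa: pd.DataFrame,
    assignment: Mapping[str, int],
    carry_forward: bool = False,
) -> pd.DataFrame:
    """Mean daily SOFA totals and subscores per subgroup over days 1-7.

    By default, patients contribute only their observed days (those who died
    or were discharged drop out); with ``carry_forward`` each patient's last
    observed day is propagated through day 7.
    """
    if not sofa["day"].between(1, 7).all():
        bad = sorted(sofa.loc[~sofa["day"].between(1, 7), "day"].unique())
        raise ValueError(f"SOFA days outside 1..7: {bad}")
    totals = sofa[list(SOFA_SUBSCORES)].sum(axis=1)
    if not (totals == sofa["total"]).all():
        raise ValueError("SOFA total != sum of subscores for some rows")
    df = sofa[sofa["patient_id"].isin(assignment)].copy()
    if carry_forward:
        full = []
        for pid, grp in df.groupby("patient_id"):
            grp = grp.set_index("day").reindex(range(1, 8)).ffill().reset_index()
            grp["patient_id"] = pid
            full.append(grp)
        df = pd.concat(full, ignore_index=True)
    df["subgroup"] = df["patient_id"].map(assignment)
    agg = (
        df.groupby(["subgroup", "day"])[["total", *SOFA_SUBSCORES]]
        .mean()
        .reset_index()
    )
    return agg


def comorbidity_incidence(
    flags: pd.DataFrame,
    assignment: Mapping[str, int],
    min_incidence: float = 0.10,
) -> pd.DataFrame:
    """Per-category per-subgroup incidence (%), retaining categories whose
    *maximum* subgroup incidence reaches ``min_incidence`` (closed boundary),
    sorted by whole-cohort incidence descending. Ties keep registry order."""
    missing = set(ELIXHAUSER_CATEGORIES) - set(flags.columns)
    if missing:
        raise KeyError(f"comorbidity table missing categories: {sorted(missing)}")
    df = flags[flags["patient_id"].isin(assignment)].copy()
    df["subgroup"] = df["patient_id"].map(assignment)
    subgroups = sorted(set(assignment.values()))
    rows = []
    for rank, cat in enumerate(ELIXHAUSER_CATEGORIES):
        rec = {"category": cat, "_registry_rank": rank}
        per_group = []
        for g in subgroups:
            inc = df.loc[df["subgroup"] == g, cat].astype(bool).mean()
            rec[f"subgroup_{g}_pct"] = 100.0 * inc
            per_group.append(inc)
        rec["cohort_pct"] = 100.0 * df[cat].astype(bool).mean()
        rec["_max_subgroup"] = max(per_group) if per_group else 0.0
        rows.append(rec)
    table = pd.DataFrame(rows)
    table = table[table["_max_subgroup"] >= min_incidence]
    table = table.sort_values(
        ["cohort_pct", "_registry_rank"], ascending=[False, True], kind="stable"
    )
    return table.drop(columns=["_registry_rank", "_max_subgroup"]).reset_index(drop=True)


def _welch_anova(samples: Sequence[np.ndarray]) -> tuple[float, float]:
    """Welch's one-way ANOVA via pingouin."""
    import pingouin as pg

    values = np.concatenate(samples)
    groups = np.concatenate([[i] * len(s) for i, s in enumerate(samples)])
    if all(np.var(s) == 0 for s in samples):
        means = [float(np.mean(s)) for s in samples]
        if len(set(means)) == 1:
            return 0.0, 1.0  # identical constants: nothing to reject
        return np.inf, 0.0
    res = pg.welch_anova(
        data=pd.DataFrame({"y": values, "g": groups}), dv="y", between="g"
    )
    p_col = "p_unc" if "p_unc" in res.columns else "p-unc"
    return float(res["F"].iloc[0]), float(res[p_col].iloc[0])


def subgroup_tests(
    outcomes: pd.DataFrame,
    flags: pd.DataFrame,
    assignment: Mapping[str, int],
    alpha: float = 0.05,
    continuous: Sequence[str] = CONTINUOUS_COLUMNS,
    correction: str | None = None,
) -> pd.DataFrame:
    """Between-subgroup hypothesis tests.

    Continuous variables: Welch one-way ANOVA across subgroups plus pairwise
    Welch t-tests. Proportions (sex, mortality, comorbidity flags): chi-square
    tests on the contingency table. No multiplicity correction by default;
    ``correction='holm'`` applies Holm's step-down adjustment.
    """
    out = outcomes.set_index("patient_id").loc[list(assignment)].copy()
    out["subgroup"] = [assignment[p] for p in out.index]
    subgroups = sorted(set(assignment.values()))
    if len(subgroups) < 2:
        raise ValueError("need at least 2 subgroups to test")
    rows = []

    for col in continuous:
        samples = [out.loc[out["subgroup"] == g, col].to_numpy(dtype=float)
                   for g in subgroups]
        if any(len(s) < 2 for s in samples):
            raise ValueError(f"subgroup with <2 observations for {col!r}")
        stat, p = _welch_anova(samples)
        rows.append({"variable": col, "test": "welch_anova",
                     "comparison": "all", "statistic": stat, "p": p})
        for i in range(len(subgroups)):
            for j in range(i + 1, len(subgroups)):
                a, b = samples[i], samples[j]
                if np.var(a) == 0 and np.var(b) == 0:
                    p_ij = 1.0 if np.mean(a) == np.mean(b) else 0.0
                    t_ij = 0.0 if p_ij == 1.0 else np.inf
                else:
                    t_ij, p_ij = sps.ttest_ind(a, b, equal_var=False)
                rows.append({"variable": col, "test": "welch_t",
                             "comparison": f"{subgroups[i]}v{subgroups[j]}",
                             "statistic": float(t_ij), "p": float(p_ij)})

    binary_cols = {"sex": out["sex"] == "male"}
    for col in PROPORTION_COLUMNS:
        binary_cols[col] = out[col].astype(bool)
    fl = flags.set_index("patient_id").reindex(out.index)
    for cat in ELIXHAUSER_CATEGORIES:
        if cat in fl.columns:
            binary_cols[cat] = fl[cat].astype(bool)
    for name, series in binary_cols.items():
        contingency = pd.crosstab(out["subgroup"], series)
        if contingency.shape[1] < 2:
            rows.append({"variable": name, "test": "chi2", "comparison": "all",
                         "statistic": 0.0, "p": 1.0})
            continue
        chi2, p, _, _ = sps.chi2_contingency(contingency)
        rows.append({"variable": name, "test": "chi2", "comparison": "all",
                     "statistic": float(chi2), "p": float(p)})

    table = pd.DataFrame(rows)
    if correction == "holm":
        from statsmodels.stats.multitest import multipletests

        table["p"] = multipletests(table["p"], method="holm")[1]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    table["reject"] = table["p"] < alpha
    return table


def elixhauser_score(
    flags: Mapping[str, bool],
    weights: Mapping[str, float] = VAN_WALRAVEN_WEIGHTS,
) -> float:
    """Weighted flag sum over the 30 Elixhauser categories."""
    missing = set(ELIXHAUSER_CATEGORIES) - set(weights)
    if missing:
        raise KeyError(f"weight table missing categories: {sorted(missing)}")
    return float(sum(weights[c] for c in ELIXHAUSER_CATEGORIES if flags.get(c, False)))
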