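"""Irregular measurements -> per-patient, per-variable integer level chains.

The pipeline's "time series graph" for one patient and one variable is a
linear chain of discretized levels: records from the first 72 h of the ICU
stay are binned into uniform windows (6 h or 24 h), window means are linearly
interpolated across empty interior windows (edges take the nearest populated
window's value), and interpolated values are z-scored cohort-wide per variable
and rounded to integers, clipped to ±`clip` standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .registry import MEASURABLE_RANGES, VARIABLES

logger = logging.getLogger(__name__)

HORIZON = 72.0


class LevelSequence(NamedTuple):
    patient_id: str
    variable: str
    levels: tuple[int, ...]


@dataclass
class InterpolatedSeries:
    patient_id: str
    variable: str
    values: np.ndarray
    observed_mask: np.ndarray


def filter_cohort_window(
    admissions: Mapping[str, tuple[float | None, float | None]],
    window_hours: float = 24.0,
) -> set[str]:
    """Patients whose suspected infection onset lies within ±window_hours of
    ICU admission (closed interval). Patients with a missing timestamp are
    excluded with a warning rather than an error."""
    kept: set[str] = set()
    for pid, (t_icu, t_susp) in admissions.items():
        if t_icu is None or t_susp is None or not (
            np.isfinite(t_icu) and np.isfinite(t_susp)
        ):
            logger.warning("patient %s excluded: missing admission/suspicion time", pid)
            continue
        if abs(t_susp - t_icu) <= window_hours:
            kept.add(pid)
    return kept


def filter_outliers(
    records: pd.DataFrame,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Drop records outside the measurable range for their variable.

    A record survives iff lo <= value <= hi. Removal counts are logged per
    variable. A variable present in ``records`` but absent from ``ranges`` is
    a configuration error.
    """
    if ranges is None:
        ranges = MEASURABLE_RANGES
    if records.empty:
        return records.copy()
    present = set(records["variable"].unique())
    missing = present - set(ranges)
    if missing:
        raise KeyError(f"no measurable range configured for variables: {sorted(missing)}")
    lo = records["variable"].map({v: r[0] for v, r in ranges.items()})
    hi = records["variable"].map({v: r[1] for v, r in ranges.items()})
    keep = (records["value"] >= lo) & (records["value"] <= hi)
    removed = records.loc[~keep, "variable"].value_counts()
    for var, cnt in removed.items():
        logger.info("outlier filter: removed %d record(s) for %s", cnt, var)
    return records.loc[keep].reset_index(drop=True)


def interpolate_series(
    times: np.ndarray,
    values: np.ndarray,
    patient_id: str = "",
    variable: str = "",
    interval: float = 6.0,
    horizon: float = HORIZON,
) -> InterpolatedSeries | None:
    """Bin one patient-variable series into uniform windows and fill gaps.

    Windows are half-open ``[w*interval, (w+1)*interval)``; a record at
    exactly t = horizon is discarded. Windows holding records take the mean of
    their records; empty interior windows are linearly interpolated between
    the nearest populated windows; empty leading/trailing windows copy the
    nearest populated value. Returns None when no record falls in [0, horizon).
    """
    n_windows = int(round(horizon / interval))
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    in_range = (times >= 0.0) & (times < horizon)
    times, values = times[in_range], values[in_range]
    if times.size == 0:
        return None
    win = np.minimum((times // interval).astype(int), n_windows - 1)
    sums = np.bincount(win, weights=values, minlength=n_windows)
    counts = np.bincount(win, minlength=n_windows)
    mask = counts > 0
    means = np.full(n_windows, np.nan)
    means[mask] = sums[mask] / counts[mask]
    filled = (
        pd.Series(means)
        .interpolate(method="linear", limit_area="inside")
        .ffill()
        .bfill()
        .to_numpy()
    )
    return InterpolatedSeries(patient_id, variable, filled, mask)


def compute_stats(
    series: Iterable[InterpolatedSeries],
    ddof: int = 1,
) -> dict[str, tuple[float, float]]:
    """Cohort-wide mean and SD per variable over all interpolated values
    (all patients, all windows). Variables with zero variance are dropped
    with a warning."""
    pooled: dict[str, list[np.ndarray]] = {}
    for s in series:
        pooled.setdefault(s.variable, []).append(s.values)
    stats: dict[str, tuple[float, float]] = {}
    for var, chunks in pooled.items():
        vals = np.concatenate(chunks)
        if vals.size < 2:
            logger.warning("variable %s dropped: fewer than 2 values", var)
            continue
        sd = float(np.std(vals, ddof=ddof))
        if sd == 0.0:
            logger.warning("variable %s dropped: zero variance", var)
            continue
        stats[var] = (float(np.mean(vals)), sd)
    return stats


def _round_half_away(z: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(z) + 0.5), z)


def discretize_levels(
    series: InterpolatedSeries,
    stats: Mapping[str, tuple[float, float]],
    clip: int = 4,
) -> LevelSequence:
    """Round z-scores half-away-from-zero to integer levels, clip to ±clip."""
    if series.variable not in stats:
        raise KeyError(f"no stats for variable {series.variable!r}")
    mean, sd = stats[series.variable]
    z = (series.values - mean) / sd
    levels = np.clip(_round_half_away(z), -clip, clip).astype(int)
    return LevelSequence(series.patient_id, series.variable, tuple(int(v) for v in levels))


def build_corpora(
    sequences: Iterable[LevelSequence],
    variables: Iterable[str] = VARIABLES,
) -> dict[str, dict[str, tuple[int, ...]]]:
    """Group chains into one corpus per variable: variable -> {patient -> chain}.

    Each patient contributes at most one chain per corpus.
    """
    corpora: dict[str, dict[str, tuple[int, ...]]] = {v: {} for v in variables}
    for seq in sequences:
        corpus = corpora.setdefault(seq.variable, {})
        if seq.patient_id in corpus:
            raise ValueError(
                f"duplicate chain for patient {seq.patient_id!r}, "
                f"variable {seq.variable!r}"
            )
        corpus[seq.patient_id] = seq.levels
    return corpora


def prepare_corpora(
    records: pd.DataFrame,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    interval: float = 6.0,
    clip: int = 4,
    horizon: float = HORIZON,
    stats_on: str = "interpolated",
) -> tuple[dict[str, dict[str, tuple[int, ...]]], dict[str, tuple[float, float]]]:
    """records table -> (per-variable corpora of level chains, variable stats).

    ``stats_on`` selects whether z-statistics come from the interpolated
    window values (default) or the raw records.
    """
    if stats_on not in ("interpolated", "raw"):
        raise ValueError("stats_on must be 'interpolated' or 'raw'")
    clean = filter_outliers(records, ranges)
    series: list[InterpolatedSeries] = []
    for (pid, var), grp in clean.groupby(["patient_id", "variable"], sort=True):
        s = interpolate_series(
            grp["t_hours"].to_numpy(), grp["value"].to_numpy(),
            patient_id=str(pid), variable=str(var),
            interval=interval, horizon=horizon,
        )
        if s is not None:
            series.append(s)
    if stats_on == "interpolated":
        stats = compute_stats(series)
    else:
        stats = {
            var: (float(grp["value"].mean()), float(grp["value"].std(ddof=1)))
            for var, grp in clean.groupby("variable")
            if grp["value"].std(ddof=1) > 0
        }
    sequences = [discretize_levels(s, stats, clip=clip) for s in series if s.variable in stats]
    return build_corpora(sequences), stats


def write_corpora(corpora: Mapping[str, Mapping[str, tuple[int, ...]]], path) -> None:
    """JSON-lines, one chain per line: {variable, patient_id, levels}."""
    import json
    with open(path, "w") as fh:
        for var in sorted(corpora):
            for pid in sorted(corpora[var]):
                fh.write(json.dumps(
                    {"variable": var, "patient_id": pid,
                     "levels": list(corpora[var][pid])}) + "\n")


def read_corpora(path) -> dict[str, dict[str, tuple[int, ...]]]:
    import json
    corpora: dict[str, dict[str, tuple[int, ...]]] = {}
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            corpora.setdefault(rec["variable"], {})[rec["patient_id"]] = tuple(rec["levels"])
    return corpora
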