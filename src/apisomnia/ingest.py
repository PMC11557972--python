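"""Reading, validating and transforming observation tables.

The canonical input is a long-format CSV with one row per (cage, hour):
``cage_id,condition,replicate_index,hour,n_alive,n_sleeping,
n_disturbance_contacts,n_sleeping_lower`` (see ``docs/data_dictionary.md``).
Validation is total: every structural invariant of the observation table is
checked and all offending rows are reported together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synth import (
    CONDITIONS,
    OBSERVATION_COLUMNS,
    ObservationRecord,
    frame_to_records,
    records_to_frame,
)


class ValidationError(ValueError):
    """Observation-table invariant violations, with row numbers."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "observation table failed validation:\n  " + "\n  ".join(self.problems)
        )


@dataclass
class SleepSeries:
    """A cage's hourly percent-asleep trajectory.

    ``percent_asleep[i]`` is 100 * n_sleeping / n_alive at ``hours[i]``
    (0 where the cage has gone extinct, with ``extinct`` flagged), and
    ``percent_alive`` is survival relative to the hour-0 census.
    """

    cage_id: str
    condition: str
    replicate_index: int
    hours: np.ndarray
    percent_asleep: np.ndarray
    percent_alive: np.ndarray
    extinct: bool = False

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=float)
        self.percent_asleep = np.asarray(self.percent_asleep, dtype=float)
        self.percent_alive = np.asarray(self.percent_alive, dtype=float)
        if not (
            len(self.hours) == len(self.percent_asleep) == len(self.percent_alive)
        ):
            raise ValueError("hours and value vectors must have equal length")
        if len(self.hours) > 1 and not np.all(np.diff(self.hours) > 0):
            raise ValueError("hours must be strictly increasing")
        for name in ("percent_asleep", "percent_alive"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 100)):
                raise ValueError(f"{name} must lie in [0, 100]")


def validate_records(records: Iterable[ObservationRecord]) -> list[ObservationRecord]:
    """Check all observation-table invariants; raise listing every violation.

    Checks per row: non-negative counts, n_sleeping <= n_alive,
    n_sleeping_lower <= n_sleeping, known condition label.  Checks per cage:
    duplicate-free complete hour grid starting at 0, non-increasing n_alive,
    consistent condition/replicate labels.
    """
    records = list(records)
    problems: list[str] = []
    for i, r in enumerate(records):
        if r.condition not in CONDITIONS:
            problems.append(f"row {i}: unknown condition {r.condition!r}")
        for name in (
            "n_alive",
            "n_sleeping",
            "n_disturbance_contacts",
            "n_sleeping_lower",
        ):
            if getattr(r, name) < 0:
                problems.append(f"row {i}: negative {name}")
        if r.hour < 0:
            problems.append(f"row {i}: negative hour")
        if r.n_sleeping > r.n_alive:
            problems.append(
                f"row {i}: n_sleeping={r.n_sleeping} exceeds n_alive={r.n_alive}"
            )
        if r.n_sleeping_lower > r.n_sleeping:
            problems.append(
                f"row {i}: n_sleeping_lower={r.n_sleeping_lower} exceeds "
                f"n_sleeping={r.n_sleeping}"
            )

    by_cage: dict[str, list[tuple[int, ObservationRecord]]] = {}
    for i, r in enumerate(records):
        by_cage.setdefault(r.cage_id, []).append((i, r))
    for cage_id, rows in by_cage.items():
        rows.sort(key=lambda ir: ir[1].hour)
        hours = [r.hour for _, r in rows]
        if len(set(hours)) != len(hours):
            dup = sorted({h for h in hours if hours.count(h) > 1})
            problems.append(f"cage {cage_id}: duplicate hours {dup}")
        else:
            expected = list(range(min(hours), max(hours) + 1))
            if hours != expected or min(hours) != 0:
                missing = sorted(set(range(0, max(hours) + 1)) - set(hours))
                problems.append(
                    f"cage {cage_id}: incomplete hour grid (missing {missing})"
                )
        alive = [r.n_alive for _, r in rows]
        for (i0, r0), (i1, r1) in zip(rows, rows[1:]):
            if r1.n_alive > r0.n_alive:
                problems.append(
                    f"cage {cage_id}: n_alive increases from {r0.n_alive} "
                    f"(hour {r0.hour}, row {i0}) to {r1.n_alive} "
                    f"(hour {r1.hour}, row {i1})"
                )
        if len({(r.condition, r.replicate_index) for _, r in rows}) > 1:
            problems.append(
                f"cage {cage_id}: inconsistent condition/replicate labels"
            )
    if problems:
        raise ValidationError(problems)
    return records


def read_observations(path) -> list[ObservationRecord]:
    """Read and validate the canonical observation CSV."""
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"missing columns: {missing}"])
    return validate_records(frame_to_records(df[OBSERVATION_COLUMNS]))


def to_sleep_series(
    records: Sequence[ObservationRecord] | pd.DataFrame,
) -> list[SleepSeries]:
    """Group validated records per cage into percent-asleep trajectories."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    out: list[SleepSeries] = []
    for cage_id, g in df.groupby("cage_id", sort=True):
        g = g.sort_values("hour")
        alive = g["n_alive"].to_numpy(dtype=float)
        sleeping = g["n_sleeping"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct_asleep = np.where(alive > 0, 100.0 * sleeping / alive, 0.0)
        n0 = alive[0] if len(alive) else 0.0
        pct_alive = 100.0 * alive / n0 if n0 > 0 else np.zeros_like(alive)
        out.append(
            SleepSeries(
                cage_id=str(cage_id),
                condition=str(g["condition"].iloc[0]),
                replicate_index=int(g["replicate_index"].iloc[0]),
                hours=g["hour"].to_numpy(dtype=float),
                percent_asleep=pct_asleep,
                percent_alive=pct_alive,
                extinct=bool(np.any(alive == 0)),
            )
        )
    return out


def default_log_offset(records: Sequence[ObservationRecord] | pd.DataFrame) -> float:
    """Half a bee out of the largest cage census: 1 / (2 * max n_alive)."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    max_alive = float(df["n_alive"].max())
    if not max_alive > 0:
        raise ValueError("no living bees in any record")
    return 1.0 / (2.0 * max_alive)


def log_transform_proportion(
    proportions, offset: float | None = None
) -> np.ndarray:
    """Natural log of (p + offset), admitting zero counts.

    *proportions* may be an array of proportions in [0, 1] or a sequence of
    observation records, in which case p = n_sleeping / n_alive per row and
    the default offset is ``1 / (2 * max n_alive)``.
    """
    if isinstance(proportions, pd.DataFrame) or (
        len(proportions) > 0 and isinstance(next(iter(proportions)), ObservationRecord)
    ):
        df = (
            proportions
            if isinstance(proportions, pd.DataFrame)
            else records_to_frame(proportions)
        )
        if offset is None:
            offset = default_log_offset(df)
        alive = df["n_alive"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(alive > 0, df["n_sleeping"].to_numpy(dtype=float) / alive, 0.0)
    else:
        p = np.asarray(proportions, dtype=float)
        if offset is None:
            raise ValueError("offset is required when passing raw proportions")
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if np.any(p > 1):
        raise ValueError("proportions must not exceed 1")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if offset == 0 and np.any(p == 0):
        raise ValueError("offset 0 with zero proportions would give -inf")
    return np.log(p + offset)


def read_light_measurements(path) -> pd.DataFrame:
    """Read and validate the light-measurement CSV (position, photon_flux)."""
    df = pd.read_csv(path)
    missing = [c for c in ("position", "photon_flux") if c not in df.columns]
    if missing:
        raise ValidationError([f"light table missing columns: {missing}"])
    bad_pos = sorted(set(df["position"]) - {"top", "bottom"})
    problems = []
    if bad_pos:
        problems.append(f"unknown positions {bad_pos}")
    flux = df["photon_flux"].to_numpy(dtype=float)
    if not np.all(np.isfinite(flux)):
        problems.append("non-finite photon_flux values")
    elif np.any(flux < 0):
        problems.append("negative photon_flux values")
    if problems:
        raise ValidationError(problems)
    return df[["position", "photon_flux"]]
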