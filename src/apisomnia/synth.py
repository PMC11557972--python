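"""Synthetic caged-bee sleep experiments.

Generates hourly ethogram observation tables with the statistical structure
the downstream analysis assumes: a circadian proportion-asleep oscillation
whose period and amplitude depend on the lighting condition, per-bee
mortality, Poisson disturbance contacts received by sleeping bees, and a
light-dependent preference for sleeping in the lower half of the cage.

Conditions
----------
``LL``  constant light; free-running period that lengthens over the trial.
``DD``  constant dark; free-running period near 24 h.
``LD``  12 h light : 12 h dark control; entrained to exactly 24 h.

The generative model for the expected proportion asleep at hour ``t`` is

    p(t) = baseline + A(t) * cos(2*pi * (t - phase0) / tau_eff(t))

clipped to [0, 1], where ``tau_eff`` lengthens by ``drift_ll`` hours per
elapsed day under LL only, and the amplitude ``A(t)`` decays geometrically
by ``amplitude_decay`` per day under the two constant (free-running)
conditions.  Counts are then drawn conditionally: sleepers binomially from
the bees currently alive, disturbance contacts Poisson with a per-sleeper
rate that switches to an elevated value late in the trial under LL, and
lower-half sleepers binomially from the sleepers.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("LL", "DD", "LD")

#: Sub-seed stride separating conditions; replicates within a condition are
#: consecutive offsets, so adding a condition never reshuffles existing cages.
_CONDITION_SEED_STRIDE = {"LL": 0, "DD": 100_000, "LD": 200_000}

#: Free-running circadian periods reported for honey bee foragers span
#: roughly 20-26 h; configs outside this range are accepted with a warning.
FREE_RUNNING_RANGE = (20.0, 26.0)

OBSERVATION_COLUMNS = [
    "cage_id",
    "condition",
    "replicate_index",
    "hour",
    "n_alive",
    "n_sleeping",
    "n_disturbance_contacts",
    "n_sleeping_lower",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates a hard invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of a simulated experiment.

    Parameters
    ----------
    n_cages_per_condition : int
        Replicate cages per lighting condition.
    n_bees : int
        Foragers per cage at hour 0.
    duration : int
        Trial length in hours; observations cover hours ``0 .. duration-1``.
    tau_ld, tau_dd, tau_ll : float
        Circadian period (h) under each condition at trial onset.
    drift_ll : float
        Period lengthening under constant light, hours per elapsed day.
    amplitude0 : float
        Peak-to-midline amplitude of the proportion-asleep oscillation.
        Caged foragers sleep predominantly in their subjective night, with
        a large day-night contrast (roughly 10% asleep at the daytime
        trough vs 80% at the nocturnal peak), hence the default 0.35
        around a mesor of 0.45.
    baseline : float
        Mesor (rhythm-adjusted mean) proportion asleep.
    amplitude_decay : float
        Fractional amplitude loss per day under the free-running conditions
        (LL and DD); the entrained LD control keeps full amplitude.
    phase0 : float
        Acrophase (hour of maximal sleep) at trial onset.  With lights on at
        hour 0 under LD, sleep peaks in the middle of the dark phase.
    mortality_hazard : float
        Per-bee per-hour death probability.
    disturb_rate_base : float
        Expected contacts received per sleeping bee per scored 5-min window.
    disturb_rate_ll_late : float
        Elevated contact rate applying under LL from ``onset_hour`` onward.
    onset_hour : int
        Hour from which the elevated LL disturbance rate applies.
    p_lower_ld_dark : float
        Probability a sleeping bee is in the lower cage half under LD/DD.
    p_lower_ll : float
        Same probability under constant light, where bees avoid the brighter
        upper half of the cage.
    seed : int
        Master RNG seed; per-cage sub-seeds are derived from it.
    """

    n_cages_per_condition: int = 3
    n_bees: int = 23
    duration: int = 120
    tau_ld: float = 24.0
    tau_dd: float = 24.0
    tau_ll: float = 24.5
    drift_ll: float = 0.25
    amplitude0: float = 0.35
    baseline: float = 0.45
    amplitude_decay: float = 0.10
    phase0: float = 18.0
    mortality_hazard: float = 0.002
    disturb_rate_base: float = 0.31
    disturb_rate_ll_late: float = 1.09
    onset_hour: int = 90
    p_lower_ld_dark: float = 0.35
    p_lower_ll: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bees <= 0:
            raise ConfigError("n_bees must be positive")
        if self.n_cages_per_condition <= 0:
            raise ConfigError("n_cages_per_condition must be positive")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if not 0.0 <= self.baseline <= 1.0:
            raise ConfigError("baseline must lie in [0, 1]")
        if not 0.0 <= self.amplitude0 <= 0.5:
            raise ConfigError("amplitude0 must lie in [0, 0.5]")
        if self.baseline + self.amplitude0 > 1.0 or self.baseline - self.amplitude0 < 0.0:
            raise ConfigError("baseline +/- amplitude0 must stay within [0, 1]")
        if not 0.0 <= self.amplitude_decay < 1.0:
            raise ConfigError("amplitude_decay must lie in [0, 1)")
        if not 0.0 <= self.mortality_hazard < 1.0:
            raise ConfigError("mortality_hazard must lie in [0, 1)")
        for name in ("disturb_rate_base", "disturb_rate_ll_late"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("p_lower_ld_dark", "p_lower_ll"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        lo, hi = FREE_RUNNING_RANGE
        for name in ("tau_ld", "tau_dd", "tau_ll"):
            tau = getattr(self, name)
            if tau <= 0:
                raise ConfigError(f"{name} must be positive")
            if not lo <= tau <= hi:
                warnings.warn(
                    f"{name}={tau} is outside the free-running range "
                    f"{lo}-{hi} h reported for honey bee foragers",
                    stacklevel=3,
                )

    def tau(self, condition: str) -> float:
        """Onset period for *condition*."""
        return {"LL": self.tau_ll, "DD": self.tau_dd, "LD": self.tau_ld}[
            _check_condition(condition)
        ]

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass(frozen=True)
class ObservationRecord:
    """One scored (cage, hour) cell of the ethogram.

    ``n_sleeping`` counts foragers showing all three sleep markers (antennal
    immobility, discontinuous abdominal pumping, leg immobility) through the
    first 5 minutes of the hour; a bee woken by a contact still counts as
    sleeping if it resumed sleep within 30 s.  ``n_disturbance_contacts`` is
    the total number of times sleeping bees were moved by physical contact
    with non-sleeping nestmates within that window, and
    ``n_sleeping_lower`` the sleepers located in the lower 50% of the cage.
    """

    cage_id: str
    condition: str
    replicate_index: int
    hour: int
    n_alive: int
    n_sleeping: int
    n_disturbance_contacts: int
    n_sleeping_lower: int


def _check_condition(condition: str) -> str:
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    return condition


def cage_seed(config: SimulationConfig, condition: str, replicate_index: int) -> int:
    """Stable per-cage sub-seed.

    ``master_seed + condition_stride + (replicate_index - 1)``, reduced
    modulo 2**31.  The stride per condition is fixed, so adding replicates
    or conditions never changes the seeds of existing cages.
    """
    _check_condition(condition)
    if replicate_index < 1:
        raise ValueError("replicate_index is 1-based")
    return int(
        (config.seed + _CONDITION_SEED_STRIDE[condition] + replicate_index - 1)
        % 2**31
    )


def effective_period(config: SimulationConfig, condition: str, hours) -> np.ndarray:
    """Period (h) at each hour; lengthens by ``drift_ll`` per day under LL."""
    t = np.asarray(hours, dtype=float)
    tau = np.full_like(t, config.tau(condition))
    if condition == "LL":
        tau = tau + config.drift_ll * t / 24.0
    return tau


def expected_proportion_asleep(
    config: SimulationConfig, condition: str, hours
) -> np.ndarray:
    """Closed-form expected proportion asleep p(t), clipped to [0, 1]."""
    _check_condition(condition)
    t = np.asarray(hours, dtype=float)
    tau = effective_period(config, condition, t)
    amp = np.full_like(t, config.amplitude0)
    if condition in ("LL", "DD"):
        amp = amp * (1.0 - config.amplitude_decay) ** (t / 24.0)
    p = config.baseline + amp * np.cos(2.0 * np.pi * (t - config.phase0) / tau)
    return np.clip(p, 0.0, 1.0)


def _disturbance_rate(config: SimulationConfig, condition: str, hour: int) -> float:
    if condition == "LL" and hour >= config.onset_hour:
        return config.disturb_rate_ll_late
    return config.disturb_rate_base


def _p_lower(config: SimulationConfig, condition: str) -> float:
    return config.p_lower_ll if condition == "LL" else config.p_lower_ld_dark


def simulate_cage(
    config: SimulationConfig,
    condition: str,
    replicate_index: int = 1,
    seed: int | None = None,
) -> list[ObservationRecord]:
    """Simulate one cage's hourly observation records.

    Parameters
    ----------
    config : SimulationConfig
    condition : {"LL", "DD", "LD"}
    replicate_index : int
        1-based replicate number within the condition.
    seed : int, optional
        Explicit sub-seed; defaults to the documented derivation from the
        master seed.  Identical seed and config give bit-identical output.
    """
    _check_condition(condition)
    if seed is None:
        seed = cage_seed(config, condition, replicate_index)
    rng = np.random.default_rng(seed)

    p = expected_proportion_asleep(config, condition, np.arange(config.duration))
    p_low = _p_lower(config, condition)
    cage_id = f"{condition}{replicate_index}"

    records: list[ObservationRecord] = []
    n_alive = config.n_bees
    for t in range(config.duration):
        n_sleeping = int(rng.binomial(n_alive, p[t])) if n_alive > 0 else 0
        rate = _disturbance_rate(config, condition, t)
        n_contacts = int(rng.poisson(n_sleeping * rate))
        n_lower = int(rng.binomial(n_sleeping, p_low)) if n_sleeping > 0 else 0
        records.append(
            ObservationRecord(
                cage_id=cage_id,
                condition=condition,
                replicate_index=replicate_index,
                hour=t,
                n_alive=n_alive,
                n_sleeping=n_sleeping,
                n_disturbance_contacts=n_contacts,
                n_sleeping_lower=n_lower,
            )
        )
        if n_alive > 0 and config.mortality_hazard > 0.0:
            n_alive -= int(rng.binomial(n_alive, config.mortality_hazard))
    return records


def simulate_experiment(config: SimulationConfig) -> list[ObservationRecord]:
    """Simulate all cages of all conditions (LL, DD, LD in fixed order)."""
    records: list[ObservationRecord] = []
    for condition in CONDITIONS:
        for rep in range(1, config.n_cages_per_condition + 1):
            records.extend(simulate_cage(config, condition, rep))
    return records


def null_calibration_config(
    seed: int, n_cages_per_condition: int = 8, n_bees: int = 100
) -> SimulationConfig:
    """A null experiment for checking the type-I error of the group tests.

    All three arms share identical generative parameters, the oscillation is
    switched off (so the mixed model's treatment + linear-time mean structure
    is correctly specified and its interaction test has a well-defined null),
    and cage/bee numbers are raised to sizes at which the F and chi-square
    reference distributions are adequate.  At the study size (3 cages of 23
    bees) the nonparametric p-values are intrinsically discrete and
    conservative, which would confound a calibration check of the procedures
    themselves.
    """
    return SimulationConfig(
        seed=seed,
        n_cages_per_condition=n_cages_per_condition,
        n_bees=n_bees,
        tau_ll=24.0,
        tau_dd=24.0,
        tau_ld=24.0,
        drift_ll=0.0,
        amplitude0=0.0,
        amplitude_decay=0.0,
        disturb_rate_ll_late=SimulationConfig.disturb_rate_base,
        p_lower_ll=SimulationConfig.p_lower_ld_dark,
    )


def simulate_light_measurements(
    n_per_position: int = 15,
    mean_top: float = 18.2,
    mean_bottom: float = 2.7,
    sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic photon-flux table (umol m^-2 s^-1) for the cage light gradient.

    Defaults emulate a cage lit from above, with roughly 7-fold more light at
    the top than at the bottom.
    """
    rng = np.random.default_rng(seed)
    top = np.clip(rng.normal(mean_top, sd, n_per_position), 0.0, None)
    bottom = np.clip(rng.normal(mean_bottom, sd, n_per_position), 0.0, None)
    return pd.DataFrame(
        {
            "position": ["top"] * n_per_position + ["bottom"] * n_per_position,
            "photon_flux": np.concatenate([top, bottom]),
        }
    )


def records_to_frame(records: Iterable[ObservationRecord]) -> pd.DataFrame:
    """Canonical long-format observation table."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if df.empty:
        return pd.DataFrame(columns=OBSERVATION_COLUMNS)
    return df[OBSERVATION_COLUMNS]


def frame_to_records(df: pd.DataFrame) -> list[ObservationRecord]:
    return [
        ObservationRecord(
            cage_id=str(row.cage_id),
            condition=str(row.condition),
            replicate_index=int(row.replicate_index),
            hour=int(row.hour),
            n_alive=int(row.n_alive),
            n_sleeping=int(row.n_sleeping),
            n_disturbance_contacts=int(row.n_disturbance_contacts),
            n_sleeping_lower=int(row.n_sleeping_lower),
        )
        for row in df.itertuples(index=False)
    ]


def write_observations(
    records: Sequence[ObservationRecord] | pd.DataFrame, path
) -> None:
    """Write the canonical observation CSV."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False)
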