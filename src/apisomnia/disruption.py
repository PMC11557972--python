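"""Sleep-disruptor analyses: cage light gradient, sleeping position, contacts.

Late in the trial (>= 90 h by default) bees under constant light receive
markedly more disturbance contacts from non-sleeping nestmates and sleep
preferentially in the dimmer lower half of the cage.  These summaries put
numbers on both effects and on the vertical light gradient itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import ObservationRecord, records_to_frame

#: Disruptor analyses cover the late-trial window, hours [90, 120).
DEFAULT_DISRUPT_WINDOW = (90.0, 120.0)


@dataclass
class LightComparison:
    """Pooled-variance t-test on top vs bottom photon flux, plus fold ratio."""

    t_statistic: float
    df: int
    p_value: float
    mean_top: float
    mean_bottom: float
    fold_ratio: float

    @property
    def headline_fold(self) -> int:
        """Fold ratio rounded to the nearest integer, as usually reported."""
        return int(round(self.fold_ratio))


@dataclass
class DisruptionSummary:
    """Per-condition contact rate and position preference over a window.

    ``mean_contacts_per_sleeper`` is the mean over scored 5-min windows of
    (contacts received by sleeping bees) / (number of sleeping bees); windows
    with no sleepers contribute no rate observation.
    """

    condition: str
    mean_contacts_per_sleeper: float
    sd_contacts: float
    n_windows: int
    prop_lower: float
    window: tuple[float, float]


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def compare_light_levels(measurements: pd.DataFrame) -> LightComparison:
    """Two-sample pooled-variance t-test of top vs bottom light levels.

    *measurements* is a (position, photon_flux) table with >= 2 readings per
    position.  The fold ratio is mean(top) / mean(bottom) and is invariant
    to rescaling all readings by a common factor.
    """
    top = measurements.loc[
        measurements["position"] == "top", "photon_flux"
    ].to_numpy(dtype=float)
    bottom = measurements.loc[
        measurements["position"] == "bottom", "photon_flux"
    ].to_numpy(dtype=float)
    if len(top) < 2 or len(bottom) < 2:
        raise ValueError("need at least 2 measurements per position")
    t, p = sps.ttest_ind(top, bottom, equal_var=True)
    mt, mb = float(top.mean()), float(bottom.mean())
    fold = mt / mb if mb > 0 else math.nan
    return LightComparison(
        t_statistic=float(t),
        df=len(top) + len(bottom) - 2,
        p_value=float(p),
        mean_top=mt,
        mean_bottom=mb,
        fold_ratio=fold,
    )


def disturbance_summary(
    records,
    window: tuple[float, float] = DEFAULT_DISRUPT_WINDOW,
) -> dict[str, DisruptionSummary]:
    """Per-condition contact rates per sleeping bee over the window.

    Each (cage, hour) cell with at least one sleeper contributes one rate
    observation contacts / n_sleeping; the summary is invariant to record
    order.  Raises on an empty window.
    """
    df = _as_frame(records)
    start, end = window
    if end <= start:
        raise ValueError(f"empty window {window}")
    sub = df[(df["hour"] >= start) & (df["hour"] < end)]
    if sub.empty:
        raise ValueError(f"no observations in window {window}")
    out: dict[str, DisruptionSummary] = {}
    for condition, g in sub.groupby("condition", sort=True):
        sleepers = g[g["n_sleeping"] > 0]
        rates = (
            sleepers["n_disturbance_contacts"] / sleepers["n_sleeping"]
        ).to_numpy(dtype=float)
        tot_sleep = float(g["n_sleeping"].sum())
        prop_lower = (
            float(g["n_sleeping_lower"].sum()) / tot_sleep
            if tot_sleep > 0
            else math.nan
        )
        out[str(condition)] = DisruptionSummary(
            condition=str(condition),
            mean_contacts_per_sleeper=float(rates.mean()) if len(rates) else math.nan,
            sd_contacts=float(rates.std(ddof=1)) if len(rates) > 1 else math.nan,
            n_windows=int(len(rates)),
            prop_lower=prop_lower,
            window=(float(start), float(end)),
        )
    return out


def contact_fold_ratio(
    summaries: dict[str, DisruptionSummary],
    numerator: str = "LL",
    denominator: str = "DD",
) -> float:
    """Ratio of mean contact rates between two conditions (NaN if undefined)."""
    num = summaries[numerator].mean_contacts_per_sleeper
    den = summaries[denominator].mean_contacts_per_sleeper
    if not (den and den > 0) or math.isnan(num):
        return math.nan
    return num / den


def position_preference(
    records,
    window: tuple[float, float] = DEFAULT_DISRUPT_WINDOW,
) -> pd.DataFrame:
    """Per-cage proportion of sleepers in the lower cage half over the window.

    Returns one row per cage with columns ``cage_id, condition,
    replicate_index, prop_lower, n_sleeping_total``; cages with no sleepers
    in the window get a NaN sentinel.  The within-cage repeated-measures
    comparison of lower-half sleeping between conditions is delegated to
    the mixed-model machinery (``stats.rm_mixed_model`` with response
    ``prop_lower``).
    """
    df = _as_frame(records)
    start, end = window
    if end <= start:
        raise ValueError(f"empty window {window}")
    sub = df[(df["hour"] >= start) & (df["hour"] < end)]
    if sub.empty:
        raise ValueError(f"no observations in window {window}")
    rows = []
    for cage_id, g in sub.groupby("cage_id", sort=True):
        tot = float(g["n_sleeping"].sum())
        rows.append(
            {
                "cage_id": str(cage_id),
                "condition": str(g["condition"].iloc[0]),
                "replicate_index": int(g["replicate_index"].iloc[0]),
                "prop_lower": float(g["n_sleeping_lower"].sum()) / tot
                if tot > 0
                else math.nan,
                "n_sleeping_total": int(g["n_sleeping"].sum()),
            }
        )
    return pd.DataFrame(rows)
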