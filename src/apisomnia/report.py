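"""Pipeline orchestration: simulate or load data, run every analysis stage,
write tidy CSV outputs, figures and a reproducibility manifest.

A run produces, in the output directory:

* ``observations.csv`` — the canonical input table (written when simulated);
* ``rhythm.csv``       — one fitted period per cage;
* ``alignment.csv``    — day-4 alignment metrics per replicate pair;
* ``disrupt.csv``      — contact rates and position preference per condition;
* ``stats.csv``        — mixed-model terms, Wilcoxon and Kruskal-Wallis rows;
* ``sleep_curves.png`` — per-condition median curves with +/- 1 MAD bands;
* ``manifest.json``    — config, windows, seed and package version; re-running
  from the same manifest reproduces every CSV byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .disruption import (
    DEFAULT_DISRUPT_WINDOW,
    compare_light_levels,
    contact_fold_ratio,
    disturbance_summary,
    position_preference,
)
from .ingest import SleepSeries, read_observations, read_light_measurements, to_sleep_series
from .rhythm import (
    DAY4_WINDOW,
    DEFAULT_PERIOD_GRID,
    align_experiment,
    estimate_period,
)
from .stats import kruskal_wallis_survival, rm_mixed_model, wilcoxon_rank_sum
from .synth import (
    CONDITIONS,
    SimulationConfig,
    records_to_frame,
    simulate_experiment,
    simulate_light_measurements,
    write_observations,
)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full analysis run.

    Exactly one of ``observations_path`` or ``simulation`` provides the
    data.  Analysis windows are on the 0-based hours-from-onset axis:
    ``crossover_h`` starts the late-trial mixed-model window, ``disrupt_h``
    the disruptor window, ``day4`` bounds the alignment metrics and
    ``end_h`` is the survival endpoint.
    """

    observations_path: str | None = None
    light_path: str | None = None
    simulation: SimulationConfig | None = None
    crossover_h: float = 79.0
    disrupt_h: tuple[float, float] = DEFAULT_DISRUPT_WINDOW
    day4: tuple[float, float] = DAY4_WINDOW
    end_h: int = 120
    period_grid: tuple[float, float, float] = DEFAULT_PERIOD_GRID
    outdir: str = "apisomnia_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.observations_path is None and self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        duration = (
            self.simulation.duration if self.simulation is not None else self.end_h
        )
        for name, (a, b) in (
            ("disrupt_h", self.disrupt_h),
            ("day4", self.day4),
        ):
            if not (0 <= a < b <= duration):
                raise ValueError(
                    f"window {name}={a, b} must lie within [0, {duration}]"
                )
        if not 0 <= self.crossover_h < self.end_h:
            raise ValueError("crossover_h must lie before end_h")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["apisomnia_version"] = __version__
        return d

    @classmethod
    def from_manifest(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d.pop("apisomnia_version", None)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig(**d["simulation"])
        for key in ("disrupt_h", "day4", "period_grid"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def load_manifest(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_manifest(json.load(fh))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - relabel with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _rhythm_table(series, grid) -> pd.DataFrame:
    rows = []
    for s in series:
        est = estimate_period(s, grid)
        rows.append(dataclasses.asdict(est))
    return pd.DataFrame(rows)


def _alignment_table(series, window) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(a) for a in align_experiment(series, window)])


def _disrupt_table(records, window) -> pd.DataFrame:
    summaries = disturbance_summary(records, window)
    pos = position_preference(records, window)
    rows = []
    for cond, s in summaries.items():
        rows.append(
            {
                "condition": cond,
                "mean_contacts_per_sleeper": s.mean_contacts_per_sleeper,
                "sd_contacts": s.sd_contacts,
                "n_windows": s.n_windows,
                "prop_lower": s.prop_lower,
                "window_start": s.window[0],
                "window_end": s.window[1],
            }
        )
    df = pd.DataFrame(rows)
    if {"LL", "DD"} <= set(summaries):
        df.attrs["fold_ratio_ll_dd"] = contact_fold_ratio(summaries)
    df.attrs["per_cage_position"] = pos
    return df


def _stats_table(records, alignment, config: PipelineConfig, light) -> pd.DataFrame:
    rows = []
    mm = rm_mixed_model(records, (config.crossover_h, config.end_h), "log_prop_asleep")
    for r in mm.itertuples(index=False):
        rows.append(
            {
                "analysis": f"mixed_model[log_prop_asleep, {config.crossover_h}-{config.end_h}h]",
                "term": r.term,
                "statistic": r.F,
                "df1": r.df_num,
                "df2": r.df_den,
                "p_value": r.p_value,
                "method": mm.attrs["method"],
            }
        )
    if not alignment.empty:
        for metric in ("abs_auc_day4", "peak_distance"):
            ll = alignment.loc[alignment["condition"] == "LL", metric].dropna()
            dd = alignment.loc[alignment["condition"] == "DD", metric].dropna()
            if len(ll) and len(dd):
                wr = wilcoxon_rank_sum(ll, dd)
                rows.append(
                    {
                        "analysis": f"wilcoxon[{metric}, LL-LD vs DD-LD]",
                        "term": "group",
                        "statistic": wr.statistic_value,
                        "df1": math.nan,
                        "df2": math.nan,
                        "p_value": wr.p_value,
                        "method": wr.method,
                    }
                )
    kw, _ = kruskal_wallis_survival(records, config.end_h)
    rows.append(
        {
            "analysis": f"kruskal_wallis[percent_alive at {config.end_h}h]",
            "term": "condition",
            "statistic": kw.statistic_value,
            "df1": kw.df,
            "df2": math.nan,
            "p_value": kw.p_value,
            "method": kw.method,
        }
    )
    if light is not None:
        lc = compare_light_levels(light)
        rows.append(
            {
                "analysis": "t_test[photon_flux top vs bottom]",
                "term": "position",
                "statistic": lc.t_statistic,
                "df1": lc.df,
                "df2": math.nan,
                "p_value": lc.p_value,
                "method": f"pooled-variance t; fold ratio {lc.fold_ratio:.3f}",
            }
        )
    return pd.DataFrame(rows)


def condition_summary_arrays(series: list[SleepSeries]) -> dict:
    """Median curve, +/- 1 MAD band and mean percent alive per condition.

    These arrays are exactly what the figure draws; tests can assert on
    them without touching rendered pixels.  The MAD is the plain median
    absolute deviation (no normal-consistency factor).
    """
    out = {}
    for cond in CONDITIONS:
        group = [s for s in series if s.condition == cond]
        if not group:
            continue
        hours = group[0].hours
        mat = np.vstack([s.percent_asleep for s in group])
        med = np.median(mat, axis=0)
        mad = np.median(np.abs(mat - med), axis=0)
        alive = np.vstack([s.percent_alive for s in group]).mean(axis=0)
        out[cond] = {"hours": hours, "median": med, "mad": mad, "percent_alive": alive}
    return out


def plot_sleep_curves(
    series: list[SleepSeries],
    outpath,
    day4: tuple[float, float] = DAY4_WINDOW,
) -> dict:
    """Per-condition median percent-asleep curves with +/- 1 MAD bands.

    Line width tracks the mean percentage of bees surviving; the day-4
    analysis window is shaded.  Returns the plotted arrays.
    """
    arrays = condition_summary_arrays(series)
    colors = {"LL": "tab:orange", "DD": "tab:blue", "LD": "tab:green"}
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for cond, a in arrays.items():
        h, med, mad = a["hours"], a["median"], a["mad"]
        ax.fill_between(h, med - mad, med + mad, color=colors[cond], alpha=0.2)
        # piecewise linewidth proportional to the percent surviving
        alive = a["percent_alive"]
        for i in range(len(h) - 1):
            lw = 0.5 + 2.5 * (alive[i] + alive[i + 1]) / 200.0
            ax.plot(
                h[i : i + 2],
                med[i : i + 2],
                color=colors[cond],
                lw=lw,
                label=cond if i == 0 else None,
            )
    ax.axvspan(day4[0], day4[1], color="0.85", zorder=0)
    ax.set_xlabel("hours from onset")
    ax.set_ylabel("% of bees asleep")
    ax.legend(title="condition")
    fig.tight_layout()
    fig.savefig(outpath, dpi=150)
    plt.close(fig)
    return arrays


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage and write the result bundle.

    Returns a dict of the in-memory tables keyed by output name.  Any stage
    error aborts with the stage name in the message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.observations_path is not None:
        records = _stage("ingest")(read_observations)(config.observations_path)
        obs = records_to_frame(records)
    else:
        records = _stage("simulate")(simulate_experiment)(config.simulation)
        obs = records_to_frame(records)
        write_observations(obs, outdir / "observations.csv")

    if config.light_path is not None:
        light = _stage("ingest")(read_light_measurements)(config.light_path)
    elif config.simulation is not None:
        light = simulate_light_measurements(seed=config.simulation.seed)
        light.to_csv(outdir / "light.csv", index=False)
    else:
        light = None

    series = _stage("series")(to_sleep_series)(obs)
    rhythm_df = _stage("rhythm")(_rhythm_table)(series, config.period_grid)
    alignment_df = _stage("alignment")(_alignment_table)(series, config.day4)
    disrupt_df = _stage("disruption")(_disrupt_table)(obs, config.disrupt_h)
    stats_df = _stage("stats")(_stats_table)(obs, alignment_df, config, light)

    rhythm_df.to_csv(outdir / "rhythm.csv", index=False)
    alignment_df.to_csv(outdir / "alignment.csv", index=False)
    disrupt_df.to_csv(outdir / "disrupt.csv", index=False)
    stats_df.to_csv(outdir / "stats.csv", index=False)
    arrays = _stage("figures")(plot_sleep_curves)(
        series, outdir / "sleep_curves.png", config.day4
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(config.to_manifest(), fh, indent=2, sort_keys=True)

    return {
        "observations": obs,
        "rhythm": rhythm_df,
        "alignment": alignment_df,
        "disrupt": disrupt_df,
        "stats": stats_df,
        "series": series,
        "figure_arrays": arrays,
    }
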