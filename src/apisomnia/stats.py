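"""Group-level inference for the sleep experiments.

Three procedures, each with an explicit contract:

* repeated-measures mixed models (REML) with a random intercept for cage
  nested within treatment, for hourly responses (log proportion asleep,
  proportion of sleepers in the lower cage half, contacts per sleeper);
* Wilcoxon rank-sum tests for paired alignment metrics, with an exact
  enumeration p-value at small sample sizes;
* a Kruskal-Wallis comparison of the percentage of bees still alive at the
  end of the trial.

All tests are two-sided.  Mixed-model F-tests use Wald statistics with a
residual-based denominator df (n_obs - n_fixed_coefficients); this is a
documented approximation, recorded in the ``method`` field of each result.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .ingest import default_log_offset
from .synth import records_to_frame

#: Combined sample size at or below which the Wilcoxon p is computed by
#: exact enumeration of labelings rather than the normal approximation.
WILCOXON_EXACT_MAX_N = 12


@dataclass
class TestResult:
    """A single hypothesis-test outcome with its method metadata."""

    statistic_name: str
    statistic_value: float
    df: float | tuple[float, float]
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _exact_rank_sum_p(ranks: np.ndarray, n_a: int) -> float:
    """Two-sided exact p by enumerating all assignments of size n_a.

    p = fraction of labelings whose rank sum deviates from its null mean by
    at least as much as the observed one (ties enter through midranks).
    """
    n = len(ranks)
    mean_w = n_a * (n + 1) / 2.0
    observed = abs(ranks[:n_a].sum() - mean_w)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n_a):
        total += 1
        if abs(ranks[list(idx)].sum() - mean_w) >= observed - 1e-9:
            count += 1
    return count / total


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    For combined n <= 12 the p-value is exact, enumerating every labeling of
    the pooled sample; otherwise the tie-corrected normal approximation with
    continuity correction is used.  The path taken is recorded in
    ``method``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: len(a)].sum())
    n = len(pooled)
    if n <= WILCOXON_EXACT_MAX_N:
        p = _exact_rank_sum_p(ranks, len(a))
        method = "exact enumeration of labelings, two-sided"
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(p)
        method = "normal approximation, tie-corrected, continuity-corrected"
    return TestResult(
        statistic_name="W (rank sum of first sample)",
        statistic_value=w,
        df=math.nan,
        p_value=min(p, 1.0),
        method=method,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis survival comparison


def percent_alive_at(records, t_end: int = 120) -> pd.DataFrame:
    """Percent of bees still alive at hour *t_end* per cage.

    ``t_end`` is the trial endpoint on the 0-based hour axis, so the last
    scored observation (hour ``t_end - 1``) carries the final census.
    """
    df = _as_frame(records)
    max_hour = int(df["hour"].max())
    if t_end - 1 > max_hour:
        raise ValueError(
            f"t_end={t_end} is beyond the data (last scored hour {max_hour})"
        )
    rows = []
    for cage_id, g in df.groupby("cage_id", sort=True):
        g = g.sort_values("hour")
        n0 = float(g["n_alive"].iloc[0])
        final = float(g.loc[g["hour"] == t_end - 1, "n_alive"].iloc[0])
        rows.append(
            {
                "cage_id": str(cage_id),
                "condition": str(g["condition"].iloc[0]),
                "replicate_index": int(g["replicate_index"].iloc[0]),
                "percent_alive": 100.0 * final / n0 if n0 > 0 else math.nan,
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis_survival(records, t_end: int = 120):
    """Kruskal-Wallis test on per-cage percent alive at the trial endpoint.

    Returns ``(TestResult, per_cage_table)``.  The H statistic carries the
    standard tie correction; with all responses tied H = 0 and p = 1.
    """
    table = percent_alive_at(records, t_end)
    groups = [
        g["percent_alive"].to_numpy(dtype=float)
        for _, g in table.groupby("condition", sort=True)
    ]
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    result = TestResult(
        statistic_name="H",
        statistic_value=float(h),
        df=float(len(groups) - 1),
        p_value=float(p),
        method="Kruskal-Wallis, tie-corrected, chi-square p",
    )
    return result, table


# ---------------------------------------------------------------------------
# Repeated-measures mixed models

RESPONSES = ("log_prop_asleep", "prop_lower", "contacts")


def _build_response_frame(df: pd.DataFrame, response: str) -> pd.DataFrame:
    if response == "log_prop_asleep":
        sub = df[df["n_alive"] > 0].copy()
        offset = default_log_offset(df)
        sub["resp"] = np.log(sub["n_sleeping"] / sub["n_alive"] + offset)
    elif response == "prop_lower":
        sub = df[df["n_sleeping"] > 0].copy()
        sub["resp"] = sub["n_sleeping_lower"] / sub["n_sleeping"]
    elif response == "contacts":
        sub = df[df["n_sleeping"] > 0].copy()
        sub["resp"] = sub["n_disturbance_contacts"] / sub["n_sleeping"]
    else:
        raise ValueError(f"unknown response {response!r}; expected one of {RESPONSES}")
    return sub


def rm_mixed_model(
    records,
    window: tuple[float, float],
    response: str = "log_prop_asleep",
) -> pd.DataFrame:
    """Repeated-measures mixed model over an analysis window.

    Fits ``response ~ treatment + time + treatment x time`` by REML with a
    random intercept for cage; because cage identifiers are unique within a
    treatment, the cage intercept is equivalently nested within treatment.
    Returns one row per fixed term with Wald F, numerator df, denominator df
    (residual approximation: n_obs - n_fixed_coefficients) and p.  The
    returned frame's ``attrs`` carry ``cage_variance_share`` (cage variance /
    (cage + residual variance)), a ``singular`` flag (zero cage variance or
    non-convergence; reported, not raised) and the method string.

    A constant response cannot support the fit and yields zero F for every
    term with the singular flag set.
    """
    df = _as_frame(records)
    start, end = window
    sub = df[(df["hour"] >= start) & (df["hour"] < end)]
    if sub.empty:
        raise ValueError(f"no observations in window {window}")
    counts = sub.groupby("condition")["cage_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need >= 2 cages per treatment in the window")
    data = _build_response_frame(sub, response)
    method = (
        "MixedLM REML, random intercept for cage (nested in treatment), "
        "Wald F with residual denominator df"
    )
    terms = ["C(condition)", "hour", "C(condition):hour"]

    if np.ptp(data["resp"].to_numpy()) == 0:
        out = pd.DataFrame(
            {
                "term": terms,
                "F": 0.0,
                "df_num": [len(data["condition"].unique()) - 1, 1,
                           len(data["condition"].unique()) - 1],
                "df_den": float(len(data)),
                "p_value": 1.0,
            }
        )
        out.attrs.update(
            cage_variance_share=0.0, singular=True, method=method, response=response
        )
        return out

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(
            "resp ~ C(condition) * hour", data=data, groups=data["cage_id"]
        )
        fit = model.fit(reml=True)

    design_info = model.data.design_info
    k_fe = model.exog.shape[1]
    k_all = len(fit.params)  # fixed effects + variance components
    ddf = float(len(data) - k_fe)
    rows = []
    for term in terms:
        sl = design_info.term_name_slices[term]
        idx = list(range(sl.start or 0, sl.stop))
        L = np.zeros((len(idx), k_all))
        for r, c in enumerate(idx):
            L[r, c] = 1.0
        q = len(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wt = fit.wald_test(L, scalar=True)
        chi2 = float(np.squeeze(wt.statistic))
        F = chi2 / q
        rows.append(
            {
                "term": term,
                "F": F,
                "df_num": q,
                "df_den": ddf,
                "p_value": float(sps.f.sf(F, q, ddf)),
            }
        )
    out = pd.DataFrame(rows)
    cage_var = float(np.squeeze(fit.cov_re.to_numpy()))
    resid_var = float(fit.scale)
    share = cage_var / (cage_var + resid_var) if cage_var + resid_var > 0 else 0.0
    out.attrs.update(
        cage_variance_share=share,
        singular=bool(cage_var <= 1e-10 or not fit.converged),
        method=method,
        response=response,
    )
    return out
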