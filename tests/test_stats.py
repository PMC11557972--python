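"""Group-level inference: Wilcoxon, Kruskal-Wallis, mixed-model contracts."""

import dataclasses
import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from apisomnia import stats, synth


def enumeration_oracle_p(a, b):
    """Independent two-sided oracle: every labeling as a bitmask, U statistic.

    Deliberately coded differently from the implementation (U rather than
    rank sums, bitmask subsets rather than combinations of indices).
    """
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    def u_stat(mask):
        grp_a = [pooled[i] for i in range(n) if mask >> i & 1]
        grp_b = [pooled[i] for i in range(n) if not mask >> i & 1]
        u = 0.0
        for x in grp_a:
            for y in grp_b:
                u += (x > y) + 0.5 * (x == y)
        return u

    mu = na * (n - na) / 2.0
    obs_mask = (1 << na) - 1
    obs_dev = abs(u_stat(obs_mask) - mu)
    hits = total = 0
    for mask in range(1 << n):
        if bin(mask).count("1") != na:
            continue
        total += 1
        if abs(u_stat(mask) - mu) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxonRankSum:
    def test_separated_triples(self):
        res = stats.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings
        assert "exact" in res.method

    def test_identical_multisets(self):
        assert stats.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_singletons(self):
        assert stats.wilcoxon_rank_sum([1], [2]).p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            stats.wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1, 2, 3], [4, 5, 6]),
            ([1.5, 2.5], [0.5, 3.5, 4.0]),
            ([1, 1, 2], [1, 2, 2]),          # ties across groups
            ([10, 20, 30, 40], [15, 25, 35]),
            ([0.0], [0.0, 1.0, 2.0]),
            ([5, 5, 5, 5], [5, 5, 5]),       # fully tied
            ([1, 2], [3]),
            ([-3, 0, 3, 6, 9], [-1, 2, 4, 7, 11]),
        ],
    )
    def test_exact_path_equals_enumeration_oracle(self, a, b):
        got = stats.wilcoxon_rank_sum(a, b).p_value
        assert got == pytest.approx(enumeration_oracle_p(a, b), abs=1e-12)

    def test_exact_and_normal_paths_agree_at_cutover(self):
        # combined n = 12, no ties: the two computations stay within 0.02
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(30):
            a = rng.normal(size=6)
            b = rng.normal(0.7, 1.0, size=6)
            exact = stats.wilcoxon_rank_sum(a, b).p_value
            approx = float(
                sps.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic").pvalue
            )
            worst = max(worst, abs(exact - approx))
        assert worst <= 0.02

    def test_large_samples_use_normal_path(self):
        rng = np.random.default_rng(1)
        res = stats.wilcoxon_rank_sum(rng.normal(size=10), rng.normal(size=10))
        assert "normal" in res.method
        assert 0.0 <= res.p_value <= 1.0


def survival_records(percents, n0=10):
    """Two-hour records whose endpoint survival percentages are as given."""
    recs = []
    for i, (cond, pct) in enumerate(percents):
        final = round(n0 * pct / 100)
        cage = f"{cond}{i}"
        recs.append(synth.ObservationRecord(cage, cond, i + 1, 0, n0, 0, 0, 0))
        recs.append(synth.ObservationRecord(cage, cond, i + 1, 1, final, 0, 0, 0))
    return recs


class TestKruskalWallisSurvival:
    def test_complete_ties(self):
        recs = survival_records(
            [(c, 100) for c in ("LL", "LL", "DD", "DD", "LD", "LD")]
        )
        res, table = stats.kruskal_wallis_survival(recs, t_end=2)
        assert res.statistic_value == 0.0
        assert res.p_value == 1.0

    def test_hand_rank_formula_no_ties(self):
        # groups {10,20,30}, {40,50,60}, {70,80,90}
        percents = (
            [("DD", p) for p in (10, 20, 30)]
            + [("LD", p) for p in (40, 50, 60)]
            + [("LL", p) for p in (70, 80, 90)]
        )
        res, table = stats.kruskal_wallis_survival(survival_records(percents), t_end=2)
        # oracle: H = 12/(N(N+1)) * sum n_i (rbar_i - (N+1)/2)^2
        h_hand = 12.0 / (9 * 10) * 3 * ((2 - 5) ** 2 + (5 - 5) ** 2 + (8 - 5) ** 2)
        assert res.statistic_value == pytest.approx(h_hand, abs=1e-12)
        assert h_hand == 7.2
        assert res.df == 2
        assert res.p_value == pytest.approx(float(sps.chi2.sf(7.2, 2)), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        pcts = rng.choice(np.arange(10, 100, 10), size=9, replace=False)
        conds = ["LL"] * 3 + ["DD"] * 3 + ["LD"] * 3
        # large cages so the transformed percentages stay distinct after
        # rounding to integer bee counts
        r1, _ = stats.kruskal_wallis_survival(
            survival_records(list(zip(conds, pcts)), n0=10_000), t_end=2
        )
        r2, _ = stats.kruskal_wallis_survival(
            survival_records(list(zip(conds, np.sqrt(pcts) * 10)), n0=10_000), t_end=2
        )
        assert r1.statistic_value == pytest.approx(r2.statistic_value, abs=1e-9)

    def test_endpoint_beyond_data_rejected(self, default_experiment):
        with pytest.raises(ValueError, match="beyond the data"):
            stats.kruskal_wallis_survival(default_experiment, t_end=200)

    def test_default_experiment_three_per_condition(self, default_experiment):
        res, table = stats.kruskal_wallis_survival(default_experiment, 120)
        assert len(table) == 9
        assert table.groupby("condition").size().eq(3).all()
        assert 0.0 <= res.p_value <= 1.0


def inject_sleep_loss(records, slope_end=0.6, window=(79, 120), seed=123):
    """Thin LL sleeping counts by a ramp over the window (power-check device)."""
    rng = np.random.default_rng(seed)
    a, b = window
    out = []
    for r in records:
        if r.condition == "LL" and a <= r.hour < b and r.n_sleeping > 0:
            keep = 1.0 - (1.0 - slope_end) * (r.hour - a) / (b - a)
            ns = int(rng.binomial(r.n_sleeping, keep))
            out.append(
                dataclasses.replace(
                    r, n_sleeping=ns, n_sleeping_lower=min(r.n_sleeping_lower, ns)
                )
            )
        else:
            out.append(r)
    return out


class TestMixedModel:
    def test_detects_injected_interaction(self):
        # strong arm-specific sleep-loss ramp: interaction p < 0.01 in
        # nearly every seed
        hits = 0
        for i in range(20):
            cfg = synth.null_calibration_config(7000 + i).replace(
                amplitude0=0.35, baseline=0.45
            )
            recs = inject_sleep_loss(synth.simulate_experiment(cfg))
            mm = stats.rm_mixed_model(recs, (79, 120), "log_prop_asleep")
            p = float(mm.loc[mm["term"] == "C(condition):hour", "p_value"].iloc[0])
            if p < 0.01:
                hits += 1
        assert hits >= 18

    def test_constant_response_flagged_singular(self):
        recs = [
            synth.ObservationRecord(f"{c}{i}", c, i, h, 10, 5, 0, 0)
            for c in ("LL", "DD")
            for i in (1, 2)
            for h in range(100)
        ]
        mm = stats.rm_mixed_model(recs, (79, 100), "log_prop_asleep")
        assert (mm["F"] == 0.0).all()
        assert mm.attrs["singular"]
        assert (mm["p_value"] == 1.0).all()

    def test_invariant_to_cage_relabelling(self, default_experiment):
        mm1 = stats.rm_mixed_model(default_experiment, (79, 120), "log_prop_asleep")
        relabelled = [
            dataclasses.replace(r, cage_id="cage_" + r.cage_id[::-1])
            for r in default_experiment
        ]
        mm2 = stats.rm_mixed_model(relabelled, (79, 120), "log_prop_asleep")
        assert np.allclose(mm1["F"], mm2["F"], rtol=1e-6)

    def test_requires_two_cages_per_treatment(self):
        recs = [
            synth.ObservationRecord(f"{c}1", c, 1, h, 10, 5, 0, 0)
            for c in ("LL", "DD")
            for h in range(100)
        ]
        with pytest.raises(ValueError, match="2 cages"):
            stats.rm_mixed_model(recs, (79, 100))

    @pytest.mark.parametrize("response", ["prop_lower", "contacts"])
    def test_alternative_responses_fit(self, default_experiment, response):
        mm = stats.rm_mixed_model(default_experiment, (90, 120), response)
        assert set(mm["term"]) == {"C(condition)", "hour", "C(condition):hour"}
        assert (mm["p_value"].between(0, 1)).all()
        assert mm.attrs["method"].startswith("MixedLM REML")
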