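"""Mann-Kendall trend test, permutation inference, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from shellmea import (
    ConfigError,
    group_trend_comparison,
    mann_kendall,
    median_percent_change,
    rank_sum_permutation,
    summarize,
)
from shellmea.sigio import GROUP_PLANAR, GROUP_SHELL


def mk_brute_force(x):
    """Oracle: O(n^2) pair enumeration + closed-form tie-corrected variance."""
    x = np.asarray(x, float)
    n = len(x)
    s = sum(
        np.sign(x[j] - x[i]) for i in range(n) for j in range(i + 1, n)
    )
    _, counts = np.unique(x, return_counts=True)
    tie = sum(t * (t - 1) * (2 * t + 5) for t in counts if t > 1)
    var = (n * (n - 1) * (2 * n + 5) - tie) / 18
    if var <= 0:
        return s, 0.0, 0.0
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    return s, var, z


class TestMannKendall:
    def test_monotone_sequence_closed_form(self):
        """x = 1..5: S = 10, var = 50/3, z = 9/sqrt(50/3) = 2.2045."""
        res = mann_kendall([1, 2, 3, 4, 5])
        assert res.S == 10
        assert res.var_S == pytest.approx(50 / 3)
        assert res.z == pytest.approx(2.2045, abs=1e-4)

    def test_constant_sequence_degenerate(self):
        res = mann_kendall([3.0, 3.0, 3.0])
        assert res.S == 0
        assert res.z == 0.0
        assert res.degenerate

    @given(seed=st.integers(0, 200))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 51))
        # mix continuous values and ties
        x = rng.choice([0.0, 1.0, 2.5], n) + rng.normal(0, 1, n) * rng.integers(0, 2)
        res = mann_kendall(x)
        s, var, z = mk_brute_force(x)
        assert res.S == s
        assert res.var_S == pytest.approx(var)
        assert res.z == pytest.approx(z)

    @given(seed=st.integers(0, 100))
    def test_reversal_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(2, 30)))
        fwd = mann_kendall(x)
        rev = mann_kendall(x[::-1])
        assert rev.S == -fwd.S
        assert rev.z == pytest.approx(-fwd.z)

    def test_too_short_rejected(self):
        with pytest.raises(ConfigError):
            mann_kendall([1.0])


class TestRankSumPermutation:
    def test_identical_samples_p_is_one(self):
        res = rank_sum_permutation([1, 2, 3], [1, 2, 3], sided="two")
        assert res.exhaustive
        assert res.p_value == pytest.approx(1.0)

    def test_separated_samples_exhaustive(self):
        """x = {1,2,3} vs y = {4,5,6}: only 2 of C(6,3) = 20 splits as extreme."""
        res = rank_sum_permutation([1, 2, 3], [4, 5, 6], sided="two")
        assert res.exhaustive
        assert res.n_perm == 20
        assert res.p_value == pytest.approx(0.1)

    def test_two_sided_symmetric_in_arguments(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 9)
        p_xy = rank_sum_permutation(x, y, sided="two").p_value
        p_yx = rank_sum_permutation(y, x, sided="two").p_value
        assert p_xy == pytest.approx(p_yx)

    def test_one_sided_tails_sum_to_one_plus_point_mass(self, rng):
        x = rng.normal(0, 1, 6)
        y = rng.normal(0, 1, 6)
        pg = rank_sum_permutation(x, y, sided="greater")
        pl = rank_sum_permutation(x, y, sided="less")
        assert pg.exhaustive and pl.exhaustive
        # P(T >= obs) + P(T <= obs) = 1 + P(T == obs); get the point mass
        # from an independent enumeration of all splits
        from itertools import combinations

        from scipy.stats import rankdata

        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        obs = ranks[: len(x)].sum()
        null = [ranks[list(c)].sum() for c in combinations(range(len(pooled)), len(x))]
        point_mass = np.mean(np.isclose(null, obs))
        assert pg.p_value + pl.p_value == pytest.approx(1.0 + point_mass)

    def test_sampled_agrees_with_exhaustive(self):
        """Monte-Carlo estimate within 3 SE of the exact tail probability."""
        rng = np.random.default_rng(4)
        x = rng.normal(0.8, 1, 9)
        y = rng.normal(0.0, 1, 9)
        exact = rank_sum_permutation(x, y, sided="two")
        assert exact.exhaustive
        import shellmea.stats as stats_mod

        old = stats_mod.EXHAUSTIVE_LIMIT
        stats_mod.EXHAUSTIVE_LIMIT = 1  # force sampling
        try:
            sampled = rank_sum_permutation(x, y, n_perm=20000, sided="two", seed=5)
        finally:
            stats_mod.EXHAUSTIVE_LIMIT = old
        assert not sampled.exhaustive
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / sampled.n_perm)
        assert abs(sampled.p_value - exact.p_value) <= 3 * se + 1e-4

    def test_sampled_p_has_add_one_floor(self):
        x = np.arange(40.0)
        y = np.arange(40.0) + 100.0
        res = rank_sum_permutation(x, y, n_perm=999, sided="two", seed=0)
        assert not res.exhaustive
        assert res.p_value >= 1.0 / (999 + 1)

    def test_empty_sample_rejected(self):
        with pytest.raises(ConfigError):
            rank_sum_permutation([], [1.0])


class TestMedianPercentChange:
    def test_reported_style_example(self):
        assert median_percent_change([10, 10, 10], [15.76, 15.76, 15.76]) == pytest.approx(57.6)

    def test_no_change_is_zero(self, rng):
        x = rng.uniform(1, 10, 31)
        assert median_percent_change(x, x) == pytest.approx(0.0)

    @given(seed=st.integers(0, 100))
    def test_matches_independent_median_computation(self, seed):
        rng = np.random.default_rng(seed)
        before = rng.uniform(1, 10, int(rng.integers(1, 40)))
        after = rng.uniform(1, 10, int(rng.integers(1, 40)))
        expected = 100 * (np.median(after) - np.median(before)) / np.median(before)
        assert median_percent_change(before, after) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ConfigError):
            median_percent_change([-1.0, 0.0, 1.0], [1.0])


def _trend_events(rng, z_boost_shell=0.0, n_rounds=3, per_round=20):
    """Synthetic per-channel event table spanning two groups and several rounds."""
    rows = []
    for cid, group in [
        ("e1", GROUP_SHELL),
        ("e2", GROUP_SHELL),
        ("e4", GROUP_PLANAR),
        ("e5", GROUP_PLANAR),
    ]:
        for r in range(n_rounds):
            times = np.sort(rng.uniform(r * 10, r * 10 + 9, per_round))
            base = rng.uniform(6, 8, per_round)
            if group == GROUP_SHELL:
                base = base + z_boost_shell * r
            for t, s in zip(times, base):
                rows.append(
                    {
                        "channel_id": cid,
                        "group": group,
                        "round_index": r,
                        "peak_time_s": t,
                        "snr": s,
                    }
                )
    return pd.DataFrame(rows)


class TestGroupTrendComparison:
    def test_label_swap_negates_delta(self, rng):
        events = _trend_events(rng, z_boost_shell=2.0)
        res = group_trend_comparison(events, seed=1)
        swapped = events.assign(
            group=events.group.map({GROUP_SHELL: GROUP_PLANAR, GROUP_PLANAR: GROUP_SHELL})
        )
        res_swapped = group_trend_comparison(swapped, seed=1)
        assert res_swapped.delta == pytest.approx(-res.delta)

    def test_strong_shell_trend_detected(self, rng):
        events = _trend_events(rng, z_boost_shell=3.0, n_rounds=4)
        res = group_trend_comparison(events, seed=2)
        assert res.z_shell > 0
        assert res.delta > 0
        assert res.permutation.exhaustive  # C(4,2) = 6 label assignments
        assert res.permutation.p_value <= 1 / 6 + 1e-12

    def test_single_round_rejected(self, rng):
        events = _trend_events(rng, n_rounds=1)
        with pytest.raises(ConfigError):
            group_trend_comparison(events)

    def test_missing_group_rejected(self, rng):
        events = _trend_events(rng)
        with pytest.raises(ConfigError):
            group_trend_comparison(events[events.group == GROUP_SHELL])


class TestSummarize:
    def test_rate_and_isi(self):
        table = pd.DataFrame(
            {
                "channel_id": ["e1"] * 10,
                "group": [GROUP_SHELL] * 10,
                "round_index": [0] * 10,
                "peak_time_s": np.linspace(0, 4.5, 10),
                "snr": np.full(10, 7.0),
            }
        )
        out = summarize(table, duration_s=5.0)
        assert out.n_spikes.item() == 10
        assert out.rate_hz.item() == pytest.approx(2.0)

    def test_isi_values(self):
        from shellmea.stats import isi_list

        np.testing.assert_allclose(isi_list([1.0, 2.0, 4.0]), [1.0, 2.0])

    def test_count_matches_rows_per_group(self, rng):
        events = _trend_events(rng)
        out = summarize(events)
        assert out.n_spikes.sum() == len(events)
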