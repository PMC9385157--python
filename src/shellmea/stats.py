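"""Nonparametric statistics for spike-train comparisons.

Two inferential tools, both distribution-free:

* **Mann-Kendall trend test.**  For an ordered sequence ``x_1..x_n`` the
  statistic is ``S = sum_{i<j} sign(x_j - x_i)``; under the no-trend null
  its variance (with a correction for tied values) is

      var(S) = [n(n-1)(2n+5) - sum_ties t(t-1)(2t+5)] / 18

  and the standardized, continuity-corrected statistic is
  ``z = (S - 1)/sqrt(var S)`` for ``S > 0``, ``0`` for ``S = 0`` and
  ``(S + 1)/sqrt(var S)`` for ``S < 0``.  z is comparable across
  recordings of different lengths; positive z means an increasing trend.

* **Permutation tests.**  The rank-sum test compares two SNR samples by the
  rank sum of the first sample within the pooled ranking (midranks for
  ties), with the null distribution built by re-assigning the pooled values
  to groups — exhaustively when the number of splits is small, otherwise by
  random sampling with the add-one p estimator.  The group-trend comparison
  permutes *channel* labels (spikes within a channel are not exchangeable),
  re-merges the permuted groups and recomputes the difference of
  Mann-Kendall z values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ConfigError, DataError
from .merge import merge_group
from .sigio import GROUP_PLANAR, GROUP_SHELL

__all__ = [
    "TrendResult",
    "PermutationResult",
    "GroupTrendResult",
    "mann_kendall",
    "rank_sum_permutation",
    "median_percent_change",
    "group_trend_comparison",
    "summarize",
]

#: switch to random sampling above this many exact label assignments
EXHAUSTIVE_LIMIT = 100_000

_EPS = 1e-12


@dataclass(frozen=True)
class TrendResult:
    n: int
    S: int
    var_S: float
    z: float
    degenerate: bool = False  # var_S == 0 (all values tied)


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    n_perm: int
    p_value: float
    sided: str
    seed: int | None
    exhaustive: bool


@dataclass(frozen=True)
class GroupTrendResult:
    """Label-permutation comparison of per-group amplitude trends."""

    z_shell: float
    z_planar: float
    delta: float          # z_shell - z_planar
    permutation: PermutationResult


def mann_kendall(x) -> TrendResult:
    """Mann-Kendall trend statistic of an ordered numeric sequence."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ConfigError("mann_kendall needs a 1-D sequence of length >= 2")
    if not np.isfinite(x).all():
        raise DataError("sequence contains non-finite values")
    n = x.size

    s = 0
    for i in range(n - 1):
        s += int(np.sign(x[i + 1 :] - x[i]).sum())

    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    tie_term = np.sum(ties * (ties - 1) * (2 * ties + 5))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0

    if var_s <= 0:
        return TrendResult(n=n, S=s, var_S=0.0, z=0.0, degenerate=True)
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    return TrendResult(n=n, S=s, var_S=float(var_s), z=float(z))


def _tail_count(null: np.ndarray, observed: float, center: float, sided: str) -> int:
    if sided == "two":
        return int(np.sum(np.abs(null - center) >= np.abs(observed - center) - _EPS))
    if sided == "greater":
        return int(np.sum(null >= observed - _EPS))
    if sided == "less":
        return int(np.sum(null <= observed + _EPS))
    raise ConfigError("sided must be 'two', 'greater' or 'less'")


def rank_sum_permutation(
    x,
    y,
    n_perm: int = 9999,
    sided: str = "two",
    seed: int | None = None,
) -> PermutationResult:
    """Wilcoxon rank-sum statistic with permutation inference.

    The observed statistic is the sum of the (mid)ranks of ``x`` within the
    pooled sample.  When the number of distinct group assignments
    C(n, n_x) is at most :data:`EXHAUSTIVE_LIMIT` the null distribution is
    enumerated exactly and the p-value is the exact tail proportion;
    otherwise ``n_perm`` random re-assignments are drawn and the add-one
    estimator ``(b + 1)/(n_perm + 1)`` is used.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ConfigError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if not np.isfinite(pooled).all():
        raise DataError("samples contain non-finite values")
    n, nx = pooled.size, x.size
    ranks = rankdata(pooled)
    observed = float(ranks[:nx].sum())
    center = nx * (n + 1) / 2.0

    n_exact = comb(n, nx)
    if n_exact <= EXHAUSTIVE_LIMIT:
        null = np.fromiter(
            (ranks[list(idx)].sum() for idx in combinations(range(n), nx)),
            dtype=np.float64,
            count=n_exact,
        )
        count = _tail_count(null, observed, center, sided)
        return PermutationResult(
            observed=observed,
            n_perm=n_exact,
            p_value=count / n_exact,
            sided=sided,
            seed=seed,
            exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    # each row of idx is a uniformly random subset of size nx
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :nx]
    null = ranks[idx].sum(axis=1)
    count = _tail_count(null, observed, center, sided)
    return PermutationResult(
        observed=observed,
        n_perm=n_perm,
        p_value=(count + 1) / (n_perm + 1),
        sided=sided,
        seed=seed,
        exhaustive=False,
    )


def median_percent_change(before, after) -> float:
    """Percent change of the median: 100 * (med(after) - med(before)) / med(before)."""
    before = np.asarray(before, dtype=np.float64)
    after = np.asarray(after, dtype=np.float64)
    if before.size == 0 or after.size == 0:
        raise ConfigError("both samples must be non-empty")
    mb = float(np.median(before))
    if mb <= 0:
        raise ConfigError("median of the reference sample must be positive")
    return 100.0 * (float(np.median(after)) - mb) / mb


def _group_trend_z(events: pd.DataFrame, merge_window_ms: float) -> float:
    """Mann-Kendall z of the merged SNR sequence in (round, time) order."""
    if len(events) < 2:
        return 0.0
    merged = merge_group(events, merge_window_ms=merge_window_ms)
    merged = merged.sort_values(["round_index", "time_s"], kind="mergesort")
    snr = merged["snr"].to_numpy()
    if snr.size < 2:
        return 0.0
    return mann_kendall(snr).z


def group_trend_comparison(
    events: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
    sided: str = "greater",
    merge_window_ms: float = 2.0,
    channels: pd.DataFrame | None = None,
) -> GroupTrendResult:
    """Is the shell group's amplitude trend stronger than the planar group's?

    ``events`` is a per-channel detection table (columns ``channel_id,
    group, round_index, peak_time_s, snr``) covering both electrode groups
    and at least two rounds.  Per group, spikes are merged and the
    Mann-Kendall z of the merged SNR sequence in (round, time) order is
    computed; the observed statistic is ``delta = z_shell - z_planar``.

    Inference permutes the *channel* group labels (keeping group sizes),
    re-merges and recomputes delta.  All C(n_channels, n_shell) assignments
    are enumerated when there are at most :data:`EXHAUSTIVE_LIMIT` of them
    (the identity assignment is part of the null set), otherwise ``n_perm``
    random assignments are drawn with the add-one estimator.

    ``channels`` optionally supplies the full electrode roster as a table
    with ``channel_id`` and ``group`` columns.  Electrodes that detected no
    spikes still carry a permutable label, so passing the roster matters
    whenever some channels are silent; without it the roster is inferred
    from the events table.
    """
    required = {"channel_id", "group", "round_index", "peak_time_s", "snr"}
    if not required.issubset(events.columns):
        raise DataError(f"events table lacks columns {sorted(required)}")
    rounds = np.unique(events["round_index"].to_numpy())
    rounds = rounds[rounds >= 0]
    if rounds.size < 2:
        raise ConfigError("group_trend_comparison needs at least 2 rounds")

    roster = channels if channels is not None else events
    if not {"channel_id", "group"}.issubset(roster.columns):
        raise DataError("channel roster needs channel_id and group columns")
    ch_groups = (
        roster[["channel_id", "group"]].drop_duplicates().sort_values("channel_id")
    )
    if ch_groups["channel_id"].duplicated().any():
        raise DataError("a channel_id appears with two different group labels")
    channel_ids = ch_groups["channel_id"].tolist()
    shell_channels = ch_groups.loc[ch_groups["group"] == GROUP_SHELL, "channel_id"]
    n_ch, n_shell = len(channel_ids), len(shell_channels)
    if n_shell == 0 or n_shell == n_ch:
        raise ConfigError("both electrode groups must be present")

    in_round = events[events["round_index"] >= 0]

    def delta_for(shell_set: frozenset) -> float:
        lab = in_round["channel_id"].isin(shell_set)
        ev_shell = in_round[lab].assign(group=GROUP_SHELL)
        ev_planar = in_round[~lab].assign(group=GROUP_PLANAR)
        return _group_trend_z(ev_shell, merge_window_ms) - _group_trend_z(
            ev_planar, merge_window_ms
        )

    observed_set = frozenset(shell_channels)
    observed = delta_for(observed_set)

    n_exact = comb(n_ch, n_shell)
    if n_exact <= min(EXHAUSTIVE_LIMIT, max(n_perm, 1)):
        null = np.array(
            [delta_for(frozenset(c)) for c in combinations(channel_ids, n_shell)]
        )
        count = _tail_count(null, observed, 0.0, sided)
        perm = PermutationResult(
            observed=observed,
            n_perm=n_exact,
            p_value=count / n_exact,
            sided=sided,
            seed=seed,
            exhaustive=True,
        )
    else:
        rng = np.random.default_rng(seed)
        null = np.array(
            [
                delta_for(frozenset(rng.choice(channel_ids, n_shell, replace=False)))
                for _ in range(n_perm)
            ]
        )
        count = _tail_count(null, observed, 0.0, sided)
        perm = PermutationResult(
            observed=observed,
            n_perm=n_perm,
            p_value=(count + 1) / (n_perm + 1),
            sided=sided,
            seed=seed,
            exhaustive=False,
        )

    z_shell = _group_trend_z(in_round[in_round["channel_id"].isin(observed_set)], merge_window_ms)
    z_planar = _group_trend_z(in_round[~in_round["channel_id"].isin(observed_set)], merge_window_ms)
    return GroupTrendResult(
        z_shell=z_shell, z_planar=z_planar, delta=observed, permutation=perm
    )


def summarize(table: pd.DataFrame, duration_s: float | None = None) -> pd.DataFrame:
    """Per-channel (or per-group) descriptive summary of a spike table.

    Accepts either a per-channel events table (grouped by ``channel_id``)
    or a merged table (grouped by ``group``).  Reports spike count, mean
    firing rate, median SNR and median inter-spike interval.  ``duration_s``
    defaults to the span of observed spike times.
    """
    key = "channel_id" if "channel_id" in table.columns else "group"
    time_col = "peak_time_s" if "peak_time_s" in table.columns else "time_s"
    if len(table) == 0:
        return pd.DataFrame(
            columns=[key, "n_spikes", "rate_hz", "median_snr", "median_isi_s"]
        )
    t = table[time_col].to_numpy(dtype=float)
    span = duration_s if duration_s is not None else float(t.max() - t.min())
    rows = []
    for name, sub in table.groupby(key, sort=True):
        times = np.sort(sub[time_col].to_numpy(dtype=float))
        isis = np.diff(times)
        rows.append(
            {
                key: name,
                "n_spikes": len(sub),
                "rate_hz": len(sub) / span if span > 0 else np.nan,
                "median_snr": float(sub["snr"].median()),
                "median_isi_s": float(np.median(isis)) if isis.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def isi_list(times) -> np.ndarray:
    """Inter-spike intervals of a time-sorted train."""
    t = np.asarray(times, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ConfigError("spike times must be sorted")
    return np.diff(t)
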