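"""Cross-electrode spike de-duplication and common-spike matching.

When several electrodes of one group (the shell electrodes, say) pick up
the same physiological spike, the detections appear as near-coincident
events.  They are collapsed by single-linkage chaining: events sorted by
peak time whose consecutive gaps are strictly less than the merge window
(default 2 ms, one waveform length) form one cluster, summarized as a
single spike carrying the maximum normalized amplitude (SNR) among its
members and that member's peak time.

``match_common`` pairs spikes detected by both groups: candidate pairs
within the matching window are taken greedily in order of increasing time
difference, each spike used at most once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError

__all__ = ["merge_group", "match_common", "count_summary", "MERGED_COLUMNS"]

MERGED_COLUMNS = [
    "group",
    "round_index",
    "time_s",
    "snr",
    "n_contributing",
    "source_channels",
]

PAIR_COLUMNS = ["time_a_s", "time_b_s", "snr_a", "snr_b"]

_EVENT_COLS = ("channel_id", "group", "round_index", "peak_time_s", "snr")


def merge_group(events: pd.DataFrame, merge_window_ms: float = 2.0) -> pd.DataFrame:
    """Collapse near-coincident detections of one electrode group.

    ``events`` must contain columns ``channel_id, group, round_index,
    peak_time_s, snr`` and a single group label.  Consecutive time-sorted
    events with gaps < ``merge_window_ms`` chain into one cluster (single
    linkage, strict inequality); each cluster yields one merged spike whose
    SNR and time come from its maximum-SNR member (SNR ties broken by the
    lexicographically smallest channel_id).  Output is time-sorted.
    """
    missing = set(_EVENT_COLS) - set(events.columns)
    if missing:
        raise DataError(f"events table lacks columns {sorted(missing)}")
    if len(events) == 0:
        return pd.DataFrame(columns=MERGED_COLUMNS)
    groups = events["group"].unique()
    if len(groups) > 1:
        raise ConfigError(
            f"merge_group expects events of a single group, got {sorted(groups)}"
        )
    window_s = merge_window_ms / 1000.0

    ev = events.sort_values(
        ["peak_time_s", "channel_id"], kind="mergesort"
    ).reset_index(drop=True)
    t = ev["peak_time_s"].to_numpy(dtype=float)
    new_cluster = np.diff(t) >= window_s
    cluster_id = np.concatenate([[0], np.cumsum(new_cluster)])

    # representative per cluster: max SNR, ties -> smallest channel_id
    snr = ev["snr"].to_numpy(dtype=float)
    ch_codes = pd.factorize(ev["channel_id"], sort=True)[0]
    order = np.lexsort((ch_codes, -snr, cluster_id))
    first = np.concatenate([[True], np.diff(cluster_id[order]) > 0])
    rep = order[first]

    tags = [
        f"{c}@{tt:.9f}" for c, tt in zip(ev["channel_id"], t)
    ]
    sources = pd.Series(tags).groupby(cluster_id, sort=True).agg(";".join)
    sizes = np.bincount(cluster_id)

    merged = pd.DataFrame(
        {
            "group": groups[0],
            "round_index": ev["round_index"].to_numpy()[rep].astype(int),
            "time_s": t[rep],
            "snr": snr[rep],
            "n_contributing": sizes,
            "source_channels": sources.to_numpy(),
        },
        columns=MERGED_COLUMNS,
    )
    return merged.sort_values("time_s", kind="mergesort").reset_index(drop=True)


def match_common(
    train_a: pd.DataFrame, train_b: pd.DataFrame, window_ms: float = 2.0
) -> pd.DataFrame:
    """One-to-one greedy matching of two merged spike trains.

    Both trains need ``time_s`` and ``snr`` columns and must be time-sorted.
    Candidate pairs with |t_a - t_b| < ``window_ms`` are processed in
    increasing |dt| (ties: earlier a-time, then earlier b-time); each spike
    is used at most once.  Returns a table with columns
    ``time_a_s, time_b_s, snr_a, snr_b``.
    """
    for name, train in (("a", train_a), ("b", train_b)):
        if not {"time_s", "snr"}.issubset(train.columns):
            raise DataError(f"train {name} lacks time_s/snr columns")
        t = train["time_s"].to_numpy(dtype=float)
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ConfigError(f"train {name} is not time-sorted")

    ta = train_a["time_s"].to_numpy(dtype=float)
    tb = train_b["time_s"].to_numpy(dtype=float)
    window_s = window_ms / 1000.0

    candidates: list[tuple[float, float, float, int, int]] = []
    j0 = 0
    for i, t in enumerate(ta):
        while j0 < tb.size and tb[j0] <= t - window_s:
            j0 += 1
        j = j0
        while j < tb.size and tb[j] < t + window_s:
            dt = abs(t - tb[j])
            if dt < window_s:
                candidates.append((dt, t, tb[j], i, j))
            j += 1
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    sa = train_a["snr"].to_numpy(dtype=float)
    sb = train_b["snr"].to_numpy(dtype=float)
    for dt, t, u, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        rows.append(
            {"time_a_s": t, "time_b_s": u, "snr_a": sa[i], "snr_b": sb[j]}
        )
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return pairs.sort_values("time_a_s", kind="mergesort").reset_index(drop=True)


def count_summary(events: pd.DataFrame, merged: pd.DataFrame) -> pd.DataFrame:
    """Per-channel spike counts plus the merged (union) count of the group.

    The union count is bounded below by every single-channel count and
    above by the sum of the per-channel counts; both bounds are verified
    and a violation raises :class:`DataError` (it would mean ``merged`` was
    not produced from ``events``).
    """
    per_channel = (
        events.groupby("channel_id").size() if len(events) else pd.Series(dtype=int)
    )
    union = len(merged)
    rows = [
        {"channel_id": cid, "kind": "single", "count": int(n)}
        for cid, n in per_channel.items()
    ]
    rows.append({"channel_id": "(union)", "kind": "union", "count": union})
    table = pd.DataFrame(rows, columns=["channel_id", "kind", "count"])
    max_single = int(per_channel.max()) if len(per_channel) else 0
    total = int(per_channel.sum()) if len(per_channel) else 0
    if not (max_single <= union <= max(total, 0) or (total == 0 and union == 0)):
        raise DataError(
            f"union count {union} violates bounds [{max_single}, {total}]"
        )
    return table
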