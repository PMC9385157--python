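"""Robust noise estimation and threshold-based spike detection.

Per channel, the noise level is estimated robustly as

    sigma_n = median(|S_t|) / 0.6745

(for Gaussian noise, median(|Z|) = 0.6745 sigma, so the estimator is
Fisher-consistent while being nearly insensitive to the small fraction of
samples occupied by spikes).  Samples whose absolute value reaches
``threshold_mult * sigma_n`` (default 5) are grouped into events by window
isolation: suprathreshold samples closer than the window length (default
3.5 ms) belong to one event, and the location of the largest absolute
amplitude in each group is the event time.  Each event carries a
fixed-length waveform snippet centered on the peak and an SNR equal to the
absolute peak amplitude divided by sigma_n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import BoundaryError, ConfigError, DataError
from .sigio import Recording

__all__ = [
    "NoiseEstimate",
    "SpikeEvent",
    "estimate_noise_sigma",
    "detect_spikes",
    "extract_waveform",
    "detect_all",
    "EVENT_COLUMNS",
]

#: Column order of the events table / CSV.
EVENT_COLUMNS = [
    "recording_id",
    "channel_id",
    "group",
    "round_index",
    "peak_time_s",
    "amplitude_uv",
    "snr",
]


@dataclass(frozen=True)
class NoiseEstimate:
    channel_id: str
    sigma_uv: float


@dataclass
class SpikeEvent:
    """One detected threshold-crossing event on one channel."""

    channel_id: str
    peak_time_s: float
    amplitude_uv: float       # signed value at the peak sample
    abs_amplitude_uv: float
    snr: float                # abs_amplitude_uv / sigma_n of the channel
    waveform: np.ndarray      # snippet centered on the peak
    round_index: int = -1
    group: str = ""

    @property
    def peak_sample_in_waveform(self) -> int:
        return int(np.argmax(np.abs(self.waveform)))


def estimate_noise_sigma(signal: np.ndarray, channel_id: str = "") -> NoiseEstimate:
    """Robust noise sigma: median(|signal|) / 0.6745 over the full trace."""
    x = np.asarray(signal, dtype=np.float64)
    if x.size == 0:
        raise ConfigError("cannot estimate noise on an empty signal")
    if not np.isfinite(x).all():
        raise DataError("signal contains non-finite values")
    return NoiseEstimate(channel_id=channel_id, sigma_uv=float(np.median(np.abs(x)) / 0.6745))


def extract_waveform(
    signal: np.ndarray, peak_index: int, fs_hz: float, window_ms: float = 3.5
) -> np.ndarray:
    """Snippet of length ``round(fs_hz * window_ms / 1000)`` centered on the peak.

    The peak sample sits at index ``length // 2``.  Raises
    :class:`BoundaryError` when the window crosses a recording boundary;
    callers drop such events so all returned waveforms are equal-length.
    """
    x = np.asarray(signal)
    length = int(round(fs_hz * window_ms / 1000.0))
    if length < 1:
        raise ConfigError("window shorter than one sample")
    start = peak_index - length // 2
    stop = start + length
    if start < 0 or stop > x.size:
        raise BoundaryError(
            f"window [{start}, {stop}) outside recording of {x.size} samples"
        )
    return x[start:stop].copy()


def detect_spikes(
    signal: np.ndarray,
    sigma: float,
    fs_hz: float,
    threshold_mult: float = 5.0,
    window_ms: float = 3.5,
    channel_id: str = "",
    polarity: str = "both",
) -> list[SpikeEvent]:
    """Threshold detection with window isolation on one channel.

    Suprathreshold samples (|x| >= threshold_mult * sigma, or -x for
    negative-only polarity) are grouped: consecutive suprathreshold samples
    with gaps shorter than ``window_ms`` form one event whose peak is the
    sample of largest absolute amplitude (earliest on ties).  Events whose
    centered ``window_ms`` snippet would cross a recording edge are dropped.
    Returned events are time-sorted with pairwise peak separation >=
    ``window_ms``.
    """
    if sigma <= 0:
        raise ConfigError("sigma must be positive")
    if polarity not in ("both", "negative"):
        raise ConfigError("polarity must be 'both' or 'negative'")
    x = np.asarray(signal, dtype=np.float64)
    thr = threshold_mult * sigma
    detection_trace = np.abs(x) if polarity == "both" else -x
    above = np.flatnonzero(detection_trace >= thr)
    if above.size == 0:
        return []

    window_samples = int(round(fs_hz * window_ms / 1000.0))
    # gap >= window starts a new group ("closer than the window" joins)
    breaks = np.flatnonzero(np.diff(above) >= window_samples)
    groups = np.split(above, breaks + 1)

    events: list[SpikeEvent] = []
    for g in groups:
        peak = int(g[np.argmax(np.abs(x[g]))])
        try:
            wf = extract_waveform(x, peak, fs_hz, window_ms)
        except BoundaryError:
            continue
        amp = float(x[peak])
        events.append(
            SpikeEvent(
                channel_id=channel_id,
                peak_time_s=peak / fs_hz,
                amplitude_uv=amp,
                abs_amplitude_uv=abs(amp),
                snr=abs(amp) / sigma,
                waveform=wf,
            )
        )
    return events


def detect_all(
    rec: Recording,
    threshold_mult: float = 5.0,
    window_ms: float = 3.5,
    polarity: str = "both",
    recording_id: str = "rec",
) -> tuple[pd.DataFrame, pd.DataFrame, list[SpikeEvent]]:
    """Independent noise estimation + detection on every channel.

    Returns ``(events, noise, spike_objects)``: an events table with columns
    ``recording_id, channel_id, group, round_index, peak_time_s,
    amplitude_uv, snr`` (time-sorted within channel), a noise table with
    ``channel_id, sigma_uv``, and the underlying :class:`SpikeEvent` objects
    (which keep the waveform snippets).
    """
    rows = []
    noise_rows = []
    all_events: list[SpikeEvent] = []
    for c, meta in enumerate(rec.channels):
        trace = rec.data[:, c]
        est = estimate_noise_sigma(trace, channel_id=meta.channel_id)
        noise_rows.append({"channel_id": meta.channel_id, "sigma_uv": est.sigma_uv})
        events = detect_spikes(
            trace,
            est.sigma_uv,
            rec.fs_hz,
            threshold_mult=threshold_mult,
            window_ms=window_ms,
            channel_id=meta.channel_id,
            polarity=polarity,
        )
        for ev in events:
            ev.round_index = meta.round_of(ev.peak_time_s)
            ev.group = meta.group
            rows.append(
                {
                    "recording_id": recording_id,
                    "channel_id": ev.channel_id,
                    "group": meta.group,
                    "round_index": ev.round_index,
                    "peak_time_s": ev.peak_time_s,
                    "amplitude_uv": ev.amplitude_uv,
                    "snr": ev.snr,
                }
            )
        all_events.extend(events)
    events_df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    noise_df = pd.DataFrame(noise_rows, columns=["channel_id", "sigma_uv"])
    return events_df, noise_df, all_events


def write_events_csv(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["peak_time_s"] = out["peak_time_s"].map(lambda t: f"{t:.9f}")
    out.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"events table lacks columns {sorted(missing)}")
    return df[EVENT_COLUMNS]
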