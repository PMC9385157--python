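"""Recording container, on-disk format, and band-pass preprocessing.

A :class:`Recording` is a time x channel matrix of extracellular voltages in
microvolts together with the sampling rate and per-channel metadata (group
label, electrode distance, stimulation-round intervals).  On disk a
recording is a flat little-endian float32 binary file, time-major (all
channels of sample 0, then all channels of sample 1, ...), plus a YAML
sidecar ``<path>.yaml`` holding everything needed to interpret the bytes.

Preprocessing is a zero-phase Butterworth band-pass (default 300-3000 Hz,
order 4) applied forward-backward so spike peak times are not shifted.  The
band and order are fully configurable and filtering can be bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import signal as _signal

from .exceptions import ConfigError, CorruptionError, DataError, FormatError

GROUP_SHELL = "shell3d"
GROUP_PLANAR = "planar2d"
_VALID_GROUPS = (GROUP_SHELL, GROUP_PLANAR)

_FORMAT_TAG = "shellmea-recording-v1"


@dataclass
class ChannelMeta:
    """Metadata for one electrode channel.

    Parameters
    ----------
    channel_id : str
        Unique channel label within a recording.
    group : str
        Electrode group, ``"shell3d"`` (electrodes folded onto the organoid
        surface) or ``"planar2d"`` (flat substrate electrodes).
    distance_um : float, optional
        Scalar distance from the organoid surface, micrometers.
    rounds : list of (int, float, float)
        Stimulation-round intervals ``(round_index, start_s, end_s)``,
        non-overlapping and ordered.  Empty means a single unlabelled epoch.
    """

    channel_id: str
    group: str
    distance_um: float | None = None
    rounds: list[tuple[int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in _VALID_GROUPS:
            raise ConfigError(
                f"channel {self.channel_id!r}: group must be one of "
                f"{_VALID_GROUPS}, got {self.group!r}"
            )
        prev_end = -np.inf
        for r, start, end in self.rounds:
            if start >= end:
                raise ConfigError(f"round {r}: empty interval [{start}, {end})")
            if start < prev_end:
                raise ConfigError("round intervals overlap or are unordered")
            prev_end = end

    def round_of(self, t_s: float) -> int:
        """Round index containing time ``t_s``; -1 outside every round."""
        for r, start, end in self.rounds:
            if start <= t_s < end:
                return int(r)
        return -1


@dataclass
class Recording:
    """Multi-channel continuous voltage recording.

    ``data`` is a (n_samples, n_channels) float array in microvolts; sample
    ``k`` corresponds to time ``k / fs_hz`` seconds (0-based).
    """

    data: np.ndarray
    fs_hz: float
    channels: list[ChannelMeta]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise DataError("data must be a 2-D time x channel array")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise DataError("data must have at least 1 sample and 1 channel")
        if not np.isfinite(self.data).all():
            raise DataError("data contains non-finite values")
        if self.fs_hz <= 0:
            raise ConfigError("fs_hz must be positive")
        if len(self.channels) != self.data.shape[1]:
            raise FormatError(
                f"{len(self.channels)} channel metadata entries for "
                f"{self.data.shape[1]} data columns"
            )
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ConfigError("channel_id values must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def channel_index(self, channel_id: str) -> int:
        for i, c in enumerate(self.channels):
            if c.channel_id == channel_id:
                return i
        raise KeyError(channel_id)


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".yaml")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` as float32 binary plus a YAML sidecar ``<path>.yaml``."""
    path = Path(path)
    rec.data.astype("<f4").tofile(path)
    meta = {
        "format": _FORMAT_TAG,
        "dtype": "float32",
        "byte_order": "little",
        "layout": "time-major",
        "units": "uV",
        "fs_hz": float(rec.fs_hz),
        "n_samples": int(rec.n_samples),
        "n_channels": int(rec.n_channels),
        "channels": [
            {
                "channel_id": c.channel_id,
                "group": c.group,
                "distance_um": None if c.distance_um is None else float(c.distance_um),
                "rounds": [[int(r), float(s), float(e)] for r, s, e in c.rounds],
            }
            for c in rec.channels
        ],
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    FormatError
        Missing or inconsistent sidecar metadata.
    CorruptionError
        Binary payload length inconsistent with the sidecar.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar}")
    if not path.exists():
        raise FormatError(f"missing binary payload {path}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or meta.get("format") != _FORMAT_TAG:
        raise FormatError(f"{sidecar} is not a {_FORMAT_TAG} sidecar")
    n_channels = int(meta["n_channels"])
    n_samples = int(meta["n_samples"])
    raw = np.fromfile(path, dtype="<f4")
    if n_channels <= 0 or raw.size % n_channels != 0:
        raise CorruptionError(
            f"binary length {raw.size} not divisible by n_channels={n_channels}"
        )
    if raw.size != n_samples * n_channels:
        raise CorruptionError(
            f"binary holds {raw.size // n_channels} samples, sidecar says {n_samples}"
        )
    if len(meta["channels"]) != n_channels:
        raise FormatError(
            f"sidecar lists {len(meta['channels'])} channels, n_channels={n_channels}"
        )
    channels = [
        ChannelMeta(
            channel_id=str(c["channel_id"]),
            group=str(c["group"]),
            distance_um=c.get("distance_um"),
            rounds=[(int(r), float(s), float(e)) for r, s, e in c.get("rounds", [])],
        )
        for c in meta["channels"]
    ]
    data = raw.reshape(n_samples, n_channels).astype(np.float64)
    return Recording(data=data, fs_hz=float(meta["fs_hz"]), channels=channels)


def preprocess(
    rec: Recording,
    band_low_hz: float = 300.0,
    band_high_hz: float = 3000.0,
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward-backward (``sosfiltfilt``) so the phase
    response is identically zero and spike peak times are preserved; the
    passband edges see the squared magnitude response.  The high-pass edge
    removes DC and slow drift.

    Raises
    ------
    ConfigError
        Unless ``0 < band_low_hz < band_high_hz < fs_hz / 2``.
    """
    nyq = rec.fs_hz / 2.0
    if not (0.0 < band_low_hz < band_high_hz < nyq):
        raise ConfigError(
            f"band must satisfy 0 < low < high < fs/2, got "
            f"({band_low_hz}, {band_high_hz}) at fs {rec.fs_hz}"
        )
    if order < 1:
        raise ConfigError("filter order must be >= 1")
    sos = _signal.butter(
        order, [band_low_hz, band_high_hz], btype="bandpass", fs=rec.fs_hz, output="sos"
    )
    filtered = _signal.sosfiltfilt(sos, rec.data, axis=0)
    return Recording(data=filtered, fs_hz=rec.fs_hz, channels=list(rec.channels))
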