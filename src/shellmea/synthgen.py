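"""Synthetic multi-channel extracellular recordings with known ground truth.

The generator emulates the statistical structure that the downstream
analysis assumes: white Gaussian background noise per channel, biphasic
extracellular spikes of ~2 ms shared across channels with sub-millisecond
per-channel jitter, distance-dependent exponential amplitude attenuation
(so proximal shell electrodes see large events and distal planar electrodes
see small ones), and an optional per-round multiplicative amplitude gain
emulating a stimulation-induced trend across recording rounds.

Rounds are concatenated on a single time axis separated by a silent gap so
that time ordering equals (round, time) ordering.  Everything is driven by
one integer seed; a fixed seed yields bit-identical output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, FormatError
from .sigio import GROUP_PLANAR, GROUP_SHELL, ChannelMeta, Recording

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_template",
    "generate_recording",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic recording session.

    Defaults describe a plausible organoid-on-shell-MEA session: 20 kHz
    sampling, three shell electrodes hugging the organoid surface (10 um)
    and four planar electrodes on the substrate (150 um away), 5 uV RMS
    noise, ~2 Hz population event rate, ~2 ms biphasic spikes, and five
    recording rounds with unit gain (no stimulation trend).
    """

    duration_s: float = 60.0          # per-round active duration, seconds
    fs_hz: float = 20_000.0           # sampling rate, samples/second
    n_shell_channels: int = 3
    n_planar_channels: int = 4
    channel_distances_um: Sequence[float] | None = None  # shell first, then planar
    noise_sigma_uv: float | Sequence[float] = 5.0
    spike_rate_hz: float = 2.0        # source-event rate before refractory thinning
    refractory_ms: float = 5.0        # minimum gap between source events
    template_duration_ms: float = 2.0
    base_amplitude_uv: float = 100.0  # absolute peak amplitude at distance 0
    attenuation_length_um: float = 150.0
    jitter_ms: float = 0.5            # per-channel peak-time jitter, uniform +-
    n_rounds: int = 5
    round_gain: Sequence[float] | None = None  # len == n_rounds; default all 1.0
    inter_round_gap_s: float = 1.0    # silence between rounds
    noise_pink_fraction: float = 0.0  # 0 = white noise; in [0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise ConfigError("fs_hz and duration_s must be positive")
        if self.n_shell_channels < 0 or self.n_planar_channels < 0:
            raise ConfigError("channel counts must be non-negative")
        if self.n_channels == 0:
            raise ConfigError("at least one channel is required")
        if self.template_duration_ms <= 0:
            raise ConfigError("template_duration_ms must be positive")
        if self.duration_s * 1000.0 < self.template_duration_ms:
            raise ConfigError("duration shorter than one spike template")
        if self.refractory_ms < self.template_duration_ms:
            raise ConfigError(
                "refractory_ms must be >= template_duration_ms "
                "(source events may not overlap)"
            )
        if self.base_amplitude_uv <= 0 or self.attenuation_length_um <= 0:
            raise ConfigError("amplitude and attenuation length must be positive")
        if self.spike_rate_hz < 0:
            raise ConfigError("spike_rate_hz must be non-negative")
        if self.jitter_ms < 0:
            raise ConfigError("jitter_ms must be non-negative")
        if not 0.0 <= self.noise_pink_fraction < 1.0:
            raise ConfigError("noise_pink_fraction must be in [0, 1)")
        if self.n_rounds < 1:
            raise ConfigError("n_rounds must be >= 1")
        if self.inter_round_gap_s < 0:
            raise ConfigError("inter_round_gap_s must be non-negative")

        if self.channel_distances_um is None:
            self.channel_distances_um = [10.0] * self.n_shell_channels + [
                150.0
            ] * self.n_planar_channels
        self.channel_distances_um = [float(d) for d in self.channel_distances_um]
        if len(self.channel_distances_um) != self.n_channels:
            raise ConfigError(
                f"channel_distances_um has {len(self.channel_distances_um)} entries "
                f"for {self.n_channels} channels"
            )
        if any(d < 0 for d in self.channel_distances_um):
            raise ConfigError("channel distances must be non-negative")

        sig = self.noise_sigma_uv
        if np.isscalar(sig):
            sig = [float(sig)] * self.n_channels
        self.noise_sigma_uv = [float(s) for s in sig]
        if len(self.noise_sigma_uv) != self.n_channels:
            raise ConfigError("noise_sigma_uv length must match channel count")
        if any(s <= 0 for s in self.noise_sigma_uv):
            raise ConfigError("noise_sigma_uv must be positive")

        if self.round_gain is None:
            self.round_gain = [1.0] * self.n_rounds
        self.round_gain = [float(g) for g in self.round_gain]
        if len(self.round_gain) != self.n_rounds:
            raise ConfigError("len(round_gain) must equal n_rounds")
        if any(g <= 0 for g in self.round_gain):
            raise ConfigError("round_gain entries must be positive")

    # -- derived --------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.n_shell_channels + self.n_planar_channels

    @property
    def channel_ids(self) -> list[str]:
        return [f"e{i + 1}" for i in range(self.n_channels)]

    @property
    def channel_groups(self) -> list[str]:
        return [GROUP_SHELL] * self.n_shell_channels + [
            GROUP_PLANAR
        ] * self.n_planar_channels

    @property
    def total_duration_s(self) -> float:
        return self.n_rounds * self.duration_s + (self.n_rounds - 1) * self.inter_round_gap_s

    def round_intervals(self) -> list[tuple[int, float, float]]:
        """(round_index, start_s, end_s) for each round on the global axis."""
        stride = self.duration_s + self.inter_round_gap_s
        return [
            (r, r * stride, r * stride + self.duration_s)
            for r in range(self.n_rounds)
        ]

    # -- config file round trip -----------------------------------------

    _FIELDS = (
        "duration_s fs_hz n_shell_channels n_planar_channels channel_distances_um "
        "noise_sigma_uv spike_rate_hz refractory_ms template_duration_ms "
        "base_amplitude_uv attenuation_length_um jitter_ms n_rounds round_gain "
        "inter_round_gap_s noise_pink_fraction seed"
    ).split()

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {k: getattr(self, k) for k in self._FIELDS}
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SimConfig":
        """Load from a YAML file path or a YAML string; unknown keys rejected."""
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        doc = yaml.safe_load(io.StringIO(text))
        if not isinstance(doc, dict):
            raise ConfigError("simulation config must be a YAML mapping")
        unknown = set(doc) - set(cls._FIELDS)
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass
class GroundTruth:
    """True source events behind a synthetic recording.

    ``event_times_s`` are source-event times on the global (concatenated)
    axis, strictly increasing with gaps >= the refractory period.
    ``per_channel_amplitude_uv`` is an (n_events, n_channels) matrix of
    injected absolute peak amplitudes, non-increasing with channel distance
    for each event.  Per-channel jitter means the realized peak on channel
    ``c`` sits within +-jitter of the source time.
    """

    event_times_s: np.ndarray
    per_channel_amplitude_uv: np.ndarray
    round_index: np.ndarray
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=np.float64)
        self.per_channel_amplitude_uv = np.atleast_2d(
            np.asarray(self.per_channel_amplitude_uv, dtype=np.float64)
        )
        self.round_index = np.asarray(self.round_index, dtype=np.int64)

    @property
    def n_events(self) -> int:
        return self.event_times_s.size

    @property
    def n_channels(self) -> int:
        return 0 if self.n_events == 0 else self.per_channel_amplitude_uv.shape[1]


def make_template(fs_hz: float, duration_ms: float = 2.0) -> np.ndarray:
    """Biphasic spike template: dominant negative lobe, smaller positive lobe.

    The analytic form is a difference of two Gaussians in normalized time
    tapered by a half-sine window, which pins both endpoints to exactly
    zero.  The relative weight of the positive lobe is chosen so the two
    lobe areas roughly balance (a near-zero-integral waveform, as real
    extracellular spikes are).  Peak absolute value is normalized to 1.

    Returns ``round(fs_hz * duration_ms / 1000)`` samples.
    """
    if duration_ms <= 0:
        raise ConfigError("duration_ms must be positive")
    if fs_hz <= 0:
        raise ConfigError("fs_hz must be positive")
    n = int(round(fs_hz * duration_ms / 1000.0))
    if n < 3:
        raise ConfigError(
            f"template of {n} sample(s) is degenerate; increase duration or fs"
        )
    u = np.linspace(0.0, 1.0, n)
    core = -np.exp(-(((u - 0.38) / 0.10) ** 2)) + 0.58 * np.exp(
        -(((u - 0.66) / 0.18) ** 2)
    )
    w = core * np.sin(np.pi * u)
    w /= np.max(np.abs(w))
    w[0] = 0.0
    w[-1] = 0.0
    return w


def _poisson_times(
    rng: np.random.Generator, rate_hz: float, lo_s: float, hi_s: float, min_gap_s: float
) -> np.ndarray:
    """Homogeneous Poisson event times on [lo, hi) thinned to a minimum gap."""
    if rate_hz <= 0 or hi_s <= lo_s:
        return np.empty(0)
    n_cand = rng.poisson(rate_hz * (hi_s - lo_s))
    cand = np.sort(rng.uniform(lo_s, hi_s, size=n_cand))
    kept: list[float] = []
    last = -np.inf
    for t in cand:
        if t - last >= min_gap_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def generate_recording(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Simulate one session; identical config and seed give identical output.

    Source events are a Poisson process per round, thinned to the refractory
    gap and kept clear of round edges so every injected waveform fits.  The
    injected absolute amplitude on channel ``c`` for an event in round ``r``
    is ``base_amplitude_uv * exp(-distance_c / attenuation_length_um) *
    round_gain[r]``; the waveform lands at the source time plus a uniform
    per-channel jitter in ``+-jitter_ms``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs_hz
    n_samples = int(round(config.total_duration_s * fs))
    n_ch = config.n_channels

    sigma = np.asarray(config.noise_sigma_uv)
    data = rng.standard_normal((n_samples, n_ch)) * sigma
    if config.noise_pink_fraction > 0.0:
        pink = _pink_noise(rng, n_samples, n_ch)
        f = config.noise_pink_fraction
        data = (np.sqrt(1 - f**2) * data / sigma + f * pink) * sigma

    template = make_template(fs, config.template_duration_ms)
    peak_offset = int(np.argmax(np.abs(template)))
    tlen = template.size

    # keep events clear of round edges: template extent + worst-case jitter
    margin_s = config.template_duration_ms / 1000.0 + config.jitter_ms / 1000.0

    times: list[np.ndarray] = []
    rounds: list[np.ndarray] = []
    for r, start, end in config.round_intervals():
        t = _poisson_times(
            rng,
            config.spike_rate_hz,
            start + margin_s,
            end - margin_s,
            config.refractory_ms / 1000.0,
        )
        times.append(t)
        rounds.append(np.full(t.size, r, dtype=np.int64))
    event_times = np.concatenate(times) if times else np.empty(0)
    round_index = np.concatenate(rounds) if rounds else np.empty(0, dtype=np.int64)

    dist = np.asarray(config.channel_distances_um)
    atten = np.exp(-dist / config.attenuation_length_um)
    gains = np.asarray(config.round_gain)
    amplitudes = (
        config.base_amplitude_uv * atten[None, :] * gains[round_index][:, None]
        if event_times.size
        else np.empty((0, n_ch))
    )

    jitter_s = config.jitter_ms / 1000.0
    for e, t0 in enumerate(event_times):
        jit = rng.uniform(-jitter_s, jitter_s, size=n_ch) if jitter_s > 0 else np.zeros(n_ch)
        for c in range(n_ch):
            start_idx = int(round((t0 + jit[c]) * fs)) - peak_offset
            data[start_idx : start_idx + tlen, c] += amplitudes[e, c] * template

    intervals = config.round_intervals()
    channels = [
        ChannelMeta(
            channel_id=cid,
            group=grp,
            distance_um=d,
            rounds=intervals,
        )
        for cid, grp, d in zip(
            config.channel_ids, config.channel_groups, config.channel_distances_um
        )
    ]
    rec = Recording(data=data, fs_hz=fs, channels=channels)
    gt = GroundTruth(
        event_times_s=event_times,
        per_channel_amplitude_uv=amplitudes,
        round_index=round_index,
        channel_ids=config.channel_ids,
    )
    return rec, gt


def _pink_noise(rng: np.random.Generator, n_samples: int, n_ch: int) -> np.ndarray:
    """Unit-variance 1/f-shaped noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_samples, n_ch))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale[:, None], n=n_samples, axis=0)
    shaped /= shaped.std(axis=0, keepdims=True)
    return shaped


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """CSV with columns event_id, time_s, round_index, amp_uv_<channel>."""
    cols = {"event_id": np.arange(gt.n_events, dtype=np.int64)}
    cols["time_s"] = gt.event_times_s
    cols["round_index"] = gt.round_index
    ids = gt.channel_ids or [f"e{i + 1}" for i in range(gt.per_channel_amplitude_uv.shape[1] if gt.n_events else 0)]
    for c, cid in enumerate(ids):
        cols[f"amp_uv_{cid}"] = (
            gt.per_channel_amplitude_uv[:, c] if gt.n_events else np.empty(0)
        )
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    required = {"event_id", "time_s", "round_index"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path} lacks ground-truth columns {sorted(required)}")
    amp_cols = [c for c in df.columns if c.startswith("amp_uv_")]
    amps = df[amp_cols].to_numpy() if len(df) else np.empty((0, len(amp_cols)))
    return GroundTruth(
        event_times_s=df["time_s"].to_numpy(),
        per_channel_amplitude_uv=amps,
        round_index=df["round_index"].to_numpy(),
        channel_ids=[c.removeprefix("amp_uv_") for c in amp_cols],
    )
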