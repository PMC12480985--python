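"""Synthetic multichannel extracellular recordings with ground truth.

Emulates a 16-channel intracortical probe sampled at 24.414 kHz whose
hardware band-passes the signal into the 300-3000 Hz spike band.  Each
configured unit fires a gamma(shape 2) renewal process with a hard
refractory floor and stamps a biphasic, negative-leading 1.6 ms template
onto its channel.  Two artifact classes are inserted on demand:
coincident-motion artifacts (simultaneous sub-threshold-window deflections
on >= 15 channels) and over-range artifacts (single-channel deflections
beyond +/-500 uV).  Every inserted event is listed in the ground-truth
table with its class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from imequant.ephys import BAND_HZ, RecordingBlock

__all__ = [
    "UnitSpec",
    "RecordingConfig",
    "GroundTruth",
    "spike_template",
    "gen_recording",
    "default_recording_config",
]

TEMPLATE_MS = 1.6  # canonical biphasic template duration


@dataclass(frozen=True)
class UnitSpec:
    """One ground-truth unit: where it lives, how fast it fires, how big it is."""

    channel: int
    rate_hz: float
    amplitude_uv: float  # |negative peak| of the template
    shape_id: int = 0


@dataclass
class RecordingConfig:
    n_channels: int = 16
    fs: float = 24414.0
    duration: float = 5.0  # s
    units: list[UnitSpec] = field(default_factory=list)
    noise_sigma: float = 7.5  # uV RMS of the band-limited noise
    pink_fraction: float = 0.3  # share of noise power from a 1/f component
    motion_artifact_rate: float = 0.1  # events/s, coincident across >= 15 channels
    overrange_artifact_rate: float = 0.05  # events/s, |amplitude| > 500 uV
    refractory_ms: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if not 0.0 <= self.pink_fraction <= 1.0:
            raise ValueError("pink_fraction must lie in [0, 1]")
        if self.refractory_ms <= 0:
            raise ValueError("refractory must be positive")
        for u in self.units:
            if u.amplitude_uv <= 0:
                raise ValueError("unit amplitudes must be positive")
            if not 0 <= u.channel < self.n_channels:
                raise ValueError(f"unit channel {u.channel} out of range")
        if self.duration * 1e3 < TEMPLATE_MS:
            raise ValueError("duration too short to hold one spike template")


@dataclass
class GroundTruth:
    """Every inserted event: spikes (with unit id) and both artifact classes."""

    events: pd.DataFrame  # columns: t_index, channel, kind, unit_id, amplitude_uv


def spike_template(fs: float, amplitude_uv: float, shape_id: int = 0) -> np.ndarray:
    """Biphasic negative-leading action-potential template, 1.6 ms long.

    A sharp negative trough followed by a slower positive overshoot;
    ``shape_id`` perturbs the lobe widths so distinct units are separable in
    waveform space.  The negative peak equals -amplitude_uv exactly.
    """
    n = int(round(TEMPLATE_MS * 1e-3 * fs))
    t = np.linspace(0, 1, n)
    w_neg = 0.10 + 0.03 * (shape_id % 3)
    w_pos = 0.28 + 0.05 * (shape_id % 2)
    c_neg = 0.25
    c_pos = c_neg + 2.2 * w_neg
    wave = -np.exp(-((t - c_neg) ** 2) / (2 * w_neg**2)) + 0.4 * np.exp(
        -((t - c_pos) ** 2) / (2 * w_pos**2)
    )
    wave *= amplitude_uv / np.abs(wave.min())
    return wave


def _gamma_spike_times(
    rng: np.random.Generator, rate_hz: float, duration: float, refractory_s: float
) -> np.ndarray:
    """Renewal process with gamma(shape 2) ISIs and a hard refractory floor."""
    if rate_hz <= 0:
        return np.empty(0)
    # Mean ISI above the floor must give the target rate overall.
    mean_isi = 1.0 / rate_hz
    free = max(mean_isi - refractory_s, 1e-4)
    n_guess = int(rate_hz * duration * 2 + 20)
    isis = refractory_s + rng.gamma(shape=2.0, scale=free / 2.0, size=n_guess)
    times = np.cumsum(isis) - isis[0] + rng.uniform(0, mean_isi)
    return times[times < duration]


def _band_limited_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    sigma: float,
    pink_fraction: float,
) -> np.ndarray:
    """Gaussian + pink noise, band-passed 300-3000 Hz, rescaled to RMS ``sigma``.

    ``sigma`` refers to the post-filter RMS, so downstream SNR truths are
    interpretable directly.
    """
    if sigma == 0:
        return np.zeros((n_channels, n_samples), dtype=np.float32)
    white = rng.standard_normal((n_channels, n_samples))
    if pink_fraction > 0:
        # Shape white noise to 1/f in the frequency domain.
        spec = np.fft.rfft(rng.standard_normal((n_channels, n_samples)), axis=1)
        freqs = np.fft.rfftfreq(n_samples, 1 / fs)
        with np.errstate(divide="ignore"):
            scale = np.where(freqs > 0, 1.0 / np.sqrt(np.maximum(freqs, 1e-12)), 0.0)
        pink = np.fft.irfft(spec * scale, n=n_samples, axis=1)
        pink /= pink.std(axis=1, keepdims=True)
        noise = np.sqrt(1 - pink_fraction) * white + np.sqrt(pink_fraction) * pink
    else:
        noise = white
    sos = signal.butter(4, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    noise = signal.sosfiltfilt(sos, noise, axis=1)
    noise *= sigma / noise.std(axis=1, keepdims=True)
    return noise.astype(np.float32)


def gen_recording(config: RecordingConfig) -> tuple[RecordingBlock, GroundTruth]:
    """Generate one recording block plus its complete ground truth.

    Deterministic: the same config (including seed) yields bit-identical
    samples and truth tables.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration * config.fs))
    samples = _band_limited_noise(
        rng, config.n_channels, n_samples, config.fs,
        config.noise_sigma, config.pink_fraction,
    )

    rows: list[dict] = []

    # Ground-truth units.
    for uid, unit in enumerate(config.units):
        template = spike_template(config.fs, unit.amplitude_uv, unit.shape_id)
        peak_off = int(np.argmin(template))
        times = _gamma_spike_times(
            rng, unit.rate_hz, config.duration, config.refractory_ms * 1e-3
        )
        for t in times:
            start = int(round(t * config.fs))
            end = start + len(template)
            if end > n_samples:
                continue
            samples[unit.channel, start:end] += template
            rows.append(
                dict(t_index=start + peak_off, channel=unit.channel, kind="spike",
                     unit_id=uid, amplitude_uv=unit.amplitude_uv)
            )

    # Coincident motion artifacts: the same deflection on >= 15 channels
    # within 0.2 ms — wide enough in amplitude to cross detection, below the
    # over-range limit so only the coincidence rule can catch them.
    n_motion = rng.poisson(config.motion_artifact_rate * config.duration)
    art_template = spike_template(config.fs, 1.0, shape_id=0)
    max_jitter = int(round(0.2e-3 * config.fs))
    for _ in range(n_motion):
        start = rng.integers(0, max(n_samples - len(art_template) - max_jitter, 1))
        n_hit = int(rng.integers(15, config.n_channels + 1))
        hit = rng.choice(config.n_channels, size=min(n_hit, config.n_channels), replace=False)
        amp = rng.uniform(80.0, 300.0)
        for ch in hit:
            jitter = int(rng.integers(0, max_jitter + 1))
            s = start + jitter
            samples[ch, s:s + len(art_template)] += art_template * amp
            rows.append(
                dict(t_index=s + int(np.argmin(art_template)), channel=int(ch),
                     kind="motion_artifact", unit_id=-1, amplitude_uv=amp)
            )

    # Over-range artifacts: single-channel events beyond |500| uV.
    n_over = rng.poisson(config.overrange_artifact_rate * config.duration)
    for _ in range(n_over):
        start = int(rng.integers(0, max(n_samples - len(art_template), 1)))
        ch = int(rng.integers(0, config.n_channels))
        amp = rng.uniform(600.0, 1500.0)
        samples[ch, start:start + len(art_template)] += art_template * amp
        rows.append(
            dict(t_index=start + int(np.argmin(art_template)), channel=ch,
                 kind="overrange_artifact", unit_id=-1, amplitude_uv=amp)
        )

    truth = pd.DataFrame(
        rows, columns=["t_index", "channel", "kind", "unit_id", "amplitude_uv"]
    ).sort_values(["t_index", "channel"], kind="stable").reset_index(drop=True)
    block = RecordingBlock(samples=samples, fs=config.fs, filtered=True)
    return block, GroundTruth(events=truth)


def default_recording_config(seed: int = 0, duration: float = 5.0) -> RecordingConfig:
    """The study-condition defaults: 16 channels, 8 of them carrying a unit.

    Unit amplitudes span 90-200 uV over 10 uV band-limited noise — the
    amplitude range where chronic cortical recordings hold well-isolated
    units — with firing rates between 6 and 15 Hz.
    """
    units = [
        UnitSpec(channel=0, rate_hz=8.0, amplitude_uv=120.0, shape_id=0),
        UnitSpec(channel=2, rate_hz=12.0, amplitude_uv=160.0, shape_id=1),
        UnitSpec(channel=4, rate_hz=6.0, amplitude_uv=95.0, shape_id=2),
        UnitSpec(channel=6, rate_hz=15.0, amplitude_uv=200.0, shape_id=0),
        UnitSpec(channel=8, rate_hz=10.0, amplitude_uv=140.0, shape_id=1),
        UnitSpec(channel=10, rate_hz=7.0, amplitude_uv=110.0, shape_id=2),
        UnitSpec(channel=12, rate_hz=9.0, amplitude_uv=180.0, shape_id=0),
        UnitSpec(channel=14, rate_hz=11.0, amplitude_uv=130.0, shape_id=1),
    ]
    return RecordingConfig(units=units, duration=duration, seed=seed)
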