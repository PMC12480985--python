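"""Single-unit detection, QC and per-channel metrics for multichannel recordings.

The stage-1 pipeline, in fixed order:

    common-median reference -> -4*sigma detection -> over-range rejection
    (|peak| > 500 uV) -> coincidence rejection (> 14 channels within 0.5 ms)
    -> waveform extraction -> PCA + k-means clustering -> Vpp validation
    (units under 40 uV discarded) -> per-channel metrics.

Definitions used throughout: sigma is the spike-robust MAD estimate
median(|x|)/0.6745 of the referenced trace; Vpp is the peak-to-peak voltage
of a unit's mean waveform; noise is the RMS of the spike-excised trace;
SNR = Vpp / noise; spike rate is the inverse of the median interspike
interval.  An outlier pass on pooled unit SNRs (robust location/scale with
FDR-controlled flagging at Q = 5%) mirrors the ROUT procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "RecordingBlock",
    "SpikeEvent",
    "SortedUnit",
    "ChannelMetrics",
    "common_median_reference",
    "bandpass_filter",
    "estimate_sigma",
    "detect_spikes",
    "reject_overrange",
    "reject_coincident",
    "extract_waveforms",
    "cluster_units",
    "validate_units",
    "noise_rms",
    "spike_rate",
    "rout_filter",
    "channel_metrics",
    "process_recording",
]

# Thresholds of the QC chain (units noted per value).
DETECT_K = 4.0  # detection threshold, multiples of sigma (negative-going)
OVERRANGE_UV = 500.0  # |peak| above this is an abnormal event, uV
COINCIDENT_CHANNELS = 14  # events spanning MORE than this many channels are artifacts
COINCIDENCE_WINDOW_MS = 0.5  # total width of the simultaneity window, ms
VPP_MIN_UV = 40.0  # units with Vpp strictly below this are non-putative, uV
LOCKOUT_MS = 1.0  # per-channel detection dead time, ms
PRE_MS, POST_MS = 0.6, 1.8  # waveform window around the negative peak, ms
EXCISION_MS = 2.4  # total spike-excision width for noise RMS, ms
ROUT_Q = 5.0  # FDR (%) for the SNR outlier pass
BAND_HZ = (300.0, 3000.0)  # spike band of the recording hardware


@dataclass
class RecordingBlock:
    """Multichannel voltage samples in microvolts, channel-major."""

    samples: np.ndarray  # (n_channels, n_samples), uV
    fs: float  # Hz
    channel_ids: list[int] | None = None
    filtered: bool = True  # whether the spike-band filter was already applied

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float32))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")
        if self.channel_ids is None:
            self.channel_ids = list(range(self.samples.shape[0]))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class SpikeEvent:
    channel: int
    t_index: int
    peak_amp: float  # uV, signed (negative for negative-going spikes)


@dataclass
class SortedUnit:
    channel: int
    spike_indices: np.ndarray
    mean_waveform: np.ndarray
    cluster_id: int

    @property
    def vpp(self) -> float:
        return float(self.mean_waveform.max() - self.mean_waveform.min())

    @property
    def n_spikes(self) -> int:
        return len(self.spike_indices)


@dataclass
class ChannelMetrics:
    channel: int
    n_units: int
    vpp_mean: float
    noise_rms: float
    snr: float
    spike_rate: float
    active: bool


def common_median_reference(block: RecordingBlock) -> RecordingBlock:
    """Subtract the across-channel median at every sample (common-mode removal)."""
    if block.n_channels < 2:
        raise ValueError("common-median reference needs at least 2 channels")
    ref = np.median(block.samples, axis=0, keepdims=True)
    return RecordingBlock(
        samples=block.samples - ref,
        fs=block.fs,
        channel_ids=list(block.channel_ids),
        filtered=block.filtered,
    )


def bandpass_filter(block: RecordingBlock, band: tuple[float, float] = BAND_HZ) -> RecordingBlock:
    """Zero-phase 4th-order Butterworth band-pass into the spike band."""
    sos = signal.butter(4, band, btype="bandpass", fs=block.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, block.samples, axis=1).astype(np.float32)
    return RecordingBlock(filtered, block.fs, list(block.channel_ids), filtered=True)


def estimate_sigma(trace: np.ndarray) -> float:
    """Spike-robust noise sigma: median(|x|) / 0.6745."""
    trace = np.asarray(trace)
    if trace.size == 0:
        raise ValueError("empty trace")
    return float(np.median(np.abs(trace)) / 0.6745)


def detect_spikes(
    trace: np.ndarray,
    sigma: float,
    fs: float,
    k: float = DETECT_K,
    lockout_ms: float = LOCKOUT_MS,
    channel: int = 0,
) -> list[SpikeEvent]:
    """Negative-threshold spike detection at -k*sigma with a lockout period.

    Each maximal run of samples below the threshold contributes one event at
    its local minimum; events closer than the lockout keep only the earlier
    one.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    trace = np.asarray(trace, dtype=float)
    thr = -k * sigma
    below = trace < thr
    if not below.any():
        return []
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        ends = np.r_[ends, len(trace)]
    lockout = int(round(lockout_ms * 1e-3 * fs))
    events: list[SpikeEvent] = []
    last_idx = -lockout - 1
    for s, e in zip(starts, ends):
        seg = trace[s:e]
        idx = s + int(np.argmin(seg))
        if idx - last_idx <= lockout:
            continue
        events.append(SpikeEvent(channel=channel, t_index=idx, peak_amp=float(trace[idx])))
        last_idx = idx
    return events


def reject_overrange(events: list[SpikeEvent], limit_uv: float = OVERRANGE_UV) -> list[SpikeEvent]:
    """Drop events whose |peak| strictly exceeds the over-range limit (500 uV)."""
    return [ev for ev in events if abs(ev.peak_amp) <= limit_uv]


def reject_coincident(
    events: list[SpikeEvent],
    fs: float,
    max_channels: int = COINCIDENT_CHANNELS,
    window_ms: float = COINCIDENCE_WINDOW_MS,
) -> list[SpikeEvent]:
    """Drop motion artifacts: events simultaneous across > ``max_channels`` channels.

    An event is removed when events on strictly more than ``max_channels``
    distinct channels fall within +/- window/2 of its time.
    """
    if not events:
        return []
    half = window_ms * 1e-3 * fs / 2.0
    times = np.array([ev.t_index for ev in events], dtype=float)
    chans = np.array([ev.channel for ev in events])
    order = np.argsort(times)
    times_s, chans_s = times[order], chans[order]
    doomed = np.zeros(len(events), dtype=bool)
    lo = np.searchsorted(times_s, times_s - half, side="left")
    hi = np.searchsorted(times_s, times_s + half, side="right")
    for i in range(len(events)):
        if hi[i] - lo[i] <= max_channels:
            continue
        group = slice(lo[i], hi[i])
        if len(np.unique(chans_s[group])) > max_channels:
            doomed[order[lo[i]:hi[i]]] = True  # map sorted positions back to input order
    return [ev for ev, d in zip(events, doomed) if not d]


def extract_waveforms(
    trace: np.ndarray,
    events: list[SpikeEvent],
    fs: float,
    pre_ms: float = PRE_MS,
    post_ms: float = POST_MS,
) -> tuple[np.ndarray, list[SpikeEvent]]:
    """Peak-aligned snippets (pre_ms before to post_ms after the trough).

    Events whose window overruns the trace are dropped.  Returns the snippet
    matrix and the surviving events in order.
    """
    pre = int(round(pre_ms * 1e-3 * fs))
    post = int(round(post_ms * 1e-3 * fs))
    snippets, kept = [], []
    n = len(trace)
    for ev in events:
        s, e = ev.t_index - pre, ev.t_index + post + 1
        if s < 0 or e > n:
            continue
        snippets.append(trace[s:e])
        kept.append(ev)
    if not snippets:
        return np.empty((0, pre + post + 1)), []
    return np.asarray(snippets, dtype=float), kept


MIN_SNIPPETS_FOR_SPLIT = 8
SILHOUETTE_MIN = 0.5
KMAX = 5
_CLUSTER_SEED = 1234  # fixed: clustering must be reproducible run-to-run


def cluster_units(
    snippets: np.ndarray, events: list[SpikeEvent], channel: int
) -> list[SortedUnit]:
    """Sort one channel's snippets into units via PCA(2) + k-means.

    k runs 1..5; the k >= 2 solution with the best mean silhouette wins if
    that silhouette reaches 0.5, otherwise everything is one unit.  Fewer
    than 8 snippets always form a single unit.
    """
    if len(snippets) == 0:
        return []
    indices = np.array([ev.t_index for ev in events])

    def build(labels: np.ndarray) -> list[SortedUnit]:
        units = []
        for cid in np.unique(labels):
            sel = labels == cid
            units.append(
                SortedUnit(
                    channel=channel,
                    spike_indices=np.sort(indices[sel]),
                    mean_waveform=snippets[sel].mean(axis=0),
                    cluster_id=int(cid),
                )
            )
        return units

    n = len(snippets)
    if n < MIN_SNIPPETS_FOR_SPLIT:
        return build(np.zeros(n, dtype=int))

    feats = PCA(n_components=2, random_state=_CLUSTER_SEED).fit_transform(snippets)
    best_labels, best_score = None, -1.0
    for k in range(2, min(KMAX, n - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=_CLUSTER_SEED)
        labels = km.fit_predict(feats)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(feats, labels)
        if score > best_score:
            best_labels, best_score = labels, score
    if best_labels is None or best_score < SILHOUETTE_MIN:
        return build(np.zeros(n, dtype=int))
    return build(best_labels)


def validate_units(units: list[SortedUnit], vpp_min: float = VPP_MIN_UV) -> list[SortedUnit]:
    """Discard non-putative units with Vpp strictly below 40 uV."""
    return [u for u in units if u.vpp >= vpp_min]


def noise_rms(
    trace: np.ndarray,
    spike_indices: np.ndarray,
    fs: float,
    excision_ms: float = EXCISION_MS,
) -> float:
    """RMS of the trace with +/- excision/2 around every spike removed."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    keep = np.ones(trace.size, dtype=bool)
    half = int(round(excision_ms * 1e-3 * fs / 2.0))
    for idx in np.asarray(spike_indices, dtype=int):
        keep[max(0, idx - half): idx + half + 1] = False
    if not keep.any():
        raise ValueError("spike excision removed every sample; cannot estimate noise")
    return float(np.sqrt(np.mean(trace[keep] ** 2)))


def spike_rate(spike_indices: np.ndarray, fs: float) -> float:
    """Firing rate as the inverse of the median interspike interval (Hz).

    Returns NaN when fewer than 2 spikes make the ISI undefined; such units
    are excluded from rate averages.
    """
    idx = np.asarray(spike_indices, dtype=float)
    if idx.size < 2:
        return float("nan")
    isis = np.diff(np.sort(idx)) / fs
    med = float(np.median(isis))
    return 1.0 / med if med > 0 else float("nan")


def rout_filter(values: np.ndarray, q_percent: float = ROUT_Q) -> tuple[np.ndarray, np.ndarray]:
    """Robust outlier removal with FDR control (ROUT-style) on a 1-D sample.

    Location is the median; the robust standard deviation of the residuals
    (RSDR) is the 68.27th percentile of |residuals| scaled by N/(N-1).
    Each residual gets a two-sided p-value from the t distribution with
    N-1 df, and a Benjamini-Hochberg pass at rate Q flags the most extreme
    residuals.  Returns (kept mask, flagged mask); fewer than 3 values are
    all kept.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    flagged = np.zeros(n, dtype=bool)
    if n < 3:
        return ~flagged, flagged
    resid = values - np.median(values)
    abs_res = np.abs(resid)
    rsdr = np.percentile(abs_res, 68.27) * n / (n - 1)
    if rsdr == 0:
        return ~flagged, flagged
    tvals = abs_res / rsdr
    pvals = 2.0 * stats.t.sf(tvals, df=n - 1)
    order = np.argsort(pvals)  # most extreme first
    q = q_percent / 100.0
    thresh_rank = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= q * rank / n:
            thresh_rank = rank
    flagged[order[:thresh_rank]] = True
    return ~flagged, flagged


def channel_metrics(
    units: list[SortedUnit],
    trace: np.ndarray,
    fs: float,
    all_spike_indices: np.ndarray | None = None,
) -> ChannelMetrics:
    """Per-channel summary over its validated units.

    ``all_spike_indices`` (every detected event on the channel, including
    those not assigned to surviving units) controls the noise excision; it
    defaults to the union of unit spikes.
    """
    channel = units[0].channel if units else -1
    if not units:
        return ChannelMetrics(channel=channel, n_units=0, vpp_mean=float("nan"),
                              noise_rms=float("nan"), snr=float("nan"),
                              spike_rate=float("nan"), active=False)
    if all_spike_indices is None:
        all_spike_indices = np.concatenate([u.spike_indices for u in units])
    noise = noise_rms(trace, all_spike_indices, fs)
    vpp_mean = float(np.mean([u.vpp for u in units]))
    rates = [spike_rate(u.spike_indices, fs) for u in units]
    rates = [r for r in rates if np.isfinite(r)]
    return ChannelMetrics(
        channel=channel,
        n_units=len(units),
        vpp_mean=vpp_mean,
        noise_rms=noise,
        snr=vpp_mean / noise if noise > 0 else float("inf"),
        spike_rate=float(np.mean(rates)) if rates else float("nan"),
        active=True,
    )


def process_recording(
    block: RecordingBlock,
    q_rout: float = ROUT_Q,
    apply_bandpass: bool | None = None,
) -> tuple[list[ChannelMetrics], list[SortedUnit], pd.DataFrame]:
    """Run the full stage-1 chain on one recording.

    Returns per-channel metrics, the validated units, and a tidy unit table
    (channel, cluster, n_spikes, vpp_uV, snr, spike_rate_hz, rout_outlier).
    The unit-level SNR outlier pass (ROUT at ``q_rout``) excludes flagged
    units from the channel averages.  ``apply_bandpass=None`` filters only
    when the block is marked unfiltered.
    """
    if apply_bandpass is None:
        apply_bandpass = not block.filtered
    if apply_bandpass:
        block = bandpass_filter(block)
    logger.info(
        "QC thresholds: -%g sigma detection, %g uV over-range, >%d channel coincidence "
        "(%g ms), %g uV Vpp floor, ROUT Q=%g%%",
        DETECT_K, OVERRANGE_UV, COINCIDENT_CHANNELS, COINCIDENCE_WINDOW_MS, VPP_MIN_UV, q_rout,
    )
    ref = common_median_reference(block)

    all_events: list[SpikeEvent] = []
    for ci in range(ref.n_channels):
        trace = ref.samples[ci]
        sigma = estimate_sigma(trace)
        if sigma <= 0:
            continue
        all_events.extend(detect_spikes(trace, sigma, ref.fs, channel=ci))
    all_events = reject_overrange(all_events)
    all_events = reject_coincident(all_events, ref.fs)

    per_channel_events: dict[int, list[SpikeEvent]] = {}
    for ev in all_events:
        per_channel_events.setdefault(ev.channel, []).append(ev)

    units: list[SortedUnit] = []
    detected_idx: dict[int, np.ndarray] = {}
    for ci, events in per_channel_events.items():
        trace = ref.samples[ci]
        snippets, kept = extract_waveforms(trace, events, ref.fs)
        detected_idx[ci] = np.array([ev.t_index for ev in kept], dtype=int)
        units.extend(validate_units(cluster_units(snippets, kept, channel=ci)))

    # Unit-level SNR (unit Vpp over its channel's noise), then the outlier pass.
    noise_by_channel = {
        ci: noise_rms(ref.samples[ci], detected_idx.get(ci, np.empty(0, int)), ref.fs)
        for ci in {u.channel for u in units}
    }
    snrs = np.array(
        [u.vpp / noise_by_channel[u.channel] if noise_by_channel[u.channel] > 0 else np.inf
         for u in units]
    )
    if len(units):
        _, flagged = rout_filter(snrs, q_percent=q_rout)
    else:
        flagged = np.zeros(0, dtype=bool)

    unit_table = pd.DataFrame(
        {
            "channel": [u.channel for u in units],
            "cluster": [u.cluster_id for u in units],
            "n_spikes": [u.n_spikes for u in units],
            "vpp_uV": [u.vpp for u in units],
            "snr": snrs,
            "spike_rate_hz": [spike_rate(u.spike_indices, ref.fs) for u in units],
            "rout_outlier": flagged,
        }
    )

    surviving = [u for u, f in zip(units, flagged) if not f]
    metrics = []
    for ci in range(ref.n_channels):
        ch_units = [u for u in surviving if u.channel == ci]
        m = channel_metrics(ch_units, ref.samples[ci], ref.fs,
                            all_spike_indices=detected_idx.get(ci))
        m.channel = ci
        metrics.append(m)
    return metrics, surviving, unit_table
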