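"""Spike-wave discharge (SWD) detection from chronic mouse EEG.

The detector works in stages on a multichannel recording:

1. zero-phase Butterworth band-pass (default 0.5-400 Hz, order 3);
2. division into non-overlapping 250-ms epochs;
3. per-epoch features on every EEG channel: RMS, spike density (count of
   sharp transients) and the frequency band ratio FBR, the summed FFT
   magnitude in an upper band (100-300 Hz) divided by that in a lower band
   (0.5-80 Hz);
4. an epoch becomes a candidate when it exceeds the thresholds for *all*
   features on at least one EEG channel;
5. contiguous candidate epochs are merged into episodes; per episode the
   spike peaks are located and duration is measured as the time difference
   between the first and last peaks;
6. episodes are grouped into clusters (>= 5 episodes, inter-episode
   interval <= 60 s) and summarized as per-hour circadian rate profiles.

Thresholds default to per-recording percentiles of the feature
distributions (self-calibrating across animals and noise levels) and can
be overridden with explicit values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .core import TimeSeriesRecording

logger = logging.getLogger(__name__)

#: Feature columns every epoch-feature table must carry.
FEATURE_COLUMNS = ("epoch_index", "start_s", "channel", "rms", "spike_density", "fbr")


class UndefinedRatioError(ValueError):
    """Raised when the FBR denominator band carries no power."""


@dataclass(frozen=True)
class FBRConfig:
    """Frequency bounds (Hz) of the band ratio: upper band [f1, f2], lower [f3, f4]."""

    f1: float = 100.0
    f2: float = 300.0
    f3: float = 0.5
    f4: float = 80.0

    def __post_init__(self) -> None:
        if not (self.f1 < self.f2 and self.f3 < self.f4):
            raise ValueError("FBR bands must be ordered: f1 < f2 and f3 < f4")


@dataclass(frozen=True)
class SpikeParams:
    """Spike operator: peaks of |signal| above ``mad_multiplier`` robust SDs.

    The robust SD is ``1.4826 * median(|x - median(x)|)`` of the band-passed
    channel, so the threshold adapts to per-animal amplitude scale. Peaks
    closer than ``min_separation_ms`` are counted once; 40 ms matches the
    shortest spacing of 3-6 Hz spike-wave cycles with margin.
    """

    mad_multiplier: float = 5.0
    min_separation_ms: float = 40.0


@dataclass(frozen=True)
class ThresholdPolicy:
    """Percentile-based self-calibrating thresholds for candidate detection.

    ``spike_density_min`` defaults to 1: at the slow end of the 3-6 Hz
    band the inter-spike interval (up to 333 ms) exceeds the 250-ms epoch,
    so no epoch of a 3-Hz discharge can ever hold two spikes.
    """

    rms_percentile: float = 99.0
    fbr_percentile: float = 95.0
    spike_density_min: int = 1


@dataclass
class SWDEpisode:
    """One detected spike-wave discharge."""

    onset_s: float
    offset_s: float
    duration_s: float  # time from first to last spike peak
    spike_count: int
    spike_rate_hz: float
    channel: str  # channel on which peaks were measured (max RMS)
    channels: list[str] = field(default_factory=list)
    state: str | None = None
    source: str = "threshold"
    cluster_id: int | None = None
    first_peak_s: float | None = None
    last_peak_s: float | None = None


@dataclass
class SWDCluster:
    """A run of >= 5 episodes with inter-episode intervals <= 60 s."""

    member_ids: list[int]
    onset_s: float
    offset_s: float

    @property
    def n_episodes(self) -> int:
        return len(self.member_ids)


# ---------------------------------------------------------------------------
# filtering and epoching
# ---------------------------------------------------------------------------

def bandpass_filter(
    rec: TimeSeriesRecording,
    low_hz: float = 0.5,
    high_hz: float = 400.0,
    order: int = 3,
) -> TimeSeriesRecording:
    """Zero-phase Butterworth band-pass applied to every channel.

    Forward-backward application (``sosfiltfilt``) preserves peak
    latencies, which matters because episode duration is defined
    peak-to-peak. Note the effective magnitude response is the squared
    one-pass response.
    """
    nyq = rec.sample_rate_hz / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.sample_rate_hz, output="sos")
    out = np.empty_like(rec.data, dtype=float)
    for i in range(rec.n_channels):
        out[i] = signal.sosfiltfilt(sos, rec.data[i].astype(float))
    return rec.copy_with(out)


def epoch_signal(rec: TimeSeriesRecording, epoch_ms: float = 250.0) -> np.ndarray:
    """Split into non-overlapping epochs.

    Returns an array of shape ``(n_epochs, n_channels, samples_per_epoch)``
    where ``samples_per_epoch = round(epoch_ms * rate / 1000)`` (1250 at
    5 kHz and 250 ms). A trailing partial epoch is discarded.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    n_ep_samp = int(round(epoch_ms * rec.sample_rate_hz / 1000.0))
    n_epochs = rec.n_samples // n_ep_samp
    trimmed = rec.data[:, : n_epochs * n_ep_samp]
    return np.swapaxes(trimmed.reshape(rec.n_channels, n_epochs, n_ep_samp), 0, 1)


# ---------------------------------------------------------------------------
# epoch features
# ---------------------------------------------------------------------------

def compute_rms(epoch: np.ndarray) -> float:
    """Root mean square, ``sqrt(sum(s_i^2)/n)``, of one epoch."""
    x = np.asarray(epoch, dtype=float)
    if x.size == 0:
        raise ValueError("empty epoch")
    return float(np.sqrt(np.mean(x**2)))


def _spike_peaks(
    x: np.ndarray,
    sample_rate_hz: float,
    params: SpikeParams,
    noise_scale: float | None = None,
) -> np.ndarray:
    """Indices of sharp transients: peaks of |x| above k robust SDs."""
    x = np.asarray(x, dtype=float)
    if noise_scale is None:
        noise_scale = robust_scale(x)
    if noise_scale == 0:
        return np.array([], dtype=int)
    dist = max(1, int(round(params.min_separation_ms * sample_rate_hz / 1000.0)))
    peaks, _ = signal.find_peaks(
        np.abs(x), height=params.mad_multiplier * noise_scale, distance=dist
    )
    return peaks


def robust_scale(x: np.ndarray) -> float:
    """Robust SD estimate: 1.4826 x median absolute deviation."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def compute_spike_density(
    epoch: np.ndarray,
    sample_rate_hz: float,
    params: SpikeParams = SpikeParams(),
    noise_scale: float | None = None,
) -> int:
    """Number of spikes in the epoch.

    ``noise_scale`` should normally be the robust SD of the whole
    band-passed channel so that an epoch full of spikes does not inflate
    its own threshold; when omitted it is estimated from the epoch itself.
    """
    return int(len(_spike_peaks(epoch, sample_rate_hz, params, noise_scale)))


def compute_fbr(epoch: np.ndarray, sample_rate_hz: float, cfg: FBRConfig = FBRConfig()) -> float:
    """Frequency band ratio of one epoch.

    Sum of FFT magnitudes over the upper band divided by the sum over the
    lower band (rectangular window, inclusive frequency bounds).
    """
    x = np.asarray(epoch, dtype=float)
    if x.size < 2:
        raise ValueError("epoch too short for a spectrum")
    if cfg.f2 > sample_rate_hz / 2.0:
        raise ValueError("upper band exceeds Nyquist")
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate_hz)
    upper = mag[(freqs >= cfg.f1) & (freqs <= cfg.f2)].sum()
    lower = mag[(freqs >= cfg.f3) & (freqs <= cfg.f4)].sum()
    if lower == 0:
        raise UndefinedRatioError("lower band carries no power; FBR undefined")
    return float(upper / lower)


def compute_epoch_features(
    rec: TimeSeriesRecording,
    epoch_ms: float = 250.0,
    fbr: FBRConfig = FBRConfig(),
    spikes: SpikeParams = SpikeParams(),
) -> pd.DataFrame:
    """Per-epoch, per-EEG-channel feature table (rms, spike_density, fbr).

    The recording should already be band-pass filtered. The spike-density
    noise scale is estimated once per channel over the whole recording.
    """
    eeg_idx = rec.eeg_indices()
    if not eeg_idx:
        raise ValueError("recording has no EEG channels")
    epochs = epoch_signal(rec, epoch_ms)  # (n_ep, n_ch, n_samp)
    n_ep, _, n_samp = epochs.shape
    epoch_s = n_samp / rec.sample_rate_hz
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / rec.sample_rate_hz)
    upper_mask = (freqs >= fbr.f1) & (freqs <= fbr.f2)
    lower_mask = (freqs >= fbr.f3) & (freqs <= fbr.f4)

    frames = []
    for ci in eeg_idx:
        ch = epochs[:, ci, :].astype(float)
        rms = np.sqrt(np.mean(ch**2, axis=1))
        mag = np.abs(np.fft.rfft(ch, axis=1))
        lower = mag[:, lower_mask].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fbr_vals = np.where(lower > 0, mag[:, upper_mask].sum(axis=1) / lower, np.nan)
        scale = robust_scale(rec.data[ci])
        density = np.zeros(n_ep, dtype=int)
        # global peak pass, binned per epoch: identical operator, no edge
        # re-thresholding per epoch
        peaks = _spike_peaks(rec.data[ci], rec.sample_rate_hz, spikes, noise_scale=scale)
        if peaks.size:
            bins = peaks // n_samp
            bins = bins[bins < n_ep]
            np.add.at(density, bins, 1)
        frames.append(
            pd.DataFrame(
                {
                    "epoch_index": np.arange(n_ep),
                    "start_s": np.arange(n_ep) * epoch_s,
                    "channel": rec.channel_labels[ci],
                    "rms": rms,
                    "spike_density": density,
                    "fbr": fbr_vals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------

def derive_thresholds(
    features: pd.DataFrame, policy: ThresholdPolicy = ThresholdPolicy()
) -> pd.DataFrame:
    """Per-channel feature thresholds from the recording's own distributions."""
    _check_schema(features)
    rows = []
    for ch, g in features.groupby("channel", sort=False):
        rows.append(
            {
                "channel": ch,
                "t_rms": float(np.percentile(g["rms"], policy.rms_percentile)),
                "t_fbr": float(np.nanpercentile(g["fbr"], policy.fbr_percentile)),
                "t_spike_density": int(policy.spike_density_min),
            }
        )
    return pd.DataFrame(rows)


def _check_schema(features: pd.DataFrame) -> None:
    missing = set(FEATURE_COLUMNS) - set(features.columns)
    if missing:
        raise KeyError(f"feature table missing columns: {sorted(missing)}")


def detect_candidates(
    features: pd.DataFrame,
    thresholds: pd.DataFrame | dict | None = None,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> np.ndarray:
    """Epoch indices where all three features exceed threshold on >= 1 channel.

    An epoch is a candidate iff, on at least one EEG channel,
    ``rms > t_rms`` and ``spike_density >= t_spike_density`` and
    ``fbr > t_fbr`` (a conjunction over all features). ``thresholds`` may
    be a per-channel table from :func:`derive_thresholds`, a flat dict
    ``{"rms": ..., "spike_density": ..., "fbr": ...}`` applied to every
    channel, or None to derive them from ``policy``.
    """
    _check_schema(features)
    if thresholds is None:
        thresholds = derive_thresholds(features, policy)
    if isinstance(thresholds, dict):
        t = features.assign(
            t_rms=thresholds["rms"],
            t_fbr=thresholds["fbr"],
            t_spike_density=thresholds["spike_density"],
        )
    else:
        t = features.merge(thresholds, on="channel", how="left", validate="many_to_one")
    hit = (
        (t["rms"] > t["t_rms"])
        & (t["spike_density"] >= t["t_spike_density"])
        & (t["fbr"] > t["t_fbr"])
    )
    return np.unique(t.loc[hit, "epoch_index"].to_numpy())


# ---------------------------------------------------------------------------
# episode assembly
# ---------------------------------------------------------------------------

def assemble_episodes(
    candidates: Sequence[int],
    filtered: TimeSeriesRecording,
    epoch_ms: float = 250.0,
    merge_gap_epochs: int = 1,
    span_margin_epochs: int = 2,
    spikes: SpikeParams = SpikeParams(),
) -> list[SWDEpisode]:
    """Merge candidate epochs into episodes and measure duration/spike rate.

    Candidate epochs separated by at most ``merge_gap_epochs`` non-flagged
    epochs belong to one episode (SWDs of 1-2 s span several 250-ms
    epochs). Because duration is defined peak-to-peak and a discharge can
    exceed its flagged epochs, peaks are measured over the run extended by
    ``span_margin_epochs`` on each side (runs whose extended spans overlap
    are merged). Spike peaks are located on the EEG channel with the
    largest RMS over the episode span; duration is the time between the
    first and last peaks and the spike rate is the peak frequency
    ``(n_peaks - 1) / duration``. Episodes with fewer than two peaks are
    discarded (logged).
    """
    cand = np.unique(np.asarray(list(candidates), dtype=int))
    if cand.size == 0:
        return []
    n_samp = int(round(epoch_ms * filtered.sample_rate_hz / 1000.0))
    epoch_s = n_samp / filtered.sample_rate_hz
    n_epochs_total = filtered.n_samples // n_samp
    eeg_idx = filtered.eeg_indices()
    scales = {ci: robust_scale(filtered.data[ci]) for ci in eeg_idx}

    runs: list[tuple[int, int]] = []
    start = prev = cand[0]
    for e in cand[1:]:
        if e - prev <= merge_gap_epochs + 1:
            prev = e
        else:
            runs.append((start, prev))
            start = prev = e
    runs.append((start, prev))

    # extend by the measurement margin and merge overlapping spans
    ext = [
        (max(0, a - span_margin_epochs), min(n_epochs_total - 1, b + span_margin_epochs))
        for a, b in runs
    ]
    merged: list[tuple[int, int]] = []
    for a, b in ext:
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))

    episodes: list[SWDEpisode] = []
    for e0, e1 in merged:
        s0, s1 = e0 * n_samp, (e1 + 1) * n_samp
        seg = filtered.data[:, s0:s1]
        rms_by_ch = {ci: float(np.sqrt(np.mean(seg[ci] ** 2))) for ci in eeg_idx}
        best = max(rms_by_ch, key=rms_by_ch.get)
        # inside a flagged episode the spikes only need locating, not
        # re-detecting against noise: accept peaks above 3.5 robust SDs or
        # half the episode's own extremum (whichever is larger, so slow
        # waves at ~0.4x the spike amplitude stay excluded)
        height = max(3.5 * scales[best], 0.5 * float(np.max(np.abs(seg[best]))))
        dist = max(1, int(round(spikes.min_separation_ms * filtered.sample_rate_hz / 1000.0)))
        peaks, _ = signal.find_peaks(np.abs(seg[best]), height=height, distance=dist)
        if len(peaks) < 2:
            logger.info(
                "discarding candidate run %s-%s: %d spike peak(s) < 2", e0, e1, len(peaks)
            )
            continue
        first = (s0 + peaks[0]) / filtered.sample_rate_hz
        last = (s0 + peaks[-1]) / filtered.sample_rate_hz
        duration = last - first
        episodes.append(
            SWDEpisode(
                onset_s=e0 * epoch_s,
                offset_s=(e1 + 1) * epoch_s,
                duration_s=duration,
                spike_count=int(len(peaks)),
                spike_rate_hz=(len(peaks) - 1) / duration,
                channel=filtered.channel_labels[best],
                channels=[filtered.channel_labels[ci] for ci in eeg_idx],
                first_peak_s=first,
                last_peak_s=last,
            )
        )
    return episodes


def annotate_states(
    episodes: Sequence[SWDEpisode],
    state_schedule: Sequence[tuple[str, float, float]],
) -> list[SWDEpisode]:
    """Label each episode with the behavioral state at its onset."""
    for ep in episodes:
        for state, lo, hi in state_schedule:
            if lo <= ep.onset_s < hi:
                ep.state = state
                break
    return list(episodes)


# ---------------------------------------------------------------------------
# clusters and circadian profile
# ---------------------------------------------------------------------------

def find_clusters(
    episodes: Sequence[SWDEpisode],
    min_episodes: int = 5,
    max_iei_s: float = 60.0,
) -> list[SWDCluster]:
    """Maximal runs of episodes with offset-to-next-onset gaps <= 60 s.

    A run qualifies as a cluster when it contains at least
    ``min_episodes`` members; the 60-s boundary is inclusive. Each episode
    belongs to at most one cluster. Episodes must be time-sorted.
    """
    eps = list(episodes)
    if any(eps[i].onset_s > eps[i + 1].onset_s for i in range(len(eps) - 1)):
        raise ValueError("episodes must be sorted by onset")
    clusters: list[SWDCluster] = []
    i = 0
    while i < len(eps):
        j = i
        while j + 1 < len(eps) and eps[j + 1].onset_s - eps[j].offset_s <= max_iei_s:
            j += 1
        if j - i + 1 >= min_episodes:
            cid = len(clusters)
            members = list(range(i, j + 1))
            for m in members:
                eps[m].cluster_id = cid
            clusters.append(
                SWDCluster(member_ids=members, onset_s=eps[i].onset_s, offset_s=eps[j].offset_s)
            )
        i = j + 1
    return clusters


def rate_profile(
    episodes: Sequence[SWDEpisode],
    start_time: datetime,
    duration_s: float,
) -> pd.DataFrame:
    """Episodes per hour of day, averaged over the days covered.

    Returns a 24-row table with columns ``hours_covered`` (total recording
    time falling in that hour-of-day, in hours) and ``mean_count``
    (episodes per covered hour; NaN where coverage is zero). The profile
    conserves counts: ``sum(mean_count * hours_covered) == len(episodes)``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    counts = np.zeros(24)
    for ep in episodes:
        if not 0 <= ep.onset_s < duration_s:
            raise ValueError(f"episode onset {ep.onset_s} outside recording span")
        counts[(start_time + timedelta(seconds=ep.onset_s)).hour] += 1
    coverage = np.zeros(24)
    t = 0.0
    while t < duration_s:
        cur = start_time + timedelta(seconds=t)
        next_hour = (cur.replace(minute=0, second=0, microsecond=0) + timedelta(hours=1))
        step = min((next_hour - cur).total_seconds(), duration_s - t)
        coverage[cur.hour] += step / 3600.0
        t += step
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_count = np.where(coverage > 0, counts / coverage, np.nan)
    return pd.DataFrame({"hour": np.arange(24), "hours_covered": coverage, "mean_count": mean_count})


def episodes_to_frame(episodes: Sequence[SWDEpisode]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of a list of episodes."""
    return pd.DataFrame(
        [
            {
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
                "duration_s": e.duration_s,
                "spike_count": e.spike_count,
                "spike_rate_hz": e.spike_rate_hz,
                "channel": e.channel,
                "state": e.state,
                "cluster_id": e.cluster_id,
                "source": e.source,
            }
            for e in episodes
        ]
    )
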