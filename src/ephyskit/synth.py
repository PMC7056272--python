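"""Synthetic EEG/EMG and voltage-clamp data with known ground truth.

Every analysis stage in this package is validated against signals whose
event times, amplitudes and kinetics are known exactly. The generators are
phenomenological, not biophysical:

* EEG background is per-channel pink (1/f) noise whose spectral content is
  modulated by behavioral state (delta boost in NREM, theta in REM/awake).
* Spike-wave discharges are injected as trains of 3-6 Hz cycles, each a
  sharp 25-ms half-cosine spike followed by an opposite-polarity slow wave
  completing the period, at 4-8x the background RMS, simultaneously on all
  EEG channels with +-20% per-channel amplitude jitter.
* Myoclonic jerks are 50-200 ms rectified EMG noise bursts with an EEG
  spike leading by a configurable lag (cortical myoclonus) or simultaneous.
* Patch-clamp sweeps carry Poisson-timed biexponential miniature IPSCs
  (lognormal amplitudes) in a baseline window and a light window, a tonic
  current that decays linearly across the light window (mirroring a
  ramped-down photostimulus), and Gaussian noise.
* Unitary-IPSC sweeps carry a 6-pulse 10-Hz IPSC train with a configurable
  per-pulse depression profile, or pure noise for unconnected pairs.

All generators are deterministic functions of their config (including the
seed): identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .core import EEG, EMG, SweepSet, TimeSeriesRecording


class ConfigurationError(ValueError):
    """Invalid simulation configuration (e.g., state schedule gap/overlap)."""


# ---------------------------------------------------------------------------
# configs and annotations
# ---------------------------------------------------------------------------

@dataclass
class EEGSimConfig:
    duration_s: float
    sample_rate_hz: float = 5000.0
    n_eeg_channels: int = 3
    #: (state, start_s, end_s) tiles of the recording; None = all awake.
    state_schedule: list[tuple[str, float, float]] | None = None
    swd_rate_per_hr: float = 20.0
    swd_freq_range_hz: tuple[float, float] = (3.0, 6.0)
    swd_duration_range_s: tuple[float, float] = (1.0, 2.0)
    long_swd_fraction: float = 0.02  # fraction of events drawn at > 4 s
    cluster_spec: tuple[int, float] | None = None  # (n_episodes >= 5, max_iei_s)
    myoclonus_rate_per_hr: float = 0.0
    eeg_emg_lag_ms: float = 15.0  # EEG spike leads EMG burst by this much
    noise_amplitude_uv: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0 or self.duration_s <= 0:
            raise ConfigurationError("duration and sample rate must be positive")
        for lo, hi in (self.swd_freq_range_hz, self.swd_duration_range_s):
            if lo > hi:
                raise ConfigurationError("ranges must be ordered low <= high")
        if self.swd_rate_per_hr < 0 or self.myoclonus_rate_per_hr < 0:
            raise ConfigurationError("event rates must be non-negative")
        if self.cluster_spec is not None and self.cluster_spec[0] < 5:
            raise ConfigurationError("a cluster needs >= 5 episodes")
        if self.state_schedule is None:
            self.state_schedule = [("awake", 0.0, float(self.duration_s))]
        sched = sorted(self.state_schedule, key=lambda s: s[1])
        t = 0.0
        for state, lo, hi in sched:
            if state not in ("awake", "NREM", "REM"):
                raise ConfigurationError(f"unknown state {state!r}")
            if abs(lo - t) > 1e-9 or hi <= lo:
                raise ConfigurationError("state schedule must tile [0, duration] without gaps/overlap")
            t = hi
        if abs(t - self.duration_s) > 1e-9:
            raise ConfigurationError("state schedule must end at duration_s")
        self.state_schedule = sched


@dataclass(frozen=True)
class GroundTruthAnnotation:
    event_kind: str  # SWD | myoclonic_jerk | myoclonic_jump
    channels: tuple[str, ...]
    onset_s: float
    offset_s: float
    state: str
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must exceed onset")


@dataclass
class PatchSimConfig:
    n_sweeps: int = 15
    baseline_window_s: tuple[float, float] = (0.0, 10.0)
    light_window_s: tuple[float, float] = (10.0, 20.0)
    rate_baseline_hz: float = 1.0
    rate_light_hz: float = 2.0
    amplitude_mean_pa: float = 20.0
    amplitude_cv: float = 0.6  # lognormal coefficient of variation
    rise_ms: float = 0.6
    decay_ms: float = 10.0
    tonic_ramp_pa: float = 20.0  # peak tonic current, decays across light window
    noise_sd_pa: float = 2.0
    sample_rate_hz: float = 10000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_baseline_hz < 0 or self.rate_light_hz < 0:
            raise ConfigurationError("event rates must be non-negative")
        if self.amplitude_mean_pa <= 0:
            raise ConfigurationError("amplitude_mean_pa must be positive")
        if self.amplitude_cv < 0:
            raise ConfigurationError("amplitude_cv must be non-negative")
        b, l = self.baseline_window_s, self.light_window_s
        if b[0] >= b[1] or l[0] >= l[1]:
            raise ConfigurationError("windows must have positive duration")
        if max(b[0], l[0]) < min(b[1], l[1]):
            raise ConfigurationError("baseline and light windows overlap")


@dataclass
class UIPSCSimConfig:
    n_sweeps: int = 40
    n_pulses: int = 6
    pulse_rate_hz: float = 10.0
    first_amplitude_pa: float = 200.0
    depression_profile: tuple[float, ...] = (1.0, 0.8, 0.7, 0.6, 0.55, 0.5)
    baseline_noise_sd_pa: float = 5.0
    connected: bool = True
    trial_cv: float = 0.2  # sweep-to-sweep amplitude variability
    rise_ms: float = 1.0
    decay_ms: float = 15.0
    pre_stim_s: float = 0.2
    sample_rate_hz: float = 10000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.depression_profile) != self.n_pulses:
            raise ConfigurationError("depression_profile length must equal n_pulses")
        if abs(self.depression_profile[0] - 1.0) > 1e-12:
            raise ConfigurationError("first pulse scale factor must be 1")


# ---------------------------------------------------------------------------
# EEG/EMG generator
# ---------------------------------------------------------------------------

def _pink_noise(
    n: int,
    rng: np.random.Generator,
    fs: float = 1.0,
    knee_hz: float | None = None,
    hf_slope: float = 2.5,
) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping of white Gaussian noise.

    With ``knee_hz`` set, the amplitude spectrum is 1/sqrt(f) up to the
    knee and falls as ``f**-hf_slope`` beyond it — mimicking the steep
    high-frequency rolloff of intracranial EEG above the gamma band.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    if knee_hz is not None:
        hi = freqs > knee_hz
        scale[hi] = (1.0 / np.sqrt(knee_hz)) * (knee_hz / freqs[hi]) ** hf_slope
    x = np.fft.irfft(spec * scale, n)
    return x / np.std(x)


def _band_noise(n: int, fs: float, low: float, high: float, rng: np.random.Generator) -> np.ndarray:
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _swd_waveform(duration_s: float, freq_hz: float, fs: float) -> np.ndarray:
    """Train of spike-wave cycles.

    Each cycle is a sharp 10-ms triangular spike carrying a small 200-Hz
    ripple (the fast component of epileptiform spikes, which gives SWD
    epochs their distinctive upper-band power), followed by an
    opposite-polarity slow wave completing the 1/f period.
    """
    period = 1.0 / freq_hz
    n_cycles = max(1, int(round(duration_s * freq_hz)))
    spike_w = min(0.010, 0.4 * period)
    n_sp = max(3, int(round(spike_w * fs)))
    n_per = int(round(period * fs))
    cycle = np.zeros(n_per)
    half = n_sp // 2
    cycle[:n_sp] = np.interp(np.arange(n_sp), [0, half, n_sp - 1], [0.0, 1.0, 0.0])
    t = (np.arange(n_sp) - half) / fs
    cycle[:n_sp] += 0.35 * np.exp(-((t / 0.004) ** 2)) * np.sin(2 * np.pi * 200.0 * t)
    n_slow = n_per - n_sp
    if n_slow > 2:
        cycle[n_sp:] = -0.4 * np.sin(np.linspace(0, np.pi, n_slow))
    return np.tile(cycle, n_cycles)


def _state_at(schedule: Sequence[tuple[str, float, float]], t: float) -> str:
    for state, lo, hi in schedule:
        if lo <= t < hi:
            return state
    return schedule[-1][0]


def generate_eeg(
    config: EEGSimConfig,
) -> tuple[TimeSeriesRecording, list[GroundTruthAnnotation]]:
    """Simulate a multichannel EEG/EMG recording with injected events.

    Returns the recording (``n_eeg_channels`` EEG channels plus one EMG
    channel) and the ground-truth annotations, sorted by onset.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate_hz
    n = int(round(config.duration_s * fs))
    n_eeg = config.n_eeg_channels
    rms = config.noise_amplitude_uv

    data = np.zeros((n_eeg + 1, n), dtype=np.float32)
    # state-dependent rhythm masks
    delta = _band_noise(n, fs, 1.0, 4.0, rng) if fs > 8 else np.zeros(n)
    theta = _band_noise(n, fs, 6.0, 9.0, rng) if fs > 18 else np.zeros(n)
    nrem_mask = np.zeros(n)
    theta_mask = np.zeros(n)
    for state, lo, hi in config.state_schedule:
        sl = slice(int(lo * fs), int(hi * fs))
        if state == "NREM":
            nrem_mask[sl] = 1.0
        else:  # awake and REM both carry theta
            theta_mask[sl] = 1.0
    for c in range(n_eeg):
        bg = _pink_noise(n, rng, fs=fs, knee_hz=min(60.0, 0.4 * fs / 2))
        data[c] = rms * (bg + 0.8 * delta * nrem_mask + 0.5 * theta * theta_mask)
    emg_rms = 0.5 * rms
    data[n_eeg] = emg_rms * rng.standard_normal(n)

    annotations: list[GroundTruthAnnotation] = []
    eeg_labels = tuple(f"EEG{i + 1}" for i in range(n_eeg))

    # --- SWD onsets: Poisson background, plus one injected cluster ---------
    onset_dur: list[tuple[float, float, int | None]] = []
    n_swd = rng.poisson(config.swd_rate_per_hr * config.duration_s / 3600.0)
    max_dur = 6.0
    for _ in range(n_swd):
        if config.long_swd_fraction > 0 and rng.random() < config.long_swd_fraction:
            dur = rng.uniform(4.0, max_dur)
        else:
            dur = rng.uniform(*config.swd_duration_range_s)
        for _attempt in range(200):
            t0 = rng.uniform(0, config.duration_s - dur) if config.duration_s > dur else 0.0
            if all(t0 + dur + 0.5 < a or t0 > a + d + 0.5 for a, d, _ in onset_dur):
                onset_dur.append((t0, dur, None))
                break
    if config.cluster_spec is not None:
        n_members, max_iei = config.cluster_spec
        t = rng.uniform(0, max(1e-6, config.duration_s * 0.2))
        for _ in range(n_members):
            dur = rng.uniform(*config.swd_duration_range_s)
            if t + dur >= config.duration_s:
                break
            onset_dur.append((t, dur, 0))
            t += dur + rng.uniform(2.0, max_iei)

    for t0, dur, cid in sorted(onset_dur):
        f = rng.uniform(*config.swd_freq_range_hz)
        wave = _swd_waveform(dur, f, fs)
        i0 = int(round(t0 * fs))
        wave = wave[: n - i0]
        amp = rng.uniform(4.0, 8.0) * rms
        for c in range(n_eeg):
            jitter = rng.uniform(0.8, 1.2)
            data[c, i0 : i0 + wave.size] += (amp * jitter * wave).astype(np.float32)
        annotations.append(
            GroundTruthAnnotation(
                event_kind="SWD",
                channels=eeg_labels,
                onset_s=i0 / fs,
                offset_s=(i0 + wave.size) / fs,
                state=_state_at(config.state_schedule, t0),
                cluster_id=cid,
            )
        )

    # --- myoclonic jerks ---------------------------------------------------
    n_myo = rng.poisson(config.myoclonus_rate_per_hr * config.duration_s / 3600.0)
    for _ in range(n_myo):
        t0 = rng.uniform(0, max(1e-6, config.duration_s - 0.5))
        if any(a - 1.0 < t0 < a + d + 1.0 for a, d, _ in onset_dur):
            continue  # keep myoclonus distinct from SWDs for clean truth
        burst_s = rng.uniform(0.05, 0.2)
        i_sp = int(round(t0 * fs))
        n_sp = max(3, int(round(0.010 * fs)))
        half = n_sp // 2
        spike = np.interp(np.arange(n_sp), [0, half, n_sp - 1], [0.0, 1.0, 0.0])
        tt = (np.arange(n_sp) - half) / fs
        spike = (spike + 0.35 * np.exp(-((tt / 0.004) ** 2)) * np.sin(2 * np.pi * 200.0 * tt))[
            : n - i_sp
        ]
        for c in range(n_eeg):
            data[c, i_sp : i_sp + spike.size] += (5.0 * rms * spike).astype(np.float32)
        i_b = int(round((t0 + config.eeg_emg_lag_ms / 1000.0) * fs))
        n_b = int(round(burst_s * fs))
        burst = np.abs(rng.standard_normal(max(0, min(n_b, n - i_b))))
        data[n_eeg, i_b : i_b + burst.size] += (4.0 * emg_rms * burst).astype(np.float32)
        annotations.append(
            GroundTruthAnnotation(
                event_kind="myoclonic_jerk",
                channels=eeg_labels + ("EMG",),
                onset_s=i_sp / fs,
                offset_s=max((i_b + burst.size) / fs, i_sp / fs + burst_s),
                state=_state_at(config.state_schedule, t0),
            )
        )

    annotations.sort(key=lambda a: a.onset_s)
    rec = TimeSeriesRecording(
        data=data,
        sample_rate_hz=fs,
        channel_labels=list(eeg_labels) + ["EMG"],
        channel_roles=[EEG] * n_eeg + [EMG],
    )
    return rec, annotations


def annotations_to_frame(annotations: Sequence[GroundTruthAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_kind": a.event_kind,
                "channel": "+".join(a.channels),
                "onset_s": a.onset_s,
                "offset_s": a.offset_s,
                "state": a.state,
                "cluster_id": a.cluster_id,
            }
            for a in annotations
        ]
    )


# ---------------------------------------------------------------------------
# patch-clamp generators
# ---------------------------------------------------------------------------

def _psc_kernel(rise_ms: float, decay_ms: float, fs: float) -> np.ndarray:
    """Unit-peak biexponential (1 - exp(-t/rise)) * exp(-t/decay)."""
    t = np.arange(int(round(8 * decay_ms / 1000.0 * fs))) / fs
    tr, td = rise_ms / 1000.0, decay_ms / 1000.0
    g = (1.0 - np.exp(-t / tr)) * np.exp(-t / td)
    return g / g.max()


def _lognormal_amps(mean: float, cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def generate_patch_sweeps(config: PatchSimConfig) -> tuple[SweepSet, pd.DataFrame]:
    """Simulate mIPSC sweeps with a baseline and a light-stimulation window.

    Returns the sweeps and a ground-truth event table with columns
    ``sweep, time_s, amplitude_pa, window``. Events are outward (positive)
    currents, as for IPSCs recorded at the excitatory reversal potential.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate_hz
    sweep_end = max(config.baseline_window_s[1], config.light_window_s[1])
    n = int(round(sweep_end * fs))
    kernel = _psc_kernel(config.rise_ms, config.decay_ms, fs)

    data = config.noise_sd_pa * rng.standard_normal((config.n_sweeps, n))
    # tonic current: peaks at light onset, decays linearly to 0 at light end
    l0, l1 = config.light_window_s
    i0, i1 = int(round(l0 * fs)), int(round(l1 * fs))
    if config.tonic_ramp_pa != 0 and i1 > i0:
        data[:, i0:i1] += config.tonic_ramp_pa * np.linspace(1.0, 0.0, i1 - i0)

    truth = []
    for s in range(config.n_sweeps):
        for (w0, w1), rate, name in (
            (config.baseline_window_s, config.rate_baseline_hz, "baseline"),
            (config.light_window_s, config.rate_light_hz, "light"),
        ):
            k = rng.poisson(rate * (w1 - w0))
            times = np.sort(rng.uniform(w0, w1, k))
            amps = _lognormal_amps(config.amplitude_mean_pa, config.amplitude_cv, k, rng)
            for t, a in zip(times, amps):
                i = int(round(t * fs))
                seg = kernel[: n - i]
                data[s, i : i + seg.size] += a * seg
                truth.append({"sweep": s, "time_s": t, "amplitude_pa": a, "window": name})

    sweeps = SweepSet(
        data=data,
        sample_rate_hz=fs,
        baseline_window=config.baseline_window_s,
        light_window=config.light_window_s,
        metadata={"config": config.__dict__.copy()},
    )
    cols = ["sweep", "time_s", "amplitude_pa", "window"]
    return sweeps, pd.DataFrame(truth, columns=cols)


def generate_uipsc_sweeps(config: UIPSCSimConfig) -> SweepSet:
    """Simulate postsynaptic sweeps aligned to a 6-pulse 10-Hz spike train.

    If ``connected`` is False the sweeps contain noise only. Pulse times
    are stored in ``metadata['stim_times_s']``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate_hz
    ipi = 1.0 / config.pulse_rate_hz
    stim_times = config.pre_stim_s + ipi * np.arange(config.n_pulses)
    dur = stim_times[-1] + 0.3
    n = int(round(dur * fs))
    kernel = _psc_kernel(config.rise_ms, config.decay_ms, fs)

    data = config.baseline_noise_sd_pa * rng.standard_normal((config.n_sweeps, n))
    if config.connected:
        for s in range(config.n_sweeps):
            for p, t in enumerate(stim_times):
                mean_amp = config.first_amplitude_pa * config.depression_profile[p]
                amp = mean_amp * max(0.0, 1.0 + config.trial_cv * rng.standard_normal())
                i = int(round(t * fs))
                seg = kernel[: n - i]
                data[s, i : i + seg.size] += amp * seg

    return SweepSet(
        data=data,
        sample_rate_hz=fs,
        metadata={
            "stim_times_s": stim_times.tolist(),
            "config": config.__dict__.copy(),
        },
    )
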