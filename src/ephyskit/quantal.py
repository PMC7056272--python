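"""Quantal IPSC isolation by rate-weighted subtraction, and unitary-IPSC
connectivity analysis.

Optogenetic quantal isolation: during each sweep, miniature IPSCs are
collected in a pre-light baseline window and a light-stimulation window.
Light raises the event rate by driving asynchronous release from the
opsin-expressing interneuron class, so light-window events are a mixture
of generic background minis and minis from the targeted class. For any
per-event statistic A (amplitude, charge, or decay time constant), the
class-specific quantal value is recovered by the subtraction

    A_quantal = (A_light * f_light - A_baseline * f_baseline)
                / (f_light - f_baseline)

where A_* are window means and f_* the window event frequencies. The same
subtraction applied to the average event waveforms yields the mean quantal
waveform. The estimate is only meaningful when light significantly raises
the rate; quality control requires a significant rate increase (exact
one-sided Poisson rate-ratio test) and at least 150 evoked events.

Unitary connectivity: a presynaptic interneuron is driven with a 6-pulse
10-Hz train while the postsynaptic pyramidal neuron is voltage clamped.
Sweeps are averaged; the pair is called connected when the first-pulse
uIPSC amplitude of the average trace is at least 3x the pre-stimulus
baseline standard deviation. Per-pulse amplitudes normalized to the first
pulse quantify short-term depression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .core import SweepSet


class DegenerateRateError(ValueError):
    """Raised when the light-window event rate does not exceed baseline."""


@dataclass
class QuantalEstimate:
    """Result of the rate-weighted subtraction for one cell."""

    a_quantal_amplitude_pa: float
    a_quantal_charge_pc: float
    a_quantal_decay_ms: float
    a_light: dict[str, float]
    a_baseline: dict[str, float]
    f_light_hz: float
    f_baseline_hz: float
    n_evoked: int
    qc_significant: bool
    qc_enough_events: bool
    qc_pvalue: float
    #: subtraction approximation degrades for decay when baseline events
    #: dominate the light-window mixture
    decay_mixture_warning: bool
    mean_quantal_waveform: np.ndarray | None = None
    waveform_times_s: np.ndarray | None = None

    @property
    def qc_pass(self) -> bool:
        return self.qc_significant and self.qc_enough_events


@dataclass
class UnitaryConnection:
    """Averaged uIPSC train of one interneuron-pyramidal pair."""

    mean_trace: np.ndarray
    sample_rate_hz: float
    n_sweeps: int
    first_pulse_amplitude_pa: float
    baseline_sd_pa: float
    is_connected: bool
    pulse_amplitudes_pa: np.ndarray = field(default_factory=lambda: np.array([]))
    normalized_train_amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# quantal subtraction
# ---------------------------------------------------------------------------

def _subtract(a_light: float, f_light: float, a_base: float, f_base: float) -> float:
    return (a_light * f_light - a_base * f_base) / (f_light - f_base)


def qc_evoked(
    events: pd.DataFrame,
    sweeps: SweepSet,
    alpha: float = 0.05,
) -> tuple[bool, bool, int]:
    """Quality control on the evoked-event yield.

    ``qc_significant``: one-sided exact Poisson rate-ratio test that the
    light-window rate exceeds baseline (conditional binomial test on the
    light count given the total, at the exposure fraction), at level
    ``alpha``. ``n_evoked`` is the light-window count minus the baseline
    count; ``qc_enough_events`` requires at least 150.
    """
    from .events import window_partition

    events, _, _ = window_partition(events, sweeps)
    sig, p = _rate_increase_test(events, sweeps, alpha)
    n_l = int((events["window"] == "light").sum())
    n_b = int((events["window"] == "baseline").sum())
    n_evoked = n_l - n_b
    return sig, n_evoked >= 150, n_evoked


def _rate_increase_test(events: pd.DataFrame, sweeps: SweepSet, alpha: float) -> tuple[bool, float]:
    n_l = int((events["window"] == "light").sum())
    n_b = int((events["window"] == "baseline").sum())
    t_l = sweeps.light_window[1] - sweeps.light_window[0]
    t_b = sweeps.baseline_window[1] - sweeps.baseline_window[0]
    if n_l + n_b == 0:
        return False, 1.0
    res = binomtest(n_l, n_l + n_b, t_l / (t_l + t_b), alternative="greater")
    return bool(res.pvalue <= alpha), float(res.pvalue)


def _mean_event_waveform(
    events: pd.DataFrame,
    sweeps: SweepSet,
    window: str,
    pre_s: float = 0.005,
    post_s: float = 0.045,
) -> np.ndarray | None:
    fs = sweeps.sample_rate_hz
    n_pre, n_post = int(round(pre_s * fs)), int(round(post_s * fs))
    snips = []
    for _, ev in events[events["window"] == window].iterrows():
        i = int(round(ev["time_s"] * fs))
        if i - n_pre < 0 or i + n_post > sweeps.n_samples:
            continue
        seg = sweeps.data[int(ev["sweep"]), i - n_pre : i + n_post]
        snips.append(seg - np.mean(seg[:n_pre]))
    if not snips:
        return None
    return np.mean(snips, axis=0)


def estimate_quantal(
    events: pd.DataFrame,
    sweeps: SweepSet,
    alpha: float = 0.05,
    compute_waveform: bool = True,
) -> QuantalEstimate:
    """Isolate quantal IPSC parameters of the light-targeted interneuron class.

    ``events`` is the window-tagged table from
    :func:`ephyskit.events.detect_events` /
    :func:`ephyskit.events.window_partition`. Raises
    :class:`DegenerateRateError` when the light rate does not exceed the
    baseline rate (the subtraction denominator is then non-positive and no
    estimate is returned).
    """
    from .events import window_partition

    events, f_base, f_light = window_partition(events, sweeps)
    if f_light <= f_base:
        raise DegenerateRateError(
            f"light rate {f_light:.3g} Hz does not exceed baseline {f_base:.3g} Hz"
        )
    light = events[events["window"] == "light"]
    base = events[events["window"] == "baseline"]
    params = {
        "amplitude_pa": "peak_amplitude_pa",
        "charge_pc": "charge_pc",
        "decay_ms": "decay_tau_ms",
    }
    a_light = {k: float(np.nanmean(light[c])) if len(light) else np.nan for k, c in params.items()}
    a_base = {k: float(np.nanmean(base[c])) if len(base) else 0.0 for k, c in params.items()}
    if f_base == 0:
        a_base = {k: 0.0 for k in params}
    quantal = {k: _subtract(a_light[k], f_light, a_base[k], f_base) for k in params}

    sig, p = _rate_increase_test(events, sweeps, alpha)
    t_light = (sweeps.light_window[1] - sweeps.light_window[0]) * sweeps.n_sweeps
    n_evoked = int(round((f_light - f_base) * t_light))

    wave = times = None
    if compute_waveform:
        w_light = _mean_event_waveform(events, sweeps, "light")
        w_base = _mean_event_waveform(events, sweeps, "baseline")
        if w_light is not None:
            if w_base is None or f_base == 0:
                w_base = np.zeros_like(w_light)
            wave = (w_light * f_light - w_base * f_base) / (f_light - f_base)
            times = np.arange(wave.size) / sweeps.sample_rate_hz - 0.005

    return QuantalEstimate(
        a_quantal_amplitude_pa=quantal["amplitude_pa"],
        a_quantal_charge_pc=quantal["charge_pc"],
        a_quantal_decay_ms=quantal["decay_ms"],
        a_light=a_light,
        a_baseline=a_base,
        f_light_hz=f_light,
        f_baseline_hz=f_base,
        n_evoked=n_evoked,
        qc_significant=sig,
        qc_enough_events=n_evoked >= 150,
        qc_pvalue=p,
        decay_mixture_warning=bool(f_base / f_light > 0.5),
        mean_quantal_waveform=wave,
        waveform_times_s=times,
    )


# ---------------------------------------------------------------------------
# unitary IPSC analysis
# ---------------------------------------------------------------------------

def analyze_uipsc(
    sweeps: SweepSet,
    stim_times_s: np.ndarray | None = None,
    baseline_window_s: float = 0.05,
    response_window_s: float = 0.015,
    smooth_ms: float = 1.0,
    min_sweeps: int = 10,
) -> UnitaryConnection:
    """Average the sweeps and call the connection from the first-pulse uIPSC.

    The baseline SD is computed over ``baseline_window_s`` (50 ms) of the
    average trace immediately preceding the first pulse. Each pulse
    amplitude is the extremal deflection of the average trace — smoothed
    with a ``smooth_ms`` moving average so the measurement does not chase
    single-sample noise excursions — relative to a 2-ms pre-pulse local
    baseline, within ``response_window_s`` after the pulse (covering
    synaptic latency plus the rise); the deflection polarity is set by
    the first pulse. The pair is connected when the first-pulse amplitude
    is at least 3x the baseline SD (inclusive).
    """
    if stim_times_s is None:
        stim_times_s = sweeps.metadata.get("stim_times_s")
    if stim_times_s is None:
        raise ValueError("stimulus times required (stim_times_s)")
    stim = np.asarray(stim_times_s, dtype=float)
    if sweeps.n_sweeps < min_sweeps:
        raise ValueError(f"need >= {min_sweeps} sweeps, got {sweeps.n_sweeps}")
    fs = sweeps.sample_rate_hz
    avg = sweeps.data.mean(axis=0)

    i_first = int(round(stim[0] * fs))
    nb = int(round(baseline_window_s * fs))
    if i_first - nb < 0:
        raise ValueError("not enough pre-stimulus baseline before the first pulse")
    baseline_sd = float(np.std(avg[i_first - nb : i_first]))

    n_sm = max(1, int(round(smooth_ms / 1000.0 * fs)))
    smoothed = np.convolve(avg, np.ones(n_sm) / n_sm, mode="same")
    n_resp = int(round(response_window_s * fs))
    n_loc = max(1, int(round(0.002 * fs)))
    amps = np.zeros(stim.size)
    sign = 0.0
    for p, t in enumerate(stim):
        i = int(round(t * fs))
        local = float(np.mean(avg[max(0, i - n_loc) : i]))
        seg = smoothed[i : i + n_resp] - local
        if p == 0:
            sign = np.sign(seg[np.argmax(np.abs(seg))]) or 1.0
        amps[p] = float(np.max(sign * seg))
    first_amp = abs(amps[0])
    connected = bool(first_amp >= 3.0 * baseline_sd)
    norm = amps / amps[0] if connected and amps[0] != 0 else np.full(stim.size, np.nan)
    return UnitaryConnection(
        mean_trace=avg,
        sample_rate_hz=fs,
        n_sweeps=sweeps.n_sweeps,
        first_pulse_amplitude_pa=first_amp,
        baseline_sd_pa=baseline_sd,
        is_connected=connected,
        pulse_amplitudes_pa=amps,
        normalized_train_amplitudes=norm,
    )


def connectivity_summary(
    group_a: tuple[int, int] | list[UnitaryConnection],
    group_b: tuple[int, int] | list[UnitaryConnection],
) -> dict:
    """Connectivity rates of two groups and the percent reduction B vs A.

    Each group is either ``(n_connected, n_pairs)`` or a list of
    :class:`UnitaryConnection`. The reduction is
    ``(1 - rate_b / rate_a) * 100`` rounded to the nearest percent.
    """
    def as_counts(g):
        if isinstance(g, tuple):
            n_conn, n_pairs = g
        else:
            n_conn, n_pairs = sum(c.is_connected for c in g), len(g)
        if n_pairs <= 0:
            raise ValueError("each group needs at least one pair")
        if not 0 <= n_conn <= n_pairs:
            raise ValueError("0 <= n_connected <= n_pairs required")
        return n_conn, n_pairs

    ca, pa = as_counts(group_a)
    cb, pb = as_counts(group_b)
    rate_a, rate_b = ca / pa, cb / pb
    if rate_a == 0:
        raise ValueError("reference group has zero connectivity; reduction undefined")
    return {
        "n_connected_a": ca,
        "n_pairs_a": pa,
        "n_connected_b": cb,
        "n_pairs_b": pb,
        "rate_a": rate_a,
        "rate_b": rate_b,
        "percent_reduction": int(round((1.0 - rate_b / rate_a) * 100.0)),
    }
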