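"""Shared in-memory containers for EEG/EMG recordings and voltage-clamp sweeps.

All signal values are stored in physical units (microvolts for EEG/EMG,
picoamperes for clamp currents) and all times in seconds from the start of
the recording or sweep. Wall-clock start time is kept once, on the
recording, so that circadian (per-hour) profiles can be computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np

EEG = "EEG"
EMG = "EMG"


@dataclass
class TimeSeriesRecording:
    """Multichannel EEG/EMG recording.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    sample_rate_hz
        Sampling rate shared by all channels.
    channel_labels
        One name per channel.
    channel_roles
        ``"EEG"`` or ``"EMG"`` per channel.
    start_time
        Wall-clock time of sample 0 (used by per-hour rate profiles).
    """

    data: np.ndarray
    sample_rate_hz: float
    channel_labels: Sequence[str]
    channel_roles: Sequence[str]
    start_time: datetime = field(default_factory=lambda: datetime(2000, 1, 1))

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        n = self.data.shape[0]
        if len(self.channel_labels) != n or len(self.channel_roles) != n:
            raise ValueError("labels/roles must match number of channels")
        bad = set(self.channel_roles) - {EEG, EMG}
        if bad:
            raise ValueError(f"unknown channel roles: {bad}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def eeg_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == EEG]

    def emg_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == EMG]

    def copy_with(self, data: np.ndarray) -> "TimeSeriesRecording":
        return TimeSeriesRecording(
            data=data,
            sample_rate_hz=self.sample_rate_hz,
            channel_labels=list(self.channel_labels),
            channel_roles=list(self.channel_roles),
            start_time=self.start_time,
        )


@dataclass
class SweepSet:
    """A set of voltage-clamp sweeps sharing a time base.

    ``data`` has shape ``(n_sweeps, n_samples)`` in pA. ``baseline_window``
    and ``light_window`` are ``(start_s, end_s)`` half-open intervals within
    a sweep; they must not overlap.
    """

    data: np.ndarray
    sample_rate_hz: float
    baseline_window: tuple[float, float] | None = None
    light_window: tuple[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        dur = self.data.shape[1] / self.sample_rate_hz
        for name, win in (("baseline", self.baseline_window), ("light", self.light_window)):
            if win is not None:
                lo, hi = win
                if not (0 <= lo < hi <= dur + 1e-9):
                    raise ValueError(f"{name} window {win} outside sweep duration {dur:.3f}s")
        if self.baseline_window and self.light_window:
            b, l = sorted([self.baseline_window, self.light_window])
            if b[1] > l[0] + 1e-12:
                raise ValueError("baseline and light windows overlap")

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz
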