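"""Readers, writers, run configuration and the end-to-end pipeline.

EEG/EMG interchange uses EDF (16-bit, physical units microvolts, one data
record per second); reading goes through MNE, writing through a compact
EDF encoder in this module. Voltage-clamp sweeps use an HDF5 container
with a JSON sidecar. All tabular outputs are CSV with stable formatting
so repeated runs of the same configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .core import EEG, EMG, SweepSet, TimeSeriesRecording

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed or unsupported file contents."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def write_edf(rec: TimeSeriesRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with one data record per second.

    Physical units are microvolts; per-channel physical min/max are taken
    from the data, so the quantization step is
    ``(max - min) / 65535`` per channel. The recording is zero-padded to
    a whole number of seconds.
    """
    path = Path(path)
    fs = rec.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sample rate")
    fs = int(round(fs))
    n_rec = int(np.ceil(rec.n_samples / fs))
    ns = rec.n_channels
    data = np.zeros((ns, n_rec * fs), dtype=float)
    data[:, : rec.n_samples] = rec.data

    # physical bounds rounded outward to 0.01 uV so the 8-char ascii
    # header fields still bound every sample (no clipping)
    pmins = np.floor(data.min(axis=1) * 100) / 100
    pmaxs = np.ceil(data.max(axis=1) * 100) / 100
    flat = pmaxs - pmins <= 0
    pmaxs[flat] = pmins[flat] + 1.0

    def f(x, width):  # fixed-width ascii field
        s = str(x)[:width]
        return s.ljust(width).encode("ascii")

    start = rec.start_time
    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),
            f("Startdate X X X X", 80),
            f(start.strftime("%d.%m.%y"), 8),
            f(start.strftime("%H.%M.%S"), 8),
            f(256 * (1 + ns), 8),
            f("", 44),
            f(n_rec, 8),
            f("1", 8),
            f(ns, 4),
        ]
    )

    def num(x):
        s = f"{x:.2f}"
        if len(s) > 8:  # |x| >= 10^5 uV: fall back to integer microvolts
            s = f"{x:.0f}"
        return s

    sig = b"".join(
        [
            b"".join(f(lbl, 16) for lbl in rec.channel_labels),
            b"".join(f("", 80) for _ in range(ns)),
            b"".join(f("uV", 8) for _ in range(ns)),
            b"".join(f(num(p), 8) for p in pmins),
            b"".join(f(num(p), 8) for p in pmaxs),
            b"".join(f(_EDF_DIG_MIN, 8) for _ in range(ns)),
            b"".join(f(_EDF_DIG_MAX, 8) for _ in range(ns)),
            b"".join(f("", 80) for _ in range(ns)),
            b"".join(f(fs, 8) for _ in range(ns)),
            b"".join(f("", 32) for _ in range(ns)),
        ]
    )

    # re-read the ascii physical bounds so the stored scaling matches the file
    pmins_w = np.array([float(num(p)) for p in pmins])
    pmaxs_w = np.array([float(num(p)) for p in pmaxs])
    gain = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmaxs_w - pmins_w)
    digital = np.clip(
        np.rint((data - pmins_w[:, None]) * gain[:, None] + _EDF_DIG_MIN),
        _EDF_DIG_MIN,
        _EDF_DIG_MAX,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # records: for each second, all samples of ch0, then ch1, ...
        recs = digital.reshape(ns, n_rec, fs)
        fh.write(np.ascontiguousarray(recs.transpose(1, 0, 2)).tobytes())


def _peek_edf_rates(path: Path) -> list[int]:
    """Samples-per-record per channel, straight from the header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header ({len(head)} bytes < 256)")
        try:
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as e:
            raise FormatError(f"{path}: bad channel count field at offset 252: {e}") from e
        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise FormatError(f"{path}: truncated signal headers")
        off = 216 * ns
        return [int(sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip()) for i in range(ns)]


def read_edf(
    path: str | Path,
    multirate: Literal["reject", "resample"] = "reject",
) -> TimeSeriesRecording:
    """Read an EDF file into a :class:`TimeSeriesRecording` (microvolts).

    Channels whose label contains ``EMG`` get the EMG role. Files whose
    channels are sampled at different rates are rejected by default;
    ``multirate="resample"`` lets MNE bring them to a common rate.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"{path}: empty or missing file")
    rates = _peek_edf_rates(path)
    if len(set(rates)) > 1 and multirate == "reject":
        raise FormatError(f"{path}: per-channel rates differ ({sorted(set(rates))}); "
                          "pass multirate='resample' to accept")
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE stores volts
    labels = list(raw.ch_names)
    roles = [EMG if "EMG" in lbl.upper() else EEG for lbl in labels]
    meas = raw.info["meas_date"]
    start = meas.astimezone(timezone.utc).replace(tzinfo=None) if meas else datetime(2000, 1, 1)
    return TimeSeriesRecording(
        data=data_uv,
        sample_rate_hz=float(raw.info["sfreq"]),
        channel_labels=labels,
        channel_roles=roles,
        start_time=start,
    )


# ---------------------------------------------------------------------------
# sweep container (HDF5 + JSON sidecar)
# ---------------------------------------------------------------------------

def write_sweeps(sweeps: SweepSet, path: str | Path) -> None:
    """HDF5 container: /data (sweeps x samples, pA) plus window attributes.

    Simulation/acquisition metadata goes to a ``.json`` sidecar next to
    the HDF5 file.
    """
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=sweeps.data)
        fh.attrs["sample_rate_hz"] = sweeps.sample_rate_hz
        if sweeps.baseline_window:
            fh.attrs["baseline_window_s"] = sweeps.baseline_window
        if sweeps.light_window:
            fh.attrs["light_window_s"] = sweeps.light_window
    if sweeps.metadata:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sweeps.metadata, default=_json_default, indent=2)
        )


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def read_sweeps(path: str | Path) -> SweepSet:
    path = Path(path)
    with h5py.File(path, "r") as fh:
        data = fh["data"][...]
        fs = float(fh.attrs["sample_rate_hz"])
        base = tuple(fh.attrs["baseline_window_s"]) if "baseline_window_s" in fh.attrs else None
        light = tuple(fh.attrs["light_window_s"]) if "light_window_s" in fh.attrs else None
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SweepSet(data=data, sample_rate_hz=fs, baseline_window=base,
                    light_window=light, metadata=meta)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterSettings(_Strict):
    low_hz: float = 0.5
    high_hz: float = 400.0
    order: int = 3


class FBRSettings(_Strict):
    f1: float = 100.0
    f2: float = 300.0
    f3: float = 0.5
    f4: float = 80.0


class SpikeSettings(_Strict):
    mad_multiplier: float = 5.0
    min_separation_ms: float = 40.0


class ThresholdSettings(_Strict):
    rms_percentile: float = 99.0
    fbr_percentile: float = 95.0
    spike_density_min: int = 1


class ClusterSettings(_Strict):
    min_episodes: int = 5
    max_iei_s: float = 60.0


class ClassifierSettings(_Strict):
    model_path: str | None = None
    threshold: float = 0.5


class EventSettings(_Strict):
    template: Literal["mipsc", "sepsc"] = "mipsc"
    criterion_threshold: float = 3.5
    lowpass_hz: float = 2000.0
    qc_alpha: float = 0.05


class RunConfig(_Strict):
    """Full parameterization of one pipeline run (JSON round-trippable)."""

    edf_path: str | None = None
    state_csv: str | None = None
    sweeps_path: str | None = None
    epoch_ms: float = 250.0
    filter: FilterSettings = FilterSettings()
    fbr: FBRSettings = FBRSettings()
    spikes: SpikeSettings = SpikeSettings()
    thresholds: ThresholdSettings = ThresholdSettings()
    cluster: ClusterSettings = ClusterSettings()
    classifier: ClassifierSettings = ClassifierSettings()
    events: EventSettings = EventSettings()
    seed: int = 0
    version: str = __version__


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage the configuration provides inputs for.

    Emits ``episodes.csv``, ``clusters.csv``, ``profile.csv`` (EEG stages),
    ``events.csv`` and ``quantal.json`` (patch stages) and a ``report.json``
    with stage timings, counts, QC flags and a configuration echo.
    """
    from . import classifier as clf_mod
    from . import events as ev_mod
    from . import quantal as q_mod
    from . import swd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config.model_dump(), "stages": {}, "counts": {}}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as e:  # noqa: BLE001 - rewrap with stage name
            report["stages"][name] = {"status": "failed", "error": str(e)}
            (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
            raise PipelineError(name, e) from e
        dt = time.perf_counter() - t0
        report["stages"][name] = {"status": "ok", "seconds": round(dt, 3)}
        logger.info("stage %-18s %.3fs", name, dt)
        return result

    if config.edf_path:
        rec = stage("read_edf", lambda: read_edf(config.edf_path))
        filtered = stage(
            "bandpass_filter",
            lambda: swd.bandpass_filter(rec, config.filter.low_hz, config.filter.high_hz, config.filter.order),
        )
        fbr_cfg = swd.FBRConfig(**config.fbr.model_dump())
        spike_cfg = swd.SpikeParams(**config.spikes.model_dump())
        features = stage(
            "epoch_features",
            lambda: swd.compute_epoch_features(filtered, config.epoch_ms, fbr_cfg, spike_cfg),
        )
        policy = swd.ThresholdPolicy(**config.thresholds.model_dump())
        candidates = stage("detect_candidates", lambda: swd.detect_candidates(features, policy=policy))
        report["counts"]["candidate_epochs"] = int(len(candidates))

        if config.classifier.model_path:
            model = stage("load_classifier", lambda: clf_mod.load_model(config.classifier.model_path))
            segs = clf_mod.extract_segments(filtered, candidates, config.epoch_ms,
                                            model.segment_length / filtered.sample_rate_hz)
            kept, _, _ = stage(
                "classify_candidates",
                lambda: clf_mod.classify_candidates(model, segs, config.classifier.threshold),
            )
            candidates = candidates[kept]
            report["counts"]["candidate_epochs_refined"] = int(len(candidates))

        episodes = stage(
            "assemble_episodes",
            lambda: swd.assemble_episodes(candidates, filtered, config.epoch_ms, spikes=spike_cfg),
        )
        if config.state_csv:
            states = pd.read_csv(config.state_csv)
            swd.annotate_states(episodes, list(states[["state", "start_s", "end_s"]].itertuples(index=False)))
        stage("find_clusters", lambda: swd.find_clusters(episodes, config.cluster.min_episodes, config.cluster.max_iei_s))
        clusters = [e.cluster_id for e in episodes if e.cluster_id is not None]
        profile = stage("rate_profile", lambda: swd.rate_profile(episodes, rec.start_time, rec.duration_s))
        report["counts"]["episodes"] = len(episodes)
        report["counts"]["clusters"] = len(set(clusters))
        _write_csv(swd.episodes_to_frame(episodes), out / "episodes.csv")
        cl = swd.find_clusters(episodes, config.cluster.min_episodes, config.cluster.max_iei_s)
        _write_csv(
            pd.DataFrame(
                [{"cluster_id": i, "onset_s": c.onset_s, "offset_s": c.offset_s, "n_episodes": c.n_episodes}
                 for i, c in enumerate(cl)]
            ),
            out / "clusters.csv",
        )
        _write_csv(profile, out / "profile.csv")

    if config.sweeps_path:
        sweeps = stage("read_sweeps", lambda: read_sweeps(config.sweeps_path))
        filtered_sw = stage("lowpass", lambda: ev_mod.lowpass_2khz(sweeps, config.events.lowpass_hz))
        template = ev_mod.MIPSC_TEMPLATE if config.events.template == "mipsc" else ev_mod.SEPSC_TEMPLATE
        ev = stage(
            "detect_events",
            lambda: ev_mod.detect_events(filtered_sw, template, config.events.criterion_threshold),
        )
        report["counts"]["events"] = int(len(ev))
        _write_csv(ev, out / "events.csv")
        est = stage("estimate_quantal", lambda: q_mod.estimate_quantal(ev, filtered_sw, config.events.qc_alpha))
        report["quantal"] = {
            "a_quantal_amplitude_pa": est.a_quantal_amplitude_pa,
            "a_quantal_charge_pc": est.a_quantal_charge_pc,
            "a_quantal_decay_ms": est.a_quantal_decay_ms,
            "f_light_hz": est.f_light_hz,
            "f_baseline_hz": est.f_baseline_hz,
            "n_evoked": est.n_evoked,
            "qc_significant": est.qc_significant,
            "qc_enough_events": est.qc_enough_events,
        }
        (out / "quantal.json").write_text(json.dumps(report["quantal"], indent=2, default=_json_default))

    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    return out
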