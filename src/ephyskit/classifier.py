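"""Convolutional refinement of SWD candidates.

The threshold stage is deliberately permissive; a small 1-D convolutional
network then scores each candidate segment (the three EEG channels around
the candidate epoch) and removes false positives. The network is a
pluggable, optional stage: the pipeline runs threshold-only when no model
is supplied.

Architecture: the first layer convolves 32 filters over non-overlapping
10-ms windows of the three-channel input (kernel size = stride = 10 ms of
samples), then two-conv blocks of 32, 64 and 128 filters, each block
followed by a 5x max pool; a global average pool, 50% dropout and a
single sigmoid unit produce the SWD probability. Training minimizes
binary cross entropy with Adadelta and stops early when the validation
loss has not decreased for three consecutive iterations (epochs).

With the default 5-kHz sampling, segments are 1.25 s (6250 samples): the
first layer maps them to 125 time steps and the three pools reduce
125 -> 25 -> 5 -> 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .core import TimeSeriesRecording

DEFAULT_SEGMENT_S = 1.25


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture and training hyperparameters."""

    conv_blocks: tuple = (32, 32, "pool", 64, 64, "pool", 128, 128, "pool")
    kernel_ms: float = 10.0  # first-layer kernel; stride equals kernel
    inner_kernel: int = 3  # stride-1 same-padding kernels in later convs
    pool_factor: int = 5
    dropout: float = 0.5
    patience: int = 3  # early stopping: val loss flat for this many iterations
    max_iterations: int = 50
    batch_size: int = 32
    decision_threshold: float = 0.5


@dataclass
class SWDClassifier:
    """A built (possibly trained) candidate classifier."""

    net: _nn.Sequential
    spec: ClassifierSpec
    segment_length: int
    sample_rate_hz: float
    n_channels: int = 3
    history: dict = field(default_factory=dict)

    def predict_proba(self, segments: np.ndarray) -> np.ndarray:
        """SWD probability per segment; dropout disabled, pure function."""
        x = _standardize(np.asarray(segments, dtype=float))
        self._check_shape(x)
        return _nn.sigmoid(self.net.forward(x, training=False))

    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 3 or x.shape[1] != self.n_channels or x.shape[2] != self.segment_length:
            raise ValueError(
                f"expected segments of shape (n, {self.n_channels}, {self.segment_length}), "
                f"got {x.shape}"
            )


def _standardize(x: np.ndarray) -> np.ndarray:
    """Per-segment zero-mean unit-SD scaling (per channel)."""
    mu = x.mean(axis=2, keepdims=True)
    sd = x.std(axis=2, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def build_model(
    spec: ClassifierSpec = ClassifierSpec(),
    segment_length: int | None = None,
    sample_rate_hz: float = 5000.0,
    n_channels: int = 3,
    seed: int = 0,
) -> SWDClassifier:
    """Assemble the network for a given segment geometry.

    Raises a shape error when the segment is too short for the stacked
    pools (the first-layer output must survive every 5x pool).
    """
    if segment_length is None:
        segment_length = int(round(DEFAULT_SEGMENT_S * sample_rate_hz))
    kernel = max(1, int(round(spec.kernel_ms / 1000.0 * sample_rate_hz)))
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    c_in, length, first = n_channels, segment_length, True
    for item in spec.conv_blocks:
        if item == "pool":
            if length // spec.pool_factor < 1:
                raise ValueError(
                    f"segment of {segment_length} samples too short for the stacked pools"
                )
            layers.append(_nn.MaxPool1d(spec.pool_factor))
            length //= spec.pool_factor
            continue
        c_out = int(item)
        if first:
            if segment_length < kernel:
                raise ValueError("segment shorter than the first-layer kernel")
            layers.append(_nn.Conv1d(c_in, c_out, kernel, stride=kernel, rng=rng))
            length //= kernel
            first = False
        else:
            layers.append(_nn.Conv1d(c_in, c_out, spec.inner_kernel, stride=1, rng=rng))
        layers.append(_nn.ReLU())
        c_in = c_out
    layers.append(_nn.GlobalAvgPool())
    layers.append(_nn.Dropout(spec.dropout, rng=np.random.default_rng(seed + 1)))
    layers.append(_nn.Dense(c_in, rng=rng))
    return SWDClassifier(
        net=_nn.Sequential(layers),
        spec=spec,
        segment_length=segment_length,
        sample_rate_hz=sample_rate_hz,
        n_channels=n_channels,
    )


def early_stop_iteration(val_losses: list[float], patience: int = 3) -> int | None:
    """Index after which training should stop, or None to continue.

    Training halts once the validation loss has failed to improve on its
    best value for ``patience`` consecutive iterations.
    """
    if not val_losses:
        return None
    best_i = int(np.argmin(val_losses))
    if len(val_losses) - 1 - best_i >= patience:
        return len(val_losses) - 1
    return None


def train(
    model: SWDClassifier,
    segments: np.ndarray,
    labels: np.ndarray,
    validation_split: float = 0.2,
    seed: int = 0,
) -> SWDClassifier:
    """Train on labeled segments; returns the model with ``history`` filled.

    ``history`` records per-iteration train/validation loss and accuracy.
    Raises on single-class data.
    """
    x = _standardize(np.asarray(segments, dtype=float))
    y = np.asarray(labels, dtype=float)
    model._check_shape(x)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_val = max(1, int(round(validation_split * len(y))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    xv, yv = x[val_idx], y[val_idx]
    xt, yt = x[tr_idx], y[tr_idx]

    opt = _nn.Adadelta(model.net.layers)
    hist: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "train_acc": [], "val_acc": []}
    best_state, best_loss = None, np.inf
    bs = model.spec.batch_size
    for _it in range(model.spec.max_iterations):
        perm = rng.permutation(len(yt))
        losses = []
        for s in range(0, len(yt), bs):
            idx = perm[s : s + bs]
            z = model.net.forward(xt[idx], training=True)
            loss, dz = _nn.bce_with_logits(z, yt[idx])
            model.net.backward(dz)
            opt.step()
            losses.append(loss)
        zt = model.net.forward(xt, training=False)
        zv = model.net.forward(xv, training=False)
        hist["train_loss"].append(_nn.bce_with_logits(zt, yt)[0])
        hist["val_loss"].append(_nn.bce_with_logits(zv, yv)[0])
        hist["train_acc"].append(float(np.mean((_nn.sigmoid(zt) >= 0.5) == (yt == 1))))
        hist["val_acc"].append(float(np.mean((_nn.sigmoid(zv) >= 0.5) == (yv == 1))))
        if hist["val_loss"][-1] < best_loss:
            best_loss = hist["val_loss"][-1]
            best_state = {k: v.copy() for k, v in model.net.state_dict().items()}
        if early_stop_iteration(hist["val_loss"], model.spec.patience) is not None:
            break
    if best_state is not None:
        model.net.load_state_dict(best_state)
    model.history = hist
    return model


def classify_candidates(
    model: SWDClassifier,
    segments: np.ndarray,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition candidates into retained / rejected by SWD probability.

    Returns ``(retained_indices, rejected_indices, probabilities)``; a
    candidate is retained iff its probability >= threshold, so the
    partition is exhaustive and disjoint and the classifier can only
    remove candidates, never add new ones.
    """
    if threshold is None:
        threshold = model.spec.decision_threshold
    probs = model.predict_proba(segments)
    keep = probs >= threshold
    idx = np.arange(len(probs))
    return idx[keep], idx[~keep], probs


def extract_segments(
    rec: TimeSeriesRecording,
    candidate_epochs: np.ndarray,
    epoch_ms: float = 250.0,
    segment_s: float = DEFAULT_SEGMENT_S,
) -> np.ndarray:
    """Cut fixed-length EEG segments centered on candidate epochs.

    Segments at the recording edges are zero-padded. Returns an array of
    shape ``(n_candidates, n_eeg_channels, segment_samples)``.
    """
    fs = rec.sample_rate_hz
    n_seg = int(round(segment_s * fs))
    n_ep = int(round(epoch_ms / 1000.0 * fs))
    eeg = rec.data[rec.eeg_indices()]
    out = np.zeros((len(candidate_epochs), eeg.shape[0], n_seg), dtype=float)
    for i, e in enumerate(np.asarray(candidate_epochs, dtype=int)):
        center = e * n_ep + n_ep // 2
        lo = center - n_seg // 2
        hi = lo + n_seg
        src_lo, src_hi = max(0, lo), min(eeg.shape[1], hi)
        out[i, :, src_lo - lo : src_lo - lo + (src_hi - src_lo)] = eeg[:, src_lo:src_hi]
    return out


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model: SWDClassifier, path: str | Path) -> None:
    """Write weights (npz) plus a JSON metadata sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.net.state_dict())
    meta = {
        "spec": {**model.spec.__dict__, "conv_blocks": list(model.spec.conv_blocks)},
        "segment_length": model.segment_length,
        "sample_rate_hz": model.sample_rate_hz,
        "n_channels": model.n_channels,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> SWDClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_d = dict(meta["spec"])
    spec_d["conv_blocks"] = tuple(spec_d["conv_blocks"])
    spec = ClassifierSpec(**spec_d)
    model = build_model(
        spec,
        segment_length=meta["segment_length"],
        sample_rate_hz=meta["sample_rate_hz"],
        n_channels=meta["n_channels"],
    )
    with np.load(path.with_suffix(".npz")) as data:
        model.net.load_state_dict(dict(data))
    return model
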