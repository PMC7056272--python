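"""Shared fixtures: synthetic recordings and a trained classifier.

The heavyweight objects (a one-hour EEG recording with its full detection
pass, and a trained candidate classifier) are session-scoped so the
end-to-end and acceptance tests reuse one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

from ephyskit import classifier as clf
from ephyskit import swd, synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@dataclass
class EEGBundle:
    config: synth.EEGSimConfig
    rec: object
    annotations: list
    filtered: object
    features: object
    candidates: np.ndarray
    episodes: list


def _overlap(a0, a1, b0, b1):
    return max(0.0, min(a1, b1) - max(a0, b0))


def episode_recall_precision(episodes, annotations):
    """Episode-level recall/precision against ground-truth SWD intervals."""
    swds = [a for a in annotations if a.event_kind == "SWD"]
    tp = sum(
        any(_overlap(e.onset_s, e.offset_s, a.onset_s, a.offset_s) > 0 for e in episodes)
        for a in swds
    )
    ptp = sum(
        any(_overlap(e.onset_s, e.offset_s, a.onset_s, a.offset_s) > 0 for a in swds)
        for e in episodes
    )
    recall = tp / len(swds) if swds else float("nan")
    precision = ptp / len(episodes) if episodes else float("nan")
    return recall, precision


@pytest.fixture(scope="session")
def eeg_hour() -> EEGBundle:
    """One hour of default synthetic EEG (~20 SWDs, some myoclonus) with
    the full threshold-stage detection pass."""
    config = synth.EEGSimConfig(duration_s=3600.0, seed=11, myoclonus_rate_per_hr=6.0)
    rec, annotations = synth.generate_eeg(config)
    filtered = swd.bandpass_filter(rec)
    features = swd.compute_epoch_features(filtered)
    candidates = swd.detect_candidates(features)
    episodes = swd.assemble_episodes(candidates, filtered)
    return EEGBundle(config, rec, annotations, filtered, features, candidates, episodes)


@dataclass
class ClassifierBundle:
    model: clf.SWDClassifier
    segments: np.ndarray
    labels: np.ndarray


@pytest.fixture(scope="session")
def trained_classifier() -> ClassifierBundle:
    """Classifier trained on a separable set: 200 SWD-morphology segments
    vs 200 background segments from one synthetic recording."""
    config = synth.EEGSimConfig(duration_s=900.0, swd_rate_per_hr=900.0, seed=21)
    rec, annotations = synth.generate_eeg(config)
    filtered = swd.bandpass_filter(rec)
    swds = [a for a in annotations if a.event_kind == "SWD"]
    pos = np.array([int((a.onset_s + a.offset_s) / 2 / 0.25) for a in swds])[:200]
    occupied = np.zeros(int(900 / 0.25) + 1, dtype=bool)
    for a in swds:
        occupied[int(a.onset_s / 0.25) : int(a.offset_s / 0.25) + 2] = True
    rng = np.random.default_rng(0)
    neg = np.array(
        [i for i in rng.permutation(len(occupied) - 10) if not occupied[max(0, i - 5) : i + 6].any()]
    )[:200]
    segments = clf.extract_segments(filtered, np.concatenate([pos, neg]))
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    model = clf.build_model(sample_rate_hz=rec.sample_rate_hz, seed=1)
    model = clf.train(model, segments, labels, seed=1)
    return ClassifierBundle(model, segments, labels)
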