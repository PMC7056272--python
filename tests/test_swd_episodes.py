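"""Candidate thresholding, episode assembly, cluster calling, rate profiles."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ephyskit import swd
from ephyskit.core import TimeSeriesRecording


def _features(rows):
    return pd.DataFrame(
        rows, columns=["epoch_index", "start_s", "channel", "rms", "spike_density", "fbr"]
    )


THRESHOLDS = {"rms": 10.0, "spike_density": 1, "fbr": 0.5}


class TestDetectCandidates:
    def test_all_below_threshold_gives_empty(self):
        feats = _features([[0, 0.0, "EEG1", 1.0, 0, 0.1], [1, 0.25, "EEG1", 2.0, 0, 0.2]])
        assert swd.detect_candidates(feats, THRESHOLDS).size == 0

    def test_conjunction_requires_all_features(self):
        """High RMS and FBR alone do not flag an epoch: every feature must pass."""
        feats = _features(
            [
                [0, 0.0, "EEG1", 50.0, 0, 2.0],  # spike density below threshold
                [1, 0.25, "EEG1", 50.0, 2, 2.0],  # all three pass
            ]
        )
        assert swd.detect_candidates(feats, THRESHOLDS).tolist() == [1]

    def test_any_channel_suffices(self):
        feats = _features(
            [
                [0, 0.0, "EEG1", 1.0, 0, 0.1],
                [0, 0.0, "EEG2", 50.0, 2, 2.0],
            ]
        )
        assert swd.detect_candidates(feats, THRESHOLDS).tolist() == [0]

    def test_missing_feature_column_is_schema_error(self):
        with pytest.raises(KeyError):
            swd.detect_candidates(pd.DataFrame({"epoch_index": [0]}), THRESHOLDS)

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_raising_any_threshold_never_adds_candidates(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        n = 50
        feats = _features(
            [
                [i, i * 0.25, "EEG1", rng.uniform(0, 20), rng.integers(0, 4), rng.uniform(0, 1)]
                for i in range(n)
            ]
        )
        base = dict(THRESHOLDS)
        key = data.draw(st.sampled_from(["rms", "spike_density", "fbr"]))
        bump = data.draw(st.floats(0.0, 5.0))
        raised = {**base, key: base[key] + bump}
        a = set(swd.detect_candidates(feats, base))
        b = set(swd.detect_candidates(feats, raised))
        assert b <= a


class TestAssembleEpisodes:
    FS = 5000.0

    def _rec_with_spikes(self, spike_times, duration=10.0, amp=50.0):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(duration * self.FS))
        for t in spike_times:
            x[int(t * self.FS)] += amp
        return TimeSeriesRecording(x[None, :], self.FS, ["EEG1"], ["EEG"])

    def test_adjacent_candidates_merge_into_one_episode(self):
        times = [2.05, 2.30, 2.55]  # spikes across epochs 8-10
        rec = self._rec_with_spikes(times)
        eps = swd.assemble_episodes([8, 9, 10], rec)
        assert len(eps) == 1
        assert eps[0].spike_count == 3

    def test_separated_candidates_make_two_episodes(self):
        times = [1.05, 1.30, 7.05, 7.30]
        rec = self._rec_with_spikes(times)
        eps = swd.assemble_episodes([4, 5, 28, 29], rec)
        assert len(eps) == 2

    def test_single_spike_run_is_discarded(self):
        rec = self._rec_with_spikes([2.1])
        assert swd.assemble_episodes([8], rec) == []

    def test_duration_and_rate_of_injected_discharge(self):
        """A 4-Hz, 1.5-s spike train yields ~4 Hz spike rate and ~1.5 s duration."""
        times = list(2.0 + np.arange(0, 1.501, 0.25))  # 7 spikes, 4 Hz
        rec = self._rec_with_spikes(times)
        eps = swd.assemble_episodes([8, 9, 10, 11, 12, 13], rec)
        assert len(eps) == 1
        assert eps[0].spike_rate_hz == pytest.approx(4.0, abs=0.5)
        assert eps[0].duration_s == pytest.approx(1.5, abs=0.25)
        assert eps[0].duration_s <= eps[0].offset_s - eps[0].onset_s + 0.5


def _episode(onset, offset):
    return swd.SWDEpisode(
        onset_s=onset, offset_s=offset, duration_s=offset - onset,
        spike_count=5, spike_rate_hz=4.0, channel="EEG1",
    )


def brute_force_clusters(episodes, min_episodes=5, max_iei_s=60.0):
    """Oracle: exhaustively test every contiguous window of episodes for the
    cluster predicate and keep maximal qualifying windows."""
    n = len(episodes)
    qualifying = []
    for i in range(n):
        for j in range(i + min_episodes - 1, n):
            gaps_ok = all(
                episodes[k + 1].onset_s - episodes[k].offset_s <= max_iei_s
                for k in range(i, j)
            )
            if gaps_ok:
                qualifying.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in qualifying
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in qualifying)
    ]
    return sorted(set(maximal))


class TestFindClusters:
    def test_four_episodes_never_cluster(self):
        eps = [_episode(i * 10.0, i * 10.0 + 1.0) for i in range(4)]
        assert swd.find_clusters(eps) == []

    def test_sixty_second_gap_is_inclusive(self):
        """Gaps of exactly 60 s still chain episodes together."""
        gaps = [10.0, 20.0, 59.0, 60.0]
        eps, t = [], 0.0
        for g in [0.0] + gaps:
            t += g
            eps.append(_episode(t, t + 1.0))
            t += 1.0
        clusters = swd.find_clusters(eps)
        assert len(clusters) == 1
        assert clusters[0].member_ids == [0, 1, 2, 3, 4]

    def test_gap_over_sixty_splits_runs_below_minimum(self):
        eps, t = [], 0.0
        for i in range(7):
            gap = 61.0 if i == 3 else 10.0
            t += gap
            eps.append(_episode(t, t + 1.0))
            t += 1.0
        assert swd.find_clusters(eps) == []  # runs of 3 and 4

    def test_episodes_must_be_sorted(self):
        with pytest.raises(ValueError):
            swd.find_clusters([_episode(10, 11), _episode(0, 1)])

    def test_matches_brute_force_on_randomized_episode_lists(self):
        """Linear-scan cluster calling agrees with the exhaustive window scan
        (1000 randomized lists of up to 30 episodes)."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(0, 31))
            t, eps = 0.0, []
            for _ in range(n):
                t += rng.choice([rng.uniform(0, 59), 60.0, rng.uniform(60.5, 200)])
                eps.append(_episode(t, t + rng.uniform(0.5, 3.0)))
                t = eps[-1].offset_s
            got = [(c.member_ids[0], c.member_ids[-1]) for c in swd.find_clusters(eps)]
            assert got == brute_force_clusters(eps)

    @settings(max_examples=200, deadline=None)
    @given(gaps=st.lists(st.floats(0.1, 200.0), max_size=15))
    def test_every_episode_in_at_most_one_cluster(self, gaps):
        eps, t = [], 0.0
        for g in gaps:
            eps.append(_episode(t, t + 1.0))
            t += 1.0 + g
        if gaps:
            eps.append(_episode(t, t + 1.0))
        clusters = swd.find_clusters(eps)
        members = [m for c in clusters for m in c.member_ids]
        assert len(members) == len(set(members))
        assert all(c.n_episodes >= 5 for c in clusters)


class TestRateProfile:
    def test_daily_event_at_half_past_two(self):
        start = datetime(2024, 1, 1, 0, 0, 0)
        eps = [_episode(d * 86400 + 2.5 * 3600, d * 86400 + 2.5 * 3600 + 2) for d in range(3)]
        prof = swd.rate_profile(eps, start, 3 * 86400.0)
        assert prof.loc[2, "mean_count"] == pytest.approx(1.0)
        other = prof.drop(index=2)
        assert (other["mean_count"] == 0).all()

    def test_counts_are_conserved(self):
        """sum(mean_count * hours_covered) recovers the total episode count."""
        rng = np.random.default_rng(7)
        start = datetime(2024, 1, 1, 13, 30, 0)  # deliberately off-hour start
        duration = 2.6 * 86400
        eps = [_episode(t, t + 1.0) for t in np.sort(rng.uniform(0, duration - 2, 137))]
        prof = swd.rate_profile(eps, start, duration)
        total = np.nansum(prof["mean_count"] * prof["hours_covered"])
        assert total == pytest.approx(137, abs=1e-6)
        assert prof["hours_covered"].sum() == pytest.approx(duration / 3600, abs=1e-6)

    def test_uniform_rate_gives_flat_profile(self):
        start = datetime(2024, 1, 1, 0, 0, 0)
        duration = 5 * 86400.0
        rng = np.random.default_rng(8)
        eps = [_episode(t, t + 1.0) for t in np.sort(rng.uniform(0, duration - 2, 2400))]
        prof = swd.rate_profile(eps, start, duration)
        assert prof["mean_count"].std() / prof["mean_count"].mean() < 0.25

    def test_empty_episode_list(self):
        prof = swd.rate_profile([], datetime(2024, 1, 1), 86400.0)
        assert (prof["mean_count"] == 0).all()

    def test_uncovered_hours_are_missing(self):
        prof = swd.rate_profile([], datetime(2024, 1, 1, 0, 0, 0), 3600.0)
        assert prof.loc[0, "mean_count"] == 0.0
        assert prof.loc[5, "mean_count"] != prof.loc[5, "mean_count"]  # NaN
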