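"""Greedy centroid matching, pipeline tracking, and wave-based ID filtering."""

import numpy as np
import pytest

from clawtrack import (
    PipelineConfig,
    SceneConfig,
    Track,
    filter_tracks,
    generate_scene,
    greedy_match,
    match_tracks_to_truth,
    run_tracking,
    tracks_to_dataframe,
)
from clawtrack.clustering import ClusterSet
from clawtrack.tracking import _TrackerState, match_ids

from .oracles import greedy_match_reference


def _clusters(centroids, speeds=None):
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    n = len(centroids)
    return ClusterSet(
        labels=np.arange(n),
        centroids=centroids,
        sizes=np.full(n, 2),
        mean_speeds=np.ones(n) if speeds is None else np.asarray(speeds, float),
    )


class TestGreedyMatch:
    def test_unique_nearest_continues_id(self):
        assert greedy_match([[10.0, 10.0]], [[12.0, 10.0]], 30) == [(0, 0)]

    def test_threshold_rejection(self):
        assert greedy_match([[10.0, 10.0]], [[100.0, 100.0]], 30) == []

    def test_contention_resolved_by_globally_smallest_distance(self):
        # distance 4 between track (0,0) and cluster (4,0) is globally smallest
        pairs = greedy_match([[0.0, 0], [10.0, 0]], [[4.0, 0], [6.0, 0]], 30)
        assert sorted(pairs) == [(0, 0), (1, 1)]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_reference_on_small_instances(self, seed):
        """Same pairs as the exhaustive repeated-full-scan greedy, up to 5x5."""
        rng = np.random.default_rng(seed)
        nr, nc = rng.integers(0, 6, size=2)
        rows = rng.uniform(0, 50, size=(nr, 2))
        cols = rng.uniform(0, 50, size=(nc, 2))
        max_dist = float(rng.uniform(5, 40))
        assert sorted(greedy_match(rows, cols, max_dist)) == sorted(
            greedy_match_reference(rows, cols, max_dist)
        )

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        rows = rng.uniform(0, 50, size=(5, 2))
        cols = rng.uniform(0, 50, size=(5, 2))
        perm = rng.permutation(5)
        base = set(greedy_match(rows, cols, 40))
        permuted = {(a, int(perm[b])) for a, b in greedy_match(rows, cols[perm], 40)}
        assert base == permuted

    def test_invalid_max_dist(self):
        with pytest.raises(ValueError):
            greedy_match([[0.0, 0]], [[1.0, 0]], 0)


class TestMatchIds:
    def test_new_id_for_unmatched_cluster_and_patience_closure(self):
        state = _TrackerState(n_frames=20)
        match_ids(state, _clusters([[10, 10]]), frame=1, max_dist=30, patience=2)
        assert [t.id for t in state.active] == [0]
        # far-away cluster: old track unmatched, new ID spawned
        match_ids(state, _clusters([[100, 100]]), frame=2, max_dist=30, patience=2)
        assert sorted(t.id for t in state.active) == [0, 1]
        # starve track 0 beyond patience
        for f in (3, 4, 5):
            match_ids(state, _clusters([[100, 100]]), frame=f, max_dist=30, patience=2)
        assert [t.id for t in state.active] == [1]
        assert [t.id for t in state.closed] == [0]

    def test_no_double_assignment(self):
        state = _TrackerState(n_frames=10)
        match_ids(state, _clusters([[0, 0], [10, 0]]), frame=1, max_dist=30, patience=5)
        match_ids(state, _clusters([[5, 0]]), frame=2, max_dist=30, patience=5)
        claimed = [t for t in state.active if t.defined[2]]
        assert len(claimed) == 1  # one cluster can continue only one track


class TestRunTracking:
    def test_static_scene_yields_no_tracks(self):
        cfg = SceneConfig(
            n_wavers=0, n_frames=20, width=128, height=96, noise_sigma=0.0, seed=1
        )
        seq, _ = generate_scene(cfg)
        tracks = run_tracking(seq)
        assert len(tracks) == 0

    def test_recovers_all_planted_wavers(self, small_scene, small_scene_tracks):
        seq, truth = small_scene
        tracks = small_scene_tracks
        assert len(tracks) == truth.n_wavers
        mapping = match_tracks_to_truth(truth, tracks)
        assert len(mapping) == truth.n_wavers
        cell = tracks.config.cell_size if tracks.config else 8
        for tid, widx in mapping.items():
            d = np.linalg.norm(
                tracks.by_id(tid).mean_position() - truth.orbit_centers[widx]
            )
            assert d <= cell

    def test_no_id_switches_on_clean_scene(self, small_scene, small_scene_tracks):
        """Each track stays near a single waver for its whole lifetime."""
        _, truth = small_scene
        for t in small_scene_tracks:
            pos = t.positions[t.defined]
            d = np.linalg.norm(pos[:, None, :] - truth.orbit_centers[None], axis=2)
            nearest = d.argmin(axis=1)
            assert np.all(nearest == nearest[0])

    def test_consecutive_steps_respect_max_distance(self, small_scene_tracks):
        cfg = small_scene_tracks.config or PipelineConfig()
        for t in small_scene_tracks:
            idx = np.nonzero(t.defined)[0]
            consec = np.diff(idx) == 1
            steps = np.linalg.norm(np.diff(t.positions[idx], axis=0), axis=1)[consec]
            assert np.all(steps <= cfg.max_distance + 1e-9)

    def test_deterministic_rerun(self):
        cfg = SceneConfig(
            n_wavers=2, n_frames=60, width=300, height=160, noise_sigma=1.0, seed=5
        )
        seq, _ = generate_scene(cfg)
        df1 = tracks_to_dataframe(run_tracking(seq))
        df2 = tracks_to_dataframe(run_tracking(seq))
        assert df1.equals(df2)


class TestFilterTracks:
    def _track_with_speeds(self, speeds, tid=0):
        speeds = np.asarray(speeds, dtype=float)
        t = Track(id=tid, n_frames=len(speeds))
        t.speeds = speeds
        t.positions[:] = 0.0
        t.first_frame, t.last_frame = 0, len(speeds) - 1
        return t

    def _track_set(self, tracks, frame_rate=30.0):
        from clawtrack.tracking import TrackSet

        return TrackSet(
            tracks=tracks,
            n_frames=tracks[0].n_frames,
            frame_rate=frame_rate,
            config=PipelineConfig(),
        )

    def test_track_without_peaks_removed(self):
        flat = self._track_with_speeds(np.zeros(100))
        assert len(filter_tracks(self._track_set([flat]), 1)) == 0

    def test_track_with_three_cycles_retained(self):
        t = np.arange(120)
        wavy = self._track_with_speeds(1 + np.sin(2 * np.pi * t / 30))  # 4 peaks
        assert len(filter_tracks(self._track_set([wavy]), 3)) == 1

    def test_single_burst_is_not_a_full_wave(self):
        burst = np.zeros(100)
        burst[40:50] = 2.0  # one transient bump: one peak, zero complete cycles
        assert len(filter_tracks(self._track_set([self._track_with_speeds(burst)]), 1)) == 0

    def test_mixed_population(self):
        t = np.arange(200)
        keep = self._track_with_speeds(1 + np.sin(2 * np.pi * t / 40), tid=0)
        burst = np.zeros(200)
        burst[20:26] = 1.0
        drop = self._track_with_speeds(burst, tid=1)
        out = filter_tracks(self._track_set([keep, drop]), 1)
        assert [tr.id for tr in out] == [0]


class TestTracksToDataframe:
    def test_columns_and_metric_conversion(self, small_scene_tracks):
        from dataclasses import replace

        ts = small_scene_tracks
        ts_metric = replace(ts, metric_scale=0.002)
        df = tracks_to_dataframe(ts_metric)
        assert list(df.columns) == [
            "frame", "time_s", "id", "x_px", "y_px", "x_m", "y_m", "speed_px_per_frame",
        ]
        assert np.allclose(df["x_m"], df["x_px"] * 0.002)
        assert (df["speed_px_per_frame"] >= 0).all()
        # without calibration the metric columns are NaN
        df2 = tracks_to_dataframe(ts)
        assert df2["x_m"].isna().all()
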