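"""Persistent-ID tracking by centroid matching, and the full pipeline driver.

Each frame's cluster centroids are matched to the live tracks from the
previous frame by Euclidean distance, greedily in order of globally smallest
distance, one-to-one, rejecting any pair farther apart than
``max_distance``. Unmatched clusters open new IDs; a track unmatched for
``patience`` consecutive frames is closed (a crab that leaves and reenters
gets a new ID — appearance-based re-identification is out of scope).

Greedy-global matching is used because per-cluster "nearest previous
centroid" is ambiguous when two clusters contend for one track; taking pairs
in increasing-distance order makes the assignment one-to-one, deterministic,
and independent of input ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterSet, MotionPointSet, cluster_centroids, dbscan
from .config import PipelineConfig
from .flow import FlowParams, downsample_flow, estimate_dense_flow, threshold_flow
from .video_io import FrameSequence, pixels_to_metric

logger = logging.getLogger(__name__)

__all__ = [
    "Track",
    "TrackSet",
    "greedy_match",
    "match_ids",
    "run_tracking",
    "filter_tracks",
    "tracks_to_dataframe",
]


def greedy_match(
    prev_positions: np.ndarray, centroids: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """One-to-one matching by globally smallest Euclidean distance.

    Candidate pairs within ``max_dist`` are taken in increasing distance
    order (ties broken by row then column index); a pair is accepted only if
    neither side is already matched. Returns accepted ``(row, col)`` index
    pairs. The result does not depend on the ordering of either input.
    """
    if not max_dist > 0:
        raise ValueError(f"max_dist must be positive, got {max_dist}")
    prev_positions = np.asarray(prev_positions, dtype=np.float64).reshape(-1, 2)
    centroids = np.asarray(centroids, dtype=np.float64).reshape(-1, 2)
    if len(prev_positions) == 0 or len(centroids) == 0:
        return []
    d = np.linalg.norm(prev_positions[:, None, :] - centroids[None, :, :], axis=2)
    ti, ci = np.nonzero(d <= max_dist)
    order = np.lexsort((ci, ti, d[ti, ci]))
    taken_row = np.zeros(len(prev_positions), dtype=bool)
    taken_col = np.zeros(len(centroids), dtype=bool)
    pairs = []
    for k in order:
        a, b = ti[k], ci[k]
        if taken_row[a] or taken_col[b]:
            continue
        taken_row[a] = True
        taken_col[b] = True
        pairs.append((int(a), int(b)))
    return pairs


@dataclass
class Track:
    """One persistent ID: per-frame centroid and mean cluster speed.

    ``positions[t]`` is NaN and ``speeds[t]`` is 0 on frames where the track
    was not matched (motion below threshold, or a detection gap shorter than
    the patience window). Arrays span the whole clip for easy alignment.
    """

    id: int
    n_frames: int
    positions: np.ndarray = field(default=None)  # (n_frames, 2), NaN where undefined
    speeds: np.ndarray = field(default=None)  # (n_frames,), 0 where undefined
    first_frame: int = -1
    last_frame: int = -1

    def __post_init__(self) -> None:
        if self.positions is None:
            self.positions = np.full((self.n_frames, 2), np.nan)
        if self.speeds is None:
            self.speeds = np.zeros(self.n_frames)

    def add(self, frame: int, position: np.ndarray, speed: float) -> None:
        self.positions[frame] = position
        self.speeds[frame] = speed
        if self.first_frame < 0:
            self.first_frame = frame
        self.last_frame = frame

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of frames where the track has a matched position."""
        return ~np.isnan(self.positions[:, 0])

    def mean_position(self) -> np.ndarray:
        return np.nanmean(self.positions, axis=0)


@dataclass
class TrackSet:
    """All tracks of one run plus the config that produced them."""

    tracks: list[Track]
    n_frames: int
    frame_rate: float
    metric_scale: float | None = None
    config: "PipelineConfig | None" = None

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def by_id(self, track_id: int) -> Track:
        for t in self.tracks:
            if t.id == track_id:
                return t
        raise KeyError(f"no track with id {track_id}")


class _TrackerState:
    """Mutable bookkeeping while scanning a clip frame by frame."""

    def __init__(self, n_frames: int) -> None:
        self.n_frames = n_frames
        self.next_id = 0
        self.active: list[Track] = []
        self.misses: dict[int, int] = {}
        self.closed: list[Track] = []

    def all_tracks(self) -> list[Track]:
        return sorted(self.closed + self.active, key=lambda t: t.id)


def match_ids(
    state: _TrackerState,
    clusters: ClusterSet,
    frame: int,
    max_dist: float,
    patience: int,
) -> None:
    """Assign this frame's clusters to live tracks, in place.

    Pairs (track, cluster) are taken in increasing distance order; a pair is
    accepted only if both sides are still unmatched and the distance is
    within ``max_dist``. Leftover clusters spawn new IDs; tracks unmatched
    for more than ``patience`` consecutive frames are closed.
    """
    if not max_dist > 0:
        raise ValueError(f"max_dist must be positive, got {max_dist}")
    n_tracks = len(state.active)
    n_clusters = clusters.n_clusters
    matched_track = np.zeros(n_tracks, dtype=bool)
    matched_cluster = np.zeros(n_clusters, dtype=bool)

    if n_tracks and n_clusters:
        prev = np.array([t.positions[t.last_frame] for t in state.active])
        for a, b in greedy_match(prev, clusters.centroids, max_dist):
            matched_track[a] = True
            matched_cluster[b] = True
            state.active[a].add(frame, clusters.centroids[b], clusters.mean_speeds[b])
            state.misses[state.active[a].id] = 0

    # unmatched clusters -> new IDs
    for b in np.nonzero(~matched_cluster)[0]:
        t = Track(id=state.next_id, n_frames=state.n_frames)
        t.add(frame, clusters.centroids[b], clusters.mean_speeds[b])
        state.active.append(t)
        state.misses[t.id] = 0
        state.next_id += 1

    # unmatched tracks age out after `patience` consecutive missed frames
    survivors = []
    for idx, t in enumerate(state.active[:n_tracks]):
        if matched_track[idx]:
            survivors.append(t)
            continue
        state.misses[t.id] += 1
        if state.misses[t.id] > patience:
            state.closed.append(t)
            del state.misses[t.id]
        else:
            survivors.append(t)
    state.active = survivors + state.active[n_tracks:]


def run_tracking(frames: FrameSequence, config: PipelineConfig | None = None) -> TrackSet:
    """Run the full per-frame pipeline on a clip.

    For every consecutive frame pair: dense flow -> grid averaging ->
    magnitude threshold -> DBSCAN on the surviving cells -> centroid
    matching against live tracks. The per-frame speed recorded on a track is
    the mean cell speed of its matched cluster.

    Flow between frames t and t+1 is attributed to frame t+1 (motion is
    observed on arrival), so tracks span frames 1..n-1 of an n-frame clip.
    """
    config = config or PipelineConfig()
    params = FlowParams(
        levels=config.flow_levels, window=config.flow_window, iterations=config.flow_iterations
    )
    state = _TrackerState(n_frames=len(frames))
    for t in range(1, len(frames)):
        fl = estimate_dense_flow(frames.frames[t - 1], frames.frames[t], params)
        grid = threshold_flow(downsample_flow(fl, config.cell_size), config.speed_cutoff)
        pts = MotionPointSet.from_grid(grid)
        labels = dbscan(pts, eps=config.epsilon, min_pts=config.minpts)
        clusters = cluster_centroids(pts, labels)
        match_ids(state, clusters, t, config.max_distance, config.patience)
        logger.debug(
            "frame %d: %d motion points, %d clusters, %d active tracks",
            t, len(pts), clusters.n_clusters, len(state.active),
        )
    return TrackSet(
        tracks=state.all_tracks(),
        n_frames=len(frames),
        frame_rate=frames.frame_rate,
        metric_scale=frames.metric_scale,
        config=config,
    )


def filter_tracks(tracks: TrackSet, min_full_waves: int = 1, config: PipelineConfig | None = None) -> TrackSet:
    """Keep only IDs that completed at least ``min_full_waves`` wave cycles.

    A full wave is one complete cycle, i.e. two successive detected speed
    peaks — the smallest unit on which a phase is definable. IDs not present
    for a full movement (transient noise blobs, crabs clipped at the clip
    boundary) are discarded; this is the spurious-ID filter applied before
    any synchrony analysis.
    """
    from .wave_sync import detect_peaks, smooth_series

    config = config or tracks.config or PipelineConfig()
    min_sep = max(1, int(round(config.min_separation_s * tracks.frame_rate)))
    prominence = config.wave_min_prominence
    kept = []
    for t in tracks.tracks:
        smoothed = smooth_series(t.speeds, config.smooth_window)
        peaks = detect_peaks(smoothed, min_prominence=prominence, min_separation=min_sep)
        if max(0, len(peaks) - 1) >= min_full_waves:
            kept.append(t)
    return TrackSet(
        tracks=kept,
        n_frames=tracks.n_frames,
        frame_rate=tracks.frame_rate,
        metric_scale=tracks.metric_scale,
        config=config,
    )


def tracks_to_dataframe(tracks: TrackSet) -> pd.DataFrame:
    """Flatten a TrackSet to one row per (frame, active id).

    Columns: ``frame, time_s, id, x_px, y_px, x_m, y_m, speed_px_per_frame``.
    Metric columns are NaN when no meters-per-pixel calibration is set.
    """
    rows = []
    for t in tracks.tracks:
        for f in np.nonzero(t.defined)[0]:
            x, y = t.positions[f]
            if tracks.metric_scale is not None:
                xm, ym = pixels_to_metric((x, y), tracks.metric_scale)
            else:
                xm = ym = np.nan
            rows.append((f, f / tracks.frame_rate, t.id, x, y, xm, ym, t.speeds[f]))
    df = pd.DataFrame(
        rows, columns=["frame", "time_s", "id", "x_px", "y_px", "x_m", "y_m", "speed_px_per_frame"]
    )
    return df.sort_values(["frame", "id"], kind="stable").reset_index(drop=True)
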