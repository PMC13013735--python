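"""Ground-truthed synthetic scenes standing in for field footage.

Field recordings of waving crabs are not distributable, so every pipeline
stage is exercised on rendered scenes that emulate the regime the tracker
was built for: 30 fps video of many small, near-stationary individuals,
each producing brief periodic local motion — the claw wave — on a static
textured background, optionally under per-frame Gaussian pixel noise.

Each synthetic crab is a static body blob plus a small bright claw patch
(~15 px across) orbiting the claw's rest point. The orbit's angular speed is
modulated once per cycle, ``omega(s) proportional to 1 - m*cos(2*pi*s)``, so
the claw speed trace has exactly one maximum per wave — the planted "time of
maximum speed" the analysis chain must recover — and, unlike a 1-D
out-and-back stroke (which necessarily stalls and peaks twice per cycle),
never stops while the crab is actively waving. ``duty_cycle < 1`` inserts a
motionless pause into each period, exercising the detection-gap and
active-waving masking behavior.

The scene is fully determined by the seed: same config + seed gives
bit-identical frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .video_io import FrameSequence
from .wave_sync import PhaseSeries, interpolate_phase, kuramoto_R

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "generate_scene",
    "planted_sync",
    "write_scene",
    "match_tracks_to_truth",
]


@dataclass
class SceneConfig:
    """Parameters of a synthetic claw-waving scene.

    Defaults describe the regime the pipeline targets: 30 fps, a 20 s clip,
    10 well-separated crabs whose claws span ~15 px, waving every 1.5 s
    (fiddler crabs typically wave every one to a few seconds), on a static
    low-contrast textured background with mild sensor noise.
    """

    width: int = 480
    height: int = 360
    n_frames: int = 600
    frame_rate: float = 30.0
    n_wavers: int = 10
    body_radius: float = 6.0
    claw_size: float = 15.0  # px; claw patch footprint and orbit diameter
    wave_period_s: float | tuple | list = 1.5  # scalar or one value per waver
    wave_phase_offset: tuple | list | None = None  # radians; None -> random per waver
    duty_cycle: float = 1.0  # fraction of each period with claw motion
    min_separation: float = 110.0  # px between body centers
    noise_sigma: float = 2.0  # per-frame Gaussian pixel noise (0-255 intensity scale)
    speed_modulation: float = 0.45  # depth m of the once-per-cycle speed modulation
    claw_sigma_frac: float = 0.2  # claw patch Gaussian sigma as a fraction of claw_size
    seed: int = 0

    # rendering constants (intensity units on a 0-255 scale)
    background_level: float = 120.0
    background_contrast: float = 12.0
    body_amplitude: float = 25.0
    claw_amplitude: float = 90.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.n_wavers < 0:
            raise ValueError("n_wavers must be >= 0")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError(f"duty_cycle must be in (0, 1], got {self.duty_cycle}")
        if not 0 <= self.speed_modulation < 1:
            raise ValueError(f"speed_modulation must be in [0, 1), got {self.speed_modulation}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def periods(self) -> np.ndarray:
        p = np.asarray(self.wave_period_s, dtype=np.float64)
        if p.ndim == 0:
            p = np.full(self.n_wavers, float(p))
        if len(p) != self.n_wavers:
            raise ValueError(f"need {self.n_wavers} periods, got {len(p)}")
        if self.n_wavers and not np.all(p > 0):
            raise ValueError("wave periods must be positive")
        return p

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class GroundTruth:
    """Everything planted in a scene, for recovery checks.

    ``peak_times`` holds, per waver, the exact times (s) of maximum claw
    speed — one per wave cycle. ``planted_phases`` applies the same
    phase-zero-at-peak, linear-in-between convention the analysis chain
    uses, so planted and recovered phases are directly comparable.
    """

    centers: np.ndarray  # (n, 2) body centers, px
    orbit_centers: np.ndarray  # (n, 2) claw orbit centers, px
    orientations: np.ndarray  # (n,) claw orbit orientation, rad
    periods: np.ndarray  # (n,) s
    phase_offsets: np.ndarray  # (n,) rad
    peak_times: list[np.ndarray]  # per waver, s
    config: SceneConfig

    @property
    def n_wavers(self) -> int:
        return len(self.centers)

    def planted_phases(self, times: np.ndarray) -> list[PhaseSeries]:
        return [
            interpolate_phase(pk, times, track_id=i) for i, pk in enumerate(self.peak_times)
        ]

    def planted_speeds(self, times: np.ndarray) -> np.ndarray:
        """Exact claw speed (px/frame) of each waver at each time, (n, t)."""
        cfg = self.config
        out = np.zeros((self.n_wavers, len(times)))
        for i in range(self.n_wavers):
            T = self.periods[i]
            shift = self.phase_offsets[i] / (2 * np.pi) * T
            tau = np.mod(np.asarray(times) + shift, T)
            s = tau / (cfg.duty_cycle * T)
            active = s < 1.0
            omega = (2 * np.pi / (cfg.duty_cycle * T)) * (
                1 - cfg.speed_modulation * np.cos(2 * np.pi * s)
            )
            speed = (cfg.claw_size / 2) * omega / cfg.frame_rate  # px per frame
            out[i] = np.where(active, speed, 0.0)
        return out


def _place_centers(cfg: SceneConfig, rng: np.random.Generator, margin: float) -> np.ndarray:
    """Place waver centers pairwise >= min_separation, fully inside the frame.

    Feasibility is judged by square-lattice capacity up front (slightly
    conservative for packings only a denser arrangement could hold); then
    rejection sampling is tried for natural-looking layouts, with a random
    subset of the lattice as fallback when the packing is tight.
    """
    n, sep = cfg.n_wavers, cfg.min_separation
    lo = np.array([margin, margin])
    hi = np.array([cfg.width - margin, cfg.height - margin])
    if n == 0:
        return np.zeros((0, 2))
    if np.any(hi < lo):
        raise ValueError(
            f"frame {cfg.width}x{cfg.height} too small for the waver footprint "
            f"(needs a {margin:.0f} px margin)"
        )
    nx = int((hi[0] - lo[0]) // sep) + 1
    ny = int((hi[1] - lo[1]) // sep) + 1
    if nx * ny < n:
        raise ValueError(
            f"cannot place {n} wavers with min_separation={sep} in a "
            f"{cfg.width}x{cfg.height} frame (margin {margin:.0f}): "
            f"a {nx}x{ny} lattice holds only {nx * ny}"
        )

    for _ in range(10):  # rejection sampling restarts
        pts: list[np.ndarray] = []
        for _ in range(200 * n):
            cand = rng.uniform(lo, hi)
            if all(np.linalg.norm(cand - p) >= sep for p in pts):
                pts.append(cand)
                if len(pts) == n:
                    return np.array(pts)

    xs = np.linspace(lo[0], hi[0], nx)
    ys = np.linspace(lo[1], hi[1], ny)
    grid = np.array([(x, y) for y in ys for x in xs])
    idx = rng.permutation(len(grid))[:n]
    return grid[idx]


def _claw_positions(truth: GroundTruth, t_s: float) -> np.ndarray:
    """Claw patch center of each waver at time ``t_s`` (s)."""
    cfg = truth.config
    pos = np.empty((truth.n_wavers, 2))
    for i in range(truth.n_wavers):
        T = truth.periods[i]
        shift = truth.phase_offsets[i] / (2 * np.pi) * T
        tau = (t_s + shift) % T
        s = tau / (cfg.duty_cycle * T)
        if s < 1.0:  # actively waving: orbit angle with once-per-cycle speed modulation
            theta = 2 * np.pi * s - cfg.speed_modulation * np.sin(2 * np.pi * s)
        else:  # pause: claw rests at the cycle start/end point
            theta = 0.0
        ang = theta + truth.orientations[i]
        r = cfg.claw_size / 2
        pos[i] = truth.orbit_centers[i] + r * np.array([np.cos(ang), np.sin(ang)])
    return pos


def _add_blob(img: np.ndarray, x: float, y: float, sigma: float, amplitude: float) -> None:
    """Add a Gaussian intensity blob at (x, y), rendered in a local window."""
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
    )


def generate_scene(cfg: SceneConfig | None = None) -> tuple[FrameSequence, GroundTruth]:
    """Render a scene and return the frames with their ground truth."""
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)

    arm = cfg.body_radius + 4.0  # claw orbit center sits just off the body
    claw_sigma = cfg.claw_sigma_frac * cfg.claw_size
    margin = arm + cfg.claw_size / 2 + 4 * claw_sigma + 2
    centers = _place_centers(cfg, rng, margin)

    arm_angle = rng.uniform(0, 2 * np.pi, size=cfg.n_wavers)
    orbit_centers = centers + arm * np.column_stack([np.cos(arm_angle), np.sin(arm_angle)])
    orientations = rng.uniform(0, 2 * np.pi, size=cfg.n_wavers)
    if cfg.wave_phase_offset is None:
        offsets = rng.uniform(0, 2 * np.pi, size=cfg.n_wavers)
    else:
        offsets = np.asarray(cfg.wave_phase_offset, dtype=np.float64)
        if len(offsets) != cfg.n_wavers:
            raise ValueError(f"need {cfg.n_wavers} phase offsets, got {len(offsets)}")

    periods = cfg.periods
    # planted speed maxima: cycle-local time tau = d*T/2, unwrapped to clip time
    peak_times = []
    for i in range(cfg.n_wavers):
        T = periods[i]
        shift = offsets[i] / (2 * np.pi) * T
        t_pk = cfg.duty_cycle * T / 2 - shift
        ks = np.arange(np.ceil(-t_pk / T), np.floor((cfg.duration_s - t_pk) / T) + 1)
        pk = t_pk + ks * T
        peak_times.append(pk[(pk >= 0) & (pk < cfg.duration_s)])

    truth = GroundTruth(
        centers=centers,
        orbit_centers=orbit_centers,
        orientations=orientations,
        periods=periods,
        phase_offsets=offsets,
        peak_times=peak_times,
        config=cfg,
    )

    # static layer: textured background + body blobs
    texture = gaussian_filter(rng.normal(0.0, 1.0, (cfg.height, cfg.width)), 2.0)
    if texture.std() > 0:
        texture *= cfg.background_contrast / texture.std()
    static = cfg.background_level + texture
    for cx, cy in centers:
        _add_blob(static, cx, cy, cfg.body_radius / 2 + 1.0, cfg.body_amplitude)

    frames = np.empty((cfg.n_frames, cfg.height, cfg.width), dtype=np.float64)
    for f in range(cfg.n_frames):
        img = static.copy()
        for x, y in _claw_positions(truth, f / cfg.frame_rate):
            _add_blob(img, x, y, claw_sigma, cfg.claw_amplitude)
        if cfg.noise_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
        frames[f] = np.clip(img, 0.0, 255.0)

    return FrameSequence(frames, frame_rate=cfg.frame_rate), truth


def planted_sync(truth: GroundTruth, times: np.ndarray) -> np.ndarray:
    """Kuramoto R over the planted phases at each requested time.

    NaN wherever fewer than two wavers have a defined planted phase.
    """
    if truth.n_wavers < 2:
        raise ValueError("planted synchrony needs at least 2 wavers")
    series = truth.planted_phases(np.asarray(times, dtype=np.float64))
    phases = np.vstack([s.phase for s in series])
    return np.array([kuramoto_R(phases[:, j]) for j in range(phases.shape[1])])


def match_tracks_to_truth(truth: GroundTruth, tracks, max_dist: float = 30.0) -> dict[int, int]:
    """Pair recovered tracks with planted wavers by position.

    A track's time-mean position sits at the claw's orbit center, so tracks
    are matched one-to-one to orbit centers, greedily by distance. Returns
    ``{track_id: waver_index}``; unmatched tracks (spurious IDs) and
    unmatched wavers (misses) are simply absent.
    """
    from .tracking import greedy_match

    track_list = list(tracks)
    if not track_list or truth.n_wavers == 0:
        return {}
    means = np.array([t.mean_position() for t in track_list])
    pairs = greedy_match(means, truth.orbit_centers, max_dist)
    return {track_list[a].id: b for a, b in pairs}


def write_scene(
    out_dir: str | Path, cfg: SceneConfig | None = None
) -> tuple[FrameSequence, GroundTruth]:
    """Render a scene to a numbered-PNG directory plus ground-truth CSVs.

    Writes ``frames/frame_000000.png`` ..., ``centers.csv`` (id,x,y),
    ``peaks.csv`` (id,peak_time_s), and ``scene.yaml`` (the full config),
    then returns the in-memory scene as well.
    """
    import imageio.v3 as iio
    import pandas as pd
    import yaml

    cfg = cfg or SceneConfig()
    seq, truth = generate_scene(cfg)
    out = Path(out_dir)
    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    for f, frame in enumerate(seq.frames):
        iio.imwrite(
            frames_dir / f"frame_{f:06d}.png", np.round(frame).clip(0, 255).astype(np.uint8)
        )
    pd.DataFrame(
        {"id": np.arange(truth.n_wavers), "x": truth.centers[:, 0], "y": truth.centers[:, 1]}
    ).to_csv(out / "centers.csv", index=False)
    rows = [(i, t) for i, pk in enumerate(truth.peak_times) for t in pk]
    pd.DataFrame(rows, columns=["id", "peak_time_s"]).to_csv(out / "peaks.csv", index=False)
    cfg_dict = {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                for k, v in vars(cfg).items()}
    (out / "scene.yaml").write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    return seq, truth
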