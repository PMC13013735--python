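"""Pipeline configuration: every user-set parameter in one place.

All stages read their knobs from a single :class:`PipelineConfig`, which can
be loaded from / dumped to a nested YAML file (``flow.window``,
``dbscan.epsilon``, ...). A serialized copy is written next to every output
for provenance. Defaults follow the field-video regime the pipeline was
built for: 30 fps footage of small (~15 px) crabs, DBSCAN radius 30 px and
minimum cluster size 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]

# dataclass attribute -> nested YAML/CLI key
_KEY_MAP = {
    "start_frame": "io.start_frame",
    "frame_count": "io.frame_count",
    "frame_rate": "io.frame_rate",
    "metric_scale": "io.metric_scale",
    "flow_levels": "flow.levels",
    "flow_window": "flow.window",
    "flow_iterations": "flow.iterations",
    "cell_size": "grid.cell_size",
    "speed_cutoff": "grid.speed_cutoff",
    "epsilon": "dbscan.epsilon",
    "minpts": "dbscan.minpts",
    "max_distance": "track.max_distance",
    "patience": "track.patience",
    "min_full_waves": "track.min_full_waves",
    "smooth_window": "wave.smooth_window",
    "min_prominence": "wave.min_prominence",
    "min_separation_s": "wave.min_separation_s",
    "chance_reps": "sync.chance_reps",
    "seed": "sync.seed",
}


@dataclass
class PipelineConfig:
    """All tunable parameters of the tracking + synchrony pipeline.

    Units: distances in pixels, speeds in px per frame interval, durations
    in seconds unless suffixed otherwise.
    """

    # --- input ---
    start_frame: int = 0
    frame_count: int | None = None
    frame_rate: float | None = None  # for image directories; containers carry their own
    metric_scale: float | None = None  # meters per pixel; None = no calibration

    # --- dense flow ---
    flow_levels: int = 3
    flow_window: int = 15
    flow_iterations: int = 3

    # --- grid downsampling / filtering ---
    cell_size: int = 8
    speed_cutoff: float = 0.28  # px/frame; calibrated so background noise yields zero cells

    # --- DBSCAN ---
    epsilon: float = 30.0
    minpts: int = 2

    # --- ID tracking ---
    max_distance: float = 30.0  # px; maxDistanceThreshold for centroid matching
    patience: int = 10  # frames a track may go unmatched before closing
    min_full_waves: int = 1

    # --- wave extraction ---
    smooth_window: int = 9  # frames, odd; ~0.3 s at 30 fps, matching the peak-separation scale
    min_prominence: float | None = None  # None -> speed_cutoff / 2 (see wave_min_prominence)
    min_separation_s: float = 0.3

    # --- synchrony ---
    chance_reps: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size < 1:
            raise ValueError(f"cell_size must be >= 1, got {self.cell_size}")
        if self.speed_cutoff < 0:
            raise ValueError(f"speed_cutoff must be >= 0, got {self.speed_cutoff}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.minpts < 1:
            raise ValueError(f"minpts must be >= 1, got {self.minpts}")
        if not self.max_distance > 0:
            raise ValueError(f"max_distance must be positive, got {self.max_distance}")
        if self.patience < 0:
            raise ValueError(f"patience must be >= 0, got {self.patience}")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError(f"smooth_window must be odd and >= 1, got {self.smooth_window}")

    @property
    def wave_min_prominence(self) -> float:
        """Peak prominence threshold; defaults to half the grid speed cutoff.

        The cluster speed trace is a cell-averaged quantity whose dynamic
        range is compressed relative to the true claw speed (slow periphery
        cells enter the average as the claw speeds up), so a prominence
        equal to the full cutoff can reject genuine waves. Half the cutoff
        still sits well above smoothed background fluctuations, which the
        cutoff calibration bounds at the raw (unsmoothed) noise ceiling.
        """
        return self.speed_cutoff / 2.0 if self.min_prominence is None else self.min_prominence

    # --- (de)serialization -------------------------------------------------

    def to_nested_dict(self) -> dict:
        out: dict = {}
        for f in fields(self):
            section, key = _KEY_MAP[f.name].split(".")
            out.setdefault(section, {})[key] = getattr(self, f.name)
        return out

    @classmethod
    def from_nested_dict(cls, data: dict) -> "PipelineConfig":
        flat = {}
        reverse = {v: k for k, v in _KEY_MAP.items()}
        for section, entries in (data or {}).items():
            if not isinstance(entries, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            for key, value in entries.items():
                dotted = f"{section}.{key}"
                if dotted not in reverse:
                    raise ValueError(f"unknown config key {dotted!r}")
                flat[reverse[dotted]] = value
        return cls(**flat)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_nested_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_nested_dict(yaml.safe_load(Path(path).read_text()) or {})

    def replace(self, **updates) -> "PipelineConfig":
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(updates)
        return PipelineConfig(**values)
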