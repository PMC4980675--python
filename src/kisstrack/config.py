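"""Configuration dataclasses shared across the pipeline.

All lengths are millimetres, times are seconds, angles are degrees unless a
field name says otherwise.  Image coordinates are (row, col), 0-based, with
row increasing downwards; world coordinates are (x, y) in mm with
x = col / px_per_mm and y = row / px_per_mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SceneConfig:
    """Parameters of a synthetic two-channel larval crawling scene.

    Defaults mirror the standard assay conditions this simulator emulates:
    12 third-instar larvae, half of them GFP-positive, on a 9.5 cm agar
    arena filmed at 10 frames per second, crawling about one body length
    (4 mm) per 5 seconds, with collision contacts whose KISS interval lasts
    1-2 s.
    """

    arena_diameter: float = 95.0   # mm
    n_larvae: int = 12
    gfp_flags: Sequence[bool] | None = None   # default: first half GFP-positive
    body_length: float = 4.0       # mm
    body_width: float = 0.8        # mm
    fps: float = 10.0              # frames / s
    duration: float = 60.0         # s
    px_per_mm: float = 10.0
    image_size: int = 1024         # square frames, px
    speed: float = 0.2             # body lengths / s  (one length per 5 s)
    reorientation_rate: float = 0.1   # spontaneous head-cast episodes / s
    kiss_duration_range: tuple[float, float] = (1.0, 2.0)  # s
    noise_sd: float = 0.02         # additive intensity noise (images in [0, 1])
    seed: int = 0
    n_spine: int = 11
    # Scripted pairwise collisions: (id_a, id_b, earliest_start_s, duration_s).
    collisions: Sequence[tuple[int, int, float, float]] = field(default_factory=list)
    pixel_dtype: str = "float"     # "float" | "uint8" | "uint16" (on write)

    def __post_init__(self) -> None:
        if self.n_larvae < 1:
            raise ConfigError("n_larvae must be >= 1")
        for name in ("arena_diameter", "body_length", "body_width", "px_per_mm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.fps <= 0:
            raise ConfigError("fps must be > 0")
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        lo, hi = self.kiss_duration_range
        if lo > hi:
            raise ConfigError("kiss_duration_range low must be <= high")
        if self.n_spine < 5 or self.n_spine % 2 == 0:
            raise ConfigError("n_spine must be odd and >= 5")
        if self.gfp_flags is None:
            half = self.n_larvae // 2
            self.gfp_flags = tuple(i < half for i in range(self.n_larvae))
        else:
            self.gfp_flags = tuple(bool(f) for f in self.gfp_flags)
            if len(self.gfp_flags) != self.n_larvae:
                raise ConfigError("gfp_flags length must equal n_larvae")
        for ia, ib, t0, dur in self.collisions:
            if ia == ib or not (0 <= ia < self.n_larvae and 0 <= ib < self.n_larvae):
                raise ConfigError(f"invalid collision pair ({ia}, {ib})")
            if dur <= 0:
                raise ConfigError("collision duration must be > 0")

    # Derived quantities -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    @property
    def go_speed(self) -> float:
        """GO-phase crawling speed in mm/s."""
        return self.speed * self.body_length

    @property
    def go_step(self) -> float:
        """GO-phase displacement per frame in mm."""
        return self.go_speed / self.fps

    @property
    def arena_radius(self) -> float:
        return self.arena_diameter / 2.0

    @property
    def arena_center(self) -> tuple[float, float]:
        c = self.image_size / 2.0 / self.px_per_mm
        return (c, c)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gfp_flags"] = list(self.gfp_flags)
        d["collisions"] = [list(c) for c in self.collisions]
        d["kiss_duration_range"] = list(self.kiss_duration_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "kiss_duration_range" in d:
            d["kiss_duration_range"] = tuple(d["kiss_duration_range"])
        if "collisions" in d:
            d["collisions"] = [tuple(c) for c in d["collisions"]]
        return cls(**d)


@dataclass
class PipelineConfig:
    """Parameters of the tracking / collision / behavior pipeline."""

    fps: float = 10.0
    px_per_mm: float = 10.0
    body_length: float = 4.0         # mm, reference for gating and degeneracy checks
    body_width: float = 0.8          # mm

    # segmentation
    ir_threshold: float = 0.3        # fixed intensity threshold on the IR channel
    auto_threshold: bool = False     # between-class-variance (Otsu) mode
    min_area: int = 20               # px^2, components below are dropped
    merged_area_factor: float = 1.5  # area > factor x single-animal reference => MERGED
    gfp_threshold: float = 0.3       # intensity threshold on the GFP channel
    gfp_fraction_min: float = 0.5    # blob is GFP-positive above this pixel fraction
    gfp_smooth_sigma: float = 1.0    # px; denoises the GFP channel before the
                                     # collision split (stabilises part boundaries)

    # posture
    n_spine: int = 11
    velocity_smoothing: bool = False  # centered 3-frame median on velocities

    # tracking
    gate_body_lengths: float = 0.5   # assignment gate, body lengths / frame
    max_gap: int = 5                 # frames a track survives unmatched
    assignment: str = "greedy"       # "greedy" | "optimal"

    # collision validity
    min_collision_s: float = 0.5     # strict: duration must exceed this
    flank_s: float = 1.0             # clean traceable margin before/after

    # perception
    alpha: float = 20.0              # full aperture of the field of perception, deg
    r: float = 10.0                  # perception radius, mm (~2 larval lengths)
    window_s: float = 7.0            # post-trigger bending observation window
    heading_smooth_frames: int = 5
    heading_speed_floor: float = 0.1  # mm/s; below, fall back to the body axis

    # KISS detection
    kiss_speed_frac: float = 0.5     # velocity must drop below this x pre-phase median
    kiss_bend_max: float = 30.0      # deg; bending must stay below (sampling, not turning)
    kiss_min_s: float = 0.5
    kiss_smooth_frames: int = 3

    # phase alignment
    pre_s: float = 1.0
    post_s: float = 1.0
    bend_threshold: float = 30.0     # deg, for bending probability
    phase_focal: str = "non_gfp"     # which participant contributes: non_gfp | gfp | both

    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.px_per_mm <= 0:
            raise ConfigError("fps and px_per_mm must be > 0")
        if self.r <= 0:
            raise ConfigError("perception radius r must be > 0")
        if not (0 < self.alpha <= 360):
            raise ConfigError("alpha must be in (0, 360]")
        if self.assignment not in ("greedy", "optimal"):
            raise ConfigError("assignment must be 'greedy' or 'optimal'")
        if self.phase_focal not in ("non_gfp", "gfp", "both"):
            raise ConfigError("phase_focal must be 'non_gfp', 'gfp' or 'both'")

    @property
    def gate_px(self) -> float:
        return self.gate_body_lengths * self.body_length * self.px_per_mm

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_scene(cls, scene: "SceneConfig", **overrides) -> "PipelineConfig":
        """Pipeline parameters consistent with a simulated scene."""
        base = dict(
            fps=scene.fps,
            px_per_mm=scene.px_per_mm,
            body_length=scene.body_length,
            body_width=scene.body_width,
            n_spine=scene.n_spine,
            seed=scene.seed,
        )
        base.update(overrides)
        return cls(**base)


def load_config(path: str | Path) -> dict:
    """Read a YAML config file into a plain dict (sections optional)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return data


def save_config(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
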