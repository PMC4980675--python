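"""Ground-truthed synthetic two-channel larval crawling scenes.

The simulator implements the larval locomotion phase model as a per-animal
state machine:

* **GO** — forward crawling at ``speed`` body lengths per second (default one
  body length per 5 s) with only micro head bends;
* **REORIENTATION** — reduced velocity with a pronounced head cast (30-90
  degrees) after which a new run direction is adopted;
* **COLLISION** — scripted pairwise contacts beginning with a KISS interval
  (strongly suppressed velocity, near-straight posture, 1-2 s) followed by a
  slow sampling interval, separation and a post-collision head cast.

Collisions are choreographed rather than emergent: the two participants are
steered onto a head-on course, held in contact for a scripted duration and
then separated, so the ground-truth contact interval is known exactly.  The
recorded contact interval is measured from the rendered body masks
(first/last frame on which the two thresholded bodies share a pixel), which
makes it consistent with what a segmenter sees by construction.

Frames are rendered lazily: :func:`simulate_scene` returns the full ground
truth plus a sequence object that rasterises any requested frame on demand,
deterministically for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import SceneConfig
from .segmentation import FramePair

# behavioral state codes
GO = 0
REORIENT = 1
COLLISION_KISS = 2
COLLISION_SAMPLING = 3
STATE_NAMES = {GO: "GO", REORIENT: "REORIENT",
               COLLISION_KISS: "COLLISION_KISS",
               COLLISION_SAMPLING: "COLLISION_SAMPLING"}

# rendering constants (px units unless noted)
_TIP_RADIUS_FRAC = 0.4      # body half-width taper factor at head/tail tips
_EDGE_SOFT_PX = 1.0         # width of the soft intensity edge
_SMOOTH_SIGMA_PX = 0.6
_GFP_RADIUS_SCALE = 0.85    # GFP silhouette sits inside the IR silhouette
_GFP_INTENSITY = 0.95
_MASK_THRESHOLD = 0.3       # reference threshold used for ground-truth masks


class PlacementError(RuntimeError):
    """Arena too small to place the requested animals without overlap."""


def _rot(v: np.ndarray, theta_rad: float) -> np.ndarray:
    c, s = math.cos(theta_rad), math.sin(theta_rad)
    return np.array([v[0] * c - v[1] * s, v[0] * s + v[1] * c])


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    if n == 0:
        return np.array([1.0, 0.0])
    return v / n


def spine_from_pose(pos, heading, bend_deg, body_length, n_spine) -> np.ndarray:
    """Spine points (tail -> head) for a two-segment body model.

    The posterior half runs straight behind the mid point along ``heading``;
    the anterior half is rotated by ``bend_deg`` so that the tail->mid /
    mid->head bending angle equals ``bend_deg`` exactly.
    """
    pos = np.asarray(pos, dtype=float)
    h = _unit(np.asarray(heading, dtype=float))
    hh = _rot(h, math.radians(bend_deg))
    m = (n_spine - 1) // 2
    half = body_length / 2.0
    pts = np.empty((n_spine, 2))
    for i in range(m + 1):
        pts[i] = pos - half * ((m - i) / m) * h
    for i in range(m, n_spine):
        pts[i] = pos + half * ((i - m) / m) * hh
    return pts


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def _taper_radii(n: int, half_width_px: float) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n)
    taper = _TIP_RADIUS_FRAC + (1 - _TIP_RADIUS_FRAC) * np.sqrt(np.sin(np.pi * u))
    return half_width_px * taper


def _render_patch(spine_px: np.ndarray, half_width_px: float,
                  shape: tuple[int, int]) -> tuple[np.ndarray, tuple[int, int]] | None:
    """Rasterise one animal as a tapered soft-edged capsule.

    ``spine_px`` is (n, 2) in (row, col).  Returns the intensity patch in
    [0, 1] and its (row0, col0) origin, or None if fully outside the image.
    """
    pad = half_width_px + _EDGE_SOFT_PX + 3
    r0 = int(np.floor(spine_px[:, 0].min() - pad))
    r1 = int(np.ceil(spine_px[:, 0].max() + pad)) + 1
    c0 = int(np.floor(spine_px[:, 1].min() - pad))
    c1 = int(np.ceil(spine_px[:, 1].max() + pad)) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0]), min(c1, shape[1])
    if r1 <= r0 or c1 <= c0:
        return None
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    grid = np.stack([rr, cc], axis=-1).astype(float)   # (H, W, 2)

    radii = _taper_radii(len(spine_px), half_width_px)
    signed = np.full(grid.shape[:2], np.inf)
    for j in range(len(spine_px) - 1):
        p0, p1 = spine_px[j], spine_px[j + 1]
        d = p1 - p0
        seg2 = float(d @ d)
        rel = grid - p0
        t = np.clip((rel @ d) / seg2, 0.0, 1.0) if seg2 > 0 else np.zeros(grid.shape[:2])
        closest = p0 + t[..., None] * d
        dist = np.linalg.norm(grid - closest, axis=-1)
        rad = radii[j] + t * (radii[j + 1] - radii[j])
        signed = np.minimum(signed, dist - rad)

    patch = np.clip(0.5 - signed / _EDGE_SOFT_PX, 0.0, 1.0)
    patch = gaussian_filter(patch, _SMOOTH_SIGMA_PX)
    return patch.astype(np.float32), (r0, c0)


def render_frame(spines_mm: Sequence[np.ndarray], gfp_flags: Sequence[bool],
                 config: SceneConfig, rng: np.random.Generator | None = None,
                 frame_index: int = 0) -> FramePair:
    """Rasterise one time point into an (IR, GFP) image pair.

    Every animal appears in the IR channel; only GFP-flagged animals appear
    in the GFP channel, with a slightly narrower silhouette so that every
    suprathreshold GFP pixel is also suprathreshold in IR.  Overlapping
    bodies combine by maximum intensity.  Additive Gaussian noise of
    ``config.noise_sd`` is applied when ``rng`` is given.
    """
    n = config.image_size
    s = config.px_per_mm
    ir = np.zeros((n, n), dtype=np.float32)
    gfp = np.zeros((n, n), dtype=np.float32)
    half_w = config.body_width / 2.0 * s
    for spine, is_gfp in zip(spines_mm, gfp_flags):
        spine_px = np.stack([spine[:, 1] * s, spine[:, 0] * s], axis=-1)  # (row, col)
        out = _render_patch(spine_px, half_w, (n, n))
        if out is None:
            continue
        patch, (r0, c0) = out
        sl = np.s_[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]]
        np.maximum(ir[sl], patch, out=ir[sl])
        if is_gfp:
            gout = _render_patch(spine_px, half_w * _GFP_RADIUS_SCALE, (n, n))
            if gout is not None:
                gpatch, (gr0, gc0) = gout
                gsl = np.s_[gr0:gr0 + gpatch.shape[0], gc0:gc0 + gpatch.shape[1]]
                np.maximum(gfp[gsl], gpatch * _GFP_INTENSITY, out=gfp[gsl])
    if rng is not None and config.noise_sd > 0:
        ir = np.clip(ir + rng.normal(0, config.noise_sd, ir.shape).astype(np.float32), 0, 1)
        gfp = np.clip(gfp + rng.normal(0, config.noise_sd, gfp.shape).astype(np.float32), 0, 1)
    return FramePair(ir=ir, gfp=gfp, frame_index=frame_index,
                     time=frame_index / config.fps)


def _animal_mask(spine_mm: np.ndarray, config: SceneConfig,
                 threshold: float = _MASK_THRESHOLD) -> tuple[np.ndarray, tuple[int, int]] | None:
    """Noise-free thresholded body mask of a single animal (patch, origin)."""
    s = config.px_per_mm
    spine_px = np.stack([spine_mm[:, 1] * s, spine_mm[:, 0] * s], axis=-1)
    out = _render_patch(spine_px, config.body_width / 2.0 * s,
                        (config.image_size, config.image_size))
    if out is None:
        return None
    patch, origin = out
    return patch >= threshold, origin


def _masks_overlap(mask_a, org_a, mask_b, org_b) -> bool:
    r0 = max(org_a[0], org_b[0]); c0 = max(org_a[1], org_b[1])
    r1 = min(org_a[0] + mask_a.shape[0], org_b[0] + mask_b.shape[0])
    c1 = min(org_a[1] + mask_a.shape[1], org_b[1] + mask_b.shape[1])
    if r1 <= r0 or c1 <= c0:
        return False
    sub_a = mask_a[r0 - org_a[0]:r1 - org_a[0], c0 - org_a[1]:c1 - org_a[1]]
    sub_b = mask_b[r0 - org_b[0]:r1 - org_b[0], c0 - org_b[1]:c1 - org_b[1]]
    return bool(np.any(sub_a & sub_b))


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class CollisionScript:
    """One scripted collision episode and its realised ground truth (frames)."""
    id_a: int                       # GFP-side participant by convention if any
    id_b: int
    target_duration_s: float
    plateau_start: int = -1         # first stationary contact frame
    plateau_end: int = -1           # last stationary/sampling contact frame
    kiss_start: int | None = None   # KISS sub-interval (velocity+bend frozen)
    kiss_end: int | None = None
    contact_start: int = -1         # measured rendered-mask overlap interval
    contact_end: int = -1

    @property
    def duration_frames(self) -> int:
        return self.contact_end - self.contact_start + 1


@dataclass
class GroundTruth:
    """Per-frame, per-animal ground truth of a simulated scene."""
    config: SceneConfig
    spine: np.ndarray          # (T, N, n_spine, 2) mm, tail -> head
    heading: np.ndarray        # (T, N, 2) unit vectors
    bend: np.ndarray           # (T, N) signed degrees
    state: np.ndarray          # (T, N) int8 state codes
    gfp: np.ndarray            # (N,) bool
    collisions: list[CollisionScript] = field(default_factory=list)
    contacts: list[tuple[int, int, int, int]] = field(default_factory=list)
    # (id_a, id_b, start_frame, end_frame) measured mask-overlap intervals
    scripted: np.ndarray | None = None
    # (T, N) bool: frames driven by collision choreography (approach legs may
    # exceed GO speed; free-behavior statistics should exclude them)

    @property
    def n_frames(self) -> int:
        return self.spine.shape[0]

    @property
    def n_animals(self) -> int:
        return self.spine.shape[1]

    @property
    def centroid(self) -> np.ndarray:
        """(T, N, 2) mm — mean of the spine points (body centroid proxy)."""
        return self.spine.mean(axis=2)

    def animal_mask(self, frame: int, animal: int,
                    threshold: float = _MASK_THRESHOLD) -> np.ndarray:
        """Full-size noise-free boolean body mask of one animal."""
        full = np.zeros((self.config.image_size, self.config.image_size), dtype=bool)
        out = _animal_mask(self.spine[frame, animal], self.config, threshold)
        if out is not None:
            mask, (r0, c0) = out
            full[r0:r0 + mask.shape[0], c0:c0 + mask.shape[1]] = mask
        return full

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per frame x animal."""
        T, N = self.bend.shape
        cent = self.centroid
        frames = np.repeat(np.arange(T), N)
        ids = np.tile(np.arange(N), T)
        d = {
            "frame": frames,
            "time_s": frames / self.config.fps,
            "id": ids,
            "x_mm": cent[:, :, 0].ravel(),
            "y_mm": cent[:, :, 1].ravel(),
            "bending_deg": self.bend.ravel(),
            "state": [STATE_NAMES[s] for s in self.state.ravel()],
            "gfp": self.gfp[ids],
        }
        spine_flat = self.spine.reshape(T * N, -1)
        for k in range(self.spine.shape[2]):
            d[f"sx{k}_mm"] = spine_flat[:, 2 * k]
            d[f"sy{k}_mm"] = spine_flat[:, 2 * k + 1]
        return pd.DataFrame(d)

    def collisions_dataframe(self) -> pd.DataFrame:
        rows = [{"id_a": c.id_a, "id_b": c.id_b,
                 "start_frame": c.contact_start, "end_frame": c.contact_end,
                 "target_duration_s": c.target_duration_s,
                 "kiss_start": -1 if c.kiss_start is None else c.kiss_start,
                 "kiss_end": -1 if c.kiss_end is None else c.kiss_end}
                for c in self.collisions]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "start_frame", "end_frame",
                                           "target_duration_s", "kiss_start", "kiss_end"])

    def write_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(outdir / "ground_truth.csv", index=False)
        self.collisions_dataframe().to_csv(outdir / "ground_truth_collisions.csv", index=False)


class FrameSequence:
    """Lazy, random-access renderer of a simulated scene.

    Frames are rasterised on demand so long scenes never materialise in
    memory; per-frame noise streams are seeded independently from
    ``(seed, frame)`` which makes random access deterministic.
    """

    def __init__(self, gt: GroundTruth):
        self._gt = gt
        self._config = gt.config

    def __len__(self) -> int:
        return self._gt.n_frames

    def __getitem__(self, i: int) -> FramePair:
        if i < 0:
            i += len(self)
        if not (0 <= i < len(self)):
            raise IndexError(i)
        cfg = self._config
        rng = None
        if cfg.noise_sd > 0:
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed % (2 ** 31), 7, i]))
        return render_frame(list(self._gt.spine[i]), list(self._gt.gfp), cfg,
                            rng=rng, frame_index=i)

    def __iter__(self) -> Iterator[FramePair]:
        for i in range(len(self)):
            yield self[i]


# ---------------------------------------------------------------------------
# behavior state machine + choreography
# ---------------------------------------------------------------------------

class _Animal:
    """Mutable controller state of one simulated larva."""

    def __init__(self, idx: int, pos: np.ndarray, heading: np.ndarray,
                 rng: np.random.Generator, cfg: SceneConfig):
        self.idx = idx
        self.pos = pos.astype(float)
        self.heading = _unit(heading)
        self.bend = 0.0
        self.mode = "go"
        self.rng = rng
        self.cfg = cfg
        self.go_frames_left = self._sample_go()
        self.cast_plan: list[tuple[float, float]] = []   # (bend, step_frac)
        self.cast_turn = 0.0
        # choreography timeline (filled by the scheduler)
        self.timeline: dict | None = None
        self.timeline_i = 0

    def _sample_go(self) -> int:
        rate = max(self.cfg.reorientation_rate, 1e-6)
        return max(int(self.rng.exponential(1.0 / rate) * self.cfg.fps), 5)

    @property
    def busy(self) -> bool:
        return self.timeline is not None

    def plan_cast(self) -> None:
        cfg = self.cfg
        amp = self.rng.uniform(30.0, 90.0) * self.rng.choice([-1.0, 1.0])
        up = max(int(round(0.4 * cfg.fps)), 2)
        hold = max(int(round(0.3 * cfg.fps)), 1)
        plan = []
        for k in range(1, up + 1):
            plan.append((amp * k / up, 0.3))
        plan.extend([(amp, 0.3)] * hold)
        for k in range(up - 1, -1, -1):
            plan.append((amp * k / up, 0.3))
        self.cast_plan = plan
        self.cast_turn = math.radians(0.65 * amp)
        self.mode = "reorient"


class _Simulator:
    def __init__(self, cfg: SceneConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed % (2 ** 31))
        self.touch_gap = self._calibrate_touch_gap()

    # -- placement -------------------------------------------------------
    def _place_animals(self) -> list[_Animal]:
        cfg = self.cfg
        center = np.array(cfg.arena_center)
        r_max = cfg.arena_radius - 1.5 * cfg.body_length
        if r_max <= 0:
            raise PlacementError("arena smaller than a body length")
        min_sep = 2.2 * cfg.body_length
        positions: list[np.ndarray] = []
        for i in range(cfg.n_larvae):
            for attempt in range(4000):
                rho = r_max * math.sqrt(self.rng.uniform())
                phi = self.rng.uniform(0, 2 * math.pi)
                p = center + rho * np.array([math.cos(phi), math.sin(phi)])
                if all(np.hypot(*(p - q)) >= min_sep for q in positions):
                    positions.append(p)
                    break
            else:
                raise PlacementError(
                    f"could not place {cfg.n_larvae} animals without overlap")
        animals = []
        for i, p in enumerate(positions):
            phi = self.rng.uniform(0, 2 * math.pi)
            animals.append(_Animal(i, p, np.array([math.cos(phi), math.sin(phi)]),
                                   self.rng, cfg))
        return animals

    # -- contact distance calibration ------------------------------------
    def _calibrate_touch_gap(self) -> float:
        """Largest head-to-head gap (mm) at which two straight rendered
        bodies on a head-on axis still share a thresholded pixel."""
        cfg = self.cfg
        c = np.array(cfg.arena_center)
        v = np.array([1.0, 0.0])
        L = cfg.body_length

        def touches(gap: float) -> bool:
            mid_a = c + (-gap / 2 - L / 2) * v
            mid_b = c + (gap / 2 + L / 2) * v
            sa = spine_from_pose(mid_a, v, 0.0, L, cfg.n_spine)
            sb = spine_from_pose(mid_b, -v, 0.0, L, cfg.n_spine)
            ma = _animal_mask(sa, cfg)
            mb = _animal_mask(sb, cfg)
            if ma is None or mb is None:
                return False
            return _masks_overlap(ma[0], ma[1], mb[0], mb[1])

        lo, hi = -0.5, 2.0    # mm; lo overlapping, hi separated
        for _ in range(12):
            mid = (lo + hi) / 2
            if touches(mid):
                lo = mid
            else:
                hi = mid
        return lo

    # -- choreography -----------------------------------------------------
    def _hermite_path(self, p0, h0, p1, h1, n_samples: int = 600) -> np.ndarray:
        scale = 0.8 * max(float(np.hypot(*(p1 - p0))), 1e-6)
        t = np.linspace(0.0, 1.0, n_samples)[:, None]
        h00 = 2 * t ** 3 - 3 * t ** 2 + 1
        h10 = t ** 3 - 2 * t ** 2 + t
        h01 = -2 * t ** 3 + 3 * t ** 2
        h11 = t ** 3 - t ** 2
        return h00 * p0 + h10 * scale * h0 + h01 * p1 + h11 * scale * h1

    def _arclength_schedule(self, path: np.ndarray, T: int, fps: float,
                            final_step: float, lunge: float = 0.0,
                            n_lunge: int = 2) -> np.ndarray:
        """Positions at T frames along path.

        The last ``n_lunge`` frames cover the final ``lunge`` mm (the quick
        closing step into contact); the ~1.5 s before that run at
        ``final_step`` per frame (GO speed); the remainder is spread evenly.
        """
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        s_cum = np.concatenate([[0.0], np.cumsum(seg)])
        S = s_cum[-1]
        nl = n_lunge if lunge > 0 and T > n_lunge else 0
        S_travel = max(S - lunge, 0.0) if nl else S
        Tt = T - nl
        ff = min(int(round(1.5 * fps)), Tt)
        if Tt > ff and S_travel > ff * final_step:
            early = (S_travel - ff * final_step) / (Tt - ff)
            steps = np.concatenate([np.full(Tt - ff, early), np.full(ff, final_step)])
        else:
            steps = np.full(Tt, S_travel / max(Tt, 1))
        if nl:
            steps = np.concatenate([steps, np.full(nl, (S - S_travel) / nl)])
        s_t = np.cumsum(steps)
        s_t[-1] = S
        out = np.empty((T, 2))
        out[:, 0] = np.interp(s_t, s_cum, path[:, 0])
        out[:, 1] = np.interp(s_t, s_cum, path[:, 1])
        return out

    def plan_collision(self, a: _Animal, b: _Animal, target_s: float,
                       frame0: int) -> bool:
        """Build pose timelines steering ``a`` and ``b`` into a contact of
        roughly ``target_s`` seconds, then apart again.

        Returns False (and leaves the pair untouched) when the meeting
        point would fall too close to another episode currently playing
        out — overlapping choreographies would pile more than two animals
        into one contour.
        """
        cfg = self.cfg
        rng = self.rng
        go_step = cfg.go_step
        target_frames = max(int(round(target_s * cfg.fps)), 2)

        center = np.array(cfg.arena_center)
        M = (a.pos + b.pos) / 2.0
        d_c = np.hypot(*(M - center))
        max_d = cfg.arena_radius - 2.5 * cfg.body_length
        if d_c > max_d:
            M = center + (M - center) * (max_d / d_c)
        self._active_meets = [(end, pt) for end, pt in self._active_meets
                              if end >= frame0]
        if any(np.hypot(*(M - pt)) < 4.0 * cfg.body_length
               for _, pt in self._active_meets):
            return False
        v = _unit(b.pos - a.pos)
        if np.allclose(a.pos, b.pos):
            v = np.array([1.0, 0.0])

        short = target_frames <= max(int(round(0.6 * cfg.fps)), 3)
        ov = 0.25 if short else 0.6        # head interpenetration depth, mm
        L = cfg.body_length
        mid_a_c = M + (ov / 2 - L / 2) * v
        mid_b_c = M - (ov / 2 - L / 2) * v

        # approach legs (Hermite splines, final ~1.5 s at GO speed)
        path_a = self._hermite_path(a.pos, a.heading, mid_a_c, v)
        path_b = self._hermite_path(b.pos, b.heading, mid_b_c, -v)
        S_a = float(np.linalg.norm(np.diff(path_a, axis=0), axis=1).sum())
        S_b = float(np.linalg.norm(np.diff(path_b, axis=0), axis=1).sum())
        # the travel leg may run up to 4x GO speed so distant pairs still
        # meet within the scene; the final ~1.5 s is always at GO speed,
        # which is what the pre-collision statistics measure
        ff = int(round(1.5 * cfg.fps))
        S_max = max(S_a, S_b)
        T_app = max(ff + int(math.ceil(max(S_max - ff * go_step, 0.0)
                                       / (4.0 * go_step))), 15)
        T_app = max(T_app, int(math.ceil(S_max / (4.0 * go_step))))
        # each animal closes the last (g_pre + ov)/2 mm in a 2-frame lunge,
        # so the rendered contact begins essentially together with the
        # velocity stop (measured KISS onset == scripted onset)
        g_pre = self.touch_gap + 0.15
        lunge = (g_pre + ov) / 2.0
        pos_a = self._arclength_schedule(path_a, T_app, cfg.fps, go_step, lunge)
        pos_b = self._arclength_schedule(path_b, T_app, cfg.fps, go_step, lunge)

        # contact bookkeeping: overlap starts during the 2 lunge frames and
        # ends a few retreat frames after the plateau.  During the sampling
        # interval after the KISS the pair slides slightly deeper into
        # contact (extra mm below) so that gentle head sweeps cannot break
        # the rendered overlap.
        retreat_step = 2.5 * go_step
        extra = 0.45  # additional interpenetration during sampling, mm
        app_extra = 2
        ret_shallow = int(math.ceil((self.touch_gap + ov) / (2 * retreat_step)))
        ret_deep = int(math.ceil((self.touch_gap + ov + 2 * extra) / (2 * retreat_step)))
        kiss_s = rng.uniform(*cfg.kiss_duration_range)
        kiss_nominal = int(round(kiss_s * cfg.fps))
        plateau_deep = target_frames - app_extra - ret_deep
        if plateau_deep > kiss_nominal:
            plateau = plateau_deep
            kiss_frames = kiss_nominal
            ov_end = ov + 2 * extra
        else:
            plateau = max(target_frames - app_extra - ret_shallow, 0)
            kiss_frames = plateau        # whole stationary contact is frozen
            ov_end = ov

        R_frames = max(int(round(1.0 * cfg.fps)),
                       int(math.ceil((self.touch_gap + ov_end) / (2 * retreat_step))) + 2)
        C_frames = max(int(round(0.9 * cfg.fps)), 4)

        def build(pos_app, mid_c, hdg, partner_sign):
            n_total = T_app + plateau + R_frames + C_frames
            pos = np.empty((n_total, 2))
            head = np.empty((n_total, 2))
            bend = np.zeros(n_total)
            state = np.full(n_total, GO, dtype=np.int8)
            # approach
            pos[:T_app] = pos_app
            diffs = np.diff(np.vstack([pos_app[:1], pos_app]), axis=0)
            for k in range(T_app):
                d = diffs[k] if np.hypot(*diffs[k]) > 1e-9 else hdg
                head[k] = _unit(d)
            head[0] = head[1] if T_app > 1 else hdg
            # plateau: frozen KISS, then slow sampling with gentle head sweeps
            depth = 0.0
            for k in range(plateau):
                i = T_app + k
                head[i] = hdg
                if k < kiss_frames:
                    state[i] = COLLISION_KISS
                    bend[i] = 0.0
                    pos[i] = mid_c
                else:
                    state[i] = COLLISION_SAMPLING
                    j = k - kiss_frames
                    depth = min(extra, extra * (j + 1) / 4.0)
                    pos[i] = mid_c + depth * hdg
                    bend[i] = 10.0 * math.sin(2 * math.pi * 0.8 * j / cfg.fps)
            # retreat (backing up along the contact axis)
            p_ret = mid_c + depth * hdg
            for k in range(R_frames):
                i = T_app + plateau + k
                pos[i] = p_ret - retreat_step * (k + 1) * hdg
                head[i] = hdg
                gap = -(ov + 2 * depth) + 2 * retreat_step * (k + 1)
                state[i] = COLLISION_SAMPLING if gap <= self.touch_gap else REORIENT
            # post-collision head cast (in place)
            amp = rng.uniform(40.0, 70.0) * rng.choice([-1.0, 1.0])
            p_final = pos[T_app + plateau + R_frames - 1]
            for k in range(C_frames):
                i = T_app + plateau + R_frames + k
                pos[i] = p_final
                head[i] = hdg
                frac = min(1.0, 2.0 * (k + 1) / C_frames)
                if k >= C_frames - 2:
                    frac = max(0.0, 1.0 - (k - (C_frames - 2)))
                bend[i] = amp * frac
                state[i] = REORIENT
            exit_heading = _rot(-hdg, math.radians(rng.uniform(-45.0, 45.0)))
            return {"pos": pos, "head": head, "bend": bend, "state": state,
                    "exit_heading": exit_heading}

        a.timeline = build(pos_a, mid_a_c, v, +1)
        b.timeline = build(pos_b, mid_b_c, -v, -1)
        a.timeline_i = b.timeline_i = 0
        a.mode = b.mode = "choreo"

        script = CollisionScript(
            id_a=a.idx, id_b=b.idx, target_duration_s=target_s,
            plateau_start=frame0 + T_app,
            plateau_end=frame0 + T_app + max(plateau, 1) - 1)
        if kiss_frames > 0:
            script.kiss_start = frame0 + T_app
            script.kiss_end = frame0 + T_app + kiss_frames - 1
        self.scripts.append(script)
        episode_end = frame0 + T_app + plateau + R_frames + C_frames
        self._active_meets.append((episode_end, M))
        return True

    # -- per-frame free behavior ------------------------------------------
    def _step_free(self, an: _Animal, others: list[_Animal]) -> None:
        cfg = self.cfg
        rng = self.rng
        center = np.array(cfg.arena_center)
        if an.mode == "reorient":
            bend, step_frac = an.cast_plan[0]
            an.cast_plan = an.cast_plan[1:]
            an.bend = bend
            an.pos = an.pos + step_frac * cfg.go_step * an.heading
            if not an.cast_plan:
                an.heading = _rot(an.heading, an.cast_turn)
                an.bend = 0.0
                an.mode = "go"
                an.go_frames_left = an._sample_go()
            return
        # GO
        an.bend = float(np.clip(0.7 * an.bend + rng.normal(0, 1.2), -3.0, 3.0))
        an.heading = _rot(an.heading, math.radians(rng.normal(0, 1.2)))
        # boundary steering: turn toward the center near the edge
        ahead = an.pos + cfg.body_length * an.heading
        if np.hypot(*(ahead - center)) > cfg.arena_radius - cfg.body_length:
            desired = _unit(center - an.pos)
            cross = an.heading[0] * desired[1] - an.heading[1] * desired[0]
            ang = math.atan2(cross, an.heading @ desired)
            an.heading = _rot(an.heading, np.clip(ang, -0.35, 0.35))
        else:
            # mild avoidance keeps unscripted contacts rare
            for other in others:
                if other.idx == an.idx:
                    continue
                rel = other.pos - an.pos
                dist = float(np.hypot(*rel))
                if dist < 2.0 * cfg.body_length and an.heading @ rel > 0:
                    side = math.copysign(
                        1.0, an.heading[0] * rel[1] - an.heading[1] * rel[0])
                    an.heading = _rot(an.heading, -side * 0.3)
                    break
        an.pos = an.pos + cfg.go_step * an.heading
        an.go_frames_left -= 1
        if an.go_frames_left <= 0:
            an.plan_cast()

    # -- main loop --------------------------------------------------------
    def run(self) -> GroundTruth:
        cfg = self.cfg
        T, N = cfg.n_frames, cfg.n_larvae
        animals = self._place_animals()
        self.scripts: list[CollisionScript] = []
        self._active_meets: list[tuple[int, np.ndarray]] = []
        pending = sorted(
            [(float(t0), int(ia), int(ib), float(dur)) for ia, ib, t0, dur in cfg.collisions])

        spine = np.empty((T, N, cfg.n_spine, 2))
        heading = np.empty((T, N, 2))
        bend = np.empty((T, N))
        state = np.empty((T, N), dtype=np.int8)
        scripted = np.zeros((T, N), dtype=bool)
        peri_phase = self.rng.uniform(0, 2 * math.pi, N)

        for t in range(T):
            # start pending scripted collisions whose participants are free
            still = []
            for ev in pending:
                t0, ia, ib, dur = ev
                started = False
                if t / cfg.fps >= t0 and not animals[ia].busy and not animals[ib].busy:
                    started = self.plan_collision(animals[ia], animals[ib], dur, t)
                if not started:
                    still.append(ev)
            pending = still

            for an in animals:
                if an.timeline is not None:
                    scripted[t, an.idx] = True
                    tl = an.timeline
                    i = an.timeline_i
                    an.pos = tl["pos"][i].copy()
                    an.heading = tl["head"][i].copy()
                    an.bend = float(tl["bend"][i])
                    st = int(tl["state"][i])
                    an.timeline_i += 1
                    if an.timeline_i >= len(tl["pos"]):
                        an.heading = tl["exit_heading"].copy()
                        an.timeline = None
                        an.mode = "go"
                        an.bend = 0.0
                        an.go_frames_left = an._sample_go()
                else:
                    self._step_free(an, animals)
                    st = GO if an.mode == "go" else REORIENT

                moving = st == GO
                L_eff = cfg.body_length * (1 + (0.03 * math.sin(
                    2 * math.pi * 1.2 * t / cfg.fps + peri_phase[an.idx]) if moving else 0.0))
                spine[t, an.idx] = spine_from_pose(an.pos, an.heading, an.bend,
                                                   L_eff, cfg.n_spine)
                heading[t, an.idx] = an.heading
                bend[t, an.idx] = an.bend
                state[t, an.idx] = st

        gt = GroundTruth(config=cfg, spine=spine, heading=heading, bend=bend,
                         state=state, gfp=np.asarray(cfg.gfp_flags, dtype=bool),
                         collisions=self.scripts, scripted=scripted)
        self._scan_contacts(gt)
        return gt

    # -- measured contact intervals ---------------------------------------
    def _scan_contacts(self, gt: GroundTruth) -> None:
        cfg = self.cfg
        cent = gt.centroid
        T, N = gt.bend.shape
        near = cfg.body_length + 1.5
        open_intervals: dict[tuple[int, int], int] = {}
        finished: list[tuple[int, int, int, int]] = []
        for t in range(T):
            touching: set[tuple[int, int]] = set()
            d = np.linalg.norm(cent[t][:, None, :] - cent[t][None, :, :], axis=-1)
            cand = np.argwhere(np.triu(d < near, k=1))
            masks: dict[int, tuple[np.ndarray, tuple[int, int]] | None] = {}
            for i, j in cand:
                for k in (i, j):
                    if k not in masks:
                        masks[k] = _animal_mask(gt.spine[t, k], cfg)
                ma, mb = masks[i], masks[j]
                if ma is not None and mb is not None and \
                        _masks_overlap(ma[0], ma[1], mb[0], mb[1]):
                    touching.add((int(i), int(j)))
            for pair in touching:
                open_intervals.setdefault(pair, t)
            for pair in list(open_intervals):
                if pair not in touching:
                    finished.append((*pair, open_intervals.pop(pair), t - 1))
        for pair, t0 in open_intervals.items():
            finished.append((*pair, t0, T - 1))
        gt.contacts = sorted(finished, key=lambda x: x[2])
        # attach measured intervals to scripts (the interval covering the plateau)
        for sc in gt.collisions:
            key = tuple(sorted((sc.id_a, sc.id_b)))
            best = None
            for ia, ib, s, e in gt.contacts:
                if (ia, ib) == key and s <= sc.plateau_end and e >= sc.plateau_start - 5:
                    if best is None or (e - s) > (best[1] - best[0]):
                        best = (s, e)
            if best is not None:
                sc.contact_start, sc.contact_end = best


def simulate_scene(config: SceneConfig) -> tuple[GroundTruth, FrameSequence]:
    """Simulate a scene and return its ground truth plus a lazy frame stream.

    Deterministic for a given config and seed: the trajectory generation,
    the choreography and every per-frame noise field derive from
    ``config.seed``.
    """
    gt = _Simulator(config).run()
    return gt, FrameSequence(gt)


def schedule_collisions(config: SceneConfig, n_events: int,
                        durations: Sequence[float] | None = None,
                        seed: int | None = None,
                        start_s: float = 1.0, spacing_s: float = 6.0,
                        ) -> list[tuple[int, int, float, float]]:
    """Build a scripted GFP / non-GFP collision schedule.

    Pairs one GFP-positive with one GFP-negative animal per event, reusing
    animals only after their previous episode has had time to finish.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gfp_ids = [i for i, f in enumerate(config.gfp_flags) if f]
    non_ids = [i for i, f in enumerate(config.gfp_flags) if not f]
    if not gfp_ids or not non_ids:
        raise ValueError("need at least one GFP and one non-GFP animal")
    if durations is None:
        durations = list(rng.uniform(0.3, 4.0, n_events))
    out = []
    for k in range(n_events):
        ia = gfp_ids[k % len(gfp_ids)]
        ib = non_ids[k % len(non_ids)]
        wave = max(k // len(gfp_ids), k // len(non_ids))
        t0 = start_s + spacing_s * (k % max(len(gfp_ids), len(non_ids))) * 0.0 \
            + wave * 25.0 + k * 0.6
        out.append((ia, ib, float(t0), float(durations[k])))
    return out


# ---------------------------------------------------------------------------
# scripted perception geometry (no rendering)
# ---------------------------------------------------------------------------

def scripted_perception_table(n_pairs: int = 3, fps: float = 10.0,
                              duration_s: float = 14.0,
                              bend_delay_s: float = 4.0,
                              bend_amp: float = 60.0,
                              seed: int = 0) -> pd.DataFrame:
    """Feature table of scripted approach scenes for perception analysis.

    Each pair holds a focal animal crawling steadily along +x and a second
    animal that converges onto its path: the radial distance drops below
    r = 10 mm almost immediately, while the angular offset from the focal
    heading shrinks linearly and crosses 10 degrees (the edge of a 20-degree
    full aperture) at t = 4 s.  The focal animal performs a scripted 1-s head
    cast of ``bend_amp`` degrees ``bend_delay_s`` seconds after that narrow-
    field entry.  With alpha = 20 the bending rise therefore appears 4 s
    after the trigger; with alpha = 90 the event triggers ~3.6 s earlier and
    the same rise falls near the end of (or outside) the 7-s window.
    """
    rng = np.random.default_rng(seed)
    T = int(round(duration_s * fps))
    speed = 0.8  # mm/s, GO-phase crawling
    trigger_narrow_s = 4.0   # angular offset crosses 10 deg here
    rows = []
    for p in range(n_pairs):
        side = 1.0 if p % 2 == 0 else -1.0
        y0 = 100.0 * p + float(rng.normal(0, 0.3))
        bend_start = trigger_narrow_s + bend_delay_s
        for t in range(T):
            ts = t / fps
            fx, fy = speed * ts, y0
            # focal bending: 1-s head cast starting at bend_start
            u = ts - bend_start
            if 0.0 <= u < 1.0:
                ramp = min(u / 0.2, 1.0, (1.0 - u) / 0.2)
                b = bend_amp * max(ramp, 0.0)
            else:
                b = float(rng.normal(0, 1.0))
            phi = math.radians(max(30.0 - 5.0 * ts, 2.0) * side)
            dist = max(10.5 - 1.5 * ts, 3.0)
            ox = fx + dist * math.cos(phi)
            oy = fy + dist * math.sin(phi)
            for i, (x, y, bnd, vel, ax) in enumerate(
                    [(fx, fy, b, speed, (1.0, 0.0)),
                     (ox, oy, 0.0, speed, (math.cos(phi), math.sin(phi)))]):
                rows.append({
                    "frame": t, "time_s": ts, "id": 2 * p + i,
                    "x_mm": x, "y_mm": y, "bending_deg": bnd,
                    "velocity_mm_s": vel,
                    "is_bend30": abs(bnd) >= 30, "is_bend40": abs(bnd) >= 40,
                    "b_gfp": False, "in_collision": False,
                    "axis_x": ax[0], "axis_y": ax[1],
                })
    return pd.DataFrame(rows)
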