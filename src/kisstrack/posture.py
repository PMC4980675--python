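"""Per-animal posture and motion features.

The midline ("spine") is extracted from the blob contour: the two body ends
are located as the farthest-apart curvature maxima of the boundary, the
contour is split into two lateral arcs, opposite arc points are paired by
arc-length fraction and their midpoints resampled to ``n_spine`` equidistant
points, tail first.  A skeletonization fallback is available for shapes
where the contour pairing is unreliable.

The bending angle is the signed angle between the tail->mid and mid->head
vectors, in degrees: 0 for a straight animal, positive for a head deviation
that appears clockwise in image coordinates (row increasing downwards).
This tail/mid/head construction is this package's working definition of
body bending; it is stated here because upstream feature conventions vary
between tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .segmentation import Blob


class DegeneratePostureError(ValueError):
    """Blob too round or too small to define a midline."""


class GapError(ValueError):
    """Velocity requested across non-consecutive frames."""


class InsufficientTrackError(ValueError):
    """Track does not cover the requested time window."""


@dataclass
class Spine:
    """Ordered midline points, tail -> head."""
    points: np.ndarray          # (n_spine, 2), (row, col) px

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        n = len(self.points)
        if n < 5 or n % 2 == 0:
            raise ValueError("n_spine must be odd and >= 5")

    @property
    def tail(self) -> np.ndarray:
        return self.points[0]

    @property
    def head(self) -> np.ndarray:
        return self.points[-1]

    @property
    def mid(self) -> np.ndarray:
        return self.points[len(self.points) // 2]

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def flipped(self) -> "Spine":
        return Spine(self.points[::-1].copy())


@dataclass
class LarvaState:
    """Posture and motion of one animal at one frame."""
    frame_index: int
    contour: np.ndarray | None
    spine: Spine | None
    centroid_mm: np.ndarray          # (x, y) mm
    centroid_px: np.ndarray          # (row, col) px
    bending_angle: float = math.nan  # signed degrees
    velocity: float | None = None    # mm/s, absent on a track's first frame
    b_gfp: bool = False
    in_collision: bool = False
    orientation_resolved: bool = False


# ---------------------------------------------------------------------------
# spine extraction
# ---------------------------------------------------------------------------

def _resample_closed(contour: np.ndarray, n: int) -> np.ndarray:
    pts = np.asarray(contour, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise DegeneratePostureError("contour has zero length")
    t = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(t, s, closed[:, 0])
    out[:, 1] = np.interp(t, s, closed[:, 1])
    return out


def _smooth_closed(pts: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return pts
    kernel = np.ones(w) / w
    out = np.empty_like(pts)
    for k in range(2):
        ext = np.concatenate([pts[-w:, k], pts[:, k], pts[:w, k]])
        out[:, k] = np.convolve(ext, kernel, mode="same")[w:-w]
    return out


def _turning_angles(pts: np.ndarray, w: int) -> np.ndarray:
    """Unsigned turning angle at each vertex of a closed polyline."""
    n = len(pts)
    prev = pts[(np.arange(n) - w) % n]
    nxt = pts[(np.arange(n) + w) % n]
    a = pts - prev
    b = nxt - pts
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = (a * b).sum(axis=1)
    return np.abs(np.arctan2(cross, dot))


def _resample_open(pts: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise DegeneratePostureError("zero-length midline")
    t = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(t, s, pts[:, 0])
    out[:, 1] = np.interp(t, s, pts[:, 1])
    return out


def extract_spine(blob: Blob, n_spine: int = 11, body_width_px: float = 8.0,
                  method: str = "contour") -> Spine:
    """Extract the midline of a single-animal blob.

    Raises :class:`DegeneratePostureError` when the blob has no usable
    elongation (tip separation below twice the body width, or a boundary
    with no curvature extremes, e.g. a disc).
    """
    if method == "skeleton":
        return _extract_spine_skeleton(blob, n_spine, body_width_px)
    K = max(120, 4 * n_spine)
    contour = _resample_closed(blob.contour, K)
    contour = _smooth_closed(contour, max(K // 40, 3))
    kappa = _turning_angles(contour, max(K // 28, 3))

    i_star = int(np.argmax(kappa))
    # opposite tip: best curvature in the far half of the boundary
    offs = (np.arange(K) - i_star) % K
    far = (offs > 0.3 * K) & (offs < 0.7 * K)
    if not far.any():
        raise DegeneratePostureError("boundary too short")
    j_star = int(np.argmax(np.where(far, kappa, -np.inf)))

    # roundness check: a disc's boundary turns evenly (max/median curvature
    # near 1-2 even with pixelation), while capsule tips turn sharply
    med = float(np.median(kappa))
    if med > 0 and kappa[i_star] < 2.5 * med:
        raise DegeneratePostureError("no curvature extremities (round blob)")
    tip_a, tip_b = contour[i_star], contour[j_star]
    if float(np.hypot(*(tip_a - tip_b))) < 2.0 * body_width_px:
        raise DegeneratePostureError("tip separation below 2x body width")

    # split into the two lateral arcs and pair points by arc-length fraction
    if i_star < j_star:
        arc1 = contour[i_star:j_star + 1]
        arc2 = np.vstack([contour[j_star:], contour[:i_star + 1]])[::-1]
    else:
        arc1 = np.vstack([contour[i_star:], contour[:j_star + 1]])
        arc2 = contour[j_star:i_star + 1][::-1]
    F = 80
    a = _resample_open(arc1, F)
    b = _resample_open(arc2, F)
    midline = (a + b) / 2.0
    midline[0], midline[-1] = tip_a, tip_b
    return Spine(_resample_open(midline, n_spine))


def _extract_spine_skeleton(blob: Blob, n_spine: int,
                            body_width_px: float) -> Spine:
    """Fallback: morphological skeleton + longest path between endpoints."""
    r0, c0, r1, c1 = blob.bbox
    mask = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
    mask[blob.pixels[:, 0] - r0 + 1, blob.pixels[:, 1] - c0 + 1] = True
    skel = morphology.skeletonize(mask)
    coords = np.argwhere(skel)
    if len(coords) < 3:
        raise DegeneratePostureError("skeleton too short")
    index = {tuple(p): i for i, p in enumerate(coords)}
    nbrs: list[list[int]] = [[] for _ in coords]
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    nbrs[i].append(j)
    ends = [i for i, nb in enumerate(nbrs) if len(nb) == 1]
    if len(ends) < 2:
        raise DegeneratePostureError("skeleton has no endpoints (round blob)")

    def bfs_path(src: int) -> list[int]:
        from collections import deque
        prev = {src: -1}
        q = deque([src])
        last = src
        while q:
            u = q.popleft()
            last = u
            for v in nbrs[u]:
                if v not in prev:
                    prev[v] = u
                    q.append(v)
        path = [last]
        while prev[path[-1]] != -1:
            path.append(prev[path[-1]])
        return path

    best: list[int] = []
    for e in ends:
        path = bfs_path(e)
        if len(path) > len(best):
            best = path
    pts = coords[best].astype(float) + np.array([r0 - 1, c0 - 1])
    if float(np.hypot(*(pts[0] - pts[-1]))) < 2.0 * body_width_px:
        raise DegeneratePostureError("tip separation below 2x body width")
    return Spine(_resample_open(pts, n_spine))


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def orient_by_continuity(spine: Spine, prev_oriented: Spine) -> tuple[Spine, bool]:
    """Choose the orientation maximising tip correspondence with the
    previous oriented spine.  Returns (spine, flipped)."""
    keep = (np.linalg.norm(spine.head - prev_oriented.head)
            + np.linalg.norm(spine.tail - prev_oriented.tail))
    flip = (np.linalg.norm(spine.tail - prev_oriented.head)
            + np.linalg.norm(spine.head - prev_oriented.tail))
    if flip < keep:
        return spine.flipped(), True
    return spine, False


def orient_by_motion(spine: Spine, net_displacement: np.ndarray) -> tuple[Spine, bool]:
    """Set head = endpoint leading the net displacement.  Returns
    (oriented spine, whether the input had to be flipped)."""
    d = np.asarray(net_displacement, dtype=float)
    n = float(np.hypot(*d))
    if n == 0:
        return spine, False
    d = d / n
    mid = spine.points.mean(axis=0)
    if float((spine.head - mid) @ d) >= float((spine.tail - mid) @ d):
        return spine, False
    return spine.flipped(), True


def assign_head_tail(spine: Spine, prev_oriented: Spine | None = None,
                     net_displacement: np.ndarray | None = None,
                     ) -> tuple[Spine, bool, bool]:
    """Orient a spine (tail -> head).

    Preference order: continuity with the previous frame's oriented spine;
    otherwise the net-displacement rule; otherwise the orientation is
    provisional.  Returns (spine, flipped, resolved).
    """
    if prev_oriented is not None:
        s, flipped = orient_by_continuity(spine, prev_oriented)
        return s, flipped, True
    if net_displacement is not None and np.hypot(*net_displacement) > 0:
        s, flipped = orient_by_motion(spine, net_displacement)
        return s, flipped, True
    return spine, False, False


# ---------------------------------------------------------------------------
# scalar features
# ---------------------------------------------------------------------------

def bending_angle(spine: Spine) -> float:
    """Signed angle (degrees) between tail->mid and mid->head."""
    a = spine.mid - spine.tail
    b = spine.head - spine.mid
    na, nb = np.hypot(*a), np.hypot(*b)
    if na == 0 or nb == 0:
        raise ValueError("zero-length spine segment")
    cross = a[0] * b[1] - a[1] * b[0]
    dot = float(a @ b)
    return math.degrees(math.atan2(cross, dot))


def velocity(state_t: LarvaState, state_prev: LarvaState, fps: float) -> float:
    """Centroid speed in mm/s between two consecutive frames of one track."""
    if state_t.frame_index != state_prev.frame_index + 1:
        raise GapError(
            f"frames {state_prev.frame_index} -> {state_t.frame_index} not consecutive")
    disp = float(np.hypot(*(state_t.centroid_mm - state_prev.centroid_mm)))
    return disp * fps


def accumulated_distance(frames: np.ndarray, positions_mm: np.ndarray,
                         fps: float, t_end: float = 90.0,
                         max_gap_frames: int = 5) -> float:
    """Accumulated centroid path length (mm) over the window [0, t_end].

    ``frames``/``positions_mm`` are a track's frame indices and (x, y)
    positions.  The track must cover the window: it must start within
    ``max_gap_frames`` of frame 0, reach ``t_end``, and contain no gap
    longer than ``max_gap_frames`` frames.
    """
    frames = np.asarray(frames)
    positions_mm = np.asarray(positions_mm, dtype=float)
    end_frame = int(round(t_end * fps))
    sel = frames <= end_frame
    f = frames[sel]
    p = positions_mm[sel]
    if len(f) < 2 or f[0] > max_gap_frames or f[-1] < end_frame - max_gap_frames:
        raise InsufficientTrackError(
            f"track does not cover [0, {t_end}] s within tolerance")
    gaps = np.diff(f)
    if gaps.max() > max_gap_frames:
        raise InsufficientTrackError("gap longer than tolerance inside the window")
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def count_head_sweeps(bending_deg: np.ndarray, threshold_deg: float = 30.0) -> int:
    """Number of maximal runs of consecutive frames with |bending| >= threshold.

    One run is counted as one head sweep.  NaN frames end a run.
    """
    b = np.asarray(bending_deg, dtype=float)
    above = np.abs(b) >= threshold_deg
    above &= ~np.isnan(b)
    if not above.any():
        return 0
    padded = np.concatenate([[False], above])
    return int(np.sum(~padded[:-1] & above))
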