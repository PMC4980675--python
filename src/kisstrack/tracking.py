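"""Frame-to-frame identity tracking with collision awareness.

Non-colliding animals are matched between frames by gated nearest-centroid
assignment (greedy on globally sorted distances by default; an optimal
linear-sum assignment mode is available and must agree on clean scenes).
When two or more tracked animals enter one merged blob, the blob becomes a
collision group: every track whose previous contour has at least one point
inside the merged contour is attached as a participant.  When the merged
blob splits again, participant identities are reassigned to the emerging
single blobs — by GFP flag when exactly one participant is GFP-positive,
otherwise by distance to the last resolved positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import PipelineConfig
from .posture import (
    DegeneratePostureError,
    LarvaState,
    Spine,
    assign_head_tail,
    bending_angle,
    extract_spine,
    orient_by_continuity,
    orient_by_motion,
)
from .segmentation import (
    MERGED,
    SINGLE,
    Blob,
    FramePair,
    ReferenceArea,
    SegmentationParams,
    measure_gfp,
    segment_frame,
)

logger = logging.getLogger(__name__)

_ORIENT_MIN_FRAMES = 5
_ORIENT_MIN_DISP_BL = 0.5      # body lengths of net displacement to fix orientation
_REVERSAL_WINDOW = 15          # frames over which sustained reversals flip the head
_REVERSAL_MIN_DISP_BL = 0.6


@dataclass
class Track:
    """Identity-stable sequence of per-frame larva states."""
    id: int
    states: list[LarvaState] = field(default_factory=list)
    collision_intervals: list[tuple[int, int, int]] = field(default_factory=list)
    active: bool = True
    orientation_flips: list[int] = field(default_factory=list)

    # internal bookkeeping (not part of the public record)
    _last_contour: np.ndarray | None = None
    _last_pixels: np.ndarray | None = None
    _miss: int = 0
    _prev_spine: Spine | None = None
    _orient_resolved: bool = False
    _in_group: int | None = None       # collision group id while merged

    @property
    def b_gfp(self) -> bool:
        """Majority vote of per-frame GFP calls over non-collision states."""
        votes = [s.b_gfp for s in self.states if not s.in_collision]
        if not votes:
            votes = [s.b_gfp for s in self.states]
        return bool(votes) and sum(votes) > len(votes) / 2

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame_index for s in self.states], dtype=int)

    def state_at(self, frame: int) -> LarvaState | None:
        lo, hi = 0, len(self.states) - 1
        while lo <= hi:
            mid = (lo + hi) // 2
            f = self.states[mid].frame_index
            if f == frame:
                return self.states[mid]
            if f < frame:
                lo = mid + 1
            else:
                hi = mid - 1
        return None

    @property
    def last_state(self) -> LarvaState | None:
        return self.states[-1] if self.states else None


@dataclass
class CollisionGroup:
    """A merged blob carrying >= 2 tracked animals, frame by frame."""
    id: int
    participant_ids: list[int]
    start_frame: int
    end_frame: int = -1
    blobs: dict[int, Blob] = field(default_factory=dict)   # frame -> merged blob
    active: bool = True
    unresolved: bool = False
    reassignment_method: str | None = None   # "gfp" | "distance"


def _pixel_overlap(a: np.ndarray, b: np.ndarray) -> bool:
    sa = set(map(tuple, a))
    return any((int(r), int(c)) in sa for r, c in b)


def _contour_points_in_mask(contour: np.ndarray, pixel_set: set[tuple[int, int]]) -> bool:
    pts = np.round(contour).astype(int)
    return any((int(r), int(c)) in pixel_set for r, c in pts)


def _greedy_assign(costs: list[tuple[float, int, int]], gate: float,
                   ) -> dict[int, int]:
    """costs: (distance, track_key, blob_key); returns track_key -> blob_key."""
    out: dict[int, int] = {}
    used_blobs: set[int] = set()
    for d, tk, bk in sorted(costs):
        if d > gate or tk in out or bk in used_blobs:
            continue
        out[tk] = bk
        used_blobs.add(bk)
    return out


def _optimal_assign(tracks_pos: dict[int, np.ndarray],
                    blobs_pos: dict[int, np.ndarray], gate: float) -> dict[int, int]:
    tks = sorted(tracks_pos)
    bks = sorted(blobs_pos)
    if not tks or not bks:
        return {}
    big = 1e6
    cost = np.full((len(tks), len(bks)), big)
    for i, tk in enumerate(tks):
        for j, bk in enumerate(bks):
            d = float(np.hypot(*(tracks_pos[tk] - blobs_pos[bk])))
            if d <= gate:
                cost[i, j] = d
    rows, cols = linear_sum_assignment(cost)
    return {tks[i]: bks[j] for i, j in zip(rows, cols) if cost[i, j] < big}


class Tracker:
    """Stateful per-frame tracker; feed frames in order via :meth:`step`."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.seg_params = SegmentationParams(
            ir_threshold=config.ir_threshold,
            auto_threshold=config.auto_threshold,
            min_area=config.min_area,
            merged_area_factor=config.merged_area_factor,
            gfp_threshold=config.gfp_threshold,
            gfp_fraction_min=config.gfp_fraction_min,
        )
        self.reference = ReferenceArea()
        self.tracks: list[Track] = []
        self.groups: list[CollisionGroup] = []
        self._next_track = 0
        self._next_group = 0
        self.frame_count = 0
        self.blob_count = 0

    # -- helpers ---------------------------------------------------------
    def _track(self, tid: int) -> Track:
        return self.tracks[tid]

    def _px_to_mm(self, centroid_px: np.ndarray) -> np.ndarray:
        s = self.config.px_per_mm
        return np.array([centroid_px[1] / s, centroid_px[0] / s])

    def _body_width_px(self) -> float:
        return self.config.body_width * self.config.px_per_mm

    def make_state(self, blob: Blob, frame_index: int, track: Track | None,
                   in_collision: bool = False,
                   prev_spine: Spine | None = None) -> LarvaState:
        """Build a LarvaState from a blob, with oriented spine if possible.

        ``prev_spine`` overrides the track's running previous spine (used
        when states are inserted out of order, e.g. collision splits).
        """
        spine = None
        bend = math.nan
        try:
            spine = extract_spine(blob, self.config.n_spine, self._body_width_px())
        except DegeneratePostureError:
            pass
        resolved = False
        if spine is not None:
            prev = prev_spine if prev_spine is not None else (
                track._prev_spine if track is not None else None)
            if prev is not None and (track is None or track._orient_resolved
                                     or prev_spine is not None):
                spine, _, _ = assign_head_tail(spine, prev_oriented=prev)
                resolved = True
            elif prev is not None:
                spine, _ = orient_by_continuity(spine, prev)
        if spine is not None:
            try:
                bend = bending_angle(spine)
            except ValueError:
                bend = math.nan
        state = LarvaState(
            frame_index=frame_index,
            contour=blob.contour,
            spine=spine,
            centroid_mm=self._px_to_mm(blob.centroid),
            centroid_px=blob.centroid.copy(),
            bending_angle=bend,
            b_gfp=bool(blob.b_gfp),
            in_collision=in_collision,
            orientation_resolved=resolved,
        )
        return state

    def _append_state(self, track: Track, blob: Blob, state: LarvaState) -> None:
        track.states.append(state)
        track._last_contour = blob.contour
        track._last_pixels = blob.pixels
        track._miss = 0
        if state.spine is not None:
            track._prev_spine = state.spine
        self._maybe_resolve_orientation(track)

    def _maybe_resolve_orientation(self, track: Track) -> None:
        """Fix head/tail from net displacement and back-propagate; afterwards
        watch for sustained reversals and log orientation flips."""
        cfg = self.config
        states = [s for s in track.states if s.spine is not None]
        if len(states) < _ORIENT_MIN_FRAMES:
            return
        if not track._orient_resolved:
            disp = states[-1].centroid_px - states[0].centroid_px
            if np.hypot(*disp) >= _ORIENT_MIN_DISP_BL * cfg.body_length * cfg.px_per_mm:
                # displacement is (row, col), same frame as the spine points
                oriented, flipped = orient_by_motion(states[-1].spine, disp)
                states[-1].spine = oriented
                states[-1].bending_angle = (-states[-1].bending_angle
                                            if flipped else states[-1].bending_angle)
                for prev, cur in zip(reversed(states[:-1]), reversed(states)):
                    new, fl = orient_by_continuity(prev.spine, cur.spine)
                    prev.spine = new
                    if fl and not math.isnan(prev.bending_angle):
                        prev.bending_angle = -prev.bending_angle
                for s in states:
                    s.orientation_resolved = True
                track._orient_resolved = True
                track._prev_spine = states[-1].spine
            return
        # resolved: check for sustained reversals
        recent = states[-_REVERSAL_WINDOW:]
        if len(recent) < _REVERSAL_WINDOW:
            return
        disp = recent[-1].centroid_px - recent[0].centroid_px
        if np.hypot(*disp) < _REVERSAL_MIN_DISP_BL * cfg.body_length * cfg.px_per_mm:
            return
        cur = recent[-1].spine
        _, flipped = orient_by_motion(cur, disp)
        if flipped:
            frame = recent[-1].frame_index
            if not track.orientation_flips or frame - track.orientation_flips[-1] > _REVERSAL_WINDOW:
                track.orientation_flips.append(frame)
                logger.info("track %d: orientation flip at frame %d", track.id, frame)
            for s in recent:
                if s.spine is not None:
                    s.spine = s.spine.flipped()
                    if not math.isnan(s.bending_angle):
                        s.bending_angle = -s.bending_angle
            track._prev_spine = recent[-1].spine

    def _new_track(self, blob: Blob, frame_index: int) -> Track:
        track = Track(id=self._next_track)
        self._next_track += 1
        state = self.make_state(blob, frame_index, None)
        self._append_state(track, blob, state)
        self.tracks.append(track)
        return track

    # -- main step -------------------------------------------------------
    def step(self, frame: FramePair) -> list[CollisionGroup]:
        """Process one frame; returns collision groups opened at this frame."""
        cfg = self.config
        t = frame.frame_index
        self.frame_count += 1
        blobs = segment_frame(frame, self.seg_params, self.reference.value)
        gfp_img = frame.gfp
        if cfg.gfp_smooth_sigma > 0:
            from scipy.ndimage import gaussian_filter
            gfp_img = gaussian_filter(frame.gfp, cfg.gfp_smooth_sigma)
        for b in blobs:
            measure_gfp(b, frame.gfp, cfg.gfp_threshold, cfg.gfp_fraction_min)
            # retain per-pixel (denoised) GFP intensities so merged blobs can
            # be split later without re-reading the frame
            b.gfp_values = gfp_img[b.pixels[:, 0], b.pixels[:, 1]].copy()
        self.blob_count += len(blobs)

        free_tracks = [tr for tr in self.tracks if tr.active and tr._in_group is None]
        gate = cfg.gate_px

        # a SINGLE blob into which >= 2 tracks map is a collision, whatever
        # its area
        for blob in blobs:
            if blob.kind != SINGLE:
                continue
            claimants = []
            for tr in free_tracks:
                last = tr.last_state
                if last is None:
                    continue
                d = float(np.hypot(*(last.centroid_px - blob.centroid)))
                if d <= gate:
                    others = [b2 for b2 in blobs if b2 is not blob and b2.kind == SINGLE
                              and float(np.hypot(*(last.centroid_px - b2.centroid))) < d]
                    if not others:
                        claimants.append(tr)
            if len(claimants) >= 2:
                blob.kind = MERGED

        # hysteresis: a blob continuing an active collision group stays
        # MERGED even if deep body overlap shrinks its area below the
        # classification threshold (down to ~1.2x a single animal)
        ref = self.reference.value
        for blob in blobs:
            if blob.kind != SINGLE or ref is None or blob.area <= 1.2 * ref:
                continue
            for grp in self.groups:
                if not grp.active:
                    continue
                last_blob = grp.blobs[max(grp.blobs)]
                if np.hypot(*(last_blob.centroid - blob.centroid)) <= gate and \
                        _pixel_overlap(last_blob.pixels, blob.pixels):
                    blob.kind = MERGED
                    break

        merged = [b for b in blobs if b.kind == MERGED]
        singles = [b for b in blobs if b.kind == SINGLE]
        self.reference.update([b.area for b in singles])
        claimed_singles: set[int] = set()
        opened: list[CollisionGroup] = []

        # 1. continue existing groups on overlapping merged blobs
        merged_taken: set[int] = set()
        for grp in [g for g in self.groups if g.active]:
            last_blob = grp.blobs[max(grp.blobs)]
            last_set = set(map(tuple, last_blob.pixels))
            found = None
            for k, b in enumerate(merged):
                if k in merged_taken:
                    continue
                if any((int(r), int(c)) in last_set for r, c in b.pixels[::4]):
                    found = k
                    break
            if found is None:
                for k, b in enumerate(merged):
                    if k in merged_taken:
                        continue
                    if float(np.hypot(*(last_blob.centroid - b.centroid))) <= gate:
                        found = k
                        break
            if found is not None:
                merged_taken.add(found)
                blob = merged[found]
                grp.blobs[t] = blob
                # late joiners make the group bigger (and unresolvable)
                pixset = blob.pixel_set()
                for tr in free_tracks:
                    if tr._in_group is None and tr._last_contour is not None and \
                            _contour_points_in_mask(tr._last_contour, pixset):
                        grp.participant_ids.append(tr.id)
                        tr._in_group = grp.id
            else:
                self._close_group(grp, t, singles, claimed_singles)

        # 2. open new groups on unclaimed merged blobs
        for k, blob in enumerate(merged):
            if k in merged_taken:
                continue
            pixset = blob.pixel_set()
            participants = [tr for tr in free_tracks
                            if tr._in_group is None and tr._last_contour is not None
                            and _contour_points_in_mask(tr._last_contour, pixset)]
            if len(participants) >= 2:
                grp = CollisionGroup(id=self._next_group,
                                     participant_ids=[tr.id for tr in participants],
                                     start_frame=t)
                self._next_group += 1
                grp.blobs[t] = blob
                for tr in participants:
                    tr._in_group = grp.id
                    tr.collision_intervals.append((t, -1, grp.id))
                self.groups.append(grp)
                opened.append(grp)
            elif len(participants) == 1:
                # an oversized blob with a single occupant is just that animal
                tr = participants[0]
                state = self.make_state(blob, t, tr)
                self._append_state(tr, blob, state)
            # merged blobs never seed new tracks

        # 3. match free tracks to single blobs
        free_tracks = [tr for tr in self.tracks if tr.active and tr._in_group is None]
        open_singles = [k for k in range(len(singles)) if k not in claimed_singles]
        track_pos = {tr.id: tr.last_state.centroid_px for tr in free_tracks
                     if tr.last_state is not None}
        blob_pos = {k: singles[k].centroid for k in open_singles}
        if cfg.assignment == "optimal":
            matches = _optimal_assign(track_pos, blob_pos, gate)
        else:
            costs = [(float(np.hypot(*(track_pos[tid] - blob_pos[k]))), tid, k)
                     for tid in sorted(track_pos) for k in open_singles]
            matches = _greedy_assign(costs, gate)
        for tid, k in matches.items():
            tr = self._track(tid)
            blob = singles[k]
            state = self.make_state(blob, t, tr)
            self._append_state(tr, blob, state)
            claimed_singles.add(k)
        # unmatched tracks age; stale tracks close
        for tr in free_tracks:
            if tr.id not in matches:
                tr._miss += 1
                if tr._miss > cfg.max_gap:
                    tr.active = False
        # leftover single blobs open new tracks
        for k in range(len(singles)):
            if k not in claimed_singles:
                self._new_track(singles[k], t)
        return opened

    # -- group closing / identity reassignment ---------------------------
    def _close_group(self, grp: CollisionGroup, t: int,
                     singles: list[Blob], claimed: set[int]) -> None:
        cfg = self.config
        grp.active = False
        grp.end_frame = max(grp.blobs)
        last_blob = grp.blobs[grp.end_frame]
        participants = [self._track(tid) for tid in grp.participant_ids]
        for tr in participants:
            # close out the open collision interval annotation
            for i, (s0, e0, gid) in enumerate(tr.collision_intervals):
                if gid == grp.id and e0 == -1:
                    tr.collision_intervals[i] = (s0, grp.end_frame, gid)
            tr._in_group = None

        near = [k for k in range(len(singles)) if k not in claimed and
                float(np.hypot(*(singles[k].centroid - last_blob.centroid)))
                <= 1.5 * cfg.body_length * cfg.px_per_mm]
        if len(near) != len(participants):
            grp.unresolved = True
            logger.warning("collision %d: %d participants but %d split blobs; "
                           "resuming by distance", grp.id, len(participants), len(near))
        gfp_votes = [tr.b_gfp for tr in participants]
        use_gfp = (len(participants) == 2 and sum(gfp_votes) == 1 and len(near) == 2
                   and sum(bool(singles[k].b_gfp) for k in near) == 1)
        if use_gfp:
            grp.reassignment_method = "gfp"
            gfp_track = participants[0] if gfp_votes[0] else participants[1]
            other_track = participants[1] if gfp_votes[0] else participants[0]
            gfp_blob = near[0] if singles[near[0]].b_gfp else near[1]
            other_blob = near[1] if singles[near[0]].b_gfp else near[0]
            pairs = [(gfp_track, gfp_blob), (other_track, other_blob)]
        else:
            grp.reassignment_method = "distance"
            costs = [(float(np.hypot(*(tr.last_state.centroid_px - singles[k].centroid))),
                      tr.id, k)
                     for tr in participants if tr.last_state is not None for k in near]
            assign = _greedy_assign(costs, np.inf)
            pairs = [(self._track(tid), k) for tid, k in assign.items()]
            if not grp.unresolved:
                logger.info("collision %d: post-collision identities assigned by "
                            "distance (lower confidence)", grp.id)
        for tr, k in pairs:
            blob = singles[k]
            state = self.make_state(blob, t, tr)
            self._append_state(tr, blob, state)
            claimed.add(k)

    # -- finalisation ----------------------------------------------------
    def finalize(self) -> None:
        """Close open groups and fill per-state velocities."""
        from .posture import velocity as _velocity
        for grp in self.groups:
            if grp.active:
                grp.active = False
                grp.end_frame = max(grp.blobs)
                for tid in grp.participant_ids:
                    tr = self._track(tid)
                    for i, (s0, e0, gid) in enumerate(tr.collision_intervals):
                        if gid == grp.id and e0 == -1:
                            tr.collision_intervals[i] = (s0, grp.end_frame, gid)
                    tr._in_group = None
        for tr in self.tracks:
            tr.states.sort(key=lambda s: s.frame_index)
            for prev, cur in zip(tr.states, tr.states[1:]):
                if cur.frame_index == prev.frame_index + 1:
                    cur.velocity = _velocity(cur, prev, self.config.fps)
                else:
                    cur.velocity = None


def assign_identities(tracker: Tracker, frame: FramePair) -> list[CollisionGroup]:
    """Assign this frame's blobs to the tracker's tracks (one step)."""
    return tracker.step(frame)


def track_scene(frames, config: PipelineConfig) -> Tracker:
    """Track a whole frame sequence; returns the finalised tracker."""
    tracker = Tracker(config)
    for frame in frames:
        tracker.step(frame)
    tracker.finalize()
    return tracker


def features_from_tracks(tracks: list[Track], fps: float,
                         bend_thresholds: tuple[float, float] = (30.0, 40.0),
                         ) -> "pd.DataFrame":
    """Long-format feature table: one row per frame x tracked animal."""
    rows = []
    for tr in tracks:
        gfp = tr.b_gfp
        for s in tr.states:
            ax_x = ax_y = math.nan
            if s.spine is not None:
                d = s.spine.head - s.spine.tail
                n = float(np.hypot(*d))
                if n > 0:
                    ax_y, ax_x = d[0] / n, d[1] / n   # (row, col) -> (y, x)
            rows.append({
                "frame": s.frame_index,
                "time_s": s.frame_index / fps,
                "id": tr.id,
                "x_mm": s.centroid_mm[0],
                "y_mm": s.centroid_mm[1],
                "bending_deg": s.bending_angle,
                "velocity_mm_s": math.nan if s.velocity is None else s.velocity,
                "is_bend30": (not math.isnan(s.bending_angle))
                             and abs(s.bending_angle) >= bend_thresholds[0],
                "is_bend40": (not math.isnan(s.bending_angle))
                             and abs(s.bending_angle) >= bend_thresholds[1],
                "b_gfp": gfp,
                "in_collision": s.in_collision,
                "axis_x": ax_x,
                "axis_y": ax_y,
            })
    import pandas as pd
    cols = ["frame", "time_s", "id", "x_mm", "y_mm", "bending_deg",
            "velocity_mm_s", "is_bend30", "is_bend40", "b_gfp", "in_collision",
            "axis_x", "axis_y"]
    return pd.DataFrame(rows, columns=cols).sort_values(["frame", "id"],
                                                        ignore_index=True)


def tracks_from_features(features) -> list[Track]:
    """Rebuild lightweight tracks (states without contours/spines) from a
    feature table — enough for the behavioral analyses and CLI composition."""
    tracks = []
    for tid, sub in features.groupby("id"):
        sub = sub.sort_values("frame")
        tr = Track(id=int(tid))
        for row in sub.itertuples():
            vel = None if (isinstance(row.velocity_mm_s, float)
                           and math.isnan(row.velocity_mm_s)) else float(row.velocity_mm_s)
            tr.states.append(LarvaState(
                frame_index=int(row.frame), contour=None, spine=None,
                centroid_mm=np.array([row.x_mm, row.y_mm]),
                centroid_px=np.array([np.nan, np.nan]),
                bending_angle=float(row.bending_deg),
                velocity=vel,
                b_gfp=bool(row.b_gfp),
                in_collision=bool(row.in_collision)))
        tracks.append(tr)
    return tracks
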