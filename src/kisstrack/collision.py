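"""Two-color collision resolution.

A collision is *resolvable* only when exactly two animals participate and
exactly one of them is GFP-positive; every other collision is rejected.  On
a resolvable collision frame the merged contour is split by the GFP
channel: every suprathreshold GFP pixel inside the merged blob is assigned
to the GFP animal, every remaining pixel to the other animal.  Each part is
reduced to its largest connected component (dropped fragments are logged)
and then flows through the normal posture feature extraction.

*Valid* collisions additionally last longer than 0.5 s with both animals
traceable and free of any other collision for at least 1 s before and
after — the filter applied before any phase-aligned statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .segmentation import Blob, _outer_contour
from .tracking import CollisionGroup, Track

logger = logging.getLogger(__name__)

_FRAGMENT_LOW_CONFIDENCE = 0.30   # part losing more of its pixels is flagged


@dataclass
class SplitResult:
    """One frame's channel split of a merged blob into two animal parts."""
    gfp_blob: Blob
    other_blob: Blob
    low_confidence: bool = False
    dropped_px: int = 0


@dataclass
class CollisionEvent:
    """An interval during which >= 2 tracked animals share one contour."""
    collision_id: int
    participant_track_ids: list[int]
    start_frame: int
    end_frame: int
    fps: float
    resolvable: bool = False
    valid: bool = False
    gfp_track_id: int | None = None
    other_track_id: int | None = None
    splits: dict[int, SplitResult] = field(default_factory=dict)
    n_unsplittable: int = 0
    merged_blobs: dict[int, Blob] = field(default_factory=dict)
    reassignment_method: str | None = None

    @property
    def duration(self) -> float:
        return (self.end_frame - self.start_frame + 1) / self.fps


class UnsplittableFrame(ValueError):
    """Channel split produced an empty part on this frame."""


def is_resolvable(event: CollisionEvent) -> bool:
    """Exactly two participants, exactly one of them GFP-positive."""
    if len(event.participant_track_ids) != 2:
        return False
    return event.gfp_track_id is not None and event.other_track_id is not None


def classify_event(event: CollisionEvent, tracks: dict[int, Track]) -> None:
    """Fill the GFP / non-GFP participant roles and the resolvable flag."""
    event.gfp_track_id = event.other_track_id = None
    if len(event.participant_track_ids) == 2:
        flags = [tracks[tid].b_gfp for tid in event.participant_track_ids]
        if sum(flags) == 1:
            event.gfp_track_id = event.participant_track_ids[flags.index(True)]
            event.other_track_id = event.participant_track_ids[flags.index(False)]
    event.resolvable = is_resolvable(event)


def _largest_component(pixels: np.ndarray) -> tuple[np.ndarray, int]:
    """Largest 8-connected component of a pixel set; returns (kept, dropped)."""
    r0, c0 = pixels.min(axis=0)
    r1, c1 = pixels.max(axis=0)
    mask = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    mask[pixels[:, 0] - r0, pixels[:, 1] - c0] = True
    labels = measure.label(mask, connectivity=2)
    if labels.max() <= 1:
        return pixels, 0
    counts = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(counts)) + 1
    kept = np.argwhere(labels == keep) + np.array([r0, c0])
    return kept.astype(np.int32), int(len(pixels) - len(kept))


def _part_blob(pixels: np.ndarray) -> Blob:
    r0, c0 = pixels.min(axis=0)
    r1, c1 = pixels.max(axis=0)
    mask = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    mask[pixels[:, 0] - r0, pixels[:, 1] - c0] = True
    contour = _outer_contour(mask, (int(r0), int(c0)))
    return Blob(pixels=pixels, contour=contour, area=int(len(pixels)),
                centroid=pixels.mean(axis=0).astype(float))


def split_collision(blob: Blob, gfp_image: np.ndarray | None,
                    gfp_threshold: float) -> SplitResult:
    """Partition a merged blob into its GFP and non-GFP animal.

    ``gfp_image`` may be None when the blob carries its own per-pixel GFP
    intensities (``blob.gfp_values``).  Raises :class:`UnsplittableFrame`
    when either part comes out empty (e.g. the whole blob is suprathreshold
    in the GFP channel); the event survives, that frame simply carries no
    per-animal features.
    """
    if gfp_image is not None:
        vals = gfp_image[blob.pixels[:, 0], blob.pixels[:, 1]]
    elif blob.gfp_values is not None:
        vals = blob.gfp_values
    else:
        raise ValueError("need a GFP image or per-blob GFP values")
    is_gfp = vals >= gfp_threshold
    gfp_px = blob.pixels[is_gfp]
    other_px = blob.pixels[~is_gfp]
    if len(gfp_px) == 0 or len(other_px) == 0:
        raise UnsplittableFrame(
            f"frame split empty (gfp {len(gfp_px)} px, other {len(other_px)} px)")
    gfp_keep, gfp_drop = _largest_component(gfp_px)
    other_keep, other_drop = _largest_component(other_px)
    dropped = gfp_drop + other_drop
    low = (gfp_drop > _FRAGMENT_LOW_CONFIDENCE * len(gfp_px)
           or other_drop > _FRAGMENT_LOW_CONFIDENCE * len(other_px))
    if dropped:
        logger.debug("split: dropped %d fragment px", dropped)
    return SplitResult(gfp_blob=_part_blob(gfp_keep),
                       other_blob=_part_blob(other_keep),
                       low_confidence=low, dropped_px=dropped)


def events_from_groups(groups: list[CollisionGroup], tracks: list[Track],
                       fps: float) -> list[CollisionEvent]:
    """Turn the tracker's raw collision groups into CollisionEvents."""
    by_id = {tr.id: tr for tr in tracks}
    events = []
    for grp in groups:
        end = grp.end_frame if grp.end_frame >= 0 else max(grp.blobs)
        ev = CollisionEvent(
            collision_id=grp.id,
            participant_track_ids=list(dict.fromkeys(grp.participant_ids)),
            start_frame=grp.start_frame,
            end_frame=end,
            fps=fps,
            merged_blobs=dict(grp.blobs),
            reassignment_method=grp.reassignment_method,
        )
        classify_event(ev, by_id)
        events.append(ev)
    return events


def events_to_dataframe(events: list[CollisionEvent]) -> "pd.DataFrame":
    import pandas as pd
    rows = []
    for ev in events:
        rows.append({
            "collision_id": ev.collision_id,
            "id_gfp": -1 if ev.gfp_track_id is None else ev.gfp_track_id,
            "id_other": -1 if ev.other_track_id is None else ev.other_track_id,
            "participant_ids": ";".join(str(t) for t in ev.participant_track_ids),
            "start_frame": ev.start_frame,
            "end_frame": ev.end_frame,
            "duration_s": ev.duration,
            "resolvable": ev.resolvable,
            "valid": ev.valid,
            "n_unsplittable_frames": ev.n_unsplittable,
            "reassignment_method": ev.reassignment_method or "",
        })
    cols = ["collision_id", "id_gfp", "id_other", "participant_ids",
            "start_frame", "end_frame", "duration_s", "resolvable", "valid",
            "n_unsplittable_frames", "reassignment_method"]
    return pd.DataFrame(rows, columns=cols)


def events_from_dataframe(df, fps: float) -> list[CollisionEvent]:
    """Rebuild events (without per-frame blobs) from a collisions table."""
    events = []
    for row in df.itertuples():
        ev = CollisionEvent(
            collision_id=int(row.collision_id),
            participant_track_ids=[int(t) for t in str(row.participant_ids).split(";") if t != ""],
            start_frame=int(row.start_frame),
            end_frame=int(row.end_frame),
            fps=fps,
            resolvable=bool(row.resolvable),
            valid=bool(row.valid),
            gfp_track_id=None if row.id_gfp < 0 else int(row.id_gfp),
            other_track_id=None if row.id_other < 0 else int(row.id_other),
            n_unsplittable=int(row.n_unsplittable_frames),
        )
        events.append(ev)
    return events


def filter_valid_collisions(events: list[CollisionEvent], tracks: list[Track],
                            min_duration_s: float = 0.5, flank_s: float = 1.0,
                            fps: float | None = None) -> list[CollisionEvent]:
    """Apply the validity criteria and return the kept events.

    Valid means: resolvable, duration strictly greater than
    ``min_duration_s``, and both participants fully traceable and involved
    in no other collision for at least ``flank_s`` before the start and
    after the end of the event.  Sets ``event.valid`` on every input.
    """
    by_id = {tr.id: tr for tr in tracks}
    if fps is None:
        fps = events[0].fps if events else 10.0
    flank_f = int(round(flank_s * fps))
    for ev in events:
        ev.valid = False
        if not ev.resolvable or ev.duration <= min_duration_s:
            continue
        ok = True
        for tid in ev.participant_track_ids:
            tr = by_id[tid]
            for f in range(ev.start_frame - flank_f, ev.start_frame):
                if tr.state_at(f) is None:
                    ok = False
                    break
            if ok:
                for f in range(ev.end_frame + 1, ev.end_frame + flank_f + 1):
                    if tr.state_at(f) is None:
                        ok = False
                        break
            if not ok:
                break
            for other in events:
                if other is ev or tid not in other.participant_track_ids:
                    continue
                if (other.start_frame <= ev.end_frame + flank_f and
                        other.end_frame >= ev.start_frame - flank_f):
                    ok = False
                    break
            if not ok:
                break
        ev.valid = ok
    return [ev for ev in events if ev.valid]


def collision_duration_stats(events: list[CollisionEvent],
                             short_s: float = 0.5) -> dict:
    """Per-event durations plus the short-collision fraction and median."""
    if not events:
        raise ValueError("no collision events")
    durations = np.array([ev.duration for ev in events])
    return {
        "durations_s": durations,
        "fraction_short": float(np.mean(durations < short_s)),
        "median_s": float(np.median(durations)),
    }


def resolve_event(event: CollisionEvent, tracker) -> None:
    """Split every frame of a resolvable event and append the per-animal
    states (flagged ``in_collision``) to the participant tracks.

    Uses the per-pixel GFP intensities retained on the merged blobs during
    tracking.  Degenerate postures and unsplittable frames are tolerated
    per frame.  Call ``tracker.finalize()`` afterwards to restore frame
    order and velocities.
    """
    if not event.resolvable:
        return
    by_id = {tr.id: tr for tr in tracker.tracks}
    gfp_track = by_id[event.gfp_track_id]
    other_track = by_id[event.other_track_id]
    prev_spines = {}
    existing = {}
    for tr in (gfp_track, other_track):
        before = [s for s in tr.states
                  if s.frame_index < event.start_frame and s.spine is not None]
        prev_spines[tr.id] = before[-1].spine if before else None
        existing[tr.id] = {s.frame_index for s in tr.states}
    for f in sorted(event.merged_blobs):
        blob = event.merged_blobs[f]
        try:
            split = split_collision(blob, None, tracker.config.gfp_threshold)
        except UnsplittableFrame:
            event.n_unsplittable += 1
            continue
        event.splits[f] = split
        for tr, part, flag in ((gfp_track, split.gfp_blob, True),
                               (other_track, split.other_blob, False)):
            state = tracker.make_state(part, f, tr, in_collision=True,
                                       prev_spine=prev_spines[tr.id])
            state.b_gfp = flag   # frozen to the channel that defined the part
            if state.spine is not None:
                prev_spines[tr.id] = state.spine
            if f not in existing[tr.id]:
                tr.states.append(state)
                existing[tr.id].add(f)
    for tr in (gfp_track, other_track):
        tr.states.sort(key=lambda s: s.frame_index)
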