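"""Collision resolution: resolvability, channel split, validity filter."""

import numpy as np
import pytest

from kisstrack.collision import (
    CollisionEvent,
    UnsplittableFrame,
    collision_duration_stats,
    filter_valid_collisions,
    is_resolvable,
    split_collision,
)
from kisstrack.posture import LarvaState
from kisstrack.segmentation import Blob
from kisstrack.tracking import Track
from tests.conftest import map_tracks_to_truth, match_event

FPS = 10.0


def _event(cid, participants, start, end, gfp=None, other=None):
    return CollisionEvent(collision_id=cid, participant_track_ids=participants,
                          start_frame=start, end_frame=end, fps=FPS,
                          gfp_track_id=gfp, other_track_id=other)


def _track(tid, frames, gfp=False):
    tr = Track(id=tid)
    for f in frames:
        tr.states.append(LarvaState(frame_index=f, contour=None, spine=None,
                                    centroid_mm=np.zeros(2),
                                    centroid_px=np.zeros(2), b_gfp=gfp))
    return tr


# -- resolvability -----------------------------------------------------------

@pytest.mark.parametrize("participants,gfp,other,expected", [
    ([1, 2], 1, 2, True),     # GFP + non-GFP
    ([1, 2], None, None, False),   # two same-genotype animals
    ([1, 2, 3], None, None, False),  # three participants
])
def test_is_resolvable_rule(participants, gfp, other, expected):
    ev = _event(0, participants, 10, 20, gfp, other)
    assert is_resolvable(ev) is expected


# -- channel split -----------------------------------------------------------

def _rect_blob(r0, c0, h, w):
    rr, cc = np.mgrid[r0:r0 + h, c0:c0 + w]
    px = np.stack([rr.ravel(), cc.ravel()], axis=-1).astype(np.int32)
    return Blob(pixels=px, contour=px[:1].astype(float), area=len(px),
                centroid=px.mean(axis=0))


def test_split_left_half_gfp():
    blob = _rect_blob(10, 10, 8, 20)
    gfp = np.zeros((40, 40), dtype=np.float32)
    gfp[:, :20] = 1.0    # left half suprathreshold
    split = split_collision(blob, gfp, 0.3)
    assert np.all(split.gfp_blob.pixels[:, 1] < 20)
    assert np.all(split.other_blob.pixels[:, 1] >= 20)
    # disjoint union within the blob
    all_px = set(map(tuple, blob.pixels))
    ga = set(map(tuple, split.gfp_blob.pixels))
    ob = set(map(tuple, split.other_blob.pixels))
    assert not (ga & ob)
    assert ga <= all_px and ob <= all_px


def test_split_all_gfp_unsplittable():
    blob = _rect_blob(10, 10, 8, 20)
    with pytest.raises(UnsplittableFrame):
        split_collision(blob, np.ones((40, 40), dtype=np.float32), 0.3)


def test_split_parts_disjoint_on_scene(small_result):
    for ev in small_result.events:
        for f, sp in ev.splits.items():
            merged = set(map(tuple, ev.merged_blobs[f].pixels))
            ga = set(map(tuple, sp.gfp_blob.pixels))
            ob = set(map(tuple, sp.other_blob.pixels))
            assert not (ga & ob)
            assert ga <= merged and ob <= merged


def test_split_masks_match_ground_truth(small_scene, small_result):
    """Per-animal split masks overlap the true body masks (IoU >= 0.7 for
    >= 90% of collision frames)."""
    cfg, gt, _ = small_scene
    mapping = map_tracks_to_truth(small_result, gt)
    sc = gt.collisions[0]
    ev = match_event(small_result, mapping, sc)
    assert ev is not None and ev.splits
    gfp_gt = sc.id_a if gt.gfp[sc.id_a] else sc.id_b
    oth_gt = sc.id_b if gt.gfp[sc.id_a] else sc.id_a
    ious = []
    for f, sp in ev.splits.items():
        for part, gid in ((sp.gfp_blob, gfp_gt), (sp.other_blob, oth_gt)):
            gm = gt.animal_mask(f, gid)
            pm = np.zeros_like(gm)
            pm[part.pixels[:, 0], part.pixels[:, 1]] = True
            ious.append((gm & pm).sum() / (gm | pm).sum())
    assert np.mean(np.asarray(ious) >= 0.7) >= 0.9


# -- validity filter ---------------------------------------------------------

def _brute_force_valid(events, tracks, min_s=0.5, flank_s=1.0, fps=FPS):
    """Independent oracle: direct scan over interval lists and coverage."""
    cover = {tr.id: {s.frame_index for s in tr.states} for tr in tracks}
    flank = int(round(flank_s * fps))
    out = []
    for ev in events:
        if not (ev.resolvable and ev.duration > min_s):
            continue
        ok = True
        for tid in ev.participant_track_ids:
            need = set(range(ev.start_frame - flank, ev.start_frame)) | \
                set(range(ev.end_frame + 1, ev.end_frame + flank + 1))
            if not need <= cover[tid]:
                ok = False
            for other in events:
                if other is ev or tid not in other.participant_track_ids:
                    continue
                if other.start_frame <= ev.end_frame + flank and \
                        other.end_frame >= ev.start_frame - flank:
                    ok = False
        if ok:
            out.append(ev.collision_id)
    return sorted(out)


def test_validity_boundary_cases():
    tracks = [_track(1, range(0, 200), gfp=True), _track(2, range(0, 200))]
    short = _event(0, [1, 2], 50, 53, gfp=1, other=2)       # 0.4 s -> rejected
    short.resolvable = True
    good = _event(1, [1, 2], 100, 124, gfp=1, other=2)      # 2.5 s, clean flanks
    good.resolvable = True
    kept = filter_valid_collisions([short, good], tracks, 0.5, 1.0, FPS)
    assert [ev.collision_id for ev in kept] == [1]
    assert short.valid is False and good.valid is True


def test_flank_violation_rejected():
    tracks = [_track(1, range(0, 300), gfp=True), _track(2, range(0, 300)),
              _track(3, range(0, 300))]
    ev1 = _event(0, [1, 2], 100, 119, gfp=1, other=2)   # 2 s
    ev1.resolvable = True
    ev2 = _event(1, [2, 3], 125, 140)                   # starts 0.5 s after ev1 ends
    kept = filter_valid_collisions([ev1, ev2], tracks, 0.5, 1.0, FPS)
    assert kept == []


def test_exact_half_second_duration_rejected():
    """duration must be strictly greater than 0.5 s."""
    tracks = [_track(1, range(0, 100), gfp=True), _track(2, range(0, 100))]
    ev = _event(0, [1, 2], 50, 54, gfp=1, other=2)   # 5 frames = 0.5 s
    ev.resolvable = True
    assert filter_valid_collisions([ev], tracks, 0.5, 1.0, FPS) == []


def test_filter_matches_brute_force_on_randomized_events():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n_tracks = rng.integers(2, 6)
        tracks = []
        for tid in range(n_tracks):
            gap_start = rng.integers(0, 150)
            frames = [f for f in range(150)
                      if not (gap_start <= f < gap_start + rng.integers(0, 30))]
            tracks.append(_track(tid, frames, gfp=bool(tid % 2)))
        events = []
        for cid in range(rng.integers(1, 4)):
            a, b = rng.choice(n_tracks, size=2, replace=False)
            start = int(rng.integers(5, 120))
            end = start + int(rng.integers(1, 30))
            ev = _event(cid, [int(a), int(b)], start, end)
            if bool(tracks[a].states[0].b_gfp) != bool(tracks[b].states[0].b_gfp):
                ev.gfp_track_id = int(a) if tracks[a].states[0].b_gfp else int(b)
                ev.other_track_id = int(b) if tracks[a].states[0].b_gfp else int(a)
                ev.resolvable = True
            events.append(ev)
        kept = filter_valid_collisions(events, tracks, 0.5, 1.0, FPS)
        assert sorted(ev.collision_id for ev in kept) == \
            _brute_force_valid(events, tracks)


def test_valid_subset_of_resolvable(small_result):
    res_ids = {ev.collision_id for ev in small_result.events if ev.resolvable}
    val_ids = {ev.collision_id for ev in small_result.valid_events}
    assert val_ids <= res_ids


# -- duration stats ----------------------------------------------------------

def test_duration_stats_examples():
    events = [_event(i, [1, 2], 0, int(d * FPS) - 1)
              for i, d in enumerate([0.3, 0.4, 1.0, 2.0])]
    stats = collision_duration_stats(events)
    assert stats["fraction_short"] == 0.5
    assert stats["median_s"] == pytest.approx(0.7)
    one = collision_duration_stats([_event(0, [1, 2], 0, 9)])
    assert one["median_s"] == pytest.approx(1.0)
    assert one["fraction_short"] == 0.0
    with pytest.raises(ValueError):
        collision_duration_stats([])


def test_scripted_durations_recovered(small_scene, small_result):
    cfg, gt, _ = small_scene
    mapping = map_tracks_to_truth(small_result, gt)
    for sc in gt.collisions:
        ev = match_event(small_result, mapping, sc)
        assert ev is not None
        gt_frames = sc.contact_end - sc.contact_start + 1
        det_frames = ev.end_frame - ev.start_frame + 1
        assert abs(det_frames - gt_frames) <= 2
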