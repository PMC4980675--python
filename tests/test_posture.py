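"""Posture features: spine extraction, bending, velocity, sweep counting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kisstrack.config import SceneConfig
from kisstrack.posture import (
    DegeneratePostureError,
    GapError,
    InsufficientTrackError,
    LarvaState,
    Spine,
    accumulated_distance,
    assign_head_tail,
    bending_angle,
    count_head_sweeps,
    extract_spine,
    velocity,
)
from kisstrack.segmentation import SegmentationParams, segment_frame
from kisstrack.synth import render_frame, spine_from_pose

BW_PX = 8.0  # body width in px at the default scale


def _blob_from_spine(spine_mm, bend=0.0):
    cfg = SceneConfig(n_larvae=1, duration=1, image_size=512, arena_diameter=40,
                      seed=0, noise_sd=0.0, gfp_flags=[False])
    frame = render_frame([spine_mm], [False], cfg)
    blobs = segment_frame(frame, SegmentationParams())
    assert len(blobs) == 1
    return blobs[0], cfg


def _point_to_polyline(points, poly):
    d = np.full(len(points), np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        t = np.clip(((points - a) @ ab) / (ab @ ab), 0, 1)
        proj = a + t[:, None] * ab
        d = np.minimum(d, np.linalg.norm(points - proj, axis=1))
    return d


@pytest.mark.parametrize("method", ["contour", "skeleton"])
def test_straight_spine_close_to_analytic_centerline(method):
    gt_spine = spine_from_pose((20.0, 20.0), (1.0, 0.0), 0.0, 4.0, 11)
    blob, cfg = _blob_from_spine(gt_spine)
    spine = extract_spine(blob, 11, BW_PX, method=method)
    gt_px = np.stack([gt_spine[:, 1] * cfg.px_per_mm,
                      gt_spine[:, 0] * cfg.px_per_mm], axis=-1)
    rms = float(np.sqrt(np.mean(_point_to_polyline(spine.points, gt_px) ** 2)))
    assert rms < (1.0 if method == "contour" else 2.0)


def test_bent_spine_arc_length_within_ten_percent():
    gt_spine = spine_from_pose((20.0, 20.0), (1.0, 0.0), 60.0, 4.0, 11)
    blob, cfg = _blob_from_spine(gt_spine)
    spine = extract_spine(blob, 11, BW_PX)
    gt_arc = np.linalg.norm(np.diff(gt_spine, axis=0), axis=1).sum() * cfg.px_per_mm
    assert spine.arc_length == pytest.approx(gt_arc, rel=0.10)


def test_disc_blob_is_degenerate():
    from kisstrack.segmentation import FramePair
    ir = np.zeros((64, 64), dtype=np.float32)
    rr, cc = np.mgrid[:64, :64]
    ir[(rr - 32) ** 2 + (cc - 32) ** 2 <= 15 ** 2] = 1.0
    frame = FramePair(ir=ir, gfp=np.zeros_like(ir), frame_index=0, time=0.0)
    blob = segment_frame(frame, SegmentationParams())[0]
    with pytest.raises(DegeneratePostureError):
        extract_spine(blob, 11, BW_PX)


def test_spine_spacing_roughly_uniform():
    gt_spine = spine_from_pose((20.0, 20.0), (0.5, 0.5), 40.0, 4.0, 11)
    blob, _ = _blob_from_spine(gt_spine)
    spine = extract_spine(blob, 11, BW_PX)
    spacing = np.linalg.norm(np.diff(spine.points, axis=0), axis=1)
    assert spacing.max() / spacing.min() <= 2.0


# -- bending angle -----------------------------------------------------------

def test_bending_collinear_is_zero():
    pts = np.stack([np.linspace(0, 10, 11), np.zeros(11)], axis=-1)
    assert bending_angle(Spine(pts)) == pytest.approx(0.0, abs=1e-9)


def test_bending_forty_five_degrees_magnitude():
    # tail->mid along +x, head segment along (1, 1)
    tail_half = np.stack([np.linspace(0, 5, 6), np.zeros(6)], axis=-1)
    head_half = np.array([[5 + k, k] for k in range(1, 6)], dtype=float)
    spine = Spine(np.vstack([tail_half, head_half]))
    assert abs(bending_angle(spine)) == pytest.approx(45.0, abs=1e-9)


@given(theta=st.floats(-170, 170), rot=st.floats(0, 2 * math.pi),
       tx=st.floats(-50, 50), ty=st.floats(-50, 50))
@settings(max_examples=60, deadline=None)
def test_bending_invariant_under_rotation_translation(theta, rot, tx, ty):
    base = spine_from_pose((0.0, 0.0), (1.0, 0.0), theta, 4.0, 11)
    c, s = math.cos(rot), math.sin(rot)
    moved = base @ np.array([[c, s], [-s, c]]) + np.array([tx, ty])
    assert bending_angle(Spine(moved)) == pytest.approx(
        bending_angle(Spine(base)), abs=1e-6)
    assert bending_angle(Spine(base)) == pytest.approx(theta, abs=1e-6)


def test_bending_zero_length_segment_errors():
    pts = np.zeros((11, 2))
    with pytest.raises(ValueError):
        bending_angle(Spine(pts))


# -- head/tail orientation ---------------------------------------------------

def test_orientation_from_steady_rightward_motion():
    spine = Spine(np.stack([np.linspace(0, 40, 11), np.full(11, 5.0)], axis=-1))
    oriented, flipped, resolved = assign_head_tail(
        spine, net_displacement=np.array([30.0, 0.0]))
    assert resolved and oriented.head[0] > oriented.tail[0]


def test_orientation_without_history_is_provisional():
    spine = Spine(np.stack([np.linspace(0, 40, 11), np.full(11, 5.0)], axis=-1))
    _, _, resolved = assign_head_tail(spine)
    assert not resolved


def test_orientation_continuity_prefers_matching_tips():
    prev = Spine(np.stack([np.linspace(0, 40, 11), np.zeros(11)], axis=-1))
    cur = Spine(np.stack([np.linspace(41, 1, 11), np.zeros(11)], axis=-1))
    oriented, flipped, resolved = assign_head_tail(cur, prev_oriented=prev)
    assert resolved and flipped and oriented.head[0] > oriented.tail[0]


def test_at_most_one_flip_on_scene_tracks(small_result):
    for tr in small_result.tracks:
        assert len(tr.orientation_flips) <= 1


# -- velocity / distance / sweeps -------------------------------------------

def _state(frame, x, y):
    return LarvaState(frame_index=frame, contour=None, spine=None,
                      centroid_mm=np.array([x, y]),
                      centroid_px=np.array([y * 10, x * 10]))


def test_velocity_zero_and_unit_cases():
    assert velocity(_state(1, 3.0, 4.0), _state(0, 3.0, 4.0), 10.0) == 0.0
    # 1 px/frame at 10 fps and 10 px/mm -> 1 mm/s
    assert velocity(_state(1, 0.1, 0.0), _state(0, 0.0, 0.0), 10.0) == \
        pytest.approx(1.0)


def test_velocity_gap_error():
    with pytest.raises(GapError):
        velocity(_state(5, 0, 0), _state(3, 0, 0), 10.0)


def test_accumulated_distance_cases():
    frames = np.arange(0, 901)
    # stationary
    pos = np.zeros((901, 2))
    assert accumulated_distance(frames, pos, 10.0) == 0.0
    # straight at 0.8 mm/s for 90 s -> 72 mm
    pos = np.stack([0.08 * frames, np.zeros(901)], axis=-1)
    assert accumulated_distance(frames, pos, 10.0) == pytest.approx(72.0, rel=0.02)


def test_accumulated_distance_at_least_net_displacement():
    rng = np.random.default_rng(0)
    frames = np.arange(0, 901)
    pos = np.cumsum(rng.normal(0, 0.05, (901, 2)), axis=0)
    acc = accumulated_distance(frames, pos, 10.0)
    assert acc >= np.linalg.norm(pos[900] - pos[0]) - 1e-9


def test_accumulated_distance_insufficient_coverage():
    frames = np.arange(0, 300)
    pos = np.zeros((300, 2))
    with pytest.raises(InsufficientTrackError):
        accumulated_distance(frames, pos, 10.0, t_end=90.0)


def test_head_sweep_examples():
    assert count_head_sweeps(np.zeros(100), 30.0) == 0
    series = np.concatenate([np.zeros(10), np.full(5, 35.0), np.zeros(10),
                             np.full(3, -40.0), np.zeros(5)])
    assert count_head_sweeps(series, 30.0) == 2


@given(st.lists(st.floats(-90, 90, allow_nan=False), min_size=1, max_size=200))
@settings(max_examples=80, deadline=None)
def test_head_sweeps_match_brute_force(series):
    series = np.asarray(series)
    expected = 0
    prev = False
    for v in np.abs(series) >= 30.0:
        if v and not prev:
            expected += 1
        prev = bool(v)
    assert count_head_sweeps(series, 30.0) == expected


def test_scripted_head_casts_counted_once_each(small_scene):
    """Every ground-truth reorientation cast of amplitude >= 30 degrees shows
    up as exactly one sweep in the bend series."""
    cfg, gt, _ = small_scene
    from kisstrack.synth import REORIENT
    for a in range(cfg.n_larvae):
        bend = gt.bend[:, a]
        casts = 0
        in_cast = False
        for t in range(gt.n_frames):
            big = gt.state[t, a] == REORIENT and abs(bend[t]) >= 30
            if big and not in_cast:
                casts += 1
            in_cast = big
        assert count_head_sweeps(bend, 30.0) == casts
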