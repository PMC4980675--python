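"""Shared fixtures: simulated scenes and pipeline runs (session-scoped).

The large 12-animal collision scene drives the end-to-end checks; the small
4-animal scene keeps the per-module tests fast.  Both are generated fresh at
test time from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from kisstrack.config import PipelineConfig, SceneConfig
from kisstrack.pipeline import run_pipeline
from kisstrack.synth import schedule_collisions, simulate_scene

SCRIPTED_DURATIONS = [0.3, 0.8, 1.2, 1.8, 2.5, 3.0, 3.6, 4.0]


@pytest.fixture(scope="session")
def small_scene():
    """4 larvae (2 GFP) on a small arena with one scripted collision."""
    cfg = SceneConfig(n_larvae=4, duration=30, image_size=512,
                      arena_diameter=45, seed=11,
                      gfp_flags=[True, True, False, False],
                      collisions=[(0, 2, 1.0, 1.5)])
    gt, frames = simulate_scene(cfg)
    return cfg, gt, frames


@pytest.fixture(scope="session")
def small_result(small_scene):
    cfg, gt, frames = small_scene
    return run_pipeline(frames, PipelineConfig.from_scene(cfg))


@pytest.fixture(scope="session")
def collision_scene():
    """The full study condition: 12 larvae (6 GFP), 60 s at 10 fps,
    1024 x 1024 px, 8 scripted GFP / non-GFP collisions of 0.3-4 s."""
    base = SceneConfig(seed=1)
    cfg = SceneConfig(seed=1, collisions=schedule_collisions(
        base, 8, durations=SCRIPTED_DURATIONS))
    gt, frames = simulate_scene(cfg)
    return cfg, gt, frames


@pytest.fixture(scope="session")
def collision_result(collision_scene):
    cfg, gt, frames = collision_scene
    return run_pipeline(frames, PipelineConfig.from_scene(cfg))


def map_tracks_to_truth(result, gt):
    """track id -> ground-truth animal id, by first-frame proximity."""
    cent = gt.centroid
    out = {}
    for tr in result.tracks:
        s0 = tr.states[0]
        d = np.linalg.norm(cent[s0.frame_index] - s0.centroid_mm, axis=-1)
        out[tr.id] = int(np.argmin(d))
    return out


def match_event(result, mapping, script):
    """The detected event whose participants and interval match a scripted
    collision, or None."""
    best = None
    for ev in result.events:
        ids = {mapping[t] for t in ev.participant_track_ids}
        if ids == {script.id_a, script.id_b} and \
                ev.start_frame <= script.contact_end + 2 and \
                ev.end_frame >= script.contact_start - 2:
            if best is None or (ev.end_frame - ev.start_frame) > \
                    (best.end_frame - best.start_frame):
                best = ev
    return best
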