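# kisstrack

Two-color multi-larva tracking with collision resolution and KISS-phase
behavioral analysis.

## The problem

Drosophila larvae crawling in groups constantly touch each other.  Standard
single-channel trackers lose identities the moment two animals merge into
one segmented contour, which makes the most interesting part of social
locomotion — what happens *during* a contact — invisible.  FTIR-style
imaging solves this with two synchronized channels: an infrared channel in
which every animal is bright, and a GFP-fluorescence channel in which only
transgenically labelled animals appear.  When exactly two animals collide
and exactly one of them is GFP-positive, the merged contour can be split
unambiguously: every suprathreshold GFP pixel inside it belongs to the GFP
animal, the remainder to the other animal.  Both postures stay measurable
through the whole contact.

`kisstrack` implements this two-color collision resolution together with
the behavioral readouts built on it:

* **Field of perception** — a larva reacts to another animal entering the
  sector ahead of it with full aperture α (±α/2 about its heading) and
  radius r = 10 mm (about two body lengths); the focal bending response is
  followed for 7 s after entry.
* **Valid-collision filtering** — a collision is *resolvable* iff exactly
  two animals participate and exactly one is GFP-positive; it is *valid*
  iff it additionally lasts > 0.5 s and both animals are traceable and
  collision-free for ≥ 1 s before and after.
* **Collision phases** — valid collisions are aligned into pre-collision,
  collision and post-collision phases; per time point the median bending
  angle |θ| (tail→mid vs mid→head), median centroid velocity, their SDs and
  the bending probability P(|θ| ≥ 30°) are reported.  The **KISS phase**
  (collision-induced stop syndrome) is the interval at contact onset where
  velocity drops below half the pre-collision median while the body stays
  straight (|θ| < 30°) — a stop without a turn, typically 1–2 s.
* **Group comparison** — two-sided Wilcoxon–Mann–Whitney rank-sum test,
  exact by enumeration for combined n ≤ 12, normal approximation with tie
  and continuity correction otherwise.

Because no recordings ship with the package, a ground-truthed scene
simulator (`kisstrack.synth`) generates two-channel image stacks of
capsule-shaped crawlers implementing the GO / REORIENTATION / COLLISION
phase model — 12 animals on a 9.5 cm arena at 10 fps, one body length per
5 s, scripted pairwise collisions with a velocity- and bending-suppressed
KISS interval — so the entire pipeline is testable against exact ground
truth.

## Worked example

```python
from kisstrack import SceneConfig, PipelineConfig, simulate_scene, run_pipeline
from kisstrack.synth import schedule_collisions
from kisstrack.behavior import detect_kiss

base = SceneConfig(seed=1)                      # 12 larvae, 6 GFP, 60 s
cfg = SceneConfig(seed=1, collisions=schedule_collisions(base, 8))
gt, frames = simulate_scene(cfg)                # lazy two-channel renderer
result = run_pipeline(frames, PipelineConfig.from_scene(cfg))
print(result.log)
for ev in result.valid_events:
    print(ev.collision_id, ev.duration, detect_kiss(ev, result.tracks, cfg.fps))
```

prints (seed 1, scheduled durations drawn from U(0.3, 4) s):

```
{'version': '0.1.0', 'config_hash': '14a23cf47ac57b83', 'n_frames': 600,
 'n_blobs': 7015, 'n_tracks': 12, 'n_collision_events': 8,
 'n_resolvable': 8, 'n_valid': 8, 'elapsed_s': 63.1}
0 2.1 (0.2, 1.9)
1 3.7 (0.3, 1.8)
2 1.4 (0.3, 1.2)
3 0.7 None
4 3.7 (0.2, 1.9)
5 1.8 (0.2, 1.6)
6 3.4 (0.3, 2.3)
7 1.7 (0.2, 1.5)
```

meaning: all 12 identities were maintained over 600 frames, 8 merged-blob
collision events were found, all were resolvable (one GFP + one non-GFP
participant) and passed the validity filter; per valid event the detected
KISS interval is printed in seconds relative to contact onset (`None` when
the contact is too brief to contain a ≥ 0.5-s stop).

The same pipeline runs from the shell on image stacks:

```bash
kisstrack simulate --out sim/ --seed 1 --n-collisions 8
kisstrack track --stacks sim/ --out run/
kisstrack collisions --run run/
kisstrack perception --run run/ --alpha 20
kisstrack phases --run run/
```

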