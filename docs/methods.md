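# Methods

This note documents the models, conventions and numerical choices behind
`kisstrack`, in the order data flows through the pipeline.

## Coordinate and unit conventions

Images are (row, col), 0-based, row increasing downwards.  World
coordinates are (x, y) in millimetres with x = col / `px_per_mm` and
y = row / `px_per_mm`; at the default scale of 10 px/mm a 1024×1024 frame
covers the 9.5 cm arena with margin.  Times are seconds, `time = frame /
fps`, frames 0-based.  Angles are degrees.  The bending sign convention is
stated under *Posture*.

## Scene simulator (`kisstrack.synth`)

### Behavioral state machine

Each simulated larva is a two-segment body (posterior half straight along
the heading, anterior half rotated by the bending angle) driven by a
per-animal state machine:

* **GO** — one step of `speed × body_length / fps` (default 0.08 mm per
  frame, i.e. one 4-mm body length per 5 s) along the heading per frame;
  micro head bends modelled as an AR(1) process clipped to ±3°, heading
  jitter N(0, 1.2°) per frame.  GO durations are exponential with mean
  `1 / reorientation_rate` (default 10 s).
* **REORIENTATION** — speed ×0.3; the bending angle ramps over ~0.4 s to a
  sampled cast amplitude (uniform 30–90°, random sign), holds ~0.3 s, ramps
  back; the heading then turns by 0.65× the cast amplitude.  One cast is
  exactly one suprathreshold bending run, which makes head-sweep counts
  exactly recoverable.
* **COLLISION** — scripted only (below).

Boundary handling is reflective steering: within one body length of the
arena edge the heading rotates toward the centre at ≤ 20°/frame (a stand-in
for the salt barrier of the physical assay).  Free animals also steer
gently away from animals ahead within two body lengths; this keeps
*unscripted* contacts rare so the scripted contact set stays the dominant
signal, but does not eliminate them — emergent contacts are recorded in the
ground truth like any other.

A cosmetic peristaltic length oscillation (±3%, 1.2 Hz, while moving)
varies the rendered silhouette without affecting centroid kinematics.

### Scripted collisions

Collisions are choreographed, not emergent, so ground-truth intervals are
exact.  For each scheduled event the two participants are steered along
Hermite splines onto a head-on axis.  The final ~1.5 s of each approach
runs at exactly GO speed (this is what pre-collision statistics see); the
travel leg before that may run up to 4× GO speed so that distant pairs
meet within the scene, and those frames are flagged `scripted` in the
ground truth so free-behavior statistics can exclude them.  The last two
approach frames are a quick closing step ("lunge") that takes the pair
from just-out-of-contact to an interpenetration of 0.6 mm in 0.2 s — this
makes the measured velocity stop coincide with the first stationary frame,
i.e. the scripted KISS onset, instead of smearing the transition over
several frames.

The contact itself is: a stationary **KISS interval** (sampled from
`kiss_duration_range`, default 1–2 s; velocity ≈ 0, bending 0), then a
**sampling interval** during which the pair slides 0.45 mm deeper into
contact and performs gentle ±10° head sweeps (deep enough that the sweeps
cannot break the rendered overlap), then a retreat at 2.5× GO speed and an
in-place post-collision head cast (40–70°) before free behavior resumes.
Contacts shorter than the KISS minimum consist of the stationary interval
only.

Reported KISS observations are qualitative (a marked velocity drop without
bending), so the simulator fixes its own quantitative convention: KISS
centroid speed ≤ 20% of GO speed and bending < 10°.  The ground-truth contact interval of every pair
is *measured* from the rendered, thresholded body masks (first/last frame
with a shared pixel), which makes it consistent with what any segmenter at
the same threshold can see; the scripted target duration is realised to
within ±2 frames.

### Rendering

Each animal is rasterised as a tapered soft-edged capsule along its
11-point spine: half-width 0.4 mm at mid-body tapering to 40% at the tips
(`taper(u) = 0.4 + 0.6·√sin(πu)`), a 1-px linear intensity edge, 0.6-px
Gaussian smoothing, additive Gaussian noise of `noise_sd` (default 0.02 on
a [0, 1] scale) clipped to [0, 1].  Overlapping bodies combine by maximum.
The GFP channel renders only GFP-flagged animals with the same geometry at
85% radius and 95% intensity, so every suprathreshold GFP pixel is also
suprathreshold in IR (channel containment holds exactly in the noise-free
render).  Frames are generated lazily; per-frame noise streams are seeded
from `(seed, frame)`, so random access is deterministic and bit-identical
across runs.

### What the simulator does and does not emulate

It reproduces the *geometry and kinematics* that the tracking method
depends on: two-channel silhouettes, realistic sizes and speeds, merged
contours during contact, KISS-like velocity/bending suppression, scripted
perception-trigger scenes.  It does not model contact mechanics, FTIR
optics (shadows, halos, uneven illumination), peristaltic segment waves or
any *emergent* decision-making.  Passing tests therefore validate the
algorithmic chain — segmentation, identity logic, channel splitting,
feature extraction, event statistics — not biological effect sizes, which
would require real recordings.

## Segmentation

Fixed IR threshold 0.3 by default (FTIR-style input is near-bimodal); an
automatic between-class-variance (Otsu) mode is available.  8-connected
components ≥ `min_area` (20 px²) become blobs; outer boundaries only.  A
blob is MERGED when its area exceeds 1.5× the single-animal reference —
the running median of SINGLE-blob areas, seeded from the first frame — or
when tracking maps ≥ 2 tracks into it.  While a collision group is active,
the blob continuing it keeps its MERGED label down to 1.2× the reference
(hysteresis: deep body overlap can shrink the merged area below the entry
threshold).  Merged blobs are never discarded.  Per-blob GFP status is the
fraction of blob pixels ≥ `gfp_threshold` (0.3); the blob is GFP-positive
when that fraction is ≥ 0.5, which tolerates bleed-through at blob edges.

## Posture

The spine is extracted from the contour: resample the boundary to ~120
points, smooth, locate the two body ends as the farthest-apart turning-
angle maxima, split the boundary into two lateral arcs, pair opposite arc
points by arc-length fraction, take midpoints, and resample to `n_spine`
(11) equidistant points.  Blobs whose boundary has no curvature extremes
(max/median turning angle < 2.5, e.g. a disc) or whose tip separation is
below twice the body width raise a degenerate-posture error; a
skeletonization fallback (`method="skeleton"`) handles shapes where the
arc pairing is unreliable.

**Bending angle**: the signed angle between tail→mid and mid→head,
0° for a straight animal, positive when the head deviates clockwise as
displayed (image row axis pointing down).  This tail/mid/head definition
is this package's reconstruction — upstream tools differ in their bending
formula, so the convention is fixed here and only |θ| is used for
thresholded statistics (30° and 40° are both reported).

**Head/tail assignment**: orientation follows frame-to-frame tip
continuity once established; before that it is provisional and is fixed —
and back-propagated — once the track has ≥ 5 frames and ≥ 0.5 body lengths
of net displacement (head = leading endpoint).  Sustained reversals (≥ 0.6
body lengths of net displacement over 15 frames against the current
orientation) flip the head and are logged; brief backing (e.g. the
post-collision retreat) deliberately does not flip.

**Velocity** is the centroid displacement × fps between consecutive
frames, in mm/s, absent across gaps; no smoothing by default, an optional
centered 3-frame median exists for noisy input.  Accumulated distance sums
per-frame displacements over [0, 90 s] and requires coverage with no gap
longer than `max_gap`.  Head sweeps are maximal runs of |θ| ≥ threshold.

## Tracking

Gated nearest-centroid assignment, greedy on globally sorted distances
(ties broken by lower track id); gate 0.5 body lengths per frame — two
orders above the typical per-frame displacement, tolerating lunges and
rendering jitter.  An optimal (linear-sum assignment) mode exists behind a
flag and must agree on clean scenes, which the tests check.  Unmatched
tracks survive `max_gap` = 5 frames; new tracks open from unmatched SINGLE
blobs only.

A track whose previous contour has ≥ 1 point inside a MERGED blob becomes
a collision participant; the group persists while a merged blob overlaps
its predecessor.  When the group's blob splits, identities are reassigned
by GFP flag when exactly one participant is GFP-positive and exactly one
emerging blob is GFP-positive, otherwise by minimal distance to the last
resolved positions (logged as lower confidence).  A mismatch between
participant and fragment counts flags the event unresolved.

## Collision resolution

Resolvable ⇔ exactly two participants, exactly one GFP-positive.  On each
resolvable frame the merged blob's pixels are partitioned by the GFP
threshold applied to a lightly denoised GFP channel (1-px Gaussian,
`gfp_smooth_sigma`) — without it, per-pixel noise flips boundary pixels
between the two parts frame to frame, which alone adds ~0.4 mm/s of jitter
to the split-part centroid velocities of a perfectly stationary pair.
Each part keeps its largest connected component (a part losing
> 30% of its pixels to fragments flags the frame low-confidence), and both
parts flow through the normal posture extraction with per-frame b_gfp
frozen to the channel that defined the part.  An empty part marks the
frame unsplittable; the event survives without features for that frame.

Validity: resolvable AND duration strictly > 0.5 s AND both participants
fully traceable and in no other collision for ≥ 1 s before the start and
after the end (at 10 fps: ≥ 6 collision frames, ≥ 10 clean flank frames).
"No overlays" is enforced through the participant rule itself: any third
animal touching the merged contour becomes a participant and makes the
event unresolvable.

## Behavioral analyses

**Field of perception**: inclusion is distance ≤ r AND unsigned angular
offset ≤ α/2, both boundary-inclusive.  The focal heading is the centroid
displacement smoothed over 5 frames; below 0.1 mm/s it falls back to the
tail→head body axis (the anterior axis matches the forward-looking larval
eye); with neither defined, no event can trigger that frame.  An event is
an outside→inside transition with the previous frame tracked; the 7-s
window is censored when the other animal leaves the radius-r circle, a
track ends, or the focal animal enters a collision.  The trigger-aligned
series reports mean |θ|, SD and bending probability per time point
(the mean-vs-median ambiguity upstream is resolved by emitting both: the
perception series uses the mean, the phase series the median).

**Phase alignment**: pre + collision series anchored at contact onset
(t = 0 first collision frame), post series anchored at separation (t = 0
last collision frame); events contribute to collision time points only
while still in contact, so n varies along the series.  Median and SD are
reported (an IQR switch exists).  The focal animal defaults to the
non-GFP participant, mirroring the convention of analysing the unlabelled
animal; `gfp` and `both` are config options.

**KISS detection**: baseline = median focal velocity over the 1 s before
onset; KISS = the maximal interval starting within 1 s of onset with
3-frame-median-smoothed velocity < 0.5× baseline and |θ| < 30°, reported
when ≥ 0.5 s.  The speed fraction, minimum length and smoothing are
config-exposed: the source biology gives no quantitative KISS criterion,
so these are calibration choices of this package, fixed once.

**Rank-sum test**: exact two-sided p by full enumeration of rank
assignments (midranks for ties) for combined n ≤ 12 — the printed example
{1,2,3} vs {4,5,6} gives p = 2/20 = 0.1 — and the normal approximation
with tie and continuity correction beyond, matching the conventional
implementation.  The statistic returned is the rank sum of the first
sample.

## Problem sizes and determinism

The shipped validation scenes are: the full study condition (12 larvae,
6 GFP, 60 s at 10 fps, 1024×1024 px, 8 scripted collisions of 0.3–4 s), a
collision-free 600-frame scene for identity checks, and a 95-s 4-animal
scene for the 90-s accumulated-distance readout.  Everything — trajectory
sampling, choreography, per-frame noise — derives from a single scene
seed, and reruns are bit-identical.

## Known limitations

* Three-animal pile-ups and same-genotype collisions are detected but
  never resolved (by design of the two-color rule).
* The contour-based spine fails on strongly curled postures (> ~150°
  bends); such frames carry NaN bending and are excluded per time point.
* Split-part centroids are biased while interpenetration deepens (the
  truncated part's centroid lags the animal); the simulator's lunge/
  retreat choreography keeps this transition to ~2 frames, but on real
  recordings slow deep overlaps would blur KISS onsets by a similar
  amount.
* The segmentation assumes high-contrast input; there is no background
  model or illumination correction.
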