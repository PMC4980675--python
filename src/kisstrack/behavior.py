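"""Behavioral readouts: field of perception, collision phases, group tests.

**Field of perception.**  A larva's visual field is modelled as the sector
ahead of it with full aperture alpha (i.e. +-alpha/2 about the heading) and
radius r = 10 mm, about two larval lengths — matching the forward-looking
geometry of Bolwig's organ.  A perception event is triggered for a focal
animal the first frame another animal enters this sector, and the focal
bending behavior is followed for a 7-s window (censored when the other
animal leaves the radius-r circle, a track ends, or a collision starts).

**Collision phases.**  Valid collisions are cut into a pre-collision phase,
the collision phase (aligned to contact onset) and a post-collision phase
(aligned to separation).  Per time point the median bending angle, the
median velocity, their standard deviations and the bending probability
(fraction of animals bent beyond 30 degrees) are reported.  The KISS phase
— the collision-induced stop: velocity strongly suppressed while the body
stays straight — is detected per event against the pre-phase velocity
baseline.

**Group comparison.**  Two-sided Wilcoxon-Mann-Whitney rank-sum test,
exact by enumeration for small samples, normal approximation with tie and
continuity correction otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .collision import CollisionEvent
from .tracking import Track


# ---------------------------------------------------------------------------
# field of perception
# ---------------------------------------------------------------------------

def in_field_of_view(focal_xy, heading_xy, other_xy,
                     alpha: float, r: float) -> bool:
    """True iff ``other`` lies within distance ``r`` of ``focal`` and within
    +-alpha/2 (degrees, inclusive) of the focal heading."""
    h = np.asarray(heading_xy, dtype=float)
    hn = float(np.hypot(*h))
    if hn == 0:
        raise ValueError("undefined heading")
    rel = np.asarray(other_xy, dtype=float) - np.asarray(focal_xy, dtype=float)
    d = float(np.hypot(*rel))
    if d > r:
        return False
    if d == 0:
        return True
    cosang = float(np.clip((rel @ h) / (d * hn), -1.0, 1.0))
    return math.degrees(math.acos(cosang)) <= alpha / 2.0


@dataclass
class PerceptionEvent:
    """One entry of another animal into a focal animal's perceptive field."""
    focal_id: int
    other_id: int
    trigger_frame: int
    alpha: float
    r: float
    window_s: float
    bending: np.ndarray          # focal |bending| per window frame (may be short)
    censored: bool


def _pivot(features: pd.DataFrame, column: str) -> pd.DataFrame:
    return features.pivot_table(index="frame", columns="id", values=column,
                                aggfunc="first")


def _headings(features: pd.DataFrame, fps: float, smooth_frames: int,
              speed_floor: float) -> dict[int, dict[int, np.ndarray]]:
    """Per animal, per frame: heading unit vector from the centroid
    displacement smoothed over ``smooth_frames`` frames, falling back to the
    tail->head body axis when the animal is slower than ``speed_floor``."""
    out: dict[int, dict[int, np.ndarray]] = {}
    half = smooth_frames // 2
    for aid, sub in features.groupby("id"):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        xy = sub[["x_mm", "y_mm"]].to_numpy(dtype=float)
        has_axis = {"axis_x", "axis_y"}.issubset(sub.columns)
        axes = sub[["axis_x", "axis_y"]].to_numpy(dtype=float) if has_axis else None
        idx = {f: i for i, f in enumerate(frames)}
        per: dict[int, np.ndarray] = {}
        for f in frames:
            i = idx[f]
            j0 = idx.get(f - half)
            j1 = idx.get(f + half)
            head = None
            if j0 is not None and j1 is not None:
                disp = xy[j1] - xy[j0]
                dt = (frames[j1] - frames[j0]) / fps
                if dt > 0 and np.hypot(*disp) / dt >= speed_floor:
                    head = disp / np.hypot(*disp)
            if head is None and axes is not None and not np.isnan(axes[i]).any():
                n = float(np.hypot(*axes[i]))
                if n > 0:
                    head = axes[i] / n
            if head is not None:
                per[f] = head
        out[aid] = per
    return out


def detect_perception_events(features: pd.DataFrame, alpha: float = 20.0,
                             r: float = 10.0, window_s: float = 7.0,
                             fps: float = 10.0, smooth_frames: int = 5,
                             speed_floor: float = 0.1,
                             ) -> list[PerceptionEvent]:
    """Find all outside->inside field-of-view transitions between tracked
    animal pairs and collect the focal bending window for each.

    ``features`` is the long-format feature table (one row per frame x
    animal).  The target animal may be stationary (a dead-larva style
    condition); only the focal animal needs a defined heading.
    """
    heads = _headings(features, fps, smooth_frames, speed_floor)
    X = _pivot(features, "x_mm")
    Y = _pivot(features, "y_mm")
    B = _pivot(features, "bending_deg")
    C = _pivot(features, "in_collision") if "in_collision" in features else None
    frames = X.index.to_numpy()
    ids = list(X.columns)
    W = int(round(window_s * fps))
    events: list[PerceptionEvent] = []

    def inside(focal, other, f) -> bool | None:
        h = heads.get(focal, {}).get(f)
        if h is None:
            return None
        fx, fy = X.at[f, focal], Y.at[f, focal]
        ox, oy = X.at[f, other], Y.at[f, other]
        if np.isnan(fx) or np.isnan(ox):
            return None
        return in_field_of_view((fx, fy), h, (ox, oy), alpha, r)

    for focal in ids:
        for other in ids:
            if focal == other:
                continue
            prev: bool | None = None
            prev_frame = None
            for f in frames:
                cur = inside(focal, other, f)
                if cur is None:
                    prev, prev_frame = None, f
                    continue
                if cur and prev is False and prev_frame == f - 1:
                    bend, censored = [], False
                    for k in range(W + 1):
                        fk = f + k
                        fx = X.at[fk, focal] if fk in X.index else np.nan
                        ox = X.at[fk, other] if fk in X.index else np.nan
                        if np.isnan(fx) or np.isnan(ox):
                            censored = True
                            break
                        if C is not None and bool(C.at[fk, focal]):
                            censored = True
                            break
                        dist = math.hypot(X.at[fk, other] - X.at[fk, focal],
                                          Y.at[fk, other] - Y.at[fk, focal])
                        if k > 0 and dist > r:
                            censored = True
                            break
                        bend.append(abs(B.at[fk, focal]))
                    events.append(PerceptionEvent(
                        focal_id=int(focal), other_id=int(other),
                        trigger_frame=int(f), alpha=alpha, r=r,
                        window_s=window_s,
                        bending=np.asarray(bend, dtype=float),
                        censored=censored))
                prev, prev_frame = cur, f
    return events


def bending_response_series(events: list[PerceptionEvent], fps: float,
                            bend_threshold: float = 30.0) -> pd.DataFrame:
    """Trigger-aligned bending statistics over perception events.

    Returns one row per window time point: n contributing events, mean
    |bending| and its SD, and the bending probability (fraction of events
    bent beyond ``bend_threshold``).
    """
    if not events:
        raise ValueError("no perception events")
    W = max(len(ev.bending) for ev in events)
    rows = []
    for k in range(W):
        vals = np.array([ev.bending[k] for ev in events if len(ev.bending) > k])
        vals = vals[~np.isnan(vals)]
        rows.append({
            "time_s": k / fps,
            "n": len(vals),
            "mean_bend": float(np.mean(vals)) if len(vals) else np.nan,
            "sd_bend": float(np.std(vals, ddof=0)) if len(vals) else np.nan,
            "p_bend": float(np.mean(vals >= bend_threshold)) if len(vals) else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# collision phases
# ---------------------------------------------------------------------------

@dataclass
class PhaseSeries:
    """Phase-aligned per-timepoint statistics over collision events."""
    anchor: str                        # COLLISION_START | COLLISION_END
    time_s: np.ndarray
    n: np.ndarray
    median_bend: np.ndarray
    sd_bend: np.ndarray
    median_vel: np.ndarray
    sd_vel: np.ndarray
    p_bend: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s, "n": self.n,
            "median_bend": self.median_bend, "sd_bend": self.sd_bend,
            "median_vel": self.median_vel, "sd_vel": self.sd_vel,
            "p_bend30": self.p_bend,
        })


def _focal_ids(event: CollisionEvent, focal: str) -> list[int]:
    if focal == "gfp":
        return [event.gfp_track_id]
    if focal == "non_gfp":
        return [event.other_track_id]
    return [event.gfp_track_id, event.other_track_id]


def _series_stats(samples: list[list[float]], times: np.ndarray,
                  vel_samples: list[list[float]], anchor: str,
                  bend_threshold: float) -> PhaseSeries:
    n = np.zeros(len(times), dtype=int)
    med_b = np.full(len(times), np.nan)
    sd_b = np.full(len(times), np.nan)
    med_v = np.full(len(times), np.nan)
    sd_v = np.full(len(times), np.nan)
    p_b = np.full(len(times), np.nan)
    for k in range(len(times)):
        b = np.array([v for v in samples[k] if not math.isnan(v)])
        v = np.array([v for v in vel_samples[k] if not math.isnan(v)])
        n[k] = len(b) if len(b) else len(v)
        if len(b):
            med_b[k] = np.median(b)
            sd_b[k] = np.std(b, ddof=0)
            p_b[k] = np.mean(b >= bend_threshold)
        if len(v):
            med_v[k] = np.median(v)
            sd_v[k] = np.std(v, ddof=0)
    return PhaseSeries(anchor=anchor, time_s=times, n=n, median_bend=med_b,
                       sd_bend=sd_b, median_vel=med_v, sd_vel=sd_v, p_bend=p_b)


def phase_align(valid_events: list[CollisionEvent], tracks: list[Track],
                fps: float, pre_s: float = 1.0, post_s: float = 1.0,
                bend_threshold: float = 30.0, focal: str = "non_gfp",
                ) -> tuple[PhaseSeries, PhaseSeries]:
    """Align valid collisions into (pre + collision, post) phase series.

    The first series is anchored at contact onset (t = 0 is the first
    collision frame; negative times are the pre-collision phase); events
    contribute to collision time points only while still in contact, so n
    varies along the series.  The second series is anchored at separation
    (t = 0 is the last collision frame).
    """
    by_id = {tr.id: tr for tr in tracks}
    pre_f = int(round(pre_s * fps))
    post_f = int(round(post_s * fps))
    max_dur = max((ev.end_frame - ev.start_frame + 1) for ev in valid_events)

    t1 = np.arange(-pre_f, max_dur) / fps
    bend1: list[list[float]] = [[] for _ in t1]
    vel1: list[list[float]] = [[] for _ in t1]
    t2 = np.arange(0, post_f + 1) / fps
    bend2: list[list[float]] = [[] for _ in t2]
    vel2: list[list[float]] = [[] for _ in t2]

    for ev in valid_events:
        for tid in _focal_ids(ev, focal):
            tr = by_id[tid]
            for k in range(-pre_f, max_dur):
                f = ev.start_frame + k
                if k >= 0 and f > ev.end_frame:
                    break
                st = tr.state_at(f)
                if st is None:
                    continue
                bend1[k + pre_f].append(abs(st.bending_angle))
                vel1[k + pre_f].append(np.nan if st.velocity is None else st.velocity)
            for k in range(post_f + 1):
                st = tr.state_at(ev.end_frame + k)
                if st is None:
                    continue
                bend2[k].append(abs(st.bending_angle))
                vel2[k].append(np.nan if st.velocity is None else st.velocity)

    s1 = _series_stats(bend1, t1, vel1, "COLLISION_START", bend_threshold)
    s2 = _series_stats(bend2, t2, vel2, "COLLISION_END", bend_threshold)
    return s1, s2


def detect_kiss(event: CollisionEvent, tracks: list[Track], fps: float,
                baseline_pre_s: float = 1.0, kiss_speed_frac: float = 0.5,
                bend_max: float = 30.0, kiss_min_s: float = 0.5,
                smooth_frames: int = 3, focal: str = "non_gfp",
                ) -> tuple[float, float] | None:
    """Detect the KISS interval of a valid collision event.

    The KISS phase is the maximal interval beginning within 1 s of contact
    onset during which the (median-smoothed) focal velocity stays below
    ``kiss_speed_frac`` times the pre-collision median velocity while
    |bending| stays below ``bend_max`` degrees — a stop without a turn.
    Returns (start_s, end_s) relative to contact onset, or None if no such
    interval lasts at least ``kiss_min_s``.
    """
    by_id = {tr.id: tr for tr in tracks}
    tid = _focal_ids(event, focal)[0]
    tr = by_id[tid]
    pre_f = int(round(baseline_pre_s * fps))
    base_vals = []
    for f in range(event.start_frame - pre_f, event.start_frame):
        st = tr.state_at(f)
        if st is not None and st.velocity is not None:
            base_vals.append(st.velocity)
    if not base_vals:
        return None
    baseline = float(np.median(base_vals))
    if baseline <= 0:
        return None

    frames = np.arange(event.start_frame, event.end_frame + 1)
    vel = np.full(len(frames), np.nan)
    bend = np.full(len(frames), np.nan)
    for i, f in enumerate(frames):
        st = tr.state_at(int(f))
        if st is not None:
            if st.velocity is not None:
                vel[i] = st.velocity
            bend[i] = abs(st.bending_angle)
    if smooth_frames > 1:
        half = smooth_frames // 2
        sm = vel.copy()
        for i in range(len(vel)):
            w = vel[max(0, i - half):i + half + 1]
            w = w[~np.isnan(w)]
            if len(w):
                sm[i] = np.median(w)
        vel = sm

    ok = (vel < kiss_speed_frac * baseline) & ~np.isnan(vel)
    ok &= np.isnan(bend) | (bend < bend_max)
    onset_limit = int(round(1.0 * fps))
    best = None
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j + 1 < len(ok) and ok[j + 1]:
                j += 1
            if i <= onset_limit:
                length = j - i + 1
                if best is None or length > best[1] - best[0] + 1:
                    best = (i, j)
            i = j + 1
        else:
            i += 1
    if best is None or (best[1] - best[0] + 1) / fps < kiss_min_s:
        return None
    return (best[0] / fps, (best[1] + 1) / fps)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def compare_groups(a, b, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Returns (W, p) where W is the rank sum of the first sample.  For a
    combined sample size of at most ``exact_max_n`` the p-value is computed
    by exact enumeration of all rank assignments (ties handled with
    midranks); larger samples use the normal approximation with tie and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    na, n = len(a), len(pooled)
    W = float(ranks[:na].sum())
    mu = na * (n + 1) / 2.0
    if n <= exact_max_n:
        dev = abs(W - mu)
        count = total = 0
        for comb in combinations(range(n), na):
            w = ranks[list(comb)].sum()
            total += 1
            if abs(w - mu) >= dev - 1e-12:
                count += 1
        return W, count / total
    nb = len(b)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return W, 1.0
    z = (W - mu - 0.5 * np.sign(W - mu)) / math.sqrt(var)
    return W, float(2 * sps.norm.sf(abs(z)))
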