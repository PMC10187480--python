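"""Synthetic multi-view wet-dog-shake session generator.

The generator emulates the statistical structure of KA-model rat recordings:
a single agent roaming a square arena, filmed by 1-4 synchronized cameras at
a fixed frame rate, with rare, short shake events (duration mean 0.33 s,
sd 0.11 s, occupying ~0.38% of frames at the default rate of 41.5 events/h).

The agent is a smoothly wandering oriented ellipse. During a shake event its
body carries a high-frequency stripe texture whose phase advances at
``shake_freq_hz`` and its contour wobbles — but only in views where the
event is *visible*. Visibility is sampled per (event, view) from a per-view
function of the agent's orientation: a camera is likely to miss the shake
when the agent faces directly away from it. Two "side" cameras mounted on
the same wall share most of their blind region; an overhead camera sees
nearly everything. This reproduces the phenomenon that motivates multi-view
fusion: single views miss events that the union of three views recovers.

Distractor behaviors (fast "walking" bouts and "rearing"-like shape changes)
are rendered without texture so that false-positive behavior of downstream
classifiers can be exercised.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import truncnorm

from .errors import ResolutionError, SchedulingError, ValidationError
from .io_formats import EventList, MultiViewSession, labels_from_events, write_session


@dataclass(frozen=True)
class ScheduleParams:
    """Event schedule statistics.

    ``n_events`` is either a fixed integer or the string ``"poisson"``, in
    which case the count is drawn as Poisson(``rate_per_hour`` x hours). The
    default rate 41.5/h makes the expected WDS frame fraction ~0.38% given
    the 0.33 s mean duration (0.0038 x 3600 / 0.33 ~ 41.5).
    """

    session_seconds: float = 3600.0
    fps: float = 30.0
    n_events: int | str = "poisson"
    rate_per_hour: float = 41.5
    duration_mean_s: float = 0.33
    duration_sd_s: float = 0.11
    duration_min_s: float = 0.10
    min_gap_s: float = 1.0

    def __post_init__(self):
        if self.duration_min_s <= 0:
            raise ValidationError("duration_min_s must be positive")
        if self.session_seconds <= 0 or self.fps <= 0:
            raise ValidationError("session_seconds and fps must be positive")


@dataclass(frozen=True)
class ViewVisibility:
    """Orientation-dependent probability that a view renders a shake visibly.

    The camera sits at ``azimuth_deg`` (direction from arena center). When
    the agent's facing direction falls within ``blind_halfwidth_deg`` of the
    direction pointing directly away from the camera, visibility drops from
    ``vis_facing`` to ``vis_blind``. A halfwidth of 0 gives a flat
    (orientation-independent) probability, used for overhead cameras.
    """

    name: str
    azimuth_deg: float = 0.0
    vis_facing: float = 0.97
    vis_blind: float = 0.62
    blind_halfwidth_deg: float = 36.0

    def prob(self, theta_rad: float) -> float:
        if self.blind_halfwidth_deg <= 0:
            return self.vis_facing
        away = math.radians(self.azimuth_deg) + math.pi
        d = abs((theta_rad - away + math.pi) % (2 * math.pi) - math.pi)
        if d <= math.radians(self.blind_halfwidth_deg):
            return self.vis_blind
        return self.vis_facing


def default_views(n_views: int) -> list[ViewVisibility]:
    """Default camera layout: two side cameras on one wall plus an overhead.

    Side cameras at azimuths +-6 deg see ~90% of events (a 72 deg blind
    cone where visibility drops to 0.62) and, being nearly co-located,
    share most of their blind region, so a second same-wall camera recovers
    only part of what the first misses; the overhead camera has flat 0.99
    visibility and recovers most of the rest. A fourth camera, when
    requested, faces the opposite wall.
    """
    layout = [
        ViewVisibility("side_a", azimuth_deg=6.0),
        ViewVisibility("side_b", azimuth_deg=-6.0),
        ViewVisibility("top", azimuth_deg=0.0, vis_facing=0.99, vis_blind=0.99,
                       blind_halfwidth_deg=0.0),
        ViewVisibility("side_c", azimuth_deg=180.0),
    ]
    if not 1 <= n_views <= 4:
        raise ValidationError("n_views must be in 1..4")
    return layout[:n_views]


@dataclass(frozen=True)
class RenderParams:
    """Rendering parameters for the stylized 2-D arena projection."""

    frame_px: int = 96
    n_views: int = 3
    session_seconds: float = 600.0
    fps: float = 30.0
    shake_freq_hz: float = 12.0
    noise_sd: float = 0.03
    views: tuple[ViewVisibility, ...] | None = None
    agent_len_frac: float = 0.16      # ellipse semi-major axis / frame side
    agent_width_frac: float = 0.08    # ellipse semi-minor axis / frame side
    wobble_frac: float = 0.10         # contour oscillation amplitude in shakes
    texture_floor: float = 0.45       # darkest stripe multiplier
    texture_wavelength_frac: float = 0.05
    walk_rate_per_min: float = 2.0
    rear_rate_per_min: float = 1.0
    background: float = 0.12
    body_intensity: float = 0.82

    def view_list(self) -> list[ViewVisibility]:
        if self.views is not None:
            if len(self.views) != self.n_views:
                raise ValidationError("len(views) must equal n_views")
            return list(self.views)
        return default_views(self.n_views)


# ---------------------------------------------------------------------------
# event schedule
# ---------------------------------------------------------------------------

def sample_durations(
    n: int, p: ScheduleParams, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw n event durations (seconds) from the truncated-normal model."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a = (p.duration_min_s - p.duration_mean_s) / p.duration_sd_s
    return truncnorm.rvs(
        a, np.inf, loc=p.duration_mean_s, scale=p.duration_sd_s, size=n,
        random_state=rng,
    )


def sample_event_schedule(
    p: ScheduleParams, seed: int | np.random.Generator
) -> EventList:
    """Sample a seeded event schedule as frame intervals.

    Durations are truncated-normal draws rounded to >= 1 frame; starts are
    uniform subject to a minimum gap of ``min_gap_s`` between consecutive
    events (exact conditional-uniform placement via sorted spacings).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(p.n_events, str):
        if p.n_events != "poisson":
            raise ValidationError(f"unknown n_events spec {p.n_events!r}")
        n = int(rng.poisson(p.rate_per_hour * p.session_seconds / 3600.0))
    else:
        n = int(p.n_events)
    if n == 0:
        return EventList()
    durations = sample_durations(n, p, rng)
    occupied = float(durations.sum()) + (n - 1) * p.min_gap_s
    free = p.session_seconds - occupied
    if free < 0:
        raise SchedulingError(
            f"{n} events (total {occupied:.1f} s with gaps) do not fit in "
            f"{p.session_seconds:.1f} s"
        )
    offsets = np.sort(rng.uniform(0.0, free, size=n))
    starts_s = offsets + np.concatenate(([0.0], np.cumsum(durations[:-1]))) \
        + p.min_gap_s * np.arange(n)
    T = int(round(p.session_seconds * p.fps))
    intervals = []
    for s, d in zip(starts_s, durations):
        start_f = int(np.floor(s * p.fps + 0.5))
        n_frames = max(1, int(np.rint(d * p.fps)))
        end_f = min(start_f + n_frames - 1, T - 1)
        start_f = min(start_f, end_f)
        intervals.append((start_f, end_f))
    return EventList(tuple(intervals))


# ---------------------------------------------------------------------------
# motion model
# ---------------------------------------------------------------------------

def _simulate_motion(
    T: int, r: RenderParams, schedule: EventList, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Smooth random walk with orientation, frozen in place during shakes.

    Velocity follows an Ornstein-Uhlenbeck process reflected at the walls;
    orientation tracks the smoothed heading with small noise. "Walking"
    bouts multiply speed, "rearing" bouts modulate body shape; both are
    Poisson-scheduled distractors.
    """
    px = r.frame_px
    dt = 1.0 / r.fps
    a = r.agent_len_frac * px
    margin = a * 1.4 + 2.0
    lo, hi = margin, px - 1 - margin

    in_event = labels_from_events(schedule, T).astype(bool)
    event_id = np.full(T, -1, dtype=np.int64)
    for i, (s, e) in enumerate(schedule):
        event_id[s : e + 1] = i

    # distractor bout envelopes
    def bouts(rate_per_min: float, dur_s: float) -> np.ndarray:
        env = np.zeros(T)
        p_start = rate_per_min / 60.0 * dt
        starts = np.nonzero(rng.random(T) < p_start)[0]
        L = max(1, int(round(dur_s * r.fps)))
        ramp = np.sin(np.linspace(0, np.pi, L)) ** 2
        for s in starts:
            e = min(T, s + L)
            env[s:e] = np.maximum(env[s:e], ramp[: e - s])
        env[in_event] = 0.0  # shakes dominate
        return env

    walk = bouts(r.walk_rate_per_min, 1.5)
    rear = bouts(r.rear_rate_per_min, 0.8)

    tau = 1.2
    speed_scale = 0.08 * px  # px per second
    x = np.empty(T)
    y = np.empty(T)
    theta = np.empty(T)
    vx, vy = 0.0, 0.0
    cx = rng.uniform(lo, hi)
    cy = rng.uniform(lo, hi)
    heading = rng.uniform(-np.pi, np.pi)
    sigma = speed_scale * math.sqrt(2 * dt / tau)
    for t in range(T):
        if in_event[t]:
            vx *= 0.0
            vy *= 0.0
        else:
            decay = 1.0 - dt / tau
            vx = vx * decay + sigma * rng.standard_normal()
            vy = vy * decay + sigma * rng.standard_normal()
            boost = 1.0 + 2.5 * walk[t]
            cx += vx * dt * boost
            cy += vy * dt * boost
            if cx < lo:
                cx, vx = 2 * lo - cx, abs(vx)
            elif cx > hi:
                cx, vx = 2 * hi - cx, -abs(vx)
            if cy < lo:
                cy, vy = 2 * lo - cy, abs(vy)
            elif cy > hi:
                cy, vy = 2 * hi - cy, -abs(vy)
            speed = math.hypot(vx, vy)
            if speed > 1e-6:
                target = math.atan2(vy, vx)
                d = (target - heading + math.pi) % (2 * math.pi) - math.pi
                heading += 0.15 * d
            heading += 0.05 * math.sqrt(dt) * rng.standard_normal()
        x[t], y[t], theta[t] = cx, cy, heading

    # freeze orientation at the event-onset value for the whole event
    for s, e in schedule:
        theta[s : e + 1] = theta[s]
    return {
        "x": x, "y": y, "theta": theta, "walk": walk, "rear": rear,
        "event_id": event_id,
    }


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _draw_body(
    canvas: np.ndarray,
    cx: float, cy: float, theta: float,
    a: float, b: float,
    intensity: float, background: float,
    texture_phase: float | None,
    texture_wavelength: float, texture_floor: float,
) -> tuple[int, int, int, int]:
    """Blend an oriented ellipse into ``canvas``; return its pixel bbox.

    Coverage falls from 1 inside to 0 outside over roughly one pixel. The
    ground-truth box is the bounding box of pixels with coverage > 0.5.
    """
    px_h, px_w = canvas.shape
    R = int(math.ceil(max(a, b))) + 3
    ix, iy = int(round(cx)), int(round(cy))
    x0, x1 = max(0, ix - R), min(px_w, ix + R + 1)
    y0, y1 = max(0, iy - R), min(px_h, iy + R + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    cov = np.clip(0.5 + (1.0 - rho) * b, 0.0, 1.0)
    if texture_phase is None:
        body = intensity
    else:
        stripes = np.sin(2 * np.pi * u / texture_wavelength + texture_phase) > 0
        body = intensity * np.where(stripes, 1.0, texture_floor)
    canvas[y0:y1, x0:x1] += cov * (body - background)
    mask = cov > 0.5
    ys, xs = np.nonzero(mask)
    if ys.size == 0:  # degenerate; should not happen with margin >= a
        return ix, iy, 1, 1
    bx0, bx1 = x0 + xs.min(), x0 + xs.max()
    by0, by1 = y0 + ys.min(), y0 + ys.max()
    return bx0, by0, bx1 - bx0 + 1, by1 - by0 + 1


def render_session(
    schedule: EventList,
    r: RenderParams,
    seed: int,
    session_id: str = "synthetic",
) -> MultiViewSession:
    """Render a multi-view session for a given event schedule.

    Deterministic given (schedule, r, seed). The returned session carries
    ground-truth per-view boxes in ``rois`` and, in ``meta``, the sampled
    per-(event, view) visibility matrix and the orientation track.
    """
    if r.frame_px < 32:
        raise ResolutionError(f"frame_px must be >= 32, got {r.frame_px}")
    T = int(round(r.session_seconds * r.fps))
    for s, e in schedule:
        if e > T - 1:
            raise ValidationError(f"event ({s}, {e}) exceeds session length {T}")
    views = r.view_list()
    n_views = len(views)
    ss = np.random.SeedSequence(seed)
    motion_rng, gate_rng, *noise_seeds = [
        np.random.default_rng(s) for s in ss.spawn(2 + n_views)
    ]

    motion = _simulate_motion(T, r, schedule, motion_rng)
    x, y, theta = motion["x"], motion["y"], motion["theta"]
    rear = motion["rear"]
    event_id = motion["event_id"]

    # per-(event, view) visibility gates, orientation-dependent
    n_events = len(schedule)
    gates = np.zeros((n_events, n_views), dtype=bool)
    for i, (s, e) in enumerate(schedule):
        th = theta[(s + e) // 2]
        probs = np.array([v.prob(th) for v in views])
        gates[i] = gate_rng.random(n_views) < probs
        if n_events and not gates[i].any():
            gates[i, int(np.argmax(probs))] = True  # every event visible somewhere

    a0 = r.agent_len_frac * r.frame_px
    b0 = r.agent_width_frac * r.frame_px
    wavelength = max(2.0, r.texture_wavelength_frac * r.frame_px)
    px = r.frame_px

    frames: list[np.ndarray] = []
    rois: list[np.ndarray] = []
    chunk = 1500
    for v_idx in range(n_views):
        noise_rng = noise_seeds[v_idx]
        arr = np.empty((T, px, px), dtype=np.uint8)
        boxes = np.empty((T, 4), dtype=np.int64)
        for c0 in range(0, T, chunk):
            c1 = min(T, c0 + chunk)
            canvas = noise_rng.normal(
                r.background, r.noise_sd, size=(c1 - c0, px, px)
            ).astype(np.float32)
            for t in range(c0, c1):
                eid = event_id[t]
                gated = eid >= 0 and gates[eid, v_idx]
                m = rear[t]
                a = a0 * (1.0 - 0.38 * m)
                b = b0 * (1.0 + 0.25 * m)
                phase = None
                if gated:
                    phase = 2 * np.pi * r.shake_freq_hz * t / r.fps
                    wob = r.wobble_frac * math.sin(phase)
                    a *= 1.0 + wob
                    b *= 1.0 - wob
                boxes[t] = _draw_body(
                    canvas[t - c0], x[t], y[t], theta[t], a, b,
                    r.body_intensity, r.background,
                    phase, wavelength, r.texture_floor,
                )
            np.clip(canvas, 0.0, 1.0, out=canvas)
            arr[c0:c1] = (canvas * 255.0 + 0.5).astype(np.uint8)
        frames.append(arr)
        rois.append(boxes)

    labels = labels_from_events(schedule, T)
    return MultiViewSession(
        session_id=session_id,
        fps=r.fps,
        views=frames,
        view_names=[v.name for v in views],
        labels=labels,
        events=schedule,
        rois=rois,
        meta={
            "event_visibility": gates,
            "orientation": theta,
            "seed": seed,
            "render_params": r,
        },
    )


def generate_session(
    sp: ScheduleParams, rp: RenderParams, seed: int, session_id: str = "synthetic"
) -> MultiViewSession:
    """Sample a schedule and render it (one seed drives both)."""
    ss = np.random.SeedSequence(seed)
    sched_seed, render_seed = ss.spawn(2)
    schedule = sample_event_schedule(sp, np.random.default_rng(sched_seed))
    return render_session(
        schedule, rp, seed=render_seed.generate_state(1)[0] % (2**31), session_id=session_id
    )


# ---------------------------------------------------------------------------
# benchmark profiles
# ---------------------------------------------------------------------------

#: Desk-scale profile: short low-resolution sessions whose event counts keep
#: the WDS frame fraction at the corpus-wide ~0.38% (7 x ~5 frames / 9000).
FAST_PROFILE = {
    "session_seconds": 600.0,
    "fps": 15.0,
    "frame_px": 64,
    "n_views": 3,
    "train_events": (7, 7),
    "val_events": 7,
}

#: Study-scale profile mirroring the three one-hour recordings (149 and 220
#: training events, a 49-event validation hour).
FULL_PROFILE = {
    "session_seconds": 3600.0,
    "fps": 30.0,
    "frame_px": 96,
    "n_views": 3,
    "train_events": (149, 220),
    "val_events": 49,
}

#: Minimal profile for exercising the full pipeline in seconds (tests,
#: smoke runs); too small for meaningful accuracy statistics.
TINY_PROFILE = {
    "session_seconds": 20.0,
    "fps": 15.0,
    "frame_px": 48,
    "n_views": 3,
    "train_events": (2, 2),
    "val_events": 2,
}

PROFILES = {"fast": FAST_PROFILE, "full": FULL_PROFILE, "tiny": TINY_PROFILE}


def benchmark_params(
    profile: str = "fast", n_views: int | None = None
) -> tuple[list[ScheduleParams], ScheduleParams, RenderParams]:
    """Schedule params for (train sessions, validation session) + render params."""
    cfg = PROFILES[profile]
    rp = RenderParams(
        frame_px=cfg["frame_px"],
        n_views=n_views or cfg["n_views"],
        session_seconds=cfg["session_seconds"],
        fps=cfg["fps"],
    )
    base = ScheduleParams(session_seconds=cfg["session_seconds"], fps=cfg["fps"])
    train = [replace(base, n_events=n) for n in cfg["train_events"]]
    val = replace(base, n_events=cfg["val_events"])
    return train, val, rp


def generate_benchmark(
    profile: str = "fast", seed: int = 0
) -> tuple[list[MultiViewSession], MultiViewSession]:
    """Generate (train sessions, validation session) in memory."""
    train_sp, val_sp, rp = benchmark_params(profile)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(train_sp) + 1)]
    trains = [
        _generate_with(sp, rp, s, f"train_{i}")
        for i, (sp, s) in enumerate(zip(train_sp, seeds))
    ]
    val = _generate_with(val_sp, rp, seeds[-1], "val")
    return trains, val


def _generate_with(
    sp: ScheduleParams, rp: RenderParams, seed: int, session_id: str
) -> MultiViewSession:
    ss = np.random.SeedSequence(seed)
    s_sched, s_render = ss.spawn(2)
    schedule = sample_event_schedule(sp, np.random.default_rng(s_sched))
    return render_session(
        schedule, rp, seed=int(s_render.generate_state(1)[0] % (2**31)),
        session_id=session_id,
    )


def make_benchmark(
    out_dir: str | Path,
    profile: str = "fast",
    seed: int = 0,
    overwrite: bool = False,
) -> Path:
    """Write the benchmark (2 train + 1 validation session) to disk."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise ValidationError(f"output {out_dir} exists; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    trains, val = generate_benchmark(profile, seed)
    for sess in [*trains, val]:
        write_session(sess, out_dir / sess.session_id, overwrite=overwrite)
    (out_dir / "benchmark.yaml").write_text(
        yaml.safe_dump({"profile": profile, "seed": seed,
                        "sessions": [s.session_id for s in [*trains, val]]})
    )
    return out_dir
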