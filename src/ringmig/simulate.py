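"""Synthetic two-state trajectories on ring-shaped microlanes.

The generator emulates the statistical structure the analysis assumes: cells
alternate between a directionally persistent *run* state (constant tangential
speed, exponential dwell time ``tau_run``) and a localized *rest* state
(confined 1D diffusion on the arc with a reflecting tether, exponential
dwell ``tau_rest``).  Per-run speeds are drawn around ``v_run`` so the
ensemble reproduces the broad run-velocity distribution of real cells, a new
run reverses direction with probability ``p_direction_flip``, and frame-wise
Gaussian jitter mimics nucleus-position noise.  Positions are emitted on a
ring of radius ``R`` every ``dt`` hours, alongside the ground-truth state
segments, so every pipeline stage can be validated against known truth.

Optionally a PEGylated barrier of configurable gap width interrupts the
lane.  Barrier encounters are resolved atomically: once a running cell
enters the encounter zone heading for the gap, it proceeds to the gap edge,
draws its outcome there — Bernoulli transit with probability
``(1 - P_turn0) * exp(-d_gap / mu_trans)``, or, under the invasion
mechanism, transit iff a drawn lamellipodium invasion depth exceeds the gap
— and then either crosses or rests at the barrier and leaves the way it
came.  This makes the generator's transit law exact at the encounter level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .barrier import CENSORED, REVERSAL, TRANSIT, BarrierEncounter
from .io import Track, TrackSet
from .segmentation import REST, RUN, StateSegment

__all__ = [
    "BernoulliMechanism",
    "InvasionMechanism",
    "BarrierModel",
    "SimulationParams",
    "simulate_track",
    "simulate_tracks",
    "simulate_barrier_track",
    "simulate_barrier_dataset",
    "simulate_encounter_outcomes",
    "simulate_invasion_depths",
    "transit_probability",
]

_EPS = 1e-12


@dataclass(frozen=True)
class BernoulliMechanism:
    """Encounter outcome drawn directly from the exponential transit law."""

    mu_trans: float = 8.3
    p_turn0: float = 0.2


@dataclass(frozen=True)
class InvasionMechanism:
    """Encounter outcome decided by a drawn lamellipodium invasion depth."""

    mu_inv: float = 11.8
    s0: float = 1.0
    d_min: float = 2.0
    d_max: float = 30.0


@dataclass(frozen=True)
class BarrierModel:
    """A PEGylated gap on the ring and the rule deciding transits."""

    d_gap: float
    mechanism: BernoulliMechanism | InvasionMechanism = BernoulliMechanism()
    angular_position: float = 0.0
    zone_half_width: float = 50.0


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults are the reference MDA-MB-436 conditions.

    Times in hours, lengths in um, velocities in um/h, diffusion in um^2/h.
    ``rest_confinement`` is the reflecting-tether half-length of rest-state
    motion; ``v_run_sigma`` the SD of per-run-state speed; ``pos_noise_sigma``
    frame-wise Gaussian jitter on (x, y).
    """

    tau_run: float = 13.6
    tau_rest: float = 6.5
    v_run: float = 30.2
    v_run_sigma: float = 0.0
    rest_diffusion: float = 20.0
    rest_confinement: float = 10.0
    pos_noise_sigma: float = 1.0
    p_direction_flip: float = 0.5
    radius: float = 50.0
    dt: float = 1.0 / 6.0
    duration: float = 48.0
    seed: int = 0
    barrier: BarrierModel | None = None

    @property
    def perimeter(self) -> float:
        return 2.0 * np.pi * self.radius

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt)) + 1


def transit_probability(mechanism, d_gap: float) -> float:
    """Model transit probability at gap width ``d_gap`` for a mechanism."""
    if isinstance(mechanism, BernoulliMechanism):
        return float((1.0 - mechanism.p_turn0) * np.exp(-d_gap / mechanism.mu_trans))
    # invasion: P(d_inv > d_gap) of the truncated survival law
    if d_gap >= mechanism.d_max:
        return 0.0
    if d_gap < mechanism.d_min:
        return 1.0
    return float(min(1.0, mechanism.s0 * np.exp(-d_gap / mechanism.mu_inv)))


def _draw_speed(p: SimulationParams, rng: np.random.Generator) -> float:
    if p.v_run_sigma == 0.0:
        return p.v_run
    while True:  # truncate at zero; negligible rejection rate at default SNR
        v = rng.normal(p.v_run, p.v_run_sigma)
        if v >= 0.0:
            return float(v)


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    if width <= 0.0:
        return lo
    y = (x - lo) % (2.0 * width)
    return lo + (y if y <= width else 2.0 * width - y)


# ---------------------------------------------------------------------------
# barrier-free engine


def _draw_state_sequence(p: SimulationParams, rng: np.random.Generator):
    """Alternating run/rest events: list of (label, t0, t1, velocity|None).

    Dwell times are exponential; event boundaries are snapped to the frame
    grid (states switch between frames), so the emitted positions contain
    no partially-mixed frame intervals and the ground-truth segments are
    exact frame tilings.  A dwell that rounds to zero frames leaves no
    event (the state is unresolvable at the acquisition rate by
    construction).
    """
    events = []
    stationary_run = p.tau_run / (p.tau_run + p.tau_rest)
    state = RUN if rng.random() < stationary_run else REST
    direction = -1.0 if rng.random() < 0.5 else 1.0
    t_raw = 0.0
    t_grid = 0.0
    while t_grid < p.duration - _EPS:
        if state == RUN:
            dwell = rng.exponential(p.tau_run)
            vel = direction * _draw_speed(p, rng)
        else:
            dwell = rng.exponential(p.tau_rest)
            vel = None
        t_raw += dwell
        end = min(round(t_raw / p.dt) * p.dt, p.duration)
        if end > t_grid + _EPS:
            events.append((state, t_grid, end, vel))
            t_grid = end
        if state == RUN:
            state = REST
        else:
            if rng.random() < p.p_direction_flip:
                direction = -direction
            state = RUN
    return events


def _path_from_events(p: SimulationParams, events, rng: np.random.Generator):
    """Arc positions at frame times implied by an event sequence."""
    n = p.n_frames
    s = np.empty(n)
    s[0] = rng.uniform(0.0, p.perimeter)
    cur = s[0]
    ev_i = 0
    anchor = cur if events[0][0] == REST else None
    L = p.rest_confinement
    for k in range(1, n):
        t1 = k * p.dt
        t_ptr = (k - 1) * p.dt
        while t_ptr < t1 - _EPS:
            label, _, ev_end, vel = events[ev_i]
            seg_end = min(ev_end, t1)
            step = seg_end - t_ptr
            if step > 0:
                if label == RUN:
                    cur += vel * step
                else:
                    cur += rng.normal(0.0, np.sqrt(2.0 * p.rest_diffusion * step))
                    cur = _reflect(cur, anchor - L, anchor + L)
            t_ptr = seg_end
            if seg_end >= ev_end - _EPS and ev_i < len(events) - 1:
                ev_i += 1
                if events[ev_i][0] == REST:
                    anchor = cur
        s[k] = cur
    return s


def _truth_from_events(
    p: SimulationParams, track_id: str, s: np.ndarray, events
) -> list[StateSegment]:
    """Exact ground-truth segments from grid-aligned events.

    Adjacent same-label events (left by a dwell that rounded away) are
    merged, except runs of opposite direction, which remain distinct states
    in the same convention the analysis uses.
    """
    n_v = len(s) - 1
    pieces: list[list] = []  # [a, b, label, vel]
    for label, t0, t1, vel in events:
        a = int(round(t0 / p.dt))
        b = min(int(round(t1 / p.dt)), n_v)
        if b <= a:
            continue
        if pieces and pieces[-1][2] == label and (
            label == REST or np.sign(pieces[-1][3]) == np.sign(vel)
        ):
            pieces[-1][1] = b
            pieces[-1][3] = vel
        else:
            pieces.append([a, b, label, vel])
    v_true = np.diff(s) / p.dt
    return [
        StateSegment(
            track_id=track_id,
            start_idx=a,
            end_idx=b,
            label=label,
            mean_velocity=float(v_true[a:b].mean()),
            duration=(b - a) * p.dt,
            t_start=a * p.dt,
            censored=bool(a * p.dt > p.duration - 20.0),
        )
        for a, b, label, _ in pieces
    ]


def _truth_segments(
    p: SimulationParams, track_id: str, s: np.ndarray, label_at
) -> list[StateSegment]:
    """Ground-truth segments in the analysis convention (velocity samples)."""
    n_v = len(s) - 1
    labels = [label_at((i + 0.5) * p.dt) for i in range(n_v)]
    v_true = np.diff(s) / p.dt
    segments = []
    a = 0
    for i in range(1, n_v + 1):
        if i == n_v or labels[i] != labels[a]:
            segments.append(
                StateSegment(
                    track_id=track_id,
                    start_idx=a,
                    end_idx=i,
                    label=labels[a],
                    mean_velocity=float(v_true[a:i].mean()),
                    duration=(i - a) * p.dt,
                    t_start=a * p.dt,
                    censored=bool(a * p.dt > p.duration - 20.0),
                )
            )
            a = i
    return segments


def _track_from_arc(p, track_id, s, rng) -> Track:
    phi = s / p.radius
    noise = rng.normal(0.0, p.pos_noise_sigma, size=(len(s), 2)) \
        if p.pos_noise_sigma > 0 else np.zeros((len(s), 2))
    t = np.arange(len(s)) * p.dt
    return Track(
        track_id=track_id,
        t=t,
        x=p.radius * np.cos(phi) + noise[:, 0],
        y=p.radius * np.sin(phi) + noise[:, 1],
    )


def simulate_track(
    p: SimulationParams,
    rng: np.random.Generator | None = None,
    track_id: str = "sim-0000",
):
    """One synthetic track plus its ground-truth state segments.

    With a barrier configured this delegates to the barrier engine and
    discards the encounter record; use :func:`simulate_barrier_track` to
    keep it.
    """
    if p.barrier is not None:
        track, segments, _ = simulate_barrier_track(p, rng=rng, track_id=track_id)
        return track, segments
    if rng is None:
        rng = np.random.default_rng(p.seed)
    events = _draw_state_sequence(p, rng)
    s = _path_from_events(p, events, rng)
    track = _track_from_arc(p, track_id, s, rng)
    return track, _truth_from_events(p, track_id, s, events)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    # splittable per-track streams: adding tracks never perturbs earlier ones
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def simulate_tracks(
    p: SimulationParams, n_tracks: int, id_prefix: str = "sim"
) -> tuple[TrackSet, dict[str, list[StateSegment]]]:
    """An ensemble of tracks with per-track ground truth, reproducible by seed."""
    tracks, truth = [], {}
    for i, rng in enumerate(_spawn_rngs(p.seed, n_tracks)):
        tid = f"{id_prefix}-{i:04d}"
        tr, segs = simulate_track(p, rng=rng, track_id=tid)
        tracks.append(tr)
        truth[tid] = segs
    return TrackSet(tracks=tracks, condition_label=id_prefix), truth


# ---------------------------------------------------------------------------
# barrier engine


def simulate_barrier_track(
    p: SimulationParams,
    rng: np.random.Generator | None = None,
    track_id: str = "sim-0000",
):
    """One track on a ring with a PEGylated gap.

    Returns ``(track, truth_segments, truth_encounters)``.  Outside the
    encounter zone the cell follows the free run/rest dynamics; a run
    entering the zone is scripted to the gap edge, draws its outcome there,
    and crosses or reverses (rest at the barrier, then a run directed away).
    """
    if p.barrier is None:
        raise ValueError("SimulationParams.barrier is not configured")
    if rng is None:
        rng = np.random.default_rng(p.seed)
    b = p.barrier
    P = p.perimeter
    ga = (b.angular_position * p.radius) % P  # gap-center arc position
    ge = b.d_gap / 2.0  # gap edge (arc distance from center)
    za = ge + b.zone_half_width  # zone boundary
    L = p.rest_confinement
    p_transit = transit_probability(b.mechanism, b.d_gap)

    def wrap_offset(u: float) -> float:
        return (u - ga + P / 2.0) % P - P / 2.0

    n = p.n_frames
    s = np.empty(n)
    # start uniformly outside the zone
    w0 = za + rng.uniform(0.0, P - 2.0 * za)
    u = ga + w0
    s[0] = u

    stationary_run = p.tau_run / (p.tau_run + p.tau_rest)
    if rng.random() < stationary_run:
        mode = "free_run"
    else:
        mode = "free_rest"
    direction = -1.0 if rng.random() < 0.5 else 1.0
    speed = _draw_speed(p, rng)
    dwell_end = rng.exponential(p.tau_run if mode == "free_run" else p.tau_rest)
    anchor = u
    target = 0.0  # scripted-run target in w coordinates
    on_arrival = ""  # "decide" | "resume"
    side = 0

    labels_t: list[tuple[float, str]] = []  # (time, label) change log
    labels_t.append((0.0, RUN if mode == "free_run" else REST))
    encounters: list[dict] = []

    def log(t: float, label: str) -> None:
        if labels_t[-1][1] != label:
            labels_t.append((t, label))

    def dist_along(frm: float, to: float, sgn: float) -> float:
        """Arc distance from w=frm to w=to moving in direction sgn.

        A zero distance means a full revolution: a cell sitting exactly on a
        boundary and moving away reaches that boundary again after one lap.
        """
        d = ((to - frm) * sgn) % P
        return P if d < 1e-9 else d

    t_now = 0.0
    frame = 1
    while frame < n:
        t_frame = frame * p.dt
        while t_now < t_frame - _EPS:
            budget = t_frame - t_now
            w = wrap_offset(u)
            if mode == "free_run":
                if abs(w) < za - 1e-9:
                    # inside the zone (rest-tether spill): script immediately
                    side = 1 if w > 0 else -1
                    moving_in = (w > 0) == (direction < 0)
                    if moving_in:
                        mode, on_arrival = "scripted_run", "decide"
                        target = side * ge
                        encounters.append(
                            {"t_entry": t_now, "side": side, "outcome": None,
                             "t_exit": None}
                        )
                    else:
                        mode, on_arrival = "scripted_run", "resume"
                        target = side * za
                    continue
                # first zone boundary reached moving in `direction`
                d_entry = min(dist_along(w, za, direction),
                              dist_along(w, -za, direction))
                t_entry = d_entry / speed if speed > 0 else np.inf
                t_dwell = dwell_end - t_now
                if t_entry <= min(budget, t_dwell) + _EPS:
                    # reach the zone boundary: begin an encounter
                    u += direction * d_entry
                    t_now += t_entry
                    w2 = wrap_offset(u)
                    side = 1 if w2 > 0 else -1
                    mode, on_arrival = "scripted_run", "decide"
                    target = side * ge
                    encounters.append(
                        {"t_entry": t_now, "side": side, "outcome": None,
                         "t_exit": None}
                    )
                elif t_dwell <= budget + _EPS:
                    u += direction * speed * t_dwell
                    t_now += t_dwell
                    mode = "free_rest"
                    anchor = u
                    dwell_end = t_now + rng.exponential(p.tau_rest)
                    log(t_now, REST)
                else:
                    u += direction * speed * budget
                    t_now = t_frame
            elif mode == "scripted_run":
                d_t = dist_along(w, target, direction)
                t_arr = d_t / speed if speed > 0 else np.inf
                if t_arr <= budget + _EPS:
                    u += direction * d_t
                    t_now += t_arr
                    if on_arrival == "decide":
                        if rng.random() < p_transit:
                            encounters[-1]["outcome"] = TRANSIT
                            mode, on_arrival = "scripted_run", "resume"
                            target = -side * za
                            # direction unchanged: the cell crosses the gap
                        else:
                            encounters[-1]["outcome"] = REVERSAL
                            mode = "barrier_rest"
                            anchor = u
                            dwell_end = t_now + rng.exponential(p.tau_rest)
                            log(t_now, REST)
                    else:  # resume free dynamics just outside the zone
                        if encounters and encounters[-1]["t_exit"] is None \
                                and encounters[-1]["outcome"] is not None:
                            encounters[-1]["t_exit"] = t_now
                        mode = "free_run"
                        dwell_end = t_now + rng.exponential(p.tau_run)
                else:
                    u += direction * speed * budget
                    t_now = t_frame
            elif mode == "barrier_rest":
                step = min(budget, dwell_end - t_now)
                if step > 0:
                    u += rng.normal(0.0, np.sqrt(2.0 * p.rest_diffusion * step))
                    # reflecting tether on the entry side of the gap edge
                    edge_u = u - (wrap_offset(u) - side * ge)
                    lo, hi = sorted((edge_u, edge_u + side * L))
                    u = _reflect(u, lo, hi)
                t_now += step
                if t_now >= dwell_end - _EPS:
                    # run directed away from the barrier until zone exit
                    direction = float(side)
                    speed = _draw_speed(p, rng)
                    mode, on_arrival = "scripted_run", "resume"
                    target = side * za
                    log(t_now, RUN)
            else:  # free_rest
                step = min(budget, dwell_end - t_now)
                if step > 0:
                    u += rng.normal(0.0, np.sqrt(2.0 * p.rest_diffusion * step))
                    u = _reflect(u, anchor - L, anchor + L)
                t_now += step
                if t_now >= dwell_end - _EPS:
                    if rng.random() < p.p_direction_flip:
                        direction = -direction
                    speed = _draw_speed(p, rng)
                    mode = "free_run"
                    dwell_end = t_now + rng.exponential(p.tau_run)
                    log(t_now, RUN)
        s[frame] = u
        frame += 1

    # label lookup from the change log
    times = np.array([t for t, _ in labels_t])
    labs = [lab for _, lab in labels_t]

    def label_at(t: float) -> str:
        idx = int(np.searchsorted(times, t, side="right")) - 1
        return labs[max(idx, 0)]

    track = _track_from_arc(p, track_id, s, rng)
    segments = _truth_segments(p, track_id, s, label_at)

    truth = []
    for e in encounters:
        if e["outcome"] is None or e["t_exit"] is None:
            outcome = CENSORED
        else:
            outcome = e["outcome"]
        truth.append(
            BarrierEncounter(
                track_id=track_id,
                entry_frame=int(np.ceil(e["t_entry"] / p.dt)),
                exit_frame=None if e["t_exit"] is None
                else int(np.ceil(e["t_exit"] / p.dt)),
                entry_side=e["side"],
                exit_side=None if outcome == CENSORED
                else (e["side"] if outcome == REVERSAL else -e["side"]),
                outcome=outcome,
            )
        )
    return track, segments, truth


def simulate_barrier_dataset(
    p: SimulationParams, d_gaps, n_tracks_per_gap: int, id_prefix: str = "bar"
):
    """Track sets with ground-truth encounters for several gap widths.

    Returns ``{d_gap: (TrackSet, {track_id: [BarrierEncounter, ...]})}``.
    Tracks may meet the barrier repeatedly, as real cells on rings do.
    """
    if p.barrier is None:
        p = replace(p, barrier=BarrierModel(d_gap=0.0))
    out = {}
    ss = np.random.SeedSequence(p.seed)
    gap_seeds = ss.spawn(len(list(d_gaps)))
    for d_gap, gseed in zip(d_gaps, gap_seeds):
        pg = replace(p, barrier=replace(p.barrier, d_gap=float(d_gap)))
        tracks, truth = [], {}
        for i, child in enumerate(gseed.spawn(n_tracks_per_gap)):
            tid = f"{id_prefix}-g{d_gap:g}-{i:04d}"
            tr, _, enc = simulate_barrier_track(
                pg, rng=np.random.default_rng(child), track_id=tid
            )
            tracks.append(tr)
            truth[tid] = enc
        out[float(d_gap)] = (
            TrackSet(tracks=tracks, condition_label=f"{id_prefix}-gap{d_gap:g}"),
            truth,
        )
    return out


def simulate_encounter_outcomes(
    d_gap: float, n: int, mechanism, rng: np.random.Generator
) -> np.ndarray:
    """Encounter-level outcomes (True = transit) without full tracks.

    Bernoulli mechanism: direct draws from the transit law.  Invasion
    mechanism: draw an invasion depth per encounter; transit iff it exceeds
    the gap width.
    """
    if isinstance(mechanism, BernoulliMechanism):
        return rng.random(n) < transit_probability(mechanism, d_gap)
    depths = simulate_invasion_depths(
        mu_inv=mechanism.mu_inv, s0=mechanism.s0, n=n, rng=rng,
        d_min=mechanism.d_min, d_max=mechanism.d_max,
    )
    return depths > d_gap


def simulate_invasion_depths(
    mu_inv: float = 11.8,
    s0: float = 1.0,
    n: int = 500,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    d_min: float = 2.0,
    d_max: float = 30.0,
) -> np.ndarray:
    """Sample invasion depths whose survival follows s0*exp(-d/mu_inv).

    Inverse-CDF sampling of the truncated law: on [d_min, d_max) the sample
    survival equals ``s0 * exp(-d / mu_inv)`` exactly, with the leftover
    probability placed as point masses at the bounds (all cells penetrate at
    least ``d_min``; none deeper than ``d_max``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < s0 <= 1.0):
        raise ValueError("s0 must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(n)
    with np.errstate(divide="ignore"):
        d = -mu_inv * np.log(u / s0)
    d = np.clip(d, d_min, d_max)
    d[u > s0 * np.exp(-d_min / mu_inv)] = d_min
    d[u <= s0 * np.exp(-d_max / mu_inv)] = d_max
    return d
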