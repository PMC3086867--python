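"""Kinematic 2-D foraging arena: 8 robots push 8 food items to a white wall.

The arena is a square with one white wall (the top wall, y = side) and
three black walls.  Robots are differential-drive discs; food items are
passive discs that move only when displaced by a robot.  An item is
"delivered" the moment its centre enters the target band of depth
``target_depth`` along the white wall; it is then deactivated and
credited to the last robot that pushed it (or the nearest robot if it
was never pushed).  The delivery is labelled *shared* if that robot's
share output is positive at the delivery step, else *selfish*.

The model is deliberately simple: quasi-static pushing (overlaps are
resolved by displacing the item along the centre line), no momentum, no
friction.  The inner loop is compiled with numba and runs over a batch
of independent "worlds" (a world = one group of robots + one random
layout), which is what makes whole-population evolutionary runs
tractable: a generation of 200 groups x 10 trials is a single batch of
2,000 worlds.

Sensor model (six channels, all in [-1, 1]):

* three short-range IR sensors at -45/0/+45 degrees (30-degree cones,
  3 cm range) returning proximity to the nearest robot, item or wall in
  the cone: +1 at contact, -1 at or beyond the range, linear between;
* one long-range IR sensor (0 degrees, 30-degree cone, 6 cm range) that
  sees robots only, which is what lets controllers distinguish a nearby
  robot from a food item;
* two vision channels: a forward field of view split into a left and a
  right half-field; a channel reads +1 if a ray through the centre of
  its half-field reaches the white wall without being blocked by another
  robot, else -1.  Walls enter IR cones through their inward normal
  direction; items do not occlude vision (cameras sit above item height).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .genome import (
    Genome,
    genes_to_weights,
    N_HIDDEN,
    N_INPUTS,
    N_OUTPUTS,
)

_EPS = 1e-9

# indices into the packed parameter vector handed to the compiled kernels
(_P_DT, _P_SIDE, _P_RR, _P_RI, _P_VMAX, _P_BAND, _P_SRANGE, _P_LRANGE,
 _P_COSHALF, _P_OFFC0, _P_OFFC1, _P_OFFC2, _P_OFFS0, _P_OFFS1, _P_OFFS2,
 _P_VISC, _P_VISS) = range(17)


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry, timing and sensor parameters of the foraging arena."""

    side: float = 50.0               # cm, square arena
    n_robots: int = 8
    n_items: int = 8
    trial_duration: float = 60.0     # s
    time_step: float = 0.1           # s
    target_depth: float = 4.0        # cm, band along the white (top) wall
    robot_radius: float = 1.3        # cm
    item_radius: float = 1.0         # cm
    max_wheel_speed: float = 4.0     # cm/s
    short_ir_range: float = 3.0      # cm
    long_ir_range: float = 6.0       # cm
    short_ir_angles_deg: tuple = (-45.0, 0.0, 45.0)
    ir_aperture_deg: float = 30.0
    vision_fov_deg: float = 60.0

    def __post_init__(self):
        if min(self.side, self.trial_duration, self.time_step, self.target_depth,
               self.robot_radius, self.item_radius, self.max_wheel_speed,
               self.short_ir_range, self.long_ir_range) <= 0:
            raise ValueError("all arena lengths, radii, speeds and times must be positive")
        if self.target_depth >= self.side:
            raise ValueError("target_depth must be smaller than the arena side")
        if self.n_robots < 1 or self.n_items < 0:
            raise ValueError("need at least one robot and a nonnegative item count")
        if len(self.short_ir_angles_deg) != 3:
            raise ValueError("exactly three short-range IR sensors are modelled")

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_duration / self.time_step))

    def params(self) -> np.ndarray:
        """Pack the scalar parameters for the compiled kernels."""
        a = np.deg2rad(np.asarray(self.short_ir_angles_deg, dtype=float))
        vis = math.radians(self.vision_fov_deg) / 4.0
        return np.array([
            self.time_step, self.side, self.robot_radius, self.item_radius,
            self.max_wheel_speed, self.side - self.target_depth,
            self.short_ir_range, self.long_ir_range,
            math.cos(math.radians(self.ir_aperture_deg) / 2.0),
            math.cos(a[0]), math.cos(a[1]), math.cos(a[2]),
            math.sin(a[0]), math.sin(a[1]), math.sin(a[2]),
            math.cos(vis), math.sin(vis),
        ])


@dataclass
class ArenaState:
    """Mutable state of a single arena world."""

    robot_pos: np.ndarray      # (R, 2)
    robot_heading: np.ndarray  # (R,)
    item_pos: np.ndarray       # (I, 2)
    item_active: np.ndarray    # (I,) bool
    item_pusher: np.ndarray    # (I,) int, -1 = never pushed
    time: float = 0.0

    def copy(self) -> "ArenaState":
        return ArenaState(self.robot_pos.copy(), self.robot_heading.copy(),
                          self.item_pos.copy(), self.item_active.copy(),
                          self.item_pusher.copy(), self.time)


@dataclass(frozen=True)
class TrialResult:
    """Per-robot delivery counts from one trial."""

    n_selfish: np.ndarray  # (R,) int
    n_shared: np.ndarray   # (R,) int

    @property
    def total_delivered(self) -> int:
        return int(self.n_selfish.sum() + self.n_shared.sum())


@dataclass(frozen=True)
class GroupEvaluation:
    """Aggregated counts for one group over several independent trials."""

    per_trial_selfish: np.ndarray  # (T, R) int
    per_trial_shared: np.ndarray   # (T, R) int

    @property
    def n_selfish(self) -> np.ndarray:
        return self.per_trial_selfish.sum(axis=0)

    @property
    def n_shared(self) -> np.ndarray:
        return self.per_trial_shared.sum(axis=0)

    @property
    def mean_items_per_trial(self) -> float:
        return float((self.per_trial_selfish.sum() + self.per_trial_shared.sum())
                     / self.per_trial_selfish.shape[0])


# ---------------------------------------------------------------------
# Controller weight plumbing
# ---------------------------------------------------------------------

def networks_to_arrays(networks) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-robot ControllerNetworks into (R,7,3) and (R,4,3) arrays."""
    w_in = np.stack([n.w_in for n in networks])
    w_out = np.stack([n.w_out for n in networks])
    return w_in, w_out


def genomes_to_arrays(genomes, weight_range: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Decode genomes (sequence of Genome or an (..., 33) array) to weights."""
    if isinstance(genomes, (list, tuple)) and len(genomes) and isinstance(genomes[0], Genome):
        genes = np.stack([g.genes for g in genomes])
    else:
        genes = np.asarray(genomes, dtype=np.uint8)
    w = genes_to_weights(genes, weight_range)
    n_in = N_INPUTS * N_HIDDEN
    w_in = w[..., :n_in].reshape(w.shape[:-1] + (N_INPUTS, N_HIDDEN))
    w_out = w[..., n_in:].reshape(w.shape[:-1] + (N_HIDDEN + 1, N_OUTPUTS))
    return np.ascontiguousarray(w_in), np.ascontiguousarray(w_out)


# ---------------------------------------------------------------------
# Compiled single-world kernels
# ---------------------------------------------------------------------

@njit(cache=True, fastmath=True, inline='always')
def _sense_robot(rpos, rhead, ipos, iactive, r, p, sensors):
    """Fill the 6-channel sensor vector of robot r (single world)."""
    R = rpos.shape[0]
    I = ipos.shape[0]
    rr = p[_P_RR]
    ri = p[_P_RI]
    side = p[_P_SIDE]
    cos_half = p[_P_COSHALF]
    x = rpos[r, 0]
    y = rpos[r, 1]
    head = rhead[r]
    ch = math.cos(head)
    sh = math.sin(head)
    for s in range(4):
        if s < 3:
            co = p[_P_OFFC0 + s]
            so = p[_P_OFFS0 + s]
            rng_ = p[_P_SRANGE]
        else:
            co = 1.0
            so = 0.0
            rng_ = p[_P_LRANGE]
        ax = ch * co - sh * so
        ay = sh * co + ch * so
        best = -1.0
        # other robots (all four IR sensors see robots)
        for j in range(R):
            if j == r:
                continue
            dx = rpos[j, 0] - x
            dy = rpos[j, 1] - y
            dist = math.sqrt(dx * dx + dy * dy)
            surf = dist - 2.0 * rr
            if surf < rng_ and dx * ax + dy * ay >= dist * cos_half:
                v = 1.0 - 2.0 * max(surf, 0.0) / rng_
                if v > best:
                    best = v
        if s < 3:
            # items (invisible to the long-range sensor)
            for i in range(I):
                if not iactive[i]:
                    continue
                dx = ipos[i, 0] - x
                dy = ipos[i, 1] - y
                dist = math.sqrt(dx * dx + dy * dy)
                surf = dist - rr - ri
                if surf < rng_ and dx * ax + dy * ay >= dist * cos_half:
                    v = 1.0 - 2.0 * max(surf, 0.0) / rng_
                    if v > best:
                        best = v
            # walls, seen through their inward normal direction
            for w in range(4):
                if w == 0:
                    surf = x - rr
                    nx, ny = -1.0, 0.0
                elif w == 1:
                    surf = side - x - rr
                    nx, ny = 1.0, 0.0
                elif w == 2:
                    surf = y - rr
                    nx, ny = 0.0, -1.0
                else:
                    surf = side - y - rr
                    nx, ny = 0.0, 1.0
                if surf < rng_ and nx * ax + ny * ay >= cos_half:
                    v = 1.0 - 2.0 * max(surf, 0.0) / rng_
                    if v > best:
                        best = v
        sensors[s] = best
    # vision: one ray through the centre of each half-field
    for c in range(2):
        so = p[_P_VISS] if c == 0 else -p[_P_VISS]
        ux = ch * p[_P_VISC] - sh * so
        uy = sh * p[_P_VISC] + ch * so
        t_hit = 1e300
        white = False
        if ux < 0.0:
            t = -x / ux
            if t < t_hit:
                t_hit = t
                white = False
        if ux > 0.0:
            t = (side - x) / ux
            if t < t_hit:
                t_hit = t
                white = False
        if uy < 0.0:
            t = -y / uy
            if t < t_hit:
                t_hit = t
                white = False
        if uy > 0.0:
            t = (side - y) / uy
            if t < t_hit:
                t_hit = t
                white = True  # top wall is the white one
        blocked = False
        for j in range(R):
            if j == r:
                continue
            dx = rpos[j, 0] - x
            dy = rpos[j, 1] - y
            tr = dx * ux + dy * uy
            if 0.0 < tr < t_hit:
                ca2 = dx * dx + dy * dy - tr * tr
                if ca2 < rr * rr:
                    blocked = True
                    break
        sensors[4 + c] = 1.0 if (white and not blocked) else -1.0


@njit(cache=True, fastmath=True, inline='always')
def _outputs_world(rpos, rhead, ipos, iactive, w_in, w_out, p, out, sensors, h):
    """Motor outputs (R, 3) of every robot from the current world state."""
    R = rpos.shape[0]
    for r in range(R):
        _sense_robot(rpos, rhead, ipos, iactive, r, p, sensors)
        for j in range(3):
            acc = -w_in[r, 6, j]  # bias input = -1
            for i in range(6):
                acc += sensors[i] * w_in[r, i, j]
            h[j] = math.tanh(acc)
        for o in range(3):
            acc = -w_out[r, 3, o]  # bias input = -1
            for j in range(3):
                acc += h[j] * w_out[r, j, o]
            out[r, o] = math.tanh(acc)


@njit(cache=True, fastmath=True, inline='always')
def _move_world(rpos, rhead, ipos, iactive, ipusher, out, p, disp):
    """One kinematic step: drive, push items, resolve overlaps, clip."""
    R = rpos.shape[0]
    I = ipos.shape[0]
    dt = p[_P_DT]
    side = p[_P_SIDE]
    rr = p[_P_RR]
    ri = p[_P_RI]
    vmax = p[_P_VMAX]
    for r in range(R):
        vl = out[r, 0] * vmax
        vr = out[r, 1] * vmax
        v = 0.5 * (vl + vr)
        omega = (vr - vl) / (2.0 * rr)  # wheel track = robot diameter
        rpos[r, 0] += v * dt * math.cos(rhead[r])
        rpos[r, 1] += v * dt * math.sin(rhead[r])
        hd = rhead[r] + omega * dt
        rhead[r] = (hd + math.pi) % (2.0 * math.pi) - math.pi
        rpos[r, 0] = min(max(rpos[r, 0], rr), side - rr)
        rpos[r, 1] = min(max(rpos[r, 1], rr), side - rr)
    # quasi-static pushing: displace each overlapped item along the centre
    # line away from its deepest-overlap robot; that robot becomes the
    # item's last pusher
    touch = rr + ri
    for i in range(I):
        if not iactive[i]:
            continue
        best_depth = 0.0
        best_r = -1
        best_dist = 0.0
        for r in range(R):
            dx = ipos[i, 0] - rpos[r, 0]
            dy = ipos[i, 1] - rpos[r, 1]
            dist = math.sqrt(dx * dx + dy * dy)
            depth = touch - dist
            if depth > best_depth:
                best_depth = depth
                best_r = r
                best_dist = dist
        if best_r >= 0:
            dx = ipos[i, 0] - rpos[best_r, 0]
            dy = ipos[i, 1] - rpos[best_r, 1]
            if best_dist > _EPS:
                ipos[i, 0] += best_depth * dx / best_dist
                ipos[i, 1] += best_depth * dy / best_dist
            else:  # exactly coincident centres: push along +x by convention
                ipos[i, 0] += best_depth
            ipusher[i] = best_r
            ipos[i, 0] = min(max(ipos[i, 0], ri), side - ri)
            ipos[i, 1] = min(max(ipos[i, 1], ri), side - ri)
    # robot-robot separation (single symmetric relaxation pass)
    for r in range(R):
        disp[r, 0] = 0.0
        disp[r, 1] = 0.0
    for r in range(R):
        for j in range(r + 1, R):
            dx = rpos[r, 0] - rpos[j, 0]
            dy = rpos[r, 1] - rpos[j, 1]
            dist = math.sqrt(dx * dx + dy * dy)
            pen = 2.0 * rr - dist
            if pen > 0.0:
                if dist > _EPS:
                    ux = dx / dist
                    uy = dy / dist
                else:
                    ux, uy = 1.0, 0.0
                disp[r, 0] += 0.5 * pen * ux
                disp[r, 1] += 0.5 * pen * uy
                disp[j, 0] -= 0.5 * pen * ux
                disp[j, 1] -= 0.5 * pen * uy
    for r in range(R):
        rpos[r, 0] = min(max(rpos[r, 0] + disp[r, 0], rr), side - rr)
        rpos[r, 1] = min(max(rpos[r, 1] + disp[r, 1], rr), side - rr)


@njit(cache=True, fastmath=True, inline='always')
def _score_world(rpos, ipos, iactive, ipusher, out, selfish, shared,
                 events, n_events, t, b, p):
    """Deliver any active item inside the target band; update counts.

    Events rows are (step, world, robot, item, shared?1:0); returns the
    new event count.
    """
    R = rpos.shape[0]
    I = ipos.shape[0]
    band_y = p[_P_BAND]
    for i in range(I):
        if not iactive[i] or ipos[i, 1] < band_y:
            continue
        credit = ipusher[i]
        if credit < 0:  # never pushed: credit the nearest robot
            best = 1e300
            for r in range(R):
                dx = ipos[i, 0] - rpos[r, 0]
                dy = ipos[i, 1] - rpos[r, 1]
                d2 = dx * dx + dy * dy
                if d2 < best:
                    best = d2
                    credit = r
        if out[credit, 2] > 0.0:
            shared[credit] += 1
            flag = 1
        else:
            selfish[credit] += 1
            flag = 0
        iactive[i] = False
        if n_events < events.shape[0]:
            events[n_events, 0] = t
            events[n_events, 1] = b
            events[n_events, 2] = credit
            events[n_events, 3] = i
            events[n_events, 4] = flag
            n_events += 1
    return n_events


@njit(cache=True, fastmath=True)
def _run_worlds(w_in, w_out, rpos, rhead, ipos, iactive, ipusher,
                selfish, shared, events, n_steps, p):
    """Full trials for a batch of worlds; returns the delivery event count."""
    B, R = rhead.shape
    out = np.empty((R, 3))
    sensors = np.empty(6)
    h = np.empty(3)
    disp = np.empty((R, 2))
    n_events = 0
    for b in range(B):
        remaining = 0
        for i in range(ipos.shape[1]):
            if iactive[b, i]:
                remaining += 1
        for t in range(n_steps):
            if remaining == 0:
                break
            _outputs_world(rpos[b], rhead[b], ipos[b], iactive[b],
                           w_in[b], w_out[b], p, out, sensors, h)
            _move_world(rpos[b], rhead[b], ipos[b], iactive[b], ipusher[b],
                        out, p, disp)
            before = n_events
            n_events = _score_world(rpos[b], ipos[b], iactive[b], ipusher[b],
                                    out, selfish[b], shared[b],
                                    events, n_events, t, b, p)
            remaining -= n_events - before
    return n_events


# ---------------------------------------------------------------------
# Batch driver
# ---------------------------------------------------------------------

def _place_batch(B: int, cfg: ArenaConfig, rng: np.random.Generator):
    """Seeded random non-overlapping start layouts for B worlds.

    Robots anywhere in the arena; items anywhere outside the target band
    (an item starting inside the band would count as delivered with no
    pushing having occurred).
    """
    R, I = cfg.n_robots, cfg.n_items
    radii = np.array([cfg.robot_radius] * R + [cfg.item_radius] * I)
    pos = np.zeros((B, R + I, 2))
    for e in range(R + I):
        r_e = radii[e]
        y_hi = cfg.side - r_e
        if e >= R:  # item: keep out of the delivery band
            y_hi = cfg.side - cfg.target_depth - r_e
        pending = np.arange(B)
        min_d = radii[:e] + r_e
        while pending.size:
            cand = np.column_stack([
                rng.uniform(r_e, cfg.side - r_e, pending.size),
                rng.uniform(r_e, y_hi, pending.size),
            ])
            if e == 0:
                ok = np.ones(pending.size, dtype=bool)
            else:
                d = np.linalg.norm(cand[:, None, :] - pos[pending, :e], axis=-1)
                ok = (d >= min_d[None, :]).all(axis=1)
            pos[pending[ok], e] = cand[ok]
            pending = pending[~ok]
    headings = rng.uniform(-np.pi, np.pi, size=(B, R))
    return np.ascontiguousarray(pos[:, :R]), headings, np.ascontiguousarray(pos[:, R:])


def simulate_worlds(w_in: np.ndarray, w_out: np.ndarray, cfg: ArenaConfig,
                    rng: np.random.Generator, record_events: bool = False):
    """Run one full trial in each of B independent worlds.

    ``w_in``/``w_out`` are (B, R, 7, 3) and (B, R, 4, 3) controller
    weights.  Returns (selfish, shared) int arrays of shape (B, R), plus
    a list of delivery events (step, world, robot, item, shared) if
    ``record_events``.
    """
    w_in = np.ascontiguousarray(w_in, dtype=np.float64)
    w_out = np.ascontiguousarray(w_out, dtype=np.float64)
    B, R = w_in.shape[:2]
    rpos, rhead, ipos = _place_batch(B, cfg, rng)
    iactive = np.ones((B, cfg.n_items), dtype=np.bool_)
    ipusher = np.full((B, cfg.n_items), -1, dtype=np.int64)
    selfish = np.zeros((B, R), dtype=np.int64)
    shared = np.zeros((B, R), dtype=np.int64)
    events = np.empty((B * cfg.n_items, 5), dtype=np.int64)
    n_ev = _run_worlds(w_in, w_out, rpos, rhead, ipos, iactive, ipusher,
                       selfish, shared, events, cfg.n_steps, cfg.params())
    if record_events:
        return selfish, shared, [tuple(row) for row in events[:n_ev]]
    return selfish, shared


# ---------------------------------------------------------------------
# Single-world public surface
# ---------------------------------------------------------------------

def initial_state(cfg: ArenaConfig, rng: np.random.Generator) -> ArenaState:
    rpos, rhead, ipos = _place_batch(1, cfg, rng)
    return ArenaState(robot_pos=rpos[0], robot_heading=rhead[0], item_pos=ipos[0],
                      item_active=np.ones(cfg.n_items, dtype=np.bool_),
                      item_pusher=np.full(cfg.n_items, -1, dtype=np.int64))


def sense(state: ArenaState, cfg: ArenaConfig, robot_index: int) -> np.ndarray:
    """Six-channel sensor vector for one robot (values in [-1, 1])."""
    if not 0 <= robot_index < state.robot_pos.shape[0]:
        raise IndexError("robot index out of range")
    sensors = np.empty(6)
    _sense_robot(state.robot_pos, state.robot_heading, state.item_pos,
                 state.item_active, robot_index, cfg.params(), sensors)
    return sensors


def _state_outputs(state: ArenaState, networks, cfg: ArenaConfig) -> np.ndarray:
    w_in, w_out = networks_to_arrays(networks)
    out = np.empty((state.robot_pos.shape[0], 3))
    _outputs_world(state.robot_pos, state.robot_heading, state.item_pos,
                   state.item_active, np.ascontiguousarray(w_in),
                   np.ascontiguousarray(w_out), cfg.params(), out,
                   np.empty(6), np.empty(3))
    return out


def step(state: ArenaState, networks, cfg: ArenaConfig) -> ArenaState:
    """Advance one time step (motion, pushing, collision resolution only).

    Delivery scoring is a separate operation (``score_deliveries``) so a
    caller can inspect the post-motion state.
    """
    new = state.copy()
    out = _state_outputs(new, networks, cfg)
    _move_world(new.robot_pos, new.robot_heading, new.item_pos, new.item_active,
                new.item_pusher, out, cfg.params(), np.empty((out.shape[0], 2)))
    new.time = state.time + cfg.time_step
    return new


def score_deliveries(state: ArenaState, networks, cfg: ArenaConfig):
    """Deactivate and credit any item inside the target band.

    Returns (new_state, events) where events is a list of
    (robot_index, item_index, shared) tuples.
    """
    new = state.copy()
    out = _state_outputs(new, networks, cfg)
    R = new.robot_pos.shape[0]
    selfish = np.zeros(R, dtype=np.int64)
    shared = np.zeros(R, dtype=np.int64)
    events = np.empty((new.item_pos.shape[0], 5), dtype=np.int64)
    n_ev = _score_world(new.robot_pos, new.item_pos, new.item_active,
                        new.item_pusher, out, selfish, shared, events, 0, 0, 0,
                        cfg.params())
    return new, [(int(r), int(i), bool(f)) for _, _, r, i, f in events[:n_ev]]


def run_trial(genomes, cfg: ArenaConfig, seed, weight_range: float = 1.0,
              networks=None) -> TrialResult:
    """One seeded 60-s trial of a group; deterministic for fixed inputs.

    ``genomes`` may be a sequence of Genome objects or an (R, 33) array;
    alternatively pass decoded/scripted ``networks`` directly.
    """
    if networks is not None:
        w_in, w_out = networks_to_arrays(networks)
    else:
        w_in, w_out = genomes_to_arrays(genomes, weight_range)
    if w_in.shape[0] != cfg.n_robots:
        raise ValueError(f"need exactly {cfg.n_robots} controllers")
    rng = np.random.default_rng(seed)
    selfish, shared = simulate_worlds(w_in[None], w_out[None], cfg, rng)
    return TrialResult(n_selfish=selfish[0], n_shared=shared[0])


def evaluate_group(genomes, cfg: ArenaConfig, n_trials: int = 10, seed=0,
                   weight_range: float = 1.0, networks=None) -> GroupEvaluation:
    """Evaluate one group over ``n_trials`` independent seeded trials.

    Trials differ only in their random start layout; counts are reported
    per trial so callers can aggregate or test distributions.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if networks is not None:
        w_in, w_out = networks_to_arrays(networks)
    else:
        w_in, w_out = genomes_to_arrays(genomes, weight_range)
    rng = np.random.default_rng(seed)
    w_in_b = np.repeat(w_in[None], n_trials, axis=0)
    w_out_b = np.repeat(w_out[None], n_trials, axis=0)
    selfish, shared = simulate_worlds(w_in_b, w_out_b, cfg, rng)
    return GroupEvaluation(per_trial_selfish=selfish, per_trial_shared=shared)
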