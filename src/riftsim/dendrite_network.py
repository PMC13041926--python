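"""Fractal dendritic trees and coincidence-grown recurrent networks.

A single core neuron carries a fractal dendritic tree whose branch lengths
shrink geometrically, ``L_n = L_0 * r**(n-1)``.  Level 1 is the longest,
most distal branch; higher levels sit progressively closer to the soma, so
the internal conduction delay ``T_internal`` strictly decreases with level
index.  Randomly placed peripheral neurons form recurrent loops back onto
the tree; a loop's round trip takes ``T_external = 2*d/v_axon + delta_syn``.
Connections are selected purely by coincidence detection at the soma: loops
whose arrivals align within a short window become permanent.  The timing
rule ``T_internal + T_external ~ constant`` is an emergent statistic of the
grown network, never imposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .integration_metrics import fractal_measures, phi_dyn, predictability_metrics
from ._seeding import named_rng

__all__ = [
    "DendriticTree",
    "PeripheralNeuron",
    "TimingConfig",
    "NetworkTrajectory",
    "TimingReport",
    "build_tree",
    "tree_fractal_dimension",
    "detect_coincidences",
    "grow_network",
    "verify_timing_rule",
    "run_delay_sweep",
]


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------

@dataclass
class TimingConfig:
    """Conduction speeds and delays (speeds in mm/ms, delays in ms)."""

    soma_delay_ms: float = 5.0
    window_ms: float = 2.0
    dendritic_speed: float = 0.05
    axonal_speed: float = 0.2
    synaptic_delay_ms: float = 0.5
    distance_range_mm: tuple[float, float] = (0.5, 2.0)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    shares = weights / weights.sum() * total
    base = np.floor(shares).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(shares - base), kind="stable")
    base[order[:rem]] += 1
    return base


@dataclass
class DendriticTree:
    trunk_length: float          # L_0, um
    scaling_factor: float        # r
    n_levels: int
    n_synapses: int
    dendritic_speed: float       # mm/ms
    lengths: np.ndarray = field(init=False)       # um per level
    slots: np.ndarray = field(init=False)         # synapse slots per level
    path_to_soma: np.ndarray = field(init=False)  # um, branch midpath to soma
    T_internal: np.ndarray = field(init=False)    # ms per level

    def __post_init__(self) -> None:
        n = np.arange(1, self.n_levels + 1)
        self.lengths = self.trunk_length * self.scaling_factor ** (n - 1)
        self.slots = _largest_remainder(self.lengths, self.n_synapses)
        # level 1 is most distal: its signal traverses every shorter branch
        # on the way in, so the conduction path is the tail sum of lengths
        self.path_to_soma = np.cumsum(self.lengths[::-1])[::-1]
        self.T_internal = self.path_to_soma / 1000.0 / self.dendritic_speed

    def level_length(self, level: int) -> float:
        return float(self.lengths[level - 1])


def build_tree(
    L_0: float,
    r: float,
    n_levels: int = 4,
    n_synapses: int = 1000,
    dendritic_speed: float = 0.05,
) -> DendriticTree:
    """Construct a fractal tree with proportional synapse allocation."""
    if L_0 <= 0:
        raise ValueError("trunk length must be positive")
    if not 0 < r < 1:
        raise ValueError("scaling factor must lie in (0, 1)")
    if n_levels < 1 or n_synapses < n_levels:
        raise ValueError("need n_levels >= 1 and n_synapses >= n_levels")
    return DendriticTree(L_0, r, n_levels, n_synapses, dendritic_speed)


def tree_fractal_dimension(N: int, r: float) -> float:
    """Self-similarity dimension log(N)/log(1/r) of an N-fold branching tree."""
    if N < 2:
        raise ValueError("branch multiplicity must be >= 2")
    if not 0 < r < 1:
        raise ValueError("scaling ratio must lie in (0, 1)")
    return math.log(N) / math.log(1.0 / r)


@dataclass
class PeripheralNeuron:
    id: int
    position: np.ndarray         # mm, 3D
    axonal_speed: float          # mm/ms
    synaptic_delay: float        # ms

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(self.position))

    @property
    def T_external(self) -> float:
        return 2.0 * self.distance / self.axonal_speed + self.synaptic_delay


@dataclass
class NetworkTrajectory:
    soma_delay: float
    coincidence_window: float
    tree: DendriticTree
    connections: pd.DataFrame
    events: pd.DataFrame
    fire_times: np.ndarray
    occupancy: np.ndarray        # per-cycle cumulative connection count
    arrival_times: np.ndarray    # every EPSP arrival at the soma (ms)
    arrival_levels: np.ndarray
    complete: bool
    cycles_used: int
    anchor_T: float              # emergent common loop time (ms)

    def branch_event_times(self) -> dict[int, np.ndarray]:
        """Arrival times grouped by branch level (connected + probing)."""
        return {
            lvl: self.arrival_times[self.arrival_levels == lvl]
            for lvl in range(1, self.tree.n_levels + 1)
        }

    def oscillation_frequency(self) -> float:
        """Reciprocal of the median inter-fire interval (kHz -> Hz).

        The first quarter of fire events is discarded as the transient
        fluctuation phase.
        """
        ft = self.fire_times
        if ft.size < 4:
            return np.nan
        ft = ft[ft.size // 4:]
        period = float(np.median(np.diff(ft)))
        return 1000.0 / period if period > 0 else np.nan


# ---------------------------------------------------------------------------
# coincidence detection
# ---------------------------------------------------------------------------

def detect_coincidences(arrivals, window: float, branch_preference: bool = False):
    """Greedy earliest-first grouping of near-simultaneous arrivals.

    ``arrivals`` is a sequence of ``(time_ms, branch_level, peripheral_id)``.
    A group collects all unassigned arrivals within ``window`` of its
    earliest member (so pairwise spacing <= window), keeping at most one
    arrival per peripheral (the earliest).  With ``branch_preference`` a
    group must span at least two distinct branch levels; failing anchors are
    consumed, their companions released.  Ties break on (time, level, id).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    items = sorted(arrivals, key=lambda a: (a[0], a[1], a[2]))
    used = [False] * len(items)
    groups = []
    i = 0
    while i < len(items):
        if used[i]:
            i += 1
            continue
        t0 = items[i][0]
        members = []
        seen_pids = set()
        idxs = []
        for j in range(i, len(items)):
            if used[j]:
                continue
            if items[j][0] - t0 > window:
                break
            if items[j][2] in seen_pids:
                continue
            members.append(items[j])
            seen_pids.add(items[j][2])
            idxs.append(j)
        ok = len(members) >= 2
        if ok and branch_preference:
            ok = len({m[1] for m in members}) >= 2
        if ok:
            for j in idxs:
                used[j] = True
            groups.append(members)
        else:
            used[i] = True  # consume the anchor, release companions
        i += 1
    return groups


# ---------------------------------------------------------------------------
# network growth
# ---------------------------------------------------------------------------

def _sample_peripherals(n, next_id, timing, rng):
    lo, hi = timing.distance_range_mm
    d = rng.uniform(lo, hi, size=n)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return [
        PeripheralNeuron(next_id + i, d[i] * v[i], timing.axonal_speed,
                         timing.synaptic_delay_ms)
        for i in range(n)
    ]


def grow_network(
    tree: DendriticTree,
    timing: TimingConfig,
    peripherals_per_cycle: int = 20,
    rng: np.random.Generator | None = None,
    max_cycles: int = 300,
    branch_preference: bool = False,
    seeded_peripherals: list[PeripheralNeuron] | None = None,
    stop_on_complete: bool = True,
) -> NetworkTrajectory:
    """Grow a recurrent network by coincidence-based synaptic selection.

    Each firing cycle: the core neuron fires, every established loop echoes
    back after its round-trip time, a fresh cohort of random peripherals
    probes all branch levels with free slots, and coincidence groups fix new
    permanent connections.  The first cycle has no rhythm to lock onto; the
    group closest to the median candidate arrival time seeds it (the
    transient fluctuation phase), after which only groups anchored by a
    returning established signal are consolidated.

    ``seeded_peripherals`` are injected into cycle 1 (used by connectivity
    cloning); their coincidences are consolidated like any others.
    """
    if peripherals_per_cycle < 1:
        raise ValueError("peripherals_per_cycle must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    window = timing.window_ms
    free = tree.slots.copy()
    next_slot = np.zeros(tree.n_levels, dtype=int)

    conns: list[dict] = []
    conn_T_total: list[float] = []
    conn_level: list[int] = []
    conn_pid: list[int] = []
    events: list[dict] = []
    fire_times: list[float] = []
    occupancy: list[int] = []
    arr_t: list[float] = []
    arr_l: list[int] = []

    t_fire = 0.0
    next_id = 0
    anchor_T = np.nan
    complete = False
    cycle = 0

    for cycle in range(1, max_cycles + 1):
        if free.sum() > 0:
            fresh = _sample_peripherals(peripherals_per_cycle, next_id, timing,
                                        rng)
            next_id += peripherals_per_cycle
        else:
            fresh = []  # fully wired: the loop oscillation continues alone
        if cycle == 1 and seeded_peripherals:
            fresh = list(seeded_peripherals) + fresh

        # candidate arrivals: each probing peripheral reaches every level
        # that still has a free synapse slot
        cand = []
        cand_by_pid = {}
        for p in fresh:
            for lvl in range(1, tree.n_levels + 1):
                if free[lvl - 1] <= 0:
                    continue
                t = t_fire + p.T_external + tree.T_internal[lvl - 1]
                cand.append((t, lvl, p.id))
            cand_by_pid[p.id] = p
        est = [
            (t_fire + conn_T_total[i], conn_level[i], conn_pid[i])
            for i in range(len(conns))
        ]
        est_pids = set(conn_pid)

        groups = detect_coincidences(cand + est, window, branch_preference)
        if not groups and not conns:
            break  # nothing to seed the rhythm with

        if not conns:
            cand_times = np.array([c[0] for c in cand])
            med = float(np.median(cand_times))
            groups = sorted(
                groups, key=lambda g: abs(np.mean([m[0] for m in g]) - med)
            )
            fixable = groups[:1]
        else:
            # the somatic spike is triggered by the strongest coincidence:
            # the group carrying the most returning loop signals. Only its
            # members consolidate, so the emergent loop time stays sharp.
            anchored = [g for g in groups
                        if any(m[2] in est_pids for m in g)]
            anchored.sort(key=lambda g: (-sum(m[2] in est_pids for m in g),
                                         g[0][0]))
            fixable = anchored[:1]

        t_coin = None
        for g in fixable:
            gt = float(np.mean([m[0] for m in g]))
            if t_coin is None or gt < t_coin:
                t_coin = gt
            events.append({"time_ms": gt, "event_type": "coincidence",
                           "peripheral_id": -1, "branch_level": -1, "slot": -1})
            for (t, lvl, pid) in g:
                if pid in est_pids or pid not in cand_by_pid:
                    continue
                if free[lvl - 1] <= 0:
                    continue
                p = cand_by_pid.pop(pid)
                slot = int(next_slot[lvl - 1])
                next_slot[lvl - 1] += 1
                free[lvl - 1] -= 1
                T_int = float(tree.T_internal[lvl - 1])
                T_ext = p.T_external
                conns.append({
                    "peripheral_id": pid, "branch_level": lvl, "slot": slot,
                    "T_internal": T_int, "T_external": T_ext,
                    "T_total": T_int + T_ext, "distance_mm": p.distance,
                    "cycle": cycle,
                    "px": p.position[0], "py": p.position[1], "pz": p.position[2],
                })
                conn_T_total.append(T_int + T_ext)
                conn_level.append(lvl)
                conn_pid.append(pid)
                est_pids.add(pid)
                events.append({"time_ms": t, "event_type": "connection_fixed",
                               "peripheral_id": pid, "branch_level": lvl,
                               "slot": slot})

        # branch-window event stream for integration analysis: arrival
        # times AT the branch (soma arrivals are coincident by design, so
        # the level-specific structure lives upstream of the dendritic
        # conduction delay)
        for (t, lvl, pid) in est:
            arr_t.append(t - tree.T_internal[lvl - 1])
            arr_l.append(lvl)
        for (t, lvl, pid) in cand:
            arr_t.append(t - tree.T_internal[lvl - 1])
            arr_l.append(lvl)

        occupancy.append(len(conns))
        if t_coin is None:
            if len(conns) >= 2:
                # loop echoes alone sustain the rhythm
                t_coin = t_fire + float(np.median(conn_T_total))
            else:
                break  # stalled: a single loop found no partner
        if np.isnan(anchor_T):
            anchor_T = t_coin - t_fire
        t_fire = t_coin + timing.soma_delay_ms
        fire_times.append(t_fire)
        events.append({"time_ms": t_fire, "event_type": "N0_fire",
                       "peripheral_id": -1, "branch_level": -1, "slot": -1})
        if free.sum() == 0:
            complete = True
            if stop_on_complete:
                break

    conn_df = pd.DataFrame(conns) if conns else pd.DataFrame(
        columns=["peripheral_id", "branch_level", "slot", "T_internal",
                 "T_external", "T_total", "distance_mm", "cycle",
                 "px", "py", "pz"])
    ev_df = pd.DataFrame(events).sort_values("time_ms", kind="stable") if events \
        else pd.DataFrame(columns=["time_ms", "event_type", "peripheral_id",
                                   "branch_level", "slot"])
    return NetworkTrajectory(
        soma_delay=timing.soma_delay_ms,
        coincidence_window=window,
        tree=tree,
        connections=conn_df,
        events=ev_df.reset_index(drop=True),
        fire_times=np.asarray(fire_times),
        occupancy=np.asarray(occupancy),
        arrival_times=np.asarray(arr_t),
        arrival_levels=np.asarray(arr_l, dtype=int),
        complete=complete,
        cycles_used=cycle,
        anchor_T=anchor_T,
    )


# ---------------------------------------------------------------------------
# timing-rule audit
# ---------------------------------------------------------------------------

@dataclass
class TimingReport:
    n_connections: int
    pearson_r: float
    cv_T_total: float
    per_level: pd.DataFrame
    insufficient: bool = False


def verify_timing_rule(traj: NetworkTrajectory) -> TimingReport:
    """Audit the emergent inverse internal/external timing relationship."""
    c = traj.connections
    if len(c) < 3:
        return TimingReport(len(c), np.nan, np.nan, pd.DataFrame(),
                            insufficient=True)
    ti = c["T_internal"].to_numpy()
    te = c["T_external"].to_numpy()
    tt = c["T_total"].to_numpy()
    r = float(np.corrcoef(ti, te)[0, 1]) if np.std(ti) > 0 and np.std(te) > 0 \
        else np.nan
    cv = float(np.std(tt) / np.mean(tt))
    per_level = (
        c.groupby("branch_level")
        .agg(mean_distance_mm=("distance_mm", "mean"),
             std_distance_mm=("distance_mm", "std"),
             mean_T_external=("T_external", "mean"),
             n=("peripheral_id", "count"))
        .reset_index()
    )
    return TimingReport(len(c), r, cv, per_level)


# ---------------------------------------------------------------------------
# somatic-delay parameter sweep
# ---------------------------------------------------------------------------

def trajectory_phi_series(traj: NetworkTrajectory, grain: float = 2.0,
                          window_cycles: int = 10) -> np.ndarray:
    """One phi_dyn value per firing cycle of a grown network.

    For each core-neuron firing, the branch-level arrival stream of the last
    ``window_cycles`` oscillation periods is binned at ``grain`` ms and the
    shift-nulled total correlation is computed over that window, normalized
    by (number of active levels - 1) so the value lies in [0, 1] regardless
    of tree depth.  Indexing the series by firing cycle (the simulation
    step) makes the somatic delay set the ratio between the fixed temporal
    grain and the network's own timescale, which is what the delay sweep
    profiles.
    """
    period = traj.anchor_T + traj.soma_delay
    if not np.isfinite(period) or period <= 0 or traj.fire_times.size == 0:
        return np.empty(0)
    span = window_cycles * period
    nb = int(np.ceil(span / grain))
    bt = traj.branch_event_times()
    phis = np.zeros(traj.fire_times.size)
    for i, tf in enumerate(traj.fire_times):
        sel = {l: t[(t >= tf - span) & (t <= tf)] for l, t in bt.items()}
        sel = {l: t for l, t in sel.items() if t.size}
        if len(sel) < 2:
            continue
        res = phi_dyn(sel, grain=grain, window=nb)
        if res.phi.size:
            phis[i] = float(res.phi[0]) / (len(sel) - 1)
    return phis


def run_delay_sweep(
    delays,
    reps: int = 5,
    seed: int = 0,
    tree_kwargs: dict | None = None,
    timing_kwargs: dict | None = None,
    peripherals_per_cycle: int = 20,
    max_cycles: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grow one network per (delay, rep) and profile its phi_dyn series.

    Returns ``(per_run, aggregate)`` tables: per-run volatility, prediction
    error, lag-1 autocorrelation, fractal metrics and mean phi; aggregate
    mean +/- sd per delay.
    """
    delays = list(delays)
    if any(d <= 0 or d > 50 for d in delays):
        raise ValueError("delays must lie in (0, 50] ms")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    for d in delays:
        for k in range(reps):
            rng = named_rng(seed, "delay_sweep", f"d{d}", f"rep{k}")
            tree = build_tree(**(tree_kwargs or {"L_0": 100.0, "r": 0.6,
                                                 "n_levels": 4,
                                                 "n_synapses": 1000}))
            timing = TimingConfig(soma_delay_ms=float(d),
                                  **(timing_kwargs or {}))
            traj = grow_network(tree, timing, peripherals_per_cycle, rng,
                                max_cycles=max_cycles, stop_on_complete=False)
            phi = trajectory_phi_series(traj)
            row = {"delay_ms": d, "rep": k, "complete": traj.complete,
                   "n_connections": len(traj.connections),
                   "phi_mean": float(np.mean(phi)) if phi.size else np.nan}
            if phi.size >= 3:
                pm = predictability_metrics(phi)
                row.update(volatility=pm.volatility,
                           prediction_error=pm.prediction_error,
                           lag1_autocorr=pm.lag1_autocorr)
            if phi.size >= 128:
                fm = fractal_measures(phi)
                row.update(box_fd=fm.box_fd, higuchi_fd=fm.higuchi_fd,
                           dfa_alpha=fm.dfa_alpha)
            rows.append(row)
    per_run = pd.DataFrame(rows)
    aggregate = (
        per_run.groupby("delay_ms")
        .agg(["mean", "std"])
        .drop(columns=["rep"], level=0)
    )
    return per_run, aggregate
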