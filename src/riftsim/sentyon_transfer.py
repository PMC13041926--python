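"""Connectivity cloning between core neurons (sentyon transfer).

Method 1 (external position copying) replicates the 3-D positions of every
peripheral neuron connected to the source core neuron; in the target these
copies re-establish their recurrent loops through ordinary coincidence
detection (their loop delays still align), after which growth may continue
with the target's own somatic delay and fresh random peripherals.

Method 2 (synaptic position copying) transfers no neurons: it reserves the
source's branch-level synapse slots, each stamped with the source
connection's loop time, entrains the target to the source rhythm, and lets
fresh random peripherals claim a reserved slot only when their arrival
matches both the rhythm and the slot's recorded timing.  Fewer connections
form, but they inherit the source's branch-level proportions - the EPSP
amplitude signature that programs the somatic multifractal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dendrite_network import (
    DendriticTree,
    NetworkTrajectory,
    TimingConfig,
    PeripheralNeuron,
    _sample_peripherals,
    build_tree,
    detect_coincidences,
    grow_network,
)

__all__ = ["CloneResult", "TransferReport", "clone_network",
           "transfer_fidelity", "epsp_signature"]


@dataclass
class CloneResult:
    trajectory: NetworkTrajectory
    method: int
    n_copied: int            # copied peripherals (M1) or reserved slots (M2)
    n_fixed_copies: int      # of those, how many got wired in the target
    utilization_pct: float


@dataclass
class TransferReport:
    method: int
    source_connections: int
    target_connections: int
    utilization_pct: float
    similarity_pct: float
    source_frequency_hz: float
    target_frequency_hz: float
    degenerate: bool = False


def epsp_signature(traj: NetworkTrajectory) -> np.ndarray:
    """Amplitude-weighted branch-level connection histogram, normalized.

    Level counts are weighted by the EPSP amplitude hierarchy
    ``A_0 * r**(level-1)`` (the quantity that programs the multifractal).
    """
    tree = traj.tree
    counts = np.zeros(tree.n_levels)
    if len(traj.connections):
        vc = traj.connections["branch_level"].value_counts()
        for lvl, n in vc.items():
            counts[lvl - 1] = n
    weights = tree.scaling_factor ** np.arange(tree.n_levels)
    sig = counts * weights
    return sig / sig.sum() if sig.sum() > 0 else sig


def _finish_trajectory(tree, timing, conns, fire_times, cycles, anchor_T,
                       complete):
    conn_df = pd.DataFrame(conns) if conns else pd.DataFrame(
        columns=["peripheral_id", "branch_level", "slot", "T_internal",
                 "T_external", "T_total", "distance_mm", "cycle",
                 "px", "py", "pz"])
    empty_ev = pd.DataFrame(columns=["time_ms", "event_type", "peripheral_id",
                                     "branch_level", "slot"])
    return NetworkTrajectory(
        soma_delay=timing.soma_delay_ms, coincidence_window=timing.window_ms,
        tree=tree, connections=conn_df, events=empty_ev,
        fire_times=np.asarray(fire_times),
        occupancy=np.asarray([len(conns)]),
        arrival_times=np.empty(0), arrival_levels=np.empty(0, dtype=int),
        complete=complete, cycles_used=cycles, anchor_T=anchor_T,
    )


def _conn_row(p: PeripheralNeuron, lvl: int, slot: int, tree, cycle: int):
    T_int = float(tree.T_internal[lvl - 1])
    return {
        "peripheral_id": p.id, "branch_level": lvl, "slot": slot,
        "T_internal": T_int, "T_external": p.T_external,
        "T_total": T_int + p.T_external, "distance_mm": p.distance,
        "cycle": cycle, "px": p.position[0], "py": p.position[1],
        "pz": p.position[2],
    }


def clone_network(
    source: NetworkTrajectory,
    method: int,
    target_timing: TimingConfig | None = None,
    rng: np.random.Generator | None = None,
    tree_params: dict | None = None,
    continue_growth: bool = True,
    peripherals_per_cycle: int = 20,
) -> CloneResult:
    """Clone the source network's connectivity onto a fresh target neuron."""
    if method not in (1, 2):
        raise ValueError("method must be 1 or 2")
    if len(source.connections) == 0:
        raise ValueError("source network has no connections to clone")
    rng = rng if rng is not None else np.random.default_rng()
    src_tree = source.tree
    tree = build_tree(**(tree_params or dict(
        L_0=src_tree.trunk_length, r=src_tree.scaling_factor,
        n_levels=src_tree.n_levels, n_synapses=src_tree.n_synapses,
        dendritic_speed=src_tree.dendritic_speed)))
    if tree.n_levels != src_tree.n_levels:
        raise ValueError("incompatible trees: level counts differ")
    timing = target_timing if target_timing is not None else TimingConfig(
        soma_delay_ms=15.0)
    window = timing.window_ms
    sc = source.connections

    if method == 1:
        return _clone_positions(source, tree, timing, rng, continue_growth,
                                peripherals_per_cycle)

    # ---- Method 2: synaptic position copying -----------------------------
    reserved = list(zip(sc["branch_level"].astype(int), sc["T_total"]))
    n_reserved = len(reserved)
    # target entrained by the source's established rhythm: the median loop
    # time of its consolidated connections
    anchor = float(np.median(sc["T_total"]))
    conns, fire_times = [], []
    t_fire = 0.0
    next_id = 0
    # equal wall-clock experience: the target's longer period means fewer
    # firing cycles within the source's growth duration, after which the
    # reserved slots expire
    period_src = anchor + source.soma_delay
    period_tgt = anchor + timing.soma_delay_ms
    budget = max(int(round(source.cycles_used * period_src / period_tgt)), 1)
    for cycle in range(1, budget + 1):
        if not reserved:
            break
        fresh = _sample_peripherals(peripherals_per_cycle, next_id, timing,
                                    rng)
        next_id += peripherals_per_cycle
        for p in fresh:
            if not reserved:
                break
            # each random axon contacts one vacant reserved synaptic
            # position; coincidence detection against that position's
            # recorded loop time decides whether the contact stabilizes
            j = int(rng.integers(len(reserved)))
            lvl, slot_time = reserved[j]
            tt = p.T_external + tree.T_internal[lvl - 1]
            if abs(tt - slot_time) <= window / 2.0:
                reserved.pop(j)
                conns.append(_conn_row(p, lvl,
                                       n_reserved - len(reserved) - 1,
                                       tree, cycle))
        # the target fires entrained to the source rhythm carried by the
        # transferred seed pattern
        t_fire += anchor + source.soma_delay
        fire_times.append(t_fire)
        if not reserved:
            break
    traj = _finish_trajectory(tree, timing, conns, fire_times, cycle,
                              anchor, complete=False)
    util = 100.0 * len(conns) / n_reserved
    return CloneResult(traj, 2, n_reserved, len(conns), util)


def _clone_positions(source, tree, timing, rng, continue_growth,
                     peripherals_per_cycle):
    """Method 1: re-wire copied peripherals, then optionally keep growing."""
    sc = source.connections
    window = timing.window_ms
    copies = [
        PeripheralNeuron(i, np.array([r.px, r.py, r.pz]),
                         timing.axonal_speed, timing.synaptic_delay_ms)
        for i, r in enumerate(sc.itertuples(index=False))
    ]
    levels = sc["branch_level"].to_numpy()
    arrivals = [
        (copies[i].T_external + tree.T_internal[levels[i] - 1],
         int(levels[i]), i)
        for i in range(len(copies))
    ]
    groups = detect_coincidences(arrivals, window)
    free = tree.slots.copy()
    next_slot = np.zeros(tree.n_levels, dtype=int)
    conns = []
    fixed_ids = set()
    for g in groups:
        for (t, lvl, pid) in g:
            if free[lvl - 1] <= 0 or pid in fixed_ids:
                continue
            conns.append(_conn_row(copies[pid], lvl, int(next_slot[lvl - 1]),
                                   tree, 1))
            next_slot[lvl - 1] += 1
            free[lvl - 1] -= 1
            fixed_ids.add(pid)
    n_fixed = len(fixed_ids)
    anchor = float(np.median([c["T_total"] for c in conns])) if conns \
        else np.nan
    if continue_growth and conns:
        extra = grow_network(
            tree, timing, peripherals_per_cycle, rng,
            max_cycles=source.cycles_used,
            seeded_peripherals=None, stop_on_complete=True,
        )
        # splice: keep copied connections, append the newly grown ones that
        # respect the copied rhythm and remaining capacity
        grown = extra.connections
        keep = grown[np.abs(grown["T_total"] - anchor) <= window]
        seen_slots = {lvl: int(next_slot[lvl - 1])
                      for lvl in range(1, tree.n_levels + 1)}
        for row in keep.itertuples(index=False):
            lvl = int(row.branch_level)
            if free[lvl - 1] <= 0:
                continue
            d = dict(row._asdict())
            d["peripheral_id"] = 10_000_000 + int(row.peripheral_id)
            d["slot"] = seen_slots[lvl]
            seen_slots[lvl] += 1
            free[lvl - 1] -= 1
            conns.append(d)
        cycles = extra.cycles_used
    else:
        cycles = 1
    # entrained rhythm: the source's oscillation drives the target
    period = anchor + source.soma_delay if conns else np.nan
    fire_times = [period * (k + 1) for k in range(max(cycles, 20))] \
        if conns else []
    traj = _finish_trajectory(tree, timing, conns, fire_times, cycles,
                              anchor, complete=bool((free == 0).all()))
    util = 100.0 * n_fixed / len(copies) if copies else 0.0
    return CloneResult(traj, 1, len(copies), n_fixed, util)


def transfer_fidelity(source: NetworkTrajectory,
                      clone: CloneResult) -> TransferReport:
    """Score a clone against its source network."""
    target = clone.trajectory
    if len(target.connections) == 0:
        return TransferReport(clone.method, len(source.connections), 0,
                              clone.utilization_pct, 0.0,
                              source.oscillation_frequency(), np.nan,
                              degenerate=True)
    hs = epsp_signature(source)
    ht = epsp_signature(target)
    similarity = 100.0 * (1.0 - 0.5 * float(np.abs(hs - ht).sum()))
    return TransferReport(
        method=clone.method,
        source_connections=len(source.connections),
        target_connections=len(target.connections),
        utilization_pct=clone.utilization_pct,
        similarity_pct=similarity,
        source_frequency_hz=source.oscillation_frequency(),
        target_frequency_hz=target.oscillation_frequency(),
    )
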