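"""Ising lipid membrane with embedded mobile ion channels.

The somatic membrane is a square lattice of binary lipid states (+1
channel-opening-associated, -1 inhibiting) evolving under Metropolis
dynamics, with ~4% of sites carrying mobile ion channels.  Branch-level
EPSP trains reach the membrane as level-dependent Gaussian kernel fields
that both depolarize channels directly and bias lipid reorganization; the
channels read the membrane state through a sigmoid opening probability

    P_open = S(E + lambda_lipid + C_coop),   S(x) = 1/(1+exp(-x)),

where ``lambda_lipid = 0.25 * gamma * <spin>_r3`` is the local lipid bias
within the 3-site influence radius and ``C_coop`` a small cooperative term
from nearby open channels.  Action potentials fire when channel-opening
activity in the center region crosses a threshold; they reset channel
positions but never the lipid field, which therefore accumulates pattern
memory across generational cycles.

Two acceptance rules are retained: the literal base rule
``P = exp(-dE * 0.5)`` (dE < 0 always accepted) and, when a spatial
temperature field is supplied, ``P = exp(-dE / T_local(x, y))``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve

from .integration_metrics import PhiStar, kl_phi_star

__all__ = [
    "LipidLattice",
    "MembraneTrajectory",
    "init_lattice",
    "epsp_spatial_field",
    "metropolis_step",
    "channel_update",
    "run_membrane_sim",
    "substrate_metrics",
    "boundary_box_fd",
    "refractory_steps_for",
]


def refractory_steps_for(consciousness_level: float) -> int:
    """Refractory duration in steps, int(consciousness_level * 25)."""
    if not 0.0 <= consciousness_level <= 1.0:
        raise ValueError("consciousness_level must lie in [0, 1]")
    return int(consciousness_level * 25)


def _disk_kernel(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    return (x * x + y * y <= r * r).astype(float)


@dataclass
class LipidLattice:
    spins: np.ndarray              # int8 field of +/-1
    channel_rc: np.ndarray         # (n_channels, 2) row/col sites
    channel_open: np.ndarray       # bool per channel
    temperature: float = 0.35
    gamma: float = 1.0             # lipid-channel coupling gain
    lam: float = 0.25              # lipid bias coefficient
    c_coop: float = 0.5            # cooperative coefficient
    influence_radius: int = 3
    mobility: float = 0.1

    @property
    def size(self) -> int:
        return self.spins.shape[0]

    @property
    def n_channels(self) -> int:
        return self.channel_rc.shape[0]

    def open_fraction(self) -> float:
        return float(self.channel_open.mean()) if self.n_channels else 0.0


def init_lattice(size: int = 100, channel_density: float = 0.04,
                 rng: np.random.Generator | None = None) -> LipidLattice:
    """Random +/-1 spins with channels at distinct random sites, all closed."""
    if size < 20:
        raise ValueError("lattice size must be >= 20")
    if not 0.0 < channel_density < 0.2:
        raise ValueError("channel density must lie in (0, 0.2)")
    n_channels = int(round(channel_density * size * size))
    if n_channels < 1:
        raise ValueError("density * size**2 must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    spins = rng.choice(np.array([-1, 1], dtype=np.int8), size=(size, size))
    flat = rng.choice(size * size, size=n_channels, replace=False)
    rc = np.column_stack(np.unravel_index(flat, (size, size)))
    return LipidLattice(spins, rc, np.zeros(n_channels, dtype=bool))


# ---------------------------------------------------------------------------
# EPSP spatial field
# ---------------------------------------------------------------------------

def _level_center(level: int, size: int) -> tuple[float, float]:
    c = (size - 1) / 2.0
    if level == 1:
        return c, c
    ang = np.deg2rad([0.0, 120.0, 240.0][(level - 2) % 3])
    rad = (level - 1) * size / 8.0
    return c + rad * np.sin(ang), c + rad * np.cos(ang)


def epsp_spatial_field(amplitudes, size: int) -> np.ndarray:
    """Sum of level Gaussian kernels, radius = size/4 - (level-1)*5.

    ``amplitudes`` maps level (1-based) -> current amplitude, or is a
    sequence indexed from level 1.
    """
    if isinstance(amplitudes, dict):
        items = sorted(amplitudes.items())
    else:
        items = list(enumerate(amplitudes, start=1))
    yy, xx = np.indices((size, size), dtype=float)
    out = np.zeros((size, size))
    for level, amp in items:
        radius = size / 4.0 - (level - 1) * 5.0
        if radius <= 0:
            raise ValueError(f"non-positive kernel radius at level {level}")
        if amp == 0:
            continue
        cy, cx = _level_center(level, size)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        out += amp * np.exp(-d2 / (2.0 * radius * radius))
    return out


# ---------------------------------------------------------------------------
# Metropolis lipid dynamics
# ---------------------------------------------------------------------------

def metropolis_step(
    lattice: LipidLattice,
    temperature_field: np.ndarray | None = None,
    site_fraction: float = 0.05,
    rng: np.random.Generator | None = None,
    external_field: np.ndarray | None = None,
    flip_accum: np.ndarray | None = None,
) -> LipidLattice:
    """Sequentially update a random 5% of sites (in place).

    Flip energy is ``dE = 2 * s * (sum of 4 periodic neighbours + h)`` with
    ``h`` the optional external (EPSP) field at the site.  Acceptance is the
    literal base rule ``min(1, exp(-dE * 0.5))`` or, with a temperature
    field, ``min(1, exp(-dE / T_local))``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    s = lattice.spins
    n = s.shape[0]
    if temperature_field is not None:
        tf = np.asarray(temperature_field, dtype=float)
        if np.any(tf <= 0):
            raise ValueError("temperature field must be strictly positive")
    n_sites = int(site_fraction * n * n)
    rows = rng.integers(0, n, size=n_sites)
    cols = rng.integers(0, n, size=n_sites)
    us = rng.random(n_sites)
    h = external_field
    for i in range(n_sites):
        r, c = int(rows[i]), int(cols[i])
        nb = (int(s[(r - 1) % n, c]) + int(s[(r + 1) % n, c])
              + int(s[r, (c - 1) % n]) + int(s[r, (c + 1) % n]))
        loc = nb + (h[r, c] if h is not None else 0.0)
        dE = 2.0 * s[r, c] * loc
        if temperature_field is None:
            acc = 1.0 if dE < 0 else np.exp(-dE * 0.5)
        else:
            acc = 1.0 if dE < 0 else np.exp(-dE / tf[r, c])
        if us[i] < acc:
            s[r, c] = -s[r, c]
            if flip_accum is not None:
                flip_accum[r, c] += 1.0
    return lattice


# ---------------------------------------------------------------------------
# channel gating and motion
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def channel_update(
    lattice: LipidLattice,
    field: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Resample channel open states and move channels; returns P_open used.

    The lipid bias and cooperative terms both average over the channel's
    3-site influence radius; the cooperative term is the open-channel site
    fraction in that disk so it stays a small logit correction.
    """
    if field.shape != lattice.spins.shape:
        raise ValueError("field and lattice sizes differ")
    rng = rng if rng is not None else np.random.default_rng()
    n = lattice.size
    disk = _disk_kernel(lattice.influence_radius)
    disk_n = disk.sum()
    mean_spin = convolve(lattice.spins.astype(float), disk, mode="wrap") / disk_n
    open_map = np.zeros((n, n))
    oc = lattice.channel_rc[lattice.channel_open]
    open_map[oc[:, 0], oc[:, 1]] = 1.0
    open_frac = convolve(open_map, disk, mode="wrap") / disk_n

    r, c = lattice.channel_rc[:, 0], lattice.channel_rc[:, 1]
    logit = (field[r, c]
             + lattice.lam * lattice.gamma * mean_spin[r, c]
             + lattice.c_coop * open_frac[r, c])
    p_open = _sigmoid(logit)
    lattice.channel_open = rng.random(p_open.size) < p_open

    # mobility: each channel tries one random 4-neighbour move
    occupied = set(map(tuple, lattice.channel_rc))
    moves = rng.random(lattice.n_channels) < lattice.mobility
    steps = rng.integers(0, 4, size=lattice.n_channels)
    retry = rng.integers(0, 4, size=lattice.n_channels)
    offs = np.array([(1, 0), (-1, 0), (0, 1), (0, -1)])
    for i in np.nonzero(moves)[0]:
        for choice in (steps[i], retry[i]):
            nr = int(np.clip(lattice.channel_rc[i, 0] + offs[choice][0], 0, n - 1))
            nc = int(np.clip(lattice.channel_rc[i, 1] + offs[choice][1], 0, n - 1))
            if (nr, nc) not in occupied:
                occupied.discard(tuple(lattice.channel_rc[i]))
                lattice.channel_rc[i] = (nr, nc)
                occupied.add((nr, nc))
                break
    return p_open


# ---------------------------------------------------------------------------
# full membrane simulation
# ---------------------------------------------------------------------------

@dataclass
class MembraneTrajectory:
    mode: str
    summary: pd.DataFrame
    spin_snapshots: list          # (step, int8 array) pairs
    open_event_map: np.ndarray    # per-site channel opening counts
    lipid_occupancy: np.ndarray   # time-averaged (spin+1)/2 map
    ap_steps: np.ndarray
    contribution_fractions: dict  # epsp / channel / lipid shares
    consciousness_level: float
    refractory_steps: int
    lattice: LipidLattice
    seeds: list = field(default_factory=list)
    lipid_coarse: np.ndarray | None = None    # (T, k, k) per-step block means
    channel_coarse: np.ndarray | None = None  # (T, k, k) open-channel counts
    flip_map: np.ndarray | None = None        # accepted lipid flips per site


def _burst_amplitudes(t_since: float, n_levels: int = 4, A_0: float = 2.3,
                      r: float = 0.6) -> dict[int, float]:
    """Per-level EPSP amplitudes for a burst started ``t_since`` ms ago."""
    from .gfm_multifractal import _unit_kernel, TAU_RISE, TAU_DECAY
    t = np.array([t_since - e for e in (0.0, 2.0, 4.0)])
    g = _unit_kernel(t, TAU_RISE, TAU_DECAY).sum()
    return {lvl: A_0 * r ** (lvl - 1) * g for lvl in range(1, n_levels + 1)}


def run_membrane_sim(
    mode: str = "blocked",
    consciousness_level: float = 0.5,
    threshold: float = 30.0,
    n_steps: int = 100,
    rng: np.random.Generator | None = None,
    size: int = 100,
    channel_density: float = 0.04,
    gamma: float = 1.0,
    temperature_field: np.ndarray | None = None,
    field_coupling: float = 1.0,
    burst_period: int = 15,
    snapshot_every: int = 5,
    dt_ms: float = 1.0,
) -> MembraneTrajectory:
    """Run the lipid-channel membrane for ``n_steps`` Monte-Carlo steps.

    ``mode='blocked'`` suppresses the EPSP field during refractory periods
    (autonomous lipid evolution between firings); ``mode='continuous'``
    keeps it on throughout.  Action potentials redistribute channel
    positions and log a peripheral seed record; the lipid field is never
    reset.
    """
    if mode not in ("continuous", "blocked"):
        raise ValueError("mode must be 'continuous' or 'blocked'")
    if not 20.0 <= threshold <= 60.0:
        raise ValueError("threshold must lie in [20, 60]")
    refr_steps = refractory_steps_for(consciousness_level)
    if n_steps < refr_steps:
        raise ValueError("n_steps must cover at least one refractory period")
    rng = rng if rng is not None else np.random.default_rng()
    lat = init_lattice(size, channel_density, rng)
    lat.gamma = gamma

    c0 = size // 2 - size // 10
    c1 = size // 2 + size // 10
    center = (slice(c0, c1), slice(c0, c1))
    center_mask = np.zeros((size, size), dtype=bool)
    center_mask[center] = True

    open_event_map = np.zeros((size, size))
    lipid_occupancy = np.zeros((size, size))
    flip_map = np.zeros((size, size))
    recent_openings: deque[float] = deque(maxlen=5)
    rows, snapshots, ap_steps, seeds = [], [], [], []
    contrib = {"epsp": 0.0, "channel": 0.0, "lipid": 0.0}
    refractory = 0
    burst_start = 0

    disk = _disk_kernel(lat.influence_radius)
    block = max(size // 20, 1)
    kc = size // block
    lipid_coarse = np.zeros((n_steps, kc, kc), dtype=np.float32)
    channel_coarse = np.zeros((n_steps, kc, kc), dtype=np.float32)

    for step in range(n_steps):
        in_refractory = refractory > 0
        blocked_now = (mode == "blocked") and in_refractory
        if blocked_now:
            amps = {lvl: 0.0 for lvl in range(1, 5)}
        else:
            if step - burst_start >= burst_period:
                burst_start = step
            amps = _burst_amplitudes((step - burst_start) * dt_ms)
        E = epsp_spatial_field(amps, size)

        # channel readout of field + lipid state
        mean_spin = convolve(lat.spins.astype(float), disk, mode="wrap") / disk.sum()
        prev_states = lat.channel_open.copy()
        prev_rc = lat.channel_rc.copy()
        channel_update(lat, E, rng)
        newly_open = lat.channel_open & ~prev_states
        rc_open = prev_rc[newly_open]
        np.add.at(open_event_map, (rc_open[:, 0], rc_open[:, 1]), 1.0)
        # center activity: open-channel occupancy accumulated over the
        # 5-step window (the membrane's short integration memory)
        rc_now = lat.channel_rc[lat.channel_open]
        recent_openings.append(int(center_mask[rc_now[:, 0], rc_now[:, 1]].sum()))
        activity = float(sum(recent_openings))

        # lipid dynamics biased by the EPSP field
        metropolis_step(lat, temperature_field, 0.05, rng,
                        external_field=field_coupling * E if np.any(E) else None,
                        flip_accum=flip_map)
        lipid_occupancy += (lat.spins + 1) / 2.0

        # substrate attribution at center channels, accumulated over
        # refractory periods (finite logit decomposition)
        if in_refractory:
            ch_center = center_mask[prev_rc[:, 0], prev_rc[:, 1]]
            if np.any(ch_center):
                r_, c_ = prev_rc[ch_center, 0], prev_rc[ch_center, 1]
                contrib["epsp"] += float(np.abs(E[r_, c_]).mean())
                contrib["lipid"] += float(
                    np.abs(lat.lam * lat.gamma * mean_spin[r_, c_]).mean())
                open_map = np.zeros((size, size))
                os_ = prev_rc[prev_states]
                open_map[os_[:, 0], os_[:, 1]] = 1.0
                of = convolve(open_map, disk, mode="wrap") / disk.sum()
                contrib["channel"] += float(
                    np.abs(lat.c_coop * of[r_, c_]).mean())

        ap = False
        if activity > threshold and not in_refractory:
            ap = True
            ap_steps.append(step)
            refractory = refr_steps
            # seed record: peripheral quadrant of the lipid pattern
            from .gfm_multifractal import extract_seed
            _seed, quad = extract_seed((lat.spins + 1) / 2.0)
            seeds.append({"step": step, "quadrant": quad})
            # channel positions reset; lipid field untouched
            flat = rng.choice(size * size, size=lat.n_channels, replace=False)
            lat.channel_rc = np.column_stack(np.unravel_index(flat, (size, size)))
        elif in_refractory:
            refractory -= 1

        rc_all = lat.channel_rc
        local_spin = mean_spin[rc_all[:, 0], rc_all[:, 1]]
        # lipid-channel state agreement: channels open on locally positive
        # (opening-promoting) lipid or closed on locally negative lipid
        agree = float(np.mean(lat.channel_open == (local_spin > 0)))
        if np.any(lat.channel_open):
            agree_open = float(np.mean(local_spin[lat.channel_open] > 0))
        else:
            agree_open = np.nan
        rows.append({
            "step": step, "center_activity": activity, "ap": ap,
            "open_fraction": lat.open_fraction(),
            "mean_spin": float(lat.spins.mean()),
            "refractory": in_refractory,
            "epsp_peak": max(amps.values()),
            "lipid_channel_agreement": agree,
            "open_lipid_agreement": agree_open,
        })
        if step % snapshot_every == 0 or step == n_steps - 1:
            snapshots.append((step, lat.spins.copy()))
        nb = kc * block
        occ01 = ((lat.spins[:nb, :nb] + 1) / 2.0).reshape(kc, block, kc, block)
        lipid_coarse[step] = occ01.mean(axis=(1, 3))
        ch_map = np.zeros((size, size), dtype=np.float32)
        ch_map[rc_now[:, 0], rc_now[:, 1]] = 1.0
        channel_coarse[step] = (
            ch_map[:nb, :nb].reshape(kc, block, kc, block).sum(axis=(1, 3)))

    tot = sum(contrib.values())
    fractions = {k: (v / tot if tot > 0 else np.nan) for k, v in contrib.items()}
    return MembraneTrajectory(
        mode=mode, summary=pd.DataFrame(rows), spin_snapshots=snapshots,
        open_event_map=open_event_map,
        lipid_occupancy=lipid_occupancy / n_steps,
        ap_steps=np.asarray(ap_steps),
        contribution_fractions=fractions,
        consciousness_level=consciousness_level,
        refractory_steps=refr_steps, lattice=lat, seeds=seeds,
        lipid_coarse=lipid_coarse, channel_coarse=channel_coarse,
        flip_map=flip_map,
    )


# ---------------------------------------------------------------------------
# substrate-partitioned metrics
# ---------------------------------------------------------------------------

def boundary_box_fd(spins: np.ndarray) -> float:
    """Box-counting dimension of the +1/-1 domain boundary set."""
    s = np.asarray(spins)
    n = s.shape[0]
    boundary = (
        (s != np.roll(s, 1, axis=0)) | (s != np.roll(s, -1, axis=0))
        | (s != np.roll(s, 1, axis=1)) | (s != np.roll(s, -1, axis=1))
    )
    if not boundary.any():
        return np.nan
    sizes = [b for b in (2, 4, 5, 10, 20, 25) if n % b == 0 and b < n]
    counts = []
    for b in sizes:
        blocks = boundary.reshape(n // b, b, n // b, b).any(axis=(1, 3))
        counts.append(blocks.sum())
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)),
                       np.log(counts), 1)[0]
    return float(slope)


def substrate_phi(activity_map: np.ndarray, n_events: float | None = None,
                  block: int = 2) -> PhiStar:
    """KL irreducibility of a substrate's reorganization-activity pattern.

    The substrate-isolated null carries no spatial preference, so phi* is
    the KL divergence of the (block-averaged) activity distribution from
    uniform - the pattern's spatial negentropy in bits.  For count-based
    maps, ``n_events`` enables a Miller-Madow-style correction that removes
    the multinomial sampling-noise floor ``(K-1)/(2 N ln 2)``.
    """
    a = np.asarray(activity_map, dtype=float)
    if a.sum() <= 0:
        return PhiStar(0.0, degenerate=True)
    n = (a.shape[0] // block) * block
    c = a[:n, :n].reshape(n // block, block, n // block, block).mean(axis=(1, 3))
    p = c.ravel() + 1e-12
    p = p / p.sum()
    K = p.size
    val = float((p * np.log2(p * K)).sum())
    if n_events:
        val -= (K - 1) / (2.0 * n_events * np.log(2))
    return PhiStar(max(val, 0.0))


@dataclass
class SubstrateMetrics:
    phi_star_lipid: float
    phi_star_channel: float
    lipid_fd_series: pd.DataFrame
    contribution_fractions: dict
    center_baseline_trend: float
    degenerate: bool = False


def substrate_metrics(traj: MembraneTrajectory) -> SubstrateMetrics:
    """phi* per molecular substrate plus fractal and baseline diagnostics.

    The lipid substrate's activity distribution is its accepted-flip
    (reorganization) map, the channel substrate's the per-site
    opening-event map; each is scored against its substrate-isolated
    uniform null by ``substrate_phi``.  The baseline trend is the slope of
    per-cycle minima of center activity.
    """
    if len(traj.summary) < 10:
        return SubstrateMetrics(0.0, 0.0, pd.DataFrame(), {}, np.nan,
                                degenerate=True)
    phi_l = substrate_phi(traj.flip_map, n_events=traj.flip_map.sum(),
                          block=2)
    # channel positions persist between repositioning events, so the
    # independent samples are position spells, not step-events; the coarser
    # block matches the channel map's sparser per-cell sampling density
    lat = traj.lattice
    n_steps = len(traj.summary)
    n_spells = lat.n_channels * (1 + len(traj.ap_steps)) \
        + int(lat.mobility * lat.n_channels * n_steps)
    phi_c = substrate_phi(traj.open_event_map, n_events=n_spells, block=5)
    fd_rows = [{"step": st, "lipid_fd": boundary_box_fd(sp)}
               for st, sp in traj.spin_snapshots]
    act = traj.summary["center_activity"].to_numpy()
    bounds = [0, *list(traj.ap_steps), len(act)]
    mins, mids = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= 2:
            mins.append(act[a:b].min())
            mids.append((a + b) / 2.0)
    trend = (float(np.polyfit(mids, mins, 1)[0])
             if len(mins) >= 3 else np.nan)
    return SubstrateMetrics(
        phi_star_lipid=phi_l.value, phi_star_channel=phi_c.value,
        lipid_fd_series=pd.DataFrame(fd_rows),
        contribution_fractions=traj.contribution_fractions,
        center_baseline_trend=trend,
        degenerate=phi_l.degenerate and phi_c.degenerate,
    )
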