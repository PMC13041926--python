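"""Generational fractal mapping on a theoretical somatic multifractal.

Branch-level EPSP trains (dual-exponential kernels, amplitude hierarchy
``A_0 * r**(i-1)``) are written onto a ``3**k`` square grid following a
nested Sierpinski-carpet rule: the level-``i`` amplitude is added uniformly
to every cell that survives ``i`` carpet subdivisions, so deeper levels
paint progressively finer, nested supports and the superposition is a
multifractal intensity field.

The GFM cycle then alternates autonomous growth (diffusive smoothing plus a
conservative transfer of intensity toward the central block) with
threshold-triggered collapse: when the center crosses the firing threshold,
an action potential is logged, the most information-rich peripheral
quadrant is extracted as a holographically compressed seed, and the next
generation starts as ``q * seed_expanded + (1-q) * fresh_epsp`` - a
weighted integration of compressed history with new input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.metrics import structural_similarity

from .integration_metrics import PhiStar, kl_phi_star

__all__ = [
    "EPSPTrain",
    "MultifractalGrid",
    "GFMTrajectory",
    "epsp_train",
    "epsp_peak_time",
    "map_epsp_to_grid",
    "extract_seed",
    "expand_seed",
    "run_gfm_cycle",
    "phi_star_multifractal",
    "whole_in_part_metrics",
    "gfm_total_information",
    "DefaultEPSPSource",
]

TAU_RISE = 0.3    # ms
TAU_DECAY = 4.0   # ms
QUADRANT_NAMES = ("NW", "NE", "SW", "SE")


# ---------------------------------------------------------------------------
# EPSP trains
# ---------------------------------------------------------------------------

def epsp_peak_time(tau_rise: float = TAU_RISE, tau_decay: float = TAU_DECAY) -> float:
    """Time to peak of the dual-exponential kernel (closed form)."""
    return tau_rise * tau_decay * math.log(tau_decay / tau_rise) / (tau_decay - tau_rise)


def _unit_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    g = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    tp = epsp_peak_time(tau_rise, tau_decay)
    peak = math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)
    return g / peak


@dataclass
class EPSPTrain:
    level: int
    A_0: float
    r: float
    event_times: np.ndarray
    tau_rise: float
    tau_decay: float
    times: np.ndarray      # ms sampling grid
    waveform: np.ndarray
    peaks: np.ndarray      # (time, amplitude) rows

    @property
    def amplitude(self) -> float:
        """Level amplitude A_0 * r**(level-1)."""
        return self.A_0 * self.r ** (self.level - 1)


def epsp_train(
    level: int,
    A_0: float = 0.15,
    r: float = 0.6,
    event_times=(0.0,),
    tau_rise: float = TAU_RISE,
    tau_decay: float = TAU_DECAY,
    dt: float = 0.05,
    duration: float | None = None,
) -> EPSPTrain:
    """Sampled branch-level EPSP train with unit-peak dual-exponential events."""
    if level < 1:
        raise ValueError("branch level must be >= 1")
    if A_0 <= 0:
        raise ValueError("base amplitude must be positive")
    if tau_decay <= tau_rise or tau_rise <= 0:
        raise ValueError("require tau_decay > tau_rise > 0")
    ev = np.sort(np.asarray(event_times, dtype=float))
    amp = A_0 * r ** (level - 1)
    if duration is None:
        duration = (ev.max() if ev.size else 0.0) + 8.0 * tau_decay
    t = np.arange(0.0, duration + dt, dt)
    wave = np.zeros_like(t)
    for e in ev:
        wave += amp * _unit_kernel(t - e, tau_rise, tau_decay)
    tp = epsp_peak_time(tau_rise, tau_decay)
    peaks = np.array([[e + tp, amp] for e in ev]) if ev.size else np.empty((0, 2))
    return EPSPTrain(level, A_0, r, ev, tau_rise, tau_decay, t, wave, peaks)


# ---------------------------------------------------------------------------
# Sierpinski-carpet mapping
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def carpet_depth_map(size: int) -> np.ndarray:
    """Per-cell carpet survival depth for a 3**k grid.

    ``depth[c] >= i`` iff the cell avoids the central ninth at every
    subdivision up to ``i``; the level-``i`` support is ``depth >= i``.
    """
    k = round(math.log(size, 3))
    if 3 ** k != size:
        raise ValueError("grid size must be a power of 3")
    idx = np.arange(size)
    depth = np.full((size, size), k, dtype=int)
    for i in range(1, k + 1):
        block = size // 3 ** i
        ti = (idx // block) % 3
        center = (ti[:, None] == 1) & (ti[None, :] == 1)
        depth = np.where(center & (depth >= i), i - 1, depth)
    return depth


@dataclass
class MultifractalGrid:
    intensity: np.ndarray
    depth_map: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return self.intensity.shape[0]

    @property
    def center_slice(self) -> tuple[slice, slice]:
        s = self.size // 3
        return slice(s, 2 * s), slice(s, 2 * s)

    @property
    def center_intensity(self) -> float:
        return float(self.intensity[self.center_slice].sum())

    def total(self) -> float:
        return float(self.intensity.sum())


def map_epsp_to_grid(trains, grid_size: int = 243,
                     total_intensity: float | None = None) -> MultifractalGrid:
    """Hierarchically assign per-level EPSP peak amplitude to carpet scales.

    The level-``i`` train's summed peak amplitude is added to every cell of
    carpet subdivision depth ``i``; levels superpose additively.  With
    ``total_intensity`` the result is rescaled to that fixed budget (the
    normalization used by the GFM cycle so the firing threshold has a
    stable meaning across generations).
    """
    depth = carpet_depth_map(grid_size)
    k = round(math.log(grid_size, 3))
    grid = np.zeros((grid_size, grid_size))
    for tr in trains:
        if tr.level > k:
            raise ValueError(
                f"level {tr.level} exceeds carpet subdivision depth {k}")
        amp = float(tr.peaks[:, 1].sum()) if tr.peaks.size else 0.0
        grid[depth >= tr.level] += amp
    if total_intensity is not None and grid.sum() > 0:
        grid *= total_intensity / grid.sum()
    return MultifractalGrid(grid, depth)


def _quadrants(a: np.ndarray) -> list[np.ndarray]:
    h, w = a.shape[0] // 2, a.shape[1] // 2
    return [a[:h, :w], a[:h, -w:], a[-h:, :w], a[-h:, -w:]]


def _shannon_entropy(p: np.ndarray) -> float:
    s = p.sum()
    if s <= 0:
        return 0.0
    q = (p / s).ravel()
    q = q[q > 0]
    return float(-(q * np.log2(q)).sum())


def extract_seed(grid: MultifractalGrid | np.ndarray):
    """Most information-rich peripheral quadrant (ties: NW, NE, SW, SE).

    Returns ``(seed_array, quadrant_name)``; raises nothing for an all-zero
    grid but flags it by returning ``(zeros, None)``.
    """
    a = grid.intensity if isinstance(grid, MultifractalGrid) else np.asarray(grid)
    quads = _quadrants(a)
    if a.sum() <= 0:
        return quads[0].copy(), None
    ents = [_shannon_entropy(q) for q in quads]
    best = int(np.argmax(ents))  # argmax takes the first maximum: NW-first
    return quads[best].copy(), QUADRANT_NAMES[best]


def expand_seed(seed: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour upscale of a seed quadrant to the full grid."""
    ri = (np.arange(size) * seed.shape[0] // size)
    ci = (np.arange(size) * seed.shape[1] // size)
    return seed[np.ix_(ri, ci)]


# ---------------------------------------------------------------------------
# phi* and whole-in-part metrics
# ---------------------------------------------------------------------------

def phi_star_multifractal(grid: MultifractalGrid | np.ndarray) -> PhiStar:
    """Quadrant-partition KL irreducibility of the intensity pattern."""
    a = grid.intensity if isinstance(grid, MultifractalGrid) else np.asarray(grid)
    quads = [q.ravel() for q in _quadrants(a)]
    whole = np.concatenate(quads)
    if whole.sum() <= 0 or any(q.sum() <= 0 for q in quads):
        return PhiStar(0.0, degenerate=True)
    parts = [q / q.sum() for q in quads]
    return kl_phi_star(whole, parts)


@dataclass
class WholeInPartMetrics:
    structural_similarity: float
    reconstruction_accuracy: float
    info_density_ratio: float
    pattern_preservation: float
    degenerate: bool = False


def _radial_profile(a: np.ndarray, n_bins: int = 24) -> np.ndarray:
    n = a.shape[0]
    yy, xx = np.indices(a.shape)
    c = (n - 1) / 2.0
    rr = np.hypot(yy - c, xx - c)
    bins = np.minimum((rr / (rr.max() + 1e-12) * n_bins).astype(int), n_bins - 1)
    prof = np.bincount(bins.ravel(), weights=a.ravel(), minlength=n_bins)
    cnt = np.bincount(bins.ravel(), minlength=n_bins)
    return prof / np.maximum(cnt, 1)


def whole_in_part_metrics(parent, seed: np.ndarray) -> WholeInPartMetrics:
    """Compare a parent multifractal with the expansion of its seed."""
    p = parent.intensity if isinstance(parent, MultifractalGrid) else np.asarray(parent)
    if seed.sum() <= 0:
        return WholeInPartMetrics(0.0, 0.0, 0.0, 0.0, degenerate=True)
    e = expand_seed(seed, p.shape[0])
    rng_ = float(max(p.max(), e.max()) - min(p.min(), e.min()))
    ssim = structural_similarity(p, e, data_range=rng_ if rng_ > 0 else 1.0)
    if np.std(p) > 0 and np.std(e) > 0:
        ncc = float(np.corrcoef(p.ravel(), e.ravel())[0, 1])
    else:
        ncc = 0.0
    den_p = _shannon_entropy(p) / math.log2(p.size)
    den_s = _shannon_entropy(seed) / math.log2(seed.size)
    idr = den_s / den_p if den_p > 0 else 0.0
    rp, re = _radial_profile(p), _radial_profile(e)
    denom = np.linalg.norm(rp) * np.linalg.norm(re)
    cosine = float(rp @ re / denom) if denom > 0 else 0.0
    clip = lambda x: float(np.clip(x, 0.0, 1.0))
    return WholeInPartMetrics(clip(ssim), clip(ncc), clip(idr), clip(cosine))


# ---------------------------------------------------------------------------
# the GFM cycle
# ---------------------------------------------------------------------------

class DefaultEPSPSource:
    """Stochastic 4-level EPSP input with the standard amplitude hierarchy.

    Each step draws a small Poisson number of events per branch level inside
    a 50-ms integration window and maps the trains onto the carpet with a
    fixed total intensity budget, so successive uploads differ in shape but
    carry a stable drive.
    """

    def __init__(self, n_levels: int = 4, A_0: float = 0.15, r: float = 0.6,
                 grid_size: int = 243, mean_events: float = 3.0,
                 total_intensity: float = 550.0):
        self.n_levels = n_levels
        self.A_0 = A_0
        self.r = r
        self.grid_size = grid_size
        self.mean_events = mean_events
        self.total_intensity = total_intensity

    def trains(self, rng: np.random.Generator) -> list[EPSPTrain]:
        out = []
        for lvl in range(1, self.n_levels + 1):
            n = max(int(rng.poisson(self.mean_events)), 1)
            ev = np.sort(rng.uniform(0.0, 50.0, size=n))
            out.append(epsp_train(lvl, self.A_0, self.r, ev))
        return out

    def __call__(self, rng: np.random.Generator) -> MultifractalGrid:
        return map_epsp_to_grid(self.trains(rng), self.grid_size,
                                total_intensity=self.total_intensity)


@dataclass
class GFMTrajectory:
    metrics: pd.DataFrame          # step, center_intensity, ap, phi_star, ...
    collapses: pd.DataFrame        # step, quadrant, ssim, ...
    q: float
    threshold: float
    final_grid: MultifractalGrid

    @property
    def collapse_steps(self) -> np.ndarray:
        return self.collapses["step"].to_numpy()

    def mean_collapse_interval(self) -> float:
        s = self.collapse_steps
        if s.size == 0:
            return np.nan
        first = float(s[0] + 1)  # steps from generation start to first collapse
        if s.size == 1:
            return first
        return float(np.mean(np.concatenate([[first], np.diff(s)])))


def _grow_step(a: np.ndarray, center: tuple[slice, slice],
               fraction: float) -> np.ndarray:
    """One conservative growth step: 3x3 smoothing + transfer to center."""
    sm = uniform_filter(a, size=3, mode="wrap")
    sm *= a.sum() / sm.sum() if sm.sum() > 0 else 1.0
    mask = np.zeros_like(sm, dtype=bool)
    mask[center] = True
    moved = sm[~mask].sum() * fraction
    out = sm.copy()
    out[~mask] *= (1.0 - fraction)
    n_center = mask.sum()
    out[mask] += moved / n_center
    return out


def run_gfm_cycle(
    initial_grid: MultifractalGrid | None = None,
    epsp_source=None,
    firing_threshold: float = 180.0,
    q: float = 0.6,
    n_steps: int = 40,
    rng: np.random.Generator | None = None,
    growth_fraction: float = 0.08,
    grid_size: int = 243,
) -> GFMTrajectory:
    """Iterate the grow -> collapse -> seed -> daughter generational cycle."""
    if firing_threshold <= 0:
        raise ValueError("firing threshold must be positive")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    if epsp_source is None:
        epsp_source = DefaultEPSPSource(grid_size=grid_size)
    if initial_grid is None:
        initial_grid = epsp_source(rng)
    grid = initial_grid
    a = grid.intensity.copy()
    center = grid.center_slice
    rows, collapses = [], []
    for step in range(n_steps):
        a = _grow_step(a, center, growth_fraction)
        ci = float(a[center].sum())
        ap = ci > firing_threshold
        ps = phi_star_multifractal(a)
        rows.append({"step": step, "center_intensity": ci, "ap": ap,
                     "phi_star": ps.value,
                     "entropy": _shannon_entropy(a),
                     "total": float(a.sum())})
        if ap:
            seed, quad = extract_seed(a)
            wip = whole_in_part_metrics(a, seed)
            collapses.append({"step": step, "quadrant": quad,
                              "ssim": wip.structural_similarity,
                              "reconstruction_accuracy": wip.reconstruction_accuracy,
                              "info_density_ratio": wip.info_density_ratio,
                              "pattern_preservation": wip.pattern_preservation,
                              "seed_entropy": _shannon_entropy(seed)})
            fresh = epsp_source(rng).intensity
            a = q * expand_seed(seed, a.shape[0]) + (1.0 - q) * fresh
    cols = ["step", "quadrant", "ssim", "reconstruction_accuracy",
            "info_density_ratio", "pattern_preservation", "seed_entropy"]
    return GFMTrajectory(
        metrics=pd.DataFrame(rows),
        collapses=pd.DataFrame(collapses, columns=cols),
        q=q, threshold=firing_threshold,
        final_grid=MultifractalGrid(a, grid.depth_map),
    )


# ---------------------------------------------------------------------------
# GFM / IDS information equivalence
# ---------------------------------------------------------------------------

def gfm_total_information(I_0: float, q: float,
                          n_generations: int | None = None) -> float:
    """Cumulative information of generational decay, sum of I_0 * q**t.

    ``n_generations=None`` takes the infinite horizon ``I_0 / (1 - q)``,
    which equals the infinite spatial-downscaling (IDS) sum with ratio
    ``r = q`` - the temporal cycle folds infinity into finite space.
    """
    if n_generations is None:
        if not 0.0 <= q < 1.0:
            raise ValueError("infinite horizon diverges for q >= 1")
        return I_0 / (1.0 - q)
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    if q == 1.0:
        return I_0 * (n_generations + 1)
    return I_0 * (1.0 - q ** (n_generations + 1)) / (1.0 - q)
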