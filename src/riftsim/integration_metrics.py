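"""Integration and fractal time-series metrics.

Dynamic integrated information (``phi_dyn``) is estimated as the total
correlation of branch-level firing-window indicators minus the same
statistic under a circular-shift null that destroys inter-level alignment
while preserving each level's marginal occupancy.  Spatial irreducibility
(``phi*``) is a Kullback-Leibler divergence between a whole pattern and the
composition of its independently treated parts.  The module also provides
the standard scaling estimators used throughout: box-counting dimension of
a series graph, Higuchi fractal dimension, and detrended fluctuation
analysis (DFA).

All functions are pure: identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhiResult",
    "MetricsRecord",
    "PhiStar",
    "phi_dyn",
    "kl_phi_star",
    "fractal_measures",
    "predictability_metrics",
]

_EPS = 1e-12  # regularization for KL divergences


@dataclass
class PhiResult:
    """Sliding-window integrated-information series.

    ``phi = max(I - I_star, 0)`` per window, in bits. ``times`` holds the
    window-end time (ms) on the binning grid.
    """

    times: np.ndarray
    I: np.ndarray
    I_star: np.ndarray
    phi: np.ndarray
    grain: float = 2.0
    window: int = 25
    degenerate: bool = False


@dataclass
class MetricsRecord:
    box_fd: float = np.nan
    higuchi_fd: float = np.nan
    dfa_alpha: float = np.nan
    volatility: float = np.nan
    prediction_error: float = np.nan
    lag1_autocorr: float = np.nan
    phase_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


@dataclass
class PhiStar:
    value: float
    degenerate: bool = False

    def __float__(self) -> float:  # pragma: no cover - trivial
        return float(self.value)


# ---------------------------------------------------------------------------
# phi* : KL irreducibility of a partitioned distribution
# ---------------------------------------------------------------------------

def kl_phi_star(whole, parts, eps: float = _EPS) -> PhiStar:
    """KL divergence between a whole distribution and its part composition.

    Parameters
    ----------
    whole : array_like
        Non-negative intensities over all cells, arranged so that the cells
        of part ``k`` occupy the ``k``-th contiguous block (or pass a 2-D
        array of shape ``(n_parts, n_cells_per_part)``).
    parts : sequence of array_like
        One normalized (or normalizable) distribution per part, each over
        that part's cells, positionally aligned across parts.

    The independent composition assigns cell ``(k, u)`` probability
    ``w_k * sum_j w_j parts_j(u)`` where ``w_k`` is the whole's mass in part
    ``k``: parts contribute only through their mass and a shared average
    shape, so the statistic vanishes exactly when all part shapes agree and
    is otherwise a non-negative irreducibility measure (in bits).
    """
    parts = [np.asarray(p, dtype=float).ravel() for p in parts]
    k = len(parts)
    if k == 0:
        raise ValueError("need at least one part distribution")
    m = parts[0].size
    if any(p.size != m for p in parts):
        raise ValueError("part distributions must be positionally aligned")
    w = np.asarray(whole, dtype=float).reshape(k, m)
    total = w.sum()
    if total <= 0 or any(p.sum() <= 0 for p in parts):
        return PhiStar(0.0, degenerate=True)
    p = w / total
    masses = p.sum(axis=1)
    shapes = np.stack([pk / pk.sum() for pk in parts])
    avg_shape = masses @ shapes
    q = masses[:, None] * avg_shape[None, :]
    val = float(np.sum(p * (np.log2(p + eps) - np.log2(q + eps))))
    return PhiStar(max(val, 0.0))


# ---------------------------------------------------------------------------
# phi_dyn : sliding-window total correlation of branch firing windows
# ---------------------------------------------------------------------------

def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of each row of a non-negative count matrix."""
    tot = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, counts / np.maximum(tot, 1e-300), 0.0)
        h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=-1)
    return h


def phi_dyn(
    firing_times_by_branch,
    grain: float = 2.0,
    window: int = 25,
) -> PhiResult:
    """phi_dyn(t) over overlapping sliding windows (stride one bin).

    ``firing_times_by_branch`` maps branch level -> event times (ms), or is
    a sequence of per-level time arrays.  Events are binned at ``grain`` ms;
    in every ``window``-bin sliding window, ``I`` is the entropy of the
    pooled (branches-intact) firing-time distribution and ``I*`` the
    event-weighted mean entropy of the branches analyzed independently, so
    ``phi = I - I*`` is the mutual information between branch identity and
    firing-window position.  It vanishes when branch windows merge within
    the grain (indistinguishable) and when they separate beyond the analysis
    window (non-interacting), peaking at intermediate gaps.
    """
    if grain <= 0:
        raise ValueError("grain must be positive")
    if isinstance(firing_times_by_branch, dict):
        levels = sorted(firing_times_by_branch)
        series = [np.asarray(firing_times_by_branch[k], dtype=float)
                  for k in levels]
    else:
        series = [np.asarray(s, dtype=float) for s in firing_times_by_branch]
    series = [s for s in series if s.size > 0]
    if len(series) < 2:
        empty = np.empty(0)
        return PhiResult(empty, empty, empty, empty, grain, window,
                         degenerate=True)

    t0 = min(s.min() for s in series)
    t1 = max(s.max() for s in series)
    n_bins = max(int(np.ceil((t1 - t0) / grain)) + 1, window)
    counts = np.zeros((len(series), n_bins))
    for i, s in enumerate(series):
        idx = np.clip(((s - t0) / grain).astype(int), 0, n_bins - 1)
        np.add.at(counts[i], idx, 1.0)

    n_win = n_bins - window + 1
    I = np.zeros(n_win)
    I_star = np.zeros(n_win)
    for w in range(n_win):
        c = counts[:, w:w + window]
        level_tot = c.sum(axis=1)
        total = level_tot.sum()
        if total <= 0:
            continue
        I[w] = _entropy_rows(c.sum(axis=0)[None, :])[0]
        I_star[w] = float((level_tot / total) @ _entropy_rows(c))
    phi = np.maximum(I - I_star, 0.0)
    times = t0 + grain * (np.arange(n_win) + window)
    return PhiResult(times, I, I_star, phi, grain, window)


# ---------------------------------------------------------------------------
# fractal scaling estimators
# ---------------------------------------------------------------------------

def _box_count_fd(series: np.ndarray) -> float:
    """Box-counting dimension of the series graph in the unit square."""
    n = series.size
    lo, hi = series.min(), series.max()
    y = (series - lo) / (hi - lo) if hi > lo else np.zeros(n)
    counts, sizes = [], []
    k = 1
    while (1 << k) <= n // 4:
        m = 1 << k  # m x m boxes
        eps = 1.0 / m
        col = np.clip((np.arange(n) / (n - 1) * m).astype(int), 0, m - 1)
        total = 0
        for c in range(m):
            sel = y[col == c]
            if sel.size == 0:
                continue
            total += int(sel.max() / eps) - int(sel.min() / eps) + 1
        counts.append(total)
        sizes.append(eps)
        k += 1
    if len(counts) < 2:
        return np.nan
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes)), np.log(counts), 1)[0]
    return float(slope)


def _higuchi_fd(series: np.ndarray, k_max: int = 10) -> float:
    n = series.size
    lk = []
    ks = np.arange(1, k_max + 1)
    for k in ks:
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            d = np.abs(np.diff(series[idx])).sum()
            norm = (n - 1) / (idx.size - 1) / k
            lengths.append(d * norm / k)
        lk.append(np.mean(lengths))
    lk = np.asarray(lk)
    if np.any(lk <= 0):
        return 1.0  # smooth-curve limit: curve length shrinks below resolution
    slope = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)[0]
    return float(slope)


def _dfa_alpha(series: np.ndarray) -> float:
    n = series.size
    if n < 128:
        return np.nan
    profile = np.cumsum(series - series.mean())
    sizes = np.unique(
        np.floor(np.logspace(np.log10(8), np.log10(n // 4), 12)).astype(int)
    )
    flucts = []
    for s in sizes:
        n_seg = n // s
        segs = profile[: n_seg * s].reshape(n_seg, s)
        x = np.arange(s)
        # linear detrend per segment
        coef = np.polynomial.polynomial.polyfit(x, segs.T, 1)
        trend = coef[0][:, None] + coef[1][:, None] * x
        flucts.append(np.sqrt(np.mean((segs - trend) ** 2)))
    slope = np.polyfit(np.log(sizes), np.log(flucts), 1)[0]
    return float(slope)


def fractal_measures(series) -> MetricsRecord:
    """Box-counting FD of the graph, Higuchi FD (k=1..10) and DFA alpha."""
    x = np.asarray(series, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    rec = MetricsRecord()
    if x.size >= 16 and x.max() > x.min():
        rec.box_fd = _box_count_fd(x)
    if x.size >= 32 and x.max() > x.min():
        rec.higuchi_fd = _higuchi_fd(x)
    rec.dfa_alpha = _dfa_alpha(x)
    return rec


def predictability_metrics(series) -> MetricsRecord:
    """Volatility, one-step prediction error, lag-1 autocorrelation."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("series too short")
    d = np.diff(x)
    rec = MetricsRecord()
    rec.volatility = float(np.std(d))
    rec.prediction_error = float(np.mean(np.abs(d)))
    if np.std(x) > 0:
        rec.lag1_autocorr = float(np.corrcoef(x[:-1], x[1:])[0, 1])
    rec.phase_pairs = np.column_stack([x[:-1], x[1:]])
    return rec
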