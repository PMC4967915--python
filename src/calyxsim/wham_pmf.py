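"""Potential-of-mean-force reconstruction from umbrella windows.

Implements the self-consistent weighted histogram analysis method (WHAM)
for one-dimensional umbrella sampling with harmonic biases
``w_i(xi) = k_i/2 (xi - c_i)^2``, with window-level bootstrap error bars
(complete histograms resampled as independent data points) and barrier /
unbinding free-energy summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import kt


@dataclass
class UmbrellaWindowData:
    """Biased reaction-coordinate samples from one umbrella window."""

    center: float              # nm
    spring_k: float            # kJ/mol/nm^2
    samples: np.ndarray        # nm

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.spring_k < 0:
            raise ValueError("spring_k must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class WHAMConfig:
    """Histogramming, convergence and bootstrap settings.

    The bin width (nm), tolerance on the window free-energy constants
    (kJ/mol) and iteration cap are numerical choices; 200 bootstrap
    replicates is the study convention for the error bars.
    """

    bin_width: float = 0.01
    tolerance: float = 1e-6
    max_iterations: int = 100_000
    temperature: float = 310.0
    n_bootstrap: int = 200
    seed: int | None = None
    #: bins with fewer total counts carry no reliable free energy and are
    #: treated as unsampled (W = +inf)
    min_counts: int = 25

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class Histograms:
    """Per-window counts on a common reaction-coordinate grid."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    counts: np.ndarray          # (n_windows, n_bins)
    window_centers: np.ndarray
    spring_ks: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    def overlap_matrix(self) -> np.ndarray:
        """Number of jointly populated bins for every window pair."""
        occ = self.counts > 0
        return (occ[:, None, :] & occ[None, :, :]).sum(axis=2)


@dataclass
class PMFProfile:
    """Reconstructed PMF: W(xi) in kJ/mol with its minimum gauged to zero.

    Bins inside the grid that received no counts carry ``W = +inf`` and are
    excluded from the gauge shift.  ``f`` holds the converged per-window
    free-energy constants (useful to warm-start bootstrap replicates).
    """

    bin_centers: np.ndarray
    W: np.ndarray
    stderr: np.ndarray | None
    n_iterations: int
    converged: bool
    f: np.ndarray = field(default=None, repr=False)

    @property
    def support(self) -> np.ndarray:
        return np.isfinite(self.W)


def build_histograms(windows, config: WHAMConfig, bin_edges=None) -> Histograms:
    """Histogram every window on a common grid spanning all samples.

    Counts are conserved: each window's bins sum to its sample count.
    """
    if len(windows) == 0:
        raise ValueError("no umbrella windows given")
    for i, w in enumerate(windows):
        if w.n_samples == 0:
            raise ValueError(f"umbrella window {i} (center {w.center:g} nm) is empty")
    if bin_edges is None:
        bw = config.bin_width
        lo = math.floor(min(w.samples.min() for w in windows) / bw) * bw
        hi = math.ceil(max(w.samples.max() for w in windows) / bw) * bw
        n_bins = max(1, int(round((hi - lo) / bw)))
        bin_edges = lo + bw * np.arange(n_bins + 1)
    counts = np.stack([np.histogram(w.samples, bins=bin_edges)[0] for w in windows])
    return Histograms(
        bin_edges=bin_edges,
        bin_centers=0.5 * (bin_edges[:-1] + bin_edges[1:]),
        counts=counts.astype(float),
        window_centers=np.array([w.center for w in windows]),
        spring_ks=np.array([w.spring_k for w in windows]),
    )


def _check_connected(counts: np.ndarray, window_centers: np.ndarray):
    """The window histograms must form one connected overlap graph (two
    windows are linked when they share a populated bin); otherwise the
    relative free-energy offsets across the break are undetermined."""
    from scipy.sparse.csgraph import connected_components

    occ = counts > 0
    if not occ.any():
        raise ValueError("no populated bins")
    adj = (occ.astype(np.int64) @ occ.T) > 0
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        order = np.argsort(window_centers)
        for a, b in zip(order[:-1], order[1:]):
            if labels[a] != labels[b]:
                raise ValueError(
                    "histogram chain is disconnected: windows at "
                    f"{window_centers[a]:.4g} and {window_centers[b]:.4g} nm "
                    "share no populated bin")
        raise ValueError("histogram chain is disconnected")


def solve_wham(histograms: Histograms, config: WHAMConfig,
               f_init=None) -> PMFProfile:
    """Self-consistent WHAM iteration.

    Alternates the unbiased probability estimate
    ``P_b = sum_i h_ib / sum_i N_i exp((f_i - w_i(xi_b))/kT)`` with the
    window constants ``f_i = -kT ln sum_b P_b exp(-w_i(xi_b)/kT)`` until the
    largest change in any ``f_i`` falls below the tolerance.  The PMF is
    ``W = -kT ln P`` shifted so its minimum over populated bins is zero.
    """
    kT = kt(config.temperature)
    xb = histograms.bin_centers
    dev = xb[None, :] - histograms.window_centers[:, None]
    bias = 0.5 * histograms.spring_ks[:, None] * dev * dev
    B = np.exp(-bias / kT)                       # (n_w, n_b)
    support = histograms.counts.sum(axis=0) >= max(1, config.min_counts)
    counts = histograms.counts * support         # drop under-sampled bins
    N = counts.sum(axis=1)
    H = counts.sum(axis=0)
    if np.any(N == 0):
        i = int(np.flatnonzero(N == 0)[0])
        raise ValueError(
            f"window at {histograms.window_centers[i]:.4g} nm retains no "
            "counts after the minimum-support filter")
    _check_connected(counts, histograms.window_centers)

    f = np.zeros(histograms.n_windows) if f_init is None \
        else np.asarray(f_init, dtype=float).copy()
    P = np.zeros_like(H)
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        denom = (N * np.exp(f / kT)) @ B
        np.divide(H, denom, out=P, where=support & (denom > 0))
        P[~support] = 0.0
        P /= P.sum()
        z = B @ P
        f_new = -kT * np.log(z)
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < config.tolerance:
            converged = True
            break

    with np.errstate(divide="ignore"):
        W = np.where(support, -kT * np.log(np.where(support, P, 1.0)), np.inf)
    W -= W[support].min()
    return PMFProfile(bin_centers=xb, W=W, stderr=None,
                      n_iterations=it, converged=converged, f=f)


@dataclass
class BootstrapResult:
    """Per-bin standard errors over window-resampled WHAM replicates."""

    stderr: np.ndarray
    n_replicates: int
    n_discarded: int
    profiles: np.ndarray = field(repr=False, default=None)  # (n_kept, n_bins)


def bootstrap_pmf_error(windows, config: WHAMConfig) -> BootstrapResult:
    """Bootstrap the PMF by resampling complete windows with replacement.

    Complete histograms are treated as independent data points: every
    replicate draws ``n_windows`` windows with replacement, re-solves WHAM
    on the original grid, and the per-bin standard error is the standard
    deviation of the replicate PMFs (each gauged to min 0).  Replicates
    whose histogram chain is disconnected are discarded and counted.
    """
    if len(windows) < 2:
        raise ValueError("bootstrap needs at least two windows")
    hist = build_histograms(windows, config)
    base = solve_wham(hist, config)
    rng = np.random.default_rng(config.seed)
    n = hist.n_windows
    kept, discarded = [], 0
    for _ in range(config.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        rep = Histograms(
            bin_edges=hist.bin_edges, bin_centers=hist.bin_centers,
            counts=hist.counts[idx], window_centers=hist.window_centers[idx],
            spring_ks=hist.spring_ks[idx],
        )
        try:
            prof = solve_wham(rep, config, f_init=base.f[idx])
        except ValueError:
            discarded += 1
            continue
        kept.append(prof.W)
    if discarded > 0.2 * config.n_bootstrap:
        warnings.warn(
            f"{discarded}/{config.n_bootstrap} bootstrap replicates had a "
            "disconnected histogram chain and were discarded",
            RuntimeWarning, stacklevel=2)
    if not kept:
        raise RuntimeError("all bootstrap replicates were discarded")
    reps = np.stack(kept)
    stderr = np.empty(reps.shape[1])
    for b in range(reps.shape[1]):
        vals = reps[:, b]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            stderr[b] = np.nan
        elif vals.size == 1:
            stderr[b] = 0.0
        else:
            stderr[b] = vals.std(ddof=1)
    if len(kept) == 1:
        stderr = np.zeros_like(stderr)
    return BootstrapResult(stderr=stderr, n_replicates=len(kept),
                           n_discarded=discarded, profiles=reps)


def pmf_summary(profile: PMFProfile, plateau_slope_tol: float = 10.0,
                plateau_min_width: float = 0.3,
                smooth_width: float = 0.1) -> dict:
    """Summarise a PMF: unbinding free energy, barrier and landmarks.

    The free-state plateau is detected as the terminal stretch (at least
    ``plateau_min_width`` nm wide) where the smoothed |dW/dxi| stays below
    ``plateau_slope_tol`` kJ/mol/nm; ``delta_g_unbind`` is the raw-PMF mean
    over that stretch.  Without a plateau the maximum of W is reported with
    ``plateau_found=False``.
    """
    fin = profile.support
    x = profile.bin_centers[fin]
    w = profile.W[fin]
    if x.size < 3:
        raise ValueError("profile too short to summarise")
    bw = float(np.median(np.diff(x)))
    n_s = max(1, int(round(smooth_width / bw)) | 1)
    pad = n_s // 2
    wp = np.pad(w, pad, mode="edge")
    ws = np.convolve(wp, np.ones(n_s) / n_s, mode="valid")
    slope = np.gradient(ws, x)

    flat = np.abs(slope) < plateau_slope_tol
    i = x.size
    while i > 0 and flat[i - 1]:
        i -= 1
    plateau_found = (x[-1] - x[i]) >= plateau_min_width if i < x.size else False
    if plateau_found:
        delta_g = float(np.mean(w[i:]))
        xi_plateau = float(x[i])
    else:
        delta_g = float(np.max(w))
        xi_plateau = float("nan")
    return {
        "delta_g_unbind": delta_g,
        "barrier": float(np.max(w)),
        "xi_min": float(x[np.argmin(w)]),
        "xi_plateau": xi_plateau,
        "plateau_found": bool(plateau_found),
    }
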