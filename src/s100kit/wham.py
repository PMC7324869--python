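"""1-D umbrella-sampling reconstruction: WHAM, error estimators, binding ΔG.

The reaction coordinate for TRTK12 unbinding is the distance between the
centre of mass of the peptide Cα atoms and that of the Cα atoms of the H3
C-terminus (K30–T39) plus H4 N-terminus (E73–A84).  Windows carry a
harmonic restraint U_i(z) = ½K(z−z_i)² (NAMD colvars convention; the
alternative U = K(z−z_i)² is available behind ``bias_convention='full'``)
with K = 18 kcal/mol/Å² and centres 9.5–33.5 Å in 0.5 Å steps (49 windows).

WHAM solves the self-consistent equations for the window free energies f_i
and the unbiased bin probabilities, giving G(z) = −RT ln ρ(z) anchored at
zero minimum.  Two error estimators are provided: a Monte-Carlo bootstrap
over window samples, and mean-force error propagation from block-averaged
window-mean variances (Zhu–Hummer style quadrature along the coordinate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import Selection, Structure, read_window_series, select

__all__ = [
    "RCDefinition",
    "UmbrellaWindow",
    "PMFProfile",
    "BlockAverageResult",
    "reaction_coordinate",
    "wham",
    "bootstrap_error",
    "block_variance",
    "propagate_pmf_error",
    "binding_dg",
    "load_windows",
    "default_window_centers",
]

KB = 0.0019872041          # kcal/mol/K
RT_300K = 0.596            # kcal/mol at the sampling temperature (300 K)


def default_window_centers(start: float = 9.5, stop: float = 33.5,
                           spacing: float = 0.5) -> np.ndarray:
    """Window centres 9.5–33.5 Å every 0.5 Å (49 windows)."""
    n = int(round((stop - start) / spacing)) + 1
    return start + spacing * np.arange(n)


@dataclass(frozen=True)
class RCDefinition:
    """COM–COM distance between two Cα groups."""

    group1: Selection
    group2: Selection


def reaction_coordinate(structure: Structure, rc: RCDefinition) -> float:
    """Distance (Å) between the mass-weighted COMs of the two groups."""
    coords, masses = structure.coords, structure.masses

    def com(sel: Selection, label: str) -> np.ndarray:
        idx = select(structure, sel)
        if not idx:
            raise ValueError(f"{label} selection resolves to no atoms")
        w = masses[idx]
        return (coords[idx] * w[:, None]).sum(axis=0) / w.sum()

    return float(np.linalg.norm(com(rc.group1, "group1") - com(rc.group2, "group2")))


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic centre, force constant, RC samples (Å)."""

    center: float
    samples: np.ndarray
    force_constant: float = 18.0       # kcal/mol/Å²; 0 = unbiased window
    window_id: str | None = None

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size == 0 or not np.all(np.isfinite(s)):
            raise ValueError("samples must be a non-empty finite 1-D array")
        self.samples = s


def bias_energy(z: np.ndarray, window: UmbrellaWindow,
                convention: str = "half") -> np.ndarray:
    """Restraint energy (kcal/mol); 'half' = ½K(z−z₀)², 'full' = K(z−z₀)²."""
    dz2 = (np.asarray(z, float) - window.center) ** 2
    if convention == "half":
        return 0.5 * window.force_constant * dz2
    if convention == "full":
        return window.force_constant * dz2
    raise ValueError(f"unknown bias convention {convention!r}")


def effective_force_constant(window: UmbrellaWindow, convention: str = "half") -> float:
    """d²U/dz² of the restraint (mean-force slope used in error propagation)."""
    return window.force_constant if convention == "half" else 2.0 * window.force_constant


@dataclass
class PMFProfile:
    """Reconstructed free-energy profile, min-anchored at zero."""

    z: np.ndarray                  # bin centres, strictly increasing (Å)
    G: np.ndarray                  # kcal/mol, min = 0
    error: np.ndarray | None = None
    rt: float = RT_300K
    window_free_energies: np.ndarray | None = None
    iterations: int = 0
    residual: float = 0.0

    @property
    def temperature(self) -> float:
        return self.rt / KB

    def to_frame(self) -> pd.DataFrame:
        d = {"z": self.z, "G": self.G}
        if self.error is not None:
            d["error"] = self.error
        return pd.DataFrame(d)


def _histogram(windows: list[UmbrellaWindow], bin_width: float,
               z_range: tuple[float, float] | None):
    if z_range is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
    else:
        lo, hi = z_range
    start = np.floor(lo / bin_width) * bin_width
    n_bins = max(int(np.ceil((hi - start) / bin_width)), 1)
    edges = start + bin_width * np.arange(n_bins + 1)
    if edges[-1] <= hi:                       # closed upper edge
        edges = np.append(edges, edges[-1] + bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    return edges, centers, counts


def _minimize_wham_likelihood(N: np.ndarray, M: np.ndarray, u: np.ndarray,
                              occupied: np.ndarray) -> np.ndarray:
    """Warm-start f_i by minimising the convex WHAM log-likelihood.

    The self-consistent WHAM equations are the stationarity conditions of
    A(f) = Σ_k M_k ln Σ_i N_i e^{f_i−u_ik} − Σ_i N_i f_i (f in units of RT,
    gauge f_0 = 0).  A quasi-Newton pass lands within round-off of the fixed
    point, so the subsequent direct iteration only polishes.
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp

    n_win = len(N)
    kmask = occupied
    Mk = M[kmask]
    uk = u[:, kmask]
    logN = np.log(np.where(N > 0, N, 1.0))

    n_tot = float(N.sum())

    def objective(g: np.ndarray):
        f = np.concatenate([[0.0], g])
        a = logN[:, None] + f[:, None] - uk
        logD = logsumexp(a, axis=0)
        val = float(np.sum(Mk * logD) - np.sum(N * f)) / n_tot
        w = np.exp(a - logD[None, :])            # window share of each bin
        grad_full = (w @ Mk - N) / n_tot
        return val, grad_full[1:]

    if n_win == 1:
        return np.zeros(1)
    res = minimize(objective, np.zeros(n_win - 1), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
    g = res.x
    # exact Newton polish: the objective is strictly convex in the gauge-fixed
    # coordinates, and the Hessian is tiny (n_windows²)
    for _ in range(50):
        f = np.concatenate([[0.0], g])
        a = logN[:, None] + f[:, None] - uk
        logD = logsumexp(a, axis=0)
        w = np.exp(a - logD[None, :])
        grad = ((w @ Mk - N) / n_tot)[1:]
        if np.max(np.abs(grad)) < 1e-15:
            break
        wm = w * Mk[None, :]
        H = (np.diag(wm.sum(axis=1)) - wm @ w.T)[1:, 1:] / n_tot
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            break
        g = g + np.clip(step, -5.0, 5.0)
    return np.concatenate([[0.0], g])


def wham(windows: list[UmbrellaWindow], bin_width: float = 0.1,
         rt: float = RT_300K, tol: float = 1e-10, max_iter: int = 100_000,
         bias_convention: str = "half",
         z_range: tuple[float, float] | None = None) -> PMFProfile:
    """Self-consistent WHAM solution of the unbiased profile.

    Iterates the window free energies f_i until max|Δf_i| < ``tol``
    (dimensionless, units of RT).  Bins never visited by any window are
    dropped from the returned profile; interior gaps raise a warning since
    the reconstruction is then disconnected.
    """
    if not windows:
        raise ValueError("no umbrella windows supplied")
    edges, centers, counts = _histogram(windows, bin_width, z_range)
    M = counts.sum(axis=0).astype(float)         # total counts per bin
    occupied = M > 0
    inner = occupied[np.argmax(occupied):len(occupied) - np.argmax(occupied[::-1])]
    if not inner.all():
        warnings.warn("gap in window histograms: bins inside the sampled "
                      "range have zero counts", stacklevel=2)
    N = counts.sum(axis=1).astype(float)         # samples per window
    u = np.stack([bias_energy(centers, w, bias_convention) for w in windows]) / rt

    f = _minimize_wham_likelihood(N, M, u, occupied)
    p = np.zeros_like(M)
    residual = np.inf
    it = 0
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        for it in range(1, max_iter + 1):
            denom = (N[:, None] * np.exp(f[:, None] - u)).sum(axis=0)
            p = np.where(occupied, M / np.where(denom > 0, denom, 1.0), 0.0)
            p /= p.sum()
            # f_i = -ln Σ_k p_k exp(-u_ik), evaluated stably
            logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
            a = logp[None, :] - u
            amax = a.max(axis=1)
            f_new = -(amax + np.log(np.exp(a - amax[:, None]).sum(axis=1)))
            f_new -= f_new[0]
            residual = float(np.max(np.abs(f_new - f)))
            f = f_new
            if residual < tol:
                break
    if residual >= tol:
        warnings.warn(f"WHAM did not converge in {max_iter} iterations "
                      f"(residual {residual:.2e})", stacklevel=2)
    G = np.full_like(p, np.nan)
    G[occupied] = -rt * np.log(p[occupied])
    G -= np.nanmin(G)
    return PMFProfile(z=centers[occupied], G=G[occupied], rt=rt,
                      window_free_energies=f * rt, iterations=it,
                      residual=residual)


def bootstrap_error(windows: list[UmbrellaWindow], n_trials: int = 30,
                    seed: int | None = None, bin_width: float = 0.1,
                    rt: float = RT_300K, tol: float = 1e-10,
                    max_iter: int = 100_000, bias_convention: str = "half",
                    anchor: str = "min") -> PMFProfile:
    """Monte-Carlo bootstrap error of the WHAM profile.

    Each trial resamples every window's samples with replacement, re-runs
    WHAM on the shared bin grid, anchors the trial profile (``anchor='min'``
    subtracts the minimum; ``'tail'`` subtracts the value at the last bin)
    and the per-bin standard deviation across trials is reported as ε(z).
    Returns the original profile with ``error`` filled in.
    """
    if anchor not in ("min", "tail"):
        raise ValueError("anchor must be 'min' or 'tail'")
    rng = np.random.default_rng(seed)
    base = wham(windows, bin_width, rt, tol, max_iter, bias_convention)
    z_range = (float(base.z[0] - bin_width), float(base.z[-1] + bin_width))
    grid = base.z
    trials = np.full((n_trials, grid.size), np.nan)
    for t in range(n_trials):
        resampled = [
            UmbrellaWindow(w.center,
                           rng.choice(w.samples, size=w.samples.size, replace=True),
                           w.force_constant, w.window_id)
            for w in windows
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)   # resampling gaps
            prof = wham(resampled, bin_width, rt, tol, max_iter,
                        bias_convention, z_range=z_range)
        G = np.interp(grid, prof.z, prof.G, left=np.nan, right=np.nan)
        if anchor == "tail":
            G = G - G[~np.isnan(G)][-1]
        else:
            G = G - np.nanmin(G)
        trials[t] = G
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        eps = np.nanstd(trials, axis=0, ddof=0)
    base.error = eps
    return base


@dataclass
class BlockAverageResult:
    """Variance of a window's mean RC from block averaging."""

    block_size: int
    n_blocks: int
    variance_of_mean: float        # σ²(x̄), Å²
    window_id: str | None = None

    def __post_init__(self) -> None:
        if self.variance_of_mean < 0:
            raise ValueError("variance must be non-negative")


def block_variance(samples: np.ndarray, block_size: int = 200,
                   window_id: str | None = None) -> BlockAverageResult:
    """Block-averaging estimate of the variance of the sample mean.

    Samples are cut into complete blocks of ``block_size`` (trailing partial
    block dropped); the reported value is the variance of the block means
    divided by the number of blocks.
    """
    s = np.asarray(samples, dtype=float)
    n_blocks = s.size // block_size
    if n_blocks < 2:
        raise ValueError(f"need at least 2 complete blocks of {block_size}; "
                         f"got {s.size} samples")
    means = s[:n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
    var = float(np.var(means, ddof=1) / n_blocks)
    return BlockAverageResult(block_size, n_blocks, var, window_id)


def propagate_pmf_error(windows: list[UmbrellaWindow],
                        block_results: list[BlockAverageResult],
                        z_grid: np.ndarray,
                        bias_convention: str = "half",
                        reference: str = "low") -> np.ndarray:
    """Mean-force error propagation of window-mean uncertainties onto ε(z).

    In the stiff-spring (mean-force integration) view the free-energy
    increment across window *i* is the restraint force K(z_i − x̄_i) times
    the centre spacing d_i, so its variance is (K·d_i)²·σ²(x̄_i).  The
    uncorrelated increments accumulate in quadrature from the reference end
    of the coordinate, giving a monotone non-decreasing ε(z).
    """
    if len(windows) != len(block_results):
        raise ValueError("one block result required per window")
    order = np.argsort([w.center for w in windows])
    if reference == "high":
        order = order[::-1]
    elif reference != "low":
        raise ValueError("reference must be 'low' or 'high'")
    centers = np.array([windows[i].center for i in order])
    sig2 = np.array([block_results[i].variance_of_mean for i in order])
    keff = np.array([effective_force_constant(windows[i], bias_convention)
                     for i in order])
    d = np.abs(np.diff(centers, prepend=centers[0]))
    inc_var = (keff * d) ** 2 * sig2
    cum = np.sqrt(np.cumsum(inc_var))
    z_grid = np.asarray(z_grid, dtype=float)
    eps = np.zeros_like(z_grid)
    for c, e in zip(centers, cum):
        crossed = z_grid >= c if reference == "low" else z_grid <= c
        eps[crossed] = e
    return eps


def binding_dg(pmf: PMFProfile, bound_region: tuple[float, float],
               unbound_region: tuple[float, float]) -> tuple[float, float | None]:
    """Binding free energy from a PMF: well minimum minus unbound plateau.

    ΔG = min G over ``bound_region`` − mean G over ``unbound_region``;
    negative values favour binding.  The error (if the profile carries one)
    combines ε at the minimum and the mean ε over the plateau in quadrature.
    """
    def region_mask(region):
        lo, hi = region
        m = (pmf.z >= lo) & (pmf.z <= hi)
        if not m.any():
            raise ValueError(f"region {region} outside profile grid "
                             f"[{pmf.z[0]:.2f}, {pmf.z[-1]:.2f}]")
        return m

    mb = region_mask(bound_region)
    mu = region_mask(unbound_region)
    i_min = np.where(mb)[0][np.argmin(pmf.G[mb])]
    dg = float(pmf.G[i_min] - pmf.G[mu].mean())
    err = None
    if pmf.error is not None:
        err = float(np.sqrt(pmf.error[i_min] ** 2 + np.nanmean(pmf.error[mu]) ** 2))
    return dg, err


def load_windows(meta_path: str | Path, time_column: bool = False
                 ) -> list[UmbrellaWindow]:
    """Load windows from a metadata CSV (window_id, center, force_constant, path).

    Sample paths are resolved relative to the metadata file's directory.
    """
    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path)
    required = {"window_id", "center", "force_constant", "path"}
    if not required <= set(meta.columns):
        raise ValueError(f"window metadata must have columns {sorted(required)}")
    windows = []
    for _, row in meta.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = meta_path.parent / p
        samples = read_window_series(p, time_column=time_column)
        windows.append(UmbrellaWindow(float(row["center"]), samples,
                                      float(row["force_constant"]),
                                      str(row["window_id"])))
    return windows
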