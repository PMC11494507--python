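"""Free-energy estimation from biased samples: MBAR, 2D PMFs, alchemy.

The multistate Bennett acceptance ratio (MBAR) is the statistically optimal
estimator of free-energy differences among K sampled states.  With pooled
samples x_n (N_k drawn from state k) and reduced energies u_k(x_n) = G_k/kT,
the state free energies f_k (reduced, gauge f_1 = 0) solve the
self-consistent equations

    f_i = -ln sum_n exp(-u_i(x_n)) / sum_k N_k exp(f_k - u_k(x_n))

Here they are solved by self-consistent iteration warm-up followed by
damped Newton polish on the equivalent convex objective.  Everything is in
reduced units (u = G/kT) internally; kcal/mol conversions happen only at
module boundaries.

Umbrella windows restrain the two reaction coordinates with harmonic
biases; `pmf_2d` unbiases their pooled samples into a gridded potential of
mean force.  Alchemical lambda windows (protonated -> deprotonated end
states) yield the deprotonation free-energy difference and hence a pKa
shift via `lfer_thermo.delta_pka_from_ddg`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import RT, T_SIMULATION
from .landscape import FreeEnergySurface

__all__ = [
    "UmbrellaWindow",
    "BiasedTrajectory",
    "MBARResult",
    "AlchemicalDataset",
    "mbar_solve",
    "umbrella_energy_matrix",
    "pmf_2d",
    "alchemical_ddg",
]

#: pairwise overlap-matrix entry below which two states are considered
#: unconnected when checking overlap-graph connectivity
OVERLAP_EDGE_THRESHOLD = 1e-3

#: factor applied to standard errors when the overlap graph is disconnected
POOR_OVERLAP_INFLATION = 10.0


def _overlap_connected(O: np.ndarray, threshold: float) -> bool:
    """True if every state is reachable via overlap-matrix edges > threshold."""
    K = O.shape[0]
    seen = np.zeros(K, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.nonzero((O[i] > threshold) & ~seen)[0]:
            seen[j] = True
            stack.append(int(j))
    return bool(seen.all())


@dataclass(frozen=True)
class UmbrellaWindow:
    """Harmonic restraint window on (xi_pt, xi_at)."""

    center: tuple[float, float]
    force_constants: tuple[float, float]  # kcal/mol/A^2 per coordinate
    n_samples: int = 1000

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.force_constants):
            raise ValueError("force constants must be positive")

    def bias_energy(self, xy: np.ndarray) -> np.ndarray:
        """(1/2) k |xi - c|^2 in kcal/mol for points of shape (..., 2)."""
        xy = np.asarray(xy, dtype=float)
        d = xy - np.asarray(self.center)
        k = np.asarray(self.force_constants)
        return 0.5 * np.sum(k * d * d, axis=-1)


@dataclass
class BiasedTrajectory:
    """Samples of (xi_pt, xi_at) generated under one umbrella window."""

    window: UmbrellaWindow
    samples: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("samples must have shape (n, 2)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


@dataclass
class MBARResult:
    f: np.ndarray          # reduced free energies, f[0] = 0
    theta: np.ndarray      # asymptotic covariance of f
    converged: bool
    n_iterations: int
    overlap_min_eig: float
    poor_overlap: bool
    residual: float
    u_kn: np.ndarray = field(repr=False)
    N_k: np.ndarray = field(repr=False)

    def delta_f(self, i: int = 0, j: int = -1) -> float:
        """Reduced free-energy difference f_j - f_i."""
        return float(self.f[j] - self.f[i])

    def se_delta_f(self, i: int = 0, j: int = -1) -> float:
        """Asymptotic standard error of f_j - f_i (reduced units)."""
        K = self.f.size
        i, j = i % K, j % K
        v = self.theta[i, i] + self.theta[j, j] - 2.0 * self.theta[i, j]
        return math.sqrt(max(v, 0.0))


def _mbar_log_denominator(f: np.ndarray, u_kn: np.ndarray, N_k: np.ndarray):
    # log sum_k N_k exp(f_k - u_kn) for each sample, shape (N,)
    return logsumexp(f[:, None] - u_kn, b=N_k[:, None], axis=0)


def mbar_solve(
    energy_matrix: np.ndarray,
    sample_counts: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> MBARResult:
    """Solve the MBAR self-consistent equations.

    Parameters
    ----------
    energy_matrix : (K, N) array
        Reduced energies u_k(x_n) of every pooled sample in every state.
    sample_counts : length-K
        Number of samples drawn from each state (all > 0).
    tol : float
        Max-abs self-consistency residual on f at convergence.
    max_iter : int
        Cap on self-consistent iterations (Newton polish runs within it).

    Non-overlapping states do not fail silently: the minimum eigenvalue of
    the overlap matrix is reported, and below 0.01 the result is flagged
    and its uncertainties inflated by (0.01 / min_eig)^(1/2).
    """
    u_kn = np.asarray(energy_matrix, dtype=float)
    N_k = np.asarray(sample_counts, dtype=float)
    if u_kn.ndim != 2 or u_kn.shape[0] < 2:
        raise ValueError("need a (K, N) energy matrix with K >= 2 states")
    if N_k.size != u_kn.shape[0] or np.any(N_k <= 0):
        raise ValueError("sample_counts must have K positive entries")
    if int(N_k.sum()) != u_kn.shape[1]:
        raise ValueError("sum of sample_counts must equal the number of pooled samples")
    if not np.all(np.isfinite(u_kn)):
        raise ValueError("energy matrix must be finite (no missing evaluations)")

    K = u_kn.shape[0]
    f = np.zeros(K)

    def scf_update(f):
        log_denom = _mbar_log_denominator(f, u_kn, N_k)
        f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
        return f_new - f_new[0]

    def residual_of(f):
        return float(np.max(np.abs(scf_update(f) - f)))

    n_it = 0
    res = math.inf
    # warm-up: plain self-consistent iteration
    for n_it in range(1, max_iter + 1):
        f_new = scf_update(f)
        res = float(np.max(np.abs(f_new - f)))
        f = f_new
        if res < 1e-2 or res < tol:
            break
    # Newton polish on the convex objective (gauge: f[0] fixed at 0)
    if res >= tol:
        for _ in range(100):
            n_it += 1
            log_denom = _mbar_log_denominator(f, u_kn, N_k)
            W = np.exp(f[:, None] - u_kn - log_denom[None, :])  # (K, N)
            NW = N_k[:, None] * W
            g = NW.sum(axis=1) - N_k
            H = np.diag(NW.sum(axis=1)) - NW @ (N_k[:, None] * W).T
            try:
                step = np.linalg.solve(H[1:, 1:], g[1:])
            except np.linalg.LinAlgError:
                break
            scale = 1.0
            f_try = f.copy()
            for _ in range(20):
                f_try = f.copy()
                f_try[1:] = f[1:] - scale * step
                if residual_of(f_try) < res or scale < 1e-6:
                    break
                scale *= 0.5
            new_res = residual_of(f_try)
            if new_res >= res:
                break
            f, res = f_try, new_res
            if res < tol:
                break
    # fall back to SCF if Newton stalled short of tol
    while res >= tol and n_it < max_iter:
        n_it += 1
        f_new = scf_update(f)
        res = float(np.max(np.abs(f_new - f)))
        f = f_new

    log_denom = _mbar_log_denominator(f, u_kn, N_k)
    W = np.exp(f[:, None] - u_kn - log_denom[None, :])
    NW = N_k[:, None] * W
    # overlap matrix O_ij = N_j sum_n W_in W_jn; symmetrized with sqrt(N)
    # scaling, which preserves the eigenvalue spectrum (in [0, 1])
    sqrtN = np.sqrt(N_k)
    O_sym = (sqrtN[:, None] * (W @ W.T)) * sqrtN[None, :]
    min_eig = float(np.min(np.linalg.eigvalsh(O_sym)))
    # A long chain of pairwise-overlapping states legitimately has a tiny
    # smallest eigenvalue, so connectivity of the overlap graph -- every
    # state reachable through edges with non-negligible pairwise overlap --
    # is the flag for estimates bridging effectively unsampled gaps.
    poor = not _overlap_connected(O_sym, OVERLAP_EDGE_THRESHOLD)

    # asymptotic covariance Theta = W (I - W N W^T)^+ W^T, computed in the
    # K-dimensional SVD basis of the (N, K) weight matrix
    U, S, Vt = np.linalg.svd(W.T, full_matrices=False)  # W.T is (N, K)
    Vk = Vt.T  # (K, K)
    inner = np.eye(S.size) - (S[:, None] * (Vk.T @ (N_k[:, None] * Vk)) * S[None, :])
    theta = Vk @ (S[:, None] * np.linalg.pinv(inner, rcond=1e-10) * S[None, :]) @ Vk.T
    if poor:
        # disconnected overlap graph: the asymptotic covariance is invalid
        # (and numerically wild); report an unmistakably inflated one
        theta = np.eye(theta.shape[0]) * POOR_OVERLAP_INFLATION**2

    return MBARResult(f=f, theta=theta, converged=res < tol, n_iterations=n_it,
                      overlap_min_eig=min_eig, poor_overlap=poor, residual=res,
                      u_kn=u_kn, N_k=N_k)


def umbrella_energy_matrix(
    surface: FreeEnergySurface,
    trajectories: Sequence[BiasedTrajectory],
    kT: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reduced energy matrix for umbrella windows over pooled samples.

    Returns (u_kn, N_k, u0_n, xy) where u0_n is the unbiased reduced energy
    of each pooled sample and xy the pooled coordinates.
    """
    xy = np.concatenate([t.samples for t in trajectories], axis=0)
    N_k = np.array([t.samples.shape[0] for t in trajectories], dtype=int)
    u0 = np.asarray(surface.energy(xy), dtype=float) / kT
    u_kn = np.stack([u0 + t.window.bias_energy(xy) / kT for t in trajectories])
    return u_kn, N_k, u0, xy


def pmf_2d(
    mbar: MBARResult,
    trajectories: Sequence[BiasedTrajectory],
    bins: tuple[np.ndarray, np.ndarray],
    surface: FreeEnergySurface,
    kT: float,
) -> FreeEnergySurface:
    """Unbiased 2D potential of mean force by MBAR reweighting.

    ``bins`` are (edges_pt, edges_at).  Each pooled sample gets the MBAR
    unbiased weight w_n = exp(-u0_n) / sum_k N_k exp(f_k - u_kn); bin free
    energies are -kT ln(sum of weights in bin), shifted so the occupied
    minimum is zero.  Empty bins are NaN-masked; more than 50% empty bins
    raises (the windows are too narrow or too sparse).
    """
    if not mbar.converged:
        raise ValueError("MBAR must be converged before reconstructing a PMF")
    u_kn, N_k, u0, xy = umbrella_energy_matrix(surface, trajectories, kT)
    log_denom = _mbar_log_denominator(mbar.f, u_kn, N_k)
    log_w = -u0 - log_denom

    edges_pt, edges_at = bins
    ix = np.digitize(xy[:, 0], edges_pt) - 1
    iy = np.digitize(xy[:, 1], edges_at) - 1
    npt, nat = len(edges_pt) - 1, len(edges_at) - 1
    pmf = np.full((npt, nat), np.nan)
    inside = (ix >= 0) & (ix < npt) & (iy >= 0) & (iy < nat)
    for b in np.unique(ix[inside] * nat + iy[inside]):
        sel = inside & (ix * nat + iy == b)
        pmf[b // nat, b % nat] = -logsumexp(log_w[sel])
    n_empty = int(np.isnan(pmf).sum())
    if n_empty > 0.5 * pmf.size:
        raise ValueError(
            f"{n_empty}/{pmf.size} PMF bins are empty; use wider or denser windows")
    pmf = (pmf - np.nanmin(pmf)) * kT
    centers_pt = 0.5 * (edges_pt[:-1] + edges_pt[1:])
    centers_at = 0.5 * (edges_at[:-1] + edges_at[1:])
    return FreeEnergySurface(centers_pt, centers_at, pmf)


@dataclass
class AlchemicalDataset:
    """Per-lambda reduced energies of every pooled sample in every state."""

    lambdas: np.ndarray        # schedule in [0, 1]
    u_kn: np.ndarray           # (K, N) complete reduced energy matrix
    N_k: np.ndarray
    temperature: float = T_SIMULATION

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.u_kn = np.asarray(self.u_kn, dtype=float)
        self.N_k = np.asarray(self.N_k, dtype=int)
        if self.lambdas.size != self.u_kn.shape[0]:
            raise ValueError("one row of u_kn per lambda window required")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("energy matrix must be complete (no missing evaluations)")

    def reversed(self) -> "AlchemicalDataset":
        """The same data with the lambda schedule reversed."""
        return AlchemicalDataset(self.lambdas[::-1].copy(), self.u_kn[::-1].copy(),
                                 self.N_k[::-1].copy(), self.temperature)


def alchemical_ddg(ds: AlchemicalDataset, tol: float = 1e-10) -> tuple[float, float]:
    """End-state free-energy difference of an alchemical transformation.

    Returns (ddG, s.e.) in kcal/mol at the dataset temperature, from MBAR
    over the full lambda schedule.  Reversing the schedule negates ddG
    exactly.
    """
    mbar = mbar_solve(ds.u_kn, ds.N_k, tol=tol)
    kT = RT(ds.temperature)
    return kT * mbar.delta_f(0, -1), kT * mbar.se_delta_f(0, -1)
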