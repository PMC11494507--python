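"""Generators for every input the analysis stages consume, with known truth.

The generators emulate the study conditions of the MTR1 system: biphasic
first-order progress curves with an inactive-fold slow fraction and
additive gel-densitometry noise; observed-rate datasets over pH 5.5-8.5
with multiplicative log-normal noise; MTR1-like free-energy surfaces with
reactant/intermediate/product basins and two saddles; overdamped Langevin
sampling under harmonic umbrella restraints; and per-lambda alchemical
samples with an analytically known free-energy difference.  Everything is
exactly reproducible from (seed, parameters).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, root

from .constants import RT, T_SIMULATION
from .kinetics import TimeCourse
from .landscape import FreeEnergySurface
from .ph_profiles import PHRateDataset, model_double_pka, model_single_pka
from .sampling_fe import AlchemicalDataset, BiasedTrajectory, UmbrellaWindow

__all__ = [
    "KineticsSpec",
    "GaussianComponent",
    "SurfaceSpec",
    "LangevinSpec",
    "gen_time_course",
    "gen_ph_rate_data",
    "gen_surface",
    "mtr1_surface_spec",
    "gen_biased_trajectories",
    "gen_alchemical_samples",
    "time_course_to_csv",
    "ph_dataset_to_csv",
]


# ---------------------------------------------------------------------------
# kinetic time courses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsSpec:
    """Ground truth for one biphasic progress curve.

    k_fast/k_slow in min^-1 (k_fast >= k_slow > 0); frac_fast is the
    initially active-fold fraction; plateau the shared saturation level;
    noise_sd an additive Gaussian s.d. on the fraction (gel densitometry).
    """

    k_fast: float
    k_slow: float
    frac_fast: float
    plateau: float
    times: tuple[float, ...]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.k_fast >= self.k_slow > 0):
            raise ValueError("need k_fast >= k_slow > 0")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise ValueError("frac_fast must be in [0, 1]")
        if not 0.0 < self.plateau <= 1.0:
            raise ValueError("plateau must be in (0, 1]")
        t = np.asarray(self.times, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValueError("times must be strictly increasing and non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def biphasic_fraction(t, k_fast, k_slow, frac_fast, plateau):
    """Noise-free shared-plateau biphasic progress model."""
    t = np.asarray(t, dtype=float)
    return plateau * (frac_fast * (1.0 - np.exp(-k_fast * t))
                      + (1.0 - frac_fast) * (1.0 - np.exp(-k_slow * t)))


def gen_time_course(spec: KineticsSpec, variant_id: str = "synthetic",
                    pH: float = 6.0) -> TimeCourse:
    """Generate one progress curve; values are reported unclipped."""
    t = np.asarray(spec.times, dtype=float)
    y = biphasic_fraction(t, spec.k_fast, spec.k_slow, spec.frac_fast, spec.plateau)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=t.size)
    return TimeCourse(t, y, variant_id=variant_id, pH=pH)


# ---------------------------------------------------------------------------
# pH-rate datasets
# ---------------------------------------------------------------------------

def gen_ph_rate_data(
    k_int: float,
    pka_acid: float,
    ph_grid: Sequence[float],
    cv: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    pka_nuc: float | None = None,
    variant_id: str = "synthetic",
) -> PHRateDataset:
    """Replicate observed rates over a pH grid with log-normal noise.

    The noise multiplier is exp(N(0, sigma)) with sigma chosen so the
    coefficient of variation equals ``cv``; its median is 1, so fits in
    log-rate space are unbiased.  ``cv = 0`` reproduces the model exactly.
    """
    if k_int <= 0:
        raise ValueError("k_int must be positive")
    if len(ph_grid) == 0:
        raise ValueError("ph_grid must be non-empty")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    ph = np.asarray(ph_grid, dtype=float)
    if pka_nuc is None:
        model = model_single_pka(ph, k_int, pka_acid)
    else:
        model = model_double_pka(ph, k_int, pka_acid, pka_nuc)
    model = np.atleast_1d(model)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    rows = []
    for rep in range(n_reps):
        mult = np.exp(rng.normal(0.0, sigma, size=ph.size)) if sigma > 0 else 1.0
        for p, k in zip(ph, model * mult):
            rows.append({"pH": p, "k_obs": k, "replicate": rep})
    return PHRateDataset(variant_id, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# free-energy surfaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian term: negative depth = basin, positive = ridge."""

    center_pt: float
    center_at: float
    depth: float          # kcal/mol; sign carries basin/ridge
    width_pt: float       # angstrom
    width_at: float

    def __post_init__(self) -> None:
        if self.width_pt <= 0 or self.width_at <= 0:
            raise ValueError("widths must be positive")


@dataclass(frozen=True)
class SurfaceSpec:
    """Gaussian-mixture surface specification on a uniform grid."""

    gaussian_components: tuple[GaussianComponent, ...]
    extent_pt: tuple[float, float] = (-3.5, 3.5)
    extent_at: tuple[float, float] = (-4.5, 4.5)
    grid_spacing: float = 0.05

    def __post_init__(self) -> None:
        if len(self.gaussian_components) == 0:
            raise ValueError("at least one Gaussian component is required")
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")


def _mixture_energy(components, xy: np.ndarray) -> np.ndarray:
    xy = np.asarray(xy, dtype=float)
    g = np.zeros(xy.shape[:-1])
    for c in components:
        dx = (xy[..., 0] - c.center_pt) / c.width_pt
        dy = (xy[..., 1] - c.center_at) / c.width_at
        g = g + c.depth * np.exp(-0.5 * (dx * dx + dy * dy))
    return g


def _mixture_grad(components, xy: np.ndarray) -> np.ndarray:
    xy = np.asarray(xy, dtype=float)
    g = np.zeros_like(xy)
    for c in components:
        dx = (xy[..., 0] - c.center_pt) / c.width_pt
        dy = (xy[..., 1] - c.center_at) / c.width_at
        e = c.depth * np.exp(-0.5 * (dx * dx + dy * dy))
        g[..., 0] += e * (-dx / c.width_pt)
        g[..., 1] += e * (-dy / c.width_at)
    return g


def _mixture_hess(components, xy: np.ndarray) -> np.ndarray:
    x, y = float(xy[0]), float(xy[1])
    H = np.zeros((2, 2))
    for c in components:
        dx = (x - c.center_pt) / c.width_pt
        dy = (y - c.center_at) / c.width_at
        e = c.depth * math.exp(-0.5 * (dx * dx + dy * dy))
        H[0, 0] += e * (dx * dx - 1.0) / c.width_pt**2
        H[1, 1] += e * (dy * dy - 1.0) / c.width_at**2
        H[0, 1] += e * dx * dy / (c.width_pt * c.width_at)
    H[1, 0] = H[0, 1]
    return H


def _basin_minimum(components, x0) -> tuple[np.ndarray, float]:
    res = minimize(lambda p: _mixture_energy(components, p), np.asarray(x0, float),
                   jac=lambda p: _mixture_grad(components, p), method="BFGS",
                   options={"gtol": 1e-12})
    return res.x, float(res.fun)


def _saddle_between(components, a, b) -> tuple[np.ndarray, float]:
    """Saddle of the mixture near the line a-b: line max then gradient root."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    ts = np.linspace(0.05, 0.95, 181)
    line = a[None, :] * (1 - ts[:, None]) + b[None, :] * ts[:, None]
    x0 = line[np.argmax(_mixture_energy(components, line))]
    sol = root(lambda p: _mixture_grad(components, p), x0,
               jac=lambda p: _mixture_hess(components, p), tol=1e-13)
    x = sol.x if sol.success else x0
    eig = np.linalg.eigvalsh(_mixture_hess(components, x))
    if not (eig[0] < 0 < eig[1]):  # fell into a minimum/maximum: keep line max
        x = x0
    return x, float(_mixture_energy(components, x))


def gen_surface(spec: SurfaceSpec) -> FreeEnergySurface:
    """Evaluate the Gaussian mixture on the grid, reactant basin at zero.

    The reactant anchor is the first negative-depth component; its
    continuous basin minimum defines the zero of free energy.  Components
    centered outside the grid only warn (their tails still contribute).
    """
    lo_pt, hi_pt = spec.extent_pt
    lo_at, hi_at = spec.extent_at
    for c in spec.gaussian_components:
        if not (lo_pt <= c.center_pt <= hi_pt and lo_at <= c.center_at <= hi_at):
            warnings.warn(
                f"component centered at ({c.center_pt}, {c.center_at}) "
                "lies outside the grid", stacklevel=2)
    n_pt = int(round((hi_pt - lo_pt) / spec.grid_spacing)) + 1
    n_at = int(round((hi_at - lo_at) / spec.grid_spacing)) + 1
    axis_pt = np.linspace(lo_pt, hi_pt, n_pt)
    axis_at = np.linspace(lo_at, hi_at, n_at)
    xx, yy = np.meshgrid(axis_pt, axis_at, indexing="ij")
    grid = np.stack([xx, yy], axis=-1)
    values = _mixture_energy(spec.gaussian_components, grid)
    basins = [c for c in spec.gaussian_components if c.depth < 0]
    if basins:
        anchor = basins[0]
        _, gmin = _basin_minimum(spec.gaussian_components,
                                 (anchor.center_pt, anchor.center_at))
        values = values - gmin
    return FreeEnergySurface(axis_pt, axis_at, values)


def mtr1_surface_spec(
    barrier: float = 16.3,
    ts2_xi_at: float = -0.24,
    grid_spacing: float = 0.05,
    n_calibration_iter: int = 40,
) -> SurfaceSpec:
    """Canonical MTR1-like surface preset.

    Three basins — reactant R near (-1.5, -2.5), intermediate I (proton
    transferred, alkyl not yet) near (1.35, -1.9), product P at (1.5, 2.5) —
    with a low proton-transfer saddle TS1 between R and I and the
    rate-controlling alkyl-transfer saddle TS2 between I and P.

    The preset is calibrated deterministically on the continuous mixture: a
    fixed-point iteration solves the reactant depth so that the TS2 saddle
    sits exactly ``barrier`` kcal/mol above the reactant minimum (default
    16.3), and shifts the intermediate basin so the saddle's xi_at equals
    ``ts2_xi_at`` (default -0.24 A, an "early" transition state).
    """
    d_r = barrier + 1.5   # refined by the fixed point below
    y_i = -1.9
    components = ()
    for _ in range(n_calibration_iter):
        components = (
            GaussianComponent(-1.5, -2.5, -d_r, 0.8, 0.8),          # R
            GaussianComponent(1.35, y_i, -(d_r - 2.5), 0.8, 0.8),   # I
            GaussianComponent(1.5, 2.5, -(d_r + 2.0), 0.9, 0.9),    # P
        )
        _, g_r = _basin_minimum(components, (-1.5, -2.5))
        s_pos, s_val = _saddle_between(components, (1.35, y_i), (1.5, 2.5))
        d_r += (barrier - (s_val - g_r)) / 0.9
        y_i += 1.8 * (ts2_xi_at - s_pos[1])
    # verify the calibration actually closed
    _, g_r = _basin_minimum(components, (-1.5, -2.5))
    s_pos, s_val = _saddle_between(components, (1.35, y_i), (1.5, 2.5))
    if abs((s_val - g_r) - barrier) > 1e-6 or abs(s_pos[1] - ts2_xi_at) > 1e-6:
        raise RuntimeError("surface preset calibration did not converge")
    return SurfaceSpec(components, grid_spacing=grid_spacing)


# ---------------------------------------------------------------------------
# umbrella-window Langevin sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LangevinSpec:
    """Overdamped (Euler-Maruyama) Langevin sampling parameters.

    kT in kcal/mol; step_size and friction in reduced units.  The first
    10% of steps are discarded as burn-in.
    """

    kT: float
    step_size: float = 0.002
    n_steps: int = 5000
    friction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.step_size <= 0 or self.friction <= 0:
            raise ValueError("step_size and friction must be positive")


BURN_IN_FRACTION = 0.1


def gen_biased_trajectories(
    surface: FreeEnergySurface,
    windows: Sequence[UmbrellaWindow],
    spec: LangevinSpec,
) -> list[BiasedTrajectory]:
    """Overdamped Langevin sampling of G + harmonic bias per window.

    All windows are propagated in lock-step from their centers with
    per-window independent noise streams spawned from ``spec.seed``; the
    first 10% of steps are discarded as burn-in and, if a window requests
    fewer samples than remain, the chain is thinned evenly.  A sample
    leaving the grid hull (or producing a non-finite energy) aborts with an
    error advising a smaller step size.
    """
    centers = np.array([w.center for w in windows], dtype=float)
    surface._check_hull(centers)
    k_bias = np.array([w.force_constants for w in windows], dtype=float)

    n_burn = int(BURN_IN_FRACTION * spec.n_steps)
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(spec.seed).spawn(len(windows))]

    x = centers.copy()
    dt, gamma, kT = spec.step_size, spec.friction, spec.kT
    noise_scale = math.sqrt(2.0 * kT * dt / gamma)
    kept: list[list[np.ndarray]] = [[] for _ in windows]
    for step in range(spec.n_steps):
        try:
            grad = surface.gradient(x)
        except ValueError as exc:
            raise ValueError(
                "trajectory left the surface grid; use a smaller step_size "
                f"or stiffer restraints ({exc})") from exc
        grad = grad + k_bias * (x - centers)
        noise = np.stack([r.normal(0.0, 1.0, size=2) for r in rngs])
        x = x - (dt / gamma) * grad + noise_scale * noise
        if not np.all(np.isfinite(x)):
            raise ValueError("energy overflow during sampling; use a smaller step_size")
        if step >= n_burn:
            for i in range(len(windows)):
                kept[i].append(x[i].copy())

    out = []
    for w, samples in zip(windows, kept):
        arr = np.asarray(samples)
        if w.n_samples < arr.shape[0]:
            idx = np.linspace(0, arr.shape[0] - 1, w.n_samples).round().astype(int)
            arr = arr[idx]
        out.append(BiasedTrajectory(w, arr))
    return out


# ---------------------------------------------------------------------------
# alchemical samples
# ---------------------------------------------------------------------------

def gen_alchemical_samples(
    ddg_true: float,
    n_windows: int = 25,
    n_per_window: int = 500,
    overlap: float = 1.0,
    seed: int = 0,
    temperature: float = T_SIMULATION,
) -> AlchemicalDataset:
    """Gaussian per-lambda states whose end-to-end free-energy gap is known.

    Window i samples x ~ N(mu_i, 1) with mu_i spaced by 1/``overlap``
    standard deviations; reduced energies are u_i(x) = (x - mu_i)^2/2 + c_i
    with offsets c_i linear in lambda so that the analytic end-to-end
    difference equals ``ddg_true`` kcal/mol at ``temperature``.  The
    distributions are exact stand-ins for per-lambda sampling: only the
    estimator downstream is of interest.
    """
    if n_windows < 2:
        raise ValueError("need at least 2 lambda windows")
    if overlap <= 0:
        raise ValueError("overlap must be positive (the estimator would not converge)")
    kT = RT(temperature)
    lambdas = np.linspace(0.0, 1.0, n_windows)
    mu = np.arange(n_windows) / overlap
    c = lambdas * (ddg_true / kT)
    rng = np.random.default_rng(seed)
    xs = np.concatenate([rng.normal(m, 1.0, size=n_per_window) for m in mu])
    u_kn = 0.5 * (xs[None, :] - mu[:, None]) ** 2 + c[:, None]
    N_k = np.full(n_windows, n_per_window)
    return AlchemicalDataset(lambdas, u_kn, N_k, temperature)


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def time_course_to_csv(tc: TimeCourse, path) -> None:
    pd.DataFrame({
        "time_min": tc.times, "fraction": tc.fractions,
        "variant": tc.variant_id, "pH": tc.pH,
    }).to_csv(path, index=False, float_format="%.10g")


def ph_dataset_to_csv(ds: PHRateDataset, path) -> None:
    df = ds.data.copy()
    df.insert(0, "variant", ds.variant_id)
    df.to_csv(path, index=False, float_format="%.10g")
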