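"""Gridded 2D free-energy surfaces and the minimum free-energy path.

Surfaces live on a uniform grid over the two reaction coordinates
(difference-of-distances, in angstroms):

* ``xi_pt`` — proton transfer, R(C10:N3-H) - R(O6alkG:N1-H)
* ``xi_at`` — alkyl transfer, R(O6alkG:O6-CR) - R(A63:N1-CR)

with free energies in kcal/mol and the reactant-basin minimum at zero.
Negative coordinates are the reactant side: the reactant basin sits near
(-1.5, -2.5) and the product basin near (1.5, 2.5).

The string method discretizes a path into images, repeatedly moves each
interior image downhill along the gradient component perpendicular to the
path tangent, and reparameterizes to equal arc length.  Its converged
maxima are the transition states; the highest is the rate-controlling
barrier.  Here the mean forces of a sampled system are replaced by the
interpolated gradient of the gridded surface (the surface itself is the
stand-in for sampling).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, RectBivariateSpline

__all__ = [
    "FreeEnergySurface",
    "PathString",
    "ReactionProfile",
    "read_surface",
    "write_surface",
    "string_mfep",
    "profile_along_path",
    "ts_coordinates",
]


@dataclass
class FreeEnergySurface:
    """G(xi_pt, xi_at) on a uniform rectangular grid, kcal/mol and angstrom.

    ``values[i, j]`` corresponds to (axis_pt[i], axis_at[j]).  NaN entries
    are permitted only to mask unsampled bins of reconstructed PMFs; a
    surface containing NaN cannot be interpolated.
    """

    axis_pt: np.ndarray
    axis_at: np.ndarray
    values: np.ndarray
    _spline: RectBivariateSpline | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.axis_pt = np.asarray(self.axis_pt, dtype=float)
        self.axis_at = np.asarray(self.axis_at, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for name, ax in (("axis_pt", self.axis_pt), ("axis_at", self.axis_at)):
            if ax.ndim != 1 or ax.size < 2:
                raise ValueError(f"{name} must be a 1D grid with >= 2 points")
            d = np.diff(ax)
            if np.any(d <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-8, atol=1e-12):
                raise ValueError(f"{name} must be uniformly spaced")
        if self.values.shape != (self.axis_pt.size, self.axis_at.size):
            raise ValueError("values shape must be (len(axis_pt), len(axis_at))")
        if np.any(np.isinf(self.values)):
            raise ValueError("surface values must not be infinite")

    @property
    def has_mask(self) -> bool:
        return bool(np.any(np.isnan(self.values)))

    def _ensure_spline(self) -> RectBivariateSpline:
        if self._spline is None:
            if self.has_mask:
                raise ValueError("cannot interpolate a surface with masked (NaN) bins")
            self._spline = RectBivariateSpline(
                self.axis_pt, self.axis_at, self.values, kx=3, ky=3, s=0)
        return self._spline

    def _check_hull(self, pts: np.ndarray) -> None:
        lo = (self.axis_pt[0], self.axis_at[0])
        hi = (self.axis_pt[-1], self.axis_at[-1])
        for d in range(2):
            bad = (pts[..., d] < lo[d]) | (pts[..., d] > hi[d])
            if np.any(bad):
                coord = np.atleast_2d(pts)[np.atleast_2d(bad).any(axis=-1)][0]
                raise ValueError(
                    f"point {tuple(coord)} outside grid hull "
                    f"[{lo[0]}, {hi[0]}] x [{lo[1]}, {hi[1]}]")

    def energy(self, points) -> np.ndarray | float:
        """Bicubic-interpolated G at (xi_pt, xi_at) point(s)."""
        pts = np.asarray(points, dtype=float)
        self._check_hull(pts)
        sp = self._ensure_spline()
        flat = pts.reshape(-1, 2)
        g = sp.ev(flat[:, 0], flat[:, 1])
        return float(g[0]) if pts.ndim == 1 else g.reshape(pts.shape[:-1])

    def gradient(self, points) -> np.ndarray:
        """Analytic gradient of the bicubic interpolant at point(s)."""
        pts = np.asarray(points, dtype=float)
        self._check_hull(pts)
        sp = self._ensure_spline()
        flat = pts.reshape(-1, 2)
        gx = sp.ev(flat[:, 0], flat[:, 1], dx=1)
        gy = sp.ev(flat[:, 0], flat[:, 1], dy=1)
        g = np.stack([gx, gy], axis=-1)
        return g[0] if pts.ndim == 1 else g.reshape(pts.shape)

    def interpolate(self, point) -> tuple[float, np.ndarray]:
        """(G, gradient) at one point; errors outside the grid hull."""
        return self.energy(point), self.gradient(point)


def write_surface(surface: FreeEnergySurface, path_or_buf) -> None:
    """Write the plain-text grid format (12 significant digits, row-major)."""
    buf = io.StringIO()
    ap, aa = surface.axis_pt, surface.axis_at
    buf.write(f"# axis_pt: {ap[0]:.12g} {ap[-1]:.12g} {ap.size}\n")
    buf.write(f"# axis_at: {aa[0]:.12g} {aa[-1]:.12g} {aa.size}\n")
    buf.write("# units: kcal/mol Angstrom\n")
    for row in surface.values:
        buf.write(" ".join(f"{v:.12g}" for v in row) + "\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_surface(path_or_buf) -> FreeEnergySurface:
    """Read the plain-text grid format written by :func:`write_surface`."""
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    header = [ln for ln in lines if ln.startswith("#")]
    body = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    axes = {}
    for ln in header:
        for key in ("axis_pt", "axis_at"):
            if ln.startswith(f"# {key}:"):
                start, stop, n = ln.split(":", 1)[1].split()
                axes[key] = np.linspace(float(start), float(stop), int(n))
    if set(axes) != {"axis_pt", "axis_at"}:
        raise ValueError("missing axis header lines")
    values = np.array([[float(v) for v in ln.split()] for ln in body])
    return FreeEnergySurface(axes["axis_pt"], axes["axis_at"], values)


@dataclass
class PathString:
    """Discretized path on a surface: ordered images at equal arc length."""

    images: np.ndarray  # (n_images, 2)
    arc_parameter: np.ndarray  # normalized [0, 1]
    converged: bool
    iterations_run: int

    @property
    def n_images(self) -> int:
        return int(self.images.shape[0])


def _reparameterize(images: np.ndarray, n_passes: int = 6) -> np.ndarray:
    """Resample the polyline at equal arc length (iterated chord equalization)."""
    pts = images
    for _ in range(n_passes):
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] == 0:
            return images.copy()
        target = np.linspace(0.0, s[-1], len(pts))
        pts = np.stack([np.interp(target, s, pts[:, d]) for d in range(2)], axis=1)
    return pts


def string_mfep(
    surface: FreeEnergySurface,
    start,
    end,
    n_images: int = 32,
    max_iter: int = 30,
    step: float = 0.01,
    tol: float = 1e-4,
    max_move: float = 0.1,
) -> PathString:
    """Relax a linear path to the minimum free-energy path on ``surface``.

    Images are initialized on the straight segment from ``start`` to
    ``end`` (both held fixed), then iterated: perpendicular gradient
    descent with step control, followed by equal-arc-length
    reparameterization.  Stops when the maximum image displacement over an
    iteration falls below ``tol`` (angstrom) or after ``max_iter``
    iterations; 32 images and 30 iterations are the conventional defaults,
    and ``max_iter`` can be raised to run to full convergence.

    If a step raises the interpolated energy on more than half the interior
    images, the step is halved; after 10 consecutive halvings a RuntimeError
    advises a smaller initial step.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    surface._check_hull(np.stack([start, end]))
    frac = np.linspace(0.0, 1.0, n_images)[:, None]
    images = start[None, :] * (1 - frac) + end[None, :] * frac

    eps = 1e-9
    lo = np.array([surface.axis_pt[0] + eps, surface.axis_at[0] + eps])
    hi = np.array([surface.axis_pt[-1] - eps, surface.axis_at[-1] - eps])

    cur_step = float(step)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = surface.gradient(images)
        # central-difference tangents, one-sided at the fixed endpoints
        tangent = np.empty_like(images)
        tangent[1:-1] = images[2:] - images[:-2]
        tangent[0] = images[1] - images[0]
        tangent[-1] = images[-1] - images[-2]
        norm = np.linalg.norm(tangent, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        tangent /= norm

        force = -grad
        f_par = np.sum(force * tangent, axis=1, keepdims=True) * tangent
        f_perp = force - f_par
        f_perp[0] = 0.0
        f_perp[-1] = 0.0

        e_before = surface.energy(images)
        halvings = 0
        while True:
            move = cur_step * f_perp
            # cap per-image displacement so stiff walls cannot fling images
            mlen = np.linalg.norm(move, axis=1, keepdims=True)
            over = mlen > max_move
            if np.any(over):
                safe = np.where(mlen > 0, mlen, 1.0)
                move = np.where(over, move * (max_move / safe), move)
            trial = np.clip(images + move, lo, hi)
            e_after = surface.energy(trial)
            n_up = int(np.sum(e_after[1:-1] > e_before[1:-1] + 1e-12))
            if n_up <= (n_images - 2) // 2:
                break
            cur_step *= 0.5
            halvings += 1
            if halvings > 10:
                raise RuntimeError(
                    "string step halved 10 times without progress; "
                    "retry with a smaller `step`")
        if halvings == 0:
            cur_step = min(cur_step * 1.05, step)
        new_images = _reparameterize(trial)
        new_images[0], new_images[-1] = start, end
        disp = float(np.max(np.linalg.norm(new_images - images, axis=1)))
        images = new_images
        if disp < tol:
            converged = True
            break

    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(images, axis=0), axis=1))])
    arc /= arc[-1] if arc[-1] > 0 else 1.0
    return PathString(images, arc, converged, it)


@dataclass
class ReactionProfile:
    """1D free energy along a path with labeled stationary states.

    ``states`` maps labels (R, TS1, I, TS2, P, ...) to (arc position,
    energy).  Energies are shifted so the first basin minimum is zero;
    ``rate_controlling_barrier`` is the profile maximum relative to that
    zero.
    """

    arc: np.ndarray
    energies: np.ndarray
    states: dict[str, tuple[float, float]]
    rate_controlling_barrier: float
    warning: str = ""


def _dense_path(path: PathString, n_per_segment: int = 20):
    """Cubic-spline the images and sample densely along the arc parameter."""
    cs = CubicSpline(path.arc_parameter, path.images, axis=0)
    s = np.linspace(0.0, 1.0, (path.n_images - 1) * n_per_segment + 1)
    return s, cs(s), cs


def _label_extrema(arc: np.ndarray, g: np.ndarray) -> dict[str, tuple[float, float]]:
    """Label alternating minima/maxima along the profile.

    Minima become R, I, I2, ..., P (first and last minima are R and P);
    maxima between them become TS1, TS2, ... in arc order.  On plateaus the
    leftmost extremal point is taken.
    """
    mins, maxs = [], []
    for i in range(1, len(g) - 1):
        if g[i] < g[i - 1] and g[i] <= g[i + 1]:
            mins.append(i)
        elif g[i] > g[i - 1] and g[i] >= g[i + 1]:
            maxs.append(i)
    # endpoints count as basin minima if the profile rises away from them
    if not mins or (len(g) > 1 and g[0] < g[1] and (not mins or mins[0] != 0)):
        mins.insert(0, 0)
    if len(g) > 1 and g[-1] < g[-2]:
        mins.append(len(g) - 1)
    mins = sorted(set(mins))
    states: dict[str, tuple[float, float]] = {}
    labels_min = []
    for idx, i in enumerate(mins):
        if idx == 0:
            labels_min.append("R")
        elif idx == len(mins) - 1:
            labels_min.append("P")
        else:
            labels_min.append("I" if len(mins) == 3 else f"I{idx}")
    for lab, i in zip(labels_min, mins):
        states[lab] = (float(arc[i]), float(g[i]))
    for k, i in enumerate(sorted(maxs)):
        states[f"TS{k + 1}"] = (float(arc[i]), float(g[i]))
    return states


def profile_along_path(
    surface: FreeEnergySurface, path: PathString, n_per_segment: int = 20
) -> ReactionProfile:
    """Free-energy profile along a path with stationary states labeled.

    The path is splined and sampled densely (``n_per_segment`` points per
    image segment) so barrier tops between images are not missed.  Energies
    are shifted so the reactant-basin minimum is zero.
    """
    warning = ""
    if not path.converged:
        warning = "path not converged; profile may not follow the MFEP"
        warnings.warn(warning, stacklevel=2)
    s, pts, _ = _dense_path(path, n_per_segment)
    g = np.asarray(surface.energy(pts), dtype=float)
    states = _label_extrema(s, g)
    shift = states.get("R", (0.0, float(g[0])))[1]
    g = g - shift
    states = {k: (a, e - shift) for k, (a, e) in states.items()}
    barrier = float(np.max(g))
    return ReactionProfile(s, g, states, barrier, warning)


def ts_coordinates(
    profile: ReactionProfile, path: PathString
) -> dict[str, tuple[float, float]]:
    """(xi_pt, xi_at) coordinates of each labeled transition state.

    A negative xi_at marks an "early" transition state: nucleophilic attack
    less advanced than leaving-group departure.  Returns an empty dict with
    no TS labeled.
    """
    _, _, cs = _dense_path(path)
    out: dict[str, tuple[float, float]] = {}
    for label, (arc_pos, _) in profile.states.items():
        if label.startswith("TS"):
            xy = cs(arc_pos)
            out[label] = (float(xy[0]), float(xy[1]))
    return out
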