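"""Progress-curve fitting for single-turnover alkyl-transfer kinetics.

Fast-reacting ribozyme preparations show biphasic progress curves: the fast
phase is the chemical (alkyl-transfer) step and is the reported rate; the
slow phase reflects a fraction of ribozyme initially folded in an inactive
conformation that must refold before reacting.  Slow reactions (roughly
below 0.01 min^-1) are monophasic because refolding outruns chemistry.

Model forms
-----------
single:  f(t) = plateau * (1 - exp(-k t))
double:  f(t) = plateau * [a*(1 - exp(-k_fast t)) + (1-a)*(1 - exp(-k_slow t))]

The double-exponential shares one plateau between phases; ``a`` is the fast
(active-fold) fraction.  Fits are damped least squares with multi-start
initialisation over a log-spaced rate grid (1e-5 to 1e2 min^-1) so that
widely separated timescales are found without manual guesses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TimeCourse",
    "KineticFit",
    "ReplicateSummary",
    "fit_single_exponential",
    "fit_double_exponential",
    "select_kinetic_model",
    "summarize_replicates",
    "read_time_courses",
    "fits_to_frame",
]

_RATE_GRID = np.logspace(-5, 2, 8)  # multi-start rate guesses, min^-1
_COST_TOL = 1e-10


@dataclass
class TimeCourse:
    """Observed fraction-modified versus time for one reaction.

    ``fractions`` are gel band fractions and may exceed [0, 1] slightly due
    to densitometry noise; they are deliberately not clipped before fitting.
    """

    times: np.ndarray
    fractions: np.ndarray
    variant_id: str = ""
    pH: float = float("nan")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.times.shape != self.fractions.shape:
            raise ValueError("times and fractions must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must be non-negative")
        lo, hi = self.fractions.min(initial=0), self.fractions.max(initial=0)
        if lo < -0.2 or hi > 1.2:
            raise ValueError(
                f"fractions outside the tolerated [-0.2, 1.2] band: [{lo}, {hi}]"
            )


@dataclass
class KineticFit:
    """Result of a progress-curve fit.

    ``k_fast`` is always the larger rate regardless of optimiser ordering;
    for a single-exponential fit ``k_slow``/``amp_slow`` are None and
    ``amp_fast`` is 1.  ``shared_plateau`` records the adopted convention
    that both phases saturate at one plateau.
    """

    model: Literal["single", "double"]
    k_fast: float
    k_slow: float | None
    amp_fast: float
    amp_slow: float | None
    plateau: float
    se_k_fast: float
    residual_rms: float
    converged: bool
    shared_plateau: bool = True
    message: str = ""


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and sample s.d. of the reported rate over >= 3 replicates."""

    mean_k: float
    sd_k: float
    n: int


def _single_model(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    lnk, plateau = theta
    return plateau * (1.0 - np.exp(-np.exp(lnk) * t))


def _double_model(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    # ordered parametrization: k_slow = k_fast * exp(-d) with d >= 0, so the
    # "fast" slot is the larger rate by construction
    lnkf, d, a, plateau = theta
    kf = np.exp(lnkf)
    ks = kf * np.exp(-d)
    return plateau * (a * (1.0 - np.exp(-kf * t)) + (1.0 - a) * (1.0 - np.exp(-ks * t)))


def _se_from_jac(res, i_lnk: int) -> float:
    """Standard error of ln k from the residual Jacobian; inf if singular."""
    n, p = res.jac.shape
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
        v = cov[i_lnk, i_lnk]
        return math.sqrt(v) if v >= 0 and np.isfinite(v) else math.inf
    except np.linalg.LinAlgError:
        return math.inf


def fit_single_exponential(tc: TimeCourse, fix_plateau: float | None = None) -> KineticFit:
    """Least-squares fit of plateau*(1 - exp(-k t)).

    Multi-start over a log-spaced rate grid plus a data-driven guess; rates
    are optimised in log space so k stays positive.  Non-convergence (or a
    degenerate flat curve) is flagged on the returned fit, never silent.

    ``fix_plateau`` pins the saturation level instead of fitting it — the
    convention for very slow reactions followed to partial completion,
    where the endpoint is known from a fast reference reaction on the same
    substrate and the free (k, plateau) pair would otherwise be strongly
    anti-correlated.
    """
    if tc.times.size < 3:
        raise ValueError("single-exponential fit needs at least 3 points")
    t, y = tc.times, tc.fractions
    if np.ptp(y) < 1e-12:
        # constant signal: no rate information at all
        return KineticFit("single", math.nan, None, 1.0, None,
                          float(np.mean(y)), math.inf, 0.0, False,
                          message="constant fractions; rate unidentifiable")
    ymax = max(float(np.max(y)), 1e-6)
    plateau0 = min(max(ymax, 1e-3), 1.2)

    starts = [np.array([math.log(k), plateau0]) for k in _RATE_GRID]
    # crude initial-slope guess
    if y[-1] > 0 and t[-1] > 0:
        k0 = max(-math.log(max(1.0 - 0.632 * min(y[-1] / plateau0, 0.99), 1e-9)) / t[-1], 1e-9)
        starts.append(np.array([math.log(k0), plateau0]))

    if fix_plateau is not None:
        if not 0.0 < fix_plateau <= 1.2:
            raise ValueError("fix_plateau must be in (0, 1.2]")

        def residual(th):
            return _single_model(np.array([th[0], fix_plateau]), t) - y

        lo, hi = [math.log(1e-9)], [math.log(1e4)]
        starts = [x0[:1] for x0 in starts]
    else:
        def residual(th):
            return _single_model(th, t) - y

        lo, hi = [math.log(1e-9), 1e-6], [math.log(1e4), 1.2]

    best = None
    for x0 in starts:
        try:
            res = least_squares(residual, x0, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # pragma: no cover - optimiser pathologies
            continue
        if best is None or res.cost < best.cost - _COST_TOL:
            best = res
    if best is None:
        return KineticFit("single", math.nan, None, 1.0, None, math.nan,
                          math.inf, math.inf, False, message="all starts failed")

    k = float(np.exp(best.x[0]))
    se_lnk = _se_from_jac(best, 0)
    rms = math.sqrt(2.0 * best.cost / t.size)
    converged = bool(best.success) and np.isfinite(se_lnk)
    msg = "" if converged else "degenerate or non-converged fit"
    plateau = fix_plateau if fix_plateau is not None else float(best.x[1])
    return KineticFit("single", k, None, 1.0, None, plateau,
                      k * se_lnk if np.isfinite(se_lnk) else math.inf,
                      rms, converged, message=msg)


def fit_double_exponential(tc: TimeCourse, separation_min: float = 20.0) -> KineticFit:
    """Fit the shared-plateau biphasic model; k_fast >= k_slow by construction.

    The phases are parametrized as (k_fast, k_slow = k_fast/separation) with
    the separation bounded below by ``separation_min`` (default 20-fold): the
    biphasic interpretation — chemistry in the fast phase, refolding of an
    initially inactive fraction in the slow phase — only exists for
    kinetically separated phases, and the bound prevents the unidentifiable
    regime where both exponentials chase the same timescale (or one phase
    collapses onto a single noisy point as an unresolvable jump).

    The multi-start grid spans fast rates 1e-4 to 1e1 min^-1 and separations
    30-1000x, and always includes the single-exponential solution
    (amp_fast = 1), which guarantees the double fit never ends with a larger
    residual RMS than the single fit on the same data (model nesting).
    """
    if tc.times.size < 5:
        raise ValueError("double-exponential fit needs at least 5 points")
    t, y = tc.times, tc.fractions
    plateau0 = min(max(float(np.max(y)), 1e-3), 1.2)
    d_min = math.log(separation_min)

    starts = [
        np.array([math.log(kf), math.log(r), 0.7, plateau0])
        for kf in (1e-4, 1e-2, 1e-1, 1.0, 10.0)
        for r in (30.0, 100.0, 1000.0)
        if math.log(r) > d_min
    ]
    single = fit_single_exponential(tc)
    if np.isfinite(single.k_fast) and single.k_fast > 0:
        starts.append(np.array([
            math.log(single.k_fast), 34.0, 1.0, max(single.plateau, 1e-3),
        ]))

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                lambda th: _double_model(th, t) - y,
                x0,
                bounds=([math.log(1e-7), d_min, 0.0, 1e-6],
                        [math.log(1e3), 35.0, 1.0, 1.2]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # pragma: no cover
            continue
        if best is None or res.cost < best.cost - _COST_TOL:
            best = res
    if best is None:
        return KineticFit("double", math.nan, math.nan, math.nan, math.nan,
                          math.nan, math.inf, math.inf, False,
                          message="all starts failed")

    kf = float(np.exp(best.x[0]))
    ks = float(kf * math.exp(-best.x[1]))
    a, plateau = float(best.x[2]), float(best.x[3])
    se_lnk = _se_from_jac(best, 0)
    rms = math.sqrt(2.0 * best.cost / t.size)
    converged = bool(best.success) and np.isfinite(se_lnk)
    if ks * t[-1] < 1.0:
        warnings.warn(
            "time course does not span the fitted slow phase; "
            "k_slow is weakly constrained", stacklevel=2)
    return KineticFit("double", kf, ks, a, 1.0 - a, plateau,
                      kf * se_lnk if np.isfinite(se_lnk) else math.inf,
                      rms, converged,
                      message="" if converged else "degenerate or non-converged fit")


def select_kinetic_model(
    tc: TimeCourse, rate_threshold: float = 0.01, rms_improvement: float = 0.20
) -> tuple[str, KineticFit]:
    """Choose between the mono- and biphasic models for one time course.

    Rule: fit both; report the double-exponential fit only when its fitted
    k_fast is at least ``rate_threshold`` (default 0.01 min^-1 — slower
    reactions are monophasic because refolding outruns chemistry) AND the
    double fit lowers residual RMS by more than ``rms_improvement``
    (default 20%).  Ties go to the single-exponential model.
    Returns (chosen model name, chosen fit).
    """
    single = fit_single_exponential(tc)
    try:
        double = fit_double_exponential(tc)
    except ValueError:
        return "single", single
    use_double = (
        double.converged
        and np.isfinite(double.k_fast)
        and double.k_fast >= rate_threshold
        and double.residual_rms < (1.0 - rms_improvement) * single.residual_rms
    )
    return ("double", double) if use_double else ("single", single)


def summarize_replicates(fits: Sequence[KineticFit]) -> ReplicateSummary:
    """Arithmetic mean and sample s.d. of k_fast over converged replicates.

    Requires at least three converged fits, matching the convention that
    reported rate constants are the mean and standard deviation of at least
    three independent experiments.
    """
    ks = [f.k_fast for f in fits if f.converged and np.isfinite(f.k_fast)]
    if len(ks) < 3:
        raise ValueError(
            "replicate summaries require >= 3 converged fits "
            "(rates are reported as mean +/- s.d. of >= 3 independent experiments)"
        )
    arr = np.asarray(ks)
    return ReplicateSummary(float(arr.mean()), float(arr.std(ddof=1)), len(ks))


def read_time_courses(path) -> list[TimeCourse]:
    """Read time courses from CSV with columns time_min, fraction, variant, pH."""
    df = pd.read_csv(path)
    out = []
    for (variant, ph), g in df.groupby(["variant", "pH"], sort=False):
        g = g.sort_values("time_min")
        out.append(TimeCourse(g["time_min"].to_numpy(), g["fraction"].to_numpy(),
                              variant_id=str(variant), pH=float(ph)))
    return out


def fits_to_frame(fits: Sequence[KineticFit]) -> pd.DataFrame:
    """Tidy table, one row per fit, with every KineticFit field."""
    return pd.DataFrame([vars(f) for f in fits])
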