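"""Transition-state-theory conversions and linear free-energy relationships.

Connects free-energy barriers (kcal/mol) with rate constants, alchemical
free-energy differences with pKa shifts, and nucleophile pKa with reactivity
through the Bronsted relation.  All functions are pure; temperature and the
transmission coefficient travel in a :class:`ThermoContext` so that the
simulation convention (298.15 K) and the experimental kinetics convention
(310.15 K) are never mixed silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import KB_OVER_H, RT, RT_ln10, T_SIMULATION

__all__ = [
    "ThermoContext",
    "BronstedInput",
    "BronstedFit",
    "eyring_rate",
    "relative_rate_from_barriers",
    "delta_pka_from_ddg",
    "ddg_from_delta_pka",
    "ribozyme_pka",
    "bronsted_beta",
]


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and transmission coefficient for rate conversions.

    Parameters
    ----------
    T : float
        Absolute temperature in kelvin. Defaults to the simulation
        temperature, 298.15 K.
    transmission_coefficient : float
        Eyring transmission coefficient (kappa), dimensionless, default 1.
    """

    T: float = T_SIMULATION
    transmission_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.transmission_coefficient <= 0:
            raise ValueError("transmission coefficient must be positive")


@dataclass(frozen=True)
class BronstedInput:
    """Nucleophile pKa / rate pairs for a Bronsted analysis.

    ``points`` holds (pKa, rate) tuples; rates may be absolute (min^-1)
    or relative — the slope is invariant to the rate unit.
    """

    points: Sequence[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("Bronsted analysis needs at least 2 (pKa, rate) points")
        for pka, rate in self.points:
            if rate <= 0:
                raise ValueError(f"rates must be positive, got {rate}")


@dataclass(frozen=True)
class BronstedFit:
    beta_nuc: float
    intercept: float
    se_beta: float | None  # only defined for > 2 points


def eyring_rate(dG_barrier: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Rate constant (s^-1) from an activation free energy via Eyring TST.

    k = kappa * (k_B T / h) * exp(-dG_barrier / RT), with the barrier in
    kcal/mol.  At 298.15 K the prefactor k_B*T/h is 6.212e12 s^-1.
    """
    prefactor = ctx.transmission_coefficient * KB_OVER_H * ctx.T
    return prefactor * math.exp(-dG_barrier / RT(ctx.T))


def relative_rate_from_barriers(
    dG_a: float, dG_b: float, ctx: ThermoContext = ThermoContext()
) -> float:
    """Fold change of the rate with barrier ``dG_b`` relative to ``dG_a``.

    Equals exp((dG_a - dG_b)/RT); Eyring prefactors cancel, so the
    transmission coefficient and prefactor play no role.  A lower second
    barrier gives a ratio > 1 (the second reaction is faster).
    """
    return math.exp((dG_a - dG_b) / RT(ctx.T))


def delta_pka_from_ddg(ddG: float, ctx: ThermoContext = ThermoContext()) -> float:
    """pKa shift from an alchemical deprotonation free-energy difference.

    dpKa = ddG / (RT ln10); RT*ln10 is 1.364 kcal/mol at 298.15 K, so
    +1.364 kcal/mol of extra deprotonation cost is +1 pKa unit.
    """
    return ddG / RT_ln10(ctx.T)


def ddg_from_delta_pka(dpka: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Inverse of :func:`delta_pka_from_ddg`: ddG = dpKa * RT ln10."""
    return dpka * RT_ln10(ctx.T)


def ribozyme_pka(pka_soln: float, dpka: float) -> float:
    """pKa of a group in the ribozyme: solution pKa plus the computed shift."""
    return pka_soln + dpka


def bronsted_beta(inp: BronstedInput) -> BronstedFit:
    """Bronsted slope beta_nuc: d log10(rate) / d pKa of the nucleophile.

    With two points this is the exact two-point slope; with more, the
    ordinary least-squares slope with its standard error.  A beta_nuc of
    ~0.5 indicates substantial bond formation to the nucleophile in the
    transition state.
    """
    pkas = np.array([p for p, _ in inp.points], dtype=float)
    logk = np.log10([r for _, r in inp.points])
    if np.ptp(pkas) == 0:
        raise ValueError("all pKa values identical; slope undefined")
    n = len(pkas)
    # OLS; for n == 2 this reduces to the exact two-point slope.
    A = np.vstack([pkas, np.ones(n)]).T
    coef, res, *_ = np.linalg.lstsq(A, logk, rcond=None)
    beta, intercept = float(coef[0]), float(coef[1])
    se_beta = None
    if n > 2:
        resid = logk - A @ coef
        s2 = float(resid @ resid) / (n - 2)
        sxx = float(np.sum((pkas - pkas.mean()) ** 2))
        se_beta = math.sqrt(s2 / sxx)
    return BronstedFit(beta_nuc=beta, intercept=intercept, se_beta=se_beta)
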