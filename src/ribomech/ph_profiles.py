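"""Activity-pH models, apparent-pKa fitting, and rate/pKa summary tables.

The observed rate of alkyl transfer falls with pH above ~6 because the
general acid (the N3-H of the nucleobase at position 10) must be protonated
to hand its proton to the O6-alkylguanine leaving group.  The single-pKa
model is the protonated-acid fraction times the intrinsic rate:

    k_obs(pH) = k_int / (1 + 10^(pH - pKa_acid))

The optional double-pKa model additionally requires the adenine N1
nucleophile to be deprotonated:

    k_obs(pH) = k_int / (1 + 10^(pH - pKa_acid)) / (1 + 10^(pKa_nuc - pH))

Fitting is done on log10(k_obs) because rates span five orders of magnitude
across variants.  Flat (pH-independent) data are flagged as unidentifiable
rather than assigned a spurious pKa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import T_SIMULATION
from .lfer_thermo import ThermoContext, eyring_rate

__all__ = [
    "PHRateDataset",
    "PHModelFit",
    "MechanismModel",
    "model_single_pka",
    "model_double_pka",
    "fit_ph_profile",
    "k_int_from_point",
    "relative_rate_table",
    "round_sig",
    "ActivityProfile",
    "build_computed_profile",
    "normalize_profiles",
]


@dataclass
class PHRateDataset:
    """Replicate observed rate constants across a pH grid for one variant."""

    variant_id: str
    data: pd.DataFrame  # columns: pH, k_obs, replicate

    def __post_init__(self) -> None:
        required = {"pH", "k_obs", "replicate"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"dataset needs columns {sorted(required)}")
        if (self.data["k_obs"] <= 0).any():
            raise ValueError("all k_obs must be positive")
        if ((self.data["pH"] < 0) | (self.data["pH"] > 14)).any():
            raise ValueError("pH outside 0-14")


@dataclass
class PHModelFit:
    model: Literal["single_pka", "double_pka"]
    k_int: float
    pka_acid: float
    pka_nuc: float | None
    se_k_int: float
    se_pka_acid: float
    se_pka_nuc: float | None
    residual_rms_log10: float
    converged: bool
    ph_independent: bool = False  # flagged when the pKa is unidentifiable
    message: str = ""


@dataclass
class MechanismModel:
    """Per-variant mechanistic summary: barrier, intrinsic rates, pKa chain.

    ``pka_ribozyme`` is always pka_soln + dpka_shift by construction, the
    defining relation between the solution pKa of the isolated nucleobase
    and its value in the folded ribozyme environment.
    """

    variant_id: str
    dG_barrier: float
    k_int_rel_calc: float
    k_int_rel_expt: float | None
    pka_soln: float
    dpka_shift: float
    pka_apparent_expt: float | None = None
    pka_ribozyme: float = field(init=False)

    def __post_init__(self) -> None:
        self.pka_ribozyme = self.pka_soln + self.dpka_shift


def model_single_pka(pH, k_int: float, pka_acid: float):
    """Single-ionization observed rate: k_int times the protonated-acid fraction."""
    if k_int <= 0:
        raise ValueError("k_int must be positive")
    pH = np.asarray(pH, dtype=float)
    out = k_int / (1.0 + 10.0 ** (pH - pka_acid))
    return float(out) if out.ndim == 0 else out


def model_double_pka(pH, k_int: float, pka_acid: float, pka_nuc: float):
    """Two-ionization bell model: acid protonated AND nucleophile deprotonated."""
    if k_int <= 0:
        raise ValueError("k_int must be positive")
    if pka_nuc >= pka_acid:
        warnings.warn(
            "pKa_nuc >= pKa_acid: the bell model expects the nucleophile "
            "ionization below the acid ionization", stacklevel=2)
    pH = np.asarray(pH, dtype=float)
    out = (k_int
           / (1.0 + 10.0 ** (pH - pka_acid))
           / (1.0 + 10.0 ** (pka_nuc - pH)))
    return float(out) if out.ndim == 0 else out


def k_int_from_point(k_obs: float, pH: float, pka_acid: float) -> float:
    """Back-solve the intrinsic rate so the single-pKa curve passes through one point."""
    return k_obs * (1.0 + 10.0 ** (pH - pka_acid))


_PKA_STARTS = np.arange(3.0, 10.5, 1.0)


def fit_ph_profile(
    ds: PHRateDataset, model: Literal["single_pka", "double_pka"] = "single_pka"
) -> PHModelFit:
    """Fit an activity-pH model to replicate rate data in log10(k) space.

    Multi-start over apparent-pKa guesses 3-10.  When the data carry no pH
    dependence the pKa standard error blows up; such fits are flagged
    ``ph_independent`` (s.e. > 2 pKa units), mirroring how a variant with no
    observable ionization in the measured window must be reported.
    """
    ph = ds.data["pH"].to_numpy(dtype=float)
    k = ds.data["k_obs"].to_numpy(dtype=float)
    n_distinct = len(np.unique(ph))
    need = 4 if model == "single_pka" else 5
    if n_distinct < need:
        raise ValueError(f"{model} fit needs >= {need} distinct pH values")
    logk = np.log10(k)
    if np.ptp(logk) < 1e-12:
        return PHModelFit(model, float(k[0]), math.nan,
                          None if model == "single_pka" else math.nan,
                          0.0, math.inf, None if model == "single_pka" else math.inf,
                          0.0, False, ph_independent=True,
                          message="all rates equal; pKa unidentifiable")

    lk0 = float(np.max(logk))

    if model == "single_pka":
        def resid(th):
            return np.log10(model_single_pka(ph, 10.0 ** th[0], th[1])) - logk
        starts = [np.array([lk0, p]) for p in _PKA_STARTS]
        n_par = 2
    else:
        def resid(th):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return np.log10(
                    model_double_pka(ph, 10.0 ** th[0], th[1], th[2])) - logk
        starts = [np.array([lk0, p, p - 3.0]) for p in _PKA_STARTS]
        n_par = 3

    best = None
    for x0 in starts:
        try:
            res = least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # pragma: no cover
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    if best is None:
        return PHModelFit(model, math.nan, math.nan, None, math.inf, math.inf,
                          None, math.inf, False, message="all starts failed")

    dof = max(ph.size - n_par, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(n_par, math.inf)

    k_int = 10.0 ** best.x[0]
    se_k_int = k_int * math.log(10.0) * se[0]
    rms = math.sqrt(2.0 * best.cost / ph.size)
    # unidentifiable pKa: the s.e. blows up, or the fitted inflection lies
    # above the measured pH window (no ionization actually observed)
    ph_independent = (
        (not np.isfinite(se[1])) or se[1] > 2.0
        or best.x[1] > float(np.max(ph)) + 0.5
    )
    msg = "no pH dependence detected" if ph_independent else ""
    if model == "single_pka":
        return PHModelFit(model, float(k_int), float(best.x[1]), None,
                          float(se_k_int), float(se[1]), None, rms,
                          bool(best.success), ph_independent, msg)
    return PHModelFit(model, float(k_int), float(best.x[1]), float(best.x[2]),
                      float(se_k_int), float(se[1]), float(se[2]), rms,
                      bool(best.success), ph_independent, msg)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention for tables)."""
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def relative_rate_table(
    rates: pd.DataFrame, reference: tuple[str, float]
) -> pd.DataFrame:
    """Relative-rate table: every (variant, pH) mean rate over the reference.

    ``rates`` needs columns variant, pH, k_mean (any consistent rate unit;
    ratios are unit-invariant).  The reference is conventionally the
    unmodified ribozyme at pH 6.0.  Full precision is kept in ``rel_rate``;
    ``rel_rate_display`` rounds to 2 significant figures as in summary
    tables.
    """
    required = {"variant", "pH", "k_mean"}
    if not required.issubset(rates.columns):
        raise ValueError(f"rates table needs columns {sorted(required)}")
    ref_var, ref_ph = reference
    sel = rates[(rates["variant"] == ref_var) & (np.isclose(rates["pH"], ref_ph))]
    if sel.empty:
        raise ValueError(f"reference rate for {ref_var} at pH {ref_ph} not found")
    ref_rate = float(sel["k_mean"].iloc[0])
    out = rates.copy()
    out["rel_rate"] = out["k_mean"] / ref_rate
    out["rel_rate_display"] = out["rel_rate"].map(lambda v: round_sig(v, 2))
    return out


@dataclass
class ActivityProfile:
    """A rate-versus-pH curve (rates in the unit produced by its builder)."""

    ph: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)

    def max(self) -> float:
        return float(np.max(self.rate))

    def to_csv(self, path) -> None:
        """Export as two-column CSV (pH, k_model)."""
        pd.DataFrame({"pH": self.ph, "k_model": self.rate}).to_csv(
            path, index=False, float_format="%.10g")


def build_computed_profile(
    mm: MechanismModel,
    T: float = T_SIMULATION,
    ph_grid: np.ndarray | Sequence[float] = np.arange(4.0, 10.01, 0.05),
    pka_nuc_ribozyme: float | None = None,
) -> ActivityProfile:
    """Computed activity-pH curve from a barrier plus a calculated pKa.

    rate(pH) = eyring_rate(dG_barrier, T) * protonation factor with the
    ribozyme-environment pKa; in s^-1 before normalization.  If
    ``pka_nuc_ribozyme`` is given the two-ionization form is used instead.
    The half-maximal pH of the single-ionization curve equals the ribozyme
    pKa exactly.
    """
    ph_grid = np.asarray(ph_grid, dtype=float)
    k_int = eyring_rate(mm.dG_barrier, ThermoContext(T=T))
    if pka_nuc_ribozyme is None:
        rate = model_single_pka(ph_grid, k_int, mm.pka_ribozyme)
    else:
        rate = model_double_pka(ph_grid, k_int, mm.pka_ribozyme, pka_nuc_ribozyme)
    return ActivityProfile(ph_grid, rate)


def normalize_profiles(
    computed: ActivityProfile, experimental: ActivityProfile
) -> tuple[ActivityProfile, float]:
    """Scale a computed curve so its maximum aligns with the experimental fit.

    Returns (scaled curve, scalar).  The scalar is max(expt)/max(computed);
    by convention the same scalar (derived from the reference variant) is
    applied to every other variant's computed curve, preserving computed
    rate ratios between variants.
    """
    cmax = computed.max()
    if cmax == 0 or experimental.max() == 0:
        raise ValueError("cannot normalize a curve with zero maximum")
    scalar = experimental.max() / cmax
    return ActivityProfile(computed.ph, computed.rate * scalar), scalar
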