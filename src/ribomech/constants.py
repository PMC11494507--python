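"""Physical constants used throughout, in kcal/mol units."""

#: Gas constant, kcal mol^-1 K^-1
R_KCAL = 1.98720425e-3

#: Boltzmann constant over Planck constant, s^-1 K^-1 (Eyring prefactor per kelvin)
KB_OVER_H = 2.083661912e10

#: Default simulation temperature (K); free-energy simulations are run here.
T_SIMULATION = 298.15

#: Default experimental kinetics temperature (K); single-turnover assays at 37 C.
T_KINETICS = 310.15


def RT(T: float) -> float:
    """Thermal energy RT in kcal/mol at temperature ``T`` (K)."""
    return R_KCAL * T


def RT_ln10(T: float) -> float:
    """RT*ln(10) in kcal/mol: the free energy of one pKa unit at ``T``."""
    import math

    return R_KCAL * T * math.log(10.0)
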