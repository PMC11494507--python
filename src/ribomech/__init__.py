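"""ribomech: kinetics and free-energy landscapes of ribozyme general-acid catalysis.

A desk-scale pipeline connecting reaction kinetics (progress curves,
pH-rate profiles, Bronsted analysis) with free-energy landscapes (minimum
free-energy paths, umbrella sampling/MBAR, alchemical pKa shifts) for the
MTR1 alkyl-transferase ribozyme and its atomic variants.
"""

from importlib import resources as _resources
import json as _json

__version__ = "0.1.0"

from .constants import R_KCAL, RT, RT_ln10, T_KINETICS, T_SIMULATION
from .kinetics import (
    KineticFit,
    ReplicateSummary,
    TimeCourse,
    fit_double_exponential,
    fit_single_exponential,
    select_kinetic_model,
    summarize_replicates,
)
from .lfer_thermo import (
    BronstedInput,
    ThermoContext,
    bronsted_beta,
    ddg_from_delta_pka,
    delta_pka_from_ddg,
    eyring_rate,
    relative_rate_from_barriers,
    ribozyme_pka,
)
from .landscape import (
    FreeEnergySurface,
    PathString,
    ReactionProfile,
    profile_along_path,
    read_surface,
    string_mfep,
    ts_coordinates,
    write_surface,
)
from .ph_profiles import (
    ActivityProfile,
    MechanismModel,
    PHModelFit,
    PHRateDataset,
    build_computed_profile,
    fit_ph_profile,
    k_int_from_point,
    model_double_pka,
    model_single_pka,
    normalize_profiles,
    relative_rate_table,
)
from .sampling_fe import (
    AlchemicalDataset,
    BiasedTrajectory,
    MBARResult,
    UmbrellaWindow,
    alchemical_ddg,
    mbar_solve,
    pmf_2d,
)
from .synthetic_data import (
    GaussianComponent,
    KineticsSpec,
    LangevinSpec,
    SurfaceSpec,
    gen_alchemical_samples,
    gen_biased_trajectories,
    gen_ph_rate_data,
    gen_surface,
    gen_time_course,
    mtr1_surface_spec,
)


def load_reference() -> dict:
    """Published MTR1 measurements and computed quantities shipped with the package."""
    with _resources.files("ribomech.data").joinpath("mtr1_reference.json").open() as fh:
        return _json.load(fh)
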