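"""2H/13C metabolic flux analysis of hepatic glucose production.

Simulates steady-state mass isotopomer distributions of plasma-glucose
fragment ions from an atom-transition network of the glucose-producing and
TCA-cycle pathways under a three-tracer protocol ([6,6-2H2]glucose, 2H2O,
[U-13C]propionate), and inverts the model by weighted least squares to
estimate gluconeogenic and mitochondrial fluxes with goodness-of-fit and
profile-likelihood confidence intervals.
"""

__version__ = "0.1.0"

import importlib.resources as _ir

from .network import (
    FluxVector,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    free_flux_basis,
    parse_network,
    stoichiometric_matrix,
    write_network,
)
from .emu import (
    EMU,
    EMUSystem,
    TracerSpec,
    convolve,
    decompose_emus,
    emu_of,
    input_emu_mid,
    simulate_mids,
)
from .measurement import (
    FragmentIon,
    MeasurementSet,
    apply_derivative_correction,
    default_fragments,
    load_fragments,
    measurement_from_frame,
    natural_mid,
    validate_unenriched,
)
from .fitting import (
    FitProblem,
    FitResult,
    chi2_goodness,
    fit_fluxes,
    profile_ci,
    ssr,
    to_absolute,
)
from .protocol import Protocol
from .synthetic import (
    Scenario,
    SyntheticDataset,
    auc_trapezoid,
    make_scenario,
    simulate_dataset,
)


def default_network_path() -> str:
    """Path of the packaged liver atom-transition network file."""
    return str(_ir.files("hepaflux") / "data" / "liver_network.tsv")


def load_default_network() -> MetabolicNetwork:
    """Parse the packaged hepatic glucose-production / TCA network."""
    return parse_network(default_network_path())


def toy_network_path(name: str) -> str:
    """Path of a packaged toy network (toy_chain, toy_condense, toy_cycle, toy_solvent)."""
    return str(_ir.files("hepaflux") / "data" / "toy" / f"{name}.tsv")
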