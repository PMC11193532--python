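"""Ground-truth flux scenarios and synthetic GC-MS datasets.

The generator runs the full forward model — steady-state EMU labeling
simulation of a known (balanced) flux vector under the three-tracer protocol,
derivative natural-abundance correction to observable fragment MIDs — and
adds independent Gaussian measurement error to each channel's mole fraction,
mimicking duplicate-injection variability.  The noisy fractions are *not*
renormalized: renormalization would correlate the channels and make the
declared per-channel SD (and with it the chi-square goodness-of-fit
calibration of the regression) inexact, so measured sums scatter around 1 by
the accumulated noise instead.  Each dataset includes a pre-infusion
(-210 min) unenriched baseline sample and a manifest that makes it
bit-for-bit reproducible from (scenario, seed).

Scenario flux magnitudes are illustrative, physiologically ordered
configuration for a fasted mouse (endogenous glucose production on the scale
of 150 umol/kg/min at rest); the knockout scenarios suppress mitochondrial
pyruvate entry (V_PC) and unlabeled anaplerotic inflow (V_LDH), and the
exercise scenarios raise TCA and glucose-producing fluxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .emu import EMUSystem
from .errors import UsageError
from .measurement import (
    BASELINE_TIME_MIN,
    FragmentIon,
    correction_matrix,
    default_fragments,
    natural_mid,
)
from .network import FluxVector, MetabolicNetwork, free_flux_basis, stoichiometric_matrix
from .protocol import Protocol

#: Free-flux values (umol/kg/min) defining each named scenario, keyed by the
#: free fluxes of the default parameterization plus the V_CS constraint.
#: Remaining fluxes follow from the steady-state balances.
SCENARIO_FREE_FLUXES: dict[str, dict[str, float]] = {
    "rest": {
        "V_CS": 130.0, "V_inf": 4.4, "V_PYGL": 40.0, "V_GK": 40.0,
        "V_Enol": 180.0, "V_PK+ME": 70.0, "V_PCC": 60.0,
    },
    "exercise": {
        "V_CS": 200.0, "V_inf": 4.4, "V_PYGL": 120.0, "V_GK": 50.0,
        "V_Enol": 260.0, "V_PK+ME": 100.0, "V_PCC": 60.0,
    },
    "rest_DKO": {
        "V_CS": 110.0, "V_inf": 4.4, "V_PYGL": 60.0, "V_GK": 50.0,
        "V_Enol": 70.0, "V_PK+ME": 20.0, "V_PCC": 60.0,
    },
    "exercise_DKO": {
        "V_CS": 120.0, "V_inf": 4.4, "V_PYGL": 100.0, "V_GK": 60.0,
        "V_Enol": 80.0, "V_PK+ME": 25.0, "V_PCC": 60.0,
    },
}

ENRICHED_TIMES = (0.0, 10.0, 20.0, 30.0)


def _balanced_truth(net: MetabolicNetwork, free_values: Mapping[str, float]) -> FluxVector:
    fixed = {"V_CS": free_values["V_CS"]}
    preferred = [k for k in free_values if k != "V_CS"]
    basis = free_flux_basis(net, fixed, preferred_free=preferred)
    missing = [n for n in basis.free_names if n not in free_values]
    if missing:
        raise UsageError(f"scenario must specify free fluxes {missing}")
    theta = np.array([free_values[n] for n in basis.free_names])
    fv = basis.flux_vector(theta, basis="absolute")
    arr = fv.as_array(basis.reaction_names)
    if arr.min() < -1e-9:
        bad = basis.reaction_names[int(arr.argmin())]
        raise UsageError(f"scenario flux {bad} is negative ({arr.min():.3g})")
    return fv


@dataclass
class Scenario:
    """A ground-truth condition from which synthetic datasets are generated."""

    name: str
    truth: FluxVector                      # absolute, umol/kg/min
    network: MetabolicNetwork
    protocol: Protocol = field(default_factory=Protocol)
    truth_by_time: dict[float, FluxVector] = field(default_factory=dict)
    noise_sd: float = 0.003                # mole fraction
    n_animals: int = 8
    n_injections: int = 2

    def __post_init__(self):
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be >= 0")
        S, _, cols = stoichiometric_matrix(self.network)
        for fv in [self.truth, *self.truth_by_time.values()]:
            resid = np.abs(S @ fv.as_array(cols)).max()
            if resid > 1e-9 * max(1.0, max(abs(v) for v in fv.values.values())):
                raise UsageError(
                    f"scenario truth violates steady state (residual {resid:.3g})"
                )

    def truth_at(self, time_min: float) -> FluxVector:
        return self.truth_by_time.get(time_min, self.truth)


def make_scenario(name: str, network: MetabolicNetwork, **overrides) -> Scenario:
    """Build a named scenario (rest, exercise, rest_DKO, exercise_DKO, custom).

    Keyword overrides may replace any scenario field or any free-flux value
    (e.g. ``V_PYGL=80``).  Exercise scenarios use the matching rest condition
    as the truth of the pre-exercise 0-min sample.
    """
    if name == "custom":
        free = dict(overrides.pop("free_fluxes"))
    elif name in SCENARIO_FREE_FLUXES:
        free = dict(SCENARIO_FREE_FLUXES[name])
    else:
        raise UsageError(
            f"unknown scenario {name!r}; choose from "
            f"{sorted(SCENARIO_FREE_FLUXES)} or 'custom'"
        )
    for k in list(overrides):
        if k in free:
            free[k] = float(overrides.pop(k))
    truth = _balanced_truth(network, free)
    truth_by_time = overrides.pop("truth_by_time", None)
    if truth_by_time is None and name.startswith("exercise"):
        rest_name = "rest" + name[len("exercise"):]
        rest_truth = _balanced_truth(network, SCENARIO_FREE_FLUXES[rest_name])
        truth_by_time = {0.0: rest_truth}
    return Scenario(
        name=name,
        truth=truth,
        network=network,
        truth_by_time=truth_by_time or {},
        **overrides,
    )


#: Floor on the recorded per-channel SD (keeps weights finite for noise-free data).
SD_FLOOR = 1e-4


@dataclass
class SyntheticDataset:
    """Long-format synthetic measurements plus the generating manifest."""

    frame: pd.DataFrame
    manifest: dict

    def write(self, directory) -> None:
        """Write mids.csv, protocol.toml and manifest.json."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(d / "mids.csv", index=False, float_format="%.10g")
        proto = Protocol(**self.manifest["protocol"])
        (d / "protocol.toml").write_text(proto.to_toml())
        (d / "manifest.json").write_text(json.dumps(self.manifest, indent=2) + "\n")


def simulate_dataset(
    scenario: Scenario,
    seed: int,
    fragments: list[FragmentIon] | None = None,
) -> SyntheticDataset:
    """Generate a noisy synthetic dataset for a scenario.

    For every animal and enriched time point the observable fragment MIDs are
    simulated from the scenario truth and independent Gaussian error of SD
    ``noise_sd`` is added per channel and injection; the recorded ``sd``
    column is that exact per-injection SD (floored at 1e-4).  The -210 min
    baseline sample is unenriched (natural abundance only).
    """
    fragments = fragments if fragments is not None else default_fragments()
    net = scenario.network
    system = EMUSystem(net, [f.emu for f in fragments])
    T = {f.name: correction_matrix(f) for f in fragments}

    # true observable MIDs per time point
    truth_obs: dict[float, dict[str, np.ndarray]] = {}
    for t in ENRICHED_TIMES:
        sol = system.mids(scenario.truth_at(t), scenario.protocol.tracer_specs())
        obs = {}
        for f in fragments:
            y = T[f.name] @ sol[f.emu]
            obs[f.name] = y / y.sum()
        truth_obs[t] = obs
    baseline_obs = {
        f.name: natural_mid(f.formula, f.n_channels) for f in fragments
    }

    rng = np.random.default_rng(seed)
    rows = []
    times = (BASELINE_TIME_MIN, *ENRICHED_TIMES)
    for a in range(1, scenario.n_animals + 1):
        sample = f"animal_{a:02d}"
        for t in times:
            obs = baseline_obs if t == BASELINE_TIME_MIN else truth_obs[t]
            for f in fragments:
                x = obs[f.name]
                sd = np.full(x.size, max(scenario.noise_sd, SD_FLOOR))
                for inj in range(1, scenario.n_injections + 1):
                    y = x + rng.normal(0.0, scenario.noise_sd, x.size)
                    for mz, val, s in zip(f.mz_channels, y, sd):
                        rows.append(
                            (sample, t, inj, f.name, int(mz), float(val), float(s))
                        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "time_min", "injection", "fragment", "mz",
            "intensity_fraction", "sd",
        ],
    )
    manifest = {
        "scenario": scenario.name,
        "seed": int(seed),
        "noise_sd": scenario.noise_sd,
        "n_animals": scenario.n_animals,
        "n_injections": scenario.n_injections,
        "truth_umol_kg_min": {k: float(v) for k, v in scenario.truth.values.items()},
        "truth_by_time": {
            str(t): {k: float(v) for k, v in fv.values.items()}
            for t, fv in scenario.truth_by_time.items()
        },
        "protocol": {
            k: float(v) for k, v in vars(scenario.protocol).items()
        },
        "fragments": [f.name for f in fragments],
        "package_version": __version__,
    }
    return SyntheticDataset(frame=frame, manifest=manifest)


def auc_trapezoid(times, values) -> float:
    """Trapezoidal area under a concentration time course (mmol/L * min)."""
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if t.size != v.size or t.size < 2:
        raise UsageError("need >= 2 matching time/value points")
    if not (np.diff(t) > 0).all():
        raise UsageError("times must be strictly increasing")
    return float(np.trapezoid(v, t))
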