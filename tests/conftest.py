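"""Shared fixtures: networks, tracer configurations, synthetic measurements."""

from __future__ import annotations

import numpy as np
import pytest

import hepaflux as hf
from hepaflux.emu import TracerSpec
from hepaflux.measurement import measurement_from_frame


@pytest.fixture(scope="session")
def liver_net():
    return hf.load_default_network()


@pytest.fixture(scope="session")
def fragments():
    return hf.default_fragments()


@pytest.fixture(scope="session")
def protocol():
    return hf.Protocol()


@pytest.fixture(scope="session")
def tracers(protocol):
    return protocol.tracer_specs()


def toy(name):
    return hf.parse_network(hf.toy_network_path(name))


@pytest.fixture(scope="session")
def toy_nets():
    return {n: toy(n) for n in ("toy_chain", "toy_condense", "toy_cycle", "toy_solvent")}


def toy_tracers(name):
    """Fully or partially labeled tracer configurations for the toy networks."""
    if name == "toy_chain":
        return [TracerSpec("input_a", "A", (("C", 1),), purity=0.98, enrichment=0.6)]
    if name == "toy_condense":
        return [
            TracerSpec("input_x", "X", (("C", 1), ("C", 2)), purity=0.99, enrichment=0.5),
            TracerSpec("input_y", "Y", (("C", 2),), purity=0.95, enrichment=0.8),
        ]
    if name == "toy_cycle":
        return [TracerSpec("input_a", "A", (("C", 1),), purity=1.0, enrichment=1.0)]
    if name == "toy_solvent":
        return [
            TracerSpec("input_a", "A", (("C", 1),), purity=1.0, enrichment=0.5),
            TracerSpec("body_water", "Water", (("H", 1),), purity=0.999, enrichment=0.045),
        ]
    raise KeyError(name)


def toy_targets(name):
    """Observable (sink) EMUs used when cross-checking the two simulators."""
    if name == "toy_chain":
        return [hf.emu_of("C", ["C1", "C2"]), hf.emu_of("C", ["C2"])]
    if name == "toy_condense":
        return [hf.emu_of("P", ["C1", "C2", "C3", "C4"]), hf.emu_of("P", ["C2", "C3"])]
    if name == "toy_cycle":
        return [hf.emu_of("Out", ["C1", "C2"]), hf.emu_of("Out", ["C1"])]
    if name == "toy_solvent":
        return [hf.emu_of("C", ["C1", "C2", "H1", "H2"]), hf.emu_of("C", ["H1"])]
    raise KeyError(name)


def random_balanced_fluxes(net, rng):
    """A strictly positive random flux vector satisfying all node balances."""
    basis = hf.free_flux_basis(net, {net.reaction_names[0]: float(rng.uniform(50, 150))})
    for _ in range(200):
        theta = rng.uniform(5.0, 100.0, basis.n_free)
        v = basis.full_array(theta)
        if v.min() > 1e-6:
            return basis.flux_vector(theta)
    raise RuntimeError("could not draw a positive balanced flux vector")


@pytest.fixture(scope="session")
def rest_scenario(liver_net):
    return hf.make_scenario("rest", liver_net, noise_sd=0.003, n_animals=1)


@pytest.fixture(scope="session")
def truth_theta(rest_scenario):
    """Relative-basis free-flux values of the rest scenario (warm start)."""
    sc = rest_scenario
    names = ["V_inf", "V_PYGL", "V_GK", "V_Enol", "V_PK+ME", "V_PCC"]
    return np.array([sc.truth[n] / sc.truth["V_CS"] * 100.0 for n in names])


def one_animal_measurement(scenario, seed, time_min=0.0):
    ds = hf.simulate_dataset(scenario, seed=seed)
    return measurement_from_frame(ds.frame, "animal_01", time_min)
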