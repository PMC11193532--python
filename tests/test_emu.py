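"""EMU decomposition and steady-state MID simulation, checked against the
full isotopomer-enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hepaflux as hf
from hepaflux.emu import EMUSystem, TracerSpec, convolve, input_emu_mid, simulate_mids
from hepaflux.errors import IdentifiabilityError, UsageError
from hepaflux.isotopomer import simulate_mids_bruteforce

from conftest import random_balanced_fluxes, toy_targets, toy_tracers


def test_chain_decomposition_levels(toy_nets):
    net = toy_nets["toy_chain"]
    system = EMUSystem(net, [hf.emu_of("C", ["C1", "C2"])])
    by_size = system.emus_by_size()
    assert set(by_size) == {2}
    assert by_size[2] == {
        hf.emu_of("C", ["C1", "C2"]),
        hf.emu_of("B", ["C1", "C2"]),
        hf.emu_of("A", ["C1", "C2"]),
    }


def test_condensation_creates_convolution_node(toy_nets):
    net = toy_nets["toy_condense"]
    # Z(C:badc): Z C2 comes from X and Z C3 from Y -> condensation EMU
    system = EMUSystem(net, [hf.emu_of("Z", ["C2", "C3"])])
    terms = system.nodes[hf.emu_of("Z", ["C2", "C3"])]
    conv = [t for t in terms if t.is_convolution]
    assert len(conv) == 1
    assert {p.metabolite for p in conv[0].parts} == {"X", "Y"}


def test_default_decomposition_is_compact(liver_net, fragments):
    system = EMUSystem(liver_net, [f.emu for f in fragments])
    # far fewer states than the 2^13 isotopomers of glucose alone
    assert system.n_emus < 2**13
    # every non-source EMU has at least one production route
    assert all(len(t) > 0 for t in system.nodes.values())


def test_input_mid_body_water():
    spec = TracerSpec("w", "Water", (("H", 1),), purity=1.0, enrichment=0.045)
    mid = input_emu_mid([spec], hf.emu_of("Water", ["H1"]), natural_abundance=False)
    assert np.allclose(mid, [0.955, 0.045], atol=1e-12)


def test_input_mid_unlabeled_two_carbons():
    mid = input_emu_mid([], hf.emu_of("X", ["C1", "C2"]), natural_abundance=False)
    assert np.allclose(mid, [1.0, 0.0, 0.0], atol=0)


def test_input_mid_u13c_propionate_binomial():
    spec = TracerSpec(
        "p", "Prop", (("C", 1), ("C", 2), ("C", 3)), purity=0.99, enrichment=1.0
    )
    mid = input_emu_mid(
        [spec], hf.emu_of("Prop", ["C1", "C2", "C3"]), natural_abundance=False
    )
    assert np.allclose(mid, [1e-6, 2.97e-4, 2.9403e-2, 0.970299], atol=1e-12)


def test_input_mid_rejects_balanced_metabolite(liver_net):
    with pytest.raises(UsageError):
        input_emu_mid([], hf.emu_of("OAA", ["C1"]), net=liver_net)


def test_convolve_identities():
    assert np.allclose(convolve([1, 0], [1, 0]), [1, 0, 0])
    assert np.allclose(convolve([0.5, 0.5], [0.5, 0.5]), [0.25, 0.5, 0.25])


@settings(max_examples=50, deadline=None)
@given(
    a=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6),
    b=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6),
)
def test_convolve_matches_double_loop(a, b):
    a = np.array(a) / np.sum(a)
    b = np.array(b) / np.sum(b)
    ref = np.zeros(len(a) + len(b) - 1)
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            ref[i + j] += ai * bj
    assert np.abs(convolve(a, b) - ref).max() < 1e-14
    assert abs(convolve(a, b).sum() - 1.0) < 1e-12


@pytest.mark.parametrize("name", ["toy_chain", "toy_condense", "toy_cycle", "toy_solvent"])
def test_emu_equals_isotopomer_enumeration(toy_nets, name):
    """Core correctness oracle: EMU cascade == brute-force 2^n enumeration."""
    net = toy_nets[name]
    tracers = toy_tracers(name)
    targets = toy_targets(name)
    system = EMUSystem(net, targets)
    rng = np.random.default_rng(42)
    for _ in range(25):
        fv = random_balanced_fluxes(net, rng)
        emu_mids = system.mids(fv, tracers)
        bf = simulate_mids_bruteforce(net, fv, tracers, targets)
        for t in targets:
            assert np.abs(emu_mids[t] - bf[t]).max() < 1e-10


def test_liver_network_matches_enumeration(liver_net, fragments, rest_scenario):
    """The full network is small enough to enumerate once as a cross-check."""
    tracers = rest_scenario.protocol.tracer_specs()
    targets = [f.emu for f in fragments]
    sol = EMUSystem(liver_net, targets).mids(rest_scenario.truth, tracers)
    bf = simulate_mids_bruteforce(liver_net, rest_scenario.truth, tracers, targets)
    assert max(np.abs(sol[t] - bf[t]).max() for t in targets) < 1e-10


def test_unlabeled_config_gives_natural_mids(liver_net, fragments, protocol):
    tracers = protocol.tracer_specs(enriched=False)
    sc = hf.make_scenario("rest", liver_net)
    sol = simulate_mids(
        liver_net, sc.truth, tracers, [f.emu for f in fragments]
    )
    for f in fragments:
        expected = input_emu_mid([], hf.emu_of("X", [f"{e}{i}" for e, i in f.emu.sorted_atoms]))
        assert np.abs(sol[f.emu] - expected).max() < 1e-12


def test_single_path_shifts_label(toy_nets):
    net = toy_nets["toy_chain"]
    tracers = [TracerSpec("input_a", "A", (("C", 1), ("C", 2)), 1.0, 1.0)]
    sol = simulate_mids(
        net, {"r1": 5.0, "r2": 5.0}, tracers, [hf.emu_of("C", ["C1", "C2"])],
        natural_abundance=False,
    )
    assert np.allclose(sol[hf.emu_of("C", ["C1", "C2"])], [0, 0, 1], atol=1e-12)


def test_scaling_invariance(liver_net, fragments, rest_scenario):
    tracers = rest_scenario.protocol.tracer_specs()
    targets = [f.emu for f in fragments]
    system = EMUSystem(liver_net, targets)
    base = system.mids(rest_scenario.truth, tracers)
    scaled = system.mids(rest_scenario.truth.scaled(3.7, "absolute"), tracers)
    for t in targets:
        assert np.abs(base[t] - scaled[t]).max() < 1e-12


def test_water_enrichment_monotonicity(toy_nets):
    net = toy_nets["toy_solvent"]
    target = hf.emu_of("C", ["H1"])
    m1 = []
    for e in (0.01, 0.03, 0.045, 0.09):
        tr = [TracerSpec("body_water", "Water", (("H", 1),), 1.0, e)]
        sol = simulate_mids(net, {"rhyd": 1.0, "rout": 1.0}, tr, [target])
        m1.append(sol[target][1])
    assert all(b > a for a, b in zip(m1, m1[1:]))


def test_mids_are_distributions(liver_net, fragments, tracers):
    rng = np.random.default_rng(5)
    system = EMUSystem(liver_net, [f.emu for f in fragments])
    for _ in range(10):
        fv = random_balanced_fluxes(liver_net, rng)
        for mid in system.mids(fv, tracers).values():
            assert mid.min() >= 0.0
            assert abs(mid.sum() - 1.0) < 1e-9


def test_zero_production_raises_identifiability_error(toy_nets):
    net = toy_nets["toy_chain"]
    system = EMUSystem(net, [hf.emu_of("C", ["C1"])])
    with pytest.raises(IdentifiabilityError, match="B"):
        system.mids({"r1": 0.0, "r2": 1.0}, toy_tracers("toy_chain"))


def test_simulate_mids_checks_balance(toy_nets):
    net = toy_nets["toy_chain"]
    with pytest.raises(UsageError, match="balance"):
        simulate_mids(
            net, {"r1": 1.0, "r2": 2.0}, toy_tracers("toy_chain"),
            [hf.emu_of("C", ["C1"])],
        )
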