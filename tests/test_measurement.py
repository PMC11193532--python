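"""Fragment-ion measurement model: natural-abundance machinery and QC."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hepaflux as hf
from hepaflux._isotopes import ELEMENT_MID
from hepaflux.errors import CorrectionError, UsageError
from hepaflux.measurement import (
    BASELINE_TIME_MIN,
    FragmentIon,
    MeasurementSet,
    apply_derivative_correction,
    formula_mass,
    measurement_from_frame,
    natural_mid,
    parse_formula,
    validate_unenriched,
)

EXPECTED_WINDOWS = {
    "aldonitrile_173": (173, 178),
    "aldonitrile_259": (259, 266),
    "aldonitrile_284": (284, 291),
    "aldonitrile_370": (370, 379),
    "methyloxime_145": (145, 149),
    "diisopropylidene_301": (301, 314),
}


def brute_force_natural(formula, n_channels):
    """Independent oracle: explicit enumeration over every atom's isotope state."""
    atoms = []
    for elem, count in parse_formula(formula).items():
        atoms.extend([ELEMENT_MID[elem]] * count)
    out = np.zeros(sum(len(a) - 1 for a in atoms) + 1)
    for states in itertools.product(*[range(len(a)) for a in atoms]):
        p = 1.0
        for a, s in zip(atoms, states):
            p *= a[s]
        out[sum(states)] += p
    padded = np.zeros(n_channels)
    k = min(n_channels, out.size)
    padded[:k] = out[:k]
    return padded / padded.sum()


def test_natural_mid_single_carbon():
    assert np.allclose(natural_mid("C1", 2), [0.9893, 0.0107], atol=1e-12)


def test_natural_mid_empty_formula():
    assert np.allclose(natural_mid({}, 4), [1, 0, 0, 0], atol=0)


@pytest.mark.parametrize("formula", ["C6H7NO6", "C3H5O2", "C2N2"])
def test_natural_mid_matches_enumeration(formula):
    got = natural_mid(formula, 6)
    ref = brute_force_natural(formula, 6)
    assert np.abs(got - ref).max() < 1e-12


def test_default_fragment_configuration(fragments):
    assert len(fragments) == 6
    assert {f.name: (f.mz_lo, f.mz_hi) for f in fragments} == EXPECTED_WINDOWS
    for f in fragments:
        assert f.n_channels >= f.skeleton_size + 1
        assert formula_mass(f.formula) == f.mz_lo
        # every covered atom exists on glucose (6 C, 7 tracked H)
        for elem, pos in f.covered_atoms:
            assert (elem == "C" and 1 <= pos <= 6) or (elem == "H" and 1 <= pos <= 7)
    whole = next(f for f in fragments if f.name == "diisopropylidene_301")
    assert whole.skeleton_size == 13  # the full glucose skeleton


def test_forward_inverse_round_trip(fragments):
    rng = np.random.default_rng(0)
    for f in fragments:
        for _ in range(100):
            s = rng.dirichlet(np.ones(f.skeleton_size + 1) * 0.5)
            y = apply_derivative_correction(s, f, "forward")
            assert abs(y.sum() - 1.0) < 1e-12
            back = apply_derivative_correction(y, f, "inverse")
            assert np.abs(back - s).max() < 1e-8


def test_unenriched_forward_equals_full_natural(fragments):
    for f in fragments:
        skeleton = natural_mid(
            {"C": sum(1 for e, _ in f.covered_atoms if e == "C"),
             "H": sum(1 for e, _ in f.covered_atoms if e == "H")},
            f.skeleton_size + 1,
        )
        # C/H skeleton atoms shift mass by at most +1 each, so the skeleton
        # natural MID is exact at size+1 channels and the identity is exact
        got = apply_derivative_correction(skeleton, f, "forward")
        ref = natural_mid(f.formula, f.n_channels)
        assert np.abs(got - ref).max() < 1e-12


def test_zero_derivative_atoms_is_identity():
    f = FragmentIon("bare", "none", 100, 102, (("C", 1), ("C", 2)), {"C": 2})
    s = np.array([0.2, 0.5, 0.3])
    assert np.allclose(apply_derivative_correction(s, f, "forward"), s, atol=1e-12)


def test_inverse_flags_inconsistent_data(fragments):
    f = next(fr for fr in fragments if fr.name == "aldonitrile_259")
    impossible = np.zeros(f.n_channels)
    impossible[0] = 1.0  # below the natural-abundance floor of the derivative
    with pytest.raises(CorrectionError):
        apply_derivative_correction(impossible, f, "inverse")


def _baseline_measurement(fragments, noise, rng, time=BASELINE_TIME_MIN):
    data = {}
    for f in fragments:
        x = natural_mid(f.formula, f.n_channels)
        y = x + rng.normal(0, noise, x.size) if noise else x.copy()
        data[f.name] = (y, np.full(x.size, max(noise, 1e-4)))
    return MeasurementSet("animal_01", time, data)


def test_unenriched_validation_zero_noise(fragments):
    meas = _baseline_measurement(fragments, 0.0, None)
    report = validate_unenriched(meas, fragments)
    assert all(r["max_abs_dev"] < 1e-12 and r["pass"] for r in report.values())


def test_unenriched_validation_monte_carlo(fragments):
    """With 0.003 noise the worst channel deviation stays below 0.015
    in at least 99% of draws."""
    rng = np.random.default_rng(123)
    ok = 0
    n = 400
    for _ in range(n):
        meas = _baseline_measurement(fragments, 0.003, rng)
        report = validate_unenriched(meas, fragments, threshold=0.015)
        worst = max(r["max_abs_dev"] for r in report.values())
        ok += worst < 0.015
    assert ok / n >= 0.99


def test_unenriched_validation_flags_shift(fragments):
    meas = _baseline_measurement(fragments, 0.0, None)
    mid, sd = meas.data["methyloxime_145"]
    mid = mid.copy()
    mid[1] += 0.02
    mid[0] -= 0.02
    meas.data["methyloxime_145"] = (mid, sd)
    report = validate_unenriched(meas, fragments)
    assert not report["methyloxime_145"]["pass"]
    assert all(report[f.name]["pass"] for f in fragments if f.name != "methyloxime_145")


def test_unenriched_validation_requires_baseline(fragments):
    meas = _baseline_measurement(fragments, 0.0, None, time=0.0)
    with pytest.raises(UsageError, match="baseline"):
        validate_unenriched(meas, fragments)


def test_measurement_loader_averages_duplicates(liver_net, fragments):
    sc = hf.make_scenario("rest", liver_net, noise_sd=0.003, n_animals=1)
    ds = hf.simulate_dataset(sc, seed=77)
    meas = measurement_from_frame(ds.frame, "animal_01", 0.0)
    assert meas.n_channels == 51
    df = ds.frame
    sub = df[(df.sample_id == "animal_01") & (df.time_min == 0.0)
             & (df.fragment == "methyloxime_145")]
    by_mz = sub.groupby("mz")["intensity_fraction"].mean()
    mid, sd = meas.data["methyloxime_145"]
    assert np.allclose(mid, by_mz.to_numpy(), atol=1e-12)
    # SD of the mean of two injections with known per-injection sd
    assert np.allclose(sd, 0.003 / np.sqrt(2), atol=1e-12)


def test_measurement_loader_half_range_fallback():
    rows = []
    for inj, vals in enumerate([[0.69, 0.2, 0.11], [0.71, 0.2, 0.09]], start=1):
        for mz, v in zip((100, 101, 102), vals):
            rows.append(("a1", 0.0, inj, "frag", mz, v))
    df = pd.DataFrame(
        rows, columns=["sample_id", "time_min", "injection", "fragment", "mz",
                       "intensity_fraction"]
    )
    meas = measurement_from_frame(df, "a1", 0.0)
    mid, sd = meas.data["frag"]
    assert np.allclose(mid, [0.70, 0.20, 0.10])
    assert np.allclose(sd, [0.01, 0.003, 0.01])  # max(floor, half-range)
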