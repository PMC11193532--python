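"""GC-MS fragment measurement model.

Maps simulated glucose-skeleton MIDs to the observable MIDs of derivatized
fragment ions, and back.  Each fragment ion covers a subset of the glucose
skeleton atoms and adds derivative atoms (propionyl, methyloxime,
isopropylidene groups...) whose natural isotope abundance spreads the signal
across mass channels; the forward model convolves the skeleton MID with the
natural MID of the derivative atoms, which is also how measurement accuracy
is validated on unenriched control samples.
"""

from __future__ import annotations

import importlib.resources as ir
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._isotopes import ELEMENT_MID, NOMINAL_MASS
from .emu import EMU
from .errors import CorrectionError, UsageError
from .network import Atom

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

BASELINE_TIME_MIN = -210.0


def parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise UsageError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if m.group(0) == "":
            break
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise UsageError(f"cannot parse formula {formula!r}")
    return counts


def formula_mass(formula: Mapping[str, int]) -> int:
    return sum(NOMINAL_MASS[e] * n for e, n in formula.items())


@dataclass(frozen=True)
class FragmentIon:
    """A measured glucose fragment ion.

    ``covered_atoms`` are the glucose skeleton atoms retained in the ion
    (as network atoms of the plasma-glucose metabolite); ``formula`` is the
    full elemental composition of the ion including derivative atoms.
    """

    name: str
    derivative: str
    mz_lo: int
    mz_hi: int
    covered_atoms: tuple[Atom, ...]
    formula: dict[str, int] = field(hash=False)
    metabolite: str = "Glc"

    def __post_init__(self):
        if self.n_channels < self.skeleton_size + 1:
            raise UsageError(
                f"fragment {self.name}: m/z window provides {self.n_channels} "
                f"channels but the ion covers {self.skeleton_size} atoms"
            )
        for elem in ("C", "H"):
            cov = sum(1 for e, _ in self.covered_atoms if e == elem)
            if self.formula.get(elem, 0) < cov:
                raise UsageError(
                    f"fragment {self.name}: formula has fewer {elem} atoms than covered"
                )

    @property
    def n_channels(self) -> int:
        return self.mz_hi - self.mz_lo + 1

    @property
    def skeleton_size(self) -> int:
        return len(self.covered_atoms)

    @property
    def emu(self) -> EMU:
        return EMU(self.metabolite, frozenset(self.covered_atoms))

    @property
    def derivative_formula(self) -> dict[str, int]:
        """Elemental composition of the ion minus the covered skeleton atoms."""
        out = dict(self.formula)
        for elem, _ in self.covered_atoms:
            out[elem] -= 1
        return {e: n for e, n in out.items() if n > 0}

    @property
    def mz_channels(self) -> np.ndarray:
        return np.arange(self.mz_lo, self.mz_hi + 1)


def load_fragments(path_or_text) -> list[FragmentIon]:
    """Read a fragment definition TSV (name, derivative, mz_lo, mz_hi, atoms, formula)."""
    text = str(path_or_text)
    if "\n" not in text:
        with open(text, "r", encoding="utf-8") as fh:
            text = fh.read()
    frags = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 6:
            raise UsageError(f"expected 6 fields in fragment line {line!r}")
        name, deriv, lo, hi, atoms, formula = fields
        covered = tuple((a[0], int(a[1:])) for a in atoms.split(","))
        frags.append(
            FragmentIon(name, deriv, int(lo), int(hi), covered, parse_formula(formula))
        )
    return frags


def default_fragments() -> list[FragmentIon]:
    """The packaged six-fragment glucose configuration."""
    return load_fragments(str(ir.files("hepaflux") / "data" / "fragments.tsv"))


# ---------------------------------------------------------------------------
# natural abundance machinery

def natural_mid(formula: Mapping[str, int] | str, n_channels: int) -> np.ndarray:
    """Theoretical natural-abundance MID of an elemental composition.

    Truncated convolution of per-element natural isotope mass-shift
    distributions, renormalized over ``n_channels``.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    mid = np.array([1.0])
    for elem, count in formula.items():
        if count < 0:
            raise UsageError(f"negative atom count for {elem}")
        base = ELEMENT_MID[elem]
        for _ in range(count):
            mid = np.convolve(mid, base)
    out = np.zeros(n_channels)
    k = min(n_channels, mid.size)
    out[:k] = mid[:k]
    return out / out.sum()


def correction_matrix(fragment: FragmentIon) -> np.ndarray:
    """Forward correction operator: observable = normalize(T @ skeleton_mid).

    ``T`` has shape ``(n_channels, skeleton_size + 1)``; column *j* is the
    natural MID of the derivative atoms shifted by *j* mass units.
    """
    d = np.array([1.0])
    for elem, count in fragment.derivative_formula.items():
        base = ELEMENT_MID[elem]
        for _ in range(count):
            d = np.convolve(d, base)
    n, s = fragment.n_channels, fragment.skeleton_size
    T = np.zeros((n, s + 1))
    for j in range(s + 1):
        k = min(n - j, d.size)
        if k > 0:
            T[j : j + k, j] = d[:k]
    return T


def apply_derivative_correction(
    skeleton_mid: np.ndarray,
    fragment: FragmentIon,
    direction: str = "forward",
) -> np.ndarray:
    """Convert between skeleton-atom MIDs and observable fragment MIDs.

    ``forward`` convolves with the derivative-atom natural MID, truncates to
    the fragment's m/z window and renormalizes (simulation -> observable).
    ``inverse`` solves the corresponding linear system (observable ->
    skeleton); entries below -0.01 after solution indicate irreconcilable
    data and raise :class:`CorrectionError`.  Intended for diagnostics —
    fitting compares in observable space.
    """
    mid = np.asarray(skeleton_mid, dtype=float)
    T = correction_matrix(fragment)
    if direction == "forward":
        if mid.size != fragment.skeleton_size + 1:
            raise UsageError(
                f"fragment {fragment.name}: skeleton MID length {mid.size} != "
                f"{fragment.skeleton_size + 1}"
            )
        y = T @ mid
        return y / y.sum()
    if direction == "inverse":
        if mid.size != fragment.n_channels:
            raise UsageError(
                f"fragment {fragment.name}: observable MID length {mid.size} != "
                f"{fragment.n_channels}"
            )
        s, *_ = np.linalg.lstsq(T, mid, rcond=None)
        s = s / s.sum()
        if s.min() < -0.01:
            raise CorrectionError(
                f"fragment {fragment.name}: inverse correction produced fraction "
                f"{s.min():.4f} < -0.01; measured MID inconsistent with the model"
            )
        s = np.clip(s, 0.0, None)
        return s / s.sum()
    raise UsageError(f"direction must be 'forward' or 'inverse', got {direction!r}")


# ---------------------------------------------------------------------------
# measurement container

@dataclass
class MeasurementSet:
    """Measured fragment MIDs (and per-channel SDs) for one sample/time point."""

    sample_id: str
    time_min: float
    data: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        for name, (mid, sd) in self.data.items():
            mid = np.asarray(mid, float)
            sd = np.asarray(sd, float)
            if mid.shape != sd.shape:
                raise UsageError(f"fragment {name}: MID/SD shape mismatch")
            if (sd <= 0).any():
                raise UsageError(f"fragment {name}: SDs must be positive")
            s = mid.sum()
            if not np.isfinite(s) or abs(s - 1.0) > 0.1:
                raise UsageError(
                    f"fragment {name}: measured fractions sum to {s:.3f}, "
                    f"not close to 1"
                )
            # note: the measured fractions are deliberately NOT renormalized —
            # renormalization correlates the channels and de-calibrates the
            # chi-square statistic of the downstream regression
            self.data[name] = (mid, sd)

    def fragments(self) -> list[str]:
        return list(self.data)

    @property
    def n_channels(self) -> int:
        return sum(mid.size for mid, _ in self.data.values())


def measurement_from_frame(
    df: pd.DataFrame,
    sample_id: str,
    time_min: float,
    sd_floor: float = 0.003,
) -> MeasurementSet:
    """Build a MeasurementSet from long-format MID data.

    Expected columns: ``sample_id, time_min, fragment, mz, intensity_fraction``
    and optionally ``injection`` and ``sd``.  Replicate injections are
    averaged; if an ``sd`` column is present the per-channel SD of the mean is
    ``sd / sqrt(k)``, otherwise it defaults to
    ``max(sd_floor, half-range of the duplicates)``.
    """
    sub = df[(df["sample_id"] == sample_id) & (df["time_min"] == time_min)]
    if sub.empty:
        raise UsageError(f"no rows for sample {sample_id!r} at t={time_min}")
    data = {}
    for frag, g in sub.groupby("fragment", sort=False):
        if "injection" in g.columns:
            piv = g.pivot_table(
                index="mz", columns="injection", values="intensity_fraction"
            ).sort_index()
            vals = piv.to_numpy()
            mid = vals.mean(axis=1)
            k = vals.shape[1]
            if "sd" in g.columns:
                sd = (
                    g.pivot_table(index="mz", columns="injection", values="sd")
                    .sort_index()
                    .to_numpy()
                    .mean(axis=1)
                    / np.sqrt(k)
                )
            else:
                half_range = (vals.max(axis=1) - vals.min(axis=1)) / 2.0
                sd = np.maximum(sd_floor, half_range)
        else:
            g = g.sort_values("mz")
            mid = g["intensity_fraction"].to_numpy()
            sd = (
                g["sd"].to_numpy()
                if "sd" in g.columns
                else np.full(mid.size, sd_floor)
            )
        data[frag] = (mid, np.maximum(sd, 1e-6))
    return MeasurementSet(sample_id, float(time_min), data)


def validate_unenriched(
    measured: MeasurementSet,
    fragments: Sequence[FragmentIon],
    threshold: float = 0.005,
) -> dict[str, dict]:
    """QC of a pre-infusion (unenriched) sample against theoretical natural MIDs.

    For each fragment, reports the channel-wise maximum absolute deviation
    between the measured MID and the theoretical MID computed from natural
    isotope abundances of the full ion formula, with a pass/fail verdict at
    *threshold* (mole fraction).
    """
    if measured.time_min > BASELINE_TIME_MIN + 1e-9:
        raise UsageError(
            f"unenriched validation requires the pre-infusion baseline sample "
            f"(t = {BASELINE_TIME_MIN:g} min), got t = {measured.time_min:g}"
        )
    report = {}
    for frag in fragments:
        if frag.name not in measured.data:
            raise UsageError(f"baseline sample lacks fragment {frag.name!r}")
        mid, _ = measured.data[frag.name]
        theo = natural_mid(frag.formula, frag.n_channels)
        dev = float(np.abs(mid - theo).max())
        report[frag.name] = {"max_abs_dev": dev, "pass": dev <= threshold}
    return report
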