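"""Elementary-metabolite-unit (EMU) decomposition and steady-state MID simulation.

An EMU is a subset of one metabolite's tracked atoms; its mass isotopomer
distribution (MID) can be balanced independently of the rest of the molecule,
which reduces steady-state labeling simulation from ``2^n`` isotopomer states
to a cascade of small linear systems ordered by EMU size.  Because both heavy
isotopes tracked here (13C and 2H) shift the nominal mass by +1 Da, carbon and
hydrogen atoms enter a single pooled mass dimension, matching what a
quadrupole GC-MS instrument resolves.

The module simulates the three-tracer protocol of the hepatic glucose
production study: [6,6-2H2]glucose infusion, 2H2O-enriched body water, and
[U-13C]propionate.  Body water is a special source pool (metabolite ``Water``)
feeding every solvent-derived hydrogen in the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._isotopes import ELEMENT_MID
from .errors import IdentifiabilityError, NetworkValidationError, UsageError
from .network import Atom, MetabolicNetwork, FluxVector, stoichiometric_matrix

WATER_METABOLITE = "Water"


@dataclass(frozen=True)
class TracerSpec:
    """An isotopic tracer (or the body-water pool).

    Parameters
    ----------
    name:
        Identifier, matched against the network's ``tracer_entry`` table.
    metabolite:
        The source metabolite this tracer feeds.
    labeled_positions:
        Atoms carrying the label in the tracer molecule, e.g.
        ``(("H", 6), ("H", 7))`` for [6,6-2H2]glucose.
    purity:
        Isotopic purity: probability that a designated position of a tracer
        molecule actually carries the heavy isotope.
    enrichment:
        Fraction of the pool that is tracer (for body water, the steady-state
        2H fraction).
    """

    name: str
    metabolite: str
    labeled_positions: tuple[Atom, ...]
    purity: float = 1.0
    enrichment: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.purity <= 1.0):
            raise UsageError(f"tracer {self.name}: purity must be in (0, 1]")
        if not (0.0 <= self.enrichment <= 1.0):
            raise UsageError(f"tracer {self.name}: enrichment must be in [0, 1]")


@dataclass(frozen=True)
class EMU:
    """A nonempty subset of one metabolite's tracked atoms."""

    metabolite: str
    atoms: frozenset[Atom]

    def __post_init__(self):
        if not self.atoms:
            raise UsageError("EMU atom set must be nonempty")

    @property
    def size(self) -> int:
        return len(self.atoms)

    @property
    def sorted_atoms(self) -> tuple[Atom, ...]:
        return tuple(sorted(self.atoms))

    def _key(self):
        return (self.metabolite, self.sorted_atoms)

    def __lt__(self, other: "EMU"):
        return self._key() < other._key()

    def __repr__(self):
        atoms = ",".join(f"{e}{i}" for e, i in self.sorted_atoms)
        return f"{self.metabolite}{{{atoms}}}"


def emu_of(metabolite: str, spec: Iterable[str | Atom]) -> EMU:
    """Convenience constructor: ``emu_of("Glc", ["C1", "C2", "H5"])``."""
    atoms = []
    for a in spec:
        if isinstance(a, str):
            atoms.append((a[0], int(a[1:])))
        else:
            atoms.append(a)
    return EMU(metabolite, frozenset(atoms))


def convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cauchy product of two MIDs (the EMU condensation rule)."""
    return np.convolve(np.asarray(a, float), np.asarray(b, float))


def check_mid(mid: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Validate MID invariants (entries >= -1e-12 clipped, unit sum)."""
    mid = np.asarray(mid, dtype=float)
    if mid.min() < -1e-12 or abs(mid.sum() - 1.0) > tol:
        raise UsageError("invalid MID: negative entries or sum != 1")
    return np.clip(mid, 0.0, None)


def _atom_natural(element: str, natural_abundance: bool) -> np.ndarray:
    if not natural_abundance:
        return np.array([1.0, 0.0])
    return ELEMENT_MID[element][:2] / ELEMENT_MID[element][:2].sum()


def input_emu_mid(
    tracer_config: Sequence[TracerSpec],
    emu: EMU,
    net: MetabolicNetwork | None = None,
    natural_abundance: bool = True,
) -> np.ndarray:
    """MID of a source-metabolite EMU under the given tracer configuration.

    The pool is a two-component mixture: a fraction ``enrichment`` of tracer
    molecules (designated positions heavy with probability ``purity``, other
    positions at natural abundance) and the complement at natural abundance.
    Within each component atom states are independent, so positions combine by
    convolution.
    """
    if net is not None:
        met = net.metabolites.get(emu.metabolite)
        if met is None:
            raise UsageError(f"unknown metabolite {emu.metabolite!r}")
        if met.role != "source":
            raise UsageError(
                f"input_emu_mid called for non-source metabolite {emu.metabolite!r}"
            )
    spec = next(
        (t for t in tracer_config if t.metabolite == emu.metabolite), None
    )
    natural = np.array([1.0])
    for elem, _ in emu.sorted_atoms:
        natural = np.convolve(natural, _atom_natural(elem, natural_abundance))
    if spec is None or spec.enrichment == 0.0:
        return natural
    labeled = np.array([1.0])
    lab = set(spec.labeled_positions)
    for atom in emu.sorted_atoms:
        if atom in lab:
            labeled = np.convolve(labeled, np.array([1.0 - spec.purity, spec.purity]))
        else:
            labeled = np.convolve(labeled, _atom_natural(atom[0], natural_abundance))
    return spec.enrichment * labeled + (1.0 - spec.enrichment) * natural


def water_mid(
    tracer_config: Sequence[TracerSpec], natural_abundance: bool = True
) -> np.ndarray:
    """Single-hydrogen MID of the body-water pool."""
    return input_emu_mid(
        tracer_config,
        EMU(WATER_METABOLITE, frozenset({("H", 1)})),
        natural_abundance=natural_abundance,
    )


@dataclass(frozen=True)
class EMUTerm:
    """One production route of an EMU: flux * weight * (convolution of parts)."""

    flux: str
    weight: float
    parts: tuple[EMU, ...]
    water: int = 0

    @property
    def is_convolution(self) -> bool:
        return len(self.parts) + self.water > 1


@dataclass
class _Level:
    size: int
    unknowns: list[EMU]
    # vectorized internal coupling: A[row, col] -= f[fidx] * w
    int_rows: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    int_cols: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    int_fidx: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    int_w: np.ndarray = field(default_factory=lambda: np.empty(0))
    # diagonal (total production): A[row, row] += f[fidx] * w
    diag_rows: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    diag_fidx: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    diag_w: np.ndarray = field(default_factory=lambda: np.empty(0))
    # external terms: (row, fidx, weight, parts, water)
    external: list[tuple[int, int, float, tuple[EMU, ...], int]] = field(
        default_factory=list
    )


class EMUSystem:
    """Compiled EMU decomposition of a network for a fixed set of target EMUs.

    Construction performs the backward trace from the targets and groups the
    reachable EMUs by size; :meth:`mids` then solves the per-size linear
    balance systems for any flux vector and tracer configuration.  The
    compiled structure is reused across the many thousands of simulations a
    flux regression performs.
    """

    def __init__(self, net: MetabolicNetwork, targets: Sequence[EMU]):
        self.net = net
        self.targets = [EMU(t.metabolite, frozenset(t.atoms)) for t in targets]
        self._flux_names = net.reaction_names
        self._fidx = {n: i for i, n in enumerate(self._flux_names)}
        self._input_cache: dict = {}
        self._build()
        self._compile()

    # -- decomposition ------------------------------------------------------
    def _build(self) -> None:
        net = self.net
        nodes: dict[EMU, list[EMUTerm]] = {}
        inputs: set[EMU] = set()
        stack = list(self.targets)
        while stack:
            emu = stack.pop()
            if emu in nodes or emu in inputs:
                continue
            met = net.metabolites.get(emu.metabolite)
            if met is None:
                raise UsageError(f"unknown metabolite {emu.metabolite!r} in target EMU")
            bad = [a for a in emu.atoms if a not in met.atoms]
            if bad:
                raise UsageError(
                    f"EMU {emu!r}: atoms {bad} not tracked on {emu.metabolite}"
                )
            if met.role == "source":
                inputs.add(emu)
                continue
            terms: list[EMUTerm] = []
            for rxn in net.reactions:
                for variant in rxn.variants:
                    for (pmet, pinst), mapping in variant.sources.items():
                        if pmet != emu.metabolite:
                            continue
                        groups: dict[tuple[str, int], set[Atom]] = {}
                        water = 0
                        for atom in emu.atoms:
                            src = mapping[atom]
                            if src is None:
                                water += 1
                            else:
                                groups.setdefault((src[0], src[1]), set()).add(src[2])
                        parts = tuple(
                            sorted(
                                EMU(m, frozenset(at)) for (m, _), at in groups.items()
                            )
                        )
                        terms.append(EMUTerm(rxn.name, variant.weight, parts, water))
                        stack.extend(parts)
            if not terms:
                raise NetworkValidationError(
                    f"EMU {emu!r} has no producing reaction; its atoms cannot be "
                    f"traced to any source"
                )
            nodes[emu] = terms
        self.nodes = nodes
        self.inputs = inputs

    def emus_by_size(self) -> dict[int, set[EMU]]:
        """All reachable EMUs (unknowns and source inputs) grouped by size."""
        out: dict[int, set[EMU]] = {}
        for emu in list(self.nodes) + list(self.inputs):
            out.setdefault(emu.size, set()).add(emu)
        return out

    @property
    def n_emus(self) -> int:
        return len(self.nodes) + len(self.inputs)

    # -- compilation --------------------------------------------------------
    def _compile(self) -> None:
        sizes = sorted({e.size for e in self.nodes})
        self.levels: list[_Level] = []
        for s in sizes:
            unknowns = sorted(e for e in self.nodes if e.size == s)
            idx = {e: i for i, e in enumerate(unknowns)}
            lev = _Level(size=s, unknowns=unknowns)
            int_entries, diag_entries = [], []
            for e in unknowns:
                row = idx[e]
                for t in self.nodes[e]:
                    fi = self._fidx[t.flux]
                    diag_entries.append((row, fi, t.weight))
                    if (
                        not t.is_convolution
                        and t.parts
                        and t.parts[0] not in self.inputs
                    ):
                        int_entries.append((row, idx[t.parts[0]], fi, t.weight))
                    else:
                        lev.external.append((row, fi, t.weight, t.parts, t.water))
            if int_entries:
                r, c, f, w = zip(*int_entries)
                lev.int_rows = np.array(r)
                lev.int_cols = np.array(c)
                lev.int_fidx = np.array(f)
                lev.int_w = np.array(w)
            r, f, w = zip(*diag_entries)
            lev.diag_rows = np.array(r)
            lev.diag_fidx = np.array(f)
            lev.diag_w = np.array(w)
            self.levels.append(lev)

    # -- input MIDs ---------------------------------------------------------
    def _inputs_for(self, tracers: tuple[TracerSpec, ...], na: bool):
        key = (tracers, na)
        cached = self._input_cache.get(key)
        if cached is None:
            cached = {
                e: input_emu_mid(tracers, e, self.net, natural_abundance=na)
                for e in self.inputs
            }
            cached["__water__"] = water_mid(tracers, natural_abundance=na)
            self._input_cache[key] = cached
        return cached

    # -- simulation ---------------------------------------------------------
    def mids(
        self,
        fluxes: Mapping[str, float] | FluxVector | np.ndarray,
        tracer_config: Sequence[TracerSpec],
        natural_abundance: bool = True,
    ) -> dict[EMU, np.ndarray]:
        """Solve all EMU balances; returns MIDs for every non-source EMU."""
        if isinstance(fluxes, FluxVector):
            f = fluxes.as_array(self._flux_names)
        elif isinstance(fluxes, np.ndarray):
            f = np.asarray(fluxes, float)
        else:
            f = np.array([fluxes[n] for n in self._flux_names], float)
        f = np.clip(f, 0.0, None)
        fscale = f.max()
        if fscale <= 0:
            raise UsageError("all fluxes are zero")
        tracers = tuple(tracer_config)
        inputs = self._inputs_for(tracers, natural_abundance)
        wmid = inputs["__water__"]
        solved: dict[EMU, np.ndarray] = {}

        def mid_of(e: EMU) -> np.ndarray:
            got = solved.get(e)
            return got if got is not None else inputs[e]

        for lev in self.levels:
            n = len(lev.unknowns)
            A = np.zeros((n, n))
            np.add.at(
                A,
                (lev.diag_rows, lev.diag_rows),
                f[lev.diag_fidx] * lev.diag_w,
            )
            if lev.int_rows.size:
                np.add.at(
                    A,
                    (lev.int_rows, lev.int_cols),
                    -f[lev.int_fidx] * lev.int_w,
                )
            R = np.zeros((n, lev.size + 1))
            for row, fi, w, parts, water in lev.external:
                coef = f[fi] * w
                if coef == 0.0:
                    continue
                m = np.array([1.0])
                for p in parts:
                    m = np.convolve(m, mid_of(p))
                for _ in range(water):
                    m = np.convolve(m, wmid)
                R[row] += coef * m
            diag = A.diagonal().copy()
            dead = diag <= 1e-12 * fscale
            if dead.any():
                which = lev.unknowns[int(np.flatnonzero(dead)[0])]
                raise IdentifiabilityError(
                    f"EMU {which!r} receives zero production flux; the labeling "
                    f"state of its pool is undefined"
                )
            try:
                X = np.linalg.solve(A / diag[:, None], R / diag[:, None])
            except np.linalg.LinAlgError as exc:
                raise IdentifiabilityError(
                    f"singular EMU balance system at size {lev.size}"
                ) from exc
            X = np.clip(X, 0.0, None)
            X /= X.sum(axis=1, keepdims=True)
            for i, e in enumerate(lev.unknowns):
                solved[e] = X[i]
        return solved


def decompose_emus(net: MetabolicNetwork, targets: Sequence[EMU]) -> EMUSystem:
    """Backward-trace the EMUs needed to simulate *targets*; see :class:`EMUSystem`."""
    return EMUSystem(net, targets)


def simulate_mids(
    net: MetabolicNetwork,
    flux: FluxVector | Mapping[str, float],
    tracer_config: Sequence[TracerSpec],
    targets: Sequence[EMU],
    natural_abundance: bool = True,
    check_balance: bool = True,
) -> dict[EMU, np.ndarray]:
    """Simulate steady-state MIDs of the target EMUs under a flux vector.

    Steady-state labeling depends only on flux ratios, so any positive scaling
    of a balanced flux vector yields identical MIDs.
    """
    if check_balance:
        S, _, cols = stoichiometric_matrix(net)
        vals = flux.values if isinstance(flux, FluxVector) else flux
        v = np.array([vals[c] for c in cols], float)
        resid = np.abs(S @ v).max()
        if resid > 1e-6 * max(1.0, np.abs(v).max()):
            raise UsageError(
                f"flux vector violates steady-state balance (residual {resid:.3g})"
            )
    system = EMUSystem(net, targets)
    sol = system.mids(flux, tracer_config, natural_abundance=natural_abundance)
    return {t: sol[t] for t in system.targets}
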