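"""Atom-transition network model for hepatic glucose-production / TCA fluxes.

A network couples ordinary stoichiometry (used for steady-state flux balances)
with per-atom carbon and hydrogen transition maps (used for isotope labeling
simulation).  Networks are read from a small tab-separated dialect::

    #METABOLITES
    # name  carbons  hydrogens  role
    OAA     4   0   balanced
    ...
    #REACTIONS
    # name  reversible  equation
    V_CS    0   OAA(C:abcd) + AcCoA(C:ef) -> SucCoA(C:cbfe) + CO2out(C:a) + CO2out(C:d)
    ...
    #TRACERS
    # source_metabolite  tracer_name
    Water   body_water

Atom labels are single characters scoped to one reaction; hydrogen labels may
use ``@`` on the product side to mark a solvent-derived atom drawn from the
body-water pool.  A reaction may list several equiprobable atom-map variants
separated by ``||`` (used for passage through symmetric intermediates such as
succinate/fumarate).  Reversible reactions (flag 1) are expanded into a
forward/reverse column pair; the reverse map is the inverse of the forward
one, which therefore must be bijective.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    AtomBalanceError,
    InfeasibleConstraintError,
    NetworkParseError,
    NetworkValidationError,
)

#: An atom is identified by element and 1-based position, e.g. ``("C", 3)``.
Atom = tuple[str, int]

#: Sentinel source for solvent-derived (body water) hydrogens.
WATER = "@"

_ROLES = ("balanced", "source", "sink", "pool")


@dataclass(frozen=True)
class Metabolite:
    """A metabolite pool with tracked carbon and hydrogen positions."""

    name: str
    carbon_count: int
    hydrogen_slots: int
    role: str = "balanced"

    def __post_init__(self):
        if self.role not in _ROLES:
            raise NetworkValidationError(
                f"metabolite {self.name}: unknown role {self.role!r}"
            )
        if self.carbon_count < 0 or self.hydrogen_slots < 0:
            raise NetworkValidationError(f"metabolite {self.name}: negative atom count")

    @property
    def atoms(self) -> tuple[Atom, ...]:
        return tuple(("C", i + 1) for i in range(self.carbon_count)) + tuple(
            ("H", i + 1) for i in range(self.hydrogen_slots)
        )

    @property
    def n_atoms(self) -> int:
        return self.carbon_count + self.hydrogen_slots


@dataclass(frozen=True)
class AtomMap:
    """One product atom and where it comes from.

    ``reactant_atom`` is ``None`` for solvent-derived hydrogens; otherwise it
    is ``(metabolite, instance, atom)`` with *instance* disambiguating repeated
    reactants (e.g. the two trioses entering aldolase).
    """

    product_atom: tuple[str, int, Atom]
    reactant_atom: tuple[str, int, Atom] | None


@dataclass
class ReactionVariant:
    """A single atom-mapping alternative of a reaction, with its probability."""

    weight: float
    # (metabolite name, carbon label string, hydrogen label string) per side,
    # in written order; retained verbatim for faithful round-trip writing.
    reactants: list[tuple[str, str, str]]
    products: list[tuple[str, str, str]]
    # (product met, instance) -> {product atom -> source}; source is either
    # (reactant met, instance, atom) or None for body water.
    sources: dict[tuple[str, int], dict[Atom, tuple[str, int, Atom] | None]]

    def atom_maps(self) -> list[AtomMap]:
        out = []
        for (met, inst), mapping in self.sources.items():
            for atom, src in mapping.items():
                out.append(AtomMap(product_atom=(met, inst, atom), reactant_atom=src))
        return out


@dataclass
class Reaction:
    name: str
    reversible: bool
    stoichiometry: dict[str, int]
    variants: list[ReactionVariant]

    @property
    def atom_maps(self) -> list[AtomMap]:
        """Atom maps of the first (or only) variant."""
        return self.variants[0].atom_maps()


@dataclass
class MetabolicNetwork:
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    tracer_entry: dict[str, str] = field(default_factory=dict)
    header_comments: list[str] = field(default_factory=list)

    def reaction(self, name: str) -> Reaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def reaction_names(self) -> list[str]:
        return [r.name for r in self.reactions]

    def producing(self, met: str) -> list[Reaction]:
        return [r for r in self.reactions if r.stoichiometry.get(met, 0) > 0]

    def consuming(self, met: str) -> list[Reaction]:
        return [r for r in self.reactions if r.stoichiometry.get(met, 0) < 0]


@dataclass
class FluxVector:
    """Named fluxes; ``basis`` is 'relative' (V_CS = 100) or 'absolute' (umol/kg/min)."""

    values: dict[str, float]
    basis: str = "relative"

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.values[n] for n in order], dtype=float)

    def scaled(self, factor: float, basis: str) -> "FluxVector":
        return FluxVector({k: v * factor for k, v in self.values.items()}, basis=basis)


# ---------------------------------------------------------------------------
# parsing

_MET_TOKEN = re.compile(r"^([A-Za-z0-9_]+)\(([^()]*)\)$")


def _parse_side(side: str, lineno: int) -> list[tuple[str, str, str]]:
    entries = []
    for token in side.split(" + "):
        token = token.strip()
        if not token:
            raise NetworkParseError("empty metabolite term", lineno)
        m = _MET_TOKEN.match(token)
        if not m:
            raise NetworkParseError(f"cannot parse metabolite term {token!r}", lineno)
        name, inner = m.group(1), m.group(2)
        labels = {"C": "", "H": ""}
        for part in inner.split("|"):
            part = part.strip()
            if not part:
                continue
            if ":" not in part:
                raise NetworkParseError(f"bad atom-label field {part!r}", lineno)
            elem, lab = part.split(":", 1)
            elem = elem.strip()
            if elem not in ("C", "H"):
                raise NetworkParseError(f"unknown element {elem!r}", lineno)
            labels[elem] = lab.strip()
        entries.append((name, labels["C"], labels["H"]))
    return entries


def _build_variant(
    weight: float,
    reactants: list[tuple[str, str, str]],
    products: list[tuple[str, str, str]],
    mets: dict[str, Metabolite],
    rxn_name: str,
    lineno: int,
) -> ReactionVariant:
    # index reactant atoms by label
    label_src: dict[str, tuple[str, int, Atom]] = {}
    seen_inst: dict[str, int] = {}
    for name, clab, hlab in reactants:
        if name not in mets:
            raise NetworkParseError(f"unknown metabolite {name!r}", lineno)
        met = mets[name]
        inst = seen_inst.get(name, 0)
        seen_inst[name] = inst + 1
        if len(clab) != met.carbon_count or len(hlab) != met.hydrogen_slots:
            raise AtomBalanceError(
                f"reaction {rxn_name}: {name} labels ({clab!r},{hlab!r}) do not match "
                f"declared atom counts ({met.carbon_count}C,{met.hydrogen_slots}H)"
            )
        for i, ch in enumerate(clab):
            if ch in label_src:
                raise AtomBalanceError(
                    f"reaction {rxn_name}: duplicate reactant label {ch!r}"
                )
            label_src[ch] = (name, inst, ("C", i + 1))
        for i, ch in enumerate(hlab):
            if ch == WATER:
                raise AtomBalanceError(
                    f"reaction {rxn_name}: '@' is only valid on the product side"
                )
            if ch in label_src:
                raise AtomBalanceError(
                    f"reaction {rxn_name}: duplicate reactant label {ch!r}"
                )
            label_src[ch] = (name, inst, ("H", i + 1))

    sources: dict[tuple[str, int], dict[Atom, tuple[str, int, Atom] | None]] = {}
    used: set[str] = set()
    seen_inst = {}
    for name, clab, hlab in products:
        if name not in mets:
            raise NetworkParseError(f"unknown metabolite {name!r}", lineno)
        met = mets[name]
        inst = seen_inst.get(name, 0)
        seen_inst[name] = inst + 1
        if len(clab) != met.carbon_count or len(hlab) != met.hydrogen_slots:
            raise AtomBalanceError(
                f"reaction {rxn_name}: {name} labels ({clab!r},{hlab!r}) do not match "
                f"declared atom counts ({met.carbon_count}C,{met.hydrogen_slots}H)"
            )
        mapping: dict[Atom, tuple[str, int, Atom] | None] = {}
        for i, ch in enumerate(clab):
            src = label_src.get(ch)
            if src is None or src[2][0] != "C":
                raise AtomBalanceError(
                    f"reaction {rxn_name}: product atom {name} C{i + 1} has no "
                    f"carbon source (label {ch!r})"
                )
            if ch in used:
                raise AtomBalanceError(
                    f"reaction {rxn_name}: reactant atom {ch!r} used twice"
                )
            used.add(ch)
            mapping[("C", i + 1)] = src
        for i, ch in enumerate(hlab):
            if ch == WATER:
                mapping[("H", i + 1)] = None
                continue
            src = label_src.get(ch)
            if src is None or src[2][0] != "H":
                raise AtomBalanceError(
                    f"reaction {rxn_name}: product atom {name} H{i + 1} has no "
                    f"hydrogen source (label {ch!r})"
                )
            if ch in used:
                raise AtomBalanceError(
                    f"reaction {rxn_name}: reactant atom {ch!r} used twice"
                )
            used.add(ch)
            mapping[("H", i + 1)] = src
        sources[(name, inst)] = mapping

    # strict carbon conservation: every reactant carbon must reach a product
    for lab, (mname, inst, atom) in label_src.items():
        if atom[0] == "C" and lab not in used:
            raise AtomBalanceError(
                f"reaction {rxn_name}: reactant carbon {mname} C{atom[1]} "
                f"(label {lab!r}) is not mapped to any product"
            )
    return ReactionVariant(weight, list(reactants), list(products), sources)


def _stoich_of(variant: ReactionVariant) -> dict[str, int]:
    st: dict[str, int] = {}
    for name, _, _ in variant.reactants:
        st[name] = st.get(name, 0) - 1
    for name, _, _ in variant.products:
        st[name] = st.get(name, 0) + 1
    return {k: v for k, v in st.items() if v != 0}


def _invert_variant(v: ReactionVariant, rxn_name: str) -> ReactionVariant:
    for (met, inst), mapping in v.sources.items():
        for atom, src in mapping.items():
            if src is None:
                raise AtomBalanceError(
                    f"reaction {rxn_name}: cannot reverse a reaction with "
                    f"solvent-derived atoms"
                )
    # check bijectivity: every reactant atom used
    n_react = sum(
        len(clab) + len(hlab) for _, clab, hlab in v.reactants
    )
    n_mapped = sum(len(m) for m in v.sources.values())
    if n_mapped != n_react:
        raise AtomBalanceError(
            f"reaction {rxn_name}: atom map is not bijective, cannot reverse"
        )
    inv_sources: dict[tuple[str, int], dict[Atom, tuple[str, int, Atom] | None]] = {}
    for (pmet, pinst), mapping in v.sources.items():
        for atom, src in mapping.items():
            rmet, rinst, ratom = src  # type: ignore[misc]
            inv_sources.setdefault((rmet, rinst), {})[ratom] = (pmet, pinst, atom)
    return ReactionVariant(v.weight, list(v.products), list(v.reactants), inv_sources)


def parse_network(path_or_text) -> MetabolicNetwork:
    """Parse and validate a network file (path, or the file content itself)."""
    text = str(path_or_text)
    if "\n" not in text:
        with open(text, "r", encoding="utf-8") as fh:
            text = fh.read()

    mets: dict[str, Metabolite] = {}
    tracer_entry: dict[str, str] = {}
    header: list[str] = []
    raw_reactions: list[tuple[int, str, bool, str]] = []
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        if line.strip() in ("#METABOLITES", "#REACTIONS", "#TRACERS"):
            section = line.strip()[1:]
            continue
        if line.lstrip().startswith("#"):
            if section is None:
                header.append(line.lstrip("# ").rstrip())
            continue
        fields = [f.strip() for f in line.split("\t") if f.strip() != ""]
        if section == "METABOLITES":
            if len(fields) != 4:
                raise NetworkParseError(
                    f"expected 4 tab-separated fields, got {len(fields)}", lineno
                )
            name, c, h, role = fields
            if name in mets:
                raise NetworkParseError(f"duplicate metabolite {name!r}", lineno)
            try:
                mets[name] = Metabolite(name, int(c), int(h), role)
            except ValueError as exc:
                raise NetworkParseError(str(exc), lineno) from exc
        elif section == "REACTIONS":
            if len(fields) != 3:
                raise NetworkParseError(
                    f"expected 3 tab-separated fields, got {len(fields)}", lineno
                )
            name, rev, eqn = fields
            if rev not in ("0", "1"):
                raise NetworkParseError(f"reversible flag must be 0/1, got {rev!r}", lineno)
            raw_reactions.append((lineno, name, rev == "1", eqn))
        elif section == "TRACERS":
            if len(fields) != 2:
                raise NetworkParseError("expected 2 fields in #TRACERS", lineno)
            tracer_entry[fields[0]] = fields[1]
        else:
            raise NetworkParseError("content outside any #SECTION", lineno)

    reactions: list[Reaction] = []
    for lineno, name, reversible, eqn in raw_reactions:
        variants: list[ReactionVariant] = []
        alts = [a.strip() for a in eqn.split("||")]
        w = 1.0 / len(alts)
        for alt in alts:
            if "->" not in alt:
                raise NetworkParseError("equation lacks '->'", lineno)
            lhs, rhs = alt.split("->", 1)
            variants.append(
                _build_variant(
                    w, _parse_side(lhs, lineno), _parse_side(rhs, lineno), mets, name, lineno
                )
            )
        st = _stoich_of(variants[0])
        for v in variants[1:]:
            if _stoich_of(v) != st:
                raise AtomBalanceError(
                    f"reaction {name}: atom-map variants disagree on stoichiometry"
                )
        reactions.append(Reaction(name, reversible, st, variants))
        if reversible:
            inv = [_invert_variant(v, name) for v in variants]
            reactions.append(
                Reaction(
                    name + ".rev",
                    True,
                    {k: -c for k, c in st.items()},
                    inv,
                )
            )

    net = MetabolicNetwork(mets, reactions, tracer_entry, header)
    validate_network(net)
    return net


def validate_network(net: MetabolicNetwork) -> None:
    """Check role/connectivity invariants and the existence of a flux space."""
    names = {r.name for r in net.reactions}
    if len(names) != len(net.reactions):
        raise NetworkValidationError("duplicate reaction names")
    for met in net.metabolites.values():
        prod = net.producing(met.name)
        cons = net.consuming(met.name)
        if met.role == "balanced":
            if not prod or not cons:
                raise NetworkValidationError(
                    f"balanced metabolite {met.name} must be both produced and consumed"
                )
        elif met.role == "source":
            if prod:
                raise NetworkValidationError(
                    f"source metabolite {met.name} has a producing reaction"
                )
        elif met.role == "sink":
            if cons:
                raise NetworkValidationError(
                    f"sink metabolite {met.name} has a consuming reaction"
                )
            if not prod:
                raise NetworkValidationError(
                    f"sink metabolite {met.name} is never produced"
                )
        elif met.role == "pool":
            # isotopically balanced, stoichiometrically vented (e.g. CO2):
            # its labeling is the production-weighted inflow mixture, and it
            # may be drawn on as a reactant without a mass balance row
            if not prod:
                raise NetworkValidationError(
                    f"pool metabolite {met.name} is never produced"
                )
    S, rows, cols = stoichiometric_matrix(net)
    if S.size and np.linalg.matrix_rank(S) >= len(cols):
        raise NetworkValidationError(
            "stoichiometric matrix has a trivial null space; no steady-state flux "
            "distribution exists"
        )


def write_network(net: MetabolicNetwork, path) -> None:
    """Write a network back to the TSV dialect accepted by :func:`parse_network`."""
    lines = [f"# {c}" for c in net.header_comments]
    lines.append("#METABOLITES")
    for m in net.metabolites.values():
        lines.append(f"{m.name}\t{m.carbon_count}\t{m.hydrogen_slots}\t{m.role}")
    lines.append("#REACTIONS")
    for r in net.reactions:
        if r.name.endswith(".rev"):
            continue  # re-generated on parse from the forward direction
        alts = []
        for v in r.variants:
            def side(entries):
                toks = []
                for name, clab, hlab in entries:
                    inner = []
                    if clab:
                        inner.append(f"C:{clab}")
                    if hlab:
                        inner.append(f"H:{hlab}")
                    toks.append(f"{name}({'|'.join(inner)})")
                return " + ".join(toks)

            alts.append(f"{side(v.reactants)} -> {side(v.products)}")
        lines.append(f"{r.name}\t{1 if r.reversible else 0}\t{' || '.join(alts)}")
    if net.tracer_entry:
        lines.append("#TRACERS")
        for met, tr in net.tracer_entry.items():
            lines.append(f"{met}\t{tr}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# flux space

def stoichiometric_matrix(net: MetabolicNetwork):
    """Stoichiometric matrix over balanced metabolites.

    Returns ``(S, balanced_names, reaction_names)`` with
    ``S[i, j]`` the signed coefficient of balanced metabolite *i* in reaction *j*.
    """
    rows = [m.name for m in net.metabolites.values() if m.role == "balanced"]
    cols = net.reaction_names
    S = np.zeros((len(rows), len(cols)))
    for j, r in enumerate(net.reactions):
        for i, met in enumerate(rows):
            S[i, j] = r.stoichiometry.get(met, 0)
    return S, rows, cols


@dataclass
class FluxBasis:
    """Affine parameterization of the steady-state flux space.

    ``v = offset + basis @ theta`` enumerates all flux vectors satisfying
    ``S v = 0`` and the fixed constraints; ``theta`` holds the values of the
    *free* fluxes named in ``free_names``.
    """

    reaction_names: list[str]
    free_names: list[str]
    offset: np.ndarray          # (R,)
    basis: np.ndarray           # (R, F)
    fixed: dict[str, float]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def full_array(self, theta: np.ndarray) -> np.ndarray:
        return self.offset + self.basis @ np.asarray(theta, dtype=float)

    def flux_vector(self, theta, basis: str = "relative") -> FluxVector:
        v = self.full_array(theta)
        return FluxVector(dict(zip(self.reaction_names, v)), basis=basis)

    def theta_of(self, flux: Mapping[str, float] | FluxVector) -> np.ndarray:
        vals = flux.values if isinstance(flux, FluxVector) else flux
        return np.array([vals[n] for n in self.free_names], dtype=float)


def free_flux_basis(
    net: MetabolicNetwork,
    fixed: Mapping[str, float],
    preferred_free: Iterable[str] | None = None,
) -> FluxBasis:
    """Parameterize the flux space subject to fixed constraints.

    The free parameters are an automatically chosen subset of reaction fluxes;
    names listed in *preferred_free* are kept free whenever possible (they are
    considered last when choosing dependent pivots).
    """
    S, _, cols = stoichiometric_matrix(net)
    col_idx = {n: j for j, n in enumerate(cols)}
    for name in fixed:
        if name not in col_idx:
            raise InfeasibleConstraintError(f"unknown flux {name!r} in constraints")
    nR = len(cols)
    rows = [S]
    b = [np.zeros(S.shape[0])]
    for name, val in fixed.items():
        e = np.zeros(nR)
        e[col_idx[name]] = 1.0
        rows.append(e[None, :])
        b.append(np.array([float(val)]))
    A = np.vstack(rows)
    rhs = np.concatenate(b)

    preferred = list(preferred_free or [])
    order = [j for j in range(nR) if cols[j] not in preferred] + [
        col_idx[n] for n in preferred if n in col_idx
    ]

    # Gauss-Jordan elimination choosing pivots in `order`
    M = np.hstack([A, rhs[:, None]]).astype(float)
    tol = 1e-10
    pivots: list[int] = []
    pivot_rows: list[int] = []
    nrow = M.shape[0]
    for j in order:
        candidates = [r for r in range(nrow) if r not in pivot_rows]
        if not candidates:
            break
        r = max(candidates, key=lambda rr: abs(M[rr, j]))
        if abs(M[r, j]) <= tol:
            continue
        M[r] /= M[r, j]
        for rr in range(nrow):
            if rr != r and abs(M[rr, j]) > 0:
                M[rr] -= M[rr, j] * M[r]
        pivots.append(j)
        pivot_rows.append(r)
    # consistency of remaining rows
    for r in range(nrow):
        if r not in pivot_rows and abs(M[r, -1]) > 1e-8 * max(1.0, abs(rhs).max()):
            raise InfeasibleConstraintError(
                "fixed constraints are inconsistent with the steady-state balances"
            )
    free_idx = [j for j in range(nR) if j not in pivots]
    # deterministic ordering: preferred order first, then file order
    pref_set = [col_idx[n] for n in preferred if col_idx.get(n) in free_idx]
    free_idx = pref_set + [j for j in free_idx if j not in pref_set]

    offset = np.zeros(nR)
    basis = np.zeros((nR, len(free_idx)))
    for k, j in enumerate(free_idx):
        basis[j, k] = 1.0
    for j, r in zip(pivots, pivot_rows):
        offset[j] = M[r, -1]
        for k, jf in enumerate(free_idx):
            basis[j, k] = -M[r, jf]
    return FluxBasis(
        reaction_names=list(cols),
        free_names=[cols[j] for j in free_idx],
        offset=offset,
        basis=basis,
        fixed=dict(fixed),
    )
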