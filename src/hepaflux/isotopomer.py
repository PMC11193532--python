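"""Full isotopomer-enumeration labeling simulator.

Independent cross-check for the EMU cascade: every metabolite's complete
joint labeling distribution (``2^n`` states over its tracked atoms) is
balanced by fixed-point iteration of the steady-state mixing equations.
Exponential in atom count, so only usable on small networks — which is
exactly its role: an oracle the EMU solver is verified against on toy
models before being trusted on the full liver network.
"""

from __future__ import annotations

import string
from typing import Mapping, Sequence

import numpy as np

from .emu import EMU, TracerSpec, _atom_natural, water_mid
from .errors import UsageError
from .network import FluxVector, MetabolicNetwork


def _atom_vector(
    atom, spec: TracerSpec | None, natural_abundance: bool, in_tracer: bool
) -> np.ndarray:
    if in_tracer and spec is not None and atom in set(spec.labeled_positions):
        return np.array([1.0 - spec.purity, spec.purity])
    return _atom_natural(atom[0], natural_abundance)


def _source_distribution(met, spec, natural_abundance: bool) -> np.ndarray:
    atoms = met.atoms
    nat = np.array(1.0)
    for a in atoms:
        nat = np.multiply.outer(nat, _atom_vector(a, None, natural_abundance, False))
    if spec is None or spec.enrichment == 0.0:
        return nat
    lab = np.array(1.0)
    for a in atoms:
        lab = np.multiply.outer(lab, _atom_vector(a, spec, natural_abundance, True))
    return spec.enrichment * lab + (1.0 - spec.enrichment) * nat


def _marginal(dist: np.ndarray, keep: Sequence[int]) -> np.ndarray:
    drop = tuple(i for i in range(dist.ndim) if i not in keep)
    return dist.sum(axis=drop) if drop else dist


def isotopomer_distributions(
    net: MetabolicNetwork,
    fluxes: Mapping[str, float] | FluxVector,
    tracer_config: Sequence[TracerSpec],
    natural_abundance: bool = True,
    tol: float = 1e-13,
    max_iter: int = 20000,
) -> dict[str, np.ndarray]:
    """Joint labeling distribution of every metabolite, shape ``(2,)*n_atoms``."""
    vals = fluxes.values if isinstance(fluxes, FluxVector) else fluxes
    f = {r.name: max(float(vals[r.name]), 0.0) for r in net.reactions}
    wv = water_mid(tracer_config, natural_abundance)

    dists: dict[str, np.ndarray] = {}
    for met in net.metabolites.values():
        spec = next((t for t in tracer_config if t.metabolite == met.name), None)
        if met.role == "source":
            dists[met.name] = _source_distribution(met, spec, natural_abundance)
        else:
            d = np.array(1.0)
            for a in met.atoms:
                d = np.multiply.outer(d, _atom_natural(a[0], natural_abundance))
            dists[met.name] = d

    # production terms per non-source metabolite
    letters = string.ascii_letters
    updates: dict[str, list] = {}
    for met in net.metabolites.values():
        if met.role == "source":
            continue
        terms = []
        axis_of = {a: i for i, a in enumerate(met.atoms)}
        for rxn in net.reactions:
            for variant in rxn.variants:
                for (pmet, pinst), mapping in variant.sources.items():
                    if pmet != met.name:
                        continue
                    groups: dict[tuple[str, int], list] = {}
                    water_atoms = []
                    for patom in met.atoms:
                        src = mapping[patom]
                        if src is None:
                            water_atoms.append(patom)
                        else:
                            groups.setdefault((src[0], src[1]), []).append(
                                (patom, src[2])
                            )
                    terms.append(
                        (rxn.name, variant.weight, groups, water_atoms, axis_of)
                    )
        if terms:
            updates[met.name] = terms

    def term_distribution(groups, water_atoms, axis_of) -> np.ndarray:
        subs, ops = [], []
        for (rmet, _), pairs in groups.items():
            ratoms = net.metabolites[rmet].atoms
            rpos = {a: i for i, a in enumerate(ratoms)}
            pairs_sorted = sorted(pairs, key=lambda pr: rpos[pr[1]])
            keep = [rpos[src] for _, src in pairs_sorted]
            marg = _marginal(dists[rmet], keep)
            subs.append("".join(letters[axis_of[p]] for p, _ in pairs_sorted))
            ops.append(marg)
        for patom in water_atoms:
            subs.append(letters[axis_of[patom]])
            ops.append(wv)
        out = "".join(letters[i] for i in range(len(axis_of)))
        return np.einsum(",".join(subs) + "->" + out, *ops)

    names = list(updates)
    for _ in range(max_iter):
        delta = 0.0
        for name in names:
            total, acc = 0.0, 0.0
            for rname, w, groups, water_atoms, axis_of in updates[name]:
                coef = f[rname] * w
                if coef == 0.0:
                    continue
                total += coef
                acc = acc + coef * term_distribution(groups, water_atoms, axis_of)
            if total == 0.0:
                raise UsageError(f"metabolite {name} has zero production flux")
            new = acc / total
            # renormalize: total probability is conserved exactly in exact
            # arithmetic, but condensations inside cycles (e.g. CO2
            # refixation) amplify floating-point mass deficits multiplicatively,
            # so the unit-sum manifold must be enforced for stability
            new = new / new.sum()
            delta = max(delta, float(np.abs(new - dists[name]).max()))
            dists[name] = new
        if delta < tol:
            break
    else:
        raise RuntimeError("isotopomer fixed point did not converge")
    return dists


def isotopomer_mid(
    dists: Mapping[str, np.ndarray], net: MetabolicNetwork, emu: EMU
) -> np.ndarray:
    """MID of an EMU computed from the full joint isotopomer distribution."""
    met = net.metabolites[emu.metabolite]
    pos = {a: i for i, a in enumerate(met.atoms)}
    keep = sorted(pos[a] for a in emu.atoms)
    marg = _marginal(dists[emu.metabolite], keep).ravel()
    k = len(keep)
    ones = np.array([bin(i).count("1") for i in range(2**k)])
    mid = np.zeros(k + 1)
    np.add.at(mid, ones, marg)
    return mid


def simulate_mids_bruteforce(
    net: MetabolicNetwork,
    fluxes,
    tracer_config: Sequence[TracerSpec],
    targets: Sequence[EMU],
    natural_abundance: bool = True,
) -> dict[EMU, np.ndarray]:
    """Brute-force counterpart of :func:`hepaflux.emu.simulate_mids`."""
    dists = isotopomer_distributions(net, fluxes, tracer_config, natural_abundance)
    return {t: isotopomer_mid(dists, net, t) for t in targets}
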