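"""Compartmentalized stoichiometric networks.

A :class:`MetabolicNetwork` holds metabolites (each with an elemental
formula and one of three compartments: extracellular, cytosol,
mitochondria), reactions with exact-rational stoichiometry, and a set of
designated exchange reactions that cross the system boundary.  Internal
reactions must be element-balanced for C, H, O, N, S and P; exchange
reactions touch exactly one metabolite and are exempt.

All coefficients are :class:`fractions.Fraction`; floating point enters
only at the LP layer (:mod:`ascoflux.yields`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

from .formula import ELEMENTS, Formula
from .linalg import Matrix

COMPARTMENTS = ("extracellular", "cytosol", "mitochondria")
COMPARTMENT_SUFFIX = {"extracellular": "e", "cytosol": "c", "mitochondria": "m"}
SUFFIX_COMPARTMENT = {v: k for k, v in COMPARTMENT_SUFFIX.items()}


class NetworkError(ValueError):
    """Structural problem with a network definition."""


class UnknownMetaboliteError(NetworkError, KeyError):
    pass


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str
    formula: Formula
    is_exchangeable: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not one of {COMPARTMENTS}"
            )


@dataclass(frozen=True)
class Reaction:
    """Stoichiometry over metabolite ids; negative coefficients are consumed."""

    id: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool = False
    pathway_tag: str = ""
    exclusion_group: str | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id!r}: empty stoichiometry")
        clean = {}
        for met, coeff in self.stoichiometry.items():
            c = Fraction(coeff)
            if c == 0:
                raise NetworkError(f"reaction {self.id!r}: zero coefficient for {met!r}")
            clean[met] = c
        object.__setattr__(self, "stoichiometry", clean)

    @property
    def substrates(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


class MetabolicNetwork:
    """Reactions + metabolites + designated boundary (exchange) reactions."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        exchange_ids: Iterable[str] = (),
        name: str = "network",
    ) -> None:
        self.name = name
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise NetworkError(f"duplicate metabolite id {met.id!r}")
            self.metabolites[met.id] = met
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise NetworkError(f"duplicate reaction id {rxn.id!r}")
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise UnknownMetaboliteError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
            self.reactions[rxn.id] = rxn
        self.exchange_ids = set(exchange_ids)
        unknown = self.exchange_ids - self.reactions.keys()
        if unknown:
            raise NetworkError(f"exchange ids not in network: {sorted(unknown)}")
        for ex in self.exchange_ids:
            if len(self.reactions[ex].stoichiometry) != 1:
                raise NetworkError(
                    f"exchange reaction {ex!r} must touch exactly one metabolite"
                )

    # -- convenience ---------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def is_exchange(self, reaction_id: str) -> bool:
        return reaction_id in self.exchange_ids

    def internal_metabolite_ids(self) -> list[str]:
        """Metabolites balanced at steady state: all except those touched only
        by their own exchange reaction are internal; a metabolite that has an
        exchange reaction still appears as a row (the exchange column drains it).
        """
        return list(self.metabolites)

    def copy(self, name: str | None = None) -> "MetabolicNetwork":
        return MetabolicNetwork(
            self.metabolites.values(),
            self.reactions.values(),
            set(self.exchange_ids),
            name=name or self.name,
        )

    def with_reactions(
        self,
        add: Iterable[Reaction] = (),
        add_metabolites: Iterable[Metabolite] = (),
        remove: Iterable[str] = (),
        add_exchanges: Iterable[str] = (),
        name: str | None = None,
    ) -> "MetabolicNetwork":
        mets = dict(self.metabolites)
        for met in add_metabolites:
            mets.setdefault(met.id, met)
        rxns = {rid: r for rid, r in self.reactions.items() if rid not in set(remove)}
        for rxn in add:
            rxns[rxn.id] = rxn
        exch = (self.exchange_ids - set(remove)) | set(add_exchanges)
        return MetabolicNetwork(mets.values(), rxns.values(), exch, name=name or self.name)


def check_mass_balance(reaction: Reaction, network: MetabolicNetwork) -> dict[str, Fraction | str]:
    """Element residuals (products minus substrates) for one reaction.

    Exchange reactions are flagged ``{'exempt': ...}`` instead of checked:
    they carry material across the system boundary by construction.
    """
    if network.is_exchange(reaction.id):
        return {"exempt": "exchange"}
    residual = {el: Fraction(0) for el in ELEMENTS}
    for met_id, coeff in reaction.stoichiometry.items():
        try:
            met = network.metabolites[met_id]
        except KeyError:
            raise UnknownMetaboliteError(
                f"reaction {reaction.id!r} references unknown metabolite {met_id!r}"
            ) from None
        for el, n in met.formula.counts().items():
            residual[el] += coeff * n
    return residual


def build_matrix(
    network: MetabolicNetwork,
) -> tuple[Matrix, list[str], list[str]]:
    """Stoichiometric matrix over internal metabolites.

    Returns ``(S, metabolite_ids, reaction_ids)`` with ``S[i][j]`` the
    coefficient of metabolite ``i`` in reaction ``j``.  Every metabolite is
    a row (boundary flows appear as exchange columns); column order follows
    insertion order of the reactions and is stable.
    """
    if not network.reactions or not network.metabolites:
        raise NetworkError("cannot build matrix of an empty network")
    met_ids = network.internal_metabolite_ids()
    rxn_ids = network.reaction_ids
    met_index = {m: i for i, m in enumerate(met_ids)}
    S: Matrix = [[Fraction(0)] * len(rxn_ids) for _ in met_ids]
    for j, rid in enumerate(rxn_ids):
        for met_id, coeff in network.reactions[rid].stoichiometry.items():
            S[met_index[met_id]][j] = coeff
    return S, met_ids, rxn_ids


def split_reversible(
    network: MetabolicNetwork,
) -> tuple[MetabolicNetwork, dict[str, tuple[str, str]]]:
    """Split every reversible reaction into irreversible forward/backward pair.

    Returns the all-irreversible network plus a fold-back mapping
    ``original id -> (forward id, backward id)``.  Two-cycle modes (both
    halves of one pair active) are excluded downstream by the EFM engine.
    """
    rxns: list[Reaction] = []
    foldback: dict[str, tuple[str, str]] = {}
    exch = set()
    for rid, rxn in network.reactions.items():
        if not rxn.reversible:
            rxns.append(rxn)
            if network.is_exchange(rid):
                exch.add(rid)
            continue
        fwd = replace(rxn, reversible=False)
        bwd = Reaction(
            id=rid + "__rev",
            stoichiometry={m: -c for m, c in rxn.stoichiometry.items()},
            reversible=False,
            pathway_tag=rxn.pathway_tag,
            exclusion_group=rxn.exclusion_group,
        )
        rxns.extend([fwd, bwd])
        foldback[rid] = (rid, bwd.id)
        if network.is_exchange(rid):
            exch.update({rid, bwd.id})
    return (
        MetabolicNetwork(network.metabolites.values(), rxns, exch, name=network.name + "_split"),
        foldback,
    )


def fold_back(rates: Mapping[str, Fraction], foldback: Mapping[str, tuple[str, str]]) -> dict[str, Fraction]:
    """Map split-network rates onto signed fluxes of the original network."""
    out: dict[str, Fraction] = {}
    rev_ids = {b: orig for orig, (_f, b) in foldback.items()}
    for rid, rate in rates.items():
        if rate == 0:
            continue
        if rid in rev_ids:
            orig = rev_ids[rid]
            out[orig] = out.get(orig, Fraction(0)) - rate
        else:
            out[rid] = out.get(rid, Fraction(0)) + rate
    return {k: v for k, v in out.items() if v != 0}


def validate_network(network: MetabolicNetwork) -> dict[str, list]:
    """Report-only diagnostics: element imbalance, dead ends, duplicates,
    unresolvable exclusion groups."""
    unbalanced = []
    for rxn in network.reactions.values():
        res = check_mass_balance(rxn, network)
        if "exempt" in res:
            continue
        bad = {el: r for el, r in res.items() if r != 0}
        if bad:
            unbalanced.append((rxn.id, {el: str(v) for el, v in bad.items()}))

    produced: dict[str, int] = {m: 0 for m in network.metabolites}
    consumed: dict[str, int] = {m: 0 for m in network.metabolites}
    for rxn in network.reactions.values():
        for met_id, coeff in rxn.stoichiometry.items():
            if rxn.reversible:
                produced[met_id] += 1
                consumed[met_id] += 1
            elif coeff > 0:
                produced[met_id] += 1
            else:
                consumed[met_id] += 1
    dead_ends = [
        m for m in network.metabolites if produced[m] == 0 or consumed[m] == 0
    ]
    orphans = [m for m in network.metabolites if produced[m] == 0 and consumed[m] == 0]

    seen: dict[tuple, str] = {}
    duplicates = []
    for rxn in network.reactions.values():
        key = (tuple(sorted(rxn.stoichiometry.items())), rxn.reversible)
        if key in seen:
            duplicates.append((seen[key], rxn.id))
        else:
            seen[key] = rxn.id

    groups: dict[str, list[str]] = {}
    for rxn in network.reactions.values():
        if rxn.exclusion_group:
            groups.setdefault(rxn.exclusion_group, []).append(rxn.id)
    unresolvable = [g for g, members in groups.items() if len(members) < 2]

    return {
        "unbalanced": unbalanced,
        "dead_ends": dead_ends,
        "orphans": orphans,
        "duplicates": duplicates,
        "unresolvable_exclusion_groups": unresolvable,
    }
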