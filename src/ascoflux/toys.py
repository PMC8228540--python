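"""Toy and random fixture networks with analytically known EFM sets.

These small networks stand in for the genome-derived model when testing
the enumeration machinery: their mode sets are known by construction (or
cheap to confirm with the brute-force oracle).  All toys are carbon
balanced; generic species carry pure-carbon formulas so that 1:1
conversions and k-way splits balance trivially.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction

from .formula import Formula
from .network import MetabolicNetwork, Metabolite, Reaction


@dataclass(frozen=True)
class ToyNetworkSpec:
    name: str
    network: MetabolicNetwork
    expected_efm_count: int
    description: str


def _met(mid: str, carbons: int, compartment: str = "cytosol") -> Metabolite:
    return Metabolite(id=mid, name=mid, compartment=compartment, formula=Formula(C=carbons))


def _uptake(mid: str) -> Reaction:
    return Reaction(id=f"EX_{mid}_in", stoichiometry={mid: Fraction(1)}, pathway_tag="substrate")


def _sink(mid: str) -> Reaction:
    return Reaction(id=f"EX_{mid}_out", stoichiometry={mid: Fraction(-1)}, pathway_tag="sink")


def linear_chain() -> MetabolicNetwork:
    """->A, A->B, B-> : exactly one EFM using all three reactions."""
    mets = [_met("A", 1), _met("B", 1)]
    rxns = [
        _uptake("A"),
        Reaction(id="r_ab", stoichiometry={"A": Fraction(-1), "B": Fraction(1)}),
        _sink("B"),
    ]
    return MetabolicNetwork(mets, rxns, {"EX_A_in", "EX_B_out"}, name="chain")


def diamond() -> MetabolicNetwork:
    """Two parallel irreversible routes A->B: exactly two EFMs."""
    mets = [_met("A", 1), _met("B", 1)]
    rxns = [
        _uptake("A"),
        Reaction(id="r_upper", stoichiometry={"A": Fraction(-1), "B": Fraction(1)}),
        Reaction(id="r_lower", stoichiometry={"A": Fraction(-1), "B": Fraction(1)}),
        _sink("B"),
    ]
    return MetabolicNetwork(mets, rxns, {"EX_A_in", "EX_B_out"}, name="diamond")


def y_branch() -> MetabolicNetwork:
    """Fermentation/respiration Y: shared upper pathway, two terminal products."""
    mets = [_met("S", 6), _met("P", 3), _met("F", 3), _met("R", 3)]
    rxns = [
        _uptake("S"),
        Reaction(id="r_upper", stoichiometry={"S": Fraction(-1), "P": Fraction(2)}),
        Reaction(id="r_ferm", stoichiometry={"P": Fraction(-1), "F": Fraction(1)}),
        Reaction(id="r_resp", stoichiometry={"P": Fraction(-1), "R": Fraction(1)}),
        _sink("F"),
        _sink("R"),
    ]
    return MetabolicNetwork(
        mets, rxns, {"EX_S_in", "EX_F_out", "EX_R_out"}, name="y_branch"
    )


def reversible_loop() -> MetabolicNetwork:
    """A<->B alongside A->B: the fwd+bwd two-cycle of the reversible pair
    must be excluded; what remains are the two through-modes plus the
    genuine futile cycle r_alt + reverse r_iso."""
    mets = [_met("A", 1), _met("B", 1)]
    rxns = [
        _uptake("A"),
        Reaction(id="r_iso", stoichiometry={"A": Fraction(-1), "B": Fraction(1)}, reversible=True),
        Reaction(id="r_alt", stoichiometry={"A": Fraction(-1), "B": Fraction(1)}),
        _sink("B"),
    ]
    return MetabolicNetwork(mets, rxns, {"EX_A_in", "EX_B_out"}, name="reversible_loop")


def exclusion_pair() -> MetabolicNetwork:
    """Diamond whose two routes share an exclusion group; with the serial
    bottom route requiring both, rule filtering keeps one of two modes."""
    mets = [_met("A", 1), _met("B", 1), _met("C", 1)]
    rxns = [
        _uptake("A"),
        Reaction(id="r_direct", stoichiometry={"A": Fraction(-1), "C": Fraction(1)},
                 exclusion_group="isozyme"),
        Reaction(id="r_step1", stoichiometry={"A": Fraction(-1), "B": Fraction(1)},
                 exclusion_group="isozyme"),
        Reaction(id="r_step2", stoichiometry={"B": Fraction(-1), "C": Fraction(1)},
                 exclusion_group="isozyme"),
        _sink("C"),
    ]
    return MetabolicNetwork(mets, rxns, {"EX_A_in", "EX_C_out"}, name="exclusion_pair")


def mini_fas_ladder() -> MetabolicNetwork:
    """Two-rung elongation ladder: C2 primer extended by C2 units, with
    release at either rung; two EFMs exporting C4 or C6."""
    mets = [_met("AC", 2), _met("C4", 4), _met("C6", 6)]
    rxns = [
        _uptake("AC"),
        Reaction(id="r_elong1", stoichiometry={"AC": Fraction(-2), "C4": Fraction(1)}),
        Reaction(id="r_elong2", stoichiometry={"C4": Fraction(-1), "AC": Fraction(-1), "C6": Fraction(1)}),
        _sink("C4"),
        _sink("C6"),
    ]
    return MetabolicNetwork(
        mets, rxns, {"EX_AC_in", "EX_C4_out", "EX_C6_out"}, name="mini_fas"
    )


def make_toy_networks() -> dict[str, ToyNetworkSpec]:
    """Named toy collection with expected EFM counts."""
    specs = [
        ToyNetworkSpec("chain", linear_chain(), 1, "linear chain, single mode"),
        ToyNetworkSpec("diamond", diamond(), 2, "two parallel routes"),
        ToyNetworkSpec("y_branch", y_branch(), 2, "fermentation/respiration split"),
        ToyNetworkSpec("reversible_loop", reversible_loop(), 3, "two-cycle exclusion"),
        ToyNetworkSpec("exclusion_pair", exclusion_pair(), 2, "rule filtering fixture"),
        ToyNetworkSpec("mini_fas", mini_fas_ladder(), 2, "elongation bookkeeping"),
    ]
    return {s.name: s for s in specs}


def random_network(seed: int, n_reactions: int = 10) -> MetabolicNetwork:
    """Seeded random element-balanced network for oracle fuzzing.

    Grows a connected conversion graph from one substrate: each internal
    reaction either converts, splits, or merges pure-carbon species with
    carbon conserved exactly; a fraction of reactions is reversible.
    Metabolites left without a consumer get sink exchanges.  Total reaction
    count (internal + exchanges) is at most ``n_reactions``.
    """
    if n_reactions < 3:
        raise ValueError("need at least 3 reactions (uptake, conversion, sink)")
    rng = random.Random(seed)

    carbons = {"M0": rng.choice([2, 4, 6])}
    reactions: list[Reaction] = [_uptake("M0")]
    exchanges = {"EX_M0_in"}
    next_id = 1

    produced = {"M0"}

    def sinks_needed() -> int:
        consumed = set()
        for rxn in reactions[1:]:
            for met, coeff in rxn.stoichiometry.items():
                if coeff < 0 or rxn.reversible:
                    consumed.add(met)
        return max(1, len(produced - consumed))

    # budget counts post-split columns: uptake + internal (+1 per reversible)
    # + one sink per dead end; stop with room to spare so the final total
    # never exceeds n_reactions
    while True:
        cols = sum(2 if r.reversible else 1 for r in reactions)
        if cols + sinks_needed() + 3 > n_reactions:
            break
        src = rng.choice(sorted(produced))
        c = carbons[src]
        kind = rng.choice(["convert", "convert", "split", "merge"])
        rid = f"r{len(reactions)}"
        reversible = rng.random() < 0.25
        if kind == "split" and c >= 2:
            a = rng.randint(1, c - 1)
            m1, m2 = f"M{next_id}", f"M{next_id + 1}"
            next_id += 2
            carbons[m1], carbons[m2] = a, c - a
            reactions.append(
                Reaction(rid, {src: Fraction(-1), m1: Fraction(1), m2: Fraction(1)},
                         reversible=reversible)
            )
            produced.update({m1, m2})
        elif kind == "merge" and len(produced) >= 2:
            other = rng.choice(sorted(produced - {src}) or sorted(produced))
            m1 = f"M{next_id}"
            next_id += 1
            carbons[m1] = carbons[src] + carbons[other]
            reactions.append(
                Reaction(rid, {src: Fraction(-1), other: Fraction(-1), m1: Fraction(1)},
                         reversible=reversible)
            )
            produced.add(m1)
        else:
            # 1:1 conversion to a new or existing species of equal carbon
            same_c = [m for m in produced if carbons[m] == c and m != src]
            if same_c and rng.random() < 0.4:
                dst = rng.choice(sorted(same_c))
            else:
                dst = f"M{next_id}"
                next_id += 1
                carbons[dst] = c
            reactions.append(
                Reaction(rid, {src: Fraction(-1), dst: Fraction(1)}, reversible=reversible)
            )
            produced.add(dst)

    # sinks for anything without a consumer
    consumed = set()
    for rxn in reactions:
        for met, coeff in rxn.stoichiometry.items():
            if coeff < 0 or rxn.reversible:
                consumed.add(met)
    for met in sorted(produced - consumed) or [sorted(produced)[-1]]:
        reactions.append(_sink(met))
        exchanges.add(f"EX_{met}_out")

    mets = [_met(m, c) for m, c in carbons.items()]
    return MetabolicNetwork(mets, reactions, exchanges, name=f"random_{seed}")
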