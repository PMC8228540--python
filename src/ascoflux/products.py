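"""Combinatorial registry of functionalized hydrocarbon (FH) products.

FHs are generated along four routes: fatty-acid derivatives (acyl chains
initiated by acetyl-CoA for even and propanoyl-CoA for odd chains,
elongated by C2 units at 1 ATP + 2 NADPH per cycle), Ehrlich derivatives
of seven amino-acid donors, oxidative-cleavage products of linoleate
(always paired with a C10 coproduct), and acetate esters.  Eight
functional groups are covered: acids, esters, aldehydes, ketones, primary
and secondary alcohols, alkanes and alkenes, with chain lengths C3-C20.

Primary groups (acid, aldehyde, primary alcohol) preserve the acyl chain
length, so their parity matches the initiator; the four carbon-losing
groups (alkane, alkene, ketone, secondary alcohol) each lose exactly one
carbon -- alkanes by aldehyde deformylation releasing formate, alkenes by
decarboxylation of the 2-enoate, ketones by decarboxylation of the
beta-keto acid, secondary alcohols by ketone reduction -- flipping parity.

The default configuration totals 161 species.  The per-class breakdown is
a calibrated fixture: the reported total, group list and length range are
fixed, but the species-level composition is the package's own
reconstruction (see docs/methods.md).

Formate, acetate, acetaldehyde and ethanol are primary fermentation
products, not FHs, and are never registry members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

from .formula import Formula, degree_of_reduction
from .network import MetabolicNetwork, Metabolite, Reaction

PRODUCT_CLASSES = ("fatty_acid", "ehrlich", "linoleic", "ester")
FUNCTIONAL_GROUPS = (
    "acid",
    "ester",
    "aldehyde",
    "ketone",
    "primary_alcohol",
    "secondary_alcohol",
    "alkane",
    "alkene",
)

#: species excluded from FH status (primary fermentation products)
NON_FH = frozenset({"formate", "acetate", "acetaldehyde", "ethanol"})

MIN_CHAIN, MAX_CHAIN = 3, 20


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class ProductSpec:
    """One excreted FH species and how it hangs off the core network."""

    name: str
    product_class: str
    functional_group: str
    chain_length: int
    formula: Formula
    initiator: str
    generating_reaction_ids: frozenset[str]
    metabolite_id: str = ""
    exchange_id: str = ""

    def __post_init__(self) -> None:
        if self.product_class not in PRODUCT_CLASSES:
            raise RegistryError(f"unknown product class {self.product_class!r}")
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise RegistryError(f"unknown functional group {self.functional_group!r}")
        if not (MIN_CHAIN <= self.chain_length <= MAX_CHAIN):
            raise RegistryError(
                f"{self.name}: chain length {self.chain_length} outside "
                f"[{MIN_CHAIN}, {MAX_CHAIN}]"
            )
        if self.name in NON_FH:
            raise RegistryError(f"{self.name} is a primary fermentation product, not an FH")

    @property
    def gamma(self) -> Fraction:
        return degree_of_reduction(self.formula)


@dataclass
class RegistryBlock:
    """Products plus the metabolites/reactions that generate them."""

    products: list[ProductSpec] = field(default_factory=list)
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    exchange_ids: set[str] = field(default_factory=set)

    def merge(self, other: "RegistryBlock") -> "RegistryBlock":
        seen_m = {m.id for m in self.metabolites}
        seen_r = {r.id for r in self.reactions}
        self.products.extend(other.products)
        self.metabolites.extend(m for m in other.metabolites if m.id not in seen_m)
        self.reactions.extend(r for r in other.reactions if r.id not in seen_r)
        self.exchange_ids |= other.exchange_ids
        return self


def _met(mid: str, name: str, formula: Formula, compartment: str = "cytosol") -> Metabolite:
    return Metabolite(id=mid, name=name, compartment=compartment, formula=formula)


def _product_entry(
    block: RegistryBlock,
    *,
    name: str,
    product_class: str,
    group: str,
    chain: int,
    formula: Formula,
    initiator: str,
    met_id: str,
    gen_ids: Iterable[str],
) -> None:
    ex_id = f"EX_{met_id}"
    block.metabolites.append(_met(met_id, name, formula))
    block.reactions.append(
        Reaction(id=ex_id, stoichiometry={met_id: Fraction(-1)}, pathway_tag="product")
    )
    block.exchange_ids.add(ex_id)
    block.products.append(
        ProductSpec(
            name=name,
            product_class=product_class,
            functional_group=group,
            chain_length=chain,
            formula=formula,
            initiator=initiator,
            generating_reaction_ids=frozenset(gen_ids),
            metabolite_id=met_id,
            exchange_id=ex_id,
        )
    )


# ---------------------------------------------------------------------------
# generic fatty-acyl species formulas (CoA-level lumping of ACP chemistry)

def acyl_coa_formula(n: int) -> Formula:
    # CoA (C21H36N7O16P3S) minus H plus acyl CnH(2n-1)O
    return Formula(C=21 + n, H=34 + 2 * n, N=7, O=17, P=3, S=1)


def oxoacyl_coa_formula(n: int) -> Formula:
    return Formula(C=21 + n, H=32 + 2 * n, N=7, O=18, P=3, S=1)


def hydroxyacyl_coa_formula(n: int) -> Formula:
    return Formula(C=21 + n, H=34 + 2 * n, N=7, O=18, P=3, S=1)


def enoyl_coa_formula(n: int) -> Formula:
    return Formula(C=21 + n, H=32 + 2 * n, N=7, O=17, P=3, S=1)


def acid_formula(n: int) -> Formula:
    return Formula(C=n, H=2 * n, O=2)


def aldehyde_formula(n: int) -> Formula:
    return Formula(C=n, H=2 * n, O=1)


def primary_alcohol_formula(n: int) -> Formula:
    return Formula(C=n, H=2 * n + 2, O=1)


def alkane_formula(n: int) -> Formula:
    return Formula(C=n, H=2 * n + 2)


def alkene_formula(n: int) -> Formula:
    return Formula(C=n, H=2 * n)


def ketone_formula(n: int) -> Formula:
    return Formula(C=n, H=2 * n, O=1)


def secondary_alcohol_formula(n: int) -> Formula:
    return Formula(C=n, H=2 * n + 2, O=1)


def enoate_formula(n: int) -> Formula:
    return Formula(C=n, H=2 * n - 2, O=2)


def oxoacid_formula(n: int) -> Formula:
    return Formula(C=n, H=2 * n - 2, O=3)


_ACID_NAMES = {3: "propanoate", 4: "butanoate", 5: "pentanoate", 6: "hexanoate",
               7: "heptanoate", 8: "octanoate", 16: "palmitate"}


def _fa_name(group: str, n: int) -> str:
    if group == "acid" and n in _ACID_NAMES:
        return _ACID_NAMES[n]
    stem = {
        "acid": f"C{n} acid", "aldehyde": f"C{n} aldehyde",
        "primary_alcohol": f"1-C{n}-ol", "alkane": f"C{n} alkane",
        "alkene": f"1-C{n}-ene", "ketone": f"C{n} methyl ketone",
        "secondary_alcohol": f"2-C{n}-ol",
    }[group]
    return stem


def _initiator_for(chain: int) -> str:
    return "acetyl-CoA" if chain % 2 == 0 else "propanoyl-CoA"


def enumerate_fatty_acid_products(
    length_range: tuple[int, int] = (MIN_CHAIN, MAX_CHAIN),
    initiators: Iterable[str] = ("acetyl-CoA", "propanoyl-CoA"),
) -> RegistryBlock:
    """Fatty-acid derivative products and the full elongation ladder.

    Acyl chains grow from acetyl-CoA (even) or propanoyl-CoA (odd) by C2
    units; each cycle costs 1 ATP (acetyl-CoA carboxylase, charged on the
    shared malonyl-CoA step of the host network) and 2 NADPH.  Primary
    groups release at chain length n; carbon-losing groups release at n-1.
    """
    lo, hi = length_range
    if not (MIN_CHAIN <= lo <= hi <= MAX_CHAIN):
        raise RegistryError(f"length range {length_range} outside [{MIN_CHAIN},{MAX_CHAIN}]")
    initiators = set(initiators)
    block = RegistryBlock()

    # elongation ladder: acyl(n-2) + malonyl-CoA -> 3-oxo(n) -> 3-OH(n)
    # -> 2-enoyl(n) -> acyl(n); acyl(2)=acetyl-CoA, acyl(3)=propanoyl-CoA
    max_acyl = hi
    parities = set()
    if "acetyl-CoA" in initiators:
        parities.add(0)
    if "propanoyl-CoA" in initiators:
        parities.add(1)

    def acyl_id(n: int) -> str:
        if n == 2:
            return "accoa_c"
        if n == 3:
            return "prcoa_c"
        return f"acyl{n}_c"

    ladder_ids: dict[int, list[str]] = {}
    for n in range(4, max_acyl + 1):
        if n % 2 not in parities:
            continue
        for mid, nm, f in [
            (f"oxoacyl{n}_c", f"3-oxo-C{n}-acyl-CoA", oxoacyl_coa_formula(n)),
            (f"ohacyl{n}_c", f"3-hydroxy-C{n}-acyl-CoA", hydroxyacyl_coa_formula(n)),
            (f"enoyl{n}_c", f"2-enoyl-C{n}-CoA", enoyl_coa_formula(n)),
        ]:
            block.metabolites.append(_met(mid, nm, f))
        if acyl_id(n) not in ("accoa_c", "prcoa_c"):
            block.metabolites.append(
                _met(acyl_id(n), f"C{n}-acyl-CoA", acyl_coa_formula(n))
            )
        rxns = [
            Reaction(
                id=f"fas_cond{n}",
                stoichiometry={
                    acyl_id(n - 2): Fraction(-1),
                    "malcoa_c": Fraction(-1),
                    f"oxoacyl{n}_c": Fraction(1),
                    "co2_c": Fraction(1),
                    "coa_c": Fraction(1),
                },
                pathway_tag="FAS",
            ),
            Reaction(
                id=f"fas_kr{n}",
                stoichiometry={
                    f"oxoacyl{n}_c": Fraction(-1),
                    "nadph_c": Fraction(-1),
                    f"ohacyl{n}_c": Fraction(1),
                    "nadp_c": Fraction(1),
                },
                pathway_tag="FAS",
            ),
            Reaction(
                id=f"fas_dh{n}",
                stoichiometry={
                    f"ohacyl{n}_c": Fraction(-1),
                    f"enoyl{n}_c": Fraction(1),
                    "h2o_c": Fraction(1),
                },
                pathway_tag="FAS",
            ),
            Reaction(
                id=f"fas_er{n}",
                stoichiometry={
                    f"enoyl{n}_c": Fraction(-1),
                    "nadph_c": Fraction(-1),
                    acyl_id(n): Fraction(1),
                    "nadp_c": Fraction(1),
                },
                pathway_tag="FAS",
            ),
        ]
        block.reactions.extend(rxns)
        ladder_ids[n] = [r.id for r in rxns]

    def ladder_for(n: int) -> list[str]:
        ids: list[str] = []
        k = n
        while k >= 4:
            ids.extend(ladder_ids.get(k, []))
            k -= 2
        return ids

    # primary groups: release at chain length n
    for n in range(lo, hi + 1):
        if n % 2 not in parities:
            continue
        init = _initiator_for(n)
        acid_mid = f"fa_acid{n}_c"
        rid = f"fa_thioesterase{n}"
        block.reactions.append(
            Reaction(
                id=rid,
                stoichiometry={
                    acyl_id(n): Fraction(-1),
                    "h2o_c": Fraction(-1),
                    acid_mid: Fraction(1),
                    "coa_c": Fraction(1),
                },
                pathway_tag="FAS",
            )
        )
        _product_entry(
            block, name=_fa_name("acid", n), product_class="fatty_acid", group="acid",
            chain=n, formula=acid_formula(n), initiator=init, met_id=acid_mid,
            gen_ids=[rid, *ladder_for(n)],
        )

        ald_mid = f"fa_ald{n}_c"
        rid = f"fa_acylred{n}"
        block.reactions.append(
            Reaction(
                id=rid,
                stoichiometry={
                    acyl_id(n): Fraction(-1),
                    "nadph_c": Fraction(-1),
                    ald_mid: Fraction(1),
                    "nadp_c": Fraction(1),
                    "coa_c": Fraction(1),
                },
                pathway_tag="FAS",
            )
        )
        _product_entry(
            block, name=_fa_name("aldehyde", n), product_class="fatty_acid",
            group="aldehyde", chain=n, formula=aldehyde_formula(n), initiator=init,
            met_id=ald_mid, gen_ids=[rid, *ladder_for(n)],
        )

        alc_mid = f"fa_ol{n}_c"
        rid = f"fa_adh{n}"
        block.reactions.append(
            Reaction(
                id=rid,
                stoichiometry={
                    ald_mid: Fraction(-1),
                    "nadh_c": Fraction(-1),
                    alc_mid: Fraction(1),
                    "nad_c": Fraction(1),
                },
                pathway_tag="FAS",
            )
        )
        _product_entry(
            block, name=_fa_name("primary_alcohol", n), product_class="fatty_acid",
            group="primary_alcohol", chain=n, formula=primary_alcohol_formula(n),
            initiator=init, met_id=alc_mid, gen_ids=[rid, *ladder_for(n)],
        )

    # carbon-losing groups: product at n-1 from acyl stage n (parity flips)
    for n in range(lo + 1, hi + 1):
        if n % 2 not in parities:
            continue
        init = _initiator_for(n)
        p = n - 1

        # alkane: aldehyde deformylation releasing formate
        alkane_mid = f"fa_alkane{p}_c"
        rid = f"fa_deformyl{n}"
        block.reactions.append(
            Reaction(
                id=rid,
                stoichiometry={
                    f"fa_ald{n}_c": Fraction(-1),
                    "h2o_c": Fraction(-1),
                    alkane_mid: Fraction(1),
                    "formate_c": Fraction(1),
                },
                pathway_tag="FAS",
            )
        )
        _product_entry(
            block, name=_fa_name("alkane", p), product_class="fatty_acid",
            group="alkane", chain=p, formula=alkane_formula(p), initiator=init,
            met_id=alkane_mid, gen_ids=[rid, f"fa_acylred{n}", *ladder_for(n)],
        )

        # alkene: decarboxylation of the 2-enoate (release at the
        # dehydratase stage of the final elongation cycle)
        enoate_mid = f"fa_enoate{n}_c"
        alkene_mid = f"fa_alkene{p}_c"
        r1 = f"fa_enoate_rel{n}"
        r2 = f"fa_enoate_dc{n}"
        block.metabolites.append(_met(enoate_mid, f"2-C{n}-enoate", enoate_formula(n)))
        block.reactions.extend([
            Reaction(
                id=r1,
                stoichiometry={
                    f"enoyl{n}_c": Fraction(-1),
                    "h2o_c": Fraction(-1),
                    enoate_mid: Fraction(1),
                    "coa_c": Fraction(1),
                },
                pathway_tag="FAS",
            ),
            Reaction(
                id=r2,
                stoichiometry={
                    enoate_mid: Fraction(-1),
                    alkene_mid: Fraction(1),
                    "co2_c": Fraction(1),
                },
                pathway_tag="FAS",
            ),
        ])
        _product_entry(
            block, name=_fa_name("alkene", p), product_class="fatty_acid",
            group="alkene", chain=p, formula=alkene_formula(p), initiator=init,
            met_id=alkene_mid, gen_ids=[r1, r2, *ladder_for(n)],
        )

        # ketone: decarboxylation of the beta-keto acid
        oxoacid_mid = f"fa_oxoacid{n}_c"
        ketone_mid = f"fa_ketone{p}_c"
        r1 = f"fa_oxoacid_rel{n}"
        r2 = f"fa_oxoacid_dc{n}"
        block.metabolites.append(_met(oxoacid_mid, f"3-oxo-C{n}-acid", oxoacid_formula(n)))
        block.reactions.extend([
            Reaction(
                id=r1,
                stoichiometry={
                    f"oxoacyl{n}_c": Fraction(-1),
                    "h2o_c": Fraction(-1),
                    oxoacid_mid: Fraction(1),
                    "coa_c": Fraction(1),
                },
                pathway_tag="FAS",
            ),
            Reaction(
                id=r2,
                stoichiometry={
                    oxoacid_mid: Fraction(-1),
                    ketone_mid: Fraction(1),
                    "co2_c": Fraction(1),
                },
                pathway_tag="FAS",
            ),
        ])
        _product_entry(
            block, name=_fa_name("ketone", p), product_class="fatty_acid",
            group="ketone", chain=p, formula=ketone_formula(p), initiator=init,
            met_id=ketone_mid, gen_ids=[r1, r2, *ladder_for(n)],
        )

        # secondary alcohol: ketone reduction
        secol_mid = f"fa_secol{p}_c"
        rid = f"fa_ketored{n}"
        block.reactions.append(
            Reaction(
                id=rid,
                stoichiometry={
                    ketone_mid: Fraction(-1),
                    "nadh_c": Fraction(-1),
                    secol_mid: Fraction(1),
                    "nad_c": Fraction(1),
                },
                pathway_tag="FAS",
            )
        )
        _product_entry(
            block, name=_fa_name("secondary_alcohol", p), product_class="fatty_acid",
            group="secondary_alcohol", chain=p, formula=secondary_alcohol_formula(p),
            initiator=init, met_id=secol_mid, gen_ids=[rid, f"fa_oxoacid_rel{n}", f"fa_oxoacid_dc{n}", *ladder_for(n)],
        )

    return block


# ---------------------------------------------------------------------------
# Ehrlich pathway derivatives

#: donor -> (2-oxo acid met id, 2-oxo acid compartment, aldehyde species)
_EHRLICH_BRANCHED = {
    "valine": ("oiv_m", "mitochondria", "isobutanal",
               Formula(C=4, H=8, O=1), 4),
    "leucine": ("oic_m", "mitochondria", "3-methylbutanal",
                Formula(C=5, H=10, O=1), 5),
    "isoleucine": ("omv_m", "mitochondria", "2-methylbutanal",
                   Formula(C=5, H=10, O=1), 5),
    "methionine": ("mtob_c", "cytosol", "methional",
                   Formula(C=4, H=8, O=1, S=1), 4),
}

#: donor -> (amino acid met id, amine, aldehyde, formulas, chain length)
_EHRLICH_AROMATIC = {
    "phenylalanine": ("phe_c", "phenylethylamine", Formula(C=8, H=11, N=1),
                      "phenylacetaldehyde", Formula(C=8, H=8, O=1), 8),
    "tyrosine": ("tyr_c", "tyramine", Formula(C=8, H=11, N=1, O=1),
                 "4-hydroxyphenylacetaldehyde", Formula(C=8, H=8, O=2), 8),
    "tryptophan": ("trp_c", "tryptamine", Formula(C=10, H=12, N=2),
                   "indole-3-acetaldehyde", Formula(C=10, H=9, N=1, O=1), 10),
}

_EHRLICH_PRODUCT_NAMES = {
    "valine": ("2-methylpropanoate", "isobutanal", "isobutanol"),
    "leucine": ("3-methylbutanoate", "3-methylbutanal", "3-methyl-1-butanol"),
    "isoleucine": ("2-methylbutanoate", "2-methylbutanal", "2-methyl-1-butanol"),
    "methionine": ("3-methylthiopropanoate", "methional", "methionol"),
    "phenylalanine": ("phenylacetate", "phenylacetaldehyde", "2-phenylethanol"),
    "tyrosine": ("4-hydroxyphenylacetate", "4-hydroxyphenylacetaldehyde", "tyrosol"),
    "tryptophan": ("indole-3-acetate", "indole-3-acetaldehyde", "indole-3-ethanol"),
}


def _slug(name: str) -> str:
    return name.replace("-", "_").replace(" ", "_")


def enumerate_ehrlich_products() -> RegistryBlock:
    """Ehrlich derivatives of the seven amino-acid donors.

    Branched/sulfur donors (valine, leucine, isoleucine, methionine): the
    2-oxo acid is decarboxylated non-oxidatively to the fusel aldehyde,
    then reduced to the alcohol or oxidized to the acid.  Aromatic donors
    (phenylalanine, tyrosine, tryptophan) lack a 2-oxo acid decarboxylase
    in this genome; the route runs amino acid -> amine -> O2-requiring
    amine oxidase -> aldehyde, so every aromatic product carries an
    obligatory O2 requirement (the H2O2 produced is dismutated by
    catalase, returning half the O2).
    """
    block = RegistryBlock()

    def terminal_steps(donor: str, ald_mid: str, ald_formula: Formula, chain: int,
                      route_ids: list[str]) -> None:
        acid_name, ald_name, alc_name = _EHRLICH_PRODUCT_NAMES[donor]
        # aldehyde itself is an excreted FH
        _product_entry(
            block, name=ald_name, product_class="ehrlich", group="aldehyde",
            chain=chain, formula=ald_formula,
            initiator=f"amino-acid:{donor}", met_id=ald_mid, gen_ids=route_ids,
        )
        acid_f = Formula(C=ald_formula.C, H=ald_formula.H, O=ald_formula.O + 1,
                         N=ald_formula.N, S=ald_formula.S)
        acid_mid = f"eh_{_slug(acid_name)}_c"
        rid = f"eh_alddh_{_slug(acid_name)}"
        block.reactions.append(
            Reaction(
                id=rid,
                stoichiometry={
                    ald_mid: Fraction(-1), "nad_c": Fraction(-1), "h2o_c": Fraction(-1),
                    acid_mid: Fraction(1), "nadh_c": Fraction(1),
                },
                pathway_tag="Ehrlich",
            )
        )
        _product_entry(
            block, name=acid_name, product_class="ehrlich", group="acid",
            chain=chain, formula=acid_f, initiator=f"amino-acid:{donor}",
            met_id=acid_mid, gen_ids=[rid, *route_ids],
        )
        alc_f = Formula(C=ald_formula.C, H=ald_formula.H + 2, O=ald_formula.O,
                        N=ald_formula.N, S=ald_formula.S)
        alc_mid = f"eh_{_slug(alc_name)}_c"
        rid = f"eh_adh_{_slug(alc_name)}"
        block.reactions.append(
            Reaction(
                id=rid,
                stoichiometry={
                    ald_mid: Fraction(-1), "nadh_c": Fraction(-1),
                    alc_mid: Fraction(1), "nad_c": Fraction(1),
                },
                pathway_tag="Ehrlich",
            )
        )
        _product_entry(
            block, name=alc_name, product_class="ehrlich", group="primary_alcohol",
            chain=chain, formula=alc_f, initiator=f"amino-acid:{donor}",
            met_id=alc_mid, gen_ids=[rid, *route_ids],
        )

    for donor, (oxo_mid, comp, ald_name, ald_f, chain) in _EHRLICH_BRANCHED.items():
        ald_slug = _slug(ald_name)
        route_ids = []
        if comp == "mitochondria":
            ald_m = f"eh_{ald_slug}_m"
            block.metabolites.append(
                Metabolite(id=ald_m, name=ald_name, compartment="mitochondria", formula=ald_f)
            )
            rid_dc = f"eh_decarb_{donor}"
            rid_tr = f"eh_transport_{ald_slug}"
            block.reactions.extend([
                Reaction(
                    id=rid_dc,
                    stoichiometry={oxo_mid: Fraction(-1), ald_m: Fraction(1),
                                   "co2_c": Fraction(1)},
                    pathway_tag="Ehrlich",
                ),
                Reaction(
                    id=rid_tr,
                    stoichiometry={ald_m: Fraction(-1), f"eh_{ald_slug}_c": Fraction(1)},
                    pathway_tag="transport",
                ),
            ])
            route_ids = [rid_dc, rid_tr]
        else:
            rid_dc = f"eh_decarb_{donor}"
            block.reactions.append(
                Reaction(
                    id=rid_dc,
                    stoichiometry={oxo_mid: Fraction(-1), f"eh_{ald_slug}_c": Fraction(1),
                                   "co2_c": Fraction(1)},
                    pathway_tag="Ehrlich",
                )
            )
            route_ids = [rid_dc]
        terminal_steps(donor, f"eh_{ald_slug}_c", ald_f, chain, route_ids)

    for donor, (aa_mid, amine_name, amine_f, ald_name, ald_f, chain) in _EHRLICH_AROMATIC.items():
        amine_slug, ald_slug = _slug(amine_name), _slug(ald_name)
        amine_mid = f"eh_{amine_slug}_c"
        block.metabolites.append(_met(amine_mid, amine_name, amine_f))
        rid_dc = f"eh_decarb_{donor}"
        rid_ox = f"eh_amineox_{amine_slug}"
        block.reactions.extend([
            Reaction(
                id=rid_dc,
                stoichiometry={aa_mid: Fraction(-1), amine_mid: Fraction(1),
                               "co2_c": Fraction(1)},
                pathway_tag="Ehrlich",
            ),
            Reaction(
                id=rid_ox,
                stoichiometry={
                    amine_mid: Fraction(-1), "o2_c": Fraction(-1), "h2o_c": Fraction(-1),
                    f"eh_{ald_slug}_c": Fraction(1), "nh3_c": Fraction(1),
                    "h2o2_c": Fraction(1),
                },
                pathway_tag="Ehrlich",
            ),
        ])
        terminal_steps(donor, f"eh_{ald_slug}_c", ald_f, chain, [rid_dc, rid_ox])

    return block


# ---------------------------------------------------------------------------
# linoleic acid oxidative cleavage

_LINOLEIC_PAIRS = [
    # (C8 product, group, formula, coproduct, coproduct group, coproduct formula,
    #  NADH consumed, O2 consumed)
    ("1-octen-3-ol", "secondary_alcohol", Formula(C=8, H=16, O=1),
     "10-oxo-8-decenoate", "aldehyde", Formula(C=10, H=16, O=3),
     Fraction(0), Fraction(1)),
    ("3-octanone", "ketone", Formula(C=8, H=16, O=1),
     "10-oxodecanoate", "aldehyde", Formula(C=10, H=18, O=3),
     Fraction(1), Fraction(1)),
    ("3-octanol", "secondary_alcohol", Formula(C=8, H=18, O=1),
     "10-hydroxy-8-decenoate", "acid", Formula(C=10, H=18, O=3),
     Fraction(2), Fraction(1)),
    ("1,3-octadiene", "alkene", Formula(C=8, H=14),
     "10-hydroxydecanoate", "acid", Formula(C=10, H=20, O=3),
     Fraction(1), Fraction("1/2")),
]


def enumerate_linoleic_products() -> RegistryBlock:
    """Lumped oxidative cleavage of linoleate into C8 product + C10 coproduct.

    No reaction yields a C8 product alone: each cleavage couples the C8
    species to an oxygenated C10 coproduct, and both are excreted FHs.
    """
    block = RegistryBlock()
    co_entries: dict[str, str] = {}
    for c8_name, c8_group, c8_f, co_name, co_group, co_f, nadh, o2 in _LINOLEIC_PAIRS:
        c8_mid = f"lin_{_slug(c8_name).replace(',', '')}_c"
        co_mid = f"lin_{_slug(co_name)}_c"
        rid = f"lin_cleave_{_slug(c8_name).replace(',', '')}"
        stoich = {
            "linoleate_c": Fraction(-1),
            c8_mid: Fraction(1),
            co_mid: Fraction(1),
        }
        if o2:
            stoich["o2_c"] = -o2
        if nadh:
            stoich["nadh_c"] = -nadh
            stoich["nad_c"] = nadh
        block.reactions.append(Reaction(id=rid, stoichiometry=stoich, pathway_tag="linoleic"))
        _product_entry(
            block, name=c8_name, product_class="linoleic", group=c8_group,
            chain=8, formula=c8_f, initiator="linoleate", met_id=c8_mid, gen_ids=[rid],
        )
        if co_mid not in co_entries:
            _product_entry(
                block, name=co_name, product_class="linoleic", group=co_group,
                chain=10, formula=co_f, initiator="linoleate", met_id=co_mid,
                gen_ids=[rid],
            )
            co_entries[co_mid] = rid
    return block


# ---------------------------------------------------------------------------
# esters

#: default acetate-ester configuration: C2 and C5-C10 alkyl acetates plus the
#: branched and aromatic esters reported for this organism
_ALKYL_ACETATE_CHAINS = (2, 5, 6, 7, 8, 9, 10)
_SPECIAL_ESTER_ALCOHOLS = (
    ("isobutanol", "eh_isobutanol_c", "isobutyl acetate"),
    ("3-methyl-1-butanol", "eh_3_methyl_1_butanol_c", "isopentyl acetate"),
    ("2-phenylethanol", "eh_2_phenylethanol_c", "2-phenylethyl acetate"),
)


def enumerate_esters(existing: RegistryBlock | None = None) -> RegistryBlock:
    """Acetate esters via alcohol acyltransferase (acyl-CoA + alcohol).

    Ester = alcohol + acetate - H2O; the alcohol moiety comes from the
    registry (or from ethanol for ethyl acetate, which is itself not an FH
    but whose ester is)."""
    block = RegistryBlock()
    by_mid = {p.metabolite_id: p for p in (existing.products if existing else [])}

    def add_ester(alc_mid: str, alc_name: str, alc_f: Formula, ester_name: str, chain: int,
                  initiator: str) -> None:
        ester_f = Formula(
            C=alc_f.C + 2, H=alc_f.H + 2, O=alc_f.O + 1, N=alc_f.N, S=alc_f.S
        )
        mid = f"est_{_slug(ester_name).replace(' ', '_')}_c"
        rid = f"est_aat_{_slug(ester_name).replace(' ', '_')}"
        block.reactions.append(
            Reaction(
                id=rid,
                stoichiometry={
                    "accoa_c": Fraction(-1), alc_mid: Fraction(-1),
                    mid: Fraction(1), "coa_c": Fraction(1),
                },
                pathway_tag="ester",
            )
        )
        _product_entry(
            block, name=ester_name, product_class="ester", group="ester",
            chain=chain, formula=ester_f, initiator=initiator, met_id=mid,
            gen_ids=[rid],
        )

    for n in _ALKYL_ACETATE_CHAINS:
        if n == 2:
            add_ester("etoh_c", "ethanol", Formula(C=2, H=6, O=1), "ethyl acetate",
                      4, "acetyl-CoA")
            continue
        alc_mid = f"fa_ol{n}_c"
        prod = by_mid.get(alc_mid)
        initiator = prod.initiator if prod else _initiator_for(n)
        add_ester(alc_mid, f"1-C{n}-ol", primary_alcohol_formula(n),
                  f"C{n} alkyl acetate", n + 2, initiator)

    for alc_name, alc_mid, ester_name in _SPECIAL_ESTER_ALCOHOLS:
        prod = by_mid.get(alc_mid)
        if prod is None:
            raise RegistryError(
                f"ester precursor {alc_name} missing: enumerate alcohols first"
            )
        add_ester(alc_mid, alc_name, prod.formula, ester_name, prod.formula.C + 2,
                  prod.initiator)
    return block


# ---------------------------------------------------------------------------

def build_default_registry() -> RegistryBlock:
    """The full default FH registry (161 species)."""
    block = enumerate_fatty_acid_products()
    block.merge(enumerate_ehrlich_products())
    block.merge(enumerate_linoleic_products())
    block.merge(enumerate_esters(block))
    return block


def registry_summary(block: RegistryBlock) -> dict:
    """Counts by class, functional group and chain length."""
    by_class: dict[str, int] = {}
    by_group: dict[str, int] = {}
    by_chain: dict[int, int] = {}
    for p in block.products:
        by_class[p.product_class] = by_class.get(p.product_class, 0) + 1
        by_group[p.functional_group] = by_group.get(p.functional_group, 0) + 1
        by_chain[p.chain_length] = by_chain.get(p.chain_length, 0) + 1
    return {
        "total": len(block.products),
        "by_class": dict(sorted(by_class.items())),
        "by_group": dict(sorted(by_group.items())),
        "by_chain_length": dict(sorted(by_chain.items())),
        "min_chain": min(by_chain) if by_chain else None,
        "max_chain": max(by_chain) if by_chain else None,
    }


def attach_registry(network: MetabolicNetwork, block: RegistryBlock) -> MetabolicNetwork:
    """Return a network with the registry's reactions/species merged in."""
    return network.with_reactions(
        add=block.reactions,
        add_metabolites=block.metabolites,
        add_exchanges=block.exchange_ids,
        name=network.name + "+registry",
    )
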