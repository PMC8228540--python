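from fractions import Fraction

import pytest

from ascoflux.formula import Formula, degree_of_reduction
from ascoflux.products import (
    FUNCTIONAL_GROUPS,
    NON_FH,
    ProductSpec,
    RegistryError,
    enumerate_ehrlich_products,
    enumerate_esters,
    enumerate_fatty_acid_products,
    enumerate_linoleic_products,
    registry_summary,
)

F = Fraction


def test_default_registry_totals(registry):
    s = registry_summary(registry)
    assert s["total"] == 161
    assert set(s["by_group"]) == set(FUNCTIONAL_GROUPS)
    assert len(s["by_group"]) == 8
    assert s["min_chain"] == 3
    assert s["max_chain"] == 20


def test_chain_lengths_within_c3_c20(registry):
    assert all(3 <= p.chain_length <= 20 for p in registry.products)


def test_primary_fermentation_products_are_never_registry_members(registry):
    names = {p.name for p in registry.products}
    assert not (names & NON_FH)
    with pytest.raises(RegistryError):
        ProductSpec(name="ethanol", product_class="fatty_acid", functional_group="acid",
                    chain_length=3, formula=Formula(C=2, H=6, O=1), initiator="n/a",
                    generating_reaction_ids=frozenset())


def test_initiator_parity_rules(registry):
    """Primary groups keep initiator parity; carbon-losing groups flip it."""
    primary = {"acid", "aldehyde", "primary_alcohol"}
    losing = {"alkane", "alkene", "ketone", "secondary_alcohol"}
    for p in registry.products:
        if p.product_class != "fatty_acid":
            continue
        even_initiated = p.initiator == "acetyl-CoA"
        if p.functional_group in primary:
            assert (p.chain_length % 2 == 0) == even_initiated, p.name
        elif p.functional_group in losing:
            assert (p.chain_length % 2 == 1) == even_initiated, p.name


def test_even_acids_start_from_acetyl_odd_from_propanoyl(products_by_name):
    assert products_by_name["palmitate"].initiator == "acetyl-CoA"
    assert products_by_name["C9 acid"].initiator == "propanoyl-CoA"
    assert products_by_name["propanoate"].initiator == "propanoyl-CoA"


def test_reduced_fatty_groups_sit_at_or_approach_gamma_six(registry):
    """Alkenes (CnH2n) and primary alcohols (CnH2n+2O) are exactly 6
    electron-mol per Cmol; alkanes (CnH2n+2) sit at 6 + 2/n, approaching 6
    from above with chain length."""
    for p in registry.products:
        if p.product_class != "fatty_acid":
            continue
        n = p.chain_length
        if p.functional_group in {"alkene", "primary_alcohol"}:
            assert p.gamma == 6, p.name
        elif p.functional_group == "alkane":
            assert p.gamma == 6 + F(2, n), p.name


def test_fatty_acid_gamma_increases_with_chain_toward_six(registry):
    acids = sorted(
        (p for p in registry.products
         if p.product_class == "fatty_acid" and p.functional_group == "acid"),
        key=lambda p: p.chain_length,
    )
    gammas = [p.gamma for p in acids]
    assert all(a < b for a, b in zip(gammas, gammas[1:]))
    assert all(g < 6 for g in gammas)
    assert gammas[-1] > F(11, 2)  # approaching 6


def test_ketone_generation_loses_exactly_one_carbon_as_co2(registry):
    # C10 acid's acyl stage also feeds the C9 ketone via the beta-keto acid
    rxn = {r.id: r for r in registry.reactions}["fa_oxoacid_dc10"]
    assert rxn.stoichiometry["co2_c"] == 1
    assert rxn.stoichiometry["fa_ketone9_c"] == 1


def test_aromatic_ehrlich_routes_consume_o2_branched_do_not(registry):
    rxns = {r.id: r for r in registry.reactions}
    by_name = {p.name: p for p in registry.products}
    for name in ["4-hydroxyphenylacetate", "2-phenylethanol", "indole-3-acetate"]:
        route = by_name[name].generating_reaction_ids
        assert any("o2_c" in rxns[rid].stoichiometry for rid in route if rid in rxns), name
    for name in ["3-methyl-1-butanol", "isobutanal", "2-methylbutanoate"]:
        route = by_name[name].generating_reaction_ids
        assert not any(
            "o2_c" in rxns[rid].stoichiometry for rid in route if rid in rxns
        ), name


def test_phenylethanol_degree_of_reduction_is_five(products_by_name):
    assert products_by_name["2-phenylethanol"].gamma == 5


def test_linoleic_c8_products_only_in_coupled_cleavages(registry):
    rxns = {r.id: r for r in registry.reactions}
    c8 = [p for p in registry.products if p.product_class == "linoleic" and p.chain_length == 8]
    assert {p.name for p in c8} >= {"1-octen-3-ol", "3-octanone", "1,3-octadiene"}
    for p in c8:
        for rid in p.generating_reaction_ids:
            rxn = rxns[rid]
            made = [m for m, c in rxn.stoichiometry.items()
                    if c > 0 and m.startswith("lin_")]
            assert len(made) == 2, f"{p.name} produced without coproduct"


def test_linoleic_cleavage_conserves_the_eighteen_carbons(registry):
    rxns = [r for r in registry.reactions if r.id.startswith("lin_cleave")]
    mets = {m.id: m for m in registry.metabolites}
    assert rxns
    for rxn in rxns:
        made = sum(mets[m].formula.C * c for m, c in rxn.stoichiometry.items()
                   if c > 0 and m in mets)
        assert made == 18


def test_ester_formula_is_alcohol_plus_acetate_minus_water(registry):
    by_name = {p.name: p for p in registry.products}
    ethanol = Formula(C=2, H=6, O=1)
    acetate = Formula(C=2, H=4, O=2)
    ea = by_name["ethyl acetate"].formula
    assert (ea.C, ea.H, ea.O) == (
        ethanol.C + acetate.C, ethanol.H + acetate.H - 2, ethanol.O + acetate.O - 1
    )
    assert "isopentyl acetate" in by_name
    assert "2-phenylethyl acetate" in by_name


def test_esters_require_prior_alcohol_enumeration():
    with pytest.raises(RegistryError):
        enumerate_esters(enumerate_fatty_acid_products((3, 6)))


def test_invalid_length_range_rejected():
    with pytest.raises(RegistryError):
        enumerate_fatty_acid_products((2, 25))
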