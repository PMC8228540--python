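from fractions import Fraction

import pytest

from ascoflux.core_model import (
    CELLOPENTAOSE,
    GLUCOSE,
    EnergyParams,
    InterventionConfig,
    apply_interventions,
    build_core_model,
    build_reduced_energy_model,
    energy_yield,
)
from ascoflux.network import validate_network
from ascoflux.yields import InfeasibleError, minimize_substrate

F = Fraction


def test_default_build_is_element_balanced(wt_model):
    diag = validate_network(wt_model)
    assert diag["unbalanced"] == []


def test_no_pyruvate_decarboxylase_in_wild_type(wt_model):
    assert not any(r.pathway_tag == "Pdc" for r in wt_model.reactions.values())
    assert "pdc" not in {rid.lower() for rid in wt_model.reactions}


def test_electron_consistency_of_hand_picked_core_reactions(wt_model):
    """Degree-of-reduction bookkeeping: substrates and products of balanced
    reactions carry equal electron totals (O2 counted at -4 e/mol)."""
    for rid in ["pdh_m", "cs", "adh", "fdh", "desaturase"]:
        rxn = wt_model.reactions[rid]
        total = F(0)
        for mid, coeff in rxn.stoichiometry.items():
            total += coeff * wt_model.metabolites[mid].formula.electrons()
        assert total == 0, rid


def test_energy_optimum_on_cellopentaose(wt_model):
    carbon, o2 = energy_yield(wt_model, "unlimited")
    assert carbon == F(30, 149)
    assert o2 == F(30, 149)
    assert round(float(carbon), 1) == 0.2
    assert round(float(o2), 1) == 0.2


def test_cellopentaose_beats_glucose_per_cmol(wt_model, glucose_model):
    cp, _ = energy_yield(wt_model, "unlimited")
    glc, _ = energy_yield(glucose_model, "unlimited")
    assert cp < glc  # fewer Cmol needed per ATP


def test_anoxic_energy_is_feasible_but_costlier(wt_model):
    carbon, o2 = energy_yield(wt_model, "zero")
    assert o2 == 0
    assert carbon > F(30, 149)


def test_biomass_needs_oxygen_under_every_intervention():
    for cp in (False, True):
        for pdh in (False, True):
            net = build_core_model(interventions=InterventionConfig(cp, pdh))
            with pytest.raises(InfeasibleError):
                minimize_substrate(net, product_row={"EX_biomass": F(1)}, o2_bound=F(0))
            res = minimize_substrate(net, product_row={"EX_biomass": F(1)})
            assert res.carbon_cost > 0


def test_cp_on_glucose_is_inert_with_warning(glucose_model):
    with pytest.warns(UserWarning):
        modified = apply_interventions(glucose_model, InterventionConfig(True, False))
    assert set(modified.reactions) == set(glucose_model.reactions)
    assert energy_yield(modified, "unlimited") == energy_yield(glucose_model, "unlimited")


def test_pdhcyt_adds_exactly_one_reaction(wt_model, pdhcyt_model):
    added = set(pdhcyt_model.reactions) - set(wt_model.reactions)
    assert added == {"pdh_c"}


def test_cp_spares_four_hexokinase_activations_per_cellopentaose(cp_model):
    cp = cp_model.reactions["cp_phosphorolysis"]
    # 4 of 5 glucosyl units appear as G1P (no ATP), one as free glucose
    assert cp.stoichiometry["g1p_c"] == 4
    assert cp.stoichiometry["glc_c"] == 1
    assert cp.stoichiometry["pi_c"] == -4
    assert "atp_c" not in cp.stoichiometry


def test_cp_lowers_the_energy_cost_on_cellopentaose(wt_model, cp_model):
    wt_c, _ = energy_yield(wt_model, "zero")
    cp_c, _ = energy_yield(cp_model, "zero")
    assert cp_c < wt_c


def test_acetyl_coa_reaches_cytosol_only_via_acl_or_acetate_route(wt_model, pdhcyt_model,
                                                                  products_by_name):
    from ascoflux.yields import min_carbon_cost

    palmitate = products_by_name["palmitate"]
    for rid in ("acl", "acs_c"):
        assert rid in wt_model.reactions
    crippled = wt_model.with_reactions(remove=["acl", "acs_c"])
    with pytest.raises(InfeasibleError):
        min_carbon_cost(crippled, palmitate)
    rescued = pdhcyt_model.with_reactions(remove=["acl", "acs_c"])
    assert min_carbon_cost(rescued, palmitate).carbon_cost == F(3, 2)


def test_reduced_energy_model_is_balanced_and_small():
    net = build_reduced_energy_model()
    assert validate_network(net)["unbalanced"] == []
    assert len(net.reactions) <= 20


def test_energy_params_reject_negative_values():
    with pytest.raises(ValueError):
        EnergyParams(po_nadh_mito=F(-1))


def test_substrate_spec_validation():
    from ascoflux.core_model import SubstrateSpec

    with pytest.raises(ValueError):
        SubstrateSpec("xylose", 5)
    assert GLUCOSE.cmol_per_molecule == 6
    assert CELLOPENTAOSE.cmol_per_molecule == 30
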