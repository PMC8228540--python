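from fractions import Fraction

import pytest

from ascoflux.formula import Formula
from ascoflux.linalg import rank
from ascoflux.network import (
    MetabolicNetwork,
    Metabolite,
    NetworkError,
    Reaction,
    UnknownMetaboliteError,
    build_matrix,
    check_mass_balance,
    fold_back,
    split_reversible,
    validate_network,
)

F = Fraction


def _met(mid, formula, comp="cytosol"):
    return Metabolite(id=mid, name=mid, compartment=comp, formula=Formula.parse(formula))


@pytest.fixture()
def fermentation_net():
    mets = [
        _met("glc", "C6H12O6"),
        _met("etoh", "C2H6O"),
        _met("co2", "CO2"),
    ]
    rxns = [
        Reaction("ferm", {"glc": F(-1), "etoh": F(2), "co2": F(2)}),
        Reaction("bad_ferm", {"glc": F(-1), "etoh": F(2)}),
        Reaction("EX_glc", {"glc": F(1)}),
    ]
    return MetabolicNetwork(mets, rxns, {"EX_glc"})


def test_mass_balance_of_alcoholic_fermentation(fermentation_net):
    res = check_mass_balance(fermentation_net.reactions["ferm"], fermentation_net)
    assert all(v == 0 for v in res.values())


def test_mass_balance_residuals_flag_missing_co2(fermentation_net):
    res = check_mass_balance(fermentation_net.reactions["bad_ferm"], fermentation_net)
    assert res["C"] == -2
    assert res["O"] == -4


def test_exchange_reactions_are_exempt_from_balance(fermentation_net):
    res = check_mass_balance(fermentation_net.reactions["EX_glc"], fermentation_net)
    assert "exempt" in res


def test_unknown_metabolite_raises_lookup_error(fermentation_net):
    orphan = Reaction("r", {"nope": F(-1), "co2": F(1)})
    with pytest.raises(UnknownMetaboliteError):
        check_mass_balance(orphan, fermentation_net)


def test_matrix_of_two_reaction_chain():
    mets = [_met("A", "C"), _met("B", "C")]
    rxns = [
        Reaction("EX_A", {"A": F(1)}),
        Reaction("r", {"A": F(-1), "B": F(1)}),
        Reaction("EX_B", {"B": F(-1)}),
    ]
    net = MetabolicNetwork(mets, rxns, {"EX_A", "EX_B"})
    S, met_ids, rxn_ids = build_matrix(net)
    row = S[met_ids.index("B")]
    assert (row[rxn_ids.index("r")], row[rxn_ids.index("EX_B")]) == (1, -1)


def test_diamond_matrix_has_full_row_rank(toys):
    S, met_ids, _ = build_matrix(toys["diamond"].network)
    assert rank(S) == len(met_ids)


def test_core_model_matrix_is_wide(wt_model):
    S, _, rxn_ids = build_matrix(wt_model)
    assert len(rxn_ids) >= 60
    assert len(S[0]) == len(rxn_ids)


def test_empty_network_matrix_errors():
    net = MetabolicNetwork([_met("A", "C")], [Reaction("EX_A", {"A": F(1)})], {"EX_A"})
    net.reactions.clear()
    with pytest.raises(NetworkError):
        build_matrix(net)


def test_split_reversible_adds_one_column_per_reversible(toys):
    net = toys["reversible_loop"].network
    split, foldback = split_reversible(net)
    n_rev = sum(r.reversible for r in net.reactions.values())
    assert len(split.reactions) == len(net.reactions) + n_rev
    assert not any(r.reversible for r in split.reactions.values())
    assert set(foldback) == {rid for rid, r in net.reactions.items() if r.reversible}


def test_fold_back_restores_signed_fluxes(toys):
    net = toys["reversible_loop"].network
    _, foldback = split_reversible(net)
    fwd, bwd = foldback["r_iso"]
    assert fold_back({fwd: F(3)}, foldback) == {"r_iso": F(3)}
    assert fold_back({bwd: F(2)}, foldback) == {"r_iso": F(-2)}


def test_split_is_identity_on_irreversible_networks(toys):
    net = toys["chain"].network
    split, foldback = split_reversible(net)
    assert foldback == {}
    assert set(split.reactions) == set(net.reactions)


def test_validator_reports_dead_end_and_duplicate():
    mets = [_met("A", "C"), _met("B", "C"), _met("dangling", "C")]
    rxns = [
        Reaction("EX_A", {"A": F(1)}),
        Reaction("r1", {"A": F(-1), "B": F(1)}),
        Reaction("r1bis", {"A": F(-1), "B": F(1)}),
        Reaction("r2", {"A": F(-1), "dangling": F(1)}),
        Reaction("EX_B", {"B": F(-1)}),
    ]
    net = MetabolicNetwork(mets, rxns, {"EX_A", "EX_B"})
    diag = validate_network(net)
    assert "dangling" in diag["dead_ends"]
    assert ("r1", "r1bis") in diag["duplicates"]
    assert not diag["unbalanced"]


def test_core_model_has_no_unbalanced_internal_reactions(wt_model):
    diag = validate_network(wt_model)
    assert diag["unbalanced"] == []
    assert diag["dead_ends"] == []


def test_exchange_must_touch_exactly_one_metabolite():
    mets = [_met("A", "C"), _met("B", "C")]
    with pytest.raises(NetworkError):
        MetabolicNetwork(
            mets,
            [Reaction("EX_bad", {"A": F(-1), "B": F(1)})],
            {"EX_bad"},
        )
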