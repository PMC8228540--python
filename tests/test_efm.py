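from fractions import Fraction

import numpy as np
import pytest
from scipy.optimize import linprog

from ascoflux.efm import (
    EFMOverflowError,
    ExclusionRuleSet,
    FluxMode,
    brute_force_efms,
    enumerate_efms,
    filter_by_exclusion_rules,
    is_elementary,
    normalize_mode,
)
from ascoflux.network import NetworkError, build_matrix, split_reversible
from ascoflux.toys import make_toy_networks, random_network

F = Fraction


@pytest.mark.parametrize("name", ["chain", "diamond", "y_branch", "reversible_loop",
                                  "exclusion_pair", "mini_fas"])
def test_toy_mode_counts_and_oracle_agreement(toys, name):
    spec = toys[name]
    modes = enumerate_efms(spec.network)
    oracle = brute_force_efms(spec.network)
    assert len(modes) == spec.expected_efm_count
    assert set(modes) == set(oracle)


def test_chain_single_mode_uses_all_reactions(toys):
    (mode,) = enumerate_efms(toys["chain"].network)
    assert mode.support == {"EX_A_in", "r_ab", "EX_B_out"}


def test_two_cycles_of_reversible_pairs_are_excluded(toys):
    modes = enumerate_efms(toys["reversible_loop"].network)
    assert not any(m.support == {"r_iso", "r_iso__rev"} for m in modes)
    # but the genuine futile cycle through two different reactions remains
    assert any(m.support == {"r_alt", "r_iso__rev"} for m in modes)


def test_no_two_returned_modes_share_a_support(toys):
    for spec in toys.values():
        modes = enumerate_efms(spec.network)
        supports = [m.support_key() for m in modes]
        assert len(supports) == len(set(supports))


def test_enumeration_is_deterministic(toys):
    net = toys["y_branch"].network
    first = enumerate_efms(net)
    for _ in range(3):
        assert enumerate_efms(net) == first


def test_overflow_cap_raises_with_ray_count(toys):
    with pytest.raises(EFMOverflowError) as err:
        enumerate_efms(toys["mini_fas"].network, max_rays=1)
    assert err.value.n_rays > 1


@pytest.mark.parametrize("seed", range(50))
def test_oracle_equivalence_on_random_networks(seed):
    net = random_network(seed, n_reactions=12)
    assert set(enumerate_efms(net)) == set(brute_force_efms(net))


def test_random_networks_are_reproducible_for_fixed_seed():
    a, b = random_network(7, 12), random_network(7, 12)
    assert set(a.reactions) == set(b.reactions)
    for rid in a.reactions:
        assert a.reactions[rid].stoichiometry == b.reactions[rid].stoichiometry


def test_every_feasible_flux_decomposes_into_modes(reduced_energy_model):
    """Any LP-feasible steady-state vector is a nonnegative combination of
    the enumerated modes (completeness of the mode set)."""
    net = reduced_energy_model
    split, _ = split_reversible(net)
    S, _, rxn_ids = build_matrix(split)
    A = np.array([[float(v) for v in row] for row in S])
    rng = np.random.default_rng(0)
    modes = enumerate_efms(net)
    M = np.array([[float(m.rates.get(rid, 0)) for m in modes] for rid in rxn_ids])
    for _ in range(5):
        c = rng.uniform(-1, 1, len(rxn_ids))
        res = linprog(c, A_eq=A, b_eq=np.zeros(len(S)),
                      bounds=[(0, 1)] * len(rxn_ids), method="highs")
        assert res.status == 0
        v = res.x.copy()
        # cancel fwd/bwd two-cycles of split reversible pairs: they are a
        # lineality direction deliberately absent from the mode set
        for j, rid in enumerate(rxn_ids):
            if rid.endswith("__rev"):
                k = rxn_ids.index(rid[: -len("__rev")])
                cancel = min(v[j], v[k])
                v[j] -= cancel
                v[k] -= cancel
        eps = 1e-7
        A_ub = np.vstack([M, -M])
        b_ub = np.concatenate([v + eps, -(v - eps)])
        dec = linprog(np.zeros(len(modes)), A_ub=A_ub, b_ub=b_ub,
                      bounds=[(0, None)] * len(modes), method="highs")
        assert dec.status == 0, "feasible vector outside the mode cone"


def test_is_elementary_on_modes_sums_and_zero(toys):
    net = toys["diamond"].network
    m1, m2 = enumerate_efms(net)
    assert is_elementary(m1.rates, net)
    combined = {rid: m1.rates.get(rid, F(0)) + m2.rates.get(rid, F(0))
                for rid in set(m1.rates) | set(m2.rates)}
    assert not is_elementary(combined, net)
    assert not is_elementary({}, net)


def test_is_elementary_rejects_non_steady_state(toys):
    net = toys["chain"].network
    with pytest.raises(NetworkError):
        is_elementary({"r_ab": F(1)}, net)


def test_exclusion_rule_filtering(toys):
    net = toys["exclusion_pair"].network
    modes = enumerate_efms(net)
    rules = ExclusionRuleSet.from_network(net)
    kept = filter_by_exclusion_rules(modes, rules, net)
    # the serial route uses two members of the group and is excluded
    assert len(kept) == 1
    assert "r_direct" in kept[0].support

    assert filter_by_exclusion_rules(modes, ExclusionRuleSet.from_dict({})) == modes
    single = ExclusionRuleSet.from_dict({"g": ["r_direct"]})
    assert filter_by_exclusion_rules(modes, single, net) == modes
    with pytest.raises(NetworkError):
        filter_by_exclusion_rules(modes, ExclusionRuleSet.from_dict({"g": ["ghost", "r_direct"]}), net)


def test_normalize_mode_by_reference_and_substrate(toys):
    net = toys["y_branch"].network
    modes = enumerate_efms(net)
    mode = next(m for m in modes if "r_ferm" in m.support)
    scaled = mode.scaled(F(5))
    normed = normalize_mode(scaled, "r_upper")
    assert normed.rates["r_upper"] == 1
    again = normalize_mode(normed, "r_upper")
    assert again == normed

    per_cmol = normalize_mode(mode, "unit-substrate", network=net)
    # substrate is C6; uptake of 1/6 molecule = 1 Cmol
    assert per_cmol.rates["EX_S_in"] * 6 == 1

    with pytest.raises(NetworkError):
        normalize_mode(mode, "r_resp")
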