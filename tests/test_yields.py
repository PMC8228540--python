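from fractions import Fraction

import pytest

from ascoflux.core_model import energy_yield
from ascoflux.efm import enumerate_efms
from ascoflux.formula import Formula
from ascoflux.yields import (
    InfeasibleError,
    YieldPoint,
    efm_yield_cloud,
    electron_bound,
    group_min_cost,
    min_carbon_cost,
    pareto_front,
    group_scan,
    tradeoff_curve,
)

F = Fraction


def _pt(c, o) -> YieldPoint:
    return YieldPoint(product_id="p", carbon_cost=F(c), o2_cost=F(o), condition="gridpoint")


class TestParetoFront:
    def test_dominated_point_removed(self):
        assert pareto_front([_pt(1, 1), _pt(2, 2)]) == [_pt(1, 1)]

    def test_incomparable_points_both_kept(self):
        front = pareto_front([_pt(1, 2), _pt(2, 1)])
        assert len(front) == 2
        assert front[0].carbon_cost == 1

    def test_ties_kept(self):
        front = pareto_front([_pt(1, 1), _pt(1, 1)])
        assert len(front) == 2

    def test_y_network_cloud_keeps_endpoints_only(self, reduced_energy_model):
        modes = enumerate_efms(reduced_energy_model)
        cloud = efm_yield_cloud(modes, reduced_energy_model, "atp_demand")
        front = pareto_front(cloud)
        # brute-force dominance check
        expected = [p for p in cloud if not any(
            (q.carbon_cost <= p.carbon_cost and q.o2_cost <= p.o2_cost) and
            (q.carbon_cost < p.carbon_cost or q.o2_cost < p.o2_cost) for q in cloud)]
        assert {(p.carbon_cost, p.o2_cost) for p in front} == {
            (p.carbon_cost, p.o2_cost) for p in expected}


class TestEfmCloud:
    def test_single_mode_network_gives_one_point(self, toys):
        net = toys["chain"].network
        modes = enumerate_efms(net)
        pts = efm_yield_cloud(modes, net, "EX_B_out")
        assert len(pts) == 1
        assert pts[0].carbon_cost == 1

    def test_modes_without_product_flux_are_excluded(self, toys):
        net = toys["y_branch"].network
        modes = enumerate_efms(net)
        pts = efm_yield_cloud(modes, net, "EX_F_out")
        # only the fermentation branch exports F; the respiration mode drops out
        assert len(modes) == 2 and len(pts) == 1
        assert pts[0].carbon_cost > 0

    def test_pure_ethanol_mode_is_the_anoxic_frontier_end(self, reduced_energy_model):
        modes = enumerate_efms(reduced_energy_model)
        cloud = efm_yield_cloud(modes, reduced_energy_model, "atp_demand")
        front = pareto_front(cloud)
        anoxic_end = front[-1]
        assert anoxic_end.o2_cost == 0
        ethanol = [m for m in modes if "to_etoh" in m.support and "atp_demand" in m.support
                   and "respiration" not in m.support]
        assert ethanol, "no pure ethanol energy mode"

    def test_cloud_points_are_dominated_by_or_on_the_lp_frontier(self, reduced_energy_model):
        modes = enumerate_efms(reduced_energy_model)
        cloud = efm_yield_cloud(modes, reduced_energy_model, "atp_demand")
        for p in cloud:
            carbon, _o2 = energy_yield_at_bound(reduced_energy_model, p.o2_cost)
            assert carbon <= p.carbon_cost

    def test_frontier_runs_from_full_oxidation_to_fermentation(self, reduced_energy_model):
        modes = enumerate_efms(reduced_energy_model)
        front = pareto_front(efm_yield_cloud(modes, reduced_energy_model, "atp_demand"))
        assert front[0].o2_cost == max(p.o2_cost for p in front)  # complete oxidation
        assert front[-1].o2_cost == 0  # fermentation


def energy_yield_at_bound(network, bound):
    from ascoflux.yields import minimize_substrate

    res = minimize_substrate(network, fixed_flux=("atp_demand", F(1)), o2_bound=F(bound),
                             minimize_o2_secondary=False)
    return res.carbon_cost, res.o2_cost


class TestMinCarbonCost:
    def test_wild_type_propanoate_is_the_electron_balance_value(self, wt_model,
                                                                products_by_name):
        pt = min_carbon_cost(wt_model, products_by_name["propanoate"])
        assert pt.carbon_cost == F(7, 6)
        assert pt.o2_cost == 0

    def test_even_chain_acid_under_both_interventions_hits_three_halves(
            self, both_model, products_by_name):
        pt = min_carbon_cost(both_model, products_by_name["palmitate"])
        assert pt.carbon_cost == F(3, 2)

    def test_electron_bound_holds_at_anoxic_optima(self, wt_model, registry):
        substrate = Formula.parse("C6H12O6")  # per-Cmol identical to cellopentaose units
        for p in registry.products[::13]:
            try:
                pt = min_carbon_cost(wt_model, p, o2_bound=F(0), minimize_o2=False)
            except InfeasibleError:
                continue
            assert pt.carbon_cost >= electron_bound(p.formula, substrate)

    def test_carbon_bound_holds_everywhere(self, wt_model, registry):
        for p in registry.products[::17]:
            pt = min_carbon_cost(wt_model, p, minimize_o2=False)
            assert pt.carbon_cost >= 1

    def test_aromatic_product_infeasible_anoxically_with_context(self, wt_model,
                                                                 products_by_name):
        with pytest.raises(InfeasibleError):
            min_carbon_cost(wt_model, products_by_name["2-phenylethanol"], o2_bound=F(0))


class TestTradeoffCurve:
    GRID = [F(0), F(1, 16), F(1, 4), F(1)]

    def test_carbon_cost_non_increasing_in_o2_bound(self, wt_model, products_by_name):
        for name in ["propanoate", "3-methyl-1-butanol", "palmitate", "1-C4-ene"]:
            pts = tradeoff_curve(wt_model, products_by_name[name], self.GRID,
                                 minimize_o2=False)
            costs = [p.carbon_cost for p in pts]
            assert all(a >= b for a, b in zip(costs, costs[1:])), name

    def test_gridpoint_zero_matches_anoxic_minimum(self, wt_model, products_by_name):
        p = products_by_name["3-methyl-1-butanol"]
        pts = tradeoff_curve(wt_model, p, [F(0)])
        direct = min_carbon_cost(wt_model, p, o2_bound=F(0))
        assert pts[0].carbon_cost == direct.carbon_cost

    def test_unsorted_grid_rejected(self, wt_model, products_by_name):
        with pytest.raises(ValueError):
            tradeoff_curve(wt_model, products_by_name["propanoate"], [F(1), F(0)])

    def test_isopentanol_flatter_than_phenylethanol(self, wt_model, products_by_name):
        """Isopentyl derivatives are less O2-sensitive than aromatic ones:
        the aromatic curve diverges (infeasible) at O2=0 while isopentanol
        rises by a finite amount."""
        iso = products_by_name["3-methyl-1-butanol"]
        aro = products_by_name["2-phenylethanol"]
        iso_span = (min_carbon_cost(wt_model, iso, o2_bound=F(0)).carbon_cost
                    - min_carbon_cost(wt_model, iso).carbon_cost)
        assert iso_span > 0
        with pytest.raises(InfeasibleError):
            min_carbon_cost(wt_model, aro, o2_bound=F(0))


class TestInterventionOrdering:
    def test_interventions_never_increase_any_minimum_cost(
            self, wt_model, cp_model, pdhcyt_model, both_model, registry):
        for p in registry.products[::11]:
            try:
                base = min_carbon_cost(wt_model, p, minimize_o2=False).carbon_cost
            except InfeasibleError:
                continue
            costs = {}
            for label, net in [("cp", cp_model), ("pdh", pdhcyt_model), ("both", both_model)]:
                costs[label] = min_carbon_cost(net, p, minimize_o2=False).carbon_cost
                assert costs[label] <= base, (p.name, label)
            assert costs["both"] <= min(costs["cp"], costs["pdh"]), p.name

    def test_pdhcyt_leaves_every_ehrlich_cost_unchanged(self, wt_model, pdhcyt_model,
                                                        registry):
        for p in registry.products:
            if p.product_class != "ehrlich":
                continue
            a = min_carbon_cost(wt_model, p, minimize_o2=False).carbon_cost
            b = min_carbon_cost(pdhcyt_model, p, minimize_o2=False).carbon_cost
            assert a == b, p.name


def test_energy_optimum_cross_checked_against_cobrapy(reduced_energy_model):
    """Independent LP route: rebuild the reduced model in cobrapy and
    minimize substrate uptake per unit ATP demand there."""
    cobra = pytest.importorskip("cobra")

    net = reduced_energy_model
    model = cobra.Model("reduced")
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment[0])
            for m in net.metabolites.values()}
    model.add_metabolites(list(mets.values()))
    crs = []
    for rxn in net.reactions.values():
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound = -1000.0 if rxn.reversible else 0.0
        cr.upper_bound = 1000.0
        crs.append(cr)
    model.add_reactions(crs)
    for rxn in net.reactions.values():
        model.reactions.get_by_id(rxn.id).add_metabolites(
            {mets[k]: float(v) for k, v in rxn.stoichiometry.items()})
    model.reactions.atp_demand.bounds = (1.0, 1.0)
    model.objective = model.reactions.EX_sub
    model.objective_direction = "min"
    sol = model.optimize()
    assert sol.status == "optimal"
    ours = energy_yield(net, "unlimited")[0]
    assert abs(sol.objective_value * 30 - float(ours)) < 1e-6


class TestGroupScan:
    def test_wt_acid_group_minimum_is_propanoate(self, wt_model, products_by_group):
        pt = group_min_cost(wt_model, products_by_group["acid"])
        assert pt.product_id == "propanoate"
        assert pt.carbon_cost == F(7, 6)
        assert pt.o2_cost == 0

    def test_alkene_group_under_both_interventions(self, both_model, products_by_group):
        pt = group_min_cost(both_model, products_by_group["alkene"], intervention="both")
        assert pt.carbon_cost == F(3, 2)
        assert pt.o2_cost == 0

    def test_group_scan_shape_single_group(self):
        df = group_scan(groups=["alkene"])
        assert len(df) == 4  # one row per strain
        assert set(df["strain"]) == {"WT", "WT+CP", "WT+PDHcyt", "WT+CP+PDHcyt"}
        both = df[df["strain"] == "WT+CP+PDHcyt"].iloc[0]
        assert both["carbon_limited"] == F(3, 2)
        assert both["o2_at_optimum"] == 0
        wt = df[df["strain"] == "WT"].iloc[0]
        assert wt["carbon_limited"] >= both["carbon_limited"]
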