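"""Resource-cost coordinates: LP yield optimization and trade-off frontiers.

Costs are expressed on a carbon-mole basis: Cmoles of
carbon source (and moles of O2) consumed per Cmole of product exported,
or per mole of ATP for the cellular-energy product.  Optima are computed
by linear programming over the steady-state flux cone (HiGHS) and then
re-verified with exact rational arithmetic on the optimal support, so the
reported values are exact Fractions, not floats.

Two bounds anchor every result: the carbon bound (at least 1 Cmol of
substrate per Cmol of product, more when a route loses CO2) and the
electron bound (at zero O2, carbon_cost * gamma_substrate must cover the
electrons of all reduced outputs).
"""

from __future__ import annotations

import weakref
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .efm import FluxMode
from .formula import degree_of_reduction
from .linalg import solve_exact
from .network import MetabolicNetwork, NetworkError, build_matrix

F = Fraction


class InfeasibleError(RuntimeError):
    """LP infeasibility with context (e.g. aromatic product at O2 = 0)."""


@dataclass(frozen=True)
class YieldPoint:
    product_id: str
    carbon_cost: Fraction
    o2_cost: Fraction | None
    condition: str
    intervention: str = "WT"
    extras: Mapping[str, Fraction] = field(default_factory=dict)


@dataclass
class LPResult:
    carbon_cost: Fraction
    o2_cost: Fraction
    fluxes: dict[str, float]
    exact: bool


# ---------------------------------------------------------------------------
# LP plumbing


def _substrate_exchange(network: MetabolicNetwork) -> tuple[str, int]:
    for rid in network.exchange_ids:
        rxn = network.reactions[rid]
        if rxn.pathway_tag == "substrate":
            (met_id, _coeff), = rxn.stoichiometry.items()
            return rid, network.metabolites[met_id].formula.C
    raise NetworkError("network has no exchange tagged 'substrate'")


def _o2_exchange(network: MetabolicNetwork) -> str | None:
    for rid in network.exchange_ids:
        if network.reactions[rid].pathway_tag == "o2":
            return rid
    return None


def _product_exchanges(network: MetabolicNetwork) -> list[str]:
    return [rid for rid in network.exchange_ids
            if network.reactions[rid].pathway_tag == "product"]


def _exact_objective(
    S_rows: list[list[Fraction]],
    extra_rows: list[tuple[list[Fraction], Fraction]],
    c_exact: list[Fraction],
    x: np.ndarray,
    float_obj: float,
    support_tol: float = 1e-8,
) -> Fraction | None:
    """Re-solve the optimum on its float support exactly; return the exact
    objective if it reproduces the LP value, else None."""
    n = len(x)
    for tol in (support_tol, 1e-6):
        sup = [j for j in range(n) if abs(x[j]) > tol]
        if not sup:
            continue
        a = [[row[j] for j in sup] for row in S_rows if any(row[j] != 0 for j in sup)]
        b = [F(0)] * len(a)
        for row, rhs in extra_rows:
            a.append([row[j] for j in sup])
            b.append(rhs)
        sol = solve_exact(a, b)
        if sol is None:
            continue
        obj = sum((c_exact[j] * v for j, v in zip(sup, sol)), F(0))
        if abs(float(obj) - float_obj) <= 1e-6 * max(1.0, abs(float_obj)):
            return obj
    return None


_matrix_cache: "weakref.WeakKeyDictionary" = weakref.WeakKeyDictionary()


def _cached_matrix(network: MetabolicNetwork):
    try:
        return _matrix_cache[network]
    except KeyError:
        S, _mets, rxn_ids = build_matrix(network)
        A = np.array([[float(v) for v in row] for row in S])
        data = (S, A, rxn_ids, {rid: j for j, rid in enumerate(rxn_ids)})
        _matrix_cache[network] = data
        return data


def _solve(
    network: MetabolicNetwork,
    objective: Mapping[str, Fraction],
    fixed_rows: Sequence[tuple[Mapping[str, Fraction], Fraction]],
    upper_bounds: Mapping[str, Fraction] | None = None,
    closed: Iterable[str] = (),
    context: str = "",
) -> tuple[Fraction, dict[str, float]]:
    """Minimize ``objective . v`` s.t. S v = 0, directionality, fixed rows,
    per-reaction upper bounds, and closed reactions forced to zero."""
    S, A_S, rxn_ids, col = _cached_matrix(network)
    n = len(rxn_ids)
    closed = set(closed)

    c_exact = [F(0)] * n
    for rid, w in objective.items():
        c_exact[col[rid]] = F(w)

    extra_rows: list[tuple[list[Fraction], Fraction]] = []
    for row_map, rhs in fixed_rows:
        row = [F(0)] * n
        for rid, w in row_map.items():
            row[col[rid]] = F(w)
        extra_rows.append((row, F(rhs)))

    bounds = []
    ub_map = {k: F(v) for k, v in (upper_bounds or {}).items()}
    for rid in rxn_ids:
        if rid in closed:
            bounds.append((0.0, 0.0))
            continue
        lo = -np.inf if network.reactions[rid].reversible else 0.0
        hi = float(ub_map[rid]) if rid in ub_map else np.inf
        bounds.append((lo, hi))

    A_eq = np.vstack([A_S] + [[float(v) for v in row] for row, _ in extra_rows]) \
        if extra_rows else A_S
    b_eq = np.concatenate([np.zeros(len(S)), [float(r) for _, r in extra_rows]])
    c = np.array([float(v) for v in c_exact])

    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        raise InfeasibleError(
            f"LP infeasible or unbounded ({res.status}: {res.message})"
            + (f" [{context}]" if context else "")
        )
    exact = _exact_objective(S, extra_rows, c_exact, res.x, res.fun)
    if exact is None:
        # degenerate support: fall back to a rationalization of the value
        exact = F(res.fun).limit_denominator(10**9)
    fluxes = {rid: float(res.x[col[rid]]) for rid in rxn_ids if abs(res.x[col[rid]]) > 1e-9}
    return exact, fluxes


def minimize_substrate(
    network: MetabolicNetwork,
    fixed_flux: tuple[str, Fraction] | None = None,
    product_row: Mapping[str, Fraction] | None = None,
    o2_bound: Fraction | None = None,
    closed: Iterable[str] = (),
    minimize_o2_secondary: bool = True,
) -> LPResult:
    """Minimize substrate uptake in Cmol per unit of demand.

    Demand is either a fixed reaction flux (``fixed_flux=(rid, value)``,
    used for the ATP demand) or a weighted exchange row summing to 1 Cmol
    of product (``product_row``).  ``o2_bound`` caps O2 uptake (None =
    unlimited).  Among carbon optima the O2 uptake is minimized in a
    second lexicographic pass.
    """
    sub_ex, sub_carbon = _substrate_exchange(network)
    o2_ex = _o2_exchange(network)
    objective = {sub_ex: F(sub_carbon)}

    fixed_rows: list[tuple[Mapping[str, Fraction], Fraction]] = []
    if fixed_flux is not None:
        fixed_rows.append(({fixed_flux[0]: F(1)}, F(fixed_flux[1])))
    if product_row is not None:
        fixed_rows.append((product_row, F(1)))
    if not fixed_rows:
        raise ValueError("need a demand: fixed_flux or product_row")

    ub = {}
    closed = set(closed)
    if o2_bound is not None and o2_ex is not None:
        if o2_bound == 0:
            closed.add(o2_ex)
        else:
            ub[o2_ex] = o2_bound

    carbon, fluxes = _solve(network, objective, fixed_rows, ub, closed,
                            context=f"o2_bound={o2_bound}")

    o2_cost = F(0)
    if o2_ex is not None and o2_ex not in closed:
        if minimize_o2_secondary:
            rows2 = list(fixed_rows) + [({sub_ex: F(sub_carbon)}, carbon)]
            o2_cost, fluxes = _solve(network, {o2_ex: F(1)}, rows2, ub, closed,
                                     context="secondary O2 minimization")
        else:
            o2_cost = F(fluxes.get(o2_ex, 0.0)).limit_denominator(10**9)
    if o2_cost < 0:
        o2_cost = F(0)
    return LPResult(carbon_cost=carbon, o2_cost=o2_cost, fluxes=fluxes, exact=True)


# ---------------------------------------------------------------------------
# public yield operations


def _resolve_exchange(network: MetabolicNetwork, product) -> tuple[str, str, int]:
    """-> (exchange id, display id, carbon count)"""
    from .products import ProductSpec

    if isinstance(product, ProductSpec):
        ex = product.exchange_id
        if ex not in network.reactions:
            raise NetworkError(f"product {product.name} not attached to this network")
        return ex, product.name, product.formula.C
    ex = product if str(product).startswith("EX_") else f"EX_{product}"
    if ex not in network.reactions:
        raise NetworkError(f"no exchange {ex!r} in network")
    (met_id, _), = network.reactions[ex].stoichiometry.items()
    return ex, str(product), network.metabolites[met_id].formula.C


def isolation_closures(
    network: MetabolicNetwork, keep_open: Iterable[str]
) -> set[str]:
    """Exchanges to close when simulating a product (group) in isolation:
    every FH product exchange except ``keep_open``; declared non-FH
    byproducts (CO2, water, formate, acetate, acetaldehyde, ethanol) and
    nutrient/O2/substrate exchanges stay open."""
    keep = set(keep_open)
    return {rid for rid in _product_exchanges(network) if rid not in keep}


def min_carbon_cost(
    network: MetabolicNetwork,
    product,
    o2_bound: Fraction | None = None,
    isolation: bool = True,
    extra_open: Iterable[str] = (),
    condition: str | None = None,
    intervention: str = "WT",
    minimize_o2: bool = True,
) -> YieldPoint:
    """LP minimum substrate Cmol per Cmol of exported product.

    With ``isolation`` (the default, matching the grouped scans) all other
    FH exchanges are closed; ``extra_open`` can re-open specific ones
    (e.g. the coproduct of a linoleic cleavage).  Raises
    :class:`InfeasibleError` with context if the product cannot be made
    under the O2 bound (e.g. aromatic products at O2 = 0).
    """
    ex, name, carbon = _resolve_exchange(network, product)
    closed = isolation_closures(network, [ex, *extra_open]) if isolation else set()
    res = minimize_substrate(
        network,
        product_row={ex: F(carbon)},
        o2_bound=o2_bound,
        closed=closed,
        minimize_o2_secondary=minimize_o2,
    )
    cond = condition or ("o2_limited" if o2_bound == 0 else "carbon_limited")
    return YieldPoint(product_id=name, carbon_cost=res.carbon_cost,
                      o2_cost=res.o2_cost, condition=cond, intervention=intervention)


def tradeoff_curve(
    network: MetabolicNetwork,
    product,
    o2_grid: Sequence[Fraction],
    isolation: bool = True,
    extra_open: Iterable[str] = (),
    intervention: str = "WT",
    minimize_o2: bool = True,
) -> list[YieldPoint]:
    """One YieldPoint per O2 bound (grid sorted ascending); points where the
    bound makes the product infeasible carry ``carbon_cost=None`` markers
    via exclusion (they are skipped, matching per-gridpoint propagation)."""
    if list(o2_grid) != sorted(o2_grid):
        raise ValueError("o2 grid must be sorted ascending")
    points = []
    for bound in o2_grid:
        try:
            pt = min_carbon_cost(network, product, o2_bound=F(bound),
                                 isolation=isolation, extra_open=extra_open,
                                 condition="gridpoint", intervention=intervention,
                                 minimize_o2=minimize_o2)
        except InfeasibleError:
            continue
        points.append(YieldPoint(
            product_id=pt.product_id, carbon_cost=pt.carbon_cost, o2_cost=pt.o2_cost,
            condition=pt.condition, intervention=pt.intervention,
            extras={"o2_bound": F(bound)},
        ))
    return points


def efm_yield_cloud(
    modes: Iterable[FluxMode],
    network: MetabolicNetwork,
    product,
) -> list[YieldPoint]:
    """Per-EFM cost coordinates; modes with zero product flux are excluded.

    ``product`` may be an exchange id or an internal demand reaction id
    (the ATP demand).  The network must be the one the modes came from
    (same reaction ids; exchanges are irreversible there, so split ids
    coincide)."""
    sub_ex, sub_carbon = _substrate_exchange(network)
    o2_ex = _o2_exchange(network)
    if product in network.reactions and product not in network.exchange_ids:
        prod_ids = {product: F(1)}
        name = product
    else:
        ex, name, carbon = _resolve_exchange(network, product)
        prod_ids = {ex: F(carbon)}
    points = []
    for mode in modes:
        prod = sum((F(w) * mode.rates.get(rid, F(0)) for rid, w in prod_ids.items()), F(0))
        if prod == 0:
            continue
        sub = mode.rates.get(sub_ex, F(0)) * sub_carbon
        o2 = mode.rates.get(o2_ex, F(0)) if o2_ex else F(0)
        points.append(YieldPoint(
            product_id=name, carbon_cost=sub / prod, o2_cost=o2 / prod,
            condition="efm",
        ))
    return points


def pareto_front(points: Iterable[YieldPoint]) -> list[YieldPoint]:
    """Non-dominated subset under (carbon_cost, o2_cost) minimization,
    sorted by carbon cost; ties kept."""
    pts = list(points)
    front = []
    for p in pts:
        dominated = any(
            (q.carbon_cost <= p.carbon_cost and q.o2_cost <= p.o2_cost)
            and (q.carbon_cost < p.carbon_cost or q.o2_cost < p.o2_cost)
            for q in pts
        )
        if not dominated:
            front.append(p)
    return sorted(front, key=lambda p: (p.carbon_cost, p.o2_cost))


def group_min_cost(
    network: MetabolicNetwork,
    members,
    o2_bound: Fraction | None = None,
    intervention: str = "WT",
    extra_open: Iterable[str] = (),
) -> YieldPoint:
    """Minimum cost over a functional group, each member simulated in
    isolation (only that member's exchange plus the declared non-FH
    byproducts open).  Members infeasible under the bound are skipped; if
    none is feasible, :class:`InfeasibleError` is raised."""
    best: YieldPoint | None = None
    for p in members:
        try:
            pt = min_carbon_cost(network, p, o2_bound=o2_bound,
                                 extra_open=extra_open, intervention=intervention)
        except InfeasibleError:
            continue
        if best is None or (pt.carbon_cost, pt.o2_cost) < (best.carbon_cost, best.o2_cost):
            best = pt
    if best is None:
        raise InfeasibleError(
            f"no group member feasible under o2_bound={o2_bound}"
        )
    cond = "o2_limited" if o2_bound == 0 else "carbon_limited"
    return YieldPoint(product_id=best.product_id, carbon_cost=best.carbon_cost,
                      o2_cost=best.o2_cost, condition=cond, intervention=intervention)


def group_scan(
    substrate=None,
    interventions: Sequence | None = None,
    groups: Sequence[str] | None = None,
):
    """Minimum carbon (and O2 at the carbon optimum) per functional group
    and strain, under carbon-limited (O2 unlimited) and O2-limited
    (O2 = 0) conditions.  Returns a pandas DataFrame.
    """
    import pandas as pd

    from .core_model import (CELLOPENTAOSE, InterventionConfig, build_core_model)
    from .products import FUNCTIONAL_GROUPS, build_default_registry

    substrate = substrate or CELLOPENTAOSE
    if interventions is None:
        interventions = [
            InterventionConfig(False, False),
            InterventionConfig(True, False),
            InterventionConfig(False, True),
            InterventionConfig(True, True),
        ]
    groups = list(groups or FUNCTIONAL_GROUPS)
    registry = build_default_registry()
    by_group: dict[str, list] = {}
    for p in registry.products:
        by_group.setdefault(p.functional_group, []).append(p)

    rows = []
    for cfg in interventions:
        net = build_core_model(substrate=substrate, interventions=cfg)
        for group in groups:
            members = by_group.get(group, [])
            entry = {"group": group, "strain": cfg.label}
            try:
                pt = group_min_cost(net, members, o2_bound=None, intervention=cfg.label)
                entry["carbon_limited"] = pt.carbon_cost
                entry["o2_at_optimum"] = pt.o2_cost
            except InfeasibleError:
                entry["carbon_limited"] = None
                entry["o2_at_optimum"] = None
            try:
                pt0 = group_min_cost(net, members, o2_bound=F(0), intervention=cfg.label)
                entry["o2_limited"] = pt0.carbon_cost
            except InfeasibleError:
                entry["o2_limited"] = None
            rows.append(entry)
    return pd.DataFrame(rows)


def electron_bound(product_formula, substrate_formula) -> Fraction:
    """Anoxic electron-balance lower bound on carbon cost (gamma ratio)."""
    return degree_of_reduction(product_formula) / degree_of_reduction(substrate_formula)
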