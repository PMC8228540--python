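"""Elementary flux mode enumeration with exact rational arithmetic.

An elementary flux mode (EFM) is a steady-state, support-minimal flux
vector of an irreversible (split) network: ``S v = 0``, ``v >= 0``, and no
other steady-state nonnegative vector has strictly contained support.
Every steady-state flux distribution is a nonnegative combination of EFMs,
which is what makes the full mode set a complete description of the
network's capabilities.

The enumerator is a double-description pass over the rows of the internal
stoichiometric matrix: rays start as the unit vectors of the nonnegative
orthant, each metabolite balance constraint splits them into
zero/positive/negative classes, and adjacent positive/negative pairs are
combined into new rays.  Adjacency is decided by the combinatorial
zero-set test.  Row order is chosen greedily to minimize the number of
generated candidates.  Arithmetic is exact (``fractions.Fraction``); the
returned modes are canonical primitive integer vectors.

A brute-force subset enumerator (:func:`brute_force_efms`) serves as an
independent oracle on small networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import reduce
from math import gcd
from typing import Iterable, Mapping, Sequence

from .linalg import nullspace, rref
from .network import MetabolicNetwork, NetworkError, build_matrix, split_reversible

REV_SUFFIX = "__rev"


class EFMOverflowError(RuntimeError):
    """Raised when intermediate ray count exceeds the configured cap."""

    def __init__(self, n_rays: int, cap: int):
        self.n_rays = n_rays
        self.cap = cap
        super().__init__(
            f"EFM enumeration exceeded the cap: {n_rays} intermediate rays > {cap}; "
            "enumerate a reduced configuration or raise max_rays"
        )


@dataclass(frozen=True)
class FluxMode:
    """One EFM on the split (all-irreversible) network."""

    rates: Mapping[str, Fraction]
    support: frozenset[str]

    @classmethod
    def from_vector(cls, vec: Sequence[Fraction], rxn_ids: Sequence[str]) -> "FluxMode":
        rates = {rid: Fraction(v) for rid, v in zip(rxn_ids, vec) if v != 0}
        return cls(rates=rates, support=frozenset(rates))

    def canonical(self) -> "FluxMode":
        """Scale to the primitive integer representative (positive, gcd 1)."""
        if not self.rates:
            return self
        denom_lcm = reduce(lambda a, b: a * b // gcd(a, b), (r.denominator for r in self.rates.values()), 1)
        ints = {k: int(v * denom_lcm) for k, v in self.rates.items()}
        g = reduce(gcd, (abs(v) for v in ints.values()))
        return FluxMode(
            rates={k: Fraction(v, g) for k, v in ints.items()},
            support=self.support,
        )

    def scaled(self, factor: Fraction) -> "FluxMode":
        if factor <= 0:
            raise ValueError("scaling factor must be positive")
        return FluxMode(
            rates={k: v * factor for k, v in self.rates.items()}, support=self.support
        )

    def support_key(self) -> tuple[str, ...]:
        return tuple(sorted(self.support))

    def __eq__(self, other) -> bool:
        if not isinstance(other, FluxMode):
            return NotImplemented
        return dict(self.canonical().rates) == dict(other.canonical().rates)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.canonical().rates.items())))


@dataclass(frozen=True)
class ExclusionRuleSet:
    """Named groups of mutually exclusive reactions (gene regulatory rules)."""

    groups: Mapping[str, frozenset[str]]

    @classmethod
    def from_dict(cls, groups: Mapping[str, Iterable[str]]) -> "ExclusionRuleSet":
        return cls(groups={g: frozenset(m) for g, m in groups.items()})

    @classmethod
    def from_network(cls, network: MetabolicNetwork) -> "ExclusionRuleSet":
        groups: dict[str, set[str]] = {}
        for rxn in network.reactions.values():
            if rxn.exclusion_group:
                groups.setdefault(rxn.exclusion_group, set()).add(rxn.id)
        return cls.from_dict(groups)

    def validate(self, network: MetabolicNetwork) -> None:
        known = set(network.reactions)
        # split networks carry both halves; accept either spelling
        known |= {rid + REV_SUFFIX for rid in network.reactions}
        for g, members in self.groups.items():
            missing = {m for m in members if m not in known}
            if missing:
                raise NetworkError(f"exclusion group {g!r} lists unknown reactions {sorted(missing)}")


def _is_two_cycle(support: frozenset[str]) -> bool:
    if len(support) != 2:
        return False
    a, b = sorted(support)
    return b == a + REV_SUFFIX


def _uses_both_directions(support: frozenset[str]) -> bool:
    return any(
        rid.endswith(REV_SUFFIX) and rid[: -len(REV_SUFFIX)] in support for rid in support
    )


def _prepare(network: MetabolicNetwork) -> tuple[MetabolicNetwork, dict]:
    if any(r.reversible for r in network.reactions.values()):
        return split_reversible(network)
    return network, {}


def _sorted_modes(modes: Iterable[FluxMode]) -> list[FluxMode]:
    return sorted(modes, key=lambda m: m.support_key())


def enumerate_efms(
    network: MetabolicNetwork,
    max_rays: int = 5_000_000,
) -> list[FluxMode]:
    """All elementary flux modes of ``network``.

    Reversible reactions are split first if present; two-cycle modes
    (forward+backward of one reversible reaction) are discarded.  Modes are
    returned in canonical primitive-integer form, deterministically ordered
    by sorted support.  Raises :class:`EFMOverflowError` naming the
    intermediate ray count if ``max_rays`` is exceeded.
    """
    split, _ = _prepare(network)
    S, _met_ids, rxn_ids = build_matrix(split)
    n = len(rxn_ids)

    # rays as coefficient vectors; zero-sets tracked as frozensets of indices
    rays: list[list[Fraction]] = [
        [Fraction(int(i == j)) for j in range(n)] for i in range(n)
    ]
    remaining = [row for row in S if any(x != 0 for x in row)]

    while remaining:
        # fewest-generated-candidates heuristic: pick the row minimizing
        # |pos| * |neg| over the current ray set
        best = None
        for k, row in enumerate(remaining):
            npos = nneg = 0
            for ray in rays:
                d = sum(c * r for c, r in zip(row, ray) if r != 0)
                if d > 0:
                    npos += 1
                elif d < 0:
                    nneg += 1
            cost = npos * nneg
            if best is None or cost < best[0]:
                best = (cost, k)
        _, k = best
        row = remaining.pop(k)

        dots = [sum(c * r for c, r in zip(row, ray) if r != 0) for ray in rays]
        zero = [ray for ray, d in zip(rays, dots) if d == 0]
        pos = [(ray, d) for ray, d in zip(rays, dots) if d > 0]
        neg = [(ray, d) for ray, d in zip(rays, dots) if d < 0]

        supports = [frozenset(i for i, v in enumerate(ray) if v != 0) for ray in rays]
        sup_by_id = {id(ray): s for ray, s in zip(rays, supports)}
        all_sups = supports

        new_rays = list(zero)
        for rp, dp in pos:
            sp = sup_by_id[id(rp)]
            for rn, dn in neg:
                sn = sup_by_id[id(rn)]
                union = sp | sn
                # combinatorial adjacency test
                adjacent = True
                for s in all_sups:
                    if s is sp or s is sn:
                        continue
                    if s <= union and s != sp and s != sn:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                combo = [dp * b - dn * a for a, b in zip(rp, rn)]
                # dp > 0, dn < 0: combo = dp*rn + |dn|*rp >= 0
                new_rays.append(combo)
                if len(new_rays) > max_rays:
                    raise EFMOverflowError(len(new_rays), max_rays)
        # canonicalize and deduplicate (degenerate pivots can repeat a ray)
        uniq: dict[tuple, list[Fraction]] = {}
        for r in new_rays:
            p = _primitive(r)
            uniq[tuple(p)] = p
        rays = list(uniq.values())
        if len(rays) > max_rays:
            raise EFMOverflowError(len(rays), max_rays)

    modes = [FluxMode.from_vector(r, rxn_ids) for r in rays if any(x != 0 for x in r)]
    modes = [m.canonical() for m in modes if not _is_two_cycle(m.support)]
    return _sorted_modes(modes)


def _primitive(vec: list[Fraction]) -> list[Fraction]:
    nz = [v for v in vec if v != 0]
    if not nz:
        return vec
    denom_lcm = reduce(lambda a, b: a * b // gcd(a, b), (v.denominator for v in nz), 1)
    ints = [int(v * denom_lcm) for v in vec]
    g = reduce(gcd, (abs(v) for v in ints if v != 0))
    return [Fraction(v, g) for v in ints]


def brute_force_efms(network: MetabolicNetwork, max_reactions: int = 16) -> list[FluxMode]:
    """Independent EFM oracle by exhaustive support enumeration.

    Considers every reaction subset, keeps supports whose restricted kernel
    is one-dimensional with a strictly positive generator, then filters to
    support-minimal sets.  Exponential in the reaction count; guarded by
    ``max_reactions``.
    """
    split, _ = _prepare(network)
    S, _met_ids, rxn_ids = build_matrix(split)
    n = len(rxn_ids)
    if n > max_reactions:
        raise NetworkError(
            f"brute-force oracle limited to {max_reactions} reactions, got {n}"
        )

    candidates: list[tuple[frozenset[int], list[Fraction]]] = []
    for mask in range(1, 1 << n):
        idx = [j for j in range(n) if mask >> j & 1]
        sub = [[row[j] for j in idx] for row in S]
        basis = nullspace(sub, ncols=len(idx))
        if len(basis) != 1:
            continue
        gen = basis[0]
        if all(v > 0 for v in gen):
            vec = gen
        elif all(v < 0 for v in gen):
            vec = [-v for v in gen]
        else:
            continue
        candidates.append((frozenset(idx), vec))

    minimal = []
    for sup, vec in candidates:
        if not any(other < sup for other, _ in candidates):
            minimal.append((sup, vec))

    modes = []
    for sup, vec in minimal:
        full = [Fraction(0)] * n
        for pos_in_sub, j in enumerate(sorted(sup)):
            full[j] = vec[pos_in_sub]
        mode = FluxMode.from_vector(full, rxn_ids).canonical()
        if not _is_two_cycle(mode.support):
            modes.append(mode)
    return _sorted_modes(modes)


def is_elementary(vector: Mapping[str, Fraction], network: MetabolicNetwork) -> bool:
    """True iff the steady-state vector's support carries a 1-dimensional kernel.

    ``vector`` maps reaction ids of the split network to nonnegative rates.
    Raises on inputs that are not steady-state or have negative entries.
    The zero vector is not elementary by convention.
    """
    split, _ = _prepare(network)
    S, _met_ids, rxn_ids = build_matrix(split)
    col = {rid: j for j, rid in enumerate(rxn_ids)}
    v = [Fraction(0)] * len(rxn_ids)
    for rid, rate in vector.items():
        if rid not in col:
            raise NetworkError(f"unknown reaction {rid!r}")
        if Fraction(rate) < 0:
            raise NetworkError("flux vector must be nonnegative on the split network")
        v[col[rid]] = Fraction(rate)
    for row in S:
        if sum(c * x for c, x in zip(row, v) if x != 0) != 0:
            raise NetworkError("input vector is not at steady state (S v != 0)")
    sup = [j for j, x in enumerate(v) if x != 0]
    if not sup:
        return False
    sub = [[row[j] for j in sup] for row in S]
    return len(nullspace(sub, ncols=len(sup))) == 1


def filter_by_exclusion_rules(
    modes: Iterable[FluxMode],
    rules: ExclusionRuleSet,
    network: MetabolicNetwork | None = None,
) -> list[FluxMode]:
    """Drop modes whose support holds two or more members of one group."""
    if network is not None:
        rules.validate(network)
    out = []
    for mode in modes:
        bare = {rid[: -len(REV_SUFFIX)] if rid.endswith(REV_SUFFIX) else rid for rid in mode.support}
        if any(len(members & bare) >= 2 for members in rules.groups.values()):
            continue
        out.append(mode)
    return out


def normalize_mode(
    mode: FluxMode,
    reference: str,
    network: MetabolicNetwork | None = None,
) -> FluxMode:
    """Scale a mode so the reference flux is 1.

    ``reference`` is a reaction id, or ``"unit-substrate"`` to scale the
    substrate uptake to 1 Cmol (requires ``network``; the substrate exchange
    is the exchange reaction tagged ``pathway_tag == "substrate"``).
    """
    if reference == "unit-substrate":
        if network is None:
            raise ValueError("unit-substrate normalization requires the network")
        sub_ids = [
            rid
            for rid, rxn in network.reactions.items()
            if network.is_exchange(rid) and rxn.pathway_tag == "substrate"
        ]
        active = [rid for rid in sub_ids if rid in mode.rates]
        if not active:
            raise NetworkError("no substrate exchange active in this mode")
        cmol = Fraction(0)
        for rid in active:
            (met_id, coeff), = network.reactions[rid].stoichiometry.items()
            carbon = network.metabolites[met_id].formula.C
            cmol += mode.rates[rid] * abs(coeff) * carbon
        return mode.scaled(1 / cmol)
    if reference not in mode.rates:
        raise NetworkError(f"reference reaction {reference!r} not in mode support")
    return mode.scaled(1 / mode.rates[reference])
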