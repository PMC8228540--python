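"""Model and report file formats.

The model TSV dialect is a single tab-separated file with two sections:

.. code-block:: text

    # ascoflux model v1
    # name: asco_core[cellopentaose,WT]
    [metabolites]
    id\tname\tcompartment\tformula
    glc[c]\tglucose\tcytosol\tC6H12O6
    [reactions]
    id\tequation\treversible\tpathway\texclusion_group\texchange
    hxk\t1 glc[c] + 1 atp[c] -> 1 g6p[c] + 1 adp[c]\t0\tglycolysis\t\t0

Compartments appear as bracket suffixes (``[e]``, ``[c]``, ``[m]``);
coefficients are exact fraction strings (``7/6``), so write-then-read is
the identity on the in-memory representation.  Report CSVs render
decimals instead and carry a provenance header.
"""

from __future__ import annotations

import csv
import re
from fractions import Fraction
from pathlib import Path
from typing import Iterable

from .formula import Formula
from .network import (
    COMPARTMENT_SUFFIX,
    SUFFIX_COMPARTMENT,
    MetabolicNetwork,
    Metabolite,
    Reaction,
)


class ModelParseError(ValueError):
    """Malformed model file; message carries the line number."""


_TERM = re.compile(r"^\s*(?:(\d+(?:/\d+)?|\d*\.\d+)\s+)?([A-Za-z0-9_\-,']+)\[([a-z])\]\s*$")


def _ext_id(met: Metabolite) -> str:
    suffix = COMPARTMENT_SUFFIX[met.compartment]
    base = met.id
    if base.endswith("_" + suffix):
        base = base[: -(len(suffix) + 1)]
    return f"{base}[{suffix}]"


def _int_id(token: str, line_no: int) -> str:
    m = _TERM.match(token)
    if not m:
        raise ModelParseError(f"line {line_no}: cannot parse term {token!r}")
    coeff, base, suffix = m.groups()
    if suffix not in SUFFIX_COMPARTMENT:
        raise ModelParseError(f"line {line_no}: unknown compartment suffix [{suffix}]")
    return f"{base}_{suffix}"


def parse_equation(equation: str, line_no: int = 0) -> tuple[dict[str, Fraction], bool]:
    """Parse ``1 a[c] + 1/2 b[c] -> 1 c[c]`` into stoichiometry.

    Returns (stoichiometry, reversible-from-arrow).  A side may be empty
    (exchange reactions).
    """
    arrow_rev = "<->" in equation
    sep = "<->" if arrow_rev else "->"
    if sep not in equation:
        raise ModelParseError(f"line {line_no}: no arrow in equation {equation!r}")
    lhs, rhs = equation.split(sep, 1)
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            m = _TERM.match(term)
            if not m:
                raise ModelParseError(f"line {line_no}: cannot parse term {term!r}")
            coeff_s, base, suffix = m.groups()
            if suffix not in SUFFIX_COMPARTMENT:
                raise ModelParseError(
                    f"line {line_no}: unknown compartment suffix [{suffix}]"
                )
            coeff = Fraction(coeff_s) if coeff_s else Fraction(1)
            mid = f"{base}_{suffix}"
            stoich[mid] = stoich.get(mid, Fraction(0)) + sign * coeff
    add_side(lhs, -1)
    add_side(rhs, +1)
    stoich = {k: v for k, v in stoich.items() if v != 0}
    if not stoich:
        raise ModelParseError(f"line {line_no}: equation cancels to nothing")
    return stoich, arrow_rev


def format_equation(rxn: Reaction, network: MetabolicNetwork) -> str:
    def fmt(side: dict[str, Fraction]) -> str:
        parts = []
        for mid, coeff in side.items():
            met = network.metabolites[mid]
            parts.append(f"{coeff} {_ext_id(met)}")
        return " + ".join(parts)

    arrow = "<->" if rxn.reversible else "->"
    return f"{fmt(rxn.substrates)} {arrow} {fmt(rxn.products)}".strip()


def write_model(path: str | Path, network: MetabolicNetwork, header_lines: Iterable[str] = ()) -> None:
    path = Path(path)
    lines = ["# ascoflux model v1", f"# name: {network.name}"]
    lines += [f"# {h}" for h in header_lines]
    lines.append("[metabolites]")
    lines.append("id\tname\tcompartment\tformula")
    for met in network.metabolites.values():
        lines.append(f"{_ext_id(met)}\t{met.name}\t{met.compartment}\t{met.formula}")
    lines.append("[reactions]")
    lines.append("id\tequation\treversible\tpathway\texclusion_group\texchange")
    for rxn in network.reactions.values():
        lines.append(
            "\t".join([
                rxn.id,
                format_equation(rxn, network),
                "1" if rxn.reversible else "0",
                rxn.pathway_tag,
                rxn.exclusion_group or "",
                "1" if network.is_exchange(rxn.id) else "0",
            ])
        )
    path.write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> MetabolicNetwork:
    path = Path(path)
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    exchanges: set[str] = set()
    name = path.stem
    section = None
    header: list[str] | None = None
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("# name:"):
                name = line.split(":", 1)[1].strip()
            continue
        if line.startswith("["):
            section = line.strip("[] ")
            header = None
            continue
        cols = line.split("\t")
        if header is None:
            header = cols
            continue
        row = dict(zip(header, cols))
        if section == "metabolites":
            mid = _int_id(row["id"], line_no)
            comp_suffix = row["id"].rsplit("[", 1)[1].rstrip("]")
            mets.append(Metabolite(
                id=mid,
                name=row.get("name", mid),
                compartment=SUFFIX_COMPARTMENT[comp_suffix],
                formula=Formula.parse(row["formula"]),
            ))
        elif section == "reactions":
            stoich, arrow_rev = parse_equation(row["equation"], line_no)
            reversible = row.get("reversible", "0") == "1" or arrow_rev
            rxns.append(Reaction(
                id=row["id"],
                stoichiometry=stoich,
                reversible=reversible,
                pathway_tag=row.get("pathway", ""),
                exclusion_group=row.get("exclusion_group") or None,
            ))
            if row.get("exchange", "0") == "1" or (
                "exchange" not in row and len(stoich) == 1
            ):
                exchanges.add(row["id"])
        else:
            raise ModelParseError(f"line {line_no}: content outside a section")
    return MetabolicNetwork(mets, rxns, exchanges, name=name)


# ---------------------------------------------------------------------------
# report writers


def write_modes_csv(path: str | Path, modes, reaction_ids: list[str] | None = None,
                    header_lines: Iterable[str] = ()) -> None:
    """Wide CSV: one row per mode, one column per reaction (decimal)."""
    modes = list(modes)
    if reaction_ids is None:
        reaction_ids = sorted({rid for m in modes for rid in m.support})
    path = Path(path)
    with path.open("w", newline="") as fh:
        for h in header_lines:
            fh.write(f"# {h}\n")
        w = csv.writer(fh)
        w.writerow(["mode", *reaction_ids])
        for i, m in enumerate(modes):
            w.writerow([i, *[float(m.rates.get(rid, 0)) for rid in reaction_ids]])


def write_supports_csv(path: str | Path, modes, header_lines: Iterable[str] = ()) -> None:
    """Compact support-only CSV: one row per mode."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        for h in header_lines:
            fh.write(f"# {h}\n")
        w = csv.writer(fh)
        w.writerow(["mode", "support"])
        for i, m in enumerate(modes):
            w.writerow([i, "|".join(sorted(m.support))])


def write_registry_csv(path: str | Path, products, header_lines: Iterable[str] = ()) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for h in header_lines:
            fh.write(f"# {h}\n")
        w = csv.writer(fh)
        w.writerow(["name", "class", "group", "chain_length", "formula", "gamma", "initiator"])
        for p in products:
            w.writerow([p.name, p.product_class, p.functional_group, p.chain_length,
                        str(p.formula), float(p.gamma), p.initiator])


def write_yield_csv(path: str | Path, points, header_lines: Iterable[str] = ()) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for h in header_lines:
            fh.write(f"# {h}\n")
        w = csv.writer(fh)
        w.writerow(["product", "carbon_cost", "o2_cost", "condition", "intervention"])
        for p in points:
            w.writerow([p.product_id, float(p.carbon_cost),
                        float(p.o2_cost) if p.o2_cost is not None else "",
                        p.condition, p.intervention])


# ---------------------------------------------------------------------------
# optional SBML Level 3 export


def write_sbml(path: str | Path, network: MetabolicNetwork) -> None:
    """SBML Level 3 (core) export; requires python-libsbml."""
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("SBML export requires python-libsbml") from exc

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId(re.sub(r"\W", "_", network.name))
    comps = {}
    for key in ("extracellular", "cytosol", "mitochondria"):
        c = model.createCompartment()
        c.setId(key[0] if key != "mitochondria" else "m")
        c.setName(key)
        c.setConstant(True)
        comps[key] = c.getId()
    for met in network.metabolites.values():
        s = model.createSpecies()
        s.setId("M_" + met.id)
        s.setName(met.name)
        s.setCompartment(comps[met.compartment])
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
    for rxn in network.reactions.values():
        r = model.createReaction()
        r.setId("R_" + rxn.id)
        r.setReversible(rxn.reversible)
        for mid, coeff in rxn.stoichiometry.items():
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies("M_" + mid)
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(path))
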