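"""Parameterized core reconstruction of *A. sarcoides* central metabolism.

The builder assembles a three-compartment (extracellular / cytosol /
mitochondria) stoichiometric network covering: ABC uptake of glucose or
cellopentaose (one ATP per transport event regardless of oligosaccharide
length), phosphate-independent intracellular hydrolysis of cellopentaose,
hexokinase activation, glycolysis, the pentose phosphate pathway,
mitochondrial pyruvate dehydrogenase (no cytosolic Pdc: the enzyme is not
in this genome), the TCA cycle, lumped oxidative phosphorylation
parameterized by P/O ratios, fermentative branches (acetaldehyde/ethanol,
acetate via acetyl-CoA hydrolase, a reversible formate dehydrogenase as
the formate electron sink), the two cytosolic acetyl-CoA delivery routes
(ATP-citrate lyase on exported citrate; acetate export plus cytosolic
acetyl-CoA synthetase at two ATP equivalents), amino-acid precursor
branches for the seven Ehrlich donors, the threonine-family route to
2-oxobutanoate and propanoyl-CoA, cytosolic fatty-acid synthesis with
O2-dependent desaturation to linoleate, and a lumped biomass equation
whose lipid term makes growth strictly O2-dependent.

Two engineering knock-ins are modeled: cellobiose phosphorylase (CP),
which phosphorolyzes four of the five glucosyl units of cellopentaose to
glucose-1-phosphate using inorganic phosphate (sparing the hexokinase
ATP), and a cytosolic pyruvate dehydrogenase (PDHcyt), which uncouples
cytosolic acetyl-CoA supply from the transport energetics.

Amino-acid scaffold branches are lumped to redox-level stoichiometry
(their kinase-step ATP charges are not itemized); see docs/methods.md for
the reasoning and consequences.  All reactions are element-balanced over
C/H/O/N/S/P, which the builder re-verifies on every build.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

from .formula import Formula
from .network import MetabolicNetwork, Metabolite, NetworkError, Reaction, validate_network
from . import yields as _yields

F = Fraction


@dataclass(frozen=True)
class EnergyParams:
    """ATP accounting knobs (all rational, all >= 0).

    P/O ratios are ATP per cofactor oxidized: 2.5 for mitochondrial NADH,
    1.5 for FADH2 and for cytosolic NADH (glycerol-3-phosphate shuttle,
    electrons enter at the FADH2 level).  ``abc_transport_atp`` is ATP per
    transported molecule, identical for glucose and cellopentaose.
    """

    po_nadh_mito: Fraction = F(5, 2)
    po_fadh2: Fraction = F(3, 2)
    po_nadh_cyt: Fraction = F(3, 2)
    abc_transport_atp: Fraction = F(1)
    maintenance_atp: Fraction = F(0)

    def __post_init__(self) -> None:
        for name in ("po_nadh_mito", "po_fadh2", "po_nadh_cyt", "abc_transport_atp", "maintenance_atp"):
            v = Fraction(getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class InterventionConfig:
    cellobiose_phosphorylase: bool = False
    pdh_cytosolic: bool = False

    @property
    def label(self) -> str:
        parts = []
        if self.cellobiose_phosphorylase:
            parts.append("CP")
        if self.pdh_cytosolic:
            parts.append("PDHcyt")
        return "WT" + ("+" + "+".join(parts) if parts else "")


WT = InterventionConfig()


@dataclass(frozen=True)
class SubstrateSpec:
    name: str
    cmol_per_molecule: int

    def __post_init__(self) -> None:
        allowed = {"glucose": 6, "cellopentaose": 30}
        if self.name not in allowed or allowed[self.name] != self.cmol_per_molecule:
            raise ValueError(f"unsupported substrate {self.name}/{self.cmol_per_molecule}")


GLUCOSE = SubstrateSpec("glucose", 6)
CELLOPENTAOSE = SubstrateSpec("cellopentaose", 30)

BIOMASS_FORMULA = Formula(C=48, H=86, O=24, N=10)

#: byproducts whose exchanges stay open when a product group is simulated
#: in isolation (declared non-FH)
BYPRODUCT_EXCHANGES = ("EX_co2", "EX_h2o", "EX_formate", "EX_acetate", "EX_acald", "EX_etoh")


def _mets_catalog(substrate: SubstrateSpec) -> list[Metabolite]:
    C, M, E = "cytosol", "mitochondria", "extracellular"

    def m(mid, name, comp, formula):
        return Metabolite(id=mid, name=name, compartment=comp, formula=Formula.parse(formula))

    mets = [
        # cofactors & small species (cytosolic pools; gases/water cytosol-only)
        m("atp_c", "ATP", C, "C10H16N5O13P3"),
        m("adp_c", "ADP", C, "C10H15N5O10P2"),
        m("pi_c", "phosphate", C, "H3O4P"),
        m("nad_c", "NAD+", C, "C21H27N7O14P2"),
        m("nadh_c", "NADH", C, "C21H29N7O14P2"),
        m("nadp_c", "NADP+", C, "C21H28N7O17P3"),
        m("nadph_c", "NADPH", C, "C21H30N7O17P3"),
        m("coa_c", "coenzyme A", C, "C21H36N7O16P3S"),
        m("accoa_c", "acetyl-CoA", C, "C23H38N7O17P3S"),
        m("malcoa_c", "malonyl-CoA", C, "C24H38N7O19P3S"),
        m("prcoa_c", "propanoyl-CoA", C, "C24H40N7O17P3S"),
        m("co2_c", "CO2", C, "CO2"),
        m("o2_c", "O2", C, "O2"),
        m("h2o_c", "water", C, "H2O"),
        m("nh3_c", "ammonia", C, "NH3"),
        m("h2o2_c", "hydrogen peroxide", C, "H2O2"),
        m("h2so4_c", "sulfate", C, "H2SO4"),
        m("h2s_c", "hydrogen sulfide", C, "H2S"),
        m("formate_c", "formate", C, "CH2O2"),
        m("acetate_c", "acetate", C, "C2H4O2"),
        m("acald_c", "acetaldehyde", C, "C2H4O"),
        m("etoh_c", "ethanol", C, "C2H6O"),
        # glycolysis / PPP
        m("glc_c", "glucose", C, "C6H12O6"),
        m("g6p_c", "glucose-6-phosphate", C, "C6H13O9P"),
        m("f6p_c", "fructose-6-phosphate", C, "C6H13O9P"),
        m("fbp_c", "fructose-1,6-bisphosphate", C, "C6H14O12P2"),
        m("g3p_c", "glyceraldehyde-3-phosphate", C, "C3H7O6P"),
        m("pg3_c", "3-phosphoglycerate", C, "C3H7O7P"),
        m("pep_c", "phosphoenolpyruvate", C, "C3H5O6P"),
        m("pyr_c", "pyruvate", C, "C3H4O3"),
        m("ru5p_c", "ribulose-5-phosphate", C, "C5H11O8P"),
        m("r5p_c", "ribose-5-phosphate", C, "C5H11O8P"),
        m("x5p_c", "xylulose-5-phosphate", C, "C5H11O8P"),
        m("e4p_c", "erythrose-4-phosphate", C, "C4H9O7P"),
        m("s7p_c", "sedoheptulose-7-phosphate", C, "C7H15O10P"),
        # anaplerosis / cytosolic acetyl-CoA delivery
        m("oaa_c", "oxaloacetate", C, "C4H4O5"),
        m("cit_c", "citrate", C, "C6H8O7"),
        # amino-acid / Ehrlich precursors (cytosol)
        m("akg_c", "2-oxoglutarate", C, "C5H6O5"),
        m("glu_c", "glutamate", C, "C5H9NO4"),
        m("oxb_c", "2-oxobutanoate", C, "C4H6O3"),
        m("mtob_c", "4-methylthio-2-oxobutanoate", C, "C5H8O3S"),
        m("chor_c", "chorismate", C, "C10H10O6"),
        m("ppy_c", "phenylpyruvate", C, "C9H8O3"),
        m("hpp_c", "4-hydroxyphenylpyruvate", C, "C9H8O4"),
        m("phe_c", "phenylalanine", C, "C9H11NO2"),
        m("tyr_c", "tyrosine", C, "C9H11NO3"),
        m("trp_c", "tryptophan", C, "C11H12N2O2"),
        m("anth_c", "anthranilate", C, "C7H7NO2"),
        m("ser_c", "serine", C, "C3H7NO3"),
        # fatty acids / lipid
        m("acyl18_c", "C18-acyl-CoA", C, "C39H70N7O17P3S"),
        m("linoleoylcoa_c", "linoleoyl-CoA", C, "C39H66N7O17P3S"),
        m("linoleate_c", "linoleate", C, "C18H32O2"),
        m("biomass_c", "biomass", C, "C48H86O24N10"),
        # mitochondria
        m("pyr_m", "pyruvate", M, "C3H4O3"),
        m("coa_m", "coenzyme A", M, "C21H36N7O16P3S"),
        m("accoa_m", "acetyl-CoA", M, "C23H38N7O17P3S"),
        m("nad_m", "NAD+", M, "C21H27N7O14P2"),
        m("nadh_m", "NADH", M, "C21H29N7O14P2"),
        m("fad_m", "FAD", M, "C27H33N9O15P2"),
        m("fadh2_m", "FADH2", M, "C27H35N9O15P2"),
        m("oaa_m", "oxaloacetate", M, "C4H4O5"),
        m("cit_m", "citrate", M, "C6H8O7"),
        m("akg_m", "2-oxoglutarate", M, "C5H6O5"),
        m("succ_m", "succinate", M, "C4H6O4"),
        m("fum_m", "fumarate", M, "C4H4O4"),
        m("mal_m", "malate", M, "C4H6O5"),
        m("acald_m", "acetaldehyde", M, "C2H4O"),
        m("etoh_m", "ethanol", M, "C2H6O"),
        m("acetate_m", "acetate", M, "C2H4O2"),
        m("oxb_m", "2-oxobutanoate", M, "C4H6O3"),
        m("oiv_m", "2-oxoisovalerate", M, "C5H8O3"),
        m("oic_m", "2-oxoisocaproate", M, "C6H10O3"),
        m("omv_m", "2-oxo-3-methylvalerate", M, "C6H10O3"),
    ]
    if substrate.name == "cellopentaose":
        mets += [
            m("cpent_e", "cellopentaose", E, "C30H52O26"),
            m("cpent_c", "cellopentaose", C, "C30H52O26"),
        ]
    else:
        mets += [m("glc_e", "glucose", E, "C6H12O6")]
    return mets


def _core_reactions(substrate: SubstrateSpec, energy: EnergyParams) -> tuple[list[Reaction], set[str]]:
    rxns: list[Reaction] = []
    exchanges: set[str] = set()

    def rx(rid, stoich, reversible=False, tag=""):
        rxns.append(Reaction(id=rid, stoichiometry={k: F(v) for k, v in stoich.items()},
                             reversible=reversible, pathway_tag=tag))

    def ex(rid, met, direction, tag, reversible=False):
        coeff = F(1) if direction == "in" else F(-1)
        rxns.append(Reaction(id=rid, stoichiometry={met: coeff}, reversible=reversible,
                             pathway_tag=tag))
        exchanges.add(rid)

    k = energy.abc_transport_atp

    # --- substrate uptake and activation
    if substrate.name == "cellopentaose":
        ex("EX_sub", "cpent_e", "in", "substrate")
        stoich = {"cpent_e": -1, "cpent_c": 1}
        if k:
            stoich.update({"atp_c": -k, "h2o_c": -k, "adp_c": k, "pi_c": k})
        rx("abc_sub", stoich, tag="transport")
        rx("cpent_hydrolysis", {"cpent_c": -1, "h2o_c": -4, "glc_c": 5}, tag="activation")
    else:
        ex("EX_sub", "glc_e", "in", "substrate")
        stoich = {"glc_e": -1, "glc_c": 1}
        if k:
            stoich.update({"atp_c": -k, "h2o_c": -k, "adp_c": k, "pi_c": k})
        rx("abc_sub", stoich, tag="transport")
    rx("hxk", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1}, tag="glycolysis")

    # --- glycolysis
    rx("pgi", {"g6p_c": -1, "f6p_c": 1}, reversible=True, tag="glycolysis")
    rx("pfk", {"f6p_c": -1, "atp_c": -1, "fbp_c": 1, "adp_c": 1}, tag="glycolysis")
    rx("fba_tpi", {"fbp_c": -1, "g3p_c": 2}, reversible=True, tag="glycolysis")
    rx("gapdh_pgk", {"g3p_c": -1, "nad_c": -1, "adp_c": -1, "pi_c": -1,
                     "pg3_c": 1, "nadh_c": 1, "atp_c": 1}, reversible=True, tag="glycolysis")
    rx("eno", {"pg3_c": -1, "pep_c": 1, "h2o_c": 1}, reversible=True, tag="glycolysis")
    rx("pyk", {"pep_c": -1, "adp_c": -1, "pyr_c": 1, "atp_c": 1}, tag="glycolysis")

    # --- pentose phosphate pathway (NADPH source)
    rx("ppp_ox", {"g6p_c": -1, "nadp_c": -2, "h2o_c": -1,
                  "ru5p_c": 1, "co2_c": 1, "nadph_c": 2}, tag="PPP")
    rx("rpi", {"ru5p_c": -1, "r5p_c": 1}, reversible=True, tag="PPP")
    rx("rpe", {"ru5p_c": -1, "x5p_c": 1}, reversible=True, tag="PPP")
    rx("tkt1", {"x5p_c": -1, "r5p_c": -1, "s7p_c": 1, "g3p_c": 1}, reversible=True, tag="PPP")
    rx("tal", {"s7p_c": -1, "g3p_c": -1, "e4p_c": 1, "f6p_c": 1}, reversible=True, tag="PPP")
    rx("tkt2", {"x5p_c": -1, "e4p_c": -1, "f6p_c": 1, "g3p_c": 1}, reversible=True, tag="PPP")

    # --- cytosolic redox interconversion (lumped malate/OAA cycle)
    rx("transhydrogenase", {"nadh_c": -1, "nadp_c": -1, "nad_c": 1, "nadph_c": 1},
       reversible=True, tag="redox")

    # --- pyruvate fate; no cytosolic Pdc in this genome
    rx("pyr_transport", {"pyr_c": -1, "pyr_m": 1}, tag="transport")
    rx("pdh_m", {"pyr_m": -1, "coa_m": -1, "nad_m": -1,
                 "accoa_m": 1, "co2_c": 1, "nadh_m": 1}, tag="PDH")
    rx("pc", {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1,
              "oaa_c": 1, "adp_c": 1, "pi_c": 1}, tag="anaplerosis")
    rx("oaa_transport", {"oaa_c": -1, "oaa_m": 1}, tag="transport")

    # --- TCA cycle
    rx("cs", {"accoa_m": -1, "oaa_m": -1, "h2o_c": -1, "cit_m": 1, "coa_m": 1}, tag="TCA")
    rx("idh", {"cit_m": -1, "nad_m": -1, "akg_m": 1, "co2_c": 1, "nadh_m": 1}, tag="TCA")
    rx("ogdh_scs", {"akg_m": -1, "nad_m": -1, "adp_c": -1, "pi_c": -1,
                    "succ_m": 1, "co2_c": 1, "nadh_m": 1, "atp_c": 1}, tag="TCA")
    rx("sdh", {"succ_m": -1, "fad_m": -1, "fum_m": 1, "fadh2_m": 1}, tag="TCA")
    rx("fum", {"fum_m": -1, "h2o_c": -1, "mal_m": 1}, reversible=True, tag="TCA")
    rx("mdh_m", {"mal_m": -1, "nad_m": -1, "oaa_m": 1, "nadh_m": 1}, reversible=True, tag="TCA")

    # --- oxidative phosphorylation (lumped; EnergyParams P/O ratios)
    for rid, (red, oxi), po in [
        ("oxphos_nadh_m", ("nadh_m", "nad_m"), energy.po_nadh_mito),
        ("oxphos_fadh2", ("fadh2_m", "fad_m"), energy.po_fadh2),
        ("oxphos_nadh_c", ("nadh_c", "nad_c"), energy.po_nadh_cyt),
    ]:
        rx(rid, {red: -1, "o2_c": F(-1, 2), "adp_c": -po, "pi_c": -po,
                 oxi: 1, "atp_c": po, "h2o_c": po + 1}, tag="oxphos")

    # --- fermentative branches
    rx("acald_dh_m", {"accoa_m": -1, "nadh_m": -1, "acald_m": 1, "nad_m": 1, "coa_m": 1},
       tag="fermentation")
    rx("acald_transport", {"acald_m": -1, "acald_c": 1}, tag="transport")
    rx("adh", {"acald_c": -1, "nadh_c": -1, "etoh_c": 1, "nad_c": 1}, tag="fermentation")
    # mitochondrial ADH isozyme: the anoxic sink for matrix NADH
    rx("adh_m", {"acald_m": -1, "nadh_m": -1, "etoh_m": 1, "nad_m": 1}, tag="fermentation")
    rx("etoh_transport", {"etoh_m": -1, "etoh_c": 1}, tag="transport")
    rx("ach_m", {"accoa_m": -1, "h2o_c": -1, "acetate_m": 1, "coa_m": 1}, tag="fermentation")
    rx("acetate_transport", {"acetate_m": -1, "acetate_c": 1}, tag="transport")
    rx("fdh", {"formate_c": -1, "nad_c": -1, "co2_c": 1, "nadh_c": 1},
       reversible=True, tag="fermentation")

    # --- cytosolic acetyl-CoA delivery (Acl and acetate routes)
    rx("cit_transport", {"cit_m": -1, "cit_c": 1}, tag="transport")
    rx("acl", {"cit_c": -1, "atp_c": -1, "coa_c": -1,
               "accoa_c": 1, "oaa_c": 1, "adp_c": 1, "pi_c": 1}, tag="acetyl_transfer")
    rx("acs_c", {"acetate_c": -1, "coa_c": -1, "atp_c": -2, "h2o_c": -1,
                 "accoa_c": 1, "adp_c": 2, "pi_c": 2}, tag="acetyl_transfer")

    # --- nitrogen / glutamate cycle
    rx("gdh", {"akg_c": -1, "nh3_c": -1, "nadph_c": -1, "glu_c": 1, "nadp_c": 1, "h2o_c": 1},
       reversible=True, tag="nitrogen")
    rx("akg_transport", {"akg_m": -1, "akg_c": 1}, reversible=True, tag="transport")

    # --- threonine-family branch to 2-oxobutanoate and propanoyl-CoA
    # (redox-level lump of the aspartate pathway; see docs/methods.md)
    rx("oxb_synth", {"pyr_c": -1, "co2_c": -1, "nadph_c": -3,
                     "oxb_c": 1, "nadp_c": 3, "h2o_c": 2}, tag="threonine_branch")
    rx("oxb_dh", {"oxb_c": -1, "coa_c": -1, "nad_c": -1,
                  "prcoa_c": 1, "co2_c": 1, "nadh_c": 1}, tag="threonine_branch")
    rx("oxb_transport", {"oxb_c": -1, "oxb_m": 1}, tag="transport")

    # --- branched-chain 2-oxo acid synthesis (mitochondrial, NADH-linked lump)
    rx("oiv_synth", {"pyr_m": -2, "nadh_m": -1, "oiv_m": 1, "co2_c": 1, "nad_m": 1, "h2o_c": 1},
       tag="BCAA")
    rx("oic_synth", {"oiv_m": -1, "accoa_m": -1, "nad_m": -1, "h2o_c": -1,
                     "oic_m": 1, "co2_c": 1, "nadh_m": 1, "coa_m": 1}, tag="BCAA")
    rx("omv_synth", {"oxb_m": -1, "pyr_m": -1, "nadh_m": -1,
                     "omv_m": 1, "co2_c": 1, "nad_m": 1, "h2o_c": 1}, tag="BCAA")

    # --- sulfur assimilation and the methionine 2-oxo acid (lumped)
    rx("sulfate_assim", {"h2so4_c": -1, "nadph_c": -4, "h2s_c": 1, "nadp_c": 4, "h2o_c": 4},
       tag="sulfur")
    rx("mtob_synth", {"oxb_c": -1, "co2_c": -1, "h2s_c": -1, "nadph_c": -2,
                      "mtob_c": 1, "nadp_c": 2, "h2o_c": 2}, tag="sulfur")

    # --- aromatic amino acids (shikimate lump)
    rx("shikimate", {"pep_c": -2, "e4p_c": -1, "nadph_c": -1, "atp_c": -1,
                     "chor_c": 1, "nadp_c": 1, "adp_c": 1, "pi_c": 4}, tag="aromatic")
    rx("chor_to_ppy", {"chor_c": -1, "ppy_c": 1, "co2_c": 1, "h2o_c": 1}, tag="aromatic")
    rx("chor_to_hpp", {"chor_c": -1, "nad_c": -1, "hpp_c": 1, "co2_c": 1, "nadh_c": 1},
       tag="aromatic")
    rx("phe_ta", {"ppy_c": -1, "glu_c": -1, "phe_c": 1, "akg_c": 1}, reversible=True,
       tag="aromatic")
    rx("tyr_ta", {"hpp_c": -1, "glu_c": -1, "tyr_c": 1, "akg_c": 1}, reversible=True,
       tag="aromatic")
    rx("ser_synth", {"pg3_c": -1, "nh3_c": -1, "ser_c": 1, "pi_c": 1}, tag="aromatic")
    rx("anth_synth", {"chor_c": -1, "nh3_c": -1, "anth_c": 1, "pyr_c": 1, "h2o_c": 1},
       tag="aromatic")
    rx("trp_synth", {"anth_c": -1, "r5p_c": -1, "ser_c": -1, "atp_c": -2,
                     "trp_c": 1, "g3p_c": 1, "co2_c": 1, "adp_c": 2, "pi_c": 2, "h2o_c": 1},
       tag="aromatic")

    # --- peroxide disposal
    rx("catalase", {"h2o2_c": -2, "o2_c": 1, "h2o_c": 2}, tag="detox")

    # --- fatty-acid synthesis base and lipid/desaturation (O2-dependent)
    rx("acc", {"accoa_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1,
               "malcoa_c": 1, "adp_c": 1, "pi_c": 1}, tag="FAS")
    rx("fas_c18_lump", {"accoa_c": -9, "atp_c": -8, "nadph_c": -16,
                        "acyl18_c": 1, "coa_c": 8, "adp_c": 8, "pi_c": 8, "nadp_c": 16},
       tag="FAS")
    rx("desaturase", {"acyl18_c": -1, "o2_c": -2, "nadh_c": -2,
                      "linoleoylcoa_c": 1, "nad_c": 2, "h2o_c": 4}, tag="lipid")
    rx("linoleate_release", {"linoleoylcoa_c": -1, "h2o_c": -1, "linoleate_c": 1, "coa_c": 1},
       tag="lipid")

    # --- biomass (lumped; lipid term makes growth O2-dependent)
    rx("biomass_synth", {"g6p_c": -6, "pyr_c": -3, "linoleate_c": F(-1, 2),
                         "nh3_c": -10, "atp_c": -30, "o2_c": F(-1, 2),
                         "nad_c": -11, "h2o_c": -25,
                         "biomass_c": 1, "co2_c": 6, "adp_c": 30, "pi_c": 36,
                         "nadh_c": 11}, tag="biomass")

    # --- ATP demand (cellular energy product)
    rx("atp_demand", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1}, tag="demand")

    # --- boundary exchanges
    ex("EX_o2", "o2_c", "in", "o2")
    ex("EX_co2", "co2_c", "out", "byproduct")
    ex("EX_h2o", "h2o_c", "out", "byproduct", reversible=True)
    ex("EX_nh3", "nh3_c", "in", "nutrient", reversible=True)
    ex("EX_h2so4", "h2so4_c", "in", "nutrient")
    ex("EX_formate", "formate_c", "out", "byproduct")
    ex("EX_acetate", "acetate_c", "out", "byproduct")
    ex("EX_acald", "acald_c", "out", "byproduct")
    ex("EX_etoh", "etoh_c", "out", "byproduct")
    ex("EX_biomass", "biomass_c", "out", "biomass")

    return rxns, exchanges


def build_core_model(
    substrate: SubstrateSpec = CELLOPENTAOSE,
    energy: EnergyParams | None = None,
    interventions: InterventionConfig = WT,
    with_registry: bool = True,
    validate: bool = True,
) -> MetabolicNetwork:
    """Build the core model, optionally with the FH registry attached.

    The returned network is verified element-balanced; a builder bug that
    breaks a balance raises immediately rather than silently corrupting
    yields downstream.
    """
    energy = energy or EnergyParams()
    mets = _mets_catalog(substrate)
    rxns, exchanges = _core_reactions(substrate, energy)
    net = MetabolicNetwork(mets, rxns, exchanges,
                           name=f"asco_core[{substrate.name},{interventions.label}]")
    if with_registry:
        from .products import attach_registry, build_default_registry

        net = attach_registry(net, build_default_registry())
        net.name = f"asco_core[{substrate.name},{interventions.label}]"
    net = apply_interventions(net, interventions)
    if validate:
        diag = validate_network(net)
        if diag["unbalanced"]:
            raise NetworkError(f"builder produced unbalanced reactions: {diag['unbalanced']}")
    return net


def apply_interventions(
    network: MetabolicNetwork,
    config: InterventionConfig,
) -> MetabolicNetwork:
    """Add the knock-in reactions to a wild-type network.

    CP on a glucose-fed model is legal but inert (glucose has no beta(1,4)
    bond to phosphorolyze); a warning is issued and nothing is added.
    """
    add: list[Reaction] = []
    add_mets: list[Metabolite] = []
    if config.cellobiose_phosphorylase:
        if "cpent_c" in network.metabolites:
            add_mets.append(
                Metabolite(id="g1p_c", name="glucose-1-phosphate", compartment="cytosol",
                           formula=Formula.parse("C6H13O9P"))
            )
            add.append(Reaction(
                id="cp_phosphorolysis",
                stoichiometry={"cpent_c": F(-1), "pi_c": F(-4),
                               "g1p_c": F(4), "glc_c": F(1)},
                pathway_tag="intervention",
            ))
            add.append(Reaction(
                id="pgm", stoichiometry={"g1p_c": F(-1), "g6p_c": F(1)},
                reversible=True, pathway_tag="intervention",
            ))
        else:
            warnings.warn(
                "cellobiose phosphorylase is inert on glucose (no beta(1,4) bonds); "
                "no reaction added",
                stacklevel=2,
            )
    if config.pdh_cytosolic:
        add.append(Reaction(
            id="pdh_c",
            stoichiometry={"pyr_c": F(-1), "coa_c": F(-1), "nad_c": F(-1),
                           "accoa_c": F(1), "co2_c": F(1), "nadh_c": F(1)},
            pathway_tag="intervention",
        ))
    if not add:
        return network
    out = network.with_reactions(add=add, add_metabolites=add_mets)
    out.name = network.name
    return out


def build_reduced_energy_model(
    substrate: SubstrateSpec = CELLOPENTAOSE,
    energy: EnergyParams | None = None,
) -> MetabolicNetwork:
    """Small single-pool energy model for exhaustive EFM analysis.

    Collapses glycolysis, respiration and the three fermentative fates
    (acetate, acetaldehyde, ethanol) into one lumped reaction each, with a
    single NADH pool.  The full core model is too large to enumerate; this
    reduced configuration reproduces the energy trade-off topology --
    a frontier running from complete oxidation (least carbon, most O2) to
    zero-O2 fermentation -- at a size the exact enumerator handles.
    """
    energy = energy or EnergyParams()
    C, E = "cytosol", "extracellular"

    def m(mid, name, comp, formula):
        return Metabolite(id=mid, name=name, compartment=comp, formula=Formula.parse(formula))

    mets = [
        m("glc_c", "glucose", C, "C6H12O6"),
        m("pyr_c", "pyruvate", C, "C3H4O3"),
        m("atp_c", "ATP", C, "C10H16N5O13P3"),
        m("adp_c", "ADP", C, "C10H15N5O10P2"),
        m("pi_c", "phosphate", C, "H3O4P"),
        m("nad_c", "NAD+", C, "C21H27N7O14P2"),
        m("nadh_c", "NADH", C, "C21H29N7O14P2"),
        m("co2_c", "CO2", C, "CO2"),
        m("o2_c", "O2", C, "O2"),
        m("h2o_c", "water", C, "H2O"),
        m("acetate_c", "acetate", C, "C2H4O2"),
        m("acald_c", "acetaldehyde", C, "C2H4O"),
        m("etoh_c", "ethanol", C, "C2H6O"),
    ]
    rxns: list[Reaction] = []
    exch: set[str] = set()

    def rx(rid, stoich, tag="", reversible=False):
        rxns.append(Reaction(id=rid, stoichiometry={k: F(v) for k, v in stoich.items()},
                             reversible=reversible, pathway_tag=tag))

    def ex(rid, met, direction, tag):
        rx(rid, {met: 1 if direction == "in" else -1}, tag=tag)
        exch.add(rid)

    k = energy.abc_transport_atp
    po = energy.po_nadh_mito
    resp_atp = 4 * po + energy.po_fadh2 + 1  # per pyruvate fully oxidized

    if substrate.name == "cellopentaose":
        mets.append(m("cpent_e", "cellopentaose", E, "C30H52O26"))
        ex("EX_sub", "cpent_e", "in", "substrate")
        rx("uptake_hydrolysis",
           {"cpent_e": -1, "atp_c": -k, "h2o_c": -(4 + k),
            "glc_c": 5, "adp_c": k, "pi_c": k}, tag="transport")
    else:
        mets.append(m("glc_e", "glucose", E, "C6H12O6"))
        ex("EX_sub", "glc_e", "in", "substrate")
        rx("uptake_hydrolysis",
           {"glc_e": -1, "atp_c": -k, "h2o_c": -k, "glc_c": 1, "adp_c": k, "pi_c": k},
           tag="transport")
    rx("glycolysis", {"glc_c": -1, "nad_c": -2, "adp_c": -2, "pi_c": -2,
                      "pyr_c": 2, "nadh_c": 2, "atp_c": 2, "h2o_c": 2}, tag="glycolysis")
    rx("respiration", {"pyr_c": -1, "o2_c": F(-5, 2), "adp_c": -resp_atp, "pi_c": -resp_atp,
                       "co2_c": 3, "atp_c": resp_atp, "h2o_c": resp_atp + 2}, tag="respiration")
    rx("to_acetate", {"pyr_c": -1, "nad_c": -1, "h2o_c": -1,
                      "acetate_c": 1, "co2_c": 1, "nadh_c": 1}, tag="fermentation")
    rx("to_acald", {"pyr_c": -1, "acald_c": 1, "co2_c": 1}, tag="fermentation")
    rx("to_etoh", {"pyr_c": -1, "nadh_c": -1, "etoh_c": 1, "co2_c": 1, "nad_c": 1},
       tag="fermentation")
    rx("nadh_ox", {"nadh_c": -1, "o2_c": F(-1, 2), "adp_c": -energy.po_nadh_cyt,
                   "pi_c": -energy.po_nadh_cyt, "nad_c": 1, "atp_c": energy.po_nadh_cyt,
                   "h2o_c": energy.po_nadh_cyt + 1}, tag="oxphos")
    rx("atp_demand", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1}, tag="demand")
    ex("EX_o2", "o2_c", "in", "o2")
    ex("EX_co2", "co2_c", "out", "byproduct")
    rx("EX_h2o", {"h2o_c": -1}, tag="byproduct", reversible=True)
    exch.add("EX_h2o")
    ex("EX_acetate", "acetate_c", "out", "byproduct")
    ex("EX_acald", "acald_c", "out", "byproduct")
    ex("EX_etoh", "etoh_c", "out", "byproduct")

    net = MetabolicNetwork(mets, rxns, exch, name=f"asco_energy_reduced[{substrate.name}]")
    diag = validate_network(net)
    if diag["unbalanced"]:
        raise NetworkError(f"reduced builder unbalanced: {diag['unbalanced']}")
    return net


def energy_yield(
    network: MetabolicNetwork,
    o2_policy: str = "unlimited",
) -> tuple[Fraction, Fraction]:
    """Minimum substrate (Cmol) and the O2 (mol) per mole of ATP demand.

    LP-minimizes substrate uptake per unit flux through the ATP demand
    reaction under the O2 policy ('unlimited' or 'zero'); among carbon
    optima the O2 uptake is then minimized (lexicographic), so the second
    coordinate is the O2 requirement of the carbon-optimal strategy.
    Raises :class:`ascoflux.yields.InfeasibleError` when no steady state
    can sustain the demand.
    """
    if o2_policy not in ("unlimited", "zero"):
        raise ValueError("o2_policy must be 'unlimited' or 'zero'")
    bound = None if o2_policy == "unlimited" else F(0)
    res = _yields.minimize_substrate(
        network, fixed_flux=("atp_demand", F(1)), o2_bound=bound
    )
    return res.carbon_cost, res.o2_cost
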