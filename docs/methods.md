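# Methods

`ascoflux` is a stoichiometric analysis of functionalized-hydrocarbon (FH)
production in the cellulolytic endophytic fungus *Ascocoryne sarcoides*.
This note records the model, its assumptions, the parameters that matter,
the deliberate lumping decisions, and what the shipped tests do and do not
demonstrate.

## The model

The network is a reduced, parameterized core reconstruction of fungal
central metabolism over three compartments (extracellular, cytosol,
mitochondria), built programmatically by `ascoflux.core_model`. It covers
substrate uptake and activation, glycolysis, the pentose phosphate
pathway, mitochondrial pyruvate dehydrogenase and the TCA cycle, lumped
oxidative phosphorylation, fermentative branches, the two cytosolic
acetyl-CoA delivery routes (ATP-citrate lyase on exported citrate, and
acetate export plus cytosolic acetyl-CoA synthetase at two ATP
equivalents), amino-acid precursor branches for the seven Ehrlich donors,
cytosolic fatty-acid synthesis with O2-dependent desaturation to
linoleate, and a lumped biomass equation. Two knock-ins are modeled:
cellobiose phosphorylase (CP) and a cytosolic pyruvate dehydrogenase
(PDHcyt).

Key structural commitments, reflecting this organism's genome-level
peculiarities:

- **No cytosolic pyruvate decarboxylase.** Acetaldehyde and ethanol are
  reached only through mitochondrial acetyl-CoA; cytosolic acetyl-CoA
  must be imported (Acl or acetate route) or, in the engineered strain,
  made by PDHcyt.
- **Aromatic Ehrlich chemistry requires O2.** Phenylalanine, tyrosine and
  tryptophan derivatives go amino acid → amine → O2-consuming amine
  oxidase → aldehyde (the genome lacks an aromatic 2-oxo acid
  decarboxylase). Catalase recovers half of the oxidase O2 from H2O2, so
  every aromatic product retains a strictly positive O2 requirement and
  is infeasible anoxically. Branched-chain and methionine derivatives
  decarboxylate their 2-oxo acids directly and stay anoxically feasible.
- **Biomass requires O2** through its lipid term: the lumped biomass
  equation consumes linoleate, whose desaturation consumes O2, plus a
  small direct O2 term for sterol synthesis. Growth is therefore
  infeasible at zero O2 under every intervention combination.

### Accounting conventions

All stoichiometric coefficients are exact rationals; every internal
reaction is element-balanced over C, H, O, N, S, P, which the builder
re-verifies on each build (an imbalance raises immediately). Charge and
protons are not modeled; metabolites are neutral species, with NAD(P)H
carrying an H2 relative to NAD(P)+. The degree of reduction is computed
against the reference states CO2/H2O/NH3/H2SO4/H3PO4, i.e. element
weights C +4, H +1, O −2, N −3, S +6, P +5 per atom; this reproduces the
conventional anchors (glucose 4, ethanol 6).

Small species (CO2, O2, H2O, NH3, H2SO4, H2S, H2O2, phosphate) live in a
single cytosolic pool with direct boundary exchanges; mitochondrial
reactions reference them there. This is a deliberate simplification
(free diffusion), halving the transport bookkeeping without touching any
carbon or electron balance. Substrates enter through the extracellular
compartment and a costed ABC transport step; product excretion is free.

### Energy parameters

`EnergyParams` defaults (all rationals):

| parameter | default | meaning |
|---|---|---|
| `po_nadh_mito` | 5/2 | ATP per mitochondrial NADH oxidized |
| `po_fadh2` | 3/2 | ATP per FADH2 |
| `po_nadh_cyt` | 3/2 | ATP per cytosolic NADH (glycerol-3-phosphate shuttle: electrons enter at the FADH2 level) |
| `abc_transport_atp` | 1 | ATP per transported substrate molecule, identical for glucose and cellopentaose |
| `maintenance_atp` | 0 | non-growth ATP drain |

With these defaults a glucosyl unit of cellopentaose yields 29.8 ATP on
complete oxidation (2 substrate-level + 3 shuttle + 20 mitochondrial
NADH + 3 FADH2 + 2 TCA-level, minus the 0.2 ATP share of the ABC event),
giving the energy optimum 30/149 ≈ 0.2013 Cmol and 0.2013 mol O2 per mol
ATP — 0.2 and 0.2 at one-decimal precision. Free glucose costs a full
ABC event per 6 carbons and lands at 6/29 ≈ 0.207 Cmol/ATP, which is why
a Cmol of cellopentaose is worth more than a Cmol of glucose here.

There is no malate/aspartate shuttle: cytosolic NADH reaches the chain
only through the lumped G3P-shuttle oxidation at P/O 3/2, and
oxaloacetate returns to the mitochondria by direct (redox-free)
transport. A single lumped reversible cytosolic transhydrogenation
(NADH + NADP+ ↔ NAD+ + NADPH, the malate/oxaloacetate dehydrogenase-pair
cycle) interconverts the two cytosolic redox pools carbon-neutrally; no
ATP is involved, so it cannot power a free-energy loop. Without such a
carbon-neutral NADPH source the fatty-acid elongation demand could only
be met through the oxidative PPP, whose CO2 loss would push even-chain
acids above their 3/2 Cmol/Cmol carbon bound.

### Lumping decisions in the amino-acid branches

The amino-acid scaffolds are lumped to redox-level stoichiometry:

- 2-oxobutanoate (threonine-family) branch:
  `pyruvate + CO2 + 3 NADPH → 2-oxobutanoate`, then oxidative
  decarboxylation to propanoyl-CoA. The kinase-step ATP charges of the
  full aspartate pathway are not itemized; the branch is treated as
  energetically neutral. This is the choice that lets propanoate reach
  its electron-balance cost of 14/12 Cmol/Cmol — the cell the
  functional-group scan reports for wild-type acids. Users probing
  absolute energetic margins of this branch should treat its ATP
  neutrality as a modeling assumption.
- Branched-chain 2-oxo acids are synthesized in the mitochondria with
  NADH-linked lumped reductions; leucine's acetyl-CoA demand is
  mitochondrial, which is exactly why PDHcyt leaves every Ehrlich
  product cost unchanged.
- The methionine precursor 4-methylthio-2-oxobutanoate is produced by a
  single element- and electron-balanced lump from 2-oxobutanoate + H2S +
  CO2 + 2 NADPH, with sulfate assimilation lumped as H2SO4 + 4 NADPH →
  H2S + 4 H2O (the APS/PAPS ATP costs are not itemized). The real route
  via homocysteine and methyl transfer is longer; only its net
  composition matters at this resolution.
- Aromatic synthesis is lumped to chorismate (2 PEP + E4P + NADPH + ATP)
  and two further steps for tryptophan via anthranilate.

A mitochondrial alcohol dehydrogenase isozyme (cf. yeast Adh3) is
included; it is the anoxic sink for matrix NADH and is what keeps
branched-chain Ehrlich products producible at zero O2. It is
redox-equivalent to the cytosolic route and does not move any optimum
that is pinned by a carbon or electron bound.

## The product registry

`ascoflux.products` generates the FH space combinatorially: 161 species
across eight functional groups (acids, esters, aldehydes, ketones,
primary and secondary alcohols, alkanes, alkenes), chain lengths C3-C20.
Formate, acetate, acetaldehyde and ethanol are primary fermentation
products, never registry members.

- **Fatty-acid derivatives (122).** Acyl chains initiate from acetyl-CoA
  (even) or propanoyl-CoA (odd; only C2 units elongate) and grow at
  1 ATP + 2 NADPH per C2 cycle, lumped to CoA-level species. Primary
  groups (acid, aldehyde, primary alcohol; 18 lengths each) release at
  the acyl length; carbon-losing groups (alkane via aldehyde
  deformylation releasing formate, alkene via 2-enoate decarboxylation,
  ketone via beta-keto acid decarboxylation, secondary alcohol via
  ketone reduction; 17 lengths each) lose exactly one carbon and flip
  parity.
- **Ehrlich derivatives (21).** Seven donors × {acid, aldehyde, primary
  alcohol}.
- **Linoleate cleavage products (8).** Four lumped oxidative cleavages,
  each coupling a C8 product (1-octen-3-ol, 3-octanone, 3-octanol,
  1,3-octadiene) to a distinct oxygenated C10 coproduct; no reaction
  yields a C8 species alone, and each cleavage conserves the 18 carbons.
- **Esters (10).** Acetate esters via alcohol acyltransferase
  (acetyl-CoA + alcohol): the C2 and C5-C10 alkyl acetates plus
  isobutyl, isopentyl and 2-phenylethyl acetate.

The total of 161 and the group/length constraints are fixed; the
species-level decomposition is this package's own calibrated fixture —
no per-class breakdown is published for this organism — so the registry
total is a structural check, not a reproduced measurement.
Propyl-cyclopropane and 2-pentyl-furan are reported for the organism but
deliberately out of model. Degree-of-reduction identities: fatty alkenes
and primary alcohols sit exactly at 6 electron-mol/Cmol; alkanes at
6 + 2/n, approaching 6 from above; acids increase strictly with chain
length toward 6.

## Elementary flux modes

`ascoflux.efm` enumerates EFMs by a double-description pass over the
rows of the internal stoichiometric matrix with exact rational
arithmetic: rays start at the unit vectors of the nonnegative orthant,
each balance row splits them and combines adjacent positive/negative
pairs (combinatorial zero-set adjacency), and row order is chosen
greedily to minimize generated candidates. Reversible reactions are
split, two-cycle modes discarded, and modes are returned as canonical
primitive integer vectors in deterministic support order — the
algorithm has no randomness. A cap on intermediate rays (default 5×10^6)
fails loudly with the ray count.

The independent oracle, `brute_force_efms`, enumerates all reaction
subsets and keeps supports whose restricted kernel is one-dimensional
with a strictly positive generator, then filters to support-minimal
sets. The two engines are checked for set equality on all toy networks
and on 50 seeded random element-balanced networks (≤ 12 reactions).
Gene-regulatory exclusion rules (groups of mutually exclusive reactions)
are applied post-enumeration: any mode using two or more members of a
group is removed.

Full-model enumeration is not attempted: yields on the full network are
computed by LP, whose optima over the same cone coincide with the best
EFM for single-objective yield questions. A reduced single-NADH-pool
energy model (`build_reduced_energy_model`, 16 reactions) supports
exhaustive mode analysis; its mode cloud reproduces the energy
trade-off topology — a frontier from complete oxidation (least carbon,
most O2) to zero-O2 ethanol fermentation.

## Yield optimization

`ascoflux.yields` minimizes substrate uptake (in Cmol) per Cmol of
exported product (or per mol of ATP-demand flux) subject to steady
state, irreversibility, and an O2 uptake bound, using HiGHS. Among
carbon optima, O2 uptake is minimized in a second lexicographic pass.
Every optimum is re-solved on its support with exact rational
arithmetic, so reported costs are exact fractions (7/6, 3/2, 30/149);
if the support system is degenerate the float value is rationalized
instead and the cases that matter are covered by exact tests.

"Simulated in isolation" (the functional-group scan) means: only the
scanned product's exchange is open among FH exchanges, while CO2, water,
formate, acetate, acetaldehyde and ethanol — declared non-FH — remain
open as byproducts. The group scan takes the minimum over members
simulated one at a time; pooling members into one LP is deliberately not
done, because joint co-production (e.g. propanoate with an aromatic
acid as electron partner) can undercut every single-product optimum and
does not correspond to the reported per-group quantities. Linoleic C8
species are infeasible in these isolation scans by construction (their
coproduct is another FH); they are analyzed with their partner exchange
opened explicitly.

Two analytic bounds anchor the numbers and are asserted as invariants:
carbon cost ≥ 1 always (≥ 3/2 when one CO2 is lost per C2 unit, which
pins acetyl-CoA-initiated even-chain fatty acids at exactly 3/2 under
CP+PDHcyt), and at zero O2 carbon cost ≥ γ(product)/γ(substrate)
(which pins even alkenes, γ = 6 from a γ = 4 substrate, at the same
3/2 with zero O2).

The anoxic cellular-energy optimum of this model is 10/3 Cmol/ATP
(substrate-level phosphorylation through the ethanol branch). A much
lower anoxic figure circulates for this system (≈1.3); no
substrate-level accounting we can justify reproduces it, and the
package makes no claim about it — the diagnostic value is simply what
the model yields.

## Synthetic fixtures

`ascoflux.toys` supplies the test surface: six hand-built toy networks
with known mode sets (linear chain, diamond, fermentation/respiration
Y-branch, reversible-loop two-cycle trap, exclusion-rule fixture,
two-rung elongation ladder) and a seeded generator of random
element-balanced networks (pure-carbon species; conversions, splits and
merges conserve carbon exactly; every dead end receives a sink). These
fixtures emulate the *combinatorial structure* of metabolic networks —
balance, branching, reversibility, coupling — not the biology; passing
the oracle-equivalence suite demonstrates the enumeration machinery is
correct, not that the core reconstruction is complete. Conversely, the
core model's numbers rest on its curated reaction set, and the
element-balance verification plus the analytic bounds are the guards
against reconstruction errors there.

## Known limitations

- Thermodynamics, kinetics, enzyme capacities, detailed gene-protein-
  reaction mapping, and charge/proton balance are out of scope.
- The amino-acid branch lumps omit kinase-level ATP itemization (see
  above); absolute costs of Ehrlich products are mildly optimistic.
- Biomass composition is a single lumped equation used only for
  feasibility properties, never for yield claims.
- The registry's species-level composition is calibrated, not measured.
- Peroxisomal beta-oxidation is not modeled.
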