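# ascoflux

Stoichiometric analysis of functionalized-hydrocarbon (FH) production in
the cellulolytic, endophytic fungus *Ascocoryne sarcoides*.

Endophytic fungi excrete a remarkable spread of functionalized
hydrocarbons — acids, esters, aldehydes, ketones, alcohols, alkanes and
alkenes from C3 to C20 — from cellulose-derived substrates. For anyone
asking *how cheaply* a given FH can be made (ecologically, or as a
bioprocess target), the binding constraints are stoichiometric: carbon
lost as CO2 along the route, electron conservation between substrate and
product, and the ATP economy of sugar activation and acetyl-CoA
compartmentalization. `ascoflux` builds a compartmentalized core model of
*A. sarcoides* central metabolism, generates the 161-species FH product
registry, and quantifies production limits as trade-off frontiers in the
(carbon, O2) cost plane. It is aimed at systems-biology practitioners who
want these analyses reproducible, exact, and scriptable.

## The core quantities

For a network with stoichiometric matrix **S**, the feasible steady
states form the flux cone {v : **S**v = 0, v_i ≥ 0 for irreversible i}.
Two views of that cone are implemented:

- **Elementary flux modes (EFMs)** — support-minimal steady-state
  vectors, enumerated with exact rational arithmetic by a
  double-description pass (every steady state is a nonnegative
  combination of EFMs). A brute-force subset enumerator serves as an
  independent oracle on small networks.
- **LP yield optima** — min Cmol substrate per Cmol product (or per mol
  ATP) under an O2 bound, solved with HiGHS and re-verified exactly on
  the optimal support, so results are true fractions (7/6, not
  1.1666667).

Products are scored per carbon mole; the **degree of reduction**
γ = (4nC + nH − 2nO − 3nN + 6nS + 5nP)/nC (glucose 4, ethanol 6) makes
the anoxic electron bound explicit: at zero O2,
cost ≥ γ(product)/γ(substrate).

Two engineered strains are analyzed in silico alongside wild type:
**CP** (cellobiose phosphorylase — phosphorolyzes β(1,4) bonds, sparing
hexokinase ATP during oligosaccharide activation) and **PDHcyt**
(cytosolic pyruvate dehydrogenase — uncouples cytosolic acetyl-CoA from
transport energetics).

## Worked example

Minimum resource costs, wild type on cellopentaose:

```sh
$ ascoflux yields --product propanoate
product=propanoate carbon_cost=1.16667 o2_cost=0 condition=carbon_limited strain=WT
```

Propanoate (C3, γ = 14/3) is made from pyruvate via 2-oxobutanoate with
no net carbon loss, so its cost is pinned by electron balance alone:
(14/3)/4 = 7/6 ≈ 1.17 Cmol of cellopentaose per Cmol of product, with
zero O2 at the optimum — the cheapest acid the wild-type network can
make. Oxygen limitation makes most FHs *more* expensive, because energy
must then come from substrate-level phosphorylation:

```sh
$ ascoflux tradeoff --product 3-methyl-1-butanol --o2-grid "0,1/16,1/8,1/4"
o2_bound<=0  carbon=2.4  o2=0
o2_bound<=0.0625  carbon=2.025  o2=0.0625
o2_bound<=0.125  carbon=1.8  o2=0.1
o2_bound<=0.25  carbon=1.8  o2=0.1
```

The isopentanol curve spans 2.4 → 1.8 Cmol/Cmol from anoxic to fully
aerated; aromatic Ehrlich products (2-phenylethanol, indole-3-acetate…)
are infeasible at zero O2 outright, since the only route to their
aldehydes runs through an O2-requiring amine oxidase. With both
knock-ins, fatty-acid derivatives reach their theoretical floor:

```sh
$ ascoflux yields --product 1-C4-ene --strain both
product=1-C4-ene carbon_cost=1.5 o2_cost=0 condition=carbon_limited strain=WT+CP+PDHcyt
```

1.5 Cmol/Cmol is simultaneously the carbon bound (one CO2 lost per C2
unit of acyl chain) and the anoxic electron bound (γ = 6 alkene from a
γ = 4 substrate) — the two constraints meet, so the optimum needs no
oxygen at all. `ascoflux registry` summarizes the 161-species product
space; `ascoflux group-scan` runs the full functional-group × strain scan;
`ascoflux build-model --out model.tsv` emits the model in a fraction-
exact TSV dialect (optionally SBML).

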