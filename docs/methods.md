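# Methods

## The community model

Two stoichiometric models — a phototrophic host and a diazotrophic
symbiont — are joined into one system by namespacing every metabolite and
reaction (`host:` / `sym:`) and adding **transfer reactions**, one per
candidate metabolite per direction, each moving the metabolite directly
between the two cytosols. Transfers are forward-only (lower bound 0) and
capped at `M`; each carries the metabolite's carbon and nitrogen atom
counts, parsed from its elemental formula. A metabolite without a formula
cannot be a transfer candidate (its atom counts would be undefined): the
default candidate policy therefore takes every cytosolic metabolite with a
formula that is present in both models, excluding a configurable currency
deny-list (photons, protons, water, inorganic phosphate, free electrons)
whose movement should not count as a trophic exchange. Explicit per-
direction candidate lists override the policy. A pooled extracellular
compartment is deliberately not modeled: direct cytosol-to-cytosol
transport is the simplest construction consistent with an endosymbiotic
partnership, and nothing downstream depends on the distinction.

The symbiont's biomass composition is unknown, so it has no biomass
reaction. Instead every biomass precursor gets a **sink** with lower bound
`ε = 0.01 mmol gDW⁻¹ hr⁻¹`; "the symbiont grows" means every sink is
simultaneously satisfiable. The host keeps an ordinary biomass drain.

Two community-level rows encode the measured exchange fractions:

* carbon: `Σ N_c,j v_j (host→sym) ≤ carbon_fraction · vCO2exchange`,
* nitrogen: `Σ N_N,j v_j (sym→host) ≥ 2 · nitrogen_fraction · vN2fixation`
  (the factor 2 converts N₂ flux to nitrogen atoms).

CO₂ uptake is measured as the flux of the designated host CO₂ exchange
(one carbon atom per unit), so the carbon row compares atom flux with atom
flux. The nitrogen row sums over *all* symbiont→host transfers; terms with
`N_N,j = 0` vanish, so restricting the sum to nitrogenous transfers would
change nothing.

### Parameters

| parameter | default | units / meaning |
|---|---|---|
| `epsilon` | 0.01 | mmol gDW⁻¹ hr⁻¹, per-precursor sink lower bound |
| `big_M` | 1000 | transfer flux cap linked to the binary activations |
| `max_scenarios` (K) | 100 | integer-cut enumeration budget |
| `carbon_fraction` | 0.17 | max share of host-fixed carbon transferable |
| `nitrogen_fraction` | 0.95 | min share of fixed nitrogen returned |
| `co2_basis` | 100 | CO₂ uptake cap during transfer minimization |
| `co2_basis_fixation` | 10 | CO₂ uptake cap during fixation maximization |
| `o2_fixed_uptake` | 0.1 | symbiont O₂ uptake pinned in the scavenging comparison |

The fractions come from isotope-tracing measurements of the real
partnership; the two CO₂ bases are the conventional baselines of the two
program variants. Photon uptake is left unbounded (phototrophic
conditions; light is not the modeled limitation), with a configurable cap.

## The programs

**Transfer minimization** is a MILP: binary `y_j` per transfer with the
big-M link `0 ≤ v_j ≤ y_j·M`, objective `min Σ y_j`, subject to mass
balance, the exchange rows, the ε sinks and the CO₂ basis. Infeasibility
is diagnosed by re-probing each sink with every transfer open and
reporting the sinks that still cannot reach ε.

**Enumeration** appends, after each solution with active set `A_k`, the
integer cut `Σ_{j∈A_k} y_j ≤ |A_k| − 1`, which excludes that set and all
its supersets. The printed form of this cut is sometimes written with the
right-hand sum over the *current* binaries; read literally that version is
satisfiable by activating one extra transfer and excludes nothing, so the
standard previous-solution form is used — it matches the stated purpose of
disallowing previously identified solutions while permitting suboptimal
successors. Two modes: `optimal_only` stops at the first solution worse
than the optimum; `nondecreasing` continues into suboptimal territory up
to K solutions. Active sets are taken from fluxes, not from the raw
binaries: big-M MILPs can return `y_j = 1` with zero flux away from the
optimum, so a transfer counts as active only above 10⁻⁶ flux. Essential
transfers are the intersection of active sets; alternate groups are the
connected components of the one-for-one substitution relation (two
transfers group together when some pair of scenarios differs exactly by
swapping them); members never seen in such a swap form singleton groups,
so AND-block ∪ OR-members always equals the union of active sets.

**Fixation maximization** is lexicographic: stage 1 maximizes
`vN2fixation` (an LP — binaries are irrelevant to the flux optimum) under
`co2_basis_fixation`; stage 2 pins the optimum and minimizes `Σ y_j`. The
ε sinks stay on by default, i.e. the symbiont keeps growing while
fixation is maximized; because one convention in the field drops the
growth requirement in this variant, `enforce_growth=False` is provided
and documented rather than silently chosen.

**Substrate ranking** restricts carbon-carrying host→symbiont transfers
to one candidate at a time and re-runs fixation maximization; yield is
`vN2fixation / vCO2exchange`. Transfers of the symbiont's biomass
precursors stay open so the growth prerequisites persist and the
candidate's effect is isolated to carbon/energy supply (a strict
single-transfer mode closes them too). ATP and reductant "yield fluxes"
are the summed positive fluxes through the community's designated
ATP-producing and NADP(H)/ferredoxin-reducing reactions; the CLI also
reports them normalized by the maximum across candidates.

**Oxygen-scavenging comparison** fixes the symbiont O₂ uptake at
`o2_fixed_uptake`, disables the competing mechanism, and maximizes
fixation per mechanism; the reported ratio is first-configured over
second-configured mechanism. When the two mechanisms differ only in net
ATP per O₂ and fixation is ATP-limited, the flux ratio equals the ATP
ratio exactly — this is the analytically forced regime the synthetic
tests exploit.

**pFBA** recomputes each scenario's flux distribution: inactive transfers
closed, objective (where present) pinned exactly at its optimum, total
absolute flux minimized via `t_j ≥ |v_j|` linearization. The optimum is
pinned exactly rather than with slack: the stage-1 vertex remains
feasible, and slack would leak into downstream quantities (total flux,
control coefficients) at the slack's magnitude.

**Gapfilling** adds a binary per universal candidate reaction, big-M
linked in both directions for reversible candidates, and minimizes the
number of additions subject to every target precursor reaching ε
simultaneously — run on a merged community model this is the two-organism
"concurrent" mode. On infeasibility the blocked targets are reported.

**Essentiality** knocks out each gene, disables reactions whose GPR turns
false, and probes each precursor sink (others relaxed to zero) for the ε
level. **Flux control coefficients** use one-sided downward
finite differences from a parsimonious reference optimum: reaction `j` is
pinned to `(1−δ)v_j*` (δ = 0.01 by default) and the objective re-solved;
the coefficient is `((Z−Z′)/Z)/δ`. Downward pinning is used because an
upward push can be infeasible at an optimum; the protocol (step,
direction, normalization) is a declared convention of this package, and
reference values computed under unknown conventions are not asserted
against it. Zero-flux reactions report 0.

## Numerical choices

LP feasibility 10⁻⁶, integrality 10⁻⁵, objective comparison 10⁻⁶ —
branch-and-cut solver class defaults. The backend is
`scipy.optimize.milp` (HiGHS) with zero MIP gap, behind a single
named-variable problem type, so a different branch-and-cut solver can be
substituted without touching the formulations. All assertions anywhere in
the package are on objective values and constraint satisfaction, never on
a unique flux vector: FBA optima are generically degenerate and any
optimal vertex is acceptable. Binary values are read at a 0.5 threshold;
ties in best-hit ortholog calling break by higher bitscore then
lexicographic subject id, and substrate-yield ties break lexicographically
by metabolite id, so every result is deterministic.

## The synthetic communities

The generator emulates the structure the analysis assumes: a host that
takes up CO₂ (uptake reaction, capped by the program basis), fixes it into
a generic one-carbon unit, synthesizes every exportable metabolite from
that unit, assimilates returned ammonia, and drains surplus fixed carbon
into biomass; and a symbiont with nitrogenase (default textbook
stoichiometry 16 ATP + 8 reduced ferredoxin + N₂ → 2 NH₃ + H₂ — only the
ratios matter to any test), ε-sinked biomass precursors, an internal
glycogen reserve feeding the precursors it can still make, and planted
auxotrophies for the rest. Auxotrophic precursors are importable directly;
OR-group precursors are alternatively importable as upstream intermediates
whose conversion steps the symbiont retains — mirroring the
terminal-precursor-or-intermediate alternatives of the real
reconstruction. Decoy candidates are importable and disposable but never
needed. Energy comes from catabolizing an imported substrate into ATP and
reduced ferredoxin, so fixation is carbon-limited through the 17%
exchange row; with O₂ mechanisms enabled, substrate catabolism yields only
reductant and ATP comes solely from the two O₂-consuming routes, making
fixation ATP-limited and the flux ratio equal to the planted ATP-per-O₂
ratio.

Toy metabolites carry real small-molecule formulas (acetate, pyruvate,
succinate, …; OR-group alternatives share a carbon count so their
interconversions balance), which keeps the atom-count constraints
non-vacuous. Carbon and nitrogen are conserved exactly in every
non-boundary toy reaction; hydrogen/oxygen balancing, charge balance, and
any claim to real pathway chemistry are not attempted. The planted
auxotrophy formulas are nitrogen-free, so a minimal-growth solution needs
no nitrogenase flux; nitrogen transfer becomes active (and the 95% return
row binding) under fixation maximization. Consequently, passing tests
demonstrate the correctness of the optimization machinery on networks
with known answers — they say nothing about the biological accuracy of any
particular genome-scale reconstruction, and the published-community
numbers are asserted only in the integration check that loads the real
reconstructions.

All stochastic choices (formula assignment, wiring) flow from one seeded
generator; the same spec yields byte-identical serialized model files.

The exhaustive oracle fixes every subset of transfer activations in
increasing cardinality and LP-checks the full constraint system,
returning all feasible sets of minimal cardinality; a combinatorial guard
refuses more than 14 candidates. Test problem sizes — 8–12 transfer
candidates, 20-seed sweeps, K ≤ 100 — were chosen so the exhaustive
cross-checks stay exact while the whole property suite solves a few
thousand small LPs/MILPs.

## Model dialect

A model is a directory with `reactions.tsv` (id, name, equation, lb, ub,
gpr, subsystem), `metabolites.tsv` (id, name, formula, charge,
compartment) and optional `model.json` (biomass reaction or precursor
list, medium); an `.xlsx` workbook with `reactions`/`metabolites` sheets
is accepted. Equations use `->` (irreversible) and `<=>` (reversible,
lb < 0); metabolite ids are BiGG-style with a one-letter compartment
suffix (`_c`, `_e`, `_u` thylakoid lumen, `_p`), and a lumen proton
written `H+[l]` in other sources maps to `_u`. Reversible reactions are
kept as single columns (no splitting) except inside the pFBA objective —
transfer reactions are forward-only, so their activation semantics never
meet a negative flux. Published supplementary reconstructions ship as
spreadsheets with their own column layouts; loading them means mapping
those columns onto this dialect once (a documented, mechanical step).
Full SBML support and thermodynamic directionality assignment are out of
scope: bounds are consumed as given.

## Known limitations

* No kinetics, regulation, or diel (day/night) two-phase structure; the
  model is a steady-state snapshot of daytime operation.
* Symbiont growth is an ε-production requirement, not a growth rate; no
  growth-vs-exchange trade-off can be read off.
* The minimal transfer count depends on the candidate universe; with the
  default shared-cytosol policy it is a property of the two loaded
  models, not a biological constant.
* The flux-control protocol is a one-sided convention (see above).
* Toy chemistry conserves only C and N; it exercises the machinery, not
  the biology.
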