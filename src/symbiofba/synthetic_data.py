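"""Seeded generator of host-symbiont toy communities with planted truth.

The toys emulate the structure the community analysis assumes: a
phototrophic host that takes up CO2, fixes it into a generic fixed-carbon
unit and synthesizes exportable metabolites from it, paired with a
reduced symbiont that fixes N2 with nitrogenase but carries planted
auxotrophies for a subset of its biomass precursors.  Auxotrophic
precursors can only be satisfied by importing either the precursor
itself or, for the planted OR-groups, one of its upstream intermediates
(the symbiont retains the downstream conversion steps) — mirroring the
"terminal precursor or biosynthetic intermediate" alternatives the real
reconstruction exhibits.  Decoy candidates are transferable but never
needed.  The symbiont's energy metabolism catabolizes an imported carbon
substrate into ATP and reduced ferredoxin, so fixation maximization is
carbon-limited through the community carbon-exchange fraction.

Toy metabolites carry real small-molecule formulas so that the
carbon/nitrogen exchange constraints are exercised with nonzero atom
counts.  Carbon and nitrogen are conserved exactly in every non-boundary
toy reaction; hydrogen and oxygen balancing is not attempted.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .community import (
    HOST_TO_SYM,
    SYM_TO_HOST,
    CommunityModel,
    SymbiosisConfig,
    build_community,
)
from .lp_engine import DEFAULT_SETTINGS, SolveSettings
from .model_io import MetabolicModel, Metabolite, Reaction, parse_formula
from .symbiosis import build_program

__all__ = [
    "ToyCommunitySpec",
    "GroundTruth",
    "generate_toy_community",
    "generate_toy_models",
    "brute_force_min_transfers",
    "BruteForceResult",
]

# Real small-molecule (carbon-only) formulas, grouped by carbon count so
# that OR-group alternatives interconvert with carbon conserved.
_FORMULA_POOL: dict[int, tuple[tuple[str, str], ...]] = {
    2: (
        ("ac", "C2H4O2"),        # acetate
        ("glyclt", "C2H4O3"),    # glycolate
        ("etoh", "C2H6O"),       # ethanol
        ("acald", "C2H4O"),      # acetaldehyde
    ),
    3: (
        ("pyr", "C3H4O3"),       # pyruvate
        ("glyc", "C3H8O3"),      # glycerol
        ("lac__D", "C3H6O3"),    # D-lactate
        ("ppa", "C3H6O2"),       # propanoate
    ),
    4: (
        ("succ", "C4H6O4"),      # succinate
        ("ery", "C4H8O4"),       # erythrose
        ("mal__L", "C4H6O5"),    # L-malate
        ("fum", "C4H4O4"),       # fumarate
        ("but", "C4H8O2"),       # butanoate
        ("thrnt", "C4H8O5"),     # threonate
    ),
}


@dataclass(frozen=True)
class ToyCommunitySpec:
    """Parameters of one generated toy community.

    ``or_groups`` holds the alternative count of each planted OR-group
    (2 = terminal precursor or one upstream intermediate; 3 adds a
    second, further-upstream intermediate).  ``substrates`` are the
    importable energy substrates as (base id, ATP yield, reduced-
    ferredoxin yield) per mmol; with O2 mechanisms enabled the ATP
    yields are forced to zero so that fixation is ATP-limited through
    the scavenging reactions and the planted ATP-per-O2 ratio
    ``o2_atp_ratio`` is recovered exactly as a fixation flux ratio.
    """

    n_precursors: int = 5
    n_essential_auxotrophies: int = 3
    or_groups: tuple[int, ...] = ()
    n_decoy_candidates: int = 3
    nitrogenase_stoichiometry: tuple[tuple[str, float], ...] = (
        ("atp", 16.0), ("fdred", 8.0), ("nh3", 2.0), ("h2", 1.0)
    )
    substrates: tuple[tuple[str, float, float], ...] = (("glc__D", 30.0, 10.0),)
    include_o2_mechanisms: bool = False
    o2_atp_ratio: float = 1.15
    o2_atp_per_o2: float = 18.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_precursors < 0 or self.n_essential_auxotrophies < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_essential_auxotrophies + len(self.or_groups) > self.n_precursors:
            raise ValueError(
                "n_essential_auxotrophies + |or_groups| must not exceed n_precursors"
            )
        if any(size < 2 for size in self.or_groups):
            raise ValueError("every OR-group needs at least 2 alternatives")
        if max(self.or_groups, default=2) > max(len(v) for v in _FORMULA_POOL.values()):
            raise ValueError("OR-group size exceeds the formula pool")
        if self.o2_atp_ratio <= 0 or self.o2_atp_per_o2 <= 0:
            raise ValueError("O2 mechanism parameters must be positive")
        if not self.substrates:
            raise ValueError("at least one energy substrate is required")
        stoich = dict(self.nitrogenase_stoichiometry)
        for key in ("atp", "fdred", "nh3"):
            if stoich.get(key, 0.0) <= 0:
                raise ValueError(f"nitrogenase stoichiometry needs positive {key!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one toy community (the test oracle)."""

    minimal_transfer_count: int
    essential_set: frozenset[str]
    alternate_groups: tuple[frozenset[str], ...]
    expected_o2_flux_ratio: float | None = None
    expected_yield_order: tuple[str, ...] = ()

    def __post_init__(self):
        expected = len(self.essential_set) + len(self.alternate_groups)
        if self.minimal_transfer_count != expected:
            raise ValueError(
                "minimal_transfer_count must be |essential_set| + |alternate_groups|"
            )


def _draw_metabolites(spec: ToyCommunitySpec, rng: random.Random):
    """Assign pool formulas: per-OR-group same-carbon sets, the rest free."""
    pool = {c: list(entries) for c, entries in _FORMULA_POOL.items()}
    for entries in pool.values():
        rng.shuffle(entries)

    groups: list[list[tuple[str, str]]] = []
    for size in sorted(spec.or_groups, reverse=True):
        classes = [c for c, entries in pool.items() if len(entries) >= size]
        if not classes:
            raise ValueError("formula pool exhausted for OR-group assignment")
        c = rng.choice(classes)
        groups.append([pool[c].pop() for _ in range(size)])

    def take(n: int) -> list[tuple[str, str]]:
        out = []
        for _ in range(n):
            classes = [c for c, entries in pool.items() if entries]
            if not classes:
                raise ValueError("formula pool exhausted")
            out.append(pool[rng.choice(classes)].pop())
        return out

    n_plain = spec.n_precursors - spec.n_essential_auxotrophies - len(spec.or_groups)
    essentials = take(spec.n_essential_auxotrophies)
    plain = take(n_plain)
    decoys = take(spec.n_decoy_candidates)
    return essentials, groups, plain, decoys


def _carbon_count(formula: str) -> int:
    return parse_formula(formula).get("C", 0)


def generate_toy_models(
    spec: ToyCommunitySpec,
) -> tuple[MetabolicModel, MetabolicModel, dict]:
    """Build the standalone host and symbiont toy models.

    Returns ``(host, symbiont, layout)`` where layout records the drawn
    candidate metabolites (used by :func:`generate_toy_community` to
    wire transfers and ground truth).
    """
    spec.validate()
    rng = random.Random(spec.seed)
    essentials, groups, plain, decoys = _draw_metabolites(spec, rng)

    host_mets = [
        Metabolite("co2_c", name="CO2", formula="CO2", compartment="c"),
        Metabolite("cfix_c", name="fixed carbon unit", formula="CH2O", compartment="c"),
        Metabolite("nh3_c", name="ammonia", formula="H3N", compartment="c"),
    ]
    host_rxns = [
        Reaction("EX_co2", {"co2_c": 1.0}, 0.0, 1000.0, name="CO2 uptake"),
        Reaction("CFIX", {"co2_c": -1.0, "cfix_c": 1.0}, 0.0, 1000.0,
                 name="photosynthetic carbon fixation", gpr="hg_cfix"),
        Reaction("NH3_ASSIM", {"nh3_c": -1.0}, 0.0, 1000.0,
                 name="host assimilation of returned nitrogen"),
        # Host growth drain: fixed carbon not shared with the symbiont is
        # sequestered into host biomass (>=83% of uptake, by the carbon
        # exchange fraction).
        Reaction("BIOMASS_host", {"cfix_c": -1.0}, 0.0, 1000.0,
                 name="host biomass drain"),
    ]

    # The host can synthesize everything it may be asked to supply:
    # auxotrophic precursors, their OR-group intermediates, decoys and
    # the energy substrates.
    substrate_entries = [(name, _substrate_formula(name)) for name, _, _ in spec.substrates]
    host_supplied = [*essentials, *[m for grp in groups for m in grp], *decoys,
                     *substrate_entries]
    for base, formula in host_supplied:
        mid = f"{base}_c"
        host_mets.append(Metabolite(mid, name=base, formula=formula, compartment="c"))
        n_c = _carbon_count(formula)
        host_rxns.append(
            Reaction(
                f"SYN_{base}", {"cfix_c": -float(n_c), mid: 1.0}, 0.0, 1000.0,
                name=f"host synthesis of {base}", gpr=f"hg_{base}",
            )
        )
    host = MetabolicModel(
        id="toy_host", metabolites=host_mets, reactions=host_rxns,
        biomass_reaction_id="BIOMASS_host",
    )

    # ---- symbiont --------------------------------------------------------
    nif = dict(spec.nitrogenase_stoichiometry)
    sym_mets = [
        Metabolite("n2_c", name="N2", formula="N2", compartment="c"),
        Metabolite("nh3_c", name="ammonia", formula="H3N", compartment="c"),
        Metabolite("h2_c", name="H2", formula="H2", compartment="c"),
        Metabolite("atp_c", name="ATP equivalent", formula=None, compartment="c"),
        Metabolite("fdred_c", name="reduced ferredoxin", formula=None, compartment="c"),
        Metabolite("glycogen_c", name="glycogen unit", formula="C6H10O5", compartment="c"),
        Metabolite("co2_c", name="CO2", formula="CO2", compartment="c"),
    ]
    sym_rxns = [
        Reaction("EX_n2", {"n2_c": 1.0}, 0.0, 1000.0, name="N2 uptake"),
        Reaction("EX_h2", {"h2_c": -1.0}, 0.0, 1000.0, name="H2 offgassing"),
        Reaction("EX_co2s", {"co2_c": -1.0}, 0.0, 1000.0, name="respiratory CO2 release"),
        Reaction(
            "NIT",
            {
                "atp_c": -nif["atp"],
                "fdred_c": -nif["fdred"],
                "n2_c": -1.0,
                "nh3_c": nif["nh3"],
                "h2_c": nif.get("h2", 1.0),
            },
            0.0, 1000.0, name="nitrogenase", gpr="sg_nifH and sg_nifD",
        ),
        Reaction("GLYCOGEN_SRC", {"glycogen_c": 1.0}, 0.0, 1000.0,
                 name="internal glycogen reserve"),
        Reaction("ATPM", {"atp_c": -1.0}, 0.0, 1000.0, name="ATP maintenance drain"),
        Reaction("FD_DISS", {"fdred_c": -1.0}, 0.0, 1000.0,
                 name="ferredoxin re-oxidation (dissipative)"),
    ]

    for name, atp_yield, fd_yield in spec.substrates:
        if spec.include_o2_mechanisms:
            atp_yield = 0.0  # ATP only via O2 scavenging in this regime
        formula = _substrate_formula(name)
        n_c = _carbon_count(formula)
        mid = f"{name}_c"
        sym_mets.append(Metabolite(mid, name=name, formula=formula, compartment="c"))
        stoich = {mid: -1.0, "fdred_c": fd_yield, "co2_c": float(n_c)}
        if atp_yield > 0:
            stoich["atp_c"] = atp_yield
        sym_rxns.append(
            Reaction(f"CAT_{name}", stoich, 0.0, 1000.0,
                     name=f"catabolism of imported {name}", gpr=f"sg_cat_{name}")
        )

    precursors: list[str] = []

    def add_sym_met(base: str, formula: str) -> str:
        mid = f"{base}_c"
        sym_mets.append(Metabolite(mid, name=base, formula=formula, compartment="c"))
        return mid

    # Essential auxotrophies: precursor exists, no synthesis route at all.
    for base, formula in essentials:
        precursors.append(add_sym_met(base, formula))

    # OR-groups: precursor plus upstream intermediates with retained
    # conversion steps intermediate -> ... -> precursor.
    for grp in groups:
        ids = [add_sym_met(base, formula) for base, formula in grp]
        precursors.append(ids[0])
        for upstream, downstream in zip(ids[1:], ids[:-1]):
            base_up = upstream[:-2]
            sym_rxns.append(
                Reaction(
                    f"CONV_{base_up}", {upstream: -1.0, downstream: 1.0}, 0.0, 1000.0,
                    name=f"salvage conversion {upstream} -> {downstream}",
                    gpr=f"sg_conv_{base_up}",
                )
            )

    # Self-sufficient precursors: synthesizable from the internal reserve.
    for base, formula in plain:
        mid = add_sym_met(base, formula)
        n_c = _carbon_count(formula)
        sym_rxns.append(
            Reaction(
                f"SYNS_{base}", {"glycogen_c": -n_c / 6.0, mid: 1.0}, 0.0, 1000.0,
                name=f"symbiont synthesis of {base}", gpr=f"sg_syn_{base}",
            )
        )
        precursors.append(mid)

    # Decoys: importable and disposable, never required.
    for base, formula in decoys:
        mid = add_sym_met(base, formula)
        sym_rxns.append(
            Reaction(f"DUMP_{base}", {mid: -1.0}, 0.0, 1000.0,
                     name=f"disposal of {base}")
        )

    if spec.include_o2_mechanisms:
        sym_mets.append(Metabolite("o2_c", name="O2", formula="O2", compartment="c"))
        sym_rxns.append(Reaction("EX_o2", {"o2_c": 1.0}, 0.0, 1000.0, name="O2 uptake"))
        a_cyt = spec.o2_atp_per_o2
        a_meh = spec.o2_atp_ratio * a_cyt
        sym_rxns.append(
            Reaction("MEHLER", {"o2_c": -1.0, "fdred_c": -2.0, "atp_c": a_meh},
                     0.0, 1000.0, name="Mehler-type O2 photoreduction (net ATP)",
                     gpr="sg_mehler")
        )
        sym_rxns.append(
            Reaction("CYTOX", {"o2_c": -1.0, "fdred_c": -2.0, "atp_c": a_cyt},
                     0.0, 1000.0, name="cytochrome-type respiration (net ATP)",
                     gpr="sg_cyo1 and sg_cyo2")
        )

    symbiont = MetabolicModel(
        id="toy_symbiont",
        metabolites=sym_mets,
        reactions=sym_rxns,
        biomass_precursors=precursors,
    )
    layout = {
        "essentials": [f"{b}_c" for b, _ in essentials],
        "groups": [[f"{b}_c" for b, _ in grp] for grp in groups],
        "plain": [f"{b}_c" for b, _ in plain],
        "decoys": [f"{b}_c" for b, _ in decoys],
        "substrates": [f"{n}_c" for n, _, _ in spec.substrates],
    }
    return host, symbiont, layout


_SUBSTRATE_FORMULAS = {
    "glc__D": "C6H12O6",
    "fru": "C6H12O6",
    "sucr": "C12H22O11",
    "g3p": "C3H7O6P",
    "dhap": "C3H7O6P",
    "hom__L": "C4H9NO3",
}


def _substrate_formula(name: str) -> str:
    return _SUBSTRATE_FORMULAS.get(name, "C6H12O6")


def generate_toy_community(
    spec: ToyCommunitySpec,
    config: SymbiosisConfig | None = None,
) -> tuple[CommunityModel, GroundTruth]:
    """Generate a toy community plus its planted ground truth.

    Generation is fully determined by ``spec.seed``: the same spec
    yields byte-identical serialized models.
    """
    config = config or SymbiosisConfig()
    host, symbiont, layout = generate_toy_models(spec)

    h2s_candidates = [
        *layout["essentials"],
        *[m for grp in layout["groups"] for m in grp],
        *layout["decoys"],
        *layout["substrates"],
    ]
    candidates = {HOST_TO_SYM: h2s_candidates, SYM_TO_HOST: ["nh3_c"]}

    if spec.include_o2_mechanisms:
        atp_rxns = ("sym:MEHLER", "sym:CYTOX")
    else:
        atp_rxns = tuple(f"sym:CAT_{n}" for n, a, _ in spec.substrates if a > 0)
    nadph_rxns = tuple(f"sym:CAT_{n}" for n, _, _ in spec.substrates)

    community = build_community(
        host,
        symbiont,
        config,
        host_co2_exchange="EX_co2",
        sym_n2_fixation="NIT",
        sym_o2_uptake="EX_o2" if spec.include_o2_mechanisms else None,
        o2_mechanisms=(
            {"mehler": "MEHLER", "cytochrome": "CYTOX"}
            if spec.include_o2_mechanisms else None
        ),
        candidates=candidates,
        atp_reactions=atp_rxns,
        nadph_reactions=nadph_rxns,
    )

    essential_ids = frozenset(f"TR_h2s_{m}" for m in layout["essentials"])
    group_ids = tuple(
        frozenset(f"TR_h2s_{m}" for m in grp) for grp in layout["groups"]
    )
    truth = GroundTruth(
        minimal_transfer_count=len(essential_ids) + len(group_ids),
        essential_set=essential_ids,
        alternate_groups=group_ids,
        expected_o2_flux_ratio=spec.o2_atp_ratio if spec.include_o2_mechanisms else None,
        expected_yield_order=_expected_yield_order(spec),
    )
    return community, truth


def _expected_yield_order(spec: ToyCommunitySpec) -> tuple[str, ...]:
    """Substrates ranked by achievable fixation per imported carbon atom."""
    nif = dict(spec.nitrogenase_stoichiometry)
    scored = []
    for name, atp_yield, fd_yield in spec.substrates:
        if spec.include_o2_mechanisms:
            atp_yield = 0.0
        n_c = _carbon_count(_substrate_formula(name))
        per_unit = min(
            atp_yield / nif["atp"] if nif["atp"] else math.inf,
            fd_yield / nif["fdred"] if nif["fdred"] else math.inf,
        )
        scored.append((per_unit / n_c if n_c else 0.0, name))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return tuple(f"{name}_c" for _, name in scored)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BruteForceResult:
    count: int | None  # None when no candidate subset is feasible
    minimal_sets: tuple[frozenset[str], ...]

    @property
    def feasible(self) -> bool:
        return self.count is not None


def brute_force_min_transfers(
    community: CommunityModel,
    config: SymbiosisConfig | None = None,
    max_candidates: int = 14,
    settings: SolveSettings = DEFAULT_SETTINGS,
) -> BruteForceResult:
    """Exhaustive minimum-transfer oracle (test-only; exponential).

    Enumerates candidate subsets in increasing cardinality, fixes the
    transfer activations accordingly (members capped at big-M, the rest
    closed) and LP-feasibility-checks the full constraint system.  All
    feasible subsets of the minimal cardinality are returned.
    """
    config = config or SymbiosisConfig()
    transfer_ids = [t.id for t in community.transfers]
    n = len(transfer_ids)
    if n > max_candidates:
        raise ValueError(
            f"{n} transfer candidates exceed the combinatorial guard "
            f"(max_candidates={max_candidates})"
        )
    base = build_program(community, config, with_binaries=False)
    caps = {t.id: t.cap for t in community.transfers}

    for k in range(n + 1):
        feasible_sets = []
        for subset in combinations(transfer_ids, k):
            chosen = set(subset)
            for tid in transfer_ids:
                base.set_bounds(tid, 0.0, caps[tid] if tid in chosen else 0.0)
            status, _, _ = base.solve({}, sense="min", settings=settings)
            if status == "optimal":
                feasible_sets.append(frozenset(chosen))
        if feasible_sets:
            return BruteForceResult(count=k, minimal_sets=tuple(sorted(
                feasible_sets, key=lambda s: sorted(s)
            )))
    return BruteForceResult(count=None, minimal_sets=())
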