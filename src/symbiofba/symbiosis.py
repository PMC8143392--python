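"""Community-level MILP programs.

* minimum-transfer-set search: minimize the number of active transfer
  reactions (binary y_j, big-M linked to fluxes) subject to mass
  balance, the carbon/nitrogen exchange fractions, epsilon-bounded
  biomass precursor sinks and a CO2 uptake basis;
* alternate-scenario enumeration via integer cuts;
* fixation maximization with lexicographic transfer minimization;
* substrate yield ranking; and
* the oxygen-scavenging mechanism comparison.

Binary activations found at >1e-6 flux count as active; big-M MILPs can
report spurious y_j = 1 with zero flux away from the optimum, so active
sets are always taken from the fluxes, not from the raw binaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .community import (
    HOST_TO_SYM,
    CommunityModel,
    SymbiosisConfig,
    exchange_constraint_rows,
)
from .lp_engine import (
    DEFAULT_SETTINGS,
    LinearProblem,
    SolveSettings,
    add_l1_minimization,
)
from .model_io import FluxDistribution

__all__ = [
    "ACTIVE_FLUX_THRESHOLD",
    "InfeasibleCommunityError",
    "TransferScenario",
    "ScenarioSet",
    "SubstrateYield",
    "MaxFixationResult",
    "O2ScavengingComparison",
    "build_program",
    "min_transfers",
    "enumerate_scenarios",
    "max_fixation",
    "rank_substrates",
    "compare_o2_scavenging",
    "infer_alternate_groups",
]

#: A transfer is considered active when it carries more flux than this.
ACTIVE_FLUX_THRESHOLD = 1e-6


class InfeasibleCommunityError(RuntimeError):
    """Raised when a community program has no feasible flux distribution.

    ``blocked_sinks`` lists the biomass precursor sinks that cannot reach
    their epsilon level even with every transfer open (an irreducible
    infeasibility diagnostic).
    """

    def __init__(self, message: str, blocked_sinks: Sequence[str] = ()):
        super().__init__(message)
        self.blocked_sinks = tuple(blocked_sinks)


@dataclass(frozen=True)
class TransferScenario:
    """One feasible trophic scenario: an active transfer set + fluxes."""

    active_transfers: frozenset[str]
    objective_count: int
    fluxes: FluxDistribution
    rank: int = 0

    def __post_init__(self):
        if self.objective_count != len(self.active_transfers):
            raise ValueError("objective_count must equal |active_transfers|")


@dataclass(frozen=True)
class ScenarioSet:
    scenarios: tuple[TransferScenario, ...]
    mode: str  # "optimal_only" | "nondecreasing"
    essential_transfers: frozenset[str]
    alternate_groups: tuple[frozenset[str], ...]
    complete: bool = True

    def __len__(self) -> int:
        return len(self.scenarios)

    @property
    def optimal_count(self) -> int:
        return min(s.objective_count for s in self.scenarios)


@dataclass(frozen=True)
class SubstrateYield:
    metabolite: str
    n2_yield: float  # mmol N2 fixed per mmol CO2 taken up by the host
    atp_flux: float
    nadph_flux: float
    n2_flux: float = 0.0
    co2_flux: float = 0.0


@dataclass(frozen=True)
class MaxFixationResult:
    n2_flux: float
    scenario: TransferScenario | None


@dataclass(frozen=True)
class O2ScavengingComparison:
    fluxes: dict[str, float]
    scenarios: dict[str, TransferScenario | None]
    ratio: float | None  # first mechanism / second mechanism


# ---------------------------------------------------------------------------
# Program construction
# ---------------------------------------------------------------------------

def _y_var(transfer_id: str) -> str:
    return f"__y__{transfer_id}"


def build_program(
    community: CommunityModel,
    config: SymbiosisConfig,
    *,
    with_binaries: bool = True,
    co2_basis: float | None = None,
    enforce_growth: bool = True,
    allowed_carbon: Iterable[str] | None = None,
    disabled_reactions: Iterable[str] = (),
    o2_fixed: float | None = None,
) -> LinearProblem:
    """Assemble the common constraint system of the community programs.

    ``allowed_carbon`` (unprefixed metabolite ids) restricts the
    carbon-carrying host->symbiont transfers to the given candidates;
    nitrogen-free transfers stay open so growth prerequisites persist.
    ``o2_fixed`` pins the symbiont O2 uptake flux.
    """
    model = community.merged_model()
    prob = LinearProblem.from_model(model)

    basis = config.co2_basis if co2_basis is None else co2_basis
    lb, ub = prob.bounds_of(community.co2_exchange_reaction)
    prob.set_bounds(community.co2_exchange_reaction, lb, min(ub, basis))

    carbon_row, nitrogen_row = exchange_constraint_rows(community, config)
    prob.add_constraint(*carbon_row)
    prob.add_constraint(*nitrogen_row)

    if allowed_carbon is not None:
        allowed = set(allowed_carbon)
        for t in community.transfers_host_to_sym:
            if t.n_carbon > 0 and t.metabolite not in allowed:
                prob.set_bounds(t.id, 0.0, 0.0)

    if with_binaries:
        for t in community.transfers:
            y = _y_var(t.id)
            prob.add_variable(y, 0.0, 1.0, integer=True)
            prob.add_constraint({t.id: 1.0, y: -t.cap}, -math.inf, 0.0)

    for sid in community.precursor_sinks.values():
        _, sub = prob.bounds_of(sid)
        prob.set_bounds(sid, config.epsilon if enforce_growth else 0.0, sub)

    for rid in disabled_reactions:
        prob.set_bounds(rid, 0.0, 0.0)

    if o2_fixed is not None:
        if community.o2_uptake_reaction is None:
            raise InfeasibleCommunityError(
                "community has no designated O2 uptake reaction to fix"
            )
        prob.fix(community.o2_uptake_reaction, o2_fixed)

    return prob


def _diagnose_infeasibility(
    community: CommunityModel,
    config: SymbiosisConfig,
    settings: SolveSettings,
    **program_kwargs,
) -> tuple[str, ...]:
    """Which precursor sinks stay below epsilon with every transfer open?"""
    kwargs = dict(program_kwargs)
    kwargs.update(with_binaries=False, enforce_growth=False)
    blocked = []
    for prec, sid in community.precursor_sinks.items():
        prob = build_program(community, config, **kwargs)
        status, _, val = prob.solve({sid: 1.0}, sense="max", settings=settings)
        if status != "optimal" or val < config.epsilon - settings.feasibility_tol:
            blocked.append(sid)
    return tuple(blocked)


def _active_set(
    community: CommunityModel, x: Mapping[str, float], threshold: float = ACTIVE_FLUX_THRESHOLD
) -> frozenset[str]:
    return frozenset(t.id for t in community.transfers if x.get(t.id, 0.0) > threshold)


def _scenario_fluxes(
    community: CommunityModel,
    config: SymbiosisConfig,
    active: frozenset[str],
    settings: SolveSettings,
    pin: Mapping[str, float] | None = None,
    **program_kwargs,
) -> FluxDistribution:
    """Parsimonious flux distribution for a fixed trophic scenario:
    inactive transfers closed, total |flux| minimized."""
    prob = build_program(community, config, with_binaries=False, **program_kwargs)
    for t in community.transfers:
        if t.id not in active:
            prob.set_bounds(t.id, 0.0, 0.0)
    if pin:
        for rid, value in pin.items():
            lb, ub = prob.bounds_of(rid)
            prob.set_bounds(rid, max(lb, value - settings.objective_tol), ub)
    model = community.merged_model()
    l1 = add_l1_minimization(prob, model.reaction_ids)
    status, x, _ = prob.solve(l1, sense="min", settings=settings)
    fluxes = {rid: x.get(rid, 0.0) for rid in model.reaction_ids} if x else {}
    return FluxDistribution(status=status, fluxes=fluxes, objective_value=math.nan)


# ---------------------------------------------------------------------------
# Transfer-set minimization and integer-cut enumeration
# ---------------------------------------------------------------------------

def _transfer_objective(community: CommunityModel) -> dict[str, float]:
    return {_y_var(t.id): 1.0 for t in community.transfers}


def min_transfers(
    community: CommunityModel,
    config: SymbiosisConfig | None = None,
    settings: SolveSettings = DEFAULT_SETTINGS,
) -> TransferScenario:
    """Provably minimal number of active transfers enabling symbiont growth."""
    config = config or SymbiosisConfig()
    result = enumerate_scenarios(community, config, mode="optimal_only", settings=settings, k=1)
    return result.scenarios[0]


def enumerate_scenarios(
    community: CommunityModel,
    config: SymbiosisConfig | None = None,
    mode: str = "nondecreasing",
    settings: SolveSettings = DEFAULT_SETTINGS,
    k: int | None = None,
    **program_kwargs,
) -> ScenarioSet:
    """Enumerate distinct trophic scenarios with integer cuts.

    After each solution with active set A, the cut
    ``sum_{j in A} y_j <= |A| - 1`` is appended, excluding that set and
    all of its supersets; enumeration stops at ``k`` scenarios, at
    infeasibility, or (in ``optimal_only`` mode) at the first solution
    whose objective exceeds the optimum.
    """
    config = config or SymbiosisConfig()
    if mode not in ("optimal_only", "nondecreasing"):
        raise ValueError(f"unknown enumeration mode {mode!r}")
    k = config.max_scenarios if k is None else k
    prob = build_program(community, config, with_binaries=True, **program_kwargs)
    objective = _transfer_objective(community)

    scenarios: list[TransferScenario] = []
    optimum: int | None = None
    complete = True
    while len(scenarios) < k:
        status, x, val = prob.solve(objective, sense="min", settings=settings)
        if status == "infeasible":
            if not scenarios:
                blocked = _diagnose_infeasibility(community, config, settings, **program_kwargs)
                raise InfeasibleCommunityError(
                    "no feasible trophic scenario: "
                    + (f"sinks blocked even with all transfers open: {list(blocked)}"
                       if blocked else "exchange constraints unsatisfiable"),
                    blocked_sinks=blocked,
                )
            break
        if status != "optimal":
            complete = False
            break
        count = int(round(val))
        if optimum is None:
            optimum = count
        if mode == "optimal_only" and count > optimum:
            break
        active = _active_set(community, x)
        fluxes = _scenario_fluxes(community, config, active, settings, **program_kwargs)
        scenarios.append(
            TransferScenario(
                active_transfers=active,
                objective_count=len(active),
                fluxes=fluxes,
                rank=len(scenarios),
            )
        )
        if not active:  # the empty set's only "cut" would exclude everything
            break
        prob.add_constraint({_y_var(t): 1.0 for t in active}, -math.inf, len(active) - 1)

    essential, groups = infer_alternate_groups(scenarios)
    return ScenarioSet(
        scenarios=tuple(scenarios),
        mode=mode,
        essential_transfers=essential,
        alternate_groups=groups,
        complete=complete,
    )


def infer_alternate_groups(
    scenarios: Sequence[TransferScenario],
) -> tuple[frozenset[str], tuple[frozenset[str], ...]]:
    """Essential transfers (intersection) and alternate groups.

    Two non-essential transfers belong to one group when some pair of
    scenarios differs exactly by swapping one for the other; groups are
    the connected components of that substitution relation.  Transfers
    active somewhere but never observed in a one-for-one swap form
    singleton groups, so the union of the AND-block and all OR-group
    members always equals the union of active sets.
    """
    if not scenarios:
        return frozenset(), ()
    active_sets = [s.active_transfers for s in scenarios]
    essential = frozenset.intersection(*active_sets)
    union = frozenset.union(*active_sets)
    non_essential = union - essential

    parent = {t: t for t in non_essential}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def join(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i in range(len(active_sets)):
        for j in range(i + 1, len(active_sets)):
            diff = active_sets[i] ^ active_sets[j]
            if len(diff) == 2:
                a, b = sorted(diff)
                join(a, b)

    components: dict[str, set[str]] = {}
    for t in non_essential:
        components.setdefault(find(t), set()).add(t)
    groups = tuple(
        sorted((frozenset(g) for g in components.values()), key=lambda g: sorted(g))
    )
    return essential, groups


# ---------------------------------------------------------------------------
# Fixation maximization
# ---------------------------------------------------------------------------

def max_fixation(
    community: CommunityModel,
    config: SymbiosisConfig | None = None,
    settings: SolveSettings = DEFAULT_SETTINGS,
    *,
    enforce_growth: bool = True,
    allowed_carbon: Iterable[str] | None = None,
    disabled_reactions: Iterable[str] = (),
    o2_fixed: float | None = None,
) -> MaxFixationResult:
    """Lexicographic solve: maximize N2 fixation, then minimize transfers.

    Stage 1 maximizes the N2 fixation flux (LP) under the fixation CO2
    basis; stage 2 pins the optimum and minimizes the number of active
    transfers (MILP).  ``enforce_growth`` keeps the epsilon precursor
    sinks on during both stages (set False to drop the growth
    requirement while maximizing fixation).
    """
    config = config or SymbiosisConfig()
    kwargs = dict(
        co2_basis=config.co2_basis_fixation,
        enforce_growth=enforce_growth,
        allowed_carbon=allowed_carbon,
        disabled_reactions=tuple(disabled_reactions),
        o2_fixed=o2_fixed,
    )
    prob = build_program(community, config, with_binaries=False, **kwargs)
    n2 = community.n2_fixation_reaction
    status, _, opt = prob.solve({n2: 1.0}, sense="max", settings=settings)
    if status == "infeasible":
        blocked = _diagnose_infeasibility(community, config, settings, **kwargs)
        raise InfeasibleCommunityError(
            "fixation maximization infeasible", blocked_sinks=blocked
        )
    if status != "optimal":
        raise InfeasibleCommunityError(f"fixation maximization failed: status {status}")
    if opt <= settings.feasibility_tol:
        opt = 0.0

    # Stage 2: pin vN2fixation at its maximum, minimize sum of y_j.
    milp_prob = build_program(community, config, with_binaries=True, **kwargs)
    lb, ub = milp_prob.bounds_of(n2)
    milp_prob.set_bounds(n2, max(lb, opt - settings.objective_tol), ub)
    status, x, _ = milp_prob.solve(_transfer_objective(community), sense="min", settings=settings)
    if status != "optimal":
        return MaxFixationResult(n2_flux=opt, scenario=None)
    active = _active_set(community, x)
    fluxes = _scenario_fluxes(
        community, config, active, settings, pin={n2: opt}, **kwargs
    )
    scenario = TransferScenario(
        active_transfers=active, objective_count=len(active), fluxes=fluxes, rank=0
    )
    return MaxFixationResult(n2_flux=opt, scenario=scenario)


# ---------------------------------------------------------------------------
# Substrate ranking
# ---------------------------------------------------------------------------

def _summed_flux(fluxes: FluxDistribution, reaction_ids: Sequence[str]) -> float:
    return sum(max(fluxes.get(rid, 0.0), 0.0) for rid in reaction_ids)


def rank_substrates(
    community: CommunityModel,
    candidates: Sequence[str],
    config: SymbiosisConfig | None = None,
    settings: SolveSettings = DEFAULT_SETTINGS,
    *,
    enforce_growth: bool = True,
    strict_single_transfer: bool = False,
) -> list[SubstrateYield]:
    """N2-fixation yield per candidate carbon substrate.

    For each candidate, carbon-carrying host->symbiont transfers are
    restricted to that candidate alone, except that transfers of the
    symbiont's biomass precursors stay open: the growth prerequisites
    persist while the carbon/energy substrate varies, so the candidate's
    effect is isolated (``strict_single_transfer=True`` closes them
    too).  Fixation is maximized per candidate and the yield reported as
    vN2fixation / vCO2exchange.  Output is sorted by yield, descending,
    ties broken lexicographically by metabolite id.
    """
    config = config or SymbiosisConfig()
    known = {t.metabolite for t in community.transfers_host_to_sym}
    prerequisites: set[str] = set()
    if not strict_single_transfer:
        prefix_len = len("sym:")
        prerequisites = {p[prefix_len:] for p in community.symbiont.biomass_precursors}
    results = []
    for met in candidates:
        if met not in known:
            raise KeyError(f"{met!r} is not a host->symbiont transfer candidate")
        try:
            res = max_fixation(
                community, config, settings,
                enforce_growth=enforce_growth,
                allowed_carbon={met} | prerequisites,
            )
        except InfeasibleCommunityError:
            results.append(SubstrateYield(met, 0.0, 0.0, 0.0))
            continue
        if res.scenario is None or res.n2_flux <= 0.0:
            results.append(SubstrateYield(met, 0.0, 0.0, 0.0))
            continue
        fluxes = res.scenario.fluxes
        co2 = fluxes.get(community.co2_exchange_reaction, 0.0)
        n2_yield = res.n2_flux / co2 if co2 > settings.feasibility_tol else 0.0
        results.append(
            SubstrateYield(
                metabolite=met,
                n2_yield=n2_yield,
                atp_flux=_summed_flux(fluxes, community.atp_reactions),
                nadph_flux=_summed_flux(fluxes, community.nadph_reactions),
                n2_flux=res.n2_flux,
                co2_flux=co2,
            )
        )
    results.sort(key=lambda s: (-s.n2_yield, s.metabolite))
    return results


# ---------------------------------------------------------------------------
# Oxygen scavenging comparison
# ---------------------------------------------------------------------------

def compare_o2_scavenging(
    community: CommunityModel,
    config: SymbiosisConfig | None = None,
    settings: SolveSettings = DEFAULT_SETTINGS,
    *,
    enforce_growth: bool = True,
) -> O2ScavengingComparison:
    """Maximum fixation flux per O2-scavenging mechanism at fixed O2 uptake.

    Each mechanism is evaluated with the competing mechanism(s) disabled
    and the symbiont O2 uptake pinned at ``config.o2_fixed_uptake``.
    ``ratio`` is the fixation flux of the first configured mechanism
    over the second (insertion order of ``community.o2_mechanisms``).
    """
    config = config or SymbiosisConfig()
    if not community.o2_mechanisms:
        raise InfeasibleCommunityError("community declares no O2-scavenging mechanisms")
    if community.o2_uptake_reaction is None:
        raise InfeasibleCommunityError("community has no designated O2 uptake reaction")

    fluxes: dict[str, float] = {}
    scenarios: dict[str, TransferScenario | None] = {}
    for name, rid in community.o2_mechanisms.items():
        disabled = [r for other, r in community.o2_mechanisms.items() if other != name]
        try:
            res = max_fixation(
                community, config, settings,
                enforce_growth=enforce_growth,
                disabled_reactions=disabled,
                o2_fixed=config.o2_fixed_uptake,
            )
            fluxes[name] = res.n2_flux
            scenarios[name] = res.scenario
        except InfeasibleCommunityError:
            fluxes[name] = math.nan
            scenarios[name] = None

    ratio: float | None = None
    names = list(community.o2_mechanisms)
    if len(names) >= 2:
        a, b = fluxes[names[0]], fluxes[names[1]]
        if not (math.isnan(a) or math.isnan(b)) and b > settings.feasibility_tol:
            ratio = a / b
    return O2ScavengingComparison(fluxes=fluxes, scenarios=scenarios, ratio=ratio)
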