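"""Solver-facing layer: FBA, parsimonious FBA, gapfilling, essentiality
and flux-control sensitivity, all through one HiGHS-backed problem type.

Every solve goes through :class:`LinearProblem`, a small named-variable
LP/MILP container built on ``scipy.optimize.milp``.  All assertions made
downstream are on objective values and constraint satisfaction, never on
a unique flux vector: FBA optima are generically degenerate and any
optimal vertex is acceptable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .model_io import (
    FEASIBILITY_TOL,
    INTEGRALITY_TOL,
    OBJECTIVE_TOL,
    FluxDistribution,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = [
    "SolveSettings",
    "LinearProblem",
    "GapfillResult",
    "fba",
    "pfba",
    "gapfill",
    "essential_genes",
    "flux_control",
]

_STATUS = {0: "optimal", 1: "unknown", 2: "infeasible", 3: "unbounded", 4: "unknown"}


@dataclass(frozen=True)
class SolveSettings:
    feasibility_tol: float = FEASIBILITY_TOL
    integrality_tol: float = INTEGRALITY_TOL
    objective_tol: float = OBJECTIVE_TOL
    time_limit: float | None = None  # seconds per solve
    seed: int = 0

    def __post_init__(self):
        if min(self.feasibility_tol, self.integrality_tol, self.objective_tol) <= 0:
            raise ValueError("tolerances must be positive")


DEFAULT_SETTINGS = SolveSettings()


def _resolve_model(model_or_community) -> MetabolicModel:
    """Accept either a MetabolicModel or anything exposing merged_model()."""
    if hasattr(model_or_community, "merged_model"):
        return model_or_community.merged_model()
    return model_or_community


class LinearProblem:
    """Named-variable LP/MILP with box bounds and two-sided row constraints."""

    def __init__(self) -> None:
        self._names: list[str] = []
        self._index: dict[str, int] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integer: list[bool] = []
        # each constraint: (coefficient mapping var-name -> coef, lo, hi)
        self._constraints: list[tuple[dict[str, float], float, float]] = []

    # -- construction -------------------------------------------------------
    @classmethod
    def from_model(cls, model: MetabolicModel) -> "LinearProblem":
        prob = cls()
        for r in model.reactions:
            prob.add_variable(r.id, r.lower_bound, r.upper_bound)
        rows: dict[str, dict[str, float]] = {}
        for r in model.reactions:
            for met, coef in r.stoichiometry.items():
                rows.setdefault(met, {})[r.id] = coef
        for met in model.metabolite_ids:
            coeffs = rows.get(met)
            if coeffs:
                prob.add_constraint(coeffs, 0.0, 0.0)
        return prob

    def add_variable(self, name: str, lb: float, ub: float, integer: bool = False) -> None:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        self._index[name] = len(self._names)
        self._names.append(name)
        self._lb.append(float(lb))
        self._ub.append(float(ub))
        self._integer.append(bool(integer))

    def add_constraint(self, coeffs: Mapping[str, float], lo: float, hi: float) -> None:
        self._constraints.append((dict(coeffs), float(lo), float(hi)))

    def has_variable(self, name: str) -> bool:
        return name in self._index

    def set_bounds(self, name: str, lb: float | None = None, ub: float | None = None) -> None:
        i = self._index[name]
        if lb is not None:
            self._lb[i] = float(lb)
        if ub is not None:
            self._ub[i] = float(ub)

    def fix(self, name: str, value: float) -> None:
        self.set_bounds(name, value, value)

    def bounds_of(self, name: str) -> tuple[float, float]:
        i = self._index[name]
        return self._lb[i], self._ub[i]

    def copy(self) -> "LinearProblem":
        other = LinearProblem()
        other._names = list(self._names)
        other._index = dict(self._index)
        other._lb = list(self._lb)
        other._ub = list(self._ub)
        other._integer = list(self._integer)
        other._constraints = [(dict(c), lo, hi) for c, lo, hi in self._constraints]
        return other

    # -- solving ------------------------------------------------------------
    def solve(
        self,
        objective: Mapping[str, float],
        sense: str = "max",
        settings: SolveSettings = DEFAULT_SETTINGS,
    ) -> tuple[str, dict[str, float], float]:
        if sense not in ("max", "min"):
            raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
        n = len(self._names)
        c = np.zeros(n)
        for name, coef in objective.items():
            c[self._index[name]] += coef
        sign = -1.0 if sense == "max" else 1.0

        constraints = []
        if self._constraints:
            rows, cols, data, lo, hi = [], [], [], [], []
            for k, (coeffs, clo, chi) in enumerate(self._constraints):
                for name, coef in coeffs.items():
                    rows.append(k)
                    cols.append(self._index[name])
                    data.append(float(coef))
                lo.append(clo)
                hi.append(chi)
            A = sparse.csr_array((data, (rows, cols)), shape=(len(self._constraints), n))
            constraints.append(LinearConstraint(A, np.array(lo), np.array(hi)))

        options: dict = {"mip_rel_gap": 0.0}
        if settings.time_limit is not None:
            options["time_limit"] = settings.time_limit

        res = milp(
            c=sign * c,
            constraints=constraints,
            integrality=np.array(self._integer, dtype=int),
            bounds=Bounds(np.array(self._lb), np.array(self._ub)),
            options=options,
        )
        status = _STATUS.get(res.status, "unknown")
        if res.x is None:
            return status, {}, math.nan
        x = {name: float(res.x[i]) for i, name in enumerate(self._names)}
        return status, x, float(sign * res.fun)

    @property
    def variable_names(self) -> list[str]:
        return list(self._names)


# ---------------------------------------------------------------------------
# FBA / pFBA
# ---------------------------------------------------------------------------

def _flux_distribution(
    model: MetabolicModel, status: str, x: Mapping[str, float], objective_value: float
) -> FluxDistribution:
    fluxes = {rid: x.get(rid, 0.0) for rid in model.reaction_ids} if x else {}
    return FluxDistribution(status=status, fluxes=fluxes, objective_value=objective_value)


def fba(
    model_or_community,
    objective: str,
    sense: str = "max",
    settings: SolveSettings = DEFAULT_SETTINGS,
) -> FluxDistribution:
    """Flux balance analysis: optimize one reaction flux subject to
    steady-state mass balance and the flux bounds."""
    model = _resolve_model(model_or_community)
    if not model.has_reaction(objective):
        raise KeyError(f"objective reaction {objective!r} not in model")
    prob = LinearProblem.from_model(model)
    status, x, val = prob.solve({objective: 1.0}, sense=sense, settings=settings)
    return _flux_distribution(model, status, x, val)


def add_l1_minimization(
    prob: LinearProblem,
    flux_vars: Sequence[str],
    cap: float = 1e6,
) -> dict[str, float]:
    """Augment a problem with |v| linearization vars; returns the L1 objective.

    For every listed variable v a helper t >= |v| is added via
    t - v >= 0 and t + v >= 0; minimizing sum(t) minimizes total
    absolute flux (split-variable / absolute-value linearization).
    """
    objective: dict[str, float] = {}
    for name in flux_vars:
        t = f"__abs__{name}"
        prob.add_variable(t, 0.0, cap)
        prob.add_constraint({t: 1.0, name: -1.0}, 0.0, math.inf)
        prob.add_constraint({t: 1.0, name: 1.0}, 0.0, math.inf)
        objective[t] = 1.0
    return objective


def pfba(
    model_or_community,
    objective: str,
    sense: str = "max",
    settings: SolveSettings = DEFAULT_SETTINGS,
) -> FluxDistribution:
    """Parsimonious FBA: pin the FBA optimum, then minimize total |flux|.

    The reported objective_value is the (pinned) FBA optimum.
    """
    model = _resolve_model(model_or_community)
    first = fba(model, objective, sense=sense, settings=settings)
    if not first.optimal:
        return first
    prob = LinearProblem.from_model(model)
    opt = first.objective_value
    # Pin the optimum exactly: the stage-1 vertex remains feasible, and an
    # exact pin keeps total-flux values and downstream sensitivities sharp.
    if sense == "max":
        prob.set_bounds(objective, opt, max(opt, prob.bounds_of(objective)[1]))
    else:
        prob.set_bounds(objective, min(opt, prob.bounds_of(objective)[0]), opt)
    l1 = add_l1_minimization(prob, model.reaction_ids)
    status, x, _ = prob.solve(l1, sense="min", settings=settings)
    if status != "optimal":  # should not happen: the FBA vertex is feasible
        return first
    return _flux_distribution(model, "optimal", x, opt)


# ---------------------------------------------------------------------------
# Gapfilling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GapfillResult:
    added_reactions: frozenset[str]
    feasible_after: bool
    blocked_precursors: tuple[str, ...] = ()

    @property
    def objective_count(self) -> int:
        return len(self.added_reactions)


def _sink_id(met: str) -> str:
    return f"SK_{met}"


def _ensure_sinks(model: MetabolicModel, targets: Sequence[str], epsilon: float) -> list[str]:
    """Install (or reuse) an epsilon-lower-bounded sink per target metabolite."""
    sinks = []
    for met in targets:
        sid = _sink_id(met)
        if not model.has_reaction(sid):
            model.add_reactions(
                [Reaction(id=sid, stoichiometry={met: -1.0}, lower_bound=epsilon,
                          upper_bound=1000.0, name=f"sink for {met}")]
            )
        else:
            model.reaction(sid).lower_bound = epsilon
        sinks.append(sid)
    return sinks


def gapfill(
    model: MetabolicModel,
    universal: MetabolicModel,
    targets: Sequence[str],
    settings: SolveSettings = DEFAULT_SETTINGS,
    epsilon: float = 0.01,
    big_m: float = 1000.0,
) -> GapfillResult:
    """Minimal-cardinality reaction additions restoring precursor production.

    Each universal candidate gets a binary activation variable linked to
    its flux by big-M rows; the MILP minimizes the number of activated
    candidates subject to every target being producible at >= epsilon
    simultaneously.  Running on a merged community model gives the
    two-organism "concurrent" mode.
    """
    work = _resolve_model(model).copy()
    candidates = [r for r in universal.reactions if not work.has_reaction(r.id)]
    new_mets = [
        m for m in universal.metabolites if not work.has_metabolite(m.id)
    ]
    work.add_metabolites(new_mets)
    work.add_reactions([r.copy() for r in candidates])
    _ensure_sinks(work, targets, epsilon)
    work.validate()

    prob = LinearProblem.from_model(work)
    objective: dict[str, float] = {}
    for r in candidates:
        z = f"__use__{r.id}"
        prob.add_variable(z, 0.0, 1.0, integer=True)
        ub = r.upper_bound if math.isfinite(r.upper_bound) else big_m
        lb = r.lower_bound if math.isfinite(r.lower_bound) else -big_m
        if ub > 0:
            prob.add_constraint({r.id: 1.0, z: -ub}, -math.inf, 0.0)
        if lb < 0:
            prob.add_constraint({r.id: 1.0, z: -lb}, 0.0, math.inf)
        objective[z] = 1.0

    status, x, val = prob.solve(objective, sense="min", settings=settings)
    if status == "optimal":
        added = frozenset(
            r.id for r in candidates if x[f"__use__{r.id}"] > 0.5
        )
        return GapfillResult(added_reactions=added, feasible_after=True)

    # Diagnose: which targets stay blocked even with the full universal set?
    blocked = []
    for met in targets:
        probe = prob.copy()
        for other in targets:
            if other != met:
                probe.set_bounds(_sink_id(other), lb=0.0)
        for r in candidates:
            probe.fix(f"__use__{r.id}", 1.0)
        st, _, _ = probe.solve({}, sense="min", settings=settings)
        if st != "optimal":
            blocked.append(met)
    return GapfillResult(
        added_reactions=frozenset(), feasible_after=False,
        blocked_precursors=tuple(blocked),
    )


# ---------------------------------------------------------------------------
# Gene essentiality
# ---------------------------------------------------------------------------

def essential_genes(
    model_or_community,
    settings: SolveSettings = DEFAULT_SETTINGS,
    epsilon: float = 0.01,
) -> dict[str, frozenset[str]]:
    """Map each gene to the biomass precursors its knockout blocks.

    A knockout disables every reaction whose gene rule evaluates false
    without the gene (but true with the full gene set); a precursor is
    blocked when its sink can no longer reach the epsilon production
    level.  Genes whose loss disables no reaction map to the empty set.
    """
    model = _resolve_model(model_or_community)
    precursors = list(model.biomass_precursors)
    all_genes = model.genes()
    base_prob = LinearProblem.from_model(model)
    sink_ids = {}
    for met in precursors:
        sid = _sink_id(met)
        if not model.has_reaction(sid):
            raise ValueError(
                f"no sink reaction {sid!r} for precursor {met!r}; build the "
                "community (or install sinks) before essentiality analysis"
            )
        sink_ids[met] = sid
        base_prob.set_bounds(sid, lb=0.0)  # probe one precursor at a time

    result: dict[str, frozenset[str]] = {}
    for gene in sorted(all_genes):
        remaining = all_genes - {gene}
        disabled = [
            r.id
            for r in model.reactions
            if not r.gene_rule.is_empty
            and r.gene_rule.evaluate(all_genes)
            and not r.gene_rule.evaluate(remaining)
        ]
        if not disabled:
            result[gene] = frozenset()
            continue
        prob = base_prob.copy()
        for rid in disabled:
            prob.fix(rid, 0.0)
        blocked = []
        for met in precursors:
            status, _, val = prob.solve({sink_ids[met]: 1.0}, sense="max", settings=settings)
            if status != "optimal" or val < epsilon - settings.feasibility_tol:
                blocked.append(met)
        result[gene] = frozenset(blocked)
    return result


# ---------------------------------------------------------------------------
# Flux control coefficients
# ---------------------------------------------------------------------------

def flux_control(
    model_or_community,
    objective: str,
    perturbation: float = 0.01,
    settings: SolveSettings = DEFAULT_SETTINGS,
) -> dict[str, float]:
    """Scaled one-sided finite-difference flux control coefficients.

    From a parsimonious reference optimum v*, each reaction in turn is
    pinned down to (1 - delta) * v_j* and the objective re-optimized;
    the coefficient is (dZ/Z) / (dv_j/v_j) = ((Z - Z') / Z) / delta.
    Reactions with (numerically) zero reference flux report 0.
    """
    if not 0 < perturbation < 1:
        raise ValueError("perturbation must be in (0, 1)")
    model = _resolve_model(model_or_community)
    ref = pfba(model, objective, sense="max", settings=settings)
    if not ref.optimal:
        raise ValueError(f"no base optimum for {objective!r}: status {ref.status}")
    Z = ref.fluxes[objective]  # realized flux: keeps Z and v_j* consistent
    if Z <= settings.feasibility_tol:
        raise ValueError("flux control requires a strictly positive base optimum")

    coefficients: dict[str, float] = {}
    base_prob = LinearProblem.from_model(model)
    for r in model.reactions:
        v = ref.fluxes[r.id]
        if abs(v) <= settings.feasibility_tol or r.id == objective:
            coefficients[r.id] = 0.0
            continue
        prob = base_prob.copy()
        pinned = (1.0 - perturbation) * v
        if v > 0:
            prob.set_bounds(r.id, ub=pinned)
        else:
            prob.set_bounds(r.id, lb=pinned)
        status, _, val = prob.solve({objective: 1.0}, sense="max", settings=settings)
        if status != "optimal":
            coefficients[r.id] = math.nan
            continue
        coefficients[r.id] = ((Z - val) / Z) / perturbation
    return coefficients
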