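"""Independent LP oracles for the test suite.

These deliberately bypass the package's solver layer: they formulate the
flux system directly for ``scipy.optimize.linprog`` (dense, equality
rows), or enumerate polytope vertices outright, so that agreement with
the package is a genuine two-route check.
"""

import itertools

import numpy as np
from scipy.optimize import linprog


def _arrays(model, bound_overrides=None):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    A = S.toarray()
    lb = np.array([model.reaction(r).lower_bound for r in rxn_ids], float)
    ub = np.array([model.reaction(r).upper_bound for r in rxn_ids], float)
    if bound_overrides:
        for rid, (lo, hi) in bound_overrides.items():
            j = rxn_ids.index(rid)
            lb[j], ub[j] = lo, hi
    return A, lb, ub, rxn_ids


def optimize(model, objective, sense="max", bound_overrides=None):
    """linprog-based FBA: returns (status, objective value, flux dict)."""
    A, lb, ub, rxn_ids = _arrays(model, bound_overrides)
    c = np.zeros(len(rxn_ids))
    for rid, coef in objective.items():
        c[rxn_ids.index(rid)] += coef
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(sign * c, A_eq=A, b_eq=np.zeros(A.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:
        return "infeasible", None, {}
    if res.status == 3:
        return "unbounded", None, {}
    assert res.status == 0, res.message
    return "optimal", float(sign * res.fun), dict(zip(rxn_ids, res.x))


def feasible(model, bound_overrides=None):
    status, _, _ = optimize(model, {}, "min", bound_overrides)
    return status == "optimal"


def vertex_enumerate_max(model, objective_rid, tol=1e-9):
    """Enumerate all vertices of {v : Sv=0, lb<=v<=ub} and maximize directly.

    Only for tiny models: fixes every choice of n - rank(S) variables at a
    bound and solves the remaining square system.
    """
    A, lb, ub, rxn_ids = _arrays(model)
    n = len(rxn_ids)
    r = np.linalg.matrix_rank(A)
    n_fix = n - r
    best = None
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.full(n, np.nan)
            for j, val in zip(fixed, bounds_choice):
                v[j] = val
            rhs = -A[:, fixed] @ np.array(bounds_choice)
            sol, residual, rank, _ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
            v[free] = sol
            if np.max(np.abs(A @ v)) > 1e-7:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            val = v[rxn_ids.index(objective_rid)]
            if best is None or val > best:
                best = val
    return best


def min_total_flux_with_pinned_objective(model, objective_rid, optimum, tol=1e-9):
    """Independent parsimonious formulation: explicit v = p - q split.

    Minimizes sum(p + q) subject to S(p - q) = 0, lb <= p - q <= ub and
    the objective pinned at its optimum; returns the minimal total |v|.
    """
    A, lb, ub, rxn_ids = _arrays(model)
    n = len(rxn_ids)
    j_obj = rxn_ids.index(objective_rid)
    # variables: p (n), q (n)
    A_eq = np.hstack([A, -A])
    b_eq = np.zeros(A.shape[0])
    # pin: p_j - q_j = optimum
    pin = np.zeros(2 * n)
    pin[j_obj], pin[n + j_obj] = 1.0, -1.0
    A_eq = np.vstack([A_eq, pin])
    b_eq = np.append(b_eq, optimum)
    # bounds on v = p - q via inequality rows
    A_ub = np.vstack([
        np.hstack([np.eye(n), -np.eye(n)]),     # v <= ub
        np.hstack([-np.eye(n), np.eye(n)]),     # -v <= -lb
    ])
    b_ub = np.concatenate([ub, -lb])
    c = np.ones(2 * n)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * (2 * n), method="highs")
    assert res.status == 0, res.message
    return float(res.fun)
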