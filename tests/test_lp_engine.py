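"""FBA/pFBA/gapfill/essentiality/flux-control against independent oracles."""

import itertools
import math
import random

import numpy as np
import pytest

import oracle_lp
from symbiofba.lp_engine import (
    SolveSettings,
    essential_genes,
    fba,
    flux_control,
    gapfill,
    pfba,
)
from symbiofba.model_io import MetabolicModel, Metabolite, Reaction


def _model(mets, rxns, **kwargs):
    return MetabolicModel(
        metabolites=[Metabolite(m) for m in mets], reactions=rxns, **kwargs
    )


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


def test_fba_chain_bottleneck(chain_model):
    sol = fba(chain_model, "SK_B", sense="max")
    assert sol.optimal
    assert sol.objective_value == pytest.approx(5.0, abs=1e-8)
    assert sol.mass_balance_residual(chain_model) <= 1e-6


def test_fba_branched_toy_matches_vertex_enumeration():
    """Optimum of a branched 5-reaction network equals the best polytope vertex."""
    model = _model(
        ["a_c", "b_c"],
        [
            Reaction("EX_A", {"a_c": 1.0}, 0.0, 10.0),
            Reaction("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, 4.0),
            Reaction("R2", {"a_c": -1.0, "b_c": 1.0}, 0.0, 8.0),
            Reaction("SK_B", {"b_c": -1.0}, 0.0, 7.0),
        ],
    )
    sol = fba(model, "SK_B", sense="max")
    expected = oracle_lp.vertex_enumerate_max(model, "SK_B")
    assert sol.optimal
    assert sol.objective_value == pytest.approx(expected, abs=1e-8)
    assert sol.objective_value == pytest.approx(7.0, abs=1e-8)


def test_fba_infeasible_when_sink_has_no_producer():
    model = _model(
        ["a_c", "b_c"],
        [
            Reaction("EX_A", {"a_c": 1.0}, 0.0, 10.0),
            Reaction("SK_A", {"a_c": -1.0}, 0.0, 1000.0),
            Reaction("SK_B", {"b_c": -1.0}, 0.01, 1000.0),  # epsilon sink, no path
        ],
    )
    sol = fba(model, "SK_A", sense="max")
    assert sol.status == "infeasible"


def test_fba_unbounded_reported_as_status():
    model = _model(
        ["a_c"],
        [
            Reaction("IN", {"a_c": 1.0}, 0.0, math.inf),
            Reaction("OUT", {"a_c": -1.0}, 0.0, math.inf),
        ],
    )
    sol = fba(model, "OUT", sense="max")
    assert sol.status == "unbounded"


def test_fba_invariant_under_row_and_column_permutation():
    rng = random.Random(5)
    mets = ["a_c", "b_c", "c_c"]
    rxns = [
        Reaction("EX_A", {"a_c": 1.0}, 0.0, 6.0),
        Reaction("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
        Reaction("R2", {"b_c": -1.0, "c_c": 2.0}, 0.0, 1000.0),
        Reaction("SK_C", {"c_c": -1.0}, 0.0, 1000.0),
    ]
    base = fba(_model(mets, rxns), "SK_C").objective_value
    for _ in range(5):
        pm = list(mets)
        pr = [r.copy() for r in rxns]
        rng.shuffle(pm)
        rng.shuffle(pr)
        assert fba(_model(pm, pr), "SK_C").objective_value == pytest.approx(base, abs=1e-8)


def test_fba_agrees_with_cobra_glpk():
    """Independent solver cross-check on a branched network."""
    cobra = pytest.importorskip("cobra")
    rxns = [
        Reaction("EX_A", {"a_c": 1.0}, 0.0, 10.0),
        Reaction("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, 4.0),
        Reaction("R2", {"a_c": -2.0, "b_c": 1.0, "c_c": 1.0}, 0.0, 8.0),
        Reaction("SK_C", {"c_c": -1.0}, 0.0, 1000.0),
        Reaction("SK_B", {"b_c": -1.0}, 0.0, 7.0),
    ]
    model = _model(["a_c", "b_c", "c_c"], rxns)
    ours = fba(model, "SK_B", sense="max").objective_value

    cm = cobra.Model("check")
    cm.solver = "glpk"
    cmets = {m: cobra.Metabolite(m) for m in ["a_c", "b_c", "c_c"]}
    for r in rxns:
        cr = cobra.Reaction(r.id)
        cr.lower_bound, cr.upper_bound = r.lower_bound, r.upper_bound
        cm.add_reactions([cr])
        cr.add_metabolites({cmets[m]: c for m, c in r.stoichiometry.items()})
    cm.objective = "SK_B"
    theirs = cm.optimize().objective_value
    assert ours == pytest.approx(theirs, abs=1e-6)


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------


def _parallel_routes_model():
    # 1-step route A->B vs 3-step route A->X->Y->B, equal yield
    return _model(
        ["a_c", "b_c", "x_c", "y_c"],
        [
            Reaction("EX_A", {"a_c": 1.0}, 0.0, 5.0),
            Reaction("DIRECT", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
            Reaction("S1", {"a_c": -1.0, "x_c": 1.0}, 0.0, 1000.0),
            Reaction("S2", {"x_c": -1.0, "y_c": 1.0}, 0.0, 1000.0),
            Reaction("S3", {"y_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
            Reaction("SK_B", {"b_c": -1.0}, 0.0, 1000.0),
        ],
    )


def test_pfba_prefers_the_short_route():
    model = _parallel_routes_model()
    sol = pfba(model, "SK_B", sense="max")
    assert sol.optimal
    assert sol.fluxes["DIRECT"] == pytest.approx(5.0, abs=1e-6)
    assert sol.fluxes["S1"] == pytest.approx(0.0, abs=1e-6)


def test_pfba_objective_equals_fba_objective():
    model = _parallel_routes_model()
    assert pfba(model, "SK_B").objective_value == pytest.approx(
        fba(model, "SK_B").objective_value, abs=1e-8
    )


def test_pfba_total_flux_matches_independent_split_formulation():
    """Total |v| agrees with a direct p/q-split LP at the pinned optimum."""
    model = _parallel_routes_model()
    first = fba(model, "SK_B")
    sol = pfba(model, "SK_B")
    ours = sum(abs(v) for v in sol.fluxes.values())
    theirs = oracle_lp.min_total_flux_with_pinned_objective(
        model, "SK_B", first.objective_value
    )
    assert ours == pytest.approx(theirs, abs=1e-6)
    # and pFBA never uses more total flux than the plain FBA vertex
    plain = sum(abs(v) for v in first.fluxes.values())
    assert ours <= plain + 1e-6


# ---------------------------------------------------------------------------
# Gapfill
# ---------------------------------------------------------------------------


def _gap_instance():
    """Chain with two independent planted gaps and decoy candidates."""
    mets = ["a_c", "b_c", "c_c", "d_c", "e_c", "x1_c", "x2_c"]
    model = _model(
        mets,
        [
            Reaction("EX_A", {"a_c": 1.0}, 0.0, 10.0),
            Reaction("R_BC", {"b_c": -1.0, "c_c": 1.0}, 0.0, 1000.0),
            Reaction("EX_D", {"d_c": 1.0}, 0.0, 10.0),
        ],
        biomass_precursors=["c_c", "e_c"],
    )
    universal = _model(
        mets,
        [
            Reaction("R_AB", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),  # gap 1
            Reaction("R_DE", {"d_c": -1.0, "e_c": 1.0}, 0.0, 1000.0),  # gap 2
            Reaction("U1", {"a_c": -1.0, "x1_c": 1.0}, 0.0, 1000.0),
            Reaction("U2", {"x1_c": -1.0, "x2_c": 1.0}, 0.0, 1000.0),
            Reaction("U3", {"x2_c": -1.0, "a_c": 1.0}, 0.0, 1000.0),
            Reaction("U4", {"d_c": -1.0, "x1_c": 1.0}, 0.0, 1000.0),
            Reaction("U5", {"b_c": -1.0, "x2_c": 1.0}, 0.0, 1000.0),
            Reaction("U6", {"c_c": -1.0, "x1_c": 1.0}, 0.0, 1000.0),
            Reaction("U7", {"e_c": -1.0, "x2_c": 1.0}, 0.0, 1000.0),
            Reaction("U8", {"x1_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
        ],
    )
    return model, universal


def test_gapfill_already_feasible_adds_nothing(chain_model):
    universal = _model(["a_c", "b_c"], [Reaction("UX", {"a_c": -1.0, "b_c": 1.0}, 0, 10)])
    chain = chain_model.copy()
    chain.biomass_precursors = ["b_c"]
    res = gapfill(chain, universal, ["b_c"])
    assert res.feasible_after and res.added_reactions == frozenset()


def test_gapfill_recovers_single_planted_gap():
    model, universal = _gap_instance()
    res = gapfill(model, universal, ["c_c"])
    assert res.feasible_after
    assert res.added_reactions == {"R_AB"}


def _brute_force_gapfill(model, universal, targets, epsilon=0.01, max_size=4):
    """Subset-enumeration oracle via the independent linprog feasibility check."""
    cand = list(universal.reactions)
    for size in range(max_size + 1):
        hits = []
        for subset in itertools.combinations(cand, size):
            probe = model.copy()
            probe.add_reactions([r.copy() for r in subset])
            for t in targets:
                probe.add_reactions(
                    [Reaction(f"SK_{t}", {t: -1.0}, epsilon, 1000.0)]
                )
            if oracle_lp.feasible(probe):
                hits.append(frozenset(r.id for r in subset))
        if hits:
            return size, hits
    return None, []


def test_gapfill_two_gaps_match_brute_force_minimum():
    model, universal = _gap_instance()
    res = gapfill(model, universal, ["c_c", "e_c"])
    size, minimal_sets = _brute_force_gapfill(model, universal, ["c_c", "e_c"])
    assert res.feasible_after
    assert len(res.added_reactions) == size == 2
    assert res.added_reactions in minimal_sets


def test_gapfill_reports_unfillable_targets():
    model, universal = _gap_instance()
    res = gapfill(model, universal, ["c_c", "x1_c", "e_c"])
    # x1 is producible; remove every path by gutting the universal set
    tiny_universal = _model(["a_c", "b_c"], [Reaction("R_AB", {"a_c": -1.0, "b_c": 1.0}, 0, 10)])
    res2 = gapfill(model, tiny_universal, ["c_c", "e_c"])
    assert res.feasible_after
    assert not res2.feasible_after
    assert res2.blocked_precursors == ("e_c",)


# ---------------------------------------------------------------------------
# Essentiality
# ---------------------------------------------------------------------------


def _essentiality_model():
    mets = ["n2_c", "nh3_c", "p1_c", "p2_c"]
    model = _model(
        mets,
        [
            Reaction("EX_N2", {"n2_c": 1.0}, 0.0, 1000.0),
            Reaction("NIT", {"n2_c": -1.0, "nh3_c": 2.0}, 0.0, 1000.0, gpr="nifH"),
            Reaction("SYN_P1", {"nh3_c": -1.0, "p1_c": 1.0}, 0.0, 1000.0, gpr="gA or gB"),
            Reaction("SYN_P2", {"nh3_c": -1.0, "p2_c": 1.0}, 0.0, 1000.0, gpr="gC"),
            Reaction("SK_p1_c", {"p1_c": -1.0}, 0.01, 1000.0),
            Reaction("SK_p2_c", {"p2_c": -1.0}, 0.01, 1000.0),
        ],
        biomass_precursors=["p1_c", "p2_c"],
    )
    return model


def test_nitrogenase_gene_blocks_all_nitrogenous_precursors():
    result = essential_genes(_essentiality_model())
    assert result["nifH"] == {"p1_c", "p2_c"}
    assert result["gC"] == {"p2_c"}
    assert result["gA"] == frozenset()  # paralog gB covers the OR rule


def test_essentiality_matches_brute_force_knockout_oracle():
    """Independent check: remove knocked-out reactions and probe each sink
    with a direct linprog feasibility test."""
    model = _essentiality_model()
    result = essential_genes(model)
    genes = model.genes()
    for gene in genes:
        remaining = genes - {gene}
        expected = set()
        for prec in model.biomass_precursors:
            probe = model.copy()
            overrides = {}
            for r in probe.reactions:
                if not r.gene_rule.is_empty and not r.gene_rule.evaluate(remaining):
                    overrides[r.id] = (0.0, 0.0)
                if r.id.startswith("SK_") and r.id != f"SK_{prec}":
                    overrides[r.id] = (0.0, r.upper_bound)
            if not oracle_lp.feasible(probe, overrides):
                expected.add(prec)
        assert result[gene] == expected, gene


# ---------------------------------------------------------------------------
# Flux control
# ---------------------------------------------------------------------------


def test_flux_control_chain_bottleneck_is_one(chain_model):
    coeffs = flux_control(chain_model, "SK_B", perturbation=0.01)
    assert coeffs["EX_A"] == pytest.approx(1.0, abs=1e-6)
    assert coeffs["R_AB"] == pytest.approx(1.0, abs=1e-6)


def test_flux_control_redundant_parallel_reaction_is_zero():
    model = _model(
        ["a_c", "b_c"],
        [
            Reaction("EX_A", {"a_c": 1.0}, 0.0, 5.0),
            Reaction("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, 10.0),
            Reaction("R2", {"a_c": -1.0, "b_c": 1.0}, 0.0, 10.0),
            Reaction("SK_B", {"b_c": -1.0}, 0.0, 1000.0),
        ],
    )
    coeffs = flux_control(model, "SK_B", perturbation=0.01)
    assert coeffs["R1"] == pytest.approx(0.0, abs=1e-6)
    assert coeffs["R2"] == pytest.approx(0.0, abs=1e-6)
    assert coeffs["EX_A"] == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("delta", [0.01, 0.05])
def test_flux_control_matches_direct_reoptimization(delta):
    """6-reaction toy: coefficients equal an independent linprog re-solve."""
    model = _model(
        ["a_c", "b_c", "c_c"],
        [
            Reaction("EX_A", {"a_c": 1.0}, 0.0, 6.0),
            Reaction("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, 4.0),
            Reaction("R2", {"a_c": -1.0, "c_c": 1.0}, 0.0, 1000.0),
            Reaction("R3", {"c_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
            Reaction("SK_B", {"b_c": -1.0}, 0.0, 1000.0),
        ],
    )
    coeffs = flux_control(model, "SK_B", perturbation=delta)
    ref = pfba(model, "SK_B")
    Z = ref.objective_value
    for rid, v in ref.fluxes.items():
        if abs(v) <= 1e-6 or rid == "SK_B":
            continue
        overrides = {rid: (model.reaction(rid).lower_bound, (1 - delta) * v)}
        status, z2, _ = oracle_lp.optimize(model, {"SK_B": 1.0}, "max", overrides)
        assert status == "optimal"
        expected = ((Z - z2) / Z) / delta
        assert coeffs[rid] == pytest.approx(expected, abs=1e-6)
        assert -1e-9 <= coeffs[rid] <= 1.0 + 1e-9
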