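"""The community MILP programs: minimal transfers, enumeration,
fixation maximization, substrate ranking, O2 scavenging."""

import math

import pytest

from symbiofba.community import SymbiosisConfig
from symbiofba.symbiosis import (
    InfeasibleCommunityError,
    build_program,
    compare_o2_scavenging,
    enumerate_scenarios,
    infer_alternate_groups,
    max_fixation,
    min_transfers,
    rank_substrates,
)
from symbiofba.synthetic_data import (
    ToyCommunitySpec,
    brute_force_min_transfers,
    generate_toy_community,
)


# ---------------------------------------------------------------------------
# min_transfers
# ---------------------------------------------------------------------------


def test_self_sufficient_symbiont_needs_zero_transfers():
    spec = ToyCommunitySpec(n_precursors=4, n_essential_auxotrophies=0,
                            n_decoy_candidates=3, seed=5)
    comm, truth = generate_toy_community(spec)
    assert truth.minimal_transfer_count == 0
    scenario = min_transfers(comm)
    assert scenario.objective_count == 0
    assert scenario.active_transfers == frozenset()


def test_planted_essentials_recovered_and_match_subset_oracle(default_toy):
    comm, truth = default_toy
    scenario = min_transfers(comm)
    oracle = brute_force_min_transfers(comm)
    assert scenario.objective_count == truth.minimal_transfer_count == oracle.count
    assert scenario.active_transfers == truth.essential_set
    assert scenario.active_transfers in oracle.minimal_sets


def test_min_transfers_infeasible_without_candidates_names_blocked_sinks():
    spec = ToyCommunitySpec(n_precursors=3, n_essential_auxotrophies=2,
                            n_decoy_candidates=0, seed=2)
    comm, _ = generate_toy_community(spec)
    # close every transfer candidate: the auxotrophies become unservable
    comm.transfers_host_to_sym = []
    comm.transfers_sym_to_host = []
    comm._merged = None
    with pytest.raises(InfeasibleCommunityError) as err:
        min_transfers(comm)
    assert len(err.value.blocked_sinks) == 2


def test_scenario_fluxes_respect_mass_balance_and_sinks(default_toy):
    comm, _ = default_toy
    scenario = min_transfers(comm)
    merged = comm.merged_model()
    assert scenario.fluxes.status == "optimal"
    assert scenario.fluxes.mass_balance_residual(merged) <= 1e-6
    for sid in comm.precursor_sinks.values():
        assert scenario.fluxes[sid] >= 0.01 - 1e-6
    # inactive transfers carry no flux; active ones carry > threshold
    for t in comm.transfers:
        flux = scenario.fluxes[t.id]
        if t.id in scenario.active_transfers:
            assert flux > 1e-6
        else:
            assert flux <= 1e-6


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def test_enumeration_recovers_all_minimal_sets(or_group_toy):
    comm, truth = or_group_toy
    result = enumerate_scenarios(comm, mode="optimal_only", k=50)
    oracle = brute_force_min_transfers(comm)
    found = {s.active_transfers for s in result.scenarios}
    assert found == set(oracle.minimal_sets)
    assert len(found) == len(result.scenarios)  # pairwise distinct
    # 2-way x 3-way planted alternatives -> 6 optimal scenarios
    assert len(found) == 6


def test_enumeration_groups_match_planted_structure(or_group_toy):
    comm, truth = or_group_toy
    result = enumerate_scenarios(comm, mode="optimal_only", k=50)
    assert result.essential_transfers == truth.essential_set
    assert set(result.alternate_groups) == set(truth.alternate_groups)


def test_unique_optimum_yields_single_optimal_scenario(default_toy):
    comm, _ = default_toy
    result = enumerate_scenarios(comm, mode="optimal_only", k=10)
    assert len(result.scenarios) == 1


def test_integer_cut_excludes_its_own_solution(default_toy):
    """Appending the cut for a solution makes that exact active set infeasible."""
    comm, _ = default_toy
    config = SymbiosisConfig()
    scenario = min_transfers(comm, config)
    prob = build_program(comm, config, with_binaries=True)
    active = scenario.active_transfers
    prob.add_constraint({f"__y__{t}": 1.0 for t in active}, -math.inf, len(active) - 1)
    for t in comm.transfers:  # pin y to the excluded solution
        prob.fix(f"__y__{t.id}", 1.0 if t.id in active else 0.0)
    status, _, _ = prob.solve({}, sense="min")
    assert status == "infeasible"


def test_nondecreasing_mode_objective_is_monotone(or_group_toy):
    comm, _ = or_group_toy
    result = enumerate_scenarios(comm, mode="nondecreasing", k=12)
    counts = [s.objective_count for s in result.scenarios]
    assert counts == sorted(counts)
    assert len({s.active_transfers for s in result.scenarios}) == len(result.scenarios)


# ---------------------------------------------------------------------------
# max_fixation
# ---------------------------------------------------------------------------


def test_max_fixation_hand_computed_optimum(default_toy):
    """Fixation is reductant-limited: the glucose import allowed by the
    carbon fraction bounds ferredoxin, hence vN2 = 10*g / 8.

    Carbon budget: 6*g + (carbon in epsilon precursor transfers)
    <= 0.17 * 10; with seed-1 precursors (C3+C2+C3 at 0.01 each) the
    sink share is 0.08, so g = (1.7-0.08)/6 = 0.27 and vN2 = 0.3375.
    """
    comm, truth = default_toy
    res = max_fixation(comm)
    sink_carbon = sum(
        0.01 * t.n_carbon
        for t in comm.transfers_host_to_sym
        if t.id in truth.essential_set
    )
    g = (0.17 * 10.0 - sink_carbon) / 6.0
    assert res.n2_flux == pytest.approx(10.0 * g / 8.0, abs=1e-6)
    # the N return rides home as ammonia
    assert res.scenario is not None
    assert res.scenario.fluxes["TR_s2h_nh3_c"] >= 1.9 * res.n2_flux - 1e-6


def test_max_fixation_zero_when_nitrogen_cannot_return(default_toy):
    """Blocking every symbiont->host transfer pins fixation at zero: the
    95%-return constraint forbids retaining fixed nitrogen."""
    comm, _ = default_toy
    res = max_fixation(comm, disabled_reactions=[t.id for t in comm.transfers_sym_to_host])
    assert res.n2_flux == 0.0


@pytest.mark.parametrize("fractions", [(0.17, 0.10, 0.05)])
def test_max_fixation_monotone_in_carbon_fraction(default_toy, fractions):
    comm, _ = default_toy
    fluxes = [
        max_fixation(comm, SymbiosisConfig(carbon_fraction=f)).n2_flux
        for f in fractions
    ]
    assert fluxes[0] >= fluxes[1] >= fluxes[2]
    assert fluxes[2] > 0


def test_max_fixation_monotone_in_co2_basis(default_toy):
    comm, _ = default_toy
    fluxes = [
        max_fixation(comm, SymbiosisConfig(co2_basis_fixation=b)).n2_flux
        for b in (10.0, 5.0, 1.0)
    ]
    assert fluxes[0] >= fluxes[1] >= fluxes[2] > 0


# ---------------------------------------------------------------------------
# substrate ranking
# ---------------------------------------------------------------------------


def test_rank_substrates_orders_by_reductant_yield():
    """Two substrates with ferredoxin yields 12 vs 8 per unit (fixation
    reductant-limited) rank 3:2 in fixation yield."""
    spec = ToyCommunitySpec(
        substrates=(("glc__D", 30.0, 8.0), ("fru", 30.0, 12.0)), seed=4
    )
    comm, truth = generate_toy_community(spec)
    ranking = rank_substrates(comm, ["glc__D_c", "fru_c"])
    assert [r.metabolite for r in ranking] == list(truth.expected_yield_order)
    assert ranking[0].metabolite == "fru_c"
    assert ranking[0].n2_yield == pytest.approx(1.5 * ranking[1].n2_yield, rel=1e-4)
    assert all(r.n2_yield >= 0 for r in ranking)
    # reductant-producing flux is reported for the bar-chart style summary
    assert ranking[0].nadph_flux > 0


def test_rank_substrates_zero_yield_for_unusable_candidate():
    """A decoy with no catabolic route supports no fixation: yield 0."""
    spec = ToyCommunitySpec(seed=1)
    comm, _ = generate_toy_community(spec)
    decoy = next(
        t.metabolite for t in comm.transfers_host_to_sym
        if t.metabolite not in ("glc__D_c",)
        and f"sym:DUMP_{t.metabolite[:-2]}" in comm.merged_model().reaction_ids
    )
    ranking = rank_substrates(comm, [decoy, "glc__D_c"])
    by_met = {r.metabolite: r for r in ranking}
    assert by_met[decoy].n2_yield == 0.0
    assert by_met["glc__D_c"].n2_yield > 0.0
    assert ranking[0].metabolite == "glc__D_c"


def test_rank_substrates_order_invariant(default_toy):
    comm, _ = default_toy
    cands = [t.metabolite for t in comm.transfers_host_to_sym][:4]
    a = rank_substrates(comm, cands)
    b = rank_substrates(comm, list(reversed(cands)))
    assert [r.metabolite for r in a] == [r.metabolite for r in b]
    for ra, rb in zip(a, b):
        assert ra.n2_yield == pytest.approx(rb.n2_yield, abs=1e-9)


# ---------------------------------------------------------------------------
# O2 scavenging
# ---------------------------------------------------------------------------


def test_o2_flux_ratio_equals_planted_atp_ratio(o2_toy):
    comm, truth = o2_toy
    result = compare_o2_scavenging(comm)
    assert result.ratio == pytest.approx(truth.expected_o2_flux_ratio, abs=1e-6)
    assert result.fluxes["mehler"] > result.fluxes["cytochrome"] > 0


def test_o2_cytochrome_flux_is_atp_limited_analytic(o2_toy):
    """vN2 = (ATP per O2) * (fixed O2) / (ATP per N2) = 18 * 0.1 / 16."""
    comm, _ = o2_toy
    result = compare_o2_scavenging(comm)
    assert result.fluxes["cytochrome"] == pytest.approx(18.0 * 0.1 / 16.0, abs=1e-6)


def test_forced_o2_with_no_scavenger_is_infeasible(o2_toy):
    comm, _ = o2_toy
    with pytest.raises(InfeasibleCommunityError):
        max_fixation(
            comm,
            disabled_reactions=list(comm.o2_mechanisms.values()),
            o2_fixed=0.1,
        )
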