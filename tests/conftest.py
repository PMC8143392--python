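"""Shared fixtures: small hand-built models and generated toy communities."""

import pytest

from symbiofba import (
    MetabolicModel,
    Metabolite,
    Reaction,
    SymbiosisConfig,
    ToyCommunitySpec,
    generate_toy_community,
)


def linear_chain_model() -> MetabolicModel:
    """EX_A -> A -> B -> sink, with a 5-unit bottleneck on uptake."""
    return MetabolicModel(
        id="chain",
        metabolites=[
            Metabolite("a_c", formula="C2H4O2"),
            Metabolite("b_c", formula="C2H4O2"),
        ],
        reactions=[
            Reaction("EX_A", {"a_c": 1.0}, 0.0, 5.0),
            Reaction("R_AB", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
            Reaction("SK_B", {"b_c": -1.0}, 0.0, 1000.0),
        ],
    )


@pytest.fixture
def chain_model():
    return linear_chain_model()


@pytest.fixture
def default_toy():
    """Canonical toy community: 3 essential auxotrophies, no OR-groups."""
    spec = ToyCommunitySpec(seed=1)
    return generate_toy_community(spec)


@pytest.fixture
def or_group_toy():
    """Toy with one 2-way and one 3-way alternative group."""
    spec = ToyCommunitySpec(
        n_precursors=6, n_essential_auxotrophies=2, or_groups=(2, 3), seed=7
    )
    return generate_toy_community(spec)


@pytest.fixture
def o2_toy():
    spec = ToyCommunitySpec(include_o2_mechanisms=True, o2_atp_ratio=1.15, seed=3)
    return generate_toy_community(spec)
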