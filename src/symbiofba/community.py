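"""Two-organism community assembly.

A community joins a phototrophic host model and a diazotrophic symbiont
model in one namespaced stoichiometric system.  The two cytosols are
linked by forward-only transfer reactions, one per candidate metabolite
per direction, each carrying the metabolite's carbon and nitrogen atom
counts (N_c,j, N_N,j).  The symbiont has no biomass reaction: its (unknown)
biomass composition is replaced by a sink per biomass precursor with a
small positive lower bound epsilon, so that "growth" means every
precursor is producible at epsilon.

Two community-level exchange constraints encode measured transfer
fractions: at most ``carbon_fraction`` of the carbon fixed by the host
(CO2 uptake flux, one C atom per unit) may flow to the symbiont through
transfers, and at least ``2 * nitrogen_fraction`` of the nitrogen fixed
by the symbiont (two N atoms per N2) must return to the host.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model_io import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    parse_formula,
    read_model,
    write_model,
)

__all__ = [
    "HOST_PREFIX",
    "SYM_PREFIX",
    "DEFAULT_CURRENCY",
    "HOST_TO_SYM",
    "SYM_TO_HOST",
    "SymbiosisConfig",
    "TransferReaction",
    "CommunityModel",
    "CommunityBuildError",
    "build_community",
    "exchange_constraint_rows",
    "write_community",
    "read_community",
]

HOST_PREFIX = "host:"
SYM_PREFIX = "sym:"
HOST_TO_SYM = "host_to_sym"
SYM_TO_HOST = "sym_to_host"

#: Currency species never counted as transfer candidates (they may still
#: move through the shared medium as free exchanges).
DEFAULT_CURRENCY = frozenset({"photon", "h", "h2o", "pi", "e"})


class CommunityBuildError(ValueError):
    """Raised when a community cannot be assembled as configured."""


@dataclass(frozen=True)
class SymbiosisConfig:
    """All community-level constants.

    epsilon            lower bound on each biomass precursor sink
                       (mmol gDW^-1 hr^-1)
    big_M              transfer flux cap linked to the binary activations
    max_scenarios      integer-cut enumeration budget K
    carbon_fraction    max fraction of host-fixed carbon transferable
    nitrogen_fraction  min fraction of fixed nitrogen returned to host
    co2_basis          CO2 uptake cap for transfer-set minimization
    co2_basis_fixation CO2 uptake cap for fixation maximization
    o2_fixed_uptake    symbiont O2 uptake fixed during the scavenging
                       comparison
    """

    epsilon: float = 0.01
    big_M: float = 1000.0
    max_scenarios: int = 100
    carbon_fraction: float = 0.17
    nitrogen_fraction: float = 0.95
    co2_basis: float = 100.0
    co2_basis_fixation: float = 10.0
    o2_fixed_uptake: float = 0.1

    def __post_init__(self):
        for name in ("epsilon", "big_M", "carbon_fraction", "nitrogen_fraction",
                     "co2_basis", "co2_basis_fixation", "o2_fixed_uptake"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_scenarios < 1:
            raise ValueError("max_scenarios must be >= 1")
        for name in ("carbon_fraction", "nitrogen_fraction"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class TransferReaction:
    """Forward-only inter-organism transport of one metabolite."""

    id: str
    metabolite: str  # unprefixed metabolite id, e.g. "glc__D_c"
    direction: str  # HOST_TO_SYM or SYM_TO_HOST
    n_carbon: int
    n_nitrogen: int
    cap: float = 1000.0

    def __post_init__(self):
        if self.direction not in (HOST_TO_SYM, SYM_TO_HOST):
            raise ValueError(f"bad transfer direction {self.direction!r}")
        if self.n_carbon < 0 or self.n_nitrogen < 0:
            raise ValueError("atom counts must be nonnegative")
        if self.cap <= 0:
            raise ValueError("transfer cap must be positive")

    def to_reaction(self) -> Reaction:
        if self.direction == HOST_TO_SYM:
            stoich = {HOST_PREFIX + self.metabolite: -1.0, SYM_PREFIX + self.metabolite: 1.0}
        else:
            stoich = {SYM_PREFIX + self.metabolite: -1.0, HOST_PREFIX + self.metabolite: 1.0}
        return Reaction(
            id=self.id,
            stoichiometry=stoich,
            lower_bound=0.0,
            upper_bound=self.cap,
            name=f"transfer {self.metabolite} ({self.direction})",
            subsystem="transfer",
        )


def _prefix_model(model: MetabolicModel, prefix: str) -> MetabolicModel:
    mets = [replace(m, id=prefix + m.id) for m in model.metabolites]
    rxns = []
    for r in model.reactions:
        rxns.append(
            Reaction(
                id=prefix + r.id,
                stoichiometry={prefix + m: c for m, c in r.stoichiometry.items()},
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                name=r.name,
                gpr=r.gpr,
                subsystem=r.subsystem,
            )
        )
    return MetabolicModel(
        id=model.id,
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=(
            None if model.biomass_reaction_id is None else prefix + model.biomass_reaction_id
        ),
        biomass_precursors=[prefix + p for p in model.biomass_precursors],
        medium={prefix + k: v for k, v in model.medium.items()},
    )


@dataclass
class CommunityModel:
    """Host + symbiont joined by transfer reactions and precursor sinks.

    ``host`` and ``symbiont`` are stored with their ids already prefixed
    ("host:" / "sym:"); transfer and sink reactions live only in the
    merged view returned by :meth:`merged_model`.
    """

    host: MetabolicModel
    symbiont: MetabolicModel
    transfers_host_to_sym: list[TransferReaction]
    transfers_sym_to_host: list[TransferReaction]
    n2_fixation_reaction: str
    co2_exchange_reaction: str
    o2_uptake_reaction: str | None = None
    o2_mechanisms: dict[str, str] = field(default_factory=dict)
    precursor_sinks: dict[str, str] = field(default_factory=dict)
    epsilon: float = 0.01
    atp_reactions: tuple[str, ...] = ()
    nadph_reactions: tuple[str, ...] = ()

    def __post_init__(self):
        self._merged: MetabolicModel | None = None

    @property
    def transfers(self) -> list[TransferReaction]:
        return [*self.transfers_host_to_sym, *self.transfers_sym_to_host]

    def transfer(self, tid: str) -> TransferReaction:
        for t in self.transfers:
            if t.id == tid:
                return t
        raise KeyError(tid)

    def merged_model(self) -> MetabolicModel:
        if self._merged is None:
            merged = MetabolicModel(
                id=f"{self.host.id}+{self.symbiont.id}",
                metabolites=[*self.host.metabolites, *self.symbiont.metabolites],
                reactions=[
                    *[r.copy() for r in self.host.reactions],
                    *[r.copy() for r in self.symbiont.reactions],
                ],
                biomass_reaction_id=self.host.biomass_reaction_id,
                biomass_precursors=list(self.symbiont.biomass_precursors),
                medium={**self.host.medium, **self.symbiont.medium},
            )
            merged.add_reactions([t.to_reaction() for t in self.transfers])
            sinks = []
            for prec, sid in self.precursor_sinks.items():
                sinks.append(
                    Reaction(
                        id=sid,
                        stoichiometry={prec: -1.0},
                        lower_bound=self.epsilon,
                        upper_bound=1000.0,
                        name=f"biomass precursor sink for {prec}",
                        subsystem="biomass",
                    )
                )
            merged.add_reactions(sinks)
            merged.validate()
            for rid in (self.n2_fixation_reaction, self.co2_exchange_reaction):
                if not merged.has_reaction(rid):
                    raise CommunityBuildError(f"designated reaction {rid!r} not in community")
            self._merged = merged
        return self._merged

    def validate(self) -> None:
        self.merged_model()


def _base_id(met_id: str) -> str:
    """Strip the compartment suffix: 'glc__D_c' -> 'glc__D'."""
    if "_" in met_id:
        stem, _, comp = met_id.rpartition("_")
        if len(comp) == 1:
            return stem
    return met_id


def _atom_counts(model: MetabolicModel, met_id: str) -> tuple[int, int]:
    met = model.metabolite(met_id)
    if met.formula is None:
        raise CommunityBuildError(
            f"transfer candidate {met_id!r} has no formula; carbon/nitrogen "
            "atom counts are undefined"
        )
    counts = parse_formula(met.formula)
    return counts.get("C", 0), counts.get("N", 0)


def _auto_candidates(
    host: MetabolicModel, symbiont: MetabolicModel, deny: frozenset[str]
) -> dict[str, list[str]]:
    """Default policy: every cytosolic metabolite present in both models,
    both directions, excluding currency species."""
    shared = sorted(
        m.id
        for m in host.metabolites
        if m.compartment == "c"
        and m.formula is not None  # atom counts must be computable
        and symbiont.has_metabolite(m.id)
        and _base_id(m.id) not in deny
    )
    return {HOST_TO_SYM: shared, SYM_TO_HOST: list(shared)}


def build_community(
    host: MetabolicModel,
    symbiont: MetabolicModel,
    config: SymbiosisConfig | None = None,
    *,
    host_co2_exchange: str,
    sym_n2_fixation: str,
    sym_o2_uptake: str | None = None,
    o2_mechanisms: Mapping[str, str] | None = None,
    candidates: Mapping[str, Sequence[str]] | None = None,
    deny: Iterable[str] = DEFAULT_CURRENCY,
    atp_reactions: Sequence[str] = (),
    nadph_reactions: Sequence[str] = (),
) -> CommunityModel:
    """Assemble a CommunityModel from two standalone models.

    ``candidates`` maps direction ("host_to_sym" / "sym_to_host") to
    unprefixed metabolite ids; when omitted, every cytosolic metabolite
    shared by both models (minus the deny list of currency species)
    becomes a candidate in both directions.  Reaction ids passed for the
    designated reactions are unprefixed host/symbiont ids.
    """
    config = config or SymbiosisConfig()
    host.validate()
    symbiont.validate()
    if not host.has_reaction(host_co2_exchange):
        raise CommunityBuildError(f"host CO2 exchange {host_co2_exchange!r} not found")
    if not symbiont.has_reaction(sym_n2_fixation):
        raise CommunityBuildError(f"symbiont N2 fixation {sym_n2_fixation!r} not found")
    if sym_o2_uptake is not None and not symbiont.has_reaction(sym_o2_uptake):
        raise CommunityBuildError(f"symbiont O2 uptake {sym_o2_uptake!r} not found")
    o2_mechanisms = dict(o2_mechanisms or {})
    for name, rid in o2_mechanisms.items():
        if not symbiont.has_reaction(rid):
            raise CommunityBuildError(f"O2 mechanism {name!r}: reaction {rid!r} not found")

    if candidates is None:
        candidates = _auto_candidates(host, symbiont, frozenset(deny))
    for direction in candidates:
        if direction not in (HOST_TO_SYM, SYM_TO_HOST):
            raise CommunityBuildError(f"unknown transfer direction {direction!r}")

    h2s: list[TransferReaction] = []
    s2h: list[TransferReaction] = []
    for direction, mets in candidates.items():
        for met_id in mets:
            for model, side in ((host, "host"), (symbiont, "symbiont")):
                if not model.has_metabolite(met_id):
                    raise CommunityBuildError(
                        f"transfer candidate {met_id!r} missing from the {side} model"
                    )
            n_c, n_n = _atom_counts(host, met_id)
            tag = "h2s" if direction == HOST_TO_SYM else "s2h"
            tr = TransferReaction(
                id=f"TR_{tag}_{met_id}",
                metabolite=met_id,
                direction=direction,
                n_carbon=n_c,
                n_nitrogen=n_n,
                cap=config.big_M,
            )
            (h2s if direction == HOST_TO_SYM else s2h).append(tr)

    host_p = _prefix_model(host, HOST_PREFIX)
    sym_p = _prefix_model(symbiont, SYM_PREFIX)
    sinks = {p: f"SK_{p}" for p in sym_p.biomass_precursors}

    community = CommunityModel(
        host=host_p,
        symbiont=sym_p,
        transfers_host_to_sym=h2s,
        transfers_sym_to_host=s2h,
        n2_fixation_reaction=SYM_PREFIX + sym_n2_fixation,
        co2_exchange_reaction=HOST_PREFIX + host_co2_exchange,
        o2_uptake_reaction=None if sym_o2_uptake is None else SYM_PREFIX + sym_o2_uptake,
        o2_mechanisms={k: SYM_PREFIX + v for k, v in o2_mechanisms.items()},
        precursor_sinks=sinks,
        epsilon=config.epsilon,
        atp_reactions=tuple(atp_reactions),
        nadph_reactions=tuple(nadph_reactions),
    )
    community.validate()
    return community


def exchange_constraint_rows(
    community: CommunityModel, config: SymbiosisConfig
) -> tuple[tuple[dict[str, float], float, float], tuple[dict[str, float], float, float]]:
    """The two community exchange constraints as (coeffs, lo, hi) rows.

    Carbon:    sum_j N_c,j v_j - carbon_fraction * vCO2exchange        <= 0
    Nitrogen:  sum_j N_N,j v_j - 2 * nitrogen_fraction * vN2fixation   >= 0
    """
    carbon = {t.id: float(t.n_carbon) for t in community.transfers_host_to_sym if t.n_carbon}
    carbon[community.co2_exchange_reaction] = (
        carbon.get(community.co2_exchange_reaction, 0.0) - config.carbon_fraction
    )
    nitrogen = {t.id: float(t.n_nitrogen) for t in community.transfers_sym_to_host if t.n_nitrogen}
    nitrogen[community.n2_fixation_reaction] = (
        nitrogen.get(community.n2_fixation_reaction, 0.0) - 2.0 * config.nitrogen_fraction
    )
    return (carbon, -math.inf, 0.0), (nitrogen, 0.0, math.inf)


# ---------------------------------------------------------------------------
# Community serialization
# ---------------------------------------------------------------------------

def write_community(community: CommunityModel, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_model(community.host, path / "host")
    write_model(community.symbiont, path / "symbiont")
    rows = [
        {
            "id": t.id,
            "metabolite": t.metabolite,
            "direction": t.direction,
            "n_carbon": t.n_carbon,
            "n_nitrogen": t.n_nitrogen,
            "cap": t.cap,
        }
        for t in community.transfers
    ]
    pd.DataFrame(
        rows, columns=["id", "metabolite", "direction", "n_carbon", "n_nitrogen", "cap"]
    ).to_csv(path / "transfers.tsv", sep="\t", index=False)
    meta = {
        "n2_fixation_reaction": community.n2_fixation_reaction,
        "co2_exchange_reaction": community.co2_exchange_reaction,
        "o2_uptake_reaction": community.o2_uptake_reaction,
        "o2_mechanisms": community.o2_mechanisms,
        "precursor_sinks": community.precursor_sinks,
        "epsilon": community.epsilon,
        "atp_reactions": list(community.atp_reactions),
        "nadph_reactions": list(community.nadph_reactions),
    }
    # insertion order is meaningful (sink order, mechanism order) — keep it
    (path / "community.json").write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_community(path: str | Path) -> CommunityModel:
    path = Path(path)
    host = read_model(path / "host")
    symbiont = read_model(path / "symbiont")
    meta = json.loads((path / "community.json").read_text())
    df = pd.read_csv(path / "transfers.tsv", sep="\t")
    h2s, s2h = [], []
    for _, row in df.iterrows():
        tr = TransferReaction(
            id=str(row["id"]),
            metabolite=str(row["metabolite"]),
            direction=str(row["direction"]),
            n_carbon=int(row["n_carbon"]),
            n_nitrogen=int(row["n_nitrogen"]),
            cap=float(row["cap"]),
        )
        (h2s if tr.direction == HOST_TO_SYM else s2h).append(tr)
    community = CommunityModel(
        host=host,
        symbiont=symbiont,
        transfers_host_to_sym=h2s,
        transfers_sym_to_host=s2h,
        n2_fixation_reaction=meta["n2_fixation_reaction"],
        co2_exchange_reaction=meta["co2_exchange_reaction"],
        o2_uptake_reaction=meta.get("o2_uptake_reaction"),
        o2_mechanisms=dict(meta.get("o2_mechanisms", {})),
        precursor_sinks=dict(meta.get("precursor_sinks", {})),
        epsilon=float(meta.get("epsilon", 0.01)),
        atp_reactions=tuple(meta.get("atp_reactions", ())),
        nadph_reactions=tuple(meta.get("nadph_reactions", ())),
    )
    community.validate()
    return community
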