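"""Draft reconstruction by ortholog mapping.

Orthologs between a scaffold organism (with a curated model) and the
target organism are called by the bidirectional-best-hit criterion on
precomputed protein alignment hit tables (BLAST outfmt-6); reactions are
then transferred from the scaffold model whenever the target's ortholog
complement satisfies the reaction's gene-protein-reaction Boolean logic.
The aligner itself is never invoked: hit tables are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model_io import MetabolicModel, Reaction

__all__ = [
    "HitRecord",
    "OrthologMap",
    "read_hit_table",
    "bidirectional_best_hits",
    "transfer_reactions",
    "merge_drafts",
    "MergeConflictError",
]


@dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    e_value: float
    bitscore: float = 0.0

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e-value must be nonnegative")


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one (scaffold gene, target gene) pairs."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self):
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        for a, b in self.pairs:
            if a in seen_a or b in seen_b:
                raise ValueError("ortholog map must be one-to-one")
            seen_a.add(a)
            seen_b.add(b)

    def scaffold_genes(self) -> frozenset[str]:
        return frozenset(a for a, _ in self.pairs)

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    def transpose(self) -> "OrthologMap":
        return OrthologMap(frozenset((b, a) for a, b in self.pairs))


#: Standard 12-column tabular alignment format.
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read an outfmt-6 TSV into hit records (qseqid, sseqid, evalue, bitscore)."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    return [
        HitRecord(
            query=str(row.qseqid),
            subject=str(row.sseqid),
            e_value=float(row.evalue),
            bitscore=float(row.bitscore),
        )
        for row in df.itertuples()
    ]


def _best_hits(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query: lowest e-value, ties broken by higher bitscore
    then lexicographically smallest subject id (deterministic)."""
    best: dict[str, HitRecord] = {}
    for hit in hits:
        cur = best.get(hit.query)
        if cur is None:
            best[hit.query] = hit
            continue
        key = (hit.e_value, -hit.bitscore, hit.subject)
        cur_key = (cur.e_value, -cur.bitscore, cur.subject)
        if key < cur_key:
            best[hit.query] = hit
    return best


def bidirectional_best_hits(
    forward: Sequence[HitRecord],
    reverse: Sequence[HitRecord],
    e_cutoff: float = 1e-30,
) -> OrthologMap:
    """Mutual-best-hit ortholog calling under an e-value cutoff.

    A pair (a, b) is returned iff b is a's best forward hit, a is b's
    best reverse hit, and both e-values pass the cutoff (both-sided,
    the stricter reading).
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    fwd_best = _best_hits(forward)
    rev_best = _best_hits(reverse)
    pairs = set()
    for a, fhit in fwd_best.items():
        b = fhit.subject
        rhit = rev_best.get(b)
        if rhit is None or rhit.subject != a:
            continue
        if fhit.e_value <= e_cutoff and rhit.e_value <= e_cutoff:
            pairs.add((a, b))
    return OrthologMap(frozenset(pairs))


def transfer_reactions(
    scaffold: MetabolicModel,
    orthologs: OrthologMap,
    transfer_orphans: bool = True,
) -> MetabolicModel:
    """Transfer scaffold reactions whose gene logic the orthologs satisfy.

    GPRs are rewritten to target gene ids.  Reactions with an empty rule
    (spontaneous, exchange) are transferred by default; set
    ``transfer_orphans=False`` to drop them.
    """
    mapping = orthologs.as_dict()
    covered = orthologs.scaffold_genes()
    kept: list[Reaction] = []
    met_ids: set[str] = set()
    for r in scaffold.reactions:
        rule = r.gene_rule
        if rule.is_empty:
            if not transfer_orphans:
                continue
            new = r.copy()
        elif rule.evaluate(covered):
            new = r.copy()
            new.gpr = rule.rename(mapping).to_string()
            new._gene_rule = None
        else:
            continue
        kept.append(new)
        met_ids.update(new.stoichiometry)
    mets = [m for m in scaffold.metabolites if m.id in met_ids]
    draft = MetabolicModel(
        id=f"{scaffold.id}_draft",
        metabolites=mets,
        reactions=kept,
    )
    draft.validate()
    return draft


class MergeConflictError(ValueError):
    """Same reaction id with differing stoichiometry across drafts."""


def merge_drafts(drafts: Sequence[MetabolicModel]) -> MetabolicModel:
    """Union of draft models, deduplicated by reaction id.

    Drafts must share the metabolite-id namespace; an id collision with
    differing stoichiometry raises :class:`MergeConflictError`.
    """
    if not drafts:
        raise ValueError("need at least one draft to merge")
    merged_rxns: dict[str, Reaction] = {}
    merged_mets: dict[str, object] = {}
    for draft in drafts:
        for m in draft.metabolites:
            merged_mets.setdefault(m.id, m)
        for r in draft.reactions:
            prev = merged_rxns.get(r.id)
            if prev is None:
                merged_rxns[r.id] = r.copy()
            elif prev.stoichiometry != r.stoichiometry:
                raise MergeConflictError(
                    f"reaction {r.id!r} conflicts across drafts: "
                    f"{prev.stoichiometry} vs {r.stoichiometry}"
                )
    merged = MetabolicModel(
        id="merged_draft",
        metabolites=list(merged_mets.values()),
        reactions=list(merged_rxns.values()),
    )
    merged.validate()
    return merged
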