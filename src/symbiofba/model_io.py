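"""Stoichiometric model types and the tabular model dialect.

Conventions used throughout the package:

* Metabolite ids are BiGG-style with a trailing compartment suffix
  (``glc__D_c``: D-glucose in the cytosol).  Declared compartments are
  ``c`` (cytosol), ``e`` (extracellular), ``u`` (thylakoid lumen) and
  ``p`` (periplasm).
* Reaction equations are plain strings such as
  ``2 h_c + 2 fdxrd_c + o2_c -> 2 fdxox_c + h2o2_c``.  The arrow ``->``
  marks an irreversible reaction, ``<=>`` a reversible one (lb < 0).
* Fluxes and bounds are in mmol gDW^-1 hr^-1.

A model on disk is a directory holding ``reactions.tsv`` (columns: id,
name, equation, lb, ub, gpr, subsystem), ``metabolites.tsv`` (columns:
id, name, formula, charge, compartment) and an optional ``model.json``
with model-level metadata (biomass reaction, biomass precursor list,
medium).  An ``.xlsx`` workbook with sheets named ``reactions`` and
``metabolites`` is accepted as an alternative serialization.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "FEASIBILITY_TOL",
    "INTEGRALITY_TOL",
    "OBJECTIVE_TOL",
    "COMPARTMENTS",
    "FormulaError",
    "ModelFormatError",
    "ModelValidationError",
    "GeneRuleError",
    "parse_formula",
    "format_formula",
    "GeneRule",
    "evaluate_gene_rule",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxDistribution",
    "parse_equation",
    "format_equation",
    "read_model",
    "write_model",
    "write_flux_distribution",
    "read_flux_distribution",
]

# Default numeric tolerances (branch-and-cut solver class defaults).
FEASIBILITY_TOL = 1e-6
INTEGRALITY_TOL = 1e-5
OBJECTIVE_TOL = 1e-6

#: Declared compartment table: suffix code -> description.
COMPARTMENTS = {
    "c": "cytosol",
    "e": "extracellular",
    "u": "thylakoid lumen",
    "p": "periplasm",
}


class FormulaError(ValueError):
    """Raised for a chemical formula that does not parse."""


class ModelFormatError(ValueError):
    """Raised when a model file is structurally malformed."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates a structural invariant."""


class GeneRuleError(ValueError):
    """Raised for a malformed gene-protein-reaction rule string."""


# ---------------------------------------------------------------------------
# Elemental formulas
# ---------------------------------------------------------------------------

def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition string into per-element counts.

    ``"C6H12O6"`` -> ``{"C": 6, "H": 12, "O": 6}``.  Elements absent from
    the formula are simply absent from the mapping (callers use
    ``.get(el, 0)``).  Raises :class:`FormulaError` on anything that is
    not a sequence of ``<Element><count?>`` tokens.
    """
    if not isinstance(formula, str):
        raise FormulaError(f"formula must be a string, got {formula!r}")
    s = formula.strip()
    if not s:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    i, n = 0, len(s)
    while i < n:
        ch = s[i]
        if not ch.isalpha() or not ch.isupper():
            raise FormulaError(f"unexpected character {ch!r} at position {i} in {formula!r}")
        element = ch
        i += 1
        if i < n and s[i].isalpha() and s[i].islower():
            element += s[i]
            i += 1
        digits = ""
        while i < n and s[i].isdigit():
            digits += s[i]
            i += 1
        count = int(digits) if digits else 1
        counts[element] = counts.get(element, 0) + count
    return counts


_HILL_FIRST = ("C", "H")


def format_formula(counts: Mapping[str, int]) -> str:
    """Render element counts as a canonical (Hill-ordered) formula string."""
    parts: list[str] = []
    rest = sorted(el for el in counts if el not in _HILL_FIRST)
    for el in (*_HILL_FIRST, *rest):
        cnt = counts.get(el, 0)
        if cnt < 0:
            raise FormulaError(f"negative count for element {el}")
        if cnt == 0:
            continue
        parts.append(el if cnt == 1 else f"{el}{cnt}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Gene-protein-reaction rules
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class _Node:
    op: str  # "gene" | "and" | "or"
    gene: str = ""
    children: tuple["_Node", ...] = ()

    def evaluate(self, present: frozenset[str]) -> bool:
        if self.op == "gene":
            return self.gene in present
        if self.op == "and":
            return all(c.evaluate(present) for c in self.children)
        return any(c.evaluate(present) for c in self.children)

    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset((self.gene,))
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.genes()
        return out

    def rename(self, mapping: Mapping[str, str]) -> "_Node":
        if self.op == "gene":
            return _Node("gene", mapping.get(self.gene, self.gene))
        return _Node(self.op, children=tuple(c.rename(mapping) for c in self.children))

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op != "gene" and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


class _GprParser:
    def __init__(self, text: str):
        self.tokens = _GPR_TOKEN.findall(text)
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GeneRuleError("unexpected end of gene rule")
        self.pos += 1
        return tok

    def parse(self) -> _Node:
        node = self.parse_or()
        if self.peek() is not None:
            raise GeneRuleError(f"trailing tokens in gene rule: {self.tokens[self.pos:]}")
        return node

    def parse_or(self) -> _Node:
        children = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else _Node("or", children=tuple(children))

    def parse_and(self) -> _Node:
        children = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            children.append(self.parse_atom())
        return children[0] if len(children) == 1 else _Node("and", children=tuple(children))

    def parse_atom(self) -> _Node:
        tok = self.next()
        if tok == "(":
            node = self.parse_or()
            if self.next() != ")":
                raise GeneRuleError("unbalanced parentheses in gene rule")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GeneRuleError(f"unexpected token {tok!r} in gene rule")
        return _Node("gene", tok)


@dataclass(frozen=True)
class GeneRule:
    """Boolean tree over gene-id leaves; the empty rule is always true.

    The empty rule stands for spontaneous / orphan reactions, which are
    retained regardless of gene content.
    """

    root: _Node | None = None
    raw: str = ""

    @classmethod
    def from_string(cls, text: str | None) -> "GeneRule":
        text = "" if text is None else str(text).strip()
        if not text:
            return cls(None, "")
        return cls(_GprParser(text).parse(), text)

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def evaluate(self, present_genes: Iterable[str]) -> bool:
        if self.root is None:
            return True
        return self.root.evaluate(frozenset(present_genes))

    def genes(self) -> frozenset[str]:
        return frozenset() if self.root is None else self.root.genes()

    def rename(self, mapping: Mapping[str, str]) -> "GeneRule":
        if self.root is None:
            return self
        root = self.root.rename(mapping)
        return GeneRule(root, root.to_string())

    def to_string(self) -> str:
        if self.root is None:
            return ""
        return self.raw if self.raw else self.root.to_string()


def evaluate_gene_rule(rule: GeneRule | str, present_genes: Iterable[str]) -> bool:
    """Standard Boolean semantics; the empty rule evaluates to True."""
    if isinstance(rule, str):
        rule = GeneRule.from_string(rule)
    return rule.evaluate(present_genes)


# ---------------------------------------------------------------------------
# Metabolites, reactions, models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: str | None = None
    charge: int = 0
    compartment: str = "c"

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("metabolite id must be nonempty")
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if self.formula is not None:
            parse_formula(self.formula)  # raises FormulaError if malformed

    def element_counts(self) -> dict[str, int]:
        if self.formula is None:
            return {}
        return parse_formula(self.formula)


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse a reaction equation string.

    Returns ``(stoichiometry, reversible)`` where stoichiometry maps
    metabolite id to a signed coefficient (substrates negative).
    """
    if "<=>" in equation:
        arrow, reversible = "<=>", True
    elif "->" in equation:
        arrow, reversible = "->", False
    else:
        raise ModelFormatError(f"no arrow token ('->' or '<=>') in equation {equation!r}")
    lhs, rhs = equation.split(arrow, 1)
    stoich: dict[str, float] = {}

    def consume(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelFormatError(f"empty term in equation {equation!r}")
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise ModelFormatError(
                        f"bad coefficient {parts[0]!r} in equation {equation!r}"
                    ) from exc
                met = parts[1]
            else:
                raise ModelFormatError(f"cannot parse term {term!r} in equation {equation!r}")
            if coef <= 0:
                raise ModelFormatError(f"nonpositive coefficient in equation {equation!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    consume(lhs, -1.0)
    consume(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelFormatError(f"equation {equation!r} has empty net stoichiometry")
    return stoich, reversible


def _coef_str(coef: float) -> str:
    if coef == int(coef):
        return str(int(coef))
    return repr(coef)


def format_equation(stoichiometry: Mapping[str, float], reversible: bool) -> str:
    subs = sorted((m, -c) for m, c in stoichiometry.items() if c < 0)
    prods = sorted((m, c) for m, c in stoichiometry.items() if c > 0)

    def side(terms):
        return " + ".join(m if c == 1 else f"{_coef_str(c)} {m}" for m, c in terms)

    arrow = "<=>" if reversible else "->"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    gpr: str = ""
    subsystem: str = ""

    _gene_rule: GeneRule | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("reaction id must be nonempty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise ModelValidationError(f"reaction {self.id!r}: zero coefficient for {met!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def gene_rule(self) -> GeneRule:
        if self._gene_rule is None:
            self._gene_rule = GeneRule.from_string(self.gpr)
        return self._gene_rule

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            name=self.name,
            gpr=self.gpr,
            subsystem=self.subsystem,
        )


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) stoichiometric model.

    The symbiont convention replaces an explicit biomass reaction by a
    list of biomass precursor metabolites, each of which is drained by a
    small-lower-bound sink installed when a community is assembled.
    """

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    biomass_reaction_id: str | None = None
    biomass_precursors: list[str] = field(default_factory=list)
    medium: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self._reindex()

    def _reindex(self) -> None:
        self._met_index = {}
        for m in self.metabolites:
            if m.id in self._met_index:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            self._met_index[m.id] = m
        self._rxn_index = {}
        for r in self.reactions:
            if r.id in self._rxn_index:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            self._rxn_index[r.id] = r

    # -- lookups ------------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return self._met_index[mid]

    def reaction(self, rid: str) -> Reaction:
        return self._rxn_index[rid]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def has_metabolite(self, mid: str) -> bool:
        return mid in self._met_index

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for r in self.reactions:
            out |= r.gene_rule.genes()
        return out

    # -- mutation -----------------------------------------------------------
    def add_metabolites(self, mets: Iterable[Metabolite]) -> None:
        for m in mets:
            if m.id in self._met_index:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            self.metabolites.append(m)
            self._met_index[m.id] = m

    def add_reactions(self, rxns: Iterable[Reaction]) -> None:
        for r in rxns:
            if r.id in self._rxn_index:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            self.reactions.append(r)
            self._rxn_index[r.id] = r

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
            biomass_precursors=list(self.biomass_precursors),
            medium=dict(self.medium),
        )

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        """Check referential integrity; raises ModelValidationError."""
        for r in self.reactions:
            for met in r.stoichiometry:
                if met not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references undeclared metabolite {met!r}"
                    )
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in self._rxn_index:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        for prec in self.biomass_precursors:
            if prec not in self._met_index:
                raise ModelValidationError(f"biomass precursor {prec!r} not in model")
        for ex in self.medium:
            if ex not in self._rxn_index:
                raise ModelValidationError(f"medium exchange {ex!r} not in model")

    # -- linear algebra view ------------------------------------------------
    def stoichiometric_matrix(self) -> tuple[sparse.csr_array, list[str], list[str]]:
        """Sparse S with one row per metabolite, one column per reaction."""
        met_ids = self.metabolite_ids
        rxn_ids = self.reaction_ids
        met_pos = {m: i for i, m in enumerate(met_ids)}
        rows, cols, data = [], [], []
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                rows.append(met_pos[met])
                cols.append(j)
                data.append(float(coef))
        S = sparse.csr_array(
            (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
        )
        return S, met_ids, rxn_ids


@dataclass
class FluxDistribution:
    """Outcome of one LP/MILP solve over a model's reactions."""

    status: str  # "optimal" | "infeasible" | "unbounded" | "unknown"
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_value: float = math.nan

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def get(self, rid: str, default: float = 0.0) -> float:
        return self.fluxes.get(rid, default)

    def mass_balance_residual(self, model: MetabolicModel) -> float:
        """max_i |sum_j S_ij v_j| — should be <= the feasibility tolerance."""
        S, met_ids, rxn_ids = model.stoichiometric_matrix()
        v = np.array([self.fluxes.get(r, 0.0) for r in rxn_ids])
        if S.shape[0] == 0:
            return 0.0
        return float(np.abs(S @ v).max())


# ---------------------------------------------------------------------------
# Tabular dialect I/O
# ---------------------------------------------------------------------------

_REACTION_COLUMNS = ("id", "name", "equation", "lb", "ub", "gpr", "subsystem")
_METABOLITE_COLUMNS = ("id", "name", "formula", "charge", "compartment")


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise ModelFormatError(f"{what} table is missing required column {col!r}")


def _load_tables(path: Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    if path.suffix.lower() == ".xlsx":
        rxn = pd.read_excel(path, sheet_name="reactions", dtype=object)
        met = pd.read_excel(path, sheet_name="metabolites", dtype=object)
        meta: dict = {}
        return rxn, met, meta
    if not path.is_dir():
        raise ModelFormatError(
            f"{path} is neither a model directory nor an .xlsx workbook"
        )
    rxn_path = path / "reactions.tsv"
    met_path = path / "metabolites.tsv"
    for p in (rxn_path, met_path):
        if not p.exists():
            raise ModelFormatError(f"model directory {path} is missing {p.name}")
    rxn = pd.read_csv(rxn_path, sep="\t", dtype=object)
    met = pd.read_csv(met_path, sep="\t", dtype=object)
    meta_path = path / "model.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return rxn, met, meta


def _cell(row, col, default=""):
    val = row.get(col, default)
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return default
    return val


def read_model(path: str | Path, dialect: str = "tabular") -> MetabolicModel:
    """Read a model from the tabular dialect; returns a validated model."""
    if dialect != "tabular":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rxn_df, met_df, meta = _load_tables(path)
    _check_columns(rxn_df, ("id", "equation", "lb", "ub"), "reactions")
    _check_columns(met_df, ("id", "formula", "compartment"), "metabolites")

    metabolites = []
    for idx, row in met_df.iterrows():
        formula = _cell(row, "formula", None)
        formula = None if formula in ("", None) else str(formula)
        try:
            metabolites.append(
                Metabolite(
                    id=str(row["id"]),
                    name=str(_cell(row, "name")),
                    formula=formula,
                    charge=int(float(_cell(row, "charge", 0) or 0)),
                    compartment=str(row["compartment"]),
                )
            )
        except (FormulaError, ModelValidationError, ValueError) as exc:
            raise ModelFormatError(f"metabolites row {idx} ({row['id']!r}): {exc}") from exc

    reactions = []
    for idx, row in rxn_df.iterrows():
        try:
            stoich, reversible = parse_equation(str(row["equation"]))
            lb = float(row["lb"])
            ub = float(row["ub"])
            reactions.append(
                Reaction(
                    id=str(row["id"]),
                    name=str(_cell(row, "name")),
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    gpr=str(_cell(row, "gpr")),
                    subsystem=str(_cell(row, "subsystem")),
                )
            )
        except (ModelFormatError, ModelValidationError, GeneRuleError, ValueError) as exc:
            raise type(exc)(f"reactions row {idx} ({row['id']!r}): {exc}") from exc

    model = MetabolicModel(
        id=str(meta.get("id", path.stem if path.suffix else path.name)),
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=meta.get("biomass_reaction_id"),
        biomass_precursors=list(meta.get("biomass_precursors", [])),
        medium={k: float(v) for k, v in meta.get("medium", {}).items()},
    )
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path) -> Path:
    """Write a model as a directory in the tabular dialect (round-trip safe)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rxn_rows = []
    for r in model.reactions:
        rxn_rows.append(
            {
                "id": r.id,
                "name": r.name,
                "equation": format_equation(r.stoichiometry, r.reversible),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
            }
        )
    met_rows = []
    for m in model.metabolites:
        met_rows.append(
            {
                "id": m.id,
                "name": m.name,
                "formula": "" if m.formula is None else m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
            }
        )
    pd.DataFrame(rxn_rows, columns=list(_REACTION_COLUMNS)).to_csv(
        path / "reactions.tsv", sep="\t", index=False
    )
    pd.DataFrame(met_rows, columns=list(_METABOLITE_COLUMNS)).to_csv(
        path / "metabolites.tsv", sep="\t", index=False
    )
    meta = {
        "id": model.id,
        "biomass_reaction_id": model.biomass_reaction_id,
        "biomass_precursors": model.biomass_precursors,
        "medium": model.medium,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def write_flux_distribution(dist: FluxDistribution, path: str | Path) -> Path:
    """Two-column TSV (reaction_id, flux) with a JSON sidecar header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("reaction_id\tflux\n")
        for rid, flux in dist.fluxes.items():
            fh.write(f"{rid}\t{flux:.10g}\n")
    header = {"status": dist.status, "objective": dist.objective_value}
    Path(str(path) + ".json").write_text(json.dumps(header, indent=2) + "\n")
    return path


def read_flux_distribution(path: str | Path) -> FluxDistribution:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    header = json.loads(Path(str(path) + ".json").read_text())
    return FluxDistribution(
        status=header["status"],
        fluxes=dict(zip(df["reaction_id"].astype(str), df["flux"].astype(float))),
        objective_value=float(header["objective"]),
    )
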