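"""Metabolic model containers, SBML/JSON I/O, and GPR rule handling.

The in-memory representation is deliberately small: a :class:`MetabolicModel`
holds metabolites, reactions (with a stoichiometry mapping and flux bounds in
mmol·gDW⁻¹·h⁻¹), and boolean gene–protein–reaction (GPR) rules.  Two file
dialects are supported:

* SBML — legacy Level 2 files with ``GENE_ASSOCIATION:`` strings in reaction
  notes, and Level 3 files using the ``fbc`` package (gene products, flux
  bounds, objectives).  Writing always emits Level 3 + fbc.
* a flat JSON dialect (``metabolites``/``reactions`` arrays with stoichiometry
  maps, bounds and GPR strings) convenient for synthetic fixtures.

Sign conventions used throughout the package: negative flux through an
exchange reaction is uptake, positive is secretion; a reaction is an exchange
when its stoichiometry touches a single species.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "GPRRule",
    "GeneRef",
    "BoolOp",
    "MetabolicModel",
    "SimulationConfig",
    "GPRParseError",
    "ModelValidationError",
    "parse_gpr",
    "evaluate_gpr",
    "stoichiometric_matrix",
    "read_model",
    "write_model",
]

DEFAULT_BOUND = 1000.0  # COBRA convention for an unconstrained flux


class GPRParseError(ValueError):
    """Raised for malformed GPR strings; carries the offending position."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRef:
    """Leaf of a GPR tree: a single gene id."""

    gene: str

    def evaluate(self, states: Mapping[str, float]) -> float:
        # genes missing from the profile count as absent; pan-genome
        # profiles routinely omit genes a strain does not carry
        return float(states.get(self.gene, 0.0))

    def genes(self) -> set[str]:
        return {self.gene}

    def to_string(self) -> str:
        return self.gene


@dataclass(frozen=True)
class BoolOp:
    """Internal AND/OR node of a GPR tree."""

    op: str  # "and" | "or"
    children: tuple["GeneRef | BoolOp", ...]

    def evaluate(self, states: Mapping[str, float]) -> float:
        vals = [c.evaluate(states) for c in self.children]
        return min(vals) if self.op == "and" else max(vals)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            # "and" binds tighter: only an OR nested under AND needs parens
            if isinstance(c, BoolOp) and self.op == "and" and c.op == "or":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


@dataclass(frozen=True)
class GPRRule:
    """Boolean gene requirement of a reaction; ``root is None`` means the
    reaction is unconditionally present (no known gene dependence)."""

    root: GeneRef | BoolOp | None = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> set[str]:
        return set() if self.root is None else self.root.genes()

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str) -> GPRRule:
    """Parse a boolean gene-association string into a :class:`GPRRule`.

    Grammar: gene ids combined with ``and`` / ``or`` (case-insensitive) and
    parentheses; ``and`` binds tighter than ``or``.  An empty/blank string
    yields the empty rule.

    Raises
    ------
    GPRParseError
        For unbalanced parentheses or dangling operators, with the character
        position of the problem.
    """
    if rule is None or not rule.strip():
        return GPRRule(None)

    tokens: list[tuple[str, int]] = [
        (m.group(0), m.start()) for m in _TOKEN_RE.finditer(rule)
    ]
    pos = 0

    def peek() -> tuple[str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> tuple[str, int]:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GeneRef | BoolOp:
        terms = [parse_and()]
        while (t := peek()) is not None and t[0].lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else BoolOp("or", tuple(terms))

    def parse_and() -> GeneRef | BoolOp:
        terms = [parse_atom()]
        while (t := peek()) is not None and t[0].lower() == "and":
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else BoolOp("and", tuple(terms))

    def parse_atom() -> GeneRef | BoolOp:
        t = peek()
        if t is None:
            raise GPRParseError(
                f"dangling operator at position {len(rule)} in {rule!r}"
            )
        tok, at = take()
        if tok == "(":
            inner = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise GPRParseError(f"unbalanced '(' at position {at} in {rule!r}")
            take()
            return inner
        if tok == ")":
            raise GPRParseError(f"unbalanced ')' at position {at} in {rule!r}")
        if tok.lower() in ("and", "or"):
            raise GPRParseError(f"dangling operator at position {at} in {rule!r}")
        return GeneRef(tok)

    tree = parse_or()
    if (t := peek()) is not None:
        raise GPRParseError(f"unexpected token {t[0]!r} at position {t[1]} in {rule!r}")
    return GPRRule(tree)


def evaluate_gpr(rule: GPRRule, gene_states: Mapping[str, float]) -> float:
    """Evaluate a GPR over gene states (AND = min, OR = max).

    Binary 0/1 states give the classical boolean evaluation; fractional
    evidence scores propagate as min/max.  Genes absent from ``gene_states``
    evaluate as 0.  The empty rule evaluates to 1 (reaction unconditionally
    present).
    """
    if rule.is_empty:
        return 1.0
    return rule.root.evaluate(gene_states)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    compartment: str = "c"


@dataclass
class Reaction:
    """One reaction: stoichiometry mapping metabolite id → coefficient
    (negative = consumed), flux bounds in mmol·gDW⁻¹·h⁻¹, a GPR rule, and an
    objective coefficient (1.0 marks the biomass reaction)."""

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""
    gpr: GPRRule = field(default_factory=GPRRule)
    objective_coefficient: float = 0.0

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class SimulationConfig:
    """Energy-parameter bundle in the iAF1260 convention: GAM is embedded in
    the biomass stoichiometry, NGAM is a fixed lower bound on the ATP
    maintenance reaction, and the P/O ratio is implied by the electron
    transport stoichiometry."""

    gam: float = 59.81  # mmol ATP per gDW of biomass
    ngam: float = 8.39  # mmol·gDW⁻¹·h⁻¹ maintenance flux
    po_ratio: float = 1.375  # ATP per electron pair
    solver_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("gam and ngam must be non-negative")
        if self.solver_tolerance <= 0:
            raise ValueError("solver_tolerance must be positive")


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ------------------------------------------------------------

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gpr.genes()
        return out

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id!r}")

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"no metabolite {mid!r} in model {self.id!r}")

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def objective_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.objective_coefficient != 0.0]

    # -- mutation helpers ---------------------------------------------------

    def copy(self, new_id: str | None = None) -> "MetabolicModel":
        return MetabolicModel(
            id=new_id or self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
        )

    def remove_reactions(
        self, reaction_ids: Iterable[str], prune_metabolites: bool = True
    ) -> "MetabolicModel":
        """Return a copy without the named reactions; orphan metabolites
        (referenced by no remaining reaction) are dropped when pruning."""
        drop = set(reaction_ids)
        unknown = drop - set(self.reaction_ids())
        if unknown:
            raise KeyError(f"unknown reactions: {sorted(unknown)}")
        kept = [r.copy() for r in self.reactions if r.id not in drop]
        if prune_metabolites:
            used = {m for r in kept for m in r.stoichiometry}
            mets = [replace(m) for m in self.metabolites if m.id in used]
        else:
            mets = [replace(m) for m in self.metabolites]
        return MetabolicModel(id=self.id, metabolites=mets, reactions=kept)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            dup = sorted({x for x in mids if mids.count(x) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({x for x in rids if rids.count(x) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        known = set(mids)
        for m in self.metabolites:
            if not m.id:
                raise ModelValidationError("metabolite with empty id")
            if not m.compartment:
                raise ModelValidationError(f"metabolite {m.id}: empty compartment")
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id}: lower_bound {r.lower_bound} > "
                    f"upper_bound {r.upper_bound}"
                )
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id} references undeclared metabolites: "
                    f"{sorted(missing)}"
                )
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id}: empty stoichiometry")


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense stoichiometric matrix S (metabolites × reactions), rows in
    metabolite declaration order, columns in reaction declaration order."""
    mindex = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            S[mindex[mid], j] = coef
    return S


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "gpr": r.gpr.to_string(),
                "objective_coefficient": r.objective_coefficient,
            }
            for r in model.reactions
        ],
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    mets = [
        Metabolite(
            id=d["id"],
            name=d.get("name", ""),
            formula=d.get("formula", ""),
            charge=int(d.get("charge", 0)),
            compartment=d.get("compartment", "c"),
        )
        for d in data.get("metabolites", [])
    ]
    rxns = []
    for d in data.get("reactions", []):
        lb = d.get("lower_bound")
        ub = d.get("upper_bound")
        if lb is None and ub is None:
            rev = bool(d.get("reversible", True))
            lb = -DEFAULT_BOUND if rev else 0.0
            ub = DEFAULT_BOUND
        rxns.append(
            Reaction(
                id=d["id"],
                name=d.get("name", ""),
                stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
                lower_bound=float(lb if lb is not None else -DEFAULT_BOUND),
                upper_bound=float(ub if ub is not None else DEFAULT_BOUND),
                subsystem=d.get("subsystem", ""),
                gpr=parse_gpr(d.get("gpr", "")),
                objective_coefficient=float(d.get("objective_coefficient", 0.0)),
            )
        )
    return MetabolicModel(id=data.get("id", "model"), metabolites=mets, reactions=rxns)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

_GA_NOTE_RE = re.compile(r"GENE[ _]?ASSOCIATION\s*:\s*(.*)", re.IGNORECASE)
_SUBSYS_NOTE_RE = re.compile(r"SUBSYSTEM\s*:\s*(.*)", re.IGNORECASE)


def _sanitize_sid(raw: str) -> str:
    # SBML SIds are [A-Za-z_][A-Za-z0-9_]*; BiGG-style ids need escaping
    s = re.sub(r"[^A-Za-z0-9_]", "__", raw)
    if not re.match(r"[A-Za-z_]", s):
        s = "_" + s
    return s


def _read_sbml(path: str | Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise ModelValidationError(
                f"SBML parse error in {path} at line {err.getLine()}: "
                f"{err.getMessage().strip()}"
            )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"{path}: no <model> element")

    fbc = sbml_model.getPlugin("fbc")

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are the implicit exterior
        formula, charge = "", 0
        sfbc = sp.getPlugin("fbc")
        if sfbc is not None:
            if sfbc.isSetChemicalFormula():
                formula = sfbc.getChemicalFormula()
            if sfbc.isSetCharge():
                charge = sfbc.getCharge()
        if not formula and sp.isSetNotes():
            m = re.search(
                r"FORMULA\s*:\s*(\S+)", libsbml.XMLNode.convertXMLNodeToString(sp.getNotes())
            )
            if m:
                formula = m.group(1)
        mets.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment() or "c",
            )
        )
    met_ids = {m.id for m in mets}

    # fbc objectives
    objective_coeffs: dict[str, float] = {}
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None:
            for i in range(active.getNumFluxObjectives()):
                fo = active.getFluxObjective(i)
                objective_coeffs[fo.getReaction()] = fo.getCoefficient()

    # fbc flux-bound parameters (L3)
    def _param_value(pid: str) -> float | None:
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else None

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            sr = rx.getReactant(k)
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for k in range(rx.getNumProducts()):
            sr = rx.getProduct(k)
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}

        lb = ub = None
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = _param_value(rfbc.getLowerFluxBound())
            if rfbc.isSetUpperFluxBound():
                ub = _param_value(rfbc.getUpperFluxBound())
        kl = rx.getKineticLaw()
        if (lb is None or ub is None) and kl is not None:
            for pname, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                p = kl.getParameter(pname)
                if p is not None:
                    if setter == "lb" and lb is None:
                        lb = p.getValue()
                    elif setter == "ub" and ub is None:
                        ub = p.getValue()
            if not objective_coeffs:
                p = kl.getParameter("OBJECTIVE_COEFFICIENT")
                if p is not None and p.getValue() != 0.0:
                    objective_coeffs[rx.getId()] = p.getValue()
        if lb is None:
            lb = -DEFAULT_BOUND if rx.getReversible() else 0.0
        if ub is None:
            ub = DEFAULT_BOUND

        gpr_str, subsystem = "", ""
        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            assoc = rfbc.getGeneProductAssociation().getAssociation()
            gpr_str = _fbc_association_to_string(assoc, sbml_model)
        if rx.isSetNotes():
            notes = libsbml.XMLNode.convertXMLNodeToString(rx.getNotes())
            notes = re.sub(r"<[^>]+>", "\n", notes)
            if not gpr_str:
                m = _GA_NOTE_RE.search(notes)
                if m:
                    gpr_str = m.group(1).strip()
            m = _SUBSYS_NOTE_RE.search(notes)
            if m:
                subsystem = m.group(1).strip()

        rxns.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or rx.getId(),
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                subsystem=subsystem,
                gpr=parse_gpr(gpr_str),
                objective_coefficient=float(objective_coeffs.get(rx.getId(), 0.0)),
            )
        )

    return MetabolicModel(id=sbml_model.getId() or "model", metabolites=mets, reactions=rxns)


def _fbc_association_to_string(assoc, sbml_model) -> str:
    """Render an fbc association tree back to an and/or string over gene ids."""
    import libsbml

    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = sbml_model.getPlugin("fbc").getGeneProduct(assoc.getGeneProduct())
        return gp.getLabel() or gp.getId() if gp is not None else assoc.getGeneProduct()
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [
            _fbc_association_to_string(assoc.getAssociation(i), sbml_model)
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [
            _fbc_association_to_string(assoc.getAssociation(i), sbml_model)
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " or ".join(parts) + ")"
    return ""


def _write_sbml(model: MetabolicModel, path: str | Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize_sid(model.id))
    mfbc = sm.getPlugin("fbc")
    mfbc.setStrict(False)

    compartments = sorted({m.compartment for m in model.metabolites})
    for cid in compartments:
        c = sm.createCompartment()
        c.setId(_sanitize_sid(cid))
        c.setConstant(True)

    id_map: dict[str, str] = {}
    for m in model.metabolites:
        sid = _sanitize_sid("M_" + m.id)
        id_map[m.id] = sid
        sp = sm.createSpecies()
        sp.setId(sid)
        sp.setName(m.name or m.id)
        sp.setCompartment(_sanitize_sid(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sfbc = sp.getPlugin("fbc")
        if m.formula:
            sfbc.setChemicalFormula(m.formula)
        sfbc.setCharge(int(m.charge))

    gene_label_to_sid: dict[str, str] = {}
    for g in sorted(model.genes):
        gid = _sanitize_sid("G_" + g)
        gene_label_to_sid[g] = gid
        gp = mfbc.createGeneProduct()
        gp.setId(gid)
        gp.setLabel(g)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = _sanitize_sid(f"fb_{len(bound_params)}")
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    objective = mfbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    mfbc.setActiveObjectiveId("obj")

    for r in model.reactions:
        rid = _sanitize_sid("R_" + r.id)
        rx = sm.createReaction()
        rx.setId(rid)
        rx.setName(r.name or r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for mid, coef in r.stoichiometry.items():
            sr = rx.createReactant() if coef < 0 else rx.createProduct()
            sr.setSpecies(id_map[mid])
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(_bound_param(r.lower_bound))
        rfbc.setUpperFluxBound(_bound_param(r.upper_bound))
        if not r.gpr.is_empty:
            gpa = rfbc.createGeneProductAssociation()
            gpa.setAssociation(
                _gpr_to_fbc_string(r.gpr.root, gene_label_to_sid), True, False
            )
        if r.objective_coefficient != 0.0:
            fo = objective.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(r.objective_coefficient)
        if r.subsystem:
            rx.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {r.subsystem}</p></body>"
            )

    libsbml.writeSBMLToFile(doc, str(path))


def _gpr_to_fbc_string(node, gene_map: dict[str, str]) -> str:
    if isinstance(node, GeneRef):
        return gene_map[node.gene]
    parts = [_gpr_to_fbc_string(c, gene_map) for c in node.children]
    return "(" + f" {node.op} ".join(parts) + ")"


def _strip_sbml_prefixes(model: MetabolicModel) -> MetabolicModel:
    """Undo the R_/M_/sanitization prefixes our writer adds, restoring the
    round-trip identity on ids that were SBML-safe to begin with."""

    def unprefix(s: str, pfx: str) -> str:
        return s[len(pfx):] if s.startswith(pfx) else s

    mets = [replace(m, id=unprefix(m.id, "M_")) for m in model.metabolites]
    rxns = []
    for r in model.reactions:
        rxns.append(
            replace(
                r,
                id=unprefix(r.id, "R_"),
                stoichiometry={unprefix(k, "M_"): v for k, v in r.stoichiometry.items()},
            )
        )
    return MetabolicModel(id=model.id, metabolites=mets, reactions=rxns)


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model from SBML (``.xml``/``.sbml``) or the JSON
    dialect (``.json``); pass ``format`` explicitly to override sniffing.

    Reaction bounds default to ±1000 (reversible) / [0, 1000] (irreversible)
    when the file omits them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise ModelValidationError(f"{path}: malformed JSON at line {e.lineno}: {e.msg}")
        return _model_from_dict(data)
    if format == "sbml":
        return _strip_sbml_prefixes(_read_sbml(path))
    raise ValueError(f"unknown format {format!r} (expected 'sbml' or 'json')")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as SBML Level 3 + fbc (``.xml``) or the JSON dialect."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1, sort_keys=False))
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'sbml' or 'json')")


# ---------------------------------------------------------------------------
# Formula utilities (element-balance checks on synthetic fixtures)
# ---------------------------------------------------------------------------

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Hill-ish formula → element counts; R groups count as element 'R'."""
    counts: dict[str, int] = {}
    for el, num in _ELEMENT_RE.findall(formula or ""):
        if not el:
            continue
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return counts


def elemental_imbalance(model: MetabolicModel, reaction_id: str) -> dict[str, float]:
    """Net element counts of a reaction (zero for a mass-balanced internal
    reaction with complete formulas); exchanges are inherently unbalanced."""
    rxn = model.get_reaction(reaction_id)
    net: dict[str, float] = {}
    for mid, coef in rxn.stoichiometry.items():
        for el, n in parse_formula(model.get_metabolite(mid).formula).items():
            net[el] = net.get(el, 0.0) + coef * n
    return {el: v for el, v in net.items() if abs(v) > 1e-9}
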