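"""Constraint-based metabolic model core.

Data structures for stoichiometric models with gene-protein-reaction (GPR)
rules, JSON round-trip I/O, reversible-reaction splitting, the glycogen
breakdown augmentation used for fasting-state hepatic models, and a built-in
miniature hepatocyte network covering gluconeogenesis, glycogenolysis, the
TCA cycle, beta-oxidation and ketogenesis.

Flux units follow the mmol/h whole-liver convention; conversion to
umol/min/kg lean body mass happens at reporting time (see
:mod:`hepatoflux.tracer`).
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "GPRTree",
    "parse_gpr",
    "Reaction",
    "MetabolicModel",
    "ModelError",
    "GPRParseError",
    "read_model",
    "write_model",
    "build_toy_hepatocyte",
    "build_chain_model",
    "add_glycogenolysis_reaction",
    "split_reversible",
    "validate_model",
    "GLYCOGEN_BREAKDOWN_ID",
    "GLUCOSE_EXPORT_ID",
    "LIPID_PRODUCTION_ID",
]

#: Reserved id for the lumped total glycogen breakdown reaction.
GLYCOGEN_BREAKDOWN_ID = "glycogen_breakdown"
#: Glucose exchange (export) reaction id, as in the human-liver template.
GLUCOSE_EXPORT_ID = "HMR_9034"
#: Lipid-pool production reaction id, as in the human-liver template.
LIPID_PRODUCTION_ID = "HMR_0031"

#: Suffix appended to the reverse half of a split reversible reaction.
REVERSE_SUFFIX = "__rev"


class ModelError(ValueError):
    """Raised for schema violations and inconsistent model edits."""


class GPRParseError(ModelError):
    """Raised when a GPR string cannot be parsed; carries the position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


# ---------------------------------------------------------------------------
# GPR trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GPRTree:
    """Boolean gene-protein-reaction tree.

    ``kind`` is ``"gene"`` (leaf, ``gene`` set), ``"and"`` (enzyme complex:
    all subunits required) or ``"or"`` (isoforms: any suffices).
    """

    kind: str
    gene: str | None = None
    children: tuple["GPRTree", ...] = ()

    def genes(self) -> set[str]:
        if self.kind == "gene":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, expression: Mapping[str, float]) -> float | None:
        """Reaction activity score: AND -> min over subunits, OR -> max over
        isoforms.  A gene absent from ``expression`` is treated as
        non-limiting: ignored inside AND (acts as +inf) and inside OR (acts
        as -inf).  Returns ``None`` when no gene in the tree has data.
        """
        if self.kind == "gene":
            v = expression.get(self.gene)
            return None if v is None else float(v)
        vals = [c.evaluate(expression) for c in self.children]
        vals = [v for v in vals if v is not None]
        if not vals:
            return None
        return min(vals) if self.kind == "and" else max(vals)

    def to_string(self) -> str:
        if self.kind == "gene":
            return self.gene
        sep = f" {self.kind} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.kind != "gene" and c.kind != self.kind:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


def _tokenize_gpr(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append((ch, i))
            i += 1
        else:
            j = i
            while j < len(text) and not text[j].isspace() and text[j] not in "()":
                j += 1
            tokens.append((text[i:j], i))
            i = j
    return tokens


def parse_gpr(text: str) -> GPRTree:
    """Parse a GPR string like ``"(A and B) or C"`` into a :class:`GPRTree`.

    Grammar: ``expr := term ("or" term)* ; term := atom ("and" atom)* ;
    atom := "(" expr ")" | gene``.  ``and``/``or`` are case-insensitive.
    """
    tokens = _tokenize_gpr(text)
    pos = 0

    def peek():
        return tokens[pos][0] if pos < len(tokens) else None

    def peek_lower():
        t = peek()
        return t.lower() if t is not None else None

    def parse_expr() -> GPRTree:
        nonlocal pos
        terms = [parse_term()]
        while peek_lower() == "or":
            pos += 1
            terms.append(parse_term())
        if len(terms) == 1:
            return terms[0]
        return GPRTree("or", children=tuple(terms))

    def parse_term() -> GPRTree:
        nonlocal pos
        atoms = [parse_atom()]
        while peek_lower() == "and":
            pos += 1
            atoms.append(parse_atom())
        if len(atoms) == 1:
            return atoms[0]
        return GPRTree("and", children=tuple(atoms))

    def parse_atom() -> GPRTree:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GPRParseError("unexpected end of GPR expression", len(text))
        tok_pos = tokens[pos][1]
        if tok == "(":
            pos += 1
            inner = parse_expr()
            if peek() != ")":
                raise GPRParseError("unbalanced parentheses in GPR", tok_pos)
            pos += 1
            return inner
        if tok == ")":
            raise GPRParseError("unbalanced parentheses in GPR", tok_pos)
        if tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected operator {tok!r} in GPR", tok_pos)
        pos += 1
        return GPRTree("gene", gene=tok)

    if not tokens:
        raise GPRParseError("empty GPR expression", 0)
    tree = parse_expr()
    if pos != len(tokens):
        raise GPRParseError(
            f"trailing token {tokens[pos][0]!r} in GPR", tokens[pos][1]
        )
    return tree


# ---------------------------------------------------------------------------
# Model data structures
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    compartment: str = "c"
    name: str = ""
    carbons: int | None = None


@dataclass
class Reaction:
    """A stoichiometric reaction.  ``stoich`` maps metabolite id to
    coefficient (negative = consumed).  Bounds in mmol/h."""

    id: str
    stoich: dict[str, float]
    lb: float = 0.0
    ub: float = 1000.0
    name: str = ""
    gpr: GPRTree | None = None

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoich=dict(self.stoich),
            lb=self.lb,
            ub=self.ub,
            name=self.name,
            gpr=self.gpr,  # GPRTree is frozen, safe to share
        )


@dataclass
class MetabolicModel:
    """Stoichiometric network with bounds, GPRs, designated exchanges and a
    single objective reaction (glucose export in the shipped models)."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_id: str = GLUCOSE_EXPORT_ID
    exchange_ids: set[str] = field(default_factory=set)
    #: populated by :func:`split_reversible`: original id -> (fwd id, rev id
    #: or None).  Empty for unsplit models.
    split_map: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    # -- lookups --------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction with id {rid!r}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= r.gpr.genes()
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[_copy.copy(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            exchange_ids=set(self.exchange_ids),
            split_map=dict(self.split_map),
        )

    def stoichiometric_matrix(self) -> tuple[np.ndarray, dict[str, int], dict[str, int]]:
        """Dense S (metabolites x reactions) plus id -> index maps."""
        met_idx = {m.id: i for i, m in enumerate(self.metabolites)}
        rxn_idx = {r.id: j for j, r in enumerate(self.reactions)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for r in self.reactions:
            j = rxn_idx[r.id]
            for mid, coef in r.stoich.items():
                if mid not in met_idx:
                    raise ModelError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )
                S[met_idx[mid], j] = coef
        return S, met_idx, rxn_idx

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "metabolites": [
            {
                "id": m.id,
                "compartment": m.compartment,
                "name": m.name,
                "carbons": m.carbons,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": r.stoich,
                "lb": r.lb,
                "ub": r.ub,
                "gpr": r.gpr.to_string() if r.gpr is not None else None,
            }
            for r in model.reactions
        ],
        "objective": model.objective_id,
        "exchanges": sorted(model.exchange_ids),
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    mets = [
        Metabolite(
            id=m["id"],
            compartment=m.get("compartment", "c"),
            name=m.get("name", ""),
            carbons=m.get("carbons"),
        )
        for m in data["metabolites"]
    ]
    met_ids = {m.id for m in mets}
    rxns = []
    for r in data["reactions"]:
        for mid in r["stoich"]:
            if mid not in met_ids:
                raise ModelError(
                    f"reaction {r['id']!r} references unknown metabolite {mid!r}"
                )
        gpr = parse_gpr(r["gpr"]) if r.get("gpr") else None
        rxns.append(
            Reaction(
                id=r["id"],
                stoich={k: float(v) for k, v in r["stoich"].items()},
                lb=float(r["lb"]),
                ub=float(r["ub"]),
                name=r.get("name", ""),
                gpr=gpr,
            )
        )
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id=data["objective"],
        exchange_ids=set(data.get("exchanges", [])),
    )
    if not model.has_reaction(model.objective_id):
        raise ModelError(f"objective reaction {model.objective_id!r} not in model")
    return model


def write_model(model: MetabolicModel, path) -> None:
    """Write a model to the package's JSON schema."""
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)


def read_model(path) -> MetabolicModel:
    """Read a model from the package's JSON schema; GPR strings are parsed
    to trees.  Raises :class:`ModelError` on schema violations."""
    with open(path) as fh:
        data = json.load(fh)
    return _model_from_dict(data)


def read_sbml(path) -> MetabolicModel:  # pragma: no cover - optional import
    """Lossy-tolerant SBML level-3 import (fbc bounds and GPRs when present).

    Requires ``python-libsbml``; raises ImportError when unavailable.
    """
    import libsbml  # type: ignore

    doc = libsbml.readSBML(str(path))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelError(f"could not parse SBML file {path}")
    mets = [
        Metabolite(id=m.getId(), compartment=m.getCompartment() or "c",
                   name=m.getName() or "")
        for m in sbml_model.getListOfSpecies()
    ]
    rxns = []
    for r in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for sr in r.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for sr in r.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        lb, ub = (-1000.0, 1000.0) if r.getReversible() else (0.0, 1000.0)
        fbc = r.getPlugin("fbc")
        gpr = None
        if fbc is not None:
            ga = fbc.getGeneProductAssociation()
            if ga is not None:
                try:
                    gpr = parse_gpr(
                        libsbml.formulaToString(ga.getAssociation().toInfix())
                    )
                except Exception:
                    gpr = None
        rxns.append(Reaction(id=r.getId(), stoich=stoich, lb=lb, ub=ub,
                             name=r.getName() or "", gpr=gpr))
    boundary = {r.id for r in rxns
                if sum(1 for c in r.stoich.values() if c != 0) == 1}
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          objective_id=rxns[0].id if rxns else "",
                          exchange_ids=boundary)


# ---------------------------------------------------------------------------
# Model edits
# ---------------------------------------------------------------------------


def add_glycogenolysis_reaction(
    model: MetabolicModel,
    ub: float = 3.0,
    glycogen_id: str = "glycogen",
    glucose_id: str = "glc",
) -> MetabolicModel:
    """Return a copy of ``model`` augmented with the lumped total glycogen
    breakdown reaction ``glycogen -> glucose`` (irreversible, upper bound
    ``ub`` mmol/h, no GPR).

    The single step lumps phosphorylase, debranching and glucose-6-phosphatase
    so the glycogen store can feed glucose export without transcript-scaled
    intermediates.
    """
    if model.has_reaction(GLYCOGEN_BREAKDOWN_ID):
        raise ModelError(
            f"model already contains reaction {GLYCOGEN_BREAKDOWN_ID!r}"
        )
    if glycogen_id not in model.metabolite_ids:
        raise ModelError(f"model has no metabolite {glycogen_id!r}")
    out = model.copy()
    out.reactions.append(
        Reaction(
            id=GLYCOGEN_BREAKDOWN_ID,
            stoich={glycogen_id: -1.0, glucose_id: 1.0},
            lb=0.0,
            ub=float(ub),
            name="total glycogen breakdown (lumped)",
        )
    )
    return out


def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Represent every reversible reaction as two complementary forward
    reactions.

    A reaction with bounds ``[lb, ub]``, ``lb < 0``, becomes a forward copy
    with bounds ``[0, ub]`` and a reverse copy (negated stoichiometry) with
    bounds ``[0, -lb]``.  The mapping original id -> (forward, reverse) is
    kept on the returned model so net flux can be reported per original id.
    """
    out = MetabolicModel(
        metabolites=[_copy.copy(m) for m in model.metabolites],
        objective_id=model.objective_id,
        exchange_ids=set(model.exchange_ids),
    )
    for r in model.reactions:
        if r.lb < 0:
            fwd = r.copy()
            fwd.lb = 0.0
            fwd.ub = max(r.ub, 0.0)
            rev = Reaction(
                id=r.id + REVERSE_SUFFIX,
                stoich={k: -v for k, v in r.stoich.items()},
                lb=0.0,
                ub=-r.lb,
                name=(r.name + " (reverse)") if r.name else "",
                gpr=r.gpr,
            )
            out.reactions.append(fwd)
            out.reactions.append(rev)
            out.split_map[r.id] = (r.id, rev.id)
            if r.id in model.exchange_ids:
                out.exchange_ids.add(rev.id)
        else:
            out.reactions.append(r.copy())
            out.split_map[r.id] = (r.id, None)
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_model(model: MetabolicModel, check_feasibility: bool = True) -> list[str]:
    """Return a list of violation messages (empty for a sane model).

    Checks bound ordering, stoichiometry references, orphan metabolites,
    exchange arity, carbon balance of internal reactions (where carbon counts
    are annotated), objective existence and steady-state feasibility.
    """
    violations: list[str] = []
    met_ids = set(model.metabolite_ids)
    carbons = {m.id: m.carbons for m in model.metabolites}
    used: set[str] = set()

    for r in model.reactions:
        if r.lb > r.ub:
            violations.append(f"reaction {r.id}: lb {r.lb} > ub {r.ub}")
        unknown = [m for m in r.stoich if m not in met_ids]
        for m in unknown:
            violations.append(f"reaction {r.id}: unknown metabolite {m!r}")
        used |= set(r.stoich)
        n_touched = sum(1 for c in r.stoich.values() if c != 0)
        if r.id in model.exchange_ids and n_touched != 1:
            violations.append(
                f"exchange reaction {r.id} touches {n_touched} metabolites"
            )
        if r.id not in model.exchange_ids and not unknown:
            cs = [carbons.get(m) for m in r.stoich]
            if all(c is not None for c in cs):
                balance = sum(coef * carbons[m] for m, coef in r.stoich.items())
                if abs(balance) > 1e-9:
                    violations.append(
                        f"reaction {r.id}: carbon imbalance ({balance:+g} C)"
                    )
    for m in model.metabolites:
        if m.id not in used:
            violations.append(f"orphan metabolite {m.id}")
    if not model.has_reaction(model.objective_id):
        violations.append(f"objective reaction {model.objective_id!r} missing")

    if check_feasibility and not violations:
        from scipy.optimize import linprog

        S, _, _ = model.stoichiometric_matrix()
        lb, ub = model.bounds_arrays()
        res = linprog(
            c=np.zeros(S.shape[1]),
            A_eq=S,
            b_eq=np.zeros(S.shape[0]),
            bounds=list(zip(lb, ub)),
            method="highs",
        )
        if res.status != 0:
            violations.append("steady state S.v=0 infeasible within bounds")
    return violations


# ---------------------------------------------------------------------------
# Built-in models
# ---------------------------------------------------------------------------


def build_chain_model(glycogen_ub: float = 2.0, lactate_ub: float = 6.0) -> MetabolicModel:
    """Minimal worked example: lactate gluconeogenesis (2 C3 -> 1 glucose)
    plus a lumped glycogen source feeding glucose export.

    With the defaults the FBA optimum is ``lactate_ub/2 + glycogen_ub = 5``:
    glycogenolysis contributes ``glycogen_ub`` (shadow price 1 on its upper
    bound) and gluconeogenesis the rest.  Used throughout the docs and tests
    as a hand-checkable oracle case.
    """
    mets = [
        Metabolite("lac", name="lactate", carbons=3),
        Metabolite("glc", name="glucose", carbons=6),
    ]
    rxns = [
        Reaction("UPT_lac", {"lac": 1.0}, 0.0, lactate_ub, name="lactate uptake"),
        Reaction("GNG", {"lac": -2.0, "glc": 1.0}, 0.0, 1000.0,
                 name="gluconeogenesis from lactate (lumped)"),
        Reaction(GLYCOGEN_BREAKDOWN_ID, {"glc": 1.0}, 0.0, glycogen_ub,
                 name="glycogen breakdown (lumped source)"),
        Reaction(GLUCOSE_EXPORT_ID, {"glc": -1.0}, 0.0, 1000.0,
                 name="glucose export (R1)"),
    ]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id=GLUCOSE_EXPORT_ID,
        exchange_ids={"UPT_lac", GLYCOGEN_BREAKDOWN_ID, GLUCOSE_EXPORT_ID},
    )


def build_toy_hepatocyte(include_glycogenolysis: bool = True) -> MetabolicModel:
    """Miniature fasting hepatocyte network.

    Covers the gluconeogenesis chain (pyruvate carboxylase, PEPCK-2,
    lumped enolase/phosphoglycerate kinase, fructose-1,6-bisphosphatase,
    glucose-6-phosphatase), lactate/alanine/glutamine/glycerol entry points,
    a lumped TCA cycle with the alpha-ketoglutarate dehydrogenase complex,
    beta-oxidation, ketogenesis, lipid-pool production ('HMR_0031') and
    glucose export ('HMR_9034', alias R1).  Cofactor bookkeeping (ATP/NAD)
    is deliberately omitted; carbon is conserved in every internal reaction.

    GPRs use the marker genes of each step: isoform alternatives as OR
    (LDHA/LDHB), complex subunits as AND (OGDH/DLST/DLD, PDHA1/DLAT), single
    genes elsewhere.  Respiration and glycogen breakdown carry no GPR.
    """
    big = 1000.0
    mets = [
        Metabolite("glc", name="glucose", carbons=6),
        Metabolite("glycogen", name="glycogen (glucosyl unit)", carbons=6),
        Metabolite("h6p", name="hexose 6-phosphate pool", carbons=6),
        Metabolite("lac", name="lactate", carbons=3),
        Metabolite("pyr", name="pyruvate", carbons=3),
        Metabolite("ala", name="alanine", carbons=3),
        Metabolite("gln", name="glutamine", carbons=5),
        Metabolite("akg", name="alpha-ketoglutarate", carbons=5),
        Metabolite("oaa", name="oxaloacetate", carbons=4),
        Metabolite("pep", name="phosphoenolpyruvate", carbons=3),
        Metabolite("dhap", name="triose phosphate pool", carbons=3),
        Metabolite("glyc", name="glycerol", carbons=3),
        Metabolite("ffa", name="free fatty acid (C16)", carbons=16),
        Metabolite("accoa", name="acetyl-CoA (acetyl unit)", carbons=2),
        Metabolite("ket", name="ketone body (acetoacetate)", carbons=4),
        Metabolite("co2", name="CO2", carbons=1),
        Metabolite("o2", name="O2", carbons=0),
        Metabolite("pi", name="inorganic phosphate", carbons=0),
        Metabolite("lipid", name="lipid pool (TAG-equivalent)", carbons=51),
    ]
    rxns = [
        # exchanges -----------------------------------------------------
        Reaction(GLUCOSE_EXPORT_ID, {"glc": -1.0}, -1.0, big,
                 name="glucose exchange / export (R1)"),
        Reaction("UPT_lac", {"lac": 1.0}, 0.0, 6.0, name="lactate uptake"),
        Reaction("UPT_ala", {"ala": 1.0}, 0.0, 2.0, name="alanine uptake"),
        Reaction("UPT_gln", {"gln": 1.0}, 0.0, 2.0, name="glutamine uptake"),
        Reaction("UPT_glyc", {"glyc": 1.0}, 0.0, 2.0, name="glycerol uptake"),
        Reaction("UPT_ffa", {"ffa": 1.0}, 0.0, 3.0, name="FFA uptake"),
        Reaction("UPT_o2", {"o2": 1.0}, 0.0, big, name="O2 uptake"),
        Reaction("EX_pi", {"pi": -1.0}, -100.0, 100.0, name="phosphate exchange"),
        Reaction("EX_co2", {"co2": -1.0}, -big, big, name="CO2 exchange"),
        Reaction("EX_ket", {"ket": -1.0}, 0.0, big, name="ketone body export"),
        Reaction("EX_lipid", {"lipid": -1.0}, 0.0, big, name="lipid pool sink"),
        Reaction("GLYC_STORE", {"glycogen": 1.0}, 0.0, big,
                 name="glycogen store mobilization"),
        # gluconeogenesis chain -----------------------------------------
        Reaction("R14", {"lac": -1.0, "pyr": 1.0}, -big, big,
                 name="L-lactate dehydrogenase",
                 gpr=parse_gpr("LDHA or LDHB")),
        Reaction("R13", {"ala": -1.0, "pyr": 1.0}, 0.0, big,
                 name="alanine transaminase (lumped)", gpr=parse_gpr("GPT")),
        Reaction("R12", {"gln": -1.0, "akg": 1.0}, 0.0, big,
                 name="glutaminolysis to alpha-ketoglutarate (lumped)",
                 gpr=parse_gpr("GLS")),
        Reaction("R23", {"akg": -1.0, "oaa": 1.0, "co2": 1.0}, 0.0, big,
                 name="alpha-ketoglutarate dehydrogenase (TCA segment, lumped)",
                 gpr=parse_gpr("OGDH and DLST and DLD")),
        Reaction("R9", {"pyr": -1.0, "co2": -1.0, "oaa": 1.0}, 0.0, big,
                 name="pyruvate carboxylase", gpr=parse_gpr("PC")),
        Reaction("R28", {"oaa": -1.0, "pep": 1.0, "co2": 1.0}, 0.0, 200.0,
                 name="phosphoenolpyruvate carboxykinase-2",
                 gpr=parse_gpr("PCK2")),
        Reaction("R4", {"pep": -1.0, "dhap": 1.0}, 0.0, 80.0,
                 name="enolase/phosphoglycerate kinase (lumped)",
                 gpr=parse_gpr("ENO1")),
        Reaction("R7", {"glyc": -1.0, "dhap": 1.0}, 0.0, big,
                 name="glycerol kinase + G3P dehydrogenase (lumped)",
                 gpr=parse_gpr("GK")),
        Reaction("R5", {"dhap": -2.0, "h6p": 1.0}, 0.0, 40.0,
                 name="fructose-1,6-bisphosphatase (with aldolase, lumped)",
                 gpr=parse_gpr("FBP1")),
        Reaction("R2", {"h6p": -1.0, "glc": 1.0, "pi": 1.0}, 0.0, 25.0,
                 name="glucose-6-phosphatase", gpr=parse_gpr("G6PC")),
        Reaction("R3", {"glc": -1.0, "pi": -1.0, "h6p": 1.0}, 0.0, big,
                 name="glucokinase", gpr=parse_gpr("GCK")),
        Reaction("R6", {"h6p": -1.0, "dhap": 2.0}, 0.0, big,
                 name="phosphofructokinase/aldolase (glycolytic, lumped)",
                 gpr=parse_gpr("PFKL")),
        # oxidative metabolism ------------------------------------------
        Reaction("R10", {"pyr": -1.0, "accoa": 1.0, "co2": 1.0}, 0.0, big,
                 name="pyruvate dehydrogenase complex",
                 gpr=parse_gpr("PDHA1 and DLAT")),
        Reaction("R11", {"accoa": -1.0, "oaa": -1.0, "akg": 1.0, "co2": 1.0},
                 0.0, big, name="citrate synthase to alpha-KG (lumped)",
                 gpr=parse_gpr("CS")),
        Reaction("R16", {"ffa": -1.0, "accoa": 8.0}, 0.0, big,
                 name="beta-oxidation (lumped)", gpr=parse_gpr("CPT1A")),
        Reaction("R17", {"accoa": -2.0, "ket": 1.0}, 0.0, big,
                 name="ketogenesis (lumped)", gpr=parse_gpr("HMGCS2")),
        Reaction("R18", {"accoa": -1.0, "o2": -2.0, "co2": 2.0}, 0.0, big,
                 name="terminal oxidation (lumped respiration)"),
        Reaction(LIPID_PRODUCTION_ID,
                 {"dhap": -1.0, "ffa": -3.0, "lipid": 1.0}, 0.0, big,
                 name="lipid (TAG) synthesis", gpr=parse_gpr("DGAT1")),
    ]
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id=GLUCOSE_EXPORT_ID,
        exchange_ids={
            GLUCOSE_EXPORT_ID, "UPT_lac", "UPT_ala", "UPT_gln", "UPT_glyc",
            "UPT_ffa", "UPT_o2", "EX_pi", "EX_co2", "EX_ket", "EX_lipid",
            "GLYC_STORE",
        },
    )
    if include_glycogenolysis:
        model = add_glycogenolysis_reaction(model)
    return model
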