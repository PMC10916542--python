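"""Read, edit, and write genome-scale metabolic models (GEMs).

The canonical in-memory representation is a :class:`StrainModel`: a flat
collection of metabolites and reactions in which, after
:func:`split_reversible`, every reaction is irreversible (lower bound 0).
A reversible parent reaction ``R`` with bounds ``(lb < 0, ub)`` becomes a
forward copy ``R`` with bounds ``(0, ub)`` and a sibling ``R_reverse`` with
bounds ``(0, -lb)`` and negated stoichiometry, so any net flux remains
representable as forward minus reverse.

File IO is delegated to cobrapy: SBML Level 3 + fbc and BiGG-style JSON both
round-trip through ``cobra.io``.  Package-specific annotations (reaction
kind, strain of origin, pre-namespace base id, enzyme kinetics) travel in
the cobra ``notes`` field so they survive serialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import cobra
from cobra.core.gene import GPR

from .errors import EditError, GEMParseError, ModelValidationError

__all__ = [
    "Enzyme",
    "Metabolite",
    "ReactionIR",
    "StrainModel",
    "read_gem",
    "write_model",
    "split_reversible",
    "apply_edits",
    "validate_model",
    "REVERSE_SUFFIX",
]

REVERSE_SUFFIX = "_reverse"

#: reaction kinds
KIND_INTERNAL = "internal"
KIND_EXCHANGE = "exchange"
KIND_LINK = "link"
KIND_BIOMASS = "biomass"
_KINDS = frozenset({KIND_INTERNAL, KIND_EXCHANGE, KIND_LINK, KIND_BIOMASS})


@dataclass(frozen=True)
class Enzyme:
    """Turnover number and molecular weight of the catalyst of one reaction.

    ``kcat`` is in h^-1 and ``mw`` in g mmol^-1 (numerically kDa), so an
    enzyme cost v * mw / kcat has units g enzyme per gDW, commensurate with
    the per-strain pool budget.
    """

    kcat: float
    mw: float

    def __post_init__(self) -> None:
        if not self.kcat > 0:
            raise ValueError(f"kcat must be positive, got {self.kcat}")
        if not self.mw > 0:
            raise ValueError(f"mw must be positive, got {self.mw}")

    @property
    def cost_coefficient(self) -> float:
        """Enzyme mass per unit flux, mw/kcat (g h gDW^-1 mmol^-1)."""
        return self.mw / self.kcat


@dataclass
class Metabolite:
    id: str
    base_id: str = ""
    name: str = ""
    compartment: str = ""
    formula: Optional[str] = None
    origin: str = ""  # strain tag, "shared", or "" for raw models

    def __post_init__(self) -> None:
        if not self.base_id:
            self.base_id = self.id


@dataclass
class ReactionIR:
    """One (irreversible, after splitting) reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed).  ``kind`` is one of internal/exchange/link/biomass.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = math.inf
    gene_rule: Optional[str] = None
    origin: str = ""
    kind: str = KIND_INTERNAL
    enzyme: Optional[Enzyme] = None
    base_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not self.base_id:
            self.base_id = self.id
        if self.kind not in _KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r} for {self.id}")

    def copy(self) -> "ReactionIR":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class StrainModel:
    """One strain's metabolic network, optionally namespaced with a tag."""

    tag: str = ""
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, ReactionIR] = field(default_factory=dict)
    biomass_id: Optional[str] = None
    pool: Optional[object] = None  # EnzymePool, set by enzyme_constraints

    def copy(self) -> "StrainModel":
        return StrainModel(
            tag=self.tag,
            metabolites={k: replace(v) for k, v in self.metabolites.items()},
            reactions={k: v.copy() for k, v in self.reactions.items()},
            biomass_id=self.biomass_id,
            pool=self.pool,
        )

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: ReactionIR) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn


def validate_model(model: StrainModel) -> None:
    """Check StrainModel invariants; raise ModelValidationError naming the violation."""
    for rxn in model.reactions.values():
        for mid in rxn.stoichiometry:
            if mid not in model.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolite {mid!r}"
                )
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r} has lower_bound {rxn.lower_bound} "
                f"> upper_bound {rxn.upper_bound}"
            )
    if model.biomass_id is not None and model.biomass_id not in model.reactions:
        raise ModelValidationError(
            f"biomass reaction {model.biomass_id!r} not present in model"
        )


# ---------------------------------------------------------------------------
# cobra conversion


def _from_cobra(cm: cobra.Model, source: str = "") -> StrainModel:
    model = StrainModel()
    for m in cm.metabolites:
        notes = dict(m.notes or {})
        model.metabolites[m.id] = Metabolite(
            id=m.id,
            base_id=str(notes.get("base_id", m.id)),
            name=m.name or "",
            compartment=m.compartment or "",
            formula=m.formula or None,
            origin=str(notes.get("origin", "")),
        )
    try:
        objective_ids = [
            r.id for r in cobra.util.solver.linear_reaction_coefficients(cm)
        ]
    except Exception:  # pragma: no cover - solver-interface quirks
        objective_ids = []
    biomass_id = objective_ids[0] if objective_ids else None
    if biomass_id is None:
        for r in cm.reactions:
            if "biomass" in r.id.lower():
                biomass_id = r.id
                break
    for r in cm.reactions:
        if r.lower_bound is None or r.upper_bound is None:
            raise GEMParseError(
                f"{source}: reaction {r.id!r} is missing flux bounds"
            )
        notes = dict(r.notes or {})
        kind = notes.get("kind")
        if kind is None:
            if r.id == biomass_id:
                kind = KIND_BIOMASS
            elif len(r.metabolites) == 1:
                kind = KIND_EXCHANGE
            else:
                kind = KIND_INTERNAL
        enzyme = None
        enz_notes = notes.get("enzyme")
        if isinstance(enz_notes, str):  # SBML notes flatten dicts to strings
            import ast
            import html

            try:
                enz_notes = ast.literal_eval(html.unescape(enz_notes))
            except (ValueError, SyntaxError):
                enz_notes = None
        if isinstance(enz_notes, Mapping):
            enzyme = Enzyme(kcat=float(enz_notes["kcat"]), mw=float(enz_notes["mw"]))
        model.reactions[r.id] = ReactionIR(
            id=r.id,
            base_id=str(notes.get("base_id", r.id)),
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gene_rule=r.gene_reaction_rule or None,
            origin=str(notes.get("origin", "")),
            kind=kind,
            enzyme=enzyme,
            name=r.name or "",
        )
    model.biomass_id = biomass_id
    return model


_SBML_UNSAFE = "@"


def _sanitize(identifier: str, fmt: str) -> str:
    # SBML SIds forbid "@"; the namespace separator falls back to "__".
    if fmt == "sbml":
        return identifier.replace(_SBML_UNSAFE, "__")
    return identifier


def _to_cobra(model, fmt: str = "json") -> cobra.Model:
    # accepts StrainModel or anything exposing .metabolites / iterable reactions
    from .community_assembly import CommunityModel  # local import, no cycle at load

    cm = cobra.Model("consortia_model")
    if isinstance(model, CommunityModel):
        metabolites = model.all_metabolites()
        reactions = list(model.all_reactions())
        biomass_id = None
    else:
        validate_model(model)
        metabolites = model.metabolites
        reactions = list(model.reactions.values())
        biomass_id = model.biomass_id

    cobra_mets = {}
    for met in metabolites.values():
        m = cobra.Metabolite(
            _sanitize(met.id, fmt),
            name=met.name,
            compartment=met.compartment or "c",
            formula=met.formula,
        )
        m.notes["base_id"] = met.base_id
        if met.origin:
            m.notes["origin"] = met.origin
        cobra_mets[met.id] = m
    cm.add_metabolites(list(cobra_mets.values()))

    big = 1e6  # cobra/SBML cannot serialize infinite bounds portably
    cobra_rxns = []
    for rxn in reactions:
        r = cobra.Reaction(_sanitize(rxn.id, fmt), name=rxn.name)
        r.notes["kind"] = rxn.kind
        r.notes["base_id"] = rxn.base_id
        if rxn.origin:
            r.notes["origin"] = rxn.origin
        if rxn.enzyme is not None:
            r.notes["enzyme"] = {"kcat": rxn.enzyme.kcat, "mw": rxn.enzyme.mw}
        cobra_rxns.append(r)
        r._consortia_stoich = rxn  # noqa: SLF001 - local staging only
    cm.add_reactions(cobra_rxns)
    for r in cobra_rxns:
        rxn = r._consortia_stoich
        del r._consortia_stoich
        r.add_metabolites(
            {cm.metabolites.get_by_id(_sanitize(mid, fmt)): coef
             for mid, coef in rxn.stoichiometry.items()}
        )
        lb = rxn.lower_bound if math.isfinite(rxn.lower_bound) else -big
        ub = rxn.upper_bound if math.isfinite(rxn.upper_bound) else big
        r.bounds = (lb, ub)
        if rxn.gene_rule:
            r.gene_reaction_rule = rxn.gene_rule
    if biomass_id is not None:
        cm.objective = cm.reactions.get_by_id(_sanitize(biomass_id, fmt))
    return cm


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("sbml", "json"):
            raise ValueError(f"unknown model format {fmt!r}")
        return fmt
    if path.suffix.lower() in (".xml", ".sbml"):
        return "sbml"
    if path.suffix.lower() == ".json":
        return "json"
    raise ValueError(f"cannot infer model format from {path.name!r}")


def read_gem(path, format: Optional[str] = None) -> StrainModel:
    """Read an SBML-fbc or BiGG-style JSON GEM into a StrainModel.

    Reversibility (negative lower bounds) is preserved until
    :func:`split_reversible` is called.
    """
    path = Path(path)
    if not path.exists():
        raise GEMParseError(f"model file not found: {path}")
    fmt = _infer_format(path, format)
    try:
        if fmt == "sbml":
            cm = cobra.io.read_sbml_model(str(path))
        else:
            cm = cobra.io.load_json_model(str(path))
    except Exception as exc:
        raise GEMParseError(f"could not parse {path.name}: {exc}") from exc
    return _from_cobra(cm, source=path.name)


def write_model(model, path, format: Optional[str] = None) -> None:
    """Write a StrainModel or CommunityModel to SBML or BiGG-style JSON.

    Round-trips through :func:`read_gem` preserve ids, stoichiometry, bounds
    and gene rules (communities read back as one flat StrainModel).  For SBML
    the "@" namespace separator is rewritten to "__" to satisfy the SId
    character set.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    cm = _to_cobra(model, fmt=fmt)
    try:
        if fmt == "sbml":
            cobra.io.write_sbml_model(cm, str(path))
        else:
            cobra.io.save_json_model(cm, str(path))
    except OSError:
        raise
    except Exception as exc:  # pragma: no cover
        raise GEMParseError(f"could not write {path.name}: {exc}") from exc


# ---------------------------------------------------------------------------
# irreversible splitting


def split_reversible(model: StrainModel) -> StrainModel:
    """Disassemble every reversible reaction into an irreversible pair.

    A parent with bounds (lb < 0, ub) yields a forward copy (0, max(ub, 0))
    and a ``_reverse`` sibling (0, -lb) with negated stoichiometry.
    Idempotent on already-split models.
    """
    out = StrainModel(
        tag=model.tag,
        metabolites={k: replace(v) for k, v in model.metabolites.items()},
        biomass_id=model.biomass_id,
        pool=model.pool,
    )
    for rxn in model.reactions.values():
        if rxn.lower_bound >= 0:
            out.add_reaction(rxn.copy())
            continue
        rev_id = rxn.id + REVERSE_SUFFIX
        if rev_id in model.reactions:
            raise ModelValidationError(
                f"cannot split {rxn.id!r}: id {rev_id!r} already exists"
            )
        fwd = rxn.copy()
        fwd.lower_bound = 0.0
        fwd.upper_bound = max(rxn.upper_bound, 0.0)
        out.add_reaction(fwd)
        rev = rxn.copy()
        rev.id = rev_id
        rev.base_id = rxn.base_id + REVERSE_SUFFIX
        rev.stoichiometry = {m: -c for m, c in rxn.stoichiometry.items()}
        rev.lower_bound = 0.0
        rev.upper_bound = -rxn.lower_bound
        out.add_reaction(rev)
    return out


# ---------------------------------------------------------------------------
# edits


def _gene_names(rule: str) -> frozenset[str]:
    try:
        return frozenset(str(g) for g in GPR.from_string(rule).genes)
    except Exception as exc:
        raise EditError(f"could not parse gene rule {rule!r}: {exc}") from exc


def gene_rule_active(rule: Optional[str], knocked_out: Iterable[str]) -> bool:
    """Evaluate a boolean and/or gene rule under a set of gene knockouts.

    "and" members form a complex (any knockout closes the reaction); "or"
    members are isozymes (all must be removed).  Empty rules stay active.
    """
    if not rule:
        return True
    return bool(GPR.from_string(rule).eval(knockouts=set(knocked_out)))


def apply_edits(
    model: StrainModel,
    knockouts: Sequence[str] = (),
    additions: Sequence[Mapping] = (),
    bound_changes: Optional[Mapping[str, tuple]] = None,
    delete: bool = False,
) -> StrainModel:
    """Apply knockouts, reaction additions, and bound changes; returns a new model.

    Knockout ids may be reaction ids or gene ids (resolved through gene
    rules).  Knocked-out reactions keep their row with upper_bound 0 for
    auditability unless ``delete=True``.
    """
    out = model.copy()
    gene_universe: set[str] = set()
    for rxn in model.reactions.values():
        if rxn.gene_rule:
            gene_universe |= _gene_names(rxn.gene_rule)

    gene_kos: set[str] = set()
    rxn_kos: list[str] = []
    unknown = []
    for kid in knockouts:
        if kid in out.reactions:
            rxn_kos.append(kid)
        elif kid in gene_universe:
            gene_kos.add(kid)
        else:
            unknown.append(kid)
    if unknown:
        raise EditError(f"unknown knockout id(s): {', '.join(sorted(unknown))}")

    for rid in rxn_kos:
        if delete:
            del out.reactions[rid]
        else:
            out.reactions[rid].upper_bound = 0.0
            out.reactions[rid].lower_bound = 0.0
    if gene_kos:
        for rxn in list(out.reactions.values()):
            if rxn.gene_rule and not gene_rule_active(rxn.gene_rule, gene_kos):
                if delete:
                    del out.reactions[rxn.id]
                else:
                    rxn.upper_bound = 0.0
                    rxn.lower_bound = 0.0

    for spec in additions:
        rid = spec["id"]
        if rid in out.reactions:
            raise EditError(f"added reaction id {rid!r} collides with existing id")
        for met_spec in spec.get("metabolites", ()):  # inline declarations
            if met_spec["id"] not in out.metabolites:
                out.add_metabolite(
                    Metabolite(
                        id=met_spec["id"],
                        name=met_spec.get("name", ""),
                        compartment=met_spec.get("compartment", "c"),
                        formula=met_spec.get("formula"),
                        origin=out.tag,
                    )
                )
        stoich = {}
        for mid, coef in spec["stoichiometry"].items():
            if mid not in out.metabolites:
                raise EditError(
                    f"added reaction {rid!r} references unknown metabolite {mid!r}"
                )
            stoich[mid] = float(coef)
        enzyme = None
        if spec.get("enzyme"):
            enzyme = Enzyme(
                kcat=float(spec["enzyme"]["kcat"]), mw=float(spec["enzyme"]["mw"])
            )
        out.add_reaction(
            ReactionIR(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(spec.get("lower_bound", 0.0)),
                upper_bound=float(spec.get("upper_bound", math.inf)),
                gene_rule=spec.get("gene_rule"),
                origin=out.tag,
                kind=KIND_INTERNAL,
                enzyme=enzyme,
            )
        )

    for rid, bounds in (bound_changes or {}).items():
        if rid not in out.reactions:
            raise EditError(f"bound change references unknown reaction {rid!r}")
        lb, ub = bounds
        rxn = out.reactions[rid]
        if lb is not None:
            rxn.lower_bound = float(lb)
        if ub is not None:
            rxn.upper_bound = float(ub)

    validate_model(out)
    return out
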