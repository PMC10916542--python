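"""Per-strain enzyme pool constraints.

Each strain x carries one inequality

    sum_i  v_xi * MW_xi / kcat_xi  <=  ENZ_x

over its enzyme-annotated reactions, where ENZ_x = ptot * f * sigma is the
strain's total enzyme budget (g enzyme per gDW): ptot the total protein
fraction (g protein gDW^-1), f the mass fraction of that protein that is
metabolically active enzyme, and sigma the average saturation.  The term
v * MW / kcat is the enzyme cost of sustaining flux v through one reaction.
Sub-models remain independently constrained: one row per strain, with
disjoint variable support.

Kinetic data arrive as a prepared TSV/CSV table (reaction_id, kcat, mw);
kcat calibration against SABIO-RK/BRENDA is upstream of this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .gem_io import KIND_INTERNAL, Enzyme, StrainModel

__all__ = [
    "EnzymeEntry",
    "EnzymePool",
    "ConstraintRow",
    "load_enzyme_table",
    "attach",
    "AttachResult",
    "enzyme_cost",
    "pool_budget",
    "constraint_row",
]

_PER_SECOND = {"1/s", "s^-1", "s-1", "per_s", "per_second"}
_PER_HOUR = {"1/h", "h^-1", "h-1", "per_h", "per_hour"}


@dataclass(frozen=True)
class EnzymeEntry:
    """One kinetic table row; kcat in h^-1, mw in g mmol^-1 (= kDa)."""

    reaction_id: str
    kcat: float
    mw: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.kcat > 0:
            raise ValueError(f"{self.reaction_id}: kcat must be > 0, got {self.kcat}")
        if not self.mw > 0:
            raise ValueError(f"{self.reaction_id}: mw must be > 0, got {self.mw}")


@dataclass(frozen=True)
class EnzymePool:
    """Total enzyme budget of one strain: enz = ptot * f * sigma."""

    tag: str
    ptot: float
    f: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.ptot > 0:
            raise ValueError(f"ptot must be > 0, got {self.ptot}")
        if not 0 < self.f <= 1:
            raise ValueError(f"f must be in (0, 1], got {self.f}")
        if not 0 < self.sigma <= 1:
            raise ValueError(f"sigma must be in (0, 1], got {self.sigma}")

    @property
    def enz(self) -> float:
        return self.ptot * self.f * self.sigma


def pool_budget(ptot: float, f: float, sigma: float, tag: str = "") -> EnzymePool:
    """Build an EnzymePool; arguments validated, enz = ptot * f * sigma."""
    return EnzymePool(tag=tag, ptot=float(ptot), f=float(f), sigma=float(sigma))


def enzyme_cost(v: float, mw: float, kcat: float) -> float:
    """Enzyme mass (g gDW^-1) needed to sustain flux v: v * mw / kcat."""
    if kcat <= 0:
        raise ValueError(f"kcat must be > 0, got {kcat}")
    return v * mw / kcat


def _convert_kcat(value: float, unit: str) -> float:
    unit = unit.strip().lower()
    if unit in _PER_SECOND:
        return value * 3600.0
    if unit in _PER_HOUR or unit == "":
        return value
    raise ValueError(f"unrecognized kcat unit {unit!r}")


def load_enzyme_table(path) -> list[EnzymeEntry]:
    """Load a kinetic table (TSV/CSV: reaction_id, kcat[, kcat_unit], mw[, provenance]).

    Per-second turnover numbers are converted to h^-1 when the unit column
    (or a ``kcat_per_s`` header) says so.  Nonpositive values and duplicate
    reaction ids are rejected with the offending row named.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, comment="#")
    frame.columns = [c.strip() for c in frame.columns]
    if "reaction_id" not in frame.columns:
        raise ValueError(f"{path.name}: missing required column 'reaction_id'")
    if "kcat" in frame.columns:
        kcat_col, header_unit = "kcat", ""
    elif "kcat_per_s" in frame.columns:
        kcat_col, header_unit = "kcat_per_s", "1/s"
    elif "kcat_per_h" in frame.columns:
        kcat_col, header_unit = "kcat_per_h", "1/h"
    else:
        raise ValueError(f"{path.name}: missing kcat column")
    if "mw" not in frame.columns:
        raise ValueError(f"{path.name}: missing required column 'mw'")

    entries: list[EnzymeEntry] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        rid = str(row["reaction_id"]).strip()
        if rid in seen:
            raise ValueError(f"{path.name} line {line}: duplicate reaction id {rid!r}")
        seen.add(rid)
        unit = str(row["kcat_unit"]).strip() if "kcat_unit" in frame.columns else header_unit
        try:
            kcat = _convert_kcat(float(row[kcat_col]), unit)
            entry = EnzymeEntry(
                reaction_id=rid,
                kcat=kcat,
                mw=float(row["mw"]),
                provenance=str(row.get("provenance", "") or ""),
            )
        except ValueError as exc:
            raise ValueError(f"{path.name} line {line}: {exc}") from exc
        entries.append(entry)
    return entries


@dataclass
class AttachResult:
    model: StrainModel
    report: pd.DataFrame  # columns: reaction_id, matched, source
    coverage: float  # fraction of internal reactions annotated from the table


def attach(
    model: StrainModel,
    entries: Sequence[EnzymeEntry],
    fallback: Literal["exclude", "default_kcat"] = "exclude",
) -> AttachResult:
    """Annotate internal reactions with (kcat, mw), matching on base_id.

    Unmatched internal reactions are handled per ``fallback``: "exclude"
    drops them from the pool inequality (constraint weakened/removed, the
    treatment used for heterologous reactions without valid kinetics);
    "default_kcat" assigns the strain-median kcat and mw of the matched set.
    Exchange, link and biomass reactions never carry enzyme cost.
    """
    by_id = {e.reaction_id: e for e in entries}
    out = model.copy()
    rows = []
    matched_entries: list[EnzymeEntry] = []
    unmatched: list[str] = []
    for rxn in out.reactions.values():
        if rxn.kind != KIND_INTERNAL:
            continue
        entry = by_id.get(rxn.base_id) or by_id.get(rxn.id)
        if entry is not None:
            rxn.enzyme = Enzyme(kcat=entry.kcat, mw=entry.mw)
            matched_entries.append(entry)
            rows.append((rxn.id, True, "table"))
        else:
            unmatched.append(rxn.id)
    if unmatched:
        if fallback == "default_kcat" and matched_entries:
            med_kcat = float(np.median([e.kcat for e in matched_entries]))
            med_mw = float(np.median([e.mw for e in matched_entries]))
            default = Enzyme(kcat=med_kcat, mw=med_mw)
            for rid in unmatched:
                out.reactions[rid].enzyme = default
                rows.append((rid, False, "default"))
        else:
            if fallback == "default_kcat":
                warnings.warn(
                    f"strain {model.tag or '<untagged>'}: no matched entries to "
                    "derive a default kcat; excluding unmatched reactions",
                    stacklevel=2,
                )
            for rid in unmatched:
                out.reactions[rid].enzyme = None
                rows.append((rid, False, "excluded"))
    if not entries:
        warnings.warn("empty enzyme table: all reactions excluded from the pool",
                      stacklevel=2)
    report = pd.DataFrame(rows, columns=["reaction_id", "matched", "source"])
    n_internal = len(report)
    coverage = float(report["matched"].sum() / n_internal) if n_internal else 0.0
    return AttachResult(model=out, report=report, coverage=coverage)


@dataclass(frozen=True)
class ConstraintRow:
    """One strain's pool inequality: sum coefficients[r] * v_r <= bound."""

    tag: str
    coefficients: dict[str, float] = field(default_factory=dict)
    bound: float = 0.0


def constraint_row(model: StrainModel) -> Optional[ConstraintRow]:
    """Assemble the strain's enzyme inequality (coefficients mw/kcat, bound enz).

    Raises if the strain has no pool; returns None with a warning when no
    reaction is annotated (the constraint is vacuous).
    """
    if model.pool is None:
        raise ValueError(
            f"strain {model.tag or '<untagged>'} has no enzyme pool set"
        )
    coeffs = {
        rxn.id: rxn.enzyme.cost_coefficient
        for rxn in model.reactions.values()
        if rxn.enzyme is not None
    }
    if not coeffs:
        warnings.warn(
            f"strain {model.tag or '<untagged>'}: no enzyme-annotated reactions; "
            "pool constraint is vacuous",
            stacklevel=2,
        )
        return None
    return ConstraintRow(tag=model.tag, coefficients=coeffs, bound=model.pool.enz)
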