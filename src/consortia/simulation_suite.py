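"""Simulation campaigns: growth prediction, overflow scans, ratio sweeps,
allocation-strategy comparison, and yield/error metrics.

Yields are mass yields, yield = (v_product * MW_product) / (v_substrate *
MW_substrate) in g product per g substrate; the experimental counterpart is
the concentration ratio C_product / C_substrate.  Simulated and measured
yield series over a ratio grid are compared with the signed relative
estimation error per point and the range-normalized root-mean-square error
(NRMSE) over the grid.  The NRMSE denominator is the experimental series'
range (max - min); the mean inside the root divides by the number of grid
points, the standard RMSE convention.

Reported flux distributions come from a parsimonious (pFBA) refinement so
sweep tables are bit-identical across runs; objective values are unaffected
by that refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .community_assembly import CommunityModel, RatioSpec, set_ratio
from .gem_io import REVERSE_SUFFIX, StrainModel
from .lp_engine import FBAResult, build_lp, pfba_resolve, solve

__all__ = [
    "YieldRecord", "SweepResult", "MetricReport", "ComparisonReport",
    "max_growth", "overflow_scan", "ratio_sweep", "compare_strategies",
    "mass_yield", "estimation_error", "nrmse", "metric_report",
    "DEFAULT_TWO_STRAIN_GRID", "DEFAULT_THREE_STRAIN_GRID",
]

#: canonical two-strain inoculation grid, 9:1 through 1:9
DEFAULT_TWO_STRAIN_GRID: tuple[tuple[float, ...], ...] = (
    (9, 1), (4, 1), (3, 1), (2, 1), (1, 1), (1, 2), (1, 4), (1, 9),
)

#: canonical 13-point three-strain inoculation grid
DEFAULT_THREE_STRAIN_GRID: tuple[tuple[float, ...], ...] = (
    (1, 1, 1),
    (2, 1, 1), (1, 2, 1), (1, 1, 2),
    (3, 1, 1), (1, 3, 1), (1, 1, 3),
    (2, 2, 1), (2, 1, 2), (1, 2, 2),
    (2, 3, 1), (3, 2, 1), (1, 2, 3),
)


def default_grid(n_strains: int) -> tuple[tuple[float, ...], ...]:
    if n_strains == 2:
        return DEFAULT_TWO_STRAIN_GRID
    if n_strains == 3:
        return DEFAULT_THREE_STRAIN_GRID
    raise ValueError(f"no default grid for {n_strains} strains")


# ---------------------------------------------------------------------------
# metrics


def mass_yield(v_p: float, mw_p: float, v_s: float, mw_s: float) -> float:
    """Mass yield (g/g): (v_p * mw_p) / (v_s * mw_s); undefined for v_s = 0."""
    if v_s == 0:
        raise ValueError("mass yield undefined: substrate flux is zero")
    return (v_p * mw_p) / (v_s * mw_s)


def estimation_error(yield_sim: float, yield_exp: float) -> float:
    """Signed relative error (sim - exp) / exp."""
    if yield_exp == 0:
        raise ValueError("estimation error undefined: experimental yield is zero")
    return (yield_sim - yield_exp) / yield_exp


def nrmse(sim: Sequence[float], exp: Sequence[float]) -> float:
    """Range-normalized RMSE of a simulated vs experimental yield series.

    sqrt(mean((sim - exp)^2)) / (max(exp) - min(exp)).  Requires equal-length
    series of at least two points and a non-constant experimental series.
    """
    s = np.asarray(sim, dtype=float)
    e = np.asarray(exp, dtype=float)
    if s.shape != e.shape:
        raise ValueError(f"series lengths differ: {s.shape} vs {e.shape}")
    if s.size < 2:
        raise ValueError("nrmse needs at least two grid points")
    spread = float(e.max() - e.min())
    if spread == 0:
        raise ValueError("experimental series is constant: zero range denominator")
    return float(np.sqrt(np.mean((s - e) ** 2)) / spread)


@dataclass(frozen=True)
class MetricReport:
    estimation_errors: tuple[float, ...]
    nrmse: float
    yield_max: float
    yield_min: float


def metric_report(sim: Sequence[float], exp: Sequence[float]) -> MetricReport:
    """Per-point signed errors plus NRMSE over a ratio grid."""
    errors = tuple(estimation_error(s, e) for s, e in zip(sim, exp, strict=True))
    return MetricReport(
        estimation_errors=errors,
        nrmse=nrmse(sim, exp),
        yield_max=float(max(exp)),
        yield_min=float(min(exp)),
    )


# ---------------------------------------------------------------------------
# campaigns


@dataclass(frozen=True)
class YieldRecord:
    product_id: str
    substrate_id: Optional[str]
    v_product: float
    v_substrate: float
    mw_product: float
    mw_substrate: float

    @property
    def mass_yield(self) -> float:
        if self.v_substrate == 0:
            return math.nan
        return mass_yield(self.v_product, self.mw_product,
                          self.v_substrate, self.mw_substrate)


@dataclass
class SweepResult:
    ratios: list[RatioSpec]
    records: list[YieldRecord]
    statuses: list[str]
    values: list[float]                # objective (product) flux per point

    @property
    def argmax_index(self) -> int:
        return int(np.argmax(self.values))

    @property
    def best_ratio(self) -> RatioSpec:
        return self.ratios[self.argmax_index]

    @property
    def best_value(self) -> float:
        return self.values[self.argmax_index]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ratio, rec, status, val in zip(self.ratios, self.records,
                                           self.statuses, self.values):
            row = {f"frac_{t}": f for t, f in ratio.fractions}
            row.update(ratio=ratio.label(), status=status,
                       product_flux=val, mass_yield=rec.mass_yield)
            rows.append(row)
        return pd.DataFrame(rows)


def max_growth(
    model: Union[CommunityModel, StrainModel],
    tag: Optional[str] = None,
    enzyme_constraints: bool = True,
) -> FBAResult:
    """Maximize one strain's biomass flux under all community constraints.

    Infeasibility is reported through the result status, never as a silent
    zero growth rate.
    """
    if isinstance(model, CommunityModel):
        sub = model.submodel(tag) if tag else model.submodels[0]
        biomass = sub.biomass_id
    else:
        biomass = model.biomass_id
    if biomass is None:
        raise ValueError("model has no biomass reaction to maximize")
    problem = build_lp(model, objective=biomass,
                       enzyme_constraints=enzyme_constraints)
    return solve(problem)


def overflow_scan(
    model: StrainModel,
    uptake_grid: Sequence[float],
    uptake_reaction: str = "EX_glc" + REVERSE_SUFFIX,
    objective: str = "EX_atp",
    byproducts: Sequence[str] = ("EX_ac",),
) -> pd.DataFrame:
    """Scan substrate uptake bounds; record objective and byproduct secretion.

    One LP per grid point, pFBA-refined so secretion fluxes are unique.
    """
    if len(uptake_grid) == 0:
        raise ValueError("empty uptake grid")
    rows = []
    for uptake in uptake_grid:
        m = model.copy()
        m.reactions[uptake_reaction].upper_bound = float(uptake)
        problem = build_lp(m, objective=objective)
        first = solve(problem)
        result = pfba_resolve(problem, first) if first.optimal else first
        row = {"uptake": float(uptake), "status": result.status,
               "objective": first.objective_value if first.optimal else 0.0}
        for bp in byproducts:
            row[bp] = result.fluxes.get(bp, 0.0) if result.optimal else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _uptake_flux(result: FBAResult, substrate: Optional[str]) -> float:
    if substrate is None:
        return 0.0
    return result.fluxes.get(substrate, 0.0)


def ratio_sweep(
    community: CommunityModel,
    grid: Optional[Sequence] = None,
    objective: Optional[str] = None,
    substrate: Optional[str] = None,
    mw_product: float = 1.0,
    mw_substrate: float = 1.0,
    enzyme_constraints: bool = True,
) -> SweepResult:
    """Sweep inoculation ratios: set_ratio -> build -> solve per grid point.

    Grid entries are RatioSpecs, tag->fraction mappings, or bare tuples
    matched against the community's strain order.  Infeasible points are
    kept in the table with value 0 and their status flagged, so grids stay
    rectangular.  Per-point values are objective (product) fluxes.
    """
    objective = objective or community.objective
    if objective is None:
        raise ValueError("no objective given for the sweep")
    tags = community.strain_tags
    if grid is None:
        grid = default_grid(len(tags))
    ratios: list[RatioSpec] = []
    for entry in grid:
        if isinstance(entry, RatioSpec):
            ratios.append(entry)
        elif isinstance(entry, Mapping):
            ratios.append(RatioSpec.of(entry))
        else:
            ratios.append(RatioSpec.of(dict(zip(tags, entry))))

    records, statuses, values = [], [], []
    for ratio in ratios:
        point = set_ratio(community, ratio)
        problem = build_lp(point, objective=objective,
                           enzyme_constraints=enzyme_constraints)
        result = solve(problem)
        if result.optimal:
            value = result.objective_value
            result = pfba_resolve(problem, result)
        else:
            value = 0.0
        statuses.append(result.status)
        values.append(value)
        records.append(YieldRecord(
            product_id=objective,
            substrate_id=substrate,
            v_product=value,
            v_substrate=_uptake_flux(result, substrate) if result.optimal else 0.0,
            mw_product=mw_product,
            mw_substrate=mw_substrate,
        ))
    return SweepResult(ratios=ratios, records=records, statuses=statuses,
                       values=values)


@dataclass
class ComparisonReport:
    labels: list[str]
    sweeps: dict[str, SweepResult] = field(default_factory=dict)
    basic_sweeps: dict[str, SweepResult] = field(default_factory=dict)

    @property
    def winner(self) -> str:
        return max(self.labels, key=lambda l: self.sweeps[l].best_value)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in self.labels:
            ec, basic = self.sweeps[label], self.basic_sweeps[label]
            rows.append({
                "strategy": label,
                "best_value": ec.best_value,
                "best_ratio": ec.best_ratio.label(),
                "best_value_basic_gem": basic.best_value,
                "best_ratio_basic_gem": basic.best_ratio.label(),
                "winner": label == self.winner,
            })
        return pd.DataFrame(rows)


def compare_strategies(
    strategies: Sequence[tuple[str, CommunityModel]],
    grid: Optional[Union[Sequence, Mapping[str, Sequence]]] = None,
    product: Optional[str] = None,
    substrate: Optional[str] = None,
) -> ComparisonReport:
    """Sweep each pathway-allocation strategy and rank by best product flux.

    Every strategy is also run with all enzyme pool rows removed ("basic
    GEM" mode) — the stoichiometry-only contrast that cannot distinguish
    allocation strategies the enzyme-constrained model separates.  All
    strategies must expose the same product (objective) reaction.
    """
    if not strategies:
        raise ValueError("no strategies given")
    report = ComparisonReport(labels=[label for label, _ in strategies])
    for label, community in strategies:
        objective = product or community.objective
        try:
            community.get_reaction(objective)
        except KeyError:
            raise ValueError(
                f"strategy {label!r} lacks the product reaction {objective!r}"
            ) from None
        this_grid = grid.get(label) if isinstance(grid, Mapping) else grid
        report.sweeps[label] = ratio_sweep(
            community, this_grid, objective=objective, substrate=substrate)
        report.basic_sweeps[label] = ratio_sweep(
            community, this_grid, objective=objective, substrate=substrate,
            enzyme_constraints=False)
    return report
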