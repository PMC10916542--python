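"""Assemble and solve the global flux-balance linear program.

The LP over the merged community network is

    maximize    c' v
    subject to  S v = 0                  (steady-state mass balance)
                sum_i (MW_i/kcat_i) v_i <= ENZ_x   (one row per strain)
                0 <= v <= v_u            (irreversible bounds)

with the inoculation-ratio link coefficients already inside S.  The
formulation contains no integer variables; it is a pure LP, solved with
scipy's HiGHS backend.  Variable ordering is the sorted reaction id list,
so repeated builds of the same model are bit-identical, and every optimal
solution is re-checked with independent numpy arithmetic before being
returned.

Flux distributions intended for reporting should come from
:func:`pfba_resolve`, which breaks alternate-optimum degeneracy by
minimizing total flux at (effectively) the same objective value.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .community_assembly import CommunityModel
from .enzyme_constraints import ConstraintRow, constraint_row
from .errors import SolverError
from .gem_io import StrainModel

__all__ = ["LPProblem", "FBAResult", "build_lp", "solve", "pfba_resolve",
           "validate", "export_mps"]

FEASIBILITY_TOL = 1e-9


@dataclass
class LPProblem:
    variables: list[str]
    c: np.ndarray                      # objective coefficients (maximize)
    A_eq: sp.csr_matrix
    b_eq: np.ndarray
    A_ub: sp.csr_matrix
    b_ub: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    eq_row_ids: list[str]              # metabolite ids
    ub_row_ids: list[str]              # strain tags of enzyme rows
    objective_id: str = ""

    @property
    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variables)}

    def matrix_hash(self) -> str:
        h = hashlib.sha256()
        h.update("\n".join(self.variables).encode())
        h.update(self.c.tobytes())
        h.update(self.A_eq.toarray().tobytes())
        h.update(self.A_ub.toarray().tobytes())
        h.update(self.b_ub.tobytes())
        h.update(self.lb.tobytes())
        h.update(self.ub.tobytes())
        return h.hexdigest()


@dataclass
class FBAResult:
    status: str                        # optimal | infeasible | unbounded | error
    objective_value: Optional[float]
    fluxes: dict[str, float] = field(default_factory=dict)
    enzyme_usage: dict[str, dict] = field(default_factory=dict)
    binding_constraints: list[str] = field(default_factory=list)
    checks: dict = field(default_factory=dict)
    total_flux: Optional[float] = None
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _iter_reactions(model: Union[CommunityModel, StrainModel]):
    if isinstance(model, CommunityModel):
        return list(model.all_reactions())
    return list(model.reactions.values())


def _enzyme_rows(model: Union[CommunityModel, StrainModel]) -> list[ConstraintRow]:
    strains = model.submodels if isinstance(model, CommunityModel) else [model]
    rows = []
    for sub in strains:
        if sub.pool is None:
            continue
        row = constraint_row(sub)
        if row is not None:
            rows.append(row)
    return rows


def build_lp(
    model: Union[CommunityModel, StrainModel],
    objective: Optional[str] = None,
    enzyme_constraints: bool = True,
) -> LPProblem:
    """Build the LP for a community or single strain.

    ``objective`` is a reaction id; for a CommunityModel it defaults to
    ``model.objective``.  ``enzyme_constraints=False`` drops all pool rows
    ("basic GEM" contrast mode).
    """
    if objective is None and isinstance(model, CommunityModel):
        objective = model.objective
    if objective is None:
        raise ValueError("no objective reaction given")

    reactions = {r.id: r for r in _iter_reactions(model)}
    if objective not in reactions:
        raise ValueError(f"objective reaction {objective!r} not in model")
    variables = sorted(reactions)
    vidx = {v: i for i, v in enumerate(variables)}
    n = len(variables)

    met_ids = sorted(
        {mid for r in reactions.values() for mid in r.stoichiometry}
    )
    midx = {m: i for i, m in enumerate(met_ids)}
    S = sp.lil_matrix((len(met_ids), n))
    lb = np.zeros(n)
    ub = np.zeros(n)
    for rid, rxn in reactions.items():
        j = vidx[rid]
        lb[j] = rxn.lower_bound
        ub[j] = rxn.upper_bound
        for mid, coef in rxn.stoichiometry.items():
            S[midx[mid], j] = coef

    rows = _enzyme_rows(model) if enzyme_constraints else []
    A_ub = sp.lil_matrix((len(rows), n))
    b_ub = np.zeros(len(rows))
    ub_row_ids = []
    for i, row in enumerate(rows):
        for rid, coef in row.coefficients.items():
            A_ub[i, vidx[rid]] = coef
        b_ub[i] = row.bound
        ub_row_ids.append(row.tag)

    c = np.zeros(n)
    c[vidx[objective]] = 1.0
    return LPProblem(
        variables=variables,
        c=c,
        A_eq=S.tocsr(),
        b_eq=np.zeros(len(met_ids)),
        A_ub=A_ub.tocsr(),
        b_ub=b_ub,
        lb=lb,
        ub=ub,
        eq_row_ids=met_ids,
        ub_row_ids=ub_row_ids,
        objective_id=objective,
    )


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded",
           4: "error"}


def _linprog(c, problem: LPProblem, extra_A=None, extra_b=None):
    A_ub, b_ub = problem.A_ub, problem.b_ub
    if extra_A is not None:
        A_ub = sp.vstack([A_ub, sp.csr_matrix(extra_A)]) if A_ub.shape[0] else sp.csr_matrix(extra_A)
        b_ub = np.concatenate([b_ub, np.atleast_1d(extra_b)]) if problem.b_ub.size else np.atleast_1d(extra_b)
    kwargs = {}
    if A_ub.shape[0]:
        kwargs = {"A_ub": A_ub, "b_ub": b_ub}
    return scipy.optimize.linprog(
        c,
        A_eq=problem.A_eq,
        b_eq=problem.b_eq,
        bounds=list(zip(problem.lb, problem.ub)),
        method="highs",
        **kwargs,
    )


def _result_from_vector(problem: LPProblem, v: np.ndarray, tol: float) -> FBAResult:
    fluxes = dict(zip(problem.variables, v.tolist()))
    obj = float(problem.c @ v)
    usage = {}
    binding = []
    if problem.A_ub.shape[0]:
        used = problem.A_ub @ v
        for tag, u, b in zip(problem.ub_row_ids, used, problem.b_ub):
            usage[tag] = {"usage": float(u), "bound": float(b),
                          "slack": float(b - u)}
            if b - u <= tol * max(1.0, abs(b)):
                binding.append(f"enzyme_pool[{tag}]")
    at_ub = np.isfinite(problem.ub) & (problem.ub - v <= tol * np.maximum(1.0, np.abs(problem.ub)))
    binding.extend(f"upper_bound[{problem.variables[j]}]" for j in np.nonzero(at_ub)[0])
    result = FBAResult(
        status="optimal",
        objective_value=obj,
        fluxes=fluxes,
        enzyme_usage=usage,
        binding_constraints=binding,
        total_flux=float(np.sum(v)),
    )
    result.checks = validate(result, problem)
    return result


def solve(problem: LPProblem, options: Optional[dict] = None) -> FBAResult:
    """Maximize the objective; report status faithfully, never a silent zero."""
    res = _linprog(-problem.c, problem)
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FBAResult(status=status, objective_value=None, message=res.message)
    tol = (options or {}).get("feasibility_tol", FEASIBILITY_TOL)
    return _result_from_vector(problem, res.x, tol)


def pfba_resolve(
    problem: LPProblem,
    result: Optional[FBAResult] = None,
    optimality_tol: float = 1e-9,
) -> FBAResult:
    """Among near-optimal solutions, return the one minimizing total flux.

    Requires a prior optimal solve (done internally if ``result`` is None).
    The objective is pinned to >= (1 - optimality_tol) * optimum and sum(v)
    is minimized, making reported flux distributions reproducible even when
    the optimum face is degenerate.
    """
    if result is None:
        result = solve(problem)
    if not result.optimal:
        return result
    opt = result.objective_value
    floor = (1.0 - optimality_tol) * opt if opt >= 0 else (1.0 + optimality_tol) * opt
    res = _linprog(
        np.ones(len(problem.variables)),
        problem,
        extra_A=-problem.c.reshape(1, -1),
        extra_b=np.array([-floor]),
    )
    if res.status != 0:
        raise SolverError(f"pFBA refinement failed: {res.message}")
    refined = _result_from_vector(problem, res.x, FEASIBILITY_TOL)
    refined.objective_value = float(problem.c @ res.x)
    return refined


def validate(result: FBAResult, problem: LPProblem, tol: float = FEASIBILITY_TOL) -> dict:
    """Re-check mass balance, bounds and enzyme rows with independent arithmetic.

    Returns {"passed": bool, "max_equality_residual": float,
    "violations": [row/bound names]}.
    """
    v = np.array([result.fluxes[r] for r in problem.variables])
    violations: list[str] = []
    residual = problem.A_eq @ v - problem.b_eq
    max_resid = float(np.max(np.abs(residual))) if residual.size else 0.0
    for i in np.nonzero(np.abs(residual) > tol)[0]:
        violations.append(f"mass_balance[{problem.eq_row_ids[i]}]")
    below = v < problem.lb - tol
    above = v > problem.ub + tol
    for j in np.nonzero(below | above)[0]:
        violations.append(f"bounds[{problem.variables[j]}]")
    if problem.A_ub.shape[0]:
        excess = problem.A_ub @ v - problem.b_ub
        for i in np.nonzero(excess > tol)[0]:
            violations.append(f"enzyme_pool[{problem.ub_row_ids[i]}]")
    return {
        "passed": not violations,
        "max_equality_residual": max_resid,
        "violations": violations,
    }


def export_mps(problem: LPProblem, path) -> None:
    """Write the LP in fixed MPS format for external inspection."""
    lines = ["NAME          CONSORTIA_LP", "ROWS", " N  OBJ"]
    for i, mid in enumerate(problem.eq_row_ids):
        lines.append(f" E  EQ{i}")
    for i in range(len(problem.ub_row_ids)):
        lines.append(f" L  ENZ{i}")
    lines.append("COLUMNS")
    A_eq = problem.A_eq.tocsc()
    A_ub = problem.A_ub.tocsc()
    for j, var in enumerate(problem.variables):
        col = f"V{j}"
        if problem.c[j]:
            lines.append(f"    {col}  OBJ  {-problem.c[j]:.17g}")  # MPS minimizes
        for k in range(A_eq.indptr[j], A_eq.indptr[j + 1]):
            lines.append(f"    {col}  EQ{A_eq.indices[k]}  {A_eq.data[k]:.17g}")
        for k in range(A_ub.indptr[j], A_ub.indptr[j + 1]):
            lines.append(f"    {col}  ENZ{A_ub.indices[k]}  {A_ub.data[k]:.17g}")
    lines.append("RHS")
    for i, b in enumerate(problem.b_ub):
        lines.append(f"    RHS  ENZ{i}  {b:.17g}")
    lines.append("BOUNDS")
    for j in range(len(problem.variables)):
        if problem.lb[j] != 0.0:
            lines.append(f" LO BND  V{j}  {problem.lb[j]:.17g}")
        if np.isfinite(problem.ub[j]):
            lines.append(f" UP BND  V{j}  {problem.ub[j]:.17g}")
        else:
            lines.append(f" PL BND  V{j}")
    lines.append("ENDATA")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
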