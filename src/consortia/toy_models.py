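"""Small fully-specified consortium models with known exact optima.

These toys make every other module testable without downloading published
GEMs.  All kinetic constants are round numbers so the optima are exact
rationals, derived in closed form and cross-checked by the exact-arithmetic
oracle in :mod:`consortia._exactlp`.

TOY2 — two-strain linear pathway (upstream/downstream module split):
  strain A converts glucose to itaconate-like intermediate "ita" at enzyme
  cost 0.5 g·h·gDW^-1·mmol^-1 per unit flux with pool 1; strain B converts
  ita to the product at cost 1.0 with pool 1; shared glucose uptake cap 10.
  With normalized inoculation fractions (m, n), the shared product flux is
  min(2/m, 1/n, 10): each module's community-side throughput is its enzyme
  capacity divided by its inoculation fraction, because the link coefficient
  1/m sits between the sub-model flux and the shared pool.  The grid optimum
  is 3.0 at ratio 2:1; 1:1 gives 2.0.

TOY3 — three-module nonlinear design: modules A and B feed module C, which
  condenses both intermediates 1:1.  Costs (0.5, 1/3, 1.0) give module
  capacities (2, 3, 1), optimum 6.0 at ratio 2:3:1, and any two-module merge
  (both capacities under one pool) is strictly worse.

Overflow toy — one strain with a high-yield, enzyme-expensive respiration
  route (26 ATP/glc, cost 0.1) and a low-yield, cheap fermentation route
  (12 ATP/glc + 2 acetate, cost 0.02), pool 1: acetate secretion switches on
  exactly when uptake exceeds pool/respiration-cost = 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Union

from ._exactlp import Unbounded, simplex_max, to_fraction
from .community_assembly import (
    CommunityModel,
    RatioSpec,
    add_shared_exchange,
    assemble,
    namespace,
)
from .gem_io import (
    KIND_EXCHANGE,
    Enzyme,
    Metabolite,
    ReactionIR,
    StrainModel,
)
from .enzyme_constraints import EnzymePool
from .lp_engine import LPProblem, build_lp

__all__ = ["make_toy2", "make_overflow_toy", "make_toy3", "vertex_oracle",
           "OracleResult"]


def _ext(mid: str) -> Metabolite:
    return Metabolite(id=mid, compartment="e")


def _strain(tag_hint: str, mets: Sequence[str], reactions: Sequence[ReactionIR],
            pool: float) -> StrainModel:
    model = StrainModel()
    for mid in mets:
        model.add_metabolite(_ext(mid))
    for rxn in reactions:
        model.add_reaction(rxn)
    model.pool = EnzymePool(tag=tag_hint, ptot=pool, f=1.0, sigma=1.0)
    return model


def _conv(rid: str, stoich: dict[str, float], cost: float) -> ReactionIR:
    # kcat 1 h^-1, mw = cost, so mw/kcat is exactly the requested cost
    return ReactionIR(id=rid, stoichiometry=stoich,
                      enzyme=Enzyme(kcat=1.0, mw=cost))


def make_toy2(
    ratio: Union[RatioSpec, dict, tuple] = (2, 1),
    cost_up: float = 0.5,
    cost_down: float = 1.0,
    pool_up: float = 1.0,
    pool_down: float = 1.0,
    glc_cap: float = 10.0,
) -> CommunityModel:
    """Deterministic two-strain community "TOY2"; objective EX_prod_shared.

    Both strains carry all three extracellular metabolites, so assembly
    creates six link pairs over {glc_e, ita_e, prod_e}.
    """
    mets = ["glc_e", "ita_e", "prod_e"]
    up = _strain("A", mets, [_conv("CONV_up", {"glc_e": -1.0, "ita_e": 1.0},
                                   cost_up)], pool_up)
    down = _strain("B", mets, [_conv("CONV_down", {"ita_e": -1.0, "prod_e": 1.0},
                                     cost_down)], pool_down)
    if isinstance(ratio, tuple):
        ratio = RatioSpec.of({"A": ratio[0], "B": ratio[1]})
    community = assemble(
        [namespace(up, "A"), namespace(down, "B")], mets, ratio
    )
    community = add_shared_exchange(community, "glc_e", uptake_ub=glc_cap,
                                    secretion_ub=0.0)
    community = add_shared_exchange(community, "prod_e", uptake_ub=0.0,
                                    secretion_ub=math.inf)
    community.objective = "EX_prod_shared"
    return community


def make_overflow_toy(uptake_cap: float = 10.0) -> StrainModel:
    """Single strain exercising overflow metabolism; objective EX_atp.

    Respiration: glc -> 26 atp, cost 0.1.  Fermentation: glc -> 12 atp +
    2 ac, cost 0.02.  Pool 1.  Glucose uptake bound is the scan variable
    (reaction EX_glc_reverse).
    """
    model = StrainModel()
    for mid in ("glc_e", "atp_c", "ac_e"):
        model.add_metabolite(Metabolite(id=mid,
                                        compartment=mid.rsplit("_", 1)[-1]))
    model.add_reaction(_conv("RESP", {"glc_e": -1.0, "atp_c": 26.0}, 0.1))
    model.add_reaction(_conv("FERM", {"glc_e": -1.0, "atp_c": 12.0, "ac_e": 2.0},
                             0.02))
    model.add_reaction(ReactionIR(id="EX_glc", stoichiometry={"glc_e": -1.0},
                                  upper_bound=0.0, kind=KIND_EXCHANGE))
    model.add_reaction(ReactionIR(id="EX_glc_reverse",
                                  stoichiometry={"glc_e": 1.0},
                                  upper_bound=uptake_cap, kind=KIND_EXCHANGE,
                                  base_id="EX_glc_reverse"))
    model.add_reaction(ReactionIR(id="EX_atp", stoichiometry={"atp_c": -1.0},
                                  kind=KIND_EXCHANGE))
    model.add_reaction(ReactionIR(id="EX_ac", stoichiometry={"ac_e": -1.0},
                                  kind=KIND_EXCHANGE))
    model.pool = EnzymePool(tag="overflow", ptot=1.0, f=1.0, sigma=1.0)
    return model


_TOY3_MERGES = {None, "AB", "BC", "AC"}


def make_toy3(
    ratio: Union[RatioSpec, dict, tuple] = (2, 3, 1),
    costs: tuple[float, float, float] = (0.5, 1.0 / 3.0, 1.0),
    pools: tuple[float, ...] = (1.0, 1.0, 1.0),
    glc_cap: float = 20.0,
    merge: Optional[str] = None,
) -> CommunityModel:
    """Three-module nonlinear community "TOY3"; objective EX_prod_shared.

    Modules A (glc -> intA) and B (glc -> intB) feed module C
    (intA + intB -> prod, 1:1).  ``merge`` collapses two modules into one
    strain sharing a single pool ("AB", "BC" or "AC"), the contrast used to
    show that splitting critical reactions across strains wins.  The
    substrate cap (20) is set so that the enzyme pools, not glucose supply,
    bind at the three-strain optimum.
    """
    if merge not in _TOY3_MERGES:
        raise ValueError(f"merge must be one of {_TOY3_MERGES}, got {merge!r}")
    ca, cb, cc = costs
    rxn_a = _conv("CONV_A", {"glc_e": -1.0, "intA_e": 1.0}, ca)
    rxn_b = _conv("CONV_B", {"glc_e": -1.0, "intB_e": 1.0}, cb)
    rxn_c = _conv("CONV_C", {"intA_e": -1.0, "intB_e": -1.0, "prod_e": 1.0}, cc)

    if merge is None:
        strains = [
            ("A", ["glc_e", "intA_e"], [rxn_a], pools[0]),
            ("B", ["glc_e", "intB_e"], [rxn_b], pools[1]),
            ("C", ["intA_e", "intB_e", "prod_e"], [rxn_c], pools[2]),
        ]
    elif merge == "AB":
        strains = [
            ("AB", ["glc_e", "intA_e", "intB_e"], [rxn_a, rxn_b], pools[0]),
            ("C", ["intA_e", "intB_e", "prod_e"], [rxn_c], pools[1]),
        ]
    elif merge == "BC":
        strains = [
            ("A", ["glc_e", "intA_e"], [rxn_a], pools[0]),
            ("BC", ["glc_e", "intA_e", "intB_e", "prod_e"], [rxn_b, rxn_c],
             pools[1]),
        ]
    else:  # AC
        strains = [
            ("AC", ["glc_e", "intA_e", "intB_e", "prod_e"], [rxn_a, rxn_c],
             pools[0]),
            ("B", ["glc_e", "intB_e"], [rxn_b], pools[1]),
        ]
    tags = [t for t, *_ in strains]
    if isinstance(ratio, tuple):
        if len(ratio) != len(tags):
            raise ValueError(f"ratio {ratio} does not match strains {tags}")
        ratio = RatioSpec.of(dict(zip(tags, ratio)))
    submodels = [
        namespace(_strain(tag, mets, [r.copy() for r in rxns], pool), tag)
        for tag, mets, rxns, pool in strains
    ]
    shared = ["glc_e", "intA_e", "intB_e", "prod_e"]
    community = assemble(submodels, shared, ratio)
    community = add_shared_exchange(community, "glc_e", uptake_ub=glc_cap,
                                    secretion_ub=0.0)
    community = add_shared_exchange(community, "prod_e", uptake_ub=0.0,
                                    secretion_ub=math.inf)
    community.objective = "EX_prod_shared"
    return community


# ---------------------------------------------------------------------------
# oracle


@dataclass
class OracleResult:
    optimum: Fraction
    vertex: dict[str, Fraction]

    @property
    def value(self) -> float:
        return float(self.optimum)


_ORACLE_MAX_VARIABLES = 64


def vertex_oracle(
    model,
    objective: Optional[str] = None,
    enzyme_constraints: bool = True,
) -> OracleResult:
    """Exact-arithmetic optimum of a toy model, independent of the LP engine.

    The constraint system is rebuilt from the model and solved with a
    Bland-rule simplex over ``fractions.Fraction`` — no floating-point
    tolerance anywhere.  Refuses systems that are not toy-sized: this is a
    verification oracle, not a production solver.
    """
    problem: LPProblem = build_lp(model, objective=objective,
                                  enzyme_constraints=enzyme_constraints)
    n = len(problem.variables)
    if n > _ORACLE_MAX_VARIABLES:
        raise ValueError(
            f"oracle refuses {n}-variable systems (limit {_ORACLE_MAX_VARIABLES})"
        )
    # all-inequality exact form: Sv <= 0, -Sv <= 0, enzyme rows, finite ubs
    A: list[list[Fraction]] = []
    b: list[Fraction] = []
    S = problem.A_eq.toarray()
    for row in S:
        A.append([to_fraction(x) for x in row])
        b.append(Fraction(0))
        A.append([-to_fraction(x) for x in row])
        b.append(Fraction(0))
    for row, bound in zip(problem.A_ub.toarray(), problem.b_ub):
        A.append([to_fraction(x) for x in row])
        b.append(to_fraction(bound))
    for j, u in enumerate(problem.ub):
        if math.isfinite(u):
            A.append([Fraction(1) if k == j else Fraction(0) for k in range(n)])
            b.append(to_fraction(u))
    c = [to_fraction(x) for x in problem.c]
    try:
        opt, x = simplex_max(c, A, b)
    except Unbounded:
        raise
    return OracleResult(
        optimum=opt,
        vertex=dict(zip(problem.variables, x)),
    )
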