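import math

import pytest

from consortia.enzyme_constraints import EnzymePool
from consortia.gem_io import (
    Enzyme,
    KIND_EXCHANGE,
    Metabolite,
    ReactionIR,
    StrainModel,
)
from consortia.toy_models import make_overflow_toy, make_toy2, make_toy3


@pytest.fixture
def toy2():
    return make_toy2()


@pytest.fixture
def toy3():
    return make_toy3()


@pytest.fixture
def overflow():
    return make_overflow_toy()


def build_mini_strain() -> StrainModel:
    """Hand-built 4-reaction strain with a reversible reaction and gene rules."""
    m = StrainModel()
    for mid, comp in [("glc__D_e", "e"), ("pyr_c", "c"), ("lac__D_e", "e")]:
        m.add_metabolite(Metabolite(id=mid, compartment=comp))
    m.add_reaction(ReactionIR(
        id="GLYC", stoichiometry={"glc__D_e": -1.0, "pyr_c": 2.0},
        upper_bound=8.0, gene_rule="g1 and g2",
        enzyme=Enzyme(kcat=100.0, mw=50.0)))
    m.add_reaction(ReactionIR(
        id="LDH", stoichiometry={"pyr_c": -1.0, "lac__D_e": 1.0},
        lower_bound=-5.0, upper_bound=10.0, gene_rule="g3 or g4"))
    m.add_reaction(ReactionIR(
        id="EX_glc__D_e", stoichiometry={"glc__D_e": -1.0},
        lower_bound=-10.0, upper_bound=1000.0, kind=KIND_EXCHANGE))
    m.add_reaction(ReactionIR(
        id="EX_lac__D_e", stoichiometry={"lac__D_e": -1.0},
        upper_bound=1000.0, kind=KIND_EXCHANGE))
    m.pool = EnzymePool(tag="", ptot=1.0, f=1.0, sigma=1.0)
    return m


@pytest.fixture
def mini_strain():
    return build_mini_strain()


def growth_strain(substrate_cap: float = math.inf) -> StrainModel:
    """One-strain model whose biomass pathway costs 0.5 g*h/gDW/mmol, pool 1."""
    m = StrainModel()
    m.add_metabolite(Metabolite(id="x_e", compartment="e"))
    m.add_reaction(ReactionIR(
        id="EX_x_reverse", stoichiometry={"x_e": 1.0},
        upper_bound=substrate_cap, kind=KIND_EXCHANGE))
    m.add_reaction(ReactionIR(
        id="GROWTH", stoichiometry={"x_e": -1.0},
        enzyme=Enzyme(kcat=1.0, mw=0.5)))
    m.biomass_id = "GROWTH"
    m.pool = EnzymePool(tag="", ptot=1.0, f=1.0, sigma=1.0)
    return m
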