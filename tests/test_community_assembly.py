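import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from consortia.community_assembly import (
    RatioSpec,
    add_shared_exchange,
    assemble,
    namespace,
    set_ratio,
    set_substrate_ratio,
    shared_metabolite_id,
)
from consortia.errors import AssemblyError
from consortia.gem_io import Metabolite, ReactionIR, StrainModel, split_reversible
from consortia.lp_engine import build_lp, pfba_resolve, solve
from consortia.toy_models import make_toy2, make_toy3

from conftest import build_mini_strain


class TestNamespace:
    def test_id_scheme_and_base_id(self, mini_strain):
        out = namespace(mini_strain, "A")
        assert "glc__D_e@A" in out.metabolites
        assert out.metabolites["glc__D_e@A"].base_id == "glc__D_e"
        assert out.metabolites["glc__D_e@A"].origin == "A"
        assert "GLYC@A" in out.reactions
        assert out.reactions["GLYC@A"].stoichiometry == {
            "glc__D_e@A": -1.0, "pyr_c@A": 2.0}

    def test_double_namespacing_refused(self, mini_strain):
        out = namespace(mini_strain, "A")
        with pytest.raises(AssemblyError, match="already namespaced"):
            namespace(out, "A")

    def test_empty_tag_refused(self, mini_strain):
        with pytest.raises(AssemblyError, match="nonempty"):
            namespace(mini_strain, "")

    def test_two_copies_merge_without_collisions(self):
        a = namespace(split_reversible(build_mini_strain()), "A")
        b = namespace(split_reversible(build_mini_strain()), "B")
        community = assemble([a, b], ["glc__D_e"], {"A": 1, "B": 1})
        internal = [r for sub in community.submodels
                    for r in sub.reactions.values()]
        assert len(internal) == 2 * len(split_reversible(build_mini_strain()).reactions)
        assert len({r.id for r in community.all_reactions()}) == len(internal) + 4

    def test_reactions_never_connect_two_namespaces(self, toy2):
        toy2.validate()  # would raise on any cross-namespace reaction


class TestAssemble:
    def test_toy2_link_counts_and_coefficients(self):
        community = make_toy2(ratio=(2, 1))
        assert len(community.links) == 6  # 3 shared metabolites x 2 strains
        assert len(community.link_reactions) == 12
        link = community.link_reactions["LINK_ita_e@A"]
        # normalized m = 2/3, shared-side coefficient 1/m = 1.5
        assert link.stoichiometry == {"ita_e@A": -1.0, "ita_shared": 1.5}
        rev = community.link_reactions["LINK_ita_e@A_reverse"]
        assert rev.stoichiometry == {"ita_e@A": 1.0, "ita_shared": -1.5}
        assert community.link_reactions["LINK_ita_e@B"].stoichiometry[
            "ita_shared"] == pytest.approx(3.0)

    def test_equal_ratio_gives_symmetric_coefficient_2(self):
        community = make_toy2(ratio=(1, 1))
        for link in community.links:
            assert link.scale_coefficient == pytest.approx(2.0)

    def test_raw_ratios_are_normalized(self):
        spec = RatioSpec.of({"A": 2, "B": 1})
        assert not spec.normalized
        norm = spec.normalize()
        assert sum(norm.as_dict().values()) == pytest.approx(1.0, abs=1e-12)

    def test_scaling_invariance(self):
        a = make_toy2(ratio=(2, 1))
        b = make_toy2(ratio=(4, 2))
        coeffs_a = {l.forward_id: l.scale_coefficient for l in a.links}
        coeffs_b = {l.forward_id: l.scale_coefficient for l in b.links}
        assert coeffs_a == coeffs_b

    def test_absent_shared_id_is_error(self, mini_strain):
        a = namespace(split_reversible(mini_strain), "A")
        with pytest.raises(AssemblyError, match="unobtanium_e"):
            assemble([a], ["unobtanium_e"], {"A": 1})

    def test_unsplit_submodel_refused(self, mini_strain):
        a = namespace(mini_strain, "A")  # LDH still has lb = -5
        with pytest.raises(AssemblyError, match="not irreversibility-split"):
            assemble([a], ["glc__D_e"], {"A": 1})

    def test_duplicate_tags_refused(self, mini_strain):
        a = namespace(build_mini_strain(), "A")
        b = namespace(build_mini_strain(), "A")
        with pytest.raises(AssemblyError, match="duplicate"):
            assemble([a, b], ["glc__D_e"], {"A": 1})

    def test_zero_fraction_rejected_with_guidance(self):
        with pytest.raises(AssemblyError, match="omitting"):
            RatioSpec.of({"A": 1, "B": 0})


class TestSetRatio:
    def test_three_strain_2_3_1_coefficients(self):
        community = set_ratio(make_toy3(ratio=(1, 1, 1)), {"A": 2, "B": 3, "C": 1})
        by_strain = {l.strain: l.scale_coefficient for l in community.links}
        assert by_strain["A"] == pytest.approx(3.0)
        assert by_strain["B"] == pytest.approx(2.0)
        assert by_strain["C"] == pytest.approx(6.0)

    def test_idempotent(self, toy2):
        once = set_ratio(toy2, {"A": 2, "B": 1})
        twice = set_ratio(once, {"A": 2, "B": 1})
        assert [l.scale_coefficient for l in once.links] == \
            [l.scale_coefficient for l in twice.links]

    def test_missing_strain_is_error(self, toy2):
        with pytest.raises(AssemblyError, match="missing strain"):
            set_ratio(toy2, {"A": 1})

    def test_sweep_without_reassembly_changes_only_links(self, toy2):
        moved = set_ratio(toy2, {"A": 1, "B": 9})
        assert {r.id for r in moved.all_reactions()} == \
            {r.id for r in toy2.all_reactions()}
        assert moved.shared_exchanges["EX_glc_shared_reverse"].upper_bound == \
            toy2.shared_exchanges["EX_glc_shared_reverse"].upper_bound


class TestSharedExchange:
    def test_uptake_and_secretion_bounds(self, toy2):
        ex = toy2.shared_exchanges
        assert ex["EX_glc_shared_reverse"].upper_bound == 10.0
        assert ex["EX_glc_shared"].upper_bound == 0.0
        assert ex["EX_prod_shared_reverse"].upper_bound == 0.0

    def test_duplicate_exchange_is_error(self, toy2):
        with pytest.raises(AssemblyError, match="already present"):
            add_shared_exchange(toy2, "glc_e", 10.0, 0.0)

    def test_unknown_metabolite_named(self, toy2):
        with pytest.raises(AssemblyError, match="xyl_e"):
            add_shared_exchange(toy2, "xyl_e", 10.0, 0.0)

    def test_shared_id_scheme(self):
        assert shared_metabolite_id("glc__D_e") == "glc__D_shared"
        assert shared_metabolite_id("ita_e") == "ita_shared"


class TestSubstrateRatio:
    def _two_substrate_community(self):
        m = StrainModel()
        for mid in ("glc_e", "xyl_e", "prod_e"):
            m.add_metabolite(Metabolite(id=mid, compartment="e"))
        m.add_reaction(ReactionIR(id="CONV_G",
                                  stoichiometry={"glc_e": -1.0, "prod_e": 1.0}))
        m.add_reaction(ReactionIR(id="CONV_X",
                                  stoichiometry={"xyl_e": -1.0, "prod_e": 1.0}))
        community = assemble([namespace(m, "A")],
                             ["glc_e", "xyl_e", "prod_e"], {"A": 1})
        community = add_shared_exchange(community, "glc_e", 1000.0, 0.0)
        community = add_shared_exchange(community, "xyl_e", 1000.0, 0.0)
        community = add_shared_exchange(community, "prod_e", 0.0, 1000.0)
        return community

    def test_4_to_1_with_cap_10(self):
        community = set_substrate_ratio(
            self._two_substrate_community(),
            {"EX_glc_shared_reverse": 4, "EX_xyl_shared_reverse": 1}, total=10)
        assert community.get_reaction("EX_glc_shared_reverse").upper_bound == 8.0
        assert community.get_reaction("EX_xyl_shared_reverse").upper_bound == 2.0

    def test_symmetric_split(self):
        community = set_substrate_ratio(
            self._two_substrate_community(),
            {"EX_glc_shared_reverse": 1, "EX_xyl_shared_reverse": 1}, total=10)
        assert community.get_reaction("EX_glc_shared_reverse").upper_bound == 5.0

    def test_single_substrate_gets_full_cap(self):
        community = set_substrate_ratio(
            self._two_substrate_community(),
            {"EX_glc_shared_reverse": 3}, total=10)
        assert community.get_reaction("EX_glc_shared_reverse").upper_bound == 10.0
        assert community.get_reaction("EX_xyl_shared_reverse").upper_bound == 1000.0

    def test_zero_weight_is_error(self):
        with pytest.raises(AssemblyError, match="must be > 0"):
            set_substrate_ratio(self._two_substrate_community(),
                                {"EX_glc_shared_reverse": 0}, total=10)


def _net_link_flux(fluxes, base, tag):
    return fluxes[f"LINK_{base}@{tag}"] - fluxes[f"LINK_{base}@{tag}_reverse"]


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.floats(0.1, 9.0), st.floats(0.1, 9.0))
def test_link_ratio_law(m, n):
    """At any feasible optimum, paired link fluxes across one shared
    metabolite satisfy v_A / v_B = m / n."""
    community = make_toy2(ratio=RatioSpec.of({"A": m, "B": n}))
    problem = build_lp(community)
    result = pfba_resolve(problem)
    assert result.optimal
    v_a = _net_link_flux(result.fluxes, "ita_e", "A")
    v_b = -_net_link_flux(result.fluxes, "ita_e", "B")
    if abs(v_b) > 1e-9:
        assert v_a / v_b == pytest.approx(m / n, rel=1e-6)


def test_shared_metabolite_conservation(toy2):
    """Net production of every shared metabolite is zero at any solution."""
    problem = build_lp(toy2)
    result = pfba_resolve(problem)
    v = np.array([result.fluxes[r] for r in problem.variables])
    residual = problem.A_eq @ v
    shared_rows = [i for i, mid in enumerate(problem.eq_row_ids)
                   if mid.endswith("_shared")]
    assert np.max(np.abs(residual[shared_rows])) <= 1e-9


def test_isolation_zeroing_links_kills_product(toy2):
    community = toy2.copy()
    for link in community.links:
        if link.strain == "B":
            community.link_reactions[link.forward_id].upper_bound = 0.0
            community.link_reactions[link.reverse_id].upper_bound = 0.0
    result = solve(build_lp(community))
    assert result.optimal
    assert result.objective_value == pytest.approx(0.0, abs=1e-9)
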