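import json
import math

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings, strategies as st

from consortia.errors import EditError, GEMParseError, ModelValidationError
from consortia.gem_io import (
    Metabolite,
    ReactionIR,
    StrainModel,
    apply_edits,
    gene_rule_active,
    read_gem,
    split_reversible,
    write_model,
)

from conftest import build_mini_strain


def _signature(model):
    return {
        rid: (tuple(sorted(r.stoichiometry.items())), r.lower_bound,
              r.upper_bound, r.gene_rule)
        for rid, r in model.reactions.items()
    }


@pytest.mark.parametrize("fmt,suffix", [("json", ".json"), ("sbml", ".xml")])
def test_round_trip_preserves_structure(tmp_path, mini_strain, fmt, suffix):
    """read(write(m)) is the identity on ids, stoichiometry, bounds, gene rules."""
    path = tmp_path / f"mini{suffix}"
    write_model(mini_strain, path, format=fmt)
    back = read_gem(path, format=fmt)
    assert set(back.metabolites) == set(mini_strain.metabolites)
    assert _signature(back) == _signature(mini_strain)
    # enzyme annotations travel through notes
    assert back.reactions["GLYC"].enzyme == mini_strain.reactions["GLYC"].enzyme


def test_community_json_carries_kind_annotations(tmp_path, toy2):
    path = tmp_path / "toy2.json"
    write_model(toy2, path)
    raw = json.loads(path.read_text())
    kinds = {r["id"]: r.get("notes", {}).get("kind") for r in raw["reactions"]}
    assert kinds["LINK_ita_e@A"] == "link"
    assert kinds["EX_prod_shared"] == "exchange"
    assert kinds["CONV_up@A"] == "internal"
    back = read_gem(path)
    assert set(back.reactions) == {r.id for r in toy2.all_reactions()}


def test_write_refuses_invariant_violations(tmp_path, mini_strain):
    mini_strain.reactions["GLYC"].stoichiometry["ghost_met"] = 1.0
    with pytest.raises(ModelValidationError, match="ghost_met"):
        write_model(mini_strain, tmp_path / "bad.json")


def test_read_missing_file_and_undeclared_metabolite(tmp_path):
    with pytest.raises(GEMParseError, match="not found"):
        read_gem(tmp_path / "nope.json")
    doc = {
        "metabolites": [{"id": "a_c", "compartment": "c"}],
        "reactions": [{"id": "R1", "metabolites": {"phantom_c": -1.0},
                       "lower_bound": 0, "upper_bound": 10}],
        "genes": [],
        "id": "broken",
    }
    bad = tmp_path / "broken.json"
    bad.write_text(json.dumps(doc))
    with pytest.raises(GEMParseError, match="phantom_c"):
        read_gem(bad)


class TestSplitReversible:
    def test_reversible_reaction_yields_negated_sibling(self, mini_strain):
        out = split_reversible(mini_strain)
        fwd, rev = out.reactions["LDH"], out.reactions["LDH_reverse"]
        assert (fwd.lower_bound, fwd.upper_bound) == (0.0, 10.0)
        assert (rev.lower_bound, rev.upper_bound) == (0.0, 5.0)
        assert rev.stoichiometry == {"pyr_c": 1.0, "lac__D_e": -1.0}

    def test_exchange_split_uses_reverse_suffix(self, mini_strain):
        out = split_reversible(mini_strain)
        rev = out.reactions["EX_glc__D_e_reverse"]
        assert rev.upper_bound == 10.0
        assert rev.stoichiometry == {"glc__D_e": 1.0}

    def test_irreversible_reaction_untouched(self, mini_strain):
        out = split_reversible(mini_strain)
        assert "GLYC_reverse" not in out.reactions
        assert out.reactions["GLYC"].upper_bound == 8.0

    def test_idempotent(self, mini_strain):
        once = split_reversible(mini_strain)
        twice = split_reversible(once)
        assert _signature(once) == _signature(twice)

    def test_collision_with_existing_reverse_id_is_error(self, mini_strain):
        mini_strain.add_reaction(ReactionIR(id="LDH_reverse",
                                            stoichiometry={"pyr_c": -1.0}))
        with pytest.raises(ModelValidationError, match="LDH_reverse"):
            split_reversible(mini_strain)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.lists(st.tuples(
    st.floats(-8, 0), st.floats(0, 8)), min_size=2, max_size=4),
    st.integers(0, 2 ** 31 - 1))
def test_split_preserves_optimum_of_random_lps(bounds, seed):
    """Splitting reversible reactions leaves the optimal net flux unchanged.

    Oracle: the same LP solved directly with signed variables.
    """
    rng = np.random.default_rng(seed)
    n = len(bounds)
    model = StrainModel()
    model.add_metabolite(Metabolite(id="m_c", compartment="c"))
    # n reactions producing/consuming one metabolite plus a drain
    coefs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=n)
    for i, ((lb, ub), coef) in enumerate(zip(bounds, coefs)):
        model.add_reaction(ReactionIR(id=f"R{i}", stoichiometry={"m_c": coef},
                                      lower_bound=lb, upper_bound=max(ub, lb)))
    c = rng.normal(size=n)

    # signed-variable oracle
    A = coefs.reshape(1, -1)
    res = scipy.optimize.linprog(
        -c, A_eq=A, b_eq=[0.0],
        bounds=[(lb, max(ub, lb)) for lb, ub in bounds], method="highs")
    split = split_reversible(model)
    ids = sorted(split.reactions)
    c_split = {f"R{i}": ci for i, ci in enumerate(c)}
    c_split.update({f"R{i}_reverse": -ci for i, ci in enumerate(c)})
    A_split = np.array([[split.reactions[r].stoichiometry["m_c"] for r in ids]])
    res_split = scipy.optimize.linprog(
        [-c_split[r] for r in ids], A_eq=A_split, b_eq=[0.0],
        bounds=[(0, split.reactions[r].upper_bound) for r in ids],
        method="highs")
    assert res.status == res_split.status
    if res.status == 0:
        assert res.fun == pytest.approx(res_split.fun, abs=1e-9)


class TestApplyEdits:
    def test_knockout_zeroes_bounds_and_keeps_reaction(self, mini_strain):
        out = apply_edits(mini_strain, knockouts=["GLYC", "LDH"])
        assert len(out.reactions) == len(mini_strain.reactions)
        assert out.reactions["GLYC"].upper_bound == 0.0
        assert out.reactions["LDH"].upper_bound == 0.0
        # non-destructive on the input
        assert mini_strain.reactions["GLYC"].upper_bound == 8.0

    def test_delete_flag_removes_reactions(self, mini_strain):
        out = apply_edits(mini_strain, knockouts=["GLYC"], delete=True)
        assert "GLYC" not in out.reactions

    def test_unknown_id_error_lists_it(self, mini_strain):
        with pytest.raises(EditError, match="NOT_A_RXN"):
            apply_edits(mini_strain, knockouts=["NOT_A_RXN"])

    def test_gene_knockouts_respect_and_or_rules(self, mini_strain):
        # "g1 and g2": a complex — deleting one member closes the reaction
        out = apply_edits(mini_strain, knockouts=["g1"])
        assert out.reactions["GLYC"].upper_bound == 0.0
        # "g3 or g4": isozymes — one deletion leaves the reaction open
        out = apply_edits(mini_strain, knockouts=["g3"])
        assert out.reactions["LDH"].upper_bound == 10.0
        out = apply_edits(mini_strain, knockouts=["g3", "g4"])
        assert out.reactions["LDH"].upper_bound == 0.0

    @pytest.mark.parametrize("rule,kos,active", [
        ("g1 and g2", {"g1"}, False),
        ("g1 and g2", {"g9"}, True),
        ("g1 or g2", {"g1"}, True),
        ("g1 or g2", {"g1", "g2"}, False),
        ("(g1 and g2) or g3", {"g1"}, True),
        ("(g1 and g2) or g3", {"g1", "g3"}, False),
    ])
    def test_gene_rule_truth_table(self, rule, kos, active):
        assert gene_rule_active(rule, kos) is active

    def test_addition_collision_is_error(self, mini_strain):
        with pytest.raises(EditError, match="GLYC"):
            apply_edits(mini_strain, additions=[
                {"id": "GLYC", "stoichiometry": {"pyr_c": -1.0}}])

    def test_heterologous_chain_addition(self, mini_strain):
        """A 5-step heterologous chain (TAL->4CL->CHS->CHI->NOMT analogue)."""
        steps = ["tal", "4cl", "chs", "chi", "nomt"]
        additions = []
        prev = "pyr_c"  # tyrosine-analogue node
        for step in steps:
            nxt = f"{step}_c"
            additions.append({
                "id": f"HET_{step.upper()}",
                "stoichiometry": {prev: -1.0, nxt: 1.0},
                "metabolites": [{"id": nxt, "compartment": "c"}],
                "enzyme": {"kcat": 36.0, "mw": 40.0},
            })
            prev = nxt
        out = apply_edits(mini_strain, additions=additions)
        assert len(out.reactions) == len(mini_strain.reactions) + 5
        # chain is connected: walk from the tyrosine-analogue node
        node, seen = "pyr_c", []
        for step in steps:
            rid = f"HET_{step.upper()}"
            assert out.reactions[rid].stoichiometry[node] == -1.0
            node = next(m for m, c in out.reactions[rid].stoichiometry.items()
                        if c > 0)
            seen.append(rid)
        assert out.reactions[seen[-1]].enzyme.kcat == 36.0

    def test_addition_with_unknown_metabolite_is_error(self, mini_strain):
        with pytest.raises(EditError, match="missing_c"):
            apply_edits(mini_strain, additions=[
                {"id": "NEW", "stoichiometry": {"missing_c": -1.0}}])

    def test_bound_changes(self, mini_strain):
        out = apply_edits(mini_strain, bound_changes={"GLYC": (1.0, 5.0)})
        assert (out.reactions["GLYC"].lower_bound,
                out.reactions["GLYC"].upper_bound) == (1.0, 5.0)

    def test_input_hash_unchanged(self, mini_strain):
        before = _signature(build_mini_strain())
        apply_edits(mini_strain, knockouts=["GLYC"],
                    bound_changes={"LDH": (0, 1)})
        assert _signature(mini_strain) == before
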