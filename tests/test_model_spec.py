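"""Model representation: EQN parsing, probabilities, constraints, df."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mptfoils import (
    AffineExpr,
    ConstraintError,
    ConstraintSet,
    EqnParseError,
    MptError,
    MptModel,
    apply_constraints,
    build_recognition_model,
    build_source_model,
    category_probabilities,
    model_degrees_of_freedom,
    parse_eqn,
    same_structure,
    write_eqn,
)

OLD_TREE_EQN = """
old_surv  hit   D_S
old_surv  miss  (1-D_S)*(1-b)
old_surv  hit   (1-D_S)*b
"""


class TestParseEqn:
    def test_single_tree_example(self):
        model = parse_eqn(OLD_TREE_EQN)
        assert len(model.trees) == 1
        assert model.trees[0].categories == ("hit", "miss")
        assert len(model.trees[0].branches) == 3
        assert set(model.parameters) == {"D_S", "b"}

    def test_empty_input_is_an_error(self):
        with pytest.raises(EqnParseError, match="empty model"):
            parse_eqn("# only a comment\n\n")

    def test_malformed_branch_names_the_line(self):
        with pytest.raises(EqnParseError, match="line 2"):
            parse_eqn("t a D\nt b D*+q\n")

    def test_category_in_two_trees_is_an_error(self):
        with pytest.raises(EqnParseError, match="already belongs"):
            parse_eqn("t1 shared D\nt2 shared (1-D)\n")

    def test_shipped_recognition_fixture(self):
        from importlib import resources

        text = (
            resources.files("mptfoils")
            .joinpath("data", "fig1_recognition.eqn")
            .read_text()
        )
        model = parse_eqn(text)
        assert len(model.trees) == 6
        assert len(model.category_order) == 12
        assert set(model.parameters) == {
            "D_Survival_SR", "D_Pleasantness_SR", "D_Foil_SR", "b_SR",
            "D_Survival_PR", "D_Pleasantness_PR", "D_Foil_PR", "b_PR",
        }

    @pytest.mark.parametrize("builder", [build_recognition_model, build_source_model])
    def test_write_then_parse_round_trips_structure(self, builder):
        model, _ = builder()
        text = write_eqn(model, header="round-trip check")
        assert same_structure(parse_eqn(text), model)
        # and the writer is stable on a re-parsed model up to the header
        assert write_eqn(parse_eqn(text)) == write_eqn(parse_eqn(write_eqn(parse_eqn(text))))


class TestCategoryProbabilities:
    def test_certain_recognition(self):
        model = parse_eqn(OLD_TREE_EQN)
        probs = category_probabilities(model, {"D_S": 1.0, "b": 0.3})
        assert probs == {"hit": 1.0, "miss": 0.0}

    def test_recognition_plus_guessing(self):
        model = parse_eqn(OLD_TREE_EQN)
        probs = category_probabilities(model, {"D_S": 0.8, "b": 0.5})
        assert probs["hit"] == pytest.approx(0.9, abs=1e-12)
        assert probs["miss"] == pytest.approx(0.1, abs=1e-12)

    def test_source_tree_hand_evaluation(self, source):
        # detected-and-remembered, detected-and-guessed, undetected-and-guessed
        model, _ = source
        params = {name: 0.0 for name in model.parameters}
        params.update(
            {"D_Survival_SR": 0.7, "d_Survival_SR": 0.5, "b_SR": 0.4, "g_SR": 0.45}
        )
        probs = category_probabilities(model, params)
        assert probs["survival_SR:survival"] == pytest.approx(
            0.7 * 0.5 + 0.7 * 0.5 * 0.45 + 0.3 * 0.4 * 0.45, abs=1e-12
        )
        assert probs["survival_SR:moving"] == pytest.approx(
            0.7 * 0.5 * 0.55 + 0.3 * 0.4 * 0.55, abs=1e-12
        )
        assert probs["survival_SR:no"] == pytest.approx(0.3 * 0.6, abs=1e-12)
        tree_sum = sum(probs[c] for c in model.tree("survival_SR").categories)
        assert tree_sum == pytest.approx(1.0, abs=1e-12)

    def test_unbound_parameter_is_named(self):
        model = parse_eqn(OLD_TREE_EQN)
        with pytest.raises(MptError, match="D_S"):
            category_probabilities(model, {"b": 0.5})

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=14, max_size=14))
    def test_tree_probabilities_sum_to_one(self, values):
        model, _ = build_source_model()
        params = dict(zip(model.parameters, values))
        probs = category_probabilities(model, params)
        for tree in model.trees:
            assert sum(probs[c] for c in tree.categories) == pytest.approx(
                1.0, abs=1e-12
            )


class TestConstraints:
    def test_derived_midpoint(self, recognition):
        model, constraints = recognition
        free = dict.fromkeys(constraints.free_parameters(model), 0.5)
        free.update({"D_Survival_SR": 0.6, "D_Pleasantness_SR": 0.4})
        bound = apply_constraints(constraints, model, free)
        assert bound["D_Foil_SR"] == pytest.approx(0.5, abs=1e-15)

    def test_equality_propagates(self, recognition):
        model, constraints = recognition
        free = dict.fromkeys(constraints.free_parameters(model), 0.5)
        bound = apply_constraints(constraints, model, free)
        assert bound["b_SR"] == bound["b_PR"] == 0.5

    def test_fixed_value_passthrough(self):
        model = parse_eqn(OLD_TREE_EQN)
        constraints = ConstraintSet.build(fixed={"b": 0.5})
        bound = apply_constraints(constraints, model, {"D_S": 0.7})
        assert bound == {"D_S": 0.7, "b": 0.5}

    def test_free_vector_mismatch_is_an_error(self, recognition):
        model, constraints = recognition
        with pytest.raises(ConstraintError, match="missing"):
            apply_constraints(constraints, model, {"b_SR": 0.5})

    def test_cyclic_derived_definition_is_an_error(self):
        model = parse_eqn("t a p*q\nt b (1-p)\n")
        constraints = ConstraintSet.build(
            derived={
                "p": AffineExpr((("q", 0.5),)),
                "q": AffineExpr((("p", 0.5),)),
            }
        )
        with pytest.raises(ConstraintError, match="cyclic"):
            constraints.free_parameters(model)

    def test_range_unsafe_affine_expression_rejected(self):
        with pytest.raises(ConstraintError, match=r"\[0, 1\]"):
            AffineExpr((("a", 0.9), ("b", 0.9)))

    def test_idempotent_and_order_independent(self, recognition):
        model, _ = recognition
        a = ConstraintSet.build(
            equalities=[("b_SR", "b_PR"), ("D_Survival_SR", "D_Survival_PR")]
        )
        b = ConstraintSet.build(
            equalities=[("D_Survival_PR", "D_Survival_SR"), ("b_PR", "b_SR")]
        )
        free = dict.fromkeys(a.free_parameters(model), 0.25)
        assert a.free_parameters(model) == b.free_parameters(model)
        bound_a = apply_constraints(a, model, free)
        assert bound_a == apply_constraints(b, model, free)
        # re-applying through an equivalent singleton free map changes nothing
        assert apply_constraints(a, model, free) == bound_a


class TestDegreesOfFreedom:
    def test_recognition_base_model(self, recognition):
        assert model_degrees_of_freedom(*recognition) == 1

    def test_source_base_model(self, source):
        model, constraints = source
        assert len(constraints.free_parameters(model)) == 11
        assert model_degrees_of_freedom(model, constraints) == 1

    def test_saturated_recognition_model(self, recognition):
        model, constraints = recognition
        saturated = ConstraintSet.build(
            derived=constraints.derived_map
        )  # D_Foil derived, b free per condition
        assert model_degrees_of_freedom(model, saturated) == 0

    def test_overparameterized_model_is_an_error(self, recognition):
        model, _ = recognition
        with pytest.raises(MptError, match="over-parameterized"):
            model_degrees_of_freedom(model, ConstraintSet.build())


class TestBuilders:
    def test_recognition_structure(self, recognition):
        model, constraints = recognition
        assert len(model.trees) == 6
        assert len(model.category_order) == 12
        assert len(constraints.free_parameters(model)) == 5

    def test_source_structure(self, source):
        model, constraints = source
        assert len(model.trees) == 6
        assert len(model.category_order) == 18
        assert len(constraints.free_parameters(model)) == 11

    def test_builders_match_shipped_fixtures(self):
        from importlib import resources

        for fixture, builder in [
            ("fig1_recognition.eqn", build_recognition_model),
            ("fig3_source.eqn", build_source_model),
        ]:
            text = resources.files("mptfoils").joinpath("data", fixture).read_text()
            assert same_structure(parse_eqn(text), builder()[0])

    def test_duplicate_category_across_trees_rejected(self):
        from mptfoils import Branch, Tree

        t1 = Tree("a", (Branch((("p", False),), "x"), Branch((("p", True),), "y")), ("x", "y"))
        t2 = Tree("b", (Branch((("q", False),), "x"), Branch((("q", True),), "z")), ("x", "z"))
        with pytest.raises(MptError, match="appears in trees"):
            MptModel(trees=(t1, t2))
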