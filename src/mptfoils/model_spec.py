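"""Multinomial processing tree (MPT) model representation.

An MPT model expresses the probabilities of discrete response categories as
sums over tree branches, each branch probability being a product of latent
process parameters and their complements.  This module provides the model
container, an EQN-format reader/writer, constraint machinery (equalities,
fixed values, affine derived parameters) and the builders for the two
models used in the memory-for-foils study: the two-high-threshold (2HT)
recognition model and its source-monitoring extension.

Parameter conventions for the built models
------------------------------------------
``D``  recognition (detection of an item as old, or of a foil as new),
``d``  source memory (retrieval of the encoding context),
``b``  bias to guess "old" for undetected items,
``g``  bias to guess the survival source.

Condition-indexed parameters carry a retrieval-condition suffix
(``_SR`` survival-constrained, ``_PR`` pleasantness-constrained,
``_MR`` moving-constrained retrieval).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MptError",
    "EqnParseError",
    "ConstraintError",
    "Parameter",
    "Branch",
    "Tree",
    "MptModel",
    "AffineExpr",
    "ConstraintSet",
    "parse_eqn",
    "write_eqn",
    "same_structure",
    "category_probabilities",
    "apply_constraints",
    "model_degrees_of_freedom",
    "build_recognition_model",
    "build_source_model",
]


class MptError(Exception):
    """Base class for model-structure errors."""


class EqnParseError(MptError):
    """Raised when an EQN model file cannot be parsed."""


class ConstraintError(MptError):
    """Raised for invalid or inconsistent constraint sets."""


@dataclass(frozen=True)
class Parameter:
    """A named latent-process probability, optionally bound to a value."""

    name: str
    value: float | None = None

    def __post_init__(self) -> None:
        if self.value is not None and not (0.0 <= self.value <= 1.0):
            raise MptError(
                f"parameter {self.name!r} bound to {self.value}, outside [0, 1]"
            )


@dataclass(frozen=True)
class Branch:
    """One root-to-leaf path: a product of factors ending in a category.

    ``factors`` is an ordered tuple of ``(parameter_name, complement)``
    pairs; the branch probability is the product of ``p`` or ``1 - p``
    accordingly.
    """

    factors: tuple[tuple[str, bool], ...]
    category: str

    def probability(self, params: Mapping[str, float]) -> float:
        prob = 1.0
        for name, complement in self.factors:
            value = params[name]
            prob *= (1.0 - value) if complement else value
        return prob

    def expression(self) -> str:
        if not self.factors:
            return "1"
        return "*".join(
            f"(1-{name})" if complement else name for name, complement in self.factors
        )


@dataclass(frozen=True)
class Tree:
    """A processing tree: branches over an ordered set of categories."""

    name: str
    branches: tuple[Branch, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        reachable = {b.category for b in self.branches}
        if reachable != set(self.categories):
            raise MptError(
                f"tree {self.name!r}: categories {sorted(reachable)} reachable "
                f"but {list(self.categories)} declared"
            )


@dataclass(frozen=True)
class MptModel:
    """A collection of processing trees sharing one parameter space."""

    trees: tuple[Tree, ...]
    parameters: tuple[str, ...] = field(default=())
    category_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.trees:
            raise MptError("empty model: no trees defined")
        seen_params: list[str] = []
        for tree in self.trees:
            for branch in tree.branches:
                for name, _ in branch.factors:
                    if name not in seen_params:
                        seen_params.append(name)
        if not self.parameters:
            object.__setattr__(self, "parameters", tuple(seen_params))
        else:
            undeclared = set(seen_params) - set(self.parameters)
            if undeclared:
                raise MptError(f"undeclared parameters: {sorted(undeclared)}")
        cats: list[str] = []
        owner: dict[str, str] = {}
        for tree in self.trees:
            for cat in tree.categories:
                if cat in owner:
                    raise MptError(
                        f"category {cat!r} appears in trees {owner[cat]!r} "
                        f"and {tree.name!r}"
                    )
                owner[cat] = tree.name
                cats.append(cat)
        if not self.category_order:
            object.__setattr__(self, "category_order", tuple(cats))
        elif set(self.category_order) != set(cats) or len(self.category_order) != len(cats):
            raise MptError("category_order does not match the trees' categories")

    @property
    def tree_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.trees)

    def tree_of_category(self, category: str) -> str:
        for tree in self.trees:
            if category in tree.categories:
                return tree.name
        raise KeyError(category)

    def tree(self, name: str) -> Tree:
        for tree in self.trees:
            if tree.name == name:
                return tree
        raise KeyError(name)


_FACTOR_RE = re.compile(r"^(?:(?P<plain>[A-Za-z_][\w.]*)|\(1-(?P<comp>[A-Za-z_][\w.]*)\))$")


def parse_eqn(text: str) -> MptModel:
    """Parse a classic three-column EQN model description.

    Each non-empty, non-comment (``#``) line reads
    ``tree-name  category-name  branch-expression`` where the branch
    expression is a ``*``-joined product of ``p`` or ``(1-p)`` tokens.
    Repeated (tree, category) lines are parallel branches and are summed.
    """
    tree_order: list[str] = []
    tree_cats: dict[str, list[str]] = {}
    tree_branches: dict[str, list[Branch]] = {}
    cat_owner: dict[str, str] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 3:
            raise EqnParseError(
                f"line {lineno}: expected 'tree category expression', got {raw!r}"
            )
        tree_name, category, expr = fields
        factors: list[tuple[str, bool]] = []
        for token in expr.split("*"):
            m = _FACTOR_RE.match(token.strip())
            if m is None:
                raise EqnParseError(
                    f"line {lineno}: malformed factor {token!r} in branch "
                    f"expression {expr!r}"
                )
            if m.group("plain"):
                factors.append((m.group("plain"), False))
            else:
                factors.append((m.group("comp"), True))
        if tree_name not in tree_cats:
            tree_order.append(tree_name)
            tree_cats[tree_name] = []
            tree_branches[tree_name] = []
        if category in cat_owner and cat_owner[category] != tree_name:
            raise EqnParseError(
                f"line {lineno}: category {category!r} already belongs to tree "
                f"{cat_owner[category]!r}"
            )
        cat_owner[category] = tree_name
        if category not in tree_cats[tree_name]:
            tree_cats[tree_name].append(category)
        tree_branches[tree_name].append(Branch(tuple(factors), category))

    if not tree_order:
        raise EqnParseError("empty model: no branch lines found")

    trees = tuple(
        Tree(name, tuple(tree_branches[name]), tuple(tree_cats[name]))
        for name in tree_order
    )
    return MptModel(trees=trees)


def write_eqn(model: MptModel, header: str | None = None) -> str:
    """Serialize a model to EQN text; re-parsing reproduces its structure."""
    lines: list[str] = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    width_t = max(len(t.name) for t in model.trees)
    width_c = max(len(c) for c in model.category_order)
    for tree in model.trees:
        for branch in tree.branches:
            lines.append(
                f"{tree.name:<{width_t}}  {branch.category:<{width_c}}  "
                f"{branch.expression()}"
            )
    return "\n".join(lines) + "\n"


def _tree_structure_key(tree: Tree):
    return (
        tree.name,
        tuple(sorted(tree.categories)),
        tuple(sorted((b.category, b.factors) for b in tree.branches)),
    )


def same_structure(a: MptModel, b: MptModel) -> bool:
    """Structural model equality: same trees (in order), categories and
    branch multisets.  Branch and category declaration order are
    serialization detail and are ignored."""
    if len(a.trees) != len(b.trees):
        return False
    return all(
        _tree_structure_key(ta) == _tree_structure_key(tb)
        for ta, tb in zip(a.trees, b.trees)
    )


def category_probabilities(
    model: MptModel, params: Mapping[str, float]
) -> dict[str, float]:
    """Evaluate category probabilities for a fully bound parameter map.

    Within each tree the probabilities sum to one; parallel branches that
    share a category are summed.
    """
    for name in model.parameters:
        if name not in params:
            raise MptError(f"unbound parameter: {name!r}")
        value = params[name]
        if not (0.0 <= value <= 1.0):
            raise MptError(f"parameter {name!r} = {value} outside [0, 1]")
    probs = {cat: 0.0 for cat in model.category_order}
    for tree in model.trees:
        for branch in tree.branches:
            probs[branch.category] += branch.probability(params)
    return probs


@dataclass(frozen=True)
class AffineExpr:
    """Affine expression ``const + sum(coeffs[p] * p)`` over parameters.

    Weights are restricted to [0, 1] with total weight plus constant not
    exceeding 1, which guarantees the result stays in [0, 1] for any
    admissible argument (sufficient for parameter averaging).
    """

    coeffs: tuple[tuple[str, float], ...]
    const: float = 0.0

    def __post_init__(self) -> None:
        total = self.const
        for name, w in self.coeffs:
            if w < 0.0 or w > 1.0:
                raise ConstraintError(
                    f"affine weight {w} for {name!r} outside [0, 1]"
                )
            total += w
        if self.const < 0.0 or total > 1.0 + 1e-12:
            raise ConstraintError(
                "affine expression may leave [0, 1]: weights plus constant "
                f"sum to {total}"
            )

    def evaluate(self, values: Mapping[str, float]) -> float:
        return self.const + sum(w * values[name] for name, w in self.coeffs)

    @classmethod
    def mean(cls, names: Sequence[str]) -> "AffineExpr":
        w = 1.0 / len(names)
        return cls(tuple((n, w) for n in names))


@dataclass(frozen=True)
class ConstraintSet:
    """Equality classes, fixed values and derived definitions.

    Together these reduce a model's parameter space to the free parameters:
    a parameter is free iff it is neither fixed nor derived and is the
    representative (first in model declaration order) of its equality class.
    """

    equalities: tuple[frozenset[str], ...] = ()
    fixed: tuple[tuple[str, float], ...] = ()
    derived: tuple[tuple[str, AffineExpr], ...] = ()

    @classmethod
    def build(
        cls,
        equalities: Iterable[Iterable[str]] = (),
        fixed: Mapping[str, float] | None = None,
        derived: Mapping[str, AffineExpr] | None = None,
    ) -> "ConstraintSet":
        classes = _merge_classes([frozenset(group) for group in equalities])
        return cls(
            equalities=tuple(classes),
            fixed=tuple(sorted((fixed or {}).items())),
            derived=tuple(sorted((derived or {}).items())),
        )

    @property
    def fixed_map(self) -> dict[str, float]:
        return dict(self.fixed)

    @property
    def derived_map(self) -> dict[str, AffineExpr]:
        return dict(self.derived)

    def with_equalities(self, *groups: Iterable[str]) -> "ConstraintSet":
        """Return a new constraint set with additional equality restrictions."""
        merged = _merge_classes(
            list(self.equalities) + [frozenset(g) for g in groups]
        )
        return ConstraintSet(tuple(merged), self.fixed, self.derived)

    def equality_class(self, name: str) -> frozenset[str]:
        for group in self.equalities:
            if name in group:
                return group
        return frozenset([name])

    def validate(self, model: MptModel) -> None:
        declared = set(model.parameters)
        fixed = self.fixed_map
        derived = self.derived_map
        for name in list(fixed) + list(derived):
            if name not in declared:
                raise ConstraintError(f"constraint on undeclared parameter {name!r}")
        for group in self.equalities:
            unknown = group - declared
            if unknown:
                raise ConstraintError(
                    f"equality class references undeclared parameters {sorted(unknown)}"
                )
            if group & set(derived):
                raise ConstraintError(
                    "derived parameters may not appear in equality classes"
                )
        for name, value in fixed.items():
            if not (0.0 <= value <= 1.0):
                raise ConstraintError(f"fixed value {name} = {value} outside [0, 1]")
            if name in derived:
                raise ConstraintError(f"parameter {name!r} both fixed and derived")
        _toposort_derived(derived)  # raises on cycles

    def free_parameters(self, model: MptModel) -> tuple[str, ...]:
        """Free parameters in model declaration order."""
        self.validate(model)
        fixed = self.fixed_map
        derived = self.derived_map
        free: list[str] = []
        for name in model.parameters:
            if name in fixed or name in derived:
                continue
            rep = self._representative(model, name)
            if rep == name:
                free.append(name)
        return tuple(free)

    def _representative(self, model: MptModel, name: str) -> str:
        group = self.equality_class(name)
        fixed = self.fixed_map
        in_fixed = group & set(fixed)
        if in_fixed:
            return sorted(in_fixed)[0]
        for candidate in model.parameters:
            if candidate in group:
                return candidate
        raise ConstraintError(f"parameter {name!r} not declared in the model")

    def affine_map(
        self, model: MptModel
    ) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
        """Express all bound parameters as ``A @ free + c``.

        Valid because equalities, fixed values and the (restricted) derived
        expressions are all affine in the free parameters.
        """
        free = self.free_parameters(model)
        free_idx = {name: j for j, name in enumerate(free)}
        n_all = len(model.parameters)
        A = np.zeros((n_all, len(free)))
        c = np.zeros(n_all)
        fixed = self.fixed_map
        derived = self.derived_map

        rows: dict[str, np.ndarray] = {}
        consts: dict[str, float] = {}

        def resolve(name: str) -> tuple[np.ndarray, float]:
            if name in rows:
                return rows[name], consts[name]
            row = np.zeros(len(free))
            const = 0.0
            if name in derived:
                expr = derived[name]
                const = expr.const
                for dep, w in expr.coeffs:
                    drow, dconst = resolve(dep)
                    row += w * drow
                    const += w * dconst
            else:
                rep = self._representative(model, name)
                if rep in fixed:
                    const = fixed[rep]
                else:
                    row[free_idx[rep]] = 1.0
            rows[name] = row
            consts[name] = const
            return row, const

        _toposort_derived(derived)
        for i, name in enumerate(model.parameters):
            row, const = resolve(name)
            A[i] = row
            c[i] = const
        return A, c, free

    def implies(self, other: "ConstraintSet") -> bool:
        """True if every restriction in `other` also holds under `self`.

        Used to verify nesting: a restricted model's constraint set must
        imply the base model's.
        """
        if set(other.fixed) - set(self.fixed):
            return False
        if set(other.derived) - set(self.derived):
            return False
        for group in other.equalities:
            first = next(iter(group))
            mine = self.equality_class(first)
            if not group <= mine:
                return False
        return True


def _merge_classes(groups: list[frozenset[str]]) -> list[frozenset[str]]:
    """Union overlapping equality classes (transitive closure)."""
    classes: list[set[str]] = []
    for group in groups:
        if len(group) < 2:
            continue
        touching = [cl for cl in classes if cl & group]
        merged = set(group).union(*touching) if touching else set(group)
        classes = [cl for cl in classes if not (cl & group)]
        classes.append(merged)
    return [frozenset(cl) for cl in sorted(classes, key=lambda c: sorted(c)[0])]


def _toposort_derived(derived: Mapping[str, AffineExpr]) -> list[str]:
    order: list[str] = []
    marks: dict[str, int] = {}  # 1 = in progress, 2 = done

    def visit(name: str, chain: tuple[str, ...]) -> None:
        state = marks.get(name)
        if state == 2:
            return
        if state == 1:
            cycle = " -> ".join(chain + (name,))
            raise ConstraintError(f"cyclic derived-parameter definition: {cycle}")
        marks[name] = 1
        for dep, _ in derived[name].coeffs:
            if dep in derived:
                visit(dep, chain + (name,))
        marks[name] = 2
        order.append(name)

    for name in derived:
        visit(name, ())
    return order


def apply_constraints(
    constraints: ConstraintSet, model: MptModel, free: Mapping[str, float]
) -> dict[str, float]:
    """Expand a free-parameter vector to a fully bound parameter map.

    Equalities hold exactly, fixed parameters take their constants, derived
    parameters satisfy their affine definitions exactly; every result is
    checked to lie in [0, 1].
    """
    free_names = constraints.free_parameters(model)
    if set(free) != set(free_names):
        missing = set(free_names) - set(free)
        extra = set(free) - set(free_names)
        raise ConstraintError(
            f"free vector mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    for name, value in free.items():
        if not (0.0 <= value <= 1.0):
            raise ConstraintError(f"free parameter {name} = {value} outside [0, 1]")
    A, c, names = constraints.affine_map(model)
    vec = A @ np.array([free[n] for n in names]) + c
    bound = dict(zip(model.parameters, vec.tolist()))
    for name, value in bound.items():
        if value < -1e-12 or value > 1.0 + 1e-12:
            raise ConstraintError(
                f"constrained parameter {name!r} = {value} outside [0, 1]"
            )
        bound[name] = min(1.0, max(0.0, value))
    return bound


def model_degrees_of_freedom(model: MptModel, constraints: ConstraintSet) -> int:
    """Residual degrees of freedom: sum over trees of (categories - 1)
    minus the number of free parameters."""
    data_df = sum(len(tree.categories) - 1 for tree in model.trees)
    df = data_df - len(constraints.free_parameters(model))
    if df < 0:
        raise MptError(
            f"over-parameterized model: {data_df} data degrees of freedom but "
            f"{data_df - df} free parameters"
        )
    return df


# ---------------------------------------------------------------------------
# Builders for the memory-for-foils study models
# ---------------------------------------------------------------------------


def _old_recognition_tree(tree: str, D: str, b: str) -> Tree:
    branches = (
        Branch(((D, False),), f"{tree}:yes"),
        Branch(((D, True), (b, False)), f"{tree}:yes"),
        Branch(((D, True), (b, True)), f"{tree}:no"),
    )
    return Tree(tree, branches, (f"{tree}:yes", f"{tree}:no"))


def _foil_recognition_tree(tree: str, D: str, b: str) -> Tree:
    branches = (
        Branch(((D, False),), f"{tree}:no"),
        Branch(((D, True), (b, False)), f"{tree}:yes"),
        Branch(((D, True), (b, True)), f"{tree}:no"),
    )
    return Tree(tree, branches, (f"{tree}:yes", f"{tree}:no"))


def build_recognition_model() -> tuple[MptModel, ConstraintSet]:
    """Six-tree 2HT recognition model for the final test of Experiment 1.

    One tree per word type (survival-judged, pleasantness-judged, foil)
    crossed with retrieval condition (_SR survival-constrained, _PR
    pleasantness-constrained).  The base constraint set derives the foil
    detection parameter as the mean of the two old-word detection
    parameters within each retrieval condition (identifiability), and
    equates the old-guessing bias b across retrieval conditions.
    """
    trees: list[Tree] = []
    derived: dict[str, AffineExpr] = {}
    for cond in ("SR", "PR"):
        trees.append(
            _old_recognition_tree(f"survival_{cond}", f"D_Survival_{cond}", f"b_{cond}")
        )
        trees.append(
            _old_recognition_tree(
                f"pleasantness_{cond}", f"D_Pleasantness_{cond}", f"b_{cond}"
            )
        )
        trees.append(
            _foil_recognition_tree(f"foil_{cond}", f"D_Foil_{cond}", f"b_{cond}")
        )
        derived[f"D_Foil_{cond}"] = AffineExpr.mean(
            [f"D_Survival_{cond}", f"D_Pleasantness_{cond}"]
        )
    model = MptModel(trees=tuple(trees))
    constraints = ConstraintSet.build(
        equalities=[("b_SR", "b_PR")], derived=derived
    )
    return model, constraints


def _old_source_tree(tree: str, D: str, d: str, b: str, g: str, own: str) -> Tree:
    branches = (
        Branch(((D, False), (d, False)), f"{tree}:{own}"),
        Branch(((D, False), (d, True), (g, False)), f"{tree}:survival"),
        Branch(((D, False), (d, True), (g, True)), f"{tree}:moving"),
        Branch(((D, True), (b, False), (g, False)), f"{tree}:survival"),
        Branch(((D, True), (b, False), (g, True)), f"{tree}:moving"),
        Branch(((D, True), (b, True)), f"{tree}:no"),
    )
    return Tree(tree, branches, (f"{tree}:survival", f"{tree}:moving", f"{tree}:no"))


def _foil_source_tree(tree: str, D: str, b: str, g: str) -> Tree:
    branches = (
        Branch(((D, False),), f"{tree}:no"),
        Branch(((D, True), (b, False), (g, False)), f"{tree}:survival"),
        Branch(((D, True), (b, False), (g, True)), f"{tree}:moving"),
        Branch(((D, True), (b, True)), f"{tree}:no"),
    )
    return Tree(tree, branches, (f"{tree}:survival", f"{tree}:moving", f"{tree}:no"))


def build_source_model() -> tuple[MptModel, ConstraintSet]:
    """Six-tree 2HT source-monitoring model for the final test of
    Experiment 2.

    Each old-word tree separates recognition (D), source memory (d), old
    guessing (b) and source guessing (g: probability of guessing the
    survival source).  The base constraint set mirrors the recognition
    model: foil detection derived as the within-condition mean of the
    old-word D parameters, b shared across retrieval conditions, g free
    per retrieval condition.
    """
    trees: list[Tree] = []
    derived: dict[str, AffineExpr] = {}
    for cond in ("SR", "MR"):
        b, g = f"b_{cond}", f"g_{cond}"
        trees.append(
            _old_source_tree(
                f"survival_{cond}",
                f"D_Survival_{cond}",
                f"d_Survival_{cond}",
                b,
                g,
                own="survival",
            )
        )
        trees.append(
            _old_source_tree(
                f"moving_{cond}",
                f"D_Moving_{cond}",
                f"d_Moving_{cond}",
                b,
                g,
                own="moving",
            )
        )
        trees.append(_foil_source_tree(f"foil_{cond}", f"D_Foil_{cond}", b, g))
        derived[f"D_Foil_{cond}"] = AffineExpr.mean(
            [f"D_Survival_{cond}", f"D_Moving_{cond}"]
        )
    model = MptModel(trees=tuple(trees))
    constraints = ConstraintSet.build(
        equalities=[("b_SR", "b_MR")], derived=derived
    )
    return model, constraints
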