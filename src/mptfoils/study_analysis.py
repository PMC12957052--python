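"""Reproduction of the memory-for-foils model-based analyses.

The two experiments' response proportions (final recognition test,
Experiment 1; final source-memory test, Experiment 2) are shipped as CSV
fixtures together with the design cell sizes.  Frequencies are
reconstructed as proportion × cell total with the last category of each
tree absorbing the rounding residual, the base models are fitted, and the
full battery of equality-restriction tests is run.

The analyses operate on frequencies aggregated across participants — a
single G² per experiment — matching the reported single-table analysis.
Because the shipped proportions carry two-decimal rounding, reconstructed
counts (and hence G²/ΔG² values) carry a small, bounded reconstruction
error; see the methods note for the implied tolerances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .estimation import EstimationError, FitResult, FrequencyTable, fit
from .inference import RestrictionTest, nested_test
from .model_spec import (
    ConstraintSet,
    MptModel,
    build_recognition_model,
    build_source_model,
)

__all__ = [
    "DesignSpec",
    "StudyReport",
    "EXP1_DESIGN",
    "EXP2_DESIGN",
    "EXP1_RESTRICTIONS",
    "EXP2_RESTRICTIONS",
    "load_proportions",
    "reconstruct_frequencies",
    "run_experiment1",
    "run_experiment2",
]

_ROW_SUM_TOL = 0.011  # printed two-decimal rounding slack per tree row


@dataclass(frozen=True)
class DesignSpec:
    """Cell sizes of the three-phase memory-for-foils design.

    Each participant contributes ``old_words_per_cell`` old words per
    encoding × retrieval cell and ``foils_per_cell`` foils per retrieval
    cell, for 80 old + 80 foil = 160 final-test decisions.
    """

    n_participants: int
    old_words_per_cell: int = 20
    foils_per_cell: int = 40

    def tree_total(self, tree_name: str) -> int:
        per_cell = (
            self.foils_per_cell if tree_name.startswith("foil") else self.old_words_per_cell
        )
        return self.n_participants * per_cell

    @property
    def decisions_per_participant(self) -> int:
        # 2 encoding conditions x 2 retrieval conditions x old words
        # + 2 retrieval conditions x foils
        return 4 * self.old_words_per_cell + 2 * self.foils_per_cell

    @property
    def n_decisions(self) -> int:
        return self.n_participants * self.decisions_per_participant


EXP1_DESIGN = DesignSpec(n_participants=97)
EXP2_DESIGN = DesignSpec(n_participants=98)

# Named equality restrictions tested against each base model.
EXP1_RESTRICTIONS: tuple[tuple[str, tuple[str, str]], ...] = (
    (
        "recognition: survival vs pleasantness words, survival-constrained retrieval",
        ("D_Survival_SR", "D_Pleasantness_SR"),
    ),
    (
        "recognition: survival vs pleasantness words, pleasantness-constrained retrieval",
        ("D_Survival_PR", "D_Pleasantness_PR"),
    ),
    (
        "recognition: retrieval-condition effect on survival-judged words",
        ("D_Survival_SR", "D_Survival_PR"),
    ),
    (
        "recognition: retrieval-condition effect on pleasantness-judged words",
        ("D_Pleasantness_SR", "D_Pleasantness_PR"),
    ),
    (
        "recognition: matched-retrieval survival vs pleasantness words",
        ("D_Survival_SR", "D_Pleasantness_PR"),
    ),
)

EXP2_RESTRICTIONS: tuple[tuple[str, tuple[str, str]], ...] = (
    (
        "recognition: survival vs moving words, survival-constrained retrieval",
        ("D_Survival_SR", "D_Moving_SR"),
    ),
    (
        "recognition: survival vs moving words, moving-constrained retrieval",
        ("D_Survival_MR", "D_Moving_MR"),
    ),
    (
        "recognition: retrieval-condition effect on survival-judged words",
        ("D_Survival_SR", "D_Survival_MR"),
    ),
    (
        "recognition: retrieval-condition effect on moving-judged words",
        ("D_Moving_SR", "D_Moving_MR"),
    ),
    (
        "source memory: survival vs moving words, survival-constrained retrieval",
        ("d_Survival_SR", "d_Moving_SR"),
    ),
    (
        "source memory: survival vs moving words, moving-constrained retrieval",
        ("d_Survival_MR", "d_Moving_MR"),
    ),
    (
        "source memory: retrieval-condition effect on survival-judged words",
        ("d_Survival_SR", "d_Survival_MR"),
    ),
    (
        "source memory: retrieval-condition effect on moving-judged words",
        ("d_Moving_SR", "d_Moving_MR"),
    ),
    (
        "source guessing: survival-constrained vs moving-constrained retrieval",
        ("g_SR", "g_MR"),
    ),
    (
        "recognition: matched-retrieval survival vs moving words",
        ("D_Survival_SR", "D_Moving_MR"),
    ),
    (
        "source memory: matched-retrieval survival vs moving words",
        ("d_Survival_SR", "d_Moving_MR"),
    ),
)


def load_proportions(experiment: int) -> pd.DataFrame:
    """Load the shipped response-proportion table for an experiment."""
    name = {1: "table1_recognition.csv", 2: "table2_source.csv"}.get(experiment)
    if name is None:
        raise ValueError(f"experiment must be 1 or 2, got {experiment}")
    with resources.files("mptfoils").joinpath("data", name).open() as handle:
        return pd.read_csv(handle)


def reconstruct_frequencies(
    proportions: pd.DataFrame, design: DesignSpec, model: MptModel
) -> FrequencyTable:
    """Turn printed response proportions into integer category counts.

    For each tree, all but the last category get ``round(p × total)``; the
    last category absorbs the residual so counts sum to the design-implied
    tree total exactly.  A negative residual count is an error.
    """
    props = dict(zip(proportions["category"], proportions["proportion"]))
    missing = set(model.category_order) - set(props)
    if missing:
        raise EstimationError(f"proportions missing for categories {sorted(missing)}")
    counts: dict[str, int] = {}
    for tree in model.trees:
        row = [props[c] for c in tree.categories]
        if abs(sum(row) - 1.0) > _ROW_SUM_TOL:
            raise EstimationError(
                f"tree {tree.name!r}: proportions sum to {sum(row):.3f}, "
                "outside printed-rounding tolerance"
            )
        total = design.tree_total(tree.name)
        allocated = 0
        for cat, p in zip(tree.categories[:-1], row[:-1]):
            counts[cat] = int(round(p * total))
            allocated += counts[cat]
        residual = total - allocated
        if residual < 0:
            raise EstimationError(
                f"tree {tree.name!r}: residual category count {residual} < 0"
            )
        counts[tree.categories[-1]] = residual
    return FrequencyTable.from_counts(model, counts)


@dataclass(frozen=True)
class StudyReport:
    """Base-model fit plus the battery of restriction tests for one experiment."""

    experiment: int
    design: DesignSpec
    model: MptModel = field(repr=False)
    base_constraints: ConstraintSet = field(repr=False)
    data: FrequencyTable = field(repr=False)
    base_fit: FitResult
    tests: tuple[RestrictionTest, ...]
    seed: int

    def test(self, description_substring: str) -> RestrictionTest:
        matches = [t for t in self.tests if description_substring in t.description]
        if len(matches) != 1:
            raise KeyError(
                f"{description_substring!r} matches {len(matches)} tests; "
                f"available: {[t.description for t in self.tests]}"
            )
        return matches[0]

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "seed": self.seed,
            "note": (
                "fits use frequencies aggregated across participants, "
                "reconstructed from printed proportions and design cell sizes"
            ),
            "design": {
                "n_participants": self.design.n_participants,
                "old_words_per_cell": self.design.old_words_per_cell,
                "foils_per_cell": self.design.foils_per_cell,
            },
            "frequencies": self.data.count_map,
            "base_fit": self.base_fit.to_dict(),
            "tests": [
                {
                    "description": t.description,
                    "delta_g_squared": t.delta_g_squared,
                    "delta_df": t.delta_df,
                    "p_value": t.p_value,
                }
                for t in self.tests
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        fit_ = self.base_fit
        lines = [
            f"Experiment {self.experiment} — aggregated-frequency MPT analysis",
            f"  N = {self.design.n_participants} participants, "
            f"{self.design.decisions_per_participant} final-test decisions each",
            f"  Base model: G²({fit_.df}) = {fit_.g_squared:.2f}, "
            f"p = {fit_.p_value:.3f}",
            "  Parameter estimates (SE):",
        ]
        ses = fit_.se_map
        for name, value in fit_.estimates:
            se = ses[name]
            se_text = f"{se:.2f}" if se == se else "n/a"
            lines.append(f"    {name:<20s} {value:.2f} ({se_text})")
        lines.append("  Equality-restriction tests:")
        for t in self.tests:
            lines.append(
                f"    ΔG²({t.delta_df}) = {t.delta_g_squared:6.2f}, "
                f"p = {t.p_value:.3f}  {t.description}"
            )
        return "\n".join(lines)


def _run_experiment(
    experiment: int,
    builder,
    design: DesignSpec,
    restrictions: tuple[tuple[str, tuple[str, str]], ...],
    *,
    starts: int,
    seed: int,
) -> StudyReport:
    model, base_constraints = builder()
    data = reconstruct_frequencies(load_proportions(experiment), design, model)
    base_fit = fit(model, base_constraints, data, starts=starts, seed=seed)
    tests = []
    for description, pair in restrictions:
        restricted_constraints = base_constraints.with_equalities(pair)
        # refit from scratch (fresh multi-starts) rather than warm-start
        restricted_fit = fit(
            model, restricted_constraints, data, starts=starts, seed=seed,
            compute_se=False,
        )
        tests.append(nested_test(base_fit, restricted_fit, description))
    return StudyReport(
        experiment=experiment,
        design=design,
        model=model,
        base_constraints=base_constraints,
        data=data,
        base_fit=base_fit,
        tests=tuple(tests),
        seed=seed,
    )


def run_experiment1(*, starts: int = 20, seed: int = 1) -> StudyReport:
    """Fit the recognition base model to the Experiment 1 frequencies and
    run its five equality-restriction tests."""
    return _run_experiment(
        1, build_recognition_model, EXP1_DESIGN, EXP1_RESTRICTIONS,
        starts=starts, seed=seed,
    )


def run_experiment2(*, starts: int = 20, seed: int = 1) -> StudyReport:
    """Fit the source-monitoring base model to the Experiment 2 frequencies
    and run its eleven equality-restriction tests."""
    return _run_experiment(
        2, build_source_model, EXP2_DESIGN, EXP2_RESTRICTIONS,
        starts=starts, seed=seed,
    )
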