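"""Participant-level synthetic data under the study's MPT models.

Generates multinomial responses per participant × tree cell from the
category probabilities implied by a fully bound parameter vector, using
the three-phase design's cell sizes (by default 20 old words per
encoding × retrieval cell and 40 foils per retrieval cell).  Sampling is
participant-level so that per-participant descriptives can be emulated;
model fitting consumes the aggregate table.

Reproducibility: a master seed spawns one independent child stream per
participant via ``numpy.random.SeedSequence.spawn``, so a dataset is
identical whether participants are generated serially or in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .estimation import FrequencyTable, fit
from .model_spec import (
    ConstraintSet,
    MptModel,
    build_recognition_model,
    build_source_model,
    category_probabilities,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "model_for_tag",
    "simulate",
    "aggregate",
    "recovery_study",
]

_BUILDERS = {
    "recognition": build_recognition_model,
    "source": build_source_model,
}


def model_for_tag(tag: str) -> tuple[MptModel, ConstraintSet]:
    """Return (model, base constraint set) for a model tag."""
    try:
        return _BUILDERS[tag]()
    except KeyError:
        raise ValueError(
            f"unknown model tag {tag!r}; expected one of {sorted(_BUILDERS)}"
        ) from None


@dataclass(frozen=True)
class SimulationConfig:
    """True parameters, design sizes and seed for one synthetic study."""

    model: str
    true_params: tuple[tuple[str, float], ...]
    n_participants: int
    old_trials: int = 20
    foil_trials: int = 40
    seed: int = 0

    @classmethod
    def create(
        cls,
        model: str,
        true_params: Mapping[str, float],
        n_participants: int,
        *,
        old_trials: int = 20,
        foil_trials: int = 40,
        seed: int = 0,
    ) -> "SimulationConfig":
        if n_participants < 1:
            raise ValueError("n_participants must be positive")
        if old_trials < 1 or foil_trials < 1:
            raise ValueError("trials per cell must be positive")
        for name, value in true_params.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"true parameter {name} = {value} outside [0, 1]")
        return cls(
            model=model,
            true_params=tuple(sorted(true_params.items())),
            n_participants=n_participants,
            old_trials=old_trials,
            foil_trials=foil_trials,
            seed=seed,
        )

    @property
    def param_map(self) -> dict[str, float]:
        return dict(self.true_params)

    def tree_trials(self, tree_name: str) -> int:
        return self.foil_trials if tree_name.startswith("foil") else self.old_trials


@dataclass(frozen=True)
class SyntheticDataset:
    """Per-participant category counts per tree, plus the generating config."""

    config: SimulationConfig
    model: MptModel = field(repr=False)
    # counts[participant, category] in the model's global category order
    counts: np.ndarray = field(repr=False)

    @property
    def n_participants(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in range(self.n_participants):
            for j, cat in enumerate(self.model.category_order):
                rows.append(
                    {
                        "participant": pid,
                        "tree": self.model.tree_of_category(cat),
                        "category": cat,
                        "count": int(self.counts[pid, j]),
                    }
                )
        return pd.DataFrame(rows)


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic dataset: an independent multinomial per
    participant × tree cell, deterministic given the config seed."""
    model, _ = model_for_tag(config.model)
    probs = category_probabilities(model, config.param_map)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    counts = np.zeros((config.n_participants, len(model.category_order)), dtype=np.int64)
    cat_index = {cat: j for j, cat in enumerate(model.category_order)}
    tree_probs = [
        (
            [cat_index[c] for c in tree.categories],
            np.array([probs[c] for c in tree.categories]),
            config.tree_trials(tree.name),
        )
        for tree in model.trees
    ]
    for pid, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        for cat_ids, p, n in tree_probs:
            draw = rng.multinomial(n, p / p.sum())
            counts[pid, cat_ids] = draw
    return SyntheticDataset(config=config, model=model, counts=counts)


def aggregate(dataset: SyntheticDataset) -> FrequencyTable:
    """Sum per-participant counts into one frequency table."""
    if dataset.n_participants == 0:
        raise ValueError("cannot aggregate an empty dataset")
    totals = dataset.counts.sum(axis=0)
    counts = {
        cat: int(totals[j]) for j, cat in enumerate(dataset.model.category_order)
    }
    return FrequencyTable.from_counts(dataset.model, counts)


def recovery_study(
    config: SimulationConfig,
    replicates: int,
    *,
    constraints: ConstraintSet | None = None,
    starts: int = 3,
    fit_seed: int = 1,
) -> pd.DataFrame:
    """Monte-Carlo parameter recovery under the study design.

    For each replicate: simulate, aggregate, fit with the model's base
    constraint set (or a supplied one), then summarize per free parameter
    the mean estimate, bias, RMSE and the coverage of the ±1.96·SE
    interval.  Replicates whose fit fails to converge are recorded and
    skipped rather than fatal.
    """
    if replicates < 2:
        raise ValueError("recovery_study needs at least 2 replicates")
    model, base_constraints = model_for_tag(config.model)
    if constraints is None:
        constraints = base_constraints
    truth = config.param_map
    free = constraints.free_parameters(model)
    rep_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(replicates)
    ]
    estimates: dict[str, list[float]] = {p: [] for p in free}
    covered: dict[str, list[bool]] = {p: [] for p in free}
    failures = 0
    for rep_seed in rep_seeds:
        rep_config = replace(config, seed=rep_seed)
        data = aggregate(simulate(rep_config))
        try:
            result = fit(model, constraints, data, starts=starts, seed=fit_seed)
        except Exception:
            failures += 1
            continue
        est, ses = result.estimate_map, result.se_map
        for p in free:
            estimates[p].append(est[p])
            se = ses[p]
            if se == se:  # not NaN
                covered[p].append(abs(est[p] - truth[p]) <= 1.96 * se)
    rows = []
    for p in free:
        values = np.array(estimates[p])
        rows.append(
            {
                "parameter": p,
                "truth": truth[p],
                "n_replicates": len(values),
                "n_failures": failures,
                "mean_estimate": float(values.mean()),
                "bias": float(values.mean() - truth[p]),
                "rmse": float(np.sqrt(np.mean((values - truth[p]) ** 2))),
                "se_coverage": float(np.mean(covered[p])) if covered[p] else float("nan"),
            }
        )
    return pd.DataFrame(rows)
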