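"""Maximum-likelihood estimation of MPT models from category frequencies.

Fitting maximizes the product-multinomial log-likelihood over the free
parameters of a constrained model (equivalently, minimizes the G²
likelihood-ratio statistic).  Free parameters are mapped to the real line
by a logit transform and the negative log-likelihood is minimized by
quasi-Newton search with analytic gradients, from multiple random starting
points.  Standard errors come from the inverse expected Fisher information
of the product-multinomial likelihood, propagated to all (possibly
constrained) parameters through the affine constraint map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .model_spec import ConstraintSet, MptError, MptModel, model_degrees_of_freedom

__all__ = [
    "EstimationError",
    "FrequencyTable",
    "FitResult",
    "RankReport",
    "g_squared",
    "fit",
    "standard_errors",
    "identifiability_check",
]

BOUNDARY_TOL = 1e-4  # estimates closer than this to 0/1 are flagged
_PROB_FLOOR = 1e-12  # floor inside the objective, avoids log(0) in line search


class EstimationError(Exception):
    """Raised for invalid data, non-convergence or degenerate statistics."""


@dataclass(frozen=True)
class FrequencyTable:
    """Observed category counts aligned to a model's category order.

    ``counts`` maps every category of the model to a nonnegative integer;
    ``tree_totals`` gives the (positive) number of observations per tree.
    """

    counts: tuple[tuple[str, int], ...]
    tree_totals: tuple[tuple[str, int], ...]

    @classmethod
    def from_counts(cls, model: MptModel, counts: Mapping[str, int]) -> "FrequencyTable":
        missing = set(model.category_order) - set(counts)
        if missing:
            raise EstimationError(f"counts missing for categories {sorted(missing)}")
        extra = set(counts) - set(model.category_order)
        if extra:
            raise EstimationError(f"counts for unknown categories {sorted(extra)}")
        clean: dict[str, int] = {}
        for cat in model.category_order:
            value = counts[cat]
            if value < 0 or int(value) != value:
                raise EstimationError(
                    f"count for {cat!r} must be a nonnegative integer, got {value}"
                )
            clean[cat] = int(value)
        totals: dict[str, int] = {}
        for tree in model.trees:
            total = sum(clean[c] for c in tree.categories)
            if total <= 0:
                raise EstimationError(f"tree {tree.name!r} has zero total count")
            totals[tree.name] = total
        return cls(tuple(clean.items()), tuple(totals.items()))

    @property
    def count_map(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def total_map(self) -> dict[str, int]:
        return dict(self.tree_totals)

    @property
    def n_total(self) -> int:
        return sum(n for _, n in self.tree_totals)

    def vector(self, order: Sequence[str]) -> np.ndarray:
        counts = self.count_map
        return np.array([counts[c] for c in order], dtype=float)

    def to_frame(self, model: MptModel) -> pd.DataFrame:
        counts = self.count_map
        rows = [
            {"tree": model.tree_of_category(cat), "category": cat, "count": counts[cat]}
            for cat in model.category_order
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path, model: MptModel) -> None:
        self.to_frame(model).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model: MptModel) -> "FrequencyTable":
        frame = pd.read_csv(path)
        required = {"tree", "category", "count"}
        if not required <= set(frame.columns):
            raise EstimationError(
                f"frequency CSV needs columns {sorted(required)}, "
                f"got {list(frame.columns)}"
            )
        counts = dict(zip(frame["category"], frame["count"]))
        table = cls.from_counts(model, counts)
        for _, row in frame.iterrows():
            if model.tree_of_category(row["category"]) != row["tree"]:
                raise EstimationError(
                    f"category {row['category']!r} listed under tree "
                    f"{row['tree']!r} but belongs to "
                    f"{model.tree_of_category(row['category'])!r}"
                )
        return table


@dataclass(frozen=True)
class FitResult:
    """Result of a constrained maximum-likelihood fit."""

    estimates: tuple[tuple[str, float], ...]
    standard_errors: tuple[tuple[str, float], ...]
    g_squared: float
    df: int
    p_value: float
    log_likelihood: float
    n_starts_converged: int
    at_boundary: frozenset[str]
    free_parameters: tuple[str, ...]
    model: MptModel = field(repr=False)
    constraints: ConstraintSet = field(repr=False)
    data: FrequencyTable = field(repr=False)

    @property
    def estimate_map(self) -> dict[str, float]:
        return dict(self.estimates)

    @property
    def se_map(self) -> dict[str, float]:
        return dict(self.standard_errors)

    def to_dict(self) -> dict:
        return {
            "estimates": {k: v for k, v in self.estimates},
            "standard_errors": {
                k: (None if np.isnan(v) else v) for k, v in self.standard_errors
            },
            "g_squared": self.g_squared,
            "df": self.df,
            "p_value": self.p_value,
            "log_likelihood": self.log_likelihood,
            "n_starts_converged": self.n_starts_converged,
            "at_boundary": sorted(self.at_boundary),
            "free_parameters": list(self.free_parameters),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def g_squared(observed: np.ndarray, expected: np.ndarray) -> float:
    """Likelihood-ratio statistic 2·Σ obs·ln(obs/exp), with 0·ln(0/e) ≡ 0.

    ``observed`` and ``expected`` are matched count vectors; expected tree
    totals must equal observed tree totals for the statistic to be a valid
    goodness-of-fit measure (the caller guarantees this).
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise EstimationError("observed and expected must have the same shape")
    pos = observed > 0
    if np.any(expected[pos] <= 0):
        raise EstimationError(
            "infinite statistic: observed count positive where expected is zero"
        )
    stat = 2.0 * float(np.sum(observed[pos] * np.log(observed[pos] / expected[pos])))
    if stat < -1e-8:
        raise EstimationError(f"negative G² beyond tolerance: {stat}")
    return max(stat, 0.0)


class _CompiledModel:
    """Index-based branch structure for fast probability/Jacobian evaluation."""

    def __init__(self, model: MptModel):
        self.model = model
        self.param_index = {name: i for i, name in enumerate(model.parameters)}
        self.cat_index = {cat: i for i, cat in enumerate(model.category_order)}
        self.n_params = len(model.parameters)
        self.n_cats = len(model.category_order)
        # branch -> (category index, [(param index, complement), ...])
        self.branches: list[tuple[int, list[tuple[int, bool]]]] = []
        for tree in model.trees:
            for branch in tree.branches:
                factors = [
                    (self.param_index[name], comp) for name, comp in branch.factors
                ]
                self.branches.append((self.cat_index[branch.category], factors))
        # per-category tree total lookup indices
        self.cat_tree = np.array(
            [
                [t.name for t in model.trees].index(model.tree_of_category(cat))
                for cat in model.category_order
            ]
        )

    def probabilities(self, theta: np.ndarray) -> np.ndarray:
        p = np.zeros(self.n_cats)
        for cat, factors in self.branches:
            prob = 1.0
            for j, comp in factors:
                prob *= (1.0 - theta[j]) if comp else theta[j]
            p[cat] += prob
        return p

    def probabilities_and_jacobian(
        self, theta: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Category probabilities and their Jacobian w.r.t. all parameters."""
        p = np.zeros(self.n_cats)
        J = np.zeros((self.n_cats, self.n_params))
        for cat, factors in self.branches:
            values = [
                (1.0 - theta[j]) if comp else theta[j] for j, comp in factors
            ]
            prob = 1.0
            for v in values:
                prob *= v
            p[cat] += prob
            for k, (j, comp) in enumerate(factors):
                partial = 1.0
                for m, v in enumerate(values):
                    if m != k:
                        partial *= v
                J[cat, j] += -partial if comp else partial
        return p, J


def _tree_total_vector(model: MptModel, data: FrequencyTable) -> np.ndarray:
    totals = data.total_map
    return np.array(
        [totals[model.tree_of_category(cat)] for cat in model.category_order],
        dtype=float,
    )


def _saturated_log_likelihood(obs: np.ndarray, totals: np.ndarray) -> float:
    pos = obs > 0
    return float(np.sum(obs[pos] * np.log(obs[pos] / totals[pos])))


def fit(
    model: MptModel,
    constraints: ConstraintSet,
    data: FrequencyTable,
    *,
    starts: int = 20,
    seed: int = 1,
    tolerance: float = 1e-10,
    compute_se: bool = True,
) -> FitResult:
    """Fit an MPT model to observed frequencies by maximum likelihood.

    The best of ``starts`` quasi-Newton runs (logit-parameterized, analytic
    gradients, starting points uniform on (0.1, 0.9) from ``seed``) is
    returned.  Deterministic given (data, seed).
    """
    df = model_degrees_of_freedom(model, constraints)
    compiled = _CompiledModel(model)
    A, c, free_names = constraints.affine_map(model)
    k = len(free_names)
    obs = data.vector(model.category_order)
    totals = _tree_total_vector(model, data)
    ll_sat = _saturated_log_likelihood(obs, totals)

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        free = special.expit(x)
        theta = A @ free + c
        p, J_theta = compiled.probabilities_and_jacobian(theta)
        p = np.maximum(p, _PROB_FLOOR)
        nll = -float(np.sum(obs * np.log(p)))
        # chain: d nll / dx = -(obs/p) @ J_theta @ A * sigmoid'(x)
        grad_free = -(obs / p) @ J_theta @ A
        grad = grad_free * free * (1.0 - free)
        return nll, grad

    def nll_of_free(free: np.ndarray) -> float:
        theta = A @ free + c
        p = np.maximum(compiled.probabilities(theta), _PROB_FLOOR)
        return -float(np.sum(obs * np.log(p)))

    def fisher_polish(free: np.ndarray, nll: float) -> tuple[np.ndarray, float]:
        """Fisher-scoring refinement: quadratic convergence near the optimum,
        needed for saturated models to reach G² ≈ 0 at machine precision."""
        for _ in range(100):
            theta = A @ free + c
            p, J_theta = compiled.probabilities_and_jacobian(theta)
            p = np.maximum(p, _PROB_FLOOR)
            J = J_theta @ A
            grad = -(J.T @ (obs / p))
            info = (J.T * (totals / p)) @ J
            try:
                step = np.linalg.solve(info, -grad)
            except np.linalg.LinAlgError:
                break
            scale = 1.0
            improved = False
            for _ in range(30):
                candidate = np.clip(free + scale * step, 1e-12, 1.0 - 1e-12)
                candidate_nll = nll_of_free(candidate)
                if candidate_nll <= nll + 1e-12:
                    improved = True
                    break
                scale *= 0.5
            if not improved:
                break
            moved = float(np.max(np.abs(candidate - free)))
            free, nll = candidate, candidate_nll
            if moved < 1e-13:
                break
        return free, nll

    rng = np.random.default_rng(seed)
    best: optimize.OptimizeResult | None = None
    n_converged = 0
    if k == 0:
        # fully constrained model: nothing to optimize
        x_best = np.zeros(0)
        nll_best, _ = objective(x_best)
        n_converged = starts
    else:
        for s in range(starts):
            start_probs = rng.uniform(0.1, 0.9, size=k) if s > 0 else np.full(k, 0.5)
            x0 = special.logit(start_probs)
            res = optimize.minimize(
                objective,
                x0,
                jac=True,
                method="L-BFGS-B",
                options={"ftol": tolerance, "gtol": 1e-9, "maxiter": 2000},
            )
            if res.success:
                n_converged += 1
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise EstimationError(
                f"no start converged in {starts} attempts (seed {seed}); "
                "check model identifiability and data validity"
            )
        x_best, nll_best = best.x, float(best.fun)

    free_hat = special.expit(x_best)
    if k > 0:
        free_hat, nll_best = fisher_polish(free_hat, nll_best)
    theta_hat = A @ free_hat + c
    p_hat = compiled.probabilities(theta_hat)
    expected = p_hat * totals
    ll_hat = -nll_best
    g2 = 2.0 * (ll_sat - ll_hat)
    if g2 < -1e-8:
        raise EstimationError(f"negative fitted G² beyond tolerance: {g2}")
    g2 = max(g2, 0.0)
    p_value = float(stats.chi2.sf(g2, df)) if df > 0 else 1.0

    estimates = dict(zip(model.parameters, theta_hat.tolist()))
    at_boundary = frozenset(
        name
        for name in free_names
        if estimates[name] < BOUNDARY_TOL or estimates[name] > 1.0 - BOUNDARY_TOL
    )
    if compute_se:
        ses = standard_errors(model, constraints, estimates, data)
    else:
        ses = {name: float("nan") for name in model.parameters}

    return FitResult(
        estimates=tuple(estimates.items()),
        standard_errors=tuple(ses.items()),
        g_squared=g2,
        df=df,
        p_value=p_value,
        log_likelihood=ll_hat,
        n_starts_converged=n_converged,
        at_boundary=at_boundary,
        free_parameters=free_names,
        model=model,
        constraints=constraints,
        data=data,
    )


def standard_errors(
    model: MptModel,
    constraints: ConstraintSet,
    estimates: Mapping[str, float],
    data: FrequencyTable,
) -> dict[str, float]:
    """Standard errors on the probability scale for all model parameters.

    Square roots of the diagonal of ``A Σ Aᵀ`` where Σ is the inverse
    expected Fisher information of the product-multinomial likelihood in
    the free parameters and A the affine constraint map.  Parameters whose
    free representative sits at the 0/1 boundary get NaN rather than a
    value from a (near-)singular information matrix.
    """
    compiled = _CompiledModel(model)
    A, c, free_names = constraints.affine_map(model)
    theta = np.array([estimates[name] for name in model.parameters])
    free_hat = np.linalg.lstsq(A, theta - c, rcond=None)[0] if len(free_names) else np.zeros(0)
    totals = _tree_total_vector(model, data)
    if len(free_names) == 0:
        return {name: float("nan") for name in model.parameters}

    p, J_theta = compiled.probabilities_and_jacobian(theta)
    J = J_theta @ A  # d p / d free
    interior = (free_hat > BOUNDARY_TOL) & (free_hat < 1.0 - BOUNDARY_TOL)
    # expected information: sum over categories of N_tree / p * outer(Jc, Jc)
    info = np.zeros((len(free_names), len(free_names)))
    safe_p = np.maximum(p, _PROB_FLOOR)
    for cat_idx in range(compiled.n_cats):
        info += totals[cat_idx] / safe_p[cat_idx] * np.outer(J[cat_idx], J[cat_idx])
    # the multinomial constraint removes one df per tree but the expected
    # information in free parameters is already correct because the
    # probabilities within each tree sum to one identically in theta.
    sub = info[np.ix_(interior, interior)]
    cov = np.full_like(info, np.nan)
    if sub.size:
        cond = np.linalg.cond(sub)
        if not np.isfinite(cond) or cond > 1e12:
            eigvals, eigvecs = np.linalg.eigh(sub)
            null_dir = eigvecs[:, 0]
            names = [n for n, keep in zip(free_names, interior) if keep]
            warnings.warn(
                "singular expected information matrix; weakest direction "
                + ", ".join(
                    f"{w:+.3f}·{n}" for w, n in zip(null_dir, names)
                ),
                stacklevel=2,
            )
            cov_sub = np.linalg.pinv(sub)
        else:
            cov_sub = np.linalg.inv(sub)
        cov[np.ix_(interior, interior)] = cov_sub
    cov = np.where(np.isnan(cov), 0.0, cov)
    full_cov = A @ cov @ A.T
    se = np.sqrt(np.maximum(np.diag(full_cov), 0.0))
    result: dict[str, float] = {}
    for i, name in enumerate(model.parameters):
        # parameters that depend only on fixed constants have zero variance;
        # those tied to a boundary estimate are not reported
        row = A[i]
        depends_on_boundary = any(
            abs(row[j]) > 0 and not interior[j] for j in range(len(free_names))
        )
        if depends_on_boundary:
            result[name] = float("nan")
        else:
            result[name] = float(se[i])
    return result


@dataclass(frozen=True)
class RankReport:
    """Numerical identifiability diagnostics for a constrained model."""

    n_free: int
    min_rank: int
    ranks: tuple[int, ...]

    @property
    def identified(self) -> bool:
        return self.min_rank == self.n_free


def identifiability_check(
    model: MptModel,
    constraints: ConstraintSet,
    probe_points: int = 10,
    seed: int = 0,
) -> RankReport:
    """Check local identifiability by the rank of the probability Jacobian.

    Evaluates the Jacobian of all category probabilities with respect to
    the free parameters at ``probe_points`` random interior points and
    reports the minimum rank; the model is locally identified when that
    rank equals the number of free parameters.
    """
    compiled = _CompiledModel(model)
    A, c, free_names = constraints.affine_map(model)
    rng = np.random.default_rng(seed)
    ranks: list[int] = []
    for _ in range(probe_points):
        free = rng.uniform(0.2, 0.8, size=len(free_names))
        theta = A @ free + c
        _, J_theta = compiled.probabilities_and_jacobian(theta)
        J = J_theta @ A
        ranks.append(int(np.linalg.matrix_rank(J, tol=1e-9)))
    return RankReport(
        n_free=len(free_names), min_rank=min(ranks) if ranks else 0, ranks=tuple(ranks)
    )
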