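"""Regression solvers for the per-node MRA systems.

Treating each node's steady-state responses as a homogeneous multilinear
regression turns MRA into N independent regressions with N-1 candidate
predictors each.  Any number of replicates or extra perturbations just
adds rows, and the regression machinery supplies residual variance and
confidence intervals.  Implemented fitters:

* ``lse``       plain least squares with t-based 95% CIs,
* ``lse_ci``    least squares, then eliminate coefficients whose CI
                contains 0,
* ``tlr``       threshold linear regression: least squares, then zero
                coefficients below the 25th-percentile magnitude pooled
                over the whole network,
* ``lasso``     L1-penalised fit with a per-node cross-validated penalty,
* ``step_fo``, ``step_ba``, ``step_bo``
                greedy forward / backward / stepwise subset selection
                under an information criterion (AIC by default),

plus the classical-MRA bootstrap (resample replicates, percentile CIs).
All fits are intercept-free: the MRA regression system is homogeneous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import GroupKFold

from .core import (
    ConnectivityMatrix,
    GlobalResponseMatrix,
    RegressionSystem,
    build_regression_system,
    solve_mra_classical,
)

__all__ = [
    "FitResult",
    "BootstrapResult",
    "fit_lse",
    "fit_lse_ci",
    "fit_tlr",
    "tlr_threshold",
    "fit_lasso",
    "fit_step",
    "fit_network",
    "bootstrap_mra",
    "REGRESSION_METHODS",
]


@dataclass
class FitResult:
    """Per-node regression outcome.

    ``coefficients`` are the post-selection values (exact zeros for
    eliminated sources), ``raw_coefficients`` the pre-selection least
    squares / LASSO estimates used e.g. as ROC scores.  Arrays align
    with ``column_index`` (source-node indices).
    """

    node: int
    column_index: list[int]
    coefficients: np.ndarray
    raw_coefficients: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    residual_variance: float = np.nan
    dof: int = 0
    selected: set[int] = field(default_factory=set)
    penalty: float | None = None

    def coef_map(self) -> dict[int, float]:
        return dict(zip(self.column_index, self.coefficients.tolist()))


def _check_rank(X: np.ndarray) -> None:
    if X.shape[0] < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"under-determined system: {X.shape[0]} rows < {X.shape[1]} columns"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank} < {X.shape[1]}): collinear predictor columns"
        )


def fit_lse(system: RegressionSystem, ci_level: float = 0.95) -> FitResult:
    """Homogeneous least squares with t-distribution confidence intervals.

    Residual variance is RSS/dof with dof = rows - columns.  A square
    system (dof 0) returns the exact solution with no CIs and a warning.
    """
    X, y = system.design_matrix, system.response
    _check_rank(X)
    n, p = X.shape
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    dof = n - p
    if dof <= 0:
        warnings.warn(
            f"node {system.node}: square system, point estimate only (no CIs)",
            stacklevel=2,
        )
        return FitResult(
            system.node, list(system.column_index), beta, beta.copy(),
            residual_variance=np.nan, dof=0, selected=set(system.column_index),
        )
    s2 = rss / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * np.diag(XtX_inv))
    tcrit = scipy.stats.t.ppf(0.5 + ci_level / 2.0, dof)
    return FitResult(
        system.node, list(system.column_index), beta, beta.copy(),
        ci_low=beta - tcrit * se, ci_high=beta + tcrit * se,
        residual_variance=s2, dof=dof, selected=set(system.column_index),
    )


def fit_lse_ci(system: RegressionSystem, ci_level: float = 0.95) -> FitResult:
    """Least squares, then eliminate coefficients whose CI includes 0."""
    fit = fit_lse(system, ci_level=ci_level)
    if fit.ci_low is None:
        raise ValueError(
            f"node {system.node}: CI-based elimination needs dof >= 1 "
            "(add replicates or perturbations)"
        )
    keep = (fit.ci_low > 0) | (fit.ci_high < 0)
    fit.coefficients = np.where(keep, fit.coefficients, 0.0)
    fit.selected = {j for j, k in zip(fit.column_index, keep) if k}
    return fit


def tlr_threshold(all_coefficients, q: float = 25.0, pool: str = "absolute") -> float:
    """Network-wide TLR threshold: the ``q``-th percentile of the pooled
    estimates (absolute values by default), linear-interpolation
    percentile convention."""
    pooled = np.concatenate([np.ravel(c) for c in all_coefficients])
    if pool == "absolute":
        pooled = np.abs(pooled)
    elif pool != "signed":
        raise ValueError("pool must be 'absolute' or 'signed'")
    return float(np.percentile(pooled, q))


def fit_tlr(system: RegressionSystem, threshold: float, ci_level: float = 0.95) -> FitResult:
    """Least squares, then zero coefficients with magnitude strictly below
    ``threshold``.

    The threshold is a network-level quantity (25th percentile of all
    nodes' pooled estimates, see :func:`tlr_threshold`); network-wide
    fitting computes it automatically.
    """
    fit = fit_lse(system, ci_level=ci_level)
    keep = np.abs(fit.coefficients) >= threshold
    fit.coefficients = np.where(keep, fit.coefficients, 0.0)
    fit.selected = {j for j, k in zip(fit.column_index, keep) if k}
    return fit


def _cv_splits(system: RegressionSystem, design, cv_folds: int):
    """Row folds grouped by experiment so replicates stay together."""
    key_ids: dict[tuple, int] = {}
    groups = np.array(
        [
            key_ids.setdefault(
                (int(design.targets[k]), float(design.intensities[k])), len(key_ids)
            )
            for k in system.row_index
        ]
    )
    n_groups = len(key_ids)
    folds = min(cv_folds, n_groups)
    if folds < cv_folds:
        warnings.warn(
            f"node {system.node}: only {n_groups} experiments, reducing CV to "
            f"{folds} folds", stacklevel=3,
        )
    if folds < 2:
        raise ValueError(
            f"node {system.node}: cross-validation needs >= 2 experiments"
        )
    gkf = GroupKFold(n_splits=folds)
    return list(gkf.split(system.design_matrix, system.response, groups))


def fit_lasso(
    system: RegressionSystem,
    design=None,
    cv_folds: int = 5,
    lambda_grid=None,
    seed: int | None = None,
    max_iter: int = 10_000,
) -> FitResult:
    """L1-penalised homogeneous regression with per-node cross-validated
    penalty.

    The penalty weight is chosen per node as the minimiser of the mean
    CV squared error over a log-spaced grid down to 1e-4 of the largest
    useful penalty; the final fit uses all rows at that penalty.  Folds
    group rows by experiment so replicates of one perturbation stay
    together.  Exact zeros count as unselected.
    """
    X, y = system.design_matrix, system.response
    if np.allclose(y, 0.0):
        z = np.zeros(X.shape[1])
        return FitResult(
            system.node, list(system.column_index), z, z.copy(),
            dof=X.shape[0] - 0, selected=set(),
            penalty=float(np.max(lambda_grid)) if lambda_grid is not None else None,
        )
    if design is not None:
        cv = _cv_splits(system, design, cv_folds)
    else:
        cv = min(cv_folds, X.shape[0])
    lcv = LassoCV(
        alphas=50 if lambda_grid is None else lambda_grid, eps=1e-4,
        fit_intercept=False, cv=cv, max_iter=max_iter, random_state=seed,
        precompute=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter at tiny penalties
        lcv.fit(X, y)
        final = Lasso(alpha=lcv.alpha_, fit_intercept=False, max_iter=max_iter,
                      precompute=True)
        final.fit(X, y)
    beta = final.coef_.copy()
    selected = {j for j, b in zip(system.column_index, beta) if b != 0.0}
    rss = float(np.sum((y - X @ beta) ** 2))
    dof = max(X.shape[0] - len(selected), 1)
    return FitResult(
        system.node, list(system.column_index), beta, beta.copy(),
        residual_variance=rss / dof, dof=X.shape[0] - len(selected),
        selected=selected, penalty=float(lcv.alpha_),
    )


# ---------------------------------------------------------------------------
# stepwise subset selection


def _subset_rss(G, c, yty, subset):
    if not subset:
        return yty, np.empty(0)
    idx = np.array(subset)
    b = np.linalg.solve(G[np.ix_(idx, idx)], c[idx])
    return max(yty - float(c[idx] @ b), 0.0), b


def _ic(rss, n, k, criterion):
    rss = max(rss, 1e-300)
    if criterion == "aic":
        return n * np.log(rss / n) + 2 * k
    if criterion == "bic":
        return n * np.log(rss / n) + np.log(n) * k
    raise ValueError("criterion must be 'aic' or 'bic'")


def fit_step(
    system: RegressionSystem,
    direction: str = "forward",
    criterion: str = "aic",
    ci_level: float = 0.95,
    max_steps: int | None = None,
) -> FitResult:
    """Greedy subset selection minimising an information criterion.

    ``forward`` adds the predictor giving the best criterion improvement,
    ``backward`` starts from the full model and drops, ``both``
    alternates additions with drop sweeps.  The final subset is refit by
    plain least squares (with CIs when dof allows); unselected
    coefficients are exact zeros.  Computations run on the Gram matrix,
    so each candidate evaluation is a small dense solve.
    """
    X, y = system.design_matrix, system.response
    n, p = X.shape
    if direction not in ("forward", "backward", "both"):
        raise ValueError("direction must be forward, backward or both")
    if direction == "backward":
        _check_rank(X)
        if n <= p:
            raise np.linalg.LinAlgError(
                "backward selection needs strictly more rows than columns"
            )
    G, c, yty = X.T @ X, X.T @ y, float(y @ y)
    max_steps = max_steps or p
    subset: list[int] = list(range(p)) if direction == "backward" else []
    rss, _ = _subset_rss(G, c, yty, subset)
    score = _ic(rss, n, len(subset), criterion)

    def try_moves(adding: bool):
        nonlocal subset, rss, score
        pool = [j for j in range(p) if (j not in subset) == adding]
        best = None
        for j in pool:
            cand = subset + [j] if adding else [i for i in subset if i != j]
            if adding and len(cand) > n:
                continue
            r, _ = _subset_rss(G, c, yty, cand)
            s = _ic(r, n, len(cand), criterion)
            if s < score - 1e-10 and (best is None or s < best[0]):
                best = (s, cand, r)
        if best is None:
            return False
        score, subset, rss = best[0], best[1], best[2]
        return True

    if direction == "forward":
        for _ in range(max_steps):
            if not try_moves(adding=True):
                break
    elif direction == "backward":
        for _ in range(p):
            if not try_moves(adding=False):
                break
    else:  # both
        for _ in range(2 * max_steps):
            added = try_moves(adding=True)
            while try_moves(adding=False):
                pass
            if not added:
                break

    beta = np.zeros(p)
    raw = np.zeros(p)
    ci_low = ci_high = None
    s2 = np.nan
    dof = n - len(subset)
    if subset:
        idx = sorted(subset)
        sub = RegressionSystem(
            system.node, X[:, idx], y,
            [system.column_index[i] for i in idx], list(system.row_index),
        )
        subfit = fit_lse(sub, ci_level=ci_level)
        beta[idx] = subfit.coefficients
        raw[idx] = subfit.coefficients
        s2, dof = subfit.residual_variance, subfit.dof
        if subfit.ci_low is not None:
            ci_low = np.zeros(p)
            ci_high = np.zeros(p)
            ci_low[idx] = subfit.ci_low
            ci_high[idx] = subfit.ci_high
    return FitResult(
        system.node, list(system.column_index), beta, raw,
        ci_low=ci_low, ci_high=ci_high, residual_variance=s2, dof=dof,
        selected={system.column_index[i] for i in subset},
    )


# ---------------------------------------------------------------------------
# network-level fitting

REGRESSION_METHODS = ("lse", "lse_ci", "tlr", "lasso", "step_fo", "step_ba", "step_bo")

_STEP_DIRECTIONS = {"step_fo": "forward", "step_ba": "backward", "step_bo": "both"}


def fit_network(
    R: GlobalResponseMatrix,
    method: str = "lse",
    prior_null: dict[int, set[int]] | None = None,
    ci_level: float = 0.95,
    seed: int | None = None,
    tlr_percentile: float = 25.0,
    tlr_pool: str = "absolute",
    step_criterion: str = "aic",
    cv_folds: int = 5,
    lambda_grid=None,
) -> tuple[ConnectivityMatrix, dict[int, FitResult]]:
    """Fit all N per-node regressions and assemble the connectivity matrix.

    ``prior_null`` maps node index -> set of source indices known to be
    null; their columns are removed from that node's system (one degree
    of freedom gained per removed column) and the corresponding entries
    are exact zeros in the output.  Per-node failures are collected; the
    whole fit only fails when more than half the nodes do.
    """
    if method not in REGRESSION_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {REGRESSION_METHODS}")
    prior_null = prior_null or {}
    n = R.n_nodes
    systems = {
        i: build_regression_system(R, i, prior_null.get(i)) for i in range(n)
    }

    def _fit_one(system):
        if method == "lse":
            return fit_lse(system, ci_level)
        if method == "lse_ci":
            return fit_lse_ci(system, ci_level)
        if method == "lasso":
            return fit_lasso(system, R.design, cv_folds, lambda_grid, seed)
        if method in _STEP_DIRECTIONS:
            return fit_step(system, _STEP_DIRECTIONS[method], step_criterion, ci_level)
        raise AssertionError(method)

    results: dict[int, FitResult] = {}
    errors: dict[int, Exception] = {}
    if method == "tlr":
        lse_fits = {}
        for i, system in systems.items():
            try:
                lse_fits[i] = fit_lse(system, ci_level)
            except Exception as exc:  # noqa: BLE001 - per-node failures are data
                errors[i] = exc
        th = tlr_threshold(
            [f.coefficients for f in lse_fits.values()], tlr_percentile, tlr_pool
        )
        for i, fit in lse_fits.items():
            keep = np.abs(fit.coefficients) >= th
            fit.coefficients = np.where(keep, fit.coefficients, 0.0)
            fit.selected = {j for j, k in zip(fit.column_index, keep) if k}
            results[i] = fit
    else:
        for i, system in systems.items():
            try:
                results[i] = _fit_one(system)
            except Exception as exc:  # noqa: BLE001
                errors[i] = exc
    if len(errors) > n / 2:
        raise RuntimeError(
            f"{len(errors)}/{n} per-node fits failed; first error: "
            f"{next(iter(errors.values()))}"
        )
    values = np.zeros((n, n))
    np.fill_diagonal(values, -1.0)
    for i, fit in results.items():
        for j, b in zip(fit.column_index, fit.coefficients):
            values[i, j] = b
    r = ConnectivityMatrix(values, list(R.node_names))
    return r, results


@dataclass
class BootstrapResult:
    """Classical-MRA bootstrap output: point estimate after CI-based
    selection, percentile CI bounds, and resampling diagnostics."""

    connectivity: ConnectivityMatrix
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    n_discarded: int


def bootstrap_mra(
    R: GlobalResponseMatrix,
    n_boot: int = 100,
    seed: int | None = None,
    ci_level: float = 0.95,
    cond_max: float = 1e8,
) -> BootstrapResult:
    """Percentile bootstrap around the classical MRA solution.

    Each repetition resamples replicate columns with replacement within
    every perturbation experiment, averages them into a square response
    matrix, and applies the classical solution.  Entry-wise CIs are the
    2.5th/97.5th percentiles (at the default 95% level); entries whose
    CI includes 0 are set to 0 in the point estimate (computed on the
    replicate means).  Singular resamples are discarded and redrawn,
    with a warning when more than 20% had to be dropped.
    """
    design = R.design
    groups: dict[tuple, list[int]] = {}
    for k in range(design.n_experiments):
        groups.setdefault(
            (int(design.targets[k]), float(design.intensities[k])), []
        ).append(k)
    if len(groups) != R.n_nodes or {t for t, _ in groups} != set(range(R.n_nodes)):
        raise ValueError("bootstrap needs a square design: one experiment per node")
    if min(len(v) for v in groups.values()) < 2:
        raise ValueError("bootstrap needs >= 2 replicates per experiment")
    order = [groups[key] for key in sorted(groups, key=lambda key: key[0])]
    rng = np.random.default_rng(seed)

    point = solve_mra_classical(R.replicate_mean(), cond_max=cond_max)
    draws = np.empty((n_boot, R.n_nodes, R.n_nodes))
    discarded = 0
    b = 0
    while b < n_boot:
        cols = np.column_stack(
            [
                R.values[:, rng.choice(idx, size=len(idx), replace=True)].mean(axis=1)
                for idx in order
            ]
        )
        try:
            draws[b] = solve_mra_classical(cols, cond_max=cond_max).values
            b += 1
        except np.linalg.LinAlgError:
            discarded += 1
            if discarded > 50 * n_boot:
                raise RuntimeError("bootstrap: too many singular resamples")
    if discarded > 0.2 * n_boot:
        warnings.warn(
            f"bootstrap discarded {discarded} singular resamples "
            f"({100 * discarded / (n_boot + discarded):.0f}%)", stacklevel=2,
        )
    alpha = 1.0 - ci_level
    ci_low = np.percentile(draws, 100 * alpha / 2, axis=0)
    ci_high = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
    values = point.values.copy()
    spans_zero = (ci_low <= 0) & (ci_high >= 0)
    np.fill_diagonal(spans_zero, False)
    values[spans_zero] = 0.0
    return BootstrapResult(
        ConnectivityMatrix(values, list(R.node_names)),
        ci_low, ci_high, n_boot, discarded,
    )
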