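"""Core modular response analysis (MRA) formalism.

MRA infers the signed, normalised influence of network module *j* on
module *i* (the connectivity coefficient ``r_ij``) from the global
responses of all modules to systematic perturbations, measured at steady
state.  This module holds the domain containers (connectivity matrix,
global response matrix, perturbation design, per-node regression system)
and the operations that are pure linear algebra:

* the mid-point relative change used to build the response matrix,
* the classical square-system solution ``r = -diag(R^-1)^-1 R^-1``,
* the exact forward map from a known network to its response matrix,
* assembly of the per-node homogeneous regression systems,
* the exact squared error between two connectivity matrices.

Conventions: diagonal of any connectivity matrix is -1; ``r[i, j]`` is
the influence of node ``j`` on node ``i``; response matrix rows are
responding nodes and columns are perturbation experiments.  All public
labels are node names or 1-based indices, internal arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "GlobalResponseMatrix",
    "PerturbationDesign",
    "RegressionSystem",
    "IllConditionedError",
    "UnderDeterminedError",
    "relative_change",
    "diagonal_response",
    "solve_mra_classical",
    "forward_response",
    "build_regression_system",
    "exact_squared_error",
]


class IllConditionedError(np.linalg.LinAlgError):
    """Raised when a response matrix is too ill-conditioned to invert safely."""


class UnderDeterminedError(ValueError):
    """Raised when a regression system has more unknowns than equations."""


def _default_names(n: int, prefix: str = "node") -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


@dataclass
class ConnectivityMatrix:
    """Square matrix of connectivity coefficients with a -1 diagonal.

    Parameters
    ----------
    values
        N x N real matrix; ``values[i, j]`` is the influence of node j on
        node i.  The diagonal must be exactly -1.
    node_names
        Optional labels, defaults to ``node1..nodeN``.
    exact
        True when the matrix holds exact (ground-truth) coefficients,
        False for estimates.
    """

    values: np.ndarray
    node_names: list[str] | None = None
    exact: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.values.shape[0] < 2:
            raise ValueError("connectivity matrix needs at least 2 nodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity matrix entries must be finite")
        if not np.all(np.diag(self.values) == -1.0):
            raise ValueError("connectivity diagonal must be exactly -1")
        if self.node_names is None:
            self.node_names = _default_names(self.n_nodes)
        elif len(self.node_names) != self.n_nodes:
            raise ValueError("node_names length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def off_diagonal_mask(self) -> np.ndarray:
        return ~np.eye(self.n_nodes, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_names, columns=self.node_names)

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(self.values.copy(), list(self.node_names), self.exact)


@dataclass
class PerturbationDesign:
    """Maps each experiment column of a response matrix to its perturbation.

    One row per experiment: the targeted node (0-based internally), the
    signed perturbation fraction (-1.0 for a full KO, -0.5 for a -50% KD)
    and a replicate identifier.
    """

    targets: np.ndarray
    intensities: np.ndarray
    replicates: np.ndarray | None = None
    experiment_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.replicates is None:
            self.replicates = np.zeros(self.n_experiments, dtype=int)
        self.replicates = np.asarray(self.replicates, dtype=int)
        if not (len(self.intensities) == len(self.replicates) == self.n_experiments):
            raise ValueError("design columns have inconsistent lengths")
        if np.any(self.intensities == 0.0):
            raise ValueError("perturbation intensity must be nonzero")
        if np.any(self.intensities < -1.0):
            raise ValueError("perturbation intensity must be >= -1 (full knockout)")
        if np.any(self.targets < 0):
            raise ValueError("negative target index")
        if self.experiment_names is None:
            self.experiment_names = [
                f"q{t + 1}" + (f".r{r + 1}" if len(set(self.replicates)) > 1 else "")
                for t, r in zip(self.targets, self.replicates)
            ]

    @property
    def n_experiments(self) -> int:
        return len(self.targets)

    @classmethod
    def one_per_node(
        cls, n_nodes: int, intensity: float = -1.0, replicates: int = 1
    ) -> "PerturbationDesign":
        """Classical design: each node targeted once (per replicate)."""
        targets = np.tile(np.arange(n_nodes), replicates)
        reps = np.repeat(np.arange(replicates), n_nodes)
        return cls(targets, np.full(n_nodes * replicates, intensity), reps)

    def to_frame(self, node_names: list[str] | None = None) -> pd.DataFrame:
        names = node_names or _default_names(int(self.targets.max()) + 1)
        return pd.DataFrame(
            {
                "experiment": self.experiment_names,
                "target_node": [names[t] for t in self.targets],
                "intensity": self.intensities,
                "replicate": self.replicates + 1,
            }
        )


@dataclass
class GlobalResponseMatrix:
    """Measured mid-point relative changes, nodes x experiments.

    ``values[i, k]`` is the relative change of node i's steady-state
    level under perturbation experiment k, computed with the mid-point
    denominator (see :func:`relative_change`), hence each entry lies in
    (-2, 2] with -2 reached only for a full knockout.
    """

    values: np.ndarray
    design: PerturbationDesign
    node_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("response matrix must be 2-D")
        if self.values.shape[1] != self.design.n_experiments:
            raise ValueError("design rows must match response matrix columns")
        if np.any(self.design.targets >= self.n_nodes):
            raise ValueError("design targets a node outside the matrix")
        if self.node_names is None:
            self.node_names = _default_names(self.n_nodes)
        elif len(self.node_names) != self.n_nodes:
            raise ValueError("node_names length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.values.shape[1]

    def replicate_mean(self) -> "GlobalResponseMatrix":
        """Average replicate columns experiment-wise.

        Columns sharing (target, intensity) are averaged; the result has
        one column per distinct perturbation, replicate id 0.
        """
        keys = list(zip(self.design.targets, self.design.intensities))
        seen: dict[tuple, list[int]] = {}
        for k, key in enumerate(keys):
            seen.setdefault(key, []).append(k)
        cols = []
        targets, intens = [], []
        for (t, f), idx in seen.items():
            cols.append(self.values[:, idx].mean(axis=1))
            targets.append(t)
            intens.append(f)
        design = PerturbationDesign(np.array(targets), np.array(intens))
        return GlobalResponseMatrix(np.column_stack(cols), design, list(self.node_names))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.node_names, columns=self.design.experiment_names
        )


@dataclass
class RegressionSystem:
    """Homogeneous linear system for one node's connectivity coefficients.

    Rows are experiments not targeting the node, columns are the
    relative changes of the candidate source nodes.  No intercept: the
    response is an exact linear combination of the predictors in the
    noise-free linear regime.
    """

    node: int
    design_matrix: np.ndarray
    response: np.ndarray
    column_index: list[int] = field(default_factory=list)
    row_index: list[int] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.design_matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.design_matrix.shape[1]


def relative_change(basal: float, perturbed: float) -> float:
    """Mid-point relative change 2*(perturbed - basal)/(perturbed + basal).

    The mid-point denominator (rather than the basal level) keeps the
    change finite for full knockouts: a knockout to 0 gives exactly -2,
    a -50% knockdown gives -2/3.  Antisymmetric under swapping the two
    arguments and bounded in [-2, 2] for nonnegative levels.
    """
    basal = float(basal)
    perturbed = float(perturbed)
    if basal <= 0:
        raise ValueError(f"basal level must be positive, got {basal}")
    if perturbed < 0:
        raise ValueError(f"perturbed level must be nonnegative, got {perturbed}")
    return 2.0 * (perturbed - basal) / (perturbed + basal)


def diagonal_response(fraction: float) -> float:
    """Response-matrix diagonal entry for a perturbation by ``fraction``.

    A perturbation multiplying a node's level by (1 + fraction) yields a
    mid-point relative change of 2*fraction/(2 + fraction): -2 for a full
    KO (fraction -1), -2/3 for a -50% KD.
    """
    if fraction <= -1.0 and fraction != -1.0:
        raise ValueError("fraction must be >= -1")
    return 2.0 * fraction / (2.0 + fraction)


def _as_square_array(R, expected_order: bool = True) -> np.ndarray:
    if isinstance(R, GlobalResponseMatrix):
        if R.n_experiments != R.n_nodes:
            raise ValueError(
                f"classical MRA needs a square response matrix (one perturbation "
                f"per node); got {R.n_nodes} nodes x {R.n_experiments} experiments. "
                "Average replicates first or use the regression path."
            )
        order = np.argsort(R.design.targets)
        if not np.array_equal(np.sort(R.design.targets), np.arange(R.n_nodes)):
            raise ValueError("classical MRA needs each node targeted exactly once")
        return R.values[:, order]
    arr = np.asarray(R, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(
            f"classical MRA needs a square matrix, got shape {arr.shape}; "
            "use the regression path for non-square systems"
        )
    return arr


def solve_mra_classical(
    R, node_names: list[str] | None = None, cond_max: float = 1e8, snap: bool = True
) -> ConnectivityMatrix:
    """Classical MRA solution ``r = -diag(R^-1)^-1 R^-1``.

    Requires a square response matrix with column k holding the responses
    to the perturbation of node k (a :class:`GlobalResponseMatrix` is
    reordered automatically).  The diagonal of the result is -1 by
    construction; with ``snap`` it is set to exactly -1.

    Raises
    ------
    IllConditionedError
        If ``cond(R) > cond_max``; noise in R is amplified by the
        inversion, so near-singular systems are refused rather than
        silently returning garbage.
    """
    arr = _as_square_array(R)
    if isinstance(R, GlobalResponseMatrix) and node_names is None:
        node_names = list(R.node_names)
    cond = np.linalg.cond(arr)
    if not np.isfinite(cond) or cond > cond_max:
        raise IllConditionedError(
            f"response matrix condition number {cond:.3g} exceeds cap {cond_max:.3g}"
        )
    Rinv = np.linalg.inv(arr)
    d = np.diag(Rinv)
    if np.any(d == 0):
        raise IllConditionedError("diag(R^-1) has a zero entry")
    r = -(Rinv / d[:, None])
    if snap:
        np.fill_diagonal(r, -1.0)
    return ConnectivityMatrix(r, node_names)


def forward_response(
    r: ConnectivityMatrix | np.ndarray, diag_R
) -> np.ndarray:
    """Exact response matrix of a known network: R = r^-1 diag(r^-1)^-1 diag(R).

    ``diag_R`` holds the self-responses implied by the perturbation
    design (-2 for KO, -2/3 for -50% KD, see :func:`diagonal_response`).
    Inverse operation of :func:`solve_mra_classical` in the noise-free
    case.
    """
    values = r.values if isinstance(r, ConnectivityMatrix) else np.asarray(r, float)
    diag_R = np.asarray(diag_R, dtype=float)
    if diag_R.ndim == 0:
        diag_R = np.full(values.shape[0], float(diag_R))
    if np.any(diag_R == 0):
        raise ValueError("diag_R entries must be nonzero")
    rinv = np.linalg.inv(values)
    d = np.diag(rinv)
    if np.any(d == 0):
        raise np.linalg.LinAlgError("diag(r^-1) has a zero entry")
    return (rinv / d[None, :]) * diag_R[None, :]


def build_regression_system(
    R: GlobalResponseMatrix,
    node: int,
    prior_null: set[int] | frozenset[int] | None = None,
    check_determined: bool = True,
) -> RegressionSystem:
    """Assemble node ``node``'s homogeneous regression system.

    The relative change of node i under any experiment not targeting i
    is a linear combination of the other nodes' relative changes with
    coefficients ``r_ij``.  Rows: experiments with target != node (the
    unmodelled direct perturbation term is nonzero on the node's own
    experiments, so they are excluded).  Columns: candidate sources
    j != node not in ``prior_null`` (known-null edges remove their
    column and free one degree of freedom each).
    """
    n = R.n_nodes
    if not 0 <= node < n:
        raise ValueError(f"node index {node} out of range")
    prior_null = set(prior_null or ())
    if node in prior_null:
        raise ValueError("prior_null may not contain the node itself")
    if not prior_null <= set(range(n)):
        raise ValueError("prior_null contains an unknown node index")
    rows = [k for k in range(R.n_experiments) if R.design.targets[k] != node]
    cols = [j for j in range(n) if j != node and j not in prior_null]
    X = R.values[np.ix_(cols, rows)].T
    y = R.values[node, rows]
    if check_determined and len(rows) < len(cols):
        raise UnderDeterminedError(
            f"node {node}: {len(rows)} equations for {len(cols)} unknowns "
            f"(deficit {len(cols) - len(rows)}); add replicates or perturbations"
        )
    return RegressionSystem(node, X, y, cols, rows)


def exact_squared_error(r_exact, r_est) -> float:
    """Sum of squared entrywise differences between two connectivity matrices.

    Diagonals contribute 0 since both are -1 by convention.
    """
    a = r_exact.values if isinstance(r_exact, ConnectivityMatrix) else np.asarray(r_exact, float)
    b = r_est.values if isinstance(r_est, ConnectivityMatrix) else np.asarray(r_est, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sum((a - b) ** 2))
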