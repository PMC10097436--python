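"""Model/Results interface tying the MRA machinery together.

``MRAModel`` wraps a global response matrix and its perturbation design;
``fit`` dispatches to the classical linear-algebra solution, the
classical bootstrap, or any of the per-node regression solvers, and
returns an ``MRAResults`` carrying the estimated connectivity matrix,
confidence bounds where the method provides them, per-node diagnostics
and a printable summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    ConnectivityMatrix,
    GlobalResponseMatrix,
    PerturbationDesign,
    solve_mra_classical,
)
from .solvers import (
    REGRESSION_METHODS,
    FitResult,
    bootstrap_mra,
    fit_network,
)

__all__ = ["MRAModel", "MRAResults"]

ALL_METHODS = ("mra", "mra_bootstrap") + REGRESSION_METHODS


class MRAModel:
    """Modular response analysis of steady-state perturbation data.

    Parameters
    ----------
    response
        :class:`GlobalResponseMatrix`, or an N x K array combined with
        ``design``.
    design
        :class:`PerturbationDesign` (required when ``response`` is a
        plain array).
    prior_null
        Known-null edges, mapping target node -> set of source nodes
        (indices or names) whose coefficients are fixed at 0.  Used by
        the regression methods.
    """

    def __init__(self, response, design: PerturbationDesign | None = None,
                 node_names=None, prior_null=None):
        if isinstance(response, GlobalResponseMatrix):
            self.response = response
        else:
            if design is None:
                raise ValueError("a plain response array needs a PerturbationDesign")
            self.response = GlobalResponseMatrix(
                np.asarray(response, float), design, node_names
            )
        self.prior_null = self._resolve_prior(prior_null)

    @classmethod
    def from_dataframe(cls, matrix: pd.DataFrame, design: pd.DataFrame,
                       prior_null=None) -> "MRAModel":
        """Build from a nodes x experiments DataFrame and a design table
        with columns ``experiment``, ``target_node``, ``intensity`` and
        optionally ``replicate``."""
        node_names = [str(i) for i in matrix.index]
        design = design.set_index("experiment").loc[[str(c) for c in matrix.columns]]
        targets = [node_names.index(str(t)) for t in design["target_node"]]
        reps = (
            design["replicate"].to_numpy(int) - 1
            if "replicate" in design.columns
            else None
        )
        pdesign = PerturbationDesign(
            np.array(targets), design["intensity"].to_numpy(float), reps,
            experiment_names=list(design.index),
        )
        return cls(matrix.to_numpy(float), pdesign, node_names, prior_null)

    def _resolve_prior(self, prior_null) -> dict[int, set[int]]:
        if not prior_null:
            return {}
        names = list(self.response.node_names)

        def _idx(x):
            return names.index(x) if isinstance(x, str) else int(x)

        resolved = {}
        for tgt, sources in prior_null.items():
            i = _idx(tgt)
            srcs = {_idx(s) for s in sources}
            if i in srcs:
                raise ValueError(f"prior_null for node {tgt} contains the node itself")
            resolved[i] = srcs
        return resolved

    @property
    def n_nodes(self) -> int:
        return self.response.n_nodes

    def fit(self, method: str = "lse", seed: int | None = None, **options
            ) -> "MRAResults":
        """Estimate the connectivity matrix.

        ``method`` is one of ``mra`` (classical square solution on
        replicate means), ``mra_bootstrap`` (classical + percentile
        bootstrap CIs and CI-based edge selection), or a regression
        solver: ``lse``, ``lse_ci``, ``tlr``, ``lasso``, ``step_fo``,
        ``step_ba``, ``step_bo``.  Extra keyword options are forwarded
        to the solver (``ci_level``, ``cv_folds``, ``tlr_percentile``,
        ``step_criterion``, ``n_boot``, ...).
        """
        if method == "mra":
            cond_max = options.pop("cond_max", 1e8)
            if options:
                raise TypeError(f"unknown options for 'mra': {sorted(options)}")
            r = solve_mra_classical(self.response.replicate_mean(), cond_max=cond_max)
            return MRAResults(self, method, r)
        if method == "mra_bootstrap":
            boot = bootstrap_mra(self.response, seed=seed, **options)
            return MRAResults(
                self, method, boot.connectivity,
                ci_low=boot.ci_low, ci_high=boot.ci_high, bootstrap=boot,
            )
        if method in REGRESSION_METHODS:
            r, node_results = fit_network(
                self.response, method, prior_null=self.prior_null,
                seed=seed, **options,
            )
            n = self.n_nodes
            low = np.full((n, n), np.nan)
            high = np.full((n, n), np.nan)
            has_ci = False
            for i, fr in node_results.items():
                if fr.ci_low is not None:
                    has_ci = True
                    for j, lo, hi in zip(fr.column_index, fr.ci_low, fr.ci_high):
                        low[i, j], high[i, j] = lo, hi
            return MRAResults(
                self, method, r,
                ci_low=low if has_ci else None,
                ci_high=high if has_ci else None,
                node_results=node_results,
            )
        raise ValueError(f"unknown method {method!r}; choose from {ALL_METHODS}")


class MRAResults:
    """Fitted connectivity estimates with uncertainty and diagnostics."""

    def __init__(self, model: MRAModel, method: str,
                 connectivity: ConnectivityMatrix,
                 ci_low: np.ndarray | None = None,
                 ci_high: np.ndarray | None = None,
                 node_results: dict[int, FitResult] | None = None,
                 bootstrap=None):
        self.model = model
        self.method = method
        self.connectivity = connectivity
        self.ci_low = ci_low
        self.ci_high = ci_high
        self.node_results = node_results or {}
        self.bootstrap = bootstrap

    @property
    def values(self) -> np.ndarray:
        return self.connectivity.values

    def ci_width(self) -> np.ndarray | None:
        """Off-diagonal CI widths (NaN diagonal), or None without CIs."""
        if self.ci_low is None:
            return None
        w = self.ci_high - self.ci_low
        np.fill_diagonal(w, np.nan)
        return w

    def to_edge_list(self) -> pd.DataFrame:
        """Nonzero off-diagonal coefficients as (source, target, coefficient)."""
        names = self.connectivity.node_names
        rows = []
        v = self.values
        for i in range(len(names)):
            for j in range(len(names)):
                if i != j and v[i, j] != 0.0:
                    rows.append((names[j], names[i], v[i, j]))
        return pd.DataFrame(rows, columns=["source", "target", "coefficient"])

    def residual_variances(self) -> pd.Series:
        return pd.Series(
            {
                self.connectivity.node_names[i]: fr.residual_variance
                for i, fr in self.node_results.items()
            },
            name="residual_variance",
        )

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        names = self.connectivity.node_names
        n = len(names)
        edges = self.to_edge_list()
        lines = [
            "Modular response analysis results",
            "=" * 48,
            f"method:            {self.method}",
            f"nodes:             {n}",
            f"experiments:       {self.model.response.n_experiments}",
            f"nonzero edges:     {len(edges)} / {n * (n - 1)} off-diagonal",
        ]
        if self.node_results:
            dofs = [fr.dof for fr in self.node_results.values()]
            lines.append(f"per-node dof:      min {min(dofs)}, max {max(dofs)}")
            rv = self.residual_variances().dropna()
            if len(rv):
                lines.append(f"residual variance: median {rv.median():.4g}")
        if self.bootstrap is not None:
            lines.append(
                f"bootstrap:         {self.bootstrap.n_boot} resamples, "
                f"{self.bootstrap.n_discarded} discarded"
            )
        lines.append("-" * 48)
        lines.append(f"{'source':>10} {'target':>10} {'coef':>10}  95% CI")
        for _, row in edges.iterrows():
            i = names.index(row["target"])
            j = names.index(row["source"])
            ci = ""
            if self.ci_low is not None and np.isfinite(self.ci_low[i, j]):
                ci = f"[{self.ci_low[i, j]: .3f}, {self.ci_high[i, j]: .3f}]"
            lines.append(
                f"{row['source']:>10} {row['target']:>10} {row['coefficient']:>10.4f}  {ci}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<MRAResults method={self.method!r} nodes={self.connectivity.n_nodes} "
            f"edges={int(np.sum(self.values != 0)) - self.connectivity.n_nodes}>"
        )
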