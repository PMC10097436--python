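"""Sparse synthetic benchmark networks and simulated perturbation responses.

Generates reference connectivity matrices with transcription-factor /
target structure (TFs regulate at least one other gene, out-degree > 0;
TAs are pure targets, out-degree 0), a configurable fraction of null
off-diagonal edges (default 85%), signed coefficient magnitudes bounded
away from zero, and a -1 diagonal.  Responses to KO/KD designs are then
derived analytically through the exact forward map, and Gaussian
additive noise N(0, k*xbar) is applied, independently per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ConnectivityMatrix,
    GlobalResponseMatrix,
    PerturbationDesign,
    diagonal_response,
    forward_response,
)

__all__ = [
    "NetworkSpec",
    "GenerationError",
    "generate_network",
    "simulate_responses",
    "make_benchmark_suite",
]


class GenerationError(RuntimeError):
    """Raised when no acceptably-conditioned network is found within the retry budget."""


@dataclass
class NetworkSpec:
    """Configuration for one synthetic reference network.

    Attributes
    ----------
    n_tf, n_ta
        Counts of regulator (out-degree > 0) and target-only
        (out-degree 0) nodes; total size N = n_tf + n_ta.
    null_fraction
        Guaranteed minimum fraction of zero off-diagonal coefficients
        (hard bound, not an expectation).
    coef_low, coef_high
        Nonzero coefficient magnitudes are uniform on
        [coef_low, coef_high] with a fair random sign; the lower bound
        keeps "nonzero" well-separated from zero for evaluation.
    cond_max, max_retries
        A draw is rejected and redrawn when cond(r) exceeds cond_max.
    """

    n_tf: int
    n_ta: int = 0
    null_fraction: float = 0.85
    coef_low: float = 0.3
    coef_high: float = 2.0
    cond_max: float = 1e6
    max_retries: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_tf < 2:
            raise ValueError("need at least 2 TF nodes")
        if self.n_ta < 0:
            raise ValueError("n_ta must be nonnegative")
        if not 0.0 <= self.null_fraction < 1.0:
            raise ValueError("null_fraction must lie in [0, 1)")
        if not 0.0 < self.coef_low <= self.coef_high:
            raise ValueError("need 0 < coef_low <= coef_high")

    @property
    def n_nodes(self) -> int:
        return self.n_tf + self.n_ta


def _draw_support(spec: NetworkSpec, rng: np.random.Generator) -> np.ndarray:
    """Boolean off-diagonal support with TA columns empty, TF columns nonempty."""
    n = spec.n_nodes
    n_offdiag = n * (n - 1)
    max_nonzero = int(np.floor((1.0 - spec.null_fraction) * n_offdiag))
    if max_nonzero < spec.n_tf:
        raise GenerationError(
            f"null_fraction {spec.null_fraction} leaves {max_nonzero} edges but "
            f"{spec.n_tf} TF columns each need one; lower the sparsity or grow N"
        )
    support = np.zeros((n, n), dtype=bool)
    # one guaranteed out-edge per TF column
    for j in range(spec.n_tf):
        rows = np.delete(np.arange(n), j)
        support[rng.choice(rows), j] = True
    # distribute the remaining budget over free TF-column slots
    remaining = max_nonzero - spec.n_tf
    if remaining > 0:
        free = [
            (i, j)
            for j in range(spec.n_tf)
            for i in range(n)
            if i != j and not support[i, j]
        ]
        picks = rng.choice(len(free), size=min(remaining, len(free)), replace=False)
        for p in picks:
            support[free[p]] = True
    return support


def generate_network(spec: NetworkSpec, seed: int | None = None) -> ConnectivityMatrix:
    """Draw a sparse signed reference connectivity matrix.

    The zero fraction of off-diagonal entries is >= ``spec.null_fraction``
    for every seed (guaranteed by construction: the nonzero budget is the
    floor of the complementary fraction).  Regenerates until
    cond(r) < ``spec.cond_max`` so the analytic response matrix exists
    and round-trips numerically.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    for _ in range(spec.max_retries):
        support = _draw_support(spec, rng)
        n_edges = int(support.sum())
        mags = rng.uniform(spec.coef_low, spec.coef_high, size=n_edges)
        signs = rng.choice([-1.0, 1.0], size=n_edges)
        r = np.zeros((spec.n_nodes, spec.n_nodes))
        r[support] = mags * signs
        np.fill_diagonal(r, -1.0)
        if np.linalg.cond(r) < spec.cond_max:
            return ConnectivityMatrix(
                r,
                [f"TF{j + 1}" for j in range(spec.n_tf)]
                + [f"TA{j + 1}" for j in range(spec.n_ta)],
                exact=True,
            )
    raise GenerationError(
        f"no network with cond < {spec.cond_max:.2g} in {spec.max_retries} draws; "
        "try lower density or a smaller size"
    )


def simulate_responses(
    r_exact: ConnectivityMatrix,
    design: PerturbationDesign | None = None,
    noise_k: float = 0.0,
    xbar: float = 1.0,
    seed: int | None = None,
    replicates: int = 1,
    noise_on: str = "response",
) -> GlobalResponseMatrix:
    """Analytic global response matrix of a known network, plus noise.

    The noise-free responses come from the exact forward map with the
    design-implied diagonal (2f/(2+f) for perturbation fraction f: -2
    for KO, -2/3 for -50% KD).  ``noise_on="response"`` then adds i.i.d.
    N(0, noise_k * xbar) to every entry, independently per replicate —
    the additive model used for benchmark noise.  ``noise_on="levels"``
    instead back-computes pseudo-concentrations at scale ``xbar``,
    perturbs those, and re-forms the mid-point relative changes, which
    bounds noisy entries to the valid (-2, 2) range.
    """
    if design is None:
        design = PerturbationDesign.one_per_node(r_exact.n_nodes, intensity=-1.0)
    if replicates > 1:
        design = PerturbationDesign(
            np.tile(design.targets, replicates),
            np.tile(design.intensities, replicates),
            np.repeat(np.arange(replicates), design.n_experiments),
        )
    n = r_exact.n_nodes
    if not set(design.targets) <= set(range(n)):
        raise ValueError("design targets a node outside the network")
    # noise-free columns: one forward map per distinct intensity
    clean = np.empty((n, design.n_experiments))
    for fraction in np.unique(design.intensities):
        R_f = forward_response(r_exact, np.full(n, diagonal_response(fraction)))
        for k in np.where(design.intensities == fraction)[0]:
            clean[:, k] = R_f[:, design.targets[k]]
    if noise_k < 0:
        raise ValueError("noise_k must be nonnegative")
    if noise_k == 0:
        return GlobalResponseMatrix(clean, design, list(r_exact.node_names))
    rng = np.random.default_rng(seed)
    sigma = noise_k * xbar
    if noise_on == "response":
        noisy = clean + rng.normal(0.0, sigma, size=clean.shape)
    elif noise_on == "levels":
        # invert the mid-point formula at basal level xbar, add noise to
        # levels, floor at a small positive epsilon, re-form the changes
        basal = np.full(clean.shape, xbar)
        perturbed = basal * (2.0 + clean) / (2.0 - clean + 1e-300)
        basal_n = np.clip(basal + rng.normal(0.0, sigma, size=clean.shape), 1e-9, None)
        pert_n = np.clip(perturbed + rng.normal(0.0, sigma, size=clean.shape), 1e-9, None)
        noisy = 2.0 * (pert_n - basal_n) / (pert_n + basal_n)
    else:
        raise ValueError("noise_on must be 'response' or 'levels'")
    return GlobalResponseMatrix(noisy, design, list(r_exact.node_names))


@dataclass
class BenchmarkCase:
    """One seeded (network, noisy responses) pair with its manifest."""

    r_exact: ConnectivityMatrix
    responses: GlobalResponseMatrix
    manifest: dict = field(default_factory=dict)


def make_benchmark_suite(
    sizes: list[int],
    ta_mode: str = "zero",
    noise_levels: list[float] = (0.1,),
    perturbation: str = "KO",
    replicates: int = 1,
    seeds: list[int] = (0,),
    null_fraction: float = 0.85,
    noise_on: str = "response",
) -> list[BenchmarkCase]:
    """Enumerate seeded benchmark cases over a (size, noise, seed) grid.

    ``ta_mode="zero"`` builds pure-TF networks (size = TF count);
    ``"equal"`` sets TA = TF (size = TF + TA).  ``perturbation`` is
    ``"KO"`` (-100%) or ``"KD"`` (-50%).  Deterministic: the same
    arguments produce the same cases.
    """
    if ta_mode not in ("zero", "equal"):
        raise ValueError("ta_mode must be 'zero' or 'equal'")
    fraction = {"KO": -1.0, "KD": -0.5}[perturbation]
    cases = []
    for size in sizes:
        if ta_mode == "zero":
            n_tf, n_ta = size, 0
        else:
            if size % 2:
                raise ValueError("ta_mode='equal' needs an even total size")
            n_tf = n_ta = size // 2
        for k in noise_levels:
            for seed in seeds:
                spec = NetworkSpec(n_tf=n_tf, n_ta=n_ta, null_fraction=null_fraction)
                # decorrelate network draw and noise draw
                net_seed = (1_000_003 * seed + 7 * size + 1) % (2**31)
                noise_seed = (1_000_033 * seed + 13 * size + int(1e4 * k)) % (2**31)
                r = generate_network(spec, seed=net_seed)
                design = PerturbationDesign.one_per_node(r.n_nodes, intensity=fraction)
                R = simulate_responses(
                    r, design, noise_k=k, seed=noise_seed,
                    replicates=replicates, noise_on=noise_on,
                )
                cases.append(
                    BenchmarkCase(
                        r, R,
                        manifest={
                            "size": size, "n_tf": n_tf, "n_ta": n_ta,
                            "ta_mode": ta_mode, "noise_k": k,
                            "perturbation": perturbation, "replicates": replicates,
                            "seed": seed, "null_fraction": null_fraction,
                        },
                    )
                )
    return cases
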