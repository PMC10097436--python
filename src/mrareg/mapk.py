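"""Six-node MAP-kinase cascade fixture for ground-truth validation.

A small ODE system with a known, reachable steady state provides exact
connectivity coefficients (via the steady-state Jacobian) against which
MRA estimates can be scored.  The fixture is a three-tier kinase relay
(MKKK -> MKK -> MAPK, two activation stages per tier, Michaelis-Menten
activation/deactivation kinetics, negative feedback from the terminal
doubly-active form onto the cascade input).  Each stage draws on its own
conserved pool, so every rate parameter enters exactly one equation and
the standard-MRA assumption that a perturbed parameter directly affects
only its target node holds exactly.

Parameter values, the perturbation-to-parameter map, and the initial
condition live in a YAML data file (``data/mapk6.yaml``); concentration
units there are calibrated so the mean basal steady-state level is 84,
which fixes the absolute scale of the additive noise model
sigma = k * xbar.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.optimize
import yaml

from .core import (
    ConnectivityMatrix,
    GlobalResponseMatrix,
    PerturbationDesign,
    exact_squared_error,
    relative_change,
    solve_mra_classical,
)

__all__ = [
    "OdeModel",
    "SteadyStateError",
    "load_model",
    "steady_state",
    "perturb_and_measure",
    "measure_response_matrix",
    "exact_connectivity",
    "intensity_noise_sweep",
]

N_STAGES = 6
CONCENTRATION_FLOOR = 1e-9


class SteadyStateError(RuntimeError):
    """Raised when the integration does not settle onto a steady state."""


@dataclass
class OdeModel:
    """The kinase-relay ODE system.

    ``parameters`` holds the twelve speed constants ``v1..v12`` (``v1``
    the cascade input Vmax, ``v2..v6`` activation catalytic constants of
    stages 2-6, ``v7..v12`` deactivation Vmax of stages 1-6), the
    Michaelis constants ``km1..km12``, and the feedback constants
    ``ki``/``n_fb``.  ``pools`` are the per-stage conserved totals.
    ``perturbation_targets`` maps each state to the speed constant that
    carries its perturbation in the standard one-parameter-per-node
    design.
    """

    state_names: list[str]
    parameters: dict[str, float]
    pools: np.ndarray
    initial_state: np.ndarray
    perturbation_targets: dict[str, str] = field(default_factory=dict)
    reference_xbar: float | None = None
    name: str = "mapk6"

    def __post_init__(self) -> None:
        if len(self.state_names) != N_STAGES:
            raise ValueError("fixture expects exactly 6 states")
        self.pools = np.asarray(self.pools, float)
        self.initial_state = np.asarray(self.initial_state, float)
        if any(v < 0 for v in self.parameters.values()):
            raise ValueError("rate parameters must be nonnegative")

    def with_parameters(self, **updates: float) -> "OdeModel":
        params = {**self.parameters, **updates}
        return OdeModel(
            self.state_names, params, self.pools.copy(),
            self.initial_state.copy(), dict(self.perturbation_targets),
            self.reference_xbar, self.name,
        )

    def perturbed(self, node: int, fraction: float) -> "OdeModel":
        """Multiply the speed constant carrying node ``node``'s
        perturbation by (1 + fraction)."""
        if fraction < -1.0:
            raise ValueError("fraction must be >= -1 (full knockout of the constant)")
        pname = self.perturbation_targets[self.state_names[node]]
        return self.with_parameters(**{pname: self.parameters[pname] * (1.0 + fraction)})

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Right-hand side f(X) of dX/dt = f(X)."""
        p = self.parameters
        c = self.pools
        f = np.empty(N_STAGES)
        free0 = c[0] - x[0]
        feedback = 1.0 + (x[5] / p["ki"]) ** p["n_fb"]
        f[0] = (
            p["v1"] * free0 / (feedback * (p["km1"] + free0))
            - p["v7"] * x[0] / (p["km7"] + x[0])
        )
        for i in range(1, N_STAGES):
            free = c[i] - x[i]
            act = p[f"v{i + 1}"] * x[i - 1] * free / (p[f"km{i + 1}"] + free)
            deact = p[f"v{i + 7}"] * x[i] / (p[f"km{i + 7}"] + x[i])
            f[i] = act - deact
        return f


def load_model(path: str | Path | None = None) -> OdeModel:
    """Load the fixture from YAML (the packaged ``mapk6.yaml`` by default)."""
    if path is None:
        source = importlib.resources.files("mrareg.data").joinpath("mapk6.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    states = raw["states"]
    return OdeModel(
        state_names=[s["name"] for s in states],
        parameters={k: float(v) for k, v in raw["parameters"].items()},
        pools=np.array([s["pool"] for s in states], float),
        initial_state=np.array([s["initial"] for s in states], float),
        perturbation_targets=dict(raw["perturbation_targets"]),
        reference_xbar=raw.get("reference_xbar"),
        name=raw.get("name", "mapk6"),
    )


def steady_state(
    model: OdeModel,
    tol: float = 1e-9,
    t_window: float = 2_000.0,
    max_horizon: float = 1e6,
    polish: bool = True,
) -> np.ndarray:
    """Integrate from the documented initial condition until dX/dt vanishes.

    Integrates in windows with a stiff solver until ||f(X)||_inf drops
    below ``tol`` (a Newton polish of the integration endpoint removes
    residual integrator error).  Deterministic for fixed parameters.
    """
    x = model.initial_state.copy()
    t = 0.0
    while t < max_horizon:
        sol = scipy.integrate.solve_ivp(
            lambda _t, y: model.rates(y), (0.0, t_window), x,
            method="LSODA", rtol=1e-10, atol=1e-10,
        )
        if not sol.success:
            raise SteadyStateError(f"integration failed: {sol.message}")
        x = np.clip(sol.y[:, -1], 0.0, model.pools)
        t += t_window
        if np.max(np.abs(model.rates(x))) < max(tol, 1e-8) or (
            polish and np.max(np.abs(model.rates(x))) < 1e-5
        ):
            if polish:
                res = scipy.optimize.root(model.rates, x, method="hybr", tol=1e-13)
                if res.success and np.max(np.abs(model.rates(res.x))) < tol:
                    x = res.x
            if np.max(np.abs(model.rates(x))) < tol:
                if np.any(x < 0) or np.any(x > model.pools + 1e-6):
                    raise SteadyStateError("steady state outside physical bounds")
                return x
        t_window *= 2.0
    raise SteadyStateError(
        f"no steady state within horizon {max_horizon:g} "
        f"(||f||_inf = {np.max(np.abs(model.rates(x))):.3g})"
    )


def check_reference_scale(model: OdeModel, x_star: np.ndarray | None = None,
                          rtol: float = 0.01) -> float:
    """Return the mean basal steady-state level, warning when it strays
    from the model's documented reference value."""
    if x_star is None:
        x_star = steady_state(model)
    xbar = float(np.mean(x_star))
    if model.reference_xbar is not None:
        if abs(xbar - model.reference_xbar) > rtol * model.reference_xbar:
            warnings.warn(
                f"mean steady-state level {xbar:.3f} deviates from the "
                f"reference scale {model.reference_xbar:.3f}", stacklevel=2,
            )
    return xbar


def _noisy(x: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return x
    noisy = x + rng.normal(0.0, sigma, size=x.shape)
    if np.any(noisy <= 0):
        warnings.warn(
            "noisy concentration fell below 0; flooring at a small epsilon",
            stacklevel=3,
        )
        noisy = np.clip(noisy, CONCENTRATION_FLOOR, None)
    return noisy


def perturb_and_measure(
    model: OdeModel,
    node: int,
    fraction: float,
    noise_k: float = 0.0,
    replicates: int = 1,
    seed=None,
    basal: np.ndarray | None = None,
) -> np.ndarray:
    """Measure one perturbation experiment: columns of relative changes.

    Multiplies node ``node``'s perturbable speed constant by
    (1 + ``fraction``), recomputes the steady state, adds Gaussian
    N(0, k * xbar) noise independently to each basal and perturbed
    measurement per replicate (xbar = mean clean basal level), and forms
    the mid-point relative changes.  Returns a (6, replicates) array.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if basal is None:
        basal = steady_state(model)
    perturbed = steady_state(model.perturbed(node, fraction))
    sigma = noise_k * float(np.mean(basal))
    rng = np.random.default_rng(seed)
    out = np.empty((N_STAGES, replicates))
    for rep in range(replicates):
        b = _noisy(basal, sigma, rng)
        p = _noisy(perturbed, sigma, rng)
        out[:, rep] = [relative_change(bi, pi) for bi, pi in zip(b, p)]
    return out


def measure_response_matrix(
    model: OdeModel,
    fraction: float,
    noise_k: float = 0.0,
    replicates: int = 1,
    seed=None,
    basal: np.ndarray | None = None,
    perturbed_states: dict[int, np.ndarray] | None = None,
) -> GlobalResponseMatrix:
    """Full response matrix: one experiment per node at ``fraction``.

    ``perturbed_states`` may carry precomputed steady states keyed by
    node to avoid re-integration across noise draws.
    """
    if basal is None:
        basal = steady_state(model)
    sigma = noise_k * float(np.mean(basal))
    rng = np.random.default_rng(seed)
    cols = np.empty((N_STAGES, N_STAGES * replicates))
    design = PerturbationDesign.one_per_node(N_STAGES, fraction, replicates)
    for k in range(design.n_experiments):
        node = int(design.targets[k])
        if perturbed_states is not None and node in perturbed_states:
            pstate = perturbed_states[node]
        else:
            pstate = steady_state(model.perturbed(node, fraction))
            if perturbed_states is not None:
                perturbed_states[node] = pstate
        b = _noisy(basal, sigma, rng)
        p = _noisy(pstate, sigma, rng)
        cols[:, k] = [relative_change(bi, pi) for bi, pi in zip(b, p)]
    return GlobalResponseMatrix(cols, design, list(model.state_names))


def exact_connectivity(
    model: OdeModel,
    x_star: np.ndarray | None = None,
    rel_step: float = 1e-6,
) -> ConnectivityMatrix:
    """Exact connectivity coefficients from the steady-state Jacobian.

    r_ij = -(X_j dF_i/dX_j) / (X_i dF_i/dX_i) for i != j (central finite
    differences with relative step ``rel_step``), diagonal -1.  Pairs of
    stages that do not interact structurally give exact zeros.
    """
    if x_star is None:
        x_star = steady_state(model)
    jac = np.empty((N_STAGES, N_STAGES))
    for j in range(N_STAGES):
        h = rel_step * max(abs(x_star[j]), 1.0)
        up, dn = x_star.copy(), x_star.copy()
        up[j] += h
        dn[j] -= h
        jac[:, j] = (model.rates(up) - model.rates(dn)) / (2 * h)
    dii = np.diag(jac)
    if np.any(np.abs(dii) < 1e-12):
        raise ValueError("degenerate node: dF_i/dX_i vanishes at the steady state")
    r = -(jac * x_star[None, :]) / (dii * x_star)[:, None]
    np.fill_diagonal(r, -1.0)
    return ConnectivityMatrix(r, list(model.state_names), exact=True)


def intensity_noise_sweep(
    model: OdeModel,
    intensities,
    noise_levels,
    replicates: int = 1,
    n_draws: int = 20,
    seed: int = 0,
    cond_max: float = 1e8,
) -> pd.DataFrame:
    """Exact squared error of classical MRA over an intensity x noise grid.

    For every (intensity, noise_k) cell: simulate ``n_draws`` noisy
    measurement sets (``replicates`` replicate measurements averaged per
    experiment), solve classical MRA, and score against the exact
    connectivity.  Solver failures are recorded as missing draws rather
    than aborting the sweep.  Noise-free cells need a single draw.
    """
    intensities = list(intensities)
    noise_levels = list(noise_levels)
    if not intensities or not noise_levels:
        raise ValueError("need nonempty intensity and noise grids")
    basal = steady_state(model)
    r_exact = exact_connectivity(model, basal)
    cache: dict[float, dict[int, np.ndarray]] = {}
    rows = []
    for ci, fraction in enumerate(intensities):
        pstates = cache.setdefault(fraction, {})
        for cj, k in enumerate(noise_levels):
            draws = 1 if k == 0 else n_draws
            errs = []
            failed = 0
            for d in range(draws):
                R = measure_response_matrix(
                    model, fraction, noise_k=k, replicates=replicates,
                    seed=np.random.default_rng([seed, ci, cj, d]).integers(2**31),
                    basal=basal, perturbed_states=pstates,
                )
                try:
                    r_est = solve_mra_classical(R.replicate_mean(), cond_max=cond_max)
                    errs.append(exact_squared_error(r_exact, r_est))
                except np.linalg.LinAlgError:
                    failed += 1
            rows.append(
                {
                    "intensity": fraction,
                    "noise_k": k,
                    "mean_sqerr": float(np.mean(errs)) if errs else np.nan,
                    "sd_sqerr": float(np.std(errs, ddof=1)) if len(errs) > 1 else 0.0,
                    "n_ok": len(errs),
                    "n_failed": failed,
                }
            )
    return pd.DataFrame(rows)
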