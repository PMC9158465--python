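"""Particle-swarm parameter estimation against calcium time courses.

The estimation honours the physiological tying rule used when fitting the
model: reaction constants are shared across experimental conditions, while
bound-protein initial concentrations (and expression-proxy maximal rates
such as v_Pmc1 or k_MS) may differ per experiment.  The optimizer is a
global-best particle swarm with constriction-style coefficients, absorbing
bounds, and optional log-scale search for parameters whose ranges span
several decades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .biophysics import BiophysicalParameters, StimulusProtocol
from .signaling import KineticParameters
from .simulator import (
    SolverSettings,
    StrainConfig,
    resting_baseline,
    simulate,
    strain_parameters,
)
from .signaling import quasi_steady_canb
from .biophysics import BiophysicalDerived

__all__ = [
    "FreeParameter",
    "Experiment",
    "EstimationProblem",
    "SwarmSettings",
    "FitResult",
    "sse_objective",
    "pso_optimize",
    "fit",
    "recovery_experiment",
]

# Initial bound-protein concentrations and expression proxies are the only
# quantities allowed to differ between experiments.
PER_EXPERIMENT_ALLOWED = {"camb0", "v_Pmc1", "k_MS"}

# Loose-but-safe solver profile for the optimizer's inner simulations.
FIT_SOLVER = SolverSettings(rtol=1e-6, atol=(1e-20, 1e-4, 1e-7, 1e-7))


@dataclass(frozen=True)
class FreeParameter:
    """A parameter left free in the fit, with its search range and scope.

    ``log`` selects base-10 log-scale search; by default it is enabled when
    the range spans at least three decades.
    """

    name: str
    lower: float
    upper: float
    scope: str = "shared"
    log: bool | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("bounds must be finite")
        if self.lower >= self.upper:
            raise ValueError(f"{self.name}: need lower < upper")
        if self.scope not in ("shared", "per-experiment"):
            raise ValueError("scope must be 'shared' or 'per-experiment'")
        if self.scope == "per-experiment" and self.name not in PER_EXPERIMENT_ALLOWED:
            raise ValueError(
                f"{self.name} cannot vary per experiment; only "
                f"{sorted(PER_EXPERIMENT_ALLOWED)} may"
            )
        if self.log is None:
            use_log = self.lower > 0 and self.upper / self.lower >= 1e3
            object.__setattr__(self, "log", use_log)

    def to_search(self, value: float) -> float:
        return math.log10(value) if self.log else value

    def from_search(self, value: float) -> float:
        return 10.0**value if self.log else value

    @property
    def search_bounds(self) -> tuple[float, float]:
        return self.to_search(self.lower), self.to_search(self.upper)


@dataclass
class Experiment:
    """One observed condition: times (s), cytosolic calcium (nM), protocol.

    ``camb0`` is the resting bound calmodulin used unless the fit frees it;
    ``overrides`` are fixed strain-specific parameter patches.
    """

    name: str
    times: np.ndarray
    ca_obs: np.ndarray
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    overrides: dict = field(default_factory=dict)
    camb0: float = 1.0
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ca_obs = np.asarray(self.ca_obs, dtype=float)
        if self.times.shape != self.ca_obs.shape:
            raise ValueError(f"{self.name}: times/observations length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.name}: times must be strictly increasing")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.times.shape:
                raise ValueError(f"{self.name}: weights length mismatch")


@dataclass
class EstimationProblem:
    """Dataset + free-parameter layout + loss configuration.

    The parameter vector is laid out shared-first, then per-experiment
    parameters expanded one slot per experiment (parameter-major order).
    ``steady_state_weight`` adds a penalty on the mismatch between the
    model's calibrated resting calcium and the observed pre-stimulus
    baseline of each experiment.
    """

    experiments: list[Experiment]
    free_parameters: list[FreeParameter]
    base_kinetic: KineticParameters = field(default_factory=KineticParameters)
    biophys: BiophysicalParameters = field(default_factory=BiophysicalParameters)
    solver: SolverSettings = field(default_factory=lambda: FIT_SOLVER)
    steady_state_weight: float = 0.0

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ValueError("dataset must contain at least one experiment")
        names = [p.name for p in self.free_parameters]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"parameter(s) named in more than one scope: {sorted(dup)}")
        kin_fields = set(KineticParameters.__dataclass_fields__) | {"camb0"}
        unknown = set(names) - kin_fields
        if unknown:
            raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")
        # identifiability guard: camb0 only acts through the MS feedback
        if any(p.name == "camb0" for p in self.free_parameters):
            for exp in self.experiments:
                k_ms = exp.overrides.get("k_MS", self.base_kinetic.k_MS)
                if k_ms == 0:
                    raise ValueError(
                        f"camb0 is non-identifiable in experiment {exp.name!r}: "
                        "k_MS is zero so the MS feedback is inert"
                    )

    @property
    def theta_names(self) -> list[str]:
        names = [p.name for p in self.free_parameters if p.scope == "shared"]
        for p in self.free_parameters:
            if p.scope == "per-experiment":
                names.extend(f"{p.name}[{e.name}]" for e in self.experiments)
        return names

    @property
    def theta_specs(self) -> list[FreeParameter]:
        specs = [p for p in self.free_parameters if p.scope == "shared"]
        for p in self.free_parameters:
            if p.scope == "per-experiment":
                specs.extend([p] * len(self.experiments))
        return specs

    @property
    def n_dim(self) -> int:
        return len(self.theta_specs)

    @property
    def search_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = zip(*(p.search_bounds for p in self.theta_specs))
        return np.array(lo), np.array(hi)

    def expand(self, theta: np.ndarray) -> list[dict]:
        """Per-experiment {parameter: natural value} dicts from a vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_dim,):
            raise ValueError(
                f"theta has length {theta.size}, expected {self.n_dim}"
            )
        per_exp = [dict() for _ in self.experiments]
        i = 0
        for p in self.free_parameters:
            if p.scope == "shared":
                val = p.from_search(theta[i])
                i += 1
                for d in per_exp:
                    d[p.name] = val
        for p in self.free_parameters:
            if p.scope == "per-experiment":
                for d in per_exp:
                    d[p.name] = p.from_search(theta[i])
                    i += 1
        return per_exp


@dataclass(frozen=True)
class SwarmSettings:
    """Global-best PSO hyperparameters (constriction-style defaults)."""

    swarm_size: int = 40
    iterations: int = 300
    inertia: float = 0.729
    cognitive: float = 1.494
    social: float = 1.494
    velocity_clamp: float = 0.5
    seed: int = 0
    boundary: str = "absorb"
    patience: int | None = 50
    patience_rel_tol: float = 1e-9
    loss_tol: float | None = None

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm size must be >= 2")
        if min(self.inertia, self.cognitive, self.social) <= 0:
            raise ValueError("PSO coefficients must be positive")


@dataclass
class FitResult:
    """Outcome of a swarm run, reproducible from seed + settings."""

    best_theta: np.ndarray
    best_loss: float
    history: np.ndarray
    n_evaluations: int
    settings: SwarmSettings
    final_positions: np.ndarray
    named_parameters: dict = field(default_factory=dict)
    per_experiment: list = field(default_factory=list)


def sse_objective(
    theta: np.ndarray,
    problem: EstimationProblem,
) -> float:
    """Weighted sum of squared calcium residuals (nM^2) across experiments.

    Each experiment is simulated from its own calibrated rest with the
    candidate parameters; a failed integration yields +inf, never an
    exception.
    """
    try:
        per_exp = problem.expand(theta)
    except ValueError:
        raise
    total = 0.0
    derived = BiophysicalDerived.from_parameters(problem.biophys)
    for exp, free_vals in zip(problem.experiments, per_exp):
        patch = dict(exp.overrides)
        camb0 = free_vals.pop("camb0", exp.camb0)
        patch.update(free_vals)
        try:
            params = problem.base_kinetic.with_overrides(**patch)
            ca0 = resting_baseline(params, camb0, problem.biophys, exp.protocol)
            y0 = (derived.V_os0, ca0, camb0, quasi_steady_canb(camb0, params))
            trace = simulate(
                params, problem.biophys, exp.protocol,
                strain=StrainConfig(name="custom", resting_camb=camb0),
                settings=problem.solver, initial_state=y0,
                t_eval=np.union1d(exp.times, [0.0]),
            )
        except (RuntimeError, ValueError, OverflowError):
            return math.inf
        ca_sim = np.interp(exp.times, trace.time, trace.Ca_cyt)
        resid = ca_sim - exp.ca_obs
        w = exp.weights if exp.weights is not None else 1.0
        total += float(np.sum(w * resid**2))
        if problem.steady_state_weight > 0:
            pre = exp.times < exp.protocol.t_off
            if pre.any():
                obs_baseline = float(exp.ca_obs[pre].mean())
                total += problem.steady_state_weight * (ca0 - obs_baseline) ** 2
        if not math.isfinite(total):
            return math.inf
    return total


def pso_optimize(
    objective,
    bounds: tuple[np.ndarray, np.ndarray],
    settings: SwarmSettings | None = None,
) -> FitResult:
    """Global-best particle swarm minimization within box bounds.

    Velocities combine inertia, cognitive and social pulls; positions are
    clipped to the bounds with the velocity component zeroed on contact
    (absorbing walls).  The best-ever loss history is monotone
    non-increasing and the whole run is reproducible from the seed.  With a
    zero iteration budget the best of the initial swarm is returned.
    """
    settings = settings or SwarmSettings()
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    if lo.shape != hi.shape or np.any(lo >= hi):
        raise ValueError("invalid bounds")
    ndim = lo.size
    span = hi - lo
    vmax = settings.velocity_clamp * span
    rng = np.random.default_rng(settings.seed)

    X = lo + span * rng.random((settings.swarm_size, ndim))
    V = vmax * (2.0 * rng.random((settings.swarm_size, ndim)) - 1.0)
    losses = np.array([objective(x) for x in X])
    n_eval = settings.swarm_size
    pbest, pbest_loss = X.copy(), losses.copy()
    g = int(np.argmin(pbest_loss))
    gbest, gbest_loss = pbest[g].copy(), float(pbest_loss[g])
    history = [gbest_loss]

    def converged(loss: float) -> bool:
        return settings.loss_tol is not None and loss <= settings.loss_tol

    stagnant = 0
    for _ in range(settings.iterations):
        if converged(gbest_loss):
            break
        r1 = rng.random((settings.swarm_size, ndim))
        r2 = rng.random((settings.swarm_size, ndim))
        V = (
            settings.inertia * V
            + settings.cognitive * r1 * (pbest - X)
            + settings.social * r2 * (gbest[None, :] - X)
        )
        np.clip(V, -vmax, vmax, out=V)
        X = X + V
        below, above = X < lo, X > hi
        V[below | above] = 0.0
        np.clip(X, lo, hi, out=X)

        losses = np.array([objective(x) for x in X])
        n_eval += settings.swarm_size
        improved = losses < pbest_loss
        pbest[improved] = X[improved]
        pbest_loss[improved] = losses[improved]
        g = int(np.argmin(pbest_loss))
        prev = gbest_loss
        if pbest_loss[g] < gbest_loss:
            gbest, gbest_loss = pbest[g].copy(), float(pbest_loss[g])
        history.append(gbest_loss)
        if settings.patience is not None:
            rel_gain = (prev - gbest_loss) / max(abs(prev), 1e-300)
            stagnant = 0 if rel_gain > settings.patience_rel_tol else stagnant + 1
            if stagnant >= settings.patience:
                break

    return FitResult(
        best_theta=gbest,
        best_loss=gbest_loss,
        history=np.asarray(history),
        n_evaluations=n_eval,
        settings=settings,
        final_positions=X,
    )


def fit(problem: EstimationProblem, settings: SwarmSettings | None = None) -> FitResult:
    """Run PSO on the problem's search space and name the result.

    Shared parameters occupy one slot; per-experiment parameters one slot
    per experiment.  The returned result carries the natural-scale values
    keyed by ``name`` or ``name[experiment]``.
    """
    settings = settings or SwarmSettings()

    def objective(theta):
        return sse_objective(theta, problem)

    result = pso_optimize(objective, problem.search_bounds, settings)
    specs = problem.theta_specs
    natural = np.array(
        [s.from_search(v) for s, v in zip(specs, result.best_theta)]
    )
    result.named_parameters = dict(zip(problem.theta_names, natural))
    per_exp = problem.expand(result.best_theta)
    result.per_experiment = [
        {"experiment": e.name, **vals}
        for e, vals in zip(problem.experiments, per_exp)
    ]
    return result


def recovery_experiment(
    problem: EstimationProblem,
    true_values: dict[str, float],
    settings: SwarmSettings | None = None,
) -> dict:
    """Fit a problem whose ground truth is known and report recovery.

    ``true_values`` maps theta names (``name`` or ``name[experiment]``) to
    the generating values.  Reports per-parameter relative error and
    whether each true value lies inside the final swarm's position spread.
    """
    result = fit(problem, settings)
    specs = dict(zip(problem.theta_names, problem.theta_specs))
    final_nat = {
        name: np.array([specs[name].from_search(v) for v in col])
        for name, col in zip(problem.theta_names, result.final_positions.T)
    }
    report = {"best_loss": result.best_loss, "parameters": {}}
    for name, true in true_values.items():
        if name not in result.named_parameters:
            raise KeyError(f"{name} is not a fitted parameter")
        est = result.named_parameters[name]
        swarm = final_nat[name]
        report["parameters"][name] = {
            "true": true,
            "estimate": est,
            "relative_error": abs(est - true) / abs(true) if true != 0 else abs(est),
            "within_swarm_spread": bool(swarm.min() <= true <= swarm.max()),
        }
    report["max_relative_error"] = max(
        (v["relative_error"] for v in report["parameters"].values()), default=0.0
    )
    report["result"] = result
    return report
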