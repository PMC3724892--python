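"""Penalized objective and the two fitting workflows.

Model 1: constant enzyme levels, all 22 rate constants fitted separately per
tissue (44 free parameters over two tissues).  Model 2: transcript-driven
enzyme levels, 22 rate constants fitted to the cotyledon data, then transferred
to the hypocotyl with only the 4 end-product reduction rates re-estimated —
the enzymes' kinetic properties are shared between tissues, so all remaining
between-tissue differences come from measured transcript abundance.

The objective is the time integral of squared relative distance between the
simulated and target end-product curves, plus a weighted integral penalty on
intermediate concentrations exceeding the detection threshold (intermediates
were never observed above it).  Optimization is a seeded evolutionary global
search (differential evolution) followed by bounded local refinement.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .curves import EnzymeProfiles, InterpolatedCurve, TissueProfiles, metabolite_targets
from .errors import InputError, IntegrationError, OptimizationError
from .io import TimeSeriesTable
from .model import (
    CompiledSystem,
    RateParameters,
    SolverSettings,
    propagate_expm,
    simulate,
)
from .topology import PathwayTopology

logger = logging.getLogger(__name__)

#: objective value substituted when the integrator fails on a candidate
FAILURE_SENTINEL = 1e12

#: strict solver used for reported values and final diagnostics
REPORT_SOLVER = SolverSettings(method="LSODA", rtol=1e-8, atol=1e-10)


@dataclass(frozen=True)
class ObjectiveConfig:
    """Objective settings.

    threshold: detection threshold θ for intermediates (µmol kg⁻¹).
    penalty_weight: weight w on the integral of threshold excess.
    grid_step: evaluation grid resolution (days).
    rel_floor: floor δ on the relative-error denominator (µmol kg⁻¹),
        preventing blow-up where target curves approach zero.
    mode: "curve" compares against the PCHIP target curves on the dense grid;
        "points" compares at the measured days only.
    solver: integrator used inside the optimization loop (fast expm default).
    """

    threshold: float = 2.0
    penalty_weight: float = 100.0
    grid_step: float = 0.05
    rel_floor: float = 0.2
    mode: str = "curve"
    solver: SolverSettings = SolverSettings(method="expm")

    def __post_init__(self):
        if self.threshold <= 0 or self.penalty_weight < 0:
            raise InputError("need threshold > 0 and penalty_weight >= 0")
        if self.grid_step <= 0 or self.rel_floor <= 0:
            raise InputError("need grid_step > 0 and rel_floor > 0")
        if self.mode not in ("curve", "points"):
            raise InputError(f"unknown comparison mode {self.mode!r}")


@dataclass(frozen=True)
class GASettings:
    """Global (evolutionary) search stage settings."""

    population: int = 100
    generations: int = 300
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.7
    tol: float = 0.01


@dataclass(frozen=True)
class LocalSettings:
    """Local refinement stage settings (bounded quasi-Newton)."""

    tol: float = 1e-10
    max_iter: int = 300


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters plus objective diagnostics for one fitted tissue."""

    params: RateParameters
    objective_value: float
    seed: int
    free_ids: tuple[str, ...]
    reported_value: float | None = None
    frozen: dict[str, float] | None = None
    tissue: str | None = None
    stage_values: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    trace: dict[str, float] = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return len(self.free_ids)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "objective_value": self.objective_value,
            "reported_value": self.reported_value,
            "seed": self.seed,
            "free_ids": list(self.free_ids),
            "frozen": self.frozen,
            "tissue": self.tissue,
            "stage_values": self.stage_values,
            "converged": self.converged,
            "trace": self.trace,
        }


@dataclass(frozen=True)
class TwoTissueFit:
    """Two-stage Model 2 outcome: cotyledon fit plus hypocotyl transfer."""

    cotyledon: FitResult
    hypocotyl: FitResult

    @property
    def combined_reported(self) -> float:
        return float(self.cotyledon.reported_value + self.hypocotyl.reported_value)

    def to_dict(self) -> dict:
        return {
            "cotyledon": self.cotyledon.to_dict(),
            "hypocotyl": self.hypocotyl.to_dict(),
            "combined_reported": self.combined_reported,
        }


def _common_window(targets: Mapping[str, InterpolatedCurve]) -> tuple[float, float]:
    t0 = max(c.domain[0] for c in targets.values())
    t1 = min(c.domain[1] for c in targets.values())
    if not t0 < t1:
        raise InputError("target curves share no common time window")
    return t0, t1


def initial_state(
    topology: PathwayTopology,
    targets: Mapping[str, InterpolatedCurve],
    t_start: float,
) -> np.ndarray:
    """End products start at their day-`t_start` target value; intermediates at 0
    (below detection)."""
    x0 = np.zeros(len(topology.species_ids))
    for sp in topology.end_products:
        x0[topology.species_index(sp)] = max(0.0, float(targets[sp](t_start)))
    return x0


class PathwayObjective:
    """Callable objective over a free-parameter subset of the rate constants.

    Compiles the topology/profile pair once; per call only the rate-constant
    vector changes.  Exposed attributes (grid, target matrix, free ids) are
    used by the fitting workflows and diagnostics.
    """

    def __init__(
        self,
        topology: PathwayTopology,
        profiles: TissueProfiles,
        targets: Mapping[str, InterpolatedCurve],
        config: ObjectiveConfig = ObjectiveConfig(),
        free_ids: Sequence[str] | None = None,
        frozen: Mapping[str, float] | None = None,
    ):
        missing = [sp for sp in topology.end_products if sp not in targets]
        if missing:
            raise InputError(f"missing end-product target curve(s): {missing}")
        self.topology = topology
        self.config = config
        self.targets = dict(targets)
        self.free_ids = tuple(free_ids) if free_ids is not None else topology.reaction_ids
        self.frozen = dict(frozen) if frozen else {}
        overlap = set(self.free_ids) & set(self.frozen)
        if overlap:
            raise InputError(f"parameters both free and frozen: {sorted(overlap)}")
        declared = set(self.free_ids) | set(self.frozen)
        if declared != set(topology.reaction_ids):
            raise InputError(
                "free + frozen parameters must cover every reaction exactly once"
            )

        t0, t1 = _common_window(targets)
        n = max(1, int(round((t1 - t0) / config.grid_step)))
        self.grid = np.linspace(t0, t1, n + 1)
        h = self.grid[1] - self.grid[0]
        self._w = np.full(len(self.grid), h)
        self._w[0] = self._w[-1] = h / 2  # trapezoid weights

        self._sys = CompiledSystem(topology, profiles)
        mid = 0.5 * (self.grid[:-1] + self.grid[1:])
        self._mid_levels = self._sys.level_matrix(mid)
        self._free_idx = np.array(
            [topology.reaction_ids.index(r) for r in self.free_ids], dtype=int
        )
        self._k_base = np.zeros(len(topology.reaction_ids))
        for rid, v in self.frozen.items():
            self._k_base[topology.reaction_ids.index(rid)] = v

        self._end_idx = np.array(
            [topology.species_index(s) for s in topology.end_products], dtype=int
        )
        self._int_idx = np.array(
            [topology.species_index(s) for s in topology.intermediates], dtype=int
        )
        C = np.stack([targets[s](self.grid) for s in topology.end_products])
        self._C = C
        self._denom = np.maximum(C, config.rel_floor)
        self.x0 = initial_state(topology, targets, t0)
        if config.mode == "points":
            days = sorted(set().union(*(map(float, targets[s].days) for s in topology.end_products)))
            self._point_cols = np.array(
                [int(np.argmin(np.abs(self.grid - d))) for d in days]
            )
        else:
            self._point_cols = None

    def full_params(self, theta: np.ndarray) -> np.ndarray:
        k = self._k_base.copy()
        k[self._free_idx] = theta
        return k

    def _simulate(self, k: np.ndarray) -> np.ndarray:
        self._sys.k = k
        if self.config.solver.method == "expm":
            return propagate_expm(self._sys, self.x0, self.grid, self._mid_levels)
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            self._sys.rhs,
            (self.grid[0], self.grid[-1]),
            self.x0,
            method=self.config.solver.method,
            t_eval=self.grid,
            rtol=self.config.solver.rtol,
            atol=self.config.solver.atol,
            jac=self._sys.jac,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError("integration failed inside objective")
        return sol.y.T

    def __call__(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        try:
            X = self._simulate(self.full_params(theta))
        except (IntegrationError, FloatingPointError, OverflowError) as e:
            logger.warning("objective: integration failure (%s); sentinel returned", e)
            return FAILURE_SENTINEL
        resid = (X[:, self._end_idx].T - self._C) / self._denom
        if self._point_cols is not None:
            data = float(np.sum(resid[:, self._point_cols] ** 2))
        else:
            data = float(np.sum(resid**2 * self._w))
        excess = np.maximum(0.0, X[:, self._int_idx].T - self.config.threshold)
        penalty = float(self.config.penalty_weight * np.sum(excess * self._w))
        return data + penalty

    def trajectory(self, theta: np.ndarray) -> np.ndarray:
        """States on the evaluation grid for a free-parameter vector."""
        return self._simulate(self.full_params(theta))


def objective(
    params: RateParameters,
    topology: PathwayTopology,
    profiles: EnzymeProfiles | TissueProfiles,
    targets: Mapping[str, InterpolatedCurve],
    config: ObjectiveConfig = ObjectiveConfig(),
    tissue: str | None = None,
) -> float:
    """One-shot penalized objective for a complete parameter set."""
    tp = profiles if isinstance(profiles, TissueProfiles) else profiles.for_tissue(tissue)
    fn = PathwayObjective(topology, tp, targets, config)
    return fn(params.as_array(topology))


def relative_sse_at_days(
    params: RateParameters,
    topology: PathwayTopology,
    profiles: EnzymeProfiles | TissueProfiles,
    targets: Mapping[str, InterpolatedCurve],
    config: ObjectiveConfig = ObjectiveConfig(),
    tissue: str | None = None,
    solver: SolverSettings = REPORT_SOLVER,
) -> float:
    """Reported fit metric: sum of squared relative residuals over the four
    end products at the measured days (unweighted; distinct from the
    optimization objective)."""
    tp = profiles if isinstance(profiles, TissueProfiles) else profiles.for_tissue(tissue)
    t0, t1 = _common_window(targets)
    x0 = initial_state(topology, targets, t0)
    traj = simulate(topology, params, tp, x0, t0, t1, settings=solver)
    total = 0.0
    for sp in topology.end_products:
        curve = targets[sp]
        days = curve.days[(curve.days >= t0 - 1e-9) & (curve.days <= t1 + 1e-9)]
        model = np.interp(days, traj.t, traj.series(sp))
        c = curve(days)
        total += float(np.sum(((model - c) / np.maximum(c, config.rel_floor)) ** 2))
    return total


def _sample_population(
    rng: np.random.Generator, bounds: np.ndarray, size: int
) -> np.ndarray:
    """Initial population: log-uniform over each parameter's box (rates span
    orders of magnitude; uniform sampling would almost never propose small
    rates), with a floor at 1e-5 of the upper bound."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    pop = np.empty((size, len(lo)))
    for j in range(len(lo)):
        if span[j] <= 0:
            pop[:, j] = lo[j]
            continue
        lo_eff = max(lo[j], hi[j] * 1e-5)
        pop[:, j] = np.exp(rng.uniform(np.log(lo_eff), np.log(hi[j]), size))
    return np.clip(pop, lo, hi)


def optimize_rates(
    objective_fn: Callable[[np.ndarray], float],
    n_params: int,
    bounds: Sequence[tuple[float, float]],
    global_settings: GASettings = GASettings(),
    local_settings: LocalSettings = LocalSettings(),
    seed: int = 0,
    param_ids: Sequence[str] | None = None,
) -> FitResult:
    """Evolutionary global search followed by bounded local refinement.

    The local result is kept only if it improves on the global stage.  Fully
    deterministic for a fixed seed.
    """
    if n_params < 1:
        raise InputError("n_params must be >= 1")
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (n_params, 2) or not np.all(np.isfinite(bounds)):
        raise InputError("bounds must be finite and one (low, high) pair per parameter")
    ids = tuple(param_ids) if param_ids is not None else tuple(
        f"p{i}" for i in range(n_params)
    )

    if np.all(bounds[:, 1] - bounds[:, 0] <= 0):
        x = bounds[:, 0].copy()
        fun = float(objective_fn(x))
        return FitResult(
            params=RateParameters(dict(zip(ids, x))),
            objective_value=fun,
            seed=seed,
            free_ids=ids,
            stage_values={"global": fun, "local": fun},
            converged=True,
            trace={"nfev": 1.0},
        )

    rng = np.random.default_rng(seed)
    pop = _sample_population(rng, bounds, max(5, global_settings.population))
    de = differential_evolution(
        objective_fn,
        bounds,
        init=pop,
        maxiter=global_settings.generations,
        mutation=global_settings.mutation,
        recombination=global_settings.recombination,
        tol=global_settings.tol,
        rng=rng,
        polish=False,
        updating="immediate",
    )
    if not np.isfinite(de.fun):
        raise OptimizationError(
            "objective non-finite at every sampled point of the global stage"
        )
    best_x, best_f = np.asarray(de.x), float(de.fun)

    loc = minimize(
        objective_fn,
        best_x,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": local_settings.max_iter, "ftol": local_settings.tol},
    )
    stage = {"global": best_f, "local": float(loc.fun)}
    improved = np.isfinite(loc.fun) and loc.fun < best_f
    if improved:
        best_x, best_f = np.asarray(loc.x), float(loc.fun)
    return FitResult(
        params=RateParameters(dict(zip(ids, np.maximum(best_x, 0.0)))),
        objective_value=best_f,
        seed=seed,
        free_ids=ids,
        stage_values=stage,
        converged=bool(de.success or loc.success),
        trace={"nfev": float(de.nfev + loc.nfev), "nit_global": float(de.nit)},
    )


#: default parameter bounds: [0, 10³] day⁻¹ (conversion/reduction) and
#: [0, 10³] µmol kg⁻¹ day⁻¹ (influx)
DEFAULT_RATE_BOUND = 1e3


def _default_bounds(n: int, upper: float = DEFAULT_RATE_BOUND) -> list[tuple[float, float]]:
    return [(0.0, upper)] * n


def _check_table(table: TimeSeriesTable, tissue: str) -> None:
    if len(table.days) < 2:
        raise InputError(f"tissue {tissue!r}: fewer than 2 sampling days")


def fit_constant_model(
    tables: Mapping[str, TimeSeriesTable],
    topology: PathwayTopology,
    config: ObjectiveConfig = ObjectiveConfig(),
    global_settings: GASettings = GASettings(),
    local_settings: LocalSettings = LocalSettings(),
    seed: int = 0,
    bound: float = DEFAULT_RATE_BOUND,
) -> dict[str, FitResult]:
    """Model 1: constant enzyme levels, all rate constants fitted per tissue.

    Each tissue is an independent 22-parameter problem; over the default two
    tissues 44 parameters are estimated in total.
    """
    from .curves import constant_profiles

    if len(tables) < 1:
        raise InputError("no metabolite tables given")
    profiles = constant_profiles(topology, sorted(tables))
    results: dict[str, FitResult] = {}
    for i, tissue in enumerate(sorted(tables)):
        _check_table(tables[tissue], tissue)
        targets = metabolite_targets(tables[tissue], topology)
        fn = PathwayObjective(
            topology, profiles.for_tissue(tissue), targets, config
        )
        fit = optimize_rates(
            fn,
            len(fn.free_ids),
            _default_bounds(len(fn.free_ids), bound),
            global_settings,
            local_settings,
            seed=seed + i,
            param_ids=fn.free_ids,
        )
        fit = dataclasses.replace(
            fit,
            tissue=tissue,
            objective_value=objective(
                fit.params, topology, profiles.for_tissue(tissue), targets,
                dataclasses.replace(config, solver=REPORT_SOLVER),
            ),
            reported_value=relative_sse_at_days(
                fit.params, topology, profiles.for_tissue(tissue), targets, config
            ),
        )
        results[tissue] = fit
    return results


def fit_transcript_model(
    cotyledon_table: TimeSeriesTable,
    profiles: EnzymeProfiles,
    topology: PathwayTopology,
    config: ObjectiveConfig = ObjectiveConfig(),
    global_settings: GASettings = GASettings(),
    local_settings: LocalSettings = LocalSettings(),
    seed: int = 0,
    tissue: str = "cotyledons",
    bound: float = DEFAULT_RATE_BOUND,
) -> FitResult:
    """Model 2 stage 1: fit all 22 rate constants against the cotyledon data,
    with transcript curves modulating every enzymatic reaction."""
    _check_table(cotyledon_table, tissue)
    targets = metabolite_targets(cotyledon_table, topology)
    tp = profiles.for_tissue(tissue)
    fn = PathwayObjective(topology, tp, targets, config)
    fit = optimize_rates(
        fn,
        len(fn.free_ids),
        _default_bounds(len(fn.free_ids), bound),
        global_settings,
        local_settings,
        seed=seed,
        param_ids=fn.free_ids,
    )
    return dataclasses.replace(
        fit,
        tissue=tissue,
        objective_value=objective(
            fit.params, topology, tp, targets,
            dataclasses.replace(config, solver=REPORT_SOLVER),
        ),
        reported_value=relative_sse_at_days(fit.params, topology, tp, targets, config),
    )


def refit_reduction_rates(
    cotyledon_fit: FitResult,
    hypocotyl_table: TimeSeriesTable,
    profiles: EnzymeProfiles,
    topology: PathwayTopology,
    config: ObjectiveConfig = ObjectiveConfig(),
    global_settings: GASettings = GASettings(),
    local_settings: LocalSettings = LocalSettings(),
    seed: int = 0,
    tissue: str = "hypocotyls",
    bound: float = DEFAULT_RATE_BOUND,
) -> FitResult:
    """Model 2 stage 2: transfer the cotyledon estimates to the hypocotyl.

    Influx and conversion constants are frozen at their cotyledon values (the
    enzymes' kinetic properties are tissue-invariant); only the 4 reduction
    rates are re-optimized against the hypocotyl data under hypocotyl
    transcript profiles.
    """
    _check_table(hypocotyl_table, tissue)
    if tissue not in profiles.profiles:
        raise InputError(f"transcript profiles missing tissue {tissue!r}")
    targets = metabolite_targets(hypocotyl_table, topology)
    tp = profiles.for_tissue(tissue)
    free = topology.reduction_ids
    frozen = {
        rid: cotyledon_fit.params[rid] for rid in topology.non_reduction_ids
    }
    fn = PathwayObjective(topology, tp, targets, config, free_ids=free, frozen=frozen)
    fit = optimize_rates(
        fn,
        len(free),
        _default_bounds(len(free), bound),
        global_settings,
        local_settings,
        seed=seed,
        param_ids=free,
    )
    full = RateParameters({**frozen, **fit.params.to_dict()})
    return dataclasses.replace(
        fit,
        params=full,
        frozen=frozen,
        tissue=tissue,
        objective_value=objective(
            full, topology, tp, targets,
            dataclasses.replace(config, solver=REPORT_SOLVER),
        ),
        reported_value=relative_sse_at_days(full, topology, tp, targets, config),
    )


def fit_two_stage(
    tables: Mapping[str, TimeSeriesTable],
    profiles: EnzymeProfiles,
    topology: PathwayTopology,
    config: ObjectiveConfig = ObjectiveConfig(),
    global_settings: GASettings = GASettings(),
    local_settings: LocalSettings = LocalSettings(),
    seed: int = 0,
    cotyledon: str = "cotyledons",
    hypocotyl: str = "hypocotyls",
    bound: float = DEFAULT_RATE_BOUND,
) -> TwoTissueFit:
    """Full Model 2 workflow: cotyledon fit, then hypocotyl reduction-rate refit."""
    cot = fit_transcript_model(
        tables[cotyledon], profiles, topology, config,
        global_settings, local_settings, seed=seed, tissue=cotyledon, bound=bound,
    )
    hyp = refit_reduction_rates(
        cot, tables[hypocotyl], profiles, topology, config,
        global_settings, local_settings, seed=seed + 1, tissue=hypocotyl, bound=bound,
    )
    return TwoTissueFit(cotyledon=cot, hypocotyl=hyp)
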