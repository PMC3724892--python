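"""Linear-kinetics ODE system on the pathway network and its simulator.

Every reaction flux is the low-substrate limit of Michaelis–Menten kinetics:
rate = c · E(t) · S, with c a lumped rate constant (k_cat·E_scale/K_M folded
together), E(t) the dimensionless enzyme-activity proxy, and S the substrate
concentration.  Influx reactions omit the substrate factor (the upstream
flavanone pool is lumped into the influx constant); reduction reactions omit
the enzyme factor (first-order loss).  The resulting system is linear and
time-varying, integrated with a stiff-capable implicit solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .curves import EnzymeProfiles, TissueProfiles
from .errors import DomainError, InputError, IntegrationError
from .topology import PathwayTopology


@dataclass(frozen=True)
class RateParameters:
    """Non-negative lumped rate constants, one per reaction.

    Units: day⁻¹ for conversion and reduction reactions, µmol kg⁻¹ day⁻¹ for
    the influx reaction.
    """

    values: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))
        for rid, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise InputError(f"rate constant {rid!r} must be finite and >= 0, got {v}")

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]

    def as_array(self, topology: PathwayTopology) -> np.ndarray:
        missing = [r for r in topology.reaction_ids if r not in self.values]
        extra = [r for r in self.values if r not in topology.reaction_ids]
        if missing or extra:
            raise InputError(
                f"parameters do not match topology (missing {missing}, extra {extra})"
            )
        return np.array([self.values[r] for r in topology.reaction_ids], dtype=float)

    @staticmethod
    def from_array(topology: PathwayTopology, values: np.ndarray) -> "RateParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(topology.reaction_ids),):
            raise InputError(
                f"expected {len(topology.reaction_ids)} values, got shape {values.shape}"
            )
        return RateParameters(dict(zip(topology.reaction_ids, values)))

    def to_dict(self) -> dict[str, float]:
        return dict(self.values)


@dataclass(frozen=True)
class SolverSettings:
    """ODE solver configuration.

    ``method`` is any scipy ``solve_ivp`` method name (stiff-capable "LSODA" by
    default), or ``"expm"`` for the exponential-midpoint (Magnus) propagator —
    an unconditionally stable fixed-grid integrator exact for frozen
    coefficients, exploiting that the system is linear and time-varying.  The
    expm path also preserves nonnegativity exactly (the system matrix is
    Metzler), and is the default inner-loop integrator during fitting.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    grid_step: float = 0.05  # days, dense output resolution


@dataclass(frozen=True)
class Trajectory:
    """Dense simulated concentration time courses (µmol kg⁻¹ vs day)."""

    t: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    species: tuple[str, ...]

    def series(self, species_id: str) -> np.ndarray:
        try:
            return self.states[:, self.species.index(species_id)]
        except ValueError:
            raise InputError(f"unknown species {species_id!r}") from None

    @property
    def t_start(self) -> float:
        return float(self.t[0])

    @property
    def t_end(self) -> float:
        return float(self.t[-1])


def reaction_rate(rate_constant: float, enzyme_level: float, substrate: float | None = None) -> float:
    """Flux of a single reaction: ``c·E·S`` (or ``c·E`` for influx, substrate omitted).

    This is the initial slope of the Michaelis–Menten curve — valid because the
    modeled substrate pools stay near or below the detection threshold.
    """
    args = (rate_constant, enzyme_level) + (() if substrate is None else (substrate,))
    for a in args:
        if a < 0:
            raise DomainError(f"reaction_rate arguments must be >= 0, got {args}")
    flux = rate_constant * enzyme_level
    return flux if substrate is None else flux * substrate


class CompiledSystem:
    """Topology + profiles compiled to index arrays for fast rhs/jacobian calls.

    The rate-constant vector ``k`` (aligned with ``topology.reaction_ids``) is a
    plain attribute so optimizers can swap parameters without recompiling.
    """

    def __init__(
        self,
        topology: PathwayTopology,
        profiles: TissueProfiles,
        k: np.ndarray | None = None,
    ):
        self.topology = topology
        self.profiles = profiles
        n_sp = len(topology.species_ids)
        sp_idx = {s: i for i, s in enumerate(topology.species_ids)}
        enz_idx = {e: i for i, e in enumerate(topology.enzymes)}
        rx = topology.reactions
        self.n_species = n_sp
        self.src = np.array([sp_idx[r.source] if r.source else -1 for r in rx])
        self.tgt = np.array([sp_idx[r.target] if r.target else -1 for r in rx])
        self.enz = np.array([enz_idx[r.enzyme] if r.enzyme else -1 for r in rx])
        self._has_src = self.src >= 0
        self._has_tgt = self.tgt >= 0
        self._has_enz = self.enz >= 0
        self._src_c = np.maximum(self.src, 0)
        self._enz_c = np.maximum(self.enz, 0)
        self._eval_enzymes = profiles.compile(topology.enzymes)
        self.k = (
            np.zeros(len(rx)) if k is None else np.asarray(k, dtype=float).copy()
        )

    def enzyme_levels(self, t: float) -> np.ndarray:
        return self._eval_enzymes(t)

    def rate_coefficients(self, t: float) -> np.ndarray:
        """k·E(t) per reaction (enzyme factor 1 where no enzyme is attached)."""
        E = self._eval_enzymes(t)
        lvl = np.where(self._has_enz, E[self._enz_c], 1.0)
        return self.k * lvl

    def rates(self, t: float, x: np.ndarray) -> np.ndarray:
        kE = self.rate_coefficients(t)
        sub = np.where(self._has_src, x[self._src_c], 1.0)
        return kE * sub

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        r = self.rates(t, x)
        dx = np.zeros(self.n_species)
        np.add.at(dx, self.tgt[self._has_tgt], r[self._has_tgt])
        np.subtract.at(dx, self.src[self._has_src], r[self._has_src])
        return dx

    def jac(self, t: float, x: np.ndarray) -> np.ndarray:
        A, _ = self.assemble(self.rate_coefficients(t))
        return A

    def assemble(self, kE: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """System matrix A and influx vector b such that x' = A·x + b."""
        A = np.zeros((self.n_species, self.n_species))
        b = np.zeros(self.n_species)
        m = self._has_src
        both = m & self._has_tgt
        np.add.at(A, (self.tgt[both], self.src[both]), kE[both])
        np.subtract.at(A, (self.src[m], self.src[m]), kE[m])
        np.add.at(b, self.tgt[~m], kE[~m])
        return A, b

    def level_matrix(self, times: np.ndarray) -> np.ndarray:
        """Enzyme-level factor per (reaction, time); 1 for enzyme-free reactions.

        Precomputable once per fit: levels depend on the profiles only, not on
        the rate constants being optimized.
        """
        out = np.ones((len(self.k), len(times)))
        for j, t in enumerate(times):
            E = self._eval_enzymes(float(t))
            out[self._has_enz, j] = E[self._enz_c[self._has_enz]]
        return out


def propagate_expm(
    sys: CompiledSystem,
    x0: np.ndarray,
    grid: np.ndarray,
    midpoint_levels: np.ndarray | None = None,
) -> np.ndarray:
    """Integrate the linear time-varying system with the exponential-midpoint rule.

    Per grid step the coefficients are frozen at the interval midpoint and the
    augmented system (state ⊕ constant 1 carrying the influx) is advanced with
    one matrix exponential.  Second-order accurate in the coefficients' time
    variation, unconditionally stable, exactly nonnegativity-preserving.
    ``midpoint_levels`` may carry :meth:`CompiledSystem.level_matrix` evaluated
    at the interval midpoints to skip per-step profile evaluation.
    """
    n = sys.n_species
    X = np.empty((len(grid), n))
    X[0] = x0
    x = np.append(np.asarray(x0, dtype=float), 1.0)
    M = np.zeros((n + 1, n + 1))
    for i in range(len(grid) - 1):
        h = grid[i + 1] - grid[i]
        if midpoint_levels is None:
            kE = sys.rate_coefficients(0.5 * (grid[i] + grid[i + 1]))
        else:
            kE = sys.k * midpoint_levels[:, i]
        A, b = sys.assemble(kE)
        M[:n, :n] = h * A
        M[:n, n] = h * b
        x = expm(M) @ x
        X[i + 1] = x[:n]
    if not np.all(np.isfinite(X)):
        bad = int(np.argmax(~np.isfinite(X).all(axis=1)))
        raise IntegrationError(
            f"expm propagation produced non-finite state at t={grid[bad]}",
            last_valid_time=float(grid[max(bad - 1, 0)]),
        )
    return X


def _resolve_profiles(
    profiles: EnzymeProfiles | TissueProfiles, tissue: str | None
) -> TissueProfiles:
    if isinstance(profiles, TissueProfiles):
        return profiles
    if tissue is None:
        tissues = profiles.tissues
        if len(tissues) != 1:
            raise InputError(
                f"profiles cover tissues {tissues}; pass tissue= to pick one"
            )
        tissue = tissues[0]
    return profiles.for_tissue(tissue)


def rhs(
    t: float,
    state: np.ndarray,
    params: RateParameters,
    profiles: EnzymeProfiles | TissueProfiles,
    topology: PathwayTopology,
    tissue: str | None = None,
) -> np.ndarray:
    """Per-species derivative at time ``t`` (µmol kg⁻¹ day⁻¹).

    Each species' derivative is the sum of incoming reaction fluxes minus the
    sum of outgoing ones.  ``t`` must lie inside the profile domain; evaluation
    outside it raises :class:`DomainError`.
    """
    tp = _resolve_profiles(profiles, tissue)
    lo, hi = tp.domain
    if t < lo - 1e-9 or t > hi + 1e-9:
        raise DomainError(f"t={t} outside enzyme-profile domain [{lo}, {hi}]")
    state = np.asarray(state, dtype=float)
    if state.shape != (len(topology.species_ids),):
        raise InputError(
            f"state length {state.shape} does not match species count "
            f"{len(topology.species_ids)}"
        )
    sys = CompiledSystem(topology, tp, params.as_array(topology))
    return sys.rhs(t, state)


def simulate(
    topology: PathwayTopology,
    params: RateParameters | np.ndarray,
    profiles: EnzymeProfiles | TissueProfiles,
    initial_state: np.ndarray | Mapping[str, float],
    t_start: float = 5.0,
    t_end: float = 9.0,
    settings: SolverSettings = SolverSettings(),
    tissue: str | None = None,
) -> Trajectory:
    """Integrate the pathway ODEs on a dense grid over [t_start, t_end]."""
    tp = _resolve_profiles(profiles, tissue)
    lo, hi = tp.domain
    if not t_start < t_end:
        raise InputError(f"need t_start < t_end, got [{t_start}, {t_end}]")
    if t_start < lo - 1e-9 or t_end > hi + 1e-9:
        raise DomainError(
            f"window [{t_start}, {t_end}] outside enzyme-profile domain [{lo}, {hi}]"
        )
    if isinstance(initial_state, Mapping):
        x0 = np.array(
            [float(initial_state.get(s, 0.0)) for s in topology.species_ids]
        )
    else:
        x0 = np.asarray(initial_state, dtype=float)
    if x0.shape != (len(topology.species_ids),):
        raise InputError("initial_state length does not match species count")
    if np.any(x0 < 0):
        raise InputError(f"initial_state must be non-negative, got {x0}")
    k = params.as_array(topology) if isinstance(params, RateParameters) else np.asarray(params, float)
    sys = CompiledSystem(topology, tp, k)

    n_steps = max(1, int(round((t_end - t_start) / settings.grid_step)))
    grid = np.linspace(t_start, t_end, n_steps + 1)
    if settings.method == "expm":
        states = propagate_expm(sys, x0, grid)
        return Trajectory(t=grid, states=states, species=topology.species_ids)
    sol = solve_ivp(
        sys.rhs,
        (t_start, t_end),
        x0,
        method=settings.method,
        t_eval=grid,
        rtol=settings.rtol,
        atol=settings.atol,
        jac=sys.jac,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        last = float(sol.t[-1]) if sol.t.size else t_start
        raise IntegrationError(
            f"integration failed at t={last}: {sol.message}", last_valid_time=last
        )
    return Trajectory(t=sol.t, states=sol.y.T, species=topology.species_ids)
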