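"""Smooth time functions from sparse measurements.

Metabolite means and transcript abundances are interpolated with shape-preserving
piecewise cubic Hermite polynomials (PCHIP); Model 1 uses constant enzyme
profiles instead.  Transcript profiles are max-normalized per enzyme with one
normalization constant shared across tissues, so the dimensionless levels lie in
(0, 1] and cross-tissue expression ratios are preserved (the absolute transcript
scale is unidentifiable — it is absorbed into the fitted rate constants).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DomainError, InputError
from .io import TimeSeriesTable
from .topology import PathwayTopology

_DOMAIN_SLACK = 1e-9


@dataclass(frozen=True)
class InterpolatedCurve:
    """Shape-preserving cubic interpolant through (day, value) knots.

    Evaluable only on [first knot, last knot]; evaluation outside the span
    raises :class:`DomainError` (no silent extrapolation).
    """

    days: np.ndarray
    values: np.ndarray
    _interp: PchipInterpolator = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "days", np.asarray(self.days, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self._interp is None:
            object.__setattr__(
                self, "_interp", PchipInterpolator(self.days, self.values, extrapolate=True)
            )

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.days[0]), float(self.days[-1])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any(t < lo - _DOMAIN_SLACK) or np.any(t > hi + _DOMAIN_SLACK):
            raise DomainError(
                f"evaluation at t={t} outside curve domain [{lo}, {hi}]"
            )
        out = self._interp(np.clip(t, lo, hi))
        return float(out) if out.ndim == 0 else out

    def clamped(self, t):
        """Evaluate with the argument clipped into the domain (solver-internal use)."""
        lo, hi = self.domain
        return self._interp(np.clip(t, lo, hi))

    def scaled(self, factor: float) -> "InterpolatedCurve":
        return fit_pchip(list(zip(self.days, self.values * factor)))


def fit_pchip(points) -> InterpolatedCurve:
    """PCHIP interpolant through ``points`` ((day, value) pairs or two arrays)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InputError("fit_pchip needs at least two (day, value) pairs")
    days, values = pts[:, 0], pts[:, 1]
    if not np.all(np.isfinite(pts)):
        raise InputError("fit_pchip: non-finite day or value")
    if np.any(np.diff(days) <= 0):
        raise InputError("fit_pchip: days must be strictly increasing (no duplicates)")
    return InterpolatedCurve(days, values)


class TissueProfiles:
    """Per-enzyme time functions for one tissue, with a fast vector evaluator."""

    def __init__(self, levels: Mapping[str, InterpolatedCurve | float], tissue: str = ""):
        self.tissue = tissue
        self.levels = dict(levels)

    @property
    def domain(self) -> tuple[float, float]:
        lo, hi = -np.inf, np.inf
        for v in self.levels.values():
            if isinstance(v, InterpolatedCurve):
                lo = max(lo, v.domain[0])
                hi = min(hi, v.domain[1])
        return lo, hi

    def level(self, enzyme: str, t) -> float:
        v = self.levels[enzyme]
        return v(t) if isinstance(v, InterpolatedCurve) else float(v)

    def compile(self, enzyme_order: tuple[str, ...]) -> Callable[[float], np.ndarray]:
        """Return ``f(t) -> levels`` aligned with ``enzyme_order``.

        Enzymes sharing a common knot grid are evaluated with a single joint
        PCHIP call; the evaluator clamps ``t`` into the profile domain (the ODE
        solver may probe marginally past the window ends).
        """
        missing = [e for e in enzyme_order if e not in self.levels]
        if missing:
            raise InputError(f"tissue {self.tissue!r}: missing enzyme profile(s) {missing}")
        const = np.array(
            [
                self.levels[e] if not isinstance(self.levels[e], InterpolatedCurve) else 0.0
                for e in enzyme_order
            ],
            dtype=float,
        )
        curve_idx = [
            i for i, e in enumerate(enzyme_order)
            if isinstance(self.levels[e], InterpolatedCurve)
        ]
        if not curve_idx:
            base = const.copy()
            return lambda t: base.copy()
        curves = [self.levels[enzyme_order[i]] for i in curve_idx]
        days0 = curves[0].days
        joint = None
        if all(len(c.days) == len(days0) and np.array_equal(c.days, days0) for c in curves):
            joint = PchipInterpolator(
                days0, np.column_stack([c.values for c in curves]), extrapolate=True
            )
            lo, hi = float(days0[0]), float(days0[-1])

            def evaluate(t: float) -> np.ndarray:
                out = const.copy()
                out[curve_idx] = joint(min(max(t, lo), hi))
                return out

            return evaluate

        def evaluate(t: float) -> np.ndarray:
            out = const.copy()
            for i, c in zip(curve_idx, curves):
                out[i] = c.clamped(t)
            return out

        return evaluate


@dataclass
class EnzymeProfiles:
    """Per-tissue, per-enzyme activity proxies (constant or transcript curves).

    ``normalization`` records the per-enzyme global maximum that was divided out,
    so normalized levels can be traced back to the input scale.
    """

    profiles: dict[str, dict[str, InterpolatedCurve | float]]
    normalization: dict[str, float] | None = None

    @property
    def tissues(self) -> list[str]:
        return sorted(self.profiles)

    @property
    def enzymes(self) -> list[str]:
        first = self.profiles[next(iter(self.profiles))]
        return sorted(first)

    def for_tissue(self, tissue: str) -> TissueProfiles:
        if tissue not in self.profiles:
            raise InputError(f"no profiles for tissue {tissue!r}")
        return TissueProfiles(self.profiles[tissue], tissue)

    def level(self, tissue: str, enzyme: str, t) -> float:
        return self.for_tissue(tissue).level(enzyme, t)


def constant_profiles(
    topology: PathwayTopology, tissues: list[str] | tuple[str, ...]
) -> EnzymeProfiles:
    """Unit enzyme levels for every (tissue, enzyme): the fitted rate constant
    then absorbs the (assumed constant) enzyme concentration."""
    return EnzymeProfiles(
        profiles={t: {e: 1.0 for e in topology.enzymes} for t in tissues},
        normalization=None,
    )


def normalize_transcript_profiles(
    tables: Mapping[str, TimeSeriesTable], log2_input: bool = False
) -> EnzymeProfiles:
    """Max-normalized PCHIP transcript curves per (tissue, enzyme).

    Replicates are averaged per (tissue, enzyme, day); with ``log2_input`` the
    values are first linearized as ``2**value`` (microarray summaries such as RMA
    are reported on a log2 scale).  Each enzyme's means in *both* tissues are
    divided by that enzyme's global maximum, so for every enzyme the maximum over
    tissues and days is exactly 1 and cross-tissue ratios are preserved.
    """
    tissues = sorted(tables)
    if not tissues:
        raise InputError("no transcript tables given")
    enzymes_per_tissue = {t: set(tables[t].entities) for t in tissues}
    all_enzymes = sorted(set().union(*enzymes_per_tissue.values()))
    missing = {
        t: sorted(set(all_enzymes) - enzymes_per_tissue[t]) for t in tissues
    }
    missing = {t: m for t, m in missing.items() if m}
    if missing:
        raise InputError(f"enzyme(s) missing in some tissue(s): {missing}")

    means: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for t in tissues:
        m = tables[t].means()
        means[t] = {}
        for e in all_enzymes:
            sub = m[m["entity"] == e]
            days = sub["day"].to_numpy()
            vals = sub["value"].to_numpy()
            if len(days) < 2:
                raise InputError(
                    f"enzyme {e!r} in tissue {t!r} has < 2 sampling days"
                )
            if log2_input:
                vals = np.power(2.0, vals)
            means[t][e] = (days, vals)

    normalization = {
        e: float(max(means[t][e][1].max() for t in tissues)) for e in all_enzymes
    }
    for e, mx in normalization.items():
        if mx <= 0:
            raise InputError(f"enzyme {e!r}: non-positive global maximum {mx}")

    profiles = {
        t: {
            e: fit_pchip(list(zip(means[t][e][0], means[t][e][1] / normalization[e])))
            for e in all_enzymes
        }
        for t in tissues
    }
    return EnzymeProfiles(profiles=profiles, normalization=normalization)


def metabolite_targets(
    table: TimeSeriesTable, topology: PathwayTopology
) -> dict[str, InterpolatedCurve]:
    """PCHIP target curves through replicate-mean end-product concentrations."""
    m = table.means()
    targets = {}
    for sp in topology.end_products:
        sub = m[m["entity"] == sp]
        if len(sub) < 2:
            raise InputError(
                f"end product {sp!r}: fewer than 2 measured days in table"
            )
        targets[sp] = fit_pchip(list(zip(sub["day"], sub["value"])))
    return targets
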