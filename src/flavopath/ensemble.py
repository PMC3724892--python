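"""Multi-start identifiability analysis ("sloppy model" ensembles).

The pathway's multiple routes to each end product, combined with intermediates
being observable only as "below detection", leave many rate-constant
combinations unconstrained: independent optimization runs reach comparably
good fits with very different parameter vectors, and many runs set individual
edges to (near) zero.  This module repeats the fitting workflow from
independent seeds and summarizes per-edge usage percentages, the solid/dashed
edge classification (an edge is drawn solid when used in more than 2/3 of
runs), and fit-quality statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import EnzymeProfiles
from .errors import FlavopathError, InputError
from .fitting import (
    FitResult,
    GASettings,
    LocalSettings,
    ObjectiveConfig,
    TwoTissueFit,
    fit_constant_model,
    fit_two_stage,
)
from .io import TimeSeriesTable
from .model import RateParameters
from .topology import PathwayTopology

logger = logging.getLogger(__name__)

#: a rate constant above this (day⁻¹) counts as the edge being "used"
DEFAULT_USE_EPS = 1e-6

#: solid/dashed classification threshold in percent: solid iff usage
#: strictly above 200/3 %
SOLID_THRESHOLD_PERCENT = 200.0 / 3.0


@dataclass(frozen=True)
class EnsembleResult:
    """Collection of independent fits plus edge-usage and fit statistics."""

    fits: tuple[TwoTissueFit | FitResult, ...]
    usage: dict[str, float]  # reaction id -> % of successful fits using it
    classification: dict[str, str]  # reaction id -> "solid" | "dashed"
    statistics: dict[str, float]  # mean/best/worst of reported fit values
    fraction_all_used: float
    n_failures: int
    base_seed: int
    topology: PathwayTopology = field(repr=False, compare=False, default=None)

    @property
    def n_runs(self) -> int:
        return len(self.fits) + self.n_failures

    def to_dict(self) -> dict:
        return {
            "usage_percent": dict(self.usage),
            "classification": dict(self.classification),
            "statistics": dict(self.statistics),
            "fraction_all_used": self.fraction_all_used,
            "n_failures": self.n_failures,
            "n_runs": self.n_runs,
            "base_seed": self.base_seed,
            "fits": [f.to_dict() for f in self.fits],
        }

    def usage_table(self) -> pd.DataFrame:
        """Edge-usage table mirroring the summary-network annotations."""
        rows = []
        for r in self.topology.reactions:
            rows.append(
                {
                    "reaction": r.id,
                    "kind": r.kind,
                    "enzyme": r.enzyme or "",
                    "source": r.source or "",
                    "target": r.target or "",
                    "usage_percent": self.usage[r.id],
                    "classification": self.classification[r.id],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.usage_table().to_csv(path, index=False)


def _fit_params(fit: TwoTissueFit | FitResult) -> RateParameters:
    """Parameter set used for edge-usage accounting.

    For two-stage fits this is the stage-1 (cotyledon) set: conversion rates
    are shared between tissues there, and its reduction rates stand for the
    edge's presence.
    """
    return fit.cotyledon.params if isinstance(fit, TwoTissueFit) else fit.params


def _reported(fit: TwoTissueFit | FitResult) -> float:
    if isinstance(fit, TwoTissueFit):
        return fit.combined_reported
    return float(fit.reported_value)


def edge_usage(
    fits: Sequence[TwoTissueFit | FitResult],
    topology: PathwayTopology,
    eps: float = DEFAULT_USE_EPS,
) -> tuple[dict[str, float], float]:
    """Percentage of fits in which each reaction's rate constant exceeds ``eps``,
    plus the fraction of fits using every reaction."""
    if eps <= 0:
        raise InputError("eps must be > 0")
    if not fits:
        raise InputError("edge_usage: empty fit list")
    counts = {rid: 0 for rid in topology.reaction_ids}
    n_all = 0
    for f in fits:
        params = _fit_params(f)
        used = {rid: params[rid] > eps for rid in topology.reaction_ids}
        for rid, u in used.items():
            counts[rid] += int(u)
        n_all += int(all(used.values()))
    n = len(fits)
    usage = {rid: 100.0 * c / n for rid, c in counts.items()}
    return usage, n_all / n


def classify_edges(usage: Mapping[str, float]) -> dict[str, str]:
    """Solid iff the edge occurs in strictly more than 2/3 of the runs."""
    return {
        rid: "solid" if pct > SOLID_THRESHOLD_PERCENT else "dashed"
        for rid, pct in usage.items()
    }


def fit_statistics(fits: Sequence[TwoTissueFit | FitResult]) -> dict[str, float]:
    """Mean, best (min), and worst (max) of the reported fit values."""
    if not fits:
        raise InputError("fit_statistics: no successful fits")
    values = np.array([_reported(f) for f in fits], dtype=float)
    return {
        "mean": float(values.mean()),
        "best": float(values.min()),
        "worst": float(values.max()),
    }


def run_ensemble(
    n: int,
    base_seed: int,
    tables: Mapping[str, TimeSeriesTable],
    topology: PathwayTopology,
    profiles: EnzymeProfiles | None = None,
    workflow: str = "transcript",
    config: ObjectiveConfig = ObjectiveConfig(),
    global_settings: GASettings = GASettings(),
    local_settings: LocalSettings = LocalSettings(),
    eps: float = DEFAULT_USE_EPS,
    cotyledon: str = "cotyledons",
    hypocotyl: str = "hypocotyls",
) -> EnsembleResult:
    """``n`` independent fits with seeds base_seed .. base_seed+n−1.

    ``workflow`` is "transcript" (two-stage Model 2; requires ``profiles``) or
    "constant" (Model 1 on the cotyledon tissue).  Seeds are pre-assigned per
    run, so results are independent of execution order.  A run that raises is
    recorded as failed and excluded from the statistics.
    """
    if n < 1:
        raise InputError("ensemble size must be >= 1")
    if workflow not in ("transcript", "constant"):
        raise InputError(f"unknown workflow {workflow!r}")
    if workflow == "transcript" and profiles is None:
        raise InputError("transcript workflow requires enzyme profiles")
    fits: list[TwoTissueFit | FitResult] = []
    failures = 0
    # stage seeds are spaced by 2: each two-stage run consumes seed and seed+1
    for i in range(n):
        seed = base_seed + 2 * i
        try:
            if workflow == "transcript":
                fit = fit_two_stage(
                    tables, profiles, topology, config,
                    global_settings, local_settings, seed=seed,
                    cotyledon=cotyledon, hypocotyl=hypocotyl,
                )
            else:
                fit = fit_constant_model(
                    {cotyledon: tables[cotyledon]}, topology, config,
                    global_settings, local_settings, seed=seed,
                )[cotyledon]
            fits.append(fit)
        except FlavopathError as e:
            logger.warning("ensemble run %d (seed %d) failed: %s", i, seed, e)
            failures += 1
    if not fits:
        raise InputError("every ensemble run failed")
    usage, frac_all = edge_usage(fits, topology, eps)
    return EnsembleResult(
        fits=tuple(fits),
        usage=usage,
        classification=classify_edges(usage),
        statistics=fit_statistics(fits),
        fraction_all_used=frac_all,
        n_failures=failures,
        base_seed=base_seed,
        topology=topology,
    )


def _objective(fit: TwoTissueFit | FitResult) -> float:
    if isinstance(fit, TwoTissueFit):
        return float(fit.cotyledon.objective_value + fit.hypocotyl.objective_value)
    return float(fit.objective_value)


def parameter_spread(
    fits: Sequence[TwoTissueFit | FitResult],
    topology: PathwayTopology,
    within_factor: float = 1.5,
    value: str = "objective",
) -> dict[str, float]:
    """Sloppiness diagnostic: maximum relative L∞ distance between parameter
    vectors whose fit quality lies within ``within_factor`` of the best.

    ``value`` selects the quality measure: the optimization "objective"
    (default) or the "reported" relative-SSE metric.  Distance between vectors
    a, b is max_i |a_i − b_i| / max_i max(|a_i|, |b_i|) (denominator the
    overall parameter scale, so exact zeros compare cleanly).
    """
    score = _objective if value == "objective" else _reported
    best_score = min(score(g) for g in fits)
    good = [f for f in fits if score(f) <= within_factor * best_score]
    vecs = [_fit_params(f).as_array(topology) for f in good]
    max_div = 0.0
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            scale = max(np.abs(vecs[i]).max(), np.abs(vecs[j]).max())
            if scale == 0:
                continue
            d = float(np.abs(vecs[i] - vecs[j]).max() / scale)
            max_div = max(max_div, d)
    return {
        "n_within": float(len(good)),
        "max_relative_linf": max_div,
    }
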