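"""Synthetic two-tissue seedling studies with known ground truth.

Emulates the statistical structure of the real study so every pipeline stage is
testable without measured data: two tissues (cotyledons, hypocotyls), end-product
concentrations on days 5–9 with three biological replicates, transcript
abundance for the seven pathway enzymes on days 5, 6, 7 and 9, mostly
decreasing transcript trends, tissue-specific expression ratios (DFR/ANS ~4×
higher in hypocotyls, FLS ~2× higher in cotyledons, F3H and F3'5'H elevated in
hypocotyls), multiplicative lognormal replicate noise, and censoring of
intermediates below the 2 µmol kg⁻¹ detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .curves import EnzymeProfiles, normalize_transcript_profiles
from .errors import InputError
from .io import TimeSeriesTable
from .model import RateParameters, SolverSettings, Trajectory, simulate
from .topology import CONVERSION, INFLUX, REDUCTION, PathwayTopology

COTYLEDONS = "cotyledons"
HYPOCOTYLS = "hypocotyls"

#: default hypocotyl:cotyledon expression ratio per enzyme.  DFR/ANS 4x and
#: FLS 0.5x follow the measured tissue contrasts; F3H and F3'5'H are elevated
#: (2x) in hypocotyls — the mechanism driving the larger influx and the flux
#: toward dihydromyricetin/myricetin there.
DEFAULT_TISSUE_RATIOS = {
    "F3H": 2.0,
    "F3'H": 1.0,
    "F3'5'H": 2.0,
    "FLS": 0.5,
    "DFR": 4.0,
    "ANS": 4.0,
    "GT": 1.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for the synthetic generator.

    Sampling days, replicate count and the detection threshold mirror the real
    study design; noise level, decay shapes and rate bounds are declared
    choices (the source data exist only as figures).
    """

    metabolite_days: tuple[float, ...] = (5.0, 6.0, 7.0, 8.0, 9.0)
    transcript_days: tuple[float, ...] = (5.0, 6.0, 7.0, 9.0)
    replicates: int = 3
    noise_cv: float = 0.15
    threshold: float = 2.0  # µmol kg⁻¹ detection limit
    tissue_ratios: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_RATIOS)
    )
    #: exponential-decay family for transcript base curves:
    #: v(t) = floor + (1 − floor)·exp(−rate·(t − t0))
    decay_rate_range: tuple[float, float] = (0.3, 1.0)
    decay_floor_range: tuple[float, float] = (0.15, 0.35)
    #: log-uniform sampling bounds for true rate constants, per reaction kind
    influx_range: tuple[float, float] = (5.0, 20.0)  # µmol kg⁻¹ day⁻¹
    conversion_range: tuple[float, float] = (3.0, 30.0)  # day⁻¹
    reduction_range: tuple[float, float] = (0.05, 0.5)  # day⁻¹
    #: initial end-product concentration sampling range (µmol kg⁻¹)
    initial_range: tuple[float, float] = (5.0, 30.0)
    #: reactions whose true rate is forced to exactly 0.  The default reflects
    #: the most frequent solution family: myricetin not produced from
    #: dihydromyricetin by FLS.
    sparsity_mask: tuple[str, ...] = ("FLS:DHM->MYR",)
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise InputError("noise_cv must be >= 0")
        if any(r <= 0 for r in self.tissue_ratios.values()):
            raise InputError("tissue ratios must be > 0")
        for lo, hi in (
            self.influx_range, self.conversion_range, self.reduction_range,
            self.decay_rate_range, self.decay_floor_range, self.initial_range,
        ):
            if not 0 < lo <= hi:
                raise InputError("sampling ranges must satisfy 0 < low <= high")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with exact coefficient of
    variation ``cv`` (concentrations stay positive; spread scales with level)."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2, sigma, size))


def _table(rows: list[dict]) -> TimeSeriesTable:
    return TimeSeriesTable(pd.DataFrame(rows))


def generate_transcript_profiles(
    config: GeneratorConfig,
    rng: np.random.Generator,
    enzymes: tuple[str, ...] | None = None,
) -> tuple[dict[str, TimeSeriesTable], EnzymeProfiles]:
    """Synthetic transcript tables per tissue plus the true noise-free profiles.

    Per enzyme a smooth decreasing base curve (exponential decay with floor) is
    sampled for the cotyledon; the hypocotyl curve is the base times the
    enzyme's tissue ratio.  Replicate table values carry multiplicative
    lognormal noise; the returned true profiles are the max-normalized PCHIP
    curves through the noise-free day values (exactly what the pipeline
    recovers from a noise-free table).
    """
    enzymes = enzymes or tuple(config.tissue_ratios)
    days = np.asarray(config.transcript_days, dtype=float)
    rows: list[dict] = []
    clean: dict[str, list[dict]] = {COTYLEDONS: [], HYPOCOTYLS: []}
    for e in enzymes:
        rate = rng.uniform(*config.decay_rate_range)
        floor = rng.uniform(*config.decay_floor_range)
        base = floor + (1 - floor) * np.exp(-rate * (days - days[0]))
        ratio = float(config.tissue_ratios.get(e, 1.0))
        for tissue, values in ((COTYLEDONS, base), (HYPOCOTYLS, base * ratio)):
            for d, v in zip(days, values):
                clean[tissue].append(
                    {"tissue": tissue, "entity": e, "day": d, "replicate": 1,
                     "value": v, "below_detection": False}
                )
                noise = _lognormal_factors(rng, config.noise_cv, config.replicates)
                for rep in range(1, config.replicates + 1):
                    rows.append(
                        {"tissue": tissue, "entity": e, "day": d,
                         "replicate": rep, "value": v * noise[rep - 1],
                         "below_detection": False}
                    )
    tables = {
        t: _table([r for r in rows if r["tissue"] == t])
        for t in (COTYLEDONS, HYPOCOTYLS)
    }
    true_profiles = normalize_transcript_profiles(
        {t: _table(clean[t]) for t in clean}
    )
    return tables, true_profiles


def sample_true_rates(
    config: GeneratorConfig,
    topology: PathwayTopology,
    rng: np.random.Generator,
) -> RateParameters:
    """Log-uniform ground-truth rate constants; masked reactions exactly 0."""
    known = set(topology.reaction_ids)
    unknown = [r for r in config.sparsity_mask if r not in known]
    if unknown:
        raise InputError(f"sparsity mask names unknown reaction(s): {unknown}")
    ranges = {
        INFLUX: config.influx_range,
        CONVERSION: config.conversion_range,
        REDUCTION: config.reduction_range,
    }
    values = {}
    for r in topology.reactions:
        lo, hi = ranges[r.kind]
        v = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        values[r.id] = 0.0 if r.id in config.sparsity_mask else v
    return RateParameters(values)


@dataclass(frozen=True)
class TruthBundle:
    """Ground truth behind a generated dataset."""

    rates: RateParameters
    profiles: EnzymeProfiles
    trajectories: dict[str, Trajectory]
    initial_states: dict[str, dict[str, float]]
    config: GeneratorConfig

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.to_dict(),
            "initial_states": self.initial_states,
            "metabolite_days": list(self.config.metabolite_days),
            "transcript_days": list(self.config.transcript_days),
            "seed": self.config.seed,
            "sparsity_mask": list(self.config.sparsity_mask),
        }


def generate_dataset(
    true_rates: RateParameters,
    true_profiles: EnzymeProfiles,
    config: GeneratorConfig,
    topology: PathwayTopology,
    rng: np.random.Generator,
) -> tuple[dict[str, TimeSeriesTable], TruthBundle]:
    """Noisy, censored metabolite tables per tissue plus the truth bundle.

    The truth is simulated per tissue over the metabolite sampling window with
    intermediates starting at 0 and end products at sampled initial values.
    End products get replicate-level multiplicative lognormal noise; sampled
    intermediates below the detection threshold are emitted as below-detection
    flags (only end products were ever quantified in the emulated study).
    """
    days = np.asarray(config.metabolite_days, dtype=float)
    t0, t1 = float(days[0]), float(days[-1])
    tables: dict[str, TimeSeriesTable] = {}
    trajectories: dict[str, Trajectory] = {}
    initial_states: dict[str, dict[str, float]] = {}
    for tissue in sorted(true_profiles.tissues):
        x0 = np.zeros(len(topology.species_ids))
        init = {
            sp: float(np.exp(rng.uniform(*np.log(config.initial_range))))
            for sp in topology.end_products
        }
        for sp, v in init.items():
            x0[topology.species_index(sp)] = v
        initial_states[tissue] = init
        traj = simulate(
            topology, true_rates, true_profiles, x0, t0, t1,
            settings=SolverSettings(), tissue=tissue,
        )
        trajectories[tissue] = traj
        rows = []
        for sp in topology.species_ids:
            series = np.interp(days, traj.t, traj.series(sp))
            is_end = sp in topology.end_products
            for d, v in zip(days, series):
                if is_end:
                    noise = _lognormal_factors(rng, config.noise_cv, config.replicates)
                    for rep in range(1, config.replicates + 1):
                        rows.append(
                            {"tissue": tissue, "entity": sp, "day": float(d),
                             "replicate": rep, "value": v * noise[rep - 1],
                             "below_detection": False}
                        )
                else:
                    # intermediates: a single censored observation per day
                    if v < config.threshold:
                        rows.append(
                            {"tissue": tissue, "entity": sp, "day": float(d),
                             "replicate": 1, "value": np.nan,
                             "below_detection": True}
                        )
                    else:
                        rows.append(
                            {"tissue": tissue, "entity": sp, "day": float(d),
                             "replicate": 1, "value": v, "below_detection": False}
                        )
        tables[tissue] = _table(rows)
    truth = TruthBundle(
        rates=true_rates,
        profiles=true_profiles,
        trajectories=trajectories,
        initial_states=initial_states,
        config=config,
    )
    return tables, truth


def generate_study(
    config: GeneratorConfig = GeneratorConfig(),
    topology: PathwayTopology | None = None,
) -> tuple[dict[str, TimeSeriesTable], dict[str, TimeSeriesTable], TruthBundle]:
    """End-to-end study generation from a config's seed.

    Returns (metabolite tables, transcript tables, truth bundle); fully
    deterministic for a fixed config.
    """
    from .topology import build_default_topology

    topology = topology or build_default_topology()
    rng = np.random.default_rng(config.seed)
    transcript_tables, true_profiles = generate_transcript_profiles(
        config, rng, enzymes=topology.enzymes
    )
    rates = sample_true_rates(config, topology, rng)
    metabolite_tables, truth = generate_dataset(
        rates, true_profiles, config, topology, rng
    )
    return metabolite_tables, transcript_tables, truth
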