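"""Shared fixtures: topologies, synthetic studies, and small optimizer budgets."""

import numpy as np
import pytest

import flavopath as fp
from flavopath.topology import (
    CONVERSION,
    END_PRODUCT,
    INFLUX,
    INTERMEDIATE,
    REDUCTION,
    PathwayTopology,
    Reaction,
    Species,
)


@pytest.fixture(scope="session")
def topo():
    return fp.build_default_topology()


def make_one_state(influx_rate=1.0, reduction_rate=0.5):
    """Minimal network: influx into a single end product with first-order loss."""
    topo = PathwayTopology(
        species=(Species("X", END_PRODUCT, "product"),),
        reactions=(
            Reaction("E1:->X", INFLUX, None, "X", "E1"),
            Reaction("red:X", REDUCTION, "X", None, None),
        ),
        enzymes=("E1",),
    )
    params = fp.RateParameters({"E1:->X": influx_rate, "red:X": reduction_rate})
    return topo, params


def make_two_state(influx_rate=1.0, conversion_rate=2.0, reduction_rate=0.5):
    """Influx -> intermediate A -> end product B -> loss."""
    topo = PathwayTopology(
        species=(
            Species("A", INTERMEDIATE, "intermediate"),
            Species("B", END_PRODUCT, "product"),
        ),
        reactions=(
            Reaction("E1:->A", INFLUX, None, "A", "E1"),
            Reaction("E2:A->B", CONVERSION, "A", "B", "E2"),
            Reaction("red:B", REDUCTION, "B", None, None),
        ),
        enzymes=("E1", "E2"),
    )
    params = fp.RateParameters(
        {"E1:->A": influx_rate, "E2:A->B": conversion_rate, "red:B": reduction_rate}
    )
    return topo, params


@pytest.fixture(scope="session")
def one_state():
    return make_one_state()


@pytest.fixture(scope="session")
def two_state():
    return make_two_state()


@pytest.fixture(scope="session")
def unit_profiles_factory():
    def build(topology, tissues=("tissue",)):
        return fp.constant_profiles(topology, list(tissues))

    return build


def random_instance(topo, rng, k_scale=20.0):
    """Random rates, decreasing random PCHIP profiles, and a random initial state."""
    days = np.array([5.0, 6.0, 7.0, 9.0])
    profiles = fp.EnzymeProfiles(
        profiles={
            "t": {
                e: fp.fit_pchip(
                    list(zip(days, np.sort(rng.uniform(0.05, 1.0, 4))[::-1]))
                )
                for e in topo.enzymes
            }
        }
    )
    k = rng.uniform(0.0, k_scale, len(topo.reaction_ids))
    params = fp.RateParameters.from_array(topo, k)
    x0 = rng.uniform(0.0, 10.0, len(topo.species_ids))
    return params, profiles, x0


def study_like_instance(topo, rng, conversion_range=(3.0, 30.0)):
    """Random instance in the generator's regime: log-uniform rates per kind,
    decreasing transcript curves, intermediates starting at 0 (below detection)
    and end products at measured-scale initial values."""
    days = np.array([5.0, 6.0, 7.0, 9.0])
    profiles = fp.EnzymeProfiles(
        profiles={
            "t": {
                e: fp.fit_pchip(
                    list(zip(days, np.sort(rng.uniform(0.1, 1.0, 4))[::-1]))
                )
                for e in topo.enzymes
            }
        }
    )
    ranges = {
        INFLUX: (5.0, 20.0),
        CONVERSION: conversion_range,
        REDUCTION: (0.05, 0.5),
    }
    values = {}
    for r in topo.reactions:
        lo, hi = ranges[r.kind]
        values[r.id] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    x0 = np.zeros(len(topo.species_ids))
    for sp in topo.end_products:
        x0[topo.species_index(sp)] = rng.uniform(5.0, 30.0)
    return fp.RateParameters(values), profiles, x0


@pytest.fixture(scope="session")
def noiseless_study():
    cfg = fp.GeneratorConfig(noise_cv=0.0, seed=11)
    met, tra, truth = fp.generate_study(cfg)
    return cfg, met, tra, truth


@pytest.fixture(scope="session")
def noisy_study():
    cfg = fp.GeneratorConfig(seed=23)
    met, tra, truth = fp.generate_study(cfg)
    return cfg, met, tra, truth


@pytest.fixture(scope="session")
def tiny_ga():
    return fp.GASettings(population=10, generations=10)


@pytest.fixture(scope="session")
def tiny_local():
    return fp.LocalSettings(max_iter=15)
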