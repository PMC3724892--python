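"""Penalized objective, optimizer, and the Model 1 / Model 2 workflows."""

import numpy as np
import pytest

import flavopath as fp
from flavopath.fitting import PathwayObjective

from conftest import make_two_state


def constant_targets(topo, level):
    days = [(5.0, level), (6.0, level), (7.0, level), (8.0, level), (9.0, level)]
    return {sp: fp.fit_pchip(days) for sp in topo.end_products}


# -- objective -----------------------------------------------------------------


def test_objective_zero_for_exact_fit(one_state, unit_profiles_factory):
    """Zero rates keep the end product at its initial value; a constant target
    at that value gives a zero data term and no intermediates exist."""
    topo, _ = one_state
    params = fp.RateParameters({"E1:->X": 0.0, "red:X": 0.0})
    prof = unit_profiles_factory(topo)
    targets = constant_targets(topo, 3.0)
    val = fp.objective(params, topo, prof, targets, tissue="tissue")
    assert val == pytest.approx(0.0, abs=1e-12)


def test_objective_constant_offset_integrates_to_four(one_state, unit_profiles_factory):
    """Model ≡ 2 vs target ≡ 1 over a 4-day window: ∫ ((2−1)/1)² dt = 4."""
    topo, _ = one_state
    params = fp.RateParameters({"E1:->X": 0.0, "red:X": 0.0})
    prof = unit_profiles_factory(topo)
    targets = constant_targets(topo, 1.0)
    fn = PathwayObjective(topo, prof.for_tissue("tissue"), targets)
    fn.x0 = np.array([2.0])
    assert fn(params.as_array(topo)) == pytest.approx(4.0, rel=1e-12)


def test_penalty_integrates_threshold_excess(unit_profiles_factory):
    """Intermediate pinned at 3 with θ=2, w=1 over [5,9]: penalty = 1·(3−2)·4."""
    topo, _ = make_two_state(0.0, 0.0, 0.0)
    prof = unit_profiles_factory(topo)
    targets = constant_targets(topo, 1.0)
    config = fp.ObjectiveConfig(penalty_weight=1.0)
    fn = PathwayObjective(topo, prof.for_tissue("tissue"), targets, config)
    fn.x0 = np.array([3.0, 1.0])  # intermediate A at 3, end product B on target
    assert fn(np.zeros(3)) == pytest.approx(4.0, rel=1e-12)


def test_penalty_monotone_in_intermediate_level(unit_profiles_factory):
    topo, _ = make_two_state(0.0, 0.0, 0.0)
    prof = unit_profiles_factory(topo)
    targets = constant_targets(topo, 1.0)
    fn = PathwayObjective(topo, prof.for_tissue("tissue"), targets)
    values = []
    for a0 in (1.0, 2.5, 3.0, 4.0):
        fn.x0 = np.array([a0, 1.0])
        values.append(fn(np.zeros(3)))
    assert all(b >= a for a, b in zip(values, values[1:]))


def test_data_term_stable_under_grid_halving(topo, noiseless_study):
    _, met, tra, truth = noiseless_study
    prof = fp.normalize_transcript_profiles(tra)
    targets = fp.metabolite_targets(met["cotyledons"], topo)
    rng = np.random.default_rng(2)
    k = rng.uniform(0.0, 5.0, 22)
    vals = []
    for step in (0.05, 0.025):
        cfg = fp.ObjectiveConfig(grid_step=step)
        fn = PathwayObjective(topo, prof.for_tissue("cotyledons"), targets, cfg)
        vals.append(fn(k))
    assert vals[1] == pytest.approx(vals[0], rel=0.02)


def test_objective_missing_target_rejected(topo, noiseless_study, unit_profiles_factory):
    _, met, _, _ = noiseless_study
    targets = fp.metabolite_targets(met["cotyledons"], topo)
    targets.pop("ANT")
    prof = unit_profiles_factory(topo)
    with pytest.raises(fp.InputError, match="ANT"):
        PathwayObjective(topo, prof.for_tissue("tissue"), targets)


def test_points_mode_matches_reported_metric_structure(topo, noiseless_study):
    """mode='points' evaluates squared relative residuals at the measured days
    only, so it has no grid-step dependence."""
    _, met, tra, _ = noiseless_study
    prof = fp.normalize_transcript_profiles(tra)
    targets = fp.metabolite_targets(met["cotyledons"], topo)
    k = np.random.default_rng(4).uniform(0.0, 5.0, 22)
    vals = []
    for step in (0.05, 0.02):
        cfg = fp.ObjectiveConfig(mode="points", grid_step=step, penalty_weight=0.0)
        fn = PathwayObjective(topo, prof.for_tissue("cotyledons"), targets, cfg)
        vals.append(fn(k))
    assert vals[0] == pytest.approx(vals[1], rel=5e-3)


# -- optimize_rates ------------------------------------------------------------


def test_optimizer_finds_convex_minimum():
    fit = fp.optimize_rates(
        lambda x: (x[0] - 3.0) ** 2, 1, [(0.0, 10.0)],
        fp.GASettings(population=20, generations=50), fp.LocalSettings(),
        seed=1,
    )
    assert fit.params["p0"] == pytest.approx(3.0, abs=1e-3)
    assert fit.objective_value < 1e-6


def test_optimizer_deterministic_under_seed():
    fn = lambda x: float(np.sum((x - 2.0) ** 2) + 0.1 * np.sum(np.sin(5 * x)))
    runs = [
        fp.optimize_rates(
            fn, 3, [(0.0, 5.0)] * 3,
            fp.GASettings(population=15, generations=30), fp.LocalSettings(),
            seed=42,
        )
        for _ in range(2)
    ]
    assert runs[0].params.to_dict() == runs[1].params.to_dict()
    assert runs[0].objective_value == runs[1].objective_value
    assert runs[0].stage_values == runs[1].stage_values


def test_optimizer_degenerate_bounds():
    fit = fp.optimize_rates(
        lambda x: float(np.sum(x**2)) + 7.0, 4, [(0.0, 0.0)] * 4,
        fp.GASettings(), fp.LocalSettings(), seed=0,
    )
    assert all(v == 0.0 for v in fit.params.to_dict().values())
    assert fit.objective_value == pytest.approx(7.0)


def test_optimizer_rejects_bad_bounds():
    with pytest.raises(fp.InputError):
        fp.optimize_rates(lambda x: 0.0, 2, [(0.0, np.inf)] * 2)


# -- workflows -----------------------------------------------------------------


def test_constant_model_parameter_counts(topo, noiseless_study, tiny_ga, tiny_local):
    _, met, _, _ = noiseless_study
    fits = fp.fit_constant_model(met, topo, fp.ObjectiveConfig(), tiny_ga, tiny_local, seed=0)
    assert set(fits) == {"cotyledons", "hypocotyls"}
    assert all(f.n_free == 22 for f in fits.values())
    assert sum(f.n_free for f in fits.values()) == 44


def test_constant_model_recovers_constant_enzyme_truth(unit_profiles_factory):
    """Self-consistency: noiseless data simulated from a constant-enzyme truth
    is fitted back to near-zero objective."""
    topo, params = make_two_state(1.5, 3.0, 0.4)
    prof = unit_profiles_factory(topo, ["t"])
    traj = fp.simulate(topo, params, prof, np.array([0.0, 4.0]), 5.0, 9.0, tissue="t")
    days = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
    import pandas as pd

    rows = [
        {"tissue": "t", "entity": "B", "day": d, "replicate": 1,
         "value": float(np.interp(d, traj.t, traj.series("B"))),
         "below_detection": False}
        for d in days
    ]
    table = fp.TimeSeriesTable(pd.DataFrame(rows))
    fits = fp.fit_constant_model(
        {"t": table}, topo, fp.ObjectiveConfig(),
        fp.GASettings(population=30, generations=100), fp.LocalSettings(),
        seed=5,
    )
    assert fits["t"].objective_value <= 1e-2


def test_transcript_model_parameter_count(topo, noiseless_study, tiny_ga, tiny_local):
    _, met, tra, _ = noiseless_study
    prof = fp.normalize_transcript_profiles(tra)
    fit = fp.fit_transcript_model(
        met["cotyledons"], prof, topo, fp.ObjectiveConfig(), tiny_ga, tiny_local, seed=0
    )
    assert fit.n_free == 22
    assert fit.tissue == "cotyledons"


def test_unit_profiles_reduce_transcript_model_to_constant_model(topo, noiseless_study):
    """With transcript profiles ≡ 1 the transcript-driven objective equals the
    constant-enzyme objective for any parameter vector."""
    _, met, _, _ = noiseless_study
    targets = fp.metabolite_targets(met["cotyledons"], topo)
    days = [5.0, 6.0, 7.0, 9.0]
    unit_curves = fp.EnzymeProfiles(
        profiles={"cotyledons": {
            e: fp.fit_pchip([(d, 1.0) for d in days]) for e in topo.enzymes
        }}
    )
    const = fp.constant_profiles(topo, ["cotyledons"])
    fn_curves = PathwayObjective(topo, unit_curves.for_tissue("cotyledons"), targets)
    fn_const = PathwayObjective(topo, const.for_tissue("cotyledons"), targets)
    rng = np.random.default_rng(8)
    for _ in range(5):
        k = rng.uniform(0, 10, 22)
        assert fn_curves(k) == pytest.approx(fn_const(k), rel=1e-12)


def test_refit_exposes_exactly_four_free_parameters(topo, noiseless_study, tiny_ga, tiny_local):
    _, met, tra, _ = noiseless_study
    prof = fp.normalize_transcript_profiles(tra)
    cot = fp.fit_transcript_model(
        met["cotyledons"], prof, topo, fp.ObjectiveConfig(), tiny_ga, tiny_local, seed=0
    )
    hyp = fp.refit_reduction_rates(
        cot, met["hypocotyls"], prof, topo, fp.ObjectiveConfig(), tiny_ga, tiny_local, seed=1
    )
    assert hyp.n_free == 4
    assert set(hyp.free_ids) == set(topo.reduction_ids)
    assert set(hyp.frozen) == set(topo.non_reduction_ids)
    for rid in topo.non_reduction_ids:
        assert hyp.params[rid] == cot.params[rid]


def test_refit_on_identical_tissue_reproduces_reduction_rates(topo, noiseless_study):
    """If the 'other' tissue has the cotyledon's data and profiles, the refit
    solves the same problem and lands on the same reduction rates."""
    _, met, tra, _ = noiseless_study
    prof = fp.normalize_transcript_profiles(tra)
    ga = fp.GASettings(population=24, generations=60)
    cot = fp.fit_transcript_model(
        met["cotyledons"], prof, topo, fp.ObjectiveConfig(), ga, fp.LocalSettings(), seed=3
    )
    clone = fp.EnzymeProfiles(
        profiles={
            "cotyledons": prof.profiles["cotyledons"],
            "hypocotyls": prof.profiles["cotyledons"],
        },
        normalization=prof.normalization,
    )
    import pandas as pd

    df = met["cotyledons"].df.copy()
    df["tissue"] = "hypocotyls"
    hyp = fp.refit_reduction_rates(
        cot, fp.TimeSeriesTable(df), clone, topo, fp.ObjectiveConfig(), ga,
        fp.LocalSettings(), seed=4,
    )
    assert hyp.objective_value <= cot.objective_value * 1.05 + 1e-9
    for rid in topo.reduction_ids:
        assert hyp.params[rid] == pytest.approx(cot.params[rid], abs=0.05)
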