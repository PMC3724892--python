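"""PCHIP interpolation, transcript normalization, and constant profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flavopath as fp
from flavopath.io import TimeSeriesTable

from conftest import make_two_state


def _table(tissue, entity_values, days, replicates=1):
    rows = []
    for entity, values in entity_values.items():
        for d, v in zip(days, values):
            for rep in range(1, replicates + 1):
                rows.append(
                    {"tissue": tissue, "entity": entity, "day": d,
                     "replicate": rep, "value": v, "below_detection": False}
                )
    return TimeSeriesTable(pd.DataFrame(rows))


# -- fit_pchip -----------------------------------------------------------------


def test_interpolation_exact_at_knots():
    curve = fp.fit_pchip([(5, 1.0), (6, 4.0), (7, 2.0)])
    assert curve(6.0) == pytest.approx(4.0, abs=0)
    assert np.max(np.abs(curve(curve.days) - curve.values)) == 0


def test_monotone_data_yields_monotone_curve():
    curve = fp.fit_pchip([(5, 8.0), (6, 4.0), (7, 2.0), (9, 1.0)])
    grid = np.arange(5.0, 9.0 + 1e-12, 0.01)
    assert np.all(np.diff(curve(grid)) <= 1e-12)


def test_constant_knots_give_constant_curve():
    curve = fp.fit_pchip([(5, 3.0), (7, 3.0), (9, 3.0)])
    assert np.allclose(curve(np.linspace(5, 9, 100)), 3.0, atol=1e-14)


@pytest.mark.parametrize(
    "points", [[(5, 1.0)], [(5, 1.0), (5, 2.0)], [(5, np.nan), (6, 1.0)],
               [(6, 1.0), (5, 2.0)]]
)
def test_invalid_knots_rejected(points):
    with pytest.raises(fp.InputError):
        fp.fit_pchip(points)


def test_no_extrapolation():
    curve = fp.fit_pchip([(5, 1.0), (9, 2.0)])
    with pytest.raises(fp.DomainError):
        curve(9.5)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    values=st.lists(
        st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
        min_size=3, max_size=7,
    )
)
def test_shape_preservation_no_new_extrema(values):
    """Between adjacent knots the interpolant stays within the knot values
    (PCHIP never overshoots), checked on a dense grid."""
    days = np.arange(5.0, 5.0 + len(values))
    curve = fp.fit_pchip(list(zip(days, values)))
    for lo_d, hi_d, lo_v, hi_v in zip(days[:-1], days[1:], values[:-1], values[1:]):
        seg = curve(np.linspace(lo_d, hi_d, 50))
        lo, hi = min(lo_v, hi_v), max(lo_v, hi_v)
        assert np.all(seg >= lo - 1e-9 * (1 + abs(lo)))
        assert np.all(seg <= hi + 1e-9 * (1 + abs(hi)))


# -- normalize_transcript_profiles ---------------------------------------------


def test_cross_tissue_ratio_preserved():
    days = [5.0, 6.0, 7.0, 9.0]
    cot = _table("cot", {"DFR": [1.0, 0.8, 0.5, 0.2]}, days)
    hyp = _table("hyp", {"DFR": [4.0, 3.2, 2.0, 0.8]}, days)
    prof = fp.normalize_transcript_profiles({"cot": cot, "hyp": hyp})
    grid = np.linspace(5, 9, 41)
    assert np.allclose(
        prof.for_tissue("hyp").levels["DFR"](grid),
        4.0 * prof.for_tissue("cot").levels["DFR"](grid),
        rtol=1e-12,
    )
    assert prof.normalization["DFR"] == pytest.approx(4.0)


def test_duplicated_tissue_is_symmetric_with_unit_max():
    days = [5.0, 6.0, 7.0, 9.0]
    t = _table("a", {"FLS": [2.0, 1.5, 1.0, 0.4]}, days)
    t2 = _table("b", {"FLS": [2.0, 1.5, 1.0, 0.4]}, days)
    prof = fp.normalize_transcript_profiles({"a": t, "b": t2})
    grid = np.linspace(5, 9, 41)
    a = prof.for_tissue("a").levels["FLS"](grid)
    b = prof.for_tissue("b").levels["FLS"](grid)
    assert np.array_equal(a, b)
    assert a.max() == pytest.approx(1.0, abs=1e-14)


def test_log2_input_linearizes_before_normalizing():
    days = [5.0, 6.0, 7.0]
    t = _table("a", {"F3H": [1.0, 2.0, 3.0]}, days)
    prof = fp.normalize_transcript_profiles({"a": t}, log2_input=True)
    # 2,4,8 after exponentiation; global max 8
    knots = prof.for_tissue("a").levels["F3H"].values
    assert knots == pytest.approx([0.25, 0.5, 1.0])


def test_missing_enzyme_listed_in_error():
    days = [5.0, 6.0, 7.0]
    a = _table("a", {"F3H": [1, 2, 3], "FLS": [3, 2, 1]}, days)
    b = _table("b", {"F3H": [1, 2, 3]}, days)
    with pytest.raises(fp.InputError, match="FLS"):
        fp.normalize_transcript_profiles({"a": a, "b": b})


def test_normalization_idempotent():
    days = [5.0, 6.0, 7.0, 9.0]
    raw = {"a": _table("a", {"DFR": [1.0, 0.7, 0.4, 0.1]}, days),
           "b": _table("b", {"DFR": [0.5, 0.35, 0.2, 0.05]}, days)}
    once = fp.normalize_transcript_profiles(raw)
    renorm_tables = {
        t: _table(t, {"DFR": list(once.for_tissue(t).levels["DFR"].values)}, days)
        for t in ("a", "b")
    }
    twice = fp.normalize_transcript_profiles(renorm_tables)
    grid = np.linspace(5, 9, 33)
    for t in ("a", "b"):
        assert np.allclose(
            once.for_tissue(t).levels["DFR"](grid),
            twice.for_tissue(t).levels["DFR"](grid),
            atol=1e-12,
        )


def test_replicates_averaged_before_interpolation():
    days = [5.0, 7.0]
    rows = []
    for d, vals in zip(days, ([1.0, 3.0], [0.5, 1.5])):
        for rep, v in enumerate(vals, 1):
            rows.append({"tissue": "a", "entity": "GT", "day": d,
                         "replicate": rep, "value": v, "below_detection": False})
    prof = fp.normalize_transcript_profiles({"a": TimeSeriesTable(pd.DataFrame(rows))})
    assert prof.for_tissue("a").levels["GT"].values == pytest.approx([1.0, 0.5])


# -- constant_profiles ---------------------------------------------------------


def test_constant_profiles_are_unit(topo):
    prof = fp.constant_profiles(topo, ["cot", "hyp"])
    for tissue in ("cot", "hyp"):
        for e in topo.enzymes:
            assert prof.level(tissue, e, 6.283) == 1.0


def test_rhs_with_constant_profiles_drops_enzyme_factor():
    topo, params = make_two_state(1.0, 2.0, 0.5)
    prof = fp.constant_profiles(topo, ["t"])
    x = np.array([3.0, 1.0])
    out = fp.rhs(6.0, x, params, prof, topo, tissue="t")
    # hand-written flux balance without enzyme terms
    assert out == pytest.approx([1.0 - 2.0 * 3.0, 2.0 * 3.0 - 0.5 * 1.0])


def test_constant_profile_simulation_is_time_homogeneous():
    topo, params = make_two_state(1.0, 2.0, 0.5)
    prof = fp.constant_profiles(topo, ["t"])
    a = fp.simulate(topo, params, prof, np.zeros(2), 5.0, 9.0, tissue="t")
    b = fp.simulate(topo, params, prof, np.zeros(2), 0.0, 4.0, tissue="t")
    assert np.allclose(a.states, b.states, rtol=1e-7, atol=1e-9)
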