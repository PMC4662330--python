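"""Unit and property tests for the conductivity law and trait aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from needlehydro.hydraulics import (
    NeedleSection,
    PhysicalConstants,
    TracheidGeometry,
    compute_traits_table,
    needle_traits,
    orient_tracheid,
    sections_from_tables,
    tracheid_conductivity,
)

from _oracle import oracle_circular, oracle_conductivity

diam = st.floats(min_value=0.5, max_value=50.0, allow_nan=False)


@pytest.mark.parametrize(
    "d_max, d_min, expected",
    [
        # frozen from the exact-rational oracle before implementation
        (6.2, 3.8, 1.2093620324986569e-11),
        (4.0, 4.0, 6.2593882131269446e-12),
    ],
)
def test_conductivity_frozen_oracle_values(d_max, d_min, expected):
    assert tracheid_conductivity(d_max, d_min) == pytest.approx(expected, rel=1e-12)


def test_conductivity_matches_oracle_on_grid():
    for d_max in (1.0, 3.3, 6.2, 12.0):
        for ratio in (1.0, 1.3, 1.75, 2.5):
            d_min = d_max / ratio
            assert tracheid_conductivity(d_max, d_min) == pytest.approx(
                oracle_conductivity(d_max, d_min), rel=1e-12
            )


@given(d=diam)
@settings(deadline=None, derandomize=True)
def test_circular_limit_equals_classical_law(d):
    assert tracheid_conductivity(d, d) == pytest.approx(oracle_circular(d), rel=1e-12)


@given(d_min=diam, excess=st.floats(min_value=0.01, max_value=3.0))
@settings(deadline=None, derandomize=True)
def test_monotone_in_each_diameter(d_min, excess):
    d_max = d_min * (1 + excess)
    k = tracheid_conductivity(d_max, d_min)
    assert tracheid_conductivity(d_max * 1.01, d_min) > k
    assert tracheid_conductivity(d_max, d_min * 1.01) > k


@given(d_min=diam, excess=st.floats(min_value=0.0, max_value=3.0),
       s=st.floats(min_value=0.1, max_value=10.0))
@settings(deadline=None, derandomize=True)
def test_scale_law_fourth_power(d_min, excess, s):
    d_max = d_min * (1 + excess)
    assert tracheid_conductivity(s * d_max, s * d_min) == pytest.approx(
        s**4 * tracheid_conductivity(d_max, d_min), rel=1e-10
    )


def test_vanishing_minor_diameter_kills_conductivity():
    ks = [tracheid_conductivity(6.0, d) for d in (3.0, 1.0, 0.1, 1e-3)]
    assert all(a > b for a, b in zip(ks, ks[1:]))
    assert ks[-1] < 1e-6 * ks[0]


def test_rejects_bad_diameters():
    with pytest.raises(ValueError):
        tracheid_conductivity(3.8, 6.2)  # unoriented
    for bad in ((0.0, 4.0), (4.0, -1.0), (math.nan, 4.0), (math.inf, 4.0)):
        with pytest.raises(ValueError):
            tracheid_conductivity(*bad)


def test_orient_tracheid():
    assert orient_tracheid(3.8, 6.2) == (6.2, 3.8)
    assert orient_tracheid(5, 5) == (5, 5)
    assert orient_tracheid(*orient_tracheid(3.8, 6.2)) == (6.2, 3.8)  # idempotent
    with pytest.raises(ValueError):
        orient_tracheid(0, 4)


def test_constants_validated():
    with pytest.raises(ValueError):
        PhysicalConstants(rho=-1.0)
    with pytest.raises(ValueError):
        PhysicalConstants(eta=0.0)


def _section(tracheids, a_n=0.35, a_v=0.019, a_x=930.0, a_p=1270.0):
    return NeedleSection(
        treatment="control", canopy="shade", tree_id="t1", shoot_id="s1",
        needle_id="n1", a_n_mm2=a_n, a_v_mm2=a_v, a_x_um2=a_x, a_p_um2=a_p,
        tracheids=tracheids,
    )


class TestNeedleTraits:
    def test_single_tracheid_identities(self):
        tr = TracheidGeometry(6.2, 3.8, 18.5)
        t = needle_traits(_section([tr]))
        assert t.k_th == pytest.approx(tracheid_conductivity(6.2, 3.8), rel=1e-12)
        assert t.f_t == pytest.approx(6.2 / 3.8)
        assert t.n_lum == tr.a_lum
        assert t.n_t == 1

    def test_two_tracheid_sum_matches_oracle(self):
        trs = [TracheidGeometry(6.2, 3.8, 18.5), TracheidGeometry(4.0, 4.0, 12.6)]
        t = needle_traits(_section(trs))
        # frozen: oracle k_t(6.2,3.8) + k_t(4.0,4.0)
        assert t.k_th == pytest.approx(1.835300853811351e-11, rel=1e-12)

    def test_area_proportions_match_published_shade_row(self):
        # A_x = 930 µm² on a 0.35 mm² needle -> 0.27% xylem proportion
        t = needle_traits(_section([TracheidGeometry(5.2, 3.4, 14.5)]))
        assert round(t.a_x_pct, 2) == 0.27

    def test_flatness_is_mean_of_ratios(self):
        trs = [TracheidGeometry(6.0, 3.0, 14.1), TracheidGeometry(4.0, 4.0, 12.6)]
        t = needle_traits(_section(trs))
        assert t.f_t == pytest.approx((2.0 + 1.0) / 2)
        assert t.f_t != pytest.approx(t.d_max / t.d_min)

    def test_ks_reported_and_si_scales(self):
        t = needle_traits(_section([TracheidGeometry(6.2, 3.8, 18.5)]))
        assert t.k_s == pytest.approx(t.k_th / 930.0)
        assert t.k_s_si == pytest.approx(t.k_th / (930.0 * 1e-12))

    def test_empty_and_invalid_sections_rejected(self):
        with pytest.raises(ValueError):
            needle_traits(_section([]))
        with pytest.raises(ValueError):
            needle_traits(_section([TracheidGeometry(5, 3, 12)], a_v=0.4))  # a_v > a_n
        with pytest.raises(ValueError):
            # lumen total exceeds xylem area
            needle_traits(_section([TracheidGeometry(5, 3, 1000.0)], a_x=900.0))


class TestTraitsTable:
    def test_aggregation_conservation(self, study_dataset, traits_table):
        tracheids, needles = study_dataset
        assert len(traits_table) == len(needles)
        assert traits_table["N_t"].sum() == len(tracheids)
        assert traits_table["N_lum"].sum() == pytest.approx(
            tracheids["a_lum_um2"].sum(), rel=1e-12
        )
        assert (traits_table["F_t"] >= 1).all()
        assert (traits_table["k_th"] > 0).all()
        assert traits_table[["A_x_pct", "A_p_pct"]].gt(0).all().all()
        assert traits_table[["A_x_pct", "A_p_pct"]].lt(100).all().all()

    def test_table_matches_per_section_computation(self, study_dataset, traits_table):
        tracheids, needles = study_dataset
        rows = [0, 57, 419]
        sections = sections_from_tables(tracheids, needles, rows)
        for i, sec in zip(rows, sections):
            expect = needle_traits(sec)
            got = traits_table.merge(
                needles.iloc[[i]][["treatment", "canopy", "tree_id", "shoot_id", "needle_id"]]
            ).iloc[0]
            assert got["k_th"] == pytest.approx(expect.k_th, rel=1e-12)
            assert got["F_t"] == pytest.approx(expect.f_t, rel=1e-12)
            assert got["N_t"] == expect.n_t

    def test_jensen_gap_nonnegative_on_simulated_anatomy(self, study_dataset):
        # size-scaling-dominated populations: summed conductivity dominates
        # the mean-diameter surrogate (strict convexity along rays)
        tracheids, needles = study_dataset
        for sec in sections_from_tables(tracheids, needles, list(range(0, 420, 40))):
            if len(sec.tracheids) < 2:
                continue
            assert needle_traits(sec).jensen_gap() >= -1e-12
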