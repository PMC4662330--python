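"""Tests of the hierarchical generator: design, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest

from needlehydro.hydraulics import compute_traits_table, sections_from_tables
from needlehydro.simulate import (
    CalibrationError,
    GroupCalibration,
    SimulationConfig,
    generate_dataset,
    no_drought_calibration,
    study_calibration,
)


def test_preset_complete_and_verbatim():
    calib = study_calibration()
    assert set(calib) == {(c, t) for c in ("sun", "shade") for t in ("control", "drought")}
    sun_ctrl = calib[("sun", "control")]
    assert (sun_ctrl.d_max, sun_ctrl.d_min, sun_ctrl.n_t, sun_ctrl.a_n_mm2) == (
        6.2, 3.8, 35.1, 0.76)
    shade_drt = calib[("shade", "drought")]
    assert (shade_drt.d_max, shade_drt.n_t, shade_drt.a_n_mm2) == (4.9, 20.0, 0.34)
    for cell in calib.values():
        for f in ("n_t", "d_max", "d_min", "f_t", "a_n_mm2", "a_v_mm2", "a_x_um2", "a_p_um2"):
            assert getattr(cell, f) > 0


def test_study_design_shape(study_dataset):
    tracheids, needles = study_dataset
    # 2 plots x 3 trees x 2 canopies x 5 shoots x 7 needles
    assert len(needles) == 420
    sizes = needles.groupby(["treatment", "canopy"]).size()
    assert (sizes == 105).all()
    per_height = needles.groupby(["tree_id", "canopy"]).size()
    assert (per_height == 35).all()  # 7 needles x 5 shoots per tree and height
    assert needles["tree_id"].nunique() == 6


def test_same_seed_reproduces_byte_identical_tables(tmp_path):
    cfg = SimulationConfig(seed=11)
    for name in ("a", "b"):
        t, n = generate_dataset(cfg)
        t.to_csv(tmp_path / f"t_{name}.csv", index=False)
        n.to_csv(tmp_path / f"n_{name}.csv", index=False)
    assert (tmp_path / "t_a.csv").read_bytes() == (tmp_path / "t_b.csv").read_bytes()
    assert (tmp_path / "n_a.csv").read_bytes() == (tmp_path / "n_b.csv").read_bytes()
    t2, _ = generate_dataset(SimulationConfig(seed=12))
    assert not t2.equals(t)


def test_rows_satisfy_section_invariants(study_dataset):
    tracheids, needles = study_dataset
    assert (tracheids["d_max_um"] >= tracheids["d_min_um"]).all()
    assert (tracheids["d_min_um"] > 0).all()
    # synthetic lumens are exact ellipses
    ellipse = np.pi / 4 * tracheids["d_max_um"] * tracheids["d_min_um"]
    assert np.allclose(tracheids["a_lum_um2"], ellipse, rtol=1e-9)
    # every section validates (spot-check a spread of needles)
    for sec in sections_from_tables(tracheids, needles, list(range(0, 420, 35))):
        sec.validate()
    lum_sums = tracheids.groupby(["treatment", "canopy", "tree_id", "shoot_id", "needle_id"])[
        "a_lum_um2"].sum().reset_index().merge(needles)
    assert (lum_sums["a_lum_um2"] <= lum_sums["a_x_um2"]).all()
    assert (needles["a_v_mm2"] < needles["a_n_mm2"]).all()
    assert (needles["a_x_um2"] + needles["a_p_um2"] <= needles["a_v_mm2"] * 1e6).all()


def test_degenerate_noise_recovers_targets_exactly(degenerate_dataset):
    tracheids, needles = degenerate_dataset
    traits = compute_traits_table(tracheids, needles)
    calib = study_calibration()
    for (canopy, trt), cell in calib.items():
        g = traits[(traits["canopy"] == canopy) & (traits["treatment"] == trt)]
        assert g["N_t"].nunique() == 1
        n_round = g["N_t"].iloc[0]
        assert n_round == round(cell.n_t)
        assert g["d_max"].iloc[0] == pytest.approx(cell.d_max, rel=1e-9)
        assert g["F_t"].iloc[0] == pytest.approx(cell.f_t, rel=1e-9)
        # areas hit targets up to tracheid-count rounding
        assert g["A_n"].iloc[0] == pytest.approx(cell.a_n_mm2 * n_round / cell.n_t, rel=1e-6)
        # every needle in the group is identical
        assert g["k_th"].nunique() == 1


def test_between_tree_variance_increases_with_tree_cv():
    spread = []
    for cv in (0.0, 0.05, 0.15):
        cfg = SimulationConfig(trees_per_plot=8, tree_cv=cv, seed=21)
        traits = compute_traits_table(*generate_dataset(cfg))
        tree_means = traits.groupby(["treatment", "canopy", "tree_id"])["A_n"].mean()
        spread.append(tree_means.groupby(["treatment", "canopy"]).std().mean())
    assert spread[0] < spread[1] < spread[2]


def test_no_drought_calibration_copies_control_cells():
    calib = no_drought_calibration()
    for canopy in ("sun", "shade"):
        ctrl, drt = calib[(canopy, "control")], calib[(canopy, "drought")]
        assert drt.treatment == "drought"
        assert (drt.d_max, drt.n_t, drt.a_n_mm2) == (ctrl.d_max, ctrl.n_t, ctrl.a_n_mm2)


def test_infeasible_calibration_rejected_with_group_name():
    with pytest.raises(CalibrationError, match="sun/control"):
        GroupCalibration(canopy="sun", treatment="control", n_t=35.1,
                         d_max=6.2, d_min=3.8, f_t=1.75,
                         a_n_mm2=0.76, a_v_mm2=0.048,
                         a_x_um2=500.0,  # less than the implied lumen total
                         a_p_um2=2940.0)
    with pytest.raises(CalibrationError):
        base = study_calibration()
        incomplete = {k: v for k, v in base.items() if k != ("sun", "drought")}
        generate_dataset(SimulationConfig(seed=1), incomplete)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(trees_per_plot=0)
    with pytest.raises(ValueError):
        SimulationConfig(tree_cv=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(packing_mean=1.2)
    cfg = SimulationConfig(seed=9)
    assert SimulationConfig.from_dict(cfg.to_dict()) == cfg
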