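"""Tests of the mixed-model stage: fits, LRT ladder, group means, t-test."""

import numpy as np
import pandas as pd
import pytest

from needlehydro.hydraulics import compute_traits_table
from needlehydro.lme import (
    LmeSpec,
    fit_trait_model,
    full_report,
    group_means_ci,
    lrt_ladder,
    sapflow_ttest,
)
from needlehydro.validation import cell_mean_coverage


@pytest.fixture(scope="module")
def degenerate_traits(degenerate_dataset):
    return compute_traits_table(*degenerate_dataset)


class TestFit:
    def test_degenerate_data_gives_zero_variance_and_cell_means(self, degenerate_traits):
        fit = fit_trait_model(degenerate_traits, LmeSpec("A_n", "identity", "canopy*drought"))
        assert fit.degenerate
        assert fit.vc["tree"] == 0.0 and fit.vc["shoot(tree)"] == 0.0
        gm = group_means_ci(degenerate_traits, "A_n")
        cells = degenerate_traits.groupby(["canopy", "treatment"])["A_n"].mean()
        for row in gm.itertuples():
            assert row.mean == pytest.approx(cells[(row.canopy, row.treatment)], rel=1e-9)
            assert row.ci_hi - row.ci_lo == pytest.approx(0.0, abs=1e-12)

    def test_interaction_pvalue_well_defined(self, traits_table):
        lad = lrt_ladder(traits_table, "A_n")
        p = lad.loc[lad["factor"] == "drought x canopy height", "p"].iloc[0]
        assert 0.0 <= p <= 1.0

    def test_too_few_trees_rejected(self, traits_table):
        one_tree = traits_table[traits_table["tree_id"].isin(
            ["control_t01", "drought_t01", "drought_t02"])]
        with pytest.raises(ValueError, match="trees per plot"):
            fit_trait_model(one_tree, LmeSpec("A_n"))

    def test_log_transform_requires_positive(self, traits_table):
        bad = traits_table.copy()
        bad.loc[bad.index[0], "k_th"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            fit_trait_model(bad, LmeSpec("k_th", "log"))


class TestLadder:
    def test_nested_model_never_beats_parent(self, traits_table):
        for trait in ("A_n", "k_th", "N_t"):
            lad = lrt_ladder(traits_table, trait)
            assert (lad["lrt"] >= 0).all()
            assert lad["p"].between(0, 1).all()
            assert (lad["df"] == 1).all()

    def test_ladder_shape_and_aic_columns(self, traits_table):
        lad = lrt_ladder(traits_table, "d_max")
        assert list(lad["factor"]) == [
            "canopy height", "drought", "drought x canopy height"]
        assert lad[["aic_simple", "aic_complex"]].notna().all().all()

    def test_full_report_covers_every_trait(self, traits_table):
        tests, means = full_report(traits_table)
        assert tests["trait"].nunique() == 14
        assert len(tests) == 14 * 3
        assert len(means) == 14 * 4
        assert (means["ci_lo"] <= means["mean"]).all()
        assert (means["mean"] <= means["ci_hi"]).all()
        kth = means[means["trait"] == "k_th"]
        assert (kth["scale"] == "geometric").all()
        assert (means.loc[means["trait"] != "k_th", "scale"] == "arithmetic").all()


def test_equal_ratio_null_gives_nonsignificant_axpct():
    """When the generator's xylem/needle-area ratio is identical across
    treatments (no-drought calibration), the xylem-proportion trait shows
    no drought effect in >= 90% of replicates.  The ratio trait carries
    almost no tree-level variance, so its LRT is well behaved even at the
    field design of 3 trees per plot."""
    from needlehydro.simulate import SimulationConfig, generate_dataset, no_drought_calibration
    from needlehydro.validation import drought_lrt_pvalue

    calib = no_drought_calibration()
    seeds = np.random.SeedSequence(77).generate_state(30) % (2**31)
    nonsig = 0
    for seed in seeds:
        traits = compute_traits_table(
            *generate_dataset(SimulationConfig(seed=int(seed)), calib))
        nonsig += drought_lrt_pvalue(traits, "A_x_pct") >= 0.05
    assert nonsig / len(seeds) >= 0.90


class TestGroupMeans:
    def test_interval_ordering_everywhere(self, traits_table):
        for trait in ("A_n", "k_th"):
            gm = group_means_ci(traits_table, trait)
            assert (gm["ci_lo"] < gm["mean"]).all()
            assert (gm["mean"] < gm["ci_hi"]).all()

    def test_cell_mean_cis_cover_generator_targets(self):
        """Nominal-95% intervals cover the calibration truth ≥90% of cells
        in a scaled-up simulation (Wald intervals under-cover slightly)."""
        assert cell_mean_coverage(25, base_seed=13) >= 0.90


class TestSapflow:
    def test_published_totals_give_56_percent_reduction(self):
        res = sapflow_ttest([198.0, 198.0, 198.0], [87.0, 87.0 + 1e-9, 87.0])
        assert round(res.percent_reduction) == 56

    def test_identical_groups(self):
        res = sapflow_ttest([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.t == 0.0 and res.p == 1.0 and res.percent_reduction == 0.0

    def test_label_swap_negates_t(self):
        a, b = [200.0, 195.0, 190.0], [90.0, 85.0, 88.0]
        r1, r2 = sapflow_ttest(a, b), sapflow_ttest(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            sapflow_ttest([1.0], [2.0, 3.0])
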