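"""Derringer–Suich desirability transforms and multi-response optimization."""

import numpy as np
import pytest

import microenc as me
from microenc import desirability as des
from microenc.rsm import quadratic_model_matrix


@pytest.fixture(scope="module")
def study_fits():
    design, resp = me.quebracho_study(correct_run7_ey=True)
    scales = {"lc": 1.0, "ee": 1.0, "ey": 1.0, "tc": 10.0}
    return [
        me.fit_quadratic(design, resp[name].to_numpy(float) * s, name)
        for name, s in scales.items()
    ]


class TestIndividualDesirability:
    def test_anchor_endpoints(self):
        assert des.individual_desirability(10.0, "maximize", 0.0, 10.0) == 1.0
        assert des.individual_desirability(0.0, "maximize", 0.0, 10.0) == 0.0
        assert des.individual_desirability(0.0, "minimize", 0.0, 10.0) == 1.0

    def test_midpoint_linear_at_unit_weight(self):
        assert des.individual_desirability(5.0, "maximize", 0.0, 10.0) == 0.5

    def test_weight_curves_the_ramp(self):
        d = des.individual_desirability(5.0, "maximize", 0.0, 10.0, weight=2.0)
        assert d == pytest.approx(0.25)

    def test_clamped_outside_anchors(self):
        assert des.individual_desirability(-3.0, "maximize", 0.0, 10.0) == 0.0
        assert des.individual_desirability(13.0, "maximize", 0.0, 10.0) == 1.0

    def test_target_goal_peaks_at_target(self):
        d = des.individual_desirability(5.0, "target", 0.0, 10.0, target=5.0)
        assert d == 1.0
        assert des.individual_desirability(2.5, "target", 0.0, 10.0, target=5.0) == 0.5

    def test_bad_anchors_rejected(self):
        with pytest.raises(ValueError):
            des.individual_desirability(1.0, "maximize", 2.0, 1.0)


class TestOverallDesirability:
    def test_all_ones_gives_one(self):
        assert des.overall_desirability([1, 1, 1, 1]) == 1.0

    def test_any_zero_kills_overall(self):
        assert des.overall_desirability([0.9, 0.0, 1.0]) == 0.0

    def test_geometric_mean(self):
        assert des.overall_desirability([0.25, 1.0]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            des.overall_desirability([])

    def test_invariant_to_response_order(self, rng):
        d = rng.uniform(0.01, 1.0, size=6)
        perm = rng.permutation(6)
        assert des.overall_desirability(d) == pytest.approx(
            des.overall_desirability(d[perm])
        )

    def test_monotone_in_each_component(self):
        d = np.array([0.3, 0.6, 0.9])
        base = des.overall_desirability(d)
        for i in range(3):
            up = d.copy()
            up[i] = min(1.0, up[i] + 0.05)
            assert des.overall_desirability(up) >= base


class TestOptimize:
    def test_single_response_lc_argmax_matches_brute_force(self, study_fits):
        lc_fit = study_fits[0]
        spec = des.DesirabilitySpec(goals={"lc": des.ResponseGoal()})
        opt = des.optimize([lc_fit], spec, design_spec=me.quebracho_design_spec())
        # brute-force oracle: dense evaluation of the fitted surface
        g = np.linspace(-1, 1, 401)
        G1, G2 = np.meshgrid(g, g, indexing="ij")
        pred = quadratic_model_matrix(
            np.column_stack([G1.ravel(), G2.ravel()])
        ) @ lc_fit.params
        brute = np.column_stack([G1.ravel(), G2.ravel()])[np.argmax(pred)]
        assert np.allclose(opt.coded, brute, atol=1e-6)
        assert np.allclose(opt.coded, [1.0, -1.0], atol=1e-6)
        # actual factor settings: core 1.5 (shell 5), maltodextrin 2 (gum arabic 3)
        assert np.allclose(opt.actual, [1.5, 2.0], atol=1e-9)

    def test_single_response_overall_equals_individual(self, study_fits):
        spec = des.DesirabilitySpec(goals={"lc": des.ResponseGoal()})
        opt = des.optimize([study_fits[0]], spec)
        assert opt.overall == pytest.approx(opt.individual["lc"], abs=1e-12)

    def test_auto_anchors_span_zero_to_one_on_grid(self, study_fits):
        spec = des.DesirabilitySpec(goals={"lc": des.ResponseGoal()})
        grid = des.desirability_grid([study_fits[0]], spec, resolution=101)
        assert grid["d_lc"].max() == pytest.approx(1.0, abs=1e-9)
        assert grid["d_lc"].min() == pytest.approx(0.0, abs=1e-9)

    def test_grid_max_consistent_with_optimize(self, study_fits):
        spec = des.DesirabilitySpec(
            goals={f.response_name: des.ResponseGoal() for f in study_fits}
        )
        grid = des.desirability_grid(study_fits, spec, resolution=201)
        opt = des.optimize(study_fits, spec, resolution=201)
        assert opt.overall >= grid["D"].max() - 1e-9

    def test_halving_grid_spacing_is_stable(self, study_fits):
        spec = des.DesirabilitySpec(
            goals={f.response_name: des.ResponseGoal() for f in study_fits}
        )
        coarse = des.optimize(study_fits, spec, resolution=51)
        fine = des.optimize(study_fits, spec, resolution=101)
        cell = 2.0 / 50
        assert np.all(np.abs(coarse.coded - fine.coded) <= cell + 1e-9)

    def test_mismatched_factors_rejected(self, study_fits, rng):
        other_spec = me.DesignSpec(
            factors=(me.FactorSpec("p", 0.0, 1.0), me.FactorSpec("q", 0.0, 1.0))
        )
        other = me.fit_quadratic(
            me.generate_ccd(other_spec), rng.normal(size=13), "lc2"
        )
        spec = des.DesirabilitySpec(
            goals={"lc": des.ResponseGoal(), "lc2": des.ResponseGoal()}
        )
        with pytest.raises(ValueError, match="same design factors"):
            des.optimize([study_fits[0], other], spec)

    def test_degenerate_region_rejected(self, study_fits):
        spec = des.DesirabilitySpec(
            goals={"lc": des.ResponseGoal()}, bounds=((1.0, 1.0), (-1.0, 1.0))
        )
        with pytest.raises(ValueError):
            des.optimize([study_fits[0]], spec)


class TestDesirabilityGrid:
    def test_constant_fits_give_uniform_grid(self, rng):
        ccd = me.generate_ccd(me.quebracho_design_spec())
        fit = me.fit_quadratic(ccd, np.full(13, 5.0), "flat")
        spec = des.DesirabilitySpec(
            goals={"flat": des.ResponseGoal(lower=0.0, upper=10.0)}
        )
        grid = des.desirability_grid([fit], spec, resolution=11)
        assert np.allclose(grid["D"], grid["D"].iloc[0])

    def test_high_desirability_region_extractable(self, study_fits):
        spec = des.DesirabilitySpec(
            goals={f.response_name: des.ResponseGoal() for f in study_fits}
        )
        grid = des.desirability_grid(study_fits, spec, resolution=51)
        region = grid[grid["D"] > 0.8]
        assert {"core_shell", "md_ga", "D"} <= set(grid.columns)
        assert len(region) < len(grid)
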