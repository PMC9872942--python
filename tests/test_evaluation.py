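"""Error metrics, region masks, throat-slab velocity and report aggregation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stenoflow as sf
from stenoflow.datasets import Sample
from stenoflow.errors import UndefinedMetricError
from stenoflow.evaluation import REGIONS, build_error_report, consistency


class TestMRE:
    def test_perfect_prediction_is_zero(self):
        y = np.array([1.0, -2.0, 3.0])
        assert sf.mre(y, y) == 0.0

    def test_hand_example_three_points(self):
        assert sf.mre([1, 2, 4], [1.1, 1.8, 4.4]) == pytest.approx(10.0)

    def test_uniform_relative_error_is_scale_invariant(self):
        y = np.array([0.5, 3.0, 40.0])
        assert sf.mre(y, 1.1 * y) == pytest.approx(10.0)
        assert sf.mre(1e6 * y, 1.1e6 * y) == pytest.approx(10.0)

    def test_denominator_guard_excludes_near_zero_truth(self):
        y = np.array([0.0, 1e-9, 1.0, 2.0])
        value, excluded = sf.mre(y, y + 0.1, return_excluded=True)
        assert excluded == 2
        assert value == pytest.approx(100.0 * (0.1 / 1.0 + 0.1 / 2.0) / 2.0)

    def test_all_excluded_raises(self):
        with pytest.raises(UndefinedMetricError):
            sf.mre(np.zeros(5), np.ones(5))


class TestNMAE:
    def test_perfect_prediction_is_zero(self):
        y = np.array([0.0, 5.0, 10.0])
        assert sf.nmae(y, y) == 0.0

    def test_hand_example_two_points(self):
        assert sf.nmae([0.0, 10.0], [1.0, 9.0]) == pytest.approx(10.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(c=st.floats(1e-3, 1e3))
    def test_joint_scaling_leaves_nmae_unchanged(self, c):
        y = np.array([0.0, 2.0, 10.0])
        y_hat = np.array([0.5, 2.5, 9.0])
        assert sf.nmae(c * y, c * y_hat) == pytest.approx(sf.nmae(y, y_hat))

    def test_zero_range_raises(self):
        with pytest.raises(UndefinedMetricError):
            sf.nmae(np.full(4, 2.0), np.zeros(4))

    def test_rotation_invariance_of_magnitude_metrics(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(50, 3))
        v_hat = v + 0.05 * rng.normal(size=(50, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        a = sf.nmae(np.linalg.norm(v, axis=1), np.linalg.norm(v_hat, axis=1))
        b = sf.nmae(np.linalg.norm(v @ rot.T, axis=1),
                    np.linalg.norm(v_hat @ rot.T, axis=1))
        assert a == pytest.approx(b, rel=1e-12)


class TestRegions:
    def test_whole_region_includes_everything(self, small_sample):
        mask = sf.region_mask(small_sample, "whole")
        assert mask.mask.all()

    def test_postoperative_stenosis_mask_is_empty(self, small_sample):
        twin_spec = sf.make_postoperative(small_sample.spec)
        cavity = sf.build_cavity_cloud(twin_spec, 800, 1)
        fluid = sf.sample_fluid_points(twin_spec, 2000, 2)
        field = sf.compute_field(twin_spec, fluid)
        twin = Sample(twin_spec, "postoperative", cavity, fluid, field)
        assert sf.region_mask(twin, "stenosis").count == 0

    def test_stenotic_fraction_matches_lesion_share(self):
        # across sampled vessels the stenotic windows hold roughly a tenth
        # of the fluid points (checked as a 5-20% band)
        fracs = []
        for seed in range(12):
            spec = sf.sample_vessel_spec(seed)
            fluid = sf.sample_fluid_points(spec, 3000, seed)
            field = sf.compute_field(spec, fluid)
            sample = Sample(spec, "preoperative",
                            sf.build_cavity_cloud(spec, 300, seed), fluid, field)
            fracs.append(sf.region_mask(sample, "stenosis").count / fluid.n2)
        assert 0.05 <= np.mean(fracs) <= 0.20

    def test_bifurcation_mask_is_a_ball_around_the_apex(self, small_sample):
        from stenoflow.geometry import VesselGeometry
        geom = VesselGeometry(small_sample.spec)
        mask = sf.region_mask(small_sample, "bifurcation")
        d = np.linalg.norm(small_sample.fluid_coords.points - geom.apex, axis=1)
        assert np.array_equal(mask.mask, d <= 1.5 * small_sample.spec.d_cca / 2)
        assert 0 < mask.count < small_sample.fluid_coords.n2


class TestMeanStenoticVelocity:
    def test_uniform_speed_field_returns_that_speed(self, small_sample):
        v = np.tile([0.0, 0.0, 0.7], (small_sample.fluid_coords.n2, 1))
        assert sf.mean_stenotic_velocity(small_sample, v) == pytest.approx(0.7)

    def test_poiseuille_slab_mean_approximates_mean_axial_speed(self):
        # volume-uniform slab average of 2*Vbar*(1 - (r/R)^2) -> Vbar
        spec = sf.straight_tube_spec(6.0, 40.0,
                                     [sf.StenosisSpec("CCA", 20.0, 10.0, 0.0)])
        # severity 0: plain tube, throat slab at z=20
        fluid = sf.sample_fluid_points(spec, 30000, 0)
        inflow = sf.InflowSpec(mass_flow_inlet=1e-5 * 1060.0)
        field = sf.compute_field(spec, fluid, inflow, stenosis_loss=False)
        sample = Sample(spec, "preoperative",
                        sf.build_cavity_cloud(spec, 300, 0), fluid, field)
        vbar = 1e-5 / (np.pi * (3e-3) ** 2)
        assert sf.mean_stenotic_velocity(sample) == pytest.approx(vbar, rel=0.05)

    def test_mean_throat_speed_increases_with_severity(self):
        means = []
        for sigma in (0.2, 0.5, 0.7):
            spec = sf.VesselSpec(d_cca=8.0, d_ica=5.4, d_eca=4.4,
                                 bifurcation_angle=50.0,
                                 stenoses=(sf.StenosisSpec("ICA", 22.0, 12.0, sigma),))
            fluid = sf.sample_fluid_points(spec, 4000, 3)
            field = sf.compute_field(spec, fluid)
            sample = Sample(spec, "preoperative",
                            sf.build_cavity_cloud(spec, 300, 3), fluid, field)
            means.append(sf.mean_stenotic_velocity(sample))
        assert means[0] < means[1] < means[2]


class TestReportsAndConsistency:
    def test_perfect_predictions_give_zero_errors_and_unit_r(self, smoke_bundles):
        bundle = smoke_bundles[("preoperative", "velocity")]
        truth = [bundle.samples[int(i)].flow.velocity for i in bundle.test_indices]
        report = build_error_report(bundle, truth, "test")
        assert (report.table["mre_mean"] == 0).all()
        assert (report.table["nmae_mean"] == 0).all()

    def test_aggregation_matches_direct_recomputation(self, smoke_bundles):
        bundle = smoke_bundles[("preoperative", "pressure")]
        rng = np.random.default_rng(1)
        preds = [bundle.samples[int(i)].flow.pressure[:, None] *
                 (1 + 0.02 * rng.standard_normal())
                 for i in bundle.test_indices]
        report = build_error_report(bundle, preds, "test")
        for _, row in report.table.iterrows():
            grp = report.per_sample[(report.per_sample["region"] == row["region"])]
            assert row["mre_mean"] == pytest.approx(grp["mre"].mean())
            assert row["nmae_sd"] == pytest.approx(grp["nmae"].std(ddof=0))

    def test_single_sample_has_zero_sd(self, small_sample):
        from stenoflow.datasets import DatasetBundle, NormalizationParams
        samples = [small_sample] * 10
        centers = np.tile(small_sample.cavity.points.mean(0), (10, 1))
        scales = np.ones(10)
        bundle = DatasetBundle(samples, "pressure", "preoperative",
                               np.arange(1, 10), np.array([0]),
                               NormalizationParams(centers, scales, 1.0), seed=0)
        preds = [samples[0].flow.pressure[:, None] * 1.01]
        report = build_error_report(bundle, preds, "test")
        assert (report.table["nmae_sd"] == 0).all()
        assert (report.table["n_samples"] == 1).all()

    def test_consistency_r_is_one_for_truth_predictions(self, smoke_bundles):
        bundle = smoke_bundles[("preoperative", "velocity")]
        truth = [bundle.samples[int(i)].flow.velocity for i in bundle.test_indices]
        assert len(truth) >= 2
        res = consistency(bundle, truth, "test")
        assert res.r == pytest.approx(1.0)
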