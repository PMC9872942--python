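"""Geometry generator: spec sampling, stenosis profile, point clouds."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stenoflow as sf
from stenoflow.config import CCA, ECA, ICA
from stenoflow.errors import ConfigurationError, DomainError
from stenoflow.geometry import VesselGeometry


class TestSpecSampling:
    def test_degenerate_ranges_reproduce_point_values(self):
        ranges = sf.GeometryRanges(
            d_cca=(8.0, 8.0), d_ica=(5.0, 5.0), d_eca=(4.0, 4.0),
            bifurcation_angle=(60.0, 60.0), n_stenoses=(1, 1),
            severity=(0.3, 0.3), stenosis_length=(10.0, 10.0))
        spec = sf.sample_vessel_spec(5, ranges)
        assert spec.d_cca == 8.0 and spec.d_ica == 5.0 and spec.d_eca == 4.0
        assert spec.bifurcation_angle == 60.0
        (st_,) = spec.stenoses
        assert st_.severity == 0.3 and st_.length == 10.0

    def test_default_ranges_give_one_or_two_bounded_stenoses(self):
        spec = sf.sample_vessel_spec(0, sf.GeometryRanges(), "preoperative")
        assert 1 <= len(spec.stenoses) <= 2
        for st_ in spec.stenoses:
            assert st_.severity <= 0.8
            assert 5.0 <= st_.length <= 20.0

    def test_sampled_parameters_stay_inside_bounds(self, default_ranges):
        r = default_ranges
        specs = [sf.sample_vessel_spec(seed, r) for seed in range(500)]
        for spec in specs:
            assert r.d_cca[0] <= spec.d_cca <= r.d_cca[1]
            assert r.d_ica[0] <= spec.d_ica <= r.d_ica[1]
            assert r.d_eca[0] <= spec.d_eca <= r.d_eca[1]
            assert r.bifurcation_angle[0] <= spec.bifurcation_angle <= r.bifurcation_angle[1]
            assert 1 <= len(spec.stenoses) <= 2
            for st_ in spec.stenoses:
                assert r.severity[0] <= st_.severity <= r.severity[1]
                assert r.stenosis_length[0] <= st_.length <= r.stenosis_length[1]
                lo, hi = st_.window
                assert lo >= 0.0 and hi <= spec.branch_lengths[st_.branch]

    def test_same_seed_same_spec(self):
        assert sf.sample_vessel_spec(42) == sf.sample_vessel_spec(42)

    def test_postoperative_stage_has_no_stenoses(self):
        spec = sf.sample_vessel_spec(3, stage="postoperative")
        assert spec.stenoses == ()

    def test_invalid_range_rejected(self):
        with pytest.raises(ConfigurationError):
            sf.GeometryRanges(d_cca=(9.0, 6.7))

    def test_ranges_load_from_yaml(self, tmp_path):
        from stenoflow.config import load_ranges
        path = tmp_path / "ranges.yaml"
        path.write_text(
            "d_cca: [7.0, 8.0]\nseverity: [0.2, 0.6]\nn_stenoses: [1, 1]\n")
        ranges = load_ranges(path)
        assert ranges.d_cca == (7.0, 8.0)
        assert ranges.severity == (0.2, 0.6)
        assert ranges.d_ica == sf.GeometryRanges().d_ica  # defaults kept

    def test_two_stenoses_on_same_branch_never_overlap(self, default_ranges):
        for seed in range(300):
            spec = sf.sample_vessel_spec(seed, default_ranges)
            if len(spec.stenoses) == 2:
                a, b = spec.stenoses
                if a.branch == b.branch:
                    assert a.window[1] < b.window[0] or b.window[1] < a.window[0]


class TestStenosedRadius:
    def test_no_stenosis_returns_baseline(self, tube_spec):
        s = np.linspace(0, 40, 50)
        assert np.allclose(sf.stenosed_radius(tube_spec, CCA, s), 3.0)

    def test_throat_diameter_reduced_by_severity(self):
        spec = sf.straight_tube_spec(6.0, 40.0,
                                     [sf.StenosisSpec(CCA, 20.0, 10.0, 0.6)])
        assert sf.stenosed_radius(spec, CCA, 20.0) == pytest.approx(0.4 * 3.0)

    def test_profile_meets_baseline_smoothly_at_window_edges(self):
        spec = sf.straight_tube_spec(6.0, 40.0,
                                     [sf.StenosisSpec(CCA, 20.0, 10.0, 0.5)])
        for edge in (15.0, 25.0):
            assert sf.stenosed_radius(spec, CCA, edge) == pytest.approx(3.0)
            # derivative continuous across the edge (cosine profile has zero slope)
            h = 1e-5
            inner = (sf.stenosed_radius(spec, CCA, edge) -
                     sf.stenosed_radius(spec, CCA, edge - np.sign(edge - 20.0) * h)) / h
            assert abs(inner) < 1e-3

    def test_out_of_branch_arc_length_rejected(self, tube_spec):
        with pytest.raises(DomainError):
            sf.stenosed_radius(tube_spec, CCA, 41.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(sigma_lo=st.floats(0.05, 0.4), dsigma=st.floats(0.05, 0.35))
    def test_minimum_radius_strictly_decreasing_in_severity(self, sigma_lo, dsigma):
        s = np.linspace(15.0, 25.0, 201)
        radii = []
        for sigma in (sigma_lo, sigma_lo + dsigma):
            spec = sf.straight_tube_spec(6.0, 40.0,
                                         [sf.StenosisSpec(CCA, 20.0, 10.0, sigma)])
            radii.append(sf.stenosed_radius(spec, CCA, s).min())
        assert radii[1] < radii[0]


class TestCavityCloud:
    def test_straight_tube_points_lie_on_the_surface(self, tube_spec):
        cloud = sf.build_cavity_cloud(tube_spec, 1000, 0)
        r = np.linalg.norm(cloud.points[:, :2], axis=1)
        assert np.allclose(r, 3.0, atol=1e-6 * 3.0)
        assert abs(cloud.n1 - 1000) <= 0.05 * 1000

    def test_severe_stenosis_reaches_the_throat_radius(self):
        spec = sf.straight_tube_spec(6.0, 40.0,
                                     [sf.StenosisSpec(CCA, 20.0, 10.0, 0.8)])
        cloud = sf.build_cavity_cloud(spec, 4000, 0)
        r = np.linalg.norm(cloud.points[:, :2], axis=1)
        assert r.min() == pytest.approx(0.2 * 3.0, rel=0.02)

    def test_same_seed_bitwise_identical(self, stenosed_spec):
        a = sf.build_cavity_cloud(stenosed_spec, 500, 9)
        b = sf.build_cavity_cloud(stenosed_spec, 500, 9)
        assert np.array_equal(a.points, b.points)

    def test_bifurcation_points_sit_on_their_nearest_tube(self, stenosed_spec):
        cloud = sf.build_cavity_cloud(stenosed_spec, 2000, 4)
        geom = VesselGeometry(stenosed_spec)
        # independent recomputation: distance to the closest branch axis
        ok = np.zeros(cloud.n1, dtype=bool)
        for name in geom.branch_order:
            b = geom.branches[name]
            rel = cloud.points - b.origin
            s = rel @ b.tangent
            d = np.linalg.norm(rel - s[:, None] * b.tangent, axis=1)
            in_slab = (s >= -1e-9) & (s <= b.length + 1e-9)
            r = geom.radius(name, np.clip(s, 0, b.length))
            ok |= in_slab & (np.abs(d - r) <= 1e-6 * r)
        assert ok.all()

    def test_cloud_count_tolerance_and_finiteness(self, stenosed_spec):
        cloud = sf.build_cavity_cloud(stenosed_spec, 1500, 11)
        assert abs(cloud.n1 - 1500) <= 0.05 * 1500
        assert np.isfinite(cloud.points).all()


class TestFluidPoints:
    def test_straight_tube_points_strictly_interior(self, tube_spec):
        pts = sf.sample_fluid_points(tube_spec, 2000, 1).points
        r = np.linalg.norm(pts[:, :2], axis=1)
        assert (r < 3.0).all()
        assert (pts[:, 2] >= 0).all() and (pts[:, 2] <= 40.0).all()

    def test_all_points_pass_point_in_lumen_check(self, stenosed_spec):
        cloud = sf.sample_fluid_points(stenosed_spec, 5000, 2)
        assert abs(cloud.n2 - 5000) <= 0.05 * 5000
        geom = VesselGeometry(stenosed_spec)
        # brute-force membership: inside at least one stenosed tube
        inside = np.zeros(cloud.n2, dtype=bool)
        for name in geom.branch_order:
            b = geom.branches[name]
            rel = cloud.points - b.origin
            s = rel @ b.tangent
            d = np.linalg.norm(rel - s[:, None] * b.tangent, axis=1)
            inside |= (s >= 0) & (s <= b.length) & (d < geom.radius(name, np.clip(s, 0, b.length)))
        assert inside.all()

    def test_zero_target_is_an_argument_error(self, tube_spec):
        with pytest.raises(ValueError):
            sf.sample_fluid_points(tube_spec, 0, 0)

    def test_interior_points_never_on_surface(self, stenosed_spec):
        geom = VesselGeometry(stenosed_spec)
        pts = sf.sample_fluid_points(stenosed_spec, 3000, 5).points
        # tolerance-checked against the stenosed radius of the owning branch
        on_surface = np.zeros(len(pts), dtype=bool)
        covered = np.zeros(len(pts), dtype=bool)
        for name in geom.branch_order:
            s, d = geom.project(name, pts)
            in_slab = (s >= 0) & (s <= geom.branches[name].length)
            r = geom.radius(name, np.clip(s, 0, geom.branches[name].length))
            inside = in_slab & (d < r)
            on_surface |= inside & (d > r * (1 - 1e-12))
            covered |= inside
        assert covered.all() and not on_surface.any()


class TestPostoperativeTwin:
    def test_twin_zeroes_severities_and_keeps_geometry(self, stenosed_spec):
        twin = sf.make_postoperative(stenosed_spec)
        assert twin.d_cca == stenosed_spec.d_cca
        assert twin.bifurcation_angle == stenosed_spec.bifurcation_angle
        assert len(twin.stenoses) == len(stenosed_spec.stenoses)
        assert twin.effective_stenoses == ()

    def test_twin_radius_equals_baseline_everywhere(self, stenosed_spec):
        twin = sf.make_postoperative(stenosed_spec)
        s = np.linspace(0, 40, 200)
        assert np.allclose(sf.stenosed_radius(twin, ICA, s), stenosed_spec.d_ica / 2)

    def test_twin_cavity_equals_unstenosed_baseline_cloud(self, stenosed_spec):
        twin = sf.make_postoperative(stenosed_spec)
        baseline = sf.VesselSpec(
            d_cca=stenosed_spec.d_cca, d_ica=stenosed_spec.d_ica,
            d_eca=stenosed_spec.d_eca,
            bifurcation_angle=stenosed_spec.bifurcation_angle,
            branch_lengths=dict(stenosed_spec.branch_lengths))
        a = sf.build_cavity_cloud(twin, 800, 3)
        b = sf.build_cavity_cloud(baseline, 800, 3)
        assert np.array_equal(a.points, b.points)

    def test_pre_and_post_clouds_coincide_outside_windows(self, stenosed_spec):
        pre = sf.build_cavity_cloud(stenosed_spec, 1200, 6).points
        post = sf.build_cavity_cloud(sf.make_postoperative(stenosed_spec), 1200, 6).points
        assert pre.shape == post.shape
        geom = VesselGeometry(stenosed_spec)
        moved = ~np.isclose(pre, post).all(axis=1)
        (st_,) = stenosed_spec.stenoses
        s, _ = geom.project(st_.branch, post[moved])
        lo, hi = st_.window
        assert ((s >= lo - 1e-9) & (s <= hi + 1e-9)).all()


class TestExports:
    def test_ply_and_vtk_round_numbers(self, tmp_path, tube_spec):
        cloud = sf.build_cavity_cloud(tube_spec, 200, 0)
        ply = tmp_path / "c.ply"
        vtk = tmp_path / "c.vtk"
        from stenoflow.geometry import write_ply, write_vtk_polydata
        write_ply(cloud.points, ply)
        write_vtk_polydata(cloud.points, vtk,
                           point_data={"pressure": np.zeros(cloud.n1)})
        header = ply.read_text().splitlines()
        assert header[0] == "ply" and f"element vertex {cloud.n1}" in header[2]
        text = vtk.read_text()
        assert f"POINTS {cloud.n1} double" in text and "SCALARS pressure" in text

    def test_spec_json_round_trip(self, stenosed_spec):
        assert sf.VesselSpec.from_json(stenosed_spec.to_json()) == stenosed_spec
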