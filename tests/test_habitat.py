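"""Raster sampling, rotation null, KS testing, depth-band occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from shelfbreak.habitat_association import (KSResult, RotationNullConfig,
                                            build_rotation_null,
                                            depth_band_occupancy,
                                            ks_two_sample,
                                            observed_depth_samples,
                                            repeated_subsample_test,
                                            rotate_track, sample_raster_at)
from shelfbreak.kinematics import great_circle_distance
from shelfbreak.track_io import RasterGrid

from conftest import make_track


def uniform_ocean(depth=-500.0, west=-5.0, north=5.0, n=100, cell=0.1):
    return RasterGrid(west=west, north=north, dlon=cell, dlat=cell,
                      values=np.ma.asarray(np.full((n, n), depth)))


class TestSampleRasterAt:
    def test_cell_centre_returns_cell_value(self):
        vals = np.arange(12, dtype=float).reshape(3, 4)
        g = RasterGrid(west=0.0, north=3.0, dlon=1.0, dlat=1.0,
                       values=np.ma.asarray(vals))
        # centre of row 1, col 2
        assert sample_raster_at(g, [(2.5, 1.5)])[0] == vals[1, 2]

    def test_boundary_point_follows_floor_convention(self):
        vals = np.arange(12, dtype=float).reshape(3, 4)
        g = RasterGrid(west=0.0, north=3.0, dlon=1.0, dlat=1.0,
                       values=np.ma.asarray(vals))
        # lon exactly on the edge between col 1 and col 2: floor((2-0)/1) = 2
        assert sample_raster_at(g, [(2.0, 1.5)])[0] == vals[1, 2]
        # lat exactly on the edge between row 0 and row 1: floor((3-2)/1) = 1
        assert sample_raster_at(g, [(0.5, 2.0)])[0] == vals[1, 0]

    def test_masked_cell_returns_nan(self):
        vals = np.ma.masked_array(np.full((2, 2), -100.0),
                                  mask=[[False, True], [False, False]])
        g = RasterGrid(west=0.0, north=2.0, dlon=1.0, dlat=1.0, values=vals)
        out = sample_raster_at(g, [(1.5, 1.5), (0.5, 1.5)])
        assert np.isnan(out[0]) and out[1] == -100.0

    def test_point_outside_extent_names_point(self):
        g = uniform_ocean()
        with pytest.raises(ValueError, match="99"):
            sample_raster_at(g, [(99.0, 0.0)])


class TestRotateTrack:
    def test_full_turn_is_identity(self):
        t = make_track([1.0, 1.5, 2.0], [0.5, 0.6, 0.9], dt_s=60.0)
        r = rotate_track(t, 360.0, origin=(1.0, 0.5))
        assert np.allclose(r.lon, t.lon, atol=1e-6)
        assert np.allclose(r.lat, t.lat, atol=1e-6)
        assert (r.time == t.time).all()

    def test_north_rotates_to_east_at_quarter_turn(self):
        t = make_track([0.0, 0.0], [0.0, 1.0], dt_s=60.0)
        r = rotate_track(t, 90.0, origin=(0.0, 0.0))
        assert r.lon[1] == pytest.approx(1.0, abs=1e-9)
        assert r.lat[1] == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(0.0, 360.0))
    @settings(deadline=None, max_examples=40)
    def test_rotation_is_an_isometry(self, angle):
        t = make_track([10.0, 10.4, 10.9, 11.0], [-40.0, -40.3, -40.1, -39.7],
                       dt_s=600.0)
        origin = (10.0, -40.0)
        r = rotate_track(t, angle, origin)
        for i in range(len(t)):
            d0 = great_circle_distance(origin, (t.lon[i], t.lat[i]))
            d1 = great_circle_distance(origin, (r.lon[i], r.lat[i]))
            assert d1 == pytest.approx(d0, rel=1e-6, abs=1e-6)
        for i in range(len(t) - 1):
            seg0 = great_circle_distance((t.lon[i], t.lat[i]), (t.lon[i + 1], t.lat[i + 1]))
            seg1 = great_circle_distance((r.lon[i], r.lat[i]), (r.lon[i + 1], r.lat[i + 1]))
            assert seg1 == pytest.approx(seg0, rel=1e-6, abs=1e-6)


class TestBuildRotationNull:
    def test_fifteen_rotation_replicates(self):
        t = make_track([0.0, 0.2, 0.4], [0.0, 0.1, 0.2], dt_s=60.0)
        null = build_rotation_null(t, uniform_ocean())
        assert null.attrs["n_angles"] == 15
        assert sorted(null["angle_deg"].unique()) == [22.5 * k for k in range(1, 16)]
        assert len(null) == 15 * len(t)

    def test_uniform_ocean_null_depths_equal_observed(self):
        t = make_track([0.0, 0.2, 0.4], [0.0, 0.1, 0.2], dt_s=60.0)
        null = build_rotation_null(t, uniform_ocean(depth=-500.0))
        obs = observed_depth_samples(t, uniform_ocean(depth=-500.0))
        assert set(null["depth_m"]) == {500.0} == set(obs["depth_m"])
        assert (null["source"] == "ROTATED").all()

    def test_land_sectors_are_excluded(self):
        # land occupies the eastern half of the grid
        vals = np.full((100, 100), -500.0)
        vals[:, 50:] = 10.0
        g = RasterGrid(west=-5.0, north=5.0, dlon=0.1, dlat=0.1,
                       values=np.ma.asarray(vals))
        t = make_track([0.0, 0.0], [0.5, 1.0], dt_s=60.0)
        null = build_rotation_null(t, g)
        assert len(null) < 15 * len(t)
        # every retained sample is over water
        assert (null["depth_m"] > 0).all()

    def test_labels_carry_over_from_unrotated_fixes(self):
        t = make_track([0.0, 0.2], [0.0, 0.1], dt_s=60.0)
        null = build_rotation_null(t, uniform_ocean(), labels=np.array([0, 1]))
        for angle, grp in null.groupby("angle_deg"):
            assert list(grp["label"]) == [0, 1]


def brute_force_ks_d(a, b):
    """Oracle: evaluate |ECDF_a - ECDF_b| at every pooled sample point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        diff = abs(np.mean(a <= x) - np.mean(b <= x))
        best = max(best, diff)
    return best


class TestKSTwoSample:
    def test_identical_samples_have_zero_d(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.D == 0.0 and r.p == 1.0

    def test_disjoint_supports_have_d_one(self):
        r = ks_two_sample([1, 2], [3, 4])
        assert r.D == 1.0

    def test_interleaved_thirds(self):
        assert ks_two_sample([1, 3, 5], [2, 4, 6]).D == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_d_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(1, 21, size=2)
            a = np.round(rng.normal(size=n1), 1)  # rounding forces ties
            b = np.round(rng.normal(size=n2), 1)
            assert ks_two_sample(a, b).D == brute_force_ks_d(a, b)

    def test_d_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.normal(size=37), rng.normal(0.3, 1.0, size=52)
            ours = ks_two_sample(a, b)
            ref = stats.ks_2samp(a, b)
            assert ours.D == pytest.approx(ref.statistic, abs=1e-15)


class TestRepeatedSubsampleTest:
    def test_same_seed_reproduces_everything(self):
        rng = np.random.default_rng(2)
        obs, pool = rng.normal(size=50), rng.normal(size=600)
        r1 = repeated_subsample_test(obs, pool, n_runs=100, seed=9)
        r2 = repeated_subsample_test(obs, pool, n_runs=100, seed=9)
        assert np.array_equal(r1.D, r2.D) and np.array_equal(r1.p, r2.p)
        assert r1.prop_significant == r2.prop_significant

    def test_strong_shift_always_significant(self):
        rng = np.random.default_rng(3)
        pool = rng.normal(size=1000)
        obs = rng.normal(loc=10.0, size=80)  # 10 SD shift
        r = repeated_subsample_test(obs, pool, n_runs=200, seed=0)
        assert r.prop_significant == 1.0
        assert r.significant_overall

    def test_pool_smaller_than_observed_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            repeated_subsample_test(np.zeros(10), np.zeros(5), n_runs=10, seed=0)

    def test_null_calibration_with_continuous_pool(self):
        """Observed drawn from the pool's own distribution: rejection rate
        stays near the nominal level."""
        rng = np.random.default_rng(4)
        pool = rng.normal(size=4000)
        obs = rng.normal(size=300)
        r = repeated_subsample_test(obs, pool, n_runs=400, alpha=0.05, seed=1)
        assert 0.0 <= r.prop_significant <= 0.12
        assert not r.significant_overall


class TestDepthBandOccupancy:
    def test_all_in_band(self):
        assert depth_band_occupancy(np.full(10, 800.0)) == 1.0

    def test_counting(self):
        assert depth_band_occupancy([100.0, 800.0, 3000.0, 800.0]) == 0.5

    def test_band_edges_inclusive(self):
        assert depth_band_occupancy([600.0, 1000.0, 599.999, 1000.001]) == 0.5

    def test_empty_is_nan(self):
        assert np.isnan(depth_band_occupancy([]))

    def test_per_label_occupancy(self):
        depths = [700.0, 2000.0, 800.0, 100.0]
        labels = [0, 0, 1, 1]
        out = depth_band_occupancy(depths, labels=labels)
        assert out[0] == 0.5 and out[1] == 0.5
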