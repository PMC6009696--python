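"""%RD geometry, summaries, Mann-Whitney and shift-table arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ctradial as ct
from ctradial.synthetic import ellipsoid_boundary_distance, ellipsoid_mask


def _sphere_mask(radius=4.0, voxel=0.105):
    n = int(np.ceil(2 * (radius + 0.3) / voxel))
    shape = (n, n, n)
    center = np.full(3, n * voxel / 2)
    return ellipsoid_mask(shape, (voxel,) * 3, center, (radius,) * 3), center, (voxel,) * 3


class TestBoundaryIntersection:
    def test_sphere_matches_analytic_radius_within_one_step(self):
        mask, center, voxel = _sphere_mask(radius=4.0)
        step = min(voxel) / 2
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            B = ct.boundary_intersection(mask, center, center + 2.0 * d,
                                         voxel_size=voxel)
            assert np.linalg.norm(B - center) == pytest.approx(4.0, abs=step)

    def test_ellipsoid_major_axis_gives_semiaxis(self):
        voxel = (0.34, 0.105, 0.105)
        shape = (28, 96, 96)
        center = np.asarray(shape) * np.asarray(voxel) / 2
        semi = (3.2, 4.0, 4.0)
        mask = ellipsoid_mask(shape, voxel, center, semi)
        B = ct.boundary_intersection(mask, center, center + np.array([0, 0, 1.0]),
                                     voxel_size=voxel)
        # in-plane axis resolved at in-plane voxel resolution
        assert np.linalg.norm(B - center) == pytest.approx(4.0, abs=0.105 / 2)
        B = ct.boundary_intersection(mask, center, center + np.array([1.0, 0, 0]),
                                     voxel_size=voxel)
        # axial boundary limited by the coarse z voxel (half a voxel)
        assert np.linalg.norm(B - center) == pytest.approx(3.2, abs=0.34 / 2)

    def test_b_is_collinear_and_beyond_c(self):
        mask, center, voxel = _sphere_mask(radius=3.0)
        C = center + np.array([0.5, 1.0, -0.8])
        B = ct.boundary_intersection(mask, center, C, voxel_size=voxel)
        d_c = (C - center) / np.linalg.norm(C - center)
        d_b = (B - center) / np.linalg.norm(B - center)
        assert np.allclose(d_c, d_b, atol=1e-12)
        assert np.linalg.norm(B - center) >= np.linalg.norm(C - center)

    def test_degenerate_direction_raises(self):
        mask, center, voxel = _sphere_mask(radius=2.0)
        with pytest.raises(ct.GeometryError):
            ct.boundary_intersection(mask, center, center, voxel_size=voxel)

    def test_external_centre_raises(self):
        mask, center, voxel = _sphere_mask(radius=2.0)
        outside = center * 0.0
        with pytest.raises(ct.GeometryError):
            ct.boundary_intersection(mask, outside, center, voxel_size=voxel)


class TestPercentRd:
    def test_centre_is_zero(self):
        N = np.zeros(3)
        assert ct.percent_rd(N, N, np.array([5.0, 0, 0])) == 0.0

    def test_boundary_is_hundred(self):
        N = np.zeros(3)
        B = np.array([0.0, 3.0, 4.0])
        assert ct.percent_rd(N, B, B) == 100.0

    def test_sphere_interior_point(self):
        # r = 10 sphere, C at 6 um from the centre -> 60%
        N = np.zeros(3)
        d = np.array([1.0, 2.0, 2.0]) / 3.0
        assert ct.percent_rd(N, 6.0 * d, 10.0 * d) == pytest.approx(60.0)

    def test_overshoot_clamped_to_hundred(self):
        N = np.zeros(3)
        d = np.array([0.0, 0.0, 1.0])
        assert ct.percent_rd(N, 10.1 * d, 10.0 * d) == 100.0

    def test_zero_span_raises(self):
        N = np.zeros(3)
        with pytest.raises(ct.GeometryError):
            ct.percent_rd(N, N, N)


class TestMeasureScene:
    def test_clean_scene_recovers_requested_position(self, clean_scene):
        _, scene, truth = clean_scene
        measured = ct.measure_scene(scene)
        assert len(measured) == 1
        assert measured[0].percent_rd == pytest.approx(
            100 * truth.territories[0].true_fractional_rd, abs=1.0
        )

    def test_default_conditions_recover_both_channels(self, default_scene):
        _, scene, truth = default_scene
        measured = {m.channel: m for m in ct.measure_scene(scene)}
        for t in truth.territories:
            assert measured[t.channel].percent_rd == pytest.approx(
                100 * t.true_fractional_rd, abs=3.0
            )

    def test_empty_scene_measures_nothing(self):
        params = ct.SceneParams(seed=0)
        scene, _ = ct.render_scene(params)
        assert ct.measure_scene(scene) == []

    def test_uniform_voxel_rescaling_leaves_rd_unchanged(self, default_scene):
        _, scene, _ = default_scene
        baseline = ct.measure_scene(scene)
        scaled = ct.Scene(voxels=scene.voxels,
                          voxel_size=tuple(2.0 * v for v in scene.voxel_size))
        rescaled = ct.measure_scene(scaled)
        for m0, m1 in zip(baseline, rescaled):
            assert m1.percent_rd == pytest.approx(m0.percent_rd, abs=1e-9)
            assert m1.R == pytest.approx(2.0 * m0.R, rel=1e-9)

    def test_translation_changes_rd_less_than_one_point(self, default_scene):
        _, scene, _ = default_scene
        baseline = ct.measure_scene(scene)
        shifted = ct.Scene(voxels=np.roll(scene.voxels, (1, 3, -4), axis=(1, 2, 3)),
                           voxel_size=scene.voxel_size)
        moved = ct.measure_scene(shifted)
        assert len(moved) == len(baseline)
        for m0, m1 in zip(baseline, moved):
            assert m1.percent_rd == pytest.approx(m0.percent_rd, abs=1.0)

    def test_inplane_rotation_changes_rd_less_than_one_point(self, default_scene):
        _, scene, _ = default_scene
        baseline = ct.measure_scene(scene)
        rotated = ct.Scene(voxels=np.rot90(scene.voxels, k=1, axes=(2, 3)).copy(),
                           voxel_size=scene.voxel_size)
        turned = ct.measure_scene(rotated)
        by_channel = {m.channel: m for m in turned}
        for m0 in baseline:
            assert by_channel[m0.channel].percent_rd == pytest.approx(
                m0.percent_rd, abs=1.0
            )


class TestSummarize:
    def test_even_spread_across_bins(self):
        s = ct.summarize([10, 30, 50, 70, 90], "glass", "CT18")
        assert np.allclose(s.bin_frequencies, 0.2)
        assert s.median == 50
        assert s.n == 5

    def test_bin_edges_are_left_closed(self):
        s = ct.summarize([20.0], "glass", "CT18")
        assert np.allclose(s.bin_frequencies, [0, 1, 0, 0, 0])

    def test_hundred_falls_in_last_bin(self):
        s = ct.summarize([100.0, 100.0], "glass", "CT18")
        assert np.allclose(s.bin_frequencies, [0, 0, 0, 0, 1])

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(2)
        s = ct.summarize(rng.uniform(0, 100, size=37), "c", "CT1")
        assert s.bin_frequencies.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ct.summarize([], "glass", "CT18")


def _exhaustive_mw(x, y):
    """Brute-force two-sided Mann-Whitney: enumerate every assignment of the
    pooled sample into groups of the observed sizes."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)

    def ustat(ix):
        xs = pooled[list(ix)]
        ys = pooled[[i for i in range(n) if i not in ix]]
        return float(sum((a > b) + 0.5 * (a == b) for a in xs for b in ys))

    u_obs = ustat(tuple(range(n1)))
    us = np.array([ustat(c) for c in itertools.combinations(range(n), n1)])
    lo = min(u_obs, n1 * (n - n1) - u_obs)
    hi = max(u_obs, n1 * (n - n1) - u_obs)
    p = (np.sum(us <= lo) + np.sum(us >= hi)) / us.size
    return u_obs, min(1.0, float(p))


class TestCompare:
    def test_complete_separation_gives_zero_u(self):
        u, p = ct.compare([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/C(6,3)

    def test_identical_samples_give_p_near_one(self):
        vals = [10.0, 20.0, 30.0, 40.0]
        _, p = ct.compare(vals, vals)
        assert p > 0.8

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (5, 5), (6, 6)])
    def test_exact_path_matches_exhaustive_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        x = rng.normal(0, 1, size=na)
        y = rng.normal(0.8, 1, size=nb)
        u, p = ct.compare(x, y)
        u_ref, p_ref = _exhaustive_mw(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n5(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, size=5)
        y = rng.normal(1, 1, size=5)
        p_exact = stats.mannwhitneyu(x, y, method="exact").pvalue
        p_asym = stats.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.05

    def test_summary_inputs_accepted(self):
        a = ct.summarize([55, 60, 70], "glass", "CT18")
        b = ct.summarize([40, 50, 52], "2kPa", "CT18")
        u, p = ct.compare(a, b)
        assert 0 <= p <= 1


class TestShiftTable:
    def test_reference_row_is_zero(self):
        med = pd.DataFrame([
            {"condition": "2kPa", "chromosome": "CT18", "median": 56.56},
            {"condition": "glass", "chromosome": "CT18", "median": 66.38},
        ])
        table = ct.shift_table(med, reference="2kPa")
        assert table.loc["2kPa", "delta_CT18"] == 0.0
        assert table.loc["glass", "delta_CT18"] == pytest.approx(9.82)

    def test_pair_column_is_within_condition_difference(self):
        med = pd.DataFrame([
            {"condition": "2kPa", "chromosome": "CT18", "median": 56.56},
            {"condition": "2kPa", "chromosome": "CT19", "median": 49.40},
        ])
        table = ct.shift_table(med, reference="2kPa", pair=("CT18", "CT19"))
        assert table.loc["2kPa", "delta_CT18_CT19"] == pytest.approx(7.16)

    def test_missing_reference_rejected(self):
        med = pd.DataFrame([
            {"condition": "glass", "chromosome": "CT18", "median": 66.38},
        ])
        with pytest.raises(ValueError):
            ct.shift_table(med, reference="2kPa")

    def test_summary_objects_accepted(self):
        a = ct.summarize([50, 60, 70], "glass", "CT18")
        b = ct.summarize([40, 50, 60], "2kPa", "CT18")
        table = ct.shift_table([a, b], reference="glass")
        assert table.loc["2kPa", "delta_CT18"] == pytest.approx(-10.0)
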