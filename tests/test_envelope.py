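"""Line-scan profiles, normalization fixed point and intensity statistics."""

import numpy as np
import pytest

import ctradial as ct


def _sections(ratio=3.0, noise=0.0, n=3, seed=0, **kw):
    params = ct.EnvelopeSimParams(rim_to_interior_ratio=ratio,
                                  noise_sigma=noise, n_nuclei=n, seed=seed, **kw)
    return params, ct.simulate_envelope_sections(params)


def _as_sections(params, pairs, condition=""):
    return [ct.Section(img, params.pixel_size, mask, condition)
            for img, mask in pairs]


class TestExtractLineProfile:
    def test_uniform_disk_gives_flat_profile(self):
        params, pairs = _sections(ratio=1.0, n=1)
        profile = ct.extract_line_profile(_as_sections(params, pairs)[0])
        assert np.allclose(profile.intensities, params.interior_intensity)
        assert profile.positions[0] == 0.0 and profile.positions[-1] == 1.0

    def test_rim_three_makes_endpoints_triple_the_middle(self):
        params, pairs = _sections(ratio=3.0, n=1)
        profile = ct.extract_line_profile(_as_sections(params, pairs)[0])
        mid = profile.intensities[profile.n_samples // 2]
        assert profile.intensities[0] == pytest.approx(3 * mid, rel=0.05)
        assert profile.intensities[-1] == pytest.approx(3 * mid, rel=0.05)

    def test_two_samples_are_the_boundary_intensities(self):
        params, pairs = _sections(ratio=3.0, n=1)
        profile = ct.extract_line_profile(_as_sections(params, pairs)[0],
                                          n_samples=2)
        assert profile.n_samples == 2
        assert np.allclose(profile.intensities,
                           3.0 * params.interior_intensity, rtol=0.05)

    def test_angles_agree_for_radially_symmetric_nucleus(self):
        params, pairs = _sections(ratio=2.0, n=1)
        section = _as_sections(params, pairs)[0]
        p1 = ct.extract_line_profile(section, angle=0.3)
        p2 = ct.extract_line_profile(section, angle=1.9)
        diff = np.abs(p1.intensities - p2.intensities)
        # pixel discretization of the rim edge perturbs a few transition
        # samples; the profiles agree everywhere else
        assert diff.mean() < 0.01
        assert diff.max() < 0.1

    def test_random_angle_needs_rng(self):
        params, pairs = _sections(n=1)
        with pytest.raises(ValueError):
            ct.extract_line_profile(_as_sections(params, pairs)[0],
                                    angle="random")

    def test_empty_mask_rejected(self):
        section = ct.Section(np.zeros((8, 8)), 0.1, np.zeros((8, 8), bool))
        with pytest.raises(ct.envelope.ProfileGeometryError):
            ct.extract_line_profile(section)


class TestAverageProfiles:
    def test_reference_peripheral_value_is_exactly_one(self):
        params, pairs = _sections(ratio=3.0, noise=0.01, n=6)
        profiles = [ct.extract_line_profile(s)
                    for s in _as_sections(params, pairs)]
        summary = ct.average_profiles(profiles, profiles)
        peripheral = 0.5 * (summary.mean_profile[0] + summary.mean_profile[-1])
        assert peripheral == 1.0
        assert summary.n_nuclei == 6

    def test_identical_condition_matches_reference(self):
        params, pairs = _sections(ratio=3.0, n=4)
        profiles = [ct.extract_line_profile(s)
                    for s in _as_sections(params, pairs)]
        summary = ct.average_profiles(profiles, profiles)
        ref_summary = ct.average_profiles(profiles, profiles)
        assert np.array_equal(summary.mean_profile, ref_summary.mean_profile)

    def test_nucleoplasmic_shift_raises_interior_signal(self):
        # reference: envelope-enriched (rim 3); test: the same amount of
        # protein redistributed uniformly (rim 1, total intensity conserved)
        ref_params, ref_pairs = _sections(ratio=3.0, n=5, seed=1)
        rim_area = 1.0 - (1.0 - ref_params.rim_width
                          / ref_params.nucleus_radius) ** 2
        conserved = ref_params.interior_intensity * (1 + 2 * rim_area)
        test_params, test_pairs = _sections(ratio=1.0, n=5, seed=2,
                                            interior_intensity=conserved)
        ref = [ct.extract_line_profile(s)
               for s in _as_sections(ref_params, ref_pairs)]
        test = [ct.extract_line_profile(s)
                for s in _as_sections(test_params, test_pairs)]
        ref_summary = ct.average_profiles(ref, ref)
        test_summary = ct.average_profiles(test, ref)
        mid = slice(40, 61)
        assert test_summary.mean_profile[mid].mean() \
            > ref_summary.mean_profile[mid].mean()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ct.average_profiles([], [])


class TestPeripheralRatio:
    def test_flat_profile_is_one(self):
        profile = ct.LineProfile(np.linspace(0, 1, 51), np.full(51, 2.0), 51)
        assert ct.peripheral_ratio(profile) == 1.0

    def test_rim_matched_to_band_recovers_contrast(self):
        # rim width 1 um of a 5 um radius = outer 10% of the profile
        params, pairs = _sections(ratio=3.0, n=1, rim_width=1.0)
        profile = ct.extract_line_profile(_as_sections(params, pairs)[0],
                                          n_samples=201)
        assert ct.peripheral_ratio(profile) == pytest.approx(3.0, rel=0.05)

    def test_monotone_in_simulated_rim_contrast(self):
        ratios = []
        for rim in (1.0, 2.0, 3.0):
            params, pairs = _sections(ratio=rim, n=1)
            profile = ct.extract_line_profile(_as_sections(params, pairs)[0])
            ratios.append(ct.peripheral_ratio(profile))
        assert ratios[0] < ratios[1] < ratios[2]

    def test_invalid_rim_fraction_rejected(self):
        profile = ct.LineProfile(np.linspace(0, 1, 51), np.ones(51), 51)
        with pytest.raises(ValueError):
            ct.peripheral_ratio(profile, rim_fraction=0.6)

    def test_too_few_samples_rejected(self):
        profile = ct.LineProfile(np.linspace(0, 1, 5), np.ones(5), 5)
        with pytest.raises(ValueError):
            ct.peripheral_ratio(profile)


class TestTotalIntensityPerArea:
    def test_uniform_disk_with_unit_pixels(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        section = ct.Section(np.where(mask, 3.0, 0.0), 1.0, mask)
        assert ct.total_intensity_per_area(section) == pytest.approx(3.0)

    def test_linearity_in_intensity(self):
        params, pairs = _sections(ratio=2.0, n=1)
        section = _as_sections(params, pairs)[0]
        doubled = ct.Section(2.0 * section.image, section.pixel_size,
                             section.nucleus_mask)
        assert ct.total_intensity_per_area(doubled) == pytest.approx(
            2.0 * ct.total_intensity_per_area(section)
        )

    def test_radius_independent_for_same_intensity(self):
        a_params, a_pairs = _sections(ratio=1.0, n=1, nucleus_radius=3.0)
        b_params, b_pairs = _sections(ratio=1.0, n=1, nucleus_radius=5.0)
        a = ct.total_intensity_per_area(_as_sections(a_params, a_pairs)[0])
        b = ct.total_intensity_per_area(_as_sections(b_params, b_pairs)[0])
        assert a == pytest.approx(b)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ct.total_intensity_per_area(
                ct.Section(np.ones((4, 4)), 1.0, np.zeros((4, 4), bool))
            )


class TestCompareConditions:
    def test_identical_zero_variance_groups(self):
        t, p = ct.compare_conditions([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_clear_shift_is_significant(self):
        t, p = ct.compare_conditions([1, 2, 3], [11, 12, 13])
        assert p < 0.01

    def test_matches_closed_form_pooled_t(self):
        a = np.array([4.1, 5.2, 6.0, 5.5])
        b = np.array([7.3, 8.1, 7.9])
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        t, p = ct.compare_conditions(a, b)
        assert t == pytest.approx(t_ref)
        from scipy import stats

        assert p == pytest.approx(
            2 * stats.t.sf(abs(t_ref), na + nb - 2)
        )

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            ct.compare_conditions([1.0], [2.0, 3.0])
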