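import numpy as np
import pytest

from glianet import (
    ConvergenceError,
    Track,
    ValidationError,
    area_overlap_percent,
    dispersion_factor,
    form_factor,
    make_orientation_texture,
    make_shape_mask,
    measure_mask,
    particle_density_profile,
    track_mean_speed,
    track_net_speed,
    volume_ratio,
)


class TestFormFactor:
    @pytest.mark.parametrize(
        "area,perimeter,expected",
        [
            (np.pi, 2 * np.pi, 1.0),  # circle: isoperimetric equality
            (1.0, 4.0, np.pi / 4),  # unit square
            (10.0, 22.0, 40 * np.pi / 484),  # 1 x 10 rectangle
        ],
    )
    def test_closed_forms(self, area, perimeter, expected):
        assert form_factor(area, perimeter) == pytest.approx(expected)

    def test_scale_invariance(self):
        base = form_factor(7.0, 11.0)
        for s in (0.1, 3.0, 100.0):
            assert form_factor(7 * s**2, 11 * s) == pytest.approx(base)

    @pytest.mark.parametrize("area,perimeter", [(0, 1), (1, 0), (-2, 3)])
    def test_nonpositive_inputs_rejected(self, area, perimeter):
        with pytest.raises(ValidationError):
            form_factor(area, perimeter)


class TestMeasureMask:
    def test_disk_close_to_isoperimetric_limit(self):
        mask, _ = make_shape_mask("disk", 128)
        sm = measure_mask(mask)
        assert abs(sm.form_factor - 1.0) <= 0.05

    def test_square_close_to_quarter_pi(self):
        mask, meta = make_shape_mask("square", 64)  # 38 px side
        sm = measure_mask(mask)
        assert sm.form_factor == pytest.approx(meta["form_factor"], rel=0.05)

    def test_raster_estimates_respect_isoperimetric_bound_ordering(self):
        ffs = {}
        for kind in ("disk", "star", "rectangle"):
            mask, _ = make_shape_mask(kind, 128)
            ffs[kind] = measure_mask(mask).form_factor
        assert ffs["star"] < ffs["disk"]
        assert ffs["rectangle"] < ffs["disk"]

    def test_pixel_size_scales_area_and_perimeter_but_not_ff(self):
        mask, _ = make_shape_mask("disk", 64)
        a = measure_mask(mask, pixel_size=1.0)
        b = measure_mask(mask, pixel_size=0.1)
        assert b.area == pytest.approx(a.area * 0.01)
        assert b.perimeter == pytest.approx(a.perimeter * 0.1)
        assert b.form_factor == pytest.approx(a.form_factor)

    def test_empty_and_multi_component_masks_rejected(self):
        with pytest.raises(ValidationError, match="0"):
            measure_mask(np.zeros((16, 16), dtype=bool))
        two = np.zeros((16, 16), dtype=bool)
        two[2:5, 2:5] = True
        two[10:13, 10:13] = True
        with pytest.raises(ValidationError, match="2"):
            measure_mask(two)


class TestParticleDensityProfile:
    def test_uniform_unit_density(self):
        distances = np.arange(15) + 0.5
        profile = particle_density_profile(distances, np.ones(15), 15.0, 1.0)
        assert profile.counts.tolist() == [1] * 15
        assert profile.densities.tolist() == [1.0] * 15

    def test_no_particles_gives_zero_bins(self):
        profile = particle_density_profile([], np.ones(15), 15.0, 1.0)
        assert profile.counts.sum() == 0

    def test_particle_beyond_segment_excluded(self):
        profile = particle_density_profile([16.0, 15.0, 14.999], np.ones(15), 15.0, 1.0)
        assert profile.counts.sum() == 1
        assert profile.counts[14] == 1

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 20, 300)
        profile = particle_density_profile(d, np.full(15, 2.0), 15.0, 1.0)
        assert profile.counts.sum() == (d < 15).sum()

    def test_density_is_count_over_volume(self):
        profile = particle_density_profile([0.5, 0.6], [4.0] + [1.0] * 14, 15.0, 1.0)
        assert profile.densities[0] == pytest.approx(0.5)

    def test_bad_volumes_rejected(self):
        with pytest.raises(ValidationError):
            particle_density_profile([1.0], np.zeros(15), 15.0, 1.0)
        with pytest.raises(ValidationError):
            particle_density_profile([1.0], np.ones(14), 15.0, 1.0)


class TestVolumeRatioAndOverlap:
    @pytest.mark.parametrize("obj,region,expected", [(0, 10, 0.0), (5, 10, 0.5), (10, 10, 1.0)])
    def test_volume_ratio(self, obj, region, expected):
        assert volume_ratio(obj, region) == expected

    def test_volume_ratio_bad_region(self):
        with pytest.raises(ValidationError):
            volume_ratio(1.0, 0.0)

    def test_overlap_identical_and_disjoint(self):
        a = np.zeros((10, 10), bool)
        a[2:6, 2:6] = True
        assert area_overlap_percent(a, a) == 100.0
        b = np.zeros((10, 10), bool)
        b[7:9, 7:9] = True
        assert area_overlap_percent(a, b) == 0.0

    def test_partial_overlap_arithmetic(self):
        a = np.zeros((10, 10), bool)
        a[0, :10] = True  # 10 px
        b = np.zeros((10, 10), bool)
        b[0, :4] = True
        assert area_overlap_percent(a, b) == pytest.approx(40.0)

    def test_asymmetry(self):
        a = np.zeros((10, 10), bool)
        a[0, :4] = True
        b = np.zeros((10, 10), bool)
        b[0, :8] = True
        assert area_overlap_percent(a, b) == 100.0
        assert area_overlap_percent(b, a) == 50.0

    def test_monotone_as_b_grows(self):
        rng = np.random.default_rng(1)
        a = rng.random((20, 20)) > 0.5
        b = np.zeros((20, 20), bool)
        prev = 0.0
        for r in range(0, 20, 4):
            b[r : r + 4] = True
            cur = area_overlap_percent(a, b)
            assert cur >= prev
            prev = cur

    def test_shape_mismatch_and_empty_a_rejected(self):
        with pytest.raises(ValidationError):
            area_overlap_percent(np.ones((4, 4), bool), np.ones((5, 5), bool))
        with pytest.raises(ValidationError):
            area_overlap_percent(np.zeros((4, 4), bool), np.ones((4, 4), bool))


class TestDispersionFactor:
    def test_clean_grating_has_tight_dispersion(self):
        img, meta = make_orientation_texture(0.0, 8, 0.0, 256, 1)
        d = dispersion_factor(img)
        assert abs(d.fitted_mean - meta["angle_deg"]) <= 2.0
        assert d.dispersion < 5.0
        assert d.goodness > 0.9

    def test_rotation_equivariance_of_mean(self):
        base = dispersion_factor(make_orientation_texture(0.0, 8, 0.0, 256, 1)[0])
        rotated = dispersion_factor(make_orientation_texture(30.0, 8, 0.0, 256, 1)[0])
        assert abs(rotated.fitted_mean - base.fitted_mean - 30.0) <= 2.0
        assert abs(rotated.dispersion - base.dispersion) <= 2.0

    @pytest.mark.parametrize("angle", [-60.0, 45.0, 80.0])
    def test_mean_recovers_generator_angle(self, angle):
        img, meta = make_orientation_texture(angle, 8, 0.1, 256, 2)
        d = dispersion_factor(img)
        assert abs(d.fitted_mean - meta["angle_deg"]) <= 2.0

    def test_white_noise_is_dispersed_with_poor_fit(self):
        noise = np.random.default_rng(2).normal(size=(256, 256))
        d = dispersion_factor(noise)
        assert d.dispersion > 30.0
        assert d.goodness < 0.5

    def test_roi_restricts_estimation(self):
        # left half grating at 0 deg, right half at 60 deg
        left, _ = make_orientation_texture(0.0, 8, 0.0, 128, 1)
        right, _ = make_orientation_texture(60.0, 8, 0.0, 128, 1)
        img = np.concatenate([left, right], axis=1)
        roi = np.zeros_like(img, dtype=bool)
        roi[:, :120] = True
        d = dispersion_factor(img, roi)
        assert abs(d.fitted_mean) <= 3.0

    def test_flat_image_rejected(self):
        with pytest.raises(ValidationError):
            dispersion_factor(np.ones((64, 64)))


class TestTrackSpeed:
    def test_straight_unit_steps(self):
        t = Track(points=[(0, 0), (1, 0), (2, 0)], frame_interval=1.0)
        assert track_mean_speed(t) == pytest.approx(1.0)

    def test_stationary_track(self):
        t = Track(points=[(1, 1), (1, 1), (1, 1)], frame_interval=1.0)
        assert track_mean_speed(t) == 0.0

    def test_diagonal_unit_steps(self):
        t = Track(points=[(0, 0), (1, 1), (2, 2)], frame_interval=1.0)
        assert track_mean_speed(t) == pytest.approx(np.sqrt(2))

    def test_frame_interval_scales_speed(self):
        t = Track(points=[(0, 0), (1, 0), (2, 0)], frame_interval=2.0)
        assert track_mean_speed(t) == pytest.approx(0.5)

    def test_net_speed_below_path_speed_for_curved_track(self):
        t = Track(points=[(0, 0), (1, 0), (1, 1), (0, 1)], frame_interval=1.0)
        assert track_net_speed(t) < track_mean_speed(t)

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            track_mean_speed(Track(points=[(0.0, 0.0)], frame_interval=1.0))
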