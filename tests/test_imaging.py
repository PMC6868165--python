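"""Image quantification: centering, radius, thresholds, porosity, profiles."""

import numpy as np
import pytest

from collagenmech.errors import (
    DegenerateInputError,
    InvalidArgumentError,
    UnreliableDetectionError,
)
from collagenmech.imaging import (
    ImageStack,
    IntensityProfile,
    axial_shg_profile,
    binarize_and_porosity,
    densified_layer_metrics,
    find_center,
    gel_thickness,
    global_threshold,
    masked_tpf_intensity,
    radial_graininess,
    radial_shg_profile,
    read_stack,
    spheroid_radius,
    write_stack,
)
from collagenmech.kinematics import SpheroidTrack
from collagenmech.synthetic import gen_shg_stack, gen_spheroid_timelapse

PIXEL = 1.126  # um/px, spinning-disk calibration used by the generators


def disk_frame(radius_px=50.0, frame_size=128, contrast=0.3, seed=5):
    track = SpheroidTrack(times=[0.0], radii=[radius_px * PIXEL])
    frames, _ = gen_spheroid_timelapse(
        track, frame_size=frame_size, texture_contrast=contrast, pixel_size_um=PIXEL, seed=seed
    )
    return frames[0]


class TestFindCenter:
    def test_centered_disk(self):
        cx, cy = find_center(disk_frame())
        assert abs(cx - 63.5) <= 2 and abs(cy - 63.5) <= 2

    def test_off_center_disk(self):
        frame = disk_frame(radius_px=30.0)
        shifted = np.roll(np.roll(frame, -40, axis=0), -40, axis=1)
        cx, cy = find_center(shifted)
        assert abs(cx - 23.5) <= 2 and abs(cy - 23.5) <= 2

    def test_constant_frame_rejected(self):
        with pytest.raises(DegenerateInputError):
            find_center(np.full((64, 64), 7.0))

    def test_deterministic(self):
        frame = disk_frame(seed=13)
        assert find_center(frame) == find_center(frame)


class TestRadialGraininess:
    def test_blank_frame_gives_zero_profile(self):
        prof = radial_graininess(np.zeros((64, 64)), (32.0, 32.0))
        assert np.all(prof.mean_intensity == 0.0)

    def test_white_noise_profile_flat(self):
        # CV across well-populated bins < 0.2 for i.i.d. noise
        rng = np.random.default_rng(2)
        frame = rng.normal(100.0, 10.0, (256, 256))
        prof = radial_graininess(frame, (128.0, 128.0), bin_width=8.0)
        sel = prof.counts >= 1000
        g = prof.mean_intensity[sel]
        assert g.std() / g.mean() < 0.2

    def test_center_outside_frame_rejected(self):
        with pytest.raises(InvalidArgumentError):
            radial_graininess(np.zeros((64, 64)), (100.0, 10.0))

    def test_textured_disk_high_inside_low_outside(self):
        prof = radial_graininess(disk_frame(radius_px=40.0), (63.5, 63.5), bin_width=4.0)
        sel = prof.counts > 0
        coords, g = prof.coords[sel], prof.mean_intensity[sel]
        assert g[coords < 30].mean() > 10 * g[coords > 50].mean()


class TestSpheroidRadius:
    def test_recovery_within_two_pixels(self):
        r_um = spheroid_radius(disk_frame(radius_px=50.0), pixel_size_um=PIXEL)
        assert abs(r_um / PIXEL - 50.0) <= 2.0

    def test_calibration_invariance(self):
        from scipy.ndimage import zoom

        frame = disk_frame(radius_px=50.0)
        upscaled = zoom(frame, 2, order=1)
        r1 = spheroid_radius(frame, pixel_size_um=PIXEL)
        r2 = spheroid_radius(upscaled, pixel_size_um=PIXEL / 2)
        assert abs(r1 - r2) <= 2.0 * PIXEL

    def test_zero_contrast_flagged(self):
        with pytest.raises(UnreliableDetectionError):
            spheroid_radius(disk_frame(contrast=0.0), pixel_size_um=PIXEL)

    def test_growth_track_recovered_monotone(self):
        radii = np.linspace(35.0, 55.0, 6)
        track = SpheroidTrack(times=np.arange(6.0), radii=radii * PIXEL)
        frames, _ = gen_spheroid_timelapse(
            track, frame_size=128, texture_contrast=0.3, pixel_size_um=PIXEL, seed=7
        )
        rec = np.array([spheroid_radius(f, pixel_size_um=PIXEL) / PIXEL for f in frames])
        assert np.abs(rec - radii).max() <= 2.0
        assert np.all(np.diff(rec) > -2.0)  # monotone within tolerance


class TestGlobalThreshold:
    def test_single_constant_roi(self):
        rep = global_threshold({"g": [np.full((5, 5), 10.0)]})
        assert rep.global_threshold == 10.0

    def test_sample_sd_convention(self):
        rois = [np.full((3, 3), v) for v in (8.0, 10.0, 12.0)]
        rep = global_threshold({"g": rois})
        assert rep.group_thresholds["g"] == pytest.approx(14.0)  # 10 + 2*2 (ddof=1)

    def test_global_is_max_over_groups(self):
        rep = global_threshold(
            {"a": [np.full((2, 2), 12.0)], "b": [np.full((2, 2), 15.0)]}
        )
        assert rep.global_threshold == 15.0
        assert rep.global_threshold == max(rep.group_thresholds.values())

    def test_empty_roi_rejected(self):
        with pytest.raises(InvalidArgumentError):
            global_threshold({"g": []})
        with pytest.raises(InvalidArgumentError):
            global_threshold({"g": [np.empty((0, 0))]})


class TestPorosity:
    def test_zero_stack_fully_porous(self):
        st = ImageStack(data=np.zeros((3, 8, 8)), pixel_size_xy=1.0, step_z=1.0)
        _, faf, poro = binarize_and_porosity(st, 1.0)
        assert (faf, poro) == (0.0, 1.0)

    def test_saturated_stack_zero_porosity(self):
        st = ImageStack(data=np.full((3, 8, 8), 255.0), pixel_size_xy=1.0, step_z=1.0)
        _, faf, poro = binarize_and_porosity(st, 1.0)
        assert (faf, poro) == (1.0, 0.0)

    def test_porosity_complements_area_fraction(self):
        st = gen_shg_stack(seed=1)
        _, faf, poro = binarize_and_porosity(st, 5.0)
        assert faf + poro == 1.0


class TestMaskedTpf:
    def test_constant_tpf(self):
        tpf = ImageStack(data=np.full((2, 4, 4), 7.0), pixel_size_xy=1.0, step_z=1.0, channel="TPF")
        mask = np.zeros((2, 4, 4), bool)
        mask[0, :2] = True
        assert masked_tpf_intensity(tpf, mask) == 7.0

    def test_mask_selects_inside_value(self):
        data = np.full((2, 4, 4), 9.0)
        data[:, :2, :] = 3.0
        mask = np.zeros((2, 4, 4), bool)
        mask[:, :2, :] = True
        tpf = ImageStack(data=data, pixel_size_xy=1.0, step_z=1.0, channel="TPF")
        assert masked_tpf_intensity(tpf, mask) == 3.0

    def test_linearity_in_gain(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 10, (2, 8, 8))
        mask = data > 5
        tpf1 = ImageStack(data=data, pixel_size_xy=1.0, step_z=1.0, channel="TPF")
        tpf2 = ImageStack(data=2 * data, pixel_size_xy=1.0, step_z=1.0, channel="TPF")
        assert masked_tpf_intensity(tpf2, mask) == pytest.approx(
            2 * masked_tpf_intensity(tpf1, mask)
        )

    def test_empty_mask_rejected(self):
        tpf = ImageStack(data=np.ones((2, 4, 4)), pixel_size_xy=1.0, step_z=1.0, channel="TPF")
        with pytest.raises(DegenerateInputError):
            masked_tpf_intensity(tpf, np.zeros((2, 4, 4), bool))


class TestProfiles:
    def test_radially_uniform_stack_flat_profile(self):
        rng = np.random.default_rng(3)
        st = ImageStack(
            data=rng.normal(100, 1.0, (4, 128, 128)), pixel_size_xy=1.0, step_z=1.0
        )
        prof = radial_shg_profile(st, (63.5, 63.5), bin_width_um=8.0)
        sel = prof.counts >= 1000
        g = prof.mean_intensity[sel]
        assert g.std() / g.mean() < 0.01

    def test_rebinning_conserves_total_mean(self):
        st = gen_shg_stack(seed=1)
        p1 = radial_shg_profile(st, (64.0, 64.0), bin_width_um=5.0)
        p2 = radial_shg_profile(st, (64.0, 64.0), bin_width_um=2.5)
        assert p1.total_mean() == pytest.approx(p2.total_mean(), rel=0.01)

    def test_axial_profile_needs_two_slices(self):
        st = ImageStack(data=np.ones((1, 8, 8)), pixel_size_xy=1.0, step_z=1.0)
        with pytest.raises(InvalidArgumentError):
            axial_shg_profile(st)


class TestGelThickness:
    def test_sharp_gel_thickness(self):
        data = np.zeros((120, 30, 30))
        data[5:106] = 50.0
        st = ImageStack(data=data, pixel_size_xy=1.0, step_z=10.0)
        assert gel_thickness(st) == pytest.approx(1000.0, abs=10.0)

    def test_onset_fraction_robustness(self):
        data = np.zeros((120, 30, 30))
        data[5:106] = 50.0
        st = ImageStack(data=data, pixel_size_xy=1.0, step_z=10.0)
        t1 = gel_thickness(st, onset_fraction=0.3)
        t2 = gel_thickness(st, onset_fraction=0.7)
        assert abs(t1 - t2) <= 10.0  # one z-step

    def test_empty_stack_rejected(self):
        st = ImageStack(data=np.zeros((10, 20, 20)), pixel_size_xy=1.0, step_z=10.0)
        with pytest.raises(UnreliableDetectionError):
            gel_thickness(st)


class TestDensifiedLayer:
    def test_monotone_decay_has_no_layer(self):
        x = np.arange(20.0)
        prof = IntensityProfile(
            coords=x, mean_intensity=100.0 * np.exp(-x / 7.0), counts=np.ones(20)
        )
        assert densified_layer_metrics(prof) is None

    def test_known_peak_recovered(self):
        x = np.arange(50.0)
        y = 50.0 * np.exp(-x / 30.0) + 20.0 * np.exp(-0.5 * ((x - 25.0) / 3.0) ** 2)
        layer = densified_layer_metrics(IntensityProfile(coords=x, mean_intensity=y, counts=np.ones(50)))
        assert layer is not None
        assert layer.position == pytest.approx(25.0, abs=1.0)
        assert layer.width == pytest.approx(2.355 * 3.0, rel=0.2)

    def test_more_prominent_of_two_peaks_wins(self):
        x = np.arange(50.0)
        y = np.full(50, 10.0)
        y[10], y[30] = 30.0, 50.0
        layer = densified_layer_metrics(IntensityProfile(coords=x, mean_intensity=y, counts=np.ones(50)))
        assert layer.position == 30.0

    def test_too_few_bins_rejected(self):
        prof = IntensityProfile(coords=np.arange(3.0), mean_intensity=np.ones(3), counts=np.ones(3))
        with pytest.raises(InvalidArgumentError):
            densified_layer_metrics(prof)


class TestTiffIO:
    def test_round_trip(self, tmp_path):
        st = gen_shg_stack(shape=(5, 32, 32), seed=1)
        path = tmp_path / "stack.tif"
        write_stack(st, path)
        back = read_stack(path, pixel_size_xy=st.pixel_size_xy, step_z=st.step_z)
        assert back.data.shape == st.data.shape
        assert np.allclose(back.data, st.data.astype(np.float32))
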