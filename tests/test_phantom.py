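"""Phantom generator: geometry oracles, determinism, rendering symmetries."""

import numpy as np
import pytest
from scipy import ndimage

from rotovol import phantom
from rotovol.stability import measure_major_axis


def ellipsoid_volume(radii):
    a, b, c = radii
    return 4.0 / 3.0 * np.pi * a * b * c


def boundary_voxel_count(mask):
    """6-connectivity boundary oracle: voxels with a background face-neighbor."""
    eroded = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1))
    return int((mask & ~eroded).sum())


class TestMakePhantom:
    @pytest.mark.parametrize("radii", [(10, 10, 10), (12, 9, 8)])
    def test_support_volume_matches_analytic_ellipsoid(self, radii):
        ph = phantom.make_phantom(1, "smooth", 64, radii)
        count = ph.support("membrane").sum()
        expected = ellipsoid_volume(radii)
        assert abs(count - expected) / expected < 0.05

    def test_deterministic_under_seed(self):
        a = phantom.make_phantom(1, "rough", 48, (10, 10, 10))
        b = phantom.make_phantom(1, "rough", 48, (10, 10, 10))
        assert np.array_equal(a.membrane_field, b.membrane_field)
        assert np.array_equal(a.nucleus_field, b.nucleus_field)

    def test_different_seeds_differ(self):
        a = phantom.make_phantom(1, "rough", 48, (10, 10, 10))
        b = phantom.make_phantom(2, "rough", 48, (10, 10, 10))
        assert not np.array_equal(a.membrane_field, b.membrane_field)

    def test_rough_surface_has_more_boundary_voxels(self, sphere_phantom, rough_phantom):
        smooth_b = boundary_voxel_count(sphere_phantom.support())
        rough_b = boundary_voxel_count(rough_phantom.support())
        assert rough_b > smooth_b
        # at (approximately) equal enclosed volume
        v_s = sphere_phantom.support().sum()
        v_r = rough_phantom.support().sum()
        assert abs(v_r - v_s) / v_s < 0.15

    def test_roughness_amp_monotone_in_boundary_count(self):
        counts = []
        for amp in (0.0, 0.05, 0.12, 0.18, 0.28):
            ph = phantom.make_phantom(1, "rough", 64, (10, 10, 10),
                                      roughness_amp=amp)
            counts.append(boundary_voxel_count(ph.support()))
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_nucleus_support_inside_membrane_support(self, rough_phantom):
        nuc = rough_phantom.nucleus_field > 0
        mem = rough_phantom.membrane_field > 0
        assert not np.any(nuc & ~mem)

    def test_fields_bounded_and_shared_shape(self, rough_phantom):
        for f in (rough_phantom.membrane_field, rough_phantom.nucleus_field):
            assert f.min() >= 0 and f.max() <= 1
        assert rough_phantom.membrane_field.shape == rough_phantom.nucleus_field.shape

    def test_radii_exceeding_grid_raises(self):
        with pytest.raises(ValueError, match="fit"):
            phantom.make_phantom(1, "smooth", 32, (20, 20, 20))

    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError, match="preset"):
            phantom.make_phantom(1, "fuzzy")

    def test_volume_conserved_under_rotation(self, ellipsoid_phantom):
        vol = ellipsoid_phantom.combined_field()
        total0 = vol.sum()
        for angle in (0.4, 1.1):
            rotated = phantom._rotate_volume(vol, angle, "in_plane")
            assert abs(rotated.sum() - total0) / total0 < 0.02


class TestRenderProjection:
    def test_sphere_projection_rotation_invariant(self, sphere_phantom):
        a = phantom.render_projection(sphere_phantom, 0.0, blur_sigma=0)
        b = phantom.render_projection(sphere_phantom, np.pi / 2, blur_sigma=0)
        rms = np.sqrt(np.mean((a.pixels - b.pixels) ** 2))
        assert rms < 1e-6

    def test_ellipsoid_twofold_symmetry(self, ellipsoid_phantom):
        a = phantom.render_projection(ellipsoid_phantom, 0.0, blur_sigma=0)
        b = phantom.render_projection(ellipsoid_phantom, np.pi, blur_sigma=0)
        rms = np.sqrt(np.mean((a.pixels - b.pixels) ** 2))
        assert rms < 0.02  # interpolation tolerance

    def test_silhouette_major_axis_matches_geometry(self, ellipsoid_phantom):
        # ellipse-fit oracle on the noiseless support silhouette: in-plane
        # semi-axes (15, 10) voxels project to a 30-voxel major axis
        silhouette = ellipsoid_phantom.support().any(axis=0).astype(float)
        d = measure_major_axis(silhouette)
        assert abs(d - 30.0) <= 1.0

    def test_intensities_normalized(self, rough_phantom):
        img = phantom.render_projection(rough_phantom, 0.3, noise_sd=0.05, rng=4)
        assert img.pixels.min() >= 0 and abs(img.pixels.max() - 1.0) < 1e-12

    def test_negative_blur_rejected(self, sphere_phantom):
        with pytest.raises(ValueError):
            phantom.render_projection(sphere_phantom, 0.0, blur_sigma=-1)


class TestRenderRotationVideo:
    def test_periodicity(self, rotation_video):
        frames = rotation_video.as_array()
        assert np.allclose(frames[0], frames[60], atol=0.02)

    def test_drift_displaces_centroid(self):
        ph = phantom.make_phantom(3, "smooth", 48, (9, 9, 9))
        video = phantom.render_rotation_video(
            ph, frames_per_rev=60, n_frames=101, drift_px_per_frame=0.1, seed=0
        )
        def centroid_x(img):
            mask = img.pixels > 0.5
            return ndimage.center_of_mass(mask)[1]
        dx = centroid_x(video.frames[100]) - centroid_x(video.frames[0])
        assert abs(dx - 10.0) < 1.5

    def test_default_protocol_matches_recording_convention(self):
        # 310 frames across a 15-second interval
        assert phantom.DEFAULT_N_FRAMES == 310
        assert phantom.DEFAULT_INTERVAL_S == pytest.approx(15.0 / 310.0)
        ph = phantom.make_phantom(1, "smooth", 32, (6, 6, 6))
        video = phantom.render_rotation_video(ph, n_frames=8, frames_per_rev=8)
        assert video.frame_interval_s == pytest.approx(15.0 / 310.0)

    def test_true_period_recorded(self, rotation_video):
        assert rotation_video.true_frames_per_rev == 60.0

    def test_too_few_frames_rejected(self, sphere_phantom):
        with pytest.raises(ValueError):
            phantom.render_rotation_video(sphere_phantom, frames_per_rev=60,
                                          n_frames=30)


class TestRenderConfocalStack:
    def test_sphere_stack_mirror_symmetric(self, sphere_phantom):
        stack = phantom.render_confocal_stack(sphere_phantom, n_slices=10)
        area0 = (stack[0] > 0.25).sum()
        area9 = (stack[9] > 0.25).sum()
        assert area0 == pytest.approx(area9, rel=0.05)

    def test_nucleus_support_within_membrane_slicewise(self, sphere_phantom):
        mem = phantom.render_confocal_stack(sphere_phantom, 10, "membrane",
                                            blur_sigma=0)
        nuc = phantom.render_confocal_stack(sphere_phantom, 10, "nucleus",
                                            blur_sigma=0)
        for m, n in zip(mem, nuc):
            assert not np.any((n > 0) & ~(m > 0))

    def test_cavalieri_volume(self, sphere_phantom):
        # summed slice areas x slice spacing approximates the analytic volume
        n_slices = 32
        stack = phantom.render_confocal_stack(sphere_phantom, n_slices,
                                              blur_sigma=0)
        spacing = (sphere_phantom.shape[0] - 1) / (n_slices - 1)
        volume = sum((s >= 0.5).sum() for s in stack) * spacing
        expected = ellipsoid_volume((10, 10, 10))
        assert abs(volume - expected) / expected < 0.10

    def test_slice_count_contract(self, sphere_phantom):
        stack = phantom.render_confocal_stack(sphere_phantom, n_slices=7)
        assert stack.shape[0] == 7
        with pytest.raises(ValueError):
            phantom.render_confocal_stack(sphere_phantom, n_slices=1)
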