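"""Shared fixtures: small phantoms and rotation videos generated at test time."""

import numpy as np
import pytest

from rotovol import phantom


@pytest.fixture(scope="session")
def sphere_phantom():
    """Smooth sphere, radius 10 voxels, in a 64-cube grid."""
    return phantom.make_phantom(1, "smooth", 64, (10.0, 10.0, 10.0))


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Smooth ellipsoid with in-plane semi-axes 15 and 10 voxels."""
    return phantom.make_phantom(2, "smooth", 64, (10.0, 15.0, 10.0))


@pytest.fixture(scope="session")
def rough_phantom():
    return phantom.make_phantom(1, "rough", 64, (10.0, 10.0, 10.0))


@pytest.fixture(scope="session")
def rotation_video():
    """Noiseless in-plane rotation video: 4 revolutions at 60 frames each.

    The phantom carries a granule landmark, as a real cell carries
    distinguishable internal features, so rotation phase is well defined.
    """
    ph = phantom.make_phantom(3, "intermediate", 48, (9.0, 12.0, 10.0),
                              granule_contrast=1.0)
    return phantom.render_rotation_video(
        ph, axis="in_plane", frames_per_rev=60, n_frames=241,
        drift_px_per_frame=0.0, seed=0, noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def period_videos():
    """Noiseless videos spanning the validated frames-per-revolution range."""
    ph = phantom.make_phantom(3, "intermediate", 40, (8.0, 11.0, 9.0),
                              granule_contrast=1.0)
    out = {}
    for fpr in (20, 60, 62, 100):
        n = int(3 * fpr) + 1
        out[fpr] = phantom.render_rotation_video(
            ph, axis="in_plane", frames_per_rev=fpr, n_frames=n,
            seed=0, noise_sd=0.0,
        )
    return out
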