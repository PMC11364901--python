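"""Synthetic rotating-cell phantoms.

This module stands in for the acoustofluidic rotation chip and the confocal
microscope: it builds voxelized single cells of known geometry (membrane and
nucleus channels), renders bright-field-like projections while the cell
rotates in-plane or out-of-plane, and renders confocal-like z-stacks that
serve as regression targets.  Every generator is a pure function of its seed
and parameters, so phantoms provide exact ground truth for the rest of the
pipeline.

Four texture presets emulate the qualitative surface phenotypes of the cell
classes the pipeline is meant to distinguish:

``smooth``        epithelial-like, no surface modulation (HeLa-like)
``rough``         short-wavelength, high-amplitude protrusions (macrophage-like)
``striated``      periodic banding along one body axis (cardiac-myoblast-like)
``intermediate``  moderate roughness (melanoma-like)

Array convention: all volumes are indexed ``(z, y, x)``; the optical axis is
``z`` and projections integrate along it.  Rotation is about the grid center
with trilinear interpolation.  All images and volumes are normalized to
``[0, 1]`` at creation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import RotovolError

PRESETS = ("smooth", "rough", "striated", "intermediate")

# (roughness amplitude, angular frequency band) per preset; striation freq is
# the band count along the body axis
_PRESET_PARAMS = {
    "smooth": dict(amp=0.0, freq=0.0),
    "rough": dict(amp=0.18, freq=9.0),
    "striated": dict(amp=0.12, freq=6.0),
    "intermediate": dict(amp=0.08, freq=5.0),
}

#: default recording protocol: 310 frames over a 15-second interval
DEFAULT_N_FRAMES = 310
DEFAULT_INTERVAL_S = 15.0 / 310.0
DEFAULT_FRAMES_PER_REV = 62.0


@dataclass(frozen=True)
class Image2D:
    """A single grayscale frame with intensities normalized to [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2:
            raise ValueError("Image2D requires a 2-D array")
        if not np.all(np.isfinite(p)):
            raise ValueError("Image2D requires finite intensities")
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("Image2D intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", np.clip(p, 0.0, 1.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RotationVideo:
    """Ordered grayscale frames of one rotating cell.

    ``true_frames_per_rev`` is known only for synthetic videos and is the
    ground truth against which period estimation is validated.
    """

    frames: tuple[Image2D, ...]
    frame_interval_s: float = DEFAULT_INTERVAL_S
    axis: str = "in_plane"
    true_frames_per_rev: float | None = None

    def __post_init__(self):
        if len(self.frames) < 2:
            raise ValueError("a rotation video needs at least 2 frames")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError("all frames must share one shape")
        if self.axis not in ("in_plane", "out_of_plane"):
            raise ValueError(f"unknown rotation axis {self.axis!r}")

    def __len__(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """Frames stacked as a (T, H, W) array."""
        return np.stack([f.pixels for f in self.frames])


@dataclass(frozen=True)
class Phantom:
    """A voxelized synthetic cell: membrane + nucleus scalar fields.

    Both fields share one ``(z, y, x)`` grid, are bounded in [0, 1], and the
    nucleus support is contained in the membrane support.  Identical
    ``(preset, seed, radii)`` give bit-identical fields.
    """

    membrane_field: np.ndarray
    nucleus_field: np.ndarray
    preset: str
    base_radii_um: tuple[float, float, float]
    roughness_amp: float
    seed: int
    voxel_size_um: float = 1.0

    def __post_init__(self):
        if self.membrane_field.shape != self.nucleus_field.shape:
            raise ValueError("membrane and nucleus fields must share a shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.membrane_field.shape

    def support(self, channel: str = "membrane", level: float = 0.5) -> np.ndarray:
        """Boolean support mask of a channel at an intensity level."""
        f = self.membrane_field if channel == "membrane" else self.nucleus_field
        return f >= level

    def combined_field(self) -> np.ndarray:
        """Membrane plus nucleus intensity, renormalized to [0, 1]."""
        total = self.membrane_field + self.nucleus_field
        m = total.max()
        return total / m if m > 0 else total


def _unit_directions(rng: np.random.Generator, n: int, freq: float):
    """Random wave vectors of magnitude ~freq for band-limited surface noise."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    scale = freq * rng.uniform(0.75, 1.25, size=(n, 1))
    phases = rng.uniform(0, 2 * np.pi, size=n)
    weights = rng.normal(size=n)
    weights /= np.sqrt(np.sum(weights**2)) + 1e-12
    return v * scale, phases, weights


def _surface_modulation(dirs: np.ndarray, preset: str, rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise on the unit sphere, evaluated at unit vectors.

    Returns values roughly in [-1, 1].  ``striated`` is deterministic
    sinusoidal banding along the z body axis; the random presets superpose
    plane waves with wave numbers in the preset's frequency band.
    """
    params = _PRESET_PARAMS[preset]
    if params["amp"] == 0.0:
        return np.zeros(len(dirs))
    if preset == "striated":
        return np.sin(np.pi * params["freq"] * dirs[:, 0])
    waves, phases, weights = _unit_directions(rng, 12, params["freq"])
    fields = np.cos(dirs @ waves.T + phases)  # (npts, nwaves)
    g = fields @ weights
    peak = np.abs(g).max()
    return g / peak if peak > 0 else g


def make_phantom(
    seed: int,
    preset: str,
    grid_size: int | tuple[int, int, int] = 64,
    radii_um: tuple[float, float, float] = (14.0, 11.0, 10.0),
    voxel_size_um: float = 1.0,
    roughness_amp: float | None = None,
    edge_width_vox: float = 1.0,
    granule_contrast: float = 0.0,
) -> Phantom:
    """Build an ellipsoidal cell phantom with preset-dependent surface texture.

    The membrane is a filled ellipsoid whose radius is modulated by
    band-limited angular noise, ``r(θ, φ) = r0 · (1 + amp · g(θ, φ))``; the
    nucleus is a concentric smooth ellipsoid at half the radii.  The interior
    intensity carries a matching volumetric texture so reconstructed volumes
    inherit the preset's co-occurrence statistics.

    Parameters
    ----------
    seed:
        Controls every random draw; identical seeds give bit-identical fields.
    preset:
        One of ``smooth``, ``rough``, ``striated``, ``intermediate``.
    grid_size:
        Cubic edge length in voxels, or a (z, y, x) triple; minimum 32.
    radii_um:
        Ellipsoid semi-axes in micrometres, ordered (z, y, x).
    voxel_size_um:
        Isotropic voxel edge; radii are divided by it to get voxel radii.
    roughness_amp:
        Overrides the preset's amplitude when given; must be >= 0.
    granule_contrast:
        When positive, adds one eccentric bright inclusion (a nucleolus-like
        landmark) of that peak intensity.  It breaks the point symmetry of
        the bare ellipsoid, giving rotation videos a trackable feature and a
        correlation series with unambiguous full-revolution peaks; off by
        default so the symmetric-geometry contracts hold exactly.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    shape = (grid_size,) * 3 if np.isscalar(grid_size) else tuple(grid_size)
    if min(shape) < 32:
        raise ValueError("grid_size must be at least 32 voxels per axis")
    radii_vox = np.asarray(radii_um, dtype=float) / voxel_size_um
    amp = _PRESET_PARAMS[preset]["amp"] if roughness_amp is None else float(roughness_amp)
    if amp < 0:
        raise ValueError("roughness_amp must be nonnegative")
    max_extent = radii_vox * (1 + amp)
    if np.any(max_extent + 2 > np.asarray(shape) / 2):
        raise ValueError(
            f"radii {tuple(radii_um)} um (+roughness) do not fit in grid "
            f"{shape} with a 2-voxel margin"
        )

    rng = np.random.default_rng(seed)
    center = (np.asarray(shape) - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1) - center
    body = coords / radii_vox  # normalized body coordinates
    rho = np.linalg.norm(body, axis=-1)

    flat = body.reshape(-1, 3)
    norms = np.maximum(np.linalg.norm(flat, axis=1, keepdims=True), 1e-9)
    g = _surface_modulation(flat / norms, preset, rng).reshape(shape)

    # soft-edged occupancy: 0.5 exactly on the modulated surface
    local_edge = edge_width_vox / np.mean(radii_vox)
    signed = (1.0 + amp * g) - rho
    occupancy = np.clip(0.5 + signed / local_edge, 0.0, 1.0)

    # interior intensity texture matched to the preset so texture features
    # separate the classes even after blurring and resampling; kept in
    # [0.55, 0.95] so the 0.5-level support stays the geometric surface
    interior = np.full(shape, 0.75)
    if preset == "striated":
        interior += 0.2 * np.sin(np.pi * _PRESET_PARAMS[preset]["freq"] * body[..., 0])
    elif amp > 0:
        waves, phases, weights = _unit_directions(rng, 12, _PRESET_PARAMS[preset]["freq"] * 1.5)
        tex = (np.cos(flat @ waves.T + phases) @ weights).reshape(shape)
        peak = np.abs(tex).max()
        interior += (0.2 * min(1.0, amp / 0.18)) * (tex / peak if peak else tex)
    membrane = np.minimum(occupancy, interior)

    if granule_contrast > 0:
        # eccentric bright inclusion: seeded direction at 0.45 of the radius
        gdir = rng.normal(size=3)
        gdir /= np.linalg.norm(gdir)
        gdist = np.linalg.norm(body - 0.5 * gdir, axis=-1)
        granule = np.clip(0.5 + (0.3 - gdist) / local_edge, 0.0, 1.0)
        membrane = np.maximum(membrane,
                              np.clip(granule * granule_contrast, 0.0, 1.0)
                              * (membrane > 0))

    # concentric smooth nucleus at 0.5x radii (rho = 0.5 on its surface)
    nucleus = np.clip(0.5 + (0.5 - rho) / local_edge, 0.0, 1.0)
    nucleus = nucleus * (membrane > 0)  # support containment

    return Phantom(
        membrane_field=membrane.astype(np.float64),
        nucleus_field=nucleus.astype(np.float64),
        preset=preset,
        base_radii_um=tuple(float(r) for r in radii_um),
        roughness_amp=amp,
        seed=int(seed),
        voxel_size_um=float(voxel_size_um),
    )


def _rotate_volume(volume: np.ndarray, angle_rad: float, axis: str) -> np.ndarray:
    """Rigid rotation about the grid center, trilinear interpolation.

    ``in_plane`` rotates about the optical (z) axis, i.e. within the (y, x)
    image plane; ``out_of_plane`` rotates about the x axis, tumbling the cell
    through the focal plane.
    """
    if axis == "in_plane":
        axes = (1, 2)
    elif axis == "out_of_plane":
        axes = (0, 1)
    else:
        raise ValueError(f"unknown rotation axis {axis!r}")
    if angle_rad == 0.0:
        return volume
    return ndimage.rotate(
        volume, np.degrees(angle_rad), axes=axes, reshape=False, order=1,
        mode="constant", cval=0.0, prefilter=False,
    )


def render_projection(
    phantom: Phantom,
    angle: float,
    axis: str = "in_plane",
    blur_sigma: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> Image2D:
    """Orthographic sum-projection of the rotated phantom along the optical axis.

    An absorption-free bright-field proxy: the summed membrane+nucleus field
    is rotated rigidly, integrated along z, Gaussian-blurred, corrupted with
    additive Gaussian noise, clipped and renormalized to [0, 1].
    """
    if blur_sigma < 0 or noise_sd < 0:
        raise ValueError("blur_sigma and noise_sd must be nonnegative")
    rotated = _rotate_volume(phantom.combined_field(), angle, axis)
    proj = rotated.sum(axis=0)
    m = proj.max()
    if m > 0:
        proj = proj / m
    if blur_sigma > 0:
        proj = ndimage.gaussian_filter(proj, blur_sigma)
    if noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        proj = proj + rng.normal(0.0, noise_sd, size=proj.shape)
    proj = np.clip(proj, 0.0, 1.0)
    m = proj.max()
    if m > 0:
        proj = proj / m
    return Image2D(proj)


def render_rotation_video(
    phantom: Phantom,
    axis: str = "in_plane",
    frames_per_rev: float = DEFAULT_FRAMES_PER_REV,
    n_frames: int = DEFAULT_N_FRAMES,
    drift_px_per_frame: float = 0.0,
    seed: int = 0,
    blur_sigma: float = 1.0,
    noise_sd: float = 0.0,
    frame_interval_s: float = DEFAULT_INTERVAL_S,
) -> RotationVideo:
    """Render a rotation video: frame k at angle 2πk / frames_per_rev.

    Optional translational drift displaces frame k by ``k * drift_px_per_frame``
    pixels along +x.  The true frames-per-revolution is recorded on the video
    for downstream validation.  Defaults follow the recording protocol of 310
    frames over 15 s.
    """
    if frames_per_rev < 4:
        raise ValueError("frames_per_rev must be at least 4")
    if n_frames < frames_per_rev:
        raise ValueError("n_frames must cover at least one revolution")
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(int(n_frames)):
        img = render_projection(
            phantom, 2 * np.pi * k / frames_per_rev, axis,
            blur_sigma=blur_sigma, noise_sd=noise_sd, rng=rng,
        )
        px = img.pixels
        if drift_px_per_frame != 0.0:
            px = ndimage.shift(px, (0.0, k * drift_px_per_frame), order=1,
                               mode="constant", cval=0.0, prefilter=False)
            px = np.clip(px, 0.0, 1.0)
        frames.append(Image2D(px))
    return RotationVideo(
        frames=tuple(frames),
        frame_interval_s=frame_interval_s,
        axis=axis,
        true_frames_per_rev=float(frames_per_rev),
    )


def render_confocal_stack(
    phantom: Phantom,
    n_slices: int = 10,
    channel: str = "membrane",
    blur_sigma: float = 1.0,
) -> np.ndarray:
    """Confocal-like z-stack: equispaced axial sections of one channel.

    Returns a ``(n_slices, H, W)`` array, slices ordered bottom → top, each
    section blurred in-plane and the stack normalized to [0, 1].
    """
    if n_slices < 2:
        raise ValueError("n_slices must be at least 2")
    if channel not in ("membrane", "nucleus"):
        raise ValueError("channel must be 'membrane' or 'nucleus'")
    fieldvol = phantom.membrane_field if channel == "membrane" else phantom.nucleus_field
    nz = fieldvol.shape[0]
    z_idx = np.round(np.linspace(0, nz - 1, int(n_slices))).astype(int)
    slices = []
    for z in z_idx:
        s = fieldvol[z]
        if blur_sigma > 0:
            s = ndimage.gaussian_filter(s, blur_sigma)
        slices.append(s)
    stack = np.stack(slices)
    m = stack.max()
    return stack / m if m > 0 else stack


def synthetic_pairs(
    n: int,
    seed: int,
    preset: str = "intermediate",
    grid_size: int = 48,
    channel: str = "membrane",
    frames_per_rev: float = 24.0,
    n_frames: int = 48,
    noise_sd: float = 0.01,
):
    """Generate (video, raw confocal slices) pairs for training experiments.

    Radii are jittered per phantom so each cell has its own geometry; the
    confocal stack is rendered at the grid's native axial sampling and the
    caller resamples it to the network target shape.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        radii = rng.uniform(9.0, 13.0, size=3)
        radii = tuple(np.sort(radii)[::-1])
        ph = make_phantom(int(rng.integers(2**31)), preset,
                          grid_size=grid_size, radii_um=radii,
                          granule_contrast=1.0)
        video = render_rotation_video(
            ph, axis="in_plane", frames_per_rev=frames_per_rev,
            n_frames=n_frames, seed=int(rng.integers(2**31)),
            noise_sd=noise_sd,
        )
        raw_stack = render_confocal_stack(ph, n_slices=grid_size, channel=channel)
        out.append((ph, video, raw_stack))
    return out
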