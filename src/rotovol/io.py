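"""Reading and writing the pipeline's on-disk formats.

Volumes, stacks and videos travel as multi-page TIFF (one page per z-slice
or frame; 32-bit float for tensors); AVI videos are read through imageio;
sidecar metadata is YAML; feature tables are CSV; meshes are ASCII PLY.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .morphometrics import Mesh
from .phantom import Image2D, RotationVideo
from .preprocess import ROIStack, VolumeStack


def write_stack_tiff(path, tensor: np.ndarray, axis_last: bool = True) -> None:
    """Write a volume as a multi-page float32 TIFF, one page per slice.

    ``axis_last`` indicates an (H, W, Z) tensor (pages taken along the last
    axis); otherwise pages are the leading axis.
    """
    t = np.asarray(tensor, dtype=np.float32)
    pages = np.moveaxis(t, -1, 0) if axis_last else t
    tifffile.imwrite(str(path), pages)


def read_stack_tiff(path, axis_last: bool = True) -> np.ndarray:
    """Read a multi-page TIFF written by :func:`write_stack_tiff`."""
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    return np.moveaxis(pages, 0, -1) if axis_last else pages


def write_video(path, video: RotationVideo) -> None:
    """Write a rotation video as multi-page TIFF with a YAML sidecar."""
    frames = (video.as_array() * 65535).astype(np.uint16)
    tifffile.imwrite(str(path), frames)
    sidecar = Path(str(path)).with_suffix(".yaml")
    meta = {
        "frame_interval_s": video.frame_interval_s,
        "axis": video.axis,
        "true_frames_per_rev": video.true_frames_per_rev,
        "n_frames": len(video),
    }
    sidecar.write_text(yaml.safe_dump(meta))


def read_video(path) -> RotationVideo:
    """Read a rotation video from multi-page TIFF or AVI (+ YAML sidecar)."""
    p = Path(str(path))
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(p)).astype(np.float64)
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(str(p))).astype(np.float64)
        if arr.ndim == 4:  # RGB frames -> luminance
            arr = arr.mean(axis=-1)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    meta = {}
    sidecar = p.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    return RotationVideo(
        frames=tuple(Image2D(f) for f in arr),
        frame_interval_s=float(meta.get("frame_interval_s", 15.0 / 310.0)),
        axis=meta.get("axis", "in_plane"),
        true_frames_per_rev=meta.get("true_frames_per_rev"),
    )


def write_roi_stack(path, stack: ROIStack) -> None:
    write_stack_tiff(path, stack.tensor)
    Path(str(path)).with_suffix(".yaml").write_text(
        yaml.safe_dump({"source_frame_indices": list(stack.source_frame_indices)})
    )


def write_volume_stack(path, stack: VolumeStack) -> None:
    write_stack_tiff(path, stack.tensor)
    Path(str(path)).with_suffix(".yaml").write_text(
        yaml.safe_dump({"z_spacing": stack.z_spacing})
    )


def write_mesh_stl(path, mesh: Mesh, name: str = "rotovol") -> None:
    """ASCII STL export of a triangular mesh (facet normals recomputed)."""
    v, f = mesh.vertices, mesh.faces
    tris = v[f]
    normals = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    lengths = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, lengths, out=np.zeros_like(normals),
                        where=lengths > 0)
    lines = [f"solid {name}"]
    for tri, n in zip(tris, normals):
        lines.append(f"  facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}")
        lines.append("    outer loop")
        for p in tri:
            lines.append(f"      vertex {p[0]:.6e} {p[1]:.6e} {p[2]:.6e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append(f"endsolid {name}")
    Path(str(path)).write_text("\n".join(lines) + "\n")


def write_mesh_ply(path, mesh: Mesh) -> None:
    """ASCII PLY export of a triangular mesh."""
    v, f = mesh.vertices, mesh.faces
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(v)}",
        "property float x", "property float y", "property float z",
        f"element face {len(f)}",
        "property list uchar int vertex_indices", "end_header",
    ]
    lines += [f"{a:.6f} {b:.6f} {c:.6f}" for a, b, c in v]
    lines += [f"3 {i} {j} {k}" for i, j, k in f]
    Path(str(path)).write_text("\n".join(lines) + "\n")
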