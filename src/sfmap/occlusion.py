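"""Occlusion saliency for volumetric VF regressors.

Each non-overlapping patch (default 4x4x4 voxels) of the input volume is
replaced in turn by a gray patch equal to the *unoccluded* volume's mean
intensity, and the saliency of the patch for VF point pt is the absolute
change in the model's prediction at pt.  This yields 52 saliency volumes per
scan on the patch grid; averaging over the depth patch axis gives the 2D
en-face saliency maps consumed by the group analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import ProcessedVolume
from .vf_grid import N_POINTS

__all__ = [
    "OcclusionSpec",
    "SaliencyVolume",
    "SaliencyMap2D",
    "patch_grid_shape",
    "occlude_patch",
    "saliency_volumes",
    "saliency_stack",
    "enface_project",
]


@dataclass(frozen=True)
class OcclusionSpec:
    """Geometry of the occlusion tiling.

    ``stride`` defaults to the patch size (non-overlapping tiling), which is
    the validated configuration; the patch dims must then divide the volume
    dims exactly.
    """

    patch_vox: tuple[int, int, int] = (4, 4, 4)
    replacement: str = "volume_mean"
    stride: tuple[int, int, int] | None = None

    def effective_stride(self) -> tuple[int, int, int]:
        return self.stride if self.stride is not None else self.patch_vox


def patch_grid_shape(vol_shape: tuple[int, int, int],
                     spec: OcclusionSpec | tuple[int, int, int] = OcclusionSpec()) -> tuple[int, int, int]:
    """Patch-grid dimensions for a volume shape under a tiling spec."""
    if isinstance(spec, OcclusionSpec):
        stride = spec.effective_stride()
        patch = spec.patch_vox
    else:
        stride = patch = tuple(spec)
    if stride == patch and any(s % p for s, p in zip(vol_shape, patch)):
        raise ValueError(f"patch {patch} does not tile volume {vol_shape}")
    return tuple(s // st for s, st in zip(vol_shape, stride))


@dataclass
class SaliencyVolume:
    """Per-VF-point 3D saliency on the patch grid (dB units)."""

    values: np.ndarray  # (gx, gy, gz)
    pt: int
    eye_id: str = ""
    scan_date: float = 0.0
    spec: OcclusionSpec = field(default_factory=OcclusionSpec)


@dataclass
class SaliencyMap2D:
    """En-face (depth-averaged) saliency map for one VF point."""

    values: np.ndarray  # (gx, gy)
    pt: int
    eye_id: str = ""
    scan_date: float = 0.0
    disc_center_vox: tuple[float, float] | None = None


def _patch_slices(j: tuple[int, int, int], spec: OcclusionSpec):
    px, py, pz = spec.patch_vox
    sx, sy, sz = spec.effective_stride()
    a, b, c = j
    return (slice(a * sx, a * sx + px),
            slice(b * sy, b * sy + py),
            slice(c * sz, c * sz + pz))


def occlude_patch(volume: ProcessedVolume, j: tuple[int, int, int],
                  spec: OcclusionSpec = OcclusionSpec(),
                  volume_mean: float | None = None) -> ProcessedVolume:
    """Replace the j-th patch with the unoccluded volume's mean intensity.

    ``volume_mean`` may be passed in to reuse a mean computed once per
    volume; this is what makes repeated occlusion of the same patch
    idempotent.  All other voxels are returned bit-identical.
    """
    grid = patch_grid_shape(volume.intensity.shape, spec)
    if not all(0 <= jj < g for jj, g in zip(j, grid)):
        raise IndexError(f"patch index {j} outside grid {grid}")
    vbar = float(volume.intensity.mean()) if volume_mean is None else float(volume_mean)
    out = ProcessedVolume(
        intensity=volume.intensity.copy(),
        voxel_spacing_um=volume.voxel_spacing_um,
        disc_center_vox=volume.disc_center_vox,
        laterality=volume.laterality,
        eye_id=volume.eye_id,
        scan_date=volume.scan_date,
        transform_log=volume.transform_log + [("occlude", {"patch": tuple(j)})],
    )
    out.intensity[_patch_slices(j, spec)] = vbar
    return out


def _predict_many(model, volumes: np.ndarray) -> np.ndarray:
    """Batched prediction helper: (n, nx, ny, nz) -> (n, 52)."""
    if hasattr(model, "predict_many"):
        return np.asarray(model.predict_many(volumes))
    return np.stack([np.asarray(model.predict(v)) for v in volumes])


def saliency_stack(model, volume: ProcessedVolume,
                   spec: OcclusionSpec = OcclusionSpec(),
                   batch_size: int = 64) -> np.ndarray:
    """All 52 saliency volumes as one array of shape (52, gx, gy, gz).

    One forward pass per patch position plus one baseline; forward passes are
    batched (the batch size must not, and does not, affect the result).
    """
    grid = patch_grid_shape(volume.intensity.shape, spec)
    vbar = float(volume.intensity.mean())
    base = np.asarray(model.predict(volume.intensity)).reshape(N_POINTS)

    idx = [(a, b, c) for a in range(grid[0]) for b in range(grid[1]) for c in range(grid[2])]
    sal = np.empty((N_POINTS,) + grid)
    for start in range(0, len(idx), batch_size):
        chunk = idx[start:start + batch_size]
        occluded = np.repeat(volume.intensity[None], len(chunk), axis=0)
        for k, j in enumerate(chunk):
            occluded[(k,) + _patch_slices(j, spec)] = vbar
        preds = _predict_many(model, occluded)  # (len(chunk), 52)
        diffs = np.abs(base[None, :] - preds)
        for k, (a, b, c) in enumerate(chunk):
            sal[:, a, b, c] = diffs[k]
    return sal


def saliency_volumes(model, volume: ProcessedVolume,
                     spec: OcclusionSpec = OcclusionSpec(),
                     batch_size: int = 64) -> list[SaliencyVolume]:
    """52 per-point SaliencyVolume objects for one scan."""
    sal = saliency_stack(model, volume, spec, batch_size=batch_size)
    return [
        SaliencyVolume(values=sal[pt], pt=pt, eye_id=volume.eye_id,
                       scan_date=volume.scan_date, spec=spec)
        for pt in range(N_POINTS)
    ]


def enface_project(sal: SaliencyVolume | np.ndarray,
                   disc_center_vox: tuple[float, float] | None = None):
    """Average a saliency volume over the depth patch axis.

    Accepts a single SaliencyVolume (returns SaliencyMap2D) or a raw array
    whose last axis is depth (returns an array with that axis averaged out).
    """
    if isinstance(sal, SaliencyVolume):
        return SaliencyMap2D(values=sal.values.mean(axis=-1), pt=sal.pt,
                             eye_id=sal.eye_id, scan_date=sal.scan_date,
                             disc_center_vox=disc_center_vox)
    return np.asarray(sal).mean(axis=-1)
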