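"""OCT volume preprocessing and VF temporal smoothing.

Mirrors the standard preparation of ONH OCT for volumetric regression:
flatten the reference surface (Bruch's membrane opening) by shifting each
A-scan axially, centrally crop around the optic-disc center, then
Gaussian-antialiased integer downsampling.  Longitudinal VF series are
denoised by pointwise linear regression over 5 consecutive visits.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .vf_grid import N_POINTS, NormativeProfile, VFTest, compute_md

__all__ = [
    "RawScan",
    "ProcessedVolume",
    "flatten",
    "central_crop",
    "downsample",
    "temporal_smooth",
]

log = logging.getLogger(__name__)

#: Antialias filter width per axis, in units of the decimation factor.
ANTIALIAS_SIGMA_PER_FACTOR = 0.5
ANTIALIAS_TRUNCATE = 4.0  # kernel support in units of sigma


@dataclass
class RawScan:
    """A pre-crop ONH intensity volume with its geometry annotations.

    Axes are (lateral x, lateral y, axial z).  ``surface_z`` holds, per
    A-scan (x, y), the axial voxel coordinate of the reference surface; it is
    a provided input (segmentation is out of scope here).
    """

    intensity: np.ndarray  # (nx, ny, nz)
    voxel_spacing_um: tuple[float, float, float]
    laterality: str
    disc_center_vox: tuple[int, int]
    surface_z: np.ndarray | None = None  # (nx, ny)
    eye_id: str = ""
    scan_date: float = 0.0
    transform_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3D (x, y, z)")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacing must be positive")
        if self.surface_z is not None:
            self.surface_z = np.asarray(self.surface_z, dtype=float)
            nz = self.intensity.shape[2]
            if self.surface_z.shape != self.intensity.shape[:2]:
                raise ValueError("surface_z must be per-A-scan (nx, ny)")
            if np.any(self.surface_z < 0) or np.any(self.surface_z >= nz):
                raise ValueError("surface_z outside axial bounds")


@dataclass
class ProcessedVolume:
    """Flattened, cropped, downsampled volume fed to the regressor."""

    intensity: np.ndarray
    voxel_spacing_um: tuple[float, float, float]
    disc_center_vox: tuple[float, float]
    laterality: str = "right"
    eye_id: str = ""
    scan_date: float = 0.0
    transform_log: list = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


def flatten(scan: RawScan, fill: str | float = "mean") -> RawScan:
    """Shift each A-scan axially so the reference surface becomes a plane.

    The target plane is the rounded median surface depth.  Shifts are integer
    voxels; voxels shifted in from outside the volume are filled with the
    volume mean intensity (or an explicit ``fill`` value).
    """
    if scan.surface_z is None:
        raise ValueError("flatten requires surface_z")
    nz = scan.intensity.shape[2]
    plane = int(round(float(np.median(scan.surface_z))))
    shifts = plane - np.rint(scan.surface_z).astype(int)  # (nx, ny)
    if np.any(np.abs(shifts) >= nz):
        raise ValueError("flattening shift moves entire depth range out of bounds")
    fill_value = float(scan.intensity.mean()) if fill == "mean" else float(fill)

    out = np.full_like(scan.intensity, fill_value)
    # group A-scans by shift so each distinct shift is one slice copy
    for s in np.unique(shifts):
        mask = shifts == s
        if s == 0:
            out[mask] = scan.intensity[mask]
        elif s > 0:
            out[mask, s:] = scan.intensity[mask, : nz - s]
        else:
            out[mask, :s] = scan.intensity[mask, -s:]

    res = copy.copy(scan)
    res.intensity = out
    res.surface_z = np.full(scan.intensity.shape[:2], float(plane))
    res.transform_log = scan.transform_log + [("flatten", {"plane": plane})]
    return res


def central_crop(scan: RawScan, out_shape: tuple[int, int, int],
                 axial_anchor_frac: float = 1.0 / 3.0) -> RawScan:
    """Crop laterally around the disc center and axially around the surface plane.

    Windows are 0-based half-open; for an even window size w the lateral
    window is [c - w/2, c + w/2).  Axially the (flattened) surface plane is
    placed ``axial_anchor_frac`` of the output depth from the top of the
    window.  No implicit padding: windows outside the scan raise.
    """
    if scan.disc_center_vox is None:
        raise ValueError("central_crop requires disc_center_vox")
    nx, ny, nz = scan.intensity.shape
    wx, wy, wz = out_shape
    cx, cy = (int(round(c)) for c in scan.disc_center_vox)
    x0, y0 = cx - wx // 2, cy - wy // 2
    if scan.surface_z is not None:
        plane = int(round(float(np.median(scan.surface_z))))
    else:
        plane = nz // 2
    z0 = plane - int(round(axial_anchor_frac * wz))
    if x0 < 0 or y0 < 0 or z0 < 0 or x0 + wx > nx or y0 + wy > ny or z0 + wz > nz:
        raise ValueError(
            f"crop window {out_shape} at disc ({cx},{cy}), plane {plane} "
            f"exceeds scan bounds {scan.intensity.shape}"
        )
    res = copy.copy(scan)
    res.intensity = scan.intensity[x0:x0 + wx, y0:y0 + wy, z0:z0 + wz].copy()
    res.disc_center_vox = (cx - x0, cy - y0)
    if scan.surface_z is not None:
        res.surface_z = scan.surface_z[x0:x0 + wx, y0:y0 + wy] - z0
    res.transform_log = scan.transform_log + [
        ("central_crop", {"origin": (x0, y0, z0), "shape": tuple(out_shape)})
    ]
    return res


def downsample(scan: RawScan, factors: tuple[int, int, int] = (2, 2, 4)) -> ProcessedVolume:
    """Gaussian-antialiased reduction by integer factors per axis.

    The low-pass sigma is factor/2 voxels per axis (kernel truncated at 4
    sigma); the filtered volume is then reduced by averaging each
    factor-sized block (a mirror-exact decimation, so downsampling commutes
    with laterality flips).  Voxel spacing is multiplied by the factors.
    """
    shape = scan.intensity.shape
    if any(s % f for s, f in zip(shape, factors)):
        raise ValueError(f"shape {shape} not divisible by factors {factors}")
    sigma = [ANTIALIAS_SIGMA_PER_FACTOR * f if f > 1 else 0.0 for f in factors]
    smoothed = gaussian_filter(scan.intensity, sigma=sigma,
                               truncate=ANTIALIAS_TRUNCATE, mode="nearest")
    fx, fy, fz = factors
    nx, ny, nz = shape
    out = (smoothed.reshape(nx // fx, fx, ny // fy, fy, nz // fz, fz)
                   .mean(axis=(1, 3, 5)))
    spacing = tuple(s * f for s, f in zip(scan.voxel_spacing_um, factors))
    cx, cy = scan.disc_center_vox
    return ProcessedVolume(
        intensity=out,
        voxel_spacing_um=spacing,
        disc_center_vox=(cx / fx, cy / fy),
        laterality=scan.laterality,
        eye_id=scan.eye_id,
        scan_date=scan.scan_date,
        transform_log=scan.transform_log + [("downsample", {"factors": tuple(factors)})],
    )


def _ols_fit_at(dates: np.ndarray, values: np.ndarray, at: float) -> np.ndarray:
    """Pointwise OLS of values (n_visits, 52) on dates, evaluated at ``at``."""
    x = dates - dates.mean()
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        return values.mean(axis=0)
    slope = x @ values / sxx
    intercept = values.mean(axis=0)
    return intercept + slope * (at - dates.mean())


def temporal_smooth(series: Sequence[VFTest], window: int = 5,
                    norm: NormativeProfile | None = None) -> list[VFTest]:
    """Smooth a single eye's VF series by pointwise linear regression.

    For each visit, sensitivities are replaced by the OLS fitted value (per
    point, sensitivity vs. date) evaluated at that visit's date, over the
    ``window`` consecutive visits ending at the visit (the first ``window``
    visits for early indices).  Eyes with fewer than ``window`` visits are
    returned unchanged.  MD is recomputed from the smoothed sensitivities
    when a normative profile is supplied, otherwise shifted by the mean
    smoothing delta.  Duplicate dates collapsing the regression fall back to
    the window mean.
    """
    series = list(series)
    if len(series) < window:
        return series
    if len({t.eye_id for t in series}) > 1:
        raise ValueError("temporal_smooth expects a single eye's series")
    dates = np.array([t.test_date for t in series])
    if np.any(np.diff(dates) < 0):
        raise ValueError("series must be date-sorted")
    sens = np.stack([t.sensitivities for t in series])

    out = []
    for i, t in enumerate(series):
        lo = max(0, i - (window - 1)) if i >= window - 1 else 0
        hi = lo + window
        d, v = dates[lo:hi], sens[lo:hi]
        if np.ptp(d) == 0.0 and len(np.unique(d)) == 1:
            log.warning("degenerate smoothing window for eye %s: duplicate dates; "
                        "using window mean", t.eye_id)
        fitted = _ols_fit_at(d, v, at=dates[i])
        if norm is not None:
            new_md = compute_md(fitted, norm)
        else:
            new_md = t.md + float(np.mean(fitted - t.sensitivities))
        tt = copy.copy(t)
        tt.sensitivities = fitted
        tt.md = new_md
        out.append(tt)
    return out
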