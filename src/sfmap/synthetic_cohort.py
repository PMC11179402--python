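"""Seeded synthetic cohort with a planted, recoverable structure-function map.

The generator emulates the statistical structure the group-mapping analysis
assumes, at desk scale: a severity spectrum of eyes (healthy through
moderate-advanced), superior/inferior/diffuse defect patterns, longitudinal
VF series with linear progression plus i.i.d. noise, mixed laterality,
disc-center jitter, and OCT-like intensity volumes in which a damage-bearing
band encodes the planted en-face damage field.

The planted ground truth is a PlantedMapping: for every VF point, the set of
en-face patch-grid regions that causally drive it, honoring the anatomic
inversion (superior VF points are driven by the inferior retinal half, and
vice versa).  Volumes render the band *darker* where damage is higher, on a
brighter surround, so that mean-intensity occlusion produces a saliency that
grows monotonically with planted damage — the severity dependence the group
analysis is designed to detect.  No anatomic realism is claimed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .preprocess import RawScan
from .vf_grid import (
    N_POINTS,
    NormativeProfile,
    VFTest,
    compute_md,
    default_normative,
    flip_permutation,
    grid_coords,
    hemifield_masks,
    vertical_mirror_permutation,
)

__all__ = [
    "PlantedMapping",
    "SyntheticCohortConfig",
    "SyntheticEye",
    "generate_mapping",
    "generate_cohort",
    "make_mirrored_cohort",
    "forward_truth",
    "pair_scans_vf",
    "OracleRegressor",
]

_MAPPING_STREAM = 999983  # substream key for the cohort-level mapping RNG


@dataclass
class PlantedMapping:
    """Ground-truth en-face regions and effect sizes per VF point.

    ``regions[pt]`` holds flat indices (row-major over the en-face patch
    grid) of the patches that drive point pt; ``effect[pt]`` is the dB of
    sensitivity loss at pt per unit mean damage over its regions.
    """

    regions: list  # list of 52 int arrays (flat en-face patch indices)
    effect: np.ndarray  # (52,)
    grid_shape: tuple[int, int]  # en-face patch grid (gx, gy)

    def __post_init__(self) -> None:
        self.effect = np.asarray(self.effect, dtype=float)
        if len(self.regions) != N_POINTS or self.effect.shape != (N_POINTS,):
            raise ValueError("mapping must cover all 52 points")
        gx, gy = self.grid_shape
        sup, inf = hemifield_masks()
        for pt in range(N_POINTS):
            r = np.asarray(self.regions[pt], dtype=int)
            if r.size < 1:
                raise ValueError(f"point {pt} has no planted region")
            rows, cols = np.divmod(r, gy)
            if np.any(rows < 0) or np.any(rows >= gx) or np.any(cols < 0) or np.any(cols >= gy):
                raise ValueError(f"point {pt} region outside grid {self.grid_shape}")
            # anatomic inversion: superior VF <- inferior retina (high cols)
            if sup[pt] and np.any(cols < gy // 2):
                raise ValueError(f"superior point {pt} maps into superior retina")
            if inf[pt] and np.any(cols >= gy - gy // 2):
                raise ValueError(f"inferior point {pt} maps into inferior retina")
            self.regions[pt] = r

    def region_mask(self, pt: int) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        gx, gy = self.grid_shape
        rows, cols = np.divmod(self.regions[pt], gy)
        m[rows, cols] = True
        return m

    def mean_damage(self, damage: np.ndarray, pt: int) -> float:
        gx, gy = self.grid_shape
        rows, cols = np.divmod(self.regions[pt], gy)
        return float(damage[rows, cols].mean())

    def mirrored(self) -> "PlantedMapping":
        """The mapping under a vertical (superior/inferior) mirror."""
        gx, gy = self.grid_shape
        perm = vertical_mirror_permutation()
        regions = [None] * N_POINTS
        effect = np.empty(N_POINTS)
        for pt in range(N_POINTS):
            rows, cols = np.divmod(self.regions[pt], gy)
            regions[perm[pt]] = np.sort(rows * gy + (gy - 1 - cols))
            effect[perm[pt]] = self.effect[pt]
        return PlantedMapping(regions=regions, effect=effect, grid_shape=self.grid_shape)

    def to_json(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "regions": [r.tolist() for r in self.regions],
            "effect": self.effect.tolist(),
        }

    @classmethod
    def from_json(cls, d: dict) -> "PlantedMapping":
        return cls(regions=[np.asarray(r, dtype=int) for r in d["regions"]],
                   effect=np.asarray(d["effect"], dtype=float),
                   grid_shape=tuple(d["grid_shape"]))


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Desk-scale study conditions for the synthetic cohort.

    The severity mix approximates a mixed clinical glaucoma cohort (overall
    MD of a few dB below normal with a moderate-advanced tail past -6 dB);
    volumes and counts are sized so the full pipeline runs on one CPU in
    minutes.  ``seed`` fully determines the cohort; eye k depends only on
    (seed, k).
    """

    n_eyes: int = 60
    seed: int = 0
    visits_min: int = 3
    visits_max: int = 8
    severity_mix: tuple = (("healthy", 0.25), ("early", 0.40), ("moderate_advanced", 0.35))
    severity_md_ranges: tuple = (("healthy", (-0.5, 0.5)),
                                 ("early", (-5.5, -1.0)),
                                 ("moderate_advanced", (-18.0, -6.5)))
    defect_pattern_mix: tuple = (("superior", 0.4), ("inferior", 0.4), ("diffuse", 0.2))
    left_eye_fraction: float = 0.5
    raw_shape: tuple[int, int, int] = (64, 64, 192)
    crop_shape: tuple[int, int, int] = (48, 48, 192)
    factors: tuple[int, int, int] = (2, 2, 4)
    patch_vox: tuple[int, int, int] = (4, 4, 4)
    voxel_spacing_um: tuple[float, float, float] = (30.0, 30.0, 1.953125)
    noise_sd_vf: float = 1.0  # dB
    noise_sd_vol: float = 0.02  # intensity units
    disc_jitter_vox: int = 4
    surface_tilt_vox: int = 3
    regions_per_point: int = 2
    effect_range: tuple[float, float] = (15.0, 25.0)
    background_intensity: float = 0.7
    band_intensity: float = 0.5
    crater_intensity: float = 0.15
    crater_radius_vox: int = 6
    band_offset_vox: int = 16  # below the flattened surface plane, raw voxels
    band_thickness_vox: int = 32
    visit_interval_days: float = 180.0
    interval_jitter_days: float = 30.0
    progression_db_per_year: float = 0.7
    sensitivity_ceiling_db: float = 40.0

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be positive")
        for name, mix in (("severity_mix", self.severity_mix),
                          ("defect_pattern_mix", self.defect_pattern_mix)):
            total = sum(p for _, p in mix)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} fractions must sum to 1, got {total}")
        if any(c % f for c, f in zip(self.crop_shape, self.factors)):
            raise ValueError("crop_shape must be divisible by factors")
        proc = self.processed_shape
        if any(p % q for p, q in zip(proc[:2], self.patch_vox[:2])) or proc[2] % self.patch_vox[2]:
            raise ValueError("processed shape must be divisible by patch_vox")
        if not (1 <= self.visits_min <= self.visits_max):
            raise ValueError("invalid visit count range")

    @property
    def processed_shape(self) -> tuple[int, int, int]:
        return tuple(c // f for c, f in zip(self.crop_shape, self.factors))

    @property
    def enface_grid(self) -> tuple[int, int]:
        p = self.processed_shape
        return (p[0] // self.patch_vox[0], p[1] // self.patch_vox[1])

    @property
    def surface_plane(self) -> int:
        # axial anchor: the flattened plane sits 1/3 of the crop depth from the top
        return int(round(self.crop_shape[2] / 3.0))

    def processed_band_z(self) -> tuple[int, int]:
        """Band depth range in processed-volume voxel coordinates."""
        z0 = self.surface_plane + self.band_offset_vox
        fz = self.factors[2]
        return (z0 // fz, (z0 + self.band_thickness_vox) // fz)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticEye:
    """One synthetic eye: ground truth, raw scans and a longitudinal VF series."""

    eye_id: str
    laterality: str
    severity_class: str
    defect_pattern: str
    truth_damage: np.ndarray  # (gx, gy) in [0, 1], right-eye frame
    truth_md: float
    raw_scans: list  # list[RawScan]
    vf_series: list  # list[VFTest], date-sorted


def _disc_patches(grid: tuple[int, int]) -> set[tuple[int, int]]:
    """Central patches overlapped by the disc crater (excluded from regions)."""
    gx, gy = grid
    xs = (gx // 2 - 1, gx // 2)
    ys = (gy // 2 - 1, gy // 2)
    return {(a, b) for a in xs for b in ys}


def generate_mapping(config: SyntheticCohortConfig) -> PlantedMapping:
    """Draw the cohort-level planted mapping (mirror-symmetric by design).

    Regions for superior VF points are sampled in the inferior retinal half;
    each inferior point's regions are the exact vertical mirror of its
    superior partner's, with the same effect size, so mirrored cohorts have
    mirrored ground truth.
    """
    gx, gy = config.enface_grid
    rng = np.random.default_rng([config.seed, _MAPPING_STREAM])
    sup, _ = hemifield_masks()
    perm = vertical_mirror_permutation()
    forbidden = _disc_patches((gx, gy))
    # candidate patches in the inferior retinal half (high column index)
    cand = [(a, b) for a in range(gx) for b in range(gy - gy // 2, gy)
            if (a, b) not in forbidden]
    cand_flat = np.array([a * gy + b for a, b in cand])

    regions: list = [None] * N_POINTS
    effect = np.empty(N_POINTS)
    lo, hi = config.effect_range
    for pt in np.flatnonzero(sup):
        k = min(config.regions_per_point, len(cand_flat))
        pick = rng.choice(cand_flat, size=k, replace=False)
        regions[pt] = np.sort(pick)
        effect[pt] = rng.uniform(lo, hi)
        # mirror partner
        rows, cols = np.divmod(regions[pt], gy)
        regions[perm[pt]] = np.sort(rows * gy + (gy - 1 - cols))
        effect[perm[pt]] = effect[pt]
    return PlantedMapping(regions=regions, effect=effect, grid_shape=(gx, gy))


def forward_truth(damage: np.ndarray, mapping: PlantedMapping,
                  norm: NormativeProfile, noise_sd: float = 0.0,
                  rng: np.random.Generator | None = None,
                  floor_db: float = 0.0, ceiling_db: float = 40.0) -> np.ndarray:
    """The generative structure-function rule.

    sensitivity_pt = norm_pt - effect_pt * meanDamage(regions_pt) + eps,
    eps ~ N(0, noise_sd), clamped to [floor_db, ceiling_db].
    """
    damage = np.asarray(damage, dtype=float)
    if damage.shape != mapping.grid_shape:
        raise ValueError(f"damage shape {damage.shape} != grid {mapping.grid_shape}")
    if np.any(damage < 0) or np.any(damage > 1):
        raise ValueError("damage values must lie in [0, 1]")
    loss = np.array([mapping.effect[pt] * mapping.mean_damage(damage, pt)
                     for pt in range(N_POINTS)])
    sens = norm.mean_sens - loss
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        sens = sens + rng.normal(0.0, noise_sd, size=N_POINTS)
    return np.clip(sens, floor_db, ceiling_db)


def _damage_field(rng: np.random.Generator, config: SyntheticCohortConfig,
                  mapping: PlantedMapping, norm: NormativeProfile,
                  pattern: str, target_md: float) -> tuple[np.ndarray, float]:
    """Damage field realizing ``pattern`` and approximately ``target_md``."""
    gx, gy = mapping.grid_shape
    damage = np.zeros((gx, gy))
    if target_md >= 0.0:
        return damage, 0.0
    sup, inf = hemifield_masks()
    if pattern == "superior":
        pts = np.flatnonzero(sup)
    elif pattern == "inferior":
        pts = np.flatnonzero(inf)
    elif pattern == "diffuse":
        pts = np.arange(N_POINTS)
    else:
        raise ValueError(f"unknown defect pattern {pattern!r}")

    base = np.zeros((gx, gy))
    for pt in pts:
        wgt = rng.uniform(0.2, 1.0)
        rows, cols = np.divmod(mapping.regions[pt], gy)
        base[rows, cols] = np.maximum(base[rows, cols], wgt)

    md0 = compute_md(forward_truth(np.clip(base, 0, 1), mapping, norm), norm)
    if md0 >= 0.0:
        return damage, 0.0
    scale = target_md / md0
    damage = np.clip(scale * base, 0.0, 1.0)
    truth_md = compute_md(forward_truth(damage, mapping, norm), norm)
    return damage, truth_md


def _smooth_tilt(rng: np.random.Generator, shape: tuple[int, int], amp: int) -> np.ndarray:
    """Integer per-A-scan surface perturbation with (near-)zero median."""
    nx, ny = shape
    x = np.arange(nx)[:, None] / nx
    y = np.arange(ny)[None, :] / ny
    ph = rng.uniform(0, 2 * np.pi, size=4)
    f = (np.sin(2 * np.pi * x + ph[0]) + np.cos(2 * np.pi * y + ph[1])
         + 0.5 * np.sin(4 * np.pi * (x + y) + ph[2]))
    f = f / np.max(np.abs(f)) * amp
    s = np.rint(f).astype(int)
    return s - int(round(float(np.median(s))))


def _shift_columns(vol: np.ndarray, shifts: np.ndarray, fill: float) -> np.ndarray:
    """Shift each A-scan (x, y) axially by shifts[x, y]; fill vacated voxels."""
    nz = vol.shape[2]
    out = np.full_like(vol, fill)
    for s in np.unique(shifts):
        mask = shifts == s
        if s == 0:
            out[mask] = vol[mask]
        elif s > 0:
            out[mask, s:] = vol[mask, : nz - s]
        else:
            out[mask, :s] = vol[mask, -s:]
    return out


def _render_volume(rng: np.random.Generator, config: SyntheticCohortConfig,
                   damage: np.ndarray,
                   disc_center: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Raw right-eye-frame intensity volume + surface_z for one scan.

    Smooth bright background, a darker band whose intensity is reduced
    further in proportion to the planted damage (rendered inside the crop
    footprint, which is anchored at the disc center), a disc crater at the
    center, surface tilt, and additive white noise.
    """
    nx, ny, nz = config.raw_shape
    wx, wy, _ = config.crop_shape
    cx, cy = disc_center
    vol = np.full(config.raw_shape, config.background_intensity)

    # lateral damage map at raw resolution, anchored to the crop window
    lat_damage = np.zeros((nx, ny))
    bx = config.patch_vox[0] * config.factors[0]
    by = config.patch_vox[1] * config.factors[1]
    x0, y0 = cx - wx // 2, cy - wy // 2
    up = np.kron(damage, np.ones((bx, by)))
    lat_damage[x0:x0 + wx, y0:y0 + wy] = up

    plane = config.surface_plane
    z0, z1 = plane + config.band_offset_vox, plane + config.band_offset_vox + config.band_thickness_vox
    vol[:, :, z0:z1] = (config.band_intensity * (1.0 - lat_damage))[:, :, None]

    # disc crater
    xs = np.arange(nx)[:, None] - cx
    ys = np.arange(ny)[None, :] - cy
    crater = xs ** 2 + ys ** 2 <= config.crater_radius_vox ** 2
    vol[crater, z0:z1] = config.crater_intensity

    # surface tilt: move columns so the reference surface is plane + s
    s = _smooth_tilt(rng, (nx, ny), config.surface_tilt_vox)
    vol = _shift_columns(vol, s, fill=config.background_intensity)
    surface_z = plane + s.astype(float)

    vol = vol + rng.normal(0.0, config.noise_sd_vol, size=config.raw_shape)
    return vol, surface_z


def _severity_draw(rng, mix) -> str:
    names = [n for n, _ in mix]
    probs = np.array([p for _, p in mix])
    return str(rng.choice(names, p=probs))


def _generate_eye(k: int, config: SyntheticCohortConfig, mapping: PlantedMapping,
                  norm: NormativeProfile) -> SyntheticEye:
    rng = np.random.default_rng([config.seed, k])
    eye_id = f"eye{k:04d}"
    laterality = "left" if rng.random() < config.left_eye_fraction else "right"
    severity = _severity_draw(rng, config.severity_mix)
    pattern = _severity_draw(rng, config.defect_pattern_mix)
    md_ranges = dict(config.severity_md_ranges)
    target_md = float(rng.uniform(*md_ranges[severity]))
    damage, truth_md = _damage_field(rng, config, mapping, norm, pattern, target_md)

    # visit schedule and scan date
    n_visits = int(rng.integers(config.visits_min, config.visits_max + 1))
    t0 = float(rng.integers(0, 61))
    gaps = config.visit_interval_days + rng.uniform(
        -config.interval_jitter_days, config.interval_jitter_days, size=max(n_visits - 1, 0))
    dates = np.concatenate([[t0], t0 + np.cumsum(gaps)]) if n_visits > 1 else np.array([t0])
    scan_date = float(dates[n_visits // 2] + rng.integers(-30, 31))

    base = forward_truth(damage, mapping, norm)  # noiseless, at scan date
    slope = -config.progression_db_per_year * np.array(
        [mapping.mean_damage(damage, pt) for pt in range(N_POINTS)])

    vf_series = []
    for d in dates:
        sens = base + slope * (d - scan_date) / 365.25
        sens = sens + rng.normal(0.0, config.noise_sd_vf, size=N_POINTS)
        sens = np.clip(sens, 0.0, config.sensitivity_ceiling_db)
        vf_series.append(VFTest(
            eye_id=eye_id, laterality="right", test_date=float(d),
            sensitivities=sens, md=compute_md(sens, norm),
            fixation_loss=float(rng.uniform(0, 0.32)),
            false_pos=float(rng.uniform(0, 0.14)),
            false_neg=float(rng.uniform(0, 0.14)),
        ))

    nx, ny, _ = config.raw_shape
    j = config.disc_jitter_vox
    disc = (nx // 2 + int(rng.integers(-j, j + 1)),
            ny // 2 + int(rng.integers(-j, j + 1)))
    vol, surface_z = _render_volume(rng, config, damage, disc)
    scan = RawScan(intensity=vol, voxel_spacing_um=config.voxel_spacing_um,
                   laterality="right", disc_center_vox=disc, surface_z=surface_z,
                   eye_id=eye_id, scan_date=scan_date)

    if laterality == "left":
        # store the eye in its native (left) frame; truth stays right-frame
        perm = flip_permutation()
        for t in vf_series:
            t.sensitivities = t.sensitivities[perm]
            t.laterality = "left"
        scan.intensity = scan.intensity[::-1, :, :].copy()
        scan.surface_z = scan.surface_z[::-1, :].copy()
        scan.disc_center_vox = (nx - 1 - disc[0], disc[1])
        scan.laterality = "left"

    return SyntheticEye(eye_id=eye_id, laterality=laterality,
                        severity_class=severity, defect_pattern=pattern,
                        truth_damage=damage, truth_md=truth_md,
                        raw_scans=[scan], vf_series=vf_series)


def generate_cohort(config: SyntheticCohortConfig,
                    norm: NormativeProfile | None = None
                    ) -> tuple[list[SyntheticEye], PlantedMapping]:
    """Generate the cohort.  Deterministic given ``config.seed``."""
    norm = norm if norm is not None else default_normative()
    mapping = generate_mapping(config)
    eyes = [_generate_eye(k, config, mapping, norm) for k in range(config.n_eyes)]
    return eyes, mapping


def make_mirrored_cohort(config: SyntheticCohortConfig,
                         norm: NormativeProfile | None = None
                         ) -> tuple[list[SyntheticEye], PlantedMapping]:
    """Cohort whose inferior-defect eyes are exact mirrors of superior ones.

    Generates right-eye, superior-defect eyes and adds, for each, a twin
    mirrored about the horizontal meridian (volume, surface, disc annotation,
    damage field, and VF series all mirrored with the same noise
    realization).  Used for the exact mirror-symmetry property of the group
    t maps.
    """
    from dataclasses import replace as dc_replace
    base = dc_replace(config,
                      left_eye_fraction=0.0,
                      defect_pattern_mix=(("superior", 1.0), ("inferior", 0.0),
                                          ("diffuse", 0.0)))
    norm = norm if norm is not None else default_normative()
    eyes, mapping = generate_cohort(base, norm)
    perm = vertical_mirror_permutation()
    twins = []
    for eye in eyes:
        scan = eye.raw_scans[0]
        ny = scan.intensity.shape[1]
        cx, cy = scan.disc_center_vox
        tscan = RawScan(
            intensity=scan.intensity[:, ::-1, :].copy(),
            voxel_spacing_um=scan.voxel_spacing_um,
            laterality="right",
            # n - c (not n-1-c): mirrors the half-open crop window exactly
            disc_center_vox=(cx, ny - cy),
            surface_z=scan.surface_z[:, ::-1].copy(),
            eye_id=eye.eye_id + "m", scan_date=scan.scan_date,
        )
        tseries = []
        for t in eye.vf_series:
            tt = copy.copy(t)
            tt.eye_id = eye.eye_id + "m"
            tt.sensitivities = t.sensitivities[perm]
            tt.md = t.md
            tseries.append(tt)
        twins.append(SyntheticEye(
            eye_id=eye.eye_id + "m", laterality="right",
            severity_class=eye.severity_class, defect_pattern="inferior",
            truth_damage=eye.truth_damage[:, ::-1].copy(),
            truth_md=eye.truth_md, raw_scans=[tscan], vf_series=tseries))
    return eyes + twins, mapping


def pair_scans_vf(eyes: Sequence[SyntheticEye], window_days: float = 90.0,
                  mode: str = "training") -> list[tuple[RawScan, VFTest]]:
    """Associate scans with VF tests of the same eye within a day window.

    ``training`` mode pairs every scan with every VF test within the window
    (inclusive); ``test`` mode enforces a unique 1:1 association by greedily
    matching closest-in-time first.
    """
    if mode not in ("training", "test"):
        raise ValueError(f"unknown pairing mode {mode!r}")
    pairs = []
    for eye in eyes:
        cands = [(abs(s.scan_date - t.test_date), si, ti)
                 for si, s in enumerate(eye.raw_scans)
                 for ti, t in enumerate(eye.vf_series)
                 if abs(s.scan_date - t.test_date) <= window_days]
        if mode == "training":
            pairs.extend((eye.raw_scans[si], eye.vf_series[ti])
                         for _, si, ti in sorted(cands, key=lambda c: (c[1], c[2])))
        else:
            used_s, used_t = set(), set()
            for _, si, ti in sorted(cands):
                if si in used_s or ti in used_t:
                    continue
                used_s.add(si)
                used_t.add(ti)
                pairs.append((eye.raw_scans[si], eye.vf_series[ti]))
    return pairs


class OracleRegressor:
    """Noise-free surrogate model that inverts the generative rule exactly.

    Reads the planted damage off a processed volume (band-depth mean
    intensity per en-face patch) and applies the forward structure-function
    rule.  Substituting it for the trained network makes occlusion saliency
    depend *only* on a point's planted regions, which is the exact locality
    surface the recovery tests check.
    """

    def __init__(self, mapping: PlantedMapping, norm: NormativeProfile,
                 config: SyntheticCohortConfig):
        self.mapping = mapping
        self.norm = norm
        self.band_intensity = config.band_intensity
        self.band_z = config.processed_band_z()
        self.patch_lateral = (config.patch_vox[0], config.patch_vox[1])
        self.input_shape = config.processed_shape

    def estimate_damage(self, vol: np.ndarray) -> np.ndarray:
        px, py = self.patch_lateral
        z0, z1 = self.band_z
        gx, gy = self.mapping.grid_shape
        band = vol[:, :, z0:z1]
        block = band.reshape(gx, px, gy, py, z1 - z0).mean(axis=(1, 3, 4))
        return np.clip(1.0 - block / self.band_intensity, 0.0, 1.0)

    def predict(self, volume) -> np.ndarray:
        vol = volume.intensity if hasattr(volume, "intensity") else np.asarray(volume)
        if vol.shape != self.input_shape:
            raise ValueError(f"volume shape {vol.shape} != expected {self.input_shape}")
        d = self.estimate_damage(vol)
        return forward_truth(d, self.mapping, self.norm)

    def predict_many(self, volumes: np.ndarray) -> np.ndarray:
        return np.stack([self.predict(v) for v in np.asarray(volumes)])
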