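"""End-to-end orchestration: simulate -> preprocess -> train -> occlude -> map -> score.

Two layers live here.  The in-memory experiment API (``preprocess_cohort``,
``build_pairs``, ``enface_saliency_stack``, ``run_study``) is what tests,
examples and the acceptance harness drive; it never touches disk.
``run_pipeline`` wraps the same stages with file I/O (NIfTI volumes, CSV VF
tables, JSON ground truth, .npy arrays), a checksummed manifest, and
per-stage resume: a stage is skipped when all of its recorded outputs are
present with matching checksums and no earlier stage was re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .group_mapping import (
    GroupSpec,
    GroupTMap,
    group_t_maps,
    mapping_recovery_score,
    register_maps,
    split_groups,
)
from .occlusion import OcclusionSpec, enface_project, patch_grid_shape, saliency_stack
from .preprocess import ProcessedVolume, central_crop, downsample, flatten, temporal_smooth
from .regressor import RegressorConfig, TrainedRegressor, mean_baseline_mae, train
from .synthetic_cohort import (
    OracleRegressor,
    PlantedMapping,
    SyntheticCohortConfig,
    SyntheticEye,
    generate_cohort,
)
from .vf_grid import (
    NormativeProfile,
    VFTest,
    default_normative,
    flip_to_right_eye,
    is_reliable,
    reliability_weights,
    vf_tests_from_csv,
    vf_tests_to_csv,
)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "desk_config",
    "paper_config",
    "validate_config",
    "run_pipeline",
    "preprocess_cohort",
    "build_pairs",
    "enface_saliency_stack",
    "run_study",
    "StudyResult",
]

#: Printed clinical-scale settings, kept verbatim in the "paper" profile.
PAPER_CONSTANTS = {
    "epochs": 200,
    "batch_size": 16,
    "lr_init": 2e-4,
    "lr_decay_factor": 0.1,
    "lr_decay_every": 100,
    "crop_shape": (144, 144, 576),
    "factors": (2, 2, 4),
    "processed_shape": (72, 72, 144),
    "patch_vox": (4, 4, 4),
    "lam": 0.75,
    "alpha": 0.05,
    "md_cutoff": -6.0,
    "healthy_cutoff": -1.0,
    "pairing_window_days": 90.0,
    "smoothing_window": 5,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Aggregated configuration of all stages."""

    profile: str = "desk"
    seed: int = 0
    output_dir: str = "sfmap_run"
    pairing_window_days: float = 90.0
    smoothing_window: int = 5
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    regressor: RegressorConfig = field(default_factory=RegressorConfig)
    occlusion: OcclusionSpec = field(default_factory=OcclusionSpec)
    group: GroupSpec = field(default_factory=GroupSpec)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def desk_config(seed: int = 0, output_dir: str = "sfmap_run",
                n_eyes: int = 60, epochs: int = 150) -> PipelineConfig:
    """Desk-scale profile: completes on one CPU in minutes."""
    return PipelineConfig(
        profile="desk", seed=seed, output_dir=output_dir,
        cohort=dataclasses.replace(SyntheticCohortConfig(), n_eyes=n_eyes, seed=seed),
        regressor=dataclasses.replace(RegressorConfig(), epochs=epochs, seed=seed),
    )


def paper_config(seed: int = 0, output_dir: str = "sfmap_run") -> PipelineConfig:
    """Clinical-scale profile recording the printed settings verbatim.

    The synthetic generator still stands in for the (private) clinical data,
    but all geometry and training constants match the published analysis.
    """
    c = PAPER_CONSTANTS
    return PipelineConfig(
        profile="paper", seed=seed, output_dir=output_dir,
        pairing_window_days=c["pairing_window_days"],
        smoothing_window=c["smoothing_window"],
        cohort=dataclasses.replace(
            SyntheticCohortConfig(), seed=seed,
            raw_shape=(208, 208, 640), crop_shape=c["crop_shape"],
            factors=c["factors"], patch_vox=c["patch_vox"],
            band_offset_vox=48, band_thickness_vox=96,
            crater_radius_vox=18, disc_jitter_vox=12, surface_tilt_vox=8,
        ),
        regressor=RegressorConfig(
            pool_vox=c["patch_vox"], epochs=c["epochs"], batch_size=c["batch_size"],
            lr_init=c["lr_init"], lr_decay_factor=c["lr_decay_factor"],
            lr_decay_every=c["lr_decay_every"], seed=seed,
        ),
        occlusion=OcclusionSpec(patch_vox=c["patch_vox"]),
        group=GroupSpec(md_cutoff=c["md_cutoff"], healthy_cutoff=c["healthy_cutoff"],
                        lam=c["lam"], alpha=c["alpha"]),
    )


@dataclass
class ValidationReport:
    checks: list  # (name, ok, detail)

    @property
    def ok(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list:
        return [c for c in self.checks if not c[1]]


def validate_config(config: PipelineConfig) -> ValidationReport:
    """Static divisibility / ordering / constant checks; never raises."""
    checks = []
    ch = config.cohort

    div_cf = all(c % f == 0 for c, f in zip(ch.crop_shape, ch.factors))
    checks.append(("crop_divisible_by_factors", div_cf,
                   f"{ch.crop_shape} / {ch.factors}"))
    proc = tuple(c // f for c, f in zip(ch.crop_shape, ch.factors))
    patch = config.occlusion.patch_vox
    div_vp = all(p % q == 0 for p, q in zip(proc, patch))
    grid = tuple(p // q for p, q in zip(proc, patch)) if div_vp else None
    checks.append(("volume_divisible_by_patch", div_vp,
                   f"processed {proc}, patch {patch}, patch grid {grid}"))
    checks.append(("cutoff_ordering", config.group.healthy_cutoff > config.group.md_cutoff,
                   f"healthy {config.group.healthy_cutoff} > severity {config.group.md_cutoff}"))
    for name, mix in (("severity_mix", ch.severity_mix),
                      ("defect_pattern_mix", ch.defect_pattern_mix)):
        s = sum(p for _, p in mix)
        checks.append((f"{name}_sums_to_1", abs(s - 1.0) < 1e-9, f"sum {s}"))
    checks.append(("lr_positive", config.regressor.lr_init > 0,
                   f"lr_init {config.regressor.lr_init}"))

    if config.profile == "paper":
        c = PAPER_CONSTANTS
        r = config.regressor
        paper_ok = (
            r.epochs == c["epochs"] and r.batch_size == c["batch_size"]
            and r.lr_init == c["lr_init"] and r.lr_decay_factor == c["lr_decay_factor"]
            and r.lr_decay_every == c["lr_decay_every"]
            and tuple(ch.crop_shape) == c["crop_shape"]
            and tuple(ch.factors) == c["factors"]
            and proc == c["processed_shape"]
            and tuple(patch) == c["patch_vox"]
            and config.group.lam == c["lam"] and config.group.alpha == c["alpha"]
            and config.group.md_cutoff == c["md_cutoff"]
            and config.group.healthy_cutoff == c["healthy_cutoff"]
            and config.pairing_window_days == c["pairing_window_days"]
            and config.smoothing_window == c["smoothing_window"]
        )
        checks.append(("paper_profile_constants", paper_ok,
                       f"patch grid {grid}"))
    return ValidationReport(checks=checks)


# ---------------------------------------------------------------------------
# In-memory experiment API


def preprocess_volume(scan, config: SyntheticCohortConfig) -> ProcessedVolume:
    """Right-eye flip, flatten, central crop, antialiased downsample."""
    s = flip_to_right_eye(scan)
    s = flatten(s)
    s = central_crop(s, config.crop_shape)
    return downsample(s, config.factors)


def preprocess_cohort(eyes: Sequence[SyntheticEye], config: SyntheticCohortConfig,
                      norm: NormativeProfile, smoothing_window: int = 5):
    """Per-eye processed volumes and smoothed right-eye VF series."""
    volumes: dict = {}
    series: dict = {}
    for eye in eyes:
        volumes[eye.eye_id] = [preprocess_volume(s, config) for s in eye.raw_scans]
        tests = sorted((flip_to_right_eye(t) for t in eye.vf_series),
                       key=lambda t: t.test_date)
        tests = [t for t in tests if is_reliable(t)]
        series[eye.eye_id] = temporal_smooth(tests, window=smoothing_window, norm=norm)
    return volumes, series


def build_pairs(volumes: dict, series: dict, window_days: float = 90.0,
                mode: str = "training") -> list[tuple[ProcessedVolume, VFTest]]:
    """Pair processed volumes with VF tests of the same eye within a window."""
    pairs = []
    for eye_id in sorted(volumes):
        scans, tests = volumes[eye_id], series.get(eye_id, [])
        cands = [(abs(s.scan_date - t.test_date), si, ti)
                 for si, s in enumerate(scans) for ti, t in enumerate(tests)
                 if abs(s.scan_date - t.test_date) <= window_days]
        if mode == "training":
            pairs.extend((scans[si], tests[ti])
                         for _, si, ti in sorted(cands, key=lambda c: (c[1], c[2])))
        else:
            used_s, used_t = set(), set()
            for _, si, ti in sorted(cands):
                if si not in used_s and ti not in used_t:
                    used_s.add(si)
                    used_t.add(ti)
                    pairs.append((scans[si], tests[ti]))
    return pairs


def enface_saliency_stack(model, pairs, spec: OcclusionSpec,
                          batch_size: int = 64) -> np.ndarray:
    """(n_pairs, 52, gx, gy) en-face saliency for test-mode pairs."""
    maps = []
    for vol, _ in pairs:
        sal = saliency_stack(model, vol, spec, batch_size=batch_size)
        maps.append(enface_project(sal))
    return np.stack(maps)


@dataclass
class StudyResult:
    """Everything the group analysis produced for one synthetic study."""

    config: PipelineConfig
    mapping: PlantedMapping
    eyes: list
    model: object
    weights: object
    test_pairs: list
    enface: np.ndarray  # (n_pairs, 52, gx, gy), registered
    group_a: list  # indices into test_pairs
    group_b: list
    tmap_a: GroupTMap | None
    tmap_b: GroupTMap | None
    val_mae: float | None
    baseline_mae: float | None


def run_study(config: PipelineConfig, model: str = "trained",
              rng: np.random.Generator | None = None) -> StudyResult:
    """Run the full analysis in memory on a synthetic cohort.

    ``model`` selects the trained regressor or the generative-rule oracle
    (used for exact locality/symmetry properties).
    """
    norm = default_normative()
    eyes, mapping = generate_cohort(config.cohort, norm)
    return run_study_on(eyes, mapping, config, model=model, norm=norm, rng=rng)


def run_study_on(eyes, mapping, config: PipelineConfig, model: str = "trained",
                 norm: NormativeProfile | None = None,
                 rng: np.random.Generator | None = None) -> StudyResult:
    """As run_study, for an externally built cohort (e.g. mirrored twins)."""
    norm = norm if norm is not None else default_normative()
    volumes, series = preprocess_cohort(eyes, config.cohort, norm,
                                        config.smoothing_window)
    all_tests = [t for s in series.values() for t in s]
    weights = reliability_weights(all_tests, config.group.healthy_cutoff)

    val_mae = baseline = None
    if model == "trained":
        train_pairs = build_pairs(volumes, series, config.pairing_window_days,
                                  mode="training")
        reg = train(train_pairs, config.regressor, weights)
        log = reg.training_log[-1]
        val_mae = log.get("val_mae")
        tr_targets = np.stack([t.sensitivities for _, t in train_pairs])
        if val_mae is not None:
            val_eyes = _val_eyes(train_pairs, config.regressor)
            va_targets = np.stack([t.sensitivities for v, t in train_pairs
                                   if v.eye_id in val_eyes])
            tr_only = np.stack([t.sensitivities for v, t in train_pairs
                                if v.eye_id not in val_eyes])
            baseline = mean_baseline_mae(tr_only, va_targets)
    elif model == "oracle":
        reg = OracleRegressor(mapping, norm, config.cohort)
    else:
        raise ValueError(f"unknown model {model!r}")

    test_pairs = build_pairs(volumes, series, config.pairing_window_days, mode="test")
    enface = enface_saliency_stack(reg, test_pairs, config.occlusion)
    patch_lat = (config.occlusion.patch_vox[0], config.occlusion.patch_vox[1])
    centers = [v.disc_center_vox for v, _ in test_pairs]
    registered = np.stack(register_maps(list(enface), centers, patch_lat))

    items = [(registered[i], t, i) for i, (_, t) in enumerate(test_pairs)]
    ga, gb = split_groups(items, config.group, rng=rng)
    tmap_a = group_t_maps(np.stack([m for m, _, _ in ga]), config.group) if len(ga) >= 2 else None
    tmap_b = group_t_maps(np.stack([m for m, _, _ in gb]), config.group) if len(gb) >= 2 else None

    return StudyResult(config=config, mapping=mapping, eyes=list(eyes), model=reg,
                       weights=weights, test_pairs=test_pairs, enface=registered,
                       group_a=[i for _, _, i in ga], group_b=[i for _, _, i in gb],
                       tmap_a=tmap_a, tmap_b=tmap_b,
                       val_mae=val_mae, baseline_mae=baseline)


def _val_eyes(pairs, reg_config: RegressorConfig) -> set:
    """Replicate the by-eye validation split used inside train()."""
    rng = np.random.default_rng(reg_config.seed)
    eyes = sorted({v.eye_id for v, _ in pairs})
    perm = rng.permutation(len(eyes))
    n_val = int(round(reg_config.val_fraction * len(eyes)))
    return {eyes[i] for i in perm[:n_val]} if n_val else set()


# ---------------------------------------------------------------------------
# File-based pipeline with manifest + resume


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # name -> {files, elapsed_s}

    def record(self, stage: str, files: Sequence[Path], elapsed: float, root: Path) -> None:
        self.stages[stage] = {
            "files": {str(f.relative_to(root)): _sha256(f) for f in files},
            "elapsed_s": elapsed,
        }

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(config=d["config"], seed=d["seed"], version=d["version"],
                   stages=d["stages"])


_STAGES = ("simulate", "preprocess", "train", "occlude", "map", "score")


def _stage_clean(manifest: RunManifest | None, stage: str, root: Path) -> bool:
    if manifest is None or stage not in manifest.stages:
        return False
    rec = manifest.stages[stage]
    for rel, digest in rec["files"].items():
        p = root / rel
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages with file outputs, checksummed manifest and resume."""
    import nibabel as nib

    root = Path(config.output_dir)
    root.mkdir(parents=True, exist_ok=True)
    probe = root / ".write_probe"
    try:
        probe.write_text("ok")
        probe.unlink()
    except OSError as e:
        raise PermissionError(f"output_dir {root} is not writable: {e}") from e

    report = validate_config(config)
    if not report.ok:
        raise ValueError(f"invalid config: {report.failures()}")

    with open(root / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, default_flow_style=None)

    manifest_path = root / "manifest.json"
    old = RunManifest.load(manifest_path) if manifest_path.exists() else None
    manifest = RunManifest(config=config.to_dict(), seed=config.seed,
                           version=__version__)

    norm = default_normative()
    state: dict = {"norm": norm}
    dirty = False
    for stage in _STAGES:
        if not dirty and _stage_clean(old, stage, root):
            manifest.stages[stage] = old.stages[stage]
            _load_stage_state(stage, root, config, state)
            continue
        dirty = True
        t0 = time.perf_counter()
        files = _run_stage(stage, root, config, state, nib)
        manifest.record(stage, files, time.perf_counter() - t0, root)
        manifest.save(manifest_path)
    manifest.save(manifest_path)
    return manifest


def _vol_path(root: Path, stage: str, eye_id: str, idx: int) -> Path:
    return root / stage / "volumes" / f"{eye_id}_scan{idx}.nii"


def _save_nii(nib, path: Path, data: np.ndarray, spacing,
              dtype=np.float32) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def _run_stage(stage: str, root: Path, config: PipelineConfig, state: dict, nib):
    norm = state["norm"]
    files: list[Path] = []

    if stage == "simulate":
        eyes, mapping = generate_cohort(config.cohort, norm)
        state["eyes"], state["mapping"] = eyes, mapping
        d = root / "simulate"
        d.mkdir(parents=True, exist_ok=True)
        for eye in eyes:
            for i, s in enumerate(eye.raw_scans):
                p = _vol_path(root, "simulate", eye.eye_id, i)
                _save_nii(nib, p, s.intensity, s.voxel_spacing_um)
                files.append(p)
        vf_path = d / "vf.csv"
        vf_tests_to_csv([t for e in eyes for t in e.vf_series], vf_path)
        files.append(vf_path)
        meta = {
            "mapping": mapping.to_json(),
            "eyes": [{"eye_id": e.eye_id, "laterality": e.laterality,
                      "severity": e.severity_class, "pattern": e.defect_pattern,
                      "truth_md": e.truth_md,
                      "damage": e.truth_damage.tolist(),
                      "scan_dates": [s.scan_date for s in e.raw_scans],
                      "disc_centers": [list(s.disc_center_vox) for s in e.raw_scans]}
                     for e in eyes],
        }
        with open(d / "truth.json", "w") as fh:
            json.dump(meta, fh)
        files.append(d / "truth.json")
        return files

    if stage == "preprocess":
        eyes = state["eyes"]
        volumes, series = preprocess_cohort(eyes, config.cohort, norm,
                                            config.smoothing_window)
        state["volumes"], state["series"] = volumes, series
        d = root / "preprocess"
        d.mkdir(parents=True, exist_ok=True)
        for eye_id, vols in volumes.items():
            for i, v in enumerate(vols):
                p = _vol_path(root, "preprocess", eye_id, i)
                # full precision: later stages reload these on resume, and a
                # resumed run must train/occlude bit-identically to a fresh one
                _save_nii(nib, p, v.intensity, v.voxel_spacing_um,
                          dtype=np.float64)
                files.append(p)
        vf_path = d / "vf_smoothed.csv"
        vf_tests_to_csv([t for s in series.values() for t in s], vf_path)
        files.append(vf_path)
        meta = {eye_id: {"disc_centers": [list(v.disc_center_vox) for v in vols],
                         "scan_dates": [v.scan_date for v in vols]}
                for eye_id, vols in volumes.items()}
        with open(d / "meta.json", "w") as fh:
            json.dump(meta, fh)
        files.append(d / "meta.json")
        return files

    if stage == "train":
        volumes, series = state["volumes"], state["series"]
        weights = reliability_weights([t for s in series.values() for t in s],
                                      config.group.healthy_cutoff)
        pairs = build_pairs(volumes, series, config.pairing_window_days, "training")
        model = train(pairs, config.regressor, weights)
        state["model"], state["weights"] = model, weights
        d = root / "train"
        d.mkdir(parents=True, exist_ok=True)
        files += _save_model(d, model, weights)
        log_path = d / "log.csv"
        pd.DataFrame(model.training_log).to_csv(log_path, index=False)
        files.append(log_path)
        return files

    if stage == "occlude":
        volumes, series = state["volumes"], state["series"]
        model = state["model"]
        pairs = build_pairs(volumes, series, config.pairing_window_days, "test")
        enface = enface_saliency_stack(model, pairs, config.occlusion)
        state["test_pairs"], state["enface"] = pairs, enface
        d = root / "occlude"
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "enface.npy", enface)
        files.append(d / "enface.npy")
        index = [{"eye_id": v.eye_id, "scan_date": v.scan_date, "md": t.md,
                  "disc_center": list(v.disc_center_vox)} for v, t in pairs]
        with open(d / "index.json", "w") as fh:
            json.dump(index, fh)
        files.append(d / "index.json")
        return files

    if stage == "map":
        pairs, enface = state["test_pairs"], state["enface"]
        patch_lat = config.occlusion.patch_vox[:2]
        centers = [v.disc_center_vox for v, _ in pairs]
        registered = np.stack(register_maps(list(enface), centers, patch_lat))
        items = [(registered[i], t, i) for i, (_, t) in enumerate(pairs)]
        rng = np.random.default_rng([config.seed, 777])
        ga, gb = split_groups(items, config.group, rng=rng)
        out = {}
        for name, grp in (("healthy_to_early", ga), ("moderate_advanced", gb)):
            if len(grp) >= 2:
                out[name] = group_t_maps(np.stack([m for m, _, _ in grp]), config.group)
        state["tmaps"] = out
        d = root / "map"
        d.mkdir(parents=True, exist_ok=True)
        rows = []
        for name, tm in out.items():
            np.save(d / f"tmap_{name}.npy", tm.t)
            files.append(d / f"tmap_{name}.npy")
            gx, gy = tm.t.shape[1:]
            for pt in range(tm.t.shape[0]):
                for a in range(gx):
                    for b in range(gy):
                        if tm.t[pt, a, b] != 0:
                            rows.append((name, pt, a, b, tm.t[pt, a, b],
                                         tm.p[pt, a, b], int(tm.n[pt, a, b])))
        csv_path = d / "tmaps.csv"
        pd.DataFrame(rows, columns=["group", "pt", "row", "col", "t", "p", "n"]
                     ).to_csv(csv_path, index=False)
        files.append(csv_path)
        return files

    if stage == "score":
        mapping = state["mapping"]
        d = root / "score"
        d.mkdir(parents=True, exist_ok=True)
        result = {}
        for name, tm in state.get("tmaps", {}).items():
            sc = mapping_recovery_score(tm, mapping)
            result[name] = {
                "mean_precision": sc.mean_precision,
                "mean_recall": sc.mean_recall,
                "mean_topm_hit_rate": sc.mean_topm_hit_rate,
                "mean_hemifield_inversion": sc.mean_hemifield_inversion,
            }
        with open(d / "recovery.json", "w") as fh:
            json.dump(result, fh, indent=2)
        files.append(d / "recovery.json")
        return files

    raise ValueError(f"unknown stage {stage!r}")


def _save_model(d: Path, model: TrainedRegressor, weights) -> list[Path]:
    files = []
    for i, (W, b) in enumerate(model.params):
        np.save(d / f"W{i}.npy", W)
        np.save(d / f"b{i}.npy", b)
        files += [d / f"W{i}.npy", d / f"b{i}.npy"]
    for name, arr in (("feat_mean", model.feat_mean), ("feat_std", model.feat_std),
                      ("target_mean", model.target_mean), ("loss_w", weights.w)):
        np.save(d / f"{name}.npy", arr)
        files.append(d / f"{name}.npy")
    meta = {"pool_vox": list(model.pool_vox),
            "input_shape": list(model.input_shape),
            "n_layers": len(model.params),
            "weights_checksum": model.weights_checksum,
            "config": dataclasses.asdict(model.config)}
    with open(d / "model.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    files.append(d / "model.json")
    return files


def _load_model(d: Path) -> TrainedRegressor:
    with open(d / "model.json") as fh:
        meta = json.load(fh)
    params = [(np.load(d / f"W{i}.npy"), np.load(d / f"b{i}.npy"))
              for i in range(meta["n_layers"])]
    cfg = meta["config"]
    for key in ("pool_vox", "hidden"):
        cfg[key] = tuple(cfg[key])
    return TrainedRegressor(
        params=params, feat_mean=np.load(d / "feat_mean.npy"),
        feat_std=np.load(d / "feat_std.npy"),
        target_mean=np.load(d / "target_mean.npy"),
        pool_vox=tuple(meta["pool_vox"]), input_shape=tuple(meta["input_shape"]),
        config=RegressorConfig(**cfg))


def _load_stage_state(stage: str, root: Path, config: PipelineConfig, state: dict) -> None:
    """Rehydrate in-memory state for a skipped (already-clean) stage."""
    import nibabel as nib

    norm = state["norm"]
    if stage == "simulate":
        # regeneration is deterministic and cheaper than re-reading volumes
        eyes, mapping = generate_cohort(config.cohort, norm)
        state["eyes"], state["mapping"] = eyes, mapping
    elif stage == "preprocess":
        d = root / "preprocess"
        with open(d / "meta.json") as fh:
            meta = json.load(fh)
        tests = vf_tests_from_csv(d / "vf_smoothed.csv")
        series: dict = {}
        for t in tests:
            series.setdefault(t.eye_id, []).append(t)
        for s in series.values():
            s.sort(key=lambda t: t.test_date)
        volumes: dict = {}
        spacing = tuple(s * f for s, f in zip(config.cohort.voxel_spacing_um,
                                              config.cohort.factors))
        for eye_id, info in meta.items():
            vols = []
            for i, (center, date) in enumerate(zip(info["disc_centers"],
                                                   info["scan_dates"])):
                img = nib.load(str(_vol_path(root, "preprocess", eye_id, i)))
                # C order: NIfTI data is Fortran-ordered, and feature pooling
                # must sum in the same order as on the freshly computed volume
                vols.append(ProcessedVolume(
                    intensity=np.ascontiguousarray(
                        np.asarray(img.dataobj, dtype=float)),
                    voxel_spacing_um=spacing, disc_center_vox=tuple(center),
                    eye_id=eye_id, scan_date=float(date)))
            volumes[eye_id] = vols
        state["volumes"], state["series"] = volumes, series
    elif stage == "train":
        state["model"] = _load_model(root / "train")
    elif stage == "occlude":
        state["enface"] = np.load(root / "occlude" / "enface.npy")
        volumes, series = state["volumes"], state["series"]
        state["test_pairs"] = build_pairs(volumes, series,
                                          config.pairing_window_days, "test")
    elif stage == "map":
        d = root / "map"
        tmaps = {}
        for name in ("healthy_to_early", "moderate_advanced"):
            p = d / f"tmap_{name}.npy"
            if p.exists():
                t = np.load(p)
                tmaps[name] = GroupTMap(t=t, p=np.full_like(t, np.nan),
                                        n=np.zeros_like(t, dtype=int),
                                        mu=np.zeros(t.shape[0]),
                                        sbar_all=np.zeros(t.shape[0]),
                                        sigma_all=np.zeros(t.shape[0]),
                                        spec=config.group)
        state["tmaps"] = tmaps
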