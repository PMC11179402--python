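"""24-2 visual-field grid geometry, laterality handling, MD, and reliability weights.

The 24-2 standard automated perimetry pattern tests 54 locations at 6 degree
spacing; two of them fall on the physiologic blind spot (15 degrees temporal,
+/-3 degrees vertically) and are excluded, leaving the 52 points the regressor
predicts.  All coordinates here follow the right-eye convention: positive x is
the temporal visual field, positive y the superior visual field.  Left-eye
tests and volumes are mirrored onto this frame before any analysis.
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VFPoint",
    "VFTest",
    "ReliabilityWeights",
    "NormativeProfile",
    "N_POINTS",
    "BLIND_SPOT_DEG",
    "build_grid",
    "grid_coords",
    "grid_to_csv",
    "hemifield_masks",
    "vertical_mirror_permutation",
    "flip_permutation",
    "flip_to_right_eye",
    "compute_md",
    "default_normative",
    "reliability_weights",
    "is_reliable",
    "vf_tests_to_csv",
    "vf_tests_from_csv",
    "vf_tests_to_json",
    "vf_tests_from_json",
]

N_POINTS = 52

#: Blind-spot locations excluded from the 24-2 grid (right-eye frame, degrees).
BLIND_SPOT_DEG = ((15, 3), (15, -3))

# Published 24-2 layout, right-eye frame.  Rows top (superior) to bottom; each
# row lists the tested x eccentricities.  The two nasal-step rows (y = +/-3)
# extend to 27 degrees nasally (negative x).  Versioned fixture table.
_GRID_ROWS: tuple[tuple[int, tuple[int, ...]], ...] = (
    (21, (-9, -3, 3, 9)),
    (15, (-15, -9, -3, 3, 9, 15)),
    (9, (-21, -15, -9, -3, 3, 9, 15, 21)),
    (3, (-27, -21, -15, -9, -3, 3, 9, 15, 21)),
    (-3, (-27, -21, -15, -9, -3, 3, 9, 15, 21)),
    (-9, (-21, -15, -9, -3, 3, 9, 15, 21)),
    (-15, (-15, -9, -3, 3, 9, 15)),
    (-21, (-9, -3, 3, 9)),
)


@dataclass(frozen=True)
class VFPoint:
    """One 24-2 test location in right-eye coordinates."""

    index: int
    x_deg: float
    y_deg: float

    @property
    def hemifield(self) -> str:
        return "superior" if self.y_deg > 0 else "inferior"


@dataclass
class VFTest:
    """One 24-2 examination: 52 sensitivities plus metadata.

    ``sensitivities`` are serialized in grid order: rows top-to-bottom, points
    left-to-right within each row, in the eye's own chart frame (left-eye
    tests use the mirrored chart until flipped to the right-eye frame).
    """

    eye_id: str
    laterality: str  # "right" | "left"
    test_date: float  # days since cohort epoch
    sensitivities: np.ndarray  # (52,) dB
    md: float  # mean deviation, dB
    fixation_loss: float = 0.0
    false_pos: float = 0.0
    false_neg: float = 0.0

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        if self.sensitivities.shape != (N_POINTS,):
            raise ValueError(
                f"expected {N_POINTS} sensitivities, got {self.sensitivities.shape}"
            )
        if self.laterality not in ("right", "left"):
            raise ValueError(f"unknown laterality {self.laterality!r}")


@dataclass(frozen=True)
class ReliabilityWeights:
    """Per-point loss weights: inverse pointwise SD among healthy eyes, max 1."""

    w: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        if self.w.shape != (N_POINTS,):
            raise ValueError("weights must have one entry per VF point")
        if not (np.all(self.w > 0) and np.all(self.w <= 1)):
            raise ValueError("weights must lie in (0, 1]")
        if not np.isclose(self.w.max(), 1.0, rtol=0, atol=0):
            raise ValueError("maximum weight must be exactly 1")


@dataclass(frozen=True)
class NormativeProfile:
    """Normative mean sensitivity per point (synthetic-cohort convention)."""

    mean_sens: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_sens", np.asarray(self.mean_sens, dtype=float))
        if self.mean_sens.shape != (N_POINTS,):
            raise ValueError("normative profile must have one entry per VF point")
        if not np.all(np.isfinite(self.mean_sens)):
            raise ValueError("normative profile must be finite")


def _layout(mirror_x: bool) -> list[tuple[float, float]]:
    """Grid coordinates in serialization order, optionally mirrored in x."""
    blind = set(BLIND_SPOT_DEG)
    pts: list[tuple[float, float]] = []
    for y, xs in _GRID_ROWS:
        row = [(-x if mirror_x else x) for x in xs]
        for x in sorted(row):
            # blind spot is defined in the eye's own chart frame
            probe = (-x, y) if mirror_x else (x, y)
            if probe in blind:
                continue
            pts.append((float(x), float(y)))
    return pts


def build_grid() -> list[VFPoint]:
    """Return the 52-point 24-2 grid (right-eye frame, blind spot excluded).

    Ordering is row-major: top row (y=+21) to bottom row (y=-21), left to
    right within a row.  The ordering is deterministic and is the
    serialization order of every 52-vector in this package.
    """
    return [VFPoint(i, x, y) for i, (x, y) in enumerate(_layout(mirror_x=False))]


def grid_coords() -> np.ndarray:
    """(52, 2) array of (x_deg, y_deg) in serialization order."""
    return np.array(_layout(mirror_x=False), dtype=float)


def grid_to_csv(path) -> None:
    """Write the grid fixture as CSV with columns index,x_deg,y_deg."""
    pts = build_grid()
    pd.DataFrame(
        {"index": [p.index for p in pts],
         "x_deg": [p.x_deg for p in pts],
         "y_deg": [p.y_deg for p in pts]}
    ).to_csv(path, index=False)


def hemifield_masks() -> tuple[np.ndarray, np.ndarray]:
    """(superior_mask, inferior_mask) boolean arrays over the 52 points."""
    y = grid_coords()[:, 1]
    return y > 0, y < 0


def vertical_mirror_permutation() -> np.ndarray:
    """Permutation p with point i at (x, y) mapping to p[i] at (x, -y).

    The 24-2 grid (including the blind-spot exclusions) is symmetric about the
    horizontal meridian, so this is a true permutation.
    """
    coords = grid_coords()
    lookup = {(x, y): i for i, (x, y) in enumerate(map(tuple, coords))}
    return np.array([lookup[(x, -y)] for x, y in coords], dtype=int)


def flip_permutation() -> np.ndarray:
    """Map left-eye serialization index -> right-eye grid index under x -> -x.

    A left-eye chart is the x-mirror of the right-eye chart (its blind spot
    sits at x = -15 in right-eye coordinates), so mirroring is a bijection
    between the two 52-point layouts.  Entry j of the returned array is the
    right-eye index receiving the left-eye chart's j-th sensitivity.
    """
    right = {(x, y): i for i, (x, y) in enumerate(map(tuple, grid_coords()))}
    left = _layout(mirror_x=True)
    return np.array([right[(-x, y)] for x, y in left], dtype=int)


def flip_to_right_eye(obj, laterality: str | None = None):
    """Mirror a VF test or a volume-like scan into the right-eye frame.

    Right-eye inputs are returned unchanged (same object).  Left-eye VF tests
    have their sensitivities re-indexed onto the right-eye grid; left-eye
    scans have their first lateral axis reversed with the disc-center
    annotation mirrored consistently.  Applying the operation twice restores
    the original serialization (involution).
    """
    lat = laterality if laterality is not None else getattr(obj, "laterality", None)
    if lat == "right":
        return obj
    if lat != "left":
        raise ValueError(f"unknown laterality {lat!r}")

    if hasattr(obj, "sensitivities"):
        perm = flip_permutation()
        out = np.empty(N_POINTS)
        out[perm] = obj.sensitivities
        return replace(obj, laterality="right", sensitivities=out)

    if hasattr(obj, "intensity"):
        out = copy.copy(obj)
        out.intensity = obj.intensity[::-1, :, :].copy()
        nx = obj.intensity.shape[0]
        cx, cy = obj.disc_center_vox
        out.disc_center_vox = (nx - 1 - cx, cy)
        if getattr(obj, "surface_z", None) is not None:
            out.surface_z = obj.surface_z[::-1, :].copy()
        out.laterality = "right"
        return out

    raise TypeError(f"cannot flip object of type {type(obj).__name__}")


def compute_md(sensitivities: np.ndarray, norm: NormativeProfile) -> float:
    """Mean deviation: unweighted mean of (sensitivity - normative mean).

    This is the synthetic-cohort convention; clinical perimeters apply a
    proprietary pointwise weighting.  The unweighted mean preserves severity
    ordering and the -1/-6 dB cutoffs, which is all the pipeline consumes.
    """
    s = np.asarray(sensitivities, dtype=float)
    if s.shape != (N_POINTS,):
        raise ValueError(f"expected {N_POINTS} sensitivities")
    if not np.all(np.isfinite(s)):
        raise ValueError("sensitivities must be finite")
    return float(np.mean(s - norm.mean_sens))


def default_normative() -> NormativeProfile:
    """Smooth eccentricity-dependent normative hill of vision (synthetic)."""
    coords = grid_coords()
    r = np.hypot(coords[:, 0], coords[:, 1])
    return NormativeProfile(mean_sens=33.0 - 0.15 * r)


def is_reliable(test: VFTest,
                fl_max: float = 0.33, fp_max: float = 0.15, fn_max: float = 0.15) -> bool:
    """Strict reliability gate: FL < 33%, FP < 15%, FN < 15%."""
    return (test.fixation_loss < fl_max
            and test.false_pos < fp_max
            and test.false_neg < fn_max)


def reliability_weights(healthy_tests: Sequence[VFTest],
                        healthy_md_cutoff: float = -1.0) -> ReliabilityWeights:
    """Pointwise loss weights from the healthy (MD > cutoff) sub-cohort.

    w_pt = (1/SD_pt) / max_q (1/SD_q), i.e. the inverse pointwise standard
    deviation of sensitivities among healthy tests, normalized so the most
    reliable point has weight exactly 1.
    """
    qual = [t for t in healthy_tests if t.md > healthy_md_cutoff]
    if len(qual) < 2:
        raise ValueError(
            f"need >=2 tests with MD > {healthy_md_cutoff} dB, got {len(qual)}"
        )
    sens = np.stack([t.sensitivities for t in qual])
    sd = sens.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate cohort: zero pointwise SD")
    inv = 1.0 / sd
    return ReliabilityWeights(w=inv / inv.max())


# ---------------------------------------------------------------------------
# VF test serialization (CSV / JSON)

_SENS_COLS = [f"s{i:02d}" for i in range(N_POINTS)]
_META_COLS = ["eye_id", "laterality", "date", "md", "fl", "fp", "fn"]


def _tests_to_frame(tests: Iterable[VFTest]) -> pd.DataFrame:
    rows = []
    for t in tests:
        row = dict(eye_id=t.eye_id, laterality=t.laterality, date=t.test_date,
                   md=t.md, fl=t.fixation_loss, fp=t.false_pos, fn=t.false_neg)
        row.update(zip(_SENS_COLS, t.sensitivities))
        rows.append(row)
    return pd.DataFrame(rows, columns=_META_COLS + _SENS_COLS)


def _frame_to_tests(df: pd.DataFrame) -> list[VFTest]:
    return [
        VFTest(eye_id=str(r.eye_id), laterality=str(r.laterality),
               test_date=float(r.date),
               sensitivities=np.array([getattr(r, c) for c in _SENS_COLS]),
               md=float(r.md), fixation_loss=float(r.fl),
               false_pos=float(r.fp), false_neg=float(r.fn))
        for r in df.itertuples(index=False)
    ]


def vf_tests_to_csv(tests: Iterable[VFTest], path) -> None:
    _tests_to_frame(tests).to_csv(path, index=False)


def vf_tests_from_csv(path) -> list[VFTest]:
    # round_trip parsing: written values must reload bit-identically
    return _frame_to_tests(pd.read_csv(path, float_precision="round_trip"))


def vf_tests_to_json(tests: Iterable[VFTest], path) -> None:
    records = _tests_to_frame(tests).to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(records, fh)


def vf_tests_from_json(path) -> list[VFTest]:
    with open(path) as fh:
        return _frame_to_tests(pd.DataFrame(json.load(fh)))
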