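"""Group-level analysis of en-face occlusion saliency.

Individual en-face saliency maps are registered by translating each map so
its optic-disc center falls on the common grid center, the cohort is split
by VF mean deviation at -6 dB, and for every VF point a one-sample t test is
run per en-face patch k against the shifted group mean

    mu_pt = Sbar_pt + lambda * sigma_pt          (lambda = 0.75)

where Sbar_pt, sigma_pt pool saliency over all patches and pairs of the
group for that point.  The group t-statistic map holds

    T_pt^k = (Sbar_pt^k - mu_pt) / (sigma_pt^k / sqrt(N))   if p <= alpha
             0                                              otherwise,

with a one-sided (upper-tail) p and no multiplicity correction by default,
both config-exposed.  Recovery scoring against a planted mapping and the
severity (saliency vs. MD) correlation live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .occlusion import SaliencyMap2D
from .synthetic_cohort import PlantedMapping
from .vf_grid import N_POINTS, NormativeProfile, VFTest, hemifield_masks

__all__ = [
    "GroupSpec",
    "GroupTMap",
    "SeverityCorrelation",
    "RecoveryScore",
    "register_maps",
    "split_groups",
    "group_t_maps",
    "severity_correlation",
    "select_hemifield_subgroup",
    "mapping_recovery_score",
    "plot_group_maps",
]


@dataclass(frozen=True)
class GroupSpec:
    """Thresholds and options of the group analysis."""

    md_cutoff: float = -6.0  # healthy-to-early vs moderate-to-advanced
    healthy_cutoff: float = -1.0  # reliability-weights cohort
    lam: float = 0.75
    alpha: float = 0.05
    one_sided: bool = True
    bh_correct: bool = False  # Benjamini-Hochberg across patches, off by default
    resample_one_per_eye: bool = False
    pool_over: str = "patches_and_pairs"  # or "patch_means"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class GroupTMap:
    """Per-point en-face t-statistic maps for one group."""

    t: np.ndarray  # (52, gx, gy), 0 where non-significant
    p: np.ndarray  # (52, gx, gy) one- or two-sided p-values (nan where n<2)
    n: np.ndarray  # (52, gx, gy) per-cell pair counts
    mu: np.ndarray  # (52,) hypothesis means
    sbar_all: np.ndarray  # (52,) pooled means
    sigma_all: np.ndarray  # (52,) pooled SDs
    spec: GroupSpec = field(default_factory=GroupSpec)


@dataclass
class SeverityCorrelation:
    """Per-point Pearson r between saliency magnitude and MD."""

    r: np.ndarray  # (52,), nan where undefined
    defined: np.ndarray  # (52,) bool
    n_pairs: int
    magnitude_rule: str = "mean"


def register_maps(maps: Sequence[SaliencyMap2D | np.ndarray],
                  disc_centers_vox: Sequence[tuple[float, float]],
                  patch_lateral: tuple[int, int] = (4, 4)):
    """Translate each en-face map so its disc center hits the grid center.

    ``disc_centers_vox`` are disc centers in processed-volume voxel
    coordinates; the shift is the nearest-integer patch offset.  Vacated
    cells are NaN (missing) and are excluded per cell from group statistics.
    A shift exceeding half the grid raises.
    """
    out = []
    for m, (cx, cy) in zip(maps, disc_centers_vox):
        values = m.values if isinstance(m, SaliencyMap2D) else np.asarray(m, dtype=float)
        gx, gy = values.shape[-2:]
        ox = int(round(cx / patch_lateral[0] - gx / 2.0))
        oy = int(round(cy / patch_lateral[1] - gy / 2.0))
        if abs(ox) > gx // 2 or abs(oy) > gy // 2:
            raise ValueError(f"registration shift ({ox},{oy}) exceeds half grid ({gx},{gy})")
        shifted = np.full_like(values, np.nan, dtype=float)
        src_x = slice(max(ox, 0), gx + min(ox, 0))
        dst_x = slice(max(-ox, 0), gx + min(-ox, 0))
        src_y = slice(max(oy, 0), gy + min(oy, 0))
        dst_y = slice(max(-oy, 0), gy + min(-oy, 0))
        shifted[..., dst_x, dst_y] = values[..., src_x, src_y]
        if isinstance(m, SaliencyMap2D):
            out.append(SaliencyMap2D(values=shifted, pt=m.pt, eye_id=m.eye_id,
                                     scan_date=m.scan_date,
                                     disc_center_vox=(gx / 2.0 * patch_lateral[0],
                                                      gy / 2.0 * patch_lateral[1])))
        else:
            out.append(shifted)
    return out


def split_groups(pairs: Sequence[tuple], spec: GroupSpec = GroupSpec(),
                 rng: np.random.Generator | None = None):
    """Split (maps, VFTest) pairs at the MD cutoff.

    Group A (healthy-to-early): MD > cutoff.  Group B
    (moderate-to-advanced): MD <= cutoff.  With ``resample_one_per_eye`` one
    random pair per eye is kept (seeded rng required), mirroring the
    within-subject-correlation robustness variant.
    """
    items = list(pairs)
    if spec.resample_one_per_eye:
        if rng is None:
            raise ValueError("resample_one_per_eye requires an rng")
        by_eye: dict = {}
        for item in items:
            by_eye.setdefault(item[1].eye_id, []).append(item)
        items = [grp[int(rng.integers(len(grp)))] for _, grp in sorted(by_eye.items())]
    group_a = [it for it in items if it[1].md > spec.md_cutoff]
    group_b = [it for it in items if it[1].md <= spec.md_cutoff]
    return group_a, group_b


def group_t_maps(maps: np.ndarray, spec: GroupSpec = GroupSpec()) -> GroupTMap:
    """One-sample t maps for one group from registered en-face maps.

    ``maps`` has shape (n_pairs, 52, gx, gy); NaN marks cells vacated by
    registration.  Per point pt, the hypothesis mean mu_pt pools saliency
    over all patches and pairs (or over per-pair patch means when
    ``spec.pool_over == "patch_means"``); per patch k the t statistic is
    (Sbar_pt^k - mu_pt) / (sigma_pt^k / sqrt(N_k)).  Cells with p > alpha,
    zero SD, or fewer than 2 pairs are set to 0.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4 or maps.shape[1] != N_POINTS:
        raise ValueError("maps must have shape (n_pairs, 52, gx, gy)")
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 pairs for a t test")

    if spec.pool_over == "patch_means":
        per_pair = np.nanmean(maps, axis=(2, 3))  # (n_pairs, 52)
        sbar_all = per_pair.mean(axis=0)
        sigma_all = per_pair.std(axis=0, ddof=1)
    else:
        pooled = maps.transpose(1, 0, 2, 3).reshape(N_POINTS, -1)
        sbar_all = np.nanmean(pooled, axis=1)
        sigma_all = np.nanstd(pooled, axis=1, ddof=1)
    mu = sbar_all + spec.lam * sigma_all

    valid = ~np.isnan(maps)
    n = valid.sum(axis=0)  # (52, gx, gy)
    filled = np.where(valid, maps, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_k = np.where(n > 0, filled.sum(axis=0) / n, np.nan)
        ss = np.where(valid, (maps - mean_k[None]) ** 2, 0.0).sum(axis=0)
        sd_k = np.where(n > 1, np.sqrt(ss / np.maximum(n - 1, 1)), np.nan)
        t = (mean_k - mu[:, None, None]) / (sd_k / np.sqrt(n))
    df = n - 1
    with np.errstate(invalid="ignore"):
        if spec.one_sided:
            p = stats.t.sf(t, np.maximum(df, 1))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    bad = (n < 2) | (sd_k == 0) | ~np.isfinite(t)
    p = np.where(bad, np.nan, p)

    signif = np.zeros_like(p, dtype=bool)
    if spec.bh_correct:
        for pt in range(N_POINTS):
            pv = p[pt].ravel()
            ok = np.isfinite(pv)
            if ok.any():
                signif[pt].ravel()[ok] = _bh_reject(pv[ok], spec.alpha)
        signif = signif.reshape(p.shape)
    else:
        signif = np.where(np.isfinite(p), p <= spec.alpha, False)

    t_out = np.where(signif & ~bad, t, 0.0)
    return GroupTMap(t=t_out, p=p, n=n, mu=mu, sbar_all=sbar_all,
                     sigma_all=sigma_all, spec=spec)


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    out = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.flatnonzero(passed))
        out[order[: k + 1]] = True
    return out


def severity_correlation(pairs: Sequence[tuple[np.ndarray, VFTest]],
                         magnitude_rule: str = "mean") -> SeverityCorrelation:
    """Pointwise Pearson r between per-pair saliency magnitude and VF MD.

    The default magnitude rule summarizes a point's en-face map by its mean
    over (non-missing) patches.  Constant saliency or constant MD yields an
    undefined flag, not r = 0.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    if magnitude_rule == "mean":
        mags = np.stack([np.nanmean(m, axis=(-2, -1)) for m, _ in pairs])  # (n, 52)
    elif magnitude_rule == "max":
        mags = np.stack([np.nanmax(m, axis=(-2, -1)) for m, _ in pairs])
    else:
        raise ValueError(f"unknown magnitude rule {magnitude_rule!r}")
    md = np.array([t.md for _, t in pairs])

    r = np.full(N_POINTS, np.nan)
    defined = np.zeros(N_POINTS, dtype=bool)
    md_var = md.std() > 0
    for pt in range(N_POINTS):
        x = mags[:, pt]
        if md_var and x.std() > 0 and np.all(np.isfinite(x)):
            r[pt] = np.corrcoef(x, md)[0, 1]
            defined[pt] = True
    return SeverityCorrelation(r=r, defined=defined, n_pairs=len(pairs),
                               magnitude_rule=magnitude_rule)


def select_hemifield_subgroup(pairs: Sequence[tuple], rule: str,
                              norm: NormativeProfile,
                              delta_db: float = 6.0) -> list:
    """Automated surrogate for manual superior/inferior defect selection.

    A pair is a superior-defect case when the superior hemifield's mean
    total deviation is at least ``delta_db`` lower (worse) than the inferior
    hemifield's, and symmetrically.  This replaces the manual chart review
    used clinically and is symmetric under vertical mirroring of the VF.
    """
    if rule not in ("superior_defect", "inferior_defect"):
        raise ValueError(f"unknown rule {rule!r}")
    sup, inf = hemifield_masks()
    out = []
    for item in pairs:
        t = item[1]
        td = t.sensitivities - norm.mean_sens
        sup_td, inf_td = td[sup].mean(), td[inf].mean()
        if rule == "superior_defect" and sup_td <= inf_td - delta_db:
            out.append(item)
        elif rule == "inferior_defect" and inf_td <= sup_td - delta_db:
            out.append(item)
    return out


@dataclass
class RecoveryScore:
    """Agreement between a (t or saliency) map stack and the planted truth."""

    precision: np.ndarray  # (52,), nan where no patch was flagged
    recall: np.ndarray  # (52,)
    topm_hit_rate: np.ndarray  # (52,)
    hemifield_inversion: np.ndarray  # (52,), nan where map is empty
    mean_precision: float
    mean_recall: float
    mean_topm_hit_rate: float
    mean_hemifield_inversion: float


def mapping_recovery_score(tmap: "GroupTMap | np.ndarray", truth: PlantedMapping,
                           threshold: float = 0.0) -> RecoveryScore:
    """Score per-point maps against the planted regions.

    Flagged patches are those with value > ``threshold`` (for a GroupTMap
    this is the significant set, since non-significant cells are zeroed).
    Per point: precision and recall of the flagged set, plus the top-m hit
    rate where m is the planted region size (ties broken by patch index).
    The hemifield-inversion score is the fraction of flagged mass lying in
    the retinal half opposite the point's VF hemifield.
    """
    values = tmap.t if isinstance(tmap, GroupTMap) else np.asarray(tmap, dtype=float)
    if values.shape != (N_POINTS,) + truth.grid_shape:
        raise ValueError(f"map shape {values.shape} does not match truth grid "
                         f"{(N_POINTS,) + truth.grid_shape}")
    gx, gy = truth.grid_shape
    sup, _ = hemifield_masks()
    prec = np.full(N_POINTS, np.nan)
    rec = np.zeros(N_POINTS)
    topm = np.zeros(N_POINTS)
    hemi = np.full(N_POINTS, np.nan)
    opp_inferior_retina = np.zeros((gx, gy), dtype=bool)
    opp_inferior_retina[:, gy - gy // 2:] = True  # inferior retinal half

    for pt in range(N_POINTS):
        v = np.nan_to_num(values[pt], nan=0.0)
        flat = v.ravel()
        truth_set = set(int(i) for i in truth.regions[pt])
        m = len(truth_set)
        pred = set(np.flatnonzero(flat > threshold).tolist())
        if pred:
            prec[pt] = len(pred & truth_set) / len(pred)
        rec[pt] = len(pred & truth_set) / m
        # top-m among cells that actually exceed the threshold: a map with
        # no supra-threshold cell makes no localization claim and scores 0
        order = [int(i) for i in np.argsort(-flat, kind="stable")[:m]
                 if flat[i] > threshold]
        topm[pt] = len(set(order) & truth_set) / m
        mass = np.abs(flat)
        total = mass.sum()
        if total > 0:
            opp = opp_inferior_retina if sup[pt] else ~opp_inferior_retina
            hemi[pt] = mass[opp.ravel()].sum() / total

    return RecoveryScore(
        precision=prec, recall=rec, topm_hit_rate=topm, hemifield_inversion=hemi,
        mean_precision=float(np.nanmean(prec)) if np.isfinite(prec).any() else float("nan"),
        mean_recall=float(rec.mean()),
        mean_topm_hit_rate=float(topm.mean()),
        mean_hemifield_inversion=(float(np.nanmean(hemi))
                                  if np.isfinite(hemi).any() else float("nan")),
    )


def plot_group_maps(tmap: GroupTMap, path, points: Sequence[int] | None = None) -> None:
    """Save a simple figure of per-point t maps arranged in a grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = list(points) if points is not None else list(range(N_POINTS))
    ncol = 8
    nrow = int(np.ceil(len(pts) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2 * ncol, 2 * nrow))
    vmax = max(float(np.abs(tmap.t).max()), 1e-9)
    for ax, pt in zip(np.atleast_1d(axes).ravel(), pts):
        ax.imshow(tmap.t[pt].T, origin="lower", cmap="magma", vmin=0, vmax=vmax)
        ax.set_title(f"pt {pt}", fontsize=7)
        ax.set_xticks([])
        ax.set_yticks([])
    for ax in np.atleast_1d(axes).ravel()[len(pts):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
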