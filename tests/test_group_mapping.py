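"""Registration, group split, t maps, severity correlation and scoring."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from sfmap.group_mapping import (
    GroupSpec,
    group_t_maps,
    mapping_recovery_score,
    register_maps,
    select_hemifield_subgroup,
    severity_correlation,
    split_groups,
)
from sfmap.synthetic_cohort import (
    PlantedMapping,
    SyntheticCohortConfig,
    generate_mapping,
)
from sfmap.vf_grid import (
    N_POINTS,
    VFTest,
    default_normative,
    grid_coords,
    hemifield_masks,
    vertical_mirror_permutation,
)


def _test(md, eye_id="e", sens=None):
    s = np.full(52, 30.0) if sens is None else sens
    return VFTest(eye_id=eye_id, laterality="right", test_date=0.0,
                  sensitivities=s, md=md)


class TestRegistration:
    def test_centered_disc_is_identity(self, rng):
        m = rng.uniform(size=(52, 6, 6))
        # disc at grid center (12, 12) in processed voxels, patch 4 -> offset 0
        out = register_maps([m], [(12.0, 12.0)])[0]
        assert np.array_equal(out, m)

    def test_known_shift(self, rng):
        m = rng.uniform(size=(52, 6, 6))
        # disc one patch to the right: cx = 16 -> offset +1 in x
        out = register_maps([m], [(16.0, 12.0)])[0]
        assert np.all(np.isnan(out[:, -1, :]))
        assert np.array_equal(out[:, :-1, :], m[:, 1:, :])

    def test_shift_too_large_raises(self, rng):
        m = rng.uniform(size=(52, 6, 6))
        with pytest.raises(ValueError):
            register_maps([m], [(50.0, 12.0)])

    def test_vacated_cells_nan_only(self, rng):
        m = rng.uniform(size=(52, 6, 6))
        out = register_maps([m], [(12.0, 8.0)])[0]  # offset -1 in y
        assert np.all(np.isnan(out[:, :, 0]))
        assert not np.any(np.isnan(out[:, :, 1:]))


class TestSplitGroups:
    def test_boundary_cases(self):
        items = [(None, _test(-1.32)), (None, _test(-6.0)), (None, _test(-17.93))]
        a, b = split_groups(items, GroupSpec())
        assert [t.md for _, t in a] == [-1.32]
        assert [t.md for _, t in b] == [-6.0, -17.93]

    def test_one_per_eye_resample(self, rng):
        items = [(i, _test(-8.0, eye_id="x")) for i in range(5)] + \
                [(9, _test(-8.0, eye_id="y"))]
        spec = GroupSpec(resample_one_per_eye=True)
        a, b = split_groups(items, spec, rng=np.random.default_rng(0))
        assert len(b) == 2 and len(a) == 0

    def test_resample_requires_rng(self):
        with pytest.raises(ValueError):
            split_groups([(None, _test(0.0))],
                         GroupSpec(resample_one_per_eye=True))


class TestGroupTMaps:
    def test_matches_scipy_reference(self, rng):
        """Cellwise t against scipy.stats.ttest_1samp with popmean = mu."""
        maps = rng.uniform(0.0, 2.0, size=(15, 52, 6, 6))
        spec = GroupSpec(alpha=0.999999, lam=0.75)  # keep almost everything
        tm = group_t_maps(maps, spec)
        pooled = maps.transpose(1, 0, 2, 3).reshape(52, -1)
        for pt, a, b in zip(rng.integers(0, 52, 100),
                            rng.integers(0, 6, 100), rng.integers(0, 6, 100)):
            mu = pooled[pt].mean() + 0.75 * pooled[pt].std(ddof=1)
            ref = stats.ttest_1samp(maps[:, pt, a, b], popmean=mu,
                                    alternative="greater")
            if tm.t[pt, a, b] != 0.0:
                assert tm.t[pt, a, b] == pytest.approx(ref.statistic, abs=1e-10)
            assert tm.p[pt, a, b] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_saliency_all_zero(self):
        maps = np.full((10, 52, 6, 6), 1.3)
        tm = group_t_maps(maps, GroupSpec())
        assert np.all(tm.t == 0.0)

    def test_nonsignificant_zeroed(self, rng):
        maps = rng.normal(1.0, 0.1, size=(8, 52, 6, 6))
        tm = group_t_maps(maps, GroupSpec())
        nz = tm.t != 0.0
        assert np.all(tm.p[nz] <= GroupSpec().alpha)

    def test_nan_cells_excluded_per_cell(self, rng):
        maps = rng.uniform(size=(6, 52, 6, 6))
        maps[0, :, 0, 0] = np.nan
        tm = group_t_maps(maps, GroupSpec(alpha=0.999999))
        assert tm.n[0, 0, 0] == 5
        assert tm.n[0, 1, 1] == 6

    def test_planted_signal_detected(self, rng):
        maps = rng.normal(1.0, 0.05, size=(20, 52, 6, 6))
        maps[:, 7, 2, 3] += 5.0  # strong hotspot for point 7
        tm = group_t_maps(maps, GroupSpec())
        assert tm.t[7, 2, 3] > 0.0

    def test_needs_two_pairs(self, rng):
        with pytest.raises(ValueError):
            group_t_maps(rng.uniform(size=(1, 52, 6, 6)), GroupSpec())

    def test_bh_more_conservative(self, rng):
        maps = rng.normal(1.0, 0.3, size=(10, 52, 6, 6))
        maps[:, :, 1, 4] += 1.0
        plain = group_t_maps(maps, GroupSpec())
        bh = group_t_maps(maps, GroupSpec(bh_correct=True))
        assert np.sum(bh.t != 0) <= np.sum(plain.t != 0)

    def test_patch_means_pooling(self, rng):
        maps = rng.uniform(size=(12, 52, 6, 6))
        tm = group_t_maps(maps, GroupSpec(pool_over="patch_means"))
        per_pair = maps.mean(axis=(2, 3))
        assert np.allclose(tm.sbar_all, per_pair.mean(axis=0))
        assert np.allclose(tm.sigma_all, per_pair.std(axis=0, ddof=1))


class TestSeverityCorrelation:
    def test_matches_scipy_pearson(self, rng):
        pairs = [(rng.uniform(size=(52, 6, 6)), _test(float(rng.uniform(-15, 0))))
                 for _ in range(12)]
        sev = severity_correlation(pairs)
        mags = np.stack([m.mean(axis=(1, 2)) for m, _ in pairs])
        md = np.array([t.md for _, t in pairs])
        for pt in (0, 17, 51):
            ref = stats.pearsonr(mags[:, pt], md)
            assert sev.r[pt] == pytest.approx(ref.statistic, abs=1e-12)

    def test_constant_saliency_undefined(self):
        pairs = [(np.ones((52, 6, 6)), _test(float(md)))
                 for md in (-1.0, -5.0, -9.0)]
        sev = severity_correlation(pairs)
        assert not sev.defined.any()
        assert np.all(np.isnan(sev.r))

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError):
            severity_correlation([(np.ones((52, 6, 6)), _test(0.0))] * 2)

    def test_max_rule(self, rng):
        pairs = [(rng.uniform(size=(52, 6, 6)), _test(float(-i)))
                 for i in range(5)]
        sev = severity_correlation(pairs, magnitude_rule="max")
        assert sev.magnitude_rule == "max"
        assert sev.defined.all()


class TestHemifieldSubgroup:
    def _pair(self, sup_drop, inf_drop, norm, eye="e"):
        sup, inf = hemifield_masks()
        s = norm.mean_sens.copy()
        s[sup] -= sup_drop
        s[inf] -= inf_drop
        return (None, _test(float(np.mean(s - norm.mean_sens)), eye_id=eye,
                            sens=s))

    def test_selects_clear_cases(self, norm):
        pairs = [self._pair(10.0, 0.0, norm, "sup_eye"),
                 self._pair(0.0, 10.0, norm, "inf_eye"),
                 self._pair(3.0, 3.0, norm, "even_eye")]
        sel_sup = select_hemifield_subgroup(pairs, "superior_defect", norm)
        sel_inf = select_hemifield_subgroup(pairs, "inferior_defect", norm)
        assert [p[1].eye_id for p in sel_sup] == ["sup_eye"]
        assert [p[1].eye_id for p in sel_inf] == ["inf_eye"]

    def test_symmetric_under_mirror(self, norm, rng):
        perm = vertical_mirror_permutation()
        sens = norm.mean_sens - rng.uniform(0, 12, 52)
        # the normative profile is mirror-symmetric, so a mirrored test flips
        # its classification
        t = _test(0.0, sens=sens)
        tm = _test(0.0, sens=sens[perm])
        a = select_hemifield_subgroup([(None, t)], "superior_defect", norm)
        b = select_hemifield_subgroup([(None, tm)], "inferior_defect", norm)
        assert len(a) == len(b)

    def test_unknown_rule(self, norm):
        with pytest.raises(ValueError):
            select_hemifield_subgroup([], "temporal_defect", norm)


class TestRecoveryScore:
    def _mapping(self):
        return generate_mapping(dataclasses.replace(SyntheticCohortConfig(),
                                                    seed=77))

    def test_perfect_maps_score_one(self):
        mapping = self._mapping()
        gx, gy = mapping.grid_shape
        vals = np.zeros((52, gx, gy))
        for pt in range(52):
            vals[pt][mapping.region_mask(pt)] = 1.0
        sc = mapping_recovery_score(vals, mapping)
        assert sc.mean_precision == 1.0
        assert sc.mean_recall == 1.0
        assert sc.mean_topm_hit_rate == 1.0
        assert sc.mean_hemifield_inversion == 1.0

    def test_empty_maps(self):
        mapping = self._mapping()
        gx, gy = mapping.grid_shape
        sc = mapping_recovery_score(np.zeros((52, gx, gy)), mapping)
        assert np.isnan(sc.mean_precision)
        assert sc.mean_recall == 0.0
        assert sc.mean_topm_hit_rate == 0.0

    def test_random_maps_near_hypergeometric(self):
        mapping = self._mapping()
        gx, gy = mapping.grid_shape
        rng = np.random.default_rng(4)
        rates = []
        for _ in range(200):
            sc = mapping_recovery_score(rng.uniform(size=(52, gx, gy)), mapping)
            rates.append(sc.mean_topm_hit_rate)
        m = len(mapping.regions[0])
        expect = m / (gx * gy)
        assert np.mean(rates) == pytest.approx(expect, abs=0.02)

    def test_shape_mismatch(self):
        mapping = self._mapping()
        with pytest.raises(ValueError):
            mapping_recovery_score(np.zeros((52, 3, 3)), mapping)
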