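"""Generator determinism, planted-mapping invariants and the oracle model."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from sfmap.preprocess import RawScan
from sfmap.synthetic_cohort import (
    OracleRegressor,
    PlantedMapping,
    SyntheticCohortConfig,
    forward_truth,
    generate_cohort,
    generate_mapping,
    make_mirrored_cohort,
    pair_scans_vf,
)
from sfmap.pipeline import preprocess_volume
from sfmap.vf_grid import (
    N_POINTS,
    compute_md,
    grid_coords,
    hemifield_masks,
    vertical_mirror_permutation,
)


class TestMapping:
    def test_every_point_has_regions(self, small_cohort_config):
        mapping = generate_mapping(small_cohort_config)
        for pt in range(N_POINTS):
            assert len(mapping.regions[pt]) >= 1

    def test_anatomic_inversion(self, small_cohort_config):
        # superior VF points map only into the inferior retinal half
        mapping = generate_mapping(small_cohort_config)
        gx, gy = mapping.grid_shape
        sup, inf = hemifield_masks()
        for pt in range(N_POINTS):
            cols = mapping.regions[pt] % gy
            if sup[pt]:
                assert np.all(cols >= gy // 2)
            else:
                assert np.all(cols < gy // 2)

    def test_mirror_symmetric_by_construction(self, small_cohort_config):
        mapping = generate_mapping(small_cohort_config)
        perm = vertical_mirror_permutation()
        gy = mapping.grid_shape[1]
        for pt in range(N_POINTS):
            rows, cols = np.divmod(mapping.regions[pt], gy)
            mirrored = np.sort(rows * gy + (gy - 1 - cols))
            assert np.array_equal(np.sort(mapping.regions[perm[pt]]), mirrored)
            assert mapping.effect[perm[pt]] == mapping.effect[pt]

    def test_mirrored_method_involution(self, small_cohort_config):
        mapping = generate_mapping(small_cohort_config)
        mm = mapping.mirrored().mirrored()
        for pt in range(N_POINTS):
            assert np.array_equal(np.sort(mm.regions[pt]),
                                  np.sort(mapping.regions[pt]))

    def test_json_roundtrip(self, small_cohort_config):
        mapping = generate_mapping(small_cohort_config)
        back = PlantedMapping.from_json(mapping.to_json())
        assert back.grid_shape == mapping.grid_shape
        for pt in range(N_POINTS):
            assert np.array_equal(back.regions[pt], mapping.regions[pt])

    def test_validation_rejects_wrong_hemifield(self):
        sup, _ = hemifield_masks()
        pt_sup = int(np.flatnonzero(sup)[0])
        regions = [np.array([35]) if s else np.array([0])
                   for s in sup]  # col 5 for superior, col 0 for inferior
        regions[pt_sup] = np.array([0])  # superior point into superior retina
        with pytest.raises(ValueError):
            PlantedMapping(regions=regions, effect=np.full(52, 20.0),
                           grid_shape=(6, 6))


class TestForwardTruth:
    def test_zero_damage_is_normative(self, small_cohort_config, norm):
        mapping = generate_mapping(small_cohort_config)
        sens = forward_truth(np.zeros(mapping.grid_shape), mapping, norm)
        assert np.allclose(sens, norm.mean_sens)

    def test_damage_lowers_mapped_points_only(self, small_cohort_config, norm):
        mapping = generate_mapping(small_cohort_config)
        gy = mapping.grid_shape[1]
        pt = 0
        damage = np.zeros(mapping.grid_shape)
        rows, cols = np.divmod(mapping.regions[pt], gy)
        damage[rows, cols] = 0.5
        sens = forward_truth(damage, mapping, norm)
        drop = norm.mean_sens - sens
        assert drop[pt] == pytest.approx(0.5 * mapping.effect[pt])
        untouched = [q for q in range(N_POINTS)
                     if not set(mapping.regions[q]) & set(mapping.regions[pt])]
        assert np.allclose(drop[untouched], 0.0)

    def test_noise_requires_rng(self, small_cohort_config, norm):
        mapping = generate_mapping(small_cohort_config)
        with pytest.raises(ValueError):
            forward_truth(np.zeros(mapping.grid_shape), mapping, norm,
                          noise_sd=1.0)

    def test_damage_out_of_range_rejected(self, small_cohort_config, norm):
        mapping = generate_mapping(small_cohort_config)
        with pytest.raises(ValueError):
            forward_truth(np.full(mapping.grid_shape, 1.5), mapping, norm)


class TestCohort:
    def test_deterministic(self, small_cohort_config, norm):
        eyes1, m1 = generate_cohort(small_cohort_config, norm)
        eyes2, m2 = generate_cohort(small_cohort_config, norm)
        for a, b in zip(eyes1, eyes2):
            assert np.array_equal(a.raw_scans[0].intensity,
                                  b.raw_scans[0].intensity)
            assert np.array_equal(a.vf_series[0].sensitivities,
                                  b.vf_series[0].sensitivities)

    def test_eye_depends_only_on_seed_and_index(self, small_cohort_config, norm):
        bigger = dataclasses.replace(small_cohort_config, n_eyes=12)
        eyes_small, _ = generate_cohort(small_cohort_config, norm)
        eyes_big, _ = generate_cohort(bigger, norm)
        for a, b in zip(eyes_small, eyes_big):
            assert np.array_equal(a.raw_scans[0].intensity,
                                  b.raw_scans[0].intensity)

    def test_severity_mix_binomial(self, norm):
        cfg = dataclasses.replace(SyntheticCohortConfig(), n_eyes=120, seed=5)
        eyes, _ = generate_cohort(cfg, norm)
        n_ma = sum(e.severity_class == "moderate_advanced" for e in eyes)
        # two-sided binomial check at p = 0.35, alpha 1e-4
        pv = stats.binomtest(n_ma, 120, 0.35).pvalue
        assert pv > 1e-4

    def test_truth_md_in_declared_range(self, small_cohort, norm):
        eyes, _ = small_cohort
        ranges = dict(SyntheticCohortConfig().severity_md_ranges)
        for e in eyes:
            lo, hi = ranges[e.severity_class]
            if e.severity_class == "healthy":
                # no damage for non-negative targets, shallow otherwise
                assert -0.6 <= e.truth_md <= 0.0
            else:
                # clipping can leave the realized MD slightly shallower
                assert e.truth_md <= hi + 1.5

    def test_vf_md_consistent(self, small_cohort, norm):
        eyes, _ = small_cohort
        for e in eyes:
            for t in e.vf_series[:2]:
                from sfmap.vf_grid import flip_to_right_eye
                rt = flip_to_right_eye(t)
                assert rt.md == pytest.approx(compute_md(rt.sensitivities, norm))

    def test_left_eyes_stored_in_native_frame(self, small_cohort):
        eyes, _ = small_cohort
        lats = {e.laterality for e in eyes}
        for e in eyes:
            assert e.raw_scans[0].laterality == e.laterality
            assert e.vf_series[0].laterality == e.laterality

    def test_damage_field_respects_pattern(self, small_cohort):
        eyes, mapping = small_cohort
        gy = mapping.grid_shape[1]
        for e in eyes:
            if e.defect_pattern == "superior" and e.truth_md < 0:
                # superior VF damage lives in the inferior retina (high cols)
                assert np.all(e.truth_damage[:, :gy // 2] == 0.0)


class TestMirroredCohort:
    def test_twins_are_exact_mirrors(self, norm):
        cfg = dataclasses.replace(SyntheticCohortConfig(), n_eyes=4, seed=9)
        eyes, mapping = make_mirrored_cohort(cfg, norm)
        assert len(eyes) == 8
        perm = vertical_mirror_permutation()
        for base, twin in zip(eyes[:4], eyes[4:]):
            assert twin.eye_id == base.eye_id + "m"
            s, ts = base.raw_scans[0], twin.raw_scans[0]
            assert np.array_equal(ts.intensity, s.intensity[:, ::-1, :])
            assert np.array_equal(ts.surface_z, s.surface_z[:, ::-1])
            assert np.array_equal(twin.truth_damage, base.truth_damage[:, ::-1])
            for a, b in zip(base.vf_series, twin.vf_series):
                assert np.array_equal(b.sensitivities, a.sensitivities[perm])

    def test_preprocessing_commutes_with_mirror(self, norm):
        # the full flatten/crop/downsample chain maps twin onto the exact
        # y-mirror of its base volume
        cfg = dataclasses.replace(SyntheticCohortConfig(), n_eyes=2, seed=9)
        eyes, _ = make_mirrored_cohort(cfg, norm)
        base, twin = eyes[0], eyes[2]
        vb = preprocess_volume(base.raw_scans[0], cfg)
        vt = preprocess_volume(twin.raw_scans[0], cfg)
        assert np.max(np.abs(vt.intensity - vb.intensity[:, ::-1, :])) < 1e-10


class TestPairing:
    def _eye(self, scan_dates, vf_dates, norm):
        from sfmap.vf_grid import VFTest
        from sfmap.synthetic_cohort import SyntheticEye
        scans = [RawScan(intensity=np.zeros((2, 2, 2)),
                         voxel_spacing_um=(1, 1, 1), laterality="right",
                         disc_center_vox=(1, 1), eye_id="e", scan_date=d)
                 for d in scan_dates]
        tests = [VFTest(eye_id="e", laterality="right", test_date=d,
                        sensitivities=np.zeros(52), md=0.0) for d in vf_dates]
        return SyntheticEye(eye_id="e", laterality="right",
                            severity_class="healthy", defect_pattern="diffuse",
                            truth_damage=np.zeros((6, 6)), truth_md=0.0,
                            raw_scans=scans, vf_series=tests)

    def test_training_mode_all_pairs_in_window(self, norm):
        eye = self._eye([100.0], [20.0, 95.0, 185.0, 300.0], norm)
        pairs = pair_scans_vf([eye], window_days=90.0, mode="training")
        assert [t.test_date for _, t in pairs] == [20.0, 95.0, 185.0]

    def test_test_mode_unique_closest(self, norm):
        eye = self._eye([100.0, 110.0], [95.0, 112.0], norm)
        pairs = pair_scans_vf([eye], window_days=90.0, mode="test")
        assert len(pairs) == 2
        matched = {(s.scan_date, t.test_date) for s, t in pairs}
        assert matched == {(110.0, 112.0), (100.0, 95.0)}

    def test_window_inclusive(self, norm):
        eye = self._eye([100.0], [10.0, 190.0], norm)
        pairs = pair_scans_vf([eye], window_days=90.0, mode="training")
        assert len(pairs) == 2

    def test_unknown_mode(self, norm):
        with pytest.raises(ValueError):
            pair_scans_vf([], mode="bogus")


class TestOracle:
    def test_estimates_planted_damage(self, norm):
        cfg = dataclasses.replace(SyntheticCohortConfig(), n_eyes=6, seed=21,
                                  noise_sd_vol=0.0, noise_sd_vf=0.0)
        eyes, mapping = generate_cohort(cfg, norm)
        oracle = OracleRegressor(mapping, norm, cfg)
        damaged = [e for e in eyes if e.truth_md < -1.0]
        assert damaged, "cohort draw contained no damaged eye"
        for e in damaged[:3]:
            vol = preprocess_volume(e.raw_scans[0], cfg)
            d_hat = oracle.estimate_damage(vol.intensity)
            d_true = e.truth_damage
            # monotone recovery away from the disc crater
            mask = d_true > 0.2
            if mask.any():
                assert np.corrcoef(d_hat[mask], d_true[mask])[0, 1] > 0.5 or \
                    np.allclose(d_hat[mask], d_true[mask], atol=0.45)

    def test_prediction_matches_forward_rule(self, norm):
        cfg = dataclasses.replace(SyntheticCohortConfig(), n_eyes=2, seed=3)
        eyes, mapping = generate_cohort(cfg, norm)
        oracle = OracleRegressor(mapping, norm, cfg)
        vol = preprocess_volume(eyes[0].raw_scans[0], cfg)
        pred = oracle.predict(vol.intensity)
        expect = forward_truth(oracle.estimate_damage(vol.intensity),
                               mapping, norm)
        assert np.allclose(pred, expect)

    def test_shape_check(self, norm):
        cfg = SyntheticCohortConfig()
        mapping = generate_mapping(cfg)
        oracle = OracleRegressor(mapping, norm, cfg)
        with pytest.raises(ValueError):
            oracle.predict(np.zeros((2, 2, 2)))


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticCohortConfig(n_eyes=0)
    with pytest.raises(ValueError):
        SyntheticCohortConfig(severity_mix=(("healthy", 0.5), ("early", 0.1)))
    with pytest.raises(ValueError):
        SyntheticCohortConfig(crop_shape=(47, 48, 192))


def test_processed_geometry_properties():
    cfg = SyntheticCohortConfig()
    assert cfg.processed_shape == (24, 24, 48)
    assert cfg.enface_grid == (6, 6)
    z0, z1 = cfg.processed_band_z()
    assert (z0, z1) == (20, 28)
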