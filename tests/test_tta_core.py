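"""Physiological statistics, OOD detection, and hybrid image generation."""

import numpy as np
import pytest

from hsi_tta.errors import DataError
from hsi_tta import optics, tta_core
from hsi_tta.optics import camera_grid, l1_normalize
from hsi_tta.spectral_db import HSICube, SyntheticDatabase, TwinMap, generate_twin, sample_params
from hsi_tta.tta_core import (
    OODMask,
    PhysioStats,
    augment_image,
    detect_ood,
    fit_physio_stats,
    select_replacement_pool,
)


def twin_from(sto2, vhb):
    sto2 = np.asarray(sto2, dtype=float)
    vhb = np.asarray(vhb, dtype=float)
    return TwinMap(
        record_id=np.zeros(sto2.shape, dtype=np.int64),
        sto2_map=sto2,
        vhb_map=vhb,
        distance_map=np.zeros(sto2.shape),
    )


class TestFitPhysioStats:
    def test_degenerate_constant_distribution(self):
        t = twin_from(np.full((4, 4), 0.6), np.full((4, 4), 0.05))
        s = fit_physio_stats([t], (25, 75))
        assert s.median_sto2 == s.lo_sto2 == s.hi_sto2 == 0.6
        assert s.median_vhb == s.lo_vhb == s.hi_vhb == 0.05

    def test_hand_computed_percentiles(self):
        # linear interpolation between order statistics: for {0.1,0.2,0.3,0.4}
        # the 25th percentile is 0.1 + 0.75*(0.2-0.1) = 0.175, the 75th 0.325
        t = twin_from([[0.1, 0.2], [0.3, 0.4]], [[0.1, 0.2], [0.3, 0.4]])
        s = fit_physio_stats([t], (25, 75))
        assert s.lo_sto2 == pytest.approx(0.175)
        assert s.hi_sto2 == pytest.approx(0.325)
        assert s.median_sto2 == pytest.approx(0.25)

    def test_wider_pair_encloses_narrower(self, rng):
        t = twin_from(rng.uniform(0, 1, (20, 20)), rng.uniform(0, 0.3, (20, 20)))
        narrow = fit_physio_stats([t], (25, 75))
        wide = fit_physio_stats([t], (5, 95))
        assert wide.lo_sto2 <= narrow.lo_sto2 and wide.hi_sto2 >= narrow.hi_sto2
        assert wide.lo_vhb <= narrow.lo_vhb and wide.hi_vhb >= narrow.hi_vhb

    def test_empty_collection_rejected(self):
        with pytest.raises(DataError):
            fit_physio_stats([], (25, 75))

    def test_json_roundtrip(self, tmp_path, rng):
        t = twin_from(rng.uniform(0, 1, (5, 5)), rng.uniform(0, 0.3, (5, 5)))
        s = fit_physio_stats([t], (5, 95), provenance=["img0"])
        s.to_json(tmp_path / "s.json")
        assert PhysioStats.from_json(tmp_path / "s.json") == s


class TestDetectOOD:
    stats = PhysioStats(0.6, 0.05, 0.5, 0.7, 0.03, 0.08, (25.0, 75.0))

    def test_center_is_in_distribution(self):
        m = detect_ood(twin_from([[0.6]], [[0.05]]), self.stats)
        assert not m.flags[0, 0]

    def test_boundary_is_in_distribution(self):
        m = detect_ood(twin_from([[0.5, 0.7]], [[0.03, 0.08]]), self.stats)
        assert not m.flags.any()

    def test_single_parameter_violation_flags(self):
        m = detect_ood(twin_from([[0.49]], [[0.05]]), self.stats)
        assert m.flags[0, 0]
        m = detect_ood(twin_from([[0.6]], [[0.081]]), self.stats)
        assert m.flags[0, 0]

    def test_resubstitution_fraction_with_or_rule(self, rng):
        """Refit on correlated physiological draws: each parameter leaves its
        own IQR half the time; the union lies between 50% and 75%."""
        z1 = rng.standard_normal(40_000)
        z2 = 0.5 * z1 + np.sqrt(0.75) * rng.standard_normal(40_000)
        t = twin_from(z1.reshape(200, 200), np.abs(z2).reshape(200, 200) / 20)
        s = fit_physio_stats([t], (25, 75))
        frac = detect_ood(t, s).fraction
        assert 0.5 - 0.01 <= frac <= 0.75 + 0.01


class TestReplacementPool:
    def test_full_range_tolerances_select_all(self, small_db):
        s = PhysioStats(0.5, 0.15, 0.4, 0.6, 0.1, 0.2, (25.0, 75.0))
        pool = select_replacement_pool(small_db, s, tol_sto2=1.0, tol_vhb=0.3)
        assert pool.size == len(small_db)

    def test_single_matching_record_forced(self):
        params = sample_params(20, seed=5)
        params[:, 0] = np.linspace(0, 1, 20)  # sto2
        params[:, 1] = 0.29  # vhb far from median for all but none
        params[7, 1] = 0.05
        spectra = l1_normalize(np.random.default_rng(0).uniform(0.01, 1, (20, 100)), axis=1)
        db = SyntheticDatabase(params, spectra)
        s = PhysioStats(params[7, 0], 0.05, 0.3, 0.5, 0.04, 0.06, (25.0, 75.0))
        pool = select_replacement_pool(db, s, tol_sto2=0.02, tol_vhb=0.01)
        assert pool.tolist() == [7]

    def test_matches_brute_force_filter(self, small_db):
        s = PhysioStats(0.6, 0.05, 0.5, 0.7, 0.03, 0.08, (25.0, 75.0))
        pool = select_replacement_pool(small_db, s, 0.05, 0.02)
        expected = [
            i for i in range(len(small_db))
            if abs(small_db.sto2[i] - 0.6) <= 0.05 and abs(small_db.vhb[i] - 0.05) <= 0.02
        ]
        assert pool.tolist() == expected

    def test_widening_until_nonempty(self, small_db, caplog):
        # medians in a corner of parameter space with tiny tolerances
        s = PhysioStats(1.0, 0.3, 1.0, 1.0, 0.3, 0.3, (25.0, 75.0))
        with caplog.at_level("WARNING", logger="hsi_tta.tta_core"):
            pool = select_replacement_pool(small_db, s, 1e-6, 1e-6)
        assert pool.size >= 1
        assert any("widening" in r.message for r in caplog.records)

    def test_nonpositive_tolerances_rejected(self, small_db):
        s = PhysioStats(0.5, 0.1, 0.4, 0.6, 0.05, 0.15, (25.0, 75.0))
        with pytest.raises(DataError):
            select_replacement_pool(small_db, s, 0.0, 0.02)


def _scene_cube(small_db, rng, shape=(6, 6)):
    vals = l1_normalize(rng.uniform(0.001, 1, (*shape, 100)), axis=2)
    return HSICube(vals, camera_grid(), normalized=True)


class TestAugmentImage:
    stats = PhysioStats(0.6, 0.05, 0.5, 0.7, 0.03, 0.08, (25.0, 75.0))

    def test_all_false_mask_is_identity(self, small_db, rng):
        cube = _scene_cube(small_db, rng)
        twin = generate_twin(cube, small_db)
        out = augment_image(cube, twin, OODMask(np.zeros((6, 6), bool)), small_db, self.stats)
        assert np.array_equal(out.values, cube.values)

    def test_in_distribution_pixels_bit_identical(self, small_db, rng):
        cube = _scene_cube(small_db, rng)
        twin = generate_twin(cube, small_db)
        ood = detect_ood(twin, self.stats)
        out = augment_image(cube, twin, ood, small_db, self.stats)
        assert np.array_equal(out.values[~ood.flags], cube.values[~ood.flags])

    def test_single_ood_pixel_recomputed_by_hand(self, small_db, rng):
        cube = _scene_cube(small_db, rng)
        twin = generate_twin(cube, small_db)
        flags = np.zeros((6, 6), bool)
        flags[2, 3] = True
        pool = select_replacement_pool(small_db, self.stats)
        out = augment_image(cube, twin, OODMask(flags), small_db, self.stats, pool)
        # recompute outside the pipeline
        s_real = cube.values[2, 3]
        d = np.linalg.norm(small_db.spectra_cam[pool] - s_real[None, :], axis=1)
        s_synth = small_db.spectra_cam[pool[np.argmin(d)]]
        expected = (s_real + s_synth) / 2.0
        expected = expected / np.abs(expected).sum()
        assert np.allclose(out.values[2, 3], expected, atol=1e-12)

    def test_output_normalized_flag(self, small_db, rng):
        cube = _scene_cube(small_db, rng)
        twin = generate_twin(cube, small_db)
        out = augment_image(cube, twin, detect_ood(twin, self.stats), small_db, self.stats)
        assert out.normalized
        assert np.allclose(out.values.sum(axis=2), 1.0, atol=1e-9)

    def test_ood_count_never_increases_when_reapplied(self, small_db, rng):
        cube = _scene_cube(small_db, rng, shape=(8, 8))
        twin = generate_twin(cube, small_db)
        ood1 = detect_ood(twin, self.stats)
        out = augment_image(cube, twin, ood1, small_db, self.stats)
        twin2 = generate_twin(out, small_db)
        ood2 = detect_ood(twin2, self.stats)
        assert ood2.flags.sum() <= ood1.flags.sum()


class TestPercentileSelection:
    def test_single_candidate_returned(self, small_db):
        from hsi_tta import scene_sim, seg_model

        layout = scene_sim.default_layout(16, 16)
        scenes = scene_sim.make_dataset(2, 1, states=("physiological",), seed=4, layout=layout)
        model = seg_model.train(scenes)
        twins = [generate_twin(s.cube, small_db) for s in scenes]
        pair = tta_core.select_percentile_setting(
            [(25.0, 75.0)], scenes, model, small_db, twins
        )
        assert pair == (25.0, 75.0)

    def test_candidate_leaving_ood_uncorrected_loses(self):
        """Constructed validation set: spectra are mixtures a*p1 + (1-a)*p2 of
        two disjoint profiles, so Euclidean geometry is linear in the mixing
        weight a. The organ trains at a=0.2, background sits at a=0.9, and the
        malperfused organ appears at a=0.8 (misclassified as background). A
        physiological twin collection with a few extreme outlier pixels makes
        the (0, 100) band cover the malperfused values, leaving them
        uncorrected, while the IQR band corrects them back; the IQR wins."""
        from hsi_tta import scene_sim, seg_model

        p1 = np.zeros(100); p1[:50] = 1 / 50.0
        p2 = np.zeros(100); p2[50:] = 1 / 50.0
        mix = lambda a: a * p1 + (1 - a) * p2

        # db clusters: background twin (a=0.9, in-distribution, vhb 0.09 so it
        # stays out of the median pool), organ pool (a=0.2, at the medians),
        # malperfused (a=0.8, extreme params)
        n_each = 10
        spectra, params = [], []
        for a, sto2, vhb in ((0.9, 0.6, 0.09), (0.2, 0.6, 0.05), (0.8, 0.05, 0.28)):
            for _ in range(n_each):
                spectra.append(mix(a))
                params.append([sto2, vhb, 20.0, 1.5, 0.9, 1.4, 0.05, 0.85])
        db = SyntheticDatabase(np.array(params), np.array(spectra))

        # physiological twins: 60% organ-like, 38% background-like, 2% outliers
        sto2_vals = np.r_[np.full(60, 0.6), np.full(38, 0.6), np.full(2, 0.03)]
        vhb_vals = np.r_[np.full(60, 0.05), np.full(38, 0.09), np.full(2, 0.29)]
        twins = [twin_from(sto2_vals.reshape(10, 10), vhb_vals.reshape(10, 10))]

        model = seg_model.FrozenModel(
            "nearest_centroid", (0, 1),
            {"centroids": np.stack([mix(0.9), mix(0.2)])},
        )
        mask = np.zeros((4, 4), dtype=np.int64)
        mask[:, 2:] = 1  # right half is the organ
        cube_vals = np.where(mask[..., None] == 1, mix(0.8), mix(0.9))
        scene = scene_sim.LabeledScene(
            HSICube(cube_vals, camera_grid(), normalized=True),
            mask, {}, "s0", "i0", scene_sim.PERFUSION_STATES["venous_congestion"],
        )
        pair = tta_core.select_percentile_setting(
            [(0.0, 100.0), (25.0, 75.0)], [scene], model, db, twins
        )
        assert pair == (25.0, 75.0)

    def test_empty_candidates_rejected(self, small_db):
        with pytest.raises(DataError):
            tta_core.select_percentile_setting([], [], None, small_db, [])
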