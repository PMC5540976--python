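"""Decoding: fold plan, SVM cross-validation, voxel selections, shifts."""

import numpy as np
import pytest

import voxelgrain as vg
from voxelgrain.decoding import GRID_DIRECTIONS, ShiftSpec, shift_mm_to_voxels
from voxelgrain.errors import InvalidParameterError

from conftest import SMALL_MAP, manual_dataset


class TestFoldPlan:
    def test_four_folds_structure(self):
        folds = vg.make_folds(4)
        assert len(folds) == 4
        for k, plan in enumerate(folds):
            assert plan.test_subrun == k
            assert len(plan.train_subruns) == 3
            assert plan.test_subrun not in plan.train_subruns
        covered = [p.test_subrun for p in folds]
        assert sorted(covered) == [0, 1, 2, 3]  # single coverage

    def test_fold_pattern_counts(self, small_mixed):
        from voxelgrain.decoding import _fold_patterns

        plan = vg.make_folds(4)[2]
        Xtr, ytr, Xte, yte = _fold_patterns(small_mixed, 0, "grating", plan)
        assert Xtr.shape[0] == 12 and Xte.shape[0] == 4
        assert list(np.bincount(ytr)) == [6, 6] and list(np.bincount(yte)) == [2, 2]

    def test_generalized_plan_warns(self):
        with pytest.warns(UserWarning):
            folds = vg.make_folds(3)
        assert len(folds) == 3

    def test_too_few_subruns(self):
        with pytest.raises(InvalidParameterError):
            vg.make_folds(1)


class TestDecode:
    def test_noise_free_separable_perfect(self, small_mixed_noisefree):
        dec = vg.train_test_decode(small_mixed_noisefree, selections=("all",))
        assert np.allclose(dec.per_fold["accuracy"], 1.0)

    def test_permutation_null_near_chance(self):
        """Condition labels permuted independently per pattern: group mean
        accuracy must stay inside the 99% interval around 0.5."""
        from scipy import stats

        rng = np.random.default_rng(0)
        accs = []
        for seed in range(5):
            sc = vg.mixed_scenario(seed=400 + seed, n_subjects=8,
                                   map=vg.NeuralMapParams(**SMALL_MAP),
                                   kinds=("grating",))
            ds = vg.generate_dataset(sc)
            t = ds.t.copy()
            # independent per-(subject, run, subrun) coin flip on the condition axis
            flips = rng.integers(0, 2, size=t.shape[:4])
            t = np.where(flips[..., None, None] == 1, t[..., ::-1, :], t)
            ds_perm = vg.PatternDataset(
                t=t, voxels=ds.voxels, kinds=ds.kinds, grid_shape=ds.grid_shape,
                patches=ds.patches)
            dec = vg.train_test_decode(ds_perm, selections=("all",))
            accs.extend(dec.per_subject()["accuracy"].tolist())
        mean = np.mean(accs)
        # 40 subjects x 16 decisions, but decisions within a subject correlate;
        # use the subject-level t-interval
        lo, hi = stats.t.interval(0.99, len(accs) - 1, loc=mean,
                                  scale=stats.sem(accs))
        assert lo <= 0.5 <= hi

    def test_accuracies_bounded(self, small_mixed):
        dec = vg.train_test_decode(small_mixed, selections=("all", "prefA", "prefB"))
        acc = dec.per_fold["accuracy"].dropna()
        assert np.all((acc >= 0) & (acc <= 1))

    def test_empty_selection_recorded_missing(self, small_coarse_noisefree):
        """Coarse-only noise-free data have no anti-preferring voxels, so
        prefB folds are recorded as missing, never as zero."""
        dec = vg.train_test_decode(small_coarse_noisefree, selections=("prefB",))
        assert dec.per_fold["accuracy"].isna().all()
        summary = dec.group_summary()
        assert (summary["n_subjects"] == 0).all()

    def test_unknown_selection_rejected(self, small_mixed):
        with pytest.raises(InvalidParameterError):
            vg.train_test_decode(small_mixed, selections=("sharpest",))


class TestShifts:
    def grid_dataset(self):
        """Single patch whose pattern encodes the voxel x coordinate."""
        ny, nx = 4, 4
        base = np.arange(ny * nx, dtype=float).reshape(ny, nx)
        t = np.tile(base.ravel(), (1, 1, 2, 4, 2, 1))
        return manual_dataset(t, grid_shape=(ny, nx)), base

    def test_magnitude_validation(self):
        with pytest.raises(InvalidParameterError):
            ShiftSpec(magnitude=1.5)
        assert shift_mm_to_voxels(6.0).magnitude == 3.0

    def test_zero_shift_identity(self, small_mixed):
        patterns = small_mixed.t[0, 0, 0, 0]
        shifted, keep = vg.shift_patterns(
            patterns, small_mixed, ShiftSpec(0.0), (0, 1)
        )
        np.testing.assert_array_equal(shifted, patterns)
        assert len(keep) == small_mixed.n_voxels

    def test_constant_pattern_invariant(self, small_mixed):
        const = np.full((2, small_mixed.n_voxels), 3.25)
        for mag in (0.5, 1.0, 2.0, 3.0):
            for d in GRID_DIRECTIONS:
                shifted, keep = vg.shift_patterns(
                    const, small_mixed, ShiftSpec(mag), d
                )
                assert np.allclose(shifted, 3.25)
                assert len(keep) < small_mixed.n_voxels  # symmetric dropping

    def test_one_voxel_shift_relabels_neighbor(self):
        ds, base = self.grid_dataset()
        pattern = ds.t[0, 0, 0, 0, 0][None]
        shifted, keep = vg.shift_patterns(pattern, ds, ShiftSpec(1.0), (0, 1))
        # voxel at x takes the value of its +x neighbor; last column dropped
        expected = base[:, 1:].ravel()
        np.testing.assert_array_equal(shifted[0], expected)
        np.testing.assert_array_equal(keep, np.flatnonzero(base % 4 < 3))

    def test_half_voxel_shift_averages_neighbors(self):
        ds, base = self.grid_dataset()
        pattern = ds.t[0, 0, 0, 0, 0][None]
        shifted, _ = vg.shift_patterns(pattern, ds, ShiftSpec(0.5), (0, 1))
        expected = ((base[:, :-1] + base[:, 1:]) / 2).ravel()
        np.testing.assert_array_equal(shifted[0], expected)

    def test_invalid_direction(self, small_mixed):
        with pytest.raises(InvalidParameterError):
            vg.shift_patterns(small_mixed.t[0, 0, 0, 0], small_mixed,
                              ShiftSpec(1.0), (1, 1))

    def test_zero_shift_curve_equals_plain_decoding(self, small_mixed):
        plain = vg.train_test_decode(small_mixed, selections=("all",))
        curve = vg.shift_decoding_curve(small_mixed, selections=("all",),
                                        shifts_mm=(0.0,))
        a = plain.per_subject().sort_values(["subject", "kind"])["accuracy"].to_numpy()
        b = curve.per_subject().sort_values(["subject", "kind"])["accuracy"].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_fine_only_shift_degrades_accuracy(self):
        """With sub-voxel columns, shifting test patterns by 3 voxels
        decorrelates the fine-grained pattern: accuracy drops toward chance
        while the unshifted accuracy stays high."""
        sc = vg.fine_only_scenario(
            seed=77, n_subjects=6, kinds=("grating",),
            map=vg.NeuralMapParams(a_rad=0, a_vert=0, **SMALL_MAP),
            noise=vg.NoiseParams(sigma_pattern=0.25, sigma_subject=0.0),
        )
        ds = vg.generate_dataset(sc)
        res = vg.shift_decoding_curve(ds, selections=("all",), shifts_mm=(0.0, 6.0))
        g = res.per_subject().groupby("shift_mm")["accuracy"].mean()
        assert g[0.0] > 0.8
        assert g[6.0] < g[0.0] - 0.2
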