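"""Synthetic V1 generator: maps, responses, voxel sampling, datasets."""

import numpy as np
import pytest

import voxelgrain as vg
from voxelgrain.errors import InvalidParameterError
from voxelgrain.preference import reference_condition_index
from voxelgrain.simulate import _column_coordinates

from conftest import SMALL_MAP


DEFAULT_MAP = vg.NeuralMapParams()


class TestOrientationMap:
    def test_determinism(self):
        a = vg.generate_orientation_map(DEFAULT_MAP, seed=3)
        b = vg.generate_orientation_map(DEFAULT_MAP, seed=3)
        np.testing.assert_array_equal(a.pref, b.pref)

    def test_preference_range_and_coords(self):
        m = vg.generate_orientation_map(DEFAULT_MAP, seed=1)
        assert np.all((m.pref >= 0) & (m.pref < 180))
        lo, hi = m.patch.polar_range
        assert np.all((m.polar >= lo) & (m.polar <= hi))
        assert np.all((m.ecc >= 1.5) & (m.ecc <= 7.04))

    def test_preference_marginal_uniform(self):
        """Chi-square goodness of fit on decorrelated column samples.

        Columns are spatially correlated at the columnar period (~3 column
        pitches), so the field is subsampled at 4x the pitch to obtain
        quasi-independent draws before applying the 18-bin chi-square test
        at alpha = 0.01.
        """
        from scipy import stats

        prefs = []
        for seed in range(4):
            m = vg.generate_orientation_map(DEFAULT_MAP, seed=seed)
            prefs.append(m.pref[::4, ::4].ravel())
        pref = np.concatenate(prefs)
        counts, _ = np.histogram(pref, bins=18, range=(0, 180))
        stat = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stat < stats.chi2.ppf(0.99, df=17)

    def test_spectral_peak_near_columnar_frequency(self):
        """Radially averaged power of exp(2i*pref) peaks within 20% of 1/period."""
        m = vg.generate_orientation_map(DEFAULT_MAP, seed=2)
        z = np.exp(2j * np.radians(m.pref))
        z = z - z.mean()
        power = np.abs(np.fft.fft2(z)) ** 2
        k = np.fft.fftfreq(m.pref.shape[0], d=DEFAULT_MAP.column_pitch)
        kk = np.hypot(*np.meshgrid(k, k, indexing="ij")).ravel()
        pw = power.ravel()
        bins = np.linspace(0, kk.max(), 40)
        which = np.digitize(kk, bins)
        radial = np.array([pw[which == i].mean() if np.any(which == i) else 0
                           for i in range(1, len(bins))])
        centers = (bins[:-1] + bins[1:]) / 2
        peak = centers[np.argmax(radial)]
        k0 = 1.0 / DEFAULT_MAP.columnar_period
        assert abs(peak - k0) <= 0.2 * k0

    def test_unresolvable_period_rejected(self):
        with pytest.raises(InvalidParameterError):
            vg.NeuralMapParams(columnar_period=0.4, column_pitch=0.25)


class TestColumnarResponse:
    def test_tuning_maximum(self):
        """Preference aligned with the stimulus everywhere gives baseline*(1+a_col)."""
        params = vg.NeuralMapParams(a_rad=0.0, a_vert=0.0, **SMALL_MAP)
        m = vg.generate_orientation_map(params, seed=0)
        m.pref = np.full_like(m.pref, 45.0)
        stim = vg.StimulusSpec("grating", "plus45")
        r = vg.columnar_response(m, stim, params)
        np.testing.assert_allclose(r, params.baseline * (1 + params.a_col))

    def test_coarse_contrast_closed_form(self):
        """Gratings contrast in a coarse-only world follows
        2*baseline*a_rad*cos(2(theta_stim - theta_radial)) and never
        changes sign within a patch; it equals 2*baseline*a_rad exactly
        where the stimulus is locally radial."""
        params = vg.NeuralMapParams(a_col=0.0, a_vert=0.0, **SMALL_MAP)
        m = vg.generate_orientation_map(params, seed=0)
        plus, minus = vg.stimulus_pair("grating")
        contrast = vg.columnar_response(m, plus, params) - vg.columnar_response(
            m, minus, params
        )
        expected = 2 * params.baseline * params.a_rad * np.cos(
            2 * np.radians(45.0 - m.polar % 180.0)
        )
        np.testing.assert_allclose(contrast, expected, atol=1e-12)
        assert np.all(contrast > 0)
        center = np.argmin(np.abs(m.polar[0] - 45.0))
        np.testing.assert_allclose(
            contrast[:, center].max(), 2 * params.baseline * params.a_rad, rtol=1e-2
        )

    def test_gratings_blind_to_vertical_bias_and_spirals_to_radial(self):
        """The vertical-bias term cancels in grating contrasts and the
        radial-bias term cancels in spiral contrasts (stimulus balance)."""
        base = vg.NeuralMapParams(a_col=0.0, a_rad=0.0, a_vert=0.05, **SMALL_MAP)
        m = vg.generate_orientation_map(base, seed=0)
        g1, g2 = vg.stimulus_pair("grating")
        c = vg.columnar_response(m, g1, base) - vg.columnar_response(m, g2, base)
        np.testing.assert_allclose(c, 0, atol=1e-12)
        base2 = vg.NeuralMapParams(a_col=0.0, a_rad=0.05, a_vert=0.0, **SMALL_MAP)
        s1, s2 = vg.stimulus_pair("spiral")
        c2 = vg.columnar_response(m, s1, base2) - vg.columnar_response(m, s2, base2)
        np.testing.assert_allclose(c2, 0, atol=1e-12)

    def test_strictly_positive(self, small_mixed):
        assert small_mixed.amplitudes is not None
        assert np.all(small_mixed.amplitudes > 0)


class TestSampleVoxels:
    def make_grid(self, gain):
        return vg.VoxelGrid(
            voxel_mm=2.0, columns_per_voxel=2, shape=(2, 2),
            gain=np.asarray(gain)[None], patch_ids=(1,),
        )

    def test_uniform_response(self):
        grid = self.make_grid([[1.0, 2.0], [3.0, 4.0]])
        out = vg.sample_voxels(np.full((4, 4), 5.0), grid)
        np.testing.assert_allclose(out, 5.0 * np.array([[1, 2], [3, 4]]))

    def test_identity_gain_footprint_means(self):
        grid = self.make_grid(np.ones((2, 2)))
        r = np.arange(16, dtype=float).reshape(4, 4)
        out = vg.sample_voxels(r, grid)
        expected = np.array([[r[:2, :2].mean(), r[:2, 2:].mean()],
                             [r[2:, :2].mean(), r[2:, 2:].mean()]])
        np.testing.assert_allclose(out, expected)

    def test_hand_computed_instance(self):
        """4x4 column sheet, 2x2-column voxels, hand-set responses and gains."""
        r = np.array([[1.0, 3.0, 2.0, 2.0],
                      [5.0, 7.0, 4.0, 8.0],
                      [1.0, 1.0, 9.0, 1.0],
                      [1.0, 3.0, 5.0, 1.0]])
        gains = np.array([[2.0, 0.5], [1.0, 4.0]])
        out = vg.sample_voxels(r, self.make_grid(gains))
        np.testing.assert_allclose(out, [[2.0 * 4.0, 0.5 * 4.0],
                                         [1.0 * 1.5, 4.0 * 4.0]])

    def test_gain_positive_enforced(self):
        with pytest.raises(InvalidParameterError):
            self.make_grid([[1.0, -0.1], [1.0, 1.0]])

    def test_mismatched_field_rejected(self):
        with pytest.raises(InvalidParameterError):
            vg.sample_voxels(np.ones((3, 3)), self.make_grid(np.ones((2, 2))))


class TestGenerateDataset:
    def test_pattern_counts(self, small_mixed):
        # 2 runs x 4 subruns = 8 t-patterns per condition per subject per kind
        assert small_mixed.t.shape[2:5] == (2, 4, 2)

    def test_no_signal_no_noise_identical_patterns(self):
        sc = vg.mixed_scenario(
            seed=4, n_subjects=1,
            map=vg.NeuralMapParams(a_col=0.0, a_rad=0.0, a_vert=0.0, **SMALL_MAP),
            noise=vg.NoiseParams(sigma_pattern=0.0, sigma_subject=0.0),
        )
        ds = vg.generate_dataset(sc)
        flat = ds.t.reshape(-1, ds.n_voxels)
        # all patterns equal within subject: contrast identically zero
        assert np.allclose(flat - flat[0], 0)

    def test_noise_sd_calibration(self):
        """Empirical per-voxel SD across noise-only subruns within 5% of sigma."""
        sc = vg.mixed_scenario(
            seed=6, n_subjects=256,  # 256 subjects x 16 patterns = 4096 noise draws
            map=vg.NeuralMapParams(a_col=0.0, a_rad=0.0, a_vert=0.0, **SMALL_MAP),
            noise=vg.NoiseParams(sigma_pattern=0.5, sigma_subject=0.0),
            kinds=("grating",),
        )
        ds = vg.generate_dataset(sc)
        resid = ds.t - ds.amplitudes[:, :, None, None, :, :]
        sd = resid.reshape(-1, ds.n_voxels).std(axis=0, ddof=1)
        assert np.all(np.abs(sd - 0.5) / 0.5 < 0.05)

    def test_scenario_determinism(self):
        sc = vg.mixed_scenario(seed=9, n_subjects=2, map=vg.NeuralMapParams(**SMALL_MAP))
        a = vg.generate_dataset(sc)
        b = vg.generate_dataset(sc)
        np.testing.assert_array_equal(a.t, b.t)

    def test_seed_required(self):
        sc = vg.mixed_scenario(seed=None, n_subjects=1)
        with pytest.raises(InvalidParameterError):
            vg.generate_dataset(sc)

    def test_gain_field_preserves_contrast_sign(self, small_coarse_noisefree):
        """Noise-free contrasts after voxel sampling are never inverted:
        in the coarse-only world every voxel keeps the reference-positive
        sign (the Fig-1-left signature, exhaustively)."""
        ds = small_coarse_noisefree
        for kind in ds.kinds:
            ref = reference_condition_index(ds, kind)
            sign = np.where(ref == 0, 1.0, -1.0)
            contrast = sign * (ds.amplitudes[:, ds.kind_index(kind), 0]
                               - ds.amplitudes[:, ds.kind_index(kind), 1])
            assert np.all(contrast > 0)

    def test_scenario_name_invariants(self):
        with pytest.raises(InvalidParameterError):
            vg.Scenario(name="coarse_only", map=vg.NeuralMapParams(a_col=0.5), seed=1)
        with pytest.raises(InvalidParameterError):
            vg.Scenario(name="fine_only", map=vg.NeuralMapParams(a_rad=0.01), seed=1)

    def test_fine_only_radial_proportion_near_half(self):
        """Without coarse biases the expected radial-preferring proportion
        is 50%: the t-interval over per-seed proportions must cover it."""
        from scipy import stats

        props = []
        for seed in range(12):
            sc = vg.fine_only_scenario(
                seed=100 + seed, n_subjects=2,
                map=vg.NeuralMapParams(a_rad=0, a_vert=0, **SMALL_MAP),
                kinds=("grating",),
            )
            ds = vg.generate_dataset(sc)
            summ = vg.preference_proportions(ds, "grating")
            props.append(summ.pooled_pct_ref)
        lo, hi = stats.t.interval(0.99, len(props) - 1,
                                  loc=np.mean(props), scale=stats.sem(props))
        assert lo <= 50.0 <= hi


class TestGenerateTimeseries:
    DESIGN = vg.BlockDesign()

    def test_zero_everything_zero_series(self):
        out = vg.generate_timeseries(
            self.DESIGN, np.zeros((2, 3)), vg.NoiseParams(0.0, 0.0), seed=0
        )
        assert out.shape == (self.DESIGN.volumes_per_run, 3)
        np.testing.assert_array_equal(out, 0)

    def test_single_block_matches_convolution_oracle(self):
        """One block, amplitude 1, no noise: equals direct-summation convolution."""
        from voxelgrain.glm import _boxcar, boynton_hrf

        design = vg.BlockDesign(subruns_per_run=1, blocks_per_subrun=2)
        amps = np.array([[1.0], [0.0]])
        out = vg.generate_timeseries(design, amps, vg.NoiseParams(0.0, 0.0), seed=0)
        box = _boxcar(design, 0, 0)
        kernel = boynton_hrf(vg.HrfParams(), dt=design.tr)
        n = design.volumes_per_run
        oracle = np.array([
            sum(box[j] * kernel[i - j] for j in range(n) if 0 <= i - j < len(kernel))
            for i in range(n)
        ])
        np.testing.assert_allclose(out[:, 0], oracle, atol=1e-10)

    def test_block_sequence_alternation(self):
        """Six blocks per subrun, three per condition, alternating, with the
        leading condition alternating across subruns."""
        onsets = self.DESIGN.block_onsets()
        for sub in range(4):
            conds = [c for (_, s, c) in onsets if s == sub]
            assert len(conds) == 6 and conds.count(0) == 3
            assert all(conds[i] != conds[i + 1] for i in range(5))
            assert conds[0] == sub % 2

    def test_timeseries_mode_dataset(self):
        """The end-to-end timeseries fidelity mode produces finite t-patterns
        of the same shape as pattern mode."""
        sc = vg.mixed_scenario(
            seed=13, n_subjects=1, mode="timeseries",
            map=vg.NeuralMapParams(**SMALL_MAP),
            noise=vg.NoiseParams(sigma_pattern=0.2, sigma_subject=0.0),
            kinds=("grating",),
        )
        ds = vg.generate_dataset(sc)
        assert ds.t.shape == (1, 1, 2, 4, 2, 64)
        assert np.all(np.isfinite(ds.t))
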