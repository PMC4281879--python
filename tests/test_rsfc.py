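"""Resting-state preprocessing and connectivity statistics."""

import numpy as np
import pytest
from scipy import stats

from handsym.imggeom import BinaryMask, BoldImage, ImageGrid, ScalarVolume
from handsym.rsfc import (
    FWHM_TO_SIGMA,
    fisher_z,
    gaussian_smooth,
    group_diff_map,
    highpass,
    preprocess_series,
    regress_out,
    roi_connectivity,
    seed_map,
    variance_controls,
)

TR = 2.41


class TestRegressOut:
    def test_self_regression_annihilates(self, rng):
        s = rng.standard_normal((1, 80))
        res = regress_out(s, s)
        assert np.linalg.norm(res) < 1e-8 * np.linalg.norm(s)

    def test_orthogonal_confound_leaves_series(self, rng):
        t = np.arange(64)
        series = np.sin(2 * np.pi * 5 * t / 64)[None, :]  # zero-mean
        conf = np.cos(2 * np.pi * 3 * t / 64)[None, :]  # orthogonal harmonic
        res = regress_out(series, conf)
        assert np.allclose(res, series, atol=1e-10)

    def test_normal_equations_oracle(self, rng):
        data = rng.standard_normal((5, 50))
        conf = rng.standard_normal((3, 50))
        X = np.column_stack([np.ones(50), conf.T])
        beta = np.linalg.inv(X.T @ X) @ X.T @ data.T
        expected = data - (X @ beta).T
        assert np.abs(regress_out(data, conf) - expected).max() < 1e-10

    def test_collinear_confounds_named(self, rng):
        c = rng.standard_normal(30)
        with pytest.raises(ValueError, match=r"collinear.*\[0, 1\]"):
            regress_out(rng.standard_normal((2, 30)), np.vstack([c, 2 * c]))


class TestHighpass:
    def test_constant_series_unchanged(self):
        data = np.full((2, 128), 7.0)
        assert np.allclose(highpass(data, TR), data)

    def test_fast_oscillation_preserved(self):
        t = np.arange(128) * TR
        sig = np.sin(2 * np.pi * t / 20.0)[None, :]  # 20 s period
        out = highpass(sig, TR, 150.0)
        # amplitude attenuation below 5 %
        assert np.linalg.norm(out) > 0.95 * np.linalg.norm(sig)

    def test_linear_drift_removed(self):
        t = np.arange(128, dtype=float)
        drift = (t / 127 - 0.5)[None, :]
        out = highpass(drift, TR, 150.0)
        assert np.linalg.norm(out) < 0.1 * np.linalg.norm(drift)

    def test_short_scan_warns(self):
        with pytest.warns(UserWarning, match="cutoff"):
            highpass(np.random.default_rng(0).standard_normal((1, 32)), TR, 150.0)


class TestGaussianSmooth:
    def test_zero_fwhm_identity(self, grid, rng):
        v = ScalarVolume(grid, rng.standard_normal(grid.shape))
        assert np.array_equal(gaussian_smooth(v, 0.0).data, v.data)

    def test_constant_volume_preserved(self, grid):
        v = ScalarVolume(grid, np.full(grid.shape, 3.25))
        assert np.allclose(gaussian_smooth(v, 8.0).data, 3.25, atol=1e-10)

    def test_impulse_matches_analytic_separable_kernel(self):
        grid = ImageGrid((25, 25, 25), (3.0, 3.0, 3.0))
        data = np.zeros(grid.shape)
        data[12, 12, 12] = 1.0
        out = gaussian_smooth(ScalarVolume(grid, data), 8.0).data
        sigma = 8.0 * FWHM_TO_SIGMA / 3.0
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1, dtype=float)
        k = np.exp(-(x ** 2) / (2 * sigma ** 2))
        k /= k.sum()
        kern = np.zeros(25)
        kern[12 - radius : 12 + radius + 1] = k
        expected = kern[:, None, None] * kern[None, :, None] * kern[None, None, :]
        assert np.abs(out - expected).max() < 1e-6

    def test_bold_smoothed_framewise(self, grid, rng):
        b = BoldImage(grid, rng.standard_normal((*grid.shape, 4)), tr=TR)
        out = gaussian_smooth(b, 6.0)
        for t in range(4):
            frame = gaussian_smooth(ScalarVolume(grid, b.data[..., t]), 6.0)
            assert np.allclose(out.data[..., t], frame.data, atol=1e-12)


class TestFisherZ:
    def test_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.66) == pytest.approx(0.7928, abs=1e-3)
        assert fisher_z(-0.4) == -fisher_z(0.4)

    def test_clamp_keeps_extremes_finite(self):
        assert np.isfinite(fisher_z(1.0)) and np.isfinite(fisher_z(-1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(0.999999))


def _toy_bold(rng, T=40):
    grid = ImageGrid((4, 2, 2))
    data = rng.standard_normal((*grid.shape, T))
    return grid, BoldImage(grid, data, tr=TR)


class TestSeedMap:
    def test_brute_force_oracle(self, rng):
        grid, bold = _toy_bold(rng)
        seed = BinaryMask(grid, np.zeros(grid.shape, bool))
        seed.data[0, 0, 0] = seed.data[0, 1, 0] = True
        brain = BinaryMask(grid, np.ones(grid.shape, bool))
        zmap = seed_map(bold, seed, brain)
        ref = bold.data[seed.data].mean(axis=0)
        for idx in np.ndindex(grid.shape):
            r = np.corrcoef(ref, bold.data[idx])[0, 1]
            assert zmap.data[idx] == pytest.approx(np.arctanh(np.clip(r, -0.999999, 0.999999)), abs=1e-12)

    def test_seed_voxel_reaches_clamped_extremes(self, rng):
        grid, bold = _toy_bold(rng)
        bold.data[1, 0, 0] = bold.data[0, 0, 0]
        bold.data[2, 0, 0] = -bold.data[0, 0, 0]
        seed = BinaryMask(grid, np.zeros(grid.shape, bool))
        seed.data[0, 0, 0] = True
        brain = BinaryMask(grid, np.ones(grid.shape, bool))
        zmap = seed_map(bold, seed, brain)
        zmax = np.arctanh(0.999999)
        assert zmap.data[1, 0, 0] == pytest.approx(zmax)
        assert zmap.data[2, 0, 0] == pytest.approx(-zmax)
        assert np.nanmax(np.abs(zmap.data)) <= zmax

    def test_constant_voxel_flagged_missing(self, rng):
        grid, bold = _toy_bold(rng)
        bold.data[3, 1, 1] = 5.0
        seed = BinaryMask(grid, np.zeros(grid.shape, bool))
        seed.data[0, 0, 0] = True
        brain = BinaryMask(grid, np.ones(grid.shape, bool))
        assert np.isnan(seed_map(bold, seed, brain).data[3, 1, 1])

    def test_constant_seed_rejected(self, rng):
        grid, bold = _toy_bold(rng)
        bold.data[0, 0, 0] = 1.0
        seed = BinaryMask(grid, np.zeros(grid.shape, bool))
        seed.data[0, 0, 0] = True
        with pytest.raises(ValueError):
            seed_map(bold, seed, BinaryMask(grid, np.ones(grid.shape, bool)))


class TestGroupDiffMap:
    def _maps(self, grid, rng, n, offset=0.0):
        return [
            ScalarVolume(grid, offset + rng.standard_normal(grid.shape)) for _ in range(n)
        ]

    def test_identical_groups_give_null_map(self, grid, rng):
        maps = self._maps(grid, rng, 3)
        brain = BinaryMask(grid, np.ones(grid.shape, bool))
        t, p = group_diff_map(maps, maps, brain)
        assert np.allclose(t.data, 0.0) and np.allclose(p.data, 1.0)

    def test_textbook_t_formula_oracle(self, grid, rng):
        g1 = self._maps(grid, rng, 4)
        g2 = self._maps(grid, rng, 6, offset=0.5)
        brain = BinaryMask(grid, np.ones(grid.shape, bool))
        t, p = group_diff_map(g1, g2, brain)
        a = np.stack([m.data for m in g1])
        b = np.stack([m.data for m in g2])
        sp2 = (3 * a.var(axis=0, ddof=1) + 5 * b.var(axis=0, ddof=1)) / 8
        expect_t = (b.mean(axis=0) - a.mean(axis=0)) / np.sqrt(sp2 * (1 / 4 + 1 / 6))
        assert np.abs(t.data - expect_t).max() < 1e-10
        assert np.allclose(p.data, 2 * stats.t.sf(np.abs(expect_t), 8), atol=1e-12)

    def test_swapping_groups_negates_t(self, grid, rng):
        g1 = self._maps(grid, rng, 3)
        g2 = self._maps(grid, rng, 4)
        brain = BinaryMask(grid, np.ones(grid.shape, bool))
        t12, _ = group_diff_map(g1, g2, brain)
        t21, _ = group_diff_map(g2, g1, brain)
        assert np.allclose(t12.data, -t21.data, atol=1e-12)

    def test_zero_variance_voxel_flagged(self, grid, rng):
        g1 = self._maps(grid, rng, 3)
        g2 = self._maps(grid, rng, 3)
        for m in (*g1, *g2):
            m.data[0, 0, 0] = 1.0
        brain = BinaryMask(grid, np.ones(grid.shape, bool))
        t, p = group_diff_map(g1, g2, brain)
        assert np.isnan(t.data[0, 0, 0]) and np.isnan(p.data[0, 0, 0])


class TestRoiConnectivity:
    def test_identical_rois_give_unit_r(self, rng):
        grid, bold = _toy_bold(rng)
        roi = BinaryMask(grid, np.zeros(grid.shape, bool))
        roi.data[0, :, :] = True
        cv = roi_connectivity(bold, roi, roi)
        assert cv.r == pytest.approx(1.0)

    def test_symmetry_in_arguments(self, rng):
        grid, bold = _toy_bold(rng)
        a = BinaryMask(grid, np.zeros(grid.shape, bool))
        b = BinaryMask(grid, np.zeros(grid.shape, bool))
        a.data[0, :, :] = True
        b.data[3, :, :] = True
        ab = roi_connectivity(bold, a, b)
        ba = roi_connectivity(bold, b, a)
        assert ab.r == pytest.approx(ba.r, abs=1e-12)
        assert ab.z == pytest.approx(ba.z, abs=1e-12)

    def test_independent_sources_average_to_zero(self, rng):
        grid = ImageGrid((2, 1, 1))
        a = BinaryMask(grid, np.array([[[True]], [[False]]]))
        b = BinaryMask(grid, np.array([[[False]], [[True]]]))
        rs = []
        for _ in range(500):
            bold = BoldImage(grid, rng.standard_normal((2, 1, 1, 128)), tr=TR)
            rs.append(roi_connectivity(bold, a, b).r)
        assert abs(np.mean(rs)) < 0.02

    def test_shared_source_attenuation_closed_form(self, rng):
        # r between s+n1 and s+n2 has expectation ~ 1/(1+sigma^2/var(s))
        grid = ImageGrid((2, 1, 1))
        a = BinaryMask(grid, np.array([[[True]], [[False]]]))
        b = BinaryMask(grid, np.array([[[False]], [[True]]]))
        sigma = 0.7
        rs = []
        for _ in range(400):
            s = rng.standard_normal(128)
            data = np.stack([s + sigma * rng.standard_normal(128),
                             s + sigma * rng.standard_normal(128)])
            bold = BoldImage(grid, data.reshape(2, 1, 1, 128), tr=TR)
            rs.append(roi_connectivity(bold, a, b).r)
        assert np.mean(rs) == pytest.approx(1 / (1 + sigma ** 2), abs=0.02)

    def test_constant_series_rejected(self, rng):
        grid, bold = _toy_bold(rng)
        bold.data[0] = 1.0
        a = BinaryMask(grid, np.zeros(grid.shape, bool))
        a.data[0, 0, 0] = True
        b = BinaryMask(grid, np.zeros(grid.shape, bool))
        b.data[3, 0, 0] = True
        with pytest.raises(ValueError):
            roi_connectivity(bold, a, b)


class TestVarianceControls:
    def test_shared_series_gives_equal_outputs(self, rng):
        grid = ImageGrid((3, 1, 1))
        s = rng.standard_normal(60)
        bold = BoldImage(grid, np.broadcast_to(s, (3, 1, 1, 60)).copy(), tr=TR)
        mask = BinaryMask(grid, np.ones(grid.shape, bool))
        vm, vv = variance_controls(bold, mask)
        assert vm == pytest.approx(s.var(ddof=1)) and vv == pytest.approx(s.var(ddof=1))

    def test_independent_voxels_shrink_mean_variance(self, rng):
        grid = ImageGrid((20, 1, 1))
        bold = BoldImage(grid, rng.standard_normal((20, 1, 1, 2000)), tr=TR)
        mask = BinaryMask(grid, np.ones(grid.shape, bool))
        vm, vv = variance_controls(bold, mask)
        assert vm == pytest.approx(1 / 20, rel=0.2)
        assert vv == pytest.approx(1.0, rel=0.05)

    def test_constant_image(self, grid):
        bold = BoldImage(grid, np.ones((*grid.shape, 10)), tr=TR)
        mask = BinaryMask(grid, np.ones(grid.shape, bool))
        assert variance_controls(bold, mask) == (0.0, 0.0)


class TestPreprocessSeries:
    def test_pure_nuisance_data_reduced_to_noise_floor(self, rng):
        # data = gains * confounds + sub-cutoff drift harmonics; cleaning
        # should leave essentially nothing
        T = 128
        t = np.arange(T)
        conf = rng.standard_normal((4, T))
        drift = np.vstack([np.cos(np.pi * (2 * t + 1) / (2 * T)),
                           np.cos(2 * np.pi * (2 * t + 1) / (2 * T))])
        gains = rng.standard_normal((6, 6))
        data = gains @ np.vstack([conf, drift])
        out = preprocess_series(data, conf, TR, 150.0)
        assert np.linalg.norm(out) < 1e-6 * np.linalg.norm(data)

    def test_linear_drift_strongly_attenuated(self):
        T = 128
        drift = (np.arange(T) / (T - 1) - 0.5)[None, :]
        conf = np.cos(np.pi * 11 * (2 * np.arange(T) + 1) / (2 * T))[None, :]
        out = preprocess_series(drift, conf, TR, 150.0)
        assert np.linalg.norm(out) < 0.1 * np.linalg.norm(drift)

    def test_deterministic(self, rng):
        data = rng.standard_normal((3, 128))
        conf = rng.standard_normal((2, 128))
        assert np.array_equal(
            preprocess_series(data, conf, TR), preprocess_series(data, conf, TR)
        )
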