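"""Unit and property tests for the fMRI metric chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from oculobrain import fmri
from oculobrain.errors import CollinearityError, InputError
from oculobrain.fmri import (
    MetricMap,
    NuisanceDesign,
    VoxelTimeSeriesVolume,
    build_group_gm_mask,
    compute_falff,
    compute_kcc,
    compute_reho_map,
    detrend_linear,
    discard_initial_volumes,
    expand_friston24,
    gaussian_smooth,
    regress_nuisance,
    standardize_map,
)


def _vol(data, tr=2.0):
    return VoxelTimeSeriesVolume(data=np.asarray(data, float),
                                 affine=np.eye(4), tr=tr)


class TestDiscardInitialVolumes:
    def test_185_minus_10_gives_175(self, rng):
        vol = _vol(rng.normal(size=(2, 2, 2, 185)))
        assert discard_initial_volumes(vol, 10).n_volumes == 175

    def test_discard_zero_is_identity(self, small_volume):
        out = discard_initial_volumes(small_volume, 0)
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_remaining_frames_unchanged(self, rng):
        vol = _vol(rng.normal(size=(2, 2, 1, 12)))
        out = discard_initial_volumes(vol, 10)
        assert out.n_volumes == 2
        np.testing.assert_array_equal(out.data, vol.data[..., 10:])

    def test_discarding_all_frames_is_an_error(self, rng):
        vol = _vol(rng.normal(size=(2, 2, 2, 5)))
        with pytest.raises(InputError):
            discard_initial_volumes(vol, 5)


class TestDetrendLinear:
    @pytest.mark.parametrize("series", [
        3.0 + 0.5 * np.arange(20),   # pure ramp
        np.full(20, 7.3),            # constant
    ])
    def test_linear_signals_vanish(self, series):
        assert np.abs(detrend_linear(series)).max() < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        t = np.arange(50, dtype=float)
        y = 2.0 + 0.3 * t + np.sin(0.4 * t)
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(detrend_linear(y), y - X @ beta, atol=1e-10)

    def test_residual_orthogonal_to_trend(self, rng):
        y = rng.normal(size=(4, 80))
        r = detrend_linear(y, axis=-1)
        t = np.arange(80) - 39.5
        assert np.abs(r.mean(axis=-1)).max() < 1e-10
        assert np.abs(r @ t).max() / np.abs(y).max() < 1e-8

    def test_too_short_is_an_error(self):
        with pytest.raises(InputError):
            detrend_linear(np.array([1.0, 2.0]))


class TestFriston24:
    def test_zero_motion_gives_zero_columns(self):
        assert not expand_friston24(np.zeros((10, 6))).any()

    def test_single_entry_expands_to_four_cells(self):
        m = np.zeros((6, 6))
        m[3, 2] = 2.0
        out = expand_friston24(m)
        nz = sorted(zip(*np.nonzero(out)))
        assert nz == [(3, 2), (3, 8), (4, 14), (4, 20)]
        assert out[3, 2] == 2.0 and out[3, 8] == 4.0
        assert out[4, 14] == 2.0 and out[4, 20] == 4.0

    def test_first_lagged_row_is_zero(self, rng):
        out = expand_friston24(rng.normal(size=(15, 6)))
        assert not out[0, 12:].any()

    def test_wrong_column_count_is_an_error(self):
        with pytest.raises(InputError):
            expand_friston24(np.zeros((10, 5)))


class TestRegressNuisance:
    def _design(self, rng, t=40, k=4):
        X = np.column_stack([np.ones(t), rng.normal(size=(t, k))])
        return NuisanceDesign(X, ["intercept"] + [f"r{i}" for i in range(k)])

    def test_regressor_itself_maps_to_zero(self, rng):
        d = self._design(rng)
        resid = regress_nuisance(d.matrix[:, 2], d)
        assert np.abs(resid).max() < 1e-10

    def test_orthogonal_series_passes_through(self, rng):
        d = self._design(rng)
        q, _ = np.linalg.qr(d.matrix)
        y = rng.normal(size=40)
        y -= q @ (q.T @ y)  # exactly orthogonal to design span
        np.testing.assert_allclose(regress_nuisance(y, d), y, atol=1e-10)

    def test_matches_lstsq_oracle(self, rng):
        d = self._design(rng)
        y = rng.normal(size=40)
        beta, *_ = np.linalg.lstsq(d.matrix, y, rcond=None)
        np.testing.assert_allclose(regress_nuisance(y, d), y - d.matrix @ beta,
                                   atol=1e-8)
        resid = regress_nuisance(y, d)
        assert np.abs(d.matrix.T @ resid).max() < 1e-8

    def test_collinear_design_names_columns(self, rng):
        X = rng.normal(size=(30, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        d = NuisanceDesign(X, ["a", "b", "c", "a_plus_b"])
        with pytest.raises(CollinearityError) as exc:
            regress_nuisance(rng.normal(size=30), d)
        assert exc.value.columns


class TestFalff:
    def test_on_bin_in_band_sinusoid_is_one(self):
        n, tr = 175, 2.0
        t = np.arange(n) * tr
        f = 7 / (n * tr)  # 0.02 Hz, an exact DFT bin inside the band
        assert compute_falff(np.sin(2 * np.pi * f * t), tr) == pytest.approx(1.0)

    def test_out_of_band_sinusoid_is_zero(self):
        n, tr = 175, 2.0
        t = np.arange(n) * tr
        f = 60 / (n * tr)  # 0.171 Hz, outside 0.01-0.1
        assert compute_falff(np.sin(2 * np.pi * f * t), tr) == pytest.approx(0.0, abs=1e-10)

    def test_white_noise_expectation_matches_bin_fraction(self, rng):
        # E[FALFF] of white noise ~ (# band bins) / (# positive bins) = 32/87
        n, tr = 175, 2.0
        x = rng.normal(size=(10_000, n))
        amp = np.abs(np.fft.rfft(x, axis=1))
        freqs = np.fft.rfftfreq(n, tr)
        pos, band = freqs > 0, (freqs >= 0.01) & (freqs <= 0.1)
        mc = (amp[:, pos & band].sum(1) / amp[:, pos].sum(1)).mean()
        single = np.mean([compute_falff(x[i], tr) for i in range(200)])
        assert mc == pytest.approx(32 / 87, abs=0.005)
        assert single == pytest.approx(mc, abs=0.01)

    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_bounded_and_scale_invariant(self, seed, scale):
        x = np.random.default_rng(seed).normal(size=64)
        v = compute_falff(x, 2.0)
        assert 0.0 <= v <= 1.0
        assert compute_falff(scale * x, 2.0) == pytest.approx(v, rel=1e-9)

    def test_bad_band_is_an_error(self):
        with pytest.raises(InputError):
            compute_falff(np.random.default_rng(0).normal(size=64), 2.0,
                          band=(0.1, 0.5))  # above Nyquist 0.25


def _kcc_bruteforce(series):
    """Independent textbook computation of tie-corrected W."""
    k, n = series.shape
    R = np.zeros(n)
    T = 0.0
    for j in range(k):
        R += rankdata(series[j])
        _, c = np.unique(series[j], return_counts=True)
        T += float(((c ** 3 - c)[c > 1]).sum())
    S = ((R - R.mean()) ** 2).sum()
    return 12.0 * S / (k ** 2 * (n ** 3 - n) - k * T)


class TestKcc:
    def test_identical_monotone_series_give_one(self):
        s = np.tile(np.arange(10.0), (5, 1))
        assert compute_kcc(s) == pytest.approx(1.0)

    def test_hand_enumerable_3x3_instance(self):
        # ranks per series: [1,2,3], [2,1,3], [1,3,2] -> rank sums [4,6,8]
        s = np.array([[10.0, 20.0, 30.0], [5.0, 1.0, 9.0], [0.1, 0.9, 0.5]])
        S = (4 - 6) ** 2 + (6 - 6) ** 2 + (8 - 6) ** 2  # = 8
        expected = 12 * S / (9 * (27 - 3))  # no ties
        assert compute_kcc(s) == pytest.approx(expected)
        assert compute_kcc(s) == pytest.approx(_kcc_bruteforce(s))

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_with_ties(self, trial):
        rng = np.random.default_rng(trial)
        k, n = rng.integers(2, 6), rng.integers(2, 7)
        s = rng.integers(0, 4, size=(k, n)).astype(float)
        if np.ptp(s, axis=1).max() == 0:
            s[0, 0] += 1.0
        assert compute_kcc(s) == pytest.approx(_kcc_bruteforce(s), abs=1e-12)

    def test_constant_series_degenerate_to_zero_with_warning(self):
        s = np.ones((3, 5))
        with pytest.warns(UserWarning, match="degenerate"):
            assert compute_kcc(s) == 0.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        s = np.random.default_rng(seed).normal(size=(4, 12))
        assert compute_kcc(np.exp(s)) == pytest.approx(compute_kcc(s), abs=1e-12)
        assert 0.0 <= compute_kcc(s) <= 1.0

    def test_null_neighborhood_level_matches_theory(self, rng):
        # independent series, k=27, n=175: E[W] ~ 1/27
        ws = [compute_kcc(rng.normal(size=(27, 175))) for _ in range(100)]
        assert np.mean(ws) == pytest.approx(1 / 27, abs=0.002)


class TestRehoMap:
    def test_shared_monotone_series_gives_one_in_interior(self):
        data = np.zeros((5, 5, 3, 8)) + np.arange(8.0)
        vol = _vol(data)
        mask = np.ones((5, 5, 3), bool)
        out = compute_reho_map(vol, mask)
        assert out.data[2, 2, 1] == pytest.approx(1.0)
        assert (out.data > 0.99).all()

    def test_noise_volume_interior_values_are_small(self, rng):
        vol = _vol(rng.normal(size=(7, 7, 5, 175)))
        mask = np.ones((7, 7, 5), bool)
        out = compute_reho_map(vol, mask)
        interior = out.data[2:-2, 2:-2, 2]
        assert interior.mean() == pytest.approx(1 / 27, abs=0.01)

    def test_single_voxel_mask_is_zero_with_warning(self, rng):
        vol = _vol(rng.normal(size=(3, 3, 3, 20)))
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with pytest.warns(UserWarning, match="degenerate"):
            out = compute_reho_map(vol, mask)
        assert out.data[1, 1, 1] == 0.0

    def test_empty_mask_is_an_error(self, small_volume):
        with pytest.raises(InputError):
            compute_reho_map(small_volume, np.zeros((6, 6, 4), bool))


class TestStandardizeMap:
    def test_constant_map_becomes_ones(self):
        m = MetricMap(np.full((3, 3, 3), 4.2), np.eye(4), "FALFF")
        out = standardize_map(m, np.ones((3, 3, 3), bool))
        np.testing.assert_allclose(out.data, 1.0)

    def test_two_voxel_hand_example(self):
        m = MetricMap(np.array([[[2.0, 4.0]]]), np.eye(4), "FALFF")
        out = standardize_map(m, np.ones((1, 1, 2), bool))
        np.testing.assert_allclose(out.data.ravel(), [2 / 3, 4 / 3])

    def test_mask_mean_is_one_and_idempotent(self, rng):
        m = MetricMap(rng.uniform(0.5, 2.0, size=(4, 4, 4)), np.eye(4), "ReHo")
        mask = rng.random((4, 4, 4)) > 0.3
        out = standardize_map(m, mask)
        assert out.data[mask].mean() == pytest.approx(1.0, abs=1e-12)
        again = standardize_map(out, mask)
        np.testing.assert_allclose(again.data, out.data, atol=1e-12)

    def test_zero_mean_is_an_error(self):
        m = MetricMap(np.zeros((2, 2, 2)), np.eye(4), "FALFF")
        with pytest.raises(InputError):
            standardize_map(m, np.ones((2, 2, 2), bool))


class TestGaussianSmooth:
    def test_fwhm_zero_is_identity(self, rng):
        m = MetricMap(rng.normal(size=(5, 5, 5)), np.diag([3, 3, 3, 1.0]), "FALFF")
        out = gaussian_smooth(m, 0.0)
        np.testing.assert_array_equal(out.data, m.data)

    def test_impulse_response_sums_to_one(self):
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 1.0
        m = MetricMap(data, np.diag([3, 3, 3, 1.0]), "FALFF")
        out = gaussian_smooth(m, 4.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_dense_convolution_oracle(self, rng):
        m = MetricMap(rng.normal(size=(9, 9, 9)), np.diag([3, 3, 3, 1.0]), "FALFF")
        sigma = 4.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        r = int(4.0 * sigma + 0.5)  # same truncation radius as the implementation
        ax = np.arange(-r, r + 1)
        k1 = np.exp(-ax ** 2 / (2 * sigma ** 2))
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        padded = np.pad(m.data, r)
        dense = np.zeros_like(m.data)
        for i in range(9):
            for j in range(9):
                for l in range(9):
                    block = padded[i:i + 2 * r + 1, j:j + 2 * r + 1, l:l + 2 * r + 1]
                    dense[i, j, l] = (block * kernel[::-1, ::-1, ::-1]).sum()
        out = gaussian_smooth(m, 4.0)
        np.testing.assert_allclose(out.data, dense, atol=1e-8)

    def test_negative_fwhm_is_an_error(self, rng):
        m = MetricMap(rng.normal(size=(3, 3, 3)), np.eye(4), "FALFF")
        with pytest.raises(InputError):
            gaussian_smooth(m, -1.0)


class TestGroupGmMask:
    def test_constant_maps_above_threshold_full(self):
        maps = [np.full((3, 3, 2), 0.5)] * 4
        assert build_group_gm_mask(maps, 0.2).all()

    def test_constant_maps_below_threshold_empty(self):
        maps = [np.full((3, 3, 2), 0.1)] * 4
        assert not build_group_gm_mask(maps, 0.2).any()

    def test_mean_at_boundary_is_included(self):
        a, b = np.full((2, 2, 2), 0.1), np.full((2, 2, 2), 0.4)
        assert build_group_gm_mask([a, b], 0.2).all()  # mean 0.25 >= 0.2

    def test_grid_mismatch_is_an_error(self):
        with pytest.raises(InputError):
            build_group_gm_mask([np.zeros((2, 2, 2)), np.zeros((3, 2, 2))])


def test_full_chain_is_deterministic(rng, small_volume):
    motion = pd.DataFrame(np.cumsum(rng.normal(0, 0.02, size=(60, 6)), axis=0))
    gm = np.full((6, 6, 4), 0.8)
    a = fmri.compute_subject_metric_maps(small_volume, motion, gm, n_discard=5)
    b = fmri.compute_subject_metric_maps(small_volume, motion, gm, n_discard=5)
    np.testing.assert_array_equal(a["FALFF"].data, b["FALFF"].data)
    np.testing.assert_array_equal(a["ReHo"].data, b["ReHo"].data)
    # standardized: in-mask mean is 1
    assert a["FALFF"].data[gm >= 0.5].mean() == pytest.approx(1.0, abs=1e-9)
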