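"""Tests for the two-stage regression engine."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from oculobrain import association, synthetic
from oculobrain.association import (
    SignificanceMask,
    find_peak,
    fit_mlr,
    run_group_pair_analysis,
    stage1_roiwise,
    stage1_voxelwise,
    stage2,
)
from oculobrain.errors import CollinearityError, InputError


def _cov_frame(rng, n):
    return pd.DataFrame({
        "age": rng.normal(66, 5, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "education": rng.normal(12, 2, n),
        "hypertension": rng.integers(0, 2, n).astype(float),
        "diabetes": rng.integers(0, 2, n).astype(float),
    })


class TestFitMlr:
    def test_noiseless_fit_recovers_slope_exactly(self, rng):
        x = rng.normal(size=30)
        cov = rng.normal(size=(30, 5))
        fit = fit_mlr(2.0 * x, x, cov)
        assert fit.beta[1] == pytest.approx(2.0, abs=1e-10)
        assert fit.p < 1e-12

    def test_eight_observation_hand_dataset_matches_normal_equations(self):
        y = np.array([3.1, 4.0, 5.2, 4.8, 6.1, 5.9, 7.2, 8.0])
        x = np.array([1.0, 2.0, 2.5, 3.0, 4.0, 4.5, 5.5, 6.0])
        cov = np.array([[0.2], [0.1], [0.5], [0.3], [0.9], [0.7], [0.4], [0.8]])
        X = np.column_stack([np.ones(8), x, cov])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_mlr(y, x, cov)
        np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-10)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_statsmodels_ols(self, trial):
        rng = np.random.default_rng(trial)
        n, k = int(rng.integers(20, 60)), int(rng.integers(1, 6))
        x, y = rng.normal(size=n), rng.normal(size=n)
        cov = rng.normal(size=(n, k))
        fit = fit_mlr(y, x, cov)
        ref = sm.OLS(y, sm.add_constant(np.column_stack([x, cov]))).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-10)
        assert fit.t == pytest.approx(ref.tvalues[1], abs=1e-10)
        assert fit.p == pytest.approx(ref.pvalues[1], abs=1e-12)

    def test_null_p_values_reject_at_nominal_rate(self, rng):
        n_rep, n = 1000, 40
        cov = rng.normal(size=(n, 3))
        x = rng.normal(size=n)
        ps = np.array([fit_mlr(rng.normal(size=n), x, cov).p for _ in range(n_rep)])
        rate = (ps < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * se
        # uniformity of the whole distribution
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_collinear_design_names_columns(self, rng):
        x = rng.normal(size=30)
        cov = np.column_stack([rng.normal(size=30), x])  # duplicate of x_obj
        with pytest.raises(CollinearityError) as exc:
            fit_mlr(rng.normal(size=30), x, cov, ["noise", "copy_of_x"])
        assert exc.value.columns

    def test_uncorrelated_covariate_barely_moves_beta1(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        extra = rng.normal(size=(n, 3))
        b_small = fit_mlr(y, x, cov).beta[1]
        b_big = fit_mlr(y, x, np.column_stack([cov, extra])).beta[1]
        assert abs(b_big - b_small) < 0.05


def _voxel_setup(rng, n=40, shape=(4, 4, 3)):
    gm = np.ones(shape, bool)
    maps = [rng.normal(size=shape) for _ in range(n)]
    cov = _cov_frame(rng, n)
    y = rng.normal(size=n)
    return maps, y, cov, gm


class TestStage1Voxelwise:
    def test_alpha_one_selects_every_in_mask_voxel(self, rng):
        maps, y, cov, gm = _voxel_setup(rng)
        m = stage1_voxelwise(maps, y, cov, gm, alpha=1.0, n_perm=100)
        assert m.n_selected == gm.sum()

    def test_low_n_perm_warns(self, rng):
        maps, y, cov, gm = _voxel_setup(rng)
        with pytest.warns(UserWarning, match="n_perm"):
            stage1_voxelwise(maps, y, cov, gm, n_perm=50)

    def test_empty_mask_is_an_error(self, rng):
        maps, y, cov, gm = _voxel_setup(rng)
        with pytest.raises(InputError):
            stage1_voxelwise(maps, y, cov, np.zeros_like(gm), n_perm=100)

    def test_stat_map_matches_per_voxel_fit(self, rng):
        maps, y, cov, gm = _voxel_setup(rng)
        m = stage1_voxelwise(maps, y, cov, gm, n_perm=100)
        data = np.stack([mm for mm in maps])
        for idx in [(0, 0, 0), (2, 3, 1), (3, 1, 2)]:
            fit = fit_mlr(y, data[(slice(None),) + idx], cov.to_numpy())
            assert m.stat_map[idx] == pytest.approx(fit.t, abs=1e-9)


class TestStage1RoiWise:
    def _setup(self, rng, n=80):
        from oculobrain.dkt import DKT_LABELS
        thickness = pd.DataFrame(rng.normal(2.5, 0.1, size=(n, 62)),
                                 columns=list(DKT_LABELS))
        cov = _cov_frame(rng, n)
        cov["etiv"] = rng.normal(1.45e6, 1e5, n)
        return thickness, rng.normal(size=n), cov

    def test_validates_62_roi_columns(self, rng):
        thickness, y, cov = self._setup(rng)
        assert len(thickness.columns) == 62
        with pytest.raises(InputError, match="missing ROI"):
            stage1_roiwise(thickness.drop(columns=["left insula"]), y, cov)

    def test_boundary_p_equal_to_threshold_is_not_selected(self, rng):
        thickness, y, cov = self._setup(rng)
        m = stage1_roiwise(thickness, y, cov)
        ps = m.correction["p"]
        roi = int(np.argmin(ps))
        # re-run with the threshold set exactly at that ROI's p: strict '<'
        m2 = stage1_roiwise(thickness, y, cov, threshold=float(ps[roi]))
        assert not m2.selected[roi]

    def test_planted_effect_recovered_and_specific(self):
        cfg = synthetic.CohortConfig(seed=5)
        cfg.group_sizes = {"HC": 75, "SCD": 75, "MCI": 75, "AD": 75}
        cfg.effects = [synthetic.PlantedEffect(
            brain_channel="thickness", roi_label="right fusiform",
            blob_center=None, brain_slope=0.08,
            cognitive_score="MMSE", cognitive_slope=1.2)]
        cohort = synthetic.generate_cohort(cfg)
        tab = synthetic.subjects_table(cohort)
        thickness = synthetic.cohort_thickness_table(cohort, cfg)
        cov = tab[["age", "sex", "education", "hypertension", "diabetes", "etiv"]]
        m = stage1_roiwise(thickness, tab["MMSE"], cov)
        assert m.selected[m.domain.index("right fusiform")]


class TestStage2:
    def test_empty_stage1_gives_empty_result_with_warning(self, rng):
        maps, y, cov, gm = _voxel_setup(rng)
        m1 = SignificanceMask(domain=gm, selected=np.zeros_like(gm),
                              stat_map=np.zeros(gm.shape), correction={},
                              stage="stage1-voxelwise")
        with pytest.warns(UserWarning, match="empty"):
            m2, fits = stage2(maps, y, cov, m1, n_perm=100)
        assert m2.n_selected == 0 and fits == []

    def test_exact_linear_biometric_selects_whole_mask(self, rng):
        maps, _, cov, gm = _voxel_setup(rng)
        sel = np.zeros_like(gm)
        sel[1, 1, 1] = sel[2, 2, 2] = True
        m1 = SignificanceMask(domain=gm, selected=sel,
                              stat_map=np.ones(gm.shape), correction={},
                              stage="stage1-voxelwise")
        data = np.stack(maps)
        biometric = 3.0 * data[:, 1, 1, 1]  # exact function of one voxel metric
        m2, _ = stage2(maps, biometric, cov, m1, n_perm=100)
        assert m2.selected[1, 1, 1]
        assert m2.n_selected >= 1

    def test_stage2_never_escapes_stage1(self, rng):
        maps, y, cov, gm = _voxel_setup(rng)
        m1 = stage1_voxelwise(maps, y, cov, gm, alpha=0.5, n_perm=200, seed=1)
        if m1.n_selected:
            m2, _ = stage2(maps, rng.normal(size=len(maps)), cov, m1,
                           alpha=0.5, n_perm=200, seed=2)
            assert not (m2.selected & ~m1.selected).any()


class TestFindPeak:
    def _mask(self, stat, sel):
        return SignificanceMask(domain=np.ones_like(sel, dtype=bool),
                                selected=sel, stat_map=stat,
                                correction={}, stage="stage2")

    def test_single_selected_voxel(self):
        stat = np.zeros((3, 3, 3))
        sel = np.zeros((3, 3, 3), bool)
        sel[1, 2, 0] = True
        stat[1, 2, 0] = -4.2
        peak = find_peak(self._mask(stat, sel))
        assert peak.voxel_index == (1, 2, 0)
        assert peak.peak_abs_t == pytest.approx(4.2)

    def test_tie_resolves_to_lowest_linear_index(self):
        stat = np.zeros((2, 2, 2))
        sel = np.ones((2, 2, 2), bool)
        stat[0, 1, 0] = 5.0
        stat[1, 0, 1] = -5.0
        assert find_peak(self._mask(stat, sel)).voxel_index == (0, 1, 0)

    def test_matches_exhaustive_scan(self, rng):
        stat = rng.normal(size=(4, 4, 4))
        sel = rng.random((4, 4, 4)) > 0.4
        peak = find_peak(self._mask(stat, sel))
        best = max(np.argwhere(sel), key=lambda ijk: (abs(stat[tuple(ijk)]),))
        # exhaustive scan with the same tie rule
        best_val = max(abs(stat[sel]))
        assert peak.peak_abs_t == pytest.approx(best_val)
        assert abs(stat[peak.voxel_index]) == pytest.approx(best_val)

    def test_world_coordinates_follow_affine(self):
        stat = np.zeros((3, 3, 3))
        sel = np.zeros((3, 3, 3), bool)
        sel[2, 1, 0] = True
        stat[2, 1, 0] = 3.0
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = [-30, -30, -18]
        peak = find_peak(self._mask(stat, sel), affine=affine)
        assert peak.world_mm == pytest.approx((-24.0, -27.0, -18.0))

    def test_empty_selection_is_an_error(self):
        with pytest.raises(InputError):
            find_peak(self._mask(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool)))


class TestGroupPairAnalysis:
    def test_absent_group_is_an_error(self, tiny_cohort_config):
        tab = synthetic.subjects_table(synthetic.generate_cohort(tiny_cohort_config))
        with pytest.raises(InputError, match="absent"):
            run_group_pair_analysis(tab.loc[tab["group"] != "AD"], ("HC", "AD"),
                                    thickness=None, metric_maps=None)

    def test_sign_recovery_and_determinism(self):
        # disease lowers the latent; thickness and GCL-IPL both fall with it,
        # so the stage-2 slope of GCL-IPL on ROI thickness is positive
        cfg = synthetic.CohortConfig(seed=21)
        cfg.group_sizes = {"HC": 40, "SCD": 5, "MCI": 40, "AD": 5}
        cfg.effects = [synthetic.PlantedEffect(
            brain_channel="thickness", roi_label="left superiortemporal",
            blob_center=None, brain_slope=0.1,
            cognitive_score="BDST", cognitive_slope=1.2,
            ocular_biometric="gcl_ipl_thickness_um", ocular_slope=3.0)]
        cohort = synthetic.generate_cohort(cfg)
        tab = synthetic.subjects_table(cohort)
        tab["gcl_ipl_thickness_um"] = tab["target_gcl_ipl_thickness_um"]
        thickness = synthetic.cohort_thickness_table(cohort, cfg)
        rep = run_group_pair_analysis(
            tab, ("HC", "MCI"), thickness=thickness,
            scores=("BDST",), biometrics=("gcl_ipl_thickness_um",), seed=3)
        hits = [s2 for res in rep["results"] for s2 in res["stage2"]
                if s2["n_selected"]]
        assert hits, "planted ROI association not detected"
        assert hits[0]["beta1_sign"] == 1
        assert hits[0]["peak"]["roi_label"] == "left superiortemporal"
        rep2 = run_group_pair_analysis(
            tab, ("HC", "MCI"), thickness=thickness,
            scores=("BDST",), biometrics=("gcl_ipl_thickness_um",), seed=3)
        assert rep == rep2
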