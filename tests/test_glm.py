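"""Design construction, OLS fitting, contrasts, cluster correction,
framewise displacement and motion scrubbing."""

import numpy as np
import pytest
from scipy import stats as sstats

from swdkit.eeg import SeizureInterval, StimulationBlock
from swdkit.glm import (build_design, cluster_correct, condition_regressors,
                        f_contrast, fit_glm, framewise_displacement,
                        mask_f_with_t, roi_extreme_beta_test,
                        scrub_stimulations)

TR = 2.0


def _frames(n):
    return np.arange(n) * TR


def _blocks(onsets, label, dur=6.0):
    return [StimulationBlock(o, dur, label=label) for o in onsets]


class TestBuildDesign:
    def test_three_regressors_per_condition(self, basis):
        """Two modeled conditions give 3 + 3 effect columns; motion and
        intercept are flagged as confounds."""
        blocks = (_blocks([20.0, 100.0], "baseline")
                  + _blocks([60.0, 140.0], "fully_inside"))
        motion = np.zeros((100, 6))
        design = build_design(blocks, [], motion, basis, _frames(100))
        eff = design.columns[~design.columns["confound"]]
        assert len(eff) == 6
        assert set(eff["condition"]) == {"interictal_stim", "ictal_stim"}
        for cond in ("interictal_stim", "ictal_stim"):
            assert len(design.condition_columns(cond)) == 3
        conf = design.columns[design.columns["confound"]]
        assert conf["name"].str.startswith("motion").sum() == 6
        assert "intercept" in conf["name"].values

    def test_empty_seizure_list_gives_interictal_only_design(self, basis):
        design = build_design(_blocks([20.0], "baseline"), [], None, basis,
                              _frames(40))
        assert design.effect_conditions == ["interictal_stim"]

    def test_solo_seizures_become_a_condition(self, basis):
        blocks = _blocks([20.0], "baseline")
        seiz = [SeizureInterval(60.0, 66.0), SeizureInterval(22.0, 25.0)]
        design = build_design(blocks, seiz, None, basis, _frames(50))
        # the 60-66 s seizure has no overlapping block; the 22-25 s one does
        cols = design.condition_columns("seizure")
        assert len(cols) == 3
        reg = design.matrix[:, cols[0]]
        assert np.argmax(reg) > 30  # response follows the solo seizure only

    def test_regressor_matches_dense_convolution_oracle(self, basis):
        """The 6 s block regressor equals a brute-force dense-grid
        convolution of its boxcar with each basis column."""
        events = [(20.0, 6.0)]
        frames = _frames(40)
        reg = condition_regressors(events, basis, frames)
        dt = TR / 50
        t = np.arange(0, frames[-1] + TR, dt)
        box = ((t >= 20.0) & (t < 26.0)).astype(float)
        for k, (shape, scale) in enumerate(basis.shapes):
            mode = (shape - 1) * scale
            h = sstats.gamma.pdf(t, a=shape, scale=scale)
            h /= sstats.gamma.pdf(mode, a=shape, scale=scale)
            h[t > basis.duration] = 0.0  # the basis kernel ends at `duration`
            conv = np.convolve(box, h)[: t.size] * dt
            brute = conv[np.round(frames / dt).astype(int)]
            assert np.allclose(reg[:, k], brute, atol=1e-9)

    def test_unlabeled_blocks_rejected(self, basis):
        with pytest.raises(ValueError, match="classified"):
            build_design([StimulationBlock(10.0, 6.0)], [], None, basis,
                         _frames(20))

    def test_nonuniform_frames_rejected(self, basis):
        with pytest.raises(ValueError, match="uniform"):
            build_design(_blocks([5.0], "baseline"), [], None, basis,
                         np.array([0.0, 2.0, 5.0]))


class TestFitGLM:
    def test_exact_recovery_on_noise_free_data(self, basis, rng):
        blocks = _blocks([20.0, 80.0], "baseline")
        design = build_design(blocks, [], None, basis, _frames(60))
        beta_true = rng.normal(size=(design.matrix.shape[1], 30))
        data = design.matrix @ beta_true
        fit = fit_glm(data, design)
        assert np.allclose(fit.betas, beta_true, atol=1e-8)
        assert np.allclose(fit.resid_var, 0.0, atol=1e-16)

    def test_null_t_statistic_follows_student_t(self, basis, rng):
        """On pure Gaussian noise the effect-beta t statistic follows
        Student t with the fit's dof (KS p > 0.01 across 10^4 voxels)."""
        blocks = _blocks([20.0, 80.0], "baseline")
        design = build_design(blocks, [], None, basis, _frames(60))
        data = rng.standard_normal((60, 10_000))
        fit = fit_glm(data, design)
        j = design.condition_columns("interictal_stim")[0]
        se = np.sqrt(fit.xtx_inv[j, j] * fit.resid_var)
        t = fit.betas[j] / se
        ks = sstats.kstest(t, "t", args=(fit.dof,))
        assert ks.pvalue > 0.01

    def test_orthogonal_confound_leaves_betas_unchanged(self, basis):
        blocks = _blocks([20.0], "baseline")
        frames = _frames(50)
        design = build_design(blocks, [], None, basis, frames)
        rng = np.random.default_rng(7)
        data = rng.standard_normal((50, 20))
        fit0 = fit_glm(data, design)
        X = design.matrix
        extra = rng.standard_normal(50)
        # orthogonalize against every existing column
        extra -= X @ np.linalg.lstsq(X, extra, rcond=None)[0]
        import pandas as pd

        cols = pd.concat([design.columns, pd.DataFrame(
            [{"name": "extra", "condition": None, "basis_index": None,
              "confound": True}])], ignore_index=True)
        from swdkit.glm import DesignMatrix

        design2 = DesignMatrix(matrix=np.column_stack([X, extra]),
                               columns=cols, frame_times=frames, basis=basis)
        fit2 = fit_glm(data, design2)
        assert np.allclose(fit2.betas[: X.shape[1]], fit0.betas, atol=1e-8)

    def test_rank_deficient_design_names_columns(self, basis):
        blocks = _blocks([20.0], "baseline")
        design = build_design(blocks, [], None, basis, _frames(40))
        design.matrix[:, -1] = design.matrix[:, 0]  # duplicate a column
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(np.zeros((40, 4)), design)

    def test_summary_lists_regressors(self, basis):
        design = build_design(_blocks([10.0], "baseline"), [], None, basis,
                              _frames(30))
        fit = fit_glm(np.random.default_rng(0).standard_normal((30, 5)), design)
        summ = fit.summary(voxel=0)
        assert {"regressor", "beta", "se", "t"} <= set(summ.columns)
        assert len(summ) == design.matrix.shape[1]


class TestFContrast:
    def _fit(self, rng, n=60, v=500, extra_cond=False):
        blocks = _blocks([20.0, 80.0], "baseline")
        if extra_cond:
            blocks += _blocks([50.0], "fully_inside")
        basis = __import__("swdkit.signals", fromlist=["gamma_basis"]).gamma_basis(TR=TR)
        design = build_design(blocks, [], None, basis, _frames(n))
        return design, rng.standard_normal((n, v))

    def test_single_column_contrast_equals_t_squared(self, basis, rng):
        design, data = self._fit(rng)
        fit = fit_glm(data, design)
        j = design.condition_columns("interictal_stim")[0]
        se = np.sqrt(fit.xtx_inv[j, j] * fit.resid_var)
        t = fit.betas[j] / se
        from swdkit.glm import ContrastResult, _contrast_matrix  # noqa: F401

        C = np.zeros((1, design.matrix.shape[1]))
        C[0, j] = 1.0
        cb = C @ fit.betas
        M = C @ fit.xtx_inv @ C.T
        F = (cb[0] ** 2 / M[0, 0]) / fit.resid_var
        assert np.allclose(F, t**2, rtol=1e-10)

    def test_null_false_positive_rate(self, basis, rng):
        design, data = self._fit(rng, v=4000)
        res = f_contrast(fit_glm(data, design), "interictal_stim")
        for alpha in (0.05, 0.01):
            frac = np.mean(res.p < alpha)
            assert frac == pytest.approx(alpha, abs=3 * np.sqrt(alpha / 4000) + 0.005)

    def test_injected_effect_dominates_null_voxels(self, basis, rng):
        design, data = self._fit(rng, v=500)
        cols = design.condition_columns("interictal_stim")
        data[:, :50] += (design.matrix[:, cols] @ np.array([3.0, 1.0, 0.5]))[:, None]
        res = f_contrast(fit_glm(data, design), "interictal_stim")
        assert res.F[:50].min() > np.median(res.F[50:])

    def test_difference_contrast_sign(self, basis, rng):
        design, data = self._fit(rng, extra_cond=True)
        ca = design.condition_columns("interictal_stim")
        data += design.matrix[:, ca] @ np.array([2.0, 0.0, 0.0])[:, None] @ np.ones((1, data.shape[1]))
        res = f_contrast(fit_glm(data, design), ("interictal_stim", "ictal_stim"))
        assert np.mean(res.t_first > 0) > 0.95

    def test_missing_condition_rejected(self, basis, rng):
        design, data = self._fit(rng)
        fit = fit_glm(data, design)
        with pytest.raises(ValueError, match="not present"):
            f_contrast(fit, "nope")


class TestClusterCorrect:
    dims = (12, 12, 6)

    def _setup(self, rng, effect=0.0):
        from swdkit.signals import gamma_basis

        basis = gamma_basis(TR=TR)
        blocks = _blocks([20.0, 60.0, 100.0], "baseline")
        design = build_design(blocks, [], None, basis, _frames(70))
        n_vox = int(np.prod(self.dims))
        data = rng.standard_normal((70, n_vox))
        blob = np.zeros(self.dims, dtype=bool)
        blob[4:9, 4:9, 2:5] = True
        if effect:
            cols = design.condition_columns("interictal_stim")
            sig = design.matrix[:, cols] @ np.array([effect, 0.3 * effect, 0.0])
            data[:, blob.ravel()] += sig[:, None]
        return design, data, blob

    def test_all_zero_map_gives_empty_mask(self, rng):
        design, data, _ = self._setup(rng)
        mask, table = cluster_correct(np.zeros(self.dims), 0.01, 50, 0.05,
                                      data=data, design=design,
                                      condition="interictal_stim", seed=0)
        assert not mask.any()
        assert table.empty

    def test_single_voxel_cluster_rejected(self, rng):
        design, data, _ = self._setup(rng)
        fmap = f_contrast(fit_glm(data, design), "interictal_stim").F.reshape(self.dims)
        # force exactly one extreme voxel
        fmap[6, 6, 3] = 1e6
        mask, table = cluster_correct(fmap, 0.001, 99, 0.05, data=data,
                                      design=design,
                                      condition="interictal_stim", seed=1)
        assert not mask[6, 6, 3] or table.loc[table["size"] == 1, "significant"].eq(False).all()

    def test_recovers_injected_blob(self, rng):
        """A 5x5x3 activation blob survives correction with Dice >= 0.8."""
        design, data, blob = self._setup(rng, effect=1.2)
        fmap = f_contrast(fit_glm(data, design), "interictal_stim").F.reshape(self.dims)
        mask, table = cluster_correct(fmap, 0.01, 99, 0.05, data=data,
                                      design=design,
                                      condition="interictal_stim", seed=2)
        inter = np.sum(mask & blob)
        dice = 2 * inter / (mask.sum() + blob.sum())
        assert dice >= 0.8

    def test_too_few_permutations_rejected(self, rng):
        design, data, _ = self._setup(rng)
        with pytest.raises(ValueError, match="permutations"):
            cluster_correct(np.zeros(self.dims), 0.01, 10, 0.05, data=data,
                            design=design, condition="interictal_stim")


class TestMaskFWithT:
    def test_nonpositive_t_empties_mask(self):
        f_mask = np.ones((3, 3, 3), dtype=bool)
        assert not mask_f_with_t(f_mask, -np.ones((3, 3, 3))).any()

    def test_positive_t_preserves_mask(self, rng):
        f_mask = rng.random((3, 3, 3)) > 0.5
        out = mask_f_with_t(f_mask, np.ones((3, 3, 3)))
        assert np.array_equal(out, f_mask)

    def test_mixed_signs_elementwise(self, rng):
        f_mask = rng.random((4, 4, 2)) > 0.4
        t = rng.normal(size=(4, 4, 2))
        out = mask_f_with_t(f_mask, t)
        assert np.array_equal(out, f_mask & (t > 0))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            mask_f_with_t(np.ones((2, 2, 2), dtype=bool), np.ones((3, 3, 3)))


class TestFramewiseDisplacement:
    def test_constant_parameters_give_zero(self):
        assert np.allclose(framewise_displacement(np.ones((10, 6))), 0.0)

    def test_single_translation_step(self):
        m = np.zeros((5, 6))
        m[2:, 0] = 1.0  # 1 mm x jump between frames 1 and 2
        fd = framewise_displacement(m)
        assert fd[2] == pytest.approx(1.0)
        assert fd[1] == 0.0 and fd[3] == 0.0

    def test_rotation_conversion_modes(self):
        """1 degree about one axis: 5*pi/180 mm in standard mode, 0.2 in
        the divide-by-radius mode."""
        m = np.zeros((4, 6))
        m[2:, 3] = 1.0
        fd_std = framewise_displacement(m, mode="standard")
        fd_lit = framewise_displacement(m, mode="divide_by_radius")
        assert fd_std[2] == pytest.approx(5 * np.pi / 180, rel=1e-9)
        assert fd_lit[2] == pytest.approx(0.2, rel=1e-9)

    def test_first_frame_is_zero(self, rng):
        fd = framewise_displacement(rng.normal(size=(8, 6)))
        assert fd[0] == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            framewise_displacement(np.zeros((3, 6)), mode="bogus")


class TestScrubStimulations:
    def _blocks(self):
        return [StimulationBlock(4.0, 6.0, label="baseline"),
                StimulationBlock(30.0, 6.0, label="baseline")]

    def test_zero_motion_retains_all(self):
        kept = scrub_stimulations(self._blocks(), np.zeros(30), TR=2.0,
                                  voxel_size_mm=0.5)
        assert len(kept) == 2

    def test_spiking_block_dropped(self):
        metric = np.zeros(30)
        metric[16] = 0.01  # 10 um spike at t = 32 s, inside block 2
        kept = scrub_stimulations(self._blocks(), metric, TR=2.0,
                                  voxel_size_mm=0.5)
        assert [b.onset for b in kept] == [4.0]

    def test_infinite_threshold_is_identity(self):
        metric = np.full(30, 100.0)
        kept = scrub_stimulations(self._blocks(), metric, TR=2.0,
                                  voxel_size_mm=0.5,
                                  threshold_fraction=np.inf)
        assert len(kept) == 2


class TestRoiExtremeBetaTest:
    def test_identical_groups_give_null_result(self):
        out = roi_extreme_beta_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_shifted_groups_significant(self):
        out = roi_extreme_beta_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert out["p"] < 0.01

    def test_matches_textbook_formula(self):
        a = np.array([2.1, 3.0, 1.2, 2.8])
        b = np.array([4.0, 5.1, 4.4])
        out = roi_extreme_beta_test(list(a), list(b))
        sp = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                     / (a.size + b.size - 2))
        t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(1 / a.size + 1 / b.size))
        assert out["t"] == pytest.approx(t_hand, rel=1e-9)

    def test_accepts_hrf_curves(self, basis):
        from swdkit.signals import hrf_from_betas

        a = [hrf_from_betas([2.0 + 0.1 * k, 0.0, 0.0], basis) for k in range(3)]
        b = [hrf_from_betas([-6.0 - 0.1 * k, 0.0, 0.0], basis) for k in range(3)]
        out = roi_extreme_beta_test(a, b)
        assert out["mean_a"] > 0 > out["mean_b"]
        assert out["p"] < 0.01

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            roi_extreme_beta_test([1.0, 1.0], [2.0, 2.0])

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError, match="sessions"):
            roi_extreme_beta_test([1.0], [2.0, 3.0])
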