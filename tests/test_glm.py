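import numpy as np
import pytest

from blockmvpa.design import make_block_design
from blockmvpa.glm import (BetaResult, RobustWLS, build_design_matrix,
                           canonical_hrf, contrast_image, dct_drift_basis,
                           fit_glm, hrf_kernel, nonsocial_contrast_weights,
                           social_contrast_weights)


class TestHRF:
    def test_zero_at_onset(self):
        assert canonical_hrf(0.0) == 0.0

    def test_peak_near_five_seconds(self):
        t = np.arange(0.0, 32.0, 0.1)
        assert abs(t[np.argmax(canonical_hrf(t))] - 5.0) <= 0.2

    def test_unit_peak_and_decayed_tail(self):
        t = np.arange(0.0, 32.0, 0.1)
        h = canonical_hrf(t)
        assert abs(h.max() - 1.0) < 1e-12
        assert abs(canonical_hrf(32.0)) < 0.01

    def test_invalid_shape_parameters(self):
        with pytest.raises(ValueError):
            canonical_hrf(1.0, peak_delay=-1.0)
        with pytest.raises(ValueError):
            canonical_hrf(-0.5)


class TestDesignMatrix:
    def test_column_bookkeeping_ds_variant(self, ds_design):
        X = build_design_matrix(ds_design, motion=np.zeros((ds_design.n_volumes, 6)),
                                spike_frames=[10, 40])
        k_drift = dct_drift_basis(ds_design.n_volumes, ds_design.tr, 100.0).shape[1]
        assert X.matrix.shape[1] == 16 + 6 + 2 + k_drift + 1
        assert len(X.task_columns) == 16
        spikes = [n for n in X.names if n.startswith("spike")]
        for name in spikes:
            col = X.matrix[:, X.names.index(name)]
            assert np.count_nonzero(col) == 1 and col.max() == 1.0

    def test_drift_basis_absorbs_slow_sinusoid(self, ds_design):
        n, tr = ds_design.n_volumes, ds_design.tr
        t = np.arange(n) * tr
        slow = np.sin(2 * np.pi * t / 300.0)
        basis = np.column_stack([dct_drift_basis(n, tr, 100.0), np.ones(n)])
        resid = slow - basis @ np.linalg.lstsq(basis, slow, rcond=None)[0]
        assert resid.var() < 0.01 * slow.var()

    def test_block_regressor_matches_direct_convolution(self):
        d = make_block_design(1, 4, targets=("faces",), seed=0)
        X = build_design_matrix(d, highpass_cutoff=1e9)
        # independent oracle: discrete convolution on a 10x oversampled grid
        block = d.blocks[0]
        dt = d.tr / 10
        n_fine = d.n_volumes * 10
        t_fine = np.arange(n_fine) * dt
        box = ((t_fine >= block.onset) & (t_fine < block.offset)).astype(float)
        h = hrf_kernel(dt)
        oracle = (np.convolve(box, h)[:n_fine] * dt)[::10]
        col = X.matrix[:, X.task_columns[0]]
        assert np.max(np.abs(col - oracle)) < 1e-10

    def test_block_outside_scan_rejected(self, ds_design):
        from blockmvpa.glm import block_regressors
        bad = ds_design.__class__(blocks=ds_design.blocks, tr=ds_design.tr,
                                  n_volumes=ds_design.n_volumes)
        object.__setattr__(bad, "n_volumes", 10)
        with pytest.raises(ValueError, match="outside"):
            block_regressors(bad)

    def test_wrong_motion_shape_rejected(self, ds_design):
        with pytest.raises(ValueError, match="motion"):
            build_design_matrix(ds_design, motion=np.zeros((5, 6)))


class TestEstimation:
    def test_noiseless_recovery_is_exact(self, ds_design):
        rng = np.random.default_rng(0)
        X = build_design_matrix(ds_design)
        beta_true = rng.normal(size=(X.matrix.shape[1], 50))
        series = X.matrix @ beta_true
        res = fit_glm(series, X, robust=True)
        assert np.max(np.abs(res.betas - beta_true)) < 1e-8

    def test_robust_matches_ols_under_homoscedastic_noise(self, ds_design):
        rng = np.random.default_rng(1)
        X = build_design_matrix(ds_design)
        n_vox = 5000  # timepoint variances pool across voxels; weights
        beta_true = rng.normal(size=(X.matrix.shape[1], n_vox))
        series = X.matrix @ beta_true + rng.normal(0, 1.0, size=(X.n_volumes, n_vox))
        robust = fit_glm(series, X, robust=True).betas
        ols = fit_glm(series, X, robust=False).betas
        denom = np.sqrt(np.mean(ols ** 2))
        assert np.sqrt(np.mean((robust - ols) ** 2)) < 0.02 * denom

    def test_robust_beats_ols_under_spiky_noise(self):
        rng = np.random.default_rng(2)
        n, p, v = 80, 5, 40
        X = np.column_stack([rng.normal(size=(n, p - 1)), np.ones(n)])
        rmse_r, rmse_o = [], []
        for _ in range(100):
            beta = rng.normal(size=(p, v))
            noise = rng.normal(0, 1.0, size=(n, v))
            spikes = rng.choice(n, size=4, replace=False)
            noise[spikes] *= 10.0
            Y = X @ beta + noise
            est_r = RobustWLS(robust=True).fit(X, Y).coef_.T
            est_o = RobustWLS(robust=False).fit(X, Y).coef_.T
            rmse_r.append(np.sqrt(np.mean((est_r - beta) ** 2)))
            rmse_o.append(np.sqrt(np.mean((est_o - beta) ** 2)))
        assert np.mean(rmse_r) < np.mean(rmse_o)

    def test_rank_deficiency_names_columns(self):
        X = np.ones((20, 3))
        X[:, 0] = np.arange(20)
        X[:, 2] = X[:, 1]  # duplicate column
        with pytest.raises(ValueError, match="rank deficient"):
            RobustWLS().fit(X, np.zeros(20))

    def test_sklearn_estimator_contract(self):
        est = RobustWLS(robust=False)
        assert est.get_params() == {"robust": False, "n_iter": 2, "tol": 1e-6}
        est.set_params(robust=True)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        pred = est.fit(X, y).predict(X)
        assert pred.shape == (30, 1)


class TestContrasts:
    def _result(self, names, betas):
        return BetaResult(betas=betas, names=names)

    def test_social_contrast_weights_sum_to_zero(self, fitted_subject):
        _, _, res = fitted_subject
        w = social_contrast_weights(res.names)
        assert abs(w.sum()) < 1e-15
        assert (w != 0).sum() == 16

    def test_null_and_unit_shift_contrasts(self, ds_design):
        X = build_design_matrix(ds_design)
        n_reg = X.matrix.shape[1]
        betas = np.ones((n_reg, 10))
        res = self._result(X.names, betas)
        w = social_contrast_weights(res.names)
        assert np.allclose(contrast_image(res, w), 0.0)
        betas2 = betas.copy()
        for i in X.task_columns:
            if X.names[i].startswith("why"):
                betas2[i] += 1.0
        assert np.allclose(contrast_image(self._result(X.names, betas2), w), 1.0)

    def test_contrast_matches_hand_computed_values(self, fitted_subject):
        _, _, res = fitted_subject
        w = social_contrast_weights(res.names)
        img = contrast_image(res, w)
        why_idx = [i for i, n in enumerate(res.names)
                   if n.startswith("why") and "_block" in n]
        how_idx = [i for i, n in enumerate(res.names)
                   if n.startswith("how") and "_block" in n]
        for vox in [0, 7, 50, 123, 215]:
            hand = res.betas[why_idx, vox].mean() - res.betas[how_idx, vox].mean()
            assert abs(img[vox] - hand) < 1e-12

    def test_missing_nonsocial_condition_raises(self, fitted_subject):
        _, _, res = fitted_subject
        with pytest.raises(ValueError, match="nonsocial"):
            nonsocial_contrast_weights(res.names)
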