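import numpy as np
import pandas as pd
import pytest

from pairdiff.estimation import (
    HRFSpec,
    PatternEstimates,
    RankDeficientDesignError,
    RoiMask,
    SelectivityMap,
    build_design_matrix,
    fit_glm,
    highpass_filter,
    localizer_contrast,
    scene_events,
    select_voxels,
)


class TestHRF:
    def test_peak_normalized_and_causal(self):
        hrf = HRFSpec()
        t = np.arange(0, 32, 0.1)
        vals = hrf.sample(t)
        assert vals.max() == pytest.approx(1.0, abs=1e-9)
        assert np.all(hrf.sample(np.array([-5.0, -0.1])) == 0)
        # positive peak near 5 s, undershoot after ~10 s
        assert 3 < t[np.argmax(vals)] < 7
        assert vals[t > 12].min() < 0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            HRFSpec(peak_delay=-1)


class TestDesignMatrix:
    def test_single_impulse_equals_sampled_hrf(self):
        hrf = HRFSpec()
        events = pd.DataFrame({"onset": [0.0], "duration": [0.5], "name": ["a"]})
        dm = build_design_matrix(events, hrf, tr=2.0, n_timepoints=16, add_intercept=False)
        np.testing.assert_allclose(dm.column("a"), hrf.sample(np.arange(16) * 2.0))

    def test_linearity_two_events(self):
        hrf = HRFSpec()
        ev2 = pd.DataFrame({"onset": [4.0, 20.0], "duration": [0.5, 0.5], "name": ["a", "a"]})
        dm = build_design_matrix(ev2, hrf, tr=2.0, n_timepoints=32, add_intercept=False)
        t = np.arange(32) * 2.0
        np.testing.assert_allclose(
            dm.column("a"), hrf.sample(t - 4.0) + hrf.sample(t - 20.0), atol=1e-12
        )

    def test_full_run_has_72_scene_regressors(self, default_sequence):
        events = scene_events(default_sequence, 0)
        dm = build_design_matrix(events, HRFSpec(), tr=2.0, n_timepoints=192)
        scene_cols = [n for n in dm.names if n.startswith("scene")]
        assert len(scene_cols) == 72
        assert "intercept" in dm.names

    def test_boxcar_mode(self):
        hrf = HRFSpec()
        events = pd.DataFrame({"onset": [10.0], "duration": [6.0], "name": ["block"]})
        dm = build_design_matrix(
            events, hrf, tr=2.0, n_timepoints=40, events_as="boxcar", add_intercept=False
        )
        col = dm.column("block")
        # boxcar response integrates more energy than a single impulse
        imp = build_design_matrix(
            events, hrf, tr=2.0, n_timepoints=40, events_as="impulse", add_intercept=False
        ).column("block")
        assert col.max() > imp.max()
        # oracle: direct Riemann integral of the HRF over the block
        t_grid = np.arange(40) * 2.0
        fine = np.arange(10.0, 16.0, 0.001)
        expected = np.array([np.trapezoid(hrf.sample(tt - fine), dx=0.001) for tt in t_grid])
        np.testing.assert_allclose(col, expected, atol=5e-3)

    def test_event_beyond_window_rejected(self):
        events = pd.DataFrame({"onset": [100.0], "duration": [0.5], "name": ["a"]})
        with pytest.raises(ValueError, match="outside scan window"):
            build_design_matrix(events, HRFSpec(), tr=2.0, n_timepoints=16)


class TestHighpass:
    def test_constant_maps_to_zero(self):
        data = np.full((3, 120), 7.0)
        out = highpass_filter(data, sigma=64.0, tr=2.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_linear_ramp_maps_to_zero(self):
        t = np.arange(120, dtype=float)
        data = np.vstack([2.0 * t + 5.0, -0.3 * t])
        out = highpass_filter(data, sigma=64.0, tr=2.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_transfer_function(self):
        """Slow drifts (period >> sigma) are removed; fast signal
        (period << sigma) passes nearly unchanged."""
        n, tr = 512, 2.0
        t = np.arange(n) * tr
        slow = np.sin(2 * np.pi * t / 800.0)
        fast = np.sin(2 * np.pi * t / 16.0)
        out = highpass_filter(np.vstack([slow, fast]), sigma=64.0, tr=tr)
        interior = slice(50, -50)  # avoid edge effects of the local fit
        slow_ratio = out[0, interior].std() / slow[interior].std()
        fast_ratio = out[1, interior].std() / fast[interior].std()
        assert slow_ratio < 0.2
        assert fast_ratio > 0.9

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            highpass_filter(np.zeros((1, 10)), sigma=0.0, tr=2.0)


def _toy_design(n, p, seed):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    from pairdiff.estimation import DesignMatrix

    return DesignMatrix(matrix=X, names=tuple(f"c{j}" for j in range(p)), tr=1.0)


class TestGlm:
    def test_matches_closed_form_ols_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            dm = _toy_design(20, 5, seed)
            X = dm.matrix
            Y = rng.standard_normal((20, 3))
            est = fit_glm(Y.T, dm, prewhiten="none")
            # independent closed-form (X'X)^-1 X'y oracle
            XtX_inv = np.linalg.inv(X.T @ X)
            beta_o = XtX_inv @ X.T @ Y
            resid = Y - X @ beta_o
            sig2 = (resid**2).sum(axis=0) / (20 - 5)
            se_o = np.sqrt(np.outer(np.diag(XtX_inv), sig2))
            np.testing.assert_allclose(est.beta, beta_o, atol=1e-10)
            np.testing.assert_allclose(est.se, se_o, atol=1e-10)
            np.testing.assert_allclose(est.tmap, beta_o / se_o, atol=1e-8)

    def test_noiseless_exact_and_capped(self):
        dm = _toy_design(30, 4, 1)
        b = np.array([1.0, -2.0, 0.5, 3.0])
        y = dm.matrix @ b
        est = fit_glm(y[None, :], dm, prewhiten="none")
        np.testing.assert_allclose(est.beta[:, 0], b, atol=1e-10)
        assert est.tmap_capped.all()
        assert np.all(np.abs(est.tmap) <= 1e6)

    def test_rank_deficient_names_columns(self):
        from pairdiff.estimation import DesignMatrix

        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        dm = DesignMatrix(matrix=X, names=("intercept", "a", "b_dup"), tr=1.0)
        with pytest.raises(RankDeficientDesignError, match="b_dup|a"):
            fit_glm(rng.standard_normal((1, 20)), dm)

    def test_prewhitening_improves_efficiency(self):
        """Monte-Carlo: under AR(1) noise the prewhitened estimator's
        sampling variance is no larger than OLS's (200 sims as voxels)."""
        n, phi, n_sims = 120, 0.6, 200
        rng = np.random.default_rng(7)
        dm = _toy_design(n, 2, 3)
        X = dm.matrix
        b = np.array([0.0, 1.0])
        eps = rng.standard_normal((n_sims, n))
        noise = np.empty_like(eps)
        noise[:, 0] = eps[:, 0]
        for t in range(1, n):
            noise[:, t] = phi * noise[:, t - 1] + np.sqrt(1 - phi**2) * eps[:, t]
        Y = (X @ b)[None, :] + noise  # (n_sims, n) = voxels
        est_ols = fit_glm(Y, dm, prewhiten="none")
        est_ar = fit_glm(Y, dm, prewhiten="ar1")
        var_ols = est_ols.beta[1].var()
        var_ar = est_ar.beta[1].var()
        assert var_ar <= var_ols * 1.05

    def test_multirun_fixed_effects(self):
        rng = np.random.default_rng(2)
        dm = _toy_design(40, 3, 2)
        b = np.array([0.5, 1.0, -1.0])
        runs = [
            (dm.matrix @ b + 0.5 * rng.standard_normal(40))[None, :] for _ in range(4)
        ]
        est = fit_glm(runs, [dm] * 4)
        single = fit_glm(runs[0], dm)
        assert est.dof == 4 * (40 - 3)
        assert np.all(est.se < single.se)  # pooling shrinks uncertainty
        np.testing.assert_allclose(est.beta[:, 0], b, atol=0.4)


class TestLocalizerContrast:
    def _category_estimates(self, means, sigma2, n=40):
        """Hand-built estimates for 3 category regressors + intercept."""
        names = ("scene", "face", "object", "intercept")
        beta = np.asarray(means, dtype=float).reshape(4, -1)
        V = beta.shape[1]
        cov = np.eye(4) / n  # orthogonal design proxy
        se = np.sqrt(np.outer(np.diag(cov), np.full(V, sigma2)))
        return PatternEstimates(
            names=names, beta=beta, se=se, tmap=beta / se, dof=100.0,
            sigma2=np.full(V, sigma2), cov_unscaled=cov,
            tmap_capped=np.zeros_like(beta, dtype=bool),
        )

    def test_hand_computed_z(self):
        est = self._category_estimates([[3.0], [1.0], [1.0], [0.0]], sigma2=4.0, n=40)
        sm = localizer_contrast(est, {"scene": 1.0, "face": -0.5, "object": -0.5})
        # oracle: effect = 2, var = (1 + .25 + .25)/40 * 4 = 0.15
        assert sm.z[0] == pytest.approx(2.0 / np.sqrt(0.15), rel=1e-12)

    def test_equal_means_give_zero(self):
        est = self._category_estimates([[2.0], [2.0], [2.0], [0.0]], sigma2=1.0)
        sm = localizer_contrast(est, {"scene": 1.0, "face": -0.5, "object": -0.5})
        assert sm.z[0] == pytest.approx(0.0, abs=1e-12)

    def test_scene_selective_voxel_large_positive(self, small_sequence, small_stimset):
        est = self._category_estimates([[10.0], [0.0], [0.0], [0.0]], sigma2=0.01)
        sm = localizer_contrast(est, {"scene": 1.0, "face": -0.5, "object": -0.5})
        assert sm.z[0] > 50

    def test_nonzero_sum_rejected(self):
        est = self._category_estimates([[1.0], [1.0], [1.0], [0.0]], sigma2=1.0)
        with pytest.raises(ValueError, match="sum to 0"):
            localizer_contrast(est, {"scene": 1.0, "face": -0.5})


class TestSelectVoxels:
    def test_threshold(self):
        sm = SelectivityMap(z=np.array([0.5, 1.2, 3.5]))
        mask = select_voxels(sm, mode="threshold", z_min=1.0)
        assert mask.n_voxels == 2
        np.testing.assert_array_equal(mask.mask, [False, True, True])

    def test_threshold_strict_inequality(self):
        sm = SelectivityMap(z=np.array([1.0, 1.5]))
        mask = select_voxels(sm, mode="threshold", z_min=1.0)
        np.testing.assert_array_equal(mask.mask, [False, True])

    def test_empty_roi_advises_lower_threshold(self):
        sm = SelectivityMap(z=np.array([0.1, 0.2]))
        with pytest.raises(ValueError, match="lower threshold"):
            select_voxels(sm, mode="threshold", z_min=3.0)

    def test_terciles_even(self, rng):
        z = rng.standard_normal(9)
        masks = select_voxels(SelectivityMap(z=z), mode="tercile")
        assert [m.n_voxels for m in masks] == [3, 3, 3]
        assert z[masks[0].mask].max() < z[masks[1].mask].min() < z[masks[2].mask].min()

    def test_tercile_remainder_to_lowest(self, rng):
        z = rng.standard_normal(10)
        masks = select_voxels(SelectivityMap(z=z), mode="tercile")
        assert [m.n_voxels for m in masks] == [4, 3, 3]
        assert [m.tercile for m in masks] == [1, 2, 3]

    def test_tercile_partition(self, rng):
        z = rng.standard_normal(11)
        masks = select_voxels(SelectivityMap(z=z), mode="tercile")
        total = np.zeros(11, dtype=int)
        for m in masks:
            total += m.mask.astype(int)
        assert (total == 1).all()

    def test_permutation_equivariance(self, rng):
        z = rng.standard_normal(12)
        perm = rng.permutation(12)
        masks = select_voxels(SelectivityMap(z=z), mode="tercile")
        masks_p = select_voxels(SelectivityMap(z=z[perm]), mode="tercile")
        for m, mp in zip(masks, masks_p):
            np.testing.assert_array_equal(m.mask[perm], mp.mask)
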