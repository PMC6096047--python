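"""Design construction, grand-mean scaling and the prewhitened GLM."""

import numpy as np
import pytest

from mvblife.cohort import (CohortSpec, NoiseSpec, ROIDataset,
                            generate_cohort, generate_trial_table)
from mvblife.design import (DesignMatrix, ScanParams, build_design_matrix,
                            contrast_vector, scale_grand_mean)
from mvblife.glm import FirstLevelGLM, contrast_effect_map, univariate_summary


def _ltm_design(age=40.0, seed=0, **kw):
    rng = np.random.default_rng(seed)
    trials = generate_trial_table("LTM", age, seed=rng)
    params = ScanParams(tr=1.97, n_scans_per_session=320).with_motion(rng, 2)
    return build_design_matrix(trials, params, **kw)


class TestDesignMatrix:
    def test_ltm_column_inventory(self):
        d = _ltm_design()
        names = [l.split("/")[1] for l in d.labels if l.startswith("s1/")]
        assert sum(n.startswith("scene_") for n in names) == 3
        assert sum(n.startswith("epoch_") for n in names) == 6
        assert names.count("keypress") == 1
        assert sum(n.startswith("motion") for n in names) == 6
        assert "constant" in names
        # epoch columns define the feature-selection F contrast
        feats = [d.labels[i] for i in d.feature_column_indices]
        assert all("epoch_" in f for f in feats) and len(feats) == 12

    def test_task_confound_partition(self):
        d = _ltm_design()
        both = set(d.task_column_indices) & set(d.confound_column_indices)
        assert not both
        assert len(d.task_column_indices) + len(d.confound_column_indices) \
            == d.n_regressors

    def test_cosine_basis_count_matches_cutoff(self):
        d = _ltm_design()
        n_drift = sum("drift" in l for l in d.labels if l.startswith("s1/"))
        t_session = 1.97 * 320
        assert n_drift == int(np.floor(2 * t_session / 128.0))

    def test_highpass_absorbs_slow_drift(self):
        """A 300 s-period sinusoid added to the data barely moves the epoch
        betas: the truncated per-session cosine basis absorbs an
        off-harmonic slow drift up to a small truncation residual (a few
        percent of its amplitude at the prescribed basis order)."""
        spec = CohortSpec(n_subjects=1, scenario="null", n_voxels_per_roi=10,
                          noise=NoiseSpec(0.0, 0.0, 0.0), rng_seed=2)
        s = generate_cohort(spec)[0]
        base = FirstLevelGLM(s.data, s.design).fit()
        amp = 5.0
        tvec = s.design.tr * np.arange(s.data.n_scans)
        drifted = ROIDataset(
            data=s.data.data + amp * np.sin(2 * np.pi * tvec / 300.0)[:, None],
            voxel_mm=s.data.voxel_mm, roi_labels=s.data.roi_labels,
            session_index=s.data.session_index, tr=s.data.tr)
        drift_fit = FirstLevelGLM(drifted, s.design).fit()
        epochs = s.design.feature_column_indices
        change = np.abs(drift_fit.betas[epochs] - base.betas[epochs]).max()
        assert change < 0.03 * amp

    def test_missing_condition_flagged_and_contrast_fails(self):
        spec = CohortSpec(memory_prob_fn=lambda age: 1.0)
        rng = np.random.default_rng(0)
        trials = generate_trial_table("LTM", 30.0, spec, seed=rng)
        d = build_design_matrix(
            trials, ScanParams(tr=1.97, n_scans_per_session=320))
        assert any("forgotten" in m for m in d.missing_conditions)
        with pytest.raises(ValueError, match="forgotten"):
            contrast_vector(d, "subsequent_memory")

    def test_onsets_beyond_scan_window_rejected(self):
        rng = np.random.default_rng(0)
        trials = generate_trial_table("LTM", 30.0, seed=rng)
        with pytest.raises(ValueError, match="scan window"):
            build_design_matrix(trials, ScanParams(tr=1.97, n_scans_per_session=100))


class TestContrasts:
    def test_weights_proportional_to_trial_counts(self):
        d = _ltm_design(seed=5)
        c = contrast_vector(d, "subsequent_memory")
        counts = d.trial_counts
        rem_total = counts.loc[counts["mem"] == "remembered", "n"].sum()
        row = counts[counts["mem"] == "remembered"].iloc[0]
        lab = f"s{row['session']}/epoch_{row['valence']}_remembered"
        assert c[d.column(lab)] == pytest.approx(row["n"] / rem_total)
        # weights sum to +1 on remembered, -1 on forgotten
        assert c[c > 0].sum() == pytest.approx(1.0)
        assert c[c < 0].sum() == pytest.approx(-1.0)

    def test_load_linear_contrast(self):
        rng = np.random.default_rng(1)
        trials = generate_trial_table("STM", 44.0, seed=rng)
        d = build_design_matrix(trials, ScanParams(tr=2.0, n_scans_per_session=340))
        c = contrast_vector(d, "load_linear")
        assert c[d.column("s1/maint_1")] == pytest.approx(-1 / 3)
        assert c[d.column("s1/maint_2")] == 0.0
        assert c[d.column("s2/maint_3")] == pytest.approx(1 / 3)

    def test_identical_condition_betas_give_null_effect(self, noiseless_subject):
        s = noiseless_subject
        fit = FirstLevelGLM(s.data, s.design).fit()
        # null scenario at zero noise: remembered/forgotten differ only via
        # the generative amplitude; zero it out by symmetric contrast on a
        # beta matrix with equal condition values
        c = contrast_vector(s.design, "subsequent_memory")
        effects = contrast_effect_map(fit, c)
        uni = s.truth.univariate_amplitude["PVC"]
        pvc = s.data.roi_indices("PVC")
        expected = uni + s.truth.differential[pvc]
        np.testing.assert_allclose(effects[pvc], expected, atol=1e-8)


class TestScaling:
    def _dataset(self, data, tr=2.0, sessions=None):
        n, v = data.shape
        return ROIDataset(data=data, voxel_mm=np.zeros((v, 3)),
                          roi_labels=np.array(["PVC"] * v),
                          session_index=sessions if sessions is not None
                          else np.ones(n, int), tr=tr)

    def test_constant_becomes_target(self):
        ds = self._dataset(np.full((10, 3), 50.0))
        out = scale_grand_mean(ds)
        np.testing.assert_allclose(out.data, 100.0)

    def test_sessionwise_mean_exactly_100(self, rng):
        data = rng.lognormal(3, 0.5, size=(40, 6))
        sessions = np.repeat([1, 2], 20)
        out = scale_grand_mean(self._dataset(data, sessions=sessions))
        for s in (1, 2):
            assert out.data[sessions == s].mean() == pytest.approx(100.0, abs=1e-10)

    def test_sessions_scaled_independently(self, rng):
        data = np.vstack([rng.normal(50, 1, (20, 4)), rng.normal(200, 1, (20, 4))])
        sessions = np.repeat([1, 2], 20)
        out = scale_grand_mean(self._dataset(data, sessions=sessions))
        ratio = out.data[sessions == 1].mean() / out.data[sessions == 2].mean()
        assert ratio == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            scale_grand_mean(self._dataset(np.full((10, 2), -1.0)))


def _simulate_ar_dataset(rho, n=3000, v=8, seed=0, p=4, n_sessions=2):
    """Small random design + AR(1) noise for noise-model tests.

    Multiple short sessions keep the per-session eigendecompositions cheap.
    """
    from mvblife.cohort import ar1_noise
    import pandas as pd

    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.normal(size=(n, p - 1)), np.ones(n)])
    betas = rng.normal(size=(p, v))
    per = n // n_sessions
    sessions = np.repeat(np.arange(1, n_sessions + 1), per)[:n]
    noise = np.vstack([ar1_noise((sessions == s).sum(), v, rho, 1.0, rng)
                       for s in range(1, n_sessions + 1)])
    design = DesignMatrix(
        matrix=X, labels=[f"s1/x{i}" for i in range(p - 1)] + ["s1/constant"],
        task_column_indices=np.arange(p - 1),
        confound_column_indices=np.array([p - 1]),
        feature_column_indices=np.arange(p - 1),
        session_index=sessions, tr=2.0,
        trial_counts=pd.DataFrame(), voxel_mm=None)
    data = ROIDataset(data=X @ betas + noise, voxel_mm=np.zeros((v, 3)),
                      roi_labels=np.array(["PVC"] * v),
                      session_index=sessions, tr=2.0)
    return data, design, betas


class TestGLMFit:
    def test_noiseless_recovery_machine_precision(self, noiseless_subject):
        s = noiseless_subject
        fit = FirstLevelGLM(s.data, s.design).fit()
        expected = s.truth.column_betas(s.design.labels)
        np.testing.assert_allclose(fit.betas, expected, atol=1e-8)

    def test_white_noise_rho_near_zero(self):
        data, design, _ = _simulate_ar_dataset(rho=0.0, n=3000)
        fit = FirstLevelGLM(data, design).fit()
        assert abs(fit.ar_rho_hat) < 0.03

    def test_ar_noise_rho_recovered(self):
        data, design, _ = _simulate_ar_dataset(rho=0.3, n=3000)
        fit = FirstLevelGLM(data, design).fit()
        assert 0.2 < fit.ar_rho_hat < 0.4

    def test_whitening_reduces_residual_autocorrelation(self):
        """Over repeated AR(1) simulations, whitened residuals have smaller
        mean |lag-1 autocorrelation| than unwhitened OLS residuals."""
        before, after = [], []
        for seed in range(25):
            data, design, _ = _simulate_ar_dataset(rho=0.3, n=400, v=4, seed=seed, n_sessions=1)
            X = design.matrix
            resid = data.data - X @ np.linalg.lstsq(X, data.data, rcond=None)[0]
            before.append(abs((resid[1:] * resid[:-1]).sum() / (resid ** 2).sum()))
            fit = FirstLevelGLM(data, design).fit()
            rw = fit.whitened_data - fit.whitened_design @ fit.betas
            after.append(abs((rw[1:] * rw[:-1]).sum() / (rw ** 2).sum()))
        assert np.mean(after) < np.mean(before)

    def test_rank_deficient_design_rejected(self):
        data, design, _ = _simulate_ar_dataset(rho=0.0, n=200, n_sessions=1)
        design.matrix[:, 0] = design.matrix[:, 1]
        with pytest.raises(ValueError, match="rank"):
            FirstLevelGLM(data, design).fit()

    def test_reml_reported_and_converged(self, small_cohort):
        s = small_cohort[0]
        fit = FirstLevelGLM(scale_grand_mean(s.data), s.design).fit()
        assert fit.reml_converged
        assert 1 <= fit.n_reml_iterations <= 64
        assert -1 < fit.ar_rho_hat < 1
        assert "prewhitened" in fit.summary()


class TestUnivariateSummary:
    def test_mean_and_sd(self):
        mean, sd = univariate_summary(np.array([1.0, 2.0, 3.0]), np.array([0, 1, 2]))
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_identical_values_zero_sd(self):
        _, sd = univariate_summary(np.full(5, 3.3), np.arange(5))
        assert sd == 0.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            univariate_summary(np.arange(4.0), np.array([], int))
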