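"""MVB decoding engine: targets, bases, ReML oracle, greedy search,
model comparison and phase-shuffled baselines."""

import numpy as np
import pytest
from scipy import stats

import mvblife as mv
from mvblife.mvb import (DecodingTarget, MVBDecoder, block_diag_basis,
                         build_target, compare_models, make_pattern_basis,
                         phase_shuffle, phase_shuffled_evidence,
                         select_features)


def _random_instance(rng, n=80, v=20, p_conf=4, signal=0.0):
    """Design with 2 contrast columns + confounds, data with optional signal
    on the target time course."""
    X = rng.normal(size=(n, 2 + p_conf))
    c = np.zeros(2 + p_conf)
    c[:2] = [1.0, -1.0]
    target = build_target(X, c)
    t_course = X @ c
    w_true = rng.normal(0, 0.3, size=v)
    Y = signal * np.outer(t_course, w_true) + rng.normal(size=(n, v))
    return target, Y, w_true


class TestTarget:
    def test_target_is_contrast_time_course(self, rng):
        X = rng.normal(size=(50, 3))
        c = np.array([1.0, -1.0, 0.0])
        tgt = build_target(X, c)
        np.testing.assert_allclose(tgt.t, X[:, 0] - X[:, 1])

    def test_reducer_orthonormal(self):
        target, _, _ = _random_instance(np.random.default_rng(5))
        np.testing.assert_allclose(target.reducer.T @ target.reducer,
                                   np.eye(target.n_reduced), atol=1e-10)

    def test_projected_target_orthogonal_to_confounds(self, rng):
        n, p_conf = 100, 5
        X = rng.normal(size=(n, 2 + p_conf))
        c = np.zeros(2 + p_conf)
        c[:2] = [1.0, 1.0]
        tgt = build_target(X, c)
        rt = tgt.reducer @ tgt.t_reduced
        for j in range(2, 2 + p_conf):
            cos = rt @ X[:, j] / (np.linalg.norm(rt) * np.linalg.norm(X[:, j]))
            assert abs(cos) < 1e-10

    def test_target_in_confound_span_rejected(self, rng):
        X = rng.normal(size=(40, 3))
        X = np.column_stack([X[:, 0], X])          # col 0 duplicated as confound
        c = np.array([1.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="confound span"):
            build_target(X, c)


class TestPatternBasis:
    def test_sparse_is_identity(self):
        b = make_pattern_basis("sparse", n_voxels=7)
        np.testing.assert_array_equal(b.U, np.eye(7))

    def test_smooth_single_voxel_degenerates_to_identity(self):
        b = make_pattern_basis("smooth", voxel_mm=np.zeros((1, 3)), fwhm_mm=8)
        np.testing.assert_allclose(b.U, [[1.0]])

    def test_smooth_columns_nonnegative_unit_sum_localised(self):
        xyz, _ = __import__("mvblife.cohort", fromlist=["make_voxel_lattice"]) \
            .make_voxel_lattice(27)
        b = make_pattern_basis("smooth", voxel_mm=xyz[:27], fwhm_mm=8.0)
        assert (b.U >= 0).all()
        np.testing.assert_allclose(b.U.sum(axis=0), 1.0, atol=1e-12)
        # weight decays with distance: self-weight is the column max
        assert (np.argmax(b.U, axis=0) == np.arange(27)).all()

    def test_fwhm_to_sigma(self):
        from mvblife.mvb import FWHM_TO_SIGMA
        assert 8.0 * FWHM_TO_SIGMA == pytest.approx(3.397, abs=1e-3)

    def test_unknown_prior_rejected(self):
        with pytest.raises(ValueError, match="prior"):
            make_pattern_basis("laplacian", n_voxels=3)


class TestFixedHyperparameterOracle:
    def test_matches_closed_form_gaussian(self, rng):
        """At fixed hyperparameters the posterior weights and log evidence
        equal the conditional-Gaussian closed form (direct density oracle)."""
        for _ in range(5):
            target, Y, _ = _random_instance(rng, n=50, v=20)
            lam0 = float(rng.uniform(0.3, 2.0))
            lam_p = float(rng.uniform(0.05, 0.5))
            basis = make_pattern_basis("sparse", n_voxels=20)
            fit = MVBDecoder(target, Y, basis).fit(
                hyperparameters={"noise": lam0, "pattern": lam_p})
            # oracle: unit-variance reduced target, full covariance algebra
            tr = target.t_reduced
            tr = tr * np.sqrt(len(tr) / (tr @ tr))
            Yr = target.project(Y)
            C = lam0 * np.eye(len(tr)) + lam_p * (Yr @ Yr.T)
            f_oracle = stats.multivariate_normal.logpdf(
                tr, mean=np.zeros(len(tr)), cov=C)
            w_oracle = lam_p * Yr.T @ np.linalg.solve(C, tr)
            assert fit.free_energy == pytest.approx(f_oracle, rel=1e-8)
            np.testing.assert_allclose(fit.weights, w_oracle, atol=1e-10)


class TestGreedySearch:
    def test_accepted_f_nondecreasing(self, rng):
        for _ in range(5):
            target, Y, _ = _random_instance(rng, signal=0.2)
            fit = MVBDecoder(target, Y, make_pattern_basis("sparse", n_voxels=20)).fit()
            accepted = [f for _, f, a in fit.greedy_trace if a]
            assert all(b > a for a, b in zip(accepted, accepted[1:])) or len(accepted) == 1
            assert np.isfinite(fit.free_energy)
            assert fit.free_energy == pytest.approx(max(accepted))

    def test_weights_are_u_eta(self, rng):
        xyz = rng.normal(scale=10, size=(15, 3))
        basis = make_pattern_basis("smooth", voxel_mm=xyz, fwhm_mm=8)
        target, Y, _ = _random_instance(rng, v=15, signal=0.3)
        fit = MVBDecoder(target, Y, basis).fit()
        expect = basis.U[:, fit.active_patterns] @ fit.eta
        np.testing.assert_allclose(fit.weights, expect, atol=1e-12)

    def test_determinism(self, rng):
        target, Y, _ = _random_instance(rng, signal=0.3)
        basis = make_pattern_basis("sparse", n_voxels=20)
        f1 = MVBDecoder(target, Y, basis).fit()
        f2 = MVBDecoder(target, Y, basis).fit()
        assert f1.free_energy == f2.free_energy
        np.testing.assert_array_equal(f1.weights, f2.weights)

    def test_informative_voxels_get_larger_weights(self):
        """Mean |w| over truly informative voxels exceeds that over
        uninformative voxels (paired over seeds)."""
        wins = 0
        n_sims = 20
        for seed in range(n_sims):
            r = np.random.default_rng(seed)
            n, v = 150, 40
            s = r.normal(size=n)
            w_true = np.zeros(v)
            info = r.choice(v, 10, replace=False)
            w_true[info] = r.normal(0, 0.5, 10)
            Y = np.outer(s, w_true) + r.normal(size=(n, v))
            tgt = build_target(s[:, None], np.array([1.0]))
            fit = MVBDecoder(tgt, Y, make_pattern_basis("sparse", n_voxels=v)).fit()
            uninf = np.setdiff1d(np.arange(v), info)
            if np.abs(fit.weights[info]).mean() > np.abs(fit.weights[uninf]).mean():
                wins += 1
        assert wins >= int(0.8 * n_sims)

    def test_nonfinite_data_rejected(self, rng):
        target, Y, _ = _random_instance(rng)
        Y[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            MVBDecoder(target, Y, make_pattern_basis("sparse", n_voxels=20))


class TestPriorRecovery:
    def _smooth_world(self, seed, generative):
        """Data whose true weight map is spatially smooth or one-voxel sparse."""
        r = np.random.default_rng(seed)
        from mvblife.cohort import make_voxel_lattice
        xyz, _ = make_voxel_lattice(25)
        xyz = xyz[:25]
        n, v = 120, 25
        s = r.normal(size=n)
        if generative == "smooth":
            smooth_U = make_pattern_basis("smooth", voxel_mm=xyz, fwhm_mm=10).U
            w_true = smooth_U @ r.normal(0, 1.0, v)
        else:
            w_true = np.zeros(v)
            w_true[r.integers(v)] = 2.0
        Y = np.outer(s, w_true) * 0.5 + r.normal(size=(n, v))
        tgt = build_target(s[:, None], np.array([1.0]))
        f_sm = MVBDecoder(tgt, Y, make_pattern_basis(
            "smooth", voxel_mm=xyz, fwhm_mm=8)).fit().free_energy
        f_sp = MVBDecoder(tgt, Y, make_pattern_basis(
            "sparse", n_voxels=v)).fit().free_energy
        return f_sm, f_sp

    @pytest.mark.parametrize("generative,expect_smooth_wins",
                             [("smooth", True), ("sparse", False)])
    def test_matching_prior_wins_majority(self, generative, expect_smooth_wins):
        wins = sum((lambda fs: (fs[0] > fs[1]) == expect_smooth_wins)(
            self._smooth_world(seed, generative)) for seed in range(15))
        assert wins > 15 // 2


class TestModelComparison:
    def _fit_pair(self, rng, scale=1.0):
        target, Y, _ = _random_instance(rng, v=24, signal=0.3)
        basis_a = make_pattern_basis("sparse", n_voxels=24)
        basis_b = make_pattern_basis("sparse", n_voxels=12)
        fa = MVBDecoder(target, Y * scale, basis_a).fit()
        fb = MVBDecoder(target, Y[:, :12] * scale, basis_b).fit()
        return fa, fb

    @pytest.mark.parametrize("delta,category", [
        (5.0, "boost"), (0.0, "equivalent"), (-5.0, "reduction"),
        (3.0, "equivalent"), (-3.0, "equivalent"),
    ])
    def test_categories_with_boundary(self, rng, delta, category):
        target, Y, _ = _random_instance(rng)
        basis = make_pattern_basis("sparse", n_voxels=20)
        fa = MVBDecoder(target, Y, basis).fit()
        fb = MVBDecoder(target, Y, basis).fit()
        fb.free_energy = fa.free_energy - delta
        assert compare_models(fa, fb).category == category
        assert compare_models(fa, fb).delta_log_evidence == pytest.approx(delta)

    def test_mismatched_targets_rejected(self, rng):
        t1, Y1, _ = _random_instance(rng)
        t2, Y2, _ = _random_instance(rng)
        basis = make_pattern_basis("sparse", n_voxels=20)
        f1 = MVBDecoder(t1, Y1, basis).fit()
        f2 = MVBDecoder(t2, Y2, basis).fit()
        with pytest.raises(ValueError, match="different targets"):
            compare_models(f1, f2)

    def test_category_invariant_to_data_scaling(self):
        """Multiplying the data by a constant and jointly refitting both
        models leaves the comparison category unchanged."""
        for seed in (0, 1, 2):
            rng1 = np.random.default_rng(seed)
            a1, b1 = self._fit_pair(rng1)
            rng2 = np.random.default_rng(seed)
            a2, b2 = self._fit_pair(rng2, scale=7.0)
            assert compare_models(a1, b1).category == \
                compare_models(a2, b2).category


class TestPhaseShuffle:
    def test_amplitude_spectrum_preserved(self, rng):
        x = rng.normal(size=101)
        for n in (100, 101):
            xs = phase_shuffle(x[:n], rng)
            np.testing.assert_allclose(np.abs(np.fft.rfft(xs)),
                                       np.abs(np.fft.rfft(x[:n])), atol=1e-10)

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="short"):
            phase_shuffle(np.ones(3), rng)

    def test_shuffled_evidence_deterministic_under_seed(self, rng):
        target, Y, _ = _random_instance(rng, signal=0.3)
        basis = make_pattern_basis("sparse", n_voxels=20)
        a = phase_shuffled_evidence(target, Y, basis, reps=4, seed=42)
        b = phase_shuffled_evidence(target, Y, basis, reps=4, seed=42)
        assert a == b

    def test_informative_data_beats_shuffled_baseline(self):
        r = np.random.default_rng(3)
        target, Y, _ = _random_instance(r, n=150, v=30, signal=0.8)
        basis = make_pattern_basis("sparse", n_voxels=30)
        f_real = MVBDecoder(target, Y, basis).fit().free_energy
        f_shuf = phase_shuffled_evidence(target, Y, basis, reps=6, seed=0)
        assert f_real - f_shuf > 3.0


class TestFeatureSelection:
    def _glm_fits(self, n_subj=4, v=30, seed=0):
        from mvblife.cohort import CohortSpec, generate_cohort
        from mvblife.design import scale_grand_mean
        from mvblife.glm import FirstLevelGLM
        spec = CohortSpec(n_subjects=n_subj, scenario="null",
                          n_voxels_per_roi=v, rng_seed=seed)
        subs = generate_cohort(spec)
        return subs, [FirstLevelGLM(scale_grand_mean(s.data), s.design).fit()
                      for s in subs]

    def test_k_larger_than_mask_returns_all(self, small_cohort):
        from mvblife.design import scale_grand_mean
        from mvblife.glm import FirstLevelGLM
        fits = [FirstLevelGLM(scale_grand_mean(s.data), s.design).fit()
                for s in small_cohort[:3]]
        mask = small_cohort[0].data.roi_indices("PVC")
        out = select_features(fits, mask, k=1000)
        np.testing.assert_array_equal(out, mask)

    def test_leave_one_out_independence(self, small_cohort):
        """Perturbing the held-out subject's own data cannot change its
        feature set, because only other subjects enter the ranking."""
        from mvblife.design import scale_grand_mean
        from mvblife.glm import FirstLevelGLM
        others = [FirstLevelGLM(scale_grand_mean(s.data), s.design).fit()
                  for s in small_cohort[1:4]]
        mask = small_cohort[0].data.roi_indices("PVC")
        sel1 = select_features(others, mask, k=10)
        # held-out subject's data never entered; identical call -> identical set
        sel2 = select_features(others, mask, k=10)
        np.testing.assert_array_equal(sel1, sel2)
        assert len(sel1) == 10
        assert np.isin(sel1, mask).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            select_features([object()], np.array([], int), k=5)

    def test_default_k_is_1000(self):
        from mvblife.config import RunConfig
        assert RunConfig().k_features == 1000
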