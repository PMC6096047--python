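"""Prewhitened first-level GLM.

The noise model is AR(1)-plus-white: the pooled AR coefficient is taken
from the lag-1 autocorrelation of pooled OLS residuals, and the relative
weights of the white and AR(1) variance components are then estimated by
Fisher-scoring ReML in the eigenbasis of the AR(1) correlation matrix
(where both components are simultaneously diagonal, so each iteration is
O(T)).  Model and data are whitened with the inverse matrix square root of
the fitted covariance and the betas re-estimated by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .cohort import ROIDataset
from .design import DesignMatrix

__all__ = ["FirstLevelGLM", "GLMResults", "contrast_effect_map",
           "univariate_summary"]

_LAM_FLOOR = np.exp(-32.0)


def _mixture_reml(power: np.ndarray, d: np.ndarray, n_vectors: int,
                  tol: float = 1e-6, max_iter: int = 64):
    """ML fit of C_t = lam_w + lam_a * d_t to per-eigenmode mean power.

    ``power`` is the mean squared rotated residual per eigenmode (averaged
    over voxels), ``d`` the AR(1) correlation eigenvalues.  Fisher scoring
    on log-variances; returns (lam_w, lam_a, n_iter, converged).
    """
    lam = np.array([0.5 * power.mean(), 0.5 * power.mean() / d.mean()])
    q = np.stack([np.ones_like(d), d])          # component spectra

    def objective(lam):
        c = lam @ q
        return -0.5 * n_vectors * float(np.sum(np.log(c) + power / c))

    f_old = objective(lam)
    n_iter, converged = 0, False
    for n_iter in range(1, max_iter + 1):
        c = lam @ q
        r = power / c ** 2
        grad = 0.5 * n_vectors * (q @ (r - 1.0 / c)) * lam
        fisher = 0.5 * n_vectors * (q / c) @ (q / c).T * np.outer(lam, lam)
        fisher[np.diag_indices_from(fisher)] += 1e-10 * np.trace(fisher)
        step = np.linalg.solve(fisher, grad)
        step = np.clip(step, -4.0, 4.0)
        for _ in range(8):
            new = np.maximum(lam * np.exp(step), _LAM_FLOOR * power.mean())
            f_new = objective(new)
            if f_new >= f_old - 1e-12:
                break
            step *= 0.5
        lam, df = new, f_new - f_old
        f_old = f_new
        if abs(df) < tol * max(1.0, abs(f_old)):
            converged = True
            break
    return float(lam[0]), float(lam[1]), n_iter, converged


@dataclass
class GLMResults:
    """Parameter estimates and noise model of a prewhitened GLM."""

    betas: np.ndarray            # (n_regressors, n_voxels)
    ar_rho_hat: float            # effective lag-1 autocorrelation of fitted V
    lambda_white: float
    lambda_ar: float
    ar_rho_component: float      # AR coefficient of the AR(1) component
    n_reml_iterations: int
    reml_converged: bool
    sigma2: np.ndarray           # residual variance per voxel (whitened space)
    residual_dof: float
    whitened_design: np.ndarray
    whitened_data: np.ndarray
    design: DesignMatrix
    _xtx_inv: np.ndarray

    def contrast_effect(self, c: np.ndarray) -> np.ndarray:
        """Per-voxel contrast effect c' beta."""
        return contrast_effect_map(self, c)

    def f_statistic(self, column_indices: np.ndarray) -> np.ndarray:
        """Per-voxel F statistic for the joint effect of a column subset."""
        idx = np.asarray(column_indices, int)
        q = len(idx)
        cb = self.betas[idx]                          # (q, v)
        m = self._xtx_inv[np.ix_(idx, idx)]
        sol = np.linalg.solve(m, cb)
        num = np.einsum("qv,qv->v", cb, sol) / q
        return num / np.maximum(self.sigma2, 1e-300)

    def summary(self) -> str:
        d = self.design
        lines = [
            "First-level GLM (AR(1)+white noise, prewhitened OLS)",
            f"  scans x regressors: {d.n_scans} x {d.n_regressors}",
            f"  task / confound columns: {len(d.task_column_indices)}"
            f" / {len(d.confound_column_indices)}",
            f"  pooled AR(1) rho_hat: {self.ar_rho_hat:.4f}"
            f" (component rho {self.ar_rho_component:.4f})",
            f"  variance components (white, AR): {self.lambda_white:.4g},"
            f" {self.lambda_ar:.4g}",
            f"  ReML iterations: {self.n_reml_iterations}"
            f" (converged: {self.reml_converged})",
            f"  median voxel residual variance: {np.median(self.sigma2):.4g}",
        ]
        return "\n".join(lines)


class FirstLevelGLM:
    """Mass-univariate GLM for an ROI dataset and a design matrix.

    Parameters
    ----------
    data : ROIDataset
        Grand-mean-scaled BOLD matrix, scans x voxels.
    design : DesignMatrix
        Must share the scan axis with ``data``.
    """

    def __init__(self, data: ROIDataset, design: DesignMatrix):
        if data.n_scans != design.n_scans:
            raise ValueError("data and design scan dimensions differ")
        self.data = data
        self.design = design

    def fit(self, tol: float = 1e-6, max_iter: int = 64) -> GLMResults:
        X = self.design.matrix
        Y = self.data.data
        n, p = X.shape
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            raise ValueError(f"rank-deficient design: rank {rank} < {p} columns")

        # 1) OLS residuals, pooled over voxels
        beta_ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta_ols

        # degenerate (numerically noiseless) data: whitening is a no-op
        if np.mean(resid ** 2) <= 1e-12 * max(np.mean(Y ** 2), 1e-300):
            xtx_inv = np.linalg.inv(X.T @ X)
            sigma2 = (resid ** 2).sum(axis=0) / (n - p)
            return GLMResults(
                betas=beta_ols, ar_rho_hat=0.0, lambda_white=float(np.mean(resid ** 2)),
                lambda_ar=0.0, ar_rho_component=0.0, n_reml_iterations=0,
                reml_converged=True, sigma2=sigma2, residual_dof=float(n - p),
                whitened_design=X, whitened_data=Y, design=self.design,
                _xtx_inv=xtx_inv)

        # 2) pooled lag-1 autocorrelation per session -> AR component rho
        num = den = 0.0
        for s in np.unique(self.design.session_index):
            r = resid[self.design.session_index == s]
            num += float(np.sum(r[1:] * r[:-1]))
            den += float(np.sum(r ** 2))
        rho = num / den if den > 0 else 0.0
        rho = float(np.clip(rho, -0.95, 0.95))

        # 3) ReML mixture of white + AR(1) components in the AR eigenbasis
        sess = np.unique(self.design.session_index)
        eig = {}
        power_all, d_all = [], []
        for s in sess:
            mask = self.design.session_index == s
            t = int(mask.sum())
            Q = toeplitz(rho ** np.arange(t))
            d, U = np.linalg.eigh(Q)
            eig[s] = (d, U, mask)
            rot = U.T @ resid[mask]
            power_all.append((rot ** 2).mean(axis=1))
            d_all.append(d)
        power = np.concatenate(power_all)
        d = np.concatenate(d_all)
        lam_w, lam_a, n_iter, conv = _mixture_reml(
            power, d, n_vectors=Y.shape[1], tol=tol, max_iter=max_iter)

        # 4) whiten model and data with V^{-1/2} per session, refit by OLS
        WX = np.empty_like(X)
        WY = np.empty_like(Y)
        for s in sess:
            dd, U, mask = eig[s]
            w = 1.0 / np.sqrt(lam_w + lam_a * dd)
            # symmetric inverse square root of V = U diag(lam_w + lam_a d) U'
            WX[mask] = U @ (w[:, None] * (U.T @ X[mask]))
            WY[mask] = U @ (w[:, None] * (U.T @ Y[mask]))
        xtx_inv = np.linalg.inv(WX.T @ WX)
        betas = xtx_inv @ WX.T @ WY
        res_w = WY - WX @ betas
        dof = n - p
        sigma2 = (res_w ** 2).sum(axis=0) / dof

        rho_eff = lam_a * rho / (lam_w + lam_a)
        return GLMResults(
            betas=betas, ar_rho_hat=float(rho_eff), lambda_white=lam_w,
            lambda_ar=lam_a, ar_rho_component=rho, n_reml_iterations=n_iter,
            reml_converged=conv, sigma2=sigma2, residual_dof=float(dof),
            whitened_design=WX, whitened_data=WY, design=self.design,
            _xtx_inv=xtx_inv,
        )


def contrast_effect_map(fit: GLMResults, c: np.ndarray) -> np.ndarray:
    """Per-voxel contrast effect vector c' beta."""
    c = np.asarray(c, float)
    if c.shape[0] != fit.betas.shape[0]:
        raise ValueError("contrast length does not match design")
    return c @ fit.betas


def univariate_summary(effects: np.ndarray,
                       voxel_subset: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD of contrast effects over a voxel subset."""
    idx = np.asarray(voxel_subset, int)
    if idx.size == 0:
        raise ValueError("empty voxel subset")
    vals = np.asarray(effects, float)[idx]
    sd = float(vals.std(ddof=1)) if idx.size > 1 else 0.0
    return float(vals.mean()), sd
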