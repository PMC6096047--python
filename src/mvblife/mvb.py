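"""Multivariate Bayesian (MVB) decoding engine.

Decoding reverses the usual GLM mapping: many voxels' activity predicts a
psychological target variable, specified as a contrast over design columns.
The model is linear-Gaussian and hierarchical,

    R t = R Y w + e,   w = U eta,   eta ~ N(0, Sigma_eta),  e ~ N(0, s2 I),

where R projects out every design column not entering the target contrast,
U is a spatial pattern basis (sparse: one pattern per voxel; smooth:
Gaussian-weighted local averages), and Sigma_eta is built from variance
components over nested pattern subsets whose scales are optimised by
Fisher-scoring ReML.  A greedy search ranks patterns by their alignment
with the target, grows the active set geometrically, and accepts a step
only if the free energy F — here the exact Gaussian log marginal likelihood
of the projected target at the optimised hyperparameters, an empirical-Bayes
bound on the log evidence — increases.  Model comparison is by differences
in F, with +/-3 nats as the strong-evidence threshold.

All covariance algebra is carried out in pattern space via the Woodbury
identity, so fits scale with the active-set size rather than scan count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "PatternBasis",
    "DecodingTarget",
    "MVBDecoder",
    "MVBResults",
    "MVBComparison",
    "make_pattern_basis",
    "build_target",
    "select_features",
    "log_evidence",
    "compare_models",
    "phase_shuffle",
    "phase_shuffled_evidence",
]

_LAM_FLOOR = np.exp(-32.0)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))   # 1/2.3548


# ---------------------------------------------------------------------------
# Pattern bases
# ---------------------------------------------------------------------------


@dataclass
class PatternBasis:
    U: np.ndarray                  # voxels x patterns
    prior_type: str                # "sparse" | "smooth"
    fwhm_mm: float | None = None

    @property
    def n_patterns(self) -> int:
        return self.U.shape[1]


def make_pattern_basis(prior_type: str, voxel_mm: np.ndarray | None = None,
                       fwhm_mm: float = 8.0, n_voxels: int | None = None
                       ) -> PatternBasis:
    """Sparse prior: each pattern is one voxel (U = I).  Smooth prior:
    pattern j holds Gaussian weights exp(-d^2 / 2 sigma^2) of the
    neighbours of voxel j (sigma = fwhm / 2.3548), normalised to unit sum.
    """
    if prior_type == "sparse":
        if n_voxels is None:
            if voxel_mm is None:
                raise ValueError("sparse basis needs n_voxels or voxel_mm")
            n_voxels = len(voxel_mm)
        return PatternBasis(np.eye(n_voxels), "sparse")
    if prior_type == "smooth":
        if voxel_mm is None:
            raise ValueError("smooth basis requires voxel coordinates")
        if fwhm_mm <= 0:
            raise ValueError("fwhm must be positive")
        xyz = np.asarray(voxel_mm, float)
        if not np.isfinite(xyz).all():
            raise ValueError("voxel coordinates must be finite")
        sigma = fwhm_mm * FWHM_TO_SIGMA
        d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
        U = np.exp(-d2 / (2.0 * sigma ** 2))
        U[U < 1e-8] = 0.0
        U /= U.sum(axis=0, keepdims=True)
        return PatternBasis(U, "smooth", fwhm_mm=fwhm_mm)
    raise ValueError(f"unknown prior type: {prior_type!r}")


def block_diag_basis(bases: Sequence[PatternBasis]) -> PatternBasis:
    """Concatenate ROI bases block-diagonally for joint two-ROI models."""
    from scipy.linalg import block_diag

    U = block_diag(*[b.U for b in bases])
    ptype = bases[0].prior_type if len({b.prior_type for b in bases}) == 1 else "mixed"
    return PatternBasis(U, ptype, fwhm_mm=bases[0].fwhm_mm)


# ---------------------------------------------------------------------------
# Targets and confound projection
# ---------------------------------------------------------------------------


@dataclass
class DecodingTarget:
    """Target time course with its confound-null-space reducer.

    ``reducer`` N is an orthonormal basis (scans x reduced) of the
    complement of the confound span; working with N'x realises the
    projector R = N N' at full rank, so the residual noise stays white.
    """

    t: np.ndarray                  # raw target time course, X c
    reducer: np.ndarray            # (n_scans, n_reduced), orthonormal
    contrast: np.ndarray
    t_reduced: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.t_reduced = self.reducer.T @ self.t

    @property
    def n_reduced(self) -> int:
        return self.reducer.shape[1]

    def project(self, data: np.ndarray) -> np.ndarray:
        """Apply the confound-removing reduction to a scans x voxels matrix."""
        return self.reducer.T @ data


def build_target(design_matrix: np.ndarray, contrast: np.ndarray,
                 rel_tol: float = 1e-10) -> DecodingTarget:
    """Form t = X c and the projector removing all columns not entering c."""
    X = np.asarray(design_matrix, float)
    c = np.asarray(contrast, float)
    t = X @ c
    conf = X[:, c == 0]
    if conf.shape[1]:
        q, _ = np.linalg.qr(conf)
        # orthonormal complement of the confound span
        proj = np.eye(X.shape[0]) - q @ q.T
        w, V = np.linalg.eigh(proj)
        N = V[:, w > 0.5]
    else:
        N = np.eye(X.shape[0])
    tr = N.T @ t
    if np.linalg.norm(tr) <= rel_tol * max(np.linalg.norm(t), 1e-300):
        raise ValueError("target lies in the confound span: nothing to decode")
    return DecodingTarget(t=t, reducer=N, contrast=c)


def select_features(other_subject_fits: Sequence, roi_mask: np.ndarray,
                    k: int = 1000, logger=None) -> np.ndarray:
    """Leave-one-participant-out feature selection.

    Ranks in-mask voxels by the mean task F statistic over *other*
    subjects' GLM fits (columns given by each fit's design
    ``feature_column_indices``) and returns the top ``k`` voxel indices.
    """
    mask = np.asarray(roi_mask, int)
    if mask.size == 0:
        raise ValueError("empty ROI mask")
    if len(other_subject_fits) == 0:
        raise ValueError("need at least one other subject")
    fsum = None
    for fit in other_subject_fits:
        f = fit.f_statistic(fit.design.feature_column_indices)
        fsum = f if fsum is None else fsum + f
    fmean = fsum[mask] / len(other_subject_fits)
    if k >= mask.size:
        if k > mask.size and logger is not None:
            logger.warning("requested %d features but mask has %d voxels; "
                           "returning all", k, mask.size)
        return mask.copy()
    order = np.argsort(-fmean, kind="stable")[:k]
    return mask[np.sort(order)]


# ---------------------------------------------------------------------------
# ReML in pattern space (Woodbury form)
# ---------------------------------------------------------------------------


def _woodbury_stats(G, b, tt, n, lam0, dvec, full=True):
    """Quantities of C = lam0 I + Xa diag(dvec) Xa' in pattern space.

    With ``full=False`` only the free energy is evaluated (line searches).
    """
    m = G.shape[0]
    A = np.diag(1.0 / dvec) + G / lam0
    cf = cho_factor(A, lower=True)
    logdetA = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Ainv_b = cho_solve(cf, b)
    logdetC = n * np.log(lam0) + logdetA + np.sum(np.log(dvec))
    alpha = (tt - b @ Ainv_b / lam0) / lam0          # t' C^-1 t
    F = -0.5 * (alpha + logdetC + n * np.log(2.0 * np.pi))
    if not full:
        return dict(F=F)
    AinvG = cho_solve(cf, G)
    xu = (b - G @ Ainv_b / lam0) / lam0              # Xa' C^-1 t
    K = np.eye(m) - AinvG / lam0
    H = G @ K / lam0                                 # Xa' C^-1 Xa
    uu = (tt - 2.0 * b @ Ainv_b / lam0
          + Ainv_b @ G @ Ainv_b / lam0 ** 2) / lam0 ** 2   # ||C^-1 t||^2
    trAinvG = np.trace(AinvG)
    trCinv = (n - trAinvG / lam0) / lam0
    trCinv2 = (n - 2.0 * trAinvG / lam0
               + np.sum(AinvG * AinvG.T) / lam0 ** 2) / lam0 ** 2
    M2 = K.T @ H / lam0                              # Xa' C^-2 Xa
    return dict(F=F, alpha=alpha, xu=xu, H=H, uu=uu, trCinv=trCinv,
                trCinv2=trCinv2, M2=M2)


def _reml_pattern_space(Xa, t, shells, tol=1e-6, max_iter=128):
    """Optimise noise + per-shell pattern variance scales by Fisher scoring.

    shells: list of index arrays partitioning the active pattern set.
    Returns (lam0, shell_lams, F, n_iter, converged, stats).
    """
    n = t.shape[0]
    G = Xa.T @ Xa
    b = Xa.T @ t
    tt = float(t @ t)
    vart = tt / n
    floor = _LAM_FLOOR * max(vart, 1e-30)
    gdiag = np.maximum(np.diag(G), 1e-30)

    lam0 = 0.5 * vart
    lams = np.array([0.5 * vart / max(gdiag[s].mean(), 1e-30) for s in shells])
    k = len(shells)

    def dvec_of(lams):
        d = np.empty(G.shape[0])
        for s, l in zip(shells, lams):
            d[s] = l
        return d

    starts = np.array([s[0] for s in shells])
    st = _woodbury_stats(G, b, tt, n, lam0, dvec_of(lams))
    f_old = st["F"]
    n_iter, converged = 0, False
    for n_iter in range(1, max_iter + 1):
        xu, H, M2 = st["xu"], st["H"], st["M2"]
        grad = np.empty(k + 1)
        grad[0] = 0.5 * (st["uu"] - st["trCinv"]) * lam0
        grad[1:] = 0.5 * (np.add.reduceat(xu ** 2, starts)
                          - np.add.reduceat(np.diag(H), starts)) * lams
        fisher = np.empty((k + 1, k + 1))
        fisher[0, 0] = 0.5 * st["trCinv2"] * lam0 ** 2
        f0 = 0.5 * np.add.reduceat(np.diag(M2), starts) * lam0 * lams
        fisher[0, 1:] = fisher[1:, 0] = f0
        blocks = np.add.reduceat(np.add.reduceat(H ** 2, starts, axis=0),
                                 starts, axis=1)
        fisher[1:, 1:] = 0.5 * blocks * np.outer(lams, lams)
        fisher[np.diag_indices_from(fisher)] += 1e-8 * max(np.trace(fisher), 1e-30)
        step = np.clip(np.linalg.solve(fisher, grad), -4.0, 4.0)
        accepted = False
        for _ in range(8):
            lam0_new = max(lam0 * np.exp(step[0]), floor)
            lams_new = np.maximum(lams * np.exp(step[1:]), floor)
            f_new = _woodbury_stats(G, b, tt, n, lam0_new, dvec_of(lams_new),
                                    full=False)["F"]
            if f_new >= f_old - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        lam0, lams = lam0_new, lams_new
        st = _woodbury_stats(G, b, tt, n, lam0, dvec_of(lams))
        df = st["F"] - f_old
        f_old = st["F"]
        if abs(df) < tol * max(1.0, abs(f_old)):
            converged = True
            break
    return lam0, lams, f_old, n_iter, converged, st


# ---------------------------------------------------------------------------
# Decoder (model) and results
# ---------------------------------------------------------------------------


@dataclass
class MVBResults:
    """Posterior weights, hyperparameters and free energy of one MVB fit."""

    weights: np.ndarray            # per-voxel posterior means w = U eta
    eta: np.ndarray                # posterior means of active pattern weights
    active_patterns: np.ndarray    # indices of patterns in the accepted set
    hyperparameters: dict
    free_energy: float             # nats; empirical-Bayes log evidence
    greedy_trace: list             # [(subset size, F, accepted), ...]
    n_voxels: int
    prior_type: str
    n_scans_effective: int
    target_checksum: float
    reml_iterations: int = 0
    reml_converged: bool = True

    def summary(self) -> str:
        acc = [(m, f) for m, f, a in self.greedy_trace if a]
        lines = [
            f"MVB fit ({self.prior_type} prior): {self.n_voxels} voxels,"
            f" {self.n_scans_effective} effective scans",
            f"  free energy (log evidence bound): {self.free_energy:.3f} nats",
            f"  greedy steps accepted: {len(acc)}"
            f" (active set {len(self.active_patterns)} patterns)",
            f"  noise scale: {self.hyperparameters['noise']:.4g}",
            f"  weight spread (SD over voxels): {np.std(self.weights, ddof=1):.4g}"
            if self.n_voxels > 1 else "",
        ]
        return "\n".join(l for l in lines if l)


@dataclass
class MVBComparison:
    delta_log_evidence: float
    category: str                  # "boost" | "equivalent" | "reduction"


class MVBDecoder:
    """MVB decoding model for one target, dataset and pattern basis.

    Parameters
    ----------
    target : DecodingTarget
        Built by :func:`build_target`; carries the confound reducer.
    data : ndarray, scans x voxels
        (Whitened) voxel time series; projected internally.
    basis : PatternBasis
    """

    def __init__(self, target: DecodingTarget, data: np.ndarray,
                 basis: PatternBasis,
                 max_greedy_steps: int = 8,
                 projected: bool = False):
        data = np.asarray(data, float)
        if not np.isfinite(data).all():
            raise ValueError("non-finite data")
        expected_rows = (target.reducer.shape[1] if projected
                         else target.reducer.shape[0])
        if data.shape[0] != expected_rows:
            raise ValueError("data and target scan axes differ")
        if data.shape[1] < 1:
            raise ValueError("need at least one voxel")
        if data.shape[1] != basis.U.shape[0]:
            raise ValueError("basis voxel dimension mismatch")
        self.target = target
        self.basis = basis
        self.max_greedy_steps = max_greedy_steps
        # reduced scans x voxels (projection is reused across refits)
        self._Yr = data if projected else target.project(data)
        self._Xp = self._Yr @ basis.U if basis.prior_type != "sparse" else self._Yr
        tr = target.t_reduced
        norm2 = float(tr @ tr)
        if norm2 <= 1e-24:
            raise ValueError("target has zero variance after confound removal")
        # unit-variance target: the model family is closed under target
        # scaling (F shifts by -n log a), so this removes the spurious
        # norm-dependence of F without changing model structure; evidences
        # of models for the same psychological variable stay comparable
        # across (real or surrogate) targets of different raw norm.
        self._t = tr * np.sqrt(tr.shape[0] / norm2)

    # -- fitting ------------------------------------------------------------

    def fit(self, hyperparameters: dict | None = None,
            tol: float = 1e-6, max_iter: int = 128) -> MVBResults:
        """Greedy free-energy maximisation (default) or a fixed-hyperparameter
        evaluation when ``hyperparameters={'noise': s2, 'pattern': var}``."""
        if hyperparameters is not None:
            return self._fit_fixed(hyperparameters)
        return self._fit_greedy(self._t, tol=tol, max_iter=max_iter)

    def _fit_greedy(self, t: np.ndarray, tol: float = 1e-6,
                    max_iter: int = 128) -> MVBResults:
        Xp = self._Xp
        n, p = Xp.shape
        order = np.argsort(-np.abs(Xp.T @ t), kind="stable")
        sizes = []
        m = 1
        for _ in range(self.max_greedy_steps):
            sizes.append(min(m, p))
            if m >= p:
                break
            m *= 2

        trace = []
        best = None
        f_prev = -np.inf
        boundaries = [0] + sizes
        for step, m in enumerate(sizes):
            active = order[:m]
            shells = [np.arange(boundaries[j], boundaries[j + 1])
                      for j in range(step + 1)
                      if boundaries[j] < m]
            shells = [s[s < m] for s in shells]
            Xa = Xp[:, active]
            lam0, lams, F, n_it, conv, st = _reml_pattern_space(
                Xa, t, shells, tol=tol, max_iter=max_iter)
            # keep the best subset size seen; a dip at one size does not
            # preclude improvement at a larger one, so all sizes up to the
            # cap are evaluated and a step is accepted iff it improves on
            # the best so far (accepted-step F is therefore non-decreasing)
            accepted = F > f_prev
            trace.append((int(m), float(F), bool(accepted)))
            if accepted:
                dvec = np.empty(m)
                for s, l in zip(shells, lams):
                    dvec[s] = l
                eta = dvec * st["xu"]
                best = (active, eta, lam0, lams, F, n_it, conv)
                f_prev = F

        active, eta, lam0, lams, F, n_it, conv = best
        w = self._weights_from_eta(active, eta)
        return MVBResults(
            weights=w, eta=eta, active_patterns=active,
            hyperparameters={"noise": lam0, "pattern": lams.tolist()},
            free_energy=float(F), greedy_trace=trace,
            n_voxels=self.basis.U.shape[0], prior_type=self.basis.prior_type,
            n_scans_effective=n,
            target_checksum=float(self.target.t_reduced @ self.target.t_reduced),
            reml_iterations=n_it, reml_converged=conv,
        )

    def _fit_fixed(self, hyper: dict) -> MVBResults:
        t = self._t
        Xp = self._Xp
        n, p = Xp.shape
        lam0 = float(hyper["noise"])
        pat = np.asarray(hyper["pattern"], float)
        if pat.ndim == 0:
            pat = np.full(p, float(pat))
        active = np.arange(p)
        st = _woodbury_stats(Xp.T @ Xp, Xp.T @ t, float(t @ t), n, lam0, pat)
        eta = pat * st["xu"]
        w = self._weights_from_eta(active, eta)
        return MVBResults(
            weights=w, eta=eta, active_patterns=active,
            hyperparameters={"noise": lam0, "pattern": pat.tolist()},
            free_energy=float(st["F"]), greedy_trace=[(p, float(st["F"]), True)],
            n_voxels=self.basis.U.shape[0], prior_type=self.basis.prior_type,
            n_scans_effective=n,
            target_checksum=float(self.target.t_reduced @ self.target.t_reduced),
        )

    def _weights_from_eta(self, active: np.ndarray, eta: np.ndarray) -> np.ndarray:
        v = self.basis.U.shape[0]
        w = np.zeros(v)
        if self.basis.prior_type == "sparse":
            w[active] = eta
        else:
            w = self.basis.U[:, active] @ eta
        return w


# ---------------------------------------------------------------------------
# Evidence utilities
# ---------------------------------------------------------------------------


def log_evidence(fit: MVBResults) -> float:
    """Free energy F of a fit: the (empirical-Bayes) log-evidence bound."""
    return fit.free_energy


EVIDENCE_THRESHOLD = 3.0


def compare_models(fit_a: MVBResults, fit_b: MVBResults,
                   threshold: float = EVIDENCE_THRESHOLD) -> MVBComparison:
    """Categorise F_a - F_b against +/- threshold (boundary -> equivalent)."""
    if not np.isclose(fit_a.target_checksum, fit_b.target_checksum,
                      rtol=1e-8, atol=1e-12):
        raise ValueError("fits decode different targets")
    delta = fit_a.free_energy - fit_b.free_energy
    if delta > threshold:
        cat = "boost"
    elif delta < -threshold:
        cat = "reduction"
    else:
        cat = "equivalent"
    return MVBComparison(delta_log_evidence=float(delta), category=cat)


def phase_shuffle(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomised surrogate: Fourier amplitudes preserved, phases
    uniform with conjugate symmetry (DC kept; Nyquist sign-randomised)."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 4:
        raise ValueError("target too short to phase shuffle")
    X = np.fft.rfft(x)
    Xs = np.abs(X) * np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, size=len(X)))
    Xs[0] = X[0]
    if n % 2 == 0:
        Xs[-1] = X[-1] * rng.choice([-1.0, 1.0])
    return np.fft.irfft(Xs, n=n)


def phase_shuffled_evidence(target: DecodingTarget, data: np.ndarray,
                            basis: PatternBasis, reps: int = 20,
                            seed: int | np.random.Generator = 0,
                            max_greedy_steps: int = 8,
                            projected: bool = False) -> float:
    """Mean free energy over ``reps`` phase-shuffled surrogates of the target.

    The raw target time course (not the data) is phase randomised; each
    surrogate is re-reduced by the same confound projector and refitted with
    the full greedy scheme.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    dec = MVBDecoder(target, data, basis, max_greedy_steps=max_greedy_steps,
                     projected=projected)
    fs = []
    for _ in range(reps):
        t_s = phase_shuffle(target.t, rng)
        tr = target.reducer.T @ t_s
        norm2 = float(tr @ tr)
        if norm2 <= 1e-24:
            raise ValueError("surrogate target vanished under projection")
        fs.append(dec._fit_greedy(tr * np.sqrt(len(tr) / norm2)).free_energy)
    return float(np.mean(fs))
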