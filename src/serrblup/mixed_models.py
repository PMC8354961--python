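"""REML variance components and mixed-model prediction.

Univariate model: y = 1 mu + g + e with g ~ N(0, sigma2_g * Gamma) and
e ~ N(0, sigma2_eps * I). REML is exact here: one eigendecomposition of
Gamma reduces the restricted likelihood to a 1-D profile in the variance
ratio delta = sigma2_eps / sigma2_g, optimized by grid search plus Brent
refinement.

Bivariate model: the same trait in two environments, stacked
environment-major, with Var(g) = H (x) Gamma (Kronecker) and residual
covariance only between the two records of the same line. Components are
estimated by EM-REML formulated in observation space (V = ZGZ' + R), which
never inverts Gamma and therefore tolerates the singular kernels that
aggressive interaction selection can produce; H and R0 are projected onto
the PSD cone after every update. Prediction solves the same equations with
the components held fixed.

All solvers are inverse-free with respect to Gamma; predictions take the
form g_hat = Cov(g, y_obs) V^{-1} (y_obs - X mu_hat).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize_scalar

from .kernels import RelationshipMatrix

__all__ = [
    "VarianceComponents",
    "BivariateVarianceComponents",
    "PredictionResult",
    "BivariateFallbackResult",
    "reml_univariate",
    "fit_univariate",
    "reml_bivariate",
    "fit_bivariate",
    "estimate_bivariate_with_fallback",
]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_eps: float
    mu_hat: float
    converged: bool = True
    n_iter: int = 0

    @property
    def lambda_(self) -> float:
        """Variance ratio sigma2_eps / sigma2_g."""
        return self.sigma2_eps / self.sigma2_g if self.sigma2_g > 0 else np.inf

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            for k in ("sigma2_g", "sigma2_eps", "mu_hat", "converged", "n_iter"):
                fh.write(f"{k}\t{getattr(self, k)!r}\n")


@dataclass
class BivariateVarianceComponents:
    """2x2 genetic (H) and residual (R0) covariance matrices."""

    H: np.ndarray
    R0: np.ndarray
    converged: bool = True
    n_iter: int = 0
    fixed_fallback_used: bool = False
    mu_hat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.float64).reshape(2, 2)
        self.R0 = np.asarray(self.R0, dtype=np.float64).reshape(2, 2)

    @property
    def genetic_correlation(self) -> float:
        d = np.sqrt(self.H[0, 0] * self.H[1, 1])
        return float(self.H[0, 1] / d) if d > 0 else np.nan

    def check_psd(self, tol: float = 1e-8) -> None:
        for name, mat in (("H", self.H), ("R0", self.R0)):
            w = np.linalg.eigvalsh(mat)
            if w.min() < -tol * max(np.trace(mat), 1.0):
                raise ValueError(f"{name} is not positive semidefinite")

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("H\t" + "\t".join(repr(v) for v in self.H.ravel()) + "\n")
            fh.write("R0\t" + "\t".join(repr(v) for v in self.R0.ravel()) + "\n")
            fh.write(f"converged\t{self.converged}\nn_iter\t{self.n_iter}\n")
            fh.write(f"fixed_fallback_used\t{self.fixed_fallback_used}\n")


@dataclass
class PredictionResult:
    """Predicted phenotypes for a target set plus genetic values for all lines."""

    line_ids: list
    y_hat: np.ndarray
    g_hat: np.ndarray
    g_hat_line_ids: list
    mu_hat: float


@dataclass
class BivariateFallbackResult:
    full: BivariateVarianceComponents
    folds: list = field(default_factory=list)


def _kernel_values(gamma) -> np.ndarray:
    return gamma.values if isinstance(gamma, RelationshipMatrix) else np.asarray(gamma, float)


# ---------------------------------------------------------------------------
# Univariate


def reml_univariate(y: np.ndarray, gamma, *, log10_delta_range=(-8.0, 8.0),
                    n_grid: int = 65) -> VarianceComponents:
    """Exact REML for one kernel plus residual via the spectral profile.

    Returns the REML estimates and the GLS mean at the optimum. Requires
    n >= 3 phenotyped lines and a (numerically) PSD kernel.
    """
    y = np.asarray(y, dtype=np.float64)
    K = _kernel_values(gamma)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 phenotyped lines for REML")
    if K.shape != (n, n):
        raise ValueError("kernel does not match the phenotype vector")
    d, U = np.linalg.eigh(K)
    if d.min() < -1e-8 * max(d.max(), 1.0):
        raise ValueError(f"kernel is not PSD (min eigenvalue {d.min():.3g})")
    d = np.clip(d, 0.0, None)
    ys = U.T @ y
    os_ = U.T @ np.ones(n)
    vy = float(np.var(y))
    if vy < 1e-30:  # constant response: both components at the boundary
        return VarianceComponents(0.0, 0.0, float(y.mean()), converged=True)

    tiny = 1e-300

    def profile(log10_delta: float) -> tuple[float, float, float]:
        delta = 10.0 ** log10_delta
        dd = d + delta
        a = float(np.sum(os_ ** 2 / dd))
        mu = float(np.sum(os_ * ys / dd)) / a
        r = ys - mu * os_
        s2g = float(np.sum(r ** 2 / dd)) / (n - 1)
        crit = ((n - 1) * np.log(max(s2g, tiny)) + float(np.sum(np.log(dd)))
                + np.log(max(a, tiny)))
        return crit, s2g, mu

    lo, hi = log10_delta_range
    grid = np.linspace(lo, hi, n_grid)
    crits = [profile(x)[0] for x in grid]
    i = int(np.argmin(crits))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(lambda x: profile(x)[0], bounds=(a, b),
                          method="bounded", options={"xatol": 1e-10})
    best = float(res.x)
    _, s2g, mu = profile(best)
    delta = 10.0 ** best
    return VarianceComponents(sigma2_g=s2g, sigma2_eps=s2g * delta, mu_hat=mu,
                              converged=bool(res.success),
                              n_iter=n_grid + int(res.nfev))


def fit_univariate(y1: np.ndarray, gamma: RelationshipMatrix,
                   vc: VarianceComponents,
                   train_idx: np.ndarray | None = None) -> PredictionResult:
    """Solve the univariate mixed model in inverse-free form.

    ``y1`` holds the training phenotypes, aligned with ``train_idx``
    positions in ``gamma`` (default: all lines). Genetic values are returned
    for every line; predicted phenotypes y_hat = mu_hat + g_hat for the
    lines outside the training set.
    """
    y1 = np.asarray(y1, dtype=np.float64)
    K = _kernel_values(gamma)
    n = K.shape[0]
    if train_idx is None:
        train_idx = np.arange(n)
    train_idx = np.asarray(train_idx, dtype=np.intp)
    if train_idx.size == 0:
        raise ValueError("no training lines")
    if y1.size != train_idx.size:
        raise ValueError("training phenotypes do not match training lines")
    Ktt = K[np.ix_(train_idx, train_idx)]
    if vc.sigma2_g <= 0:
        mu = float(y1.mean())
        g_all = np.zeros(n)
    else:
        V = vc.sigma2_g * Ktt + vc.sigma2_eps * np.eye(train_idx.size)
        cf = sla.cho_factor(V, check_finite=False)
        ones = np.ones(train_idx.size)
        vi1 = sla.cho_solve(cf, ones, check_finite=False)
        mu = float(vi1 @ y1) / float(vi1 @ ones)
        w = sla.cho_solve(cf, y1 - mu, check_finite=False)
        g_all = vc.sigma2_g * (K[:, train_idx] @ w)
    test_mask = np.ones(n, dtype=bool)
    test_mask[train_idx] = False
    test_idx = np.nonzero(test_mask)[0]
    ids = list(gamma.line_ids) if isinstance(gamma, RelationshipMatrix) \
        else list(range(n))
    return PredictionResult(
        line_ids=[ids[i] for i in test_idx],
        y_hat=mu + g_all[test_idx], g_hat=g_all, g_hat_line_ids=ids, mu_hat=mu)


# ---------------------------------------------------------------------------
# Bivariate


def _sym_inv(V: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric PD matrix via Cholesky; jittered retry if needed."""
    from scipy.linalg.lapack import dpotrf, dpotri

    for jitter in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        A = V if jitter == 0.0 else V + jitter * np.mean(np.diag(V)) * np.eye(len(V))
        c, info = dpotrf(A, lower=1, overwrite_a=False)
        if info != 0:
            continue
        vi, info = dpotri(c, lower=1)
        if info != 0:
            continue
        return vi + np.tril(vi, -1).T
    raise ValueError("covariance matrix is numerically singular")


def _psd_project(A: np.ndarray, floor_scale: float = 1e-10) -> np.ndarray:
    A = (A + A.T) / 2.0
    w, Q = np.linalg.eigh(A)
    floor = floor_scale * max(float(np.trace(A)), 1e-12)
    return (Q * np.clip(w, floor, None)) @ Q.T


class _BivariateSystem:
    """Observation-space bookkeeping shared by EM-REML and prediction."""

    def __init__(self, gamma, l1: np.ndarray, l2: np.ndarray):
        self.K = _kernel_values(gamma)
        self.l1 = np.asarray(l1, dtype=np.intp)
        self.l2 = np.asarray(l2, dtype=np.intp)
        self.n = self.K.shape[0]
        self.n1, self.n2 = self.l1.size, self.l2.size
        self.M = self.n1 + self.n2
        self.G11 = self.K[np.ix_(self.l1, self.l1)]
        self.G12 = self.K[np.ix_(self.l1, self.l2)]
        self.G22 = self.K[np.ix_(self.l2, self.l2)]
        # partner obs index of the same line in the other environment (-1: none)
        pos2 = {l: i for i, l in enumerate(self.l2)}
        self.part = np.full(self.M, -1, dtype=np.intp)
        for i, l in enumerate(self.l1):
            j = pos2.get(l)
            if j is not None:
                self.part[i] = self.n1 + j
                self.part[self.n1 + j] = i
        self.shared1 = np.nonzero(self.part[: self.n1] >= 0)[0]
        self.n_shared = self.shared1.size
        self.env = np.concatenate([np.zeros(self.n1, int), np.ones(self.n2, int)])
        self.X = np.zeros((self.M, 2))
        self.X[: self.n1, 0] = 1.0
        self.X[self.n1:, 1] = 1.0

    def build_V(self, H: np.ndarray, R0: np.ndarray) -> np.ndarray:
        V = np.empty((self.M, self.M))
        V[: self.n1, : self.n1] = H[0, 0] * self.G11
        V[: self.n1, self.n1:] = H[0, 1] * self.G12
        V[self.n1:, : self.n1] = H[0, 1] * self.G12.T
        V[self.n1:, self.n1:] = H[1, 1] * self.G22
        d = np.where(self.env == 0, R0[0, 0], R0[1, 1])
        V[np.diag_indices(self.M)] += d
        if R0[0, 1] != 0.0:
            has = self.part >= 0
            V[np.nonzero(has)[0], self.part[has]] += R0[0, 1]
        return V

    def gls(self, Vi: np.ndarray, y: np.ndarray):
        ViX = Vi @ self.X
        B = self.X.T @ ViX
        mu = np.linalg.solve(B, ViX.T @ y)
        return mu, ViX, B


def _as_series(y, name: str) -> pd.Series:
    if isinstance(y, pd.Series):
        return y
    raise TypeError(f"{name} must be a pandas Series indexed by line id")


def reml_bivariate(y1: pd.Series, y2: pd.Series, gamma: RelationshipMatrix,
                   init: BivariateVarianceComponents | None = None,
                   max_iter: int = 100, tol: float = 1e-6
                   ) -> BivariateVarianceComponents:
    """EM-REML for the two-environment model with Var(g) = H (x) Gamma.

    ``y1`` and ``y2`` are Series indexed by line id (possibly different line
    sets, both genotyped). Stops at relative parameter change < ``tol`` or
    after ``max_iter`` EM updates, returning the last iterate either way.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    y1 = _as_series(y1, "y1")
    y2 = _as_series(y2, "y2")
    ids = list(gamma.line_ids)
    lookup = {l: i for i, l in enumerate(ids)}
    try:
        l1 = np.array([lookup[l] for l in y1.index], dtype=np.intp)
        l2 = np.array([lookup[l] for l in y2.index], dtype=np.intp)
    except KeyError as e:
        raise ValueError(f"phenotyped line {e.args[0]!r} not in kernel") from None
    if l1.size < 2 or l2.size < 2:
        raise ValueError("each environment needs at least 2 phenotyped lines")
    sys_ = _BivariateSystem(gamma, l1, l2)
    y = np.concatenate([y1.to_numpy(float), y2.to_numpy(float)])

    if init is None:
        v1, v2 = max(float(y1.var()), 1e-12), max(float(y2.var()), 1e-12)
        H = np.diag([v1 / 2, v2 / 2])
        R0 = np.diag([v1 / 2, v2 / 2])
    else:
        H, R0 = init.H.copy(), init.R0.copy()
    mu = np.zeros(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = sys_.build_V(H, R0)
        Vi = _sym_inv(V)
        mu, ViX, B = sys_.gls(Vi, y)
        Py = Vi @ (y - sys_.X @ mu)
        P = Vi - ViX @ np.linalg.solve(B, ViX.T)

        # genetic update: H <- H + H (Q - T) H / n
        v_a = np.zeros((2, sys_.n))
        v_a[0, sys_.l1] = Py[: sys_.n1]
        v_a[1, sys_.l2] = Py[sys_.n1:]
        Kv = v_a @ sys_.K
        Q = Kv @ v_a.T
        T = np.empty((2, 2))
        P11 = P[: sys_.n1, : sys_.n1]
        P12 = P[: sys_.n1, sys_.n1:]
        P22 = P[sys_.n1:, sys_.n1:]
        T[0, 0] = float(np.sum(P11 * sys_.G11))
        T[0, 1] = T[1, 0] = float(np.sum(P12 * sys_.G12))
        T[1, 1] = float(np.sum(P22 * sys_.G22))
        H_new = _psd_project(H + H @ (Q - T) @ H / sys_.n)

        # residual update from E[e e' | y] = e_hat e_hat' + R - R P R
        r_d = np.where(sys_.env == 0, R0[0, 0], R0[1, 1])
        r_c = np.where(sys_.part >= 0, R0[0, 1], 0.0)
        part_safe = np.where(sys_.part >= 0, sys_.part, 0)

        def rmul(Mat):  # left-multiply by sparse R
            return r_d[:, None] * Mat + r_c[:, None] * Mat[part_safe]

        e_hat = r_d * Py + r_c * Py[part_safe]
        RP = rmul(P)
        # diag(RPR) and shared-pair entries of RPR
        diag_RP = np.diagonal(RP)
        RP_part = RP[np.arange(sys_.M), part_safe]
        rpr_diag = r_d * diag_RP + r_c * RP_part
        s1 = slice(0, sys_.n1)
        s2 = slice(sys_.n1, sys_.M)
        R0_new = np.empty((2, 2))
        R0_new[0, 0] = (np.sum(e_hat[s1] ** 2) + sys_.n1 * R0[0, 0]
                        - np.sum(rpr_diag[s1])) / sys_.n1
        R0_new[1, 1] = (np.sum(e_hat[s2] ** 2) + sys_.n2 * R0[1, 1]
                        - np.sum(rpr_diag[s2])) / sys_.n2
        if sys_.n_shared:
            o1 = sys_.shared1
            o2 = sys_.part[o1]
            # (RPR)[o1,o2] = r_d[o2]*RP[o1,o2] + r_c[o2]*RP[o1,o1]
            rpr_12 = r_d[o2] * RP[o1, o2] + r_c[o2] * RP[o1, o1]
            R0_new[0, 1] = R0_new[1, 0] = (
                np.sum(e_hat[o1] * e_hat[o2]) + sys_.n_shared * R0[0, 1]
                - np.sum(rpr_12)) / sys_.n_shared
        else:
            R0_new[0, 1] = R0_new[1, 0] = 0.0
        R0_new = _psd_project(R0_new)

        theta_old = np.concatenate([H.ravel(), R0.ravel()])
        theta_new = np.concatenate([H_new.ravel(), R0_new.ravel()])
        rel = np.linalg.norm(theta_new - theta_old) / (
            np.linalg.norm(theta_old) + 1e-12)
        H, R0 = H_new, R0_new
        if rel < tol:
            converged = True
            break
    return BivariateVarianceComponents(H=H, R0=R0, converged=converged,
                                       n_iter=it, mu_hat=np.asarray(mu))


def fit_bivariate(y1: pd.Series, y2_obs: pd.Series, masked_ids,
                  gamma: RelationshipMatrix,
                  bvc: BivariateVarianceComponents) -> PredictionResult:
    """Predict masked environment-2 phenotypes from the bivariate model.

    ``y1`` is the complete environment-1 data, ``y2_obs`` the unmasked
    environment-2 records; predictions are y_hat = mu_hat_2 + g_hat_2 for
    the masked lines. ``g_hat`` holds environment-2 genetic values for
    every line in the kernel.
    """
    y1 = _as_series(y1, "y1")
    y2_obs = _as_series(y2_obs, "y2_obs")
    masked_ids = list(masked_ids)
    if set(masked_ids) & set(y2_obs.index):
        raise ValueError("masked lines overlap observed environment-2 lines")
    bvc.check_psd()
    ids = list(gamma.line_ids)
    lookup = {l: i for i, l in enumerate(ids)}
    l1 = np.array([lookup[l] for l in y1.index], dtype=np.intp)
    l2 = np.array([lookup[l] for l in y2_obs.index], dtype=np.intp)
    lm = np.array([lookup[l] for l in masked_ids], dtype=np.intp)
    sys_ = _BivariateSystem(gamma, l1, l2)
    y = np.concatenate([y1.to_numpy(float), y2_obs.to_numpy(float)])
    V = sys_.build_V(bvc.H, bvc.R0)
    Vi = _sym_inv(V)
    mu, _, _ = sys_.gls(Vi, y)
    w = Vi @ (y - sys_.X @ mu)
    w1, w2 = w[: sys_.n1], w[sys_.n1:]
    K = sys_.K
    g2 = bvc.H[1, 0] * (K[:, l1] @ w1) + bvc.H[1, 1] * (K[:, l2] @ w2)
    y_hat = mu[1] + g2[lm] if lm.size else np.empty(0)
    return PredictionResult(line_ids=masked_ids, y_hat=y_hat, g_hat=g2,
                            g_hat_line_ids=ids, mu_hat=float(mu[1]))


def estimate_bivariate_with_fallback(
        full_y1: pd.Series, full_y2: pd.Series, gamma: RelationshipMatrix,
        fold_training_subsets, max_iter_full: int = 100,
        max_iter_fold: int = 50, tol: float = 1e-6) -> BivariateFallbackResult:
    """Two-stage component estimation with the fixed-value fallback.

    Stage 1 estimates (H, R0) from the full data, capped at
    ``max_iter_full`` EM updates, keeping the last iterate whether or not
    it converged. Stage 2 re-estimates per fold from environment-1 full
    data plus the fold's environment-2 training subset, warm-started at the
    stage-1 values and capped at ``max_iter_fold`` updates; on
    non-convergence the stage-1 values are used as fixed components and the
    fold is flagged.
    """
    full = reml_bivariate(full_y1, full_y2, gamma, init=None,
                          max_iter=max_iter_full, tol=tol)
    folds = []
    for train_ids in fold_training_subsets:
        y2_train = full_y2.loc[[l for l in full_y2.index if l in set(train_ids)]]
        fit = reml_bivariate(full_y1, y2_train, gamma, init=full,
                             max_iter=max_iter_fold, tol=tol)
        if not fit.converged:
            fit = BivariateVarianceComponents(
                H=full.H.copy(), R0=full.R0.copy(), converged=False,
                n_iter=fit.n_iter, fixed_fallback_used=True, mu_hat=fit.mu_hat)
        folds.append(fit)
    return BivariateFallbackResult(full=full, folds=folds)
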