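"""Penalized logistic regression: ridge, lasso, elastic net, optional
nonnegativity constraints, regularization paths and cross-validated λ choice.

The fitted objective is the glmnet-style scaled penalized negative
log-likelihood

    J(b0, β) = (1/n) Σ_i [log(1 + exp(η_i)) − y_i η_i]
               + λ (α ‖β‖₁ + (1−α)/2 ‖β‖₂²),       η = b0 + Xβ,

with the intercept b0 unpenalized and, when requested, all slopes
constrained to β_j ≥ 0 (the nonnegative lasso used by the stacked model's
combiner levels). The solver is iteratively reweighted least squares with,
for the L1-containing penalties, cyclic coordinate descent and
soft-thresholding; the nonnegativity constraint is exact because each
coordinate-wise subproblem is solved by clipping at zero. Pure
unconstrained ridge steps are solved in closed form.

When ``standardize`` is on, features are scaled to unit variance internally
and the penalty applies on that scale; reported coefficients are always on
the original feature scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.special import logit as _logit

from .data import FoldPlan, make_folds

logger = logging.getLogger("staplr")

__all__ = [
    "PenaltySpec",
    "LambdaPath",
    "PenalizedLogisticModel",
    "ConvergenceError",
    "logistic",
    "soft_threshold",
    "compute_lambda_path",
    "fit_penalized_logistic",
    "cv_select_lambda",
    "fit_cv_logistic",
    "logistic_objective",
]

# IRLS working probabilities are clipped to keep the weights bounded away
# from zero; out-of-fold deviances clip harder only to avoid log(0).
_PROB_CLIP = 1e-5
_DEV_CLIP = 1e-10
# surrogate mixing floor used to define a finite lambda_max for pure ridge
_ALPHA_FLOOR = 1e-3


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries iteration diagnostics."""

    def __init__(self, message: str, n_iter: int, delta: float):
        super().__init__(f"{message} (iterations={n_iter}, last max coefficient change={delta:.3e})")
        self.n_iter = n_iter
        self.delta = delta


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty configuration: ``alpha`` mixes L1 (1) and L2 (0); ``nonnegative``
    constrains slopes (never the intercept) to be >= 0."""

    alpha: float = 0.0
    nonnegative: bool = False
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


#: defaults used by the stacked model
RIDGE = PenaltySpec(alpha=0.0, nonnegative=False, standardize=True)
NONNEGATIVE_LASSO = PenaltySpec(alpha=1.0, nonnegative=True, standardize=False)


@dataclass(frozen=True)
class LambdaPath:
    """Decreasing, log-equispaced sequence of penalty strengths."""

    values: np.ndarray
    epsilon: float

    @property
    def lambda_max(self) -> float:
        return float(self.values[0])

    @property
    def lambda_min(self) -> float:
        return float(self.values[-1])

    @property
    def n_lambda(self) -> int:
        return int(self.values.size)


@dataclass
class PenalizedLogisticModel:
    """One fitted penalized logistic regression.

    ``coefficients`` are on the original feature scale regardless of internal
    standardization. ``cv_curve`` holds the per-λ mean out-of-fold binomial
    deviance when the model came from :func:`fit_cv_logistic`.
    """

    intercept: float
    coefficients: np.ndarray
    penalty: PenaltySpec
    lambda_selected: float
    feature_names: list[str] | None = None
    cv_curve: np.ndarray | None = None
    lambda_path: np.ndarray | None = None
    n_iter: int = 0

    def predict_proba(self, X_new) -> np.ndarray:
        """ψ(intercept + X_new · coefficients) per subject; columns matched
        by name when ``X_new`` is a DataFrame."""
        import pandas as pd

        if isinstance(X_new, pd.DataFrame):
            if self.feature_names is None:
                raise ValueError("model has no stored feature names; pass an array")
            missing = [c for c in self.feature_names if c not in X_new.columns]
            if missing:
                raise KeyError(f"missing feature columns: {missing}")
            X_new = X_new[self.feature_names].to_numpy(dtype=float)
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != self.coefficients.size:
            raise ValueError(
                f"expected {self.coefficients.size} feature columns, got {X_new.shape[1]}"
            )
        return logistic(self.intercept + X_new @ self.coefficients)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "feature_names": self.feature_names,
            "penalty": {
                "alpha": self.penalty.alpha,
                "nonnegative": self.penalty.nonnegative,
                "standardize": self.penalty.standardize,
            },
            "lambda_selected": self.lambda_selected,
            "cv_curve": None if self.cv_curve is None else np.asarray(self.cv_curve).tolist(),
            "lambda_path": None if self.lambda_path is None else np.asarray(self.lambda_path).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PenalizedLogisticModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            penalty=PenaltySpec(**d["penalty"]),
            lambda_selected=float(d["lambda_selected"]),
            feature_names=d.get("feature_names"),
            cv_curve=None if d.get("cv_curve") is None else np.asarray(d["cv_curve"]),
            lambda_path=None if d.get("lambda_path") is None else np.asarray(d["lambda_path"]),
        )


def logistic(x) -> np.ndarray | float:
    """The logistic function ψ(x) = exp(x) / (1 + exp(x)), overflow-safe."""
    out = expit(x)
    return float(out) if np.isscalar(x) else out


def soft_threshold(z: float, gamma: float, nonnegative: bool = False) -> float:
    """sign(z)·max(|z|−γ, 0); with ``nonnegative`` additionally clipped below at 0."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    out = np.sign(z) * max(abs(z) - gamma, 0.0)
    if nonnegative and out < 0.0:
        out = 0.0
    return float(out)


# -- internals ---------------------------------------------------------------


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0  # constant column: becomes all-zero, slope stays 0
    return (X - center) / scale, center, scale


def _null_score(Xw: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(1/n) X'(y − ȳ): the score of the slopes at the null (intercept-only) model."""
    return Xw.T @ (y - y.mean()) / y.shape[0]


def compute_lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    penalty: PenaltySpec,
    n_lambda: int = 100,
    epsilon: float = 0.01,
) -> LambdaPath:
    """λ sequence from λ_max (smallest λ with an all-zero slope vector) down to
    ε·λ_max, log-equispaced.

    For pure ridge the exact λ_max is infinite; the conventional surrogate of
    flooring α at 0.001 in the λ_max formula is used. Under nonnegativity only
    positive components of the null-model score can activate a slope; if none
    is positive the null model is optimal for every λ and the path collapses
    to a single value (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    if np.unique(y).size < 2:
        raise ValueError("constant outcome: lambda_max is undefined")
    Xw = _standardize(X)[0] if penalty.standardize else X
    score = _null_score(Xw, y)
    if penalty.nonnegative:
        magnitude = float(np.max(score)) if score.size else 0.0
        if magnitude <= 0.0:
            logger.info(
                "no positive null-model score under nonnegativity: the null model "
                "is optimal for all lambda; path collapses to a single value"
            )
            fallback = float(np.max(np.abs(score))) or 1.0
            lam = fallback / max(penalty.alpha, _ALPHA_FLOOR)
            return LambdaPath(values=np.array([lam]), epsilon=epsilon)
    else:
        magnitude = float(np.max(np.abs(score))) if score.size else 0.0
    if magnitude <= 0.0:
        magnitude = 1.0
    lam_max = magnitude / max(penalty.alpha, _ALPHA_FLOOR)
    values = np.geomspace(lam_max, epsilon * lam_max, n_lambda)
    return LambdaPath(values=values, epsilon=epsilon)


def _wls_ridge_solve(X: np.ndarray, w: np.ndarray, z: np.ndarray, lam_l2: float) -> tuple[float, np.ndarray]:
    """Exact weighted least squares with an unpenalized intercept and L2
    penalty ``lam_l2`` on the slopes (objective scaled by 1/n)."""
    n, p = X.shape
    sw = w.sum()
    xm = (w @ X) / sw
    zm = float(w @ z) / sw
    sq = np.sqrt(w)
    Aw = sq[:, None] * (X - xm)
    zc = sq * (z - zm)
    if p <= n:
        A = Aw.T @ Aw
        A *= 1.0 / n
        A.flat[:: p + 1] += lam_l2
        b = Aw.T @ zc
        b *= 1.0 / n
        try:
            beta = cho_solve(cho_factor(A, lower=True, check_finite=False), b, check_finite=False)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
    else:
        # dual (Gram) form, cheaper when p > n
        G = Aw @ Aw.T
        G *= 1.0 / n
        G.flat[:: n + 1] += lam_l2
        try:
            alpha_dual = cho_solve(cho_factor(G, lower=True, check_finite=False), zc, check_finite=False)
        except np.linalg.LinAlgError:
            alpha_dual = np.linalg.lstsq(G, zc, rcond=None)[0]
        beta = Aw.T @ alpha_dual / n
    b0 = zm - float(xm @ beta)
    return b0, beta


def _working_response(X, y, b0, beta):
    eta = b0 + X @ beta
    p = np.clip(expit(eta), _PROB_CLIP, 1.0 - _PROB_CLIP)
    w = p * (1.0 - p)
    z = eta + (y - p) / w
    return w, z


def _irls_ridge(X, y, lam_l2, b0, beta, max_iter, tol):
    for it in range(1, max_iter + 1):
        eta = X @ beta
        eta += b0
        p = np.clip(expit(eta), _PROB_CLIP, 1.0 - _PROB_CLIP)
        w = p * (1.0 - p)
        z = eta + (y - p) / w
        b0n, betan = _wls_ridge_solve(X, w, z, lam_l2)
        delta = max(abs(b0n - b0), float(np.abs(betan - beta).max()) if beta.size else 0.0)
        b0, beta = b0n, betan
        if delta < tol * max(1.0, float(np.abs(beta).max()) if beta.size else 1.0):
            return b0, beta, it, True
    return b0, beta, max_iter, False


def _irls_ridge_path(X, y, lams, max_iter=100, tol=1e-8):
    """Newton/IRLS for the whole ridge λ path at once.

    All λ values are iterated simultaneously (each with its own weights and
    exact weighted-least-squares solve, so the per-λ solutions are identical
    to one-at-a-time fits up to the convergence tolerance); converged λs are
    masked out. The dual (Gram) form is used when p > n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    lams = np.asarray(lams, dtype=float)
    L = lams.size
    ybar = float(np.clip(y.mean(), _PROB_CLIP, 1.0 - _PROB_CLIP))
    n_left = 0
    chunk = max(4, min(16, L))
    if p <= n:
        # primal: joint (intercept, slopes) Newton on the augmented design,
        # with cheap gradient-refinement steps between Hessian refreshes
        Xa = np.empty((n, p + 1))
        Xa[:, 0] = 1.0
        Xa[:, 1:] = X
        params = np.zeros((L, p + 1))
        params[:, 0] = _logit(ybar)
        for start in range(0, L, chunk):
            stop = min(start + chunk, L)
            if start > 0:
                params[start:stop] = params[start - 1]
            n_left += _ridge_newton_block_primal(
                Xa, y, lams, params, np.arange(start, stop), max_iter, tol
            )
        return params[:, 0].copy(), params[:, 1:].copy()
    # dual (Gram) form when p > n
    b0 = np.full(L, _logit(ybar))
    B = np.zeros((L, p))
    Xt = np.ascontiguousarray(X.T)
    PX = X @ Xt
    for start in range(0, L, chunk):
        stop = min(start + chunk, L)
        if start > 0:
            B[start:stop] = B[start - 1]
            b0[start:stop] = b0[start - 1]
        n_left += _ridge_newton_block_dual(
            X, Xt, y, lams, b0, B, np.arange(start, stop), PX, max_iter, tol
        )
    if n_left:
        logger.warning("ridge path: %d lambda values stopped before convergence", n_left)
    return b0, B


def _ridge_newton_block_primal(Xa, y, lams, params, block, max_iter, tol, max_inner=6):
    """Iterate one block of λ values to convergence in place.

    Each outer pass rebuilds the exact (batched) penalized Hessian; the inner
    passes reuse it against fresh gradients, whose common fixed point is the
    exact penalized-likelihood stationary point. Returns the count of
    non-converged entries.
    """
    n, p1 = Xa.shape
    diag = np.arange(1, p1)
    active = np.ones(block.size, dtype=bool)
    Xat = Xa.T
    for _ in range(max_iter):
        idx = block[np.flatnonzero(active)]
        par = params[idx]
        P = np.clip(expit(par @ Xat), _PROB_CLIP, 1.0 - _PROB_CLIP)
        W = P * (1.0 - P)
        H = np.matmul(Xat[None, :, :], W[:, :, None] * Xa[None, :, :])
        H *= 1.0 / n
        H[:, diag, diag] += lams[idx, None]
        deltas = np.empty(len(idx))
        for inner in range(max_inner):
            g = (P - y) @ Xa
            g *= 1.0 / n
            g[:, 1:] += lams[idx, None] * par[:, 1:]
            try:
                step = np.linalg.solve(H, g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.stack([np.linalg.lstsq(H[k], g[k], rcond=None)[0] for k in range(len(idx))])
            par = par - step
            deltas = np.abs(step).max(axis=1)
            scale = np.maximum(1.0, np.abs(par[:, 1:]).max(axis=1) if p1 > 1 else 1.0)
            if (deltas < tol * scale).all():
                break
            P = np.clip(expit(par @ Xat), _PROB_CLIP, 1.0 - _PROB_CLIP)
        params[idx] = par
        scale = np.maximum(1.0, np.abs(par[:, 1:]).max(axis=1) if p1 > 1 else 1.0)
        still = deltas >= tol * scale
        pos = np.flatnonzero(active)
        active[pos[~still]] = False
        if not active.any():
            break
    return int(active.sum())


def _ridge_newton_block_dual(X, Xt, y, lams, b0, B, block, PX, max_iter, tol):
    """Dual-form Newton for one block of λ values (p > n), in place."""
    n, p = X.shape
    active = np.ones(block.size, dtype=bool)
    for _ in range(max_iter):
        idx = block[np.flatnonzero(active)]
        ETA = B[idx] @ Xt
        ETA += b0[idx, None]
        P = np.clip(expit(ETA), _PROB_CLIP, 1.0 - _PROB_CLIP)
        W = P * (1.0 - P)
        Z = ETA + (y - P) / W
        SW = W.sum(axis=1)
        XM = (W @ X) / SW[:, None]
        ZM = (W * Z).sum(axis=1) / SW
        sq = np.sqrt(W)
        XXM = X @ XM.T  # (n, L_active)
        Bn = np.empty((len(idx), p))
        for k in range(len(idx)):
            M = PX - XXM[:, k][:, None] - XXM[:, k][None, :] + float(XM[k] @ XM[k])
            Gk = (sq[k][:, None] * sq[k][None, :]) * M
            Gk *= 1.0 / n
            Gk.flat[:: n + 1] += lams[idx[k]]
            rhs_k = sq[k] * (Z[k] - ZM[k])
            try:
                ak = cho_solve(cho_factor(Gk, lower=True, check_finite=False), rhs_k, check_finite=False)
            except np.linalg.LinAlgError:
                ak = np.linalg.lstsq(Gk, rhs_k, rcond=None)[0]
            sa = sq[k] * ak
            Bn[k] = (sa @ X - sa.sum() * XM[k]) / n
        b0n = ZM - (XM * Bn).sum(axis=1)
        delta = np.maximum(np.abs(Bn - B[idx]).max(axis=1) if p else 0.0, np.abs(b0n - b0[idx]))
        scale = np.maximum(1.0, np.abs(Bn).max(axis=1) if p else 1.0)
        B[idx] = Bn
        b0[idx] = b0n
        still = delta >= tol * scale
        pos = np.flatnonzero(active)
        active[pos[~still]] = False
        if not active.any():
            break
    return int(active.sum())


def _wls_enet_active(M, q, gam, l2, nonneg, u_init, kkt_tol):
    """Exact solver for the weighted-least-squares elastic-net subproblem in
    covariance form.

    Minimizes ½ u'Mu − q'u + gam‖u₁:‖₁ + ½ l2‖u₁:‖² (u₀ the unpenalized
    intercept, slopes optionally constrained ≥ 0) by active-set pivoting:
    solve the equality-constrained system on the current signed support,
    step back to the first sign crossing when a coordinate leaves, and add
    the worst violator of the subgradient conditions until none remains.
    Returns ``(u, converged)``.
    """
    p1 = M.shape[0]
    u = np.zeros(p1)
    active = [j for j in range(1, p1) if u_init[j] != 0.0]
    sgn = {j: (1.0 if u_init[j] > 0 else -1.0) for j in active}
    if nonneg:
        sgn = {j: 1.0 for j in active}
    for _ in range(6 * p1 + 30):
        # solve on the current signed support, dropping crossers one at a time
        for _drop in range(len(active) + 1):
            idx = np.array([0] + active, dtype=int)
            Msub = M[np.ix_(idx, idx)].copy()
            Msub[np.arange(1, idx.size), np.arange(1, idx.size)] += l2
            rhs = q[idx].copy()
            rhs[1:] -= gam * np.array([sgn[j] for j in active])
            try:
                sol = np.linalg.solve(Msub, rhs)
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(Msub, rhs, rcond=None)[0]
            ssub = np.array([sgn[j] for j in active])
            bad = np.flatnonzero(sol[1:] * ssub <= 0.0)
            if bad.size == 0:
                u = np.zeros(p1)
                u[idx] = sol
                break
            cur = u[idx]
            dvec = sol - cur
            # largest feasible step toward sol before a sign crossing
            with np.errstate(divide="ignore", invalid="ignore"):
                steps = cur[1:][bad] / (cur[1:][bad] - sol[1:][bad])
            steps = np.where(np.isfinite(steps), steps, 0.0)
            k = int(bad[np.argmin(steps)])
            a = float(np.clip(steps.min(), 0.0, 1.0))
            u[idx] = cur + a * dvec
            dropped = active[k]
            u[dropped] = 0.0
            active.pop(k)
            sgn.pop(dropped)
        else:
            return u, False
        g = M @ u - q
        g[1:] += l2 * u[1:]
        if p1 == 1:
            return u, True
        viol = (-g[1:] - gam) if nonneg else (np.abs(g[1:]) - gam)
        viol[u[1:] != 0.0] = -np.inf
        j = int(np.argmax(viol))
        if viol[j] <= kkt_tol:
            return u, True
        active.append(j + 1)
        sgn[j + 1] = 1.0 if (nonneg or g[j + 1] < 0.0) else -1.0
    return u, False


def _irls_enet_cov(X, y, lam, alpha, nonneg, b0, beta, max_iter, tol):
    """IRLS whose weighted-least-squares subproblems are solved exactly by
    the active-set solver (covariance form; efficient for moderate p)."""
    n, p = X.shape
    gam = lam * alpha
    l2 = lam * (1.0 - alpha)
    Xa = np.empty((n, p + 1))
    Xa[:, 0] = 1.0
    Xa[:, 1:] = X
    Xat = Xa.T
    u = np.empty(p + 1)
    u[0] = b0
    u[1:] = beta
    for it in range(1, max_iter + 1):
        eta = Xa @ u
        prob = np.clip(expit(eta), _PROB_CLIP, 1.0 - _PROB_CLIP)
        w = prob * (1.0 - prob)
        z = eta + (y - prob) / w
        wXa = Xat * w
        M = (wXa @ Xa) / n
        q = (wXa @ z) / n
        kkt_tol = 1e-11 * max(1.0, float(np.abs(q).max()))
        un, ok = _wls_enet_active(M, q, gam, l2, nonneg, u, kkt_tol)
        if not ok:  # pivoting stalled (degenerate Gram): fall back to CD
            b0f, betaf, its, okf = _irls_cd(
                X, y, lam, alpha, nonneg, float(u[0]), u[1:].copy(), max_iter, tol
            )
            return b0f, betaf, it + its, okf
        delta = float(np.abs(un - u).max())
        u = un
        if delta < tol * max(1.0, float(np.abs(u[1:]).max()) if p else 1.0):
            return float(u[0]), u[1:], it, True
    return float(u[0]), u[1:], max_iter, False


def _irls_cd(X, y, lam, alpha, nonneg, b0, beta, max_iter, tol, max_sweeps=100000):
    """IRLS with cyclic coordinate descent on each weighted LS subproblem.

    Uses an active-set strategy: after a full sweep, only currently-nonzero
    coordinates are cycled until stable, then a full sweep verifies the
    optimality conditions for the rest.
    """
    n, p = X.shape
    gam = lam * alpha
    l2 = lam * (1.0 - alpha)
    XT = np.ascontiguousarray(X.T)
    all_idx = range(p)
    for it in range(1, max_iter + 1):
        w, z = _working_response(X, y, b0, beta)
        wXT = XT * w
        xwx = (wXT * XT).sum(axis=1) / n
        denom = xwx + l2
        sw = float(w.sum())
        r = z - b0 - X @ beta
        b0_old, beta_old = b0, beta.copy()

        def sweep(indices):
            nonlocal b0, r
            maxd = 0.0
            d0 = float(w @ r) / sw
            if d0 != 0.0:
                b0 += d0
                r = r - d0
                maxd = abs(d0)
            for j in indices:
                dj = denom[j]
                if dj <= 0.0:
                    continue
                bj = beta[j]
                num = float(wXT[j] @ r) / n + xwx[j] * bj
                if num > gam:
                    nbj = (num - gam) / dj
                    if nonneg and nbj < 0.0:
                        nbj = 0.0
                elif not nonneg and num < -gam:
                    nbj = (num + gam) / dj
                else:
                    nbj = 0.0
                if nbj != bj:
                    d = nbj - bj
                    r = r - XT[j] * d
                    beta[j] = nbj
                    if abs(d) > maxd:
                        maxd = abs(d)
            return maxd

        thr = 0.1 * tol * max(1.0, float(np.abs(beta).max()) if p else 1.0)
        sweeps = 0
        maxd = sweep(all_idx)
        sweeps += 1
        while maxd >= thr and sweeps < max_sweeps:
            active = np.flatnonzero(beta)
            while sweeps < max_sweeps:
                maxd = sweep(active)
                sweeps += 1
                if maxd < thr:
                    break
            maxd = sweep(all_idx)  # verify coordinate-wise optimality globally
            sweeps += 1
        delta = max(abs(b0 - b0_old), float(np.max(np.abs(beta - beta_old))) if p else 0.0)
        if delta < tol * max(1.0, float(np.max(np.abs(beta))) if p else 1.0):
            return b0, beta, it, True
    return b0, beta, max_iter, False


# problems up to this width use the exact covariance-form subproblem solver;
# wider ones use residual-updating coordinate descent
_COV_MODE_MAX_P = 400


def _irls_l1(X, y, lam, alpha, nonneg, b0, beta, max_iter, tol):
    if X.shape[1] <= _COV_MODE_MAX_P:
        return _irls_enet_cov(X, y, lam, alpha, nonneg, b0, beta, max_iter, tol)
    return _irls_cd(X, y, lam, alpha, nonneg, b0, beta, max_iter, tol)


def logistic_objective(X, y, intercept, coefficients, lam, alpha) -> float:
    """The scaled penalized negative log-likelihood this module minimizes
    (diagnostic; computed on whatever scale ``X`` is given in)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(coefficients, dtype=float)
    eta = intercept + X @ beta
    nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    pen = lam * (alpha * float(np.sum(np.abs(beta))) + 0.5 * (1 - alpha) * float(beta @ beta))
    return nll + pen


def fit_penalized_logistic(
    X: np.ndarray,
    y: np.ndarray,
    penalty: PenaltySpec,
    lam: float,
    *,
    feature_names: Sequence[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    warm_start: tuple[float, np.ndarray] | None = None,
    raise_on_nonconvergence: bool = True,
) -> PenalizedLogisticModel:
    """Fit one penalized logistic regression at penalty strength ``lam``.

    ``warm_start`` takes ``(intercept, slopes)`` on the *internal* (possibly
    standardized) scale and is used for path acceleration; results are
    identical to a cold start up to the convergence tolerance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if np.unique(y).size < 2:
        raise ValueError("constant outcome: cannot fit a logistic model")
    n, p = X.shape
    if penalty.standardize:
        Xw, center, scale = _standardize(X)
    else:
        Xw, center, scale = X, np.zeros(p), np.ones(p)
    ybar = float(y.mean())
    if warm_start is not None:
        b0, beta = float(warm_start[0]), np.array(warm_start[1], dtype=float)
    else:
        b0, beta = float(_logit(ybar)), np.zeros(p)
    if penalty.alpha == 0.0 and not penalty.nonnegative:
        b0, beta, n_iter, ok = _irls_ridge(Xw, y, lam, b0, beta, max_iter, tol)
    else:
        b0, beta, n_iter, ok = _irls_l1(
            Xw, y, lam, penalty.alpha, penalty.nonnegative, b0, beta, max_iter, tol
        )
    if not ok:
        err = ConvergenceError("penalized logistic fit did not converge", n_iter, tol)
        if raise_on_nonconvergence:
            raise err
        logger.warning(str(err))
    coef = beta / scale
    intercept = b0 - float((beta * center / scale).sum())
    if penalty.nonnegative:
        coef = np.maximum(coef, 0.0)  # exact: CD clips every coordinate update
    return PenalizedLogisticModel(
        intercept=float(intercept),
        coefficients=coef,
        penalty=penalty,
        lambda_selected=float(lam),
        feature_names=list(feature_names) if feature_names is not None else None,
        n_iter=n_iter,
    )


def _path_fit_internal(Xw, y, penalty, lams, max_iter, tol):
    """Warm-started fits along a λ path on the already-scaled matrix ``Xw``.

    Returns arrays ``b0s`` (n_lambda,) and ``betas`` (n_lambda, p) on the
    internal scale.
    """
    n, p = Xw.shape
    ridge = penalty.alpha == 0.0 and not penalty.nonnegative
    if ridge:
        return _irls_ridge_path(Xw, y, lams, max_iter=max(max_iter, 100), tol=tol)
    b0 = float(_logit(np.clip(y.mean(), _PROB_CLIP, 1 - _PROB_CLIP)))
    beta = np.zeros(p)
    b0s = np.empty(len(lams))
    betas = np.empty((len(lams), p))
    for k, lam in enumerate(lams):
        b0, beta, _, ok = _irls_l1(
            Xw, y, lam, penalty.alpha, penalty.nonnegative, b0, beta.copy(), max_iter, tol
        )
        if not ok:
            logger.warning("path fit at lambda=%.4g stopped before convergence", lam)
        b0s[k] = b0
        betas[k] = beta
    return b0s, betas


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    penalty: PenaltySpec,
    lams: np.ndarray,
    *,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Original-scale ``(intercepts, slope matrix)`` along a λ path."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if penalty.standardize:
        Xw, center, scale = _standardize(X)
    else:
        Xw, center, scale = X, np.zeros(p), np.ones(p)
    b0s, betas = _path_fit_internal(Xw, y, penalty, np.asarray(lams, dtype=float), max_iter, tol)
    coefs = betas / scale
    intercepts = b0s - (betas * (center / scale)).sum(axis=1)
    return intercepts, coefs


def binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    """Mean binomial deviance −2[y log p + (1−y) log(1−p)], probabilities clipped."""
    p = np.clip(prob, _DEV_CLIP, 1.0 - _DEV_CLIP)
    y = np.asarray(y, dtype=float)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    penalty: PenaltySpec,
    path: LambdaPath,
    fold_plan: FoldPlan,
    *,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[float, np.ndarray]:
    """Pick the λ on ``path`` minimizing mean out-of-fold binomial deviance.

    Path fits are warm-started within each fold. Ties on the curve go to the
    largest penalty (smallest path index), favoring sparsity. A validation
    fold containing a single class still contributes a finite deviance via
    probability clipping.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lams = path.values
    n = y.shape[0]
    oof = np.empty((n, lams.size))
    for f in range(fold_plan.n_folds):
        tr = fold_plan.train_rows(f)
        te = fold_plan.test_rows(f)
        if np.unique(y[te]).size < 2:
            logger.info("validation fold %d contains a single class; deviance uses clipped probabilities", f)
        b0s, coefs = fit_path(X[tr], y[tr], penalty, lams, max_iter=max_iter, tol=tol)
        eta = X[te] @ coefs.T + b0s
        oof[te, :] = expit(eta)
    curve = np.array([binomial_deviance(y, oof[:, k]) for k in range(lams.size)])
    best = int(np.argmin(curve))  # first minimum = largest lambda
    return float(lams[best]), curve


def fit_cv_logistic(
    X: np.ndarray,
    y: np.ndarray,
    penalty: PenaltySpec,
    *,
    n_lambda: int = 100,
    epsilon: float = 0.01,
    fold_plan: FoldPlan | None = None,
    n_folds: int = 10,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> PenalizedLogisticModel:
    """Compute the λ path, select λ by internal cross-validation, refit on all
    rows; the model records the path and its CV deviance curve."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    path = compute_lambda_path(X, y, penalty, n_lambda=n_lambda, epsilon=epsilon)
    if path.values.size == 1:
        lam_sel, curve = float(path.values[0]), np.array([np.nan])
    else:
        if fold_plan is None:
            fold_plan = make_folds(y.astype(int), n_folds, seed)
        lam_sel, curve = cv_select_lambda(X, y, penalty, path, fold_plan, max_iter=max_iter, tol=tol)
    model = fit_penalized_logistic(
        X, y, penalty, lam_sel, feature_names=feature_names, max_iter=max_iter, tol=tol,
        raise_on_nonconvergence=False,
    )
    model.cv_curve = curve
    model.lambda_path = path.values
    return model


def predict_proba_glm(model: PenalizedLogisticModel, X_new) -> np.ndarray:
    """Functional alias for :meth:`PenalizedLogisticModel.predict_proba`."""
    return model.predict_proba(X_new)
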