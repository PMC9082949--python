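"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles — a generic
constrained convex optimizer for the penalized logistic objective, a direct
transcription of the depth-3 importance formula, and a brute-force
pairwise AUC — and shares no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def convex_logistic_oracle(X, y, lam, alpha, nonnegative):
    """Minimize (1/n)Σ[log(1+e^η) − yη] + λ(α‖β‖₁ + (1−α)/2‖β‖₂²) with a
    general-purpose solver, splitting β = β⁺ − β⁻ so the objective is smooth.

    Returns (intercept, coefficients, objective).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape

    def objective(par):
        b0 = par[0]
        bp, bm = par[1 : p + 1], par[p + 1 :]
        beta = bp - bm
        eta = b0 + X @ beta
        nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
        return nll + lam * (alpha * np.sum(bp + bm) + 0.5 * (1 - alpha) * np.sum(beta**2))

    bounds = [(None, None)] + [(0.0, None)] * p + ([(0.0, 0.0)] if nonnegative else [(0.0, None)]) * p
    res = minimize(
        objective,
        np.zeros(2 * p + 1),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
    )
    beta = res.x[1 : p + 1] - res.x[p + 1 :]
    return float(res.x[0]), beta, float(res.fun)


def penalized_objective(X, y, b0, beta, lam, alpha):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    eta = b0 + X @ beta
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    return float(nll + lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * beta @ beta))


def _psi(x):
    return np.exp(x) / (1.0 + np.exp(x))


def mrm_depth3_g(omega0, omega, beta0, betas, s, i, value, c):
    """Direct transcription of the depth-3 g(·): the stacked output when the
    probed leaf's prediction is ``value`` and every other leaf sits at ``c``.

    ``omega``: meta weights per branch; ``beta0``/``betas``: per-branch
    intermediate intercepts and coefficient lists; (s, i) index the probed
    branch and leaf within it (0-based).
    """
    inner_s = beta0[s] + betas[s][i] * value
    for j in range(len(betas[s])):
        if j != i:
            inner_s += betas[s][j] * c
    total = omega0 + omega[s] * _psi(inner_s)
    for k in range(len(omega)):
        if k != s:
            inner_k = beta0[k]
            for j in range(len(betas[k])):
                inner_k += betas[k][j] * c
            total += omega[k] * _psi(inner_k)
    return _psi(total)


def mrm_depth3_direct(omega0, omega, beta0, betas, s, i, a, b, c):
    """g(b) − g(a): the minority-report measure of leaf (s, i)."""
    return mrm_depth3_g(omega0, omega, beta0, betas, s, i, b, c) - mrm_depth3_g(
        omega0, omega, beta0, betas, s, i, a, c
    )


def auc_bruteforce(y, scores):
    """Mean over all case–control pairs of 1[case > control] + ½·1[tie]."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    cases = scores[y == 1]
    controls = scores[y == 0]
    total = 0.0
    for sc in cases:
        for sk in controls:
            if sc > sk:
                total += 1.0
            elif sc == sk:
                total += 0.5
    return total / (len(cases) * len(controls))
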