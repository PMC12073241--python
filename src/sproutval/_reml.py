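"""Internal REML and BLUP machinery for balanced and unbalanced designs.

For a balanced design the REML log-likelihood factorises over the ANOVA
strata: each stratum sum of squares ``SS_s`` on ``df_s`` degrees of
freedom is (up to constants) an independent ``theta_s * chi2(df_s)``
draw, where the expected mean square ``theta_s`` is a known non-negative
linear combination of the variance components.  REML estimation then
reduces to maximising

    -1/2 * sum_s [ df_s * ln(theta_s) + SS_s / theta_s ]

subject to component non-negativity.  At an interior optimum this
coincides with the classical expected-mean-squares (ANOVA) estimator;
on the boundary it is the non-negativity-constrained REML solution.

Unbalanced designs use the generic dense-covariance REML criterion
``-1/2 [ ln|V| + ln|X'V^-1 X| + y'Py ]``.

BLUPs are obtained from Henderson's mixed-model equations at the
estimated components.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

_EPS = 1e-12


def stratum_reml(ss: np.ndarray, df: np.ndarray, ems_coef: np.ndarray,
                 start: np.ndarray) -> np.ndarray:
    """Non-negativity-constrained REML for a balanced design.

    Parameters
    ----------
    ss, df
        Stratum sums of squares and degrees of freedom (length S).
    ems_coef
        (S, C) matrix mapping variance components to stratum expected
        mean squares; the residual component must have coefficient 1 in
        every stratum so all EMS stay positive.
    start
        Starting components (length C), e.g. truncated EMS estimates.
    """
    ss = np.asarray(ss, dtype=float)
    df = np.asarray(df, dtype=float)
    C = ems_coef.shape[1]
    scale = max(float(np.sum(ss) / np.sum(df)), _EPS)

    def neg2ll(sig):
        theta = ems_coef @ sig
        if np.any(theta <= 0):
            return np.inf
        return float(np.sum(df * np.log(theta) + ss / theta))

    x0 = np.maximum(np.asarray(start, dtype=float), scale * 1e-8)
    # keep the residual component strictly positive so every stratum EMS
    # stays in the likelihood's domain while the optimizer probes bounds
    bounds = [(0.0, None)] * C
    bounds[-1] = (scale * 1e-10, None)
    res = optimize.minimize(
        neg2ll, x0, method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
    )
    sig = np.maximum(res.x, 0.0)
    # polish: exact EMS solution is optimal when fully interior
    return sig


def generic_reml(y: np.ndarray, X: np.ndarray, Z_list: list[np.ndarray],
                 start: np.ndarray) -> np.ndarray:
    """Dense-covariance REML for possibly unbalanced designs.

    ``Z_list`` holds one indicator matrix per random term; the last
    returned component is the residual variance.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.asarray(X, dtype=float)
    G = [Z @ Z.T for Z in Z_list]
    vary = max(float(np.var(y)), _EPS)

    def neg2ll(log_sig):
        sig = np.exp(log_sig)
        V = sig[-1] * np.eye(n)
        for s, GG in zip(sig[:-1], G):
            V += s * GG
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        Vinv_y = np.linalg.solve(V, y)
        Vinv_X = np.linalg.solve(V, X)
        XtVX = X.T @ Vinv_X
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
        resid_quad = float(y @ Vinv_y - (X.T @ Vinv_y) @ beta)
        return logdetV + logdetXtVX + resid_quad

    x0 = np.log(np.maximum(np.asarray(start, dtype=float), vary * 1e-6))
    res = optimize.minimize(neg2ll, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
    sig = np.exp(res.x)
    # snap effectively-zero components (log-scale cannot reach 0 exactly)
    sig[sig < vary * 1e-7] = 0.0
    return sig


def henderson_blup(y: np.ndarray, X: np.ndarray, Z_list: list[np.ndarray],
                   sigma2_terms: list[float], sigma2_eps: float):
    """Solve Henderson's mixed-model equations.

    Returns (beta, [u_t per random term]).  Terms with zero variance get
    zero effects.  A relative ridge keeps the system well-posed when the
    residual variance is (numerically) zero, in which case BLUPs shrink
    toward the unshrunken group means as they should.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    active = [(Z, s) for Z, s in zip(Z_list, sigma2_terms) if s > 0]
    eps_eff = sigma2_eps + 1e-10 * max(float(np.var(y)), _EPS) + 1e-300
    if not active:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta, [np.zeros(Z.shape[1]) for Z in Z_list]
    W = np.hstack([X] + [Z for Z, _ in active])
    p = X.shape[1]
    lhs = W.T @ W
    ofs = p
    for Z, s in active:
        q = Z.shape[1]
        lam = eps_eff / s
        lhs[ofs:ofs + q, ofs:ofs + q] += lam * np.eye(q)
        ofs += q
    sol = np.linalg.solve(lhs, W.T @ y)
    beta = sol[:p]
    us, ofs = [], p
    it = iter(active)
    out = []
    for Z, s in zip(Z_list, sigma2_terms):
        if s > 0:
            q = Z.shape[1]
            out.append(sol[ofs:ofs + q])
            ofs += q
        else:
            out.append(np.zeros(Z.shape[1]))
    return beta, out


def indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Dense 0/1 indicator matrix from integer level codes."""
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z
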