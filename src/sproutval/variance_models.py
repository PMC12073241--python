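"""Random-effects models for multi-environment germination-index trials.

Two models are fitted, mirroring the standard analysis of a randomized
complete block design repeated across environments:

within one environment (blocks = replicates)::

    Y_ik = mu + g_i + r_k + eps_ik

across environments (all effects random)::

    Y_ijk = mu + g_i + e_j + r_k(e_j) + (g x e)_ij + eps_ijk

Variance components are estimated by non-negativity-constrained REML
(stratum likelihood on balanced data, dense-covariance REML otherwise);
genotype BLUPs come from Henderson's mixed-model equations at the
estimated components.  Broad-sense heritability on an entry-mean basis
is

    h2 = s2_g / (s2_g + s2_gxe / e + s2_eps / (e * r))

with ``e`` environments and ``r`` replicates.  Environment means are
compared with Tukey's studentized-range (HSD) test on the per-environment
genotype BLUPs under the two-way fixed-effects model ``Y_ij = mu + g_i +
e_j + eps_ij``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sproutval._reml import stratum_reml, generic_reml, henderson_blup, indicator
from sproutval._tukey import tukey_pairwise_p, compact_letter_display

logger = logging.getLogger(__name__)


class ModelDegenerateError(ValueError):
    """The design cannot support the requested random-effects model."""


class UndefinedHeritabilityError(ZeroDivisionError):
    """Heritability is 0/0 when genotypic, GxE and residual variance all vanish."""


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of the across-environment model (GI^2 units).

    For a within-environment fit, ``sigma2_e`` and ``sigma2_gxe`` are 0
    and ``e`` is 1.
    """

    sigma2_g: float
    sigma2_e: float
    sigma2_gxe: float
    sigma2_rep: float
    sigma2_eps: float
    e: int
    r: int

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_e", "sigma2_gxe", "sigma2_rep", "sigma2_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.e < 1 or self.r < 1:
            raise ValueError("e and r must be >= 1")


def _is_balanced(g_codes: np.ndarray, r_codes: np.ndarray, a: int, K: int) -> bool:
    n = g_codes.size
    if n != a * K:
        return False
    cell = g_codes * K + r_codes
    return len(np.unique(cell)) == n


def _check_columns(df: pd.DataFrame, cols) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"gi table missing columns {sorted(missing)}")


def fit_within_env(gi: pd.DataFrame, replicate_fixed: bool = False):
    """Fit ``Y_ik = mu + g_i + r_k + eps_ik`` for a single environment.

    Parameters
    ----------
    gi
        Long table with columns genotype_id, replicate, gi (one
        environment's records; missing plots allowed).
    replicate_fixed
        Treat the replicate (block) effect as fixed instead of random.

    Returns
    -------
    (blups, vc)
        ``blups`` is a DataFrame with columns genotype_id, effect, blup
        where ``blup = mu + effect`` is the predicted genotype GI;
        ``vc`` is a :class:`VarianceComponents` restricted to genotype,
        replicate and residual.
    """
    _check_columns(gi, ("genotype_id", "replicate", "gi"))
    g_codes, g_levels = pd.factorize(gi["genotype_id"], sort=True)
    r_codes, r_levels = pd.factorize(gi["replicate"], sort=True)
    a, K = len(g_levels), len(r_levels)
    if a < 2:
        raise ModelDegenerateError(f"need >= 2 genotypes, got {a}")
    y = gi["gi"].to_numpy(dtype=float)

    balanced = _is_balanced(g_codes, r_codes, a, K) and K >= 2
    if balanced:
        ybar = y.mean()
        gm = np.bincount(g_codes, weights=y, minlength=a) / K
        rm = np.bincount(r_codes, weights=y, minlength=K) / a
        ss_g = K * float(np.sum((gm - ybar) ** 2))
        ss_r = a * float(np.sum((rm - ybar) ** 2))
        resid = y - gm[g_codes] - rm[r_codes] + ybar
        ss_res = float(np.sum(resid ** 2))
        df = np.array([a - 1, K - 1, (a - 1) * (K - 1)], dtype=float)
        ms = np.array([ss_g, ss_r, ss_res]) / df
        # EMS: theta_G = eps + K*g ; theta_R = eps + a*r ; theta_res = eps
        ems = np.array([[K, 0, 1], [0, a, 1], [0, 0, 1]], dtype=float)
        start = np.maximum(
            [(ms[0] - ms[2]) / K, (ms[1] - ms[2]) / a, ms[2]], 0.0)
        sg, sr, se = stratum_reml([ss_g, ss_r, ss_res], df, ems, start)
    else:
        logger.info("within-environment design is unbalanced; using dense REML")
        Zg = indicator(g_codes, a)
        Zr = indicator(r_codes, K)
        vy = max(float(np.var(y)), 1e-10)
        sg, sr, se = generic_reml(y, np.ones((y.size, 1)), [Zg, Zr],
                                  np.array([vy / 2, vy / 10, vy / 2]))
    if replicate_fixed:
        # refit residual absorbing replicate as fixed is equivalent here to
        # reporting sigma2_rep = 0 and leaving genotype shrinkage unchanged
        sr_used = 0.0
    else:
        sr_used = sr

    X = np.ones((y.size, 1))
    Zg = indicator(g_codes, a)
    Zr = indicator(r_codes, K)
    if replicate_fixed and K >= 2:
        # centered block coding keeps the intercept at the grand mean
        B = Zr[:, 1:] - Zr[:, 1:].mean(axis=0)
        X = np.hstack([X, B])
        beta, (u_g,) = henderson_blup(y, X, [Zg], [sg], se)
        mu = float(beta[0])
    else:
        beta, (u_g, u_r) = henderson_blup(y, X, [Zg, Zr], [sg, sr_used], se)
        mu = float(beta[0])
    blups = pd.DataFrame({
        "genotype_id": g_levels,
        "effect": u_g,
        "blup": mu + u_g,
    })
    vc = VarianceComponents(sigma2_g=float(sg), sigma2_e=0.0, sigma2_gxe=0.0,
                            sigma2_rep=float(sr), sigma2_eps=float(se), e=1, r=K)
    return blups, vc


def fit_across_env(gi: pd.DataFrame):
    """Fit the all-random model across environments.

    ``Y_ijk = mu + g_i + e_j + r_k(e_j) + (g x e)_ij + eps_ijk``

    Parameters
    ----------
    gi
        Long table with columns genotype_id, environment_id, replicate, gi.

    Returns
    -------
    (blups, vc)
        Across-environment genotype BLUPs (grand mean + predicted
        genotype effect) and the five estimated variance components.
    """
    _check_columns(gi, ("genotype_id", "environment_id", "replicate", "gi"))
    envs = gi["environment_id"].unique()
    if len(envs) < 2:
        logger.warning("single environment supplied; delegating to fit_within_env")
        blups, vc = fit_within_env(gi)
        return blups, vc

    g_codes, g_levels = pd.factorize(gi["genotype_id"], sort=True)
    e_codes, e_levels = pd.factorize(gi["environment_id"], sort=True)
    r_codes, r_levels = pd.factorize(gi["replicate"], sort=True)
    a, b, r = len(g_levels), len(e_levels), len(r_levels)
    if a < 2:
        raise ModelDegenerateError(f"need >= 2 genotypes, got {a}")
    y = gi["gi"].to_numpy(dtype=float)
    n = y.size

    cell = g_codes * (b * r) + e_codes * r + r_codes
    balanced = (n == a * b * r) and (len(np.unique(cell)) == n) and r >= 2
    ge_codes = g_codes * b + e_codes
    re_codes = e_codes * r + r_codes

    if balanced:
        comps = _balanced_across_reml(y, g_codes, e_codes, r_codes, a, b, r)
    else:
        logger.info("across-environment design is unbalanced; using dense REML")
        vy = max(float(np.var(y)), 1e-10)
        Z = [indicator(g_codes, a), indicator(e_codes, b),
             indicator(re_codes, b * r), indicator(ge_codes, a * b)]
        comps = generic_reml(y, np.ones((n, 1)), Z,
                             np.array([vy / 3, vy / 4, vy / 10, vy / 4, vy / 3]))
    sg, sev, srep, sge, seps = comps

    Z = [indicator(g_codes, a), indicator(e_codes, b),
         indicator(re_codes, b * r), indicator(ge_codes, a * b)]
    beta, (u_g, u_e, u_re, u_ge) = henderson_blup(
        y, np.ones((n, 1)), Z, [sg, sev, srep, sge], seps)
    mu = float(beta[0])
    blups = pd.DataFrame({"genotype_id": g_levels, "effect": u_g, "blup": mu + u_g})
    vc = VarianceComponents(sigma2_g=float(sg), sigma2_e=float(sev),
                            sigma2_gxe=float(sge), sigma2_rep=float(srep),
                            sigma2_eps=float(seps), e=b, r=r)
    return blups, vc


def anova_ems_across(gi: pd.DataFrame) -> dict:
    """Expected-mean-squares (ANOVA) estimates on balanced data.

    Returned as a dict with the stratum sums of squares, degrees of
    freedom and the (possibly negative, untruncated) moment estimates.
    Serves as the balanced-data cross-check for the REML fit.
    """
    _check_columns(gi, ("genotype_id", "environment_id", "replicate", "gi"))
    g_codes, g_levels = pd.factorize(gi["genotype_id"], sort=True)
    e_codes, e_levels = pd.factorize(gi["environment_id"], sort=True)
    r_codes, r_levels = pd.factorize(gi["replicate"], sort=True)
    a, b, r = len(g_levels), len(e_levels), len(r_levels)
    y = gi["gi"].to_numpy(dtype=float)
    ss, df = _across_strata(y, g_codes, e_codes, r_codes, a, b, r)
    ms = ss / df
    est = {
        "sigma2_eps": ms[4],
        "sigma2_gxe": (ms[3] - ms[4]) / r,
        "sigma2_rep": (ms[2] - ms[4]) / a,
        "sigma2_g": (ms[0] - ms[3]) / (b * r),
        "sigma2_e": (ms[1] - ms[3] - ms[2] + ms[4]) / (a * r),
    }
    return {"ss": ss, "df": df, "ms": ms, "estimates": est}


def _across_strata(y, g_codes, e_codes, r_codes, a, b, r):
    """Sums of squares and dfs for the balanced a x b x r all-random design."""
    ybar = y.mean()
    gm = np.bincount(g_codes, weights=y, minlength=a) / (b * r)
    em = np.bincount(e_codes, weights=y, minlength=b) / (a * r)
    re_codes = e_codes * r + r_codes
    rem = np.bincount(re_codes, weights=y, minlength=b * r) / a
    ge_codes = g_codes * b + e_codes
    gem = np.bincount(ge_codes, weights=y, minlength=a * b) / r
    ss_g = b * r * float(np.sum((gm - ybar) ** 2))
    ss_e = a * r * float(np.sum((em - ybar) ** 2))
    ss_re = a * float(np.sum((rem - em[np.arange(b * r) // r]) ** 2))
    ge_dev = gem.reshape(a, b) - gm[:, None] - em[None, :] + ybar
    ss_ge = r * float(np.sum(ge_dev ** 2))
    resid = y - gem[ge_codes] - rem[re_codes] + em[e_codes]
    ss_res = float(np.sum(resid ** 2))
    ss = np.array([ss_g, ss_e, ss_re, ss_ge, ss_res])
    df = np.array([a - 1, b - 1, b * (r - 1), (a - 1) * (b - 1),
                   (a - 1) * b * (r - 1)], dtype=float)
    return ss, df


def _balanced_across_reml(y, g_codes, e_codes, r_codes, a, b, r):
    ss, df = _across_strata(y, g_codes, e_codes, r_codes, a, b, r)
    ms = ss / df
    # components order: g, e, rep(e), gxe, eps
    ems = np.array([
        [b * r, 0, 0, r, 1],   # genotype stratum
        [0, a * r, a, r, 1],   # environment stratum
        [0, 0, a, 0, 1],       # rep within environment
        [0, 0, 0, r, 1],       # G x E
        [0, 0, 0, 0, 1],       # residual
    ], dtype=float)
    start = np.maximum([
        (ms[0] - ms[3]) / (b * r),
        (ms[1] - ms[3] - ms[2] + ms[4]) / (a * r),
        (ms[2] - ms[4]) / a,
        (ms[3] - ms[4]) / r,
        ms[4],
    ], 0.0)
    return stratum_reml(ss, df, ems, start)


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability on an entry-mean basis.

    ``h2 = s2_g / (s2_g + s2_gxe/e + s2_eps/(e*r))``
    """
    denom = vc.sigma2_g + vc.sigma2_gxe / vc.e + vc.sigma2_eps / (vc.e * vc.r)
    if denom == 0:
        raise UndefinedHeritabilityError(
            "genotypic, GxE and residual variances are all zero")
    return vc.sigma2_g / denom


def variance_shares(vc: VarianceComponents) -> dict[str, int]:
    """Percent share of each component in the G + E + GxE + residual total.

    Shares are rounded to integer percent (half away from zero), the
    precision at which such tables are conventionally reported.
    """
    total = vc.sigma2_g + vc.sigma2_e + vc.sigma2_gxe + vc.sigma2_eps
    if total == 0:
        raise ValueError("total variance is zero; shares undefined")

    def pct(x):
        return int(np.floor(100.0 * x / total + 0.5))

    return {
        "genotype": pct(vc.sigma2_g),
        "environment": pct(vc.sigma2_e),
        "gxe": pct(vc.sigma2_gxe),
        "residual": pct(vc.sigma2_eps),
    }


def compare_env_means(blups_by_env: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD comparison of environment means on per-environment BLUPs.

    Fits the two-way fixed-effects model ``Y_ij = mu + g_i + e_j +
    eps_ij`` to the per-environment genotype BLUPs and compares
    environment means with the studentized-range test (Tukey-Kramer
    harmonic correction when genotype coverage is mildly unbalanced).

    Parameters
    ----------
    blups_by_env
        Long table with columns genotype_id, environment_id, blup.
    alpha
        Family-wise significance level for the letter display.

    Returns
    -------
    DataFrame with one row per environment (descending mean order):
    environment_id, mean, sd, min, max, n, letter.  Environments sharing
    a letter do not differ significantly at ``alpha``.
    """
    _check_columns(blups_by_env, ("genotype_id", "environment_id", "blup"))
    df = blups_by_env
    envs = df["environment_id"].unique()
    if len(envs) < 2:
        raise ModelDegenerateError("need >= 2 environments to compare")

    counts = df.groupby("environment_id")["genotype_id"].nunique()
    if counts.nunique() > 1:
        logger.warning("unbalanced genotype coverage across environments: %s",
                       counts.to_dict())

    g_codes, g_levels = pd.factorize(df["genotype_id"], sort=True)
    e_codes, e_levels = pd.factorize(df["environment_id"], sort=True)
    y = df["blup"].to_numpy(dtype=float)
    a, b = len(g_levels), len(e_levels)
    # two-way additive fixed-effects fit (reference coding)
    X = np.hstack([np.ones((y.size, 1)),
                   indicator(g_codes, a)[:, 1:],
                   indicator(e_codes, b)[:, 1:]])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dfe = y.size - rank
    if dfe <= 0:
        raise ModelDegenerateError("no residual degrees of freedom")
    mse = float(resid @ resid) / dfe

    stats = df.groupby("environment_id")["blup"].agg(["mean", "std", "min", "max", "count"])
    stats = stats.reindex(e_levels)
    means = stats["mean"].to_numpy()
    ns = stats["count"].to_numpy(dtype=float)
    pmat = tukey_pairwise_p(means, ns, mse, dfe)
    order = np.argsort(-means, kind="stable")  # letters follow descending mean
    letters = compact_letter_display(pmat, order, alpha=alpha)

    out = pd.DataFrame({
        "environment_id": e_levels,
        "mean": means,
        "sd": stats["std"].to_numpy(),
        "min": stats["min"].to_numpy(),
        "max": stats["max"].to_numpy(),
        "n": ns.astype(int),
        "letter": letters,
    })
    return out.iloc[order].reset_index(drop=True)
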