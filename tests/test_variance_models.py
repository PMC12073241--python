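"""Variance components, BLUPs, heritability and environment comparison.

Oracles: the within-environment BLUPs are checked against a direct
generalized-least-squares solve built in the test (V-matrix route,
independent of the mixed-model-equations implementation); the
across-environment REML fit is checked against the expected-mean-squares
closed form on balanced data and against direct evaluation of the dense
REML log-likelihood at perturbed points.
"""

import numpy as np
import pandas as pd
import pytest

from sproutval.variance_models import (
    ModelDegenerateError,
    UndefinedHeritabilityError,
    VarianceComponents,
    anova_ems_across,
    compare_env_means,
    fit_across_env,
    fit_within_env,
    heritability,
    variance_shares,
)
from sproutval.synthetic_data import SimulationConfig, simulate_panel, simulate_trials
from sproutval.phenotype import gi_table

from conftest import make_gi_frame


# ---------------------------------------------------------------- heritability

def test_heritability_formula_and_edges():
    vc = VarianceComponents(0.031, 0.015, 0.018, 0.0, 0.003, e=4, r=2)
    assert heritability(vc) == pytest.approx(0.86, abs=0.005)

    noiseless = VarianceComponents(0.02, 0.0, 0.0, 0.0, 0.0, e=4, r=2)
    assert heritability(noiseless) == 1.0
    no_genetics = VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.01, e=4, r=2)
    assert heritability(no_genetics) == 0.0
    with pytest.raises(UndefinedHeritabilityError):
        heritability(VarianceComponents(0.0, 0.5, 0.0, 0.0, 0.0, e=2, r=2))


def test_heritability_monotonicity():
    base = VarianceComponents(0.031, 0.015, 0.018, 0.0, 0.003, e=4, r=2)
    more_g = VarianceComponents(0.05, 0.015, 0.018, 0.0, 0.003, e=4, r=2)
    more_gxe = VarianceComponents(0.031, 0.015, 0.05, 0.0, 0.003, e=4, r=2)
    more_eps = VarianceComponents(0.031, 0.015, 0.018, 0.0, 0.05, e=4, r=2)
    assert heritability(more_g) > heritability(base)
    assert heritability(more_gxe) < heritability(base)
    assert heritability(more_eps) < heritability(base)


def test_variance_shares():
    vc = VarianceComponents(0.031, 0.015, 0.018, 0.0, 0.003, e=4, r=2)
    shares = variance_shares(vc)
    assert (shares["genotype"], shares["environment"], shares["gxe"]) == (46, 22, 27)

    single = VarianceComponents(0.02, 0.0, 0.0, 0.0, 0.0, e=1, r=1)
    assert variance_shares(single)["genotype"] == 100
    equal = VarianceComponents(0.01, 0.01, 0.01, 0.0, 0.01, e=2, r=2)
    assert set(variance_shares(equal).values()) == {25}
    with pytest.raises(ValueError):
        variance_shares(VarianceComponents(0, 0, 0, 0.5, 0, e=2, r=2))


# --------------------------------------------------------------- within-env fit

def test_constant_observations_give_zero_components():
    gi = make_gi_frame(np.full((6, 2), 0.4))
    blups, vc = fit_within_env(gi)
    assert vc.sigma2_g == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(blups["effect"], 0.0, atol=1e-6)


def test_noise_free_blups_equal_genotype_means():
    vals = np.repeat(np.linspace(0.1, 0.9, 8)[:, None], 2, axis=1)
    gi = make_gi_frame(vals)
    blups, vc = fit_within_env(gi)
    assert vc.sigma2_eps == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(blups["blup"], vals[:, 0], atol=1e-4)


def test_within_env_blups_match_gls_oracle():
    """Balanced 10x2 fit agrees with a direct V-matrix GLS/BLUP solve."""
    rng = np.random.default_rng(42)
    a, k = 10, 2
    g = rng.normal(0, 0.15, a)
    r = rng.normal(0, 0.03, k)
    vals = 0.4 + g[:, None] + r[None, :] + rng.normal(0, 0.05, (a, k))
    gi = make_gi_frame(vals)
    blups, vc = fit_within_env(gi)

    # oracle: u = s2g * Zg' V^-1 (y - X mu_hat) with V from the estimates
    y = vals.ravel()
    Zg = np.kron(np.eye(a), np.ones((k, 1)))
    Zr = np.kron(np.ones((a, 1)), np.eye(k))
    V = (vc.sigma2_g * Zg @ Zg.T + vc.sigma2_rep * Zr @ Zr.T
         + vc.sigma2_eps * np.eye(a * k))
    Vi = np.linalg.inv(V)
    X = np.ones((a * k, 1))
    mu = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y).item()
    u = vc.sigma2_g * Zg.T @ Vi @ (y - mu)
    assert np.allclose(blups["effect"], u, atol=1e-6)

    # shrinkage form: effect = shrink * (genotype mean - grand mean)
    shrink = vc.sigma2_g / (vc.sigma2_g + vc.sigma2_eps / k)
    dev = vals.mean(axis=1) - vals.mean()
    assert np.allclose(blups["effect"], shrink * dev, atol=1e-6)


def test_blup_shrinkage_never_exceeds_raw_deviation():
    rng = np.random.default_rng(3)
    vals = 0.35 + rng.normal(0, 0.12, (15, 2))
    gi = make_gi_frame(vals)
    blups, _ = fit_within_env(gi)
    dev = vals.mean(axis=1) - vals.mean()
    assert np.all(np.abs(blups["effect"]) <= np.abs(dev) + 1e-10)
    assert abs(blups["effect"].mean()) < 1e-6


def test_within_env_needs_two_genotypes():
    gi = make_gi_frame(np.array([[0.2, 0.3]]))
    with pytest.raises(ModelDegenerateError):
        fit_within_env(gi)


def test_within_env_handles_missing_plot():
    rng = np.random.default_rng(11)
    vals = 0.4 + rng.normal(0, 0.1, (8, 2))
    gi = make_gi_frame(vals).drop(index=3).reset_index(drop=True)
    blups, vc = fit_within_env(gi)   # unbalanced path
    assert len(blups) == 8
    assert vc.sigma2_g >= 0 and vc.sigma2_eps >= 0


# --------------------------------------------------------------- across-env fit

def _across_frame(rng, a=12, b=3, r=2, comps=(0.03, 0.015, 0.018, 0.001, 0.003)):
    sg, se, sge, sr, seps = comps
    g = rng.normal(0, np.sqrt(sg), a)
    e = rng.normal(0, np.sqrt(se), b)
    ge = rng.normal(0, np.sqrt(sge), (a, b))
    rep = rng.normal(0, np.sqrt(sr), (b, r))
    eps = rng.normal(0, np.sqrt(seps), (a, b, r))
    rows = []
    for i in range(a):
        for j in range(b):
            for k in range(r):
                rows.append({
                    "genotype_id": f"G{i:02d}", "environment_id": f"E{j}",
                    "replicate": k + 1,
                    "gi": 0.35 + g[i] + e[j] + ge[i, j] + rep[j, k] + eps[i, j, k],
                })
    return pd.DataFrame(rows)


def test_across_env_reml_matches_ems_on_balanced_interior_fit():
    gi = _across_frame(np.random.default_rng(5), a=40, b=4, r=2)
    _, vc = fit_across_env(gi)
    ems = anova_ems_across(gi)["estimates"]
    # all generating components comfortably positive -> interior optimum
    for name in ("sigma2_g", "sigma2_e", "sigma2_gxe", "sigma2_rep", "sigma2_eps"):
        assert getattr(vc, name) == pytest.approx(ems[name], abs=1e-6)


def test_across_env_reml_is_local_optimum_of_dense_loglik():
    """Tiny 4x2x2 fit beats random perturbations of the dense REML criterion."""
    gi = _across_frame(np.random.default_rng(8), a=4, b=2, r=2)
    _, vc = fit_across_env(gi)
    est = np.array([vc.sigma2_g, vc.sigma2_e, vc.sigma2_rep,
                    vc.sigma2_gxe, vc.sigma2_eps])

    g_codes, _ = pd.factorize(gi["genotype_id"], sort=True)
    e_codes, _ = pd.factorize(gi["environment_id"], sort=True)
    r_codes, _ = pd.factorize(gi["replicate"], sort=True)
    y = gi["gi"].to_numpy()
    n = y.size

    def Z(codes, m):
        out = np.zeros((n, m))
        out[np.arange(n), codes] = 1
        return out

    Zs = [Z(g_codes, 4), Z(e_codes, 2), Z(e_codes * 2 + r_codes, 4),
          Z(g_codes * 2 + e_codes, 8)]
    X = np.ones((n, 1))

    def neg2ll(sig):
        V = sig[4] * np.eye(n)
        for s, Zi in zip(sig[:4], Zs):
            V += s * Zi @ Zi.T
        Vi = np.linalg.inv(V)
        _, ld = np.linalg.slogdet(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        res = y - X @ beta
        return float(ld + np.linalg.slogdet(XtViX)[1] + res @ Vi @ res)

    base = neg2ll(est)
    rng = np.random.default_rng(0)
    for _ in range(50):
        pert = np.clip(est * np.exp(rng.normal(0, 0.3, 5)) + rng.normal(0, 1e-4, 5),
                       1e-10, None)
        assert neg2ll(pert) >= base - 1e-6


def test_across_env_zero_interaction_recovered():
    gi = _across_frame(np.random.default_rng(2), a=30, b=3, r=2,
                       comps=(0.03, 0.01, 0.0, 0.001, 0.0))
    _, vc = fit_across_env(gi)
    assert vc.sigma2_gxe <= 1e-6
    assert vc.sigma2_eps <= 1e-6


def test_across_env_single_environment_delegates():
    gi = _across_frame(np.random.default_rng(4), a=10, b=1, r=2)
    blups, vc = fit_across_env(gi)
    assert vc.e == 1 and len(blups) == 10


def test_balanced_anova_decomposition_is_exact():
    gi = _across_frame(np.random.default_rng(9), a=10, b=3, r=2)
    res = anova_ems_across(gi)
    y = gi["gi"].to_numpy()
    total_ss = float(np.sum((y - y.mean()) ** 2))
    assert np.sum(res["ss"]) == pytest.approx(total_ss, rel=1e-8)


def test_component_recovery_from_binomial_trials():
    """Variance components are recovered from full simulated trials.

    Estimates are compared with the realized variances of the effects
    the generator drew: with only four environments the environment
    draw itself scatters widely around its generating value, so the
    realized variance is the estimable target.  The plot-level binomial
    counting process adds p(1-p)[(2-p)^2+(1-p)]/(4N) of variance on top
    of the generating residual, so the residual estimate is checked
    against generating-plus-counting variance.
    """
    rel_err = []
    eps_hat = []
    for seed in range(20):
        cfg = SimulationConfig(rng_seed=seed)
        _, _, truth = simulate_panel(cfg)
        gi = gi_table(simulate_trials(cfg, truth))
        _, vc = fit_across_env(gi)
        rc = truth.realized_components
        est = np.array([vc.sigma2_g, vc.sigma2_e, vc.sigma2_gxe])
        tgt = np.array([rc["sigma2_g"], rc["sigma2_e"], rc["sigma2_gxe"]])
        rel_err.append(np.abs(est - tgt) / tgt)
        eps_hat.append(vc.sigma2_eps)
    med = np.median(np.array(rel_err), axis=0)
    assert np.all(med <= 0.25)
    # counting variance at the grand-mean latent value (m = 0.35, p = 0.255)
    p = (3 - np.sqrt(9 - 8 * 0.35)) / 2
    counting = p * (1 - p) * ((2 - p) ** 2 + (1 - p)) / (4 * 40)
    assert np.median(eps_hat) == pytest.approx(0.003 + counting, rel=0.25)


# --------------------------------------------------------- environment means

def _blup_frame(means, a=30, sd=0.01, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for j, m in enumerate(means):
        for i in range(a):
            rows.append({"genotype_id": f"G{i:02d}", "environment_id": f"E{j + 1}",
                         "blup": m + rng.normal(0, sd)})
    return pd.DataFrame(rows)


def test_env_means_distinct_letters_when_far_apart():
    cmp_ = compare_env_means(_blup_frame([0.6, 0.2], sd=0.01))
    assert set(cmp_["letter"]) == {"a", "b"}


def test_env_means_share_letter_when_identical():
    cmp_ = compare_env_means(_blup_frame([0.4, 0.4, 0.4], sd=0.02))
    assert set(cmp_["letter"]) == {"a"}


def test_env_means_reference_letter_pattern():
    """Means 0.50/0.36/0.33/0.19 group as a/b/b/c under GxE-scale noise.

    The per-environment BLUP noise is set to the GxE standard deviation
    (sqrt(0.018) ~ 0.134), the residual scale the two-way fixed model
    sees after absorbing genotype and environment means.
    """
    cmp_ = compare_env_means(_blup_frame([0.50, 0.36, 0.33, 0.19],
                                         a=200, sd=0.134, seed=0))
    by_env = cmp_.set_index("environment_id")["letter"]
    assert by_env["E1"] == "a"
    assert by_env["E2"] == by_env["E3"] == "b"
    assert by_env["E4"] == "c"
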