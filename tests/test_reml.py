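"""REML engine: grid-search oracle equivalence, BLUP/MME identities, bivariate."""

import numpy as np
import pytest

import phenoblup as pb
from conftest import random_kinship
from phenoblup.errors import ConfigurationError, StructuralError


def reml_loglik_oracle(y, X, V):
    """Restricted log-likelihood written independently from first principles."""
    n = len(y)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    (_, ld_v) = np.linalg.slogdet(V)
    (_, ld_x) = np.linalg.slogdet(XtViX)
    return -0.5 * (ld_v + ld_x + r @ Vi @ r)


def _simulate_single_kernel(n=25, seed=0, s2g=1.0, s2e=0.5):
    k = random_kinship(n, 2 * n, seed)
    rng = np.random.default_rng(seed + 1)
    w, U = np.linalg.eigh(k.values)
    g = (U * np.sqrt(np.clip(w, 0, None) * s2g)) @ rng.standard_normal(n)
    y = 3.0 + g + rng.normal(0, np.sqrt(s2e), n)
    return k, y


def test_single_kernel_fit_matches_grid_search():
    """REML solution sits on the grid-search optimum of the likelihood."""
    k, y = _simulate_single_kernel()
    levels = list(k.ids)
    fm = pb.fit_reml(y, [pb.RandomEffect("g", levels, k)])
    X = np.ones((len(y), 1))
    grid = np.linspace(0.01, 3.0, 200)
    best, best_ll = None, -np.inf
    for s2g in grid:
        for s2e in grid:
            ll = reml_loglik_oracle(y, X, s2g * k.values + s2e * np.eye(len(y)))
            if ll > best_ll:
                best, best_ll = (s2g, s2e), ll
    step = grid[1] - grid[0]
    assert fm.varcomp["g"] == pytest.approx(best[0], abs=step)
    assert fm.varcomp["residual"] == pytest.approx(best[1], abs=step)
    assert fm.loglik >= best_ll - 1e-6


def test_constant_response_all_variances_floor():
    k = random_kinship(12, 30, 3)
    fm = pb.fit_reml(np.full(12, 4.2), [pb.RandomEffect("g", list(k.ids), k)])
    assert fm.mu == pytest.approx(4.2)
    assert fm.varcomp["g"] == 0.0
    assert fm.varcomp["residual"] == 0.0


def test_solution_beats_random_admissible_points():
    k, y = _simulate_single_kernel(n=20, seed=5)
    eff = [pb.RandomEffect("g", list(k.ids), k)]
    fm = pb.fit_reml(y, eff)
    rng = np.random.default_rng(0)
    for _ in range(50):
        s2 = {"g": rng.uniform(0.01, 4), "residual": rng.uniform(0.01, 4)}
        assert fm.loglik >= pb.restricted_loglik(y, eff, s2) - 1e-8


def test_missing_observations_dropped_rowwise():
    k, y = _simulate_single_kernel(n=20, seed=9)
    y2 = y.copy()
    y2[[3, 7]] = np.nan
    keep = ~np.isnan(y2)
    fm_full = pb.fit_reml(
        y[keep],
        [pb.RandomEffect("g", [g for g, m in zip(k.ids, keep) if m], k)],
    )
    fm_nan = pb.fit_reml(y2, [pb.RandomEffect("g", list(k.ids), k)])
    assert fm_nan.loglik == pytest.approx(fm_full.loglik, abs=1e-8)
    assert fm_nan.mu == pytest.approx(fm_full.mu, abs=1e-8)


def test_predict_training_equals_blup_combination(small_dataset, small_kernels):
    design = small_dataset["design"]
    phen = small_dataset["phen"]
    y = (
        phen.pivot(index="hybrid_id", columns="trait", values="value")
        .loc[design.hybrid_ids, "trait1"]
        .to_numpy()
    )
    eff = [
        pb.RandomEffect(
            "gca_d", [d for _, d, _ in design.hybrids], small_kernels["gca_dent"]
        ),
        pb.RandomEffect(
            "gca_f", [f for _, _, f in design.hybrids], small_kernels["gca_flint"]
        ),
    ]
    fm = pb.fit_reml(y, eff)
    pred = pb.predict(
        fm,
        {
            "gca_d": [d for _, d, _ in design.hybrids],
            "gca_f": [f for _, _, f in design.hybrids],
        },
    )
    manual = fm.mu + np.array(
        [
            fm.blup["gca_d"][d] + fm.blup["gca_f"][f]
            for _, d, f in design.hybrids
        ]
    )
    np.testing.assert_allclose(pred, manual, atol=1e-9)


def test_predict_matches_mixed_model_equations():
    """Out-of-sample BLUP equals the Henderson MME solution."""
    n_all, n_train = 12, 9
    k = random_kinship(n_all, 40, 21)
    rng = np.random.default_rng(2)
    w, U = np.linalg.eigh(k.values)
    g = (U * np.sqrt(np.clip(w, 0, None))) @ rng.standard_normal(n_all)
    y = 1.0 + g[:n_train] + rng.normal(0, 0.6, n_train)
    train_ids = k.ids[:n_train]
    fm = pb.fit_reml(y, [pb.RandomEffect("g", train_ids, k)])
    s2g, s2e = fm.varcomp["g"], fm.varcomp["residual"]
    # Henderson MME over ALL kernel levels, Z selecting the training ones
    Z = np.zeros((n_train, n_all))
    Z[np.arange(n_train), np.arange(n_train)] = 1.0
    X = np.ones((n_train, 1))
    Kinv = np.linalg.inv(k.values + 1e-10 * np.eye(n_all))
    lam = s2e / s2g
    lhs = np.block(
        [
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + Kinv * lam],
        ]
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    mme_pred = sol[0] + sol[1 + n_train :]  # mu + u for held-out levels
    pred = pb.predict(fm, {"g": k.ids[n_train:]})
    np.testing.assert_allclose(pred, mme_pred, atol=1e-6)


def test_predict_with_no_kernel_covariance_returns_mu():
    k = pb.KernelMatrix(
        np.diag([1.0, 1.0, 1.0, 1.0]), list("abcd"), "genomic", "GCA_dent"
    )
    rng = np.random.default_rng(0)
    y = 5.0 + rng.normal(0, 1, 3)
    fm = pb.fit_reml(y, [pb.RandomEffect("g", ["a", "b", "c"], k)])
    pred = pb.predict(fm, {"g": ["d"]})  # level d: zero covariance to training
    assert pred[0] == pytest.approx(fm.mu, abs=1e-12)


def test_near_zero_residual_interpolates_training_data():
    k, _ = _simulate_single_kernel(n=15, seed=13)
    rng = np.random.default_rng(4)
    w, U = np.linalg.eigh(k.values)
    g = (U * np.sqrt(np.clip(w, 0, None))) @ rng.standard_normal(15)
    y = 2.0 + g + rng.normal(0, 1e-5, 15)
    fm = pb.fit_reml(y, [pb.RandomEffect("g", list(k.ids), k)])
    pred = pb.predict(fm, {"g": list(k.ids)})
    np.testing.assert_allclose(pred, y, atol=1e-3)


def test_zero_variance_effect_leaves_fit_unchanged():
    """Adding an effect estimated at the floor does not move the solution."""
    k, y = _simulate_single_kernel(n=22, seed=17)
    eff1 = [pb.RandomEffect("g", list(k.ids), k)]
    fm1 = pb.fit_reml(y, eff1)
    # a pure-noise second kernel unrelated to y's structure, tiny signal
    k2 = random_kinship(22, 60, 99, ids=list(k.ids), role="GCA_flint")
    fm2 = pb.fit_reml(y, eff1 + [pb.RandomEffect("z", list(k.ids), k2)])
    if fm2.varcomp["z"] < 1e-6:
        assert fm2.mu == pytest.approx(fm1.mu, abs=1e-4)
        assert fm2.varcomp["g"] == pytest.approx(fm1.varcomp["g"], rel=0.05)
        p1 = pb.predict(fm1, {"g": list(k.ids)})
        p2 = pb.predict(fm2, {"g": list(k.ids), "z": list(k.ids)})
        np.testing.assert_allclose(p1, p2, atol=1e-3)


def test_two_kernel_fit_matches_grid_search():
    n = 24
    k1 = random_kinship(n, 50, 31)
    k2 = random_kinship(n, 50, 32, ids=list(k1.ids), role="GCA_flint")
    rng = np.random.default_rng(33)
    w1, U1 = np.linalg.eigh(k1.values)
    w2, U2 = np.linalg.eigh(k2.values)
    y = (
        1.0
        + (U1 * np.sqrt(np.clip(w1, 0, None) * 1.2)) @ rng.standard_normal(n)
        + (U2 * np.sqrt(np.clip(w2, 0, None) * 0.6)) @ rng.standard_normal(n)
        + rng.normal(0, 0.8, n)
    )
    eff = [
        pb.RandomEffect("a", list(k1.ids), k1),
        pb.RandomEffect("b", list(k1.ids), k2),
    ]
    fm = pb.fit_reml(y, eff)
    X = np.ones((n, 1))
    grid = np.linspace(0.02, 4.0, 35)
    best, best_ll = None, -np.inf
    for sa in grid:
        for sb in grid:
            for se in grid:
                V = sa * k1.values + sb * k2.values + se * np.eye(n)
                ll = reml_loglik_oracle(y, X, V)
                if ll > best_ll:
                    best, best_ll = (sa, sb, se), ll
    step = grid[1] - grid[0]
    assert fm.varcomp["a"] == pytest.approx(best[0], abs=step)
    assert fm.varcomp["b"] == pytest.approx(best[1], abs=step)
    assert fm.varcomp["residual"] == pytest.approx(best[2], abs=step)
    assert fm.loglik >= best_ll - 1e-6


def test_insufficient_observations_rejected():
    k = random_kinship(3, 10, 0)
    with pytest.raises(ConfigurationError):
        pb.fit_reml(np.array([1.0, 2.0]), [pb.RandomEffect("g", k.ids[:2], k)])


# ---------------------------------------------------------------------------
# bivariate model
# ---------------------------------------------------------------------------

def _bivariate_data(n=40, s_g=1.0, rho=0.9, s_e=0.5, seed=0):
    k = random_kinship(n, 100, seed)
    rng = np.random.default_rng(seed + 7)
    w, U = np.linalg.eigh(k.values)
    F = U * np.sqrt(np.clip(w, 0, None))
    shared = F @ rng.standard_normal(n)
    own1 = F @ rng.standard_normal(n)
    own2 = F @ rng.standard_normal(n)
    u1 = np.sqrt(s_g) * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * own1)
    u2 = np.sqrt(s_g) * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * own2)
    y1 = 1.0 + u1 + rng.normal(0, np.sqrt(s_e), n)
    y2 = 2.0 + u2 + rng.normal(0, np.sqrt(s_e), n)
    return k, y1, y2


def test_bivariate_swap_symmetry():
    k, y1, y2 = _bivariate_data(seed=3)
    a = pb.fit_bivariate(y1, y2, k.ids, k.ids, k)
    b = pb.fit_bivariate(y2, y1, k.ids, k.ids, k)
    assert a.sigma2_u1 == pytest.approx(b.sigma2_u2, rel=1e-3, abs=1e-5)
    assert a.sigma2_e1 == pytest.approx(b.sigma2_e2, rel=1e-3, abs=1e-5)
    assert a.sigma_u12 == pytest.approx(b.sigma_u12, rel=1e-3, abs=1e-5)


def test_bivariate_recovers_shared_genetics():
    """y2 = y1's genetic part + its own noise: covariance ~ variance."""
    comps = []
    for seed in range(10):
        k, y1, y2 = _bivariate_data(rho=1.0, seed=seed)
        comps.append(pb.fit_bivariate(y1, y2, k.ids, k.ids, k))
    cov = np.mean([c.sigma_u12 for c in comps])
    v1 = np.mean([c.sigma2_u1 for c in comps])
    assert cov == pytest.approx(v1, rel=0.25)
    assert cov == pytest.approx(1.0, rel=0.3)


def test_bivariate_independent_trials_near_zero_covariance():
    covs = []
    for seed in range(8):
        k, y1, _ = _bivariate_data(rho=1.0, seed=seed)
        k2, _, y2 = _bivariate_data(rho=1.0, seed=seed + 100)
        covs.append(pb.fit_bivariate(y1, y2, k.ids, k.ids, k).sigma_u12)
    assert abs(np.mean(covs)) < 0.15


def test_bivariate_empty_trial_instructs_univariate():
    k = random_kinship(10, 20, 0)
    with pytest.raises(ConfigurationError, match="univariate"):
        pb.fit_bivariate(np.array([]), np.ones(10), [], k.ids, k)


def test_bivariate_genetic_matrix_psd():
    k, y1, y2 = _bivariate_data(seed=11)
    comp = pb.fit_bivariate(y1, y2, k.ids, k.ids, k)
    assert np.linalg.eigvalsh(comp.genetic_matrix())[0] >= -1e-12


# ---------------------------------------------------------------------------
# Yamada decomposition (closed forms)
# ---------------------------------------------------------------------------

def test_yamada_closed_forms():
    b = pb.BivariateComponents(2.0, 4.0, 1.0, 1.0, 3.0)
    dec = pb.yamada_decomposition(b)
    assert dec["sigma2_G"] == 1.0
    assert dec["sigma2_GxE"] == 2.0  # (2+4)/2 - 1
    assert dec["sigma2_e"] == 2.0  # (1+3)/2


def test_yamada_perfect_correlation_no_gxe():
    v = 1.7
    dec = pb.yamada_decomposition(pb.BivariateComponents(v, v, v, 0.4, 0.4))
    assert dec["sigma2_G"] == pytest.approx(v)
    assert dec["sigma2_GxE"] == pytest.approx(0.0, abs=1e-12)
    assert dec["prop_G"] + dec["prop_GxE"] + dec["prop_e"] == pytest.approx(1.0)
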