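import numpy as np
import pandas as pd
import pytest

from hzkit.errors import ContractError, ValidationError
from hzkit.selection import (composite_fitness, fit_nb_glm,
                             lr_interaction_test, selection_coefficients)

from conftest import make_transplant


# --------------------------------------------------------- composite fitness

def test_dead_plant_zero_fitness():
    tt = make_transplant([["a", "P1", "dune", "ambient", 0, 50.0, "burial"],
                          ["b", "P2", "dune", "ambient", 1, 1.0, "alive"]])
    assert composite_fitness(tt)[0] == 0.0


def test_survivor_zero_biomass_zero_fitness():
    tt = make_transplant([["a", "P1", "dune", "ambient", 1, 0.0, "alive"],
                          ["b", "P2", "dune", "ambient", 1, 1.0, "alive"]])
    assert composite_fitness(tt)[0] == 0.0


def test_ln_identity():
    tt = make_transplant(
        [["a", "P1", "dune", "ambient", 1, float(np.e - 1), "alive"],
         ["b", "P2", "dune", "ambient", 1, 1.0, "alive"]])
    assert composite_fitness(tt)[0] == pytest.approx(1.0)


# ----------------------------------------------------- selection coefficients

def test_hand_arithmetic_s(two_cell_transplant):
    out = selection_coefficients(two_cell_transplant, n_boot=0)
    s = {(f.habitat, f.phenotype): f.s for f in out}
    assert s[("dune", "P1")] == pytest.approx(0.0)
    assert s[("dune", "P2")] == pytest.approx(0.75)


def test_identical_cells_all_s_zero():
    rows = []
    for i in range(6):
        for phe in ("P1", "P2", "HYB"):
            rows.append([f"{phe}{i}", phe, "ecotone", "ambient", 1, 5.0,
                         "alive"])
    out = selection_coefficients(make_transplant(rows), n_boot=50, seed=1)
    for f in out:
        assert f.s == pytest.approx(0.0)
        assert f.ci == (0.0, 0.0)


def test_exactly_one_zero_s_per_habitat():
    rng = np.random.default_rng(4)
    rows = []
    for hab in ("desert", "ecotone", "dune"):
        for phe in ("P1", "P2", "HYB"):
            for i in range(8):
                surv = int(rng.random() < 0.6)
                rows.append([f"{hab}_{phe}_{i}", phe, hab, "ambient", surv,
                             float(rng.gamma(3, 4)),
                             "alive" if surv else "other"])
    out = selection_coefficients(make_transplant(rows), n_boot=0)
    for hab in ("desert", "ecotone", "dune"):
        svals = [f.s for f in out if f.habitat == hab]
        assert sum(1 for s in svals if s == 0.0) == 1
        assert all(0.0 <= s <= 1.0 for s in svals)


def test_bootstrap_reproducible_and_truncated():
    rng = np.random.default_rng(9)
    rows = []
    for phe, mean in (("P1", 20.0), ("P2", 2.0)):
        for i in range(12):
            surv = int(rng.random() < 0.7)
            rows.append([f"{phe}{i}", phe, "dune", "ambient", surv,
                         float(rng.lognormal(np.log(mean), 0.6)),
                         "alive" if surv else "herbivory"])
    tt = make_transplant(rows)
    a = selection_coefficients(tt, n_boot=200, seed=3)
    b = selection_coefficients(tt, n_boot=200, seed=3)
    for fa, fb in zip(a, b):
        assert fa.ci == fb.ci
        assert 0.0 <= fa.ci[0] <= fa.ci[1] <= 1.0


def test_bootstrap_requires_seed(two_cell_transplant):
    with pytest.raises(ValidationError):
        selection_coefficients(two_cell_transplant, n_boot=10, seed=None)


def test_single_phenotype_habitat_rejected():
    tt = make_transplant([["a", "P1", "dune", "ambient", 1, 1.0, "alive"],
                          ["b", "P1", "dune", "ambient", 1, 2.0, "alive"]])
    with pytest.raises(ValidationError):
        selection_coefficients(tt, n_boot=0)


def test_zero_fitness_habitat_undefined():
    tt = make_transplant([["a", "P1", "dune", "ambient", 0, 5.0, "other"],
                          ["b", "P2", "dune", "ambient", 0, 5.0, "other"]])
    out = selection_coefficients(tt, n_boot=0)
    assert all(np.isnan(f.relative_w) and np.isnan(f.s) for f in out)


def test_recovery_at_design_scale():
    # paper-scale design: ~276 plants across 9 habitat x phenotype cells
    from hzkit.synthetic_data import (SimConfig, default_transplant_config,
                                      simulate_transplant)
    errs = []
    for seed in range(5):
        cfg = SimConfig(seed=seed,
                        transplant=default_transplant_config(n_per_cell=31))
        tt, truth = simulate_transplant(cfg)
        assert len(tt.df) == 279
        out = selection_coefficients(tt, n_boot=0)
        for f in out:
            errs.append(abs(f.s - truth["true_s"][f"{f.habitat}:{f.phenotype}"]))
    assert np.mean(errs) < 0.05


# ---------------------------------------------------------------- NB GLM

def test_intercept_only_mean():
    rng = np.random.default_rng(0)
    y = rng.negative_binomial(2, 0.25, 300).astype(float)
    res = fit_nb_glm(pd.DataFrame({"y": y}), "y ~ 1")
    assert np.exp(res.params["Intercept"]) == pytest.approx(y.mean(),
                                                            rel=1e-6)


def test_nb_parameter_recovery():
    rng = np.random.default_rng(42)
    n = 500
    cells = {"a": 5.0, "b": 20.0}
    theta = 2.0  # variance mu + mu^2/theta; alpha = 1/theta = 0.5
    g = np.repeat(list(cells), n)
    mu = np.array([cells[x] for x in g])
    y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
    res = fit_nb_glm(pd.DataFrame({"g": g, "y": y}), "y ~ g")
    mu_a = np.exp(res.params["Intercept"])
    mu_b = np.exp(res.params["Intercept"] + res.params["g[T.b]"])
    assert mu_a == pytest.approx(5.0, rel=0.05)
    assert mu_b == pytest.approx(20.0, rel=0.05)
    assert 1.0 / res.alpha == pytest.approx(theta, rel=0.20)


def poisson_irls_oracle(X, y, n_iter=100):
    """Plain Newton/IRLS for a log-link Poisson GLM, written from scratch."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-9))
    for _ in range(n_iter):
        eta = X @ beta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        W = mu
        beta_new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
        if np.abs(beta_new - beta).max() < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    return beta


def test_poisson_limit_matches_irls_oracle():
    rng = np.random.default_rng(7)
    n = 400
    g = np.repeat(["a", "b"], n // 2)
    mu = np.where(g == "b", 12.0, 4.0)
    y = rng.poisson(mu).astype(float)
    res = fit_nb_glm(pd.DataFrame({"g": g, "y": y}), "y ~ g")
    X = np.column_stack([np.ones(n), (g == "b").astype(float)])
    oracle = poisson_irls_oracle(X, y)
    # Poisson data drives alpha toward 0; coefficients approach Poisson IRLS
    assert res.alpha < 0.05
    assert np.abs(res.params.to_numpy() - oracle).max() < 1e-4


def test_non_integer_response_accepted():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"g": np.repeat(["a", "b"], 50),
                       "y": rng.lognormal(1.0, 0.4, 100)})
    res = fit_nb_glm(df, "y ~ g")
    assert np.isfinite(res.loglik)


def test_negative_response_rejected():
    with pytest.raises(ValidationError):
        fit_nb_glm(pd.DataFrame({"y": [-1.0, 2.0]}), "y ~ 1")


def test_gamma_family_alternative():
    rng = np.random.default_rng(2)
    df = pd.DataFrame({"y": rng.gamma(3.0, 2.0, 200) + 1e-6})
    res = fit_nb_glm(df, "y ~ 1", family="gamma")
    assert np.exp(res.params["Intercept"]) == pytest.approx(df.y.mean(),
                                                            rel=1e-4)


# ---------------------------------------------------------------- LR test

def test_identical_models_lr_zero():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"y": rng.negative_binomial(2, 0.3, 100).astype(float)})
    m = fit_nb_glm(df, "y ~ 1")
    lr, dof, p = lr_interaction_test(m, m)
    assert lr == 0.0 and dof == 0 and p == 1.0


def test_nested_loglik_ordering():
    rng = np.random.default_rng(8)
    g = np.repeat(["a", "b"], 100)
    y = rng.negative_binomial(2, 0.3, 200).astype(float)
    df = pd.DataFrame({"g": g, "y": y})
    full = fit_nb_glm(df, "y ~ g")
    red = fit_nb_glm(df, "y ~ 1")
    assert red.loglik <= full.loglik + 1e-6
    lr, dof, p = lr_interaction_test(full, red)
    assert dof == 1 and 0 <= p <= 1


def test_non_nested_rejected():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({"a": np.repeat(["x", "y"], 30),
                       "b": np.tile(np.repeat(["u", "v"], 15), 2),
                       "y": rng.poisson(5, 60).astype(float)})
    m1 = fit_nb_glm(df, "y ~ a")
    m2 = fit_nb_glm(df, "y ~ b")
    with pytest.raises(ContractError):
        lr_interaction_test(m1, m2)


def test_interaction_power():
    # strong interaction (1.0 on the log scale) should be detected
    rng = np.random.default_rng(11)
    n = 50
    df0 = pd.DataFrame({"h": np.repeat(["a", "b"], 2 * n),
                        "p": np.tile(np.repeat(["x", "y"], n), 2)})
    eta = (1.0 + 0.3 * (df0.h == "b") + 0.3 * (df0.p == "y")
           + 1.0 * ((df0.h == "b") & (df0.p == "y")))
    mu = np.exp(eta)
    rejections = 0
    reps = 30
    for _ in range(reps):
        y = rng.negative_binomial(2, 2 / (2 + mu)).astype(float)
        d = df0.assign(y=y)
        full = fit_nb_glm(d, "y ~ h * p")
        red = fit_nb_glm(d, "y ~ h + p")
        _, _, p = lr_interaction_test(full, red)
        rejections += p < 0.05
    assert rejections / reps >= 0.9
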