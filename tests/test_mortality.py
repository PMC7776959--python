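import itertools

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import chi2

from hzkit.errors import ContractError, ValidationError
from hzkit.mortality import (Table3, backward_stepwise, ipf_fit, model_df,
                             table_from_transplant)

from conftest import make_transplant

FACTORS = ("habitat", "phenotype", "outcome")


def make_table(counts, mask=None):
    counts = np.asarray(counts, dtype=float)
    levels = {f: [f"{f[0]}{i}" for i in range(counts.shape[k])]
              for k, f in enumerate(FACTORS)}
    return Table3(counts, FACTORS, levels, mask=mask)


def random_table(rng, shape=(2, 2, 2), n=400):
    probs = rng.dirichlet(np.ones(int(np.prod(shape))))
    return make_table(rng.multinomial(n, probs).reshape(shape))


SATURATED = [FACTORS]
ALL_TWO_WAY = [("habitat", "phenotype"), ("habitat", "outcome"),
               ("phenotype", "outcome")]
INDEPENDENCE = [("habitat",), ("phenotype",), ("outcome",)]


# ------------------------------------------------------------------- IPF fit

def test_saturated_reproduces_observed():
    rng = np.random.default_rng(0)
    T = random_table(rng)
    res = ipf_fit(T, SATURATED)
    assert np.allclose(res.fitted, T.counts, atol=1e-8)
    assert res.g2 == pytest.approx(0.0, abs=1e-8)
    assert res.df == 0


def test_independence_closed_form_2x2x2():
    rng = np.random.default_rng(1)
    T = random_table(rng)
    res = ipf_fit(T, INDEPENDENCE)
    N = T.counts.sum()
    a = T.counts.sum(axis=(1, 2))
    b = T.counts.sum(axis=(0, 2))
    c = T.counts.sum(axis=(0, 1))
    closed = np.einsum("i,j,k->ijk", a, b, c) / N**2
    assert np.allclose(res.fitted, closed, atol=1e-7)
    assert res.df == 4  # 8 cells - 1 - 3 main-effect params


def test_margins_reproduced_to_tolerance():
    rng = np.random.default_rng(2)
    for _ in range(10):
        T = random_table(rng, shape=(3, 3, 2), n=600)
        res = ipf_fit(T, ALL_TWO_WAY, tol=1e-8)
        for term in ALL_TWO_WAY:
            axes = tuple(i for i, f in enumerate(FACTORS) if f not in term)
            assert np.abs(res.fitted.sum(axis=axes)
                          - T.counts.sum(axis=axes)).max() < 1e-8


def test_df_counting():
    T = make_table(np.ones((3, 3, 2)))
    assert model_df(T, frozenset({frozenset(FACTORS)})) == 0
    # all two-way: 18 - (1 + 2+2+1 + 4+2+2) = 4
    assert model_df(T, frozenset(frozenset(t) for t in ALL_TWO_WAY)) == 4


def test_g2_nesting_monotonicity():
    rng = np.random.default_rng(3)
    pool = [INDEPENDENCE, ALL_TWO_WAY[:1] + [("outcome",)],
            ALL_TWO_WAY[:2], ALL_TWO_WAY, SATURATED]
    for _ in range(20):
        T = random_table(rng, n=300)
        g2s = [ipf_fit(T, m).g2 for m in pool]
        # each successive model adds terms; G2 must not increase
        assert all(g2s[i + 1] <= g2s[i] + 1e-6 for i in range(len(g2s) - 1))


def test_delta_g2_equals_poisson_loglik_difference():
    # direct Poisson log-likelihood oracle on 2x2x2 fixtures
    rng = np.random.default_rng(4)

    def pois_ll(obs, fitted):
        pos = fitted > 0
        return float((obs[pos] * np.log(fitted[pos]) - fitted[pos]
                      - gammaln(obs[pos] + 1)).sum())

    for _ in range(5):
        T = random_table(rng)
        full = ipf_fit(T, ALL_TWO_WAY)
        red = ipf_fit(T, INDEPENDENCE)
        delta_g2 = red.g2 - full.g2
        delta_ll = 2 * (pois_ll(T.counts, full.fitted)
                        - pois_ll(T.counts, red.fitted))
        assert delta_g2 == pytest.approx(delta_ll, abs=1e-6)


def test_three_way_power():
    # strong three-way interaction: all-two-way model must be rejected
    rng = np.random.default_rng(5)
    base = np.exp(rng.normal(2.5, 0.2, (2, 2, 2)))
    base[1, 1, 1] *= 6.0  # odds-ratio structure only a 3-way term captures
    rejections = 0
    reps = 60
    for _ in range(reps):
        T = make_table(rng.poisson(base * 4))
        res = ipf_fit(T, ALL_TWO_WAY)
        rejections += res.g2 > chi2.ppf(0.95, res.df)
    assert rejections / reps >= 0.9


def test_non_hierarchical_spec_rejected():
    T = make_table(np.ones((2, 2, 2)))
    with pytest.raises(ContractError):
        ipf_fit(T, [("habitat", "ghost")])
    with pytest.raises(ContractError):
        ipf_fit(T, [])


def test_non_integer_counts_rejected():
    with pytest.raises(ValidationError):
        make_table(np.full((2, 2, 2), 0.5))


def test_structural_zero_mask_respected():
    rng = np.random.default_rng(6)
    T0 = random_table(rng)
    counts = T0.counts.copy()
    counts[0, 0, 0] = 0
    mask = np.ones_like(counts)
    mask[0, 0, 0] = 0
    T = make_table(counts, mask=mask)
    res = ipf_fit(T, INDEPENDENCE)
    assert res.fitted[0, 0, 0] == 0.0


# ------------------------------------------------------------------ stepwise

def test_mutual_independence_keeps_main_effects_only():
    rng = np.random.default_rng(7)
    hits = 0
    reps = 60
    for _ in range(reps):
        pa = np.array([0.6, 0.4])
        pb = np.array([0.3, 0.7])
        pc = np.array([0.5, 0.5])
        probs = np.einsum("i,j,k->ijk", pa, pb, pc).ravel()
        T = make_table(rng.multinomial(400, probs).reshape(2, 2, 2))
        res = backward_stepwise(T)
        hits += all(len(t) == 1 for t in res.final_model)
    # sequential alpha=0.05 tests compound: the null pass-through rate is
    # ~0.95^2 minus correlated intermediate-step losses, empirically ~0.83
    assert hits / reps >= 0.75


def test_three_way_dependence_retained():
    counts = np.full((2, 2, 2), 50.0)
    counts[1, 1, 1] *= 10  # hard-coded three-way dependence, n large
    res = backward_stepwise(make_table(counts))
    assert frozenset(FACTORS) in res.final_model
    assert res.three_way_test[2] < 0.05


def test_identical_layers_drop_outcome_interactions():
    rng = np.random.default_rng(8)
    layer = rng.integers(20, 120, (3, 3)).astype(float)
    counts = np.stack([layer, layer], axis=2)  # outcome independent
    T = make_table(counts)
    res = backward_stepwise(T)
    for term in res.final_model:
        if len(term) >= 2:
            assert "outcome" not in term
    # the outcome-independent model reproduces the table exactly
    fit = ipf_fit(T, [("habitat", "phenotype"), ("outcome",)])
    assert fit.g2 == pytest.approx(0.0, abs=1e-6)


def test_first_step_is_three_way_lr():
    rng = np.random.default_rng(9)
    T = random_table(rng, n=500)
    res = backward_stepwise(T)
    full = ipf_fit(T, SATURATED)
    red = ipf_fit(T, ALL_TWO_WAY)
    assert res.three_way_test[0] == pytest.approx(red.g2 - full.g2, abs=1e-6)
    assert res.three_way_test[1] == red.df - full.df


# ------------------------------------------------------------ cross-tabulation

def test_table_from_transplant_counts():
    rows = [
        ["a", "P1", "dune", "ambient", 0, 1.0, "burial"],
        ["b", "P1", "dune", "ambient", 1, 1.0, "alive"],
        ["c", "P2", "dune", "ambient", 0, 1.0, "herbivory"],
        ["d", "P2", "desert", "ambient", 0, 1.0, "burial"],
    ]
    T = table_from_transplant(make_transplant(rows), "burial")
    habs = T.levels["habitat"]
    phes = T.levels["phenotype"]
    assert T.counts[habs.index("dune"), phes.index("P1"), 1] == 1  # yes
    assert T.counts[habs.index("dune"), phes.index("P1"), 0] == 1  # no
    assert T.counts[habs.index("desert"), phes.index("P2"), 1] == 1
    assert T.counts.sum() == 4
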