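"""Loss closed forms, ZINB oracle equivalence, decoder contracts."""

import numpy as np
import pytest
from scipy.stats import nbinom

from oncvae import (
    LatentGaussian,
    LibraryPrior,
    LossBreakdown,
    LossWeights,
    ModelConfig,
    Orion,
    ZINBParams,
    kl_l,
    kl_z,
    library_prior,
    total_loss,
    zinb_nll,
)


def zinb_logpmf_oracle(x, mu, theta, phi):
    """Independent direct-pmf ZINB log-likelihood (Gamma-function NB form)."""
    nb = nbinom.pmf(x, theta, theta / (theta + mu))
    p = np.where(x == 0, phi + (1 - phi) * nb, (1 - phi) * nb)
    return np.log(p)


# ----------------------------------------------------------------- KL terms
def test_kl_z_closed_forms():
    assert kl_z(LatentGaussian(np.zeros((1, 3)), np.zeros((1, 3)))) == 0.0
    assert kl_z(LatentGaussian(np.array([[1.0]]), np.array([[0.0]]))) == pytest.approx(0.5)
    expected = (4 - 1 - np.log(4)) / 2
    assert kl_z(
        LatentGaussian(np.array([[0.0]]), np.array([[np.log(2.0)]]))
    ) == pytest.approx(expected)


def test_kl_l_closed_forms():
    prior = LibraryPrior(log_mean=2.0, log_sd=1.0)
    q = LatentGaussian(np.array([[2.0]]), np.array([[0.0]]))
    assert kl_l(q, prior) == pytest.approx(0.0)
    q2 = LatentGaussian(np.array([[3.0]]), np.array([[0.0]]))
    assert kl_l(q2, prior) == pytest.approx(0.5)


def test_kl_matches_monte_carlo():
    """Closed-form KL agrees with an E_q[log q - log p] estimate at 1e5 draws."""
    rng = np.random.default_rng(3)
    for _ in range(5):
        qm, qs = rng.normal(), np.exp(rng.normal(scale=0.5))
        pm, ps = rng.normal(), np.exp(rng.normal(scale=0.5))
        z = rng.normal(qm, qs, size=100_000)
        log_q = -0.5 * ((z - qm) / qs) ** 2 - np.log(qs) - 0.5 * np.log(2 * np.pi)
        log_p = -0.5 * ((z - pm) / ps) ** 2 - np.log(ps) - 0.5 * np.log(2 * np.pi)
        diff = log_q - log_p
        mc, se = diff.mean(), diff.std() / np.sqrt(len(z))
        closed = kl_l(
            LatentGaussian(np.array([[qm]]), np.array([[np.log(qs)]])),
            LibraryPrior(pm, ps),
        )
        assert abs(closed - mc) < 3 * se

    # standard-normal prior case against kl_z
    qm, qs = 0.7, 1.3
    z = rng.normal(qm, qs, size=100_000)
    log_q = -0.5 * ((z - qm) / qs) ** 2 - np.log(qs)
    log_p = -0.5 * z**2
    diff = log_q - log_p
    closed = kl_z(LatentGaussian(np.array([[qm]]), np.array([[np.log(qs)]])))
    assert abs(closed - diff.mean()) < 3 * diff.std() / np.sqrt(len(z))


def test_kl_nonnegative_property():
    rng = np.random.default_rng(8)
    for _ in range(50):
        q = LatentGaussian(rng.normal(size=(4, 3)),
                           rng.normal(scale=0.5, size=(4, 3)))
        assert kl_z(q) >= 0
        ql = LatentGaussian(rng.normal(size=(4, 1)), rng.normal(scale=0.5, size=(4, 1)))
        assert kl_l(ql, LibraryPrior(rng.normal(), np.exp(rng.normal()))) >= -1e-12


# -------------------------------------------------------------- library prior
def test_library_prior_closed_forms():
    r = np.array([[50.0, 50.0], [60.0, 40.0]])  # both rows sum to 100
    prior = library_prior(r)
    assert prior.log_mean == pytest.approx(np.log(100.0))
    assert prior.log_sd == pytest.approx(1e-3)  # degenerate SD -> floor

    r2 = np.array([[np.exp(2.0)], [np.exp(4.0)]])
    prior2 = library_prior(r2)
    assert prior2.log_mean == pytest.approx(3.0)
    assert prior2.log_sd == pytest.approx(1.0)  # population SD convention

    prior3 = library_prior(5.0 * r2)
    assert prior3.log_mean == pytest.approx(3.0 + np.log(5.0))
    assert prior3.log_sd == pytest.approx(1.0)


def test_library_prior_rejects_zero_rows():
    with pytest.raises(ValueError):
        library_prior(np.array([[0.0, 0.0], [1.0, 2.0]]))


# ----------------------------------------------------------------------- ZINB
def test_zinb_nll_point_cases():
    mk = lambda mu, th, phi: ZINBParams(
        rho=None, mu=np.array([[mu]]), theta=np.array([th]), phi=np.array([[phi]])
    )
    assert zinb_nll(np.array([[0.0]]), mk(1.0, 1.0, 1.0)) == pytest.approx(0.0)
    assert zinb_nll(np.array([[0.0]]), mk(1.0, 1.0, 0.0)) == pytest.approx(np.log(2))
    val = zinb_nll(np.array([[3.0]]), mk(2.0, 5.0, 0.2))
    oracle = -np.log(0.8 * nbinom.pmf(3, 5, 5 / 7))
    assert val == pytest.approx(oracle, abs=1e-10)


def test_zinb_nll_matches_pmf_oracle_on_random_tuples():
    rng = np.random.default_rng(11)
    n = 200
    x = rng.poisson(2.0, size=(1, n)).astype(float)
    mu = np.exp(rng.normal(0, 1, size=(1, n)))
    theta = np.exp(rng.normal(0.5, 0.7, size=n))
    phi = rng.uniform(0, 1, size=(1, n))
    ours = zinb_nll(x, ZINBParams(rho=None, mu=mu, theta=theta, phi=phi))
    oracle = -zinb_logpmf_oracle(x, mu, theta[None, :], phi).sum()
    assert ours == pytest.approx(oracle, abs=1e-6)


def test_zinb_limits():
    """phi=0 reduces to plain NB; phi=1 is a point mass at zero."""
    rng = np.random.default_rng(4)
    x = rng.poisson(1.5, size=(1, 20)).astype(float)
    mu = np.full((1, 20), 1.7)
    th = np.full(20, 2.3)
    nb_nll = -nbinom.logpmf(x, th[None], th[None] / (th[None] + mu)).sum()
    assert zinb_nll(x, ZINBParams(None, mu, th, np.zeros((1, 20)))) == pytest.approx(nb_nll, rel=1e-9)
    zeros = np.zeros((1, 20))
    assert zinb_nll(zeros, ZINBParams(None, mu, th, np.ones((1, 20)))) == pytest.approx(0.0)


def test_zinb_rejects_negative_counts():
    with pytest.raises(ValueError):
        zinb_nll(np.array([[-1.0]]),
                 ZINBParams(None, np.array([[1.0]]), np.array([1.0]), np.array([[0.1]])))


# ----------------------------------------------------------------- total loss
def test_total_loss_weighted_sum():
    bd = LossBreakdown(kl_z=1.0, kl_l=2.0, nll=3.0, tml=4.0, ce=5.0,
                       smooth_l1=0.0, total=0.0)
    w0 = LossWeights(kl_z=0, kl_l=0, nll=1, tml=0, ce=0)
    assert total_loss(bd, w0) == 3.0
    w1 = LossWeights(kl_z=1, kl_l=1, nll=1, tml=1, ce=1)
    assert total_loss(bd, w1) == pytest.approx(15.0)
    w2 = LossWeights(kl_z=2, kl_l=2, nll=2, tml=2, ce=2)
    assert total_loss(bd, w2) == pytest.approx(2 * total_loss(bd, w1))


def test_negative_weight_rejected():
    with pytest.raises(ValueError):
        LossWeights(ce=-1.0)


# ------------------------------------------------------------ network contracts
@pytest.fixture(scope="module")
def fresh_model():
    return Orion(ModelConfig(d=40, m=6, k=5, hidden_onc=16, hidden_lib=8,
                             hidden_dec=16, eta=4, seed=0))


def test_encoder_shapes_and_determinism(fresh_model):
    rng = np.random.default_rng(0)
    x = rng.poisson(0.5, size=(4, 40)).astype(float)
    q = fresh_model.encode_oncrna(x)
    assert q.mean.shape == (4, 5) and q.log_sd.shape == (4, 5)
    x2 = np.vstack([x[0], x[0]])
    q2 = fresh_model.encode_oncrna(x2)
    np.testing.assert_array_equal(q2.mean[0], q2.mean[1])

    r = rng.poisson(100, size=(4, 6)).astype(float)
    ql = fresh_model.encode_library(r)
    assert ql.mean.shape == (4, 1)
    with pytest.raises(ValueError):
        fresh_model.encode_oncrna(x[:, :10])


def test_decoder_contracts(fresh_model):
    rng = np.random.default_rng(1)
    z = rng.normal(size=(3, 5))
    params = fresh_model.decode(z, np.zeros(3))
    np.testing.assert_allclose(params.rho.sum(axis=1), 1.0, atol=1e-5)
    # ell = 0 -> mu equals rho exactly
    np.testing.assert_allclose(params.mu, params.rho, rtol=1e-12)
    # shifting ell by ln 2 doubles mu, leaves rho unchanged
    params2 = fresh_model.decode(z, np.full(3, np.log(2.0)))
    np.testing.assert_allclose(params2.mu, 2.0 * params.rho, rtol=1e-10)
    np.testing.assert_allclose(params2.rho, params.rho, rtol=1e-12)
    assert params.theta.min() > 0
    assert params.phi.min() >= 0 and params.phi.max() <= 1
    with pytest.raises(ValueError):
        fresh_model.decode(np.full((1, 5), np.nan), np.zeros(1))


def test_classifier_head_outputs_probabilities(fresh_model):
    rng = np.random.default_rng(2)
    z = rng.normal(size=(6, 5))
    ell = rng.normal(size=6)
    p = fresh_model.classify_head(z, ell)
    assert p.shape == (6, 2)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
    assert p.min() >= 0
    np.testing.assert_array_equal(p, fresh_model.classify_head(z, ell))


def test_eta_validation(fresh_model):
    rng = np.random.default_rng(3)
    x = rng.poisson(0.5, size=(5, 40)).astype(float)
    r = rng.poisson(100, size=(5, 6)).astype(float) + 1
    with pytest.raises(ValueError):
        fresh_model.generative_ce_loss(x, r, np.array([0, 1, 0, 1, 0]), eta=0)


def test_generative_ce_variance_shrinks_with_eta(fresh_model):
    """The Monte-Carlo CE estimate tightens roughly like 1/eta."""
    rng = np.random.default_rng(5)
    x = rng.poisson(0.5, size=(8, 40)).astype(float)
    r = rng.poisson(100, size=(8, 6)).astype(float) + 1
    y = np.array([0, 1] * 4)
    variances = []
    for eta in (1, 10, 100):
        vals = [
            fresh_model.generative_ce_loss(x, r, y, eta=eta,
                                           rng=np.random.default_rng(1000 + i))
            for i in range(60)
        ]
        variances.append(np.var(vals))
    assert variances[0] > variances[1] > variances[2]
    assert variances[0] / variances[2] > 5


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(d=10, m=2, eta=0)
    with pytest.raises(ValueError):
        ModelConfig(d=10, m=2, alpha=0.0)
    with pytest.raises(ValueError):
        ModelConfig(d=10, m=2, k=0)
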