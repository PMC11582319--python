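"""Orion: a two-arm semi-supervised VAE for sparse small-RNA counts.

One arm encodes the sparse oncRNA counts x into a k-dimensional Gaussian
posterior q(z|x); the other encodes dense endogenous smRNA counts r into a
one-dimensional posterior q(l|r) over log library size, whose prior is
recomputed from the row sums of r in every mini-batch.  A decoder maps a
latent draw back to the parameters of a zero-inflated negative binomial
(ZINB): a per-sample simplex rho (softmax), mean mu = rho * exp(l), a free
per-feature inverse dispersion theta, and a zero-inflation probability phi.

Training minimizes a weighted sum of five losses: the two KL terms, the
ZINB negative log-likelihood, a confounder-aware triplet margin loss on z,
and a cross-entropy classification loss computed on eta posterior draws per
data point (generative sampling).  At test time the deterministic posterior
means are used.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import gammaln

from . import _autodiff as ad
from ._autodiff import Adam, Tensor
from .containers import EndogenousCountMatrix, OncCountMatrix, SampleAnnotations
from .triplets import sample_batch_triplets

__all__ = [
    "LossWeights",
    "ModelConfig",
    "TrainOpts",
    "LatentGaussian",
    "LibraryPrior",
    "ZINBParams",
    "LossBreakdown",
    "Orion",
    "fit",
    "library_prior",
    "kl_z",
    "kl_l",
    "zinb_nll",
    "total_loss",
]

_LOGSD_MIN, _LOGSD_MAX = -6.0, 4.0
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class LossWeights:
    """Weights lambda_1..lambda_5 of the composite objective.

    Cross-entropy is up-weighted by default so the (per-sample scalar)
    classification signal is not drowned by the reconstruction term, which
    sums over thousands of features.
    """

    kl_z: float = 1.0
    kl_l: float = 1.0
    nll: float = 1.0
    tml: float = 25.0
    ce: float = 50.0
    smooth_l1: float = 0.0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"loss weight {name} must be non-negative")


@dataclass
class ModelConfig:
    d: int
    m: int
    k: int = 50
    s: int = 1
    hidden_onc: int = 1500
    hidden_lib: int = 1500
    hidden_dec: int | None = None
    classifier_hidden: int = 25
    n_classes: int = 2
    dropout_p: float = 0.5
    l2_strength: float = 2.0
    eta: int = 100
    alpha: float = 1.0
    omega: int = 16
    generative_sampling: bool = True
    #: apply the triplet loss to posterior means rather than draws
    #: (less gradient noise in the hinge; draws match the sampled ELBO path)
    tml_on_posterior_mean: bool = True
    lib_sd_floor: float = 1e-3
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dec is None:
            self.hidden_dec = self.hidden_onc
        if self.k < 1:
            raise ValueError("latent dimension k must be >= 1")
        if self.eta < 1:
            raise ValueError("eta must be >= 1")
        if self.alpha <= 0:
            raise ValueError("triplet margin alpha must be positive")


@dataclass
class TrainOpts:
    lr: float = 1e-3
    batch_size: int = 128
    n_epochs: int = 30
    confounders: tuple[str, ...] = ("supplier", "experiment_id")


@dataclass
class LatentGaussian:
    mean: np.ndarray
    log_sd: np.ndarray


@dataclass
class LibraryPrior:
    log_mean: float
    log_sd: float


@dataclass
class ZINBParams:
    rho: np.ndarray
    mu: np.ndarray
    theta: np.ndarray
    phi: np.ndarray


@dataclass
class LossBreakdown:
    kl_z: float
    kl_l: float
    nll: float
    tml: float
    ce: float
    smooth_l1: float
    total: float


# --------------------------------------------------------------- loss algebra
def total_loss(components: LossBreakdown, weights: LossWeights) -> float:
    """The lambda-weighted sum of the loss components."""
    return (
        weights.kl_z * components.kl_z
        + weights.kl_l * components.kl_l
        + weights.nll * components.nll
        + weights.tml * components.tml
        + weights.ce * components.ce
        + weights.smooth_l1 * components.smooth_l1
    )


def library_prior(r: EndogenousCountMatrix | np.ndarray,
                  sd_floor: float = 1e-3) -> LibraryPrior:
    """Mini-batch prior over log library size from endogenous row sums.

    log_mean / log_sd are the mean and population SD of log(sum_m r_im)
    over the batch; the SD is floored so a batch of identical depths does
    not collapse the prior.
    """
    vals = r.values if isinstance(r, EndogenousCountMatrix) else np.asarray(r)
    sums = vals.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("zero endogenous row sum: log library size undefined")
    logs = np.log(sums)
    return LibraryPrior(
        log_mean=float(logs.mean()),
        log_sd=float(max(logs.std(), sd_floor)),
    )


def _kl_z_t(mean: Tensor, log_sd: Tensor) -> Tensor:
    """KL(q || N(0, I)), summed over latent dims, mean over samples."""
    var = ad.exp(2.0 * log_sd)
    per = 0.5 * (mean**2.0 + var - 1.0) - log_sd
    return ad.mean(ad.sum_(per, axis=1))


def kl_z(q: LatentGaussian) -> float:
    mean = np.atleast_2d(np.asarray(q.mean, dtype=np.float64))
    log_sd = np.atleast_2d(np.asarray(q.log_sd, dtype=np.float64))
    return _kl_z_t(Tensor(mean), Tensor(log_sd)).item()


def _kl_l_t(mean: Tensor, log_sd: Tensor, prior: LibraryPrior) -> Tensor:
    if prior.log_sd <= 0:
        raise ValueError("prior log_sd must be positive after flooring")
    var = ad.exp(2.0 * log_sd)
    ps2 = prior.log_sd**2
    per = (
        0.5 * ((var + (mean - prior.log_mean) ** 2.0) / ps2 - 1.0)
        + np.log(prior.log_sd)
        - log_sd
    )
    return ad.mean(ad.sum_(per, axis=1))


def kl_l(q: LatentGaussian, prior: LibraryPrior) -> float:
    mean = np.asarray(q.mean, dtype=np.float64).reshape(-1, 1)
    log_sd = np.asarray(q.log_sd, dtype=np.float64).reshape(-1, 1)
    return _kl_l_t(Tensor(mean), Tensor(log_sd), prior).item()


def _zinb_log_pmf_t(x: np.ndarray, log_mu: Tensor, theta: Tensor,
                    phi_logit: Tensor) -> Tensor:
    """Entrywise log p(x | mu, theta, phi) in log space.

    p(0) = phi + (1 - phi) NB(0), p(x>0) = (1 - phi) NB(x), combined via
    log-sum-exp; NB uses the Gamma-function form of the pmf.
    """
    mu = ad.exp(log_mu)
    log_theta_mu = ad.log(theta + mu)
    log_nb = (
        ad.lgamma(x + theta)
        - ad.lgamma(theta)
        - Tensor(gammaln(x + 1.0))
        + theta * (ad.log(theta) - log_theta_mu)
        + Tensor(x) * (log_mu - log_theta_mu)
    )
    log_phi = -ad.softplus(-phi_logit)
    log_1mphi = -ad.softplus(phi_logit)
    log_p0 = ad.logaddexp(log_phi, log_1mphi + log_nb)
    return ad.where(x == 0, log_p0, log_1mphi + log_nb)


def zinb_nll(x: np.ndarray, params: ZINBParams) -> float:
    """ZINB negative log-likelihood: mean over samples, sum over features."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.min() < 0:
        raise ValueError("counts must be non-negative")
    mu = np.atleast_2d(np.asarray(params.mu, dtype=np.float64))
    phi = np.atleast_2d(np.asarray(params.phi, dtype=np.float64))
    theta = np.asarray(params.theta, dtype=np.float64)
    with np.errstate(divide="ignore"):
        phi_logit = np.log(phi) - np.log1p(-phi)
    logp = _zinb_log_pmf_t(x, Tensor(np.log(mu)), Tensor(theta), Tensor(phi_logit))
    return (-ad.mean(ad.sum_(logp, axis=1))).item()


# ----------------------------------------------------------------------- model
def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class Orion:
    """The two-arm semi-supervised ZINB VAE with a classification head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        p: dict[str, Tensor] = {}

        def lin(prefix: str, fan_in: int, fan_out: int):
            p[f"{prefix}_W"] = Tensor(_glorot(rng, fan_in, fan_out), requires_grad=True)
            p[f"{prefix}_b"] = Tensor(np.zeros(fan_out), requires_grad=True)

        lin("enc1", c.d, c.hidden_onc)
        lin("enc_mu", c.hidden_onc, c.k)
        lin("enc_sd", c.hidden_onc, c.k)
        lin("lib1", c.m, c.hidden_lib)
        lin("lib_mu", c.hidden_lib, c.s)
        lin("lib_sd", c.hidden_lib, c.s)
        lin("dec1", c.k, c.hidden_dec)
        lin("dec_rho", c.hidden_dec, c.d)
        lin("dec_phi", c.hidden_dec, c.d)
        lin("clf1", c.k, c.classifier_hidden)
        lin("clf2", c.classifier_hidden, c.n_classes)
        lin("reg", c.classifier_hidden, 1)  # smooth-L1 head, disabled by default
        p["theta_raw"] = Tensor(np.zeros(c.d), requires_grad=True)
        p["bn_gamma"] = Tensor(np.ones(c.k), requires_grad=True)
        p["bn_beta"] = Tensor(np.zeros(c.k), requires_grad=True)
        self.params = p
        self.decay_keys = [
            k for k in p if k.endswith("_W") and k.split("_")[0] in
            ("enc1", "enc", "lib1", "lib", "dec1", "dec")
        ]
        # running statistics of the classifier batch norm
        self.bn_mean = np.zeros(c.k)
        self.bn_var = np.ones(c.k)
        self.feature_ids: np.ndarray | None = None
        self.endo_feature_ids: np.ndarray | None = None
        self.fitted = False

    # --------------------------------------------------------------- encoders
    def _encode_onc_t(self, x_dense: np.ndarray, train: bool = False,
                      rng: np.random.Generator | None = None):
        if x_dense.shape[1] != self.config.d:
            raise ValueError(
                f"expected {self.config.d} oncRNA features, got {x_dense.shape[1]}"
            )
        h = ad.relu(Tensor(np.log1p(x_dense)) @ self.params["enc1_W"]
                    + self.params["enc1_b"])
        if train and self.config.dropout_p > 0:
            keep = rng.random(h.shape) >= self.config.dropout_p
            h = h * Tensor(keep / (1.0 - self.config.dropout_p))
        mean = h @ self.params["enc_mu_W"] + self.params["enc_mu_b"]
        log_sd = ad.clip(h @ self.params["enc_sd_W"] + self.params["enc_sd_b"],
                         _LOGSD_MIN, _LOGSD_MAX)
        return mean, log_sd

    def _encode_lib_t(self, r_dense: np.ndarray, train: bool = False,
                      rng: np.random.Generator | None = None):
        if r_dense.shape[1] != self.config.m:
            raise ValueError(
                f"expected {self.config.m} endogenous features, got {r_dense.shape[1]}"
            )
        sums = r_dense.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("zero endogenous row sum: log library size undefined")
        h = ad.relu(Tensor(np.log1p(r_dense)) @ self.params["lib1_W"]
                    + self.params["lib1_b"])
        if train and self.config.dropout_p > 0:
            keep = rng.random(h.shape) >= self.config.dropout_p
            h = h * Tensor(keep / (1.0 - self.config.dropout_p))
        # skip connection: the network learns a correction around the
        # observed log endogenous total, so q(l|r) starts near the prior
        mean = (h @ self.params["lib_mu_W"] + self.params["lib_mu_b"]
                + Tensor(np.log(sums)))
        log_sd = ad.clip(h @ self.params["lib_sd_W"] + self.params["lib_sd_b"],
                         _LOGSD_MIN, _LOGSD_MAX)
        return mean, log_sd

    def encode_oncrna(self, x: OncCountMatrix | np.ndarray) -> LatentGaussian:
        """Deterministic (inference-mode) posterior q(z|x)."""
        dense = x.dense() if isinstance(x, OncCountMatrix) else np.asarray(x, float)
        mean, log_sd = self._encode_onc_t(dense)
        return LatentGaussian(mean=mean.data.copy(), log_sd=log_sd.data.copy())

    def encode_library(self, r: EndogenousCountMatrix | np.ndarray) -> LatentGaussian:
        """Deterministic posterior q(l|r) over log library size."""
        dense = r.values if isinstance(r, EndogenousCountMatrix) else np.asarray(r, float)
        mean, log_sd = self._encode_lib_t(dense)
        return LatentGaussian(mean=mean.data.copy(), log_sd=log_sd.data.copy())

    # ---------------------------------------------------------------- decoder
    def _decode_t(self, z: Tensor, ell: Tensor):
        h = ad.relu(z @ self.params["dec1_W"] + self.params["dec1_b"])
        rho_logits = h @ self.params["dec_rho_W"] + self.params["dec_rho_b"]
        log_rho = rho_logits - ad.logsumexp(rho_logits, axis=1, keepdims=True)
        phi_logit = h @ self.params["dec_phi_W"] + self.params["dec_phi_b"]
        theta = ad.softplus(self.params["theta_raw"]) + 1e-4
        log_mu = log_rho + ell
        return log_rho, log_mu, theta, phi_logit

    def decode(self, z: np.ndarray, ell: np.ndarray) -> ZINBParams:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        ell = np.asarray(ell, dtype=np.float64).reshape(-1, 1)
        if not (np.isfinite(z).all() and np.isfinite(ell).all()):
            raise ValueError("non-finite latent draw")
        log_rho, log_mu, theta, phi_logit = self._decode_t(Tensor(z), Tensor(ell))
        return ZINBParams(
            rho=np.exp(log_rho.data),
            mu=np.exp(log_mu.data),
            theta=theta.data.copy(),
            phi=1.0 / (1.0 + np.exp(-phi_logit.data)),
        )

    # ------------------------------------------------------------- classifier
    def _classify_t(self, z: Tensor, ell: Tensor, train: bool,
                    stats: tuple[Tensor, Tensor] | None = None):
        u = z * ell  # library embedding scales each latent coordinate
        if train:
            if stats is None:
                bm = ad.mean(u, axis=0, keepdims=True)
                bv = ad.mean((u - bm) ** 2.0, axis=0, keepdims=True)
            else:
                # normalize with the posterior-mean statistics so posterior
                # draws act as augmentation around a test-consistent scale
                bm, bv = stats
            self.bn_mean = (_BN_MOMENTUM * self.bn_mean
                            + (1 - _BN_MOMENTUM) * bm.data.ravel())
            self.bn_var = (_BN_MOMENTUM * self.bn_var
                           + (1 - _BN_MOMENTUM) * bv.data.ravel())
            xhat = (u - bm) * (bv + _BN_EPS) ** -0.5
        else:
            xhat = (u - Tensor(self.bn_mean)) * Tensor(
                1.0 / np.sqrt(self.bn_var + _BN_EPS)
            )
        normed = xhat * self.params["bn_gamma"] + self.params["bn_beta"]
        h = ad.relu(normed @ self.params["clf1_W"] + self.params["clf1_b"])
        logits = h @ self.params["clf2_W"] + self.params["clf2_b"]
        log_probs = logits - ad.logsumexp(logits, axis=1, keepdims=True)
        return log_probs, h

    def classify_head(self, z: np.ndarray, ell: np.ndarray) -> np.ndarray:
        """Class probabilities for given latent draws (inference-mode BN)."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        ell = np.asarray(ell, dtype=np.float64).reshape(-1, 1)
        log_probs, _ = self._classify_t(Tensor(z), Tensor(ell), train=False)
        return np.exp(log_probs.data)

    # ----------------------------------------------------------------- losses
    def generative_ce_loss(self, x, r, labels: np.ndarray,
                           eta: int | None = None,
                           rng: np.random.Generator | None = None) -> float:
        """Monte-Carlo cross-entropy over eta posterior draws per data point."""
        eta = self.config.eta if eta is None else int(eta)
        if eta < 1:
            raise ValueError("eta must be >= 1")
        rng = np.random.default_rng(0) if rng is None else rng
        x_dense = x.dense() if isinstance(x, OncCountMatrix) else np.asarray(x, float)
        r_dense = r.values if isinstance(r, EndogenousCountMatrix) else np.asarray(r, float)
        labels = np.asarray(labels, dtype=np.int64)
        z_mean, z_logsd = self._encode_onc_t(x_dense)
        l_mean, l_logsd = self._encode_lib_t(r_dense)
        n = x_dense.shape[0]
        rep = np.tile(np.arange(n), eta)
        z = ad.take(z_mean, rep) + Tensor(
            rng.standard_normal((eta * n, self.config.k))
        ) * ad.exp(ad.take(z_logsd, rep))
        ell = ad.take(l_mean, rep) + Tensor(
            rng.standard_normal((eta * n, 1))
        ) * ad.exp(ad.take(l_logsd, rep))
        log_probs, _ = self._classify_t(z, ell, train=False)
        onehot = np.eye(self.config.n_classes)[labels[rep]]
        return (-ad.sum_(Tensor(onehot) * log_probs) * (1.0 / (eta * n))).item()

    # -------------------------------------------------------------------- fit
    def fit(self, x: OncCountMatrix, r: EndogenousCountMatrix,
            annotations: SampleAnnotations,
            train_opts: TrainOpts | None = None,
            y_real: np.ndarray | None = None) -> list[LossBreakdown]:
        opts = train_opts or TrainOpts()
        cfg = self.config
        w = cfg.loss_weights
        x_dense = x.dense()
        r_dense = np.asarray(r.values, dtype=np.float64)
        if x_dense.shape[0] != r_dense.shape[0] or x_dense.shape[0] != len(annotations):
            raise ValueError("x, r and annotations must share sample ordering")
        labels = annotations.labels
        if len(np.unique(labels)) < 2:
            raise ValueError("training requires at least two classes")
        conf = annotations.confounder_codes()
        n = x_dense.shape[0]
        self.feature_ids = np.asarray(x.feature_ids)
        self.endo_feature_ids = np.asarray(r.feature_ids)

        rng = np.random.default_rng(cfg.seed)
        opt = Adam(self.params, lr=opts.lr, weight_decay=cfg.l2_strength,
                   decay_keys=self.decay_keys)
        onehot_all = np.eye(cfg.n_classes)[labels]
        history: list[LossBreakdown] = []

        for _epoch in range(opts.n_epochs):
            perm = rng.permutation(n)
            sums = dict(kl_z=0.0, kl_l=0.0, nll=0.0, tml=0.0, ce=0.0, smooth_l1=0.0)
            n_batches = 0
            for start in range(0, n, opts.batch_size):
                idx = perm[start:start + opts.batch_size]
                if len(idx) < 2:
                    continue
                xb, rb, yb = x_dense[idx], r_dense[idx], labels[idx]
                nb = len(idx)
                prior = library_prior(rb, sd_floor=cfg.lib_sd_floor)

                z_mean, z_logsd = self._encode_onc_t(xb, train=True, rng=rng)
                l_mean, l_logsd = self._encode_lib_t(rb, train=True, rng=rng)
                z_sd, l_sd = ad.exp(z_logsd), ad.exp(l_logsd)
                z = z_mean + Tensor(rng.standard_normal((nb, cfg.k))) * z_sd
                ell = l_mean + Tensor(rng.standard_normal((nb, 1))) * l_sd

                _log_rho, log_mu, theta, phi_logit = self._decode_t(z, ell)
                logp = _zinb_log_pmf_t(xb, log_mu, theta, phi_logit)
                loss_nll = -ad.mean(ad.sum_(logp, axis=1))
                loss_klz = _kl_z_t(z_mean, z_logsd)
                loss_kll = _kl_l_t(l_mean, l_logsd, prior)

                if w.tml > 0:
                    tset = sample_batch_triplets(yb, conf[idx], cfg.omega, rng)
                else:
                    tset = None
                if tset is not None:
                    z_tml = z_mean if cfg.tml_on_posterior_mean else z
                    zi = ad.take(z_tml, tset.i)
                    zj = ad.take(z_tml, tset.j)
                    zk = ad.take(z_tml, tset.j_prime)
                    d_pos = ad.sum_((zi - zj) ** 2.0, axis=1)
                    d_neg = ad.sum_((zi - zk) ** 2.0, axis=1)
                    hinge = ad.relu(d_pos - d_neg + cfg.alpha)
                    loss_tml = ad.sum_(hinge) * (
                        1.0 / (cfg.omega * conf.shape[1] * tset.n_anchors)
                    )
                else:
                    loss_tml = Tensor(0.0)

                u_mean = z_mean * l_mean
                bm = ad.mean(u_mean, axis=0, keepdims=True)
                bv = ad.mean((u_mean - bm) ** 2.0, axis=0, keepdims=True)
                if cfg.generative_sampling:
                    rep = np.tile(np.arange(nb), cfg.eta)
                    z_e = ad.take(z_mean, rep) + Tensor(
                        rng.standard_normal((cfg.eta * nb, cfg.k))
                    ) * ad.take(z_sd, rep)
                    l_e = ad.take(l_mean, rep) + Tensor(
                        rng.standard_normal((cfg.eta * nb, 1))
                    ) * ad.take(l_sd, rep)
                    y_e = onehot_all[idx][np.tile(np.arange(nb), cfg.eta)]
                else:
                    z_e, l_e, y_e = z_mean, l_mean, onehot_all[idx]
                log_probs, h_clf = self._classify_t(z_e, l_e, train=True,
                                                    stats=(bm, bv))
                loss_ce = -ad.sum_(Tensor(y_e) * log_probs) * (1.0 / y_e.shape[0])

                if y_real is not None and w.smooth_l1 > 0:
                    pred = (h_clf @ self.params["reg_W"] + self.params["reg_b"])
                    yr = np.asarray(y_real, dtype=np.float64).reshape(-1, 1)
                    yr_e = yr[idx] if not cfg.generative_sampling else \
                        yr[idx][np.tile(np.arange(nb), cfg.eta)]
                    diff = pred - Tensor(yr_e)
                    small = np.abs(diff.data) < 1.0
                    loss_sl1 = ad.mean(
                        ad.where(small, 0.5 * diff**2.0, ad.abs_(diff) - 0.5)
                    )
                else:
                    loss_sl1 = Tensor(0.0)

                total = (w.kl_z * loss_klz + w.kl_l * loss_kll + w.nll * loss_nll
                         + w.tml * loss_tml + w.ce * loss_ce
                         + w.smooth_l1 * loss_sl1)
                if not np.isfinite(total.data):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {_epoch}: "
                        f"nll={loss_nll.item():.3g} klz={loss_klz.item():.3g} "
                        f"ce={loss_ce.item():.3g}"
                    )
                opt.zero_grad()
                total.backward()
                opt.step()

                sums["kl_z"] += loss_klz.item()
                sums["kl_l"] += loss_kll.item()
                sums["nll"] += loss_nll.item()
                sums["tml"] += loss_tml.item()
                sums["ce"] += loss_ce.item()
                sums["smooth_l1"] += loss_sl1.item()
                n_batches += 1

            avg = {k: v / max(n_batches, 1) for k, v in sums.items()}
            bd = LossBreakdown(total=0.0, **avg)
            bd.total = total_loss(bd, w)
            history.append(bd)

        self.fitted = True
        return history

    # ---------------------------------------------------------------- predict
    def predict(self, x: OncCountMatrix | np.ndarray,
                r: EndogenousCountMatrix | np.ndarray) -> np.ndarray:
        """Positive-class probability from deterministic posterior means."""
        if not self.fitted:
            raise RuntimeError("model has not been fitted")
        if isinstance(x, OncCountMatrix) and self.feature_ids is not None:
            if not np.array_equal(x.feature_ids, self.feature_ids):
                raise ValueError("oncRNA feature identifiers differ from training")
        x_dense = x.dense() if isinstance(x, OncCountMatrix) else np.asarray(x, float)
        r_dense = r.values if isinstance(r, EndogenousCountMatrix) else np.asarray(r, float)
        z_mean, _ = self._encode_onc_t(x_dense)
        l_mean, _ = self._encode_lib_t(r_dense)
        log_probs, _ = self._classify_t(z_mean, l_mean, train=False)
        return np.exp(log_probs.data[:, 1])

    def input_attribution(self, x, r) -> np.ndarray:
        """Gradient x input attribution of the positive-class score.

        The gradient is taken with respect to the log1p-transformed oncRNA
        counts along the deterministic prediction path and multiplied by
        that input, so an always-zero feature receives zero attribution.
        """
        if not self.fitted:
            raise RuntimeError("model has not been fitted")
        x_dense = x.dense() if isinstance(x, OncCountMatrix) else np.asarray(x, float)
        r_dense = r.values if isinstance(r, EndogenousCountMatrix) else np.asarray(r, float)
        xin = Tensor(np.log1p(x_dense), requires_grad=True)
        h = ad.relu(xin @ self.params["enc1_W"] + self.params["enc1_b"])
        z_mean = h @ self.params["enc_mu_W"] + self.params["enc_mu_b"]
        l_mean, _ = self._encode_lib_t(r_dense)
        log_probs, _ = self._classify_t(z_mean, l_mean, train=False)
        pick = np.zeros((1, self.config.n_classes))
        pick[0, 1] = 1.0
        ad.sum_(log_probs * Tensor(pick)).backward()
        attr = xin.grad * xin.data
        for p in self.params.values():
            p.grad = None
        return attr

    # ------------------------------------------------------------ persistence
    def save(self, path: str) -> None:
        cfg = asdict(self.config)
        buf = io.BytesIO()
        np.savez(buf, bn_mean=self.bn_mean, bn_var=self.bn_var,
                 feature_ids=np.asarray(self.feature_ids, dtype=str),
                 endo_feature_ids=np.asarray(self.endo_feature_ids, dtype=str),
                 **{k: t.data for k, t in self.params.items()})
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(cfg))
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str) -> "Orion":
        with zipfile.ZipFile(path) as zf:
            cfg = json.loads(zf.read("config.json"))
            arrs = np.load(io.BytesIO(zf.read("weights.npz")))
        cfg["loss_weights"] = LossWeights(**cfg["loss_weights"])
        model = cls(ModelConfig(**cfg))
        for k in model.params:
            model.params[k].data = arrs[k]
        model.bn_mean = arrs["bn_mean"]
        model.bn_var = arrs["bn_var"]
        model.feature_ids = arrs["feature_ids"]
        model.endo_feature_ids = arrs["endo_feature_ids"]
        model.fitted = True
        return model


def fit(x: OncCountMatrix, r: EndogenousCountMatrix,
        annotations: SampleAnnotations, config: ModelConfig,
        train_opts: TrainOpts | None = None) -> tuple[Orion, list[LossBreakdown]]:
    """Train a fresh model; returns (model, per-epoch loss history)."""
    model = Orion(config)
    history = model.fit(x, r, annotations, train_opts)
    return model, history
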