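"""Normal mixture CFA baseline: the model that *should* fail on VAS data.

A one-factor confirmatory factor analysis with a normal careless component,

.. math::

    f(y_{ij}) = \\pi_i \\, N(y_{ij}; \\nu_j + \\lambda_j \\theta_i, \\sigma_j)
            + (1 - \\pi_i) \\, N(y_{ij}; \\mu_c, \\sigma_c),

is applied, deliberately mis-specified, to bounded (0, 1) slider responses.
As in the Beta mixture, pi_i is a person-level mixing weight per cell.
Its normality assumptions do not hold for bounded, often skewed VAS data, so
head-to-head comparison against the Beta mixture IRM isolates the value of
modeling the bounded response distribution.  Loading signs are fixed by item
wording; the trait is standardized (mean 0, variance 1) for identification,
with loadings free.  The attentiveness hierarchy (pi_i, pi, omega) and its
priors match the Beta mixture exactly for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, expit

from .estimation import (
    ItemsMeta,
    McmcSpec,
    PosteriorResult,
    PriorConfig,
    log_half_cauchy,
    log_normal_pdf,
)
from .sampler import _Adapt, _logit, _WINDOW, summarize_draws

__all__ = ["CfaParams", "cfa_mixture_log_likelihood", "fit_cfa_mixture"]

_TARGET_1D = 0.44
_TARGET_ND = 0.30


@dataclass
class CfaParams:
    """Parameter set of the normal mixture CFA."""

    intercepts: np.ndarray       # (J,) nu_j
    loadings: np.ndarray         # (J,) lambda_j, sign matches wording
    residual_sd: np.ndarray      # (J,) sigma_j > 0
    trait: np.ndarray            # (N,) scalar factor scores
    careless_mean: float         # mu_c
    careless_sd: float           # sigma_c > 0
    person_prob: np.ndarray      # (N,) pi_i
    attentive_prop: float = 0.8
    concentration: float = 2.0

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.residual_sd = np.asarray(self.residual_sd, dtype=float)
        self.trait = np.asarray(self.trait, dtype=float)
        self.person_prob = np.atleast_1d(np.asarray(self.person_prob, dtype=float))


def cfa_mixture_log_likelihood(responses, params: CfaParams) -> float:
    """Cell-wise mixture log likelihood; -inf for non-positive sds."""
    y = np.asarray(responses, dtype=float)
    if np.any(params.residual_sd <= 0) or params.careless_sd <= 0:
        return -np.inf
    mu = params.intercepts[None, :] + params.loadings[None, :] * params.trait[:, None]
    log_att = log_normal_pdf(y - mu, params.residual_sd[None, :])
    log_care = log_normal_pdf(y - params.careless_mean, params.careless_sd)
    p = params.person_prob[:, None]
    with np.errstate(divide="ignore"):
        cell = np.logaddexp(np.log(p) + log_att, np.log1p(-p) + log_care)
    return float(np.sum(cell))


class _CfaChain:
    """One MCMC chain for the normal mixture CFA."""

    def __init__(self, responses, meta: ItemsMeta, config: PriorConfig,
                 rng: np.random.Generator):
        self.y = np.asarray(responses, dtype=float)
        self.meta = meta
        self.cfg = config
        self.rng = rng
        n, j = self.y.shape
        self.n, self.j = n, j

        self.nu = self.y.mean(axis=0) + 0.05 * rng.standard_normal(j)
        self.log_lam = np.log(0.1) + 0.1 * rng.standard_normal(j)
        self.log_sig = np.log(self.y.std(axis=0) + 0.05) + 0.05 * rng.standard_normal(j)
        self.theta = 0.1 * rng.standard_normal(n)
        self.mu_c = 0.5 + 0.05 * rng.standard_normal()
        self.log_sig_c = np.log(0.3) + 0.1 * rng.standard_normal()
        self.logit_pi_i = np.full(n, _logit(0.9)) + 0.1 * rng.standard_normal(n)
        self.logit_pi = float(_logit(0.8) + 0.1 * rng.standard_normal())
        self.log_omega = float(np.log(2.0) + 0.1 * rng.standard_normal())

        self.ad_theta = _Adapt(n, 0.5, _TARGET_1D)
        self.ad_item = _Adapt(j, 0.1, _TARGET_ND)
        self.ad_care = _Adapt((), 0.1, _TARGET_ND)
        self.ad_pi_i = _Adapt(n, 1.0, _TARGET_1D)
        self.ad_pi = _Adapt((), 0.3, _TARGET_1D)
        self.ad_omega = _Adapt((), 0.5, _TARGET_1D)

        self.log_att = self._att_matrix(self.nu, self.log_lam, self.log_sig, self.theta)
        self.log_care = self._care_matrix(self.mu_c, self.log_sig_c)
        self.cell = self._mix(self.log_att, self.log_care, self.logit_pi_i)

    def _att_matrix(self, nu, log_lam, log_sig, theta):
        lam = self.meta.wording * np.exp(log_lam)
        mu = nu[None, :] + lam[None, :] * theta[:, None]
        return log_normal_pdf(self.y - mu, np.exp(log_sig)[None, :])

    def _care_matrix(self, mu_c, log_sig_c):
        return log_normal_pdf(self.y - mu_c, np.exp(log_sig_c))

    @staticmethod
    def _mix(log_att, log_care, logit_pi_i):
        lp = -np.logaddexp(0.0, -logit_pi_i)[:, None]
        lq = -np.logaddexp(0.0, logit_pi_i)[:, None]
        return np.logaddexp(lp + log_att, lq + log_care)

    def update_theta(self):
        prop = self.theta + self.ad_theta.scale * self.rng.standard_normal(self.n)
        att_prop = self._att_matrix(self.nu, self.log_lam, self.log_sig, prop)
        cell_prop = self._mix(att_prop, self.log_care, self.logit_pi_i)
        delta = (cell_prop.sum(axis=1) - self.cell.sum(axis=1)
                 - 0.5 * (prop ** 2 - self.theta ** 2))
        acc = np.log(self.rng.random(self.n)) < delta
        self.theta[acc] = prop[acc]
        self.log_att[acc] = att_prop[acc]
        self.cell[acc] = cell_prop[acc]
        self.ad_theta.record(acc)

    def update_items(self):
        eps = self.rng.standard_normal((3, self.j))
        nu_p = self.nu + self.ad_item.scale * eps[0]
        lam_p = self.log_lam + self.ad_item.scale * eps[1]
        sig_p = self.log_sig + self.ad_item.scale * eps[2]
        att_prop = self._att_matrix(nu_p, lam_p, sig_p, self.theta)
        cell_prop = self._mix(att_prop, self.log_care, self.logit_pi_i)
        sd = self.cfg.item_prior_sd
        # half-normal(0, sd) on |lambda| with log Jacobian, normal(0, sd) on nu,
        # half-Cauchy on sigma_j with log Jacobian
        prior_delta = (
            -(np.exp(2 * lam_p) - np.exp(2 * self.log_lam)) / (2 * sd ** 2)
            + (lam_p - self.log_lam)
            - (nu_p ** 2 - self.nu ** 2) / (2 * sd ** 2)
            + log_half_cauchy(np.exp(sig_p), self.cfg.trait_sd_scale)
            - log_half_cauchy(np.exp(self.log_sig), self.cfg.trait_sd_scale)
            + (sig_p - self.log_sig)
        )
        delta = cell_prop.sum(axis=0) - self.cell.sum(axis=0) + prior_delta
        acc = np.log(self.rng.random(self.j)) < delta
        self.nu[acc] = nu_p[acc]
        self.log_lam[acc] = lam_p[acc]
        self.log_sig[acc] = sig_p[acc]
        self.log_att[:, acc] = att_prop[:, acc]
        self.cell[:, acc] = cell_prop[:, acc]
        self.ad_item.record(acc)

    def update_careless(self):
        eps = self.rng.standard_normal(2)
        mu_p = self.mu_c + self.ad_care.scale * eps[0]
        sig_p = self.log_sig_c + self.ad_care.scale * eps[1]
        care_prop = self._care_matrix(mu_p, sig_p)
        cell_prop = self._mix(self.log_att, care_prop, self.logit_pi_i)
        sd = self.cfg.item_prior_sd
        delta = (np.sum(cell_prop - self.cell)
                 - (mu_p ** 2 - self.mu_c ** 2) / (2 * sd ** 2)
                 + float(log_half_cauchy(np.exp(sig_p), self.cfg.trait_sd_scale)
                         - log_half_cauchy(np.exp(self.log_sig_c), self.cfg.trait_sd_scale))
                 + (sig_p - self.log_sig_c))
        if np.log(self.rng.random()) < delta:
            self.mu_c, self.log_sig_c = float(mu_p), float(sig_p)
            self.log_care = care_prop
            self.cell = cell_prop
            self.ad_care.record(1.0)

    def _pi_i_log_prior(self, logit_pi_i):
        omega = np.exp(self.log_omega)
        pi = expit(self.logit_pi)
        a, b = omega * pi, omega * (1.0 - pi)
        lp = -np.logaddexp(0.0, -logit_pi_i)
        lq = -np.logaddexp(0.0, logit_pi_i)
        return a * lp + b * lq - betaln(a, b)

    def update_pi_i(self):
        prop = self.logit_pi_i + self.ad_pi_i.scale * self.rng.standard_normal(self.n)
        cell_prop = self._mix(self.log_att, self.log_care, prop)
        delta = (cell_prop.sum(axis=1) - self.cell.sum(axis=1)
                 + self._pi_i_log_prior(prop) - self._pi_i_log_prior(self.logit_pi_i))
        acc = np.log(self.rng.random(self.n)) < delta
        self.logit_pi_i[acc] = prop[acc]
        self.cell[acc] = cell_prop[acc]
        self.ad_pi_i.record(acc)

    def _hyper_target(self, logit_pi, log_omega):
        omega = np.exp(log_omega)
        pi = expit(logit_pi)
        a, b = omega * pi, omega * (1.0 - pi)
        lp = -np.logaddexp(0.0, -self.logit_pi_i)
        lq = -np.logaddexp(0.0, self.logit_pi_i)
        loglik = np.sum((a - 1.0) * lp + (b - 1.0) * lq) - self.n * betaln(a, b)
        a0, b0 = self.cfg.dirichlet_base
        prior_pi = (a0 - 1.0) * np.log(pi) + (b0 - 1.0) * np.log1p(-pi)
        jac_pi = np.log(pi) + np.log1p(-pi)
        return float(loglik + prior_pi + jac_pi
                     + float(log_half_cauchy(omega, self.cfg.concentration_scale))
                     + log_omega)

    def update_hyper(self):
        lpi = self.logit_pi + self.ad_pi.scale * self.rng.standard_normal()
        delta = self._hyper_target(lpi, self.log_omega) - self._hyper_target(
            self.logit_pi, self.log_omega)
        if np.log(self.rng.random()) < delta:
            self.logit_pi = float(lpi)
            self.ad_pi.record(1.0)
        lom = self.log_omega + self.ad_omega.scale * self.rng.standard_normal()
        delta = self._hyper_target(self.logit_pi, lom) - self._hyper_target(
            self.logit_pi, self.log_omega)
        if np.log(self.rng.random()) < delta:
            self.log_omega = float(lom)
            self.ad_omega.record(1.0)

    def sweep(self, adapting: bool, iteration: int):
        self.update_theta()
        self.update_items()
        self.update_careless()
        self.update_pi_i()
        self.update_hyper()
        if adapting and (iteration + 1) % _WINDOW == 0:
            for ad in (self.ad_theta, self.ad_item, self.ad_care,
                       self.ad_pi_i, self.ad_pi, self.ad_omega):
                ad.adapt()

    def snapshot(self) -> dict:
        return {
            "intercepts": self.nu.copy(),
            "loadings": self.meta.wording * np.exp(self.log_lam),
            "residual_sd": np.exp(self.log_sig),
            "theta": self.theta.copy(),
            "careless_mean": self.mu_c,
            "careless_sd": np.exp(self.log_sig_c),
            "attentive_prop": expit(self.logit_pi),
            "concentration": np.exp(self.log_omega),
            "person_prob": expit(self.logit_pi_i),
            "class_prob": expit(
                self.logit_pi_i + (self.log_att - self.log_care).sum(axis=1)),
        }


def fit_cfa_mixture(responses, meta: ItemsMeta, config: PriorConfig = None,
                    spec: McmcSpec = None) -> PosteriorResult:
    """Fit the normal mixture CFA by adaptive Metropolis-within-Gibbs MCMC."""
    config = config or PriorConfig()
    spec = spec or McmcSpec()
    responses = np.asarray(responses, dtype=float)
    seed_seq = np.random.SeedSequence(spec.seed)
    chain_draws = []
    for child in seed_seq.spawn(spec.chains):
        rng = np.random.default_rng(child)
        chain = _CfaChain(responses, meta, config, rng)
        kept: dict[str, list] = {}
        for it in range(spec.iterations):
            chain.sweep(adapting=it < spec.burn_in, iteration=it)
            if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
                for k, v in chain.snapshot().items():
                    kept.setdefault(k, []).append(v)
        chain_draws.append({k: np.asarray(v) for k, v in kept.items()})
    draws = {k: np.stack([cd[k] for cd in chain_draws]) for k in chain_draws[0]}
    return summarize_draws(draws, spec)
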