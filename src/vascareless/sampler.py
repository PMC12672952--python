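"""Adaptive Metropolis-within-Gibbs samplers for the mixture models.

The posterior is explored with blocked random-walk Metropolis updates.  The
key structural fact exploited throughout: given the item parameters and the
careless component, the per-person blocks (trait value theta_i, attentiveness
probability pi_i) are conditionally independent across persons, and given the
traits the per-item blocks (difficulty, dispersion) are conditionally
independent across items.  Each such block therefore gets its own proposal
scale and its own accept/reject decision, all evaluated in one vectorized
pass over the full response matrix.

Proposal scales adapt toward standard acceptance targets (0.44 for scalar
blocks, 0.30 for small vector blocks) in windows during burn-in only, so the
post-burn-in chain is a fixed-kernel Markov chain.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, expit

from .estimation import (
    ItemsMeta,
    McmcSpec,
    PosteriorResult,
    PriorConfig,
    epsr as compute_epsr,
    log_half_cauchy,
)

__all__ = ["run_beta_mixture", "build_corr_from_cpc", "cpc_log_prior"]

_WINDOW = 50
_TARGET_1D = 0.44
_TARGET_ND = 0.30


# ---------------------------------------------------------------------------
# LKJ via canonical partial correlations (C-vine representation)

def build_corr_from_cpc(z: np.ndarray, n_dims: int) -> np.ndarray:
    """Correlation matrix from atanh canonical partial correlations.

    ``z`` has length D(D-1)/2, ordered row-wise over the strict lower
    triangle of the Cholesky factor.  The construction is the standard
    CPC-to-Cholesky recursion; the result is always a valid correlation
    matrix for any real ``z``.
    """
    p = np.tanh(np.asarray(z, dtype=float))
    L = np.zeros((n_dims, n_dims))
    L[0, 0] = 1.0
    k = 0
    for i in range(1, n_dims):
        rem = 1.0
        for j in range(i):
            L[i, j] = p[k] * np.sqrt(rem)
            rem -= L[i, j] ** 2
            k += 1
        L[i, i] = np.sqrt(max(rem, 0.0))
    return L @ L.T


def cpc_log_prior(z: np.ndarray, n_dims: int, eta: float) -> float:
    """Log prior on atanh-CPCs equivalent to LKJ(eta) on the correlation.

    The level-j canonical partial correlation (1-based column j of the
    Cholesky recursion) is independently shifted-Beta with shape
    eta + (D - 1 - j)/2, so in atanh space the density kernel is
    shape * log(1 - tanh(z)^2) including the change of variables.
    """
    z = np.asarray(z, dtype=float)
    total = 0.0
    k = 0
    for i in range(1, n_dims):
        for j in range(1, i + 1):
            shape = eta + (n_dims - 1 - j) / 2.0
            total += shape * np.log1p(-np.tanh(z[k]) ** 2)
            k += 1
    return float(total)


# ---------------------------------------------------------------------------
# sampler core

class _Adapt:
    """Per-block proposal scales with windowed Robbins-Monro adaptation."""

    def __init__(self, shape, init, target):
        self.scale = np.full(shape, init, dtype=float)
        self.target = target
        self.accepted = np.zeros(shape)
        self.window = 0

    def record(self, accepted):
        self.accepted += accepted

    def adapt(self):
        self.window += 1
        rate = self.accepted / _WINDOW
        gain = min(0.5, 2.0 / np.sqrt(self.window))
        self.scale *= np.exp(gain * (rate - self.target))
        self.accepted[...] = 0.0


class _BetaMixtureChain:
    """One chain of the Beta mixture IRM (or plain Beta IRM) sampler."""

    def __init__(self, responses, meta: ItemsMeta, config: PriorConfig,
                 mixture: bool, rng: np.random.Generator):
        self.y = np.asarray(responses, dtype=float)
        if np.any(self.y <= 0) or np.any(self.y >= 1):
            raise ValueError("responses must be clamped strictly inside (0, 1)")
        self.log_y = np.log(self.y)
        self.log_1my = np.log1p(-self.y)
        self.meta = meta
        self.cfg = config
        self.mixture = mixture
        self.rng = rng
        n, j = self.y.shape
        d = meta.n_dims
        self.n, self.j, self.d = n, j, d

        # initialization near the attentive-dominant regime, jittered per chain
        self.b = 0.1 * rng.standard_normal(j)
        self.alpha = np.abs(0.5 + 0.1 * rng.standard_normal(j))
        self.theta = 0.1 * rng.standard_normal((n, d))
        self.log_sigma = 0.05 * rng.standard_normal(d)
        self.z_cpc = np.zeros(d * (d - 1) // 2)
        if mixture:
            self.log_m = float(0.05 * rng.standard_normal())
            self.log_n = float(0.05 * rng.standard_normal())
            self.logit_pi_i = np.full(n, _logit(0.9)) + 0.1 * rng.standard_normal(n)
            self.logit_pi = float(_logit(0.8) + 0.1 * rng.standard_normal())
            self.log_omega = float(np.log(2.0) + 0.1 * rng.standard_normal())

        self.ad_theta = _Adapt(n, 0.5, _TARGET_1D if d == 1 else _TARGET_ND)
        self.ad_item = _Adapt(j, 0.2, _TARGET_ND)
        self.ad_sigma = _Adapt((), 0.3, _TARGET_1D if d == 1 else _TARGET_ND)
        if d > 1:
            self.ad_cpc = _Adapt((), 0.3, _TARGET_ND)
        if mixture:
            self.ad_mn = _Adapt((), 0.3, _TARGET_ND)
            self.ad_pi_i = _Adapt(n, 1.0, _TARGET_1D)
            # pi and omega get separate scalar blocks: their conditional
            # posteriors have very different widths, so a joint proposal
            # scale would throttle whichever mixes slower
            self.ad_pi = _Adapt((), 0.3, _TARGET_1D)
            self.ad_omega = _Adapt((), 0.5, _TARGET_1D)

        self._refresh_trait_prior()
        self.log_att = self._att_matrix(self.b, self.alpha, self.theta)
        if mixture:
            self.log_care = self._care_matrix(self.log_m, self.log_n)
            self.cell = self._mix(self.log_att, self.log_care, self.logit_pi_i)
        else:
            self.cell = self.log_att

    # -- matrix helpers ----------------------------------------------------
    def _att_matrix(self, b, alpha, theta):
        th = theta[:, self.meta.dim_map]
        eta = self.meta.wording[None, :] * th - b[None, :]
        A = np.exp(0.5 * (eta + alpha[None, :]))
        B = np.exp(-0.5 * (eta - alpha[None, :]))
        return (A - 1.0) * self.log_y + (B - 1.0) * self.log_1my - betaln(A, B)

    def _care_matrix(self, log_m, log_n):
        m, n_ = np.exp(log_m), np.exp(log_n)
        return (m - 1.0) * self.log_y + (n_ - 1.0) * self.log_1my - betaln(m, n_)

    @staticmethod
    def _mix(log_att, log_care, logit_pi_i):
        # item-level mixture: pi_i is a person-level weight applied per cell
        lp = -np.logaddexp(0.0, -logit_pi_i)[:, None]     # log pi_i
        lq = -np.logaddexp(0.0, logit_pi_i)[:, None]      # log (1 - pi_i)
        return np.logaddexp(lp + log_att, lq + log_care)

    def _refresh_trait_prior(self):
        sd = np.exp(self.log_sigma)
        if self.d == 1:
            self.prec = np.array([[1.0 / sd[0] ** 2]])
            self.logdet_cov = 2.0 * self.log_sigma[0]
        else:
            R = build_corr_from_cpc(self.z_cpc, self.d)
            cov = np.diag(sd) @ R @ np.diag(sd)
            self.prec = np.linalg.inv(cov)
            self.logdet_cov = np.linalg.slogdet(cov)[1]

    def _theta_prior_rows(self, theta):
        quad = np.einsum("nd,de,ne->n", theta, self.prec, theta)
        return -0.5 * (quad + self.logdet_cov)

    # -- update blocks -----------------------------------------------------
    def update_theta(self):
        prop = self.theta + self.ad_theta.scale[:, None] * self.rng.standard_normal((self.n, self.d))
        att_prop = self._att_matrix(self.b, self.alpha, prop)
        cell_prop = (self._mix(att_prop, self.log_care, self.logit_pi_i)
                     if self.mixture else att_prop)
        delta = (cell_prop.sum(axis=1) - self.cell.sum(axis=1)
                 + self._theta_prior_rows(prop) - self._theta_prior_rows(self.theta))
        acc = np.log(self.rng.random(self.n)) < delta
        self.theta[acc] = prop[acc]
        self.log_att[acc] = att_prop[acc]
        self.cell[acc] = cell_prop[acc]
        self.ad_theta.record(acc)

    def update_items(self):
        # cells are mixed independently, so per-item accept/reject decisions
        # factorize over columns and run in one vectorized pass
        eps = self.rng.standard_normal((2, self.j))
        b_prop = self.b + self.ad_item.scale * eps[0]
        a_prop = self.alpha + self.ad_item.scale * eps[1]
        att_prop = self._att_matrix(b_prop, a_prop, self.theta)
        cell_prop = (self._mix(att_prop, self.log_care, self.logit_pi_i)
                     if self.mixture else att_prop)
        sd = self.cfg.item_prior_sd
        prior_delta = (-(b_prop ** 2 - self.b ** 2) - (a_prop ** 2 - self.alpha ** 2)) / (2 * sd ** 2)
        delta = cell_prop.sum(axis=0) - self.cell.sum(axis=0) + prior_delta
        acc = np.log(self.rng.random(self.j)) < delta
        self.b[acc] = b_prop[acc]
        self.alpha[acc] = a_prop[acc]
        self.log_att[:, acc] = att_prop[:, acc]
        self.cell[:, acc] = cell_prop[:, acc]
        self.ad_item.record(acc)

    def _sigma_target(self, log_sigma, z_cpc):
        sd = np.exp(log_sigma)
        if self.d == 1:
            quad = np.sum(self.theta ** 2) / sd[0] ** 2
            trait = -0.5 * quad - self.n * log_sigma[0]
        else:
            R = build_corr_from_cpc(z_cpc, self.d)
            cov = np.diag(sd) @ R @ np.diag(sd)
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                return -np.inf
            prec = np.linalg.inv(cov)
            quad = np.einsum("nd,de,ne->", self.theta, prec, self.theta)
            trait = -0.5 * (quad + self.n * logdet)
        prior = float(np.sum(log_half_cauchy(sd, self.cfg.trait_sd_scale)))
        jac = float(np.sum(log_sigma))
        cpc = (cpc_log_prior(z_cpc, self.d, self.cfg.lkj_shape) if self.d > 1 else 0.0)
        return trait + prior + jac + cpc

    def update_sigma(self):
        prop = self.log_sigma + self.ad_sigma.scale * self.rng.standard_normal(self.d)
        delta = self._sigma_target(prop, self.z_cpc) - self._sigma_target(self.log_sigma, self.z_cpc)
        if np.log(self.rng.random()) < delta:
            self.log_sigma = prop
            self._refresh_trait_prior()
            self.ad_sigma.record(1.0)

    def update_cpc(self):
        prop = self.z_cpc + self.ad_cpc.scale * self.rng.standard_normal(self.z_cpc.size)
        delta = self._sigma_target(self.log_sigma, prop) - self._sigma_target(self.log_sigma, self.z_cpc)
        if np.log(self.rng.random()) < delta:
            self.z_cpc = prop
            self._refresh_trait_prior()
            self.ad_cpc.record(1.0)

    def update_mn(self):
        eps = self.rng.standard_normal(2)
        lm, ln = self.log_m + self.ad_mn.scale * eps[0], self.log_n + self.ad_mn.scale * eps[1]
        care_prop = self._care_matrix(lm, ln)
        cell_prop = self._mix(self.log_att, care_prop, self.logit_pi_i)
        scale = self.cfg.careless_shape_scale
        delta = (np.sum(cell_prop - self.cell)
                 + float(log_half_cauchy(np.exp(lm), scale) - log_half_cauchy(np.exp(self.log_m), scale))
                 + float(log_half_cauchy(np.exp(ln), scale) - log_half_cauchy(np.exp(self.log_n), scale))
                 + (lm - self.log_m) + (ln - self.log_n))
        if np.log(self.rng.random()) < delta:
            self.log_m, self.log_n = float(lm), float(ln)
            self.log_care = care_prop
            self.cell = cell_prop
            self.ad_mn.record(1.0)

    def _pi_i_log_prior(self, logit_pi_i):
        # Beta(omega*pi, omega*(1-pi)) on pi_i, plus the logit Jacobian
        omega = np.exp(self.log_omega)
        pi = expit(self.logit_pi)
        a, b = omega * pi, omega * (1.0 - pi)
        lp = -np.logaddexp(0.0, -logit_pi_i)
        lq = -np.logaddexp(0.0, logit_pi_i)
        return a * lp + b * lq - betaln(a, b)   # (a-1)lp+(b-1)lq + Jacobian(lp+lq)

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
        prior_omega = float(log_half_cauchy(omega, self.cfg.concentration_scale))
        return float(loglik + prior_pi + jac_pi + prior_omega + log_omega)

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

    # -- one sweep ---------------------------------------------------------
    def sweep(self, adapting: bool, iteration: int):
        self.update_theta()
        self.update_items()
        self.update_sigma()
        if self.d > 1:
            self.update_cpc()
        if self.mixture:
            self.update_mn()
            self.update_pi_i()
            self.update_hyper()
        if adapting and (iteration + 1) % _WINDOW == 0:
            self.ad_theta.adapt()
            self.ad_item.adapt()
            self.ad_sigma.adapt()
            if self.d > 1:
                self.ad_cpc.adapt()
            if self.mixture:
                self.ad_mn.adapt()
                self.ad_pi_i.adapt()
                self.ad_pi.adapt()
                self.ad_omega.adapt()

    def snapshot(self) -> dict:
        out = {
            "difficulty": self.b.copy(),
            "dispersion": self.alpha.copy(),
            "theta": (self.theta[:, 0].copy() if self.d == 1 else self.theta.copy()),
            "trait_sd": np.exp(self.log_sigma),
        }
        if self.d > 1:
            out["trait_corr"] = build_corr_from_cpc(self.z_cpc, self.d)
        if self.mixture:
            out["careless_m"] = np.exp(self.log_m)
            out["careless_n"] = np.exp(self.log_n)
            out["attentive_prop"] = expit(self.logit_pi)
            out["concentration"] = np.exp(self.log_omega)
            out["person_prob"] = expit(self.logit_pi_i)
            # whole-row Bayes-rule attentiveness diagnostic at this draw
            out["class_prob"] = expit(
                self.logit_pi_i + (self.log_att - self.log_care).sum(axis=1))
        return out


def _logit(p):
    return np.log(p) - np.log1p(-p)


def run_beta_mixture(responses, meta: ItemsMeta, config: PriorConfig,
                     spec: McmcSpec, mixture: bool) -> PosteriorResult:
    """Run all chains and assemble a :class:`PosteriorResult`."""
    responses = np.asarray(responses, dtype=float)
    seed_seq = np.random.SeedSequence(spec.seed)
    chain_draws: list[dict] = []
    for child in seed_seq.spawn(spec.chains):
        rng = np.random.default_rng(child)
        chain = _BetaMixtureChain(responses, meta, config, mixture, rng)
        kept: dict[str, list] = {}
        for it in range(spec.iterations):
            chain.sweep(adapting=it < spec.burn_in, iteration=it)
            if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
                snap = chain.snapshot()
                for k, v in snap.items():
                    kept.setdefault(k, []).append(v)
        chain_draws.append({k: np.asarray(v) for k, v in kept.items()})

    draws = {k: np.stack([cd[k] for cd in chain_draws]) for k in chain_draws[0]}
    return summarize_draws(draws, spec)


# strictly positive parameters get a log transform before EPSR: their
# posteriors can be heavy-tailed (half-Cauchy priors), and the Gelman-Rubin
# statistic needs a finite-variance estimand to stabilize
_LOG_SCALE_EPSR = {"trait_sd", "careless_m", "careless_n", "concentration",
                   "residual_sd", "careless_sd"}
# derived per-person quantities are summarized but not part of the gate
_UNGATED = {"class_prob"}


def summarize_draws(draws: dict, spec: McmcSpec,
                    epsr_threshold: float = 1.1) -> PosteriorResult:
    """Posterior means, central 95% intervals, and EPSR from raw draws."""
    point, ci95, epsr_vals = {}, {}, {}
    for name, arr in draws.items():
        flat = arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])
        point[name] = flat.mean(axis=0)
        ci95[name] = np.percentile(flat, [2.5, 97.5], axis=0)
        if arr.shape[0] >= 2 and name not in _UNGATED:
            epsr_vals[name] = compute_epsr(
                np.log(arr) if name in _LOG_SCALE_EPSR else arr)
    converged = bool(epsr_vals) and all(
        np.all(np.asarray(v) < epsr_threshold) for v in epsr_vals.values()
    )
    return PosteriorResult(draws=draws, point=point, ci95=ci95,
                           epsr=epsr_vals, converged=converged, spec=spec)
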