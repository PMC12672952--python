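"""Bayesian estimation of the Beta mixture IRM for careless-respondent detection.

The observed response matrix is modeled, per person i and item j, as a
two-component mixture

.. math::

    f(y_{ij}) = \\pi_i \\, \\mathrm{Beta}(y_{ij}; a_{ij}, b_{ij})
            + (1 - \\pi_i) \\, \\mathrm{Beta}(y_{ij}; m, n),

where the first (attentive) component is the Beta IRM driven by the person's
trait and the item's wording/difficulty/dispersion, and the second (careless)
component is a single unstructured Beta common to all persons and items.
The mixing weight pi_i — person i's probability of attentiveness — is a
person-level parameter applied to every cell of that person's row, with the
class indicator marginalized out.  pi_i carries a hierarchical Dirichlet
prior Beta(omega*pi, omega*(1-pi)) that shrinks individuals toward the
population attentive proportion pi; this shrinkage is what makes the simple
0.5 threshold fail when careless respondents are rare.

Priors: N(0, 10) on difficulties and dispersions, half-Cauchy(0, 5) on trait
SDs and on the careless shapes m and n, LKJ on the trait correlation matrix,
a flat Dirichlet(1, 1) on (pi, 1-pi), and half-Cauchy(0, 5) on the
concentration omega.  Posterior computation uses adaptive random-walk
Metropolis-within-Gibbs (see :mod:`vascareless.sampler`); convergence is
judged by the Gelman-Rubin estimated potential scale reduction (EPSR),
with all values below 1.1 taken as satisfactory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, logsumexp

from .beta_irm import beta_logpdf
from .careless import CarelessBeta

__all__ = [
    "ItemsMeta",
    "PriorConfig",
    "McmcSpec",
    "MixtureParams",
    "PosteriorResult",
    "attentive_loglik_matrix",
    "mixture_log_likelihood",
    "log_prior",
    "epsr",
    "posterior_class_probability",
    "fit_mixture",
    "fit_beta_irm",
]


# ---------------------------------------------------------------------------
# configuration types

@dataclass(frozen=True)
class ItemsMeta:
    """Fixed item structure: wording signs and item-to-dimension map."""

    wording: np.ndarray          # (J,) entries in {-1, +1}
    dim_map: np.ndarray = None   # (J,) integer dimension indices

    def __post_init__(self) -> None:
        w = np.asarray(self.wording, dtype=int)
        if not np.all(np.isin(w, (-1, 1))):
            raise ValueError("wording entries must be -1 or +1")
        object.__setattr__(self, "wording", w)
        d = (np.zeros(w.size, dtype=int) if self.dim_map is None
             else np.asarray(self.dim_map, dtype=int))
        if d.size != w.size or np.any(d < 0):
            raise ValueError("dim_map must align with wording and be nonnegative")
        object.__setattr__(self, "dim_map", d)

    @property
    def n_items(self) -> int:
        return int(self.wording.size)

    @property
    def n_dims(self) -> int:
        return int(self.dim_map.max()) + 1


@dataclass(frozen=True)
class PriorConfig:
    """Scales of the prior stack; defaults are the diffuse choices."""

    item_prior_sd: float = 10.0
    trait_sd_scale: float = 5.0
    lkj_shape: float = 1.0
    careless_shape_scale: float = 5.0
    dirichlet_base: tuple = (1.0, 1.0)
    concentration_scale: float = 5.0

    def __post_init__(self) -> None:
        for name in ("item_prior_sd", "trait_sd_scale", "lkj_shape",
                     "careless_shape_scale", "concentration_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class McmcSpec:
    """Sampler run lengths.  ``burn_in`` defaults to half the iterations."""

    chains: int = 2
    iterations: int = 40_000
    burn_in: int = None
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 2:
            raise ValueError("need at least one chain and two iterations")
        if self.burn_in is None:
            object.__setattr__(self, "burn_in", self.iterations // 2)
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must lie in [0, iterations)")


@dataclass
class MixtureParams:
    """One full set of model unknowns (plus the fixed item structure)."""

    difficulty: np.ndarray       # (J,)
    dispersion: np.ndarray       # (J,)
    theta: np.ndarray            # (N, D)
    trait_sd: np.ndarray         # (D,)
    trait_corr: np.ndarray       # (D, D) correlation matrix
    careless: CarelessBeta
    attentive_prop: float        # population pi
    concentration: float         # omega
    person_prob: np.ndarray      # (N,) per-person attentiveness pi_i

    def __post_init__(self) -> None:
        self.difficulty = np.asarray(self.difficulty, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if self.theta.shape[0] == 1 and self.person_prob is not None:
            n = np.asarray(self.person_prob).size
            if n != 1 and self.theta.size == n:
                self.theta = self.theta.reshape(n, 1)
        self.trait_sd = np.atleast_1d(np.asarray(self.trait_sd, dtype=float))
        self.trait_corr = np.atleast_2d(np.asarray(self.trait_corr, dtype=float))
        self.person_prob = np.atleast_1d(np.asarray(self.person_prob, dtype=float))


@dataclass
class PosteriorResult:
    """Posterior draws, summaries, and convergence diagnostics for one fit."""

    draws: dict                  # name -> (chains, kept_iters, *shape)
    point: dict                  # name -> posterior mean over chains+iters
    ci95: dict                   # name -> (2.5%, 97.5%) stacked on first axis
    epsr: dict                   # name -> per-element EPSR
    converged: bool
    spec: McmcSpec
    accept_rates: dict = field(default_factory=dict)

    @property
    def max_epsr(self) -> float:
        return max(float(np.max(v)) for v in self.epsr.values())


# ---------------------------------------------------------------------------
# density helpers

LOG_2_OVER_PI = np.log(2.0 / np.pi)


def log_half_cauchy(x, scale):
    """Log density of |Cauchy(0, scale)|; -inf for nonpositive x."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        LOG_2_OVER_PI - np.log(scale) - np.log1p(np.square(np.where(x > 0, x, 1.0) / scale)),
        -np.inf,
    )
    return out if out.ndim else float(out)


def log_normal_pdf(x, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * (x / sd) ** 2


def log_beta_prior(x, a, b):
    """Log Beta(a, b) density at x in (0, 1), the two-class Dirichlet collapsed."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x >= 1):
        return -np.inf if x.ndim == 0 else np.where((x > 0) & (x < 1), 0.0, -np.inf)
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b)


def lkj_log_kernel(corr: np.ndarray, eta: float) -> float:
    """Unnormalized LKJ log density (eta - 1) * log det R; -inf if R invalid."""
    corr = np.asarray(corr, dtype=float)
    if corr.shape[0] != corr.shape[1] or not np.allclose(np.diag(corr), 1.0):
        return -np.inf
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        return -np.inf
    return (eta - 1.0) * logdet


# ---------------------------------------------------------------------------
# likelihood

def attentive_loglik_matrix(responses, difficulty, dispersion, theta, meta: ItemsMeta):
    """(N, J) matrix of attentive Beta IRM log densities.

    ``theta`` may be (N,) for a unidimensional model or (N, D); items pick
    their dimension through ``meta.dim_map``.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[0] == 1 and np.asarray(responses).shape[0] != 1:
        theta = theta.T
    th = theta[:, meta.dim_map]                        # (N, J)
    eta = meta.wording[None, :] * th - np.asarray(difficulty)[None, :]
    a = np.exp(0.5 * (eta + np.asarray(dispersion)[None, :]))
    b = np.exp(-0.5 * (eta - np.asarray(dispersion)[None, :]))
    return beta_logpdf(responses, a, b)


def _mixture_cell_loglik(log_att, log_care, person_prob):
    p = np.asarray(person_prob, dtype=float)[:, None]
    with np.errstate(divide="ignore"):
        return np.logaddexp(np.log(p) + log_att, np.log1p(-p) + log_care)


def mixture_log_likelihood(responses, params: MixtureParams, meta: ItemsMeta) -> float:
    """Marginal mixture log likelihood of the full response matrix.

    Each cell is a two-component mixture weighted by the person-level
    attentiveness probability:
    sum_i sum_j log[pi_i f_att(y_ij) + (1 - pi_i) f_care(y_ij)],
    evaluated with log-sum-exp.
    """
    responses = np.asarray(responses, dtype=float)
    log_att = attentive_loglik_matrix(
        responses, params.difficulty, params.dispersion, params.theta, meta
    )
    log_care = beta_logpdf(responses, params.careless.m, params.careless.n)
    return float(np.sum(_mixture_cell_loglik(log_att, log_care, params.person_prob)))


def log_prior(params: MixtureParams, config: PriorConfig, meta: ItemsMeta = None) -> float:
    """Joint log prior; returns -inf outside the support, never raises."""
    p = params
    if (np.any(p.trait_sd <= 0) or p.careless.m <= 0 or p.careless.n <= 0
            or not (0 < p.attentive_prop < 1) or p.concentration <= 0
            or np.any(p.person_prob <= 0) or np.any(p.person_prob >= 1)):
        return -np.inf
    total = float(np.sum(log_normal_pdf(p.difficulty, config.item_prior_sd)))
    total += float(np.sum(log_normal_pdf(p.dispersion, config.item_prior_sd)))
    total += float(np.sum(log_half_cauchy(p.trait_sd, config.trait_sd_scale)))
    if p.trait_sd.size > 1:
        kern = lkj_log_kernel(p.trait_corr, config.lkj_shape)
        if not np.isfinite(kern):
            return -np.inf
        total += kern
    total += float(log_half_cauchy(p.careless.m, config.careless_shape_scale))
    total += float(log_half_cauchy(p.careless.n, config.careless_shape_scale))
    a0, b0 = config.dirichlet_base
    total += float(log_beta_prior(p.attentive_prop, a0, b0))
    total += float(log_half_cauchy(p.concentration, config.concentration_scale))
    total += float(np.sum(log_beta_prior(
        p.person_prob,
        p.concentration * p.attentive_prop,
        p.concentration * (1.0 - p.attentive_prop),
    )))
    # multivariate-normal prior on traits (zero mean, diag(sd) R diag(sd))
    sd = p.trait_sd
    if sd.size == 1:
        total += float(np.sum(log_normal_pdf(p.theta.ravel(), sd[0])))
    else:
        cov = np.diag(sd) @ p.trait_corr @ np.diag(sd)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            return -np.inf
        prec = np.linalg.inv(cov)
        quad = np.einsum("nd,de,ne->", p.theta, prec, p.theta)
        n, d = p.theta.shape
        total += -0.5 * (n * (d * np.log(2 * np.pi) + logdet) + quad)
    if not np.isfinite(total):
        return -np.inf
    return total


# ---------------------------------------------------------------------------
# diagnostics

def epsr(draws_by_chain, split: bool = False):
    """Gelman-Rubin estimated potential scale reduction per parameter.

    Parameters
    ----------
    draws_by_chain : array-like
        Shape (chains, iterations) or (chains, iterations, *param_shape);
        post-burn-in draws only.
    split : bool
        If True each chain is split in half first (split-R-hat variant).
    """
    x = np.asarray(draws_by_chain, dtype=float)
    if x.ndim == 1 or x.shape[0] < 2:
        raise ValueError("EPSR needs at least two chains")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, n = x.shape[0], x.shape[1]
    if n < 2:
        raise ValueError("EPSR needs at least two iterations per chain")
    chain_means = x.mean(axis=1)
    within = x.var(axis=1, ddof=1).mean(axis=0)
    between_over_n = chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * within + between_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / within)
    r = np.where(within == 0, 1.0, r)
    return float(r) if r.ndim == 0 else r


def posterior_class_probability(y_row, params: MixtureParams, meta: ItemsMeta,
                                person_index: int = 0) -> float:
    """Bayes-rule posterior probability that one response row is attentive.

    Computed in log space at fixed parameter values:
    pi_i prod_j f_att / (pi_i prod_j f_att + (1 - pi_i) prod_j f_care).
    """
    y = np.asarray(y_row, dtype=float)[None, :]
    theta_row = np.atleast_2d(params.theta)[person_index][None, :]
    log_att = float(np.sum(attentive_loglik_matrix(
        y, params.difficulty, params.dispersion, theta_row, meta)))
    log_care = float(np.sum(beta_logpdf(y, params.careless.m, params.careless.n)))
    pi_i = float(np.atleast_1d(params.person_prob)[person_index])
    if pi_i >= 1.0:
        return 1.0
    if pi_i <= 0.0:
        return 0.0
    la = np.log(pi_i) + log_att
    lc = np.log1p(-pi_i) + log_care
    return float(np.exp(la - logsumexp([la, lc])))


# ---------------------------------------------------------------------------
# fitting front-ends (samplers live in vascareless.sampler)

def fit_mixture(responses, meta: ItemsMeta, config: PriorConfig = None,
                spec: McmcSpec = None) -> PosteriorResult:
    """Fit the Beta mixture IRM by adaptive Metropolis-within-Gibbs MCMC."""
    from .sampler import run_beta_mixture
    return run_beta_mixture(responses, meta, config or PriorConfig(),
                            spec or McmcSpec(), mixture=True)


def fit_beta_irm(responses, meta: ItemsMeta, config: PriorConfig = None,
                 spec: McmcSpec = None) -> PosteriorResult:
    """Fit the attentive-only Beta IRM (no careless component, pi_i = 1)."""
    from .sampler import run_beta_mixture
    return run_beta_mixture(responses, meta, config or PriorConfig(),
                            spec or McmcSpec(), mixture=False)
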