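"""Beta item response model for bounded continuous (visual-analogue-scale) responses.

The attentive measurement model treats a response :math:`y_{ij} \\in (0, 1)` as
Beta-distributed with "acceptance" and "refusal" shape parameters that depend on
the respondent's latent trait, the item's wording sign, difficulty, and
dispersion.  With :math:`\\eta = s_j\\,\\theta_{i,d(j)} - b_j`,

.. math::

    a_{ij} = \\exp\\{(\\eta + \\alpha_j)/2\\}, \\qquad
    b_{ij} = \\exp\\{-(\\eta - \\alpha_j)/2\\},

so the expected response is the logistic function of :math:`\\eta` and the
dispersion :math:`\\alpha_j` shifts only the total concentration
:math:`a_{ij} + b_{ij}`, never the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, expit

__all__ = [
    "ItemParams",
    "TraitVector",
    "ShapePair",
    "shape_params",
    "expected_response",
    "log_density",
    "conditional_variance",
    "item_information",
    "beta_logpdf",
]


@dataclass(frozen=True)
class ItemParams:
    """Parameters of one item in the attentive Beta IRM.

    Attributes
    ----------
    difficulty : float
        Location of the item characteristic curve on the trait scale.
    dispersion : float
        Log-precision parameter; larger values concentrate responses around
        the expected value without moving it.
    wording : int
        +1 for a positively worded item, -1 for a reverse-keyed item.
    dimension : int
        Index of the latent dimension the item measures (simple structure).
    """

    difficulty: float
    dispersion: float
    wording: int = 1
    dimension: int = 0

    def __post_init__(self) -> None:
        if self.wording not in (-1, 1):
            raise ValueError(f"wording must be -1 or +1, got {self.wording}")
        if self.dimension < 0:
            raise ValueError(f"dimension must be >= 0, got {self.dimension}")
        if not (np.isfinite(self.difficulty) and np.isfinite(self.dispersion)):
            raise ValueError("difficulty and dispersion must be finite")


@dataclass(frozen=True)
class TraitVector:
    """Latent trait location of one respondent, one entry per dimension."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if not np.all(np.isfinite(arr)):
            raise ValueError("trait entries must be finite")
        object.__setattr__(self, "theta", arr)


@dataclass(frozen=True)
class ShapePair:
    """Acceptance/refusal shape parameters of the conditional Beta."""

    accept: float
    refuse: float

    def __post_init__(self) -> None:
        if not (self.accept > 0 and self.refuse > 0):
            raise ValueError("shape parameters must be strictly positive")


def _as_trait(theta) -> np.ndarray:
    if isinstance(theta, TraitVector):
        return theta.theta
    arr = np.atleast_1d(np.asarray(theta, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("trait entries must be finite")
    return arr


def _linear_predictor(theta, item: ItemParams) -> float:
    arr = _as_trait(theta)
    if item.dimension >= arr.size:
        raise ValueError(
            f"item dimension {item.dimension} outside trait vector of length {arr.size}"
        )
    return item.wording * arr[item.dimension] - item.difficulty


def shape_params(theta, item: ItemParams) -> ShapePair:
    """Acceptance/refusal Beta shapes for one respondent and one item."""
    eta = _linear_predictor(theta, item)
    return ShapePair(
        accept=float(np.exp(0.5 * (eta + item.dispersion))),
        refuse=float(np.exp(-0.5 * (eta - item.dispersion))),
    )


def expected_response(theta, item: ItemParams) -> float:
    """Expected response: logistic in (wording * trait - difficulty).

    The dispersion parameter cancels from a/(a+b) exactly, so the mean is
    computed directly from the linear predictor and is bit-identical under
    any change of dispersion alone.
    """
    return float(expit(_linear_predictor(theta, item)))


def beta_logpdf(y, a, b):
    """Log Beta(a, b) density at y, vectorized, via log-gamma.

    Stable for shapes below 1 (densities unbounded at the endpoints) as long
    as y stays strictly inside (0, 1).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("responses must lie strictly inside (0, 1)")
    return (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y) - betaln(a, b)


def log_density(y: float, theta, item: ItemParams) -> float:
    """Log density of the attentive Beta IRM at response ``y``."""
    sp = shape_params(theta, item)
    return float(beta_logpdf(y, sp.accept, sp.refuse))


def conditional_variance(theta, item: ItemParams) -> float:
    """Variance of the response given trait and item: mu(1-mu)/(a+b+1)."""
    sp = shape_params(theta, item)
    total = sp.accept + sp.refuse
    mu = sp.accept / total
    return float(mu * (1.0 - mu) / (total + 1.0))


def item_information(
    theta_grid,
    item: ItemParams,
    n_quad: int = 201,
    step: float = 1e-4,
) -> np.ndarray:
    """Numerical Fisher information of one item along a trait grid.

    For each grid point the expectation (Gauss-Legendre quadrature in the
    response) of the negative second derivative (central differences in the
    trait) of the log density is computed.  The closed form is not used.

    Parameters
    ----------
    theta_grid : array-like
        Trait values at which to evaluate the information (unidimensional).
    n_quad : int
        Number of Gauss-Legendre nodes on (0, 1).
    step : float
        Central-difference step in the trait.
    """
    grid = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    if grid.size == 0 or not np.all(np.isfinite(grid)):
        raise ValueError("theta grid must be nonempty and finite")
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    y = 0.5 * (nodes + 1.0)  # map (-1,1) -> (0,1)
    w = 0.5 * weights

    def logf(th):
        eta = item.wording * th - item.difficulty
        a = np.exp(0.5 * (eta + item.dispersion))
        b = np.exp(-0.5 * (eta - item.dispersion))
        return beta_logpdf(y, a, b)

    info = np.empty_like(grid)
    for k, th in enumerate(grid):
        center = logf(th)
        d2 = (logf(th + step) - 2.0 * center + logf(th - step)) / step**2
        density = np.exp(logf(th))
        info[k] = -np.sum(w * density * d2)
    return info
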