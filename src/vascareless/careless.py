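"""Careless-response component: common Beta(m, n) density and generating patterns.

The mixture model's careless class is a residual class: a single Beta(m, n)
shared by all persons and items, intended to absorb the marginal distribution
of whatever careless behaviors are present.  The simulation study contaminates
data with three generating patterns, only the first of which is itself a Beta:

* ``beta_extremes`` — values clustered at both ends, Beta(0.5, 0.5);
* ``end_preference`` — each careless person picks one end of the slider and
  stays there, U(0, 0.2) or U(0.8, 1) depending on the person's side;
* ``midpoint_normal`` — values around the midpoint, Normal(0.5, 0.25)
  truncated to (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .beta_irm import beta_logpdf

__all__ = [
    "CLAMP",
    "CarelessBeta",
    "CarelessPattern",
    "PATTERNS",
    "careless_log_density",
    "sample_careless",
    "sample_careless_matrix",
]

#: Generated responses are squeezed into [CLAMP, 1-CLAMP] so that Beta
#: log-densities (including shapes below 1) remain finite.
CLAMP = 1e-3


@dataclass(frozen=True)
class CarelessBeta:
    """Common Beta shape parameters of the careless component."""

    m: float
    n: float

    def __post_init__(self) -> None:
        if not (self.m > 0 and self.n > 0):
            raise ValueError("careless Beta shapes must be strictly positive")


PATTERNS = ("beta_extremes", "end_preference", "midpoint_normal")


@dataclass(frozen=True)
class CarelessPattern:
    """One of the three generating patterns used in the simulation study."""

    kind: str
    beta_shape: float = 0.5            # Beta(s, s) for beta_extremes
    end_width: float = 0.2             # U(0, w) / U(1-w, 1) for end_preference
    normal_mean: float = 0.5           # truncated-normal location
    normal_sd: float = 0.25            # truncated-normal scale

    def __post_init__(self) -> None:
        if self.kind not in PATTERNS:
            raise ValueError(f"unknown careless pattern {self.kind!r}; one of {PATTERNS}")


def careless_log_density(y, comp: CarelessBeta):
    """Log Beta(m, n) density at y; independent of item and trait."""
    return beta_logpdf(y, comp.m, comp.n)


def _clamp(values: np.ndarray) -> np.ndarray:
    return np.clip(values, CLAMP, 1.0 - CLAMP)


def sample_careless(pattern: CarelessPattern, count: int, rng) -> np.ndarray:
    """Draw ``count`` careless responses for a single person.

    For ``end_preference`` the person's side (left/right) is drawn once and
    all of their responses fall on that side — the side is a person
    attribute, not a per-response coin flip.
    """
    if count <= 0:
        raise ValueError("count must be positive")
    rng = np.random.default_rng(rng)
    if pattern.kind == "beta_extremes":
        out = rng.beta(pattern.beta_shape, pattern.beta_shape, size=count)
    elif pattern.kind == "end_preference":
        right = rng.random() < 0.5
        u = rng.uniform(0.0, pattern.end_width, size=count)
        out = 1.0 - u if right else u
    elif pattern.kind == "midpoint_normal":
        lo = (0.0 - pattern.normal_mean) / pattern.normal_sd
        hi = (1.0 - pattern.normal_mean) / pattern.normal_sd
        out = stats.truncnorm.rvs(
            lo, hi, loc=pattern.normal_mean, scale=pattern.normal_sd,
            size=count, random_state=rng,
        )
    else:  # pragma: no cover - guarded by CarelessPattern
        raise ValueError(f"unknown pattern kind {pattern.kind!r}")
    return _clamp(out)


def sample_careless_matrix(pattern: CarelessPattern, n_persons: int, n_items: int, rng) -> np.ndarray:
    """Careless responses for ``n_persons`` rows, person-level coherence kept."""
    rng = np.random.default_rng(rng)
    return np.vstack([
        sample_careless(pattern, n_items, rng) for _ in range(n_persons)
    ]) if n_persons > 0 else np.empty((0, n_items))
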