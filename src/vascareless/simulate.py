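"""Synthetic-data generator for the careless-contamination simulation design.

Attentive rows follow a unidimensional Beta IRM whose generating parameters
are drawn fresh per dataset: difficulties and traits from N(0, 1), dispersions
from U(0, 3), wording -1 for the first half of the items.  A fixed number
round(N * pi_c) of persons, chosen uniformly without replacement, is replaced
by careless rows drawn from one of the three contamination patterns.  The full
generating truth (item parameters, traits, class memberships) travels with the
response matrix so recovery and classification can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .beta_irm import ItemParams
from .careless import CLAMP, CarelessPattern, sample_careless

__all__ = ["SimulationCondition", "SimulatedDataset", "draw_generating_params", "generate_dataset"]

ATTENTIVE = "attentive"
CARELESS = "careless"


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design."""

    careless_pattern: CarelessPattern
    prop_careless: float
    seed: int
    n_persons: int = 300
    n_items: int = 10
    n_negative: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.prop_careless < 1.0):
            raise ValueError("prop_careless must lie in [0, 1)")
        if self.n_negative > self.n_items:
            raise ValueError("n_negative cannot exceed n_items")


@dataclass
class SimulatedDataset:
    """Responses plus the generating truth for one simulated dataset."""

    responses: np.ndarray             # (n_persons, n_items), open unit interval
    items: list                       # list[ItemParams]
    traits: np.ndarray                # (n_persons,) generating trait values
    membership: np.ndarray            # (n_persons,) strings: attentive/careless
    condition: SimulationCondition

    @property
    def careless_mask(self) -> np.ndarray:
        return self.membership == CARELESS

    @property
    def n_careless(self) -> int:
        return int(np.sum(self.careless_mask))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"item{j + 1}" for j in range(self.responses.shape[1])]
        df = pd.DataFrame(self.responses, columns=cols)
        df.insert(0, "person", [f"p{i + 1}" for i in range(len(df))])
        return df

    def write(self, csv_path, truth_path=None) -> None:
        """Write the response CSV plus a JSON sidecar with the truth."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        if truth_path is None:
            truth_path = csv_path.with_suffix(".truth.json")
        truth = {
            "seed": self.condition.seed,
            "pattern": self.condition.careless_pattern.kind,
            "prop_careless": self.condition.prop_careless,
            "difficulty": [it.difficulty for it in self.items],
            "dispersion": [it.dispersion for it in self.items],
            "wording": [it.wording for it in self.items],
            "traits": self.traits.tolist(),
            "membership": self.membership.tolist(),
        }
        Path(truth_path).write_text(json.dumps(truth, indent=1))


def draw_generating_params(condition: SimulationCondition, rng) -> tuple[list, np.ndarray]:
    """Draw item parameters and unidimensional traits for one dataset.

    b_j ~ N(0,1), alpha_j ~ U(0,3), theta_i ~ N(0,1); the first
    ``n_negative`` items are reverse keyed.
    """
    rng = np.random.default_rng(rng)
    b = rng.standard_normal(condition.n_items)
    alpha = rng.uniform(0.0, 3.0, size=condition.n_items)
    theta = rng.standard_normal(condition.n_persons)
    items = [
        ItemParams(
            difficulty=float(b[j]),
            dispersion=float(alpha[j]),
            wording=-1 if j < condition.n_negative else 1,
            dimension=0,
        )
        for j in range(condition.n_items)
    ]
    return items, theta


def generate_dataset(condition: SimulationCondition) -> SimulatedDataset:
    """Generate one contaminated dataset with exact careless count."""
    rng = np.random.default_rng(condition.seed)
    items, theta = draw_generating_params(condition, rng)

    n, j = condition.n_persons, condition.n_items
    eta = np.empty((n, j))
    a = np.empty((n, j))
    bshape = np.empty((n, j))
    for jj, item in enumerate(items):
        eta[:, jj] = item.wording * theta - item.difficulty
        a[:, jj] = np.exp(0.5 * (eta[:, jj] + item.dispersion))
        bshape[:, jj] = np.exp(-0.5 * (eta[:, jj] - item.dispersion))
    responses = rng.beta(a, bshape)

    n_careless = int(round(n * condition.prop_careless))
    careless_idx = rng.choice(n, size=n_careless, replace=False)
    membership = np.full(n, ATTENTIVE, dtype=object)
    membership[careless_idx] = CARELESS
    for i in careless_idx:
        responses[i] = sample_careless(condition.careless_pattern, j, rng)

    responses = np.clip(responses, CLAMP, 1.0 - CLAMP)
    return SimulatedDataset(
        responses=responses,
        items=items,
        traits=theta,
        membership=membership.astype(str),
        condition=condition,
    )
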