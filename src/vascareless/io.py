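"""File formats and run configuration.

Responses travel as CSV (first column person id, remaining columns item
ids); item metadata as CSV or JSON (item id, wording sign, dimension label);
run configuration as YAML or JSON with ``prior``, ``mcmc``, ``simulate`` and
``study`` sections.  Stored response values may sit on the closed interval
[0, 1] — slider software exports the endpoints — and are squeezed into the
open interval on load with a counted clamp rather than rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .careless import CLAMP
from .estimation import McmcSpec, PriorConfig

log = logging.getLogger("vascareless")

__all__ = [
    "ResponseTable",
    "ItemMetadata",
    "RunConfig",
    "read_responses",
    "read_item_metadata",
    "load_config",
    "write_summary",
    "write_cell_summaries",
]


@dataclass
class ResponseTable:
    person_ids: list
    item_ids: list
    values: np.ndarray                  # clamped into (0, 1)
    n_clamped: int = 0
    n_dropped_rows: int = 0

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)


@dataclass
class ItemMetadata:
    item_ids: list
    wording: np.ndarray
    dimension: np.ndarray

    def aligned_to(self, item_ids) -> "ItemMetadata":
        index = {iid: k for k, iid in enumerate(self.item_ids)}
        missing = [iid for iid in item_ids if iid not in index]
        if missing:
            raise ValueError(f"items without metadata: {missing}")
        order = [index[iid] for iid in item_ids]
        return ItemMetadata(
            item_ids=list(item_ids),
            wording=self.wording[order],
            dimension=self.dimension[order],
        )


def read_responses(path) -> ResponseTable:
    """Load a person-by-item response CSV, clamping and dropping as documented."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("response CSV needs a person-id column plus item columns")
    person_col = df.columns[0]
    item_ids = list(df.columns[1:])
    values = df[item_ids]
    non_numeric = values.map(lambda v: not (pd.isna(v) or isinstance(v, (int, float, np.number))))
    if non_numeric.any().any():
        r, c = np.argwhere(non_numeric.values)[0]
        raise ValueError(f"non-numeric response at row {r} column {item_ids[c]!r}")
    arr = values.to_numpy(dtype=float)

    all_missing = np.all(np.isnan(arr), axis=1)
    n_dropped = int(all_missing.sum())
    if n_dropped:
        log.info("dropped %d all-missing rows", n_dropped)
    arr = arr[~all_missing]
    person_ids = list(df.loc[~all_missing, person_col])

    finite = arr[np.isfinite(arr)]
    if np.any(finite < 0) or np.any(finite > 1):
        raise ValueError("responses must lie within [0, 1]")
    needs_clamp = np.isfinite(arr) & ((arr < CLAMP) | (arr > 1 - CLAMP))
    n_clamped = int(needs_clamp.sum())
    if n_clamped:
        log.info("clamped %d boundary responses into [%g, %g]", n_clamped, CLAMP, 1 - CLAMP)
    arr = np.clip(arr, CLAMP, 1 - CLAMP)
    return ResponseTable(person_ids=person_ids, item_ids=item_ids, values=arr,
                         n_clamped=n_clamped, n_dropped_rows=n_dropped)


def read_item_metadata(path) -> ItemMetadata:
    """Item metadata from CSV (columns item, wording, dimension) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        entries = json.loads(path.read_text())
        df = pd.DataFrame(entries)
    else:
        df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("item", "wording"):
        if needed not in cols:
            raise ValueError(f"item metadata missing column {needed!r}")
    wording = df[cols["wording"]].to_numpy(dtype=int)
    if not np.all(np.isin(wording, (-1, 1))):
        raise ValueError("wording entries must be -1 or +1")
    if "dimension" in cols:
        dim_labels = df[cols["dimension"]].astype(str)
        _, dimension = np.unique(dim_labels, return_inverse=True)
    else:
        dimension = np.zeros(len(df), dtype=int)
    return ItemMetadata(item_ids=list(df[cols["item"]]), wording=wording,
                        dimension=dimension.astype(int))


# ---------------------------------------------------------------------------
# configuration

_SIMULATE_DEFAULTS = {
    "n_persons": 300, "n_items": 10, "n_negative": 5,
    "pattern": "beta_extremes", "prop_careless": 0.10,
}
_STUDY_DEFAULTS = {
    "patterns": ["beta_extremes", "end_preference", "midpoint_normal"],
    "proportions": [0.05, 0.10, 0.15, 0.25, 0.40],
    "n_replications": 100,
}


@dataclass
class RunConfig:
    prior: PriorConfig
    mcmc: McmcSpec
    simulate: dict
    study: dict
    epsr_threshold: float = 1.1
    clamp: float = CLAMP


def load_config(path=None) -> RunConfig:
    """Parse YAML/JSON configuration, filling documented defaults.

    Unknown keys in any section are rejected so typos cannot silently fall
    back to defaults.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    known = {"prior", "mcmc", "simulate", "study", "epsr_threshold"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    def section(name, allowed):
        sec = raw.get(name, {}) or {}
        bad = set(sec) - set(allowed)
        if bad:
            raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
        return sec

    prior = PriorConfig(**section("prior", PriorConfig.__dataclass_fields__))
    mcmc = McmcSpec(**section("mcmc", McmcSpec.__dataclass_fields__))
    if mcmc.chains < 2:
        raise ValueError("EPSR convergence checking requires at least 2 chains")
    simulate = {**_SIMULATE_DEFAULTS, **section("simulate", _SIMULATE_DEFAULTS)}
    study = {**_STUDY_DEFAULTS, **section("study", _STUDY_DEFAULTS)}
    return RunConfig(prior=prior, mcmc=mcmc, simulate=simulate, study=study,
                     epsr_threshold=float(raw.get("epsr_threshold", 1.1)))


# ---------------------------------------------------------------------------
# output

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_summary(result, path, seeds=None, config_echo=None) -> None:
    """JSON summary of one fit: point estimates, 95% CIs, EPSR, convergence."""
    payload = {
        "schema": "vascareless/fit-summary/1",
        "point": _jsonable(result.point),
        "ci95": _jsonable(result.ci95),
        "epsr": _jsonable(result.epsr),
        "converged": bool(result.converged),
        "mcmc": {"chains": result.spec.chains, "iterations": result.spec.iterations,
                 "burn_in": result.spec.burn_in, "thin": result.spec.thin,
                 "seed": result.spec.seed},
        "seeds": _jsonable(seeds),
        "config": _jsonable(config_echo),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_cell_summaries(summaries, out_dir) -> dict:
    """One CSV per table analogue: classification (both rules) and estimation."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows_thr, rows_prop, rows_est, rows_care = [], [], [], []
    for s in summaries:
        base = {"pattern": s.pattern, "prop_careless": s.prop_careless,
                "n_replications": s.n_replications,
                "convergence_rate": s.convergence_rate}
        rows_thr.append({**base, **s.threshold_metrics})
        rows_prop.append({**base, **s.proportion_metrics})
        rows_est.append({**base, **s.estimation})
        rows_care.append({**base,
                          "careless_prop_estimate_mean": s.careless_prop_estimate_mean,
                          "careless_prop_relative_bias": s.careless_prop_relative_bias})
    paths = {}
    for name, rows in (("classification_threshold", rows_thr),
                       ("classification_proportion", rows_prop),
                       ("estimation", rows_est),
                       ("careless_distribution", rows_care)):
        p = out_dir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths[name] = p
    return paths
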