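"""Configuration files, batch export and deterministic test fixtures.

Configs are YAML with two blocks::

    design:
      n_arms: 5
      m1: 28
      m2: 140
      futility_threshold: 0.0
      sigma: 5.0
      alpha: 0.025
    scenario:            # optional
      kind: permutation  # single | permutation | ordered
      gammas: [0.75, 0.8125, 0.875, 0.9375]
      delta: 2.0

Fixture files are plain CSV (one row per replicate: stage-1 estimates,
selected arm, continuation flag, stage-2 estimate) with a JSON sidecar
echoing the design, effect vector and seed, so every fixture is
reproducible from its sidecar alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import Design, ScenarioFamily, make_scenario
from .simulate import TrialBatch, simulate_batch

__all__ = [
    "load_config",
    "design_from_dict",
    "scenario_from_dict",
    "batch_to_frame",
    "write_fixtures",
    "read_fixture_batch",
]


def design_from_dict(block: dict) -> Design:
    return Design(
        n_arms=int(block["n_arms"]),
        m1=float(block["m1"]),
        m2=float(block["m2"]),
        futility_threshold=float(block.get("futility_threshold", 0.0)),
        sigma=float(block.get("sigma", 1.0)),
        alpha=float(block.get("alpha", 0.025)),
    )


def scenario_from_dict(block: dict, n_arms: int) -> ScenarioFamily:
    return make_scenario(
        n_arms=n_arms,
        gammas=block["gammas"],
        delta=float(block["delta"]),
        kind=block.get("kind", "permutation"),
    )


def load_config(path) -> tuple[Design, ScenarioFamily | None]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    design = design_from_dict(cfg["design"])
    scenario = None
    if "scenario" in cfg and cfg["scenario"]:
        scenario = scenario_from_dict(cfg["scenario"], design.n_arms)
    return design, scenario


def batch_to_frame(batch: TrialBatch) -> pd.DataFrame:
    K = batch.design.n_arms
    data = {f"theta_hat1_{i + 1}": batch.theta_hat1[:, i] for i in range(K)}
    data["selected"] = batch.selected
    data["continued"] = batch.continued.astype(int)
    data["theta_hat2"] = batch.theta_hat2
    return pd.DataFrame(data)


def write_fixtures(
    design: Design,
    theta,
    n: int,
    seed: int,
    path,
) -> tuple[Path, Path]:
    """Write ``n`` deterministic simulated trials to ``<path>.csv`` with a
    ``<path>.json`` sidecar; identical arguments give identical bytes."""
    if n < 1:
        raise ValueError("fixture count must be >= 1")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    batch = simulate_batch(design, np.asarray(theta, dtype=float), n, seed)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    batch_to_frame(batch).to_csv(csv_path, index=False, float_format="%.12g")
    sidecar = {
        "design": {
            "n_arms": design.n_arms,
            "m1": design.m1,
            "m2": design.m2,
            "futility_threshold": design.futility_threshold,
            "sigma": design.sigma,
            "alpha": design.alpha,
        },
        "theta": list(np.asarray(theta, dtype=float)),
        "replications": n,
        "seed": seed,
    }
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return csv_path, json_path


def read_fixture_batch(csv_path) -> TrialBatch:
    """Rebuild a TrialBatch from a fixture CSV + JSON sidecar pair."""
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    design = design_from_dict(sidecar["design"])
    frame = pd.read_csv(csv_path)
    K = design.n_arms
    theta_hat1 = frame[[f"theta_hat1_{i + 1}" for i in range(K)]].to_numpy()
    return TrialBatch(
        design=design,
        theta=np.asarray(sidecar["theta"], dtype=float),
        theta_hat1=theta_hat1,
        selected=frame["selected"].to_numpy(dtype=int),
        continued=frame["continued"].to_numpy(dtype=bool),
        theta_hat2=frame["theta_hat2"].to_numpy(dtype=float),
    )
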