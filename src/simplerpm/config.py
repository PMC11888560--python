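"""Run configuration, provenance records, and the human-comparison helper."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import __version__

__all__ = ["RunConfig", "load_config", "write_provenance", "compare_human"]


@dataclass
class RunConfig:
    """Knobs shared by the CLI subcommands."""

    seed: int = 0
    out_dir: str = "runs"
    n_train: int = 10_000
    n_val: int = 1_000
    n_test: int = 1_000
    n_splits: int = 15
    n_trials_per_pair: int = 500
    projection_dim: int | None = 400
    rules: list[int] | None = None
    objective: str = "ce"
    epochs: int = 10

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus CLI overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def write_provenance(out_dir: str | Path, config: RunConfig, artifact: str) -> Path:
    """Record config hash, seed and package version next to an artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = config.to_dict()
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
    record = {
        "artifact": artifact,
        "config": payload,
        "config_sha256": digest,
        "seed": config.seed,
        "version": __version__,
    }
    path = out / f"{artifact}.provenance.json"
    path.write_text(json.dumps(record, indent=2))
    return path


def compare_human(
    model_errors: pd.DataFrame | dict,
    human_table: pd.DataFrame | str | Path,
) -> dict[str, float]:
    """Rank-correlate model per-pair errors with human error and response time.

    ``model_errors`` maps rule-pair labels to model error (dict or a
    DataFrame with ``pair``/``error`` columns); ``human_table`` is a CSV or
    DataFrame with columns ``pair``, ``human_error`` and optionally
    ``response_time``. Returns Spearman rho and p for each comparison.
    Requires at least 3 matched pairs; unmatched labels are an error.
    """
    if isinstance(model_errors, dict):
        model = pd.DataFrame({"pair": list(model_errors), "error": list(model_errors.values())})
    else:
        model = model_errors[["pair", "error"]].copy()
    if not isinstance(human_table, pd.DataFrame):
        human_table = pd.read_csv(human_table)
    missing = set(model["pair"]) ^ set(human_table["pair"])
    if missing:
        raise ValueError(f"rule-pair labels do not match: {sorted(missing)}")
    merged = model.merge(human_table, on="pair")
    if len(merged) < 3:
        raise ValueError("need at least 3 matched rule pairs")
    out: dict[str, float] = {}
    rho, p = spearmanr(merged["error"], merged["human_error"])
    out["rho_error"], out["p_error"] = float(rho), float(p)
    if "response_time" in merged:
        rho, p = spearmanr(merged["error"], merged["response_time"])
        out["rho_rt"], out["p_rt"] = float(rho), float(p)
    return out
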