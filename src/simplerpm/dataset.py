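"""Balanced per-rule row collections and held-out rule splits.

The dataset is organized per rule with train/validation/test partitions
(defaults 10,000 / 1,000 / 1,000 rows per rule). Rows are globally unique:
two rows are duplicates when their canonical forms (panels as sorted object
tuples, object order being display-irrelevant) coincide. A held-out split
removes 5 of the 40 rules from training such that each abstract relation
appears at most once among the held-out rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .render import render_row
from .rules import (
    ATTRIBUTES,
    RELATIONS,
    RelationalRule,
    RowSpec,
    RuleSamplingError,
    enumerate_rules,
    rule_by_id,
    sample_row_spec,
)

__all__ = [
    "DatasetConfig",
    "SplitSpec",
    "RuleDataset",
    "build_dataset",
    "sample_splits",
    "ordered_heldout_pairs",
]

PARTITIONS = ("train", "val", "test")


@dataclass(frozen=True)
class DatasetConfig:
    """Row counts per rule and generation seed."""

    n_train: int = 10_000
    n_val: int = 1_000
    n_test: int = 1_000
    seed: int = 0
    rules: tuple[int, ...] = tuple(r.rule_id for r in enumerate_rules())
    max_attempts_per_row: int = 10_000

    @property
    def counts(self) -> dict[str, int]:
        return {"train": self.n_train, "val": self.n_val, "test": self.n_test}


@dataclass(frozen=True)
class SplitSpec:
    """35 training rules vs 5 held-out rules, relations distinct among held-out."""

    train_rules: tuple[int, ...]
    heldout_rules: tuple[int, ...]
    split_seed: int = 0

    def __post_init__(self) -> None:
        train, held = set(self.train_rules), set(self.heldout_rules)
        if train & held:
            raise ValueError("train and held-out rules overlap")
        if train | held != {r.rule_id for r in enumerate_rules()}:
            raise ValueError("split must cover all 40 rules")
        relations = [rule_by_id(r).relation for r in self.heldout_rules]
        if len(set(relations)) != len(relations):
            raise ValueError("each relation may appear at most once among held-out rules")

    def to_dict(self) -> dict:
        return {
            "train_rules": list(self.train_rules),
            "heldout_rules": list(self.heldout_rules),
            "split_seed": self.split_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitSpec":
        return cls(tuple(d["train_rules"]), tuple(d["heldout_rules"]), d.get("split_seed", 0))


def ordered_heldout_pairs(split: SplitSpec) -> list[tuple[int, int]]:
    """All ordered pairs (a, b), a != b, of the held-out rules (20 per split)."""
    held = split.heldout_rules
    return [(a, b) for a in held for b in held if a != b]


class RuleDataset:
    """In-memory dataset: rule_id -> partition -> list of RowSpec."""

    def __init__(self, config: DatasetConfig):
        self.config = config
        self.rows: dict[int, dict[str, list[RowSpec]]] = {}

    def partition(self, rule_id: int, part: str) -> list[RowSpec]:
        return self.rows[rule_id][part]

    def all_rows(self):
        for rule_id, parts in self.rows.items():
            for part, rows in parts.items():
                for row in rows:
                    yield rule_id, part, row

    # -- manifest / persistence --------------------------------------------

    def manifest(self) -> pd.DataFrame:
        records = [
            {"row_uid": row.seed_info, "rule_id": rule_id, "partition": part}
            for rule_id, part, row in self.all_rows()
        ]
        return pd.DataFrame.from_records(records)

    def save(self, out_dir: str | Path, render: bool = False) -> Path:
        """Write row specs as JSON, the manifest as CSV, optionally NPZ pixels."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spec_payload = {
            str(rule_id): {
                part: [row.to_dict() for row in rows]
                for part, rows in parts.items()
            }
            for rule_id, parts in self.rows.items()
        }
        (out / "rows.json").write_text(json.dumps(spec_payload))
        (out / "config.json").write_text(
            json.dumps(
                {
                    "n_train": self.config.n_train,
                    "n_val": self.config.n_val,
                    "n_test": self.config.n_test,
                    "seed": self.config.seed,
                    "rules": list(self.config.rules),
                }
            )
        )
        self.manifest().to_csv(out / "manifest.csv", index=False)
        if render:
            for rule_id, parts in self.rows.items():
                arrays = {
                    part: np.stack([render_row(r) for r in rows])
                    for part, rows in parts.items()
                    if rows
                }
                np.savez_compressed(out / f"rule{rule_id:02d}.npz", **arrays)
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "RuleDataset":
        out = Path(in_dir)
        cfg = json.loads((out / "config.json").read_text())
        config = DatasetConfig(
            n_train=cfg["n_train"], n_val=cfg["n_val"], n_test=cfg["n_test"],
            seed=cfg["seed"], rules=tuple(cfg["rules"]),
        )
        ds = cls(config)
        payload = json.loads((out / "rows.json").read_text())
        for rule_id, parts in payload.items():
            ds.rows[int(rule_id)] = {
                part: [RowSpec.from_dict(d) for d in rows]
                for part, rows in parts.items()
            }
        return ds


def build_dataset(config: DatasetConfig | None = None, rng: np.random.Generator | None = None) -> RuleDataset:
    """Generate unique, exclusively-conforming rows for every configured rule.

    Canonical-form hashing detects duplicates (within and across partitions);
    duplicates are resampled. Deterministic given ``config.seed`` (an explicit
    ``rng`` overrides the seed).
    """
    config = config or DatasetConfig()
    rng = rng or np.random.default_rng(config.seed)
    ds = RuleDataset(config)
    seen: set = set()

    for rule_id in config.rules:
        rule = rule_by_id(rule_id)
        parts: dict[str, list[RowSpec]] = {p: [] for p in PARTITIONS}
        for part in PARTITIONS:
            target = config.counts[part]
            n_built = 0
            duplicate_streak = 0
            while n_built < target:
                row = sample_row_spec(rule, rng, max_attempts=config.max_attempts_per_row)
                key = (row.canonical())
                if key in seen:
                    duplicate_streak += 1
                    if duplicate_streak > config.max_attempts_per_row:
                        achieved = sum(len(v) for v in parts.values())
                        raise RuleSamplingError(
                            f"rule {rule.name!r}: only {achieved} distinct rows "
                            f"achievable at the requested counts"
                        )
                    continue
                duplicate_streak = 0
                seen.add(key)
                uid = f"r{rule_id:02d}-{part}-{n_built:06d}"
                parts[part].append(RowSpec(panels=row.panels, rule=row.rule, seed_info=uid))
                n_built += 1
        ds.rows[rule_id] = parts
    return ds


def sample_splits(n_splits: int, rng: np.random.Generator | int = 0) -> list[SplitSpec]:
    """Sample distinct held-out splits (5 rules, relations pairwise distinct)."""
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    all_ids = [r.rule_id for r in enumerate_rules()]
    splits: list[SplitSpec] = []
    seen: set[frozenset] = set()
    while len(splits) < n_splits:
        held = rng.choice(all_ids, size=5, replace=False)
        relations = {rule_by_id(int(r)).relation for r in held}
        if len(relations) != 5:
            continue
        key = frozenset(int(r) for r in held)
        if key in seen:
            continue
        seen.add(key)
        held_t = tuple(sorted(int(r) for r in held))
        train_t = tuple(r for r in all_ids if r not in key)
        splits.append(SplitSpec(train_t, held_t, split_seed=len(splits)))
    return splits
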