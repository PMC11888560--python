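"""Relational rule space: 40 (relation, attribute) rules over three-panel rows.

A row is three panels of objects on a 3x3 grid. Each object has four
attributes: position (grid cell), shape (7 ordinal forms), size (10 ordinal
bounding-box heights) and shade (10 ordinal grayscale levels). A relational
rule pairs an abstract relation with a governed attribute; ``number`` and
``position`` are merged into a single attribute so that, e.g., a constant
position pattern does not silently impose a second (constant number) rule.

Relation semantics on the governed attribute:

* shape / size / shade
    - constant, progression(+-1, +-2) and arithmetic relations require every
      object within a panel to share the governed value and act on its
      ordinal index (1-based for arithmetic, so ``addition`` means
      ``value3 = value1 + value2`` on 1-based indices);
    - logical relations (AND/OR/XOR) act on the *set of distinct values*
      present in each panel: ``set3 = op(set1, set2)``.
* number/position
    - constant, progressions and arithmetic act on the object *count*;
    - logical relations act on the *set of occupied cells*.

Logical relations additionally require panels 1 and 2 to contain at least two
distinct values and the result set to be non-empty, so the relation is
actually evidenced by the row; without this requirement any constant row
would vacuously satisfy AND and OR and no row could satisfy exactly one rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ATTRIBUTES",
    "RELATIONS",
    "RELATION_CATEGORIES",
    "SHAPE_NAMES",
    "SIZE_HEIGHTS",
    "SHADE_LEVELS",
    "NUMBER_VALUES",
    "POSITION_CENTROIDS",
    "N_CELLS",
    "RelationalRule",
    "ObjectSpec",
    "RowSpec",
    "RuleSamplingError",
    "enumerate_rules",
    "rule_by_id",
    "rule_by_name",
    "rules_table",
    "satisfies",
    "satisfied_rules",
    "sample_row_spec",
]

# ---------------------------------------------------------------------------
# attribute specification (cardinalities 7 / 10 / 10 / 9 / 9)

SHAPE_NAMES: tuple[str, ...] = (
    "circle", "triangle", "square", "pentagon", "hexagon", "octagon", "star",
)

#: bounding-box heights in pixels, 20..40 in ten evenly spaced increments
SIZE_HEIGHTS: np.ndarray = np.linspace(20.0, 40.0, 10)

#: grayscale levels from 230 (close to white) down to 0 (black), ten steps
SHADE_LEVELS: np.ndarray = np.rint(np.linspace(230.0, 0.0, 10)).astype(np.uint8)

#: object counts per panel
NUMBER_VALUES: tuple[int, ...] = tuple(range(1, 10))

#: centroid (x, y) of each of the nine grid cells in a 160x160 panel
POSITION_CENTROIDS: tuple[tuple[int, int], ...] = (
    (20, 20), (20, 60), (20, 100),
    (60, 20), (60, 60), (60, 100),
    (100, 20), (100, 60), (100, 100),
)

N_CELLS = 9

N_SHAPES = len(SHAPE_NAMES)
N_SIZES = len(SIZE_HEIGHTS)
N_SHADES = len(SHADE_LEVELS)

_ORDINAL_CARD = {"shape": N_SHAPES, "size": N_SIZES, "shade": N_SHADES}

# ---------------------------------------------------------------------------
# rules

#: abstract relations in the order they are defined (progression family,
#: arithmetic family, logical family)
RELATIONS: tuple[str, ...] = (
    "constant",
    "progression+2", "progression-2", "progression+1", "progression-1",
    "addition", "subtraction",
    "AND", "OR", "XOR",
)

ATTRIBUTES: tuple[str, ...] = ("shape", "size", "shade", "number/position")

RELATION_CATEGORIES: dict[str, str] = {
    "constant": "progression",
    "progression+2": "progression",
    "progression-2": "progression",
    "progression+1": "progression",
    "progression-1": "progression",
    "addition": "arithmetic",
    "subtraction": "arithmetic",
    "AND": "logical",
    "OR": "logical",
    "XOR": "logical",
}

_PROG_STEP = {
    "progression+2": 2, "progression-2": -2,
    "progression+1": 1, "progression-1": -1,
}

_LOGICAL_OPS = {
    "AND": lambda s1, s2: s1 & s2,
    "OR": lambda s1, s2: s1 | s2,
    "XOR": lambda s1, s2: s1 ^ s2,
}


@dataclass(frozen=True, order=True)
class RelationalRule:
    """One of the 40 (relation, attribute) rules."""

    relation: str
    attribute: str

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.attribute not in ATTRIBUTES:
            raise ValueError(f"unknown attribute {self.attribute!r}")

    @property
    def category(self) -> str:
        return RELATION_CATEGORIES[self.relation]

    @property
    def rule_id(self) -> int:
        return RELATIONS.index(self.relation) * len(ATTRIBUTES) + ATTRIBUTES.index(
            self.attribute
        )

    @property
    def name(self) -> str:
        return f"{self.relation} {self.attribute}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def enumerate_rules() -> list[RelationalRule]:
    """All 40 rules in a fixed order (relation-major, then attribute)."""
    return [RelationalRule(rel, att) for rel in RELATIONS for att in ATTRIBUTES]


def rule_by_id(rule_id: int) -> RelationalRule:
    rules = enumerate_rules()
    if not 0 <= rule_id < len(rules):
        raise ValueError(f"rule_id {rule_id} outside 0..{len(rules) - 1}")
    return rules[rule_id]


def rule_by_name(name: str) -> RelationalRule:
    """Parse ``"<relation> <attribute>"`` (as produced by ``RelationalRule.name``)."""
    relation, _, attribute = name.partition(" ")
    return RelationalRule(relation, attribute)


def rules_table() -> pd.DataFrame:
    """Rule table (rule_id, relation, attribute, category), exportable as CSV."""
    rules = enumerate_rules()
    return pd.DataFrame(
        {
            "rule_id": [r.rule_id for r in rules],
            "relation": [r.relation for r in rules],
            "attribute": [r.attribute for r in rules],
            "category": [r.category for r in rules],
        }
    )


# ---------------------------------------------------------------------------
# row specifications


@dataclass(frozen=True, order=True)
class ObjectSpec:
    """A single object: grid cell plus shape/size/shade indices."""

    position: int
    shape: int
    size: int
    shade: int

    def __post_init__(self) -> None:
        if not 0 <= self.position < N_CELLS:
            raise ValueError(f"position {self.position} outside 0..8")
        if not 0 <= self.shape < N_SHAPES:
            raise ValueError(f"shape index {self.shape} outside 0..6")
        if not 0 <= self.size < N_SIZES:
            raise ValueError(f"size index {self.size} outside 0..9")
        if not 0 <= self.shade < N_SHADES:
            raise ValueError(f"shade index {self.shade} outside 0..9")


@dataclass(frozen=True)
class RowSpec:
    """Three panels of objects governed by a single relational rule."""

    panels: tuple[tuple[ObjectSpec, ...], ...]
    rule: RelationalRule
    seed_info: str = ""

    def __post_init__(self) -> None:
        if len(self.panels) != 3:
            raise ValueError("a row has exactly 3 panels")
        for panel in self.panels:
            if not 1 <= len(panel) <= 9:
                raise ValueError("each panel holds 1..9 objects")
            positions = [o.position for o in panel]
            if len(set(positions)) != len(positions):
                raise ValueError("at most one object per cell within a panel")

    def canonical(self) -> tuple:
        """Order-independent panel content; used for uniqueness hashing."""
        return tuple(tuple(sorted(panel)) for panel in self.panels)

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rule": self.rule.name,
            "seed_info": self.seed_info,
            "panels": [
                [[o.position, o.shape, o.size, o.shade] for o in panel]
                for panel in self.panels
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "RowSpec":
        panels = tuple(
            tuple(ObjectSpec(*obj) for obj in panel) for panel in d["panels"]
        )
        return cls(panels=panels, rule=rule_by_name(d["rule"]), seed_info=d.get("seed_info", ""))

    @classmethod
    def from_json(cls, s: str) -> "RowSpec":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# satisfaction predicate


def _panel_uniform_value(panel: Sequence[ObjectSpec], attribute: str) -> int | None:
    """Shared governed value of a panel, or None if objects disagree."""
    values = {getattr(o, attribute) for o in panel}
    return values.pop() if len(values) == 1 else None


def _panel_value_set(panel: Sequence[ObjectSpec], attribute: str) -> frozenset[int]:
    return frozenset(getattr(o, attribute) for o in panel)


def _ordinal_triplet_ok(relation: str, v: Sequence[int], card: int, one_based: bool) -> bool:
    v1, v2, v3 = v
    if relation == "constant":
        return v1 == v2 == v3
    if relation in _PROG_STEP:
        k = _PROG_STEP[relation]
        return v2 - v1 == k and v3 - v2 == k
    offset = 1 if one_based else 0
    a, b, c = v1 + offset, v2 + offset, v3 + offset
    if relation == "addition":
        return a + b == c
    if relation == "subtraction":
        return a - b == c
    raise ValueError(f"relation {relation} is not ordinal")


def satisfies(row: RowSpec, rule: RelationalRule) -> bool:
    """Pure predicate: does ``row`` conform to ``rule``?"""
    relation, attribute = rule.relation, rule.attribute
    logical = relation in _LOGICAL_OPS

    if attribute == "number/position":
        if logical:
            sets = [_panel_value_set(p, "position") for p in row.panels]
        else:
            counts = [len(p) for p in row.panels]
            return _ordinal_triplet_ok(relation, counts, card=9, one_based=False)
    else:
        if logical:
            sets = [_panel_value_set(p, attribute) for p in row.panels]
        else:
            values = [_panel_uniform_value(p, attribute) for p in row.panels]
            if any(v is None for v in values):
                return False
            return _ordinal_triplet_ok(
                relation, values, card=_ORDINAL_CARD[attribute], one_based=True
            )

    # logical relations must be evidenced: two distinct values in the operand
    # panels and a non-empty result
    s1, s2, s3 = sets
    if len(s1) < 2 or len(s2) < 2:
        return False
    result = _LOGICAL_OPS[relation](s1, s2)
    return len(result) >= 1 and s3 == result


def satisfied_rules(row: RowSpec) -> list[RelationalRule]:
    """All rules (of the 40) that the row conforms to."""
    return [r for r in enumerate_rules() if satisfies(row, r)]


# ---------------------------------------------------------------------------
# rejection sampling of rows


class RuleSamplingError(RuntimeError):
    """Raised when no exclusively-conforming row is found within the budget."""


def _sample_ordinal_triplet(relation: str, card: int, one_based: bool, rng) -> tuple[int, int, int]:
    """Sample (v1, v2, v3) of 0-based ordinals obeying an ordinal relation.

    Arithmetic operand pairs are drawn only from in-range results, which
    guarantees termination.
    """
    lo, hi = 0, card - 1
    if relation == "constant":
        v = int(rng.integers(lo, hi + 1))
        return v, v, v
    if relation in _PROG_STEP:
        k = _PROG_STEP[relation]
        if k > 0:
            v1 = int(rng.integers(lo, hi - 2 * k + 1))
        else:
            v1 = int(rng.integers(lo - 2 * k, hi + 1))
        return v1, v1 + k, v1 + 2 * k
    offset = 1 if one_based else 0
    top = card - 1 + offset  # largest 1-based (or raw) value
    if relation == "addition":
        a = int(rng.integers(1, top))          # 1..top-1
        b = int(rng.integers(1, top - a + 1))  # a+b <= top
        c = a + b
    elif relation == "subtraction":
        a = int(rng.integers(2, top + 1))      # 2..top
        b = int(rng.integers(1, a))            # 1..a-1
        c = a - b
    else:  # pragma: no cover - guarded by callers
        raise ValueError(relation)
    return a - offset, b - offset, c - offset


def _sample_value_sets(relation: str, card: int, max_panel: int, rng) -> tuple[frozenset, frozenset, frozenset]:
    """Sample (S1, S2, S3 = op(S1, S2)) with |S1|,|S2| >= 2 and S3 evidenced."""
    op = _LOGICAL_OPS[relation]
    universe = np.arange(card)
    while True:
        n1 = int(rng.integers(2, min(card, max_panel) + 1))
        n2 = int(rng.integers(2, min(card, max_panel) + 1))
        s1 = frozenset(int(x) for x in rng.choice(universe, size=n1, replace=False))
        s2 = frozenset(int(x) for x in rng.choice(universe, size=n2, replace=False))
        s3 = op(s1, s2)
        if 1 <= len(s3) <= max_panel:
            return s1, s2, s3


def _random_positions(n: int, rng) -> list[int]:
    return [int(p) for p in rng.choice(N_CELLS, size=n, replace=False)]


def _random_object(position: int, rng, **fixed: int) -> ObjectSpec:
    return ObjectSpec(
        position=position,
        shape=fixed.get("shape", int(rng.integers(N_SHAPES))),
        size=fixed.get("size", int(rng.integers(N_SIZES))),
        shade=fixed.get("shade", int(rng.integers(N_SHADES))),
    )


def _panel_from_value_multiset(attribute: str, values: Sequence[int], rng) -> tuple[ObjectSpec, ...]:
    positions = _random_positions(len(values), rng)
    return tuple(
        _random_object(pos, rng, **{attribute: val})
        for pos, val in zip(positions, values)
    )


def _propose(rule: RelationalRule, rng) -> RowSpec:
    """One candidate row obeying ``rule`` (other rules not yet excluded)."""
    relation, attribute = rule.relation, rule.attribute
    logical = relation in _LOGICAL_OPS
    panels: list[tuple[ObjectSpec, ...]] = []

    if attribute == "number/position":
        if logical:
            sets = _sample_value_sets(relation, N_CELLS, max_panel=9, rng=rng)
            for s in sets:
                panels.append(tuple(_random_object(pos, rng) for pos in sorted(s)))
        else:
            # counts live on 1..9; the one_based sampler yields 0-based values
            # whose 1-based shifts obey the relation
            triplet = _sample_ordinal_triplet(relation, card=9, one_based=True, rng=rng)
            for n in (v + 1 for v in triplet):
                positions = _random_positions(n, rng)
                panels.append(tuple(_random_object(pos, rng) for pos in positions))
    else:
        if logical:
            sets = _sample_value_sets(relation, _ORDINAL_CARD[attribute], max_panel=9, rng=rng)
            for s in sets:
                values = list(s)
                n_extra = int(rng.integers(0, 9 - len(values) + 1))
                if n_extra:
                    values += [int(v) for v in rng.choice(sorted(s), size=n_extra)]
                panels.append(_panel_from_value_multiset(attribute, values, rng))
        else:
            triplet = _sample_ordinal_triplet(
                relation, card=_ORDINAL_CARD[attribute], one_based=True, rng=rng
            )
            for v in triplet:
                n = int(rng.integers(1, 10))
                panels.append(_panel_from_value_multiset(attribute, [v] * n, rng))

    return RowSpec(panels=tuple(panels), rule=rule)


def sample_row_spec(
    rule: RelationalRule,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
    seed_info: str = "",
) -> RowSpec:
    """Sample a row satisfying ``rule`` and none of the other 39 rules.

    Candidate rows conforming to the designated rule are drawn and rejected
    while they incidentally conform to any unintended rule. Deterministic
    given the generator state.
    """
    others = [r for r in enumerate_rules() if r != rule]
    for _ in range(max_attempts):
        row = _propose(rule, rng)
        if not satisfies(row, rule):  # pragma: no cover - sampler guarantee
            continue
        if any(satisfies(row, other) for other in others):
            continue
        if seed_info:
            row = RowSpec(panels=row.panels, rule=row.rule, seed_info=seed_info)
        return row
    raise RuleSamplingError(
        f"no exclusively-conforming row for rule {rule.name!r} "
        f"within {max_attempts} attempts; the rule may be over-constrained"
    )
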