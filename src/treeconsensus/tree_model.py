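"""Core domain model: criteria, scenarios, decision trees and decision tables.

A *criterion* is a named categorical decision axis with an ordered set of
levels.  A *scenario* assigns one level to every criterion of a governing
:class:`CriteriaSet`; the full Cartesian product of levels is the *scenario
space*.  A participant's algorithm is a :class:`DecisionTree` whose internal
nodes test criteria via level-subset branches and whose leaves carry
:class:`RecommendationSet` payloads; its flat equivalent is a
:class:`DecisionTable` mapping every scenario to a recommendation set.

Level order within a criterion is entry order and is used purely for
deterministic output; no ordinal semantics are attached anywhere.
"""

from __future__ import annotations

import datetime
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Union

__all__ = [
    "KIND_CATEGORICAL",
    "KIND_CUTOFF",
    "MULT_SINGLE",
    "MULT_ALTERNATIVES",
    "MULT_RANKED",
    "ModelError",
    "EvaluationError",
    "MissingBranchError",
    "AmbiguousBranchError",
    "UnknownCriterionError",
    "Criterion",
    "CriteriaSet",
    "Scenario",
    "Recommendation",
    "RecommendationSet",
    "Leaf",
    "Branch",
    "Internal",
    "Node",
    "DecisionTree",
    "DecisionTable",
    "evaluate",
    "scenario_space",
    "depends_on",
]

KIND_CATEGORICAL = "categorical"
KIND_CUTOFF = "derived-from-cutoff"

MULT_SINGLE = "single"
MULT_ALTERNATIVES = "equivalent-alternatives"
MULT_RANKED = "ranked"


class ModelError(Exception):
    """Base class for domain-model errors."""


class EvaluationError(ModelError):
    """Raised when a tree cannot route a scenario to a unique leaf."""

    def __init__(self, message: str, scenario: "Scenario | None" = None):
        super().__init__(message)
        self.scenario = scenario


class MissingBranchError(EvaluationError):
    """No branch at an internal node matches the scenario's level."""


class AmbiguousBranchError(EvaluationError):
    """More than one branch matches (branch subsets overlap)."""


class UnknownCriterionError(EvaluationError):
    """A node tests a criterion the scenario does not assign."""


def _norm_label(label: str) -> str:
    # case-sensitive comparison after whitespace normalization
    return " ".join(str(label).split())


@dataclass(frozen=True)
class Criterion:
    """A named categorical decision axis with ordered, distinct levels."""

    name: str
    levels: tuple[str, ...]
    description: str = ""
    kind: str = KIND_CATEGORICAL
    source_scale: str | None = None
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ModelError("criterion name must be nonempty")
        levels = tuple(str(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise ModelError(f"criterion {self.name!r} needs >= 2 levels, got {levels!r}")
        if len(set(levels)) != len(levels):
            raise ModelError(f"criterion {self.name!r} has duplicate levels: {levels!r}")
        if self.kind not in (KIND_CATEGORICAL, KIND_CUTOFF):
            raise ModelError(f"criterion {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == KIND_CUTOFF and (self.source_scale is None or self.cutoff is None):
            raise ModelError(
                f"criterion {self.name!r}: kind {KIND_CUTOFF!r} requires source_scale and cutoff"
            )

    def level_index(self, level: str) -> int:
        return self.levels.index(level)


class CriteriaSet:
    """An immutable collection of uniquely named criteria.

    Iteration and :attr:`names` are sorted lexicographically by criterion
    name, which fixes the scenario-space ordering.
    """

    __slots__ = ("_by_name",)

    def __init__(self, criteria: Iterable[Criterion]):
        by_name: dict[str, Criterion] = {}
        for c in criteria:
            if c.name in by_name:
                raise ModelError(f"duplicate criterion name {c.name!r}")
            by_name[c.name] = c
        self._by_name = {name: by_name[name] for name in sorted(by_name)}

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._by_name)

    def __iter__(self) -> Iterator[Criterion]:
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, name: object) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Criterion:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown criterion {name!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CriteriaSet):
            return NotImplemented
        return self._by_name == other._by_name

    def __hash__(self) -> int:
        return hash(tuple(self._by_name.values()))

    def __repr__(self) -> str:
        return f"CriteriaSet({list(self._by_name.values())!r})"

    def without(self, name: str) -> "CriteriaSet":
        if name not in self._by_name:
            raise KeyError(f"unknown criterion {name!r}")
        return CriteriaSet(c for c in self if c.name != name)

    def n_scenarios(self) -> int:
        n = 1
        for c in self:
            n *= len(c.levels)
        return n


@dataclass(frozen=True, order=True)
class Scenario:
    """One cell of the Cartesian product: a total level assignment.

    Stored as a tuple of ``(criterion name, level)`` pairs sorted by name,
    so scenarios are hashable and order deterministically.
    """

    items: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        items = tuple((str(k), str(v)) for k, v in self.items)
        if tuple(sorted(items)) != items or len({k for k, _ in items}) != len(items):
            items = tuple(sorted(dict(items).items()))
        object.__setattr__(self, "items", items)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "Scenario":
        return cls(tuple(sorted((str(k), str(v)) for k, v in mapping.items())))

    def as_dict(self) -> dict[str, str]:
        return dict(self.items)

    def __getitem__(self, name: str) -> str:
        for k, v in self.items:
            if k == name:
                return v
        raise KeyError(f"scenario does not assign criterion {name!r}")

    def get(self, name: str, default: str | None = None) -> str | None:
        for k, v in self.items:
            if k == name:
                return v
        return default

    def __contains__(self, name: object) -> bool:
        return any(k == name for k, _ in self.items)

    @property
    def criteria_names(self) -> tuple[str, ...]:
        return tuple(k for k, _ in self.items)

    def without(self, name: str) -> "Scenario":
        return Scenario(tuple(p for p in self.items if p[0] != name))

    def with_value(self, name: str, level: str) -> "Scenario":
        d = self.as_dict()
        d[name] = level
        return Scenario.from_mapping(d)

    def __str__(self) -> str:
        return ", ".join(f"{k}={v}" for k, v in self.items)


@dataclass(frozen=True)
class Recommendation:
    """A single treatment option, identified by a normalized label."""

    label: str
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        label = _norm_label(self.label)
        if not label:
            raise ModelError("recommendation label must be nonempty")
        object.__setattr__(self, "label", label)
        object.__setattr__(
            self, "attributes", tuple(sorted((str(k), str(v)) for k, v in self.attributes))
        )


@dataclass(frozen=True)
class RecommendationSet:
    """A nonempty set of recommendations with a declared multiplicity.

    The multiplicity-consistency invariant (``|members| == 1`` iff
    ``single``; a ``ranked`` set carries a total ranking) is deliberately
    NOT enforced at construction time: draft input routinely violates it
    and the validation layer must be able to observe the violation.  Use
    :attr:`is_consistent` to test it.
    """

    members: tuple[Recommendation, ...]
    multiplicity: str = MULT_SINGLE
    ranking: tuple[str, ...] | None = None
    note: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        members = tuple(
            m if isinstance(m, Recommendation) else Recommendation(str(m)) for m in self.members
        )
        dedup = {m.label: m for m in members}
        members = tuple(dedup[label] for label in sorted(dedup))
        if not members:
            raise ModelError("recommendation set must be nonempty")
        object.__setattr__(self, "members", members)
        if self.multiplicity not in (MULT_SINGLE, MULT_ALTERNATIVES, MULT_RANKED):
            raise ModelError(f"unknown multiplicity {self.multiplicity!r}")
        if self.ranking is not None:
            ranking = tuple(_norm_label(r) for r in self.ranking)
            object.__setattr__(self, "ranking", ranking)
            if sorted(ranking) != [m.label for m in members]:
                raise ModelError(
                    f"ranking {ranking!r} is not a total order over members {self.labels!r}"
                )
        if self.multiplicity == MULT_RANKED and self.ranking is None:
            raise ModelError("ranked multiplicity requires an explicit ranking")
        if self.multiplicity != MULT_RANKED and self.ranking is not None:
            raise ModelError("ranking present but multiplicity is not 'ranked'")

    @classmethod
    def single(cls, label: str, note: str = "") -> "RecommendationSet":
        return cls((Recommendation(label),), MULT_SINGLE, note=note)

    @classmethod
    def alternatives(cls, *labels: str, note: str = "") -> "RecommendationSet":
        return cls(tuple(Recommendation(x) for x in labels), MULT_ALTERNATIVES, note=note)

    @classmethod
    def ranked(cls, *labels_best_first: str, note: str = "") -> "RecommendationSet":
        members = tuple(Recommendation(x) for x in labels_best_first)
        return cls(members, MULT_RANKED, tuple(m.label for m in members), note=note)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(m.label for m in self.members)

    @property
    def sorted_labels(self) -> tuple[str, ...]:
        return tuple(m.label for m in self.members)

    @property
    def top(self) -> str | None:
        """Main recommendation: the single member, or the best-ranked one."""
        if len(self.members) == 1:
            return self.members[0].label
        if self.multiplicity == MULT_RANKED and self.ranking:
            return self.ranking[0]
        return None

    @property
    def is_consistent(self) -> bool:
        if self.multiplicity == MULT_SINGLE:
            return len(self.members) == 1
        if self.multiplicity == MULT_ALTERNATIVES:
            return len(self.members) > 1
        return self.ranking is not None  # ranked: ranking totality enforced in __post_init__

    @classmethod
    def merge(cls, sets: Iterable["RecommendationSet"], note: str = "") -> "RecommendationSet":
        """Union of member labels; single iff the union is a singleton.

        Used when harmonization or marginalization pools several source
        cells; a non-singleton union is declared ``equivalent-alternatives``
        because no preference was ever stated for it.
        """
        sets = list(sets)
        if not sets:
            raise ModelError("cannot merge zero recommendation sets")
        by_label: dict[str, Recommendation] = {}
        for rs in sets:
            for m in rs.members:
                by_label.setdefault(m.label, m)
        members = tuple(by_label[label] for label in sorted(by_label))
        if len(members) == 1:
            return cls(members, MULT_SINGLE, note=note)
        return cls(members, MULT_ALTERNATIVES, note=note)


@dataclass(frozen=True)
class Leaf:
    recommendations: RecommendationSet


@dataclass(frozen=True)
class Branch:
    levels: tuple[str, ...]
    node: "Node"

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))


@dataclass(frozen=True)
class Internal:
    criterion: str
    branches: tuple[Branch, ...]


Node = Union[Leaf, Internal]


@dataclass(frozen=True)
class DecisionTree:
    """One participant's algorithm with provenance.

    ``criteria_used`` is derived from the structure rather than stored, so
    it can never disagree with the node contents.
    """

    participant_id: str
    root: Node
    finalisation_date: datetime.date | None = None

    @property
    def criteria_used(self) -> tuple[str, ...]:
        names: set[str] = set()

        def walk(node: Node) -> None:
            if isinstance(node, Internal):
                names.add(node.criterion)
                for b in node.branches:
                    walk(b.node)

        walk(self.root)
        return tuple(sorted(names))

    def iter_leaves(self) -> Iterator[tuple[str, Leaf]]:
        """Yield ``(path, leaf)`` pairs; paths are slash-joined edge labels."""

        def walk(node: Node, path: str) -> Iterator[tuple[str, Leaf]]:
            if isinstance(node, Leaf):
                yield path, node
            else:
                for b in node.branches:
                    label = f"{node.criterion}={'|'.join(b.levels)}"
                    yield from walk(b.node, f"{path}/{label}" if path else label)

        yield from walk(self.root, "")

    def depth(self) -> int:
        def walk(node: Node) -> int:
            if isinstance(node, Leaf):
                return 0
            return 1 + max(walk(b.node) for b in node.branches)

        return walk(self.root)


@dataclass
class DecisionTable:
    """A participant's complete mapping scenario -> recommendations.

    ``excluded`` holds scenarios explicitly marked not-applicable together
    with a reason; a table is complete when cells and exclusions tile the
    scenario space exactly.
    """

    participant_id: str
    criteria: CriteriaSet
    cells: dict[Scenario, RecommendationSet]
    excluded: dict[Scenario, str] = field(default_factory=dict)
    finalisation_date: datetime.date | None = None

    def __post_init__(self) -> None:
        names = self.criteria.names
        for s in itertools.chain(self.cells, self.excluded):
            if s.criteria_names != names:
                raise ModelError(
                    f"scenario ({s}) does not match criteria {names!r}"
                )
            for name, level in s.items:
                if level not in self.criteria[name].levels:
                    raise ModelError(
                        f"scenario ({s}): level {level!r} invalid for criterion {name!r}"
                    )
        both = set(self.cells) & set(self.excluded)
        if both:
            raise ModelError(f"{len(both)} scenario(s) both populated and excluded")

    def missing_scenarios(self) -> list[Scenario]:
        covered = set(self.cells) | set(self.excluded)
        return [s for s in scenario_space(self.criteria) if s not in covered]

    @property
    def is_complete(self) -> bool:
        return len(self.cells) + len(self.excluded) == self.criteria.n_scenarios()

    def labels(self) -> frozenset[str]:
        out: set[str] = set()
        for rs in self.cells.values():
            out |= rs.labels
        return frozenset(out)


def scenario_space(criteria: CriteriaSet) -> list[Scenario]:
    """All scenarios over ``criteria``, each exactly once, in a stable order.

    Order is lexicographic by criterion name, then by level entry order
    within each criterion (the last-named criterion varies fastest).
    """
    if len(criteria) == 0:
        raise ModelError("scenario space of an empty criteria set is undefined")
    names = criteria.names
    out = []
    for combo in itertools.product(*(criteria[n].levels for n in names)):
        out.append(Scenario(tuple(zip(names, combo))))
    return out


def evaluate(tree: DecisionTree, scenario: Scenario) -> RecommendationSet:
    """Route ``scenario`` through ``tree`` and return the leaf's payload.

    Requires the tree to satisfy the partition invariant along the taken
    path; otherwise a :class:`MissingBranchError` (gap) or
    :class:`AmbiguousBranchError` (overlap) pinpoints the violation.
    """
    node = tree.root
    while isinstance(node, Internal):
        level = scenario.get(node.criterion)
        if level is None:
            raise UnknownCriterionError(
                f"node tests criterion {node.criterion!r} absent from scenario ({scenario})",
                scenario,
            )
        matches = [b for b in node.branches if level in b.levels]
        if not matches:
            raise MissingBranchError(
                f"no branch for {node.criterion}={level} (scenario {scenario})", scenario
            )
        if len(matches) > 1:
            raise AmbiguousBranchError(
                f"{len(matches)} branches match {node.criterion}={level} (scenario {scenario})",
                scenario,
            )
        node = matches[0].node
    return node.recommendations


def depends_on(table: DecisionTable, criterion_name: str) -> bool:
    """Semantic dependence: does any pair of scenarios differing only in
    ``criterion_name`` map to different recommendation sets?

    Exclusion status is ignored; only populated cells are compared, so a
    vacuous syntactic split in the originating tree does not register.
    """
    if criterion_name not in table.criteria:
        return False
    groups: dict[Scenario, RecommendationSet] = {}
    for s, rs in table.cells.items():
        key = s.without(criterion_name)
        if key in groups:
            if groups[key] != rs:
                return True
        else:
            groups[key] = rs
    return False
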