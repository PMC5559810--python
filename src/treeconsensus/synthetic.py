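"""Synthetic expert ensembles with known ground truth, plus packaged
fixtures, so every pipeline stage is testable offline.

An ensemble is generated from a truth tree: each participant starts from
the truth's expanded table, first becomes independent of each criterion
with probability ``omission_rate`` (marginalizing by the union rule), then
flips each cell independently with probability ``deviation_rate`` to a
uniformly random label not already in the cell.  Deviations are i.i.d. per
cell — the simplest null model for consensus-recovery experiments.

The random stream is split per participant with
:class:`numpy.random.SeedSequence`, so enlarging an ensemble never
perturbs the participants already generated.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io_formats
from .harmonization import RuleSet, marginalize
from .consensus_engine import expand
from .tree_model import (
    Branch,
    Criterion,
    CriteriaSet,
    DecisionTable,
    DecisionTree,
    Internal,
    Leaf,
    ModelError,
    Node,
    RecommendationSet,
    Scenario,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticEnsemble",
    "CutoffRecord",
    "default_criteria",
    "default_labels",
    "random_tree",
    "random_table",
    "generate_ensemble",
    "table1_fixture",
    "fig2_fixture",
    "load_spec",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic ensemble.

    ``criteria``/``truth``/``labels`` may be given explicitly; otherwise
    they are derived from the counts (criteria ``c1..``, levels ``l1..``,
    labels ``tx1..``) and the truth tree is generated randomly.
    """

    n_participants: int
    n_criteria: int = 3
    n_levels: int | tuple[int, ...] = 2
    n_labels: int = 4
    deviation_rate: float = 0.0
    omission_rate: float = 0.0
    seed: int = 0
    criteria: CriteriaSet | None = None
    truth: DecisionTree | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ModelError("n_participants must be >= 1")
        for name in ("deviation_rate", "omission_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ModelError(f"{name} must lie in [0, 1], got {p!r}")
        if self.labels is None and self.n_labels < 2:
            raise ModelError("label universe must contain >= 2 labels")
        if self.labels is not None and len(self.labels) < 2:
            raise ModelError("label universe must contain >= 2 labels")

    def resolve_criteria(self) -> CriteriaSet:
        if self.criteria is not None:
            return self.criteria
        return default_criteria(self.n_criteria, self.n_levels)

    def resolve_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return tuple(self.labels)
        return default_labels(self.n_labels)


@dataclass
class SyntheticEnsemble:
    tables: list[DecisionTable]
    truth_table: DecisionTable
    truth_tree: DecisionTree
    criteria: CriteriaSet
    labels: tuple[str, ...]
    spec: SyntheticSpec = field(repr=False, default=None)  # type: ignore[assignment]


def default_criteria(n_criteria: int, n_levels: int | tuple[int, ...]) -> CriteriaSet:
    if n_criteria < 1:
        raise ModelError("need at least one criterion")
    if isinstance(n_levels, int):
        per = [n_levels] * n_criteria
    else:
        per = list(n_levels)
        if len(per) != n_criteria:
            raise ModelError("n_levels tuple length must equal n_criteria")
    return CriteriaSet(
        Criterion(f"c{i + 1}", tuple(f"l{j + 1}" for j in range(k)))
        for i, k in enumerate(per)
    )


def default_labels(n_labels: int) -> tuple[str, ...]:
    return tuple(f"tx{i + 1}" for i in range(n_labels))


def random_tree(
    criteria: CriteriaSet,
    labels: tuple[str, ...],
    rng: np.random.Generator,
    participant_id: str = "truth",
    leaf_prob: float = 0.3,
) -> DecisionTree:
    """A uniformly scrambled valid tree: random criterion order, random
    branch partitions, random singleton leaves."""

    def rec(remaining: tuple[str, ...], depth: int) -> Node:
        if not remaining or (depth > 0 and rng.random() < leaf_prob):
            return Leaf(RecommendationSet.single(labels[int(rng.integers(len(labels)))]))
        name = remaining[int(rng.integers(len(remaining)))]
        levels = list(criteria[name].levels)
        k = int(rng.integers(2, len(levels) + 1))
        order = list(rng.permutation(len(levels)))
        groups: list[list[int]] = [[order[i]] for i in range(k)]
        for idx in order[k:]:
            groups[int(rng.integers(k))].append(idx)
        groups.sort(key=min)
        rest = tuple(n for n in remaining if n != name)
        branches = tuple(
            Branch(tuple(levels[i] for i in sorted(g)), rec(rest, depth + 1)) for g in groups
        )
        return Internal(name, branches)

    return DecisionTree(participant_id, rec(tuple(criteria.names), 0))


def random_table(
    criteria: CriteriaSet,
    labels: tuple[str, ...],
    rng: np.random.Generator,
    participant_id: str = "random",
) -> DecisionTable:
    from .tree_model import scenario_space

    cells = {
        s: RecommendationSet.single(labels[int(rng.integers(len(labels)))])
        for s in scenario_space(criteria)
    }
    return DecisionTable(participant_id, criteria, cells)


def _flip_cells(
    table: DecisionTable,
    labels: tuple[str, ...],
    deviation_rate: float,
    rng: np.random.Generator,
) -> DecisionTable:
    cells: dict[Scenario, RecommendationSet] = {}
    for s, rs in sorted(table.cells.items()):  # sorted: order-independent stream use
        if deviation_rate > 0 and rng.random() < deviation_rate:
            alternatives = [x for x in labels if x not in rs.labels]
            if alternatives:
                rs = RecommendationSet.single(alternatives[int(rng.integers(len(alternatives)))])
        cells[s] = rs
    return DecisionTable(
        table.participant_id, table.criteria, cells, dict(table.excluded), table.finalisation_date
    )


def generate_ensemble(spec: SyntheticSpec) -> SyntheticEnsemble:
    """Generate ``spec.n_participants`` complete tables around a truth tree.

    Fully reproducible from ``spec.seed``; see the module docstring for the
    deviation model.
    """
    criteria = spec.resolve_criteria()
    labels = spec.resolve_labels()
    root_seq = np.random.SeedSequence(spec.seed)
    truth_seq = root_seq.spawn(1)[0]
    truth_tree = spec.truth
    if truth_tree is None:
        truth_tree = random_tree(criteria, labels, np.random.default_rng(truth_seq))
    truth_table = expand(truth_tree, criteria)
    tables: list[DecisionTable] = []
    for i in range(spec.n_participants):
        rng = np.random.default_rng(root_seq.spawn(1)[0])
        pid = f"p{i + 1:03d}"
        table = DecisionTable(pid, criteria, dict(truth_table.cells))
        if spec.omission_rate > 0:
            for name in criteria.names:
                if len(table.criteria) > 1 and rng.random() < spec.omission_rate:
                    # become independent of the criterion, then re-key onto
                    # the full space so the ensemble stays comparable
                    marg = marginalize(table, name)
                    cells = {
                        s: marg.cells[s.without(name)]
                        for s in truth_table.cells
                        if s.without(name) in marg.cells
                    }
                    table = DecisionTable(pid, criteria, cells)
        table = _flip_cells(table, labels, spec.deviation_rate, rng)
        tables.append(table)
    return SyntheticEnsemble(tables, truth_table, truth_tree, criteria, labels, spec)


# ---------------------------------------------------------------------------
# packaged fixtures


@dataclass(frozen=True)
class CutoffRecord:
    """One center's raw performance-status encoding before harmonization."""

    center: str
    scale: str | None
    cutoff: float | None
    levels: tuple[str, ...]
    note: str = ""


def _fixture_text(name: str) -> str:
    return (
        importlib.resources.files("treeconsensus").joinpath("fixtures", name).read_text("utf-8")
    )


def table1_fixture() -> tuple[list[CutoffRecord], RuleSet]:
    """Six-center performance-status census plus the fit/unfit mapping rules."""
    text = _fixture_text("performance_status_cutoffs.yaml")
    data = yaml.safe_load(text)
    records = []
    for entry in data["records"]:
        records.append(
            CutoffRecord(
                center=str(entry["center"]),
                scale=None if entry.get("scale") is None else str(entry["scale"]),
                cutoff=None if entry.get("cutoff") is None else float(entry["cutoff"]),
                levels=tuple(str(v) for v in entry["levels"]),
                note=str(entry.get("note", "")),
            )
        )
    ruleset = io_formats.parse_rules(text)
    return records, ruleset


def fig2_fixture() -> tuple[DecisionTree, CriteriaSet]:
    """The draft pancreatic-cancer tree with its documented imperfections.

    Parsed in non-strict mode: the defects (undifferentiated double
    recommendation, branch overlap, coverage gap) are the point.
    """
    doc = io_formats.parse_tree_document(_fixture_text("draft_pancreatic_tree.yaml"), strict=False)
    return doc.tree, doc.criteria


def load_spec(text: str, seed: int | None = None) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a YAML document (CLI entry)."""
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise io_formats.SchemaError("simulation spec: top level must be a mapping")
    known = {
        "n_participants",
        "n_criteria",
        "n_levels",
        "n_labels",
        "deviation_rate",
        "omission_rate",
        "seed",
    }
    unknown = sorted(set(data) - known)
    if unknown:
        raise io_formats.SchemaError(f"simulation spec: unknown key(s) {unknown!r}")
    if "n_participants" not in data:
        raise io_formats.SchemaError("simulation spec: missing required key 'n_participants'")
    kwargs = dict(data)
    if isinstance(kwargs.get("n_levels"), list):
        kwargs["n_levels"] = tuple(kwargs["n_levels"])
    if seed is not None:
        kwargs["seed"] = seed
    return SyntheticSpec(**kwargs)
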