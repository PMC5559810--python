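"""Structural validation of draft trees and tables.

Validation reports defects, it never repairs them and it never judges the
clinical content of a recommendation.  Categories:

``gap``
    a scenario no leaf is reachable for (tree) / a missing row (table)
``conflict``
    a reachable leaf or cell whose member count contradicts its declared
    multiplicity, or duplicate rows with different recommendation sets
``overlap``
    intersecting branch level-subsets at one node, or duplicate identical
    rows covering one scenario twice
``unknown-level``
    a level (or criterion) absent from the governing criteria set
``unreachable-branch``
    a branch whose level-subset is emptied by ancestor constraints

A report is valid iff it contains no gap/conflict/overlap/unknown-level
issue; unreachable branches are dead code, not correctness defects.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

from .tree_model import (
    Branch,
    CriteriaSet,
    DecisionTable,
    DecisionTree,
    Internal,
    Leaf,
    Node,
    RecommendationSet,
    Scenario,
    scenario_space,
)

__all__ = [
    "GAP",
    "CONFLICT",
    "OVERLAP",
    "UNKNOWN_LEVEL",
    "UNREACHABLE",
    "INVALIDATING_CATEGORIES",
    "ValidationIssue",
    "ValidationReport",
    "validate_tree",
    "validate_table",
]

GAP = "gap"
CONFLICT = "conflict"
OVERLAP = "overlap"
UNKNOWN_LEVEL = "unknown-level"
UNREACHABLE = "unreachable-branch"

INVALIDATING_CATEGORIES = frozenset({GAP, CONFLICT, OVERLAP, UNKNOWN_LEVEL})


@dataclass(frozen=True)
class ValidationIssue:
    category: str
    location: str
    message: str
    scenario: Scenario | None = None


@dataclass
class ValidationReport:
    participant_id: str
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not any(i.category in INVALIDATING_CATEGORIES for i in self.issues)

    def by_category(self, category: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.category == category]

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(i.category for i in self.issues)

    def gap_scenarios(self) -> set[Scenario]:
        return {i.scenario for i in self.by_category(GAP) if i.scenario is not None}

    def to_text(self) -> str:
        lines = [f"validation report for participant {self.participant_id!r}:"]
        if not self.issues:
            lines.append("  no issues")
        for i in self.issues:
            lines.append(f"  [{i.category}] at {i.location}: {i.message}")
        lines.append(f"  verdict: {'VALID' if self.is_valid else 'NOT VALID'}")
        return "\n".join(lines)

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["participant_id", "category", "location", "message"])
        for i in self.issues:
            w.writerow([self.participant_id, i.category, i.location, i.message])
        return buf.getvalue()


def _check_leaf(leaf: Leaf, path: str, issues: list[ValidationIssue]) -> None:
    rs = leaf.recommendations
    if not rs.is_consistent:
        if rs.multiplicity == "single" and len(rs.members) > 1:
            msg = (
                f"{len(rs.members)} recommendations {sorted(rs.labels)} without a declared "
                "multiplicity (alternatives or ranking must be stated explicitly)"
            )
        else:
            msg = (
                f"multiplicity {rs.multiplicity!r} inconsistent with "
                f"{len(rs.members)} member(s) {sorted(rs.labels)}"
            )
        issues.append(ValidationIssue(CONFLICT, path or "root", msg))


def validate_tree(tree: DecisionTree, criteria: CriteriaSet) -> ValidationReport:
    """Exhaustive structural report; defects are content, not exceptions."""
    issues: list[ValidationIssue] = []

    def walk(node: Node, path: str, allowed: dict[str, frozenset[str]]) -> None:
        if isinstance(node, Leaf):
            _check_leaf(node, path, issues)
            return
        here = path or "root"
        if node.criterion not in criteria:
            issues.append(
                ValidationIssue(
                    UNKNOWN_LEVEL,
                    here,
                    f"node tests criterion {node.criterion!r} absent from the criteria set",
                )
            )
            return
        full = frozenset(criteria[node.criterion].levels)
        known_subsets: list[tuple[Branch, frozenset[str]]] = []
        for b in node.branches:
            unknown = [v for v in b.levels if v not in full]
            if unknown:
                issues.append(
                    ValidationIssue(
                        UNKNOWN_LEVEL,
                        here,
                        f"branch {node.criterion}={'|'.join(b.levels)} uses level(s) "
                        f"{unknown!r} not defined for criterion {node.criterion!r}",
                    )
                )
            known_subsets.append((b, frozenset(b.levels) & full))
        for i in range(len(known_subsets)):
            for j in range(i + 1, len(known_subsets)):
                inter = known_subsets[i][1] & known_subsets[j][1]
                if inter:
                    issues.append(
                        ValidationIssue(
                            OVERLAP,
                            here,
                            f"branches {i} and {j} on {node.criterion!r} overlap on "
                            f"level(s) {sorted(inter)}",
                        )
                    )
        reach = allowed.get(node.criterion, full)
        for b, subset in known_subsets:
            effective = subset & reach
            label = f"{node.criterion}={'|'.join(b.levels)}"
            child_path = f"{path}/{label}" if path else label
            if not effective:
                issues.append(
                    ValidationIssue(
                        UNREACHABLE,
                        child_path,
                        f"branch subset {sorted(b.levels)} is emptied by ancestor "
                        f"constraints on {node.criterion!r}",
                    )
                )
                continue
            child_allowed = dict(allowed)
            child_allowed[node.criterion] = effective
            walk(b.node, child_path, child_allowed)

    walk(tree.root, "", {})

    # Gap sweep: a scenario is covered iff at least one root-to-leaf route
    # accepts it (overlapping branches are followed in parallel so an
    # overlap does not mask coverage).
    def reaches_leaf(node: Node, scenario: Scenario) -> bool:
        if isinstance(node, Leaf):
            return True
        level = scenario.get(node.criterion)
        if level is None:
            return False
        return any(level in b.levels and reaches_leaf(b.node, scenario) for b in node.branches)

    for s in scenario_space(criteria):
        if not reaches_leaf(tree.root, s):
            issues.append(
                ValidationIssue(GAP, f"scenario({s})", f"no recommendation stated for ({s})", s)
            )

    return ValidationReport(tree.participant_id, issues)


def _validate_cells(
    cells: dict[Scenario, RecommendationSet],
    excluded: set[Scenario],
    criteria: CriteriaSet,
    issues: list[ValidationIssue],
) -> None:
    covered = set(cells) | excluded
    for s in scenario_space(criteria):
        if s not in covered:
            issues.append(
                ValidationIssue(GAP, f"scenario({s})", f"no row for scenario ({s})", s)
            )
    for s, rs in cells.items():
        if not rs.is_consistent:
            issues.append(
                ValidationIssue(
                    CONFLICT,
                    f"scenario({s})",
                    f"multiplicity {rs.multiplicity!r} inconsistent with members "
                    f"{sorted(rs.labels)}",
                    s,
                )
            )


def validate_table(source, criteria: CriteriaSet | None = None, participant_id: str | None = None) -> ValidationReport:
    """Validate a :class:`DecisionTable` or a raw list of parsed rows.

    Passing rows (``io_formats.TableRow``) additionally surfaces duplicate
    scenarios and unknown levels, which a constructed table cannot contain.
    """
    issues: list[ValidationIssue] = []
    if isinstance(source, DecisionTable):
        _validate_cells(source.cells, set(source.excluded), source.criteria, issues)
        return ValidationReport(source.participant_id, issues)

    if criteria is None:
        raise ValueError("criteria are required when validating raw rows")
    pid = participant_id if participant_id is not None else "<rows>"
    cells: dict[Scenario, RecommendationSet] = {}
    excluded: set[Scenario] = set()
    seen: dict[Scenario, RecommendationSet | None] = {}
    for row in source:
        bad = False
        for name, level in row.assignment.items():
            if name not in criteria:
                issues.append(
                    ValidationIssue(
                        UNKNOWN_LEVEL, f"line {row.line_no}", f"unknown criterion {name!r}"
                    )
                )
                bad = True
            elif level not in criteria[name].levels:
                issues.append(
                    ValidationIssue(
                        UNKNOWN_LEVEL,
                        f"line {row.line_no}",
                        f"level {level!r} invalid for criterion {name!r}",
                    )
                )
                bad = True
        missing = [n for n in criteria.names if n not in row.assignment]
        if missing:
            issues.append(
                ValidationIssue(
                    UNKNOWN_LEVEL, f"line {row.line_no}", f"row does not assign {missing!r}"
                )
            )
            bad = True
        if bad:
            continue
        s = Scenario.from_mapping(row.assignment)
        if s in seen:
            if seen[s] != row.recommendations:
                issues.append(
                    ValidationIssue(
                        CONFLICT,
                        f"line {row.line_no}",
                        f"duplicate rows for scenario ({s}) with different recommendations",
                        s,
                    )
                )
            else:
                issues.append(
                    ValidationIssue(
                        OVERLAP,
                        f"line {row.line_no}",
                        f"scenario ({s}) covered by duplicate identical rows",
                        s,
                    )
                )
            continue
        seen[s] = row.recommendations
        if row.recommendations is None:
            excluded.add(s)
        else:
            cells[s] = row.recommendations
    _validate_cells(cells, excluded, criteria, issues)
    return ValidationReport(pid, issues)
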