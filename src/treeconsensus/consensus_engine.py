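"""Expansion, per-scenario vote tallies, consensus summaries and tree
induction.

All tallies use exact rational arithmetic (:class:`fractions.Fraction`) so
boundary cases — a 12-of-24 split is exactly half, never a float whisker
above it — resolve correctly.  Majority is STRICT: a label is the majority
only when its weight exceeds half of the participants voting at that
scenario; exactly half is no majority.  Mode ties are never broken.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from fractions import Fraction

from .tree_model import (
    Branch,
    CriteriaSet,
    DecisionTable,
    DecisionTree,
    EvaluationError,
    Internal,
    Leaf,
    ModelError,
    MULT_RANKED,
    Node,
    RecommendationSet,
    Scenario,
    evaluate,
    scenario_space,
)

__all__ = [
    "POLICY_ANY",
    "POLICY_MAIN",
    "POLICIES",
    "PolicyError",
    "EnsembleMismatchError",
    "ConsensusCell",
    "ConsensusTable",
    "expand",
    "vote_of",
    "consensus",
    "induce_tree",
    "write_consensus_csv",
]

POLICY_ANY = "any-recommended"
POLICY_MAIN = "main-recommended"
POLICIES = (POLICY_ANY, POLICY_MAIN)


class PolicyError(ModelError):
    """The multiplicity policy cannot be applied to a cell."""


class EnsembleMismatchError(ModelError):
    """Participant tables do not share one criteria universe."""


def expand(tree: DecisionTree, criteria: CriteriaSet) -> DecisionTable:
    """Flatten a tree into its complete decision table over ``criteria``.

    Criteria the tree never tests replicate recommendations across their
    levels.  Evaluation failures are re-raised naming the scenario.
    """
    missing = [n for n in tree.criteria_used if n not in criteria]
    if missing:
        raise ModelError(
            f"tree for {tree.participant_id!r} tests criteria {missing!r} outside the "
            "expansion universe"
        )
    cells = {}
    for s in scenario_space(criteria):
        try:
            cells[s] = evaluate(tree, s)
        except EvaluationError as exc:
            raise type(exc)(f"expanding {tree.participant_id!r}: {exc}", s) from exc
    return DecisionTable(tree.participant_id, criteria, cells, {}, tree.finalisation_date)


def vote_of(
    cell_value: RecommendationSet, policy: str, fractional: bool = True
) -> dict[str, Fraction]:
    """One participant's vote weights for a cell.

    ``any-recommended`` spreads one unit of weight over the members
    (``fractional=True``, the default) so each participant weighs exactly 1;
    with ``fractional=False`` every member gets a full vote instead (weight
    ``|members|`` — documented alternative, changes the congruency
    denominator semantics).  ``main-recommended`` gives the single or
    top-ranked member a full vote and rejects unranked non-singletons.
    """
    if policy == POLICY_ANY:
        labels = cell_value.sorted_labels
        weight = Fraction(1, len(labels)) if fractional else Fraction(1)
        return {label: weight for label in labels}
    if policy == POLICY_MAIN:
        top = cell_value.top
        if top is None:
            raise PolicyError(
                f"policy {POLICY_MAIN!r} undefined for unranked alternatives "
                f"{sorted(cell_value.labels)}"
            )
        return {top: Fraction(1)}
    raise PolicyError(f"unknown policy {policy!r} (expected one of {POLICIES})")


@dataclass(frozen=True)
class ConsensusCell:
    """Per-scenario tally across the ensemble.

    ``congruency_rate`` is max count / participants voting, as an exact
    fraction in [0, 1]; :attr:`congruency_pct` reports it as a percentage.
    ``majority`` is the unique label with count strictly above half of
    ``n_voting``, or ``None``.
    """

    scenario: Scenario
    counts: tuple[tuple[str, Fraction], ...]
    n_voting: int
    mode_set: frozenset[str]
    congruency_rate: Fraction | None
    majority: str | None

    @property
    def counts_dict(self) -> dict[str, Fraction]:
        return dict(self.counts)

    @property
    def congruency_pct(self) -> float | None:
        return None if self.congruency_rate is None else float(self.congruency_rate * 100)


def _make_cell(scenario: Scenario, counts: dict[str, Fraction], n_voting: int) -> ConsensusCell:
    if n_voting == 0 or not counts:
        return ConsensusCell(scenario, (), n_voting, frozenset(), None, None)
    top = max(counts.values())
    mode_set = frozenset(label for label, c in counts.items() if c == top)
    congruency = top / n_voting
    majority = None
    if len(mode_set) == 1 and top > Fraction(n_voting, 2):
        majority = next(iter(mode_set))
    return ConsensusCell(
        scenario, tuple(sorted(counts.items())), n_voting, mode_set, congruency, majority
    )


@dataclass
class ConsensusTable:
    criteria: CriteriaSet
    cells: dict[Scenario, ConsensusCell]
    participants: tuple[str, ...]
    finalisation_dates: dict[str, str] = field(default_factory=dict)
    policy: str = POLICY_ANY
    fractional: bool = True

    def mode_table(self, participant_id: str = "consensus-mode") -> DecisionTable:
        """Project each cell onto its mode set (ties kept as alternatives)."""
        cells: dict[Scenario, RecommendationSet] = {}
        excluded: dict[Scenario, str] = {}
        for s, cell in self.cells.items():
            if not cell.mode_set:
                excluded[s] = "no participant voted at this scenario"
            elif len(cell.mode_set) == 1:
                cells[s] = RecommendationSet.single(next(iter(cell.mode_set)))
            else:
                cells[s] = RecommendationSet.alternatives(
                    *sorted(cell.mode_set), note="mode tie"
                )
        return DecisionTable(participant_id, self.criteria, cells, excluded)


def consensus(
    ensemble: list[DecisionTable], policy: str = POLICY_ANY, fractional: bool = True
) -> ConsensusTable:
    """Tally the ensemble per scenario: counts, mode set, congruency,
    strict majority.  Excluded scenarios abstain and shrink that cell's
    denominator ``n_voting``."""
    if not ensemble:
        raise ModelError("consensus of an empty ensemble is undefined")
    criteria = ensemble[0].criteria
    for t in ensemble[1:]:
        if t.criteria != criteria:
            diff = sorted(set(t.criteria.names) ^ set(criteria.names))
            detail = f"criteria names differ by {diff!r}" if diff else "level sets differ"
            raise EnsembleMismatchError(
                f"table for {t.participant_id!r} does not share the ensemble criteria "
                f"universe ({detail})"
            )
    for t in ensemble:
        if not t.is_complete:
            raise ModelError(
                f"table for {t.participant_id!r} is incomplete: "
                f"{len(t.missing_scenarios())} scenario(s) missing"
            )
    cells: dict[Scenario, ConsensusCell] = {}
    for s in scenario_space(criteria):
        counts: dict[str, Fraction] = {}
        n_voting = 0
        for t in ensemble:
            if s in t.excluded:
                continue
            n_voting += 1
            for label, weight in vote_of(t.cells[s], policy, fractional).items():
                counts[label] = counts.get(label, Fraction(0)) + weight
        cells[s] = _make_cell(s, counts, n_voting)
    dates = {
        t.participant_id: t.finalisation_date.isoformat()
        for t in ensemble
        if t.finalisation_date is not None
    }
    return ConsensusTable(
        criteria, cells, tuple(t.participant_id for t in ensemble), dates, policy, fractional
    )


def induce_tree(table: DecisionTable) -> DecisionTree:
    """Induce a compact decision tree that losslessly reproduces ``table``.

    At each node the split criterion is the one whose level-wise sub-tables
    collapse into the fewest distinct groups (ties broken lexicographically
    by name); levels with identical sub-tables share one branch subset.
    Criteria the table does not depend on are never tested, so
    ``expand(induce_tree(T), T.criteria) == T`` and the tree is free of
    vacuous splits.
    """
    if table.excluded:
        raise ModelError(
            "cannot induce a tree from a table with excluded scenarios "
            f"({len(table.excluded)} excluded)"
        )
    if not table.is_complete:
        raise ModelError(
            f"cannot induce a tree from an incomplete table "
            f"({len(table.missing_scenarios())} scenario(s) missing)"
        )

    def rec(cells: dict[Scenario, RecommendationSet], remaining: tuple[str, ...]) -> Node:
        distinct_values = set(cells.values())
        if len(distinct_values) == 1:
            return Leaf(next(iter(distinct_values)))
        best_name = None
        best_groups: list[tuple[list[str], dict[Scenario, RecommendationSet]]] = []
        for name in remaining:  # remaining is sorted, so ties fall to the first
            levels = table.criteria[name].levels
            subtables = {
                lv: {s.without(name): rs for s, rs in cells.items() if s[name] == lv}
                for lv in levels
            }
            groups: list[tuple[list[str], dict[Scenario, RecommendationSet]]] = []
            keys: list[frozenset] = []
            for lv in levels:
                key = frozenset(subtables[lv].items())
                try:
                    groups[keys.index(key)][0].append(lv)
                except ValueError:
                    keys.append(key)
                    groups.append(([lv], subtables[lv]))
            if len(groups) == 1:
                continue  # table independent of this criterion here
            if best_name is None or len(groups) < len(best_groups):
                best_name, best_groups = name, groups
        assert best_name is not None, "non-constant complete table must depend on something"
        rest = tuple(n for n in remaining if n != best_name)
        return Internal(
            best_name,
            tuple(Branch(tuple(lvls), rec(sub, rest)) for lvls, sub in best_groups),
        )

    root = rec(dict(table.cells), table.criteria.names)
    return DecisionTree(table.participant_id, root, table.finalisation_date)


def _fraction_str(x: Fraction) -> str:
    return str(x.numerator) if x.denominator == 1 else f"{x.numerator}/{x.denominator}"


def write_consensus_csv(ct: ConsensusTable) -> str:
    """One row per scenario: levels, per-label counts (exact fractions),
    n_voting, mode set, congruency (exact and %), majority."""
    labels = sorted({label for cell in ct.cells.values() for label, _ in cell.counts})
    buf = io.StringIO()
    buf.write(f"#participants={'|'.join(ct.participants)}\n")
    if ct.finalisation_dates:
        pairs = "|".join(f"{p}:{d}" for p, d in sorted(ct.finalisation_dates.items()))
        buf.write(f"#finalisation_dates={pairs}\n")
    buf.write(f"#policy={ct.policy}\n")
    buf.write(f"#vote_weighting={'fractional' if ct.fractional else 'full-per-member'}\n")
    names = ct.criteria.names
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(
        list(names)
        + [f"votes:{label}" for label in labels]
        + ["n_voting", "mode_set", "congruency", "congruency_pct", "majority"]
    )
    for s in scenario_space(ct.criteria):
        cell = ct.cells[s]
        counts = cell.counts_dict
        row = [s[n] for n in names]
        row += [_fraction_str(counts[label]) if label in counts else "0" for label in labels]
        row.append(str(cell.n_voting))
        row.append("|".join(sorted(cell.mode_set)))
        if cell.congruency_rate is None:
            row += ["", "", ""]
        else:
            row.append(_fraction_str(cell.congruency_rate))
            row.append(f"{cell.congruency_pct:.4f}")
            row.append(cell.majority or "")
        w.writerow(row)
    return buf.getvalue()
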