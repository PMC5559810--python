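"""Criteria harmonization: cut-off translation, synonym merging, inclusion
thresholds.

Rules are author-supplied (the moderated step of the workflow); this module
only applies them mechanically.  A rule maps the levels of one participant's
source criterion onto the levels of a shared harmonized criterion — e.g. a
KPS cut-off at 70 onto fit/unfit.  Harmonized criteria absent from a
participant's table are treated as explicit non-dependence: the
participant's cells replicate across the new criterion's levels (the
collectively-introduced-criterion pattern).

Setting-level criteria (e.g. informed consent) never enter the scenario
space; they are carried as annotations on the rule set and surfaced in
logs, not computed over.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .tree_model import (
    CriteriaSet,
    DecisionTable,
    ModelError,
    RecommendationSet,
    Scenario,
    depends_on,
    scenario_space,
)

__all__ = [
    "HarmonizationError",
    "RuleCoverageError",
    "MergeAmbiguityError",
    "HarmonizationRule",
    "RuleSet",
    "CriterionCensus",
    "ExclusionRecord",
    "apply_rules",
    "census",
    "inclusion_filter",
    "marginalize",
    "DEFAULT_INCLUSION_THRESHOLD",
]

#: Minimum number of participants that must use a criterion for it to be
#: retained, unless overridden in configuration.
DEFAULT_INCLUSION_THRESHOLD = 3


class HarmonizationError(ModelError):
    pass


class RuleCoverageError(HarmonizationError):
    """A criterion is touched by rules that do not cover all its levels."""


class MergeAmbiguityError(HarmonizationError):
    """Harmonized scenarios whose source preimage is empty or contradictory."""

    def __init__(self, message: str, scenarios: list[Scenario] | None = None):
        super().__init__(message)
        self.scenarios = scenarios or []


@dataclass(frozen=True)
class HarmonizationRule:
    """Map one participant's source criterion levels onto a harmonized one.

    ``participants`` is ``None`` for a global rule, otherwise the set of
    participant ids it applies to.  ``source_scale``/``cutoff`` record the
    provenance of cut-off-derived levels (e.g. ``KPS`` / ``70``).
    """

    source: str
    target: str
    level_map: tuple[tuple[str, str], ...]
    participants: frozenset[str] | None = None
    source_scale: str | None = None
    cutoff: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        pairs = tuple(sorted((str(k), str(v)) for k, v in dict(self.level_map).items()))
        object.__setattr__(self, "level_map", pairs)
        if self.participants is not None:
            object.__setattr__(self, "participants", frozenset(str(p) for p in self.participants))

    @property
    def mapping(self) -> dict[str, str]:
        return dict(self.level_map)

    def applies_to(self, participant_id: str) -> bool:
        return self.participants is None or participant_id in self.participants


@dataclass
class RuleSet:
    """A harmonized criteria universe plus the rules that map into it."""

    criteria: CriteriaSet
    rules: tuple[HarmonizationRule, ...] = ()
    setting_annotations: tuple[str, ...] = ()

    def mapping_for(self, participant_id: str, source: str) -> tuple[str, dict[str, str]] | None:
        """Resolve the (target, level map) for one source criterion.

        Participant-specific rules shadow global ones; several applicable
        rules for the same source are merged and must agree cell-wise and
        share one target.
        """
        applicable = [r for r in self.rules if r.source == source and r.applies_to(participant_id)]
        specific = [r for r in applicable if r.participants is not None]
        chosen = specific if specific else applicable
        if not chosen:
            return None
        targets = {r.target for r in chosen}
        if len(targets) > 1:
            raise RuleCoverageError(
                f"rules for source {source!r} (participant {participant_id!r}) disagree on "
                f"target: {sorted(targets)}"
            )
        merged: dict[str, str] = {}
        for r in chosen:
            for src_level, tgt_level in r.level_map:
                if merged.get(src_level, tgt_level) != tgt_level:
                    raise RuleCoverageError(
                        f"rules for source {source!r} map level {src_level!r} to both "
                        f"{merged[src_level]!r} and {tgt_level!r}"
                    )
                merged[src_level] = tgt_level
        return next(iter(targets)), merged


@dataclass
class CriterionCensus:
    """Criterion name -> set of participants whose table depends on it."""

    users: dict[str, frozenset[str]] = field(default_factory=dict)

    def count(self, name: str) -> int:
        return len(self.users.get(name, frozenset()))


@dataclass(frozen=True)
class ExclusionRecord:
    criterion: str
    n_users: int
    users: tuple[str, ...]
    threshold: int


def apply_rules(table: DecisionTable, ruleset: RuleSet) -> DecisionTable:
    """Re-key a complete table onto the harmonized criteria universe.

    Each harmonized cell is the union of the source cells in its preimage;
    a non-singleton union becomes ``equivalent-alternatives`` with a
    merge-ambiguity note.  Harmonized criteria with no counterpart in the
    source table replicate the participant's cells (non-dependence).
    """
    if not table.is_complete:
        raise HarmonizationError(
            f"table for {table.participant_id!r} is incomplete: "
            f"{len(table.missing_scenarios())} scenario(s) missing"
        )
    tcrit = ruleset.criteria
    pid = table.participant_id

    # source criterion name -> (target name, source level -> target level)
    maps: dict[str, tuple[str, dict[str, str]]] = {}
    for c in table.criteria:
        resolved = ruleset.mapping_for(pid, c.name)
        if resolved is None:
            if c.name not in tcrit:
                raise RuleCoverageError(
                    f"criterion {c.name!r} of participant {pid!r} has no rule and is not a "
                    "harmonized criterion"
                )
            extra = set(c.levels) - set(tcrit[c.name].levels)
            if extra:
                raise RuleCoverageError(
                    f"pass-through criterion {c.name!r}: level(s) {sorted(extra)} are not "
                    "harmonized levels"
                )
            maps[c.name] = (c.name, {v: v for v in c.levels})
            continue
        target, level_map = resolved
        if target not in tcrit:
            raise RuleCoverageError(
                f"rule target {target!r} is not in the harmonized criteria set"
            )
        unmapped = [v for v in c.levels if v not in level_map]
        if unmapped:
            raise RuleCoverageError(
                f"rules for {c.name!r} (participant {pid!r}) leave level(s) "
                f"{unmapped!r} unmapped"
            )
        bad_targets = sorted(set(level_map.values()) - set(tcrit[target].levels))
        if bad_targets:
            raise RuleCoverageError(
                f"rules for {c.name!r} map onto level(s) {bad_targets!r} not defined for "
                f"harmonized criterion {target!r}"
            )
        maps[c.name] = (target, level_map)

    source_names = sorted(maps)
    cells: dict[Scenario, RecommendationSet] = {}
    excluded: dict[Scenario, str] = {}
    empty_preimage: list[Scenario] = []
    for hs in scenario_space(tcrit):
        allowed: list[list[str]] = []
        for src in source_names:
            target, level_map = maps[src]
            levels = [lv for lv in table.criteria[src].levels if level_map[lv] == hs[target]]
            allowed.append(levels)
        if any(not lv for lv in allowed):
            empty_preimage.append(hs)
            continue
        pooled: list[RecommendationSet] = []
        reasons: list[str] = []
        n_src = 0
        for combo in itertools.product(*allowed):
            ss = Scenario(tuple(zip(source_names, combo)))
            n_src += 1
            if ss in table.excluded:
                reasons.append(table.excluded[ss])
            else:
                pooled.append(table.cells[ss])
        if not pooled:
            excluded[hs] = "; ".join(dict.fromkeys(reasons)) or "all source scenarios excluded"
            continue
        if n_src == 1:
            cells[hs] = pooled[0]
            continue
        labels = frozenset().union(*(rs.labels for rs in pooled))
        note = ""
        if len(labels) > 1 and len({rs.labels for rs in pooled}) > 1:
            note = (
                f"merge-ambiguity: union of {len(pooled)} source cells yields "
                f"alternatives {sorted(labels)}"
            )
        cells[hs] = RecommendationSet.merge(pooled, note=note)
    if empty_preimage:
        raise MergeAmbiguityError(
            f"{len(empty_preimage)} harmonized scenario(s) have an empty source preimage "
            f"for participant {pid!r} (first: {empty_preimage[0]})",
            empty_preimage,
        )
    return DecisionTable(pid, tcrit, cells, excluded, table.finalisation_date)


def census(ensemble: list[DecisionTable]) -> CriterionCensus:
    """Per-criterion participant sets under the semantic-dependence rule."""
    names: set[str] = set()
    for t in ensemble:
        names |= set(t.criteria.names)
    users = {
        name: frozenset(t.participant_id for t in ensemble if depends_on(t, name))
        for name in sorted(names)
    }
    return CriterionCensus(users)


def marginalize(table: DecisionTable, criterion_name: str) -> DecisionTable:
    """Drop one criterion, unioning cells over its levels (never choosing)."""
    if criterion_name not in table.criteria:
        raise KeyError(f"unknown criterion {criterion_name!r}")
    reduced = table.criteria.without(criterion_name)
    if len(reduced) == 0:
        raise HarmonizationError("cannot marginalize away the last criterion")
    levels = table.criteria[criterion_name].levels
    cells: dict[Scenario, RecommendationSet] = {}
    excluded: dict[Scenario, str] = {}
    for s in scenario_space(reduced):
        group = [s.with_value(criterion_name, lv) for lv in levels]
        pooled = [table.cells[g] for g in group if g in table.cells]
        if not pooled:
            reasons = [table.excluded[g] for g in group if g in table.excluded]
            excluded[s] = "; ".join(dict.fromkeys(reasons)) or "all source scenarios excluded"
            continue
        labels = frozenset().union(*(rs.labels for rs in pooled))
        note = ""
        if len({rs.labels for rs in pooled}) > 1 and len(labels) > 1:
            note = (
                f"marginalized over {criterion_name!r}: alternatives {sorted(labels)} pooled"
            )
        cells[s] = pooled[0] if len(pooled) == 1 else RecommendationSet.merge(pooled, note=note)
    return DecisionTable(table.participant_id, reduced, cells, excluded, table.finalisation_date)


def inclusion_filter(
    ensemble: list[DecisionTable],
    criterion_census: CriterionCensus | None = None,
    k: int = DEFAULT_INCLUSION_THRESHOLD,
) -> tuple[list[DecisionTable], list[ExclusionRecord]]:
    """Remove criteria used by fewer than ``k`` participants.

    Every exclusion is logged — dropping a criterion silently is never
    acceptable.  With ``k == 1`` this is the identity.
    """
    if k < 1:
        raise ValueError("inclusion threshold k must be >= 1")
    if not ensemble:
        return [], []
    if k == 1:
        # k=1 means "no exclusion": even a criterion nobody's table depends
        # on is kept, since the threshold exists to prune rare criteria,
        # not to second-guess the harmonized universe
        return list(ensemble), []
    if criterion_census is None:
        criterion_census = census(ensemble)
    all_names = sorted(set().union(*(set(t.criteria.names) for t in ensemble)))
    dropped = [n for n in all_names if criterion_census.count(n) < k]
    log = [
        ExclusionRecord(
            n, criterion_census.count(n), tuple(sorted(criterion_census.users.get(n, ()))), k
        )
        for n in dropped
    ]
    keep = [n for n in all_names if n not in dropped]
    if not keep:
        raise HarmonizationError(
            f"inclusion threshold k={k} would drop every criterion ({all_names!r})"
        )
    out = []
    for t in ensemble:
        reduced = t
        for n in dropped:
            if n in reduced.criteria:
                reduced = marginalize(reduced, n)
        out.append(reduced)
    return out, log
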