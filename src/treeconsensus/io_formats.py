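"""Text interchange formats.

Trees, criteria sets and harmonization rules travel as versioned YAML
documents; decision tables as RFC-4180-style CSV (UTF-8, LF, header row,
plus leading ``#key=value`` provenance lines).  Parsers reject rather than
repair: a missing field is an error, never silently defaulted.  Writers are
canonical — equal in-memory objects serialize to byte-identical documents.

Multiple recommendations within one table cell are joined by ``|``; for
``ranked`` cells the joined order IS the ranking (best first), otherwise
members are written in sorted label order.
"""

from __future__ import annotations

import csv
import datetime
import io
from dataclasses import dataclass

import yaml

from . import validation
from .harmonization import HarmonizationRule, RuleSet
from .tree_model import (
    Branch,
    Criterion,
    CriteriaSet,
    DecisionTable,
    DecisionTree,
    Internal,
    Leaf,
    ModelError,
    MULT_RANKED,
    MULT_SINGLE,
    Node,
    Recommendation,
    RecommendationSet,
    Scenario,
    scenario_space,
)

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "SemanticError",
    "TreeDocument",
    "TableRow",
    "parse_tree_document",
    "parse_tree",
    "write_tree",
    "parse_criteria",
    "write_criteria",
    "parse_rules",
    "write_rules",
    "read_table_rows",
    "parse_table",
    "write_table",
    "to_dot",
]

SCHEMA_VERSION = "1"


class SchemaError(ModelError):
    """The document does not match the published schema (malformed)."""


class SemanticError(ModelError):
    """The document is well-formed but violates a model invariant."""


@dataclass(frozen=True)
class TreeDocument:
    schema_version: str
    tree: DecisionTree
    criteria: CriteriaSet


# ---------------------------------------------------------------------------
# low-level helpers


def _require(data: dict, key: str, where: str):
    if not isinstance(data, dict):
        raise SchemaError(f"{where}: expected a mapping, got {type(data).__name__}")
    if key not in data:
        raise SchemaError(f"{where}: missing required key {key!r}")
    return data[key]


def _parse_date(value, where: str) -> datetime.date:
    if isinstance(value, datetime.date) and not isinstance(value, datetime.datetime):
        return value
    try:
        return datetime.date.fromisoformat(str(value))
    except ValueError as exc:
        raise SchemaError(f"{where}: not an ISO-8601 date: {value!r}") from exc


def _yaml_load(text: str, what: str) -> dict:
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"{what}: not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError(f"{what}: top level must be a mapping")
    return data


def _yaml_dump(data: dict) -> str:
    return yaml.safe_dump(data, sort_keys=False, allow_unicode=True, default_flow_style=False)


def _check_version(data: dict, what: str) -> str:
    version = str(_require(data, "schema_version", what))
    if version != SCHEMA_VERSION:
        raise SchemaError(f"{what}: unsupported schema_version {version!r}")
    return version


# ---------------------------------------------------------------------------
# criteria documents


def _criterion_from_data(data: dict, where: str) -> Criterion:
    name = str(_require(data, "name", where))
    levels = _require(data, "levels", where)
    if not isinstance(levels, list):
        raise SchemaError(f"{where}: levels must be a list")
    kwargs = {}
    if data.get("source_scale") is not None:
        kwargs["source_scale"] = str(data["source_scale"])
    if data.get("cutoff") is not None:
        kwargs["cutoff"] = float(data["cutoff"])
    try:
        return Criterion(
            name,
            tuple(str(v) for v in levels),
            description=str(data.get("description", "")),
            kind=str(data.get("kind", "categorical")),
            **kwargs,
        )
    except ModelError as exc:
        raise SemanticError(f"{where}: {exc}") from exc


def _criterion_to_data(c: Criterion) -> dict:
    data: dict = {"name": c.name, "levels": list(c.levels)}
    if c.description:
        data["description"] = c.description
    if c.kind != "categorical":
        data["kind"] = c.kind
    if c.source_scale is not None:
        data["source_scale"] = c.source_scale
    if c.cutoff is not None:
        data["cutoff"] = c.cutoff
    return data


def parse_criteria(text: str) -> CriteriaSet:
    data = _yaml_load(text, "criteria document")
    _check_version(data, "criteria document")
    entries = _require(data, "criteria", "criteria document")
    if not isinstance(entries, list) or not entries:
        raise SchemaError("criteria document: 'criteria' must be a nonempty list")
    try:
        return CriteriaSet(
            _criterion_from_data(e, f"criteria[{i}]") for i, e in enumerate(entries)
        )
    except ModelError as exc:
        if isinstance(exc, (SchemaError, SemanticError)):
            raise
        raise SemanticError(f"criteria document: {exc}") from exc


def write_criteria(criteria: CriteriaSet) -> str:
    return _yaml_dump(
        {"schema_version": SCHEMA_VERSION, "criteria": [_criterion_to_data(c) for c in criteria]}
    )


# ---------------------------------------------------------------------------
# tree documents


def _rset_from_data(data: dict, where: str) -> RecommendationSet:
    raw = _require(data, "recommendations", where)
    if not isinstance(raw, list) or not raw:
        raise SchemaError(f"{where}: 'recommendations' must be a nonempty list")
    members = []
    for i, entry in enumerate(raw):
        if isinstance(entry, dict):
            label = str(_require(entry, "label", f"{where}.recommendations[{i}]"))
            attrs = entry.get("attributes", {})
            if not isinstance(attrs, dict):
                raise SchemaError(f"{where}.recommendations[{i}]: attributes must be a mapping")
            members.append(Recommendation(label, tuple((str(k), str(v)) for k, v in attrs.items())))
        else:
            members.append(Recommendation(str(entry)))
    multiplicity = str(data.get("multiplicity", MULT_SINGLE))
    ranking = data.get("ranking")
    if multiplicity == MULT_RANKED and ranking is None:
        # the list order of a ranked cell is the ranking
        ranking = [m.label for m in members]
    try:
        return RecommendationSet(
            tuple(members),
            multiplicity,
            tuple(str(r) for r in ranking) if ranking is not None else None,
            note=str(data.get("note", "")),
        )
    except ModelError as exc:
        raise SemanticError(f"{where}: {exc}") from exc


def _rset_to_data(rs: RecommendationSet) -> dict:
    order = rs.ranking if rs.multiplicity == MULT_RANKED and rs.ranking else rs.sorted_labels
    by_label = {m.label: m for m in rs.members}
    recs = []
    for label in order:
        m = by_label[label]
        if m.attributes:
            recs.append({"label": m.label, "attributes": dict(m.attributes)})
        else:
            recs.append(m.label)
    data: dict = {"recommendations": recs, "multiplicity": rs.multiplicity}
    if rs.note:
        data["note"] = rs.note
    return data


def _node_from_data(data: dict, criteria: CriteriaSet, where: str) -> Node:
    if not isinstance(data, dict):
        raise SchemaError(f"{where}: expected a mapping")
    if "recommendations" in data:
        return Leaf(_rset_from_data(data, where))
    criterion = str(_require(data, "criterion", where))
    raw_branches = _require(data, "branches", where)
    if not isinstance(raw_branches, list) or not raw_branches:
        raise SchemaError(f"{where}: 'branches' must be a nonempty list")
    branches = []
    for i, b in enumerate(raw_branches):
        bw = f"{where}.branches[{i}]"
        levels = _require(b, "levels", bw)
        if not isinstance(levels, list) or not levels:
            raise SchemaError(f"{bw}: 'levels' must be a nonempty list")
        levels = [str(v) for v in levels]
        # normalize to the criterion's level order; unknown levels keep
        # document order at the end (validation will flag them)
        if criterion in criteria:
            order = {lv: i for i, lv in enumerate(criteria[criterion].levels)}
            levels = sorted(levels, key=lambda lv: (order.get(lv, len(order)),))
        child = _node_from_data(_require(b, "node", bw), criteria, f"{bw}.node")
        branches.append(Branch(tuple(levels), child))
    return Internal(criterion, tuple(branches))


def _node_to_data(node: Node, criteria: CriteriaSet) -> dict:
    if isinstance(node, Leaf):
        return _rset_to_data(node.recommendations)
    branches = []
    for b in node.branches:
        levels = list(b.levels)
        if node.criterion in criteria:
            order = {lv: i for i, lv in enumerate(criteria[node.criterion].levels)}
            levels = sorted(levels, key=lambda lv: (order.get(lv, len(order)),))
        branches.append({"levels": levels, "node": _node_to_data(b.node, criteria)})
    return {"criterion": node.criterion, "branches": branches}


def _check_tree_strict(tree: DecisionTree, criteria: CriteriaSet) -> None:
    report = validation.validate_tree(tree, criteria)
    bad = [i for i in report.issues if i.category in validation.INVALIDATING_CATEGORIES]
    if bad:
        first = bad[0]
        raise SemanticError(
            f"tree for {tree.participant_id!r} violates model invariants "
            f"({len(bad)} issue(s); first: [{first.category}] at {first.location}: "
            f"{first.message})"
        )

    def no_repeats(node: Node, seen: frozenset[str]) -> None:
        if isinstance(node, Internal):
            if node.criterion in seen:
                raise SemanticError(
                    f"criterion {node.criterion!r} re-tested on a root-to-leaf path"
                )
            for b in node.branches:
                no_repeats(b.node, seen | {node.criterion})

    no_repeats(tree.root, frozenset())


def parse_tree_document(text: str, strict: bool = True) -> TreeDocument:
    """Parse a tree document; ``strict=False`` admits draft (defective) trees
    so the validation workflow can inspect them."""
    data = _yaml_load(text, "tree document")
    version = _check_version(data, "tree document")
    participant = _require(data, "participant", "tree document")
    pid = str(_require(participant, "id", "participant"))
    date = None
    if participant.get("finalisation_date") is not None:
        date = _parse_date(participant["finalisation_date"], "participant.finalisation_date")
    entries = _require(data, "criteria", "tree document")
    if not isinstance(entries, list) or not entries:
        raise SchemaError("tree document: 'criteria' must be a nonempty list")
    criteria = CriteriaSet(_criterion_from_data(e, f"criteria[{i}]") for i, e in enumerate(entries))
    root = _node_from_data(_require(data, "tree", "tree document"), criteria, "tree")
    tree = DecisionTree(pid, root, date)
    if strict:
        _check_tree_strict(tree, criteria)
    return TreeDocument(version, tree, criteria)


def parse_tree(text: str, strict: bool = True) -> DecisionTree:
    return parse_tree_document(text, strict=strict).tree


def write_tree(tree: DecisionTree, criteria: CriteriaSet) -> str:
    participant: dict = {"id": tree.participant_id}
    if tree.finalisation_date is not None:
        participant["finalisation_date"] = tree.finalisation_date.isoformat()
    return _yaml_dump(
        {
            "schema_version": SCHEMA_VERSION,
            "participant": participant,
            "criteria": [_criterion_to_data(c) for c in criteria],
            "tree": _node_to_data(tree.root, criteria),
        }
    )


# ---------------------------------------------------------------------------
# harmonization rule documents


def parse_rules(text: str) -> RuleSet:
    data = _yaml_load(text, "rules document")
    _check_version(data, "rules document")
    entries = _require(data, "harmonized_criteria", "rules document")
    if not isinstance(entries, list) or not entries:
        raise SchemaError("rules document: 'harmonized_criteria' must be a nonempty list")
    criteria = CriteriaSet(
        _criterion_from_data(e, f"harmonized_criteria[{i}]") for i, e in enumerate(entries)
    )
    rules = []
    for i, r in enumerate(data.get("rules", []) or []):
        where = f"rules[{i}]"
        source = str(_require(r, "source", where))
        target = str(_require(r, "target", where))
        level_map = _require(r, "map", where)
        if not isinstance(level_map, dict) or not level_map:
            raise SchemaError(f"{where}: 'map' must be a nonempty mapping")
        participants = r.get("participants")
        if participants is not None and participants != "*":
            if not isinstance(participants, list):
                raise SchemaError(f"{where}: 'participants' must be a list or '*'")
            participants = frozenset(str(p) for p in participants)
        else:
            participants = None
        kwargs = {}
        if r.get("source_scale") is not None:
            kwargs["source_scale"] = str(r["source_scale"])
        if r.get("cutoff") is not None:
            kwargs["cutoff"] = float(r["cutoff"])
        rules.append(
            HarmonizationRule(
                source,
                target,
                tuple((str(k), str(v)) for k, v in level_map.items()),
                participants,
                note=str(r.get("note", "")),
                **kwargs,
            )
        )
    annotations = tuple(str(a) for a in data.get("setting_annotations", []) or [])
    return RuleSet(criteria, tuple(rules), annotations)


def write_rules(ruleset: RuleSet) -> str:
    rules = []
    for r in ruleset.rules:
        entry: dict = {"source": r.source, "target": r.target, "map": dict(r.level_map)}
        if r.participants is not None:
            entry["participants"] = sorted(r.participants)
        if r.source_scale is not None:
            entry["source_scale"] = r.source_scale
        if r.cutoff is not None:
            entry["cutoff"] = r.cutoff
        if r.note:
            entry["note"] = r.note
        rules.append(entry)
    data: dict = {
        "schema_version": SCHEMA_VERSION,
        "harmonized_criteria": [_criterion_to_data(c) for c in ruleset.criteria],
        "rules": rules,
    }
    if ruleset.setting_annotations:
        data["setting_annotations"] = list(ruleset.setting_annotations)
    return _yaml_dump(data)


# ---------------------------------------------------------------------------
# decision tables (CSV)

_EXCLUDED = "excluded"
_FIXED_COLUMNS = ("recommendations", "multiplicity", "note")


@dataclass(frozen=True)
class TableRow:
    """One parsed CSV row; ``recommendations is None`` marks an exclusion."""

    line_no: int
    assignment: dict[str, str]
    recommendations: RecommendationSet | None
    excluded_reason: str = ""


def read_table_rows(text: str, criteria: CriteriaSet) -> tuple[str, datetime.date | None, list[TableRow]]:
    """Parse CSV into raw rows without enforcing table-level invariants.

    Returns ``(participant_id, finalisation_date, rows)``.  Only schema
    problems raise; duplicate/missing/unknown-level rows are left to
    :func:`treeconsensus.validation.validate_table`.
    """
    meta: dict[str, str] = {}
    body_lines = []
    offset = 0
    for line in text.splitlines():
        if line.startswith("#") and not body_lines:
            key, sep, value = line[1:].partition("=")
            if sep:
                meta[key.strip()] = value.strip()
            offset += 1
        else:
            body_lines.append(line)
    pid = meta.get("participant_id", "")
    date = _parse_date(meta["finalisation_date"], "finalisation_date") if "finalisation_date" in meta else None
    reader = csv.reader(io.StringIO("\n".join(body_lines)))
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError("table: empty document (header row required)") from None
    for col in _FIXED_COLUMNS:
        if col not in header:
            raise SchemaError(f"table header: missing required column {col!r}")
    crit_cols = [c for c in header if c not in _FIXED_COLUMNS]
    if not crit_cols:
        raise SchemaError("table header: no criterion columns")
    idx = {c: header.index(c) for c in header}
    rows: list[TableRow] = []
    for line_no, record in enumerate(reader, start=offset + 2):
        if not record or all(not f for f in record):
            continue
        if len(record) != len(header):
            raise SchemaError(
                f"table line {line_no}: expected {len(header)} fields, got {len(record)}"
            )
        assignment = {c: record[idx[c]] for c in crit_cols}
        multiplicity = record[idx["multiplicity"]].strip()
        note = record[idx["note"]]
        rec_field = record[idx["recommendations"]]
        if multiplicity == _EXCLUDED:
            if rec_field:
                raise SchemaError(
                    f"table line {line_no}: excluded row must have empty recommendations"
                )
            rows.append(TableRow(line_no, assignment, None, note))
            continue
        labels = [x for x in rec_field.split("|") if x.strip()]
        if not labels:
            raise SchemaError(f"table line {line_no}: empty recommendations")
        if not multiplicity:
            raise SchemaError(f"table line {line_no}: missing multiplicity")
        try:
            if multiplicity == MULT_RANKED:
                rs = RecommendationSet.ranked(*labels, note=note)
            else:
                rs = RecommendationSet(
                    tuple(Recommendation(x) for x in labels), multiplicity, note=note
                )
        except ModelError as exc:
            raise SchemaError(f"table line {line_no}: {exc}") from exc
        rows.append(TableRow(line_no, assignment, rs))
    return pid, date, rows


def parse_table(text: str, criteria: CriteriaSet | None = None) -> DecisionTable:
    """Parse a complete decision table; raises on duplicates and bad levels.

    With ``criteria=None`` the criteria are inferred from the observed
    columns and cell values, with levels in sorted order.
    """
    if criteria is None:
        inferred_pid, _, raw = read_table_rows_infer(text)
        criteria = raw
        pid, date, rows = read_table_rows(text, criteria)
    else:
        pid, date, rows = read_table_rows(text, criteria)
    report = validation.validate_table(rows, criteria, pid)
    fatal = [
        i
        for i in report.issues
        if i.category in (validation.CONFLICT, validation.OVERLAP, validation.UNKNOWN_LEVEL)
    ]
    if fatal:
        first = fatal[0]
        raise SemanticError(
            f"table for {pid!r}: {len(fatal)} defect(s); first: [{first.category}] "
            f"at {first.location}: {first.message}"
        )
    cells: dict[Scenario, RecommendationSet] = {}
    excluded: dict[Scenario, str] = {}
    for row in rows:
        s = Scenario.from_mapping(row.assignment)
        if row.recommendations is None:
            excluded[s] = row.excluded_reason
        else:
            cells[s] = row.recommendations
    return DecisionTable(pid, criteria, cells, excluded, date)


def read_table_rows_infer(text: str) -> tuple[str, datetime.date | None, CriteriaSet]:
    """Infer a CriteriaSet (sorted levels) from a table's criterion columns."""
    body = [ln for ln in text.splitlines() if not ln.startswith("#")]
    reader = csv.reader(io.StringIO("\n".join(body)))
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError("table: empty document (header row required)") from None
    crit_cols = [c for c in header if c not in _FIXED_COLUMNS]
    if not crit_cols:
        raise SchemaError("table header: no criterion columns")
    observed: dict[str, set[str]] = {c: set() for c in crit_cols}
    for record in reader:
        if not record or all(not f for f in record):
            continue
        for c in crit_cols:
            observed[c].add(record[header.index(c)])
    try:
        criteria = CriteriaSet(
            Criterion(c, tuple(sorted(observed[c]))) for c in crit_cols
        )
    except ModelError as exc:
        raise SemanticError(f"table: cannot infer criteria: {exc}") from exc
    meta: dict[str, str] = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        key, sep, value = line[1:].partition("=")
        if sep:
            meta[key.strip()] = value.strip()
    pid = meta.get("participant_id", "")
    date = _parse_date(meta["finalisation_date"], "finalisation_date") if "finalisation_date" in meta else None
    return pid, date, criteria


def write_table(table: DecisionTable) -> str:
    """Canonical CSV: provenance comments, header, rows in scenario order."""
    buf = io.StringIO()
    buf.write(f"#participant_id={table.participant_id}\n")
    if table.finalisation_date is not None:
        buf.write(f"#finalisation_date={table.finalisation_date.isoformat()}\n")
    names = table.criteria.names
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(list(names) + list(_FIXED_COLUMNS))
    for s in scenario_space(table.criteria):
        levels = [s[n] for n in names]
        if s in table.excluded:
            w.writerow(levels + ["", _EXCLUDED, table.excluded[s]])
        elif s in table.cells:
            rs = table.cells[s]
            order = rs.ranking if rs.multiplicity == MULT_RANKED and rs.ranking else rs.sorted_labels
            w.writerow(levels + ["|".join(order), rs.multiplicity, rs.note])
        # incomplete tables simply omit the row; validation reports the gap
    return buf.getvalue()


# ---------------------------------------------------------------------------
# DOT export


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def to_dot(tree: DecisionTree, title: str | None = None) -> str:
    """Graphviz DOT rendering of a tree (internal = box, leaf = ellipse)."""
    lines = ["digraph decision_tree {"]
    if title:
        lines.append(f'  label="{_dot_escape(title)}";')
    lines.append("  node [fontname=Helvetica];")
    counter = [0]

    def walk(node: Node) -> str:
        nid = f"n{counter[0]}"
        counter[0] += 1
        if isinstance(node, Leaf):
            rs = node.recommendations
            order = rs.ranking if rs.multiplicity == MULT_RANKED and rs.ranking else rs.sorted_labels
            sep = " > " if rs.multiplicity == MULT_RANKED else " / "
            lines.append(f'  {nid} [shape=ellipse, label="{_dot_escape(sep.join(order))}"];')
        else:
            lines.append(f'  {nid} [shape=box, label="{_dot_escape(node.criterion)}"];')
            for b in node.branches:
                child = walk(b.node)
                lines.append(
                    f'  {nid} -> {child} [label="{_dot_escape(", ".join(b.levels))}"];'
                )
        return nid

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines) + "\n"
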