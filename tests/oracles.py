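"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the code paths under test: trees are
checked by enumerating root-to-leaf constraint paths, scenario spaces by
nested loops, consensus tallies by direct counting over per-tree
evaluation, dependence by all-pairs scenario comparison, and the
mode-recovery probability by exact multinomial enumeration.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from treeconsensus.tree_model import Internal, Leaf


# --- path-enumeration oracle for tree evaluation ---------------------------


def enumerate_paths(node, constraints=None):
    """All root-to-leaf paths as (criterion -> allowed level set, leaf payload)."""
    if constraints is None:
        constraints = {}
    if isinstance(node, Leaf):
        return [(dict(constraints), node.recommendations)]
    paths = []
    for branch in node.branches:
        levels = set(branch.levels)
        if node.criterion in constraints:
            levels &= constraints[node.criterion]
        child = dict(constraints)
        child[node.criterion] = levels
        paths.extend(enumerate_paths(branch.node, child))
    return paths


def oracle_routes(tree, scenario):
    """Leaf payloads of every path consistent with the scenario."""
    out = []
    for constraints, payload in enumerate_paths(tree.root):
        ok = True
        for criterion, allowed in constraints.items():
            level = scenario.get(criterion)
            if level is None or level not in allowed:
                ok = False
                break
        if ok:
            out.append(payload)
    return out


def oracle_evaluate(tree, scenario):
    """The unique payload, or None (gap) — raises on ambiguity."""
    routes = oracle_routes(tree, scenario)
    if not routes:
        return None
    assert len(routes) == 1, f"ambiguous routing for {scenario}"
    return routes[0]


def oracle_gap_scenarios(tree, scenarios):
    return {s for s in scenarios if not oracle_routes(tree, s)}


# --- nested-loop scenario enumeration --------------------------------------


def oracle_scenario_dicts(criteria):
    """All total assignments by explicit nested recursion over sorted names."""
    names = sorted(c.name for c in criteria)

    def rec(i):
        if i == len(names):
            return [{}]
        out = []
        for level in criteria[names[i]].levels:
            for rest in rec(i + 1):
                d = {names[i]: level}
                d.update(rest)
                out.append(d)
        return out

    return rec(0)


# --- counting oracle for consensus cells -----------------------------------


def oracle_tally(vote_sets, fractional=True):
    """Tally a list of per-participant label collections (None = abstain).

    Returns (counts, n_voting, mode_set, congruency, majority) with exact
    Fractions, computed by straightforward counting.
    """
    counts = {}
    n_voting = 0
    for labels in vote_sets:
        if labels is None:
            continue
        n_voting += 1
        weight = Fraction(1, len(labels)) if fractional else Fraction(1)
        for label in labels:
            counts[label] = counts.get(label, Fraction(0)) + weight
    if n_voting == 0:
        return counts, 0, frozenset(), None, None
    top = max(counts.values())
    mode_set = frozenset(k for k, v in counts.items() if v == top)
    congruency = top / n_voting
    majority = None
    if len(mode_set) == 1 and 2 * top > n_voting:
        majority = next(iter(mode_set))
    return counts, n_voting, mode_set, congruency, majority


def oracle_consensus_cell(trees, scenario, policy, fractional=True):
    """Brute-force tally at one scenario by evaluating each tree directly."""
    vote_sets = []
    for tree in trees:
        payload = oracle_evaluate(tree, scenario)
        assert payload is not None, "oracle requires valid trees"
        if policy == "any-recommended":
            vote_sets.append(list(payload.sorted_labels))
        else:
            top = payload.top
            assert top is not None
            vote_sets.append([top])
    return oracle_tally(vote_sets, fractional)


# --- dependence oracle ------------------------------------------------------


def oracle_dependent_criteria(table):
    """Criteria c such that two scenarios differing ONLY in c give
    different cells, found by comparing every pair of populated cells."""
    items = list(table.cells.items())
    dependent = set()
    for i in range(len(items)):
        s1, v1 = items[i]
        for j in range(i + 1, len(items)):
            s2, v2 = items[j]
            if v1 == v2:
                continue
            diff = [k for k, v in s1.items if s2[k] != v]
            if len(diff) == 1:
                dependent.add(diff[0])
    return dependent


# --- regrouping oracle for harmonization ------------------------------------


def oracle_regroup(table, source_to_target_level, target_criteria):
    """Harmonized cells by scanning source cells and pooling labels by image.

    ``source_to_target_level``: source criterion -> (target name, level map).
    Returns target scenario dict (as sorted tuple) -> frozenset of labels.
    """
    pooled = {}
    for s, rs in table.cells.items():
        image = {}
        for name, level in s.items:
            target, level_map = source_to_target_level[name]
            image[target] = level_map[level]
        key = tuple(sorted(image.items()))
        pooled.setdefault(key, set()).update(rs.labels)
    return {k: frozenset(v) for k, v in pooled.items()}


# --- exact mode-recovery probability ----------------------------------------


def _compositions(n, k):
    if k == 1:
        yield (n,)
        return
    for i in range(n + 1):
        for rest in _compositions(n - i, k - 1):
            yield (i,) + rest


def exact_unique_mode_recovery(n_participants, n_labels, deviation_rate):
    """P(truth label is the unique mode) when each of n participants keeps
    the truth with probability 1-eps and otherwise votes uniformly for one
    of the other labels.  Exact multinomial enumeration over count vectors.
    """
    eps = Fraction(deviation_rate).limit_denominator(10**9)
    p_truth = 1 - eps
    p_other = eps / (n_labels - 1)
    total = Fraction(0)
    for counts in _compositions(n_participants, n_labels):
        if counts[0] <= max(counts[1:]):
            continue
        coeff = 1
        left = n_participants
        for c in counts:
            coeff *= comb(left, c)
            left -= c
        total += coeff * p_truth ** counts[0] * p_other ** (n_participants - counts[0])
    return total
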