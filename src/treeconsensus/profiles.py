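"""Ensemble-level binary profiles: which criteria drive each participant's
decisions, and which treatments each participant offers.

"Uses criterion c" means semantic dependence of the participant's expanded
table on c — two scenarios differing only in c with different
recommendation sets — not the mere syntactic presence of a test in the
tree, so vacuous splits do not inflate the profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tree_model import DecisionTable, ModelError, depends_on

__all__ = ["BinaryProfileMatrix", "criteria_usage", "treatment_portfolio", "RENDERING_HINTS"]

#: Conventional rendering of profile matrices in the published figures.
RENDERING_HINTS = {"true": "green", "false": "red"}


@dataclass
class BinaryProfileMatrix:
    """Boolean participants x features matrix with deterministic ordering
    (rows sorted by participant id, columns lexicographic)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates or self.frame.columns.has_duplicates:
            raise ModelError("profile matrix labels must be unique")
        self.frame = self.frame.sort_index().sort_index(axis=1).astype(bool)

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def cell(self, participant_id: str, feature: str) -> bool:
        return bool(self.frame.at[participant_id, feature])

    def column_sums(self) -> dict[str, int]:
        return {c: int(n) for c, n in self.frame.sum(axis=0).items()}

    def to_csv(self) -> str:
        out = self.frame.map(lambda v: "true" if v else "false")
        out.index.name = "participant_id"
        return out.to_csv(lineterminator="\n")


def _shared_criteria(ensemble: list[DecisionTable]):
    if not ensemble:
        raise ModelError("profile of an empty ensemble is undefined")
    criteria = ensemble[0].criteria
    for t in ensemble[1:]:
        if t.criteria != criteria:
            raise ModelError(
                f"table for {t.participant_id!r} does not share the ensemble criteria set"
            )
    pids = [t.participant_id for t in ensemble]
    if len(set(pids)) != len(pids):
        raise ModelError("duplicate participant ids in ensemble")
    return criteria


def criteria_usage(ensemble: list[DecisionTable]) -> BinaryProfileMatrix:
    """Participants x criteria: true iff the table depends on the criterion."""
    criteria = _shared_criteria(ensemble)
    data = {
        t.participant_id: {name: depends_on(t, name) for name in criteria.names}
        for t in ensemble
    }
    return BinaryProfileMatrix(pd.DataFrame.from_dict(data, orient="index"))


def treatment_portfolio(ensemble: list[DecisionTable]) -> BinaryProfileMatrix:
    """Participants x treatments: true iff the label appears in any cell.

    The column universe is the union of labels over the whole ensemble, so
    a treatment nobody offers never appears.
    """
    _shared_criteria(ensemble)
    universe = sorted(set().union(*(t.labels() for t in ensemble)))
    data = {
        t.participant_id: {label: label in t.labels() for label in universe}
        for t in ensemble
    }
    frame = pd.DataFrame.from_dict(data, orient="index")
    if not universe:  # degenerate: no populated cells anywhere
        frame = pd.DataFrame(index=[t.participant_id for t in ensemble])
    return BinaryProfileMatrix(frame)
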