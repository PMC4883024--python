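"""Rich-club node selection and rich-club / feeder / local edge taxonomy.

Given a rich-club node set, every present edge falls into exactly one class:

* ``rich_club`` — both endpoints are rich-club nodes,
* ``feeder``    — exactly one endpoint is,
* ``local``     — neither is.

Node selection follows a rule cascade: nodes whose group-mean fiber-density
degree clears a floor in *every* diagnostic group are selected; bilateral
homologues and explicitly named regions can be force-included.  The
published 26-node membership (13 bilateral regions) ships with the package
(:func:`richclub.network_model.canonical_rich_club_labels`) so downstream
stages can be run exactly as reported.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network_model import Cohort, Group, SubjectRecord, nodal_degree

__all__ = ["EdgeClass", "RichNodeSet", "EdgeClassMap", "select_rich_nodes",
           "classify_edges", "per_subject_class_counts"]


class EdgeClass(str, enum.Enum):
    rich_club = "rich_club"
    feeder = "feeder"
    local = "local"


@dataclass(frozen=True)
class RichNodeSet:
    """A rich-club node membership plus the rule that produced it."""

    members: frozenset[int]
    labels: tuple[str, ...] = ()
    selection_rule: Mapping[str, object] = field(default_factory=dict)

    @classmethod
    def from_labels(
        cls, member_labels: Iterable[str], node_labels: Sequence[str],
        rule: Mapping[str, object] | None = None,
    ) -> "RichNodeSet":
        index = {lab: i for i, lab in enumerate(node_labels)}
        missing = [lab for lab in member_labels if lab not in index]
        if missing:
            raise KeyError(f"labels not in node list: {missing}")
        members = frozenset(index[lab] for lab in member_labels)
        return cls(members=members,
                   labels=tuple(node_labels[i] for i in sorted(members)),
                   selection_rule=dict(rule or {"source": "explicit_labels"}))


@dataclass
class EdgeClassMap:
    """Partition of present edges into rich-club / feeder / local."""

    classes: dict[tuple[int, int], EdgeClass]
    counts: dict[EdgeClass, int]

    def edges_of(self, cls: EdgeClass | str) -> list[tuple[int, int]]:
        cls = EdgeClass(cls)
        return sorted(e for e, c in self.classes.items() if c is cls)


def _homologue(label: str) -> str:
    if label.startswith("lh_"):
        return "rh_" + label[3:]
    if label.startswith("rh_"):
        return "lh_" + label[3:]
    return label


def select_rich_nodes(
    cohort: Cohort,
    k_threshold: int = 15,
    degree_floor: int = 30,
    top_fraction: float = 0.12,
    overrides: Sequence[str] = (),
    bilateral: bool = True,
) -> RichNodeSet:
    """Select rich-club nodes from group-mean fiber-density degree.

    A node is selected when its mean degree (fiber-density support) is at
    least ``degree_floor`` in every diagnostic group present in the cohort.
    With ``bilateral=True``, a node whose contralateral homologue qualifies
    is pulled in too, keeping the membership hemispherically symmetric.
    ``overrides`` force-includes named regions regardless of degree.

    ``k_threshold`` and ``top_fraction`` are recorded in the selection rule
    for provenance; the operative criterion is the degree floor, which is
    how the published membership extends the k > 15 rich-club regime.
    """
    if not cohort.subjects:
        raise ValueError("cohort is empty")
    labels = cohort.node_labels
    index = {lab: i for i, lab in enumerate(labels)}
    bad = [lab for lab in overrides if lab not in index]
    if bad:
        raise KeyError(f"override labels not in node list: {bad}")

    group_means = []
    for g in cohort.groups():
        degs = np.vstack([nodal_degree(s.fiber_density) for s in cohort.by_group(g)])
        group_means.append(degs.mean(axis=0))
    group_means = np.vstack(group_means)
    qualifies = (group_means >= degree_floor).all(axis=0)

    members = set(np.flatnonzero(qualifies).tolist())
    if bilateral:
        for i in list(members):
            twin = _homologue(labels[i])
            if twin in index:
                members.add(index[twin])
    members.update(index[lab] for lab in overrides)

    rule = {
        "k_threshold": k_threshold,
        "degree_floor": degree_floor,
        "top_fraction": top_fraction,
        "bilateral": bilateral,
        "overrides": tuple(overrides),
    }
    return RichNodeSet(
        members=frozenset(members),
        labels=tuple(labels[i] for i in sorted(members)),
        selection_rule=rule,
    )


def classify_edges(
    support: Iterable[tuple[int, int]], rich: RichNodeSet | frozenset[int]
) -> EdgeClassMap:
    """Assign every present edge to rich_club / feeder / local."""
    members = rich.members if isinstance(rich, RichNodeSet) else frozenset(rich)
    classes: dict[tuple[int, int], EdgeClass] = {}
    counts = {c: 0 for c in EdgeClass}
    for i, j in support:
        key = (min(i, j), max(i, j))
        n_rich = (i in members) + (j in members)
        cls = (EdgeClass.local, EdgeClass.feeder, EdgeClass.rich_club)[n_rich]
        classes[key] = cls
        counts[cls] += 1
    return EdgeClassMap(classes=classes, counts=counts)


def per_subject_class_counts(
    subject: SubjectRecord, rich: RichNodeSet
) -> tuple[int, int, int]:
    """(rich_club, feeder, local) edge counts over the subject's present edges.

    Counts are taken on the fiber-density support, which defines edge
    existence for all three weight kinds.  Group means of these counts serve
    as the expected class totals in the chi-squared enrichment tests.
    """
    cmap = classify_edges(subject.fiber_density.edge_list(), rich)
    return (cmap.counts[EdgeClass.rich_club],
            cmap.counts[EdgeClass.feeder],
            cmap.counts[EdgeClass.local])
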