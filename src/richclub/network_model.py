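"""Core data types and elementary measures for cortical structural connectomes.

A connectome here is an undirected weighted network over the 68 cortical
regions of the Desikan–Killiany atlas (34 per hemisphere).  Edge weights come
in three kinds derived from diffusion MRI tractography:

* ``fiber_density`` — normalized streamline count linking two regions,
* ``FA``            — mean fractional anisotropy along the connecting tracts
  (dimensionless, in [0, 1]),
* ``MD``            — mean diffusivity along the tracts (mm^2/s-scaled).

All three weight kinds of one subject share a single binary support: FA and
MD are only defined along tracts that exist, i.e. where fiber density is
nonzero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WeightKind",
    "Group",
    "ConnectomeMatrix",
    "SubjectRecord",
    "Cohort",
    "InvalidMatrixError",
    "dk68_labels",
    "canonical_rich_club_labels",
    "nodal_degree",
    "edge_count",
    "strength_distribution",
]

#: tolerance within which (i, j) and (j, i) entries may differ at load time
SYMMETRY_TOL = 1e-8


class InvalidMatrixError(ValueError):
    """Raised when a connectivity matrix violates its structural invariants."""


class WeightKind(str, enum.Enum):
    fiber_density = "fiber_density"
    FA = "FA"
    MD = "MD"


class Group(str, enum.Enum):
    control = "control"
    bvFTD = "bvFTD"
    EOAD = "EOAD"


def dk68_labels() -> list[str]:
    """Canonical ordered list of the 68 Desikan–Killiany cortical labels.

    Order convention: 34 left-hemisphere labels (``lh_`` prefix) followed by
    34 right-hemisphere labels, alphabetical within hemisphere.
    """
    text = resources.files("richclub.data").joinpath("dk68_labels.txt").read_text()
    labels = [ln.strip() for ln in text.splitlines() if ln.strip()]
    assert len(labels) == 68
    return labels


def canonical_rich_club_labels() -> list[str]:
    """The published 26-node rich-club membership (13 bilateral regions)."""
    text = resources.files("richclub.data").joinpath("rich_club_26.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip()]


def _validate_weights(
    weights: np.ndarray, weight_kind: WeightKind, symmetrize: bool = True
) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InvalidMatrixError(f"weights must be square, got shape {w.shape}")
    asym = np.abs(w - w.T).max() if w.size else 0.0
    if asym > SYMMETRY_TOL:
        raise InvalidMatrixError(
            f"matrix asymmetric beyond tolerance: max |w - w.T| = {asym:.3g}"
        )
    if symmetrize:
        w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    if (w < 0).any():
        raise InvalidMatrixError("negative edge weights are not allowed")
    if weight_kind is WeightKind.FA and (w > 1.0 + 1e-12).any():
        raise InvalidMatrixError("FA weights must lie in [0, 1]")
    return w


@dataclass(frozen=True)
class ConnectomeMatrix:
    """One subject's symmetric nonnegative connectivity matrix for one weight kind.

    Parameters
    ----------
    weights
        Square symmetric matrix of nonnegative reals; the diagonal is zeroed.
        Small asymmetries (< 1e-8) are averaged away; larger ones are errors.
    weight_kind
        Which edge-weight semantics the matrix carries.
    node_labels
        Ordered region names, one per row/column.  Defaults to the canonical
        68 Desikan–Killiany labels when the matrix is 68x68.
    """

    weights: np.ndarray
    weight_kind: WeightKind = WeightKind.fiber_density
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        kind = WeightKind(self.weight_kind)
        w = _validate_weights(self.weights, kind)
        labels = tuple(self.node_labels)
        if not labels:
            if w.shape[0] == 68:
                labels = tuple(dk68_labels())
            else:
                labels = tuple(f"node{i}" for i in range(w.shape[0]))
        if len(labels) != w.shape[0]:
            raise InvalidMatrixError(
                f"{len(labels)} labels for a {w.shape[0]}-node matrix"
            )
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "weight_kind", kind)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def support(self) -> np.ndarray:
        """Boolean adjacency of the binary support (weight strictly > 0)."""
        return self.weights > 0

    def edge_list(self) -> list[tuple[int, int]]:
        """Unordered present edges as (i, j) index pairs with i < j."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.weights[iu, ju] > 0
        return list(zip(iu[mask].tolist(), ju[mask].tolist()))


def nodal_degree(m: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """Number of distinct regions each node connects to (integer vector).

    Degree counts connections, not their weight: node i's degree is the
    number of j != i with weight(i, j) > 0.
    """
    w = m.weights if isinstance(m, ConnectomeMatrix) else _validate_weights(
        np.asarray(m, dtype=float), WeightKind.fiber_density
    )
    return (w > 0).sum(axis=1).astype(int)


def edge_count(m: ConnectomeMatrix | np.ndarray) -> int:
    """Number of unordered node pairs with positive weight (the symbol E)."""
    w = m.weights if isinstance(m, ConnectomeMatrix) else _validate_weights(
        np.asarray(m, dtype=float), WeightKind.fiber_density
    )
    return int(np.count_nonzero(np.triu(w, k=1) > 0))


def strength_distribution(m: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """Nodal strength: sum of incident edge weights per node."""
    w = m.weights if isinstance(m, ConnectomeMatrix) else _validate_weights(
        np.asarray(m, dtype=float), WeightKind.fiber_density
    )
    return w.sum(axis=1)


@dataclass
class SubjectRecord:
    """Matrices for all three weight kinds plus covariates for one subject."""

    subject_id: str
    matrices: dict[WeightKind, ConnectomeMatrix]
    age: float
    sex: str  # "M" or "F"
    brain_volume: float  # mm^3
    group: Group
    mmse: int | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.matrices = {WeightKind(k): v for k, v in self.matrices.items()}
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ValueError(f"MMSE must be in [0, 30], got {self.mmse}")
        fd = self.matrices.get(WeightKind.fiber_density)
        if fd is not None:
            support = fd.support()
            for kind, mat in self.matrices.items():
                if kind is WeightKind.fiber_density:
                    continue
                if (mat.weights[~support] > 0).any():
                    raise InvalidMatrixError(
                        f"{kind.value} has weight outside the fiber-density support "
                        f"for subject {self.subject_id}"
                    )

    @property
    def fiber_density(self) -> ConnectomeMatrix:
        return self.matrices[WeightKind.fiber_density]


@dataclass
class Cohort:
    """A list of subjects plus the pooled edge support.

    Node pairs where every subject has zero weight carry no information and
    are excluded from all edgewise analyses; ``edge_support`` is the set of
    (i, j) pairs (i < j) with at least one subject nonzero.
    """

    subjects: list[SubjectRecord]
    edge_support: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.subjects and not self.edge_support:
            self.edge_support = self._compute_support()

    def _compute_support(self) -> frozenset[tuple[int, int]]:
        n = self.subjects[0].fiber_density.n_nodes
        any_present = np.zeros((n, n), dtype=bool)
        for s in self.subjects:
            any_present |= s.fiber_density.support()
        iu, ju = np.triu_indices(n, k=1)
        mask = any_present[iu, ju]
        return frozenset(zip(iu[mask].tolist(), ju[mask].tolist()))

    @property
    def n_nodes(self) -> int:
        return self.subjects[0].fiber_density.n_nodes

    @property
    def node_labels(self) -> tuple[str, ...]:
        return self.subjects[0].fiber_density.node_labels

    def by_group(self, group: Group | str) -> list[SubjectRecord]:
        group = Group(group)
        return [s for s in self.subjects if s.group is group]

    def groups(self) -> list[Group]:
        seen: list[Group] = []
        for s in self.subjects:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def sorted_support(self) -> list[tuple[int, int]]:
        return sorted(self.edge_support)

    def weight_table(self, kind: WeightKind | str) -> np.ndarray:
        """Subjects x supported-edges weight matrix (edge order = sorted support)."""
        kind = WeightKind(kind)
        edges = self.sorted_support()
        out = np.empty((len(self.subjects), len(edges)))
        for si, s in enumerate(self.subjects):
            w = s.matrices[kind].weights
            out[si] = [w[i, j] for i, j in edges]
        return out

    def covariate_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "brain_volume": [s.brain_volume for s in self.subjects],
                "group": [s.group.value for s in self.subjects],
                "mmse": [s.mmse for s in self.subjects],
            }
        )
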