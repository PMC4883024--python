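"""Readers and writers for matrices, covariates, memberships and results.

All on-disk formats are plain text: connectivity matrices are TSV (68 rows x
68 columns, with an optional header row/column of region labels, auto-
detected on read), covariates a CSV table, node memberships one label per
line, and result summaries TSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classes import EdgeClassMap, RichNodeSet
from .network_model import Cohort, ConnectomeMatrix, Group, SubjectRecord, WeightKind
from .rich_club import RichClubCurve

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_covariates_csv",
    "write_covariates_csv",
    "load_cohort",
    "write_cohort",
    "read_membership",
    "write_membership",
    "write_edge_classes",
    "write_curve_tsv",
    "write_json",
]


def read_matrix_tsv(
    path: str | Path,
    weight_kind: WeightKind | str = WeightKind.fiber_density,
) -> ConnectomeMatrix:
    """Read a square TSV connectivity matrix, auto-detecting a label header."""
    path = Path(path)
    first = path.open().readline().rstrip("\n").split("\t")
    has_header = any(_is_not_number(tok) for tok in first if tok != "")
    if has_header:
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = tuple(str(c) for c in df.columns)
        values = df.to_numpy(dtype=float)
    else:
        values = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        labels = ()
    return ConnectomeMatrix(values, WeightKind(weight_kind), labels)


def _is_not_number(tok: str) -> bool:
    try:
        float(tok)
        return False
    except ValueError:
        return True


def write_matrix_tsv(m: ConnectomeMatrix, path: str | Path, header: bool = True) -> None:
    path = Path(path)
    if header:
        df = pd.DataFrame(m.weights, index=m.node_labels, columns=m.node_labels)
        df.to_csv(path, sep="\t")
    else:
        pd.DataFrame(m.weights).to_csv(path, sep="\t", header=False, index=False)


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "age", "sex", "brain_volume", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    if "mmse" not in df.columns:
        df["mmse"] = pd.NA
    return df


def write_covariates_csv(cohort: Cohort, path: str | Path) -> None:
    cohort.covariate_frame().to_csv(path, index=False)


_KIND_SUFFIX = {
    WeightKind.fiber_density: "fiber_density",
    WeightKind.FA: "FA",
    WeightKind.MD: "MD",
}


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write per-subject matrix TSVs plus the covariates CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        for kind, m in s.matrices.items():
            write_matrix_tsv(m, out / f"{s.subject_id}_{_KIND_SUFFIX[kind]}.tsv")
    write_covariates_csv(cohort, out / "covariates.csv")


def load_cohort(data_dir: str | Path, covariates: str | Path | None = None) -> Cohort:
    """Load a cohort from ``<subject_id>_<kind>.tsv`` matrices and a covariates CSV."""
    data_dir = Path(data_dir)
    cov = read_covariates_csv(covariates or data_dir / "covariates.csv")
    subjects = []
    for row in cov.itertuples(index=False):
        matrices = {}
        for kind, suffix in _KIND_SUFFIX.items():
            p = data_dir / f"{row.subject_id}_{suffix}.tsv"
            if p.exists():
                matrices[kind] = read_matrix_tsv(p, kind)
        if WeightKind.fiber_density not in matrices:
            raise FileNotFoundError(
                f"no fiber-density matrix for subject {row.subject_id} in {data_dir}"
            )
        mmse = None if pd.isna(row.mmse) else int(row.mmse)
        subjects.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                matrices=matrices,
                age=float(row.age),
                sex=str(row.sex),
                brain_volume=float(row.brain_volume),
                group=Group(row.group),
                mmse=mmse,
            )
        )
    return Cohort(subjects=subjects)


def read_membership(path: str | Path, node_labels: Sequence[str]) -> RichNodeSet:
    labels = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return RichNodeSet.from_labels(labels, node_labels, rule={"source": str(path)})


def write_membership(rich: RichNodeSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{lab}\n" for lab in rich.labels))


def write_edge_classes(
    cmap: EdgeClassMap, node_labels: Sequence[str], path: str | Path
) -> None:
    rows = [
        {"node_i": node_labels[i], "node_j": node_labels[j], "class": cls.value}
        for (i, j), cls in sorted(cmap.classes.items())
    ]
    pd.DataFrame(rows, columns=["node_i", "node_j", "class"]).to_csv(
        path, sep="\t", index=False
    )


def write_curve_tsv(
    curves: Iterable[tuple[str, RichClubCurve]], path: str | Path
) -> None:
    """Long-format curve table: subject_id, weight_kind, k, phi_w, phi_rand_mean, phi_norm."""
    rows = []
    for subject_id, c in curves:
        for k, pw, prm, pn in zip(c.k_values, c.phi_w, c.phi_rand_mean, c.phi_norm):
            rows.append(
                {
                    "subject_id": subject_id,
                    "weight_kind": c.weight_kind.value,
                    "k": int(k),
                    "phi_w": pw,
                    "phi_rand_mean": prm,
                    "phi_norm": pn,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj
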