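"""End-to-end orchestration: curves, node selection, group tests, enrichment.

``run_pipeline`` executes the full published analysis on a cohort:
per-subject normalized rich-club curves, rich-node selection, edge
classification, permutation group tests of global measures (edge count E,
per-class edge counts, phi_n per k with FDR across k), nodal-degree and
edgewise tests with FDR, chi-squared enrichment of the altered edges over
the rich-club / feeder / local classes, and the MMSE association — and
writes result tables plus a run manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classes import EdgeClass, RichNodeSet, classify_edges, per_subject_class_counts, select_rich_nodes
from .inference import (
    Chi2Result,
    chi2_proportions,
    edgewise_group_test,
    fdr_bh,
    mmse_association,
    nodal_degree_group_test,
    permutation_group_test,
    residualize,
)
from .network_model import Cohort, Group, WeightKind, edge_count
from .rich_club import rich_club_curve
from .io import write_curve_tsv, write_edge_classes, write_json, write_membership

__all__ = ["PipelineConfig", "run_pipeline", "chi2_class_report"]


@dataclass
class PipelineConfig:
    """All tunable parameters of one analysis run.

    Defaults are the reference values: rich-club regime threshold k > 15,
    degree floor 30 for node selection, 500 random networks for curve
    normalization, 10,000 label permutations, FDR level q = 0.05.
    """

    k_threshold: int = 15
    degree_floor: int = 30
    top_fraction: float = 0.12
    n_random: int = 500
    permutations: int = 10000
    fdr_q: float = 0.05
    k_max: int = 30
    seed: int = 0
    contrasts: tuple[tuple[str, str], ...] = (
        ("bvFTD", "control"),
        ("EOAD", "control"),
        ("bvFTD", "EOAD"),
    )
    weight_kinds: tuple[str, ...] = ("fiber_density", "FA", "MD")
    membership_file: str | None = None  # use a fixed membership instead of selecting
    compute_curves: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("k_threshold", "degree_floor", "n_random", "permutations", "k_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0, 1)")


def _covariates(subjects):
    import pandas as pd

    return pd.DataFrame(
        {
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "brain_volume": [s.brain_volume for s in subjects],
        }
    )


def chi2_class_report(
    affected: dict[str, int], totals: dict[str, int]
) -> dict[str, object]:
    """Overall and pairwise chi-squared tests of class-wise affected proportions.

    ``affected`` and ``totals`` map class names (e.g. rich_club/feeder/local)
    to counts.  The overall test uses the full 2 x C table; each class pair
    gets its own 2 x 2 test.  This is also how counts printed in a report
    can be re-tested directly.
    """
    names = list(totals)
    aff = [affected.get(c, 0) for c in names]
    tot = [totals[c] for c in names]
    overall = chi2_proportions(aff, tot)
    report: dict[str, object] = {
        "classes": names,
        "affected": aff,
        "totals": tot,
        "chi2": overall.chi2,
        "df": overall.df,
        "p": overall.p,
        "pairwise": {},
    }
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            if tot[a] == 0 or tot[b] == 0:
                continue
            pair = chi2_proportions([aff[a], aff[b]], [tot[a], tot[b]])
            report["pairwise"][f"{names[a]}_vs_{names[b]}"] = {
                "chi2": pair.chi2,
                "p": pair.p,
            }
    return report


def _global_measure_tests(cohort, rich, contrast, m, seed, q):
    """Permutation tests of E and per-class edge counts for one contrast."""
    g1, g0 = Group(contrast[0]), Group(contrast[1])
    subjects = [s for s in cohort.subjects if s.group in (g1, g0)]
    labels = np.array([1.0 if s.group is g1 else 0.0 for s in subjects])
    cov = _covariates(subjects)
    counts = np.array([per_subject_class_counts(s, rich) for s in subjects], dtype=float)
    measures = {
        "E": np.array([edge_count(s.fiber_density) for s in subjects], dtype=float),
        "rich_club_edges": counts[:, 0],
        "feeder_edges": counts[:, 1],
        "local_edges": counts[:, 2],
    }
    out = {}
    rng = np.random.default_rng(seed)
    for name, vals in measures.items():
        resid = residualize(vals, cov)
        res = permutation_group_test(resid, labels, m=m, seed=rng)
        out[name] = {"t_obs": res.t_obs, "p_perm": res.p_perm, "m": res.m, "b": res.b}
    return out


def _curve_tests(cohort, kind, contrast, config, curves_by_subject):
    """Per-k group tests of phi_n with FDR across k, for one weight kind."""
    g1, g0 = Group(contrast[0]), Group(contrast[1])
    subjects = [s for s in cohort.subjects if s.group in (g1, g0)]
    labels = np.array([1.0 if s.group is g1 else 0.0 for s in subjects])
    cov = _covariates(subjects)
    mat = np.vstack([curves_by_subject[s.subject_id][kind].phi_norm for s in subjects])
    rng = np.random.default_rng(config.seed + 1)
    results = {}
    p_list, k_list = [], []
    for ki in range(mat.shape[1]):
        col = mat[:, ki]
        ok = ~np.isnan(col)
        if ok.sum() < 5 or len(np.unique(labels[ok])) < 2:
            continue
        resid = residualize(col[ok], cov[ok].reset_index(drop=True))
        res = permutation_group_test(resid, labels[ok], m=config.permutations, seed=rng)
        k = ki + 1
        results[k] = {"t_obs": res.t_obs, "p_perm": res.p_perm}
        p_list.append(res.p_perm)
        k_list.append(k)
    fdr = fdr_bh(p_list, q=config.fdr_q) if p_list else None
    sig_k = (
        [k for k, r in zip(k_list, fdr.reject_mask) if r] if fdr is not None else []
    )
    return {
        "per_k": results,
        "fdr_critical_p": fdr.critical_p if fdr is not None else None,
        "significant_k": sig_k,
    }


def _enrichment(cohort, rich, edge_res, contrast, declining_group):
    """Chi-squared enrichment of FDR-significant declining edges per class."""
    cmap = classify_edges(cohort.edge_support, rich)
    subjects = cohort.by_group(declining_group)
    counts = np.array([per_subject_class_counts(s, rich) for s in subjects], dtype=float)
    totals = {
        "rich_club": int(round(counts[:, 0].mean())),
        "feeder": int(round(counts[:, 1].mean())),
        "local": int(round(counts[:, 2].mean())),
    }
    sign_for_decline = -1 if declining_group == contrast[0] else 1
    affected = {c: 0 for c in totals}
    for edge, rej, sg in zip(edge_res.items, edge_res.fdr.reject_mask, edge_res.sign):
        if rej and sg == sign_for_decline:
            affected[cmap.classes[edge].value] += 1
    n_sig = sum(affected.values())
    if n_sig == 0:
        return {"affected": affected, "totals": totals, "n_significant": 0, "p": None}
    try:
        report = chi2_class_report(affected, totals)
    except ValueError:
        return {"affected": affected, "totals": totals, "n_significant": n_sig, "p": None}
    report["n_significant"] = n_sig
    return report


def run_pipeline(config: PipelineConfig, cohort: Cohort) -> dict:
    """Execute the full analysis; return (and optionally write) the report bundle."""
    stage = "setup"
    try:
        report: dict = {"manifest": _manifest(config)}

        stage = "node_selection"
        if config.membership_file:
            from .io import read_membership

            rich = read_membership(config.membership_file, cohort.node_labels)
        else:
            rich = select_rich_nodes(
                cohort,
                k_threshold=config.k_threshold,
                degree_floor=config.degree_floor,
                top_fraction=config.top_fraction,
            )
        report["rich_nodes"] = {
            "labels": list(rich.labels),
            "n": len(rich.members),
            "rule": dict(rich.selection_rule),
        }

        stage = "edge_classification"
        cmap = classify_edges(cohort.edge_support, rich)
        report["edge_classes"] = {c.value: n for c, n in cmap.counts.items()}

        stage = "rich_club_curves"
        curves_by_subject: dict[str, dict[str, object]] = {}
        if config.compute_curves:
            rng = np.random.default_rng(config.seed)
            for s in cohort.subjects:
                curves_by_subject[s.subject_id] = {
                    kind: rich_club_curve(
                        s.matrices[WeightKind(kind)],
                        k_max=config.k_max,
                        n_random=config.n_random,
                        seed=rng,
                    )
                    for kind in config.weight_kinds
                }

        stage = "global_tests"
        report["global"] = {}
        for contrast in config.contrasts:
            key = f"{contrast[0]}_vs_{contrast[1]}"
            entry = _global_measure_tests(
                cohort, rich, contrast, config.permutations, config.seed, config.fdr_q
            )
            if config.compute_curves:
                entry["curves"] = {
                    kind: _curve_tests(cohort, kind, contrast, config, curves_by_subject)
                    for kind in config.weight_kinds
                }
            report["global"][key] = entry

        stage = "nodal_tests"
        report["nodal"] = {}
        for contrast in config.contrasts:
            key = f"{contrast[0]}_vs_{contrast[1]}"
            res = nodal_degree_group_test(
                cohort, contrast, m=config.permutations,
                seed=config.seed + 2, q=config.fdr_q,
            )
            affected_nodes = [
                i for i, (rej, sg) in enumerate(zip(res.fdr.reject_mask, res.sign))
                if rej and sg == -1
            ]
            rich_aff = sum(1 for i in affected_nodes if i in rich.members)
            node_chi2 = None
            if affected_nodes:
                n_rich = len(rich.members)
                n_non = cohort.n_nodes - n_rich
                try:
                    c = chi2_proportions(
                        [rich_aff, len(affected_nodes) - rich_aff], [n_rich, n_non]
                    )
                    node_chi2 = {"chi2": c.chi2, "p": c.p}
                except ValueError:
                    node_chi2 = None
            report["nodal"][key] = {
                "fdr_critical_p": res.fdr.critical_p,
                "n_affected": len(affected_nodes),
                "affected_nodes": [cohort.node_labels[i] for i in affected_nodes],
                "rich_vs_nonrich_chi2": node_chi2,
            }

        stage = "edgewise_tests"
        report["edgewise"] = {}
        for contrast in config.contrasts:
            key = f"{contrast[0]}_vs_{contrast[1]}"
            report["edgewise"][key] = {}
            for kind in config.weight_kinds:
                res = edgewise_group_test(
                    cohort, kind, contrast, m=config.permutations,
                    seed=config.seed + 3, q=config.fdr_q,
                )
                entry = {
                    "fdr_critical_p": res.fdr.critical_p,
                    "n_significant": res.fdr.n_rejected,
                    "enrichment": {
                        contrast[0]: _enrichment(cohort, rich, res, contrast, contrast[0]),
                        contrast[1]: _enrichment(cohort, rich, res, contrast, contrast[1]),
                    },
                }
                report["edgewise"][key][kind] = entry

        stage = "mmse_association"
        report["mmse"] = {}
        have_mmse = sum(s.mmse is not None for s in cohort.subjects)
        if have_mmse >= 0.8 * len(cohort.subjects):
            measures = {
                "E": np.array(
                    [edge_count(s.fiber_density) for s in cohort.subjects], dtype=float
                ),
            }
            counts = np.array(
                [per_subject_class_counts(s, rich) for s in cohort.subjects], dtype=float
            )
            measures["rich_club_edges"] = counts[:, 0]
            measures["feeder_edges"] = counts[:, 1]
            measures["local_edges"] = counts[:, 2]
            for name, vals in measures.items():
                res = mmse_association(
                    cohort, vals, m=config.permutations, seed=config.seed + 4
                )
                report["mmse"][name] = {"t_obs": res.t_obs, "p_perm": res.p_perm}
        else:
            report["mmse"]["skipped"] = "MMSE present for fewer than 80% of subjects"

        if config.out_dir:
            stage = "write_outputs"
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_membership(rich, out / "rich_nodes.txt")
            write_edge_classes(cmap, cohort.node_labels, out / "edge_classes.tsv")
            if config.compute_curves:
                write_curve_tsv(
                    (
                        (sid, curves[kind])
                        for sid, curves in curves_by_subject.items()
                        for kind in config.weight_kinds
                    ),
                    out / "rich_club_curves.tsv",
                )
            write_json(report, out / "report.json")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _manifest(config: PipelineConfig) -> dict:
    import networkx
    import pandas
    import scipy

    return {
        "config": dataclasses.asdict(config),
        "versions": {
            "richclub": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
        },
    }
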