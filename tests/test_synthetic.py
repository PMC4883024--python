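import dataclasses

import numpy as np
import pytest

import richclub as rc
from richclub.classes import EdgeClass
from richclub.network_model import WeightKind


class TestBaseConnectome:
    def test_full_density_gives_complete_graph(self):
        spec = rc.GeneratorSpec(base_density=1.0, seed=1)
        fd, fa, md = rc.generate_base_connectome(spec)
        assert rc.edge_count(fd) == 68 * 67 // 2

    def test_infeasible_density_rejected(self):
        spec = rc.GeneratorSpec(base_density=0.05, seed=1)  # core alone needs 325/2278
        with pytest.raises(ValueError, match="infeasible"):
            rc.generate_base_connectome(spec)

    def test_unknown_core_label_rejected(self):
        spec = rc.GeneratorSpec(rich_core=("lh_precuneus", "lh_madeup"), seed=1)
        with pytest.raises(KeyError):
            rc.generate_base_connectome(spec)

    @pytest.mark.parametrize("seed", range(20))
    def test_core_occupies_top_degree_ranks(self, seed):
        """Planted 26-node core out-degrees every peripheral node (ties allowed)."""
        fd, _, _ = rc.generate_base_connectome(rc.GeneratorSpec(seed=seed))
        deg = rc.nodal_degree(fd)
        labels = fd.node_labels
        core = [labels.index(lab) for lab in rc.canonical_rich_club_labels()]
        periph = [i for i in range(68) if i not in core]
        assert deg[core].min() >= deg[periph].max()

    def test_fa_md_anticorrelated(self):
        fd, fa, md = rc.generate_base_connectome(rc.GeneratorSpec(seed=3))
        iu, ju = np.triu_indices(68, 1)
        present = fd.weights[iu, ju] > 0
        r = np.corrcoef(fa.weights[iu, ju][present], md.weights[iu, ju][present])[0, 1]
        assert r < -0.5

    def test_fa_tracks_log_fiber_density(self):
        fd, fa, _ = rc.generate_base_connectome(rc.GeneratorSpec(seed=4))
        iu, ju = np.triu_indices(68, 1)
        present = fd.weights[iu, ju] > 0
        r = np.corrcoef(
            np.log(fd.weights[iu, ju][present]), fa.weights[iu, ju][present]
        )[0, 1]
        assert r > 0.5

    def test_shared_support_and_ranges(self):
        fd, fa, md = rc.generate_base_connectome(rc.GeneratorSpec(seed=5))
        assert ((fa.weights > 0) == (fd.weights > 0)).all()
        assert ((md.weights > 0) == (fd.weights > 0)).all()
        present = fd.weights > 0
        assert fa.weights[present].min() >= 0.2
        assert fa.weights[present].max() <= 0.8
        assert md.weights[present].min() > 0  # diffusivity strictly positive


class TestCohortGeneration:
    def test_bit_identical_reproducibility(self):
        spec = rc.default_spec(seed=41)
        c1, t1 = rc.generate_cohort(spec)
        c2, t2 = rc.generate_cohort(spec)
        for a, b in zip(c1.subjects, c2.subjects):
            assert a.age == b.age and a.mmse == b.mmse and a.sex == b.sex
            for kind in a.matrices:
                assert np.array_equal(a.matrices[kind].weights, b.matrices[kind].weights)
        assert t1.lesioned_edges == t2.lesioned_edges

    def test_seed_changes_output(self):
        c1, _ = rc.generate_cohort(rc.default_spec(seed=1))
        c2, _ = rc.generate_cohort(rc.default_spec(seed=2))
        assert not np.array_equal(
            c1.subjects[0].fiber_density.weights, c2.subjects[0].fiber_density.weights
        )

    def test_group_sizes_default(self, default_cohort):
        cohort, _ = default_cohort
        assert len(cohort.by_group("control")) == 37
        assert len(cohort.by_group("bvFTD")) == 20
        assert len(cohort.by_group("EOAD")) == 23

    def test_lesion_bookkeeping_reflects_group_means(self, default_cohort):
        """Lesioned edges are attenuated in the target group relative to controls."""
        cohort, truth = default_cohort
        W = cohort.weight_table("fiber_density")
        edges = cohort.sorted_support()
        eidx = {e: i for i, e in enumerate(edges)}
        ctrl = np.array([s.group.value == "control" for s in cohort.subjects])
        eoad = np.array([s.group.value == "EOAD" for s in cohort.subjects])
        lesioned = [
            e for e in truth.lesioned_edges["EOAD"]
            if e not in truth.removed_edges["EOAD"] and e in eidx
        ]
        ratios = [
            W[eoad, eidx[e]].mean() / W[ctrl, eidx[e]].mean()
            for e in lesioned
            if W[ctrl, eidx[e]].mean() > 0
        ]
        assert np.mean(ratios) < 0.95  # mean shift toward the 0.8 multiplier

    def test_removed_edges_zero_in_group(self, default_cohort):
        cohort, truth = default_cohort
        W = cohort.weight_table("fiber_density")
        edges = cohort.sorted_support()
        eidx = {e: i for i, e in enumerate(edges)}
        eoad = np.array([s.group.value == "EOAD" for s in cohort.subjects])
        for e in truth.removed_edges["EOAD"]:
            if e in eidx:
                assert (W[eoad, eidx[e]] == 0).all()

    def test_mmse_clamped_and_group_ordered(self, default_cohort):
        cohort, _ = default_cohort
        for s in cohort.subjects:
            assert 0 <= s.mmse <= 30
        ctrl = np.mean([s.mmse for s in cohort.by_group("control")])
        bvftd = np.mean([s.mmse for s in cohort.by_group("bvFTD")])
        eoad = np.mean([s.mmse for s in cohort.by_group("EOAD")])
        assert ctrl > bvftd and ctrl > eoad
        assert ctrl > 28.0  # healthy controls near ceiling

    def test_lesion_classes_respected(self, default_cohort):
        cohort, truth = default_cohort
        for e in truth.lesioned_edges["EOAD"]:
            assert truth.edge_class[e] is EdgeClass.rich_club
        for e in truth.lesioned_edges["bvFTD"]:
            assert truth.edge_class[e] in (EdgeClass.feeder, EdgeClass.local)

    def test_fa_stays_in_unit_interval(self, default_cohort):
        cohort, _ = default_cohort
        for s in cohort.subjects[:10]:
            fa = s.matrices[WeightKind.FA].weights
            assert fa.min() >= 0 and fa.max() <= 1

    def test_null_cohort_fdr_mostly_silent(self):
        """Without lesions, BH-FDR across edges rejects nothing in most replicates."""
        silent = 0
        n_rep = 8
        for rep in range(n_rep):
            spec = rc.GeneratorSpec(
                n_per_group={"control": 20, "bvFTD": 14}, seed=100 + rep
            )
            cohort, _ = rc.generate_cohort(spec)
            res = rc.edgewise_group_test(
                cohort, "fiber_density", ("bvFTD", "control"), m=20000, seed=rep
            )
            silent += res.fdr.n_rejected == 0
        assert silent >= n_rep - 1

    def test_invalid_lesion_parameters(self):
        with pytest.raises(ValueError):
            rc.LesionSpec(edge_classes=("local",), affected_fraction=1.5, effects={})
        with pytest.raises(ValueError):
            rc.LesionSpec(
                edge_classes=("local",), affected_fraction=0.5,
                effects={"FA": 1.2},
            )
        with pytest.raises(ValueError):
            rc.LesionSpec(
                edge_classes=("local",), affected_fraction=0.5,
                effects={"fiber_density": -0.2},
            )
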