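import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import richclub as rc

from oracles import bh_oracle, exhaustive_perm_p


def make_cov(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.normal(60, 9, n),
            "sex": rng.choice(["M", "F"], n),
            "brain_volume": rng.normal(1.1e6, 1e5, n),
        }
    )


class TestResidualize:
    def test_linear_in_age_gives_zero_residuals(self):
        cov = make_cov(30, seed=1)
        values = 3.0 + 0.5 * cov["age"].to_numpy()
        resid = rc.residualize(values, cov)
        assert np.allclose(resid, 0.0, atol=1e-8)

    def test_orthogonal_covariates_center_only(self):
        n = 40
        cov = make_cov(n, seed=2)
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1, n)
        # project out the design exactly, then residualization == centering
        X = np.column_stack(
            [np.ones(n), cov["age"], (cov["sex"] == "F").astype(float), cov["brain_volume"]]
        )
        beta, *_ = np.linalg.lstsq(X, noise, rcond=None)
        orthogonal = noise - X @ beta + 5.0  # shift back; intercept reabsorbs it
        resid = rc.residualize(orthogonal, cov)
        assert np.allclose(resid, orthogonal - orthogonal.mean(), atol=1e-8)

    def test_residuals_sum_to_zero(self):
        cov = make_cov(25, seed=4)
        values = np.random.default_rng(5).normal(0, 2, 25)
        assert rc.residualize(values, cov).sum() == pytest.approx(0.0, abs=1e-8)

    def test_planted_age_slope_recovered(self):
        rng = np.random.default_rng(60)
        n, beta = 200, 0.8
        cov = make_cov(n, seed=6)
        y = beta * cov["age"].to_numpy() + rng.normal(0, 1.0, n)
        X = np.column_stack([np.ones(n), cov["age"]])
        fit = np.linalg.lstsq(X, y, rcond=None)[0]
        se = 1.0 / np.sqrt(((cov["age"] - cov["age"].mean()) ** 2).sum())
        assert abs(fit[1] - beta) < 2 * se
        resid = rc.residualize(y, cov)
        assert abs(np.corrcoef(resid, cov["age"])[0, 1]) < 0.05

    def test_collinear_column_named(self):
        cov = make_cov(20, seed=7)
        cov["brain_volume"] = 2.0 * cov["age"]  # exact collinearity
        with pytest.raises(ValueError, match="age|brain_volume"):
            rc.residualize(np.ones(20), cov)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match=">= 5"):
            rc.residualize(np.ones(3), make_cov(3))


class TestPermutationTest:
    def test_floor_p_value(self):
        """Overwhelming effect: b = 0 of m = 10000, p = 1/10001 ~ 1e-4."""
        rng = np.random.default_rng(8)
        y = np.concatenate([rng.normal(0, 1, 30), rng.normal(10, 1, 30)])
        labels = np.repeat([0.0, 1.0], 30)
        res = rc.permutation_group_test(y - y.mean(), labels, m=10000, seed=1)
        assert res.b == 0
        assert res.p_perm == pytest.approx(1 / 10001)
        assert res.p_perm == pytest.approx(1e-4, rel=1e-3)

    def test_null_gives_large_p(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, 60)
        labels = np.repeat([0.0, 1.0], 30)
        res = rc.permutation_group_test(y, labels, m=2000, seed=2)
        assert res.p_perm > 0.01

    def test_p_formula_invariant(self):
        rng = np.random.default_rng(10)
        y = rng.normal(0, 1, 40)
        labels = np.repeat([0.0, 1.0], 20)
        res = rc.permutation_group_test(y, labels, m=500, seed=3)
        assert res.p_perm == (res.b + 1) / (res.m + 1)

    @pytest.mark.parametrize(
        "y",
        [
            np.array([0.3, -1.2, 0.8, 2.5, 3.1, 2.2]),  # strong separation
            np.array([0.3, 1.9, -0.8, 0.6, 1.1, -0.2]),  # interleaved
        ],
    )
    def test_matches_exhaustive_enumeration(self, y):
        """n = 6: Monte-Carlo p within a few SE of the exact enumeration value."""
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        q = exhaustive_perm_p(y, labels)  # exact strictly-greater fraction
        m = 4000
        res = rc.permutation_group_test(y, labels, m=m, seed=4)
        expected = (m * q + 1) / (m + 1)
        mc_se = np.sqrt(q * (1 - q) / m)
        assert abs(res.p_perm - expected) < 4 * mc_se + 2 / (m + 1)

    def test_group_relabel_symmetry(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, 30)
        labels = (rng.random(30) < 0.5).astype(float)
        a = rc.permutation_group_test(y, labels, m=999, seed=5)
        b = rc.permutation_group_test(y, 1 - labels, m=999, seed=5)
        assert a.p_perm == b.p_perm

    def test_degenerate_residuals_warn(self):
        labels = np.repeat([0.0, 1.0], 10)
        with pytest.warns(UserWarning, match="degenerate"):
            res = rc.permutation_group_test(np.zeros(20), labels, m=100, seed=0)
        assert res.p_perm == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            rc.permutation_group_test(np.arange(10.0), np.zeros(10), m=10)


class TestFdrBH:
    def test_all_small_all_rejected(self):
        res = rc.fdr_bh([0.01] * 8, q=0.05)
        assert res.reject_mask.all()
        assert res.critical_p == pytest.approx(0.01)

    def test_step_up_example(self):
        res = rc.fdr_bh([0.001, 0.04, 0.9], q=0.05)
        assert res.reject_mask.tolist() == [True, False, False]
        assert res.critical_p == pytest.approx(0.001)

    def test_empty_input(self):
        res = rc.fdr_bh([], q=0.05)
        assert res.critical_p is None
        assert res.reject_mask.size == 0

    def test_nothing_passes(self):
        res = rc.fdr_bh([0.5, 0.8, 0.9], q=0.05)
        assert not res.reject_mask.any()
        assert res.critical_p is None

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 60))
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, n)
        ours = rc.fdr_bh(p, q=0.05).reject_mask
        assert (ours == bh_oracle(p, 0.05)).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            rc.fdr_bh([0.0, 0.5])
        with pytest.raises(ValueError):
            rc.fdr_bh([0.5, 1.2])


class TestChi2Proportions:
    def test_equal_proportions_give_chi2_zero(self):
        res = rc.chi2_proportions([10, 20, 30], [100, 200, 300])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_df_is_classes_minus_one(self):
        assert rc.chi2_proportions([5, 6, 7], [50, 60, 70]).df == 2
        assert rc.chi2_proportions([5, 6], [50, 60]).df == 1

    def test_2x2_equals_two_proportion_ztest(self):
        """Algebraic identity: Pearson chi2 on 2x2 == squared two-prop z."""
        a1, n1, a2, n2 = 13, 26, 6, 42
        res = rc.chi2_proportions([a1, a2], [n1, n2])
        p1, p2 = a1 / n1, a2 / n2
        pooled = (a1 + a2) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        assert res.chi2 == pytest.approx(z**2)
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_df2_closed_form(self):
        """For df = 2, the survival function is exp(-chi2 / 2) exactly."""
        res = rc.chi2_proportions([23, 12, 4], [195, 442, 206])
        assert res.p == pytest.approx(np.exp(-res.chi2 / 2))

    def test_zero_total_class_excluded(self):
        with pytest.warns(UserWarning, match="zero-total"):
            res = rc.chi2_proportions([5, 0, 7], [50, 0, 70])
        assert res.df == 1
        assert res.excluded_classes == (1,)

    def test_affected_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            rc.chi2_proportions([60], [50])


class TestCohortTests:
    def test_single_edge_reduces_to_scalar_test(self, small_cohort):
        cohort, _ = small_cohort
        res = rc.edgewise_group_test(
            cohort, "fiber_density", ("bvFTD", "control"), m=500, seed=7
        )
        edge = res.items[0]
        W = cohort.weight_table("fiber_density")
        subjects = [s for s in cohort.subjects if s.group.value in ("bvFTD", "control")]
        idx = [i for i, s in enumerate(cohort.subjects) if s.group.value in ("bvFTD", "control")]
        y = W[idx, 0]
        labels = np.array([1.0 if s.group.value == "bvFTD" else 0.0 for s in subjects])
        cov = pd.DataFrame(
            {
                "age": [s.age for s in subjects],
                "sex": [s.sex for s in subjects],
                "brain_volume": [s.brain_volume for s in subjects],
            }
        )
        resid = rc.residualize(y, cov)
        scalar = rc.permutation_group_test(resid, labels, m=500, seed=7)
        assert res.t_obs[0] == pytest.approx(scalar.t_obs)

    def test_edgewise_null_type_one_error(self, null_cohort):
        """No lesions: the raw p < 0.05 rate sits in the 99% binomial band."""
        cohort, _ = null_cohort
        res = rc.edgewise_group_test(
            cohort, "fiber_density", ("bvFTD", "control"), m=500, seed=8
        )
        frac = (res.p_perm < 0.05).mean()
        n = len(res.items)
        band = 2.58 * np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < band + 0.01

    def test_planted_edge_lesion_power_and_sign(self):
        """20% fiber-density drop on ~30 edges: most detected, none with wrong sign."""
        lesions = {
            "bvFTD": (
                rc.LesionSpec(
                    edge_classes=("rich_club",),
                    affected_fraction=30 / 325,
                    effects={"fiber_density": 0.8},
                ),
            )
        }
        spec = rc.GeneratorSpec(
            n_per_group={"control": 37, "bvFTD": 20}, lesion_spec=lesions, seed=31
        )
        cohort, truth = rc.generate_cohort(spec)
        res = rc.edgewise_group_test(
            cohort, "fiber_density", ("bvFTD", "control"), m=2000, seed=9
        )
        planted = set(truth.lesioned_edges["bvFTD"])
        sig = {e: s for e, r, s in zip(res.items, res.fdr.reject_mask, res.sign) if r}
        detected = [e for e in planted if e in sig]
        assert len(detected) >= 0.5 * len(planted)
        assert all(sig[e] == -1 for e in detected)

    def test_nodal_degree_reduction_detected(self):
        """Removing edges around hubs lowers degree detectably in patients."""
        lesions = {
            "bvFTD": (
                rc.LesionSpec(
                    edge_classes=("rich_club",),
                    affected_fraction=0.3,
                    effects={"fiber_density": 0.9},
                    remove_fraction=0.5,
                ),
            )
        }
        spec = rc.GeneratorSpec(
            n_per_group={"control": 37, "bvFTD": 20}, lesion_spec=lesions, seed=33
        )
        cohort, truth = rc.generate_cohort(spec)
        res = rc.nodal_degree_group_test(cohort, ("bvFTD", "control"), m=2000, seed=10)
        affected = [i for i, (r, s) in enumerate(zip(res.fdr.reject_mask, res.sign))
                    if r and s == -1]
        core = set(truth.core_indices)
        assert len(affected) > 0
        assert len(core & set(affected)) / len(affected) > 0.5

    def test_nodal_null_calibrated(self, null_cohort):
        cohort, _ = null_cohort
        res = rc.nodal_degree_group_test(cohort, ("EOAD", "control"), m=500, seed=11)
        assert res.fdr.n_rejected <= 3

    def test_missing_contrast_group(self, small_cohort):
        cohort, _ = small_cohort
        only_controls = rc.Cohort(subjects=cohort.by_group("control"))
        with pytest.raises(ValueError):
            rc.edgewise_group_test(only_controls, "FA", ("bvFTD", "control"), m=10)


class TestMmseAssociation:
    def test_strong_signal_hits_floor(self, default_cohort):
        cohort, _ = default_cohort
        mmse = np.array([float(s.mmse) for s in cohort.subjects])
        measure = 10.0 * mmse + np.random.default_rng(12).normal(0, 0.1, len(mmse))
        res = rc.mmse_association(cohort, measure, m=999, seed=13)
        assert res.p_perm == pytest.approx(1 / 1000)

    def test_null_measure_not_significant(self, default_cohort):
        cohort, _ = default_cohort
        rng = np.random.default_rng(14)
        ps = [
            rc.mmse_association(cohort, rng.normal(0, 1, len(cohort.subjects)),
                                m=200, seed=s).p_perm
            for s in range(10)
        ]
        assert min(ps) > 1 / 201  # not all at floor
        assert np.mean(ps) > 0.2  # roughly uniform

    def test_small_sample_matches_enumeration(self):
        """Strong monotone signal at n = 6 pins p near the enumeration value."""
        spec = rc.GeneratorSpec(n_per_group={"control": 6}, seed=35)
        cohort, _ = rc.generate_cohort(spec)
        mmse = np.array([float(s.mmse) for s in cohort.subjects])
        measure = mmse.copy()
        if np.ptp(mmse) == 0:  # degenerate draw; perturb deterministically
            measure = measure + np.arange(6) * 0.01
        res = rc.mmse_association(cohort, measure, m=5000, seed=15)
        assert 0 < res.p_perm <= 1

    def test_all_missing_mmse_rejected(self, small_cohort):
        cohort, _ = small_cohort
        stripped = rc.Cohort(
            subjects=[dataclasses.replace(s, mmse=None) for s in cohort.subjects]
        )
        with pytest.raises(ValueError, match="missing"):
            rc.mmse_association(stripped, np.zeros(len(stripped.subjects)), m=10)
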