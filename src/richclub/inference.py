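"""Permutation-based group inference with covariate residualization.

The inference scheme: network measures are first residualized against
nuisance covariates (age, sex, total brain volume) by ordinary least
squares, pooled over the subjects entering the contrast.  The group effect
is then the t-statistic of the diagnosis indicator in a regression on those
residuals, and its significance comes from randomly permuting the diagnosis
labels m times:

    p = (b + 1) / (m + 1),

where b counts permuted statistics whose magnitude strictly exceeds the
observed one.  Benjamini–Hochberg FDR (q = 0.05) corrects across edges,
nodes or k-levels within each family.  Chi-squared tests compare how the
significantly altered edges distribute over the rich-club / feeder / local
classes against each class's share of all edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network_model import Cohort, Group, WeightKind, nodal_degree

__all__ = [
    "PermResult",
    "FdrResult",
    "Chi2Result",
    "EdgewiseResult",
    "residualize",
    "permutation_group_test",
    "fdr_bh",
    "chi2_proportions",
    "edgewise_group_test",
    "nodal_degree_group_test",
    "mmse_association",
]


@dataclass(frozen=True)
class PermResult:
    """One permutation test: observed t, permutation p = (b+1)/(m+1)."""

    t_obs: float
    p_perm: float
    m: int
    b: int
    seed: int | None = None

    def __post_init__(self) -> None:
        expected = (self.b + 1) / (self.m + 1)
        assert abs(self.p_perm - expected) < 1e-12


@dataclass(frozen=True)
class FdrResult:
    """Benjamini–Hochberg step-up decision over a family of p-values."""

    q: float
    critical_p: float | None
    reject_mask: np.ndarray

    @property
    def n_rejected(self) -> int:
        return int(self.reject_mask.sum())


@dataclass(frozen=True)
class Chi2Result:
    """Pearson chi-squared on a 2 x C affected/unaffected contingency table."""

    table: np.ndarray
    chi2: float
    df: int
    p: float
    excluded_classes: tuple[int, ...] = ()


@dataclass
class EdgewiseResult:
    """Per-item permutation tests plus the family-wise FDR decision.

    ``items`` are edge index pairs for edgewise tests or node indices for
    nodal tests; ``sign`` is the sign of the observed t (positive means the
    first contrast group has the larger adjusted mean).
    """

    items: list
    t_obs: np.ndarray
    p_perm: np.ndarray
    fdr: FdrResult
    sign: np.ndarray
    m: int
    seed: int | None = None

    def significant_items(self) -> list:
        return [it for it, r in zip(self.items, self.fdr.reject_mask) if r]


# ---------------------------------------------------------------------------
# residualization

_SEX_CODE = {"M": 0.0, "F": 1.0}


def _design_matrix(covariates: pd.DataFrame, extra: pd.DataFrame | None = None) -> tuple[np.ndarray, list[str]]:
    cols = {"intercept": np.ones(len(covariates))}
    cols["age"] = covariates["age"].to_numpy(float)
    sex = covariates["sex"]
    cols["sex"] = (
        sex.map(_SEX_CODE).to_numpy(float) if sex.dtype == object else sex.to_numpy(float)
    )
    cols["brain_volume"] = covariates["brain_volume"].to_numpy(float)
    if extra is not None:
        for c in extra.columns:
            cols[c] = extra[c].to_numpy(float)
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names


def residualize(
    values: np.ndarray, covariates: pd.DataFrame, extra: pd.DataFrame | None = None
) -> np.ndarray:
    """OLS residuals of values against intercept + age + sex + brain volume.

    ``values`` may be a vector (one measure) or a 2-D array (subjects x
    items); residualization is applied column-wise with a single hat matrix.
    ``extra`` appends further nuisance columns (e.g. disease-status dummies
    for the MMSE analysis).

    Raises
    ------
    ValueError
        If fewer than 5 subjects, or the design is rank deficient (the
        error names the collinear column).
    """
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    if n < 5:
        raise ValueError(f"residualization needs >= 5 subjects, got {n}")
    X, names = _design_matrix(covariates, extra)
    if X.shape[0] != n:
        raise ValueError("values and covariates disagree on subject count")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for drop in range(1, X.shape[1]):
            sub = np.delete(X, drop, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"design is rank deficient: column '{names[drop]}' is collinear")
        raise ValueError("design is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


# ---------------------------------------------------------------------------
# permutation machinery

def _perm_t_matrix(
    Y: np.ndarray, x: np.ndarray, m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and permuted t-statistics of simple OLS slope, vectorized.

    Y : (n, p) response columns (already residualized); x : (n,) regressor.
    Returns (t_obs (p,), t_perm (m, p)).  One shared permutation sequence is
    used across all columns.  Columns with zero variance get t = 0.
    """
    n, p = Y.shape
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("regressor has zero variance (only one group present)")
    Yc = Y - Y.mean(axis=0)
    ssy = np.einsum("ij,ij->j", Yc, Yc)
    dof = n - 2

    def t_from_cross(cross: np.ndarray) -> np.ndarray:
        # cross: (..., p) = xc' Y per permutation
        b = cross / sxx
        resid_ss = np.maximum(ssy - b**2 * sxx, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b * np.sqrt(sxx * dof) / np.sqrt(resid_ss)
        t = np.where(ssy == 0, 0.0, t)
        return np.where(np.isfinite(t), t, np.sign(b) * np.inf)

    t_obs = t_from_cross(xc @ Yc)
    perm_idx = np.array([rng.permutation(n) for _ in range(m)])
    Xp = xc[perm_idx]  # (m, n)
    t_perm = t_from_cross(Xp @ Yc)
    return np.atleast_1d(t_obs), t_perm


def _p_from_t(t_obs: np.ndarray, t_perm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation p per column: b counts strict |t_perm| > |t_obs|."""
    b = (np.abs(t_perm) > np.abs(t_obs)[None, :]).sum(axis=0)
    m = t_perm.shape[0]
    return (b + 1) / (m + 1), b


def permutation_group_test(
    residuals: np.ndarray,
    group_labels: np.ndarray,
    m: int = 10000,
    seed: int | np.random.Generator = 0,
) -> PermResult:
    """Permutation test of a binary group effect on residualized values."""
    y = np.asarray(residuals, dtype=float).reshape(-1, 1)
    x = np.asarray(group_labels, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("both group labels must be present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.ptp(y) == 0:
        warnings.warn("degenerate residuals (zero variance); p = 1")
        return PermResult(t_obs=0.0, p_perm=1.0, m=m, b=m,
                          seed=seed if isinstance(seed, int) else None)
    t_obs, t_perm = _perm_t_matrix(y, x, m, rng)
    p, b = _p_from_t(t_obs, t_perm)
    return PermResult(
        t_obs=float(t_obs[0]), p_perm=float(p[0]), m=m, b=int(b[0]),
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# multiple testing and proportions

def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> FdrResult:
    """Benjamini–Hochberg step-up: find i* = max{i : p_(i) <= (i/n) q}.

    All p_(i) with i <= i* are rejected; ``critical_p`` is p_(i*) (None when
    nothing passes).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FdrResult(q=q, critical_p=None, reject_mask=np.zeros(0, dtype=bool))
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    n = p.size
    passing = np.flatnonzero(sorted_p <= (np.arange(1, n + 1) / n) * q)
    if passing.size == 0:
        return FdrResult(q=q, critical_p=None, reject_mask=np.zeros(n, dtype=bool))
    i_star = passing[-1]
    critical_p = float(sorted_p[i_star])
    return FdrResult(q=q, critical_p=critical_p, reject_mask=p <= critical_p)


def chi2_proportions(
    affected: Sequence[int], totals: Sequence[int]
) -> Chi2Result:
    """Pearson chi-squared comparing affected proportions across edge classes.

    Builds the 2 x C table with rows (affected, unaffected = totals -
    affected) and applies the Pearson test without continuity correction;
    df = C - 1.  Classes with a zero total are excluded (with a warning) and
    df reduced accordingly.
    """
    aff = np.asarray(affected, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if aff.shape != tot.shape or aff.ndim != 1:
        raise ValueError("affected and totals must be equal-length vectors")
    if (aff > tot).any():
        raise ValueError("affected counts exceed class totals")
    excluded = tuple(np.flatnonzero(tot == 0).tolist())
    if excluded:
        warnings.warn(f"excluding zero-total classes {excluded}; df reduced")
        keep = tot > 0
        aff, tot = aff[keep], tot[keep]
    if aff.size < 2:
        raise ValueError("need at least 2 non-empty classes")
    table = np.vstack([aff, tot - aff])
    if aff.sum() == 0 or (tot - aff).sum() == 0:
        # one margin empty: proportions identical by construction
        return Chi2Result(table=table, chi2=0.0, df=int(aff.size - 1), p=1.0,
                          excluded_classes=excluded)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return Chi2Result(table=table, chi2=float(chi2), df=int(df), p=float(p),
                      excluded_classes=excluded)


# ---------------------------------------------------------------------------
# cohort-level tests

def _contrast_subset(cohort: Cohort, contrast: tuple[str, str]):
    g1, g0 = Group(contrast[0]), Group(contrast[1])
    subjects = [s for s in cohort.subjects if s.group in (g1, g0)]
    if not any(s.group is g1 for s in subjects) or not any(s.group is g0 for s in subjects):
        raise ValueError(f"contrast {contrast} needs subjects in both groups")
    labels = np.array([1.0 if s.group is g1 else 0.0 for s in subjects])
    cov = pd.DataFrame(
        {
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "brain_volume": [s.brain_volume for s in subjects],
        }
    )
    return subjects, labels, cov


def _matrix_group_test(
    Y: np.ndarray,
    labels: np.ndarray,
    covariates: pd.DataFrame,
    items: list,
    m: int,
    seed: int | np.random.Generator,
    q: float,
) -> EdgewiseResult:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    resid = residualize(Y, covariates)
    t_obs, t_perm = _perm_t_matrix(resid, labels, m, rng)
    p, _ = _p_from_t(t_obs, t_perm)
    return EdgewiseResult(
        items=items,
        t_obs=t_obs,
        p_perm=p,
        fdr=fdr_bh(p, q=q),
        sign=np.sign(t_obs).astype(int),
        m=m,
        seed=seed if isinstance(seed, int) else None,
    )


def edgewise_group_test(
    cohort: Cohort,
    weight_kind: WeightKind | str,
    contrast: tuple[str, str],
    m: int = 10000,
    seed: int | np.random.Generator = 0,
    q: float = 0.05,
) -> EdgewiseResult:
    """Residualize-and-permute every supported edge's weight; BH-FDR across edges.

    ``contrast = (group1, group0)``; the t sign is positive where group1 has
    the larger covariate-adjusted weight.  One permutation sequence (from
    ``seed``) is shared across edges.
    """
    subjects, labels, cov = _contrast_subset(cohort, contrast)
    edges = cohort.sorted_support()
    kind = WeightKind(weight_kind)
    Y = np.empty((len(subjects), len(edges)))
    for si, s in enumerate(subjects):
        w = s.matrices[kind].weights
        Y[si] = [w[i, j] for i, j in edges]
    return _matrix_group_test(Y, labels, cov, edges, m, seed, q)


def nodal_degree_group_test(
    cohort: Cohort,
    contrast: tuple[str, str],
    m: int = 10000,
    seed: int | np.random.Generator = 0,
    q: float = 0.05,
) -> EdgewiseResult:
    """Residualize-and-permute each node's degree; BH-FDR across nodes."""
    subjects, labels, cov = _contrast_subset(cohort, contrast)
    Y = np.vstack([nodal_degree(s.fiber_density) for s in subjects]).astype(float)
    items = list(range(cohort.n_nodes))
    return _matrix_group_test(Y, labels, cov, items, m, seed, q)


def mmse_association(
    cohort: Cohort,
    measure: np.ndarray,
    m: int = 10000,
    seed: int | np.random.Generator = 0,
) -> PermResult:
    """Permutation test of the MMSE term against one network measure.

    The measure is residualized on age, sex, brain volume and disease-status
    indicators over all subjects with an MMSE score; the MMSE values are then
    permuted.  Requires MMSE for at least 80% of subjects.
    """
    measure = np.asarray(measure, dtype=float)
    if measure.shape[0] != len(cohort.subjects):
        raise ValueError("measure must have one value per subject")
    has = np.array([s.mmse is not None for s in cohort.subjects])
    if not has.any():
        raise ValueError("MMSE missing for all subjects")
    if has.mean() < 0.8:
        raise ValueError("MMSE present for fewer than 80% of subjects")
    subjects = [s for s, h in zip(cohort.subjects, has) if h]
    y = measure[has]
    cov = pd.DataFrame(
        {
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "brain_volume": [s.brain_volume for s in subjects],
        }
    )
    groups = sorted({s.group.value for s in subjects})
    dummies = pd.DataFrame(
        {f"group_{g}": [1.0 if s.group.value == g else 0.0 for s in subjects]
         for g in groups[1:]}  # first group is reference
    )
    resid = residualize(y, cov, extra=dummies if not dummies.empty else None)
    mmse = np.array([float(s.mmse) for s in subjects])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.ptp(mmse) == 0:
        warnings.warn("degenerate MMSE (zero variance); p = 1")
        return PermResult(t_obs=0.0, p_perm=1.0, m=m, b=m,
                          seed=seed if isinstance(seed, int) else None)
    t_obs, t_perm = _perm_t_matrix(resid.reshape(-1, 1), mmse, m, rng)
    p, b = _p_from_t(t_obs, t_perm)
    return PermResult(t_obs=float(t_obs[0]), p_perm=float(p[0]), m=m, b=int(b[0]),
                      seed=seed if isinstance(seed, int) else None)
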