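# richclub

Weighted rich-club analysis of structural brain connectomes, with
permutation-based group inference — the network-neuroscience workflow used
to compare white-matter connectivity between dementia patients (behavioral-
variant frontotemporal dementia, early-onset Alzheimer's disease) and
healthy controls.

## What it computes

Structural connectomes are 68×68 symmetric weighted networks over the
Desikan–Killiany cortical atlas, with edge weights from diffusion MRI
tractography: fiber density, mean fractional anisotropy (FA), or mean
diffusivity (MD).

**Weighted rich-club coefficient.** For each degree level *k*, take the
subnetwork of nodes with degree > *k*; with *E₍>k₎* edges of total weight
*W₍>k₎* inside it,

    Φʷ(k) = W₍>k₎ / Σ of the E₍>k₎ strongest edge weights in the whole network.

Because strong edges concentrate on high-degree nodes even in random graphs,
Φʷ is normalized by its mean over degree-preserving random networks
(Maslov–Sneppen rewiring with the original weight multiset reshuffled):
Φₙ(k) = Φʷ(k) / ⟨Φʷ_rand(k)⟩. A rich club is present where Φₙ > 1.

**Edge taxonomy.** Given a rich-club node set (default: 13 bilateral
regions, 26 nodes, selected by group-mean degree ≥ 30 in every diagnostic
group), each edge is *rich-club* (both endpoints in the club), *feeder*
(one), or *local* (neither).

**Group inference.** Measures are residualized against age, sex and total
brain volume by OLS; the diagnosis effect is the t-statistic of the group
indicator on those residuals, with significance from *m* = 10,000 label
permutations, p = (b+1)/(m+1) where *b* counts permuted |t| exceeding the
observed. Benjamini–Hochberg FDR (q = 0.05) corrects across edges, nodes or
*k*-levels. Chi-squared tests then ask whether the significantly altered
edges are distributed across the three classes in proportion to each
class's share of all edges.

**Synthetic cohorts.** Because subject-level MRI data cannot be shipped, a
calibrated generator produces cohorts with the structure the analysis
assumes: exponentially truncated power-law strengths, a planted fully
connected 26-node core, anticorrelated FA/MD weights sharing one support,
covariate effects, group-specific edge lesions with exact ground-truth
bookkeeping, and MMSE scores tracking lesion burden.

## Worked example

```python
import richclub as rc

cohort, truth = rc.generate_cohort(rc.default_spec(seed=11))
res = rc.edgewise_group_test(cohort, "fiber_density", ("EOAD", "control"),
                             m=2000, seed=3)
cmap = rc.classify_edges(cohort.edge_support, frozenset(truth.core_indices))
```

Running `python examples/04_group_inference.py` (the full version of the
above) prints:

```
edges tested: 760
FDR-significant: 152 (critical p = 0.009995)

class      affected / total   rate
rich_club   145 /  325      0.446
feeder        2 /  318      0.006
local         1 /  117      0.009

chi-squared enrichment: chi2 = 228.9, df = 2, p = 1.99e-50
```

Of 760 edges carried by at least one subject, 152 are significantly reduced
in the synthetic EOAD group after covariate adjustment and FDR correction.
44.6% of rich-club edges are affected against under 1% of feeder and local
edges — the chi-squared test confirms the planted rich-club lesion is
recovered as rich-club enrichment. The other scripts in `examples/` walk
through the rich-club curve, cohort simulation, node/edge classification,
and re-testing published class counts.

Published count tables can be re-tested directly:

```python
rc.chi2_class_report(
    affected={"rich_club": 23, "feeder": 12, "local": 4},
    totals={"rich_club": 195, "feeder": 442, "local": 206},
)["p"]            # 3.49e-07
```

A thin CLI mirrors the stages (`richclub simulate`, `richclub richclub`,
`richclub select-nodes`, `richclub classify`, `richclub group-test`,
`richclub chi2`, `richclub run-all`, `richclub report`); matrices are plain
TSV and covariates CSV, so the pipeline also runs on any external data in
those formats.

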