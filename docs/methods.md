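# Methods

## Network model

A connectome is an undirected weighted graph on the 68 cortical regions of
the Desikan–Killiany atlas (34 per hemisphere; canonical node order is 34
left-hemisphere labels then 34 right, alphabetical within hemisphere, shipped
as `richclub/data/dk68_labels.txt`). An edge exists wherever its weight is
strictly positive; no minimum-weight threshold is applied (streamline-count
filtering belongs to tractography preprocessing, upstream of this package).
Matrices are validated at load time: symmetry within 1e-8 (small
discrepancies are averaged, larger ones are errors, since tractography
matrices are symmetric by construction), zero diagonal, nonnegative
weights, FA ≤ 1. The three weight kinds of one subject share a single
binary support — FA and MD are only defined along tracts that exist. At the
cohort level, node pairs with zero weight in every subject carry no
information and are excluded from all edgewise analyses.

## Weighted rich club

phi_w(k) compares the weight captured by the subnetwork of nodes with
degree strictly greater than k against the maximum that many edges could
carry anywhere in the network. Membership uses strict inequality (> k).
The coefficient is undefined (carried as NaN, never 0) when the subnetwork
has no edges, and is invariant to rescaling all weights by a positive
constant.

The null model is Maslov–Sneppen degree-preserving rewiring of the binary
support — 10·E attempted double-edge swaps per replicate, rejecting swaps
that would create self-loops or multi-edges — followed by a random
permutation of the original weight multiset onto the rewired edges. This
conserves the degree sequence and the weight distribution exactly, which
the test suite asserts per replicate. 500 replicates is the reference
default; calibration checks in the tests use 100, which already gives a
null-mean standard error well under the effects of interest. Networks too
sparse to admit any valid swap (e.g. a triangle) fall back to a
weight-reshuffled copy with a logged warning. The normalization phi_n uses
the null mean (not median), matching the convention of normalizing one
coefficient by the average of its random counterparts; observed and null
undefined values propagate to NaN pairwise.

The swap loop is implemented directly on the edge list rather than through
a general graph library: profiling showed the generic implementation spent
nearly all its time in weighted node sampling it does not need, and the
direct loop is ~20× faster at identical semantics.

## Node selection and edge classes

The published rich-club membership mixes several criteria (a k > 15 regime,
"top 12%", a degree-≥30 floor, and ad-hoc bilateral inclusions). This is
implemented as an auditable rule cascade: a node qualifies when its
group-mean fiber-density degree clears the floor (default 30) in **every**
diagnostic group; bilateral symmetrization pulls in a hemisphere's
homologue; an explicit override list force-includes named regions. The
selection rule travels with the resulting node set. The published 26-node
membership (13 bilateral regions) ships as a data file so downstream stages
can run exactly as reported, sidestepping the under-specified ranking
procedure. Selection always uses fiber-density degree; FA/MD analyses reuse
the same membership. Edge classification is purely topological: rich-club /
feeder / local by whether two / one / zero endpoints are club members; the
classes partition the present edges and are invariant to weight values.

## Group inference

Measures are residualized once on the pooled contrast sample by OLS against
intercept + age + sex (0/1) + total brain volume; the group effect is the
t-statistic of the diagnosis indicator regressed on those residuals, and
its null distribution comes from permuting the diagnosis labels
(permutation-of-residuals scheme; the Freedman–Lane refinement is a known
alternative but the simpler scheme is the reference procedure and its
type-I error is verified empirically — 0.05-level error within [0.03, 0.07]
over 2,000 null simulations). p = (b+1)/(m+1) with b counting permuted |t|
**strictly** exceeding the observed |t|; two-sided by magnitude, so the p
is invariant to which group is coded 1. The smallest attainable p is
1/(m+1) ≈ 1e-4 at the reference m = 10,000.

Edgewise and nodal tests vectorize the same statistic across items and
share one permutation sequence per family (so a max-statistic correction
could be derived later); BH-FDR is applied per contrast per weight kind.
The step-up rule is implemented directly (critical p = largest p_(i) with
p_(i) ≤ (i/n)q) and property-tested against a naive O(n²) threshold search.

Chi-squared enrichment uses the Pearson statistic on the 2×C table of
affected vs unaffected counts per edge class, without continuity
correction — validated by exact reproduction of nine published p-values
from their printed count tables. Expected class totals are each group's
mean per-subject class counts rounded to the nearest integer. Classes with
zero total are excluded with a warning and df reduced; a table with an
empty margin (no affected edges at all) has identical proportions by
construction and returns chi2 = 0, p = 1. One published inconsistency is
reproduced as the counts give it: the bvFTD-vs-EOAD pairwise values printed
as local-vs-rich = 0.016 and local-vs-feeder = 0.1 come out swapped
(0.108 and 0.0166) when recomputed from the printed counts; the
implementation reports what the counts give.

The MMSE association residualizes the measure on the nuisance covariates
plus disease-status indicators over all subjects with a score (required for
≥ 80% of subjects), then permutes the MMSE values.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuned per experiment.

* **Sizes and covariates.** 37 controls / 20 bvFTD / 23 EOAD; ages drawn
  per group (59.4 ± 9.6, 60.7 ± 10.7, 59.0 ± 5.0 years), sex balanced,
  brain volume ~ Normal(1.1e6, 1e5) mm³.
* **Topology.** Node propensities from Gamma(α = 1.5, s_c = 40) — the
  density s^(α−1)e^(−s/s_c) is the exponentially truncated power law
  reported for empirical fiber-density networks. The 26 largest draws are
  assigned to the rich-core nodes and boosted ×1.5; the core block is fully
  connected; remaining pairs connect with probability
  min(1, 0.10 + c·sᵢsⱼ), with c solved by bisection so overall density is
  0.33 (≈ 750 of 2278 pairs, matching empirical edge counts). The flat
  0.10 background represents short-range connectivity that exists
  regardless of hub status; without it the periphery barely interconnects
  and the local edge class collapses to a handful of edges, unlike real
  cortical networks.
* **Weights.** Fiber density ∝ sᵢsⱼ with log-normal dispersion, scaled to
  mean 1; FA in (0.2, 0.8) increasing in log fiber density; MD ≈ 1.5e-3 −
  1.0e-3·FA mm²/s plus noise — anticorrelated with FA, the degeneration
  signature's direction.
* **Lesions** are planted before subject noise, so the multiplier is the
  population mean effect, and are fixed per group (the same edges in every
  subject of the group — a population-level disease pattern). Defaults:
  EOAD attenuates 50% of rich-club edges (fiber ×0.8, FA ×0.97, MD ×1.1);
  bvFTD attenuates 40% of feeder+local edges (fiber ×0.75, FA ×0.9,
  MD ×1.08); 15% of affected edges are removed outright, producing the
  drop in edge count and nodal degree seen in disease. Affected fractions
  are the package's choice of a realistic lesion extent (roughly a fifth
  of all edges carrying a 20–25% weight loss).
* **Noise.** Multiplicative log-normal subject noise (σ = 0.15) keeps
  weights positive and effects interpretable as percentages; each subject
  additionally drops 2% of edges at random. MMSE = 29.1 −
  20·√(group burden) + noise (σ = 0.9 controls / 4.5 patients), clamped to
  [0, 30] — controls near ceiling, patient means in the low-to-mid 20s.
* **Reproducibility.** Everything derives from one integer seed;
  identical spec + seed gives a bit-identical cohort, and the ground-truth
  ledger (lesioned and removed edge lists per group, class map, burden)
  makes downstream sensitivity/specificity exactly computable.

What the generator does **not** emulate: spatial embedding and distance-
dependent connection probability, tractography false positives/negatives,
site or scanner effects, hemispheric asymmetries, and subject-specific
support beyond uniform dropout. Passing recovery tests therefore shows the
statistical machinery recovers planted effects under the assumed noise
model — not that it is robust to tractography artifacts.

## Numerical choices and degenerate inputs

Undefined rich-club values are NaN throughout and excluded pairwise, never
imputed. Degenerate permutation inputs (zero-variance residuals or MMSE)
return p = 1 with a warning rather than failing. Rank-deficient designs
raise an error naming a collinear column. The permutation floor, strict
inequality for b, and the BH critical-p convention are all pinned by tests
against closed forms or exhaustive enumeration. Brute-force oracle
equivalence for the rich-club coefficient is checked exhaustively over all
4-node supports and by a wide randomized sweep over 5–8-node graphs
(the full cross-product of supports and integer weightings up to 8 nodes is
combinatorially out of reach, but the sweep covers hundreds of instances
per run with exact agreement required).

## Problem sizes in tests and the acceptance script

Calibration and recovery runs are sized to what the statistics need:
null-model normalization uses 100 replicates where the reference default is
500 (the null-mean SE at 100 replicates is already an order of magnitude
below the effects tested); permutation tests in simulations use m = 500 or
2,000 rather than 10,000 (resolution 2e-3 / 5e-4, sufficient for FDR at the
observed significance levels); the type-I error estimate uses 2,000 null
simulations and each recovery rate 50 replicate cohorts. These choices make
the whole suite and the acceptance script each run in well under a minute
of compute per stage on a single core.

## Known limitations

* The "top 12%" ranking step of the published node selection is not fully
  specified; the rule cascade plus the shipped canonical membership is a
  reproducible stand-in, not a reconstruction of the original ranking.
* Per-subject normalization of rich-club curves is the default for
  statistics; normalizing a group-average network first is supported but
  not the default (the published choice is not stated).
* The per-subject normalized-curve stage of the full pipeline is the one
  computationally heavy step (subjects × replicates rewirings); the
  pipeline exposes `n_random` and `compute_curves` to scale it.
* MD curves use the identical formula with no inversion; interpreting
  lower MD-weighted phi_w in disease is left to reporting.
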