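"""Independent brute-force oracles, kept free of the implementation's code paths."""

import itertools

import networkx as nx
import numpy as np


def brute_force_phi(weights: np.ndarray, k: int) -> float:
    """Weighted rich-club coefficient by direct enumeration via networkx.

    Builds the graph, finds nodes of degree > k, enumerates the edges of the
    induced subgraph, and divides their weight sum by the sum of the same
    number of globally strongest weights.  Returns NaN for an empty club.
    """
    g = nx.Graph()
    n = weights.shape[0]
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if weights[i, j] > 0:
            g.add_edge(i, j, weight=float(weights[i, j]))
    club = [v for v in g if g.degree(v) > k]
    sub_edges = [d["weight"] for u, v, d in g.subgraph(club).edges(data=True)]
    if not sub_edges:
        return float("nan")
    all_w = sorted((d["weight"] for _, _, d in g.edges(data=True)), reverse=True)
    return sum(sub_edges) / sum(all_w[: len(sub_edges)])


def bh_oracle(p_values, q: float) -> np.ndarray:
    """Benjamini–Hochberg by naive O(n^2) threshold search.

    For every candidate threshold t in the observed p-values, check whether
    p_(rank of t) <= rank/n * q; reject at the largest passing threshold.
    """
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    best = None
    for t in p:
        rank = int((p <= t).sum())
        if t <= rank / n * q:
            if best is None or t > best:
                best = t
    if best is None:
        return np.zeros(n, dtype=bool)
    return p <= best


def exhaustive_perm_p(y: np.ndarray, labels: np.ndarray) -> float:
    """Exact strictly-greater fraction of the permutation t distribution.

    Enumerates every distinct assignment of the label multiset and returns
    the proportion with |t| strictly above |t_obs| — the population value
    of b/m under the (b+1)/(m+1) convention.
    """
    from scipy import stats

    def tstat(lab):
        a, b = y[lab == 1], y[lab == 0]
        return stats.ttest_ind(a, b, equal_var=True).statistic

    t_obs = abs(tstat(labels))
    n1 = int(labels.sum())
    idx = range(len(y))
    count = 0
    total = 0
    for ones in itertools.combinations(idx, n1):
        lab = np.zeros(len(y))
        lab[list(ones)] = 1
        total += 1
        if abs(tstat(lab)) > t_obs + 1e-12:
            count += 1
    return count / total
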