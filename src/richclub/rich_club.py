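"""Weighted rich-club coefficient, degree-preserving nulls, and normalized curves.

The weighted rich-club coefficient at degree level k,

    phi_w(k) = W_{>k} / sum of the E_{>k} strongest edge weights in the network,

takes the subnetwork of nodes with degree strictly greater than k, sums the
weights of the E_{>k} edges inside it, and divides by the maximum that sum
could have been had those E_{>k} edges carried the strongest weights found
anywhere in the network.  phi_w is therefore a ratio in [0, 1]; it equals 1
when the high-degree core monopolizes the strongest connections.

Because even random networks concentrate strong edges on high-degree nodes,
phi_w is normalized by its mean over degree-preserving random networks:
phi_n(k) = phi_w(k) / <phi_w_rand(k)>.  A rich-club phenomenon is present
where phi_n > 1 over a range of k.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .network_model import ConnectomeMatrix, WeightKind, nodal_degree

__all__ = ["RichClubCurve", "weighted_rich_club", "randomized_null", "rich_club_curve"]

logger = logging.getLogger(__name__)

#: attempted Maslov–Sneppen double-edge swaps per replicate, as a multiple of E
SWAP_MULTIPLIER = 10


@dataclass
class RichClubCurve:
    """Observed, null and normalized rich-club coefficients over k = 1..k_max.

    Undefined values (empty >k subnetwork, or zero null mean) are carried as
    NaN, never as 0.
    """

    k_values: np.ndarray
    phi_w: np.ndarray
    phi_rand_mean: np.ndarray
    phi_rand_samples: np.ndarray  # shape (n_random, k_max)
    phi_norm: np.ndarray
    weight_kind: WeightKind = WeightKind.fiber_density

    def defined_k(self) -> np.ndarray:
        """k values at which the normalized coefficient is defined."""
        return self.k_values[~np.isnan(self.phi_norm)]

    def null_band(self, lo: float = 2.5, hi: float = 97.5) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise percentile band of the null phi_w, normalized by the null mean."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo_b = np.nanpercentile(self.phi_rand_samples, lo, axis=0) / self.phi_rand_mean
            hi_b = np.nanpercentile(self.phi_rand_samples, hi, axis=0) / self.phi_rand_mean
        return lo_b, hi_b


def _phi_many(weights: np.ndarray, k_values: np.ndarray) -> np.ndarray:
    """phi_w over a vector of k levels for one weight matrix (NaN = undefined)."""
    deg = (weights > 0).sum(axis=1)
    iu, ju = np.triu_indices(weights.shape[0], k=1)
    w_edges = weights[iu, ju]
    present = w_edges > 0
    ranked = np.sort(w_edges[present])[::-1]  # strongest first
    cum = np.concatenate(([0.0], np.cumsum(ranked)))
    out = np.full(len(k_values), np.nan)
    for idx, k in enumerate(k_values):
        member = deg > k
        in_club = member[iu] & member[ju] & present
        e_k = int(in_club.sum())
        if e_k == 0:
            continue
        out[idx] = w_edges[in_club].sum() / cum[e_k]
    return out


def weighted_rich_club(m: ConnectomeMatrix | np.ndarray, k: int) -> float:
    """Weighted rich-club coefficient phi_w at a single degree level k.

    Returns NaN when no edge survives in the >k subnetwork.

    Raises
    ------
    ValueError
        If k is negative.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if not isinstance(m, ConnectomeMatrix):
        m = ConnectomeMatrix(np.asarray(m, dtype=float))
    return float(_phi_many(m.weights, np.array([k]))[0])


def _ms_rewire(
    edges: list[tuple[int, int]], nswap: int, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], int]:
    """Maslov–Sneppen double-edge swaps on an undirected simple edge list.

    Attempts ``nswap`` swaps; each picks two edges (a,b), (c,d), randomly
    orients them, and rewires to (a,d), (c,b) unless that would create a
    self-loop or a multi-edge.  Degrees are preserved exactly.  Returns the
    rewired edge list and the number of successful swaps.
    """
    edges = [tuple(sorted(e)) for e in edges]
    present = set(edges)
    n_edges = len(edges)
    if n_edges < 2:
        return edges, 0
    done = 0
    pick = rng.integers(0, n_edges, size=2 * nswap)
    flip = rng.random(size=2 * nswap) < 0.5
    for t in range(nswap):
        e1, e2 = pick[2 * t], pick[2 * t + 1]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[2 * t]:
            a, b = b, a
        if flip[2 * t + 1]:
            c, d = d, c
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if a == d or c == b or new1 in present or new2 in present:
            continue
        present.discard(edges[e1])
        present.discard(edges[e2])
        present.add(new1)
        present.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        done += 1
    return edges, done


def randomized_null(
    m: ConnectomeMatrix,
    n_random: int = 500,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Degree-preserving random surrogates of a weighted network.

    Each replicate rewires the binary support by Maslov–Sneppen double-edge
    swaps (10·E attempted swaps), preserving every node's degree exactly,
    then reassigns the original multiset of edge weights to the rewired
    edges in random order.  Both the degree sequence and the weight
    distribution of the observed network are thus conserved exactly.

    Networks too sparse for any valid swap fall back to a weight-reshuffled
    copy of the original support, with a logged warning.

    Returns a list of weight matrices (plain arrays, same shape as input).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    edges0 = m.edge_list()
    edge_weights = m.weights[np.triu_indices(m.n_nodes, k=1)]
    weight_pool = edge_weights[edge_weights > 0]
    n_edges = len(edges0)
    replicates: list[np.ndarray] = []
    for _ in range(n_random):
        edges, done = _ms_rewire(edges0, SWAP_MULTIPLIER * n_edges, rng)
        if n_edges >= 2 and done == 0:
            logger.warning("network too sparse to rewire; weight-reshuffled copy returned")
        out = np.zeros_like(m.weights)
        idx = np.array(edges, dtype=int).reshape(-1, 2)
        w = weight_pool[rng.permutation(n_edges)]
        out[idx[:, 0], idx[:, 1]] = w
        out[idx[:, 1], idx[:, 0]] = w
        replicates.append(out)
    return replicates


def rich_club_curve(
    m: ConnectomeMatrix,
    k_max: int = 30,
    n_random: int = 500,
    seed: int | np.random.Generator = 0,
) -> RichClubCurve:
    """Observed, null-mean and normalized rich-club coefficients for k = 1..k_max.

    phi_norm is NaN wherever the observed phi_w is undefined or the null mean
    is zero/undefined.
    """
    if k_max > m.n_nodes - 1:
        raise ValueError(f"k_max={k_max} exceeds n-1={m.n_nodes - 1}")
    k_values = np.arange(1, k_max + 1)
    phi_w = _phi_many(m.weights, k_values)
    nulls = randomized_null(m, n_random=n_random, seed=seed)
    samples = np.vstack([_phi_many(w, k_values) for w in nulls])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        phi_rand_mean = np.nanmean(samples, axis=0)
        phi_norm = np.where(
            np.isnan(phi_w) | np.isnan(phi_rand_mean) | (phi_rand_mean == 0),
            np.nan,
            phi_w / phi_rand_mean,
        )
    return RichClubCurve(
        k_values=k_values,
        phi_w=phi_w,
        phi_rand_mean=phi_rand_mean,
        phi_rand_samples=samples,
        phi_norm=phi_norm,
        weight_kind=m.weight_kind,
    )
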