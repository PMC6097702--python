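"""Node centralities, quartile-intersection hub calls and the label-permutation
group comparison.

Four centrality metrics are used: weighted degree (Wdg, sum of incident |r|
weights) and eigenvector centrality (Evc) are connection-based; closeness
(Clo) and betweenness (Bet), computed on shortest paths over distances
1 - |r|, are distance-based. A hub is a region in the upper quantile
(default 25%) of at least ``min_metrics`` (default 3) of the four metrics;
a stable hub is a hub at every p-threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .datatypes import ExpressionMatrix
from .network import ThresholdedNetwork

METRICS = ("Wdg", "Evc", "Clo", "Bet")

__all__ = [
    "METRICS",
    "centralities",
    "identify_hubs",
    "HubSet",
    "stable_hubs",
    "PermutationResult",
    "permutation_centrality_test",
]


def _eigenvector_from_weights(w: np.ndarray) -> np.ndarray:
    """Principal-eigenvector scores on the weighted adjacency, max-normalized.

    For a disconnected graph the leading eigenvector of the full adjacency is
    supported on the spectrally dominant component; nodes of the remaining
    components (and isolates) score ~0, which is the convention adopted at
    the fragmented strict thresholds.
    """
    if not w.any():
        return np.zeros(w.shape[0])
    vals, vecs = np.linalg.eigh(w)
    v = np.abs(vecs[:, -1])
    peak = v.max()
    if peak <= 0:
        return np.zeros(w.shape[0])
    v = v / peak
    v[v < 1e-10] = 0.0
    return v


def _closeness_from_sp(sp: np.ndarray) -> np.ndarray:
    """Closeness with the reachable-count rescaling for disconnected graphs:
    Clo(v) = (k / sum of distances to the k reachable nodes) * (k / (N - 1))."""
    n = sp.shape[0]
    clo = np.zeros(n)
    if n < 2:
        return clo
    for i in range(n):
        d = sp[i]
        mask = np.isfinite(d)
        mask[i] = False
        k = int(mask.sum())
        total = d[mask].sum()
        if k > 0 and total > 0:
            clo[i] = (k / total) * (k / (n - 1))
    return clo


def _betweenness_from_weights(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    ai, bi = np.where(np.triu(w, k=1) > 0)
    if len(ai) == 0:
        return np.zeros(n)
    dist = np.maximum(1.0 - w[ai, bi], 1e-12)
    g = ig.Graph(n=n, edges=list(zip(ai.tolist(), bi.tolist())))
    return np.asarray(g.betweenness(weights=dist.tolist()), dtype=float)


def _centralities_from_weights(w: np.ndarray) -> np.ndarray:
    """(n_nodes, 4) array of Wdg, Evc, Clo, Bet for a |r| weight matrix."""
    wdg = w.sum(axis=0)
    evc = _eigenvector_from_weights(w)
    graph = np.where(w > 0, np.maximum(1.0 - w, 1e-12), 0.0)
    sp = dijkstra(csr_matrix(graph), directed=False)
    clo = _closeness_from_sp(sp)
    bet = _betweenness_from_weights(w)
    return np.column_stack([wdg, evc, clo, bet])


def centralities(net: ThresholdedNetwork) -> pd.DataFrame:
    """Per-region centrality table (columns Wdg, Evc, Clo, Bet).

    Isolates score 0 on every metric; an empty graph yields an all-zero table.
    """
    table = _centralities_from_weights(net.weight_matrix())
    return pd.DataFrame(table, index=net.nodes, columns=list(METRICS))


def _top_set(values: pd.Series, quantile: float) -> set[str]:
    k = math.ceil(quantile * len(values))
    ranked = values.sort_values(ascending=False)
    cutoff = ranked.iloc[k - 1]
    # ties at the cutoff value are all included (rank-based, order-independent)
    return set(values.index[values >= cutoff])


def identify_hubs(
    table: pd.DataFrame, quantile: float = 0.25, min_metrics: int = 3
) -> set[str]:
    """Regions in the top ``quantile`` of at least ``min_metrics`` metrics."""
    if table.empty:
        raise ValueError("empty centrality table")
    counts: dict[str, int] = {r: 0 for r in table.index}
    for metric in table.columns:
        for region in _top_set(table[metric], quantile):
            counts[region] += 1
    return {r for r, c in counts.items() if c >= min_metrics}


@dataclass
class HubSet:
    """Hub calls per threshold, their intersection, and per-region hub scores."""

    per_threshold: dict[float, set[str]]
    stable: set[str] = field(init=False)
    hub_score: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.per_threshold:
            raise ValueError("no thresholds supplied")
        sets = list(self.per_threshold.values())
        self.stable = set.intersection(*sets)
        score: dict[str, int] = {}
        for hubs in sets:
            for region in hubs:
                score[region] = score.get(region, 0) + 1
        self.hub_score = score


def stable_hubs(hubsets: dict[float, set[str]]) -> HubSet:
    """Intersect per-threshold hub calls into stable hubs with hub scores."""
    return HubSet(per_threshold=dict(hubsets))


def _critical_r(n: int, level: float) -> float:
    """|r| above which the two-tailed p of a Pearson coefficient is <= level."""
    t_crit = stats.t.isf(level / 2.0, df=n - 2)
    return t_crit / math.sqrt(n - 2 + t_crit**2)


def _thresholded_weights(x: np.ndarray, r_crit: float) -> np.ndarray:
    """|r| adjacency of the p-thresholded correlation network of data x."""
    r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 0.0)
    a = np.abs(r)
    # p <= level is equivalent to |r| >= r_crit at fixed n (monotone t-transform)
    return np.where(a >= r_crit - 1e-15, a, 0.0)


@dataclass
class PermutationResult:
    """Empirical centrality differences (group A - group B) and permutation p."""

    diff: pd.DataFrame  # regions x metrics
    p: pd.DataFrame  # regions x metrics
    n_permutations: int
    level: float
    two_sided: bool
    add_one: bool
    rng_seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in self.diff.index:
            for metric in self.diff.columns:
                rows.append(
                    {
                        "region": region,
                        "metric": metric,
                        "diff": self.diff.loc[region, metric],
                        "p": self.p.loc[region, metric],
                    }
                )
        return pd.DataFrame(rows)


def permutation_centrality_test(
    exprA: ExpressionMatrix,
    exprB: ExpressionMatrix,
    level: float = 0.05,
    n_permutations: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
    two_sided: bool = True,
    add_one: bool = False,
) -> PermutationResult:
    """Label-permutation test of per-region centrality differences.

    Both groups must share an identical region set (compare same-size
    networks only). Each permutation reassigns subjects without replacement
    to two pseudo-groups of the original sizes and re-runs the full
    correlation -> threshold -> centrality pipeline, because group labels
    enter the analysis only through the correlation matrices. The default
    p-value is two-sided, the fraction of permuted |Diff| >= empirical
    |Diff|; ``two_sided=False`` gives the one-sided fraction of permuted
    Diff > empirical Diff, and ``add_one`` switches to (b + 1) / (m + 1).
    """
    regionsA, regionsB = exprA.regions, exprB.regions
    if set(regionsA) != set(regionsB):
        raise ValueError(
            "groups must share an identical region set; restrict them first"
        )
    exprB = exprB.restrict(regionsA)
    xA = exprA.data.to_numpy(dtype=float)
    xB = exprB.data.to_numpy(dtype=float)
    nA, nB = len(xA), len(xB)
    if nA + nB < 8:
        raise ValueError("at least 8 subjects combined are required")
    r_critA = _critical_r(nA, level)
    r_critB = _critical_r(nB, level)
    emp = _centralities_from_weights(
        _thresholded_weights(xA, r_critA)
    ) - _centralities_from_weights(_thresholded_weights(xB, r_critB))

    pooled = np.vstack([xA, xB])
    n_total = nA + nB
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    exceed = np.zeros_like(emp)
    for _ in range(n_permutations):
        perm = rng.permutation(n_total)
        pa = pooled[perm[:nA]]
        pb = pooled[perm[nA:]]
        diff = _centralities_from_weights(
            _thresholded_weights(pa, r_critA)
        ) - _centralities_from_weights(_thresholded_weights(pb, r_critB))
        if two_sided:
            exceed += np.abs(diff) >= np.abs(emp)
        else:
            exceed += diff > emp
    denom = n_permutations + 1 if add_one else n_permutations
    numer = exceed + 1 if add_one else exceed
    p = numer / denom
    seed = rng_seed if isinstance(rng_seed, int) else None
    return PermutationResult(
        diff=pd.DataFrame(emp, index=regionsA, columns=list(METRICS)),
        p=pd.DataFrame(np.clip(p, 0.0, 1.0), index=regionsA, columns=list(METRICS)),
        n_permutations=n_permutations,
        level=level,
        two_sided=two_sided,
        add_one=add_one,
        rng_seed=seed,
    )
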