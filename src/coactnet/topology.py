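"""Network topology: efficiency metrics and small-world assessment.

Global efficiency (Geff) is the mean of the inverse shortest-path length
over all unordered node pairs, computed on distance weights 1 - |r|;
unreachable pairs contribute 0 with the full pair count as denominator
(the harmonic-mean convention), so the measure is defined on fragmented
networks. Local efficiency (Leff) of a node is the Geff of the subgraph
induced on its neighbors. Small-worldness is assessed against ensembles
of degree-preserving rewired null networks: empirical/random Geff ratios
around 1 (integration no better than random) together with mean-Leff
ratios above 1 (above-random segregation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .network import ThresholdedNetwork

__all__ = [
    "global_efficiency",
    "local_efficiency",
    "mean_local_efficiency",
    "rewire_null",
    "NullEnsemble",
    "smallworld_assessment",
    "ci_overlap",
]


def _distance_from_weights(w: np.ndarray) -> np.ndarray:
    dist = np.where(w > 0, 1.0 - w, np.inf)
    np.fill_diagonal(dist, 0.0)
    return dist


def _geff_from_weights(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2:
        return 0.0
    # distance floor keeps |r| = 1 edges (distance 0) in the sparse graph
    graph = np.where(w > 0, np.maximum(1.0 - w, 1e-12), 0.0)
    sp = dijkstra(csr_matrix(graph), directed=False)
    iu = np.triu_indices(n, k=1)
    d = sp[iu]
    inv = np.zeros_like(d)
    reachable = np.isfinite(d) & (d > 0)
    inv[reachable] = 1.0 / d[reachable]
    return float(inv.sum() / len(d))


def _leff_node(w: np.ndarray, i: int) -> float:
    nbrs = np.flatnonzero(w[i] > 0)
    if nbrs.size < 2:
        return 0.0
    sub = w[np.ix_(nbrs, nbrs)]
    return _geff_from_weights(sub)


def _mean_leff_from_weights(w: np.ndarray) -> float:
    n = w.shape[0]
    return float(np.mean([_leff_node(w, i) for i in range(n)])) if n else 0.0


def global_efficiency(net: ThresholdedNetwork | np.ndarray) -> float:
    """Mean inverse shortest-path length over all unordered node pairs."""
    w = net.weight_matrix() if isinstance(net, ThresholdedNetwork) else np.asarray(net)
    if w.shape[0] < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _geff_from_weights(w)


def local_efficiency(net: ThresholdedNetwork, node: str) -> float:
    """Geff of the subgraph induced on the neighbors of ``node`` (node excluded)."""
    if node not in net.nodes:
        raise KeyError(f"node {node!r} not in network")
    return _leff_node(net.weight_matrix(), net.nodes.index(node))


def mean_local_efficiency(net: ThresholdedNetwork) -> float:
    """Mean of per-node local efficiencies; nodes with < 2 neighbors score 0."""
    return _mean_leff_from_weights(net.weight_matrix())


def _rewire_edges(
    a: np.ndarray,
    b: np.ndarray,
    n_swaps: int,
    rng: np.random.Generator,
    max_tries: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Degree-preserving double-edge swaps on an edge list (weights keep their
    slot, so the weight multiset travels with the swapped edges)."""
    a = a.copy()
    b = b.copy()
    present = set(map(frozenset, zip(a.tolist(), b.tolist())))
    n_edges = len(a)
    done = 0
    tries = 0
    while done < n_swaps:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"rewiring stalled after {max_tries} attempts "
                f"({done}/{n_swaps} swaps); graph admits too few legal swaps"
            )
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        u, v = a[i], b[i]
        x, y = a[j], b[j]
        if rng.integers(2):
            x, y = y, x
        # propose (u,v),(x,y) -> (u,x),(v,y)
        if u == x or v == y:
            continue
        e1 = frozenset((int(u), int(x)))
        e2 = frozenset((int(v), int(y)))
        if e1 in present or e2 in present:
            continue
        present.discard(frozenset((int(u), int(v))))
        present.discard(frozenset((int(x), int(y))))
        present.add(e1)
        present.add(e2)
        a[i], b[i] = u, x
        a[j], b[j] = v, y
        done += 1
    return a, b


@dataclass
class NullEnsemble:
    """Per-null empirical/random efficiency ratios for one network."""

    n_nets: int
    geff_ratio: np.ndarray
    leff_ratio: np.ndarray
    empirical_geff: float
    empirical_leff: float
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        self.geff_ratio = np.asarray(self.geff_ratio, dtype=float)
        self.leff_ratio = np.asarray(self.leff_ratio, dtype=float)
        if len(self.geff_ratio) != self.n_nets or len(self.leff_ratio) != self.n_nets:
            raise ValueError("ratio vectors must have length n_nets")
        if not (np.isfinite(self.geff_ratio).all() and (self.geff_ratio > 0).all()):
            raise ValueError("Geff ratios must be positive and finite")

    def ci(self, metric: str) -> tuple[float, float]:
        """Percentile confidence interval of the ratio distribution."""
        ratios = {"geff": self.geff_ratio, "leff": self.leff_ratio}[metric]
        alpha = (1.0 - self.ci_level) / 2.0
        # order statistics without interpolation: Leff ratios can be inf when
        # a null network has no local structure at all
        lo = np.quantile(ratios, alpha, method="lower")
        hi = np.quantile(ratios, 1.0 - alpha, method="higher")
        return float(lo), float(hi)

    @property
    def small_world(self) -> bool:
        """Leff-ratio CI entirely above 1 (with Geff ratio expected near 1)."""
        lo, _ = self.ci("leff")
        return lo > 1.0


def rewire_null(
    net: ThresholdedNetwork,
    n_nets: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
    max_tries_factor: int = 200,
) -> NullEnsemble:
    """Ensemble of degree-preserving rewired nulls with efficiency ratios.

    Each null copies the empirical network and applies floor(E/2) successful
    double-edge swaps (self-loops and multi-edges rejected and retried);
    node degrees and the edge-weight multiset are preserved exactly. The
    per-null ratios are empirical Geff / null Geff and empirical mean-Leff /
    null mean-Leff.
    """
    edges = net.edge_list()
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    nodes = net.nodes
    index = {r: i for i, r in enumerate(nodes)}
    a0 = np.array([index[r] for r in edges["region_a"]])
    b0 = np.array([index[r] for r in edges["region_b"]])
    weights = edges["weight"].to_numpy()
    n_swaps = n_edges // 2
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    emp_geff = _geff_from_weights(net.weight_matrix())
    emp_leff = _mean_leff_from_weights(net.weight_matrix())
    n_nodes = len(nodes)
    geff_ratio = np.empty(n_nets)
    leff_ratio = np.empty(n_nets)
    for k in range(n_nets):
        a, b = _rewire_edges(
            a0, b0, n_swaps, rng, max_tries_factor * max(n_edges, n_swaps)
        )
        w = np.zeros((n_nodes, n_nodes))
        w[a, b] = weights
        w[b, a] = weights
        null_geff = _geff_from_weights(w)
        null_leff = _mean_leff_from_weights(w)
        if null_geff <= 0:
            raise RuntimeError("null network has zero global efficiency")
        geff_ratio[k] = emp_geff / null_geff
        # a null can have zero mean Leff (e.g. tree-like); ratio is inf then
        leff_ratio[k] = emp_leff / null_leff if null_leff > 0 else np.inf
    return NullEnsemble(
        n_nets=n_nets,
        geff_ratio=geff_ratio,
        leff_ratio=leff_ratio,
        empirical_geff=emp_geff,
        empirical_leff=emp_leff,
    )


def ci_overlap(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> bool:
    """True when two confidence intervals overlap (touching counts as overlap)."""
    return ci_a[0] <= ci_b[1] and ci_b[0] <= ci_a[1]


def smallworld_assessment(
    ensembles: dict[str, NullEnsemble]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries and pairwise CI-overlap comparisons for named ensembles.

    Returns a per-network summary (ratio means, 95% CIs, small-world call)
    and a pairwise table flagging significant differences (CI non-overlap)
    per metric. Lack of overlap between two 95% CIs is read as a significant
    group difference.
    """
    rows = []
    for name, ens in ensembles.items():
        geff_lo, geff_hi = ens.ci("geff")
        leff_lo, leff_hi = ens.ci("leff")
        rows.append(
            {
                "network": name,
                "geff": ens.empirical_geff,
                "leff": ens.empirical_leff,
                "geff_ratio_mean": float(np.mean(ens.geff_ratio)),
                "geff_ci_lo": geff_lo,
                "geff_ci_hi": geff_hi,
                "leff_ratio_mean": (
                    float(np.mean(finite))
                    if len(finite := ens.leff_ratio[np.isfinite(ens.leff_ratio)])
                    else float("inf")
                ),
                "leff_ci_lo": leff_lo,
                "leff_ci_hi": leff_hi,
                "small_world": ens.small_world,
            }
        )
    summary = pd.DataFrame(rows)
    names = list(ensembles)
    comp_rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            for metric in ("geff", "leff"):
                ci_a = ensembles[na].ci(metric)
                ci_b = ensembles[nb].ci(metric)
                comp_rows.append(
                    {
                        "network_a": na,
                        "network_b": nb,
                        "metric": metric,
                        "significant": not ci_overlap(ci_a, ci_b),
                    }
                )
    comparisons = pd.DataFrame(
        comp_rows, columns=["network_a", "network_b", "metric", "significant"]
    )
    return summary, comparisons
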