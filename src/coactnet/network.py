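"""Correlation-network construction.

Cross-subject Pearson correlations between all region pairs, exact
two-tailed p-values from the t-transform, p-thresholding into weighted
undirected graphs, and a component census. Edge weights are |r| (negative
correlations enter as absolute values); the distance view is 1 - |r|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix


@dataclass
class CorrelationResult:
    """All-pairs Pearson coefficients and two-tailed p-values at sample size n."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    @property
    def regions(self) -> list[str]:
        return list(self.r.columns)

    @property
    def n_pairs(self) -> int:
        k = len(self.r)
        return k * (k - 1) // 2


@dataclass
class ThresholdedNetwork:
    """Weighted undirected graph of regions surviving a p-threshold.

    ``weight`` is the |r| adjacency (0 where no edge), ``signed_r`` keeps the
    sign for reporting. ``corr`` retains the unthresholded correlation result
    so edge-level comparisons can fall back to sub-threshold coefficients.
    """

    level: float
    weight: pd.DataFrame
    signed_r: pd.DataFrame
    n: int
    corr: CorrelationResult | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        w = self.weight.to_numpy(dtype=float)
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.diag(w).any():
            raise ValueError("self-loops are not allowed")
        if (w < 0).any() or (w > 1).any():
            raise ValueError("edge weights must lie in (0, 1]")

    @property
    def nodes(self) -> list[str]:
        return list(self.weight.columns)

    @property
    def n_nodes(self) -> int:
        return len(self.weight)

    @property
    def n_edges(self) -> int:
        return int((self.weight.to_numpy() > 0).sum() // 2)

    def weight_matrix(self) -> np.ndarray:
        return self.weight.to_numpy(dtype=float)

    def distance_matrix(self) -> np.ndarray:
        """Per-edge distance 1 - |r|; np.inf where there is no edge."""
        w = self.weight_matrix()
        dist = np.where(w > 0, 1.0 - w, np.inf)
        np.fill_diagonal(dist, 0.0)
        return dist

    def edge_list(self) -> pd.DataFrame:
        """One row per edge: region_a, region_b, weight, signed_r (a < b order)."""
        w = self.weight_matrix()
        iu = np.triu_indices_from(w, k=1)
        mask = w[iu] > 0
        nodes = np.asarray(self.nodes)
        return pd.DataFrame(
            {
                "region_a": nodes[iu[0][mask]],
                "region_b": nodes[iu[1][mask]],
                "weight": w[iu][mask],
                "signed_r": self.signed_r.to_numpy()[iu][mask],
            }
        )

    def edge_weights(self) -> np.ndarray:
        w = self.weight_matrix()
        iu = np.triu_indices_from(w, k=1)
        return w[iu][w[iu] > 0]

    def edge_signed_r(self) -> np.ndarray:
        w = self.weight_matrix()
        r = self.signed_r.to_numpy()
        iu = np.triu_indices_from(w, k=1)
        return r[iu][w[iu] > 0]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edge_list().itertuples(index=False):
            g.add_edge(
                row.region_a,
                row.region_b,
                weight=float(row.weight),
                signed_r=float(row.signed_r),
                distance=float(1.0 - row.weight),
            )
        return g


def two_tailed_p(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Exact two-tailed p for a Pearson coefficient at sample size n.

    Uses t = r * sqrt((n - 2) / (1 - r^2)) referred to Student's t with
    n - 2 degrees of freedom. |r| = 1 maps to p = 0 by convention.
    """
    if n < 4:
        raise ValueError("n >= 4 required (need n - 2 >= 2 degrees of freedom)")
    r_arr = np.asarray(r, dtype=float)
    if (np.abs(r_arr) > 1 + 1e-12).any():
        raise ValueError("|r| must be <= 1")
    r_clip = np.clip(r_arr, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_clip * np.sqrt((n - 2) / (1.0 - r_clip**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r_clip) >= 1.0, 0.0, p)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(r) or np.ndim(r) == 0 else p


def pearson_matrix(expr: ExpressionMatrix) -> CorrelationResult:
    """All unordered region-pair Pearson correlations with two-tailed p-values.

    The expression matrix must hold a single group's subjects (use
    ``ExpressionMatrix.for_group`` first when it carries several groups).
    Zero-variance regions are rejected by name: their correlations are
    undefined.
    """
    labels = expr.group_labels()
    if len(labels) > 1:
        raise ValueError(
            f"expression matrix holds several groups {labels}; select one first"
        )
    x = expr.data.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("at least 4 subjects required")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [expr.regions[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance regions (correlation undefined): {bad}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    off = ~np.eye(len(r), dtype=bool)
    p = np.ones_like(r)
    p[off] = np.asarray(two_tailed_p(r[off], n))
    regions = expr.regions
    return CorrelationResult(
        r=pd.DataFrame(r, index=regions, columns=regions),
        p=pd.DataFrame(p, index=regions, columns=regions),
        n=n,
    )


def threshold(corr: CorrelationResult, level: float) -> ThresholdedNetwork:
    """Keep edges with p <= level (non-strict); weight = |r|, sign preserved."""
    r = corr.r.to_numpy(dtype=float)
    p = corr.p.to_numpy(dtype=float)
    keep = p <= level
    np.fill_diagonal(keep, False)
    weight = np.where(keep, np.abs(r), 0.0)
    signed = np.where(keep, r, 0.0)
    regions = corr.regions
    return ThresholdedNetwork(
        level=level,
        weight=pd.DataFrame(weight, index=regions, columns=regions),
        signed_r=pd.DataFrame(signed, index=regions, columns=regions),
        n=corr.n,
        corr=corr,
    )


def drop_regions(
    expr: ExpressionMatrix, flag: str = "in_dorsal_hippocampus"
) -> ExpressionMatrix:
    """Restrict the matrix to regions whose catalogue flag is False.

    Used to derive the control network with the lesioned regions removed
    (e.g. SHAM-nH from SHAM) so it matches the lesioned group's node set.
    Pearson correlations among the surviving regions are unchanged.
    """
    if expr.catalogue is None:
        raise ValueError("expression matrix carries no region catalogue")
    keep = [
        r
        for r in expr.regions
        if not getattr(expr.catalogue.lookup(r), flag, False)
    ]
    return expr.restrict(keep)


@dataclass(frozen=True)
class ComponentCensus:
    """Connected-component sizes (multi-node only) and isolate count."""

    component_sizes: tuple[int, ...]
    n_isolates: int

    @property
    def n_components(self) -> int:
        return len(self.component_sizes)


def component_census(net: ThresholdedNetwork) -> ComponentCensus:
    """Multi-node connected components and degree-0 isolates, counted apart."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    w = net.weight_matrix()
    n_comp, labels = connected_components(csr_matrix(w > 0), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    multi = tuple(sorted((int(s) for s in sizes if s > 1), reverse=True))
    isolates = int((sizes == 1).sum())
    return ComponentCensus(component_sizes=multi, n_isolates=isolates)
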