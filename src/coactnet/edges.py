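"""Edge-level comparison of two same-size correlation networks.

The two networks' surviving coefficients are Fisher-Z transformed and
compared as distributions (two-sample KS test) and cell by cell: the
difference z-score for one region pair is

    dC = (Z_A - Z_B) / sqrt(1/(df_A - 3) + 1/(df_B - 3))

where Z is the Fisher transform arctanh(r) and df the per-group sample
size (1/(n - 3) being the sampling variance of Z). |dC| above a cutoff
(default 2) is deemed a significant connectivity change; each significant
cell is attributed to the group with the larger coefficient and annotated
with that group's hub membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import ThresholdedNetwork

__all__ = [
    "fisher_z",
    "ks_edge_distributions",
    "EdgeDiffResult",
    "edge_diff_zscores",
    "classify_significant",
]


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher's variance-stabilizing transform Z = arctanh(r); |r| < 1 required."""
    arr = np.asarray(r, dtype=float)
    if (np.abs(arr) >= 1).any():
        raise ValueError("|r| must be < 1 for the Fisher Z transform")
    out = np.arctanh(arr)
    return float(out) if np.ndim(r) == 0 else out


def ks_edge_distributions(
    netA: ThresholdedNetwork, netB: ThresholdedNetwork
) -> tuple[float, float]:
    """Two-sample KS test on the networks' Fisher-Z edge-value multisets.

    D is the maximum ECDF gap; the p-value is the asymptotic two-sample
    Kolmogorov distribution at the standard effective sample size.
    """
    zA = fisher_z(netA.edge_signed_r())
    zB = fisher_z(netB.edge_signed_r())
    if len(zA) == 0 or len(zB) == 0:
        raise ValueError("both networks must have at least one edge")
    res = stats.ks_2samp(zA, zB, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class EdgeDiffResult:
    """Per-cell Fisher-Z difference z-scores between two networks."""

    cells: pd.DataFrame  # region_a, region_b, r_a, r_b, z_a, z_b, dC, significant, owner
    ks_D: float
    ks_p: float
    z_cutoff: float
    nA: int
    nB: int
    df_convention: str
    absent_edge_mode: str

    @property
    def significant_cells(self) -> pd.DataFrame:
        return self.cells[self.cells["significant"]]


def edge_diff_zscores(
    netA: ThresholdedNetwork,
    netB: ThresholdedNetwork,
    nA: int | None = None,
    nB: int | None = None,
    z_cutoff: float = 2.0,
    df_convention: str = "n",
    absent_edge_mode: str = "unthresholded",
    labels: tuple[str, str] = ("A", "B"),
) -> EdgeDiffResult:
    """dC z-scores over the union of the two networks' edges.

    For cells where the edge survives in only one network, the absent side
    contributes its unthresholded coefficient by default (``absent_edge_mode
    = "unthresholded"``; requires the networks to carry their correlation
    result). ``absent_edge_mode = "zero"`` treats sub-threshold coefficients
    as exactly 0 instead. ``df_convention`` is "n" (variance of Z is
    1/(n - 3), the standard two-correlation comparison) or "n-2".
    """
    if netA.nodes != netB.nodes:
        if set(netA.nodes) != set(netB.nodes):
            raise ValueError("networks must share an identical node set")
        raise ValueError("networks must list their nodes in the same order")
    nA = netA.n if nA is None else nA
    nB = netB.n if nB is None else nB
    if nA < 4 or nB < 4:
        raise ValueError("both groups need at least 4 subjects")
    dfA = {"n": nA, "n-2": nA - 2}[df_convention]
    dfB = {"n": nB, "n-2": nB - 2}[df_convention]
    if dfA <= 3 or dfB <= 3:
        raise ValueError("degrees of freedom must exceed 3")
    if absent_edge_mode not in ("unthresholded", "zero"):
        raise ValueError(f"unknown absent_edge_mode: {absent_edge_mode!r}")

    wA = netA.weight_matrix()
    wB = netB.weight_matrix()
    union = (wA > 0) | (wB > 0)
    iu = np.triu_indices_from(wA, k=1)
    mask = union[iu]
    rows_a, rows_b = iu[0][mask], iu[1][mask]

    sA = netA.signed_r.to_numpy()
    sB = netB.signed_r.to_numpy()
    if absent_edge_mode == "unthresholded":
        if netA.corr is None or netB.corr is None:
            raise ValueError(
                "unthresholded fallback needs networks carrying their "
                "correlation result"
            )
        fullA = netA.corr.r.to_numpy()
        fullB = netB.corr.r.to_numpy()
        rA = np.where(wA > 0, sA, fullA)[rows_a, rows_b]
        rB = np.where(wB > 0, sB, fullB)[rows_a, rows_b]
    else:
        rA = sA[rows_a, rows_b]
        rB = sB[rows_a, rows_b]

    zA = fisher_z(rA)
    zB = fisher_z(rB)
    se = np.sqrt(1.0 / (dfA - 3) + 1.0 / (dfB - 3))
    dC = (zA - zB) / se
    significant = np.abs(dC) > z_cutoff
    owner = np.where(zA > zB, labels[0], labels[1])

    nodes = np.asarray(netA.nodes)
    cells = pd.DataFrame(
        {
            "region_a": nodes[rows_a],
            "region_b": nodes[rows_b],
            "r_a": rA,
            "r_b": rB,
            "z_a": zA,
            "z_b": zB,
            "dC": dC,
            "significant": significant,
            "owner": owner,
        }
    )
    ks_D, ks_p = ks_edge_distributions(netA, netB)
    return EdgeDiffResult(
        cells=cells,
        ks_D=ks_D,
        ks_p=ks_p,
        z_cutoff=z_cutoff,
        nA=nA,
        nB=nB,
        df_convention=df_convention,
        absent_edge_mode=absent_edge_mode,
    )


def classify_significant(
    result: EdgeDiffResult,
    hubsA: set[str],
    hubsB: set[str],
    labels: tuple[str, str] = ("A", "B"),
) -> dict[str, int]:
    """Counts of significant cells: total, per owner group, and per owner
    group touching one of that group's hubs."""
    sig = result.significant_cells
    own_a = sig[sig["owner"] == labels[0]]
    own_b = sig[sig["owner"] == labels[1]]

    def touches(cells: pd.DataFrame, hubs: set[str]) -> int:
        return int(
            (cells["region_a"].isin(hubs) | cells["region_b"].isin(hubs)).sum()
        )

    return {
        "total": int(len(sig)),
        f"owned_{labels[0]}": int(len(own_a)),
        f"owned_{labels[1]}": int(len(own_b)),
        f"hub_edges_{labels[0]}": touches(own_a, hubsA),
        f"hub_edges_{labels[1]}": touches(own_b, hubsB),
    }
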