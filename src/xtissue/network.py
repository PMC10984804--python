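"""Shared two-tissue co-expression network construction and community detection.

Per-tissue edges are all gene pairs with Pearson r above a threshold at a
Benjamini-Hochberg FDR below a cap; the shared network is the intersection of
the two tissues' edge sets (optionally requiring sign concordance), and is
partitioned with the Louvain modularity algorithm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeSet",
    "CoexpressionNetwork",
    "CommunityPartition",
    "NetworkSummary",
    "tissue_edges",
    "intersect_edges",
    "louvain_partition",
    "network_summary",
]

#: community label given to nodes whose Louvain community is below min_size
UNASSIGNED = 0


@dataclass
class EdgeSet:
    """Retained co-expression edges of one tissue.

    ``table`` columns: gene_a, gene_b (gene_a < gene_b lexicographically),
    r, p, q.  ``n_pairs_tested`` is the BH universe size.
    """

    table: pd.DataFrame
    tissue: str
    n_samples: int
    n_pairs_tested: int


class NetworkSummary(NamedTuple):
    n_nodes: int
    n_edges: int
    mean_r: float


@dataclass
class CoexpressionNetwork:
    """Shared edge set: pairs retained in both tissues.

    ``edges`` columns: gene_a, gene_b, r_sm, r_sat.  ``nodes`` are the edge
    endpoints (degree-0 genes are excluded by construction).
    """

    nodes: list[str]
    edges: pd.DataFrame

    @property
    def summary(self) -> NetworkSummary:
        return network_summary(self)


@dataclass
class CommunityPartition:
    """Gene -> community id (ints, ordered by decreasing size; 0 = unassigned)."""

    membership: pd.Series
    modularity: float
    min_size: int
    resolution: float
    seed: int

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gene, cid in self.membership.items():
            out.setdefault(int(cid), []).append(gene)
        return out


def pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform t = r*sqrt((n-2)/(1-r^2))."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def tissue_edges(
    expr: pd.DataFrame,
    r_min: float = 0.30,
    fdr_max: float = 0.01,
    tissue: str = "",
    use_abs_r: bool = False,
) -> EdgeSet:
    """All gene pairs with Pearson r above threshold at BH FDR below ``fdr_max``.

    BH is applied across *all* pairs tested in the tissue.  ``r_min`` is a
    signed threshold (r > r_min) by default; ``use_abs_r`` switches to
    |r| > r_min.  Constant genes are excluded from pairing (logged).
    """
    n = expr.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for the correlation t-test")
    sd = expr.std(axis=1, ddof=1)
    const = sd <= 0
    if const.any():
        logger.warning("excluding %d constant gene(s) from edge testing", int(const.sum()))
        expr = expr.loc[~const]
    genes = expr.index.to_numpy()
    if len(genes) < 2:
        raise ValueError("fewer than 2 non-constant genes")

    corr = np.corrcoef(expr.to_numpy(dtype=float))
    iu, ju = np.triu_indices(len(genes), k=1)
    r = np.clip(corr[iu, ju], -1.0, 1.0)
    p = pearson_pvalues(r, n)
    q = multipletests(p, method="fdr_bh")[1]

    passed = (np.abs(r) > r_min) if use_abs_r else (r > r_min)
    keep = passed & (q < fdr_max)
    ga, gb = genes[iu[keep]], genes[ju[keep]]
    swap = ga > gb
    ga[swap], gb[swap] = gb[swap], ga[swap]
    table = pd.DataFrame(
        {"gene_a": ga, "gene_b": gb, "r": r[keep], "p": p[keep], "q": q[keep]}
    ).sort_values(["gene_a", "gene_b"], ignore_index=True)
    return EdgeSet(table=table, tissue=tissue, n_samples=n, n_pairs_tested=len(r))


def intersect_edges(
    edges_sm: EdgeSet,
    edges_sat: EdgeSet,
    require_sign_concordance: bool = True,
) -> CoexpressionNetwork:
    """Shared network: pairs passing in both tissues (optionally same r sign)."""
    merged = edges_sm.table.merge(
        edges_sat.table, on=["gene_a", "gene_b"], suffixes=("_sm", "_sat")
    )
    if require_sign_concordance and len(merged):
        merged = merged[np.sign(merged["r_sm"]) == np.sign(merged["r_sat"])]
    if merged.empty:
        raise ValueError(
            "no edge is shared between the two tissues; consider relaxing "
            "r_min/fdr_max or disabling sign concordance"
        )
    cols = ["gene_a", "gene_b", "r_sm", "r_sat"] + [
        c for c in ("p_sm", "q_sm", "p_sat", "q_sat") if c in merged.columns
    ]
    edges = merged[cols].reset_index(drop=True)
    nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    return CoexpressionNetwork(nodes=nodes, edges=edges)


def louvain_partition(
    network: CoexpressionNetwork,
    resolution: float = 1.0,
    min_size: int = 10,
    seed: int = 0,
    weighted: bool = False,
) -> CommunityPartition:
    """Louvain modularity communities of the (default unweighted) shared network.

    Communities smaller than ``min_size`` are relabeled ``UNASSIGNED`` (0);
    surviving communities are numbered 1, 2, ... by decreasing size.  The
    reported modularity is that of the raw Louvain partition on the graph used.
    """
    if not network.nodes:
        raise ValueError("empty network")
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    if weighted:
        mean_r = (network.edges["r_sm"].to_numpy() + network.edges["r_sat"].to_numpy()) / 2
        g.add_weighted_edges_from(
            zip(network.edges["gene_a"], network.edges["gene_b"], np.abs(mean_r))
        )
        weight = "weight"
    else:
        g.add_edges_from(zip(network.edges["gene_a"], network.edges["gene_b"]))
        weight = None
    comms = nx.community.louvain_communities(
        g, weight=weight, resolution=resolution, seed=seed
    )
    modularity = nx.community.modularity(g, comms, weight=weight, resolution=resolution)

    comms = sorted(comms, key=len, reverse=True)
    membership = pd.Series(UNASSIGNED, index=pd.Index(network.nodes, name="gene"), dtype=int)
    next_id = 1
    for c in comms:
        if len(c) >= min_size:
            membership.loc[sorted(c)] = next_id
            next_id += 1
    return CommunityPartition(
        membership=membership,
        modularity=float(modularity),
        min_size=min_size,
        resolution=resolution,
        seed=seed,
    )


def network_summary(network: CoexpressionNetwork) -> NetworkSummary:
    """(n_nodes, n_edges, mean over edges of the per-edge mean tissue r)."""
    n_edges = len(network.edges)
    if n_edges == 0:
        warnings.warn("empty network: mean_r is undefined (NaN)")
        return NetworkSummary(len(network.nodes), 0, float("nan"))
    mean_r = float(
        ((network.edges["r_sm"] + network.edges["r_sat"]) / 2.0).mean()
    )
    return NetworkSummary(len(network.nodes), n_edges, mean_r)
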