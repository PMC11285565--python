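"""Consensus ("significant") edges across folds and iterations, and their
network-level summaries.

An edge counts as *significant* for a sign if, in at least 40% of the
iterations, it was selected with that sign in >= 2 of the 5 folds (the fold
minimum generalizes to ceil(0.4 * k) for non-default k).  Between-network
summaries count significant edges per network pair normalized by the number
of possible edges between the pair; within-network heatmaps sum signed
fold-level selections over all folds x iterations, bounded by +/-(k * iters)
(+/-5,000 at the default 5 folds x 1,000 iterations), with a per-node summed
vector (SV) given by half the row sum of the symmetric within-network matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Atlas
from .connectome import edge_pairs, n_edges
from .cpm import CPMIterationResult


@dataclass
class ConsensusEdgeTable:
    """Per-edge, per-sign selection tallies across a CPM ensemble."""

    n_edges: int
    k_folds: int
    n_iterations: int
    fold_count_pos: np.ndarray       # total fold-level selections, 0..k*iters
    fold_count_neg: np.ndarray
    qualifying_pos: np.ndarray       # iterations with >= min_folds selections
    qualifying_neg: np.ndarray
    significant_pos: np.ndarray      # boolean flags
    significant_neg: np.ndarray
    min_folds: int = 2
    iteration_fraction: float = 0.4
    #: edges that met the criterion in both signs with equal qualifying
    #: counts; excluded from both flags and logged here.
    sign_ties: list[int] = field(default_factory=list)

    def to_frame(self, atlas: Atlas | None = None) -> pd.DataFrame:
        if atlas is not None:
            i, j = edge_pairs(atlas.n_nodes)
        else:
            # infer node count from edge count
            n = int((1 + math.isqrt(1 + 8 * self.n_edges)) // 2)
            i, j = edge_pairs(n)
        sign = np.where(self.significant_pos, "positive",
                        np.where(self.significant_neg, "negative", "none"))
        return pd.DataFrame({
            "node_i": i, "node_j": j,
            "fold_count_pos": self.fold_count_pos,
            "fold_count_neg": self.fold_count_neg,
            "qualifying_pos": self.qualifying_pos,
            "qualifying_neg": self.qualifying_neg,
            "sign": sign,
            "significant": sign != "none",
        })


def build_consensus(results: list[CPMIterationResult], n_edges_total: int,
                    min_folds: int | None = None,
                    iteration_fraction: float = 0.4) -> ConsensusEdgeTable:
    """Tally fold-level selections and apply the significance rule.

    An edge that meets the criterion in both signs is assigned the sign with
    the larger qualifying count; exact ties are excluded and logged.
    """
    if not results:
        raise ValueError("no iterations")
    k = len(results[0].fold_models)
    n_iter = len(results)
    if min_folds is None:
        min_folds = math.ceil(0.4 * k)
    fold_pos = np.zeros(n_edges_total, dtype=np.int64)
    fold_neg = np.zeros(n_edges_total, dtype=np.int64)
    qual_pos = np.zeros(n_edges_total, dtype=np.int64)
    qual_neg = np.zeros(n_edges_total, dtype=np.int64)
    for res in results:
        it_pos = np.zeros(n_edges_total, dtype=np.int32)
        it_neg = np.zeros(n_edges_total, dtype=np.int32)
        for fm in res.fold_models:
            it_pos[fm.selection.positive] += 1
            it_neg[fm.selection.negative] += 1
        fold_pos += it_pos
        fold_neg += it_neg
        qual_pos += it_pos >= min_folds
        qual_neg += it_neg >= min_folds
    need = iteration_fraction * n_iter
    sig_pos = qual_pos >= need
    sig_neg = qual_neg >= need
    both = sig_pos & sig_neg
    ties: list[int] = []
    if both.any():
        for e in np.flatnonzero(both):
            if qual_pos[e] > qual_neg[e]:
                sig_neg[e] = False
            elif qual_neg[e] > qual_pos[e]:
                sig_pos[e] = False
            else:
                sig_pos[e] = sig_neg[e] = False
                ties.append(int(e))
    return ConsensusEdgeTable(
        n_edges=n_edges_total, k_folds=k, n_iterations=n_iter,
        fold_count_pos=fold_pos, fold_count_neg=fold_neg,
        qualifying_pos=qual_pos, qualifying_neg=qual_neg,
        significant_pos=sig_pos, significant_neg=sig_neg,
        min_folds=min_folds, iteration_fraction=iteration_fraction,
        sign_ties=ties,
    )


def summarize_internetwork(consensus: ConsensusEdgeTable, atlas: Atlas,
                           sign: str = "positive") -> pd.DataFrame:
    """Significant-edge count per network pair, normalized by pair size.

    The denominator for distinct networks A, B is |A|*|B|; for (A, A) it is
    |A|*(|A|-1)/2.  Symmetric table indexed by network name; a network with
    fewer than 2 nodes would get a NaN diagonal cell (the atlas contract
    forbids such networks, so this is defensive).
    """
    flags = _sign_flags(consensus, sign)
    nets = atlas.networks
    i, j = edge_pairs(atlas.n_nodes)
    li = atlas.labels[i]
    lj = atlas.labels[j]
    table = pd.DataFrame(0.0, index=nets, columns=nets)
    sizes = atlas.network_sizes()
    for a_pos, a in enumerate(nets):
        for b in nets[a_pos:]:
            if a == b:
                denom = sizes[a] * (sizes[a] - 1) / 2
                mask = (li == a) & (lj == a)
            else:
                denom = sizes[a] * sizes[b]
                mask = ((li == a) & (lj == b)) | ((li == b) & (lj == a))
            count = int(flags[mask].sum())
            val = count / denom if denom > 0 else float("nan")
            table.loc[a, b] = val
            table.loc[b, a] = val
    return table


def internetwork_counts(consensus: ConsensusEdgeTable, atlas: Atlas,
                        sign: str = "positive") -> pd.DataFrame:
    """Unnormalized significant-edge counts per network pair (for the
    conservation check: their upper-triangle-plus-diagonal sum equals the
    total significant edge count)."""
    flags = _sign_flags(consensus, sign)
    nets = atlas.networks
    i, j = edge_pairs(atlas.n_nodes)
    li = atlas.labels[i]
    lj = atlas.labels[j]
    table = pd.DataFrame(0, index=nets, columns=nets)
    for a_pos, a in enumerate(nets):
        for b in nets[a_pos:]:
            if a == b:
                mask = (li == a) & (lj == a)
            else:
                mask = ((li == a) & (lj == b)) | ((li == b) & (lj == a))
            c = int(flags[mask].sum())
            table.loc[a, b] = c
            table.loc[b, a] = c
    return table


def _sign_flags(consensus: ConsensusEdgeTable, sign: str) -> np.ndarray:
    if sign == "positive":
        return consensus.significant_pos
    if sign == "negative":
        return consensus.significant_neg
    raise ValueError(f"sign must be positive or negative, got {sign!r}")


def difference_map(summary_a: pd.DataFrame, summary_b: pd.DataFrame) -> pd.DataFrame:
    """Cellwise A - B (e.g. female minus male network-pair summaries)."""
    if list(summary_a.index) != list(summary_b.index) or \
            list(summary_a.columns) != list(summary_b.columns):
        raise ValueError("summaries come from different atlases")
    return summary_a - summary_b


@dataclass
class IntraNetworkHeatmap:
    """Signed within-network edge-selection sums and the node summed vector."""

    network: str
    nodes: np.ndarray                # atlas node indices of the network
    matrix: np.ndarray               # symmetric signed sums, zero diagonal
    summed_vector: np.ndarray        # per node: row sum / 2 (default rule)
    bound: int                       # k_folds * n_iterations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.nodes, columns=self.nodes)


def intranetwork_heatmap(consensus: ConsensusEdgeTable, atlas: Atlas,
                         network: str, halve_sv: bool = True) -> IntraNetworkHeatmap:
    """Signed fold-selection sums for every within-network edge.

    Each edge's value is (positive fold selections) - (negative fold
    selections) over all folds x iterations, in [-(k*iters), +(k*iters)].
    The summed vector halves each node's row sum of the symmetric matrix
    (set ``halve_sv=False`` for the unhalved sensitivity variant).
    """
    nodes = atlas.nodes_in(network)
    signed = consensus.fold_count_pos.astype(np.int64) - consensus.fold_count_neg
    full = np.zeros((atlas.n_nodes, atlas.n_nodes), dtype=np.int64)
    i, j = edge_pairs(atlas.n_nodes)
    full[i, j] = signed
    full[j, i] = signed
    sub = full[np.ix_(nodes, nodes)]
    sv = sub.sum(axis=1) / (2.0 if halve_sv else 1.0)
    return IntraNetworkHeatmap(network=network, nodes=nodes, matrix=sub,
                               summed_vector=sv,
                               bound=consensus.k_folds * consensus.n_iterations)
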