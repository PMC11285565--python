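"""Association-ratio network segregation and its between-sex comparison.

The association ratio of a network is the weighted sum of its within-network
edges divided by the weighted sum of *all* edges with at least one endpoint
in the network (within + boundary edges, each edge counted once):

    AR(network) = sum_{i<j in network} w_ij
                  / ( sum_{i<j in network} w_ij
                      + sum_{i in network, j not in network} w_ij ).

Higher values indicate stronger segregation of the network from the rest of
the graph.  Weights are raw signed Fisher-z values (no thresholding or
absolute value); for non-negative weights the ratio lies in [0, 1], equals 1
for a perfectly disconnected network, and is invariant to global rescaling.

Group comparisons use pooled-variance two-sample t-tests per (network, scan)
with the sign convention t > 0 <=> first group (female) mean higher, and
Benjamini-Hochberg correction across the 7 scans within each network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import Atlas
from .connectome import edge_pairs
from .stats import bh_adjust

#: |denominator| below this is treated as undefined (pathological signed sums).
DENOMINATOR_TOL = 1e-12


def association_ratio(connectome: np.ndarray, atlas: Atlas, network: str,
                      denominator: str = "incident",
                      tol: float = DENOMINATOR_TOL) -> float:
    """Association ratio of ``network`` in one connectome.

    ``denominator="incident"`` (default) normalizes by within + boundary
    weight; ``"boundary"`` is the strict within/boundary odds variant.
    Returns NaN when the denominator is within ``tol`` of zero.
    """
    members = np.zeros(atlas.n_nodes, dtype=bool)
    members[atlas.nodes_in(network)] = True
    m = np.asarray(connectome, float)
    i, j = edge_pairs(atlas.n_nodes)
    w = m[i, j]
    within = members[i] & members[j]
    boundary = members[i] ^ members[j]
    num = float(w[within].sum())
    boundary_sum = float(w[boundary].sum())
    den = num + boundary_sum if denominator == "incident" else boundary_sum
    if denominator not in ("incident", "boundary"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    if abs(den) < tol:
        return float("nan")
    return num / den


def association_ratio_edges(edge_matrix: np.ndarray, atlas: Atlas, network: str,
                            denominator: str = "incident",
                            tol: float = DENOMINATOR_TOL) -> np.ndarray:
    """Vectorized association ratio over a subjects x edges matrix."""
    members = np.zeros(atlas.n_nodes, dtype=bool)
    members[atlas.nodes_in(network)] = True
    i, j = edge_pairs(atlas.n_nodes)
    within = members[i] & members[j]
    boundary = members[i] ^ members[j]
    W = np.atleast_2d(np.asarray(edge_matrix, float))
    num = W[:, within].sum(axis=1)
    den = num + W[:, boundary].sum(axis=1) if denominator == "incident" \
        else W[:, boundary].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(den) < tol, np.nan, num / den)
    return out


def pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t-test; positive t when mean(a) > mean(b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 finite observations per group")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SegregationComparison:
    """Table-shaped between-group comparison of association ratios."""

    table: pd.DataFrame   # rows: scan; columns: MultiIndex (network, field)

    def cell(self, scan: str, network: str) -> dict:
        return {f: self.table.loc[scan, (network, f)]
                for f in ("t", "p", "p_bh", "survives")}


DEFAULT_COMPARE_NETWORKS: tuple[str, ...] = ("DMN", "VI", "VII", "VAs")


def compare_segregation(ratios_f: pd.DataFrame, ratios_m: pd.DataFrame,
                        networks: tuple[str, ...] = DEFAULT_COMPARE_NETWORKS,
                        scans: tuple[str, ...] | None = None,
                        q: float = 0.05, welch: bool = False,
                        bh_family: str = "per-network") -> SegregationComparison:
    """Compare per-subject association ratios between two groups.

    ``ratios_f``/``ratios_m``: DataFrames indexed by subject with columns
    MultiIndex (scan, network) or flat columns named "{scan}:{network}".
    BH correction runs across the scans within each network by default
    (``bh_family="per-network"``); ``"global"`` pools all cells.  Cells with
    fewer than two finite observations in either group are skipped (NaN).
    """
    rf = _normalize_columns(ratios_f)
    rm = _normalize_columns(ratios_m)
    if scans is None:
        scans = tuple(dict.fromkeys(s for s, _ in rf.columns))
    rows = []
    for nw in networks:
        for scan in scans:
            key = (scan, nw)
            t = p = float("nan")
            if key in rf.columns and key in rm.columns:
                a = rf[key].to_numpy(float)
                b = rm[key].to_numpy(float)
                a = a[np.isfinite(a)]
                b = b[np.isfinite(b)]
                if a.size >= 2 and b.size >= 2:
                    if welch:
                        res = sps.ttest_ind(a, b, equal_var=False)
                        t, p = float(res.statistic), float(res.pvalue)
                    else:
                        t, p = pooled_t(a, b)
            rows.append({"scan": scan, "network": nw, "t": t, "p": p})
    df = pd.DataFrame(rows)
    df["p_bh"] = np.nan
    if bh_family == "global":
        ok = df["p"].notna()
        if ok.any():
            df.loc[ok, "p_bh"] = bh_adjust(df.loc[ok, "p"].to_numpy())
    else:
        for nw in networks:
            ok = (df["network"] == nw) & df["p"].notna()
            if ok.any():
                df.loc[ok, "p_bh"] = bh_adjust(df.loc[ok, "p"].to_numpy())
    df["survives"] = df["p_bh"] < q
    wide = df.pivot(index="scan", columns="network")
    wide = wide.reorder_levels([1, 0], axis=1)
    wide = wide[[(nw, f) for nw in networks
                 for f in ("t", "p", "p_bh", "survives")]]
    wide = wide.loc[list(scans)]
    return SegregationComparison(table=wide)


def subject_ratios(edge_data: dict[str, np.ndarray], atlas: Atlas,
                   networks: tuple[str, ...],
                   denominator: str = "incident") -> pd.DataFrame:
    """Per-subject association ratios for every (scan, network) combination."""
    cols = {}
    for scan, W in edge_data.items():
        for nw in networks:
            cols[(scan, nw)] = association_ratio_edges(W, atlas, nw, denominator)
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["scan", "network"])
    return df


def format_table2(comp: SegregationComparison,
                  networks: tuple[str, ...] = DEFAULT_COMPARE_NETWORKS) -> pd.DataFrame:
    """Human-readable "t (p)" cells, daggered where BH correction fails."""
    out = {}
    for nw in networks:
        col = []
        for scan in comp.table.index:
            t = comp.table.loc[scan, (nw, "t")]
            p = comp.table.loc[scan, (nw, "p")]
            surv = comp.table.loc[scan, (nw, "survives")]
            if not np.isfinite(t):
                col.append("n/a")
            else:
                col.append(f"{t:.2f} ({p:.4g})" + ("" if surv else " †"))
        out[nw] = col
    return pd.DataFrame(out, index=comp.table.index)


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    if isinstance(df.columns, pd.MultiIndex):
        return df
    out = df.copy()
    out.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split(":", 1)) for c in df.columns], names=["scan", "network"])
    return out
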