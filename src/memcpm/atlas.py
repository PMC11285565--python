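"""Node-to-network atlas definitions.

A functional atlas assigns each of N nodes (regions of interest) to exactly one
intrinsic connectivity network.  The default convention is the 10-network
grouping used with the 268-node Shen parcellation, in the order::

    MF, FP, DMN, Mot, VI, VII, VAs, SAL, SC, CBL

(medial frontal, fronto-parietal, default mode, motor, visual I, visual II,
visual association, salience/limbic, subcortical, cerebellum).

No real parcellation label table ships with this package; :func:`synthetic_atlas`
builds a stand-in with plausible network proportions for simulation and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical network order for the 10-network grouping.
NETWORK_ORDER: tuple[str, ...] = (
    "MF", "FP", "DMN", "Mot", "VI", "VII", "VAs", "SAL", "SC", "CBL",
)

#: Approximate fraction of nodes per network used by :func:`synthetic_atlas`.
#: These proportions are synthetic (chosen as plausible; the real parcellation
#: table is not distributed here) and sum to 1.
DEFAULT_PROPORTIONS: dict[str, float] = {
    "MF": 0.11, "FP": 0.13, "DMN": 0.15, "Mot": 0.13, "VI": 0.08,
    "VII": 0.08, "VAs": 0.08, "SAL": 0.10, "SC": 0.07, "CBL": 0.07,
}


@dataclass(frozen=True)
class Atlas:
    """Immutable node → network assignment.

    Parameters
    ----------
    labels
        Length-N array of network names, one per node (0-based node index is
        the array position).
    node_names
        Optional per-node anatomical names.
    """

    labels: np.ndarray
    node_names: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("atlas labels must be a non-empty 1-D sequence")
        counts = pd.Series(labels).value_counts()
        tiny = counts[counts < 2]
        if len(tiny):
            raise ValueError(
                f"every network needs >=2 nodes; too small: {sorted(tiny.index)}"
            )

    @property
    def n_nodes(self) -> int:
        return int(self.labels.size)

    @property
    def networks(self) -> list[str]:
        """Network names present, in canonical order then first appearance."""
        present = set(self.labels.tolist())
        ordered = [n for n in NETWORK_ORDER if n in present]
        extra = [n for n in pd.unique(self.labels) if n not in set(ordered)]
        return ordered + list(extra)

    def nodes_in(self, network: str) -> np.ndarray:
        """0-based node indices belonging to ``network``."""
        idx = np.flatnonzero(self.labels == network)
        if idx.size == 0:
            raise KeyError(f"unknown network {network!r}")
        return idx

    def network_sizes(self) -> dict[str, int]:
        return {n: int((self.labels == n).sum()) for n in self.networks}

    # -- round-trip TSV interface ------------------------------------------
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"node_index": np.arange(self.n_nodes), "network_name": self.labels}
        )
        if self.node_names is not None:
            df["node_name"] = self.node_names
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Atlas":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("node_index")
        if not np.array_equal(df["node_index"].to_numpy(), np.arange(len(df))):
            raise ValueError("atlas node_index must be 0..N-1 with no gaps")
        names = df["node_name"].to_numpy() if "node_name" in df else None
        return cls(labels=df["network_name"].to_numpy(dtype=object), node_names=names)


def synthetic_atlas(n_nodes: int = 268,
                    proportions: dict[str, float] | None = None) -> Atlas:
    """Build a synthetic atlas distributing ``n_nodes`` over the 10 networks.

    Nodes are assigned in contiguous blocks following :data:`NETWORK_ORDER`
    with sizes proportional to ``proportions`` (largest-remainder rounding),
    every network receiving at least 2 nodes.
    """
    props = dict(DEFAULT_PROPORTIONS if proportions is None else proportions)
    names = [n for n in NETWORK_ORDER if n in props] + [
        n for n in props if n not in NETWORK_ORDER
    ]
    if n_nodes < 2 * len(names):
        raise ValueError(f"need >= {2 * len(names)} nodes for {len(names)} networks")
    total = sum(props.values())
    raw = np.array([props[n] / total * n_nodes for n in names])
    sizes = np.maximum(np.floor(raw).astype(int), 2)
    while sizes.sum() > n_nodes:
        sizes[int(np.argmax(sizes))] -= 1
    rema = raw - np.floor(raw)
    while sizes.sum() < n_nodes:
        order = np.argsort(-rema)
        k = int(order[0])
        sizes[k] += 1
        rema[k] = -1.0
    labels = np.concatenate([np.repeat(n, s) for n, s in zip(names, sizes)])
    return Atlas(labels=labels.astype(object))
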