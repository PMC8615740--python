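"""Seed-PLSC functional connectivity and graph-theoretic summaries.

Two channels (F3/F4 by default, proxies for left/right dorsolateral
prefrontal cortex) are pulled out of the feature matrix to act as the second
block: Y_seed holds the seed columns, X_seed the remaining channels. Running
the PLSC chain on (X_seed, Y_seed) yields a stacked correlation matrix whose
entries are within-group correlations between each seed's complexity and
every other channel's — a primitive functional-connectivity map. The brain
salience matrix is further condensed into a weighted undirected channel
graph (row-wise Pearson correlations), thresholded, and summarized with
degree, strength, density and betweenness centrality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .entropy import FeatureMatrix
from .errors import DegenerateRowError, ValidationError
from .io import channel_hemisphere
from .plsc import (
    GroupedDesign,
    PLSCDecomposition,
    build_correlation_matrix,
    brain_scores,
    decompose,
    normalize_within_group,
)

logger = logging.getLogger(__name__)

DEFAULT_SEEDS = ("F3", "F4")


def split_seed(
    features: pd.DataFrame, seeds: tuple[str, ...] = DEFAULT_SEEDS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a subjects x channels block into (X_seed, Y_seed).

    Y_seed holds the seed columns in the given seed order; X_seed keeps the
    remaining columns in montage order. Rows stay aligned.
    """
    missing = [s for s in seeds if s not in features.columns]
    if missing:
        raise ValidationError(f"seed channel(s) {missing} not in montage")
    y = features[list(seeds)]
    x = features[[c for c in features.columns if c not in seeds]]
    return x, y


@dataclass
class SeedPLSCResult:
    """Seed-PLSC decomposition plus the labeled connectivity blocks."""

    seeds: tuple[str, ...]
    design: GroupedDesign
    X_seed: pd.DataFrame
    Y_seed: pd.DataFrame
    decomposition: PLSCDecomposition
    L_X: np.ndarray

    @property
    def R_frame(self) -> pd.DataFrame:
        """Stacked correlations, rows (group, seed), columns non-seed channels."""
        rows = pd.MultiIndex.from_tuples(
            self.decomposition.row_labels, names=["group", "seed"]
        )
        return pd.DataFrame(
            self.decomposition.R, index=rows, columns=list(self.X_seed.columns)
        )

    @property
    def V_frame(self) -> pd.DataFrame:
        d = self.decomposition
        return pd.DataFrame(
            d.V, index=pd.Index(list(self.X_seed.columns), name="channel"),
            columns=[f"LV{l}" for l in range(1, d.rank + 1)],
        )


def seed_plsc(
    features: FeatureMatrix, seeds: tuple[str, ...] = DEFAULT_SEEDS
) -> SeedPLSCResult:
    """Run the PLSC chain with the seed channels as the second block."""
    design = GroupedDesign(tuple(features.groups))
    x, y = split_seed(features.data, seeds)
    Z_X = normalize_within_group(x.to_numpy(float), design)
    Z_Y = normalize_within_group(y.to_numpy(float), design)
    R = build_correlation_matrix(Z_X, Z_Y, design)
    row_labels = [(g, s) for g in design.groups for s in seeds]
    dec = decompose(R, row_labels=row_labels, col_labels=list(x.columns))
    return SeedPLSCResult(
        seeds=tuple(seeds), design=design, X_seed=x, Y_seed=y,
        decomposition=dec, L_X=brain_scores(Z_X, dec.V),
    )


def edges_from_saliences(
    connectivity: pd.DataFrame, display_threshold: float = 0.3
) -> pd.DataFrame:
    """Edge list (group, seed, channel, weight) above a display threshold.

    ``connectivity`` has MultiIndex rows (group, seed) and channel columns —
    the layout of the stacked seed correlation matrix. Signs are retained
    (positive vs negative co-activation). ``display_threshold=0`` emits all
    entries.
    """
    if not 0 <= display_threshold < 1:
        raise ValidationError(
            f"display threshold must be in [0, 1), got {display_threshold}"
        )
    records = []
    for (group, seed), row in connectivity.iterrows():
        for channel, w in row.items():
            if abs(w) > display_threshold:
                records.append((group, seed, channel, float(w)))
    return pd.DataFrame(
        records, columns=["group", "seed", "channel", "weight"]
    )


@dataclass
class WeightedGraph:
    """Symmetric channel-channel weight matrix with a zero diagonal."""

    nodes: list[str]
    weights: np.ndarray
    threshold_mode: str | None = None
    threshold_value: float | None = None

    def __post_init__(self):
        W = np.asarray(self.weights, float)
        if W.shape != (len(self.nodes), len(self.nodes)):
            raise ValidationError("weight matrix shape does not match node count")
        if np.abs(W - W.T).max() > 1e-12:
            raise ValidationError("weight matrix is not symmetric")
        if np.abs(np.diag(W)).max() != 0:
            raise ValidationError("weight matrix diagonal must be exactly 0")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int((np.abs(np.triu(self.weights)) > 0).sum())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.nodes, columns=self.nodes)


def salience_to_weight_matrix(V: pd.DataFrame) -> WeightedGraph:
    """Correlate the rows (channels) of a salience matrix across its columns.

    W[i, j] is the Pearson correlation of channel i's and channel j's salience
    profiles; the diagonal is zeroed. A constant row has undefined
    correlations and raises :class:`DegenerateRowError`.
    """
    if V.shape[1] < 2:
        raise ValidationError("need at least 2 salience columns to correlate rows")
    M = V.to_numpy(float)
    sd = M.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateRowError(
            f"constant salience row(s) {[V.index[i] for i in bad]}: "
            "correlation undefined"
        )
    W = np.corrcoef(M)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2  # enforce exact symmetry against rounding
    return WeightedGraph(nodes=list(V.index), weights=W)


def threshold_weights(
    graph: WeightedGraph, mode: str = "absolute", value: float = 0.20
) -> WeightedGraph:
    """Remove weak links, keeping either |w| >= value or the top fraction.

    'absolute' retains edges with |w| >= value (value in (0, 1));
    'proportional' retains the ceil(value * n(n-1)/2) strongest edges by |w|,
    with ties at the cutoff included. Removed edges are set to 0.
    """
    W = graph.weights.copy()
    n = graph.n_nodes
    if mode == "absolute":
        if not 0 < value < 1:
            raise ValidationError(f"absolute threshold must be in (0, 1), got {value}")
        W[np.abs(W) < value] = 0.0
    elif mode == "proportional":
        if not 0 < value <= 1:
            raise ValidationError(
                f"proportional threshold must be in (0, 1], got {value}"
            )
        iu = np.triu_indices(n, 1)
        mags = np.abs(W[iu])
        k = math.ceil(value * n * (n - 1) / 2)
        if k < mags.size:
            cutoff = np.sort(mags)[::-1][k - 1]
            W[np.abs(W) < cutoff] = 0.0
    else:
        raise ValidationError(f"unknown threshold mode {mode!r}")
    np.fill_diagonal(W, 0.0)
    return WeightedGraph(
        nodes=list(graph.nodes), weights=W,
        threshold_mode=mode, threshold_value=value,
    )


@dataclass
class GraphMetrics:
    """Per-node degree/strength/betweenness and the global edge density."""

    per_node: pd.DataFrame
    density: float


def graph_metrics(graph: WeightedGraph) -> GraphMetrics:
    """Degree, strength, density and betweenness of a thresholded graph.

    Strength sums |w| over retained edges. Betweenness uses the standard
    brain-connectivity convention of 1/|w| edge distances and is normalized
    by (n-1)(n-2)/2 paths per node. An edgeless graph yields all-zero metrics.
    """
    W = graph.weights
    n = graph.n_nodes
    adj = np.abs(W) > 0
    degree = adj.sum(axis=1)
    strength = np.abs(W).sum(axis=1)
    density = float(adj[np.triu_indices(n, 1)].sum() / (n * (n - 1) / 2))

    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i, j in zip(*np.nonzero(np.triu(adj, 1))):
        G.add_edge(int(i), int(j), distance=1.0 / abs(W[i, j]))
    if G.number_of_edges() == 0:
        logger.warning("graph has no edges above threshold; metrics are all zero")
        bc = {i: 0.0 for i in range(n)}
    else:
        bc = nx.betweenness_centrality(G, weight="distance", normalized=True)
    per_node = pd.DataFrame({
        "degree": degree.astype(int),
        "strength": strength,
        "betweenness": [bc[i] for i in range(n)],
    }, index=pd.Index(graph.nodes, name="node"))
    return GraphMetrics(per_node=per_node, density=density)


def hemisphere_summary(edges: pd.DataFrame, signed: bool = True) -> pd.DataFrame:
    """Mean connection intensity for same- vs different-hemisphere edges.

    Each (seed, channel) edge falls in exactly one cell per group: 'same' if
    the seed and target share a hemisphere (odd suffix = left, even = right),
    'different' otherwise. Both signed and absolute-value means are reported.
    """
    if edges.empty:
        raise ValidationError("no edges to summarize")
    df = edges.copy()
    df["pairing"] = [
        "same" if channel_hemisphere(s) == channel_hemisphere(c) else "different"
        for s, c in zip(df["seed"], df["channel"])
    ]
    out = df.groupby(["group", "pairing"])["weight"].agg(
        mean_signed="mean",
        mean_absolute=lambda w: w.abs().mean(),
        n_edges="count",
    ).reset_index()
    if not signed:
        out = out.drop(columns="mean_signed")
    return out
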