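"""Suspension mass-cytometry subset analysis.

The workflow mirrors standard practice for high-dimensional cytometry of
human B cells: arcsinh transform, sequential gating to live single
CD45+CD3-CD14-CD19+ B cells, a nonlinear 2-D embedding on the subset-defining
markers, clustering of events into nodes on the two embedding coordinates
(so phenotypically similar events share a node), rule-based grouping of
nodes into subset "bubbles", per-subset median profiles, and two summary
views: a metric MDS of per-sample profiles with Kruskal stress-1, and an
agglomerative dendrogram over subsets using all measured markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .panels import SubsetRule

META_COLUMNS = ("sample_id", "tissue", "donor", "truth_subset")


@dataclass
class EventTable:
    """Events x markers intensity table with per-event metadata.

    ``data`` holds one column per marker plus any of the metadata columns
    ``sample_id``, ``tissue``, ``donor``, ``truth_subset``.
    """

    data: pd.DataFrame
    markers: list[str]

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("EventTable requires at least one event")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        missing = [m for m in self.markers if m not in self.data.columns]
        if missing:
            raise ValueError(f"markers absent from data: {missing}")
        if self.data[self.markers].isna().any().any():
            raise ValueError("missing intensities are not allowed")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def intensities(self) -> np.ndarray:
        return self.data[self.markers].to_numpy(dtype=float)

    def select(self, mask: np.ndarray) -> "EventTable":
        return EventTable(self.data.loc[mask].reset_index(drop=True),
                          list(self.markers))


@dataclass(frozen=True)
class Gate:
    """1-D threshold gate: keep events above or below ``threshold``."""

    marker: str
    threshold: float
    keep: str = "above"  # "above" | "below"


@dataclass(frozen=True)
class PolygonGate:
    """2-D polygon gate on two markers; keeps events inside the polygon."""

    marker_x: str
    marker_y: str
    vertices: tuple[tuple[float, float], ...]


@dataclass
class NodeGraph:
    """Partition of embedded events into nodes with per-marker medians."""

    node_of_event: np.ndarray          # node id per event
    members: dict[int, np.ndarray]     # node id -> event indices
    medians: pd.DataFrame              # nodes x markers
    sizes: pd.Series                   # node id -> member count
    coords: np.ndarray                 # events x 2 embedding


@dataclass
class SubsetBubble:
    name: str
    node_ids: list[int]


@dataclass
class SubsetProfile:
    """Median transformed intensity per (tissue, subset, marker) and subset
    event fractions per tissue."""

    medians: pd.DataFrame    # index (tissue, subset), columns markers
    fractions: pd.DataFrame  # index tissue, columns subset, values sum to 1


def transform_intensities(table: EventTable, cofactor: float = 5.0) -> EventTable:
    """Apply the arcsinh transform x -> asinh(x / cofactor) to every marker."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    out = table.data.copy()
    out[table.markers] = np.arcsinh(out[table.markers].to_numpy(float) / cofactor)
    return EventTable(out, list(table.markers))


def _in_polygon(x: np.ndarray, y: np.ndarray,
                vertices: tuple[tuple[float, float], ...]) -> np.ndarray:
    from matplotlib.path import Path
    return Path(np.asarray(vertices)).contains_points(np.column_stack([x, y]))


def gate_events(table: EventTable, gates: list[Gate | PolygonGate],
                log: list[str] | None = None) -> EventTable:
    """Apply gates sequentially; events must satisfy every gate."""
    out = table
    for g in gates:
        refs = (g.marker,) if isinstance(g, Gate) else (g.marker_x, g.marker_y)
        for m in refs:
            if m not in out.markers:
                raise KeyError(f"gate references unknown marker {m!r}")
        if isinstance(g, Gate):
            v = out.data[g.marker].to_numpy(float)
            mask = v >= g.threshold if g.keep == "above" else v <= g.threshold
        else:
            mask = _in_polygon(out.data[g.marker_x].to_numpy(float),
                               out.data[g.marker_y].to_numpy(float),
                               g.vertices)
        if log is not None:
            log.append(f"gate {g}: kept {int(mask.sum())}/{len(mask)}")
        out = out.select(mask)
    return out


def default_b_cell_gates(threshold: float = 1.6) -> list[Gate]:
    """Live single CD45+CD3-CD14-CD19+ B-cell pre-gate (arcsinh scale)."""
    return [Gate("CD45", threshold, "above"), Gate("CD3", threshold, "below"),
            Gate("CD14", threshold, "below"), Gate("CD19", threshold, "above")]


def embed_2d(table: EventTable, markers: list[str], seed: int,
             method: str = "tsne", perplexity: float = 30.0) -> np.ndarray:
    """Neighbourhood-preserving 2-D embedding of events on ``markers``.

    The embedding algorithm is pluggable; ``"tsne"`` (default) uses
    Barnes-Hut t-SNE, ``"pca"`` a deterministic linear projection useful for
    smoke tests. Output rows align with input events.
    """
    if not markers:
        raise ValueError("markers must be non-empty")
    if table.n_events < 2:
        raise ValueError("need at least 2 events to embed")
    x = table.data[list(markers)].to_numpy(float)
    if method == "pca":
        from sklearn.decomposition import PCA
        return PCA(n_components=2, random_state=seed).fit_transform(x)
    if method == "tsne":
        perplexity = min(perplexity, max(1.0, (table.n_events - 1) / 3.0))
        ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                  init="pca", max_iter=750)
        return ts.fit_transform(x)
    raise ValueError(f"unknown embedding method {method!r}")


def cluster_nodes(coords: np.ndarray, table: EventTable, k: int = 100,
                  seed: int = 0) -> NodeGraph:
    """Partition events into ``k`` nodes by k-means on the two embedding
    coordinates; node medians are computed on all panel markers, including
    markers not used for the embedding (e.g. CD45RB)."""
    n = len(coords)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} events")
    if n != table.n_events:
        raise ValueError("coords and table are misaligned")
    km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    labels = km.fit_predict(np.asarray(coords, float))
    members = {int(i): np.flatnonzero(labels == i) for i in range(k)}
    x = table.intensities
    med = pd.DataFrame(
        {m: [float(np.median(x[idx, j])) for i, idx in sorted(members.items())]
         for j, m in enumerate(table.markers)},
        index=sorted(members),
    )
    sizes = pd.Series({i: len(idx) for i, idx in members.items()}).sort_index()
    return NodeGraph(labels, members, med, sizes, np.asarray(coords, float))


def assign_bubbles(graph: NodeGraph, rules: list[SubsetRule]) -> tuple[
        list[SubsetBubble], pd.Series]:
    """Assign each node to the first matching rule (fixed priority order).

    Returns the bubbles and a per-event subset label series. Unmatched nodes
    fall into "other".
    """
    node_label: dict[int, str] = {}
    for nid in graph.medians.index:
        med = graph.medians.loc[nid].to_dict()
        label = "other"
        for rule in rules:
            if rule.matches(med):
                label = rule.name
                break
        node_label[int(nid)] = label
    names = sorted({*node_label.values()})
    bubbles = [SubsetBubble(nm, [i for i, l in node_label.items() if l == nm])
               for nm in names]
    per_event = pd.Series([node_label[int(n)] for n in graph.node_of_event])
    return bubbles, per_event


def subset_medians(table: EventTable, subset_labels: pd.Series) -> SubsetProfile:
    """Median marker expression and event fractions per (tissue, subset).

    Empty subsets simply do not appear (medians of nothing are reported as
    missing, never zero).
    """
    df = table.data.copy()
    df["_subset"] = subset_labels.to_numpy()
    if "tissue" not in df.columns:
        df["tissue"] = "all"
    med = df.groupby(["tissue", "_subset"], observed=True)[table.markers].median()
    med.index.names = ["tissue", "subset"]
    counts = df.groupby(["tissue", "_subset"], observed=True).size()
    frac = counts.unstack(fill_value=0)
    frac = frac.div(frac.sum(axis=1), axis=0)
    frac.columns.name = "subset"
    return SubsetProfile(med, frac)


def profile_vector(table: EventTable, subset_labels: pd.Series,
                   subsets: list[str] | None = None) -> pd.Series:
    """Flatten a sample into one vector: per-subset marker medians plus
    subset fractions, suitable as an MDS input row.

    ``subsets`` fixes the subset universe so vectors from different samples
    align; absent subsets contribute zero fraction and zero medians.
    """
    labels = subset_labels.to_numpy()
    subsets = subsets or sorted(set(labels))
    parts: dict[str, float] = {}
    x = table.intensities
    n = len(labels)
    for s in subsets:
        sel = labels == s
        parts[f"frac|{s}"] = float(sel.sum()) / n
        med = (np.median(x[sel], axis=0) if sel.any()
               else np.zeros(x.shape[1]))
        for m, v in zip(table.markers, med):
            parts[f"med|{s}|{m}"] = float(v)
    return pd.Series(parts)


def mds_samples(profiles: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Classical (Torgerson) metric MDS of per-sample profile vectors to 2-D.

    Point-to-point distances in the plane approximate the Euclidean distances
    between the sample profile vectors; Kruskal stress-1,
    sqrt(sum (d_ij - delta_ij)^2 / sum delta_ij^2), reports the information
    lost by the reduction.

    Parameters
    ----------
    profiles : DataFrame, samples x features.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 samples for MDS")
    x = profiles.to_numpy(float)
    delta = squareform(pdist(x))
    if np.allclose(delta, 0):
        raise ValueError("degenerate: all profiles identical")
    n = len(x)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (delta ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:2]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    d = squareform(pdist(coords))
    iu = np.triu_indices(n, 1)
    stress = float(np.sqrt(np.sum((d[iu] - delta[iu]) ** 2)
                           / np.sum(delta[iu] ** 2)))
    return coords, stress


def hcluster_subsets(profiles: pd.DataFrame, method: str = "ward") -> np.ndarray:
    """Agglomerative hierarchy over subset median vectors (all markers).

    Euclidean distance, Ward linkage by default. Returns the scipy linkage
    matrix; rows of ``profiles`` are subsets.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 subsets")
    if profiles.isna().any().any():
        raise ValueError("missing marker values in subset profiles")
    return linkage(profiles.to_numpy(float), method=method, metric="euclidean")


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + i] = h
    return nodes[n + len(z) - 1] + ";"
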