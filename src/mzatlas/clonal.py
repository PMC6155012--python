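"""Clonal grouping of IgH rearrangements and lineage reconstruction.

Two-step clone definition: sequences are first partitioned by germline V
gene, J gene (allele suffixes collapsed to the gene level) and junction
length; within each partition, sequences whose normalised weighted junction
distance is below 0.2 are linked into clones by single-linkage connected
components.

The distance between two equal-length junctions is the number of nucleotide
differences, each weighted by a 5-mer context substitution model of somatic
hypermutation targeting (the human S5F model in the original analysis; a
model TSV can be supplied, uniform weights otherwise), divided by the
junction length.  With uniform weights this is exactly the normalised
Hamming distance.

Lineages are germline-rooted minimum-spanning trees on substitution-count
distances — a parsimony-style approximation to full maximum-parsimony tree
search; the total edge weight is reported as the parsimony score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_NT_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class FivemerModel:
    """5-mer context -> per-target substitution weight.

    ``weights[fivemer][target]`` is the weight of mutating the centre base of
    ``fivemer`` to ``target``.  Missing contexts fall back to 1.0 (uniform).
    Directional weights are symmetrised by averaging both directions.
    """

    weights: dict[str, dict[str, float]] = field(default_factory=dict)
    symmetrization: str = "mean"

    def weight(self, fivemer: str, target: str) -> float:
        w = self.weights.get(fivemer)
        if w is None:
            return 1.0
        v = w.get(target, 1.0)
        if v <= 0:
            raise ValueError("model weights must be positive")
        return v

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FivemerModel":
        df = pd.read_csv(path, sep="\t")
        weights: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            weights[row["fivemer"]] = {b: float(row[b]) for b in "ACGT"}
        return cls(weights)


def _context(seq: str, i: int) -> str:
    pad = "NN" + seq + "NN"
    return pad[i:i + 5]


def weighted_junction_distance(a: str, b: str,
                               model: FivemerModel | None = None) -> float:
    """Normalised weighted distance between equal-length junctions.

    Each mismatch contributes the symmetrised model weight of the
    substitution in its 5-mer context; the sum is divided by the evaluated
    length.  N positions are skipped and excluded from the length.
    """
    if len(a) != len(b):
        raise ValueError("junctions must have equal length")
    model = model or FivemerModel()
    total = 0.0
    length = 0
    for i, (x, y) in enumerate(zip(a, b)):
        if x == "N" or y == "N":
            continue
        length += 1
        if x != y:
            w_ab = model.weight(_context(a, i), y)
            w_ba = model.weight(_context(b, i), x)
            total += 0.5 * (w_ab + w_ba)
    if length == 0:
        return 0.0
    return total / length


_ALLELE = re.compile(r"\*\d+$")


def gene_call(call: str) -> str:
    """Collapse an allele-level call (IGHV5-51*01) to the gene (IGHV5-51)."""
    return _ALLELE.sub("", call.split(",")[0].strip())


def vj_partition(records: pd.DataFrame) -> dict[tuple[str, str, int], np.ndarray]:
    """Group records by (V gene, J gene, junction length); allele suffixes
    are ignored.  Returns key -> integer row positions."""
    for col in ("v_call", "j_call", "junction"):
        if col not in records.columns or records[col].isna().any():
            raise ValueError(f"missing {col} for partitioning")
    keys = list(zip(records["v_call"].map(gene_call),
                    records["j_call"].map(gene_call),
                    records["junction"].str.len()))
    groups: dict[tuple[str, str, int], list[int]] = {}
    for pos, k in enumerate(keys):
        groups.setdefault(k, []).append(pos)
    return {k: np.asarray(v) for k, v in groups.items()}


def _group_distance_matrix(junctions: list[str],
                           model: FivemerModel | None) -> np.ndarray:
    n = len(junctions)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = weighted_junction_distance(
                junctions[i], junctions[j], model)
    return d


def define_clones(records: pd.DataFrame, threshold: float = 0.2,
                  model: FivemerModel | None = None) -> pd.Series:
    """Assign clone ids: single-linkage components under d < threshold
    within each V/J/junction-length group.

    Clone ids are assigned in first-seen member order, so the labelling is
    deterministic given the input row order.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    groups = vj_partition(records)
    clone = np.full(len(records), -1, dtype=int)
    next_id = 0
    order = sorted(groups, key=lambda k: int(groups[k].min()))
    for key in order:
        idx = groups[key]
        juncs = records["junction"].iloc[idx].tolist()
        d = _group_distance_matrix(juncs, model)
        adj = d < threshold
        seen = np.zeros(len(idx), dtype=bool)
        for start in range(len(idx)):
            if seen[start]:
                continue
            stack = [start]
            seen[start] = True
            comp = []
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in np.flatnonzero(adj[u] & ~seen):
                    seen[v] = True
                    stack.append(v)
            clone[idx[sorted(comp)]] = next_id
            next_id += 1
    return pd.Series(clone, index=records.index, name="clone_id")


@dataclass
class DistanceToNearest:
    nearest: pd.Series           # per sequence; NaN for singletons
    suggested_threshold: float | None


def distance_to_nearest(records: pd.DataFrame,
                        model: FivemerModel | None = None
                        ) -> DistanceToNearest:
    """Per-sequence minimum distance to any other sequence in its
    V/J/length group; singletons are undefined (NaN), never zero.

    The suggested threshold is the deepest density valley between the two
    largest modes of the nearest-distance distribution — a diagnostic to
    sanity-check the default of 0.2, not a replacement for it.
    """
    groups = vj_partition(records)
    nearest = np.full(len(records), np.nan)
    for idx in groups.values():
        if len(idx) < 2:
            continue
        juncs = records["junction"].iloc[idx].tolist()
        d = _group_distance_matrix(juncs, model)
        np.fill_diagonal(d, np.inf)
        nearest[idx] = d.min(axis=1)
    vals = nearest[~np.isnan(nearest)]
    suggestion = None
    if len(vals) >= 10 and np.ptp(vals) > 0:
        from scipy.stats import gaussian_kde
        grid = np.linspace(vals.min(), vals.max(), 256)
        dens = gaussian_kde(vals)(grid)
        maxima = [i for i in range(1, 255)
                  if dens[i] >= dens[i - 1] and dens[i] >= dens[i + 1]]
        if len(maxima) >= 2:
            top = sorted(sorted(maxima, key=lambda i: -dens[i])[:2])
            lo, hi = top
            valley = lo + int(np.argmin(dens[lo:hi + 1]))
            suggestion = float(grid[valley])
    return DistanceToNearest(
        pd.Series(nearest, index=records.index, name="dist_to_nearest"),
        suggestion)


@dataclass
class LineageTree:
    """Germline-rooted tree: parent[i] is the parent of node i; node 0 is
    the germline root.  ``ids`` aligns node indices with sequence ids."""

    ids: list[str]               # node 0 = "germline"
    parent: np.ndarray           # parent[0] == -1
    edge_weights: np.ndarray     # substitutions on edge (node, parent)
    parsimony_score: float
    annotations: pd.DataFrame    # per observed node: subset/site/isotype/dups


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b) if x != "N" and y != "N")


def build_lineage(members: pd.DataFrame, germline: str) -> LineageTree:
    """Minimum-spanning tree over clone members plus the germline, on
    substitution-count distance, rooted at the germline.

    Ties in MST construction are broken toward higher duplicate count, then
    lexicographic sequence id (stable, documented).  The summed edge weight
    is reported as the parsimony score.
    """
    if len(members) < 2:
        raise ValueError("lineage requires a clone of at least 2 members")
    seqs = ["germline-root"] + members["sequence_id"].tolist()
    strings = [germline] + members["sequence"].tolist()
    dups = [np.inf] + members["duplicate_count"].tolist()
    n = len(strings)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _hamming(strings[i], strings[j])
    # Prim's algorithm from the germline with explicit tie-breaking
    in_tree = [0]
    parent = np.full(n, -1, dtype=int)
    while len(in_tree) < n:
        best = None
        for u in in_tree:
            for v in range(n):
                if v in in_tree:
                    continue
                cand = (d[u, v], -dups[v], seqs[v], v, u)
                if best is None or cand < best:
                    best = cand
        _, _, _, v, u = best
        parent[v] = u
        in_tree.append(v)
    weights = np.array([0.0 if parent[i] < 0 else d[i, parent[i]]
                        for i in range(n)])
    ann_cols = [c for c in ("subset", "site", "c_call", "duplicate_count")
                if c in members.columns]
    return LineageTree(seqs, parent, weights, float(weights.sum()),
                       members[["sequence_id", *ann_cols]].reset_index(drop=True))


def lineage_to_newick(tree: LineageTree) -> str:
    children: dict[int, list[int]] = {}
    for i, p in enumerate(tree.parent):
        if p >= 0:
            children.setdefault(int(p), []).append(i)

    def render(i: int) -> str:
        kids = children.get(i, [])
        label = tree.ids[i]
        if not kids:
            return f"{label}:{tree.edge_weights[i]:g}"
        inner = ",".join(render(k) for k in kids)
        if i == 0:
            return f"({inner}){label}"
        return f"({inner}){label}:{tree.edge_weights[i]:g}"

    return render(0) + ";"
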