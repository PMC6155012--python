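"""Pixel-as-event imaging mass cytometry subset mapping.

The unit of analysis is the pixel, not a segmented cell: tiles are stitched
into a mosaic, low-intensity pixels are cleaned by per-channel thresholds,
pixels become rows of an event table (with x/y coordinates on a linear
scale), and classification proceeds in two sequential stages — stage 1
selects nodes of CD19+CD20+ pixels after embedding/clustering on all
channels, stage 2 re-embeds the selected pixels on the nine B-cell markers
and assigns nodes to subset bubbles with the same rule machinery as the
suspension arm.  Nodes that no rule claims go to "other" and are excluded
from every mask.

Coordinates are 0-based, row-major, origin top-left; x = column, y = row.
For scalability the embedding runs on a random pixel subsample and the
remaining pixels join the nearest node centroid in marker space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .cytometry import EventTable, cluster_nodes, embed_2d
from .panels import IMC_B_MARKERS, SubsetRule, THRESH, imc_subset_rules


@dataclass
class TileSet:
    tiles: list[tuple[np.ndarray, list[str]]]  # (H x W x C, channel names)
    offsets: list[tuple[int, int]]             # (row, col) shifts


def stitch_tiles(tiles: TileSet) -> tuple[np.ndarray, list[str]]:
    """Place each tile at its (row, col) offset; on overlap the later tile
    wins.  Channel sets must agree; placements must stay in bounds of the
    mosaic implied by the tile extents."""
    if not tiles.tiles:
        raise ValueError("no tiles")
    channels = tiles.tiles[0][1]
    for _, ch in tiles.tiles:
        if ch != channels:
            raise ValueError("channel mismatch between tiles")
    h = max(off[0] + t.shape[0] for (t, _), off in zip(tiles.tiles, tiles.offsets))
    w = max(off[1] + t.shape[1] for (t, _), off in zip(tiles.tiles, tiles.offsets))
    for (t, _), (r, c) in zip(tiles.tiles, tiles.offsets):
        if r < 0 or c < 0:
            raise ValueError("negative offsets place tiles out of bounds")
    mosaic = np.zeros((h, w, len(channels)))
    for (t, _), (r, c) in zip(tiles.tiles, tiles.offsets):
        mosaic[r:r + t.shape[0], c:c + t.shape[1]] = t
    return mosaic, list(channels)


def denoise_threshold(image: np.ndarray, channels: list[str],
                      thresholds: dict[str, float]) -> np.ndarray:
    """Zero out intensities strictly below the per-channel threshold;
    values at or above the threshold pass unchanged."""
    for ch, t in thresholds.items():
        if ch not in channels:
            raise KeyError(f"unknown channel {ch!r}")
        if t < 0:
            raise ValueError("thresholds must be >= 0")
    out = image.copy()
    for ch, t in thresholds.items():
        k = channels.index(ch)
        plane = out[..., k]
        plane[plane < t] = 0.0
    return out


def pixels_to_events(image: np.ndarray, channels: list[str],
                     roi: np.ndarray | None = None) -> EventTable:
    """One event per retained pixel, with x (column) and y (row) stored as
    linear-scale columns alongside the channel intensities."""
    h, w, _ = image.shape
    if roi is None:
        roi = np.ones((h, w), dtype=bool)
    if roi.shape != (h, w):
        raise ValueError("ROI shape does not match image")
    if not roi.any():
        raise ValueError("empty ROI")
    ys, xs = np.nonzero(roi)
    df = pd.DataFrame(image[ys, xs], columns=channels)
    df["x"] = xs
    df["y"] = ys
    return EventTable(df, list(channels))


def events_to_image(events: EventTable, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of pixels_to_events within the ROI (unset pixels are zero)."""
    img = np.zeros((*shape, len(events.markers)))
    xs = events.data["x"].to_numpy(int)
    ys = events.data["y"].to_numpy(int)
    img[ys, xs] = events.intensities
    return img


def _stage_cluster(events: EventTable, markers: list[str], seed: int, k: int,
                   subsample: int) -> tuple[np.ndarray, pd.DataFrame]:
    """Embed a subsample on ``markers``, k-means the embedding into nodes,
    then assign every pixel to the nearest node centroid in marker space.
    Returns (node label per event, node medians over all channels)."""
    rng = np.random.default_rng(seed)
    n = events.n_events
    k = min(k, max(2, n - 1))
    if n > subsample:
        pick = np.sort(rng.choice(n, size=subsample, replace=False))
    else:
        pick = np.arange(n)
    sub = EventTable(events.data.iloc[pick].reset_index(drop=True),
                     list(events.markers))
    coords = embed_2d(sub, markers, seed=seed)
    graph = cluster_nodes(coords, sub, k=min(k, len(pick)), seed=seed)
    x_sub = sub.data[markers].to_numpy(float)
    centroids = np.vstack([x_sub[graph.members[i]].mean(axis=0)
                           for i in sorted(graph.members)])
    x_all = events.data[markers].to_numpy(float)
    # nearest centroid in marker space, chunked to bound memory
    labels = np.empty(n, dtype=int)
    for s in range(0, n, 65536):
        chunk = x_all[s:s + 65536]
        d2 = ((chunk[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        labels[s:s + 65536] = d2.argmin(axis=1)
    allx = events.intensities
    medians = pd.DataFrame(
        [np.median(allx[labels == i], axis=0) if (labels == i).any()
         else np.full(allx.shape[1], np.nan)
         for i in range(centroids.shape[0])],
        columns=events.markers)
    return labels, medians


def classify_pixels(events: EventTable, seed: int = 0,
                    rules: list[SubsetRule] | None = None,
                    stage1_k: int = 30, stage2_k: int = 60,
                    subsample: int = 3000,
                    b_thresholds: dict[str, float] | None = None) -> pd.Series:
    """Two-stage pixel classification into B-cell subset labels.

    Stage 1 clusters all pixels on every channel and keeps nodes whose CD19
    and CD20 medians clear their thresholds; stage 2 re-clusters the kept
    pixels on the nine B-cell markers and assigns nodes to subsets by rule.
    Pixels outside B-cell nodes, and nodes no rule claims, are labelled
    "other".
    """
    rules = rules if rules is not None else imc_subset_rules()
    b_thresholds = b_thresholds or {"CD19": THRESH["pos"],
                                    "CD20": THRESH["pos"]}
    for ch in (*b_thresholds, "CD19", "CD20"):
        if ch not in events.markers:
            raise KeyError(f"missing channel {ch!r}")
    labels1, med1 = _stage_cluster(events, list(events.markers), seed,
                                   stage1_k, subsample)
    b_nodes = med1.index[(med1["CD19"] > b_thresholds["CD19"])
                         & (med1["CD20"] > b_thresholds["CD20"])]
    is_b = np.isin(labels1, b_nodes)
    if not is_b.any():
        raise ValueError("no CD19+CD20+ pixels found")
    out = pd.Series("other", index=events.data.index, dtype=object)
    b_events = EventTable(events.data.loc[is_b].reset_index(drop=True),
                          list(events.markers))
    markers2 = [m for m in IMC_B_MARKERS if m in events.markers]
    labels2, med2 = _stage_cluster(b_events, markers2, seed + 1, stage2_k,
                                   subsample)
    node_label = {}
    for nid in med2.index:
        med = med2.loc[nid].to_dict()
        lab = "other"
        for rule in rules:
            if rule.matches(med):
                lab = rule.name
                break
        node_label[nid] = lab
    out.loc[is_b] = [node_label[l] for l in labels2]
    return out


def masks_from_labels(labels: pd.Series, xs: np.ndarray, ys: np.ndarray,
                      shape: tuple[int, int],
                      vocabulary: list[str] | None = None
                      ) -> dict[str, np.ndarray]:
    """One binary H x W mask per subset label; "other" pixels appear in no
    mask.  Masks are pairwise disjoint by construction."""
    names = sorted(set(labels) - {"other"})
    if vocabulary is not None:
        bad = set(names) - set(vocabulary)
        if bad:
            raise ValueError(f"labels outside subset vocabulary: {bad}")
    masks = {}
    for nm in names:
        m = np.zeros(shape, dtype=bool)
        sel = (labels == nm).to_numpy()
        m[ys[sel], xs[sel]] = True
        masks[nm] = m
    return masks


def composite_image(masks: dict[str, np.ndarray],
                    shape: tuple[int, int]) -> np.ndarray:
    """Pseudocolour composite: one colour per subset, one subset per pixel."""
    import matplotlib.pyplot as plt
    cmap = plt.get_cmap("tab10")
    rgb = np.zeros((*shape, 3))
    for i, nm in enumerate(sorted(masks)):
        rgb[masks[nm]] = cmap(i % 10)[:3]
    return rgb


def validate_against_suspension(pixel_profiles: pd.DataFrame,
                                suspension_profiles: pd.DataFrame,
                                markers: tuple[str, ...] = ("CD45RB", "CD24")
                                ) -> pd.DataFrame:
    """Concordance of held-out-marker subset profiles between arms.

    For each held-out marker, Spearman rank correlation of subset medians
    between the pixel and suspension arms over shared subsets; the
    concordance flag records whether the subset rank order agrees exactly.
    """
    from scipy.stats import spearmanr
    shared = sorted(set(pixel_profiles.index) & set(suspension_profiles.index))
    if not shared:
        raise ValueError("no shared subsets between arms")
    rows = []
    for m in markers:
        a = pixel_profiles.loc[shared, m].to_numpy(float)
        b = suspension_profiles.loc[shared, m].to_numpy(float)
        rho = float(spearmanr(a, b).statistic) if len(shared) > 1 else np.nan
        rows.append({"marker": m, "n_subsets": len(shared), "spearman": rho,
                     "concordant": bool(np.array_equal(np.argsort(a),
                                                       np.argsort(b)))})
    return pd.DataFrame(rows)


def spatial_summary(masks: dict[str, np.ndarray],
                    reference_masks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Distance statistics of subset pixels to reference-mask boundaries.

    Distances are Euclidean, measured from the boundary of each reference
    mask (zero inside the reference), via the exact distance transform.
    """
    rows = []
    for ref_name, ref in reference_masks.items():
        if not ref.any():
            raise ValueError(f"empty reference mask {ref_name!r}")
        dist = distance_transform_edt(~ref)
        for nm, mask in masks.items():
            if mask.shape != ref.shape:
                raise ValueError("mask and reference shapes differ")
            vals = dist[mask]
            if len(vals) == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"subset": nm, "reference": ref_name,
                         "n_pixels": int(mask.sum()),
                         "mean": float(vals.mean()), "median": float(med),
                         "q1": float(q1), "q3": float(q3)})
    return pd.DataFrame(rows)
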