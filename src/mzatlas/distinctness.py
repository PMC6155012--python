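"""Bootstrap z-score test for subpopulation distinctness.

Question: does a focal subpopulation (e.g. CD45RB+ cells sitting inside the
naive bubble) have a marker profile that could plausibly arise by drawing
the same number of cells at random from its parent population?

Procedure: resample ``n_focal`` cells with replacement from the parent B
times (default 10,000); record the per-marker median of each resample to
form the null distribution of the median; compare the observed focal median
to the null via z = (observed - null mean) / null SD.  An empirical p-value
(rank with +1 smoothing) accompanies the z-score because resample medians
can be distinctly non-normal when n_focal is small.

The null SD uses denominator B (the null vector is the full Monte-Carlo
distribution, not a sample whose variance needs an unbiased estimate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cytometry import EventTable

# Chunk resampling to bound memory at ~tens of MB for large n_focal * B.
_CHUNK_CELLS = 20_000_000


@dataclass
class BootstrapNull:
    markers: list[str]
    resample_medians: np.ndarray  # B x markers
    null_mean: np.ndarray
    null_sd: np.ndarray
    n_focal: int
    B: int
    seed: int


@dataclass
class ZScoreResult:
    table: pd.DataFrame  # marker, focal_median, null_mean, null_sd, z, p_emp,
    #                      direction, flag
    n_markers: int
    threshold: float | None = None


def bootstrap_null(parent: EventTable, n_focal: int, B: int = 10_000,
                   seed: int = 0) -> BootstrapNull:
    """Null distribution of per-marker medians of size-``n_focal`` resamples
    drawn with replacement from ``parent``."""
    if n_focal < 1:
        raise ValueError("n_focal must be >= 1")
    if B < 1:
        raise ValueError("B must be >= 1")
    if parent.n_events < 1:
        raise ValueError("parent is empty")
    rng = np.random.default_rng(seed)
    x = parent.intensities
    n = len(x)
    meds = np.empty((B, x.shape[1]))
    step = max(1, _CHUNK_CELLS // max(1, n_focal))
    for start in range(0, B, step):
        stop = min(B, start + step)
        idx = rng.integers(0, n, size=(stop - start, n_focal))
        meds[start:stop] = np.median(x[idx], axis=1)
    return BootstrapNull(list(parent.markers), meds, meds.mean(axis=0),
                         meds.std(axis=0, ddof=0), n_focal, B, seed)


def zscore_markers(focal: EventTable, null: BootstrapNull) -> ZScoreResult:
    """z-scores of observed focal medians against the bootstrap null.

    Degenerate nulls (SD == 0): z is 0 when the observed median equals the
    null mean, and signed infinity otherwise.
    """
    if focal.n_events < 1:
        raise ValueError("focal is empty")
    if list(focal.markers) != list(null.markers):
        raise ValueError("marker sets of focal and null do not match")
    obs = np.median(focal.intensities, axis=0)
    diff = obs - null.null_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null.null_sd > 0, diff / np.where(null.null_sd > 0,
                                                       null.null_sd, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    # empirical two-sided p: rank of observed among null medians, +1 smoothed
    b = null.B
    ge = (null.resample_medians >= obs).sum(axis=0)
    le = (null.resample_medians <= obs).sum(axis=0)
    p_emp = np.minimum(1.0, 2.0 * (np.minimum(ge, le) + 1) / (b + 1))
    tab = pd.DataFrame({
        "marker": null.markers,
        "focal_median": obs,
        "null_mean": null.null_mean,
        "null_sd": null.null_sd,
        "z": z,
        "p_emp": p_emp,
        "direction": np.where(z > 0, "over", np.where(z < 0, "under", "none")),
    })
    return ZScoreResult(tab, n_markers=len(null.markers))


def significance_call(result: ZScoreResult, threshold: float = 2.0) -> ZScoreResult:
    """Flag markers with |z| >= threshold (boundary inclusive, two-sided)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    tab = result.table.copy()
    tab["flag"] = np.abs(tab["z"].to_numpy()) >= threshold
    return ZScoreResult(tab, result.n_markers, threshold)
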