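"""Thresholded-map overlap, shuffle nulls, threshold sweeps, patch counting.

Two interdigitated column systems should overlap *less* than chance: the
aligned overlap of their thresholded maps falls below a null distribution
built by spatially shuffling one map relative to the other. The same
machinery, applied to the same contrast mapped in two sessions, quantifies
session consistency (aligned overlap *above* the null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .glm import ContrastMap

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(1.3, 10.01, 0.5), 2))


@dataclass
class BinaryMask:
    """Thresholded selectivity mask within a reference ROI."""

    mask: np.ndarray  # bool (ny, nx)
    roi: np.ndarray  # bool (ny, nx)
    threshold: float = np.nan

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        self.roi = np.asarray(self.roi, bool)
        if self.mask.shape != self.roi.shape:
            raise ValueError("mask and roi must share a shape")
        if np.any(self.mask & ~self.roi):
            raise ValueError("mask must be contained in the ROI")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def threshold_map(
    cmap: ContrastMap,
    threshold: float,
    roi: np.ndarray | None = None,
    pole: str = "positive",
) -> BinaryMask:
    """Binarize a signed -log10(p) map at a threshold, one pole at a time."""
    signed = cmap.signed_logp
    if roi is None:
        roi = np.ones(signed.shape, bool)
    if pole == "positive":
        mask = signed >= threshold
    elif pole == "negative":
        mask = signed <= -threshold
    else:
        raise ValueError("pole must be 'positive' or 'negative'")
    return BinaryMask(mask=mask & roi, roi=roi, threshold=threshold)


def overlap_fraction(m1: BinaryMask, m2: BinaryMask) -> float:
    """Overlap of two masks as a percentage of the shared ROI."""
    if not np.array_equal(m1.roi, m2.roi):
        raise ValueError("masks must share the same ROI")
    n_roi = int(m1.roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    return 100.0 * float((m1.mask & m2.mask).sum()) / n_roi


@dataclass
class OverlapResult:
    """Aligned overlap versus a spatial-shuffle null distribution."""

    aligned_overlap: float  # % of ROI
    null: np.ndarray  # (n_shuffles,) overlaps
    n_shuffles: int
    p_upper: float  # fraction of shuffles with overlap >= aligned
    p_lower: float  # fraction of shuffles with overlap <= aligned
    seed: int | None = None

    @property
    def null_mean(self) -> float:
        return float(self.null.mean())

    def null_percentile(self, q: float) -> float:
        return float(np.percentile(self.null, q))


def _roll_within_roi(mask: np.ndarray, roi: np.ndarray,
                     dy: int, dx: int) -> np.ndarray:
    """Circular shift of the mask within the ROI bounding frame."""
    ys, xs = np.nonzero(roi)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    out = np.zeros_like(mask)
    out[y0:y1, x0:x1] = np.roll(mask[y0:y1, x0:x1], (dy, dx), axis=(0, 1))
    return out


def shuffled_null(
    m1: BinaryMask,
    m2: BinaryMask,
    n_shuffles: int = 1000,
    seed: int | None = None,
    mode: str = "shift",
) -> OverlapResult:
    """Overlap of m1 with randomly misaligned copies of m2.

    ``mode='shift'`` (default) applies an independent random 2-D circular
    shift within the ROI bounding frame, preserving mask area and spatial
    autocorrelation; ``mode='permute'`` permutes m2's vertices within the ROI
    instead (sensitivity analysis). Both tail p values are reported as the
    fraction of shuffles at or beyond the aligned overlap.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    if mode not in ("shift", "permute"):
        raise ValueError("mode must be 'shift' or 'permute'")
    rng = np.random.default_rng(seed)
    aligned = overlap_fraction(m1, m2)
    roi = m1.roi
    n_roi = int(roi.sum())
    null = np.empty(n_shuffles)
    if mode == "shift":
        ys, xs = np.nonzero(roi)
        h = ys.max() - ys.min() + 1
        w = xs.max() - xs.min() + 1
        if roi.sum() != h * w:
            logger.warning(
                "ROI is not rectangular; circular shifts may clip the mask "
                "at the ROI boundary")
        for i in range(n_shuffles):
            shifted = _roll_within_roi(m2.mask, roi, int(rng.integers(h)),
                                       int(rng.integers(w)))
            null[i] = 100.0 * float((m1.mask & shifted & roi).sum()) / n_roi
    else:
        flat2 = m2.mask[roi]
        flat1 = m1.mask[roi]
        for i in range(n_shuffles):
            null[i] = 100.0 * float(
                (flat1 & rng.permutation(flat2)).sum()) / n_roi
    p_upper = float(np.mean(null >= aligned))
    p_lower = float(np.mean(null <= aligned))
    return OverlapResult(aligned_overlap=aligned, null=null,
                         n_shuffles=n_shuffles, p_upper=p_upper,
                         p_lower=p_lower, seed=seed)


def overlap_curve(
    map1: ContrastMap,
    map2: ContrastMap,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    roi: np.ndarray | None = None,
    poles: tuple[str, str] = ("positive", "positive"),
    n_shuffles: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Aligned and null overlap across a sweep of -log10(p) thresholds.

    Returns one row per threshold with the aligned overlap, the null mean and
    2.5/97.5 percentiles, both tail p values, and mask areas. When either
    mask is empty at a threshold the overlap is 0 and the row is flagged.
    """
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for thr in thresholds:
        m1 = threshold_map(map1, thr, roi, poles[0])
        m2 = threshold_map(map2, thr, roi, poles[1])
        if m1.area == 0 or m2.area == 0:
            rows.append({
                "threshold": thr, "aligned": 0.0, "null_mean": 0.0,
                "null_q025": 0.0, "null_q975": 0.0, "p_upper": 1.0,
                "p_lower": 1.0, "area1": m1.area, "area2": m2.area,
                "empty": True})
            continue
        res = shuffled_null(m1, m2, n_shuffles,
                            seed=int(rng.integers(2**31)))
        rows.append({
            "threshold": thr, "aligned": res.aligned_overlap,
            "null_mean": res.null_mean,
            "null_q025": res.null_percentile(2.5),
            "null_q975": res.null_percentile(97.5),
            "p_upper": res.p_upper, "p_lower": res.p_lower,
            "area1": m1.area, "area2": m2.area, "empty": False})
    return pd.DataFrame(rows)


def conjunction_map(
    maps: dict[str, ContrastMap],
    threshold: float,
    roi: np.ndarray | None = None,
    pole: str = "positive",
) -> tuple[np.ndarray, dict[int, str]]:
    """Categorical map: which single contrast (if any) each vertex prefers.

    Vertices selective for exactly one contrast get that contrast's code;
    vertices selective for two or more get the code -1 ("overlap"); others 0.
    """
    names = list(maps)
    shape = next(iter(maps.values())).signed_logp.shape
    if roi is None:
        roi = np.ones(shape, bool)
    stack = np.stack([
        threshold_map(maps[n], threshold, roi, pole).mask for n in names])
    counts = stack.sum(axis=0)
    out = np.zeros(shape, dtype=np.int16)
    for i, n in enumerate(names):
        out[(counts == 1) & stack[i]] = i + 1
    out[counts >= 2] = -1
    legend = {0: "none", -1: "overlap"}
    legend.update({i + 1: n for i, n in enumerate(names)})
    return out, legend


def count_patches(
    mask: BinaryMask | np.ndarray,
    connectivity: int = 2,
    min_size: int = 5,
) -> int:
    """Connected-component count after discarding components below min_size.

    ``connectivity=2`` is 8-neighbor adjacency on the grid; ``connectivity=1``
    is 4-neighbor.
    """
    arr = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    labeled = measure.label(arr, connectivity=connectivity)
    if labeled.max() == 0:
        return 0
    sizes = np.bincount(labeled.ravel())[1:]
    return int(np.sum(sizes >= min_size))
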