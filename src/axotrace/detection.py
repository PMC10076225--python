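"""Per-frame axon segmentation and the operations built on it.

The classical segmentation pipeline, per frame and in order: non-local-means
denoising of each channel over a 5-frame temporal window, grayscale as the
per-pixel maximum over the two channels, Gaussian smoothing (sigma = 2 px),
Otsu thresholding, one binary erosion, and removal of connected components
below 11 pixels.  An ROI (putative axon) is a connected set of foreground
pixels (8-connectivity).

Also here: the cross-entropy weight-map used when training a segmentation
network (background weighted towards ROI borders and axon-axon boundaries),
the Sorensen-Dice overlap, density-based clustering of self-similar frames
(OPTICS on negative cross-correlation of normalized red frames), and the
cluster-average target mask that seeds both tracker initialization and ROI
separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, restoration
from skimage.measure import label, regionprops
from sklearn.cluster import OPTICS

from .core import RecordingStack

__all__ = [
    "ROI",
    "SegmentationResult",
    "WeightConfig",
    "FrameCluster",
    "FinetuneResult",
    "NoClusterError",
    "denoise_stack",
    "segment_stack_cv",
    "segment_frame_cv",
    "min_size_filter",
    "loss_weight_map",
    "dice",
    "cluster_similar_frames",
    "finetune_target",
]

MIN_ROI_SIZE = 11  # pixels; empirical floor below which regions are spurious


@dataclass
class ROI:
    """One connected foreground component: pixel set, area and centroid."""

    pixels: np.ndarray  # (N, 2) array of (row, col) indices
    area: int
    centroid: np.ndarray  # (row, col)

    @classmethod
    def from_coords(cls, coords: np.ndarray) -> "ROI":
        coords = np.asarray(coords, dtype=int)
        if coords.size == 0:
            raise ValueError("ROI must have at least one pixel")
        return cls(
            pixels=coords,
            area=len(coords),
            centroid=coords.mean(axis=0),
        )

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class SegmentationResult:
    """Binary foreground mask of one frame plus its connected components."""

    mask: np.ndarray
    rois: list[ROI] = field(default_factory=list)

    @classmethod
    def from_mask(cls, mask: np.ndarray, connectivity: int = 2) -> "SegmentationResult":
        labels = label(mask, connectivity=connectivity)
        rois = [
            ROI.from_coords(p.coords)
            for p in regionprops(labels)
        ]
        return cls(mask=mask.astype(bool), rois=rois)

    @property
    def n_rois(self) -> int:
        return len(self.rois)


@dataclass
class WeightConfig:
    """Foreground/background pixel counts over a training set, used to scale
    the cross-entropy weight map for class imbalance."""

    b: int
    f: int

    def __post_init__(self) -> None:
        if self.b <= 0 or self.f <= 0:
            raise ValueError("b and f must be positive")


@dataclass
class FrameCluster:
    """A self-similar subset of frames found by OPTICS."""

    indices: np.ndarray
    mean_cross_correlation: float

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class FinetuneResult:
    """Temporal average of a self-similar frame cluster and its target mask."""

    average_green: np.ndarray
    average_red: np.ndarray
    grayscale: np.ndarray  # min-max normalized to [0, 1]
    mask: np.ndarray
    segmentation: SegmentationResult
    smoothed: bool


class NoClusterError(RuntimeError):
    """OPTICS found no cluster of self-similar frames; fine-tune-dependent
    steps (and hence automatic ROI separation) must be skipped."""


def denoise_stack(
    stack: RecordingStack,
    h: float = 11.0,
    temporal_window: int = 5,
    patch_size: int = 3,
) -> RecordingStack:
    """Non-local-means denoising of both channels.

    Each channel is treated as a (T, H, W) spatiotemporal volume and denoised
    with 3-D non-local means whose search radius along time is
    ``(temporal_window - 1) // 2`` frames.  ``h`` is the filter strength on a
    0-255 intensity scale (it is rescaled to each channel's actual range).
    """
    radius = (temporal_window - 1) // 2
    out = []
    for chan in (stack.green, stack.red):
        rng_max = chan.max()
        if rng_max <= 0:
            out.append(chan.copy())
            continue
        scaled = chan / rng_max
        den = restoration.denoise_nl_means(
            scaled,
            h=(h / 255.0),
            sigma=0.0,
            patch_size=patch_size,
            patch_distance=radius,
            fast_mode=True,
        )
        out.append(np.clip(den, 0.0, None) * rng_max)
    return RecordingStack(green=out[0], red=out[1], fps=stack.fps)


def min_size_filter(mask: np.ndarray, min_size: int = MIN_ROI_SIZE,
                    connectivity: int = 2) -> np.ndarray:
    """Drop connected components smaller than ``min_size`` pixels.

    Components of exactly ``min_size`` pixels survive; no pixel is ever
    added.  Idempotent and monotone in ``min_size``.
    """
    mask = np.asarray(mask, dtype=bool)
    if min_size <= 1:
        return mask.copy()
    # remove_small_objects(max_size=s) drops components of area <= s, so
    # components of exactly min_size pixels survive
    return morphology.remove_small_objects(
        mask, max_size=min_size - 1, connectivity=connectivity
    )


def _segment_gray(gray: np.ndarray, sigma: float, min_size: int,
                  connectivity: int) -> SegmentationResult:
    lo, hi = gray.min(), gray.max()
    if hi <= lo:
        warnings.warn("constant frame: Otsu threshold undefined, empty mask",
                      stacklevel=3)
        return SegmentationResult.from_mask(np.zeros_like(gray, dtype=bool))
    norm = (gray - lo) / (hi - lo)
    smooth = ndimage.gaussian_filter(norm, sigma=sigma)
    try:
        thr = filters.threshold_otsu(smooth)
    except ValueError:
        warnings.warn("constant frame after smoothing: empty mask", stacklevel=3)
        return SegmentationResult.from_mask(np.zeros_like(gray, dtype=bool))
    mask = smooth > thr
    mask = ndimage.binary_erosion(mask)  # 3x3 cross, 1 iteration
    mask = min_size_filter(mask, min_size, connectivity)
    return SegmentationResult.from_mask(mask, connectivity)


def segment_stack_cv(
    stack: RecordingStack,
    sigma: float = 2.0,
    min_size: int = MIN_ROI_SIZE,
    connectivity: int = 2,
    denoise: bool = True,
    nlm_h: float = 11.0,
) -> list[SegmentationResult]:
    """Classical segmentation of every frame (denoising once for the stack)."""
    dn = denoise_stack(stack, h=nlm_h) if denoise else stack
    # channels are assumed acquired on a common intensity scale (as for
    # gain-balanced PMT channels); the grayscale is their per-pixel maximum
    gray = np.maximum(dn.green, dn.red)
    return [
        _segment_gray(gray[t], sigma, min_size, connectivity)
        for t in range(stack.n_frames)
    ]


def segment_frame_cv(
    stack: RecordingStack,
    frame_index: int,
    **kwargs,
) -> SegmentationResult:
    """Segment a single frame of the stack (convenience over
    :func:`segment_stack_cv`; denoising still uses the temporal context)."""
    if not 0 <= frame_index < stack.n_frames:
        raise IndexError("frame_index out of range")
    return segment_stack_cv(stack, **kwargs)[frame_index]


def loss_weight_map(mask: np.ndarray, config: WeightConfig) -> np.ndarray:
    """Cross-entropy weight map for a target segmentation.

    Background pixels are weighted ``1 + exp(-(d/3)^2) +
    exp(-((d1+d2)/6)^2)`` where ``d`` is the Euclidean distance to the
    nearest ROI and ``d1, d2`` are the distances to the two nearest ROIs (the
    border term is 0 with fewer than two ROIs), then scaled by
    ``(b+f)/(2b)``.  Foreground pixels get the constant ``(b+f)/(2f)``.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = label(mask, connectivity=2)
    n_rois = labels.max()
    bg_scale = (config.b + config.f) / (2.0 * config.b)
    fg_scale = (config.b + config.f) / (2.0 * config.f)
    weights = np.full(mask.shape, bg_scale, dtype=float)
    if n_rois >= 1:
        dists = np.stack([
            ndimage.distance_transform_edt(labels != k)
            for k in range(1, n_rois + 1)
        ])
        dists.sort(axis=0)
        d = dists[0]
        unscaled = 1.0 + np.exp(-((d / 3.0) ** 2))
        if n_rois >= 2:
            unscaled = unscaled + np.exp(-(((dists[0] + dists[1]) / 6.0) ** 2))
        weights = unscaled * bg_scale
    weights[mask] = fg_scale
    return weights


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Sorensen-Dice coefficient ``2|A & B| / (|A| + |B|)``; 1.0 when both
    masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / total


def _normalized_frames(red: np.ndarray) -> np.ndarray:
    """Per-frame mean/sd normalization, flattened to rows."""
    flat = red.reshape(red.shape[0], -1).astype(float)
    mu = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (flat - mu) / sd


def cross_correlation_matrix(red: np.ndarray) -> np.ndarray:
    """Pairwise cross-correlation sum(p_m * p_n) of normalized red frames."""
    x = _normalized_frames(red)
    return x @ x.T


def cluster_similar_frames(
    stack: RecordingStack,
    min_samples: int = 20,
) -> FrameCluster:
    """Find the most self-similar cluster of frames on the red channel.

    Distance between two frames is the negative cross-correlation of their
    mean/sd-normalized red channels.  Because OPTICS expects non-negative
    distances, the matrix is shifted by its minimum (rank order, and hence
    the clustering, is unchanged); the maximum neighborhood distance is half
    the largest (shifted) pairwise distance.  The cluster with the highest
    mean pairwise cross-correlation is returned.
    """
    n = stack.n_frames
    if n < min_samples:
        raise ValueError(
            f"need at least {min_samples} frames to cluster, got {n}"
        )
    cc = cross_correlation_matrix(stack.red)
    dist = -cc
    # shift so the closest pair of distinct frames is at distance 0 (OPTICS
    # needs non-negative distances; the shift preserves rank order)
    offdiag = ~np.eye(n, dtype=bool)
    dist = dist - dist[offdiag].min()
    np.fill_diagonal(dist, 0.0)
    max_eps = 0.5 * dist[offdiag].max()
    if max_eps <= 0:
        # all frames identical: a single cluster of everything
        idx = np.arange(n)
        return FrameCluster(idx, _mean_offdiag(cc, idx))
    clustering = OPTICS(
        min_samples=min_samples, max_eps=max_eps, metric="precomputed"
    ).fit(dist)
    labels = clustering.labels_
    best: FrameCluster | None = None
    for lab in np.unique(labels):
        if lab < 0:
            continue
        idx = np.flatnonzero(labels == lab)
        mean_cc = _mean_offdiag(cc, idx)
        if best is None or mean_cc > best.mean_cross_correlation:
            best = FrameCluster(idx, mean_cc)
    if best is None:
        raise NoClusterError("OPTICS found no cluster of similar frames")
    return best


def _mean_offdiag(cc: np.ndarray, idx: np.ndarray) -> float:
    sub = cc[np.ix_(idx, idx)]
    m = len(idx)
    if m < 2:
        return float(sub.mean())
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def smooth_average(avg: np.ndarray) -> np.ndarray:
    """Gaussian (sigma = 1 px) then 3x3 median filtering, per channel."""
    sm = ndimage.gaussian_filter(avg, sigma=1.0)
    return ndimage.median_filter(sm, size=3)


def finetune_target(
    stack: RecordingStack,
    cluster: FrameCluster,
    smooth_below: int = 50,
    block_size: int = 25,
    offset: float = 0.05,
    min_size: int = MIN_ROI_SIZE,
) -> FinetuneResult:
    """Temporal average of the cluster frames and its target mask.

    The average is smoothed (Gaussian sigma = 1 px then median, per channel)
    only when the cluster holds fewer than ``smooth_below`` frames.  The
    grayscale (per-pixel channel maximum, min-max normalized to [0, 1]) is
    thresholded locally: a pixel is foreground when it exceeds the
    Gaussian-weighted mean of its ``block_size`` x ``block_size``
    neighborhood by ``offset``.  Components below ``min_size`` pixels are
    removed.
    """
    if len(cluster) == 0:
        raise ValueError("empty frame cluster")
    idx = np.asarray(cluster.indices)
    avg_g = stack.green[idx].mean(axis=0)
    avg_r = stack.red[idx].mean(axis=0)
    smoothed = len(cluster) < smooth_below
    if smoothed:
        avg_g = smooth_average(avg_g)
        avg_r = smooth_average(avg_r)
    gray = np.maximum(avg_g, avg_r)
    lo, hi = gray.min(), gray.max()
    gray = (gray - lo) / (hi - lo) if hi > lo else np.zeros_like(gray)
    local = filters.threshold_local(
        gray, block_size=block_size, method="gaussian", offset=-offset
    )
    mask = gray > local
    mask = min_size_filter(mask, min_size)
    seg = SegmentationResult.from_mask(mask)
    return FinetuneResult(
        average_green=avg_g,
        average_red=avg_r,
        grayscale=gray,
        mask=mask,
        segmentation=seg,
        smoothed=smoothed,
    )
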