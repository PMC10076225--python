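"""Splitting ROIs that contain several axons.

On the cluster-average image, local intensity maxima (>= 0.05 on a [0, 1]
grayscale) seed a watershed inside each parent ROI; sub-regions below 11
pixels are fused into an adjacent sub-region; a 1-pixel border is inserted
between the final sub-regions.  Each border is fitted as a straight "cut
line" (normal n, signed distance d to the image origin, top-left) and stored
*normalized* to the parent ROI's least-squares ellipse — the transform that
maps the ellipse to a centered, axis-aligned unit circle is applied to the
line.  On every other frame the cut is mapped back through that frame's own
ROI ellipse, so the same anatomical division follows the ROI as it moves and
deforms.  The pixels on the far side of the cut (relative to the ellipse
center) become the new axon's ROI.

Geometry in this module uses (x, y) = (col, row) vectors; the conversion
from array indexing happens at the module boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import EllipseModel, label, regionprops
from skimage.segmentation import watershed

from .detection import MIN_ROI_SIZE, ROI, FinetuneResult, SegmentationResult
from .tracking import FrameAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "EllipseFit",
    "CutLine",
    "Cut",
    "EllipseFitError",
    "fit_ellipse",
    "fit_line_tls",
    "normalize_line",
    "fit_line",
    "find_cuts",
    "apply_cuts",
]


class EllipseFitError(ValueError):
    """Raised when a least-squares ellipse cannot be fitted to a contour."""


@dataclass
class EllipseFit:
    """Least-squares ellipse: center (x, y), half-axes w >= h > 0, rotation
    theta in (-pi/2, pi/2] of the w-axis from the x-axis."""

    center: np.ndarray
    w: float
    h: float
    theta: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.w <= 0 or self.h <= 0:
            raise ValueError("half-axes must be positive")
        if not (-np.pi / 2 < self.theta <= np.pi / 2):
            raise ValueError("theta must lie in (-pi/2, pi/2]")


@dataclass
class CutLine:
    """Line {p : n . p = d} with unit normal n = (n_x, n_y)."""

    n: np.ndarray
    d: float

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        norm = np.linalg.norm(self.n)
        if norm == 0:
            raise ValueError("line normal must be non-zero")
        self.n = self.n / norm
        self.d = float(self.d) / norm


@dataclass
class Cut:
    """One ROI division: the parent axon it splits, the cut line normalized
    to the parent's average-image ellipse, and the new child identity."""

    parent_axon: int
    line: CutLine  # normalized (unit-circle) coordinates
    child_axon: int
    parent_ellipse: EllipseFit = field(repr=False)


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _canonical_ellipse(xc, yc, a, b, theta) -> EllipseFit:
    """Canonicalize so the major half-axis is w and theta in (-pi/2, pi/2]."""
    if b > a:
        a, b = b, a
        theta = theta + np.pi / 2
    theta = np.mod(theta, np.pi)
    if theta > np.pi / 2:
        theta -= np.pi
    return EllipseFit(center=np.array([xc, yc]), w=a, h=b, theta=theta)


def fit_ellipse(roi_mask: np.ndarray) -> EllipseFit:
    """Least-squares ellipse through an ROI's outer contour pixels.

    The contour is the set of mask pixels removed by one binary erosion.
    Raises :class:`EllipseFitError` on degenerate (e.g. collinear) contours.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    contour = mask & ~ndimage.binary_erosion(mask)
    rows, cols = np.nonzero(contour)
    if len(rows) < 5:
        raise EllipseFitError("need >= 5 contour pixels to fit a conic")
    pts = np.column_stack([cols, rows]).astype(float)  # (x, y)
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise EllipseFitError("ellipse fit failed (degenerate contour)")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])) or a <= 0 or b <= 0:
        raise EllipseFitError("ellipse fit produced a degenerate conic")
    return _canonical_ellipse(xc, yc, a, b, theta)


def fit_line_tls(points_xy: np.ndarray) -> CutLine:
    """Total-least-squares line through points: the normal is the direction
    of least variance (second principal component), d = n . centroid."""
    pts = np.asarray(points_xy, dtype=float)
    if len(pts) < 2:
        raise ValueError("need >= 2 points to fit a line")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    return CutLine(n=normal, d=float(normal @ centroid))


def normalize_line(line: CutLine, ellipse: EllipseFit,
                   variant: str = "hw") -> CutLine:
    """Transform a cut line into the ellipse's unit-circle coordinates.

    Steps: subtract the center projection, rotate the normal by -theta,
    divide its x component by h and its y component by w, divide the
    distance by w*h, then renormalize to a unit normal.  This is the exact
    line image under the affine map taking the ellipse to a centered
    axis-aligned unit circle (up to overall scale), and is inverted exactly
    by :func:`fit_line`.

    ``variant="printed"`` instead divides the normal components by the
    ellipse *center* coordinates (c.y, c.x); it is ill-defined for centered
    ellipses and kept only for comparison.
    """
    n = line.n.copy()
    d = line.d
    c, w, h, theta = ellipse.center, ellipse.w, ellipse.h, ellipse.theta
    d1 = d - float(c @ n)
    m = _rot(-theta) @ n
    if variant == "hw":
        m = np.array([m[0] / h, m[1] / w])
    elif variant == "printed":
        if c[1] == 0 or c[0] == 0:
            raise ZeroDivisionError(
                "printed variant divides by the ellipse center coordinates"
            )
        m = np.array([m[0] / c[1], m[1] / c[0]])
    else:
        raise ValueError("variant must be 'hw' or 'printed'")
    d1 = d1 / (w * h)
    norm = np.linalg.norm(m)
    return CutLine(n=m / norm, d=d1 / norm)


def fit_line(line: CutLine, ellipse: EllipseFit, variant: str = "hw") -> CutLine:
    """Map a normalized cut line back into image space through an ellipse.

    Exact inverse of :func:`normalize_line` (the final center offset uses
    the rotated normal, which is what makes the round trip exact).
    """
    n = line.n.copy()
    d = line.d
    c, w, h, theta = ellipse.center, ellipse.w, ellipse.h, ellipse.theta
    if variant == "hw":
        m = np.array([n[0] * h, n[1] * w])
    elif variant == "printed":
        m = np.array([n[0] * c[1], n[1] * c[0]])
    else:
        raise ValueError("variant must be 'hw' or 'printed'")
    d1 = d * (w * h)
    norm = np.linalg.norm(m)
    d1 = d1 / norm
    m = m / norm
    n_img = _rot(theta) @ m
    return CutLine(n=n_img, d=d1 + float(c @ n_img))


def _fuse_small_regions(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Merge watershed sub-regions below ``min_size`` into the adjacent
    sub-region sharing the longest boundary."""
    labels = labels.copy()
    struct = np.ones((3, 3), dtype=bool)
    while True:
        ids, sizes = np.unique(labels[labels > 0], return_counts=True)
        if len(ids) <= 1:
            break
        order = np.argsort(sizes)
        smallest, size = ids[order[0]], sizes[order[0]]
        if size >= min_size:
            break
        region = labels == smallest
        ring = ndimage.binary_dilation(region, structure=struct) & ~region
        neighbors = labels[ring]
        neighbors = neighbors[neighbors > 0]
        if neighbors.size == 0:
            # isolated small region: drop it
            labels[region] = 0
            continue
        vals, counts = np.unique(neighbors, return_counts=True)
        labels[region] = vals[np.argmax(counts)]
    return labels


def _pair_borders(labels: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Pixels separating each pair of adjacent sub-regions.

    For labels la < lb, the border is the set of pixels of either region
    with an 8-neighbor in the other; returned as (N, 2) (row, col) arrays.
    """
    borders: dict[tuple[int, int], list] = {}
    h, w = labels.shape
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    rows, cols = np.nonzero(labels > 0)
    for r, c in zip(rows, cols):
        lab = labels[r, c]
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                other = labels[rr, cc]
                if other > 0 and other != lab:
                    key = (min(lab, other), max(lab, other))
                    borders.setdefault(key, []).append((r, c))
    return {
        k: np.unique(np.array(v), axis=0) for k, v in borders.items()
    }


def watershed_split(
    grayscale: np.ndarray,
    roi_mask: np.ndarray,
    maxima_threshold: float = 0.05,
    min_size: int = MIN_ROI_SIZE,
) -> np.ndarray | None:
    """Watershed partition of one ROI seeded at retained intensity maxima.

    Local maxima of the [0, 1] grayscale below ``maxima_threshold`` are
    discarded; with fewer than two retained seeds inside the ROI there is
    nothing to split and ``None`` is returned.  Sub-regions below
    ``min_size`` pixels are fused into an adjacent sub-region.
    """
    peaks = peak_local_max(
        grayscale, threshold_abs=maxima_threshold, exclude_border=False
    )
    if len(peaks) == 0:
        return None
    inside = roi_mask[peaks[:, 0], peaks[:, 1]]
    peaks = peaks[inside]
    if len(peaks) < 2:
        return None
    # adjacent seed pixels (intensity plateaus) count as one maximum
    seed_mask = np.zeros_like(roi_mask, dtype=bool)
    seed_mask[peaks[:, 0], peaks[:, 1]] = True
    markers = label(seed_mask, connectivity=2)
    if markers.max() < 2:
        return None
    labels = watershed(-grayscale, markers=markers, mask=roi_mask)
    labels = _fuse_small_regions(labels, min_size)
    if len(np.unique(labels[labels > 0])) < 2:
        return None
    return labels


def insert_border(labels: np.ndarray) -> np.ndarray:
    """Set to 0 a 1-pixel-wide border between distinct sub-regions (the
    inner boundary pixels of the higher-numbered label of each pair)."""
    out = labels.copy()
    for (la, lb), pix in _pair_borders(labels).items():
        keep = labels[pix[:, 0], pix[:, 1]] == lb
        out[pix[keep, 0], pix[keep, 1]] = 0
    return out


def find_cuts(
    finetune: FinetuneResult,
    roi_axon_ids: dict[int, int],
    maxima_threshold: float = 0.05,
    min_size: int = MIN_ROI_SIZE,
    next_identity: int | None = None,
    variant: str = "hw",
) -> tuple[list[Cut], np.ndarray]:
    """Detect cut lines on the cluster-average image.

    Parameters
    ----------
    finetune : FinetuneResult
        Average image (grayscale in [0, 1]) and its target mask.
    roi_axon_ids : dict
        Maps each parent ROI's index in ``finetune.segmentation.rois`` to the
        axon identity it tracks to.
    next_identity : int, optional
        First identity to assign to newly created axons (default: one past
        the largest parent identity).

    Returns
    -------
    (cuts, partition) : the detected cuts (one new axon per cut) and the
        full-frame partition labels (0 = background/border) for diagnostics.
    """
    gray = finetune.grayscale
    seg = finetune.segmentation
    if next_identity is None:
        next_identity = (max(roi_axon_ids.values()) + 1) if roi_axon_ids else 0
    cuts: list[Cut] = []
    partition = np.zeros(gray.shape, dtype=int)
    part_next = 1
    for roi_idx, roi in enumerate(seg.rois):
        roi_mask = roi.mask(gray.shape)
        labels = watershed_split(gray, roi_mask, maxima_threshold, min_size)
        if labels is None:
            partition[roi_mask] = part_next
            part_next += 1
            continue
        parent_axon = roi_axon_ids.get(roi_idx)
        if parent_axon is None:
            partition[roi_mask] = part_next
            part_next += 1
            continue
        try:
            ellipse = fit_ellipse(roi_mask)
        except EllipseFitError as exc:
            logger.warning("cut skipped for ROI %d: %s", roi_idx, exc)
            partition[roi_mask] = part_next
            part_next += 1
            continue
        bordered = insert_border(labels)
        for (la, lb), pix in _pair_borders(labels).items():
            pts_xy = np.column_stack([pix[:, 1], pix[:, 0]]).astype(float)
            try:
                line = fit_line_tls(pts_xy)
            except ValueError:
                continue
            cuts.append(
                Cut(
                    parent_axon=parent_axon,
                    line=normalize_line(line, ellipse, variant),
                    child_axon=next_identity,
                    parent_ellipse=ellipse,
                )
            )
            next_identity += 1
        # remap bordered labels into the global partition
        for lab in np.unique(bordered[bordered > 0]):
            partition[bordered == lab] = part_next
            part_next += 1
    return cuts, partition


def _signed_side(points_xy: np.ndarray, line: CutLine) -> np.ndarray:
    return points_xy @ line.n - line.d


def apply_cuts(
    cuts: list[Cut],
    assignments: list[FrameAssignment],
    segmentations: list[SegmentationResult],
    variant: str = "hw",
) -> list[dict[int, np.ndarray]]:
    """Split each frame's parent ROIs along the stored cuts.

    For every frame: locate the parent axon's ROI through the tracking
    assignment, fit an ellipse to it, map each normalized cut back through
    that ellipse, and give the pixels on the far side of the line (relative
    to the ellipse center) to the child axon.  Multiple cuts of one parent
    are applied in order of increasing distance from the ellipse center.
    Pixels on the near side (including the border convention) stay with the
    parent, so the children and the remaining parent always partition the
    original ROI.

    Returns per-frame dictionaries mapping axon identity to an (N, 2)
    (row, col) pixel array; axons missing in a frame are absent from its
    dictionary.
    """
    by_parent: dict[int, list[Cut]] = {}
    for cut in cuts:
        by_parent.setdefault(cut.parent_axon, []).append(cut)

    out: list[dict[int, np.ndarray]] = []
    for assignment, seg in zip(assignments, segmentations):
        frame_rois: dict[int, np.ndarray] = {}
        for roi_idx, axon_id in assignment.matched_pairs():
            frame_rois[axon_id] = seg.rois[roi_idx].pixels
        for parent, parent_cuts in by_parent.items():
            if parent not in frame_rois:
                continue
            pixels = frame_rois[parent]
            shape = seg.mask.shape
            parent_mask = np.zeros(shape, dtype=bool)
            parent_mask[pixels[:, 0], pixels[:, 1]] = True
            try:
                ellipse = fit_ellipse(parent_mask)
            except EllipseFitError as exc:
                logger.warning(
                    "cut skipped in a frame (parent axon %d): %s", parent, exc
                )
                continue
            image_lines = [
                (cut, fit_line(cut.line, ellipse, variant)) for cut in parent_cuts
            ]
            image_lines.sort(
                key=lambda cl: abs(float(ellipse.center @ cl[1].n) - cl[1].d)
            )
            remaining = pixels
            for cut, line in image_lines:
                pts_xy = np.column_stack(
                    [remaining[:, 1], remaining[:, 0]]
                ).astype(float)
                side = _signed_side(pts_xy, line)
                center_side = float(ellipse.center @ line.n) - line.d
                far = (side * np.sign(center_side)) < 0 if center_side != 0 else side > 0
                child_pixels = remaining[far]
                remaining = remaining[~far]
                if len(child_pixels) > 0:
                    frame_rois[cut.child_axon] = child_pixels
            frame_rois[parent] = remaining
            if len(remaining) == 0:
                del frame_rois[parent]
        out.append(frame_rois)
    return out
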