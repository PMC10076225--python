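"""Persistent axon identities via nested Hungarian matching.

A tracker template holds one model per axon (running-mean area and centroid,
update count).  Every frame's ROIs are matched against the template by
minimizing a matching cost:

* the *outer* cost of pairing ROI ``i`` with axon ``k`` is
  ``w_area * |area_i - area_k|`` plus the mean cost of an optimal *inner*
  assignment of the remaining ROIs to the remaining axons, assuming ``(i, k)``
  already matched;
* the *inner* cost of pairing ROI ``i'`` with axon ``k'`` compares the
  displacement vectors ``x_i' - x_i`` and ``x_k' - x_k`` (length and angle,
  normalized by min(H, W) and an arctan angular scale), attenuated along the
  image height (the connective is scanned top to bottom, so vertical movement
  artifacts are tolerated more), plus the area difference;
* "dummy" axons with a flat cost ``max(v, 1.1 * min(costs))`` let spurious
  ROIs stay unmatched.

Tracking runs two passes: a sequential pass whose matches update the template
as running averages, then a re-match of every frame against the frozen
template, which yields the final identities.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import RecordingStack
from .detection import ROI, FinetuneResult, SegmentationResult, _normalized_frames

__all__ = [
    "AxonModel",
    "TrackerTemplate",
    "MatchCostConfig",
    "FrameAssignment",
    "init_template",
    "inner_cost",
    "outer_cost",
    "dummy_cost",
    "match_frame",
    "track_stack",
]


@dataclass
class MatchCostConfig:
    """Weights and constants of the matching cost."""

    w_area: float = 0.1
    w_dist: float = 1.0
    w_theta: float = 0.1
    alpha_theta: float = 0.1
    dummy_floor: float = 0.3  # v
    dummy_margin: float = 1.1
    # "printed": attenuate by H/(H + row(k')); "relative": H/(H + |row(k')-row(k)|)
    height_term: str = "printed"

    def __post_init__(self) -> None:
        for name in ("w_area", "w_dist", "w_theta", "alpha_theta",
                     "dummy_floor", "dummy_margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.height_term not in ("printed", "relative"):
            raise ValueError("height_term must be 'printed' or 'relative'")


@dataclass
class AxonModel:
    """One tracked axon: running-mean area and position (row, col)."""

    identity: int
    area: float
    position: np.ndarray
    n_updates: int = 1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.n_updates < 0:
            raise ValueError("n_updates must be >= 0")

    def update(self, roi: ROI) -> None:
        """Running-average update with the matched ROI's area and centroid."""
        n = self.n_updates
        self.area = (self.area * n + roi.area) / (n + 1)
        self.position = (self.position * n + roi.centroid) / (n + 1)
        self.n_updates = n + 1


@dataclass
class TrackerTemplate:
    """The persistent axon population matched against every frame."""

    axons: list[AxonModel]
    reference_image: np.ndarray | None = None
    frozen: bool = False

    def __post_init__(self) -> None:
        ids = [a.identity for a in self.axons]
        if len(set(ids)) != len(ids):
            raise ValueError("axon identities must be unique")

    @property
    def n_axons(self) -> int:
        return len(self.axons)

    def copy(self) -> "TrackerTemplate":
        return copy.deepcopy(self)


@dataclass
class FrameAssignment:
    """Per-ROI axon identity for one frame; ``None`` means unmatched."""

    roi_to_axon: list[int | None]
    total_cost: float = 0.0

    def matched_pairs(self) -> list[tuple[int, int]]:
        """(roi_index, axon_identity) for matched ROIs."""
        return [
            (i, a) for i, a in enumerate(self.roi_to_axon) if a is not None
        ]


def init_template(
    stack: RecordingStack,
    segmentations: list[SegmentationResult],
    finetune: FinetuneResult | None = None,
) -> TrackerTemplate:
    """Initialize the tracker template.

    With a fine-tune result, the cluster-average segmentation defines the
    axons directly.  Otherwise the initialization frame is chosen among the
    frames whose ROI count equals the most frequent (non-zero) ROI count, as
    the one with the highest cross-correlation with the temporal average of
    those frames (computed on normalized red frames, as in frame clustering).
    """
    if finetune is not None:
        rois = finetune.segmentation.rois
        if not rois:
            raise ValueError("fine-tune segmentation has no ROIs")
        axons = [
            AxonModel(identity=k, area=float(r.area), position=r.centroid)
            for k, r in enumerate(rois)
        ]
        return TrackerTemplate(axons=axons, reference_image=finetune.grayscale)

    counts = np.array([s.n_rois for s in segmentations])
    nonzero = counts[counts > 0]
    if nonzero.size == 0:
        raise ValueError("no frame has any ROI; cannot initialize template")
    modal = int(np.bincount(nonzero).argmax())
    candidates = np.flatnonzero(counts == modal)
    norm = _normalized_frames(stack.red)
    avg = norm[candidates].mean(axis=0)
    scores = norm[candidates] @ avg
    chosen = int(candidates[int(np.argmax(scores))])
    rois = segmentations[chosen].rois
    axons = [
        AxonModel(identity=k, area=float(r.area), position=r.centroid)
        for k, r in enumerate(rois)
    ]
    return TrackerTemplate(axons=axons, reference_image=stack.red[chosen].copy())


def _wrap_angle_diff(a: float, b: float) -> float:
    """|a - b| wrapped to [0, pi]."""
    d = abs(a - b) % (2 * np.pi)
    return min(d, 2 * np.pi - d)


def inner_cost(
    roi_pos: np.ndarray,
    roi_area: float,
    axon_pos: np.ndarray,
    axon_area: float,
    matched_roi_pos: np.ndarray,
    matched_axon_pos: np.ndarray,
    height: int,
    width: int,
    config: MatchCostConfig | None = None,
) -> float:
    """Inner matching cost of ROI i' vs axon k' given the matched pair (i, k).

    cost' = (w_dist/eta_dist * ||(x_i'-x_i) - (x_k'-x_k)||
             + w_theta/eta_theta * |theta_i' - theta_k'|) * attenuation
            + w_area * |area_i' - area_k'|

    with eta_dist = min(H, W), eta_theta = arctan(alpha_theta * eta_dist /
    ||x_k' - x_k||) (pi/2 in the coincident-axon limit), angles measured on
    the two displacement vectors and their difference wrapped to [0, pi], and
    the attenuation H/(H + row(k')) ("printed" form) or
    H/(H + |row(k') - row(k)|) ("relative" form).
    """
    cfg = config or MatchCostConfig()
    d_roi = np.asarray(roi_pos, float) - np.asarray(matched_roi_pos, float)
    d_axon = np.asarray(axon_pos, float) - np.asarray(matched_axon_pos, float)
    eta_dist = float(min(height, width))
    sep = float(np.linalg.norm(d_axon))
    if sep == 0.0:
        eta_theta = np.pi / 2
    else:
        eta_theta = np.arctan(cfg.alpha_theta * eta_dist / sep)
    theta_roi = np.arctan2(d_roi[0], d_roi[1])
    theta_axon = np.arctan2(d_axon[0], d_axon[1])
    dtheta = _wrap_angle_diff(theta_roi, theta_axon)
    if cfg.height_term == "printed":
        y_term = float(np.asarray(axon_pos, float)[0])
    else:
        y_term = abs(float(d_axon[0]))
    atten = height / (height + y_term)
    geom = (
        cfg.w_dist / eta_dist * float(np.linalg.norm(d_roi - d_axon))
        + cfg.w_theta / eta_theta * dtheta
    )
    return geom * atten + cfg.w_area * abs(roi_area - axon_area)


def dummy_cost(cost_matrix: np.ndarray, config: MatchCostConfig | None = None) -> float:
    """Flat cost of matching to a dummy axon: ``max(v, 1.1 * min(costs))``."""
    cfg = config or MatchCostConfig()
    m = np.asarray(cost_matrix, dtype=float)
    if m.size == 0:
        raise ValueError("empty cost matrix")
    return max(cfg.dummy_floor, cfg.dummy_margin * float(m.min()))


def _solve_with_dummies(
    cost: np.ndarray, config: MatchCostConfig
) -> tuple[list[int | None], float]:
    """Assign every row (ROI) to a column (axon) or a dummy.

    ``cost`` is (n_rois, n_axons); one dummy column per ROI is appended at
    the flat dummy cost so any subset of ROIs can stay unmatched.  Returns
    the per-row assignment (column index or None) and the total cost.
    """
    n_rois, n_axons = cost.shape
    if n_rois == 0:
        return [], 0.0
    if n_axons == 0:
        flat = config.dummy_floor
        return [None] * n_rois, flat * n_rois
    flat = dummy_cost(cost, config)
    full = np.full((n_rois, n_axons + n_rois), flat, dtype=float)
    full[:, :n_axons] = cost
    rows, cols = linear_sum_assignment(full)
    assign: list[int | None] = [None] * n_rois
    total = 0.0
    for r, c in zip(rows, cols):
        total += full[r, c]
        if c < n_axons:
            assign[r] = int(c)
    return assign, total


def _inner_mean_cost(
    i: int,
    k: int,
    rois: list[ROI],
    axons: list[AxonModel],
    height: int,
    width: int,
    cfg: MatchCostConfig,
) -> float:
    """Mean cost of the optimal inner assignment given (i, k) matched."""
    other_rois = [r for j, r in enumerate(rois) if j != i]
    other_axons = [a for j, a in enumerate(axons) if j != k]
    if not other_rois:
        return 0.0
    xi, xk = rois[i].centroid, axons[k].position
    cost = np.empty((len(other_rois), len(other_axons)))
    for a, r in enumerate(other_rois):
        for b, ax in enumerate(other_axons):
            cost[a, b] = inner_cost(
                r.centroid, r.area, ax.position, ax.area, xi, xk,
                height, width, cfg,
            )
    _assign, total = _solve_with_dummies(cost, cfg)
    return total / len(other_rois)


def outer_cost(
    i: int,
    k: int,
    rois: list[ROI],
    axons: list[AxonModel],
    height: int,
    width: int,
    config: MatchCostConfig | None = None,
) -> float:
    """Outer cost of matching ROI ``i`` to template axon ``k``.

    ``w_area * |area_i - area_k|`` plus the mean optimal inner-assignment
    cost of the remaining ROIs against the remaining axons (dummies
    included); the second term is 0 when the frame has a single ROI.
    """
    cfg = config or MatchCostConfig()
    base = cfg.w_area * abs(rois[i].area - axons[k].area)
    return base + _inner_mean_cost(i, k, rois, axons, height, width, cfg)


def match_frame(
    rois: list[ROI],
    template: TrackerTemplate,
    height: int,
    width: int,
    config: MatchCostConfig | None = None,
) -> FrameAssignment:
    """Minimum-total-cost assignment of a frame's ROIs to template axons.

    Dummy axons (one per ROI, at the flat dummy cost computed from the outer
    cost matrix) allow any subset of ROIs to remain unmatched.
    """
    cfg = config or MatchCostConfig()
    if template.n_axons == 0:
        raise ValueError("template has no axons")
    if not rois:
        return FrameAssignment(roi_to_axon=[], total_cost=0.0)
    cost = np.empty((len(rois), template.n_axons))
    for i in range(len(rois)):
        for k in range(template.n_axons):
            cost[i, k] = outer_cost(i, k, rois, template.axons, height, width, cfg)
    assign, total = _solve_with_dummies(cost, cfg)
    roi_to_axon = [
        template.axons[c].identity if c is not None else None for c in assign
    ]
    return FrameAssignment(roi_to_axon=roi_to_axon, total_cost=total)


def track_stack(
    stack: RecordingStack,
    segmentations: list[SegmentationResult],
    template: TrackerTemplate,
    config: MatchCostConfig | None = None,
) -> tuple[list[FrameAssignment], TrackerTemplate]:
    """Two-pass tracking over the whole stack.

    Pass 1 matches frames sequentially and updates each matched axon's area
    and position as running averages (the update count increments only on a
    match).  Pass 2 freezes the template and re-matches every frame; the
    pass-2 assignments are returned together with the frozen template.
    """
    if len(segmentations) != stack.n_frames:
        raise ValueError("one segmentation per frame required")
    cfg = config or MatchCostConfig()
    h, w = stack.frame_shape
    work = template.copy()
    by_id = {a.identity: a for a in work.axons}
    for seg in segmentations:
        assignment = match_frame(seg.rois, work, h, w, cfg)
        for roi_idx, axon_id in assignment.matched_pairs():
            by_id[axon_id].update(seg.rois[roi_idx])
    work.frozen = True
    final = [match_frame(seg.rois, work, h, w, cfg) for seg in segmentations]
    return final, work
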