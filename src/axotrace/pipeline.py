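"""Three-variant workflow orchestration.

The fluorescence-extraction pipeline runs up to three times: on the raw
stack, on the cross-correlation-registered stack and on the optic-flow-
registered stack.  The raw variant skips frame clustering and the
cluster-average fine-tune target (they are built on cross-correlation
similarity, so on raw data they would duplicate the cc variant), and hence
also skips automatic ROI separation.  Results are written side by side; a
failed variant is logged and skipped as long as at least one succeeds.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import RecordingStack
from .detection import (
    NoClusterError,
    SegmentationResult,
    cluster_similar_frames,
    dice,
    finetune_target,
    segment_stack_cv,
)
from .fluorescence import FluorescenceTable, extract_traces
from .registration import TranslationShift, register_cc, register_flow
from .separation import Cut, apply_cuts, find_cuts
from .synthetic import GroundTruth
from .tracking import (
    FrameAssignment,
    MatchCostConfig,
    TrackerTemplate,
    init_template,
    match_frame,
    track_stack,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "VariantResult",
    "run_variant",
    "run_all_variants",
    "evaluate_against_truth",
]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters; defaults are the method's standard
    values.  Serializable to/from YAML (round-trippable)."""

    min_size: int = 11
    smoothing_sigma: float = 2.0
    denoise: bool = True
    nlm_h: float = 11.0
    connectivity: int = 2
    cluster_min_samples: int = 20
    finetune_block_size: int = 25
    finetune_offset: float = 0.05
    maxima_threshold: float = 0.05
    baseline_window_seconds: float = 10.0
    registration_upsample: int = 1
    reference_index: int = 1
    w_area: float = 0.1
    w_dist: float = 1.0
    w_theta: float = 0.1
    alpha_theta: float = 0.1
    dummy_floor: float = 0.3
    dummy_margin: float = 1.1
    height_term: str = "printed"
    line_variant: str = "hw"
    variants: list[str] = field(default_factory=lambda: ["raw", "cc", "flow"])
    seed: int = 0

    def match_config(self) -> MatchCostConfig:
        return MatchCostConfig(
            w_area=self.w_area,
            w_dist=self.w_dist,
            w_theta=self.w_theta,
            alpha_theta=self.alpha_theta,
            dummy_floor=self.dummy_floor,
            dummy_margin=self.dummy_margin,
            height_term=self.height_term,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class VariantResult:
    """Everything one pipeline variant produces."""

    variant: str
    stack: RecordingStack
    segmentations: list[SegmentationResult]
    template: TrackerTemplate
    assignments: list[FrameAssignment]
    frame_rois: list[dict[int, np.ndarray]]
    fluorescence: FluorescenceTable
    shifts: list[TranslationShift] | None = None
    cuts: list[Cut] = field(default_factory=list)
    finetuned: bool = False


def _assignments_to_frame_rois(
    assignments: list[FrameAssignment],
    segmentations: list[SegmentationResult],
) -> list[dict[int, np.ndarray]]:
    out = []
    for assignment, seg in zip(assignments, segmentations):
        frame = {
            axon: seg.rois[i].pixels for i, axon in assignment.matched_pairs()
        }
        out.append(frame)
    return out


def run_variant(
    stack: RecordingStack,
    config: PipelineConfig | None = None,
    variant: str = "raw",
    flow_registrar=None,
) -> VariantResult:
    """Run detection -> tracking -> separation -> fluorescence for one
    variant ("raw", "cc" or "flow")."""
    cfg = config or PipelineConfig()
    shifts = None
    if variant == "cc":
        work, shifts = register_cc(
            stack, upsample=cfg.registration_upsample,
            reference_index=cfg.reference_index,
        )
    elif variant == "flow":
        if flow_registrar is None:
            raise RuntimeError(
                "no optic-flow registrar plugged in; flow variant unavailable"
            )
        work = register_flow(stack, registrar=flow_registrar)
    elif variant == "raw":
        work = stack
    else:
        raise ValueError(f"unknown variant {variant!r}")

    segmentations = segment_stack_cv(
        work,
        sigma=cfg.smoothing_sigma,
        min_size=cfg.min_size,
        connectivity=cfg.connectivity,
        denoise=cfg.denoise,
        nlm_h=cfg.nlm_h,
    )

    finetune = None
    if variant != "raw":
        try:
            cluster = cluster_similar_frames(work, cfg.cluster_min_samples)
            finetune = finetune_target(
                work,
                cluster,
                block_size=cfg.finetune_block_size,
                offset=cfg.finetune_offset,
                min_size=cfg.min_size,
            )
            if finetune.segmentation.n_rois == 0:
                logger.warning(
                    "%s: fine-tune target mask empty; continuing without", variant
                )
                finetune = None
        except (NoClusterError, ValueError) as exc:
            logger.warning("%s: no frame cluster (%s); continuing without",
                           variant, exc)
            finetune = None

    template = init_template(work, segmentations, finetune)
    match_cfg = cfg.match_config()
    assignments, frozen = track_stack(work, segmentations, template, match_cfg)

    cuts: list[Cut] = []
    if finetune is not None:
        # map each fine-tune ROI to the axon identity it tracks to
        h, w = work.frame_shape
        ft_assignment = match_frame(
            finetune.segmentation.rois, frozen, h, w, match_cfg
        )
        roi_axon_ids = dict(ft_assignment.matched_pairs())
        cuts, _partition = find_cuts(
            finetune,
            roi_axon_ids,
            maxima_threshold=cfg.maxima_threshold,
            min_size=cfg.min_size,
            variant=cfg.line_variant,
        )
    if cuts:
        frame_rois = apply_cuts(cuts, assignments, segmentations,
                                variant=cfg.line_variant)
    else:
        frame_rois = _assignments_to_frame_rois(assignments, segmentations)

    fluor = extract_traces(work, frame_rois).compute_ratios(
        cfg.baseline_window_seconds
    )
    return VariantResult(
        variant=variant,
        stack=work,
        segmentations=segmentations,
        template=frozen,
        assignments=assignments,
        frame_rois=frame_rois,
        fluorescence=fluor,
        shifts=shifts,
        cuts=cuts,
        finetuned=finetune is not None,
    )


def run_all_variants(
    stack: RecordingStack,
    config: PipelineConfig | None = None,
    flow_registrar=None,
) -> dict[str, VariantResult]:
    """Run every configured variant; failures are logged and skipped but at
    least one variant must succeed."""
    cfg = config or PipelineConfig()
    results: dict[str, VariantResult] = {}
    for variant in cfg.variants:
        try:
            results[variant] = run_variant(
                stack, cfg, variant, flow_registrar=flow_registrar
            )
        except Exception as exc:  # noqa: BLE001 - variant isolation by design
            logger.warning("variant %s failed and is skipped: %s", variant, exc)
    if not results:
        raise RuntimeError("all pipeline variants failed")
    return results


def _aligned_truth_masks(result: VariantResult, truth: GroundTruth) -> np.ndarray:
    """Ground-truth masks brought into the variant's (possibly registered)
    coordinates by applying the same wrap-around translations."""
    if result.shifts is None:
        return truth.masks
    masks = np.empty_like(truth.masks)
    for t, s in enumerate(result.shifts):
        masks[t] = np.roll(
            truth.masks[t], (int(round(s.dy)), int(round(s.dx))), axis=(1, 2)
        )
    return masks


def _map_axons_to_truth(
    frame_rois: list[dict[int, np.ndarray]], gt_masks: np.ndarray
) -> dict[int, int]:
    """Global predicted-axon -> true-axon mapping by total pixel overlap
    (optimal one-to-one assignment)."""
    from scipy.optimize import linear_sum_assignment

    pred_ids = sorted({a for frame in frame_rois for a in frame})
    if not pred_ids:
        return {}
    n_axons = gt_masks.shape[1]
    overlap = np.zeros((len(pred_ids), n_axons))
    for t, frame in enumerate(frame_rois):
        for i, pid in enumerate(pred_ids):
            pix = frame.get(pid)
            if pix is None or len(pix) == 0:
                continue
            for k in range(n_axons):
                overlap[i, k] += gt_masks[t, k][pix[:, 0], pix[:, 1]].sum()
    rows, cols = linear_sum_assignment(-overlap)
    return {pred_ids[r]: int(c) for r, c in zip(rows, cols) if overlap[r, c] > 0}


def evaluate_against_truth(
    result: VariantResult, truth: GroundTruth
) -> dict:
    """Score a synthetic run against its ground truth.

    ``identity_accuracy`` is the fraction of assigned (axon, frame) ROIs
    that carry the correct identity (an identity-switch-free rate); axons
    the tracker left unmatched in a frame are missing values by design, so
    they lower ``coverage`` (the fraction of visible true axon-slots
    recovered with the right identity) but are not identity errors.  Also
    reported: the mean Dice of the predicted foreground against the true
    union mask, and the per-axon Pearson correlation of the extracted F
    (and dF/F) traces against the true calcium traces.
    """
    gt_masks = _aligned_truth_masks(result, truth)
    mapping = _map_axons_to_truth(result.frame_rois, gt_masks)
    inverse = {v: k for k, v in mapping.items()}
    n_correct = 0          # assigned identities that are correct
    n_assigned = 0         # all assigned (pred axon, frame) pairs
    n_covered = 0          # true axon-slots recovered with the right identity
    n_slots = 0            # all (frame, true axon) slots with a visible mask
    dices = []
    shape = gt_masks.shape[2:]
    for t, frame in enumerate(result.frame_rois):
        pred_union = np.zeros(shape, dtype=bool)
        for pix in frame.values():
            pred_union[pix[:, 0], pix[:, 1]] = True
        dices.append(dice(pred_union, gt_masks[t].any(axis=0)))
        for pid, pix in frame.items():
            if len(pix) == 0:
                continue
            n_assigned += 1
            overlaps = [gt_masks[t, k][pix[:, 0], pix[:, 1]].sum()
                        for k in range(truth.n_axons)]
            best_k = int(np.argmax(overlaps))
            if overlaps[best_k] > 0 and mapping.get(pid) == best_k:
                n_correct += 1
        for k in range(truth.n_axons):
            gt_mask = gt_masks[t, k]
            if not gt_mask.any():
                continue
            n_slots += 1
            best_pid, best_ov = None, 0
            for pid, pix in frame.items():
                ov = gt_mask[pix[:, 0], pix[:, 1]].sum()
                if ov > best_ov:
                    best_pid, best_ov = pid, ov
            if best_pid is not None and inverse.get(k) == best_pid:
                n_covered += 1
    fluor = result.fluorescence
    correlations: dict[int, float] = {}
    dff_correlations: dict[int, float] = {}
    for pid, k in mapping.items():
        if pid not in fluor.axon_ids:
            continue
        j = fluor.axon_ids.index(pid)
        trace = fluor.f[:, j]
        valid = ~np.isnan(trace)
        gt = truth.traces[k]
        if valid.sum() >= 2 and np.std(trace[valid]) > 0 and np.std(gt[valid]) > 0:
            correlations[k] = float(np.corrcoef(trace[valid], gt[valid])[0, 1])
        if fluor.dff is not None:
            dtrace = fluor.dff[:, j]
            dvalid = ~np.isnan(dtrace)
            if dvalid.sum() >= 2 and np.std(dtrace[dvalid]) > 0 and np.std(gt[dvalid]) > 0:
                dff_correlations[k] = float(
                    np.corrcoef(dtrace[dvalid], gt[dvalid])[0, 1]
                )
    identity_mismatch = len(
        {a for frame in result.frame_rois for a in frame}
    ) != truth.n_axons
    return {
        "variant": result.variant,
        "identity_accuracy": (n_correct / n_assigned) if n_assigned else float("nan"),
        "coverage": (n_covered / n_slots) if n_slots else float("nan"),
        "mean_dice": float(np.mean(dices)) if dices else float("nan"),
        "trace_correlation": correlations,
        "dff_correlation": dff_correlations,
        "identity_count_mismatch": identity_mismatch,
        "n_assigned": n_assigned,
        "n_slots": n_slots,
    }
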