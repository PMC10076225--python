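"""Reading and writing recordings, masks and results.

Stacks are stored as two multi-page TIFFs (one per channel) plus a sidecar
JSON declaring fps and channel order; masks as multi-page TIFF (0/255);
tables as CSV; cuts and templates as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import RecordingStack
from .detection import SegmentationResult
from .separation import Cut
from .synthetic import GroundTruth
from .tracking import FrameAssignment, TrackerTemplate

__all__ = [
    "save_stack", "load_stack",
    "save_masks", "save_ground_truth",
    "save_shifts", "save_assignments", "save_template", "save_cuts",
]


def save_stack(stack: RecordingStack, out_dir: str | Path, stem: str = "stack") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{stem}_green.tif", stack.green.astype(np.float32))
    tifffile.imwrite(out / f"{stem}_red.tif", stack.red.astype(np.float32))
    sidecar = {
        "fps": stack.fps,
        "channels": {"green": f"{stem}_green.tif", "red": f"{stem}_red.tif"},
        "n_frames": stack.n_frames,
        "height": stack.height,
        "width": stack.width,
    }
    (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))


def load_stack(out_dir: str | Path, stem: str = "stack") -> RecordingStack:
    out = Path(out_dir)
    sidecar = json.loads((out / f"{stem}.json").read_text())
    green = tifffile.imread(out / sidecar["channels"]["green"]).astype(float)
    red = tifffile.imread(out / sidecar["channels"]["red"]).astype(float)
    if green.ndim == 2:
        green = green[None]
        red = red[None]
    return RecordingStack(green=green, red=red, fps=sidecar["fps"])


def save_masks(segmentations: list[SegmentationResult], path: str | Path) -> None:
    masks = np.stack([s.mask for s in segmentations]).astype(np.uint8) * 255
    tifffile.imwrite(path, masks)


def save_roi_table(segmentations: list[SegmentationResult], path: str | Path) -> None:
    rows = []
    for t, seg in enumerate(segmentations):
        for i, roi in enumerate(seg.rois):
            rows.append(
                {
                    "frame": t,
                    "roi_id": i,
                    "area": roi.area,
                    "centroid_row": roi.centroid[0],
                    "centroid_col": roi.centroid[1],
                }
            )
    pd.DataFrame(
        rows, columns=["frame", "roi_id", "area", "centroid_row", "centroid_col"]
    ).to_csv(path, index=False)


def save_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / "ground_truth_masks.npz", masks=truth.masks)
    pd.DataFrame(
        truth.traces.T,
        columns=[f"axon{ax.identity}" for ax in truth.axons],
    ).to_csv(out / "ground_truth_traces.csv", index_label="frame")
    meta = {
        "axons": [
            {
                "identity": ax.identity,
                "center": ax.center.tolist(),
                "covariance": ax.covariance.tolist(),
                "tdtomato_level": ax.tdtomato_level,
                "spike_rate": ax.spike_rate,
            }
            for ax in truth.axons
        ],
        "deformations": truth.deformations,
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=2))


def save_shifts(shifts, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"frame": t, "dy": s.dy, "dx": s.dx,
             "peak_correlation": s.peak_correlation}
            for t, s in enumerate(shifts)
        ]
    ).to_csv(path, index=False)


def save_assignments(
    assignments: list[FrameAssignment], path: str | Path
) -> None:
    rows = []
    for t, a in enumerate(assignments):
        for i, axon in enumerate(a.roi_to_axon):
            rows.append(
                {
                    "frame": t,
                    "roi_id": i,
                    "axon_id": axon if axon is not None else "unmatched",
                }
            )
    pd.DataFrame(rows, columns=["frame", "roi_id", "axon_id"]).to_csv(
        path, index=False
    )


def save_template(template: TrackerTemplate, path: str | Path) -> None:
    data = {
        "frozen": template.frozen,
        "axons": [
            {
                "identity": a.identity,
                "area": a.area,
                "position": a.position.tolist(),
                "n_updates": a.n_updates,
            }
            for a in template.axons
        ],
    }
    Path(path).write_text(json.dumps(data, indent=2))


def save_cuts(cuts: list[Cut], path: str | Path) -> None:
    data = [
        {
            "parent_axon": c.parent_axon,
            "child_axon": c.child_axon,
            "normal": c.line.n.tolist(),
            "distance": c.line.d,
        }
        for c in cuts
    ]
    Path(path).write_text(json.dumps(data, indent=2))
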