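"""Per-axon fluorescence time series, baselines, dF/F and dR/R.

For each axon and frame, the raw GCaMP signal ``F_t`` is the mean of the
*non-zero* green pixels of the axon's ROI, ``tdTom_t`` likewise on the red
channel, and ``R_t = F_t / tdTom_t`` — the ratio cancels global intensity
fluctuations because tdTomato is activity-independent.  The baseline ``F``
(or ``R``) is the minimal mean over sliding 10-s windows of the series, and

    dF/F = (F_t - F) / F,       dR/R = (R_t - R) / R.

Axons can be missing in frames (not detected, or moved out of the image);
missing values propagate explicitly (NaN in memory, empty fields in CSV).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RecordingStack

logger = logging.getLogger(__name__)

__all__ = ["FluorescenceTable", "extract_traces", "baseline", "dff"]


def _nonzero_mean(values: np.ndarray) -> float:
    nz = values[values > 0]
    return float(nz.mean()) if nz.size else np.nan


def extract_traces(
    stack: RecordingStack,
    frame_rois: list[dict[int, np.ndarray]],
) -> "FluorescenceTable":
    """Raw per-axon traces from per-frame ROI pixel sets.

    ``frame_rois[t]`` maps axon identity to an (N, 2) (row, col) pixel array
    for frame ``t``; axons absent from a frame's dictionary are missing
    there.  An ROI whose pixels are all zero in a channel yields a missing
    value for that channel in that frame (logged).
    """
    if len(frame_rois) != stack.n_frames:
        raise ValueError("one ROI dictionary per frame required")
    axon_ids = sorted({a for frame in frame_rois for a in frame})
    n_t, n_a = stack.n_frames, len(axon_ids)
    f = np.full((n_t, n_a), np.nan)
    td = np.full((n_t, n_a), np.nan)
    for t, frame in enumerate(frame_rois):
        for j, axon in enumerate(axon_ids):
            pix = frame.get(axon)
            if pix is None or len(pix) == 0:
                continue
            rows, cols = pix[:, 0], pix[:, 1]
            f[t, j] = _nonzero_mean(stack.green[t][rows, cols])
            td[t, j] = _nonzero_mean(stack.red[t][rows, cols])
            if np.isnan(f[t, j]) or np.isnan(td[t, j]):
                logger.info(
                    "axon %d frame %d: all-zero pixels in a channel", axon, t
                )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(td > 0, f / td, np.nan)
    return FluorescenceTable(
        axon_ids=axon_ids, f=f, tdtom=td, r=r, fps=stack.fps
    )


def baseline(
    trace: np.ndarray,
    fps: float,
    window_seconds: float = 10.0,
    max_missing_frac: float = 0.5,
) -> float:
    """Minimal mean over sliding windows of ``window_seconds``.

    Window means skip missing (NaN) frames; windows with more than
    ``max_missing_frac`` missing frames are excluded from the minimum.
    Traces shorter than one window fall back to the mean of the whole
    trace.  An all-missing trace raises ``ValueError``.
    """
    trace = np.asarray(trace, dtype=float)
    valid = ~np.isnan(trace)
    if not valid.any():
        raise ValueError("all-missing trace has no baseline")
    win = int(round(window_seconds * fps))
    if win < 1 or win > len(trace):
        return float(np.nanmean(trace))
    filled = np.where(valid, trace, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccount = np.concatenate([[0], np.cumsum(valid.astype(int))])
    sums = csum[win:] - csum[:-win]
    counts = ccount[win:] - ccount[:-win]
    ok = counts >= win * (1.0 - max_missing_frac)
    ok &= counts > 0
    if not ok.any():
        return float(np.nanmean(trace))
    means = sums[ok] / counts[ok]
    return float(means.min())


def dff(trace: np.ndarray, base: float) -> np.ndarray:
    """Elementwise ``(value - base) / base``; missing values propagate."""
    if not np.isfinite(base) or base <= 0:
        raise ValueError(f"baseline must be finite and > 0, got {base}")
    trace = np.asarray(trace, dtype=float)
    return (trace - base) / base


@dataclass
class FluorescenceTable:
    """Per-axon fluorescence time series with explicit missing values.

    Arrays are (n_frames, n_axons), NaN marking frames where the axon was
    unmatched (or a channel all-zero).  ``dff``/``drr`` and the baselines
    are filled in by :meth:`compute_ratios`.
    """

    axon_ids: list[int]
    f: np.ndarray
    tdtom: np.ndarray
    r: np.ndarray
    fps: float
    dff: np.ndarray | None = None
    drr: np.ndarray | None = None
    f_baselines: dict[int, float] = field(default_factory=dict)
    r_baselines: dict[int, float] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.f.shape[0]

    def compute_ratios(self, window_seconds: float = 10.0) -> "FluorescenceTable":
        """Compute baselines and dF/F, dR/R for every axon (in place)."""
        self.dff = np.full_like(self.f, np.nan)
        self.drr = np.full_like(self.r, np.nan)
        for j, axon in enumerate(self.axon_ids):
            for series, out, store in (
                (self.f, self.dff, self.f_baselines),
                (self.r, self.drr, self.r_baselines),
            ):
                trace = series[:, j]
                if not np.any(~np.isnan(trace)):
                    logger.warning("axon %d: trace entirely missing", axon)
                    continue
                b = baseline(trace, self.fps, window_seconds)
                store[axon] = b
                out[:, j] = dff(trace, b)
        return self

    def to_dataframe(self) -> pd.DataFrame:
        """One row per frame; columns axonK_F, axonK_tdTom, axonK_dFF,
        axonK_dRR."""
        cols: dict[str, np.ndarray] = {}
        for j, axon in enumerate(self.axon_ids):
            cols[f"axon{axon}_F"] = self.f[:, j]
            cols[f"axon{axon}_tdTom"] = self.tdtom[:, j]
            if self.dff is not None:
                cols[f"axon{axon}_dFF"] = self.dff[:, j]
            if self.drr is not None:
                cols[f"axon{axon}_dRR"] = self.drr[:, j]
        df = pd.DataFrame(cols)
        df.index.name = "frame"
        return df

    def to_csv(self, path: str | Path) -> None:
        """CSV with empty fields for missing values, plus a JSON sidecar
        carrying fps and the baselines."""
        path = Path(path)
        self.to_dataframe().to_csv(path, na_rep="")
        sidecar = {
            "fps": self.fps,
            "f_baselines": {str(k): v for k, v in self.f_baselines.items()},
            "r_baselines": {str(k): v for k, v in self.r_baselines.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
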