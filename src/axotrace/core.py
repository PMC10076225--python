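"""Shared container for two-channel recordings.

Conventions used throughout the package:

* image arrays are indexed ``[row, col]`` with the origin at the top-left of
  the frame; the *y* (height) component of a position is its row index,
* positions/centroids are ``(row, col)`` float pairs,
* the geometry helpers in :mod:`axotrace.separation` work in ``(x, y)`` =
  ``(col, row)`` vectors; conversion happens at that module's boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RecordingStack:
    """Ordered two-channel frame sequence with frame-rate metadata.

    Parameters
    ----------
    green, red : ndarray, shape (T, H, W)
        GCaMP (activity) and tdTomato (anatomy) channels.  Non-negative.
    fps : float
        Acquisition rate in frames per second; used for the 10-s baseline
        window of the fluorescence stage.
    """

    green: np.ndarray
    red: np.ndarray
    fps: float = 4.0

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green.ndim != 3 or self.red.ndim != 3:
            raise ValueError("channels must be (T, H, W) arrays")
        if self.green.shape != self.red.shape:
            raise ValueError(
                f"channel shapes differ: {self.green.shape} vs {self.red.shape}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if np.any(self.green < 0) or np.any(self.red < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def height(self) -> int:
        return self.green.shape[1]

    @property
    def width(self) -> int:
        return self.green.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.green.shape[1:]

    def __len__(self) -> int:
        return self.n_frames

    def copy(self) -> "RecordingStack":
        return RecordingStack(self.green.copy(), self.red.copy(), self.fps)
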