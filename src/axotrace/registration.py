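"""Frame registration.

Cross-correlation registration translates each frame so that its correlation
with a reference frame is maximized, using the single-step DFT algorithm
(Guizar-Sicairos upsampled phase correlation, as implemented by
``skimage.registration.phase_cross_correlation``).  Shifts are estimated on
the red (tdTomato) channel only — it is activity-independent, so GCaMP
dynamics cannot masquerade as motion — and the same shift is applied to both
channels with wrap-around (pixels leaving one edge reappear at the other).

The reference is the *second* frame of the recording: the first frame of an
acquisition sometimes carries start-of-scan artifacts.

Non-rigid (optic-flow) registration is exposed only as a pluggable interface:
any callable mapping ``(stack, reference_index) -> stack`` may be registered;
the default is a logged no-op.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core import RecordingStack

logger = logging.getLogger(__name__)

__all__ = ["TranslationShift", "register_cc", "register_flow"]


@dataclass
class TranslationShift:
    """Applied translation (pixels; possibly subpixel) and the normalized
    correlation between the registered frame and the reference."""

    dy: float
    dx: float
    peak_correlation: float


def _translate(frame: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Circularly translate a frame by (dy, dx)."""
    if dy == int(dy) and dx == int(dx):
        return np.roll(frame, (int(dy), int(dx)), axis=(0, 1))
    shifted = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(frame), (dy, dx)))
    return shifted.real


def _norm_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def register_cc(
    stack: RecordingStack,
    upsample: int = 1,
    reference_index: int = 1,
) -> tuple[RecordingStack, list[TranslationShift]]:
    """Register every frame to the reference by wrap-around translation.

    Parameters
    ----------
    stack : RecordingStack
        At least two frames.
    upsample : int
        Upsampling factor of the DFT refinement; 1 gives integer shifts
        (bit-exact for integer circular displacements), larger values give
        subpixel shifts applied by Fourier phase shift.
    reference_index : int
        0-based index of the reference frame (default 1, i.e. the second
        frame).

    Returns
    -------
    (registered stack, list of per-frame TranslationShift)
    """
    if stack.n_frames < 2:
        raise ValueError("registration needs at least 2 frames (no reference)")
    if not 0 <= reference_index < stack.n_frames:
        raise ValueError("reference_index out of range")
    ref = stack.red[reference_index]
    green = np.empty_like(stack.green)
    red = np.empty_like(stack.red)
    shifts: list[TranslationShift] = []
    for t in range(stack.n_frames):
        if t == reference_index:
            dy = dx = 0.0
        else:
            shift, _error, _phase = phase_cross_correlation(
                ref, stack.red[t], upsample_factor=upsample, normalization=None
            )
            dy, dx = float(shift[0]), float(shift[1])
        red[t] = _translate(stack.red[t], dy, dx)
        green[t] = _translate(stack.green[t], dy, dx)
        shifts.append(TranslationShift(dy, dx, _norm_corr(red[t], ref)))
    np.clip(green, 0.0, None, out=green)
    np.clip(red, 0.0, None, out=red)
    return RecordingStack(green=green, red=red, fps=stack.fps), shifts


FlowRegistrar = Callable[[RecordingStack, int], RecordingStack]


def register_flow(
    stack: RecordingStack,
    reference_index: int = 0,
    registrar: FlowRegistrar | None = None,
) -> RecordingStack:
    """Non-rigid registration slot.

    ``registrar`` is any callable ``(stack, reference_index) -> stack`` of the
    same shape (e.g. an optic-flow warper).  Without one, the stack is
    returned unchanged and a warning is logged so the pipeline can still run
    its other variants.
    """
    if registrar is None:
        logger.warning(
            "no optic-flow registrar plugged in: returning the stack unchanged"
        )
        return stack
    out = registrar(stack, reference_index)
    if out.frame_shape != stack.frame_shape or out.n_frames != stack.n_frames:
        raise ValueError("flow registrar must preserve the stack shape")
    return out
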