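"""Ground-truthed synthetic two-photon recordings.

Emulates the statistical structure of coronal-section recordings of axon
bundles: axon cross-sections are elliptical 2-D Gaussians, the red (tdTomato)
channel carries a static per-axon level, the green (GCaMP) channel follows a
calcium trace built from Poisson spikes convolved with a calcium response
kernel, each frame is deformed by a smooth random warp emulating movement
artifacts, and noise (shot + Gaussian read noise) is added last.

Every stochastic choice is driven by independent child streams of a single
seed, so geometry, spikes, deformations and noise can be varied independently
while the rest stays fixed (e.g. raising ``spike_rate`` at a fixed seed keeps
the same geometry and monotonically increases every spike count, because
spikes are drawn by inverse-CDF from per-frame uniforms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.stats import poisson as poisson_dist

from .core import RecordingStack

__all__ = [
    "AxonSpec",
    "CalciumKernel",
    "GroundTruth",
    "calcium_kernel",
    "generate_experiment",
]


@dataclass
class AxonSpec:
    """Static description of one synthetic axon cross-section.

    ``center`` is ``(row, col)`` in pixels; ``covariance`` is the 2x2
    covariance of the elliptical Gaussian density (pixels^2), required to be
    symmetric positive definite.  ``tdtomato_level`` is the static red-channel
    intensity in (0, 1]; ``spike_rate`` the Poisson event rate in events/s.
    """

    identity: int
    center: np.ndarray
    covariance: np.ndarray
    tdtomato_level: float
    spike_rate: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.center.shape != (2,):
            raise ValueError("center must be a (row, col) pair")
        if self.covariance.shape != (2, 2):
            raise ValueError("covariance must be 2x2")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(self.covariance)
        if np.any(eigvals <= 0):
            raise ValueError("covariance must be positive definite")
        if self.tdtomato_level <= 0:
            raise ValueError("tdtomato_level must be > 0")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")


@dataclass
class CalciumKernel:
    """Calcium response kernel: difference of exponentials, unit peak.

    ``rise_time`` is the time from onset to the kernel peak (s); ``half_life``
    the half-life of the decaying exponential (s).  The discrete kernel is
    sampled at ``sampling_rate`` frames/s.
    """

    rise_time: float
    half_life: float
    sampling_rate: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rise_time <= 0 or self.half_life <= 0 or self.sampling_rate <= 0:
            raise ValueError("kernel parameters must be positive")
        if np.any(self.values < -1e-12):
            raise ValueError("kernel values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def calcium_kernel(
    rise_time: float = 0.1415,
    half_life: float = 0.95,
    fps: float = 4.0,
    tail_fraction: float = 1e-3,
) -> CalciumKernel:
    """Build a discrete calcium response kernel.

    The continuous form is ``k(t) = exp(-lam_d t) - exp(-lam_r t)`` with the
    decay rate ``lam_d = ln2 / half_life`` and the rise rate ``lam_r`` solved
    numerically so the peak occurs at ``t = rise_time``.  The kernel is
    normalized to unit peak and truncated once the tail falls below
    ``tail_fraction`` of the peak.

    Defaults follow common GCaMP6f response parameters: 0.1415 s rise, 0.95 s
    half-life.
    """
    if rise_time <= 0 or half_life <= 0 or fps <= 0:
        raise ValueError("rise_time, half_life and fps must be positive")
    lam_d = np.log(2.0) / half_life
    # peak time of a difference of exponentials: ln(r/d)/(r-d); as the rise
    # rate approaches the decay rate the peak time approaches 1/lam_d, so a
    # requested peak at or beyond that is unreachable for this kernel form.
    if rise_time >= 1.0 / lam_d:
        raise ValueError(
            f"rise_time must be < half_life/ln(2) = {1.0 / lam_d:.4g} s "
            "for a difference-of-exponentials kernel"
        )

    def peak_time(lam_r: float) -> float:
        return np.log(lam_r / lam_d) / (lam_r - lam_d)

    lo = lam_d * (1 + 1e-9)
    hi = lam_d * 2.0
    while peak_time(hi) > rise_time:
        hi *= 2.0
    lam_r = optimize.brentq(lambda r: peak_time(r) - rise_time, lo, hi)

    t_end = rise_time + half_life * np.log2(1.0 / tail_fraction)
    n = max(int(np.ceil(t_end * fps)) + 1, 2)
    t = np.arange(n) / fps
    values = np.exp(-lam_d * t) - np.exp(-lam_r * t)
    peak = values.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (no positive values)")
    values = np.clip(values / peak, 0.0, None)
    if rise_time * fps < 0.5:
        warnings.warn(
            f"sampling rate {fps} frames/s too low to resolve the "
            f"{rise_time} s rise: the peak falls before the first sample",
            stacklevel=2,
        )
    return CalciumKernel(rise_time, half_life, fps, values)


@dataclass
class GroundTruth:
    """Per-frame truth recorded by the generator.

    ``masks[t, k]`` is the boolean pixel mask of axon ``k`` in frame ``t``
    (deformed like the rendered image); ``traces[k]`` is axon ``k``'s true
    GCaMP trace (a.u.); ``deformations[t]`` stores the affine applied to
    frame ``t``.
    """

    axons: list[AxonSpec]
    masks: np.ndarray
    traces: np.ndarray
    deformations: list[dict]

    def __post_init__(self) -> None:
        if self.traces.shape[1] != self.masks.shape[0]:
            raise ValueError("trace length must equal frame count")
        if self.masks.shape[1] != len(self.axons):
            raise ValueError("one mask track per axon required")

    @property
    def n_axons(self) -> int:
        return len(self.axons)

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    def union_mask(self, t: int) -> np.ndarray:
        return self.masks[t].any(axis=0)


def _render_density(center, cov, shape, oversample: int = 2) -> np.ndarray:
    """Unit-peak Gaussian density integrated over pixels (midpoint rule on an
    oversampled sub-grid)."""
    h, w = shape
    step = 1.0 / oversample
    offs = (np.arange(oversample) + 0.5) * step - 0.5
    rows = np.arange(h)[:, None] + offs[None, :]
    cols = np.arange(w)[:, None] + offs[None, :]
    prec = np.linalg.inv(cov)
    dr = rows.reshape(-1) - center[0]
    dc = cols.reshape(-1) - center[1]
    quad = (
        prec[0, 0] * dr[:, None] ** 2
        + 2 * prec[0, 1] * dr[:, None] * dc[None, :]
        + prec[1, 1] * dc[None, :] ** 2
    )
    dens = np.exp(-0.5 * quad)
    # the exponential is exactly 1 at the (continuous) center, so the field
    # is already unit-peak; renormalizing by the sampled maximum would make
    # the blob's brightness flutter with its subpixel position
    return dens.reshape(h, oversample, w, oversample).mean(axis=(1, 3))


def _sample_axons(
    rng: np.random.Generator,
    n_axons: int,
    shape: tuple[int, int],
    axis_range: tuple[float, float],
    tdtomato_range: tuple[float, float],
    spike_rate: float,
    margin_frac: float,
    min_separation: float | None,
) -> list[AxonSpec]:
    h, w = shape
    margin = max(margin_frac * min(h, w), axis_range[1] + 1)
    if 2 * margin >= min(h, w):
        raise ValueError("frame too small for the requested axon margin")
    if min_separation is None:
        min_separation = 5.0 * axis_range[1]
    centers: list[np.ndarray] = []
    for _ in range(n_axons):
        for _attempt in range(2000):
            c = np.array(
                [
                    rng.uniform(margin, h - margin),
                    rng.uniform(margin, w - margin),
                ]
            )
            if all(np.linalg.norm(c - o) >= min_separation for o in centers):
                centers.append(c)
                break
        else:
            raise ValueError(
                f"could not place {n_axons} axons with separation "
                f">= {min_separation} in a {h}x{w} frame"
            )
    axons = []
    for k, c in enumerate(centers):
        a, b = rng.uniform(*axis_range, size=2)
        phi = rng.uniform(-np.pi / 2, np.pi / 2)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        cov = rot @ np.diag([a**2, b**2]) @ rot.T
        cov = 0.5 * (cov + cov.T)
        axons.append(
            AxonSpec(
                identity=k,
                center=c,
                covariance=cov,
                tdtomato_level=rng.uniform(*tdtomato_range),
                spike_rate=spike_rate,
            )
        )
    return axons


def _spike_trace(
    u: np.ndarray, rate_per_frame: float, kernel: CalciumKernel
) -> np.ndarray:
    """Poisson spikes by inverse CDF (monotone in the rate) convolved with the
    kernel."""
    spikes = poisson_dist.ppf(u, rate_per_frame) if rate_per_frame > 0 else np.zeros_like(u)
    return np.convolve(spikes, kernel.values)[: len(u)]


def _frame_affine(
    rng: np.random.Generator, magnitude: float, shape: tuple[int, int]
) -> dict:
    h, w = shape
    dy = rng.uniform(-0.1, 0.1) * magnitude * h
    dx = rng.uniform(-0.1, 0.1) * magnitude * w
    angle = rng.uniform(-np.deg2rad(5), np.deg2rad(5)) * magnitude
    scale = 1.0 + rng.uniform(-0.05, 0.05) * magnitude
    return {"dy": dy, "dx": dx, "angle": angle, "scale": scale}


def _transform_axon(
    center: np.ndarray, cov: np.ndarray, params: dict, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Map a Gaussian axon through the frame affine analytically.

    The affine (rotation and scale about the frame center, then translation)
    sends a Gaussian to a Gaussian: center' = A (center - c0) + c0 + t and
    covariance' = A cov A^T.  Rendering from the transformed parameters avoids
    interpolation artifacts entirely.
    """
    h, w = shape
    c0 = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    cth, sth = np.cos(params["angle"]), np.sin(params["angle"])
    a_mat = params["scale"] * np.array([[cth, -sth], [sth, cth]])
    shift = np.array([params["dy"], params["dx"]])
    new_center = a_mat @ (center - c0) + c0 + shift
    new_cov = a_mat @ cov @ a_mat.T
    return new_center, 0.5 * (new_cov + new_cov.T)


def _elastic_field(
    rng: np.random.Generator, magnitude: float, shape: tuple[int, int], grid: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    amp = 0.02 * magnitude * min(h, w)
    coarse = rng.uniform(-amp, amp, size=(2, grid, grid))
    zoom = (h / grid, w / grid)
    dy = ndimage.zoom(coarse[0], zoom, order=3)[:h, :w]
    dx = ndimage.zoom(coarse[1], zoom, order=3)[:h, :w]
    return dy, dx


def _apply_elastic(image: np.ndarray, dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
    h, w = image.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rows + dy, cols + dx])
    return ndimage.map_coordinates(image, coords, order=1, mode="constant", cval=0.0)


def generate_experiment(
    n_axons: int,
    n_frames: int,
    size: tuple[int, int] = (64, 64),
    seed: int = 0,
    artifact_magnitude: float = 0.0,
    *,
    fps: float = 4.0,
    axons: list[AxonSpec] | None = None,
    kernel: CalciumKernel | None = None,
    spike_rate: float = 1.0,
    gcamp_amplitude: float = 0.05,
    gcamp_baseline: float = 0.0,
    tdtomato_range: tuple[float, float] = (0.5, 1.0),
    axis_range: tuple[float, float] = (1.8, 3.2),
    min_separation: float | None = None,
    margin_frac: float = 0.18,
    elastic: bool = False,
    noise: bool = True,
    gaussian_sigma: float = 0.02,
    shot_scale: float = 200.0,
    mask_cutoff: float = 0.2,
    oversample: int = 2,
) -> tuple[RecordingStack, GroundTruth]:
    """Generate a synthetic two-channel recording with full ground truth.

    Parameters
    ----------
    n_axons, n_frames : int
        Number of axons (>= 1) and frames (>= 2).
    size : (H, W)
        Frame shape in pixels.
    seed : int
        Fixes all randomness (geometry, spikes, deformation, noise) through
        independent child streams.
    artifact_magnitude : float
        Scales the per-frame random affine (at 1.0: translation within +-10 %
        of the frame, rotation within +-5 deg, scale within +-5 %).  0 turns
        deformation off entirely (frames share identical geometry).
    axons : list of AxonSpec, optional
        Explicit axon population; when given, ``n_axons`` must match and no
        geometry is sampled.  Axon centers must lie inside the frame.
    spike_rate : float
        Poisson event rate (events/s) used for sampled axons.
    gcamp_amplitude : float
        Green-channel intensity of one unit of calcium trace, on the common
        intensity scale shared with the red channel.  The default keeps
        typical GCaMP transients below the tdTomato level (the anatomical
        marker is expressed brightly and detector gains are set to avoid
        clipping), so segmentation geometry is anatomy-driven.
    gcamp_baseline : float
        Tonic calcium-trace offset (0 keeps the green channel identically
        zero in the absence of spikes).
    noise, gaussian_sigma, shot_scale :
        Noise model: Poisson shot noise at ``shot_scale`` photons per unit
        intensity followed by additive Gaussian read noise, clipped at 0.
    mask_cutoff : float
        Ground-truth mask threshold as a fraction of each axon's per-frame
        peak rendered density.

    Returns
    -------
    (RecordingStack, GroundTruth)
    """
    if n_axons < 1:
        raise ValueError("n_axons must be >= 1")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    h, w = size
    ss = np.random.SeedSequence(seed)
    rng_geom, rng_spike, rng_def, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    if axons is None:
        axons = _sample_axons(
            rng_geom, n_axons, (h, w), axis_range, tdtomato_range,
            spike_rate, margin_frac, min_separation,
        )
    else:
        if len(axons) != n_axons:
            raise ValueError("len(axons) must equal n_axons")
        for ax in axons:
            if not (0 <= ax.center[0] < h and 0 <= ax.center[1] < w):
                raise ValueError(f"axon {ax.identity} placed outside the frame")
        ids = [ax.identity for ax in axons]
        if len(set(ids)) != len(ids):
            raise ValueError("axon identities must be distinct")

    if kernel is None:
        kernel = calcium_kernel(fps=fps)

    base = np.stack(
        [_render_density(ax.center, ax.covariance, (h, w), oversample) for ax in axons]
    )

    traces = np.empty((n_axons, n_frames))
    for k, ax in enumerate(axons):
        u = rng_spike.uniform(size=n_frames)
        traces[k] = gcamp_baseline + _spike_trace(u, ax.spike_rate / fps, kernel)

    green = np.zeros((n_frames, h, w))
    red = np.zeros((n_frames, h, w))
    masks = np.zeros((n_frames, n_axons, h, w), dtype=bool)
    deformations: list[dict] = []

    for t in range(n_frames):
        if artifact_magnitude > 0:
            params = _frame_affine(rng_def, artifact_magnitude, (h, w))
            fields = (
                _elastic_field(rng_def, artifact_magnitude, (h, w))
                if elastic else None
            )
            dens_t = np.empty_like(base)
            for k, ax in enumerate(axons):
                new_center, new_cov = _transform_axon(
                    ax.center, ax.covariance, params, (h, w)
                )
                d = _render_density(new_center, new_cov, (h, w), oversample)
                if fields is not None:
                    d = _apply_elastic(d, *fields)
                dens_t[k] = d
        else:
            params = {"dy": 0.0, "dx": 0.0, "angle": 0.0, "scale": 1.0}
            dens_t = base
        deformations.append(params)
        for k, ax in enumerate(axons):
            red[t] += ax.tdtomato_level * dens_t[k]
            green[t] += gcamp_amplitude * traces[k, t] * dens_t[k]
            # density fields are unit-peak, so the cutoff is absolute
            masks[t, k] = dens_t[k] >= mask_cutoff

    if noise:
        for chan in (green, red):
            if shot_scale > 0:
                chan[:] = rng_noise.poisson(np.clip(chan, 0, None) * shot_scale) / shot_scale
            if gaussian_sigma > 0:
                chan += rng_noise.normal(0.0, gaussian_sigma, size=chan.shape)
            np.clip(chan, 0.0, None, out=chan)

    stack = RecordingStack(green=green, red=red, fps=fps)
    truth = GroundTruth(
        axons=list(axons), masks=masks, traces=traces, deformations=deformations
    )
    return stack, truth
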