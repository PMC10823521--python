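"""Denoising, scan-line flattening and lateral drift correction.

HS-AFM raw frames carry line-by-line DC offsets from the scanner and slow
lateral drift of the field of view.  The standard treatment — Gaussian
smoothing, per-line polynomial background removal, then cross-correlation
registration against a reference frame — is implemented here on calibrated
height stacks (nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import fourier_shift, gaussian_filter
from skimage.registration import phase_cross_correlation

__all__ = ["RasterStack", "DriftTrack", "flatten_lines", "denoise_flatten",
           "drift_correct"]


@dataclass
class RasterStack:
    """Calibrated height-image time series."""

    frames: np.ndarray   # (T, H, W) nm
    pixel_size: float    # nm / px
    fps: float           # frames / s

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size <= 0 or self.fps <= 0:
            raise ValueError("pixel_size and fps must be positive")

    def __len__(self):
        return self.frames.shape[0]

    @property
    def times_s(self):
        return np.arange(len(self)) / self.fps


@dataclass
class DriftTrack:
    """Per-frame (dy, dx) displacements in px relative to the reference."""

    shifts: np.ndarray
    reference_frame: int = 0

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, float)


def flatten_lines(frame, degree: int = 1, bg_percentile: float = 70.0):
    """Remove a per-scanline polynomial background.

    Background pixels are taken below the global ``bg_percentile`` height so
    that particles do not bias the fit; the fitted polynomial is subtracted
    from the whole line.  Idempotent to numerical precision.
    """
    frame = np.asarray(frame, dtype=float)
    if np.all(np.isnan(frame)):
        raise ValueError("all-NaN frame")
    x = np.arange(frame.shape[1], dtype=float)
    out = frame.copy()
    # iterate to a fixed point: the background set depends on the current
    # estimate, so a single pass is not exactly idempotent
    for _ in range(10):
        thresh = np.nanpercentile(out, bg_percentile)
        correction = 0.0
        for i, line in enumerate(out):
            bg = line <= thresh
            if bg.sum() < degree + 2:
                bg = np.ones_like(bg)
            coef = np.polyfit(x[bg], line[bg], degree)
            fit = np.polyval(coef, x)
            out[i] = line - fit
            correction = max(correction, np.abs(fit).max())
        if correction < 1e-10:
            break
    return out


def denoise_flatten(frame, sigma: float = 1.0, degree: int = 1,
                    bg_percentile: float = 70.0):
    """Gaussian smoothing followed by per-line flattening.

    After flattening the median of the background region is ~0 nm.
    """
    frame = np.asarray(frame, dtype=float)
    if np.all(np.isnan(frame)):
        raise ValueError("all-NaN frame")
    smoothed = gaussian_filter(frame, sigma) if sigma > 0 else frame
    return flatten_lines(smoothed, degree=degree, bg_percentile=bg_percentile)


def drift_correct(stack: RasterStack, reference_frame_index: int = 0,
                  upsample_factor: int = 20):
    """Align every frame to the reference by 2D cross-correlation.

    Subpixel shifts come from upsampled cross-correlation; frames are
    translated spectrally (Fourier shift) to avoid resampling blur.
    Featureless frames (zero variance) get a zero shift with a warning.
    """
    frames = stack.frames
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to drift-correct")
    ref = np.asarray(frames[reference_frame_index], float)
    shifts = np.zeros((len(frames), 2))
    aligned = np.empty_like(frames, dtype=np.float32)
    for i, frame in enumerate(frames):
        frame = np.asarray(frame, float)
        if i == reference_frame_index:
            aligned[i] = frame
            continue
        if frame.std() == 0 or ref.std() == 0:
            warnings.warn(f"frame {i} is featureless; zero shift assumed")
            aligned[i] = frame
            continue
        correction, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None)
        shifts[i] = -correction        # the frame's displacement from ref
        aligned[i] = np.real(np.fft.ifft2(
            fourier_shift(np.fft.fft2(frame), correction)))
    out = RasterStack(aligned, stack.pixel_size, stack.fps)
    return out, DriftTrack(shifts, reference_frame_index)
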