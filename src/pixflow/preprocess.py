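"""Temporal normalisation and filtering of registered image sequences.

The processing chain applied before velocimetry is, in order:

1. :func:`normalize_frame_means` — divide each frame by its mean.
2. :func:`subtract_rolling_mean` — remove a centred rolling temporal mean
   (200 ms window by default).
3. :func:`temporal_filter` — per-pixel linear detrend followed by removal of
   the lowest Fourier modes (0 < f <= 2 cycles/sequence).
4. :func:`motion_contrast` — per-pixel temporal standard deviation.
5. :func:`split_epochs` — cut the filtered sequence into overlapping
   analysis epochs (100 ms epochs stepped by 50 ms by default).

All operations preserve frame shape and the temporal/spatial calibration of
the input. Standard deviations use the population (divide-by-N) convention
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageSequence",
    "Epoch",
    "window_frames",
    "normalize_frame_means",
    "subtract_rolling_mean",
    "temporal_filter",
    "motion_contrast",
    "split_epochs",
    "preprocess_sequence",
]


@dataclass(frozen=True)
class ImageSequence:
    """A registered grayscale video with calibration.

    Parameters
    ----------
    frames
        Array of shape ``(time, rows, cols)``.
    fps
        Frame rate in frames per second.
    pixel_um
        Pixel pitch on the sample in micrometres per pixel.
    """

    frames: np.ndarray
    fps: float
    pixel_um: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, r, c), got {frames.ndim}-D")
        if frames.shape[0] < 2:
            raise ValueError("sequence needs at least 2 frames")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if not self.pixel_um > 0:
            raise ValueError("pixel_um must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_ms(self) -> float:
        return self.n_frames / self.fps * 1000.0

    def with_frames(self, frames: np.ndarray) -> "ImageSequence":
        """Same calibration, new frame data."""
        return ImageSequence(frames, self.fps, self.pixel_um)


@dataclass(frozen=True)
class Epoch:
    """One analysis window cut from a longer sequence."""

    frames: np.ndarray
    start_ms: float
    fps: float
    pixel_um: float
    duration_ms: float = field(default=0.0)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        object.__setattr__(self, "frames", frames)
        dur = frames.shape[0] / self.fps * 1000.0
        if self.duration_ms == 0.0:
            object.__setattr__(self, "duration_ms", dur)
        elif abs(self.duration_ms - dur) > 1000.0 / self.fps:
            raise ValueError("duration_ms inconsistent with frame count and fps")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def window_frames(window_ms: float, fps: float) -> int:
    """Length in frames of a temporal window, rounded to the nearest frame.

    ``window_frames(200, 300) == 60`` and ``window_frames(100, 300) == 30``.
    """
    return int(round(window_ms * fps / 1000.0))


def normalize_frame_means(seq: ImageSequence) -> ImageSequence:
    """Scale every frame to unit mean intensity.

    Raises
    ------
    ValueError
        If any frame has zero mean (no meaningful normalisation exists).
    """
    means = seq.frames.mean(axis=(1, 2))
    if np.any(means == 0):
        raise ValueError("frame with zero mean intensity")
    return seq.with_frames(seq.frames / means[:, None, None])


def subtract_rolling_mean(seq: ImageSequence, window_ms: float = 200.0) -> ImageSequence:
    """Subtract a centred rolling temporal mean from every pixel trace.

    The window spans ``round(window_ms * fps / 1000)`` frames and is centred
    on each output frame; at the sequence ends the window is truncated to the
    available frames (no padding).
    """
    n = seq.n_frames
    w = window_frames(window_ms, seq.fps)
    if w < 2:
        raise ValueError(f"rolling window of {w} frames is too short")
    if w > n:
        raise ValueError("sequence shorter than the rolling window")

    lo = (w - 1) // 2  # frames before the centre
    hi = w - 1 - lo  # frames after the centre
    flat = seq.frames.reshape(n, -1)
    csum = np.zeros((n + 1, flat.shape[1]))
    np.cumsum(flat, axis=0, out=csum[1:])
    starts = np.maximum(np.arange(n) - lo, 0)
    stops = np.minimum(np.arange(n) + hi + 1, n)
    rolling = (csum[stops] - csum[starts]) / (stops - starts)[:, None]
    return seq.with_frames((flat - rolling).reshape(seq.frames.shape))


def temporal_filter(seq: ImageSequence) -> ImageSequence:
    """Linear detrend each pixel trace, then zero Fourier modes f <= 2 cyc/seq.

    The best-fit straight line is removed from every pixel's temporal profile,
    after which the discrete Fourier coefficients at 1 and 2 cycles per
    sequence (and, implicitly, their conjugates) are zeroed. The residual DC
    bin is also cleared so every output trace has mean ~0.
    """
    n = seq.n_frames
    if n < 4:
        raise ValueError("temporal_filter needs at least 4 frames")
    flat = seq.frames.reshape(n, -1)

    t = np.arange(n, dtype=np.float64)
    t = t - t.mean()
    slope = (t @ flat) / (t @ t)
    mean = flat.mean(axis=0)
    detr = flat - mean[None, :] - t[:, None] * slope[None, :]

    spec = np.fft.rfft(detr, axis=0)
    spec[:3] = 0.0  # bins 0, 1, 2 cycles/sequence
    out = np.fft.irfft(spec, n=n, axis=0)
    return seq.with_frames(out.reshape(seq.frames.shape))


def motion_contrast(seq: ImageSequence | Epoch) -> np.ndarray:
    """Per-pixel temporal standard deviation (population convention)."""
    if seq.frames.shape[0] < 2:
        raise ValueError("motion contrast needs at least 2 frames")
    return seq.frames.std(axis=0, ddof=0)


def split_epochs(
    seq: ImageSequence, epoch_ms: float = 100.0, step_ms: float = 50.0
) -> list[Epoch]:
    """Cut a sequence into overlapping epochs.

    Epochs are ``round(epoch_ms * fps / 1000)`` frames long and start every
    ``round(step_ms * fps / 1000)`` frames; a trailing partial epoch is
    discarded.
    """
    ew = window_frames(epoch_ms, seq.fps)
    sw = window_frames(step_ms, seq.fps)
    if ew < 2 or sw < 1:
        raise ValueError("epoch or step window too short")
    if seq.n_frames < ew:
        raise ValueError(
            f"sequence of {seq.n_frames} frames is shorter than one "
            f"{ew}-frame epoch"
        )
    epochs = []
    for start in range(0, seq.n_frames - ew + 1, sw):
        epochs.append(
            Epoch(
                frames=seq.frames[start : start + ew],
                start_ms=start / seq.fps * 1000.0,
                fps=seq.fps,
                pixel_um=seq.pixel_um,
            )
        )
    return epochs


def preprocess_sequence(
    seq: ImageSequence,
    rolling_window_ms: float = 200.0,
    apply_temporal_filter: bool = True,
) -> ImageSequence:
    """Full pre-velocimetry chain: unit frame means, rolling-mean
    subtraction, temporal filter. Order is fixed.

    ``apply_temporal_filter=False`` reproduces the variant used for the
    baseline (PIV/STK) methods, which skip the detrend/Fourier step.
    """
    out = normalize_frame_means(seq)
    out = subtract_rolling_mean(out, rolling_window_ms)
    if apply_temporal_filter:
        out = temporal_filter(out)
    return out
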