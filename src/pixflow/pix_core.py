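"""Per-pixel trace-matching velocimetry.

For every reference pixel in an analysis epoch the algorithm:

1. builds the pixel's temporal intensity trace plus one-frame forward- and
   backward-shifted traces of all candidate pixels (:func:`shifted_traces`);
2. computes the RMS trace difference against every candidate
   (:func:`similarity_map`); the lowest RMS marks the likely destination
   (forward) or source (backward) of the flowing material;
3. removes static background structure by z-standardising both the
   (negated) RMS map and the epoch's temporal-standard-deviation map over
   the candidate support and subtracting them (:func:`normalize_similarity`);
4. gates the winning candidate by a physiological speed cap and a
   Bonferroni-corrected significance threshold (:func:`gate_and_match`);
5. averages the forward and backward speeds (:func:`combine_directions`).

:func:`velocity_map` runs the full chain, vectorised over all reference
pixels, and returns a :class:`VelocityField`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.stats import norm

from .preprocess import Epoch, motion_contrast
from .vesselmask import VesselSegmentation

__all__ = [
    "SimilarityMap",
    "VelocityField",
    "GateParams",
    "shifted_traces",
    "similarity_map",
    "normalize_similarity",
    "gate_and_match",
    "displacement_to_speed",
    "combine_directions",
    "velocity_map",
]

Direction = Literal["forward", "backward"]

# reference pixels whose trace standard deviation is below this carry no
# temporal information and are rejected before matching
MIN_TRACE_STD = 1e-9


@dataclass
class GateParams:
    """Physiological and statistical acceptance gates.

    ``z_threshold`` is the inverse standard-normal quantile of
    ``1 - p_one_tail / n_hypotheses`` (one-tailed Bonferroni bound over the
    candidate pixels actually compared) and is recomputed whenever
    ``n_hypotheses`` changes.
    """

    v_max: float = 4.5
    p_one_tail: float = 0.025
    n_hypotheses: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.p_one_tail < 1:
            raise ValueError("p_one_tail must lie in (0, 1)")
        if self.n_hypotheses < 1:
            raise ValueError("n_hypotheses must be >= 1")

    @property
    def z_threshold(self) -> float:
        return float(norm.ppf(1.0 - self.p_one_tail / self.n_hypotheses))

    def with_hypotheses(self, n: int) -> "GateParams":
        return GateParams(self.v_max, self.p_one_tail, n)


@dataclass
class SimilarityMap:
    """Similarity of one reference pixel's trace to all shifted candidates.

    ``rms`` holds the RMS trace difference (NaN outside the candidate
    support), ``z`` the background-normalised similarity in Z units (filled
    by :func:`normalize_similarity`). Larger ``z`` means more similar.
    """

    reference_pixel: tuple[int, int]
    direction: Direction
    rms: np.ndarray
    z: np.ndarray | None = None
    best_match: tuple[int, int] | None = None


@dataclass
class VelocityField:
    """Per-epoch speed map in mm/s; NaN marks rejected pixels."""

    speed: np.ndarray
    displacement: np.ndarray  # (rows, cols, 2): (drow, dcol) in pixels
    epoch_start_ms: float
    v_max: float
    frame_lag: int = 1
    z_threshold: float = field(default=np.nan)
    n_hypotheses: int = 0

    def __post_init__(self) -> None:
        finite = self.speed[np.isfinite(self.speed)]
        if finite.size and finite.max() > self.v_max + 1e-9:
            raise AssertionError("speed exceeds v_max")

    @property
    def n_accepted(self) -> int:
        return int(np.isfinite(self.speed).sum())


def shifted_traces(epoch: Epoch) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Original, forward-shifted and backward-shifted trace stacks.

    Returns three ``(pixels, n_frames - 1)`` arrays. Comparing
    ``original[r]`` to ``forward[q]`` aligns the reference at times
    ``0..T-2`` with candidate ``q`` at times ``1..T-1`` (candidate as
    *destination*); ``backward`` is the converse (candidate as *source*).
    The non-overlapping frame at each end is dropped so compared traces have
    equal length.
    """
    if epoch.n_frames < 3:
        raise ValueError("epoch must have at least 3 frames")
    traces = epoch.frames.reshape(epoch.n_frames, -1).T  # (P, T)
    original_fwd = traces[:, :-1]
    forward = traces[:, 1:]
    # for the backward direction the reference trace is traces[:, 1:] and
    # candidates use traces[:, :-1]; returned as (original, fwd, bwd) stacks
    return traces, forward, traces[:, :-1]


def _direction_pair(traces: np.ndarray, direction: Direction) -> tuple[np.ndarray, np.ndarray]:
    """(reference, candidate) trace stacks for one shift direction."""
    if direction == "forward":
        return traces[:, :-1], traces[:, 1:]
    if direction == "backward":
        return traces[:, 1:], traces[:, :-1]
    raise ValueError(f"unknown direction {direction!r}")


def _rms_rows(
    ref_traces: np.ndarray, cand_traces: np.ndarray, chunk: int = 1024
) -> np.ndarray:
    """RMS difference between every reference row and every candidate row.

    ``|a-b|^2 = |a|^2 + |b|^2 - 2 a.b`` evaluated blockwise via BLAS.
    Returns ``(n_ref, n_cand)``.
    """
    n_t = ref_traces.shape[1]
    cand_sq = np.einsum("ij,ij->i", cand_traces, cand_traces)
    out = np.empty((ref_traces.shape[0], cand_traces.shape[0]))
    for lo in range(0, ref_traces.shape[0], chunk):
        hi = min(lo + chunk, ref_traces.shape[0])
        block = ref_traces[lo:hi]
        sq = np.einsum("ij,ij->i", block, block)
        cross = block @ cand_traces.T
        mse = (sq[:, None] + cand_sq[None, :] - 2.0 * cross) / n_t
        np.sqrt(np.clip(mse, 0.0, None, out=mse), out=mse)
        out[lo:hi] = mse
    return out


def similarity_map(
    epoch: Epoch,
    ref_pixel: tuple[int, int],
    direction: Direction = "forward",
    candidate_support: np.ndarray | None = None,
) -> SimilarityMap:
    """RMS trace difference of one reference pixel against all candidates.

    ``candidate_support`` restricts the comparison to a binary mask (e.g. the
    vessel mask); ``None`` compares against every pixel in the frame. Pixels
    outside the support are NaN in the returned map.
    """
    rows, cols = epoch.shape
    r, c = ref_pixel
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError(f"reference pixel {ref_pixel} outside frame {epoch.shape}")
    support = _support_indices(candidate_support, (rows, cols))
    traces = epoch.frames.reshape(epoch.n_frames, -1).T
    ref_stack, cand_stack = _direction_pair(traces, direction)
    ref_idx = r * cols + c
    rms_row = _rms_rows(ref_stack[ref_idx : ref_idx + 1], cand_stack[support])[0]
    rms = np.full(rows * cols, np.nan)
    rms[support] = rms_row
    rms = rms.reshape(rows, cols)
    best_flat = support[int(np.argmin(rms_row))]
    return SimilarityMap(
        reference_pixel=(r, c),
        direction=direction,
        rms=rms,
        best_match=(best_flat // cols, best_flat % cols),
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def normalize_similarity(sim: SimilarityMap, std_map: np.ndarray) -> SimilarityMap:
    """Fill ``sim.z`` by subtracting the standardised background.

    For an uncorrelated candidate the expected squared RMS difference is the
    sum of the reference and candidate trace variances, so the background of
    the RMS map grows with each candidate's own temporal standard deviation.
    Both maps are standardised to zero mean and unit variance over the
    candidate support and the background is subtracted from the RMS map; the
    result is negated so that larger ``z`` means more similar:
    ``z = standardize(sd_map) - standardize(rms)``. Under pure noise the two
    standardised maps are positively correlated, so the difference has
    variance below one and the standard-normal significance gate is
    conservative. The best match becomes the argmax of ``z``.
    """
    valid = np.isfinite(sim.rms)
    if valid.sum() < 2:
        raise ValueError("candidate support smaller than 2 pixels")
    s = sim.rms[valid]
    b = np.asarray(std_map, dtype=np.float64)[valid]
    zvals = _standardize(b) - _standardize(s)
    z = np.full(sim.rms.shape, np.nan)
    z[valid] = zvals
    flat_support = np.flatnonzero(valid.ravel())
    best_flat = flat_support[int(np.argmax(zvals))]
    cols = sim.rms.shape[1]
    sim.z = z
    sim.best_match = (best_flat // cols, best_flat % cols)
    return sim


def displacement_to_speed(
    disp: tuple[float, float], fps: float, pixel_um: float, frame_lag: int = 1
) -> float:
    """Convert a pixel displacement per ``frame_lag`` frames to mm/s."""
    if frame_lag < 1:
        raise ValueError("frame_lag must be >= 1")
    drow, dcol = disp
    return float(np.hypot(drow, dcol) * pixel_um * fps / frame_lag / 1000.0)


def gate_and_match(
    sim: SimilarityMap,
    gate: GateParams,
    fps: float,
    pixel_um: float,
    frame_lag: int = 1,
) -> tuple[int, int] | None:
    """Pick the global best candidate and gate it; ``None`` means rejected.

    The winner is the argmax of ``z`` over the *entire* candidate support
    (deliberately not restricted to the physiologically plausible radius, so
    that noisy pixels whose spurious best correlate lies far away are
    rejected). Rejection occurs when the implied speed exceeds ``v_max`` or
    the peak ``z`` falls below the Bonferroni threshold. Exact ``z`` ties are
    broken by smaller displacement, then row-major candidate order.
    """
    if sim.z is None:
        raise ValueError("similarity map has no z values; normalize first")
    valid = np.isfinite(sim.z)
    zvals = sim.z[valid]
    flat_support = np.flatnonzero(valid.ravel())
    cols = sim.z.shape[1]
    zmax = zvals.max()
    ties = np.flatnonzero(zvals == zmax)
    r0, c0 = sim.reference_pixel
    if len(ties) == 1:
        best_flat = flat_support[ties[0]]
    else:
        cand = flat_support[ties]
        d2 = (cand // cols - r0) ** 2 + (cand % cols - c0) ** 2
        best_flat = cand[np.lexsort((cand, d2))[0]]
    drow = int(best_flat // cols - r0)
    dcol = int(best_flat % cols - c0)
    if displacement_to_speed((drow, dcol), fps, pixel_um, frame_lag) > gate.v_max:
        return None
    if zmax < gate.z_threshold:
        return None
    return drow, dcol


def combine_directions(
    v_fwd: float | None,
    v_bwd: float | None,
    z_fwd: float = np.nan,
    z_bwd: float = np.nan,
    mode: Literal["mean", "best"] = "mean",
) -> float | None:
    """Merge forward and backward speed estimates for one pixel.

    ``mean`` averages when both are valid and falls back to the surviving one
    otherwise; ``best`` keeps the direction with the higher peak ``z``.
    ``None`` marks a rejected estimate.
    """
    if v_fwd is None and v_bwd is None:
        return None
    if v_fwd is None:
        return v_bwd
    if v_bwd is None:
        return v_fwd
    if mode == "mean":
        return 0.5 * (v_fwd + v_bwd)
    if mode == "best":
        return v_fwd if z_fwd >= z_bwd else v_bwd
    raise ValueError(f"unknown combine mode {mode!r}")


def _support_indices(
    mask: np.ndarray | None, shape: tuple[int, int]
) -> np.ndarray:
    if mask is None:
        return np.arange(shape[0] * shape[1])
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("candidate support shape mismatch")
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        raise ValueError("candidate support is empty")
    return idx


def _match_direction(
    traces: np.ndarray,
    support: np.ndarray,
    std_vals_std: np.ndarray,
    direction: Direction,
    shape: tuple[int, int],
    gate: GateParams,
    fps: float,
    pixel_um: float,
    active: np.ndarray,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised gate_and_match for every active reference pixel.

    Returns per-reference speed (NaN = rejected), displacement and peak z.
    ``std_vals_std`` is the standardised temporal-SD map over the support.
    """
    rows, cols = shape
    ref_stack, cand_stack = _direction_pair(traces, direction)
    refs = support[active]
    cand = cand_stack[support]
    n = refs.size
    speed = np.full(n, np.nan)
    disp = np.zeros((n, 2), dtype=np.int32)
    peak_z = np.full(n, np.nan)
    cand_rows = support // cols
    cand_cols = support % cols
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        block_refs = refs[lo:hi]
        rms = _rms_rows(ref_stack[block_refs], cand, chunk=chunk)
        mu = rms.mean(axis=1, keepdims=True)
        sd = rms.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = np.inf
        z = std_vals_std[None, :] - (rms - mu) / sd
        best = np.argmax(z, axis=1)
        zmax = z[np.arange(hi - lo), best]
        # exact ties: smaller displacement, then row-major order
        tie_rows = np.flatnonzero((z == zmax[:, None]).sum(axis=1) > 1)
        for i in tie_rows:
            r0, c0 = divmod(block_refs[i], cols)
            t = np.flatnonzero(z[i] == zmax[i])
            d2 = (cand_rows[t] - r0) ** 2 + (cand_cols[t] - c0) ** 2
            best[i] = t[np.lexsort((support[t], d2))[0]]
        drow = cand_rows[best] - block_refs // cols
        dcol = cand_cols[best] - block_refs % cols
        v = np.hypot(drow, dcol) * pixel_um * fps / 1000.0
        ok = (v <= gate.v_max) & (zmax >= gate.z_threshold)
        speed[lo:hi] = np.where(ok, v, np.nan)
        disp[lo:hi, 0] = np.where(ok, drow, 0)
        disp[lo:hi, 1] = np.where(ok, dcol, 0)
        peak_z[lo:hi] = zmax
    return speed, disp, peak_z


def velocity_map(
    epoch: Epoch,
    segmentation: VesselSegmentation | np.ndarray | None = None,
    gate: GateParams | None = None,
    combine: Literal["mean", "best"] = "mean",
    min_trace_std: float = MIN_TRACE_STD,
) -> VelocityField:
    """Full per-pixel velocimetry for one epoch.

    ``segmentation`` may be a :class:`~pixflow.vesselmask.VesselSegmentation`
    (its binary mask is used), a binary mask array, or ``None`` to process
    every pixel. Reference pixels and candidate pixels use the same support.
    Rejected pixels are NaN in the returned speed map.
    """
    if gate is None:
        gate = GateParams()
    rows, cols = epoch.shape
    if isinstance(segmentation, VesselSegmentation):
        mask = segmentation.mask
    else:
        mask = segmentation
    support = _support_indices(mask, (rows, cols))
    gate = gate.with_hypotheses(support.size)

    traces = epoch.frames.reshape(epoch.n_frames, -1).T
    std_map = motion_contrast(epoch).ravel()
    std_vals_std = _standardize(std_map[support])

    # references with ~zero trace variance carry no information
    active = traces[support].std(axis=1, ddof=0) > min_trace_std

    shape = (rows, cols)
    sf, df, zf = _match_direction(
        traces, support, std_vals_std, "forward", shape, gate, epoch.fps, epoch.pixel_um, active
    )
    sb, db, zb = _match_direction(
        traces, support, std_vals_std, "backward", shape, gate, epoch.fps, epoch.pixel_um, active
    )

    both = np.isfinite(sf) & np.isfinite(sb)
    if combine == "mean":
        merged = np.where(both, 0.5 * (sf + sb), np.where(np.isfinite(sf), sf, sb))
    elif combine == "best":
        pick_f = np.where(both, zf >= zb, np.isfinite(sf))
        merged = np.where(pick_f, sf, sb)
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    merged_disp = np.where(
        (np.isfinite(sf) & ((zf >= zb) | ~np.isfinite(sb)))[:, None], df, db
    )

    speed = np.full(rows * cols, np.nan)
    refs = support[active]
    speed[refs] = merged
    displacement = np.zeros((rows * cols, 2), dtype=np.int32)
    displacement[refs] = merged_disp
    return VelocityField(
        speed=speed.reshape(rows, cols),
        displacement=displacement.reshape(rows, cols, 2),
        epoch_start_ms=epoch.start_ms,
        v_max=gate.v_max,
        frame_lag=1,
        z_threshold=gate.z_threshold,
        n_hypotheses=gate.n_hypotheses,
    )
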