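"""Simplified reference velocimetry baselines.

``piv_map`` is a block-wise particle image velocimetry: per ROI centre on a
grid, normalised 2-D cross-correlation between successive frame pairs (small
template in frame t, larger search window in frame t+1), with tiered search
sizes and velocity caps, and a per-epoch median over the surviving frame
pairs.

``stk_segment_velocity`` is a spatiotemporal kymograph: intensity sampled
along a segment's ordered skeleton per frame forms a space-time plot whose
streak slope is the speed. Three plot variants (raw, spatial correlogram,
temporal correlogram) are computed and the highest-contrast one is used;
the slope is estimated by an orientation sweep maximising projected
variance.

Both are deliberate simplifications of the fuller published methods: the
PIV validity tiers reduce to accept-in-tier-else-escalate, and the
kymograph slope estimator is a plain angle sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .pix_core import VelocityField
from .preprocess import Epoch
from .vesselmask import VesselSegmentation

__all__ = ["PivParams", "StkPlot", "piv_map", "stk_segment_velocity", "stk_map"]


@dataclass(frozen=True)
class PivParams:
    """ROI geometry and velocity validity tiers (sizes in micrometres)."""

    roi_small_um: float = 12.0
    roi_large_um: tuple[float, ...] = (18.0, 30.0, 36.0)
    roi_step_um: float = 6.0
    v_min: float = 0.3
    v_max_tiers: tuple[float, ...] = (2.25, 3.75, 4.5)

    def __post_init__(self) -> None:
        if self.roi_small_um <= 0 or self.roi_step_um <= 0:
            raise ValueError("ROI sizes must be positive")
        if len(self.roi_large_um) != len(self.v_max_tiers):
            raise ValueError("one velocity cap per large-ROI tier")
        if any(self.v_min >= v for v in self.v_max_tiers):
            raise ValueError("v_min must be below every tier cap")


@dataclass
class StkPlot:
    """Space-time intensity plot along one vessel segment."""

    positions_um: np.ndarray  # uniform arc-length samples
    times: np.ndarray  # frame indices
    intensity: np.ndarray  # (positions, times)
    chosen_variant: Literal["raw", "spatial_correlogram", "temporal_correlogram"] = "raw"
    slope_um_per_ms: float = field(default=np.nan)


def _tier_estimate(
    small: np.ndarray, search: np.ndarray, params, tier: int, fps, pixel_um
) -> float | None:
    """Speed from one frame pair at one tier; None when out of range."""
    if search.shape[0] <= small.shape[0] or search.shape[1] <= small.shape[1]:
        return None
    if small.std() == 0 or search.std() == 0:
        return None
    cc = match_template(search, small, pad_input=False)
    peak = np.unravel_index(np.argmax(cc), cc.shape)
    centre = ((search.shape[0] - small.shape[0]) // 2, (search.shape[1] - small.shape[1]) // 2)
    drow = peak[0] - centre[0]
    dcol = peak[1] - centre[1]
    speed = float(np.hypot(drow, dcol)) * pixel_um * fps / 1000.0
    if params.v_min <= speed <= params.v_max_tiers[tier]:
        return speed
    return None


def piv_map(
    epoch: Epoch,
    mask: np.ndarray | VesselSegmentation,
    params: PivParams = PivParams(),
) -> VelocityField:
    """Tiered block cross-correlation velocimetry for one epoch.

    ROI centres lie on a grid of spacing ``roi_step_um``; centres whose small
    ROI misses the binary mask are skipped. Per frame pair the smallest tier
    whose speed estimate falls inside its validity range wins; the per-ROI
    epoch estimate is the median of surviving pair estimates, painted over
    the ROI's grid cell (within the mask). NaN where nothing survives.
    """
    if isinstance(mask, VesselSegmentation):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    rows, cols = epoch.shape
    px = epoch.pixel_um
    step = max(1, int(round(params.roi_step_um / px)))
    small_half = max(1, int(round(params.roi_small_um / px / 2)))
    large_halves = [max(sh + 1, int(round(u / px / 2))) for sh, u in
                    ((small_half, u) for u in params.roi_large_um)]

    speed = np.full((rows, cols), np.nan)
    frames = epoch.frames
    for r0 in range(small_half, rows - small_half, step):
        for c0 in range(small_half, cols - small_half, step):
            roi_mask = mask[r0 - small_half : r0 + small_half + 1,
                            c0 - small_half : c0 + small_half + 1]
            if not roi_mask.any():
                continue
            estimates = []
            for k in range(epoch.n_frames - 1):
                small = frames[k, r0 - small_half : r0 + small_half + 1,
                               c0 - small_half : c0 + small_half + 1]
                est = None
                for tier, lh in enumerate(large_halves):
                    # require the full search window so the zero-lag position
                    # stays centred
                    if r0 - lh < 0 or r0 + lh + 1 > rows or c0 - lh < 0 or c0 + lh + 1 > cols:
                        continue
                    search = frames[k + 1, r0 - lh : r0 + lh + 1, c0 - lh : c0 + lh + 1]
                    est = _tier_estimate(
                        small, search, params, tier, epoch.fps, px
                    )
                    if est is not None:
                        break
                if est is not None:
                    estimates.append(est)
            if estimates:
                half_step = step // 2
                r_lo, r_hi = max(0, r0 - half_step), min(rows, r0 + half_step + 1)
                c_lo, c_hi = max(0, c0 - half_step), min(cols, c0 + half_step + 1)
                block = np.s_[r_lo:r_hi, c_lo:c_hi]
                val = float(np.median(estimates))
                cell = mask[block]
                out = speed[block]
                out[cell] = val
                speed[block] = out
    return VelocityField(
        speed=speed,
        displacement=np.zeros((rows, cols, 2), dtype=np.int32),
        epoch_start_ms=epoch.start_ms,
        v_max=max(params.v_max_tiers),
        frame_lag=1,
    )


def _ordered_skeleton_path(piece: np.ndarray) -> np.ndarray:
    """Order the pixels of a thin branch-free skeleton piece into a path."""
    pts = np.argwhere(piece)
    if len(pts) < 2:
        return pts
    pixset = {tuple(p) for p in pts}
    neigh = {}
    for p in pixset:
        nb = [
            (p[0] + dr, p[1] + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0) and (p[0] + dr, p[1] + dc) in pixset
        ]
        neigh[p] = nb
    ends = [p for p, nb in neigh.items() if len(nb) == 1]
    start = min(ends) if ends else min(pixset)
    path = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [q for q in neigh[cur] if q not in seen]
        if not nxt:
            break
        # prefer axial continuation for stable arc spacing
        nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        cur = nxt[0]
        path.append(cur)
        seen.add(cur)
    return np.asarray(path)


def _correlogram(plot: np.ndarray, axis: Literal["spatial", "temporal"]) -> np.ndarray:
    """Cross-correlate the mean-subtracted plot with its central row/column.

    The spatial variant correlates the central position's time trace against
    all positions at all temporal lags; the temporal variant correlates the
    central frame's spatial profile against all frames at all spatial lags.
    Streak orientation is preserved in both.
    """
    p = plot - plot.mean()
    if axis == "spatial":
        kernel = p[p.shape[0] // 2 : p.shape[0] // 2 + 1, :]
    else:
        kernel = p[:, p.shape[1] // 2 : p.shape[1] // 2 + 1]
    from scipy.signal import correlate

    return correlate(p, kernel, mode="same")


def _slope_by_orientation_sweep(
    plot: np.ndarray, angle_step_deg: float = 0.5
) -> float | None:
    """Streak slope (array rows per column) maximising projected variance.

    The plot is rotated over a sweep of angles; at each angle the variance of
    the profile obtained by summing along rows is recorded. When the rotation
    aligns streaks with the rows, that variance is maximal. Returns None when
    no orientation dominates (temporally constant plot).
    """
    p = plot - plot.mean()
    if p.std() == 0:
        return None
    angles = np.arange(-89.5, 90.0, angle_step_deg)
    best_var = -np.inf
    best_angle = None
    for a in angles:
        rot = ndimage.rotate(p, a, reshape=True, order=1, mode="constant", cval=0.0)
        prof = rot.sum(axis=1)
        v = prof.var()
        if v > best_var:
            best_var = v
            best_angle = a
    if best_angle is None:
        return None
    return float(np.tan(np.deg2rad(best_angle)))


def stk_segment_velocity(
    epoch: Epoch,
    segmentation: VesselSegmentation,
    label: int,
    v_max: float = 4.5,
    angle_step_deg: float = 0.5,
    return_plot: bool = False,
) -> float | StkPlot | None:
    """Kymograph speed (mm/s) for one labeled segment; None when rejected.

    Intensity is sampled along the segment's ordered skeleton (resampled to
    uniform ``pixel_um`` arc spacing) for every epoch frame. Of the raw plot
    and its two correlogram variants, the one with the largest standard
    deviation (highest contrast) supplies the slope. Speeds above ``v_max``
    or plots with no dominant orientation are rejected.
    """
    piece = segmentation.labels == label
    skel_piece = segmentation.skeleton & piece
    path = _ordered_skeleton_path(skel_piece)
    if len(path) < 3:
        raise ValueError(f"segment {label} skeleton has fewer than 3 samples")
    px = segmentation.pixel_um
    steps = np.hypot(*np.diff(path.astype(float), axis=0).T) * px
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    uniform = np.arange(0.0, arc[-1] + 1e-9, px)
    r = np.interp(uniform, arc, path[:, 0])
    c = np.interp(uniform, arc, path[:, 1])

    n_t = epoch.n_frames
    plot = np.empty((uniform.size, n_t))
    for k in range(n_t):
        plot[:, k] = ndimage.map_coordinates(
            epoch.frames[k], [r, c], order=1, mode="nearest"
        )

    # a temporally constant plot has no streaks to orient on
    if (plot - plot.mean(axis=1, keepdims=True)).std() < 1e-12:
        if return_plot:
            return StkPlot(positions_um=uniform, times=np.arange(n_t), intensity=plot)
        return None

    variants = {
        "raw": plot - plot.mean(),
        "spatial_correlogram": _correlogram(plot, "spatial"),
        "temporal_correlogram": _correlogram(plot, "temporal"),
    }
    chosen = max(variants, key=lambda k: variants[k].std())
    slope_rows_per_col = _slope_by_orientation_sweep(
        variants[chosen], angle_step_deg=angle_step_deg
    )
    result = StkPlot(
        positions_um=uniform,
        times=np.arange(n_t),
        intensity=plot,
        chosen_variant=chosen,  # type: ignore[arg-type]
    )
    if slope_rows_per_col is None:
        return result if return_plot else None
    # rows are pixel_um of arc per sample; columns are 1000/fps ms per frame
    dt_ms = 1000.0 / epoch.fps
    speed = abs(slope_rows_per_col) * px / dt_ms  # um/ms == mm/s
    result.slope_um_per_ms = speed
    if return_plot:
        return result
    if speed > v_max:
        return None
    return float(speed)


def stk_map(
    epoch: Epoch, segmentation: VesselSegmentation, v_max: float = 4.5
) -> VelocityField:
    """Per-segment kymograph speeds painted over the label supports."""
    speed = np.full(epoch.shape, np.nan)
    for label in segmentation.label_ids():
        try:
            v = stk_segment_velocity(epoch, segmentation, label, v_max=v_max)
        except ValueError:
            continue
        if v is not None:
            speed[segmentation.labels == label] = v
    return VelocityField(
        speed=speed,
        displacement=np.zeros(epoch.shape + (2,), dtype=np.int32),
        epoch_start_ms=epoch.start_ms,
        v_max=v_max,
        frame_lag=1,
    )
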