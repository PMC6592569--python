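"""Segment-wise filling, per-segment traces and network flow statistics.

All statistics operate on *raw* (unfilled) velocity fields; segment filling
exists purely as a rendering aid. Transit times are in milliseconds
(segment length in micrometres divided by speed in mm/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .pix_core import VelocityField
from .vesselmask import VesselSegmentation

__all__ = [
    "SegmentTrace",
    "FlowStats",
    "fill_segments",
    "segment_traces",
    "pulsatility_index",
    "goodness_of_fit",
    "field_average_correlation",
    "ctt_analysis",
]


@dataclass
class SegmentTrace:
    """Per-epoch mean speed of one labeled vessel segment."""

    label: int
    epoch_starts_ms: np.ndarray
    speeds: np.ndarray  # mm/s, NaN where no pixel survived
    length_um: float

    def __post_init__(self) -> None:
        self.epoch_starts_ms = np.asarray(self.epoch_starts_ms, dtype=np.float64)
        self.speeds = np.asarray(self.speeds, dtype=np.float64)
        if self.speeds.shape != self.epoch_starts_ms.shape:
            raise ValueError("speeds and epoch_starts_ms lengths differ")
        if not self.length_um > 0:
            raise ValueError("length_um must be positive")


@dataclass
class FlowStats:
    """Summary statistics of one segment trace."""

    AV: float  # mean speed, mm/s
    PI: float  # (max - min) / mean
    R2: float | None = None  # vs a reference trace, when available
    RMS_resid: float | None = None  # mm/s


def fill_segments(
    field: VelocityField,
    segmentation: VesselSegmentation,
    radius_um: float = 5.0,
) -> VelocityField:
    """Median filling within each labeled segment (render aid only).

    Every labeled pixel is replaced by the median of the valid same-label
    pixels lying within ``radius_um`` of the *closest valid* same-label
    pixel; segments with no valid pixel stay NaN. Values never cross label
    boundaries.
    """
    if field.speed.shape != segmentation.labels.shape:
        raise ValueError("field and segmentation shapes differ")
    px = segmentation.pixel_um
    radius_px = radius_um / px
    out = np.full_like(field.speed, np.nan)
    for label in segmentation.label_ids():
        support = segmentation.labels == label
        valid = support & np.isfinite(field.speed)
        if not valid.any():
            continue
        # nearest valid pixel for every support pixel
        _, (nr, nc) = ndimage.distance_transform_edt(~valid, return_indices=True)
        vcoords = np.argwhere(valid)
        vvalues = field.speed[valid]
        tree = cKDTree(vcoords)
        scoords = np.argwhere(support)
        anchors = np.stack([nr[support], nc[support]], axis=1)
        for (r, c), anchor in zip(scoords, anchors):
            idx = tree.query_ball_point(anchor, radius_px)
            out[r, c] = np.median(vvalues[idx])
    return VelocityField(
        speed=out,
        displacement=field.displacement,
        epoch_start_ms=field.epoch_start_ms,
        v_max=field.v_max,
        frame_lag=field.frame_lag,
        z_threshold=field.z_threshold,
        n_hypotheses=field.n_hypotheses,
    )


def segment_traces(
    fields: list[VelocityField], segmentation: VesselSegmentation
) -> list[SegmentTrace]:
    """Mean raw speed per label per epoch (NaN when nothing survived)."""
    starts = np.array([f.epoch_start_ms for f in fields])
    traces = []
    for label in segmentation.label_ids():
        support = segmentation.labels == label
        speeds = np.full(len(fields), np.nan)
        for i, f in enumerate(fields):
            vals = f.speed[support]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                speeds[i] = vals.mean()
        traces.append(
            SegmentTrace(
                label=label,
                epoch_starts_ms=starts,
                speeds=speeds,
                length_um=segmentation.segment_lengths[label],
            )
        )
    return traces


def pulsatility_index(speeds: np.ndarray) -> float:
    """(max - min) / mean over the non-NaN entries of a speed trace."""
    v = np.asarray(speeds, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no valid entries in trace")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("nonpositive mean speed")
    return float((v.max() - v.min()) / mean)


def goodness_of_fit(
    trace: np.ndarray, reference: np.ndarray
) -> tuple[float, float]:
    """R^2 (squared Pearson correlation) and RMS of direct residuals.

    NaN pairs are dropped; at least 3 complete pairs are required. The RMS
    residual is computed on raw differences, not on fit residuals.
    """
    a = np.asarray(trace, dtype=np.float64)
    b = np.asarray(reference, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("traces differ in length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete pairs")
    a, b = a[ok], b[ok]
    rms = float(np.sqrt(np.mean((a - b) ** 2)))
    if a.std() == 0 or b.std() == 0:
        return 0.0, rms
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2), rms


def field_average_correlation(traces: list[SegmentTrace]) -> dict[int, float]:
    """Squared correlation of each segment to the field-average trace.

    The field model is the per-epoch NaN-aware mean across all segments.
    Constant (zero-variance) segments get R^2 = 0 with a warning.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 segments")
    stack = np.stack([t.speeds for t in traces])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = np.nanmean(stack, axis=0)
    if np.nanstd(model) == 0:
        raise ValueError("degenerate (constant) field model")
    out = {}
    for t in traces:
        ok = np.isfinite(t.speeds) & np.isfinite(model)
        if ok.sum() < 3 or t.speeds[ok].std() == 0:
            warnings.warn(f"segment {t.label}: degenerate trace, R^2 set to 0")
            out[t.label] = 0.0
            continue
        r = np.corrcoef(t.speeds[ok], model[ok])[0, 1]
        out[t.label] = float(r**2)
    return out


def ctt_analysis(
    traces: list[SegmentTrace], min_segments: int = 2
) -> dict:
    """Capillary transit time statistics per epoch plus the CTTH-CTT line.

    Per epoch, each segment's transit time is ``length_um / speed_mm_s``
    (milliseconds); CTT is the mean and CTTH the (population) standard
    deviation across segments. A least-squares line ``CTTH = m * CTT + b``
    is fitted across epochs along with its R^2. Zero or negative speeds are
    excluded with a warning; epochs with fewer than ``min_segments`` valid
    segments yield NaN.
    """
    if not traces:
        raise ValueError("no traces")
    n_epochs = traces[0].speeds.size
    ctt = np.full(n_epochs, np.nan)
    ctth = np.full(n_epochs, np.nan)
    warned = False
    for e in range(n_epochs):
        tt = []
        for t in traces:
            v = t.speeds[e]
            if not np.isfinite(v):
                continue
            if v <= 0:
                if not warned:
                    warnings.warn("nonpositive speed excluded from CTT")
                    warned = True
                continue
            tt.append(t.length_um / v)  # um / (mm/s) = ms
        if len(tt) >= min_segments:
            tt = np.asarray(tt)
            ctt[e] = tt.mean()
            ctth[e] = tt.std(ddof=0)
    ok = np.isfinite(ctt) & np.isfinite(ctth)
    result = {
        "epoch_starts_ms": traces[0].epoch_starts_ms,
        "ctt_ms": ctt,
        "ctth_ms": ctth,
        "slope": np.nan,
        "intercept": np.nan,
        "r2": np.nan,
    }
    if ok.sum() >= 2 and ctt[ok].std() > 0:
        m, b = np.polyfit(ctt[ok], ctth[ok], 1)
        pred = m * ctt[ok] + b
        ss_res = np.sum((ctth[ok] - pred) ** 2)
        ss_tot = np.sum((ctth[ok] - ctth[ok].mean()) ** 2)
        result["slope"] = float(m)
        result["intercept"] = float(b)
        result["r2"] = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else np.nan
    elif ok.sum() >= 2:
        warnings.warn("zero CTT variance across epochs: slope undefined")
    return result
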