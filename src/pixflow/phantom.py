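"""Synthetic capillary-flow phantoms with known ground truth.

A phantom is a tube network carrying single-file trains of dark,
Gaussian-profiled cells over a textured static background. Cell diameters,
contrasts and plasma gaps are drawn per cell from configurable
distributions: trains with nonzero coefficients of variation carry the
persistent intensity signature that trace-matching velocimetry relies on,
while the degenerate cv = 0 train (identical, evenly spaced cells) is a
documented stress case that defeats it.

Build order: :func:`build_network` (geometry) -> :func:`simulate_cells`
(kinematics) -> :func:`render_sequence` (appearance + ground truth), or the
one-call convenience :func:`generate_phantom`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .preprocess import ImageSequence, window_frames

__all__ = [
    "VesselSpec",
    "WaveformSpec",
    "VesselGeometry",
    "NetworkGeometry",
    "CellTrain",
    "NoiseSpec",
    "PhantomTruth",
    "build_network",
    "simulate_cells",
    "render_sequence",
    "generate_phantom",
]

# background texture correlation length on the sample (photoreceptor mosaic
# scale); an artifact choice, exposed for override
BACKGROUND_CORR_UM = 4.0
# brightness added by plasma inside the tube relative to unit background
PLASMA_GAIN = 0.15
# intensity dip of a unit-contrast cell
CELL_GAIN = 0.35


@dataclass(frozen=True)
class VesselSpec:
    """Geometry and cell-train statistics for one vessel."""

    centerline: tuple[tuple[float, float], ...]  # (row, col) pixel coords
    width_um: float = 8.0
    cell_mean_diam_um: float = 4.0
    cell_diam_cv: float = 0.2
    cell_contrast_cv: float = 0.35
    mean_gap_um: float = 4.0
    gap_cv: float = 0.5
    # per-cell radial offset SD as a fraction of the tube radius; off-axis
    # cells give the train a cross-tube signature
    lateral_sd_frac: float = 0.45

    def __post_init__(self) -> None:
        pts = tuple((float(r), float(c)) for r, c in self.centerline)
        if len(pts) < 2:
            raise ValueError("centerline needs at least 2 points")
        if not self.width_um > 0:
            raise ValueError("width_um must be positive")
        if not self.mean_gap_um > 0:
            raise ValueError("mean_gap_um must be positive")
        for name in ("cell_diam_cv", "cell_contrast_cv", "gap_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "centerline", pts)


@dataclass(frozen=True)
class WaveformSpec:
    """Pulsatile plug-flow velocity waveform.

    ``v(t) = mean_velocity * (1 + pulsatility_depth * sin(2 pi t / period
    + phase))``, optionally scaled by ``(1 - depth)`` during a transient
    interval (emulating a white-blood-cell stall).
    """

    mean_velocity: float  # mm/s
    pulsatility_depth: float = 0.0
    period: float = 1.0  # s
    phase: float = 0.0  # radians
    transient: tuple[float, float, float] | None = None  # (start s, duration s, depth)

    def __post_init__(self) -> None:
        if self.mean_velocity < 0:
            raise ValueError("mean_velocity must be >= 0")
        if not 0 <= self.pulsatility_depth < 1:
            raise ValueError("pulsatility_depth must lie in [0, 1)")
        if not self.period > 0:
            raise ValueError("period must be positive")
        if self.transient is not None and self.transient[2] > 1:
            raise ValueError("transient depth > 1 implies negative velocity")

    def velocity(self, t: np.ndarray | float) -> np.ndarray:
        """Speed in mm/s at time ``t`` seconds."""
        t = np.asarray(t, dtype=np.float64)
        v = self.mean_velocity * (
            1.0 + self.pulsatility_depth * np.sin(2.0 * np.pi * t / self.period + self.phase)
        )
        if self.transient is not None:
            start, dur, depth = self.transient
            v = np.where((t >= start) & (t < start + dur), v * (1.0 - depth), v)
        return v

    @property
    def max_velocity(self) -> float:
        return self.mean_velocity * (1.0 + self.pulsatility_depth)

    def displacement_per_frame(self, n_frames: int, fps: float) -> np.ndarray:
        """Cumulative displacement (um) at each frame time, midpoint rule."""
        dt = 1.0 / fps
        mids = (np.arange(n_frames - 1) + 0.5) * dt
        steps = self.velocity(mids) * dt * 1000.0  # mm/s * s -> mm -> um
        return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class VesselGeometry:
    """Rasterizable vessel: densely resampled centerline + arc lengths."""

    spec: VesselSpec
    points: np.ndarray  # (n, 2) float pixel coords along the centerline
    arc_px: np.ndarray  # cumulative arc length, pixels
    pixel_um: float

    @property
    def length_px(self) -> float:
        return float(self.arc_px[-1])

    @property
    def length_um(self) -> float:
        return self.length_px * self.pixel_um

    def point_at_um(self, s_um: np.ndarray) -> np.ndarray:
        """Interpolate (row, col) at arc positions in micrometres."""
        s_px = np.asarray(s_um) / self.pixel_um
        r = np.interp(s_px, self.arc_px, self.points[:, 0])
        c = np.interp(s_px, self.arc_px, self.points[:, 1])
        return np.stack([r, c], axis=-1)

    def normal_at_um(self, s_um: np.ndarray) -> np.ndarray:
        """Unit normal to the centerline at arc positions in micrometres."""
        s_px = np.asarray(s_um, dtype=np.float64) / self.pixel_um
        eps = 0.5
        ahead = self.point_at_um((s_px + eps) * self.pixel_um)
        behind = self.point_at_um((s_px - eps) * self.pixel_um)
        tang = ahead - behind
        norm = np.linalg.norm(tang, axis=-1, keepdims=True)
        norm[norm == 0] = 1.0
        tang /= norm
        return np.stack([-tang[..., 1], tang[..., 0]], axis=-1)


@dataclass
class NetworkGeometry:
    vessels: list[VesselGeometry]
    field_size: tuple[int, int]
    pixel_um: float
    junctions: list[tuple[float, float]] = field(default_factory=list)

    def tube_masks(self) -> list[np.ndarray]:
        """Per-vessel boolean masks of pixels within width/2 of the centerline."""
        rows, cols = self.field_size
        rr, cc = np.mgrid[0:rows, 0:cols]
        grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
        masks = []
        for ves in self.vessels:
            tree = cKDTree(ves.points)
            d, _ = tree.query(grid)
            radius_px = ves.spec.width_um / 2.0 / self.pixel_um
            masks.append((d <= radius_px).reshape(rows, cols))
        return masks


@dataclass
class CellTrain:
    """Cells of one vessel: entry arc offsets plus per-cell draws."""

    s0_um: np.ndarray  # initial arc position of each cell centre, um
    diam_um: np.ndarray
    contrast: np.ndarray  # relative contrast draw, mean 1
    offset_um: np.ndarray  # radial offset from the centerline per cell
    displacement_um: np.ndarray  # cumulative plug-flow displacement per frame
    waveform: WaveformSpec

    def positions_at(self, frame: int) -> np.ndarray:
        return self.s0_um + self.displacement_um[frame]


@dataclass(frozen=True)
class NoiseSpec:
    background_texture_amplitude: float = 0.0
    photon_noise_sd: float = 0.0
    bleach_drift_per_s: float = 0.0


@dataclass
class PhantomTruth:
    """Rendered sequence plus ground truth for parameter-recovery tests."""

    sequence: ImageSequence
    truth_speed_maps: np.ndarray  # (epochs, rows, cols) mm/s, NaN off-vessel
    truth_traces: np.ndarray  # (vessels, epochs) mm/s at epoch midpoints
    epoch_starts_ms: np.ndarray
    mask: np.ndarray
    seed: int
    max_speed: float

    def __post_init__(self) -> None:
        if self.truth_speed_maps.shape[1:] != self.sequence.shape:
            raise ValueError("truth map shape differs from sequence shape")
        on = self.truth_speed_maps[np.isfinite(self.truth_speed_maps)]
        if on.size and on.max() > self.max_speed + 1e-9:
            raise ValueError("truth speed exceeds programmed maximum")


def build_network(
    specs: list[VesselSpec],
    field_size: tuple[int, int],
    pixel_um: float = 1.0,
) -> NetworkGeometry:
    """Rasterise centerlines and parameterise each vessel by arc length.

    Arc length is the summed Euclidean step length of the polyline, resampled
    densely (4 samples/pixel) for smooth interpolation. Endpoints shared by
    two or more vessels are recorded as junctions. Deterministic given the
    specs.
    """
    if not specs:
        raise ValueError("empty vessel spec list")
    rows, cols = field_size
    vessels = []
    endpoints: list[tuple[float, float]] = []
    for spec in specs:
        pts = np.asarray(spec.centerline, dtype=np.float64)
        steps = np.hypot(*np.diff(pts, axis=0).T)
        if steps.sum() == 0:
            raise ValueError("degenerate centerline of zero length")
        if np.any(pts[:, 0] < 0) or np.any(pts[:, 1] < 0) or np.any(
            pts[:, 0] >= rows
        ) or np.any(pts[:, 1] >= cols):
            raise ValueError("centerline point outside field")
        arc = np.concatenate([[0.0], np.cumsum(steps)])
        fine = np.linspace(0.0, arc[-1], max(2, int(np.ceil(arc[-1] * 4)) + 1))
        fine_pts = np.stack(
            [np.interp(fine, arc, pts[:, 0]), np.interp(fine, arc, pts[:, 1])], axis=1
        )
        vessels.append(
            VesselGeometry(spec=spec, points=fine_pts, arc_px=fine, pixel_um=pixel_um)
        )
        endpoints.extend([tuple(pts[0]), tuple(pts[-1])])

    junctions = []
    for i, p in enumerate(endpoints):
        for q in endpoints[:i]:
            if np.hypot(p[0] - q[0], p[1] - q[1]) < 1e-9 and p not in junctions:
                junctions.append(p)
    return NetworkGeometry(
        vessels=vessels, field_size=field_size, pixel_um=pixel_um, junctions=junctions
    )


def simulate_cells(
    geometry: NetworkGeometry,
    waveform: WaveformSpec | list[WaveformSpec],
    duration_s: float,
    fps: float,
    seed: int,
) -> list[CellTrain]:
    """Place cell trains along each vessel and integrate plug-flow kinematics.

    Gaps and diameters are drawn once per cell with the given seed. Every
    cell advances by ``v(t) * dt`` per frame (midpoint-rule integration), so
    ordering along the vessel is preserved. Cells are seeded upstream far
    enough that the vessel stays populated for the whole duration.
    """
    if not fps > 0:
        raise ValueError("fps must be positive")
    if duration_s < 1.0 / fps:
        raise ValueError("duration shorter than one frame period")
    waveforms = waveform if isinstance(waveform, list) else [waveform] * len(
        geometry.vessels
    )
    if len(waveforms) != len(geometry.vessels):
        raise ValueError("need one waveform per vessel")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * fps))
    trains = []
    for ves, wf in zip(geometry.vessels, waveforms):
        disp = wf.displacement_per_frame(n_frames, fps)
        total_disp = disp[-1]
        spec = ves.spec
        span = ves.length_um + total_disp + 4 * spec.cell_mean_diam_um
        pitch = spec.mean_gap_um + spec.cell_mean_diam_um
        n_cells = max(1, int(np.ceil(span / max(pitch, 1e-6))) + 2)
        diam = rng.normal(
            spec.cell_mean_diam_um, spec.cell_diam_cv * spec.cell_mean_diam_um, n_cells
        )
        diam = np.clip(diam, 0.25 * spec.cell_mean_diam_um, None)
        gaps = rng.normal(spec.mean_gap_um, spec.gap_cv * spec.mean_gap_um, n_cells)
        gaps = np.clip(gaps, 0.2 * spec.mean_gap_um, None)
        contrast = rng.normal(1.0, spec.cell_contrast_cv, n_cells)
        contrast = np.clip(contrast, 0.1, None)
        radius = spec.width_um / 2.0
        offset = rng.normal(0.0, spec.lateral_sd_frac * radius, n_cells)
        offset = np.clip(offset, -0.8 * radius, 0.8 * radius)
        # centre-to-centre pitch i -> i+1 is gap_i + (d_i + d_{i+1})/2
        pitches = gaps[:-1] + 0.5 * (diam[:-1] + diam[1:])
        start = ves.length_um + 2 * spec.cell_mean_diam_um
        s0 = start - np.concatenate([[0.0], np.cumsum(pitches)])
        trains.append(
            CellTrain(
                s0_um=s0, diam_um=diam, contrast=contrast, offset_um=offset,
                displacement_um=disp, waveform=wf,
            )
        )
    return trains


def _background(shape, amplitude, pixel_um, rng) -> np.ndarray:
    if amplitude == 0:
        return np.ones(shape)
    raw = rng.standard_normal(shape)
    smooth = gaussian_filter(raw, sigma=BACKGROUND_CORR_UM / pixel_um, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    return 1.0 + amplitude * smooth


def render_sequence(
    trains: list[CellTrain],
    geometry: NetworkGeometry,
    fps: float,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    epoch_ms: float = 100.0,
    step_ms: float = 50.0,
    plasma_gain: float = PLASMA_GAIN,
    cell_gain: float = CELL_GAIN,
) -> PhantomTruth:
    """Render frames and assemble ground truth.

    Appearance per frame: unit-mean textured background, a soft bright tube
    (plasma), Gaussian intensity dips at every in-field cell clipped to the
    tube, an exponential bleaching decay, and additive photon noise. Frames
    are clipped to be nonnegative. Truth speed maps sample each vessel's
    waveform at epoch midpoints over the tube support.
    """
    rows, cols = geometry.field_size
    pixel_um = geometry.pixel_um
    n_frames = trains[0].displacement_um.shape[0] if trains else 2
    rng = np.random.default_rng(seed)
    bg = _background((rows, cols), noise.background_texture_amplitude, pixel_um, rng)

    tube_soft = np.zeros((rows, cols))
    masks = geometry.tube_masks()
    mask = np.zeros((rows, cols), dtype=bool)
    for ves, m in zip(geometry.vessels, masks):
        mask |= m
        radius_px = ves.spec.width_um / 2.0 / pixel_um
        tube_soft = np.maximum(tube_soft, _soft_tube(ves, (rows, cols), radius_px))

    frames = np.empty((n_frames, rows, cols))
    static = bg + plasma_gain * tube_soft
    rr_grid, cc_grid = np.mgrid[0:rows, 0:cols]
    for k in range(n_frames):
        frame = static.copy()
        for ves, m, train in zip(geometry.vessels, masks, trains):
            s = train.positions_at(k)
            inside = (s > -train.diam_um) & (s < ves.length_um + train.diam_um)
            if not inside.any():
                continue
            centers = ves.point_at_um(s[inside])
            normals = ves.normal_at_um(s[inside])
            centers = centers + normals * (train.offset_um[inside] / pixel_um)[:, None]
            for (r0, c0), d_um, con in zip(
                centers, train.diam_um[inside], train.contrast[inside]
            ):
                sigma = max(d_um / pixel_um / 2.355, 0.5)  # FWHM = diameter
                half = int(np.ceil(3 * sigma))
                r_lo, r_hi = max(0, int(r0) - half), min(rows, int(r0) + half + 1)
                c_lo, c_hi = max(0, int(c0) - half), min(cols, int(c0) + half + 1)
                if r_lo >= r_hi or c_lo >= c_hi:
                    continue
                dr = rr_grid[r_lo:r_hi, c_lo:c_hi] - r0
                dc = cc_grid[r_lo:r_hi, c_lo:c_hi] - c0
                dip = cell_gain * con * np.exp(-(dr**2 + dc**2) / (2 * sigma**2))
                frame[r_lo:r_hi, c_lo:c_hi] -= dip * m[r_lo:r_hi, c_lo:c_hi]
        if noise.bleach_drift_per_s > 0:
            frame = frame * np.exp(-noise.bleach_drift_per_s * k / fps)
        if noise.photon_noise_sd > 0:
            frame = frame + rng.normal(0.0, noise.photon_noise_sd, frame.shape)
        frames[k] = np.clip(frame, 0.0, None)

    seq = ImageSequence(frames, fps=fps, pixel_um=pixel_um)

    ew = window_frames(epoch_ms, fps)
    sw = window_frames(step_ms, fps)
    starts = np.arange(0, n_frames - ew + 1, sw)
    mids_s = (starts + ew / 2.0) / fps
    n_epochs = starts.size
    truth_maps = np.full((n_epochs, rows, cols), np.nan)
    truth_traces = np.zeros((len(trains), n_epochs))
    max_speed = 0.0
    for vi, (train, m) in enumerate(zip(trains, masks)):
        v = train.waveform.velocity(mids_s)
        truth_traces[vi] = v
        max_speed = max(max_speed, train.waveform.max_velocity)
        for ei in range(n_epochs):
            truth_maps[ei][m] = v[ei]
    return PhantomTruth(
        sequence=seq,
        truth_speed_maps=truth_maps,
        truth_traces=truth_traces,
        epoch_starts_ms=starts / fps * 1000.0,
        mask=mask,
        seed=seed,
        max_speed=max_speed,
    )


def _soft_tube(ves: VesselGeometry, shape, radius_px: float) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
    tree = cKDTree(ves.points)
    d, _ = tree.query(grid)
    return np.exp(-(d**2) / (2 * (radius_px / 1.5) ** 2)).reshape(rows, cols)


def generate_phantom(
    specs: list[VesselSpec],
    waveforms: WaveformSpec | list[WaveformSpec],
    field_size: tuple[int, int],
    duration_s: float,
    fps: float = 300.0,
    pixel_um: float = 1.0,
    noise: NoiseSpec = NoiseSpec(background_texture_amplitude=0.08, photon_noise_sd=0.01),
    seed: int = 0,
    epoch_ms: float = 100.0,
    step_ms: float = 50.0,
) -> PhantomTruth:
    """One-call phantom: network + kinematics + rendering."""
    geom = build_network(specs, field_size, pixel_um=pixel_um)
    trains = simulate_cells(geom, waveforms, duration_s, fps, seed)
    return render_sequence(
        trains, geom, fps=fps, noise=noise, seed=seed, epoch_ms=epoch_ms, step_ms=step_ms
    )
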