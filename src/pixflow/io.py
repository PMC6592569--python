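"""Readers and writers for sequences, masks, velocity maps and tables."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .preprocess import ImageSequence

__all__ = [
    "read_sequence",
    "write_sequence",
    "read_sidecar",
    "write_sidecar",
    "write_velocity_tiff",
    "render_velocity_png",
    "write_segment_table",
    "write_traces_csv",
]


def read_sidecar(path: str | Path) -> dict:
    """Load fps / pixel_um metadata from a YAML or JSON sidecar file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_sidecar(path: str | Path, meta: dict) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(meta, indent=2))
    else:
        path.write_text(yaml.safe_dump(meta))


def read_sequence(
    path: str | Path,
    fps: float | None = None,
    pixel_um: float | None = None,
    sidecar: str | Path | None = None,
) -> ImageSequence:
    """Read a multi-page TIFF or AVI stack into an :class:`ImageSequence`.

    Calibration comes from explicit arguments or a sidecar YAML/JSON with
    ``fps`` and ``pixel_um`` keys (an adjacent ``<stem>.yaml``/``.json`` is
    picked up automatically).
    """
    path = Path(path)
    if sidecar is None:
        for suffix in (".yaml", ".yml", ".json"):
            cand = path.with_suffix(suffix)
            if cand.exists():
                sidecar = cand
                break
    if sidecar is not None:
        meta = read_sidecar(sidecar)
        fps = fps if fps is not None else meta.get("fps")
        pixel_um = pixel_um if pixel_um is not None else meta.get("pixel_um")
    if fps is None or pixel_um is None:
        raise ValueError("fps and pixel_um required (argument or sidecar)")

    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    else:
        frames = iio.imread(path)
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 4:  # color video: collapse channels
        frames = frames.mean(axis=-1)
    return ImageSequence(frames, fps=float(fps), pixel_um=float(pixel_um))


def write_sequence(path: str | Path, seq: ImageSequence) -> None:
    """Multi-page float32 TIFF plus an adjacent YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, seq.frames.astype(np.float32), photometric="minisblack")
    write_sidecar(path.with_suffix(".yaml"), {"fps": seq.fps, "pixel_um": seq.pixel_um})


def write_velocity_tiff(path: str | Path, speed: np.ndarray) -> None:
    tifffile.imwrite(Path(path), speed.astype(np.float32), photometric="minisblack")


def render_velocity_png(
    path: str | Path, speed: np.ndarray, v_max: float = 4.5
) -> None:
    """Speed map on a fixed 0..v_max perceptual scale, NaN rendered black."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import cm

    norm = np.clip(np.nan_to_num(speed, nan=0.0) / v_max, 0.0, 1.0)
    rgba = cm.viridis(norm)
    rgba[~np.isfinite(speed)] = (0, 0, 0, 1)
    iio.imwrite(Path(path), (rgba[..., :3] * 255).astype(np.uint8))


def write_segment_table(path: str | Path, segmentation) -> None:
    rows = [
        {
            "label": label,
            "length_um": segmentation.segment_lengths[label],
            "pixel_count": int((segmentation.labels == label).sum()),
        }
        for label in segmentation.label_ids()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_traces_csv(path: str | Path, traces) -> None:
    """Long-format CSV: epoch_start_ms, segment_id, speed_mm_s."""
    rows = []
    for t in traces:
        for start, v in zip(t.epoch_starts_ms, t.speeds):
            rows.append(
                {"epoch_start_ms": start, "segment_id": t.label, "speed_mm_s": v}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
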