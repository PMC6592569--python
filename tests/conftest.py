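import numpy as np
import pytest

import pixflow as pf


@pytest.fixture
def straight_phantom_factory():
    """Single straight-vessel phantom with known constant or pulsatile flow."""

    def make(
        mean_velocity=0.9,
        duration_s=0.3,
        seed=1,
        field=(40, 120),
        pulsatility_depth=0.0,
        period=1.0,
        margin=5,
        **vessel_kw,
    ):
        rows, cols = field
        spec = pf.VesselSpec(
            centerline=((rows / 2.0, float(margin)), (rows / 2.0, float(cols - margin))),
            **vessel_kw,
        )
        wf = pf.WaveformSpec(
            mean_velocity=mean_velocity,
            pulsatility_depth=pulsatility_depth,
            period=period,
        )
        return pf.generate_phantom([spec], wf, field, duration_s, seed=seed)

    return make


@pytest.fixture
def noise_epoch_factory():
    def make(shape=(30, 32, 32), seed=0, fps=300.0, pixel_um=1.0):
        rng = np.random.default_rng(seed)
        return pf.Epoch(
            frames=rng.standard_normal(shape), start_ms=0.0, fps=fps, pixel_um=pixel_um
        )

    return make


@pytest.fixture
def two_label_segmentation():
    """Two parallel 40 um segments with hand-built labels (pixel_um = 1)."""
    shape = (30, 60)
    skeleton = np.zeros(shape, dtype=bool)
    skeleton[8, 10:50] = True
    skeleton[22, 10:50] = True
    labels = np.zeros(shape, dtype=np.int32)
    labels[6:11, 10:50] = 1
    labels[20:25, 10:50] = 2
    return pf.VesselSegmentation(
        mask=labels > 0,
        skeleton=skeleton,
        labels=labels,
        segment_lengths={1: 39.0, 2: 39.0},
        pixel_um=1.0,
    )
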