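import numpy as np
import pytest

from cytolink.ctc_io import Detection, LabelStack
from cytolink.synthetic import SynthConfig, generate_sequence


def make_detection(
    frame=0,
    label=1,
    centroid=(0.0, 0.0),
    area=100.0,
    **overrides,
):
    """A Detection with sensible defaults for geometric toy cases."""
    values = dict(
        frame=frame,
        label=label,
        centroid=centroid,
        area=area,
        equivalent_diameter=2.0 * np.sqrt(area / np.pi),
        perimeter=2.0 * np.sqrt(np.pi * area),
        eccentricity=0.0,
        solidity=1.0,
        orient_sin2=0.0,
        orient_cos2=1.0,
    )
    values.update(overrides)
    return Detection(**values)


def disk_frame(shape, blobs, dtype=np.uint16):
    """Render labeled disks: blobs = [(label, row, col, radius), ...]."""
    from skimage.draw import disk

    frame = np.zeros(shape, dtype=dtype)
    for label, r, c, radius in blobs:
        rr, cc = disk((r, c), radius, shape=shape)
        frame[rr, cc] = label
    return frame


@pytest.fixture(scope="session")
def small_synth():
    """A small clean sequence with 2 divisions and 1 fusion."""
    cfg = SynthConfig(
        n_initial_cells=5,
        n_frames=20,
        n_mitosis=2,
        n_fusion=1,
        field_size=(256, 256),
        cell_radius=8,
        base_speed=2.0,
        noise_sigma=0.5,
        lifespan_interval=(5, 12),
        seed=7,
    )
    return generate_sequence(cfg)


@pytest.fixture(scope="session")
def benchmark_200f():
    """The 200-frame benchmark: 16 initial cells, 41 divisions, 1 fusion."""
    cfg = SynthConfig(
        n_initial_cells=16, n_frames=200, n_mitosis=41, n_fusion=1, seed=1
    )
    return generate_sequence(cfg)


@pytest.fixture(scope="session")
def benchmark_fusion_heavy():
    """The fusion stress benchmark: 24 initial cells, 34 divisions, 6 fusions."""
    cfg = SynthConfig(
        n_initial_cells=24, n_frames=200, n_mitosis=34, n_fusion=6, seed=1
    )
    return generate_sequence(cfg)
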