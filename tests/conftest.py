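import numpy as np
import pytest

from cementochron import synthgen


@pytest.fixture
def clean_texture():
    """Noise-free, perfectly coherent banding."""
    return synthgen.TextureParams(contrast=0.5, anisotropy=1e9, noise_sd=0.0)


@pytest.fixture
def constant_spec(clean_texture):
    """Five years of constant 10 μm growth, 1 μm voxels, no noise."""
    return synthgen.SyntheticSpec(
        schedule=synthgen.GrowthSchedule("linear", (10.0, 0.0), 5, base_width_um=10.0),
        texture=clean_texture,
        voxel_size_um=1.0,
        image_shape=(80, 120),
        seed=1,
    )


@pytest.fixture
def hill_spec(clean_texture):
    """Decreasing Hill sigmoid from 12 to ~4 μm over 10 years."""
    return synthgen.SyntheticSpec(
        schedule=synthgen.GrowthSchedule(
            "hill_sigmoid", (12.0, 4.0, 5.0, 6.0), 10, base_width_um=12.0
        ),
        texture=clean_texture,
        voxel_size_um=1.0,
        image_shape=(160, 120),
        seed=2,
    )


def measure_image(img, voxel_size_um=1.0, **detect_kwargs):
    """Shared helper: trim, transect, detect; returns list of
    (positions in original μm coordinates, IncrementSeries)."""
    from cementochron import increments
    from cementochron.imgstack import StraightenedCementum, trim_boundary_artifacts

    region, off = trim_boundary_artifacts(
        StraightenedCementum(pixels=img, voxel_size_um=voxel_size_um)
    )
    out = []
    for prof in increments.extract_transects(region):
        pk = increments.detect_peaks(prof, **detect_kwargs)
        out.append((pk.peak_positions_um + off, increments.measure_widths(pk)))
    return out
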