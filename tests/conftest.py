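import numpy as np
import pandas as pd
import pytest

from bactvolt.imgseg import SegmentationParams
from bactvolt.synthgen import ImagingSpec, PopulationSpec


@pytest.fixture
def clean_imaging():
    """Noise- and blur-free acquisition: rendering is exact."""
    return ImagingSpec(read_noise_sd=0.0, psf_sigma_px=0.0)


@pytest.fixture
def noisy_imaging():
    """Moderate read noise, no blur: per-pixel SNR >= 5 for cell-level signals."""
    return ImagingSpec(read_noise_sd=2.0, psf_sigma_px=0.0)


@pytest.fixture
def small_population():
    return PopulationSpec(n_cells=50, frac_depolarized=0.4)


@pytest.fixture
def default_params(small_population):
    return SegmentationParams.from_median_cell_area(
        small_population.median_cell_area()
    )


def make_cell_table(intensities, replicate="R1", condition="Control"):
    """Minimal cell table from a flat list of intensities."""
    intensities = np.asarray(intensities, dtype=float)
    return pd.DataFrame(
        {
            "condition": condition,
            "replicate": replicate,
            "image_id": f"{condition}_{replicate}",
            "cell_id": np.arange(1, len(intensities) + 1),
            "area_px": 120,
            "mean_intensity": intensities,
        }
    )
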