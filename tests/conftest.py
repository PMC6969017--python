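import numpy as np
import pytest

from csdi.geometry import GridSpec, RasterSpec, build_masks


@pytest.fixture(scope="session")
def grid_od():
    return GridSpec()


@pytest.fixture(scope="session")
def device_raster():
    """The device scan geometry: 31 B-scans spaced 0.240 mm, 768 A-scans over 9 mm."""
    return RasterSpec(
        n_rows=31,
        n_cols=768,
        row_spacing_mm=0.240,
        col_spacing_mm=9.0 / 768,
        fovea_row=15.0,
        fovea_col=383.5,
    )


@pytest.fixture(scope="session")
def fine_raster():
    """Near-isotropic fine raster (0.01 mm) for analytic-area comparisons."""
    return RasterSpec(
        n_rows=701,
        n_cols=701,
        row_spacing_mm=0.01,
        col_spacing_mm=0.01,
        fovea_row=350.0,
        fovea_col=350.0,
    )


@pytest.fixture(scope="session")
def fine_masks(grid_od, fine_raster):
    return build_masks(grid_od, fine_raster)


@pytest.fixture(scope="session")
def device_masks(grid_od, device_raster):
    return build_masks(grid_od, device_raster)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
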