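import numpy as np
import pytest

from stimsort.spectra import RamanSpectrum


@pytest.fixture
def grid():
    return np.arange(400.0, 3200.0 + 1.0, 1.0)


@pytest.fixture
def flat_spectrum(grid):
    def make(value: float = 1.0, cell_id: str = "flat") -> RamanSpectrum:
        return RamanSpectrum(grid, np.full(grid.size, value), cell_id=cell_id)

    return make


@pytest.fixture
def gaussian_spectrum(grid):
    """Spectrum = offset + sum of Gaussian bands of given (area, center, sigma)."""

    def make(bands, offset: float = 0.0, slope: float = 0.0) -> RamanSpectrum:
        y = offset + slope * (grid - grid[0])
        for area, center, sigma in bands:
            y = y + area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
                -0.5 * ((grid - center) / sigma) ** 2
            )
        return RamanSpectrum(grid, y, cell_id="gauss")

    return make
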