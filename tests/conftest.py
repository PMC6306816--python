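import numpy as np
import pytest

from fibralign import ImageRaster
from fibralign.spectral import OrientationDistribution, SpectralParams, bin_centers


@pytest.fixture
def make_grating():
    """Factory for a sinusoidal grating whose stripes run along a given angle."""

    def _make(angle_deg: float, n: int = 256, period_px: float = 10.0) -> ImageRaster:
        rr, cc = np.mgrid[:n, :n]
        x, y = cc.astype(float), -rr.astype(float)
        a = np.radians(angle_deg)
        k = 2.0 * np.pi / period_px
        phase = k * (-np.sin(a) * x + np.cos(a) * y)  # wavevector perpendicular to stripes
        return ImageRaster(0.5 + 0.4 * np.cos(phase))

    return _make


@pytest.fixture
def make_distribution():
    """Factory for an OrientationDistribution from raw non-negative weights."""

    def _make(weights, n_bins: int = 180) -> OrientationDistribution:
        w = np.asarray(weights, dtype=float)
        return OrientationDistribution(
            bin_centers_deg=bin_centers(n_bins),
            percent=100.0 * w / w.sum(),
            total_energy=float(w.sum()),
            params=SpectralParams(n_bins=n_bins),
        )

    return _make


@pytest.fixture
def delta_distribution(make_distribution):
    """Factory for a distribution with all mass in the bin nearest an angle."""

    def _make(angle_deg: float, n_bins: int = 180) -> OrientationDistribution:
        w = np.zeros(n_bins)
        width = 180.0 / n_bins
        w[int(round((angle_deg + 90.0) / width)) % n_bins] = 1.0
        return make_distribution(w, n_bins)

    return _make
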