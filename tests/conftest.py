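"""Shared fixtures and oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

import coce
from coce.phantom import speckle_field


def make_ramp_pair(strain: float, *, depth_px: int = 300,
                   lateral_px: int = 64, axial_pixel_um: float = 4.0,
                   wavelength_um: float = 1.31, refractive_index: float = 1.4,
                   speckled: bool = True, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless frame pair with a uniform true axial strain.

    Frame b equals frame a advanced in phase by (4 pi n / lambda) * u(z)
    with u the cumulative compression of a homogeneous column.
    """
    rng = np.random.default_rng(seed)
    shape = (depth_px, lateral_px)
    if speckled:
        amp = np.ones(shape)
        base = speckle_field(shape, amp, 15.0 / axial_pixel_um,
                             25.0 / axial_pixel_um, rng)
    else:
        base = np.ones(shape, dtype=complex)
    u = strain * (np.arange(depth_px) + 1.0)[:, None] * axial_pixel_um
    k = 4.0 * np.pi * refractive_index / wavelength_um
    return base, base * np.exp(1j * k * u)


def unwrap_lstsq_strain(field: np.ndarray, *, window_px: int,
                        axial_pixel_um: float, wavelength_um: float = 1.31,
                        refractive_index: float = 1.4) -> np.ndarray:
    """Brute-force strain oracle: unwrap the interframe phase along depth
    and fit a least-squares slope per axial window, column by column.
    Independent of the vector method (explicit unwrapping, amplitude
    ignored, plain polyfit)."""
    phi = np.unwrap(np.angle(field), axis=0)
    h, w = field.shape
    k = 4.0 * np.pi * refractive_index / wavelength_um
    z = np.arange(h) * axial_pixel_um
    half = window_px // 2
    out = np.full((h, w), np.nan)
    for x in range(w):
        for zc in range(half, h - half):
            sl = slice(zc - half, zc + half + 1)
            slope = np.polyfit(z[sl], phi[sl, x], 1)[0]
            out[zc, x] = slope / k
    return out


@pytest.fixture(scope="session")
def default_config() -> coce.PipelineConfig:
    return coce.PipelineConfig()


@pytest.fixture(scope="session")
def homogeneous_run():
    """One simulated and reconstructed homogeneous phantom (reused by
    several tests); modest grid to keep the suite quick."""
    phantom = coce.homogeneous_phantom(295.0, depth_px=350, lateral_px=128)
    acq = coce.AcquisitionSpec(n_frames=60, max_stress_kPa=6.0, snr_db=25.0,
                               seed=11)
    series, truth = coce.simulate_compression_series(phantom, acq)
    stiff = coce.reconstruct(series)
    return phantom, series, truth, stiff


@pytest.fixture(scope="session")
def cohort30():
    """Seeded default cohort with full pipeline results (shared by the
    agreement and detection tests)."""
    samples = coce.make_cohort(30, seed=2026)
    results = [coce.run_sample(s.series) for s in samples]
    return samples, results
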