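"""Phase-resolved interframe strain estimation (the "vector method").

Compression OCE infers local axial strain from the phase difference between
consecutive complex-valued OCT B-scans.  An axial displacement u of a
scatterer changes the optical path by 2*n*u and hence the detected phase by

    dphi = (4 * pi * n / lambda) * u,

so the axial gradient of the interframe phase map is proportional to the
interframe strain.  The vector method estimates that gradient without ever
unwrapping the phase: complex signal values are treated as vectors in the
complex plane, axial lag products are averaged *as complex numbers* over a
spatial window, and the phase is singled out only at the very last step.
This makes the estimator robust to noise and allows interframe strains up
to ~1% per frame pair; larger total strains are reached by summing a series
of interframe estimates (cumulative strain).

Coordinate and sign conventions used throughout the package:

* row 0 is the probe output window; depth z increases down the columns;
* compression is applied from the top and compressive strain is positive;
* under compression the material moves toward the probe, and the simulator
  books this as phase advancing by (4*pi*n/lambda)*u(z) with u(z) the
  accumulated compression above depth z, so a positive phase gradient with
  depth means positive (compressive) strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import uniform_filter


@dataclass
class ComplexFrameSeries:
    """A series of complex OCT B-scans acquired during compression.

    data : (n_frames, depth_px, lateral_px) complex array
    wavelength_um : central wavelength of the source in microns (1.31 for
        the 1310 nm instrument emulated by the simulator)
    refractive_index : bulk refractive index used for the phase-to-
        displacement conversion (soft tissue ~ 1.4)
    axial_pixel_um, lateral_pixel_um : pixel pitch in microns
    silicone_interface_row : first tissue row (the reference silicone layer
        occupies rows [0, silicone_interface_row)); optional metadata
    """

    data: np.ndarray
    wavelength_um: float = 1.31
    refractive_index: float = 1.4
    axial_pixel_um: float = 4.0
    lateral_pixel_um: float = 4.0
    silicone_interface_row: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_frames, depth, lateral)")
        if self.data.shape[0] < 2:
            raise ValueError("a frame series needs at least 2 frames")
        if not np.all(np.isfinite(self.data.view(float))):
            raise ValueError("frame data contains non-finite values")
        for name in ("wavelength_um", "refractive_index", "axial_pixel_um",
                     "lateral_pixel_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def phase_to_displacement_um(self) -> float:
        """Microns of axial displacement per radian of interframe phase."""
        return self.wavelength_um / (4.0 * np.pi * self.refractive_index)


@dataclass
class StrainField:
    """Per-pixel axial strain with a validity mask.

    kind is "interframe" (one frame pair) or "cumulative" (running sum over
    the series).  Values are dimensionless, compression positive.  Pixels
    with valid_mask False carry no meaningful value.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    window_axial_um: float
    window_lateral_um: float
    kind: Literal["interframe", "cumulative"] = "interframe"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")


def interframe_field(frame_a: np.ndarray, frame_b: np.ndarray) -> np.ndarray:
    """Complex field whose argument is the interframe phase variation.

    The pixelwise product conj(a)*b has argument phi_b - phi_a in (-pi, pi]
    and amplitude |a||b|, so strong-signal pixels dominate any subsequent
    complex averaging.
    """
    frame_a = np.asarray(frame_a)
    frame_b = np.asarray(frame_b)
    if frame_a.shape != frame_b.shape:
        raise ValueError(
            f"frame shapes differ: {frame_a.shape} vs {frame_b.shape}")
    return np.conj(frame_a) * frame_b


def vector_strain(
    field: np.ndarray,
    *,
    wavelength_um: float = 1.31,
    refractive_index: float = 1.4,
    axial_pixel_um: float = 4.0,
    lateral_pixel_um: float = 4.0,
    window_axial_um: float = 100.0,
    window_lateral_um: float = 100.0,
    axial_lag_px: int = 3,
    amplitude_floor: float = 0.25,
    min_coverage: float = 0.5,
) -> StrainField:
    """Estimate interframe strain from an interframe phase field.

    Per pixel the axial lag product P(z, x) = conj(F(z, x)) * F(z+lag, x)
    carries the phase accrued over `lag` axial pixels.  P is averaged as a
    complex number over a rectangular window (default 100 um, the upper end
    of the 80-100 um range used in practice) and only then is the argument
    taken:

        strain = arg(mean P) * lambda / (4 pi n * lag * axial_pixel).

    Because only the per-lag phase increment must stay inside (-pi, pi],
    strains of ~1% per frame pair are recovered without unwrapping even
    where the raw interframe phase wraps many times along depth.

    Pixels are marked invalid where |mean P| falls below `amplitude_floor`
    times the window mean of the lag-product amplitude (vector averaging of
    incoherent phases cancels, which is exactly what happens in non-signal
    regions), or where less than `min_coverage` of the window is in-image.
    """
    field = np.asarray(field)
    if field.ndim != 2:
        raise ValueError("field must be 2-D (depth, lateral)")
    lag = int(axial_lag_px)
    if lag < 1:
        raise ValueError("axial_lag_px must be >= 1")
    h, w = field.shape
    wa = max(1, int(round(window_axial_um / axial_pixel_um)))
    wl = max(1, int(round(window_lateral_um / lateral_pixel_um)))
    if wa > h or wl > w:
        raise ValueError(
            f"averaging window {wa}x{wl} px exceeds image {h}x{w} px")
    if wa < lag:
        raise ValueError("axial window must be at least the axial lag")
    if h <= lag:
        raise ValueError("image shallower than the axial lag")

    lag_prod = np.conj(field[:-lag, :]) * field[lag:, :]

    # Center the lag product between its two source rows, zero-fill the rest
    # and track in-image coverage so border windows can be masked.
    full = np.zeros((h, w), dtype=complex)
    cover = np.zeros((h, w), dtype=np.float64)
    off = lag // 2
    full[off:off + h - lag, :] = lag_prod
    cover[off:off + h - lag, :] = 1.0

    size = (wa, wl)
    mean_re = uniform_filter(full.real, size=size, mode="constant")
    mean_im = uniform_filter(full.imag, size=size, mode="constant")
    mean_amp = uniform_filter(np.abs(full), size=size, mode="constant")
    coverage = uniform_filter(cover, size=size, mode="constant")

    mean_p = mean_re + 1j * mean_im
    scale = wavelength_um / (4.0 * np.pi * refractive_index
                             * lag * axial_pixel_um)
    values = np.angle(mean_p) * scale

    valid = coverage >= min_coverage
    with np.errstate(invalid="ignore"):
        valid &= np.abs(mean_p) >= amplitude_floor * mean_amp
    valid &= mean_amp > 0

    return StrainField(values=values, valid_mask=valid,
                       window_axial_um=window_axial_um,
                       window_lateral_um=window_lateral_um,
                       kind="interframe")


def interframe_strains(
    series: ComplexFrameSeries,
    *,
    window_axial_um: float = 100.0,
    window_lateral_um: float = 100.0,
    axial_lag_px: int = 3,
    amplitude_floor: float = 0.25,
) -> list[StrainField]:
    """Vector-method strain for every consecutive frame pair of a series."""
    out = []
    for f in range(series.n_frames - 1):
        fld = interframe_field(series.data[f], series.data[f + 1])
        out.append(vector_strain(
            fld,
            wavelength_um=series.wavelength_um,
            refractive_index=series.refractive_index,
            axial_pixel_um=series.axial_pixel_um,
            lateral_pixel_um=series.lateral_pixel_um,
            window_axial_um=window_axial_um,
            window_lateral_um=window_lateral_um,
            axial_lag_px=axial_lag_px,
            amplitude_floor=amplitude_floor,
        ))
    return out


def cumulate(fields: Sequence[StrainField]) -> list[StrainField]:
    """Running pixelwise sum of interframe strains.

    Returns one cumulative field per input field (the k-th output is the sum
    of inputs 0..k).  The validity mask of each output is the conjunction of
    the masks of the fields summed so far.  Random per-frame estimation
    errors add in quadrature while the strain adds linearly, so the relative
    noise of the cumulative strain *decreases* along the series.
    """
    if not fields:
        raise ValueError("no strain fields to accumulate")
    shape = fields[0].values.shape
    out: list[StrainField] = []
    total = np.zeros(shape)
    mask = np.ones(shape, dtype=bool)
    for f in fields:
        if f.kind != "interframe":
            raise ValueError("cumulate expects interframe strain fields")
        if f.values.shape != shape:
            raise ValueError("strain field shapes differ")
        total = total + f.values
        mask = mask & f.valid_mask
        out.append(StrainField(values=total.copy(), valid_mask=mask.copy(),
                               window_axial_um=f.window_axial_um,
                               window_lateral_um=f.window_lateral_um,
                               kind="cumulative"))
    return out
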