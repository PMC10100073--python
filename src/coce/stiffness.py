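"""Reference-silicone stress calibration and tangent Young's-modulus maps.

The applied stress is never measured directly: the strain of the
pre-calibrated, highly linear reference silicone layer on top of the tissue
reports it (sigma = E_sil * eps_sil).  Plotting that stress against the
local cumulative tissue strain yields a spatially resolved stress-strain
record per pixel, whose local slope is the tangent Young's modulus.  Since
real tissue is markedly nonlinear, moduli are only comparable at a common
loading; maps here are standardized to 4 kPa applied stress, estimated as
the secant slope between the points where the stress first crosses 3 and
5 kPa (linear interpolation in stress).

Stress is estimated per lateral column by default (a simplified stand-in
for full local-stress standardization); pass ``per_column=False`` for a
frame-global stress value.  Cumulative strain is summed in the lab frame
without advection of pixels between frames -- a documented approximation,
acceptable for the <=10% total strains used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .strain import ComplexFrameSeries, StrainField, cumulate, interframe_strains


class InsufficientCompressionError(ValueError):
    """Applied stress never reached the upper end of the stress window."""


@dataclass
class StressStrainGrid:
    """Per-pixel stress-strain records over a compression series.

    stress : (n_frames, lateral) applied stress per frame and column, kPa
    strain : (n_frames, depth, lateral) cumulative strain per pixel
    valid_mask : (depth, lateral) pixels with a usable record
    """

    stress: np.ndarray
    strain: np.ndarray
    valid_mask: np.ndarray
    E_sil: float
    silicone_mask: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.stress.shape[0]


@dataclass
class StiffnessMap:
    """Tangent Young's modulus (kPa) at a standardized applied stress."""

    values: np.ndarray
    signal_mask: np.ndarray
    standardized_stress_kPa: float = 4.0
    stress_window_kPa: tuple[float, float] = (3.0, 5.0)
    axial_pixel_um: float = 4.0
    lateral_pixel_um: float = 4.0
    silicone_interface_row: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.stress_window_kPa
        if not (lo < self.standardized_stress_kPa < hi):
            raise ValueError("stress window must contain the standardized "
                             "stress")


def silicone_stress(
    cumulative: list[StrainField] | np.ndarray,
    silicone_mask: np.ndarray,
    E_sil: float,
    *,
    valid_mask: np.ndarray | None = None,
    per_column: bool = True,
    min_valid_fraction: float = 0.5,
) -> np.ndarray:
    """Applied stress per frame (and lateral column) from silicone strain.

    sigma(f, x) = E_sil * mean cumulative strain over the valid silicone
    pixels of column x at frame f.  Requires at least `min_valid_fraction`
    of the silicone rows to be valid in every column.
    """
    if E_sil <= 0:
        raise ValueError("E_sil must be positive")
    silicone_mask = np.asarray(silicone_mask, dtype=bool)
    if not silicone_mask.any():
        raise ValueError("silicone region is empty")

    if isinstance(cumulative, np.ndarray):
        strain = cumulative
        valid = (np.ones(strain.shape[1:], dtype=bool)
                 if valid_mask is None else np.asarray(valid_mask, dtype=bool))
    else:
        strain = np.stack([f.values for f in cumulative])
        valid = np.logical_and.reduce([f.valid_mask for f in cumulative])

    sil_valid = silicone_mask & valid
    n_rows = silicone_mask.sum(axis=0)
    cols = n_rows > 0
    ok = sil_valid.sum(axis=0)[cols] >= min_valid_fraction * n_rows[cols]
    if not ok.all():
        raise ValueError("silicone region invalid in >50% of pixels for "
                         f"{int((~ok).sum())} lateral columns")

    weights = sil_valid.astype(float)
    sums = np.einsum("fzx,zx->fx", strain, weights)
    counts = weights.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = E_sil * sums / counts
    if not per_column:
        sigma = np.repeat(sigma[:, cols].mean(axis=1, keepdims=True),
                          sigma.shape[1], axis=1)
    return sigma


def build_stress_strain(
    cumulative_strain: np.ndarray,
    stress: np.ndarray,
    *,
    valid_mask: np.ndarray,
    invalid_frame_count: np.ndarray | None = None,
    E_sil: float = 100.0,
    silicone_mask: np.ndarray | None = None,
    max_invalid_fraction: float = 0.3,
    monotone_tol_kPa: float = 0.15,
) -> StressStrainGrid:
    """Assemble per-pixel stress-strain records.

    `cumulative_strain` is (n_frames, depth, lateral) and `stress` is
    (n_frames, lateral).  Pixels invalid in more than `max_invalid_fraction`
    of the frames are masked out.  A stress schedule that decreases by more
    than `monotone_tol_kPa` anywhere signals failed silicone tracking and
    is an error.
    """
    cumulative_strain = np.asarray(cumulative_strain)
    stress = np.asarray(stress)
    if cumulative_strain.ndim != 3 or stress.ndim != 2:
        raise ValueError("expected (F,Z,X) strain and (F,X) stress")
    if (cumulative_strain.shape[0] != stress.shape[0]
            or cumulative_strain.shape[2] != stress.shape[1]):
        raise ValueError("strain and stress shapes inconsistent")

    if np.any(np.diff(stress, axis=0) < -monotone_tol_kPa):
        raise ValueError("recovered stress schedule is non-monotone beyond "
                         "tolerance: silicone tracking failed")

    mask = np.asarray(valid_mask, dtype=bool).copy()
    if invalid_frame_count is not None:
        n = cumulative_strain.shape[0]
        mask &= invalid_frame_count <= max_invalid_fraction * n
    if silicone_mask is None:
        silicone_mask = np.zeros(mask.shape, dtype=bool)

    return StressStrainGrid(stress=stress, strain=cumulative_strain,
                            valid_mask=mask, E_sil=E_sil,
                            silicone_mask=np.asarray(silicone_mask, bool))


def _interp_strain_at_stress(strain: np.ndarray, stress_col: np.ndarray,
                             target: float) -> np.ndarray:
    """Strain of every pixel of one column at a given stress, linearly
    interpolated in stress; ties broken toward the earlier frame."""
    j = int(np.searchsorted(stress_col, target, side="left"))
    if j == 0:
        return strain[0]
    j = min(j, len(stress_col) - 1)
    s0, s1 = stress_col[j - 1], stress_col[j]
    w = 0.0 if s1 == s0 else (target - s0) / (s1 - s0)
    return (1.0 - w) * strain[j - 1] + w * strain[j]


def tangent_modulus_map(
    grid: StressStrainGrid,
    *,
    stress_window_kPa: tuple[float, float] = (3.0, 5.0),
    standardized_stress_kPa: float = 4.0,
    max_modulus_kPa: float = 5000.0,
    axial_pixel_um: float = 4.0,
    lateral_pixel_um: float = 4.0,
    silicone_interface_row: int | None = None,
) -> StiffnessMap:
    """Tangent Young's modulus at the standardized stress.

    Per pixel, E_t = (s_hi - s_lo) / (eps(s_hi) - eps(s_lo)) with the
    strains at the window endpoints interpolated in stress.  Pixels with a
    non-positive strain increment, an invalid record, or a modulus beyond
    `max_modulus_kPa` (far above any observed tissue value; treated as an
    artifact) are masked out.
    """
    s_lo, s_hi = stress_window_kPa
    if not (0 < s_lo < s_hi):
        raise ValueError("invalid stress window")
    max_sigma = grid.stress.max(axis=0)
    if float(max_sigma.min()) < s_hi:
        raise InsufficientCompressionError(
            f"max applied stress {float(max_sigma.min()):.2f} kPa < "
            f"{s_hi:.2f} kPa: insufficient compression")

    n_f, h, w = grid.strain.shape
    eps_lo = np.empty((h, w))
    eps_hi = np.empty((h, w))
    for x in range(w):
        col = grid.stress[:, x]
        eps_lo[:, x] = _interp_strain_at_stress(grid.strain[:, :, x], col, s_lo)
        eps_hi[:, x] = _interp_strain_at_stress(grid.strain[:, :, x], col, s_hi)

    d_eps = eps_hi - eps_lo
    mask = grid.valid_mask & (d_eps > 0)
    values = np.zeros((h, w))
    np.divide(s_hi - s_lo, d_eps, out=values, where=mask)
    mask &= values <= max_modulus_kPa
    mask &= values > 0
    values[~mask] = 0.0

    return StiffnessMap(values=values, signal_mask=mask,
                        standardized_stress_kPa=standardized_stress_kPa,
                        stress_window_kPa=(s_lo, s_hi),
                        axial_pixel_um=axial_pixel_um,
                        lateral_pixel_um=lateral_pixel_um,
                        silicone_interface_row=silicone_interface_row)


def detect_silicone_interface(series: ComplexFrameSeries) -> int:
    """Interface row from metadata, or the documented fallback.

    When the container does not carry the silicone-tissue interface row, the
    topmost contiguous band whose stress-strain record is linear is the
    silicone; for the phantoms handled here the metadata is always present,
    so the fallback simply errors out rather than guessing silently.
    """
    if series.silicone_interface_row is not None:
        return int(series.silicone_interface_row)
    raise ValueError("series carries no silicone_interface_row metadata")


def silicone_interior_mask(shape: tuple[int, int], interface_row: int,
                           margin_px: int) -> np.ndarray:
    """Silicone rows eroded away from the probe window and the tissue
    interface, where window averaging mixes materials."""
    mask = np.zeros(shape, dtype=bool)
    top = min(margin_px, interface_row)
    bot = max(top + 1, interface_row - margin_px)
    mask[top:bot, :] = True
    return mask


def reconstruct_stiffness(
    series: ComplexFrameSeries,
    *,
    E_sil: float = 100.0,
    window_axial_um: float = 100.0,
    window_lateral_um: float = 100.0,
    axial_lag_px: int = 3,
    stress_window_kPa: tuple[float, float] = (3.0, 5.0),
    standardized_stress_kPa: float = 4.0,
    max_modulus_kPa: float = 5000.0,
    per_column_stress: bool = True,
    interface_row: int | None = None,
) -> StiffnessMap:
    """Full reconstruction: frames -> interframe strains -> cumulative
    strains -> silicone-calibrated stress -> tangent-modulus map."""
    if interface_row is None:
        interface_row = detect_silicone_interface(series)

    increments = interframe_strains(
        series, window_axial_um=window_axial_um,
        window_lateral_um=window_lateral_um, axial_lag_px=axial_lag_px)
    cumulative = cumulate(increments)

    h, w = series.shape
    n = series.n_frames
    # frame 0 carries zero stress and zero strain by definition
    strain = np.zeros((n, h, w), dtype=np.float64)
    invalid_count = np.zeros((h, w), dtype=np.int64)
    for f, fld in enumerate(cumulative, start=1):
        strain[f] = fld.values
    for fld in increments:
        invalid_count += ~fld.valid_mask
    final_mask = cumulative[-1].valid_mask

    half_window_px = int(round(0.5 * window_axial_um / series.axial_pixel_um))
    margin = half_window_px + axial_lag_px + 1
    sil_mask = silicone_interior_mask((h, w), interface_row, margin)

    sigma = silicone_stress(strain, sil_mask, E_sil,
                            valid_mask=final_mask, per_column=per_column_stress)
    grid = build_stress_strain(strain, sigma, valid_mask=final_mask,
                               invalid_frame_count=invalid_count,
                               E_sil=E_sil, silicone_mask=sil_mask)
    return tangent_modulus_map(
        grid, stress_window_kPa=stress_window_kPa,
        standardized_stress_kPa=standardized_stress_kPa,
        max_modulus_kPa=max_modulus_kPa,
        axial_pixel_um=series.axial_pixel_um,
        lateral_pixel_um=series.lateral_pixel_um,
        silicone_interface_row=interface_row)


def tissue_interior_mask(map_shape: tuple[int, int], interface_row: int,
                         axial_pixel_um: float, *,
                         margin_um: float = 120.0) -> np.ndarray:
    """Tissue region away from the silicone interface and the image bottom,
    where window truncation and material mixing bias the estimates; used
    when summarizing homogeneous-region statistics."""
    h, w = map_shape
    m = int(round(margin_um / axial_pixel_um))
    mask = np.zeros(map_shape, dtype=bool)
    mask[interface_row + m:h - m, :] = True
    return mask
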