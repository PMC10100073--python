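"""Mechanical phantoms and a forward model of compression-OCE acquisition.

The simulator emulates the study geometry: a pre-calibrated, linearly
elastic reference silicone layer resting on tissue whose tangent Young's
modulus may stiffen with stress,

    E_t(sigma) = E0 + beta * sigma        (kPa; beta dimensionless),

the simplest law reproducing the pronounced nonlinearity of real tissue
stress-strain curves.  Mechanics is a 1-D series stack per lateral column:
each column carries the full applied stress, so the local cumulative strain
under stress sigma is the closed-form integral

    eps(sigma) = int_0^sigma dE / E_t = log(1 + beta*sigma/E0) / beta,

reducing to sigma/E0 for a linear material.  Axial displacement is the
running depth integral of strain from the compressed top surface, and the
complex OCT field advances in phase by (4 pi n / lambda) * u(z).  Speckle
is a circular-Gaussian scatterer field scaled by per-class backscatter
amplitude and blurred by the instrument PSF (15 um axial x 25 um lateral
FWHM at 1310 nm); the speckle realization is frozen across frames so that
interframe decorrelation comes only from strain and additive noise, the
regime the phase-resolved method assumes.  Mucin-like regions scatter
nothing and contribute noise only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .strain import ComplexFrameSeries

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Mean tangent moduli (kPa) reported for colorectal tissue classes; used
#: as the phantom template defaults.
CLASS_MEAN_KPA = {
    "mucosa": 58.0,
    "submucosa": 43.0,
    "adenoma": 46.0,
    "stroma": 295.0,
    "gland": 724.0,
    "nonglandular": 954.0,
}


class StrainLimitError(ValueError):
    """Per-frame stress step too large for phase-resolved strain tracking."""


@dataclass(frozen=True)
class MechanicalClass:
    """A tissue (or mucin) class with its mechanical and optical behaviour.

    E0 is the tangent Young's modulus at zero stress in kPa; beta the
    dimensionless stiffening rate of E_t(sigma) = E0 + beta*sigma.
    scatter_amp in [0, 1] scales the backscattered amplitude; is_nonsignal
    marks mucin/lumen regions that return no useful signal (for those, E0
    is only displacement bookkeeping for the material below them).
    """

    label: int
    name: str
    E0: float
    beta: float = 0.0
    scatter_amp: float = 1.0
    is_nonsignal: bool = False

    def __post_init__(self) -> None:
        if self.label < 0 or self.label > 255:
            raise ValueError("label must fit in uint8")
        if self.E0 <= 0 and not self.is_nonsignal:
            raise ValueError(f"class {self.name!r}: E0 must be > 0")
        if self.beta < 0:
            raise ValueError(f"class {self.name!r}: beta must be >= 0")
        if not 0.0 <= self.scatter_amp <= 1.0:
            raise ValueError(f"class {self.name!r}: scatter_amp not in [0,1]")

    def tangent_modulus(self, stress_kpa: float) -> float:
        return self.E0 + self.beta * stress_kpa


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned rectangle in tissue coordinates (um; z from the
    silicone-tissue interface, x from the left image edge)."""

    x_um: float
    z_um: float
    width_um: float
    height_um: float

    def contains(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        return ((x >= self.x_um) & (x < self.x_um + self.width_um)
                & (z >= self.z_um) & (z < self.z_um + self.height_um))

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in tissue coordinates (um)."""

    cx_um: float
    cz_um: float
    rx_um: float
    rz_um: float

    def contains(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        return (((x - self.cx_um) / self.rx_um) ** 2
                + ((z - self.cz_um) / self.rz_um) ** 2) <= 1.0

    @property
    def area_um2(self) -> float:
        return math.pi * self.rx_um * self.rz_um


Shape = Union[Rectangle, Ellipse]

SILICONE_LABEL = 0
#: Backscatter amplitude of the reference silicone (scattering particles
#: are admixed so its strain can be tracked).
SILICONE_SCATTER_AMP = 0.8


@dataclass
class PhantomSpec:
    """Geometry and material layout of a silicone-tissue sandwich phantom.

    The silicone occupies exactly the topmost rows; `background` fills the
    tissue region and `shapes` are painted over it in order (later shapes
    overwrite earlier ones).  Shape coordinates are tissue coordinates in
    microns, z measured down from the silicone-tissue interface.
    """

    background: MechanicalClass
    shapes: Sequence[tuple[Shape, MechanicalClass]] = field(default_factory=list)
    depth_px: int = 500
    lateral_px: int = 512
    axial_pixel_um: float = 4.0
    lateral_pixel_um: float = 4.0
    silicone_thickness_um: float = 300.0
    E_sil: float = 100.0
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if self.depth_px < 2 or self.lateral_px < 1:
            raise ValueError("grid too small")
        if self.axial_pixel_um <= 0 or self.lateral_pixel_um <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.E_sil <= 0:
            raise ValueError("E_sil must be positive")
        if self.depth_px * self.axial_pixel_um > 2000.0 + 1e-9:
            raise ValueError("imaged depth exceeds the 2000 um scanning depth")
        if not (0 < self.silicone_thickness_um
                < self.depth_px * self.axial_pixel_um):
            raise ValueError("silicone thickness outside the imaged depth")
        if self.background.label == SILICONE_LABEL:
            raise ValueError(f"label {SILICONE_LABEL} is reserved for silicone")
        for _, cls in self.shapes:
            if cls.label == SILICONE_LABEL:
                raise ValueError(
                    f"label {SILICONE_LABEL} is reserved for silicone")

    @property
    def interface_row(self) -> int:
        """First tissue row; silicone occupies rows [0, interface_row)."""
        return int(round(self.silicone_thickness_um / self.axial_pixel_um))

    @property
    def tissue_depth_um(self) -> float:
        return (self.depth_px - self.interface_row) * self.axial_pixel_um


@dataclass
class Phantom:
    """Rasterized phantom: label map plus per-pixel mechanical fields."""

    spec: PhantomSpec
    label_map: np.ndarray        # uint8, SILICONE_LABEL in the top rows
    E0: np.ndarray               # kPa, float64
    beta: np.ndarray
    scatter_amp: np.ndarray
    is_nonsignal: np.ndarray     # bool
    classes: dict[int, MechanicalClass]

    @property
    def interface_row(self) -> int:
        return self.spec.interface_row

    def tangent_modulus_map(self, stress_kpa: float) -> np.ndarray:
        return self.E0 + self.beta * stress_kpa


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministically rasterize a phantom spec onto the pixel grid.

    A pixel belongs to a shape if its center lies inside the shape; later
    shapes overwrite earlier ones.  A shape that is geometrically empty, or
    whose footprint covers no pixel of the tissue region, is an error.
    """
    h, w = spec.depth_px, spec.lateral_px
    ir = spec.interface_row

    # pixel-center tissue coordinates
    x = (np.arange(w) + 0.5) * spec.lateral_pixel_um
    z = (np.arange(h) - ir + 0.5) * spec.axial_pixel_um
    xx, zz = np.meshgrid(x, z)
    tissue = np.zeros((h, w), dtype=bool)
    tissue[ir:, :] = True

    label_map = np.full((h, w), spec.background.label, dtype=np.uint8)
    label_map[:ir, :] = SILICONE_LABEL
    classes: dict[int, MechanicalClass] = {spec.background.label: spec.background}

    for idx, (shape, cls) in enumerate(spec.shapes):
        if shape.area_um2 <= 0:
            raise ValueError(f"shape #{idx} ({cls.name!r}) has zero area")
        inside = shape.contains(xx, zz) & tissue
        if not inside.any():
            raise ValueError(
                f"shape #{idx} ({cls.name!r}) lies outside the tissue grid")
        prev = classes.get(cls.label)
        if prev is not None and prev != cls:
            raise ValueError(
                f"label {cls.label} bound to two different classes")
        classes[cls.label] = cls
        label_map[inside] = cls.label

    silicone_cls = MechanicalClass(
        label=SILICONE_LABEL, name="silicone", E0=spec.E_sil, beta=0.0,
        scatter_amp=SILICONE_SCATTER_AMP)
    classes[SILICONE_LABEL] = silicone_cls

    E0 = np.empty((h, w))
    beta = np.empty((h, w))
    amp = np.empty((h, w))
    nonsig = np.zeros((h, w), dtype=bool)
    for label, cls in classes.items():
        sel = label_map == label
        # mucin needs a finite effective modulus for the displacement of
        # material beneath it; confined fluid pockets are given a nominal
        # stroma-like value when E0 is not meaningful
        E0[sel] = cls.E0 if cls.E0 > 0 else 150.0
        beta[sel] = cls.beta
        amp[sel] = cls.scatter_amp
        nonsig[sel] = cls.is_nonsignal

    return Phantom(spec=spec, label_map=label_map, E0=E0, beta=beta,
                   scatter_amp=amp, is_nonsignal=nonsig, classes=classes)


@dataclass
class AcquisitionSpec:
    """Acquisition protocol: frame count, loading, optics, noise, seed.

    Defaults follow the emulated instrument (1310 nm center wavelength,
    15 um axial / 25 um lateral FWHM resolution) and protocol (about a
    hundred frames acquired while compressing to a few kPa).
    """

    n_frames: int = 100
    max_stress_kPa: float = 6.0
    wavelength_um: float = 1.31
    psf_axial_um: float = 15.0
    psf_lateral_um: float = 25.0
    snr_db: float | None = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.max_stress_kPa < 0:
            raise ValueError("max_stress_kPa must be >= 0")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")


@dataclass
class GroundTruth:
    """Exact per-frame mechanics of a simulated acquisition."""

    stress_per_frame: np.ndarray          # (n_frames,) kPa, starts at 0
    true_cumulative_strain: np.ndarray    # (n_frames, H, W) float32
    true_stiffness_map: np.ndarray        # E_t at 4 kPa, kPa
    label_map: np.ndarray
    cancer_area_percent: float
    interface_row: int
    is_nonsignal: np.ndarray

    def tissue_mask(self) -> np.ndarray:
        m = np.zeros_like(self.label_map, dtype=bool)
        m[self.interface_row:, :] = True
        return m


def _cumulative_strain(E0: np.ndarray, beta: np.ndarray,
                       sigma: float) -> np.ndarray:
    """Closed-form eps(sigma) for the affine tangent-modulus law."""
    out = np.empty_like(E0)
    lin = beta == 0
    out[lin] = sigma / E0[lin]
    nl = ~lin
    out[nl] = np.log1p(beta[nl] * sigma / E0[nl]) / beta[nl]
    return out


def speckle_field(shape: tuple[int, int], scatter_amp: np.ndarray,
                  psf_axial_px: float, psf_lateral_px: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Fully developed speckle: circular-Gaussian scatterers scaled by the
    backscatter amplitude and blurred by a Gaussian PSF."""
    g = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    g = g * scatter_amp / math.sqrt(2.0)
    sa = psf_axial_px * FWHM_TO_SIGMA
    sl = psf_lateral_px * FWHM_TO_SIGMA
    return (gaussian_filter(g.real, sigma=(sa, sl))
            + 1j * gaussian_filter(g.imag, sigma=(sa, sl)))


def simulate_compression_series(
    phantom: Phantom,
    acq: AcquisitionSpec,
    *,
    standardized_stress_kPa: float = 4.0,
    cancer_threshold_kPa: float = 520.0,
) -> tuple[ComplexFrameSeries, GroundTruth]:
    """Simulate the complex OCT frame series of a compressed phantom.

    Stress rises linearly from 0 to max_stress_kPa over the frames.  Per
    frame, the cumulative strain of every pixel follows the closed-form
    series-stack solution, displacement is the depth integral of strain,
    and the frozen speckle field is advanced in phase accordingly; complex
    white Gaussian noise is added at snr_db relative to the mean signal
    power.  Raises StrainLimitError if any interframe strain of a signal
    pixel would exceed 1%, the tracking limit of the phase-gradient method.
    """
    spec = phantom.spec
    h, w = spec.depth_px, spec.lateral_px
    n = acq.n_frames
    stress = np.linspace(0.0, acq.max_stress_kPa, n)

    # interframe strain is largest at zero stress where E_t = E0 is smallest
    if n > 1 and acq.max_stress_kPa > 0:
        dstress = stress[1] - stress[0]
        relevant = ~phantom.is_nonsignal
        e_min = float(phantom.E0[relevant].min())
        worst = dstress / e_min
        if worst > 0.01 + 1e-12:
            raise StrainLimitError(
                f"interframe strain {worst:.3%} exceeds the 1% tracking "
                "limit; raise n_frames or lower max_stress_kPa")

    rng = np.random.default_rng(acq.seed)
    base = speckle_field(
        (h, w), phantom.scatter_amp,
        acq.psf_axial_um / spec.axial_pixel_um,
        acq.psf_lateral_um / spec.lateral_pixel_um, rng)

    signal = phantom.scatter_amp > 0.05
    p_signal = float(np.mean(np.abs(base[signal]) ** 2)) if signal.any() else 1.0
    if acq.snr_db is None or not np.isfinite(acq.snr_db):
        noise_std = 0.0
    else:
        noise_std = math.sqrt(p_signal * 10.0 ** (-acq.snr_db / 10.0) / 2.0)

    k_phase = 4.0 * math.pi * spec.refractive_index / acq.wavelength_um

    frames = np.empty((n, h, w), dtype=np.complex128)
    cum = np.empty((n, h, w), dtype=np.float32)
    for f in range(n):
        eps = _cumulative_strain(phantom.E0, phantom.beta, float(stress[f]))
        cum[f] = eps
        u = np.cumsum(eps, axis=0) * spec.axial_pixel_um
        frame = base * np.exp(1j * k_phase * u)
        if noise_std > 0:
            frame = frame + noise_std * (
                rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w)))
        frames[f] = frame

    series = ComplexFrameSeries(
        data=frames, wavelength_um=acq.wavelength_um,
        refractive_index=spec.refractive_index,
        axial_pixel_um=spec.axial_pixel_um,
        lateral_pixel_um=spec.lateral_pixel_um,
        silicone_interface_row=spec.interface_row)

    e_t4 = phantom.tangent_modulus_map(standardized_stress_kPa)
    tissue = np.zeros((h, w), dtype=bool)
    tissue[spec.interface_row:, :] = True
    cancer = tissue & ~phantom.is_nonsignal & (e_t4 >= cancer_threshold_kPa)
    cancer_pct = 100.0 * cancer.sum() / tissue.sum()

    truth = GroundTruth(
        stress_per_frame=stress,
        true_cumulative_strain=cum,
        true_stiffness_map=e_t4,
        label_map=phantom.label_map.copy(),
        cancer_area_percent=float(cancer_pct),
        interface_row=spec.interface_row,
        is_nonsignal=phantom.is_nonsignal.copy())
    return series, truth


# ---------------------------------------------------------------------------
# Cohort templates: synthetic stand-ins for the morphological subtypes
# ---------------------------------------------------------------------------

SUBTYPES = ("normal", "adenoma", "low_grade", "high_grade", "cribriform", "mac")

#: Expected subtype call for each phantom template (used to score the
#: end-to-end classifier).
TEMPLATE_EXPECTED_CALL = {
    "normal": "NON_CANCEROUS",
    "adenoma": "NON_CANCEROUS",
    "low_grade": "LOW_GRADE_CRAC",
    "high_grade": "HIGH_GRADE_CRAC",
    "cribriform": "CRAC_CRIBRIFORM",
    "mac": "MAC",
}

_MUCOSA = MechanicalClass(1, "mucosa", CLASS_MEAN_KPA["mucosa"], beta=1.0)
_ADENOMA = MechanicalClass(2, "adenoma", CLASS_MEAN_KPA["adenoma"], beta=1.0)
_STROMA = MechanicalClass(3, "stroma", CLASS_MEAN_KPA["stroma"], beta=3.0)
_GLAND = MechanicalClass(4, "gland", CLASS_MEAN_KPA["gland"], beta=8.0)
_NONGLAND = MechanicalClass(5, "nonglandular", CLASS_MEAN_KPA["nonglandular"],
                            beta=10.0)
_MUCIN = MechanicalClass(6, "mucin", 150.0, beta=0.0, scatter_amp=0.0,
                         is_nonsignal=True)


@dataclass
class CohortSample:
    series: ComplexFrameSeries
    truth: GroundTruth
    subtype: str


def _gland_positions(rng: np.random.Generator, width_um: float,
                     depth_lo: float, depth_hi: float, r_um: float,
                     n_wanted: int) -> list[tuple[float, float]]:
    """Jittered grid placement of non-overlapping gland centers."""
    pitch = 2.3 * r_um
    xs = np.arange(r_um * 1.2, width_um - r_um * 1.2, pitch)
    zs = np.arange(depth_lo, depth_hi, pitch)
    cells = [(cx, cz) for cz in zs for cx in xs]
    rng.shuffle(cells)
    out = []
    for cx, cz in cells[:n_wanted]:
        jx = rng.uniform(-0.1, 0.1) * pitch
        jz = rng.uniform(-0.1, 0.1) * pitch
        out.append((cx + jx, cz + jz))
    return out


def _template_shapes(subtype: str, cancer_fraction: float,
                     spec_geo: PhantomSpec, rng: np.random.Generator
                     ) -> tuple[MechanicalClass, list[tuple[Shape, MechanicalClass]]]:
    """Shape list realizing a morphological subtype at a target cancer
    area fraction (fraction of tissue area in the cancer stiffness range).
    Geometry follows the histology each template mimics: discrete stiff
    gland nests in stroma (low grade), a solid very-stiff field (high
    grade), wide-lumen stiff glands (cribriform), and mucin fields covering
    most of the shallow tissue with a small very-stiff nest (MAC)."""
    w_um = spec_geo.lateral_px * spec_geo.lateral_pixel_um
    t_um = spec_geo.tissue_depth_um
    tissue_area = w_um * t_um
    shapes: list[tuple[Shape, MechanicalClass]] = []

    if subtype == "normal":
        return _MUCOSA, shapes
    if subtype == "adenoma":
        return _ADENOMA, shapes

    if subtype == "high_grade":
        # one solid non-glandular field, full width if needed
        area = cancer_fraction * tissue_area
        height = min(area / (0.9 * w_um), t_um - 200.0)
        width = area / height if height > 0 else 0.0
        x0 = max(0.0, (w_um - width) / 2)
        shapes.append((Rectangle(x0, 120.0, width, height), _NONGLAND))
        return _STROMA, shapes

    if subtype == "low_grade":
        r = rng.uniform(140.0, 170.0)
        n_glands = max(2, int(round(cancer_fraction * tissue_area
                                    / (math.pi * r * r * 0.85))))
        pos = _gland_positions(rng, w_um, r + 80.0, t_um - r - 60.0, r,
                               n_glands)
        for cx, cz in pos:
            shapes.append((Ellipse(cx, cz, r, r * 0.85), _GLAND))
        return _STROMA, shapes

    if subtype == "cribriform":
        # wide-lumen glands: a stiff ring around a non-scattering lumen,
        # the lumen wide enough (>= the averaging window) to register as a
        # signal-void in the reconstructed map
        r = 240.0
        ring_area = math.pi * r * r * 0.85 * (1 - 0.6 ** 2)
        n_glands = max(2, int(round(cancer_fraction * tissue_area / ring_area)))
        pos = _gland_positions(rng, w_um, 300.0,
                               min(421.0, t_um - r - 60.0), r, n_glands)
        for cx, cz in pos:
            shapes.append((Ellipse(cx, cz, r, r * 0.85), _GLAND))
            shapes.append((Ellipse(cx, cz, r * 0.6, r * 0.85 * 0.6), _MUCIN))
        return _STROMA, shapes

    if subtype == "mac":
        # extracellular mucin dominating the shallow 500 um band, plus a
        # small cluster of very stiff cancer cells on a stromal wall
        shapes.append((Rectangle(0.0, 40.0, w_um, 380.0), _MUCIN))
        nest = rng.uniform(260.0, 300.0)
        cx = rng.uniform(nest, w_um - nest)
        shapes.append((Rectangle(cx - nest / 2, 470.0, nest, nest), _NONGLAND))
        return _STROMA, shapes

    raise ValueError(f"unknown subtype template {subtype!r}")


def template_phantom(subtype: str, cancer_fraction: float = 0.3,
                     seed: int = 0, *, depth_px: int = 350,
                     lateral_px: int = 320) -> Phantom:
    """Build one morphological-subtype phantom from its geometry template."""
    geo = PhantomSpec(background=_MUCOSA, depth_px=depth_px,
                      lateral_px=lateral_px)
    background, shapes = _template_shapes(subtype, cancer_fraction, geo,
                                          np.random.default_rng(seed))
    spec = PhantomSpec(background=background, shapes=shapes,
                       depth_px=depth_px, lateral_px=lateral_px)
    return build_phantom(spec)


def homogeneous_phantom(E0_kPa: float, beta: float = 0.0, *,
                        depth_px: int = 450, lateral_px: int = 256,
                        silicone_thickness_um: float = 300.0,
                        E_sil: float = 100.0) -> Phantom:
    """Uniform tissue of one mechanical class under the reference silicone
    (the parameter-recovery geometry)."""
    cls = MechanicalClass(1, "tissue", E0_kPa, beta=beta)
    spec = PhantomSpec(background=cls, depth_px=depth_px,
                       lateral_px=lateral_px,
                       silicone_thickness_um=silicone_thickness_um,
                       E_sil=E_sil)
    return build_phantom(spec)


_DEFAULT_MIX = {"normal": 0.2, "adenoma": 0.1, "low_grade": 0.3,
                "high_grade": 0.2, "cribriform": 0.1, "mac": 0.1}

#: Per-template range of achievable cancer-area fractions (discrete gland
#: nests cannot tile 80% of the tissue; solid high-grade fields can).
_TEMPLATE_FRACTION_RANGE = {
    "normal": (0.0, 0.0),
    "adenoma": (0.0, 0.0),
    "low_grade": (0.10, 0.50),
    "high_grade": (0.15, 1.0),
    "cribriform": (0.08, 0.35),
    "mac": (0.03, 0.08),
}


def make_cohort(
    n_samples: int,
    class_mix: dict[str, float] | None = None,
    cancer_fraction_range: tuple[float, float] = (0.0, 0.8),
    seed: int = 0,
    *,
    depth_px: int = 350,
    lateral_px: int = 320,
    n_frames: int = 60,
    max_stress_kPa: float = 6.0,
    snr_db: float | None = 25.0,
) -> list[CohortSample]:
    """Generate a reproducible cohort of subtype phantoms with simulated
    acquisitions and exact ground truth.

    Subtypes are drawn from `class_mix`; cancer-bearing samples get target
    cancer-area fractions spanning `cancer_fraction_range` (clipped to what
    each template's geometry can realize).  The returned ground-truth
    cancer percentages are recounted from the rasterized label maps, not
    from the targets.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mix = dict(_DEFAULT_MIX if class_mix is None else class_mix)
    if not mix:
        raise ValueError("class_mix is empty")
    for k in mix:
        if k not in SUBTYPES:
            raise ValueError(f"unknown subtype {k!r} in class_mix")
    lo, hi = cancer_fraction_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("cancer_fraction_range must be within [0, 1]")

    rng = np.random.default_rng(seed)
    names = sorted(mix)
    probs = np.array([mix[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    subtypes = [names[i] for i in rng.choice(len(names), size=n_samples,
                                             p=probs)]

    # spread target fractions evenly over the requested range across the
    # cancer-bearing samples so the cohort spans it
    bearing = [i for i, s in enumerate(subtypes)
               if _TEMPLATE_FRACTION_RANGE[s][1] > 0]
    targets = np.full(n_samples, 0.0)
    if bearing:
        grid = np.linspace(max(lo, 0.05), hi if hi > 0 else 0.05,
                           len(bearing))
        rng.shuffle(grid)
        for i, t in zip(bearing, grid):
            tlo, thi = _TEMPLATE_FRACTION_RANGE[subtypes[i]]
            targets[i] = float(np.clip(t, tlo, thi))

    out: list[CohortSample] = []
    for i, subtype in enumerate(subtypes):
        sample_seed = int(rng.integers(0, 2 ** 31 - 1))
        geo = PhantomSpec(background=_MUCOSA, depth_px=depth_px,
                          lateral_px=lateral_px)
        background, shapes = _template_shapes(
            subtype, targets[i], geo, np.random.default_rng(sample_seed))
        spec = PhantomSpec(background=background, shapes=shapes,
                           depth_px=depth_px, lateral_px=lateral_px)
        phantom = build_phantom(spec)
        acq = AcquisitionSpec(n_frames=n_frames, max_stress_kPa=max_stress_kPa,
                              snr_db=snr_db, seed=sample_seed)
        series, truth = simulate_compression_series(phantom, acq)
        out.append(CohortSample(series=series, truth=truth, subtype=subtype))
    return out
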