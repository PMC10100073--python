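"""Stiffness-threshold segmentation and morphological subtype calling.

Colorectal tissue classes separate by tangent Young's modulus at 4 kPa:
cancer cells occupy 520-1418 kPa (520-950 kPa for gland-like structures of
low-grade adenocarcinoma, >950 kPa for the non-glandular foci of high-grade
tumors), tumor stroma 92-515 kPa, and normal mucosa/submucosa/adenoma sit
below that.  Pixels with stiffness under 1 kPa, or with no valid stiffness
estimate at all, are non-signal (mucin, wide gland lumina).  A small
decision table over four image-level features -- presence of the 520-950
and >950 kPa classes, discrete gland-like stiff nests, and the non-signal
area fraction of the shallow 500 um of tissue -- assigns the morphological
subtype call.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, model_validator
from skimage import measure

from .stiffness import StiffnessMap


class TissueClass(enum.IntEnum):
    NON_SIGNAL = 0
    LOW = 1          # mucosa / submucosa / adenoma range
    STROMA = 2
    CANCER_GLAND = 3  # 520-950 kPa, gland-like (glandular cancer)
    VERY_HIGH = 4     # >950 kPa, non-glandular cancer


class Subtype(str, enum.Enum):
    NON_CANCEROUS = "NON_CANCEROUS"
    LOW_GRADE_CRAC = "LOW_GRADE_CRAC"
    HIGH_GRADE_CRAC = "HIGH_GRADE_CRAC"
    CRAC_CRIBRIFORM = "CRAC_CRIBRIFORM"
    MAC = "MAC"
    INDETERMINATE = "INDETERMINATE"


class ClassRanges(BaseModel):
    """Stiffness class boundaries in kPa.

    Intervals are upper-exclusive except the cancer-gland class, which is
    closed at cancer_high; the printed 515-520 kPa gap between the stroma
    maximum and the cancer minimum is assigned to stroma (conservative
    toward fewer false cancer calls).
    """

    model_config = {"extra": "forbid", "frozen": True}

    signal_floor: float = 1.0
    stroma_min: float = 92.0
    stroma_max: float = 515.0
    cancer_low: float = 520.0
    cancer_high: float = 950.0
    cancer_max: float = 1418.0

    @model_validator(mode="after")
    def _ordered(self) -> "ClassRanges":
        if not (0 < self.signal_floor < self.stroma_min < self.stroma_max
                < self.cancer_low < self.cancer_high <= self.cancer_max):
            raise ValueError("class boundaries out of order")
        return self


@dataclass
class ClassMap:
    """Per-pixel tissue class with geometry metadata."""

    classes: np.ndarray            # uint8 of TissueClass
    axial_pixel_um: float
    lateral_pixel_um: float
    tissue_top_row: int = 0        # first tissue row (silicone excluded)

    @property
    def pixel_area_um2(self) -> float:
        return self.axial_pixel_um * self.lateral_pixel_um

    def tissue_region(self) -> np.ndarray:
        return self.classes[self.tissue_top_row:, :]


@dataclass
class FeatureVector:
    """Image-level features feeding the subtype decision table."""

    has_520_950: bool
    has_gt950: bool
    has_gland_like: bool
    nonsignal_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonsignal_fraction <= 1.0:
            raise ValueError("nonsignal_fraction must be in [0, 1]")


@dataclass
class SubtypeCall:
    call: Subtype
    features: FeatureVector
    cancer_area_percent: float


def classify_pixels(stiffness: StiffnessMap | np.ndarray,
                    ranges: ClassRanges | None = None,
                    *,
                    signal_mask: np.ndarray | None = None,
                    axial_pixel_um: float = 4.0,
                    lateral_pixel_um: float = 4.0,
                    tissue_top_row: int | None = None) -> ClassMap:
    """Assign every pixel to exactly one stiffness class.

    [signal_floor, stroma_min) -> LOW, [stroma_min, cancer_low) -> STROMA,
    [cancer_low, cancer_high] -> CANCER_GLAND, (cancer_high, inf) ->
    VERY_HIGH; masked pixels and values below the signal floor ->
    NON_SIGNAL.
    """
    ranges = ranges or ClassRanges()
    if isinstance(stiffness, StiffnessMap):
        values = stiffness.values
        mask = stiffness.signal_mask if signal_mask is None else signal_mask
        axial_pixel_um = stiffness.axial_pixel_um
        lateral_pixel_um = stiffness.lateral_pixel_um
        if tissue_top_row is None:
            tissue_top_row = stiffness.silicone_interface_row or 0
    else:
        values = np.asarray(stiffness, dtype=float)
        mask = (np.ones(values.shape, dtype=bool)
                if signal_mask is None else np.asarray(signal_mask, bool))
        tissue_top_row = tissue_top_row or 0

    cls = np.full(values.shape, TissueClass.NON_SIGNAL, dtype=np.uint8)
    sig = mask & (values >= ranges.signal_floor)
    cls[sig & (values < ranges.stroma_min)] = TissueClass.LOW
    cls[sig & (values >= ranges.stroma_min)
        & (values < ranges.cancer_low)] = TissueClass.STROMA
    cls[sig & (values >= ranges.cancer_low)
        & (values <= ranges.cancer_high)] = TissueClass.CANCER_GLAND
    cls[sig & (values > ranges.cancer_high)] = TissueClass.VERY_HIGH
    return ClassMap(classes=cls, axial_pixel_um=axial_pixel_um,
                    lateral_pixel_um=lateral_pixel_um,
                    tissue_top_row=int(tissue_top_row))


@dataclass
class Component:
    label: int
    area_um2: float
    n_pixels: int


def _components_of(class_map: ClassMap, tissue_class: TissueClass,
                   min_area_um2: float) -> list[Component]:
    tissue = class_map.tissue_region()
    labeled = measure.label(tissue == tissue_class, connectivity=2)
    out = []
    for region_label in range(1, labeled.max() + 1):
        n_px = int((labeled == region_label).sum())
        area = n_px * class_map.pixel_area_um2
        if area >= min_area_um2:
            out.append(Component(label=region_label, area_um2=area,
                                 n_pixels=n_px))
    return out


def gland_like_components(class_map: ClassMap,
                          min_area_um2: float = 110.0 * 110.0,
                          *,
                          max_coverage: float = 0.7
                          ) -> tuple[list[Component], bool]:
    """Discrete stiff nests in a softer background.

    Components are 8-connected regions of CANCER_GLAND pixels of at least
    one analysis ROI (110x110 um) in area.  "Gland-like structures present"
    requires at least two such nests covering together less than
    `max_coverage` of the signal area -- a contiguous stiff field is the
    signature of high-grade tumors, not of gland-like architecture.
    """
    comps = _components_of(class_map, TissueClass.CANCER_GLAND, min_area_um2)
    tissue = class_map.tissue_region()
    signal_px = int((tissue != TissueClass.NON_SIGNAL).sum())
    gland_px = int((tissue == TissueClass.CANCER_GLAND).sum())
    coverage = gland_px / signal_px if signal_px else 0.0
    has_gland_like = len(comps) >= 2 and coverage < max_coverage
    return comps, has_gland_like


def nonsignal_fraction(class_map: ClassMap,
                       depth_limit_um: float = 500.0) -> float:
    """Fraction of the shallow tissue ROI that carries no signal.

    Counted over the tissue rows within `depth_limit_um` of the
    silicone-tissue interface (the depth beyond which even scattering
    tissue rarely returns signal); the fraction is of *total* ROI area,
    matching the >=50%-of-tissue-area criterion for mucinous tumors.
    """
    rows = int(round(depth_limit_um / class_map.axial_pixel_um))
    top = class_map.tissue_top_row
    band = class_map.classes[top:min(top + rows, class_map.classes.shape[0])]
    if band.size == 0:
        raise ValueError("empty ROI: depth limit leaves no tissue rows")
    return float((band == TissueClass.NON_SIGNAL).sum() / band.size)


def subtype_call(features: FeatureVector) -> SubtypeCall:
    """Morphological subtype from the decision table.

    Evaluated in order: no cancer-range stiffness at all -> NON_CANCEROUS;
    signal loss over half the shallow ROI -> MAC when very-high stiffness
    is present without gland-like architecture, otherwise INDETERMINATE;
    partial signal loss with gland-like nests and no very-high stiffness ->
    cribriform pattern; gland-like nests alone -> low-grade CRAC; very-high
    stiffness alone -> high-grade CRAC; anything else is INDETERMINATE
    rather than a forced call.
    """
    f = features
    loss = f.nonsignal_fraction
    if not f.has_520_950 and not f.has_gt950:
        call = Subtype.NON_CANCEROUS
    elif loss > 0.5:
        call = (Subtype.MAC if f.has_gt950 and not f.has_gland_like
                else Subtype.INDETERMINATE)
    elif loss > 0.0 and f.has_gland_like and not f.has_gt950:
        call = Subtype.CRAC_CRIBRIFORM
    elif f.has_gland_like and not f.has_gt950:
        call = Subtype.LOW_GRADE_CRAC
    elif f.has_gt950 and not f.has_gland_like and loss == 0.0:
        call = Subtype.HIGH_GRADE_CRAC
    else:
        call = Subtype.INDETERMINATE
    return SubtypeCall(call=call, features=f, cancer_area_percent=float("nan"))


def cancer_area_percent(class_map: ClassMap) -> float:
    """Percent of the tissue region (silicone excluded) in cancer classes."""
    tissue = class_map.tissue_region()
    if tissue.size == 0:
        raise ValueError("class map has no tissue rows")
    cancer = ((tissue == TissueClass.CANCER_GLAND)
              | (tissue == TissueClass.VERY_HIGH))
    return float(100.0 * cancer.sum() / tissue.size)


def extract_features(class_map: ClassMap,
                     *,
                     min_roi_area_um2: float = 110.0 * 110.0,
                     min_gland_area_um2: float = 110.0 * 110.0,
                     gland_max_coverage: float = 0.7,
                     depth_limit_um: float = 500.0,
                     loss_floor: float = 0.02) -> FeatureVector:
    """Image-level features from a class map.

    Class presence requires at least one full analysis ROI (110x110 um) of
    contiguous pixels of that class, not a single speckle outlier.
    Non-signal fractions below `loss_floor` are reported as zero: isolated
    dropout pixels are estimator noise, not mucin or lumina.
    """
    has_520 = bool(_components_of(class_map, TissueClass.CANCER_GLAND,
                                  min_roi_area_um2))
    has_hi = bool(_components_of(class_map, TissueClass.VERY_HIGH,
                                 min_roi_area_um2))
    _, gland_like = gland_like_components(class_map, min_gland_area_um2,
                                          max_coverage=gland_max_coverage)
    loss = nonsignal_fraction(class_map, depth_limit_um)
    if loss < loss_floor:
        loss = 0.0
    return FeatureVector(has_520_950=has_520, has_gt950=has_hi,
                         has_gland_like=gland_like, nonsignal_fraction=loss)


def analyze_class_map(class_map: ClassMap, **feature_kwargs) -> SubtypeCall:
    """Features + decision table + cancer-area morphometry in one step."""
    features = extract_features(class_map, **feature_kwargs)
    call = subtype_call(features)
    call.cancer_area_percent = cancer_area_percent(class_map)
    return call


def is_cancerous(class_map: ClassMap,
                 min_roi_area_um2: float = 110.0 * 110.0) -> bool:
    """Sample-level cancer flag: one full analysis ROI of contiguous
    cancer-range (>= 520 kPa) pixels anywhere in the tissue."""
    tissue = class_map.tissue_region()
    cancer = ((tissue == TissueClass.CANCER_GLAND)
              | (tissue == TissueClass.VERY_HIGH))
    labeled = measure.label(cancer, connectivity=2)
    if labeled.max() == 0:
        return False
    areas = np.bincount(labeled.ravel())[1:] * class_map.pixel_area_um2
    return bool((areas >= min_roi_area_um2).any())
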