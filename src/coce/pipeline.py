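"""End-to-end orchestration: frames -> stiffness -> classes -> call.

Thin glue over the module API, shared by the command-line interface, the
tests and the acceptance runs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .segmentation import ClassMap, SubtypeCall, analyze_class_map, \
    classify_pixels, is_cancerous
from .stiffness import StiffnessMap, reconstruct_stiffness
from .strain import ComplexFrameSeries


@dataclass
class SampleResult:
    stiffness: StiffnessMap
    class_map: ClassMap
    call: SubtypeCall
    cancerous: bool


def reconstruct(series: ComplexFrameSeries,
                config: PipelineConfig | None = None) -> StiffnessMap:
    config = config or PipelineConfig()
    return reconstruct_stiffness(
        series,
        E_sil=config.E_sil_kPa,
        window_axial_um=config.window_axial_um,
        window_lateral_um=config.window_lateral_um,
        axial_lag_px=config.axial_lag_px,
        stress_window_kPa=config.stress_window_kPa,
        standardized_stress_kPa=config.standardized_stress_kPa,
        max_modulus_kPa=config.max_modulus_kPa,
        per_column_stress=config.per_column_stress)


def segment(stiffness: StiffnessMap,
            config: PipelineConfig | None = None
            ) -> tuple[ClassMap, SubtypeCall, bool]:
    config = config or PipelineConfig()
    class_map = classify_pixels(stiffness, config.class_ranges)
    call = analyze_class_map(
        class_map,
        min_roi_area_um2=config.min_roi_area_um2,
        min_gland_area_um2=config.min_gland_area_um2,
        gland_max_coverage=config.gland_max_coverage,
        depth_limit_um=config.depth_limit_um,
        loss_floor=config.loss_floor)
    return class_map, call, is_cancerous(class_map, config.min_roi_area_um2)


def run_sample(series: ComplexFrameSeries,
               config: PipelineConfig | None = None) -> SampleResult:
    """Full reconstruction and morphological analysis of one acquisition."""
    stiffness = reconstruct(series, config)
    class_map, call, cancerous = segment(stiffness, config)
    return SampleResult(stiffness=stiffness, class_map=class_map, call=call,
                        cancerous=cancerous)
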