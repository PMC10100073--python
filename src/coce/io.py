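"""File formats: HDF5 frame containers, TIFF float maps, PNG class maps.

One container format holds a complex frame series losslessly (real and
imaginary parts as float64 datasets plus the optical metadata as
attributes); 32-bit float TIFFs with JSON sidecars carry stiffness and
strain maps; 8-bit paletted PNGs carry categorical maps with a fixed
legend.  None of these choices is mandated by the method -- they are for
interoperability.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
from PIL import Image

from .segmentation import ClassMap, TissueClass
from .stiffness import StiffnessMap
from .strain import ComplexFrameSeries

_SERIES_ATTRS = ("wavelength_um", "refractive_index", "axial_pixel_um",
                 "lateral_pixel_um")


def write_series(series: ComplexFrameSeries, path: str | Path,
                 *, stress_truth: np.ndarray | None = None) -> None:
    """Write a complex frame series to an HDF5 container (lossless)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames_real", data=series.data.real)
        h5.create_dataset("frames_imag", data=series.data.imag)
        if stress_truth is not None:
            h5.create_dataset("stress_truth", data=np.asarray(stress_truth))
        for name in _SERIES_ATTRS:
            h5.attrs[name] = getattr(series, name)
        if series.silicone_interface_row is not None:
            h5.attrs["silicone_interface_row"] = int(
                series.silicone_interface_row)


def read_series(path: str | Path
                ) -> tuple[ComplexFrameSeries, np.ndarray | None]:
    """Read a frame series container; returns (series, stress_truth)."""
    with h5py.File(path, "r") as h5:
        for name in ("frames_real", "frames_imag"):
            if name not in h5:
                raise ValueError(f"container missing dataset {name!r}")
        for name in _SERIES_ATTRS:
            if name not in h5.attrs:
                raise ValueError(f"container missing attribute {name!r}")
        data = h5["frames_real"][()] + 1j * h5["frames_imag"][()]
        kwargs = {name: float(h5.attrs[name]) for name in _SERIES_ATTRS}
        row = h5.attrs.get("silicone_interface_row")
        stress = h5["stress_truth"][()] if "stress_truth" in h5 else None
    series = ComplexFrameSeries(
        data=data, silicone_interface_row=None if row is None else int(row),
        **kwargs)
    return series, stress


def write_stiffness(stiff: StiffnessMap, path: str | Path) -> None:
    """32-bit float TIFF (kPa; masked pixels NaN) plus a JSON sidecar."""
    path = Path(path)
    values = stiff.values.astype(np.float32).copy()
    values[~stiff.signal_mask] = np.nan
    tifffile.imwrite(path, values)
    sidecar = {
        "standardized_stress_kPa": stiff.standardized_stress_kPa,
        "stress_window_kPa": list(stiff.stress_window_kPa),
        "axial_pixel_um": stiff.axial_pixel_um,
        "lateral_pixel_um": stiff.lateral_pixel_um,
        "silicone_interface_row": stiff.silicone_interface_row,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))


def read_stiffness(path: str | Path) -> StiffnessMap:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=np.float64)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    mask = np.isfinite(values)
    values = np.where(mask, values, 0.0)
    row = sidecar.get("silicone_interface_row")
    return StiffnessMap(
        values=values, signal_mask=mask,
        standardized_stress_kPa=sidecar["standardized_stress_kPa"],
        stress_window_kPa=tuple(sidecar["stress_window_kPa"]),
        axial_pixel_um=sidecar["axial_pixel_um"],
        lateral_pixel_um=sidecar["lateral_pixel_um"],
        silicone_interface_row=None if row is None else int(row))


#: Fixed class-map legend: white = non-signal, red tones = soft tissue,
#: turquoise = gland-range cancer, blue = very high stiffness.
CLASS_PALETTE = {
    TissueClass.NON_SIGNAL: (255, 255, 255),
    TissueClass.LOW: (214, 69, 65),
    TissueClass.STROMA: (239, 154, 108),
    TissueClass.CANCER_GLAND: (64, 199, 194),
    TissueClass.VERY_HIGH: (38, 84, 198),
}


def write_class_png(class_map: ClassMap, path: str | Path) -> None:
    """8-bit paletted PNG with the fixed legend, plus a JSON sidecar."""
    path = Path(path)
    img = Image.fromarray(class_map.classes, mode="P")
    palette = [0] * (256 * 3)
    for cls, rgb in CLASS_PALETTE.items():
        palette[cls * 3:cls * 3 + 3] = rgb
    img.putpalette(palette)
    img.save(path)
    sidecar = {
        "axial_pixel_um": class_map.axial_pixel_um,
        "lateral_pixel_um": class_map.lateral_pixel_um,
        "tissue_top_row": class_map.tissue_top_row,
        "legend": {TissueClass(c).name: list(rgb)
                   for c, rgb in CLASS_PALETTE.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))


def read_class_png(path: str | Path) -> ClassMap:
    path = Path(path)
    classes = np.asarray(Image.open(path), dtype=np.uint8)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ClassMap(classes=classes,
                    axial_pixel_um=sidecar["axial_pixel_um"],
                    lateral_pixel_um=sidecar["lateral_pixel_um"],
                    tissue_top_row=sidecar["tissue_top_row"])


def write_float_tiff(values: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))


def write_label_png(label_map: np.ndarray, path: str | Path) -> None:
    img = Image.fromarray(np.asarray(label_map, dtype=np.uint8), mode="P")
    rng = np.random.default_rng(12)  # fixed, palette is cosmetic
    palette = list(rng.integers(40, 255, size=256 * 3, dtype=np.uint8))
    palette[0:3] = [230, 230, 230]
    img.putpalette(palette)
    img.save(path)


def render_stiffness_png(stiff: StiffnessMap, path: str | Path,
                         *, vmax_kPa: float = 1400.0) -> None:
    """Render a stiffness map with the low=red, high=turquoise/blue palette
    used for elastograms of this tissue; non-signal pixels are white."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "coce", ["#8e1b12", "#d64541", "#ef9a6c", "#f2d184",
                 "#40c7c2", "#2654c6"])
    v = np.clip(stiff.values / vmax_kPa, 0.0, 1.0)
    rgba = (cmap(v)[:, :, :3] * 255).astype(np.uint8)
    rgba[~stiff.signal_mask] = (255, 255, 255)
    Image.fromarray(rgba, mode="RGB").save(path)
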