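"""File I/O: HDF5 depth-time maps, CSV spectra and study tables, TIFF images,
and key-value calibration files."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .brillouin import BrillouinSpectrum, SpectralCalibration
from .oce import SpatioTemporalMap
from .study import STUDY_COLUMNS, validate_study_table

__all__ = [
    "save_map_h5",
    "load_map_h5",
    "save_spectrum_csv",
    "load_spectrum_csv",
    "save_calibration",
    "load_calibration",
    "save_study_csv",
    "load_study_csv",
    "save_image_tiff",
    "load_image_tiff",
]

_MAP_ATTRS = ("kind", "axial_pitch_um", "frame_interval_s", "center_wavelength_nm", "refractive_index")


def save_map_h5(m: SpatioTemporalMap, path, dataset: str = "map") -> None:
    """Write a depth-time map to HDF5: one dataset plus attribute metadata."""
    with h5py.File(path, "a") as f:
        if dataset in f:
            del f[dataset]
        d = f.create_dataset(dataset, data=m.values)
        for name in _MAP_ATTRS:
            value = getattr(m, name)
            if value is not None:
                d.attrs[name] = value
        d.attrs["metadata_json"] = json.dumps(m.metadata)


def load_map_h5(path, dataset: str = "map") -> SpatioTemporalMap:
    with h5py.File(path, "r") as f:
        d = f[dataset]
        values = d[()]
        attrs = dict(d.attrs)
    meta = json.loads(attrs.pop("metadata_json", "{}"))
    return SpatioTemporalMap(
        values=values,
        kind=str(attrs["kind"]),
        axial_pitch_um=float(attrs["axial_pitch_um"]),
        frame_interval_s=float(attrs["frame_interval_s"]),
        center_wavelength_nm=float(attrs["center_wavelength_nm"]) if "center_wavelength_nm" in attrs else None,
        refractive_index=float(attrs["refractive_index"]) if "refractive_index" in attrs else None,
        metadata=meta,
    )


def save_spectrum_csv(spectrum: BrillouinSpectrum, path) -> None:
    pd.DataFrame(
        {"pixel": np.arange(spectrum.n_pixels), "intensity": spectrum.intensity}
    ).to_csv(path, index=False)


def load_spectrum_csv(path, label: str = "") -> BrillouinSpectrum:
    df = pd.read_csv(path)
    return BrillouinSpectrum(intensity=df["intensity"].to_numpy(dtype=float), label=label or Path(path).stem)


def save_calibration(cal: SpectralCalibration, path) -> None:
    """Key-value text file: dispersion, FSR, anchor, residuals per material."""
    lines = [
        f"dispersion_ghz_per_px = {cal.dispersion_ghz_per_px!r}",
        f"free_spectral_range_ghz = {cal.free_spectral_range_ghz!r}",
        f"order_anchor_px = {cal.order_anchor_px!r}",
        f"residual_rms_ghz = {cal.residual_rms_ghz!r}",
        f"high_residual_warning = {cal.high_residual_warning}",
        "materials = " + ",".join(cal.materials_used),
    ]
    for name, r in cal.residuals_ghz.items():
        lines.append(f"residual[{name}] = {r!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_calibration(path) -> SpectralCalibration:
    fields: dict = {}
    residuals: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("residual[") and key.endswith("]"):
            residuals[key[len("residual["):-1]] = float(value)
        elif key == "materials":
            fields["materials_used"] = value.split(",") if value else []
        elif key == "high_residual_warning":
            fields["high_residual_warning"] = value == "True"
        else:
            fields[key] = float(value)
    return SpectralCalibration(residuals_ghz=residuals, **fields)


def save_study_csv(table: pd.DataFrame, path) -> None:
    validate_study_table(table)[STUDY_COLUMNS].to_csv(path, index=False)


def load_study_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["day"] = table["day"].astype(int)
    return validate_study_table(table)


def save_image_tiff(pixels: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(pixels, dtype=np.float32))


def load_image_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)
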