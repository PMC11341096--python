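"""Reading and writing stacks, maps, masks and object tables.

File conventions
----------------
* An input stack is a 4-page TIFF or OME-TIFF; page order maps to the
  excitation polarization sequence as page ``i`` <-> ``45*i`` degrees
  (0, 45, 90, 135). This convention is fixed, not configurable.
* Pixelwise maps (S0, order, azimuth) are written as 32-bit float
  single-page TIFFs; the azimuth map is stored in **radians** in
  [-pi/2, pi/2) with NaN at pixels where the direction is undefined.
  Degrees appear only at the reporting surface (CSV, CLI).
* Masks are 8-bit TIFFs with background 0 and foreground 255.
* Object tables are UTF-8 CSV with '.' as the decimal separator.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import TYPE_CHECKING, Dict, Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import FPMStack, FlatFieldStack, StackFormatError

if TYPE_CHECKING:  # pragma: no cover
    from .features import FPMObject
    from .stats import PixelMaps

__all__ = [
    "read_fpm_stack",
    "write_fpm_stack",
    "read_flat_field_stack",
    "write_maps",
    "read_map",
    "write_mask",
    "read_mask",
    "OBJECT_TABLE_COLUMNS",
    "write_object_table",
    "write_midline_table",
]


def _read_pages(path: os.PathLike | str) -> np.ndarray:
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise StackFormatError(f"{path}: expected a multi-page grayscale TIFF")
    return data


def read_fpm_stack(
    path: os.PathLike | str, pixel_size: float = 1.0, name: str | None = None
) -> FPMStack:
    """Read a 4-page (OME-)TIFF as an FPM stack.

    Pages are mapped to polarization angles in file order:
    page 0 -> 0 deg, 1 -> 45, 2 -> 90, 3 -> 135. Values are cast to float.
    """
    data = _read_pages(path)
    if data.shape[0] != 4:
        raise StackFormatError(
            f"{path}: an FPM stack must have exactly 4 pages, found {data.shape[0]}"
        )
    return FPMStack(
        data.astype(float),
        pixel_size=pixel_size,
        name=name if name is not None else Path(path).stem,
    )


def write_fpm_stack(stack: FPMStack, path: os.PathLike | str) -> Path:
    """Write a stack as a 4-page float32 OME-TIFF (page i <-> 45*i deg)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.images.astype(np.float32),
        photometric="minisblack",
        ome=str(path).endswith(".ome.tif"),
    )
    return path


def read_flat_field_stack(path: os.PathLike | str) -> FlatFieldStack:
    """Read a 4-page TIFF as a flat-field calibration stack."""
    data = _read_pages(path)
    if data.shape[0] != 4:
        raise StackFormatError(
            f"{path}: a flat-field stack must have exactly 4 pages, found {data.shape[0]}"
        )
    return FlatFieldStack(data.astype(float))


def write_maps(maps: "PixelMaps", directory: os.PathLike | str) -> Dict[str, Path]:
    """Write S0/order/azimuth (and custom) maps as float32 TIFFs.

    Undefined pixels (NaN in order or azimuth) are written as NaN.
    Returns a manifest mapping map name -> file path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rasters: Dict[str, np.ndarray] = {
        "S0": maps.S0,
        "order": maps.order,
        "azimuth": maps.azimuth,
    }
    for cname, raster in maps.custom.items():
        rasters[f"custom_{cname}"] = raster
    manifest: Dict[str, Path] = {}
    for mname, raster in rasters.items():
        out = directory / f"{mname}.tif"
        tifffile.imwrite(out, np.asarray(raster, dtype=np.float32))
        manifest[mname] = out
    return manifest


def read_map(path: os.PathLike | str) -> np.ndarray:
    """Read back a single-page float map written by :func:`write_maps`."""
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise StackFormatError(f"{path}: expected a single-page map")
    return np.asarray(data)


def write_mask(mask: np.ndarray, path: os.PathLike | str) -> Path:
    """Write a binary mask as an 8-bit TIFF (0 background / 255 foreground)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path


def read_mask(path: os.PathLike | str) -> np.ndarray:
    data = tifffile.imread(path)
    return np.asarray(data) > 0


#: fixed object-table schema; custom statistics append `custom_<name>` columns
OBJECT_TABLE_COLUMNS = [
    "group",
    "image",
    "object_id",
    "area",
    "perimeter",
    "eccentricity",
    "length_um",
    "mean_intensity",
    "local_sb",
    "mean_order",
    "mean_azimuth_image",
    "mean_azimuth_midline",
    "azimuth_std",
    "label",
    "cluster",
]


def objects_to_frame(objects: Sequence["FPMObject"]) -> pd.DataFrame:
    """Assemble the object table (one row per object, fixed schema)."""
    rows = []
    custom_names: list[str] = []
    for obj in objects:
        for cname in obj.custom_means:
            if cname not in custom_names:
                custom_names.append(cname)
    for obj in objects:
        row = {
            "group": obj.group,
            "image": obj.image,
            "object_id": obj.id,
            "area": obj.area,
            "perimeter": obj.perimeter,
            "eccentricity": obj.eccentricity,
            "length_um": obj.length_um,
            "mean_intensity": obj.mean_intensity,
            "local_sb": obj.local_sb,
            "mean_order": obj.mean_order,
            "mean_azimuth_image": obj.mean_azimuth_image,
            "mean_azimuth_midline": obj.mean_azimuth_midline,
            "azimuth_std": obj.azimuth_std,
            "label": obj.group_label,
            "cluster": obj.cluster_id,
        }
        for cname in custom_names:
            row[f"custom_{cname}"] = obj.custom_means.get(cname, np.nan)
        rows.append(row)
    columns = OBJECT_TABLE_COLUMNS + [f"custom_{c}" for c in custom_names]
    return pd.DataFrame(rows, columns=columns)


def write_object_table(objects: Sequence["FPMObject"], path: os.PathLike | str) -> int:
    """Write the per-object CSV; returns the number of data rows written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = objects_to_frame(objects)
    frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return len(frame)


def write_midline_table(objects: Iterable["FPMObject"], path: os.PathLike | str) -> int:
    """Export midlines as CSV polylines (object id, point index, x, y, tangent)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for obj in objects:
        if obj.midline is None or not obj.midline.valid:
            continue
        for i, ((x, y), tangent) in enumerate(
            zip(obj.midline.points, obj.midline.tangents_deg)
        ):
            rows.append(
                {"object_id": obj.id, "point": i, "x": x, "y": y, "tangent_deg": tangent}
            )
    frame = pd.DataFrame(rows, columns=["object_id", "point", "x", "y", "tangent_deg"])
    frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return len(frame)
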