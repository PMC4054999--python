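"""Reading and writing calibrated binary section masks.

Masks are single-channel rasters (0 = background, nonzero = foreground) in
TIFF or PNG; physical calibration (pixel size, vertical axis, section
thickness/position) travels in a JSON sidecar next to the masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .counting import SectionImage

__all__ = ["read_mask", "write_mask", "save_section", "load_section"]

_SIDECAR_KEYS = ("pixel_size_um", "vertical_axis", "section_thickness_um", "section_position_um")


def read_mask(path: str | Path) -> np.ndarray:
    """Load a single-channel raster as a boolean mask (nonzero = foreground)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:  # collapse any trivial channel axis
        arr = arr[..., 0]
    return arr.astype(bool)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    data = np.asarray(mask, bool).astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def save_section(section: SectionImage, out_dir: str | Path, stem: str, fmt: str = "tif") -> dict:
    """Write the three masks plus a JSON calibration sidecar; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, mask in (
        ("vessel", section.vessel_mask),
        ("tissue", section.tissue_mask),
        ("cell", section.cell_mask),
    ):
        p = out / f"{stem}_{name}.{fmt}"
        write_mask(p, mask)
        paths[name] = str(p)
    if section.vessel_mask_projected is not None:
        p = out / f"{stem}_vessel_projected.{fmt}"
        write_mask(p, section.vessel_mask_projected)
        paths["vessel_projected"] = str(p)
    sidecar = {
        "pixel_size_um": section.pixel_size,
        "vertical_axis": section.vertical_axis,
        "section_thickness_um": section.section_thickness,
        "section_position_um": section.section_position,
        "masks": paths,
    }
    sidecar_path = out / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    paths["sidecar"] = str(sidecar_path)
    return paths


def load_section(sidecar_path: str | Path) -> SectionImage:
    """Rebuild a :class:`SectionImage` from its JSON sidecar."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    masks = meta["masks"]
    proj = masks.get("vessel_projected")
    return SectionImage(
        vessel_mask=read_mask(masks["vessel"]),
        tissue_mask=read_mask(masks["tissue"]),
        cell_mask=read_mask(masks["cell"]),
        pixel_size=float(meta["pixel_size_um"]),
        vertical_axis=meta.get("vertical_axis", "rows"),
        section_thickness=float(meta.get("section_thickness_um", 5.0)),
        section_position=float(meta.get("section_position_um", 0.0)),
        vessel_mask_projected=read_mask(proj) if proj else None,
    )
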