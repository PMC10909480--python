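"""Lossless label-image I/O and greyscale threshold segmentation.

Label rasters travel as 8-bit lossless PNG or TIFF with a JSON sidecar
(`<stem>.json`) holding the physical pixel size, the label legend and
any generation metadata.  Lossy formats are refused outright -- a single
recompressed pixel silently corrupts a segmentation.

On disk the first file row is the top of the image (the usual viewer
convention); in memory row 0 is the image bottom (see ``core``), so
readers and writers flip rows.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
import tifffile

from .core import LabelImage, GreyImage, LABEL_NAMES, STROMA, EPITHELIUM, LUMEN

_LOSSLESS = {".png", ".tif", ".tiff"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_label_image(label: LabelImage, path, metadata: dict | None = None) -> None:
    """Write a LabelImage losslessly with its JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() not in _LOSSLESS:
        raise ValueError(
            f"refusing lossy/unknown format {path.suffix!r}; use one of "
            + ", ".join(sorted(_LOSSLESS))
        )
    raster = np.flipud(label.labels.astype(np.uint8))
    if path.suffix.lower() == ".png":
        PILImage.fromarray(raster, mode="L").save(path, format="PNG")
    else:
        tifffile.imwrite(path, raster)
    sidecar = {
        "pixel_size_um": label.pixel_size_um,
        "legend": {str(k): v for k, v in LABEL_NAMES.items()},
    }
    if metadata:
        sidecar.update(metadata)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_label_image(path, pixel_size_um: float | None = None) -> LabelImage:
    """Read a label raster written by :func:`write_label_image`.

    ``pixel_size_um`` overrides (or replaces, if absent) the sidecar value.
    """
    path = Path(path)
    if path.suffix.lower() not in _LOSSLESS:
        raise ValueError(
            f"refusing lossy/unknown format {path.suffix!r} (JPEG and "
            "friends are not label-safe)"
        )
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".png":
        raster = np.asarray(PILImage.open(path).convert("L"))
    else:
        raster = np.asarray(tifffile.imread(path))
    raster = np.flipud(raster).copy()
    if pixel_size_um is None:
        sc = _sidecar_path(path)
        if not sc.exists():
            raise ValueError(
                f"pixel size unknown: provide pixel_size_um or a sidecar {sc.name}"
            )
        pixel_size_um = json.loads(sc.read_text())["pixel_size_um"]
    return LabelImage(raster, pixel_size_um)  # validates label values


def threshold_segment(grey: GreyImage, t_low: float, t_high: float) -> LabelImage:
    """Three-band greyscale segmentation into a label image.

    In an H&E-like greyscale rendering the hematoxylin-dense epithelium
    is darkest and the acinar lumen brightest, so intensities below
    ``t_low`` map to epithelium, the middle band to stroma, and
    intensities at or above ``t_high`` to lumen.
    """
    if not (0.0 <= t_low < t_high <= 1.0):
        raise ValueError(
            f"thresholds must satisfy 0 <= t_low < t_high <= 1, got "
            f"({t_low}, {t_high})"
        )
    I = grey.intensities
    labels = np.full(I.shape, STROMA, dtype=np.uint8)
    labels[I < t_low] = EPITHELIUM
    labels[I >= t_high] = LUMEN
    return LabelImage(labels, grey.pixel_size_um)
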