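"""Pellet colorimetry: RGB colour distance against a white reference pellet.

The colorimetric biosensor accumulates a blue chromoprotein; after
centrifugation the pellet's blueness is scored from a photograph as the
Euclidean distance E in RGB space between the pellet's mean colour and a
reference pellet of non-transformed cells:

    E = sqrt((R_s - R_r)^2 + (G_s - G_r)^2 + (B_s - B_r)^2)

Channel means are taken over a small square region of interest (nine pixels
by default).  The original selection of the "representative" region was
manual; here an automatic rule (centroid of the largest non-background
component) makes it deterministic, and a manual override is first-class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


class PelletNotFoundError(ValueError):
    pass


@dataclass
class PelletMeasurement:
    sample_rgb: tuple[float, float, float]
    reference_rgb: tuple[float, float, float]
    E: float
    roi_center: tuple[int, int]  # (row, col), 0-based
    roi_size: int
    auto_roi: bool = False       # True when the ROI was chosen automatically


def _check_rgb(rgb, name: str) -> np.ndarray:
    arr = np.asarray(rgb, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be an RGB triple, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError(f"{name} channels must lie in [0, 255], got {rgb}")
    return arr


def color_distance(sample_rgb, reference_rgb) -> float:
    """Euclidean distance between two RGB triples on the 0-255 scale.

    Symmetric in its arguments; zero iff the triples are equal.
    """
    s = _check_rgb(sample_rgb, "sample_rgb")
    r = _check_rgb(reference_rgb, "reference_rgb")
    return float(np.sqrt(np.sum((s - r) ** 2)))


def _load_image(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        with Image.open(image) as im:
            image = np.asarray(im.convert("RGB"))
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an RGB raster, got shape {arr.shape}")
    return arr.astype(float)


def find_pellet(image, background_factor: float = 0.9) -> tuple[int, int]:
    """Locate the pellet as the centroid of the largest non-background blob.

    The background level is the mode of the per-pixel channel mean (pellet
    photos have a dominant near-white background); pixels darker than
    ``background_factor`` times that mode are foreground.
    """
    arr = _load_image(image)
    mean = arr.mean(axis=2)
    counts = np.bincount(np.round(mean).astype(int).ravel(), minlength=256)
    background_mode = float(np.argmax(counts))
    fg = mean < background_factor * background_mode
    if not np.any(fg):
        raise PelletNotFoundError("no pellet found (image is uniform "
                                  "background)")
    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=range(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    r, c = ndimage.center_of_mass(labels == largest)
    return int(round(r)), int(round(c))


def measure_pellet(image, reference_rgb,
                   roi_center: tuple[int, int] | None = None,
                   roi_size: int = 3,
                   background_factor: float = 0.9) -> PelletMeasurement:
    """Average an roi_size x roi_size block per channel and score E.

    If ``roi_center`` is omitted the pellet is located automatically with
    :func:`find_pellet`.  Channel means are real-valued (no integer
    truncation).  The ROI must lie fully inside the image.
    """
    arr = _load_image(image)
    ref = tuple(float(v) for v in _check_rgb(reference_rgb, "reference_rgb"))
    auto = roi_center is None
    if auto:
        roi_center = find_pellet(arr, background_factor=background_factor)
    r, c = roi_center
    half = roi_size // 2
    lo_r, hi_r = r - half, r - half + roi_size
    lo_c, hi_c = c - half, c - half + roi_size
    if lo_r < 0 or lo_c < 0 or hi_r > arr.shape[0] or hi_c > arr.shape[1]:
        raise ValueError(f"ROI centered at {roi_center} with size {roi_size} "
                         f"falls outside the {arr.shape[:2]} image")
    block = arr[lo_r:hi_r, lo_c:hi_c]
    sample = tuple(float(v) for v in block.reshape(-1, 3).mean(axis=0))
    return PelletMeasurement(sample_rgb=sample, reference_rgb=ref,
                             E=color_distance(sample, ref),
                             roi_center=(int(r), int(c)), roi_size=roi_size,
                             auto_roi=auto)
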