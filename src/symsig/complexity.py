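"""Perimetric complexity of binary drawings.

Perimetric complexity summarises the visual complexity of an inked figure as

    PC = (inside perimeter + outside perimeter)^2 / ink

where *ink* is the number of foreground pixels, the *outside perimeter* is
the total length of boundary between ink and background reachable from the
canvas exterior, and the *inside perimeter* is the boundary around enclosed
background holes.  The measure is scale-free: under nearest-neighbour
magnification by k, perimeters scale by k and ink by k^2, leaving PC fixed.

Conventions (the estimator is not uniquely defined in the literature):

- perimeter = count of unit pixel edges between foreground and background
  (no diagonal/Crofton correction); pixels outside the canvas are background;
- foreground is 8-connected, background 4-connected, which decides what
  counts as an enclosed hole;
- no pre-blurring by default.

Analyses use the natural log of PC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import SymsigError

logger = logging.getLogger(__name__)

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)  # 4-connectivity


@dataclass(frozen=True)
class ComplexityResult:
    """Perimeter components, ink, and the (log-)perimetric complexity."""

    perimeter_outside: int
    perimeter_inside: int
    ink: int
    pc: float
    log_pc: float


def binarise(
    image: np.ndarray,
    method: str = "automatic",
    threshold: float | None = None,
) -> np.ndarray:
    """Threshold a greyscale raster to an ink mask (dark pixels = foreground).

    ``method="fixed"`` uses the given intensity threshold (pixel < threshold
    is ink); ``method="automatic"`` picks the Otsu threshold maximising
    between-class variance.  An all-ink or all-background result is legal but
    logged as a warning.
    """
    arr = np.asarray(image)
    if arr.ndim == 3:  # RGB(A): luminance
        arr = arr[..., :3].mean(axis=-1)
    if arr.size == 0:
        raise ValueError("empty image")
    arr = arr.astype(float)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed-threshold binarisation needs a threshold")
        t = float(threshold)
    elif method == "automatic":
        if arr.min() == arr.max():
            t = arr.min()  # degenerate uniform image
        else:
            from skimage.filters import threshold_otsu

            t = float(threshold_otsu(arr))
    else:
        raise ValueError(f"unknown binarisation method: {method!r}")
    mask = arr < t
    if mask.all() or not mask.any():
        logger.warning(
            "binarise produced an %s mask (threshold %.3f)",
            "all-foreground" if mask.all() else "all-background",
            t,
        )
    return mask


def perimeter_components(mask: np.ndarray) -> tuple[int, int]:
    """(outside, inside) perimeter of a boolean ink mask, in pixel-edge units.

    An ink/background edge is *outside* if its background pixel is 4-connected
    to the canvas exterior, *inside* if the background pixel lies in an
    enclosed hole.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    # Pad with background so the exterior is a single 4-connected region.
    p = np.pad(m, 1, constant_values=False)
    bg_labels, _ = ndimage.label(~p, structure=_CROSS)
    exterior = bg_labels[0, 0]

    outside = inside = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb = np.roll(bg_labels, shift, axis=axis)
        edge = p & (nb > 0)  # ink pixel whose neighbour in this direction is background
        outside += int((edge & (nb == exterior)).sum())
        inside += int((edge & (nb != exterior)).sum())
    return outside, inside


def perimetric_complexity(mask: np.ndarray) -> ComplexityResult:
    """Measure a binary drawing; raises on a blank (no-ink) image."""
    m = np.asarray(mask, dtype=bool)
    ink = int(m.sum())
    if ink == 0:
        raise SymsigError("no ink: perimetric complexity undefined for a blank image")
    outside, inside = perimeter_components(m)
    pc = (outside + inside) ** 2 / ink
    return ComplexityResult(
        perimeter_outside=outside,
        perimeter_inside=inside,
        ink=ink,
        pc=pc,
        log_pc=log_pc(pc),
    )


def log_pc(pc: float) -> float:
    """Natural log of a positive perimetric complexity."""
    if pc <= 0:
        raise SymsigError(f"log_pc requires pc > 0, got {pc}")
    return math.log(pc)
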