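"""Optical porosity from binary cortical-bone masks.

Porosity (Po.Ar, %) is the areal fraction of a cortical cross-section not
occupied by bone tissue.  The input is a binary mask with void pixels as
foreground (True / nonzero); the specimen value is the arithmetic mean over
the four sampling quadrants (two pleural, two cutaneous).  A grey-level
input can be thresholded with Otsu's method first, but the binary path is
the reference one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["CorticalMask", "PorosityResult", "porosity", "specimen_porosity",
           "load_mask_png", "save_mask_png", "otsu_binarize"]


@dataclass
class CorticalMask:
    """Binary void mask (void = True) for one sampling quadrant."""

    voids: np.ndarray
    quadrant: int = 1
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.voids)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, [0, 1])) and not np.all(np.isin(uniq, [0, 255])):
                raise ValueError("mask is not binary; threshold it first (see otsu_binarize)")
            arr = arr > 0
        if arr.size == 0:
            raise ValueError("empty mask")
        self.voids = arr


@dataclass
class PorosityResult:
    per_quadrant_pct: dict[int, float]
    po_ar_pct: float


def porosity(mask: CorticalMask) -> float:
    """Void area fraction of one quadrant, per cent."""
    return 100.0 * float(mask.voids.mean())


def specimen_porosity(masks: list[CorticalMask], require_four: bool = True) -> PorosityResult:
    """Mean porosity over the quadrant masks.

    With ``require_four`` (default) fewer than four quadrants is an error;
    otherwise a warning is issued and the available quadrants are averaged
    (mirroring a manual-measurement fallback for thin cortices).
    """
    if not masks:
        raise ValueError("no masks supplied")
    if len(masks) < 4:
        msg = f"only {len(masks)} quadrant mask(s) supplied (4 expected)"
        if require_four:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    per_q = {m.quadrant: porosity(m) for m in masks}
    return PorosityResult(per_q, float(np.mean(list(per_q.values()))))


def otsu_binarize(grey: np.ndarray) -> np.ndarray:
    """Otsu threshold a grey-level image; darker-than-threshold = void."""
    grey = np.asarray(grey, dtype=float)
    hist, edges = np.histogram(grey.ravel(), bins=256)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    best_t, best_var = centers[0], -1.0
    csum = np.cumsum(w)
    cmean = np.cumsum(w * centers)
    mean_total = cmean[-1] / total
    for i in range(1, 256):
        w0 = csum[i - 1]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = cmean[i - 1] / w0
        m1 = (cmean[-1] - cmean[i - 1]) / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[i]
    return grey < best_t


def load_mask_png(path: str | Path, quadrant: int = 1) -> CorticalMask:
    """Read a binary PNG (white = void) as a :class:`CorticalMask`."""
    img = np.asarray(Image.open(path).convert("L"))
    return CorticalMask(voids=img > 127, quadrant=quadrant)


def save_mask_png(mask: CorticalMask, path: str | Path) -> None:
    Image.fromarray((mask.voids * 255).astype(np.uint8), mode="L").save(path)
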