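"""ATR-FTIR bone-matrix indices from absorbance spectra.

Four semi-quantitative ratios characterise the mineral and organic phases:

* ``MM`` -- mineral-to-matrix: integrated v1v3 phosphate (1200-900 cm^-1)
  over amide I (1750-1600 cm^-1);
* ``CP`` -- carbonate substitution: v2 carbonate (890-850 cm^-1) over v1v3
  phosphate;
* ``CI`` -- crystallinity (splitting) index on the v4 phosphate doublet:
  (I605 + I565) / I595 after a local linear baseline over 650-500 cm^-1;
* ``CC`` -- collagen content: amide I over v1v3 phosphate (the reciprocal
  of MM by definition).

Band areas use a per-band linear (chord) baseline and trapezoidal
integration; intensities at non-grid wavenumbers are linearly interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import FTIR_BANDS, FTIR_CI_BASELINE, FTIR_CI_POSITIONS

__all__ = ["Spectrum", "FtirResult", "band_area", "ftir_indices"]


@dataclass
class Spectrum:
    """Absorbance spectrum; accepts ascending or descending wavenumber grids."""

    wavenumber_cm1: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumber_cm1, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        d = np.diff(w)
        if np.all(d < 0):  # normalise 4000 -> 400 input to ascending
            w, a = w[::-1], a[::-1]
        elif not np.all(d > 0):
            raise ValueError("wavenumber grid must be strictly monotone")
        self.wavenumber_cm1, self.absorbance = w, a

    def intensity_at(self, wn: float) -> float:
        return float(np.interp(wn, self.wavenumber_cm1, self.absorbance))


@dataclass
class FtirResult:
    MM: float
    CP: float
    CI: float
    CC: float


def band_area(spec: Spectrum, lo: float, hi: float) -> float:
    """Chord-baseline-corrected trapezoidal band area over [lo, hi] cm^-1.

    Negative net areas are floored at zero with a warning (a band sitting
    below its own chord carries no usable signal).
    """
    w = spec.wavenumber_cm1
    if lo < w[0] - 1e-9 or hi > w[-1] + 1e-9 or lo >= hi:
        raise ValueError(f"band [{lo}, {hi}] outside spectral grid [{w[0]}, {w[-1]}]")
    inner = (w > lo) & (w < hi)
    ww = np.concatenate(([lo], w[inner], [hi]))
    aa = np.interp(ww, w, spec.absorbance)
    baseline = np.interp(ww, [lo, hi], [aa[0], aa[-1]])
    area = float(np.trapezoid(aa - baseline, ww))
    if area < 0:
        warnings.warn(f"negative net area in band [{lo}, {hi}]; floored at 0", stacklevel=2)
        area = 0.0
    return area


def _ci_intensities(spec: Spectrum,
                    positions: tuple[float, float, float] = FTIR_CI_POSITIONS,
                    baseline_span: tuple[float, float] = FTIR_CI_BASELINE) -> tuple[float, float, float]:
    lo, hi = baseline_span
    a_lo, a_hi = spec.intensity_at(lo), spec.intensity_at(hi)
    out = []
    for wn in positions:
        base = np.interp(wn, [lo, hi], [a_lo, a_hi])
        out.append(spec.intensity_at(wn) - base)
    return tuple(out)  # type: ignore[return-value]


def ftir_indices(
    spec: Spectrum,
    bands: dict[str, tuple[float, float]] = FTIR_BANDS,
    ci_positions: tuple[float, float, float] = FTIR_CI_POSITIONS,
    ci_baseline: tuple[float, float] = FTIR_CI_BASELINE,
) -> FtirResult:
    """Compute the four matrix indices from one spectrum."""
    a_phos = band_area(spec, *bands["phosphate"])
    a_amide = band_area(spec, *bands["amide_I"])
    a_carb = band_area(spec, *bands["carbonate"])
    if a_phos <= 0 or a_amide <= 0:
        raise ValueError("zero denominator band area; indices undefined")
    i605, i565, i595 = _ci_intensities(spec, ci_positions, ci_baseline)
    if i595 <= 0:
        raise ValueError("zero intensity at the v4 valley; CI undefined")
    return FtirResult(
        MM=a_phos / a_amide,
        CP=a_carb / a_phos,
        CI=(i605 + i565) / i595,
        CC=a_amide / a_phos,
    )
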