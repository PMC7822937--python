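"""Instrumented-indentation analysis (Oliver-Pharr) and Vickers microhardness.

A load-depth-time record is reduced to four tissue-level mechanical
parameters:

* ``H_IT`` -- indentation hardness, maximum load over projected contact area
  at the contact depth (reported in MPa with a Vickers-equivalent alongside);
* ``E_IT`` -- elastic modulus of the tissue, solved from the reduced modulus
  of the unloading contact stiffness assuming a sample Poisson ratio of 0.3;
* ``C_IT`` -- indentation creep, the relative depth increase during the
  constant-load hold (ISO 14577 convention, positive when depth grows);
* ``eta_IT`` -- elastic fraction of the total indentation work, per cent.

Sites are labelled by sampling quadrant (1-4) and tissue compartment:
osteonal (``on``) or interstitial (``it``).  Specimen-level aggregation
averages within each compartment and defines the mean-tissue value as the
average of the two compartment means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import MPA_TO_VICKERS, VICKERS_GEOM_FACTOR, IndenterConstants

__all__ = [
    "IndentationCurve",
    "IndentationResult",
    "ExtractionError",
    "analyze_indentation",
    "aggregate_sites",
    "vickers_hv",
    "aggregate_vickers",
    "reduced_modulus",
    "sample_modulus",
]

PHASES = ("loading", "hold", "unloading")


class ExtractionError(ValueError):
    """Raised when a curve cannot be reduced to mechanical parameters."""


@dataclass
class IndentationCurve:
    """One load-depth-time record with optional per-point phase labels."""

    time_s: np.ndarray
    load_mN: np.ndarray
    depth_nm: np.ndarray
    phase: np.ndarray | None = None  # strings from PHASES
    quadrant: int = 1
    compartment: str = "on"  # "on" | "it"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.load_mN = np.asarray(self.load_mN, dtype=float)
        self.depth_nm = np.asarray(self.depth_nm, dtype=float)
        if self.phase is not None:
            self.phase = np.asarray(self.phase)
        if np.any(self.load_mN < -1e-9):
            raise ValueError("negative load in indentation curve")
        if self.compartment not in ("on", "it"):
            raise ValueError(f"compartment must be 'on' or 'it', got {self.compartment!r}")


@dataclass
class IndentationResult:
    H_IT_MPa: float
    H_IT_vickers: float
    E_IT_GPa: float
    C_IT_pct: float
    eta_IT_pct: float
    quadrant: int
    compartment: str
    stiffness_mN_nm: float
    h_max_nm: float
    h_contact_nm: float
    unload_exponent: float


def reduced_modulus(E_s_GPa: float, c: IndenterConstants = IndenterConstants()) -> float:
    """Reduced contact modulus E_r from sample modulus, GPa."""
    inv = (1 - c.nu_s**2) / E_s_GPa + (1 - c.nu_i**2) / c.E_i_GPa
    return 1.0 / inv


def sample_modulus(E_r_GPa: float, c: IndenterConstants = IndenterConstants()) -> float:
    """Invert the reduced-modulus relation for the sample modulus, GPa."""
    inv_s = 1.0 / E_r_GPa - (1 - c.nu_i**2) / c.E_i_GPa
    if inv_s <= 0:
        raise ExtractionError("non-physical reduced modulus (exceeds indenter term)")
    return (1 - c.nu_s**2) / inv_s


def segment_phases(curve: IndentationCurve, hold_tol: float = 0.01) -> dict[str, np.ndarray]:
    """Index masks for loading / hold / unloading.

    Uses explicit labels when present; otherwise points with load within
    ``hold_tol`` of the maximum form the hold, preceded by loading and
    followed by unloading.
    """
    n = len(curve.load_mN)
    if curve.phase is not None:
        masks = {p: np.asarray(curve.phase) == p for p in PHASES}
    else:
        p = curve.load_mN
        near_max = p >= (1 - hold_tol) * p.max()
        idx = np.flatnonzero(near_max)
        first, last = idx[0], idx[-1]
        masks = {
            "loading": np.arange(n) < first,
            "hold": (np.arange(n) >= first) & (np.arange(n) <= last),
            "unloading": np.arange(n) > last,
        }
    for name in ("loading", "hold", "unloading"):
        if masks[name].sum() < 3:
            raise ExtractionError(f"missing or too-short {name} phase")
    return masks


def _fit_unloading(h: np.ndarray, p: np.ndarray, frac: tuple[float, float]) -> tuple[float, float, float]:
    """Fit P = alpha * (h - h_f)^m to the selected top fraction of unloading.

    Returns (alpha, h_f, m).
    """
    p_max = p.max()
    sel = (p >= frac[0] * p_max) & (p <= frac[1] * p_max)
    if sel.sum() < 5:
        sel = p > 0.05 * p_max
    hs, ps = h[sel], p[sel]

    def model(hh, alpha, hf, m):
        return alpha * np.clip(hh - hf, 1e-9, None) ** m

    h_lo, h_hi = hs.min(), hs.max()
    p0 = (ps.max() / max(h_hi - h_lo, 1.0) ** 1.5, h_lo - 0.3 * (h_hi - h_lo), 1.5)
    try:
        popt, _ = curve_fit(
            model, hs, ps, p0=p0,
            bounds=([1e-12, -np.inf, 1.0], [np.inf, h_lo * (1 - 1e-9) if h_lo > 0 else 0.0, 4.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise ExtractionError(f"unloading power-law fit failed: {exc}") from exc
    return float(popt[0]), float(popt[1]), float(popt[2])


def analyze_indentation(
    curve: IndentationCurve,
    constants: IndenterConstants = IndenterConstants(),
) -> IndentationResult:
    """Reduce one curve to (H_IT, E_IT, C_IT, eta_IT).

    Raises :class:`ExtractionError` on non-positive stiffness or a missing
    hold phase.
    """
    masks = segment_phases(curve)
    h, p = curve.depth_nm, curve.load_mN

    h_hold = h[masks["hold"]]
    h1, h2 = float(h_hold[0]), float(h_hold[-1])
    if h2 < h1 - 1e-9 * max(abs(h1), 1.0):
        raise ExtractionError("depth decreases during hold; C_IT undefined")
    c_it = (h2 - h1) / h1 * 100.0

    h_un, p_un = h[masks["unloading"]], p[masks["unloading"]]
    p_max = float(p.max())
    h_max = float(h2)

    alpha, h_f, m = _fit_unloading(h_un, p_un, constants.unload_fit_range)
    stiffness = alpha * m * (h_max - h_f) ** (m - 1)  # mN/nm
    if not np.isfinite(stiffness) or stiffness <= 0:
        raise ExtractionError("non-positive unloading stiffness")

    h_c = h_max - constants.epsilon * p_max / stiffness
    if h_c <= 0:
        raise ExtractionError("non-positive contact depth")
    area_nm2 = constants.area_coeff * h_c**2
    h_mpa = 1e9 * p_max / area_nm2  # mN/nm^2 -> MPa

    # E_r [GPa]; S in mN/nm, sqrt(A) in nm: E_r = sqrt(pi)/2 * S / sqrt(A) * 1e6
    e_r = np.sqrt(np.pi) / 2.0 * stiffness / np.sqrt(area_nm2) * 1e6
    e_s = sample_modulus(e_r, constants)

    # Work partition by trapezoidal integration over depth, mN*nm.  The
    # loading+hold span is integrated as one contiguous slice and the last
    # hold point is prepended to unloading, so phase-boundary segments are
    # not dropped from either integral.
    i_hold_last = int(np.flatnonzero(masks["hold"])[-1])
    w_elast = abs(np.trapezoid(p[i_hold_last:], h[i_hold_last:]))
    w_total = np.trapezoid(p[: i_hold_last + 1], h[: i_hold_last + 1])
    eta = 100.0 * w_elast / w_total if w_total > 0 else np.nan

    return IndentationResult(
        H_IT_MPa=float(h_mpa),
        H_IT_vickers=float(h_mpa * MPA_TO_VICKERS),
        E_IT_GPa=float(e_s),
        C_IT_pct=float(c_it),
        eta_IT_pct=float(eta),
        quadrant=curve.quadrant,
        compartment=curve.compartment,
        stiffness_mN_nm=float(stiffness),
        h_max_nm=h_max,
        h_contact_nm=float(h_c),
        unload_exponent=float(m),
    )


class AggregationError(ValueError):
    """A tissue compartment has no indentation results."""


def aggregate_sites(results: list[IndentationResult]) -> dict[str, float]:
    """Specimen-level means per compartment plus mean-tissue values.

    Returns a dict with keys ``On_E_IT, It_E_IT, E_IT, ...`` for the four
    parameters; mean tissue is the average of the two compartment means.
    Raises :class:`AggregationError` if either compartment is empty.
    """
    out: dict[str, float] = {}
    by_comp = {"on": [r for r in results if r.compartment == "on"],
               "it": [r for r in results if r.compartment == "it"]}
    missing = [k for k, v in by_comp.items() if not v]
    if missing:
        raise AggregationError(f"no indentations for compartment(s): {missing}")
    fields = {
        "E_IT": "E_IT_GPa",
        "H_IT": "H_IT_MPa",
        "C_IT": "C_IT_pct",
        "eta_IT": "eta_IT_pct",
    }
    for name, attr in fields.items():
        on = float(np.mean([getattr(r, attr) for r in by_comp["on"]]))
        it = float(np.mean([getattr(r, attr) for r in by_comp["it"]]))
        out[f"On_{name}"] = on
        out[f"It_{name}"] = it
        out[name] = (on + it) / 2.0
    return out


def vickers_hv(load_gf: float, diagonal_um: float) -> float:
    """Vickers hardness, kg/mm^2, from load in gf and mean diagonal in um."""
    if load_gf <= 0:
        raise ValueError("load must be positive")
    if diagonal_um <= 0:
        raise ValueError("diagonal must be positive")
    p_kgf = load_gf / 1000.0
    d_mm = diagonal_um / 1000.0
    return VICKERS_GEOM_FACTOR * p_kgf / d_mm**2


def vickers_diagonal_um(hv: float, load_gf: float) -> float:
    """Forward model: diagonal (um) producing a target HV at the given load."""
    if hv <= 0:
        raise ValueError("HV must be positive")
    return 1000.0 * np.sqrt(VICKERS_GEOM_FACTOR * (load_gf / 1000.0) / hv)


def aggregate_vickers(values: list[tuple[str, float]]) -> dict[str, float]:
    """Mean HV per compartment and mean tissue from (compartment, HV) pairs."""
    on = [v for c, v in values if c == "on"]
    it = [v for c, v in values if c == "it"]
    if not on or not it:
        raise AggregationError("Vickers values required for both compartments")
    out = {"On_HV": float(np.mean(on)), "It_HV": float(np.mean(it))}
    out["HV"] = (out["On_HV"] + out["It_HV"]) / 2.0
    return out
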