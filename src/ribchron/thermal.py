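"""TGA/DSC reduction: mass fractions and transition enthalpies.

The experiment ramps bone powder from 25 to 550 degC at 10 degC/min (a final
isothermal hold is folded into the last sample).  The thermogram is split at
nominal boundaries 25 / 200 / 550 degC:

* ``W%``  -- dehydration weight loss between 25 and 200 degC,
* ``Or%`` -- organic combustion loss between 200 degC and the end,
* ``Ash%`` = 100 - W% - Or%, the mineral fraction,

all relative to the mass at the lower boundary, read by local interpolation.
Enthalpies are linear-baseline integrals of the heat-flow curve over the same
windows, converted from temperature to time with the heating rate: ``LdH``
(dehydration endotherm) and ``CdH`` (organic-combustion exotherm), both
reported as positive magnitudes in J/g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HEATING_RATE_C_MIN, THERMAL_WINDOWS

__all__ = ["Thermogram", "HeatFlowCurve", "ThermalResult", "tga_steps", "dsc_enthalpies"]


@dataclass
class Thermogram:
    temperature_C: np.ndarray
    mass_mg: np.ndarray
    initial_mass_mg: float | None = None

    def __post_init__(self) -> None:
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.mass_mg = np.asarray(self.mass_mg, dtype=float)
        if np.any(np.diff(self.temperature_C) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if np.any(self.mass_mg <= 0):
            raise ValueError("mass must stay positive")
        # non-increasing within noise tolerance (0.1% upticks allowed)
        up = np.diff(self.mass_mg)
        if np.any(up > 1e-3 * self.mass_mg[0]):
            raise ValueError("mass increases beyond noise tolerance")
        if self.initial_mass_mg is None:
            self.initial_mass_mg = float(self.mass_mg[0])


@dataclass
class HeatFlowCurve:
    temperature_C: np.ndarray
    heatflow_W_g: np.ndarray
    exo_up: bool = True  #: sign convention: exothermic positive

    def __post_init__(self) -> None:
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.heatflow_W_g = np.asarray(self.heatflow_W_g, dtype=float)
        if not np.all(np.isfinite(self.heatflow_W_g)):
            raise ValueError("non-finite heat-flow values")


@dataclass
class ThermalResult:
    W_pct: float
    Or_pct: float
    Ash_pct: float
    LdH_J_g: float
    CdH_J_g: float


def _mass_at(tg: Thermogram, t: float) -> float:
    tt = tg.temperature_C
    if t < tt[0] - 1e-9 or t > tt[-1] + 1e-9:
        raise ValueError(f"boundary {t} degC outside thermogram span [{tt[0]}, {tt[-1]}]")
    return float(np.interp(t, tt, tg.mass_mg))


def tga_steps(
    tg: Thermogram,
    t_low: float = THERMAL_WINDOWS["t_low"],
    t_mid: float = THERMAL_WINDOWS["t_mid"],
    t_high: float = THERMAL_WINDOWS["t_high"],
) -> tuple[float, float, float]:
    """Step-horizontal weight-loss fractions (W%, Or%, Ash%).

    The organic step ends at the final recorded sample (the isothermal hold
    end), not at ``t_high`` itself, so residual slow loss is captured.
    The three fractions sum to 100 by construction.
    """
    m_low = _mass_at(tg, t_low)
    m_mid = _mass_at(tg, t_mid)
    if tg.temperature_C[-1] < t_high - 5.0:
        raise ValueError(f"thermogram does not reach {t_high} degC")
    m_end = float(tg.mass_mg[-1])
    w = 100.0 * (m_low - m_mid) / m_low
    org = 100.0 * (m_mid - m_end) / m_low
    ash = 100.0 - w - org
    return w, org, ash


def dsc_enthalpies(
    hf: HeatFlowCurve,
    t_low: float = THERMAL_WINDOWS["t_low"],
    t_mid: float = THERMAL_WINDOWS["t_mid"],
    t_high: float = THERMAL_WINDOWS["t_high"],
    heating_rate_C_min: float = HEATING_RATE_C_MIN,
) -> tuple[float, float]:
    """Linear-baseline enthalpies (LdH, CdH) in J/g.

    Each window's enthalpy is the integral over *time* of the heat flow minus
    the chord between the window's endpoint values.  The dehydration window
    is reported with the endothermic sign convention (positive magnitude for
    an endotherm) and the combustion window with the exothermic one.
    """
    if heating_rate_C_min <= 0:
        raise ValueError("heating rate must be positive")
    rate_C_s = heating_rate_C_min / 60.0

    def window_integral(lo: float, hi: float) -> float:
        t, y = hf.temperature_C, hf.heatflow_W_g
        sel = (t >= lo) & (t <= hi)
        if sel.sum() < 3:
            raise ValueError(f"window [{lo}, {hi}] covers fewer than 3 samples")
        tw, yw = t[sel], y[sel]
        baseline = np.interp(tw, [tw[0], tw[-1]], [yw[0], yw[-1]])
        # dT / rate = dt
        return float(np.trapezoid(yw - baseline, tw) / rate_C_s)

    sign = 1.0 if hf.exo_up else -1.0
    endo = window_integral(t_low, t_mid) * sign   # endotherm integrates negative when exo-up
    exo = window_integral(t_mid, t_high) * sign
    ldh = -endo  # report endotherm as positive magnitude
    cdh = exo
    return ldh, cdh


def thermal_result(tg: Thermogram, hf: HeatFlowCurve, **kw) -> ThermalResult:
    """Convenience wrapper running both reductions with shared windows."""
    w, org, ash = tga_steps(tg, **{k: v for k, v in kw.items() if k.startswith("t_")})
    ldh, cdh = dsc_enthalpies(hf, **kw)
    return ThermalResult(w, org, ash, ldh, cdh)
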