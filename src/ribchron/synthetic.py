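"""Forward generation of synthetic rib-cortical-bone study data.

Two layers:

1. **Parameter tables** -- specimen ages are drawn from a truncated normal
   matching the study cohort (n=113, 46.64 +/- 16.33 yr, range 12-84); each
   tissue parameter X is drawn as

       X = mean + r * sd * z_age + sd * sqrt(1 - r^2) * eps

   with ``z_age`` the empirically standardised age and ``eps`` iid standard
   normal, so the sample correlation of X with age converges to the target
   ``r``.  Columns that the extraction pipeline computes from others
   (mean-tissue mechanics, HV, Ash%, MM, CL002/CL004) are *derived* with the
   extractor's own algebra, so the generated table is internally consistent.

2. **Raw modality bundles** -- every raw record a specimen would produce
   (indentation curves, Vickers diagonals, TGA/DSC curves, FTIR spectrum,
   diffraction scans, porosity masks) is rendered from the specimen's
   parameter row by the physical forward models, so that running the
   extraction modules on the rendered data recovers the generating
   parameters (the round-trip validation this package leans on).

One global seed; per-specimen streams are derived from (seed, specimen
index) so bundles are reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import indentation as ind
from .constants import (
    CAGLIOTI_UVW,
    FTIR_CI_POSITIONS,
    HEATING_RATE_C_MIN,
    INDENT_PROTOCOL,
    PARAMETER_DEFAULTS,
    PARAMETER_NAMES,
    POPULATION_DEFAULTS,
    SCHERRER_K,
    THERMAL_WINDOWS,
    VICKERS_LOAD_GF,
    XRAY_WAVELENGTH_A,
    XRAY_WAVELENGTH_NM,
    IndenterConstants,
)
from .ftir import Spectrum
from .histomorphometry import CorticalMask
from .thermal import HeatFlowCurve, Thermogram
from .xrd import (
    DiffractionPattern,
    bragg_two_theta_deg,
    caglioti_fwhm_deg,
    hexagonal_d_spacing,
    split_pseudo_voigt,
)

__all__ = [
    "PopulationSpec",
    "ParameterSpec",
    "RenderOptions",
    "RawBundle",
    "GenerationError",
    "draw_population",
    "draw_parameters",
    "derive_columns",
    "default_parameter_specs",
    "build_parameter_table",
    "render_raw",
]


class GenerationError(ValueError):
    """A specimen record holds a value outside the renderable physical range."""


# --------------------------------------------------------------------------
# population and parameter tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """Cohort-level sampling frame; defaults reproduce the study cohort."""

    n_specimens: int = POPULATION_DEFAULTS["n_specimens"]
    age_mean: float = POPULATION_DEFAULTS["age_mean"]
    age_sd: float = POPULATION_DEFAULTS["age_sd"]
    age_min: float = POPULATION_DEFAULTS["age_min"]
    age_max: float = POPULATION_DEFAULTS["age_max"]
    sex_fraction_male: float = POPULATION_DEFAULTS["sex_fraction_male"]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")
        if not 0 <= self.sex_fraction_male <= 1:
            raise ValueError("sex_fraction_male must lie in [0, 1]")
        if self.n_specimens < 2:
            raise ValueError("need at least 2 specimens")
        if self.age_sd < 0:
            raise ValueError("age_sd must be non-negative")


@dataclass(frozen=True)
class ParameterSpec:
    """Target population structure of one generated parameter."""

    name: str
    mean: float
    sd: float
    age_correlation: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or not np.isfinite(self.sd) or self.sd <= 0:
            raise ValueError(f"{self.name}: mean/sd must be finite with sd > 0")
        if abs(self.age_correlation) > 1:
            raise ValueError(f"{self.name}: |age correlation| must be <= 1")


def default_parameter_specs(
    overrides: Mapping[str, float] | None = None,
) -> list[ParameterSpec]:
    """The independently-drawn parameter set with shipped defaults.

    ``overrides`` maps parameter name to a replacement age correlation
    (e.g. to flip the sign of CdH or eta, which the source reports
    ambiguously).
    """
    overrides = dict(overrides or {})
    specs = []
    for p in PARAMETER_DEFAULTS:
        if p.derived:
            continue
        r = overrides.pop(p.name, p.age_r)
        specs.append(ParameterSpec(p.name, p.mean, p.sd, r))
    if overrides:
        raise KeyError(f"unknown parameter override(s): {sorted(overrides)}")
    return specs


def draw_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw (specimen_id, sex, age) rows; ages truncated-normal by rejection."""
    rng = np.random.default_rng(spec.seed)
    ages = np.empty(0)
    while len(ages) < spec.n_specimens:
        block = rng.normal(spec.age_mean, spec.age_sd, size=4 * spec.n_specimens + 16)
        if spec.age_sd == 0:
            block = np.full_like(block, spec.age_mean)
        block = block[(block >= spec.age_min) & (block <= spec.age_max)]
        ages = np.concatenate([ages, block])
    ages = ages[: spec.n_specimens]
    n_male = int(round(spec.sex_fraction_male * spec.n_specimens))
    sex = np.array(["M"] * n_male + ["F"] * (spec.n_specimens - n_male))
    rng.shuffle(sex)
    ids = [f"S{i + 1:03d}" for i in range(spec.n_specimens)]
    return pd.DataFrame({"specimen_id": ids, "sex": sex, "age": ages})


def draw_parameters(
    ages: Sequence[float],
    specs: Sequence[ParameterSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Generate one column per spec with the target age correlation.

    Porosity draws are floored at 0.2% (physical lower bound); the floor is
    essentially never reached under the default structure.
    """
    ages = np.asarray(ages, dtype=float)
    sd_age = ages.std()
    if sd_age == 0:
        raise ValueError("ages are degenerate; correlations undefined")
    z = (ages - ages.mean()) / sd_age
    n = len(ages)
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for s in specs:
        eps = rng.standard_normal(n)
        if n > 2 and abs(s.age_correlation) < 1:
            # empirical calibration (the mvrnorm empirical=TRUE idea): project
            # the noise out of the age direction and restandardise, so the
            # realised sample correlation equals the target exactly rather
            # than to O(1/sqrt(n)).
            eps = eps - (eps @ z) / (z @ z) * z
            eps = (eps - eps.mean()) / eps.std()
        x = s.mean + s.age_correlation * s.sd * z + s.sd * np.sqrt(1 - s.age_correlation**2) * eps
        if s.name == "PoAr_pct":
            x = np.clip(x, 0.2, 100.0)
        cols[s.name] = x
    return pd.DataFrame(cols)


def _wh_beta_cos_theta(size_nm: float, strain: float, theta_rad: float) -> float:
    return 4.0 * strain * np.sin(theta_rad) + SCHERRER_K * XRAY_WAVELENGTH_NM / size_nm


def derive_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Fill the derived columns with the extraction pipeline's own algebra.

    Ash% = 100 - W% - Or%;  MM = 1/CC;  mean-tissue mechanics and HV are
    compartment averages; CL002/CL004 follow from (Size, Strain, c-axis)
    through the Williamson-Hall relation.
    """
    out = df.copy()
    out["Ash_pct"] = 100.0 - out["W_pct"] - out["Or_pct"]
    out["MM"] = 1.0 / out["CC"]
    for name in ("E_IT", "H_IT", "C_IT", "eta_IT"):
        out[name] = (out[f"On_{name}"] + out[f"It_{name}"]) / 2.0
    out["HV"] = (out["On_HV"] + out["It_HV"]) / 2.0
    th002 = np.arcsin(XRAY_WAVELENGTH_A / (2.0 * out["c_axis"] / 2.0))
    th004 = np.arcsin(XRAY_WAVELENGTH_A / (2.0 * out["c_axis"] / 4.0))
    for name, th in (("CL002", th002), ("CL004", th004)):
        bcos = 4.0 * out["Strain"] * np.sin(th) + SCHERRER_K * XRAY_WAVELENGTH_NM / out["Size"]
        out[name] = SCHERRER_K * XRAY_WAVELENGTH_NM / bcos
    return out


def build_parameter_table(
    pop: PopulationSpec | None = None,
    specs: Sequence[ParameterSpec] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort table: id, sex, age plus the full 33-parameter feature set."""
    if pop is None:
        pop = PopulationSpec(seed=seed)
    elif pop.seed != seed:
        pop = replace(pop, seed=seed)
    specs = specs if specs is not None else default_parameter_specs()
    cohort = draw_population(pop)
    params = draw_parameters(cohort["age"].to_numpy(), specs, seed=seed + 1)
    table = pd.concat([cohort.reset_index(drop=True), params], axis=1)
    table = derive_columns(table)
    return table[["specimen_id", "sex", "age", *PARAMETER_NAMES]]


# --------------------------------------------------------------------------
# raw-bundle rendering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderOptions:
    """Knobs of the raw-data renderers (instrument-level, not population-level)."""

    indents_per_site: int = 8          #: indentations per quadrant per compartment
    site_scatter_rel: float = 0.01     #: relative scatter of site-level mechanics
    vickers_scatter_rel: float = 0.005
    indenter: IndenterConstants = field(default_factory=IndenterConstants)
    # thermal forward model: logistic step centres/widths (degC)
    tga_step_centres: tuple[float, float] = (110.0, 330.0)
    tga_step_widths: tuple[float, float] = (12.0, 20.0)
    tga_noise_rel: float = 1e-4
    dsc_peak_sigmas: tuple[float, float] = (15.0, 28.0)
    dsc_noise_W_g: float = 1e-3
    initial_mass_mg: float = 10.0
    # FTIR forward model
    ftir_noise: float = 2e-6
    ftir_grid_step: float = 2.0
    # XRD forward model
    caglioti: tuple[float, float, float] = CAGLIOTI_UVW
    xrd_noise_frac: float = 0.15
    xrd_eta_mix: float = 0.45
    xrd_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"002": 1500.0, "210": 600.0, "030": 1200.0, "004": 300.0}
    )
    xrd_stepped_gain: float = 3.0      #: count-time ratio of stepped vs wide scans
    # porosity masks
    mask_shape: tuple[int, int] = (256, 256)
    disk_radius_px: tuple[int, int] = (3, 8)


@dataclass
class RawBundle:
    """Everything one specimen's bench session would produce."""

    specimen_id: str
    indentation_curves: list[ind.IndentationCurve]
    vickers: list[tuple[int, str, float, float]]  #: (quadrant, compartment, load_gf, diagonal_um)
    thermogram: Thermogram
    heatflow: HeatFlowCurve
    ftir_spectrum: Spectrum
    diffraction: dict[str, DiffractionPattern]    #: keys: wide, stepped_002, stepped_004
    porosity_masks: list[CorticalMask]


def _check_range(record: Mapping[str, float], name: str, lo: float, hi: float) -> float:
    v = float(record[name])
    if not (lo <= v <= hi) or not np.isfinite(v):
        raise GenerationError(f"{name}={v} outside physical range [{lo}, {hi}]")
    return v


def render_indentation_curve(
    E_GPa: float,
    H_MPa: float,
    C_pct: float,
    eta_pct: float,
    constants: IndenterConstants = IndenterConstants(),
    protocol: Mapping[str, float] = INDENT_PROTOCOL,
    quadrant: int = 1,
    compartment: str = "on",
) -> ind.IndentationCurve:
    """Analytic Oliver-Pharr-consistent load-depth-time curve.

    The unloading branch is a power law (exponent 1.5) whose stiffness at
    maximum depth matches the target modulus; the hold phase creeps by the
    target C_IT; the loading exponent is solved so the elastic/total work
    ratio equals the target eta_IT.  eta_IT = 100 renders the fully elastic
    limit (unloading retraces loading, no creep).
    """
    if not (0 < eta_pct <= 100):
        raise GenerationError(f"eta_IT={eta_pct} outside (0, 100]")
    if C_pct < 0:
        raise GenerationError(f"C_IT={C_pct} negative")
    if H_MPa <= 0 or E_GPa <= 0:
        raise GenerationError("H_IT and E_IT must be positive")

    p_max = protocol["p_max_mN"]
    t_ramp = p_max / protocol["rate_mN_min"] * 60.0
    t_hold = protocol["hold_s"]
    dt = protocol["dt_s"]

    area_nm2 = 1e9 * p_max / H_MPa
    h_c = np.sqrt(area_nm2 / constants.area_coeff)
    e_r = ind.reduced_modulus(E_GPa, constants)
    stiffness = 2.0 / np.sqrt(np.pi) * e_r * 1e-6 * np.sqrt(area_nm2)  # mN/nm
    h2 = h_c + constants.epsilon * p_max / stiffness

    nl = max(int(round(t_ramp / dt)), 30)
    nh = max(int(round(t_hold / dt)), 30)

    if eta_pct >= 100.0 - 1e-9:
        # fully elastic: loading and unloading share one Hertz-like path
        m = 1.5
        t_l = np.linspace(0, t_ramp, nl + 1)[:-1]
        p_l = p_max * t_l / t_ramp
        h_l = h2 * (p_l / p_max) ** (1.0 / m)
        t_h = np.linspace(0, t_hold, nh + 1)
        t_u = np.linspace(0, t_ramp, nl + 1)[1:]
        p_u = p_max * (1 - t_u / t_ramp)
        h_u = h2 * (p_u / p_max) ** (1.0 / m)
        time = np.concatenate([t_l, t_ramp + t_h, t_ramp + t_hold + t_u])
        load = np.concatenate([p_l, np.full(nh + 1, p_max), p_u])
        depth = np.concatenate([h_l, np.full(nh + 1, h2), h_u])
        phase = np.array(["loading"] * nl + ["hold"] * (nh + 1) + ["unloading"] * nl)
        return ind.IndentationCurve(time, load, depth, phase, quadrant, compartment)

    m = 1.5
    h1 = h2 / (1.0 + C_pct / 100.0)
    h_f = h2 - m * p_max / stiffness
    if h_f < 0:
        raise GenerationError("E_IT/H_IT combination implies negative final depth")
    w_elast = p_max * (h2 - h_f) / (m + 1.0)
    w_total = 100.0 * w_elast / eta_pct
    w_hold = p_max * (h2 - h1)
    w_load = w_total - w_hold
    if w_load <= 0:
        raise GenerationError("eta_IT infeasible: hold work alone exceeds the work budget")
    p_exp = p_max * h1 / w_load - 1.0
    if not (1.02 <= p_exp <= 15.0):
        raise GenerationError(
            f"eta_IT={eta_pct} infeasible with this E/H/C combination (loading exponent {p_exp:.2f})"
        )

    t_l = np.linspace(0, t_ramp, nl + 1)[:-1]
    p_l = p_max * t_l / t_ramp
    h_l = h1 * (p_l / p_max) ** (1.0 / p_exp)
    t_h = np.linspace(0, t_hold, nh + 1)
    h_h = h1 + (h2 - h1) * np.sqrt(t_h / t_hold)
    t_u = np.linspace(0, t_ramp, nl + 1)[1:]
    p_u = p_max * (1 - t_u / t_ramp)
    h_u = h_f + (h2 - h_f) * (p_u / p_max) ** (1.0 / m)

    time = np.concatenate([t_l, t_ramp + t_h, t_ramp + t_hold + t_u])
    load = np.concatenate([p_l, np.full(nh + 1, p_max), p_u])
    depth = np.concatenate([h_l, h_h, h_u])
    phase = np.array(["loading"] * nl + ["hold"] * (nh + 1) + ["unloading"] * nl)
    return ind.IndentationCurve(time, load, depth, phase, quadrant, compartment)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def render_thermogram(
    w_pct: float, or_pct: float, rng: np.random.Generator, opt: RenderOptions
) -> Thermogram:
    """Two smooth sigmoidal mass-loss steps; final mass = (100-W-Or)% of initial."""
    if w_pct < 0 or or_pct < 0 or w_pct + or_pct >= 100:
        raise GenerationError(f"W_pct={w_pct}, Or_pct={or_pct} not a valid mass partition")
    t = np.arange(THERMAL_WINDOWS["t_low"], THERMAL_WINDOWS["t_high"] + 0.5, 0.5)
    (c1, c2), (w1, w2) = opt.tga_step_centres, opt.tga_step_widths
    m0 = opt.initial_mass_mg
    frac = 1.0 - w_pct / 100.0 * _logistic((t - c1) / w1) - or_pct / 100.0 * _logistic((t - c2) / w2)
    mass = m0 * frac
    mass = mass + rng.normal(0.0, opt.tga_noise_rel * m0, size=mass.shape)
    return Thermogram(t, mass, initial_mass_mg=m0)


def render_heatflow(
    ldh: float, cdh: float, rng: np.random.Generator, opt: RenderOptions
) -> HeatFlowCurve:
    """One endotherm (dehydration) + one exotherm (combustion), exo-up.

    Gaussian peaks whose *time* integrals equal the target enthalpies at the
    nominal heating rate.
    """
    if ldh < 0 or cdh < 0:
        raise GenerationError("enthalpies must be non-negative magnitudes")
    t = np.arange(THERMAL_WINDOWS["t_low"], THERMAL_WINDOWS["t_high"] + 0.5, 0.5)
    (c1, c2) = (110.0, 330.0)
    s1, s2 = opt.dsc_peak_sigmas
    rate_C_s = HEATING_RATE_C_MIN / 60.0
    # unit-area (in degC) Gaussians scaled so integral over time = dH
    g1 = np.exp(-0.5 * ((t - c1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
    g2 = np.exp(-0.5 * ((t - c2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
    hf = (-ldh * g1 + cdh * g2) * rate_C_s
    hf = hf + rng.normal(0.0, opt.dsc_noise_W_g, size=hf.shape)
    return HeatFlowCurve(t, hf, exo_up=True)


def _ci_sigma_for_target(ci: float) -> float:
    """Width of the equal-height v4 doublet Gaussians yielding a target CI."""
    from scipy.optimize import brentq

    p1, p2, valley = FTIR_CI_POSITIONS  # 605, 565, 595
    c1, c2 = 603.0, 565.0  # band centres

    def ci_of(sigma: float) -> float:
        def g(x, c):
            return np.exp(-0.5 * ((x - c) / sigma) ** 2)

        i605 = g(p1, c1) + g(p1, c2)
        i565 = g(p2, c1) + g(p2, c2)
        i595 = g(valley, c1) + g(valley, c2)
        return (i605 + i565) / i595

    lo, hi = 4.0, 14.0
    if not (ci_of(hi) < ci < ci_of(lo)):
        raise GenerationError(f"CI={ci} outside renderable range "
                              f"[{ci_of(hi):.2f}, {ci_of(lo):.2f}]")
    return brentq(lambda s: ci_of(s) - ci, lo, hi)


def render_ftir(
    mm: float, cp: float, ci: float, cc: float, rng: np.random.Generator, opt: RenderOptions
) -> Spectrum:
    """Gaussian bands on the standard bone intervals hitting the four indices.

    The phosphate band area is fixed at 1 a.u.; amide I and carbonate areas
    follow from CC and CP, and the v4 doublet width is solved for CI.  The
    MM/CC reciprocity of the generating record is required.
    """
    for name, v in (("MM", mm), ("CP", cp), ("CI", ci), ("CC", cc)):
        if v <= 0:
            raise GenerationError(f"{name}={v} must be positive")
    if abs(mm * cc - 1.0) > 1e-6:
        raise GenerationError("record violates MM = 1/CC reciprocity")
    wn = np.arange(399.0, 4001.0, opt.ftir_grid_step)  # odd grid: CI read positions land on samples
    a_phos, s_phos, c_phos = 1.0, 25.0, 1015.0
    a_amide, s_amide, c_amide = cc * a_phos, 15.0, 1660.0
    a_carb, s_carb, c_carb = cp * a_phos, 5.0, 872.0

    def gauss(area, sigma, centre):
        return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((wn - centre) / sigma) ** 2)

    y = gauss(a_phos, s_phos, c_phos) + gauss(a_amide, s_amide, c_amide) + gauss(a_carb, s_carb, c_carb)
    sigma_v4 = _ci_sigma_for_target(ci)
    v4_height = 0.15 * a_phos / (sigma_v4 * np.sqrt(2 * np.pi))  # arbitrary but visible
    for centre in (603.0, 565.0):
        y = y + v4_height * np.exp(-0.5 * ((wn - centre) / sigma_v4) ** 2)
    y = y + rng.normal(0.0, opt.ftir_noise, size=y.shape)
    return Spectrum(wn, y)


def render_diffraction(
    record: Mapping[str, float], rng: np.random.Generator, opt: RenderOptions
) -> dict[str, DiffractionPattern]:
    """Wide 10-80 deg scan plus the two high-count stepped scans.

    Peak positions follow from the record's lattice parameters; 00l widths
    from (Size, Strain) via Williamson-Hall, 030/210 widths from their
    coherence lengths via Scherrer; the Caglioti instrument width is folded
    in by Gaussian quadrature.
    """
    a = _check_range(record, "a_axis", 8.0, 11.0)
    c = _check_range(record, "c_axis", 6.0, 8.0)
    size = _check_range(record, "Size", 2.0, 200.0)
    strain = _check_range(record, "Strain", 0.0, 0.05)
    cl030 = _check_range(record, "CL030", 1.0, 200.0)
    cl210 = _check_range(record, "CL210", 1.0, 200.0)

    hkl_map = {"002": (0, 0, 2), "210": (2, 1, 0), "030": (0, 3, 0), "004": (0, 0, 4)}
    pos = {k: bragg_two_theta_deg(hexagonal_d_spacing(*v, a, c)) for k, v in hkl_map.items()}

    beta_sample_deg: dict[str, float] = {}
    for k in ("002", "004"):
        th = np.radians(pos[k] / 2.0)
        bcos = _wh_beta_cos_theta(size, strain, th)
        beta_sample_deg[k] = np.degrees(bcos / np.cos(th))
    for k, cl in (("030", cl030), ("210", cl210)):
        th = np.radians(pos[k] / 2.0)
        beta_sample_deg[k] = np.degrees(SCHERRER_K * XRAY_WAVELENGTH_NM / (cl * np.cos(th)))

    fwhm_obs = {
        k: float(np.hypot(beta_sample_deg[k], caglioti_fwhm_deg(pos[k] / 2.0, opt.caglioti)))
        for k in pos
    }

    def scan(lo: float, hi: float, step: float, peaks: list[str], gain: float) -> DiffractionPattern:
        x = np.arange(lo, hi + step / 2, step)
        y = np.full_like(x, 20.0) + 0.1 * (x - lo)  # linear background
        for k in peaks:
            y = y + split_pseudo_voigt(
                x, gain * opt.xrd_amplitudes[k], pos[k], fwhm_obs[k], fwhm_obs[k], opt.xrd_eta_mix
            )
        y = y + rng.normal(0.0, opt.xrd_noise_frac * np.sqrt(np.clip(y, 1.0, None)))
        return DiffractionPattern(x, np.clip(y, 0.0, None))

    return {
        "wide": scan(10.0, 80.0, 0.02, ["002", "210", "030", "004"], 1.0),
        "stepped_002": scan(23.0, 27.0, 0.01, ["002"], opt.xrd_stepped_gain),
        "stepped_004": scan(50.0, 55.0, 0.01, ["004"], opt.xrd_stepped_gain),
    }


def render_porosity_masks(
    po_ar_pct: float, rng: np.random.Generator, opt: RenderOptions
) -> list[CorticalMask]:
    """Four quadrant masks of non-overlapping void disks at the target fraction."""
    if not (0 <= po_ar_pct < 60):
        raise GenerationError(f"PoAr_pct={po_ar_pct} outside renderable range [0, 60)")
    h, w = opt.mask_shape
    target = po_ar_pct / 100.0
    masks = []
    yy, xx = np.mgrid[0:h, 0:w]
    for q in range(1, 5):
        voids = np.zeros((h, w), dtype=bool)
        frac = 0.0
        attempts = 0
        while attempts < 20000:
            attempts += 1
            r = rng.integers(opt.disk_radius_px[0], opt.disk_radius_px[1] + 1)
            cy = rng.integers(r, h - r)
            cx = rng.integers(r, w - r)
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            if (voids & disk).any():
                continue
            new_frac = frac + disk.sum() / (h * w)
            if new_frac - target > target - frac:  # adding overshoots more than staying under
                break
            voids |= disk
            frac = new_frac
            if frac >= target:
                break
        masks.append(CorticalMask(voids=voids, quadrant=q))
    return masks


def render_raw(
    record: Mapping[str, float],
    seed: int,
    options: RenderOptions | None = None,
    specimen_index: int = 0,
) -> RawBundle:
    """Render the complete raw bundle for one specimen record.

    ``record`` must carry the full parameter row (compartment-level
    mechanics, thermal fractions and enthalpies, FTIR indices, XRD
    structure, porosity).  The random stream is derived from
    ``(seed, specimen_index)``.
    """
    opt = options or RenderOptions()
    rng = np.random.default_rng([seed, specimen_index])
    sid = str(record.get("specimen_id", f"S{specimen_index:03d}"))

    curves: list[ind.IndentationCurve] = []
    for quadrant in range(1, 5):
        for comp in ("on", "it"):
            prefix = "On_" if comp == "on" else "It_"
            e0 = _check_range(record, f"{prefix}E_IT", 1.0, 100.0)
            h0 = _check_range(record, f"{prefix}H_IT", 50.0, 5000.0)
            c0 = _check_range(record, f"{prefix}C_IT", 0.0, 50.0)
            n0 = _check_range(record, f"{prefix}eta_IT", 0.0, 100.0)
            for _ in range(opt.indents_per_site):
                s = 1.0 + opt.site_scatter_rel * rng.standard_normal(4)
                curves.append(
                    render_indentation_curve(
                        e0 * s[0], h0 * s[1], max(c0 * s[2], 0.0), min(n0 * s[3], 100.0),
                        opt.indenter, INDENT_PROTOCOL, quadrant, comp,
                    )
                )

    vickers = []
    for quadrant in range(1, 5):
        for comp, key in (("on", "On_HV"), ("it", "It_HV")):
            hv = _check_range(record, key, 1.0, 2000.0)
            hv_i = hv * (1.0 + opt.vickers_scatter_rel * rng.standard_normal())
            d_um = ind.vickers_diagonal_um(hv_i, VICKERS_LOAD_GF)
            vickers.append((quadrant, comp, VICKERS_LOAD_GF, float(d_um)))

    tg = render_thermogram(float(record["W_pct"]), float(record["Or_pct"]), rng, opt)
    hf = render_heatflow(float(record["LdH"]), float(record["CdH"]), rng, opt)
    spectrum = render_ftir(
        float(record["MM"]), float(record["CP"]), float(record["CI"]), float(record["CC"]),
        rng, opt,
    )
    diffraction = render_diffraction(record, rng, opt)
    masks = render_porosity_masks(float(record["PoAr_pct"]), rng, opt)

    return RawBundle(
        specimen_id=sid,
        indentation_curves=curves,
        vickers=vickers,
        thermogram=tg,
        heatflow=hf,
        ftir_spectrum=spectrum,
        diffraction=diffraction,
        porosity_masks=masks,
    )
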