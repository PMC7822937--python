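"""Shared physical constants and study-condition defaults.

Everything a user might legitimately want to swap (instrument broadening,
indenter constants, band limits, fit windows, the per-parameter population
structure of the synthetic cohort) lives here or in the YAML config layer;
the analysis modules take these as arguments with these values as defaults.

Units are stated per entry.  Where the source study does not publish a
population mean/SD for a parameter, the default is a plausible value for
fresh human rib cortical bone, flagged ``reported=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# --------------------------------------------------------------------------
# Study cohort
# --------------------------------------------------------------------------

#: Cohort of 113 rib specimens, ages 12-84 yr, 46.64 +/- 16.33, 77 male / 36 female.
POPULATION_DEFAULTS = dict(
    n_specimens=113,
    age_mean=46.64,
    age_sd=16.33,
    age_min=12.0,
    age_max=84.0,
    sex_fraction_male=77 / 113,
)

# --------------------------------------------------------------------------
# X-ray diffraction
# --------------------------------------------------------------------------

SCHERRER_K = 0.9                #: dimensionless Scherrer shape constant
XRAY_WAVELENGTH_NM = 0.15406    #: Cu K-alpha1, nm
XRAY_WAVELENGTH_A = 1.5406      #: same, Angstrom

#: Reference stoichiometric hydroxyapatite hexagonal lattice (Angstrom).
HA_A_AXIS = 9.418
HA_C_AXIS = 6.884

#: Caglioti instrument-resolution polynomial FWHM^2 = U tan^2(th) + V tan(th) + W,
#: FWHM in degrees 2-theta; values typical of a well-aligned lab diffractometer
#: calibrated on a silicon line-position/broadening standard.
CAGLIOTI_UVW = (0.005, -0.002, 0.003)

#: Default single-peak fit windows, degrees 2-theta.  The 210/030 windows
#: are generous because nanocrystalline bioapatite maxima run to ~2 deg
#: FWHM, which a 2-2.5 deg window cannot constrain; on patterns with
#: overlapping neighbour reflections narrow these via configuration.
XRD_FIT_WINDOWS = {
    "002": (23.0, 27.0),
    "210": (27.5, 30.5),
    "030": (31.0, 35.5),
    "004": (50.0, 55.0),
}

# --------------------------------------------------------------------------
# Instrumented indentation (Oliver-Pharr)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IndenterConstants:
    """Constants of the Oliver-Pharr reduction.

    E_i / nu_i are diamond; nu_s = 0.3 is the assumed bone Poisson ratio.
    ``epsilon`` is the contact-depth geometry factor and ``area_coeff`` the
    ideal Berkovich-equivalent projected area function A = area_coeff * h_c^2.
    ``unload_fit_range`` is the (low, high) fraction of P_max used for the
    unloading power-law fit.
    """

    E_i_GPa: float = 1141.0
    nu_i: float = 0.07
    nu_s: float = 0.3
    epsilon: float = 0.75
    area_coeff: float = 24.5
    unload_fit_range: tuple[float, float] = (0.40, 0.98)


#: Nanoindentation protocol: 10 mN hold load, 20 mN/min ramps, 30 s phases.
INDENT_PROTOCOL = dict(p_max_mN=10.0, rate_mN_min=20.0, hold_s=30.0, dt_s=0.1)

#: kgf/mm^2 Vickers number for load P [kgf] and mean diagonal d [mm].
VICKERS_GEOM_FACTOR = 1.8544

#: Vickers-equivalent of a projected-area hardness in MPa
#: (surface/projected area ratio of the 136 deg pyramid over g).
MPA_TO_VICKERS = VICKERS_GEOM_FACTOR / 2.0 / 9.80665

VICKERS_LOAD_GF = 10.0

# --------------------------------------------------------------------------
# Thermal analysis
# --------------------------------------------------------------------------

#: TGA/DSC window boundaries, deg C: dehydration 25-200, organic combustion 200-550.
THERMAL_WINDOWS = dict(t_low=25.0, t_mid=200.0, t_high=550.0)
HEATING_RATE_C_MIN = 10.0

# --------------------------------------------------------------------------
# ATR-FTIR
# --------------------------------------------------------------------------

#: Integration bands (cm^-1): v1v3 phosphate, amide I, v2 carbonate.
FTIR_BANDS = {
    "phosphate": (900.0, 1200.0),
    "amide_I": (1600.0, 1750.0),
    "carbonate": (850.0, 890.0),
}

#: Crystallinity-index intensity positions on the v4 phosphate doublet and the
#: local baseline span used before the three intensities are read.
FTIR_CI_POSITIONS = (605.0, 565.0, 595.0)
FTIR_CI_BASELINE = (500.0, 650.0)

# --------------------------------------------------------------------------
# The 33-parameter feature set
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterDefault:
    """Population structure of one synthetic parameter.

    ``age_r`` is the target Pearson correlation with age used by the
    generator; ``reported`` marks whether that correlation was published for
    the source cohort or is a package default.  ``derived`` parameters are
    computed from others (see ``synthetic.derive_columns``) and their
    ``age_r`` is informational only.
    """

    name: str
    mean: float
    sd: float
    age_r: float
    unit: str
    group: str
    reported: bool = True
    derived: bool = False


# Independent columns are drawn as X = mean + r*sd*z_age + sd*sqrt(1-r^2)*eps.
# Derived columns (mean-tissue mechanics, HV, Ash%, MM, CL002, CL004) keep the
# extractor's algebra and the generator's algebra identical, which is what the
# round-trip validation leans on.
PARAMETER_DEFAULTS: tuple[ParameterDefault, ...] = (
    # -- histomorphometry ---------------------------------------------------
    ParameterDefault("PoAr_pct", 10.5, 3.5, 0.83, "%", "histo"),
    # -- nanoindentation, osteonal ------------------------------------------
    ParameterDefault("On_E_IT", 19.5, 2.0, -0.20, "GPa", "nano"),
    ParameterDefault("On_H_IT", 620.0, 60.0, -0.10, "MPa", "nano", reported=False),
    ParameterDefault("On_C_IT", 4.0, 0.7, -0.29, "%", "nano"),
    ParameterDefault("On_eta_IT", 30.0, 4.0, 0.40, "%", "nano"),
    # -- nanoindentation, interstitial --------------------------------------
    ParameterDefault("It_E_IT", 21.5, 2.0, 0.00, "GPa", "nano"),
    ParameterDefault("It_H_IT", 680.0, 60.0, -0.10, "MPa", "nano", reported=False),
    ParameterDefault("It_C_IT", 3.8, 0.7, -0.27, "%", "nano"),
    ParameterDefault("It_eta_IT", 32.0, 4.0, 0.38, "%", "nano"),
    # -- Vickers microhardness ----------------------------------------------
    ParameterDefault("On_HV", 52.0, 6.0, 0.44, "kg/mm^2", "micro"),
    ParameterDefault("It_HV", 58.0, 6.0, 0.55, "kg/mm^2", "micro"),
    # -- thermal -------------------------------------------------------------
    ParameterDefault("W_pct", 7.5, 1.3, -0.25, "%", "thermal"),
    ParameterDefault("Or_pct", 26.0, 2.5, -0.39, "%", "thermal"),
    ParameterDefault("LdH", 120.0, 25.0, -0.27, "J/g", "thermal"),
    ParameterDefault("CdH", 900.0, 150.0, -0.24, "J/g", "thermal"),
    # -- FTIR ----------------------------------------------------------------
    ParameterDefault("CP", 0.22, 0.025, 0.36, "-", "ftir"),
    ParameterDefault("CI", 3.8, 0.25, 0.10, "-", "ftir", reported=False),
    ParameterDefault("CC", 0.30, 0.035, -0.20, "-", "ftir", reported=False),
    # -- XRD -----------------------------------------------------------------
    ParameterDefault("CL030", 9.0, 1.5, 0.23, "nm", "xrd"),
    ParameterDefault("CL210", 12.0, 2.0, 0.10, "nm", "xrd", reported=False),
    ParameterDefault("a_axis", 9.420, 0.004, -0.20, "Angstrom", "xrd"),
    ParameterDefault("c_axis", 6.885, 0.003, 0.05, "Angstrom", "xrd", reported=False),
    ParameterDefault("Size", 28.0, 4.0, 0.22, "nm", "xrd"),
    ParameterDefault("Strain", 0.0045, 0.0008, -0.15, "-", "xrd", reported=False),
    # -- derived columns -----------------------------------------------------
    ParameterDefault("E_IT", 20.5, 1.5, -0.19, "GPa", "nano", derived=True),
    ParameterDefault("H_IT", 650.0, 45.0, -0.10, "MPa", "nano", reported=False, derived=True),
    ParameterDefault("C_IT", 3.9, 0.5, -0.30, "%", "nano", derived=True),
    ParameterDefault("eta_IT", 31.0, 3.0, -0.41, "%", "nano", derived=True),
    ParameterDefault("HV", 55.0, 4.5, 0.50, "kg/mm^2", "micro", reported=False, derived=True),
    ParameterDefault("Ash_pct", 66.5, 2.9, 0.41, "%", "thermal", derived=True),
    ParameterDefault("MM", 3.38, 0.40, 0.10, "-", "ftir", reported=False, derived=True),
    ParameterDefault("CL002", 15.4, 1.5, 0.15, "nm", "xrd", reported=False, derived=True),
    ParameterDefault("CL004", 10.7, 1.0, 0.10, "nm", "xrd", reported=False, derived=True),
)

PARAMETER_NAMES: tuple[str, ...] = tuple(p.name for p in PARAMETER_DEFAULTS)
INDEPENDENT_PARAMETERS: tuple[str, ...] = tuple(
    p.name for p in PARAMETER_DEFAULTS if not p.derived
)
DERIVED_PARAMETERS: tuple[str, ...] = tuple(
    p.name for p in PARAMETER_DEFAULTS if p.derived
)

#: Candidate pools for stepwise model building.
CANDIDATE_SETS = {
    "all": list(PARAMETER_NAMES),
    "nano": [p.name for p in PARAMETER_DEFAULTS if p.group in ("nano", "micro", "histo")],
    "physchem": [p.name for p in PARAMETER_DEFAULTS if p.group in ("thermal", "ftir", "xrd")],
}


def parameter_default(name: str) -> ParameterDefault:
    for p in PARAMETER_DEFAULTS:
        if p.name == name:
            return p
    raise KeyError(f"unknown parameter {name!r}")
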