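# Methods

`ribchron` implements a multifactorial laboratory workflow for estimating
age at death from rib cortical bone: five measurement modalities reduce raw
instrument output to a 33-parameter feature vector per specimen, and a
regression layer turns a cohort of such vectors into age-estimation
equations with diagnostics and cross-validation. A seeded forward generator
renders raw modality data from known parameters so that every reduction
stage can be validated by round-trip recovery.

## Measurement reductions

### Instrumented indentation (Oliver–Pharr)

Curves follow a 10 mN / 20 mN·min⁻¹ / 30 s-phase protocol. The unloading
branch is fitted with a power law `P = α(h − h_f)^m` over the 40–98 %
load fraction; the contact stiffness `S = dP/dh` at maximum depth gives the
contact depth `h_c = h_max − ε P_max/S` (ε = 0.75), the projected area
`A = 24.5 h_c²` (ideal Berkovich-equivalent), and from these

- hardness `H_IT = P_max / A` (MPa; a Vickers-equivalent scale
  `HV ≈ 0.09455 · H_IT[MPa]` is reported alongside, because fixed published
  equations quote H_IT on that scale),
- modulus `E_IT` from the reduced modulus
  `E_r = √π S / (2√A)` with `1/E_r = (1−ν_s²)/E_s + (1−ν_i²)/E_i`,
  ν_s = 0.3, diamond constants E_i = 1141 GPa, ν_i = 0.07,
- creep `C_IT = (h₂ − h₁)/h₁ × 100` over the hold phase (ISO 14577 sign
  convention: positive when depth grows during hold; the source formula
  prints the opposite difference but treats the quantity as positive),
- elastic work fraction `η_IT = w_elast/(w_elast + w_plast) × 100` with
  works integrated trapezoidally over depth; loading+hold are integrated as
  one contiguous slice and the last hold point is prepended to unloading so
  no phase-boundary segment is dropped.

Phase labels are honoured when present; otherwise samples within 1 % of
maximum load form the hold. Sites are aggregated per compartment (osteonal
/ interstitial, 8 indentations × 4 quadrants each by default) and the
mean-tissue value is the average of the two compartment means. Vickers
microhardness is `HV = 1.8544 P/d²` (P kgf, d mm) at 10 gf.

### Thermal analysis (TGA/DSC)

The 25→550 °C, 10 °C/min ramp is reduced by boundary reads at 25/200 °C
and the final sample (the 550 °C isothermal hold is folded into the last
point): `W% = 100(m₂₅ − m₂₀₀)/m₂₅`, `Or% = 100(m₂₀₀ − m_end)/m₂₅`,
`Ash% = 100 − W% − Or%` (an identity by construction). Masses at the
boundaries are linearly interpolated, not tangent-constructed. Enthalpies
are linear-baseline integrals of heat flow over *time* (temperature/rate)
within the same windows; the dehydration endotherm (LΔH) and combustion
exotherm (CΔH) are reported as positive magnitudes in J/g — an integral of
W/g over seconds, although source tables sometimes print the instrument
unit W/g for these.

### ATR-FTIR

Band areas use a per-band chord baseline and trapezoidal integration:
ν₁ν₃ phosphate 1200–900 cm⁻¹, amide I 1750–1600 cm⁻¹, ν₂ carbonate
890–850 cm⁻¹. Indices: `MM = A_phos/A_amide`, `CP = A_carb/A_phos`,
`CC = A_amide/A_phos` (so `MM·CC = 1` identically), and the crystallinity
splitting index `CI = (I₆₀₅ + I₅₆₅)/I₅₉₅` — read as the conventional
splitting factor, not the literal left-to-right parse of the printed
string — with the three intensities taken after a local linear baseline
over 650–500 cm⁻¹ and linear interpolation at off-grid positions.

### X-ray diffraction

Four bioapatite maxima (002, 210, 030, 004) are fitted with asymmetric
split pseudo-Voigt profiles (independent left/right FWHM, shared
Gauss/Lorentz mixing) plus a linear background; 002/004 come from dedicated
stepped scans (≈3× count time), 210/030 from the 10–80° wide scan.
Single-peak analysis replaces whole-pattern refinement deliberately: every
derived quantity below needs only the four fitted positions/widths.

Instrument broadening from a Caglioti polynomial
(`FWHM² = U tan²θ + V tanθ + W`, silicon-standard provenance) is removed by
Gaussian quadrature subtraction (`β_s = √(β_obs² − β_inst²)`; Lorentzian
linear subtraction available). Then

- Scherrer coherence lengths `CL = Kλ/(β cosθ)`, K = 0.9, λ = 0.15406 nm,
- ⟨00ℓ⟩ size/strain separation by the two-point Williamson–Hall line
  `β cosθ = 4ε sinθ + Kλ/L` through the 002 and 004 points,
- lattice parameters from Bragg positions via the hexagonal d-spacing
  relation: `c = 2d₀₀₂` cross-checked against `4d₀₀₄` (warning above 0.5 %
  disagreement, average reported), `a = d₀₃₀√12`.

Fit windows default to 23–27° (002), 27.5–30.5° (210), 31.0–35.5° (030),
50–55° (004). The 210/030 windows are wider than the minimal ones around
those maxima because nanocrystalline bone apatite peaks reach ~2° FWHM and
a window comparable to the FWHM cannot constrain the profile (verified to
produce 8–22 % width errors); on patterns with strong neighbouring
reflections (211/112/300) the windows should be narrowed via configuration.
The fit uses a small multi-start over mixing/width initialisations to avoid
noise-driven local minima.

### Histomorphometry

Optical porosity `Po.Ar% = 100 · void pixels / total pixels` per binary
quadrant mask (void = foreground; osteocyte-lacuna-scale objects count when
the threshold captured them), averaged over the four sampling quadrants.
Although the source text describes "dividing bone area by total cortical
surface", the quantity is implemented as the void fraction — the only
reading consistent with calling it porosity. Grey-level input can be
binarised by Otsu's method, but the reference path takes pre-thresholded
masks; manual region outlines are represented by externally supplied masks
rather than re-implemented tracing.

## Regression layer

Screening: Shapiro–Wilk normality, one-way ANOVA by sex, Pearson
correlation with age, flagged at α = 0.05.

Model building: bidirectional stepwise OLS starting from the empty model,
scoring all single add/remove moves by AIC (Gaussian log-likelihood form)
and taking the best strict improvement; ties resolve deterministically to
the earliest candidate in input order. Direction and start are
configurable. Candidate pools: the full 33-parameter set, the
mechanical/porosity subset, and the physicochemical subset.

Diagnostics on the final fit: VIF from auxiliary regressions (capped at
10⁶ for numerically collinear predictors; exact duplicates raise), the
condition index of the column-scaled design, Breusch–Pagan overall plus
per-predictor with Bonferroni adjustment, Shapiro–Wilk on residuals,
Durbin–Watson with a permutation p-value (2000 seeded shuffles of the
residual order; the statistic's null distribution is model-dependent and
the permutation approach avoids tabulated bounds), and Cook's distances
flagged at 4/n.

Validation: leave-one-out cross-validation by explicit refitting;
`CV-R² = 1 − SS_pred/SS_tot`, CV-RMSE, CV-MAE. Missing values fail fast —
no imputation.

Fixed published equations (E1 full-set, E2 mechanical, E3 physicochemical)
ship as JSON with their reported fit statistics and apply as dot products
over named parameters in their original reporting units. Where the printed
three-column coefficient table interleaves ambiguously, the encoded
assignment follows the per-model degrees of freedom (10/6/5), the narrative
composition of E2, and the observation that the large opposite-signed
a-axis/c-axis coefficients only balance the −759.525 constant if both sit
in E1; the assignment is overridable by a user equations file.

## Synthetic cohort generator

Ages are truncated-normal (rejection sampling) with defaults n = 113,
46.64 ± 16.33 yr on [12, 84], 77/113 male. Each independently drawn
parameter follows

    X = mean + r·sd·z_age + sd·√(1−r²)·ε

with z_age the empirically standardised age. The noise ε is residualised
against z_age and restandardised (the `mvrnorm(empirical = TRUE)` device),
so the realised sample correlation equals the target r exactly at any
cohort size instead of to O(n^−1/2); with ~24 parameters checked at once,
literal iid noise would leave the ±0.02 fidelity band by chance in most
runs. Parameters are mutually independent given age; cross-parameter
structure beyond age is not modelled.

Nine columns are *derived*, with the same algebra the extraction layer
uses, so generated tables are internally consistent and round-trippable:
Ash% = 100 − W% − Or%; MM = 1/CC; mean-tissue E_IT/H_IT/C_IT/η_IT and HV
as compartment averages; CL002/CL004 from (Size, Strain, c-axis) through
the Williamson–Hall relation. Their age correlations are therefore implied
rather than enforced (the implied Ash% correlation ≈ 0.44 under the
default W/Or structure, against a target of ≈ 0.4). Two reported
correlation signs are internally contradictory in the source (CΔH; the
mean-tissue vs compartment η_IT signs): defaults follow the narrative sign
(CΔH negative) and the derivation (mean-tissue η positive), and every sign
is overridable in configuration.

Default means/SDs are plausible values for fresh human rib cortical bone
(flagged `reported=False` in `constants.py` where the source publishes no
value): e.g. E_IT ≈ 20 GPa, H_IT ≈ 650 MPa, HV ≈ 55 kg/mm², porosity
≈ 10 %, W/Or/Ash ≈ 7.5/26/66.5 %, MM ≈ 3.4, CP ≈ 0.22, CL002 ≈ 15 nm,
lattice a ≈ 9.420 Å, c ≈ 6.885 Å.

### Raw-data renderers

Each renderer is the forward model of its extraction stage:

- **Indentation**: the unloading power law (m = 1.5) is anchored to the
  target stiffness/modulus, the hold creeps by the target C_IT (√t
  profile), and the loading exponent is solved per curve so the elastic
  work fraction equals the target η_IT. η_IT = 100 renders the fully
  elastic limit (unloading retraces loading). The loading exponent is
  generator plumbing — it absorbs the work-partition constraint and is not
  a claim about real bone loading curves. Site-level values scatter by 1 %
  (relative) around the specimen value.
- **TGA/DSC**: two logistic mass-loss steps centred at 110/330 °C (widths
  12/20 °C) with magnitudes W%/Or%; Gaussian heat-flow peaks at the same
  centres whose time-integrals equal LΔH (endothermic) and CΔH
  (exothermic), exo-up convention, ~10 mg initial mass.
- **FTIR**: Gaussian bands (phosphate area 1 a.u. at 1015 cm⁻¹, σ 25;
  amide I area CC at 1660, σ 15; carbonate area CP at 872, σ 5) plus an
  equal-height ν₄ doublet at 603/565 cm⁻¹ whose width is solved
  numerically for the target CI. The 2 cm⁻¹ grid is offset so the three CI
  read positions are exact grid points.
- **XRD**: peak positions recomputed from the record's lattice parameters;
  00ℓ widths from (Size, Strain) via Williamson–Hall, 030/210 widths from
  their coherence lengths via Scherrer; Caglioti instrument width folded in
  by quadrature; symmetric split pseudo-Voigt profiles (mixing 0.45) on a
  linear background with count noise 0.15·√I (stepped scans 3× amplitude).
- **Porosity**: four 256×256 masks of random non-overlapping disks (radii
  3–8 px) accumulated until the void fraction is as close as one disk
  allows to the target (≤ ~0.3 pp discretisation).

One global seed; the per-specimen stream is `default_rng([seed, index])`,
so any specimen's bundle is reproducible in isolation and fixed seeds give
byte-identical tables and files.

### What the generator does and does not emulate

It reproduces the study's age-correlation structure, cohort frame,
modality protocols and the noise scales of well-behaved instruments. It
does **not** model: cross-parameter correlations beyond age, diagenesis or
taphonomy, pathological subgroups, osteon microstructure (masks are void
disks, not histology), overlapping neighbour reflections in the 25–35°
diffraction region, ATR penetration-depth effects, thermal drift or frame
compliance, or operator-dependent thresholding. Passing round-trip tests
therefore demonstrates correctness of the reductions under controlled
conditions, not robustness to every artefact of real bench data.

## Tolerances and verification

Round-trip recovery over 50 seeded specimens (the acceptance suite):
mechanics within 2 % relative; W/Or/Ash within 0.5 percentage points and
enthalpies within 2 %; FTIR indices within 2 %; CL002/CL004/CL030 within
2 %; lattice axes within 0.1 %; porosity within 0.5 pp. Oracle
equivalences: stepwise selection equals exhaustive best-subset on a
6-candidate problem; LOO metrics equal an explicit refit loop; published
equations equal independent dot products; Scherrer and two-point
Williamson–Hall invert algebraically to machine precision. Statistical
null behaviour: Breusch–Pagan type-I error ≈ 5 % over 1000 homoskedastic
replicates; Durbin–Watson ≈ 2 ± 0.06 at n = 10⁴.

Problem sizes used by `scripts/acceptance.py`: 20 round-trip specimens
with 2 indentations per site, n = 10⁴ for correlation fidelity, the full
n = 113 cohort for model building and LOO, 1000 replicates for the
Breusch–Pagan rate — sizes at which every reported quantity is stable at
the precision reported while the whole script stays desk-scale.

## Known limitations

- Whether the source instrument's hardness used projected or developed
  area is unrecoverable; the choice shifts absolute H_IT scale but not
  age-correlation structure.
- The Breusch–Pagan "Bonferroni adjusted" procedure is reconstructed as
  per-predictor tests with multiplicity correction; the source does not
  specify its exact form.
- The fixed-equation column assignment (C_IT, lattice axes, CL004, the two
  HV coefficients) follows documented reasoning but cannot be verified
  against the typeset source table; it is deliberately overridable.
- LΔH/CΔH round-trip accuracy is bounded by chord-baseline sensitivity to
  endpoint noise (~1.5 % at the default DSC noise), inherent to linear
  baseline integration.
- Stepwise AIC is a greedy search; equality with the exhaustive optimum is
  a property of well-separated signals, not a guarantee.
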