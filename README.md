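# ribchron

Multifactorial **age-at-death estimation from rib cortical bone** for
forensic anthropology. The package implements the full laboratory-to-model
workflow: reduction of five raw measurement modalities to a 33-parameter
bone-matrix feature vector per specimen, stepwise regression modelling of
chronological age with complete diagnostics and leave-one-out validation,
application of published fixed estimation equations, and a seeded
synthetic-cohort generator whose raw output round-trips through every
extraction stage.

**Who it is for:** forensic anthropologists and bone-biomaterials
researchers who want an observer-independent, fully scripted age-estimation
pipeline, and methodologists who want a controlled test bed for
multifactorial skeletal-ageing statistics.

## The measurements and the model

Each specimen contributes:

| Modality | Raw data | Derived parameters |
|---|---|---|
| Nanoindentation (Oliver–Pharr) | load–depth–time curves, 10 mN protocol | `H_IT`, `E_IT`, creep `C_IT`, elastic work ratio `η_IT` — per osteonal (On) / interstitial (It) compartment and mean tissue |
| Vickers microhardness | indent diagonals, 10 gf | `HV = 1.8544·P/d²` per compartment |
| TGA/DSC 25→550 °C | mass and heat-flow curves | water `W%`, organic `Or%`, mineral `Ash% = 100−W%−Or%`, enthalpies `LΔH`, `CΔH` |
| ATR-FTIR 4000–400 cm⁻¹ | absorbance spectra | mineral-to-matrix `MM`, carbonate `CP`, crystallinity `CI = (I₆₀₅+I₅₆₅)/I₅₉₅`, collagen `CC = 1/MM` |
| Powder XRD | wide + stepped 2θ scans | coherence lengths `CL = Kλ/(β cosθ)` (Scherrer) for 002/004/030/210, Williamson–Hall size/strain (`β cosθ = 4ε sinθ + Kλ/L`), hexagonal lattice `a`, `c` |
| Histomorphometry | binary cortical masks | optical porosity `Po.Ar%` (void fraction, 4-quadrant mean) |

Age is modelled by ordinary least squares with bidirectional stepwise
selection minimising AIC over a candidate pool (full set, mechanical-only,
or physicochemical-only), followed by collinearity (VIF, condition index),
heteroscedasticity (Breusch–Pagan), residual-normality (Shapiro–Wilk),
autocorrelation (Durbin–Watson, permutation p) and influence (Cook's
distance) diagnostics, and leave-one-out cross-validation (CV-R², CV-RMSE,
CV-MAE). Published equations E1/E2/E3 ship as data and apply as dot
products.

## Worked example

```python
from ribchron import build_parameter_table, stepwise_aic, loo_cv
from ribchron.constants import CANDIDATE_SETS

table = build_parameter_table(seed=17)          # 113 synthetic specimens
fitted = stepwise_aic(table, CANDIDATE_SETS["all"], dw_permutations=0)
cv = loo_cv(table, fitted.predictors)
print(len(fitted.predictors), round(fitted.r2, 3), round(cv.cv_mae, 2))
```

prints

```
10 0.833 5.46
```

— stepwise selection kept 10 of 33 parameters, the fit explains 83 % of
age variance on this synthetic cohort, and the cross-validated mean
absolute error is 5.5 years. (The cohort is generated with the porosity-
dominated age-correlation structure of real rib data — porosity r = 0.83,
interstitial microhardness r = 0.55 — so porosity and microhardness lead
the selected set.) The same run from the shell:

```bash
ribchron simulate --n 113 --seed 17 --out demo/        # raw bundles + parameters.csv
ribchron extract  --raw-dir demo/raw --out demo/extracted.csv --meta demo/parameters.csv
ribchron validate --table demo/extracted.csv --out demo/report.json
```

`examples/` contains one short script per capability (cohort simulation,
indentation reduction, physicochemical reductions, model building, full
pipeline); each prints the numbers it computes and what they mean.

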