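{
  "_comment": "Published fixed age-estimation equations for rib cortical bone. E1: stepwise over the full 33-parameter set (df 10); E2: nanoindentation/microhardness/porosity subset (df 6); E3: physicochemical-only subset (df 5). Coefficients apply to variables in their original reporting units (H_IT on the Vickers-equivalent scale). The 0.466 HV coefficient in E2 is assigned to It_HV following the narrative model composition; the interleaved table column assignment for C_IT, the lattice axes and CL004 follows the per-model degrees of freedom and is overridable via a custom equations file.",
  "equations": {
    "E1": {
      "constant": -759.525,
      "coefficients": {
        "PoAr_pct": 6.001,
        "H_IT": -0.446,
        "C_IT": 3.825,
        "On_E_IT": 1.222,
        "On_eta_IT": 2.523,
        "On_HV": 0.624,
        "CdH": -0.005,
        "CL030": 5.450,
        "a_axis": -369.968,
        "c_axis": 597.609
      },
      "fit": {"n": 113, "r2": 0.863, "adj_r2": 0.850, "rse": 6.453, "df": 102,
              "f": 64.425, "aic": 754.5063, "bic": 787.235,
              "cv_r2": 0.835, "rmse": 6.453, "cv_rmse": 6.736,
              "mae": 4.644, "cv_mae": 5.125}
    },
    "E2": {
      "constant": -62.45,
      "coefficients": {
        "PoAr_pct": 6.120,
        "H_IT": -0.858,
        "On_E_IT": 1.683,
        "HV": 0.531,
        "On_eta_IT": 1.946,
        "It_HV": 0.466
      },
      "fit": {"n": 113, "r2": 0.845, "adj_r2": 0.836, "rse": 6.737, "df": 106,
              "f": 96.441, "aic": 760.5891, "bic": 782.4082,
              "cv_r2": 0.825, "rmse": 6.737, "cv_rmse": 6.946,
              "mae": 5.098, "cv_mae": 5.428}
    },
    "E3": {
      "constant": -249.937,
      "coefficients": {
        "Ash_pct": 4.697,
        "CdH": -0.012,
        "CC": 204.382,
        "CL030": 8.938,
        "CL004": -3.455
      },
      "fit": {"n": 113, "r2": 0.315, "adj_r2": 0.283, "rse": 14.101, "df": 107,
              "f": 9.860, "aic": 926.564, "bic": 945.6557,
              "cv_r2": 0.249, "rmse": 14.101, "cv_rmse": 14.420,
              "mae": 11.395, "cv_mae": 11.996}
    }
  }
}
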