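"""Workflow orchestration: simulate -> extract -> fit / predict / validate.

All tabular interchange is CSV (auditable, diff-able); masks are PNG.  A
run's configuration hash is stamped into every report so results are
traceable to the exact constants that produced them.

Per-specimen raw files::

    <id>_indent_q<1-4>_<on|it>_<k>.csv   time_s, load_mN, depth_nm, phase
    <id>_vickers.csv                     quadrant, compartment, load_gf, diagonal_um
    <id>_tga.csv                         temperature_C, mass_mg  (+ initial-mass header)
    <id>_dsc.csv                         temperature_C, heatflow_Wg (+ convention header)
    <id>_ftir.csv                        wavenumber_cm1, absorbance
    <id>_xrd_wide.csv / _xrd_002.csv / _xrd_004.csv   two_theta_deg, intensity
    <id>_quadrant<1-4>.png               binary void masks
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age_model import (
    FittedModel,
    apply_published,
    load_published_equations,
    loo_cv,
    stepwise_aic,
)
from .constants import CANDIDATE_SETS, HEATING_RATE_C_MIN, PARAMETER_NAMES
from .ftir import Spectrum, ftir_indices
from .histomorphometry import CorticalMask, load_mask_png, save_mask_png, specimen_porosity
from .indentation import (
    IndentationCurve,
    aggregate_sites,
    aggregate_vickers,
    analyze_indentation,
    vickers_hv,
)
from .synthetic import (
    PopulationSpec,
    RawBundle,
    RenderOptions,
    build_parameter_table,
    render_raw,
)
from .thermal import HeatFlowCurve, Thermogram, dsc_enthalpies, tga_steps
from .xrd import DiffractionPattern, analyze_patterns

__all__ = [
    "config_hash",
    "load_config",
    "simulate_dataset",
    "write_bundle",
    "read_bundle",
    "extract_bundle",
    "extract_all",
    "validate",
    "ExtractionFailure",
]

log = logging.getLogger("ribchron")

_FLOAT_FMT = "%.10g"


class ExtractionFailure(RuntimeError):
    """Raised under strict mode when any specimen fails extraction."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def load_config(path: str | Path | None) -> dict:
    """YAML run configuration; an absent path yields the empty (default) config."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def population_from_config(cfg: Mapping, seed: int, n: int | None = None) -> PopulationSpec:
    pop = dict(cfg.get("population", {}))
    if n is not None:
        pop["n_specimens"] = n
    return PopulationSpec(seed=seed, **pop)


def render_options_from_config(cfg: Mapping) -> RenderOptions:
    return RenderOptions(**cfg.get("render", {}))


# --------------------------------------------------------------------------
# raw-bundle file IO
# --------------------------------------------------------------------------

def write_bundle(bundle: RawBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = bundle.specimen_id

    counters: dict[tuple[int, str], int] = {}
    for c in bundle.indentation_curves:
        key = (c.quadrant, c.compartment)
        counters[key] = counters.get(key, 0) + 1
        df = pd.DataFrame({
            "time_s": c.time_s, "load_mN": c.load_mN,
            "depth_nm": c.depth_nm, "phase": c.phase,
        })
        df.to_csv(outdir / f"{sid}_indent_q{c.quadrant}_{c.compartment}_{counters[key]}.csv",
                  index=False, float_format=_FLOAT_FMT)

    pd.DataFrame(bundle.vickers,
                 columns=["quadrant", "compartment", "load_gf", "diagonal_um"]).to_csv(
        outdir / f"{sid}_vickers.csv", index=False, float_format=_FLOAT_FMT)

    tga_path = outdir / f"{sid}_tga.csv"
    with open(tga_path, "w") as fh:
        fh.write(f"# initial_mass_mg={bundle.thermogram.initial_mass_mg:.10g}\n")
        pd.DataFrame({"temperature_C": bundle.thermogram.temperature_C,
                      "mass_mg": bundle.thermogram.mass_mg}).to_csv(
            fh, index=False, float_format=_FLOAT_FMT)

    dsc_path = outdir / f"{sid}_dsc.csv"
    with open(dsc_path, "w") as fh:
        conv = "exo_up" if bundle.heatflow.exo_up else "endo_up"
        fh.write(f"# sign_convention={conv} heating_rate_C_min={HEATING_RATE_C_MIN}\n")
        pd.DataFrame({"temperature_C": bundle.heatflow.temperature_C,
                      "heatflow_Wg": bundle.heatflow.heatflow_W_g}).to_csv(
            fh, index=False, float_format=_FLOAT_FMT)

    pd.DataFrame({"wavenumber_cm1": bundle.ftir_spectrum.wavenumber_cm1,
                  "absorbance": bundle.ftir_spectrum.absorbance}).to_csv(
        outdir / f"{sid}_ftir.csv", index=False, float_format=_FLOAT_FMT)

    suffix = {"wide": "wide", "stepped_002": "002", "stepped_004": "004"}
    for kind, pattern in bundle.diffraction.items():
        pd.DataFrame({"two_theta_deg": pattern.two_theta_deg,
                      "intensity": pattern.intensity}).to_csv(
            outdir / f"{sid}_xrd_{suffix[kind]}.csv", index=False, float_format=_FLOAT_FMT)

    for mask in bundle.porosity_masks:
        save_mask_png(mask, outdir / f"{sid}_quadrant{mask.quadrant}.png")


def _read_csv_skip_comments(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_bundle(raw_dir: str | Path, specimen_id: str) -> RawBundle:
    """Load one specimen's raw files back into a :class:`RawBundle`."""
    d = Path(raw_dir)
    sid = specimen_id

    curves = []
    pat = re.compile(rf"{re.escape(sid)}_indent_q(\d)_(on|it)_(\d+)\.csv$")
    for path in sorted(d.glob(f"{sid}_indent_q*_*.csv")):
        m = pat.search(path.name)
        if not m:
            continue
        df = pd.read_csv(path)
        curves.append(IndentationCurve(
            df["time_s"].to_numpy(), df["load_mN"].to_numpy(), df["depth_nm"].to_numpy(),
            df["phase"].to_numpy() if "phase" in df else None,
            quadrant=int(m.group(1)), compartment=m.group(2),
        ))

    vick_df = pd.read_csv(d / f"{sid}_vickers.csv")
    vickers = [(int(r.quadrant), str(r.compartment), float(r.load_gf), float(r.diagonal_um))
               for r in vick_df.itertuples()]

    with open(d / f"{sid}_tga.csv") as fh:
        header = fh.readline()
    m0 = float(header.split("initial_mass_mg=")[1]) if "initial_mass_mg=" in header else None
    tga_df = _read_csv_skip_comments(d / f"{sid}_tga.csv")
    tg = Thermogram(tga_df["temperature_C"].to_numpy(), tga_df["mass_mg"].to_numpy(), m0)

    with open(d / f"{sid}_dsc.csv") as fh:
        header = fh.readline()
    exo_up = "endo_up" not in header
    dsc_df = _read_csv_skip_comments(d / f"{sid}_dsc.csv")
    hf = HeatFlowCurve(dsc_df["temperature_C"].to_numpy(), dsc_df["heatflow_Wg"].to_numpy(), exo_up)

    ftir_df = pd.read_csv(d / f"{sid}_ftir.csv")
    spec = Spectrum(ftir_df["wavenumber_cm1"].to_numpy(), ftir_df["absorbance"].to_numpy())

    diffraction = {}
    for kind, suffix in (("wide", "wide"), ("stepped_002", "002"), ("stepped_004", "004")):
        df = pd.read_csv(d / f"{sid}_xrd_{suffix}.csv")
        diffraction[kind] = DiffractionPattern(
            df["two_theta_deg"].to_numpy(), df["intensity"].to_numpy(), scan_kind=kind)

    masks = [load_mask_png(d / f"{sid}_quadrant{q}.png", quadrant=q)
             for q in range(1, 5) if (d / f"{sid}_quadrant{q}.png").exists()]

    return RawBundle(sid, curves, vickers, tg, hf, spec, diffraction, masks)


# --------------------------------------------------------------------------
# extraction
# --------------------------------------------------------------------------

def extract_bundle(bundle: RawBundle, cfg: Mapping | None = None) -> dict[str, float]:
    """Run every modality's extraction on one bundle; returns the 33 parameters."""
    cfg = cfg or {}
    out: dict[str, float] = {}

    results = [analyze_indentation(c) for c in bundle.indentation_curves]
    out.update(aggregate_sites(results))

    out.update(aggregate_vickers(
        [(comp, vickers_hv(load, diag)) for _, comp, load, diag in bundle.vickers]))

    w, org, ash = tga_steps(bundle.thermogram, **cfg.get("thermal_windows", {}))
    ldh, cdh = dsc_enthalpies(bundle.heatflow, **cfg.get("thermal_windows", {}))
    out.update(W_pct=w, Or_pct=org, Ash_pct=ash, LdH=ldh, CdH=cdh)

    fr = ftir_indices(bundle.ftir_spectrum)
    out.update(MM=fr.MM, CP=fr.CP, CI=fr.CI, CC=fr.CC)

    xr = analyze_patterns(
        bundle.diffraction["wide"],
        bundle.diffraction.get("stepped_002"),
        bundle.diffraction.get("stepped_004"),
    )
    out.update(CL002=xr.CL002_nm, CL004=xr.CL004_nm, CL030=xr.CL030_nm, CL210=xr.CL210_nm,
               a_axis=xr.a_axis_A, c_axis=xr.c_axis_A, Size=xr.size_nm, Strain=xr.strain)

    out["PoAr_pct"] = specimen_porosity(bundle.porosity_masks).po_ar_pct
    return out


def discover_specimens(raw_dir: str | Path) -> list[str]:
    ids = sorted({p.name.rsplit("_tga.csv", 1)[0]
                  for p in Path(raw_dir).glob("*_tga.csv")})
    return ids


def extract_all(
    raw_dir: str | Path,
    cfg: Mapping | None = None,
    metadata: pd.DataFrame | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Extract every specimen in a raw directory into one parameter table.

    Specimens that fail a modality get NaN for the affected columns and a
    collected warning; ``strict`` upgrades any failure (or an empty
    directory) to :class:`ExtractionFailure`.  ``metadata`` (specimen_id,
    sex, age) is merged in when supplied.
    """
    ids = discover_specimens(raw_dir)
    if not ids:
        if strict:
            raise ExtractionFailure(f"no raw bundles found in {raw_dir}")
        return pd.DataFrame(columns=["specimen_id", *PARAMETER_NAMES])

    rows, errors = [], []
    for sid in ids:
        row: dict[str, object] = {"specimen_id": sid}
        try:
            bundle = read_bundle(raw_dir, sid)
            row.update(extract_bundle(bundle, cfg))
        except Exception as exc:  # noqa: BLE001 - collected per specimen
            errors.append((sid, str(exc)))
            log.warning("extraction failed for %s: %s", sid, exc)
        rows.append(row)
    if errors and strict:
        raise ExtractionFailure(f"{len(errors)} specimen(s) failed: {errors[:3]}")
    table = pd.DataFrame(rows)
    for name in PARAMETER_NAMES:
        if name not in table.columns:
            table[name] = np.nan
    table = table[["specimen_id", *PARAMETER_NAMES]]
    if metadata is not None:
        table = metadata.merge(table, on="specimen_id", how="right")
    return table


# --------------------------------------------------------------------------
# simulation driver
# --------------------------------------------------------------------------

def simulate_dataset(
    outdir: str | Path,
    n: int | None = None,
    seed: int = 0,
    cfg: Mapping | None = None,
    write_raw: bool = True,
) -> pd.DataFrame:
    """Generate a cohort, write ``parameters.csv`` and (optionally) raw bundles."""
    cfg = cfg or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop = population_from_config(cfg, seed=seed, n=n)
    table = build_parameter_table(pop, seed=seed)
    table.to_csv(outdir / "parameters.csv", index=False, float_format=_FLOAT_FMT)
    if write_raw:
        opt = render_options_from_config(cfg)
        raw_dir = outdir / "raw"
        for i, rec in enumerate(table.to_dict("records")):
            bundle = render_raw(rec, seed=seed, options=opt, specimen_index=i)
            write_bundle(bundle, raw_dir)
    log.info("simulated %d specimens into %s (config %s)", len(table), outdir, config_hash(cfg))
    return table


# --------------------------------------------------------------------------
# validation report
# --------------------------------------------------------------------------

def _model_block(table: pd.DataFrame, fitted: FittedModel) -> dict:
    cv = loo_cv(table, fitted.predictors) if fitted.predictors else None
    block = {"fit": fitted.summary_dict()}
    block["cv"] = (
        {"cv_r2": cv.cv_r2, "cv_rmse": cv.cv_rmse, "cv_mae": cv.cv_mae} if cv else None
    )
    block["rmse"] = float(np.sqrt(np.mean(fitted.residuals**2)))
    block["mae"] = float(np.mean(np.abs(fitted.residuals)))
    return block


def validate(
    table: pd.DataFrame,
    candidate_sets: Sequence[str] = ("all", "nano", "physchem"),
    cfg: Mapping | None = None,
    dw_permutations: int = 2000,
) -> dict:
    """Fit stepwise models per candidate pool, with side-by-side fit and CV metrics.

    Returns the machine-readable run report (JSON-serialisable dict).
    """
    cfg = cfg or {}
    if "age" not in table.columns:
        raise ValueError("table must contain an 'age' column")
    model_cfg = cfg.get("model", {})
    direction = model_cfg.get("direction", "both")
    start = model_cfg.get("start", "empty")

    report: dict = {
        "software_version": __version__,
        "config_hash": config_hash(cfg),
        "n_specimens": int(len(table)),
        "models": {},
        "warnings": [],
    }
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for name in candidate_sets:
            pool = CANDIDATE_SETS.get(name, None)
            if pool is None:
                raise KeyError(f"unknown candidate set {name!r}")
            pool = [p for p in pool if p in table.columns]
            fitted = stepwise_aic(table, pool, direction=direction, start=start,
                                  dw_permutations=dw_permutations)
            report["models"][name] = _model_block(table, fitted)
    report["warnings"] = sorted({str(w.message) for w in caught})
    return report


def predict_table(
    table: pd.DataFrame,
    equation: str = "E1",
    equations_path: str | None = None,
) -> pd.DataFrame:
    """Apply a published fixed equation to every row of a parameter table."""
    eqs = load_published_equations(equations_path)
    if equation not in eqs:
        raise KeyError(f"unknown equation {equation!r}; available: {sorted(eqs)}")
    out = table[["specimen_id"]].copy() if "specimen_id" in table.columns else pd.DataFrame(index=table.index)
    out["predicted_age"] = apply_published(table, eqs[equation])
    return out
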