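"""CSV ingest/emit, run configuration and the end-to-end pipeline.

The pipeline sequences the analysis stages in assay order: (optionally)
simulate or read well-level plates, reduce them to tidy inhibition
observations, fit 4PL curves per treatment, invert to IC10/IC50, compute
relative potencies, analyse mixtures on the TU scale, and screen guideline
ETVs. Stages fail independently: an error in one stage is recorded in the run
log without aborting the others. All outputs carry the config hash and seed.

CSV dialect is fixed (comma separator, '.' decimal, UTF-8, mandatory header)
to avoid locale drift.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .doseresponse import (
    FitError,
    ICxNotReachedError,
    LogisticFit,
    bootstrap_icx,
    fit_4pl,
    invert_icx,
    relative_potency_table,
)
from .fluorometry import WellRecord, plate_endpoints
from .guidelines import protectiveness_table
from .mixtures import MixtureSpec, classify_additivity, design_mixture_series
from .simulate import AssayScenario, default_scenario, simulate_mixture_assay, simulate_single_assay

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_plate_csv",
    "read_observations_csv",
    "write_fit_results",
    "run_pipeline",
]

PLATE_COLUMNS = [
    "plate_id",
    "well_id",
    "leaf_id",
    "treatment_id",
    "timepoint_h",
    "F",
    "Fm_prime",
    "F0",
    "Fm",
    "is_control",
]

OBSERVATION_COLUMNS = ["treatment_id", "dose", "replicate", "duration_h", "inhibition"]


class SchemaError(ValueError):
    """Input CSV does not conform to the expected schema."""


def read_plate_csv(path: str | Path) -> tuple[list[WellRecord], pd.DataFrame]:
    """Read a well-level plate CSV into validated records.

    Returns (records, errors): rows violating physical invariants are
    collected into the error table (row index + message) instead of aborting
    the load. Missing required columns abort with :class:`SchemaError`.
    """
    df = pd.read_csv(path, comment="#")
    required = [c for c in PLATE_COLUMNS if c not in ("F0", "Fm")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"plate CSV {path}: missing column(s) {missing}")
    records: list[WellRecord] = []
    errors: list[dict] = []
    for i, row in df.iterrows():
        try:
            f0 = row.get("F0")
            fm = row.get("Fm")
            records.append(
                WellRecord(
                    plate_id=str(row["plate_id"]),
                    well_id=str(row["well_id"]),
                    leaf_id=str(row["leaf_id"]),
                    treatment_id=str(row["treatment_id"]),
                    timepoint_h=float(row["timepoint_h"]),
                    F=float(row["F"]),
                    Fm_prime=float(row["Fm_prime"]),
                    F0=None if pd.isna(f0) else float(f0),
                    Fm=None if pd.isna(fm) else float(fm),
                    is_solvent_control=bool(int(row["is_control"])),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append({"row": i, "error": str(exc)})
    return records, pd.DataFrame(errors, columns=["row", "error"])


def read_observations_csv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a tidy inhibition-observation CSV, rejecting invalid rows.

    Returns (observations, errors). Rows with negative or non-numeric doses
    or non-numeric inhibition are rejected row-wise; a missing required
    column is a hard :class:`SchemaError` naming the column.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"observations CSV {path}: missing column(s) {missing}")
    errors = []
    dose = pd.to_numeric(df["dose"], errors="coerce")
    inhib = pd.to_numeric(df["inhibition"], errors="coerce")
    bad = dose.isna() | inhib.isna() | (dose < 0)
    for i in df.index[bad]:
        errors.append(
            {"row": int(i), "error": f"invalid dose/inhibition: {df.loc[i, 'dose']!r}, "
                                     f"{df.loc[i, 'inhibition']!r}"}
        )
    good = df[~bad].copy()
    good["dose"] = dose[~bad]
    good["inhibition"] = inhib[~bad]
    if "dose_scale" not in good.columns:
        good["dose_scale"] = "concentration"
    return good, pd.DataFrame(errors, columns=["row", "error"])


def _icx_row(fit: LogisticFit, level: float, cfg: "RunConfig", obs=None):
    try:
        if cfg.ci_method == "bootstrap" and obs is not None:
            est = bootstrap_icx(
                obs, level, n_boot=cfg.bootstrap_n, seed=cfg.seed, mode=cfg.icx_mode
            )
        else:
            est = invert_icx(fit, level, mode=cfg.icx_mode)
        return est.value, est.ci_low, est.ci_high
    except ICxNotReachedError:
        return np.nan, np.nan, np.nan


def write_fit_results(
    fits: dict[str, LogisticFit],
    path: str | Path,
    cfg: "RunConfig",
    observations: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Emit the fit-results CSV (one row per treatment) and return it."""
    rows = []
    for tid, fit in fits.items():
        obs = None if observations is None else observations.get(tid)
        ic50, ic50_lo, ic50_hi = _icx_row(fit, 50.0, cfg, obs)
        ic10, ic10_lo, ic10_hi = _icx_row(fit, 10.0, cfg, obs)
        rows.append(
            {
                "treatment_id": tid,
                "duration_h": fit.duration_h,
                "dose_scale": fit.dose_scale,
                "bottom": fit.bottom,
                "top": fit.top,
                "hill": fit.hill,
                "ic50": ic50,
                "ic50_lo": ic50_lo,
                "ic50_hi": ic50_hi,
                "ic10": ic10,
                "ic10_lo": ic10_lo,
                "ic10_hi": ic10_hi,
                "r2": fit.r2,
                "n_obs": fit.n_obs,
                "convergence_flag": fit.converged,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(path, index=False, float_format="%.15g")
    return out


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`.

    With no ``observations_csv`` the pipeline generates the demo scenario
    (published endpoint truths, nine replicates) from ``seed``.
    """

    out_dir: str = "pamtox_out"
    seed: int = 0
    observations_csv: str | None = None
    plate_csv: str | None = None
    # dose-response options
    constrain_4pl: bool = False
    icx_mode: str = "absolute"  # absolute | relative
    ci_method: str = "delta"  # delta | bootstrap
    bootstrap_n: int = 1000
    ftest_sharing: str = "shared_bth"  # shared_bth | separate_all
    # mixture options
    tu_basis_duration_h: float = 24.0
    mixture_duration_h: float = 24.0
    alpha: float = 0.05
    run_mixtures: bool = True
    run_guidelines: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.icx_mode not in ("absolute", "relative"):
            raise ValueError(f"unknown icx_mode {self.icx_mode!r}")
        if self.ci_method not in ("delta", "bootstrap"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")
        if self.run_mixtures and self.mixture_duration_h != self.tu_basis_duration_h:
            raise ValueError(
                "mixture design duration must match the Toxic-Unit basis duration"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis; returns a result bundle and writes CSV outputs.

    Bundle keys: ``fits`` (DataFrame), ``rep`` (DataFrame), ``mixtures``
    (DataFrame or None), ``guideline_flags`` (DataFrame or None), ``log``
    (dict). Stage errors are caught and recorded under ``log['errors']``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "errors": {},
    }
    bundle: dict[str, Any] = {"log": log}

    # --- observations ------------------------------------------------------
    obs_by_treatment: dict[str, pd.DataFrame] = {}
    try:
        if config.plate_csv:
            records, errs = read_plate_csv(config.plate_csv)
            if len(errs):
                log["errors"]["plate_ingest_rows"] = errs.to_dict("records")
            tidy = plate_endpoints(records)
            tidy.to_csv(out / "endpoints.csv", index=False)
            obs = tidy[~tidy["is_control"]].copy()
            parts = obs["treatment_id"].str.split("@", expand=True)
            obs["treatment_id"], obs["dose"] = parts[0], parts[1].astype(float)
            obs = obs.rename(columns={"inhibition_pct": "inhibition"})
            obs["duration_h"] = obs["timepoint_h"]
            obs["dose_scale"] = "concentration"
        elif config.observations_csv:
            obs, errs = read_observations_csv(config.observations_csv)
            if len(errs):
                log["errors"]["observation_rows"] = errs.to_dict("records")
        else:
            scenario = default_scenario(seed=config.seed)
            frames = [
                simulate_single_assay(scenario, h) for h in scenario.truths
            ]
            obs = pd.concat(frames, ignore_index=True)
        for tid, grp in obs.groupby("treatment_id"):
            obs_by_treatment[str(tid)] = grp.reset_index(drop=True)
    except Exception as exc:  # stage failure: nothing downstream can run
        log["errors"]["ingest"] = str(exc)
        return bundle

    # --- fits + ICx --------------------------------------------------------
    fits: dict[str, LogisticFit] = {}
    for tid, grp in obs_by_treatment.items():
        try:
            fits[tid] = fit_4pl(grp, constrain=config.constrain_4pl, treatment_id=tid)
        except FitError as exc:
            log["errors"][f"fit:{tid}"] = str(exc)
    fit_table = write_fit_results(fits, out / "fits.csv", config, obs_by_treatment)
    bundle["fits"] = fit_table

    # --- relative potencies ------------------------------------------------
    try:
        ep = fit_table.rename(columns={"treatment_id": "herbicide"})
        ep = ep[ep["dose_scale"] == "concentration"].dropna(subset=["ic50"])
        ref = "diuron" if "diuron" in set(ep["herbicide"]) else None
        if ref:
            rep = relative_potency_table(ep, reference=ref)
            rep.to_csv(out / "rep.csv", index=False, float_format="%.15g")
            bundle["rep"] = rep
    except Exception as exc:
        log["errors"]["rep"] = str(exc)

    # --- mixtures ----------------------------------------------------------
    if config.run_mixtures:
        try:
            bundle["mixtures"] = _mixture_stage(config, out, log)
        except Exception as exc:
            log["errors"]["mixtures"] = str(exc)

    # --- guidelines --------------------------------------------------------
    if config.run_guidelines:
        try:
            flags = protectiveness_table(
                datasets.guideline_icx(10), datasets.guideline_etvs()
            )
            flags.to_csv(out / "guideline_flags.csv", index=False)
            bundle["guideline_flags"] = flags
        except Exception as exc:
            log["errors"]["guidelines"] = str(exc)

    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, default=str)
    return bundle


def _mixture_stage(config: RunConfig, out: Path, log: dict) -> pd.DataFrame:
    """Demo mixture analysis: the two test mixtures vs the two sham references."""
    table = datasets.toxic_unit_table(config.tu_basis_duration_h)
    scenario = default_scenario(seed=config.seed)
    all_herbicides = sorted(
        h for h in scenario.truths if not h.endswith("_48h")
    )
    specs = {
        "diuron+atrazine": MixtureSpec.equal_proportions(
            "diuron+atrazine", ["diuron", "atrazine"]
        ),
        "10-herbicide-mix": MixtureSpec.equal_proportions(
            "10-herbicide-mix", all_herbicides
        ),
    }
    ref_specs = {
        "diuron+diuron": MixtureSpec.equal_proportions(
            "diuron+diuron", ["diuron", "diuron"]
        ),
        "atrazine+atrazine": MixtureSpec.equal_proportions(
            "atrazine+atrazine", ["atrazine", "atrazine"]
        ),
    }
    design = pd.concat(
        [design_mixture_series(s, table) for s in {**specs, **ref_specs}.values()],
        ignore_index=True,
    )
    design.to_csv(out / "mixture_design.csv", index=False, float_format="%.15g")

    ref_obs = {
        mid: simulate_mixture_assay(scenario, s, table) for mid, s in ref_specs.items()
    }
    rows = []
    for mid, s in specs.items():
        res = classify_additivity(
            simulate_mixture_assay(scenario, s, table),
            list(ref_obs.values()),
            alpha=config.alpha,
            mixture_id=mid,
            reference_ids=list(ref_obs),
        )
        rows.append(
            {
                "mixture_id": mid,
                "ic10_tu": res.ic10_tu,
                "ic50_tu": res.ic50_tu,
                "ci_lo": res.ci[0],
                "ci_hi": res.ci[1],
                "classification": res.classification,
                "rule": res.rule,
                "comparison_p": ";".join(
                    f"{r.reference}={r.p:.4g}"
                    for r in res.reference_comparisons.itertuples()
                ),
            }
        )
    report = pd.DataFrame(rows)
    report.to_csv(out / "mixture_report.csv", index=False, float_format="%.15g")
    return report
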