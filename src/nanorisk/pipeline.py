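"""End-to-end orchestration of the probabilistic risk assessment.

``run_scenario`` executes the classical four-step chain on one
:class:`~nanorisk.config.ScenarioConfig`:

1. hazard / dose–response — fit and pool benchmark-dose models (skipped
   when the config supplies a published BMCL_a or BMC_h directly);
2. extrapolation — Monte Carlo division by the uncertainty factors to a
   human BMC_h in µg/m^3;
3. exposure — moment-matched lognormal per (technique, work event) cell;
4. risk characterization — RCR draws, exceedance probability and
   significance per cell, plus a nominal range sensitivity analysis.

All randomness flows from the single root seed in the config through
named child streams, so a run is bit-reproducible and every stage is
individually reproducible.  ``ScenarioResult.write`` emits the CSV
tables and a JSON run manifest recording the seed and settings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import pandas as pd

from . import bmd
from .config import Finding, ScenarioConfig, validate_config
from .distributions import LognormalDist, MonteCarloSettings
from .exposure import (
    BACKGROUND_EVENT,
    ExposureRecord,
    build_exposure_distribution,
    exposure_table,
    load_exposure_csv,
    paper_exposure_records,
    subtract_background,
)
from .extrapolation import ExtrapolationResult, extrapolate_bmch
from .risk import build_risk_table, compute_rcr
from .sensitivity import nominal_range_sa, sensitivity_table

__all__ = ["ScenarioResult", "run_scenario", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a scenario configuration fails validation."""


@dataclass
class ScenarioResult:
    """All tables and intermediate objects of one run."""

    config: ScenarioConfig
    bmd_fits: pd.DataFrame | None
    pool: bmd.BMDPool | None
    bmcl_a: LognormalDist | None
    bmch: ExtrapolationResult | None
    bmch_dist: LognormalDist
    exposure_summaries: list
    exposure_table: pd.DataFrame
    rcr_results: list
    risk_table: pd.DataFrame
    sensitivity: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> None:
        """Write bmd_fits.csv, bmch.csv, exposure_table.csv,
        risk_table.csv, sensitivity.csv and run_manifest.json."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.bmd_fits is not None:
            self.bmd_fits.to_csv(out / "bmd_fits.csv", index=False)
        pd.DataFrame([{
            "gm_ug_m3": self.bmch_dist.gm,
            "gsd": self.bmch_dist.gsd,
            "closed_form_gm": self.bmch.closed_form.gm if self.bmch else math.nan,
            "closed_form_gsd": self.bmch.closed_form.gsd if self.bmch else math.nan,
        }]).to_csv(out / "bmch.csv", index=False)
        self.exposure_table.to_csv(out / "exposure_table.csv", index=False)
        self.risk_table.to_csv(out / "risk_table.csv", index=False)
        self.sensitivity.to_csv(out / "sensitivity.csv", index=False)
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _bmd_stage(config: ScenarioConfig):
    """Fit, screen and pool the dose-response models; returns
    (fits table, pool) or (None, None) when an override is configured."""
    datasets = bmd.read_dose_response_csv(config.dose_response_csv)
    rows, items = [], []
    for ds in datasets:
        for fit in bmd.fit_all_models(ds):
            est = bmd.estimate_bmd(fit, ds)
            rows.append({
                "study_id": ds.study_id, "endpoint": ds.endpoint, "model": fit.model,
                "converged": fit.converged, "loglik": fit.loglik, "aic": fit.aic,
                "gof_p": fit.gof_p, "bmc": est.bmc, "bmcl": est.bmcl, "bmcu": est.bmcu,
            })
            items.append((fit, est))
    kept = bmd.filter_reliable(items, gof_min=config.gof_min,
                               bmc_bmcl_ratio_max=config.bmc_bmcl_ratio_max)
    pool = bmd.pool_models(kept, weighting=config.weighting)
    kept_keys = {id(f) for f, _ in kept}
    for row, (fit, _) in zip(rows, items):
        row["reliable"] = id(fit) in kept_keys
    return pd.DataFrame(rows), pool


def _exposure_records(config: ScenarioConfig) -> list:
    records = (load_exposure_csv(config.exposure_csv)
               if config.exposure_csv else paper_exposure_records())
    if not config.background_subtraction:
        return records
    # subtract each technique's NWH mean from its work-event means
    background = {r.mt: r.mean for r in records if r.we == BACKGROUND_EVENT and r.available}
    adjusted = []
    for r in records:
        if not r.available or r.we == BACKGROUND_EVENT or r.mt not in background:
            adjusted.append(r)
            continue
        net = subtract_background(r.mean, background[r.mt])
        if net == 0:
            adjusted.append(ExposureRecord(mt=r.mt, we=r.we, available=False))
        else:
            adjusted.append(ExposureRecord(mt=r.mt, we=r.we, mean=net, sd=r.sd))
    return adjusted


def run_scenario(config: ScenarioConfig, out_dir=None) -> ScenarioResult:
    """Execute the full chain for one scenario configuration.

    Raises :class:`ConfigError` when validation reports errors.  With
    ``out_dir`` the result tables and run manifest are also written.
    """
    findings = validate_config(config)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise ConfigError("; ".join(f.message for f in errors))

    mc = config.monte_carlo

    # 1-2. hazard side: animal BMCL -> human BMC_h
    bmd_fits = pool = None
    extrap = None
    if config.bmch is not None:
        bmch_dist = config.resolve_bmch()
        bmcl_a = None
        factors = None
    else:
        if config.dose_response_csv:
            bmd_fits, pool = _bmd_stage(config)
            bmcl_a = pool.bmcl_a
        else:
            bmcl_a = config.resolve_bmcl_a()
        factors = config.resolve_factors()
        extrap = extrapolate_bmch(bmcl_a, factors, mc.spawn("extrapolation"))
        bmch_dist = extrap.dist

    # 3. exposure
    records = _exposure_records(config)
    summaries = [
        build_exposure_distribution(rec, mc.spawn(f"exposure/{rec.mt}/{rec.we}"))
        for rec in records
    ]
    exp_table = exposure_table(summaries)

    # 4. risk characterization (background NWH rows are not risk rows)
    shared = extrap.draws if (config.shared_bmch_draws and extrap is not None) else None
    rcr_results = [
        compute_rcr(s, bmch_dist, mc, bmch_draws=shared, level=config.significance_level)
        for s in summaries
        if s.we != BACKGROUND_EVENT
    ]
    risk = build_risk_table(rcr_results)

    # sensitivity per available cell
    sens_frames = []
    for s in summaries:
        if not s.available or s.we == BACKGROUND_EVENT:
            continue
        try:
            if factors is not None:
                inputs = {"bmcl_a": bmcl_a, "ef_inter": factors.ef_inter,
                          "ef_intra": factors.ef_intra, "uf": factors.uf,
                          "exposure": s.dist}
                res = nominal_range_sa(inputs, range_spec=config.sensitivity_range)
            else:
                inputs = {"exposure": s.dist, "bmch": bmch_dist}
                res = nominal_range_sa(
                    inputs, range_spec=config.sensitivity_range,
                    chain=lambda v: v["exposure"] / v["bmch"],
                )
        except ValueError:
            # fully degenerate cell (all point masses): contributions undefined
            continue
        frame = sensitivity_table(res)
        frame.insert(0, "we", s.we)
        frame.insert(0, "mt", s.mt)
        sens_frames.append(frame)
    sens = (pd.concat(sens_frames, ignore_index=True)
            if sens_frames else pd.DataFrame(
                columns=["mt", "we", "input", "rcr_at_low", "rcr_at_high",
                         "swing", "contribution_pct"]))

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_iter": config.n_iter,
        "sampling_method": config.sampling_method,
        "bmch_gm_ug_m3": bmch_dist.gm,
        "bmch_gsd": bmch_dist.gsd,
        "warnings": [f.message for f in findings if f.severity == "warning"],
    }

    result = ScenarioResult(
        config=config,
        bmd_fits=bmd_fits,
        pool=pool,
        bmcl_a=bmcl_a,
        bmch=extrap,
        bmch_dist=bmch_dist,
        exposure_summaries=summaries,
        exposure_table=exp_table,
        rcr_results=rcr_results,
        risk_table=risk,
        sensitivity=sens,
        manifest=manifest,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
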