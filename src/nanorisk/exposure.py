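"""Occupational exposure distributions from measurement summaries.

Workplace monitoring campaigns typically report, per work event (WE) and
measurement technique (MT), only the arithmetic mean and SD of the mass
concentration (µg/m^3).  This module moment-matches a lognormal to each
such summary cell, samples it by Latin hypercube Monte Carlo, and builds
descriptive summaries (GM, GSD, min, percentiles, max) of the draws.

The packaged reference scenario covers the manufacture of single-walled
carbon nanotube conductive films: WE1 (production with local exhaust
ventilation), WE2 (production without LEV), WE3 (reactor cleaning), plus
whole working hours (WH) and non-working hours (NWH, the background),
each characterized by three direct-reading techniques (MT1 electrical
mobility spectrometer, MT2 low-pressure impactor, MT3 optical sizer).
Cells the campaign could not measure propagate as structured
not-available records, never as zeros.

The risk-assessment default keeps exposure *without* background
subtraction (a precautionary choice: airborne background particles are
counted as if they were the nanomaterial); subtraction of the NWH mean
is available as an explicit opt-in and happens on arithmetic means
before the lognormal fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .distributions import (
    LognormalDist,
    MonteCarloSettings,
    ks_lognormality,
    lognormal_from_moments,
    prob_ge,
    sample,
)

__all__ = [
    "ExposureRecord",
    "ExposureSummary",
    "REFERENCE_LIMITS",
    "build_exposure_distribution",
    "subtract_background",
    "compare_to_limits",
    "load_exposure_csv",
    "paper_exposure_records",
    "exposure_table",
]

#: Reference mass-concentration limits (µg/m^3) used for reporting only.
REFERENCE_LIMITS = {"NIOSH_REL": 1.0}

WORK_EVENT_ORDER = ("WE1", "WE2", "WE3", "WH", "NWH")
BACKGROUND_EVENT = "NWH"


@dataclass(frozen=True)
class ExposureRecord:
    """One (measurement technique, work event) summary cell.

    ``mean``/``sd`` are the arithmetic mean and SD of the mass
    concentration in µg/m^3; ``available`` is False for cells the
    campaign did not measure.
    """

    mt: str
    we: str
    mean: float = math.nan
    sd: float = math.nan
    available: bool = True

    def __post_init__(self) -> None:
        if self.available:
            if not (self.mean > 0):
                raise ValueError(f"{self.mt}/{self.we}: mean must be > 0, got {self.mean}")
            if not (self.sd >= 0):
                raise ValueError(f"{self.mt}/{self.we}: sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class ExposureSummary:
    """A sampled exposure distribution with descriptive statistics.

    For an unavailable record, ``available`` is False and the numeric
    fields are NaN / None.
    """

    mt: str
    we: str
    available: bool
    dist: LognormalDist | None = None
    draws: np.ndarray | None = None
    gm: float = math.nan
    gsd: float = math.nan
    min: float = math.nan
    p5: float = math.nan
    p95: float = math.nan
    max: float = math.nan
    ks_p: float = math.nan


def build_exposure_distribution(rec: ExposureRecord, mc: MonteCarloSettings) -> ExposureSummary:
    """Moment-match and sample the exposure distribution of one cell.

    Unavailable records yield an explicit not-available summary so that
    downstream tables can carry the gap through to reports.
    """
    if not rec.available:
        return ExposureSummary(mt=rec.mt, we=rec.we, available=False)
    dist = lognormal_from_moments(rec.mean, rec.sd)
    draws = sample(dist, mc)
    logs = np.log(draws)
    return ExposureSummary(
        mt=rec.mt,
        we=rec.we,
        available=True,
        dist=dist,
        draws=draws,
        gm=float(np.exp(logs.mean())),
        gsd=float(np.exp(logs.std())),
        min=float(draws.min()),
        p5=float(np.percentile(draws, 5)),
        p95=float(np.percentile(draws, 95)),
        max=float(draws.max()),
        ks_p=ks_lognormality(draws),
    )


def subtract_background(we_mean: float, nwh_mean: float) -> float:
    """Net exposure mean after removing the non-working-hours background.

    Zero-floored: if the background exceeds the signal the net mean is 0
    and a warning is emitted (a zero mean cannot seed a lognormal).
    """
    if we_mean < 0 or nwh_mean < 0:
        raise ValueError("concentrations must be >= 0")
    net = we_mean - nwh_mean
    if net < 0:
        warnings.warn(
            f"background ({nwh_mean} ug/m3) exceeds the work-event mean ({we_mean} ug/m3); "
            "net exposure floored at 0",
            stacklevel=2,
        )
        return 0.0
    return net


def compare_to_limits(summary: ExposureSummary, limits: dict | None = None) -> pd.DataFrame:
    """Exceedance report of one exposure summary against reference limits.

    Per limit: the fraction of Monte Carlo draws above it, the analytic
    exceedance probability, and whether the arithmetic mean exceeds it.
    """
    if limits is None:
        limits = REFERENCE_LIMITS
    rows = []
    for name, limit in limits.items():
        if not summary.available:
            rows.append({"limit_name": name, "limit_ug_m3": limit, "frac_draws_above": math.nan,
                         "prob_above": math.nan, "mean_exceeds": None})
            continue
        frac = float(np.mean(summary.draws >= limit)) if math.isfinite(limit) else 0.0
        prob = prob_ge(summary.dist, limit) if math.isfinite(limit) else 0.0
        rows.append({
            "limit_name": name,
            "limit_ug_m3": limit,
            "frac_draws_above": frac,
            "prob_above": prob,
            "mean_exceeds": bool(summary.dist.mean > limit),
        })
    return pd.DataFrame(rows)


def load_exposure_csv(path) -> list:
    """Read exposure summary cells from CSV.

    Columns: mt, we, mean_ug_m3, sd_ug_m3; the value ``NA`` marks a cell
    the campaign did not measure.
    """
    df = pd.read_csv(path)
    required = ["mt", "we", "mean_ug_m3", "sd_ug_m3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"exposure CSV missing columns: {missing}")
    records = []
    for r in df.itertuples():
        if pd.isna(r.mean_ug_m3) or pd.isna(r.sd_ug_m3):
            records.append(ExposureRecord(mt=str(r.mt), we=str(r.we), available=False))
        else:
            records.append(ExposureRecord(
                mt=str(r.mt), we=str(r.we),
                mean=float(r.mean_ug_m3), sd=float(r.sd_ug_m3),
            ))
    return records


def paper_exposure_records() -> list:
    """The packaged reference exposure scenario (15 MT x WE cells)."""
    with resources.as_file(resources.files("nanorisk.data") / "exposure_table.csv") as p:
        return load_exposure_csv(p)


def exposure_table(summaries) -> pd.DataFrame:
    """Descriptive-statistics table of exposure summaries (one row per cell)."""
    rows = []
    for s in summaries:
        rows.append({
            "mt": s.mt, "we": s.we, "available": s.available,
            "gm_ug_m3": s.gm, "gsd": s.gsd,
            "min": s.min, "p5": s.p5, "p95": s.p95, "max": s.max,
            "ks_p": s.ks_p,
        })
    return pd.DataFrame(rows)
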