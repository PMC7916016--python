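"""Scenario configuration: one structured, round-trippable description
of a full probabilistic risk-assessment run.

A scenario needs exactly one source for the hazard side of the chain:

* ``dose_response_csv`` — fit the benchmark-dose models to animal data
  and pool them into an animal BMCL distribution, or
* ``bmcl_a`` — a published animal BMCL summary (GM/GSD, mg/m^3), or
* ``bmch`` — a human guidance value directly (GM/GSD, µg/m^3), skipping
  extrapolation.

plus exposure summary cells (defaults to the packaged reference
scenario) and Monte Carlo settings.  ``validate_config`` returns findings
rather than raising, so callers can decide how strict to be.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .distributions import LognormalDist, MonteCarloSettings
from .extrapolation import FACTOR_PRESETS, ExtrapolationFactorSet

__all__ = ["ScenarioConfig", "Finding", "validate_config"]


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    message: str


def _dist_from_mapping(m: dict) -> LognormalDist:
    return LognormalDist(gm=float(m["gm"]), gsd=float(m.get("gsd", 1.0)))


@dataclass
class ScenarioConfig:
    """Everything needed to reproduce a risk-assessment run."""

    dose_response_csv: str | None = None
    exposure_csv: str | None = None  # None -> packaged reference scenario
    bmcl_a: dict | None = None  # {"gm": ..., "gsd": ...} in mg/m^3
    bmch: dict | None = None  # {"gm": ..., "gsd": ...} in µg/m^3
    factors: object = "paper_calibration"  # preset name or per-factor mapping
    n_iter: int = 10_000
    seed: int = 0
    sampling_method: str = "latin_hypercube"
    background_subtraction: bool = False
    gof_min: float = 0.10
    bmc_bmcl_ratio_max: float = 20.0
    weighting: str = "akaike"
    significance_level: float = 0.95
    reference_limits: dict = field(default_factory=lambda: {"NIOSH_REL": 1.0})
    sensitivity_range: tuple = (0.05, 0.95)
    shared_bmch_draws: bool = False

    # -- resolved objects ---------------------------------------------------

    @property
    def monte_carlo(self) -> MonteCarloSettings:
        return MonteCarloSettings(n_iter=self.n_iter, seed=self.seed, method=self.sampling_method)

    def resolve_factors(self) -> ExtrapolationFactorSet:
        if isinstance(self.factors, str):
            if self.factors not in FACTOR_PRESETS:
                raise ValueError(f"unknown factor preset {self.factors!r}; "
                                 f"known presets: {sorted(FACTOR_PRESETS)}")
            return FACTOR_PRESETS[self.factors]()
        m = self.factors
        return ExtrapolationFactorSet(
            ef_inter=_dist_from_mapping(m["ef_inter"]),
            ef_intra=_dist_from_mapping(m["ef_intra"]),
            uf=_dist_from_mapping(m["uf"]),
        )

    def resolve_bmcl_a(self) -> LognormalDist | None:
        return _dist_from_mapping(self.bmcl_a) if self.bmcl_a else None

    def resolve_bmch(self) -> LognormalDist | None:
        return _dist_from_mapping(self.bmch) if self.bmch else None

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sensitivity_range"] = list(self.sensitivity_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "sensitivity_range" in d:
            d["sensitivity_range"] = tuple(d["sensitivity_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @classmethod
    def paper_scenario(cls, seed: int = 0, n_iter: int = 10_000) -> "ScenarioConfig":
        """The packaged reference scenario: published BMCL_a summary
        (GM 9.4, GSD 1.006 mg/m^3), calibrated factor preset, packaged
        exposure cells."""
        return cls(bmcl_a={"gm": 9.4, "gsd": 1.006}, seed=seed, n_iter=n_iter)


def validate_config(config: ScenarioConfig) -> list:
    """Structural and invariant checks; returns findings, never raises."""
    findings: list[Finding] = []
    sources = [s for s in
               ("dose_response_csv" if config.dose_response_csv else None,
                "bmcl_a" if config.bmcl_a else None,
                "bmch" if config.bmch else None) if s]
    if len(sources) == 0:
        findings.append(Finding("error", "no BMC source: provide dose_response_csv, bmcl_a or bmch"))
    elif len(sources) > 1:
        findings.append(Finding("error", f"multiple BMC sources given: {sources}; exactly one required"))

    for label, m in (("bmcl_a", config.bmcl_a), ("bmch", config.bmch)):
        if m:
            try:
                _dist_from_mapping(m)
            except (KeyError, ValueError, TypeError) as exc:
                findings.append(Finding("error", f"invalid {label} distribution: {exc}"))

    if config.bmch is None:
        try:
            config.resolve_factors()
        except (KeyError, ValueError, TypeError) as exc:
            findings.append(Finding("error", f"invalid extrapolation factors: {exc}"))

    try:
        config.monte_carlo
    except ValueError as exc:
        findings.append(Finding("error", f"invalid Monte Carlo settings: {exc}"))

    if not (0.5 < config.significance_level < 1.0):
        findings.append(Finding("error",
                                f"significance level must be in (0.5, 1), got {config.significance_level}"))
    lo, hi = config.sensitivity_range
    if not (0.0 < lo < hi < 1.0):
        findings.append(Finding("error", f"sensitivity range must satisfy 0 < low < high < 1, got {(lo, hi)}"))
    if config.weighting not in ("akaike", "equal"):
        findings.append(Finding("error", f"weighting must be 'akaike' or 'equal', got {config.weighting!r}"))
    if not (0.0 <= config.gof_min <= 1.0):
        findings.append(Finding("error", f"gof_min must be in [0, 1], got {config.gof_min}"))
    for name, limit in (config.reference_limits or {}).items():
        if not limit > 0:
            findings.append(Finding("error", f"reference limit {name} must be positive, got {limit}"))
    if config.background_subtraction:
        findings.append(Finding("warning",
                                "background subtraction is ON; the precautionary default is OFF"))
    return findings
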