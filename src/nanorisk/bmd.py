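"""Continuous benchmark-dose (benchmark-concentration) modeling.

Fits the standard continuous dose–response families (linear, quadratic
polynomial, power, Hill, exponential) to per-group summary data
(dose, n, mean, SD) by maximum likelihood under normal responses with a
constant variance across groups, computes the benchmark concentration
(BMC) for a benchmark response of one control-group standard deviation,
derives one-sided 95% profile-likelihood bounds (BMCL/BMCU), screens fits
for reliability, and pools the surviving models into lognormal
BMC/BMCL/BMCU summaries via Akaike (or equal) weighting.

The likelihood is written on sufficient statistics, so raw animal-level
responses are never needed: for group ``i`` with ``n_i`` animals, sample
mean ``m_i`` and sample SD ``s_i``,

    ll = sum_i [ -n_i/2 ln(2 pi sigma^2)
                 - ((n_i - 1) s_i^2 + n_i (m_i - mu_i)^2) / (2 sigma^2) ]

with ``mu_i`` the model mean at dose ``d_i``.  The benchmark-response
anchor defaults to the model's own (pooled MLE) estimate of the
control-group SD, which is what the constant-variance model says that SD
is; an explicit anchor can be supplied instead.  With the modeled anchor,
the profile-likelihood bound ties the variance parameter to the BMC
constraint, so anchor uncertainty is propagated into the BMCL.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .distributions import LognormalDist

__all__ = [
    "DoseGroup",
    "DoseResponseDataset",
    "ModelFit",
    "BMDEstimate",
    "BMDPool",
    "MODEL_NAMES",
    "NoReliableModelsError",
    "fit_model",
    "fit_all_models",
    "goodness_of_fit",
    "saturated_loglik",
    "bmc_from_fit",
    "profile_bounds",
    "estimate_bmd",
    "filter_reliable",
    "pool_models",
    "model_mean",
    "read_dose_response_csv",
    "write_dose_response_csv",
]

MODEL_NAMES = ("linear", "polynomial2", "power", "hill", "exponential")

# one-sided 95% profile bound: drop of chi2_1(0.90)/2 from the maximum
_PROFILE_DROP_90 = float(chi2.ppf(0.90, 1)) / 2.0
_PENALTY = 1e12
_POWER_MAX = 18.0  # upper cap on power/Hill/exponential shape exponents


class NoReliableModelsError(RuntimeError):
    """Raised when every fitted model fails the reliability screen."""


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class DoseGroup:
    """Summary statistics of one dose group: concentration (mg/m^3),
    group size, mean response and response SD (endpoint units)."""

    dose: float
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"response SD must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class DoseResponseDataset:
    """One study/endpoint dose–response series.

    Doses must be strictly increasing and include exactly one control
    (dose 0) group.  ``direction`` states whether the adverse response
    rises or falls with dose.
    """

    study_id: str
    endpoint: str
    groups: tuple
    direction: str

    def __post_init__(self) -> None:
        groups = tuple(self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) < 3:
            raise ValueError("need at least 3 dose groups")
        doses = [g.dose for g in groups]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if sum(1 for d in doses if d == 0) != 1:
            raise ValueError("dataset must contain exactly one control (dose 0) group")
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(f"direction must be 'increasing' or 'decreasing', got {self.direction!r}")

    @property
    def doses(self) -> np.ndarray:
        return np.array([g.dose for g in self.groups], dtype=float)

    @property
    def ns(self) -> np.ndarray:
        return np.array([g.n for g in self.groups], dtype=float)

    @property
    def means(self) -> np.ndarray:
        return np.array([g.mean for g in self.groups], dtype=float)

    @property
    def sds(self) -> np.ndarray:
        return np.array([g.sd for g in self.groups], dtype=float)

    @property
    def control(self) -> DoseGroup:
        return self.groups[0]

    @property
    def direction_sign(self) -> int:
        return 1 if self.direction == "increasing" else -1

    @staticmethod
    def infer_direction(doses: Sequence[float], means: Sequence[float]) -> str:
        """Direction from the sign of the dose–mean covariance."""
        d = np.asarray(doses, dtype=float)
        m = np.asarray(means, dtype=float)
        cov = float(np.mean((d - d.mean()) * (m - m.mean())))
        return "increasing" if cov >= 0 else "decreasing"


@dataclass(frozen=True)
class ModelFit:
    """A fitted dose–response model.

    ``params`` maps parameter names to MLEs; ``aic = 2k - 2 loglik`` with
    ``k = n_mean_params + 1`` (the constant variance counts as a free
    parameter).  ``converged`` is honest: a fit that did not converge is
    returned flagged, never silently treated as reliable.
    """

    model: str
    params: dict
    loglik: float
    n_mean_params: int
    converged: bool
    direction: str
    gof_p: float = math.nan

    @property
    def aic(self) -> float:
        return 2.0 * (self.n_mean_params + 1) - 2.0 * self.loglik

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.params[p] for p in _PARAM_NAMES[self.model]], dtype=float)


@dataclass(frozen=True)
class BMDEstimate:
    """Benchmark concentration with profile-likelihood bounds (mg/m^3)."""

    bmc: float
    bmcl: float = math.nan
    bmcu: float = math.nan
    reliable: bool = True
    warnings: tuple = ()

    def __post_init__(self) -> None:
        vals = [v for v in (self.bmcl, self.bmc, self.bmcu) if not math.isnan(v)]
        if any(v <= 0 for v in vals):
            raise ValueError("BMC estimates must be positive")
        if not math.isnan(self.bmcl) and self.bmcl > self.bmc * (1 + 1e-9):
            raise ValueError("bmcl must not exceed bmc")
        if not math.isnan(self.bmcu) and self.bmcu < self.bmc * (1 - 1e-9):
            raise ValueError("bmcu must not be below bmc")


@dataclass(frozen=True)
class BMDPool:
    """Model-averaged lognormal summaries of BMC, BMCL and BMCU."""

    bmc_a: LognormalDist
    bmcl_a: LognormalDist
    bmcu_a: LognormalDist
    weights: dict


# ---------------------------------------------------------------------------
# mean functions

_PARAM_NAMES = {
    "linear": ("gamma", "beta"),
    "polynomial2": ("gamma", "beta1", "beta2"),
    "power": ("gamma", "beta", "delta"),
    "hill": ("gamma", "v", "k", "eta"),
    "exponential": ("a", "b", "c"),
}


def _mean_linear(d, theta, s):
    return theta[0] + theta[1] * d


def _mean_poly2(d, theta, s):
    return theta[0] + theta[1] * d + theta[2] * d * d


def _mean_power(d, theta, s):
    gamma, beta, delta = theta
    return gamma + beta * np.power(d, delta)


def _hill_frac(d, k, eta):
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    pos = d > 0
    de = np.power(d[pos], eta)
    out[pos] = de / (np.power(k, eta) + de)
    return out


def _mean_hill(d, theta, s):
    gamma, v, k, eta = theta
    return gamma + v * _hill_frac(d, k, eta)


def _mean_exponential(d, theta, s):
    a, b, c = theta
    expo = np.clip(s * np.power(b * np.asarray(d, dtype=float), c), -500, 500)
    return a * np.exp(expo)


_MEAN_FUNCS = {
    "linear": _mean_linear,
    "polynomial2": _mean_poly2,
    "power": _mean_power,
    "hill": _mean_hill,
    "exponential": _mean_exponential,
}


def model_mean(model: str, doses, params: dict, direction: str = "increasing") -> np.ndarray:
    """Evaluate a model's mean response at the given doses."""
    theta = np.array([params[p] for p in _PARAM_NAMES[model]], dtype=float)
    s = 1 if direction == "increasing" else -1
    return _MEAN_FUNCS[model](np.asarray(doses, dtype=float), theta, s)


def _predict(fit: ModelFit, doses) -> np.ndarray:
    s = 1 if fit.direction == "increasing" else -1
    return _MEAN_FUNCS[fit.model](np.asarray(doses, dtype=float), fit.theta, s)


# ---------------------------------------------------------------------------
# likelihood machinery


def _within_ss(data: DoseResponseDataset) -> float:
    return float((((data.ns - 1) * data.sds**2)).sum())


def _total_ss(data: DoseResponseDataset, mu: np.ndarray) -> float:
    return _within_ss(data) + float((data.ns * (data.means - mu) ** 2).sum())


def _loglik_profiled(data: DoseResponseDataset, mu: np.ndarray) -> float:
    """Log-likelihood with the constant variance profiled out analytically."""
    N = data.ns.sum()
    sigma2 = max(_total_ss(data, mu) / N, 1e-300)
    return -0.5 * N * (math.log(2 * math.pi * sigma2) + 1.0)


def _loglik_at_sigma(data: DoseResponseDataset, mu: np.ndarray, sigma2: float) -> float:
    N = data.ns.sum()
    sigma2 = max(sigma2, 1e-300)
    return -0.5 * N * math.log(2 * math.pi * sigma2) - _total_ss(data, mu) / (2 * sigma2)


def saturated_loglik(data: DoseResponseDataset) -> float:
    """Log-likelihood of the saturated (free group means) model."""
    return _loglik_profiled(data, data.means)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def _wmean(y: np.ndarray, w: np.ndarray) -> float:
    return float((w * y).sum() / w.sum())


# ---------------------------------------------------------------------------
# fitting


def _fit_linear(data):
    X = np.column_stack([np.ones_like(data.doses), data.doses])
    coef = _wls(X, data.means, data.ns)
    return coef, True


def _fit_poly2(data):
    # coefficients sign-restricted to the adverse direction (monotone
    # curve), mirroring standard restricted-polynomial practice
    d = data.doses
    s = data.direction_sign
    X = np.column_stack([np.ones_like(d), s * d, s * d * d])
    sw = np.sqrt(data.ns)
    res = optimize.lsq_linear(
        X * sw[:, None], data.means * sw,
        bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
    )
    coef = np.array([res.x[0], s * res.x[1], s * res.x[2]])
    return coef, bool(res.success)


def _fit_power(data):
    d, m, w = data.doses, data.means, data.ns

    def inner(delta):
        X = np.column_stack([np.ones_like(d), np.power(d, delta)])
        coef = _wls(X, m, w)
        r = m - X @ coef
        return float((w * r * r).sum()), coef

    res = optimize.minimize_scalar(
        lambda t: inner(t)[0], bounds=(1.0, _POWER_MAX), method="bounded",
        options={"xatol": 1e-10},
    )
    _, coef = inner(res.x)
    return np.array([coef[0], coef[1], float(res.x)]), bool(res.success)


def _hill_sse(z, data):
    d, m, w = data.doses, data.means, data.ns
    k = math.exp(min(z[0], 50.0))
    eta = 1.0 + math.exp(min(z[1], 5.0))
    if eta > _POWER_MAX or k > 1e4 * d.max() or k < 1e-6 * d.max():
        return _PENALTY + abs(z[0]) + abs(z[1]), None
    frac = _hill_frac(d, k, eta)
    X = np.column_stack([np.ones_like(d), frac])
    coef = _wls(X, m, w)
    r = m - X @ coef
    return float((w * r * r).sum()), np.array([coef[0], coef[1], k, eta])


def _fit_hill(data):
    d = data.doses
    pos = d[d > 0]
    med = float(np.median(pos))
    starts = [
        (math.log(med), math.log(2.0 - 1.0)),
        (math.log(pos.max() / 4), math.log(2.0 - 1.0)),
        (math.log(pos.max()), math.log(2.0 - 1.0)),
        (math.log(med), math.log(4.0 - 1.0)),
        (math.log(pos.min()), math.log(1.2 - 1.0)),
    ]
    best = (math.inf, None, False)
    for z0 in starts:
        res = optimize.minimize(
            lambda z: _hill_sse(z, data)[0], np.array(z0), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 600},
        )
        sse, theta = _hill_sse(res.x, data)
        if theta is not None and sse < best[0]:
            best = (sse, theta, bool(res.success))
    if best[1] is None:
        return np.array([data.means[0], 0.0, med, 2.0]), False
    return best[1], best[2]


def _exp_sse(z, data, s):
    d, m, w = data.doses, data.means, data.ns
    b = math.exp(min(z[0], 50.0))
    c = z[1]
    if not (1.0 <= c <= _POWER_MAX):
        return _PENALTY + abs(c), None
    expo = np.clip(s * np.power(b * d, c), -500, 500)
    col = np.exp(expo)
    denom = float((w * col * col).sum())
    a = float((w * m * col).sum() / denom) if denom > 0 else -1.0
    if a <= 0:
        return _PENALTY, None
    r = m - a * col
    return float((w * r * r).sum()), np.array([a, b, c])


def _fit_exponential(data):
    s = data.direction_sign
    d, m = data.doses, data.means
    a0 = max(m[0], 1e-12)
    ratio = m[-1] / a0
    dmax = d.max()
    if s * math.log(max(ratio, 1e-12)) > 0:
        b0 = math.pow(abs(math.log(ratio)), 1.0) / dmax
    else:
        b0 = 1.0 / dmax
    b0 = max(b0, 1e-12)
    starts = [
        (math.log(b0), 1.0),
        (math.log(b0), 2.0),
        (math.log(b0 * 0.3), 1.0),
        (math.log(b0 * 3.0), 1.0),
        (math.log(b0), 4.0),
    ]
    best = (math.inf, None, False)
    for z0 in starts:
        res = optimize.minimize(
            lambda z: _exp_sse(z, data, s)[0], np.array(z0), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 600},
        )
        sse, theta = _exp_sse(res.x, data, s)
        if theta is not None and sse < best[0]:
            best = (sse, theta, bool(res.success))
    if best[1] is None:
        return np.array([a0, b0, 1.0]), False
    return best[1], best[2]


_FITTERS = {
    "linear": _fit_linear,
    "polynomial2": _fit_poly2,
    "power": _fit_power,
    "hill": _fit_hill,
    "exponential": _fit_exponential,
}


def fit_model(data: DoseResponseDataset, model: str) -> ModelFit:
    """Maximum-likelihood fit of one dose–response family.

    Mean parameters are estimated by (weighted) least squares on the group
    means — equivalent to the constant-variance MLE since the profiled
    variance enters only through the residual sum of squares.  Nonlinear
    families use deterministic multi-start optimization.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    theta, converged = _FITTERS[model](data)
    theta = np.asarray(theta, dtype=float)
    s = data.direction_sign
    mu = _MEAN_FUNCS[model](data.doses, theta, s)
    ll = _loglik_profiled(data, mu)
    params = dict(zip(_PARAM_NAMES[model], (float(t) for t in theta)))
    fit = ModelFit(
        model=model, params=params, loglik=ll,
        n_mean_params=len(_PARAM_NAMES[model]),
        converged=converged, direction=data.direction,
    )
    return ModelFit(**{**fit.__dict__, "gof_p": goodness_of_fit(fit, data)})


def fit_all_models(data: DoseResponseDataset, models: Sequence[str] = MODEL_NAMES) -> list:
    return [fit_model(data, m) for m in models]


def goodness_of_fit(fit: ModelFit, data: DoseResponseDataset) -> float:
    """Likelihood-ratio lack-of-fit p-value against the saturated model.

    df = (#groups - #mean parameters); when no degrees of freedom remain
    the test is undefined (NaN) and the fit must be treated as unreliable.
    """
    df = len(data.groups) - fit.n_mean_params
    if df <= 0:
        return math.nan
    lr = 2.0 * (saturated_loglik(data) - fit.loglik)
    return float(chi2.sf(max(lr, 0.0), df))


# ---------------------------------------------------------------------------
# benchmark concentration


def _modeled_anchor(fit: ModelFit, data: DoseResponseDataset) -> float:
    """Pooled MLE estimate of the (constant) response SD under the fit."""
    mu = _predict(fit, data.doses)
    return math.sqrt(max(_total_ss(data, mu) / data.ns.sum(), 0.0))


def bmc_from_fit(
    fit: ModelFit,
    data: DoseResponseDataset,
    bmr_sd: float | None = None,
    dose_cap_factor: float = 10.0,
) -> float:
    """Benchmark concentration on the fitted curve.

    Solves |m(bmc) - m(0)| = anchor, where the anchor is the benchmark
    response: one control-group SD.  By default the model's own pooled
    SD estimate is used; pass ``bmr_sd`` to anchor on an explicit value.
    Returns NaN when the fitted curve never reaches the benchmark response
    within ``dose_cap_factor`` times the top dose (flat curve).
    """
    delta = float(bmr_sd) if bmr_sd is not None else _modeled_anchor(fit, data)
    if not (delta > 0):
        raise ValueError("benchmark-response anchor must be positive")
    s = 1 if fit.direction == "increasing" else -1
    cap = data.doses.max() * dose_cap_factor
    grid = np.linspace(0.0, cap, 513)
    m = _predict(fit, grid)
    g = s * (m - m[0]) - delta
    hits = np.nonzero(g >= 0)[0]
    if hits.size == 0:
        return math.nan
    i = hits[0]
    if i == 0:
        return float(grid[0])
    f = lambda d: float(s * (_predict(fit, [d])[0] - m[0]) - delta)
    return float(optimize.brentq(f, grid[i - 1], grid[i], xtol=1e-12, rtol=1e-12))


# --- profile likelihood -----------------------------------------------------


def _theta_in_bounds(model: str, theta: np.ndarray, s: int) -> bool:
    """Parameter-space constraints shared by fitting and profiling."""
    if model == "polynomial2":
        return s * theta[1] >= 0 and s * theta[2] >= 0
    if model == "power":
        return 1.0 <= theta[2] <= _POWER_MAX
    if model == "hill":
        return theta[2] > 0 and 1.0 <= theta[3] <= _POWER_MAX
    if model == "exponential":
        return theta[0] > 0 and theta[1] > 0 and 1.0 <= theta[2] <= _POWER_MAX
    return True


def _profile_ll_modeled(fit, data, b, x0):
    """Max log-likelihood at BMC = b with sigma tied to the benchmark
    constraint sigma = |m(b) - m(0)| (modeled-SD anchor)."""
    meanf = _MEAN_FUNCS[fit.model]
    s = data.direction_sign
    d_ext = np.concatenate([[b, 0.0], data.doses])

    def negll(theta):
        if not _theta_in_bounds(fit.model, theta, s):
            return _PENALTY
        mu_ext = meanf(d_ext, theta, s)
        dlt = s * (mu_ext[0] - mu_ext[1])
        if not np.isfinite(dlt) or dlt <= 0:
            return _PENALTY
        val = _loglik_at_sigma(data, mu_ext[2:], dlt * dlt)
        return -val if np.isfinite(val) else _PENALTY

    res = optimize.minimize(
        negll, np.asarray(x0, dtype=float), method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 2000},
    )
    return -float(res.fun), res.x


def _profile_ll_fixed(fit, data, b, delta, x0):
    """Max profiled log-likelihood at BMC = b with a fixed explicit anchor.

    The response-scale coefficient is eliminated through the constraint
    m(b) - m(0) = s * delta; remaining parameters are optimized.
    """
    d, m, w = data.doses, data.means, data.ns
    s = data.direction_sign
    ds = s * delta
    model = fit.model

    if model == "linear":
        beta = ds / b
        gamma = _wmean(m - beta * d, w)
        return _loglik_profiled(data, gamma + beta * d), x0
    if model == "polynomial2":
        X = np.column_stack([np.ones_like(d), d * d - b * d])
        off = (ds / b) * d
        coef = _wls(X, m - off, w)
        beta2 = coef[1]
        beta1 = (ds - beta2 * b * b) / b
        cands = []
        if s * beta1 >= 0 and s * beta2 >= 0:
            cands.append(X @ coef + off)
        # boundary candidates respecting the sign restriction
        mu_lin = (ds / b) * d  # beta2 = 0
        cands.append(_wmean(m - mu_lin, w) + mu_lin)
        mu_quad = (ds / (b * b)) * d * d  # beta1 = 0
        cands.append(_wmean(m - mu_quad, w) + mu_quad)
        return max(_loglik_profiled(data, mu) for mu in cands), x0
    if model == "power":

        def ll_at(delta_exp):
            shape = np.power(d / b, delta_exp) * ds
            gamma = _wmean(m - shape, w)
            return _loglik_profiled(data, gamma + shape)

        res = optimize.minimize_scalar(
            lambda t: -ll_at(t), bounds=(1.0, _POWER_MAX), method="bounded",
            options={"xatol": 1e-10},
        )
        return -float(res.fun), x0
    if model == "hill":

        def negll(z):
            k = math.exp(min(z[0], 50.0))
            eta = 1.0 + math.exp(min(z[1], 5.0))
            if eta > _POWER_MAX:
                return _PENALTY
            fb = _hill_frac(np.array([b]), k, eta)[0]
            if fb <= 0:
                return _PENALTY
            v = ds / fb
            shape = v * _hill_frac(d, k, eta)
            gamma = _wmean(m - shape, w)
            return -_loglik_profiled(data, gamma + shape)

        res = optimize.minimize(
            negll, np.asarray(x0, dtype=float), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 1500},
        )
        return -float(res.fun), res.x
    if model == "exponential":

        def negll(z):
            a = (delta if s < 0 else 0.0) + math.exp(min(z[0], 300.0))
            c = z[1]
            if not (1.0 <= c <= _POWER_MAX):
                return _PENALTY + abs(c)
            q = 1.0 + ds / a
            if q <= 0:
                return _PENALTY
            mu = a * np.power(q, np.power(d / b, c))
            return -_loglik_profiled(data, mu)

        res = optimize.minimize(
            negll, np.asarray(x0, dtype=float), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 1500},
        )
        return -float(res.fun), res.x
    raise ValueError(f"unknown model {model!r}")


def _profile_start(fit: ModelFit, data: DoseResponseDataset, fixed_delta: bool):
    if not fixed_delta:
        return fit.theta
    p = fit.params
    if fit.model == "hill":
        return np.array([math.log(max(p["k"], 1e-12)), math.log(max(p["eta"] - 1.0, 1e-6))])
    if fit.model == "exponential":
        base = p["a"] if data.direction_sign > 0 else max(p["a"] - data.control.sd, 1e-9)
        return np.array([math.log(max(base, 1e-12)), min(max(p["c"], 1.0), _POWER_MAX)])
    return fit.theta  # unused by the closed-form branches


def profile_bounds(
    fit: ModelFit,
    data: DoseResponseDataset,
    level: float = 0.95,
    bmr_sd: float | None = None,
    bmc: float | None = None,
    span_decades: float = 3.0,
    n_grid: int = 200,
):
    """One-sided profile-likelihood bounds (BMCL, BMCU) on the BMC.

    The bound at confidence ``level`` collects parameter vectors whose
    log-likelihood lies within ``chi2_1(2*level - 1)/2`` of the maximum
    (1.353 at the default 95%) and takes the extreme BMC among them.  The
    profile is walked outward from the MLE on a log-dose grid (``n_grid``
    points spanning ``span_decades`` decades) and the crossing is refined
    by bisection to ~1e-6 relative precision.  If the likelihood never
    drops below the cutoff within the searched span, the widest searched
    bound is returned and a warning recorded.

    Returns ``(bmcl, bmcu, warnings)``.
    """
    if bmc is None:
        bmc = bmc_from_fit(fit, data, bmr_sd=bmr_sd)
    if math.isnan(bmc):
        return math.nan, math.nan, ("no-bmc",)
    fixed = bmr_sd is not None
    delta = float(bmr_sd) if fixed else None

    def prof(b, x0):
        if fixed:
            return _profile_ll_fixed(fit, data, b, delta, x0)
        return _profile_ll_modeled(fit, data, b, x0)

    x_hat = _profile_start(fit, data, fixed)
    ll_hat, x_hat = prof(bmc, x_hat)
    ll_max = max(fit.loglik, ll_hat)
    cutoff = ll_max - float(chi2.ppf(2 * level - 1, 1)) / 2.0

    warns = []
    step = 10.0 ** (span_decades / n_grid)

    def walk_down():
        b, x0 = bmc, x_hat.copy()
        for _ in range(n_grid):
            b_next = b / step
            ll, x0 = prof(b_next, x0)
            if ll < cutoff:
                lo, hi = b_next, b  # ll(lo) < cutoff <= ll(hi)
                for _ in range(60):
                    mid = math.sqrt(lo * hi)
                    ll_mid, x0 = prof(mid, x0)
                    if ll_mid >= cutoff:
                        hi = mid
                    else:
                        lo = mid
                    if hi / lo < 1 + 1e-6:
                        break
                return math.sqrt(lo * hi), False
            b = b_next
        return b, True

    def walk_up():
        b, x0 = bmc, x_hat.copy()
        for _ in range(n_grid):
            b_next = b * step
            ll, x0 = prof(b_next, x0)
            if ll < cutoff:
                lo, hi = b, b_next  # ll(hi) < cutoff <= ll(lo)
                for _ in range(60):
                    mid = math.sqrt(lo * hi)
                    ll_mid, x0 = prof(mid, x0)
                    if ll_mid >= cutoff:
                        lo = mid
                    else:
                        hi = mid
                    if hi / lo < 1 + 1e-6:
                        break
                return math.sqrt(lo * hi), False
            b = b_next
        return b, True

    bmcl, unbracketed_l = walk_down()
    bmcu, unbracketed_u = walk_up()
    if unbracketed_l:
        warns.append("bmcl-unbracketed")
    if unbracketed_u:
        warns.append("bmcu-unbracketed")
    bmcl = min(bmcl, bmc)
    bmcu = max(bmcu, bmc)
    return bmcl, bmcu, tuple(warns)


def estimate_bmd(
    fit: ModelFit,
    data: DoseResponseDataset,
    level: float = 0.95,
    bmr_sd: float | None = None,
) -> BMDEstimate:
    """BMC with profile bounds, packaged with a reliability verdict."""
    bmc = bmc_from_fit(fit, data, bmr_sd=bmr_sd)
    if math.isnan(bmc):
        return BMDEstimate(bmc=math.nan, reliable=False, warnings=("no-bmc",))
    bmcl, bmcu, warns = profile_bounds(fit, data, level=level, bmr_sd=bmr_sd, bmc=bmc)
    return BMDEstimate(bmc=bmc, bmcl=bmcl, bmcu=bmcu,
                       reliable=not warns, warnings=warns)


# ---------------------------------------------------------------------------
# screening and pooling


def filter_reliable(
    items: Sequence[tuple],
    gof_min: float = 0.10,
    bmc_bmcl_ratio_max: float = 20.0,
) -> list:
    """Keep (ModelFit, BMDEstimate) pairs that pass the reliability screen.

    A fit is reliable when it converged, its lack-of-fit p-value is at
    least ``gof_min`` (boundary inclusive), its BMCL is finite and
    positive, and BMC/BMCL does not exceed ``bmc_bmcl_ratio_max`` (guards
    degenerate profiles).  Raises :class:`NoReliableModelsError` when
    nothing survives.
    """
    kept = []
    for fit, est in items:
        if not fit.converged:
            continue
        if math.isnan(fit.gof_p) or fit.gof_p < gof_min:
            continue
        if math.isnan(est.bmc) or math.isnan(est.bmcl):
            continue
        if not (est.bmcl > 0 and math.isfinite(est.bmcl)):
            continue
        if est.bmc / est.bmcl > bmc_bmcl_ratio_max:
            continue
        kept.append((fit, est))
    if not kept:
        raise NoReliableModelsError("no reliable models: every fit failed the screen")
    return kept


def pool_models(kept: Sequence[tuple], weighting: str = "akaike") -> BMDPool:
    """Average reliable fits into lognormal BMC/BMCL/BMCU summaries.

    Weights are Akaike weights ``exp(-dAIC/2)`` normalized over the kept
    fits (or equal weights).  Each pooled quantity is summarized on the
    log scale: ``mu = sum w_i ln x_i`` and
    ``sigma = sqrt(sum w_i (ln x_i - mu)^2)``.
    """
    if weighting not in ("akaike", "equal"):
        raise ValueError(f"weighting must be 'akaike' or 'equal', got {weighting!r}")
    if not kept:
        raise NoReliableModelsError("cannot pool an empty model set")
    fits = [f for f, _ in kept]
    if weighting == "akaike":
        aics = np.array([f.aic for f in fits])
        raw = np.exp(-(aics - aics.min()) / 2.0)
    else:
        raw = np.ones(len(fits))
    w = raw / raw.sum()
    if len(kept) == 1:
        warnings.warn("single reliable model: pooled GSD degenerates to 1", stacklevel=2)

    def pooled(values):
        x = np.log(np.array(values, dtype=float))
        mu = float((w * x).sum())
        sigma = math.sqrt(max(float((w * (x - mu) ** 2).sum()), 0.0))
        return LognormalDist.from_mu_sigma(mu, sigma)

    weights = {f.model: float(wi) for f, wi in zip(fits, w)}
    return BMDPool(
        bmc_a=pooled([e.bmc for _, e in kept]),
        bmcl_a=pooled([e.bmcl for _, e in kept]),
        bmcu_a=pooled([e.bmcu for _, e in kept]),
        weights=weights,
    )


# ---------------------------------------------------------------------------
# CSV I/O

_CSV_COLUMNS = ["study_id", "endpoint", "dose_mg_m3", "n", "mean", "sd"]


def read_dose_response_csv(path) -> list:
    """Read dose–response summary data (one dataset per study/endpoint).

    Expected columns: study_id, endpoint, dose_mg_m3, n, mean, sd.
    Direction is inferred from the dose–mean covariance of each dataset.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dose-response CSV missing columns: {missing}")
    datasets = []
    for (study, endpoint), grp in df.groupby(["study_id", "endpoint"], sort=False):
        grp = grp.sort_values("dose_mg_m3")
        groups = tuple(
            DoseGroup(dose=float(r.dose_mg_m3), n=int(r.n), mean=float(r.mean), sd=float(r.sd))
            for r in grp.itertuples()
        )
        direction = DoseResponseDataset.infer_direction(grp["dose_mg_m3"], grp["mean"])
        datasets.append(DoseResponseDataset(str(study), str(endpoint), groups, direction))
    return datasets


def write_dose_response_csv(datasets: Sequence[DoseResponseDataset], path) -> None:
    rows = [
        {"study_id": ds.study_id, "endpoint": ds.endpoint, "dose_mg_m3": g.dose,
         "n": g.n, "mean": g.mean, "sd": g.sd}
        for ds in datasets for g in ds.groups
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
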