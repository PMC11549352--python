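"""Parametric growth-curve fitting and cross-strain parameter comparison.

Implements the three classical reparameterised growth models (logistic,
Gompertz, Richards) in which the parameters are directly the biological
quantities of interest: capacity ``A``, maximal growth rate ``mu`` and lag
period ``lam``. Fits are nonlinear least squares; model choice is by AIC;
group comparisons use one-way ANOVA followed by Tukey HSD (all pairs) or
Dunnett's many-to-one test (versus control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    InvalidDesignError,
    InvalidInputError,
    InvalidParameterError,
    SelectionError,
)

_E = math.e

RICHARDS_NU_BOUNDS = (0.1, 10.0)


def logistic(t, A, mu, lam):
    """Reparameterised logistic: inflection slope mu, lag lam, capacity A."""
    t = np.asarray(t, dtype=float)
    return A / (1.0 + np.exp(4.0 * mu * (lam - t) / A + 2.0))


def gompertz(t, A, mu, lam):
    """Reparameterised Gompertz (Zwietering form)."""
    t = np.asarray(t, dtype=float)
    return A * np.exp(-np.exp(mu * _E * (lam - t) / A + 1.0))


def richards(t, A, mu, lam, nu):
    """Reparameterised Richards; nu shapes asymmetry (nu=1 -> logistic)."""
    t = np.asarray(t, dtype=float)
    inner = mu * (1.0 + nu) ** (1.0 + 1.0 / nu) * (lam - t) / A
    return A * (1.0 + nu * np.exp(1.0 + nu) * np.exp(inner)) ** (-1.0 / nu)


MODEL_FORMS: dict[str, Callable] = {
    "logistic": logistic,
    "gompertz": gompertz,
    "richards": richards,
}

_N_PARAMS = {"logistic": 3, "gompertz": 3, "richards": 4}


@dataclass
class GrowthCurve:
    """Biomass readings over time for one culture well."""

    well_id: str
    strain: str
    treatment: str
    time_h: np.ndarray
    biomass: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if self.time_h.shape != self.biomass.shape:
            raise InvalidInputError("time and biomass must have equal length")
        if len(self.time_h) < 8:
            raise InvalidInputError("at least 8 samples required for fitting")
        if not np.all(np.diff(self.time_h) > 0):
            raise InvalidInputError("times must be strictly increasing")


@dataclass
class GrowthFit:
    model: str
    A: float
    mu: float
    lam: float
    rss: float
    aic: float
    converged: bool
    nu: Optional[float] = None
    n_params: int = 3
    message: str = ""


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic start: A0 = max biomass; mu0 = steepest finite-difference
    slope; lam0 = intercept of the max-slope tangent with the baseline."""
    a0 = float(np.max(y))
    slopes = np.diff(y) / np.diff(t)
    k = int(np.argmax(slopes))
    mu0 = float(slopes[k])
    t_star = 0.5 * (t[k] + t[k + 1])
    y_star = 0.5 * (y[k] + y[k + 1])
    baseline = float(np.min(y))
    lam0 = t_star - (y_star - baseline) / mu0 if mu0 > 0 else float(t[0])
    return a0, mu0, lam0


def fit_growth_model(curve: GrowthCurve, model: str) -> GrowthFit:
    """Fit one named model by nonlinear least squares.

    Non-convergence is reported via ``converged=False`` with a diagnostic
    message; there is no silent fallback to another model.
    """
    if model not in MODEL_FORMS:
        raise InvalidParameterError(
            f"unknown model {model!r}; choose from {sorted(MODEL_FORMS)}"
        )
    t, y = curve.time_h, curve.biomass
    n = len(t)
    k_params = _N_PARAMS[model]

    if np.ptp(y) == 0:
        return GrowthFit(
            model=model, A=float(y[0]), mu=0.0, lam=0.0, rss=0.0,
            aic=math.inf, converged=False, n_params=k_params,
            message="degenerate constant-biomass curve",
        )

    a0, mu0, lam0 = _initial_guess(t, y)
    func = MODEL_FORMS[model]
    if model == "richards":
        p0 = [a0, max(mu0, 1e-6), lam0, 1.0]
        lo = [1e-12, 1e-12, -np.inf, RICHARDS_NU_BOUNDS[0]]
        hi = [np.inf, np.inf, np.inf, RICHARDS_NU_BOUNDS[1]]
    else:
        p0 = [a0, max(mu0, 1e-6), lam0]
        lo = [1e-12, 1e-12, -np.inf]
        hi = [np.inf, np.inf, np.inf]

    try:
        popt, _ = optimize.curve_fit(
            func, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning, ValueError) as exc:
        return GrowthFit(
            model=model, A=a0, mu=mu0, lam=lam0, rss=math.inf,
            aic=math.inf, converged=False, n_params=k_params,
            message=f"curve_fit failed: {exc}",
        )

    resid = y - func(t, *popt)
    rss = float(np.sum(resid**2))
    # Gaussian log-likelihood AIC; +1 free parameter for the noise variance
    if rss <= 0:
        rss_for_aic = np.finfo(float).tiny
    else:
        rss_for_aic = rss
    aic = n * math.log(rss_for_aic / n) + 2.0 * (k_params + 1)
    return GrowthFit(
        model=model,
        A=float(popt[0]),
        mu=float(popt[1]),
        lam=float(popt[2]),
        nu=float(popt[3]) if model == "richards" else None,
        rss=rss,
        aic=aic,
        converged=True,
        n_params=k_params,
    )


def select_best_model(fits: Sequence[GrowthFit]) -> GrowthFit:
    """Return the converged fit with minimal AIC; AIC ties go to the model
    with fewer parameters."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise SelectionError("no converged fit to select from")
    return min(converged, key=lambda f: (f.aic, f.n_params))


@dataclass
class ComparisonResult:
    anova_f: float
    anova_p: float
    scheme: str
    method: str
    table: pd.DataFrame = field(repr=False)


def _extract_param(values, param: str) -> np.ndarray:
    out = []
    for v in values:
        out.append(float(getattr(v, param)) if isinstance(v, GrowthFit) else float(v))
    return np.asarray(out)


def compare_growth_params(
    groups: Mapping[str, Sequence[Union[GrowthFit, float]]],
    param: str = "mu",
    scheme: str = "all_pairs",
    control: Optional[str] = None,
) -> ComparisonResult:
    """One-way ANOVA on a fitted parameter, with multiplicity-adjusted
    pairwise comparisons.

    ``scheme='all_pairs'`` adjusts with Tukey HSD; ``scheme='vs_control'``
    uses Dunnett's many-to-one procedure against ``control``. The adjustment
    method actually used is recorded in the result.
    """
    names = list(groups)
    if len(names) < 2:
        raise InvalidDesignError("need at least 2 groups")
    data = {name: _extract_param(groups[name], param) for name in names}
    for name, vals in data.items():
        if len(vals) < 2:
            raise InvalidDesignError(f"group {name!r} has fewer than 2 wells")

    f_stat, anova_p = stats.f_oneway(*[data[name] for name in names])

    rows = []
    if scheme == "all_pairs":
        res = stats.tukey_hsd(*[data[name] for name in names])
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "estimate_diff": float(np.mean(data[names[i]]) - np.mean(data[names[j]])),
                        "p_adjusted": float(res.pvalue[i, j]),
                    }
                )
        method = "tukey_hsd"
    elif scheme == "vs_control":
        if control is None or control not in groups:
            raise InvalidDesignError("vs_control scheme requires a valid control group")
        treat_names = [name for name in names if name != control]
        res = stats.dunnett(
            *[data[name] for name in treat_names], control=data[control]
        )
        for name, p in zip(treat_names, np.atleast_1d(res.pvalue)):
            rows.append(
                {
                    "group_a": name,
                    "group_b": control,
                    "estimate_diff": float(np.mean(data[name]) - np.mean(data[control])),
                    "p_adjusted": float(p),
                }
            )
        method = "dunnett_multivariate_t"
    else:
        raise InvalidParameterError(f"unknown scheme {scheme!r}")

    return ComparisonResult(
        anova_f=float(f_stat),
        anova_p=float(anova_p),
        scheme=scheme,
        method=method,
        table=pd.DataFrame(rows),
    )
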