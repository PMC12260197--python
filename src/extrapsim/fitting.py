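"""Maximum-likelihood fitting of parametric survival models.

Supports two modes sharing one likelihood:

* ``naive`` — the usual right-censored parametric likelihood,
  ``sum_events log h(t) - sum_all H(t)``.
* ``excess`` — internal additive hazards (relative survival): the total
  death hazard is ``h*(t) + lambda(t)`` with ``h*`` a fixed background
  mortality law evaluated along each subject's age, and only the excess
  ``lambda`` is parametric.  The naive mode is the special case ``h* = 0``.

Optimisation runs on the estimation scale (log for strictly positive
parameters) via Nelder–Mead followed by a BFGS polish, with up to three
fixed perturbed starts before a fit is declared non-converged.  The
covariance comes from the numeric Hessian of the negative log-likelihood
at the optimum (ridge 1e-8); a non-positive-definite Hessian marks the
fit failed.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import math
from typing import Sequence

import numpy as np
from scipy import optimize

from . import distributions as dist
from .mortality import MortalityLaw, cumulative_hazard as law_cumhaz, hazard as law_hazard

__all__ = [
    "FitResult",
    "fit_parametric",
    "fit_excess",
    "fit_all_families",
    "aicc",
    "bic",
    "select_best",
    "draw_parameters",
    "survival_eval",
    "hazard_eval",
]

_BIG = 1e12


@dataclass
class FitResult:
    """A fitted (or failed) parametric model for one transition/outcome."""

    family: str
    mode: str = "naive"                 # 'naive' | 'excess'
    params: dict | None = None          # natural scale
    cov: np.ndarray | None = None       # estimation scale
    loglik: float | None = None
    aicc: float | None = None
    n: int = 0
    n_events: int = 0
    converged: bool = False
    reason: str = ""
    background: MortalityLaw | None = None
    age0: float | np.ndarray | None = None

    @property
    def k(self) -> int:
        return dist.n_params(self.family)

    def to_json(self) -> str:
        d = {
            "family": self.family, "mode": self.mode, "params": self.params,
            "cov": None if self.cov is None else np.asarray(self.cov).tolist(),
            "loglik": self.loglik, "aicc": self.aicc, "n": self.n,
            "n_events": self.n_events, "converged": self.converged,
            "reason": self.reason,
        }
        return json.dumps(d, indent=2)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC; ``inf`` marks an ineligible model (n <= k+1)."""
    if n <= k + 1:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def bic(loglik: float, k: int, n: int) -> float:
    if n <= 0:
        return math.inf
    return -2.0 * loglik + k * math.log(n)


def _prepare_times(times: np.ndarray, events: np.ndarray):
    times = np.asarray(times, dtype=float).copy()
    events = np.asarray(events).astype(bool)
    if times.shape != events.shape:
        raise ValueError("times and events must have matching shapes")
    n_shift = int(np.sum(times <= 0))
    times[times <= 0] = 1e-6  # zero sojourns nudged off the boundary
    return times, events, n_shift


def _initial_values(family: str, times, events) -> dict[str, float]:
    et = times[events] if events.any() else times
    mean_t = float(np.mean(times))
    rate0 = max(float(np.sum(events)) / max(float(np.sum(times)), 1e-12), 1e-6)
    mln = float(np.mean(np.log(np.maximum(et, 1e-12))))
    sln = float(np.std(np.log(np.maximum(et, 1e-12))))
    sln = min(max(sln, 0.2), 4.0)
    if family == "exponential":
        return {"rate": rate0}
    if family == "weibull":
        shape0 = min(max(math.pi / (math.sqrt(6.0) * sln), 0.3), 4.0)
        return {"shape": shape0, "scale": max(math.exp(mln), 1e-6)}
    if family == "gompertz":
        return {"rate": rate0, "shape": 0.0}
    if family == "lognormal":
        return {"mu": mln, "sigma": sln}
    if family == "loglogistic":
        shape0 = min(max(math.pi / (math.sqrt(3.0) * sln), 0.3), 4.0)
        return {"shape": shape0, "scale": max(math.exp(mln), 1e-6)}
    if family == "gengamma":
        return {"mu": mln, "sigma": sln, "q": 0.5}
    raise ValueError(f"unknown family {family!r}")


def _nll_factory(family, times, events, bg_hazard, bg_cumhaz):
    """Negative log-likelihood on the estimation scale.

    ``bg_hazard``/``bg_cumhaz`` are fixed per-subject background terms
    (zeros in naive mode).
    """
    ev_t = times[events]
    bg_h_ev = bg_hazard[events]

    def nll(theta):
        try:
            params = dist.from_estimation_scale(family, theta)
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                H = dist.cumulative_hazard(family, params, times)
                lam = np.exp(dist.log_hazard(family, params, ev_t))
                total_h = bg_h_ev + lam
                if np.any(total_h <= 0) or not np.all(np.isfinite(H)):
                    return _BIG
                val = -(np.sum(np.log(total_h)) - np.sum(H + bg_cumhaz))
        except (OverflowError, ValueError, FloatingPointError):
            return _BIG
        if not np.isfinite(val):
            return _BIG
        return float(val)

    return nll


def _numeric_hessian(f, x, step=1e-4):
    k = x.size
    H = np.empty((k, k))
    hs = step * (1.0 + np.abs(x))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / hs[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * hs[i] * hs[j])
    return H


def _fit(family, times, events, mode, background=None, age0=None,
         criterion="aicc") -> FitResult:
    times, events, _ = _prepare_times(times, events)
    n, n_events = times.size, int(np.sum(events))
    result = FitResult(family=family, mode=mode, n=n, n_events=n_events,
                       background=background, age0=age0)
    if n == 0:
        result.reason = "empty dataset"
        return result
    if n_events == 0:
        result.reason = "no events"
        return result
    k = dist.n_params(family)
    if n <= k + 1:
        result.reason = "ineligible: n <= k+1"
        return result

    if mode == "excess":
        a0 = np.broadcast_to(np.asarray(age0, dtype=float), times.shape)
        bg_h = np.asarray(law_hazard(background, a0 + times), dtype=float)
        bg_H = np.asarray(law_cumhaz(background, a0, times), dtype=float)
    else:
        bg_h = np.zeros_like(times)
        bg_H = np.zeros_like(times)

    nll = _nll_factory(family, times, events, bg_h, bg_H)
    theta0 = dist.to_estimation_scale(family, _initial_values(family, times, events))
    # three fixed starts: base init plus two deterministic perturbations
    starts = [theta0,
              theta0 + np.linspace(0.5, -0.5, theta0.size),
              theta0 + np.linspace(-0.8, 0.8, theta0.size)]

    for theta_start in starts:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            res = optimize.minimize(nll, theta_start, method="Nelder-Mead",
                                    options={"maxiter": 500, "xatol": 1e-6,
                                             "fatol": 1e-9})
            polish = optimize.minimize(nll, res.x, method="BFGS",
                                       options={"maxiter": 100})
            cand = polish if polish.fun <= res.fun else res
            if not np.isfinite(cand.fun) or cand.fun >= _BIG / 2:
                continue
            H = _numeric_hessian(nll, cand.x)
        if not np.all(np.isfinite(H)):
            continue
        H = 0.5 * (H + H.T) + 1e-8 * np.eye(H.shape[0])
        try:
            eigs = np.linalg.eigvalsh(H)
        except np.linalg.LinAlgError:
            continue
        if np.any(eigs <= 0):
            continue
        cov = np.linalg.inv(H)
        result.params = dist.from_estimation_scale(family, cand.x)
        result.cov = 0.5 * (cov + cov.T)
        result.loglik = -float(cand.fun)
        result.aicc = (aicc(result.loglik, k, n) if criterion == "aicc"
                       else bic(result.loglik, k, n))
        result.converged = np.isfinite(result.aicc)
        if not result.converged:
            result.params = result.cov = result.loglik = result.aicc = None
            result.reason = "ineligible information criterion"
        return result

    result.reason = "optimizer failed on all starts"
    return result


def fit_parametric(times, events, family: str, criterion: str = "aicc") -> FitResult:
    """Standard right-censored MLE of one family (no background hazard)."""
    return _fit(family, times, events, "naive", criterion=criterion)


def fit_excess(times, events, family: str, background: MortalityLaw,
               age0, criterion: str = "aicc") -> FitResult:
    """Additive-hazards (relative-survival) MLE of the excess hazard.

    ``age0`` is the attained age at the start of each subject's clock —
    a scalar applied to everyone, or one value per subject.
    """
    return _fit(family, times, events, "excess", background=background,
                age0=age0, criterion=criterion)


class SelectionFailure(RuntimeError):
    """All candidate families failed to converge for a transition."""


def select_best(fits: Sequence[FitResult]) -> FitResult:
    """Lowest-AICc converged fit; ties -> fewer parameters -> family order."""
    order = {f: i for i, f in enumerate(dist.FAMILIES)}
    ok = [f for f in fits if f.converged]
    if not ok:
        raise SelectionFailure("no parametric family converged")
    return min(ok, key=lambda f: (f.aicc, f.k, order.get(f.family, 99)))


def fit_all_families(times, events, mode: str = "naive",
                     background: MortalityLaw | None = None, age0=None,
                     families: Sequence[str] = dist.FAMILIES,
                     criterion: str = "aicc") -> list[FitResult]:
    """Fit every candidate family to one transition dataset."""
    out = []
    for fam in families:
        if mode == "excess":
            out.append(fit_excess(times, events, fam, background, age0, criterion))
        else:
            out.append(fit_parametric(times, events, fam, criterion))
    return out


def draw_parameters(fit: FitResult, n_draws: int, seed) -> dict[str, np.ndarray]:
    """Multivariate-normal PSA draws on the estimation scale.

    Returns a dict of natural-scale parameter arrays of length ``n_draws``.
    NaN draws (possible with extreme covariances) are rejected and redrawn,
    up to 100 attempts.
    """
    if not fit.converged or fit.cov is None:
        raise SelectionFailure("cannot draw from a non-converged fit")
    rng = np.random.default_rng(seed)
    mean = dist.to_estimation_scale(fit.family, fit.params)
    cov = np.asarray(fit.cov, dtype=float)
    draws = rng.multivariate_normal(mean, cov, size=n_draws, method="svd")
    for _ in range(100):
        bad = ~np.all(np.isfinite(draws), axis=1)
        if not bad.any():
            break
        draws[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()), method="svd")
    names = dist.PARAM_NAMES[fit.family]
    logs = dist.LOG_SCALE[fit.family]
    with np.errstate(over="ignore"):
        return {nm: (np.exp(draws[:, i]) if lg else draws[:, i])
                for i, (nm, lg) in enumerate(zip(names, logs))}


def survival_eval(family: str, params: dict, t) -> np.ndarray:
    """S(t) for the named family (closed forms, log-space stable)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return dist.survival(family, params, t)


def hazard_eval(family: str, params: dict, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return dist.hazard(family, params, t)
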