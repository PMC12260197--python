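"""The six parametric time-to-event families used by both model engines.

Parameterisations follow the conventional flexible-survival set:

========== ============================ ======================================
family      parameters                   survival function
========== ============================ ======================================
exponential rate                         exp(-rate*t)
weibull     shape a, scale b             exp(-(t/b)^a)
gompertz    rate, shape (real)           exp(-(rate/shape)(e^{shape t}-1))
lognormal   mu, sigma                    Phi-bar((ln t - mu)/sigma)
loglogistic shape a, scale b             1 / (1 + (t/b)^a)
gengamma    mu, sigma, q                 generalised gamma, (mu, sigma, Q)
                                         form; q=1 -> weibull, q=0 -> lognormal
========== ============================ ======================================

Each family exposes log-hazard, cumulative hazard, survival and an
inverse-survival (quantile) used for inverse-CDF event sampling.  Strictly
positive parameters are estimated on the log scale; the Gompertz shape,
log-normal mu and generalised-gamma q are unconstrained.
"""

from __future__ import annotations

import numpy as np
from scipy.special import (gammainc, gammaincc, gammainccinv, gammaincinv,
                           gammaln, log_ndtr, ndtri)

FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic", "gengamma", "gompertz")

# parameter names in estimation order, and which are log-transformed
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("rate", "shape"),
    "lognormal": ("mu", "sigma"),
    "loglogistic": ("shape", "scale"),
    "gengamma": ("mu", "sigma", "q"),
}
LOG_SCALE: dict[str, tuple[bool, ...]] = {
    "exponential": (True,),
    "weibull": (True, True),
    "gompertz": (True, False),
    "lognormal": (False, True),
    "loglogistic": (True, True),
    "gengamma": (False, True, False),
}

_Q_EPS = 1e-6  # |q| below this: treat gengamma as log-normal


def n_params(family: str) -> int:
    return len(PARAM_NAMES[family])


def to_estimation_scale(family: str, params: dict[str, float]) -> np.ndarray:
    vals = [params[k] for k in PARAM_NAMES[family]]
    return np.array([np.log(v) if lg else v for v, lg in zip(vals, LOG_SCALE[family])])


def from_estimation_scale(family: str, theta: np.ndarray) -> dict[str, float]:
    out = {}
    with np.errstate(over="ignore"):
        for name, lg, v in zip(PARAM_NAMES[family], LOG_SCALE[family], theta):
            out[name] = float(np.exp(v)) if lg else float(v)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


_NORM_LOGC = -0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(z):
    return _NORM_LOGC - 0.5 * z * z


def _gg_logsf(t, mu, sigma, q):
    """log S(t) of the (mu, sigma, Q) generalised gamma, q != 0.

    With w = (ln t - mu)/sigma and a = 1/q^2, the survival is the upper
    (q > 0) or lower (q < 0) regularised gamma tail at g = a*exp(q*w).
    """
    a = 1.0 / (q * q)
    w = (np.log(np.maximum(t, 1e-300)) - mu) / sigma
    with np.errstate(over="ignore"):
        g = a * np.exp(q * w)
    tail = gammaincc(a, g) if q > 0 else gammainc(a, g)
    return np.log(np.maximum(tail, 1e-300))


def _gg_logpdf(t, mu, sigma, q):
    a = 1.0 / (q * q)
    tt = np.maximum(t, 1e-300)
    w = (np.log(tt) - mu) / sigma
    with np.errstate(over="ignore"):
        return (np.log(abs(q)) - np.log(sigma * tt) + a * np.log(a)
                - gammaln(a) + a * q * w - a * np.exp(q * w))


def log_hazard(family: str, params: dict[str, float], t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    tiny = np.maximum(t, 1e-300)
    if family == "exponential":
        return np.full_like(t, np.log(params["rate"]))
    if family == "weibull":
        a, b = params["shape"], params["scale"]
        return np.log(a / b) + (a - 1.0) * np.log(tiny / b)
    if family == "gompertz":
        return np.log(params["rate"]) + params["shape"] * t
    if family == "lognormal":
        z = (np.log(tiny) - params["mu"]) / params["sigma"]
        return _norm_logpdf(z) - np.log(params["sigma"] * tiny) - log_ndtr(-z)
    if family == "loglogistic":
        a, b = params["shape"], params["scale"]
        z = a * np.log(tiny / b)
        return np.log(a) - np.log(tiny) + z - _softplus(z)
    if family == "gengamma":
        mu, sigma, q = params["mu"], params["sigma"], params["q"]
        if abs(q) < _Q_EPS:
            return log_hazard("lognormal", params, t)
        return _gg_logpdf(t, mu, sigma, q) - _gg_logsf(t, mu, sigma, q)
    raise ValueError(f"unknown family {family!r}")


def cumulative_hazard(family: str, params: dict[str, float], t: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        return _cumulative_hazard(family, params, t)


def _cumulative_hazard(family, params, t):
    t = np.asarray(t, dtype=float)
    tiny = np.maximum(t, 0.0)
    if family == "exponential":
        return params["rate"] * tiny
    if family == "weibull":
        return (tiny / params["scale"]) ** params["shape"]
    if family == "gompertz":
        rate, shape = params["rate"], params["shape"]
        if shape == 0.0:
            return rate * tiny
        return (rate / shape) * np.expm1(shape * tiny)
    if family == "lognormal":
        z = (np.log(np.maximum(tiny, 1e-300)) - params["mu"]) / params["sigma"]
        return np.where(tiny > 0, -log_ndtr(-z), 0.0)
    if family == "loglogistic":
        a, b = params["shape"], params["scale"]
        z = a * np.log(np.maximum(tiny, 1e-300) / b)
        return np.where(tiny > 0, _softplus(z), 0.0)
    if family == "gengamma":
        mu, sigma, q = params["mu"], params["sigma"], params["q"]
        if abs(q) < _Q_EPS:
            return cumulative_hazard("lognormal", params, t)
        return np.where(tiny > 0, -_gg_logsf(tiny, mu, sigma, q), 0.0)
    raise ValueError(f"unknown family {family!r}")


def survival(family: str, params: dict[str, float], t: np.ndarray) -> np.ndarray:
    """S(t) = exp(-H(t)); S(0) = 1 by construction."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        return np.exp(-cumulative_hazard(family, params, t))


def hazard(family: str, params: dict[str, float], t: np.ndarray) -> np.ndarray:
    return np.exp(log_hazard(family, params, t))


def inverse_survival(family: str, params: dict[str, float], p: np.ndarray) -> np.ndarray:
    """Return t with S(t) = p; ``inf`` where the distribution is improper.

    Feeding uniform draws yields inverse-CDF samples.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p must lie in (0, 1]")
    target = -np.log(p)  # required cumulative hazard
    if family == "exponential":
        return target / params["rate"]
    if family == "weibull":
        return params["scale"] * target ** (1.0 / params["shape"])
    if family == "gompertz":
        rate, shape = params["rate"], params["shape"]
        if shape == 0.0:
            return target / rate
        z = shape * target / rate
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(z > -1.0, np.log1p(np.maximum(z, -1.0 + 1e-300)) / shape,
                            np.inf)
    if family == "lognormal":
        return np.exp(params["mu"] - params["sigma"] * ndtri(p))
    if family == "loglogistic":
        a, b = params["shape"], params["scale"]
        return b * ((1.0 - p) / p) ** (1.0 / a)
    if family == "gengamma":
        mu, sigma, q = params["mu"], params["sigma"], params["q"]
        if abs(q) < _Q_EPS:
            return np.exp(mu - sigma * ndtri(p))
        # invert via the underlying gamma tail; stable for q of either sign
        aa = 1.0 / (q * q)
        g = gammainccinv(aa, p) if q > 0 else gammaincinv(aa, p)
        w = np.log(q * q * g) / q
        return np.exp(mu + sigma * w)
    raise ValueError(f"unknown family {family!r}")
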