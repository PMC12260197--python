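"""Background (general-population) mortality: life tables and parametric laws.

Two parametric mortality laws are supported:

* **Kannisto–Makeham** — a logistic old-age hazard with a constant
  (Makeham) term, ``mu(x) = c + a*exp(b*x) / (1 + a*exp(b*x))``.  Used on
  the data-generation side, where a realistic late-life plateau matters.
* **Gompertz** — ``mu(x) = rate * exp(shape*(x - x0))``, the standard
  analysis-side choice when fitting from a fixed starting age.

Laws are fitted to life-table central death rates by minimising the Poisson
deviance, treating rates as piecewise-constant over one-year age intervals
(the law is evaluated at the interval midpoint).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LifeTable",
    "MortalityLaw",
    "MortalityFitError",
    "load_life_table",
    "fit_mortality_law",
    "cumulative_hazard",
    "hazard",
    "sample_death_time",
    "fixture_law",
    "fixture_life_table_path",
]

_INF = float("inf")


class MortalityFitError(RuntimeError):
    """Raised when a mortality-law fit fails to converge."""


@dataclass(frozen=True)
class LifeTable:
    """Central death rates by single year of age."""

    ages: np.ndarray          # integer years, strictly increasing
    rates: np.ndarray         # central death rates m_x, in [0, 1]
    label: str = ""
    source_year: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if ages.ndim != 1 or ages.shape != rates.shape or ages.size == 0:
            raise ValueError("ages and rates must be matching 1-d arrays")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("life-table ages must be strictly increasing")
        if np.any(rates < 0) or np.any(rates > 1) or not np.all(np.isfinite(rates)):
            raise ValueError("life-table rates must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)

    def subset(self, lo: float, hi: float) -> "LifeTable":
        m = (self.ages >= lo) & (self.ages <= hi)
        return LifeTable(self.ages[m], self.rates[m], self.label, self.source_year)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "mx": self.rates})


@dataclass(frozen=True)
class MortalityLaw:
    """A parametric background-mortality hazard by age.

    ``kannisto_makeham``: params ``a > 0``, ``b > 0``, ``c >= 0`` with
    hazard ``c + a*e^{b x} / (1 + a*e^{b x})`` (age ``x`` absolute).
    ``gompertz``: params ``rate > 0``, ``shape`` (real) with hazard
    ``rate * e^{shape (x - x0)}``.
    """

    law_kind: str
    params: dict[str, float]
    x0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.law_kind not in ("kannisto_makeham", "gompertz"):
            raise ValueError(f"unknown law_kind {self.law_kind!r}")
        p = dict(self.params)
        if self.law_kind == "kannisto_makeham":
            if p["a"] <= 0 or p["b"] <= 0 or p["c"] < 0:
                raise ValueError("kannisto_makeham requires a>0, b>0, c>=0")
        else:
            if p["rate"] <= 0:
                raise ValueError("gompertz requires rate>0")
        object.__setattr__(self, "params", p)

    # -- serialisation -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "law_kind": self.law_kind,
            "params": self.params,
            "x0": self.x0,
            "label": self.label,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MortalityLaw":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(d["law_kind"], d["params"], d.get("x0", 0.0), d.get("label", ""))


class _ZeroLaw(MortalityLaw):
    """Degenerate hazard-free law, handy for tests and null comparisons."""

    def __init__(self, x0: float = 0.0):
        object.__setattr__(self, "law_kind", "gompertz")
        object.__setattr__(self, "params", {"rate": 0.0, "shape": 0.0})
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "label", "zero-hazard")


def zero_law(x0: float = 0.0) -> MortalityLaw:
    """A law whose hazard is identically zero (deaths never occur)."""
    return _ZeroLaw(x0)


# ---------------------------------------------------------------------------
# hazard / cumulative hazard / sampling
# ---------------------------------------------------------------------------

def hazard(law: MortalityLaw, age: float | np.ndarray) -> np.ndarray | float:
    """Instantaneous hazard mu(age)."""
    age = np.asarray(age, dtype=float)
    if law.law_kind == "gompertz":
        rate, shape = law.params["rate"], law.params["shape"]
        out = rate * np.exp(shape * (age - law.x0))
    else:
        a, b, c = law.params["a"], law.params["b"], law.params["c"]
        # logistic term a e^{bx}/(1+a e^{bx}) computed via log for stability
        z = np.log(a) + b * age
        out = c + 1.0 / (1.0 + np.exp(-z))
    return out if out.ndim else float(out)


def cumulative_hazard(
    law: MortalityLaw, age0: float | np.ndarray, t: float | np.ndarray
) -> np.ndarray | float:
    """Integrated hazard over [age0, age0 + t]; closed form for both laws."""
    age0 = np.asarray(age0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if law.law_kind == "gompertz":
        rate, shape = law.params["rate"], law.params["shape"]
        if shape == 0.0:
            out = rate * t * np.ones_like(age0 + t)
        else:
            out = (rate / shape) * np.exp(shape * (age0 - law.x0)) * np.expm1(shape * t)
    else:
        a, b, c = law.params["a"], law.params["b"], law.params["c"]
        # int a e^{bx}/(1+a e^{bx}) dx = (1/b) ln(1 + a e^{bx})
        la = np.log(a)
        out = c * t + (np.logaddexp(0.0, la + b * (age0 + t))
                       - np.logaddexp(0.0, la + b * age0)) / b
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def _km_invert(law: MortalityLaw, age0: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Solve H(age0 -> age0+t) = target for Kannisto–Makeham (vectorised).

    Safeguarded Newton: H is increasing and smooth; start from the
    constant-hazard guess and keep a bisection bracket for stragglers.
    """
    h0 = np.maximum(np.asarray(hazard(law, age0), dtype=float), 1e-12)
    t = np.maximum(target / h0, 1e-12)
    lo = np.zeros_like(t)
    # expand an upper bracket geometrically
    hi = np.maximum(t * 2.0, 1.0)
    for _ in range(200):
        bad = cumulative_hazard(law, age0, hi) < target
        if not np.any(bad):
            break
        hi[bad] *= 2.0
    for _ in range(100):
        H = np.asarray(cumulative_hazard(law, age0, t), dtype=float)
        resid = H - target
        done = np.abs(resid) <= 1e-10 * np.maximum(1.0, target)
        if np.all(done):
            break
        lo = np.where(resid < 0, np.maximum(lo, t), lo)
        hi = np.where(resid > 0, np.minimum(hi, t), hi)
        step = resid / np.maximum(np.asarray(hazard(law, age0 + t), dtype=float), 1e-300)
        tn = t - step
        out_of_bracket = (tn <= lo) | (tn >= hi)
        tn = np.where(out_of_bracket, 0.5 * (lo + hi), tn)
        t = np.where(done, t, tn)
    return t


def sample_death_time(
    law: MortalityLaw,
    age0: float | np.ndarray,
    u: float | np.ndarray,
) -> np.ndarray | float:
    """Inverse-CDF draw of remaining lifetime at age ``age0``.

    Solves ``H(age0 -> age0+t) = -ln(u)`` for ``t``; returns ``inf`` when
    the total hazard mass is insufficient (possible for Gompertz with
    negative shape, whose cumulative hazard plateaus).
    """
    scalar = np.isscalar(age0) and np.isscalar(u)
    age0 = np.atleast_1d(np.asarray(age0, dtype=float))
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly inside (0, 1)")
    age0, u = np.broadcast_arrays(age0, u)
    target = -np.log(u)
    if law.law_kind == "gompertz":
        rate, shape = law.params["rate"], law.params["shape"]
        if rate == 0.0:
            t = np.full_like(target, _INF)
        elif shape == 0.0:
            t = target / rate
        else:
            z = shape * target / (rate * np.exp(shape * (age0 - law.x0)))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(z > -1.0,
                             np.log1p(np.maximum(z, -1.0 + 1e-300)) / shape, _INF)
    else:
        t = _km_invert(law, age0.astype(float).copy(), target)
    return float(t[0]) if scalar else t


# ---------------------------------------------------------------------------
# life-table IO and law fitting
# ---------------------------------------------------------------------------

def load_life_table(
    path: str | Path,
    dialect: str = "mx",
    age_col: str = "age",
    rate_col: str | None = None,
    label: str = "",
    source_year: str = "",
) -> LifeTable:
    """Read a life-table CSV.

    ``dialect='mx'`` reads central death rates directly; ``dialect='qx'``
    reads annual death probabilities and converts via ``m = -ln(1 - q)``
    (constant hazard within the year).  ``q = 1`` is rejected — it implies
    zero within-year survival and an infinite rate.
    """
    if dialect not in ("mx", "qx"):
        raise ValueError("dialect must be 'mx' or 'qx'")
    df = pd.read_csv(path, comment="#")
    rate_col = rate_col or dialect
    for col in (age_col, rate_col):
        if col not in df.columns:
            raise ValueError(f"life table is missing column {col!r}")
    ages = df[age_col].to_numpy(dtype=float)
    vals = df[rate_col].to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("mortality values outside [0, 1]")
    if dialect == "qx":
        if np.any(vals >= 1.0):
            raise ValueError("qx = 1 implies infinite central rate")
        vals = -np.log1p(-vals)
    return LifeTable(ages, vals, label=label, source_year=source_year)


def _poisson_deviance(m: np.ndarray, mu: np.ndarray) -> float:
    mu = np.maximum(mu, 1e-12)
    m_safe = np.maximum(m, 1e-12)
    return float(2.0 * np.sum(m * np.log(m_safe / mu) - (m - mu)))


def fit_mortality_law(
    table: LifeTable,
    law_kind: str,
    age_range: tuple[float, float] | None = None,
    x0: float | None = None,
    label: str = "",
) -> MortalityLaw:
    """Fit a mortality law to central rates by minimum Poisson deviance.

    Rates are matched at age-interval midpoints (``age + 0.5``).  Raises
    :class:`MortalityFitError` with optimiser diagnostics on failure —
    a silently defaulted law is never returned.
    """
    sub = table if age_range is None else table.subset(*age_range)
    min_rows = 4 if law_kind == "kannisto_makeham" else 2
    if sub.ages.size < min_rows:
        raise ValueError(f"{law_kind} fit needs at least {min_rows} rows in range")
    xm = sub.ages + 0.5
    m = sub.rates
    x0 = float(x0 if x0 is not None else sub.ages[0])

    if law_kind == "gompertz":
        # log-linear regression on log-rates gives the exact deviance optimum
        # as a starting point (and the optimum itself for noiseless tables)
        logm = np.log(np.maximum(m, 1e-12))
        slope, icept = np.polyfit(xm - x0, logm, 1)
        theta0 = np.array([icept, slope])  # [log rate, shape]

        def unpack(th):
            return MortalityLaw("gompertz", {"rate": math.exp(th[0]), "shape": th[1]}, x0, label)
    else:
        c0 = max(0.25 * float(np.min(m)), 1e-6)
        y = np.log(np.maximum(m - c0, 1e-8))
        b0, la0 = np.polyfit(xm, y, 1)
        b0 = min(max(b0, 1e-3), 0.5)
        theta0 = np.array([la0, math.log(b0), math.log(c0)])  # [log a, log b, log c]

        def unpack(th):
            return MortalityLaw(
                "kannisto_makeham",
                {"a": math.exp(th[0]), "b": math.exp(th[1]), "c": math.exp(th[2])},
                x0, label,
            )

    def objective(th):
        try:
            law = unpack(th)
        except (OverflowError, ValueError):
            return 1e12
        mu = np.asarray(hazard(law, xm), dtype=float)
        if not np.all(np.isfinite(mu)):
            return 1e12
        return _poisson_deviance(m, mu)

    res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
    polish = optimize.minimize(objective, res.x, method="BFGS",
                               options={"maxiter": 200})
    best = polish if polish.fun <= res.fun else res
    if not np.isfinite(best.fun) or best.fun >= 1e11:
        raise MortalityFitError(
            f"{law_kind} fit did not converge: fun={best.fun!r}, "
            f"message={getattr(best, 'message', '')!r}"
        )
    return unpack(best.x)


# ---------------------------------------------------------------------------
# shipped fixtures (synthetic approximations of Canadian period life tables)
# ---------------------------------------------------------------------------

def fixture_life_table_path(which: str) -> Path:
    """Path to a shipped synthetic life-table CSV ('generation' or 'analysis')."""
    name = {
        "generation": "life_table_1981_synthetic.csv",
        "analysis": "life_table_2018_synthetic.csv",
    }[which]
    return Path(str(resources.files("extrapsim.data").joinpath(name)))


def fixture_law(which: str) -> MortalityLaw:
    """A shipped mortality-law fixture.

    ``'generation'``: Kannisto–Makeham law fitted to a synthetic
    approximation of the Canadian 1980/82 period life table (used by the
    data generator).  ``'analysis'``: Gompertz law from age 60 fitted to a
    synthetic approximation of the 2017/19 table (used by the estimators).
    ``'zero'``: identically-zero hazard.
    """
    if which == "zero":
        return zero_law()
    name = {
        "generation": "law_generation_kannisto_makeham.json",
        "analysis": "law_analysis_gompertz.json",
    }[which]
    text = resources.files("extrapsim.data").joinpath(name).read_text()
    d = json.loads(text)
    return MortalityLaw(d["law_kind"], d["params"], d.get("x0", 0.0), d.get("label", ""))
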