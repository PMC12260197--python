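"""Population estimands and performance metrics.

The truth against which every model estimate is judged comes from the
complete (uncensored) population: restricted mean years in PF and overall,
as areas under Kaplan–Meier curves up to the scenario's time horizon — the
first whole year by which population overall survival has fallen to 1%.
Performance per grouping (sample size x event fraction x method) is
summarised as MAPE, MAE, bias, CI coverage and the proportion of failed
(non-estimable) replications.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time

from .scenarios import Population

__all__ = ["Estimands", "km_restricted_mean", "compute_estimands",
           "performance_metrics"]

OUTCOMES = ("PF", "PD", "OS")


@dataclass(frozen=True)
class Estimands:
    scenario_id: int
    pf: float
    pd: float
    os: float
    horizon: float

    def outcome(self, name: str) -> float:
        return {"PF": self.pf, "PD": self.pd, "OS": self.os}[name]


def km_restricted_mean(times, events, horizon: float) -> float:
    """Area under the Kaplan–Meier step function on [0, horizon]."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty input")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    return float(restricted_mean_survival_time(kmf, t=horizon))


def compute_estimands(population: Population, tail_fraction: float = 0.01
                      ) -> Estimands:
    """Restricted-mean estimands from a complete population.

    The horizon is the first OS time at which Kaplan–Meier survival drops
    to ``tail_fraction`` (1% by default), rounded up to a whole year; if
    the tail is never reached the maximum observed time is used.
    """
    df = population.df
    os_times = df["death_time"].to_numpy(dtype=float)
    finite = np.isfinite(os_times)
    os_times = os_times[finite]
    kmf = KaplanMeierFitter()
    kmf.fit(os_times, event_observed=np.ones_like(os_times))
    sf = kmf.survival_function_.iloc[:, 0]
    below = sf[sf.values <= tail_fraction]
    if len(below):
        horizon = float(math.ceil(below.index[0]))
    else:
        horizon = float(os_times.max())
    pfs_times = np.fmin(df["prog_time"].to_numpy(dtype=float),
                        df["death_time"].to_numpy(dtype=float))[finite]
    os_mean = km_restricted_mean(os_times, np.ones_like(os_times), horizon)
    pf_mean = km_restricted_mean(pfs_times, np.ones_like(pfs_times), horizon)
    return Estimands(population.scenario_id, pf=pf_mean, pd=os_mean - pf_mean,
                     os=os_mean, horizon=horizon)


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Flatten ModelEstimate objects into a long DataFrame (one row per outcome)."""
    rows = []
    for est in estimates:
        base = {"method": est.method, "failed": est.failed, **est.labels}
        if est.failed:
            for oc in OUTCOMES:
                rows.append({**base, "outcome": oc, "estimate": np.nan,
                             "ci_lo": np.nan, "ci_hi": np.nan})
        else:
            for oc in OUTCOMES:
                lo, hi = est.ci.get(oc, (np.nan, np.nan))
                rows.append({**base, "outcome": oc, "estimate": est.outcome(oc),
                             "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def performance_metrics(estimates: pd.DataFrame, estimands: Estimands,
                        nsim: int | None = None,
                        group_cols: tuple[str, ...] = ("method", "n_obs", "pe"),
                        ) -> pd.DataFrame:
    """Per-grouping error and coverage metrics.

    ``estimates`` is the long frame from :func:`estimates_to_frame` (or a
    compatible CSV).  Failed replications are excluded from the error
    metrics and reported as a separate ``failure_prop`` (denominator:
    ``nsim``, defaulting to the number of replications present).
    """
    recs = []
    for keys, grp in estimates.groupby(list(group_cols), dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n_total = nsim if nsim is not None else grp["replication"].nunique() \
            if "replication" in grp else len(grp) // len(OUTCOMES)
        for oc in OUTCOMES:
            sub = grp[grp["outcome"] == oc]
            ok = sub[~sub["failed"].astype(bool)]
            truth = estimands.outcome(oc)
            rec = dict(zip(group_cols, keys))
            rec.update({"outcome": oc,
                        "n_effective": len(ok),
                        "failure_prop": 1.0 - len(ok) / max(n_total, 1)})
            if len(ok):
                err = ok["estimate"].to_numpy(dtype=float) - truth
                rec.update({
                    "mape": 100.0 * float(np.mean(np.abs(err))) / truth,
                    "mae": float(np.mean(np.abs(err))),
                    "bias": float(np.mean(err)),
                    "coverage": float(np.mean((ok["ci_lo"] <= truth)
                                              & (truth <= ok["ci_hi"]))),
                })
            else:
                rec.update({"mape": np.nan, "mae": np.nan, "bias": np.nan,
                            "coverage": np.nan, "failure_prop": 1.0})
            recs.append(rec)
    return pd.DataFrame(recs)
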