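"""Partitioned survival model (PSM) engine.

State occupancy is read directly off two independently fitted curves:
PF = S_PFS(t), PD = S_OS(t) - S_PFS(t), dead = 1 - S_OS(t), on a monthly
cycle grid.  OS can be the naive parametric fit or the additive-hazards
composition S(t) = S*(t) * R(t) with S* from a background Gompertz law at
a fixed starting age and R(t) the fitted relative (excess-hazard)
survival.  Where the extrapolated curves cross, PFS is capped at OS so PD
occupancy stays non-negative.  Mean years per state are trapezoid areas
under the occupancy curves; probabilistic (PSA) uncertainty comes from
multivariate-normal parameter draws for each fitted component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import distributions as dist
from .fitting import FitResult, draw_parameters
from .mortality import MortalityLaw, cumulative_hazard as law_cumhaz

__all__ = ["ModelEstimate", "psm_occupancy", "integrate_means", "run_psm"]

MONTHLY = 1.0 / 12.0


@dataclass
class ModelEstimate:
    """Mean years per state with percentile CIs over PSA iterations."""

    method: str
    pf: float | None = None
    pd: float | None = None
    os: float | None = None
    ci: dict = field(default_factory=dict)   # outcome -> (lo, hi)
    n_psa: int = 0
    failed: bool = False
    reason: str = ""
    labels: dict = field(default_factory=dict)
    base_case: dict = field(default_factory=dict)

    def outcome(self, name: str) -> float | None:
        return {"PF": self.pf, "PD": self.pd, "OS": self.os}[name]


def _grid(horizon: float, cycle: float) -> np.ndarray:
    n = int(np.ceil(horizon / cycle))
    return np.linspace(0.0, n * cycle, n + 1)


def _os_survival(os_model, t: np.ndarray) -> np.ndarray:
    """S_OS on the grid: naive parametric, or S*(t)*R(t) in excess mode."""
    family, params, mode, background, age0 = os_model
    R = dist.survival(family, params, t)
    if mode == "naive":
        return R
    H_star = np.asarray(law_cumhaz(background, age0, t), dtype=float)
    return np.exp(-H_star) * R


def psm_occupancy(pfs_model, os_model, horizon: float, cycle: float = MONTHLY
                  ) -> dict[str, np.ndarray]:
    """Occupancy curves on the cycle grid.

    ``pfs_model`` is ``(family, params)``; ``os_model`` is
    ``(family, params, mode, background_law_or_None, age0_or_None)``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t = _grid(horizon, cycle)
    s_pfs = dist.survival(pfs_model[0], pfs_model[1], t)
    s_os = _os_survival(os_model, t)
    if not (np.all(np.isfinite(s_pfs)) and np.all(np.isfinite(s_os))):
        raise FloatingPointError("non-finite survival values in occupancy grid")
    s_pfs = np.minimum(s_pfs, s_os)   # curve-crossing correction: PFS <= OS
    return {"t": t, "pf": s_pfs, "pd": s_os - s_pfs, "dead": 1.0 - s_os,
            "s_pfs": s_pfs, "s_os": s_os}


def integrate_means(occupancy: dict[str, np.ndarray], cycle: float = MONTHLY
                    ) -> tuple[float, float, float]:
    """Trapezoid areas under PF and PD occupancy; OS = PF + PD."""
    t = occupancy["t"]
    pf = float(np.trapezoid(occupancy["pf"], t))
    pd_ = float(np.trapezoid(occupancy["pd"], t))
    return pf, pd_, pf + pd_


def run_psm(pfs_fit: FitResult, os_fit: FitResult, horizon: float,
            background: MortalityLaw | None = None, age0: float = 60.0,
            n_psa: int = 1000, cycle: float = MONTHLY, seed=0,
            method_label: str | None = None, labels: dict | None = None
            ) -> ModelEstimate:
    """Probabilistic PSM run: point = PSA mean, CI = 2.5/97.5 percentiles.

    ``os_fit.mode`` decides between the naive PSM and PSM-with-GPM; in the
    latter case ``background`` defaults to the law stored on the fit.
    Parameter draws for the PFS and OS components use independent streams.
    """
    mode = os_fit.mode
    method = method_label or ("psm_gpm" if mode == "excess" else "psm_naive")
    est = ModelEstimate(method=method, n_psa=n_psa, labels=dict(labels or {}))
    if not (pfs_fit and os_fit and pfs_fit.converged and os_fit.converged):
        est.failed = True
        est.reason = "component fit not converged"
        return est
    bg = background if background is not None else os_fit.background

    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    seed_pfs, seed_os = ss.spawn(2)
    pfs_draws = draw_parameters(pfs_fit, n_psa, seed_pfs)
    os_draws = draw_parameters(os_fit, n_psa, seed_os)

    base_occ = psm_occupancy(
        (pfs_fit.family, pfs_fit.params),
        (os_fit.family, os_fit.params, mode, bg, age0),
        horizon, cycle)
    est.base_case = dict(zip(("PF", "PD", "OS"), integrate_means(base_occ, cycle)))

    sims = np.empty((n_psa, 3))
    for i in range(n_psa):
        p_pfs = {k: v[i] for k, v in pfs_draws.items()}
        p_os = {k: v[i] for k, v in os_draws.items()}
        try:
            occ = psm_occupancy((pfs_fit.family, p_pfs),
                                (os_fit.family, p_os, mode, bg, age0),
                                horizon, cycle)
            sims[i] = integrate_means(occ, cycle)
        except FloatingPointError:
            sims[i] = np.nan
    ok = np.all(np.isfinite(sims), axis=1)
    if not ok.any():
        est.failed = True
        est.reason = "all PSA iterations invalid"
        return est
    sims = sims[ok]
    est.pf, est.pd, est.os = (float(x) for x in sims.mean(axis=0))
    lo, hi = np.percentile(sims, [2.5, 97.5], axis=0)
    est.ci = {"PF": (float(lo[0]), float(hi[0])),
              "PD": (float(lo[1]), float(hi[1])),
              "OS": (float(lo[2]), float(hi[2]))}
    return est
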