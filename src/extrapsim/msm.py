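"""Semi-Markov multistate decision model run by discrete event simulation.

The transition structure has states PF (progression-free), PD (progressed
disease) and death.  Each PF-exit and PD-exit transition carries its own
hazard source — a fitted parametric distribution (naive or excess) with a
state-entry clock, or the background mortality law with an age clock —
and competing events are resolved "first event wins": one event time is
sampled per transition from its cause-specific distribution and the
minimum determines the trajectory, which reproduces the additive total
hazard.

Variants:

* ``msm_gpm`` (5 transitions): PF->PD fitted; PF->death background +
  fitted excess; PD->death background + fitted excess.  If the PF->death
  excess component could not be estimated the model degrades to a
  4-transition fallback without it.
* ``msm_partly_naive`` (4 transitions): PF->death is a single naively
  fitted hazard (no background from PF); PD->death keeps background +
  excess.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import distributions as dist
from .fitting import FitResult, draw_parameters
from .mortality import MortalityLaw, sample_death_time
from .psm import ModelEstimate

__all__ = ["Transition", "TransitionMatrix", "ModelFailure",
           "build_transition_matrix", "simulate_sojourns", "run_msm"]


class ModelFailure(RuntimeError):
    """A required transition hazard could not be estimated."""


@dataclass
class Transition:
    from_state: str             # 'PF' | 'PD'
    to_state: str               # 'PD' | 'death'
    source: str                 # 'fitted' | 'background'
    clock: str                  # 'state-entry' | 'age'
    fit: FitResult | None = None
    law: MortalityLaw | None = None

    def describe(self) -> dict:
        return {"from": self.from_state, "to": self.to_state,
                "source": self.source, "clock": self.clock,
                "family": self.fit.family if self.fit else None,
                "mode": self.fit.mode if self.fit else None}


@dataclass
class TransitionMatrix:
    variant: str                # msm_gpm_5 | msm_gpm_4_fallback | partly_naive_4
    transitions: list[Transition]

    def pf_exits(self) -> list[Transition]:
        return [tr for tr in self.transitions if tr.from_state == "PF"]

    def pd_exits(self) -> list[Transition]:
        return [tr for tr in self.transitions if tr.from_state == "PD"]

    def to_json(self) -> str:
        return json.dumps({"variant": self.variant,
                           "transitions": [tr.describe() for tr in self.transitions]},
                          indent=2)


def _ok(fit: FitResult | None) -> bool:
    return fit is not None and fit.converged


def build_transition_matrix(
    pf_pd_fit: FitResult,
    pd_death_excess_fit: FitResult,
    background: MortalityLaw,
    variant: str = "msm_gpm",
    pf_death_excess_fit: FitResult | None = None,
    pf_death_naive_fit: FitResult | None = None,
) -> TransitionMatrix:
    """Assemble the requested transition matrix from fitted components.

    Raises :class:`ModelFailure` when a required component (PF->PD,
    PD->death excess, or — for the partly naive variant — the naive
    PF->death fit) is missing; a missing PF->death excess component under
    ``msm_gpm`` triggers the documented 4-transition fallback instead.
    """
    if not _ok(pf_pd_fit):
        raise ModelFailure("PF->PD hazard not estimable")
    if not _ok(pd_death_excess_fit):
        raise ModelFailure("PD->death excess hazard not estimable")
    prog = Transition("PF", "PD", "fitted", "state-entry", fit=pf_pd_fit)
    pd_bg = Transition("PD", "death", "background", "age", law=background)
    pd_ex = Transition("PD", "death", "fitted", "state-entry", fit=pd_death_excess_fit)

    if variant == "msm_gpm":
        pf_bg = Transition("PF", "death", "background", "age", law=background)
        if _ok(pf_death_excess_fit):
            pf_ex = Transition("PF", "death", "fitted", "state-entry",
                               fit=pf_death_excess_fit)
            return TransitionMatrix("msm_gpm_5", [prog, pf_bg, pf_ex, pd_bg, pd_ex])
        return TransitionMatrix("msm_gpm_4_fallback", [prog, pf_bg, pd_bg, pd_ex])
    if variant == "msm_partly_naive":
        if not _ok(pf_death_naive_fit):
            raise ModelFailure("naive PF->death hazard not estimable")
        pf_naive = Transition("PF", "death", "fitted", "state-entry",
                              fit=pf_death_naive_fit)
        return TransitionMatrix("partly_naive_4", [prog, pf_naive, pd_bg, pd_ex])
    raise ValueError(f"unknown variant {variant!r}")


def _sample_transition(tr: Transition, n: int, rng, age_at_entry,
                       params_override: dict | None = None) -> np.ndarray:
    u = rng.uniform(1e-15, 1.0, size=n)
    if tr.source == "background":
        return np.asarray(sample_death_time(tr.law, age_at_entry, u))
    params = params_override if params_override is not None else tr.fit.params
    return np.asarray(dist.inverse_survival(tr.fit.family, params, u))


def simulate_sojourns(matrix: TransitionMatrix, horizon: float,
                      n_individuals: int = 10_000, age0: float = 60.0,
                      seed=0, overrides: dict[int, dict] | None = None
                      ) -> tuple[float, float, float]:
    """First-event-wins DES over ``n_individuals``; returns mean (PF, PD, OS).

    All individuals start in PF at age ``age0``; state-entry clocks reset
    on transition and the background clock advances with model time
    (PD entry age = ``age0`` + time to progression).  Sojourns are
    truncated at ``horizon``.  ``overrides`` maps transition index ->
    parameter dict (used by PSA draws).
    """
    rng = np.random.default_rng(seed)
    n = int(n_individuals)
    overrides = overrides or {}
    if horizon <= 0:
        return 0.0, 0.0, 0.0

    pf_exits = matrix.pf_exits()
    times = np.empty((len(pf_exits), n))
    for j, tr in enumerate(pf_exits):
        times[j] = _sample_transition(
            tr, n, rng, age0, overrides.get(id(tr)))
    first = np.argmin(times, axis=0)
    t_exit = times[first, np.arange(n)]
    to_pd = np.array([tr.to_state == "PD" for tr in pf_exits])[first]
    progressed = to_pd & (t_exit < horizon)

    pf_time = np.minimum(t_exit, horizon)
    pd_time = np.zeros(n)

    idx = np.flatnonzero(progressed)
    if idx.size:
        u_entry = t_exit[idx]
        pd_candidates = []
        for tr in matrix.pd_exits():
            age_entry = age0 + u_entry if tr.source == "background" else None
            pd_candidates.append(_sample_transition(
                tr, idx.size, rng, age_entry, overrides.get(id(tr))))
        sojourn = np.min(np.vstack(pd_candidates), axis=0)
        pd_time[idx] = np.clip(np.minimum(u_entry + sojourn, horizon) - u_entry,
                               0.0, None)
    os_time = pf_time + pd_time
    return float(pf_time.mean()), float(pd_time.mean()), float(os_time.mean())


def run_msm(matrix: TransitionMatrix, horizon: float,
            n_individuals: int = 10_000, n_psa: int = 1000, age0: float = 60.0,
            seed=0, labels: dict | None = None) -> ModelEstimate:
    """Probabilistic MSM run.

    Per PSA iteration the parameters of every fitted transition are drawn
    from their estimation-scale multivariate normals (independent streams
    per transition), and a fresh first-order DES stream simulates the
    sojourns.  Point estimates are PSA means; CIs are 2.5/97.5 percentiles.
    """
    method = "msm_partly_naive" if matrix.variant == "partly_naive_4" else "msm_gpm"
    est = ModelEstimate(method=method, n_psa=n_psa, labels=dict(labels or {}))
    est.labels.setdefault("variant", matrix.variant)

    fitted = [tr for tr in matrix.transitions if tr.source == "fitted"]
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    param_seeds = ss.spawn(len(fitted))
    des_seeds = ss.spawn(1)[0].spawn(n_psa)
    draws = {id(tr): draw_parameters(tr.fit, n_psa, s)
             for tr, s in zip(fitted, param_seeds)}

    est.base_case = dict(zip(
        ("PF", "PD", "OS"),
        simulate_sojourns(matrix, horizon, n_individuals, age0, seed=ss.spawn(1)[0])))

    sims = np.empty((n_psa, 3))
    for i in range(n_psa):
        overrides = {key: {k: v[i] for k, v in d.items()} for key, d in draws.items()}
        sims[i] = simulate_sojourns(matrix, horizon, n_individuals, age0,
                                    seed=des_seeds[i], overrides=overrides)
    est.pf, est.pd, est.os = (float(x) for x in sims.mean(axis=0))
    lo, hi = np.percentile(sims, [2.5, 97.5], axis=0)
    est.ci = {"PF": (float(lo[0]), float(hi[0])),
              "PD": (float(lo[1]), float(hi[1])),
              "OS": (float(lo[2]), float(hi[2]))}
    return est
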