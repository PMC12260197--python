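"""End-to-end study orchestration.

Ties the stages together — population generation, replicated trial
sampling, event-fraction censoring, six-family parametric fitting, PSM and
MSM engines, and performance summarisation — under a single master seed,
with per-(scenario, replication, grouping, stage) child seeds derived
through ``numpy`` seed sequences so any failing dataset can be replayed in
isolation.  Results are plain CSV/JSON; interrupted runs resume from the
per-replication checkpoint file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from .evaluate import compute_estimands, estimates_to_frame, performance_metrics
from .fitting import SelectionFailure, fit_all_families, select_best
from .mortality import MortalityLaw, fixture_law
from .msm import ModelFailure, build_transition_matrix, run_msm
from .psm import ModelEstimate, run_psm
from .scenarios import make_scenario, simulate_population
from .trials import StudyDesign, TrialDataset, censor_at_event_fraction, \
    dataset_census, draw_replication

__all__ = ["StudyConfig", "analyze_dataset", "run_study"]

ALL_METHODS = ("psm_naive", "psm_gpm", "msm_gpm", "msm_partly_naive")


@dataclass
class StudyConfig:
    scenarios: tuple[int, ...] = (1,)
    population_size: int = 50_000
    nsim: int = 1000
    nobs: tuple[int, ...] = (30, 60, 90, 120, 250, 500)
    pe: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    methods: tuple[str, ...] = ALL_METHODS
    n_psa: int = 1000
    n_des_individuals: int = 10_000
    analysis_age0: float = 60.0
    criterion: str = "aicc"        # 'aicc' | 'bic'
    generation_law: str = "generation"   # fixture name or path to a law JSON
    analysis_law: str = "analysis"
    seed: int = 0
    out_dir: str = "results"
    workers: int = 1

    def __post_init__(self):
        if any(m not in ALL_METHODS for m in self.methods):
            raise ValueError(f"methods must be a subset of {ALL_METHODS}")
        for v in (self.population_size, self.nsim, self.n_psa,
                  self.n_des_individuals):
            if v <= 0:
                raise ValueError("all counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("scenarios", "nobs", "pe", "methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir"); d.pop("workers")
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


def _resolve_law(name: str) -> MortalityLaw:
    if name in ("generation", "analysis", "zero"):
        return fixture_law(name)
    return MortalityLaw.from_json(Path(name))


def _best_or_none(times, events, mode="naive", background=None, age0=None,
                  criterion="aicc"):
    fits = fit_all_families(times, events, mode=mode, background=background,
                            age0=age0, criterion=criterion)
    try:
        return select_best(fits)
    except SelectionFailure:
        return None


def _failed(method, labels, reason):
    return ModelEstimate(method=method, failed=True, reason=reason,
                         labels=dict(labels))


def analyze_dataset(dataset: TrialDataset, methods, analysis_law: MortalityLaw,
                    horizon: float, n_psa: int, n_des: int, seed,
                    age0: float = 60.0, criterion: str = "aicc"
                    ) -> list[ModelEstimate]:
    """Fit every transition the requested methods need and run the engines.

    Fits are shared across methods (e.g. the PFS fit feeds both PSM
    variants).  A method whose required components cannot be estimated
    yields a failed :class:`ModelEstimate` rather than an exception.
    """
    df = dataset.df
    labels = dict(dataset.labels)
    labels.setdefault("pe", dataset.pe)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    stage_seeds = iter(ss.spawn(8))
    out: list[ModelEstimate] = []

    pfs_t = df["pfs_time"].to_numpy(float)
    pfs_e = df["pfs_event"].to_numpy(bool)
    os_t = df["os_time"].to_numpy(float)
    os_e = df["os_event"].to_numpy(bool)

    want_psm = [m for m in methods if m.startswith("psm")]
    want_msm = [m for m in methods if m.startswith("msm")]

    if want_psm:
        pfs_best = _best_or_none(pfs_t, pfs_e, criterion=criterion)
        for method in want_psm:
            sd = next(stage_seeds)
            if method == "psm_naive":
                os_best = _best_or_none(os_t, os_e, criterion=criterion)
            else:
                os_best = _best_or_none(os_t, os_e, mode="excess",
                                        background=analysis_law, age0=age0,
                                        criterion=criterion)
            if pfs_best is None or os_best is None:
                out.append(_failed(method, labels, "all families failed"))
                continue
            out.append(run_psm(pfs_best, os_best, horizon,
                               background=analysis_law, age0=age0,
                               n_psa=n_psa, seed=sd,
                               method_label=method, labels=labels))

    if want_msm:
        prog_e = df["progression_observed"].to_numpy(bool)
        pf_death_e = df["pf_death_event"].to_numpy(bool)
        mask_pd = prog_e
        pd_t = df.loc[mask_pd, "pd_exit_time"].to_numpy(float)
        pd_e = df.loc[mask_pd, "pd_event"].to_numpy(bool)
        pd_age0 = age0 + df.loc[mask_pd, "pd_entry_time"].to_numpy(float)

        pf_pd_best = _best_or_none(pfs_t, prog_e, criterion=criterion)
        pd_death_best = (
            _best_or_none(pd_t, pd_e, mode="excess", background=analysis_law,
                          age0=pd_age0, criterion=criterion)
            if mask_pd.any() else None)
        for method in want_msm:
            sd = next(stage_seeds)
            if method == "msm_gpm":
                pf_death_excess = _best_or_none(
                    pfs_t, pf_death_e, mode="excess", background=analysis_law,
                    age0=age0, criterion=criterion)
                kwargs = {"variant": "msm_gpm",
                          "pf_death_excess_fit": pf_death_excess}
            else:
                pf_death_naive = _best_or_none(pfs_t, pf_death_e,
                                               criterion=criterion)
                kwargs = {"variant": "msm_partly_naive",
                          "pf_death_naive_fit": pf_death_naive}
            try:
                if pf_pd_best is None or pd_death_best is None:
                    raise ModelFailure("required transition not estimable")
                matrix = build_transition_matrix(
                    pf_pd_best, pd_death_best, analysis_law, **kwargs)
            except ModelFailure as exc:
                out.append(_failed(method, labels, str(exc)))
                continue
            out.append(run_msm(matrix, horizon, n_individuals=n_des,
                               n_psa=n_psa, age0=age0, seed=sd, labels=labels))
    return out


def _replication_rows(population, design, config, analysis_law, horizon, r):
    rows = []
    cohorts = draw_replication(population, design, r)
    for n_obs, cohort in zip(design.nobs, cohorts):
        for j, pe in enumerate(design.pe):
            labels = {"scenario": population.scenario_id, "replication": r,
                      "n_obs": n_obs, "pe": pe}
            dataset = censor_at_event_fraction(cohort, pe, labels=labels)
            seed = np.random.SeedSequence(
                (config.seed, population.scenario_id, r, n_obs, j))
            ests = analyze_dataset(dataset, config.methods, analysis_law,
                                   horizon, config.n_psa,
                                   config.n_des_individuals, seed,
                                   age0=config.analysis_age0,
                                   criterion=config.criterion)
            rows.append(estimates_to_frame(ests))
    return pd.concat(rows, ignore_index=True)


def run_study(config: StudyConfig) -> Path:
    """Run the configured study; returns the output directory.

    Writes per scenario: ``estimands_<s>.json``, checkpointed
    ``estimates_<s>.csv`` (one row per replication x grouping x method x
    outcome) and ``performance_<s>.csv``; plus a ``manifest.json`` with
    the config, its hash and the master seed.  A rerun with the same
    config and output directory resumes after the last completed
    replication.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    chash = config.config_hash()
    manifest = {"config": asdict(config), "config_hash": chash,
                "census_per_scenario": dataset_census(
                    StudyDesign(config.nsim, config.nobs, config.pe, config.seed))}
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    gen_law = _resolve_law(config.generation_law)
    analysis_law = _resolve_law(config.analysis_law)
    design = StudyDesign(config.nsim, config.nobs, config.pe, config.seed)

    for s in config.scenarios:
        spec = make_scenario(s)
        pop_seed = np.random.SeedSequence((config.seed, s, 7))
        population = simulate_population(spec, gen_law,
                                         n=config.population_size, seed=pop_seed)
        estimands = compute_estimands(population)
        (out / f"estimands_{s}.json").write_text(json.dumps({
            "scenario": s, "pf": estimands.pf, "pd": estimands.pd,
            "os": estimands.os, "horizon": estimands.horizon}, indent=2))

        est_path = out / f"estimates_{s}.csv"
        done: set[int] = set()
        if est_path.exists():
            prev = pd.read_csv(est_path)
            done = set(prev["replication"].unique())
        todo = [r for r in range(config.nsim) if r not in done]

        if config.workers > 1:
            frames = Parallel(n_jobs=config.workers)(
                delayed(_replication_rows)(population, design, config,
                                           analysis_law, estimands.horizon, r)
                for r in todo)
            for frame in frames:
                frame.to_csv(est_path, mode="a", index=False,
                             header=not est_path.exists())
        else:
            for r in todo:
                frame = _replication_rows(population, design, config,
                                          analysis_law, estimands.horizon, r)
                frame.to_csv(est_path, mode="a", index=False,
                             header=not est_path.exists())

        all_est = pd.read_csv(est_path)
        perf = performance_metrics(all_est, estimands, nsim=config.nsim)
        perf.insert(0, "scenario", s)
        perf.to_csv(out / f"performance_{s}.csv", index=False)
    return out
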