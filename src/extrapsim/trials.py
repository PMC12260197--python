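"""Trial cohorts and event-driven administrative censoring.

Replicated cohorts of six sample sizes are drawn from a simulated
population; each cohort is then artificially truncated at the calendar
(study-clock) time when a chosen fraction of subjects has had a PFS event
(first of progression or death), mimicking the event-count data cutoffs
used in oncology trials.  The censored dataset carries both the
endpoint-level views needed by a partitioned survival analysis (PFS, OS)
and the transition-level records needed by a multistate analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from .scenarios import Population

__all__ = ["StudyDesign", "TrialDataset", "draw_replication",
           "censor_at_event_fraction", "dataset_census"]

DEFAULT_NOBS = (30, 60, 90, 120, 250, 500)
DEFAULT_PE = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass(frozen=True)
class StudyDesign:
    """Replication plan: sample sizes, event-fraction cutoffs, seeding."""

    nsim: int = 1000
    nobs: tuple[int, ...] = DEFAULT_NOBS
    pe: tuple[float, ...] = DEFAULT_PE
    seed: int = 0

    def __post_init__(self):
        if self.nsim <= 0 or any(n <= 0 for n in self.nobs):
            raise ValueError("counts must be positive")
        if any(not (0 < p <= 1) for p in self.pe):
            raise ValueError("event fractions must lie in (0, 1]")

    @property
    def total_per_replication(self) -> int:
        return sum(self.nobs)


@dataclass
class TrialDataset:
    """One censored sample dataset.

    ``df`` columns: pfs_time, pfs_event, os_time, os_event,
    progression_observed, pf_death_event, pd_entry_time, pd_exit_time,
    pd_event (PD columns NaN for subjects without observed progression).
    """

    df: pd.DataFrame
    cutoff: float               # calendar study time of the data cut
    pe: float
    n_requested: int
    n_dropped: int              # enrolled after the cutoff, excluded
    labels: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        header = (f"# pe={self.pe} cutoff={self.cutoff:.6f} "
                  f"dropped={self.n_dropped} labels={self.labels}\n")
        with open(path, "w") as fh:
            fh.write(header)
            self.df.to_csv(fh, index=False)


def draw_replication(population: Population, design: StudyDesign, r: int
                     ) -> list[pd.DataFrame]:
    """Draw one replication: disjoint cohorts of sizes ``design.nobs``.

    Within a replication the ``sum(nobs)`` subjects are drawn without
    replacement; across replications draws are independent (sampling with
    replacement at the replication level).  Seeded by ``(design.seed, r)``.
    """
    total = design.total_per_replication
    if len(population) < total:
        raise ValueError(f"population of {len(population)} cannot supply {total} subjects")
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, r)))
    chosen = rng.choice(len(population), size=total, replace=False)
    cohorts, start = [], 0
    for n in design.nobs:
        idx = chosen[start:start + n]
        cohorts.append(population.df.iloc[idx].reset_index(drop=True))
        start += n
    return cohorts


def censor_at_event_fraction(cohort: pd.DataFrame, pe: float,
                             labels: dict | None = None) -> TrialDataset:
    """Censor a complete-history cohort at an event-count data cutoff.

    The cutoff is the calendar time of the ``ceil(pe * n)``-th PFS event
    (enrollment time + subject-clock PFS time).  Every subject's follow-up
    is ``cutoff - enroll_time``; events beyond follow-up are censored at
    the follow-up time, and subjects enrolled after the cutoff are dropped
    (their count is recorded in ``n_dropped``).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if not (0 < pe <= 1):
        raise ValueError("pe must lie in (0, 1]")
    n = len(cohort)
    prog = cohort["prog_time"].to_numpy(dtype=float)
    death = cohort["death_time"].to_numpy(dtype=float)
    enroll = cohort["enroll_time"].to_numpy(dtype=float)
    pfs_true = np.fmin(prog, death)             # NaN-aware min
    calendar_pfs = enroll + pfs_true
    k = ceil(pe * n)
    cutoff = float(np.sort(calendar_pfs)[k - 1])

    follow = cutoff - enroll
    keep = follow > 0
    n_dropped = int(np.sum(~keep))
    prog, death, follow = prog[keep], death[keep], follow[keep]
    pfs_true = pfs_true[keep]

    pfs_event = pfs_true <= follow
    pfs_time = np.minimum(pfs_true, follow)
    os_event = death <= follow
    os_time = np.minimum(death, follow)
    progression_observed = (~np.isnan(prog)) & (prog <= follow)
    pf_death_event = pfs_event & ~progression_observed

    pd_entry = np.where(progression_observed, prog, np.nan)
    pd_exit = np.where(progression_observed, np.minimum(death, follow) - prog, np.nan)
    pd_event = np.where(progression_observed, os_event, False).astype(bool)

    df = pd.DataFrame({
        "pfs_time": pfs_time, "pfs_event": pfs_event,
        "os_time": os_time, "os_event": os_event,
        "progression_observed": progression_observed,
        "pf_death_event": pf_death_event,
        "pd_entry_time": pd_entry, "pd_exit_time": pd_exit, "pd_event": pd_event,
    })
    return TrialDataset(df, cutoff=cutoff, pe=pe, n_requested=n,
                        n_dropped=n_dropped, labels=dict(labels or {}))


def dataset_census(design: StudyDesign) -> int:
    """Number of sample datasets one scenario run analyses."""
    return len(design.nobs) * len(design.pe) * design.nsim
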