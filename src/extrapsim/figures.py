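"""Summary figure panels: failure proportions and MAPE grids.

One panel per method; sample size on the x axis, one line per
event-fraction cutoff.  Mirrors the usual way simulation-study
performance surfaces are displayed.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_failure_panels", "plot_mape_panels", "make_figures"]


def _panel_grid(perf: pd.DataFrame, value: str, out_path: Path,
                outcome: str = "OS", ylabel: str = "") -> Path:
    sub = perf[perf["outcome"] == outcome]
    methods = sorted(sub["method"].unique())
    fig, axes = plt.subplots(1, max(len(methods), 1),
                             figsize=(3.2 * max(len(methods), 1), 3.2),
                             sharey=True, squeeze=False)
    for ax, method in zip(axes[0], methods):
        m = sub[sub["method"] == method]
        for pe, grp in m.groupby("pe"):
            grp = grp.sort_values("n_obs")
            ax.plot(grp["n_obs"], grp[value], marker="o", ms=3,
                    label=f"pe={pe:g}")
        ax.set_title(method, fontsize=9)
        ax.set_xlabel("sample size")
    axes[0, 0].set_ylabel(ylabel or value)
    handles, lab = axes[0, 0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, lab, loc="center right", fontsize=7)
    fig.tight_layout(rect=(0, 0, 0.88, 1))
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_failure_panels(perf: pd.DataFrame, out_path: str | Path) -> Path:
    return _panel_grid(perf, "failure_prop", Path(out_path),
                       ylabel="proportion of replications failed")


def plot_mape_panels(perf: pd.DataFrame, out_path: str | Path,
                     outcome: str = "OS") -> Path:
    return _panel_grid(perf, "mape", Path(out_path), outcome=outcome,
                       ylabel=f"MAPE (%) — {outcome}")


def make_figures(performance_csv: str | Path, out_dir: str | Path) -> list[Path]:
    """Produce the failure-proportion and MAPE panels from a performance CSV."""
    perf = pd.read_csv(performance_csv)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = Path(performance_csv).stem
    paths = [plot_failure_panels(perf, out / f"{stem}_failures.png")]
    for oc in ("PF", "PD", "OS"):
        paths.append(plot_mape_panels(perf, out / f"{stem}_mape_{oc}.png", oc))
    return paths
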