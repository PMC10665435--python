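#!/usr/bin/env python
"""Fit the piecewise exponential models to every reconstructed trace.

Reads results/cohort_traces.csv, fits both model variants per cell with
automatic variant selection, and writes one row per track to
results/cohort_fits.csv (variant, k_on, t_on, R_eq, k_off, t_off, fit
diagnostics, generator cell id).  If matplotlib is available, an ensemble
plot of the normalized traces per archetype goes to results/figures/.

Run after 02:  python analysis/03_fit_kinetics.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ktr.kinetics import fit_trace

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    traces = pd.read_csv(RESULTS / "cohort_traces.csv")
    traces["excluded"] = traces["excluded"].fillna("")
    rows = []
    for tid, sub in traces.groupby("track_id"):
        if sub["excluded"].iloc[0] != "":
            continue
        t = sub["time_s"].to_numpy()
        y = sub["cn_norm"].to_numpy()
        chosen, fit, _, _ = fit_trace((t, y), "auto")
        row = {
            "track_id": int(tid),
            "cell": int(sub["cell"].iloc[0]),
            "variant": chosen,
            "converged": fit.converged,
            "sse": fit.sse,
            "rmse": fit.rmse,
            "n_points": fit.n_points,
        }
        if fit.converged:
            row.update(
                k_on=fit.params.k_on,
                t_on=fit.params.t_on,
                R_eq=fit.params.R_eq,
                k_off=fit.params.k_off,
                t_off=fit.params.t_off,
            )
        rows.append(row)
    fits = pd.DataFrame(rows)
    fits.to_csv(RESULTS / "cohort_fits.csv", index=False)
    conv = fits[fits["converged"] == True]  # noqa: E712
    print(f"fitted {len(conv)}/{len(fits)} tracks; variants:",
          conv["variant"].value_counts().to_dict())
    print(f"fits -> {RESULTS / 'cohort_fits.csv'}")
    _plot(traces, fits)


def _plot(traces: pd.DataFrame, fits: pd.DataFrame) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    truth = pd.read_csv(RESULTS / "cohort_truth.csv")
    cell_arch = truth.set_index("cell")["archetype"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    for ax, arch in zip(axes, ("young", "mid_old", "old")):
        cells = set(cell_arch[cell_arch == arch].index)
        for tid, sub in traces.groupby("track_id"):
            if int(sub["cell"].iloc[0]) in cells and sub["excluded"].iloc[0] == "":
                ax.plot(sub["time_s"] / 60.0, sub["cn_norm"], lw=0.7, alpha=0.7)
        ax.set_title(arch)
        ax.set_xlabel("time after stimulation (min)")
    axes[0].set_ylabel("normalized C/N")
    fig.tight_layout()
    out = RESULTS / "figures"
    out.mkdir(exist_ok=True)
    fig.savefig(out / "trace_ensembles.png", dpi=150)
    print(f"figure -> {out / 'trace_ensembles.png'}")


if __name__ == "__main__":
    main()
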