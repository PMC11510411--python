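"""Plot helpers for the fitted model's diagnostic and decision tables.

All functions take the plot-ready DataFrames produced elsewhere in the
package and return a matplotlib Axes, so they compose with any figure layout.
"""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_pcvpc(table: pd.DataFrame, ax=None):
    """Prediction-corrected VPC: observed percentiles over simulated bands."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for p, color in zip((5.0, 50.0, 95.0), ("C0", "C3", "C0")):
        sub = table[table.percentile == p].sort_values("t_mid")
        if sub.empty:
            continue
        ax.fill_between(sub.t_mid, sub.sim_lo, sub.sim_hi, alpha=0.25,
                        color=color, lw=0)
        ax.plot(sub.t_mid, sub.observed, "o-", color=color,
                label=f"observed P{p:g}")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("prediction-corrected PASI")
    ax.set_yscale("log")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_exposure_response(records: pd.DataFrame, target: float = 1.0, ax=None):
    """Per-clone PASI against steady-state trough across all tested regimens."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for regimen, grp in records.groupby("regimen"):
        ax.scatter(grp.trough_ss, grp.pasi, s=6, alpha=0.4, label=regimen)
    ax.axhline(target, color="k", ls="--", lw=1)
    ax.set_xlabel("C_trough-ss (mg/L)")
    ax.set_ylabel("absolute PASI (cycle 10)")
    ax.set_xscale("symlog", linthresh=0.01)
    ax.legend(frameon=False, fontsize=7, ncol=2)
    return ax


def plot_individual_fit(patient, pk_individual, pd_params, ax=None, t_max=None):
    """Observed concentrations/PASI with the individual model predictions."""
    from . import pkpd

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    t_max = t_max or max(
        [d.time for d in patient.doses]
        + list(patient.pk_times) + list(patient.pd_times) + [1.0]
    )
    grid = np.arange(0.0, t_max + 0.25, 0.25)
    conc = pkpd.pk_concentration(pk_individual, patient.doses, grid)
    pasi = pkpd.pd_trajectory_grid(
        pd_params.kout, pd_params.pasi0, pkpd.inhibition(conc, pd_params), 0.25
    )
    ax.plot(grid, conc, "C2-", lw=1, label="predicted conc (mg/L)")
    ax.plot(patient.pk_times, patient.pk_conc, "C2o", ms=4, label="observed conc")
    ax2 = ax.twinx()
    ax2.plot(grid, pasi, "C3-", lw=1, label="predicted PASI")
    ax2.plot(patient.pd_times, patient.pd_pasi, "C3s", ms=4, label="observed PASI")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("concentration (mg/L)", color="C2")
    ax2.set_ylabel("PASI", color="C3")
    ax.set_title(patient.patient_id)
    return ax
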