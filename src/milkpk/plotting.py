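"""Simple concentration–time and withdrawal-regression figures."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .data import StudyDataset

__all__ = ["plot_concentrations", "plot_withdrawal"]


def plot_concentrations(dataset: StudyDataset, matrix: str = "plasma",
                        dose: float | None = None, ax=None, logy: bool = True):
    """Semi-logarithmic spaghetti plot of one matrix (optionally one dose)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for p in dataset.select(matrix=matrix, dose=dose):
        t, c = p.quantifiable()
        ax.plot(t, c, "o-", ms=3, lw=0.8, alpha=0.7,
                label=f"{p.subject_id} ({p.dose} mg/kg)")
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (µg/mL)")
    ax.set_title(f"{matrix} concentration–time")
    return ax


def plot_withdrawal(results, mrl: float = 50.0, density: float = 1.0,
                    p: float = 0.95, conf: float = 0.95, ax=None):
    """Data, fitted depletion line, upper tolerance limit and MRL cutoff."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    reg = results.regression
    t = results.model.times
    y = results.model.ln_concs
    mrl_conc = mrl * density / 1000.0
    try:
        wt = results.estimate_wt(mrl, density, p, conf)
        t_hi = max(wt.wt_reported * 1.3, max(t) * 1.2)
    except Exception:
        wt = None
        t_hi = max(t) * 2.0
    grid = np.linspace(0, t_hi, 300)
    ax.plot(t, np.exp(y), "ko", ms=4, label="observations")
    ax.plot(grid, np.exp(reg.predict(grid)), "b-", label="regression")
    ax.plot(grid, np.exp(results.tolerance_limit(grid, p, conf)), "r--",
            label=f"{100*p:g}/{100*conf:g} tolerance limit")
    ax.axhline(mrl_conc, color="grey", ls=":", label=f"MRL {mrl:g} µg/kg")
    if wt is not None:
        ax.axvline(wt.wt_estimate, color="green", ls="-.",
                   label=f"WT {wt.wt_estimate:.2f} h "
                         f"(reported {wt.wt_reported:g} h)")
    ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("milk concentration (µg/mL)")
    ax.legend(fontsize=7)
    return ax
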