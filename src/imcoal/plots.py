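"""Summary plots: estimate vs. number of loci, one line per recombination rate."""

from __future__ import annotations

from typing import Optional

import pandas as pd

__all__ = ["plot_parameter"]


def plot_parameter(
    summary: pd.DataFrame,
    parameter: str,
    truth: Optional[float] = None,
    ax=None,
):
    """Mean estimate against locus count (log x) with standard-error bars.

    ``summary`` is the table produced by :func:`imcoal.experiment.summarize`,
    possibly concatenated across recombination rates; one errorbar line is
    drawn per distinct ``rho`` and the true value, when given, as a horizontal
    reference line.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    sub = summary[summary["parameter"] == parameter]
    if sub.empty:
        raise ValueError(f"no rows for parameter {parameter!r}")
    for rho, cell in sub.groupby("rho"):
        cell = cell.sort_values("n_loci")
        ax.errorbar(
            cell["n_loci"],
            cell["mean"],
            yerr=cell["se"],
            marker="o",
            capsize=3,
            label=f"rho = {rho:g}",
        )
    if truth is not None:
        ax.axhline(truth, color="grey", lw=1, zorder=0)
    ax.set_xscale("log")
    ax.set_xlabel("number of loci")
    ax.set_ylabel(parameter)
    ax.legend(fontsize=8)
    return ax
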