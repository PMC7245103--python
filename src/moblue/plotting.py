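"""Optional matplotlib views of sweep and trajectory artifacts.

Figures are always drawn from the flat data containers (or the CSVs they
serialize to), never from transient simulation state, so every plotted
number is re-derivable.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .analysis import SweepResult, coexistence_curve  # noqa: E402
from .engine import EnsembleResult  # noqa: E402


def plot_sweep(result: SweepResult, log_x: bool = True, ax=None):
    """Time-averaged abundances of the tracked species vs the swept value."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for sid in result.tracked:
        ax.errorbar(
            result.grid, result.series(sid),
            yerr=result.sems[:, result.tracked.index(sid)],
            label=sid, marker="o", ms=3, lw=1,
        )
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel(result.parameter)
    ax.set_ylabel("time-averaged count")
    ax.legend(frameon=False)
    return ax


def plot_coexistence(result: SweepResult, ax=None):
    """Normalized-minimum coexistence score along the sweep."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(result.grid, coexistence_curve(result), marker="o", ms=3)
    ax.set_xscale("log")
    ax.set_xlabel(result.parameter)
    ax.set_ylabel("coexistence score")
    return ax


def plot_growth(ens: EnsembleResult, species=("Mo36", "Mo132", "Mo154"), ax=None):
    """Replicate-mean growth curves."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for sid in species:
        if sid in ens.species_ids:
            ax.plot(ens.grid, ens.mean_series(sid), label=sid)
    ax.set_xlabel("model time")
    ax.set_ylabel("mean count")
    ax.legend(frameon=False)
    return ax
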