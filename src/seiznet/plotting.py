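"""Optional matplotlib views of index time courses and phase densities."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np


def plot_index_time_course(indices, fs: float = 512.0, ax=None):
    """H_in, H_se and normalized H_sb against time in seconds."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    t = np.array([ix.time for ix in indices]) / fs
    ax.plot(t, [ix.H_sb_norm for ix in indices], label="H_sb (norm)", color="tab:blue")
    ax.plot(t, [ix.H_in for ix in indices], label="H_in", color="tab:green", alpha=0.6)
    ax.plot(t, [ix.H_se for ix in indices], label="H_se", color="tab:orange", alpha=0.6)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.legend(loc="best", fontsize="small")
    return ax


def plot_phase_densities(densities: dict, ax=None):
    """Overlay per-interval kernel densities of H_sb."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    for iid, summary in densities.items():
        ax.plot(summary.grid, summary.density, label=iid)
        ax.axvline(summary.peak_x, ls="--", lw=0.5)
    ax.set_xlabel("H_sb (normalized)")
    ax.set_ylabel("density")
    ax.legend(fontsize="x-small")
    return ax


def plot_peak_track(plunge, ax=None):
    """Per-interval KDE peak location with the plunge extremes shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(len(plunge.interval_ids))
    ax.plot(x, plunge.peak_x, "o--", color="tab:blue", label="peak_x")
    lo, hi, _ = plunge.plunge_interval
    ax.axhspan(lo, hi, color="tab:blue", alpha=0.1)
    ax.set_xticks(x, plunge.interval_ids, rotation=45, fontsize="x-small")
    ax.set_ylabel("KDE peak of H_sb")
    ax.legend()
    return ax
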