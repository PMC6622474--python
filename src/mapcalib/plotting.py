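"""Figure helpers: every plot is regenerable from saved logs alone."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_error_course", "plot_crosstalk", "plot_shift_profiles", "plot_grid"]


def plot_error_course(log: pd.DataFrame, out: str | Path, window: int = 100):
    """Per-trial orienting error norm and its trailing mean."""
    fig, ax = plt.subplots(figsize=(6, 4))
    err = log["err"]
    ax.plot(log["trial"], err, lw=0.3, alpha=0.4, label="per-trial")
    ax.plot(log["trial"], err.rolling(window).mean(), lw=1.5,
            label=f"trailing-{window} mean")
    if "err_nobias" in log:
        ax.plot(log["trial"], log["err_nobias"].rolling(window).mean(),
                lw=1.0, ls="--", label="no-bias baseline")
    ax.set_xlabel("target presentation")
    ax.set_ylabel("orienting error (map units)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def plot_crosstalk(crosstalk: pd.DataFrame, out: str | Path):
    """Cross-talk weight RMS over training for both microzone pairs."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for i in (1, 2):
        ax.plot(crosstalk["trial"], crosstalk[f"crosstalk_rms_{i}"],
                label=f"pair {i}")
    ax.set_xlabel("trial")
    ax.set_ylabel("cross-talk weight RMS")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def plot_shift_profiles(profiles, out: str | Path):
    """Learnt receptive-field shift vs position for each sweep velocity."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        ax.plot(p.positions, p.shifts, lw=0.5 + abs(p.velocity),
                label=f"v = {p.velocity:+g} m/s")
    ax.set_xlabel("delayed input position (m)")
    ax.set_ylabel("learnt shift (m)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def plot_grid(calibrator, out: str | Path, n: int = 9, limit: float = 0.75):
    """Distorted vs recalibrated grid overlay for a single-map calibrator."""
    from .experiments import probe_lattice

    targets = probe_lattice(n, limit)
    raw = np.empty_like(targets)
    adj = np.empty_like(targets)
    for i, t in enumerate(targets):
        rec = calibrator.trial(t, rng=None, learn=False)
        raw[i] = rec["x_g"]
        adj[i] = rec["x_a"]
    fig, ax = plt.subplots(figsize=(5, 5))
    for pts, style, label in (
        (targets, "g-", "true grid"),
        (raw, "r-", "distorted"),
        (adj, "c--", "recalibrated"),
    ):
        g = pts.reshape(n, n, 2)
        for row in range(n):
            ax.plot(g[row, :, 0], g[row, :, 1], style, lw=0.8,
                    label=label if row == 0 else None)
            ax.plot(g[:, row, 0], g[:, row, 1], style, lw=0.8)
    ax.set_aspect("equal")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
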