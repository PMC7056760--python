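"""Plotting helpers for the standard evaluation figures: window line
profiles, recovery vs sphere size, and recovery convergence/dilation
curves. All functions take the analysis module's data structures and
return the matplotlib Axes for further styling."""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_line_profiles(profiles: dict[str, np.ndarray], pitch_cm: float,
                       ax=None):
    """Overlay per-window 1-D profiles (counts vs transaxial position)."""
    ax = _ax(ax)
    for label, prof in profiles.items():
        x = (np.arange(prof.size) - prof.size / 2) * pitch_cm
        ax.plot(x, prof, label=label)
    ax.set_xlabel("position (cm)")
    ax.set_ylabel("counts")
    ax.legend()
    return ax


def plot_recovery_vs_diameter(report, ax=None, label=None):
    """Recovery coefficient vs sphere diameter from a VOI report."""
    ax = _ax(ax)
    for dil, grp in report.groupby("dilation_mm"):
        g = grp.sort_values("diameter_mm")
        style = "-o" if dil == 0 else "--s"
        name = label or (f"+{dil:g} mm VOI" if dil else "matched VOI")
        ax.plot(g.diameter_mm, g.rc_percent, style, label=name)
    ax.set_xlabel("sphere diameter (mm)")
    ax.set_ylabel("recovered activity (%)")
    ax.legend()
    return ax


def plot_convergence(curve, sphere_ids=None, ax=None):
    """Recovery vs iteration per sphere from a convergence table."""
    ax = _ax(ax)
    ids = sphere_ids or sorted(curve.sphere_id.unique())
    for sid in ids:
        g = curve[curve.sphere_id == sid].sort_values("iteration")
        ax.plot(g.iteration, g.rc_percent, "-o", label=sid)
    ax.set_xlabel("iteration")
    ax.set_ylabel("recovered activity (%)")
    ax.legend()
    return ax


def plot_dilation_sweep(sweep, sphere_ids=None, ax=None):
    """Recovery vs VOI dilation per sphere."""
    ax = _ax(ax)
    ids = sphere_ids or sorted(sweep.sphere_id.unique())
    for sid in ids:
        g = sweep[sweep.sphere_id == sid].sort_values("dilation_mm")
        ax.plot(g.dilation_mm, g.rc_percent, "-o", label=sid)
    ax.set_xlabel("VOI dilation (mm)")
    ax.set_ylabel("recovered activity (%)")
    ax.legend()
    return ax
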