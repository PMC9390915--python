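"""Thin optional plotting layer over the tabular outputs."""

from __future__ import annotations

import numpy as np

from .spectra import SpectralReport
from .task import PsychometricCurve


def plot_spectrum(report: SpectralReport, ax=None):
    """Scatter the eigenvalues in the complex plane with the unit circle,
    the theoretical bulk circle and the predicted outlier when available."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ev = report.eigenvalues
    ax.scatter(ev.real, ev.imag, s=4, color="sienna", alpha=0.6)
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), "k--", lw=0.8, label="unit circle")
    if report.theory is not None:
        R = report.theory.bulk_radius
        ax.plot(R * np.cos(theta), R * np.sin(theta), color="steelblue", lw=1.2,
                label="bulk radius (theory)")
        ax.plot([report.theory.outlier], [0.0], "o", color="goldenrod", ms=8,
                label="outlier (theory)")
    ax.set_xlabel("Re λ")
    ax.set_ylabel("Im λ")
    ax.set_aspect("equal")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_psychometric(curves: list[PsychometricCurve], labels=None, ax=None):
    """Proportion of positive decisions vs mean stimulus strength."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3))
    for i, curve in enumerate(curves):
        lab = labels[i] if labels else None
        ax.plot(curve.c_bar, curve.proportion_positive, "o-", label=lab)
    ax.axhline(0.5, color="grey", lw=0.6, ls=":")
    ax.set_xlabel("mean stimulus strength c̄")
    ax.set_ylabel("proportion positive")
    ax.set_ylim(-0.05, 1.05)
    if labels:
        ax.legend(frameon=False, fontsize=8)
    return ax
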