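"""Minimal figure helpers for run reports."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stats import AgeAlignedCurve, SurvivalCurve

__all__ = ["plot_age_curve", "plot_survival"]


def plot_age_curve(curve: AgeAlignedCurve, ax: Optional[plt.Axes] = None,
                   label: Optional[str] = None) -> plt.Axes:
    """Event probability vs replicative age (SEM error bars)."""
    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(curve.ages, curve.p, yerr=curve.sem, marker="o", capsize=2,
                label=label)
    xlabel = ("replicative age (divisions)" if curve.alignment == "birth"
              else "divisions before death")
    if curve.alignment == "death":
        ax.invert_xaxis()
    ax.set_xlabel(xlabel)
    ax.set_ylabel("GLM probability")
    if label:
        ax.legend()
    return ax


def plot_survival(curve: SurvivalCurve, ax: Optional[plt.Axes] = None,
                  label: Optional[str] = None) -> plt.Axes:
    """Kaplan-Meier replicative-lifespan curve."""
    if ax is None:
        _, ax = plt.subplots()
    ax.step(curve.times, curve.survival, where="post", label=label)
    ax.set_xlabel("replicative age (divisions)")
    ax.set_ylabel("surviving fraction")
    ax.set_ylim(0, 1.02)
    if label:
        ax.legend()
    return ax
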