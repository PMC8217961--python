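"""Matplotlib summaries of angle densities and anisotropy profiles."""

from __future__ import annotations

import numpy as np


def plot_angle_pdf(pdf, ax=None, label=None, flat_reference=True):
    """Step plot of one binned angle density with the flat 1/2π reference."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.stairs(pdf.density, pdf.bin_edges, label=label)
    if flat_reference:
        ax.axhline(1.0 / (2 * np.pi), ls="--", color="gray", lw=0.8)
    ax.set_xlabel("WTMM angle A (rad)")
    ax.set_ylabel(r"$P_a(A)$ (1/rad)")
    if label:
        ax.legend()
    return ax


def plot_profile(profile, ax=None, **kwargs):
    """F_a (or normalised ratio) versus scale on a log-scale axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.scales_um, profile.fa, marker="o", ms=3,
            label=profile.label or None, **kwargs)
    ax.set_xscale("log")
    ax.set_xlabel("scale a (µm)")
    ax.set_ylabel("median ratio" if profile.is_ratio else r"$F_a$")
    if profile.label:
        ax.legend()
    return ax


def plot_group_boxes(scores, value="fa", by="theta_min", ax=None):
    """Box plots of per-image scores grouped by a design column."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    keys = sorted(scores[by].unique())
    data = [scores.loc[scores[by] == k, value].dropna() for k in keys]
    ax.boxplot(data, tick_labels=[f"{k:g}" for k in keys])
    ax.set_xlabel(by)
    ax.set_ylabel(value)
    return ax
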