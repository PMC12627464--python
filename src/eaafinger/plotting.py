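"""Utilitarian plots: offset violins and the LD-score scatter with ellipses."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fingerprint import Ellipse


def plot_offset_violins(per_sample: pd.DataFrame, ax=None):
    """Split distributions of per-mouse mean offsets by organ and group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    organs = sorted(per_sample["organ"].unique())
    groups = sorted(per_sample["group"].unique())
    width = 0.35
    for gi, group in enumerate(groups):
        data = [
            per_sample[
                (per_sample["organ"] == o) & (per_sample["group"] == group)
            ]["mean_offset"].to_numpy()
            for o in organs
        ]
        pos = np.arange(len(organs)) + (gi - (len(groups) - 1) / 2) * width
        parts = ax.violinplot(data, positions=pos, widths=width, showmeans=True)
        for body in parts["bodies"]:
            body.set_alpha(0.6)
        for x, d in zip(pos, data):
            ax.plot(np.full_like(d, x), d, "o", ms=3, color="k", alpha=0.6)
    ax.set_xticks(np.arange(len(organs)))
    ax.set_xticklabels(organs)
    ax.set_ylabel("mean Δδ¹³C-EAA (‰)")
    ax.axhline(0.0, color="grey", lw=0.8, ls=":")
    return ax


def _ellipse_path(ell: Ellipse, n: int = 200) -> tuple[np.ndarray, np.ndarray]:
    t = np.linspace(0.0, 2.0 * np.pi, n)
    a, b = ell.semimajor, ell.semiminor
    phi = np.radians(ell.angle_deg)
    x = a * np.cos(t) * np.cos(phi) - b * np.sin(t) * np.sin(phi) + ell.center[0]
    y = a * np.cos(t) * np.sin(phi) + b * np.sin(t) * np.cos(phi) + ell.center[1]
    return x, y


def plot_lda(score_df: pd.DataFrame, ellipses: dict[str, Ellipse] | None = None, ax=None):
    """LD1/LD2 scatter coloured by group with optional coverage ellipses."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for group, sub in score_df.groupby("group"):
        ax.scatter(sub["LD1"], sub["LD2"], s=18, label=str(group), alpha=0.8)
    if ellipses:
        for label, ell in ellipses.items():
            if isinstance(ell, dict):
                ell = Ellipse(**ell)
            x, y = _ellipse_path(ell)
            ax.plot(x, y, lw=1.0, alpha=0.7)
    ax.set_xlabel("LD1")
    ax.set_ylabel("LD2")
    ax.legend(fontsize=8)
    return ax
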