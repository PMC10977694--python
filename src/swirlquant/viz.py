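"""Overlay and scatter figures for visual inspection of results."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .defects import DefectSet
from .io import WellImage
from .orientation import OrientationField, orientation_vectorfield

_CHARGE_COLORS = {0.5: "tab:red", 1.0: "tab:orange", -0.5: "tab:blue"}


def save_defect_overlay(
    image: WellImage,
    field: OrientationField,
    defects: DefectSet,
    path: str | Path,
    step: int = 16,
) -> None:
    """PNG of the image with director glyphs and charge-colored defect markers."""
    vf = orientation_vectorfield(field, step)
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.imshow(image.pixels, cmap="gray", interpolation="nearest")
    # directors are headless: draw symmetric segments, flip dy for row axis
    dx = np.cos(np.radians(vf["theta_deg"])) * step * 0.45
    dy = -np.sin(np.radians(vf["theta_deg"])) * step * 0.45
    ax.quiver(vf["x"], vf["y"], dx, dy, angles="xy", scale_units="xy", scale=1,
              headwidth=1, headlength=0, headaxislength=0, width=0.002,
              color="yellow", alpha=0.7, pivot="middle")
    for d in defects.defects:
        color = _CHARGE_COLORS.get(d.charge, "white")
        ax.plot(d.x_px, d.y_px, "o", ms=12, mfc="none", mec=color, mew=2)
        ax.annotate(f"{d.charge:+.1f}", (d.x_px, d.y_px), color=color,
                    xytext=(8, 8), textcoords="offset points", fontsize=9)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_correlation_scatter(
    summary: pd.DataFrame,
    proteins: pd.DataFrame,
    corr_row: pd.Series,
    path: str | Path,
    metric: str = "voc",
) -> None:
    """Scatter of donor means +/- SEM vs one protein, with the fitted line."""
    day, protein = int(corr_row["day"]), str(corr_row["protein"])
    sub = summary[summary["day"] == day].merge(proteins, on="donor_id")
    x = sub[f"{metric}_mean"].to_numpy()
    y = sub[protein].to_numpy()
    xerr = sub.get(f"{metric}_sem")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(x, y, xerr=None if xerr is None else xerr.to_numpy(),
                fmt="o", color="k", capsize=3)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, corr_row["slope"] * xs + corr_row["intercept"], "r-")
    ax.set_xlabel(f"{metric} (day {day} donor mean)")
    ax.set_ylabel(protein)
    ax.set_title(f"r = {corr_row['r']:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
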