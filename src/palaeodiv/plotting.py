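"""Minimal matplotlib figures for richness curves, maps and collector's curves."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .collectors import CumulativeCurve
from .diversity import ProxySeries, RichnessSeries
from .timescale import CompositeInterval


def plot_richness_with_proxies(richness: RichnessSeries,
                               proxies: Sequence[ProxySeries],
                               intervals: Sequence[CompositeInterval],
                               path: str | Path) -> None:
    """Richness (solid) and sampling proxies (dashed) against interval midpoints."""
    mids = {iv.id: (iv.start_ma + iv.end_ma) / 2 for iv in intervals}
    x = [mids[i] for i in richness.values]
    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.plot(x, list(richness.values.values()), "k-o", lw=2,
            label=f"{richness.rank} richness")
    styles = {"localities": "--", "geological_units": ":", "grid_cells": "-."}
    for p in proxies:
        ax.plot([mids[i] for i in p.values], list(p.values.values()),
                styles.get(p.metric, "--"), label=p.metric.replace("_", " "))
    ax.invert_xaxis()
    ax.set_xlabel("Age (Ma)")
    ax.set_ylabel("count per bin")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_localities(latitudes, longitudes, path: str | Path) -> None:
    """Present-day locality scatter on a plain lat/lon frame (no coastlines)."""
    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.scatter(longitudes, latitudes, s=8, alpha=0.6)
    ax.set_xlim(-180, 180)
    ax.set_ylim(-90, 90)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_collectors(curves: Sequence[CumulativeCurve],
                    path: str | Path) -> None:
    """Cumulative described-species curves, one line per group."""
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for c in curves:
        dense = c.densify()
        ax.plot(dense["year"], dense["cumulative_count"], label=c.group)
    ax.set_xlabel("year of description")
    ax.set_ylabel("cumulative species")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
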