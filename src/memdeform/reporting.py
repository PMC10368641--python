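"""Tabular (TSV) and graphical (PNG) output for maps, series and metrics.

Every TSV starts with ``#``-prefixed header lines recording the parameters
that produced it, so any number in a report is traceable to its
configuration.  Headers carry no timestamps: identical inputs give
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import TiltSeries
from .membrane import GridField

__all__ = [
    "write_gridfield_tsv",
    "write_tilt_tsv",
    "write_profile_tsv",
    "write_metrics_report",
    "heatmap_png",
]


def _header_lines(params: dict | None) -> list[str]:
    if not params:
        return []
    return [f"# {k}={params[k]}" for k in sorted(params)]


def write_gridfield_tsv(field: GridField, path: str | Path,
                        params: dict | None = None) -> None:
    """One row per cell: i, j, x_center, y_center, value, occupancy, mask.

    Masked cells are written with mask flag 1 and an empty value field.
    """
    spec = field.spec
    xc, yc = spec.x_centers(), spec.y_centers()
    lines = _header_lines(params)
    lines.append("i\tj\tx_center\ty_center\tvalue\toccupancy\tmask")
    for i in range(spec.nx):
        for j in range(spec.ny):
            masked = not field.mask[i, j]
            value = "" if masked else f"{field.values[i, j]:.6g}"
            lines.append(f"{i}\t{j}\t{xc[i]:.3f}\t{yc[j]:.3f}\t{value}"
                         f"\t{int(field.occupancy[i, j])}\t{int(masked)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_tilt_tsv(series: TiltSeries, path: str | Path,
                   params: dict | None = None) -> None:
    lines = _header_lines(params)
    lines.append("frame\tangle_deg")
    for f, a in enumerate(series.angles):
        lines.append(f"{f}\t{a:.4f}")
    lines.append(f"# mean={series.mean:.4f}")
    lines.append(f"# sd={series.std:.4f}")
    lines.append(f"# block_sem={series.block_sem:.4f} (blocks={series.n_blocks})")
    Path(path).write_text("\n".join(lines) + "\n")


def write_profile_tsv(profile: pd.DataFrame, path: str | Path,
                      params: dict | None = None) -> None:
    lines = _header_lines(params)
    lines.append("\t".join(profile.columns))
    for _, row in profile.iterrows():
        lines.append(f"{row['distance']:.3f}\t{row['mean_value']:.6g}\t{int(row['n_cells'])}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_metrics_report(metrics: dict, path: str | Path,
                         params: dict | None = None) -> None:
    """Key-value text report for superposition/displacement metrics."""
    lines = _header_lines(params)
    for k in metrics:
        v = metrics[k]
        lines.append(f"{k}={v:.6g}" if isinstance(v, float) else f"{k}={v}")
    Path(path).write_text("\n".join(lines) + "\n")


def heatmap_png(field: GridField, path: str | Path, kind: str = "thickness",
                title: str | None = None) -> None:
    """Render a grid field as a heatmap.

    Thickness uses a sequential colormap; curvature a symmetric diverging one
    centered on zero, so bulges and dimples read as opposite colors.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = field.spec
    data = np.ma.masked_invalid(field.values).T  # imshow rows = y
    fig, ax = plt.subplots(figsize=(5, 4.2))
    if kind == "curvature":
        finite = field.values[field.mask]
        vmax = float(np.max(np.abs(finite))) if finite.size else 1.0
        vmax = vmax or 1.0
        im = ax.imshow(data, origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                       extent=(0, spec.box[0], 0, spec.box[1]))
        label = "mean curvature H (1/Å)"
    else:
        im = ax.imshow(data, origin="lower", cmap="viridis",
                       extent=(0, spec.box[0], 0, spec.box[1]))
        label = "thickness (Å)" if kind == "thickness" else kind
    fig.colorbar(im, ax=ax, label=label)
    ax.set_xlabel("x (Å)")
    ax.set_ylabel("y (Å)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
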