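"""Optional static figure exports mirroring the standard result views.

Rendering is best-effort: the CSV tables are the pipeline's contract and
callers treat any exception here as a warning.  Uses the Agg backend so the
pipeline stays headless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .detectability import DetectabilityMatrix, coverage_counts
from .model import MatrixKey, MeasurementTable
from .variability import Band, CVRecord

BAND_COLORS = {
    Band.EXCELLENT: "#1a9850",
    Band.GOOD: "#91cf60",
    Band.ACCEPTABLE: "#fee08b",
    Band.NOT_ACCEPTABLE: "#d73027",
}


def coverage_figure(
    table: MeasurementTable,
    detectability: Mapping[MatrixKey, DetectabilityMatrix],
    path: Path,
) -> None:
    """Stacked per-class coverage bars, one panel per sample matrix."""
    matrices = list(detectability)
    fig, axes = plt.subplots(
        1, len(matrices), figsize=(4 * len(matrices), 4), squeeze=False, sharey=True
    )
    classes = table.panel.classes
    cmap = plt.get_cmap("tab20", len(classes))
    for ax, matrix in zip(axes[0], matrices):
        counts = coverage_counts(detectability[matrix], table.panel)
        bottom = None
        for ci, cls in enumerate(classes):
            vals = counts[cls]
            ax.bar(range(len(counts)), vals, bottom=bottom, color=cmap(ci),
                   label=cls if matrix == matrices[0] else None)
            bottom = vals if bottom is None else bottom + vals
        ax.set_xticks(range(len(counts)))
        ax.set_xticklabels(counts.index, rotation=90, fontsize=7)
        ax.set_title("/".join(matrix), fontsize=9)
    axes[0][0].set_ylabel("detectable metabolites")
    fig.legend(fontsize=5, loc="outside right upper")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cv_band_figure(records: Iterable[CVRecord], denominator: int, path: Path) -> None:
    """Stacked CV-band fractions per (matrix, protocol)."""
    groups: dict[tuple, dict[Band, int]] = {}
    for r in records:
        key = (*r.matrix_key, r.protocol)
        groups.setdefault(key, {b: 0 for b in Band})[r.band] += 1
    keys = sorted(groups)
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(keys)), 4))
    bottom = [0.0] * len(keys)
    for band in Band:
        vals = [100.0 * groups[k][band] / denominator for k in keys]
        ax.bar(range(len(keys)), vals, bottom=bottom,
               color=BAND_COLORS[band], label=band.value)
        bottom = [b + v for b, v in zip(bottom, vals)]
    ax.set_xticks(range(len(keys)))
    ax.set_xticklabels(["/".join(map(str, k)) for k in keys], rotation=90, fontsize=6)
    ax.set_ylabel(f"% of {denominator}-metabolite panel")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_all(
    table: MeasurementTable,
    detectability: Mapping[MatrixKey, DetectabilityMatrix],
    records: Iterable[CVRecord] | None,
    outdir: Path,
    denominator: int = 630,
) -> None:
    coverage_figure(table, detectability, outdir / "coverage.png")
    if records is not None:
        cv_band_figure(records, denominator, outdir / "cv_bands.png")
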