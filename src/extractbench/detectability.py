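"""Detectability filtering and quantitation-status summaries.

A metabolite counts as *detectable* under an extraction protocol (within one
sample matrix) when enough of its replicates are above the limit of
detection.  The canonical rule for triplicate designs is "at least 2 of 3
replicates above LOD"; for other replicate counts the same fraction is kept,
i.e. at least ``ceil(2n/3)`` of ``n`` replicates.  "Above LOD" means the
cell's status is ``below_loq`` or ``valid`` — a below-LOQ measurement is
detected even though it is not reliably quantified — while ``below_lod``
and ``missing`` cells provide no evidence of detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .model import (
    ABOVE_LOD_STATUSES,
    ConfigError,
    IntegrityError,
    MatrixKey,
    MeasurementTable,
    MetabolitePanel,
    QuantStatus,
)

__all__ = [
    "DetectionRule",
    "at_least",
    "DetectabilityMatrix",
    "compute_detectability",
    "coverage_counts",
    "status_proportions",
]


@dataclass(frozen=True)
class DetectionRule:
    """Minimum above-LOD replicate rule, as a fraction ``numerator/denominator``.

    ``min_count(n)`` is the smallest number of above-LOD replicates out of
    ``n`` that makes a metabolite detectable: ``ceil(n * numerator /
    denominator)``, i.e. exactly 2-of-3 for triplicates with the default
    2/3 rule.
    """

    numerator: int = 2
    denominator: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.numerator <= self.denominator):
            raise ConfigError(
                f"invalid detection rule {self.numerator}/{self.denominator}"
            )

    def min_count(self, n_replicates: int) -> int:
        return math.ceil(n_replicates * self.numerator / self.denominator)


def at_least(count: int, of: int) -> DetectionRule:
    """Rule factory: ``at_least(2, of=3)`` is the canonical triplicate rule."""
    return DetectionRule(count, of)


@dataclass
class DetectabilityMatrix:
    """Per-matrix boolean detectability with its supporting replicate counts.

    ``detectable``, ``n_above_lod`` and ``n_total`` are DataFrames indexed by
    metabolite (panel order) with one column per protocol.
    """

    matrix_key: MatrixKey
    detectable: pd.DataFrame
    n_above_lod: pd.DataFrame
    n_total: pd.DataFrame

    def detected_set(self, protocol: str) -> list[str]:
        col = self.detectable[protocol]
        return [m for m in col.index if col[m]]


def compute_detectability(
    table: MeasurementTable, rule: DetectionRule = DetectionRule()
) -> dict[MatrixKey, DetectabilityMatrix]:
    """Apply the above-LOD replicate rule per (matrix, protocol, metabolite)."""
    out: dict[MatrixKey, DetectabilityMatrix] = {}
    names = table.panel.names
    stat = table.statuses.to_numpy()
    above = np.isin(stat, list(ABOVE_LOD_STATUSES))
    for matrix in table.matrices():
        protocols = table.protocols(matrix)
        n_above = pd.DataFrame(0, index=names, columns=protocols, dtype=int)
        n_total = pd.DataFrame(0, index=names, columns=protocols, dtype=int)
        for prot in protocols:
            rows = table.group_rows(matrix, prot)
            if rows.size == 0:
                raise IntegrityError(
                    f"empty replicate group {matrix[0]}/{matrix[1]}/{prot}"
                )
            n_above[prot] = above[rows].sum(axis=0)
            n_total[prot] = rows.size
        need = n_total.map(rule.min_count)
        det = n_above >= need
        out[matrix] = DetectabilityMatrix(matrix, det, n_above, n_total)
    return out


def coverage_counts(
    det: DetectabilityMatrix, panel: MetabolitePanel
) -> pd.DataFrame:
    """Detectable-metabolite counts per (protocol, compound class).

    Rows are protocols, columns compound classes in panel order, plus a
    ``total`` column; this is the per-matrix coverage bar chart in tabular
    form.
    """
    cls = pd.Series(panel.class_of())
    classes = panel.classes
    counts = pd.DataFrame(0, index=det.detectable.columns, columns=classes,
                          dtype=int)
    for prot in det.detectable.columns:
        detected = det.detectable[prot]
        by_class = cls[detected[detected].index].value_counts()
        for c, n in by_class.items():
            counts.loc[prot, c] = int(n)
    counts["total"] = counts[classes].sum(axis=1)
    return counts


def status_proportions(table: MeasurementTable) -> pd.DataFrame:
    """Fractions of panel cells per status for every (matrix, protocol) group.

    The denominator is panel size × replicate count, so the four fractions
    sum to 1 per group.
    """
    order = [s.value for s in QuantStatus]
    stat = table.statuses.to_numpy()
    rows = []
    index = []
    for matrix in table.matrices():
        for prot in table.protocols(matrix):
            r = table.group_rows(matrix, prot)
            group = stat[r].ravel()
            n = group.size
            rows.append([np.count_nonzero(group == s) / n for s in order])
            index.append((*matrix, prot))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index,
                                        names=["organism", "tissue", "protocol"]),
        columns=order,
    )
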