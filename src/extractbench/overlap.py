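"""Cross-matrix overlap of detectable metabolites within one protocol.

For a fixed extraction protocol, the sets of detectable metabolites in each
sample matrix (organism × tissue) are decomposed into exclusive Venn
regions: for every nonempty subset of matrices, the metabolites detectable
in exactly those matrices.  Regions are disjoint and cover the union; the
all-matrices region is the core of metabolites the protocol recovers
everywhere.  Full decomposition is refused above 6 matrices (2^k − 1
regions stop being interpretable); pairwise intersection counts are emitted
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .detectability import DetectabilityMatrix
from .model import ConfigError, MatrixKey

__all__ = ["OverlapResult", "venn_overlap", "shared_unique_lists"]

MAX_FULL_DECOMPOSITION = 6


def _label(matrix: MatrixKey) -> str:
    return f"{matrix[0]}/{matrix[1]}"


@dataclass
class OverlapResult:
    """Exclusive region decomposition for one protocol across matrices.

    ``regions`` maps a sorted tuple of matrix keys (the exact membership
    pattern) to the metabolites detectable in precisely those matrices, in
    panel order.  ``pairwise`` replaces ``regions`` beyond the matrix-count
    guardrail.
    """

    protocol: str
    matrices: tuple[MatrixKey, ...]
    regions: dict[tuple[MatrixKey, ...], list[str]] | None
    pairwise: dict[tuple[MatrixKey, MatrixKey], int] | None = None

    def region_counts(self) -> dict[tuple[MatrixKey, ...], int]:
        if self.regions is None:
            raise ConfigError("no full decomposition available (guardrail)")
        return {k: len(v) for k, v in self.regions.items()}

    def core(self) -> list[str]:
        """Metabolites detectable in every matrix under this protocol."""
        if self.regions is None:
            raise ConfigError("no full decomposition available (guardrail)")
        return list(self.regions.get(self.matrices, []))

    def union_size(self) -> int:
        if self.regions is None:
            raise ConfigError("no full decomposition available (guardrail)")
        return sum(len(v) for v in self.regions.values())


def venn_overlap(
    detectability: Mapping[MatrixKey, DetectabilityMatrix],
    protocol: str,
    max_full: int = MAX_FULL_DECOMPOSITION,
) -> OverlapResult:
    """Decompose per-matrix detectable sets for ``protocol`` into regions."""
    matrices = tuple(sorted(detectability))
    if len(matrices) < 2:
        raise ConfigError(
            f"overlap needs >= 2 matrices, got {len(matrices)}"
        )
    sets: dict[MatrixKey, set[str]] = {}
    panel_order: list[str] | None = None
    for m in matrices:
        det = detectability[m]
        if protocol not in det.detectable.columns:
            raise ConfigError(
                f"protocol {protocol!r} absent from matrix {_label(m)}"
            )
        sets[m] = set(det.detected_set(protocol))
        if panel_order is None:
            panel_order = list(det.detectable.index)

    if len(matrices) > max_full:
        pairwise = {
            (a, b): len(sets[a] & sets[b])
            for i, a in enumerate(matrices)
            for b in matrices[i + 1:]
        }
        return OverlapResult(protocol, matrices, None, pairwise)

    order = {name: i for i, name in enumerate(panel_order or [])}
    regions: dict[tuple[MatrixKey, ...], list[str]] = {}
    union = set().union(*sets.values())
    for met in sorted(union, key=lambda n: order.get(n, len(order))):
        pattern = tuple(m for m in matrices if met in sets[m])
        regions.setdefault(pattern, []).append(met)
    return OverlapResult(protocol, matrices, regions)


def shared_unique_lists(result: OverlapResult) -> pd.DataFrame:
    """Long-format region table: one row per metabolite of the union.

    Columns: metabolite, one boolean per matrix, and the serialized
    membership pattern.  Row count equals the union size.
    """
    if result.regions is None:
        raise ConfigError("no full decomposition available (guardrail)")
    rows = []
    for pattern, mets in sorted(result.regions.items()):
        label = " & ".join(_label(m) for m in pattern)
        for met in mets:
            row: dict = {"metabolite": met}
            for m in result.matrices:
                row[_label(m)] = m in pattern
            row["pattern"] = label
            rows.append(row)
    cols = ["metabolite", *(_label(m) for m in result.matrices), "pattern"]
    return pd.DataFrame(rows, columns=cols)
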