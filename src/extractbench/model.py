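"""Core data model for kit-style targeted metabolomics measurements.

A *panel* is the fixed list of metabolites a quantification kit reports
(e.g. a 630-metabolite broad-coverage panel), each annotated with a
compound class and the acquisition mode it is measured in (LC-MS/MS for
small molecules, FIA-MS/MS for lipids and hexoses).  A *sample* is one
extraction replicate of one sample matrix (organism × tissue) processed
with one extraction protocol.  Every (sample, metabolite) cell carries a
concentration in kit units together with a quantitation status assigned
by the kit software: below the limit of detection, between LOD and the
limit of quantification, within the calibrated range ("valid"), or
missing altogether.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionMode",
    "QuantStatus",
    "Metabolite",
    "MetabolitePanel",
    "SampleKey",
    "MatrixKey",
    "MeasurementTable",
    "validate",
    "ExtractBenchError",
    "ParseError",
    "IntegrityError",
    "ConfigError",
]

SAMPLE_FIELDS = ("organism", "tissue", "protocol", "replicate")

MatrixKey = tuple[str, str]


class ExtractBenchError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ExtractBenchError):
    """A file does not conform to its declared dialect."""


class IntegrityError(ExtractBenchError):
    """Structurally readable data violates a model invariant."""


class ConfigError(ExtractBenchError):
    """An invalid configuration value."""


class AcquisitionMode(str, enum.Enum):
    """How a metabolite is acquired on the instrument."""

    LC = "LC"
    FIA = "FIA"


class QuantStatus(str, enum.Enum):
    """Per-cell quantitation status as categorized by the kit software."""

    BELOW_LOD = "below_lod"
    BELOW_LOQ = "below_loq"
    VALID = "valid"
    MISSING = "missing"


STATUS_TOKENS: frozenset[str] = frozenset(s.value for s in QuantStatus)

#: Statuses that count as "above the limit of detection".  LOQ > LOD, so a
#: below-LOQ measurement is detected, just not reliably quantified.
ABOVE_LOD_STATUSES: frozenset[str] = frozenset(
    {QuantStatus.BELOW_LOQ.value, QuantStatus.VALID.value}
)


@dataclass(frozen=True)
class Metabolite:
    name: str
    compound_class: str
    acquisition_mode: AcquisitionMode

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "acquisition_mode", AcquisitionMode(self.acquisition_mode)
        )


@dataclass(frozen=True)
class MetabolitePanel:
    """The ordered metabolite list of a quantification kit.

    Metabolite names are unique; each metabolite belongs to exactly one
    compound class and one acquisition mode.
    """

    metabolites: tuple[Metabolite, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        names = [m.name for m in self.metabolites]
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise IntegrityError(f"duplicate metabolite name in panel: {n!r}")
            seen.add(n)

    def __len__(self) -> int:
        return len(self.metabolites)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.metabolites]

    @property
    def classes(self) -> list[str]:
        """Compound classes in order of first appearance."""
        out: list[str] = []
        for m in self.metabolites:
            if m.compound_class not in out:
                out.append(m.compound_class)
        return out

    def class_of(self) -> dict[str, str]:
        return {m.name: m.compound_class for m in self.metabolites}

    def mode_of(self) -> dict[str, AcquisitionMode]:
        return {m.name: m.acquisition_mode for m in self.metabolites}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite": self.names,
                "class": [m.compound_class for m in self.metabolites],
                "mode": [m.acquisition_mode.value for m in self.metabolites],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MetabolitePanel":
        mets = tuple(
            Metabolite(str(r.metabolite), str(getattr(r, "class")), AcquisitionMode(r.mode))
            for r in frame.itertuples(index=False)
        )
        return cls(mets)


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one measured sample.

    (organism, tissue) defines the sample *matrix*; (matrix, protocol)
    defines a replicate group within which replicate indices are unique.
    """

    organism: str
    tissue: str
    protocol: str
    replicate: int

    def __post_init__(self) -> None:
        if int(self.replicate) < 1:
            raise IntegrityError(f"replicate index must be >= 1, got {self.replicate}")
        object.__setattr__(self, "replicate", int(self.replicate))

    @property
    def matrix(self) -> MatrixKey:
        return (self.organism, self.tissue)

    def as_tuple(self) -> tuple[str, str, str, int]:
        return (self.organism, self.tissue, self.protocol, self.replicate)


def _sample_index(samples: Sequence[SampleKey]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(
        [s.as_tuple() for s in samples], names=list(SAMPLE_FIELDS)
    )


@dataclass
class MeasurementTable:
    """Samples × metabolites concentrations with per-cell quantitation status.

    ``concentrations`` and ``statuses`` are pandas DataFrames of identical
    shape: rows indexed by (organism, tissue, protocol, replicate), columns
    named by panel metabolites in panel order.  Missing cells hold NaN in
    ``concentrations`` and the token ``"missing"`` in ``statuses``.
    Censored cells (below LOD / below LOQ) may carry the instrument's
    numeric estimate or NaN.
    """

    panel: MetabolitePanel
    concentrations: pd.DataFrame
    statuses: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.concentrations.columns) != self.panel.names:
            raise IntegrityError("concentration columns must match panel order")
        if list(self.statuses.columns) != self.panel.names:
            raise IntegrityError("status columns must match panel order")
        if self.concentrations.shape != self.statuses.shape:
            raise IntegrityError("concentrations and statuses must share a shape")
        if not self.concentrations.index.equals(self.statuses.index):
            raise IntegrityError("concentrations and statuses must share an index")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        panel: MetabolitePanel,
        samples: Sequence[SampleKey],
        concentrations: np.ndarray,
        statuses: np.ndarray,
    ) -> "MeasurementTable":
        idx = _sample_index(samples)
        conc = pd.DataFrame(np.asarray(concentrations, dtype=float), index=idx,
                            columns=panel.names)
        stat = pd.DataFrame(np.asarray(statuses, dtype=object), index=idx,
                            columns=panel.names)
        return cls(panel, conc, stat).normalize()

    # -- views ----------------------------------------------------------------

    @property
    def samples(self) -> list[SampleKey]:
        return [SampleKey(*t) for t in self.concentrations.index]

    @property
    def n_samples(self) -> int:
        return self.concentrations.shape[0]

    def matrices(self) -> list[MatrixKey]:
        seen: dict[MatrixKey, None] = {}
        for org, tis, _, _ in self.concentrations.index:
            seen[(org, tis)] = None
        return sorted(seen)

    def protocols(self, matrix: MatrixKey | None = None) -> list[str]:
        out: dict[str, None] = {}
        for org, tis, prot, _ in self.concentrations.index:
            if matrix is None or (org, tis) == matrix:
                out[prot] = None
        return list(out)

    def subset_matrix(self, matrix: MatrixKey) -> "MeasurementTable":
        mask = [
            (org, tis) == matrix for org, tis, _, _ in self.concentrations.index
        ]
        return MeasurementTable(
            self.panel, self.concentrations.loc[mask], self.statuses.loc[mask]
        )

    def group_rows(self, matrix: MatrixKey, protocol: str) -> np.ndarray:
        """Positional row indices of one (matrix, protocol) replicate group."""
        idx = self.concentrations.index
        return np.flatnonzero(
            [
                (org, tis) == matrix and prot == protocol
                for org, tis, prot, _ in idx
            ]
        )

    # -- normalization and equality -------------------------------------------

    def normalize(self) -> "MeasurementTable":
        """Canonical form: samples sorted by (matrix, protocol, replicate),
        metabolites sorted by name (with the panel reordered to match), so
        that equal data compares equal regardless of input row/column order."""
        order = self.concentrations.index.sortlevel(list(SAMPLE_FIELDS))[1]
        mets = sorted(self.panel.metabolites, key=lambda m: m.name)
        names = [m.name for m in mets]
        return MeasurementTable(
            MetabolitePanel(tuple(mets)),
            self.concentrations.iloc[order][names],
            self.statuses.iloc[order][names],
        )

    def equals(self, other: "MeasurementTable") -> bool:
        return (
            self.panel == other.panel
            and self.concentrations.index.equals(other.concentrations.index)
            and np.array_equal(
                self.concentrations.to_numpy(),
                other.concentrations.to_numpy(),
                equal_nan=True,
            )
            and self.statuses.to_numpy().tolist() == other.statuses.to_numpy().tolist()
        )


def validate(table: MeasurementTable) -> list[str]:
    """Check model invariants; returns one message per violation.

    Reports rather than raises: a table that parses may still carry
    questionable cells (negative concentrations, a "valid" status without a
    number, duplicate replicate indices) that the caller should see all at
    once.
    """
    violations: list[str] = []
    conc = table.concentrations.to_numpy()
    stat = table.statuses.to_numpy()
    names = table.panel.names
    index = list(table.concentrations.index)

    for i, key in enumerate(index):
        label = "/".join(str(p) for p in key)
        for j, met in enumerate(names):
            s = stat[i, j]
            c = conc[i, j]
            if s not in STATUS_TOKENS:
                violations.append(f"cell ({label}, {met}): unknown status {s!r}")
                continue
            finite = np.isfinite(c)
            if s == QuantStatus.MISSING.value and finite:
                violations.append(
                    f"cell ({label}, {met}): status 'missing' but concentration {c!r}"
                )
            if s == QuantStatus.VALID.value and not finite:
                violations.append(
                    f"cell ({label}, {met}): status 'valid' without a finite concentration"
                )
            if finite and c < 0:
                violations.append(
                    f"cell ({label}, {met}): negative concentration {c!r}"
                )
            if s == QuantStatus.VALID.value and finite and c == 0:
                violations.append(
                    f"cell ({label}, {met}): zero concentration with status 'valid'"
                )

    seen: set[tuple[str, str, str, int]] = set()
    for key in index:
        if key in seen:
            violations.append(
                "duplicate replicate index in group "
                f"{key[0]}/{key[1]}/{key[2]}: replicate {key[3]}"
            )
        seen.add(key)
    return violations
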