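"""Replicate variability: CV% and MAD per metabolite × protocol, with bands.

The robustness of an extraction protocol is scored by the coefficient of
variation of its replicate concentrations, CV% = 100 · sd / mean (sample SD,
n−1 denominator, raw linear-scale concentrations), together with the scaled
median absolute deviation.  CVs are classified into the conventional QC
bands: 0–10% excellent, >10–20% good, >20–30% acceptable, >30% not
acceptable (right-closed intervals on the unrounded CV).  Band percentages
are reported against a fixed panel denominator (default 630) so that a
protocol's robustness and its coverage are visible at once: bands of a
low-coverage protocol cannot sum to 100%.

CVs are computed only for detectable (metabolite, protocol) pairs, from
their non-missing replicates, with no prior imputation — a constant
imputation floor would fabricate spurious precision.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detectability import DetectabilityMatrix
from .model import (
    ConfigError,
    ExtractBenchError,
    MatrixKey,
    MeasurementTable,
    QuantStatus,
)

__all__ = [
    "Band",
    "CVRecord",
    "BandSummary",
    "InsufficientReplicatesError",
    "UndefinedCVError",
    "compute_cv",
    "assign_band",
    "cv_records",
    "band_summary",
    "band_summary_from_counts",
    "median_mad_of_cv",
    "round_half_up",
]

logger = logging.getLogger(__name__)

#: Normal-consistency scaling for the median absolute deviation.
MAD_SCALE_NORMAL = 1.4826


class Band(str, enum.Enum):
    EXCELLENT = "excellent"
    GOOD = "good"
    ACCEPTABLE = "acceptable"
    NOT_ACCEPTABLE = "not_acceptable"


class InsufficientReplicatesError(ExtractBenchError):
    """Fewer usable replicates than the configured minimum."""


class UndefinedCVError(ExtractBenchError):
    """CV is undefined for a non-positive replicate mean."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), for display."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def compute_cv(
    replicates: Sequence[float],
    min_n: int = 2,
    mad_scale: float = MAD_SCALE_NORMAL,
) -> tuple[float, float]:
    """CV% and scaled MAD of one replicate group's raw concentrations.

    CV% = 100 · sample SD (n−1) / mean.  MAD = ``mad_scale`` × median |x −
    median x| (1.4826 for normal consistency), in concentration units.
    """
    arr = np.asarray(replicates, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < min_n:
        raise InsufficientReplicatesError(
            f"need >= {min_n} finite replicates, got {arr.size}"
        )
    mean = arr.mean()
    if mean <= 0:
        raise UndefinedCVError(f"CV undefined for non-positive mean {mean!r}")
    cv = 100.0 * arr.std(ddof=1) / mean
    mad = mad_scale * float(np.median(np.abs(arr - np.median(arr))))
    return float(cv), mad


def assign_band(
    cv_percent: float, boundaries: tuple[float, float, float] = (10.0, 20.0, 30.0)
) -> Band:
    """Classify an unrounded CV% into its QC band (right-closed intervals)."""
    if cv_percent < 0:
        raise ValueError(f"negative CV {cv_percent!r}")
    b1, b2, b3 = boundaries
    if not (0 < b1 < b2 < b3):
        raise ConfigError(f"band boundaries must increase, got {boundaries}")
    if cv_percent <= b1:
        return Band.EXCELLENT
    if cv_percent <= b2:
        return Band.GOOD
    if cv_percent <= b3:
        return Band.ACCEPTABLE
    return Band.NOT_ACCEPTABLE


@dataclass(frozen=True)
class CVRecord:
    matrix_key: MatrixKey
    metabolite: str
    protocol: str
    cv_percent: float
    mad: float
    band: Band


def cv_records(
    table: MeasurementTable,
    detectability: Mapping[MatrixKey, DetectabilityMatrix],
    min_n: int = 2,
    boundaries: tuple[float, float, float] = (10.0, 20.0, 30.0),
    mad_scale: float = MAD_SCALE_NORMAL,
) -> list[CVRecord]:
    """CV/MAD/band for every detectable (matrix, protocol, metabolite).

    Pairs with fewer than ``min_n`` usable replicates or a non-positive mean
    are skipped and logged, not errored: they carry no variability evidence.
    """
    records: list[CVRecord] = []
    conc = table.concentrations.to_numpy()
    stat = table.statuses.to_numpy()
    names = table.panel.names
    for matrix, det in detectability.items():
        for prot in det.detectable.columns:
            rows = table.group_rows(matrix, prot)
            for j, met in enumerate(names):
                if not det.detectable.loc[met, prot]:
                    continue
                vals = conc[rows, j].copy()
                vals[stat[rows, j] == QuantStatus.MISSING.value] = np.nan
                try:
                    cv, mad = compute_cv(vals, min_n=min_n, mad_scale=mad_scale)
                except (InsufficientReplicatesError, UndefinedCVError) as exc:
                    logger.info(
                        "skipping CV for %s/%s/%s: %s", matrix, prot, met, exc
                    )
                    continue
                records.append(
                    CVRecord(matrix, met, prot, cv, mad, assign_band(cv, boundaries))
                )
    return records


@dataclass
class BandSummary:
    """Band counts and percentages for one (matrix, protocol).

    Percentages use a fixed panel denominator so that the four bands sum to
    the protocol's defined-CV coverage share, not to 100%.
    """

    matrix_key: MatrixKey
    protocol: str
    counts: dict[Band, int]
    percentages: dict[Band, float]
    denominator: int
    detectable_total: int

    def as_row(self) -> dict:
        row: dict = {
            "organism": self.matrix_key[0],
            "tissue": self.matrix_key[1],
            "protocol": self.protocol,
            "denominator": self.denominator,
            "detectable_total": self.detectable_total,
        }
        for band in Band:
            row[f"n_{band.value}"] = self.counts[band]
            row[f"pct_{band.value}"] = self.percentages[band]
        return row


def band_summary_from_counts(
    counts: Mapping[Band, int] | Sequence[int],
    denominator: int = 630,
    matrix_key: MatrixKey = ("", ""),
    protocol: str = "",
    detectable_total: int | None = None,
) -> BandSummary:
    """Summary from explicit per-band counts over a fixed denominator.

    Percentages are 100 × count / denominator, rounded half-up to one
    decimal for display.
    """
    if denominator <= 0:
        raise ConfigError(f"denominator must be positive, got {denominator}")
    if not isinstance(counts, Mapping):
        counts = dict(zip(Band, counts))
    counts = {band: int(counts.get(band, 0)) for band in Band}
    pct = {
        band: round_half_up(100.0 * counts[band] / denominator, 1)
        for band in Band
    }
    total = sum(counts.values()) if detectable_total is None else detectable_total
    return BandSummary(matrix_key, protocol, counts, pct, denominator, total)


def band_summary(
    records: Iterable[CVRecord],
    denominator: int = 630,
    matrix_key: MatrixKey | None = None,
    protocol: str | None = None,
) -> BandSummary:
    """Summarize the CV records of one (matrix, protocol) group."""
    records = list(records)
    if records:
        keys = {(r.matrix_key, r.protocol) for r in records}
        if len(keys) > 1:
            raise ConfigError(
                f"band_summary expects records of one (matrix, protocol), got {keys}"
            )
        matrix_key, protocol = next(iter(keys))
    counts = {band: 0 for band in Band}
    for r in records:
        counts[r.band] += 1
    return band_summary_from_counts(
        counts, denominator, matrix_key or ("", ""), protocol or ""
    )


def median_mad_of_cv(
    records: Iterable[CVRecord], mad_scale: float = MAD_SCALE_NORMAL
) -> pd.DataFrame:
    """Median and scaled MAD of the CV% distribution per (matrix, protocol)."""
    frame = pd.DataFrame(
        [
            {
                "organism": r.matrix_key[0],
                "tissue": r.matrix_key[1],
                "protocol": r.protocol,
                "cv_percent": r.cv_percent,
            }
            for r in records
        ]
    )
    if frame.empty:
        raise ConfigError("no CV records to summarize")

    def _agg(g: pd.Series) -> pd.Series:
        med = float(np.median(g))
        mad = mad_scale * float(np.median(np.abs(g - med)))
        return pd.Series({"median_cv": med, "mad_cv": mad, "n": int(g.size)})

    out = (
        frame.groupby(["organism", "tissue", "protocol"])["cv_percent"]
        .apply(_agg)
        .unstack()
    )
    out["n"] = out["n"].astype(int)
    return out
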