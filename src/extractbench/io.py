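"""Reading and writing portable text dialects of kit measurement exports.

Vendor software exports annotated spreadsheets in which the quantitation
status of each cell is encoded as a background color.  This package instead
defines two equivalent plain-text dialects with an explicit status token per
cell, so that files are diffable, version-controllable and stable to parse:

``long_csv``
    UTF-8 CSV, one row per (sample, metabolite) cell, header exactly::

        organism,tissue,protocol,replicate,metabolite,class,mode,concentration,status

    An empty ``concentration`` field encodes an absent number.

``wide_tsv``
    Tab-separated, one row per sample.  Columns ``organism``, ``tissue``,
    ``protocol``, ``replicate``, then per metabolite a value column
    ``<name>`` and a status column ``<name>__status``.  Panel annotations
    (compound class, acquisition mode) are carried as leading comment lines
    ``# <name>\t<class>\t<mode>`` so the dialect round-trips the full data
    model; files without these comments parse with class ``unknown`` and
    mode ``LC`` under a warning.

Status vocabulary is ``below_lod`` / ``below_loq`` / ``valid`` / ``missing``.
Legacy kit tokens ``< LLOQ`` and ``> ULOQ`` map onto ``below_loq`` with a
warning; anything else is a parse error naming the offending row.

Concentrations are serialized with ``repr`` (shortest round-trip decimal),
so write→read reproduces bit-identical floats.
"""

from __future__ import annotations

import io as _stdio
import warnings
from pathlib import Path
import numpy as np
import pandas as pd

from .model import (
    AcquisitionMode,
    ConfigError,
    IntegrityError,
    MeasurementTable,
    Metabolite,
    MetabolitePanel,
    ParseError,
    QuantStatus,
    SampleKey,
    STATUS_TOKENS,
)

__all__ = ["read_measurements", "write_measurements", "LONG_COLUMNS", "DIALECTS"]

LONG_COLUMNS = (
    "organism", "tissue", "protocol", "replicate",
    "metabolite", "class", "mode", "concentration", "status",
)
DIALECTS = ("long_csv", "wide_tsv")

#: Tokens from other kit software versions accepted with a warning.
LEGACY_STATUS_ALIASES = {
    "< lloq": QuantStatus.BELOW_LOQ.value,
    "<lloq": QuantStatus.BELOW_LOQ.value,
    "> uloq": QuantStatus.BELOW_LOQ.value,
    ">uloq": QuantStatus.BELOW_LOQ.value,
}


def _normalize_status(token: str, where: str) -> str:
    tok = token.strip()
    if tok in STATUS_TOKENS:
        return tok
    alias = LEGACY_STATUS_ALIASES.get(tok.lower())
    if alias is not None:
        warnings.warn(
            f"{where}: legacy status token {token!r} mapped to {alias!r}",
            stacklevel=3,
        )
        return alias
    raise ParseError(f"{where}: unknown status token {token!r}")


def _fmt(x: float) -> str:
    return "" if not np.isfinite(x) else repr(float(x))


def _parse_conc(tok: str, where: str) -> float:
    if tok == "":
        return float("nan")
    try:
        return float(tok)
    except ValueError as exc:
        raise ParseError(f"{where}: unparseable concentration {tok!r}") from exc


# ---------------------------------------------------------------------------
# long_csv


def _read_long_csv(path: Path) -> MeasurementTable:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(frame.columns) != list(LONG_COLUMNS):
        raise ParseError(
            f"{path}: long_csv header must be {','.join(LONG_COLUMNS)}, "
            f"got {','.join(frame.columns)}"
        )

    # panel in order of first appearance; annotation must be consistent
    panel_rows: dict[str, tuple[str, str]] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        met = row.metabolite
        ann = (getattr(row, "_5"), row.mode)  # 'class' is positional field 5
        prev = panel_rows.setdefault(met, ann)
        if prev != ann:
            raise IntegrityError(
                f"{path} line {i}: inconsistent class/mode for metabolite {met!r}: "
                f"{ann!r} vs {prev!r}"
            )
    try:
        panel = MetabolitePanel(
            tuple(
                Metabolite(name, cls, AcquisitionMode(mode))
                for name, (cls, mode) in panel_rows.items()
            )
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc

    names = panel.names
    col_of = {n: j for j, n in enumerate(names)}
    cells: dict[tuple[str, str, str, int], int] = {}
    seen_cells: set[tuple[int, int]] = set()
    sample_keys: list[SampleKey] = []
    conc_rows: list[np.ndarray] = []
    stat_rows: list[np.ndarray] = []

    for i, row in enumerate(frame.itertuples(index=False), start=2):
        where = f"{path} line {i}"
        try:
            rep = int(row.replicate)
        except ValueError as exc:
            raise ParseError(f"{where}: replicate must be an integer, "
                             f"got {row.replicate!r}") from exc
        key = (row.organism, row.tissue, row.protocol, rep)
        if key not in cells:
            cells[key] = len(sample_keys)
            sample_keys.append(SampleKey(*key))
            conc_rows.append(np.full(len(names), np.nan))
            stat_rows.append(np.full(len(names), QuantStatus.MISSING.value,
                                     dtype=object))
        r = cells[key]
        j = col_of[row.metabolite]
        if (r, j) in seen_cells:
            raise IntegrityError(
                f"{where}: duplicate cell for sample "
                f"{'/'.join(map(str, key))}, metabolite {row.metabolite!r}"
            )
        seen_cells.add((r, j))
        stat_rows[r][j] = _normalize_status(row.status, where)
        conc_rows[r][j] = _parse_conc(row.concentration, where)

    return MeasurementTable.from_arrays(
        panel, sample_keys, np.array(conc_rows), np.array(stat_rows, dtype=object)
    )


def _write_long_csv(table: MeasurementTable, path: Path) -> None:
    lines = [",".join(LONG_COLUMNS)]
    conc = table.concentrations.to_numpy()
    stat = table.statuses.to_numpy()
    cls = table.panel.class_of()
    mode = table.panel.mode_of()
    names = table.panel.names
    for i, key in enumerate(table.concentrations.index):
        org, tis, prot, rep = key
        for j, met in enumerate(names):
            lines.append(
                ",".join(
                    (
                        str(org), str(tis), str(prot), str(rep),
                        met, cls[met], mode[met].value,
                        _fmt(conc[i, j]), str(stat[i, j]),
                    )
                )
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# wide_tsv


def _read_wide_tsv(path: Path) -> MeasurementTable:
    annotations: dict[str, tuple[str, str]] = {}
    body_lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("#"):
                parts = raw[1:].strip("\n").strip().split("\t")
                if len(parts) == 3:
                    annotations[parts[0]] = (parts[1], parts[2])
                continue
            body_lines.append(raw)
    if not body_lines:
        raise ParseError(f"{path}: empty wide_tsv file")
    frame = pd.read_csv(_stdio.StringIO("".join(body_lines)), sep="\t",
                        dtype=str, keep_default_na=False)
    meta_cols = list(frame.columns[:4])
    if meta_cols != ["organism", "tissue", "protocol", "replicate"]:
        raise ParseError(
            f"{path}: wide_tsv must start with organism/tissue/protocol/replicate "
            f"columns, got {meta_cols}"
        )
    rest = list(frame.columns[4:])
    names: list[str] = []
    for col in rest:
        if col.endswith("__status"):
            continue
        if f"{col}__status" not in rest:
            raise ParseError(f"{path}: metabolite column {col!r} lacks its "
                             f"{col}__status companion")
        names.append(col)
    if not annotations:
        warnings.warn(
            f"{path}: no panel annotation comments; classes set to 'unknown', "
            "mode to 'LC'",
            stacklevel=3,
        )
    mets = []
    for n in names:
        cls, mode = annotations.get(n, ("unknown", "LC"))
        mets.append(Metabolite(n, cls, AcquisitionMode(mode)))
    panel = MetabolitePanel(tuple(mets))

    sample_keys: list[SampleKey] = []
    conc = np.full((len(frame), len(names)), np.nan)
    stat = np.full((len(frame), len(names)), QuantStatus.MISSING.value, dtype=object)
    meta = frame[meta_cols].to_numpy(dtype=object)
    vals = frame[names].to_numpy(dtype=object)
    stats_raw = frame[[f"{n}__status" for n in names]].to_numpy(dtype=object)
    for i in range(len(frame)):
        where = f"{path} data row {i + 1}"
        try:
            rep = int(meta[i, 3])
        except ValueError as exc:
            raise ParseError(f"{where}: replicate must be an integer") from exc
        sample_keys.append(SampleKey(meta[i, 0], meta[i, 1], meta[i, 2], rep))
        for j in range(len(names)):
            stat[i, j] = _normalize_status(stats_raw[i, j], where)
            conc[i, j] = _parse_conc(vals[i, j], where)

    keys = [k.as_tuple() for k in sample_keys]
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise IntegrityError(f"{path}: duplicate sample row {'/'.join(map(str, dup))}")
    return MeasurementTable.from_arrays(panel, sample_keys, conc, stat)


def _write_wide_tsv(table: MeasurementTable, path: Path) -> None:
    names = table.panel.names
    cls = table.panel.class_of()
    mode = table.panel.mode_of()
    lines = [f"# {n}\t{cls[n]}\t{mode[n].value}" for n in names]
    header = ["organism", "tissue", "protocol", "replicate"]
    for n in names:
        header += [n, f"{n}__status"]
    lines.append("\t".join(header))
    conc = table.concentrations.to_numpy()
    stat = table.statuses.to_numpy()
    for i, key in enumerate(table.concentrations.index):
        row = [str(p) for p in key]
        for j in range(len(names)):
            row += [_fmt(conc[i, j]), str(stat[i, j])]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# public interface


def read_measurements(path: str | Path, dialect: str = "long_csv") -> MeasurementTable:
    """Read a measurement table from ``path`` in the given dialect.

    Returns a normalized table: samples sorted by (organism, tissue,
    protocol, replicate), metabolites in panel order.  Raises
    :class:`ParseError` for malformed files and :class:`IntegrityError`
    for well-formed files that violate model invariants (duplicate cells,
    inconsistent per-metabolite annotations).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if dialect == "long_csv":
        return _read_long_csv(path)
    if dialect == "wide_tsv":
        return _read_wide_tsv(path)
    raise ConfigError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_measurements(
    table: MeasurementTable, path: str | Path, dialect: str = "long_csv"
) -> Path:
    """Write ``table`` to ``path``; the file re-reads to an equal table."""
    path = Path(path)
    table = table.normalize()
    if dialect == "long_csv":
        _write_long_csv(table, path)
    elif dialect == "wide_tsv":
        _write_wide_tsv(table, path)
    else:
        raise ConfigError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    return path
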