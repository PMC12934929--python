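"""Reading and writing ``samtools idxstats`` tables and result tables.

An idxstats file has one tab-separated row per reference sequence —
``name, length, mapped, unmapped`` — plus a sentinel row ``*`` holding the
count of fully unmapped reads.  The sentinel is retained on parse but never
treated as a chromosome.  The ``unmapped`` column is parsed and preserved
but plays no role in the coverage statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .genome import GenomeSpec, Role

__all__ = [
    "IdxstatsRow",
    "IdxstatsTable",
    "IdxstatsParseError",
    "MetadataError",
    "read_idxstats",
    "write_idxstats",
    "total_host_reads",
    "missing_scaffolds",
    "ResultRow",
    "RESULT_COLUMNS",
    "results_to_frame",
    "write_results",
    "read_table",
    "amend_metadata",
]

RESULT_COLUMNS = ("sample_id", "total_host_reads", "rx", "ry", "posterior", "call")


class IdxstatsParseError(ValueError):
    """Raised for malformed idxstats input, naming the offending line."""


class MetadataError(ValueError):
    """Raised for metadata tables that cannot be joined unambiguously."""


@dataclass(frozen=True)
class IdxstatsRow:
    length: int
    mapped: int
    unmapped: int


@dataclass
class IdxstatsTable:
    """Per-sample mapped-read counts keyed by reference-sequence name."""

    sample_id: str
    rows: dict[str, IdxstatsRow]

    def mapped(self, chrom_id: str) -> int:
        """Mapped-read count for a chromosome; absent chromosomes count 0."""
        row = self.rows.get(chrom_id)
        return row.mapped if row is not None else 0


def read_idxstats(path: Union[str, Path], sample_id: str | None = None) -> IdxstatsTable:
    """Parse a samtools idxstats file.

    ``sample_id`` defaults to the file stem (``.idxstats``/``.txt``/``.tsv``
    suffixes stripped).
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name
        for suffix in (".idxstats", ".txt", ".tsv"):
            if sample_id.endswith(suffix):
                sample_id = sample_id[: -len(suffix)]
                break
    rows: dict[str, IdxstatsRow] = {}
    n_data = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise IdxstatsParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            name = parts[0]
            try:
                length, mapped, unmapped = (int(p) for p in parts[1:])
            except ValueError as exc:
                raise IdxstatsParseError(f"{path}:{lineno}: non-integer count field") from exc
            if mapped < 0 or unmapped < 0:
                raise IdxstatsParseError(f"{path}:{lineno}: negative count")
            if name != "*" and length <= 0:
                raise IdxstatsParseError(
                    f"{path}:{lineno}: non-positive length for sequence {name!r}"
                )
            if name in rows:
                raise IdxstatsParseError(f"{path}:{lineno}: duplicate sequence {name!r}")
            rows[name] = IdxstatsRow(length=length, mapped=mapped, unmapped=unmapped)
            n_data += 1
    if n_data == 0:
        raise IdxstatsParseError(f"{path}: no data lines")
    return IdxstatsTable(sample_id=sample_id, rows=rows)


def write_idxstats(table: IdxstatsTable, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, row in table.rows.items():
            fh.write(f"{name}\t{row.length}\t{row.mapped}\t{row.unmapped}\n")


def total_host_reads(table: IdxstatsTable, spec: GenomeSpec) -> int:
    """Mapped reads summed over the spec's non-ignored chromosomes.

    Scaffolds present in the table but absent from (or ignored by) the spec
    do not count: the scaffold list is the inclusion filter.
    """
    return sum(
        table.mapped(rec.id) for rec in spec.chromosomes if rec.role is not Role.IGNORED
    )


def missing_scaffolds(table: IdxstatsTable, spec: GenomeSpec) -> list[str]:
    """Spec chromosomes (non-ignored) with no row in the idxstats table."""
    return [
        rec.id
        for rec in spec.chromosomes
        if rec.role is not Role.IGNORED and rec.id not in table.rows
    ]


@dataclass(frozen=True)
class ResultRow:
    """One sample's classification summary.

    ``call`` is one of ``female``, ``male``, ``uncertain`` or
    ``insufficient_reads``; the last is used exactly when
    ``total_host_reads`` falls below the minimum-reads cutoff.  ``rx``,
    ``ry`` and ``posterior`` are ``None`` when undefined and rendered as
    ``NA`` on output.
    """

    sample_id: str
    total_host_reads: int
    rx: float | None
    ry: float | None
    posterior: float | None
    call: str


def _fmt(value: float | None) -> str:
    return "NA" if value is None else repr(float(value))


def results_to_frame(results: Sequence[ResultRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "total_host_reads": [r.total_host_reads for r in results],
            "rx": [None if r.rx is None else float(r.rx) for r in results],
            "ry": [None if r.ry is None else float(r.ry) for r in results],
            "posterior": [None if r.posterior is None else float(r.posterior) for r in results],
            "call": [r.call for r in results],
        },
        columns=list(RESULT_COLUMNS),
    )


def write_results(
    results: Sequence[ResultRow],
    path: Union[str, Path],
    header_lines: Iterable[str] = (),
) -> None:
    """Write the fixed-order TSV result table with optional '#' header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    (
                        r.sample_id,
                        str(r.total_host_reads),
                        _fmt(r.rx),
                        _fmt(r.ry),
                        _fmt(r.posterior),
                        r.call,
                    )
                )
                + "\n"
            )


def _sep_for(path: Union[str, Path], sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_table(path: Union[str, Path], sep: str | None = None) -> pd.DataFrame:
    """Read a delimited metadata table; comma for .csv, tab otherwise."""
    return pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)


def amend_metadata(
    metadata: Union[pd.DataFrame, str, Path],
    results: Sequence[ResultRow],
    id_column: str,
    sep: str | None = None,
) -> pd.DataFrame:
    """Left-join classification results onto a sample metadata table.

    All input rows and columns are preserved; the result columns are
    appended, empty for samples without a result.  Duplicate sample IDs in
    the metadata make the join ambiguous and raise :class:`MetadataError`.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_table(metadata, sep=sep)
    if id_column not in metadata.columns:
        raise MetadataError(f"id column {id_column!r} not in metadata columns")
    dup = metadata[id_column][metadata[id_column].duplicated()].tolist()
    if dup:
        raise MetadataError(f"duplicate sample IDs in metadata: {sorted(set(dup))}")
    by_id = {r.sample_id: r for r in results}
    if len(by_id) != len(results):
        raise MetadataError("duplicate sample IDs in results")
    out = metadata.copy()
    for col in RESULT_COLUMNS[1:]:
        values = []
        for sid in out[id_column]:
            r = by_id.get(sid)
            if r is None:
                values.append("")
            elif col == "total_host_reads":
                values.append(str(r.total_host_reads))
            elif col == "call":
                values.append(r.call)
            else:
                values.append(_fmt(getattr(r, col)))
        out[f"metasex_{col}"] = values
    return out
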