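"""FASTA input and seven-column report output.

Reading is delegated to Biopython's ``SimpleFastaParser`` and wrapped with the
validation this tool needs: sequences are uppercased, RNA ``U`` is converted to
``T``, identifiers are the first whitespace-delimited header token, and records
with empty sequences or non-nucleotide characters are rejected with an error
naming the offending record.

The report mirrors the seven-column layout of the original SSFinder output:
identifier, classification, site_with_pam, start, end, seed_condition,
specific_target.  Two dialects are supported: ``tsv`` (tab separated, also
serving ``.txt``/``.xls`` requests as plain text) and ``csv``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FastaError, ReportError

__all__ = [
    "SequenceRecord",
    "ReportRow",
    "REPORT_COLUMNS",
    "read_fasta",
    "write_fasta",
    "write_report",
    "read_report",
]

# IUPAC nucleotide one-letter codes accepted on ingest (after U -> T).
INGEST_ALPHABET = frozenset("ACGTNRYSWKMBDHV")

REPORT_COLUMNS = (
    "identifier",
    "classification",
    "site_with_pam",
    "start",
    "end",
    "seed_condition",
    "specific_target",
)

_DIALECT_DELIMITERS = {"tsv": "\t", "csv": ","}


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: identifier plus uppercased nucleotide sequence."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.identifier or any(c.isspace() for c in self.identifier):
            raise ValueError(f"invalid sequence identifier: {self.identifier!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReportRow:
    """One output line of the seven-column site report.

    ``specific`` is only populated when a report includes non-specific
    candidates; the default report lists specific sites only and omits it.
    """

    identifier: str
    classification: str
    site_with_pam: str
    start: int
    end: int
    seed_condition: str
    specific_target: str
    specific: bool | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.site_with_pam):
            raise ValueError(
                f"coordinates [{self.start}, {self.end}] do not span "
                f"{len(self.site_with_pam)}-nt site"
            )
        if not self.site_with_pam.startswith(self.specific_target):
            raise ValueError("specific_target must be a prefix of site_with_pam")
        if len(self.site_with_pam) - len(self.specific_target) != 3:
            raise ValueError("site must be the target plus a 3-nt PAM")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased with U converted to T; multi-line bodies are
    concatenated and blank lines ignored.  An all-blank file yields an empty
    list.  Raises :class:`FastaError` for a missing file, for content whose
    first non-blank character is not ``>``, for an empty-sequence record, and
    for characters outside the IUPAC nucleotide alphabet.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"input file not found: {path}")
    with open(path) as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaError(
                    f"not FASTA: first non-blank character of {path} is not '>'"
                )
            break
        else:
            return []
        handle.seek(0)
        records = []
        for title, seq in SimpleFastaParser(handle):
            identifier = title.split()[0] if title.split() else ""
            if not identifier:
                raise FastaError(f"record #{len(records) + 1} in {path} has an empty header")
            seq = seq.upper().replace("U", "T")
            if not seq:
                raise FastaError(f"record {identifier!r} in {path} has an empty sequence")
            bad = set(seq) - INGEST_ALPHABET
            if bad:
                raise FastaError(
                    f"record {identifier!r} contains non-nucleotide "
                    f"character(s): {''.join(sorted(bad))}"
                )
            records.append(SequenceRecord(identifier, seq))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> Path:
    """Write records as FASTA with ``width``-column wrapped bodies."""
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
    return path


def write_report(
    rows: Sequence[ReportRow],
    path: str | Path,
    dialect: str = "tsv",
    include_specific: bool = False,
) -> Path:
    """Write the seven-column report (header + one line per row).

    ``tsv`` uses tab separators, ``csv`` commas with quoting only where a
    field contains the delimiter.  With ``include_specific`` an eighth
    ``specific`` column (true/false) is appended to every line.
    """
    if dialect not in _DIALECT_DELIMITERS:
        raise ReportError(f"unknown report dialect: {dialect!r} (expected tsv or csv)")
    path = Path(path)
    header = REPORT_COLUMNS + (("specific",) if include_specific else ())
    try:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(
                handle, delimiter=_DIALECT_DELIMITERS[dialect], lineterminator="\n"
            )
            writer.writerow(header)
            for row in rows:
                fields = [
                    row.identifier,
                    row.classification,
                    row.site_with_pam,
                    row.start,
                    row.end,
                    row.seed_condition,
                    row.specific_target,
                ]
                if include_specific:
                    fields.append("true" if row.specific else "false")
                writer.writerow(fields)
    except OSError as exc:
        raise ReportError(f"cannot write report to {path}: {exc}") from exc
    return path


def infer_dialect(path: str | Path) -> str:
    """Map an output extension to a report dialect (.csv -> csv, else tsv)."""
    return "csv" if Path(path).suffix.lower() == ".csv" else "tsv"


def read_report(path: str | Path, dialect: str | None = None) -> list[ReportRow]:
    """Parse a report written by :func:`write_report` back into rows."""
    path = Path(path)
    if dialect is None:
        dialect = infer_dialect(path)
    if dialect not in _DIALECT_DELIMITERS:
        raise ReportError(f"unknown report dialect: {dialect!r}")
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter=_DIALECT_DELIMITERS[dialect])
        try:
            header = next(reader)
        except StopIteration:
            raise ReportError(f"report {path} is empty (no header)") from None
        if tuple(header[: len(REPORT_COLUMNS)]) != REPORT_COLUMNS:
            raise ReportError(f"unexpected report header in {path}: {header}")
        has_specific = len(header) > len(REPORT_COLUMNS)
        rows = []
        for fields in reader:
            specific = None
            if has_specific:
                specific = fields[7].strip().lower() == "true"
            rows.append(
                ReportRow(
                    identifier=fields[0],
                    classification=fields[1],
                    site_with_pam=fields[2],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    seed_condition=fields[5],
                    specific_target=fields[6],
                    specific=specific,
                )
            )
    return rows
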