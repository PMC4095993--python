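"""Run-level summary statistics for a scan.

The headline numbers of a run: how many candidate sites were found, how many
are specific, how many sequences carry (specific) sites, and the mean spacing
between specific sites.  Spacing is defined as the start-to-start difference
of consecutive specific sites within each sequence, with all gaps pooled
across sequences and weighted equally; it is undefined (None, serialized as
``NA``) when no sequence holds two specific sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .scan import CandidateSite
from .seqio import ReportRow, SequenceRecord

__all__ = ["SiteStatistics", "summarize", "summarize_rows", "write_stats", "read_stats"]


@dataclass(frozen=True)
class SiteStatistics:
    total_sites: int
    specific_sites: int
    sequences_with_sites: int
    sequences_with_specific_sites: int
    mean_specific_spacing: float | None

    def format(self) -> str:
        spacing = (
            "NA"
            if self.mean_specific_spacing is None
            else f"{self.mean_specific_spacing:.6g}"
        )
        return "\n".join(
            [
                f"total_sites: {self.total_sites}",
                f"specific_sites: {self.specific_sites}",
                f"sequences_with_sites: {self.sequences_with_sites}",
                f"sequences_with_specific_sites: {self.sequences_with_specific_sites}",
                f"mean_specific_spacing: {spacing}",
            ]
        )


def _summarize(
    items: Sequence[tuple[str, int, bool]],
) -> SiteStatistics:
    """Shared tally over (sequence_id, start, specific) triples."""
    seq_with_sites: set[str] = set()
    seq_with_specific: set[str] = set()
    specific_starts: dict[str, list[int]] = {}
    n_specific = 0
    for seq_id, start, specific in items:
        seq_with_sites.add(seq_id)
        if specific:
            n_specific += 1
            seq_with_specific.add(seq_id)
            specific_starts.setdefault(seq_id, []).append(start)
    gaps: list[int] = []
    for starts in specific_starts.values():
        starts.sort()
        gaps.extend(b - a for a, b in zip(starts, starts[1:]))
    return SiteStatistics(
        total_sites=len(items),
        specific_sites=n_specific,
        sequences_with_sites=len(seq_with_sites),
        sequences_with_specific_sites=len(seq_with_specific),
        mean_specific_spacing=sum(gaps) / len(gaps) if gaps else None,
    )


def summarize(
    candidates: Sequence[CandidateSite],
    records: Sequence[SequenceRecord] | None = None,
) -> SiteStatistics:
    """Summarize a marked candidate set covering all records of a run."""
    stats = _summarize(
        [(c.sequence_id, c.start, bool(c.specific)) for c in candidates]
    )
    if records is not None and stats.sequences_with_sites > len(records):
        raise ValueError("candidates reference more sequences than records supplied")
    return stats


def summarize_rows(rows: Sequence[ReportRow]) -> SiteStatistics:
    """Recompute statistics from report rows.

    Rows without a ``specific`` column come from a specific-only report and
    are treated as specific.  Only an all-sites report (written with the
    specificity column) can reproduce the total-site numbers of the run.
    """
    return _summarize(
        [
            (r.identifier, r.start, True if r.specific is None else r.specific)
            for r in rows
        ]
    )


def write_stats(stats: SiteStatistics, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(stats.format() + "\n")
    return path


def read_stats(path: str | Path) -> SiteStatistics:
    """Parse a ``key: value`` statistics file written by :func:`write_stats`."""
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            key, _, value = line.partition(":")
            values[key.strip()] = value.strip()
    spacing = values["mean_specific_spacing"]
    return SiteStatistics(
        total_sites=int(values["total_sites"]),
        specific_sites=int(values["specific_sites"]),
        sequences_with_sites=int(values["sequences_with_sites"]),
        sequences_with_specific_sites=int(values["sequences_with_specific_sites"]),
        mean_specific_spacing=None if spacing == "NA" else float(spacing),
    )
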