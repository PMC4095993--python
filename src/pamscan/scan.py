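"""Candidate-site enumeration and spacer classification.

A candidate CRISPR-Cas9 target site is a 23-nt window whose last three
nucleotides are an NGG protospacer-adjacent motif (PAM): 20-nt spacer, then
one arbitrary base, then GG.  The scanner slides the window one nucleotide at
a time along the forward strand; overlapping sites are all reported, and any
window containing a non-ACGT character (including N) is rejected outright —
a seed with ambiguity codes cannot be meaningfully tested for uniqueness.

Spacers are partitioned into four groups by their first and twentieth
nucleotides, strong (S = G/C) versus weak (W = A/T):

====== ====================== =========================
group  classification label   seed-condition label
====== ====================== =========================
SS     G/C_N18_G/C            G/C_N7_S11_G/C
SW     G/C_N18_A/T            G/C_N7_S11_A/T
WW     A/T_N18_A/T            A/T_N7_S11_A/T
WS     A/T_N18_G/C            A/T_N7_S11_G/C
====== ====================== =========================

Labels are whitespace-free tokens so TSV/CSV fields never need quoting; N18
reads "18 unconstrained inner spacer bases", N7_S11 "7 unconstrained bases
then the 11 inner bases of the seed", matching the conventional motif
notation for these four spacer classes.

All reported coordinates are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

from .errors import PamscanError
from .seqio import ReportRow, SequenceRecord

__all__ = [
    "ScanConfig",
    "CandidateSite",
    "DEFAULT_CONFIG",
    "GROUPS",
    "CLASSIFICATION_LABELS",
    "SEED_CONDITION_LABELS",
    "scan_candidates",
    "classify_spacer",
    "extract_seed",
    "to_report_row",
]

GROUPS = ("SS", "SW", "WW", "WS")

CLASSIFICATION_LABELS = {
    "SS": "G/C_N18_G/C",
    "SW": "G/C_N18_A/T",
    "WW": "A/T_N18_A/T",
    "WS": "A/T_N18_G/C",
}

SEED_CONDITION_LABELS = {
    "SS": "G/C_N7_S11_G/C",
    "SW": "G/C_N7_S11_A/T",
    "WW": "A/T_N7_S11_A/T",
    "WS": "A/T_N7_S11_G/C",
}

_STRONG = frozenset("GC")
_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class ScanConfig:
    """Scanner geometry: 20-nt spacer + NGG PAM = 23-nt window, 12-nt seed.

    Only forward-strand scanning over strict A/C/G/T windows is supported;
    the fields exist so the contract is explicit and validated, not to offer
    alternative chemistries.
    """

    window_length: int = 23
    spacer_length: int = 20
    seed_length: int = 12
    pam_suffix: str = "NGG"
    strand_mode: str = "forward"
    alphabet_policy: str = "strict_acgt"

    def __post_init__(self) -> None:
        if self.window_length != self.spacer_length + len(self.pam_suffix):
            raise ValueError("window_length must equal spacer_length + PAM length")
        if not 0 < self.seed_length <= self.spacer_length:
            raise ValueError("seed_length must be in 1..spacer_length")
        if set(self.pam_suffix) - (_ACGT | {"N"}):
            raise ValueError(f"invalid PAM pattern: {self.pam_suffix!r}")
        if self.strand_mode != "forward":
            raise ValueError("only forward-strand scanning is supported")
        if self.alphabet_policy != "strict_acgt":
            raise ValueError("only the strict_acgt alphabet policy is supported")


DEFAULT_CONFIG = ScanConfig()


@dataclass
class CandidateSite:
    """One PAM-bearing window, with 1-based inclusive coordinates.

    ``specific`` is None until the seed index marks the site (True when its
    12-nt seed occurs exactly once in the whole input dataset).
    """

    sequence_id: str
    start: int
    end: int
    site_with_pam: str
    spacer: str
    seed: str
    group: str
    specific: bool | None = field(default=None, compare=False)


@lru_cache(maxsize=8)
def _window_pattern(config: ScanConfig) -> re.Pattern[str]:
    # Lookahead makes overlapping windows all match; group 1 is the window.
    pam = "".join("[ACGT]" if c == "N" else c for c in config.pam_suffix)
    return re.compile(rf"(?=([ACGT]{{{config.spacer_length}}}{pam}))")


def classify_spacer(spacer: str, config: ScanConfig = DEFAULT_CONFIG) -> str:
    """Return the spacer's group code (SS/SW/WW/WS) from its end nucleotides."""
    if len(spacer) != config.spacer_length:
        raise ValueError(
            f"spacer must be {config.spacer_length} nt, got {len(spacer)}"
        )
    if set(spacer) - _ACGT:
        raise ValueError(f"spacer contains non-ACGT characters: {spacer!r}")
    first = "S" if spacer[0] in _STRONG else "W"
    last = "S" if spacer[-1] in _STRONG else "W"
    return first + last


def extract_seed(
    site: "CandidateSite | str", config: ScanConfig = DEFAULT_CONFIG
) -> str:
    """Seed = the 3'-most ``seed_length`` nt of the spacer (positions 9-20)."""
    spacer = site.spacer if isinstance(site, CandidateSite) else site
    return spacer[-config.seed_length :]


def scan_candidates(
    record: SequenceRecord, config: ScanConfig = DEFAULT_CONFIG
) -> list[CandidateSite]:
    """Enumerate all candidate sites of a record, ordered by start position.

    Every offset whose 23-nt window is ACGT-only and ends in GG (the NGG PAM)
    yields one site; overlapping and bookended sites are all reported.  Short
    or PAM-free sequences simply yield an empty list.
    """
    sites = []
    for match in _window_pattern(config).finditer(record.sequence):
        window = match.group(1)
        spacer = window[: config.spacer_length]
        sites.append(
            CandidateSite(
                sequence_id=record.identifier,
                start=match.start() + 1,
                end=match.start() + config.window_length,
                site_with_pam=window,
                spacer=spacer,
                seed=spacer[-config.seed_length :],
                group=classify_spacer(spacer, config),
            )
        )
    return sites


def to_report_row(site: CandidateSite) -> ReportRow:
    """Convert a candidate site into a seven-column report row."""
    if site.group not in CLASSIFICATION_LABELS:
        raise PamscanError(f"unknown spacer group: {site.group!r}")
    return ReportRow(
        identifier=site.sequence_id,
        classification=CLASSIFICATION_LABELS[site.group],
        site_with_pam=site.site_with_pam,
        start=site.start,
        end=site.end,
        seed_condition=SEED_CONDITION_LABELS[site.group],
        specific_target=site.spacer,
        specific=site.specific,
    )
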