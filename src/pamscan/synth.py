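"""Synthetic FASTA datasets with planted ground truth, plus brute-force oracles.

The generator draws i.i.d. background sequence at a chosen GC fraction and
plants non-overlapping 23-nt PAM-bearing windows of two kinds:

``unique_seed``
    A site whose 12-nt seed is verified (after assembly) to occur nowhere
    else in the whole dataset, so a correct pipeline must flag it specific.
``duplicated_seed``
    Pairs of sites sharing one seed but carrying distinct 8-nt prefixes —
    two different 23-mers whose seeds collide, so both must be flagged
    non-specific.  This exercises seed-level, not site-level, uniqueness.

Uniqueness of planted seeds is guaranteed by post-hoc verification against
the final assembled sequences (colliding plants are redrawn), so the truth
table is exact, not probabilistic.  Generation is fully deterministic given
``rng_seed``.

The oracles (:func:`oracle_scan`, :func:`oracle_count_substring`) examine
every offset independently with direct character comparisons — no regex, no
encoding, no shared state — and exist solely to cross-check the production
scanner and seed index in tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import SynthSpecError
from .seqio import SequenceRecord, write_fasta

__all__ = [
    "SynthSpec",
    "TruthRecord",
    "generate_records",
    "generate",
    "oracle_scan",
    "oracle_count_substring",
]

_WINDOW = 23
_SEED_LEN = 12
_PREFIX_LEN = 8  # spacer positions 1-8, upstream of the seed
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic dataset."""

    n_sequences: int = 1
    length_per_sequence: int = 100_000
    gc_fraction: float = 0.5
    n_planted_unique_sites: int = 0
    n_planted_duplicate_seed_pairs: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise SynthSpecError("gc_fraction must be in [0, 1]")
        if self.n_sequences < 1 or self.length_per_sequence < 1:
            raise SynthSpecError("need at least one sequence of positive length")


@dataclass(frozen=True)
class TruthRecord:
    """Where a site was planted and which kind it is (start is 1-based)."""

    sequence_id: str
    start: int
    planted_kind: str  # unique_seed | duplicated_seed


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(_BASES, size=n, p=p))


def _random_site(rng: np.random.Generator) -> str:
    """A random 23-mer ending in GG (uniform over the 21 free positions)."""
    return "".join(rng.choice(_BASES, size=_WINDOW - 2)) + "GG"


def _site_from_seed(rng: np.random.Generator, seed: str) -> str:
    prefix = "".join(rng.choice(_BASES, size=_PREFIX_LEN))
    pam_n = str(rng.choice(_BASES))
    return prefix + seed + pam_n + "GG"


def generate_records(
    spec: SynthSpec,
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Build the dataset in memory; deterministic given ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    n_plants = spec.n_planted_unique_sites + 2 * spec.n_planted_duplicate_seed_pairs

    # Round-robin assignment of plant slots to sequences, then non-overlapping
    # positions per sequence via the gaps construction.
    per_seq = [0] * spec.n_sequences
    for i in range(n_plants):
        per_seq[i % spec.n_sequences] += 1
    if any(m * _WINDOW > spec.length_per_sequence for m in per_seq):
        raise SynthSpecError(
            f"{n_plants} planted windows of {_WINDOW} nt do not fit in "
            f"{spec.n_sequences} x {spec.length_per_sequence} nt"
        )
    slots: list[tuple[int, int]] = []  # (sequence index, 0-based start)
    for seq_idx, m in enumerate(per_seq):
        if m == 0:
            continue
        extra = spec.length_per_sequence - m * _WINDOW
        cuts = np.sort(rng.integers(0, extra + 1, size=m))
        for rank, cut in enumerate(cuts):
            slots.append((seq_idx, int(cut) + rank * _WINDOW))

    # Plant contents: unique sites first, then the duplicate pairs.
    kinds: list[str] = []
    sites: list[str] = []
    for _ in range(spec.n_planted_unique_sites):
        kinds.append("unique_seed")
        sites.append(_random_site(rng))
    for _ in range(spec.n_planted_duplicate_seed_pairs):
        seed = "".join(rng.choice(_BASES, size=_SEED_LEN))
        first = _site_from_seed(rng, seed)
        second = _site_from_seed(rng, seed)
        while second[:_PREFIX_LEN] == first[:_PREFIX_LEN]:
            second = _site_from_seed(rng, seed)
        kinds.extend(["duplicated_seed", "duplicated_seed"])
        sites.extend([first, second])

    sequences = [
        list(_random_bases(rng, spec.length_per_sequence, spec.gc_fraction))
        for _ in range(spec.n_sequences)
    ]

    def install(plant_idx: int) -> None:
        seq_idx, pos = slots[plant_idx]
        sequences[seq_idx][pos : pos + _WINDOW] = sites[plant_idx]

    for i in range(n_plants):
        install(i)

    # Post-hoc verification: every unique-seed plant's seed must occur exactly
    # once dataset-wide (junction windows and background included). Redraw
    # colliding plants until the truth table is exact.
    def seed_of(site: str) -> str:
        return site[_PREFIX_LEN : _PREFIX_LEN + _SEED_LEN]

    for _ in range(100):
        texts = ["".join(chars) for chars in sequences]
        colliding = [
            i
            for i in range(spec.n_planted_unique_sites)
            if sum(oracle_count_substring(t, seed_of(sites[i])) for t in texts) != 1
        ]
        if not colliding:
            break
        for i in colliding:
            sites[i] = _random_site(rng)
            install(i)
    else:  # pragma: no cover - 4^12 seed space makes this unreachable
        raise SynthSpecError("could not place unique seeds without collision")

    records = [
        SequenceRecord(f"synth_{i + 1}", "".join(chars))
        for i, chars in enumerate(sequences)
    ]
    truths = [
        TruthRecord(records[slots[i][0]].identifier, slots[i][1] + 1, kinds[i])
        for i in range(n_plants)
    ]
    truths.sort(key=lambda t: (t.sequence_id, t.start))
    return records, truths


def generate(
    spec: SynthSpec,
    fasta_path: str | Path,
    truth_path: str | Path | None = None,
) -> tuple[Path, list[TruthRecord]]:
    """Write the dataset as FASTA (plus an optional TSV truth table)."""
    records, truths = generate_records(spec)
    fasta_path = write_fasta(records, fasta_path)
    if truth_path is not None:
        with open(truth_path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["sequence_id", "start", "planted_kind"])
            for t in truths:
                writer.writerow([t.sequence_id, t.start, t.planted_kind])
    return fasta_path, truths


def oracle_scan(sequence: str) -> list[tuple[int, str]]:
    """Naive reference scanner: every offset checked independently.

    Returns (1-based start, 23-mer window) for each ACGT-only window whose
    last two characters are GG.  Intentionally O(L * 23).
    """
    hits = []
    for i in range(len(sequence) - _WINDOW + 1):
        window = sequence[i : i + _WINDOW]
        ok = window[-2] == "G" and window[-1] == "G"
        if ok:
            for ch in window:
                if ch not in "ACGT":
                    ok = False
                    break
        if ok:
            hits.append((i + 1, window))
    return hits


def oracle_count_substring(haystack: str, needle: str) -> int:
    """Overlapping substring occurrences by per-offset comparison."""
    count = 0
    pos = haystack.find(needle)
    while pos != -1:
        count += 1
        pos = haystack.find(needle, pos + 1)
    return count
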