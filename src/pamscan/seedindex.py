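"""Dataset-wide 12-mer seed counting and specificity marking.

A candidate site is *specific* when its 12-nt seed occurs exactly once in the
entire input dataset.  Two notions of "occurs" are supported:

``substring``
    Count every (overlapping) forward-strand occurrence of the seed as a
    substring of every input sequence.  This is the default and the stricter
    reading: a seed repeated outside any PAM context still disqualifies a
    site.
``candidate``
    Count only how many candidate sites carry the seed, i.e. uniqueness among
    PAM-bearing windows.

Substring counting is done with a dense numpy histogram over all 4^12
2-bit-encoded 12-mers (one pass per sequence), so peak memory is bounded by
O(4^12) counters regardless of input size — a whole chromosome streams
through on a laptop.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .scan import CandidateSite
from .seqio import SequenceRecord

__all__ = [
    "SeedIndex",
    "encode_kmer",
    "decode_kmer",
    "count_kmers_dense",
    "build_seed_index",
    "mark_specific",
]

MODES = ("substring", "candidate")

_BASES = "ACGT"
_CODE = {base: code for code, base in enumerate(_BASES)}

# ASCII -> 2-bit base code; 255 marks any non-ACGT byte.
_LUT = np.full(256, 255, dtype=np.uint8)
for _base, _code in _CODE.items():
    _LUT[ord(_base)] = _code


def encode_kmer(kmer: str) -> int:
    """Encode an ACGT k-mer as a big-endian base-4 integer (A=0..T=3)."""
    code = 0
    try:
        for base in kmer:
            code = (code << 2) | _CODE[base]
    except KeyError as exc:
        raise ValueError(f"non-ACGT character in k-mer: {kmer!r}") from exc
    return code


def decode_kmer(code: int, k: int) -> str:
    """Invert :func:`encode_kmer` for a k-mer of length ``k``."""
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    bases = []
    for _ in range(k):
        bases.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(bases))


def count_kmers_dense(sequences: Iterable[str], k: int) -> np.ndarray:
    """Dense occurrence counts of every ACGT ``k``-mer across ``sequences``.

    Overlapping occurrences count; windows containing a non-ACGT character
    are skipped.  Returns an int64 array of length 4**k indexed by
    :func:`encode_kmer`.
    """
    total = np.zeros(4**k, dtype=np.int64)
    for seq in sequences:
        n = len(seq) - k + 1
        if n <= 0:
            continue
        codes = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        valid = codes < 4
        acc = np.zeros(n, dtype=np.int64)
        ok = np.ones(n, dtype=bool)
        for j in range(k):
            acc = (acc << 2) | codes[j : j + n]
            ok &= valid[j : j + n]
        total += np.bincount(acc[ok], minlength=4**k)
    return total


@dataclass(frozen=True)
class SeedIndex:
    """Occurrence counts for the seeds of one candidate set.

    ``counts`` maps each distinct candidate seed to its dataset-wide count
    under the index's ``mode``; every key present has count >= 1.
    """

    mode: str
    counts: dict[str, int]

    def count(self, seed: str) -> int:
        if seed not in self.counts:
            raise ValueError(f"seed {seed!r} is not in the index")
        return self.counts[seed]


def build_seed_index(
    records: Sequence[SequenceRecord],
    candidates: Sequence[CandidateSite],
    mode: str = "substring",
) -> SeedIndex:
    """Count the occurrences of every candidate seed across the whole dataset.

    The index always spans the ENTIRE record collection — uniqueness is a
    dataset-level property, never per-sequence.
    """
    if mode not in MODES:
        raise ValueError(f"unknown uniqueness mode: {mode!r} (expected {MODES})")
    if candidates and not records:
        raise ValueError("candidates supplied without the records they came from")
    seeds = {site.seed for site in candidates}
    if not seeds:
        return SeedIndex(mode, {})
    if mode == "candidate":
        return SeedIndex(mode, dict(Counter(site.seed for site in candidates)))
    k = len(next(iter(seeds)))
    dense = count_kmers_dense((rec.sequence for rec in records), k)
    return SeedIndex(mode, {seed: int(dense[encode_kmer(seed)]) for seed in seeds})


def mark_specific(
    candidates: Sequence[CandidateSite], index: SeedIndex
) -> Sequence[CandidateSite]:
    """Set ``specific`` on every candidate (seed count == 1) and return them.

    Order is preserved and non-specific sites are kept, so callers can report
    totals and specifics separately.  A seed absent from the index means the
    index was built over a different candidate set and raises ``ValueError``.
    """
    for site in candidates:
        site.specific = index.count(site.seed) == 1
    return candidates
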