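"""Canonical k-mer counting and k-mer-spectrum genome-size estimation.

The survey estimator: count every k-mer occurrence in the clean reads
(K_num), locate the main peak of the k-mer depth histogram (K_depth),
and estimate the genome size as ``G = K_num // K_depth`` (floor integer
division). The sequencing depth of the clean data is then
``clean_bases // G``.

Counting is exact and strand-symmetric: each window over {A,C,G,T} is
counted under its canonical form, the lexicographic minimum of the k-mer
and its reverse complement. Windows containing N (or any other symbol)
are skipped and excluded from K_num. k must be odd so canonicalisation
never ties on a palindrome. The counter packs k-mers into 2-bit codes in
uint64 and streams reads in bounded batches, so memory stays proportional
to the number of distinct k-mers, not to the read set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np

from .seq_io import SeqRecord

__all__ = [
    "KmerHistogram",
    "GenomeSizeEstimate",
    "count_kmers",
    "find_peak_depth",
    "estimate_genome_size",
]

# A..Z lookup: A,C,G,T -> 0..3, everything else (incl. N) -> 4 (invalid)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BATCH_BASES = 8_000_000


@dataclass
class KmerHistogram:
    """Depth histogram of distinct canonical k-mers plus total occurrences."""

    k: int
    counts: Dict[int, int] = field(default_factory=dict)
    k_num: int = 0

    def mass(self) -> int:
        """Total occurrences implied by the histogram: sum of depth*count."""
        return sum(d * c for d, c in self.counts.items())

    def n_distinct(self) -> int:
        return sum(self.counts.values())


@dataclass
class GenomeSizeEstimate:
    k_depth: int
    genome_size: int
    clean_bases: int
    depth_x: int

    @property
    def genome_size_gb(self) -> float:
        """Genome size in Gb, rounded to one decimal."""
        return round(self.genome_size / 1e9, 1)


def _encode_batch(seqs: list[str], k: int) -> Tuple[np.ndarray, int]:
    """Canonical uint64 codes of all valid k-mer windows in a batch of reads.

    Reads are joined with a sentinel (invalid) byte so windows never span
    two reads. Returns (codes, n_valid_windows).
    """
    blob = b"\xff".join(s.encode("ascii") for s in seqs)
    b = _CODE[np.frombuffer(blob, dtype=np.uint8)]
    n = b.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), 0
    # windows containing any invalid base are masked out
    bad = (b >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    b64 = b.astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd <<= np.uint64(2)
        fwd |= b64[j : j + m]
    comp = (np.uint64(3) - b64) & np.uint64(3)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):  # reverse complement read in the opposite direction
        rev |= comp[j : j + m] << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)[valid]
    return canon, int(canon.size)


def count_kmers(reads: Iterable[SeqRecord], k: int = 17) -> KmerHistogram:
    """Exact canonical k-mer depth histogram of a read stream.

    Reads shorter than k are skipped. Raises for even k (a canonical
    palindrome could tie) or k outside [3, 31] (the 2-bit uint64 packing).
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if not 3 <= k <= 31:
        raise ValueError(f"k must be in [3, 31], got {k}")

    partial: Dict[int, int] = {}
    k_num = 0
    batch: list[str] = []
    batch_bases = 0

    def flush() -> None:
        nonlocal k_num, batch_bases
        if not batch:
            return
        codes, nwin = _encode_batch(batch, k)
        k_num += nwin
        if nwin:
            uniq, cnt = np.unique(codes, return_counts=True)
            for code, c in zip(uniq.tolist(), cnt.tolist()):
                partial[code] = partial.get(code, 0) + c
        batch.clear()
        batch_bases = 0

    for read in reads:
        if len(read.seq) < k:
            continue
        batch.append(read.seq)
        batch_bases += len(read.seq)
        if batch_bases >= _BATCH_BASES:
            flush()
    flush()

    hist = KmerHistogram(k=k, k_num=k_num)
    if partial:
        depths, ncounts = np.unique(
            np.fromiter(partial.values(), dtype=np.int64, count=len(partial)),
            return_counts=True,
        )
        hist.counts = {int(d): int(c) for d, c in zip(depths, ncounts)}
    return hist


def find_peak_depth(hist: KmerHistogram, min_valley_depth: int = 2) -> Tuple[int, bool]:
    """Main-peak depth of a k-mer histogram, past the sequencing-error slope.

    Scanning depths in ascending order (absent depths count 0), the error
    valley is the first depth ``v >= min_valley_depth`` with
    ``counts[v] < counts[v+1]``; the peak is the argmax of counts over
    depths > v. A monotone-decreasing histogram has no such valley: the
    global argmax is returned with ``low_confidence=True``.

    Returns ``(k_depth, low_confidence)``.
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    max_d = max(hist.counts)
    dense = np.zeros(max_d + 2, dtype=np.int64)
    for d, c in hist.counts.items():
        dense[d] = c
    valley = None
    # the error slope can only start at an observed depth
    for v in range(max(min_valley_depth, min(hist.counts)), max_d):
        if dense[v] < dense[v + 1]:
            valley = v
            break
    if valley is None:
        return int(np.argmax(dense)), True
    sub = dense[valley + 1 :]
    return valley + 1 + int(np.argmax(sub)), False


def estimate_genome_size(k_num: int, k_depth: int, clean_bases: int) -> GenomeSizeEstimate:
    """Genome size and sequencing depth from k-mer totals.

    genome_size = k_num // k_depth and depth_x = clean_bases // genome_size,
    both floor divisions on exact integers.
    """
    if k_depth < 1:
        raise ValueError(f"k_depth must be >= 1, got {k_depth}")
    genome_size = k_num // k_depth
    if genome_size == 0:
        raise ValueError("estimated genome size is zero; k_num < k_depth")
    depth_x = clean_bases // genome_size
    return GenomeSizeEstimate(
        k_depth=k_depth,
        genome_size=genome_size,
        clean_bases=clean_bases,
        depth_x=depth_x,
    )
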