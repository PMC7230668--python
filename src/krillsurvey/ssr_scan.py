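"""Perfect microsatellite (SSR) detection and length-class summaries.

Finds every maximal perfect tandem repeat of a 2-6 bp motif in nucleotide
sequences (MISA-convention minimum repeat counts: di >= 6, tri/tetra/
penta/hexa >= 5), resolves overlaps between motif-length classes, and
summarises counts per class (di- through hexanucleotide).

Conventions: only whole motif copies count toward a tract (a trailing
partial copy neither extends nor shifts it); the reported motif is the
lexicographically smallest cyclic rotation of the as-found motif; motifs
that are themselves periodic (e.g. ACAC) are never reported — the repeat
surfaces in its primitive class instead. N breaks any tract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np

from .seq_io import SeqRecord

__all__ = [
    "SSRRecord",
    "SSRSummary",
    "DEFAULT_MIN_REPEATS",
    "scan_ssrs",
    "summarize_ssrs",
    "canonical_motif",
    "is_primitive",
]

DEFAULT_MIN_REPEATS: Dict[int, int] = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

_CLASS_NAMES = {2: "Di", 3: "Tri", 4: "Tetra", 5: "Penta", 6: "Hexa"}

_ACGT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ACGT[_b] = _i

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter unit."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def canonical_motif(motif: str, merge_revcomp: bool = False) -> str:
    """Lexicographically smallest cyclic rotation (optionally over both strands)."""
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    if merge_revcomp:
        rc = _revcomp(motif)
        rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


@dataclass(frozen=True)
class SSRRecord:
    """One perfect tandem repeat; start/end are 1-based inclusive."""

    seq_id: str
    motif: str
    motif_len: int
    repeats: int
    start: int
    end: int
    tract: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.motif_len * self.repeats:
            raise ValueError(
                f"span [{self.start},{self.end}] inconsistent with "
                f"{self.repeats} x {self.motif_len} bp motif"
            )


@dataclass
class SSRSummary:
    counts: Dict[int, int]
    percentages: Dict[int, float]
    total: int

    def rows(self) -> List[tuple[str, int, float]]:
        """(class name, count, percentage) rows ordered Di..Hexa."""
        return [
            (_CLASS_NAMES[m], self.counts[m], self.percentages[m])
            for m in sorted(_CLASS_NAMES)
        ]


def _candidates_for_motif_len(seq: str, codes: np.ndarray, m: int, min_rep: int):
    """Maximal perfect tandem tracts of period m as (start0, copies, tract)."""
    n = codes.size
    if n < 2 * m:
        return
    # eq[i]: position i matches position i+m and both are unambiguous bases
    eq = (codes[:-m] == codes[m:]) & (codes[:-m] < 4) & (codes[m:] < 4)
    if not eq.any():
        return
    # maximal runs of eq
    padded = np.concatenate(([False], eq, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    for a, b in zip(edges[::2].tolist(), edges[1::2].tolist()):
        copies = (b - a + m) // m
        if copies < min_rep:
            continue
        motif = seq[a : a + m]
        if not is_primitive(motif):
            continue
        yield a, copies, seq[a : a + copies * m]


def scan_ssrs(
    seqs: Iterable[SeqRecord],
    min_repeats: Optional[Dict[int, int]] = None,
    merge_revcomp: bool = False,
) -> List[SSRRecord]:
    """Scan sequences for perfect SSRs of motif length 2-6.

    Overlapping candidates from different motif-length classes are
    resolved greedily: longer tract first, then smaller motif, then
    leftmost. ``merge_revcomp=True`` folds reverse-complement motifs into
    one canonical name (AC == GT); off by default.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    bad = set(min_repeats) - set(_CLASS_NAMES)
    if bad:
        raise ValueError(f"motif lengths must be in 2..6, got {sorted(bad)}")

    out: List[SSRRecord] = []
    for rec in seqs:
        seq = rec.seq
        codes = _ACGT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        cands = []
        for m, min_rep in sorted(min_repeats.items()):
            for a, copies, tract in _candidates_for_motif_len(seq, codes, m, min_rep):
                cands.append((a, m, copies, tract))
        # greedy: longest tract, then smallest motif, then leftmost
        cands.sort(key=lambda c: (-len(c[3]), c[1], c[0]))
        taken: List[tuple[int, int]] = []
        chosen = []
        for a, m, copies, tract in cands:
            end0 = a + len(tract) - 1
            if any(a <= t_end and end0 >= t_start for t_start, t_end in taken):
                continue
            taken.append((a, end0))
            chosen.append((a, m, copies, tract))
        for a, m, copies, tract in sorted(chosen):
            out.append(
                SSRRecord(
                    seq_id=rec.id,
                    motif=canonical_motif(tract[:m], merge_revcomp),
                    motif_len=m,
                    repeats=copies,
                    start=a + 1,
                    end=a + copies * m,
                    tract=tract,
                )
            )
    return out


def summarize_ssrs(records: Iterable[SSRRecord]) -> SSRSummary:
    """Count SSRs per motif-length class, with percentages of the total."""
    counts = {m: 0 for m in _CLASS_NAMES}
    for rec in records:
        counts[rec.motif_len] += 1
    total = sum(counts.values())
    percentages = {
        m: (100.0 * c / total if total else 0.0) for m, c in counts.items()
    }
    return SSRSummary(counts=counts, percentages=percentages, total=total)
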