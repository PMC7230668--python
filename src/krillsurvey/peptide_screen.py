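"""Translated homology screening and bioactive-peptide mining.

Four pieces, shared by the transcriptome/genome screens and the
mitochondrial pipeline:

* ORF extraction over all six reading frames (ATG-initiated, plus
  open-ended ORFs at sequence edges), translated with the standard code;
* an exact local protein aligner: Smith-Waterman with affine gaps over
  BLOSUM62 (a gap of length g costs gap_open + gap_extend*(g-1)) and a
  Karlin-Altschul bit-score/E-value layer — the exhaustive stand-in for
  a translated BLAST search at desk scale;
* the antimicrobial-peptide (AMP) homology screen: every reference
  peptide against every target protein or six-frame-translated contig,
  keeping hits with E <= 1e-5 and a query-align ratio >= 0.5;
* the antihypertensive-peptide (AHTP) mapper: exact substring search of
  short (2-10 aa) peptides against a proteome, overlapping occurrences
  included.

The aligner's dynamic programming is delegated to Biopython's
PairwiseAligner (exact, not heuristic); scoring conventions, spans,
ratios and E-values are defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq as _BioSeq

from .seq_io import SeqRecord

__all__ = [
    "ORF",
    "AMPReference",
    "AlignmentHit",
    "AHTPHit",
    "find_orfs",
    "six_frame_segments",
    "local_align",
    "screen_amps",
    "map_ahtps",
    "load_amp_reference",
]

# Gapped Karlin-Altschul constants for BLOSUM62 with open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_MATRIX_ALPHABET = set(_BLOSUM62.alphabet)

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _sanitize_protein(seq: str) -> str:
    """Uppercase and map residues outside the BLOSUM62 alphabet to X."""
    seq = seq.upper()
    if set(seq) <= _MATRIX_ALPHABET:
        return seq
    return "".join(c if c in _MATRIX_ALPHABET else "X" for c in seq)


def _make_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = _BLOSUM62
    # first gap residue costs open, each further residue extend
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class ORF:
    """An open reading frame; nucleotide span is 1-based inclusive on the
    forward strand and includes the stop codon when one terminates the ORF."""

    frame: int  # +1,+2,+3,-1,-2,-3
    start: int
    end: int
    protein: str
    has_start: bool
    has_stop: bool
    longest: bool = False


@dataclass
class AMPReference:
    """Curated antimicrobial-peptide list: (id, family label, sequence)."""

    entries: List[Tuple[str, str, str]]

    def __post_init__(self) -> None:
        for pid, family, seq in self.entries:
            if not family:
                raise ValueError(f"AMP {pid!r}: family label must be non-empty")
            if not seq:
                raise ValueError(f"AMP {pid!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a reference peptide against a target.

    ``frame`` is None for protein targets, else the reading frame of the
    translated contig segment. Spans are 1-based inclusive: the query
    span in query residues; the target span in residues of the aligned
    protein (for translated segments, of the full-frame translation).
    """

    query_id: str
    target_id: str
    frame: Optional[int]
    raw_score: int
    bit_score: float
    evalue: float
    query_span: Tuple[int, int]
    target_span: Tuple[int, int]
    query_align_ratio: float
    identity: float


@dataclass(frozen=True)
class AHTPHit:
    peptide: str
    protein_id: str
    start: int  # 1-based inclusive
    end: int


def _translate(nt: str, table: int) -> str:
    usable = len(nt) - len(nt) % 3
    return str(_BioSeq(nt[:usable]).translate(table=table))


def find_orfs(transcript: SeqRecord, min_aa: int = 100, table: int = 1) -> List[ORF]:
    """ORFs of at least ``min_aa`` residues on all six frames.

    Within each stop-delimited stretch of a frame the ORF starts at the
    first ATG; a stretch flush with the sequence edge also yields an
    open-ended ORF starting at the frame's first codon. The single
    longest ORF of the transcript is flagged.
    """
    nt = transcript.seq.upper()
    L = len(nt)
    orfs: List[ORF] = []
    for strand, seq in ((1, nt), (-1, _revcomp(nt))):
        for off in range(3):
            aa = _translate(seq[off:], table)
            frame = strand * (off + 1)
            pos = 0
            for seg in aa.split("*"):
                seg_start = pos  # aa index of segment start in this frame
                pos += len(seg) + 1
                seg_end = seg_start + len(seg)  # exclusive
                has_stop = seg_end < len(aa)
                starts = []
                m_idx = seg.find("M")
                if m_idx >= 0:
                    starts.append((m_idx, True))
                if seg_start == 0 and m_idx != 0:
                    starts.append((0, False))  # open-ended at the 5' edge
                for rel, has_start in starts:
                    prot = seg[rel:]
                    if len(prot) < min_aa or not prot:
                        continue
                    a0 = off + 3 * (seg_start + rel)  # nt offset in frame seq
                    b0 = off + 3 * seg_end + (3 if has_stop else 0)
                    b0 = min(b0, len(seq))
                    if strand == 1:
                        start, end = a0 + 1, b0
                    else:
                        start, end = L - b0 + 1, L - a0
                    orfs.append(
                        ORF(frame, start, end, prot, has_start, has_stop)
                    )
    if orfs:
        best = max(range(len(orfs)), key=lambda i: len(orfs[i].protein))
        orfs[best] = replace(orfs[best], longest=True)
    return orfs


def six_frame_segments(
    nt: str, table: int = 1
) -> List[Tuple[int, int, str]]:
    """Stop-split translated segments of all six frames.

    Returns ``(frame, aa_offset, segment)`` where ``aa_offset`` is the
    0-based residue offset of the segment within its full-frame
    translation.
    """
    nt = nt.upper()
    out = []
    for strand, seq in ((1, nt), (-1, _revcomp(nt))):
        for off in range(3):
            aa = _translate(seq[off:], table)
            frame = strand * (off + 1)
            pos = 0
            for seg in aa.split("*"):
                if seg:
                    out.append((frame, pos, seg))
                pos += len(seg) + 1
    return out


def local_align(
    query: str,
    target: str,
    query_id: str = "query",
    target_id: str = "target",
    frame: Optional[int] = None,
    target_aa_offset: int = 0,
) -> Optional[AlignmentHit]:
    """Optimal Smith-Waterman alignment of two protein sequences.

    Affine gap costs: a gap of length g costs 11 + (g-1). Returns None
    when no alignment scores above zero. Bit score
    ``(lambda*S - ln K)/ln 2`` and E-value ``m*n*2^(-bit)`` use fixed
    gapped BLOSUM62 constants (lambda=0.267, K=0.041) with m, n the
    query and target lengths.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    q = _sanitize_protein(query)
    t = _sanitize_protein(target)
    alns = _ALIGNER.align(q, t)
    if alns.score <= 0:
        return None
    aln = alns[0]
    q_blocks, t_blocks = aln.aligned
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    aligned_q = int(sum(b - a for a, b in q_blocks))
    n_ident = 0
    n_cols = 0
    for (qa, qb), (ta, tb) in zip(q_blocks, t_blocks):
        n_cols += qb - qa
        n_ident += sum(1 for i in range(qb - qa) if q[qa + i] == t[ta + i])
    raw = int(round(alns.score))
    bit = (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2)
    evalue = len(q) * len(t) * 2.0 ** (-bit)
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        frame=frame,
        raw_score=raw,
        bit_score=bit,
        evalue=evalue,
        query_span=(q_start + 1, q_end),
        target_span=(
            target_aa_offset + t_start + 1,
            target_aa_offset + t_end,
        ),
        query_align_ratio=aligned_q / len(q),
        identity=n_ident / n_cols if n_cols else 0.0,
    )


def _looks_nucleotide(seq: str) -> bool:
    return set(seq.upper()) <= set("ACGTN")


def screen_amps(
    refs: AMPReference,
    targets: Sequence[SeqRecord],
    evalue_max: float = 1.0e-5,
    min_ratio: float = 0.5,
    table: int = 1,
    target_type: str = "auto",
) -> Tuple[List[AlignmentHit], Dict[str, int]]:
    """Homology screen of an AMP reference list against a target set.

    Nucleotide targets are six-frame translated and split at stop codons
    first. For every (query, target) pair only the best-scoring local
    alignment is considered; it is kept when E <= ``evalue_max`` and the
    query-align ratio >= ``min_ratio``. Returns the kept hits plus hit
    counts per AMP family label.
    """
    if not len(refs):
        raise ValueError("empty AMP reference list")
    if target_type not in ("auto", "protein", "nucleotide"):
        raise ValueError(f"unknown target_type {target_type!r}")

    # (target_id, frame, aa_offset, protein) units to align against
    units: List[Tuple[str, Optional[int], int, str]] = []
    for rec in targets:
        kind = target_type
        if kind == "auto":
            kind = "nucleotide" if _looks_nucleotide(rec.seq) else "protein"
        if kind == "protein":
            units.append((rec.id, None, 0, rec.seq))
        else:
            for frame, aa_off, seg in six_frame_segments(rec.seq, table):
                units.append((rec.id, frame, aa_off, seg))

    family = {pid: fam for pid, fam, _ in refs.entries}
    hits: List[AlignmentHit] = []
    for pid, _fam, qseq in refs.entries:
        best: Dict[str, AlignmentHit] = {}
        for tid, frame, aa_off, prot in units:
            if len(prot) < 3:
                continue
            hit = local_align(
                qseq, prot, query_id=pid, target_id=tid,
                frame=frame, target_aa_offset=aa_off,
            )
            if hit is None:
                continue
            cur = best.get(tid)
            if cur is None or hit.raw_score > cur.raw_score:
                best[tid] = hit
        for hit in best.values():
            if hit.evalue <= evalue_max and hit.query_align_ratio >= min_ratio:
                hits.append(hit)

    family_counts: Dict[str, int] = {}
    for hit in hits:
        fam = family[hit.query_id]
        family_counts[fam] = family_counts.get(fam, 0) + 1
    return hits, family_counts


def map_ahtps(
    peptides: Sequence[str],
    proteins: Sequence[SeqRecord],
) -> Tuple[List[AHTPHit], Dict[str, int], Dict[str, int]]:
    """Exact-substring mapping of short antihypertensive peptides.

    Every occurrence is reported, overlapping ones included. Returns
    (hits, per-protein counts, per-peptide counts); the protein with the
    most hits is first in the per-protein dict ordering.
    """
    peps = []
    seen = set()
    for p in peptides:
        p = p.strip().upper()
        if not 2 <= len(p) <= 10:
            raise ValueError(f"AHTP {p!r}: length must be 2-10 aa")
        if p not in seen:
            seen.add(p)
            peps.append(p)

    hits: List[AHTPHit] = []
    per_protein: Dict[str, int] = {}
    per_peptide: Dict[str, int] = {p: 0 for p in peps}
    for rec in proteins:
        seq = rec.seq.upper()
        count = 0
        for pep in peps:
            i = seq.find(pep)
            while i != -1:
                hits.append(AHTPHit(pep, rec.id, i + 1, i + len(pep)))
                per_peptide[pep] += 1
                count += 1
                i = seq.find(pep, i + 1)
        if count:
            per_protein[rec.id] = count
    per_protein = dict(
        sorted(per_protein.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return hits, per_protein, per_peptide


def load_amp_reference(path, fmt: str = "auto") -> AMPReference:
    """Read an AMP list from FASTA (``family=NAME`` in the description)
    or a 3-column TSV (id, family, sequence)."""
    from .seq_io import read_fastx

    path = str(path)
    if fmt == "auto":
        fmt = "tsv" if path.endswith((".tsv", ".txt")) else "fasta"
    entries: List[Tuple[str, str, str]] = []
    if fmt == "fasta":
        for rec in read_fastx(path, "fasta"):
            fam = ""
            for tok in rec.description.split():
                if tok.startswith("family="):
                    fam = tok[len("family="):]
            entries.append((rec.id, fam, rec.seq))
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                pid, fam, seq = line.split("\t")[:3]
                entries.append((pid, fam, seq.upper()))
    return AMPReference(entries)
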