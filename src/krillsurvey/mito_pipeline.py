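"""Reference-baited mitochondrial assembly and gene extraction.

The organelle genome is tiny and high-copy, so a shotgun survey covers
it deeply even when the nuclear genome is far beyond assembly. The
pipeline mirrors that situation end to end:

1. recruit reads sharing canonical k-mers with a reference mitogenome
   (k=21 bait; a random read almost surely shares none);
2. assemble the recruited reads with a bidirected de Bruijn unitig
   assembler (k=31, k-mer coverage >= 2 to shed sequencing errors);
3. drop short contigs (< 200 bp);
4. pull each of the 13 invertebrate mitochondrial protein-coding genes
   out of the contigs by translated local alignment of the reference
   protein against all six frames (genetic code table 5), flagging a
   gene complete when the alignment covers >= 95% of the reference
   protein;
5. count residue differences between pre-aligned proteins for the
   cross-sample/cross-species comparisons.

Circular unitigs are detected and flagged; gene extraction scans them
with a wrap-around copy so a gene straddling the arbitrary
linearisation point is still recovered intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from Bio.Seq import Seq as _BioSeq

from . import peptide_screen
from .seq_io import SeqRecord, read_genbank_reference

__all__ = [
    "MITO_GENE_NAMES",
    "MitoGene",
    "MitoReference",
    "Contig",
    "GeneExtract",
    "recruit_reads",
    "assemble_contigs",
    "filter_contigs",
    "extract_genes",
    "count_residue_diffs",
]

MITO_GENE_NAMES = (
    "coxI", "coxII", "coxIII", "atp8", "atp6", "nad1", "nad2", "nad3",
    "nad4", "nad4L", "nad5", "nad6", "Cytb",
)

# common GenBank /gene spellings -> canonical names
_NAME_ALIASES = {
    "cox1": "coxI", "coi": "coxI", "co1": "coxI", "coxi": "coxI",
    "cox2": "coxII", "coii": "coxII", "co2": "coxII", "coxii": "coxII",
    "cox3": "coxIII", "coiii": "coxIII", "co3": "coxIII", "coxiii": "coxIII",
    "atp8": "atp8", "atp6": "atp6", "cytb": "Cytb", "cob": "Cytb",
    "nad1": "nad1", "nd1": "nad1", "nad2": "nad2", "nd2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nad4": "nad4", "nd4": "nad4",
    "nad4l": "nad4L", "nd4l": "nad4L", "nad5": "nad5", "nd5": "nad5",
    "nad6": "nad6", "nd6": "nad6",
}

_COMP = str.maketrans("ACGTN", "TGCAN")
MITO_TABLE = 5  # invertebrate mitochondrial genetic code


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _canon(kmer: str) -> str:
    rc = _revcomp(kmer)
    return kmer if kmer <= rc else rc


def normalize_gene_name(name: str) -> str:
    key = name.strip().lower().replace("-", "").replace("_", "")
    if key in _NAME_ALIASES:
        return _NAME_ALIASES[key]
    raise ValueError(f"unrecognised mitochondrial gene name {name!r}")


@dataclass
class MitoGene:
    name: str
    spans: List[Tuple[int, int, int]]  # 0-based half-open (start, end, strand)
    translation: str


@dataclass
class MitoReference:
    """Reference mitogenome: sequence plus the 13 protein-coding genes."""

    seq: str
    circular: bool = True
    genes: List[MitoGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.name not in MITO_GENE_NAMES:
                raise ValueError(f"unknown mitochondrial gene {g.name!r}")
            for s, e, _ in g.spans:
                if not 0 <= s < e <= len(self.seq):
                    raise ValueError(f"{g.name}: span ({s},{e}) outside sequence")

    @classmethod
    def from_genbank(cls, path) -> "MitoReference":
        seq, topology, cds = read_genbank_reference(path)
        genes = [
            MitoGene(normalize_gene_name(name), spans, translation)
            for name, spans, translation in cds
        ]
        return cls(seq=seq, circular=(topology == "circular"), genes=genes)

    def kmer_set(self, k: int) -> set:
        """Canonical k-mers of the reference (wrap-around included when circular)."""
        seq = self.seq + (self.seq[: k - 1] if self.circular else "")
        return {
            _canon(seq[i : i + k])
            for i in range(len(seq) - k + 1)
            if set(seq[i : i + k]) <= set("ACGT")
        }


@dataclass
class Contig:
    id: str
    seq: str
    mean_coverage: float
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)


def recruit_reads(
    reads: Iterable[SeqRecord],
    ref: MitoReference,
    k: int = 21,
    min_shared: int = 2,
) -> Iterator[SeqRecord]:
    """Yield reads sharing at least ``min_shared`` canonical k-mers with
    the reference."""
    bait = ref.kmer_set(k)
    for read in reads:
        seq = read.seq
        shared = 0
        for i in range(len(seq) - k + 1):
            if _canon(seq[i : i + k]) in bait:
                shared += 1
                if shared >= min_shared:
                    yield read
                    break


def assemble_contigs(
    reads: Iterable[SeqRecord],
    k: int = 31,
    min_kmer_cov: int = 2,
) -> List[Contig]:
    """Unitigs of the bidirected de Bruijn graph of the reads.

    Canonical k-mers below ``min_kmer_cov`` are discarded (error
    removal); maximal non-branching paths are emitted as contigs with
    their mean k-mer coverage. An isolated cycle — the signature of a
    circular source — is emitted once as its bare rotation (one base per
    cycle k-mer) and flagged circular.
    """
    counts: Dict[str, int] = {}
    for read in reads:
        seq = read.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            c = _canon(kmer)
            counts[c] = counts.get(c, 0) + 1
    solid = {c for c, n in counts.items() if n >= min_kmer_cov}
    if not solid:
        return []

    def present(kmer: str) -> bool:
        return _canon(kmer) in solid

    def fwd(s: str) -> List[str]:
        return [s[1:] + b for b in "ACGT" if present(s[1:] + b)]

    def bwd(s: str) -> List[str]:
        return [b + s[:-1] for b in "ACGT" if present(b + s[:-1])]

    contigs: List[Contig] = []
    visited: set = set()

    def emit(path: List[str], circular: bool) -> None:
        seq = path[0] + "".join(p[-1] for p in path[1:])
        if circular:
            # emit the bare rotation (c bases for a cycle of c k-mers);
            # consumers re-add the wrap by doubling when needed
            seq = seq[: len(path)]
        cov = sum(counts[_canon(p)] for p in path) / len(path)
        contigs.append(
            Contig(
                id=f"contig_{len(contigs) + 1}",
                seq=seq,
                mean_coverage=cov,
                circular=circular,
            )
        )

    def walk(start: str) -> List[str]:
        path = [start]
        visited.add(_canon(start))
        cur = start
        while True:
            nxt_list = fwd(cur)
            if len(nxt_list) != 1:
                break
            nxt = nxt_list[0]
            if len(bwd(nxt)) != 1 or _canon(nxt) in visited:
                break
            path.append(nxt)
            visited.add(_canon(nxt))
            cur = nxt
        return path

    ordered = sorted(solid)
    for c in ordered:
        for s in (c, _revcomp(c)):
            if _canon(s) in visited:
                continue
            preds = bwd(s)
            is_start = len(preds) != 1 or len(fwd(preds[0])) != 1
            if is_start:
                emit(walk(s), circular=False)
    # leftovers are cycles
    for c in ordered:
        if c in visited:
            continue
        path = [c]
        visited.add(c)
        cur = c
        circular = False
        while True:
            nxt_list = fwd(cur)
            if len(nxt_list) != 1:
                break
            nxt = nxt_list[0]
            if _canon(nxt) in visited:
                circular = nxt == path[0]
                break
            path.append(nxt)
            visited.add(_canon(nxt))
            cur = nxt
        emit(path, circular)
    return contigs


def filter_contigs(contigs: Sequence[Contig], min_len: int = 200) -> List[Contig]:
    """Remove contigs shorter than ``min_len`` (strictly; length-200
    contigs survive the default threshold), preserving order."""
    return [c for c in contigs if len(c) >= min_len]


@dataclass
class GeneExtract:
    """One mitochondrial gene recovered from an assembly."""

    gene: str
    contig_id: str
    nt_seq: str
    aa_seq: str
    complete: bool
    identity: float
    query_cov: float


def extract_genes(
    contigs: Sequence[Contig],
    ref: MitoReference,
    min_query_cov: float = 0.5,
    complete_cov: float = 0.95,
    evalue_max: float = 1.0e-5,
) -> List[GeneExtract]:
    """Translated-alignment extraction of the reference genes from contigs.

    Each reference protein is aligned (Smith-Waterman, BLOSUM62) against
    all six frames of every contig, stop-split, under the invertebrate
    mitochondrial code; the best hit with E <= ``evalue_max`` covering at
    least ``min_query_cov`` of the reference protein yields an extract,
    complete when coverage reaches ``complete_cov``. Genes without such a
    hit are absent from the result. (The E-value gate matters: a gappy
    chance alignment can cover half of a query at ~20% identity, so
    coverage alone cannot certify presence.)
    """
    # (contig, search sequence, frame segments) — circular contigs are
    # doubled so genes spanning the linearisation point stay contiguous
    prepared = []
    for c in contigs:
        seq = c.seq + c.seq if c.circular else c.seq
        prepared.append((c, seq, peptide_screen.six_frame_segments(seq, MITO_TABLE)))

    extracts: List[GeneExtract] = []
    for gene in ref.genes:
        best = None
        best_contig = None
        best_seq = None
        for c, seq, segments in prepared:
            for frame, aa_off, seg in segments:
                if len(seg) < 5:
                    continue
                hit = peptide_screen.local_align(
                    gene.translation, seg,
                    query_id=gene.name, target_id=c.id,
                    frame=frame, target_aa_offset=aa_off,
                )
                if hit is None:
                    continue
                if best is None or hit.raw_score > best.raw_score:
                    best, best_contig, best_seq = hit, c, seq
        if (
            best is None
            or best.query_align_ratio < min_query_cov
            or best.evalue > evalue_max
        ):
            continue
        nt_seq = _hit_nucleotides(best, best_seq)
        aa_seq = str(_BioSeq(nt_seq[: len(nt_seq) - len(nt_seq) % 3]).translate(table=MITO_TABLE))
        extracts.append(
            GeneExtract(
                gene=gene.name,
                contig_id=best.target_id,
                nt_seq=nt_seq,
                aa_seq=aa_seq,
                complete=best.query_align_ratio >= complete_cov,
                identity=best.identity,
                query_cov=best.query_align_ratio,
            )
        )
    return extracts


def _hit_nucleotides(hit, contig_seq: str) -> str:
    """Nucleotides under an alignment's target span, oriented with the gene."""
    aa_start, aa_end = hit.target_span  # 1-based residues of full-frame translation
    off = abs(hit.frame) - 1
    a0 = off + 3 * (aa_start - 1)
    b0 = off + 3 * aa_end
    if hit.frame > 0:
        return contig_seq[a0:b0]
    rc = _revcomp(contig_seq)
    return rc[a0:b0]


def count_residue_diffs(a: str, b: str) -> int:
    """Differing columns between two pre-aligned equal-length proteins;
    columns with a gap in either sequence are ignored."""
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    return sum(
        1 for x, y in zip(a.upper(), b.upper())
        if x != "-" and y != "-" and x != y
    )
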