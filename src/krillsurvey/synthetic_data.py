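"""Synthetic inputs with known ground truth for every pipeline stage.

Stands in for the deposited survey data: shotgun reads from a diploid
genome of chosen size/heterozygosity/error rate (substitutions only, so
k-mer expectations stay closed-form), random sequences with planted SSR
tracts, random proteins carrying mutated homologs of reference AMPs and
exact AHTP substrings, back-translated coding contigs, and a toy
circular mitogenome with planted protein-coding genes. All generators
are pure functions of their spec and seed, and every truth table uses
the pipeline's own record types and coordinate conventions so stage
outputs are directly set-comparable to truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable

from . import ssr_scan
from .mito_pipeline import MITO_GENE_NAMES, MitoGene, MitoReference
from .seq_io import SeqRecord
from .ssr_scan import SSRRecord

__all__ = [
    "SimGenomeSpec",
    "SimReadSpec",
    "simulate_diploid_genome",
    "simulate_reads",
    "plant_ssrs",
    "plant_peptides",
    "PeptidePlantTruth",
    "random_amp_reference",
    "back_translate",
    "make_toy_mito",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimGenomeSpec:
    """A diploid genome to simulate: haploid size (bp), per-site
    heterozygosity, GC content, and the RNG seed."""

    size: int = 1_000_000
    heterozygosity: float = 0.0
    gc: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 1000:
            raise ValueError(f"size must be >= 1000, got {self.size}")
        if not 0.0 <= self.heterozygosity <= 0.1:
            raise ValueError("heterozygosity must be in [0, 0.1]")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")


@dataclass(frozen=True)
class SimReadSpec:
    """Shotgun sequencing to emulate: 100 bp single-end reads at a given
    fold coverage with a per-base substitution error rate."""

    read_length: int = 100
    depth: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 3:
            raise ValueError("read_length must be >= 3")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_diploid_genome(
    spec: SimGenomeSpec,
) -> Tuple[SeqRecord, SeqRecord, List[int]]:
    """Two haplotypes differing by binomially sampled substitutions.

    Returns (hapA, hapB, variant positions); positions are 0-based sites
    where the haplotypes differ. Expected variant count is
    heterozygosity * size.
    """
    rng = np.random.default_rng(spec.seed)
    p = np.array(
        [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    )
    hap_a = rng.choice(4, size=spec.size, p=p).astype(np.uint8)
    hap_b = hap_a.copy()
    variants: List[int] = []
    if spec.heterozygosity > 0:
        mask = rng.random(spec.size) < spec.heterozygosity
        idx = np.flatnonzero(mask)
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
        hap_b[idx] = (hap_b[idx] + shift) % 4
        variants = idx.tolist()
    return (
        SeqRecord(id="hapA", seq=_codes_to_str(hap_a)),
        SeqRecord(id="hapB", seq=_codes_to_str(hap_b)),
        variants,
    )


def simulate_reads(
    hap_a: SeqRecord,
    hap_b: Optional[SeqRecord],
    spec: SimReadSpec,
    circular: bool = False,
) -> List[SeqRecord]:
    """Uniform shotgun reads from one or two haplotypes.

    Reads are drawn 50/50 from the two haplotypes (pass ``hap_b=None``
    for a haploid source), uniformly positioned, half reverse-
    complemented, with substitution errors at ``error_rate``. Correct
    bases carry Phred quality 40; erroneous bases quality 10. Total
    bases are ceil(depth * genome size / read length) reads' worth. With
    ``circular=True`` reads may span the origin.
    """
    haps = [hap_a.seq] if hap_b is None else [hap_a.seq, hap_b.seq]
    if hap_b is not None and len(hap_a.seq) != len(hap_b.seq):
        raise ValueError("haplotypes must have equal length")
    L = len(hap_a.seq)
    rl = spec.read_length
    if rl > L:
        raise ValueError(f"read_length {rl} exceeds genome size {L}")
    rng = np.random.default_rng(spec.seed)
    n_reads = math.ceil(spec.depth * L / rl)
    hap_idx = rng.integers(0, len(haps), size=n_reads)
    starts = rng.integers(0, L if circular else L - rl + 1, size=n_reads)
    flip = rng.random(n_reads) < 0.5
    comp = str.maketrans("ACGT", "TGCA")
    sources = [h + h[: rl - 1] for h in haps] if circular else haps

    reads: List[SeqRecord] = []
    for i in range(n_reads):
        seq = sources[hap_idx[i]][starts[i] : starts[i] + rl]
        if flip[i]:
            seq = seq.translate(comp)[::-1]
        quals = [40] * rl
        if spec.error_rate > 0:
            nerr = rng.binomial(rl, spec.error_rate)
            if nerr:
                pos = rng.choice(rl, size=nerr, replace=False)
                chars = list(seq)
                for p_ in pos:
                    old = chars[p_]
                    choices = [b for b in "ACGT" if b != old]
                    chars[p_] = choices[rng.integers(0, 3)]
                    quals[p_] = 10
                seq = "".join(chars)
        reads.append(
            SeqRecord(
                id=f"read{i + 1}",
                seq=seq,
                description=f"hap={hap_idx[i]} start={starts[i]} rc={int(flip[i])}",
                quals=quals,
            )
        )
    return reads


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _codes_to_str(rng.choice(4, size=n, p=p).astype(np.uint8))


def plant_ssrs(
    background: SeqRecord,
    tracts: Sequence[Tuple[str, int, int]],
    min_repeats: Optional[Dict[int, int]] = None,
    seed: int = 0,
) -> Tuple[SeqRecord, List[SSRRecord]]:
    """Overwrite perfect SSR tracts into a background sequence.

    ``tracts`` are (motif, repeat_count, 1-based start position). The
    background is adjusted so the truth set is exactly what a scan at
    ``min_repeats`` reports: flank bases that would extend or shift a
    planted tract are re-drawn, and chance tracts arising in the random
    background are broken by a single substitution. Truth records use
    the scanner's own conventions (canonical motif, 1-based inclusive
    span). Overlapping planted tracts raise.
    """
    if min_repeats is None:
        min_repeats = ssr_scan.DEFAULT_MIN_REPEATS
    rng = np.random.default_rng(seed)
    seq = list(background.seq)
    spans: List[Tuple[int, int]] = []  # 0-based inclusive
    truth: List[SSRRecord] = []
    for motif, reps, start in tracts:
        motif = motif.upper()
        m = len(motif)
        if not 2 <= m <= 6:
            raise ValueError(f"motif {motif!r}: length must be 2-6")
        if not ssr_scan.is_primitive(motif):
            raise ValueError(f"motif {motif!r} is not primitive")
        a0 = start - 1
        b0 = a0 + m * reps - 1
        if a0 < 0 or b0 >= len(seq):
            raise ValueError(f"tract {motif}x{reps}@{start} outside background")
        for s0, e0 in spans:
            if a0 <= e0 + 1 and b0 >= s0 - 1:  # adjacency also disallowed
                raise ValueError("planted tracts overlap")
        spans.append((a0, b0))
        seq[a0 : b0 + 1] = list(motif * reps)
        truth.append(
            SSRRecord(
                seq_id=background.id,
                motif=ssr_scan.canonical_motif(motif),
                motif_len=m,
                repeats=reps,
                start=start,
                end=b0 + 1,
                tract=motif * reps,
            )
        )
        # flanks must not continue the periodicity (which would shift or
        # extend the reported tract)
        if a0 > 0 and seq[a0 - 1] == seq[a0 - 1 + m]:
            seq[a0 - 1] = rng.permutation(
                [b for b in "ACGT" if b != seq[a0 - 1 + m]]
            )[0]
        if b0 + 1 < len(seq) and seq[b0 + 1] == seq[b0 + 1 - m]:
            seq[b0 + 1] = rng.permutation(
                [b for b in "ACGT" if b != seq[b0 + 1 - m]]
            )[0]

    truth_spans = {(t.start, t.end) for t in truth}
    # break chance tracts in the background (keep planted ones intact)
    for _ in range(20):
        rec = SeqRecord(id=background.id, seq="".join(seq))
        extra = [
            r
            for r in ssr_scan.scan_ssrs([rec], min_repeats)
            if (r.start, r.end) not in truth_spans
        ]
        if not extra:
            break
        for r in extra:
            # mutate a base of the stray tract lying outside planted spans
            for p0 in range(r.start - 1 + (r.end - r.start) // 2, r.end):
                if not any(s0 <= p0 <= e0 for s0, e0 in spans):
                    old = seq[p0]
                    seq[p0] = rng.permutation(
                        [b for b in "ACGT" if b != old]
                    )[0]
                    break
    else:
        raise RuntimeError("failed to scrub chance SSR tracts from background")
    return SeqRecord(id=background.id, seq="".join(seq)), truth


# ---------------------------------------------------------------------------
# peptide fixtures

_STANDARD_CODONS: Dict[str, List[str]] = {}
_MITO_CODONS: Dict[str, List[str]] = {}
for _table_id, _target in ((1, _STANDARD_CODONS), (5, _MITO_CODONS)):
    _tab = CodonTable.unambiguous_dna_by_id[_table_id]
    for _codon, _aa in _tab.forward_table.items():
        _target.setdefault(_aa, []).append(_codon)


def back_translate(
    protein: str, rng: np.random.Generator, table: int = 1
) -> str:
    """Random synonymous back-translation of a protein (no stop codon)."""
    codons = _STANDARD_CODONS if table == 1 else _MITO_CODONS
    out = []
    for aa in protein.upper():
        opts = codons[aa]
        out.append(opts[rng.integers(0, len(opts))])
    return "".join(out)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_AA20), size=n)
    return "M" + "".join(_AA20[i] for i in idx[1:])


def random_amp_reference(
    n: int = 20, seed: int = 0, min_len: int = 20, max_len: int = 60
):
    """A synthetic AMP reference list with round-robin family labels,
    standing in for a curated antimicrobial-peptide collection."""
    from .peptide_screen import AMPReference

    rng = np.random.default_rng(seed)
    families = ["crustin", "penaeidin", "defensin", "buforin"]
    entries = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(_AA20[j] for j in rng.integers(0, 20, size=length))
        entries.append((f"amp{i + 1}", families[i % len(families)], seq))
    return AMPReference(entries)


@dataclass
class PeptidePlantTruth:
    """Ground truth of a peptide-planting run.

    ``amps``: (protein_id, amp_id, start, end, realised identity) with
    1-based inclusive residue spans of the planted homolog. ``ahtps``:
    every occurrence of every reference peptide in the final proteins
    (planted and incidental alike), as (protein_id, peptide, start, end).
    """

    amps: List[Tuple[str, str, int, int, float]]
    ahtps: List[Tuple[str, str, int, int]]


def _mutate_to_identity(
    peptide: str, identity: float, rng: np.random.Generator
) -> Tuple[str, float]:
    n = len(peptide)
    n_mut = round((1.0 - identity) * n)
    chars = list(peptide)
    if n_mut:
        pos = rng.choice(n, size=n_mut, replace=False)
        for p in pos:
            options = [a for a in _AA20 if a != chars[p]]
            chars[p] = options[rng.integers(0, len(options))]
    return "".join(chars), (n - n_mut) / n


def plant_peptides(
    n_proteins: int,
    amp_refs,
    ahtp_list: Sequence[str],
    identity: float = 0.9,
    seed: int = 0,
    protein_len: Tuple[int, int] = (150, 400),
) -> Tuple[List[SeqRecord], List[SeqRecord], PeptidePlantTruth]:
    """Random proteins carrying mutated AMP homologs and AHTP substrings.

    The first ``len(amp_refs)`` proteins each embed one reference AMP
    mutated to the target identity; the rest are decoys. Each AHTP is
    written once into a random protein (outside any AMP span); the truth
    table then records *every* occurrence, so it is exactly the expected
    output of the substring mapper. Contigs are random synonymous
    back-translations of the proteins flanked by short UTRs with
    in-frame stops, so the ORF finder recovers each protein exactly.
    """
    if not 0.5 < identity <= 1.0:
        raise ValueError("identity must be in (0.5, 1.0]")
    if n_proteins < len(amp_refs.entries):
        raise ValueError("n_proteins must cover all AMP references")
    rng = np.random.default_rng(seed)

    proteins: List[SeqRecord] = []
    amp_truth: List[Tuple[str, str, int, int, float]] = []
    amp_spans: Dict[str, Tuple[int, int]] = {}
    for i in range(n_proteins):
        length = int(rng.integers(protein_len[0], protein_len[1] + 1))
        prot = _random_protein(rng, length)
        pid = f"prot{i + 1}"
        if i < len(amp_refs.entries):
            amp_id, _fam, amp_seq = amp_refs.entries[i]
            homolog, realised = _mutate_to_identity(amp_seq, identity, rng)
            pos = int(rng.integers(1, length - len(homolog)))
            prot = prot[:pos] + homolog + prot[pos + len(homolog) :]
            amp_truth.append((pid, amp_id, pos + 1, pos + len(homolog), realised))
            amp_spans[pid] = (pos, pos + len(homolog) - 1)
        proteins.append(SeqRecord(id=pid, seq=prot))

    # plant each AHTP once, avoiding AMP homolog spans
    for pep in ahtp_list:
        pep = pep.strip().upper()
        for _attempt in range(50):
            i = int(rng.integers(0, n_proteins))
            rec = proteins[i]
            if len(rec.seq) < len(pep) + 2:
                continue
            pos = int(rng.integers(1, len(rec.seq) - len(pep)))
            span = amp_spans.get(rec.id)
            if span and pos <= span[1] and pos + len(pep) - 1 >= span[0]:
                continue
            proteins[i] = SeqRecord(
                id=rec.id,
                seq=rec.seq[:pos] + pep + rec.seq[pos + len(pep) :],
            )
            break
        else:
            raise RuntimeError(f"could not place AHTP {pep!r}")

    # truth: every occurrence in the final proteins
    ahtp_truth: List[Tuple[str, str, int, int]] = []
    uniq = sorted({p.strip().upper() for p in ahtp_list})
    for rec in proteins:
        for pep in uniq:
            start = 0
            while True:
                j = rec.seq.find(pep, start)
                if j == -1:
                    break
                ahtp_truth.append((rec.id, pep, j + 1, j + len(pep)))
                start = j + 1

    # coding contigs: 5' UTR ending in an in-frame stop, ATG..protein, stop
    contigs: List[SeqRecord] = []
    for rec in proteins:
        utr5 = _random_dna(rng, 9) + "TAA"
        utr3 = _random_dna(rng, 12)
        cds = back_translate(rec.seq, rng, table=1)
        stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
        contigs.append(
            SeqRecord(id=f"contig_{rec.id}", seq=utr5 + cds + stop + utr3)
        )
    return proteins, contigs, PeptidePlantTruth(amps=amp_truth, ahtps=ahtp_truth)


def make_toy_mito(
    seed: int = 0,
    length: int = 5000,
    n_genes: int = 4,
    gene_len_aa: Tuple[int, int] = (80, 120),
) -> MitoReference:
    """A toy circular mitogenome with planted protein-coding genes.

    Random backbone of ``length`` bp; ``n_genes`` genes (named after the
    first few canonical mitochondrial protein-coding genes) are random
    proteins back-translated under the invertebrate mitochondrial code
    and written onto the forward strand at evenly spaced positions,
    each delimited by ATG ... TAA.
    """
    if n_genes > len(MITO_GENE_NAMES):
        raise ValueError(f"at most {len(MITO_GENE_NAMES)} genes")
    rng = np.random.default_rng(seed)
    seq = list(_random_dna(rng, length))
    genes: List[MitoGene] = []
    slot = length // n_genes
    for g in range(n_genes):
        aa_len = int(rng.integers(gene_len_aa[0], gene_len_aa[1] + 1))
        nt_len = 3 * aa_len + 3  # incl. stop
        if nt_len + 20 > slot:
            raise ValueError("genes do not fit: increase length or shrink genes")
        prot = _random_protein(rng, aa_len)
        cds = back_translate(prot, rng, table=5) + "TAA"
        start = g * slot + int(rng.integers(0, slot - nt_len))
        seq[start : start + nt_len] = list(cds)
        genes.append(
            MitoGene(
                name=MITO_GENE_NAMES[g],
                spans=[(start, start + nt_len, 1)],
                translation=prot,
            )
        )
    return MitoReference(seq="".join(seq), circular=True, genes=genes)
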