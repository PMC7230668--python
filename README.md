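# krillsurvey

Desk-scale genome-survey computations for shotgun sequencing of large
(even unassemblable) animal genomes, written around the survey of the
Antarctic krill *Euphausia superba* — a crustacean whose ~42 Gb genome
is far beyond routine assembly, but whose raw reads still yield a
genome-size estimate, microsatellite markers, a mitochondrial gene set,
and bioactive-peptide candidates. The package is for bioinformaticians
who want those survey computations as a reusable, tested library and
CLI rather than a stack of one-off scripts, plus synthetic-data
generators that make every stage verifiable against known ground truth.

## What it computes

* **Genome size from the k-mer spectrum.** Count every canonical
  17-mer occurrence in the clean reads (`K_num`), find the main peak
  depth of the k-mer histogram (`K_depth`), and estimate

  `G = K_num // K_depth`, with sequencing depth
  `X = clean_bases // G` (floor division throughout).

* **Read QC**: drop reads with >5% N or >20% of bases at Phred ≤ 10.
* **SSRs**: every maximal perfect tandem repeat of a primitive 2–6 bp
  motif (MISA-style minimum copy numbers), with per-class summaries.
* **Mitochondrial genes**: recruit reads by shared canonical k-mers
  with a reference mitogenome, assemble them with a de Bruijn unitig
  assembler, drop contigs <200 bp, and pull out the 13 invertebrate
  mitochondrial protein-coding genes by translated Smith–Waterman
  alignment (genetic code table 5).
* **AMP screen**: exact Smith–Waterman (BLOSUM62, affine gaps 11/1)
  of an antimicrobial-peptide reference list against proteins or
  six-frame-translated contigs, keeping hits with E ≤ 1e−5 and query
  align ratio ≥ 0.5.
* **AHTP mapping**: exact substring search of short (2–10 aa)
  antihypertensive peptides against a proteome, overlapping matches
  included.
* **Phylogenetics**: p-distances, Saitou–Nei neighbor joining, and
  column-resampling bootstrap supports, written as Newick.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

Simulate a 100 kb genome, sequence it error-free to 30× with 100 bp
reads, and recover its size from the 17-mer spectrum:

```bash
krillsurvey simulate genome --size 100000 --seed 1 -o genome.fasta
krillsurvey simulate reads genome.fasta --depth 30 --seed 2 -o reads.fastq.gz
krillsurvey kmer reads.fastq.gz --k 17 -o hist.tsv
krillsurvey estimate hist.tsv --clean-bases 3000000
```

which prints

```
K-mer   K_num    K_depth  Genome Size  Clean Base (bp)  Depth (X)
17      2520000  25       100800       3000000          29
genome size: 100,800 bp
```

Reading the numbers: 30,000 reads of 100 bp contribute
84 seventeen-mer windows each, so `K_num = 2,520,000`; the histogram
peak sits at depth 25 ≈ 30 × 84/100 (a read covers a given k-mer only
when the whole window fits); and `2,520,000 // 25 = 100,800` bp — 0.8%
from the simulated truth, with the residual set by the integer peak
depth. The same command on the krill survey totals
(`K_num = 758,531,899,196`, peak 18, clean bases 902,660,212,000)
gives 42,140,661,066 bp — 42.1 Gb at 21× depth.

Other entry points: `krillsurvey qc`, `krillsurvey ssr scan|summarize`,
`krillsurvey mito`, `krillsurvey amp`, `krillsurvey ahtp`,
`krillsurvey nj`, and `krillsurvey simulate ssr|peptides` for fixtures
with truth tables. Every command is a thin wrapper over the library
(`import krillsurvey`).

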