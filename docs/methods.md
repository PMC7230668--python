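# Methods

`krillsurvey` reimplements the computational core of a genome survey of
a very large crustacean genome: genome-size estimation from a k-mer
spectrum, microsatellite (SSR) scanning, reference-baited extraction of
mitochondrial protein-coding genes, translated homology screening for
antimicrobial peptides (AMPs), exact mapping of antihypertensive
peptides (AHTPs), and neighbor-joining phylogenetics. Everything runs
at desk scale on synthetic data with known ground truth; this note
records the models, the defaults, and the choices made where the design
was genuinely open.

## Read quality control

A read is discarded when more than 5% of its bases are undetermined (N)
or more than 20% of its bases have Phred quality ≤ 10. Both thresholds
are strict inequalities, so a 100 bp read with exactly 5 N's and exactly
20 bases at Q10 is kept. Filtering is per read (the cleaner interpreted
reading; read-pair co-filtering adds nothing downstream here, since the
k-mer survey is pairing-blind). FASTQ qualities are fixed to Phred+33;
other encodings are rejected rather than guessed. N's count only toward
the N-fraction rule, never double-counted as low-quality bases.

## K-mer survey and genome-size estimation

Every window of k consecutive unambiguous bases in the clean reads is
counted under its canonical form, the lexicographic minimum of the
k-mer and its reverse complement; k must be odd so canonicalisation
never ties. Windows containing N are skipped and excluded from the
occurrence total K_num. The estimator is

    G = K_num // K_depth,        depth_X = clean_bases // G,

with floor (integer) division throughout — the only rule that
reproduces the published survey table bit-exactly (K_num
758,531,899,196 at K_depth 18 gives 42,140,661,066 bp, i.e. 42.1 Gb,
and 21× depth on 902,660,212,000 clean bases). K_num deliberately
includes *all* k-mer occurrences, error k-mers too; the published
totals are consistent with that convention (9.03 × 10⁹ reads of 100 bp
× 84 windows ≈ the printed K_num) and subtracting the error peak would
not reproduce them.

K_depth is the main-peak depth of the raw histogram (no smoothing).
Scanning depths upward from the smallest observed depth, the
sequencing-error valley is the first depth v ≥ 2 with
counts[v] < counts[v+1]; the peak is the argmax over depths > v. A
monotone-decreasing spectrum has no valley: the global argmax is
returned with a low-confidence flag, and callers (CLI `--k-depth`) can
pin the peak manually. Under error-free uniform coverage the peak sits
near depth × (L−k+1)/L (≈ 25 for 100 bp reads at 30× with k = 17), and
the histogram identity Σ_d d·counts[d] = K_num holds on every input.

The counter packs k-mers (k ≤ 31) into 2-bit codes in uint64 and
streams reads in ~8 Mb batches through vectorised numpy window
encoding, so memory scales with distinct k-mers, not read volume.
Counting correctness is cross-checked against an explicit
string-dictionary counter in the tests.

## Synthetic data

Generators are pure functions of (spec, seed) and emit truth tables in
the pipeline's own record types, so outputs are set-comparable to truth.

* **Diploid genome**: i.i.d. bases at a target GC (default 0.42, a
  typical invertebrate value); the second haplotype differs by
  binomially sampled substitutions at the chosen per-site
  heterozygosity. Substitutions only — no indels — which keeps the
  k-mer peak expectation closed-form and the toy assembler exact;
  indels are a documented extension point.
* **Reads**: single-end 100 bp (the survey's read length) drawn
  uniformly from both haplotypes, half reverse-complemented, optional
  wrap-around for circular sources, substitution errors at a per-base
  rate; correct bases carry Q40, erroneous bases Q10. Uniform coverage,
  no GC bias: the estimator's accuracy contract is stated under this
  model. Pairing is omitted because no implemented computation uses it.
* **SSR fixtures**: requested perfect tracts are written over a random
  background; flank bases that would extend or phase-shift a tract are
  re-drawn, and chance tracts arising in the background are broken by a
  single substitution, so the truth set is exactly what a correct
  scanner must report — chance di-nucleotide tracts are common enough
  (~10⁻⁶/bp at the default thresholds) that unscrubbed fixtures would
  fail exact-set comparisons.
* **Peptide fixtures**: random proteins (150–400 aa, uniform
  composition, M-initial); carrier proteins embed one reference AMP
  mutated to a target identity; AHTPs are overwritten at random
  positions outside AMP spans, and the truth table records *every*
  occurrence in the final proteins (planted and incidental), matching
  the mapper's contract. Coding contigs are random synonymous
  back-translations flanked by short UTRs whose 5' side ends in an
  in-frame stop, so ORF extraction recovers each protein exactly.
* **Toy mitogenome**: a 5 kb circular backbone carrying four planted
  forward-strand genes (random proteins back-translated under the
  invertebrate mitochondrial code, ~80–120 aa), used by the end-to-end
  assembly tests.

What passing on these fixtures does *not* show: robustness to indels,
coverage bias, adapter contamination, repetitive genomes, or real
k-mer error spectra. The contracts are exactness of the combinatorial
cores and statistical recovery under the stated generative model.

## SSR scanning

Perfect tandem repeats of primitive 2–6 bp motifs, with MISA-convention
minimum copy numbers (di ≥ 6; tri/tetra/penta/hexa ≥ 5) — the
convention is ours to choose since only the 2–6 bp range is inherent to
the analysis; thresholds are fully configurable. Only whole motif
copies count; a tract is maximal when it cannot be extended by a full
copy on either side, and the reported start is the leftmost full copy.
Candidates are found per motif length via vectorised periodicity runs
(s[i] = s[i+m]); non-primitive motifs (e.g. ACAC) are suppressed in
favour of their primitive class, and mononucleotide runs are excluded
by the 2–6 bp range. Overlaps across motif-length classes are resolved
greedily: longest tract first, then smaller motif, then leftmost.
Motifs are reported as their lexicographically smallest rotation;
folding reverse complements together (AC ≡ GT) is available behind a
flag but off by default. N breaks any tract. The scanner's contract is
exact equivalence with a position-by-position brute-force oracle, not
reproduction of any particular corpus counts (those depend on external
data).

## Mitochondrial pipeline

The heavy external stack (short-read mapper + SPAdes + BLAST) is
replaced by a self-contained equivalent of the same shape:

* **Recruitment**: a read is recruited when it shares ≥ 2 canonical
  21-mers with the reference mitogenome (wrap-around k-mers included
  for circular references). A random 100 bp read collides with a 15 kb
  reference k-mer set with probability ≪ 10⁻⁶, so the bait is
  effectively specific; two shared k-mers make the criterion robust to
  a single chance collision.
* **Assembly**: a bidirected de Bruijn graph on canonical 31-mers with
  coverage ≥ 2 (drops singleton error k-mers); maximal non-branching
  paths become contigs with mean k-mer coverage. An isolated cycle is
  emitted once as its bare rotation and flagged circular; gene
  extraction doubles circular contigs internally so genes straddling
  the arbitrary linearisation point stay intact.
* **Length filter**: contigs shorter than 200 bp are removed; the
  threshold is strict, so a 200 bp contig survives.
* **Gene extraction**: each reference protein is Smith-Waterman-aligned
  (BLOSUM62, translated under genetic code table 5 — invertebrate
  mitochondrial) against all stop-split six-frame segments of every
  contig. The best hit must satisfy E ≤ 10⁻⁵ *and* cover ≥ 50% of the
  reference protein; coverage ≥ 95% marks the gene complete. The
  E-value gate is essential: a meandering gappy alignment against
  unrelated sequence can cover half a query at ~20% identity, so
  coverage alone cannot certify presence. Nucleotide extraction is by
  reversal of the frame arithmetic, oriented with the gene.
* **Residue differences** between pre-aligned proteins count columns
  where both symbols are non-gap and unequal.

Translated (protein-level) extraction was chosen over nucleotide
alignment because it is robust to synonymous divergence and matches the
cross-species comparisons the genes are used for. GenBank parsing keeps
only what the pipeline needs: sequence, topology, and CDS features
carrying /gene and /translation.

## Peptide screens

**ORFs.** All six frames, standard genetic code; within each
stop-delimited stretch the ORF starts at the first ATG, and stretches
flush with a sequence edge additionally yield open-ended ORFs. The
default minimum is 100 aa; nucleotide spans are 1-based on the forward
strand and include the terminating stop.

**Aligner.** Exact Smith-Waterman with affine gaps over BLOSUM62: a gap
of length g costs 11 + (g−1) (the first gap residue costs the full
open penalty). At desk scale (10²–10⁴ targets) exhaustive DP is
affordable and strictly dominates seed-and-extend heuristics, so a
translated-BLAST stand-in can apply the published filters to exact
scores. The DP engine is Biopython's PairwiseAligner configured to this
convention; tests verify score equality against an independent
brute-force DP on random pairs. Bit scores use fixed gapped BLOSUM62
constants λ = 0.267, K = 0.041 (the standard values for open 11 /
extend 1), bit = (λS − ln K)/ln 2, and E = m·n·2^(−bit) with m, n the
query and target lengths. Residues outside the matrix alphabet score as
X.

**AMP screen.** Every reference peptide against every protein target
(nucleotide targets are six-frame translated and split at stops first);
the best hit per (query, target) is kept when E ≤ 10⁻⁵ and the query
align ratio ≥ 0.5. The ratio is aligned query residues / query length;
gaps in the query do not count as aligned — the natural reading of a
"query align ratio" filter, configurable if a different convention is
wanted. Family summaries come from reference-list metadata (a curated
list's grouping is inherited, not re-clustered).

**AHTP mapper.** Exact substring search of 2–10 aa peptides; every
occurrence is reported, overlapping ones included; per-protein and
per-peptide counts identify the most AHTP-dense protein. The published
hit totals depend on the original curated lists and external
transcriptomes, so the contract here is exact agreement with a naive
substring oracle, not count reproduction.

## Phylogenetics

p-distance (differing residues over both-ungapped columns) with an
optional Poisson correction −ln(1−p), p capped at 0.95 to stay finite;
the distance model behind the published tree is unreported, and
p-distance is the minimal-assumption default for closely related
protein sequences. Neighbor joining follows Saitou–Nei with the
standard Q-criterion; ties break toward the smallest (i, j) index pair;
negative branch-length estimates are clamped to zero and counted on the
tree. NJ is exact on additive matrices, which the tests use as the
oracle (random additive trees, Robinson–Foulds distance 0 required).
Bootstrap resamples alignment columns with replacement (default 1,000
replicates, seeded and deterministic), rebuilds the NJ tree, and scores
each internal edge of the full-data tree with the percentage of
successful replicates containing the same bipartition; replicates whose
resampled columns leave some pair with no comparable columns are
skipped and counted separately. All-identical alignments are flagged
degenerate. Outgroup rooting is display-time only; NJ itself is
unrooted. Trees are scikit-bio `TreeNode` objects and Newick output
carries supports as internal labels.

## Problem sizes used in the test and acceptance runs

Chosen as the smallest scales at which each statistical contract is
sharp: genome-size recovery uses a 1 Mb haploid genome at 30× (five
seeds, mean relative error < 5%); SSR oracle equivalence uses 1,000 ×
1 kb sequences with 200 planted tracts; the AMP screen plants 50
homologs at 90% identity among 500 decoys; the AHTP oracle runs 1,000
random draws; the mitochondrial end-to-end runs five seeds of the 5 kb
toy; NJ consistency covers 4–8 taxa. The published corpus-scale numbers
(the 911 Gb run, the 12,272 bp partial assembly, corpus SSR/AMP/AHTP
counts) depend on external accessions and are out of numeric scope; the
property suites above stand in for them.

## Known limitations

No indels anywhere in the generative model or the assembler's test
envelope; no paired-end logic; no heterozygosity-aware spectrum fitting
(the peak rule is exposed, not model-fit); the unitig assembler handles
clean bidirected graphs, not tangled repeat structures; Karlin–Altschul
constants are fixed rather than estimated per matrix; compound or
interrupted SSRs are not modelled.
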