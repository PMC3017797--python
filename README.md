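# rgacluster

Comparative analysis of the two haplotypes of a plant disease-resistance
(NB-LRR) gene cluster within a single diploid genotype.

Resistance-gene analog (RGA) clusters are among the fastest-evolving regions
of plant genomes: tandem arrays of CC-NB-LRR genes expand and contract
through unequal recombination, exchange sequence between paralogs, and
accumulate retroelement insertions, while the flanking gene-rich regions
stay almost perfectly colinear. Given two annotated haplotype sequences of
such a locus (e.g. two BAC contigs from one heterozygous plant),
`rgacluster` reconstructs that picture quantitatively:

- **Colinearity** — exact k-mer anchors chained into colinear blocks,
  refined to base-level alignments; SNP and indel catalogue; nucleotide
  diversity over aligned columns.
- **Molecular dating** — Nei–Gojobori counting of synonymous sites *S* and
  differences *S*<sub>d</sub> over allelic CDS pairs; the synonymous
  p-distance *p*<sub>S</sub> = *S*<sub>d</sub>/*S* dates the haplotype
  divergence through *T* = *p*<sub>S</sub>/(2*r*) at the coding synonymous
  rate *r* = 4.5×10⁻⁹ /site/yr. LTR retroelement insertions are dated
  through *T* = *K*/(2*r*) where *K* is the Kimura 2-parameter distance
  between the element's two LTRs and *r* = 9×10⁻⁹ /site/yr (noncoding).
- **Repeats** — LTR retroelement structural annotation (paired LTRs by
  self-comparison, TG…CA termini, 4–6 bp target-site duplications) and a
  genome-wide survey of perfect SSRs (2–6 bp units) with cross-haplotype
  matching and heterozygosity.
- **Gene family** — completeness classification
  (complete/pseudogene/fragment/remnant from Qcov/Scov coverage and
  expression-preventing mutations), pairwise identity matrix, reciprocal-best
  allele assignment with an ambiguity rule for recent duplications,
  two-clade clustering, NB-ARC motif and LRR-repeat annotation
  (consensus `LxxLxxLxxLxLxx(N/C/T)x(x)LxxIPxx`), coding microsatellites.
- **Recombination** — sliding-window percent-identity profiles of a
  putative recombinant against candidate parents with breakpoint calls at
  sustained identity-rank shifts, and a screen for unequal recombination
  mediated by duplicated ~1 kb intergenic sequences.
- **Simulator** — a synthetic haplotype-pair generator
  (`rgacluster.synthetic_data`) that plants all of the above with a full
  ground-truth table, so every stage is testable without any downloads.

## Worked example

```bash
python examples/03_molecular_dating.py
```

simulates a haplotype pair that diverged 1 million years ago, counts
synonymous substitutions over every allelic CDS pair, and prints (numbers
from seed 11):

```
concatenated: Sd = 36.0 over S = 4643 synonymous sites
pS = 0.00775  ->  T = 0.861 MY (simulated truth: 1.0 MY)

pS = 0.0088 at r = 0.45e-8  ->  T = 0.978 MY (just under one million years)
```

The first block is parameter recovery: 36 synonymous differences over 4643
synonymous sites give *p*<sub>S</sub> = 0.0078, which the clock converts to
0.86 MY — a single-replicate estimate of the simulated 1 MY truth (the mean
over 50 replicates lands within a few percent of 1.0). The last line is the
dating formula applied to a published synonymous p-distance of 0.0088,
giving just under one million years.

The other scripts in `examples/` walk through each capability
(simulation, colinearity, repeats, gene family, recombination, and the full
pipeline); `examples/07_full_pipeline.py` produces every report table —
region composition, dating, repeat/LTR, SSR heterozygosity, alleles,
clades, classification, breakpoints — in one run directory.

A thin CLI wraps the same entry points:

```bash
rgacluster simulate --seed 7 --out-dir fixture
rgacluster compare --locus-a fixture/hapA.fasta --annotations-a fixture/hapA.gff3 \
                   --locus-b fixture/hapB.fasta --annotations-b fixture/hapB.gff3 \
                   --out-dir report
```

Real loci are accepted as FASTA + GFF3 or as EMBL flat files.

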