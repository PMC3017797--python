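# Methods

This note documents the models and procedures implemented in `rgacluster`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Haplotype colinearity

Two haplotype sequences are compared dotplot-style. Maximal exact matches
are seeded from shared k-mers (default `k = 15`); k-mers occurring more
than `max_kmer_freq = 8` times in either sequence are discarded, which
suppresses seeds inside microsatellites and high-copy repeats. Overlapping
seeds on one diagonal are merged and extended to maximal exact matches.
Anchors are chained by repeated maximum-weight monotone chaining (weight =
summed anchor length); a chain is split where the inter-anchor gap on
either sequence exceeds `max_gap = 5000` bp, and chains spanning less than
`min_block = 500` bp are dropped. Reverse-strand anchors can be computed
and are reported (dotplot export flags them `-`) but are never chained into
forward blocks.

Block refinement is anchored-piecewise: exact anchor runs are copied
verbatim and inter-anchor gaps aligned with an affine-gap (Gotoh) aligner
restricted to a diagonal band sized from the gap geometry
(`|Δlength| + 50`, at least 50). Scoring is match +1, mismatch −2, gap of
length L costs −6 − L. A banded result is only trusted when its score
equals a fast score-only full-DP pass; otherwise the full-DP aligner
recomputes the piece — a too-narrow band can contain an interior
suboptimal path that no band-edge check can detect, so score verification,
not edge detection, is the guard against silent truncation.

Identity is reported over aligned non-gap columns; contiguous gap runs are
reported separately as indel events with length and carrier haplotype.
This separation (SNPs vs indels) is deliberate: insertions of mobile
elements would otherwise swamp the substitution signal. Nucleotide
diversity is substitutions ÷ aligned non-gap columns, optionally restricted
to a column mask (e.g. coding columns).

## Molecular dating

**Coding clock.** For an aligned allelic CDS pair, synonymous sites are
counted per codon as the fraction of one-step changes that preserve the
amino acid (changes to stop codons are not counted as sites), averaged
between the two sequences. Differences between codons differing at *d*
positions are averaged over all *d*! substitution pathways, excluding
pathways through stop codons and re-weighting the remainder equally — the
classic unweighted-pathway convention. Codon pairs containing gaps,
ambiguity codes or stop codons are skipped. The synonymous p-distance is
*p*<sub>S</sub> = *S*<sub>d</sub>/*S*, deliberately uncorrected (a
Jukes–Cantor-corrected variant is not applied by default because at the
sub-percent distances this package targets the correction is negligible and
the uncorrected ratio is what the dating formula expects). Divergence time
in million years is *T* = *p*<sub>S</sub>/(2*r*) with
*r* = 4.5×10⁻⁹ synonymous substitutions/site/yr, the rate estimated for
banana coding sequences. The headline estimate pools
*S*<sub>d</sub> and *S* over the concatenation of all pairs rather than
averaging per-gene ratios; per-gene values are reported alongside.

**Noncoding clock.** LTR retroelements carry two LTRs that are identical at
insertion, so their divergence dates the element: *T* = *K*/(2*r*) with *K*
the Kimura 2-parameter distance between the aligned LTRs
(*K* = −½ ln(1−2P−Q) − ¼ ln(1−2Q); gap and ambiguous columns excluded;
non-positive log arguments raise an explicit saturation error) and
*r* = 9×10⁻⁹ /site/yr — two-fold the coding rate, reflecting faster
noncoding evolution. Only LTR pairs of at least 300 bp are dated by
default; shorter pairs give estimates too noisy to report.

The Nei–Gojobori counter is validated in the test suite against an
independent brute-force pathway enumerator built directly on Biopython's
translation table; agreement is exact, without tolerance.

## LTR retroelement structural annotation

Candidate elements are found by self-comparison of the search range:
direct-repeat pairs are chained from exact k-mer anchors (k = 11) with a
minimum internal separation. Anchor-derived boundaries are then sharpened
in two steps: a local alignment of the two copies trims unrelated flank,
and a joint micro-shift search (±5 bp on all four boundaries) scores every
structural signal at once — shared TG starts, shared CA ends, an exact
4–6 bp target-site duplication between the left flank of the 5′ copy and
the right flank of the 3′ copy, and equal LTR lengths — preferring small
shifts. This mirrors how integrase signatures are used to resolve
boundaries in practice and recovers planted LTR lengths and TSD texts
exactly even when terminal bases have mutated. The refined LTR pair is
re-aligned globally for the identity and K2P estimates. A near-TSD with
one mismatch can be reported behind the `allow_tsd_mismatch` flag.

## SSR analysis

SSRs are maximal perfect tandem repeats of 2–6 bp units. Homopolymers are
excluded; a run is only reported at its smallest period, so a (CTCT)ₙ run
appears once as CT. Minimum repeat counts are di ≥ 6, tri ≥ 5,
tetra/penta/hexa ≥ 4 (configurable); these survey-style thresholds are a
package choice, since any SSR census is threshold-dependent. Motifs are
canonicalised to the lexicographically minimal rotation over both strands
(CT/TC/AG/GA → AG). Cross-haplotype matching projects each locus through
the colinear block that contains it, using the nearest exact anchor for the
coordinate mapping (robust to large internal indels), and pairs same-motif
loci within a 500 bp tolerance; loci inside RGA coding sequence are
excluded from the common-noncoding report because orthology of coding
microsatellites within a tandem array is ambiguous. The repeat-count
difference of a matched pair is its heterozygosity.

## Gene family analysis

**Classification** uses protein-similarity coverage of the best reference
(Qcov, Scov) plus expression-preventing mutations (missing start/stop,
non-canonical splice, frameshift, in-frame stop, TE insertion), evaluated
most-degraded-first: remnant (Qcov < 0.3, or more than three alignment
fragments with Qcov < 0.5, or more than two mutations), else pseudogene
(≥ 1 mutation), else fragment (Qcov < 0.8), else complete
(Qcov ≥ 0.8 and Scov ≥ 0.8). The precedence order is a design choice — the
rules themselves do not order themselves — and prevents, e.g., a
Qcov = 0.25 relic being labelled merely "fragment".

**Allele assignment** works on the pairwise identity matrix of all family
CDSs (global affine alignment, identity over non-gap columns). A gene
whose best and second-best cross-haplotype identities lie within
`tie_margin = 0.01` of each other (at identity ≥ `min_identity = 0.90`) is
flagged ambiguous together with its near-tied partners — the signature of a
recent within-haplotype duplication, which genuinely has no unique allele.
Remaining genes pair by reciprocal best identity ≥ 0.90; the rest are
haplotype-specific paralogs. Clades come from average-linkage hierarchical
clustering of 1 − identity cut at 1 − 0.80; the cut sits between the
~0.70 inter-clade and ~0.90 intra-clade identity levels typical of such
families, and labels are renumbered by smallest member index so they are
permutation-invariant.

**Domain annotation** locates the NB-ARC motifs (P-loop, RNBS-A, kinase-2,
RNBS-B, RNBS-C, GLPL, RNBS-D, MHD) by ordered regular-expression search,
each downstream of the previous hit. The shipped patterns are loose,
field-standard consensus approximations and are explicitly meant to be
overridden per family — motif definitions are not standardised. LRR
repeats are scanned greedily against the consensus
`LxxLxxLxxLxLxx(N/C/T)x(x)LxxIPxx` (L = aliphatic {L,I,V,M,F}; the `(x)`
is an optional extra residue): a window is accepted when at least 70% of
the nine constrained positions are satisfied, a tolerance required because
real repeats are degenerate. The x positions of each repeat's `LxxLxLxx`
core are reported as solvent-exposed positions.

## Recombination breakpoints

A putative recombinant is globally aligned to each candidate parent and
percent identity computed in sliding windows (default 100 bp window, 10 bp
step) along the recombinant; gaps count as mismatches inside windows
(conservative: penalises indel-rich misalignments), and windows with under
50% aligned coverage are masked. Each window votes for its best parent;
windows where no site separates the parents are uninformative and do not
vote. A breakpoint is called at the midpoint between adjacent runs of
different labels when both runs span ≥ 3 windows and the mean identity
advantage is ≥ 0.02 on both sides. Breakpoint positions are therefore
accurate only to window resolution (≈ window/2 + step). At parent–parent
divergence near 3%, the 0.02 advantage gate sits close to the sampling
noise of a 100 bp window and recovery drops below the ~99% seen at 5%
divergence; the defaults favour specificity (no calls when the recombinant
equals one parent) over sensitivity at very low divergence.

The unequal-recombination screen locates all copies of a duplicated
intergenic probe (≥ 200 bp) by anchor-seeded candidate spans verified with
global alignment at identity ≥ 0.7, both strands, non-overlapping
best-first. Every colinearity breakpoint (block boundary or indel ≥ 5 kb)
within 2 kb of a copy becomes a candidate event, and the two nearest
copies are profiled against the fused region so the identity shift can be
inspected with the same breakpoint caller. Statistical significance
testing of recombination events is out of scope; the calls are structural.

## The synthetic-data generator

The generator emulates the structure the analysis assumes: an ancestral
locus with conserved flanking genes (four upstream, an MTERF-like and a
kinase-like gene downstream), a central tandem array of single-exon
CC-NB-LRR genes in two clades (two direct-strand copies; the reverse-strand
clade expanded), interspersed MTERF-like fragments, four copies of a 1 kb
noncoding intergenic repeat, planted perfect SSRs, and intergenic
background at 40% GC. Coding sequence matches that composition because
synonymous-codon choice is weighted by the background base frequencies and
the amino-acid composition is AT-leaning (plant-proteome-like); genome-wide
GC lands at 0.40 ± 0.01. Default sizes (eight RGA copies of 2.4 kb,
1 kb spacers, ≈ 50 kb per haplotype) are a deliberately compact rendering
of a real cluster locus — the structure, rates and event types are
faithful; the sequence scale is reduced so that full analyses and
50-replicate calibrations run in seconds.

Divergence is simulated per haplotype for *T* = 1 MY by default:

- noncoding sites substitute with probability `rate_noncoding × T` with a
  2:1 transition:transversion ratio, making the K2P model well-specified
  for LTR dating;
- CDS sites receive uniformly proposed substitutions at
  `rate_coding × T`; synonymous proposals are always accepted,
  nonsynonymous ones with probability ω = 0.15 (purifying selection), and
  proposals creating stop codons are rejected. With a uniform alternative-
  base choice the expected Nei–Gojobori synonymous p-distance between the
  haplotypes is exactly 2 *r* *T*, so clock recovery is unbiased. A 2:1
  transition bias is *not* used inside CDS: transitions at two-fold
  degenerate sites are predominantly synonymous, which would inflate
  *S*<sub>d</sub> relative to the unweighted site counts and bias recovered
  *T* upward by ~20%. Amino-acid changes at NB-ARC motif letters and LRR
  structural positions are restricted to their residue class, emulating
  purifying selection on the domain scaffold, so diverged family members
  still carry 15 detectable LRR repeats and the full motif series.
- clade and paralog divergence use the same CDS mutator at 30% and 15%
  per-site proposal rates. The paralog level is chosen so within-clade
  copies align at ~0.87 identity — inside the family's observed range but
  clearly below the 0.95–0.99 band where allelic pairs live and below the
  0.90 pairing threshold, which makes allele-pairing truth well-defined;
- retroelement insertions write an exact `TG…CA`-terminated LTR pair
  around a random internal region, duplicate the 4–6 bp target site, then
  mutate each LTR independently to `age × rate_noncoding`, so K2P dating
  of the pair is calibrated to the planted age;
- SSR slippage deltas are configured, not stochastic, so heterozygosity
  truth is exact; planted SSR loci (±6 bp of flank) are protected from
  point substitutions for the same reason;
- the intragenic event splices two paralog CDSs at a configured breakpoint
  into a third gene; the intergenic event deletes the block of genes
  between two copies of the 1 kb repeat on haplotype B, fusing the copies.

Structural edits are applied in coordinate-descending order and every
recorded coordinate (features, genes, truth records) is shifted through
each edit, so the truth table always resolves on the emitted sequences.
Identical configurations (including the seed) produce byte-identical
output.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: indel evolution other than planted events,
nested or truncated retroelements, compound/imperfect SSRs, multi-exon RGA
genes, segmental inversions, sequencing or assembly error, and
population-level processes (a single ancestor splits into exactly two
lineages). Real annotations also carry uncertainty in gene models and
repeat boundaries that the simulator's exact coordinates do not.

## Numerical choices and degenerate inputs

- Alignment scores are integers by construction; traceback ties resolve
  deterministically (substitution > gap-in-a > gap-in-b).
- All randomness flows from `numpy.random.default_rng` seeds; profiles,
  chains and clustering are deterministic given inputs.
- Empty anchor sets, empty feature sets and zero-length overlaps return
  empty results; zero eligible columns (diversity, K2P, p-distance) raise
  explicit undefined-value errors rather than returning NaN.
- K2P saturation (log argument ≤ 0) raises a typed error; callers that
  date elements catch it and report the element undated.
- Codon pairs whose every substitution pathway passes through a stop codon
  split their differences evenly between synonymous and nonsynonymous —
  an arbitrary but symmetric convention for an (extremely rare) corner.

## Validation problem sizes

The shipped acceptance script and test suite size their computations to
the package's own calibration standards: 50 simulated pairs for the
divergence clock (mean recovered *T* expected in [0.85, 1.15] MY), 30
replicates × 3 element ages for the LTR clock (pooled means within 3
binomial standard errors), 200 random 30-codon pairs for the
Nei–Gojobori oracle, alignments up to 2 kb for the banded/full-DP
equivalence, and 100 planted chimeras at 5% parent divergence for
breakpoint recovery (≥ 95% within window/2 + step).
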