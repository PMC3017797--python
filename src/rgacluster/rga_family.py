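"""NB-LRR gene family analysis: classification, allele pairing, clades,
domain annotation and coding microsatellites.

Gene models are classified complete / pseudogene / fragment / remnant from
protein-similarity coverage (Qcov/Scov) and expression-preventing mutations,
evaluated most-degraded-first.  Allelic relationships across the two
haplotypes are assigned by reciprocal best identity with an ambiguity margin
(recent within-haplotype duplications can tie a gene's best cross-haplotype
partners).  The family is split into clades by average-linkage hierarchical
clustering of 1 - identity.  Domain annotation locates the ordered NB-ARC
motifs (P-loop .. MHD) and scans the C-terminal region for leucine-rich
repeats matching the consensus LxxLxxLxxLxLxx(N/C/T)x(x)LxxIPxx, recording
the solvent-exposed x positions of each repeat's LxxLxLxx core.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from . import moldating
from .alignment import biopython_global
from .locus_io import GeneModel
from .repeats import SSRLocus

ALIPHATIC = set("LIVMF")

#: Default seed patterns for the ordered NB-ARC motifs.  These are loose,
#: field-standard consensus approximations and are meant to be overridden
#: from a config file for a specific gene family.
DEFAULT_NBARC_PATTERNS: dict[str, str] = {
    "P-loop": r"G[GSAM][GSAVM]GKTT",
    "RNBS-A": r"F[DE][LIVM].{1,3}W",
    "kinase-2": r"[LIVMF][LIVM][LIVM]DD[VIL][WDE]",
    "RNBS-B": r"[GS][SN]R[LIVM][LIVM][LIVM]TTR",
    "RNBS-C": r"[YWF].{2}L.{2}[LIVM].{2}[EDQ]",
    "GLPL": r"GLPL[AG]",
    "RNBS-D": r"CF[LIVMA][YF]C[AS]",
    "MHD": r"[LIVM]?MHD[LIVM]",
}


@dataclass
class SimilarityEvidence:
    """Best-reference protein similarity summary for one gene."""

    gene_id: str
    q_cov: float
    s_cov: float
    identity: float = 0.0
    n_fragments: int = 1

    def __post_init__(self) -> None:
        for frac in (self.q_cov, self.s_cov, self.identity):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{self.gene_id}: fraction {frac} outside [0,1]")
        if self.n_fragments < 1:
            raise ValueError(f"{self.gene_id}: n_fragments must be >= 1")


@dataclass
class GeneClass:
    label: str  # complete | pseudogene | fragment | remnant
    sublabel: str | None = None  # N_terminal | C_terminal for fragments/remnants


@dataclass
class AllelicPairing:
    pairs: list[tuple[str, str, float]]
    ambiguous: list[tuple[str, str, str]]
    unpaired: list[str]


@dataclass
class LRRRepeat:
    start: int  # protein coordinates, 0-based
    end: int
    score: float
    exposed_positions: list[int]


@dataclass
class NBLRRAnnotation:
    nbarc_motifs: dict[str, tuple[int, int]]
    lrr_repeats: list[LRRRepeat]
    exposed_positions: list[int]
    coding_ssrs: list[SSRLocus] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Classification


def classify_gene(model: GeneModel, evidence: SimilarityEvidence | None) -> GeneClass:
    """Classify a gene model by completeness, most-degraded-first.

    remnant: Qcov < 0.3, or more than three alignment fragments with
    Qcov < 0.5, or more than two expression-preventing mutations;
    else pseudogene: at least one such mutation; else fragment: Qcov < 0.8;
    else complete: Qcov >= 0.8 and Scov >= 0.8 with a canonical CDS.
    """
    n_disruptions = len(model.disruptions)
    if evidence is None:
        # classify on disruptions alone
        if n_disruptions > 2:
            return GeneClass("remnant")
        if n_disruptions >= 1:
            return GeneClass("pseudogene")
        return GeneClass("complete")
    if (
        evidence.q_cov < 0.3
        or (evidence.n_fragments > 3 and evidence.q_cov < 0.5)
        or n_disruptions > 2
    ):
        return GeneClass("remnant")
    if n_disruptions >= 1:
        return GeneClass("pseudogene")
    if evidence.q_cov < 0.8:
        return GeneClass("fragment")
    if evidence.q_cov >= 0.8 and evidence.s_cov >= 0.8:
        return GeneClass("complete")
    return GeneClass("fragment")  # e.g. s_cov < 0.8 with full query coverage


# ---------------------------------------------------------------------------
# Identity matrix, alleles, clades


def pairwise_identity_matrix(cds_list: list[str]) -> np.ndarray:
    """Symmetric matrix of pairwise global-alignment identities.

    Identity is computed over aligned non-gap columns of an affine-gap
    global alignment; the diagonal is 1.
    """
    n = len(cds_list)
    if n < 2:
        raise ValueError("need at least two sequences")
    for i, s in enumerate(cds_list):
        if not s:
            raise ValueError(f"sequence {i} is empty")
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident = biopython_global(cds_list[i], cds_list[j]).identity()
            mat[i, j] = mat[j, i] = ident
    return mat


def assign_alleles(
    matrix: np.ndarray,
    haplotype_of_gene: list[str],
    gene_ids: list[str] | None = None,
    min_identity: float = 0.90,
    tie_margin: float = 0.01,
) -> AllelicPairing:
    """Reciprocal-best-identity allele pairing across haplotypes.

    A gene whose best and second-best cross-haplotype identities differ by
    at most ``tie_margin`` is flagged ambiguous (with its two near-tied
    partners) instead of paired.  Remaining genes pair when each is the
    other's best cross-haplotype match at identity >= ``min_identity``;
    everything left is a haplotype-specific paralog.
    """
    n = matrix.shape[0]
    ids = gene_ids if gene_ids is not None else [str(i) for i in range(n)]
    haps = list(haplotype_of_gene)

    def cross_ranked(i: int) -> list[int]:
        others = [j for j in range(n) if haps[j] != haps[i]]
        return sorted(others, key=lambda j: -matrix[i, j])

    ambiguous: list[tuple[str, str, str]] = []
    ambiguous_genes: set[int] = set()
    best: dict[int, int] = {}
    for i in range(n):
        ranked = cross_ranked(i)
        if not ranked:
            continue
        best[i] = ranked[0]
        if (
            len(ranked) > 1
            and matrix[i, ranked[0]] >= min_identity
            and matrix[i, ranked[0]] - matrix[i, ranked[1]] <= tie_margin
        ):
            ambiguous.append((ids[i], ids[ranked[0]], ids[ranked[1]]))
            ambiguous_genes.update({i, ranked[0], ranked[1]})

    pairs: list[tuple[str, str, float]] = []
    paired: set[int] = set()
    for i in range(n):
        j = best.get(i)
        if j is None or i in paired or j in paired:
            continue
        if i in ambiguous_genes or j in ambiguous_genes:
            continue
        if best.get(j) == i and matrix[i, j] >= min_identity and haps[i] != haps[j]:
            lo, hi = (i, j) if ids[i] <= ids[j] else (j, i)
            pairs.append((ids[lo], ids[hi], float(matrix[i, j])))
            paired.update({i, j})
    unpaired = [ids[i] for i in range(n) if i not in paired and i not in ambiguous_genes]
    pairs.sort()
    return AllelicPairing(pairs=pairs, ambiguous=ambiguous, unpaired=sorted(unpaired))


def cluster_clades(
    matrix: np.ndarray,
    cut_identity: float = 0.80,
) -> list[int]:
    """Average-linkage clustering of 1 - identity, cut at 1 - cut_identity.

    Clade labels are deterministic: clades are numbered 1, 2, ... by the
    smallest member index, invariant under input permutation.
    """
    dist = 1.0 - np.asarray(matrix, dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = average(squareform(dist, checks=False))
    raw = fcluster(linkage, t=1.0 - cut_identity, criterion="distance")
    # renumber by smallest member index
    order: dict[int, int] = {}
    for idx, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order) + 1
    remap = {}
    for lab in sorted(order, key=lambda L: min(i for i, x in enumerate(raw) if x == L)):
        remap[lab] = len(remap) + 1
    return [remap[lab] for lab in raw]


# ---------------------------------------------------------------------------
# Domain annotation

_NBARC_ORDER = list(DEFAULT_NBARC_PATTERNS)

# LRR consensus: L x x L x x L x x L x L x x (N/C/T) x (x) L x x I P x x
# Constrained positions without the optional extra x (unit length 23):
_LRR_CONSTRAINTS = [
    (0, ALIPHATIC),
    (3, ALIPHATIC),
    (6, ALIPHATIC),
    (9, ALIPHATIC),
    (11, ALIPHATIC),
    (14, set("NCT")),
    (16, ALIPHATIC),
    (19, set("I")),
    (20, set("P")),
]
_LRR_CORE_X = [7, 8, 10, 12, 13]  # x positions of the LxxLxLxx core
LRR_UNIT_LEN = 23


def _lrr_score(window: str, extra_x: int) -> float:
    hits = 0
    for pos, allowed in _LRR_CONSTRAINTS:
        p = pos + (extra_x if pos >= 16 else 0)
        if p < len(window) and window[p] in allowed:
            hits += 1
    return hits / len(_LRR_CONSTRAINTS)


def annotate_nblrr(
    protein_text: str,
    motif_patterns: dict[str, str] | None = None,
    lrr_score_threshold: float = 0.7,
) -> NBLRRAnnotation:
    """Locate NB-ARC motifs and LRR repeats on a protein sequence.

    Motifs are searched in their canonical order, each downstream of the
    previous hit.  LRR repeats are scanned greedily left-to-right with both
    consensus variants (with/without the optional extra x) and accepted at
    score >= ``lrr_score_threshold``; internal stops truncate the annotated
    region with a warning.
    """
    warnings: list[str] = []
    protein_text = protein_text.upper()
    if "*" in protein_text:
        protein_text = protein_text.split("*", 1)[0]
        warnings.append("internal stop codon: annotation truncated at first stop")
    patterns = dict(DEFAULT_NBARC_PATTERNS)
    if motif_patterns:
        patterns.update(motif_patterns)
    if len(protein_text) < LRR_UNIT_LEN:
        return NBLRRAnnotation({}, [], [], warnings=warnings + ["sequence shorter than one LRR unit"])

    motifs: dict[str, tuple[int, int]] = {}
    cursor = 0
    for name in _NBARC_ORDER:
        pat = patterns.get(name)
        if not pat:
            continue
        m = re.search(pat, protein_text[cursor:])
        if m:
            motifs[name] = (cursor + m.start(), cursor + m.end())
            cursor += m.end()

    # LRR scan starts after the NB-ARC domain when located
    lrr_from = motifs.get("MHD", (0, 0))[1]
    repeats: list[LRRRepeat] = []
    i = lrr_from
    n = len(protein_text)
    while i <= n - (LRR_UNIT_LEN - 2):
        best = None
        for extra in (0, 1):
            unit_len = LRR_UNIT_LEN + extra
            window = protein_text[i : i + unit_len]
            score = _lrr_score(window, extra)
            if best is None or score > best[0]:
                best = (score, unit_len)
        score, unit_len = best
        if score >= lrr_score_threshold:
            repeats.append(
                LRRRepeat(
                    start=i,
                    end=min(i + unit_len, n),
                    score=score,
                    exposed_positions=[i + p for p in _LRR_CORE_X],
                )
            )
            i += unit_len
        else:
            i += 1
    exposed = [p for rep in repeats for p in rep.exposed_positions]
    return NBLRRAnnotation(
        nbarc_motifs=motifs, lrr_repeats=repeats, exposed_positions=exposed, warnings=warnings
    )


# ---------------------------------------------------------------------------
# Coding microsatellites


@dataclass
class CodingSSRReport:
    loci: list[SSRLocus]
    tracts: list[str]  # e.g. "S x9"
    compound: list[list[SSRLocus]]  # adjacent same-frame units merged


def detect_coding_ssr(cds_text: str, min_repeats: int = 4) -> CodingSSRReport:
    """Trinucleotide SSRs within a CDS, with the encoded amino-acid tract.

    Adjacent units (contiguous ranges) are merged into compound reports,
    e.g. a (GAT)n(GCT)n(GAA)n run at the 3' end.
    """
    from .repeats import scan_ssr

    cds_text = cds_text.upper()
    loci = [
        loc
        for loc in scan_ssr(cds_text, {2: 10**9, 3: min_repeats, 4: 10**9, 5: 10**9, 6: 10**9})
        if len(loc.unit) == 3
    ]
    tracts = []
    for loc in loci:
        # translate the codons of the reading frame covering the repeat
        frame_start = loc.start - (loc.start % 3)
        frame_end = loc.end + (-loc.end) % 3
        codons = [
            cds_text[i : i + 3]
            for i in range(frame_start, min(frame_end, len(cds_text) - 2), 3)
        ]
        aas = [moldating.CODON_AA.get(c, "X") for c in codons if len(c) == 3]
        dominant = max(set(aas), key=aas.count) if aas else "X"
        tracts.append(f"{dominant}x{aas.count(dominant)}")
    compound: list[list[SSRLocus]] = []
    current: list[SSRLocus] = []
    for loc in loci:
        if current and loc.start - current[-1].end <= 3:
            current.append(loc)
        else:
            if len(current) > 1:
                compound.append(current)
            current = [loc]
    if len(current) > 1:
        compound.append(current)
    return CodingSSRReport(loci=loci, tracts=tracts, compound=compound)


def pairwise_dnds(alignment: moldating.CodonAlignment) -> tuple[float | None, float | None, float | None]:
    """(pN, pS, pN/pS) via Nei-Gojobori counts; ratio None when pS = 0."""
    cnt = moldating.nei_gojobori(alignment)
    p_n = cnt.Nd / cnt.N if cnt.N > 0 else None
    p_s = cnt.Sd / cnt.S if cnt.S > 0 else None
    ratio = (p_n / p_s) if (p_n is not None and p_s not in (None, 0.0)) else None
    return p_n, p_s, ratio
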