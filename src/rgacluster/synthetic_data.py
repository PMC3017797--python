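"""Synthetic haplotype-pair generator with a full ground-truth table.

The generator emulates the structure the comparative analysis assumes: a
single ancestral locus carrying conserved flanking genes, a central tandem
array of single-exon CC-NB-LRR (RGA) genes in two clades (a small direct-
strand clade and an expanded reverse-strand clade), interspersed MTERF-like
fragments, copies of a ~1 kb duplicated noncoding intergenic repeat,
planted perfect SSRs, and 40%-GC intergenic background.  Two haplotypes
then descend independently from the ancestor for T million years:

* noncoding sites mutate at ``rate_noncoding`` (default 9e-9/site/yr) with
  a 2:1 transition:transversion ratio, so K2P-based dating is
  well-specified;
* CDS sites receive uniformly proposed substitutions at the synonymous rate
  (default 4.5e-9/site/yr); synonymous proposals are always accepted and
  nonsynonymous ones with probability ``omega`` (purifying selection), so
  the expected Nei-Gojobori synonymous p-distance between haplotypes is
  exactly 2 r T;
* configured LTR retroelements are inserted with exact TG...CA-terminated
  LTR pairs plus a target-site duplication, then each LTR accumulates
  age x rate_noncoding substitutions so the element dates to its age;
* configured SSR loci slip by a fixed repeat-count delta on haplotype B;
* an intragenic unequal-recombination event splices two paralog CDSs into
  a chimeric gene, and an intergenic event deletes a block of RGA genes
  between two copies of the 1 kb repeat on haplotype B.

Every planted event is recorded in a TruthTable with coordinates that stay
valid on the emitted haplotypes (structural edits are applied in
coordinate-descending order and all recorded coordinates are shifted).
Identical configs (including the seed) produce byte-identical fixtures.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .locus_io import (
    AnnotatedLocus,
    Feature,
    FeatureKind,
    GeneModel,
    HaplotypeSequence,
    reverse_complement,
    write_fasta,
    write_gff3,
)
from .moldating import CODON_AA, CODING_RATE, NONCODING_RATE, STOP_CODONS

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# codons per amino acid, for encoding designed proteins
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in CODON_AA.items():
    if aa != "*":
        _CODONS_BY_AA.setdefault(aa, []).append(codon)
for codons in _CODONS_BY_AA.values():
    codons.sort()

_ALIPHATIC = "LIVMF"
_LRR_X = "KNEDSTYQ"  # filler residues for x positions (never aliphatic, AT-leaning)

# NB-ARC seed motifs planted in the template protein, in canonical order
_NBARC_SEEDS = [
    ("P-loop", "GGVGKTT"),
    ("RNBS-A", "FDLRAW"),
    ("kinase-2", "LLVLDDVW"),
    ("RNBS-B", "GSRIIITTR"),
    ("RNBS-C", "YAALAAIAAE"),
    ("GLPL", "GLPLA"),
    ("RNBS-D", "CFLYCA"),
    ("MHD", "MHDL"),
]


@dataclass
class RetroEvent:
    haplotype: str = "A"  # which haplotype receives the insertion
    age_my: float = 0.3
    ltr_length: int = 400
    internal_length: int = 1500
    tsd_length: int = 4


@dataclass
class SSRSpec:
    motif: str = "CT"
    repeat_count: int = 12
    slippage_delta: int = 0  # repeat-count change on haplotype B


@dataclass
class SimulationConfig:
    seed: int = 0
    n_rga: int = 8
    n_clade1: int = 2  # direct-strand RGAs; the rest form the expanded clade
    rga_template_length: int = 2400  # nt including start and stop
    n_flank_left: int = 4
    n_flank_right: int = 2  # MTERF-like gene + kinase-like gene
    flank_cds_length: int = 1200
    spacer_length: int = 1000
    gc_background: float = 0.40
    clade_divergence: float = 0.30  # nt divergence between clade ancestors
    # paralog divergence is chosen so within-clade copies align at ~85-90%
    # identity — inside the family's observed range but clearly below the
    # 95-99% band where allelic pairs live, so pairing truth is well-defined
    paralog_divergence: float = 0.15
    divergence_T: float = 1.0  # million years per haplotype lineage pair
    rate_coding: float = CODING_RATE
    rate_noncoding: float = NONCODING_RATE
    omega: float = 0.15  # acceptance probability of nonsynonymous proposals
    retro_events: list[RetroEvent] = field(
        default_factory=lambda: [
            RetroEvent("A", 0.3, 400, 1500, 4),
            RetroEvent("A", 1.2, 400, 1500, 4),
            RetroEvent("B", 2.2, 400, 1500, 5),
        ]
    )
    ssr_loci: list[SSRSpec] = field(
        default_factory=lambda: [
            SSRSpec("CT", 12, 4),
            SSRSpec("GA", 10, 0),
            SSRSpec("AAT", 8, 2),
            SSRSpec("ATG", 9, -3),
        ]
    )
    intergenic_repeat_length: int = 1000
    intergenic_repeat_copies: int = 4
    intragenic_event: bool = True
    intragenic_breakpoint_frac: float = 0.5
    intergenic_event: bool = True
    n_deleted_genes: int = 2

    def __post_init__(self) -> None:
        if self.rate_coding <= 0 or self.rate_noncoding <= 0:
            raise ValueError("substitution rates must be positive")
        if self.divergence_T < 0:
            raise ValueError("divergence_T must be nonnegative")
        if self.n_clade1 > self.n_rga:
            raise ValueError("n_clade1 cannot exceed n_rga")
        if self.intergenic_event and self.n_rga and (
            self.n_deleted_genes >= self.n_rga - self.n_clade1
        ):
            raise ValueError("cannot delete that many clade-2 genes")


@dataclass
class TruthTable:
    allele_pairs: list[str] = field(default_factory=list)  # gene ids on both haplotypes
    a_specific: list[str] = field(default_factory=list)
    b_specific: list[str] = field(default_factory=list)
    clade_labels: dict[str, int] = field(default_factory=dict)
    ssr: list[dict] = field(default_factory=list)
    retro: list[dict] = field(default_factory=list)
    intragenic: list[dict] = field(default_factory=list)
    intergenic: list[dict] = field(default_factory=list)
    substitutions: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence builders


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=length, p=probs))


_CODON_WEIGHTS: dict[str, np.ndarray] = {}


def _codon_weights(aa: str, gc: float) -> np.ndarray:
    """Synonymous-codon weights matching the background base composition,
    so coding and noncoding sequence share one GC content (plant nuclear
    genomes show exactly this AT-biased wobble)."""
    key = f"{aa}:{gc:.3f}"
    if key not in _CODON_WEIGHTS:
        w = []
        for codon in _CODONS_BY_AA[aa]:
            p = 1.0
            for b in codon:
                p *= (gc / 2) if b in "GC" else ((1 - gc) / 2)
            w.append(p)
        arr = np.array(w)
        _CODON_WEIGHTS[key] = arr / arr.sum()
    return _CODON_WEIGHTS[key]


def _encode_protein(rng: np.random.Generator, protein: str, gc: float = 0.40) -> str:
    parts = []
    for aa in protein:
        codons = _CODONS_BY_AA[aa]
        parts.append(codons[rng.choice(len(codons), p=_codon_weights(aa, gc))])
    return "".join(parts)


# AT-leaning amino-acid composition (plant-proteome-like, tilted toward
# residues with AT-rich codon families) so coding sequence matches the
# 40% GC background under the wobble weighting of _encode_protein
_AA_LETTERS = list("LSAGVEKIDTRPNFQYMHCW")
_AA_FREQS = np.array(
    [0.0979, 0.0831, 0.0472, 0.0451, 0.0646, 0.0636, 0.0880, 0.0745, 0.0518,
     0.0489, 0.0347, 0.0333, 0.0610, 0.0583, 0.0352, 0.0393, 0.0247, 0.0225,
     0.0176, 0.0090]
)
_AA_FREQS = _AA_FREQS / _AA_FREQS.sum()


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA_LETTERS, size=length, p=_AA_FREQS))


# LRR unit layout (23 aa): constrained positions and their allowed classes
_LRR_UNIT_CONSTRAINTS = {
    0: set(_ALIPHATIC), 3: set(_ALIPHATIC), 6: set(_ALIPHATIC),
    9: set(_ALIPHATIC), 11: set(_ALIPHATIC), 14: set("NCT"),
    16: set(_ALIPHATIC), 19: set("I"), 20: set("P"),
}


def _lrr_unit(rng: np.random.Generator) -> str:
    x = lambda: _LRR_X[rng.integers(len(_LRR_X))]
    L = lambda: _ALIPHATIC[rng.integers(3)]  # L/I/V
    nct = "NCT"[rng.integers(3)]
    return (
        L() + x() + x() + L() + x() + x() + L() + x() + x() + L() + x() + L()
        + x() + x() + nct + x() + L() + x() + x() + "I" + "P" + x() + x()
    )


def build_rga_template(
    rng: np.random.Generator, total_nt: int, n_lrr: int = 15
) -> tuple[str, dict[int, set[str]]]:
    """A single-exon CC-NB-LRR CDS: CC region, seeded NB-ARC motifs, and
    ``n_lrr`` exact-consensus LRR units, padded to ``total_nt`` (incl. stop).

    Returns the CDS and a map of constrained protein positions to their
    allowed residue classes (NB-ARC motif letters, LRR structural
    positions); divergence within the family respects these, emulating
    purifying selection on the domain scaffold.
    """
    aa_total = total_nt // 3 - 1  # minus stop codon
    constraints: dict[int, set[str]] = {}
    nbarc = ""
    nbarc_offset = 0
    nbarc_parts: list[tuple[int, str]] = []
    for _, seed in _NBARC_SEEDS:
        nbarc_parts.append((nbarc_offset, seed))
        nbarc += seed + _random_protein(rng, 18)
        nbarc_offset += len(seed) + 18
    lrr = "".join(_lrr_unit(rng) for _ in range(n_lrr))
    cc_len = aa_total - len(nbarc) - len(lrr) - 1  # minus leading M
    if cc_len < 20:
        raise ValueError("rga_template_length too short for the domain layout")
    protein = "M" + _random_protein(rng, cc_len) + nbarc + lrr
    nbarc_at = 1 + cc_len
    for off, seed in nbarc_parts:
        for k, ch in enumerate(seed):
            constraints[nbarc_at + off + k] = {ch}
    lrr_at = nbarc_at + len(nbarc)
    for unit in range(n_lrr):
        for off, allowed in _LRR_UNIT_CONSTRAINTS.items():
            constraints[lrr_at + unit * 23 + off] = allowed
    return _encode_protein(rng, protein) + "TGA", constraints


def mutate_cds(
    rng: np.random.Generator,
    cds: str,
    divergence: float,
    constraints: dict[int, set[str]] | None = None,
) -> str:
    """Substitute ~divergence of CDS sites, never creating internal stops and
    keeping the start/stop codons intact.  At constrained protein positions,
    amino-acid changes outside the allowed class are rejected (purifying
    selection on the domain scaffold)."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for ci in range(1, len(codons) - 1):
        allowed = constraints.get(ci) if constraints else None
        new = codons[ci]
        for pos in range(3):
            if rng.random() >= divergence:
                continue
            alt = _BASES[rng.integers(4)]
            cand = new[:pos] + alt + new[pos + 1 :]
            if cand in STOP_CODONS:
                continue
            if allowed is not None and CODON_AA[cand] not in allowed and CODON_AA[cand] != CODON_AA[new]:
                continue
            new = cand
        codons[ci] = new
    return "".join(codons)


def _make_ssr(spec: SSRSpec) -> str:
    return spec.motif * spec.repeat_count


# ---------------------------------------------------------------------------
# the editable locus (sequence + annotations + truth anchors)


class _EditableLocus:
    """A haplotype under construction; structural edits shift everything."""

    def __init__(self, hap_id: str, sequence: str, genes: list[GeneModel], features: list[Feature]):
        self.id = hap_id
        self.sequence = sequence
        self.genes = genes
        self.features = features
        self.anchors: list[dict] = []  # truth records with 'start'/'end' keys

    def _remap_all(self, mv) -> None:
        for g in self.genes:
            g.exon_ranges = [(mv(s), mv(e)) for s, e in g.exon_ranges]
            g.cds_ranges = [(mv(s), mv(e)) for s, e in g.cds_ranges]
        for f in self.features:
            f.start, f.end = mv(f.start), mv(f.end)
        for rec in self.anchors:
            rec["start"], rec["end"] = mv(rec["start"]), mv(rec["end"])

    def insert(self, pos: int, text: str) -> None:
        self.sequence = self.sequence[:pos] + text + self.sequence[pos:]
        delta = len(text)
        self._remap_all(lambda x: x + delta if x >= pos else x)

    def delete(self, start: int, end: int) -> list[str]:
        """Remove [start, end); returns ids of genes wholly removed.
        Coordinates inside the removed range are clamped to its start, so
        straddling features become fused remainders."""
        removed = [g.id for g in self.genes if start <= g.span[0] and g.span[1] <= end]
        self.genes = [g for g in self.genes if g.id not in removed]
        self.features = [f for f in self.features if not (start <= f.start and f.end <= end)]
        self.sequence = self.sequence[:start] + self.sequence[end:]
        length = end - start

        def mv(x: int) -> int:
            if x >= end:
                return x - length
            if x > start:
                return start
            return x

        self._remap_all(mv)
        return removed

    def replace_range(self, start: int, end: int, text: str) -> None:
        assert len(text) == end - start
        self.sequence = self.sequence[:start] + text + self.sequence[end:]

    def to_locus(self) -> AnnotatedLocus:
        return AnnotatedLocus(
            sequence=HaplotypeSequence(self.id, self.sequence),
            features=self.features,
            genes=self.genes,
        )


# ---------------------------------------------------------------------------
# ancestor


@dataclass
class AncestorPlan:
    """Planted-element geometry decided at ancestor-construction time."""

    ssr_sites: list[dict] = field(default_factory=list)
    retro_sites: list[int] = field(default_factory=list)
    repeat_ranges: list[tuple[int, int]] = field(default_factory=list)
    deletable: dict | None = None  # {'genes', 'left_mid', 'right_mid'}
    intragenic: dict | None = None  # {'recombinant', 'parents'}
    clade_labels: dict[str, int] = field(default_factory=dict)


def simulate_ancestor(config: SimulationConfig) -> tuple[AnnotatedLocus, AncestorPlan]:
    """Build the ancestral locus and the geometry plan for planted events."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_background
    plan = AncestorPlan()

    parts: list[str] = []
    genes: list[GeneModel] = []
    features: list[Feature] = []
    pos = 0
    seq_id = "ancestor"

    ssr_queue = list(config.ssr_loci)
    retro_needed = len(config.retro_events)

    def spacer(tag: str, plant_ssr: bool = True, plant_retro_site: bool = True) -> None:
        nonlocal pos
        text = _random_seq(rng, config.spacer_length, gc)
        if plant_ssr and ssr_queue:
            spec = ssr_queue.pop(0)
            ssr_text = _make_ssr(spec)
            at = 150
            text = text[:at] + ssr_text + text[at + len(ssr_text):]
            plan.ssr_sites.append(
                {
                    "motif": spec.motif,
                    "repeat_count": spec.repeat_count,
                    "slippage_delta": spec.slippage_delta,
                    "start": pos + at,
                    "end": pos + at + len(ssr_text),
                }
            )
        if plant_retro_site and len(plan.retro_sites) < retro_needed:
            plan.retro_sites.append(pos + int(0.7 * config.spacer_length))
        parts.append(text)
        pos += len(text)

    def add_gene(gid: str, cds: str, strand: str, kind: FeatureKind = FeatureKind.gene) -> None:
        nonlocal pos
        text = cds if strand == "+" else reverse_complement(cds)
        genes.append(
            GeneModel(
                id=gid,
                seqid=seq_id,
                strand=strand,
                exon_ranges=[(pos, pos + len(text))],
                cds_ranges=[(pos, pos + len(text))],
            )
        )
        features.append(
            Feature(id=f"{gid}_feat", kind=kind, seqid=seq_id, start=pos, end=pos + len(text), strand=strand)
        )
        parts.append(text)
        pos += len(text)

    def add_repeat_copy(label: str, divergence: float, repeat_seq: str) -> tuple[int, int]:
        nonlocal pos
        text = _mutate_noncoding_text(rng, repeat_seq, divergence)
        features.append(
            Feature(
                id=label, kind=FeatureKind.intergenic_repeat, seqid=seq_id,
                start=pos, end=pos + len(text), strand="+",
            )
        )
        rng_range = (pos, pos + len(text))
        plan.repeat_ranges.append(rng_range)
        parts.append(text)
        pos += len(text)
        return rng_range

    n2 = config.n_rga - config.n_clade1
    # deletable block: the last n_deleted_genes clade-2 genes before the final one
    del_first = config.n_rga - 1 - config.n_deleted_genes if config.intergenic_event else None

    # --- left flank: conserved genes
    for i in range(config.n_flank_left):
        spacer(f"lf{i}", plant_ssr=(i % 2 == 0), plant_retro_site=(i == 1))
        protein = "M" + _random_protein(rng, config.flank_cds_length // 3 - 2)
        add_gene(f"FLK{i + 1:02d}", _encode_protein(rng, protein) + "TAA", "+")

    # --- RGA cluster
    template, constraints = build_rga_template(rng, config.rga_template_length)
    clade_anc = {
        1: template,
        2: mutate_cds(rng, template, config.clade_divergence, constraints),
    }
    repeat_seq = _random_seq(rng, config.intergenic_repeat_length, gc)

    clade_of = lambda i: 1 if i < config.n_clade1 else 2
    copies_placed = 1  # one copy reserved for the right flank (upstream MTERF)
    mterf_frag_count = 0

    rga_ids = [f"RGA{i + 1:02d}" for i in range(config.n_rga)]
    for i in range(config.n_rga):
        before_block = del_first is None or i < del_first
        spacer(
            f"cl{i}",
            plant_ssr=before_block,
            plant_retro_site=before_block and i % 2 == 0,
        )
        if del_first is not None and i == del_first:
            left_mid = add_repeat_copy("IGR_left", 0.03, repeat_seq)
        elif (
            copies_placed < config.intergenic_repeat_copies - (2 if del_first is not None else 0)
            and i == 1
        ):
            add_repeat_copy("IGR_extra%d" % copies_placed, 0.10, repeat_seq)
            copies_placed += 1
        if mterf_frag_count < 2 and i in (2, max(3, config.n_rga - 2)):
            frag = _random_seq(rng, 300, gc)
            features.append(
                Feature(
                    id=f"MTERF_frag{mterf_frag_count + 1}", kind=FeatureKind.remnant,
                    seqid=seq_id, start=pos, end=pos + len(frag), strand="+",
                )
            )
            parts.append(frag)
            pos += len(frag)
            mterf_frag_count += 1
        clade = clade_of(i)
        cds = mutate_cds(rng, clade_anc[clade], config.paralog_divergence, constraints)
        strand = "+" if clade == 1 else "-"
        add_gene(rga_ids[i], cds, strand)
        plan.clade_labels[rga_ids[i]] = clade
        if del_first is not None and i == del_first + config.n_deleted_genes - 1:
            spacer(f"cl{i}b", plant_ssr=False, plant_retro_site=False)
            right_mid = add_repeat_copy("IGR_right", 0.03, repeat_seq)

    if del_first is not None:
        plan.deletable = {
            "genes": rga_ids[del_first : del_first + config.n_deleted_genes],
            "left_range": left_mid,
            "right_range": right_mid,
        }
    if config.intragenic_event and n2 >= 3:
        clade2_ids = [g for g in rga_ids if plan.clade_labels[g] == 2]
        safe = [g for g in clade2_ids if not (plan.deletable and g in plan.deletable["genes"])]
        if len(safe) >= 3:
            plan.intragenic = {"recombinant": safe[0], "parents": (safe[1], safe[2])}

    # --- right flank: intergenic repeat master copy, MTERF gene, kinase gene
    spacer("rf0", plant_ssr=False, plant_retro_site=False)
    add_repeat_copy("IGR_master", 0.0, repeat_seq)
    spacer("rf1", plant_ssr=False, plant_retro_site=False)
    if config.n_flank_right >= 1:
        protein = "M" + _random_protein(rng, config.flank_cds_length // 3 - 2)
        add_gene("MTERF1", _encode_protein(rng, protein) + "TAA", "+")
    spacer("rf2", plant_ssr=False, plant_retro_site=False)
    if config.n_flank_right >= 2:
        protein = "M" + _random_protein(rng, config.flank_cds_length // 3 - 2)
        add_gene("STK1", _encode_protein(rng, protein) + "TAA", "+")
        spacer("rf3", plant_ssr=False, plant_retro_site=False)

    sequence = "".join(parts)
    locus = AnnotatedLocus(
        sequence=HaplotypeSequence(seq_id, sequence), features=features, genes=genes
    )
    return locus, plan


def _mutate_noncoding_text(rng: np.random.Generator, text: str, per_site: float) -> str:
    """Substitute noncoding text at the given per-site probability with a
    2:1 transition:transversion ratio."""
    if per_site <= 0:
        return text
    chars = list(text)
    hits = np.nonzero(rng.random(len(chars)) < per_site)[0]
    for i in hits:
        base = chars[i]
        if base not in _TRANSITION:
            continue
        if rng.random() < 0.5:
            chars[i] = _TRANSITION[base]
        else:
            chars[i] = _TRANSVERSIONS[base][rng.integers(2)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# divergence


def diverge_haplotypes(
    ancestor: AnnotatedLocus,
    config: SimulationConfig,
    plan: AncestorPlan,
) -> tuple[AnnotatedLocus, AnnotatedLocus, TruthTable]:
    """Descend two haplotypes from the ancestor and record the truth table."""
    rng = np.random.default_rng(config.seed + 1)
    truth = TruthTable()
    truth.clade_labels = dict(plan.clade_labels)

    editables = {}
    for hap in ("A", "B"):
        ed = _EditableLocus(
            f"hap{hap}",
            ancestor.sequence.residues,
            _copy.deepcopy(ancestor.genes),
            _copy.deepcopy(ancestor.features),
        )
        for g in ed.genes:
            g.seqid = ed.id
        for f in ed.features:
            f.seqid = ed.id
        editables[hap] = ed

    t_years = config.divergence_T * 1e6
    # pad by 6 bp: flank mutations could extend a repeat run in one haplotype
    # only, which would break the exactness of the slippage-delta truth
    protected = [(s["start"] - 6, s["end"] + 6) for s in plan.ssr_sites]
    for hap, ed in editables.items():
        n_sub = _apply_substitutions(rng, ed, config, t_years, protected)
        truth.substitutions[hap] = n_sub

    # truth anchors that must track structural edits
    for site in plan.ssr_sites:
        for hap, ed in editables.items():
            rec = {
                "kind": "ssr", "haplotype": hap, "motif": site["motif"],
                "start": site["start"], "end": site["end"],
                "repeat_count": site["repeat_count"],
                "slippage_delta": site["slippage_delta"],
            }
            ed.anchors.append(rec)

    # ---- structural events, applied per haplotype in descending coordinate order
    events: dict[str, list[tuple[int, str, object]]] = {"A": [], "B": []}
    for idx, rev in enumerate(config.retro_events):
        if idx >= len(plan.retro_sites):
            break  # no remaining planted insertion site for this event
        events[rev.haplotype].append((plan.retro_sites[idx], "retro", rev))
    if plan.deletable is not None:
        left = plan.deletable["left_range"]
        right = plan.deletable["right_range"]
        bp_left = (left[0] + left[1]) // 2
        bp_right = (right[0] + right[1]) // 2
        events["B"].append((bp_left, "intergenic_del", (bp_left, bp_right)))
    for site in plan.ssr_sites:
        if site["slippage_delta"]:
            events["B"].append((site["start"], "slippage", site))

    for hap, ed in editables.items():
        for pos, kind, payload in sorted(events[hap], key=lambda e: -e[0]):
            if kind == "retro":
                _insert_retroelement(rng, ed, pos, payload, config, truth)
            elif kind == "intergenic_del":
                _apply_intergenic_deletion(ed, payload, truth)
            elif kind == "slippage":
                _apply_slippage(ed, payload)

    # intragenic recombination: same-length CDS splice on haplotype A
    if plan.intragenic is not None:
        _apply_intragenic(editables["A"], plan.intragenic, config, truth)

    # SSR truth from anchors (coordinates now final)
    for hap, ed in editables.items():
        for rec in ed.anchors:
            if rec["kind"] == "ssr":
                delta = rec["slippage_delta"] if hap == "B" else 0
                truth.ssr.append(
                    {
                        "haplotype": hap, "motif": rec["motif"],
                        "start": rec["start"], "end": rec["end"],
                        "repeat_count": rec["repeat_count"] + delta,
                        "slippage_delta": rec["slippage_delta"],
                    }
                )

    rga_a = {g.id for g in editables["A"].genes if g.id.startswith("RGA")}
    rga_b = {g.id for g in editables["B"].genes if g.id.startswith("RGA")}
    truth.allele_pairs = sorted(rga_a & rga_b)
    truth.a_specific = sorted(rga_a - rga_b)
    truth.b_specific = sorted(rga_b - rga_a)

    locus_a = editables["A"].to_locus()
    locus_b = editables["B"].to_locus()
    return locus_a, locus_b, truth


def simulate_pair(config: SimulationConfig) -> tuple[AnnotatedLocus, AnnotatedLocus, TruthTable]:
    """Convenience: ancestor + divergence in one call."""
    ancestor, plan = simulate_ancestor(config)
    return diverge_haplotypes(ancestor, config, plan)


def _apply_substitutions(
    rng: np.random.Generator,
    ed: _EditableLocus,
    config: SimulationConfig,
    t_years: float,
    protected: list[tuple[int, int]] | None = None,
) -> int:
    """Noncoding substitutions at rate_noncoding, CDS proposals at
    rate_coding with synonymous acceptance 1 and nonsynonymous ``omega``.
    ``protected`` ranges (planted SSRs, whose heterozygosity truth must stay
    exact) receive no point substitutions."""
    n_before = len(ed.sequence)
    chars = list(ed.sequence)
    in_cds = np.zeros(len(chars), dtype=bool)
    for g in ed.genes:
        for s, e in g.cds_ranges:
            in_cds[s:e] = True
    skip = np.zeros(len(chars), dtype=bool)
    for s, e in protected or []:
        skip[s:e] = True
    count = 0

    p_nc = config.rate_noncoding * t_years
    if p_nc > 0:
        hits = np.nonzero((rng.random(len(chars)) < p_nc) & ~in_cds & ~skip)[0]
        for i in hits:
            base = chars[i]
            if base not in _TRANSITION:
                continue
            chars[i] = (
                _TRANSITION[base]
                if rng.random() < 0.5
                else _TRANSVERSIONS[base][rng.integers(2)]
            )
            count += 1

    ed.sequence = "".join(chars)

    p_c = config.rate_coding * t_years
    if p_c > 0:
        for g in ed.genes:
            s, e = g.cds_ranges[0]
            cds = ed.sequence[s:e]
            if g.strand == "-":
                cds = reverse_complement(cds)
            codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
            for ci in range(1, len(codons) - 1):
                codon = codons[ci]
                if codon in STOP_CODONS or codon not in CODON_AA:
                    continue
                for posn in range(3):
                    if rng.random() >= p_c:
                        continue
                    old = codons[ci]
                    alts = [b for b in _BASES if b != old[posn]]
                    alt = alts[rng.integers(3)]
                    cand = old[:posn] + alt + old[posn + 1 :]
                    if cand in STOP_CODONS:
                        continue
                    if CODON_AA[cand] == CODON_AA[old]:
                        codons[ci] = cand
                        count += 1
                    elif rng.random() < config.omega:
                        codons[ci] = cand
                        count += 1
            new_cds = "".join(codons) + cds[len(codons) * 3 :]
            if g.strand == "-":
                new_cds = reverse_complement(new_cds)
            ed.replace_range(s, e, new_cds)
    assert len(ed.sequence) == n_before
    return count


def _insert_retroelement(
    rng: np.random.Generator,
    ed: _EditableLocus,
    pos: int,
    rev: RetroEvent,
    config: SimulationConfig,
    truth: TruthTable,
) -> None:
    ltr = "TG" + _random_seq(rng, rev.ltr_length - 4, 0.45) + "CA"
    internal = _random_seq(rng, rev.internal_length, 0.45)
    p = rev.age_my * 1e6 * config.rate_noncoding
    ltr5 = "TG" + _mutate_noncoding_text(rng, ltr[2:-2], p) + "CA"
    ltr3 = "TG" + _mutate_noncoding_text(rng, ltr[2:-2], p) + "CA"
    tsd = ed.sequence[pos : pos + rev.tsd_length]
    element = ltr5 + internal + ltr3
    # integration duplicates the target site: ...tsd [element] tsd...
    # the host tsd at [pos, pos+L) stays as the left copy; the element plus
    # a fresh right copy are inserted immediately after it
    start = pos + rev.tsd_length
    ed.insert(start, element + tsd)
    ed.features.append(
        Feature(
            id=f"{ed.id}_te{len(truth.retro) + 1:02d}",
            kind=FeatureKind.repeat_element,
            seqid=ed.id,
            start=start,
            end=start + len(element),
            strand="+",
            attributes={"class": "LTR_retrotransposon"},
        )
    )
    rec = {
        "kind": "retro",
        "haplotype": ed.id[-1],
        "start": start,
        "end": start + len(element),
        "ltr_length": rev.ltr_length,
        "tsd": tsd,
        "tsd_length": rev.tsd_length,
        "age_my": rev.age_my,
    }
    ed.anchors.append(rec)  # later (lower-coordinate) edits must shift it
    truth.retro.append(rec)


def _apply_intergenic_deletion(ed: _EditableLocus, payload, truth: TruthTable) -> None:
    bp_left, bp_right = payload
    removed = ed.delete(bp_left, bp_right)
    rec = {
        "kind": "intergenic",
        "haplotype": ed.id[-1],
        "start": bp_left,
        "end": bp_left,
        "deleted_genes": removed,
        "deleted_length": bp_right - bp_left,
    }
    ed.anchors.append(rec)
    truth.intergenic.append(rec)


def _apply_slippage(ed: _EditableLocus, site) -> None:
    rec = next(
        r
        for r in ed.anchors
        if r["kind"] == "ssr" and r["motif"] == site["motif"] and r["slippage_delta"] == site["slippage_delta"]
        and r["repeat_count"] == site["repeat_count"]
    )
    unit = ed.sequence[rec["start"] : rec["start"] + len(site["motif"])]
    delta = site["slippage_delta"]
    if delta > 0:
        # appending whole units at the run's end keeps the repeat perfect;
        # insert() shifts rec["end"] to the new run end automatically
        ed.insert(rec["end"], unit * delta)
    else:
        ed.delete(rec["start"], rec["start"] - len(unit) * delta)


def _apply_intragenic(ed: _EditableLocus, spec, config: SimulationConfig, truth: TruthTable) -> None:
    rec_gene = next(g for g in ed.genes if g.id == spec["recombinant"])
    p1 = next(g for g in ed.genes if g.id == spec["parents"][0])
    p2 = next(g for g in ed.genes if g.id == spec["parents"][1])

    def cds_of(g: GeneModel) -> str:
        s, e = g.cds_ranges[0]
        txt = ed.sequence[s:e]
        return reverse_complement(txt) if g.strand == "-" else txt

    c1, c2 = cds_of(p1), cds_of(p2)
    bp = int(len(c1) * config.intragenic_breakpoint_frac)
    bp -= bp % 3
    chimera = c1[:bp] + c2[bp : len(c1)]
    s, e = rec_gene.cds_ranges[0]
    text = reverse_complement(chimera) if rec_gene.strand == "-" else chimera
    ed.replace_range(s, e, text)
    truth.intragenic.append(
        {
            "haplotype": ed.id[-1],
            "recombinant": rec_gene.id,
            "parents": list(spec["parents"]),
            "cds_breakpoint": bp,
        }
    )


# ---------------------------------------------------------------------------
# fixture emission


def emit_fixture(
    locus_a: AnnotatedLocus,
    locus_b: AnnotatedLocus,
    truth: TruthTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + GFF3 per haplotype plus truth TSVs; re-loadable by
    locus_io."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, locus in (("hapA", locus_a), ("hapB", locus_b)):
        fasta = out / f"{name}.fasta"
        gff = out / f"{name}.gff3"
        write_fasta([locus.sequence], fasta)
        feats = list(locus.features)
        for g in locus.genes:
            feats.append(
                Feature(
                    id=g.id, kind=FeatureKind.gene, seqid=locus.sequence.id,
                    start=g.span[0], end=g.span[1], strand=g.strand,
                    attributes={"cds": ",".join(f"{s}-{e}" for s, e in g.cds_ranges)},
                )
            )
        write_gff3(feats, gff)
        paths[f"{name}.fasta"] = fasta
        paths[f"{name}.gff3"] = gff

    tables = {
        "truth_ssr.tsv": pd.DataFrame(truth.ssr),
        "truth_retro.tsv": pd.DataFrame(truth.retro),
        "truth_intragenic.tsv": pd.DataFrame(truth.intragenic),
        "truth_intergenic.tsv": pd.DataFrame(
            [
                {**rec, "deleted_genes": ",".join(rec["deleted_genes"])}
                for rec in truth.intergenic
            ]
        ),
        "truth_alleles.tsv": pd.DataFrame(
            [{"gene": g, "status": "allelic_pair"} for g in truth.allele_pairs]
            + [{"gene": g, "status": "A_specific"} for g in truth.a_specific]
            + [{"gene": g, "status": "B_specific"} for g in truth.b_specific]
        ),
        "truth_clades.tsv": pd.DataFrame(
            [{"gene": g, "clade": c} for g, c in sorted(truth.clade_labels.items())]
        ),
    }
    for fname, df in tables.items():
        p = out / fname
        df.to_csv(p, sep="\t", index=False)
        paths[fname] = p
    return paths
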