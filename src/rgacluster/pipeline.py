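"""End-to-end orchestration: load two annotated haplotypes, run
colinearity, repeats, dating, gene-family and recombination analyses, and
assemble the comparison report tables.

The report mirrors the tables of a locus-comparison study: per-region
composition statistics (sizes, % exon/intron/TE/SSR/intergenic, gene
densities), the per-allele-pair dating table, the repeat/LTR table, the
allele/clade/classification tables and the breakpoint table.  Composition
percentages resolve feature overlaps by the precedence
exon > intron > TE > SSR > intergenic, so each base is counted once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import colinearity, moldating, recombination, repeats, rga_family
from .locus_io import (
    AnnotatedLocus,
    Feature,
    FeatureKind,
    GeneModel,
    extract_cds,
    read_embl_flat,
    read_fasta,
    read_gff3,
)

log = logging.getLogger("rgacluster")


@dataclass
class PipelineConfig:
    locus_a: str = ""
    locus_b: str = ""
    annotations_a: str | None = None
    annotations_b: str | None = None
    pairing_table: str | None = None  # TSV gene_a, gene_b of allelic CDS pairs
    evidence_table: str | None = None  # TSV gene_id, q_cov, s_cov, identity, n_fragments
    out_dir: str = "rgacluster_out"
    log_level: str = "INFO"
    seed: int = 0
    # module parameters
    anchor_k: int = 15
    max_kmer_freq: int = 8
    max_gap: int = 5000
    min_block: int = 500
    band: int = 200
    min_identity_allele: float = 0.90
    tie_margin: float = 0.01
    clade_cut_identity: float = 0.80
    window: int = 100
    step: int = 10
    min_delta: float = 0.02
    min_run: int = 3
    flank: int = 2000
    rate_coding: float = moldating.CODING_RATE
    rate_noncoding: float = moldating.NONCODING_RATE
    detect_ltr_in_repeats: bool = True
    intergenic_probe: str | None = None  # feature id of the duplicated 1 kb repeat

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("locus_a", "locus_b"):
            p = getattr(self, key)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p!r} does not exist")
        for key in ("annotations_a", "annotations_b", "pairing_table", "evidence_table"):
            p = getattr(self, key)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p!r} does not exist")


@dataclass
class ComparisonReport:
    region_stats: pd.DataFrame
    dating: pd.DataFrame
    repeat_table: pd.DataFrame
    ssr_matches: pd.DataFrame
    alleles: pd.DataFrame
    clades: pd.DataFrame
    classification: pd.DataFrame
    breakpoints: pd.DataFrame
    blocks: pd.DataFrame
    diversity: dict = field(default_factory=dict)
    config: PipelineConfig | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "region_stats", "dating", "repeat_table", "ssr_matches", "alleles",
            "clades", "classification", "breakpoints", "blocks",
        ):
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t", index=False)
        summary = dict(self.diversity)
        if self.config is not None:
            summary["config"] = {
                f.name: getattr(self.config, f.name) for f in fields(PipelineConfig)
            }
        (out / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))


def load_locus(fasta_path: str | Path, gff_path: str | Path | None = None) -> AnnotatedLocus:
    """Load a haplotype from FASTA+GFF3 (or an EMBL flat file).

    Gene features carrying a ``cds`` attribute ("start-end[,start-end...]",
    0-based half-open, as written by the simulator) are promoted to
    GeneModels.
    """
    fasta_path = Path(fasta_path)
    if fasta_path.suffix.lower() in (".embl", ".dat"):
        return read_embl_flat(fasta_path)
    seqs = read_fasta(fasta_path)
    seq = seqs[0]
    features: list[Feature] = []
    genes: list[GeneModel] = []
    if gff_path is not None:
        for f in read_gff3(gff_path, seqs):
            cds_attr = f.attributes.get("cds")
            if f.kind is FeatureKind.gene and cds_attr:
                ranges = [
                    tuple(int(x) for x in part.split("-")) for part in cds_attr.split(",")
                ]
                genes.append(
                    GeneModel(
                        id=f.id, seqid=f.seqid, strand=f.strand,
                        exon_ranges=ranges, cds_ranges=ranges,
                    )
                )
            else:
                features.append(f)
    return AnnotatedLocus(sequence=seq, features=features, genes=genes)


def _rga_genes(locus: AnnotatedLocus) -> list[GeneModel]:
    rga = [g for g in locus.genes if g.id.upper().startswith("RGA")]
    return rga if rga else list(locus.genes)


def run_pipeline(config: PipelineConfig) -> ComparisonReport:
    """Execute every stage in dependency order and assemble the report."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage load: %s / %s", config.locus_a, config.locus_b)
    locus_a = load_locus(config.locus_a, config.annotations_a)
    locus_b = load_locus(config.locus_b, config.annotations_b)
    seq_a, seq_b = locus_a.sequence.residues, locus_b.sequence.residues

    log.info("stage colinearity")
    anchors, refined = colinearity.compare_haplotypes(
        seq_a, seq_b,
        k=config.anchor_k, max_kmer_freq=config.max_kmer_freq,
        max_gap=config.max_gap, min_block=config.min_block, band=config.band,
    )
    colinearity.export_dotplot(anchors, out / "dotplot.tsv")
    blocks_df = pd.DataFrame(
        [
            {
                "start_a": r.block.range_a[0], "end_a": r.block.range_a[1],
                "start_b": r.block.range_b[0], "end_b": r.block.range_b[1],
                "identity": round(r.block.identity or 0.0, 4),
                "snps": r.block.snp_count, "indels": r.block.gap_count,
            }
            for r in refined
        ]
    )
    subs = sum(r.block.snp_count for r in refined)
    cols = sum(
        sum(1 for x, y in zip(r.alignment.aligned_a, r.alignment.aligned_b) if x != "-" and y != "-")
        for r in refined
    )
    diversity = {"nucleotide_diversity": subs / cols if cols else float("nan")}

    log.info("stage repeats")
    ssr_a = repeats.scan_ssr(seq_a)
    ssr_b = repeats.scan_ssr(seq_b)
    coding_a = [(s, e) for g in locus_a.genes for s, e in g.cds_ranges]
    coding_b = [(s, e) for g in locus_b.genes for s, e in g.cds_ranges]
    matches = repeats.match_ssr_pairs(
        ssr_a, ssr_b, [r.block for r in refined], coding_a, coding_b
    )
    ssr_df = pd.DataFrame(
        [
            {
                "motif": m.locus_a.motif,
                "start_a": m.locus_a.start, "start_b": m.locus_b.start,
                "count_a": m.locus_a.repeat_count, "count_b": m.locus_b.repeat_count,
                "repeat_delta": m.repeat_delta, "heterozygous": m.heterozygous,
            }
            for m in matches
        ]
    )

    repeat_rows = []
    if config.detect_ltr_in_repeats:
        for name, locus in (("A", locus_a), ("B", locus_b)):
            for feat in locus.features:
                if feat.kind is not FeatureKind.repeat_element:
                    continue
                lo = max(0, feat.start - 50)
                hi = min(len(locus.sequence), feat.end + 50)
                if hi - lo < 300:
                    continue
                try:
                    calls = repeats.detect_ltr(
                        locus.sequence.residues, (lo, hi),
                        rate=config.rate_noncoding,
                    )
                except ValueError:
                    continue
                for c in calls:
                    repeat_rows.append(
                        {
                            "haplotype": name, "feature": feat.id,
                            "start": c.element_range[0], "length": c.element_range[1] - c.element_range[0],
                            "ltr5": c.ltr5_length, "ltr3": c.ltr3_length,
                            "tg_ca_5": c.tg_ca_5, "tg_ca_3": c.tg_ca_3,
                            "tsd": f"{c.tsd_left}/{c.tsd_right}" if c.has_tsd else "-",
                            "ltr_identity": round(c.ltr_identity, 4),
                            "age_my": round(c.insertion_time.T, 3) if c.insertion_time else float("nan"),
                        }
                    )
    repeat_df = pd.DataFrame(repeat_rows)

    log.info("stage gene family")
    rga_a, rga_b = _rga_genes(locus_a), _rga_genes(locus_b)
    cds, haps, ids = [], [], []
    for hap, locus, genes in (("A", locus_a, rga_a), ("B", locus_b, rga_b)):
        for g in genes:
            cds.append(extract_cds(g, locus.sequence).text)
            haps.append(hap)
            ids.append(g.id)
    pairing = None
    if len(cds) >= 2:
        matrix = rga_family.pairwise_identity_matrix(cds)
        pairing = rga_family.assign_alleles(
            matrix, haps, ids,
            min_identity=config.min_identity_allele, tie_margin=config.tie_margin,
        )
        clade_labels = rga_family.cluster_clades(matrix, cut_identity=config.clade_cut_identity)
        alleles_df = pd.DataFrame(
            [{"gene_a": a, "gene_b": b, "identity": round(i, 4), "status": "pair"} for a, b, i in pairing.pairs]
            + [{"gene_a": g, "gene_b": f"{p}|{q}", "identity": float("nan"), "status": "ambiguous"} for g, p, q in pairing.ambiguous]
            + [{"gene_a": g, "gene_b": "-", "identity": float("nan"), "status": "unpaired"} for g in pairing.unpaired]
        )
        clades_df = pd.DataFrame({"gene": ids, "haplotype": haps, "clade": clade_labels})
    else:
        alleles_df = pd.DataFrame(columns=["gene_a", "gene_b", "identity", "status"])
        clades_df = pd.DataFrame(columns=["gene", "haplotype", "clade"])

    log.info("stage dating")
    # ambiguous genes (e.g. recent within-haplotype duplications or
    # recombinants) cannot be dated as allelic pairs
    ambiguous_ids = (
        {g for triple in pairing.ambiguous for g in triple} if pairing else set()
    )
    pairs = _collect_pairs(config, locus_a, locus_b, exclude=ambiguous_ids)
    dating_df = (
        moldating.dating_table(pairs, rate=config.rate_coding)
        if pairs
        else pd.DataFrame(columns=["gene_pair", "length", "S", "N", "Sd", "Nd", "pS", "T_my"])
    )
    if pairs:
        diversity["concatenated_pS"] = dating_df.attrs["concatenated"]["pS"]
        diversity["divergence_T_my"] = dating_df.attrs["concatenated"]["T_my"]

    evidence = _load_evidence(config.evidence_table)
    class_rows = []
    for locus, hap in ((locus_a, "A"), (locus_b, "B")):
        for g in locus.genes:
            ev = evidence.get(g.id)
            cls = rga_family.classify_gene(g, ev)
            g.classification = cls.label
            class_rows.append({"gene": g.id, "haplotype": hap, "classification": cls.label})
    classification_df = pd.DataFrame(class_rows)

    log.info("stage recombination")
    all_indels = [i for r in refined for i in r.indels]
    probe = _find_probe(config, locus_a, locus_b)
    bp_rows = []
    if probe is not None:
        hits = recombination.find_duplicated_intergenic(
            {"A": seq_a, "B": seq_b}, probe, min_identity=0.7
        )
        candidates = recombination.scan_intergenic_recombination(
            [r.block for r in refined], all_indels, hits,
            haplotypes={"A": seq_a, "B": seq_b},
            flank=config.flank, window=config.window, step=config.step,
        )
        for cand in candidates:
            for bp in cand.breakpoints or [None]:
                bp_rows.append(
                    {
                        "haplotype": cand.haplotype,
                        "candidate_position": cand.breakpoint_position,
                        "kind": cand.kind,
                        "shift_position": bp.position if bp else float("nan"),
                        "left_parent": bp.left_parent if bp else "-",
                        "right_parent": bp.right_parent if bp else "-",
                    }
                )
    breakpoints_df = pd.DataFrame(bp_rows)

    log.info("stage region stats")
    region_rows = []
    for name, locus in (("A", locus_a), ("B", locus_b)):
        bounds = _cluster_bounds(locus)
        if bounds is not None:
            row = summarize_regions(locus, bounds)
            row.update({"haplotype": name, "region": "cluster"})
            region_rows.append(row)
        row = summarize_regions(locus, None)
        row.update({"haplotype": name, "region": "flanks" if bounds else "whole"})
        region_rows.append(row)
    region_df = pd.DataFrame(region_rows)

    report = ComparisonReport(
        region_stats=region_df,
        dating=dating_df,
        repeat_table=repeat_df,
        ssr_matches=ssr_df,
        alleles=alleles_df,
        clades=clades_df,
        classification=classification_df,
        breakpoints=breakpoints_df,
        blocks=blocks_df,
        diversity=diversity,
        config=config,
    )
    report.write(out)
    return report


def _collect_pairs(config, locus_a, locus_b, exclude: set[str] | None = None):
    exclude = exclude or set()
    pairs = []
    if config.pairing_table:
        table = pd.read_csv(config.pairing_table, sep="\t")
        for _, row in table.iterrows():
            ga = locus_a.gene(row["gene_a"])
            gb = locus_b.gene(row["gene_b"])
            ca = extract_cds(ga, locus_a.sequence).text
            cb = extract_cds(gb, locus_b.sequence).text
            if len(ca) == len(cb):
                pairs.append((ga.id, gb.id, ca, cb))
    else:
        ids_b = {g.id for g in locus_b.genes}
        for g in locus_a.genes:
            if g.id not in ids_b or g.id in exclude:
                continue
            ca = extract_cds(g, locus_a.sequence).text
            cb = extract_cds(locus_b.gene(g.id), locus_b.sequence).text
            if len(ca) == len(cb) and len(ca) % 3 == 0:
                pairs.append((g.id, g.id, ca, cb))
    return pairs


def _load_evidence(path):
    if not path:
        return {}
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[row["gene_id"]] = rga_family.SimilarityEvidence(
            gene_id=row["gene_id"],
            q_cov=float(row["q_cov"]),
            s_cov=float(row["s_cov"]),
            identity=float(row.get("identity", 0.0)),
            n_fragments=int(row.get("n_fragments", 1)),
        )
    return out


def _find_probe(config, locus_a, locus_b) -> str | None:
    for locus in (locus_a, locus_b):
        for f in locus.features:
            if f.kind is FeatureKind.intergenic_repeat and (
                config.intergenic_probe is None or f.id == config.intergenic_probe
            ):
                if len(f) >= 200:
                    return locus.sequence.residues[f.start : f.end]
    return None


def _cluster_bounds(locus: AnnotatedLocus, margin: int = 500) -> tuple[int, int] | None:
    rga = [g for g in locus.genes if g.id.upper().startswith("RGA")]
    if not rga:
        return None
    lo = min(g.span[0] for g in rga)
    hi = max(g.span[1] for g in rga)
    return max(0, lo - margin), min(len(locus.sequence), hi + margin)


def summarize_regions(
    locus: AnnotatedLocus, cluster_boundaries: tuple[int, int] | None = None
) -> dict:
    """Composition statistics for one region of a haplotype.

    Per-base precedence: exon > intron > TE > SSR > intergenic.  When
    ``cluster_boundaries`` is None the complement of the cluster (or the
    whole sequence if no cluster is annotated) is summarised.
    """
    n = len(locus.sequence)
    bounds = cluster_boundaries
    cluster = _cluster_bounds(locus)
    mask = np.zeros(n, dtype=bool)
    if bounds is not None:
        lo, hi = bounds
        if lo < 0 or hi > n:
            raise ValueError("cluster boundaries outside sequence")
        mask[lo:hi] = True
    else:
        mask[:] = True
        if cluster is not None:
            mask[cluster[0] : cluster[1]] = False

    # precedence codes: 0 intergenic, 1 SSR, 2 TE, 3 intron, 4 exon
    code = np.zeros(n, dtype=np.int8)
    ssr_loci = repeats.scan_ssr(locus.sequence.residues)
    for loc in ssr_loci:
        code[loc.start : loc.end] = np.maximum(code[loc.start : loc.end], 1)
    for f in locus.features:
        if f.kind is FeatureKind.repeat_element:
            code[f.start : f.end] = np.maximum(code[f.start : f.end], 2)
    for g in locus.genes:
        s, e = g.span
        code[s:e] = np.maximum(code[s:e], 3)
        for xs, xe in g.exon_ranges:
            code[xs:xe] = np.maximum(code[xs:xe], 4)

    size = int(mask.sum())
    sel = code[mask]
    pct = lambda c: round(100.0 * float((sel == c).sum()) / size, 1) if size else 0.0
    genes_in = [g for g in locus.genes if mask[min(g.span[0], n - 1)]]
    n_genes = len(genes_in)
    n_rga = sum(1 for g in genes_in if g.id.upper().startswith("RGA"))
    return {
        "size_bp": size,
        "exon_pct": pct(4),
        "intron_pct": pct(3),
        "te_pct": pct(2),
        "ssr_pct": pct(1),
        "intergenic_pct": pct(0),
        "gene_density_kb": round(size / 1000.0 / n_genes, 1) if n_genes else float("nan"),
        "n_genes": n_genes,
        "n_rga": n_rga,
        "n_plus_strand": sum(1 for g in genes_in if g.strand == "+"),
        "n_minus_strand": sum(1 for g in genes_in if g.strand == "-"),
    }
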