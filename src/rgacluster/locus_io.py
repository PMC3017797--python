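"""Core data model and readers/writers for FASTA, GFF3 and EMBL flat files.

All in-memory coordinates are 0-based half-open intervals on the forward
strand; file formats that use 1-based inclusive coordinates (GFF3, EMBL)
are converted on the way in and out.  Minus-strand features keep
forward-strand coordinates; only :func:`extract_cds` reverse-complements.

IUPAC ambiguity codes are accepted on input and stored uppercase; distance
computations downstream treat anything outside {A, C, G, T} as missing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

IUPAC_NT = set("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB"
)


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Coordinates or attributes inconsistent with the loaded sequences."""


class FeatureKind(str, Enum):
    gene = "gene"
    pseudogene = "pseudogene"
    fragment = "fragment"
    remnant = "remnant"
    repeat_element = "repeat_element"
    ssr = "SSR"
    domain = "domain"
    intergenic_repeat = "intergenic_repeat"
    misc = "misc"


class Disruption(str, Enum):
    """Mutations that prevent correct expression of a coding sequence."""

    missing_start = "missing_start"
    missing_stop = "missing_stop"
    noncanonical_splice = "noncanonical_splice"
    frameshift = "frameshift"
    inframe_stop = "inframe_stop"
    te_insertion = "TE_insertion"


@dataclass
class HaplotypeSequence:
    """One haplotype of the locus: an id plus its DNA residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace("U", "T")
        bad = set(self.residues) - IUPAC_NT
        if bad:
            raise ParseError(
                f"sequence {self.id!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        return self.residues[start:end]


def reverse_complement(text: str) -> str:
    return text.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """A located annotation on a named sequence (0-based half-open)."""

    id: str
    kind: FeatureKind
    seqid: str
    start: int
    end: int
    strand: str = "."
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.id!r}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"feature {self.id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A gene structure with exon/CDS intervals and degradation evidence.

    ``q_cov``/``s_cov`` are the query/subject coverage fractions of the best
    protein-similarity hit; ``disruptions`` lists expression-preventing
    mutations.  ``classification`` is filled in by the gene-family module.
    """

    id: str
    seqid: str
    strand: str
    exon_ranges: list[tuple[int, int]]
    cds_ranges: list[tuple[int, int]]
    disruptions: list[Disruption] = field(default_factory=list)
    q_cov: float | None = None
    s_cov: float | None = None
    classification: str | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exon_ranges = sorted(tuple(r) for r in self.exon_ranges)
        self.cds_ranges = sorted(tuple(r) for r in self.cds_ranges)
        for ranges, label in ((self.exon_ranges, "exon"), (self.cds_ranges, "CDS")):
            prev_end = -1
            for s, e in ranges:
                if not (0 <= s < e):
                    raise ValidationError(f"{self.id}: bad {label} interval [{s},{e})")
                if s < prev_end:
                    raise ValidationError(f"{self.id}: overlapping {label} intervals")
                prev_end = e
        for s, e in self.cds_ranges:
            if not any(xs <= s and e <= xe for xs, xe in self.exon_ranges):
                raise ValidationError(
                    f"{self.id}: CDS [{s},{e}) not contained in any exon"
                )
        for cov in (self.q_cov, self.s_cov):
            if cov is not None and not (0.0 <= cov <= 1.0):
                raise ValidationError(f"{self.id}: coverage {cov} outside [0,1]")

    @property
    def span(self) -> tuple[int, int]:
        return self.exon_ranges[0][0], self.exon_ranges[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_ranges)


@dataclass
class AnnotatedLocus:
    """A haplotype sequence plus its features and gene models."""

    sequence: HaplotypeSequence
    features: list[Feature] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValidationError(
                    f"feature {f.id!r} end {f.end} beyond sequence length {n}"
                )
        for g in self.genes:
            if g.span[1] > n:
                raise ValidationError(
                    f"gene {g.id!r} extends beyond sequence length {n}"
                )

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[HaplotypeSequence]:
    """Read a (multi-record) FASTA file into HaplotypeSequence records."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(HaplotypeSequence(id=rec.id, residues=str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[HaplotypeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_KIND_BY_SOTYPE = {
    "gene": FeatureKind.gene,
    "pseudogene": FeatureKind.pseudogene,
    "gene_fragment": FeatureKind.fragment,
    "remnant": FeatureKind.remnant,
    "repeat_region": FeatureKind.repeat_element,
    "microsatellite": FeatureKind.ssr,
    "polypeptide_domain": FeatureKind.domain,
    "intergenic_repeat": FeatureKind.intergenic_repeat,
}
_SOTYPE_BY_KIND = {v: k for k, v in _KIND_BY_SOTYPE.items()}


def read_gff3(path: str | Path, sequences: Sequence[HaplotypeSequence] | None = None) -> list[Feature]:
    """Read GFF3 (1-based inclusive on disk) into 0-based half-open Features.

    When ``sequences`` is given, seqids and bounds are validated against them.
    """
    lengths = {s.id: len(s) for s in sequences} if sequences is not None else None
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                gf = feature_from_line(line)
            except Exception as exc:  # gffutils raises bare exceptions
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if gf.end < gf.start:
                raise ValidationError(f"{path}:{lineno}: end < start")
            if lengths is not None:
                if gf.seqid not in lengths:
                    raise ValidationError(
                        f"{path}:{lineno}: unknown seqid {gf.seqid!r}"
                    )
                if gf.end > lengths[gf.seqid]:
                    raise ValidationError(
                        f"{path}:{lineno}: end {gf.end} beyond sequence length "
                        f"{lengths[gf.seqid]}"
                    )
            attrs = {k: v[0] if len(v) == 1 else ",".join(v) for k, v in gf.attributes.items()}
            fid = attrs.pop("ID", f"{gf.seqid}:{lineno}")
            kind = _KIND_BY_SOTYPE.get(gf.featuretype, FeatureKind.misc)
            if kind is FeatureKind.misc and gf.featuretype != "misc_feature":
                attrs.setdefault("so_type", gf.featuretype)
            feats.append(
                Feature(
                    id=fid,
                    kind=kind,
                    seqid=gf.seqid,
                    start=gf.start - 1,
                    end=gf.end,
                    strand=gf.strand if gf.strand in "+-" else ".",
                    attributes=attrs,
                )
            )
    return feats


def _escape_gff(value: str) -> str:
    return str(value).replace("%", "%25").replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff3(features: Iterable[Feature], path: str | Path, source: str = "rgacluster") -> None:
    """Write features as GFF3, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            sotype = _SOTYPE_BY_KIND.get(f.kind, f.attributes.get("so_type", "misc_feature"))
            attrs = [f"ID={_escape_gff(f.id)}"]
            for k, v in f.attributes.items():
                if k == "so_type":
                    continue
                attrs.append(f"{_escape_gff(k)}={_escape_gff(v)}")
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        source,
                        sotype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# EMBL flat files

_LOC_ALLOWED = re.compile(r"^[0-9.,()<> ]|join|complement|order")


def read_embl_flat(path: str | Path) -> AnnotatedLocus:
    """Read an EMBL flat file (ID/FT/SQ blocks) into an AnnotatedLocus.

    Only the location operators ``join``, ``complement`` and ``order`` are
    supported; CDS features become GeneModels (one exon per joined segment),
    ``repeat_region`` features become repeat Features, plain ``gene``
    features become gene Features.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "embl")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(record.seq) == 0:
        raise ParseError(f"{path}: EMBL record has no sequence block")
    seq = HaplotypeSequence(id=record.id or record.name, residues=str(record.seq))
    locus = AnnotatedLocus(sequence=seq)
    counters: dict[str, int] = {}
    for feat in record.features:
        op = getattr(feat.location, "operator", None)
        if op not in (None, "join", "order"):
            raise ParseError(f"{path}: unsupported location operator {op!r}")
        counters[feat.type] = counters.get(feat.type, 0) + 1
        qualifiers = {k: v[0] for k, v in feat.qualifiers.items() if v}
        default_id = f"{seq.id}_{feat.type}{counters[feat.type]:03d}"
        fid = qualifiers.get("locus_tag") or qualifiers.get("gene") or default_id
        strand = {1: "+", -1: "-"}.get(feat.location.strand, ".")
        parts = sorted(
            (int(p.start), int(p.end)) for p in feat.location.parts
        )
        if feat.type == "CDS":
            locus.genes.append(
                GeneModel(
                    id=fid,
                    seqid=seq.id,
                    strand=strand,
                    exon_ranges=parts,
                    cds_ranges=parts,
                    attributes=qualifiers,
                )
            )
        elif feat.type in ("repeat_region", "LTR"):
            locus.features.append(
                Feature(
                    id=default_id if fid == default_id else fid,
                    kind=FeatureKind.repeat_element,
                    seqid=seq.id,
                    start=parts[0][0],
                    end=parts[-1][1],
                    strand=strand,
                    attributes=qualifiers,
                )
            )
        elif feat.type == "gene":
            locus.features.append(
                Feature(
                    id=fid,
                    kind=FeatureKind.gene,
                    seqid=seq.id,
                    start=parts[0][0],
                    end=parts[-1][1],
                    strand=strand,
                    attributes=qualifiers,
                )
            )
    locus.validate()
    return locus


# ---------------------------------------------------------------------------
# CDS extraction


@dataclass
class CDSResult:
    text: str
    multiple_of_three: bool


def extract_cds(gene: GeneModel, sequence: HaplotypeSequence) -> CDSResult:
    """Concatenate a gene's CDS segments, reverse-complementing minus strand.

    A length not divisible by 3 is flagged, not fatal: such genes are
    pseudogene/fragment candidates, and the classifier wants to see them.
    """
    if not gene.cds_ranges:
        raise ValueError(f"gene {gene.id!r} has no CDS ranges")
    if gene.cds_ranges[-1][1] > len(sequence):
        raise ValidationError(f"gene {gene.id!r} CDS beyond sequence end")
    text = "".join(sequence.residues[s:e] for s, e in gene.cds_ranges)
    if gene.strand == "-":
        text = reverse_complement(text)
    return CDSResult(text=text, multiple_of_three=len(text) % 3 == 0)
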