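"""Colinearity between two haplotypes: anchors, block chaining, refinement.

The comparison skeleton is built dotplot-style: maximal exact matches seeded
by shared k-mers (repetitive k-mers filtered by frequency) are chained into
monotone colinear blocks, and each block is refined into a base-level
alignment from which SNPs, indel events and per-region nucleotide diversity
are catalogued.  Identity is always reported over aligned non-gap columns;
gap runs are reported separately as indel events, mirroring the separate
treatment of SNPs and indels in haplotype comparisons.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .alignment import AlignmentResult, align_global
from .locus_io import reverse_complement

DEFAULT_K = 15
DEFAULT_MAX_KMER_FREQ = 8
DEFAULT_MAX_GAP = 5000
DEFAULT_MIN_BLOCK = 500


@dataclass(frozen=True)
class AnchorMatch:
    """A maximal exact match between the two sequences."""

    pos_a: int
    pos_b: int
    length: int
    strand: str = "+"

    @property
    def diagonal(self) -> int:
        return self.pos_a - self.pos_b

    @property
    def end_a(self) -> int:
        return self.pos_a + self.length

    @property
    def end_b(self) -> int:
        return self.pos_b + self.length


@dataclass
class IndelEvent:
    """A contiguous gap run: extra sequence carried by one haplotype."""

    pos_a: int  # position on A at/after which the event sits
    pos_b: int
    length: int
    carrier: str  # "A" or "B": which haplotype carries the extra bases
    annotation: str = ""


@dataclass
class ColinearBlock:
    range_a: tuple[int, int]
    range_b: tuple[int, int]
    identity: float | None = None
    snp_count: int | None = None
    gap_count: int | None = None
    anchors: list[AnchorMatch] = field(default_factory=list)

    @property
    def length_a(self) -> int:
        return self.range_a[1] - self.range_a[0]

    @property
    def length_b(self) -> int:
        return self.range_b[1] - self.range_b[0]


@dataclass
class RefinedBlock:
    block: ColinearBlock
    alignment: AlignmentResult
    snps: list[tuple[int, int, str, str]]  # (pos_a, pos_b, base_a, base_b)
    indels: list[IndelEvent]


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def find_anchors(
    seq_a: str,
    seq_b: str,
    k: int = DEFAULT_K,
    max_kmer_freq: int = DEFAULT_MAX_KMER_FREQ,
    with_reverse: bool = False,
) -> list[AnchorMatch]:
    """Maximal exact matches seeded by shared k-mers.

    k-mers occurring more than ``max_kmer_freq`` times in either sequence are
    discarded (repeat filter); overlapping seeds on one diagonal are merged
    and the merged run extended to a maximal exact match.  With
    ``with_reverse`` anti-diagonal (reverse-strand) matches are reported too,
    flagged strand "-"; they are never chained into forward blocks.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    anchors = _forward_anchors(seq_a, seq_b, k, max_kmer_freq)
    if with_reverse:
        rc = reverse_complement(seq_b)
        for anc in _forward_anchors(seq_a, rc, k, max_kmer_freq):
            pos_b = len(seq_b) - (anc.pos_b + anc.length)
            anchors.append(AnchorMatch(anc.pos_a, pos_b, anc.length, strand="-"))
    anchors.sort(key=lambda x: (x.pos_a, x.pos_b))
    return anchors


def _forward_anchors(seq_a: str, seq_b: str, k: int, max_kmer_freq: int) -> list[AnchorMatch]:
    index_a = _kmer_index(seq_a, k)
    # count k-mer frequency in b in one pass, then match
    counts_b: dict[str, int] = defaultdict(int)
    for j in range(len(seq_b) - k + 1):
        counts_b[seq_b[j : j + k]] += 1
    by_diag: dict[int, list[int]] = defaultdict(list)  # diag -> sorted pos_a starts
    for j in range(len(seq_b) - k + 1):
        kmer = seq_b[j : j + k]
        hits = index_a.get(kmer)
        if not hits or len(hits) > max_kmer_freq or counts_b[kmer] > max_kmer_freq:
            continue
        for i in hits:
            by_diag[i - j].append(i)
    anchors: list[AnchorMatch] = []
    for diag, starts in by_diag.items():
        starts.sort()
        run_start = starts[0]
        run_end = starts[0] + k
        for i in starts[1:]:
            if i <= run_end:  # overlapping/adjacent seeds -> exact join
                run_end = max(run_end, i + k)
            else:
                anchors.append(_extend(seq_a, seq_b, run_start, run_start - diag, run_end - run_start))
                run_start, run_end = i, i + k
        anchors.append(_extend(seq_a, seq_b, run_start, run_start - diag, run_end - run_start))
    # dedupe anchors that extended to the same maximal match
    return sorted(set(anchors), key=lambda x: (x.pos_a, x.pos_b))


def _extend(seq_a: str, seq_b: str, i: int, j: int, length: int) -> AnchorMatch:
    while i > 0 and j > 0 and seq_a[i - 1] == seq_b[j - 1]:
        i -= 1
        j -= 1
        length += 1
    while i + length < len(seq_a) and j + length < len(seq_b) and seq_a[i + length] == seq_b[j + length]:
        length += 1
    return AnchorMatch(i, j, length)


def chain_blocks(
    anchors: list[AnchorMatch],
    max_gap: int = DEFAULT_MAX_GAP,
    min_block: int = DEFAULT_MIN_BLOCK,
) -> list[ColinearBlock]:
    """Chain anchors into coarse colinear blocks.

    Repeated highest-scoring monotone chaining (score = summed anchor length,
    longest-increasing-subsequence style on both coordinates); each extracted
    chain is split where the inter-anchor gap on either sequence exceeds
    ``max_gap``, and chains spanning less than ``min_block`` are dropped.
    """
    pool = [a for a in anchors if a.strand == "+"]
    blocks: list[ColinearBlock] = []
    while pool:
        chain = _best_chain(pool)
        if not chain:
            break
        span = sum(a.length for a in chain)
        if span < min_block:
            break
        used = set(chain)
        # remove chained anchors and anchors conflicting with the chain's span
        lo_a, hi_a = chain[0].pos_a, chain[-1].end_a
        lo_b, hi_b = chain[0].pos_b, chain[-1].end_b
        pool = [
            a
            for a in pool
            if a not in used
            and not (a.pos_a < hi_a and a.end_a > lo_a)
            and not (a.pos_b < hi_b and a.end_b > lo_b)
        ]
        blocks.extend(_split_chain(chain, max_gap, min_block))
    blocks.sort(key=lambda b: b.range_a)
    return blocks


def _best_chain(anchors: list[AnchorMatch]) -> list[AnchorMatch]:
    """O(n^2) DP for the maximum-weight chain monotone in both coordinates."""
    arr = sorted(anchors, key=lambda x: (x.pos_a, x.pos_b))
    n = len(arr)
    best = [float(a.length) for a in arr]
    back = [-1] * n
    for t in range(n):
        at = arr[t]
        for s in range(t):
            a = arr[s]
            if a.end_a <= at.pos_a and a.end_b <= at.pos_b:
                cand = best[s] + at.length
                if cand > best[t]:
                    best[t] = cand
                    back[t] = s
    t = max(range(n), key=lambda x: best[x])
    chain = []
    while t != -1:
        chain.append(arr[t])
        t = back[t]
    return chain[::-1]


def _split_chain(chain: list[AnchorMatch], max_gap: int, min_block: int) -> list[ColinearBlock]:
    pieces: list[list[AnchorMatch]] = [[chain[0]]]
    for prev, cur in zip(chain, chain[1:]):
        gap_a = cur.pos_a - prev.end_a
        gap_b = cur.pos_b - prev.end_b
        if gap_a > max_gap or gap_b > max_gap:
            pieces.append([cur])
        else:
            pieces[-1].append(cur)
    out = []
    for piece in pieces:
        ra = (piece[0].pos_a, piece[-1].end_a)
        rb = (piece[0].pos_b, piece[-1].end_b)
        if min(ra[1] - ra[0], rb[1] - rb[0]) >= min_block:
            out.append(ColinearBlock(range_a=ra, range_b=rb, anchors=piece))
    return out


def refine_block(
    seq_a: str,
    seq_b: str,
    block: ColinearBlock,
    band: int = 200,
) -> RefinedBlock:
    """Base-level alignment of a coarse block.

    Anchored piecewise mode: exact anchor runs are copied verbatim and the
    inter-anchor gaps aligned with the banded affine aligner; when a gap's
    optimal path would leave the band, the band is widened and finally the
    full-DP aligner is used (never silent truncation).  Identity is computed
    over aligned non-gap columns; contiguous gap runs become IndelEvents.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    anchors = block.anchors or [
        AnchorMatch(block.range_a[0], block.range_b[0], 0)
    ]
    parts_a: list[str] = []
    parts_b: list[str] = []
    ca, cb = block.range_a[0], block.range_b[0]
    score = 0.0

    def emit_gap(ga: str, gb: str) -> None:
        nonlocal score
        if not ga and not gb:
            return
        piece_band = max(50, abs(len(ga) - len(gb)) + 50, min(band, max(len(ga), len(gb))))
        res = align_global(ga, gb, band=piece_band)
        parts_a.append(res.aligned_a)
        parts_b.append(res.aligned_b)
        score += res.score

    for anc in anchors:
        emit_gap(seq_a[ca : anc.pos_a], seq_b[cb : anc.pos_b])
        parts_a.append(seq_a[anc.pos_a : anc.end_a])
        parts_b.append(seq_b[anc.pos_b : anc.end_b])
        score += anc.length  # match score 1 per base
        ca, cb = anc.end_a, anc.end_b
    emit_gap(seq_a[ca : block.range_a[1]], seq_b[cb : block.range_b[1]])

    aligned_a = "".join(parts_a)
    aligned_b = "".join(parts_b)
    result = AlignmentResult(score=score, aligned_a=aligned_a, aligned_b=aligned_b)

    snps: list[tuple[int, int, str, str]] = []
    indels: list[IndelEvent] = []
    pa, pb = block.range_a[0], block.range_b[0]
    matches = cols = 0
    gap_carrier: str | None = None
    gap_len = 0
    gap_pos: tuple[int, int] = (0, 0)

    def close_gap() -> None:
        nonlocal gap_carrier, gap_len
        if gap_carrier is not None:
            indels.append(
                IndelEvent(pos_a=gap_pos[0], pos_b=gap_pos[1], length=gap_len, carrier=gap_carrier)
            )
        gap_carrier, gap_len = None, 0

    for x, y in zip(aligned_a, aligned_b):
        if x == "-":
            if gap_carrier != "B":
                close_gap()
                gap_carrier, gap_pos, gap_len = "B", (pa, pb), 0
            gap_len += 1
            pb += 1
            continue
        if y == "-":
            if gap_carrier != "A":
                close_gap()
                gap_carrier, gap_pos, gap_len = "A", (pa, pb), 0
            gap_len += 1
            pa += 1
            continue
        close_gap()
        cols += 1
        if x == y:
            matches += 1
        else:
            snps.append((pa, pb, x, y))
        pa += 1
        pb += 1
    close_gap()

    block.identity = matches / cols if cols else None
    block.snp_count = len(snps)
    block.gap_count = len(indels)
    return RefinedBlock(block=block, alignment=result, snps=snps, indels=indels)


def nucleotide_diversity(
    alignment: AlignmentResult, mask: list[tuple[int, int]] | None = None
) -> float:
    """Substitutions per aligned non-gap column, optionally restricted to a
    mask of column intervals (e.g. coding columns)."""
    in_mask = None
    if mask is not None:
        in_mask = [False] * alignment.columns
        for s, e in mask:
            for i in range(max(0, s), min(alignment.columns, e)):
                in_mask[i] = True
    subs = cols = 0
    for i, (x, y) in enumerate(zip(alignment.aligned_a, alignment.aligned_b)):
        if in_mask is not None and not in_mask[i]:
            continue
        if x == "-" or y == "-":
            continue
        cols += 1
        if x != y:
            subs += 1
    if cols == 0:
        raise ZeroDivisionError("no eligible aligned columns")
    return subs / cols


def export_dotplot(anchors: list[AnchorMatch], path: str | Path) -> None:
    """Write anchors as a tab-separated (pos_a, pos_b, length, strand) file."""
    with open(path, "w") as fh:
        fh.write("pos_a\tpos_b\tlength\tstrand\n")
        for a in anchors:
            fh.write(f"{a.pos_a}\t{a.pos_b}\t{a.length}\t{a.strand}\n")


def compare_haplotypes(
    seq_a: str,
    seq_b: str,
    k: int = DEFAULT_K,
    max_kmer_freq: int = DEFAULT_MAX_KMER_FREQ,
    max_gap: int = DEFAULT_MAX_GAP,
    min_block: int = DEFAULT_MIN_BLOCK,
    band: int = 200,
) -> tuple[list[AnchorMatch], list[RefinedBlock]]:
    """Convenience wrapper: anchors -> chained blocks -> refined blocks."""
    anchors = find_anchors(seq_a, seq_b, k=k, max_kmer_freq=max_kmer_freq)
    blocks = chain_blocks(anchors, max_gap=max_gap, min_block=min_block)
    refined = [refine_block(seq_a, seq_b, blk, band=band) for blk in blocks]
    return anchors, refined
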