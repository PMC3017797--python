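"""Structural annotation of LTR retroelements and SSR scanning.

LTR retroelements are found dotplot-style by self-comparison: a pair of
direct repeats near the two ends of a candidate range is chained from k-mer
anchors, the two long terminal repeats are aligned to measure their
identity, TG...CA termini are flagged, and the flanks are scanned for the
4-6 bp target-site duplication (TSD) left by integration.  Because the two
LTRs are identical at insertion, their K2P divergence dates the element
(T = K / 2r at the noncoding rate).

SSRs (microsatellites) are maximal perfect tandem repeats of 2-6 bp units;
homopolymers are excluded and nested reports suppressed (a (CTCT)n run is
reported once, as CT).  Motifs are canonicalised to the lexicographically
minimal rotation over both strands so CT/TC/AG/GA runs collapse to one
class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import moldating
from .alignment import biopython_global
from .colinearity import ColinearBlock, _forward_anchors
from .locus_io import reverse_complement

DEFAULT_MIN_REPEATS = {2: 6, 3: 5, 4: 4, 5: 4, 6: 4}
MIN_DATED_LTR = 300  # only LTR pairs at least this long are dated by default


@dataclass
class LTRElementCall:
    element_range: tuple[int, int]
    ltr5_range: tuple[int, int]
    ltr3_range: tuple[int, int]
    ltr_identity: float
    tg_ca_5: bool
    tg_ca_3: bool
    tsd_left: str | None = None
    tsd_right: str | None = None
    tsd_mismatches: int = 0
    insertion_time: moldating.DatingResult | None = None

    @property
    def ltr5_length(self) -> int:
        return self.ltr5_range[1] - self.ltr5_range[0]

    @property
    def ltr3_length(self) -> int:
        return self.ltr3_range[1] - self.ltr3_range[0]

    @property
    def has_tsd(self) -> bool:
        return self.tsd_left is not None


@dataclass
class SSRLocus:
    motif: str  # canonical unit (lexicographically minimal rotation, both strands)
    unit: str  # unit as it appears on the forward strand at this locus
    repeat_count: int
    start: int
    end: int
    perfect: bool = True

    @property
    def range(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SSRMatch:
    locus_a: SSRLocus
    locus_b: SSRLocus
    repeat_delta: int

    @property
    def heterozygous(self) -> bool:
        return self.repeat_delta != 0


def canonical_motif(unit: str) -> str:
    """Lexicographic minimum over all rotations of the unit and its reverse
    complement."""
    unit = unit.upper()
    rc = reverse_complement(unit)
    rotations = [unit[i:] + unit[:i] for i in range(len(unit))]
    rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


def _is_homopolymer(unit: str) -> bool:
    return len(set(unit)) == 1


def _smallest_period(unit: str) -> int:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return p
    return len(unit)


def scan_ssr(
    sequence: str,
    min_repeats_by_unit: dict[int, int] | None = None,
) -> list[SSRLocus]:
    """Maximal perfect tandem repeats of 2-6 bp units.

    ``min_repeats_by_unit`` maps unit length to the minimum repeat count
    (defaults di>=6, tri>=5, tetra/penta/hexa>=4).  Homopolymer runs are
    excluded and a run is only reported at its smallest period.
    """
    thresholds = dict(DEFAULT_MIN_REPEATS)
    if min_repeats_by_unit:
        thresholds.update(min_repeats_by_unit)
    for u, t in thresholds.items():
        if t < 3:
            raise ValueError(f"minimum repeats for unit {u} must be >= 3")
    sequence = sequence.upper()
    n = len(sequence)
    loci: list[SSRLocus] = []
    claimed: list[tuple[int, int]] = []  # ranges already reported (smaller periods first)
    for u in range(2, 7):
        need = thresholds.get(u, 4)
        i = 0
        while i + u * need <= n:
            # length of the period-u run starting at i
            j = i + u
            while j < n and sequence[j] == sequence[j - u]:
                j += 1
            run = j - i
            count = run // u
            if count >= need:
                unit = sequence[i : i + u]
                if not _is_homopolymer(unit) and _smallest_period(unit) == u:
                    end = i + count * u
                    if not any(s < end and e > i for s, e in claimed):
                        loci.append(
                            SSRLocus(
                                motif=canonical_motif(unit),
                                unit=unit,
                                repeat_count=count,
                                start=i,
                                end=end,
                            )
                        )
                        claimed.append((i, end))
                i = j - u + 1  # a longer run cannot restart inside this one
            else:
                i += 1
    loci.sort(key=lambda x: x.start)
    return loci


def match_ssr_pairs(
    loci_a: list[SSRLocus],
    loci_b: list[SSRLocus],
    colinear_blocks: list[ColinearBlock],
    coding_ranges_a: list[tuple[int, int]] | None = None,
    coding_ranges_b: list[tuple[int, int]] | None = None,
    tolerance: int = 500,
) -> list[SSRMatch]:
    """Pair SSR loci across haplotypes through the colinear blocks.

    Each locus on A is projected through the block containing it (linear
    interpolation inside the block) and paired with a same-motif locus on B
    within ``tolerance`` bases of the projected position.  Loci inside the
    supplied coding ranges (RGA CDS) are excluded from the common-noncoding
    report, since orthology of coding microsatellites is ambiguous.
    """

    def in_ranges(locus: SSRLocus, ranges) -> bool:
        if not ranges:
            return False
        return any(locus.start < e and locus.end > s for s, e in ranges)

    def project(pos: int) -> int | None:
        for blk in colinear_blocks:
            (sa, ea), (sb, eb) = blk.range_a, blk.range_b
            if sa <= pos < ea:
                if blk.anchors:
                    # exact-match anchors give a near-exact mapping even
                    # when the block contains large internal indels
                    anchor = min(
                        blk.anchors,
                        key=lambda a: 0 if a.pos_a <= pos < a.end_a else min(
                            abs(pos - a.pos_a), abs(pos - a.end_a)
                        ),
                    )
                    return pos + (anchor.pos_b - anchor.pos_a)
                frac = (pos - sa) / max(1, ea - sa)
                return sb + int(round(frac * (eb - sb)))
        return None

    avail_b = [
        loc for loc in loci_b if not in_ranges(loc, coding_ranges_b)
    ]
    used_b: set[int] = set()
    matches: list[SSRMatch] = []
    for la in loci_a:
        if in_ranges(la, coding_ranges_a):
            continue
        proj = project(la.start)
        if proj is None:
            continue
        best = None
        best_dist = tolerance + 1
        for idx, lb in enumerate(avail_b):
            if idx in used_b or lb.motif != la.motif:
                continue
            dist = abs(lb.start - proj)
            if dist < best_dist:
                best, best_dist = idx, dist
        if best is not None:
            lb = avail_b[best]
            used_b.add(best)
            matches.append(
                SSRMatch(locus_a=la, locus_b=lb, repeat_delta=lb.repeat_count - la.repeat_count)
            )
    return matches


def gc_profile(sequence: str, window: int, step: int) -> list[tuple[int, float]]:
    """GC fraction per window (Ns excluded from the denominator)."""
    if window < 100:
        raise ValueError("window must be >= 100")
    if window > len(sequence):
        raise ValueError("window longer than sequence")
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_gc = ((seq == ord("G")) | (seq == ord("C"))).astype(np.int32)
    is_acgt = np.isin(seq, [ord(c) for c in "ACGT"]).astype(np.int32)
    cgc = np.concatenate([[0], np.cumsum(is_gc)])
    cat = np.concatenate([[0], np.cumsum(is_acgt)])
    out = []
    for start in range(0, len(sequence) - window + 1, step):
        end = start + window
        denom = cat[end] - cat[start]
        frac = (cgc[end] - cgc[start]) / denom if denom else float("nan")
        out.append((start + window // 2, float(frac)))
    return out


# ---------------------------------------------------------------------------
# LTR retroelements


def detect_ltr(
    sequence: str,
    search_range: tuple[int, int] | None = None,
    min_ltr: int = 100,
    min_identity: float = 0.8,
    tsd_range: tuple[int, int] = (4, 6),
    min_internal: int = 200,
    k: int = 11,
    date: bool = True,
    rate: float = moldating.NONCODING_RATE,
    allow_tsd_mismatch: bool = False,
) -> list[LTRElementCall]:
    """Find LTR retroelement structures by self-comparison.

    Direct-repeat pairs (the paired LTRs) are chained from exact k-mer
    anchors of the range against itself, requiring copy length >= min_ltr,
    alignment identity >= min_identity and an internal region of at least
    ``min_internal`` bases.  Non-overlapping candidates are accepted
    best-first (longest LTR).  TG...CA termini are flagged and the flanks
    scanned for an exact 4-6 bp TSD (``allow_tsd_mismatch`` reports near-TSDs
    with one mismatch).  Elements whose LTRs are at least 300 bp are dated
    from the K2P distance of the LTR pair.
    """
    if min_ltr < 50:
        raise ValueError("min_ltr must be >= 50")
    if min_identity < 0.7:
        raise ValueError("min_identity must be >= 0.7")
    sequence = sequence.upper()
    lo, hi = search_range if search_range else (0, len(sequence))
    if hi - lo < 2 * min_ltr:
        raise ValueError("search range shorter than twice min_ltr")
    region = sequence[lo:hi]

    anchors = [
        a
        for a in _forward_anchors(region, region, k, max_kmer_freq=20)
        if a.pos_b - a.end_a >= min_internal  # direct repeat, downstream copy
    ]
    # group anchors into candidate repeat pairs by similar separation
    anchors.sort(key=lambda a: -a.length)
    candidates: list[tuple[int, int, int, int]] = []  # (s5, e5, s3, e3)
    for seed in anchors:
        sep = seed.pos_b - seed.pos_a
        group = [
            a
            for a in anchors
            if abs((a.pos_b - a.pos_a) - sep) <= 50
            and abs(a.pos_a - seed.pos_a) <= 2000
        ]
        s5 = min(a.pos_a for a in group)
        e5 = max(a.end_a for a in group)
        s3 = min(a.pos_b for a in group)
        e3 = max(a.end_b for a in group)
        if e5 - s5 >= min_ltr and e5 <= s3:
            candidates.append((s5, e5, s3, e3))
    calls: list[LTRElementCall] = []
    taken: list[tuple[int, int]] = []
    for s5, e5, s3, e3 in sorted(candidates, key=lambda c: -(c[1] - c[0])):
        if any(s5 < te and e3 > ts for ts, te in taken):
            continue
        refined = _refine_boundaries(region, s5, e5, s3, e3)
        if refined is None:
            continue
        s5, e5, s3, e3 = refined
        if min(e5 - s5, e3 - s3) < min_ltr:
            continue
        aln = biopython_global(region[s5:e5], region[s3:e3])
        try:
            ident = aln.identity()
        except ZeroDivisionError:
            continue
        if ident < min_identity:
            continue
        call = _build_call(
            sequence, lo + s5, lo + e5, lo + s3, lo + e3, ident, aln,
            tsd_range, date, rate, allow_tsd_mismatch,
        )
        calls.append(call)
        taken.append((s5, e3))
    calls.sort(key=lambda c: c.element_range)
    return calls


def _refine_boundaries(
    region: str, s5: int, e5: int, s3: int, e3: int, margin: int = 40, micro: int = 5
) -> tuple[int, int, int, int] | None:
    """Sharpen anchor-derived LTR boundaries.

    The two candidate copies (with margins, never crossing into each other)
    are locally aligned, which trims unrelated flank; then the start pair is
    micro-shifted onto a shared TG and the end pair onto a shared CA when
    such termini exist within a few bases — the structural signals
    integrases leave, which resolve the boundary exactly even when the
    terminal bases of the two copies have diverged.
    """
    from Bio import Align

    lo5 = max(0, s5 - margin)
    hi5 = min(s3, e5 + margin)
    lo3 = max(e5, s3 - margin)
    hi3 = min(len(region), e3 + margin)
    if hi5 - lo5 < 20 or hi3 - lo3 < 20:
        return None
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -1
    try:
        aln = aligner.align(region[lo5:hi5], region[lo3:hi3])[0]
    except (IndexError, ValueError):
        return None
    blocks_u, blocks_v = aln.aligned
    if len(blocks_u) == 0:
        return None
    s5r, e5r = lo5 + int(blocks_u[0][0]), lo5 + int(blocks_u[-1][1])
    s3r, e3r = lo3 + int(blocks_v[0][0]), lo3 + int(blocks_v[-1][1])

    # Joint micro-shift of the four boundaries, scoring every structural
    # signal at once: shared TG starts, shared CA ends, an exact 4-6 bp TSD
    # between the left flank of the 5' copy and the right flank of the 3'
    # copy, and equal LTR lengths.  Small shifts are preferred.
    ds = list(range(-micro, micro + 1))
    tg5 = {d: region[s5r + d : s5r + d + 2] == "TG" for d in ds}
    tg3 = {d: region[s3r + d : s3r + d + 2] == "TG" for d in ds}
    ca5 = {d: region[e5r + d - 2 : e5r + d] == "CA" for d in ds}
    ca3 = {d: region[e3r + d - 2 : e3r + d] == "CA" for d in ds}
    tsd = {}
    for d1 in ds:
        for d4 in ds:
            bonus = 0.0
            for t in range(6, 3, -1):
                p, q = s5r + d1, e3r + d4
                if p - t >= 0 and q + t <= len(region) and region[p - t : p] == region[q : q + t]:
                    bonus = 3.0 + 0.1 * t
                    break
            tsd[(d1, d4)] = bonus
    base_l5 = e5r - s5r
    base_l3 = e3r - s3r
    best = (-1.0, 0, 0, 0, 0)
    for d1 in ds:
        for d2 in ds:
            for d3 in ds:
                for d4 in ds:
                    score = (
                        2.0 * (tg5[d1] and tg3[d3])
                        + 2.0 * (ca5[d2] and ca3[d4])
                        + tsd[(d1, d4)]
                        + 2.0 * ((base_l5 - d1 + d2) == (base_l3 - d3 + d4))
                        - 0.25 * (abs(d1) + abs(d2) + abs(d3) + abs(d4))
                    )
                    if score > best[0]:
                        best = (score, d1, d2, d3, d4)
    _, d1, d2, d3, d4 = best
    s5r, e5r, s3r, e3r = s5r + d1, e5r + d2, s3r + d3, e3r + d4
    if not (s5r < e5r <= s3r < e3r):
        return None
    return s5r, e5r, s3r, e3r


def _build_call(
    sequence, s5, e5, s3, e3, ident, aln, tsd_range, date, rate, allow_tsd_mismatch
) -> LTRElementCall:
    tg5 = sequence[s5 : s5 + 2] == "TG" and sequence[e5 - 2 : e5] == "CA"
    tg3 = sequence[s3 : s3 + 2] == "TG" and sequence[e3 - 2 : e3] == "CA"
    tsd_left = tsd_right = None
    mismatches = 0
    for tlen in range(tsd_range[1], tsd_range[0] - 1, -1):
        if s5 - tlen < 0 or e3 + tlen > len(sequence):
            continue
        left = sequence[s5 - tlen : s5]
        right = sequence[e3 : e3 + tlen]
        mm = sum(1 for x, y in zip(left, right) if x != y)
        if mm == 0:
            tsd_left, tsd_right, mismatches = left, right, 0
            break
        if allow_tsd_mismatch and mm == 1 and tsd_left is None:
            tsd_left, tsd_right, mismatches = left, right, 1
    dating = None
    ltr_len = min(e5 - s5, e3 - s3)
    if date and ltr_len >= MIN_DATED_LTR:
        try:
            est = moldating.k2p(aln.aligned_a, aln.aligned_b)
            dating = moldating.date_insertion(est, rate=rate)
        except (moldating.SaturationError, moldating.UndefinedValueError):
            dating = None
    return LTRElementCall(
        element_range=(s5, e3),
        ltr5_range=(s5, e5),
        ltr3_range=(s3, e3),
        ltr_identity=ident,
        tg_ca_5=tg5,
        tg_ca_3=tg3,
        tsd_left=tsd_left,
        tsd_right=tsd_right,
        tsd_mismatches=mismatches,
        insertion_time=dating,
    )
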