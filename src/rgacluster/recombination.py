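"""Recombination breakpoint detection by sliding-window percent identity.

A putative recombinant is compared against two (or more) candidate parental
sequences: each parent is globally aligned to the recombinant and the
percent identity plotted in sliding windows along the recombinant.  A shift
in which parent ranks highest — sustained over several windows on both
sides — is called as a breakpoint.  The same construction, applied to the
duplicated ~1 kb intergenic sequences flanking colinearity breakpoints,
screens for unequal recombination events mediated by non-coding duplications.
Statistical significance testing of events is out of scope; the calls are
structural, at window resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import biopython_global
from .colinearity import ColinearBlock, IndelEvent, _forward_anchors
from .locus_io import reverse_complement

DEFAULT_WINDOW = 100
DEFAULT_STEP = 10
DEFAULT_MIN_DELTA = 0.02
DEFAULT_MIN_RUN = 3
DEFAULT_FLANK = 2000


@dataclass
class IdentityProfile:
    recombinant_id: str
    parent_ids: list[str]
    window_centers: np.ndarray
    identity_tracks: np.ndarray  # shape (n_parents, n_windows); NaN = masked
    window: int
    step: int


@dataclass
class BreakpointCall:
    position: int  # recombinant coordinate
    left_parent: str
    right_parent: str
    delta: float  # mean identity advantage, min of the two sides
    run_length: tuple[int, int]  # supporting windows left/right


@dataclass
class IntergenicRepeatHit:
    haplotype: str
    start: int
    end: int
    identity: float
    strand: str = "+"


@dataclass
class RecombinationCandidate:
    haplotype: str
    breakpoint_position: int
    kind: str  # "block_boundary" | "large_indel"
    nearby_hits: list[IntergenicRepeatHit]
    profile: IdentityProfile | None = None
    breakpoints: list[BreakpointCall] = field(default_factory=list)


def identity_profile(
    recombinant: str,
    parents: dict[str, str],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    recombinant_id: str = "recombinant",
) -> IdentityProfile:
    """Windowed percent identity of each parent along the recombinant.

    Each parent is globally aligned to the recombinant; per recombinant
    position, a match scores 1 and a mismatch or gap scores 0 (gaps count
    as mismatch, penalising indel-rich misalignments).  Windows where less
    than half the positions are aligned to the parent are masked (NaN).
    """
    if len(parents) < 2:
        raise ValueError("need at least two candidate parents")
    if window < 50:
        raise ValueError("window must be >= 50")
    n = len(recombinant)
    centers = np.arange(0, n - window + 1, step) + window // 2
    tracks = np.full((len(parents), len(centers)), np.nan)
    for row, (pid, pseq) in enumerate(parents.items()):
        aln = biopython_global(recombinant, pseq)
        match = np.zeros(n)
        covered = np.zeros(n)
        pos = 0
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if x == "-":
                continue
            if y != "-":
                covered[pos] = 1.0
                if x == y:
                    match[pos] = 1.0
            pos += 1
        cmatch = np.concatenate([[0.0], np.cumsum(match)])
        ccov = np.concatenate([[0.0], np.cumsum(covered)])
        for t, c in enumerate(centers):
            s = c - window // 2
            e = s + window
            cov = ccov[e] - ccov[s]
            if cov < 0.5 * window:
                continue
            tracks[row, t] = (cmatch[e] - cmatch[s]) / window
    return IdentityProfile(
        recombinant_id=recombinant_id,
        parent_ids=list(parents),
        window_centers=centers,
        identity_tracks=tracks,
        window=window,
        step=step,
    )


def call_breakpoints(
    profile: IdentityProfile,
    min_delta: float = DEFAULT_MIN_DELTA,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[BreakpointCall]:
    """Call breakpoints where the best-parent label shifts.

    Per window the parent with the highest identity is labelled (masked
    windows skipped).  A breakpoint is emitted at the midpoint between two
    adjacent runs of different labels when both runs span at least
    ``min_run`` windows and the mean identity advantage of the winning
    parent is at least ``min_delta`` on both sides.
    """
    tracks = profile.identity_tracks
    labels: list[int] = []
    deltas: list[float] = []
    centers: list[int] = []
    for t in range(tracks.shape[1]):
        col = tracks[:, t]
        if np.all(np.isnan(col)):
            continue
        order = np.argsort(np.nan_to_num(col, nan=-1.0))
        best, second = order[-1], order[-2]
        second_val = col[second] if not np.isnan(col[second]) else 0.0
        if col[best] == second_val:
            continue  # uninformative window: no site separates the parents
        labels.append(int(best))
        deltas.append(float(col[best] - second_val))
        centers.append(int(profile.window_centers[t]))
    runs: list[tuple[int, int, int]] = []  # (label, first_idx, last_idx)
    for idx, lab in enumerate(labels):
        if runs and runs[-1][0] == lab:
            runs[-1] = (lab, runs[-1][1], idx)
        else:
            runs.append((lab, idx, idx))
    calls: list[BreakpointCall] = []
    for (lab1, s1, e1), (lab2, s2, e2) in zip(runs, runs[1:]):
        len1, len2 = e1 - s1 + 1, e2 - s2 + 1
        if len1 < min_run or len2 < min_run:
            continue
        d1 = float(np.mean(deltas[s1 : e1 + 1]))
        d2 = float(np.mean(deltas[s2 : e2 + 1]))
        if d1 < min_delta or d2 < min_delta:
            continue
        pos = (centers[e1] + centers[s2]) // 2
        calls.append(
            BreakpointCall(
                position=pos,
                left_parent=profile.parent_ids[lab1],
                right_parent=profile.parent_ids[lab2],
                delta=min(d1, d2),
                run_length=(len1, len2),
            )
        )
    return calls


def find_duplicated_intergenic(
    haplotypes: dict[str, str],
    probe_sequence: str,
    min_identity: float = 0.7,
    k: int = 9,
) -> list[IntergenicRepeatHit]:
    """All occurrences of a duplicated intergenic probe in each haplotype.

    Candidate loci are seeded by exact k-mer anchors of the probe (both
    strands), grouped by diagonal neighbourhood, and verified by global
    alignment of the probe against the candidate span; hits at identity >=
    ``min_identity`` are kept, non-overlapping best-first.
    """
    if len(probe_sequence) < 200:
        raise ValueError("probe must be at least 200 bp")
    probe = probe_sequence.upper()
    hits: list[IntergenicRepeatHit] = []
    for hap_id, seq in haplotypes.items():
        seq = seq.upper()
        for strand, target in (("+", seq), ("-", reverse_complement(seq))):
            for start, end in _candidate_spans(probe, target, k, len(probe)):
                aln = biopython_global(probe, target[start:end])
                try:
                    ident = aln.identity()
                except ZeroDivisionError:
                    continue
                if ident < min_identity:
                    continue
                if strand == "-":
                    start, end = len(seq) - end, len(seq) - start
                hits.append(
                    IntergenicRepeatHit(
                        haplotype=hap_id, start=start, end=end,
                        identity=ident, strand=strand,
                    )
                )
    hits.sort(key=lambda h: -h.identity)
    kept: list[IntergenicRepeatHit] = []
    for h in hits:
        if any(
            k2.haplotype == h.haplotype and h.start < k2.end and h.end > k2.start
            for k2 in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.haplotype, h.start))
    return kept


def _candidate_spans(probe: str, target: str, k: int, probe_len: int):
    anchors = _forward_anchors(probe, target, k, max_kmer_freq=50)
    if not anchors:
        return []
    # cluster anchors by approximate target offset (pos_b - pos_a)
    anchors.sort(key=lambda a: a.pos_b - a.pos_a)
    clusters: list[list] = [[anchors[0]]]
    for a in anchors[1:]:
        if (a.pos_b - a.pos_a) - (clusters[-1][-1].pos_b - clusters[-1][-1].pos_a) <= probe_len // 2:
            clusters[-1].append(a)
        else:
            clusters.append([a])
    spans = []
    for cl in clusters:
        if sum(a.length for a in cl) < max(2 * k, probe_len // 50):
            continue
        # anchor the candidate on the longest exact match: short spurious
        # anchors in the cluster must not drag the span off the true copy
        longest = max(cl, key=lambda a: a.length)
        offset = (longest.pos_b - longest.pos_a)
        start = max(0, offset)
        end = min(len(target), offset + probe_len)
        if end - start >= probe_len // 2:
            spans.append((start, end))
    return spans


def scan_intergenic_recombination(
    blocks: list[ColinearBlock],
    indels: list[IndelEvent],
    repeat_hits: list[IntergenicRepeatHit],
    haplotypes: dict[str, str] | None = None,
    flank: int = DEFAULT_FLANK,
    min_indel: int = 5000,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[RecombinationCandidate]:
    """Screen colinearity breakpoints for nearby duplicated intergenic copies.

    Every block boundary and every indel of at least ``min_indel`` bases is
    checked against the repeat hits; a breakpoint within ``flank`` bases of
    a hit on either haplotype becomes a candidate unequal-recombination
    event.  When ``haplotypes`` sequences are supplied, the two nearest
    repeat copies are profiled against the fused region around the
    breakpoint so the identity shift can be inspected and breakpoint-called.
    """
    breakpoints: list[tuple[str, int, str]] = []
    for blk in blocks:
        breakpoints.append(("A", blk.range_a[0], "block_boundary"))
        breakpoints.append(("A", blk.range_a[1], "block_boundary"))
        breakpoints.append(("B", blk.range_b[0], "block_boundary"))
        breakpoints.append(("B", blk.range_b[1], "block_boundary"))
    for ind in indels:
        if ind.length >= min_indel:
            pos = ind.pos_a if ind.carrier == "A" else ind.pos_b
            breakpoints.append((ind.carrier, pos, "large_indel"))

    candidates: list[RecombinationCandidate] = []
    seen: set[tuple[str, int]] = set()
    for hap, pos, kind in breakpoints:
        key = (hap, pos // max(1, flank))
        if key in seen:
            continue
        near = [
            h
            for h in repeat_hits
            if h.haplotype == hap and abs((h.start + h.end) // 2 - pos) <= flank
        ]
        if not near:
            continue
        seen.add(key)
        cand = RecombinationCandidate(
            haplotype=hap, breakpoint_position=pos, kind=kind, nearby_hits=near
        )
        if haplotypes and hap in haplotypes and len(near) >= 1:
            seq = haplotypes[hap]
            lo = max(0, pos - flank)
            hi = min(len(seq), pos + flank)
            fused = seq[lo:hi]
            copies = _nearest_copies(repeat_hits, hap, pos, haplotypes)
            if len(copies) >= 2:
                cand.profile = identity_profile(
                    fused, copies, window=window, step=step,
                    recombinant_id=f"{hap}:{lo}-{hi}",
                )
                cand.breakpoints = [
                    BreakpointCall(
                        position=b.position + lo,
                        left_parent=b.left_parent,
                        right_parent=b.right_parent,
                        delta=b.delta,
                        run_length=b.run_length,
                    )
                    for b in call_breakpoints(cand.profile)
                ]
        candidates.append(cand)
    return candidates


def _nearest_copies(repeat_hits, hap, pos, haplotypes) -> dict[str, str]:
    """Sequences of the two repeat copies nearest the breakpoint, from the
    opposite haplotype when available (the parental copies), else same."""
    other = [h for h in repeat_hits if h.haplotype != hap]
    pool = other if len(other) >= 2 else [h for h in repeat_hits if h.haplotype == hap]
    pool = sorted(pool, key=lambda h: abs((h.start + h.end) // 2 - pos))[:2]
    out: dict[str, str] = {}
    for h in pool:
        seq = haplotypes.get(h.haplotype)
        if seq is None:
            continue
        out[f"{h.haplotype}:{h.start}-{h.end}"] = seq[h.start : h.end]
    return out
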