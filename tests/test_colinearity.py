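"""Anchor finding, block chaining and base-level refinement."""

import numpy as np
import pytest

from rgacluster import colinearity
from rgacluster.alignment import biopython_score
from rgacluster.colinearity import (
    AnchorMatch,
    chain_blocks,
    export_dotplot,
    find_anchors,
    nucleotide_diversity,
    refine_block,
)


def _random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestAnchors:
    def test_identical_sequences_one_anchor(self, rng):
        s = _random_dna(rng, 1000)
        anchors = find_anchors(s, s, k=15)
        assert len(anchors) == 1
        a = anchors[0]
        assert (a.pos_a, a.pos_b, a.length) == (0, 0, 1000)
        assert a.diagonal == 0

    def test_insertion_splits_diagonals(self, rng):
        s = _random_dna(rng, 1000)
        ins = _random_dna(rng, 100)
        b = s[:500] + ins + s[500:]
        anchors = find_anchors(s, b, k=15)
        diags = sorted({a.diagonal for a in anchors})
        assert diags == [-100, 0]

    def test_repetitive_kmers_filtered(self):
        # every poly-A k-mer occurs ~490 times, far over the cap: no seeds
        s = "A" * 500
        assert find_anchors(s, s, k=10, max_kmer_freq=10) == []

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            find_anchors("ACGTACGT", "ACGTACGT", k=4)

    def test_reverse_strand_anchors_flagged(self, rng):
        s = _random_dna(rng, 600)
        from rgacluster.locus_io import reverse_complement

        b = reverse_complement(s)
        anchors = find_anchors(s, b, k=15, with_reverse=True)
        assert any(a.strand == "-" for a in anchors)
        assert not any(a.strand == "+" and a.length > 50 for a in anchors)


class TestChaining:
    def test_identical_sequences_one_block(self, rng):
        s = _random_dna(rng, 2000)
        blocks = chain_blocks(find_anchors(s, s), min_block=500)
        assert len(blocks) == 1
        assert blocks[0].range_a == (0, 2000)

    def test_large_gap_splits_blocks(self, rng):
        s = _random_dna(rng, 6000)
        ins = _random_dna(rng, 5000)
        b = s[:3000] + ins + s[3000:]
        blocks = chain_blocks(find_anchors(s, b), max_gap=2000, min_block=500)
        assert len(blocks) == 2
        assert blocks[0].range_a[1] <= 3000 <= blocks[1].range_a[0]

    def test_blocks_monotone_and_disjoint(self, rng):
        # shuffled-with-noise input: chained blocks must stay monotone in
        # both coordinates and non-overlapping on each sequence
        s = _random_dna(rng, 5000)
        b = s[:2000] + _random_dna(rng, 800) + s[2500:]
        blocks = chain_blocks(find_anchors(s, b), min_block=300)
        for prev, cur in zip(blocks, blocks[1:]):
            assert prev.range_a[1] <= cur.range_a[0]
            assert prev.range_b[1] <= cur.range_b[0]

    def test_empty_input(self):
        assert chain_blocks([]) == []


class TestRefinement:
    def test_identical_block_identity_one(self, rng):
        s = _random_dna(rng, 1500)
        blocks = chain_blocks(find_anchors(s, s))
        ref = refine_block(s, s, blocks[0])
        assert ref.block.identity == 1.0
        assert ref.block.snp_count == 0
        assert ref.indels == []

    def test_planted_substitutions_counted_exactly(self, rng):
        s = _random_dna(rng, 1000)
        b = list(s)
        positions = rng.choice(900, size=10, replace=False) + 50
        for p in positions:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        b = "".join(b)
        blocks = chain_blocks(find_anchors(s, b), min_block=200)
        ref = refine_block(s, b, blocks[0])
        assert ref.block.snp_count == 10
        assert ref.block.identity == pytest.approx(0.99, abs=0.001)
        # identity is exactly 1 - SNPs / aligned columns
        cols = sum(
            1 for x, y in zip(ref.alignment.aligned_a, ref.alignment.aligned_b)
            if x != "-" and y != "-"
        )
        assert ref.block.identity == pytest.approx(1 - ref.block.snp_count / cols)

    def test_planted_indels_recovered_exactly(self, rng):
        s = _random_dna(rng, 3000)
        ins = _random_dna(rng, 37)
        b = s[:1000] + ins + s[1000:2000] + s[2060:]  # +37 insertion, -60 deletion
        blocks = chain_blocks(find_anchors(s, b), min_block=500, max_gap=5000)
        assert len(blocks) == 1
        ref = refine_block(s, b, blocks[0])
        lengths = sorted((e.length, e.carrier) for e in ref.indels)
        assert lengths == [(37, "B"), (60, "A")]
        assert ref.block.snp_count == 0

    def test_refined_score_matches_full_dp_small(self, rng):
        """Oracle equivalence: anchored-piecewise refinement reaches the
        same score as an unbanded full-DP alignment on short sequences."""
        s = _random_dna(rng, 1200)
        b = list(s)
        for p in rng.choice(1100, size=12, replace=False) + 50:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        b = "".join(b[:600]) + _random_dna(rng, 20) + "".join(b[600:])
        blocks = chain_blocks(find_anchors(s, b), min_block=400)
        ref = refine_block(s, b, blocks[0])
        assert ref.alignment.score == pytest.approx(biopython_score(s, b))


class TestDiversity:
    def test_identical_alignment_zero(self, rng):
        s = _random_dna(rng, 500)
        blocks = chain_blocks(find_anchors(s, s))
        ref = refine_block(s, s, blocks[0])
        assert nucleotide_diversity(ref.alignment) == 0.0

    def test_direct_ratio(self):
        from rgacluster.alignment import AlignmentResult

        aln = AlignmentResult(0, "A" * 200, "C" * 2 + "A" * 198)
        assert nucleotide_diversity(aln) == pytest.approx(0.01)

    def test_mask_restricts_columns(self):
        from rgacluster.alignment import AlignmentResult

        aln = AlignmentResult(0, "AAAA", "CAAA")
        assert nucleotide_diversity(aln, mask=[(0, 1)]) == 1.0
        assert nucleotide_diversity(aln, mask=[(1, 4)]) == 0.0

    def test_no_columns_error(self):
        from rgacluster.alignment import AlignmentResult

        aln = AlignmentResult(0, "----", "AAAA")
        with pytest.raises(ZeroDivisionError):
            nucleotide_diversity(aln)


class TestDotplotExport:
    def test_empty_and_single(self, tmp_path):
        p = tmp_path / "dots.tsv"
        export_dotplot([], p)
        assert p.read_text() == "pos_a\tpos_b\tlength\tstrand\n"
        export_dotplot([AnchorMatch(0, 0, 1000)], p)
        lines = p.read_text().splitlines()
        assert lines[1] == "0\t0\t1000\t+"

    def test_inversion_rows_flagged(self, rng, tmp_path):
        from rgacluster.locus_io import reverse_complement

        s = _random_dna(rng, 1200)
        inv = s[:400] + reverse_complement(s[400:800]) + s[800:]
        anchors = find_anchors(s, inv, with_reverse=True)
        p = tmp_path / "dots.tsv"
        export_dotplot(anchors, p)
        strands = {line.split("\t")[3] for line in p.read_text().splitlines()[1:]}
        assert "-" in strands
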