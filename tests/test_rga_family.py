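"""Gene classification, allele pairing, clade clustering, domain annotation."""

import itertools

import numpy as np
import pytest

from rgacluster import rga_family
from rgacluster.locus_io import Disruption, GeneModel
from rgacluster.moldating import CodonAlignment
from rgacluster.rga_family import (
    SimilarityEvidence,
    annotate_nblrr,
    assign_alleles,
    classify_gene,
    cluster_clades,
    detect_coding_ssr,
    pairwise_dnds,
    pairwise_identity_matrix,
)


def _model(n_disruptions=0):
    kinds = [Disruption.inframe_stop, Disruption.frameshift, Disruption.missing_start]
    return GeneModel(
        id="g", seqid="s", strand="+", exon_ranges=[(0, 300)], cds_ranges=[(0, 300)],
        disruptions=kinds[:n_disruptions],
    )


class TestClassifier:
    def test_complete(self):
        ev = SimilarityEvidence("g", q_cov=0.9, s_cov=0.9)
        assert classify_gene(_model(0), ev).label == "complete"

    def test_small_fragment_is_remnant(self):
        ev = SimilarityEvidence("g", q_cov=0.25, s_cov=0.9)
        assert classify_gene(_model(0), ev).label == "remnant"

    def test_many_fragments_is_remnant(self):
        ev = SimilarityEvidence("g", q_cov=0.45, s_cov=0.9, n_fragments=4)
        assert classify_gene(_model(0), ev).label == "remnant"

    def test_many_disruptions_is_remnant(self):
        ev = SimilarityEvidence("g", q_cov=0.95, s_cov=0.95)
        assert classify_gene(_model(3), ev).label == "remnant"

    def test_single_disruption_is_pseudogene(self):
        ev = SimilarityEvidence("g", q_cov=0.95, s_cov=0.95)
        assert classify_gene(_model(1), ev).label == "pseudogene"

    def test_partial_coverage_is_fragment(self):
        ev = SimilarityEvidence("g", q_cov=0.6, s_cov=0.9)
        assert classify_gene(_model(0), ev).label == "fragment"

    def test_no_evidence_falls_back_to_disruptions(self):
        assert classify_gene(_model(0), None).label == "complete"
        assert classify_gene(_model(1), None).label == "pseudogene"
        assert classify_gene(_model(3), None).label == "remnant"

    @pytest.mark.parametrize(
        "q_cov,n_frag,n_dis",
        list(itertools.product([0.2, 0.4, 0.6, 0.9], [1, 4], [0, 1, 3])),
    )
    def test_total_function_with_documented_precedence(self, q_cov, n_frag, n_dis):
        """Exhaustive rule grid: exactly one label, and it matches the
        most-degraded-first precedence evaluated by hand."""
        ev = SimilarityEvidence("g", q_cov=q_cov, s_cov=0.9, n_fragments=n_frag)
        label = classify_gene(_model(n_dis), ev).label
        if q_cov < 0.3 or (n_frag > 3 and q_cov < 0.5) or n_dis > 2:
            expected = "remnant"
        elif n_dis >= 1:
            expected = "pseudogene"
        elif q_cov < 0.8:
            expected = "fragment"
        else:
            expected = "complete"
        assert label == expected


class TestIdentityMatrix:
    def test_identical_pair(self):
        m = pairwise_identity_matrix(["ATGAAACCC" * 20, "ATGAAACCC" * 20])
        assert m[0, 1] == 1.0

    def test_planted_divergence(self, rng):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        b = list(a)
        for p in rng.choice(1000, size=100, replace=False):
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        m = pairwise_identity_matrix([a, "".join(b)])
        assert m[0, 1] == pytest.approx(0.90, abs=0.01)

    def test_requirements(self):
        with pytest.raises(ValueError):
            pairwise_identity_matrix(["ACGT"])
        with pytest.raises(ValueError):
            pairwise_identity_matrix(["ACGT", ""])


class TestAssignAlleles:
    def test_single_cross_haplotype_pair(self):
        m = np.array([[1.0, 0.99], [0.99, 1.0]])
        res = assign_alleles(m, ["A", "B"], ["a1", "b1"])
        assert res.pairs == [("a1", "b1", pytest.approx(0.99))]
        assert res.unpaired == []

    def test_near_tie_flagged_ambiguous(self):
        # a recent duplication: a1 and a2 both ~equally close to b1
        ids = ["a1", "a2", "b1"]
        m = np.array(
            [[1.0, 0.98, 0.980], [0.98, 1.0, 0.975], [0.980, 0.975, 1.0]]
        )
        res = assign_alleles(m, ["A", "A", "B"], ids, tie_margin=0.01)
        assert res.pairs == []
        assert any(t[0] == "b1" for t in res.ambiguous)

    def test_pairs_and_paralogs_partition(self):
        # 5 clean pairs + 3 one-sided paralogs
        rngm = np.random.default_rng(0)
        ids = [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(5)]
        haps = ["A"] * 8 + ["B"] * 5
        n = len(ids)
        m = np.full((n, n), 0.75) + rngm.uniform(0, 0.01, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        for i in range(5):  # a0..a4 pair with b0..b4
            m[i, 8 + i] = m[8 + i, i] = 0.97 + 0.002 * i
        res = assign_alleles(m, haps, ids)
        assert sorted(p[:2] for p in res.pairs) == [(f"a{i}", f"b{i}") for i in range(5)]
        assert res.unpaired == ["a5", "a6", "a7"]

    def test_never_pairs_within_haplotype_and_stable_under_relabeling(self):
        rngm = np.random.default_rng(1)
        n = 10
        m = np.full((n, n), 0.8) + rngm.uniform(0, 0.05, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        haps = ["A", "B"] * 5
        ids = [f"g{i}" for i in range(n)]
        res = assign_alleles(m, haps, ids, min_identity=0.8, tie_margin=0.0)
        hap_of = dict(zip(ids, haps))
        assert all(hap_of[a] != hap_of[b] for a, b, _ in res.pairs)
        # permuting the input order yields the same pair set
        perm = rngm.permutation(n)
        res2 = assign_alleles(
            m[np.ix_(perm, perm)], [haps[i] for i in perm], [ids[i] for i in perm],
            min_identity=0.8, tie_margin=0.0,
        )
        assert sorted(p[:2] for p in res.pairs) == sorted(p[:2] for p in res2.pairs)


class TestClades:
    def test_single_clade(self):
        m = np.full((4, 4), 0.96)
        np.fill_diagonal(m, 1.0)
        assert cluster_clades(m, cut_identity=0.80) == [1, 1, 1, 1]

    def test_two_planted_families(self):
        # 90% within, 70% between, cut at 80%
        n = 6
        m = np.full((n, n), 0.70)
        for i in range(3):
            for j in range(3):
                m[i, j] = m[i + 3, j + 3] = 0.90
        np.fill_diagonal(m, 1.0)
        labels = cluster_clades(m, cut_identity=0.80)
        assert labels == [1, 1, 1, 2, 2, 2]

    def test_labels_invariant_under_permutation(self):
        n = 6
        m = np.full((n, n), 0.70)
        for i in range(3):
            for j in range(3):
                m[i, j] = m[i + 3, j + 3] = 0.90
        np.fill_diagonal(m, 1.0)
        perm = [3, 0, 4, 1, 5, 2]
        labels = cluster_clades(m[np.ix_(perm, perm)])
        # members of one family always share a label
        fam = {}
        for orig, lab in zip(perm, labels):
            fam.setdefault(orig // 3, set()).add(lab)
        assert all(len(s) == 1 for s in fam.values())


CONSENSUS_UNIT = "LKK" + "LNN" + "LDD" + "LK" + "LSE" + "NE" + "LQQ" + "IP" + "KD"


class TestAnnotateNBLRR:
    def test_no_aliphatic_residues_no_repeats(self):
        ann = annotate_nblrr("GGSGGSGGRDNQEEKKHH" * 10)
        assert ann.lrr_repeats == []

    def test_exact_consensus_units_all_found(self):
        assert len(CONSENSUS_UNIT) == 23
        text = CONSENSUS_UNIT * 15
        ann = annotate_nblrr(text)
        assert len(ann.lrr_repeats) == 15
        assert all(r.score == 1.0 for r in ann.lrr_repeats)
        # repeats are contiguous
        starts = [r.start for r in ann.lrr_repeats]
        assert starts == list(range(0, 15 * 23, 23))

    def test_exposed_positions_are_core_x_sites(self):
        ann = annotate_nblrr(CONSENSUS_UNIT * 2)
        first = ann.lrr_repeats[0]
        # core LxxLxLxx occupies unit positions 6..13; x at 7,8,10,12,13
        assert first.exposed_positions == [7, 8, 10, 12, 13]

    def test_motifs_found_in_order(self):
        protein = (
            "M" + "KE" * 30
            + "GGVGKTT" + "A" * 10 + "FDLRAW" + "A" * 10 + "LLVLDDVW"
            + "A" * 10 + "GSRIIITTR" + "A" * 10 + "GLPLA" + "A" * 10
            + "CFLYCA" + "A" * 10 + "MHDL" + CONSENSUS_UNIT * 3
        )
        ann = annotate_nblrr(protein)
        found = [n for n in ("P-loop", "kinase-2", "GLPL", "MHD") if n in ann.nbarc_motifs]
        assert found == ["P-loop", "kinase-2", "GLPL", "MHD"]
        positions = [ann.nbarc_motifs[n][0] for n in found]
        assert positions == sorted(positions)
        assert len(ann.lrr_repeats) == 3

    def test_internal_stop_truncates_with_warning(self):
        ann = annotate_nblrr(CONSENSUS_UNIT * 2 + "*" + CONSENSUS_UNIT * 5)
        assert len(ann.lrr_repeats) == 2
        assert any("stop" in w for w in ann.warnings)


class TestCodingSSR:
    def test_no_repeats_empty(self, rng):
        cds = "ATG" + "GAACTT" * 30 + "TGA"
        assert detect_coding_ssr(cds).loci == []

    def test_serine_tract_reported(self):
        cds = "ATG" + "GAACAT" * 10 + "TCT" * 9 + "GAACAT" * 10 + "TGA"
        rep = detect_coding_ssr(cds)
        assert len(rep.loci) == 1
        assert rep.tracts[0].startswith("S")
        assert int(rep.tracts[0].split("x")[1]) >= 9

    def test_compound_three_prime_motif(self):
        cds = "ATG" + "GAACTT" * 20 + "GAT" * 4 + "GCT" * 4 + "GAA" * 6 + "TGA"
        rep = detect_coding_ssr(cds)
        assert len(rep.compound) == 1
        assert len(rep.compound[0]) == 3


class TestPairwiseDnds:
    def test_identical_pair_undefined_ratio(self):
        aln = CodonAlignment.from_sequences("ATGAAACCC", "ATGAAACCC")
        p_n, p_s, ratio = pairwise_dnds(aln)
        assert p_n == 0 and p_s == 0 and ratio is None

    def test_synonymous_only_changes_ratio_zero(self):
        a = "TTTAAAGGTCGT" * 5
        b = "TTCAAAGGGCGT" * 5  # third-position synonymous changes only
        p_n, p_s, ratio = pairwise_dnds(CodonAlignment.from_sequences(a, b))
        assert p_n == 0
        assert p_s > 0
        assert ratio == 0

    def test_nonsynonymous_excess_ratio_above_one(self):
        a = "TTTGCTAAA" * 10
        b = "CATGCTAAA" * 10  # first codon Phe->His: nonsynonymous
        p_n, p_s, ratio = pairwise_dnds(CodonAlignment.from_sequences(a, b))
        assert p_n > 0 and p_s == 0
        assert ratio is None  # pS = 0 flagged undefined rather than infinite
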