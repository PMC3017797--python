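"""The haplotype-pair simulator: determinism, composition, truth recovery."""

import numpy as np
import pytest

from rgacluster import moldating, repeats
from rgacluster.locus_io import FeatureKind, extract_cds, read_fasta, read_gff3
from rgacluster.moldating import CODON_AA
from rgacluster.rga_family import annotate_nblrr
from rgacluster.synthetic_data import (
    SimulationConfig,
    SSRSpec,
    build_rga_template,
    emit_fixture,
    simulate_ancestor,
    simulate_pair,
)


def _translate(cds):
    return "".join(CODON_AA.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3))


class TestConfig:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(rate_coding=0)
        with pytest.raises(ValueError):
            SimulationConfig(divergence_T=-1)
        with pytest.raises(ValueError):
            SimulationConfig(n_rga=4, n_clade1=5)


class TestAncestor:
    def test_no_rga_gives_flanking_genes_only(self):
        cfg = SimulationConfig(seed=1, n_rga=0, n_clade1=0,
                               intragenic_event=False, intergenic_event=False)
        locus, plan = simulate_ancestor(cfg)
        assert all(not g.id.startswith("RGA") for g in locus.genes)
        assert len(locus.genes) == cfg.n_flank_left + cfg.n_flank_right

    def test_genome_gc_near_background(self):
        locus, _ = simulate_ancestor(SimulationConfig(seed=2))
        s = locus.sequence.residues
        gc = (s.count("G") + s.count("C")) / len(s)
        assert gc == pytest.approx(0.40, abs=0.01)

    def test_every_rga_copy_carries_the_domain_layout(self):
        cfg = SimulationConfig(seed=3, n_rga=6)
        locus, plan = simulate_ancestor(cfg)
        for g in locus.genes:
            if not g.id.startswith("RGA"):
                continue
            prot = _translate(extract_cds(g, locus.sequence).text).rstrip("*")
            ann = annotate_nblrr(prot)
            assert len(ann.lrr_repeats) == 15
            assert "P-loop" in ann.nbarc_motifs

    def test_template_length_and_translatability(self, rng):
        cds, constraints = build_rga_template(rng, 2400)
        assert len(cds) == 2400
        prot = _translate(cds)
        assert prot.endswith("*") and "*" not in prot[:-1]
        assert constraints  # structural positions recorded


class TestDivergence:
    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(seed=11)
        a1, b1, t1 = simulate_pair(cfg)
        a2, b2, t2 = simulate_pair(SimulationConfig(seed=11))
        assert a1.sequence.residues == a2.sequence.residues
        assert b1.sequence.residues == b2.sequence.residues
        assert t1.retro == t2.retro and t1.ssr == t2.ssr

    def test_zero_time_no_events_identical_haplotypes(self):
        cfg = SimulationConfig(
            seed=4, divergence_T=0.0, retro_events=[],
            ssr_loci=[SSRSpec("CT", 12, 0)],
            intragenic_event=False, intergenic_event=False,
        )
        a, b, truth = simulate_pair(cfg)
        assert a.sequence.residues == b.sequence.residues
        assert truth.substitutions == {"A": 0, "B": 0}

    def test_truth_ssr_coordinates_resolve(self, default_pair):
        a, b, truth = default_pair
        for rec in truth.ssr:
            locus = a if rec["haplotype"] == "A" else b
            text = locus.sequence.residues[rec["start"] : rec["end"]]
            assert text == rec["motif"] * rec["repeat_count"]

    def test_truth_retro_coordinates_resolve(self, default_pair):
        a, b, truth = default_pair
        for rec in truth.retro:
            locus = a if rec["haplotype"] == "A" else b
            s = locus.sequence.residues
            element = s[rec["start"] : rec["end"]]
            assert element.startswith("TG") and element.endswith("CA")
            # flanks carry the exact target-site duplication
            t = rec["tsd_length"]
            assert s[rec["start"] - t : rec["start"]] == rec["tsd"]
            assert s[rec["end"] : rec["end"] + t] == rec["tsd"]

    def test_deleted_genes_absent_from_carrier(self, default_pair):
        a, b, truth = default_pair
        deleted = truth.intergenic[0]["deleted_genes"]
        assert deleted
        ids_b = {g.id for g in b.genes}
        assert not set(deleted) & ids_b
        assert set(deleted) <= {g.id for g in a.genes}
        assert sorted(truth.a_specific) == sorted(deleted)

    def test_synonymous_divergence_matches_clock(self):
        """Pooled over a few replicates, the measured synonymous p-distance
        across allele pairs recovers T = 1 MY."""
        Sd = S = 0.0
        for seed in range(6):
            cfg = SimulationConfig(seed=200 + seed, intragenic_event=False,
                                   retro_events=[], n_rga=6)
            a, b, truth = simulate_pair(cfg)
            for gid in truth.allele_pairs:
                ca = extract_cds(a.gene(gid), a.sequence).text
                cb = extract_cds(b.gene(gid), b.sequence).text
                cnt = moldating.nei_gojobori(
                    moldating.CodonAlignment.from_sequences(ca, cb)
                )
                Sd += cnt.Sd
                S += cnt.S
        t_hat = moldating.date_divergence(Sd / S).T
        # 3 binomial SE around the 1 MY expectation
        se = 3 * np.sqrt(0.009 * (1 - 0.009) / S) / (2 * 4.5e-9) / 1e6
        assert abs(t_hat - 1.0) <= se

    def test_slippage_recoverable_through_scan(self, default_pair):
        a, b, truth = default_pair
        sa, sb = a.sequence.residues, b.sequence.residues
        by_hap = {"A": repeats.scan_ssr(sa), "B": repeats.scan_ssr(sb)}
        for rec in truth.ssr:
            hits = [
                l
                for l in by_hap[rec["haplotype"]]
                if l.start < rec["end"] and l.end > rec["start"]
            ]
            assert len(hits) == 1
            assert hits[0].repeat_count >= rec["repeat_count"]


class TestEmit:
    def test_fixture_round_trip(self, tmp_path, clean_pair):
        a, b, truth = clean_pair
        paths = emit_fixture(a, b, truth, tmp_path)
        seqs = read_fasta(paths["hapA.fasta"])
        assert seqs[0].residues == a.sequence.residues
        feats = read_gff3(paths["hapA.gff3"], seqs)
        gene_feats = {f.id for f in feats if f.kind is FeatureKind.gene}
        assert {g.id for g in a.genes} <= gene_feats
        # gene coordinates survive the round trip exactly
        by_id = {f.id: f for f in feats}
        for g in a.genes:
            assert (by_id[g.id].start, by_id[g.id].end) == g.span
        assert (tmp_path / "truth_alleles.tsv").exists()

    def test_emitted_files_are_modest_text(self, tmp_path, clean_pair):
        a, b, truth = clean_pair
        paths = emit_fixture(a, b, truth, tmp_path)
        for p in paths.values():
            assert p.stat().st_size < 200_000
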