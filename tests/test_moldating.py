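"""Synonymous-site counting and the two dating formulas.

The Nei-Gojobori implementation is checked against an independent
brute-force pathway enumerator built here from Biopython's translation
table: for every codon pair it explicitly walks all orderings of the
differing positions, drops orderings that pass through a stop codon, and
averages synonymous/nonsynonymous step counts.
"""

import math
from itertools import permutations

import numpy as np
import pytest
from Bio.Seq import Seq

from rgacluster import moldating
from rgacluster.moldating import (
    CodonAlignment,
    SaturationError,
    UndefinedValueError,
    date_divergence,
    date_insertion,
    k2p,
    nei_gojobori,
    p_distance,
)

# ---------------------------------------------------------------------------
# independent oracle


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _oracle_sites(codon: str) -> float:
    if _aa(codon) == "*":
        return 0.0
    s = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if _aa(mut) == "*":
                continue
            if _aa(mut) == _aa(codon):
                s += 1 / 3
    return s


def _oracle_differences(ca: str, cb: str):
    diff = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in permutations(diff):
        cur, syn, non = ca, 0, 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            results.append((syn, non))
    if not results:
        return len(diff) / 2, len(diff) / 2
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def _oracle_count(codons_a, codons_b):
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if "*" in (_aa(ca), _aa(cb)) or any(c not in "ACGT" for c in ca + cb):
            continue
        sa, sb = _oracle_sites(ca), _oracle_sites(cb)
        S += (sa + sb) / 2
        N += 3 - (sa + sb) / 2
        syn, non = _oracle_differences(ca, cb)
        Sd += syn
        Nd += non
    return S, N, Sd, Nd


def _random_codon_pairs(rng, n_codons):
    bases = "ACGT"
    while True:
        a = ["".join(bases[i] for i in rng.integers(0, 4, 3)) for _ in range(n_codons)]
        b = []
        for codon in a:
            c = list(codon)
            for _ in range(int(rng.integers(0, 3))):
                c[rng.integers(3)] = bases[rng.integers(4)]
            b.append("".join(c))
        if all(_aa(c) != "*" for c in a[:1]):  # keep the first codon sane
            return a, b


# ---------------------------------------------------------------------------


class TestNeiGojobori:
    def test_identical_pair_has_zero_differences(self):
        aln = CodonAlignment.from_sequences("ATGAAATTT", "ATGAAATTT")
        cnt = nei_gojobori(aln)
        assert cnt.Sd == 0 and cnt.Nd == 0
        assert cnt.usable_codons == 3

    def test_single_synonymous_third_position_change(self):
        # Phe TTT <-> Phe TTC: one synonymous difference, no nonsynonymous
        cnt = nei_gojobori(CodonAlignment.from_sequences("TTT", "TTC"))
        assert cnt.Sd == pytest.approx(1.0)
        assert cnt.Nd == pytest.approx(0.0)

    def test_single_nonsynonymous_change(self):
        # Phe TTT <-> Leu CTT at position one
        cnt = nei_gojobori(CodonAlignment.from_sequences("TTT", "CTT"))
        assert cnt.Sd == pytest.approx(0.0)
        assert cnt.Nd == pytest.approx(1.0)

    def test_gap_and_ambiguity_codons_skipped(self):
        aln = CodonAlignment(["TTT", "NNN", "T-T"], ["TTC", "AAA", "TTT"])
        cnt = nei_gojobori(aln)
        assert cnt.usable_codons == 1
        assert cnt.Sd == pytest.approx(1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            CodonAlignment.from_sequences("ATGAAA", "ATG")
        with pytest.raises(ValueError):
            CodonAlignment.from_sequences("ATGA", "ATGA")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumerator(self, seed):
        """Sd/Nd agree exactly with explicit pathway enumeration on random
        30-codon pairs."""
        rng = np.random.default_rng(seed)
        a, b = _random_codon_pairs(rng, 30)
        cnt = nei_gojobori(CodonAlignment(a, b))
        S, N, Sd, Nd = _oracle_count(a, b)
        assert cnt.S == pytest.approx(S)
        assert cnt.N == pytest.approx(N)
        assert cnt.Sd == pytest.approx(Sd)
        assert cnt.Nd == pytest.approx(Nd)

    @pytest.mark.parametrize("seed", range(5))
    def test_site_conservation_and_symmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = _random_codon_pairs(rng, 25)
        fwd = nei_gojobori(CodonAlignment(a, b))
        rev = nei_gojobori(CodonAlignment(b, a))
        assert fwd.S + fwd.N == pytest.approx(3 * fwd.usable_codons)
        assert fwd.Sd == pytest.approx(rev.Sd)
        assert fwd.Nd == pytest.approx(rev.Nd)
        assert fwd.S == pytest.approx(rev.S)


class TestDistances:
    def test_p_distance_zero_when_no_differences(self):
        cnt = moldating.SynonymyCount(S=300.0, N=600.0, Sd=0.0, Nd=0.0)
        assert p_distance(cnt).p_s == 0.0

    def test_p_distance_direct_ratio(self):
        cnt = moldating.SynonymyCount(S=300.0, N=600.0, Sd=3.0, Nd=6.0)
        est = p_distance(cnt)
        assert est.p_s == pytest.approx(0.01)
        assert est.p_n == pytest.approx(0.01)

    def test_p_distance_requires_sites(self):
        with pytest.raises(UndefinedValueError):
            p_distance(moldating.SynonymyCount(S=0.0, N=3.0, Sd=0.0, Nd=0.0))

    def test_k2p_identical_is_zero(self):
        assert k2p("ACGTACGT", "ACGTACGT").k2p == pytest.approx(0.0)

    def test_k2p_closed_form(self):
        # 20 columns: 2 transitions (P=0.1), 1 transversion (Q=0.05)
        a = "A" * 20
        b = "G" * 2 + "C" * 1 + "A" * 17
        est = k2p(a, b)
        expected = -0.5 * math.log(1 - 2 * 0.1 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
        assert est.k2p == pytest.approx(expected)
        assert est.k2p == pytest.approx(0.1702, abs=1e-4)

    def test_k2p_saturation_error(self):
        # P=0.5, Q=0.25 -> log argument 1-2P-Q < 0
        a = "A" * 20
        b = "G" * 10 + "C" * 5 + "A" * 5
        with pytest.raises(SaturationError):
            k2p(a, b)

    def test_k2p_excludes_gaps_and_ns(self):
        est = k2p("ACGT-N", "ACGAAN")
        # only 4 eligible columns, one transversion T->A at position 3
        assert est.k2p == pytest.approx(
            -0.5 * math.log(1 - 0.25) - 0.25 * math.log(1 - 0.5)
        )

    def test_k2p_small_distance_approaches_p_plus_q(self):
        a = "ACGT" * 250
        b = "GCGT" + "ACGT" * 249  # one transition in 1000 columns
        est = k2p(a, b)
        assert est.k2p == pytest.approx(0.001, rel=0.01)


class TestDating:
    def test_zero_distance_zero_time(self):
        assert date_divergence(0.0).T == 0.0
        assert date_insertion(0.0).T == 0.0

    def test_headline_coding_example(self):
        res = date_divergence(0.0088, rate=0.45e-8)
        assert res.T == pytest.approx(0.9778, abs=1e-3)

    def test_interspecies_scale(self):
        assert date_divergence(0.04, rate=4.5e-9).T == pytest.approx(4.44, abs=0.01)

    def test_ltr_insertion_example(self):
        assert date_insertion(0.0396, rate=9e-9).T == pytest.approx(2.2, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            date_divergence(0.01, rate=0)
        with pytest.raises(ValueError):
            date_divergence(-0.1)
        with pytest.raises(ValueError):
            date_insertion(moldating.DistanceEstimate(valid=False))


class TestDatingTable:
    def test_concatenated_headline_estimate(self):
        pairs = [
            ("g1", "g1b", "TTTAAAGGG" * 10, "TTCAAAGGG" * 10),
            ("g2", "g2b", "ATGCCC" * 10, "ATGCCC" * 10),
        ]
        df = moldating.dating_table(pairs)
        assert list(df["gene_pair"]) == ["g1/g1b", "g2/g2b"]
        cc = df.attrs["concatenated"]
        assert cc["Sd"] == pytest.approx(10.0)
        # concatenated pS pools sites across pairs, not a mean of per-gene pS
        assert cc["pS"] == pytest.approx(10.0 / cc["S"])
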