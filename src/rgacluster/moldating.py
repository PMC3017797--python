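"""Synonymous-site counting and molecular dating.

Implements the Nei & Gojobori (1986) unweighted-pathway method for counting
synonymous/nonsynonymous sites and differences between two aligned coding
sequences, the uncorrected synonymous p-distance pS = Sd/S, the Kimura
2-parameter distance, and the two dating formulas used for haplotype and
retroelement ages:

    T = pS / (2 r)   with r the synonymous substitution rate (default
                     4.5e-9 substitutions per synonymous site per year,
                     the rate determined for banana coding sequences), and
    T = K  / (2 r)   with K the K2P distance between the two LTRs of one
                     element and r the noncoding rate (default 9e-9/site/yr,
                     two-fold the coding rate).

Both formulas return time in million years (MY).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

from Bio.Data import CodonTable

CODING_RATE = 4.5e-9  # synonymous substitutions / synonymous site / year
NONCODING_RATE = 9e-9  # substitutions / site / year

_BASES = "ACGT"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_AA: dict[str, str] = dict(_TABLE.forward_table)
for stop in _TABLE.stop_codons:
    CODON_AA[stop] = "*"
STOP_CODONS = frozenset(_TABLE.stop_codons)


class SaturationError(ValueError):
    """The K2P logarithm argument is non-positive; distance undefined."""


class UndefinedValueError(ValueError):
    """A ratio with a zero denominator (no eligible sites/columns)."""


@dataclass
class CodonAlignment:
    """Paired codon lists of two aligned coding sequences."""

    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon lists differ in length")
        for c in self.codons_a + self.codons_b:
            if len(c) != 3:
                raise ValueError(f"not a codon: {c!r}")

    @classmethod
    def from_sequences(cls, a: str, b: str) -> "CodonAlignment":
        a, b = a.upper(), b.upper()
        if len(a) != len(b):
            raise ValueError("aligned CDS pair has unequal lengths")
        if len(a) % 3 != 0:
            raise ValueError("aligned CDS length is not a multiple of 3")
        return cls(
            [a[i : i + 3] for i in range(0, len(a), 3)],
            [b[i : i + 3] for i in range(0, len(b), 3)],
        )

    @property
    def usable_codons(self) -> int:
        return sum(1 for a, b in zip(self.codons_a, self.codons_b) if _usable(a, b))


def _usable(ca: str, cb: str) -> bool:
    ok = all(x in _BASES for x in ca + cb)
    return ok and ca not in STOP_CODONS and cb not in STOP_CODONS


@dataclass
class SynonymyCount:
    S: float  # synonymous sites (fractional, averaged over both sequences)
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences (pathway-averaged)
    Nd: float  # nonsynonymous differences
    usable_codons: int = 0


@dataclass
class DistanceEstimate:
    p_s: float | None = None
    p_n: float | None = None
    k2p: float | None = None
    valid: bool = True


@dataclass
class DatingResult:
    T: float  # million years
    rate: float  # substitutions / site / year
    method: str  # "coding_pS" | "ltr_K2P"


def synonymous_sites(codon: str) -> float:
    """Fractional synonymous sites of one codon: at each of the 3 positions,
    the share of the 3 one-step changes that are synonymous."""
    if codon in STOP_CODONS or any(x not in _BASES for x in codon):
        return 0.0
    aa = CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue  # changes to stop codons are not counted as sites
            if CODON_AA[mutant] == aa:
                s += 1.0 / 3.0
    return s


def _pathway_differences(ca: str, cb: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences between two codons over
    all orderings of the differing positions, excluding pathways through
    stop codons (remaining pathways re-weighted equally)."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = 0.0
    non_tot = 0.0
    n_valid = 0
    for order in permutations(diff_pos):
        current = ca
        syn = non = 0
        valid = True
        for pos in order:
            mutant = current[:pos] + cb[pos] + current[pos + 1 :]
            if mutant in STOP_CODONS:
                valid = False
                break
            if CODON_AA[mutant] == CODON_AA[current]:
                syn += 1
            else:
                non += 1
            current = mutant
        if valid:
            n_valid += 1
            syn_tot += syn
            non_tot += non
    if n_valid == 0:
        # every pathway passes through a stop: split differences evenly
        d = len(diff_pos)
        return d / 2.0, d / 2.0
    return syn_tot / n_valid, non_tot / n_valid


def nei_gojobori(alignment: CodonAlignment) -> SynonymyCount:
    """Count synonymous/nonsynonymous sites and differences (NG86).

    Sites are averaged between the two sequences; codon pairs containing
    gaps, ambiguity codes or stop codons are skipped entirely.
    """
    S = N = Sd = Nd = 0.0
    usable = 0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        if not _usable(ca, cb):
            continue
        usable += 1
        sa, sb = synonymous_sites(ca), synonymous_sites(cb)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        syn, non = _pathway_differences(ca, cb)
        Sd += syn
        Nd += non
    return SynonymyCount(S=S, N=N, Sd=Sd, Nd=Nd, usable_codons=usable)


def p_distance(count: SynonymyCount) -> DistanceEstimate:
    """Uncorrected synonymous/nonsynonymous p-distances pS = Sd/S, pN = Nd/N."""
    if count.S <= 0:
        raise UndefinedValueError("no synonymous sites (S = 0)")
    p_n = count.Nd / count.N if count.N > 0 else None
    return DistanceEstimate(p_s=count.Sd / count.S, p_n=p_n)


def k2p(aligned_a: str, aligned_b: str) -> DistanceEstimate:
    """Kimura 2-parameter distance between two aligned sequences.

    Columns containing gaps or non-ACGT characters are excluded.  With P the
    transition and Q the transversion fraction over eligible columns:
    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).
    """
    import math

    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    ts = tv = cols = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in _BASES or y not in _BASES:
            continue
        cols += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if cols == 0:
        raise UndefinedValueError("no eligible aligned columns")
    P, Q = ts / cols, tv / cols
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P saturated (P={P:.3f}, Q={Q:.3f}); distance undefined"
        )
    k = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DistanceEstimate(k2p=k, valid=True)


def date_divergence(p_s: float, rate: float = CODING_RATE) -> DatingResult:
    """Divergence time in MY from a synonymous p-distance: T = pS / (2r)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if p_s < 0:
        raise ValueError("p_s must be nonnegative")
    return DatingResult(T=p_s / (2.0 * rate) / 1e6, rate=rate, method="coding_pS")


def date_insertion(k2p_value: float | DistanceEstimate, rate: float = NONCODING_RATE) -> DatingResult:
    """LTR-pair insertion age in MY: T = K / (2r)."""
    if isinstance(k2p_value, DistanceEstimate):
        if not k2p_value.valid or k2p_value.k2p is None:
            raise ValueError("invalid K2P estimate")
        k2p_value = k2p_value.k2p
    if rate <= 0:
        raise ValueError("rate must be positive")
    if k2p_value < 0:
        raise ValueError("K must be nonnegative")
    return DatingResult(T=k2p_value / (2.0 * rate) / 1e6, rate=rate, method="ltr_K2P")


def dating_table(pairs: list[tuple[str, str, str, str]], rate: float = CODING_RATE):
    """Per-gene-pair dating report plus the concatenated headline estimate.

    ``pairs`` holds (name_a, name_b, cds_a, cds_b) with each CDS pair already
    codon-aligned (equal length, multiple of 3).  Returns a pandas DataFrame
    with columns gene_pair, length, S, N, Sd, Nd, pS, T_my and, as an
    attribute ``concatenated``, the estimate over the concatenation of all
    pairs (the headline divergence time is computed on the concatenation,
    not the per-gene mean).
    """
    import pandas as pd

    rows = []
    total = SynonymyCount(0.0, 0.0, 0.0, 0.0, 0)
    for name_a, name_b, cds_a, cds_b in pairs:
        aln = CodonAlignment.from_sequences(cds_a, cds_b)
        cnt = nei_gojobori(aln)
        total.S += cnt.S
        total.N += cnt.N
        total.Sd += cnt.Sd
        total.Nd += cnt.Nd
        total.usable_codons += cnt.usable_codons
        ps = cnt.Sd / cnt.S if cnt.S > 0 else float("nan")
        rows.append(
            {
                "gene_pair": f"{name_a}/{name_b}",
                "length": len(cds_a),
                "S": round(cnt.S, 2),
                "N": round(cnt.N, 2),
                "Sd": round(cnt.Sd, 2),
                "Nd": round(cnt.Nd, 2),
                "pS": round(ps, 4) if ps == ps else ps,
                "T_my": round(date_divergence(ps, rate).T, 3) if ps == ps else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    concat_ps = total.Sd / total.S if total.S > 0 else float("nan")
    df.attrs["concatenated"] = {
        "S": total.S,
        "Sd": total.Sd,
        "pS": concat_ps,
        "T_my": date_divergence(concat_ps, rate).T if concat_ps == concat_ps else float("nan"),
    }
    return df
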