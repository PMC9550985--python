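"""Unit and property tests for the molecular-evolution module.

The NG86 checks compare against an independent brute-force enumerator
built directly on Biopython's translation, not on the package's codon
utilities.
"""

import itertools
import math
import random

import numpy as np
import pytest
from Bio.Seq import Seq

from ydelseek import molevo
from ydelseek.molevo import (
    CodonAlignment,
    codon_align,
    divergence_time,
    lineage_replacements,
    ng86_divergence,
    pathway_counts,
    syn_fraction,
    tajima_rrt,
)

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if str(Seq(c).translate()) != "*"]


# ---------------------------------------------------------------------------
# independent oracle


def oracle_syn_sites(codon):
    aa = str(Seq(codon).translate())
    syn = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = str(Seq(alt).translate())
            if alt_aa == aa and alt_aa != "*":
                syn += 1
    return syn / 3.0


def oracle_pathways(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if str(Seq(nxt).translate()) == "*" and nxt != c2:
                blocked = True
                break
            steps.append((cur, nxt))
            cur = nxt
        if not blocked:
            valid.append(steps)
    if not valid:  # fall back to all pathways, stops included
        valid = []
        for order in itertools.permutations(diff):
            cur = c1
            steps = []
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                steps.append((cur, nxt))
                cur = nxt
            valid.append(steps)
    syn = non = 0.0
    for steps in valid:
        for cur, nxt in steps:
            a1, a2 = str(Seq(cur).translate()), str(Seq(nxt).translate())
            if a1 == a2 and a2 != "*":
                syn += 1
            else:
                non += 1
    return syn / len(valid), non / len(valid)


# ---------------------------------------------------------------------------
# NG86


def test_identical_sequences_zero_divergence():
    aln = CodonAlignment(["a", "b"], ["ATGGCT" * 5, "ATGGCT" * 5])
    d = ng86_divergence(aln)
    assert d.Sd == d.Nd == 0
    assert d.dS == d.dN == 0
    assert d.omega is None


def test_glycine_family_hand_example():
    # ten GGT vs nine GGT + one GGC: 1 synonymous difference over 10
    # synonymous sites (third position of glycine is fourfold degenerate)
    aln = CodonAlignment(["a", "b"], ["GGT" * 10, "GGT" * 9 + "GGC"])
    d = ng86_divergence(aln)
    assert d.S == pytest.approx(10.0)
    assert d.Sd == pytest.approx(1.0)
    assert d.Nd == pytest.approx(0.0)
    assert d.pS == pytest.approx(0.1)
    assert d.dS == pytest.approx(-0.75 * math.log(1 - 4 * 0.1 / 3), abs=1e-12)
    assert d.dS == pytest.approx(0.1073, abs=5e-5)


def test_two_difference_pathway_conservation():
    # Sd + Nd == 2 for every sense codon pair at Hamming distance 2
    pairs = [
        (c1, c2)
        for c1, c2 in itertools.product(SENSE_CODONS, repeat=2)
        if sum(a != b for a, b in zip(c1, c2)) == 2
    ]
    for c1, c2 in pairs:
        s, n = pathway_counts(c1, c2)
        assert s + n == pytest.approx(2.0), (c1, c2)


def test_site_and_pathway_counts_match_oracle():
    rng = random.Random(42)
    for _ in range(500):
        c1, c2 = rng.choice(SENSE_CODONS), rng.choice(SENSE_CODONS)
        assert syn_fraction(c1) == pytest.approx(oracle_syn_sites(c1)), c1
        s, n = pathway_counts(c1, c2)
        os, on = oracle_pathways(c1, c2)
        assert s == pytest.approx(os), (c1, c2)
        assert n == pytest.approx(on), (c1, c2)


def test_symmetry_and_site_conservation():
    rng = random.Random(7)
    cods1 = [rng.choice(SENSE_CODONS) for _ in range(60)]
    cods2 = list(cods1)
    for i in rng.sample(range(60), 12):  # perturb a fifth of the codons
        cods2[i] = rng.choice(SENSE_CODONS)
    aln = CodonAlignment(["a", "b"], ["".join(cods1), "".join(cods2)])
    d12 = ng86_divergence(aln, (0, 1))
    d21 = ng86_divergence(aln, (1, 0))
    assert d12.S + d12.N == pytest.approx(3 * 60, abs=1e-9)
    assert d12.dS == pytest.approx(d21.dS)
    assert d12.dN == pytest.approx(d21.dN)
    assert d12.Sd == pytest.approx(d21.Sd)


def test_jukes_cantor_small_p_limit():
    # at pS = 1e-4 the correction is within 1e-3 relative of identity
    aln = CodonAlignment(["a", "b"], ["GGT" * 10000, "GGT" * 9999 + "GGC"])
    d = ng86_divergence(aln)
    assert d.pS == pytest.approx(1e-4)
    assert d.dS / d.pS == pytest.approx(1.0, rel=1e-3)


def test_saturation_raises():
    with pytest.raises(ValueError, match="3/4"):
        molevo._jukes_cantor(0.76, "synonymous")


def test_dS_lower_bounds_pS():
    seq1 = "GGT" * 10 + "AAA" * 20
    seq2 = "GGC" * 5 + "GGT" * 5 + "AAA" * 10 + "AAT" * 10
    aln = CodonAlignment(["a", "b"], [seq1, seq2])
    d = ng86_divergence(aln)
    assert d.Sd == pytest.approx(5.0) and d.Nd == pytest.approx(10.0)
    assert d.dS >= d.pS
    assert d.dN >= d.pN


def test_no_gap_free_columns_raises():
    aln = CodonAlignment(["a", "b"], ["---", "ATG"])
    with pytest.raises(ValueError, match="gap-free"):
        ng86_divergence(aln)


# ---------------------------------------------------------------------------
# codon alignment


def test_align_identical_gap_free():
    cds = "ATGGCTGGTAAACCT"
    aln = codon_align([cds, cds])
    assert aln.seqs[0] == aln.seqs[1] == cds
    assert "-" not in aln.seqs[0]


def test_align_single_codon_deletion():
    cds = "ATGGCTTGGAAGCCTATTGAGCGT"
    deleted = cds[:9] + cds[12:]  # drop codon 4 (AAG)
    aln = codon_align([cds, deleted])
    assert aln.seqs[0] == cds
    assert aln.seqs[1].count("-") == 3
    gap_at = aln.seqs[1].index("-")
    assert gap_at % 3 == 0
    assert aln.seqs[1] == deleted[:gap_at] + "---" + deleted[gap_at:]


def test_align_frame_break_raises():
    with pytest.raises(ValueError, match="divisible by 3"):
        codon_align(["ATGGC", "ATGGCT"])


def test_align_internal_stop_raises():
    with pytest.raises(ValueError, match="stop"):
        codon_align(["ATGTAAGCT", "ATGGCTGCT"])


def test_align_three_sequences():
    cds = "ATGGCTTGGAAGCCTATTGAGCGT"
    aln = codon_align([cds, cds[:9] + cds[12:], cds], names=["x", "y", "out"])
    assert len(aln.seqs) == 3
    assert len({len(s) for s in aln.seqs}) == 1
    assert aln.seqs[0] == aln.seqs[2]


# ---------------------------------------------------------------------------
# relative-rate test


def test_lineage_replacements_examples():
    out = "AAAAAAAA"
    seq2 = "AAAAWWWW"
    assert lineage_replacements(out, seq2, out) == (0, 4)
    # column pattern (A, B, B) with outgroup third counts toward m1
    assert lineage_replacements("A", "B", "B") == (1, 0)
    assert lineage_replacements(out, out, out) == (0, 0)


def test_lineage_replacements_skips_triple_diff_and_gaps():
    assert lineage_replacements("A", "B", "C") == (0, 0)
    assert lineage_replacements("A-", "B-", "BB") == (1, 0)


def test_tajima_printed_counts():
    r = tajima_rrt(12, 3)
    assert r.chi_square == pytest.approx(5.4)
    assert round(r.p_value, 2) == 0.02


def test_tajima_symmetric_cases():
    r = tajima_rrt(5, 5)
    assert r.chi_square == 0
    assert r.p_value == 1.0
    assert tajima_rrt(3, 12).p_value == pytest.approx(tajima_rrt(12, 3).p_value)


def test_tajima_zero_counts_flagged():
    r = tajima_rrt(0, 0)
    assert r.chi_square == 0 and r.p_value == 1.0 and not r.informative


def test_tajima_p_monotone_in_asymmetry():
    total = 20
    ps = [tajima_rrt(total // 2 + d, total // 2 - d).p_value for d in range(0, 10)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# dating


def test_divergence_time_printed_values():
    dt = divergence_time(0.18, 7.31e-9, 1.5)
    assert round(dt.T_generations / 1e6) == 12
    assert round(dt.T_years / 1e6) == 18


def test_divergence_time_arithmetic():
    dt = divergence_time(0.1, 1e-8, 2.0)
    assert dt.T_generations == pytest.approx(5.0e6)
    assert dt.T_years / dt.T_generations == pytest.approx(2.0)
    zero = divergence_time(0.0)
    assert zero.T_generations == 0 and zero.T_years == 0


def test_divergence_time_bad_mu():
    with pytest.raises(ValueError):
        divergence_time(0.1, mu=0)
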