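import dataclasses
import io

import numpy as np
import pytest

from ydelseek import molevo
from ydelseek._seq import revcomp, translate
from ydelseek.readkit import write_fastq_pairs
from ydelseek.synthdata import (
    BranchParams,
    CrossConfig,
    GSF_PRESET,
    QualityModel,
    SimConfig,
    evolve_branch,
    evolve_gametolog_trio,
    random_cds,
    simulate_cross,
    simulate_expression_reads,
    simulate_reads,
    simulate_system,
)
from ydelseek.synthdata.config import substream
from ydelseek.synthdata.genomes import read_truth_bed, write_truth_bed


def kmers_both_strands(seq, k=35):
    out = set()
    for s in (seq, revcomp(seq)):
        for i in range(len(s) - k + 1):
            out.add(s[i : i + k])
    return out


# ---------------------------------------------------------------------------
# simulate_system


def test_determinism_byte_identical(small_config):
    g1 = simulate_system(small_config)
    g2 = simulate_system(small_config)
    assert g1.haplotypes == g2.haplotypes
    assert g1.truth == g2.truth
    assert g1.cds == g2.cds


def test_sex_chromosome_structure(small_genome):
    hap = small_genome.haplotypes
    female_chroms = [c for c, _ in hap["female"]]
    male_chroms = [c for c, _ in hap["male"]]
    assert sum(c.startswith("chrX") for c in female_chroms) == 2
    assert not any(c.startswith("chrY") for c in female_chroms)
    assert sum(c.startswith("chrX") for c in male_chroms) == 1
    assert sum(c.startswith("chrY") for c in male_chroms) == 1


def test_mutant_is_male_minus_deletions(small_genome, small_config):
    male_y = dict(small_genome.haplotypes["male"])["chrY"]
    off = small_config.y_shared_length
    for mutant in small_config.mutant_ids:
        intervals = sorted(
            (off + s, off + e)
            for m, s, e in small_config.deletion_intervals
            if m == mutant
        )
        expected = ""
        pos = 0
        for s, e in intervals:
            expected += male_y[pos:s]
            pos = e
        expected += male_y[pos:]
        assert dict(small_genome.haplotypes[mutant])["chrY"] == expected


def test_focal_gene_absent_from_mutants(small_genome, small_config):
    male_y = dict(small_genome.haplotypes["male"])["chrY"]
    off = small_config.y_shared_length
    fg = small_config.focal_gene
    focal_region = male_y[off + fg.start : off + fg.end]
    focal_kmers = kmers_both_strands(focal_region)
    for mutant in small_config.mutant_ids:
        mut_y = dict(small_genome.haplotypes[mutant])["chrY"]
        assert not (focal_kmers & kmers_both_strands(mut_y))
    # but present in the male
    assert focal_region in male_y


def test_focal_gene_is_valid_cds(small_genome):
    y_cds = small_genome.cds["y"]
    aa = translate(y_cds)
    assert aa.startswith("M")
    assert "*" not in aa


def test_degenerate_no_y_specific():
    config = SimConfig(
        seed=1,
        autosome_length=12_000,
        x_length=11_000,
        y_shared_length=0,
        y_specific_length=0,
        deletion_intervals=[],
    )
    genome = simulate_system(config)
    male = dict(genome.haplotypes["male"])
    female = dict(genome.haplotypes["female"])
    assert "chrY" not in male
    assert male["chrX"] == female["chrX_1"]
    assert male["chrA_1"] == female["chrA_1"]


def test_invalid_deletion_interval_rejected():
    with pytest.raises(ValueError, match="outside"):
        SimConfig(deletion_intervals=[("m1", -5, 100)]).validate()


def test_mutant_missing_focal_coverage_rejected():
    cfg = SimConfig(deletion_intervals=[("R025", 0, 1000), ("EGP14", 5000, 12000)])
    with pytest.raises(ValueError, match="focal"):
        cfg.validate()


def test_deletion_kmer_soundness(small_genome, small_config):
    """Every male-Y k-mer missing from a mutant overlaps a deleted interval;
    every mutant k-mer is a male k-mer or spans a deletion junction."""
    k = 35
    male_y = dict(small_genome.haplotypes["male"])["chrY"]
    off = small_config.y_shared_length
    mutant = small_config.mutant_ids[0]
    intervals = sorted(
        (off + s, off + e) for m, s, e in small_config.deletion_intervals if m == mutant
    )
    mut_y = dict(small_genome.haplotypes[mutant])["chrY"]
    male_k = kmers_both_strands(male_y, k)
    mut_k = kmers_both_strands(mut_y, k)

    deleted_windows = set()
    for i in range(len(male_y) - k + 1):
        if any(i < e and s < i + k for s, e in intervals):
            w = male_y[i : i + k]
            deleted_windows.add(w)
            deleted_windows.add(revcomp(w))
    missing = male_k - mut_k
    assert missing <= deleted_windows

    # junction positions in mutant coordinates
    junctions = []
    removed = 0
    for s, e in intervals:
        junctions.append(s - removed)
        removed += e - s
    extra = mut_k - male_k
    junction_windows = set()
    for j in junctions:
        lo, hi = max(0, j - k + 1), min(len(mut_y) - k + 1, j + 1)
        for i in range(lo, hi):
            w = mut_y[i : i + k]
            junction_windows.add(w)
            junction_windows.add(revcomp(w))
    assert extra <= junction_windows


def test_truth_bed_round_trip(small_genome, tmp_path):
    path = tmp_path / "truth.bed"
    write_truth_bed(small_genome, path)
    back = read_truth_bed(path)
    assert back == small_genome.truth
    for f in small_genome.truth:
        chroms = dict(small_genome.haplotypes[f.individual])
        assert 0 <= f.start < f.end <= len(chroms[f.chrom])


# ---------------------------------------------------------------------------
# codon evolution


def test_zero_divergence_identity():
    anc = random_cds(50, np.random.default_rng(0))
    zero = {n: BranchParams(0.0, 0.0) for n in ("x", "y", "outgroup")}
    x, y, out = evolve_gametolog_trio(anc, zero, seed=1)
    assert x == y == out == anc


def test_omega_zero_preserves_protein():
    anc = random_cds(200, np.random.default_rng(1))
    evolved = evolve_branch(anc, BranchParams(0.1, 0.0), substream(5, 1))
    assert translate(evolved) == translate(anc)
    assert evolved != anc  # synonymous changes did land


def test_no_stops_introduced():
    anc = random_cds(300, np.random.default_rng(2))
    for seed in range(3):
        x, y, out = evolve_gametolog_trio(anc, GSF_PRESET, seed)
        for s in (x, y, out):
            assert "*" not in translate(s)


def test_excessive_target_rejected():
    with pytest.raises(ValueError, match="Jukes-Cantor"):
        BranchParams(2.5, 0.1)


def test_preset_ds_recovery_small():
    # quick 3-seed sanity check; the full 10-seed acceptance check lives in
    # tests/test_acceptance.py
    values = []
    for seed in (1, 2, 3):
        anc = random_cds(3000, np.random.default_rng(1000 + seed))
        x, y, _ = evolve_gametolog_trio(anc, GSF_PRESET, seed)
        aln = molevo.CodonAlignment(["x", "y"], [x, y])
        values.append(molevo.ng86_divergence(aln).dS)
    assert np.mean(values) == pytest.approx(0.18, abs=0.03)


# ---------------------------------------------------------------------------
# read simulation


def test_error_free_reads_are_substrings():
    rng = np.random.default_rng(3)
    genome = [("chr1", "".join(rng.choice(list("ACGT"), 1000)))]
    pairs = simulate_reads(genome, "ind", coverage=30, read_length=100, error_rate=0.0, seed=7)
    seq = genome[0][1]
    for p in pairs:
        for mate in (p.mate1, p.mate2):
            assert mate.seq in seq or revcomp(mate.seq) in seq


def test_pair_count_expectation():
    rng = np.random.default_rng(4)
    genome = [("chr1", "".join(rng.choice(list("ACGT"), 5000)))]
    expected = 30 * 5000 / (2 * 100)
    counts = [
        len(simulate_reads(genome, "i", coverage=30, read_length=100, seed=s))
        for s in range(20)
    ]
    mean = np.mean(counts)
    se = np.sqrt(expected / 20)  # Poisson
    assert abs(mean - expected) < 3 * se


def test_read_simulation_deterministic(tmp_path):
    genome = [("chr1", "ACGT" * 300)]
    buf1, buf2 = [], []
    for sub in (buf1, buf2):
        pairs = simulate_reads(genome, "i", coverage=10, read_length=50, error_rate=0.01, seed=11)
        r1, r2 = tmp_path / "a1.fastq", tmp_path / "a2.fastq"
        write_fastq_pairs(pairs, r1, r2)
        sub.append(r1.read_bytes())
        sub.append(r2.read_bytes())
    assert buf1 == buf2


def test_read_length_exceeds_chromosome():
    with pytest.raises(ValueError, match="read_length"):
        simulate_reads([("c", "ACGT" * 10)], "i", coverage=5, read_length=100)


def test_error_rate_flips_bases():
    genome = [("chr1", "A" * 2000)]
    pairs = simulate_reads(genome, "i", coverage=20, read_length=100, error_rate=0.1, seed=2)
    mismatches = sum(
        sum(1 for c in m.seq if c != "A") for p in pairs for m in (p.mate1, p.mate2)
    )
    total = sum(len(m.seq) for p in pairs for m in (p.mate1, p.mate2))
    # revcomp of poly-A is poly-T; count non-A on the A-strand reads only
    rate = mismatches / total
    assert 0.0 < rate


def test_quality_tails():
    genome = [("chr1", "ACGT" * 100)]
    qm = QualityModel(mean_q=35, tail_len=5, tail_q=2)
    pairs = simulate_reads(genome, "i", coverage=5, read_length=50, quality_model=qm, seed=1)
    m = pairs[0].mate1
    assert m.qual[-5:] == (2,) * 5
    assert m.qual[0] == 35


def test_read_names_encode_truth():
    genome = [("chrZ", "ACGT" * 100)]
    pairs = simulate_reads(genome, "indiv7", coverage=5, read_length=50, seed=1)
    for p in pairs:
        indiv, chrom, start, end, _ = p.id.split("|")
        assert indiv == "indiv7" and chrom == "chrZ"
        assert 0 <= int(start) < int(end) <= 400


# ---------------------------------------------------------------------------
# expression reads


def test_focal_reads_only_in_male():
    features = {"focal": "ACGT" * 50, "other": "TTGGCCAA" * 25}
    design = {"male": {"focal": 10.0, "other": 5.0}, "female": {"focal": 0.0, "other": 5.0}}
    sets = simulate_expression_reads(features, design, n_reads=500, read_length=50, seed=5)
    assert not any("focal" in rid for rid, _ in sets["female"])
    assert any("focal" in rid for rid, _ in sets["male"])


def test_abundance_ratio_three_to_one():
    features = {"a": "ACGT" * 100, "b": "TGCA" * 100}
    design = {"s": {"a": 3.0, "b": 1.0}}
    counts_a = 0
    total = 0
    for seed in range(5):
        sets = simulate_expression_reads(features, design, n_reads=2000, read_length=50, seed=seed)
        for rid, _ in sets["s"]:
            counts_a += rid.split("|")[1] == "a"
            total += 1
    p = counts_a / total
    se = np.sqrt(0.75 * 0.25 / total)
    assert abs(p - 0.75) < 4 * se


def test_zero_reads_valid_empty():
    sets = simulate_expression_reads({"a": "ACGT" * 20}, {"s": {"a": 1.0}}, 0, 50, seed=1)
    assert sets["s"] == []


def test_all_zero_abundance_errors():
    with pytest.raises(ValueError, match="no expressed"):
        simulate_expression_reads({"a": "ACGT" * 20}, {"s": {"a": 0.0}}, 10, 50, seed=1)


# ---------------------------------------------------------------------------
# cross simulation


def test_cross_family_size_default():
    cross = simulate_cross(CrossConfig(), seed=1)
    assert len(cross.sons) == 4
    assert len(cross.daughters) == 6
    assert len(cross.sites) == 50


def test_cross_x_site_rules():
    cross = simulate_cross(CrossConfig(n_sites=200), seed=2)
    for site in cross.sites:
        if site.truth_class != "X":
            continue
        maternal = set(site.mother)
        assert len(site.father) == 1
        for indiv, geno in site.offspring.items():
            if cross.sexes[indiv] == "M":
                assert len(geno) == 1 and geno[0] in maternal
            else:
                assert site.father[0] in geno
                assert set(geno) <= maternal | set(site.father)


def test_cross_autosomal_mendelian():
    cross = simulate_cross(CrossConfig(n_sites=200), seed=3)
    for site in cross.sites:
        if site.truth_class != "A":
            continue
        for geno in site.offspring.values():
            assert len(geno) == 2
            assert geno[0] in site.mother or geno[0] in site.father
            assert geno[1] in site.mother or geno[1] in site.father


def test_cross_deterministic():
    c1 = simulate_cross(CrossConfig(), seed=9)
    c2 = simulate_cross(CrossConfig(), seed=9)
    assert c1.sites == c2.sites and c1.sexes == c2.sexes
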