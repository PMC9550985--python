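"""Genome construction: inbred background, X/Y haplotypes, deletion mutants.

Individuals carry explicit haplotype sequences. The female is two X and no
Y; the male one X and one Y whose Y-specific tail holds the focal gene, a
planted transposable-element copy and a broadly transcribed fragment; each
deletion mutant equals the male with its stated interval(s) excised from
the Y-specific region. Feature placements are tracked as 0-based half-open
truth intervals (BED on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._seq import BASES
from .codonsim import evolve_gametolog_trio, random_cds
from .config import SimConfig, substream

__all__ = [
    "PlacedFeature",
    "GenomeSet",
    "simulate_system",
    "write_genome_fasta",
    "write_truth_bed",
    "read_truth_bed",
]

# fixed in-region placements of the planted non-focal features, relative to
# the start of the Y-specific region (all inside the default deletion
# overlap so every mutant loses them)
_TE_OFFSET = 7_000
_TE_LENGTH = 300
_BROAD_OFFSET = 8_000
_BROAD_LENGTH = 400
_AUTO_GENE_OFFSET = 10_000
_AUTO_GENE_LENGTH = 500
_X_GENE_OFFSET = 9_000


@dataclass(frozen=True)
class PlacedFeature:
    feature_id: str
    individual: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"


@dataclass
class GenomeSet:
    haplotypes: dict  # individual -> list[(chrom name, sequence)]
    truth: list  # list[PlacedFeature]
    transcripts: dict = field(default_factory=dict)  # feature -> sequence
    te_library: dict = field(default_factory=dict)
    cds: dict = field(default_factory=dict)  # x / y / outgroup focal CDS
    config: SimConfig | None = None

    def individual(self, individual_id: str) -> list:
        return self.haplotypes[individual_id]

    def genome_size(self, individual_id: str) -> int:
        return sum(len(seq) for _, seq in self.haplotypes[individual_id])


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _overwrite(seq: str, start: int, insert: str) -> str:
    if start + len(insert) > len(seq):
        raise ValueError("insert exceeds sequence bounds")
    return seq[:start] + insert + seq[start + len(insert) :]


def _excise(seq: str, intervals: list[tuple[int, int]]) -> str:
    kept = []
    pos = 0
    for start, end in sorted(intervals):
        start, end = max(start, pos), max(end, pos)
        kept.append(seq[pos:start])
        pos = end
    kept.append(seq[pos:])
    return "".join(kept)


def _shift_features(
    features: list[PlacedFeature], intervals: list[tuple[int, int]], individual: str
) -> list[PlacedFeature]:
    """Drop features overlapping a deleted interval; shift the rest left."""
    out = []
    merged = sorted(intervals)
    for f in features:
        if any(f.start < e and s < f.end for s, e in merged):
            continue
        shift = sum(e - s for s, e in merged if e <= f.start)
        out.append(
            PlacedFeature(f.feature_id, individual, f.chrom, f.start - shift, f.end - shift, f.strand)
        )
    return out


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        old = arr[i].decode()
        alts = [b for b in BASES if b != old]
        arr[i] = alts[int(rng.integers(0, 3))].encode()
    return arr.tobytes().decode()


def simulate_system(config: SimConfig) -> GenomeSet:
    """Build the full genome set (male, female, deletion mutants) plus
    transcripts, TE library and focal gametolog CDS, deterministically from
    ``config.seed``."""
    config.validate()
    seed = config.seed
    rng_bg = substream(seed, 1)

    autosome = _random_seq(config.autosome_length, rng_bg)
    x_chrom = _random_seq(config.x_length, substream(seed, 2))
    y_shared = _random_seq(config.y_shared_length, substream(seed, 3))
    y_specific = _random_seq(config.y_specific_length, substream(seed, 4))

    # focal gametolog trio
    fg = config.focal_gene
    ancestor = random_cds(fg.n_codons, substream(seed, 5), start_codon=True)
    x_cds, y_cds, out_cds = evolve_gametolog_trio(ancestor, config.gsf_preset, seed)

    te_seq = _random_seq(_TE_LENGTH, substream(seed, 6))

    features: list[PlacedFeature] = []
    transcripts: dict[str, str] = {}

    if config.y_specific_length:
        y_specific = _overwrite(y_specific, fg.start, y_cds)
        y_specific = _overwrite(y_specific, _TE_OFFSET, te_seq)
        broad_seq = y_specific[_BROAD_OFFSET : _BROAD_OFFSET + _BROAD_LENGTH]
        transcripts["focal_y"] = y_cds
        transcripts["te_frag"] = te_seq
        transcripts["ydel_broad"] = broad_seq
    if config.x_length >= _X_GENE_OFFSET + len(x_cds):
        x_chrom = _overwrite(x_chrom, _X_GENE_OFFSET, x_cds)
    auto_gene = autosome[_AUTO_GENE_OFFSET : _AUTO_GENE_OFFSET + _AUTO_GENE_LENGTH]
    transcripts["auto_gene"] = auto_gene

    y_chrom = y_shared + y_specific
    het = config.heterozygosity
    auto2 = _mutate(autosome, het, substream(seed, 7))
    x2 = _mutate(x_chrom, het, substream(seed, 8))

    male_haps = [("chrA_1", autosome), ("chrA_2", auto2), ("chrX", x_chrom)]
    if y_chrom:
        male_haps.append(("chrY", y_chrom))
    haplotypes = {
        "male": male_haps,
        "female": [
            ("chrA_1", autosome),
            ("chrA_2", auto2),
            ("chrX_1", x_chrom),
            ("chrX_2", x2),
        ],
    }

    def male_y_features() -> list[PlacedFeature]:
        off = config.y_shared_length
        feats = []
        if config.y_specific_length:
            feats = [
                PlacedFeature("focal_y", "male", "chrY", off + fg.start, off + fg.end),
                PlacedFeature("te_frag", "male", "chrY", off + _TE_OFFSET, off + _TE_OFFSET + _TE_LENGTH),
                PlacedFeature("ydel_broad", "male", "chrY", off + _BROAD_OFFSET, off + _BROAD_OFFSET + _BROAD_LENGTH),
                PlacedFeature("y_specific_region", "male", "chrY", off, off + config.y_specific_length),
            ]
        return feats

    features.extend(male_y_features())
    for indiv in ("male", "female"):
        features.append(
            PlacedFeature("auto_gene", indiv, "chrA_1", _AUTO_GENE_OFFSET, _AUTO_GENE_OFFSET + _AUTO_GENE_LENGTH)
        )
        xname = "chrX" if indiv == "male" else "chrX_1"
        if config.x_length >= _X_GENE_OFFSET + len(x_cds):
            features.append(
                PlacedFeature("focal_x", indiv, xname, _X_GENE_OFFSET, _X_GENE_OFFSET + len(x_cds))
            )

    # deletion mutants: male genome minus excised Y intervals
    off = config.y_shared_length
    for mutant in config.mutant_ids:
        intervals = [
            (off + s, off + e)
            for m, s, e in config.deletion_intervals
            if m == mutant
        ]
        y_del = _excise(y_chrom, intervals)
        haplotypes[mutant] = [
            ("chrA_1", autosome),
            ("chrA_2", auto2),
            ("chrX", x_chrom),
            ("chrY", y_del),
        ]
        y_feats = [f for f in features if f.individual == "male" and f.chrom == "chrY"]
        features.extend(_shift_features(y_feats, intervals, mutant))
        features.append(
            PlacedFeature("auto_gene", mutant, "chrA_1", _AUTO_GENE_OFFSET, _AUTO_GENE_OFFSET + _AUTO_GENE_LENGTH)
        )

    return GenomeSet(
        haplotypes=haplotypes,
        truth=features,
        transcripts=transcripts,
        te_library={"te_consensus": te_seq},
        cds={"x": x_cds, "y": y_cds, "outgroup": out_cds, "ancestor": ancestor},
        config=config,
    )


# ---------------------------------------------------------------------------
# writers / readers


def write_genome_fasta(genome: GenomeSet, individual: str, path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.haplotypes[individual]:
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_truth_bed(genome: GenomeSet, path) -> None:
    with open(path, "w") as fh:
        for f in genome.truth:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\t{f.individual}\n"
            )


def read_truth_bed(path) -> list[PlacedFeature]:
    out = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, fid, _score, strand, indiv = line.rstrip("\n").split("\t")
            out.append(PlacedFeature(fid, indiv, chrom, int(start), int(end), strand))
    return out
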