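"""Paired-end genomic read simulation and expression read simulation.

Read names encode their origin (individual|chromosome|fragment interval) so
downstream stages can be scored against truth. Sequencing errors are
uniform single-base flips; qualities follow a constant-mean model with
optional degraded head/tail segments to exercise the trimmer.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .._seq import BASES, revcomp
from ..readkit import Mate, ReadPair
from .config import QualityModel, SimConfig, substream
from .genomes import GenomeSet

__all__ = [
    "simulate_reads",
    "simulate_reads_for_genome_set",
    "simulate_expression_reads",
]


def _qualities(n: int, model: QualityModel, rng: np.random.Generator) -> tuple[int, ...]:
    if model.noise_sd > 0:
        q = np.clip(np.rint(rng.normal(model.mean_q, model.noise_sd, size=n)), 2, 93)
        quals = q.astype(int)
    else:
        quals = np.full(n, model.mean_q, dtype=int)
    if model.head_len:
        quals[: model.head_len] = model.tail_q
    if model.tail_len:
        quals[len(quals) - model.tail_len :] = model.tail_q
    return tuple(int(v) for v in quals)


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if not len(hits):
        return seq
    chars = list(seq)
    for i in hits:
        alts = [b for b in BASES if b != chars[i]]
        chars[i] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_reads(
    haplotypes,
    individual_id: str,
    coverage: float,
    read_length: int,
    error_rate: float = 0.0,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    quality_model: QualityModel = QualityModel(),
    seed: int = 0,
) -> list[ReadPair]:
    """Simulate paired-end reads over a list of (chromosome, sequence).

    Pair counts per chromosome are Poisson around
    coverage * length / (2 * read_length); fragments are uniform with a
    truncated-normal insert, sampled from either strand.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    pairs: list[ReadPair] = []
    for chrom, seq in haplotypes:
        length = len(seq)
        if read_length > length:
            raise ValueError(
                f"read_length {read_length} exceeds {chrom} length {length}"
            )
        n_pairs = int(rng.poisson(coverage * length / (2.0 * read_length)))
        for i in range(n_pairs):
            insert = int(round(rng.normal(insert_mean, insert_sd)))
            insert = max(read_length, min(insert, length))
            start = int(rng.integers(0, length - insert + 1))
            frag = seq[start : start + insert]
            fwd = frag[:read_length]
            rev = revcomp(frag[-read_length:])
            if rng.random() < 0.5:  # fragment drawn from the minus strand
                fwd, rev = revcomp(frag[-read_length:]), frag[:read_length]
            rid = f"{individual_id}|{chrom}|{start}|{start + insert}|{i}"
            m1 = Mate(_apply_errors(fwd, error_rate, rng), _qualities(read_length, quality_model, rng))
            m2 = Mate(_apply_errors(rev, error_rate, rng), _qualities(read_length, quality_model, rng))
            pairs.append(ReadPair(rid, m1, m2))
    return pairs


def simulate_reads_for_genome_set(
    genome: GenomeSet, config: SimConfig | None = None
) -> dict[str, list[ReadPair]]:
    """Genomic read sets for every individual, on derived RNG substreams."""
    config = config or genome.config
    if config is None:
        raise ValueError("no simulation config available")
    out = {}
    for idx, individual in enumerate(sorted(genome.haplotypes)):
        out[individual] = simulate_reads(
            genome.haplotypes[individual],
            individual,
            coverage=config.coverage,
            read_length=config.read_length,
            error_rate=config.error_rate,
            insert_mean=config.insert_mean,
            insert_sd=config.insert_sd,
            quality_model=config.quality_model,
            seed=substream(config.seed, 20, idx),
        )
    return out


def simulate_expression_reads(
    features: Mapping[str, str],
    design: Mapping[str, Mapping[str, float]],
    n_reads: int,
    read_length: int,
    seed: int = 0,
    error_rate: float = 0.0,
    mean_q: int = 35,
) -> dict[str, list[tuple[str, Mate]]]:
    """Single-end expression read sets per sample.

    Reads are drawn from features with probability proportional to
    abundance x feature length; zero-abundance features yield no reads.
    """
    if not features:
        raise ValueError("no features to express")
    out: dict[str, list[tuple[str, Mate]]] = {}
    for s_idx, (sample, abundances) in enumerate(sorted(design.items())):
        rng = substream(seed, 30, s_idx) if isinstance(seed, int) else seed
        names = [f for f in abundances if abundances[f] > 0]
        if any(abundances[f] < 0 for f in abundances):
            raise ValueError(f"negative abundance in sample {sample!r}")
        weights = np.array([abundances[f] * len(features[f]) for f in names], dtype=float)
        if not names or weights.sum() <= 0:
            raise ValueError(f"sample {sample!r} has no expressed features")
        probs = weights / weights.sum()
        reads: list[tuple[str, Mate]] = []
        if n_reads:
            choices = rng.choice(len(names), size=n_reads, p=probs)
            for i, fi in enumerate(choices):
                fname = names[int(fi)]
                fseq = features[fname]
                span = min(read_length, len(fseq))
                start = int(rng.integers(0, len(fseq) - span + 1))
                seq = fseq[start : start + span]
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                seq = _apply_errors(seq, error_rate, rng)
                qual = tuple([mean_q] * span)
                reads.append((f"{sample}|{fname}|{start}|{start + span}|{i}", Mate(seq, qual)))
        out[sample] = reads
    return out
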