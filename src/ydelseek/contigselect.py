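"""Pseudo-mapping of genotype reads onto candidate contigs and the
coverage-ratio filter that defines the deleted-Y assembly.

The mapper is a deterministic seed-and-extend stand-in for a full aligner:
a read maps to a contig when a seed k-mer (default 21) matches and ungapped
extension reaches >= 90% identity over >= 90% of the read. A pair counts
once, to the contig(s) of its best mate hit; ties are split equally as
fractional counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import revcomp
from .readkit import ReadPair
from .ydelscan import Contig

__all__ = [
    "ContigCountMatrix",
    "RatioFilterParams",
    "PseudoMapper",
    "count_mapped_reads",
    "normalize_counts",
    "select_ydel_contigs",
]

SEED_K = 21
MIN_IDENTITY = 0.90
MIN_COVERAGE = 0.90


@dataclass
class ContigCountMatrix:
    counts: pd.DataFrame  # contigs x samples, fractional mapped-pair counts
    library_sizes: dict[str, float]  # sample -> total read pairs in library
    normalized: bool = False
    unmapped: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class RatioFilterParams:
    female_ratio_max: float = 0.20
    mutant_ratio_max: float = 0.40

    def __post_init__(self) -> None:
        for v in (self.female_ratio_max, self.mutant_ratio_max):
            if not 0 < v <= 1:
                raise ValueError("ratio thresholds must lie in (0, 1]")


class PseudoMapper:
    """Seed-and-extend ungapped read-to-contig mapper."""

    def __init__(
        self,
        contigs: Sequence[Contig],
        seed_k: int = SEED_K,
        min_identity: float = MIN_IDENTITY,
        min_coverage: float = MIN_COVERAGE,
    ):
        if not contigs:
            raise ValueError("no contigs to map against")
        self.contigs = list(contigs)
        self.seed_k = seed_k
        self.min_identity = min_identity
        self.min_coverage = min_coverage
        self._index: dict[str, list[tuple[int, int]]] = {}
        for ci, contig in enumerate(self.contigs):
            seq = contig.sequence
            for i in range(len(seq) - seed_k + 1):
                self._index.setdefault(seq[i : i + seed_k], []).append((ci, i))

    def _seed_positions(self, n: int) -> list[int]:
        k = self.seed_k
        if n < k:
            return []
        positions = list(range(0, n - k + 1, max(1, k // 2)))
        if positions[-1] != n - k:
            positions.append(n - k)
        return positions

    def best_hits(self, read: str) -> tuple[dict[int, int], int]:
        """Best-scoring contigs for a read.

        Returns ({contig index: matches}, best score); only contigs tied at
        the best score are included, and only if the alignment clears the
        identity and coverage thresholds.
        """
        read = read.upper()
        n = len(read)
        best: dict[int, int] = {}
        best_score = 0
        for oriented in (read, revcomp(read)):
            tried: set[tuple[int, int]] = set()
            for pos in self._seed_positions(n):
                seed = oriented[pos : pos + self.seed_k]
                for ci, cpos in self._index.get(seed, ()):
                    offset = cpos - pos
                    key = (ci, offset)
                    if key in tried:
                        continue
                    tried.add(key)
                    contig_seq = self.contigs[ci].sequence
                    lo = max(0, offset)
                    hi = min(len(contig_seq), offset + n)
                    overlap = hi - lo
                    if overlap < self.min_coverage * n:
                        continue
                    matches = sum(
                        1
                        for i in range(lo, hi)
                        if contig_seq[i] == oriented[i - offset]
                    )
                    if matches < self.min_identity * overlap:
                        continue
                    if matches > best_score:
                        best = {ci: matches}
                        best_score = matches
                    elif matches == best_score and matches > 0:
                        prev = best.get(ci, 0)
                        best[ci] = max(prev, matches)
        return best, best_score

    def map_pair(self, pair: ReadPair) -> set[int]:
        """Contigs receiving this pair's (split) count; empty if unmapped."""
        h1, s1 = self.best_hits(pair.mate1.seq)
        h2, s2 = self.best_hits(pair.mate2.seq)
        if s1 == s2 == 0:
            return set()
        if s1 >= s2:
            return set(h1)
        return set(h2)

    def map_read(self, seq: str) -> set[int]:
        hits, score = self.best_hits(seq)
        return set(hits) if score > 0 else set()


def count_mapped_reads(
    reads_per_sample: Mapping[str, Iterable[ReadPair]],
    contigs: Sequence[Contig],
    mapper: PseudoMapper | None = None,
) -> ContigCountMatrix:
    """Pseudo-map each sample's pairs onto the contigs and tally counts."""
    mapper = mapper or PseudoMapper(contigs)
    ids = [c.id for c in mapper.contigs]
    columns: dict[str, list[float]] = {}
    library_sizes: dict[str, float] = {}
    unmapped: dict[str, int] = {}
    for sample, pairs in reads_per_sample.items():
        col = [0.0] * len(ids)
        n_pairs = 0
        n_unmapped = 0
        for pair in pairs:
            n_pairs += 1
            targets = mapper.map_pair(pair)
            if not targets:
                n_unmapped += 1
                continue
            share = 1.0 / len(targets)
            for ci in targets:
                col[ci] += share
        columns[sample] = col
        library_sizes[sample] = float(n_pairs)
        unmapped[sample] = n_unmapped
    frame = pd.DataFrame(columns, index=ids)
    return ContigCountMatrix(counts=frame, library_sizes=library_sizes, unmapped=unmapped)


def normalize_counts(matrix: ContigCountMatrix, male_sample: str = "male") -> ContigCountMatrix:
    """Scale each column by (male library size / sample library size)."""
    if male_sample not in matrix.library_sizes:
        raise ValueError(f"male sample {male_sample!r} not in matrix")
    male_lib = matrix.library_sizes[male_sample]
    scaled = matrix.counts.copy()
    for sample in scaled.columns:
        lib = matrix.library_sizes[sample]
        if lib <= 0:
            raise ValueError(f"sample {sample!r} has zero library size")
        scaled[sample] = scaled[sample] * (male_lib / lib)
    return ContigCountMatrix(
        counts=scaled,
        library_sizes=dict(matrix.library_sizes),
        normalized=True,
        unmapped=dict(matrix.unmapped),
    )


def select_ydel_contigs(
    matrix: ContigCountMatrix,
    params: RatioFilterParams = RatioFilterParams(),
    male_sample: str = "male",
    female_sample: str = "female",
    mutant_sample: str = "mutant",
) -> tuple[list[str], pd.DataFrame]:
    """Apply the female/male OR mutant/male coverage-ratio filter.

    Returns (selected contig ids, per-contig ratio report). Contigs with a
    zero male count are rejected and flagged.
    """
    if not matrix.normalized:
        raise ValueError("matrix must be normalized before ratio filtering")
    counts = matrix.counts
    rows = []
    selected = []
    for contig_id, row in counts.iterrows():
        male = row[male_sample]
        if male <= 0:
            rows.append((contig_id, male, float("nan"), float("nan"), False, "no_male_coverage"))
            continue
        f_ratio = row[female_sample] / male
        m_ratio = row[mutant_sample] / male
        keep = f_ratio < params.female_ratio_max or m_ratio < params.mutant_ratio_max
        rows.append((contig_id, male, f_ratio, m_ratio, keep, ""))
        if keep:
            selected.append(contig_id)
    report = pd.DataFrame(
        rows,
        columns=["contig", "male_count", "female_male_ratio", "mutant_male_ratio", "selected", "flag"],
    ).set_index("contig")
    return selected, report
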