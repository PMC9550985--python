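"""Expression-based candidate screen.

Pieces: an ungapped seed-and-extend local homology search with
Karlin–Altschul E-values (word 11, match +1 / mismatch -2, X-drop 20),
length-normalized expression quantification over fragments with equal-split
multi-mapping, a transposable-element exclusion filter, and the
male-specific-expression candidate rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import revcomp
from .contigselect import PseudoMapper
from .ydelscan import Contig

__all__ = [
    "HomologyHit",
    "ExpressionMatrix",
    "CandidateFilterParams",
    "ScoringParams",
    "local_homology_search",
    "quantify",
    "te_filter",
    "candidate_filter",
    "hits_to_table",
]


@dataclass(frozen=True)
class ScoringParams:
    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    xdrop: int = 20

    @property
    def karlin_lambda(self) -> float:
        return _solve_lambda(self.match, self.mismatch)

    @property
    def karlin_k(self) -> float:
        # tabulated ungapped K for the default +1/-2 scheme; other schemes
        # fall back to a conservative constant (E-values order-of-magnitude)
        return 0.621 if (self.match, self.mismatch) == (1, -2) else 0.3


def _solve_lambda(match: int, mismatch: int) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda s_ij) = 1 (uniform bases)."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    lo, hi = 1e-9, 10.0
    while f(hi) < 0:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class HomologyHit:
    query: str
    subject: str
    q_start: int  # half-open on the query plus strand
    q_end: int
    s_start: int  # half-open on the subject plus strand
    s_end: int
    strand: str  # '+' or '-'
    matches: int
    mismatches: int
    score: int
    bit_score: float
    evalue: float

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


def _extend(q: str, s: str, qpos: int, spos: int, word: int, p: ScoringParams):
    """Ungapped X-drop extension around an exact word match."""
    match, mismatch, xdrop = p.match, p.mismatch, p.xdrop
    score = word * match
    # right
    best = score
    best_right = 0
    i = 0
    while qpos + word + i < len(q) and spos + word + i < len(s):
        score += match if q[qpos + word + i] == s[spos + word + i] else mismatch
        i += 1
        if score > best:
            best, best_right = score, i
        elif best - score > xdrop:
            break
    score = best
    # left
    best_left = 0
    j = 0
    while qpos - j - 1 >= 0 and spos - j - 1 >= 0:
        score += match if q[qpos - j - 1] == s[spos - j - 1] else mismatch
        j += 1
        if score > best:
            best, best_left = score, j
        elif best - score > xdrop:
            break
    qs, qe = qpos - best_left, qpos + word + best_right
    matches = sum(1 for a, b in zip(q[qs:qe], s[spos - best_left : spos - best_left + (qe - qs)]) if a == b)
    return qs, qe, spos - best_left, best, matches


def local_homology_search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    evalue_max: float = 1e-7,
    scoring: ScoringParams = ScoringParams(),
) -> list[HomologyHit]:
    """Seed-and-extend ungapped search of each query against all subjects.

    Both query strands are searched; the best-scoring hit per
    (query, subject) pair with E-value <= ``evalue_max`` is returned,
    ordered by ascending E-value.
    """
    if not queries or not subjects:
        return []
    word = scoring.word_size
    lam, kk = scoring.karlin_lambda, scoring.karlin_k
    db_size = sum(len(s) for s in subjects.values())

    index: dict[str, list[tuple[str, int]]] = {}
    for sid, sseq in subjects.items():
        sseq = sseq.upper()
        for i in range(len(sseq) - word + 1):
            index.setdefault(sseq[i : i + word], []).append((sid, i))

    hits: dict[tuple[str, str], HomologyHit] = {}
    for qid, qseq in queries.items():
        qseq = qseq.upper()
        m = len(qseq)
        for strand, oriented in (("+", qseq), ("-", revcomp(qseq))):
            seen_diag: set[tuple[str, int]] = set()
            for qpos in range(len(oriented) - word + 1):
                for sid, spos in index.get(oriented[qpos : qpos + word], ()):
                    diag = (sid, spos - qpos)
                    if diag in seen_diag:
                        continue
                    seen_diag.add(diag)
                    sseq = subjects[sid].upper()
                    qs, qe, ss, score, matches = _extend(
                        oriented, sseq, qpos, spos, word, scoring
                    )
                    evalue = kk * m * db_size * math.exp(-lam * score)
                    if evalue > evalue_max:
                        continue
                    length = qe - qs
                    if strand == "-":
                        q_start, q_end = m - qe, m - qs
                    else:
                        q_start, q_end = qs, qe
                    hit = HomologyHit(
                        query=qid,
                        subject=sid,
                        q_start=q_start,
                        q_end=q_end,
                        s_start=ss,
                        s_end=ss + length,
                        strand=strand,
                        matches=matches,
                        mismatches=length - matches,
                        score=score,
                        bit_score=(lam * score - math.log(kk)) / math.log(2),
                        evalue=evalue,
                    )
                    key = (qid, sid)
                    if key not in hits or hit.score > hits[key].score:
                        hits[key] = hit
    return sorted(hits.values(), key=lambda h: (h.evalue, h.query, h.subject))


def hits_to_table(hits: Sequence[HomologyHit]) -> pd.DataFrame:
    """12-column tabular layout (1-based inclusive coordinates, as is
    conventional for tabular homology-search output)."""
    rows = []
    for h in hits:
        if h.strand == "+":
            s_start, s_end = h.s_start + 1, h.s_end
        else:
            s_start, s_end = h.s_end, h.s_start + 1
        rows.append(
            (
                h.query,
                h.subject,
                round(100.0 * h.identity, 2),
                h.length,
                h.mismatches,
                0,
                h.q_start + 1,
                h.q_end,
                s_start,
                s_end,
                h.evalue,
                round(h.bit_score, 1),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query", "subject", "pident", "length", "mismatches", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ],
    )


# ---------------------------------------------------------------------------
# quantification


@dataclass
class ExpressionMatrix:
    counts: pd.DataFrame  # fragments x samples, fractional read counts
    tpm: pd.DataFrame  # fragments x samples, transcripts-per-million
    lengths: dict[str, int]


def quantify(
    reads_per_sample: Mapping[str, Iterable[str]],
    fragments: Mapping[str, str],
    seed_k: int = 21,
) -> ExpressionMatrix:
    """Assign reads to fragments with the pseudo-mapper and compute TPM.

    Multi-mapping reads are split equally. Abundance is the
    length-normalized read rate rescaled per sample to sum to one million;
    a sample with zero assigned reads yields an all-zero column.
    """
    if not fragments:
        raise ValueError("no fragments to quantify against")
    frag_ids = list(fragments)
    contigs = [Contig(id=fid, sequence=str(seq).upper(), support=0) for fid, seq in fragments.items()]
    mapper = PseudoMapper(contigs, seed_k=seed_k)
    counts: dict[str, list[float]] = {}
    for sample, reads in reads_per_sample.items():
        col = [0.0] * len(frag_ids)
        for read in reads:
            seq = read if isinstance(read, str) else read.seq
            targets = mapper.map_read(seq)
            if not targets:
                continue
            share = 1.0 / len(targets)
            for ci in targets:
                col[ci] += share
        counts[sample] = col
    count_df = pd.DataFrame(counts, index=frag_ids)
    lengths = {fid: len(seq) for fid, seq in fragments.items()}
    rate = count_df.divide(
        pd.Series({fid: lengths[fid] / 1000.0 for fid in frag_ids}), axis=0
    )
    tpm = rate.copy()
    for sample in tpm.columns:
        total = rate[sample].sum()
        if total > 0:
            tpm[sample] = rate[sample] / total * 1e6
        else:
            warnings.warn(f"sample {sample!r}: no reads assigned to any fragment")
            tpm[sample] = 0.0
    return ExpressionMatrix(counts=count_df, tpm=tpm, lengths=lengths)


# ---------------------------------------------------------------------------
# filters


def te_filter(
    fragments: Mapping[str, str],
    te_library: Mapping[str, str],
    evalue_max: float = 1e-7,
    scoring: ScoringParams = ScoringParams(),
) -> tuple[dict[str, str], list[str]]:
    """Drop fragments with a homology hit to any TE library sequence.

    Returns (retained fragments, removed fragment ids). An empty library
    removes nothing.
    """
    if not te_library:
        return dict(fragments), []
    hits = local_homology_search(fragments, te_library, evalue_max, scoring)
    te_like = {h.query for h in hits}
    kept = {fid: seq for fid, seq in fragments.items() if fid not in te_like}
    return kept, sorted(te_like)


@dataclass(frozen=True)
class CandidateFilterParams:
    expressed_min: float = 1.0  # TPM at/above which a fragment is "expressed"
    silent_max: float = 0.1  # TPM below which a fragment is "not expressed"

    def __post_init__(self) -> None:
        if not self.silent_max < self.expressed_min:
            raise ValueError("silent_max must be below expressed_min")


def candidate_filter(
    matrix: ExpressionMatrix,
    male_sample: str,
    silent_samples: Sequence[str],
    params: CandidateFilterParams = CandidateFilterParams(),
) -> list[str]:
    """Fragments expressed in the male sample and silent in every other
    listed sample."""
    for name in [male_sample, *silent_samples]:
        if name not in matrix.tpm.columns:
            raise KeyError(f"sample {name!r} not present in expression matrix")
    out = []
    for fid, row in matrix.tpm.iterrows():
        if row[male_sample] < params.expressed_min:
            continue
        if all(row[s] < params.silent_max for s in silent_samples):
            out.append(fid)
    return out
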