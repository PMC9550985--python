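"""FASTQ I/O and quality trimming.

The trimmer reproduces a LEADING/TRAILING/SLIDINGWINDOW/MINLEN recipe:
leading and trailing bases below a per-base threshold are removed, the read
is cut at the start of the first sliding window whose mean quality falls
below the window threshold (followed by a second trailing pass), and reads
shorter than the minimum length are dropped. Pairs survive only if both
mates survive.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

__all__ = [
    "Mate",
    "ReadPair",
    "TrimParams",
    "TrimReport",
    "trim_read",
    "trim_pairs",
    "read_fastq",
    "write_fastq",
    "read_fastq_pairs",
    "write_fastq_pairs",
]

MAX_PHRED = 93


@dataclass(frozen=True)
class Mate:
    """One sequencing read: sequence plus per-base Phred qualities."""

    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("sequence and quality lengths differ")
        if self.qual and not all(0 <= q <= MAX_PHRED for q in self.qual):
            raise ValueError("Phred values must lie in [0, 93]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadPair:
    id: str
    mate1: Mate
    mate2: Mate


@dataclass(frozen=True)
class TrimParams:
    leading_q: int = 20
    trailing_q: int = 20
    window_size: int = 4
    window_q: float = 28.0
    min_len: int = 40

    def __post_init__(self) -> None:
        if min(self.leading_q, self.trailing_q, self.min_len) < 0 or self.window_q < 0:
            raise ValueError("trim parameters must be non-negative")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


def _trailing_trim(seq: str, qual: tuple[int, ...], threshold: int):
    end = len(seq)
    while end > 0 and qual[end - 1] < threshold:
        end -= 1
    return seq[:end], qual[:end]


def trim_read(mate: Mate, params: TrimParams = TrimParams()) -> Mate | None:
    """Trim one mate; returns None when the read is dropped.

    Rule order: leading, trailing, sliding window (cut at the first window
    whose mean quality is below ``window_q``, then re-apply the trailing
    rule), minimum length.
    """
    seq, qual = mate.seq, mate.qual
    # fast path: nothing can be trimmed when every base clears all thresholds
    if qual and min(qual) >= max(params.leading_q, params.trailing_q, params.window_q):
        return mate if len(seq) >= params.min_len else None
    start = 0
    while start < len(seq) and qual[start] < params.leading_q:
        start += 1
    seq, qual = seq[start:], qual[start:]
    seq, qual = _trailing_trim(seq, qual, params.trailing_q)

    w = params.window_size
    if len(seq) >= w and (not qual or min(qual) < params.window_q):
        for i in range(len(seq) - w + 1):
            if sum(qual[i : i + w]) / w < params.window_q:
                seq, qual = seq[:i], qual[:i]
                seq, qual = _trailing_trim(seq, qual, params.trailing_q)
                break
    if len(seq) < params.min_len:
        return None
    return Mate(seq, qual)


@dataclass
class TrimReport:
    n_input: int = 0
    n_surviving: int = 0
    n_dropped_mate1: int = 0
    n_dropped_mate2: int = 0
    n_dropped_both: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_mate1 + self.n_dropped_mate2 + self.n_dropped_both

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_surviving": self.n_surviving,
            "n_dropped_mate1": self.n_dropped_mate1,
            "n_dropped_mate2": self.n_dropped_mate2,
            "n_dropped_both": self.n_dropped_both,
        }


def trim_pairs(
    pairs: Iterable[ReadPair], params: TrimParams = TrimParams()
) -> tuple[list[ReadPair], TrimReport]:
    """Trim both mates of each pair; a pair survives only if both mates do."""
    report = TrimReport()
    out: list[ReadPair] = []
    for pair in pairs:
        report.n_input += 1
        m1 = trim_read(pair.mate1, params)
        m2 = trim_read(pair.mate2, params)
        if m1 is not None and m2 is not None:
            out.append(ReadPair(pair.id, m1, m2))
            report.n_surviving += 1
        elif m1 is None and m2 is None:
            report.n_dropped_both += 1
        elif m1 is None:
            report.n_dropped_mate1 += 1
        else:
            report.n_dropped_mate2 += 1
    return out, report


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33, gzip-transparent)


def _open_text(path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, Mate]]:
    """Yield (read id, Mate) records from a FASTQ file."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()  # '+'
            qual = fh.readline().strip()
            rid = header.strip()[1:].split()[0]
            yield rid, Mate(seq, tuple(ord(c) - 33 for c in qual))


def write_fastq(records: Iterable[tuple[str, Mate]], path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, mate in records:
            fh.write(f"@{rid}\n{mate.seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in mate.qual) + "\n")
            n += 1
    return n


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Read synchronized mate files into ReadPairs (ids must correspond)."""
    for (id1, m1), (id2, m2) in zip(read_fastq(path1), read_fastq(path2), strict=True):
        base = id1[:-2] if id1.endswith(("/1", "/2")) else id1
        yield ReadPair(base, m1, m2)


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> int:
    n = 0
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for pair in pairs:
            f1.write(f"@{pair.id}/1\n{pair.mate1.seq}\n+\n")
            f1.write("".join(chr(q + 33) for q in pair.mate1.qual) + "\n")
            f2.write(f"@{pair.id}/2\n{pair.mate2.seq}\n+\n")
            f2.write("".join(chr(q + 33) for q in pair.mate2.qual) + "\n")
            n += 1
    return n
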