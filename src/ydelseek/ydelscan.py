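"""K-mer subtraction core.

Counts fixed-length, prefix-constrained k-mers per genotype (both strands of
every read are scanned but only windows starting with the prefix base are
kept — a ~1/4 subsampling of k-mer space that cuts memory), identifies
male-specific k-mers by subtraction against female and deletion-mutant
tables under total-count thresholds, retains read pairs carrying at least
one such k-mer, and assembles them with a small de Bruijn unitig assembler.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ._seq import revcomp
from .readkit import ReadPair

__all__ = [
    "KmerCountTable",
    "SubtractionParams",
    "Contig",
    "extract_kmers",
    "male_specific_kmers",
    "retain_read_pairs",
    "assemble_contigs",
    "write_kmer_table",
    "read_kmer_table",
    "write_contigs_fasta",
]

DEFAULT_K = 35
DEFAULT_PREFIX = "A"
_ACGT = frozenset("ACGT")


@dataclass
class KmerCountTable:
    k: int
    prefix: str
    counts: Counter
    sample_id: str = ""

    def __getitem__(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class SubtractionParams:
    min_total: int = 10
    max_total: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.min_total <= self.max_total:
            raise ValueError("need 0 < min_total <= max_total")


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    support: float  # mean multiplicity of constituent assembly k-mers

    def __len__(self) -> int:
        return len(self.sequence)


def _count_windows(seq: str, k: int, prefix: str, counts: Counter) -> None:
    limit = len(seq) - k
    if limit < 0:
        return
    clean = _ACGT.issuperset(seq)
    find = seq.find
    i = find(prefix)
    while 0 <= i <= limit:
        kmer = seq[i : i + k]
        if clean or _ACGT.issuperset(kmer):
            counts[kmer] += 1
        i = find(prefix, i + 1)


def iter_sequences(reads) -> Iterable[str]:
    """Accept ReadPairs, (id, Mate) tuples, Mates, or plain strings."""
    for r in reads:
        if isinstance(r, ReadPair):
            yield r.mate1.seq
            yield r.mate2.seq
        elif isinstance(r, str):
            yield r
        elif hasattr(r, "seq"):
            yield r.seq
        else:  # (id, mate) tuple from read_fastq
            yield r[1].seq


def extract_kmers(
    reads, k: int = DEFAULT_K, prefix: str = DEFAULT_PREFIX, sample_id: str = ""
) -> KmerCountTable:
    """Count prefix-constrained k-mers over both strands of each read.

    Windows containing non-ACGT characters are skipped. Reads shorter than
    k contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    for seq in iter_sequences(reads):
        seq = seq.upper()
        _count_windows(seq, k, prefix, counts)
        _count_windows(revcomp(seq), k, prefix, counts)
    return KmerCountTable(k=k, prefix=prefix, counts=counts, sample_id=sample_id)


def male_specific_kmers(
    male: KmerCountTable,
    others: list[KmerCountTable],
    params: SubtractionParams = SubtractionParams(),
) -> set[str]:
    """K-mers present in the male table, absent from every other table, with
    combined (male + other) count within [min_total, max_total] for every
    pairing — which, given absence elsewhere, is a bound on the male count.
    """
    for other in others:
        if other.k != male.k or other.prefix != male.prefix:
            raise ValueError(
                f"table {other.sample_id!r} has k={other.k}/prefix={other.prefix!r}, "
                f"male table has k={male.k}/prefix={male.prefix!r}"
            )
    lo, hi = params.min_total, params.max_total
    result = set()
    for kmer, count in male.counts.items():
        if not lo <= count <= hi:
            continue
        if any(other.counts.get(kmer) for other in others):
            continue
        result.add(kmer)
    return result


def _read_kmers(seq: str, k: int, prefix: str):
    seq = seq.upper()
    for s in (seq, revcomp(seq)):
        limit = len(s) - k
        i = s.find(prefix)
        while 0 <= i <= limit:
            yield s[i : i + k]
            i = s.find(prefix, i + 1)


def retain_read_pairs(
    pairs: Iterable[ReadPair],
    kmer_set: set[str],
    k: int = DEFAULT_K,
    prefix: str = DEFAULT_PREFIX,
) -> list[ReadPair]:
    """Keep pairs where either mate carries at least one k-mer from the set."""
    if not kmer_set:
        raise ValueError("k-mer set is empty")
    retained = []
    for pair in pairs:
        if any(
            km in kmer_set
            for mate in (pair.mate1, pair.mate2)
            for km in _read_kmers(mate.seq, k, prefix)
        ):
            retained.append(pair)
    return retained


# ---------------------------------------------------------------------------
# mini de Bruijn assembler


def assemble_contigs(
    reads, assembly_k: int = 31, min_support: int = 2
) -> list[Contig]:
    """Assemble unitigs of a de Bruijn graph built from the reads.

    Nodes are (assembly_k - 1)-mers, edges are assembly_k-mers observed at
    least ``min_support`` times across reads and their reverse complements.
    Unbranched paths are compressed; each unitig and its reverse complement
    collapse to the lexicographically smaller strand. Output is ordered by
    (length desc, sequence asc) with ids c0000, c0001, ...
    """
    k = assembly_k
    edge_counts: Counter = Counter()
    for seq in iter_sequences(reads):
        seq = seq.upper()
        for s in (seq, revcomp(seq)):
            if len(s) < k or not _ACGT.issuperset(s):
                if not _ACGT.issuperset(s):
                    s = "".join(c if c in _ACGT else "N" for c in s)
                    for part in s.split("N"):
                        for i in range(len(part) - k + 1):
                            edge_counts[part[i : i + k]] += 1
                    continue
            for i in range(len(s) - k + 1):
                edge_counts[s[i : i + k]] += 1

    edges = {e: c for e, c in edge_counts.items() if c >= min_support}
    if not edges:
        return []

    out_edges: dict[str, list[str]] = {}
    in_deg: Counter = Counter()
    for e in edges:
        u, v = e[:-1], e[1:]
        out_edges.setdefault(u, []).append(v)
        in_deg[v] += 1
        in_deg.setdefault(u, 0)
        out_edges.setdefault(v, [])

    def is_through(node: str) -> bool:
        return in_deg[node] == 1 and len(out_edges[node]) == 1

    unitigs: dict[str, float] = {}
    visited_edges: set[str] = set()

    def emit(path_nodes: list[str]) -> None:
        seq = path_nodes[0] + "".join(n[-1] for n in path_nodes[1:])
        kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
        support = sum(edges[km] for km in kmers) / len(kmers)
        canon = min(seq, revcomp(seq))
        prev = unitigs.get(canon)
        if prev is None or support > prev:
            unitigs[canon] = support

    # maximal non-branching paths from branching/terminal nodes
    for node in out_edges:
        if is_through(node):
            continue
        for nxt in out_edges[node]:
            edge = node + nxt[-1]
            if edge in visited_edges:
                continue
            path = [node, nxt]
            visited_edges.add(edge)
            while is_through(path[-1]):
                follower = out_edges[path[-1]][0]
                e2 = path[-1] + follower[-1]
                if e2 in visited_edges:
                    break
                visited_edges.add(e2)
                path.append(follower)
            emit(path)

    # isolated cycles: every node is a through-node
    for e in edges:
        if e in visited_edges:
            continue
        u = e[:-1]
        if not is_through(u):
            continue
        path = [u]
        while True:
            nxt = out_edges[path[-1]][0]
            edge = path[-1] + nxt[-1]
            if edge in visited_edges:
                break
            visited_edges.add(edge)
            path.append(nxt)
            if nxt == u:
                break
        if len(path) > 1:
            emit(path)

    ordered = sorted(unitigs.items(), key=lambda kv: (-len(kv[0]), kv[0]))
    width = max(4, len(str(len(ordered))))
    return [
        Contig(id=f"c{idx:0{width}d}", sequence=seq, support=sup)
        for idx, (seq, sup) in enumerate(ordered)
    ]


# ---------------------------------------------------------------------------
# serialization


def write_kmer_table(table: KmerCountTable, path) -> None:
    """Sorted two-column TSV with a header line recording k/prefix/sample."""
    with open(path, "w") as fh:
        fh.write(f"#k={table.k}\tprefix={table.prefix}\tsample={table.sample_id}\n")
        for kmer in sorted(table.counts):
            fh.write(f"{kmer}\t{table.counts[kmer]}\n")


def read_kmer_table(path) -> KmerCountTable:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#k="):
            raise ValueError(f"{path}: missing k-mer table header")
        fields = dict(
            item.split("=", 1) for item in header.lstrip("#").split("\t")
        )
        counts: Counter = Counter()
        for line in fh:
            kmer, count = line.split("\t")
            counts[kmer] = int(count)
    return KmerCountTable(
        k=int(fields["k"]),
        prefix=fields["prefix"],
        counts=counts,
        sample_id=fields.get("sample", ""),
    )


def write_contigs_fasta(contigs: list[Contig], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id} length={len(c.sequence)} support={c.support:.1f}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i : i + 80] + "\n")
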