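"""Gametolog molecular evolution: codon-aware alignment, NG86 divergence,
Tajima's relative-rate test and mutation-rate dating.

The divergence estimator follows the Nei–Gojobori (1986) counting
conventions: fractional synonymous/nonsynonymous site counts per codon,
observed differences averaged with equal weight over all minimal
substitution pathways (pathways through stop codons excluded), and
Jukes–Cantor multiple-hit correction of the proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
import math

from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import chi2 as _chi2

from ._seq import BASES, CODON_TABLE, check_cds, codons, translate

__all__ = [
    "CodonAlignment",
    "PairwiseDivergence",
    "RelativeRateResult",
    "DivergenceTime",
    "codon_align",
    "ng86_divergence",
    "lineage_replacements",
    "tajima_rrt",
    "divergence_time",
    "syn_fraction",
    "pathway_counts",
]

# default constants for the dating step (per-nucleotide per-generation
# mutation rate and years per generation)
DEFAULT_MU = 7.31e-9
DEFAULT_GENERATION_TIME = 1.5


# ---------------------------------------------------------------------------
# codon alignment


@dataclass
class CodonAlignment:
    """Two or three coding sequences aligned with codon-sized gaps."""

    names: list[str]
    seqs: list[str]  # aligned nucleotide sequences, '-' gaps

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError("aligned sequences have unequal lengths")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length not divisible by 3")

    @property
    def n_codon_columns(self) -> int:
        return len(self.seqs[0]) // 3

    def codon_columns(self, indices: list[int] | None = None):
        """Yield tuples of codons per column; gap codons appear as '---'."""
        seqs = self.seqs if indices is None else [self.seqs[i] for i in indices]
        for i in range(0, len(seqs[0]), 3):
            yield tuple(s[i : i + 3] for s in seqs)

    def gapfree_codon_columns(self, indices: list[int] | None = None):
        """Codon columns with no gap in any of the selected sequences."""
        return [
            col for col in self.codon_columns(indices) if all("-" not in c for c in col)
        ]

    def translated(self) -> list[str]:
        out = []
        for s in self.seqs:
            aa = []
            for i in range(0, len(s), 3):
                c = s[i : i + 3]
                aa.append("-" if "-" in c else CODON_TABLE.get(c, "X"))
            out.append("".join(aa))
        return out


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def _align_protein_pair(p1: str, p2: str) -> tuple[str, str]:
    aln = _protein_aligner().align(p1, p2)[0]
    a1, a2 = str(aln[0]), str(aln[1])
    return a1, a2


def _thread_codons(aligned_protein: str, cds: str) -> str:
    cods = codons(cds)
    out, j = [], 0
    for aa in aligned_protein:
        if aa == "-":
            out.append("---")
        else:
            out.append(cods[j])
            j += 1
    return "".join(out)


def _merge_star(a_center: str, a_other: str, b_center: str, b_other: str):
    """Merge two pairwise protein alignments sharing the same center sequence.

    Returns aligned (center, other_a, other_b) strings.
    """
    out_c: list[str] = []
    out_a: list[str] = []
    out_b: list[str] = []
    i = j = 0
    la, lb = len(a_center), len(b_center)
    while i < la or j < lb:
        ins_a = i < la and a_center[i] == "-"
        ins_b = j < lb and b_center[j] == "-"
        if ins_a:  # insertion in other_a relative to center
            out_c.append("-")
            out_a.append(a_other[i])
            out_b.append("-")
            i += 1
        elif ins_b:
            out_c.append("-")
            out_a.append("-")
            out_b.append(b_other[j])
            j += 1
        else:
            # both alignments at a real center residue
            out_c.append(a_center[i])
            out_a.append(a_other[i])
            out_b.append(b_other[j])
            i += 1
            j += 1
    return "".join(out_c), "".join(out_a), "".join(out_b)


def codon_align(cds_list, names: list[str] | None = None) -> CodonAlignment:
    """Align 2 or 3 coding sequences codon-wise.

    Translates each CDS, globally aligns the proteins (BLOSUM62, gap open
    11 / extend 1) and back-threads the codons, so gaps come only in
    whole-codon units. Three sequences are star-merged on the first.
    """
    cds_list = [str(s).upper() for s in cds_list]
    if not 2 <= len(cds_list) <= 3:
        raise ValueError("codon_align expects 2 or 3 sequences")
    if names is None:
        names = [f"seq{i + 1}" for i in range(len(cds_list))]
    proteins = []
    for name, cds in zip(names, cds_list):
        check_cds(cds, name)
        aa = translate(cds)
        proteins.append(aa[:-1] if aa.endswith("*") else aa)
    # trailing stop codons are aligned as-is only when every sequence has one
    has_stop = [translate(c).endswith("*") for c in cds_list]
    trimmed = [c[:-3] if s else c for c, s in zip(cds_list, has_stop)]

    if len(cds_list) == 2:
        a1, a2 = _align_protein_pair(proteins[0], proteins[1])
        aligned = [_thread_codons(a1, trimmed[0]), _thread_codons(a2, trimmed[1])]
    else:
        a1a, a2 = _align_protein_pair(proteins[0], proteins[1])
        b1, b3 = _align_protein_pair(proteins[0], proteins[2])
        c, oa, ob = _merge_star(a1a, a2, b1, b3)
        aligned = [
            _thread_codons(c, trimmed[0]),
            _thread_codons(oa, trimmed[1]),
            _thread_codons(ob, trimmed[2]),
        ]
    if all(has_stop):
        stops = [c[-3:] for c in cds_list]
        aligned = [a + s for a, s in zip(aligned, stops)]
    return CodonAlignment(names=list(names), seqs=aligned)


# ---------------------------------------------------------------------------
# NG86 divergence


@lru_cache(maxsize=None)
def syn_fraction(codon: str) -> float:
    """Fractional number of synonymous sites in a codon (0..3).

    Per position, the fraction of the 3 possible single-base changes that
    preserve the amino acid; changes to stop codons count as nonsynonymous.
    """
    aa = CODON_TABLE[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = CODON_TABLE[alt]
            if alt_aa == aa and alt_aa != "*":
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged with equal weight over all minimal substitution pathways;
    pathways visiting a stop codon are excluded. If every pathway is
    blocked by stops, all pathways are used as a fallback.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    nd = len(diff_pos)
    if nd == 0:
        return 0.0, 0.0

    def walk(order, allow_stops):
        syn = non = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_TABLE[nxt] == "*" and not allow_stops and nxt != c2:
                return None
            if CODON_TABLE[nxt] == CODON_TABLE[cur] and CODON_TABLE[nxt] != "*":
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non

    results = [r for order in permutations(diff_pos) if (r := walk(order, False))]
    if not results:
        results = [walk(order, True) for order in permutations(diff_pos)]
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


def _jukes_cantor(p: float, label: str) -> float:
    if p >= 0.75:
        raise ValueError(
            f"{label} proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class PairwiseDivergence:
    """NG86 synonymous/nonsynonymous divergence between two coding sequences."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None
    n_codons: int
    n_codons_total: int = 0  # codon columns before gap filtering

    def as_dict(self) -> dict:
        return {
            "S": self.S,
            "N": self.N,
            "Sd": self.Sd,
            "Nd": self.Nd,
            "pS": self.pS,
            "pN": self.pN,
            "dS": self.dS,
            "dN": self.dN,
            "omega": self.omega,
            "n_codons": self.n_codons,
            "n_codons_total": self.n_codons_total,
        }


def ng86_divergence(alignment: CodonAlignment, pair: tuple[int, int] = (0, 1)) -> PairwiseDivergence:
    """NG86 dS/dN with Jukes–Cantor correction for one sequence pair.

    Gapped codon columns are dropped pairwise. Raises on zero usable
    columns, zero synonymous sites, or proportions >= 3/4.
    """
    cols = alignment.gapfree_codon_columns(list(pair))
    if not cols:
        raise ValueError("no gap-free codon columns to compare")
    s_sites = n_sites = sd = nd = 0.0
    for c1, c2 in cols:
        s_sites += (syn_fraction(c1) + syn_fraction(c2)) / 2.0
        ds, dn = pathway_counts(c1, c2)
        sd += ds
        nd += dn
    n_sites = 3.0 * len(cols) - s_sites
    if s_sites <= 0:
        raise ValueError("zero synonymous sites in comparison")
    ps, pn = sd / s_sites, nd / n_sites
    dS = _jukes_cantor(ps, "synonymous")
    dN = _jukes_cantor(pn, "nonsynonymous")
    omega = (dN / dS) if dS > 0 else None
    return PairwiseDivergence(
        S=s_sites,
        N=n_sites,
        Sd=sd,
        Nd=nd,
        pS=ps,
        pN=pn,
        dS=dS,
        dN=dN,
        omega=omega,
        n_codons=len(cols),
        n_codons_total=alignment.n_codon_columns,
    )


# ---------------------------------------------------------------------------
# Tajima relative-rate test


def lineage_replacements(
    seq1: str, seq2: str, outgroup: str
) -> tuple[int, int]:
    """Lineage-specific difference counts judged against the outgroup.

    Inputs are aligned character sequences (amino acids by default usage;
    nucleotides work identically). Over gap-free columns, m1 counts columns
    where seq1 is the odd one out (seq2 equals the outgroup) and m2 the
    symmetric case; columns where all three differ or the outgroup is the
    odd one out contribute to neither.
    """
    if not (len(seq1) == len(seq2) == len(outgroup)):
        raise ValueError("sequences must be aligned to equal length")
    m1 = m2 = 0
    for a, b, o in zip(seq1, seq2, outgroup):
        if "-" in (a, b, o):
            continue
        if a != b:
            if b == o:
                m1 += 1
            elif a == o:
                m2 += 1
            # all three distinct: uninformative
    return m1, m2


@dataclass
class RelativeRateResult:
    m1: int
    m2: int
    chi_square: float
    p_value: float
    informative: bool = True

    def as_dict(self) -> dict:
        return {
            "m1": self.m1,
            "m2": self.m2,
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "informative": self.informative,
        }


def tajima_rrt(m1: int, m2: int) -> RelativeRateResult:
    """Tajima's 1D relative-rate chi-square test on lineage-specific counts."""
    if m1 < 0 or m2 < 0:
        raise ValueError("counts must be non-negative")
    if m1 == m2 == 0:
        return RelativeRateResult(0, 0, 0.0, 1.0, informative=False)
    stat = (m1 - m2) ** 2 / (m1 + m2)
    p = float(_chi2.sf(stat, df=1))
    return RelativeRateResult(m1, m2, stat, p)


def tajima_rrt_from_alignment(
    alignment: CodonAlignment,
    seq1: int = 0,
    seq2: int = 1,
    outgroup: int = 2,
    level: str = "aa",
) -> RelativeRateResult:
    """Run the relative-rate test directly from a 3-sequence codon alignment.

    ``level`` selects amino-acid (default) or nucleotide columns.
    """
    if len(alignment.seqs) < 3:
        raise ValueError("relative-rate test needs 3 aligned sequences")
    if level == "aa":
        seqs = alignment.translated()
    elif level == "nt":
        seqs = alignment.seqs
    else:
        raise ValueError(f"unknown level {level!r}")
    m1, m2 = lineage_replacements(seqs[seq1], seqs[seq2], seqs[outgroup])
    return tajima_rrt(m1, m2)


# ---------------------------------------------------------------------------
# dating


@dataclass
class DivergenceTime:
    dS: float
    mu: float = DEFAULT_MU
    generation_time: float = DEFAULT_GENERATION_TIME
    T_generations: float = field(init=False)
    T_years: float = field(init=False)

    def __post_init__(self) -> None:
        self.T_generations = self.dS / (2.0 * self.mu)
        self.T_years = self.T_generations * self.generation_time

    def as_dict(self) -> dict:
        return {
            "dS": self.dS,
            "mu": self.mu,
            "generation_time": self.generation_time,
            "T_generations": self.T_generations,
            "T_years": self.T_years,
        }


def divergence_time(
    dS: float,
    mu: float = DEFAULT_MU,
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> DivergenceTime:
    """Date a split as T = dS / (2 mu), converted to years by generation time."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if dS < 0:
        raise ValueError("dS must be non-negative")
    return DivergenceTime(dS=dS, mu=mu, generation_time=generation_time)
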