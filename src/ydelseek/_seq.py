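"""Small shared sequence helpers used across modules."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: codon -> one-letter amino acid, '*' for stops (universal code)
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    CODON_TABLE[_stop] = "*"

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a frame-0 CDS; '*' marks stop codons, 'X' unknown codons."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(
        CODON_TABLE.get(cds[i : i + 3].upper(), "X") for i in range(0, len(cds), 3)
    )


def codons(cds: str) -> list[str]:
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def check_cds(cds: str, name: str = "sequence") -> None:
    """Raise ValueError on frame-breaking length or internal stop codons."""
    if len(cds) % 3:
        raise ValueError(f"{name}: length {len(cds)} not divisible by 3")
    aa = translate(cds)
    internal = aa[:-1]
    if "*" in internal:
        pos = internal.index("*")
        raise ValueError(f"{name}: internal stop codon at codon {pos}")
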