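"""Simulation configuration types and the default gametolog preset."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BranchParams",
    "FocalGene",
    "QualityModel",
    "CrossConfig",
    "SimConfig",
    "GSF_PRESET",
    "default_expression_design",
    "substream",
]


@dataclass(frozen=True)
class BranchParams:
    """Per-branch evolution targets: synonymous substitutions per synonymous
    site, and the dN/dS ratio applied on that branch."""

    syn_divergence: float
    omega: float

    def __post_init__(self) -> None:
        if self.syn_divergence < 0 or self.omega < 0:
            raise ValueError("branch targets must be non-negative")
        # beyond ~2 substitutions/site the observable proportion saturates
        # toward 3/4 and the Jukes-Cantor correction is no longer usable
        if self.syn_divergence > 2.0 or self.syn_divergence * self.omega > 2.0:
            raise ValueError(
                "divergence target too large: observed proportions approach 3/4 "
                "where the Jukes-Cantor correction is undefined"
            )

    @property
    def nonsyn_divergence(self) -> float:
        return self.syn_divergence * self.omega


#: Branch targets tuned so the *pairwise* quantities hit the preset goals:
#: dS(x, y) = 0.18, pairwise dN/dS(x, outgroup) = 0.38, pairwise
#: dN/dS(y, outgroup) = 0.08, and y-vs-outgroup nucleotide identity ~93%.
#: The x branch carries the elevated replacement rate (released constraint);
#: y and outgroup branches evolve under purifying selection (omega 0.08).
GSF_PRESET: dict[str, BranchParams] = {
    "x": BranchParams(syn_divergence=0.09, omega=(0.38 * 0.23 - 0.08 * 0.14) / 0.09),
    "y": BranchParams(syn_divergence=0.09, omega=0.08),
    "outgroup": BranchParams(syn_divergence=0.14, omega=0.08),
}


@dataclass(frozen=True)
class FocalGene:
    """Placement of the focal CDS on the Y-specific region."""

    start: int = 6000
    n_codons: int = 96

    @property
    def length(self) -> int:
        return 3 * self.n_codons

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class QualityModel:
    mean_q: int = 35
    noise_sd: float = 0.0
    tail_len: int = 0  # degraded 3' tail length (exercises the trimmer)
    head_len: int = 0  # degraded 5' head length
    tail_q: int = 2


@dataclass(frozen=True)
class CrossConfig:
    n_sons: int = 4
    n_daughters: int = 6
    n_sites: int = 50

    def __post_init__(self) -> None:
        if self.n_sons + self.n_daughters < 1:
            raise ValueError("cross needs at least one offspring")


def default_expression_design() -> dict[str, dict[str, float]]:
    """Sample -> {feature: relative abundance}. The focal gene is expressed
    only in the male early-bud sample; one Y-specific fragment and the
    TE-like fragment are expressed broadly, as is the autosomal gene."""
    base = {"ydel_broad": 50.0, "te_frag": 30.0, "auto_gene": 100.0}
    design = {
        "male": {"focal_y": 200.0, **base},
        "female": dict(base),
        "R025": dict(base),
        "EGP14": dict(base),
        "EGP15": dict(base),
    }
    return design


@dataclass
class SimConfig:
    """Full simulation design; defaults give the 'gsf-default' preset."""

    seed: int = 0
    autosome_length: int = 40_000
    x_length: int = 25_000
    y_shared_length: int = 8_000
    y_specific_length: int = 15_000
    deletion_intervals: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("R025", 2_000, 9_000), ("EGP14", 5_000, 12_000)]
    )
    focal_gene: FocalGene = field(default_factory=FocalGene)
    gsf_preset: dict[str, BranchParams] = field(default_factory=lambda: dict(GSF_PRESET))
    coverage: float = 30.0
    read_length: int = 100
    error_rate: float = 0.002
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    quality_model: QualityModel = field(default_factory=QualityModel)
    expression_design: dict[str, dict[str, float]] = field(
        default_factory=default_expression_design
    )
    rna_reads_per_sample: int = 20_000
    rna_read_length: int = 75
    cross: CrossConfig = field(default_factory=CrossConfig)
    heterozygosity: float = 0.0  # residual het rate of the inbred background
    focal_loss_mutants: list[str] | None = None  # None = every mutant

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.focal_gene.length % 3:
            raise ValueError("focal CDS length must be divisible by 3")
        for mutant, start, end in self.deletion_intervals:
            if not 0 <= start < end <= self.y_specific_length:
                raise ValueError(
                    f"deletion {mutant}:[{start},{end}) outside Y-specific region "
                    f"[0,{self.y_specific_length})"
                )
        if self.y_specific_length and not (
            0 <= self.focal_gene.start < self.focal_gene.end <= self.y_specific_length
        ):
            raise ValueError("focal gene interval outside Y-specific region")
        must_lose = (
            set(self.focal_loss_mutants)
            if self.focal_loss_mutants is not None
            else {m for m, _, _ in self.deletion_intervals}
        )
        for mutant in must_lose:
            intervals = [
                (s, e) for m, s, e in self.deletion_intervals if m == mutant
            ]
            if not any(
                s <= self.focal_gene.start and self.focal_gene.end <= e
                for s, e in intervals
            ):
                raise ValueError(
                    f"mutant {mutant!r} deletions do not cover the focal gene"
                )

    @property
    def mutant_ids(self) -> list[str]:
        seen: list[str] = []
        for m, _, _ in self.deletion_intervals:
            if m not in seen:
                seen.append(m)
        return seen


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent deterministic RNG substream for (seed, purpose key)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))
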