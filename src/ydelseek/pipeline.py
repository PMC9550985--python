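"""End-to-end orchestration: trim -> k-mer subtraction -> read retention ->
assembly -> coverage-ratio selection -> homology/expression screen ->
segregation -> molecular evolution, with every intermediate persisted and a
JSON + Markdown run report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import contigselect, exprscreen, molevo, readkit, xlinkage, ydelscan
from .readkit import TrimParams
from .synthdata import (
    SimConfig,
    simulate_cross,
    simulate_expression_reads,
    simulate_reads_for_genome_set,
    simulate_system,
    write_genome_fasta,
    write_truth_bed,
)

logger = logging.getLogger("ydelseek")

__all__ = ["RunConfig", "run_all", "make_fixture", "PRESETS"]

STAGES = ["trim", "kmers", "retain", "assemble", "select", "screen", "segregate", "molevo"]


@dataclass
class RunConfig:
    """Paths and stage parameters for a full pipeline run."""

    out_dir: str
    genomic_reads: dict  # sample -> [r1 path, r2 path]
    rna_reads: dict = field(default_factory=dict)  # sample -> fastq path
    transcripts_fasta: str | None = None
    te_fasta: str | None = None
    cross_tsv: str | None = None
    cds_fasta: str | None = None
    male_sample: str = "male"
    female_sample: str = "female"
    ratio_mutant: str = "EGP14"
    rna_male_sample: str = "male"
    seed: int = 0
    trim: TrimParams = field(default_factory=TrimParams)
    kmer_k: int = 35
    kmer_prefix: str = "A"
    subtraction: ydelscan.SubtractionParams = field(default_factory=ydelscan.SubtractionParams)
    assembly_k: int = 31
    assembly_min_support: int = 2
    ratio_filter: contigselect.RatioFilterParams = field(default_factory=contigselect.RatioFilterParams)
    candidate_filter: exprscreen.CandidateFilterParams = field(default_factory=exprscreen.CandidateFilterParams)
    evalue_max: float = 1e-7
    mu: float = molevo.DEFAULT_MU
    generation_time: float = molevo.DEFAULT_GENERATION_TIME
    enabled_stages: list = field(default_factory=lambda: list(STAGES))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, klass in (
            ("trim", TrimParams),
            ("subtraction", ydelscan.SubtractionParams),
            ("ratio_filter", contigselect.RatioFilterParams),
            ("candidate_filter", exprscreen.CandidateFilterParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run report dict.

    Any stage failure raises StageError naming the stage; partial outputs
    written so far are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    enabled = set(config.enabled_stages)

    trimmed: dict[str, list] = {}
    contigs: list[ydelscan.Contig] = []
    selected_ids: list[str] = []
    candidates: list[str] | None = None

    def stage_enabled(name: str) -> bool:
        if name not in enabled:
            report["stages"][name] = {"enabled": False}
            return False
        return True

    # ----- trim -------------------------------------------------------
    try:
        if stage_enabled("trim"):
            trim_reports = {}
            for sample, (r1, r2) in config.genomic_reads.items():
                pairs = list(readkit.read_fastq_pairs(r1, r2))
                kept, trep = readkit.trim_pairs(pairs, config.trim)
                trimmed[sample] = kept
                trim_reports[sample] = trep.as_dict()
                readkit.write_fastq_pairs(
                    kept, out / f"trimmed_{sample}_R1.fastq", out / f"trimmed_{sample}_R2.fastq"
                )
            report["stages"]["trim"] = {"enabled": True, "per_sample": trim_reports}
        else:
            for sample, (r1, r2) in config.genomic_reads.items():
                trimmed[sample] = list(readkit.read_fastq_pairs(r1, r2))
    except Exception as exc:  # noqa: BLE001
        raise StageError("trim", exc) from exc

    # ----- k-mer subtraction -----------------------------------------
    kmer_set: set[str] = set()
    try:
        if stage_enabled("kmers"):
            tables = {}
            for sample, pairs in trimmed.items():
                table = ydelscan.extract_kmers(
                    pairs, k=config.kmer_k, prefix=config.kmer_prefix, sample_id=sample
                )
                tables[sample] = table
                ydelscan.write_kmer_table(table, out / f"kmers_{sample}.tsv")
            others = [t for s, t in tables.items() if s != config.male_sample]
            kmer_set = ydelscan.male_specific_kmers(
                tables[config.male_sample], others, config.subtraction
            )
            (out / "male_specific_kmers.txt").write_text(
                "\n".join(sorted(kmer_set)) + ("\n" if kmer_set else "")
            )
            report["stages"]["kmers"] = {
                "enabled": True,
                "table_sizes": {s: len(t) for s, t in tables.items()},
                "n_male_specific": len(kmer_set),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("kmers", exc) from exc

    # ----- retention & assembly --------------------------------------
    retained: list = []
    try:
        if stage_enabled("retain"):
            retained = ydelscan.retain_read_pairs(
                trimmed[config.male_sample], kmer_set, k=config.kmer_k, prefix=config.kmer_prefix
            )
            readkit.write_fastq_pairs(
                retained, out / "retained_R1.fastq", out / "retained_R2.fastq"
            )
            report["stages"]["retain"] = {
                "enabled": True,
                "n_input_pairs": len(trimmed[config.male_sample]),
                "n_retained_pairs": len(retained),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("retain", exc) from exc

    try:
        if stage_enabled("assemble"):
            contigs = ydelscan.assemble_contigs(
                retained, assembly_k=config.assembly_k, min_support=config.assembly_min_support
            )
            ydelscan.write_contigs_fasta(contigs, out / "contigs.fasta")
            report["stages"]["assemble"] = {
                "enabled": True,
                "n_contigs": len(contigs),
                "total_bases": sum(len(c) for c in contigs),
                "longest": max((len(c) for c in contigs), default=0),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("assemble", exc) from exc

    # ----- ratio selection -------------------------------------------
    selected_contigs: list[ydelscan.Contig] = []
    try:
        if stage_enabled("select") and contigs:
            matrix = contigselect.count_mapped_reads(trimmed, contigs)
            matrix.counts.to_csv(out / "contig_counts_raw.tsv", sep="\t")
            norm = contigselect.normalize_counts(matrix, male_sample=config.male_sample)
            norm.counts.to_csv(out / "contig_counts_normalized.tsv", sep="\t")
            selected_ids, ratio_report = contigselect.select_ydel_contigs(
                norm,
                config.ratio_filter,
                male_sample=config.male_sample,
                female_sample=config.female_sample,
                mutant_sample=config.ratio_mutant,
            )
            ratio_report.to_csv(out / "contig_ratios.tsv", sep="\t")
            selected_contigs = [c for c in contigs if c.id in set(selected_ids)]
            ydelscan.write_contigs_fasta(selected_contigs, out / "ydel_contigs.fasta")
            report["stages"]["select"] = {
                "enabled": True,
                "n_contigs": len(contigs),
                "n_selected": len(selected_ids),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("select", exc) from exc

    # ----- expression screen -----------------------------------------
    try:
        if stage_enabled("screen") and config.transcripts_fasta:
            transcripts = _read_fasta(config.transcripts_fasta)
            subjects = {c.id: c.sequence for c in selected_contigs}
            hits = exprscreen.local_homology_search(
                transcripts, subjects, evalue_max=config.evalue_max
            )
            exprscreen.hits_to_table(hits).to_csv(out / "ydel_hits.tsv", sep="\t", index=False)
            expressed = {q: transcripts[q] for q in sorted({h.query for h in hits})}
            rna = {
                sample: [m.seq for _, m in readkit.read_fastq(path)]
                for sample, path in config.rna_reads.items()
            }
            matrix = exprscreen.quantify(rna, expressed) if expressed else None
            if matrix is not None:
                matrix.tpm.to_csv(out / "expression_tpm.tsv", sep="\t")
            te_library = _read_fasta(config.te_fasta) if config.te_fasta else {}
            kept, te_removed = exprscreen.te_filter(
                expressed, te_library, evalue_max=config.evalue_max
            )
            silent = [s for s in config.rna_reads if s != config.rna_male_sample]
            if matrix is not None:
                full = exprscreen.candidate_filter(
                    matrix, config.rna_male_sample, silent, config.candidate_filter
                )
                candidates = [c for c in full if c in kept]
            else:
                candidates = []
            with open(out / "candidates.tsv", "w") as fh:
                fh.write("fragment\n")
                for c in candidates:
                    fh.write(c + "\n")
            with open(out / "candidates.fasta", "w") as fh:
                for c in candidates:
                    fh.write(f">{c}\n{transcripts[c]}\n")
            report["stages"]["screen"] = {
                "enabled": True,
                "n_transcripts": len(transcripts),
                "n_expressed_ydel_fragments": len(expressed),
                "n_te_removed": len(te_removed),
                "te_removed": te_removed,
                "candidates": candidates,
            }
        elif "screen" in enabled:
            report["stages"]["screen"] = {"enabled": False, "reason": "no transcripts provided"}
    except Exception as exc:  # noqa: BLE001
        raise StageError("screen", exc) from exc

    # ----- segregation -----------------------------------------------
    try:
        if stage_enabled("segregate") and config.cross_tsv:
            cross = xlinkage.read_cross_tsv(config.cross_tsv)
            entry: dict = {"enabled": True}
            x_sites = [s for s in cross.sites if s.truth_class == "X"]
            if x_sites:
                focal = xlinkage.CrossGenotypes(sexes=cross.sexes, sites=x_sites)
                entry["focal_locus"] = xlinkage.classify_sites(focal).as_dict()
                auto_sites = [s for s in cross.sites if s.truth_class == "A"]
                if auto_sites:
                    auto = xlinkage.CrossGenotypes(sexes=cross.sexes, sites=auto_sites)
                    entry["autosomal_control"] = xlinkage.classify_sites(auto).as_dict()
            else:
                entry["focal_locus"] = xlinkage.classify_sites(cross).as_dict()
            with open(out / "xlinkage.json", "w") as fh:
                json.dump(entry, fh, indent=2)
            report["stages"]["segregate"] = entry
        elif "segregate" in enabled:
            report["stages"]["segregate"] = {"enabled": False, "reason": "no cross table"}
    except Exception as exc:  # noqa: BLE001
        raise StageError("segregate", exc) from exc

    # ----- molecular evolution ---------------------------------------
    try:
        if stage_enabled("molevo") and config.cds_fasta:
            cds = _read_fasta(config.cds_fasta)
            names = [n for n in ("x", "y", "outgroup") if n in cds]
            if len(names) < 2:
                raise ValueError("cds fasta must contain 'x' and 'y' records")
            aln = molevo.codon_align([cds[n] for n in names], names)
            entry = {"enabled": True, "pairs": {}}
            pair_indices = {(a, b): (names.index(a), names.index(b))
                            for a in names for b in names if a < b}
            for (a, b), (ia, ib) in sorted(pair_indices.items()):
                div = molevo.ng86_divergence(aln, (ia, ib))
                entry["pairs"][f"{a}:{b}"] = div.as_dict()
            ds_xy = entry["pairs"]["x:y"]["dS"]
            if len(names) == 3:
                rrt = molevo.tajima_rrt_from_alignment(
                    aln, names.index("x"), names.index("y"), names.index("outgroup")
                )
                entry["relative_rate"] = rrt.as_dict()
            entry["dating"] = molevo.divergence_time(
                ds_xy, config.mu, config.generation_time
            ).as_dict()
            with open(out / "molevo.json", "w") as fh:
                json.dump(entry, fh, indent=2)
            report["stages"]["molevo"] = entry
        elif "molevo" in enabled:
            report["stages"]["molevo"] = {"enabled": False, "reason": "no CDS fasta"}
    except Exception as exc:  # noqa: BLE001
        raise StageError("molevo", exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_markdown_report(report, out / "report.md")
    return report


def _write_markdown_report(report: dict, path) -> None:
    lines = ["# Pipeline run report", "", f"seed: {report['seed']}", ""]
    for stage, entry in report["stages"].items():
        lines.append(f"## {stage}")
        lines.append("```json")
        lines.append(json.dumps(entry, indent=2))
        lines.append("```")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# fixtures


PRESETS: dict[str, dict] = {
    "gsf-default": {},
    "gsf-small": {
        "autosome_length": 12_000,
        "x_length": 11_000,
        "y_shared_length": 2_000,
        "y_specific_length": 12_000,
        "deletion_intervals": [("R025", 1_000, 9_000), ("EGP14", 4_000, 10_000)],
        "rna_reads_per_sample": 6_000,
    },
}


def preset_config(preset_name: str, seed: int) -> SimConfig:
    if preset_name not in PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; available: {sorted(PRESETS)}"
        )
    from .synthdata.config import FocalGene, QualityModel

    overrides = dict(PRESETS[preset_name])
    overrides.setdefault("quality_model", QualityModel(tail_len=2, tail_q=2))
    if preset_name == "gsf-small":
        overrides.setdefault("focal_gene", FocalGene(start=6_000, n_codons=96))
    return SimConfig(seed=seed, **overrides)


def make_fixture(preset_name: str, seed: int, out_dir) -> dict:
    """Write a complete on-disk input bundle for ``run_all``.

    Returns the manifest dict (also written as manifest.json). The bundle
    holds per-individual genome FASTA, truth BED, genomic FASTQ pairs, RNA
    FASTQ per sample, transcript/TE/CDS FASTA and the cross TSV.
    """
    config = preset_config(preset_name, seed)
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "reads").mkdir(exist_ok=True)
    (out / "rna").mkdir(exist_ok=True)

    genome = simulate_system(config)
    for individual in genome.haplotypes:
        write_genome_fasta(genome, individual, out / "genomes" / f"{individual}.fasta")
    write_truth_bed(genome, out / "truth.bed")

    genomic = {}
    for individual, pairs in simulate_reads_for_genome_set(genome, config).items():
        r1 = out / "reads" / f"{individual}_R1.fastq"
        r2 = out / "reads" / f"{individual}_R2.fastq"
        readkit.write_fastq_pairs(pairs, r1, r2)
        genomic[individual] = [str(r1), str(r2)]

    rna_sets = simulate_expression_reads(
        genome.transcripts,
        config.expression_design,
        n_reads=config.rna_reads_per_sample,
        read_length=config.rna_read_length,
        seed=config.seed,
    )
    rna = {}
    for sample, reads in rna_sets.items():
        path = out / "rna" / f"{sample}.fastq"
        readkit.write_fastq(reads, path)
        rna[sample] = str(path)

    with open(out / "transcripts.fasta", "w") as fh:
        for name, seq in genome.transcripts.items():
            fh.write(f">{name}\n{seq}\n")
    with open(out / "te_library.fasta", "w") as fh:
        for name, seq in genome.te_library.items():
            fh.write(f">{name}\n{seq}\n")
    with open(out / "cds.fasta", "w") as fh:
        for name in ("x", "y", "outgroup"):
            fh.write(f">{name}\n{genome.cds[name]}\n")

    cross = simulate_cross(config.cross, seed=config.seed)
    xlinkage.write_cross_tsv(cross, out / "cross.tsv")

    manifest = {
        "preset": preset_name,
        "seed": seed,
        "individuals": sorted(genome.haplotypes),
        "rna_samples": sorted(rna),
        "genomic_reads": genomic,
        "rna_reads": rna,
        "transcripts_fasta": str(out / "transcripts.fasta"),
        "te_fasta": str(out / "te_library.fasta"),
        "cds_fasta": str(out / "cds.fasta"),
        "cross_tsv": str(out / "cross.tsv"),
        "truth_bed": str(out / "truth.bed"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_config_from_manifest(manifest: dict, out_dir, seed: int | None = None) -> RunConfig:
    """Convenience wiring of a fixture manifest into a RunConfig."""
    return RunConfig(
        out_dir=str(out_dir),
        genomic_reads=dict(manifest["genomic_reads"]),
        rna_reads=dict(manifest["rna_reads"]),
        transcripts_fasta=manifest["transcripts_fasta"],
        te_fasta=manifest["te_fasta"],
        cross_tsv=manifest["cross_tsv"],
        cds_fasta=manifest["cds_fasta"],
        seed=manifest["seed"] if seed is None else seed,
    )
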