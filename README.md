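# ydelseek

Desk-scale, fully tested reimplementation of a k-mer–subtraction pipeline for
discovering a Y-linked candidate gene from male / female / Y-deletion-mutant
genomes, plus the downstream screens used to validate it:

- **readkit** — FASTQ I/O and quality trimming (LEADING 20 / TRAILING 20 /
  SLIDINGWINDOW 4:28 / MINLEN 40 semantics).
- **ydelscan** — prefix-constrained 35-mer counting over both strands,
  male-specific k-mer identification by subtraction (absent in female and
  mutants, male count within [10, 1000]), retention of read pairs carrying a
  male-specific k-mer, and a mini de Bruijn unitig assembler.
- **contigselect** — deterministic seed-and-extend pseudo-mapper, library-size
  normalization, and the female/male < 20% OR mutant/male < 40% coverage-ratio
  contig filter.
- **exprscreen** — ungapped seed-and-extend homology search with
  Karlin–Altschul E-values (word 11, +1/−2, X-drop 20), TPM quantification
  with equal-split multi-mapping, TE exclusion, and the
  male-specific-expression candidate filter.
- **xlinkage** — X-linkage segregation test on a two-parent family with sexed
  offspring (sons must inherit only maternal alleles) and a Monte-Carlo power
  estimate of the design.
- **molevo** — codon-aware alignment (protein-guided, BLOSUM62), NG86
  synonymous/nonsynonymous divergence with Jukes–Cantor correction, Tajima's
  relative-rate test on amino acids, and mutation-rate dating
  T = dS / (2·µ).
- **synthdata** — synthetic genomes (inbred background, X/Y haplotypes,
  deletion mutants), paired-end and expression read simulation, codon-level
  gametolog evolution to divergence/ω targets, and a sexed cross simulator —
  all deterministic given a seed, with ground truth emitted as BED/TSV.
- **pipeline** — orchestration of the full flow with persisted intermediates
  and a JSON/Markdown run report, plus fixture presets.

## CLI

```bash
# write a synthetic input bundle (genomes, reads, RNA, cross, CDS trio)
ydelseek simulate --preset gsf-default --seed 1 --out-dir fixture/

# run the whole pipeline from the bundle
ydelseek run-all --manifest fixture/manifest.json --out-dir run1/

# individual stages
ydelseek trim --in1 R1.fastq --in2 R2.fastq --out1 t1.fastq --out2 t2.fastq
ydelseek kmers --in1 t1.fastq --in2 t2.fastq --out male.tsv --sample-id male
ydelseek subtract --male male.tsv --other female.tsv --other mutant.tsv --out specific.txt
ydelseek retain --in1 t1.fastq --in2 t2.fastq --kmers specific.txt --out1 k1.fastq --out2 k2.fastq
ydelseek assemble --in1 k1.fastq --in2 k2.fastq --out contigs.fasta
ydelseek select --contigs contigs.fasta --reads male=... --reads female=... --out-dir sel/
ydelseek screen --transcripts tx.fasta --contigs sel/ydel_contigs.fasta --rna male=... --out-dir scr/
ydelseek segregate --cross cross.tsv
ydelseek molevo --cds cds.fasta
```

`run-all` writes every intermediate (k-mer tables, retained reads, contigs,
count matrices, TPM matrix, candidate list, segregation verdict, divergence
report) under `--out-dir`, plus `report.json` / `report.md`.

## Conventions

Coordinates are 0-based half-open everywhere; truth intervals are BED;
qualities are Phred+33; k-mer tables are sorted TSV with a `#k=`/`prefix=`
header; homology hits use the conventional 12-column tabular layout.
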