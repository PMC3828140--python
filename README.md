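# parasitome

Genome-architecture and infection-transcriptome analyses for (fungal)
genomes, exercised end-to-end on seeded synthetic data:

- **RIP dinucleotide metrics** (`parasitome.rip`): dinucleotide counting
  with N-skipping, the TpA/ApT index (RIP-affected at >= 0.89) and the
  composite (CpA+TpG)/(ApC+GpT) index (affected at <= 1.03), per-gene
  affected fractions, stop-codon bias (TAA/TGA, TAG/TGA ratios),
  pooled dinucleotide log10 fold changes and a one-sided Fisher test for
  comparing affected fractions.
- **Tandem duplications** (`parasitome.duplication`): adjacent same-family
  pair/run detection on start-sorted gene order, a gene-order permutation
  test with the add-one Monte-Carlo estimator, gene–TE proximity
  (< 10 kb edge-to-edge by default), and recent-duplicate identification by
  affine-gap global-alignment identity (> 400 bp, >= 80% by default).
- **Secreted-protein clusters** (`parasitome.clusters`): SSP classification
  (secreted and < 300 aa), cysteine-rich counts, maximal secreted-gene
  chains with at most one non-secreted gene between consecutive secreted
  members and >= 3 secreted members, plus summary fractions.
- **Infection expression** (`parasitome.expression`): median-of-ratios
  normalization, strict >2x/>10x regulation sets, top-decile expression
  sets, hypergeometric enrichment, focal-set composition reports and
  cross-species ortholog fold-change comparison.
- **Synthetic data** (`parasitome.synth`): seeded genomes with plantable
  tandem runs, secreted clusters and a CpA→TpA (both strands) RIP mutation
  operator, plus negative-binomial expression counts with planted fold
  changes; every planted structure is recorded as ground truth.
- **Data model and I/O** (`parasitome.annotation`): GFF3 + FASTA + flags
  TSV readers/writers with exact round-tripping.
- **Pipeline** (`parasitome.pipeline`): one-command orchestration with a
  versioned, byte-reproducible JSON report.

## CLI

The umbrella command is `parasitome`; the domain groups are also installed
as standalone scripts:

```sh
parasitome synth-demo --seed 7 --out demo/      # synthetic data + full pipeline
parasitome run --config cfg.yaml                # pipeline from a YAML config

synth genome --config genome.yaml --seed 3 --out genome/
synth expr --annotation genome/ --seed 3 --out counts.tsv
rip scan --cds genome/cds.fasta --index tpa_apt --out rip.tsv
rip stops --cds genome/cds.fasta
rip dinuc-fc --target dups.fasta --control genome.fasta
dup tandem --gff3 genome/genes.gff3 --flags genome/flags.tsv --perms 1000 --seed 7
dup recent --cds genome/cds.fasta --min-len 400 --min-ident 0.8
dup te-near --gff3 ... --flags ... --te te.bed --max-dist 10000
clusters detect --gff3 ... --flags ... --out clusters.tsv
clusters summary --clusters clusters.tsv --flags ...
expr normalize --counts counts.tsv --design design.tsv --out norm.tsv
expr regsets --counts counts.tsv --design design.tsv
expr enrich 3 3 5 10
expr ortho-compare --pairs pairs.tsv
```

Inputs: GFF3 (gene/mRNA/CDS), FASTA (genome, CDS, proteins), a per-gene
flags TSV (`gene_id, secreted, protein_length, cysteines, family_id,
category, orphan, pfam_families, expanded_family, qvalue`), TE intervals
as BED (0-based half-open) or GFF3, counts as a gene x sample TSV with a
`sample<TAB>condition` design file, and ortholog pairs as a TSV with
columns `gene_a, gene_b[, expr_a, expr_b, qvalue]`.

## Conventions

- Coordinates are 1-based inclusive (GFF3); BED is converted at the boundary.
- "Adjacent" genes are consecutive in the start-sorted gene list of a
  contig, regardless of strand or distance.
- Reported percentages and ratios are rounded half-up.
- Strict vs inclusive thresholds follow the source wording: "more than
  two-fold" is strict, "at least 80% identical" is inclusive, SSP length
  "< 300 aa" is strict, RIP index calls are inclusive at the threshold.
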