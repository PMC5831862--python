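# mirmeta

Reusable pipeline for small RNA / miRNA analyses around larval metamorphosis
studies: read cleaning, annotation-based read classification, cross-species
miRNA family clustering, Dollo-parsimony gain/loss reconstruction on a species
tree, 2^−ΔΔCt qPCR expression profiling, and miRNA–target integration with
network export and gene-set over-representation. A synthetic-data generator
produces every input with known ground truth, so the whole pipeline is
testable offline.

## Modules

| module | what it does |
|---|---|
| `mirmeta.simulate` | planted read mixtures (FASTQ + per-category references), family histories evolved on a tree, mature miRNA catalogs, Ct tables, predictor tables, gene sets — all seeded and byte-stable |
| `mirmeta.qc` | fixed-order read filters (poly-N, 5′ adapter contaminant, missing 3′ adapter, homopolymer, low quality, length), length histogram, per-position base frequencies |
| `mirmeta.annotate` | exact full-read substring classification against per-category references (FASTA sets or GFF3+genome), priority resolution, removal bookkeeping |
| `mirmeta.families` | seed-anchored ungapped pairwise match (overlap ≥ 15 nt covering positions 2–8, ≤ 2 mismatches, ≤ 1 nt 5′ overhang), single-linkage family clustering, presence/absence matrix |
| `mirmeta.dollo` | single-gain / multiple-loss reconstruction (gain = MRCA of present species, losses = maximal absent subtrees), taxon acquisition assignment, per-node +/− summaries |
| `mirmeta.expression` | replicate-wise ΔCt against a U6 reference, ΔΔCt vs a reference stage, Student's t tests on ΔCt, hierarchical clustering of expression profiles |
| `mirmeta.targets` | two-clause target selection (in both predictor tables, or in table A with Pearson r < 0 across stages), seed-site scanning, edge-list export, hypergeometric ORA with BH adjustment |
| `mirmeta.cli` | `mirmeta` command with one subcommand per stage plus `run` for the full pipeline |

## CLI

Each stage is a subcommand; `run` chains them on a YAML config and writes a
SHA-256 manifest of every output:

```sh
mirmeta run --config configs/demo.yaml --out runs/demo
mirmeta simulate --out sim --seed 1
mirmeta qc --reads sim/reads.fastq --adapter3 TGGAATTCTCGGGTGCCAAGG \
           --adapter5 GTTCAGAGTTCTACAGTCCGACGATC --out qc
mirmeta classify --reads qc/clean.fa --refs sim/refs --out classify
mirmeta families --catalogs sim/catalog.fa --out families
mirmeta evolve --matrix families/presence_absence.tsv --tree sim/tree.nwk \
               --focal Ciona_savignyi --out evolve
mirmeta expression --ct sim/ct.csv --reference-stage 18 --out expression
mirmeta targets --pred-a sim/pred_a.tsv --pred-b sim/pred_b.tsv \
                --mirna-expr sim/mirna_profiles.tsv --gene-expr sim/gene_profiles.tsv \
                --gene-sets sim/gene_sets.gmt --out targets
```

Rerunning `run` with the same config and seed reproduces identical file
hashes.

## File conventions

- FASTQ with Sanger qualities; FASTA catalogs use `>id|species` headers.
- Newick trees are rooted, with named internal nodes (taxon names) and
  underscores preserved in labels.
- Ct tables are CSV with columns `mirna, stage, replicate, ct` and must
  include the reference gene (default `U6`) for every stage/replicate.
- Predictor tables are TSV with columns `mirna, gene, score[, energy]`;
  stage-profile TSVs have the feature id in the first column and one column
  per stage; gene sets are GMT.
- U and T are interchangeable on input; reports use RNA bases.
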