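# splice-shift

Detection of genotype-dependent shifts in splicing from bulk RNA-seq.
Given a gene annotation (GFF3) and spliced alignments (SAM) — or precomputed
per-sample count tables (TSV) — for two genotypes with biological replicates,
the pipeline:

1. **counts** per-gene unique reads, per-exon and per-intron average depths,
   per-junction read counts (every observed alignment gap), and reads
   contiguously spanning exon–intron boundaries;
2. **normalizes** gene counts with TMM (verified against edgeR), transforms
   to logCPM, length-adjusts to log-scale RPKM, and calls differential
   expression with a two-sided t-test (p < 0.01 and |log2FC| ≥ 0.6);
3. **detects splicing events** per replicate pair on 2×2 contingency tables:
   - intron retention (IR) / more-efficient splicing (MES): intron depth vs
     flanking-exon depth, Pearson χ² (df = 1, no correction);
   - exon skipping (ES): skip-junction reads vs inclusion-junction reads, χ²;
   - alternative 5′/3′ splice sites (A5SS/A3SS): variant-junction reads vs
     the intron's other junctions **and** vs the gene's unique read count,
     both by Fisher's exact test;

   an event is reported only if p < 0.01 in **every** replicate pair and the
   direction of the ratio shift agrees in every pair (no multiple-testing
   correction, by design);
4. **quantifies a three-variant reporter locus** — a GT–AG intron nested in
   an AT–AC intron whose 3′ splice sites are 3 nt apart — into unspliced /
   GT–AG-spliced / AT–AC-spliced proportions per sample.

A synthetic-data module generates gene models, negative-binomial replicate
counts, injected events with known truth, reporter mixtures, and optional
concrete SAM reads, so the whole pipeline runs and is testable offline.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact-test oracle
equivalence, χ² correctness, type-I calibration, event recovery on synthetic
truth, TMM/DEG boundary properties, reporter mixture recovery, pipeline
determinism).

## CLI

```sh
# write a seeded synthetic data set (annotation, count tables, sample sheet,
# truth table, and a ready-to-run config)
splice-shift simulate --out sim --seed 1 --n-genes 300 --n-ir 10 --n-mes 5

# run the full pipeline
splice-shift run --config sim/config.toml

# count a single SAM file against an annotation
splice-shift count --annotation genes.gff3 --sam reads.sam --out counts/s1
```

`run` writes `models.tsv`, `deg_<group>.tsv`, `events_<group>.tsv`,
`summary.json` (event counts per type, multi-intron IR genes, cross-contrast
overlap, DEG counts), `reporter.tsv`, and `run_report.json` into the
configured output directory. Outputs are deterministic: rerunning the same
config yields byte-identical tables.

Configuration is TOML:

```toml
[paths]
annotation = "annotation.gff3"
sample_sheet = "sample_sheet.tsv"   # columns: sample_id, group, path
out_dir = "out"

[params]
min_identity = 0.90   # alignment identity filter
alpha = 0.01          # per-replicate significance threshold
min_abs_lfc = 0.6     # DEG fold-change threshold (log2)
pairing = "index"     # or "pooled"
control_group = "wt"

[reporter]            # optional
gene_id = "REPORTER"
chrom = "chrR"
outer = [1201, 1500]  # AT–AC intron
inner = [1261, 1497]  # nested GT–AG intron
```

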