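# methwin

Sliding-window analysis of whole-genome bisulfite sequencing data:

* **mC calling** — per-cytosine methylation calls from Bismark-style
  cytosine reports (coverage ≥ 5; one-sided binomial test against the
  measured bisulfite non-conversion rate at P ≤ 1e-4), with conversion
  efficiency estimated from an unmethylated control contig and global
  per-context (CG/CHG/CHH) summaries.
* **Metagene profiles** — pooled methylation density over gene bodies and
  2-kb flanks, each split into 10 bins, strand-aware.
* **DMR calling** — 100-bp windows on a 50-bp grid; per-window pooled 2×2
  counts over cytosines covered in both samples; exact two-sided Fisher
  test; q-values via a sliding-linear-model estimate of the null
  proportion; DMRs require ≥ 5 cytosines, |difference| ≥ 25 percent points
  and q ≤ 0.01, and are classified hyper/hypo.
* **Annotation integration** — DMR association with genes
  (promoter/body/downstream), transposable elements and 24-nt smRNA loci,
  plus cross-tabulation against a differential-expression table
  (|fold change| ≥ 2, P ≤ 0.05).
* **Synthetic data** — a generator that builds toy genomes, beta-mixture
  methylation surfaces with feature effects (gene-body CG, flank CHH, TE
  hypermethylation, TSS depletion), planted differential windows with a
  ground-truth table, read counts, smRNA loci and coupled expression.

## CLI

All stages are subcommands of `methwin`; every threshold can be set in a
YAML config file (`--config`) and the pipeline is fully reproducible under
a fixed `--seed`.

```bash
methwin simulate --seed 1 --out-dir data/             # synthetic dataset + truth
methwin call-mc  --input data/ref.cx.tsv --control-contig ChrC \
                 --out calls_ref.tsv --summary mc.json
methwin profile  --calls calls_ref.tsv --genes data/genes.gff3 --out profile.tsv
methwin call-dmr --test calls_test.tsv --ref calls_ref.tsv \
                 --chrom-lengths lengths.json --out dmrs.tsv
methwin annotate --dmrs dmrs.tsv --genes data/genes.gff3 \
                 --tes data/tes.bed --smrnas data/smrnas.bed --out assoc.tsv
methwin integrate --associations assoc.tsv --expression data/expression.tsv \
                 --genes data/genes.gff3 --out integration.json
methwin report   --inputs mc.json --inputs integration.json --out report.json
```

Input formats: 7-column cytosine reports (chrom, 1-based position, strand,
methylated count, unmethylated count, context, trinucleotide), GFF3 or
BED6 annotations (auto-detected by extension, normalized to 1-based closed
coordinates), and a TSV expression table (gene_id, comparison,
fold_change, p_value).

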