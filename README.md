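# germnet

Germline variation network analysis: a tested, reusable pipeline from
per-position sequencing pileups to a two-feature risk classifier.

The pipeline stages are:

1. **variant_calling** — SNV detection per pileup position with a one-sided
   Fisher exact test (observed alt/ref counts vs an idealised all-reference
   sample of equal depth; depth ≥ 10, p < 0.01), germline/somatic
   classification against a matched normal with coverage-gated absence,
   cross-individual shared-variant intersection, and minimal VCF output.
2. **gene_annotation** — refFlat gene models (0-based half-open UCSC
   coordinates), codon-level consequence calls on either strand, and
   selection of the nonsynonymous gene set that feeds the network stages.
3. **network_analysis** — STRING-style edge tables combined per evidence
   channel with a noisy-OR and thresholded at 0.700 (inclusive); main-graph
   (largest-component) statistics: characteristic path length, shortest-path
   and degree histograms, mean neighbor count, and a log-log least-squares
   power-law fit.
4. **pathway_analysis** — GMT gene sets, per-individual overlap counts,
   hypergeometric top-k ranking, shared-top-k intersection.
5. **risk_classification** — per-individual features (two pathway gene
   counts + main-graph fraction), average-linkage two-group clustering, a
   maximum-margin linear boundary, and the explicit decision rule
   (> 15 genes in the first pathway AND > 10 in the second; main-graph
   fraction > 0.60 reported as a parallel flag).
6. **epidemiology** — 2×2 exposure-by-status tables and crude odds ratios
   with Woolf 95% CIs (z = 1.96; Haldane-Anscombe correction on zero cells).
7. **stats_core** — the exact/asymptotic statistics backing all of the
   above: fixed-margin Fisher exact, hypergeometric tails, exact
   Mann-Whitney U (enumerated null for n ≤ 25), two-sample KS with the
   asymptotic Kolmogorov p-value.
8. **synthetic_data** — a fully deterministic generator for every input:
   genome + gene models, pileups with planted germline/somatic variants
   under a binomial read model on Poisson depths, a preferential-attachment
   interaction network with a planted dense module, pathway files, and
   case-control cohorts with a designed exposure odds ratio. The original
   study cohort was never deposited; these generators are explicit stand-ins
   at desk scale.

## CLI

```bash
# generate a complete synthetic input directory
germnet simulate --outdir sim/ --seed 42

# stage by stage
germnet call     --pileup sim/pileups/IND01_para.tsv --out calls.vcf
germnet annotate --vcf calls.vcf --genome sim/genome.fa \
                 --refflat sim/genes.refflat --out consequences.tsv
germnet network  --edges sim/ppi_edges.tsv --genes genes.txt --out stats.json
germnet pathways --gmt sim/pathways.gmt --genes genes.txt --out top10.tsv
germnet epi      --cohort sim/cohort.csv --out odds_ratios.tsv

# or everything at once from a YAML config (see PipelineConfig fields)
echo "root: sim" > config.yaml
germnet run-all --config config.yaml --outdir report/
```

All intermediate artifacts are plain text (pileup TSV, FASTA, refFlat,
VCF 4.2, STRING-style TSV, GMT, CSV, JSON) and re-readable by the package's
own parsers, so every stage can restart from the previous stage's files.

## Notes on reconstructions

Three pieces of the original analysis are under-specified in the source
material and are implemented as documented reconstructions: the exact 2×2
construction of the Fisher variant caller, the channel-combination formula
for interaction scores (noisy-OR without a version-dependent prior), and
the classifier details (hard-margin linear SVM on the two pathway counts).
Each is flagged in the corresponding module docstring.
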