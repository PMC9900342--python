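# pirnapipe

A tested, reusable pipeline for small-RNA analysis of Piwi-interacting
RNAs (piRNAs): read cleaning and ncRNA decontamination, piRNA
identification against an annotated reference, genomic cluster calling
and counting, sequence-signature characterization (length distribution,
5′U bias, 5′–5′ distance probability with LOWESS smoothing), expression
quantification with a negative-binomial differential-expression
surrogate, and in-silico piRNA target assignment with target-vs-nontarget
modulation statistics.

A first-class synthetic-data module generates genomes, annotations,
reads, and knockdown-vs-control expression tables with planted ground
truth, so every stage is testable offline with no downloads.

## Layout

| Module | Role |
| --- | --- |
| `pirnapipe.io` | FASTA / FASTQ (phred+33) / BED6 / TSV-matrix readers and writers; core domain types |
| `pirnapipe.simdata` | Synthetic genomes, piRNA/ncRNA references, reads, expression tables + truth |
| `pirnapipe.preprocess` | 3′ quality/adapter trimming, length filter, read collapsing, ncRNA decontamination |
| `pirnapipe.discovery` | Zero-mismatch reference matching, exact genome alignment, cluster merging, `-f 1` containment counting |
| `pirnapipe.characterize` | Length distribution, positional nucleotide bias, primary/secondary 5′–5′ distance profile, LOWESS |
| `pirnapipe.expression` | TPM normalization, NB differential-expression surrogate, scaled-MAD outlier filter, ANOVA, z-score/k-means matrices |
| `pirnapipe.targeting` | Annotation categories, sequence-based target sites, per-gene target loads, KS / Spearman statistics |
| `pirnapipe.cli` / `pirnapipe.pipeline` | Subcommand CLI and end-to-end orchestration with a summary JSON |

Default numeric parameters (trim quality 20, minimum insert 25 nt,
identity 80%, ≤1 mismatch, ≥90% query coverage, 100-alignment cap, full
containment intersection, padj ≤ 0.05 with |log2FC| ≥ 1, ±200 nt distance
window, LOWESS span 0.1, 3 scaled MADs, ANOVA α 0.05) live in
`pirnapipe.config.RunConfig` and can be overridden from a JSON/YAML
config file; unknown keys are rejected.

## CLI

```bash
# generate a synthetic dataset with ground truth
pirnapipe simulate --seed 1 --out simdir

# stage by stage
pirnapipe trim simdir/DIF0.fastq --out DIF0.collapsed.fa
pirnapipe filter-ncrna DIF0.collapsed.fa --references simdir/ncrna_reference.fa --out DIF0.clean.fa
pirnapipe discover DIF0.clean.fa --genome simdir/genome.fa \
    --pirna-reference simdir/pirna_reference.fa --out-clusters clusters.tsv
pirnapipe de counts.tsv --conditions ctrl_1=control,ctrl_2=control,kd_1=KD,kd_2=KD --out de.tsv

# full simulate -> analyze -> report path
pirnapipe run-all --seed 1 --out outdir
```

`run-all` writes every stage artifact plus `summary.json` with the
headline statistics (putative/matched read counts, cluster number and
mean length, modal read length, 1U fraction, distance-profile argmax, DE
calls, target loads, KS D and p) and a read-count ledger that reconciles
exactly across stages.

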