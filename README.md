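# synsig

A significance caller for genes enriched in **synonymous** mutations in
cancer cohorts. Each gene's synonymous burden is tested against a
background model built from **non-coding (intron/UTR) mutations**,
corrected for patient-, category-, and gene-level mutational
heterogeneity:

1. **Genome model** — KNOWN protein-coding genes from a Gencode-v19-style
   GTF (principal transcript if supplied, else longest); every possible
   single-nucleotide change is classified into an effect zone
   (synonymous / nonsynonymous / noncoding) and a mutation category
   (CpG/non-CpG × C:G/A:T × transition/transversion, plus indel/null),
   each (position, allele) carrying 1/3 site.
2. **Coverage** — per-patient WIG callability masks folded into the
   21-bin per-gene coverage structure (3 zones × 6 substitution
   categories, plus whole-gene category-7 bins); unreported positions
   count as covered.
3. **Background** — per-gene non-coding counts/coverage pooled with
   covariate-nearest neighbors ("bagels", beta-binomial compatibility
   check), scaled by per-patient and per-category marginal relative
   rates.
4. **Significance** — beta-binomial priors for 0/1/2+ events per
   (category, patient), 2-D projection onto the two most extreme
   mutations, −log10 scoring, cross-patient convolution of the null
   score distribution, and an inclusive tail p-value.
5. **FDR** — empirical-Bayes local FDR (kernel-smoothed null CDF from
   non-expressed genes, FPKM < 1 everywhere; p0 = 0.99) for the
   synonymous mode; Benjamini–Hochberg for the non-synonymous QC mode.

Also included: per-patient synonymous-rate descriptives, sliding-window
chromosome profiles, a motif permutation-enrichment test (the BCL-2/BH4
analysis), and a synthetic-cohort generator that emits every input
format at toy scale.

## CLI

```sh
# write a complete synthetic bundle (GTF, FASTA, MAF, WIGs, tables)
synsig simulate --outdir demo --n-genes 20 --n-patients 8 --seed 1 \
    --base-rate 0.003 --n-null-genes 5 --spike G0010=10

# full per-cohort analysis
synsig run --gtf demo/annotation.gtf --fasta demo/genome.fa \
    --maf demo/mutations.maf --wig-dir demo \
    --covariates demo/covariates.tsv --expression demo/expression.tsv \
    --manifest demo/manifest.tsv --synonyms demo/synonyms.tsv \
    --principal demo/principal_transcripts.tsv --outdir demo/out

# motif permutation test (coordinates in 0-based CDS nucleotides)
synsig motif-test --motifs motifs.tsv --gene BCL2 --motif BH4 \
    --cds-length 717 --n-mutations 39 --observed 9 --seed 1

# per-patient synonymous rates / category fractions
synsig rates --gtf demo/annotation.gtf --fasta demo/genome.fa \
    --maf demo/mutations.maf --wig-dir demo --manifest demo/manifest.tsv \
    --out rates.tsv
```

`synsig run` writes `gene_results.tsv` and `candidates.tsv` with a
provenance header (package version + config hash). Thresholds
(hypermutator 50,000; p-cutoff 0.05; FDR 1e-2; p0 0.99) are flags.

## Layout

```
src/synsig/
  genome.py         gene models, site-effect enumeration, categories
  maf.py            MAF reader, category/zone assignment, filters
  coverage.py       WIG parsing, 21-bin coverage tensors
  background.py     bagels, marginal rates, beta-binomial priors
  significance.py   projection, convolution, p-values
  fdr.py            kernel-CDF local FDR, Benjamini-Hochberg
  heterogeneity.py  rate descriptives, sliding-window profiles
  motif.py          motif permutation test
  simulate.py       synthetic cohorts (tensor- and file-level)
  evaluation.py     replicate experiments used by the acceptance suite
  pipeline.py       per-cohort orchestration
  cli.py            command-line interface
```
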