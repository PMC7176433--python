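# apakit

Alternative-polyadenylation (APA) analysis from 3'-end mRNA sequencing, with a
proteome-integration arm and a fully synthetic study generator so every stage
can be verified against known ground truth.

## What it does

| stage | module | summary |
|---|---|---|
| simulate | `apakit.simulate` | genome FASTA, BED12 gene models, BED6 poly(A)-site annotation, per-read cleavage positions (Dirichlet-multinomial counts, Laplace position jitter), log-normal proteome with abundance-dependent missingness, truth table |
| site calling | `apakit.sites` | cleavage-event extraction from BAM/SAM/BED, 15-nt single-linkage merging, mapping to an annotated site catalogue, 5'UTR/CDS/intron/3'UTR region classification |
| filtering | `apakit.counts` | low-support site filter (>=5 reads in n-1 samples, >=1 in the rest, either condition), <10%-usage filter, unexpressed-gene filter, CPM normalisation |
| usage testing | `apakit.dmtest` | per-gene Dirichlet-multinomial likelihood-ratio test with a shared Cox-Reid-estimated precision, BH adjustment |
| length scoring | `apakit.lengthscore` | weighted mRNA length score (W_i = 1 - (i-1)/(NS-1), distal-first), relative length change, shortening-enrichment chi-square |
| motif profiling | `apakit.motif` | UGUA frequency in +/-200-nt strand-specific flanks of maximum-loss/gain sites, 5-nt sliding window, Gaussian smoothing (sigma 20) |
| proteomics | `apakit.proteome` | median normalisation, consistency filter, downshifted-Gaussian imputation, empirical-Bayes moderated t-test, conditional chi-square battery |
| expression | `apakit.diffexpr` | gene-level aggregation over annotated sites and a simplified NB Wald test (clearly labelled stand-in, not a full NB GLM package) |

All coordinates are 0-based half-open (BED-native); all inputs and outputs are
plain text (FASTA/BED/TSV/SAM).

## CLI

Every stage is exposed under one `apakit` entry point:

```sh
apakit simulate --outdir study/ --seed 3 --n-genes 60 --n-targets 20
apakit sites --reads control_1=study/reads_control_1.bed ... \
    --annotation study/pas_annotation.bed --gene-models study/gene_models.bed \
    --gap 15 --orientation forward --out pas.tsv
apakit counts --counts pas.tsv --design study/design.tsv \
    --min-major 5 --min-minor 1 --min-fraction 0.10 --min-mean 5 \
    --out filtered.tsv --cpm-out cpm.tsv
apakit dmtest --counts filtered.tsv --design study/design.tsv --out apa.tsv
apakit lengthscore --cpm cpm.tsv --design study/design.tsv --apa apa.tsv \
    --proportion-based --out results.tsv
apakit motif --genome study/genome.fa --cpm cpm.tsv --sites pas.tsv \
    --apa results.tsv --design study/design.tsv --out profiles.tsv
apakit proteome --intensities study/proteome.tsv --design study/design.tsv \
    --seed 1 --out protein_results.tsv
apakit diffexpr --counts study/site_counts.tsv --design study/design.tsv \
    --out expression.tsv
```

## Notes

- The length score is, by definition, a weighted CPM sum, so expression
  changes leak into it; `length_scores(..., proportion_based=True)` provides
  a within-gene usage-fraction variant bounded in [0, 1], which is also what
  the motif non-target threshold (|change| <= 0.05) assumes.
- `lrt_apa` defaults to a single study-wide precision (Cox-Reid adjusted
  profile likelihood across genes); `precision="genewise"` restores
  strictly per-gene estimation, which is anti-conservative in 3-vs-3 designs.
- The NB differential-expression test is deliberately simplified (no
  dispersion shrinkage, no outlier or independent filtering) and labels its
  output accordingly.
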