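# arrayqc

Automated quality control for genotyping-array data in standard PLINK
format.

Genotyping arrays remain the workhorse of large genetic association
studies, and public repositories hold thousands of array datasets of
uneven quality — mislabelled sex and race, contaminated samples, and
systematically miscalled variants all survive into downstream analysis
unless they are caught early. `arrayqc` is a desk-scale toolkit for
exactly that triage: it reads a PLINK fileset (binary `.bed/.bim/.fam` or
text `.ped/.map`), computes the standard per-sample and per-variant QC
metrics, and renders everything into one self-contained HTML report plus
machine-readable TSV tables. It is aimed at analysts receiving array data
of unknown provenance — their own lab's or a public cohort's — who need a
defensible pass/flag summary before modelling.

## What it computes

- **Call rates.** Sample call rate = fraction of the study's variants
  called in a sample; variant call rate = fraction of samples called at a
  variant; both summarised over a threshold ladder (0.90/0.95/0.98/0.99).
  Y-chromosome variant call rates are assessed within males only.
- **Minor allele frequency.** Per-variant alt-allele frequency and
  MAF = min(q, 1−q) over diploid regions, with Pearson concordance against
  an optional reference panel's MAF table.
- **Sex check.** The chromosome-X inbreeding coefficient
  F = (O − E)/(N − E), where O is a sample's observed homozygote count
  over non-PAR X variants, N its called count, and
  E = Σⱼ [1 − 2pⱼ(1−pⱼ)·nⱼ/(nⱼ−1)] the count expected under
  Hardy–Weinberg. Hemizygous males read as homozygous, so F ≈ 1
  (expected range 0.98–1); diploid females sit near 0 (−0.3–0.2).
  Pseudo-autosomal regions are classified out beforehand and reported sex
  is flagged, never rewritten.
- **Hardy–Weinberg equilibrium.** The exact conditional test (two-sided,
  log-space enumeration over heterozygote counts), run race by race —
  allele frequencies differ across ancestries, so a pooled test confounds
  population structure with genotyping error — optionally on controls
  only, with per-stratum Bonferroni adjustment at α = 0.05.
- **Heterozygosity ratio.** Per sample, #heterozygous / #non-reference
  homozygous calls over diploid variants. Its theoretical expectation is 2
  (at allele frequency ½, 2pq/q² = 2) but it is strongly
  ancestry-dependent, so outliers are flagged relative to the race-stratum
  median: exceedingly high values indicate contamination, exceedingly low
  values inbreeding.
- **Ancestry PCA.** Principal components of variance-standardized
  genotypes ((g − 2p)/√(2p(1−p))) over MAF/call-rate-filtered, LD-pruned
  autosomal variants; PC1-vs-PC2 clusters are checked against reported
  race by robust nearest-centroid distance.
- **Duplicate concordance.** Dosage agreement between designated duplicate
  samples and between variants probed twice, allele-swap aware.

A synthetic-cohort generator (`arrayqc.simulate`) draws PLINK filesets
with controlled structure — HWE or planted violations, hemizygous male X,
missingness, duplicate pairs, pooled-DNA contamination, divergent
populations — so the whole suite is testable without external data.

## Worked example

Simulate a small cohort and run the full pipeline:

```sh
cat > spec.yaml <<EOF
n_samples: 40
n_variants: 300
n_x: 150
seed: 12
EOF
arrayqc simulate --spec spec.yaml --out sim
arrayqc run --bfile sim --meta sim.meta.tsv --out qc_out --seed 3
```

which prints

```
wrote sim.bed/.bim/.fam and sim.meta.tsv (40 samples x 450 variants)
report written to qc_out/qc_report.html
2 flagged items
```

(450 variants = 300 autosomal + 150 X.) `qc_out/qc_report.html` is a
single portable file; `qc_out/tables/` holds every underlying table as
TSV. The two flags land in `qc_out/tables/flag_summary.tsv`:

```
item_type	id	stage	reason
sample	S36	sex_check	X inbreeding F=0.219 outside expected ranges
sample	S39	het_ratio	heterozygosity ratio 6.947 high vs stratum median 3.885
```

Both are sampling noise made visible: at only 150 X variants the female
inbreeding estimate is noisy enough for one sample to graze past the 0.2
ceiling, and one sample's heterozygosity ratio strays beyond 1.5× the
cohort median — exactly the kind of borderline case the report surfaces
for a human decision rather than silently dropping. Individual stages run
standalone too, e.g. `arrayqc sexcheck --bfile sim`, and the library API
mirrors the CLI (`arrayqc.run_pipeline`, `arrayqc.sex_check`,
`arrayqc.hwe.hwe_scan`, ...).

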