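# mirtisect

Detection of **tissue-enriched (TE)**, **tissue-specific (TS)** and
**organ-specific (OS)** miRNAs from a multi-tissue small-RNA-seq count
matrix, for researchers who profile miRNA expression across a body atlas
(e.g. biomarker qualification or toxicology panels) and need to know which
miRNAs are confined to — or strongly enriched in — one tissue or organ.

Three complementary pipelines answer the question from different angles, so
their agreement can be used as a confidence measure:

1. **NMF** — replicate counts are summed per tissue, collapsed to organs by
   element-wise maximum, stratified into high-/low-expression groups with a
   two-component Poisson mixture (EM), and each stratum is factorized,
   `X ≈ WH` (generalized Kullback–Leibler loss, multiplicative updates).
   With rows of `W` and `H` normalized to sum to 1, `W_norm H_norm` is each
   miRNA's share-of-total-expression across organs; a share ≥ 0.6 gives TE,
   ≥ 0.8 gives OS, and a TS call additionally requires the OS call.
2. **Quasi-Poisson one-vs-rest** — per miRNA, a log-link GLM with variance
   φμ on per-million-ceiled counts contrasts one tissue (or organ) against
   the pooled rest; Wald *t*-test with Pearson-χ²/df dispersion. TE: *p* <
   α (default 0.05) with positive direction. TS: a TE miRNA whose mean is
   ≥ 90 percentage points above the maximum mean of any other tissue.
3. **Proportion of total** — counts are divided by each miRNA's number of
   genomic loci, TMM-normalized and floored (≥ 10 TMM in at least one
   sample); TE when one tissue holds > 0.5 of the summed group means, TS/OS
   when it holds > 0.9.

The package also computes the **tissue-specificity index**

```
TSI_j = Σ_i (1 − x_ij) / (N − 1),   x_ij = mean_ij / max_i mean_ij
```

(0 = ubiquitous, 1 = exclusive), compares call sets across pipelines as
exact Venn regions (with optional identifier reconciliation through an
alias table), reports tissue-dependent dominant isomiRs, and ships a seeded
negative-binomial atlas simulator with planted TE/TS/OS miRNAs whose
default layout is the 23-tissue / 14-organ rat body-atlas design.

## Worked example

Simulate a default-layout atlas (215 samples) with a liver-specific miRNA
planted at fold 1000 and a Brain-organ miRNA at fold 200, then run all
three pipelines against the liver:

```sh
mirtisect simulate --n-mirnas 50 --seed 7 \
    --plant 0:liver:1000:TS --plant 1:Brain:200:OS --out-prefix sim
mirtisect detect --counts sim.counts.tsv --samples sim.samples.tsv \
    --annot sim.annotation.tsv --target liver --seed 7 --out-prefix demo
```

`demo.proportion.calls.tsv` begins

```
mirna_id      pipeline    status  target  score    p_value
syn-miR-0001  proportion  TE      liver   0.98377
syn-miR-0001  proportion  TS      liver   0.98377
```

i.e. the planted miRNA carries 98.4 % of its total mean expression in
liver, above both the 0.5 (TE) and 0.9 (TS) bars. The quasi-Poisson
pipeline agrees (`coefficient 4.11` ≈ log fold, `p = 9.3e-168`, excess
99.9 percentage points), the NMF pipeline calls it TE/OS/TS in the Liver
organ with share 0.991, and its TSI in `demo.tsi.tsv` is 0.9993. The
cross-pipeline report `demo.overlap.csv` puts it in the three-way region:

```
region                        n  members
nmf                           1  syn-miR-0002
nmf&proportion&quasipoisson   1  syn-miR-0001
```

(the Brain-planted miRNA appears only in the NMF set because the other two
pipelines were asked about liver).

Everything is also available as a library — see `mirtisect.run_detection`,
`mirtisect.compute_tsi`, `mirtisect.generate_atlas`, and the per-pipeline
functions (`run_nmf_pipeline`, `fit_one_vs_rest`, `run_proportion_pipeline`).

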