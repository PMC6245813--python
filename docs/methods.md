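# Methods

## Data model

The universal input is a non-negative miRNA × sample matrix plus a sample
sheet mapping each sample to a tissue and each tissue to exactly one organ.
The packaged default grouping is the 23-tissue / 14-organ rat body-atlas
layout (kidney cortex/kidney/medulla → Kidney; glandular and non-glandular
stomach → Stomach; duodenum/ileum/jejunum → Intestine; brainstem/cerebellum/
cerebrum/hippocampus → Brain; biceps/soleus → Muscle; the other nine tissues
are their own organs). A user-supplied map replaces the default entirely —
merging two maps silently is a recipe for mixed-up groupings. Samples present
in the count matrix but missing from the sample sheet are a hard error, never
silently dropped: sample exclusions should be an explicit, documented input
decision. Identifier matching is exact and case-sensitive after trimming
surrounding whitespace, because case-folding would hide annotation errors.

Organ aggregation takes the element-wise **maximum** over member-tissue
columns rather than the mean: averaging would dilute an organ signal carried
by a single member tissue (e.g. one brain region). When the NMF pipeline
builds its organ matrix it aggregates per-tissue **summed** counts (pooling
replicates); displayed tables use per-group **means** of TMM values. These
two conventions coexist deliberately: sums feed the count-based model,
means are the human-readable expression summary.

## TMM normalization

`tmm_factors` implements the trimmed mean of M-values with the standard
defaults: reference sample = the one whose 75th-percentile count fraction is
closest to the sample mean; per sample, M (log2 ratio) and A (average log2
abundance) are computed over miRNAs positive in both libraries, doubly
trimmed (30 % of M, 5 % of A, rank-based), and combined by a
precision-weighted mean with delta-method binomial weights. Genes with a
zero in either library of a pair are excluded (their log-ratio is
undefined). Factors are rescaled to geometric mean 1 so they are comparable
across runs; normalized expression is `count / (library × factor) × 1e6`.
The implementation reproduces edgeR's `calcNormFactors(method="TMM")` to
nine decimal places on a frozen toy matrix (see the test suite).

A note on naming: the per-million transform used ahead of the quasi-Poisson
model is reads-per-million followed by an element-wise ceiling (so a count
model can be fit to integers). It is sometimes labelled "TPM" in the miRNA
literature, but no transcript-length normalization is involved.

### Filters

Each pipeline has its own abundance floor, applied exactly as stated by its
authors: strictly `> 10` (NMF) or `> 3` (quasi-Poisson) summed counts in at
least one tissue/organ; for the proportion pipeline, rows whose TMM value is
`< 10` in **all** samples are removed (i.e. one sample at exactly 10 keeps
the row). Filtering is idempotent and preserves row order.

## NMF pipeline

**Why stratify first.** A single factorization of a matrix spanning five
orders of magnitude is dominated by the most abundant miRNAs; a weakly
expressed but perfectly specific miRNA contributes almost nothing to the
objective and is absorbed into diffuse factors. A two-component Poisson
mixture is therefore fitted by EM to each miRNA's total organ-level count;
miRNAs with posterior probability of the high component > 0.5 form the high
stratum (ties go low), and NMF runs per stratum. The regression test
`test_stratification_rescues_low_expression_specific_mirna` demonstrates the
failure mode the stratification exists to prevent. Fitting the mixture to a
per-miRNA level statistic (the total count) is our reading of "stratify by
expression level": it is the choice that makes a per-miRNA high/low split
actionable. All-equal inputs are returned flagged `degenerate` rather than
silently fitted.

**Factorization.** Generalized Kullback–Leibler loss (the Poisson-compatible
divergence for counts) minimized by multiplicative updates, ε = 1e-12 inside
divisions; seeded random initialization, 10 restarts by default, best final
objective wins with ties broken by restart index, so results are
deterministic given the seed. The rank defaults to the number of organs (14
in the default layout) — each factor can then specialize to one organ; it is
capped at the stratum size. The objective trace is retained and asserted
non-increasing.

**From factors to calls.** The returned factorization is canonically scaled
(each factor's H row sums to 1, scale absorbed into W). A miRNA's organ-share
vector is its row-normalized W row times H — algebraically the row-normalized
reconstruction `WH`, i.e. a genuine "% of total expression" vector. The exact
post-normalization scheme behind published share thresholds is not uniquely
determined by their description; this construction is one defensible reading
and is the package's own design choice. TE requires share ≥ 0.6 (by default
a miRNA may be TE in several organs; `te_mode="exclusive"` restricts TE to
the case of a single qualifying organ, the alternative reading of "60 % in
more than one tissue/organ"). OS requires the maximal share ≥ 0.8; TS
requires in addition that only one organ reaches that bar, so TS ⇒ OS holds
by construction. Thresholds are compared with ≥; whether the published rules
meant strict inequalities at the 0.6/0.8 boundary is immaterial for
measure-zero events and the non-strict form keeps the documented examples
true.

## Quasi-Poisson pipeline

Per miRNA, a log-link GLM with design `[1, target-indicator]` is fit by IRLS
to the per-million-ceiled counts (no offset term — the per-million transform
has already equalized depth). The dispersion φ is Pearson χ²/df; the target
coefficient (log mean ratio) is tested with a Wald statistic against a *t*
distribution on n−2 df. Two-sided p with a separate positivity condition is
the conservative reading of "significant with a positive difference".
Nominal p-values are the default (that is what the rule says);
Benjamini–Hochberg is available behind a flag. The implementation is a
deliberate simplification of spline-adjusted quasi-likelihood machinery:
plain IRLS + Pearson dispersion + t reference. It agrees with an independent
IRLS implementation (statsmodels GLM with Pearson scale) to < 1e-6 in
coefficient and p-value.

Degenerate inputs: an all-zero miRNA returns p = 1, coefficient 0, flagged
`all_zero`. Complete separation (one side all zero) cannot be Wald-tested;
rather than inject pseudocounts the coefficient is capped at ±700, p is set
to 0 and the result flagged `separation` — the evidence for a group
difference is unbounded, and the flag makes the condition auditable.

TS applies a percentage-point margin on TMM group means to TE calls only
(TS ⊆ TE enforced): `excess` mode (default) requires
`100·(mean_t − max_other)/mean_t ≥ 90`; `share` mode requires the target
mean to hold ≥ 90 % of the summed group means. Both are exposed because the
published wording ("a number of percentage points above the maximum mean
expression") is not a formula and its worked table admits rows that fail
every natural reading; neither mode is asserted as ground truth. OS uses
the same model and manner as TE with organ-vs-rest grouping; by default no
percentage-point rule is applied to OS (that rule belongs to TS), but one
can be requested.

**Calibration design.** The type-I-error check uses 1,000 null miRNAs with
NB(mean 100, size 5) counts in 23 groups of 5 samples, one-vs-rest on the
first group — the shape of the atlas contrast at its reduced-replicate
sample size. Under a common mean the quasi-Poisson variance φμ absorbs the
NB overdispersion exactly, so the empirical rejection rate at α = 0.05 lands
near nominal (0.03–0.07); planted 10× miRNAs are recovered at ≥ 95 %
sensitivity, and the dispersion estimate is ≈ 1 under true Poisson noise and
≫ 1 under NB(size 2).

## Proportion pipeline

Counts are divided by the miRNA's number of assigned genomic loci (a read
mapping to k loci would otherwise be counted k times), TMM-normalized,
floored, averaged within groups, and converted to row shares. Shares are
computed on per-group **means** (consistent with the displayed TMM means);
a raw-count mode (`use_tmm=False`) supports the literal reads-aligned
reading. TE: top share > 0.5; TS (tissue) / OS (organ): top share > 0.9 —
strict inequalities exactly as published. Zero-total miRNAs are excluded
with a warning.

IsomiR dominance: within a tissue, an isomiR's proportion is its mean count
over the summed mean of all isomiRs of the same mature miRNA; the dominant
isomiR is the argmax (exact ties broken lexicographically and flagged), and
a mature is reported when its dominant isomiR is not identical across
tissues. The literal "differs between **all** tissues" (pairwise
all-different) reading is unusable for more than a handful of isoforms, so
"not identical across tissues" is implemented.

## Tissue-specificity index

`TSI_j = Σ_i (1 − x_ij)/(N − 1)` with `x_ij` the group mean normalized by
the row maximum; computed on TMM group means. It is scale-invariant per
miRNA, 0 for uniform and 1 for exclusive profiles, and strictly decreases
when any off-maximum tissue rises. Ties for the row maximum do not affect
the value (the formula only uses the max). Zero rows are excluded with a
warning; N ≥ 2 is required. Comparative use against a second atlas is
supported simply by computing TSI on any user-supplied means matrix.

## Cross-pipeline comparison

Identifier reconciliation maps each pipeline's ids through an optional
two-column alias table (identity by default; the table must be functional,
and within-set collisions are deduplicated with a warning). Overlap of two
or three sets is an exact region partition: regions are disjoint, cover the
union, and are exported as CSV with member lists.

## Synthetic atlases

The generator's defaults are the study conditions the package is validated
under: the 23-tissue / 14-organ layout with 10 samples per tissue (5 per
sex) and 5 for the sex-specific ovary, uterus and testicle (215 samples);
300 miRNAs; NB noise with baseline mean 100 and size 5 (typical of
moderately expressed miRNAs with biological replication); log-normal
library-size factors with σ = 0.25; locus counts drawn from {1, 2, 3} with
probabilities (0.80, 0.15, 0.05). Planted effects multiply the baseline mean
by a fold in the target tissue (or in every tissue of a target organ).
Poisson noise is available via `dispersion=inf`. Output is deterministic per
seed.

What the generator does **not** emulate: the heavy-tailed abundance
distribution of real miRNomes (a handful of miRNAs taking most of the
library), sequence-dependent ligase bias, correlated animals across tissues,
batch effects, and sparse low-input libraries. Passing recovery tests on
these atlases therefore demonstrates the pipelines' logic and calibration
under controlled noise, not end-to-end performance on real atlas data.

The isomiR generator gives each mature miRNA isoforms at expected
within-mature proportions (0.7/0.2/0.1 by default) at high counts, with
optional per-tissue dominance switches.

## Problem sizes and numerics

Validation runs use a 300-miRNA, 215-sample atlas with 20 planted
tissue-specific miRNAs at fold 1000 over four target tissues — large enough
that every pipeline's grouping logic (including multi-tissue organs) is
exercised, small enough to run in seconds. Numerical guards: ε = 1e-12 in
NMF divisions and mixture weights; NMF convergence when the objective change
is ≤ 1e-6 relative; EM convergence at |Δ log-likelihood| < 1e-8; IRLS
convergence at 1e-10 on coefficients; dispersion floored at 1e-12. Tables
round-trip at 6 significant digits.

## Known limitations

- The NMF share construction is one defensible reading of an underspecified
  post-normalization; other constructions would shift shares near the
  thresholds.
- The quasi-Poisson model ignores sex and animal pairing; a miRNA with
  strong sex dimorphism in a mixed-sex tissue inflates the dispersion and
  loses power.
- The NMF pipeline provides no statistical inference — shares have no
  p-values; agreement across pipelines is the intended confidence proxy.
- TMM assumes most miRNAs are not differentially expressed between samples;
  atlases violating this (e.g. a tissue dominated by one miRNA family)
  shift factors.
- Organ aggregation by maximum makes OS calls sensitive to a single
  outlying member tissue by design.
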