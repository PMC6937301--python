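# Methods

## Presence calling and thresholds

Expression is a tri-state property per (gene, dataset): *expressed*,
*not_expressed*, or *not_measured* (the gene is absent from the platform's
measured universe). The thresholds live in one `ThresholdConfig`:

| parameter | default | units | reading |
|---|---|---|---|
| `min_reads` | 5 | raw reads | strict: a count of exactly 5 fails ("greater than five") |
| `min_samples` | 1 | samples | "in at least one replicate" |
| `array_min_intensity` | 40 | raw intensity units | inclusive: 40 qualifies (a *minimum* threshold) |
| `ct_max` | 33 | qPCR cycles | strict: CT above 33 is beyond quantification |
| `fold_validation` | 1.5 | fold | inclusive by default (`fold_boundary_inclusive`) |
| `fdr_cutoff` | 0.10 | — | strict: significant means q < 0.10 |

Thresholds apply to **raw** read counts; normalized input is rejected at
parse time (counts must be integers). Microarray probes are averaged over
array replicates first, then a gene is expressed if *any* of its probes
passes — probes are redundant detectors of one transcript. The per-gene
averaged-replicate convention is a design choice; per-array application is
possible by calling the probe-level function directly.

### Oocyte consensus and the provisional rule

The two oocyte references (one microarray, one RNA-seq) are reconciled per
gene: found in both → expressed; found in neither → not expressed; found
in exactly one → *ambiguous*, which the classifier turns into the
*provisional* label. `not_measured` counts as not-found here, so
"expressed in one reference, absent from the other's universe" is still
ambiguous: absence of evidence on one platform must not create a
confident call. The alternative reading — treating an unmeasured
reference as confirming — would silently promote single-platform
detections and was rejected.

Sperm has a single dataset, so its `not_measured` is treated as
not-found directly; there is no sperm-side provisional state.

## Origin classification

Only embryo-expressed genes are classified (genes below the embryo
presence call are omitted). The label is a pure function of
(sperm status, oocyte consensus): both → `sperm_and_oocyte`, sperm only →
`sperm_only`, oocyte only → `oocyte_only`, neither → `embryo_only`,
ambiguous consensus → `provisional`. The five labels partition the
embryo-expressed set; the summary's invariants (four confident counts sum
to the confident total; confident + provisional = embryo-expressed) are
validated at construction and re-checked against raw rows on every run.
Provisional genes are reported but excluded from the confident counts.
Gene identifiers are harmonized by exact string match after probe→gene
mapping; no fuzzy symbol matching.

## Differential expression

Counts are modeled negative-binomial with mean *m* and variance
*m* + φ*m*² (φ = 0 reduces to Poisson). The stage mirrors the classic
exact-test workflow for two-group comparisons:

- **Library-size equalization**: each sample is scaled to the
  geometric-mean depth and rounded to integers. The exact test conditions
  on a gene's total count, which requires exchangeable samples; this
  simple documented equalization achieves that without importing a
  full quantile-adjustment machinery.
- **Common dispersion** (no tagwise/trended shrinkage): maximized
  Cox–Reid adjusted profile likelihood with group-wise gene means
  profiled out, optimized on the log scale over [1e-8, 10]. The CR
  adjustment (−½ log of the observed information about each profiled
  mean) matters: plain profile ML is biased low by roughly a factor
  (n−1)/n at n = 3 per group, which would make the exact test
  anti-conservative. Estimates pinned at the lower bound are reported
  as 0 (Poisson).
- **Exact test**: conditioned on the total t, the group-A sum follows
  the convolution of two NB sums (a sum of n iid NB(size r, p) is
  NB(size n·r, p)); the two-sided p-value sums the probabilities of all
  splits with probability ≤ the observed one, ties included at relative
  tolerance 1e-12 (no doubling).
- **BH step-up**, hand-implemented: q₍ᵢ₎ = min over j ≥ i of
  min(1, p₍ⱼ₎·m/j); cross-checked in tests against an independent
  step-up oracle and statsmodels.
- log2 fold change is high-over-low on normalized group means with a 0.5
  pseudo-count per mean.
- The pre-test filter is the embryo presence call itself, so the tested
  universe equals the expressed-gene universe; filtered genes carry
  `tested = False` and NaN statistics.

The design is unpaired two-group; a pairing of high/low samples by IVF
replicate is not modeled.

## qPCR validation

ΔCT = CT_target − CT_reference per condition, ΔΔCT = ΔCT_case −
ΔCT_control, fold = 2^−ΔΔCT. Any of the four CTs missing or above
`ct_max` makes the replicate unquantifiable — a value, not an error. The
reference gene is chosen among candidates as the one with the smallest
standard deviation of quantifiable CTs across all samples (ties break
lexicographically); an M-value-style stability metric was considered but
the simple CT-SD proxy is transparent and sufficient for the plate sizes
involved. Per-replicate validation is direction-aware: fold ≥ 1.5 for
genes called up in sequencing, fold ≤ 1/1.5 for genes called down.
The cross-replicate significance test is a paired t-test **on ΔCT
values**, not on folds: t = mean(d)/(sd(d)/√n), df = n−1, two-sided.
Degenerate cases: zero difference variance with zero mean → p = 1; with
nonzero mean → t infinite, p = 0, with a warning. The per-gene "mean
fold" is the arithmetic mean of replicate folds by default (geometric
available via `fold_average="geometric"`), since the publication-style
summary tables this mirrors report arithmetic averages.

## Phenotype rates

Cleavage rate = cleaved / oocytes inseminated; blastocyst rate =
blastocysts / **cleaved** embryos. Arm comparisons are paired by
replicate: percent change = 100·(mean treated − mean control)/mean
control on replicate-mean rates (the percentage-point difference is
reported alongside, since "an X% increase" can be read either way), and
the p-value is the same paired t-test, shared with the qPCR module.

## Synthetic data generator

The generator emulates the study design: 6 embryo RNA-seq samples (3 per
fertility group), 2 sperm samples, 2 oocyte RNA-seq replicates, a
one-probe-per-gene microarray with 3 arrays, 3-replicate qPCR plates, and
paired treated/control tallies. Defaults, chosen once as realistic desk-
scale conditions (the source study reports no distributional parameters
for its libraries, so these are not claimed to match any real dataset):

- `nb_mean = 100` expected counts for an expressed gene;
  `nb_dispersion = 0.2` (typical biological-replicate overdispersion);
  `background_mean = 0.5` for not-expressed genes — NB, not structural
  zero, so threshold behavior is exercised.
- Origin mixture 0.377 / 0.363 / 0.066 / 0.094 (both / oocyte / sperm /
  embryo-only), proportioned after the published four-category breakdown,
  plus a 0.100 provisional slice.
- `de_fraction = 0.05`, `de_log2fc = 3`; DE genes split the two embryo
  group means symmetrically around `nb_mean`.
- Array intensities are log-normal around 500 (expressed) or 10
  (background) with log-sd 0.2; both margins sit many sigmas from the
  40-unit cutoff, so array noise alone essentially never flips a call.
- qPCR: the planted fold f enters as ΔΔCT = −log2 f in expectation;
  independent N(0, 0.25²) cycles of noise per CT. ΔΔCT is unbiased, so
  folds are unbiased on the log (geometric-mean) scale; the arithmetic
  mean of noisy folds is log-normally inflated by construction, which is
  why Monte-Carlo checks of the generator average log2 folds.
- Tallies: cleaved ~ Binomial(oocytes, 0.80); blastocysts ~
  Binomial(cleaved, 0.35 control / 0.43 treated), i.e. a planted 22.86%
  relative increase.
- One named RNG stream per generator, all derived from the single global
  seed, so adding a generator never perturbs the others; identical
  configs give bit-identical output.

Provisional genes are planted as expressed in exactly one oocyte
reference (coin flip which), and independently may or may not be
sperm-expressed — the provisional label is oocyte-driven either way.

What the generator does **not** emulate: amplification (WTA) bias, probe-
level array chemistry, gene-length or GC effects, correlated library
composition, or any real biological covariance between datasets. Passing
recovery tests therefore demonstrates correctness of the decision logic
and the statistics under the stated model, not robustness to real-data
artifacts.

## Numerical choices and problem sizes

- Exact-test pmfs are computed in log space and renormalized; totals of 0
  return p = 1.
- The dispersion optimizer is bounded scalar minimization with xatol 1e-6
  on log φ.
- Equalized counts are rounded to the nearest integer; rounding noise is
  negligible at the default depths.
- Test and acceptance runs use 2,000–10,000 genes and the default sample
  sizes; these sizes give sub-minute runtimes while leaving Monte-Carlo
  margins (e.g. binomial sampling error of recovery percentages) far from
  the asserted bounds.

## Known limitations

- Common dispersion only; genes with gene-specific overdispersion are not
  modeled, matching the minimal faithful reading of the published
  workflow.
- The unpaired exact test ignores any IVF-replicate pairing of embryo
  samples.
- No amplification-efficiency correction in the ΔΔCT stage (no Pfaffl
  correction, no standard curves).
- The reference-gene stability proxy (CT SD) is simpler than geNorm-style
  pairwise stability measures.
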