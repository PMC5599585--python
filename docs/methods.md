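# Methods

`methvar` implements the analysis of a two-color CpG-microarray methylation
study of canine diffuse large B-cell lymphoma (cDLBCL): tumors are compared
with control lymph nodes to find differentially methylated sequences, to
discover epigenetic subtypes, and to score each tumor's genome-wide
*methylation disruption*. This note records the models, the parameters that
matter, and the numerical choices, including where a design question was
genuinely open and what we chose.

## Assay model

Each probe measures the log2 ratio between a methylation-enriched DNA
fraction and a non-enriched input of the same sample (Cy5/Cy3 competitive
hybridization). Probes tile target sequences — CpG regions (~2.8 probes
each) and coding sequences (~100 probes each). A sequence's methylation
level is the median of its probe signals; the β value
`β = 2^m / (2^m + 1)` maps the log2 ratio `m` onto a methylation proportion
in (0, 1) with `m = 0 ↔ β = 0.5`. The array design excludes chromosome X.

## Preprocessing

1. **Dye-bias loess correction** (per array): a lowess curve of log2 ratio
   versus mean log2 intensity (span 0.3, `statsmodels` with a speed `delta`)
   is subtracted and residuals re-centered to the array median. Re-centering
   matters because methylation log-ratios, unlike expression M-values, are
   not globally zero-centered.
2. **Array QC**: arrays whose median or spread (MAD) of log2 ratios is a
   robust-z outlier (> 5) *and* deviates by a practical margin (median by
   > 0.5 log2 units; spread by > 50% of the typical spread) are dropped.
   The magnitude floors exist because with ~37 near-identical tumor arrays
   the across-array MAD is tiny, and a pure z threshold flags the control
   group's ordinary biological difference — losing controls is fatal for
   the rank test (with 37 vs 5 the minimal exact p exceeds a genome-wide
   Bonferroni threshold).
3. **Quantile normalization** across all QC-passed arrays at probe level:
   every sample's sorted vector is replaced by the across-sample mean of
   sorted vectors; ties share averaged ranks; re-application is exactly
   idempotent (identical-marginal inputs take an exact code path so no
   floating-point drift accumulates).
4. **Aggregation**: per-sequence, per-sample median over probes.
5. **Low-methylation filter**: a sample counts as *enriched* at a sequence
   when β ≥ 0.5 (threshold configurable; the source material never defines
   "enriched" numerically, so we align it with the β dichotomy). A sequence
   is retained iff the enriched fraction reaches 25% in the tumor group
   **or** in the control group. The OR rule keeps sequences that are
   methylated only in controls, preserving tumor hypo-methylation signal.

## Differential methylation and variability

- **Level**: two-sided Mann–Whitney–Wilcoxon per sequence, Bonferroni over
  the sequences actually tested (the post-filter set, ~30k), significance
  at adjusted p < 0.01. With 7 controls the exact tail is material, so the
  null distribution of U is computed exactly (Gaussian-binomial recurrence,
  vectorized over sequences) whenever the smaller group has ≤ 8 samples and
  the row is tie-free; otherwise a normal approximation with tie and
  continuity corrections is used. Two-sided p = 2·min(P(U≤u), P(U≥u)),
  capped at 1; direction is the sign of (median tumor − median control).
  The implementation matches `scipy.stats.mannwhitneyu` to 1e-9 in tests
  but runs the genome-wide pass in milliseconds.
- **Variability**: two-sided variance-ratio F test on the study's binary
  clinical pairings (stage III–IV vs V; substage a vs b; extranodal;
  CH vs CH+VAX; steroid pre-treatment; relapse coded both as yes/no and as
  before-end vs after-end+never). Rows constant in both groups are flagged
  and excluded from the correction.
- **Multivariate**: per-sequence OLS of methylation on a covariate set,
  dummy-coded against first levels, overall-model F p-value with
  Bonferroni; rank-deficient designs are rejected naming the collinear
  columns.
- **Fisher's exact test** is implemented with exact integer hypergeometric
  arithmetic under the two-sided *minlike* convention (sum of all tables
  with probability ≤ observed). Exact integer comparison makes tie handling
  reproducible to the bit; `scipy.stats.fisher_exact` (which uses a small
  relative fudge on the threshold) serves as an independent cross-check in
  tests. Used for genomic-location enrichment (multi-label sequences count
  once per overlapped category; background = all tested sequences) and for
  the β-dichotomized per-sequence group test.

## Epigenetic subtyping

PCA is computed over tumor samples with sequences centered. Sequences whose
methylation vector has |Pearson r| > 0.85 with a retained principal
component's score vector are selected; tumors are then clustered on the
selected sequences (centered and scaled per sequence) by agglomerative
Ward/Euclidean clustering (scipy's Ward.D2-style criterion, deterministic).
k is user-chosen (the study context suggests 3) or selected by maximal mean
silhouette over k ∈ 2..6. Cluster–clinical association uses Fisher (2×2),
chi-square (larger tables) and Kruskal–Wallis (continuous), Bonferroni
across factors. Survival is compared with Kaplan–Meier curves and the
two-group log-rank test; besides the asymptotic chi-square p, a permutation
p (exhaustive over label assignments when the comparison has ≤ 20 samples)
is available, which is exact at small n where the chi-square approximation
is poor.

## Methylation disruption

For every sample, the *change* at a sequence is its level minus the median
level across control lymph nodes. A sample's **methylation variability
profile (MVP)** is a Gaussian KDE of its change distribution evaluated on a
grid shared by all samples (pooled 0.1–99.9 percentile range, 512 points),
renormalized to integrate to 1. The distance between two samples is the
**L1 distance** between their MVP curves — the area bounded by the two
densities, which is twice the total-variation distance and bounded by 2.
(The literal "signed difference of areas under the curves" of two
normalized densities is identically zero, so the absolute-area reading is
the only non-degenerate one.) The **Methylation Variability Score (MVS)**
is the L1 distance between a tumor's MVP and the renormalized pointwise
median of the control MVPs: the higher the MVS, the greater the disruption.

Two numerical choices matter here and were forced by measurement:

- **Shared bandwidth for compared profiles.** `mvp()` defaults to
  Silverman's rule of thumb with the robust spread estimate,
  `0.9·min(sd, IQR/1.34)·n^(−1/5)`. But profiles that are *compared* (MVS,
  consensus clustering) all use one bandwidth equal to the robust SD
  (IQR/1.34) of the pooled changes. Per-sample optimal bandwidths resolve
  sample-specific fine structure of the quantile-normalized bulk — an
  artifact that anti-correlates with true disruption — whereas a common,
  scale-matched bandwidth makes curve differences reflect which sequences
  deviate and by how much. It is also independent of the sequence-subset
  size, keeping profiles comparable across consensus subset sizes.
- **Leave-one-out control reference.** Each control's reference changes are
  taken against the median of the *other* controls. With an odd handful of
  controls, the plain control-vs-own-median change vector contains an atom
  of exact zeros (each control is itself the per-sequence median for a
  share of sequences), which makes the reference density artificially
  spiky and lets the spike mismatch dominate every distance.

**MAD ranking** orders sequences by decreasing median absolute deviation
(unscaled; the 1.4826 normal-consistency factor is an option) of the tumor
changes, ties broken by sequence id. **Consensus clustering** restricts to
the top-MAD subset (250–20,000), builds one MVP per tumor on that
restriction, and repeatedly (default 1,000×) clusters a random 80% of the
tumors with average linkage on the MVP L1 distance (Ward is not used here
because the L1 profile distance is not Euclidean). The consensus entry for
a pair is co-assignments divided by co-draws; the final partition clusters
the distance 1 − consensus. The cluster with the highest median MVS is
tested for short survival with Fisher's exact test on (in-cluster) ×
(lymphoma-specific survival < 180 days); samples censored before the cutoff
are uninformative and excluded, samples surviving past it count as long.

## Synthetic data generator

The generator emulates the full study design with known ground truth:
36,807 CpG regions (~2.8 probes each, Poisson, min 1) + 672 CDS (~101
probes each) ≈ 170,000 probes; 37 tumors, 7 controls. A probe's log2 ratio
is the sum of

- a bimodal per-sequence baseline (78% "methylated" mode N(1.5, 0.5), 22%
  "unmethylated" mode N(−1.2, 0.35)), chosen so that the 25%-enrichment
  filter retains roughly the fraction of the design the study analyzed;
- planted DMR effects: ~1,011 hyper-methylated CpG sequences (drawn from
  the unmethylated mode, shifted +1.8 in every tumor) and ~183
  hypo-methylated sequences (~23% in CDS, shifted −1.8), each with
  lognormal mean-1 response jitter (σ = 0.4) per sequence and sample —
  biological variability in the magnitude of the shared aberration;
- subtype signatures: 3 planted subgroups; each of the k−1 Helmert
  contrasts over the subgroups gets its own 250-sequence signature with
  amplitude 1.5 (declining 20% per contrast so the contrasts map onto
  distinct principal components rather than a degenerate pair);
- disruption: a pool of ~7.5% "epigenetically unstable" sequences at which
  each tumor receives Gaussian deviations with SD = 1.2 × a per-sequence
  instability weight (U(0.5, 1.5)) × the sample's disruption multiplier.
  Multipliers follow a gradient 0.7–1.8 over 31 tumors plus a planted
  block of 6 tumors at 3.5. Deviations are sample-specific, so the
  *number/extent* of deviating loci — not a marginal scale factor, which
  quantile normalization would erase — carries the disruption signal;
- a per-probe offset (SD 0.15), technical noise (SD 0.25), and a smooth
  per-array polynomial dye bias in mean intensity (amplitude 0.3) for the
  loess step to remove.

Survival is Weibull proportional hazards (baseline scale 600 days, shape
1.3, ~median 280 days at the middle hazard), with subgroup hazard
multipliers (1, 1.7, 3) and the disruption multiplier entering the hazard
directly, so the planted high-disruption tumors die early; censoring is
independent (rate 0.05, matching the nearly complete follow-up of the
cohort). Other clinical covariates are drawn independently with the
cohort's published frequencies and carry no methylation signal, mirroring
the absence of level–clinical associations in the study.

**What the generator does not emulate**: spatial array artifacts,
probe-sequence affinity differences, batch structure, copy-number-driven
ratio distortion, correlated methylation along the genome (sequences are
independent given their type), and tumor purity variation. Passing tests
therefore demonstrate the pipeline's statistical behavior under the study
design, not robustness to those real-data complications.

## Problem sizes in the test suite

Unit tests run on a ~2,000-sequence / ~6,200-probe version of the design
(the planted fractions scaled so each structure keeps a meaningful count);
acceptance-style checks run one full-design experiment (~170k probes),
a 10,000-sequence null calibration, and a 50-seed survival power study with
two subgroups at hazard ratio 3 and uniform disruption (isolating the
planted contrast from disruption frailty). A full-design run of the entire
pipeline takes ~30 s on one CPU.

## Known limitations

- The exact rank-sum null is only used for tie-free rows; post-median ties
  across samples fall back to the corrected normal approximation.
- With 37 vs 7 samples, rank-test p-values are discrete (260 support
  points); they are exactly calibrated at every achievable level but a
  continuous-uniformity test (e.g. Kolmogorov–Smirnov) will reject on
  structural grounds at genome-wide sequence counts.
- Consensus clustering with k = 3 can transiently split the
  high-disruption block in individual resamples when subtype-signature
  sequences enter the top-MAD subset; the final consensus partition has
  kept the block intact in every configuration we measured.
- MVS compares whole change distributions; two samples with equal numbers
  of hyper- and hypo-deviations but opposite asymmetry can receive similar
  scores.
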