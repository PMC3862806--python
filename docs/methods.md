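# Methods

## Moderated d-statistic and permutation FDR

The per-gene score is d = r/(s + s₀), with r the difference of group means on
the log2 scale (group 1 minus group 2, so positive d means increased
expression in group 1), s the pooled-SD-based gene scatter
`sqrt[(1/n1 + 1/n2)·SS_pooled/(n1+n2−2)]`, and s₀ an additive stabilizer.
With s₀ = 0, d is exactly the classical pooled two-sample t-statistic; the
test suite asserts this and the elementwise formula to 1e−12.

**s₀ selection.** Candidates are the 0th–100th percentiles (step 5) of the
gene scatter s. For each candidate, genes are split into 100 quantile windows
of s and the median absolute deviation of d is computed per window; the
candidate with the smallest coefficient of variation of these MADs wins, with
ties going to the smaller candidate. Fewer than ~1000 genes shrink the window
count to n/10 (minimum 2). A degenerate scatter (all s equal) returns s₀ = 0
with a warning, since no stabilization is needed or identifiable.

**Permutation null.** Group labels over the pooled contrast samples are
reassigned; all C(n, n1) distinct assignments are enumerated when their count
is ≤ B (default B = 1000), otherwise B assignments are sampled uniformly
without replacement. A caller can force sampling (`exhaustive=False`), in
which case more draws than distinct assignments fall back to sampling with
replacement — the only way to obtain, say, 2000 Monte-Carlo draws from a 3v3
design's 20 assignments. Sorted permuted d's are averaged per rank to give
the expected order statistics d̄₍ᵢ₎, which are non-decreasing by
construction; ties in the observed order statistics are broken by stable
probeset-ID order.

**Delta table and calls.** For each symmetric offset Δ on a grid (default
101 points from 0 to the largest |d₍ᵢ₎ − d̄₍ᵢ₎|), cut_up is the smallest
observed d whose order statistic exceeds its expectation by more than Δ, and
cut_low the largest one falling short by more than Δ; genes beyond either cut
are called, with direction from the side crossed. Estimated FDR is π₀ times
the median over permutations of the permuted-d count beyond (cut_low,
cut_up), divided by the call count, capped at 1 (π₀ = 1 by default; a flag
exposes it). Zero calls give an undefined (NA) FDR. The FDR column is then
monotone-regularised by a reversed cumulative maximum — each Δ's estimate
becomes the maximum of the raw estimates at that and every larger Δ — so the
estimate is non-increasing in Δ and regularisation can only raise, never
lower, an estimate. Significance at a target FDR picks the smallest Δ whose
estimate meets the target; a target of exactly 0 additionally requires that
no permutation produced any call beyond the cutoffs, because a zero *median*
false count alone is satisfiable on pure-noise data.

The calibration this buys is checked by simulation: over planted-effect
cohorts, the median estimated FDR at the Δ targeting 0.10 tracks the realised
false-call fraction within 0.05 (tests/test_acceptance.py).

## Ingest, normalization, filtering, QC

Matrices are tab-delimited, probesets × samples, log2 intensities; sample
sheets join annotations by ID (order-independent). Quantile normalization
replaces each sample's i-th smallest value by the across-sample mean of i-th
smallest values, with ties broken by stable row order — which makes the
operation exactly idempotent (asserted to 1e−9 under property testing).

The low-expression cutoff is the density minimum between the two highest
modes of a Gaussian-KDE (Scott bandwidth, 512-point grid) of per-gene mean
intensities; if fewer than two modes with ≥5% relative prominence are found,
or the dip is not at least 5% below the lower mode, the conventional default
of log2 = 4 is used. Filtering drops whole genes whose across-sample mean is
strictly below the cutoff: the d-statistic needs complete per-gene vectors,
and per-gene means are what the bimodal distribution describes, so
value-wise omission was rejected as incoherent with downstream needs.

Outlier arrays are flagged quantitatively (in place of visual MDS/pseudoimage
inspection, for reproducibility): a sample whose median Pearson correlation
to all other samples falls strictly below Q1 − 1.5·IQR of the per-sample
medians is flagged, capped at 20% of samples (keeping the lowest medians).
Fewer than 4 samples yields an empty report with a warning. On homogeneous
simulated cohorts the flag rate stays below 5% (asserted over 200
simulations).

## Ordination

Distances are 1 − Pearson r over retained genes (range [0, 2], exact
symmetry enforced). MDS is classical/Torgerson — double-centred Gram
eigendecomposition — chosen over stress-minimizing variants because it is
deterministic and consumes the 1 − r matrix directly; negative eigenvalues
(the non-Euclidean part) are truncated with their magnitude logged. PCA
sample scores come from the gene-centred covariance eigendecomposition
(scikit-learn, full SVD solver). Both fix signs by making the
largest-magnitude coordinate of each axis positive, so outputs are
reproducible run to run. Euclidean-embeddable inputs round-trip through MDS
to 1e−6 or better.

## Cross-dataset comparison and gene-set shifts

Independently run datasets are never compared at the intensity level —
scaling differs — but per-probeset d-statistics are comparable. Vectors are
inner-joined on probeset ID (platform subsets pair down to the smaller set),
and concordance is Pearson r with a two-sided p, reported as "<1e-300" below
the floating-point reporting floor.

A gene set's behaviour is tested by comparing its members' d values against
the background of all tested genes. The default test is the two-sided
Wilcoxon rank-sum against the complement — rank-based, hence robust to the
d-statistic's heavy tails; two-sample KS and a random-set permutation test
(≥10,000 same-size draws, two-sided on the mean-d difference) are exposed as
alternatives, and all three report direction as the sign of
median(set) − median(background). Set members are excluded from the
background by default (a flag includes them; both conventions appear in the
literature). Sets with fewer than 5 members present are refused rather than
scored unstably. Under a global null the rank-sum p-values are uniform and
the α = 0.05 rejection rate sits in its binomial confidence band (asserted
over 1000 random sets).

## Over-representation

Each annotation group (GMT format) is intersected with the analysis universe
— all probesets surviving the low-expression filter, not the whole platform,
since only tested genes could have been called — and scored by the upper-tail
hypergeometric probability of the observed overlap with the query list
(observed count included in the tail). Bonferroni correction multiplies by
the number of groups with non-zero universe overlap; groups are flagged at
corrected p < 0.05. The hypergeometric tail equals brute-force enumeration on
small universes (asserted, including the 1/C(20,5) perfect-overlap case).
Increased and decreased calls are queried separately.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- **Design**: 2 phenotypes × 2 conditions with `group_sizes` defaulting to
  8/8/8/7 arrays (the post-QC layout of the emulated study: one cell reduced
  by an excluded outlier array).
- **Bimodality**: each gene joins a low (log2 ≈ 2) or high (log2 ≈ 8) mode
  with probability `frac_low_expressed` (default 0.4), plus per-gene baseline
  scatter (`mode_spread`, 0.8 log2 units) within the mode — reproducing the
  bimodal intensity histogram that motivates the empirical cutoff.
- **Variance heterogeneity**: gene SDs follow a scaled inverse-chi-square
  family (`gene_sd_scale` 0.25 log2 units, `gene_sd_shape` 4 df — a heavy
  enough tail that s₀ selection is non-trivial). The observation noise is
  gene-wise normal on the log2 scale; with nothing planted, per-gene pooled
  t-statistics are exactly t-distributed (KS-asserted).
- **Planted effects**: `n_de` genes (default 300) among the expressed mode
  are shifted by `effect_size` (default 2, interpreted as multiples of the
  gene's own SD when `effect_in_sd_units`, giving a standardized effect of
  exactly 2 per gene), up with probability `de_up_fraction` (default 0.5;
  raise it to reproduce up-dominated profiles) in the `de_phenotype` groups.
- **Array effects**: additive per-array offsets (`array_effect_sd`, 0.1 log2
  units) that quantile normalization should remove.
- **Paired datasets**: `round(cross_dataset_share · n_de)` effects are forced
  common with equal signs; each dataset's remaining effects are drawn
  independently, so chance overlap beyond the forced core is possible. Gene
  baselines and SDs are shared across the pair (same platform and biology);
  arrays and noise are independent.

All randomness flows from one config seed through spawned `SeedSequence`
streams (structure / effects / noise, and per-dataset streams for pairs), so
identical configs are bit-identical. The generator does **not** emulate
probe-level (PM/MM) structure, GC-content background, inter-gene correlation
(co-expression), or heavy-tailed/outlier noise; passing tests therefore
demonstrate correctness and calibration of the machinery under the model's
assumptions, not robustness of the pipeline to correlated or non-Gaussian
real-array artifacts.

## Problem sizes and numerical conventions

Simulation-backed tests use cohorts of 1,200–10,000 genes with B = 60–500
permutations and 5–200 replicates per property — large enough for the
binomial/KS tolerances asserted, small enough to keep the full suite under a
minute on one core. The acceptance script runs the pipeline at the full
31,000-probeset, 31-array design with B = 500. Other conventions: p-value
reporting floor 1e−300 (printed "<1e-300"); zero within-group variance with
s₀ = 0 reports ±inf d with a warning; single-sample quantile normalization
and sub-4-sample QC degrade to warned no-ops; empty filtered matrices,
empty ID intersections and zero-variance vectors raise typed errors naming
the offender.

## Known limitations

- FDR estimation uses all genes' permuted statistics; planted/true effects
  inflate the permuted tails, so estimates are mildly conservative unless the
  optional π₀ multiplier is supplied.
- The d-statistic machinery covers two-group contrasts only (no multi-class,
  paired or survival variants); combined groups are handled by label merging.
- Gene identifiers must already match across datasets; no cross-platform or
  annotation-version mapping is attempted.
- With ~16 arrays per side and standardized effects near 2, no thresholding
  method reaches high sensitivity at FDR 0.05 under ~10k-gene multiplicity;
  recovery expectations should be set by the noncentral-t power of the
  design, which the test suite measures rather than assumes.
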