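# Methods

## Overview

glyconet tests, for a two-group bulk RNA-seq comparison, whether the
co-expression between transcription factors (TFs) and glycolysis-related
genes differs between the groups, and ranks the genes driving that
difference. The unit of inference is the *gene pair*: a per-sample LIONESS
edge weight is computed for every unordered pair over the TF + glycolysis
list, the weights are contrasted between groups with a moderated t-statistic,
significant pairs are intersected with directed regulatory databases, and
network centralities select the key regulators and targets.

## Synthetic data generator

The generator draws counts from a hierarchical model:

- Baseline means μ_g are log-uniform over `mu_range` (default 100–1000),
  a typical range for moderately expressed genes in bulk libraries.
- Each sample's latent natural-log mean is
  ln m_gs = ln μ_g − σ²/2 + σ·Z_gs, with `latent_sd` σ (default 1.0) and
  Z a standard-normal field. Within each group, the Z rows of genes named in
  `coexpr_plan` are drawn with the planted correlation matrix (a Gaussian
  copula); the −σ²/2 term keeps E[m] = μ. Case samples additionally receive
  the `de_plan` log2 shifts.
- Counts are negative-binomial with var = μ + φμ² (`dispersion` φ, default
  0.05, Poisson at φ = 0).

**Why correlations are planted on the latent scale.** The pipeline
correlates log-transformed counts, and the latent log scale is the only
place a target Pearson r is well defined. Count-level noise attenuates the
attained correlation by ≈ σ²/(σ² + φ + 1/μ) per gene; with σ = 1.0 and the
default dispersion a planted r = 0.9 is observed as ≈ 0.85 on log counts.
The default σ is deliberately large enough that this systematic attenuation
stays within 0.1 of the plant — with a much smaller latent SD the planted
correlation would be unrecoverable in principle, not merely noisy.

**Correlation-plan validity.** The per-group correlation matrix assembled
from the pairwise plan must be positive semidefinite; the generator checks
eigenvalues and fails loudly, naming the offending pairs, rather than
silently repairing the matrix. Note that a "hub" of strong pairwise
correlations (one gene at r = 0.9 with k partners, partners uncorrelated) is
not PSD for k ≥ 2; hub structures are planted as equicorrelated blocks,
which are PSD at any size.

**Regulatory tables.** A promoter-class or enhancer-class table emits
round(coverage · k) of the k planted differential pairs that contain a TF
(directed TF → partner, a seeded random direction for TF–TF pairs) plus
optional decoy records drawn from non-differential pairs. Binding-site
counts follow a shifted geometric law (support ≥ 1), mimicking the long
right tail of real promoter/enhancer site counts without asserting any
particular values.

Each logical component (mean draws, latent field, NB sampling, each DB)
consumes an independent RNG stream derived from the master seed, so adding
decoys never perturbs the counts.

**What the generator does not emulate:** library-size variation (size
factors are genuinely ≈ 1 and the normalization step is exercised only
statistically), batch effects, covariates, gene-length bias, and read-level
noise. Tests passing on these fixtures therefore validate the statistics
and bookkeeping of the pipeline, not robustness to those artefacts.

## Normalization, transform, differential expression

Size factors follow the median-of-ratios convention (median over genes
expressed in all samples of count/geometric-mean, rescaled to geometric mean
1; the median is taken on the ratio scale, which matters for even gene
counts). The co-expression transform is log2(count/factor + 1) by default;
a `shrunken` mode additionally pulls each gene's values toward its
cross-sample mean with weight s²/(s² + s²₀) on the deviation (s²₀ the median
gene variance) as a monotone variance-stabilizing surrogate for
regularized-log transforms.

Differential expression is a simplified per-gene negative-binomial Wald
test: method-of-moments dispersion from the pooled within-group variance
(floored at 1e−8), delta-method standard error on the log2 ratio of
normalized group means, BH correction over tested (not all-zero) genes, and
the two published thresholds applied separately (FDR ≤ 0.1 and linear fold
change ≥ 1.5, the latter on the raw point estimate). When exactly one group
mean is zero, 0.5 is added to both means so the fold change stays finite.
This caller only feeds node up/down labels and filters; it does not attempt
shrinkage-based effect estimates, outlier replacement, or independent
filtering.

## LIONESS edge weights

For pair (i, j) and sample q: e_q = N(e^α − e^(α−q)) + e^(α−q), with e^α the
Pearson correlation over all N pooled samples of the two compared groups and
e^(α−q) the leave-one-out value. Implementation notes:

- N + 1 full correlation-matrix evaluations (one aggregate, one per left-out
  sample) rather than rank-one updates — exact and transparent at this scale
  (≈1.3k genes, tens of samples; the full paper-scale problem of ~854k pairs
  × ~20 samples fits comfortably in memory).
- Only the samples of the two compared groups enter the computation; pooling
  unrelated cohorts would move e^α and therefore every pseudo-weight.
- Constant genes get correlation 0 (with a warning) instead of NaN, keeping
  the matrix rectangular; such pairs can never reach significance.
- e_q is unbounded even though both correlations are bounded; no clipping.
- All C(G, 2) canonical (lexicographically ordered) pairs are computed —
  TF–TF, TF–target and target–target — and the BH universe downstream is
  exactly this pair set; direction and pruning happen only at annotation.

## Moderated t

Per pair, the two-group linear model has the closed form logFC = mean_case −
mean_ref, s² = pooled residual variance, d = N − 2. The prior (d₀, s₀²) is
estimated by moment-matching of log s² to a scaled log-F distribution:
e = log s² − ψ(d/2) + log(d/2); solve ψ′(d₀/2) = Var(e) − ψ′(d/2) by Newton
inversion of the trigamma function, then s₀² = exp(mean(e) + ψ(d₀/2) −
log(d₀/2)). If the observed variances are underdispersed relative to χ²
sampling noise (Var(e) ≤ ψ′(d/2)) the prior degrees of freedom are infinite
and every posterior variance collapses to s₀²; in the exactly-degenerate
case (all s² identical) s₀² is that common value and t reduces to the plain
z statistic. Otherwise s²_post = (d₀s₀² + d·s²)/(d₀ + d) and p-values come
from the t distribution with d + d₀ degrees of freedom. Zero variances are
excluded from prior estimation. This reproduces the standard
empirical-Bayes moderated t to machine precision on shared inputs.

## Annotation and centrality

A significant pair {a, b} yields edge a→b when the database holds record
(a, b) and b→a when it holds (b, a); both can fire for TF–TF pairs. Edge
sign is the sign of the pair's logFC (+: higher edge weight in the case
group). Databases are validated tables of (tf, target, binding_sites,
region_class); duplicate records collapse by summing sites with a warning;
self-records and non-positive counts are rejected with row numbers. A
network keeping fewer than `min_targets` (default 20) glycolysis genes is
excluded from centrality analysis (the pipeline marks the stage SKIPPED).

Centralities: integer in/out-degree; Brandes betweenness (directed,
unweighted, unnormalized, endpoints excluded — normalization is irrelevant
for ranking); HITS hub/authority by power iteration from the uniform vector
with Euclidean renormalization, converged when successive vectors change by
less than `tol` (1e−10) in the max norm. Since glycolysis genes are pure
sinks, their betweenness is identically zero and out-based measures are
ranked over TFs only; in-based measures over targets only. Top-ten lists
keep all nodes tied with the tenth distinct value (deterministic secondary
sort by gene identifier) rather than dropping ties arbitrarily; central TFs
= out-degree ∩ hub ∩ betweenness top lists, central targets = in-degree ∩
authority.

## Statistical power: what the tests do and do not show

Differential co-expression has intrinsically low power at small n. For a
pair whose latent correlation moves from 0 to 0.9 (attained ≈ 0.85 after
count-noise attenuation), the per-sample LIONESS pseudo-weights have
within-group variance near 1, so the moderated t is roughly
0.85·√(n/2) in expectation: ≈ 1.9 at n = 10 per group, ≈ 4.7 at n = 60.
When only ~1% of the C(100, 2) pair universe is non-null, BH at q = 0.1
requires p ≲ 10⁻³ (|t| ≳ 3.6), so at n = 10 per group the expected
sensitivity is a few percent — no implementation can do better, since even
the asymptotically efficient two-sample Fisher-z statistic is only
(z(0.9) − z(0))/√(2/(n−3)) ≈ 2.75 there. Studies reporting large numbers
of significant edges at such sample sizes do so because differential
co-expression is genome-wide in real contrasts, which makes the BH
threshold adaptive; a sparse planted fixture cannot reproduce that regime.
The recovery experiments therefore demonstrate correctness at n = 60 per
group (sensitivity ≈ 0.96, FDP ≈ 0.16, hub TF always selected across
seeds) and honestly report the near-zero sensitivity at n = 10.

## Problem sizes and runtime

Default experiment sizes were chosen so the whole suite runs in seconds:
recovery fixtures use 100 genes (20 TF, 80 target; 4,950 pairs) at 10–80
samples per group; null calibration uses 5,000 pairs at n = 10 per group;
prior recovery 10,000 variances; oracle sweeps 200 random matrices
(≤ 6×8) and 100 random digraphs (≤ 15 nodes). All are comfortably above the
sizes where the asymptotics they test become accurate.

## Known limitations

- The DE caller is a Wald approximation; its p-values are slightly
  anti-conservative for very low counts (the planted-recovery tests do not
  depend on it).
- The `shrunken` transform is a heuristic surrogate, not a likelihood-based
  regularized log; ranking-sensitive analyses should use the default
  transform.
- Two-group designs only; no covariates, array weights, or robust
  moderation.
- The enhancer-class table is treated as disjoint from the promoter window
  (sites outside −1000..+100); a database mixing both would need
  pre-splitting.
- Edge signs are relative to the group listed as `case`; swapping labels
  negates all logFCs and swaps up/down calls (asserted as a test).
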