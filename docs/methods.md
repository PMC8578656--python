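# Methods

This note documents the statistical models implemented by `leukdriver`,
the design choices made where the procedures admitted more than one
reading, and what the synthetic cohort does and does not emulate.

## Background model and recurrence test for non-coding regions

For each tumour *t* an independent logistic regression models the
probability that the tumour carries at least one mutation in region *r*:

    p_tr = logistic(a_t + β_t · x_r)

with covariates x_r = (GC fraction, mean replication timing, mean
coverage, log region length), standardized internally. Fits use
iteratively reweighted least squares (statsmodels GLM, binomial family).
The per-tumour genome-wide mutation rate is deliberately not a separate
covariate: with one regression per tumour a per-tumour constant is
collinear with the intercept a_t, which already absorbs it. Tumours with
an all-zero (or all-one) response, or whose fit fails to converge, fall
back to an intercept-only model at the empirical rate with a probability
floor of 1/(2·n_regions), and are flagged.

The recurrence statistic for region *r* is the upper tail
P(K_r ≥ k_obs) of the Poisson-binomial distribution of
K_r = Σ_t Bernoulli(p_tr). The tail is computed by exact O(n²) dynamic-
programming convolution up to n = 5000 tumours; beyond that a refined
normal approximation (continuity-corrected, with a first Edgeworth
skewness term) takes over and the method used is recorded. A vectorized
batch form runs the DP across all regions simultaneously, which makes
whole-cohort scans take under a second. Tails are clamped to
[tiny, 1] before log transforms downstream.

Multiple hits of one region in the same tumour count once for the burden
test; all positions feed the clustering test.

## Clustering permutation test

The procedure tests regions carrying more than five mutations cohort-wide
for positional clustering under a uniform placement null. The clustering
statistic is not uniquely determined by the procedure's description, so
the package defines it as S = the width of the smallest window containing
at least ⌈m/2⌉ of the m mutation positions — robust to outlier positions
and sensitive to a single tight cluster. P = (#{S_perm ≤ S_obs} + 1) /
(n_perm + 1); the +1 form is used here (unlike the SV permutation test, which
follows the plain proportion) so that Fisher combination and BH never
receive an exact zero. The null is simulated on the unit interval
(positions/L), a continuous approximation of bp-uniform placement that is
negligible for regions ≥ 100 bp; inside the cohort pipeline null samples
are cached and shared between regions with equal mutation counts, which
is exact for the marginal distribution of each P value.

Burden and clustering P values are combined with Fisher's method
(χ² with 4 df); regions without a clustering result keep the burden P as
the combined value. BH adjustment is applied across all regions, and
regions at q < 0.1 are validated by a two-sided Wilcoxon rank-sum test of
target-gene TPM in mutated vs non-mutated tumours, excluding tumours with
CNVs at the region or target gene; expression P values are BH-adjusted
across the tested set.

## Consensus combination for coding genes

Per-gene P values from external driver callers are combined with the
unweighted harmonic mean, HMP = n / Σ(1/p_i). The harmonic mean is used
directly as the combined P — a valid approximation for small P; the
asymptotically exact Landau-distribution correction is out of scope and
would only matter near P ≈ 1. With missing method outputs the HMP runs
over the available methods while the "significant in ≥ 2 methods" filter
still requires two absolute methods. BH is applied to all genes before the
evidence filters by default; the post-filter ordering is also computed and
reported, since the original procedure does not fix the order.

## Copy states, SV consensus and joint tests

The printed log2→copy-state threshold list in the source procedure is
internally inconsistent as printed; the package default is the monotone
reading (< −1.1 → 0, [−1.1, −0.3) → 1, [−0.3, 0.3] → 2, (0.3, 0.7] → 3,
> 0.7 → 4) and the map is fully configurable — it is a package default,
not an assertion about the original thresholds. A segment is arm-level
iff it covers strictly more than 80% of either arm's mappable length;
mappable arm intervals are inputs, not derived.

SV consensus merging clusters calls by single linkage on (same type, same
orientations, both breakends within a tolerance of 200 bp — the upstream
merging scheme's distance is not printed, so the tolerance is
configurable), takes median breakend positions, and keeps clusters
supported by ≥ 2 distinct callers. Panel-of-normals matching for SVs is
exact on (chrom1, pos1, chrom2, pos2, type).

The SV-enrichment test re-places each SV uniformly over the arm's
mappable intervals (concatenated coordinate space, lengths preserved) and
reports the plain proportion of 1000 permutations with simulated overlap
count ≥ observed, so the minimum attainable P is 0; a pseudocount option
computes (r+1)/(n+1) instead. With sparse SV sets the plain-proportion P
is conservative under count ties; the calibration fixtures therefore use
dense SV sets (hundreds per arm) so the overlap count is
quasi-continuous. Chromothripsis flagging reports maximal runs of
adjacent segments alternating between exactly two copy states with run
length > 3 and > 5 SVs having both breakends inside the run span;
breakend orientation is ignored.

## Subtyping

Chromosome counts are sums over contigs of the length-weighted modal copy
state (ties break to the lower state); each contig models one chromosome
pair, so a fully diploid genome over 23 contigs counts 46. Ploidy classes:
> 50 hyperdiploid, 24–30 near-haploid, otherwise < 45 hypodiploid.
Fusion subtypes require a clonal SV (CCF ≥ 0.9) joining the partner loci
plus fusion expression. iAMP21 is a declared simplification: modal copy
state over the RUNX1 region ≥ 5 (configurable); the full clinical rule is
not reproduced. Precedence is fusion > iAMP21 > ploidy > other, chosen
because fusions and RUNX1 amplification are initiating lesions;
the order is configurable.

## Clonality

The maximal-CCF cluster is clonal iff 0.9 < CCF < 1.1 (strict); samples
fail QC on any of: a cluster with CCF > 1.1, no clonal cluster, a
VAF-cluster mismatch flag, or a homozygous deletion > 3 Mb (the last two
are auxiliary inputs). Heterogeneity uses the Gini–Simpson complement
1 − Σ f_i² (higher = more heterogeneous), over disjoint subpopulation
fractions obtained from nested CCFs under a linear-nesting assumption
(f_i = CCF_i − CCF_child, floored at 0, renormalized) — cluster tables
carry no branching information, so linear nesting is the only
assumption-free conversion. Subclonal driver enrichment is a one-sided
exact binomial of the subclonal share of driver mutations against the
subclonal share of all mutations. Per-compartment driver mutation rate =
nonsynonymous driver variants / nonsynonymous sites / total compartment
mutations. Neutral-tail compartment labels are taken as input when
available; otherwise compartments are clonal/subclonal only.

## Breakpoint motifs

Each retained SV contributes two 100 bp windows (±50 bp per breakend);
SVs with both breakends in immunoglobulin regions are excluded (the rule
is conjunctive). Default query motifs are the canonical recombination
signal sequences (heptamer CACAGTG, nonamer ACAAAAACC) and the AID core
WRCY/RGYW — the original candidate motif tables live in unavailable
supplementary material, so all motifs are configuration-driven and the
defaults are standard literature motifs. AID positivity requires strictly
more than 10 core-motif repeats summed over both windows; the core list
carries both orientations, so scanning is forward-strand to avoid double
counting. A calibration helper returns a quantile of repeat counts at
immunoglobulin-region SVs for users who want to re-derive the threshold.
Enrichment uses a one-sided Fisher exact test against per-sequence
dinucleotide-shuffled backgrounds (Altschul–Erickson Eulerian shuffle,
seeded). PWM annotation takes the best-offset Pearson correlation over
flattened matrices (shorter matrix padded with uniform 0.25 columns),
substitutes a candidate label when it beats the best reference, and
excludes below r = 0.85.

## Synthetic cohort: what it emulates, and what it does not

The generator produces, from one seeded numpy Generator: subtype labels,
whole-contig karyotypes realising the ALL ploidy classes, region tables
with covariates, mutation placements from the same logistic family the
background model fits (so parameter recovery is well-posed), planted
driver regions with elevated recurrence, positional clustering and a
multiplicative expression effect, log-normal expression, Poisson numbers
of intra-contig SVs, breakend windows with planted motifs, and nested CCF
clusters. Identical config and seed reproduce the cohort bit for bit, and
truth tables record every per-sample draw, probability matrix, planted
driver and subclone.

Scale choices (the package's own design, fixed once): a compressed
23-contig genome of 1–5 Mb contigs, 2000 regions of ~1 kb, 300 tumours,
and a background rate of 1e-4 mutations/bp/tumour, i.e. a per-region
per-tumour mutation probability around 0.1 and expected recurrence of
~30 mutated tumours per region. Real ALL burden (~0.4 mutations/Mb) at
real region sizes would put expected recurrence well below one tumour per
region, a regime where the exact-tail test is so discrete that
calibration bands and power statements are uninformative at desk scale;
the compressed genome trades genomic realism for an informative,
quasi-continuous counting regime while preserving the model family. The
generator does not emulate: read-level data, trinucleotide signature
context, germline variation, linked CNV/expression dosage effects, or
inter-region covariate correlation. Passing tests therefore demonstrate
the statistics are correctly implemented and calibrated under the model's
own assumptions — not that the background model is adequate for any real
cohort.

Default covariate effects are β = (1.0, 0.5, 0.3, 0.5) on the
standardized covariates, with per-tumour intercept jitter of SD 0.3
emulating burden variation; subclone counts default to 1–3 per tumour
(mode 2).

## Numerical choices and degenerate inputs

* Poisson-binomial tails: exact ≤ 5000 trials; refined-normal beyond;
  k ≤ 0 → 1, k > n → 0; exact/approximate agreement at the crossover is
  within 1e-3 absolute.
* Fisher combination clamps zero inputs to the smallest positive float.
* BH: NaN entries are excluded from m and returned as NaN.
* Copy-state maps must be strictly increasing; NaN log2 → unassigned.
* Modal-state ties break to the lower state (deterministic).
* Exact binomial tests with a zero background rate report the limiting P
  with a degenerate flag rather than erroring.
* All permutation and simulation functions take an explicit seed or
  Generator; nothing uses global random state.

## Known limitations

* The harmonic-mean combined P lacks the exact tail correction (small-P
  approximation only).
* The clustering statistic is package-defined (the source procedure names
  the test but not the statistic) and pluggable.
* iAMP21 calling is a one-threshold simplification.
* The SV panel match is exact-coordinate; real pipelines may want a
  tolerance there too.
* Expression validation assumes one target gene per region; multi-gene
  regions are evaluated per linked gene.
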