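# Methods

This note documents the statistical machinery in `ftqc`: the estimators,
their tunable parameters, the generative model behind the synthetic
cohorts, the numerical conventions, and what the test suite does and does
not establish about real data.

## Replicate noise

**Definition.** For a pair of technical replicates, noise is the fraction
of reads in the reference replicate that behave as randomly counted. It is
defined operationally through a perturbation operator: remove
`round(f·T)` reads (T = total reads) drawn without replacement with
probability proportional to current counts, then add the same number of
reads uniformly at random over genes. Removal proportional to abundance
models indiscriminate read loss; uniform gain models reads that no longer
map to a sample-specific gene. Both kernels are configurable
(`removal=`/`addition=` in `perturb`), and the operator preserves the
library size exactly.

**Estimation.** Let `D*` be the observed dissimilarity between reference
and target and `D(f)` the mean dissimilarity between the reference and
`n_repeats` perturbed copies of itself. `E[D(f)]` is monotone in `f`
(checked empirically for all four metrics), so `D(f̂) = D*` is solved by
bisection on [0, 1]. Defaults (`NoiseOptions`): 25 perturbations per
evaluation, bisection interval tolerance 1e-3 on `f` (0.1 pp on the
reported percentage), at most 40 iterations, and convergence flagged when
the final mismatch is within 10% of `D*`. Pairs more dissimilar than pure
randomness (`D* > D(1)`) are pinned at 100% with `converged=False`.

Counts are `log2(x+1)`-transformed before the Euclidean, RMSE, and Pearson
metrics — raw Euclidean distance is otherwise dominated by a few high
expressors — while Spearman uses ranks of the raw counts. Only replicates
with the same freeze-thaw count are compared; the replicate appearing first
in metadata order is the reference (an option averages both orientations).

**Recovery and depth dependence.** On 5,000-gene, 25k-read synthetic
replicates the estimator recovers generating fractions of 2–20% with a
mean absolute error below 0.4 pp for every metric. The estimate is *not*
invariant to sequencing depth: at greater depth the same observed
dissimilarity corresponds to a larger equivalent random-read fraction,
because fine-grained randomization perturbs deep counts relatively less.
Noise percentages should therefore be compared between samples of similar
depth, which technical replicates are by design.

**Quality regressions.** All regressions in the package are identity-link
Gaussian linear models, fitted as OLS with t-based Wald tests and
confidence intervals (the exact small-sample inference for this model).
Before any noise regression, pairs whose input RNA concentration is in the
top or bottom 5% (|z| ≥ 1.645) are dropped. Noise-on-RIN fits are run
separately within each freeze-thaw stratum, since RIN predicts noise after
one freeze-thaw but not after two; noise-on-concentration fits exclude
samples beyond one freeze-thaw. Simulation at the package's cohort scale
shows each coefficient's 95% CI covering its generating value at the
nominal rate (94–97% over 100 replications).

## Differential-expression reproducibility

**Gene filter.** Genes with an average count ≤ 20 across all samples are
removed (strictly greater than 20 retained).

**Subsets.** For each even size N in 4–14, balanced subsets are drawn with
N/2 ASD and N/2 TD samples, at most one replicate per individual, and no
duplicates; samples without a diagnostic group (industry standards,
unassigned) or without recorded quality values are ineligible. Draws are
uniform over the valid set: a uniform N/2-sample draw per group is rejected
on replicate collision, which leaves accepted subsets exactly uniform. The
combinatorial maximum is computed with elementary symmetric polynomials
over per-individual replicate counts, and requests beyond it are capped
with a warning. The default is 2,000 subsets per size.

**DE engine.** The default engine computes median-of-ratios size factors
over the subset's samples, group means of normalized counts, and
`lfc = log2((μ_ASD + 0.5)/(μ_TD + 0.5))`. The LFC standard error follows
from the delta method under a negative-binomial variance `μ + αμ²` with a
pooled within-group method-of-moments dispersion estimate, floored at a
small positive constant; `wald = lfc/se`. A per-gene Cohen's d on log₂
normalized counts is carried along for the effect-size metrics. Any
callable honouring the same output contract (for example a DESeq2 bridge)
can replace the engine; confounder-adjustment covariates are likewise a
user-supplied hook rather than a built-in control-gene procedure.

**Similarity.** Genes whose median base mean or median |LFC| across
subsets falls in the bottom 10th percentile are excluded (|LFC| rather
than signed median, which would discard strong down-regulation; a signed
option exists). Similarity is the Spearman correlation of LFC vectors for
a pair of same-size subsets. With 2,000 subsets there are ~2M pairs per
size, so pairs are a seeded random sample (default 10,000; all pairs when
fewer). A `disjoint` mode instead draws a random perfect matching so no
subset appears in two pairs; these pairs are mutually independent, which
the rank-sum test below assumes. Quality bins split pairs at the median of
the pair-averaged covariate (high quality = fewer freeze-thaws or higher
RIN; ties go to the low-quality bin) and are compared with a one-sided
Mann-Whitney U test plus the high/low fold change of median similarity.
Because sampled pairs share subsets, the MWU on the default pairing is
anti-conservative; calibration-sensitive uses should prefer the disjoint
mode, and the acceptance suite documents this trade-off. Three similarity
regressions are available: freeze-thaw + RIN + subset size, and each
quality metric alone.

**Discordance.** Discordance is the per-gene sample SD (n−1) of LFC across
subsets, after excluding the bottom base-mean decile. Effect size is one
of: the mean-variance standardized effect (median |lfc/se| across
subsets, the default), Cohen's d, or |median LFC|. Per size,
`Discordance ~ Effect Size × Quality` is fitted with the quality dummy
(0 = low, 1 = high); ΔD per bin, the disparity Δm = ΔD_low/ΔD_high, and
BH-adjusted Wald q-values across sizes are reported.

## Coverage bias

Each gene's per-base depth (5′→3′; minus-strand genes reversed) is
resampled onto 101 percentile positions by nearest-base lookup, summed over
genes, and scaled to a within-sample maximum of 1 (the MCP is invariant to
the scaling constant). Genes shorter than 101 bases are skipped with a
warning. A BAM + BED12 path builds spliced per-transcript depth with
pysam, skipping secondary/supplementary alignments; coordinates are
0-based half-open.

The MCP is computed under two conventions. The discrete first-crossing
index (smallest percentile whose cumulative coverage reaches ≥ 50% of the
total) is bit-stable and matches hand-computable oracles: a uniform profile
gives 50, a linear ramp gives 71. The interpolated variant inverts the
cumulative curve linearly between adjacent percentiles; regressions use it
by default because integer quantization of the response biases slope
estimates when generating shifts are below one percentile (the 1.12
pp/ln-cycle shift spans only ~1.8 pp over cycles 1–5). Normalization
subtracts the mean MCP of one-freeze-thaw samples within each library-prep
stratum; `normalized MCP ~ ln(cycles)` is fitted per stratum (natural log;
the transformation stabilizes variance across cycle counts). A
`five_to_three_ratio` (mean of percentile bins 0–19 over bins 80–100,
windows configurable) supports ratio-style comparisons, and group
comparisons offer pairwise t-tests with BH correction, two-way ANOVA,
one-sided rank-sum tests, and Kruskal-Wallis.

## Synthetic cohorts

The generator emulates a study of 16 individuals with technical replicates
(default 3, i.e. 48 poly(A) samples), a 50/50 ASD/TD split, and 1–5
freeze-thaw cycles. Cycle counts are an assigned experimental condition:
they are spread evenly over the range within each diagnostic group and
randomly permuted, so cycles are never confounded with group or with any
individual's expression idiosyncrasies by an unlucky draw.

Counts: gene means are log-normal (ln-scale sd 1.5); each individual's
expression is those means times a group log₂ fold change on a `de_fraction`
of genes (LFCs ~ Normal(0, `de_lfc_sd`)) times per-individual biological
jitter (log₂ sd 0.15); each replicate draws negative-binomially
(gamma-Poisson, dispersion 0.005 — technical replicates of a single
extraction are near-Poisson) at the configured depth and is then degraded
by applying the perturbation operator once per freeze-thaw cycle with
fraction `noise_per_cycle` (default 0.04) on its own random stream, so a
replicate pair at c cycles embodies c cycles' worth of mutual randomness.
RIN is a noisy, clipped linear function of cycles
(`rin_baseline − rin_decay·(cycles−1) + Normal(0, rin_noise_sd)`);
concentration is log-normal and independent of quality.

Coverage profiles: ribosomal-depletion samples draw from a near-uniform
baseline with a mild drop-off at transcript ends; poly(A) samples draw from
a smooth unimodal baseline whose tails vanish well inside the percentile
window, translated toward the 3′ end by `bias_per_log_cycle·ln(cycles)` pp
(so one freeze-thaw reproduces the baseline exactly), with optional
multiplicative log-normal bin noise. The compact baseline support makes
the interpolated MCP respond to translation one-for-one, so the generating
slope is recoverable to < 0.001 pp without noise.

Problem sizes: the noise-module desk scale is 5,000 genes at 25,000 reads
(the emulated study's 25M depth scaled by 1,000). Reproducibility analyses
instead use 2,000 genes at 200,000 reads — 100 reads per gene,
conservatively below the study's ~2,500 — because per-gene coverage, not
total depth, sets DE noise, and a 5-read/gene matrix leaves almost nothing
above the count filter.

**What the generator does not emulate.** Degradation is uniform read
randomization; real freeze-thaw damage is transcript-specific and
length/GC-structured, which is why real data shows effect-size-dependent
discordance growth that this generator does not reproduce (the degradation
contribution here is effect-independent and shifts the discordance
intercept instead). Inter-individual biological variability is set low so
that technical degradation dominates replicate comparisons; real cohorts
have severalfold larger biological spread, and passing tests demonstrate
that the pipeline detects quality-dependent technical noise, not that real
cohorts behave this way. RIN decay is linear by construction, and no
attempt is made to simulate reads, fragments, or electropherograms.

## Numerical conventions and degenerate inputs

Ties at a quality median go to the low-quality bin. Percentile exclusions
use a strict cut, falling back to an inclusive one only when a tied
distribution would otherwise exclude every gene. Constant vectors under
correlation metrics yield NaN with a warning; all-zero coverage profiles,
single-group subsets, sub-minimal row counts, and zero-variance or
collinear designs raise typed errors (`DataError`,
`InsufficientDataError`, `SingularFitError`). One master seed fans out to
per-stage children (`SeedSequence`), making full pipeline runs
bit-reproducible while allowing stages to be re-run independently.

## Known limitations

The noise estimate is depth-dependent (see above) and undefined for
replicate pairs more dissimilar than pure randomness. The default
dependent-pair similarity test is powerful but anti-conservative under the
null; the calibrated disjoint mode has limited power at a few hundred
subsets per size because only n/2 independent pairs exist. Discordance
slope contrasts between quality bins require effect-proportional
degradation, which uniform randomization does not generate. The DE engine
is a deliberately simple Wald estimator; for publication-grade DE, plug in
an external engine through the contract.
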