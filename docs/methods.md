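# Methods

`liverdev` implements an analysis pipeline for a seven-comparison,
dye-swapped two-color microarray design probing sex-specific and
developmental gene expression in mouse liver, together with a synthetic
data generator that reproduces the statistical structure the analysis
assumes. This note records the models, the parameters that matter, and
the design choices made where the design was genuinely open.

## The design

Six biological conditions (male/female liver at 3, 4 and 8 wk of age) are
collapsed into seven competitive hybridizations, each run as a pair of
dye-swapped biological replicates (14 arrays total):

| # | comparison | reported ratio | up flag (1) means |
|---|------------|----------------|-------------------|
| 1 | M3 vs F3   | M3/F3          | male-biased at 3 wk |
| 2 | M4 vs F4   | M4/F4          | male-biased at 4 wk |
| 3 | M8 vs F8   | M8/F8          | male-biased at 8 wk |
| 4 | M3 vs M8   | M8/M3          | rises with age in male |
| 5 | M4 vs M8   | M8/M4          | rises with age in male |
| 6 | F3 vs F8   | F8/F3          | rises with age in female |
| 7 | F4 vs F8   | F8/F4          | rises with age in female |

The developmental comparisons are oriented adult-over-juvenile: that is
the orientation under which the canonical worked TFS example
(28.0022200 — female-specific at 8 wk, falling with age in male liver)
decodes correctly, and it makes "up/down" mean "up/down with age".

## Synthetic data

**Truth model.** Each gene carries a class (male-specific,
female-specific, sex-independent), an onset age for sex specificity (3, 4
or 8 wk; sex-specific genes only), per-sex developmental change
directions, a baseline level and an effect fold. The six true expression
cells are built from the female trajectory (flat from 3 to 4 wk, moved by
the effect fold at 8 wk when a female developmental change is declared)
and a sex-ratio step applied to the male side at every age at or past the
onset. Two structural consequences are deliberate:

- For sex-specific genes the male developmental change is **derived**
  from this construction, not sampled: with six cells and five ratio
  constraints the system is exactly determined, and sampling the male
  change independently would make the record set contradictory.
- Sex-independent genes get independently sampled per-sex trajectories
  that meet at 8 wk. Genes whose sexes move differently therefore carry a
  genuine transient early sex-bias — mirroring the minority of adult
  sex-independent genes that are sex-biased at 3 or 4 wk in real liver —
  and the classifier reports these under `transient_bias`, not onset.

**Anchoring.** Each gene's six cells are rescaled so their geometric mean
equals the gene's baseline level. Anchoring at a fixed age instead (an
earlier construction) makes the direction of a gene's change correlate
with its mean spot intensity A across the gene population, and an
intensity-dependent normalizer then absorbs real signal; geometric-mean
centering removes almost all of that correlation. This is a property of
the generator, not of the analysis.

**Baseline levels** are log-normal (median 1000 linear units, natural-log
sigma 1.6 — several orders of magnitude, as on real arrays),
left-truncated at 200: truth records describe *expressed* genes, while a
separate fraction of probes (`frac_low_expressed`, default 0.1) is set to
background level and is what the well-above-background filter exists to
remove.

**Noise model** (additive + multiplicative, Rocke–Durbin form): each
observed channel intensity is
`true * exp(N(0, sigma_mult^2)) + N(0, sigma_add^2)`, truncated at zero.
Defaults: `sigma_mult = 0.1` (10% CV), `sigma_add = 5` linear units,
background mean 20 ± 4. A smooth intensity-dependent dye bias
(`0.3 * cos(pi (A - 8)/6)` log2 units by default) is applied with
opposite signs to the two channels; the dye-swapped replicate of each
pair has its channels exchanged. Each array draws from an RNG stream
sub-seeded from the design seed, so adding arrays never perturbs earlier
ones. Pooling of several animals per replicate is not simulated
explicitly; the multiplicative CV is interpreted as the post-pooling
biological + technical coefficient of variation.

**What the generator does not emulate:** probe sequences and
cross-hybridization, spatial array artifacts, scanner saturation, and
probe-specific affinity differences. Passing recovery tests therefore
demonstrate correctness of the statistical chain under the stated noise
model, not robustness to those artifacts.

## Normalization and the error model

1. **Linear normalization** equalizes the channel medians over
   well-above-background probes (red channel as reference).
2. **Well above background**: both raw channels must strictly exceed the
   99th percentile (nearest-rank) of the array's background population.
3. **Intensity-dependent (LOWESS) normalization.** The standalone
   operation fits M = log2(red/green) on A per array (span 0.3, tricube,
   2 robustness iterations) over well-above-background probes and
   subtracts the fit. The comparison pipeline instead exploits the
   balanced dye swap: the unoriented per-probe mean of a swap pair's M
   values cancels the biological signal and leaves the dye-bias curve
   plus noise, so one shared curve is fitted to that mean and subtracted
   from both arrays. Per-array fitting would absorb whatever real
   regulation is locally correlated with intensity — an error that is
   common-mode across the swap pair and survives averaging, while the
   dye bias it targets cancels in the oriented mean anyway. The
   correction is held constant outside the central 95% intensity range,
   where the local window is dominated by a handful of probes.
4. **Feature-level error.** The technology component propagates the
   additive + multiplicative model to the log2-ratio scale:
   `sigma_tech^2 = [sigma_add^2/red^2 + sigma_add^2/green^2 +
   2 sigma_mult^2] / ln(2)^2`. The replicate component is the pooled
   between-replicate scatter of oriented ratios, estimated within ten
   intensity quantile bins (scatter is strongly intensity-dependent)
   after subtracting a smooth of each replicate's deviation versus log
   intensity — that smooth is the dye-swap-antisymmetric residual, which
   cancels exactly in the oriented mean and must not be charged to its
   error. Each replicate's variance is `max(sigma_tech^2, sigma_rep^2)`:
   the maximum guards against underestimating error with only two
   replicates, at the cost of mild conservatism.
5. **Combination**: inverse-variance weighting of the oriented replicate
   ratios; `p = 2(1 - Phi(|ratio|/sigma))`. No t-correction is applied
   with k = 2; the z form follows from the error-weighted-average
   formulation. A sigma floor of 1e-6 log2 units keeps weights defined in
   the noiseless limit.

Under self-self simulation at the default noise settings the null
p-values are uniform (Kolmogorov–Smirnov); the error model is by design
slightly conservative, never anticonservative.

## Flags and classification

A comparison is flagged 1 (up) when ratio > 1.5, p < 1e-4 and the probe
is well above background on all contributing arrays; 2 (down) when ratio
< 1/1.5 under the same conditions; else 0. All inequalities are strict.
The seven flags encode as a TFS code: binary weights 1, 2, 4, 8, 16, 32,
64 mark which comparisons fired (whole number), and the seven ternary
digits after the decimal point carry the directions.

Redundant probes — same gene symbol, same TFS group — are collapsed to
the probe minimizing the sum of log10 p over its flagged comparisons
("lowest set of p-values" as a single scalar; ties break to the smallest
probe id). Probes of one gene in different TFS groups are all retained,
as separate rows.

Classification reads the flags only: adult sex class from comparison 3;
onset as the earliest age whose sex flag matches the adult direction;
early sex flags in the other direction (or with no adult call) recorded
as `transient_bias`; per-sex developmental calls from the two interval
flags (both directions present → `mixed`, reported rather than coerced).
The stringent sex-independent call additionally requires an 8-wk sex
ratio below 1.2 in either direction, p > 0.01, and mean signal intensity
≥ 25 (mean of the two normalized channels on the 8-wk sex comparison).
Candidate transcriptional regulators are regulated genes whose GO
descriptor contains "DNA binding" or "transcription" (case-insensitive),
with 8-wk intensity ≥ 25, |fold| > 2 on every comparison significant at
p < 1e-4, and — for sex-biased genes — an 8-wk sex ratio above 2 (or
below 0.5).

## Profile clustering

The seven log2 ratios form an ordered pseudo-series. Candidates are all
integer profiles starting at 0 with steps bounded by c = 2 (5^6 - 1 =
15,624); a greedy max-min algorithm (first pick: maximum summed distance;
ties to enumeration order) selects m = 30 (or 50) mutually distinctive
profiles under the 1 - Pearson distance; genes go to their nearest
profile (ties to the lowest id); constant vectors are quarantined in a
flat bucket. Significance: B within-gene permutations (each gene's seven
values shuffled) give the expected count per profile; the observed count
is tested against Binomial(n, expected/n) upper tail, Bonferroni-corrected
over profiles at 0.05. Sex-specific and sex-independent genes are
clustered separately and never mixed. Hierarchical clustering (average
linkage, same distance; constant rows at distance 1) provides gene and
array orderings and a Newick export.

## Enrichment statistics

For gene sets of sizes n and K overlapping in k genes on a background of
N, fold enrichment is `k N / (n K)`. The two-tail Fisher exact p-value is
computed in log space (log-gamma point probabilities; all tables at most
as probable as the observed one, with the standard 1 + 1e-7 tie
tolerance). Two table conventions are provided: the default **marginal**
layout `[[k, n-k], [K, N-K]]` compares the overlap rate within set A to
set B's prevalence in the whole background and is the convention under
which the published enrichment tables this package mirrors reproduce to
print precision; the **partitioned** layout `[[k, n-k], [K-k, N-n-K+k]]`
is the textbook 2x2 partition. Fold enrichment is symmetric in the two
sets; the marginal p-value conditions on set A and is not. Backgrounds
are case-folded symbol intersections of the two platforms, optionally
restricted to stringent sex-independent genes when the foreground sets
are themselves sex-independent.

## Numerical and degenerate-input choices

- Strict inequalities at every filter boundary (a ratio of exactly 1.5
  is unflagged; a signal equal to the background threshold fails).
- Undefined feature error (non-positive intensity) yields NaN and the
  probe is excluded, never imputed.
- Correlation with a constant vector is treated as 0 (distance 1).
- Truth-record developmental directions use a 1e-9 relative tolerance on
  linear ratios.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning (per-array and per-purpose
  streams), so outputs are byte-identical across runs.

## Problem sizes used in tests

The test suite exercises the pipeline at reduced scale: 2,000-probe
noiseless end-to-end runs (exact truth recovery), a 5,000-probe noisy
recovery simulation (effect folds 2–4, two dye-swap replicates), and
10,000-probe self-self null calibration — sizes chosen so the full suite
runs in well under a minute per property while keeping every estimate's
sampling error far below the tested tolerances.

## Known limitations

- The error model is a documented surrogate for the proprietary Rosetta
  model: same contract (intensity-dependent technology error combined
  with replicate scatter, error-weighted averaging), not the same code.
- With two replicates the z-based p-values lean on the technology error
  component; grossly misspecified noise parameters would miscalibrate
  them (the max rule protects only against underestimation).
- Gene symbols are matched case-insensitively with no alias resolution.
- The marginal Fisher convention reproduces the published tables but is
  not the textbook partition; both are exposed and tested.
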