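# Methods

## Data model

A cohort is an `ArraySet`: two probes × samples matrices of methylated (M)
and unmethylated (U) fluorescence intensities plus a manifest assigning each
probe to one of three classes — Type I green (P1g), Type I red (P1r), Type II
(P2) — with chromosome and CpG/non-CpG annotation. Methylation is summarised
as m = ln(M/U) (natural log throughout; a `base` argument is available) or
β = M/(M+U), inter-convertible by the logistic transform β = e^m/(e^m + 1).
Missing values are NaN and propagate through every transform; β ∈ {0, 1}
maps to missing m rather than ±∞. Intensities ≤ 0 (possible in data that
was background-subtracted upstream) are clamped to a configurable floor
(default 1.0) before logs; clamped counts are logged.

## The normalization

Per colour channel, the housekeeping probes of the matching Type I class
provide fit points: both M and U signals of each probe are pooled into one
point cloud (each signal is just a measurement in that channel), giving per
point an explanatory value ln S and a response ln S − S\*, where S\* is the
per-(probe, signal) median of ln S across samples. A robust loess curve f is
fitted per sample and applied multiplicatively, S′ = S·e^(−f(ln S)), to all
intensities of that channel — including the Type II channel that shares the
dye: methylated Type II signals are green (Cy3), unmethylated red (Cy5). A
second, subtractive loess stage on Type II m-values (m″ = m′ − f₂(m′),
reference = per-probe median m′ over samples on the housekeeping Type II
probes) removes the residual methylation-dependent dye bias. Type I m-values
are not touched by stage two, and disabling stage two leaves them
bit-identical.

Normalization involves no randomness: given inputs and parameters the output
is byte-reproducible.

### Loess

No suitable local-regression implementation with degree-2 fits and bisquare
robustness was available as a dependency, so `methloess.smoothing` provides
one: for each evaluation point the span-fraction of nearest neighbours
(exact contiguous-window selection on sorted x) is fitted by weighted least
squares with tricube weights, and `robust_iterations` bisquare re-weighting
passes (weights (1 − (r/6s)²)²₊ with s the median absolute residual)
down-weight outliers such as contaminating variable CpG sites. Defaults:
span 0.75, degree 2, 4 robustness iterations — conventional loess defaults;
the method's sensitivity to them has not been explored here and all are
exposed in `LoessParams`. The curve is evaluated on a dense grid (2048
points, configurable) spanning the fit points and interpolated linearly
elsewhere, which makes evaluation cheap and deterministic; a tiny relative
ridge (1e-10) keeps degenerate windows solvable without visibly perturbing
the fit. The test suite cross-checks the degree-1 path against statsmodels'
independent lowess implementation.

### Out-of-range policy

The fitted curve is only trusted on the range of the sample's housekeeping
fit points. Measurements outside it are discarded (set missing) and counted
per sample — the default — or, with `CLAMP_TO_BOUNDARY`, corrected with the
boundary value of the curve, trading a boundary bias for completeness. The
two policies produce identical stage-one outputs except at the discarded
entries; stage two, however, refits f₂ on whichever housekeeping m-values
survived stage one, so Type II outputs may differ slightly everywhere
between the policies. `n_discarded` counts discarded *measurements* (M or U
signals, and stage-two m-values); a probe losing both channels contributes
two discarded measurements but only one missing m-value.

### References

References are per-probe medians (midpoint convention for even sample
counts), computed once per cohort and shared by all its samples.
Housekeeping probes missing in more than half the samples are dropped from
the reference with a warning; housekeeping ids absent from the manifest are
reported, not silently ignored. A previously computed `ReferenceVector` can
be frozen to file and supplied to `normalize`, so new samples can be
normalized against an earlier cohort's baseline.

## Quantile-normalization baselines

`quantile_normalize` replaces each column's sorted values by the mean sorted
profile (Bolstad-style), ties receiving the mean of their would-be quantile
values. Columns with missing entries are mapped through average-rank
interpolation onto the mean quantile profile, which reduces exactly to the
classic construction for complete columns. QN1 applies this to intensities
in four independent blocks — P1g (M and U pooled, since the two signals of a
Type I probe live in one channel), P1r (pooled), P2 methylated, P2
unmethylated — and then computes m-values; QN2 applies it to raw m-values in
three blocks (P1g, P1r, P2). Because forcing identical distributions across
mixed-sex cohorts distorts sex-chromosome probes, both default to
normalizing autosomal probes only and passing the rest through.

## The simulator

The generator produces cohorts exhibiting the three documented phenomena the
normalization targets, with ground truth for benchmarking:

* per-sample smooth intensity bias: observed log-intensities are distorted
  by g_z (linear, quadratic or sigmoid family; per-sample coefficients drawn
  from a configured range with random sign);
* Type II dye bias: an additive log-scale term with opposite sign in the two
  channels, scaled by the probe's methylation state (1 − 2β), so the induced
  m-value bias is a smooth decreasing function of m — intensity plots of
  replicates then show unmethylated probes above and methylated probes below
  the diagonal;
* heteroscedastic m-values: an additive fluorescence background
  (mean 100, sd 50 in intensity units against a full-signal scale of 5000)
  makes the weaker channel noisy, so the sd of m rises steeply at extreme
  methylation (the U-shape of sd against mean m).

Signals are M = a·c·β·D and U = a·c·(1−β)·D with probe affinity a lognormal
(log-sd 0.8), sample scale c lognormal (log-sd 0.15), D = 5000, plus
multiplicative log-normal measurement noise (log-sd 0.10). True β comes from
class-specific Beta mixtures — Type I (CpG-island-like) mostly unmethylated,
Type II mostly methylated. Technical replicate pairs share the underlying
individual (β and affinities) and draw independent scale, bias and noise;
biological variation across individuals is an m-scale jitter (sd 0.3).
Housekeeping probes (5% of each class) are constant across individuals
except for a 5% contamination fraction of variable sites, exercising the
loess robustness. Planted differential probes shift one sex group by a
configured m-effect (default 50 probes, 1.0 m-units); planted
trait-associated probes track age. The default cohort is 20,000 probes
(3,000 / 3,000 / 14,000 across P1g/P1r/P2, approximating the chip's ~30/70
type split — scaled down from the chip's ~485k probes to keep simulation
cheap) and 10 replicate pairs; under these defaults raw replicate m-value
correlations land in the 0.95–0.99 range typical of real replicate pairs.

In the fully deterministic configuration (bias family `none`, zero noise,
zero dye amplitude, zero background sd) sample scale factors are shared
within replicate pairs so replicates coincide exactly; this is the
degenerate case used to test fixed-point behaviour.

What the simulator does **not** emulate: bead-level replicates and their
summarisation, cross-hybridization, probe-sequence-dependent bias, plate or
chip spatial layout, cell-type composition. Passing benchmarks on synthetic
cohorts therefore demonstrates that the pipeline removes the bias structure
it models — not that it removes every artefact of real 450K data.

## Benchmarks

1. **Replicate correlation** — Pearson correlation per technical-replicate
   pair over shared non-missing probes, on m- and on β-values, separately
   for P1 and P2; non-CpG probes and X/Y probes excluded. Per method: the
   number of pairs where it achieved the highest correlation (ties count for
   all tied methods) and where it declined versus raw.
2. **Split-half concordance** — pairs split into two halves (first member →
   half 1; a seeded shuffle option exists); per half, probes ranked by
   two-sample t-test p-value on m-values between groups (Welch by default;
   pooled-variance optional), ties broken by |t| then probe id; the curve
   100·|top-k ∩ top-k|/k over k. A permutation-of-labels baseline estimates
   the no-signal overlap. With few pairs per group this benchmark is noisy;
   the gain from normalization emerges reliably at ≈20 pairs and above.
3. **Trait correlation** — Spearman correlation of a probe's methylation
   with a trait; invariant under the m/β transform, so reported once.

t-test rankings are invariant under affine transformations of the m-values,
which is why between-sample comparability — not absolute accuracy — is what
normalization must deliver for univariate screening.

## Numerical and design choices

* Matrix orientation is probes × samples everywhere; text I/O is
  tab-separated with `NA` for missing.
* Pearson correlations exclude missing values pairwise; a replicate pair
  sharing fewer than 100 probes is an error.
* Fitting requires at least 50 usable points per curve (configurable);
  fewer is an error naming the sample, advising a larger housekeeping set.
* Sex-chromosome probes **are** normalized by the loess method; their
  exclusion is a benchmark-level filter only. The QN baselines, by
  contrast, restrict to autosomes by default.
* Per-signal (unpooled) channel fits are available behind
  `pool_signals=False` for sensitivity analysis.
* Loess fits use all housekeeping points (no subsampling); stage two uses
  only probes whose both channels survived stage one, since missingness
  propagates through m′.

## Known limitations

* The housekeeping set is user-supplied and assumed mostly invariant;
  deriving an invariant set from data is out of scope.
* The discard policy loses a small fraction of measurements at the intensity
  extremes; clamping is offered but introduces boundary bias.
* Within-array Type I/Type II harmonisation (SWAN/BMIQ-style) is
  deliberately out of scope; the benchmark harness accepts externally
  produced matrices for such methods instead.
* Benchmark sizes in the test suite are scaled-down study conditions chosen
  for cheap simulation; they reproduce the qualitative behaviour of the
  method, not cohort-scale effect sizes.
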