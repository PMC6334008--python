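# Methods

## Cardiac model and ABT estimation

The simulated heart-rate curve is two-phase in Arrhenius coordinates
(x = 1000/K with K = °C + 273.15, fixed convention; y = ln beats min⁻¹):
a pre-breakpoint segment of slope `slope_pre` (default −7, i.e. rate
rising with temperature at a Q10 of roughly 2) and a post-breakpoint
collapse of slope `slope_post` (default +40), continuous at
x_b = 1000/(ABT + 273.15) and anchored so the rate at 20 °C equals
`hr_at_20C` (default 30 beats min⁻¹, rising to ~75 near a 31.9 °C
breakpoint — the range reported for tolerant-line abalone).  Observation
noise is Gaussian on ln(hr) (`noise_sd`, default 0.05); each observation
can independently be flagged arrhythmic (`arrhythmia_prob`), emulating
the arrhythmia bursts seen near the breakpoint.  The ramp is 0.1 °C min⁻¹
over 20–34 °C with 60 observations by default; the number of observations
per individual is exposed (`n_points`) rather than assumed.

The fitter does **not** assume continuity: each side of a candidate split
is fit by independent OLS, every split with at least `min_seg` points per
segment (default 4, keeping both fits overdetermined) is enumerated, and
the minimum-total-RSS split wins.  The breakpoint is the intersection of
the two fitted lines when it falls between the bracketing data points,
otherwise the bracket midpoint; `convention="split-midpoint"` forces the
midpoint.  Exact ties in RSS (which arise for exactly collinear data) are
resolved toward the larger pre-breakpoint segment, then the lower
breakpoint temperature; for this purpose RSS values below 10⁻¹² × TSS are
snapped to zero, since below that level differences are pure rounding
noise.  When the two-segment fit reduces the single-line RSS by less than
5% the fit is annotated `no_distinct_breakpoint`.  The reported ABT is
always inside the observed temperature range by construction.

Raw pulse traces are simulated as raised-cosine pulse trains driven by the
integrated instantaneous rate (trapezoidal integration of the model rate;
beats at unit phase crossings), with corrupted 30-s windows flagged and
their beats removed.  Beat detection is peak-picking
(`scipy.signal.find_peaks`) with a prominence threshold and a refractory
distance; a flat signal warns and returns no beats rather than raising.
Heart rate per 0.5 °C temperature window (≈ 5 min of ramp) is
60 × beats / window duration; windows overlapping arrhythmia flags or
containing fewer than two beats are excluded and counted in diagnostics.

## Line comparison

One-way ANOVA is computed from the standard sum-of-squares decomposition.
Duncan's multiple range test compares each stretch of p adjacent ordered
means against q(α_p, p, df_within)·√(MS_within/n_h), with protection
level α_p = 1 − (1 − α)^(p−1) and n_h the harmonic mean group size
(unbalanced designs are accepted with a logged note).  Studentized-range
quantiles come from `scipy.stats.studentized_range` (numerically
integrated; cached, since the same quantile recurs across stretches).  A
pair contained in a non-significant longer stretch is itself
non-significant; the compact letter display assigns one letter per
maximal mutually-non-significant run, so lines share a letter iff they
are statistically indistinguishable.  At k = 2 the procedure reduces
exactly to the pooled two-sample t-test via q(α, 2, df) = √2·t(α/2, df).
Reported spreads are sample standard deviations across individuals
(ddof = 1); the package treats published "mean ± value" figures as sd.

## Count model and differential expression

Counts are negative binomial, Var = μ + αμ², with log-normal baseline
means (ln-scale mean 5, sd 1.5 — median ≈ 150 counts) and a decreasing
dispersion trend α(μ) = 0.05 + 2/μ, the standard bulk RNA-seq shape.  The
default design is 2 lines × 2 conditions × 3 replicates.  Heat-response
fold changes are spiked into 10% of genes in the sensitive line and 4% in
the tolerant line (preserving the ~2.5:1 DEG asymmetry reported for
sensitive vs tolerant responses); 75% of tolerant-line responders are
shared with the sensitive line and keep the same sign, scaled by
N(1.15, 0.2) so shared genes respond somewhat more strongly in the
tolerant line.  Spiked |log2 FC| is 1.6 + Exp(1.5) truncated at 11.9,
covering the span observed for the HSP family.  A separate 3% of genes
carry constitutive between-line differences, feeding the between-line
contrasts.  The truth table records the implied log2 FC for all four
contrasts.

Size factors are median-of-ratios over genes positive in every sample.
Because the per-gene reference is the geometric mean across samples, only
ratios of size factors are identified: multiplying one library by c
multiplies its factor by c·c^(−1/m) and every other factor by c^(−1/m).
Dispersions are per-gene method-of-moments on normalized counts, with the
within-cell variance pooled across all (line, condition) cells, floored
by a least-squares α(μ) = a₀ + a₁/μ trend (final = max(gene, trend), the
conservative choice).  The test is a Wald test on the difference of log
normalized group means with the delta-method SE from
Var(K_ij/s_j) = μ/s_j + αμ², against a normal reference.  This choice was
calibrated on the generator's null (5000 genes, 3 vs 3): empirical type-I
error at nominal 0.05 was 0.033–0.042 across seeds; a t(df = 4) reference
was rejected as far too conservative (0.003).  Power for |log2 FC| = 2
spikes at mean 200 and dispersion 0.05 exceeds 0.99.  The DEG filter is
the strict raw-p rule (p < 0.05 and |log2 FC| > 1); a Benjamini–Hochberg
column is provided for modern use but does not drive the flag.  The gene
universe per contrast is genes with nonzero total count across the
compared samples.  When exactly one group mean is zero, a pseudocount of
1 is added to both means and the gene flagged; both-zero genes are
excluded with a flag.  Note that spiking a large fraction of genes in one
direction violates the median-of-ratios assumption that most genes are
unchanged — power/calibration simulations here keep spike fractions ≤ 10%.

## Enrichment

The probability-weighting function P(DE | length) is fit by increasing
isotonic regression on equal-count length bins (30 by default) — monotone
by construction, simpler than a spline, and degenerate inputs (all or no
genes DE) fall back to flat weights with a warning.  Weights are clipped
to (10⁻⁶, 1 − 10⁻⁶).  Category odds are the mean weight inside the
category over the mean weight outside; the upper-tail p comes from
`scipy.stats.nchypergeom_wallenius`, which matches the exact
sequential-draw recursion to ~10⁻¹² and reduces to the central
hypergeometric at odds = 1 to the same accuracy (both verified in the
test suite against enumeration oracles).  Note the tail p *increases*
with the category's odds: heavier category weights make large DE counts
in the category less surprising under the null.  KEGG-style enrichment is
the central hypergeometric with optional BH adjustment.  GO-hierarchy
propagation is out of scope; categories are flat sets.

Family summaries average each line's log2 FC over that line's **own** DE
family members (signed); on the packaged HSP table this gives 5.5
(sensitive) and 7.1 (tolerant), a tenth of a unit above the published
rounded values, consistent with the source having averaged unrounded
fold changes.

## Problem sizes and determinism

Simulation-based checks use 200 ramps (ABT recovery), 500 instances
(breakpoint oracle), 5000 genes (test calibration), 2000 replicates
(Duncan/t-test agreement) and 500 replicates (five-line identification)
— sizes at which the Monte-Carlo error is well below the decision margins
while the whole suite runs in seconds.  All generators take explicit
seeds and are bitwise reproducible; the pipeline writes byte-identical
report bundles under a fixed config.

## Known limitations

The count simulator draws independent NB counts per gene (no gene–gene
correlation, GC bias, or batch structure) and the cardiac simulator uses
a sharply two-phase curve, so passing recovery tests demonstrates
estimator correctness under the assumed model, not robustness to real
sensor artefacts or library-preparation effects.  The Wald/normal test is
mildly conservative at n = 3.  Under Gaussian sampling at the published
five-line means and spreads with 16 individuals per line, the probability
that the extreme lines are both correctly identified by sample means is
≈ 0.92 — the overlap between the most sensitive line (28.5 ± 1.8 °C) and
its neighbours (29.5 ± 1.2/1.7 °C) caps the identification rate, a
constraint inherent to those study conditions rather than to the
estimator.
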