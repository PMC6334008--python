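# haliotherm

Heat-tolerance analysis for Pacific abalone (*Haliotis discus hannai*)
selective lines: estimation of the **Arrhenius breakpoint temperature
(ABT)** of cardiac performance from temperature-ramp heart-rate recordings,
statistical comparison of lines, and a from-first-principles
**negative-binomial differential-expression and enrichment** stage for the
paired heat-stress RNA-seq design, with synthetic-data generators that
reproduce the statistical structure of both assays.

## The science

In marine ectotherms the upper thermal limit of cardiac function is a
reliable, non-invasive proxy for whole-animal heat tolerance.  On an
Arrhenius plot — ln(heart rate, beats min⁻¹) against inverse absolute
temperature x = 1000/K, K = °C + 273.15 — heart rate rises approximately
linearly as the animal warms, then collapses abruptly past a critical
temperature.  The ABT is located by **broken-stick regression**: every
admissible split of the x-sorted series into a low- and a high-temperature
segment (each with ≥ `min_seg` points) is evaluated, two independent OLS
lines are fit, and the split minimising total residual sum of squares is
selected; the breakpoint is the intersection of the two fitted lines
(or the bracket midpoint).  Lines are compared by one-way ANOVA with
Duncan's multiple range test and compact letter display.

The expression stage re-implements the classic count-based DE pipeline:
median-of-ratios size factors, method-of-moments dispersion estimates
floored by a fitted α(μ) = a₀ + a₁/μ trend, a per-gene Wald test on the
difference of log normalized means (Var K = μ + αμ²), and the strict DEG
filter *p* < 0.05 and |log2 FC| > 1, applied to four contrasts (between
lines at each temperature; between temperatures within each line) with
Venn partitioning.  Category enrichment corrects for gene-length detection
bias via a monotone probability-weighting function and the **Wallenius
non-central hypergeometric** distribution; pathway enrichment uses the
central hypergeometric.  The two reference tables of the underlying study
(35 differentially expressed heat-shock-protein genes; 12 down-regulated
cell-cycle / DNA-replication genes) ship as packaged fixtures.

## Worked example

Simulate one tolerant-line individual's ramp recording and estimate its
ABT:

```bash
$ python -c "
from haliotherm.io import write_series_csv
from haliotherm.simulate import CardiacSimParams, simulate_heart_rate_series
write_series_csv(simulate_heart_rate_series(
    CardiacSimParams(abt_true=31.9, noise_sd=0.05, seed=42)), 'yl_01.csv')"
$ haliotherm abt yl_01.csv
ABT_C	31.98
max_hr_bpm	77.05	at_temp_C	31.86
rss_total	0.0859589
```

The estimated breakpoint (31.98 °C) recovers the simulated 31.9 °C within
a tenth of a degree, and the maximum heart rate occurs just below the
breakpoint, as expected for a two-phase thermal performance curve.

Simulate the 2-line × 2-condition × 3-replicate count matrix and run the
four contrasts:

```bash
$ haliotherm simulate counts --n-genes 2000 --seed 1 --out-prefix sim
$ haliotherm de sim_counts.tsv sim_samples.tsv --out-dir de_out
I	DEGs	68	up	37	down	31
II	DEGs	244	up	137	down	107
III	DEGs	216	up	140	down	76
IV	DEGs	95	up	61	down	34
venn_III_IV	common	60	only_III	156	only_IV	35
```

Contrast III (heat vs control in the sensitive line) yields more than
twice the DEGs of contrast IV (the tolerant line), mirroring the
asymmetric transcriptional response the simulator encodes.  The packaged
reference tables are available via `haliotherm fixtures table1|table2`,
and `haliotherm report --out-dir out` runs the full pipeline (ABT table,
line summary with significance letters, contrasts, Venn partition,
enrichment and family/pathway summaries plus a JSON manifest).

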