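# Methods

## The screening procedure

`radscreen` implements a dose-response screen over bulk RNA-seq counts from
a dose x timepoint x replicate irradiation experiment (the reference design:
*Drosophila melanogaster* sampled 2, 10 and 20 days after X-ray exposures of
0, 10, 1000, 5000, 10,000 and 20,000 roentgen, three replicates per
condition, with one failed control replicate at day 20). The goal is to find
genes whose expression responds to dose predictably enough to act as a
biological dosimeter.

The stages, in run order:

1. **Depth normalization.** Median-of-ratios size factors: the reference for
   gene *g* is its geometric mean across samples (genes with any zero count
   are excluded from the reference but are still normalized), and sample
   *j*'s factor is the median over reference genes of `count[g,j] / ref[g]`.
   Even-length medians are the arithmetic midpoint of the two central
   ratios. The estimator leaves a free global scale; we fix it by rescaling
   factors to unit geometric mean. This makes normalization exactly
   idempotent (renormalizing a normalized matrix gives unit factors) and is
   invisible to everything downstream, since fold changes are ratios in
   which any global scale cancels. For matrices with an odd number of
   reference genes the factors coincide (to 1e-12, after scale fixing) with
   pydeseq2's implementation of the same estimator, which one test uses as
   an independent cross-check; for even counts the two differ microscopically
   because pydeseq2 takes the median on the log scale (a geometric midpoint).

2. **Condition means and the present/absent cutoff.** Mean normalized
   expression per (gene, timepoint, dose), over however many replicates the
   condition has. Per timepoint, the cutoff is the 0.25 quantile
   (linear-interpolation convention) of all per-(gene, condition) means of
   that timepoint, control conditions included. Under the generator's
   default baseline distribution this lands at ~18.5 counts, consistent with
   the bottom-quartile filter (~18-20 counts) used on the reference dataset.

3. **Fold changes.** For each gene, timepoint and dose > 0:
   `FC = mean(dose) / mean(0)`. A fold change is *absent* when both means
   fall below the timepoint's cutoff; it is *undefined* when the control
   mean is zero while the experimental mean passes the cutoff (the ratio is
   infinite; treating it as a non-passing dose is the conservative choice).
   Only *defined* fold changes feed either screen.

4. **Linear screen.** Per gene and timepoint, ordinary least squares of fold
   change on dose — dose on the linear roentgen scale, fold change as a
   plain ratio, no log transforms — over the defined fold changes, after
   removing any excluded doses. Selection requires at least `min_doses = 4`
   defined fold changes and `R^2 > 0.9` strictly. R^2 is undefined (and the
   gene unselectable) when the fold changes are constant, including constant
   up to float rounding (relative spread <= 1e-12): a zero-variance ratio
   carries no dose information, and without the tolerance a noise-free gene
   written to TSV and re-read could acquire an arbitrary R^2 from its
   last-ulp rounding pattern. The dose-0 point (FC = 1 by construction) is
   *not* a regression point by default — it would add a constant-by-
   construction observation and inflate R^2 — but `include_control_in_fit`
   exposes the alternative, since the choice is not derivable from the
   screen's published description and changes gene counts on real data.

5. **Spike screen.** Per gene and timepoint, over the same defined fold
   changes: the gene spikes if `max FC >= 5 x second-largest FC` (inclusive,
   reading "at least five times") and `max FC > 1`. Ties for the maximum
   give ratio 1 and can never spike. At least 3 defined fold changes are
   required (with two, "second largest" is degenerate); the gate is
   configurable because the original screen states none. For reporting
   spikes grouped by dose, spikes at the highest analyzed dose are omitted
   (a top-dose maximum is more plausibly a monotonically increasing gene),
   but such genes still count in the per-timepoint sets and overlaps, which
   are formed before grouping.

6. **Overlaps.** For every non-empty subset of timepoints, the intersection
   of the selected sets and the exclusive (Venn) region. The genes selected
   at *all* timepoints are the dosimeter candidates.

The pipeline always emits four analyses — linear and spike, each with all
doses and with the excluded doses removed. When no exclusion is configured
the secondary analyses drop the lowest positive dose present (10 R in the
reference design, a dose small enough for flies that its signal may be
noise).

## Null behaviour of the R^2 gate

For a gene whose fold changes at *n* doses are i.i.d. Gaussian noise around
a constant, R^2 of the OLS fit follows Beta(1/2, (n-2)/2). At n = 5 the
survival at the 0.9 threshold is 0.0138, so the linear screen passes ~1.4%
of pure-noise genes per timepoint; requiring all three timepoints drives the
expected null rate to ~3e-6. The screen applies no multiple-testing
correction (none is part of the procedure being reproduced); the Beta tail
is verified by Monte Carlo in the acceptance suite.

## The synthetic-data generator

`SimConfig` defaults encode the study conditions: the 3 x 6 x 3 design with
one dropped control replicate; log-normal baselines with `log mean 3.6, log
sd 1.0`, chosen so the bottom quartile of baseline means sits at ~18.5
counts (matching the reference dataset's reported cutoff range); negative-
binomial counts with `variance = mean + alpha * mean^2` and `alpha = 0.05`
(typical bulk RNA-seq biological replicate overdispersion; `alpha = 0`
degenerates to Poisson, `zero_noise=True` emits expected values exactly);
log-normal per-sample depth multipliers with log-sd 0.15, which the
normalization stage must undo.

Planted classes: 5% linear genes (`expected FC = 1 + slope * dose`, slope
uniform in [5e-5, 1.5e-4] per roentgen, so FC at the top dose spans 2-4;
negative slopes are admissible and the expected FC is floored at 0.05), 1%
spike genes (amplitude uniform in [8, 25] at one planted dose), the rest
null. Two generator choices deserve justification:

* **Planted signal genes get a +2 baseline log-mean boost over null genes.**
  The present/absent filter removes the bottom quartile of expression by
  construction; planting signals inside that quartile would make exact
  recovery impossible for reasons unrelated to the screen's logic. The
  generator therefore emulates genuinely expressed responsive genes, and the
  filter's behaviour on low-expression genes is exercised by direct unit
  tests instead. Consequently, recovery results say nothing about the
  screen's sensitivity to weakly expressed responders — on real data a
  dose-linear gene below the cutoff is invisible to this procedure.
* **Spikes are planted at interior doses (1000/5000/10,000 R) by default.**
  A spike at the lowest dose vanishes from the lowest-dose-excluded
  analysis, and one at the top dose is excluded from dose grouping by
  design; interior doses make all four analyses exercise the planted truth.
  `spike_dose_choices` overrides this.

All randomness flows from one `numpy` Generator seeded from `SimConfig.seed`
with a fixed draw order (baselines, slopes, spike parameters, depths, then
counts gene-row by gene-row in sample order), so outputs are bit-identical
across runs and platforms.

What the generator does **not** emulate: gene-length and GC biases,
correlated genes, batch effects, count truncation from alignment/filtering
pipelines, or timepoint-dependent effect sizes (a planted gene has the same
slope or spike at every timepoint, which makes the all-timepoint overlap a
clean recovery target but is more regular than real biology). Passing
recovery tests therefore validate the screen's logic and numerics, not its
biological yield on any particular dataset.

## Recovery performance and its limits

With zero noise, recovery is exact: all planted linear genes (R^2 = 1) and
spike genes are selected at every timepoint, null genes have zero
fold-change variance (undefined R^2) and can never be selected, and the same
sets survive exclusion of the 10 R dose using exactly the four high doses.

With noise the screen degrades smoothly. At `alpha = 0.05` and planted FC 3
at the top dose, the CV of a 3-replicate condition mean is
`sqrt(alpha/3) ~= 0.13` (control-mean noise multiplies all of a gene's fold
changes equally and cancels out of R^2, which is scale-invariant);
propagating this through the leverage-weighted OLS residual gives a per-gene
probability of R^2 > 0.9 around 0.87, so per-timepoint sensitivity settles
near 0.85-0.90 and degrades monotonically as dispersion grows (to ~0.4 at
`alpha = 0.2`). The R^2 > 0.9 gate is, in other words, roughly a one-sigma
criterion at this design's noise level — a useful thing to know before
applying the screen to designs with fewer replicates.

## Problem sizes

Tests and the acceptance script use 1000-gene datasets in the full 53-sample
design (the screen is linear in genes, so gene count affects only the
granularity of rate estimates), 10,000 genes for the null-calibration Monte
Carlo, and 1000 random inputs for the OLS oracle comparison. The whole suite
runs in well under a minute.
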