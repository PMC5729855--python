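# radscreen

Dose-response gene-expression screening for radiation biodosimetry.

When someone is exposed to ionizing radiation without a physical dosimeter,
the absorbed dose can in principle be read off biological measurements.
`radscreen` implements the transcriptomic version of that idea as a tested,
reusable pipeline: starting from a bulk RNA-seq count matrix over a
dose x timepoint x replicate design (the reference design is *Drosophila
melanogaster* at 2, 10 and 20 days after X-ray exposures of 0-20,000
roentgen), it finds the genes whose expression tracks dose predictably —
the candidate biodosimeter panel.

## The screen

For gene *g*, timepoint *t* and dose *d* > 0, the fold change is

```
FC(g,t,d) = mean normalized expression at (t,d) / mean normalized expression at (t,0)
```

computed on median-of-ratios (size-factor) normalized counts, with a
present/absent filter: FC is ignored when both means fall below the bottom
quartile of that timepoint's per-(gene, condition) means (~18-20 counts at
the defaults). Two selection rules are applied per timepoint:

* **linear:** ordinary least squares of FC on dose (linear roentgen scale);
  select if at least 4 doses have defined fold changes and R² > 0.9;
* **spike:** select if the largest FC is ≥ 5x the second largest and > 1 —
  a single-dose expression burst rather than a monotone trend.

Both screens are rerun with the lowest dose (10 R, likely noise-level for
flies) excluded, and gene sets are intersected across timepoints; genes
selected at every timepoint are the dosimeter candidates. A synthetic-data
module generates negative-binomial count datasets in the same design with
planted linear, spike and null genes, so every stage is verifiable by
parameter recovery without any external download. See `docs/methods.md` for
conventions and caveats.

## Worked example

Simulate a 300-gene dataset in the full study design (15 planted linear,
3 planted spike, 282 null genes), run all four analyses, and print the
all-timepoint overlaps:

```
$ radscreen all --simulate-genes 300 --seed 42 --out-dir demo
linear: all-timepoints overlap ['g0000', 'g0002', 'g0003', 'g0004', 'g0006', 'g0007', 'g0010', 'g0011', 'g0012']
linear_excluded: all-timepoints overlap ['g0000', 'g0002', 'g0003', 'g0006', 'g0007', 'g0010', 'g0011']
spike: all-timepoints overlap ['g0015', 'g0016', 'g0017']
spike_excluded: all-timepoints overlap ['g0015', 'g0016', 'g0017']
```

Genes `g0000`-`g0014` are the planted linear genes and `g0015`-`g0017` the
planted spikes: at this noise level (negative-binomial dispersion 0.05) the
spike screen recovers all 3 planted spike genes exactly, while the linear
screen recovers 9 of 15 at all three timepoints simultaneously — the R² > 0.9
gate is roughly a one-sigma criterion at this replicate count, so genes with
the weakest planted slopes drop out of one timepoint or another. Rerunning
the screen on the written files shows the per-timepoint set sizes and the
filter cascade:

```
$ radscreen -v screen --counts demo/inputs/counts.tsv --samples demo/inputs/samples.tsv --out-dir demo2
INFO [normalize] median-of-ratios size factors
INFO [cutoff] per-timepoint presence cutoffs: {2: 19.377, 10: 19.359, 20: 19.72}
INFO [fold-change] 3519/4500 fold changes defined
INFO [screen] linear: {'2': 16, '10': 19, '20': 17, 'all': 9}
...
```

Each analysis directory contains the per-gene statistics
(`linear_screen.tsv`: slope, intercept, R², selected flag; `spike_screen.tsv`:
spike dose, max/second fold change, ratio), a Venn-style `overlap_summary.tsv`,
a `recovery.tsv` scored against the planted truth for simulated inputs, and a
`manifest.json` recording thresholds, seed and input checksums.

The same operations are available as a library
(`simulate_dataset`, `size_factors`, `condition_means`, `fold_change_table`,
`select_linear_genes`, `select_spike_genes`, `recovery_metrics`, ...) — see
the module docstrings.

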