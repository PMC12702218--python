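# harmolib

Harmonized DIA chromatogram-library workflow across biofluid matrices.

When the same peptides are profiled by data-independent acquisition (DIA) in
several biofluids — urine, plasma, serum — each fluid gets its own
chromatogram library, searched and error-controlled in isolation. Comparing
quantities *between* fluids then suffers from three problems: error rates
are controlled per fluid rather than globally, each fluid may use a
different fragmentation template and different quantitative transitions for
the same peptide, and retention times shift between matrix backgrounds.
`harmolib` implements the library-harmonization strategy that fixes all
three, producing per-fluid libraries that share one peptide set, one
fragmentation template per peptide, and one interference-screened
quantitative-ion set, while keeping fluid-specific retention times.

## What it computes

Given per-fluid scored transition libraries (targets + decoys), per-run
fragment chromatograms and a wide-window isolation scheme:

1. **Global FDR.** Each peptide keeps its best score over all fluids and
   charge states; q-values use the conservative target-decoy estimator
   FDR̂(t) = (1 + #decoys ≥ t) / (#targets ≥ t), monotonized, and the
   peptide set is filtered at q ≤ α (default 1%).
2. **Template selection.** The fragmentation pattern for each peptide is
   taken from the fluid where it scored best.
3. **RT calibration.** Peptides identified in two fluids anchor a monotone
   warp fitted by binned kernel-density modes + isotonic regression;
   peptides missing from a fluid get a match-between-runs RT through the
   warp from their best fluid.
4. **Quantitative-ion preselection.** Every precursor is re-evaluated under
   the wide-window scheme (default 16 m/z, staggered): a fragment is flagged
   when a co-isolated, co-eluting (≤ 30 s) precursor has a fragment within
   10 ppm. Unflagged ions are ranked by how well their peak shape tracks the
   precursor's summed elution profile in *every* fluid (leave-one-out
   Pearson correlation, aggregated by the minimum over fluids); the top 5
   become quantitative, requiring at least 3, otherwise the peptide is
   detection-only.
5. **Quantification and summaries.** Quant-flagged ions are integrated
   (trapezoid over expected RT ± 3σ), runs normalized to the average log2
   intensity, proteins rolled up from unique peptides, and fluids compared:
   per-protein "top" biofluids (within 50% of the most intense fluid),
   detection-overlap partitions, paired fold changes, absolute deltas, and
   pooled two-sided t tests between sample groups.

A synthetic-data module generates complete three-fluid experiments — known
true/false targets, monotone RT warps, Gaussian elution peaks, injected
co-isolating interferers, spiked protein fold changes — so every stage is
testable with known ground truth.

## Worked example

```sh
harmolib run --simulate --seed 1 --outdir demo/
```

runs the packaged demo configuration (three fluids, 150 true peptides, 80
false targets, 230 decoys, 4 runs per fluid) through all seven stages. The
manifest reports, per stage:

```
simulate     peptides=230  decoys=230  runs=12
fdr          peptides_in=459  accepted=148  alpha=0.01
align        n_warps=6
select_ions  peptides=148  quantifiable=148
harmonize    peptides=148
quantify     peptides=148  proteins=50
summarize    proteins=50
```

148 of the 150 true peptides survive the global 1% filter (none of the
false targets do), every accepted peptide ends with 3–5 interference-free
quantitative ions, and `harmonization_report.tsv` shows the harmonized
libraries sharing one peptide set while RT imputation does the most work in
the fluid with the lowest detection probability:

```
matrix_id  peptides_before  peptides_after  fraction_imputed_rt  templates_from_plasma/serum/urine
plasma     195              148             0.223                42 / 44 / 62
serum      201              148             0.189                42 / 44 / 62
urine      221              148             0.047                42 / 44 / 62
```

Outputs include the three harmonized library TSVs, q-values, warps,
ion-flag decisions, peptide/protein quant reports, and catalog-style
summaries (per-fluid means with top-fluid calls, a 7-region overlap table,
paired fold changes, deltas, and group t tests). Each stage is also
available as its own subcommand (`simulate`, `fdr`, `align`, `select-ions`,
`harmonize`, `quantify`, `summarize`); see `harmolib <cmd> --help`.

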