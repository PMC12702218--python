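# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the known limitations of `harmolib`.

## Global peptide error control

Libraries arrive with one score per precursor (higher = stronger evidence)
and explicit decoy entries. Evidence is collapsed to the peptide level
before error control ("picked" competition): each peptide keeps the maximal
score over every fluid and charge state, with exact ties broken to the
lexicographically smallest fluid label so the choice is deterministic. For
a score threshold t the estimated false-discovery rate is

    FDR̂(t) = (1 + #decoys ≥ t) / (#targets ≥ t)

and the q-value of score s is min over thresholds t ≤ s of FDR̂(t), capped
at 1. The +1 numerator makes the estimator conservative at small decoy
counts; with zero decoys the estimate degrades to 1/#targets and a warning
is logged. The global filter returns exactly the target peptides with
q ≤ α (default α = 0.01); decoys are never returned, and the operation is
idempotent and order-independent.

A consequence of the +1 numerator worth knowing when sizing experiments:
q-values cannot fall below 1/k where k is the number of accepted targets,
so a 1% filter needs on the order of a hundred confidently detected
peptides before it accepts anything. The synthetic defaults (150 true
peptides) were chosen with this floor in mind.

## Retention-time calibration

Peptides identified in two fluids anchor a warp between their RT spaces.
The fit is a binned conditional-mode construction:

1. Source RTs are binned on a uniform grid (64 cells over the observed
   range).
2. In each bin the density of the target RTs is estimated with a Gaussian
   kernel (bandwidth in seconds: Silverman's rule per bin, or fixed), and
   the anchor whose target RT maximizes the density becomes the bin's
   calibration point. Taking the mode *at an anchor* rather than on an
   arbitrary grid keeps perfect relations (e.g. self-alignment) exactly
   reproduced and makes the fit robust to a minority of outlier anchors.
3. Isotonic regression over the calibration points (weighted by bin
   occupancy) enforces monotonicity.
4. The warp is linear interpolation between the resulting knots, with
   linear extrapolation from the end segments; the residual scale is
   1.4826 × the median absolute deviation of the anchors about the fit.

Warps require ≥ 20 anchors. A peptide missing from a fluid receives the RT
warped from its best-scoring fluid (mirroring template selection); when no
direct warp exists the route composes through the intermediate fluid with
the most shared anchors. Observed RTs are never overwritten.

## Interference screening under wide windows

Chromatogram libraries are acquired with narrow windows, but quantification
happens in wide-window runs. The screen therefore re-evaluates every
library precursor under the wide-window scheme (default 16 m/z, staggered,
400–1000 m/z). Windows are half-open [start, start + width); a staggered
scheme adds a second cycle offset by half a width, so interior precursors
are co-isolated by exactly two windows. A fragment f of analyte a is
flagged when some other target precursor e satisfies all of:

* co-isolation — under the default `union` rule, any shared staggered
  window; under `demultiplexed`, the same half-width effective window
  (a weaker condition, so `union` flags a superset);
* co-elution — |RT(e) − RT(a)| ≤ 30 s;
* mass interference — some fragment of e within 10 ppm of f's m/z
  (ppm measured relative to f).

Decoy entries are not considered interferers: they are score-calibration
devices, not physical species. The production implementation sorts by RT
and indexes windows; its output is tested for exact set equality against a
naive all-pairs enumeration.

## Quantitative-ion selection

Within each fluid, each run's fragment traces are resampled to a shared
0.5 s grid (zero outside a trace's own range) and each fragment is
correlated (Pearson, raw intensities) against the leave-one-out reference —
the sum of the *other* fragments — so a dominant interfered ion cannot
validate itself; zero-variance traces score 0, runs are averaged within a
fluid. Candidates are the fragments flagged in **no** fluid, ranked by the
cross-fluid aggregate (minimum by default — the strictest reading of
"interference-free everywhere"; mean available), ties broken by library
intensity then ascending m/z. The top 5 become quantitative; with fewer
than 3 candidates the peptide is retained for detection only (all ions
flagged detection-only) rather than dropped.

## Harmonized libraries, quantification, summaries

Each fluid's harmonized library carries the same accepted peptide set, the
same template (the best-scoring fluid's entry: precursor, score, fragment
m/z and intensities) and the same quant/detection flags; only RT and its
origin flag (observed/imputed) differ. Output ordering is fixed so repeated
runs are byte-identical.

Peptide intensity per run is the summed trapezoidal area of quant-flagged
traces within expected RT ± 3 peak sigmas (σ = 6 s default); a quant ion
without a trace contributes zero (logged), a peptide with no quant ions is
missing, never zero. Normalization: x′(i,j) = log2 x(i,j) − m(j) + M with
m(j) the run's mean log2 intensity over complete-case rows and M the grand
mean — complete cases only, because rows quantified everywhere are the only
ones that constrain between-run scale without imputation. Proteins are the
sum of their *unique* peptides (a peptide mapping to several proteins
counts for none), on linear intensities.

Summaries: per-protein per-fluid means with "top" fluids = those within
50% of the most intense fluid (inclusive, on linear means; the scale is
configurable); the 7-region detection-overlap partition; per-protein paired
between-fluid Δlog2 (mean of per-subject differences); a deltas table of
per-subject absolute between-fluid differences; and a pooled two-sided
Student t test with fixed degenerate conventions (zero pooled variance:
p = 1 on equal means, p = 0 with a warning otherwise).

## Synthetic experiments

The generator emulates a three-fluid study on a 90-minute (5400 s)
gradient:

* **Peptides** are random tryptic-like sequences (7–25 residues, C-terminal
  K/R, fixed carbamidomethyl-C), with y/b ladders from a monoisotopic
  residue-mass table so ppm logic meets realistic mass coincidences; 2+
  precursors are kept inside the 400–1000 m/z acquisition range.
* **Scores**: true targets ~ N(4.5, 1), false targets and decoys share one
  null component N(0, 1) — the standard target-decoy assumption.
* **Warps** are affine + low-amplitude sinusoid (slope·t + offset +
  amp·sin(t/period)), strictly monotone, with per-fluid parameters and 3 s
  library-RT jitter; per-fluid detection probabilities (0.95 urine, 0.80
  plasma/serum) create the missingness that match-between-runs must fill.
* **Chromatograms** are Gaussian peaks (σ = 6 s, 1 s sampling, ±4σ span)
  with a shared per-precursor apex per run, amplitude = peptide amount ×
  fragment library intensity, and 5% multiplicative Gaussian noise.
  Traces are generated for true targets and interferers — the species
  downstream quantification can encounter.
* **Interferers** are false-target precursors re-positioned to co-isolate
  (Δm/z ≤ 4), co-elute (|ΔRT| 5–15 s) and overlap the analyte's most
  intense fragment within 8 ppm, at twice the analyte's abundance — so
  naive intensity-based ion selection is maximally exposed.
* **Design**: 3 peptides per protein, one run per subject per fluid, half
  the subjects "disease" with 5 proteins (≈10% of peptides) spiked
  two-fold.

Ground truth (true peptides, warps, interference pairs, protein map,
per-run amounts) is returned and serialized as `ground_truth.json`.

What the generator does **not** model: MS1/isotope envelopes, charge-state
envelopes, chimeric spectra beyond the injected pairs, peak tailing or
saturation, batch drift within a fluid, and missingness beyond the
detection probability. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under these idealized
conditions, not performance on real instrument data.

## Problem sizes and numerical choices

Simulation studies use desk-scale sizes chosen to keep each study's Monte
Carlo error well below its acceptance margin: FDR calibration uses 20
replicates of 3 × 20,000 targets + 20,000 decoys; warp recovery 2,000
anchors with 10 s noise and 10% uniform outliers; interference-screen
equivalence 50 random libraries of 50–500 precursors under both staggered
rules; quantification studies 5–10 full pipeline replicates. The packaged
demo runs 150 true peptides across 12 runs in a few seconds.

Tolerances and tie-breaks worth noting: float serialization uses shortest
round-trip repr so read∘write is exact; window membership is half-open (a
boundary precursor belongs to the higher window); score ties break to the
lexicographically smallest fluid; ion-ranking ties break by intensity then
m/z; all randomness flows from a single integer seed, and repeated runs are
byte-identical.

## Limitations

* Scores are consumed as given; no recalibration across fluids is
  attempted, so the global filter assumes cross-fluid score comparability.
* FDR is controlled at the peptide level only (no PSM- or protein-level
  control).
* Interfered ions are excluded, not corrected; no spectral deconvolution.
* Peak boundaries are fixed (expected RT ± 3σ); there is no boundary
  re-detection, smoothing, or tailing model.
* The catalog "deltas" are paired per-subject between-fluid differences;
  other pairings (between subjects within a fluid) are not produced.
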