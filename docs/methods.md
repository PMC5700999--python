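# Methods

## The scoring model

The unit of analysis is a protein-group intensity matrix from a label-free
differential co-IP experiment: rows are proteins identified in the
precipitates, columns are runs (default design: 4 control + 4 heat-stress
immunoprecipitations, half of each with chemical crosslinker; crosslinker
status is carried as a covariate but pooled within condition). A stored zero
or blank means *not detected*; it is never imputed, because dropout in
label-free MS is strongly intensity-dependent and therefore informative.

**Stage 1 — training labels.** Proteins with ≥ 2 detected intensities per
condition form the training set. For each, Welch's two-sample *t*-test with
Satterthwaite degrees of freedom is applied to log10 intensities (intensities
are multiplicative; the log scale makes replicate noise approximately
additive). p-values are adjusted by the Benjamini–Hochberg step-up across all
training proteins. A protein is labeled `true_interactor` iff q ≤ α (default
0.05) *and* its mean log stress intensity exceeds its mean log control
intensity; otherwise `false_interactor`. The two-sided-test-plus-sign
convention is equivalent to a one-sided rule at matched α and keeps the test
machinery symmetric. Degenerate inputs (zero variance in both groups) take
p = 1 on equal means and p = 0 otherwise — a documented convention, not a
statistical claim.

**Stage 2 — empirical error probability.** The training set is ordered by
its per-protein stress summary — the *median* of detected log10 stress
intensities, robust to one dropout among four runs — and split into
`n_bins = 10` equal-count bins (ties broken by protein id for determinism;
equal-count binning avoids empty bins at the sparse tails). Each bin yields
an anchor: x = median member summary, e = n_false / (n_false + n_true), the
only reading of "fraction of false to true" that is a probability. The error
fraction must be nonincreasing in abundance for the curve to act as a
probability function of intensity, so the anchor values are first replaced by
their best nonincreasing fit (antitonic pool-adjacent-violators, equal
weights — the exact least-squares solution), then interpolated by a cubic
Hermite spline with Fritsch–Carlson tangent limiting, which preserves the
monotonicity of its data. Evaluation clamps to the boundary anchors outside
the fitted domain. Anchors sharing an abscissa are merged by averaging; a
single anchor degenerates to a constant model.

Every protein detected in at least one stress run — including proteins
missing from *all* control runs, which stage 1 cannot test — receives
p-score = curve(median log10 stress intensity). p-score ≤ 0.05 calls an
interactor. Proteins never detected under stress keep a missing p-score and
are reported but never called, so output rows equal input rows.

The p-score is a heuristic estimate of the local false-interactor fraction
at a given abundance, not an exact FDR: it inherits the label noise of
stage 1. When the per-protein test power is high (strong enrichment, tight
replicates), the curve reaches ~0 at high intensity and calling behaves like
binning-smoothed FDR control. When power is partial (e.g. +2.5 log2
enrichment at σ_log10 = 0.25 and n = 4 + 4, noncentrality ≈ 4.3, BH-adjusted
label power ≈ 0.4–0.65), even bins composed purely of true interactors carry
error fractions near 1 − power, the curve plateaus above the threshold, and
the caller is extremely conservative (few or no calls, realized FDP ≈ 0).
This regime dependence is intrinsic to the construction and is demonstrated
by `analysis/02` (moderate vs strong scenarios) and `analysis/04`.

## Sequence-property characterization

Given the called interactors and a proteome, the second stage compares
composition statistics:

- **Mature proteome.** A targeting/cleavage table (score, 1-based position of
  the last transit-peptide residue) filters to proteins with targeting score
  above a threshold and truncates each to the mature sequence
  (`seq[position:]`); records whose cleavage would empty the sequence are
  skipped. Cleavage position 0 keeps the full sequence.
- **Raw property.** The mean of a 20-value amino-acid property index over the
  standard residues of the sequence; non-standard residues (X, B, Z, U) are
  ignored. Five indices ship as package constants (helicity, amphiphilicity,
  coil, β-sheet propensity, hydrophobicity) with stated sign conventions;
  they are configuration — any AAindex-style vector can be substituted.
- **Monte-Carlo normalization.** Because a composition mean drifts with
  sequence length and background composition, each raw value is standardized
  against μ and σ of the same statistic over n = 5000 random sequences drawn
  i.i.d. from the background proteome's residue frequencies, length-matched
  to the query's standard-residue count. One index draw per length is shared
  across the five scales (marginally identical to independent draws, 5× 
  cheaper). Degenerate nulls (σ numerically 0, e.g. a point-mass frequency
  vector) are flagged invalid and refuse normalization.
- **Isoelectric point.** Henderson–Hasselbalch net charge over N-terminus,
  C-terminus and D, E, C, Y (acidic) / H, K, R (basic) side chains with the
  IPC protein pKa set (N-term 9.094, C-term 2.869, C 7.555, D 3.872, E 4.412,
  Y 10.85, H 5.637, K 9.052, R 11.84); cysteine is ionizable in this set.
  The charge is strictly decreasing in pH, so the root is unique; bisection
  runs to an interval < 1e−6 pH. An interval criterion is used instead of
  |Q| < ε because weakly ionizable peptides have a wide near-zero charge
  plateau on which a charge criterion stops far from the root.
- **Distributions and tests.** Gaussian-kernel density on a 512-point grid
  spanning the data range ± 4 bandwidths (Silverman's rule by default;
  explicit bandwidth required for degenerate samples), and Welch's test
  between interactors and background per property. Strictly positive
  quantities (pI, length) are compared in log10 space; z-scores, which can be
  negative, on the raw scale, and the report records which was used.

## Synthetic data

`simulate_coip` draws per-protein base log10 abundances from
N(7.0, 1.0) — the central decades of a label-free IP's dynamic range — adds
`log2_enrichment · log10(2)` to planted proteins under stress (shift in log
space, no variance change), adds per-run replicate noise N(0, 0.25), and
deletes each cell independently with probability
1 − logistic(2.0 · (log10 intensity − 6.0)), so dropout concentrates at low
intensity and proteins can be missing from an entire condition. Defaults
mirror the target study design: 129 background + 39 planted proteins,
4 + 4 runs, the bait simulated as the most abundant planted protein.
Default enrichment is +2.5 log2 with σ_log10 = 0.25.

What the generator does *not* emulate: peptide-level structure (scoring is
protein-level), match-between-runs artifacts, heteroscedastic noise,
correlated contaminant clusters, and compositional coupling between
abundance and sequence properties. Passing tests therefore demonstrate the
procedure's statistical behavior under its own assumptions, not performance
on any real instrument's output.

`simulate_proteome` draws residues i.i.d. from a fixed frequency vector
(alanine-rich, GC-rich-genome-like background) with lengths uniform on
[150, 450]; a planted subset uses frequencies shifted by a zero-sum delta
vector (default: K/R → D/E and A/L → G/P), producing an acid-enriched,
helix-depleted group — the directional signature the property comparison is
designed to detect. `simulate_cleavage_table` assigns targeting scores so an
expected fraction passes the threshold and cleavage positions uniform on
[0, min(60, length − 1)].

## Problem sizes and numerical choices

Simulation studies use 20 seeded replicates of 190-protein experiments for
operating characteristics, 5000-draw nulls at length 200 for z-calibration,
50 random sequences against a 1e−3 pH grid for the pI cross-check, and a
340-protein proteome (40 shifted) for the directional comparison — sizes at
which every reported mean is stable to well within the stated bounds.
Oracle agreements (spline vs per-interval polynomial arithmetic, PAVA vs
exhaustive level-set search, BH vs its min-formula) are asserted at 1e−12 /
1e−9 on hundreds of random instances. All generators take explicit seeds;
derived seeds stay below 2^31. Pipelines write no timestamps, so repeated
runs are byte-identical.

## Known limitations

- The p-score is calibrated only as well as the stage-1 labels; at moderate
  effect sizes it is conservative by construction (see above).
- Bin count (10), bin representative (median) and the spline tangent rule
  are explicit configuration; other choices change the curve between
  anchors but not its monotonicity or anchor interpolation.
- Property indices are shipped stand-in tables with documented conventions,
  not authoritative literature values; conclusions from them in this package
  are directional, never absolute.
- The charge model ignores folded-state pKa shifts, phosphorylation and
  terminal modifications; pI values are sequence-level predictions.
- Whether interactor properties should be computed on precursor or mature
  sequences is genuinely ambiguous in differential co-IP practice; the
  pipeline defaults to mature when a cleavage table is supplied and records
  the choice in its report.
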