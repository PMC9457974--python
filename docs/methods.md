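# Methods

## Scoring model

Each of the six descriptors (MW, log p, HD, HA, PSA, RB) is mapped to a
desirability index through a Gaussian centered on the known-drug mean,
`I_d = exp(−(x_d − μ_d)² / (2σ_d²))`, normalized to 1 at the mean. The
shipped (μ, σ) pairs (see `src/kdikit/data/kdi_params.yaml`) are the
published fits to a curated collection of drugs in clinical use
(Eurtivong & Reynisson, *Mol. Inform.* 2019). The aggregates are the sum
(KDI_2a, max 6) and product (KDI_2b, max 1) of the six indexes; no
clipping or renormalization is applied, since the formulas are already
bounded. Users may override any (mean, sigma) pair via a YAML file or
`GaussianParamSet.replace`; sigmas must be strictly positive.

Assumptions worth keeping in mind: the indexes treat descriptors as
independent (no covariance between, say, MW and PSA enters the score),
and the Gaussians are symmetric, so a descriptor below the drug-like
mean is penalized identically to one equally far above it.

Collection summaries report the arithmetic mean and sample standard
deviation (n−1 denominator) of both aggregates; for n = 1 the sd is
reported as 0 with a warning rather than NaN.

## Descriptor provenance

Published descriptor tables in this field often come from commercial
engines with unpublished conventions (fractional acceptor counts, custom
log p models). The built-in engine uses open standards instead: average
molecular weight, Crippen atom-contribution log p, Lipinski-style
donor/acceptor counts, topological PSA, and the strict rotatable-bond
definition that excludes amide C–N bonds. Scores meant to reproduce a
published table should therefore be computed from the *printed*
descriptor values (`read_descriptor_csv` + the `prefer_table` policy),
not recomputed from structure; the `resolve_descriptors` policy records
which source each value came from. Molecules are canonicalized before
computation so equivalent SMILES writings and atom renumberings give
bit-identical descriptor vectors.

A reproduction subtlety: published KDI values are typically computed
from unrounded engine descriptors, while tables print rounded ones.
Rescoring the printed three-compound fixture shifts KDI_2a by up to
~0.01 (4.06 vs printed 4.05; 3.37 vs printed 3.38), so table comparisons
in the tests use ±0.02 absolute tolerance on KDI_2a; all KDI_2b values
match exactly at two decimals.

## Chemical-space regions

Regions are axis-aligned boxes with closed intervals, ordered innermost
to outermost; region sets declared nested are validated interval-by-
interval before use. The shipped defaults are the conventional bounds
from the virtual-screening literature — lead-like (MW ≤ 300, log p ≤ 3,
HD/HA/RB ≤ 3, PSA ≤ 60), drug-like (Lipinski plus Veber: MW ≤ 500,
log p ≤ 5, HD ≤ 5, HA ≤ 10, RB ≤ 10, PSA ≤ 140) and Known Drug Space
(MW ≤ 800, log p ≤ 6.5, HD ≤ 7, HA ≤ 15, RB ≤ 17, PSA ≤ 180). They are
package defaults traceable to that literature, not a re-derivation from
drug databases; every report records which region file was used, and a
`--regions` flag / `load_regions(path)` swaps in user bounds.

## Trend analysis

Per descriptor, complete cases (records carrying both the descriptor and
logBB) feed Pearson's r, Spearman's ρ and an ordinary least-squares
line. Pearson is the primary coefficient for direction calls —
"facilitates" above +t, "impedes" below −t, default t = 0.1 with no
p-value gate, since the underlying analyses report qualitative
directions; Spearman is reported as the outlier-robust check. Fewer than
3 complete cases for a descriptor yields "insufficient data", a
zero-variance descriptor "undefined correlation", and fewer than 3
complete cases overall is an input error. No imputation is performed.

## Synthetic collections

The generator emulates two statistical features of curated logBB
collections: descriptor marginals drawn from the known-drug Gaussians,
truncated at physical lower bounds (MW > 0; HD, HA, PSA, RB ≥ 0) by
rejection sampling, and a logBB built as Σ w_d·z_d + ε with ε ~ N(0,
noise_sd²). z_d standardizes each *latent* (truncated, unrounded)
descriptor by its sample mean/sd, so the implied descriptor–logBB
correlation is exactly w_d / √(Σw² + noise_sd²) regardless of
truncation; HD and RB are rounded to integer counts only afterwards,
which slightly attenuates their realized correlations. Default weights
are log p +0.5, HD −0.4, HA −0.4, PSA −0.5, MW and RB 0, with noise_sd
0.6: this yields univariate correlations of magnitude ≈0.35–0.45,
comparable to published descriptor–logBB trends, with size and
flexibility neutral. The default collection size is 208 compounds, the
scale of a typical curated logBB set. Descriptors are independent by
default; a 6×6 latent correlation matrix can be supplied for stress
tests (e.g. realistic MW–PSA coupling). All randomness flows through
numpy's PCG64 generator, so a seed reproduces collections bit-for-bit
across platforms.

What passing tests on synthetic data do **not** show: real logBB
collections have correlated descriptors, non-Gaussian marginals,
measurement error in logBB, and curation biases; sign-recovery results
here demonstrate that the analysis machinery is correct, not that any
particular real collection shows these effect sizes.

`generate_druglike_kdi_sample` reuses the same sampling to answer "what
KDI does a drug-like population show?"; with independent marginals the
mean KDI_2a is ≈4.4 ± 0.64 (each continuous descriptor contributes
E[exp(−z²/2)] = 1/√2 plus a small truncation lift). An optional
`score_params` argument decouples the sampled population from the
scoring desirability, e.g. to show that a population concentrated near
the known-drug means out-scores the dispersed one under the same
desirability.

## Numerical choices and problem sizes

- Scoring is plain double-precision `exp`; the spreadsheet-transcription
  cross-check in the tests agrees to 1e−12.
- CSV reports round KDI columns to 2 decimals (the precision such tables
  are printed at) but keep descriptors at full precision so reports
  round-trip losslessly; JSON reports keep full precision everywhere.
- Duplicate record ids are suffixed `_2`, `_3`… with a warning rather
  than aborting merged collections.
- Test problem sizes: trend-recovery runs use 50 seeds at n = 1000;
  the Monte-Carlo summary oracle compares a 50,000-draw sample against a
  10⁶-draw independent oracle. These sizes put sampling error well below
  the asserted tolerances while keeping the suite fast.

## Known limitations

- No 3D or conformer-dependent descriptors, no pKa/protonation modeling,
  and no attempt to reproduce proprietary engines' fractional
  donor/acceptor conventions.
- The KDI variants beyond the sum/product pair, and refitting the
  Gaussians to new drug collections, are out of scope.
- Region bounds are conventions, not fitted objects; conclusions phrased
  as "lead-like except log p" are conditional on the configured bounds.
- The synthetic generator produces descriptor-level records only, not
  chemically valid structures.
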