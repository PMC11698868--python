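# Methods

## Scope and model

`alphadiv` treats alpha diversity not as one number but as four
complementary aspects of a within-sample microbial community profile,
each with its own metric family:

| category | metrics | what it measures |
|---|---|---|
| richness | observed_features, chao1, ace, fisher_alpha, margalef, menhinick, robbins | how many taxa are (or are estimated to be) present |
| dominance | berger_parker, simpson, dominance, enspie, gini, mcintosh, strong | how concentrated the abundance distribution is |
| information | shannon, brillouin, heip, pielou | entropy blends of richness and evenness |
| phylogenetic | faith_pd | branch length spanned by the observed taxa |

All abundance metrics are functions of a single count vector
(non-negative integers; zeros are absences). The quantities that drive
most of them are S (observed taxa), N (total reads), F1 (singletons)
and F2 (doubletons) — unseen-species corrections (Chao1, ACE, Robbins)
are driven almost entirely by the rare tail, which is why denoisers
that delete singletons make those estimators collapse to S.

## Formula conventions

Printed formulas for several classical indices circulate in mutually
inconsistent notational variants (S for N, ambiguous Lorenz weights).
This package implements the literature-standard forms used by the
mainstream amplicon toolchains, and the tests pin them against both
naive transcriptions and scikit-bio:

* Berger-Parker: n_max / N.
* McIntosh: (N − U)/(N − √N), U = ‖counts‖₂. 0 when one taxon holds
  every read, 1 when every read is its own taxon.
* Brillouin: (ln N! − Σ ln n_i!)/N via log-gamma.
* Strong: max_i (b_i/N − i/S) over the descending cumulative curve.
* Gini: mean-absolute-difference form Σ_ij |x_i − x_j| / (2 S² m),
  range [0, 1 − 1/S], 0 = perfectly even. Note that Lorenz-curve
  integral variants (e.g. scikit-bio's `gini_index`) are *different
  estimators* and are deliberately not used as oracles.
* Chao1: S + F1²/(2 F2); when F2 = 0 the bias-corrected
  S + F1(F1−1)/(2(F2+1)) replaces the undefined classic form.
* ACE: Chao–Lee with rare threshold k = 10 (the conventional cutoff)
  and the coefficient-of-variation term floored at 0. When every rare
  taxon is a singleton the coverage estimate is 0 and ACE is reported
  as undefined rather than infinite.
* Fisher's alpha: the root of S = α ln(1 + N/α), solved by Brent's
  method on [1e−8, 1e8] with residual tolerance 1e−10. No finite root
  exists when S = N (all singletons); that is an error.
* Robbins: two variants are exposed. The default `reads` form
  F1/(N+1) is Robbins' estimator of the probability that the next read
  is an unseen taxon (what amplicon toolchains compute); the
  `features` form F1/(S+1) is available by flag.
* Shannon is reported in base 2 (configurable). Heip uses natural-log
  entropy internally so that e^H is coherent; Pielou (H/ln S) is
  base-invariant, which a test asserts.

Degenerate-sample conventions: all-zero vectors are errors at the
single-metric level but become missing-value rows (with a logged
warning) in table runs; Heip and Pielou are 0/0 at S = 1 and return
NaN; Margalef, Gini and Strong return 0 at S = 1; McIntosh needs
N ≥ 2. Missing values serialize as empty TSV fields, never the text
"nan".

## Faith PD

faith_pd sums branch lengths over the union of root-to-tip paths of
the observed taxa; abundances are ignored. Paths run to the tree root
by default (the toolchain convention); `include_root=False` instead
counts only branches below the MRCA of the observed set. A feature
observed in the sample but absent from the tree is a hard error:
silently dropping it would bias PD downward invisibly.

## Synthetic community generator

The generator produces the study conditions for every comparison in
this package:

* richness levels S = 50 … 500 in steps of 10 (46 levels);
* singleton targets F1 = 0, 3, 6, … capped at min(100, ⌊0.40 S⌋);
* doubletons F2 = round(0.40 F1);
* the remaining S − F1 − F2 taxa get counts 3 + round(draw) from one
  of five families — normal(50, 15) truncated at 0,
  negative binomial(mean 50, dispersion 0.5), uniform(0, 100),
  exponential(mean 50), Poisson(λ = 50). The abundance scale (~50
  reads/taxon) is a plausible non-rarefied 16S depth; the comparative
  findings are rank-based and insensitive to it.

The +3 offset is what makes rare-class control *exact*: a drawn
abundance can never collide with the bookkeeping counts 1 and 2, so
realized S, F1, F2 equal their targets in every sample (asserted for
all five families). The default grid yields 1,284 designs per dataset;
a `replicates` multiplier can scale it.

Unevenness manipulation: with ratio r (2, 10, 100), the most abundant
taxon's count is set to round(r × second-most-abundant count). Since r
and the counts are integers the realized top-two fold ratio is exactly
r; the operation touches no other count, so F1/F2 bookkeeping is
preserved, and it is idempotent. Direction: r is max/second, so larger
r means stronger dominance (Berger-Parker rises, Shannon falls —
asserted as a strict ordering across 2x/10x/100x).

Features are sample-private (`ASV_<sample>_<k>`): alpha diversity is
strictly within-sample, so cross-sample taxon identity would only
inflate the union table (block-diagonal, multi-GB dense at full grid).
`SyntheticDataset` therefore stores per-sample vectors, streams metric
computation, and offers a sparse `long` TSV layout; the dense wide
table is materialized only on request.

Random trees for Faith PD are coalescent-style: uniformly random
pairwise joins with i.i.d. exponential(1) branch lengths — enough to
exercise the metric, with no claim of realistic 16S phylogenetics.

What the generator does **not** emulate: sequencing error, chimeras,
compositionality/depth variation, shared taxa between samples, or
amplicon-region effects. Passing tests therefore demonstrate metric
behaviour under controlled composition, not robustness to real
sequencing artefacts.

## Comparison pipeline

* Min-max normalization maps each metric column to [0, 1]; constant
  columns go to 0 with a warning; idempotent.
* Correlations (Pearson + Spearman) are pairwise-complete, never
  listwise: evenness metrics are missing for S = 1 samples and
  listwise deletion would bias every other pair. Per-pair n is kept.
* Dominance regressions are OLS on Berger-Parker; the `exponential`
  transform regresses log(response) (appropriate for ENSPIE).
  Slope/intercept/R² are checked against the normal-equations closed
  form at 1e−10.
* LOESS is a tricube-weighted local polynomial (span 0.75, degree 2 by
  default — the conventions of the usual statistical environments),
  with R² = 1 − SS_res/SS_tot over fitted values and no robustness
  iterations. Hand-written because the available lowess implementations
  are locally linear only.
* Kruskal-Wallis uses the tie-corrected H with a chi-square p-value
  (no exact small-sample enumeration); all-constant input is rejected
  explicitly. Calibration is checked empirically: over 500 null
  replicates of two identically-generated groups (15 Shannon values
  each) the 5% test rejects at 4–5%. Shannon is used because the
  generator controls S exactly, making observed richness degenerate
  under a rank test. No multiple-testing correction is applied by
  default.
* The recommended reporting panel is one metric per category:
  observed_features (+ robbins as the unseen-taxa likelihood),
  berger_parker, shannon, faith_pd when a tree exists (a note is
  emitted otherwise), with per-group median/quartiles under a metadata
  grouping.

## Problem sizes and numerical choices

Analyses in the test suite and acceptance script run the full default
grid (1,284 samples per dataset, five datasets) in seconds; the
end-to-end determinism check uses a reduced richness grid via CLI
flags, which suffices for a byte-identity property. Gini is computed
via the sorted O(S log S) identity (the O(S²) double loop survives
only as a test oracle). Strong and Berger-Parker divide integers only
at the last step to avoid floating-point tie artefacts.

## Known limitations

* The mutual rank-correlation of richness estimators on the synthetic
  grid is weaker than on real cohorts: the grid deliberately crosses S
  with F1 (they are nearly orthogonal by design), and Menhinick's
  S/√N then mixes ranks within richness levels, giving
  observed-vs-menhinick Spearman ≈ 0.83–0.87 instead of the ≥ 0.90 seen
  when S and F1 co-vary naturally. This is scale-free (independent of
  the abundance mean) and intrinsic to the crossed design; the
  corresponding acceptance assertion is left failing rather than
  weakened, and all non-Menhinick pairs exceed 0.93.
* ACE's rare threshold (k = 10) and the distribution parameters are
  conventions, exposed in the API but not fitted to data.
* The chi-square approximation in Kruskal-Wallis is anti-conservative
  for very small groups; calibration was checked at n = 15 per group.
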