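# Methods

This note documents the statistical model behind `hcsprofile`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## Data model

The pipeline consumes a long-format per-cell table: metadata columns
`plate` (plate *position* within a replicate set — compounds are split across
positions), `replicate`, `row`, `col`, `treatment` (`DMSO` = vehicle
control), `concentration` (µM), followed by numeric feature columns. A
physical plate is the pair (plate, replicate). Well coordinates are 1-based;
the outer ring of a 384-well plate (row 1/16, column 1/24) is excluded from
analysis by design, leaving a 14×22 = 308-well region. The default layout
places 55 control wells on wrap-around diagonals so that every analyzable row
and column contains at least one control — the property that makes row and
column effects identifiable from controls alone. The exact published diagonal
coordinates are not available in machine-readable form; any layout satisfying
the coverage contract can be supplied as YAML.

A feature catalog annotates each feature with its marker (stained component),
compartment (`Circ` = nucleus, `Ring` = simulated cytoplasm) and class
(intensity / shape / texture / spot), plus a biological-relevance flag.
Relevance encodes assay knowledge the algorithms cannot infer — nuclear
markers measured in the cytoplasm are background, as are optics-driven
exclusions such as bleed-through channels — and is therefore catalog *data*,
not code.

## Positional-effect detection

Per physical plate and feature, control-well medians are modeled additively
on the two categorical factors row and column (two-way ANOVA, no
interaction). Because the diagonal control design is unbalanced, Type-II sums
of squares are used; row/column are unordered factors, not trends. A feature
is flagged on a plate when either factor's −log *P* exceeds 10 (natural log;
e⁻¹⁰ ≈ 4.5×10⁻⁵, consistent with a *P* < 0.0001 working level; base and
threshold configurable). Degenerate designs (fewer than two distinct control
rows/columns, or no residual degree of freedom) are skipped and logged rather
than guessed at. *F* statistics are scale-free, so flags are invariant to
affine rescaling of a feature. A factor whose explained variance is
numerically zero reports F = 0, P = 1; a saturated noiseless fit reports P at
a 1e-300 floor to keep −log *P* finite.

## Correction and standardization

For each flagged (plate, feature) pair, Tukey's median polish decomposes the
well-median matrix into overall + row + column + residual (row sweep first,
relative tolerance 1e-6 on Σ|residual|, max 100 iterations — the classical
defaults; the decomposition reconstructs its input exactly and is idempotent
on its own residuals). Every well on the plate — control and treatment — is
then shifted by −(row_i + col_j), and the adjustment is stored per well.

**Fit set.** The polish is fitted on the *control-well* matrix by default and
its row/column effects applied to all wells (`fit_on="controls"`). Fitting on
all inner wells (`fit_on="all"`) is available but not the default: dilution
series run along rows, so strong treatment effects are spatially structured
and bias an all-wells fit; in closed-loop simulation that bias re-introduced
detectable row structure into the corrected controls (post-adjustment
−log *P* up to ≈10 on occasional plates), whereas the control-only fit leaves
all previously flagged pairs far below threshold (≈3). The diagonal design
guarantees the control matrix covers every row and column.

Two standardizations follow. The **B score** divides polish residuals by the
per-plate MAD of residuals — a well-level, plate-comparable QC track; it does
not feed downstream profiling. The **BZ score** operates per cell: the stored
well adjustment is added to each cell value (strictly additive propagation —
the same amount for every cell of a well), then the value is centered on the
median and scaled by the MAD of the plate's pooled position-adjusted control
cells. MADs are unscaled (no 1.4826 factor) throughout; the constant cancels
in every relative comparison. By construction each plate's pooled controls
have median exactly 0 and MAD exactly 1, which harmonizes feature
distributions across plates (in the default simulation with injected plate
offset/scale effects, cross-plate control EMD is ~0.05–0.13 in BZ units).
Features with a zero control MAD on any plate are excluded with a prominent
warning rather than epsilon-padded, which would manufacture arbitrarily large
scores.

## Dissimilarity metrics

* **EMD / Wasserstein-1**: ∫|F₁ − F₂|dx over the merged empirical support,
  computed by accumulating |ΔECDF| × gap after one merge sort,
  O((n+m) log(n+m)). Right-continuous ECDF tie convention. For equal n it
  equals the mean absolute difference of the sorted samples, and
  emd(X, X+c) = |c| for any sample — both used as independent oracles in the
  tests, alongside a brute-force minimal-transport LP on small instances.
  No directional sign is attached (a signed variant is out of scope).
* **KS statistic**: sup-norm of the ECDF difference on the same merged
  support; verified against breakpoint enumeration.
* **Robust Z**: (median(sample) − median(reference)) / MAD(reference),
  signed; the absolute value is used when ranking dissimilarity. The exact
  formula behind published replicate "Z-scores" is often left implicit; this
  median/MAD form is a documented interpretation, flagged here for users.

Under a variance-inflation alternative (σ 1→1.5, n = 500/sample, 1000 pairs)
the standardized separation of EMD scores exceeds KS by ~2.5× while |Z| is
blind (≈0) — the motivating failure mode for median-based scores.

## Replicate reproducibility

Pairs are enumerated by design: in the two-position layout, control wells
occupy the same coordinates on both positions, so each control well id yields
all R×R cross-position replicate pairs (9 for R = 3), while each treatment
well id yields C(R,2) within-position pairs (3 for R = 3). A generic
within-position mode covers other designs; `auto` picks between them. Every
pair is scored per feature with EMD, KS and |Z| on the BZ cell populations.
Features are ranked by mean pairwise EMD over all pairs (controls and
treatments pooled; configurable to controls-only) and flagged irreproducible
strictly above the Tukey fence Q3 + 1.5·IQR (quartiles by linear
interpolation; a value exactly at the fence is not an outlier).

## Profiling, counts and toxicity

All BZ control cells pool into the **global control** per feature (sorted
once; profiling uses a pre-sorted-reference EMD fast path). Controls are
profiled per individual well — their spread is the technical-variation band
that anchors the residual fingerprints — while treatments are profiled as
replicate-merged conditions. Merging is unconditional by default; an optional
gate drops a replicate whose median pairwise EMD to its siblings exceeds the
feature-wise irreproducibility fence.

One consequence worth knowing: merged conditions (~10³ cells) have a lower
EMD sampling floor than individual control wells (~10² cells), so even
phenotypically null treatments sit slightly apart from control wells in
profile space. This is a property of any sample-size-asymmetric EMD profile,
not an artifact of this implementation; the trajectory analysis therefore
measures travel along each compound's own dose gradient rather than distance
to the control centroid.

Percent-of-control uses the mean control well count on the plate position(s)
carrying the condition (min/max/median also reported). A condition is flagged
cytotoxic when its merged count falls strictly below 30% of that control mean
(>70% cell reduction); toxic conditions are excluded from feature-reduction
statistics but stay in the profile. DNA-content (total nucleus intensity)
distributions are exported as binned densities per condition and dose for
overlay plots; no cell-cycle phase calling is attempted — the distributions
themselves are the readout.

## Feature reduction

Four filters in fixed order, each deterministic given its inputs (ties by
feature name):

1. **irreproducible** — the fence flags above;
2. **irrelevant** — catalog relevance rules;
3. **correlated** — on the EMD profile restricted to non-toxic treatment
   rows, pairs with |Pearson r| ≥ 0.9 are visited in descending |r| and the
   weaker member removed unless its partner already was. "Weaker" = lower
   variance across those rows, reading variance as activity in profile
   space (an alternative — lower mean EMD — is selectable). Constant columns
   have undefined correlations and are left to the variance filter, with a
   warning;
4. **inactive** — treatment-row variance < 2× control-row variance
   (boundary kept: "at least double" is inclusive).

The cascade emits a ledger whose set algebra always balances and is
idempotent on its own output. Correlation and variance are computed between
*profile columns*, not raw per-cell values, because the filters sit after
profiling in the workflow. If a screen has no responsive features at all
(e.g. a clean negative-control run empties the cascade), the visualization
stages fall back to the full feature set with a warning; the ledger still
records the true outcome.

## Fingerprints, clustering, trajectories

Profiles are log1p-transformed (entries can be exactly 0, so bare log is not
an option) and min–max scaled per feature over the combined
control + treatment rows. Residual fingerprints subtract the per-feature
median of the control rows (control residual medians are exactly 0). The
+0.5 radial-plot offset is rendering only. Clustering is Euclidean/average
linkage (UPGMA), cut at a user-set k (default 4 — the screen's expected
granularity: control, low-stress, active, broadly active/toxic — not an
algorithmic output); a Newick export of the dendrogram is provided. The UMAP
embedding wraps the reference implementation (n_neighbors = 15,
min_dist = 0.1, n_components = 3, seeded and hence deterministic;
hyperparameters are library defaults with config override). Trajectories are
the embedded coordinates per compound ordered by ascending concentration with
percent-of-control annotations.

## Synthetic screens

The generator draws per-cell feature values from Gaussian, log-normal or
two-component-mixture control distributions (the mixture models 2n/4n DNA
content; medians/MADs of the non-Gaussian laws are obtained by root-finding
on the exact CDF). Treatment effects act on the latent value — location
shift, spread change about the median, a signed power stretch of positive
residuals (tail effects are described qualitatively in the literature; the
power form is this package's concrete choice), and a G1-weight shift for the
DNA feature — attenuated by a Hill dose response c^h/(c^h + EC50^h).
Technical artifacts are overlaid afterwards: per-plate additive offsets and
multiplicative scales per feature, then additive linear-in-index row/column
vectors whose class-level amplitudes put markedly larger artifacts on
intensity features (amplitude ×1.2/0.6 MAD rows/columns) than on morphology
(×0.1/0.05), with a per-plate random magnitude. Because the positional terms
are strictly additive they are exactly removable by an additive
decomposition, which the closed-loop tests exploit. Cell counts are truncated
negative-binomial (dispersion 50); the paper-calibrated control sampler spans
419–990 cells/well (mean 650), and cytotoxicity multiplies mean and bounds by
the surviving fraction 1 − toxicity·Hill(c).

The desk-scale default (14 features, 8 compounds — two low-stress, three
dose-responsive with graded pure location shifts, one dose-insensitive with
a Z-blind spread change, two cytotoxic — 2 plate positions × 3 replicates,
100–300 cells/well) runs the full pipeline in about a minute. A full-size
structural analog (174 generated features, 65 compounds split 33/32 across
positions, paper-calibrated counts) sits behind `full_config()`; its feature
list is structural, not the real assay's. Dilution-series slots beyond the
configured compounds are filled by cycling through them so every inner well
carries cells. One default feature carries planted well-level jitter so the
reproducibility fence has a true positive.

**What passing tests show, and what they do not.** The generator reproduces
the *statistical structure* the pipeline assumes: additive positional
artifacts, plate-level affine effects, Hill-monotone perturbations of known
parametric shapes, over-dispersed counts. Real screens add things it does not
model: non-additive and edge-localized spatial effects, within-well spatial
correlation, batch drift beyond plate effects, feature noise laws that are
none of the three menus, and segmentation errors. Closed-loop recovery here
therefore validates the implementation and its identifiability logic, not the
adequacy of the additive model for any particular instrument.

**Recovery conventions used in testing.** Expected profile entries are exact
only for pure location shifts (EMD translation property), so the
effect-recovery rank correlation is computed over pure-shift
(condition, feature) pairs with expected BZ shift ≥ 0.2 — effects below the
EMD sampling floor at the default cell counts are not meaningfully "planted".
The control/active clustering check labels a condition active when its
largest expected BZ shift is ≥ 1, and compares the default k = 4 partition
against the binary control/active labels with the adjusted Rand index:
the planted groups are phenotypically diverse (they respond on different
feature sets), so expecting a single treatment cluster would contradict the
design; controls concentrating in one cluster is the property under test.

## Numerical conventions and limitations

* Unscaled MAD everywhere; medians/quartiles by linear interpolation.
* Median polish: row-first sweeps; agreement with an independent reference
  implementation frozen into the tests at 1e-9.
* P values floored at 1e-300; F reported as 0 (P = 1) for numerically
  zero factor variance.
* Seeds: one generator per simulation run; UMAP seeded separately.
* Not modeled: LOESS/spatial smoothing, multiplicative positional models,
  batch (beyond plate) harmonization, multivariate Wasserstein, significance
  tests on profile entries, mechanism-of-action classification.
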