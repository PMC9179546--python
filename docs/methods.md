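# Methods

## Model and processing chain

The package treats a tumour cohort as three gene-by-sample score
matrices over one shared gene and sample index: log-scale expression
(Gex), promoter methylation (Dme) and gene-centric copy number (CNV).
The chain is strictly ordered:

1. **Centralization.**  Each gene row has its cohort mean subtracted,
   per modality.  Scores become deviations from the cohort-average
   state, which makes group contrasts signed: an aberration carried by
   a minority group appears deeper (further from the mean) than the
   same aberration in a larger group.  Downstream consequences of this
   are noted under *Spot detection*.
2. **Harmonization.**  Each modality is divided by the global standard
   deviation of all its entries, so that the three layers contribute on
   a common numerical scale (global SD 1).  An all-constant modality is
   left untouched with a warning.  Harmonization is equivariant under
   positive rescaling of the raw input.
3. **Combination.**  Per gene, the three S-length profiles are
   concatenated in fixed (Gex, Dme, CNV) block order, block *b* scaled
   by its weight *w<sub>b</sub>* with Σ*w<sub>b</sub>* = 1.  Scaling is
   linear, so squared Euclidean distances decompose as
   Σ *w<sub>b</sub>*² *d<sub>b</sub>*² and decomposition (dividing block
   *b* by *w<sub>b</sub>*) is an exact inverse; the scheme is recorded
   in the persisted model so an alternative (e.g. √w) could be added
   without breaking old files.  A zero weight makes that modality's
   decomposed component undefined (NaN), by contract.
4. **SOM training.**  Batch Kohonen training on the combined vectors:
   units are initialized on a lattice spanning the first two principal
   components (±2 component SDs; SVD signs fixed by the
   largest-loading-positive convention so the run is reproducible), then
   updated per epoch as Gaussian-neighbourhood-weighted means of the
   vectors mapped to them.  Two phases: radius grid/2 → 3 over 20
   epochs (ordering), 3 → 1 over 30 epochs (fine tuning).  The optional
   learning-rate schedule damps the batch update (`new = old + lr·(mean
   − old)`); its default of 1.0 is the plain batch rule.  A `sample`
   init scheme (seeded draw of data vectors) is available; it is used
   where bit-exact equality between runs on padded and unpadded inputs
   matters, since LAPACK SVDs of differently shaped matrices need not
   agree to the last bit.  Final gene assignment is the exact
   nearest-unit argmin with ties to the lowest unit index; grid
   coordinates are (row, col) = (u // side, u % side), row 0 on top.

All cross-sample variances and covariances downstream use denominator
S − 1; the GSZ background SD uses the population convention (ddof 0),
matching its definition as a per-sample z score of the set mean.

## Spot detection

Per portrait and sign, cells reaching 90% (configurable) of the
portrait's own extremum are split into 8-connected components;
components under `min_size` = 3 cells are treated as speckle.  The
cohort summary map collects over- and under-components from every group
portrait in every modality and merges the ones describing the same map
region.  "Same region" is operationalized as *sharing at least
`min_size` cells*: single-cell contacts between adjacent territories do
occur (e.g. methylation-gradient highlights straddling a module
boundary) and would otherwise chain unrelated regions through
union-find.  Residual overlaps below that size are resolved by giving
each contested cell to the largest claiming spot (ties to the spot with
the lowest minimum unit index), so the labelled regions are disjoint;
spots reduced below `min_size` are dropped.  Labels run A, B, …
clockwise around the grid centre starting from the top-left diagonal
(angular sort of spot centroids).  A per-modality *global* reference
extremum was considered instead of per-portrait thresholds and
rejected: with centralized scores it systematically discards modules
carried by larger groups (their deviations are shallower, see step 1).

Spot dominance (Gex/Dme/CNV tag) is the modality whose group-portrait
spot means vary most across groups (variance over group means, S − 1).

## Prognostic maps

Per unit and modality, samples with metagene score above the unit's
mean + 1 SD form the high group; `HR = exp(β)` from a univariate Cox
proportional-hazards fit (lifelines) of high vs rest.  Cells are
undefined (NaN) when the high group is smaller than `min_group` = 5,
when either arm has no events, or when the fit fails to converge.
Identical dichotomizations across units share one fit (memoized), which
keeps a 400-unit map to a few seconds.  The construction is invariant
under positive rescaling of the scores.  The baseline is the
complementary ("rest") group, the simpler of the two readings of a
metagene-wise HR; an all-cohort baseline would need an external
reference survival model.

## Synthetic cohorts

The generator draws cohorts with the structure the method assumes,
plus ground truth.  Defaults (the study conditions of the test suite
and acceptance script):

| parameter | default | meaning |
| --- | --- | --- |
| n_genes / n_samples | 2000 / 120 | genome-scale-down cohort |
| groups | wt-like 40, A-like 50, O-like 30 | glioma-like genetic strata |
| γ (`cnv_dose_response`) | 1.0 | ~1 log2 unit expression per copy-number unit |
| β (`dme_repression`) | −0.8 | expression response per methylation-shift unit |
| gradient amplitude | 0.8 | hypermethylator gradient, × per-gene susceptibility ~ U(0,1), group levels 0 / 0.6 / 1.0 |
| noise SD | 0.4 / 0.3 / 0.3 | Gex / Dme / CNV Gaussian noise |
| low-purity fraction, α | 0.1, 0.3 | "neuronal-like" samples retain 30% of group effects |
| survival | exponential, base rate 1/60 mo, censor 120 mo | wt-like hazard ×3, others ×1 |

Five planted modules: two 180-gene arm-level trinary CNV segments in
the wt-like group (gain and loss), one 180-gene co-deletion (two
ranges) in the O-like group, one 80-gene repressive hypermethylation
module (shift 1.5, wt-like), one 80-gene TF-driven pure-expression
module (shift 1.2, A-like).  Sizes are deliberately asymmetric —
chromosome arms contain more genes than focal functional signatures —
and the couplings are balanced so that expression variance receives
comparable contributions from the CNV and methylation layers, which is
the structural premise of the combined portrayal (methylation and CNV
vary along independent axes, expression along both).

The methylation gradient uses per-gene susceptibility loadings rather
than a uniform offset: hypermethylator phenotypes affect genes
differentially, and a strictly uniform offset would turn a whole group
portrait into one flat plateau — a degenerate input for
fraction-of-maximum spot detection.  Per-gene *module* effect sizes are
homogeneous by default (`module_loading_spread` = 0): a coherent
within-module amplitude gradient conflicts in principle with the sharp
90%-of-maximum rule, under which any gene below 90% of the module peak
leaves the spot.  Heterogeneous modules (spread > 0) are available in
the config and are used by the correlation-plot tests, where per-gene
methylation/expression anti-coupling is the point.

What the generator does *not* emulate: realistic 450K beta-value
marginals, microarray intensity distributions, segment-boundary noise in
CNV calls, and intra-group substructure beyond the purity split.
Passing tests therefore demonstrate that the machinery recovers planted
structure under Gaussian noise at realistic effect sizes — not that it
would resolve the finer subtype structure of a real cohort.

## Problem sizes and numerical choices

The test suite and acceptance script run the full cohort (2000 × 120)
on a 20 × 20 grid — the package's test-scale choice; the full-scale
default remains 45 × 45 and is reported as such.  Hazard-ratio CI
coverage is estimated over 20 independently generated cohorts.
Deterministic fixtures use ≤ 100 genes and exact or 1e-9-relative
comparisons against loop-level oracles.  Tie-breaks are lowest-index
everywhere (BMU assignment, network neighbour selection via
(−correlation, order) sort keys, ranked profiles via (score, sample-id)
keys).  Text matrices round-trip at 10 significant digits; model files
round-trip bit-exactly through HDF5.

## Known limitations

- The batch-SOM schedule is a standard recipe, not a re-derivation of
  any particular legacy implementation's defaults; map topologies are
  therefore comparable in character, not cell-for-cell.
- Per-sample ScoV (signed-root product of two centralized metagene
  scores) is the single-sample analogue of a covariance, not an
  estimator with error control.
- GSZ uses the plain normalized set-mean z form, without
  variance-shrinkage elaborations.
- The prognostic map fits one univariate model per metagene with no
  multiplicity adjustment; it is a visualization of local hazard
  structure, not a marker-discovery test.
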