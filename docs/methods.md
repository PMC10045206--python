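# Methods

`pcatomics` implements a pericoronary adipose tissue (PCAT) radiomics
pipeline for straightened-vessel coronary CT angiography (CCTA) stacks:
segmentation of the peri-vessel fat, extraction of a fixed 1356-value
radiomic vector per vessel and frame range, a cascade feature-selection
procedure, and repeated cross-validated logistic modelling of binary
vulnerable-plaque labels (thin-cap fibroatheroma, TCFA; microchannels,
MC; their conjunction).  Because real registered CCTA/IVOCT cohorts are
not publicly available, a synthetic phantom module generates labelled
cohorts with controllable effect sizes; all statistical claims made by
the test-suite are claims about those phantoms.

## PCAT segmentation

The vessel wall is given as per-slice filled lumen and outer-wall masks.
For each slice:

1. **Vessel diameter.** `d = 2 * sqrt(area / pi)` of the outer-wall
   region (equivalent-disc diameter, in mm).  This is rotation invariant
   and well defined for irregular walls; the diameter definition is a
   modelling choice, as only "the vessel diameter" is fixed by the
   underlying protocol.
2. **Candidate annulus.** All voxels strictly outside the wall whose
   Euclidean distance to the wall region is at most `d`.  Distances are
   computed with a sampled distance transform, so anisotropic in-plane
   spacing is handled in millimetres.  Distance is measured from the
   filled region, not the contour curve — identical for convex walls,
   and well defined otherwise.
3. **Adipose window.** Candidates are intersected with the fat
   attenuation window `[-190, -30]` HU, inclusive at both endpoints
   (the inclusive reading of "between", matching fat-attenuation-index
   practice).

Processing is strictly per-slice (2-D): the input is a straightened
multiplanar-reformatted stack, and whether the radial distance should be
2-D per slice or 3-D along the centreline is not decidable from the
protocol text; 2-D was chosen and is the simpler, more reproducible
reading.  Frame ranges: the lesion of interest (`LOI`) is a sub-interval
of the whole-vessel interval (`Vessel`); an optional
`exclude_proximal_mm` drops leading slices (the right-coronary ostium
convention).  Slices with an empty wall are skipped and logged.

## Radiomic features

Per retained slice (those with at least `min_fat_voxels = 10` fat
voxels) and per discretization setting, 113 base features are computed:

| family      | count | notes |
|-------------|------:|-------|
| shape       | 21    | binary mask only |
| first-order | 17    | raw HU, except entropy/uniformity on levels |
| GLCM        | 24    | distance 1, four angles, symmetric, angle-summed |
| GLDM        | 14    | alpha = 0, 8-neighbourhood, dependence + 1 indexing |
| GLRLM       | 16    | per-angle features averaged over four angles |
| GLSZM       | 16    | 8-connected constant-level zones |
| NGTDM       | 5     | 8-neighbour mean differences |

Gray levels are discretized into 8, 16 or 32 equal bins over the fixed
window `(-190, -30)` rather than the per-mask range, so levels are
comparable across vessels ("equal HU ranges"); level arithmetic is
`min(floor((x - lo)/width) + 1, n_bins)`.  The 339 per-slice columns
(113 x 3 bins) are aggregated across slices by min, max, mean and
sample (n-1) SD, yielding 113 x 3 x 4 = 1356 named values
(`{stat}_{family}_{feature}_{bins}b`), partitioned 252 shape / 204
intensity / 900 texture.  Shape and most first-order features do not
depend on the bin setting and are replicated identically across the
three settings: the partition identity requires the replication, and
the aggregation axis (slices) is the only axis that yields a
distribution per vessel.  Logarithms are base 2 with `0 log 0 = 0`.

Degenerate-mask conventions (needed because tiny PCAT slices occur):
single-gray-level masks return correlation = MCC = 1 and zero
entropies; NGTDM coarseness is capped at 1e6 when its denominator
vanishes; first-order skewness/kurtosis are 0 at zero variance.  Shape
perimeters use the 4-direction Crofton estimator (an approximately
unbiased estimate of true boundary length); circularity
`4 pi A / P^2` is clamped to 1 because discretization can push the
estimate marginally above the ideal disc value.  Shape features require
isotropic in-plane spacing.

## Feature selection cascade

1. **Correlation pruning** (`|r| > 0.95`): greedy scan in the canonical
   (stat, family, feature, bins) column order, keeping the earlier
   member of each correlated pair — which member is dropped is
   otherwise arbitrary, and a fixed rule makes the stage deterministic.
   Constant columns (undefined r) are kept with a warning.
2. **Univariate screening.** Each surviving feature is scored by the
   mean, over repeats, of the pooled out-of-fold AUC of a
   single-feature logistic model (intercept + slope, slope ridge 1e-2,
   fitted by a vectorised Newton/IRLS on training folds with
   training-fold standardization).  All features share the same fold
   splits.
3. **Family pooling.** The 15 best features per family (7 families)
   give at most 105 candidates; ties break by name.
4. **mRMR** (mutual-information difference variant): features are
   3-level discretized at mean +/- SD; the first pick maximizes
   I(f; y), each next pick maximizes I(f; y) minus the mean MI against
   the already-selected set.  Applied 105 -> 50, then 50 -> 10.
5. **Recursive elimination.** A multivariate logistic model (ridge
   C = 100) is fitted on the standardized table; the
   smallest-|coefficient| feature is dropped; the mean CV AUC is
   recorded at every subset size and the best subset wins, ties going
   to the smaller subset.

Determinism: every stage is a deterministic function of the table and
the CV seed.

### Selection bias and the nested mode

The univariate screen (and the elimination stage's model choice) sees
the full table, as is usual when the goal is a per-feature association
map.  The price is optimism: on label-permuted phantom tables at n = 30
the plain cascade's final-model CV AUC measures ~0.8, because a screen
over ~300 features always finds chance associations that the same 30
samples then "validate".  `nested_model_auc` re-runs a fast variant of
the cascade (rank-AUC screening per family + mRMR) inside every
training fold; under permuted labels it measures ~0.50.  Null
calibration is therefore a property of the nested protocol; the plain
cascade's headline AUCs on small cohorts should be read as
association-map summaries, not as unbiased prediction estimates.

## Evaluation

Stratified 3-fold CV repeated (reference protocol: 1000 repeats;
acceptance-scale runs use 100).  Per repeat, out-of-fold decision
scores are pooled and give one AUC; shuffles whose training folds would
be single-class are redrawn, keeping the repeat count exact.  The
summary is mean +/- sample SD over repeats; the mean ROC is the
vertical (fixed-FPR-grid, 101 points) average of per-repeat curves.
The pooled-score AUC is exactly the Mann-Whitney statistic
`U / (n+ n-)` (mid-rank tie handling), an identity the tests assert to
1e-12.

## Phantom

Each vessel is a stack of axial slices (default 24 slices of 48 x 48
voxels at 0.5 mm isotropic): contrast-bright lumen (~400 HU, radius
1.5 mm), soft-tissue wall (~50 HU, 0.75 mm thick), and a surrounding
adipose field of spatially correlated Gaussian noise (mean -80 HU,
SD 15 HU), plus ~5% scattered bright specks (> -30 HU) so the HU-window
rule has work to do.  The vessel radius is modulated +/-10% smoothly
along the stack, making the per-slice diameter informative.  The LOI is
the central 20% of frames.  Labels: TCFA and MC are independent
Bernoulli(0.47) draws (the conjunction is correspondingly rarer),
matching a ~14/30-positive cohort.

Positive vessels (on the configured effect channel, default TCFA)
receive a +15 HU adipose mean shift — a stylised inflammation
signature — and a doubled texture correlation length (0.6 -> 1.2 mm),
giving intensity and texture families separable signal channels.  Wall
masks are exact by construction, so segmentation is noiseless and
deterministic given the seed.

What the phantom does **not** emulate: calcification blooming, beam
hardening, cardiac motion, wall-segmentation error, anisotropic
reconstruction, intensity inhomogeneity along the vessel, or any
IVOCT-side physics.  Passing tests therefore demonstrate the internal
correctness and calibration of the pipeline, not clinical performance.

## Problem sizes and numerical choices

Test-suite and acceptance runs use 30-vessel cohorts, 100 CV repeats,
and 10 phantom seeds for the effect-recovery check; these sizes are the
package's chosen desk-scale protocol, keeping full runs in minutes.
Tolerances: texture features match brute-force enumeration to 1e-9
relative; the AUC/Mann-Whitney identity to 1e-12; statistical bands
(null AUC in [0.35, 0.65], recovery mean AUC >= 0.85) follow the
calibration targets of the protocol.  All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`.
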