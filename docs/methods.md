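# Methods

## Laminar profiles

A cortical ribbon is described by two polyline contours (pial surface,
gray/white border) in pixel coordinates (0-based, x right, y down).  Traverses
join arc-length-matched points of the two contours: pial anchors at fractions
(i + ½)/n of total arc length, so a single traverse sits at mid-arc.
Traverses are straight segments; this is exact for a rectangle and for an
annulus sector (where arc-length matching of concentric arcs reproduces the
radial direction), the two geometries the synthetic renderer supports.  A
curvature-following (Laplace-field streamline) construction is a documented
extension point, not implemented.

Profiles are sampled by bilinear interpolation at D equidistant arc-length
positions and are therefore depth-normalized by construction (0 % = pial,
100 % = white matter).  D = 101 by default; the choice only has to resolve
laminar structure (layers are ≳5 % of depth) and normalizing an already
D-sampled profile is the identity.  GLI images are computed from binary
cell masks as windowed volume fractions over a square measuring field
(default 32 px at 1 µm/px, recorded in provenance) using an integral image
with edge-truncated windows.

## Border detection

Each profile is summarized by 10 features: (mean amplitude, centroid depth,
dispersion, skewness, excess kurtosis) of the profile treated as a weight
distribution over depth, and of the magnitude of its first differences.
Absolute rather than signed differences are used because signed differences
integrate to y(100) − y(0) and make the odd moments of the derivative block
degenerate for near-balanced curves.  An all-zero profile maps to the
sentinel (0, 50, 0, 0, 0) with a warning.

The sliding-block statistic at position i compares the b preceding and b
following feature vectors by the squared Mahalanobis distance with the
bias-corrected pooled covariance.  When the pooled covariance is
ill-conditioned (condition number > 1e8 — inevitable when 2b − 2 < 10, or
with noise-free synthetic data) the covariance is shrunk toward its diagonal
with the smallest shrinkage weight from (1e-6 … 1) that restores
conditioning; fully degenerate (zero) covariances fall back to a 1e-12 ridge,
which preserves the geometry of the mean difference and makes zero-noise
border recovery exact.  The trace records whether regularization engaged.

Significance: Hotelling's T² = (b²/2b)·D² with
F = T²(n−p−1)/(p(n−2)) ~ F(p, n−p−1), n = 2b, p = 10.  The Bonferroni family
is the set of evaluated positions within one trace (one block size, one
section); local maxima are strict, plateaus take the leftmost index.  The
block-size sweep (10–24) groups significant maxima by single-linkage with a
±3-traverse gap tolerance and emits a consensus call (median position) when
at least 60 % of block sizes contribute; both knobs are configurable.
Cross-section confirmation groups calls the same way across sections and
labels each group confirmed/unconfirmed (≥ 2 matching sections by default);
unconfirmed calls are reported, never dropped.  No automatic artifact
(blood-vessel) rejection is attempted: calls are for human review.

The false-positive behavior is measured, not assumed: on homogeneous ribbons
(no border) the fraction of ribbons with any significant maximum stays below
the nominal α = 0.01 (the Bonferroni bound holds with margin because the
local-maximum requirement is an additional filter and the moment features
are only approximately Gaussian).

## Synthetic ribbons

Templates are smooth baseline-plus-Gaussian-bump laminar curves clipped to
[0, 1] (GLI mode).  A ribbon is piecewise-constant in the template across
traverses with iid additive Gaussian noise per sample, floored at zero
(negative volume fractions or densities are unphysical; at the default SNR
the floor is a ≳5σ event and negligible).  The standard two-area recipe
controls the border strength by the root-mean-square template contrast,
default 3× the noise sd (`separation=3`); with `noise_sd=0` the contrast is
referenced to the default noise amplitude so noise-free ribbons keep a
genuine border.  Section images paint the template value at each pixel's
analytic depth, padded by 2 % depth so bilinear sampling at the ribbon
boundary is not contaminated by background zeros.

## Autoradiograph calibration

Co-exposed standards (default: 14 evenly spaced activities, in the 8–16
range of commercial tritium microscale steps) are fitted by a monotone
piecewise-linear curve after isotonic (pool-adjacent-violators) cleanup;
a relative isotonic residual above 5 % rejects the standards.  Evaluation
outside the calibrated gray range clamps to the end knots (never linear
extrapolation, which could produce negative densities) and flags the event.
With the default saturating logistic film response the interpolation error
at mid-knot positions stays below 2 % of the true activity over the interior
of the standard range, which bounds the end-to-end density recovery error.

Gray → density conversion is the parameterized chain

    density = C(gray) / (specific_activity × protein_factor) × (K_D + L)/L

with the free ligand concentration L taken from the packaged incubation
metadata and K_D, specific activity and protein factor supplied as
configuration (their units depend on assay bookkeeping that is not part of
this package).  Nonspecific binding is not modeled (a constant-subtraction
option exists, off by default).  Mean areal density is the flat average over
all depth samples of all profiles (90–150 profiles recommended; counts
outside that range warn).  Pseudocolor export maps the density range
linearly onto a black→blue→cyan→green→yellow→red spectrum and records the
true limits in metadata.

## Fingerprints and multivariate analysis

Fingerprints use a fixed canonical receptor order (AMPA, kainate, NMDA,
GABA_A, GABA_B, GABA_A/BZ, M1, M2, M3, α1, α2, 5-HT1A, 5-HT2, A1, D1).
The packaged 16-area × 15-receptor mean (± sd) table ships as a long-format
CSV.  For clustering, each receptor column is z-scored across areas
(sample sd) so all receptor systems weigh equally; the tree is built on
Euclidean distances with Ward linkage (standard in this literature;
complete/average available), and the cluster count is chosen by the mean
silhouette of multi-start k-means partitions over k = 2…8 (50 restarts,
fixed seed, ties to the smaller k).  PCA uses the column-centered SVD with a
deterministic sign convention (largest-magnitude loading positive).

On the packaged table the silhouette rule selects **k = 2** (0.272 vs 0.220
at k = 3), splitting the rostral sulcal-wall areas from everything else.
The three-group reading — rostral {AIP, LIPd, LIPv, PEipe, PEipi, MIPd,
MIPv}, intermediate {VIPm, VIPl, V6Ad}, caudal {V6, V6Av, V3A, V3d, LOP,
PIP} — is exactly the Ward (and complete-linkage) tree cut at k = 3, i.e.
one level below the top split, and `ClusterResult.cut(3)` reproduces it
verbatim.  We examined the standard internal indices (silhouette under
Euclidean and squared-Euclidean distances, micro and macro averaged,
Calinski–Harabasz, Davies–Bouldin, the gap statistic, the elbow rule,
restart stability, k-means/tree agreement): none selects three clusters on
this matrix; the three-cluster partition is a k-means fixed point but not
the multi-start optimum.  The package therefore reports the index-selected
k together with the per-k silhouettes and leaves descending the tree to the
analyst; tests pin both facts (the k = 2 selection and the exact k = 3
memberships) so neither can drift silently.

## Group statistics

Per-hemisphere densities are z-scored within receptor type, then tested in
three tiers: (1) an omnibus linear mixed model over all areas with random
subject and receptor intercepts; (2) the same model per adjacent area pair,
Benjamini–Hochberg-corrected across pairs; (3) per-receptor models (random
subject intercept) within surviving pairs, BH-corrected across
pair × receptor.  The full decision trail (p, q, flags per tier) is
returned.  The default adjacency list contains the eleven neighbor pairs of
the parcellation that the package's density table describes.

The variance components are estimated by (restricted) maximum likelihood on
a profiled Woodbury-form deviance — crossed random intercepts enter as
indicator blocks, so each likelihood evaluation costs one q × q Cholesky
(q = total random levels) — optimized over log-variances by L-BFGS-B
(tolerance 1e-8).  Fixed-effect p-values: maximum-likelihood likelihood
ratio (chi-square) or a Wald F with containment denominator degrees of
freedom, n − rank([X Z]).  The tiered scheme uses the F form throughout
because it is exact for the balanced designs here; in the tier-3
two-area × four-subject layout it reduces to the paired t test with 3
degrees of freedom (verified against scipy and against statsmodels MixedLM
in the test suite), whereas a chi-square likelihood ratio at n = 8 is
anticonservative and would undermine the scheme's false-discovery guarantee.

A structural property worth knowing: a contrast confined to a *single*
receptor is diluted 15-fold in the tier-2 pooled pair model while its
deviation from the common area effect inflates the pooled residual in
proportion to the same effect.  The tier-2 statistic for such a contrast is
therefore bounded (t ≈ 2.8 in this design) independent of effect size, which
is close to the BH threshold across eleven pairs — so single-receptor
differences pass the tier-2 gate only sporadically, whatever their
magnitude.  Contrasts spread over several receptors (which is what real
adjacent areas show) are detected reliably, and the per-receptor tier then
resolves which receptors drive them; the test suite demonstrates both
regimes, and the acceptance suite keeps the single-receptor expectation as a
failing check rather than weakening it.

## Simulated observations

`simulate_density_observations` mirrors the study design (4 hemispheres ×
16 areas × 15 receptors) around the packaged table:

    density = mean(area, receptor) × (1 + subject) × (1 + noise)

with proportional hemisphere effects (cv 0.15; the printed per-area sds are
7–22 % of their means and are dominated by inter-individual differences)
and proportional measurement noise (cv 0.03; each observation is itself an
average over ~100 laminar profiles, which suppresses measurement error).
Effects are multiplicative — a common additive spread would be larger than
the lowest receptor means (D1 ≈ 77 fmol/mg).  `base="null"` replaces area
means by receptor grand means for error-control experiments; a planted
contrast shifts one area of one pair by a chosen amount for one receptor or
a receptor set.

## What passing tests do and do not show

The synthetic ribbons have iid Gaussian profile noise, exactly
piecewise-constant areas and analytically perpendicular traverses; real
sections add spatially correlated texture, curvature-estimation error,
staining artifacts and blood vessels (excluded here by design — the tool
reports calls for human review).  Error control and recovery results
therefore validate the statistics and the implementation, not robustness to
histological artifacts.  Likewise the observation simulator has no
area × subject interaction and no section-level batch structure; the
false-discovery results validate the testing scheme under its own model.

## Problem sizes

Default experiment sizes were chosen so every stage is exercised at the
scale the procedures are designed for: 500 null ribbons / 100 recovery
ribbons of 200 profiles × 101 depth samples; 10,000 Monte-Carlo draws for
the Hotelling null; 100 replicates of the 960-observation tiered testing
scheme; 1,000 random p-vectors against the step-up oracle.
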