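# Methods

This note documents the models and procedures implemented in `uqtriage`,
the defaults they ship with, and the boundaries of what the synthetic
experiments demonstrate.

## The classification problem

Each case is one IPMN lesion with a radiomic feature vector, a binary
dysplasia-grade label (Low-Risk = low-grade dysplasia; High-Risk = high-grade
dysplasia or invasive carcinoma), an IPMN type (branch-duct BD vs
main-duct/mixed MD), a size measurement (maximum cyst diameter for BD, main
pancreatic duct diameter for MD), an anatomical region (head, body, tail,
head+body, body+tail, whole pancreas), and a contributing center. Extent of
involvement (single region / two regions / whole pancreas) is a deterministic
function of region. Size bins follow Kyoto-guideline thresholds: BD
<15 / 15–30 / >30 mm (boundaries 15 and 30 mm both fall in the middle bin,
matching the printed strict "<15" and ">30" labels) and MD <10 / ≥10 mm
(10 mm falls in the high-risk bin).

## Fusion classifier

The radiomics branch is a bagged ensemble of 47 decision trees
(`min_samples_leaf = 5` so leaves stay impure and per-tree outputs are soft
leaf class-frequency vectors — hard votes would artifactually zero the
aleatoric component downstream). The "DL" branch is a small dropout network:
a two-hidden-layer MLP (32/16 units, dropout 0.3) on the same selected
features, or a one-convolution 3D network (3×3×3 "same" kernels, ReLU,
dropout, global average pooling, linear softmax head) when toy volumes are
used. Both are trained with Adam on cross-entropy and are exactly
reproducible under their seed.

Decision-level fusion: if the radiomics branch's maximum class probability
strictly exceeds threshold *t*, its vector is returned unchanged; otherwise
the fused output is (1−k)·p_rad + k·p_dl. The threshold is read on the
maximum class probability (class-symmetric; the alternative — thresholding
the High-Risk probability only — changes nothing for binary argmax
decisions above 0.5). Note the identities: k = 0 reproduces the radiomics
branch for any t, and t = 1 with k = 1 reproduces the DL branch (at t = 0
the threshold is always exceeded, so fusion degenerates to the radiomics
branch — the DL-identity limit is t = 1, not t = 0).

*Hyperparameter search.* Grids default to t ∈ {0.50, 0.55, …, 1.00} and
k ∈ {0.0, 0.1, …, 1.0}; both branches are refit on each of 5 stratified CV
folds and mean fused validation accuracy is maximized, with ties broken
toward smaller k then smaller t (prefer the simpler, radiomics-only model).

*Feature selection.* Features are ranked once by absolute Spearman
correlation with the label on the full training set; a greedy pass then
retains a feature iff its absolute Spearman correlation with every
already-retained feature is below 0.6, run within 5-fold CV with the fold
selections intersected. Ranking inside the folds instead is unstable when
informative features form a tightly correlated block (the realistic
radiomics situation: one underlying texture signal measured many ways):
near-tied folds elect different block representatives and the intersection
deletes the entire block. Fixing the ranking and letting the folds vote only
on redundancy keeps the selection stable without weakening the redundancy
filter.

*Evaluation protocol.* Held-out-center trials: four splits whose test sets
are unions of one or two whole centers, sized 29/35/35/75 at the study
scale; per-trial metrics are pooled by test-set-size weighted averaging
(algebraically, pooled accuracy equals total correct over total tested).
Centers may appear in more than one trial's test set — the four trial sizes
sum to more than the cohort, so the trials are independent splits, not a
partition.

## Uncertainty decomposition

For one case, n_passes = 30 Monte Carlo dropout forward passes are paired
with all 47 per-tree probability vectors; every (pass, tree) pair is
combined through the trained fusion rule, giving T = 1410 predictive samples
p_t. The pairwise combination operator is not uniquely determined by the
framework's description; fusing each pair with the trained (t, k) is the
only reading under which the sample set is drawn from the *fused* model, so
that is what is implemented.

With p̂ the sample mean:

* total = H(p̂) = −Σ_c p̂_c log(p̂_c + ε), natural log;
* aleatoric = E[H(p_t)] (each sample is itself ambiguous);
* epistemic = total − aleatoric (the samples disagree; equals the mutual
  information between prediction and model posterior, ≥ 0 by Jensen).

ε = 1e−12 sits inside the log argument (the standard stability guard;
results shift by < 1e−6 as ε varies over [1e−15, 1e−9]). All three values
are also reported normalized by log C, so the additive identity survives
normalization. Natural logarithms throughout — after log C normalization
the base choice is immaterial.

## Selective prediction

Retention is non-strict (uncertainty ≤ τ) with stable ordering on ties.
Fixed-coverage accuracy retains the ⌊coverage·n⌋ lowest-uncertainty cases by
rank rather than by threshold interpolation, making realized coverage exact
and the result invariant to strictly monotone transforms of the signal. The
weighting grid scans w_a ∈ {0, 0.05, …, 1} over
w_a·aleatoric + (1−w_a)·epistemic (normalized components; w_a = ½ recovers
half the normalized total by additivity) across coverage levels, reporting
the accuracy matrix and the best weight per coverage.

## Subgroup statistics

Accuracy differences across categories are tested with the exact
conditional test on the r×2 correct/incorrect table: conditional on all
margins, a table's probability is the multivariate hypergeometric mass, and
the two-sided p-value sums the masses of all margin-fixed tables whose
probability does not exceed the observed one (with a 1e−7 relative tie
tolerance). For r = 2 this is the classical two-sided Fisher test (verified
against an exhaustive hypergeometric oracle on every margin configuration
with n ≤ 20, and against scipy); for r > 2 it is the Freeman–Halton
generalization, implemented by enumerating row-count vectors in two halves
and matching the halves on the first-column margin with sorted prefix sums —
exact and sub-second for the 6×2 tables of a 170-case cohort.

Continuous uncertainty differences use one-way ANOVA (F-test) with
Tukey-HSD-adjusted pairwise comparisons; per-group means are reported with
pooled-variance standard errors (the estimated marginal means of the one-way
model). Groups with fewer than two observations are excluded with a warning.
Discrimination metrics: trapezoidal AUC, sensitivity/specificity at the
Youden point (ties resolved to the lowest threshold), Brier score, and
accuracy at the 0.5 cut.

## Attributions

*Tree Shapley.* Exact, analytic, on the predicted-probability scale. The
coalition valuation is the standard path-conditional traversal (features in
the coalition follow the input; all other splits take both children weighted
by training cover). Restricted to a single leaf the game is multiplicative
over the distinct features on the leaf's path, so each leaf's Shapley
contribution has a closed form in elementary symmetric polynomials of the
inverse cover ratios; summing over leaves and trees gives the ensemble
attribution in O(leaves · depth³) per case without any 2^p enumeration.
Efficiency (baseline + Σφ = predicted probability, baseline = cover-weighted
mean prediction), the null-player property, and symmetry are exercised in
the tests, including equality with a brute-force 2^p coalition oracle for
p ≤ 8. Attributions are computed on the radiomics branch — the only branch
for which exact tree attributions are defined.

*Perturbation surrogate.* 5000 Gaussian perturbations around the case,
exponential proximity kernel of width 0.75·√p on standardized distance,
weighted ridge regression on the predicted High-Risk probability;
coefficients are the attributions. Explanation strength is Σ_j |φ_j| for
either method, and its Spearman/Pearson coupling with normalized uncertainty
is reported with a 95% regression confidence band.

*Grad-CAM.* With one convolutional layer, global average pooling, and a
linear head, the gradient of the class score with respect to feature map k
is spatially constant and equals w_kc / V, so the channel weights are exact;
the map is the rectified weighted sum of feature maps on the input grid.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the *structure* of the study cohort: 170 cases by
default with exactly 63 High-Risk; seven centers sized (29, 35, 17, 18, 40,
16, 15) so the four trial test sizes are reachable as whole-center unions;
type and region mixtures per risk group matching the published tables; sizes
lognormal with medians/IQRs anchored at the published per-(type, risk)
values (18.2/25.1 mm BD, 8.6/10.3 mm MD).

Class signal lives in a correlated "texture block" of 5 of 20 features
sharing a per-case latent: for signed label s and difficulty d,
latent = s(1−d) + d·z with z ~ N(0,1), and each informative feature is
latent + 0.3d·ε. Difficulty 0 gives exactly separable classes; difficulty 1
removes all signal; the per-(risk, type) defaults (0.45–0.70, High-Risk and
MD harder) produce the qualitative accuracy gradient seen on the real
cohort. Misclassification is monotone in difficulty by construction and by
test.

Toy volumes contain one ellipsoidal lesion whose voxel diameter tracks
size_mm; the interior mixes a narrow fluid signal with a uniform-intensity
heterogeneous component whose fraction is larger for High-Risk lesions, so
within-mask histogram entropy separates the classes — the imaging correlate
the texture features stand in for. Lesion size varies with the size
distribution, and a global-average-pooled network conflates texture fraction
with lesion volume; the Grad-CAM localization test therefore fixes lesion
size to isolate the texture signal.

What passing tests therefore show: the machinery is correct (exact tests
against oracles, entropy identities, fusion algebra) and the *qualitative*
clinical findings re-emerge under controlled conditions — errors carry
higher uncertainty, deferral raises retained accuracy, texture features
dominate attributions. What they do not show: any real-data quantity.
Real-cohort accuracies, subgroup uncertainty means (0.69–0.78), and the
negative attribution–uncertainty correlation are properties of the real MRI
cohort; on synthetic cohorts the attribution–uncertainty correlation can
take either sign, and no synthetic number should be read as a reproduction
of a real one. The published contingency tables are the exception: they are
embedded as data, and the exact-test p-values computed from them are
genuine reproductions.

## Numerical and scale choices

Default problem sizes keep the full suite and the acceptance script at
desk scale: synthetic pipeline runs use n = 500 cases with a 50/50
stratified split, 30 dropout passes, 47 trees; the Freeman–Halton
enumeration is exact (no Monte Carlo); Shapley values are analytic. The
seeds of every stochastic component are explicit arguments, and identical
seeds reproduce identical cohorts, fits, dropout masks, and perturbations.

## Known limitations

* The DL branch is deliberately small; it stands behind the same interface
  a larger 3D network would use, but its capacity is desk-scale.
* The perturbation surrogate perturbs features independently (no
  correlation-aware sampling), the standard local-surrogate simplification.
* The Freeman–Halton implementation targets r×2 tables (the study's shape);
  general r×c would need a different enumeration strategy.
* Selective-prediction results assume the uncertainty signal is computed on
  held-out data; applying it in-sample overstates the deferral gain.
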