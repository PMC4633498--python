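# Methods

`petcad` implements a computer-aided diagnosis pipeline that separates
idiopathic Parkinson's disease (PD) from atypical parkinsonian syndromes
(APS — multiple system atrophy and progressive supranuclear palsy pooled)
using spatially aligned 3D striatal-PET-like volumes. This note documents the
model, the assumptions behind each stage, the tunable parameters, and what
the synthetic phantom does and does not establish about real data.

## Pipeline

For a cohort of N labeled volumes on a common grid with an integer-labeled
atlas of R disjoint regions:

1. **Intensity normalization.** Each image is divided by its own scalar
   I_max, the mean of the top 0.1% of its voxel intensities. This removes
   between-subject global-uptake differences while being robust to single
   bright voxels. On the small phantom grids the top set is
   `ceil(0.001 · n_voxels)` voxels, minimum one, so the estimator is always
   defined.
2. **Region-of-interest selection.** A voxelwise pooled-variance two-sample
   t-test compares APS against PD on 8 mm-FWHM-smoothed normalized images,
   one-tailed in the direction APS > PD (PD hypointensity — the expected
   direction for D2/3-receptor ligands). The map is thresholded at
   p < 0.001 uncorrected, and atlas regions are ranked by the fraction of
   their voxels above threshold; the top 4 regions are selected (ties go to
   the smaller region id, making selection deterministic).
3. **Per-region SVMs.** Each selected region contributes a linear SVM
   (cost C = 1) on its raw normalized voxel intensities in raster order.
   A leave-one-out loop over the training subjects assigns each region an
   accuracy and, simultaneously, a cross-validated binary decision per
   training subject.
4. **Bayesian-network fusion.** The M region decisions plus the true label
   form an (M+1)-column binary table. A directed acyclic graph over these
   M+1 nodes is learned by Metropolis-Hastings search scored by BIC;
   conditional probability tables are fitted by Dirichlet-MAP counting
   (symmetric prior, α = 1). A new subject's region decisions are fused by
   exact posterior inference over the label; posterior argmax decides, an
   exact 0.5/0.5 tie (tolerance 1e−12) falls back to the majority vote over
   region decisions, and a tied vote follows the most accurate region.
5. **Evaluation.** A nested leave-one-out scheme: the outer loop holds out
   one subject; region selection, the inner accuracy loop, the region SVMs
   and the network are all re-fit on the remaining subjects only. Six
   systems are compared — whole-brain voxels-as-features, striatum-only,
   concatenated selected regions, per-region majority voting, a
   multiple-kernel SVM with one linear kernel per region, and the
   Bayesian-network fusion.

## Model details and numerical choices

**Joint model.** The network defines
p(x, y) = ∏_v θ_{v | Pa(v)} over binary nodes; with ≤ ~10 nodes inference is
exact by enumeration over the label, and test oracles can enumerate the full
joint.

**BIC.** Family-decomposable: maximized multinomial log-likelihood minus
(q/2)·ln N per node, q = 2^|parents| free parameters for a binary child.
Empty count cells use the 0·ln 0 := 0 convention. Decomposability lets the
sampler cache family scores across iterations.

**MH sampler.** State = DAG; proposal = uniform choice among all valid
single-edge moves (add, delete, reverse; acyclicity-preserving); acceptance
min(1, exp(Δscore)·|N(G)|/|N(G′)|), the Hastings correction for the
state-dependent move count. Start is the empty graph; defaults are 1000
iterations with burn-in 200 — the acceptance-ratio trace stabilizes within
the first few hundred iterations on the default 5-node problem, and 1000
leaves a wide margin. The returned structure is the best-scoring state
visited from the burn-in onwards. Under a constant score the sampler's
visit frequencies over the 25 three-node DAGs are uniform (checked in the
test suite), validating the Hastings factor.

**CPT fitting.** θ = (N_state + α)/(N_config + 2α). α = 0 reduces to the
MLE with a logged uniform fallback for parent configurations never observed.
The naive (label → region) structure parameterized directly by the M scalar
accuracies is available as `naive_cpts_from_accuracies` — the closed-form
conditional-independence fusion rule — and a discrete network trained on the
decision table reproduces those accuracies in its CPTs under the naive
structure, which is why training on the cross-validated decision table is
the default reading of "train the network from the region accuracies".

**SVMs.** Hard labels only are passed downstream: the fusion network is
discrete, and discretizing margins would introduce an extra design axis.
A margin of exactly zero maps to APS; the convention is arbitrary but fixed
and configurable. No feature standardization is applied (features are
already on a common normalized-intensity scale). The MKL baseline combines
per-region linear Gram matrices as a convex combination with uniform weights
by default (accuracy-proportional weights are a config option); no kernel
weights are learned.

**t-test.** Pooled-variance (Student) rather than Welch: the classical
mass-univariate two-sample design, and the phantom has equal group variances
by construction. Zero-variance voxels are kept total: t = 0 (p = 0.5) when
group means agree, ±inf (p = 0 or 1) otherwise. Analysis is restricted to
atlas-labeled voxels; background voxels would distort the null calibration.
A two-tailed switch exists for reuse outside the PD-hypointensity setting.

**Smoothing.** Separable Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in voxel
units, reflective boundaries (preserves constant images exactly and avoids
edge darkening on small grids). Classification consumes *unsmoothed*
normalized volumes; smoothing enters only the t-test stage. This is a config
switch (`classify_smoothed`) because the protocol for classification
features is genuinely open; unsmoothed is the default to keep the two stages
independent.

**Leakage.** Selection-inside-the-fold is the default. The alternative
single whole-cohort selection (`selection_scope="global"`) is retained
because published single-map protocols often select once on all data; it is
not leak-free and is off by default. The test suite checks leak-freedom
operationally: arbitrarily rewriting the held-out subject's voxels changes
neither the fold's selected regions nor its region accuracies nor the
learned network.

## The phantom

Real D2/3 PET cohorts for this problem are not publicly deposited, so the
package ships a generator of synthetic aligned cohorts. Defaults mirror the
emulated study population: 87 subjects (39 PD / 48 APS), a 40³ grid of
2 mm voxels, 8 box regions (~1000 voxels each) of which 4 are affected and
2 are tagged striatal. Brain voxels have mean 100 (arbitrary units); PD
subjects lose `effect_size` units of mean in each affected region; i.i.d.
Gaussian noise (σ = 10) is added per brain voxel and intensities are clipped
at 0, since tracer-uptake images are non-negative. The default effect size
20 (= 2σ per voxel) is a *strong* effect: with ~1000-voxel regions the
multivariate separation is essentially complete and every method should
reach 100% accuracy — a pipeline-integrity condition, not a realistic one.
The *moderate* condition used in the evaluation scripts, effect 2 (= 0.2σ
per voxel), was chosen once so that per-region accuracies land in the
70–85% band typical of early-stage clinical separability, producing
non-trivial fusion behavior.

What the phantom does **not** emulate: PET physics (PSF, partial-volume
effects, reconstruction artifacts), spatial misalignment, anatomical region
shapes, between-region intensity correlation, or unequal group variances.
Passing tests therefore establish the correctness and calibration of the
computational pipeline under its stated assumptions — not clinical
performance on real images.

Noise is i.i.d. Gaussian per voxel deliberately: it is the simplest model
satisfying the t-test's assumptions, so the voxelwise false-positive rate at
p < 0.001 can be checked against a binomial band. That calibration check
runs on unsmoothed volumes: smoothing leaves the marginal rate at the
nominal level but correlates neighbouring voxels, inflating the variance of
the suprathreshold count far beyond binomial, so the unsmoothed test is the
one for which the binomial tolerance is exact.

## Parameters at a glance

| parameter | default | meaning |
|---|---|---|
| `top_fraction` | 0.001 | fraction of brightest voxels averaged into I_max |
| `smoothing_fwhm_mm` | 8.0 | Gaussian FWHM for the t-map (mm) |
| `p_threshold` | 0.001 | uncorrected voxelwise threshold |
| `n_select_regions` | 4 | regions kept after ranking |
| `svm_c` | 1.0 | linear SVM cost |
| `mh_iterations` / `mh_burn_in` | 1000 / 200 | structure-search length |
| `dirichlet_alpha` | 1.0 | symmetric CPT prior (Laplace) |
| `effect_size` / `noise_sd` | 20 / 10 | phantom group effect and noise (a.u.) |

## Problem sizes

The shipped evaluation runs use the full default cohort (87 subjects, 40³
grid, ~8000 brain voxels): one nested-LOO evaluation performs 87 outer
folds, each with an 86-subject inner LOO per selected region and a
1000-iteration structure search, and completes in about a minute on one
core thanks to precomputed per-region Gram matrices (the linear-kernel inner
products are fold-independent; every fit uses only training-row/column
submatrices). Calibration suites use 20 Monte-Carlo cohorts (1.6 × 10⁵
voxel-tests for the null band); sampler and parameter-recovery checks use
decision tables of 500–2000 rows.

## Known limitations

- Binary PD-vs-APS only; no three-way PD/MSA/PSP discrimination.
- No multiple-comparison correction in the univariate stage (by design —
  the ranking consumes the uncorrected map).
- No registration: volumes must already share a grid.
- The MH sampler explores DAGs over few nodes; for networks much beyond
  ~10 nodes both the sampler and exact enumeration would need replacing.
- Likelihood ratios are reported as infinity when their denominator is 0
  (perfect specificity or zero specificity), following the usual diagnostic
  convention rather than continuity corrections.
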