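# Methods

## Model

Two feature tables share one space: a labeled source sample
{(xᵢˢ, yᵢˢ)}ᵢ₌₁ⁿ and an unlabeled target sample {xⱼᵗ}ⱼ₌₁ᵐ, with N = n + m
pooled rows and C classes (1-based codes; class index 0 is reserved for the
whole-domain column throughout). Samples enter all distribution terms
through a kernel k and its feature map φ, so distances live in the induced
RKHS and are computed purely from Gram-matrix expansions.

**Distribution alignment.** The empirical squared MMD between the domains,
‖(1/n)Σφ(xᵢˢ) − (1/m)Σφ(xⱼᵗ)‖², can be related to a one-cluster-center
objective Σₖ ςₖ‖φ(xₖ) − μ‖² with ςₖ = 1/n² (source rows), 1/m² (target
rows), and blended center μ = δμₛ + (1−δ)μₜ. P-DDM relaxes the fixed
weights ςₖ into free memberships λₖ,c ∈ [0, 1] — one column for the whole
domain (c = 0) and one per class, with per-class blended means
μ_c = δμ_{s,c} + (1−δ)μ_{t,c} — and regularizes them with the fuzzy entropy
β(λ² ln λ² − λ²). Minimizing over λ at fixed means yields
λ²ₖ,c = exp(−(dₖ,c + eₖ)/β), where dₖ,c is the squared RKHS distance of
sample k to mean c and eₖ its classifier residual: samples far from every
mean, or badly predicted, decay exponentially and stop influencing the
alignment. That is the entire robustness mechanism.

**Classification and label propagation.** A bias-augmented linear decision
function W (optionally on a seeded random-Fourier map, so the ℓ2,1 norm
stays defined on explicit feature rows) is fit by membership-weighted least
squares with a row-sparsity penalty ρ‖W‖₂,₁, solved by IRLS: alternate
W = (X̃ᵀΩX̃ + ρU)⁻¹X̃ᵀΩY with Uᵢᵢ = 1/(2‖wⁱ‖ + ε). Geometric consistency is
enforced by tr(YᵀLY) with L = D − M the Laplacian of a symmetrized k-NN
Gaussian affinity graph over the pooled rows. Substituting the closed-form
W = AY turns the label update into min_{YᵀY=I} tr(YᵀHY) with
H = αL + BᵀΩB (B = X̃A − I), solved by the C smallest eigenvectors of H.

**Fusion.** After convergence a source classifier f̃ₛ (true source labels)
and a target classifier f̃ₜ (inferred target labels) are refit — each
carrying the learned membership weights, which is how the final prediction
inherits the robustness — and new samples are scored by
υ·f̃ₛ(x) + (1−υ)·f̃ₜ(x).

## Alternating optimization and its bookkeeping

The solver iterates λ → W → Y. Internally the loop runs entirely on the
*relaxed* orthonormal label matrix (the actual feasible set of the
constraint YᵀY = I): residuals, IRLS targets and the eigen step all consume
it, which makes every block update a guaranteed-descent step on one and the
same relaxed objective —

* the λ update is the exact per-element minimizer (the residual weight of
  sample k in the joint objective is the membership row sum
  ωₖ = Σ_c λ²ₖ,c, which is precisely the weight under which the closed-form
  update is optimal);
* the W update is IRLS warm-started from the previous W, a
  majorize-minimize scheme whose objective never increases;
* the Y step folds the majorized penalty ρAᵀUA (U frozen at the IRLS fixed
  point) into H, so the eigenvector solution is a genuine
  majorize-minimize step of the full objective; W is then set to AY.

The *discretized* label matrix — Procrustes-aligned to the fixed one-hot
source block, rounded row-wise by argmax, source rows restored — is the
read-out: it supplies the target pseudo-labels that refresh the class means
each iteration (dynamic pseudo-labeling; a frozen mode is available via
`refresh_pseudo_labels=False`), the stopping statistic Θ (absolute change
< ε), and the final predictions. Because the mean refresh redefines the
objective between iterations, the quantity with a descent guarantee is the
within-iteration chain (start ≥ after-λ ≥ after-W ≥ after-Y), which the
solver records in `relaxed_block_trace_` and the tests assert to 1e-9.

## Parameters

| name | meaning | default |
|---|---|---|
| α, β, ρ | graph / entropy / sparsity weights (dimensionless; typical grid 10⁻⁶…10⁶) | 1 |
| δ | source share of the blended means | 0.5 |
| υ | source share of the fused prediction | 0.9 |
| k_neighbors | affinity-graph neighbourhood (practical grid {3, 5, 10, 15, 17}) | 5 |
| σ | kernel bandwidth; default √(mean ‖xᵢ‖), ×C for C > 2 (median pairwise distance offered as an alternative) | heuristic |
| θ | bandwidth divisor of the generalized Gaussian kernel, in [1, θ₀], θ₀ = 10 | 1 |
| ε (stop) | absolute threshold on the objective change | 1e-5 |
| Z | iteration cap | 50 |

Kernel families: Gaussian exp(−‖x−x′‖²/(2(σ/θ)²)), inverse square distance
1/(1 + s‖x−x′‖²), Laplacian exp(−s‖x−x′‖) and inverse distance
1/(1 + s‖x−x′‖) with s = σθ (all four are positive semidefinite; the
non-Gaussian σ acts as an inverse length scale, so θ narrows every family).
Multi-kernel mode sums the component Gram matrices — the Gram of the
concatenated feature map [φ₁; …; φ_A], which is what every downstream
distance formula consumes (some presentations write the combination as a
stacked block matrix; the entrywise sum is the mathematically equivalent
object at the Gram level).

## Conventions adopted where the formulation is ambiguous

* **Membership exponent.** The stationarity condition of the entropy-
  regularized problem gives λ² = exp(−(d+e)/β); we implement exactly that
  (reading the update at the λ level instead would just rescale β). The
  residual eₖ enters every class column of sample k identically, and the
  update is element-wise — a single global exponent would make all
  memberships equal and defeat the noise-downweighting purpose.
* **Class means** are within-class averages (1/n_c); a printed variant that
  normalizes by 1/n over all classes conflicts with the means being
  class-conditional. If one side of a class is empty (common for early
  pseudo-labels) the populated side receives full weight; a class empty on
  both sides is flagged inactive and its distance column is a sentinel.
* **Laplacian sign.** L = D − M (the smoothness form); the opposite sign
  would make the propagation loss unbounded below.
* **Orthogonality** is YᵀY = I (N×C with N > C; the transposed constraint
  is infeasible).
* **Relaxed → discrete labels.** The eigenvector basis is defined only up
  to rotation, so it is aligned to the known source block by orthogonal
  Procrustes before the row-wise argmax (ties break to the lowest class
  index); eigenvector signs are fixed deterministically (largest-magnitude
  entry positive).
* **Residual weight in the classifier.** The joint objective weighs sample
  k's residual by the sum of its membership row; the IRLS diagonal uses the
  standard 1/(2‖wⁱ‖ + ε) majorizer with ε = 1e-12, small enough that the
  majorization slack (~ε/4 per zeroed row) is invisible at the 1e-9 descent
  tolerance. Exponents below −700 underflow to an exact zero membership;
  squared RKHS distances are clamped at 0, and anything below −1e-10 raises
  an internal-consistency error rather than being silently clipped.

## Synthetic data

`make_two_domain_blobs` draws per-class unit-variance isotropic Gaussians
at the vertices of a regular simplex (all pairwise class-mean distances
equal `class_separation`, default 4), translates the target means by a
random unit vector × `shift_magnitude` (default 1), optionally replaces a
fraction of source rows with a far noise cluster (radius
`outlier_scale` × `class_separation` from the centroid along one seeded
direction, all carrying one random class label — a mislabeled artifact
batch that actually drags the empirical source mean, which is the failure
mode possibilistic weighting addresses), and optionally flips an exact
rounded fraction of source labels uniformly. Everything is reproducible
from a single seed; fraction counts round half away from zero.

These fixtures exercise the mechanics, not field realism: real feature
tables (e.g. 310-dimensional band-power EEG features) have correlated,
heteroscedastic, non-Gaussian dimensions, structured session/subject
shifts, and no oracle outlier flags. Passing tests here demonstrates that
the algorithm does what its derivation says under controlled conditions,
not that it attains any particular accuracy on real recordings.

Problem sizes used by the test suite and `scripts/acceptance.py` — chosen
desk-scale so each property is measured on tens of fits — are
n = m = 60–120, d = 5, C = 3, with 10–20 seeds per condition and 200
random instances for the distance-bound checks.

## Known limitations

* **The one-cluster-center bound is not a per-instance upper bound of the
  empirical MMD.** With weights 1/n², 1/m², the bound's expectation equals
  the V-statistic MMD times (1 − 1/(2n)) for identically distributed
  domains (each sample is part of the blended mean), so empirical
  violations occur on roughly half of random instances; a factor
  2·max(n, m) makes the inequality rigorous, and that scaled form is what
  the unit tests assert. The one-cluster quantity is still the object the
  memberships relax, and minimizing it still drives the domains together —
  only its advertised tightness fails.
* **Extreme outliers degrade the spectral label update.** A far noise
  cluster has near-zero graph degree (Gaussian affinities underflow) and
  near-unit leverage in the linear hat matrix, so both terms of H vanish on
  it and some of the C smallest eigenvectors localize on outlier rows
  instead of class structure; target pseudo-labels then lose accuracy. The
  fusion prediction (υ = 0.9 on the membership-weighted source refit) is
  what carries robustness in that regime.
* **The fusion does not transform features.** f̃ₛ is applied to the raw
  target coordinates, so a genuine covariate shift is only compensated
  implicitly (through pseudo-labels and f̃ₜ); under small shift and heavy
  contamination this roughly ties with explicit mean-translation baselines
  rather than dominating them seed-by-seed.
* N is desk-scale by design: dense N×N Gram, affinity and H matrices and a
  dense eigen-decomposition per iteration (O(N³)).
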