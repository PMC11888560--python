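# Methods

This note records the scientific conventions, numerical choices and known
limitations of the package. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. The rule space

A row is three panels; each panel holds 1–9 objects on a 3×3 grid of cells
with centroids {20, 60, 100}² in a 160×160 panel. Object attributes and their
cardinalities: shape (7: circle, triangle, square, pentagon, hexagon,
octagon, star), size (10 bounding-box heights, 20–40 px evenly spaced), shade
(10 grayscale levels, 230 down to 0 evenly spaced, rounded to integers),
position (9 cells), number (1–9). Number and position form a single merged
attribute: a constant-position row necessarily has a constant count, so
treating them separately would make rows ambiguous.

Ten abstract relations × four attributes give 40 rules, enumerated in a fixed
order (constant, progression+2, progression−2, progression+1, progression−1,
addition, subtraction, AND, OR, XOR) × (shape, size, shade,
number/position); `rule_id` is the row-major index. The sign of a progression
is part of the rule identity, not a per-row degree of freedom.

**Relation semantics.** The full relation×attribute matrix is a convention of
this package (the fine print differs across published benchmark variants):

* shape/size/shade, non-logical relations: every object in a panel must share
  the governed value; the relation acts on its ordinal index, 1-based for
  arithmetic (so `addition` means v₃ = v₁ + v₂ on 1-based indices).
* shape/size/shade, logical relations: the relation acts on the set of
  distinct values present per panel, set₃ = op(set₁, set₂).
* number/position: constant/progression/arithmetic act on the object count;
  logical relations act on the set of occupied cells.

Logical relations are only deemed satisfied when *evidenced*: panels 1 and 2
contain ≥ 2 distinct values and the result set is non-empty. This is part of
the predicate, not merely the sampler, because a constant row vacuously
satisfies AND and OR under the naive set semantics and the exclusivity
requirement below would be unsatisfiable.

**Sampling.** Governed attribute values are drawn only from combinations with
in-range results (arithmetic operand pairs are enumerated so termination is
guaranteed); ungoverned attributes are drawn independently per object. The
whole row is rejected and resampled while it satisfies any unintended rule,
with a cap of 10,000 attempts (observed acceptance is far higher; a cap hit
names the offending rule). Rows are deterministic given the generator state.

## 2. Rendering

Objects are filled binary masks — a pixel belongs to a shape when its center
lies inside — with no anti-aliasing, so renders are bit-exact across
platforms. Background is 255 (white); shades span 230→0, consistent with a
lighter-than-every-object background. Shapes are drawn vertex-up and scaled
so the vertical ink extent equals the size value; the pentagon and 5-point
star (inner/outer radius ratio sin 18°/sin 54°) are ~5% wider than tall in
regular form and are squeezed horizontally to respect the 40×40 bounding box
(the grid pitch is 40 px). The triangle is positioned by its area centroid so
every object's ink centroid falls within 2 px of its cell centroid (verified
in tests). Pointy shapes (triangle, star) rasterize a few pixels short of
their geometric height because the apex is thinner than one pixel; ink area
remains strictly monotone in the size index for every shape.

## 3. Dataset and splits

Default counts are 10,000/1,000/1,000 train/val/test rows per rule; counts
are plain configuration. Uniqueness is global and canonical: two rows are
duplicates when their panels, as *sorted* object tuples, coincide (object
order within a panel is display-irrelevant). Held-out splits remove 5 of the
40 rules with pairwise-distinct relations, leaving 35 training rules and
5·4 = 20 ordered held-out pairs per split.

## 4. Trials and scoring

A trial for the ordered pair (a, b) holds a sample row and a correct choice
(distinct rows of rule a) and an incorrect choice (rule b); trial sets are
unique at the level of row-index triples. A representation solves a trial
when the correct choice is *strictly* closer in Euclidean distance; ties
count as incorrect. The tie convention is conservative, only matters for
degenerate (e.g. constant) representations, and makes their behavior
well-defined: a collapsed representation scores error 1, a random one 0.5.
Scoring is invariant to positive rescaling of all representations.

The pixel baseline represents a row by its flattened (3·160·160) pixels,
optionally through a seeded random projection to 400 dimensions with i.i.d.
N(0, 1)/√400 entries — an unbiased distance-preserving reduction; projected
and raw errors agree within Monte-Carlo noise (tested). Trials are built
from test-partition rows.

## 5. The error theory

Write the trial margin h = ‖s − c‖² − ‖s − i‖² with s, c drawn from manifold
a and i from manifold b; the generalization error is ε = P(h > 0). Model
each manifold as a Gaussian with centroid x₀, axes uᵢ, radii Rᵢ, covariance
Σ = Σᵢ Rᵢ² uᵢuᵢᵀ, and let Δ = x₀ᵇ − x₀ᵃ, Tₐ = Σᵢ (Rᵢᵃ)² = tr Σₐ. Exact
moments of h:

    −E[h]  = ‖Δ‖² + T_b − Tₐ
    Var[h] = 6 Σᵢ(Rᵢᵃ)⁴ + 2 Σᵢ(Rᵢᵇ)⁴ + 4 tr(ΣₐΣ_b) + 4 ΔᵀΣₐΔ + 4 ΔᵀΣ_bΔ

Dividing by Tₐ (numerator) and Tₐ² (variance) gives the closed-form,
dominant-terms SNR exposed as `snr_dominant`:

    SNR = (signal + bias) /
          sqrt( 6/Dₐ + 2 (1 + bias)² / D_b + 4 x_ab + 4 ov_a + 4 ov_b )

with signal = ‖Δ‖²/Tₐ, bias = T_b/Tₐ − 1, participation ratio
D = (Σ Rᵢ²)²/Σ Rᵢ⁴, signal–noise overlaps ov_{a,b} = ΔᵀΣ_{a,b}Δ/Tₐ², and the
noise–noise alignment x_ab = tr(ΣₐΣ_b)/Tₐ². Note the normalization: *signal
and the overlaps are measured in units of the total squared radius*
Σᵢ Rᵢ², not the per-dimension mean — with the per-dimension mean the signal
and bias terms would not be commensurate in the numerator. The reported
normalized overlap is (ov_a + ov_b)/signal, which isolates axis alignment
from signal magnitude and is invariant under joint rescaling.

ε = H(SNR) with the Gaussian tail H is exact only insofar as h is Gaussian.
h is a quadratic form in Gaussians; at low manifold dimensionality (D ≲ 20)
its skewness moves the true error by up to a few hundredths. The package
therefore computes the predicted error *exactly* under the Gaussian-manifold
model: in the joint span of both manifolds' axes and Δ (dimension ≤ kₐ+k_b+1),
h = Σ λⱼ zⱼ² + gⱼ zⱼ + c in independent standard normals, and P(h > 0) is
obtained by Gil-Pelaez/Imhof characteristic-function inversion
(`scipy.integrate.quad`; the integrand decays like u^(−n/2)). The default
`snr` is the Gaussian-equivalent margin Φ⁻¹(1 − ε), clipped to |SNR| ≤ 8
where the tail probability under/overflows, so ε = H(SNR) holds identically
and `snr` → `snr_dominant` as D grows (they agree to a few percent by
D ≈ 50). The test suite verifies |simulated − predicted| ≤ 3 Monte-Carlo
s.e. at 5,000 trials across a 12-point grid of planted geometries
(signal ∈ {0, 1, 4} × D ∈ {5, 50} × overlap ∈ {none, high}).

**Estimation.** `estimate_manifold` uses the sample mean and the unbiased
(M−1) covariance spectrum via SVD — no shrinkage, because downstream formulas
use whole-spectrum traces that are well-conditioned; the SNR-loss path, where
gradients flow through small-batch estimates, instead uses the biased (1/P)
covariance with a ridge of 10⁻⁶ on the radii². Geometry workflows default to
all available test rows per rule (1,000 at full scale).

**Subspace alignment** computes the top-k (default 35) principal components
of all pooled training-rule rows — centroids *and* within-rule variation, the
variance actually available to shape the learned subspace — and reports the
energy fraction of held-out rows, centered on the training mean, inside that
subspace.

## 6. The simulator

`simulate` builds Gaussian ellipsoids with geometric variance spectra
r²ᵢ ∝ qⁱ, with q solved (Brent) so the participation ratio matches a target —
a smooth spectrum, as measured representations have, rather than D equal
radii padded with zeros. It emulates controlled signal, dimensionality,
overlap and bias at the *representation* level. It does not emulate:
non-Gaussian manifold shape, pixel-space correlations between rules, or the
discrete attribute structure of real rows. Tests passing on the simulator
therefore validate the theory and the scoring machinery, not any claim that
real network manifolds are Gaussian; for real representations the theory's
accuracy is an empirical question the `layerwise_report` driver is built to
answer.

## 7. Training objectives

`snr_loss` draws episodic batches of P rows from each of m rules (P ≥ 2 so
radii are estimable, m ≥ 2 so pairs exist) and returns the *mean* over the
m(m−1) ordered pairs of exp(−SNRₐ), using the closed-form SNR on within-batch
moments. The mean (rather than the sum) keeps the loss scale independent of
the episode size; ordered pairs are used because the SNR is asymmetric.
Gradients are fully analytic (the closed form needs only traces and
quadratics of the covariance — no eigendecomposition — so differentiation is
elementary) and are verified against finite differences in the tests.

Baselines: a trainable linear cross-entropy readout (chance error
34/35 ≈ 0.97 for 35 training rules) and the episodic prototypical loss
(softmax over negative squared distances to class centroids; the first
`n_support` rows per class in batch order form the prototype).

All objectives run in plain numpy through a common encoder interface
(`forward`/`backward`/`params`/`grads`); reference encoders are a linear map
and a relational MLP (shared dense per-panel features, dense relational head
over the concatenated panels). The optimizer is SGD with momentum 0.9, weight
decay 5·10⁻⁴, base learning rate 0.1, linear warmup over the first two
epochs, batch size 512, and a plateau scheduler multiplying the rate by 0.2
when the validation loss fails to improve by more than 10⁻⁴ for 5
consecutive epochs — the concrete quantification adopted for "plateaued".
Identical seeds reproduce identical loss curves, and the episode stream
depends only on the seed, not the objective, so objective comparisons are
like-for-like.

## 8. Problem sizes and limitations

The test suite and acceptance script run reduced problem sizes chosen to
keep the statistics meaningful on a single CPU: the pixel baseline uses
5 splits × 20 ordered pairs × 200 trials with pools of 250 rows per held-out
rule (split-level s.e.m. ≈ 0.003; single-split means scatter by ~±0.02);
the theory oracle uses 5,000 trials per geometry; SNR-loss mechanics use a
3-rule planted toy with a linear encoder. Full-scale settings
(15 splits × 500 trials, 10,000 training rows per rule, deep encoders) are
the same code paths with larger arguments.

Known limitations: only the dominant-moment and exact-Gaussian error
predictors are provided (no corrections for non-Gaussian manifolds); the
exact predictor costs an eigendecomposition of size ≈ 3(kₐ+k_b) and is meant
for analysis, not inner training loops (the loss uses the closed form); the
reference encoders are deliberately small — the encoder interface, not the
bundled architectures, is the extension point; and pixel-level parity with
any particular external image set is not promised, only the statistical
behavior of the protocol.
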