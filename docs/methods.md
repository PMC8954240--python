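# Methods

`cosreg` registers a pair of 2D images of the same scene acquired with two
different modalities — the motivating case is an intra-operative
photoacoustic (PA) image against a pre-operative MR slice for brain-shift
compensation — by minimizing a *joint co-sparse analysis* cost with a pair
of learned analysis operators, and compares the result against a normalized
mutual information (NMI) baseline that shares every other part of the
pipeline. Because no public PA/MR brain-shift data set with ground truth
exists, the package ships a phantom simulator that provides paired
modalities, vessel landmarks and a known deformation field, so every claim
the package makes is measurable.

## The co-sparse analysis model

The analysis (co-sparse) model assumes that for a patch `x ∈ R^n` there is
an over-complete analysis operator `Ω ∈ R^{k×n}` (`k > n`, unit Euclidean
row norms) whose response `Ωx` is sparse. Structure is encoded in the
*zeros* of the response (the co-support): the rows with zero response are
normal vectors of hyperplanes whose intersection contains the signal.

For two modalities we learn a pair `(Ω_a, Ω_b)` whose **stacked** response
to co-located patches is sparse:

    g(Ω_a x_a, Ω_b x_b) = Σ_k log(1 + ν (Ω_a x_a + Ω_b x_b)_k²)

The log-square term is a smooth surrogate of the zero norm (exact counting
as ν → ∞; default ν = 10³). Summing the two responses row by row makes the
pair encode a *common* component: at alignment the responses cancel, and
zeroing one modality's patch does not lower the surrogate. (The
sum-of-squares alternative `log(1+ν(a²+b²))` is strictly decreased by
zeroing either argument, which hands the registration cost a trivial
minimum at featureless background; we verified this failure empirically
before settling on the stacked form, which is also the construction used in
the bimodal analysis-operator literature the approach descends from.)

Two penalties keep the operators away from trivial solutions, and are
*added* to the objective (they diverge for degenerate operators, so
subtracting them would reward degeneracy):

* full rank: `h(Ω) = −(1/(n log n)) · log det((1/m) ΩᵀΩ)` with `m = k`
  (row-averaged Gram matrix); computed from Gram eigenvalues, `+∞` when
  rank deficient;
* row incoherence: `r(Ω) = −Σ_{k<l} log(1 − (Ω_k·Ω_l)²)`, `+∞` for
  parallel rows.

The learning objective over an ensemble of `N` co-located zero-mean patch
pairs is

    (1/N) Σ_i g(Ω_a x_a,i, Ω_b x_b,i) + κ [h(Ω_a)+h(Ω_b)] + μ [r(Ω_a)+r(Ω_b)]

with defaults κ = 10, μ = 0.01, k = 2n (98 rows for 7×7 patches).

## ADMM learning

The solver splits coefficients from operators (`Y_a = Ω_a X_a`,
`Y_b = Ω_b X_b`) and alternates:

1. **Coefficient block.** The joint surrogate depends on the pair only
   through the sum `c = u + v`, so its 2-D proximal map reduces to a 1-D
   prox on `c` (effective penalty ρ/2) followed by an equal split of the
   correction. The 1-D prox is solved by safeguarded Newton iterations
   bracketed in `[0, |s|]`, tolerance 1e-10.
2. **Operator block.** A few backtracking gradient steps on the penalized
   least-squares sub-problem, each followed by retraction of every row to
   unit norm (oblique-manifold projection). A monotone safeguard rejects an
   update that would raise the *true* objective (the block minimizes the
   augmented Lagrangian, which near convergence can differ by a hair).
3. **Dual ascent** on the scaled multipliers, `λ ← λ + ρ(ΩX − Y)`.

Defaults are ρ = 0.3 and at most 100 iterations: on desk-scale ensembles
(2,000 patches of 7×7) this reaches the same held-out co-sparsity as
ρ = 1.0 in roughly a third of the iterations, with the recorded objective
still monotone after the burn-in. Primal/dual residuals are normalized by
the coefficient-array size; the unit-row deviation is recorded every
iteration. Divergence (primal residual growing 10× over a 20-iteration
window) raises an error carrying the full trace.

**Initialization.** Both operators start from a single seeded Gaussian
draw with unit-normalized rows, with the *sign* of the second operator
chosen to minimize the initial data term. The additive coupling has two
symmetry manifolds that the update dynamics preserve: the antisymmetric
pair `Ω_b = −Ω_a` (stacked response = response to the modality difference)
is exact for identical or positively correlated ensembles — it makes
self-registration of an aligned pair an exact fixed point — while
anticorrelated modality pairs (PA/MR: vessels bright in one, dark in the
other) start nearer the cancelling solution on the symmetric manifold. A
fixed orientation serves one regime and fails the other; the two-candidate
initial test serves both and is deterministic.

## Registration

The transform is a cubic B-spline free-form deformation (FFD) with control
spacing 16 px; `T x = x + d(x)` maps float-frame pixels into the reference
frame, and the cost samples the float on-grid and the reference off-grid:

    C(T) = (1/N) Σ_i g(Ω_flt · patch(flt, x_i), Ω_ref · patch(ref, T x_i))

Patches are zero-mean normalized exactly as in training; the displacement
interpolated at a centre translates its whole 7×7 window (locally rigid
approximation), so off-grid sampling is a bilinear read. Centres lie on a
grid with stride = patch size (the windows tile the interior); centres
whose float patch carries no signal (patch standard deviation below the
70th percentile) are dropped for both metrics alike — they contribute only
a noise plateau and give the FFD freedom to chase noise. With the
convention above, the ground-truth field applied to the float by backward
warping is *directly* the field registration recovers, so evaluation
compares the two fields without inversion; the aligned `warped_float`
output is produced by resampling the float through the numerical inverse
of the recovered field (fixed-point inversion).

**Optimization.** First-order descent with a backtracking Armijo line
search; the descent direction is normalized so the step parameter is the
largest control-point motion in pixels (scale-free across metrics — an NMI
gradient is orders of magnitude smaller than a co-sparsity gradient).
Gradients are central finite differences on control-point displacements
(step 0.5 px); a perturbed control point only affects the centres inside
its cubic support, so each partial derivative re-evaluates a small centre
subset (and, for NMI, updates the joint histogram incrementally). The line
search makes each level's cost trace non-increasing by construction.

**Coarse-to-fine.** Levels are realized by Gaussian smoothing at native
resolution (σ = 2, 1, 0 for three levels) with the control spacing doubled
at the coarsest levels — *not* by decimation: the operators are tied to
the native pixel scale, and decimation erases the 2-px-wide vessels that
carry the cross-modality signal (a decimating pyramid failed outright on
several phantom draws). An optional ν-annealing hook (graduated
non-convexity) exists but is off by default.

**Regularization.** A discrete thin-plate bending energy on the control
lattice (mean squared second differences, weight 0.2, curvature normalized
to the finest spacing) suppresses high-curvature wiggles. Without it the
similarity cost admits minima *below* the ground-truth cost — with ~340
informative centres constraining ~650 FFD parameters, unregularized
descent overfits noise-level response cancellations.

**NMI baseline.** `register_nmi` shares the identical scaffold — same
centres, levels, optimizer, bending term — and differs only in the
similarity: negated NMI of the joint histogram (32 bins) pooled over the
patch-pixel correspondences of the same centres. Since the windows tile
the interior at stride = patch size, this is the NMI of the sampled
correspondence field rather than of a resampled full image; the standalone
`nmi_metric` implements the classical full-image definition
`(H(A)+H(B))/H(A,B)`.

## Phantom simulator

The generator emulates a desk-scale tissue slab (150 × 40 mm, curved
head-like top) with embedded tubular vessels (inner diameters 1.2/1.4 mm,
tortuous centrelines: ±7 mm wiggle, ≈5 bends across the span — near-straight
tubes make the along-vessel displacement component unobservable for *any*
similarity metric). Contrast models are analytic renderings, not physics:

* MR-like: bright tissue (0.8) + smooth texture (amplitude 0.15, σ 6 px),
  mildly dark vessels (0.35), additive Gaussian noise (σ 0.02);
* PA-like: absorption (vessels 1.0, tissue 0.008) × depth-attenuated
  fluence `exp(−0.1 · depth_mm)`, additive noise (σ 0.02);
* US-like: multiplicative gamma speckle on tissue, weak vessel contrast.

Landmarks sit on vessel centrelines (3 per vessel). Deformations are
channel-wise Gaussian noise smoothed with a periodic boundary (edge modes
inflate border variance and park the peak in a corner), de-meaned, and
rescaled so the peak magnitude equals `max_displacement_px` exactly
(default 8 px ≈ 4.8 mm; smoothness σ 20 px). Everything is reproducible
from integer seeds.

What the simulator does *not* emulate: acoustic propagation, laser fluence
heterogeneity, speckle decorrelation, out-of-plane motion, intensity
non-uniformity, or anatomy beyond vessels-in-tissue. Passing tests
demonstrate the method's mechanics and the direction of the JACSM-vs-NMI
comparison under controlled conditions; they do not certify performance on
clinical data.

## Evaluation

All metrics are reported in mm.

* **TRE** — Euclidean distance per matched landmark label. Float-frame
  landmark positions are obtained by inverting the known field (exact
  fixed-point solve, which only evaluation may use), then pushed through
  the recovered transform and compared with the reference positions.
* **RMSE** — root mean square of the displacement-*vector* residual
  between known and recovered fields over the interior (8-px border
  excluded, where no cost centres constrain the FFD). An intensity-RMSE
  secondary reading is available and labelled separately.
* **HD95** — vessel-mask boundary points are propagated through the
  ground-truth mapping into the float frame and back through the recovered
  transform; the 95th percentile (linear-interpolation convention) of each
  directed nearest-neighbour distance distribution is taken before the
  outer maximum. The classical maximum (HD) is computed alongside. Working
  with propagated points rather than re-rasterized masks makes perfect
  recovery score exactly zero.

## Problem sizes and known limitations

The shipped study conditions are 256 × 256 px at 0.6 mm spacing, 2,000
training patch pairs, k = 98 operators, 60–100 ADMM iterations and 30
optimizer iterations per registration level — a full
simulate/learn/register-both/evaluate repeat takes well under a minute on
one core, and the five-repeat experiment the acceptance script runs takes
a few minutes.

Known limitations, measured on the simulator:

* Along-vessel (tangential) displacement is only observable at bends; on
  draws where landmarks sit on locally straight segments part of the error
  is irreducible for any intensity- or patch-based metric.
* At perfect alignment the co-sparse cost's minimum is displaced by about
  one pixel by the noise floor of the responses, so registering an
  already-aligned multimodal pair introduces ≈0.2 mm TRE (NMI: ≈0.03 mm).
* Across repeated phantom draws the median TRE reduction of JACSM sits
  near 50%, with occasional wrong-basin draws (the cost admits a
  lower-than-truth minimum on some geometries); JACSM's median TRE is
  consistently at or below NMI's on the same draws.
* 2D only; no rigid/affine pre-alignment; no diffeomorphic guarantee
  (the bending penalty discourages but does not forbid folding).
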