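# Methods

## Shape representation and conventions

A shape is an ordered list of n landmarks (x, y) in image coordinates
(origin top-left, x rightward, y downward, 0-based, subpixel), stored
as the interleaved vector (x₁, y₁, …, xₙ, yₙ).  Shapes carry a block
structure — V vertebrae × L landmarks — with the vertebra contour
marked counter-clockwise (in the y-down frame) from the upper-anterior
corner, so the four corners sit at indices 0, L/4, L/2, 3L/4.  The
classic illustration uses 16 points with corners at 1, 5, 9, 13; the
experiments behind the default L = 20 never spell out the layout, so
the equal-points-per-edge scheme is generalised to any L divisible by
4.  The anterior side is the smaller-x side, as on a standard lateral
cervical radiograph; mirrored images should be flipped before
annotation.

## Point distribution model

Training shapes are brought into a common frame by generalized
Procrustes analysis.  The pairwise alignment minimises
Σ w_k ‖T(p_k) − q_k‖² over similarity transforms T in closed form (the
complex-number least-squares solution); weights are uniform by default
— the classic formulation says "weighted" but never defines the
weights, so a per-landmark weight vector is accepted and defaults to
1.  The group loop aligns everything to the first shape, then repeats
{mean → re-anchor the mean's pose to the first shape → re-align all
shapes to the mean} until the RMS mean displacement, normalised by the
mean's RMS size, falls below 1e-6 (max 100 iterations).  Because a
similarity transform commutes with averaging, the final anchoring is
applied jointly to the mean and the aligned set: the returned mean is
simultaneously the exact arithmetic average of the aligned shapes and
exactly posed like shape 1.

PCA on the aligned shape vectors retains the smallest t modes whose
eigenvalues cover `variance_fraction` (default 0.98) of the total
variance; eigenvector signs are fixed (first nonzero component
positive) for reproducibility.  Mode weights are clamped to
±3√λ_i.  The source text renders the constraint as ±3λ_i, but the
standard ASM constraint is ±3 standard deviations and the rendering
almost certainly lost a square root; both readings are available
(`bound="sqrt"` default, `"raw"` optional).  Clamping is applied on
every model fit during search (standard practice; whether the original
procedure clamps per-iteration or only tests acceptability is not
stated).

Two model kinds exist.  The *vertebra* model pools every vertebra
instance of every training image into one single-vertebra PDM and lets
each vertebra evolve independently at search time; the *column* model
treats the whole spine as one shape, coupling the vertebrae.  On the
synthetic phantoms both work; the vertebra model is the default.

## Grey-level profile model

At each landmark the contour direction is the chord through its two
neighbours (wrap-around within the vertebra block) and the normal
points away from the block centroid.  A profile samples k_p + 1 grey
values by bilinear interpolation (edge-clamped) at half-integer
multiples of the spacing symmetric about the landmark, takes k_p first
differences, and normalises.  Defaults: k_p = 7 points spaced 5% of
the vertebra size, the size being the distance between the vertebra's
upper and lower anterior corner landmarks — the formulation only says
the spacing is proportional to vertebra size/area, and the corner
distance is precisely the quantity the initializer provides.  The
default normaliser divides by the sum of the sampled grey levels,
following the source wording; the more common ASM normaliser (sum of
absolute differences) and no normalisation are selectable
(`profile_norm`).  Note the grey-sum normaliser makes profiles
sensitive to additive intensity offsets even though raw gradients are
not.

Per landmark, the training profiles give a mean ḡ and covariance S_g;
the Mahalanobis score uses (S_g + εI)⁻¹ with
ε = 1e-6 · trace(S_g)/k_p (ε = 1e-6 when the trace vanishes), so
degenerate training sets remain usable.

## Semiautomatic initialization

The two anchor clicks define the search window (bounding box + 20 px
margin) and the geometry prior: with N vertebrae and anchor distance
d, the height/gap model d ≈ Nα + (N−1)β with the empirical α = 4β
gives α = 4d/(5N−1), which satisfies both identities exactly.

Candidate generation uses scikit-image: Canny (σ = 1.5, hysteresis
thresholds at the 70th/90th gradient-magnitude quantiles) and Harris
(k = 0.04, σ = 2, non-max suppression radius 3 px, responses ≥ 1% of
the maximum).  None of these values is prescribed by the original
formulation; all are exposed as configuration.  Harris runs on the
grey window; candidates are associated with edges afterwards.

Two filters prune the Harris set, both tracing the 8-connected Canny
edge from the pixel nearest the candidate (snap radius 3 px, geodesic
distances by Dijkstra with unit/√2 steps):

* *Isolation filter* — a candidate survives only if the traced edge
  reaches a geodesic distance of ≥ 0.9 × the estimated vertebra height
  α (the 0.9 absorbs the pixel or two that hysteresis shaves off edge
  ends).  Isolated points and short fragments are eliminated.
* *Angle filter* — the two contour neighbours are the most separated
  pair of edge pixels in a ±1.5 px band around geodesic distance
  0.25·α on the traced contour; the candidate survives if the angle it
  subtends lies in [10°, 160°].  Straight runs (~180°) and needle
  artefacts (<10°) drop out; candidates with fewer than two traceable
  neighbours count as isolated.  The neighbour distance matters
  (too close → angles too sharp, too far → too many false accepts) and
  was never given numerically; 0.25·α is this package's choice.

The 2N corners are then the shortest alternating path from l₁ to l₂N:
a depth-first recursion extends an upper corner with candidates at
distance in (α ± δ_α) — which become lower corners — and a lower
corner with candidates at distance in (β ± δ_β), finishing by
appending the user's l₂N once 2N−1 points are placed; among all stored
sequences the minimal total path length wins (ties by lexicographic
candidate index).  δ_α = 0.4α and δ_β = 0.75β by default ("fixed
experimentally" in the source, without values).  The stated
progression rule — each new point having a "lower y-coordinate" — is
ambiguous in image coordinates, so the default requires the projection
onto the l₁→l₂N axis to increase strictly, which generalises to tilted
spines; `literal_y` restores the literal reading (strictly increasing
image y).  Complexity guards: at most the 8 nearest feasible
candidates per extension and at most 10,000 stored sequences; the test
suite verifies global optimality against exhaustive enumeration on
instances small enough to enumerate.

## Search loop

The mean shape is placed per vertebra by the exact two-point
similarity fit of its anterior corner landmarks onto the detected
pair (column model: one joint least-squares fit to all 2N corners).
Each iteration then (1) moves every landmark to the candidate offset
in {−5…+5} × step (step = profile spacing) minimising the Mahalanobis
distance, ties preferring the smallest magnitude then the negative
offset, landmarks whose candidates all fall outside the image staying
put; and (2) regularises the moved cloud by alternating the similarity
pose fit with the clamped b-projection until both stabilise (tol 1e-6,
max 20 inner iterations).  Consequently every iterate is exactly a
posed model instance.  `pose_update=False` freezes the pose at its
initial placement and lets only b evolve.

Stopping: a landmark counts as moved when displaced > 0.5 px between
consecutive regularised shapes (subpixel jitter must not defeat the
counter); the search stops when the moved count reaches zero, or drops
to ≤ 10% of the previous iteration's count, or at `max_iter = 250` —
typical converged runs on the phantoms take well under 50 iterations,
and the cap matches the 50–250 range the method is reported to need.

## Synthetic phantoms

The generator emulates the geometry the initializer assumes: N = 5
bright convex quadrilaterals (grey 180) on a dark background (grey
60), height α = 40 px, gap β = 10 px (α = 4β by construction), width
1.5α, stacked vertically with a per-image global tilt (sd 2°) and
position jitter (sd 1 px).  Each body is deformed by exactly two
generative modes — anisotropic scaling (sd 0.04) and shear (sd 0.03) —
so PCA recovery is checkable; rendering is 4× supersampled
(anti-aliased), blurred (Gaussian σ = 1 px) and corrupted with
additive Gaussian noise (σ = 6 grey levels).  Ground-truth landmarks
(L = 20 via the standard marking), the 2N anterior corners and the two
anchors are emitted exactly, and all randomness flows from a single
seed.  An optional corner-rounding radius softens rendered corners
without touching the truth.

What the phantoms do *not* emulate: overlapping anatomy (posterior
elements, soft tissue, airway shadows), spatially varying exposure,
scanner blur kernels, inter-subject variability beyond two modes, or
pathological shapes.  Passing the end-to-end checks therefore
demonstrates the machinery is correct and self-consistent under the
method's stated assumptions — not clinical-grade accuracy, which can
only be established on real radiographs.

## Evaluation

Point-to-point error is the Euclidean distance between corresponding
landmarks; point-to-line error is the distance to the closed
piecewise-linear true contour of the landmark's vertebra, which
forgives sliding along the boundary and is never larger.  The success
rate is the percentage of vertebrae whose mean point-to-line error
falls under a threshold, 2 px by default on the phantoms.  The
original study's success-rate threshold on clinical images is not
stated numerically, so rates computed here are not comparable to the
published clinical tables; the reproducibility script reports phantom
quantities only.

## Problem sizes in the reproducibility script

`scripts/acceptance.py` trains on 75 phantoms and evaluates on 20
held-out phantoms (the sample-size study behind the method settled on
75 training images), plus 5 noise-free phantoms with exact corner
initialization; oracle comparisons use 10–100 random instances and 50
corner-search instances small enough for exhaustive enumeration.

## Known limitations

* Single-resolution profiles; no image pyramid.
* The Harris corners are pixel-accurate (no subpixel refinement), so
  detected initializations carry ~1–2 px corner error; the profile
  search absorbs it.
* The grey-sum profile normaliser is unusual; on images with a
  near-zero local grey sum the profile degenerates to zero.
* The recursive corner search is exponential in the worst case and
  relies on its branching/sequence caps in pathological candidate
  clouds.
* 2-D only; no DICOM, no appearance (texture) model.
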