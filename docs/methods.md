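# Methods

`kidseg` segments a kidney from a 2D dynamic contrast-enhanced MRI (DCE-MRI)
slice by evolving a level-set contour under a variational energy that couples
three sources of information: contour smoothness, fuzzy c-means (FCM)
intensity clustering, and a statistical shape prior whose alignment to the
image is refined simultaneously by gradient descent on affine parameters.
This note records the model, its discretization, the defaults, and what the
synthetic experiments do and do not establish.

## The energy

The contour is the zero level of a scalar field φ on the image grid (φ > 0
kidney, φ < 0 background). With V_ε and δ_ε the smeared Heaviside and Dirac
kernels of half-width ε (cosine form: V_ε is 0/1 outside the band and
`1/2 + φ/2ε + sin(πφ/ε)/2π` inside; δ_ε = V_ε′), the total energy is

    E(φ, A, T) = λ1 L(φ) + λ2 E_FCM(φ, A, T) + λ3 E_REG(φ, A, T)

* `L = Σ δ_ε(φ) |∇φ|` — contour length (smoothness);
* `E_FCM = Σ V_ε(φ) m_B P_B(X̂) + Σ (1−V_ε(φ)) m_K P_K(X̂)` — penalizes
  background-membership pixels inside the contour and kidney-membership
  pixels outside it, each weighted by the *warped* prior probability;
* `E_REG = Σ [V_ε(φ) − V_ε(φ_PK(X̂))]²` — squared mismatch between the
  contour's Heaviside and that of the prior's level set.

Here `X̂ = A(X − c) + c + T` maps image coordinates into the prior's
reference frame, with `A = R(θ) H(h_x, h_y) S(s_x, s_y)` (rotation · shear ·
scale, applied about the image center c — the rotation center is not part of
the model statement, and an origin-centered rotation would make the angle
step size depend on the organ's distance from the corner) and translation T.

Descent in φ gives the contour update

    ∂φ/∂t = λ1 δ_ε div(∇φ/|∇φ|) + λ2 δ_ε [m_K P_K(X̂) − m_B P_B(X̂)]
            − 2 λ3 δ_ε [V_ε(φ) − V_ε(φ_PK(X̂))],
    φ ← φ + γ1 ∂φ/∂t.

Descent in each affine parameter uses the discretized pixel-sum gradients
(the integrand vectors `λ2 V m_B ∇P_B + λ2 (1−V) m_K ∇P_K − 2λ3 δ_ε(φ_PK)
[V − V_ε(φ_PK)] ∇φ_PK`, projected on the closed-form coordinate Jacobians
∂X̂/∂p) with per-group step sizes γ2..γ5.

## Fuzzy clustering

Two clusters (kidney/background), fuzzifier fixed at 2. Memberships are
inverse-square distances to the centroids, `m_L = d_L^{-2} / (d_K^{-2} +
d_B^{-2})`, with exact-hit pixels assigned crisp membership (0.5/0.5 when
both centroids coincide). Centroids are region-weighted fuzzy means,
`C_L = Σ R_L(φ) I m_L² / Σ R_L(φ) m_L²`, with `R_K = V_ε(φ)` and
`R_B = 1 − V_ε(φ)`.

Initialization matters more than it may appear. Centroids start as the mean
intensity inside/outside the initial contour; for a border or random contour
these two means are nearly equal, and memberships computed from near-equal
centroids misclassify the organ for the first several iterations — long
enough for the evolution to push pixels across the smearing band, where the
vanishing Dirac factor makes them unrecoverable. `fcm.init_state` therefore
runs plain intensity-only FCM alternations (no spatial weighting) to
convergence before the contour moves, and labels the brighter cluster as
kidney (the organ is contrast-enhanced). Within each loop iteration the
order is: evolve φ, update centroids, update memberships, update affine
parameters.

## Statistical shape prior

From N co-aligned binary expert masks (pre-aligned; co-registration of the
training cohort is out of scope), each reference-grid pixel gets a Bayesian
label-probability estimate. With per-pixel kidney count N_K, additive weight
β > 0, ℓ = 2 labels and O the number of labels observed at the pixel:

* observed label: `P_L = [(N_L + β)/(N + βO)] · [N/(N + ℓ − O)]`
* unobserved label (O = 1): `P_L = [1/(ℓ − O)] · [1 − N/(N + ℓ − O)]`

so a pixel marked kidney in all N masks gets P_K = N/(N+1), not 1 — a test
kidney extending slightly beyond every training kidney is penalized, not
vetoed. P_K + P_B = 1 holds exactly and both probabilities are strictly
inside (0, 1).

The prior's level-set field φ_PK is defined as the signed Euclidean distance
to the 0.5 isocontour of P_K (positive inside). The model statement never
defines φ_PK; a distance function makes |∇φ_PK| ≈ 1 so the shape-alignment
force has a well-scaled direction field everywhere in its band.

## Discretization and numerics

* Spatial derivatives of φ: central differences with replicate-edge padding;
  |∇φ| regularized as `sqrt(|∇φ|² + 1e−10)` so flat regions return zero
  curvature.
* **Initialization of φ.** The signed distance of the requested geometry
  (border band / disk / smooth seeded random field) is squashed by tanh into
  the open band (−ε/2, ε/2), keeping unit slope at the contour. This is
  essential, not cosmetic: the Dirac factor gates the update, so any pixel
  outside the band is frozen. A raw signed-distance initialization freezes
  the whole image interior and the contour can never leave its initial
  band; a field parked near ±ε evolves at δ_ε ≈ 0 and wrong early
  commitments become permanent. Starting mid-band realizes the
  initialization-independent behavior the smeared kernels are meant to
  provide.
* No signed-distance reinitialization during evolution; active-band pixels
  are clamped to ±5ε per step (pixels outside the band are untouched, so the
  update is exactly the identity wherever |φ| > ε).
* **Prior warping.** Prior fields are sampled at X̂ by bilinear
  interpolation. Their gradients are the exact spatial derivatives of the
  bilinear interpolant (with the symmetric two-cell derivative exactly on
  grid nodes), so the affine-parameter gradients are the exact derivatives
  of the discretely evaluated energy; interpolating a pre-computed
  central-difference field instead leaves a systematic ~1% cell-phase error
  against finite differences of the energy. Coordinates outside the prior
  grid receive the off-organ limits: P_B = max in-grid P_B (P_K its
  complement, gradient zero) and φ_PK continues as nearest-edge value minus
  distance to the grid, with the matching analytic gradient, so the contour
  is never attracted off-image.
* Convergence: relative change of E over a 10-iteration window below
  `energy_tol` (default 1e−4), or `max_iters`. Non-convergence is reported
  in the result, not raised.
* All randomness flows from explicit integer seeds; identical inputs and
  seeds give bit-identical results.

## Parameters

Defaults are the operating point established for 256×256 clinical DCE-MRI:

| parameter | value | role |
|---|---|---|
| λ1, λ2, λ3 | 6, 6, 0.1 | length / data / shape-alignment weights |
| ε | 1.5 px | smearing half-width |
| β | 1 | Bayesian prior additive weight |
| γ1 | 0.8 | contour step |
| γ2, γ3, γ4, γ5 | 1e−14, 1e−10, 1e−10, 1e−9 | scale/shear/translation/angle steps on raw pixel-sum gradients |

The γ2..γ5 defaults deserve a caveat: raw pixel-sum gradients on a 256×256
image are of order 1e2–1e5, so these steps move the affine parameters by
≲1e−5 per iteration — over a full run the prior is re-aligned by at most
~1e−3 px. The registration term shapes the energy, but parameter recovery at
this operating point is effectively infinitesimal. `SegmentationConfig`
therefore exposes `normalize_gradients` (pixel means instead of sums, making
usable steps independent of image area), and `for_phantom()` is the preset
used by all synthetic experiments: γ1 = 0.3 with 4 contour steps per
registration update (the explicit curvature step λ1·γ1·δ_ε must stay below
the stability limit on high-contrast two-level images, where λ1 = 6 with
γ1 = 0.8 catapults band pixels across ε and freezes speckles), affine steps
γ2 = γ3 = 1e−5, γ4 = 10, γ5 = 1e−4 on normalized gradients, and a 6-iteration
registration warm-up — the Eq.-gradient integrands are meaningless while the
smeared Heaviside of the young contour is still far from binary, because the
(1−V) residual then pushes the prior off the organ regardless of alignment.

## Synthetic phantoms

The clinical cohort behind the reference results is private, so every stage
is exercised on phantoms: a bean-shaped organ (outer ellipse minus an offset
notch ellipse, semi-axes 42×26 px on a 256×256 grid, ≈4.5% of the image
area), kidney/background base intensities 150/50 with a multiplicative
contrast-phase factor, additive Gaussian noise (σ = 10 default), per-mask
±10% semi-axis jitter for cohort variability, and affine misalignments
sampled from rotation ±2°, shear coefficients in [0, 0.12] (the shearing
range is stated without units in the source experiment description; a shear
*coefficient* of 12 is geometrically absurd, so the dimensionless reading is
used) and translations up to ±5 px.

What the phantoms do **not** emulate: intensity inhomogeneity, partial
voluming, neighboring bright organs (spleen, liver), perfusion-phase
*texture* change, breathing motion. Passing synthetic tests therefore
establishes the correctness of the machinery — kernels, clustering, prior,
gradients, energy descent, initialization independence — not clinical-grade
accuracy.

## Known limitations

* **Affine parameter recovery is locally limited.** The shape-alignment
  gradient only acts inside the Dirac band (±ε) of the warped prior contour,
  plus the prior's probability transition band (set by cohort variability;
  ~2.6 px in the short-axis direction for ±10% jitter). Misalignments beyond
  that radius are not recovered: once the contour has adapted to the
  misplaced prior (rim pixels suppressed where the warped P_K is low), the
  data term's registration gradient points *away* from the true alignment —
  probing the joint energy along translation at a converged state shows its
  minimum at the adapted alignment, and gradient flow started at the true
  parameters drifts off. Misalignment robustness of the *segmentation*
  (small Dice degradation) comes from the energy's tolerance — the smeared
  kernels and the intensity term dominating within the prior's soft band —
  not from large prior motion. The phantom preset keeps affine steps gentle
  for exactly this reason: stronger steps let the anti-restoring drift
  inflate the energy without improving recovery.
* Two clusters only; no spatial regularization inside FCM.
* 2D single-slice; no temporal propagation across the perfusion series.
* The kidney is assumed brighter than the local background (post-contrast
  regime); pre-contrast slices with inverted contrast would need the cluster
  labelling convention flipped.

## Metrics

Dice `2|A∩B|/(|A|+|B|)` and IoU `|A∩B|/|A∪B|` (both 1 when both masks are
empty), and 95HD: the 95th percentile of the *pooled* directed
boundary-to-boundary Euclidean distances (boundaries are 4-connectivity edge
pixels; both directed distance sets are pooled before the percentile, one of
the two common conventions, chosen and fixed here). Distances are in pixels;
DICOM pixel spacing is carried as metadata but not applied to 95HD.

## Experiment sizes

The acceptance experiments use 20 seeded phantoms per condition (aligned /
misaligned), a 30-mask training cohort, 256×256 grids, and a 200-iteration
cap with the windowed energy-change stop — sizes at which a full
`scripts/acceptance.py` run completes in minutes on one CPU while the
medians are stable to well within the acceptance margins.
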