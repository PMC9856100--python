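# kidseg

Joint kidney segmentation and shape-prior registration for 2D dynamic
contrast-enhanced MRI (DCE-MRI).

Assessing renal function from DCE-MRI — a time series of scans acquired while
a contrast agent perfuses the kidney — requires segmenting the kidney from
every time-point image first. Shape priors help enormously here (kidneys have
a characteristic bean shape; intensities alone are ambiguous during contrast
transit), but a prior is only useful if it is *aligned* with the image, and
alignment errors propagate directly into segmentation errors. `kidseg`
implements a variational approach that performs both tasks in one loop: a
level-set contour evolves under an energy whose alignment parameters are
updated simultaneously by gradient descent.

## The model

The contour is the zero level of a field φ (φ > 0 kidney). With V_ε and δ_ε
the smeared Heaviside/Dirac kernels of half-width ε, the energy is

    E(φ, A, T) = λ1 Σ δ_ε(φ)|∇φ|
               + λ2 [ Σ V_ε(φ) m_B P_B(X̂) + Σ (1−V_ε(φ)) m_K P_K(X̂) ]
               + λ3 Σ [ V_ε(φ) − V_ε(φ_PK(X̂)) ]²

where m_K, m_B are fuzzy c-means memberships of each pixel to the
kidney/background intensity clusters, P_K, P_B are per-pixel label
probabilities of a statistical shape prior built from co-aligned expert
masks by Bayesian estimation (a pixel marked kidney in all N training masks
gets P_K = N/(N+1), never 1), φ_PK is the prior's signed-distance level-set
field, and X̂ = A(X − c) + c + T is the affine map (rotation·shear·scale
about the image center, plus translation) from image coordinates into the
prior's frame. Each iteration evolves φ one step, updates the cluster
centroids and memberships, and takes one gradient-descent step on the seven
affine parameters. Output quality is scored with Dice, IoU and the 95th
percentile of boundary Hausdorff distance (95HD).

The clinical datasets this method targets are not publicly deposited, so the
package ships a first-class phantom module (`kidseg.phantoms`) that generates
bean-shaped kidney phantoms, training cohorts for the prior, perfusion-phase
contrast variation, noise, and controlled affine misalignments — every stage
of the pipeline is testable end to end without patient data.

## Worked example

The `kidseg` command chains the whole pipeline on phantoms:

```sh
kidseg simulate --out-dir demo --n-images 1 --n-train 30 --seed 7
kidseg build-prior --masks-dir demo/train --out demo/prior.kprior
kidseg segment --image demo/images/img_000.png --prior demo/prior.kprior \
    --out-mask demo/pred/mask_000.png --out-trace demo/trace.csv \
    --phantom-preset --seed 7
kidseg evaluate --pred-dir demo/pred --truth-dir demo/truth --out demo/metrics.csv
```

which prints

```
wrote 1 phantom image(s) and 30 training masks to demo
prior built from 30 masks -> demo/prior.kprior
converged=False iterations=200 theta_rad=-1.66498e-07 sx=1 sy=0.999997 hx=2.54581e-07 hy=2.37932e-07 tx_px=0.0300353 ty_px=6.88552e-07
DC: 0.9987 +/- 0.0000
IoU: 0.9973 +/- 0.0000
95HD: 0.0000 +/- 0.0000
```

Reading the output: the segmentation of this aligned, noisy (σ = 10) phantom
overlaps the ground truth almost perfectly (Dice 0.9987; 95HD of 0 px means
95% of boundary pixels coincide exactly), and the recovered affine
parameters stay at the identity, as they should for an aligned image. The
energy/parameter trace per iteration lands in `demo/trace.csv`.

The same steps work on clinical data: `segment` reads single-frame DICOM
(rescale slope/intercept applied) as well as PNG/TIFF, and without
`--phantom-preset` it uses the clinical operating point
(λ1, λ2, λ3, ε, β, γ1..γ5) = (6, 6, 0.1, 1.5, 1, 0.8, 1e−14, 1e−10, 1e−10,
1e−9), overridable via `--config` (flat YAML).

From Python:

```python
from kidseg import phantoms, shape_prior, metrics
from kidseg.segmentation import SegmentationConfig, segment

spec = phantoms.PhantomSpec(seed=42)
prior = shape_prior.build_prior(phantoms.generate_training_cohort(30, spec))
truth = phantoms.generate_kidney_mask(spec)
image = phantoms.generate_dce_image(truth, spec)
result = segment(image, prior, SegmentationConfig.for_phantom(seed=42))
print(metrics.dice(result.mask, truth))
```

See `docs/methods.md` for the model details, discretization choices, the
phantom preset, and known limitations (in particular the limited capture
radius of the affine recovery).

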