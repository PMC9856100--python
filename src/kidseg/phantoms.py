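"""Synthetic kidney phantoms: bean-shaped masks, contrast-phase images,
training cohorts and controlled affine misalignments.

The clinical DCE-MRI data the method targets is not publicly available, so
every stage of the pipeline is exercised on phantoms instead: a bright
bean-shaped organ (outer ellipse minus an offset notch ellipse) on a darker
background, a multiplicative contrast-phase factor emulating perfusion-phase
intensity changes, additive Gaussian noise, and affine misalignments in the
ranges used to stress the registration (rotations within a couple of degrees,
shear coefficients up to 0.12, translations of a few pixels).

All generators are reproducible from the seed recorded in the spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .affine import AffineParams, transform_coords


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one phantom; all lengths in pixels."""

    shape: tuple[int, int] = (256, 256)
    outer_axes: tuple[float, float] = (42.0, 26.0)  # (a, b) semi-axes, x and y
    notch_axes: tuple[float, float] = (18.0, 12.0)
    notch_offset: tuple[float, float] = (-42.0, 0.0)  # notch center rel. image center
    kidney_intensity: float = 150.0
    background_intensity: float = 50.0
    phase_multiplier: float = 1.0
    noise_sigma: float = 10.0
    axis_jitter: float = 0.1  # relative semi-axis perturbation for variability
    seed: int = 0

    def __post_init__(self) -> None:
        if min(*self.outer_axes, *self.notch_axes) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.kidney_intensity == self.background_intensity:
            raise ValueError("kidney and background intensities must differ")
        if self.axis_jitter < 0 or self.noise_sigma < 0:
            raise ValueError("jitter and noise sigma must be nonnegative")


def _ellipse(xx, yy, cx, cy, a, b):
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def generate_kidney_mask(spec: PhantomSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Bean-shaped binary mask: outer ellipse minus the offset notch ellipse.

    Semi-axes are perturbed by seeded uniform factors in
    ``1 +/- axis_jitter``; with ``axis_jitter=0`` the mask is deterministic and
    symmetric about the horizontal axis through the image center.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    a, b = spec.outer_axes
    na, nb = spec.notch_axes
    if spec.axis_jitter > 0:
        f = rng.uniform(1.0 - spec.axis_jitter, 1.0 + spec.axis_jitter, size=4)
        a, b, na, nb = a * f[0], b * f[1], na * f[2], nb * f[3]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    max_jitter = 1.0 + spec.axis_jitter
    if (
        spec.outer_axes[0] * max_jitter >= min(cx, w - 1 - cx)
        or spec.outer_axes[1] * max_jitter >= min(cy, h - 1 - cy)
    ):
        raise ValueError("phantom geometry exceeds the grid")
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    outer = _ellipse(xx, yy, cx, cy, a, b)
    notch = _ellipse(xx, yy, cx + spec.notch_offset[0], cy + spec.notch_offset[1], na, nb)
    return outer & ~notch


def generate_dce_image(mask: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Two-level image plus seeded Gaussian noise, clipped to [0, 255].

    Kidney pixels take ``kidney_intensity * phase_multiplier`` so a sequence of
    specs with varying multipliers emulates perfusion-phase contrast change.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != spec.shape:
        raise ValueError("mask shape disagrees with the spec grid")
    img = np.where(
        mask, spec.kidney_intensity * spec.phase_multiplier, spec.background_intensity
    ).astype(float)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng((spec.seed, 17))
        img = img + rng.normal(0.0, spec.noise_sigma, size=mask.shape)
    return np.clip(img, 0.0, 255.0)


def generate_training_cohort(n: int, spec: PhantomSpec) -> list[np.ndarray]:
    """``n`` co-aligned (centered) masks with independent seeded perturbations."""
    if n < 2:
        raise ValueError("a training cohort needs at least 2 masks")
    return [
        generate_kidney_mask(spec, rng=np.random.default_rng((spec.seed, 1000 + i)))
        for i in range(n)
    ]


@dataclass(frozen=True)
class AffineRanges:
    """Half-widths / upper bounds of the misalignment sampling ranges."""

    rotation_deg: float = 2.0
    shear: float = 0.12
    translation: float = 5.0
    scale: float = 0.0

    def __post_init__(self) -> None:
        if min(self.rotation_deg, self.shear, self.translation, self.scale) < 0:
            raise ValueError("ranges must be nonnegative")


def apply_affine(
    field: np.ndarray,
    p: AffineParams,
    center: tuple[float, float] | None = None,
    order: int = 1,
) -> np.ndarray:
    """Resample ``field`` so output(X) = field(X_hat) with X_hat = A(X-c)+c+T.

    A phantom transformed this way is brought back into the prior's reference
    frame by exactly the parameters ``p``; use order=1 (bilinear) for images
    and order=0 (nearest) for masks.
    """
    h, w = field.shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    x_hat, y_hat = transform_coords(xx, yy, p, center)
    out = map_coordinates(
        np.asarray(field, float),
        np.stack([y_hat.ravel(), x_hat.ravel()]),
        order=order,
        mode="nearest",
    ).reshape(field.shape)
    return out


def sample_affine(ranges: AffineRanges, rng: np.random.Generator) -> AffineParams:
    return AffineParams(
        theta=np.deg2rad(rng.uniform(-ranges.rotation_deg, ranges.rotation_deg)),
        sx=1.0 + rng.uniform(-ranges.scale, ranges.scale),
        sy=1.0 + rng.uniform(-ranges.scale, ranges.scale),
        hx=rng.uniform(0.0, ranges.shear),
        hy=rng.uniform(0.0, ranges.shear),
        tx=rng.uniform(-ranges.translation, ranges.translation),
        ty=rng.uniform(-ranges.translation, ranges.translation),
    )


def perturb_affine(
    image: np.ndarray,
    mask: np.ndarray,
    ranges: AffineRanges,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, AffineParams]:
    """Misalign an image/mask pair by a random affine map in the given ranges.

    Returns the transformed image (bilinear), transformed mask (nearest) and
    the ground-truth parameters that map the transformed frame back onto the
    original; re-applying :func:`apply_affine` with them reproduces the output
    bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    p = sample_affine(ranges, rng)
    new_image = apply_affine(np.asarray(image, float), p, order=1)
    new_mask = apply_affine(np.asarray(mask, float), p, order=0) > 0.5
    return new_image, new_mask, p
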