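"""2D affine alignment of the shape prior to the image.

Image coordinates X = (x, y) (x = column, y = row, 0-based, pixel-centered)
are mapped into the prior's reference frame by

    X_hat = A (X - c) + c + T,      A = R(theta) H(hx, hy) S(sx, sy)

i.e. rotation * shear * scale, applied about a configurable center c (the
image center by default) followed by a translation T. The seven scalar
parameters are refined by explicit gradient descent on the joint energy; the
analytic per-parameter gradients are discretized pixel sums over the image
domain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .level_set import LevelSetField, smeared_dirac, smeared_heaviside, EnergyWeights

_MIN_SCALE = 1e-3


@dataclass(frozen=True)
class AffineParams:
    """Rotation angle (radians), scales, shears and translations (pixels)."""

    theta: float = 0.0
    sx: float = 1.0
    sy: float = 1.0
    hx: float = 0.0
    hy: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("scale factors must be positive")

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls()

    def as_dict(self) -> dict[str, float]:
        return {
            "theta": self.theta,
            "sx": self.sx,
            "sy": self.sy,
            "hx": self.hx,
            "hy": self.hy,
            "tx": self.tx,
            "ty": self.ty,
        }


@dataclass(frozen=True)
class StepSizes:
    """Positive gradient-descent step sizes.

    gamma1 drives the level-set update; gamma2..gamma5 drive the scale, shear,
    translation and rotation parameter groups respectively.
    """

    gamma1: float = 0.8
    gamma2: float = 1e-14
    gamma3: float = 1e-10
    gamma4: float = 1e-10
    gamma5: float = 1e-9

    def __post_init__(self) -> None:
        if min(self.gamma1, self.gamma2, self.gamma3, self.gamma4, self.gamma5) <= 0:
            raise ValueError("all step sizes must be positive")


PARAM_NAMES = ("sx", "sy", "hx", "hy", "tx", "ty", "theta")


def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _shear(hx: float, hy: float) -> np.ndarray:
    return np.array([[1.0, hx], [hy, 1.0]])


def _scale(sx: float, sy: float) -> np.ndarray:
    return np.array([[sx, 0.0], [0.0, sy]])


def compose_matrix(p: AffineParams) -> tuple[np.ndarray, np.ndarray]:
    """Linear part A = R H S (in that order) and translation vector T."""
    a = _rotation(p.theta) @ _shear(p.hx, p.hy) @ _scale(p.sx, p.sy)
    t = np.array([p.tx, p.ty])
    return a, t


def transform_coords(
    x: np.ndarray,
    y: np.ndarray,
    p: AffineParams,
    center: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Map (x, y) to (x_hat, y_hat); ``center`` is (cx, cy) in (col, row)."""
    a, t = compose_matrix(p)
    cx, cy = center
    dx = np.asarray(x, float) - cx
    dy = np.asarray(y, float) - cy
    x_hat = a[0, 0] * dx + a[0, 1] * dy + cx + t[0]
    y_hat = a[1, 0] * dx + a[1, 1] * dy + cy + t[1]
    return x_hat, y_hat


def _matrix_derivatives(p: AffineParams) -> dict[str, np.ndarray]:
    """dA/dp for the five linear parameters, plus markers for translations."""
    r = _rotation(p.theta)
    h = _shear(p.hx, p.hy)
    s = _scale(p.sx, p.sy)
    c, sn = np.cos(p.theta), np.sin(p.theta)
    dr = np.array([[-sn, -c], [c, -sn]])
    return {
        "sx": r @ h @ np.array([[1.0, 0.0], [0.0, 0.0]]),
        "sy": r @ h @ np.array([[0.0, 0.0], [0.0, 1.0]]),
        "hx": r @ np.array([[0.0, 1.0], [0.0, 0.0]]) @ s,
        "hy": r @ np.array([[0.0, 0.0], [1.0, 0.0]]) @ s,
        "theta": dr @ h @ s,
    }


def param_jacobians(
    x: np.ndarray,
    y: np.ndarray,
    p: AffineParams,
    center: tuple[float, float],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Closed-form dX_hat/dp for each of the 7 parameters at (x, y).

    Returns a mapping parameter name -> (d x_hat / dp, d y_hat / dp); for the
    translations these are the constant unit vectors.
    """
    cx, cy = center
    dx = np.asarray(x, float) - cx
    dy = np.asarray(y, float) - cy
    derivs = _matrix_derivatives(p)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, da in derivs.items():
        out[name] = (da[0, 0] * dx + da[0, 1] * dy, da[1, 0] * dx + da[1, 1] * dy)
    one = np.ones_like(dx)
    zero = np.zeros_like(dx)
    out["tx"] = (one, zero)
    out["ty"] = (zero, one)
    return out


def registration_gradients(
    phi: LevelSetField,
    m_k: np.ndarray,
    m_b: np.ndarray,
    warped,
    p: AffineParams,
    weights: EnergyWeights,
    center: tuple[float, float],
    normalize: bool = False,
) -> dict[str, float]:
    """Discretized energy gradients w.r.t. the 7 affine parameters.

    ``warped`` carries the prior fields and their gradients already sampled at
    X_hat on the image grid (see :func:`kidseg.segmentation.warp_prior`).
    Each gradient is the pixel sum of the data-term and shape-term integrands
    projected on the parameter's coordinate Jacobian. With ``normalize`` the
    sums become means over the pixel count, which makes usable step sizes
    independent of image area (intended for phantom-scale experiments).
    """
    if m_k.shape != phi.shape or warped.p_k.shape != phi.shape:
        raise ValueError("field shape mismatch")
    v_phi = phi.heaviside()
    v_prior = smeared_heaviside(warped.phi_pk, phi.eps)
    delta_prior = smeared_dirac(warped.phi_pk, phi.eps)

    w_data_b = weights.lambda2 * v_phi * m_b
    w_data_k = weights.lambda2 * (1.0 - v_phi) * m_k
    w_shape = 2.0 * weights.lambda3 * delta_prior * (v_phi - v_prior)

    # Shared force field F = sum of integrand vectors; per-parameter gradient
    # is then <F, dX_hat/dp>.
    fx = (
        w_data_b * warped.grad_p_b[0]
        + w_data_k * warped.grad_p_k[0]
        - w_shape * warped.grad_phi_pk[0]
    )
    fy = (
        w_data_b * warped.grad_p_b[1]
        + w_data_k * warped.grad_p_k[1]
        - w_shape * warped.grad_phi_pk[1]
    )
    h, w = phi.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    jac = param_jacobians(xx, yy, p, center)
    scale = 1.0 / (h * w) if normalize else 1.0
    return {
        name: float(np.sum(fx * jx + fy * jy) * scale)
        for name, (jx, jy) in jac.items()
    }


def update_params(
    p: AffineParams, grads: dict[str, float], steps: StepSizes
) -> AffineParams:
    """One gradient-descent step; scales are clamped to stay positive."""
    return replace(
        p,
        sx=max(p.sx - steps.gamma2 * grads["sx"], _MIN_SCALE),
        sy=max(p.sy - steps.gamma2 * grads["sy"], _MIN_SCALE),
        hx=p.hx - steps.gamma3 * grads["hx"],
        hy=p.hy - steps.gamma3 * grads["hy"],
        tx=p.tx - steps.gamma4 * grads["tx"],
        ty=p.ty - steps.gamma4 * grads["ty"],
        theta=p.theta - steps.gamma5 * grads["theta"],
    )
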