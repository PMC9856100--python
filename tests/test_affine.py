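import dataclasses

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from kidseg.affine import (
    PARAM_NAMES,
    AffineParams,
    StepSizes,
    compose_matrix,
    param_jacobians,
    registration_gradients,
    transform_coords,
    update_params,
)
from kidseg.level_set import EnergyWeights, LevelSetField
from kidseg.segmentation import total_energy, warp_prior
from kidseg.shape_prior import ShapePriorModel


def smooth_prior(shape=(64, 64), blob=None):
    """Synthetic smooth prior fields for gradient oracles (not cohort-built)."""
    h, w = shape
    cx, cy = blob if blob is not None else ((w - 1) / 2, (h - 1) / 2)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    r2 = ((xx - cx) / 16.0) ** 2 + ((yy - cy) / 11.0) ** 2
    p_k = 0.02 + 0.96 * np.exp(-r2)
    phi_pk = gaussian_filter((p_k - 0.5) * 10.0, 2.0)
    return ShapePriorModel(p_k=p_k, p_b=1 - p_k, phi_pk=phi_pk, n_masks=2, beta=1.0)


class TestCompose:
    def test_identity(self):
        a, t = compose_matrix(AffineParams.identity())
        np.testing.assert_allclose(a, np.eye(2), atol=1e-15)
        np.testing.assert_allclose(t, 0, atol=1e-15)

    def test_quarter_rotation(self):
        a, _ = compose_matrix(AffineParams(theta=np.pi / 2))
        np.testing.assert_allclose(a, [[0, -1], [1, 0]], atol=1e-12)

    def test_composition_order_rotation_shear_scale(self):
        p = AffineParams(theta=0.3, sx=1.2, sy=0.8, hx=0.1, hy=-0.05)
        c, s = np.cos(0.3), np.sin(0.3)
        r = np.array([[c, -s], [s, c]])
        h = np.array([[1, 0.1], [-0.05, 1]])
        sc = np.diag([1.2, 0.8])
        a, _ = compose_matrix(p)
        np.testing.assert_allclose(a, r @ h @ sc, atol=1e-14)

    def test_pure_shear(self):
        a, _ = compose_matrix(AffineParams(hx=0.1))
        np.testing.assert_allclose(a, [[1, 0.1], [0, 1]], atol=1e-15)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            AffineParams(sx=0.0)


class TestTransform:
    def test_identity_map(self):
        x, y = transform_coords(np.array([3.0]), np.array([7.0]),
                                AffineParams.identity(), center=(10, 10))
        assert x[0] == 3.0 and y[0] == 7.0

    def test_pure_translation(self):
        p = AffineParams(tx=2.5, ty=-1.5)
        x, y = transform_coords(np.array([3.0]), np.array([7.0]), p, center=(0, 0))
        assert x[0] == 5.5 and y[0] == 5.5

    def test_half_turn_reflects_through_center(self):
        p = AffineParams(theta=np.pi)
        x, y = transform_coords(np.array([10.0]), np.array([20.0]), p, center=(16.0, 16.0))
        assert x[0] == pytest.approx(22.0)
        assert y[0] == pytest.approx(12.0)

    def test_invertible_linear_part(self):
        p = AffineParams(theta=0.2, sx=1.1, sy=0.9, hx=0.1, hy=0.2)
        a, _ = compose_matrix(p)
        assert abs(np.linalg.det(a)) > 1e-6


class TestJacobians:
    def test_translation_jacobians_are_unit_vectors(self):
        jac = param_jacobians(np.array([5.0]), np.array([9.0]),
                              AffineParams(theta=0.4, hx=0.2), center=(3, 3))
        assert jac["tx"][0][0] == 1.0 and jac["tx"][1][0] == 0.0
        assert jac["ty"][0][0] == 0.0 and jac["ty"][1][0] == 1.0

    def test_rotation_jacobian_at_identity(self):
        # at identity and center 0: d(x_hat, y_hat)/d(theta) = (-y, x)
        jac = param_jacobians(np.array([4.0]), np.array([2.0]),
                              AffineParams.identity(), center=(0.0, 0.0))
        assert jac["theta"][0][0] == pytest.approx(-2.0, abs=1e-12)
        assert jac["theta"][1][0] == pytest.approx(4.0, abs=1e-12)

    @pytest.mark.parametrize("name", PARAM_NAMES)
    def test_jacobians_match_finite_differences(self, name):
        p = AffineParams(theta=0.15, sx=1.1, sy=0.95, hx=0.07, hy=-0.04, tx=2, ty=-3)
        center = (12.0, 8.0)
        x = np.array([3.0, 20.0, 11.5])
        y = np.array([17.0, 2.0, 9.25])
        h = 1e-6
        pp = dataclasses.replace(p, **{name: getattr(p, name) + h})
        pm = dataclasses.replace(p, **{name: getattr(p, name) - h})
        xp, yp = transform_coords(x, y, pp, center)
        xm, ym = transform_coords(x, y, pm, center)
        fd_x = (xp - xm) / (2 * h)
        fd_y = (yp - ym) / (2 * h)
        jx, jy = param_jacobians(x, y, p, center)[name]
        np.testing.assert_allclose(jx, fd_x, rtol=1e-6, atol=1e-6)
        np.testing.assert_allclose(jy, fd_y, rtol=1e-6, atol=1e-6)


class TestRegistrationGradients:
    def _state(self, shape=(64, 64), seed=0):
        rng = np.random.default_rng(seed)
        phi = LevelSetField(10 * gaussian_filter(rng.standard_normal(shape), 6), eps=1.5)
        m_k = gaussian_filter(rng.random(shape), 4)
        m_k = np.clip(m_k / (m_k.max() + 1e-12), 0, 1)
        return phi, m_k, 1 - m_k

    def test_zero_weights_give_zero_gradients(self):
        prior = smooth_prior()
        phi, m_k, m_b = self._state()
        center = (31.5, 31.5)
        p = AffineParams(theta=0.1, tx=1.0)
        warped = warp_prior(prior, p, phi.shape, center)
        grads = registration_gradients(phi, m_k, m_b, warped, p,
                                       EnergyWeights(6.0, 0.0, 0.0), center)
        assert all(g == 0.0 for g in grads.values())

    def test_symmetric_setup_zero_translation_gradient(self):
        # reflection-symmetric contour and prior at identity: no translation pull
        prior = smooth_prior()
        h, w = 64, 64
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        r = np.hypot(xx - 31.5, yy - 31.5)
        phi = LevelSetField(np.clip(12.0 - r, -7.5, 7.5), eps=1.5)
        m_k = np.exp(-((r / 12.0) ** 2))
        center = (31.5, 31.5)
        p = AffineParams.identity()
        warped = warp_prior(prior, p, (h, w), center)
        grads = registration_gradients(phi, m_k, 1 - m_k, warped, p,
                                       EnergyWeights(6, 6, 0.1), center)
        scale = max(abs(grads["theta"]), 1.0)
        assert abs(grads["tx"]) < 1e-6 * scale + 1e-9
        assert abs(grads["ty"]) < 1e-6 * scale + 1e-9

    @pytest.mark.parametrize("name", PARAM_NAMES)
    def test_gradients_match_energy_finite_differences(self, name):
        # prior blob strictly inside a larger grid (no out-of-domain samples,
        # where the off-grid continuation rules make the energy only piecewise
        # differentiable) and off the rotation center so every parameter has a
        # coherent gradient
        prior = smooth_prior(shape=(96, 96), blob=(60.0, 40.0))
        phi, m_k, m_b = self._state()
        center = (31.5, 31.5)
        w = EnergyWeights(6.0, 6.0, 0.1)
        p0 = AffineParams(theta=0.02, sx=1.02, sy=0.98, hx=0.01, hy=-0.015,
                          tx=16.8, ty=15.6)

        def energy(p):
            warped = warp_prior(prior, p, phi.shape, center)
            return total_energy(phi, m_k, m_b, warped, w)[0]

        warped0 = warp_prior(prior, p0, phi.shape, center)
        assert warped0.in_domain.all()
        grads = registration_gradients(phi, m_k, m_b, warped0, p0, w, center)
        h = 1e-5 if name in ("tx", "ty") else 1e-7
        pp = dataclasses.replace(p0, **{name: getattr(p0, name) + h})
        pm = dataclasses.replace(p0, **{name: getattr(p0, name) - h})
        fd = (energy(pp) - energy(pm)) / (2 * h)
        assert grads[name] == pytest.approx(fd, rel=1e-3)

    def test_shape_gradient_vanishes_when_contours_agree(self):
        # V_phi == V_eps(phi_PK(X_hat)) makes the registration-term force zero
        prior = smooth_prior()
        center = (31.5, 31.5)
        p = AffineParams.identity()
        warped = warp_prior(prior, p, (64, 64), center)
        phi = LevelSetField(warped.phi_pk.copy(), eps=1.5)
        m_k = np.zeros((64, 64))
        grads = registration_gradients(phi, m_k, 1 - m_k, warped, p,
                                       EnergyWeights(0, 0, 0.1), center)
        for g in grads.values():
            assert abs(g) < 1e-9


class TestUpdate:
    def test_zero_gradient_fixed_point(self):
        p = AffineParams(theta=0.1, sx=1.1, tx=2.0)
        grads = {name: 0.0 for name in PARAM_NAMES}
        assert update_params(p, grads, StepSizes()) == p

    def test_known_gradient_arithmetic(self):
        steps = StepSizes(gamma1=0.8, gamma2=0.01, gamma3=0.02, gamma4=0.5, gamma5=0.1)
        grads = dict(sx=1.0, sy=-2.0, hx=3.0, hy=-4.0, tx=5.0, ty=-6.0, theta=0.7)
        p = update_params(AffineParams.identity(), grads, steps)
        assert p.sx == pytest.approx(1 - 0.01)
        assert p.sy == pytest.approx(1 + 0.02)
        assert p.hx == pytest.approx(-0.06)
        assert p.hy == pytest.approx(0.08)
        assert p.tx == pytest.approx(-2.5)
        assert p.ty == pytest.approx(3.0)
        assert p.theta == pytest.approx(-0.07)

    def test_scale_clamped_positive(self):
        grads = dict(sx=1e9, sy=0.0, hx=0.0, hy=0.0, tx=0.0, ty=0.0, theta=0.0)
        p = update_params(AffineParams.identity(), grads, StepSizes(gamma2=1.0))
        assert p.sx > 0

    def test_default_steps_match_reference_operating_point(self):
        s = StepSizes()
        assert (s.gamma2, s.gamma3, s.gamma4, s.gamma5) == (1e-14, 1e-10, 1e-10, 1e-9)
        assert s.gamma1 == 0.8

    def test_nonpositive_steps_rejected(self):
        with pytest.raises(ValueError):
            StepSizes(gamma4=0.0)
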