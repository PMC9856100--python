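"""Two-cluster fuzzy c-means coupled to the level-set contour.

Each pixel carries soft memberships to the kidney and background clusters,
weighted by squared intensity distance to the cluster centroids (fuzzifier
fixed at 2). Centroid updates are restricted to each cluster's side of the
contour through the smeared Heaviside, so the clustering and the contour
evolve together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .level_set import LevelSetField


@dataclass
class FuzzyState:
    """Per-pixel memberships and the two cluster centroids."""

    m_k: np.ndarray
    m_b: np.ndarray
    c_k: float
    c_b: float

    def validate(self) -> None:
        if self.m_k.shape != self.m_b.shape:
            raise ValueError("membership fields must share a shape")
        if np.any(self.m_k < 0) or np.any(self.m_k > 1):
            raise ValueError("memberships must lie in [0, 1]")
        if not np.allclose(self.m_k + self.m_b, 1.0, atol=1e-12):
            raise ValueError("memberships must sum to 1 per pixel")


class DegenerateClusterError(RuntimeError):
    """A cluster region or centroid denominator collapsed to nothing."""


def init_centroids(image: np.ndarray, phi: LevelSetField) -> tuple[float, float]:
    """Initial centroids: mean intensity inside ({phi>0}) and outside ({phi<0})
    the contour."""
    image = np.asarray(image, dtype=float)
    if image.shape != phi.shape:
        raise ValueError("image and level-set shapes differ")
    inside = phi.values > 0
    outside = phi.values < 0
    if not inside.any() or not outside.any():
        raise DegenerateClusterError(
            "initial contour must have pixels strictly inside and outside"
        )
    return float(image[inside].mean()), float(image[outside].mean())


def update_memberships(
    image: np.ndarray, c_k: float, c_b: float
) -> tuple[np.ndarray, np.ndarray]:
    """Memberships from inverse-square intensity distances to the centroids.

    m_L = d_L^-2 / (d_K^-2 + d_B^-2) with d_L = |I - C_L|. A pixel exactly at
    one centroid gets full membership there; equidistant from both (including
    coincident centroids) gets 0.5 each.
    """
    image = np.asarray(image, dtype=float)
    if not (np.isfinite(c_k) and np.isfinite(c_b)):
        raise ValueError("centroids must be finite")
    d_k = np.abs(image - c_k)
    d_b = np.abs(image - c_b)
    zero_k = d_k == 0
    zero_b = d_b == 0
    # Guard the inverse squares; exact-hit pixels are overwritten below.
    safe_k = np.where(zero_k, 1.0, d_k)
    safe_b = np.where(zero_b, 1.0, d_b)
    w_k = safe_k**-2.0
    w_b = safe_b**-2.0
    m_k = w_k / (w_k + w_b)
    m_k = np.where(zero_k & ~zero_b, 1.0, m_k)
    m_k = np.where(zero_b & ~zero_k, 0.0, m_k)
    m_k = np.where(zero_k & zero_b, 0.5, m_k)
    return m_k, 1.0 - m_k


def update_centroids(
    image: np.ndarray,
    phi: LevelSetField,
    m_k: np.ndarray,
    m_b: np.ndarray,
) -> tuple[float, float]:
    """Region-weighted fuzzy centroids.

    C_L = sum(R_L(phi) I m_L^2) / sum(R_L(phi) m_L^2) where R_K is the smeared
    Heaviside of phi and R_B its complement.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != phi.shape or m_k.shape != image.shape:
        raise ValueError("field shape mismatch")
    r_k = phi.heaviside()
    r_b = 1.0 - r_k
    num_k = float(np.sum(r_k * image * m_k**2))
    den_k = float(np.sum(r_k * m_k**2))
    num_b = float(np.sum(r_b * image * m_b**2))
    den_b = float(np.sum(r_b * m_b**2))
    if den_k <= 0 or den_b <= 0:
        raise DegenerateClusterError("centroid denominator vanished")
    return num_k / den_k, num_b / den_b


def init_state(
    image: np.ndarray,
    phi: LevelSetField,
    n_alternations: int = 20,
    tol: float = 1e-8,
) -> FuzzyState:
    """Initial fuzzy state: region-mean centroids refined by plain clustering.

    Centroids start as the mean intensities inside/outside the initial
    contour, then membership/centroid alternations of intensity-only fuzzy
    c-means (no spatial weighting) are run to convergence. Starting the
    contour evolution from crisp, intensity-faithful memberships matters: a
    contour initialized far from the kidney yields nearly equal initial
    centroids, and memberships computed from those would misclassify kidney
    pixels long enough for the evolution to commit them irrecoverably to the
    wrong side of the smearing band.
    """
    image = np.asarray(image, dtype=float)
    c_k, c_b = init_centroids(image, phi)
    m_k, m_b = update_memberships(image, c_k, c_b)
    for _ in range(n_alternations):
        den_k = float(np.sum(m_k**2))
        den_b = float(np.sum(m_b**2))
        if den_k <= 0 or den_b <= 0:
            break
        new_k = float(np.sum(image * m_k**2)) / den_k
        new_b = float(np.sum(image * m_b**2)) / den_b
        moved = abs(new_k - c_k) + abs(new_b - c_b)
        c_k, c_b = new_k, new_b
        m_k, m_b = update_memberships(image, c_k, c_b)
        if moved < tol:
            break
    # Labelling convention: the kidney cluster is the brighter one (the organ
    # is contrast-enhanced relative to its surroundings).
    if c_k < c_b:
        c_k, c_b = c_b, c_k
        m_k, m_b = m_b, m_k
    return FuzzyState(m_k=m_k, m_b=m_b, c_k=c_k, c_b=c_b)
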