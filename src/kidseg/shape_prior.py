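"""Statistical shape prior from co-aligned expert kidney masks.

The prior stores, per pixel of a common reference grid, a Bayesian estimate of
the probability that the pixel is kidney (P_K) or background (P_B). Unlike a
plain label-frequency prior, pixels labelled unanimously across the training
cohort still receive a strictly-positive probability for the unobserved label,
so a test kidney that extends slightly beyond every training kidney is not
vetoed outright.

With N training masks, per-pixel kidney count N_K and additive weight beta,
let O be the number of labels observed at the pixel (2 if 0 < N_K < N, else
1) and l = 2 the number of possible labels. An observed label L gets

    P_L = [(N_L + beta) / (N + beta O)] * [N / (N + l - O)]

and, when only one label was observed, the unobserved label gets

    P_L = [1 / (l - O)] * [1 - N / (N + l - O)]

These two rules sum to 1 per pixel by construction. A level-set view of the
prior, ``phi_pk``, is defined here as the signed Euclidean distance to the
0.5 isocontour of P_K (positive inside); this choice gives the registration
force a well-scaled gradient field (|grad phi_pk| ~ 1).

Coordinate convention for all stored fields: pixel-centered, 0-based,
x = column, y = row.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

N_LABELS = 2  # kidney, background


@dataclass
class ShapePriorModel:
    """Pixel-wise kidney/background probabilities plus the derived level set."""

    p_k: np.ndarray
    p_b: np.ndarray
    phi_pk: np.ndarray
    n_masks: int
    beta: float

    def validate(self) -> None:
        if self.p_k.shape != self.p_b.shape or self.p_k.shape != self.phi_pk.shape:
            raise ValueError("prior fields must share a shape")
        if np.max(np.abs(self.p_k + self.p_b - 1.0)) > 1e-6:
            raise ValueError("P_K + P_B must equal 1 at every pixel")
        if np.any(self.p_k <= 0) or np.any(self.p_k >= 1):
            raise ValueError("Bayesian prior probabilities must be strictly in (0,1)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_k.shape

    def mean_mask(self) -> np.ndarray:
        return self.p_k > 0.5


class DegeneratePriorError(RuntimeError):
    pass


def label_probabilities(
    n_k: np.ndarray, n: int, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bayesian per-pixel probabilities from kidney counts ``n_k`` of ``n`` masks."""
    n_k = np.asarray(n_k, dtype=float)
    n_b = n - n_k
    observed_both = (n_k > 0) & (n_k < n)
    o = np.where(observed_both, 2.0, 1.0)

    def eq11(n_l: np.ndarray) -> np.ndarray:
        return ((n_l + beta) / (n + beta * o)) * (n / (n + N_LABELS - o))

    # Unobserved-label likelihood; only used where O == 1.
    eq12 = (1.0 / (N_LABELS - np.where(observed_both, 1.0, o))) * (
        1.0 - n / (n + N_LABELS - o)
    )
    p_k = np.where(n_k > 0, eq11(n_k), eq12)
    p_b = np.where(n_b > 0, eq11(n_b), eq12)
    return p_k, p_b


def build_prior(masks, beta: float = 1.0) -> ShapePriorModel:
    """Estimate the prior from >= 2 co-aligned binary masks.

    Masks must share a shape and contain only {0, 1} (booleans accepted).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    masks = [np.asarray(m) for m in masks]
    if len(masks) < 2:
        raise ValueError("at least 2 training masks are required")
    shape = masks[0].shape
    stack = []
    for m in masks:
        if m.shape != shape:
            raise ValueError("all training masks must share a shape")
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("training masks must be binary (values in {0,1})")
        stack.append(m.astype(float))
    n = len(stack)
    n_k = np.sum(stack, axis=0)
    p_k, p_b = label_probabilities(n_k, n, beta)
    phi_pk = prior_levelset(p_k)
    model = ShapePriorModel(p_k=p_k, p_b=p_b, phi_pk=phi_pk, n_masks=n, beta=float(beta))
    model.validate()
    return model


def prior_levelset(p_k: np.ndarray) -> np.ndarray:
    """Signed distance to the 0.5 isocontour of P_K, positive where P_K > 0.5."""
    inside = np.asarray(p_k) > 0.5
    if not inside.any() or inside.all():
        raise DegeneratePriorError("P_K never crosses 0.5; no prior contour exists")
    # Distance to the opposite region, measured from pixel centers; subtracting
    # 0.5 px puts the zero crossing midway between boundary pixel pairs.
    d_in = ndimage.distance_transform_edt(inside)
    d_out = ndimage.distance_transform_edt(~inside)
    return np.where(inside, d_in - 0.5, -(d_out - 0.5))


# --- serialization ----------------------------------------------------------
#
# The prior is stored as a ZIP of .npy members plus a small metadata text
# member. Entries are written with a fixed timestamp so identical models
# serialize to byte-identical files (np.savez embeds wall-clock time).

_FIXED_DATE = (1980, 1, 1, 0, 0, 0)
_FIELDS = ("p_k", "p_b", "phi_pk")


def _npy_bytes(arr: np.ndarray) -> bytes:
    buf = io.BytesIO()
    np.lib.format.write_array(buf, np.ascontiguousarray(arr), allow_pickle=False)
    return buf.getvalue()


def save_prior(model: ShapePriorModel, path) -> None:
    model.validate()
    path = Path(path)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in _FIELDS:
            info = zipfile.ZipInfo(f"{name}.npy", date_time=_FIXED_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, _npy_bytes(getattr(model, name)))
        meta = f"n_masks={model.n_masks}\nbeta={model.beta!r}\ncoords=xy-col-row-0based\n"
        info = zipfile.ZipInfo("meta.txt", date_time=_FIXED_DATE)
        info.compress_type = zipfile.ZIP_DEFLATED
        zf.writestr(info, meta)


def load_prior(path) -> ShapePriorModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"prior model file not found: {path}")
    try:
        with zipfile.ZipFile(path) as zf:
            arrays = {}
            for name in _FIELDS:
                with zf.open(f"{name}.npy") as fh:
                    arrays[name] = np.lib.format.read_array(fh, allow_pickle=False)
            meta_lines = zf.read("meta.txt").decode().strip().splitlines()
    except (zipfile.BadZipFile, KeyError) as exc:
        raise OSError(f"corrupt or invalid prior model file: {path}") from exc
    meta = dict(line.split("=", 1) for line in meta_lines)
    model = ShapePriorModel(
        p_k=arrays["p_k"],
        p_b=arrays["p_b"],
        phi_pk=arrays["phi_pk"],
        n_masks=int(meta["n_masks"]),
        beta=float(meta["beta"]),
    )
    model.validate()
    return model
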