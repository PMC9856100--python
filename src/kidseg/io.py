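"""Image/mask readers and writers and configuration files.

Supported inputs are single-frame DICOM (rescale slope/intercept applied,
pixel spacing retained), PNG and TIFF. Masks round-trip as 0/255 PNG.
Configuration files are flat YAML key/value documents mirroring
:class:`kidseg.segmentation.SegmentationConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .affine import StepSizes
from .level_set import EnergyWeights
from .segmentation import SegmentationConfig

logger = logging.getLogger("kidseg")

# ITU-R BT.601 luminance weights for RGB inputs.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageData:
    pixels: np.ndarray
    spacing: tuple[float, float] | None = None  # (row, col) pixel spacing, mm
    source: str = ""


def read_image(path) -> ImageData:
    """Read a 2D grayscale intensity field from DICOM, PNG or TIFF."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        return _read_dicom(path)
    if suffix in (".png", ".tif", ".tiff"):
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            logger.warning("%s: RGB input collapsed to luminance", path.name)
            arr = arr[..., :3].astype(float) @ _LUMA
        return ImageData(pixels=arr.astype(float), spacing=None, source=str(path))
    raise OSError(f"unsupported image format {suffix!r} (expect DICOM/PNG/TIFF): {path}")


def _read_dicom(path: Path) -> ImageData:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
    except Exception as exc:  # pragma: no cover - pydicom raises many types
        raise OSError(f"cannot read DICOM file {path}: {exc}") from exc
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    if arr.ndim != 2:
        raise OSError(f"expected a single-frame 2D DICOM image: {path}")
    spacing = getattr(ds, "PixelSpacing", None)
    spacing = (float(spacing[0]), float(spacing[1])) if spacing is not None else None
    return ImageData(pixels=arr, spacing=spacing, source=str(path))


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as a 0/255 8-bit PNG."""
    mask = np.asarray(mask)
    out = (mask.astype(bool).astype(np.uint8)) * 255
    iio.imwrite(Path(path), out)


def read_mask(path, threshold: float | None = None) -> np.ndarray:
    """Read a binary mask from PNG/TIFF.

    Files must contain exactly the values {0, 255} or {0, 1} (either level may
    be absent) unless an explicit binarization ``threshold`` is given.
    """
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    vals = np.unique(arr)
    if threshold is None:
        if np.all(np.isin(vals, (0, 255))):
            return arr > 0
        if np.all(np.isin(vals, (0, 1))):
            return arr > 0
        raise ValueError(
            f"{path}: mask is not binary (values {vals[:6]}...); pass a threshold"
        )
    return arr.astype(float) >= threshold


# --- configuration ----------------------------------------------------------


def config_to_dict(cfg: SegmentationConfig) -> dict:
    return {
        "lambda1": cfg.weights.lambda1,
        "lambda2": cfg.weights.lambda2,
        "lambda3": cfg.weights.lambda3,
        "eps": cfg.eps,
        "beta": cfg.beta,
        "gamma1": cfg.steps.gamma1,
        "gamma2": cfg.steps.gamma2,
        "gamma3": cfg.steps.gamma3,
        "gamma4": cfg.steps.gamma4,
        "gamma5": cfg.steps.gamma5,
        "max_iters": cfg.max_iters,
        "energy_tol": cfg.energy_tol,
        "init_mode": cfg.init_mode,
        "seed": cfg.seed,
        "normalize_gradients": cfg.normalize_gradients,
        "rescale_intensities": cfg.rescale_intensities,
        "inner_steps": cfg.inner_steps,
        "clamp_phi": cfg.clamp_phi,
    }


def config_from_dict(d: dict) -> SegmentationConfig:
    base = config_to_dict(SegmentationConfig())
    unknown = set(d) - set(base)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    base.update(d)
    return SegmentationConfig(
        weights=EnergyWeights(base["lambda1"], base["lambda2"], base["lambda3"]),
        eps=base["eps"],
        beta=base["beta"],
        steps=StepSizes(
            gamma1=base["gamma1"],
            gamma2=base["gamma2"],
            gamma3=base["gamma3"],
            gamma4=base["gamma4"],
            gamma5=base["gamma5"],
        ),
        max_iters=base["max_iters"],
        energy_tol=base["energy_tol"],
        init_mode=base["init_mode"],
        seed=base["seed"],
        normalize_gradients=base["normalize_gradients"],
        rescale_intensities=base["rescale_intensities"],
        inner_steps=base["inner_steps"],
        clamp_phi=base["clamp_phi"],
    )


def save_config(cfg: SegmentationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path) -> SegmentationConfig:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ValueError(f"configuration file {path} must hold a key/value mapping")
    return config_from_dict(d)
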