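"""ROI extraction and fixed-size patch preparation.

Raw lesion/nodule crops of arbitrary size are resized to 28×28 patches for
the network input; the information lost in the resize — the two per-axis
scale factors and the original aspect ratio — is preserved as three auxiliary
scalars that rejoin the network at the supervised stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = [
    "PATCH_SIZE",
    "RoiSample",
    "AuxStandardizer",
    "extract_roi",
    "to_patch",
    "flatten_with_aux",
]

PATCH_SIZE = 28


@dataclass
class RoiSample:
    """A 28×28 normalized patch plus the geometry of its source ROI.

    ``scale_x`` = original width / 28, ``scale_y`` = original height / 28,
    ``aspect_ratio`` = width / height; original dimensions are recoverable as
    ``round(28 * scale)``.
    """

    patch: np.ndarray
    scale_x: float
    scale_y: float
    aspect_ratio: float
    label: str = "unknown"
    case_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=float)
        if self.patch.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {self.patch.shape}")
        if self.patch.min() < -1e-12 or self.patch.max() > 1 + 1e-12:
            raise ValueError("patch values must lie in [0, 1]")
        if min(self.scale_x, self.scale_y, self.aspect_ratio) <= 0:
            raise ValueError("scale factors and aspect ratio must be positive")


def extract_roi(image: np.ndarray, mask: np.ndarray, margin: float = 0.0) -> np.ndarray:
    """Crop the axis-aligned bounding box of ``mask``, expanded by ``margin``.

    ``margin`` is a fraction of each box dimension, applied on every side
    (rounded up to whole pixels) and clipped to the image bounds.
    """
    image = np.asarray(image)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1  # half-open
    c0, c1 = cols[0], cols[-1] + 1
    pad_r = int(math.ceil(margin * (r1 - r0)))
    pad_c = int(math.ceil(margin * (c1 - c0)))
    r0 = max(r0 - pad_r, 0)
    r1 = min(r1 + pad_r, image.shape[0])
    c0 = max(c0 - pad_c, 0)
    c1 = min(c1 + pad_c, image.shape[1])
    return image[r0:r1, c0:c1]


def to_patch(
    roi: np.ndarray,
    label: str = "unknown",
    case_id: str = "",
    slice_index: int = 0,
) -> RoiSample:
    """Bilinear-resize an ROI to 28×28 and min-max normalize it to [0, 1].

    A constant-valued ROI maps to an all-zero patch.  The per-axis scale
    factors and the width/height aspect ratio of the original ROI are carried
    alongside the patch.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[0] < 2 or roi.shape[1] < 2:
        raise ValueError("roi must be a 2-D array of at least 2x2 pixels")
    rows, cols = roi.shape
    patch = resize(
        roi, (PATCH_SIZE, PATCH_SIZE), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    lo, hi = patch.min(), patch.max()
    patch = (patch - lo) / (hi - lo) if hi > lo else np.zeros_like(patch)
    return RoiSample(
        patch=patch,
        scale_x=cols / PATCH_SIZE,
        scale_y=rows / PATCH_SIZE,
        aspect_ratio=cols / rows,
        label=label,
        case_id=case_id,
        slice_index=slice_index,
    )


class AuxStandardizer:
    """Z-scores the three auxiliary scalars; fitted on training samples only.

    Raw scale factors span roughly 1–20 and would dominate sigmoid inputs,
    so they are standardized with training-fold statistics before entering
    the network.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    @staticmethod
    def _aux(samples) -> np.ndarray:
        return np.array([[s.scale_x, s.scale_y, s.aspect_ratio] for s in samples], dtype=float)

    def fit(self, samples) -> "AuxStandardizer":
        aux = self._aux(samples)
        self.mean_ = aux.mean(axis=0)
        std = aux.std(axis=0, ddof=0)
        self.std_ = np.where(std > 0, std, 1.0)
        return self

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def transform(self, samples) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("AuxStandardizer must be fitted before transform")
        return (self._aux(samples) - self.mean_) / self.std_


def flatten_with_aux(sample: RoiSample, standardizer: AuxStandardizer) -> np.ndarray:
    """Row-major flatten of the patch (784 values) + 3 standardized scalars.

    During pretraining only the first 784 entries are consumed; the trailing
    auxiliary scalars join at the supervised stage.
    """
    if not standardizer.fitted:
        raise RuntimeError("auxiliary standardizer is unfitted")
    aux = standardizer.transform([sample])[0]
    return np.concatenate([sample.patch.ravel(), aux])
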