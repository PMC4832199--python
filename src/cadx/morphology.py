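"""Clinical morphological (MORPH) features from binary lesion/nodule masks.

Breast lesions (single-slice US): lesion area and the major-axis length of
the moment-matched ellipse.  Lung nodules (CT slice stacks): approximate
volume (sum of slice areas times slice thickness), the maximum per-slice
ellipse major diameter, and the maximum per-slice area.  Masks are taken as
given — they stand in for expert manual outlines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthdata import SynthCase
from .texture import FeatureVector

__all__ = ["MaskGeometry", "mask_geometry", "lung_morph", "breast_morph"]


@dataclass(frozen=True)
class MaskGeometry:
    """Area, moment-ellipse major axis and centroid of one binary mask."""

    area_mm2: float
    major_axis_mm: float
    minor_axis_mm: float
    centroid: tuple[float, float]  # (row, col) in pixels


def mask_geometry(mask: np.ndarray, spacing_mm: tuple[float, float] = (1.0, 1.0)) -> MaskGeometry:
    """Area and moment-matched-ellipse axes of a binary mask.

    The ellipse comes from the second central moments of the foreground
    pixel coordinates: axis length = 4*sqrt(eigenvalue of the coordinate
    covariance), i.e. the ellipse with identical normalized second moments.
    Anisotropic spacing is applied to the coordinates before the moments.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    sr, sc = spacing_mm
    if sr <= 0 or sc <= 0:
        raise ValueError("spacing must be positive")
    rows, cols = np.nonzero(mask)
    area = float(mask.sum()) * sr * sc
    coords = np.column_stack([rows * sr, cols * sc])
    centroid_mm = coords.mean(axis=0)
    centered = coords - centroid_mm
    # population covariance of pixel-center coordinates (matches the
    # moment-matched-ellipse convention of skimage regionprops)
    cov = centered.T @ centered / len(coords)
    eig = np.sort(np.linalg.eigvalsh(cov))
    major = 4.0 * float(np.sqrt(max(eig[1], 0.0)))
    minor = 4.0 * float(np.sqrt(max(eig[0], 0.0)))
    return MaskGeometry(
        area_mm2=area,
        major_axis_mm=major,
        minor_axis_mm=minor,
        centroid=(float(rows.mean()), float(cols.mean())),
    )


def lung_morph(case: SynthCase) -> FeatureVector:
    """Nodule volume, max per-slice ellipse major diameter, max slice area.

    Volume is the slice-area sum times the slice thickness — an
    approximation whose error grows with thickness.
    """
    if case.thickness is None or case.thickness <= 0:
        raise ValueError("case has no valid slice thickness")
    geoms = [mask_geometry(m, (case.spacing, case.spacing)) for m in case.masks]
    areas = np.array([g.area_mm2 for g in geoms])
    majors = np.array([g.major_axis_mm for g in geoms])
    return FeatureVector(
        names=["volume_mm3", "max_major_diameter_mm", "max_area_mm2"],
        values=np.array([float(areas.sum() * case.thickness), float(majors.max()), float(areas.max())]),
        sample_id=case.case_id,
    )


def breast_morph(case: SynthCase) -> FeatureVector:
    """Lesion area and moment-ellipse major axis of a single-slice case."""
    if len(case.masks) != 1:
        raise ValueError("breast_morph expects exactly one slice")
    g = mask_geometry(case.masks[0], (case.spacing, case.spacing))
    return FeatureVector(
        names=["area_mm2", "major_axis_mm"],
        values=np.array([g.area_mm2, g.major_axis_mm]),
        sample_id=case.case_id,
    )
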