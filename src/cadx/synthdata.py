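"""Seeded synthetic ultrasound- and CT-like lesion datasets.

This module fabricates labelled grayscale ROI datasets with the statistical
structure a benign/malignant CADx classifier assumes:

* **US-like** single-slice cases: a hypoechoic star-convex lesion on a
  brighter background, multiplicative Rayleigh speckle with log compression,
  optional posterior acoustic shadowing, and class-dependent boundary
  irregularity and internal texture heterogeneity.
* **CT-like** multi-slice cases: a lobulated ellipsoidal nodule sampled at a
  configurable slice thickness; every per-slice mask is the analytic
  slice-plane cross-section of the ellipsoid, so the middle slice carries the
  maximal cross-section area.

Masks are generated exactly from the analytic boundary — they stand in for
expert manual outlines; no segmentation is simulated.  All randomness flows
through one :class:`numpy.random.Generator` derived from ``SynthConfig.seed``,
so a fixed config yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "ClassDependent",
    "SynthConfig",
    "SynthCase",
    "generate_us_dataset",
    "generate_ct_dataset",
    "spherical_ct_case",
    "write_manifest",
    "read_manifest",
]

LABELS = ("benign", "malignant")


@dataclass(frozen=True)
class ClassDependent:
    """A parameter taking one value per diagnostic class."""

    benign: float
    malignant: float

    def get(self, label: str) -> float:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        return getattr(self, label)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic dataset.

    Parameters
    ----------
    modality
        ``"us"`` (single-slice sonogram-like) or ``"ct"`` (slice stacks).
    n_benign, n_malignant
        Case counts per class; must be positive.
    image_size
        Square image side in pixels.
    pixel_spacing
        In-plane pixel size in mm.
    slice_thickness
        Axial spacing in mm (CT only); must lie in (0, 10].
    slices_per_case_range
        Inclusive ``(lo, hi)`` interval the per-case slice count is drawn
        from (CT only).
    speckle_scale
        Strength of the multiplicative Rayleigh speckle (0 = none).
    boundary_irregularity
        Per-class amplitude in [0, 1] of the star-convex harmonic boundary
        perturbation (spiculation/lobulation proxy).
    texture_contrast
        Per-class amplitude of the smoothed intra-lesion texture field.
    shadowing_prob
        Probability of posterior acoustic shadowing (US only).
    seed
        Master seed; a fixed config reproduces identical pixel arrays.
    """

    modality: str = "us"
    n_benign: int = 100
    n_malignant: int = 100
    image_size: int = 64
    pixel_spacing: float = 0.15
    slice_thickness: float = 1.5
    slices_per_case_range: tuple[int, int] = (3, 9)
    speckle_scale: float = 0.6
    boundary_irregularity: ClassDependent = field(
        default_factory=lambda: ClassDependent(benign=0.08, malignant=0.30)
    )
    texture_contrast: ClassDependent = field(
        default_factory=lambda: ClassDependent(benign=0.05, malignant=0.15)
    )
    shadowing_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("us", "ct"):
            raise ValueError(f"modality must be 'us' or 'ct', got {self.modality!r}")
        if self.n_benign <= 0 or self.n_malignant <= 0:
            raise ValueError("case counts must be positive")
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16 pixels")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.modality == "ct":
            if not (0.0 < self.slice_thickness <= 10.0):
                raise ValueError("slice_thickness must lie in (0, 10] mm")
            lo, hi = self.slices_per_case_range
            if lo < 1 or hi < lo:
                raise ValueError("slices_per_case_range must satisfy 1 <= lo <= hi")


@dataclass
class SynthCase:
    """One synthetic lesion/nodule: ordered slices, analytic masks, geometry."""

    case_id: str
    label: str
    images: list[np.ndarray]  # uint8, one per slice
    masks: list[np.ndarray]  # bool, one per slice, each nonempty
    spacing: float  # mm per pixel, isotropic in-plane
    thickness: float  # mm between slices (1.0 for single-slice US)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.masks) or len(self.images) == 0:
            raise ValueError("images and masks must be equal-length and nonempty")
        for m in self.masks:
            if not m.any():
                raise ValueError("each mask must be nonempty")


# -- star-convex boundary -----------------------------------------------------

_HARMONICS = np.arange(2, 8)  # k = 2..7: lobes, no pure translation/dilation


def _boundary_profile(rng: np.random.Generator, amplitude: float):
    """Return r(theta)/r0 as a callable; amplitude scales the harmonic sum."""
    coeffs = rng.normal(0.0, 1.0, size=_HARMONICS.size) / _HARMONICS
    total = np.abs(coeffs).sum()
    if total > 0:
        coeffs = coeffs / total
    phases = rng.uniform(0.0, 2.0 * np.pi, size=_HARMONICS.size)

    def profile(theta: np.ndarray) -> np.ndarray:
        s = np.zeros_like(theta)
        for k, c, p in zip(_HARMONICS, coeffs, phases):
            s += c * np.cos(k * theta + p)
        # clip keeps the region star-convex and connected
        return np.clip(1.0 + amplitude * s, 0.35, 1.8)

    return profile


def _star_mask(size: int, cy: float, cx: float, r0: float, profile) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = rr - cy, cc - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    return dist <= r0 * profile(theta)


def _texture_field(rng: np.random.Generator, size: int, sigma: float = 3.0) -> np.ndarray:
    f = gaussian_filter(rng.normal(size=(size, size)), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


# -- ultrasound ---------------------------------------------------------------

_US_BG = 0.65
_US_LESION = 0.32
_LOG_GAIN = 25.0


def _render_us_case(cfg: SynthConfig, label: str, case_id: str, rng: np.random.Generator) -> SynthCase:
    n = cfg.image_size
    cy = n / 2 + rng.uniform(-0.08, 0.08) * n
    cx = n / 2 + rng.uniform(-0.08, 0.08) * n
    r0 = rng.uniform(0.18, 0.32) * n
    profile = _boundary_profile(rng, cfg.boundary_irregularity.get(label))
    mask = _star_mask(n, cy, cx, r0, profile)
    if not mask.any():  # pragma: no cover - r0 >= 0.18*16 > 2 px
        mask[int(cy), int(cx)] = True

    envelope = np.full((n, n), _US_BG)
    tc = cfg.texture_contrast.get(label)
    lesion = _US_LESION * (1.0 + tc * _texture_field(rng, n))
    envelope = np.where(mask, lesion, envelope)
    envelope = gaussian_filter(envelope, 1.0)  # soft acoustic boundary

    # posterior shadowing: darkened column band below the lesion
    if rng.random() < cfg.shadowing_prob:
        atten = np.ones((n, n))
        band = np.abs(np.arange(n) - cx) <= 0.6 * r0
        below = np.arange(n) > cy
        atten[np.ix_(below, band)] = 0.55
        envelope *= gaussian_filter(atten, 2.0)

    # multiplicative Rayleigh speckle, unit mean, then log compression
    ray = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=(n, n))
    mult = np.clip(1.0 + cfg.speckle_scale * (ray - 1.0), 0.02, None)
    intensity = np.clip(envelope * mult, 0.0, None)
    compressed = np.log1p(_LOG_GAIN * intensity) / math.log1p(_LOG_GAIN)

    return SynthCase(
        case_id=case_id,
        label=label,
        images=[_to_uint8(compressed)],
        masks=[mask],
        spacing=cfg.pixel_spacing,
        thickness=1.0,
    )


def generate_us_dataset(cfg: SynthConfig) -> list[SynthCase]:
    """Generate ``cfg.n_benign + cfg.n_malignant`` single-slice US-like cases.

    Benign cases precede malignant ones in the returned list; each case's
    lesion is darker than the background, with class-dependent boundary
    irregularity and internal texture.
    """
    if cfg.modality != "us":
        raise ValueError("generate_us_dataset requires cfg.modality == 'us'")
    rng = np.random.default_rng(cfg.seed)
    cases = []
    for label, count in (("benign", cfg.n_benign), ("malignant", cfg.n_malignant)):
        for i in range(count):
            cases.append(_render_us_case(cfg, label, f"us-{label}-{i:04d}", rng))
    return cases


# -- CT -----------------------------------------------------------------------

_CT_BG = 0.22
_CT_NODULE = 0.62
_RADIUS_MM = {"benign": (2.5, 6.0), "malignant": (4.0, 9.0)}


def _render_ct_case(cfg: SynthConfig, label: str, case_id: str, rng: np.random.Generator) -> SynthCase:
    n = cfg.image_size
    lo, hi = cfg.slices_per_case_range
    k = int(rng.integers(lo, hi + 1))
    mid = (k - 1) // 2
    z = (np.arange(k) - mid) * cfg.slice_thickness  # mm; slice `mid` at z=0

    r_mm = rng.uniform(*_RADIUS_MM[label])
    max_abs_z = float(np.abs(z).max())
    # z semi-axis large enough that every sampled slice cuts the nodule
    c_mm = max(r_mm, 1.25 * max_abs_z + 0.5 * cfg.slice_thickness)
    r_px = r_mm / cfg.pixel_spacing

    cy = n / 2 + rng.uniform(-0.06, 0.06) * n
    cx = n / 2 + rng.uniform(-0.06, 0.06) * n
    profile = _boundary_profile(rng, cfg.boundary_irregularity.get(label))
    tc = cfg.texture_contrast.get(label)

    images, masks = [], []
    for zi in z:
        frac = math.sqrt(max(1.0 - (zi / c_mm) ** 2, 0.0))
        mask = _star_mask(n, cy, cx, r_px * frac, profile)
        if not mask.any():
            mask[int(round(cy)), int(round(cx))] = True
        img = _CT_BG + 0.05 * _texture_field(rng, n, sigma=4.0)
        nodule = _CT_NODULE * (1.0 + tc * _texture_field(rng, n))
        img = np.where(mask, nodule, img)
        img = gaussian_filter(img, 0.8)
        img = img + rng.normal(0.0, 0.03, size=(n, n))
        images.append(_to_uint8(img))
        masks.append(mask)

    return SynthCase(
        case_id=case_id,
        label=label,
        images=images,
        masks=masks,
        spacing=cfg.pixel_spacing,
        thickness=cfg.slice_thickness,
    )


def generate_ct_dataset(cfg: SynthConfig) -> list[SynthCase]:
    """Generate CT-like nodule slice stacks.

    Each case holds ``k`` slices with ``k`` drawn from
    ``cfg.slices_per_case_range``; the nodule is a lobulated ellipsoid whose
    analytic cross-sections provide the masks, maximal at the middle slice.
    """
    if cfg.modality != "ct":
        raise ValueError("generate_ct_dataset requires cfg.modality == 'ct'")
    rng = np.random.default_rng(cfg.seed)
    cases = []
    for label, count in (("benign", cfg.n_benign), ("malignant", cfg.n_malignant)):
        for i in range(count):
            cases.append(_render_ct_case(cfg, label, f"ct-{label}-{i:04d}", rng))
    return cases


def spherical_ct_case(
    radius_mm: float,
    thickness_mm: float,
    pixel_spacing: float = 0.5,
    image_size: int = 96,
    label: str = "benign",
    seed: int = 0,
) -> SynthCase:
    """An exactly spherical nodule sampled symmetrically about its equator.

    Slices lie at z = i·thickness for integer i with \\|z\\| < radius, so the
    per-slice mask areas follow the analytic circle cross-sections
    r(z) = sqrt(R² − z²).  Used for geometric validation of the mask and
    morphology code.
    """
    if radius_mm <= 0 or thickness_mm <= 0:
        raise ValueError("radius and thickness must be positive")
    rng = np.random.default_rng(seed)
    half = int(math.ceil(radius_mm / thickness_mm)) - 1
    while half * thickness_mm >= radius_mm:  # strict interior
        half -= 1
    z = np.arange(-half, half + 1) * thickness_mm
    n = image_size
    cy = cx = (n - 1) / 2
    images, masks = [], []
    for zi in z:
        r_px = math.sqrt(radius_mm**2 - zi**2) / pixel_spacing
        rr, cc = np.mgrid[0:n, 0:n].astype(float)
        mask = np.hypot(rr - cy, cc - cx) <= r_px
        img = np.where(mask, _CT_NODULE, _CT_BG) + rng.normal(0, 0.02, (n, n))
        images.append(_to_uint8(img))
        masks.append(mask)
    return SynthCase(
        case_id="ct-sphere-0000",
        label=label,
        images=images,
        masks=masks,
        spacing=pixel_spacing,
        thickness=thickness_mm,
    )


# -- manifest IO --------------------------------------------------------------

MANIFEST_COLUMNS = [
    "case_id",
    "slice_index",
    "label",
    "image_path",
    "mask_path",
    "pixel_spacing_mm",
    "slice_thickness_mm",
]


def write_manifest(cases: list[SynthCase], out_dir: str | Path) -> Path:
    """Write 8-bit PNG images/masks plus a manifest CSV; return the CSV path.

    The manifest holds one row per slice with columns
    ``case_id, slice_index, label, image_path, mask_path, pixel_spacing_mm,
    slice_thickness_mm``; paths are relative to the manifest's directory.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        if case.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {case.label!r}")
        for idx, (img, mask) in enumerate(zip(case.images, case.masks)):
            ipath = f"images/{case.case_id}_{idx:03d}.png"
            mpath = f"masks/{case.case_id}_{idx:03d}.png"
            Image.fromarray(img.astype(np.uint8), mode="L").save(out / ipath)
            Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(out / mpath)
            rows.append(
                {
                    "case_id": case.case_id,
                    "slice_index": idx,
                    "label": case.label,
                    "image_path": ipath,
                    "mask_path": mpath,
                    "pixel_spacing_mm": case.spacing,
                    "slice_thickness_mm": case.thickness,
                }
            )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path: str | Path) -> list[SynthCase]:
    """Load a manifest CSV back into :class:`SynthCase` objects."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    cases = []
    for case_id, grp in df.groupby("case_id", sort=False):
        grp = grp.sort_values("slice_index")
        images = [np.asarray(Image.open(base / p)) for p in grp["image_path"]]
        masks = [np.asarray(Image.open(base / p)) > 127 for p in grp["mask_path"]]
        cases.append(
            SynthCase(
                case_id=str(case_id),
                label=str(grp["label"].iloc[0]),
                images=images,
                masks=masks,
                spacing=float(grp["pixel_spacing_mm"].iloc[0]),
                thickness=float(grp["slice_thickness_mm"].iloc[0]),
            )
        )
    return cases
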