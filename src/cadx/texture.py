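"""Texture feature stacks: GLCM/Haralick statistics, the ranklet transform,
a pluggable sub-band decomposition, angle averaging and bootstrap feature
selection.

Two conventional CADx feature pipelines are assembled from these pieces:

* **RANK** — ranklet transform of the ROI (rank-based, hence invariant to
  any strictly increasing intensity change and robust to speckle), GLCM
  Haralick statistics on every ranklet response, angle averaging, and a
  bootstrap selection of the most discriminative features.
* **CURVE** — multi-band image decomposition (2-level separable wavelet by
  default, standing in for directional multi-scale transforms), GLCM
  Haralick statistics per band, angle averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata
from skimage.feature import graycomatrix
from sklearn.metrics import roc_auc_score

__all__ = [
    "GlcmSpec",
    "RankletSpec",
    "FeatureVector",
    "quantize",
    "glcm",
    "haralick",
    "HARALICK_NAMES",
    "RANK_SUBSET",
    "ranklet_transform",
    "Decomposition",
    "decompose",
    "average_over_angles",
    "bootstrap_select",
    "rank_features",
    "curve_features",
]

ANGLES_DEG = (0, 45, 90, 135)


@dataclass(frozen=True)
class GlcmSpec:
    """Gray-level co-occurrence matrix settings."""

    levels: int = 16
    distances: tuple[int, ...] = (1,)
    angles: tuple[int, ...] = ANGLES_DEG
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1")
        if any(a not in ANGLES_DEG for a in self.angles):
            raise ValueError(f"angles must be in {ANGLES_DEG}")


@dataclass(frozen=True)
class RankletSpec:
    """Ranklet window sizes (even) and Haar-like orientations."""

    window_sizes: tuple[int, ...] = (4, 8)
    orientations: tuple[str, ...] = ("vertical", "horizontal", "diagonal")

    def __post_init__(self) -> None:
        if any(w < 2 or w % 2 for w in self.window_sizes):
            raise ValueError("window sizes must be even and >= 2")
        bad = set(self.orientations) - {"vertical", "horizontal", "diagonal"}
        if bad:
            raise ValueError(f"unknown orientations: {sorted(bad)}")


@dataclass
class FeatureVector:
    """Named real-valued features for one sample."""

    names: list[str]
    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def quantize(img: np.ndarray, levels: int, value_range: tuple[float, float] | None = None) -> np.ndarray:
    """Uniformly bin ``img`` into integer levels 0..levels-1.

    ``value_range`` defaults to the image's own (min, max); a constant image
    maps to all zeros.
    """
    img = np.asarray(img, dtype=float)
    lo, hi = value_range if value_range is not None else (img.min(), img.max())
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    idx = np.floor((img - lo) / (hi - lo) * levels).astype(int)
    return np.clip(idx, 0, levels - 1).astype(np.uint8)


# -- GLCM ---------------------------------------------------------------------


def glcm(img: np.ndarray, spec: GlcmSpec, distance: int, angle: int) -> np.ndarray:
    """Co-occurrence matrix of integer ``img`` at one displacement.

    The displacement for angle a (degrees) and distance d is
    (rows, cols) = (round(d sin a), round(d cos a)); the matrix is
    symmetrized by adding its transpose and normalized to sum 1 when the
    spec asks for it.
    """
    img = np.asarray(img)
    if img.min() < 0 or img.max() >= spec.levels:
        raise ValueError(f"image values must lie in [0, {spec.levels})")
    if angle not in ANGLES_DEG:
        raise ValueError(f"angle must be in {ANGLES_DEG}")
    P = graycomatrix(
        img.astype(np.uint8),
        distances=[distance],
        angles=[np.deg2rad(angle)],
        levels=spec.levels,
        symmetric=spec.symmetric,
        normed=False,
    )[:, :, 0, 0].astype(float)
    if spec.normalized:
        total = P.sum()
        if total > 0:
            P = P / total
    return P


HARALICK_NAMES = [
    "energy",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "max_correlation_coeff",
]

# the 12-feature subset drops the two numerically most fragile statistics
RANK_SUBSET = HARALICK_NAMES[:12]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def haralick(P: np.ndarray, subset: list[str] | None = None) -> FeatureVector:
    """The 14 classic Haralick statistics of a normalized GLCM.

    Natural logarithms throughout; degenerate denominators (zero marginal
    variance, empty marginal entropies) yield the documented conventions
    (correlation 0, information measures 0).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be a square matrix")
    if abs(P.sum() - 1.0) > 1e-8:
        raise ValueError("P must be normalized to sum 1")
    N = P.shape[0]
    i = np.arange(N)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # p_{x+y}(k), k = 0..2N-2 and p_{x-y}(k), k = 0..N-1
    p_sum = np.bincount((ii + jj).ravel(), weights=P.ravel(), minlength=2 * N - 1)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=P.ravel(), minlength=N)
    k_sum = np.arange(2 * N - 1)
    k_diff = np.arange(N)

    energy = float((P**2).sum())
    contrast = float(((ii - jj) ** 2 * P).sum())
    if sd_x * sd_y > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float((((ii - mu_x) ** 2) * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy(p_sum)
    entropy = _entropy(P.ravel())
    diff_mean = float(k_diff @ p_diff)
    diff_variance = float(((k_diff - diff_mean) ** 2) @ p_diff)
    diff_entropy = _entropy(p_diff)

    # information measures of correlation
    hx, hy = _entropy(px), _entropy(py)
    outer = np.outer(px, py)
    mask = (P > 0) & (outer > 0)
    hxy1 = float(-(P[mask] * np.log(outer[mask])).sum())
    hxy2 = _entropy(outer.ravel())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    # maximal correlation coefficient: sqrt of the 2nd largest eigenvalue of Q
    nz = (px > 0) & (py > 0)
    if nz.sum() >= 2:
        Psub = P[np.ix_(nz, nz)]
        Q = (Psub / px[nz, None]) @ (Psub / py[nz][None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, ev[-2])))
    else:
        mcc = 0.0

    values = dict(
        zip(
            HARALICK_NAMES,
            [
                energy, contrast, correlation, variance, idm, sum_average,
                sum_variance, sum_entropy, entropy, diff_variance,
                diff_entropy, imc1, imc2, mcc,
            ],
        )
    )
    names = subset if subset is not None else HARALICK_NAMES
    return FeatureVector(names=list(names), values=np.array([values[n] for n in names]))


# -- ranklet transform --------------------------------------------------------


def _orientation_split(w: int, orientation: str) -> np.ndarray:
    """Boolean treatment mask on the flattened w*w window."""
    half = w // 2
    rows, cols = np.mgrid[0:w, 0:w]
    if orientation == "vertical":  # responds to vertical edges: right half treated
        t = cols >= half
    elif orientation == "horizontal":  # top half treated
        t = rows < half
    elif orientation == "diagonal":  # main-diagonal quadrants treated
        t = (rows < half) == (cols < half)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return t.ravel()


def ranklet_response(window: np.ndarray, orientation: str) -> float:
    """Ranklet of one even-sized square window: 2*U/(nT*nC) - 1 in [-1, 1].

    U is the Mann-Whitney count of (treatment > control) pixel pairs with
    ties counting one half, computed from midranks.
    """
    w = window.shape[0]
    if window.shape != (w, w) or w % 2:
        raise ValueError("window must be square with even side")
    t = _orientation_split(w, orientation)
    ranks = rankdata(window.ravel(), method="average")
    n_t = int(t.sum())
    n_c = t.size - n_t
    U = ranks[t].sum() - n_t * (n_t + 1) / 2.0
    return float(2.0 * U / (n_t * n_c) - 1.0)


def ranklet_transform(img: np.ndarray, spec: RankletSpec = RankletSpec()) -> dict[tuple[int, str], np.ndarray]:
    """Dense ranklet responses: one image per (window size, orientation).

    Responses are computed at every position where the window fits, so a
    window of side w on an (H, W) image yields an (H-w+1, W-w+1) response.
    """
    img = np.asarray(img, dtype=float)
    out: dict[tuple[int, str], np.ndarray] = {}
    for w in spec.window_sizes:
        if w > min(img.shape):
            raise ValueError(f"window {w} exceeds image dims {img.shape}")
        windows = sliding_window_view(img, (w, w)).reshape(-1, w * w)
        ranks = rankdata(windows, method="average", axis=1)
        shape_out = (img.shape[0] - w + 1, img.shape[1] - w + 1)
        for orientation in spec.orientations:
            t = _orientation_split(w, orientation)
            n_t = int(t.sum())
            n_c = t.size - n_t
            U = ranks[:, t].sum(axis=1) - n_t * (n_t + 1) / 2.0
            out[(w, orientation)] = (2.0 * U / (n_t * n_c) - 1.0).reshape(shape_out)
    return out


# -- sub-band decomposition ---------------------------------------------------


@dataclass
class Decomposition:
    """Named sub-band images plus enough state to invert the transform."""

    method: str
    names: list[str]
    bands: list[np.ndarray]
    _coeffs: list = field(default_factory=list, repr=False)
    _wavelet: str = "db2"
    _mode: str = "periodization"

    def reconstruct(self) -> np.ndarray:
        if self.method == "identity":
            return self.bands[0]
        if self.method == "wavelet":
            return pywt.waverec2(self._coeffs, wavelet=self._wavelet, mode=self._mode)
        raise ValueError(f"cannot reconstruct method {self.method!r}")


def decompose(
    img: np.ndarray,
    method: str | Callable[[np.ndarray], list[tuple[str, np.ndarray]]] = "wavelet",
    wavelet: str = "db2",
    level: int = 2,
) -> Decomposition:
    """Split an image into named sub-band components.

    ``wavelet`` (default): ``level``-deep separable DWT with periodization,
    giving 1 approximation band plus 3 detail bands per level (7 bands at
    level 2).  ``identity`` returns the image itself as the only band.  A
    callable acts as a plugin returning ``[(name, band), ...]``.
    """
    img = np.asarray(img, dtype=float)
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError("image must be at least 8x8")
    if callable(method):
        named = method(img)
        return Decomposition(method="plugin", names=[n for n, _ in named], bands=[b for _, b in named])
    if method == "identity":
        return Decomposition(method="identity", names=["identity"], bands=[img])
    if method == "wavelet":
        coeffs = pywt.wavedec2(img, wavelet=wavelet, level=level, mode="periodization")
        names = [f"approx_{level}"]
        bands = [coeffs[0]]
        for depth, (cH, cV, cD) in enumerate(coeffs[1:], start=1):
            lv = level - depth + 1
            names += [f"horizontal_{lv}", f"vertical_{lv}", f"diagonal_{lv}"]
            bands += [cH, cV, cD]
        return Decomposition(
            method="wavelet", names=names, bands=bands,
            _coeffs=coeffs, _wavelet=wavelet, _mode="periodization",
        )
    raise ValueError(f"unknown decomposition method {method!r}")


# -- aggregation and selection ------------------------------------------------


def average_over_angles(features: list[FeatureVector]) -> FeatureVector:
    """Elementwise mean of per-angle feature vectors sharing one name set."""
    if not features:
        raise ValueError("no feature vectors to average")
    names = features[0].names
    for f in features[1:]:
        if f.names != names:
            raise ValueError("feature name sets differ across angles")
    stacked = np.vstack([f.values for f in features])
    return FeatureVector(names=list(names), values=stacked.mean(axis=0), sample_id=features[0].sample_id)


def bootstrap_select(
    X,
    y,
    B: int = 50,
    k: int = 8,
    tau: float = 0.5,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Bootstrap-stability feature selection by single-feature AUC.

    For each of ``B`` bootstrap resamples the features are ranked by
    single-feature discriminative AUC (max of AUC and 1-AUC) and the top
    ``k`` recorded; features present in at least ``tau*B`` of the top-k sets
    (at least one, so ``tau=0`` returns the pooled union) are returned in
    decreasing order of selection frequency.  Resamples that lose a class
    are redrawn (bounded retries).
    """
    import pandas as pd

    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a pandas DataFrame of named features")
    if B < 1 or not (1 <= k <= X.shape[1]):
        raise ValueError("require B >= 1 and 1 <= k <= n_features")
    rng = rng if rng is not None else np.random.default_rng(0)
    y = np.asarray([1 if lbl == "malignant" else 0 for lbl in y])
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    n = len(y)
    counts: dict[str, int] = {name: 0 for name in X.columns}
    values = X.to_numpy(dtype=float)
    for _ in range(B):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        scores = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            col = values[idx, j]
            if np.ptp(col) == 0:
                scores[j] = 0.5
            else:
                a = roc_auc_score(y[idx], col)
                scores[j] = max(a, 1.0 - a)
        top = np.argsort(-scores, kind="stable")[:k]
        for j in top:
            counts[X.columns[j]] += 1
    threshold = max(tau * B, 1.0)
    selected = [(name, c) for name, c in counts.items() if c >= threshold]
    selected.sort(key=lambda nc: -nc[1])
    return [name for name, _ in selected]


# -- assembled stacks ---------------------------------------------------------


def _glcm_haralick_avg(
    quantized: np.ndarray, spec: GlcmSpec, subset: list[str] | None, prefix: str
) -> FeatureVector:
    parts = []
    for d in spec.distances:
        per_angle = [haralick(glcm(quantized, spec, d, a), subset=subset) for a in spec.angles]
        avg = average_over_angles(per_angle)
        tag = f"{prefix}d{d}_" if len(spec.distances) > 1 else prefix
        parts.append(FeatureVector(names=[tag + n for n in avg.names], values=avg.values))
    return FeatureVector(
        names=[n for p in parts for n in p.names],
        values=np.concatenate([p.values for p in parts]),
    )


def rank_features(
    roi: np.ndarray,
    ranklet_spec: RankletSpec = RankletSpec(),
    glcm_spec: GlcmSpec = GlcmSpec(),
    sample_id: str = "",
) -> FeatureVector:
    """RANK stack: ranklet responses -> GLCM -> 12 Haralick stats -> angle mean.

    Computed on the pre-resize ROI by default (rank statistics depend on
    resolution); windows larger than the ROI are skipped.
    """
    roi = np.asarray(roi, dtype=float)
    usable = [w for w in ranklet_spec.window_sizes if w <= min(roi.shape)]
    if not usable:
        raise ValueError("ROI smaller than every ranklet window")
    responses = ranklet_transform(roi, RankletSpec(tuple(usable), ranklet_spec.orientations))
    parts = []
    for (w, orientation), resp in responses.items():
        q = quantize(resp, glcm_spec.levels, value_range=(-1.0, 1.0000001))
        parts.append(_glcm_haralick_avg(q, glcm_spec, RANK_SUBSET, f"w{w}_{orientation}_"))
    return FeatureVector(
        names=[n for p in parts for n in p.names],
        values=np.concatenate([p.values for p in parts]),
        sample_id=sample_id,
    )


def curve_features(
    img: np.ndarray,
    glcm_spec: GlcmSpec = GlcmSpec(),
    method: str = "wavelet",
    sample_id: str = "",
) -> FeatureVector:
    """CURVE stack: sub-band decomposition -> GLCM -> 14 Haralick stats -> angle mean."""
    dec = decompose(img, method=method)
    parts = []
    for name, band in zip(dec.names, dec.bands):
        q = quantize(band, glcm_spec.levels)
        parts.append(_glcm_haralick_avg(q, glcm_spec, None, f"{name}_"))
    return FeatureVector(
        names=[n for p in parts for n in p.names],
        values=np.concatenate([p.values for p in parts]),
        sample_id=sample_id,
    )
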