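"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (loops, all-pairs enumeration,
closed-form hand formulas) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_bruteforce(img: np.ndarray, levels: int, distance: int, angle_deg: int,
                    symmetric: bool = True, normalized: bool = True) -> np.ndarray:
    """Pair enumeration co-occurrence matrix; displacement
    (rows, cols) = (round(d sin a), round(d cos a))."""
    a = math.radians(angle_deg)
    dr = int(round(math.sin(a) * distance))
    dc = int(round(math.cos(a) * distance))
    P = np.zeros((levels, levels))
    H, W = img.shape
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                P[img[r, c], img[r2, c2]] += 1
    if symmetric:
        P = P + P.T
    if normalized and P.sum() > 0:
        P = P / P.sum()
    return P


def haralick_naive(P: np.ndarray) -> dict[str, float]:
    """All 14 Haralick statistics by direct elementwise summation."""
    N = P.shape[0]
    px = [sum(P[i, j] for j in range(N)) for i in range(N)]
    py = [sum(P[i, j] for i in range(N)) for j in range(N)]
    mu_x = sum(i * px[i] for i in range(N))
    mu_y = sum(j * py[j] for j in range(N))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(N)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(N)))
    p_sum = [0.0] * (2 * N - 1)
    p_diff = [0.0] * N
    for i in range(N):
        for j in range(N):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    def ent(ps):
        return -sum(p * math.log(p) for p in ps if p > 0)

    energy = sum(P[i, j] ** 2 for i in range(N) for j in range(N))
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(N) for j in range(N))
    if sd_x * sd_y > 0:
        corr = (sum(i * j * P[i, j] for i in range(N) for j in range(N)) - mu_x * mu_y) / (sd_x * sd_y)
    else:
        corr = 0.0
    variance = sum((i - mu_x) ** 2 * P[i, j] for i in range(N) for j in range(N))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(N) for j in range(N))
    sa = sum(k * p_sum[k] for k in range(2 * N - 1))
    sv = sum((k - sa) ** 2 * p_sum[k] for k in range(2 * N - 1))
    se = ent(p_sum)
    entropy = ent(P.ravel().tolist())
    dm = sum(k * p_diff[k] for k in range(N))
    dv = sum((k - dm) ** 2 * p_diff[k] for k in range(N))
    de = ent(p_diff)
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        P[i, j] * math.log(px[i] * py[j])
        for i in range(N) for j in range(N)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = ent([px[i] * py[j] for i in range(N) for j in range(N)])
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    keep = [i for i in range(N) if px[i] > 0 and py[i] > 0]
    if len(keep) >= 2:
        Q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                Q[a, b] = sum(
                    P[i, k] * P[j, k] / (px[i] * py[k]) for k in keep
                )
        ev = sorted(np.real(np.linalg.eigvals(Q)))
        mcc = math.sqrt(max(0.0, ev[-2]))
    else:
        mcc = 0.0
    return {
        "energy": energy, "contrast": contrast, "correlation": corr,
        "variance": variance, "inverse_difference_moment": idm,
        "sum_average": sa, "sum_variance": sv, "sum_entropy": se,
        "entropy": entropy, "difference_variance": dv, "difference_entropy": de,
        "imc1": imc1, "imc2": imc2, "max_correlation_coeff": mcc,
    }


def ranklet_pairs(window: np.ndarray, treatment_mask: np.ndarray) -> float:
    """All-pairs Mann-Whitney ranklet: ties count one half."""
    vals = window.ravel()
    t_vals = vals[treatment_mask]
    c_vals = vals[~treatment_mask]
    U = 0.0
    for tv in t_vals:
        for cv in c_vals:
            if tv > cv:
                U += 1.0
            elif tv == cv:
                U += 0.5
    return 2.0 * U / (len(t_vals) * len(c_vals)) - 1.0


def auc_pairs(y: np.ndarray, scores: np.ndarray) -> float:
    """All-pairs rank AUC: P(score_pos > score_neg) + half-ties."""
    pos = scores[np.asarray(y) == 1]
    neg = scores[np.asarray(y) == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def pooled_t(a, b) -> tuple[float, float]:
    """Hand-computed pooled-variance two-sample t statistic and two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_stat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t_stat), na + nb - 2)
    return t_stat, p


def bilinear_resize_naive(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Pixel-center-aligned bilinear interpolation, looped."""
    H, W = img.shape
    h, w = out_shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            y = (r + 0.5) * H / h - 0.5
            x = (c + 0.5) * W / w - 0.5
            y0 = min(max(int(math.floor(y)), 0), H - 1)
            x0 = min(max(int(math.floor(x)), 0), W - 1)
            y1, x1 = min(y0 + 1, H - 1), min(x0 + 1, W - 1)
            fy = min(max(y - y0, 0.0), 1.0)
            fx = min(max(x - x0, 0.0), 1.0)
            out[r, c] = (
                img[y0, x0] * (1 - fy) * (1 - fx)
                + img[y1, x0] * fy * (1 - fx)
                + img[y0, x1] * (1 - fy) * fx
                + img[y1, x1] * fy * fx
            )
    return out
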