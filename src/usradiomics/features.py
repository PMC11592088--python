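"""IBSI-style radiomic feature families.

Seven families computed per (filter, ROI) pair: intensity-based statistics,
intensity histogram, and the five grey-level texture matrices (GLCM, GLRLM,
GLSZM, NGTDM, NGLDM). All textural families operate on FBN-discretized grey
levels 1..n_bins (default 64). Computation is strictly 2D (single B-mode
frames); matrix families use the 4 unique 2D directions (0, 45, 90, 135
degrees) and merge them by averaging the normalized matrices. Count-based
non-uniformity statistics (which are not well defined on an averaged
probability table) are computed per direction on the raw count matrices and
averaged. The NGLDM dependence count includes the centre pixel (j >= 1) with
coarseness tolerance alpha (default 0).

Feature names follow ``<filter>__<family>__<feature>`` in snake case, e.g.
``gradient__ngldm__dependence_count_energy``.

Every feature here is covered by an independent brute-force oracle in the
test suite (pair enumeration for GLCM, run walks for GLRLM, flood fill for
GLSZM, per-pixel neighbourhood loops for NGTDM/NGLDM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .prep import (
    DiscretizedROI,
    GrayImage,
    PrepConfig,
    ROIMask,
    discretize_fbn,
    resample_isotropic,
)
from .filters import FilterSpec, apply_filter, default_filter_bank

#: the 4 unique 2D offsets: 0, 45, 90, 135 degrees
DIRECTIONS_2D = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
_NEIGH8 = tuple(
    (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
)
NGTDM_COARSENESS_CAP = 1e6

FAMILIES = ("stats", "hist", "glcm", "glrlm", "glszm", "ngtdm", "ngldm")


@dataclass
class TextureConfig:
    """Texture-matrix parameters: GLCM offset distance, NGLDM coarseness
    tolerance alpha; neighbourhoods are Chebyshev radius 1."""

    glcm_distance: int = 1
    ngldm_alpha: int = 0
    directions: tuple[tuple[int, int], ...] = DIRECTIONS_2D

    def __post_init__(self) -> None:
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")
        if self.ngldm_alpha < 0:
            raise ValueError("ngldm_alpha must be >= 0")


def _crop(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Crop levels/mask to the ROI bounding box (features are unaffected)."""
    rows = np.flatnonzero(d.mask.any(axis=1))
    cols = np.flatnonzero(d.mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return d.levels[sl], d.mask[sl]


# ---------------------------------------------------------------------------
# intensity-based statistics (continuous ROI values)
# ---------------------------------------------------------------------------

def intensity_statistics(roi_values: np.ndarray) -> dict[str, float]:
    """First-order statistics of the raw (non-discretized) ROI intensities.

    Percentiles use linear interpolation between order statistics; the same
    convention is used by the univariate statistics module. Variance is the
    population variance; skewness/kurtosis are the standardized third moment
    and the excess fourth moment (0 for a degenerate distribution). The
    quartile coefficient of dispersion (P75-P25)/(P75+P25) is 0 with a
    warning when the denominator vanishes.
    """
    x = np.asarray(roi_values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    m3 = np.mean(dev**3)
    m4 = np.mean(dev**4)
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 - 3.0 if m2 > 0 else 0.0
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    denom = p75 + p25
    if denom == 0:
        if p75 != p25:
            warnings.warn("quartile coefficient undefined (P75 + P25 = 0); set to 0")
        qcd = 0.0
    else:
        qcd = (p75 - p25) / denom
    return {
        "mean": float(mean),
        "variance": float(m2),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "median": float(p50),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "p10": float(p10),
        "p25": float(p25),
        "p75": float(p75),
        "p90": float(p90),
        "interquartile_range": float(p75 - p25),
        "quartile_coefficient": float(qcd),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.mean(np.abs(dev))),
        "energy": float(np.sum(x**2)),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
    }


# ---------------------------------------------------------------------------
# intensity histogram (discretized levels)
# ---------------------------------------------------------------------------

def intensity_histogram_features(d: DiscretizedROI) -> dict[str, float]:
    """First-order statistics of the discretized grey-level histogram
    (levels 1..n_bins). Entropy is in bits; mode breaks ties toward the
    smallest level."""
    lv = d.roi_levels.astype(np.float64)
    counts = np.bincount(d.roi_levels, minlength=d.n_bins + 1)[1:]
    p = counts / counts.sum()
    nz = p > 0
    mean = lv.mean()
    dev = lv - mean
    m2 = np.mean(dev**2)
    m3 = np.mean(dev**3)
    m4 = np.mean(dev**4)
    return {
        "mean": float(mean),
        "variance": float(m2),
        "skewness": float(m3 / m2**1.5 if m2 > 0 else 0.0),
        "kurtosis": float(m4 / m2**2 - 3.0 if m2 > 0 else 0.0),
        "entropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "uniformity": float(np.sum(p**2)),
        "mode": float(np.argmax(counts) + 1),
        "min_grey_level": float(lv.min()),
        "max_grey_level": float(lv.max()),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_matrix(d: DiscretizedROI, cfg: TextureConfig) -> np.ndarray:
    """Average of the 4 direction-wise symmetric, normalized co-occurrence
    matrices; pairs with either pixel outside the ROI are skipped."""
    L, M = _crop(d)
    nb = d.n_bins
    dist = cfg.glcm_distance
    mats = []
    for dy, dx in cfg.directions:
        oy, ox = dy * dist, dx * dist
        h, w = L.shape
        ys = slice(max(0, -oy), min(h, h - oy))
        xs = slice(max(0, -ox), min(w, w - ox))
        ys2 = slice(max(0, oy), min(h, h + oy))
        xs2 = slice(max(0, ox), min(w, w + ox))
        valid = M[ys, xs] & M[ys2, xs2]
        if not valid.any():
            continue
        a = L[ys, xs][valid] - 1
        b = L[ys2, xs2][valid] - 1
        P = np.zeros((nb, nb))
        np.add.at(P, (a, b), 1.0)
        P = P + P.T  # symmetric
        mats.append(P / P.sum())
    if not mats:
        raise ValueError("GLCM undefined: no valid in-ROI pixel pairs")
    return np.mean(mats, axis=0)


def glcm_features(d: DiscretizedROI, cfg: TextureConfig | None = None) -> dict[str, float]:
    cfg = cfg or TextureConfig()
    P = _glcm_matrix(d, cfg)
    nb = P.shape[0]
    i = np.arange(1, nb + 1)[:, None] * np.ones((1, nb))
    j = i.T
    nz = P > 0
    pi = P.sum(axis=1)  # marginal (symmetric => both marginals equal)
    mu = np.sum(np.arange(1, nb + 1) * pi)
    var = np.sum((np.arange(1, nb + 1) - mu) ** 2 * pi)
    autoc = float(np.sum(i * j * P))
    if var > 0:
        corr = (autoc - mu * mu) / var
    else:
        corr = 1.0  # degenerate single-level ROI
    return {
        "joint_average": float(np.sum(i * P)),
        "autocorrelation": autoc,
        "sum_average": float(np.sum((i + j) * P)),
        "joint_entropy": float(-np.sum(P[nz] * np.log2(P[nz]))),
        "contrast": float(np.sum((i - j) ** 2 * P)),
        "correlation": float(corr),
        "joint_maximum": float(P.max()),
        "inverse_difference": float(np.sum(P / (1.0 + np.abs(i - j)))),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _lines(L: np.ndarray, direction: tuple[int, int]):
    """Scan lines of the level image (0 = outside ROI) along a direction."""
    if direction == (0, 1):
        yield from L
    elif direction == (-1, 0):
        yield from L.T
    elif direction == (-1, 1):  # anti-diagonals, traversed consistently
        F = np.flipud(L)
        for k in range(-F.shape[0] + 1, F.shape[1]):
            yield np.diagonal(F, offset=k)
    elif direction == (-1, -1):
        F = np.flipud(np.fliplr(L))
        for k in range(-F.shape[0] + 1, F.shape[1]):
            yield np.diagonal(F, offset=k)
    else:  # pragma: no cover
        raise ValueError(direction)


def _accumulate_runs(concat: np.ndarray, R: np.ndarray) -> None:
    """Vectorized run-length accumulation over concatenated scan lines
    (0 separates lines and breaks runs)."""
    n = len(concat)
    if n == 0:
        return
    change = np.flatnonzero(np.diff(concat) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))
    vals = concat[starts]
    keep = vals > 0
    lens = (ends - starts + 1)[keep]
    np.add.at(R, (vals[keep] - 1, lens - 1), 1.0)


def _glrlm_matrices(
    d: DiscretizedROI, directions: tuple = DIRECTIONS_2D
) -> list[np.ndarray]:
    L, M = _crop(d)
    Lm = np.where(M, L, 0)
    nb = d.n_bins
    max_len = max(Lm.shape)
    zero = np.zeros(1, dtype=Lm.dtype)
    mats = []
    for direction in directions:
        R = np.zeros((nb, max_len))
        parts: list[np.ndarray] = []
        for line in _lines(Lm, direction):
            parts.append(np.asarray(line))
            parts.append(zero)
        _accumulate_runs(np.concatenate(parts), R)
        mats.append(R)
    return mats


def glrlm_features(d: DiscretizedROI, cfg: TextureConfig | None = None) -> dict[str, float]:
    cfg = cfg or TextureConfig()
    mats = _glrlm_matrices(d, cfg.directions)
    n_pix = int(d.mask.sum())
    p = np.mean([R / R.sum() for R in mats], axis=0)
    nb, ml = p.shape
    i = np.arange(1, nb + 1)[:, None]
    j = np.arange(1, ml + 1)[None, :]
    glnu = float(np.mean([np.sum(R.sum(axis=1) ** 2) / R.sum() for R in mats]))
    rlnu = float(np.mean([np.sum(R.sum(axis=0) ** 2) / R.sum() for R in mats]))
    return {
        "short_run_emphasis": float(np.sum(p / j**2)),
        "long_run_emphasis": float(np.sum(p * j**2)),
        "high_grey_level_run_emphasis": float(np.sum(p * i**2)),
        "low_grey_level_run_emphasis": float(np.sum(p / i**2)),
        "run_percentage": float(np.mean([R.sum() / n_pix for R in mats])),
        "grey_level_non_uniformity": glnu,
        "run_length_non_uniformity": rlnu,
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT8 = np.ones((3, 3), dtype=int)


def _glszm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Zone counts s(i, j): 8-connected components of equal grey level."""
    L, M = _crop(d)
    nb = d.n_bins
    max_size = int(M.sum())
    S = np.zeros((nb, max_size))
    for lv in np.unique(L[M]):
        lab, n = ndimage.label((L == lv) & M, structure=_STRUCT8)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            S[lv - 1, sz - 1] += 1
    return S


def glszm_features(d: DiscretizedROI) -> dict[str, float]:
    S = _glszm_matrix(d)
    n_pix = int(d.mask.sum())
    n_zones = S.sum()
    p = S / n_zones
    nb, ms = p.shape
    i = np.arange(1, nb + 1)[:, None]
    j = np.arange(1, ms + 1)[None, :]
    return {
        "small_zone_emphasis": float(np.sum(p / j**2)),
        "large_zone_emphasis": float(np.sum(p * j**2)),
        "zone_percentage": float(n_zones / n_pix),
        "grey_level_non_uniformity": float(np.sum(S.sum(axis=1) ** 2) / n_zones),
        "zone_size_non_uniformity": float(np.sum(S.sum(axis=0) ** 2) / n_zones),
        "high_grey_level_zone_emphasis": float(np.sum(p * i**2)),
        "low_grey_level_zone_emphasis": float(np.sum(p / i**2)),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def _ngtdm_table(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-level (n_i, p_i, s_i) over ROI pixels that have at least one
    in-ROI Chebyshev-1 neighbour."""
    L, M = _crop(d)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    cnt = ndimage.convolve(M.astype(float), kernel, mode="constant", cval=0.0)
    ssum = ndimage.convolve(np.where(M, L, 0).astype(float), kernel,
                            mode="constant", cval=0.0)
    valid = M & (cnt > 0)
    if not valid.any():
        raise ValueError("NGTDM undefined: no ROI pixel has an in-ROI neighbour")
    levels = L[valid]
    abar = ssum[valid] / cnt[valid]
    nb = d.n_bins
    n_i = np.bincount(levels, minlength=nb + 1)[1:].astype(float)
    s_i = np.zeros(nb)
    np.add.at(s_i, levels - 1, np.abs(levels - abar))
    N = int(valid.sum())
    return n_i, n_i / N, s_i, N


def ngtdm_features(d: DiscretizedROI, cfg: TextureConfig | None = None) -> dict[str, float]:
    _, p, s, N = _ngtdm_table(d)
    nz = np.flatnonzero(p)
    lv = nz + 1.0
    pv, sv = p[nz], s[nz]
    ngp = len(nz)
    den = float(np.sum(pv * sv))
    coarseness = NGTDM_COARSENESS_CAP if den == 0 else min(1.0 / den, NGTDM_COARSENESS_CAP)
    ii = lv[:, None]
    jj = lv[None, :]
    pij = pv[:, None] * pv[None, :]
    if ngp > 1:
        contrast = (np.sum(pij * (ii - jj) ** 2) / (ngp * (ngp - 1))) * (s.sum() / N)
    else:
        contrast = 0.0
    busy_den = float(np.sum(np.abs(ii * pv[:, None] - jj * pv[None, :])))
    busyness = den / busy_den if busy_den > 0 else 0.0
    ps = pv * sv
    complexity = float(
        np.sum(np.abs(ii - jj) * (ps[:, None] + ps[None, :])
               / (pv[:, None] + pv[None, :]))
    ) / N
    s_sum = float(s.sum())
    strength = (
        float(np.sum((pv[:, None] + pv[None, :]) * (ii - jj) ** 2)) / s_sum
        if s_sum > 0 else 0.0
    )
    return {
        "coarseness": float(coarseness),
        "contrast": float(contrast),
        "busyness": float(busyness),
        "complexity": float(complexity),
        "strength": float(strength),
    }


# ---------------------------------------------------------------------------
# NGLDM
# ---------------------------------------------------------------------------

def _ngldm_matrix(d: DiscretizedROI, cfg: TextureConfig) -> np.ndarray:
    """Dependence counts s(i, j): j = 1 + number of in-ROI Chebyshev-1
    neighbours whose level differs from the centre by <= alpha (the centre
    itself contributes the 1)."""
    L, M = _crop(d)
    h, w = L.shape
    Lp = np.pad(L, 1)
    Mp = np.pad(M, 1)
    dep = np.ones(L.shape, dtype=np.int64)
    for dy, dx in _NEIGH8:
        nL = Lp[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
        nM = Mp[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
        dep += (nM & (np.abs(nL - L) <= cfg.ngldm_alpha)) & M
    nb = d.n_bins
    S = np.zeros((nb, 9))
    np.add.at(S, (L[M] - 1, dep[M] - 1), 1.0)
    return S


def ngldm_features(d: DiscretizedROI, cfg: TextureConfig | None = None) -> dict[str, float]:
    cfg = cfg or TextureConfig()
    S = _ngldm_matrix(d, cfg)
    N = S.sum()
    p = S / N
    nb, mj = p.shape
    i = np.arange(1, nb + 1)[:, None]
    j = np.arange(1, mj + 1)[None, :]
    nz = p > 0
    mu_j = float(np.sum(j * p))
    return {
        "dependence_count_energy": float(np.sum(p**2)),
        "dependence_count_variance": float(np.sum(p * (j - mu_j) ** 2)),
        "high_grey_level_count_emphasis": float(np.sum(p * i**2)),
        "low_grey_level_count_emphasis": float(np.sum(p / i**2)),
        "dependence_count_entropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
    }


# ---------------------------------------------------------------------------
# full bank
# ---------------------------------------------------------------------------

_MATRIX_FAMILIES = {
    "glcm": lambda d, cfg: glcm_features(d, cfg),
    "glrlm": lambda d, cfg: glrlm_features(d, cfg),
    "glszm": lambda d, cfg: glszm_features(d),
    "ngtdm": lambda d, cfg: ngtdm_features(d, cfg),
    "ngldm": lambda d, cfg: ngldm_features(d, cfg),
}


def extract_all(
    image: GrayImage,
    mask: ROIMask,
    prep: PrepConfig | None = None,
    filters: list[FilterSpec] | None = None,
    tex: TextureConfig | None = None,
    families: tuple[str, ...] = FAMILIES,
) -> dict[str, float]:
    """Extract the full feature bank for one case.

    For each filter: apply the filter, resample (texture cap for the matrix
    families, the lower cap for the first-order families), FBN-discretize the
    filtered ROI over its own min/max, and run the requested families.
    """
    prep = prep or PrepConfig()
    filters = filters if filters is not None else default_filter_bank()
    tex = tex or TextureConfig()
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}")
    out: dict[str, float] = {}
    for spec in filters:
        try:
            filtered = apply_filter(image, spec, mask)
            if any(f in families for f in ("stats", "hist")):
                img_o, mask_o = resample_isotropic(filtered, mask, prep, "other")
                if "stats" in families:
                    feats = intensity_statistics(img_o.values[mask_o.values])
                    out.update({f"{spec.kind}__stats__{k}": v for k, v in feats.items()})
                if "hist" in families:
                    feats = intensity_histogram_features(
                        discretize_fbn(img_o, mask_o, prep)
                    )
                    out.update({f"{spec.kind}__hist__{k}": v for k, v in feats.items()})
            wanted = [f for f in families if f in _MATRIX_FAMILIES]
            if wanted:
                img_t, mask_t = resample_isotropic(filtered, mask, prep, "texture")
                d = discretize_fbn(img_t, mask_t, prep)
                for fam in wanted:
                    feats = _MATRIX_FAMILIES[fam](d, tex)
                    out.update({f"{spec.kind}__{fam}__{k}": v for k, v in feats.items()})
        except ValueError as exc:
            raise ValueError(f"feature extraction failed (filter={spec.kind}): {exc}") from exc
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features: {bad[:5]}")
    return out


def extract_table(
    cases,
    prep: PrepConfig | None = None,
    filters: list[FilterSpec] | None = None,
    tex: TextureConfig | None = None,
    families: tuple[str, ...] = FAMILIES,
):
    """Extract the bank for a list of cases into a DataFrame
    (case_id, label, then one column per feature)."""
    import pandas as pd

    rows = []
    for case in cases:
        feats = extract_all(case.image, case.mask, prep, filters, tex, families)
        rows.append({"case_id": case.case_id, "label": case.label, **feats})
    df = pd.DataFrame(rows)
    names = [c for c in df.columns if c not in ("case_id", "label")]
    if len(set(names)) != len(names):  # pragma: no cover
        raise ValueError("duplicate feature names")
    return df


def feature_schema(df) -> list[dict]:
    """Filter/family/feature provenance per feature column."""
    schema = []
    for col in df.columns:
        if col in ("case_id", "label"):
            continue
        filt, family, feat = col.split("__", 2)
        schema.append({"column": col, "filter": filt, "family": family, "feature": feat})
    return schema
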