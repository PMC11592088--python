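"""Independent brute-force oracles for the texture-matrix families.

Everything here is written with explicit Python loops over pixels, pairs,
runs, zones and neighbourhoods — no shared code with the package — and
encodes the same documented conventions (4-direction merge by averaging
normalized matrices, count-based non-uniformities averaged per direction,
NGLDM dependence count includes the centre pixel, NGTDM coarseness capped
at 1e6).
"""

from __future__ import annotations

import math

import numpy as np

DIRS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]
NEIGH8 = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
CAP = 1e6


def _inside(M, y, x):
    return 0 <= y < M.shape[0] and 0 <= x < M.shape[1] and M[y, x]


# ------------------------------------------------------------------ GLCM

def glcm_bf(L, M, nb, distance=1, dirs=DIRS):
    mats = []
    for dy, dx in dirs:
        P = np.zeros((nb, nb))
        for y in range(L.shape[0]):
            for x in range(L.shape[1]):
                y2, x2 = y + dy * distance, x + dx * distance
                if M[y, x] and _inside(M, y2, x2):
                    P[L[y, x] - 1, L[y2, x2] - 1] += 1
                    P[L[y2, x2] - 1, L[y, x] - 1] += 1  # symmetric
        if P.sum() > 0:
            mats.append(P / P.sum())
    P = sum(mats) / len(mats)
    feats = {}
    nzsum = 0.0
    ja = ac = sa = je = co = jm = idm = 0.0
    mu = 0.0
    pi = P.sum(axis=1)
    for i in range(nb):
        mu += (i + 1) * pi[i]
    var = sum((i + 1 - mu) ** 2 * pi[i] for i in range(nb))
    for i in range(nb):
        for j in range(nb):
            p = P[i, j]
            ja += (i + 1) * p
            ac += (i + 1) * (j + 1) * p
            sa += (i + 1 + j + 1) * p
            co += (i - j) ** 2 * p
            idm += p / (1 + abs(i - j))
            if p > 0:
                je -= p * math.log2(p)
            jm = max(jm, p)
    corr = (ac - mu * mu) / var if var > 0 else 1.0
    return {
        "joint_average": ja, "autocorrelation": ac, "sum_average": sa,
        "joint_entropy": je, "contrast": co, "correlation": corr,
        "joint_maximum": jm, "inverse_difference": idm,
    }


# ------------------------------------------------------------------ GLRLM

def _runs_bf(L, M, dy, dx):
    """Enumerate maximal runs along (dy, dx) by walking each line."""
    h, w = L.shape
    runs = []
    seen = np.zeros_like(M, dtype=bool)
    for y in range(h):
        for x in range(w):
            if not M[y, x] or seen[y, x]:
                continue
            py, px = y - dy, x - dx
            if _inside(M, py, px) and L[py, px] == L[y, x]:
                continue  # not the start of a run
            ln = 0
            cy, cx = y, x
            while _inside(M, cy, cx) and L[cy, cx] == L[y, x]:
                seen[cy, cx] = True
                ln += 1
                cy, cx = cy + dy, cx + dx
            runs.append((L[y, x], ln))
    return runs


def glrlm_bf(L, M, nb, dirs=DIRS):
    n_pix = int(M.sum())
    max_len = max(L.shape)
    mats = []
    for dy, dx in dirs:
        R = np.zeros((nb, max_len))
        for lv, ln in _runs_bf(L, M, dy, dx):
            R[lv - 1, ln - 1] += 1
        mats.append(R)
    p = sum(R / R.sum() for R in mats) / len(mats)
    sre = lre = hgl = lgl = 0.0
    for i in range(nb):
        for j in range(max_len):
            sre += p[i, j] / (j + 1) ** 2
            lre += p[i, j] * (j + 1) ** 2
            hgl += p[i, j] * (i + 1) ** 2
            lgl += p[i, j] / (i + 1) ** 2
    glnu = float(np.mean([sum(R.sum(axis=1) ** 2) / R.sum() for R in mats]))
    rlnu = float(np.mean([sum(R.sum(axis=0) ** 2) / R.sum() for R in mats]))
    rp = float(np.mean([R.sum() / n_pix for R in mats]))
    return {
        "short_run_emphasis": sre, "long_run_emphasis": lre,
        "high_grey_level_run_emphasis": hgl, "low_grey_level_run_emphasis": lgl,
        "run_percentage": rp, "grey_level_non_uniformity": glnu,
        "run_length_non_uniformity": rlnu,
    }


# ------------------------------------------------------------------ GLSZM

def zones_bf(L, M):
    """8-connected equal-level zones by explicit flood fill."""
    h, w = L.shape
    seen = np.zeros_like(M, dtype=bool)
    zones = []
    for y in range(h):
        for x in range(w):
            if not M[y, x] or seen[y, x]:
                continue
            lv = L[y, x]
            stack, size = [(y, x)], 0
            seen[y, x] = True
            while stack:
                cy, cx = stack.pop()
                size += 1
                for dy, dx in NEIGH8:
                    ny, nx = cy + dy, cx + dx
                    if _inside(M, ny, nx) and not seen[ny, nx] and L[ny, nx] == lv:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            zones.append((lv, size))
    return zones


def glszm_bf(L, M, nb):
    zones = zones_bf(L, M)
    n_pix = int(M.sum())
    nz = len(zones)
    sze = lze = hgl = lgl = 0.0
    per_level = {}
    per_size = {}
    for lv, sz in zones:
        sze += (1 / sz**2) / nz
        lze += (sz**2) / nz
        hgl += (lv**2) / nz
        lgl += (1 / lv**2) / nz
        per_level[lv] = per_level.get(lv, 0) + 1
        per_size[sz] = per_size.get(sz, 0) + 1
    return {
        "small_zone_emphasis": sze, "large_zone_emphasis": lze,
        "zone_percentage": nz / n_pix,
        "grey_level_non_uniformity": sum(c**2 for c in per_level.values()) / nz,
        "zone_size_non_uniformity": sum(c**2 for c in per_size.values()) / nz,
        "high_grey_level_zone_emphasis": hgl, "low_grey_level_zone_emphasis": lgl,
    }


# ------------------------------------------------------------------ NGTDM

def ngtdm_table_bf(L, M, nb):
    """(n_i, p_i, s_i, N) by looping every in-ROI pixel's neighbourhood."""
    n = np.zeros(nb)
    s = np.zeros(nb)
    N = 0
    for y in range(L.shape[0]):
        for x in range(L.shape[1]):
            if not M[y, x]:
                continue
            neigh = [L[y + dy, x + dx] for dy, dx in NEIGH8 if _inside(M, y + dy, x + dx)]
            if not neigh:
                continue
            N += 1
            i = L[y, x]
            n[i - 1] += 1
            s[i - 1] += abs(i - sum(neigh) / len(neigh))
    return n, n / N, s, N


def ngtdm_bf(L, M, nb):
    _, p, s, N = ngtdm_table_bf(L, M, nb)
    present = [i for i in range(nb) if p[i] > 0]
    den = sum(p[i] * s[i] for i in present)
    coarseness = CAP if den == 0 else min(1.0 / den, CAP)
    ngp = len(present)
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
        ) * (sum(s) / N)
    else:
        contrast = 0.0
    busy_den = sum(
        abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
    )
    busyness = den / busy_den if busy_den > 0 else 0.0
    complexity = sum(
        abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
        for i in present for j in present
    ) / N
    s_sum = sum(s)
    strength = (
        sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / s_sum
        if s_sum > 0 else 0.0
    )
    return {
        "coarseness": coarseness, "contrast": contrast, "busyness": busyness,
        "complexity": complexity, "strength": strength,
    }


# ------------------------------------------------------------------ NGLDM

def ngldm_matrix_bf(L, M, nb, alpha=0):
    S = np.zeros((nb, 9))
    for y in range(L.shape[0]):
        for x in range(L.shape[1]):
            if not M[y, x]:
                continue
            j = 1  # centre pixel counts itself
            for dy, dx in NEIGH8:
                if _inside(M, y + dy, x + dx) and abs(int(L[y + dy, x + dx]) - int(L[y, x])) <= alpha:
                    j += 1
            S[L[y, x] - 1, j - 1] += 1
    return S


def ngldm_bf(L, M, nb, alpha=0):
    S = ngldm_matrix_bf(L, M, nb, alpha)
    N = S.sum()
    dce = dcv = hgl = lgl = ent = mu_j = 0.0
    for i in range(nb):
        for j in range(9):
            p = S[i, j] / N
            mu_j += (j + 1) * p
    for i in range(nb):
        for j in range(9):
            p = S[i, j] / N
            dce += p**2
            dcv += p * (j + 1 - mu_j) ** 2
            hgl += p * (i + 1) ** 2
            lgl += p / (i + 1) ** 2
            if p > 0:
                ent -= p * math.log2(p)
    return {
        "dependence_count_energy": dce, "dependence_count_variance": dcv,
        "high_grey_level_count_emphasis": hgl, "low_grey_level_count_emphasis": lgl,
        "dependence_count_entropy": ent,
    }
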