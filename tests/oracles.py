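"""Independent brute-force oracles for the test-suite.

Everything here is written as plain per-pixel / per-entry Python loops,
deliberately sharing no code path with the vectorized implementations
under test.  Matrices are enumerated pixel by pixel; feature formulas
are re-stated as explicit summations over matrix entries.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS4 = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]
NEIGHBOURS8 = [
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
]


def _xlog2(v: float) -> float:
    return v * math.log2(v) if v > 0 else 0.0


def _inside(shape, r, c):
    return 0 <= r < shape[0] and 0 <= c < shape[1]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(levels, mask, ng):
    counts = np.zeros((ng, ng))
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in OFFSETS4:
                for sign in (1, -1):
                    rr, cc = r + sign * dr, c + sign * dc
                    if _inside(mask.shape, rr, cc) and mask[rr, cc]:
                        counts[levels[r, c] - 1, levels[rr, cc] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def glcm_features(P):
    ng = P.shape[0]
    out = {name: 0.0 for name in (
        "autocorrelation", "cluster_prominence", "cluster_shade", "cluster_tendency",
        "contrast", "correlation", "difference_average", "difference_entropy",
        "difference_variance", "id", "idm", "idmn", "idn", "imc1", "imc2",
        "inverse_variance", "joint_average", "joint_energy", "joint_entropy",
        "maximum_probability", "mcc", "sum_average", "sum_entropy", "sum_squares")}
    if P.sum() == 0:
        out["correlation"] = 1.0
        out["mcc"] = 1.0
        return out
    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * P[i, j] for i in range(ng) for j in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * P[i, j] for i in range(ng) for j in range(ng))
    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += P[i, j]
            p_sum[i + j] += P[i, j]
    da = sum(k * p_diff[k] for k in range(ng))
    out["autocorrelation"] = sum((i + 1) * (j + 1) * P[i, j] for i in range(ng) for j in range(ng))
    out["joint_average"] = mu
    for power, name in ((2, "cluster_tendency"), (3, "cluster_shade"), (4, "cluster_prominence")):
        out[name] = sum((i + 1 + j + 1 - 2 * mu) ** power * P[i, j] for i in range(ng) for j in range(ng))
    out["contrast"] = sum((i - j) ** 2 * P[i, j] for i in range(ng) for j in range(ng))
    out["correlation"] = 1.0 if sigma2 <= 0 else (out["autocorrelation"] - mu * mu) / sigma2
    out["difference_average"] = da
    out["difference_entropy"] = -sum(_xlog2(p) for p in p_diff)
    out["difference_variance"] = sum((k - da) ** 2 * p_diff[k] for k in range(ng))
    out["id"] = sum(p_diff[k] / (1 + k) for k in range(ng))
    out["idm"] = sum(p_diff[k] / (1 + k * k) for k in range(ng))
    out["idmn"] = sum(p_diff[k] / (1 + (k / ng) ** 2) for k in range(ng))
    out["idn"] = sum(p_diff[k] / (1 + k / ng) for k in range(ng))
    out["inverse_variance"] = sum(p_diff[k] / k**2 for k in range(1, ng))
    out["joint_energy"] = sum(P[i, j] ** 2 for i in range(ng) for j in range(ng))
    hxy = -sum(_xlog2(P[i, j]) for i in range(ng) for j in range(ng))
    out["joint_entropy"] = hxy
    out["maximum_probability"] = P.max()
    out["sum_average"] = sum((k + 2) * p_sum[k] for k in range(2 * ng - 1))
    out["sum_entropy"] = -sum(_xlog2(p) for p in p_sum)
    out["sum_squares"] = sigma2
    hx = -sum(_xlog2(p) for p in px)
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * px[j])
        for i in range(ng) for j in range(ng) if px[i] * px[j] > 0 and P[i, j] > 0
    )
    hxy2 = -sum(_xlog2(px[i] * px[j]) for i in range(ng) for j in range(ng))
    out["imc1"] = 0.0 if hx == 0 else (hxy - hxy1) / hx
    out["imc2"] = 0.0 if hxy2 < hxy else math.sqrt(1.0 - math.exp(-2.0 * (hxy2 - hxy)))
    keep = [i for i in range(ng) if px[i] > 0]
    if len(keep) <= 1:
        out["mcc"] = 1.0
    else:
        q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                q[a, b] = sum(
                    P[i, k] * P[j, k] / (px[i] * px[k]) for k in keep
                )
        eig = sorted(np.real(np.linalg.eigvals(q)))
        out["mcc"] = math.sqrt(max(eig[-2], 0.0))
    return out


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(levels, mask, ng, alpha=0):
    counts = np.zeros((ng, 9))
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = 0
            for dr, dc in NEIGHBOURS8:
                rr, cc = r + dr, c + dc
                if _inside(mask.shape, rr, cc) and mask[rr, cc]:
                    if abs(int(levels[r, c]) - int(levels[rr, cc])) <= alpha:
                        dep += 1
            counts[levels[r, c] - 1, dep] += 1
    return counts


def gldm_features(counts):
    names = (
        "dependence_entropy", "dependence_non_uniformity",
        "dependence_non_uniformity_normalized", "dependence_variance",
        "gray_level_non_uniformity", "gray_level_variance", "high_gray_level_emphasis",
        "large_dependence_emphasis", "large_dependence_high_gray_level_emphasis",
        "large_dependence_low_gray_level_emphasis", "low_gray_level_emphasis",
        "small_dependence_emphasis", "small_dependence_high_gray_level_emphasis",
        "small_dependence_low_gray_level_emphasis")
    out = {n: 0.0 for n in names}
    nz = counts.sum()
    if nz == 0:
        return out
    ng, nd = counts.shape
    p = counts / nz
    mu_i = sum((i + 1) * p[i, j] for i in range(ng) for j in range(nd))
    mu_j = sum((j + 1) * p[i, j] for i in range(ng) for j in range(nd))
    for i in range(ng):
        for j in range(nd):
            pij = p[i, j]
            gi, dj = i + 1.0, j + 1.0
            out["small_dependence_emphasis"] += pij / dj**2
            out["large_dependence_emphasis"] += pij * dj**2
            out["gray_level_variance"] += pij * (gi - mu_i) ** 2
            out["dependence_variance"] += pij * (dj - mu_j) ** 2
            out["dependence_entropy"] -= _xlog2(pij)
            out["low_gray_level_emphasis"] += pij / gi**2
            out["high_gray_level_emphasis"] += pij * gi**2
            out["small_dependence_low_gray_level_emphasis"] += pij / (gi**2 * dj**2)
            out["small_dependence_high_gray_level_emphasis"] += pij * gi**2 / dj**2
            out["large_dependence_low_gray_level_emphasis"] += pij * dj**2 / gi**2
            out["large_dependence_high_gray_level_emphasis"] += pij * gi**2 * dj**2
    out["gray_level_non_uniformity"] = sum(counts[i, :].sum() ** 2 for i in range(ng)) / nz
    dn = sum(counts[:, j].sum() ** 2 for j in range(nd)) / nz
    out["dependence_non_uniformity"] = dn
    out["dependence_non_uniformity_normalized"] = dn / nz
    return out


# ---------------------------------------------------------------------------
# GLRLM / GLSZM
# ---------------------------------------------------------------------------

def _walk_lines(shape, offset):
    """Starting points and steps covering the grid for one direction."""
    h, w = shape
    dr, dc = offset
    starts = []
    if (dr, dc) == (0, 1):
        starts = [(r, 0) for r in range(h)]
    elif (dr, dc) == (-1, 0):
        # walk downwards from the top row; run content is direction-symmetric
        starts = [(0, c) for c in range(w)]
        dr, dc = 1, 0
    elif (dr, dc) == (-1, -1):
        # anti-parallel walk of the main diagonals
        starts = [(0, c) for c in range(w)] + [(r, 0) for r in range(1, h)]
        dr, dc = 1, 1
    elif (dr, dc) == (-1, 1):
        starts = [(0, c) for c in range(w)] + [(r, w - 1) for r in range(1, h)]
        dr, dc = 1, -1
    return starts, (dr, dc)


def glrlm_matrix(levels, mask, ng, offset):
    h, w = mask.shape
    counts = np.zeros((ng, max(h, w)))
    starts, (dr, dc) = _walk_lines(mask.shape, offset)
    for r0, c0 in starts:
        r, c = r0, c0
        run_level, run_len = 0, 0
        while _inside(mask.shape, r, c):
            lv = levels[r, c] if mask[r, c] else 0
            if lv == run_level:
                run_len += 1
            else:
                if run_level > 0:
                    counts[run_level - 1, run_len - 1] += 1
                run_level, run_len = lv, 1
            r, c = r + dr, c + dc
        if run_level > 0:
            counts[run_level - 1, run_len - 1] += 1
    return counts


def rlm_features(counts, n_pixels, roles):
    out = {name: 0.0 for name in roles.values()}
    nr = counts.sum()
    if nr == 0:
        return out
    ng, nl = counts.shape
    p = counts / nr
    mu_i = sum((i + 1) * p[i, l] for i in range(ng) for l in range(nl))
    mu_l = sum((l + 1) * p[i, l] for i in range(ng) for l in range(nl))
    for i in range(ng):
        for l in range(nl):
            pij = p[i, l]
            gi, ll = i + 1.0, l + 1.0
            out[roles["sre"]] += pij / ll**2
            out[roles["lre"]] += pij * ll**2
            out[roles["glv"]] += pij * (gi - mu_i) ** 2
            out[roles["rv"]] += pij * (ll - mu_l) ** 2
            out[roles["re"]] -= _xlog2(pij)
            out[roles["lglre"]] += pij / gi**2
            out[roles["hglre"]] += pij * gi**2
            out[roles["srlgle"]] += pij / (gi**2 * ll**2)
            out[roles["srhgle"]] += pij * gi**2 / ll**2
            out[roles["lrlgle"]] += pij * ll**2 / gi**2
            out[roles["lrhgle"]] += pij * ll**2 * gi**2
    out[roles["gln"]] = sum(counts[i, :].sum() ** 2 for i in range(ng)) / nr
    out[roles["glnn"]] = sum(counts[i, :].sum() ** 2 for i in range(ng)) / nr**2
    out[roles["rln"]] = sum(counts[:, l].sum() ** 2 for l in range(nl)) / nr
    out[roles["rlnn"]] = sum(counts[:, l].sum() ** 2 for l in range(nl)) / nr**2
    out[roles["rp"]] = nr / n_pixels if n_pixels else 0.0
    return out


GLRLM_ROLES = {
    "sre": "short_run_emphasis", "lre": "long_run_emphasis",
    "gln": "gray_level_non_uniformity", "glnn": "gray_level_non_uniformity_normalized",
    "rln": "run_length_non_uniformity", "rlnn": "run_length_non_uniformity_normalized",
    "rp": "run_percentage", "glv": "gray_level_variance", "rv": "run_variance",
    "re": "run_entropy", "lglre": "low_gray_level_run_emphasis",
    "hglre": "high_gray_level_run_emphasis",
    "srlgle": "short_run_low_gray_level_emphasis",
    "srhgle": "short_run_high_gray_level_emphasis",
    "lrlgle": "long_run_low_gray_level_emphasis",
    "lrhgle": "long_run_high_gray_level_emphasis"}

GLSZM_ROLES = {
    "sre": "small_area_emphasis", "lre": "large_area_emphasis",
    "gln": "gray_level_non_uniformity", "glnn": "gray_level_non_uniformity_normalized",
    "rln": "size_zone_non_uniformity", "rlnn": "size_zone_non_uniformity_normalized",
    "rp": "zone_percentage", "glv": "gray_level_variance", "rv": "zone_variance",
    "re": "zone_entropy", "lglre": "low_gray_level_zone_emphasis",
    "hglre": "high_gray_level_zone_emphasis",
    "srlgle": "small_area_low_gray_level_emphasis",
    "srhgle": "small_area_high_gray_level_emphasis",
    "lrlgle": "large_area_low_gray_level_emphasis",
    "lrhgle": "large_area_high_gray_level_emphasis"}


def glrlm_features(levels, mask, ng):
    n_pixels = int(mask.sum())
    acc = {name: 0.0 for name in GLRLM_ROLES.values()}
    for offset in OFFSETS4:
        counts = glrlm_matrix(levels, mask, ng, offset)
        for name, value in rlm_features(counts, n_pixels, GLRLM_ROLES).items():
            acc[name] += value
    return {name: value / 4.0 for name, value in acc.items()}


def glszm_zones(levels, mask):
    """All 8-connected constant-level zones via explicit BFS flood fill."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            level = levels[r, c]
            queue = [(r, c)]
            seen[r, c] = True
            size = 0
            while queue:
                rr, cc = queue.pop()
                size += 1
                for dr, dc in NEIGHBOURS8:
                    r2, c2 = rr + dr, cc + dc
                    if (
                        _inside(mask.shape, r2, c2)
                        and mask[r2, c2]
                        and not seen[r2, c2]
                        and levels[r2, c2] == level
                    ):
                        seen[r2, c2] = True
                        queue.append((r2, c2))
            zones.append((int(level), size))
    return zones


def glszm_matrix(levels, mask, ng):
    n_pixels = int(mask.sum())
    counts = np.zeros((ng, max(n_pixels, 1)))
    for level, size in glszm_zones(levels, mask):
        counts[level - 1, size - 1] += 1
    return counts


def glszm_features(levels, mask, ng):
    return rlm_features(glszm_matrix(levels, mask, ng), int(mask.sum()), GLSZM_ROLES)


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(levels, mask, ng):
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nbrs = [
                levels[r + dr, c + dc]
                for dr, dc in NEIGHBOURS8
                if _inside(mask.shape, r + dr, c + dc) and mask[r + dr, c + dc]
            ]
            if not nbrs:
                continue
            n_i[levels[r, c] - 1] += 1
            s_i[levels[r, c] - 1] += abs(levels[r, c] - sum(nbrs) / len(nbrs))
    return n_i, s_i


def ngtdm_features(levels, mask, ng, cap=1.0e6):
    n_i, s_i = ngtdm_table(levels, mask, ng)
    out = {n: 0.0 for n in ("busyness", "coarseness", "complexity", "contrast", "strength")}
    nvp = n_i.sum()
    if nvp == 0:
        out["coarseness"] = cap
        return out
    p_i = n_i / nvp
    occ = [i for i in range(ng) if p_i[i] > 0]
    denom = sum(p_i[i] * s_i[i] for i in range(ng))
    out["coarseness"] = cap if denom == 0 else min(1.0 / denom, cap)
    if len(occ) > 1:
        ngp = len(occ)
        out["contrast"] = (
            sum(p_i[i] * p_i[j] * (i - j) ** 2 for i in occ for j in occ)
            / (ngp * (ngp - 1)) * (s_i.sum() / nvp)
        )
        busy_den = sum(
            abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in occ for j in occ
        )
        out["busyness"] = 0.0 if busy_den == 0 else denom / busy_den
        out["complexity"] = sum(
            abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j]) / (p_i[i] + p_i[j])
            for i in occ for j in occ
        ) / nvp
        s_total = s_i.sum()
        if s_total > 0:
            out["strength"] = (
                sum((p_i[i] + p_i[j]) * (i - j) ** 2 for i in occ for j in occ) / s_total
            )
    return out


# ---------------------------------------------------------------------------
# Segmentation and AUC oracles
# ---------------------------------------------------------------------------

def brute_annulus(wall, diameter_mm, spacing_mm):
    """Exhaustive per-voxel annulus: min distance to any wall voxel."""
    h, w = wall.shape
    dy, dx = spacing_mm
    wall_pts = [(r, c) for r in range(h) for c in range(w) if wall[r, c]]
    out = np.zeros_like(wall, dtype=bool)
    for r in range(h):
        for c in range(w):
            if wall[r, c]:
                continue
            dmin = min(
                math.hypot((r - rr) * dy, (c - cc) * dx) for rr, cc in wall_pts
            )
            out[r, c] = 0 < dmin <= diameter_mm
    return out


def mann_whitney_auc(scores, y):
    """Pairwise-counting AUC with half-credit for ties."""
    pos = [s for s, lab in zip(scores, y) if lab == 1]
    neg = [s for s, lab in zip(scores, y) if lab == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
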