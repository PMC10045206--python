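"""Gray-level texture matrices and their derived features.

Implements the five classic 2-D texture families on discretized
gray-level slices: co-occurrence (GLCM), dependence (GLDM), run length
(GLRLM), size zone (GLSZM) and neighbouring gray-tone difference
(NGTDM).  Conventions follow common radiomics practice:

* distance 1, the four 2-D angles 0/45/90/135 degrees;
* GLCM is angle-summed, symmetrised and normalised to sum 1;
* GLRLM features are computed per angle and averaged;
* GLDM uses alpha = 0 (neighbours "depend" when their level is equal)
  over the 8-neighbourhood, with dependence recorded as count + 1;
* GLSZM zones are 8-connected components of constant level;
* logarithms are base 2 with the 0*log(0) = 0 convention.

Degenerate masks (a single pixel, a single gray level, no valid
neighbour pairs) return the conventional values documented on each
function rather than NaN, so tiny PCAT slices never break aggregation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# (dr, dc) offsets for angles 0, 45, 90, 135 degrees at distance 1
ANGLE_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

# 8-neighbourhood offsets
NEIGHBOUR_OFFSETS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)

GLCM_FEATURES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "id",
    "idm",
    "idmn",
    "idn",
    "imc1",
    "imc2",
    "inverse_variance",
    "joint_average",
    "joint_energy",
    "joint_entropy",
    "maximum_probability",
    "mcc",
    "sum_average",
    "sum_entropy",
    "sum_squares",
)

GLDM_FEATURES = (
    "dependence_entropy",
    "dependence_non_uniformity",
    "dependence_non_uniformity_normalized",
    "dependence_variance",
    "gray_level_non_uniformity",
    "gray_level_variance",
    "high_gray_level_emphasis",
    "large_dependence_emphasis",
    "large_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "low_gray_level_emphasis",
    "small_dependence_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "small_dependence_low_gray_level_emphasis",
)

GLRLM_FEATURES = (
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "gray_level_variance",
    "high_gray_level_run_emphasis",
    "long_run_emphasis",
    "long_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "low_gray_level_run_emphasis",
    "run_entropy",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalized",
    "run_percentage",
    "run_variance",
    "short_run_emphasis",
    "short_run_high_gray_level_emphasis",
    "short_run_low_gray_level_emphasis",
)

GLSZM_FEATURES = (
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "gray_level_variance",
    "high_gray_level_zone_emphasis",
    "large_area_emphasis",
    "large_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis",
    "low_gray_level_zone_emphasis",
    "size_zone_non_uniformity",
    "size_zone_non_uniformity_normalized",
    "small_area_emphasis",
    "small_area_high_gray_level_emphasis",
    "small_area_low_gray_level_emphasis",
    "zone_entropy",
    "zone_percentage",
    "zone_variance",
)

NGTDM_FEATURES = ("busyness", "coarseness", "complexity", "contrast", "strength")

COARSENESS_CAP = 1.0e6


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0*log(0) = 0 convention."""
    out = np.zeros_like(p, dtype=float)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int]):
    """Level values of all in-mask pixel pairs separated by ``offset``."""
    dr, dc = offset
    h, w = mask.shape
    r0 = max(0, -dr)
    r1 = min(h, h - dr)
    c0 = max(0, -dc)
    c1 = min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        empty = np.empty(0, dtype=levels.dtype)
        return empty, empty
    a_mask = mask[r0:r1, c0:c1]
    b_mask = mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    both = a_mask & b_mask
    return levels[r0:r1, c0:c1][both], levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc][both]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric, angle-summed, normalised co-occurrence matrix.

    Returns an all-zero matrix when the mask has no in-mask neighbouring
    pixel pair (degenerate case).
    """
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for offset in ANGLE_OFFSETS:
        a, b = _shifted_pairs(levels, mask, offset)
        if a.size:
            np.add.at(counts, (a - 1, b - 1), 1.0)
    counts = counts + counts.T  # symmetrise: count each pair in both directions
    total = counts.sum()
    if total == 0:
        return counts
    return counts / total


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 24 co-occurrence features of a normalised symmetric GLCM.

    Degenerate conventions: a zero matrix yields zeros with
    ``correlation = imc... = mcc`` set as for a single gray level; a
    single-gray-level matrix has ``correlation = 1`` and ``mcc = 1``
    (perfect association) and zero entropies.
    """
    ng = P.shape[0]
    out = {name: 0.0 for name in GLCM_FEATURES}
    total = P.sum()
    if total == 0:
        out["correlation"] = 1.0
        out["mcc"] = 1.0
        return out

    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # == py by symmetry
    mu = float((ii * P).sum())
    sigma2 = float(((ii - mu) ** 2 * P).sum())
    sigma = np.sqrt(sigma2)

    # difference distribution p_{x-y}(k), k = 0..ng-1
    k_diff = np.arange(ng, dtype=float)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), P)
    # sum distribution p_{x+y}(k), k = 2..2*ng
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, P)

    da = float((k_diff * p_diff).sum())
    out["autocorrelation"] = float((ii * jj * P).sum())
    out["joint_average"] = mu
    for power, name in ((2, "cluster_tendency"), (3, "cluster_shade"), (4, "cluster_prominence")):
        out[name] = float(((ii + jj - 2 * mu) ** power * P).sum())
    out["contrast"] = float(((ii - jj) ** 2 * P).sum())
    out["correlation"] = (
        1.0 if sigma2 <= 0 else float((out["autocorrelation"] - mu * mu) / sigma2)
    )
    out["difference_average"] = da
    out["difference_entropy"] = float(-_xlog2(p_diff).sum())
    out["difference_variance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    out["id"] = float((p_diff / (1.0 + k_diff)).sum())
    out["idm"] = float((p_diff / (1.0 + k_diff**2)).sum())
    out["idmn"] = float((p_diff / (1.0 + (k_diff / ng) ** 2)).sum())
    out["idn"] = float((p_diff / (1.0 + k_diff / ng)).sum())
    nonzero_k = k_diff > 0
    out["inverse_variance"] = float((p_diff[nonzero_k] / k_diff[nonzero_k] ** 2).sum())
    out["joint_energy"] = float((P**2).sum())
    hxy = float(-_xlog2(P).sum())
    out["joint_entropy"] = hxy
    out["maximum_probability"] = float(P.max())
    out["sum_average"] = float((k_sum * p_sum).sum())
    out["sum_entropy"] = float(-_xlog2(p_sum).sum())
    out["sum_squares"] = sigma2

    # information measures of correlation
    hx = float(-_xlog2(px).sum())
    pxpy = np.outer(px, px)
    valid = pxpy > 0
    hxy1 = float(-(P[valid] * np.log2(pxpy[valid])).sum())
    hxy2 = float(-_xlog2(pxpy).sum())
    out["imc1"] = 0.0 if hx == 0 else float((hxy - hxy1) / hx)
    out["imc2"] = (
        0.0 if hxy2 < hxy else float(np.sqrt(1.0 - np.exp(-2.0 * (hxy2 - hxy))))
    )
    out["mcc"] = _glcm_mcc(P, px)
    return out


def _glcm_mcc(P: np.ndarray, px: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second eigenvalue of Q."""
    keep = px > 0
    if keep.sum() <= 1:
        return 1.0
    p = P[np.ix_(keep, keep)]
    marg = px[keep]
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    q = (p / marg[:, None]) @ (p / marg[None, :]).T
    eig = np.sort(np.real(np.linalg.eigvals(q)))
    second = eig[-2] if eig.size >= 2 else 0.0
    return float(np.sqrt(max(second, 0.0)))


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0
) -> np.ndarray:
    """Dependence matrix P(i, j): in-mask pixels of level i with j-1
    "dependent" 8-neighbours (|level difference| <= alpha); the column
    index is dependence count + 1, so it spans 1..9 at distance 1."""
    dep = np.zeros(mask.shape, dtype=int)
    for offset in NEIGHBOUR_OFFSETS:
        dr, dc = offset
        h, w = mask.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        contrib = np.zeros(mask.shape, dtype=int)
        centre = mask[r0:r1, c0:c1]
        nbr = mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        close = (
            np.abs(
                levels[r0:r1, c0:c1].astype(int)
                - levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc].astype(int)
            )
            <= alpha
        )
        contrib[r0:r1, c0:c1] = (centre & nbr & close).astype(int)
        dep += contrib
    counts = np.zeros((n_levels, 9), dtype=float)
    lv = levels[mask]
    dp = dep[mask]
    if lv.size:
        np.add.at(counts, (lv - 1, dp), 1.0)
    return counts


def gldm_features(counts: np.ndarray) -> dict[str, float]:
    """The 14 dependence features; all zeros for an empty matrix."""
    out = {name: 0.0 for name in GLDM_FEATURES}
    nz = counts.sum()
    if nz == 0:
        return out
    ng, nd = counts.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nd + 1, dtype=float)[None, :]
    p = counts / nz
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    out["small_dependence_emphasis"] = float((p / j**2).sum())
    out["large_dependence_emphasis"] = float((p * j**2).sum())
    out["gray_level_non_uniformity"] = float((counts.sum(axis=1) ** 2).sum() / nz)
    dn = float((counts.sum(axis=0) ** 2).sum() / nz)
    out["dependence_non_uniformity"] = dn
    out["dependence_non_uniformity_normalized"] = dn / nz
    out["gray_level_variance"] = float((p * (i - mu_i) ** 2).sum())
    out["dependence_variance"] = float((p * (j - mu_j) ** 2).sum())
    out["dependence_entropy"] = float(-_xlog2(p).sum())
    out["low_gray_level_emphasis"] = float((p / i**2).sum())
    out["high_gray_level_emphasis"] = float((p * i**2).sum())
    out["small_dependence_low_gray_level_emphasis"] = float((p / (i**2 * j**2)).sum())
    out["small_dependence_high_gray_level_emphasis"] = float((p * i**2 / j**2).sum())
    out["large_dependence_low_gray_level_emphasis"] = float((p * j**2 / i**2).sum())
    out["large_dependence_high_gray_level_emphasis"] = float((p * i**2 * j**2).sum())
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _lines_for_angle(arr: np.ndarray, offset: tuple[int, int]) -> list[np.ndarray]:
    """Decompose a 2-D array into the 1-D scan lines of one direction."""
    dr, dc = offset
    if (dr, dc) == (0, 1):
        return [arr[r] for r in range(arr.shape[0])]
    if (dr, dc) == (-1, 0):
        return [arr[:, c] for c in range(arr.shape[1])]
    if (dr, dc) == (-1, -1):
        # runs along the main diagonals
        return [
            np.diagonal(arr, off) for off in range(-arr.shape[0] + 1, arr.shape[1])
        ]
    if (dr, dc) == (-1, 1):
        flipped = np.fliplr(arr)
        return [
            np.diagonal(flipped, off)
            for off in range(-flipped.shape[0] + 1, flipped.shape[1])
        ]
    raise ValueError(f"unsupported offset {offset}")


def _run_lengths(lines: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of maximal constant-level runs, skipping level 0."""
    if not lines:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    flat = np.concatenate([np.concatenate((line, [0])) for line in lines])
    changes = np.flatnonzero(np.diff(flat) != 0) + 1
    starts = np.concatenate(([0], changes))
    ends = np.concatenate((changes, [flat.size]))
    values = flat[starts]
    keep = values > 0
    return values[keep].astype(int), (ends - starts)[keep].astype(int)


def glrlm_matrix(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, offset: tuple[int, int]
) -> np.ndarray:
    """Run-length matrix R(i, l) for one direction; out-of-mask pixels break runs."""
    masked = np.where(mask, levels, 0)
    vals, lens = _run_lengths(_lines_for_angle(masked, offset))
    max_len = max(mask.shape)
    counts = np.zeros((n_levels, max_len), dtype=float)
    if vals.size:
        np.add.at(counts, (vals - 1, lens - 1), 1.0)
    return counts


def _rlm_style_features(
    counts: np.ndarray, n_pixels: int, names: dict[str, str]
) -> dict[str, float]:
    """Shared 16-feature formulas for run-length / size-zone matrices.

    ``names`` maps the canonical role ("sre", "lre", ...) to the family's
    feature name.  Returns zeros when the matrix is empty.
    """
    out = {name: 0.0 for name in names.values()}
    nr = counts.sum()
    if nr == 0:
        return out
    ng, nl = counts.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    l = np.arange(1, nl + 1, dtype=float)[None, :]
    p = counts / nr
    mu_i = float((i * p).sum())
    mu_l = float((l * p).sum())
    out[names["sre"]] = float((p / l**2).sum())
    out[names["lre"]] = float((p * l**2).sum())
    out[names["gln"]] = float((counts.sum(axis=1) ** 2).sum() / nr)
    out[names["glnn"]] = float((counts.sum(axis=1) ** 2).sum() / nr**2)
    out[names["rln"]] = float((counts.sum(axis=0) ** 2).sum() / nr)
    out[names["rlnn"]] = float((counts.sum(axis=0) ** 2).sum() / nr**2)
    out[names["rp"]] = float(nr / n_pixels) if n_pixels else 0.0
    out[names["glv"]] = float((p * (i - mu_i) ** 2).sum())
    out[names["rv"]] = float((p * (l - mu_l) ** 2).sum())
    out[names["re"]] = float(-_xlog2(p).sum())
    out[names["lglre"]] = float((p / i**2).sum())
    out[names["hglre"]] = float((p * i**2).sum())
    out[names["srlgle"]] = float((p / (i**2 * l**2)).sum())
    out[names["srhgle"]] = float((p * i**2 / l**2).sum())
    out[names["lrlgle"]] = float((p * l**2 / i**2).sum())
    out[names["lrhgle"]] = float((p * l**2 * i**2).sum())
    return out


_GLRLM_ROLE_NAMES = {
    "sre": "short_run_emphasis",
    "lre": "long_run_emphasis",
    "gln": "gray_level_non_uniformity",
    "glnn": "gray_level_non_uniformity_normalized",
    "rln": "run_length_non_uniformity",
    "rlnn": "run_length_non_uniformity_normalized",
    "rp": "run_percentage",
    "glv": "gray_level_variance",
    "rv": "run_variance",
    "re": "run_entropy",
    "lglre": "low_gray_level_run_emphasis",
    "hglre": "high_gray_level_run_emphasis",
    "srlgle": "short_run_low_gray_level_emphasis",
    "srhgle": "short_run_high_gray_level_emphasis",
    "lrlgle": "long_run_low_gray_level_emphasis",
    "lrhgle": "long_run_high_gray_level_emphasis",
}

_GLSZM_ROLE_NAMES = {
    "sre": "small_area_emphasis",
    "lre": "large_area_emphasis",
    "gln": "gray_level_non_uniformity",
    "glnn": "gray_level_non_uniformity_normalized",
    "rln": "size_zone_non_uniformity",
    "rlnn": "size_zone_non_uniformity_normalized",
    "rp": "zone_percentage",
    "glv": "gray_level_variance",
    "rv": "zone_variance",
    "re": "zone_entropy",
    "lglre": "low_gray_level_zone_emphasis",
    "hglre": "high_gray_level_zone_emphasis",
    "srlgle": "small_area_low_gray_level_emphasis",
    "srhgle": "small_area_high_gray_level_emphasis",
    "lrlgle": "large_area_low_gray_level_emphasis",
    "lrhgle": "large_area_high_gray_level_emphasis",
}


def glrlm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """Run-length features averaged over the four 2-D angles."""
    n_pixels = int(mask.sum())
    acc = {name: 0.0 for name in GLRLM_FEATURES}
    for offset in ANGLE_OFFSETS:
        counts = glrlm_matrix(levels, mask, n_levels, offset)
        feats = _rlm_style_features(counts, n_pixels, _GLRLM_ROLE_NAMES)
        for name, value in feats.items():
            acc[name] += value
    return {name: value / len(ANGLE_OFFSETS) for name, value in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_ZONE_STRUCTURE = np.ones((3, 3), dtype=int)  # 8-connectivity


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix S(i, s): 8-connected constant-level zones of size s."""
    max_size = int(mask.sum())
    counts = np.zeros((n_levels, max(max_size, 1)), dtype=float)
    for g in range(1, n_levels + 1):
        region = mask & (levels == g)
        if not region.any():
            continue
        labelled, n_zones = ndimage.label(region, structure=_ZONE_STRUCTURE)
        sizes = np.bincount(labelled.ravel())[1:]
        for s in sizes:
            counts[g - 1, s - 1] += 1.0
    return counts


def glszm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    counts = glszm_matrix(levels, mask, n_levels)
    return _rlm_style_features(counts, int(mask.sum()), _GLSZM_ROLE_NAMES)


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) per gray level.

    ``n_i`` counts in-mask pixels of level i that have at least one
    in-mask 8-neighbour; ``s_i`` accumulates |level - mean neighbour
    level| over those pixels.
    """
    nbr_sum = np.zeros(mask.shape, dtype=float)
    nbr_cnt = np.zeros(mask.shape, dtype=float)
    lv = levels.astype(float)
    for dr, dc in NEIGHBOUR_OFFSETS:
        h, w = mask.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        nbr = mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        nbr_sum[r0:r1, c0:c1] += np.where(nbr, lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc], 0.0)
        nbr_cnt[r0:r1, c0:c1] += nbr
    valid = mask & (nbr_cnt > 0)
    diffs = np.zeros(mask.shape, dtype=float)
    diffs[valid] = np.abs(lv[valid] - nbr_sum[valid] / nbr_cnt[valid])
    n_i = np.zeros(n_levels, dtype=float)
    s_i = np.zeros(n_levels, dtype=float)
    if valid.any():
        np.add.at(n_i, levels[valid] - 1, 1.0)
        np.add.at(s_i, levels[valid] - 1, diffs[valid])
    return n_i, s_i


def ngtdm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """The five gray-tone difference features.

    Conventions: coarseness is capped at 1e6 when its denominator is 0
    (perfectly uniform region); contrast and strength are 0 with fewer
    than two occupied gray levels; busyness is 0 when its denominator
    vanishes.
    """
    n_i, s_i = ngtdm_table(levels, mask, n_levels)
    out = {name: 0.0 for name in NGTDM_FEATURES}
    nvp = n_i.sum()
    if nvp == 0:
        out["coarseness"] = COARSENESS_CAP
        return out
    p_i = n_i / nvp
    occupied = p_i > 0
    ngp = int(occupied.sum())
    i = np.arange(1, n_levels + 1, dtype=float)

    denom = float((p_i * s_i).sum())
    out["coarseness"] = COARSENESS_CAP if denom == 0 else min(1.0 / denom, COARSENESS_CAP)

    if ngp > 1:
        pi_o = p_i[occupied]
        ii_o = i[occupied]
        diff2 = (ii_o[:, None] - ii_o[None, :]) ** 2
        out["contrast"] = float(
            (pi_o[:, None] * pi_o[None, :] * diff2).sum()
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvp)
        )
        busy_den = float(
            np.abs(ii_o[:, None] * pi_o[:, None] - ii_o[None, :] * pi_o[None, :]).sum()
        )
        num = float((p_i * s_i).sum())
        out["busyness"] = 0.0 if busy_den == 0 else num / busy_den
        si_o = s_i[occupied]
        absdiff = np.abs(ii_o[:, None] - ii_o[None, :])
        pair_term = (
            absdiff
            * (pi_o[:, None] * si_o[:, None] + pi_o[None, :] * si_o[None, :])
            / (pi_o[:, None] + pi_o[None, :])
        )
        out["complexity"] = float(pair_term.sum() / nvp)
        s_total = float(s_i.sum())
        if s_total > 0:
            out["strength"] = float(
                ((pi_o[:, None] + pi_o[None, :]) * diff2).sum() / s_total
            )
    return out
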