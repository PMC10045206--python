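"""First-order (intensity) features of the in-mask HU distribution.

All features except ``entropy`` and ``uniformity`` are computed on the
raw HU values; those two are computed on the discretized gray levels and
therefore vary with the bin setting while the rest are replicated
identically across bin settings.
"""

from __future__ import annotations

import numpy as np

FIRSTORDER_FEATURES = (
    "energy",
    "entropy",
    "minimum",
    "percentile10",
    "percentile90",
    "maximum",
    "mean",
    "median",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "root_mean_squared",
    "skewness",
    "kurtosis",
    "variance",
    "uniformity",
)

#: Names whose value does not depend on the discretization setting.
BIN_INDEPENDENT = tuple(n for n in FIRSTORDER_FEATURES if n not in ("entropy", "uniformity"))


def first_order_features(hu_values: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    """The 17 first-order features.

    Degenerate conventions: skewness and kurtosis are 0 for a constant
    input (zero variance); entropy of a single occupied level is 0.
    """
    x = np.asarray(hu_values, dtype=float).ravel()
    lv = np.asarray(levels).ravel()
    if x.size == 0:
        raise ValueError("first-order features need at least one voxel")
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = np.sqrt(var)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    counts = np.bincount(lv)[1:].astype(float)
    p = counts[counts > 0] / lv.size

    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd**3)
        kurt = float(((x - mean) ** 4).mean() / var**2)
    else:
        skew = kurt = 0.0

    return {
        "energy": float((x**2).sum()),
        "entropy": float(-(p * np.log2(p)).sum()),
        "minimum": float(x.min()),
        "percentile10": float(p10),
        "percentile90": float(p90),
        "maximum": float(x.max()),
        "mean": mean,
        "median": float(np.median(x)),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "robust_mean_absolute_deviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "root_mean_squared": float(np.sqrt((x**2).mean())),
        "skewness": skew,
        "kurtosis": kurt,
        "variance": var,
        "uniformity": float((p**2).sum()),
    }
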