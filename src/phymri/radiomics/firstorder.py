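"""First-order (histogram) intensity statistics of a region."""

from __future__ import annotations

import numpy as np

FIRSTORDER_NAMES = [
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "MeanAbsoluteDeviation", "Mean", "Median",
    "Minimum", "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "TotalEnergy", "Uniformity", "Variance",
]


def first_order_features(image: np.ndarray, mask: np.ndarray,
                         levels: np.ndarray | None = None,
                         voxel_volume: float = 1.0) -> dict:
    """The 18 first-order features of the masked intensities.

    ``levels`` (the discretized image, levels >= 1 in-mask) supplies the
    histogram for entropy and uniformity; if omitted both are computed
    from integer-rounded intensities.  Kurtosis is the raw fourth
    standardized moment (Fisher +3 convention); a constant region has
    entropy 0, uniformity 1 and skewness/kurtosis 0.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(image, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("empty valid mask")
    mean = float(vals.mean())
    var = float(vals.var())
    std = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(vals, [10, 25, 50, 75, 90])
    robust = vals[(vals >= p10) & (vals <= p90)]

    if levels is not None:
        lv = np.asarray(levels)[mask]
    else:
        lv = np.round(vals).astype(int)
    counts = np.bincount(lv - lv.min())
    p = counts[counts > 0] / lv.size

    if std > 0:
        skew = float(np.mean(((vals - mean) / std) ** 3))
        kurt = float(np.mean(((vals - mean) / std) ** 4))
    else:
        skew = kurt = 0.0

    energy = float((vals**2).sum())
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": float(-(p * np.log2(p)).sum()),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": kurt,
        "Maximum": float(vals.max()),
        "MeanAbsoluteDeviation": float(np.abs(vals - mean).mean()),
        "Mean": mean,
        "Median": float(p50),
        "Minimum": float(vals.min()),
        "Range": float(vals.max() - vals.min()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((vals**2).mean())),
        "Skewness": skew,
        "TotalEnergy": energy * voxel_volume,
        "Uniformity": float((p**2).sum()),
        "Variance": var,
    }
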