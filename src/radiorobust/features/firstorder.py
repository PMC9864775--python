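"""First-order (intensity histogram) features over the in-mask voxels."""

from __future__ import annotations

import numpy as np

from ..images import Mask, Volume

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    volume: Volume, mask: Mask, bin_width: float
) -> dict[str, float]:
    """18 first-order statistics of the in-mask intensities.

    Entropy and Uniformity use the fixed-bin-width discretized histogram; all
    others use raw intensities.  Variance is the population variance;
    Kurtosis is uncorrected (Fisher's definition without the -3, so a
    Gaussian gives ~3); Skewness and Kurtosis of a constant region are 0.
    Percentiles use the linear-interpolation convention.
    """
    x = volume.voxels[mask.voxels]
    n = x.size
    mean = float(x.mean())
    dev = x - mean
    m2 = float((dev**2).mean())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    levels = np.floor((x - x.min()) / bin_width).astype(np.int64)
    p = np.bincount(levels) / n
    p = p[p > 0]

    out = {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(volume.voxel_volume_mm3 * (x**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(dev).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float((dev**3).mean() / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float((dev**4).mean() / m2**2) if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": float((p**2).sum()),
    }
    return out
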