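"""First-order (histogram) intensity statistics, IBSI definitions."""

from __future__ import annotations

import numpy as np

__all__ = ["first_order_features", "FIRSTORDER_NAMES"]

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def first_order_features(
    values: np.ndarray,
    voxel_volume: float = 1.0,
    bin_width: float = 25.0,
) -> dict[str, float]:
    """The 18 first-order features of the ROI intensity sample.

    Entropy and uniformity use the fixed-bin-width histogram of the
    sample; skewness and kurtosis are the population (biased) moments,
    with 0 returned for a zero-variance ROI.  Kurtosis is not
    excess-corrected (a Gaussian scores 3).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    mean = x.mean()
    var = x.var()
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    edges_lo = np.floor(x.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((x.max() - edges_lo) / bin_width)))
    hist, _ = np.histogram(x, bins=n_bins, range=(edges_lo, edges_lo + n_bins * bin_width))
    p = hist[hist > 0] / x.size

    robust = x[(x >= p10) & (x <= p90)]
    sigma = np.sqrt(var)
    if sigma > 0:
        skew = np.mean((x - mean) ** 3) / sigma**3
        kurt = np.mean((x - mean) ** 4) / sigma**4
    else:
        skew = kurt = 0.0

    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume * np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }
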