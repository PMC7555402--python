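"""First-order radiomic features of a masked lesion ROI.

Seven histogram statistics are computed per image — mean, variation
coefficient (VC = sigma/mu), gray-level range (Max-Min), skewness, entropy,
relative smoothness and kurtosis — on both the low-energy (LE) and
recombined (RC) views, giving 14 features per lesion.

Definitions (population-moment convention by default, configurable):

* ``Mean``      arithmetic mean mu
* ``VC``        sigma / mu, undefined when |mu| is below an epsilon
* ``Max-Min``   max - min of the ROI gray levels
* ``Skewness``  m3 / sigma^3 (m_k the k-th central moment)
* ``Entropy``   -sum p_i log2 p_i over an equal-width histogram of
  ``n_bins`` bins spanning the ROI's own [min, max]; 0 when max == min
* ``RelativeSmoothness``  1 - 1/(1 + sigma_n^2) with sigma_n the standard
  deviation of intensities rescaled to [0, 1] by the image's representable
  range (Gonzalez-Woods normalization)
* ``Kurtosis``  m4 / sigma^4 (non-excess; normal distribution = 3)

Undefined values (zero variance, near-zero mean) propagate as NaN so that
downstream analyses can apply pairwise deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FeatureConfig

__all__ = [
    "FEATURE_BASES",
    "FEATURE_NAMES",
    "FeatureVector",
    "first_order_features",
    "extract_cohort_features",
    "features_to_frame",
]

#: the seven per-image statistics, in reporting order
FEATURE_BASES: tuple[str, ...] = (
    "Mean", "VC", "Max-Min", "Skewness", "Entropy", "RelativeSmoothness", "Kurtosis",
)

#: the 14 per-lesion feature names: LE block then RC block
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{img}_{base}" for img in ("LE", "RC") for base in FEATURE_BASES
)


@dataclass(frozen=True)
class FeatureVector:
    """The 14 named first-order features of one lesion (NaN = undefined)."""

    lesion_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            raise ValueError(
                "FeatureVector requires exactly the 14 canonical feature names "
                f"in order; got {tuple(self.values.keys())}"
            )


def first_order_features(
    pixels,
    n_bins: int = 256,
    value_range: tuple[float, float] | None = None,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Compute the seven first-order statistics of a pixel vector.

    Parameters
    ----------
    pixels
        1-D array of ROI gray levels (length >= 16 in pipeline use; shorter
        vectors are accepted to keep degenerate cases testable).
    n_bins
        histogram bins for entropy (ignored if ``config`` is given).
    value_range
        (min, max) representable by the image, used to normalize the
        relative-smoothness variance; falls back to the ROI's own span.
    config
        full convention set; overrides ``n_bins``.

    Returns
    -------
    dict
        ``{"Mean": ..., "VC": ..., "Max-Min": ..., "Skewness": ...,
        "Entropy": ..., "RelativeSmoothness": ..., "Kurtosis": ...}`` with
        NaN for undefined entries.
    """
    cfg = config if config is not None else FeatureConfig(n_bins=n_bins)
    cfg.validate()
    x = np.asarray(pixels, dtype=np.float64).ravel()
    n = x.size
    if n < 2:
        raise ValueError("at least 2 pixels are required")

    mu = float(x.mean())
    dev = x - mu
    m2 = float(np.mean(dev * dev))
    if cfg.moments == "sample":
        var = m2 * n / (n - 1)
    else:
        var = m2
    sigma = math.sqrt(var)

    lo = float(x.min())
    hi = float(x.max())
    span_repr = (value_range[1] - value_range[0]) if value_range is not None else (hi - lo)

    # variation coefficient: guard against the near-zero means of
    # subtraction (RC) images; a zero-variance ROI has no meaningful
    # dispersion ratio either
    eps = cfg.vc_epsilon_rel * span_repr if span_repr > 0 else cfg.vc_epsilon_rel
    vc = sigma / mu if (abs(mu) > eps and sigma > 0) else math.nan

    if sigma > 0:
        m3 = float(np.mean(dev ** 3))
        m4 = float(np.mean(dev ** 4))
        skewness = m3 / sigma ** 3
        kurtosis = m4 / sigma ** 4
        if cfg.kurtosis == "excess":
            kurtosis -= 3.0
    else:
        skewness = math.nan
        kurtosis = math.nan

    if hi == lo:
        entropy = 0.0
    else:
        counts, _ = np.histogram(x, bins=cfg.n_bins, range=(lo, hi))
        p = counts[counts > 0] / n
        h_bits = float(-np.sum(p * np.log2(p)))
        if cfg.entropy_log_base == "e":
            entropy = h_bits * math.log(2.0)
        elif cfg.entropy_log_base == 2:
            entropy = h_bits
        else:
            entropy = h_bits / math.log2(float(cfg.entropy_log_base))

    if cfg.smoothness_norm == "roi":
        norm_span = hi - lo
    else:
        norm_span = span_repr
    if norm_span > 0:
        s_norm = sigma / norm_span
        smoothness = 1.0 - 1.0 / (1.0 + s_norm * s_norm)
    else:
        smoothness = 0.0

    return {
        "Mean": mu,
        "VC": vc,
        "Max-Min": hi - lo,
        "Skewness": skewness,
        "Entropy": entropy,
        "RelativeSmoothness": smoothness,
        "Kurtosis": kurtosis,
    }


def extract_cohort_features(pairs, config: FeatureConfig | None = None) -> list[FeatureVector]:
    """Extract the 14-feature vector for every image pair in a cohort.

    ``pairs`` is a list of :class:`~cesm_radiomics.cohort_io.ImagePair`;
    LE_* features come from the LE ROI pixels and RC_* from the RC ROI
    pixels, sharing the lesion's mask.
    """
    from .cohort_io import extract_roi_pixels  # local import: avoid cycle

    if len(pairs) == 0:
        raise ValueError("cohort is empty")
    cfg = config if config is not None else FeatureConfig()
    out: list[FeatureVector] = []
    for pair in pairs:
        values: dict[str, float] = {}
        for img in ("LE", "RC"):
            px = extract_roi_pixels(pair, img)
            feats = first_order_features(px, value_range=pair.pixel_value_range, config=cfg)
            for base in FEATURE_BASES:
                values[f"{img}_{base}"] = feats[base]
        out.append(FeatureVector(lesion_id=pair.lesion_id, values=values))
    return out


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a lesion-by-feature DataFrame (14 columns)."""
    index = [v.lesion_id for v in vectors]
    data = {name: [v.values[name] for v in vectors] for name in FEATURE_NAMES}
    return pd.DataFrame(data, index=pd.Index(index, name="lesion_id"))
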