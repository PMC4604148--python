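"""Normalized mean deviation product (nMDP) colocalization.

Within a whole-cell ROI, each channel's pixel intensities are normalized to
the ROI mean and rescaled so the mean maps to 0, the brightest ROI pixel to
+1 and the dimmest to -1 (a two-sided rescaling: values above the mean are
divided by ``max - mean``, values below by ``mean - min``). The two
normalized channels are multiplied pixelwise: pixels whose intensities
co-vary (bright-bright or dim-dim) give positive products, anti-correlating
pixels give negative products. The scalar nMDP score of an image is the
arithmetic mean of the product over ROI pixels; the score is comparable
across cells of different sizes and is symmetric in its arguments.

For display, mutually-dim pixels (negative in both channels, hence a
positive product) are blacked out for clarity — strictly after the score is
computed, so the rendering never changes the number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizedImage",
    "NmdpResult",
    "normalize_channel",
    "nmdp_image",
    "nmdp_score",
    "render_nmdp_display",
]

GOLD = np.array([255, 215, 0], dtype=np.float64)
GREEN = np.array([0, 255, 0], dtype=np.float64)


@dataclass(frozen=True)
class NormalizedImage:
    """Mean-deviation-normalized channel: values in [-1, 1] on the ROI, 0 outside."""

    values: np.ndarray
    roi: np.ndarray
    source_stats: tuple[float, float, float]  # (mean, min, max) of raw ROI pixels


@dataclass(frozen=True)
class NmdpResult:
    """Pixelwise product of two normalized channels and its scalar score."""

    product_image: np.ndarray
    score: float
    roi: np.ndarray
    channel_pair: tuple[str, str]


def normalize_channel(
    raw: np.ndarray,
    roi: np.ndarray,
    one_sided: bool = False,
) -> NormalizedImage:
    """Normalize a channel over the whole-cell ROI to the [-1, 1] deviation scale.

    For ROI pixels with intensity I, ROI mean m, max M and min L:
    ``(I - m)/(M - m)`` if ``I >= m`` else ``(I - m)/(m - L)``, so that
    mean -> 0, brightest -> 1, dimmest -> -1. With ``one_sided=True`` both
    branches use the ``M - m`` denominator (the variant found in the earlier
    nMDP literature; the dimmest pixel then maps above -1 in general).

    A channel that is constant on the ROI normalizes to all zeros (the
    no-information value). Pixels outside the ROI are set to 0 and excluded
    from every statistic.
    """
    raw = np.asarray(raw, dtype=np.float64)
    roi = np.asarray(roi, dtype=bool)
    if raw.shape != roi.shape:
        raise ValueError("raw image and ROI shapes differ")
    if not roi.any():
        raise ValueError("ROI is empty")
    vals = raw[roi]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite pixel intensities inside the ROI")
    m = vals.mean()
    lo = vals.min()
    hi = vals.max()
    out = np.zeros_like(raw)
    if hi > lo:
        dev = raw - m
        upper = hi - m
        lower = m - lo
        if one_sided:
            norm = dev / upper if upper > 0 else np.zeros_like(dev)
        else:
            norm = np.where(
                dev >= 0,
                dev / upper if upper > 0 else 0.0,
                dev / lower if lower > 0 else 0.0,
            )
        out[roi] = norm[roi]
    return NormalizedImage(values=out, roi=roi, source_stats=(m, lo, hi))


def nmdp_image(
    a: NormalizedImage,
    b: NormalizedImage,
    channel_pair: tuple[str, str] = ("A", "B"),
) -> NmdpResult:
    """Multiply two normalized channels and score the product over the ROI.

    The score is the arithmetic mean of the product image over ROI pixels;
    it lies in [-1, 1] and is symmetric in the two channels.
    """
    if a.values.shape != b.values.shape or not np.array_equal(a.roi, b.roi):
        raise ValueError("the two channels must share one ROI and shape")
    product = np.zeros_like(a.values)
    product[a.roi] = a.values[a.roi] * b.values[a.roi]
    score = float(product[a.roi].mean())
    return NmdpResult(
        product_image=product, score=score, roi=a.roi, channel_pair=channel_pair
    )


def nmdp_score(
    raw_a: np.ndarray,
    raw_b: np.ndarray,
    roi: np.ndarray,
    one_sided: bool = False,
) -> float:
    """Convenience: nMDP score of two raw channels within one ROI."""
    a = normalize_channel(raw_a, roi, one_sided=one_sided)
    b = normalize_channel(raw_b, roi, one_sided=one_sided)
    return nmdp_image(a, b).score


def render_nmdp_display(
    result: NmdpResult, a: NormalizedImage, b: NormalizedImage
) -> np.ndarray:
    """Render the product image as uint8 RGB with the display convention.

    Positive products ramp linearly black -> gold (255, 215, 0); negative
    products ramp black -> green; pixels dim in BOTH channels (a < 0 and
    b < 0, a positive product) are set to black for clarity. Blanking happens
    after scoring, so ``result.score`` is unaffected. Outside-ROI pixels are
    black.
    """
    if result.product_image.shape != a.values.shape:
        raise ValueError("result and normalized images have different shapes")
    p = result.product_image
    rgb = np.zeros(p.shape + (3,), dtype=np.float64)
    pos = (p > 0) & result.roi
    neg = (p < 0) & result.roi
    rgb[pos] = p[pos, None] * GOLD
    rgb[neg] = (-p[neg, None]) * GREEN
    mutually_dim = (a.values < 0) & (b.values < 0) & result.roi
    rgb[mutually_dim] = 0.0
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
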