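"""Hue histograms of masked pixels and the binned two-sample KS comparison.

Hue is the angular coordinate of HSV color space, in degrees: 0 is red, 60
yellow, 120 green.  Plant color profiles are summarized as per-degree
percentage histograms of the hues of masked (plant) pixels; two profiles are
compared with a two-sample Kolmogorov-Smirnov test on the binned cumulative
distributions,

    reject iff  K > c(alpha) * sqrt((n + m) / (n * m)),
    K = sup |F_x(hue) - F_y(hue)|,   c(alpha) = sqrt(-ln(alpha / 2) / 2).

What to use for the sample sizes n and m is a genuine modeling choice when
histograms are averaged over many images: ``n_mode='pixels'`` (default) uses
the total masked pixel counts — the most conservative reading — while
``n_mode='bins'`` uses the number of histogram bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import skimage.color

from .errors import ConfigError, EmptyObjectError, GeometryError, GridError
from .segmentation import BinaryMask


@dataclass
class HueHistogram:
    """Percentage-of-mask histogram over the full 0-360 degree support.

    ``bin_edges`` has one more entry than ``percentages``; the display range
    (default 0-140, where plant hues live) is presentation metadata only —
    all bins are retained and all statistics use the full support.
    """

    bin_edges: np.ndarray
    percentages: np.ndarray
    n_pixels: int
    display_range: tuple[float, float] = (0.0, 140.0)
    image_id: str = ""

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.percentages = np.asarray(self.percentages, dtype=float)
        if self.bin_edges.size != self.percentages.size + 1:
            raise ConfigError("bin_edges must have one more entry than percentages")
        if self.n_pixels < 1:
            raise EmptyObjectError("histogram requires at least one pixel")
        if np.any(self.percentages < 0):
            raise ConfigError("percentages must be nonnegative")
        if abs(self.percentages.sum() - 100.0) > 1e-6:
            raise ConfigError("percentages must sum to 100 over the full support")


@dataclass
class KSResult:
    K: float
    n: int
    m: int
    alpha: float
    c_alpha: float
    threshold: float
    reject: bool


def masked_hues(image: np.ndarray, mask: BinaryMask, return_achromatic: bool = False):
    """Hue (degrees in [0, 360)) of every foreground pixel.

    Achromatic pixels (R == G == B) are assigned hue 0; with
    ``return_achromatic`` a boolean flag array marking them is also returned.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise GeometryError(f"expected an H x W x 3 raster, got shape {image.shape}")
    if image.shape[:2] != mask.values.shape:
        raise GeometryError("image and mask dimensions differ")
    if mask.n_foreground == 0:
        raise EmptyObjectError("mask has no foreground pixels")
    pixels = image[mask.values.astype(bool)].astype(float)
    hsv = skimage.color.rgb2hsv(pixels[None, :, :] / 255.0)[0]
    hues = (hsv[:, 0] * 360.0) % 360.0
    achromatic = (pixels[:, 0] == pixels[:, 1]) & (pixels[:, 1] == pixels[:, 2])
    hues[achromatic] = 0.0
    if return_achromatic:
        return hues, achromatic
    return hues


def hue_histogram(
    hues,
    bin_width: float = 1.0,
    display_range: tuple[float, float] = (0.0, 140.0),
    image_id: str = "",
) -> HueHistogram:
    """Bin hues into half-open [edge, edge + width) bins over 0-360 degrees."""
    hues = np.asarray(hues, dtype=float)
    if hues.size == 0:
        raise EmptyObjectError("no hues to histogram")
    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    # wrapping to [0, 360) keeps every value out of np.histogram's closed top
    # edge, so all bins behave as half-open [edge, edge + width)
    counts, _ = np.histogram(hues % 360.0, bins=edges)
    return HueHistogram(
        bin_edges=edges,
        percentages=100.0 * counts / hues.size,
        n_pixels=int(hues.size),
        display_range=display_range,
        image_id=image_id,
    )


def cumulative(hist: HueHistogram) -> np.ndarray:
    """Binned CDF on [0, 1]; nondecreasing, final value 1."""
    return np.cumsum(hist.percentages) / 100.0


def average_histograms(hists: list[HueHistogram]) -> tuple[HueHistogram, np.ndarray]:
    """Arithmetic mean of per-image percentage histograms.

    Returns the mean histogram (n_pixels = summed contributions) and the
    per-bin half-width of the 95% confidence band (1.96 * SE over images).
    """
    if not hists:
        raise EmptyObjectError("no histograms to average")
    grid = hists[0].bin_edges
    for h in hists[1:]:
        if h.bin_edges.shape != grid.shape or not np.allclose(h.bin_edges, grid):
            raise GridError("histograms are on different bin grids")
    stack = np.vstack([h.percentages for h in hists])
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(len(hists)) if len(hists) > 1 else np.zeros_like(mean)
    out = HueHistogram(
        bin_edges=grid,
        percentages=mean,
        n_pixels=int(sum(h.n_pixels for h in hists)),
        display_range=hists[0].display_range,
    )
    return out, 1.96 * se


def ks_critical_coefficient(alpha: float) -> float:
    """Closed-form c(alpha) = sqrt(-ln(alpha/2) / 2); c(0.05) ~ 1.3581."""
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    return float(np.sqrt(-0.5 * np.log(alpha / 2.0)))


def ks_test(
    x: HueHistogram, y: HueHistogram, alpha: float = 0.05, n_mode: str = "pixels"
) -> KSResult:
    """Two-sample KS test on binned hue CDFs."""
    if x.bin_edges.shape != y.bin_edges.shape or not np.allclose(x.bin_edges, y.bin_edges):
        raise GridError("histograms must share an identical bin grid")
    c_alpha = ks_critical_coefficient(alpha)
    if n_mode == "pixels":
        n, m = x.n_pixels, y.n_pixels
    elif n_mode == "bins":
        n = m = x.percentages.size
    else:
        raise ConfigError(f"n_mode must be 'pixels' or 'bins', got {n_mode!r}")
    k = float(np.max(np.abs(cumulative(x) - cumulative(y))))
    threshold = c_alpha * np.sqrt((n + m) / (n * m))
    return KSResult(
        K=k, n=n, m=m, alpha=alpha, c_alpha=c_alpha,
        threshold=float(threshold), reject=bool(k > threshold),
    )
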