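"""Fixed-threshold plant segmentation and the shape-descriptor panel.

Segmentation is deliberately simple: a pixel is plant iff it satisfies every
configured channel bound (RGB and/or HSV), with no morphological cleanup
unless ``keep_largest_component`` is set.  Misclassified isolated pixels
("salt and pepper") are therefore preserved, which is exactly the failure
mode standardization is meant to remove.

The descriptor panel covers the 19 morphometrics commonly reported in plant
phenotyping: pixel-count area, convex hull area and vertex count, bounding
box width/height, outer-contour perimeter, circularity, solidity, roundness,
moment-ellipse parameters, eccentricity, aspect ratio, box-counting fractal
dimension, and centers of mass.  Units are pixels throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import skimage.color
import skimage.measure
import scipy.spatial

from .errors import ConfigError, EmptyObjectError, GeometryError

_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass
class ThresholdConfig:
    """Channel bounds defining plant pixels.

    ``rgb_bounds`` / ``hsv_bounds`` map channel name ('r','g','b' / 'h','s','v')
    to an inclusive (min, max) pair.  Hue is in degrees [0, 360); saturation
    and value in [0, 1].  A pixel is foreground iff all bounds hold.
    """

    rgb_bounds: dict = field(default_factory=dict)
    hsv_bounds: dict = field(default_factory=dict)
    keep_largest_component: bool = False

    def __post_init__(self):
        if not self.rgb_bounds and not self.hsv_bounds:
            raise ConfigError("threshold config must constrain at least one channel")
        for name, bounds in list(self.rgb_bounds.items()) + list(self.hsv_bounds.items()):
            lo, hi = bounds
            if lo > hi:
                raise ConfigError(f"channel {name!r}: min {lo} > max {hi}")

    @classmethod
    def from_dict(cls, doc: dict) -> "ThresholdConfig":
        return cls(
            rgb_bounds={k: tuple(v) for k, v in doc.get("rgb", {}).items()},
            hsv_bounds={k: tuple(v) for k, v in doc.get("hsv", {}).items()},
            keep_largest_component=bool(doc.get("keep_largest_component", False)),
        )


@dataclass
class BinaryMask:
    values: np.ndarray
    image_id: str = ""
    threshold_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GeometryError("mask must be 2-D")
        self.values = (self.values > 0).astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())


@dataclass
class ShapeDescriptors:
    area: float
    convex_hull_area: float
    convex_hull_vertices: float
    width: float
    height: float
    perimeter: float
    circularity: float
    solidity: float
    roundness: float
    eccentricity: float
    aspect_ratio: float
    fractal_dimension: float
    center_of_mass_x: float
    center_of_mass_y: float
    ellipse_center_x: float
    ellipse_center_y: float
    ellipse_major_axis: float
    ellipse_minor_axis: float
    ellipse_angle: float

    @classmethod
    def column_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def as_row(self) -> list[float]:
        return [getattr(self, name) for name in self.column_names()]


def threshold_segment(image: np.ndarray, cfg: ThresholdConfig, image_id: str = "") -> BinaryMask:
    """Pixel = 1 iff every configured RGB/HSV bound is satisfied."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise GeometryError(f"expected an H x W x 3 raster, got shape {image.shape}")
    keep = np.ones(image.shape[:2], dtype=bool)
    rgb = image.astype(float)
    idx = {"r": 0, "g": 1, "b": 2}
    for name, (lo, hi) in cfg.rgb_bounds.items():
        keep &= (rgb[..., idx[name]] >= lo) & (rgb[..., idx[name]] <= hi)
    if cfg.hsv_bounds:
        hsv = skimage.color.rgb2hsv(rgb / 255.0)
        chans = {"h": hsv[..., 0] * 360.0, "s": hsv[..., 1], "v": hsv[..., 2]}
        for name, (lo, hi) in cfg.hsv_bounds.items():
            keep &= (chans[name] >= lo) & (chans[name] <= hi)
    mask = keep.astype(np.uint8)
    if cfg.keep_largest_component and mask.any():
        labels = skimage.measure.label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = (labels == counts.argmax()).astype(np.uint8)
    return BinaryMask(mask, image_id=image_id)


def _trace_contour(component: np.ndarray) -> float:
    """Arc length of the outer 8-connected boundary (Moore-neighbor tracing).

    Unit steps for orthogonal moves, sqrt(2) for diagonal; terminates via
    Jacob's stopping criterion.  A single pixel has length 0.
    """
    coords = np.argwhere(component)
    # topmost, then leftmost foreground pixel; entered from the (background) west
    start = tuple(coords[np.lexsort((coords[:, 1], coords[:, 0]))[0]])
    on = lambda p: (
        0 <= p[0] < component.shape[0]
        and 0 <= p[1] < component.shape[1]
        and component[p]
    )
    cur, back = start, (start[0], start[1] - 1)
    length = 0.0
    seen: dict[tuple, float] = {}  # (cur, back) at sweep start -> length so far
    for _ in range(8 * coords.shape[0] + 8):
        state = (cur, back)
        if state in seen:
            return length - seen[state]  # drop the acyclic lead-in, keep one full loop
        seen[state] = length
        d0 = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for step in range(1, 9):  # clockwise sweep starting just past the backtrack
            d = (d0 + step) % 8
            cand = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if on(cand):
                nxt = cand
                break
            back = cand  # last background examined becomes the new backtrack
        if nxt is None:
            return 0.0  # isolated pixel
        length += np.sqrt(2.0) if (nxt[0] != cur[0] and nxt[1] != cur[1]) else 1.0
        cur = nxt
    raise RuntimeError("contour tracing failed to close")  # pragma: no cover


def perimeter(mask: BinaryMask) -> float:
    """Summed outer-contour arc length over all 8-connected components."""
    if mask.n_foreground == 0:
        raise EmptyObjectError("cannot measure an empty mask")
    labels = skimage.measure.label(mask.values, connectivity=2)
    total = 0.0
    for lab in range(1, labels.max() + 1):
        total += _trace_contour(labels == lab)
    return total


def fractal_dimension(mask: BinaryMask) -> float:
    """Box-counting dimension over dyadic box sizes (least-squares slope)."""
    if mask.n_foreground == 0:
        raise EmptyObjectError("cannot measure an empty mask")
    coords = np.argwhere(mask.values)
    y0, x0 = coords.min(axis=0)
    y1, x1 = coords.max(axis=0) + 1
    crop = mask.values[y0:y1, x0:x1]
    extent = max(crop.shape)
    n = 1 << max(int(np.ceil(np.log2(extent))), 2)  # >= 2 dyadic scales
    padded = np.zeros((n, n), dtype=np.uint8)
    padded[: crop.shape[0], : crop.shape[1]] = crop
    sizes, counts = [], []
    size = n // 2
    while size >= 1:
        blocks = padded.reshape(n // size, size, n // size, size)
        occupied = int(blocks.any(axis=(1, 3)).sum())
        sizes.append(size)
        counts.append(occupied)
        size //= 2
    x = np.log(1.0 / np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    x -= x.mean()
    return float((x @ (y - y.mean())) / (x @ x))


def measure_shapes(mask: BinaryMask) -> ShapeDescriptors:
    """Compute the full 19-descriptor panel for one (possibly fragmented) mask."""
    if mask.n_foreground == 0:
        raise EmptyObjectError("cannot measure an empty mask")
    values = mask.values
    coords = np.argwhere(values)  # (row, col) = (y, x)
    ys, xs = coords[:, 0], coords[:, 1]
    area = float(values.sum())
    width = float(xs.max() - xs.min() + 1)
    height = float(ys.max() - ys.min() + 1)

    # regionprops over the whole mask as one (possibly disconnected) region
    props = skimage.measure.regionprops(values.astype(np.uint8))[0]
    convex_hull_area = float(props.area_convex)
    solidity = float(props.solidity)
    eccentricity = float(props.eccentricity)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    cy, cx = props.centroid  # moment centroid doubles as the ellipse center
    # orientation is measured from the row axis; convert to degrees from x-axis
    angle = float(np.degrees(np.pi / 2 - props.orientation) % 180.0)

    if area >= 3 and not (np.all(xs == xs[0]) or np.all(ys == ys[0])):
        hull = scipy.spatial.ConvexHull(np.column_stack([xs, ys]).astype(float))
        hull_vertices = float(len(hull.vertices))
    else:
        hull_vertices = float(min(area, 2))

    perim = perimeter(mask)
    circularity = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
    roundness = 4.0 * area / (np.pi * major**2) if major > 0 else 0.0

    return ShapeDescriptors(
        area=area,
        convex_hull_area=convex_hull_area,
        convex_hull_vertices=hull_vertices,
        width=width,
        height=height,
        perimeter=perim,
        circularity=float(circularity),
        solidity=solidity,
        roundness=float(roundness),
        eccentricity=eccentricity,
        aspect_ratio=width / height,
        fractal_dimension=fractal_dimension(mask),
        center_of_mass_x=float(xs.mean()),
        center_of_mass_y=float(ys.mean()),
        ellipse_center_x=float(cx),
        ellipse_center_y=float(cy),
        ellipse_major_axis=major,
        ellipse_minor_axis=minor,
        ellipse_angle=angle,
    )


def compare_masks(a: BinaryMask, b: BinaryMask) -> dict:
    """Exact pixel-set overlap: counts only-in-a, only-in-b, and both."""
    if a.values.shape != b.values.shape:
        raise GeometryError(
            f"mask shapes differ: {a.values.shape} vs {b.values.shape}"
        )
    av, bv = a.values.astype(bool), b.values.astype(bool)
    return {
        "only_in_a": int(np.sum(av & ~bv)),
        "only_in_b": int(np.sum(~av & bv)),
        "both": int(np.sum(av & bv)),
    }
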