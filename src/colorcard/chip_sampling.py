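"""Extract chip color matrices from images given a configured card layout.

The card is located by configuration, not detection: a :class:`CardLayout`
lists one axis-aligned rectangle per chip, in row-major card order (top-left
to bottom-right of the 4 x 6 grid in its configured orientation).  Each chip's
color is the arithmetic mean over the rectangle shrunk on every side by
``inset_fraction``, which keeps chip borders and their shadows out of the
sample.  Coordinates are 0-based, origin top-left, x rightward, y downward;
rectangles are half-open ``[x, x+w) x [y, y+h)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .color_model import ChipColorMatrix
from .errors import ConfigError, GeometryError, InvalidInputError

SATURATION_LIMIT = 254.5  # mean at or above this flags the chip as saturated


@dataclass
class CardLayout:
    rows: int = 4
    cols: int = 6
    chip_rois: list[tuple[int, int, int, int]] = field(default_factory=list)
    inset_fraction: float = 0.25

    def __post_init__(self):
        if self.rows * self.cols != len(self.chip_rois):
            raise ConfigError(
                f"grid is {self.rows} x {self.cols} = {self.rows * self.cols} chips "
                f"but {len(self.chip_rois)} ROIs were given"
            )
        if not (0 <= self.inset_fraction < 0.5):
            raise ConfigError("inset_fraction must lie in [0, 0.5)")
        self.chip_rois = [tuple(int(v) for v in roi) for roi in self.chip_rois]

    @property
    def chip_ids(self) -> list[str]:
        """Canonical row-major labels chip_00 .. chip_NN."""
        return [f"chip_{i:02d}" for i in range(len(self.chip_rois))]

    def inset_rois(self) -> list[tuple[int, int, int, int]]:
        """ROIs shrunk on all sides by inset_fraction (integer pixel bounds)."""
        out = []
        for x, y, w, h in self.chip_rois:
            dx = int(round(w * self.inset_fraction))
            dy = int(round(h * self.inset_fraction))
            out.append((x + dx, y + dy, w - 2 * dx, h - 2 * dy))
        return out

    # -- YAML round-trip -------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "rows": self.rows,
                "cols": self.cols,
                "inset_fraction": self.inset_fraction,
                "chip_rois": [list(r) for r in self.chip_rois],
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "CardLayout":
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as e:
            raise ConfigError(f"card layout YAML is unreadable: {e}") from e
        if not isinstance(doc, dict):
            raise ConfigError("card layout YAML must be a mapping")
        for key in ("rows", "cols", "chip_rois"):
            if key not in doc:
                raise ConfigError(f"card layout is missing required key {key!r}")
        rois = doc["chip_rois"]
        for i, roi in enumerate(rois):
            if len(roi) != 4 or any(int(v) != v for v in roi):
                raise ConfigError(f"chip_rois entry {i} must be four integers (x, y, w, h)")
            if roi[2] <= 0 or roi[3] <= 0:
                raise ConfigError(f"chip_rois entry {i} has non-positive size")
        return cls(
            rows=int(doc["rows"]),
            cols=int(doc["cols"]),
            chip_rois=[tuple(r) for r in rois],
            inset_fraction=float(doc.get("inset_fraction", 0.25)),
        )


@dataclass
class ChipQualityReport:
    """Per-chip quality flags; overall failure only on geometry problems."""

    saturated: list[bool]
    low_variance_ok: list[bool]
    out_of_bounds: list[bool]
    passed: bool


def sample_chips(
    image: np.ndarray, layout: CardLayout, image_id: str = ""
) -> ChipColorMatrix:
    """Mean RGB per chip over the inset ROIs, rows in canonical card order."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise GeometryError(f"expected an H x W x 3 raster, got shape {image.shape}")
    height, width = image.shape[:2]
    means = np.empty((len(layout.chip_rois), 3))
    for i, (x, y, w, h) in enumerate(layout.inset_rois()):
        if w <= 0 or h <= 0:
            raise GeometryError(f"chip {i}: ROI empty after inset")
        if x < 0 or y < 0 or x + w > width or y + h > height:
            raise GeometryError(
                f"chip {i}: inset ROI ({x}, {y}, {w}, {h}) outside {width} x {height} image"
            )
        means[i] = image[y : y + h, x : x + w].reshape(-1, 3).mean(axis=0)
    return ChipColorMatrix(means, layout.chip_ids, source_image_id=image_id)


def validate_chips(chips: ChipColorMatrix) -> ChipQualityReport:
    """Flag saturated chips (any channel mean >= 254.5); never mutates input."""
    if not isinstance(chips, ChipColorMatrix):
        raise InvalidInputError("validate_chips requires a ChipColorMatrix")
    saturated = [bool(np.any(row >= SATURATION_LIMIT)) for row in chips.values]
    low_variance_ok = [True] * chips.k  # variance is unknowable from means alone
    out_of_bounds = [False] * chips.k  # bounds were enforced at sampling time
    return ChipQualityReport(
        saturated=saturated,
        low_variance_ok=low_variance_ok,
        out_of_bounds=out_of_bounds,
        passed=not any(out_of_bounds),
    )
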