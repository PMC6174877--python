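"""Seeded scene generator: reference/distorted image pairs with ground truth.

Each scene is a uniform background carrying a rendered 24-chip color card and
a synthetic green "plant" disc, with the exact chip colors, card layout, and
plant mask returned alongside the raster.  A parametric distortion family —
global brightness scale, per-channel gamma, optional per-channel cubic
polynomial shifts, additive Gaussian noise — emulates the kind of
temperature-dependent lamp brightness and color drift that plagues
long-running imaging experiments: images taken under cool nighttime
conditions come out darker and hue-shifted relative to warm daytime ones.

Everything is deterministic given the seeds carried in the specs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chip_sampling import CardLayout
from .color_model import ChipColorMatrix
from .errors import GeometryError
from .segmentation import BinaryMask

#: Nominal sRGB values of the classic 24-patch ColorChecker chart (row-major,
#: dark skin .. black).  Fixture constants, not measurements.
CLASSIC_CHIP_COLORS: np.ndarray = np.array(
    [
        [115, 82, 68], [194, 150, 130], [98, 122, 157], [87, 108, 67],
        [133, 128, 177], [103, 189, 170], [214, 126, 44], [80, 91, 166],
        [193, 90, 99], [94, 60, 108], [157, 188, 64], [224, 163, 46],
        [56, 61, 150], [70, 148, 73], [175, 54, 60], [231, 199, 31],
        [187, 86, 149], [8, 133, 161], [243, 243, 242], [200, 200, 200],
        [160, 160, 160], [122, 122, 121], [85, 85, 85], [52, 52, 52],
    ],
    dtype=float,
)

DEFAULT_SEED = 2024


@dataclass
class SceneSpec:
    width: int = 320
    height: int = 240
    card_rect: tuple[int, int, int, int] = (10, 10, 180, 120)  # x, y, w, h
    chip_colors: np.ndarray = field(default_factory=lambda: CLASSIC_CHIP_COLORS.copy())
    plant_center: tuple[int, int] = (240, 170)  # x, y
    plant_radius: int = 40
    plant_color: tuple[int, int, int] = (60, 140, 50)
    plant_color_jitter: float = 12.0  # sd of per-pixel color texture on the plant
    background_color: tuple[int, int, int] = (190, 190, 195)
    seed: int = DEFAULT_SEED


@dataclass
class DistortionSpec:
    brightness_scale: float = 1.0
    gamma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    polynomial: np.ndarray | None = None  # optional 3 x 9 cubic coefficient table
    noise_sd: float = 0.0
    seed: int = DEFAULT_SEED

    def is_identity(self) -> bool:
        return (
            self.brightness_scale == 1.0
            and tuple(self.gamma) == (1.0, 1.0, 1.0)
            and self.polynomial is None
            and self.noise_sd == 0.0
        )


def _card_layout(spec: SceneSpec, rows: int = 4, cols: int = 6) -> CardLayout:
    x0, y0, w, h = spec.card_rect
    cw, ch = w // cols, h // rows
    rois = [
        (x0 + c * cw, y0 + r * ch, cw, ch)
        for r in range(rows)
        for c in range(cols)
    ]
    return CardLayout(rows=rows, cols=cols, chip_rois=rois, inset_fraction=0.25)


def _plant_mask(spec: SceneSpec) -> np.ndarray:
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cx, cy = spec.plant_center
    return ((xx - cx) ** 2 + (yy - cy) ** 2 <= spec.plant_radius**2).astype(np.uint8)


def render_scene(
    spec: SceneSpec,
) -> tuple[np.ndarray, BinaryMask, ChipColorMatrix, CardLayout]:
    """Render the reference scene with full ground truth.

    Chip ROIs are uniform at the spec's chip colors; the plant disc carries
    seeded per-pixel color texture (clipped normal around ``plant_color``) so
    its hue distribution has realistic spread.
    """
    layout = _card_layout(spec)
    x0, y0, w, h = spec.card_rect
    if x0 < 0 or y0 < 0 or x0 + w > spec.width or y0 + h > spec.height:
        raise GeometryError("card rectangle out of image bounds")
    mask = _plant_mask(spec)
    card_region = np.zeros_like(mask)
    card_region[y0 : y0 + h, x0 : x0 + w] = 1
    if np.any(mask & card_region):
        raise GeometryError("card and plant regions overlap")

    image = np.empty((spec.height, spec.width, 3), dtype=np.uint8)
    image[:] = np.asarray(spec.background_color, dtype=np.uint8)
    for roi, color in zip(layout.chip_rois, spec.chip_colors):
        x, y, cw, ch = roi
        image[y : y + ch, x : x + cw] = np.asarray(color, dtype=np.uint8)

    rng = np.random.default_rng(spec.seed)
    n_plant = int(mask.sum())
    sd = spec.plant_color_jitter
    # truncate at 2.5 sd so the plant's color support is bounded and a fixed
    # threshold with margin can recover the disc exactly on the reference
    jitter = np.clip(rng.normal(0.0, sd, size=(n_plant, 3)), -2.5 * sd, 2.5 * sd)
    plant = np.clip(np.asarray(spec.plant_color, float) + jitter, 0, 255)
    image[mask.astype(bool)] = np.floor(plant + 0.5).astype(np.uint8)

    chips = ChipColorMatrix(
        spec.chip_colors.copy(), layout.chip_ids, source_image_id="ground_truth"
    )
    return image, BinaryMask(mask, image_id="ground_truth"), chips, layout


def distort(image: np.ndarray, d: DistortionSpec) -> np.ndarray:
    """Apply brightness scale, per-channel gamma, optional cubic shift, noise.

    Per channel on [0, 1]-normalized values: v' = (scale * v) ** gamma, then
    rescaled to [0, 255]; the optional 3 x 9 polynomial table is applied on
    the native scale like a color transform; truncated Gaussian noise last.
    """
    image = np.asarray(image)
    out = image.astype(float) / 255.0
    out = out * d.brightness_scale
    out = np.clip(out, 0.0, None) ** np.asarray(d.gamma, dtype=float)
    out = out * 255.0
    if d.polynomial is not None:
        from .color_model import ChannelCoefficients, ColorTransform, apply_transform_image

        table = np.asarray(d.polynomial, dtype=float)
        t = ColorTransform(
            ChannelCoefficients(table[0], "R"),
            ChannelCoefficients(table[1], "G"),
            ChannelCoefficients(table[2], "B"),
        )
        out = apply_transform_image(t, out, output="float")
    if d.noise_sd > 0:
        rng = np.random.default_rng(d.seed)
        out = out + rng.normal(0.0, d.noise_sd, size=out.shape)
    out = np.clip(out, 0.0, 255.0)
    if image.dtype == np.uint8:
        return np.floor(out + 0.5).astype(np.uint8)
    return out


def make_pair(
    scene: SceneSpec, d: DistortionSpec
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Reference image, distorted image, and the ground-truth bundle."""
    reference, mask, chips, layout = render_scene(scene)
    distorted = distort(reference, d)
    truths = {
        "mask": mask,
        "chips": chips,
        "layout": layout,
        "scene": scene,
        "distortion": d,
    }
    return reference, distorted, truths


def plant_threshold_config():
    """Fixed-threshold config that recovers the rendered plant disc exactly.

    Bounds leave a safety margin around the truncated color support of the
    default plant (green hue, mid saturation and value); the card's green
    chip is removed by keeping only the largest connected component.
    """
    from .segmentation import ThresholdConfig

    return ThresholdConfig(
        hsv_bounds={"h": (70.0, 160.0), "s": (0.25, 1.0), "v": (0.40, 1.0)},
        keep_largest_component=True,
    )


def day_night_distortions(
    n_scenes: int, seed: int = DEFAULT_SEED
) -> list[tuple[str, DistortionSpec]]:
    """Alternating day/night distortion specs for an n-scene study.

    Day images are mildly dimmed (scale 0.80-0.90, gamma near 1); night images
    are strongly dimmed (scale 0.50-0.65) with a warm per-channel gamma shift
    (R up, B down) — the signature of fluorescent bulbs running cold.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_scenes):
        if i % 2 == 0:  # day
            spec = DistortionSpec(
                brightness_scale=float(rng.uniform(0.80, 0.90)),
                gamma=tuple(rng.uniform(0.98, 1.02, size=3)),
                noise_sd=1.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out.append(("day", spec))
        else:  # night
            spec = DistortionSpec(
                brightness_scale=float(rng.uniform(0.50, 0.65)),
                gamma=(
                    float(rng.uniform(1.10, 1.20)),
                    float(rng.uniform(0.98, 1.02)),
                    float(rng.uniform(0.85, 0.95)),
                ),
                noise_sd=1.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out.append(("night", spec))
    return out
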