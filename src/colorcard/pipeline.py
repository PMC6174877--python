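"""Batch orchestration: standardize a directory of images against a reference.

For every image the pipeline samples the card chips, fits the color transform
to the declared reference, scores the deviance, writes the standardized
image, segments plant pixels before and after standardization, and measures
shapes and hue histograms for both.  Results land in three tidy CSVs
(``deviance.csv``, ``shapes.csv``, ``hue.csv``) plus an ``errors.csv`` naming
any skipped images.  Processing order is lexicographic by filename and float
formatting is fixed at 6 significant digits, so re-runs are byte-identical.
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import chip_sampling, color_model, hue, segmentation
from .errors import ColorCardError, ConfigError

log = logging.getLogger("colorcard")

FLOAT_FORMAT = "%.6g"


def read_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit RGB raster (PNG/TIFF/JPEG); alpha is dropped."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image)).save(path)


def write_mask(path: str | Path, mask: segmentation.BinaryMask) -> None:
    """Masks are stored as 8-bit PNG with foreground 255."""
    Image.fromarray((mask.values * 255).astype(np.uint8)).save(path)


@dataclass
class RunConfig:
    input_glob: str
    reference: str  # path of the reference image
    layout_path: str
    threshold: dict | None = None  # ThresholdConfig.from_dict document
    output_dir: str = "colorcard_out"
    write_masks: bool = False
    write_standardized: bool = False
    float_output: bool = False
    hue_bin_width: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError("run config must be a YAML mapping")
        missing = {"input_glob", "reference", "layout_path"} - set(doc)
        if missing:
            raise ConfigError(f"run config missing keys: {sorted(missing)}")
        return cls(**doc)


def _image_id(path: str) -> str:
    return Path(path).stem


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full batch; returns the result tables that were written."""
    paths = sorted(glob.glob(cfg.input_glob))
    if cfg.reference not in paths and not os.path.exists(cfg.reference):
        raise ConfigError(f"reference image {cfg.reference!r} not found")
    ids = [_image_id(p) for p in paths]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigError(f"image id collisions: {dupes}")

    with open(cfg.layout_path) as fh:
        layout = chip_sampling.CardLayout.from_yaml(fh.read())
    thresh = (
        segmentation.ThresholdConfig.from_dict(cfg.threshold) if cfg.threshold else None
    )

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    ref_image = read_image(cfg.reference)
    ref_id = _image_id(cfg.reference)
    ref_chips = chip_sampling.sample_chips(ref_image, layout, ref_id)

    dev_rows, shape_rows, hue_rows, err_rows = [], [], [], []
    for path in paths:
        image_id = _image_id(path)
        try:
            image = read_image(path)
            chips = chip_sampling.sample_chips(image, layout, image_id)
            quality = chip_sampling.validate_chips(chips)
            if any(quality.saturated):
                log.warning("%s: %d saturated chip(s)", image_id, sum(quality.saturated))
            d_before = color_model.deviance_between(chips, ref_chips).value
            transform = color_model.fit_transform(chips, ref_chips)
            standardized = color_model.apply_transform_image(
                transform, image, output="float" if cfg.float_output else "uint8"
            )
            std_sampleable = (
                np.floor(np.clip(standardized, 0, 255) + 0.5).astype(np.uint8)
                if cfg.float_output
                else standardized
            )
            std_chips = chip_sampling.sample_chips(std_sampleable, layout, image_id)
            d_after = color_model.deviance_between(std_chips, ref_chips).value
            dev_rows.append(
                {
                    "image_id": image_id,
                    "reference_id": ref_id,
                    "n_chips": chips.k,
                    "deviance_before": d_before,
                    "deviance_after": d_after,
                    "saturated_chips": int(sum(quality.saturated)),
                }
            )
            if cfg.write_standardized:
                write_image(out / f"{image_id}_standardized.png", std_sampleable)

            if thresh is not None:
                for stage, raster in (("before", image), ("after", std_sampleable)):
                    mask = segmentation.threshold_segment(raster, thresh, image_id)
                    if cfg.write_masks:
                        write_mask(out / f"{image_id}_{stage}_mask.png", mask)
                    if mask.n_foreground == 0:
                        err_rows.append(
                            {"image_id": image_id, "stage": stage, "error": "empty mask"}
                        )
                        continue
                    shapes = segmentation.measure_shapes(mask)
                    shape_rows.append(
                        {"image_id": image_id, "stage": stage}
                        | dict(zip(shapes.column_names(), shapes.as_row()))
                    )
                    hist = hue.hue_histogram(
                        hue.masked_hues(raster, mask),
                        bin_width=cfg.hue_bin_width,
                        image_id=image_id,
                    )
                    for start, pct in zip(hist.bin_edges[:-1], hist.percentages):
                        if pct > 0:
                            hue_rows.append(
                                {
                                    "image_id": image_id,
                                    "stage": stage,
                                    "bin_start_deg": start,
                                    "percent": pct,
                                }
                            )
        except (ColorCardError, OSError) as exc:
            log.error("skipping %s: %s", path, exc)
            err_rows.append({"image_id": image_id, "stage": "load", "error": str(exc)})

    tables = {
        "deviance": pd.DataFrame(dev_rows),
        "shapes": pd.DataFrame(shape_rows),
        "hue": pd.DataFrame(hue_rows),
        "errors": pd.DataFrame(err_rows, columns=["image_id", "stage", "error"]),
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format=FLOAT_FORMAT)
    return tables
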