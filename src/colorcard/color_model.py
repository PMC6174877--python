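"""Polynomial color standardization between images sharing a reference card.

The model regresses each target color channel on the source chips' linear,
quadratic, and cubic channel values.  With ``S`` the k x 9 extended source
design and ``T`` the k x 3 target chip matrix, the per-channel standardization
vectors are ``M T_c`` where ``M = (S' S)^-1 S'`` is the Moore-Penrose inverse
of the design.  Applying the three 9-vectors to every pixel's extended RGB
tuple maps the source image onto the target's brightness, contrast, and color
profile.  Extending the *target* matrix the same way yields nine regressions
whose coefficient rows form a 9 x 9 homography ``H``; the scalar deviance

    D = 1 - det(H)

is 0 when source and target share a color profile and moves away from 0
(signed, often strongly negative for dimmed images) as the profiles diverge.

All fitting is done in double precision on the native 0-255 intensity scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import CorrespondenceError, InvalidInputError, SingularDesignError

#: Relative singular-value cutoff for declaring the extended design rank-deficient.
#: Cubed 8-bit intensities span ~7 orders of magnitude, so the cutoff is relative
#: to the largest singular value.
RANK_RTOL = 1e-10

_DESIGN_COLS = ("r", "g", "b", "r2", "g2", "b2", "r3", "g3", "b3")


@dataclass
class ChipColorMatrix:
    """Mean RGB of each reference chip, rows in canonical card order.

    ``values`` is k x 3 on the native 0-255 scale, columns R, G, B.
    """

    values: np.ndarray
    chip_ids: list[str]
    source_image_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise InvalidInputError(f"chip matrix must be k x 3, got {self.values.shape}")
        k = self.values.shape[0]
        if k < 9:
            raise InvalidInputError(f"need at least 9 chips, got {k}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("chip values must be finite")
        if self.values.min() < 0 or self.values.max() > 255:
            raise InvalidInputError("chip values must lie in [0, 255]")
        if len(self.chip_ids) != k:
            raise InvalidInputError("one chip id per row required")
        if len(set(self.chip_ids)) != k:
            raise InvalidInputError("chip ids must be unique")

    @property
    def k(self) -> int:
        return self.values.shape[0]


@dataclass
class ChannelCoefficients:
    """Nine standardization coefficients for one output channel.

    Order matches the design columns (r, g, b, r^2, g^2, b^2, r^3, g^3, b^3).
    """

    coeffs: np.ndarray
    channel: str

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (9,):
            raise InvalidInputError("channel coefficient vector must have length 9")
        if not np.all(np.isfinite(self.coeffs)):
            raise InvalidInputError("coefficients must be finite")
        if self.channel not in ("R", "G", "B"):
            raise InvalidInputError(f"channel must be R, G, or B, got {self.channel!r}")


@dataclass
class ColorTransform:
    """Fitted standardization: one coefficient vector per output channel."""

    r: ChannelCoefficients
    g: ChannelCoefficients
    b: ChannelCoefficients
    target_image_id: str = ""
    source_image_id: str = ""

    def __post_init__(self):
        if (self.r.channel, self.g.channel, self.b.channel) != ("R", "G", "B"):
            raise InvalidInputError("transform channels must be tagged R, G, B in order")

    def as_matrix(self) -> np.ndarray:
        """3 x 9 coefficient table, rows R, G, B."""
        return np.vstack([self.r.coeffs, self.g.coeffs, self.b.coeffs])

    # -- JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "model": "cubic-polynomial-color-standardization",
            "design_columns": list(_DESIGN_COLS),
            "coefficients": {
                "R": self.r.coeffs.tolist(),
                "G": self.g.coeffs.tolist(),
                "B": self.b.coeffs.tolist(),
            },
            "target_image_id": self.target_image_id,
            "source_image_id": self.source_image_id,
            "solver": {"method": "svd-lstsq", "rank_rtol": RANK_RTOL},
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ColorTransform":
        doc = json.loads(text)
        c = doc["coefficients"]
        return cls(
            r=ChannelCoefficients(np.array(c["R"]), "R"),
            g=ChannelCoefficients(np.array(c["G"]), "G"),
            b=ChannelCoefficients(np.array(c["B"]), "B"),
            target_image_id=doc.get("target_image_id", ""),
            source_image_id=doc.get("source_image_id", ""),
        )


@dataclass
class HomographyMatrix:
    """9 x 9 color homography; rows ordered R, G, B, R^2, G^2, B^2, R^3, G^3, B^3."""

    values: np.ndarray
    source_image_id: str = ""
    target_image_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (9, 9):
            raise InvalidInputError("homography must be 9 x 9")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("homography entries must be finite")


@dataclass
class DevianceScore:
    """Signed deviance D = 1 - det(H); 0 when source matches target."""

    value: float
    source_image_id: str = ""
    target_image_id: str = ""


def identity_transform() -> ColorTransform:
    """Transform whose application leaves every pixel unchanged."""
    eye = np.zeros((3, 9))
    eye[0, 0] = eye[1, 1] = eye[2, 2] = 1.0
    return ColorTransform(
        ChannelCoefficients(eye[0], "R"),
        ChannelCoefficients(eye[1], "G"),
        ChannelCoefficients(eye[2], "B"),
    )


def _extend(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return np.concatenate([v, v**2, v**3], axis=-1)


def extend_design(chips: ChipColorMatrix | np.ndarray) -> np.ndarray:
    """k x 9 design with columns (r, g, b, r^2, g^2, b^2, r^3, g^3, b^3)."""
    values = chips.values if isinstance(chips, ChipColorMatrix) else np.asarray(chips, float)
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("design input must be finite")
    return _extend(values)


def pseudoinverse(design: np.ndarray, rank_rtol: float = RANK_RTOL) -> np.ndarray:
    """Moore-Penrose inverse M of the extended design, M S = I_9.

    Computed via SVD for numerical stability; equivalent to (S'S)^-1 S' for
    full-rank designs.  Raises :class:`SingularDesignError` naming the
    numerical rank when fewer than 9 independent columns remain -- the failure
    mode seen when too many chips are removed from the card.
    """
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[1] != 9:
        raise InvalidInputError(f"design must be k x 9, got {design.shape}")
    u, s, vt = np.linalg.svd(design, full_matrices=False)
    rank = int(np.sum(s > rank_rtol * s[0]))
    if rank < 9:
        raise SingularDesignError(rank)
    return (vt.T / s) @ u.T


def _check_pair(source: ChipColorMatrix, target: ChipColorMatrix) -> None:
    if source.k != target.k or source.chip_ids != target.chip_ids:
        raise CorrespondenceError(
            "source and target chips must be homologous: identical chip ids in "
            "identical order"
        )


def fit_transform(source: ChipColorMatrix, target: ChipColorMatrix) -> ColorTransform:
    """Least-squares fit of the three standardization vectors mapping source to target."""
    _check_pair(source, target)
    m = pseudoinverse(extend_design(source))
    coeffs = m @ target.values  # 9 x 3, columns R, G, B
    return ColorTransform(
        r=ChannelCoefficients(coeffs[:, 0], "R"),
        g=ChannelCoefficients(coeffs[:, 1], "G"),
        b=ChannelCoefficients(coeffs[:, 2], "B"),
        target_image_id=target.source_image_id,
        source_image_id=source.source_image_id,
    )


def apply_transform_pixel(t: ColorTransform, rgb) -> np.ndarray:
    """Standardize one RGB tuple; output clipped to [0, 255] (float)."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,) or not np.all(np.isfinite(rgb)):
        raise InvalidInputError("pixel must be a finite 3-vector")
    ext = _extend(rgb)
    out = t.as_matrix() @ ext
    return np.clip(out, 0.0, 255.0)


def apply_transform_image(
    t: ColorTransform, image: np.ndarray, output: str = "uint8"
) -> np.ndarray:
    """Standardize every pixel of a 3-channel raster.

    ``output='uint8'`` clips to [0, 255] then rounds half-up; ``output='float'``
    returns the unclipped polynomial values for analysis.
    """
    from .errors import FormatError

    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"expected an H x W x 3 raster, got shape {image.shape}")
    flat = image.reshape(-1, 3).astype(float)
    out = _extend(flat) @ t.as_matrix().T
    out = out.reshape(image.shape)
    if output == "float":
        return out
    if output != "uint8":
        raise InvalidInputError(f"unknown output mode {output!r}")
    return np.floor(np.clip(out, 0.0, 255.0) + 0.5).astype(np.uint8)


def fit_homography(source: ChipColorMatrix, target: ChipColorMatrix) -> HomographyMatrix:
    """9 x 9 homography: regressions of T, T^2, T^3 channels on the extended source."""
    _check_pair(source, target)
    m = pseudoinverse(extend_design(source))
    extended_target = _extend(target.values)  # k x 9, cols R,G,B,R2,G2,B2,R3,G3,B3
    h = (m @ extended_target).T  # rows follow extended-target column order
    return HomographyMatrix(
        h,
        source_image_id=source.source_image_id,
        target_image_id=target.source_image_id,
    )


def deviance(h: HomographyMatrix) -> DevianceScore:
    """D = 1 - det(H), computed from an LU factorization."""
    det = scipy.linalg.det(h.values)
    return DevianceScore(
        value=1.0 - det,
        source_image_id=h.source_image_id,
        target_image_id=h.target_image_id,
    )


def deviance_between(source: ChipColorMatrix, target: ChipColorMatrix) -> DevianceScore:
    """Convenience: fit the homography and score it in one call."""
    return deviance(fit_homography(source, target))
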