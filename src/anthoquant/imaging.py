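"""Image calibration against two gray standards and ROI statistics.

The pipeline assumes *linear* RGB input (8- or 16-bit TIFF/PNG; gamma-encoded
input can be pre-linearized with a power law).  A per-channel affine map is
anchored on two gray standards of known reflectance — defaults 9.11% and
60.90%, the Neutral 3.5 and Neutral 8 patches of a ColorChecker chart — so
that calibrated pixel values are in percent-reflectance units.  One chart's
map may be applied to a batch of photographs taken under the same light (the
"sequential method").

Coordinate conventions, used everywhere: 0-based pixels, origin top-left,
rectangles ``(x, y, w, h)`` half-open in width and height.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from anthoquant.rgb import RGBTriplet

__all__ = [
    "LinearImage",
    "ROI",
    "CalibrationMap",
    "ROIStats",
    "load_image",
    "fit_two_point_calibration",
    "apply_calibration",
    "extract_roi_stats",
    "load_rois",
]

#: Pixels at or above this fraction of the sensor maximum count as clipped.
CLIP_FRACTION = 0.995

DEFAULT_DARK_REF = 9.11
DEFAULT_LIGHT_REF = 60.90

_BIT_DEPTH_MAX = {8: 255.0, 16: 65535.0}


class CalibrationError(ValueError):
    """Raised when the two-standard constraint cannot be satisfied."""


@dataclass
class LinearImage:
    """In-memory linear RGB image (float64 H×W×3).

    ``clip_mask`` marks pixels that were at/near the sensor maximum *before*
    calibration; it survives calibration so ROI statistics can report the
    clipped fraction on the original sensor scale.
    """

    data: np.ndarray
    bit_depth: int
    calibrated: bool = False
    calibration_id: str | None = None
    scale_mm_per_px: float | None = None
    clip_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(
                f"expected 3 channels (H, W, 3); got shape {self.data.shape}"
            )
        if self.bit_depth not in _BIT_DEPTH_MAX:
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        if self.clip_mask is None:
            sensor_max = _BIT_DEPTH_MAX[self.bit_depth]
            self.clip_mask = np.any(self.data >= CLIP_FRACTION * sensor_max, axis=2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]


@dataclass(frozen=True)
class ROI:
    """Region of interest: a rectangle or an explicit boolean mask."""

    label: str = ""
    rect: tuple[int, int, int, int] | None = None  # x, y, w, h
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.mask is None):
            raise ValueError("give exactly one of rect or mask")
        if self.rect is not None:
            x, y, w, h = self.rect
            if w <= 0 or h <= 0:
                raise ValueError("rectangle width and height must be positive")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the ROI clipped to the image; empty -> error."""
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != shape:
                raise ValueError(
                    f"mask shape {m.shape} does not match image shape {shape}"
                )
        else:
            x, y, w, h = self.rect
            m = np.zeros(shape, dtype=bool)
            m[max(y, 0): y + h, max(x, 0): x + w] = True
        if not m.any():
            raise ValueError(f"ROI {self.label!r} does not intersect the image")
        return m

    @classmethod
    def from_dict(cls, d: dict) -> "ROI":
        kind = d.get("type", "rect")
        if kind == "rect":
            return cls(label=d.get("label", ""), rect=tuple(int(v) for v in d["coords"]))
        if kind == "mask":
            return cls(label=d.get("label", ""), mask=np.asarray(d["mask"], dtype=bool))
        raise ValueError(f"unknown ROI type {kind!r}")

    def to_dict(self) -> dict:
        if self.rect is not None:
            return {"label": self.label, "type": "rect", "coords": list(self.rect)}
        return {
            "label": self.label,
            "type": "mask",
            "mask": np.asarray(self.mask, dtype=int).tolist(),
        }


def load_rois(path) -> list[ROI]:
    """Read ROIs from a JSON file holding one ROI object or a list of them."""
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, dict):
        payload = [payload]
    return [ROI.from_dict(d) for d in payload]


@dataclass
class CalibrationMap:
    """Per-channel affine device-value -> percent-reflectance map."""

    gains: np.ndarray
    offsets: np.ndarray
    dark_means: np.ndarray
    light_means: np.ndarray
    dark_ref: float = DEFAULT_DARK_REF
    light_ref: float = DEFAULT_LIGHT_REF
    bit_depth: int = 16
    calibration_id: str = ""

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.dark_means = np.asarray(self.dark_means, dtype=float)
        self.light_means = np.asarray(self.light_means, dtype=float)
        if np.any(self.gains <= 0):
            raise CalibrationError("calibration gains must be positive")
        if not self.dark_ref < self.light_ref:
            raise CalibrationError("dark reference must be below light reference")
        if not self.calibration_id:
            digest = hashlib.sha1(
                np.concatenate(
                    [self.dark_means, self.light_means, [self.dark_ref, self.light_ref]]
                ).tobytes()
            ).hexdigest()
            self.calibration_id = f"cal-{digest[:10]}"

    @classmethod
    def from_channel_means(
        cls,
        dark_means,
        light_means,
        dark_ref: float = DEFAULT_DARK_REF,
        light_ref: float = DEFAULT_LIGHT_REF,
        bit_depth: int = 16,
    ) -> "CalibrationMap":
        dark = np.asarray(dark_means, dtype=float)
        light = np.asarray(light_means, dtype=float)
        if np.any(dark >= light):
            raise CalibrationError(
                "dark-standard mean >= light-standard mean in at least one "
                "channel (standards swapped or image saturated)"
            )
        gains = (light_ref - dark_ref) / (light - dark)
        offsets = dark_ref - gains * dark
        cal = cls(gains, offsets, dark, light, dark_ref, light_ref, bit_depth)
        # fixed-point property holds by construction; assert to catch drift
        assert np.allclose(cal.apply_to_values(dark), dark_ref, atol=1e-9)
        assert np.allclose(cal.apply_to_values(light), light_ref, atol=1e-9)
        return cal

    def apply_to_values(self, values) -> np.ndarray:
        """Apply the per-channel map to an (..., 3) array of device values."""
        return np.asarray(values, dtype=float) * self.gains + self.offsets

    def apply_to_triplet(self, t: RGBTriplet) -> RGBTriplet:
        r, g, b = self.apply_to_values(t.as_array())
        return RGBTriplet(r, g, b, bit_depth=t.bit_depth, pixel_count=t.pixel_count)

    def to_json(self, path=None) -> str:
        payload = {
            "gains": self.gains.tolist(),
            "offsets": self.offsets.tolist(),
            "dark_means": self.dark_means.tolist(),
            "light_means": self.light_means.tolist(),
            "dark_ref": self.dark_ref,
            "light_ref": self.light_ref,
            "bit_depth": self.bit_depth,
            "calibration_id": self.calibration_id,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "CalibrationMap":
        d = json.loads(Path(path).read_text())
        return cls(
            d["gains"], d["offsets"], d["dark_means"], d["light_means"],
            d["dark_ref"], d["light_ref"], d["bit_depth"], d["calibration_id"],
        )


@dataclass(frozen=True)
class ROIStats:
    """Per-channel summary over one ROI."""

    triplet: RGBTriplet
    sds: tuple[float, float, float]
    pixel_count: int
    clipped_fraction: float
    area_mm2: float | None = None


def load_image(
    path,
    assume_linear: bool = True,
    gamma: float | None = None,
    scale_mm_per_px: float | None = None,
) -> LinearImage:
    """Load an 8/16-bit RGB TIFF or PNG as a :class:`LinearImage`.

    With ``assume_linear=False`` a power-law exponent must be supplied; each
    normalized channel value v/max is replaced by (v/max)**gamma (then scaled
    back), undoing a display gamma before calibration.
    """
    path = Path(path)
    raw = iio.imread(path)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError(f"{path.name}: expected 3 channels, got shape {raw.shape}")
    if raw.dtype == np.uint8:
        bit_depth = 8
    elif raw.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"{path.name}: unsupported dtype {raw.dtype}; expected uint8/uint16")
    sensor_max = _BIT_DEPTH_MAX[bit_depth]
    data = raw.astype(float)
    clip_mask = np.any(data >= CLIP_FRACTION * sensor_max, axis=2)
    if not assume_linear:
        if gamma is None:
            raise ValueError("assume_linear=False requires a gamma exponent")
        data = (data / sensor_max) ** gamma * sensor_max
    return LinearImage(
        data, bit_depth, calibrated=False,
        scale_mm_per_px=scale_mm_per_px, clip_mask=clip_mask,
    )


def fit_two_point_calibration(
    img: LinearImage,
    dark_roi: ROI,
    light_roi: ROI,
    dark_ref: float = DEFAULT_DARK_REF,
    light_ref: float = DEFAULT_LIGHT_REF,
) -> CalibrationMap:
    """Fit the per-channel affine map anchored on the two gray standards."""
    if img.calibrated:
        raise CalibrationError("image is already calibrated")
    dark = extract_roi_stats(img, dark_roi, allow_uncalibrated=True)
    light = extract_roi_stats(img, light_roi, allow_uncalibrated=True)
    for name, stats in (("dark", dark), ("light", light)):
        if stats.clipped_fraction > 0.01:
            warnings.warn(
                f"{name}-standard ROI has {stats.clipped_fraction:.1%} clipped "
                "pixels; calibration may be biased",
                stacklevel=2,
            )
    return CalibrationMap.from_channel_means(
        dark.triplet.as_array(), light.triplet.as_array(),
        dark_ref=dark_ref, light_ref=light_ref, bit_depth=img.bit_depth,
    )


def apply_calibration(img: LinearImage, cal: CalibrationMap) -> LinearImage:
    """Map an image into percent-reflectance units (sequential-method safe:
    one chart's map may be applied to every photo of its batch)."""
    if img.calibrated:
        raise CalibrationError("image is already calibrated")
    if img.bit_depth != cal.bit_depth:
        raise CalibrationError(
            f"bit-depth mismatch: image {img.bit_depth}, calibration {cal.bit_depth}"
        )
    out = LinearImage(
        cal.apply_to_values(img.data),
        img.bit_depth,
        calibrated=True,
        calibration_id=cal.calibration_id,
        scale_mm_per_px=img.scale_mm_per_px,
        clip_mask=img.clip_mask.copy(),
    )
    return out


def extract_roi_stats(
    img: LinearImage,
    roi: ROI,
    allow_uncalibrated: bool = False,
) -> ROIStats:
    """Per-channel mean/SD over the ROI, pixel count, clipped fraction and
    physical area when the image carries a mm-per-pixel scale."""
    if not img.calibrated and not allow_uncalibrated:
        raise ValueError(
            "image is not calibrated; pass allow_uncalibrated=True to override"
        )
    mask = roi.to_mask(img.shape)
    pixels = img.data[mask]  # (n, 3)
    means = pixels.mean(axis=0)
    sds = pixels.std(axis=0, ddof=0)
    n = int(mask.sum())
    clipped = float(img.clip_mask[mask].mean())
    area = None
    if img.scale_mm_per_px is not None:
        area = n * img.scale_mm_per_px ** 2
    triplet = RGBTriplet(
        float(means[0]), float(means[1]), float(means[2]),
        bit_depth=img.bit_depth, pixel_count=n,
    )
    return ROIStats(triplet, tuple(float(s) for s in sds), n, clipped, area)
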