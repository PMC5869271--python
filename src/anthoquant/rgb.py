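"""The 14 image-based color indices from calibrated RGB channel means.

Two symbol families are used, matching the split in the index definitions:
``N_red/N_green/N_blue`` are raw (calibrated) channel means feeding the
chroma, anthocyanin-content, red:green and strength indices; ``r/g/b`` are
those means divided by the channel maximum (255 for 8-bit, 65,535 for
16-bit, or an explicit maximum such as 100 for percent-reflectance data)
and feed the hue/lightness/saturation/brightness family together with
``I_max``/``I_min``.

The hue formula divides by 60 exactly as the source material defines it;
the conventional HSL sector hue (×60) is available via
``hue_convention="hsl"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from anthoquant.indexset import IndexSet

__all__ = [
    "RGBTriplet",
    "NormalizedRGB",
    "normalize_rgb",
    "rgb_hsl_indices",
    "rgb_chroma_indices",
    "rgb_anthocyanin_indices",
    "rgb_strength_indices",
    "compute_rgb_indices",
    "read_triplets_csv",
]

_BIT_DEPTH_MAX = {8: 255.0, 16: 65535.0}


@dataclass(frozen=True)
class RGBTriplet:
    """Calibrated channel means over an ROI (reflectance-scaled units)."""

    n_red: float
    n_green: float
    n_blue: float
    bit_depth: int | None = None
    pixel_count: int = 1

    def __post_init__(self) -> None:
        for v in (self.n_red, self.n_green, self.n_blue):
            if not np.isfinite(v) or v < 0:
                raise ValueError("channel means must be finite and >= 0")
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.n_red, self.n_green, self.n_blue], dtype=float)

    def scaled(self, k: float) -> "RGBTriplet":
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return RGBTriplet(self.n_red * k, self.n_green * k, self.n_blue * k,
                          self.bit_depth, self.pixel_count)


@dataclass(frozen=True)
class NormalizedRGB:
    """Unit-scaled channels with their max/min."""

    r: float
    g: float
    b: float
    i_max: float
    i_min: float


def normalize_rgb(
    t: RGBTriplet,
    max_value: float | None = None,
    clamp: bool = False,
) -> NormalizedRGB:
    """Divide channels by the channel maximum (from bit depth or explicit).

    Calibrated values above the maximum are an error unless ``clamp=True``.
    """
    if max_value is None:
        if t.bit_depth not in _BIT_DEPTH_MAX:
            raise ValueError(
                "unknown bit depth; supply max_value explicitly "
                f"(got bit_depth={t.bit_depth!r})"
            )
        max_value = _BIT_DEPTH_MAX[t.bit_depth]
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    vals = t.as_array() / max_value
    if np.any(vals > 1.0):
        if clamp:
            vals = np.clip(vals, 0.0, 1.0)
        else:
            raise ValueError(
                f"channel values exceed maximum {max_value}; pass clamp=True to clip"
            )
    r, g, b = (float(v) for v in vals)
    return NormalizedRGB(r, g, b, i_max=max(r, g, b), i_min=min(r, g, b))


def rgb_hsl_indices(n: NormalizedRGB, hue_convention: str = "paper") -> IndexSet:
    """Hue (two variants), brightness, lightness, saturation from (r, g, b).

    * ``H = (g−b)/((I_max−I_min)×60)`` — the as-defined convention divides
      by 60; ``hue_convention="hsl"`` multiplies instead, giving the
      standard sector-degree magnitude.
    * ``H′ = (2r−g−b)/(g−b)``; ``B = sqrt((r²+g²+b²)/3)``;
      ``L = (I_max+I_min)/2``; ``S = (I_max−I_min)/(2−(I_max+I_min))``.
    """
    if hue_convention not in ("paper", "hsl"):
        raise ValueError(f"unknown hue convention {hue_convention!r}")
    out = IndexSet("image")
    r, g, b = n.r, n.g, n.b
    spread = n.i_max - n.i_min
    if spread == 0.0:
        out.set("H", None, flag="undefined:achromatic")
    elif hue_convention == "paper":
        out.set("H", (g - b) / (spread * 60.0))
    else:
        out.set("H", 60.0 * (g - b) / spread)
    if g == b:
        out.set("H_prime", None, flag="undefined:g-equals-b")
    else:
        out.set("H_prime", (2.0 * r - g - b) / (g - b))
    out.set("B", float(np.sqrt((r * r + g * g + b * b) / 3.0)))
    out.set("L", (n.i_max + n.i_min) / 2.0)
    den = 2.0 - (n.i_max + n.i_min)
    if den == 0.0:
        out.set("S", None, flag="undefined:pure-white")
    else:
        out.set("S", spread / den)
    return out


def rgb_chroma_indices(t: RGBTriplet) -> IndexSet:
    """``C = (N_red−N_green)/((N_red+N_green+N_blue)/3)`` and
    ``C′ = sqrt((N_red−N_green)² + (N_blue−N_green)²)``."""
    out = IndexSet("image")
    total = t.n_red + t.n_green + t.n_blue
    if total == 0.0:
        out.set("C", None, flag="undefined:zero-sum")
    else:
        out.set("C", (t.n_red - t.n_green) / (total / 3.0))
    out.set(
        "C_prime",
        float(np.hypot(t.n_red - t.n_green, t.n_blue - t.n_green)),
    )
    return out


def rgb_anthocyanin_indices(t: RGBTriplet) -> IndexSet:
    """``AC_CD = (N_blue+N_red)/2 − N_green``,
    ``AC_CR = N_green/((N_blue+N_red)/2)``,
    ``AC_CB = (N_blue+N_red)/N_green``, ``R:G_R = N_red/N_green``."""
    out = IndexSet("image")
    plateau = (t.n_blue + t.n_red) / 2.0
    out.set("AC_CD", plateau - t.n_green)
    if plateau == 0.0:
        out.set("AC_CR", None, flag="undefined:zero-denominator")
    else:
        out.set("AC_CR", t.n_green / plateau)
    if t.n_green == 0.0:
        out.set("AC_CB", None, flag="undefined:zero-denominator")
        out.set("R:G_R", None, flag="undefined:zero-denominator")
    else:
        out.set("AC_CB", (t.n_blue + t.n_red) / t.n_green)
        out.set("R:G_R", t.n_red / t.n_green)
    return out


def rgb_strength_indices(t: RGBTriplet) -> IndexSet:
    """Each channel divided by the channel sum; defined strengths add to 1."""
    out = IndexSet("image")
    total = t.n_red + t.n_green + t.n_blue
    if total == 0.0:
        for name in ("S_green", "S_red", "S_blue"):
            out.set(name, None, flag="undefined:zero-sum")
        return out
    out.set("S_green", t.n_green / total)
    out.set("S_red", t.n_red / total)
    out.set("S_blue", t.n_blue / total)
    return out


def compute_rgb_indices(
    t: RGBTriplet,
    max_value: float | None = None,
    hue_convention: str = "paper",
    clamp: bool = False,
) -> IndexSet:
    """All 14 image-branch indices for one ROI triplet."""
    out = IndexSet("image")
    n = normalize_rgb(t, max_value=max_value, clamp=clamp)
    out.update(rgb_hsl_indices(n, hue_convention=hue_convention))
    out.update(rgb_chroma_indices(t))
    out.update(rgb_anthocyanin_indices(t))
    out.update(rgb_strength_indices(t))
    return out


def read_triplets_csv(path) -> dict[str, RGBTriplet]:
    """Read triplets from CSV with columns sample_id, n_red, n_green, n_blue
    and optional bit_depth / pixel_count."""
    df = pd.read_csv(path)
    required = {"sample_id", "n_red", "n_green", "n_blue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"triplet CSV missing columns: {sorted(missing)}")
    out: dict[str, RGBTriplet] = {}
    for _, row in df.iterrows():
        out[str(row["sample_id"])] = RGBTriplet(
            float(row["n_red"]),
            float(row["n_green"]),
            float(row["n_blue"]),
            bit_depth=int(row["bit_depth"]) if "bit_depth" in df.columns and pd.notna(row.get("bit_depth")) else None,
            pixel_count=int(row["pixel_count"]) if "pixel_count" in df.columns and pd.notna(row.get("pixel_count")) else 1,
        )
    return out
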