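"""Synthetic specimens: paired concentration, spectrum and rendered image.

The generator gives every other module a testable end-to-end path with the
optical structure the estimation method assumes:

* **Pigment model** — tissue reflectance is a smooth baseline attenuated
  Beer–Lambert style, ``R(λ) = baseline(λ)·10^(−(c_anth·ε_a(λ) + c_chl·ε_c(λ)))``,
  with Gaussian absorptivity bands: one anthocyanin band centered at 530 nm
  (anthocyanins absorb at ~520–560 nm) and two chlorophyll bands at 430 and
  660 nm.  Concentrations are in the same AU·cm⁻² units as the biochemical
  response, so the ground truth plugs directly into the regression modules.
  Measurement noise is multiplicative lognormal per wavelength.
* **Camera model** — three Gaussian channel sensitivities (centers
  600/530/460 nm for R/G/B) integrate the spectrum under an illuminant; the
  product of sensitivity and illuminant is normalized to unit area so a flat
  R% spectrum maps to ``gain·R + offset`` digital numbers, making the sensor
  affine in band-weighted reflectance and hence exactly invertible by
  two-gray-standard calibration.
* **Renderer** — an image frame containing the two gray-standard patches
  (rendered through the same camera from their known reflectances) and a
  tissue region that is uniform, striped, spotted or veined, with per-pixel
  Gaussian read noise and quantization to the sensor bit depth.

All randomness flows from one seeded generator per dataset, so a fixed seed
reproduces every file bit for bit.
"""

from __future__ import annotations

import json
import math
import warnings
from collections.abc import Callable
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from anthoquant.imaging import (
    DEFAULT_DARK_REF,
    DEFAULT_LIGHT_REF,
    LinearImage,
    ROI,
)
from anthoquant.rgb import RGBTriplet
from anthoquant.spectra import Spectrum

__all__ = [
    "PigmentModel",
    "CameraModel",
    "SyntheticSpecimen",
    "simulate_reflectance",
    "camera_response",
    "render_specimen",
    "generate_dataset",
    "write_dataset",
]

PATTERNS = ("uniform", "striped", "spotted", "veined")


@dataclass(frozen=True)
class PigmentModel:
    """Optical model of pigmented tissue reflectance.

    Defaults describe an anthocyanin-bearing petal: a logistic baseline
    rising from ~10% (UV) to ~70% (NIR); an anthocyanin absorption band at
    530 nm (σ 35 nm) whose strength of 2.5 per AU·cm⁻² puts the peak optical
    density near 0.83 at the top of the petal concentration range
    (0.33 AU·cm⁻²), dropping 550-nm reflectance to roughly 13% — the level of
    the darkest petals the method targets; chlorophyll bands at 430 and
    660 nm; and 5% multiplicative measurement noise (CV).
    """

    base_min: float = 10.0
    base_amp: float = 60.0
    base_center_nm: float = 420.0
    base_scale_nm: float = 60.0
    anth_center_nm: float = 530.0
    anth_width_nm: float = 35.0
    anth_strength: float = 2.5
    chl_centers_nm: tuple[float, float] = (430.0, 660.0)
    chl_widths_nm: tuple[float, float] = (25.0, 18.0)
    chl_strengths: tuple[float, float] = (1.0, 0.8)
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        centers = (self.anth_center_nm, *self.chl_centers_nm)
        if any(not (300.0 <= c <= 800.0) for c in centers):
            raise ValueError("absorption band centers must lie in 300–800 nm")
        widths = (self.anth_width_nm, *self.chl_widths_nm)
        if any(w <= 0 for w in widths):
            raise ValueError("band widths must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")

    def baseline(self, wl: np.ndarray) -> np.ndarray:
        """Unpigmented tissue reflectance, percent."""
        return self.base_min + self.base_amp / (
            1.0 + np.exp(-(wl - self.base_center_nm) / self.base_scale_nm)
        )

    def absorptivity_anthocyanin(self, wl: np.ndarray) -> np.ndarray:
        """Optical density per unit anthocyanin concentration."""
        z = (wl - self.anth_center_nm) / self.anth_width_nm
        return self.anth_strength * np.exp(-0.5 * z * z)

    def absorptivity_chlorophyll(self, wl: np.ndarray) -> np.ndarray:
        """Optical density per unit chlorophyll concentration (two bands)."""
        total = np.zeros_like(wl, dtype=float)
        for c, w, s in zip(self.chl_centers_nm, self.chl_widths_nm, self.chl_strengths):
            z = (wl - c) / w
            total += s * np.exp(-0.5 * z * z)
        return total


def simulate_reflectance(
    model: PigmentModel,
    c_anth: float,
    c_chl: float = 0.0,
    rng: np.random.Generator | None = None,
    grid_step: float = 1.0,
) -> Spectrum:
    """Render a 300–800 nm reflectance spectrum for given pigment loads.

    Noise (multiplicative lognormal at the model's CV, unit mean) is applied
    only when an ``rng`` is supplied; pass ``rng=None`` for the noise-free
    expectation.
    """
    if c_anth < 0 or c_chl < 0:
        raise ValueError("concentrations must be >= 0")
    n = int(round(500.0 / grid_step))
    wl = 300.0 + grid_step * np.arange(n + 1)
    od = c_anth * model.absorptivity_anthocyanin(wl)
    od += c_chl * model.absorptivity_chlorophyll(wl)
    r = model.baseline(wl) * 10.0 ** (-od)
    if rng is not None and model.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + model.noise_cv**2))
        r = r * rng.lognormal(-0.5 * sigma * sigma, sigma, size=r.shape)
    return Spectrum(wl, r, meta=f"synthetic c_anth={c_anth:.4f} c_chl={c_chl:.4f}")


@dataclass(frozen=True)
class CameraModel:
    """Three-channel camera with Gaussian sensitivities and affine gain.

    ``gains`` are digital numbers per percent reflectance and ``offsets``
    are dark-level DN; defaults keep a 60.9% standard near 56% of the 16-bit
    range, mimicking the deliberate underexposure used to avoid clipping.
    """

    centers_nm: tuple[float, float, float] = (600.0, 530.0, 460.0)  # R, G, B
    widths_nm: tuple[float, float, float] = (30.0, 30.0, 30.0)
    gains: tuple[float, float, float] = (560.0, 580.0, 600.0)
    offsets: tuple[float, float, float] = (800.0, 900.0, 1000.0)
    bit_depth: int = 16
    read_noise_dn: float = 30.0
    #: callable λ(nm array) -> relative power; None means a flat illuminant
    illuminant: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gains):
            raise ValueError("gains must be positive")
        if any(w <= 0 for w in self.widths_nm):
            raise ValueError("sensitivity widths must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")

    @property
    def sensor_max(self) -> float:
        return float(2**self.bit_depth - 1)

    def weights(self, wl: np.ndarray) -> np.ndarray:
        """(3, n) sensitivity×illuminant weights, each normalized to unit sum."""
        illum = np.ones_like(wl) if self.illuminant is None else self.illuminant(wl)
        rows = []
        for c, w in zip(self.centers_nm, self.widths_nm):
            z = (wl - c) / w
            s = np.exp(-0.5 * z * z) * illum
            rows.append(s / s.sum())
        return np.vstack(rows)


def camera_response(
    spec: Spectrum,
    cam: CameraModel,
    rng: np.random.Generator | None = None,
    quantize: bool = True,
) -> RGBTriplet:
    """Project a spectrum through the camera: band-weighted reflectance per
    channel, scaled by gain, shifted by offset, optionally noised and
    quantized to the sensor bit depth."""
    wl = spec.wavelengths_nm
    lo, hi = spec.span
    for c, w in zip(cam.centers_nm, cam.widths_nm):
        if c - 3 * w < lo or c + 3 * w > hi:
            raise ValueError(
                f"spectrum [{lo}, {hi}] nm does not cover channel support "
                f"around {c} nm"
            )
    band_refl = cam.weights(wl) @ spec.reflectance  # percent, per channel
    dn = np.asarray(cam.gains) * band_refl + np.asarray(cam.offsets)
    if rng is not None and cam.read_noise_dn > 0:
        dn = dn + rng.normal(0.0, cam.read_noise_dn, size=3)
    if quantize:
        dn = np.clip(np.rint(dn), 0, cam.sensor_max)
    return RGBTriplet(float(dn[0]), float(dn[1]), float(dn[2]), bit_depth=cam.bit_depth)


def _flat_spectrum(level_pct: float) -> Spectrum:
    wl = np.arange(300.0, 801.0, 1.0)
    return Spectrum(wl, np.full_like(wl, level_pct))


def standard_responses(cam: CameraModel,
                       dark_ref: float = DEFAULT_DARK_REF,
                       light_ref: float = DEFAULT_LIGHT_REF) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free, unquantized DN means of the two gray standards."""
    dark = camera_response(_flat_spectrum(dark_ref), cam, quantize=False)
    light = camera_response(_flat_spectrum(light_ref), cam, quantize=False)
    return dark.as_array(), light.as_array()


# ---------------------------------------------------------------------------
# pattern fields


def _pattern_field(
    pattern: str,
    shape: tuple[int, int],
    rng: np.random.Generator,
    stripe_period_px: int = 16,
    stripe_duty: float = 0.5,
    n_spots: int = 12,
    spot_radius_px: float = 6.0,
) -> np.ndarray:
    """Pigment-richness field in [0, 1]: 1 = pigment-rich phase."""
    h, w = shape
    if pattern == "uniform":
        return np.ones(shape)
    if pattern == "striped":
        y = np.arange(h)[:, None] * np.ones((1, w))
        phase = (y / stripe_period_px) % 1.0
        return (phase < stripe_duty).astype(float)
    if pattern == "spotted":
        field_ = np.zeros(shape)
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(n_spots):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            r = spot_radius_px * rng.uniform(0.6, 1.4)
            field_[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = 1.0
        return field_
    if pattern == "veined":
        field_ = np.zeros(shape)

        def branch(y, x, angle, length, width, depth):
            for _ in range(int(length)):
                y += math.sin(angle)
                x += math.cos(angle)
                angle += rng.normal(0.0, 0.15)
                iy, ix = int(round(y)), int(round(x))
                if not (0 <= iy < h and 0 <= ix < w):
                    return
                r = int(math.ceil(width))
                field_[max(0, iy - r): iy + r + 1, max(0, ix - r): ix + r + 1] = 1.0
            if depth > 0:
                for sign in (-1.0, 1.0):
                    branch(y, x, angle + sign * rng.uniform(0.3, 0.8),
                           length * 0.6, max(1.0, width * 0.7), depth - 1)

        for x0 in np.linspace(0.15 * w, 0.85 * w, 3):
            branch(0.0, float(x0), math.pi / 2, h * 0.45, 1.5, 2)
        return field_
    raise ValueError(f"unknown pattern {pattern!r}; expected one of {PATTERNS}")


# ---------------------------------------------------------------------------
# rendering


def render_specimen(
    triplet_rich: RGBTriplet,
    pattern: str,
    cam: CameraModel,
    rng: np.random.Generator,
    triplet_poor: RGBTriplet | None = None,
    modulation_depth: float = 0.0,
    size: tuple[int, int] = (96, 128),
    dark_ref: float = DEFAULT_DARK_REF,
    light_ref: float = DEFAULT_LIGHT_REF,
    add_noise: bool = True,
    **pattern_kwargs,
) -> tuple[LinearImage, dict[str, ROI]]:
    """Render a specimen frame: two gray-standard patches plus a tissue area.

    The tissue mixes a pigment-rich and a pigment-poor triplet through the
    pattern field: pixel = rich + depth·(1−field)·(poor−rich), so depth 0 or
    pattern ``uniform`` gives a constant tissue.  Returns the (uncalibrated)
    sensor image and the dark/light/tissue ROIs, which are disjoint by
    construction.
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("image must be at least 64×64")
    if not 0.0 <= modulation_depth <= 1.0:
        raise ValueError("modulation_depth must lie in [0, 1]")
    if modulation_depth > 0:
        if triplet_poor is None:
            raise ValueError("modulation_depth > 0 requires a pigment-poor triplet")
        if np.allclose(triplet_poor.as_array(), triplet_rich.as_array()):
            warnings.warn("modulation requested but rich and poor triplets are "
                          "identical: zero pigment contrast", stacklevel=2)
    strip = h // 4
    img = np.zeros((h, w, 3), dtype=float)
    dark_dn, light_dn = standard_responses(cam, dark_ref, light_ref)
    dark_rect = (2, 2, w // 2 - 4, strip - 4)
    light_rect = (w // 2 + 2, 2, w // 2 - 4, strip - 4)
    tissue_rect = (2, strip + 2, w - 4, h - strip - 4)
    img[2: strip - 2, 2: w // 2 - 2] = dark_dn
    img[2: strip - 2, w // 2 + 2: w - 2] = light_dn

    rich = triplet_rich.as_array()
    poor = rich if triplet_poor is None else triplet_poor.as_array()
    tx, ty, tw, th = tissue_rect
    field_ = _pattern_field(pattern, (th, tw), rng, **pattern_kwargs)
    mix = rich[None, None, :] + modulation_depth * (1.0 - field_[..., None]) * (
        poor - rich
    )[None, None, :]
    img[ty: ty + th, tx: tx + tw] = mix

    if add_noise and cam.read_noise_dn > 0:
        img = img + rng.normal(0.0, cam.read_noise_dn, size=img.shape)
    img = np.clip(np.rint(img), 0, cam.sensor_max)
    rois = {
        "dark_standard": ROI(label="dark_standard", rect=dark_rect),
        "light_standard": ROI(label="light_standard", rect=light_rect),
        "tissue": ROI(label="tissue", rect=tissue_rect),
    }
    return LinearImage(img, cam.bit_depth), rois


@dataclass
class SyntheticSpecimen:
    """One synthetic sample with ground truth alongside every rendering."""

    sample_id: str
    true_concentration: float
    c_chlorophyll: float
    spectrum: Spectrum
    triplet: RGBTriplet  # camera response of the (rich-phase) spectrum
    pattern: str
    seed: int
    image: LinearImage | None = None
    rois: dict[str, ROI] | None = None


def generate_dataset(
    n: int,
    conc_range: tuple[float, float] = (0.04, 0.33),
    pattern: str = "uniform",
    model: PigmentModel | None = None,
    cam: CameraModel | None = None,
    seed: int | None = None,
    c_chl: float = 0.0,
    modulation_depth: float = 0.5,
    size: tuple[int, int] = (96, 128),
    render_images: bool = True,
) -> list[SyntheticSpecimen]:
    """Draw ``n`` specimens with concentrations uniform over ``conc_range``.

    The default range, 0.04–0.33 AU·cm⁻², is a petal-like span of relative
    anthocyanin concentrations.  A fixed seed reproduces the dataset
    bit-identically.  ``render_images=False`` skips the rendering branch for
    purely statistical studies; the spectrum and camera triplet are always
    produced.
    """
    if n < 4:
        raise ValueError("need n >= 4 specimens")
    lo, hi = conc_range
    if not lo < hi:
        raise ValueError(f"degenerate concentration range {conc_range}")
    if lo < 0:
        raise ValueError("concentrations must be >= 0")
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; expected one of {PATTERNS}")
    model = model or PigmentModel()
    cam = cam or CameraModel()
    root_seed = 0 if seed is None else int(seed)
    rng = np.random.default_rng(root_seed)
    concs = rng.uniform(lo, hi, size=n)
    specimens: list[SyntheticSpecimen] = []
    for i, c in enumerate(concs):
        spec = simulate_reflectance(model, float(c), c_chl, rng=rng)
        triplet = camera_response(spec, cam)
        image = rois = None
        if render_images:
            poor = None
            if pattern != "uniform" and modulation_depth > 0:
                poor_spec = simulate_reflectance(
                    model, float(c) * (1.0 - modulation_depth), c_chl, rng=rng
                )
                poor = camera_response(poor_spec, cam)
            image, rois = render_specimen(
                triplet,
                pattern,
                cam,
                rng,
                triplet_poor=poor,
                modulation_depth=modulation_depth if pattern != "uniform" else 0.0,
                size=size,
            )
        specimens.append(
            SyntheticSpecimen(
                sample_id=f"syn{i:03d}",
                true_concentration=float(c),
                c_chlorophyll=c_chl,
                spectrum=spec,
                triplet=triplet,
                pattern=pattern,
                seed=root_seed,
                image=image,
                rois=rois,
            )
        )
    return specimens


def write_dataset(specimens: list[SyntheticSpecimen], out_dir) -> pd.DataFrame:
    """Write TIFF images, spectrum CSVs, ROI JSONs and ground_truth.csv."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sp in specimens:
        np.savetxt(
            out / f"{sp.sample_id}_spectrum.csv",
            np.column_stack([sp.spectrum.wavelengths_nm, sp.spectrum.reflectance]),
            delimiter=",",
            header="wavelength_nm,reflectance_pct",
            comments="# ",
            fmt="%.6f",
        )
        if sp.image is not None:
            dtype = np.uint8 if sp.image.bit_depth == 8 else np.uint16
            tifffile.imwrite(
                out / f"{sp.sample_id}.tif", sp.image.data.astype(dtype)
            )
            (out / f"{sp.sample_id}_rois.json").write_text(
                json.dumps([r.to_dict() for r in sp.rois.values()], indent=2)
            )
        rows.append(
            {
                "sample_id": sp.sample_id,
                "true_concentration_au_cm2": sp.true_concentration,
                "c_chlorophyll": sp.c_chlorophyll,
                "pattern": sp.pattern,
                "seed": sp.seed,
            }
        )
    truth = pd.DataFrame(rows)
    truth.to_csv(out / "ground_truth.csv", index=False)
    return truth
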