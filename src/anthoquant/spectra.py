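"""Reflectance spectra and the 14 spectral color indices.

A :class:`Spectrum` holds percent reflectance relative to a white standard
on a strictly increasing wavelength grid, nominally 300–800 nm.  From it the
module computes:

* basic indices — hue ``H`` (wavelength of peak reflectance), brightness
  ``B`` (300–699 nm aggregate) and chroma ``C``;
* segment-classification indices ``H_SC`` / ``C_SC`` from the contrasts of
  the four 100-nm segments of 300–699 nm (Endler-style segment analysis);
* anthocyanin-content indices ``AC_CD``, ``AC_CR``, ``AC_CB`` built on the
  reflectance plateau/trough structure (peaks near 450 and 650 nm, trough
  near 550 nm where anthocyanins absorb), plus red:green ratios ``R:G_R``,
  ``R:G_I`` and the modified anthocyanin content index ``mACI``;
* channel-strength indices ``S_green``, ``S_red``, ``S_blue``.

Window aggregation defaults to the band *mean* so that windows of unequal
width (e.g. 760–800 vs 540–560 nm) contribute width-invariant quantities;
``mode="sum"`` reproduces the literal summation formulas.  The two choices
agree up to the per-window point count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from anthoquant.indexset import IndexSet

__all__ = [
    "Spectrum",
    "resample_spectrum",
    "band_aggregate",
    "point_reflectance",
    "spectral_basic_indices",
    "spectral_segment_indices",
    "spectral_anthocyanin_indices",
    "spectral_strength_indices",
    "compute_spectral_indices",
    "read_spectrum_text",
    "read_spectra_wide_csv",
]

_TOL = 1e-9

# Analysis range shared by H, B, C and the segment indices.
ANALYSIS_RANGE = (300.0, 699.0)
SEGMENTS = ((300.0, 399.0), (400.0, 499.0), (500.0, 599.0), (600.0, 699.0))


@dataclass
class Spectrum:
    """Percent reflectance on a strictly increasing wavelength grid (nm)."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    meta: str = ""
    clamp_negative: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or r.ndim != 1 or wl.size != r.size:
            raise ValueError("wavelengths and reflectance must be equal-length 1-D")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectance values must be finite")
        if np.any(r < 0):
            if self.clamp_negative:
                r = np.clip(r, 0.0, None)
            else:
                raise ValueError(
                    "negative reflectance values; pass clamp_negative=True to clip to 0"
                )
        self.wavelengths_nm = wl
        self.reflectance = r

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def covers(self, lo: float, hi: float) -> bool:
        a, b = self.span
        return a <= lo + _TOL and b >= hi - _TOL

    def scaled(self, k: float) -> "Spectrum":
        """Spectrum with reflectance multiplied by ``k`` (k > 0)."""
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return Spectrum(self.wavelengths_nm.copy(), self.reflectance * k, self.meta)


def resample_spectrum(
    raw_pairs,
    grid_start: float,
    grid_stop: float,
    grid_step: float,
) -> Spectrum:
    """Linearly interpolate raw (nm, reflectance) pairs onto a uniform grid.

    Duplicate input wavelengths are averaged; the requested grid must lie
    inside the span of the raw data (no extrapolation).
    """
    pairs = np.asarray(list(raw_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("raw_pairs must be (wavelength, reflectance) pairs")
    order = np.argsort(pairs[:, 0], kind="stable")
    wl, r = pairs[order, 0], pairs[order, 1]
    # average duplicated wavelengths
    uniq, inverse, counts = np.unique(wl, return_inverse=True, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct wavelengths to resample")
    sums = np.zeros_like(uniq)
    np.add.at(sums, inverse, r)
    r_uniq = sums / counts
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if grid_start < uniq[0] - _TOL or grid_stop > uniq[-1] + _TOL:
        raise ValueError(
            f"grid [{grid_start}, {grid_stop}] outside data span "
            f"[{uniq[0]}, {uniq[-1]}]"
        )
    n = int(round((grid_stop - grid_start) / grid_step))
    grid = grid_start + grid_step * np.arange(n + 1)
    grid = grid[grid <= grid_stop + _TOL]
    values = np.interp(grid, uniq, r_uniq)
    return Spectrum(grid, values)


def band_aggregate(spec: Spectrum, lo: float, hi: float, mode: str = "mean") -> float:
    """Aggregate reflectance over the inclusive window ``lo <= λ <= hi``.

    ``mode="sum"`` is the raw Σ over grid points, ``mode="mean"`` divides by
    the point count.
    """
    if lo > hi:
        raise ValueError(f"empty window: lo {lo} > hi {hi}")
    if mode not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    wl = spec.wavelengths_nm
    mask = (wl >= lo - _TOL) & (wl <= hi + _TOL)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] nm contains no grid points")
    if np.median(np.diff(wl)) > 1.0 + _TOL:
        warnings.warn(
            "spectrum grid is coarser than 1 nm; window aggregates may be crude",
            stacklevel=2,
        )
    total = float(spec.reflectance[mask].sum())
    if mode == "sum":
        return total
    return total / int(mask.sum())


def point_reflectance(spec: Spectrum, target: float) -> float:
    """Reflectance at ``target`` nm: exact grid value, else linear interpolation."""
    a, b = spec.span
    if target < a - _TOL or target > b + _TOL:
        raise ValueError(f"target {target} nm outside spectrum span [{a}, {b}]")
    return float(np.interp(target, spec.wavelengths_nm, spec.reflectance))


def _require_coverage(spec: Spectrum, lo: float, hi: float) -> None:
    if not spec.covers(lo, hi):
        a, b = spec.span
        raise ValueError(
            f"spectrum spans [{a}, {b}] nm but [{lo}, {hi}] nm is required"
        )


def spectral_basic_indices(spec: Spectrum, mode: str = "mean") -> IndexSet:
    """Hue H (λ of peak reflectance, ties to the lowest λ), brightness B, chroma C."""
    _require_coverage(spec, *ANALYSIS_RANGE)
    out = IndexSet("spectral")
    lo, hi = ANALYSIS_RANGE
    wl = spec.wavelengths_nm
    mask = (wl >= lo - _TOL) & (wl <= hi + _TOL)
    r = spec.reflectance[mask]
    w = wl[mask]
    out.set("B", band_aggregate(spec, lo, hi, mode=mode))
    r_max, r_min = float(r.max()), float(r.min())
    if r_max == r_min:
        # constant spectrum: peak position is arbitrary, chroma vanishes
        out.set("H", float(w[0]), flag="degenerate-constant")
        out.set("C", 0.0, flag="degenerate-constant")
        return out
    out.set("H", float(w[np.argmax(r)]))  # argmax -> first (lowest λ) on ties
    out.set("C", (r_max - r_min) / float(r.mean()))
    return out


def spectral_segment_indices(spec: Spectrum, mode: str = "mean") -> IndexSet:
    """Segment-analysis hue H_SC (radians, in [0, 2π)) and chroma C_SC.

    With segment aggregates Q1..Q4 over the four 100-nm bands of 300–699 nm:
    ``C_SC = hypot(Q4−Q2, Q3−Q1)`` and
    ``H_SC = sign(Q3−Q1)·arcsin((Q4−Q2)/C_SC) mod 2π``.
    ``sign(0)`` is taken as 0 (flagged sign-degenerate); C_SC = 0 leaves
    H_SC undefined.
    """
    _require_coverage(spec, *ANALYSIS_RANGE)
    out = IndexSet("spectral")
    q = [band_aggregate(spec, lo, hi, mode=mode) for lo, hi in SEGMENTS]
    dx = q[3] - q[1]  # red − blue segment contrast
    dy = q[2] - q[0]  # green − UV/violet segment contrast
    c_sc = math.hypot(dx, dy)
    out.set("C_SC", c_sc)
    if c_sc == 0.0:
        out.set("H_SC", None, flag="undefined:zero-segment-chroma")
        return out
    ratio = min(1.0, max(-1.0, dx / c_sc))
    if dy == 0.0:
        out.set("H_SC", 0.0, flag="sign-degenerate")
        return out
    h = math.copysign(1.0, dy) * math.asin(ratio)
    out.set("H_SC", h % (2.0 * math.pi))
    return out


def spectral_anthocyanin_indices(spec: Spectrum, mode: str = "mean") -> IndexSet:
    """Anthocyanin-content and red:green indices.

    ``AC_CD = (R450+R650)/2 − R550``, ``AC_CR = R550/((R450+R650)/2)``,
    ``AC_CB = (R450+R650)/R550``; ``R:G_R``, ``R:G_I`` and ``mACI`` are
    window-aggregate ratios (600–699/500–599, 690–710/540–560 and
    760–800/540–560 nm respectively).
    """
    out = IndexSet("spectral")
    _require_coverage(spec, 450.0, 650.0)
    r450 = point_reflectance(spec, 450.0)
    r550 = point_reflectance(spec, 550.0)
    r650 = point_reflectance(spec, 650.0)
    plateau = (r450 + r650) / 2.0
    out.set("AC_CD", plateau - r550)
    if plateau == 0.0:
        out.set("AC_CR", None, flag="undefined:zero-denominator")
    else:
        out.set("AC_CR", r550 / plateau)
    if r550 == 0.0:
        out.set("AC_CB", None, flag="undefined:zero-denominator")
    else:
        out.set("AC_CB", (r450 + r650) / r550)

    def ratio(name, num_win, den_win):
        _require_coverage(spec, den_win[0], den_win[1])
        _require_coverage(spec, num_win[0], num_win[1])
        den = band_aggregate(spec, *den_win, mode=mode)
        if den == 0.0:
            out.set(name, None, flag="undefined:zero-denominator")
        else:
            out.set(name, band_aggregate(spec, *num_win, mode=mode) / den)

    ratio("R:G_R", (600.0, 699.0), (500.0, 599.0))
    ratio("R:G_I", (690.0, 710.0), (540.0, 560.0))
    ratio("mACI", (760.0, 800.0), (540.0, 560.0))
    return out


def spectral_strength_indices(spec: Spectrum, mode: str = "mean") -> IndexSet:
    """Channel strengths S_green/S_red/S_blue from three visible windows.

    The green (545–565 nm), red (620–670 nm) and blue (459–479 nm) window
    aggregates are each divided by their three-way sum, so the defined
    strengths always add to 1.
    """
    out = IndexSet("spectral")
    for lo, hi in ((459.0, 479.0), (545.0, 565.0), (620.0, 670.0)):
        _require_coverage(spec, lo, hi)
    g = band_aggregate(spec, 545.0, 565.0, mode=mode)
    r = band_aggregate(spec, 620.0, 670.0, mode=mode)
    b = band_aggregate(spec, 459.0, 479.0, mode=mode)
    den = g + r + b
    if den == 0.0:
        for name in ("S_green", "S_red", "S_blue"):
            out.set(name, None, flag="undefined:zero-denominator")
        return out
    out.set("S_green", g / den)
    out.set("S_red", r / den)
    out.set("S_blue", b / den)
    return out


def compute_spectral_indices(spec: Spectrum, mode: str = "mean") -> IndexSet:
    """All 14 spectral indices; indices whose windows fall outside the
    spectrum's span are flagged undefined rather than raising, so a sweep
    over heterogeneous spectra always completes."""
    out = IndexSet("spectral")
    groups = (
        (spectral_basic_indices, ("H", "B", "C")),
        (spectral_segment_indices, ("H_SC", "C_SC")),
        (spectral_anthocyanin_indices, ("AC_CD", "AC_CR", "AC_CB", "R:G_R", "R:G_I", "mACI")),
        (spectral_strength_indices, ("S_green", "S_red", "S_blue")),
    )
    for fn, names in groups:
        try:
            out.update(fn(spec, mode=mode))
        except ValueError as exc:
            for name in names:
                out.set(name, None, flag=f"undefined:{exc}")
    return out


# ---------------------------------------------------------------------------
# I/O


def read_spectrum_text(path, clamp_negative: bool = False, meta: str | None = None) -> Spectrum:
    """Read a two-column delimited text spectrum (nm, % reflectance).

    Lines starting with ``#`` are comments; whitespace and comma delimiters
    are both accepted.
    """
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}: cannot parse line {line!r}")
        rows.append((float(parts[0]), float(parts[1])))
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    return Spectrum(
        arr[order, 0],
        arr[order, 1],
        meta=meta if meta is not None else path.stem,
        clamp_negative=clamp_negative,
    )


def read_spectra_wide_csv(path, clamp_negative: bool = False) -> dict[str, Spectrum]:
    """Read a wide CSV (first column wavelength, one column per sample)."""
    df = pd.read_csv(path, comment="#")
    wl_col = df.columns[0]
    df = df.sort_values(wl_col)
    wl = df[wl_col].to_numpy(dtype=float)
    return {
        str(col): Spectrum(wl, df[col].to_numpy(dtype=float), meta=str(col),
                           clamp_negative=clamp_negative)
        for col in df.columns[1:]
    }
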