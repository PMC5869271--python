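"""Spectrophotometric absorbance -> relative anthocyanin concentration.

Extract absorbance at the pigment's λ_max, averaged over replicates, is the
biochemical measure of anthocyanin content.  In photosynthetic tissue a
chlorophyll contribution is removed first (A_max − 0.24·A_653); the result
is divided by the sampled tissue area to give the per-area concentration in
AU·cm⁻² used as the regression response throughout the package.  A corrected
absorbance that comes out negative is floored to zero and flagged so the
event stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CHLOROPHYLL_COEFF",
    "AbsorbanceRecord",
    "AnthocyaninConcentration",
    "correct_photosynthetic_absorbance",
    "anthocyanin_per_area",
    "read_absorbance_csv",
    "concentrations_to_frame",
]

#: Coefficient removing chlorophyll's contribution at λ_max via A_653.
CHLOROPHYLL_COEFF = 0.24


@dataclass(frozen=True)
class AbsorbanceRecord:
    """Replicate absorbance readings at λ_max for one tissue sample."""

    replicates: tuple[float, ...]
    area_cm2: float
    a_653: float = 0.0
    photosynthetic: bool = False
    dilution_factor: float = 1.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValueError("need at least one replicate reading")
        if any(a < 0 for a in self.replicates) or self.a_653 < 0:
            raise ValueError("absorbances must be >= 0")
        if self.area_cm2 <= 0:
            raise ValueError("tissue area must be positive")
        if self.dilution_factor <= 0:
            raise ValueError("dilution factor must be positive")

    @property
    def a_max(self) -> float:
        """Replicate mean absorbance at λ_max."""
        return float(np.mean(self.replicates))


@dataclass(frozen=True)
class AnthocyaninConcentration:
    """Relative anthocyanin concentration, AU·cm⁻²."""

    value: float
    corrected: bool
    floored: bool = False
    sample_id: str = ""


def correct_photosynthetic_absorbance(a_max: float, a_653: float) -> tuple[float, bool]:
    """Remove chlorophyll's contribution: ``A_max − 0.24·A_653``.

    Returns ``(corrected, floored)``; a negative result is floored to 0 and
    flagged.
    """
    if a_max < 0 or a_653 < 0:
        raise ValueError("absorbances must be >= 0")
    value = a_max - CHLOROPHYLL_COEFF * a_653
    if value < 0:
        return 0.0, True
    return value, False


def anthocyanin_per_area(rec: AbsorbanceRecord) -> AnthocyaninConcentration:
    """Replicate-mean absorbance (chlorophyll-corrected for photosynthetic
    tissue), scaled by the dilution factor and divided by tissue area."""
    floored = False
    a = rec.a_max
    if rec.photosynthetic:
        a, floored = correct_photosynthetic_absorbance(a, rec.a_653)
    value = a * rec.dilution_factor / rec.area_cm2
    return AnthocyaninConcentration(
        value=value,
        corrected=rec.photosynthetic,
        floored=floored,
        sample_id=rec.sample_id,
    )


def read_absorbance_csv(path) -> list[AbsorbanceRecord]:
    """Read absorbance records from CSV.

    Expected columns: ``sample_id, area_cm2, photosynthetic`` plus either
    replicate columns ``rep1, rep2, ...`` or a single ``a_max`` column;
    optional ``a_653`` and ``dilution_factor``.
    """
    df = pd.read_csv(Path(path))
    rep_cols = [c for c in df.columns if c.lower().startswith("rep")]
    records = []
    for _, row in df.iterrows():
        if rep_cols:
            reps = tuple(float(row[c]) for c in rep_cols if pd.notna(row[c]))
        else:
            reps = (float(row["a_max"]),)
        records.append(
            AbsorbanceRecord(
                replicates=reps,
                area_cm2=float(row["area_cm2"]),
                a_653=float(row.get("a_653", 0.0) or 0.0),
                photosynthetic=bool(row.get("photosynthetic", False)),
                dilution_factor=float(row.get("dilution_factor", 1.0) or 1.0),
                sample_id=str(row["sample_id"]),
            )
        )
    return records


def concentrations_to_frame(concs) -> pd.DataFrame:
    """Tabulate concentrations: sample_id, concentration_au_cm2, corrected, floored."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "concentration_au_cm2": c.value,
                "corrected": c.corrected,
                "floored": c.floored,
            }
            for c in concs
        ]
    )
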