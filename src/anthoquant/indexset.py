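"""Named color-index collections shared by the spectral and image branches.

An :class:`IndexSet` maps index names to values for one sample and one data
source.  Indices whose defining formula is degenerate on a given sample
(zero denominator, achromatic input, ...) are stored as NaN with a flag
explaining why — a full 14-index sweep always completes, it never raises.
"""

from __future__ import annotations

import math
from collections.abc import Iterator, Mapping

import pandas as pd

#: The 14 indices computed from reflectance spectra.
SPECTRAL_INDEX_NAMES: tuple[str, ...] = (
    "H",
    "H_SC",
    "B",
    "C",
    "C_SC",
    "AC_CD",
    "AC_CR",
    "AC_CB",
    "R:G_R",
    "R:G_I",
    "mACI",
    "S_green",
    "S_red",
    "S_blue",
)

#: The 14 indices computed from calibrated RGB channel means.
IMAGE_INDEX_NAMES: tuple[str, ...] = (
    "H",
    "H_prime",
    "B",
    "L",
    "S",
    "C",
    "C_prime",
    "AC_CD",
    "AC_CR",
    "AC_CB",
    "R:G_R",
    "S_green",
    "S_red",
    "S_blue",
)


class IndexSet(Mapping):
    """Mapping of index name -> value with per-index definedness flags.

    Parameters
    ----------
    source:
        ``"spectral"`` or ``"image"`` — which branch produced the values.
    """

    def __init__(self, source: str) -> None:
        if source not in ("spectral", "image"):
            raise ValueError(f"unknown index source {source!r}")
        self.source = source
        self._values: dict[str, float] = {}
        self.flags: dict[str, str] = {}

    def set(self, name: str, value: float | None, flag: str | None = None) -> None:
        """Record one index.  ``value=None`` marks it undefined (stored NaN)."""
        if value is None:
            self._values[name] = math.nan
            self.flags[name] = flag or "undefined"
        else:
            self._values[name] = float(value)
            if flag is not None:
                self.flags[name] = flag

    def defined(self, name: str) -> bool:
        return name in self._values and not math.isnan(self._values[name])

    def update(self, other: "IndexSet") -> None:
        if other.source != self.source:
            raise ValueError("cannot merge index sets from different sources")
        self._values.update(other._values)
        self.flags.update(other.flags)

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ", ".join(f"{k}={v:.4g}" for k, v in self._values.items())
        return f"IndexSet({self.source}: {parts})"

    def to_tidy(self, sample_id: str) -> pd.DataFrame:
        """Tidy one-row-per-index frame: sample_id, source, index_name, value, defined_flag."""
        rows = [
            {
                "sample_id": sample_id,
                "source": self.source,
                "index_name": name,
                "value": value,
                "defined_flag": self.defined(name),
            }
            for name, value in self._values.items()
        ]
        return pd.DataFrame(rows)


def indices_to_tidy(sets: Mapping[str, IndexSet]) -> pd.DataFrame:
    """Concatenate per-sample index sets into one tidy frame keyed by sample id."""
    frames = [s.to_tidy(sample_id) for sample_id, s in sets.items()]
    if not frames:
        return pd.DataFrame(
            columns=["sample_id", "source", "index_name", "value", "defined_flag"]
        )
    return pd.concat(frames, ignore_index=True)


def tidy_to_wide(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy index frame to samples × indices (NaN where undefined)."""
    return tidy.pivot_table(
        index="sample_id", columns="index_name", values="value", dropna=False
    )
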