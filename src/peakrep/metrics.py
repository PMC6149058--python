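"""Daily sperm production (DSP) from testis homogenate counts.

A weighed testis fragment is homogenised in a known volume; spermatid heads
are counted on a haemocytometer.  Scaling the chamber count to the full
homogenate volume and from fragment to whole-testis weight gives total
spermatids per testis; dividing by the 4.84 days spermatids spend in
developmental steps 14-16 gives spermatids produced per day.

The haemocytometer chamber-count -> heads/microlitre conversion factor is
an explicit instrument input — no hidden constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["RESIDENCE_DAYS", "SpermCountInput", "daily_sperm_production", "dsp_batch"]

#: Days spermatids spend in steps 14-16 of spermatogenesis.
RESIDENCE_DAYS = 4.84


@dataclass(frozen=True)
class SpermCountInput:
    """Inputs for one testis sample.

    mean_heads_per_chamber : mean spermatid heads counted per chamber read
    heads_per_unit_volume_factor : heads/µl represented by one chamber count
        unit (instrument constant)
    homogenate_volume : µl of homogenate the fragment was dispersed in
    fragment_weight, testis_weight : mg
    residence_days : days in steps 14-16 (default 4.84)
    """

    mean_heads_per_chamber: float
    heads_per_unit_volume_factor: float
    homogenate_volume: float = 600.0
    fragment_weight: float = 1.0
    testis_weight: float = 1.0
    residence_days: float = RESIDENCE_DAYS

    def __post_init__(self) -> None:
        if self.mean_heads_per_chamber < 0:
            raise ValueError("mean_heads_per_chamber must be >= 0")
        for attr in (
            "heads_per_unit_volume_factor",
            "homogenate_volume",
            "fragment_weight",
            "testis_weight",
            "residence_days",
        ):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if self.fragment_weight > self.testis_weight:
            raise ValueError("fragment_weight cannot exceed testis_weight")


def daily_sperm_production(inp: SpermCountInput) -> float:
    """Spermatids produced per testis per day.

    total_spermatids = heads * factor * volume * (testis / fragment);
    DSP = total_spermatids / residence_days.  Linear in the chamber count
    and in the testis/fragment weight ratio.
    """
    total = (
        inp.mean_heads_per_chamber
        * inp.heads_per_unit_volume_factor
        * inp.homogenate_volume
        * (inp.testis_weight / inp.fragment_weight)
    )
    return total / inp.residence_days


def dsp_batch(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised DSP over a table of samples.

    Expects the :class:`SpermCountInput` field names as columns (missing
    optional columns take their defaults); returns the input with
    ``total_spermatids`` and ``dsp`` columns appended.
    """
    out = df.copy()
    defaults = SpermCountInput(0, 1)
    for col in ("homogenate_volume", "fragment_weight", "testis_weight", "residence_days"):
        if col not in out.columns:
            out[col] = getattr(defaults, col)
    out["dsp"] = [
        daily_sperm_production(
            SpermCountInput(
                mean_heads_per_chamber=row.mean_heads_per_chamber,
                heads_per_unit_volume_factor=row.heads_per_unit_volume_factor,
                homogenate_volume=row.homogenate_volume,
                fragment_weight=row.fragment_weight,
                testis_weight=row.testis_weight,
                residence_days=row.residence_days,
            )
        )
        for row in out.itertuples()
    ]
    out["total_spermatids"] = out["dsp"] * out["residence_days"]
    return out
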