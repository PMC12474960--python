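"""Derived germination and seedling-quality traits.

Emergence traits come from count series recorded at fixed inspection days on
boxes of sown seeds; seedling quality combines dry masses with the
height:diameter and shoot:root ratios (Dickson's quality index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class EmergenceSeries:
    """New-emergent counts per inspection day for one box of sown seeds."""

    box: int | str
    genotype: str
    days: np.ndarray  # strictly increasing positive integers, days after sowing
    counts: np.ndarray  # new emergents at each inspection
    seeds_sown: int = 25

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.days.size == 0:
            raise ValueError("emergence series must have at least one inspection day")
        if self.days.shape != self.counts.shape:
            raise ValueError("days and counts must have equal length")
        if (np.diff(self.days) <= 0).any():
            raise ValueError("inspection days must be strictly increasing")
        if (self.days <= 0).any() and self.counts[self.days <= 0].any():
            raise ValueError("nonzero emergence recorded at day <= 0")
        if (self.counts < 0).any():
            raise ValueError("emergent counts must be nonnegative")
        if self.seeds_sown <= 0:
            raise ValueError("seeds_sown must be positive")
        if self.counts.sum() > self.seeds_sown:
            raise ValueError(
                f"total emergents {self.counts.sum()} exceed seeds sown {self.seeds_sown}"
            )


def emergence_speed_index(series: EmergenceSeries) -> float:
    """Maguire's emergence speed index: sum of n_i / t_i over inspection days."""
    mask = series.counts > 0
    if not mask.any():
        return 0.0
    days = series.days[mask]
    if (days <= 0).any():
        raise ValueError("emergence at day <= 0 makes the speed index undefined")
    return float(np.sum(series.counts[mask] / days))


def mean_emergence_time(series: EmergenceSeries) -> float:
    """Labouriau's mean time to emergence: count-weighted mean inspection day.

    Returns NaN when nothing emerged (the mean is undefined, not zero).
    """
    total = series.counts.sum()
    if total == 0:
        return float("nan")
    return float(np.sum(series.counts * series.days) / total)


def emergence_percentage(series: EmergenceSeries) -> float:
    """Percentage of sown seeds that emerged over the whole series."""
    return 100.0 * float(series.counts.sum()) / series.seeds_sown


@dataclass
class SeedlingMeasurement:
    """One destructive seedling evaluation.

    Units as recorded in the nursery: height (SH) in cm, basal diameter (DSB)
    in mm, leaf area in cm², masses in g, Fv/Fm dimensionless.
    """

    genotype: str
    replicate: int
    eval_time: int
    height_cm: float
    diameter_mm: float
    leaf_area_cm2: float = np.nan
    shoot_dry_mass_g: float = np.nan
    total_dry_mass_g: float = np.nan
    fv_fm: float = np.nan

    def __post_init__(self) -> None:
        for name in ("height_cm", "diameter_mm", "leaf_area_cm2"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be nonnegative")
        sdm, tdm = self.shoot_dry_mass_g, self.total_dry_mass_g
        if np.isfinite(sdm) and sdm < 0:
            raise ValueError("shoot dry mass must be nonnegative")
        if np.isfinite(tdm) and np.isfinite(sdm) and tdm < sdm:
            raise ValueError("total dry mass cannot be below shoot dry mass")
        if np.isfinite(self.fv_fm) and not 0.0 <= self.fv_fm <= 1.0:
            raise ValueError("Fv/Fm must lie in [0, 1]")


def dickson_quality_index(
    total_dry_mass_g: float,
    shoot_dry_mass_g: float,
    height_cm: float,
    diameter_mm: float,
    diameter_in_cm: bool = False,
) -> float:
    """Dickson quality index: TDM / (SH/DSB + SDM/RDM).

    Root dry mass is derived as RDM = TDM - SDM. By default the
    height:diameter ratio mixes cm (height) and mm (diameter) as recorded;
    set ``diameter_in_cm`` to convert the diameter to cm first. Returns NaN
    (with a logged warning) when RDM <= 0 or the diameter is zero.
    """
    rdm = total_dry_mass_g - shoot_dry_mass_g
    if diameter_mm == 0 or not np.isfinite(diameter_mm):
        log.warning("DQI undefined: zero or missing basal diameter")
        return float("nan")
    if not rdm > 0:
        log.warning("DQI undefined: root dry mass TDM - SDM = %.4g <= 0", rdm)
        return float("nan")
    dsb = diameter_mm / 10.0 if diameter_in_cm else diameter_mm
    return float(total_dry_mass_g / (height_cm / dsb + shoot_dry_mass_g / rdm))


def dqi_from_measurement(m: SeedlingMeasurement, diameter_in_cm: bool = False) -> float:
    return dickson_quality_index(
        m.total_dry_mass_g, m.shoot_dry_mass_g, m.height_cm, m.diameter_mm, diameter_in_cm
    )


def derive_emergence_traits(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-box ESI, MTE and emergence % from a count table.

    ``counts`` has columns box, genotype, day, new_emergents, seeds_sown (the
    layout the emergence simulator and the CSV reader produce). Returns one
    row per box in long phenotype format (traits ESI, MTE, E).
    """
    rows = []
    for (box, genotype), grp in counts.groupby(["box", "genotype"], sort=True):
        grp = grp.sort_values("day")
        series = EmergenceSeries(
            box=box,
            genotype=genotype,
            days=grp["day"].to_numpy(),
            counts=grp["new_emergents"].to_numpy(),
            seeds_sown=int(grp["seeds_sown"].iloc[0]),
        )
        rows.append((box, genotype, "ESI", emergence_speed_index(series)))
        rows.append((box, genotype, "MTE", mean_emergence_time(series)))
        rows.append((box, genotype, "E", emergence_percentage(series)))
    return pd.DataFrame(rows, columns=["box", "genotype", "trait", "value"])
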