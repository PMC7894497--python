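"""Day-0 residue estimation: generic crop-filter model and scaled lookups.

Two first-tier routes to the residue directly after spraying (day 0):

1. **Generic crop-filter model** — the crop canopy intercepts a fraction
   of the spray equal to its soil coverage; the intercepted mass is
   diluted into the standing plant biomass:

       C0,gen [mg/kg] = coverage x rate [kg/ha]
                        / (plant weight [kg] x plants per ha) x 1e6

   Valid only where the edible commodity is essentially the whole plant
   (leafy vegetables, herbs) — not fruiting vegetables, where the fruit
   is shielded and has a low surface-to-weight ratio.

2. **Scaled day-0 lookup** — published per-crop-group medians and 90th
   percentiles of day-0 residues normalized to 1 kg a.s./ha, compiled
   from large collections of supervised residue trials.  Scaling back to
   the actual substance rate is linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import pandas as pd
import yaml

__all__ = [
    "CropParameters",
    "ScaledDay0Table",
    "generic_day0",
    "scaled_day0_lookup",
    "load_scaled_day0_table",
    "read_crop_parameters_csv",
]

log = logging.getLogger(__name__)

Percentile = Literal["median", "p90"]


@dataclass(frozen=True)
class CropParameters:
    """Canopy and biomass parameters for the crop-filter model."""

    crop: str
    soil_coverage: float  # fraction of ground covered by the canopy, 0..1
    plant_weight_kg: float  # fresh weight of one plant, kg
    plants_per_ha: float  # planting density
    whole_plant_commodity: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.soil_coverage <= 1.0:
            raise ValueError("soil_coverage must be in [0, 1]")
        if self.plant_weight_kg <= 0:
            raise ValueError("plant_weight_kg must be > 0")
        if self.plants_per_ha <= 0:
            raise ValueError("plants_per_ha must be > 0")

    @property
    def biomass_kg_per_ha(self) -> float:
        return self.plant_weight_kg * self.plants_per_ha


@dataclass(frozen=True)
class ScaledDay0Entry:
    median_mg_per_kg: float
    p90_mg_per_kg: float
    surrogate_for: str | None = None  # set when the entry is borrowed from another group

    def __post_init__(self) -> None:
        if not self.p90_mg_per_kg >= self.median_mg_per_kg > 0:
            raise ValueError("require p90 >= median > 0")


@dataclass(frozen=True)
class ScaledDay0Table:
    """Per-crop-group scaled day-0 residues (median and 90th percentile)."""

    entries: dict[str, ScaledDay0Entry]

    def lookup(self, crop_group: str) -> ScaledDay0Entry:
        key = crop_group.strip().lower()
        if key not in self.entries:
            raise KeyError(
                f"unknown crop group {crop_group!r}; available: {sorted(self.entries)}"
            )
        entry = self.entries[key]
        if entry.surrogate_for is not None:
            log.warning(
                "crop group %r has no published day-0 residues; using %r as surrogate",
                crop_group,
                entry.surrogate_for,
            )
        return entry

    @property
    def crop_groups(self) -> list[str]:
        return sorted(self.entries)


def generic_day0(crop_params: CropParameters, application_rate_kg_per_ha: float) -> float:
    """Day-0 residue from the crop-filter model, mg/kg fresh weight.

    Linear in application rate and coverage, inversely linear in total
    standing biomass.  Raises if the crop's edible commodity is not the
    whole plant (the filter assumption breaks for fruiting vegetables).
    """
    if application_rate_kg_per_ha <= 0:
        raise ValueError("application rate must be > 0")
    if not crop_params.whole_plant_commodity:
        raise ValueError(
            f"{crop_params.crop}: crop-filter model applies only to whole-plant "
            "commodities (not fruiting vegetables)"
        )
    return (
        crop_params.soil_coverage
        * application_rate_kg_per_ha
        / crop_params.biomass_kg_per_ha
        * 1e6
    )


def scaled_day0_lookup(
    crop_group: str,
    percentile: Percentile,
    application_rate_kg_per_ha: float,
    table: ScaledDay0Table | None = None,
) -> float:
    """Scaled day-0 residue for a crop group, rescaled to the actual rate.

    ``percentile`` selects the median or the 90th percentile of the
    published distribution (both at 1 kg/ha); the result scales linearly
    with the substance application rate.
    """
    if table is None:
        table = load_scaled_day0_table()
    if application_rate_kg_per_ha < 0:
        raise ValueError("application rate must be >= 0")
    entry = table.lookup(crop_group)
    if percentile == "median":
        base = entry.median_mg_per_kg
    elif percentile == "p90":
        base = entry.p90_mg_per_kg
    else:
        raise ValueError("percentile must be 'median' or 'p90'")
    return base * application_rate_kg_per_ha


def load_scaled_day0_table(path=None) -> ScaledDay0Table:
    """Load the scaled day-0 table from YAML (packaged default config).

    Format: ``crop_group: {median: <mg/kg>, p90: <mg/kg>
    [, surrogate_for: <group>]}``, values at 1 kg/ha.
    """
    if path is None:
        text = resources.files("coformkin.data").joinpath("scaled_day0_defaults.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    entries = {
        str(k).lower(): ScaledDay0Entry(
            median_mg_per_kg=float(v["median"]),
            p90_mg_per_kg=float(v["p90"]),
            surrogate_for=v.get("surrogate_for"),
        )
        for k, v in raw.items()
    }
    return ScaledDay0Table(entries=entries)


def read_crop_parameters_csv(path) -> dict[str, CropParameters]:
    """Read the crop parameter CSV dialect into {crop: CropParameters}.

    Columns: ``crop, soil_coverage, plant_weight_kg, plants_per_ha,
    whole_plant_commodity``.
    """
    df = pd.read_csv(path)
    required = ["crop", "soil_coverage", "plant_weight_kg", "plants_per_ha", "whole_plant_commodity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"crop parameter CSV {path}: missing columns {missing}")
    out = {}
    for r in df.itertuples():
        out[str(r.crop)] = CropParameters(
            crop=str(r.crop),
            soil_coverage=float(r.soil_coverage),
            plant_weight_kg=float(r.plant_weight_kg),
            plants_per_ha=float(r.plants_per_ha),
            whole_plant_commodity=bool(r.whole_plant_commodity),
        )
    return out
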