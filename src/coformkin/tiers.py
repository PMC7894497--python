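"""Tiered prediction of co-formulant residues at a pre-harvest interval.

A first-tier screening estimate combines a day-0 residue estimate with a
default SFO decline:

    C(PHI) = C0_estimate x exp(-ln 2 x PHI / DT50)

Two standard tiers are provided:

* **median** — median scaled day-0 residue with the median foliar
  dissipation half-life of 5 days from public data reviews;
* **worst_case** — 90th-percentile day-0 residue with the 80th
  percentile half-life of 12 days.

The worst-case tier dominates the median tier at every pre-harvest
interval by construction (both the day-0 percentile and the DT50 are
ordered).  Predictions are linear in the substance application rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .initial_residues import (
    CropParameters,
    ScaledDay0Table,
    generic_day0,
    load_scaled_day0_table,
    scaled_day0_lookup,
)

__all__ = [
    "TierConfig",
    "ExposurePrediction",
    "MEDIAN_TIER",
    "WORST_CASE_TIER",
    "predict_residue",
    "decline_curve",
]

TierName = Literal["median", "worst_case"]


@dataclass(frozen=True)
class TierConfig:
    """One screening tier: day-0 percentile paired with a default DT50."""

    tier: TierName
    day0_percentile: Literal["median", "p90"]
    dt50_days: float
    day0_source: Literal["scaled_lookup", "generic_eq", "user"] = "scaled_lookup"

    def __post_init__(self) -> None:
        if self.dt50_days <= 0:
            raise ValueError("dt50_days must be > 0")


#: Median tier: median scaled day-0 residue, median DT50 of 5 days.
MEDIAN_TIER = TierConfig(tier="median", day0_percentile="median", dt50_days=5.0)
#: Worst-case tier: 90th-percentile day-0 residue, 80th-percentile DT50 of 12 days.
WORST_CASE_TIER = TierConfig(tier="worst_case", day0_percentile="p90", dt50_days=12.0)

_TIERS: dict[str, TierConfig] = {"median": MEDIAN_TIER, "worst_case": WORST_CASE_TIER}


def resolve_tier(tier: TierConfig | str) -> TierConfig:
    if isinstance(tier, TierConfig):
        return tier
    key = tier.replace("-", "_").lower()
    if key not in _TIERS:
        raise ValueError(f"unknown tier {tier!r}; available: {sorted(_TIERS)}")
    return _TIERS[key]


@dataclass(frozen=True)
class ExposurePrediction:
    """Predicted residue at one pre-harvest interval."""

    crop: str
    substance_rate_kg_per_ha: float
    phi_days: float
    residue_mg_per_kg: float
    tier: str


def _day0_estimate(
    crop_group: str,
    rate_kg_per_ha: float,
    tier: TierConfig,
    table: ScaledDay0Table | None,
    crop_params: CropParameters | None,
) -> float:
    if tier.day0_source == "generic_eq":
        if crop_params is None:
            raise ValueError("generic day-0 source requires CropParameters")
        return generic_day0(crop_params, rate_kg_per_ha)
    try:
        return scaled_day0_lookup(crop_group, tier.day0_percentile, rate_kg_per_ha, table=table)
    except KeyError:
        if crop_params is not None:
            return generic_day0(crop_params, rate_kg_per_ha)
        raise


def predict_residue(
    crop_group: str,
    rate_kg_per_ha: float,
    phi_days: float,
    tier: TierConfig | str = "median",
    table: ScaledDay0Table | None = None,
    crop_params: CropParameters | None = None,
) -> ExposurePrediction:
    """Screening-level residue at harvest, mg/kg fresh weight.

    The day-0 estimate (scaled lookup at the tier's percentile, or the
    crop-filter model when no lookup entry exists and ``crop_params``
    are supplied) is declined with the tier's default SFO half-life over
    the pre-harvest interval ``phi_days``.
    """
    tier = resolve_tier(tier)
    if phi_days < 0:
        raise ValueError("pre-harvest interval must be >= 0 days")
    if table is None and tier.day0_source == "scaled_lookup":
        table = load_scaled_day0_table()
    c0 = _day0_estimate(crop_group, rate_kg_per_ha, tier, table, crop_params)
    residue = c0 * np.exp(-np.log(2.0) * phi_days / tier.dt50_days)
    return ExposurePrediction(
        crop=crop_group,
        substance_rate_kg_per_ha=rate_kg_per_ha,
        phi_days=phi_days,
        residue_mg_per_kg=float(residue),
        tier=tier.tier,
    )


def decline_curve(
    tier: TierConfig | str,
    crop_group: str,
    rate_kg_per_ha: float,
    t_grid: Iterable[float],
    table: ScaledDay0Table | None = None,
    crop_params: CropParameters | None = None,
) -> list[tuple[float, float]]:
    """Tier decline curve: (t, residue mg/kg) at each grid time.

    Pointwise equal to :func:`predict_residue`; the grid must be
    non-negative and increasing.
    """
    t = np.asarray(list(t_grid), dtype=float)
    if len(t) and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise ValueError("t_grid must be non-negative and strictly increasing")
    tier = resolve_tier(tier)
    if table is None and tier.day0_source == "scaled_lookup":
        table = load_scaled_day0_table()
    return [
        (
            float(ti),
            predict_residue(
                crop_group, rate_kg_per_ha, float(ti), tier, table=table, crop_params=crop_params
            ).residue_mg_per_kg,
        )
        for ti in t
    ]
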