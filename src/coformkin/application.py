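"""Per-substance application rates and day-0 residue normalization.

A PPP (plant protection product) is applied at some rate in kg
formulation per hectare; each constituent substance has a content in g
per kg formulation, so its own application rate is the product of the
two, in g substance per hectare.  Day-0 residues measured at different
substance rates become comparable after linear rescaling to a common
rate of 1 kg substance per hectare (C0,norm).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SubstanceApplication",
    "NormalizedDay0",
    "substance_application_rate",
    "normalize_day0",
    "round_sig",
    "read_ppp_csv",
]

log = logging.getLogger(__name__)


def substance_application_rate(content_g_per_kg: float, ppp_rate_kg_per_ha: float) -> float:
    """Substance application rate in g/ha from PPP content and PPP rate.

    rate [g/ha] = content [g substance / kg PPP] x PPP rate [kg PPP / ha].
    No rounding is applied.
    """
    if content_g_per_kg < 0 or ppp_rate_kg_per_ha < 0:
        raise ValueError("content and PPP rate must be >= 0")
    return content_g_per_kg * ppp_rate_kg_per_ha


@dataclass(frozen=True)
class SubstanceApplication:
    """One substance within one PPP use event.

    ``rate_g_per_ha`` is always derived as content x PPP rate unless an
    explicit ``rate_override_g_per_ha`` is supplied, in which case the
    override wins and the discrepancy is logged.  The override exists
    because published application-rate tables are sometimes measured in
    the tank mix rather than computed from the label content.
    """

    substance: str
    content_g_per_kg: float
    ppp_rate_kg_per_ha: float
    water_l_per_ha: float | None = None
    rate_override_g_per_ha: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.content_g_per_kg <= 1000:
            raise ValueError("content must be in [0, 1000] g/kg")
        if self.ppp_rate_kg_per_ha <= 0:
            raise ValueError("PPP rate must be > 0")
        derived = substance_application_rate(self.content_g_per_kg, self.ppp_rate_kg_per_ha)
        if self.rate_override_g_per_ha is not None and not math.isclose(
            self.rate_override_g_per_ha, derived, rel_tol=5e-3
        ):
            log.warning(
                "%s: rate override %.4g g/ha differs from derived %.4g g/ha "
                "(content %.4g g/kg x PPP rate %.4g kg/ha)",
                self.substance,
                self.rate_override_g_per_ha,
                derived,
                self.content_g_per_kg,
                self.ppp_rate_kg_per_ha,
            )

    @property
    def rate_g_per_ha(self) -> float:
        if self.rate_override_g_per_ha is not None:
            return self.rate_override_g_per_ha
        return substance_application_rate(self.content_g_per_kg, self.ppp_rate_kg_per_ha)


def normalize_day0(c0_mg_per_kg: float, rate_g_per_ha: float) -> float:
    """Scale a day-0 residue to an application rate of 1 kg substance/ha.

    c0_norm = c0 / (rate / 1000), i.e. mg/kg per kg substance applied
    per ha.  Exact (unrounded); round with :func:`round_sig` only at the
    reporting layer.
    """
    if rate_g_per_ha <= 0:
        raise ValueError("application rate must be > 0")
    if c0_mg_per_kg < 0:
        raise ValueError("day-0 residue must be >= 0")
    return c0_mg_per_kg / (rate_g_per_ha / 1000.0)


@dataclass(frozen=True)
class NormalizedDay0:
    """Measured day-0 residue together with its rate-normalized value."""

    c0_mg_per_kg: float
    c0_norm: float

    @classmethod
    def from_application(cls, c0_mg_per_kg: float, application: SubstanceApplication) -> "NormalizedDay0":
        return cls(c0_mg_per_kg, normalize_day0(c0_mg_per_kg, application.rate_g_per_ha))

    def reported(self, sig: int = 2) -> float:
        """Reporting-layer rounding (2 significant figures by default)."""
        return round_sig(self.c0_norm, sig)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


PPP_COLUMNS = [
    "ppp",
    "formulation_type",
    "substance",
    "function",
    "content_g_per_kg",
    "ppp_rate_kg_per_ha",
    "water_l_per_ha",
]


def read_ppp_csv(path) -> dict[tuple[str, str], SubstanceApplication]:
    """Read a PPP composition CSV into {(ppp, substance): SubstanceApplication}.

    Columns: ``ppp, formulation_type, substance, function,
    content_g_per_kg, ppp_rate_kg_per_ha, water_l_per_ha`` and the
    optional ``rate_override_g_per_ha``.
    """
    df = pd.read_csv(path)
    missing = [c for c in PPP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PPP CSV {path}: missing columns {missing}")
    has_override = "rate_override_g_per_ha" in df.columns
    out: dict[tuple[str, str], SubstanceApplication] = {}
    for r in df.itertuples():
        override = None
        if has_override and not pd.isna(r.rate_override_g_per_ha):
            override = float(r.rate_override_g_per_ha)
        out[(str(r.ppp), str(r.substance))] = SubstanceApplication(
            substance=str(r.substance),
            content_g_per_kg=float(r.content_g_per_kg),
            ppp_rate_kg_per_ha=float(r.ppp_rate_kg_per_ha),
            water_l_per_ha=float(r.water_l_per_ha) if not pd.isna(r.water_l_per_ha) else None,
            rate_override_g_per_ha=override,
        )
    return out
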