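"""Packaged reference tables and synthetic fixtures.

Two kinds of files ship with the package:

* transcribed published tables — PPP compositions with per-substance
  application rates, and measured day-0 residues with their printed
  rate-normalized values (``consistent`` flags rows where the printed
  normalized value is reproduced from the printed inputs after
  2-significant-figure rounding; the remainder were evidently computed
  from unrounded raw measurements);
* synthetic stand-ins, labelled ``*_synthetic`` — crop canopy/biomass
  parameters and conservative rate-normalized decline series
  reconstructed from published summary bounds, used for regression
  checks where the underlying raw data are not public.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .application import SubstanceApplication, read_ppp_csv
from .initial_residues import CropParameters, read_crop_parameters_csv

__all__ = [
    "load_ppp_compositions",
    "load_day0_residues",
    "load_crop_parameters_synthetic",
    "load_cnorm_timeseries_synthetic",
]


def _data_path(name: str):
    return resources.files("coformkin.data").joinpath(name)


def load_ppp_compositions() -> dict[tuple[str, str], SubstanceApplication]:
    """PPP composition table: {(ppp, substance): SubstanceApplication}."""
    with resources.as_file(_data_path("ppp_compositions.csv")) as p:
        return read_ppp_csv(p)


def application_rates() -> dict[tuple[str, str], SubstanceApplication]:
    """Application data keyed by (trial, substance).

    The same PPP was used in both the vegetable and the apple trial at
    different rates (and, for one product, with a different batch), so
    substances are resolved per trial.
    """
    with resources.as_file(_data_path("ppp_compositions.csv")) as p:
        df = pd.read_csv(p)
        apps = read_ppp_csv(p)
    out: dict[tuple[str, str], SubstanceApplication] = {}
    for r in df.itertuples():
        out[(str(r.trial), str(r.substance))] = apps[(str(r.ppp), str(r.substance))]
    return out


def load_day0_residues() -> pd.DataFrame:
    """Measured day-0 residues and printed normalized values (mg/kg)."""
    with resources.as_file(_data_path("day0_residues.csv")) as p:
        return pd.read_csv(p)


def load_crop_parameters_synthetic() -> dict[str, CropParameters]:
    """Synthetic crop-filter parameters (plausible stand-in values)."""
    with resources.as_file(_data_path("crop_parameters_synthetic.csv")) as p:
        return read_crop_parameters_csv(p)


def load_cnorm_timeseries_synthetic() -> pd.DataFrame:
    """Synthetic conservative rate-normalized decline series (mg/kg at 1 kg/ha).

    Reconstructed from published day-0 values and upper-bound remaining
    fractions at days 3 and 14; every value is at or above what was
    measured, making the table suitable for worst-case-dominance
    regression checks but not for kinetic fitting.
    """
    with resources.as_file(_data_path("vegetable_cnorm_timeseries_synthetic.csv")) as p:
        return pd.read_csv(p)
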