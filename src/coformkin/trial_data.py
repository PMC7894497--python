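"""Residue-trial data model, QC statistics and LOQ censoring.

Supervised residue trials sample a treated crop repeatedly after a plant
protection product (PPP) application: typically a pre-treatment control
(day -1), a sample ~1 h after treatment (day 0, stored here as t = 0
exactly) and several later days.  Each sample is analysed in one or more
analytical replicates.  Concentrations are mg/kg fresh weight; the limit
of quantification (LOQ) is the lowest calibration level of the analytical
method.

Before any kinetic fitting, measurements are censored by the rule used to
display decline data: a time point is retained only if *every* replicate
is above the LOQ, and pre-treatment (day < 0) samples are always dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

__all__ = [
    "Measurement",
    "ResidueTimeSeries",
    "QcRecord",
    "aggregate_replicates",
    "censor_loq",
    "recovery_pct",
    "storage_stability_pct",
    "read_trial_csv",
    "write_trial_csv",
    "read_qc_csv",
]

#: Fraction of the day-0 mean above which a pre-treatment (control)
#: concentration triggers a contamination warning.
CONTROL_WARN_FRACTION = 0.10


@dataclass(frozen=True)
class Measurement:
    """One sampling occasion: replicate concentrations at one day.

    Parameters
    ----------
    day : float
        Days after treatment; may be negative for pre-treatment controls.
    replicate_values : tuple of float
        Concentration of each analytical replicate, mg/kg fresh weight.
    loq : float
        Limit of quantification, mg/kg.  Must be positive.
    """

    day: float
    replicate_values: tuple[float, ...]
    loq: float

    def __post_init__(self) -> None:
        if len(self.replicate_values) == 0:
            raise ValueError("replicate_values must be non-empty")
        if any(v < 0 for v in self.replicate_values):
            raise ValueError("replicate concentrations must be >= 0")
        if self.loq <= 0:
            raise ValueError("loq must be > 0")
        object.__setattr__(self, "replicate_values", tuple(float(v) for v in self.replicate_values))

    @property
    def all_above_loq(self) -> bool:
        """True if every replicate strictly exceeds the LOQ."""
        return all(v > self.loq for v in self.replicate_values)


@dataclass(frozen=True)
class ResidueTimeSeries:
    """Residue measurements for one crop x substance combination.

    ``measurements`` are kept sorted by day; at most one Measurement per
    day.  ``application`` optionally references the
    :class:`~coformkin.application.SubstanceApplication` behind the trial
    so day-0 residues can be normalized to a unit application rate.
    """

    crop: str
    substance: str
    measurements: tuple[Measurement, ...]
    application: object | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ms = tuple(sorted(self.measurements, key=lambda m: m.day))
        days = [m.day for m in ms]
        if len(set(days)) != len(days):
            raise ValueError("at most one Measurement per day")
        object.__setattr__(self, "measurements", ms)
        self._check_controls()

    def _check_controls(self) -> None:
        day0 = [m for m in self.measurements if m.day == 0]
        if not day0:
            return
        mean0, _ = aggregate_replicates(day0[0])
        if mean0 <= 0:
            return
        for m in self.measurements:
            if m.day < 0:
                c_mean = sum(m.replicate_values) / len(m.replicate_values)
                if c_mean > CONTROL_WARN_FRACTION * mean0:
                    warnings.warn(
                        f"{self.crop}/{self.substance}: pre-treatment control at day "
                        f"{m.day} ({c_mean:.3g} mg/kg) exceeds {CONTROL_WARN_FRACTION:.0%} "
                        f"of the day-0 mean ({mean0:.3g} mg/kg)",
                        stacklevel=3,
                    )

    @property
    def days(self) -> tuple[float, ...]:
        return tuple(m.day for m in self.measurements)

    def replicate_means(self) -> tuple[tuple[float, float], ...]:
        """(day, mean concentration) pairs over all measurements."""
        return tuple((m.day, aggregate_replicates(m)[0]) for m in self.measurements)


@dataclass(frozen=True)
class QcRecord:
    """Method-performance record for one analyte x matrix combination."""

    analyte: str
    matrix: str
    recovery_pct: float = 0.0
    precision_pct: float = 0.0
    storage_stability_pct: float = 0.0

    def __post_init__(self) -> None:
        for name in ("recovery_pct", "precision_pct", "storage_stability_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def aggregate_replicates(m: Measurement) -> tuple[float, float]:
    """Mean concentration and replicate precision of one measurement.

    Precision is expressed as the maximum relative deviation of any
    replicate from the mean, in percent.  A single replicate has
    precision 0 by definition.

    Returns
    -------
    (mean, rel_dev_pct) : tuple of float
        mean in mg/kg; rel_dev_pct in percent.  If all replicates are
        zero the relative deviation is undefined; 0 is returned with a
        warning.
    """
    vals = m.replicate_values
    mean = sum(vals) / len(vals)
    if mean == 0.0:
        if len(vals) > 1:
            warnings.warn("all replicates zero: relative deviation undefined, returning 0")
        return 0.0, 0.0
    rel_dev = max(abs(v - mean) / mean for v in vals) * 100.0
    return mean, rel_dev


def censor_loq(series: ResidueTimeSeries) -> ResidueTimeSeries:
    """Censor a series for fitting: keep only fully quantifiable points.

    A measurement is retained only if every replicate exceeds the LOQ.
    Pre-treatment samples (day < 0) are always dropped.  Order is
    preserved and the operation is idempotent.  An empty result is legal
    and flagged ``"no quantifiable decline data"``.
    """
    kept = tuple(m for m in series.measurements if m.day >= 0 and m.all_above_loq)
    flags = series.flags
    if not kept and "no quantifiable decline data" not in flags:
        flags = flags + ("no quantifiable decline data",)
    return replace(series, measurements=kept, flags=flags)


def recovery_pct(measured: float, fortified: float) -> float:
    """Analytical recovery: measured concentration as % of the fortified level."""
    if fortified <= 0:
        raise ValueError("fortified concentration must be > 0")
    return 100.0 * measured / fortified


def storage_stability_pct(fresh: float, stored: float) -> float:
    """Storage stability: stored-extract concentration as % of the fresh one."""
    if fresh <= 0:
        raise ValueError("fresh concentration must be > 0")
    return 100.0 * stored / fresh


# ---------------------------------------------------------------------------
# CSV dialects

TRIAL_COLUMNS = ["crop", "substance", "day", "replicate", "concentration_mg_kg", "loq_mg_kg"]


def read_trial_csv(path) -> list[ResidueTimeSeries]:
    """Read a long-format trial CSV into one series per crop x substance.

    Expected columns: ``crop, substance, day, replicate,
    concentration_mg_kg, loq_mg_kg`` (UTF-8, '.' decimal separator,
    header required).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV {path}: missing columns {missing}")
    out: list[ResidueTimeSeries] = []
    for (crop, substance), grp in df.groupby(["crop", "substance"], sort=True):
        ms = []
        for day, day_grp in grp.groupby("day", sort=True):
            vals = tuple(day_grp.sort_values("replicate")["concentration_mg_kg"])
            loq = float(day_grp["loq_mg_kg"].iloc[0])
            ms.append(Measurement(day=float(day), replicate_values=vals, loq=loq))
        out.append(ResidueTimeSeries(crop=str(crop), substance=str(substance), measurements=tuple(ms)))
    return out


def write_trial_csv(series_list: Sequence[ResidueTimeSeries], path) -> None:
    """Write series back to the long-format trial CSV dialect."""
    rows = []
    for s in series_list:
        for m in s.measurements:
            for i, v in enumerate(m.replicate_values, start=1):
                rows.append(
                    {
                        "crop": s.crop,
                        "substance": s.substance,
                        "day": m.day,
                        "replicate": i,
                        "concentration_mg_kg": v,
                        "loq_mg_kg": m.loq,
                    }
                )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_qc_csv(path) -> list[QcRecord]:
    """Read the QC CSV dialect and compute recoveries.

    Columns: ``analyte, matrix, level_mg_kg, measured_mg_kg,
    fortified_mg_kg``.  One QcRecord per row with recovery computed from
    measured/fortified.
    """
    df = pd.read_csv(path)
    required = ["analyte", "matrix", "measured_mg_kg", "fortified_mg_kg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"QC CSV {path}: missing columns {missing}")
    return [
        QcRecord(
            analyte=str(r.analyte),
            matrix=str(r.matrix),
            recovery_pct=recovery_pct(r.measured_mg_kg, r.fortified_mg_kg),
        )
        for r in df.itertuples()
    ]
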