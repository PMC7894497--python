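"""Seeded generator of synthetic residue-trial data.

Emulates the statistical structure of a supervised residue trial: a
true decline curve (SFO or bi-phasic) evaluated on the trial sampling
schedule (default -1, 0, 1, 2, 3, 7, 14, 21 days), optional rain-pulse
wash-off events that instantaneously remove a fraction of the surface
residue, and multiplicative lognormal measurement noise per analytical
replicate.  The noise is mean-one ("mean-corrected") so that the
expected generated concentration equals the truth curve times the
cumulative wash-off factor; its coefficient of variation defaults to
15%, the middle of the 1-25% replicate-precision range typical of
LC-MS/MS residue methods.

Everything is deterministic for a fixed seed, which makes the generator
usable both as a test fixture factory and as the engine of Monte-Carlo
parameter-recovery studies (:func:`recovery_study`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .kinetics import (
    BiphasicParams,
    KineticFit,
    SfoParams,
    biphasic_predict,
    dt50_from_k,
    overall_dt50,
    sfo_predict,
)
from .trial_data import Measurement, ResidueTimeSeries

__all__ = ["TrialScenario", "generate_trial", "recovery_study", "RecoveryStudyResult"]

#: Default sampling schedule: pre-treatment control, ~1 h after
#: treatment (t = 0), then 1, 2, 3, 7, 14 and 21 days after treatment.
DEFAULT_SAMPLING_DAYS = (-1.0, 0.0, 1.0, 2.0, 3.0, 7.0, 14.0, 21.0)


@dataclass(frozen=True)
class TrialScenario:
    """Ground truth and design of one synthetic residue trial."""

    truth_params: SfoParams | BiphasicParams
    sampling_days: tuple[float, ...] = DEFAULT_SAMPLING_DAYS
    n_replicates: int = 2
    cv_pct: float = 15.0
    loq: float = 0.001
    washoff_events: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    seed: int = 0
    crop: str = "synthetic-crop"
    substance: str = "synthetic-substance"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.cv_pct < 0:
            raise ValueError("cv_pct must be >= 0")
        if self.loq <= 0:
            raise ValueError("loq must be > 0")
        for day, frac in self.washoff_events:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("wash-off fraction_removed must be in [0, 1]")

    @property
    def truth_model(self) -> str:
        return "SFO" if isinstance(self.truth_params, SfoParams) else "biphasic"

    def true_curve(self, t):
        if isinstance(self.truth_params, SfoParams):
            return sfo_predict(self.truth_params, t)
        return biphasic_predict(self.truth_params, t)

    def true_dt50(self) -> float:
        if isinstance(self.truth_params, SfoParams):
            return dt50_from_k(self.truth_params.k)
        return overall_dt50(self.truth_params)

    def washoff_factor(self, t: float) -> float:
        """Cumulative fraction remaining after all wash-off events up to t."""
        f = 1.0
        for day, frac in self.washoff_events:
            if day <= t:
                f *= 1.0 - frac
        return f


def _lognormal_multipliers(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one lognormal noise factors with the given CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv**2)
    return np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size))


def generate_trial(s: TrialScenario) -> ResidueTimeSeries:
    """Generate one synthetic residue time series from a scenario.

    The truth curve is evaluated at each non-negative sampling day,
    multiplied by the cumulative wash-off factor of all past events, and
    perturbed per replicate with mean-one multiplicative lognormal noise
    at the scenario CV.  Pre-treatment days yield zero concentrations.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(s.seed)
    measurements = []
    for day in s.sampling_days:
        if day < 0:
            vals = (0.0,) * s.n_replicates
        else:
            truth = float(s.true_curve(day)) * s.washoff_factor(day)
            vals = tuple(truth * _lognormal_multipliers(rng, s.cv_pct / 100.0, s.n_replicates))
        measurements.append(Measurement(day=day, replicate_values=vals, loq=s.loq))
    return ResidueTimeSeries(
        crop=s.crop, substance=s.substance, measurements=tuple(measurements)
    )


@dataclass(frozen=True)
class RecoveryStudyResult:
    """Summary of a Monte-Carlo DT50 parameter-recovery study."""

    dt50_true_days: float
    n_sims: int
    n_failed: int
    dt50_estimates: tuple[float, ...]
    median_bias_pct: float  # median of (est - true)/true, %
    median_abs_rel_error_pct: float  # median of |est - true|/true, %
    relative_rmse_pct: float  # sqrt(mean((est - true)/true)^2), %


def recovery_study(
    s: TrialScenario,
    n_sims: int,
    estimator: Callable[[ResidueTimeSeries], KineticFit],
) -> RecoveryStudyResult:
    """Repeatedly simulate a scenario and summarize DT50 recovery.

    Per-simulation seeds are derived reproducibly from the scenario
    seed.  Estimator failures (exceptions or non-finite DT50) are
    counted, not raised.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    seed_rng = np.random.default_rng(s.seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=n_sims)
    true_dt50 = s.true_dt50()

    estimates: list[float] = []
    n_failed = 0
    for seed in seeds:
        scenario = TrialScenario(
            truth_params=s.truth_params,
            sampling_days=s.sampling_days,
            n_replicates=s.n_replicates,
            cv_pct=s.cv_pct,
            loq=s.loq,
            washoff_events=s.washoff_events,
            seed=int(seed),
            crop=s.crop,
            substance=s.substance,
        )
        try:
            fit = estimator(generate_trial(scenario))
            if not np.isfinite(fit.dt50_days):
                raise ValueError("non-finite DT50")
        except Exception:
            n_failed += 1
            continue
        estimates.append(fit.dt50_days)

    if estimates:
        rel = (np.array(estimates) - true_dt50) / true_dt50
        median_bias = float(np.median(rel) * 100.0)
        median_abs = float(np.median(np.abs(rel)) * 100.0)
        rmse = float(np.sqrt(np.mean(rel**2)) * 100.0)
    else:
        median_bias = median_abs = rmse = float("nan")
    return RecoveryStudyResult(
        dt50_true_days=true_dt50,
        n_sims=n_sims,
        n_failed=n_failed,
        dt50_estimates=tuple(estimates),
        median_bias_pct=median_bias,
        median_abs_rel_error_pct=median_abs,
        relative_rmse_pct=rmse,
    )
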