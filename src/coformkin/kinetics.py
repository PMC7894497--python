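"""Decline-kinetics models: single first order (SFO) and bi-phasic (DFOP).

Residue dissipation from treated crops is routinely summarized by an
exponential decline

    C(t) = C0 * exp(-k t),        DT50 = ln 2 / k

fitted by nonlinear least squares in linear concentration space.  Where
a fast surface-loss phase (e.g. rain wash-off) is followed by a slower
one, the double-first-order-in-parallel (DFOP) model is the standard
bi-phasic extension:

    C(t) = C0 * [ g * exp(-k1 t) + (1 - g) * exp(-k2 t) ],  k1 >= k2

with mixing fraction g in [0, 1].  Its "overall DT50" is the time at
which the fitted curve reaches half of the fitted C0, found numerically;
in the g -> 1 limit it coincides with ln 2 / k1.

The fitters are scikit-learn estimators (``fit(X, y)`` on days vs
concentrations); :func:`fit_sfo` and :func:`fit_biphasic` wrap them for
censored :class:`~coformkin.trial_data.ResidueTimeSeries` inputs and
return a :class:`KineticFit` record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq, least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .trial_data import ResidueTimeSeries, censor_loq

__all__ = [
    "SfoParams",
    "BiphasicParams",
    "KineticFit",
    "sfo_predict",
    "biphasic_predict",
    "dt50_from_k",
    "overall_dt50",
    "SFODeclineModel",
    "BiphasicDeclineModel",
    "fit_sfo",
    "fit_biphasic",
]

#: Convergence tolerance on the change of the residual sum of squares.
RSS_TOL = 1e-10


@dataclass(frozen=True)
class SfoParams:
    """Single-first-order parameters: initial residue and rate constant."""

    c0: float  # mg/kg
    k: float  # 1/day

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError("c0 must be > 0")
        if self.k < 0:
            raise ValueError("k must be >= 0")


@dataclass(frozen=True)
class BiphasicParams:
    """DFOP parameters: fast-phase fraction g and two rate constants."""

    c0: float  # mg/kg
    g: float  # fast-phase weight, 0..1
    k1: float  # fast rate, 1/day
    k2: float  # slow rate, 1/day

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError("c0 must be > 0")
        if not 0.0 <= self.g <= 1.0:
            raise ValueError("g must be in [0, 1]")
        if not self.k1 >= self.k2 >= 0.0:
            raise ValueError("require k1 >= k2 >= 0")


@dataclass(frozen=True)
class KineticFit:
    """Result of a kinetic fit: model, parameters, half-life, diagnostics."""

    model: Literal["SFO", "biphasic"]
    params: SfoParams | BiphasicParams
    dt50_days: float
    rss: float
    n_points: int
    converged: bool
    degenerate: bool = False  # biphasic only: g stuck at 0 or 1


def sfo_predict(p: SfoParams, t):
    """SFO concentration at time(s) t (days): c0 * exp(-k t)."""
    return p.c0 * np.exp(-p.k * np.asarray(t, dtype=float))


def biphasic_predict(p: BiphasicParams, t):
    """DFOP concentration at time(s) t (days)."""
    t = np.asarray(t, dtype=float)
    return p.c0 * (p.g * np.exp(-p.k1 * t) + (1.0 - p.g) * np.exp(-p.k2 * t))


def dt50_from_k(k: float) -> float:
    """Dissipation half-life (days) of a first-order decline: ln 2 / k."""
    if k <= 0:
        raise ValueError("k must be > 0 (no decline)")
    return np.log(2.0) / k


def overall_dt50(p: BiphasicParams, xtol: float = 1e-9) -> float:
    """Time (days) at which a DFOP curve reaches half of its initial value.

    Solved by bracketing and Brent root-finding on
    g*exp(-k1 t) + (1-g)*exp(-k2 t) = 1/2; accurate to well below
    1e-6 days.  For 0 < g < 1 the root lies in [ln2/k1, ln2/k2].  Raises
    if no rate is positive or if the slow-phase plateau (k2 = 0 with
    1 - g >= 1/2) never reaches 50%.
    """
    if p.k1 <= 0 and p.k2 <= 0:
        raise ValueError("no positive rate: curve does not decline")
    if p.g >= 1.0:
        return dt50_from_k(p.k1)
    if p.g <= 0.0:
        return dt50_from_k(p.k2)
    if p.k2 <= 0 and (1.0 - p.g) >= 0.5:
        raise ValueError("slow phase never degrades and holds >= 50% of c0")

    def frac_remaining(t: float) -> float:
        return p.g * np.exp(-p.k1 * t) + (1.0 - p.g) * np.exp(-p.k2 * t) - 0.5

    lo = 0.0
    if p.k2 > 0:
        hi = np.log(2.0) / p.k2
    else:
        hi = np.log(2.0) / p.k1
        while frac_remaining(hi) > 0:
            hi *= 2.0
    return float(brentq(frac_remaining, lo, hi, xtol=xtol))


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("X must be shape (n,) or (n, 1): days after treatment")
        X = X[:, 0]
    y = np.asarray(y, dtype=float)
    if X.shape != y.shape:
        raise ValueError("X and y must have the same length")
    if np.any(X < 0):
        raise ValueError("days must be >= 0 (censor pre-treatment samples first)")
    if np.any(y <= 0):
        raise ValueError("concentrations must be > 0 (apply LOQ censoring first)")
    order = np.argsort(X)
    return X[order], y[order]


def _loglinear_init(t, y):
    """(c0, k) from ordinary least squares on log concentration vs time."""
    slope, intercept = np.polyfit(t, np.log(y), 1)
    return float(np.exp(intercept)), float(max(-slope, 1e-8))


class SFODeclineModel(RegressorMixin, BaseEstimator):
    """Single-first-order decline fitted by nonlinear least squares.

    Parameters
    ----------
    log_space : bool, default False
        Fit residuals in log concentration space instead of linear
        space.  Linear space weights the (large) early residues most;
        log space balances the tail, which matters for ill-conditioned
        late time points.

    Attributes
    ----------
    c0_ : float
        Fitted initial concentration, mg/kg.
    k_ : float
        Fitted first-order rate constant, 1/day.
    dt50_ : float
        Dissipation half-life ln 2 / k_, days (inf if k_ == 0).
    rss_ : float
        Residual sum of squares in linear concentration space.
    n_points_ : int
        Number of fitted (day, concentration) points.
    converged_ : bool
        False if the optimizer failed; parameters then fall back to the
        log-linear regression estimate.
    """

    def __init__(self, log_space: bool = False):
        self.log_space = log_space

    _n_free_params = 2

    def fit(self, X, y):
        t, c = _validate_xy(X, y)
        if len(t) < self._n_free_params + 1:
            raise ValueError(
                f"need >= {self._n_free_params + 1} points for an SFO fit, got {len(t)}"
            )
        c0_init, k_init = _loglinear_init(t, c)

        def residuals(theta):
            pred = theta[0] * np.exp(-theta[1] * t)
            if self.log_space:
                return np.log(pred) - np.log(c)
            return pred - c

        try:
            sol = least_squares(
                residuals,
                x0=[c0_init, k_init],
                bounds=([1e-300, 0.0], [np.inf, np.inf]),
                ftol=RSS_TOL,
                xtol=1e-12,
                gtol=1e-12,
            )
            ok = bool(sol.success)
        except Exception:
            ok = False
        if ok:
            self.c0_, self.k_ = float(sol.x[0]), float(max(sol.x[1], 0.0))
        else:
            self.c0_, self.k_ = c0_init, k_init
        self.converged_ = ok
        self.dt50_ = dt50_from_k(self.k_) if self.k_ > 0 else np.inf
        self.rss_ = float(np.sum((self.c0_ * np.exp(-self.k_ * t) - c) ** 2))
        self.n_points_ = int(len(t))
        return self

    def predict(self, X):
        check_is_fitted(self, "c0_")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        return self.c0_ * np.exp(-self.k_ * t)

    def params_(self) -> SfoParams:
        check_is_fitted(self, "c0_")
        return SfoParams(c0=self.c0_, k=self.k_)


class BiphasicDeclineModel(RegressorMixin, BaseEstimator):
    """Bi-phasic (DFOP) decline fitted by multi-start nonlinear least squares.

    Starts are taken over fast-phase fractions ``g0_grid`` with the fast
    rate initialized from a log-linear regression and the slow rate at
    one tenth of it; the best converged start by RSS wins.  The fit is
    deterministic for identical inputs.

    Attributes follow :class:`SFODeclineModel`, plus ``g_``, ``k1_``,
    ``k2_`` (k1_ >= k2_), ``dt50_`` as the overall half-life (time to
    50% of fitted c0_) and ``degenerate_`` flagging boundary-stuck g
    (pure single-phase behaviour; an SFO fit is then preferable).
    """

    def __init__(self, log_space: bool = False, g0_grid: tuple = (0.2, 0.5, 0.8)):
        self.log_space = log_space
        self.g0_grid = g0_grid

    _n_free_params = 4
    _g_boundary_tol = 1e-3

    def fit(self, X, y):
        t, c = _validate_xy(X, y)
        if len(t) < self._n_free_params + 1:
            raise ValueError(
                f"need >= {self._n_free_params + 1} points for a bi-phasic fit, got {len(t)}"
            )
        c0_init, k_init = _loglinear_init(t, c)

        def residuals(theta):
            c0, g, k1, k2 = theta
            pred = c0 * (g * np.exp(-k1 * t) + (1.0 - g) * np.exp(-k2 * t))
            if self.log_space:
                return np.log(np.maximum(pred, 1e-300)) - np.log(c)
            return pred - c

        best = None
        for g0 in self.g0_grid:
            try:
                sol = least_squares(
                    residuals,
                    x0=[c0_init, g0, max(k_init, 1e-6), max(k_init / 10.0, 1e-8)],
                    bounds=([1e-300, 0.0, 0.0, 0.0], [np.inf, 1.0, np.inf, np.inf]),
                    ftol=RSS_TOL,
                    xtol=1e-12,
                    gtol=1e-12,
                )
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(np.sum(residuals(sol.x) ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)

        if best is None:
            # fall back to an SFO-shaped solution from the log-linear estimate
            self.c0_, self.g_, self.k1_, self.k2_ = c0_init, 1.0, k_init, 0.0
            self.converged_ = False
        else:
            c0, g, k1, k2 = (float(v) for v in best[1])
            if k1 < k2:  # phases are exchangeable; normalize to k1 >= k2
                k1, k2 = k2, k1
                g = 1.0 - g
            self.c0_, self.g_, self.k1_, self.k2_ = c0, min(max(g, 0.0), 1.0), k1, k2
            self.converged_ = True
        self.degenerate_ = (
            self.g_ <= self._g_boundary_tol or self.g_ >= 1.0 - self._g_boundary_tol
        )
        self.rss_ = float(np.sum((self._curve(t) - c) ** 2))
        self.n_points_ = int(len(t))
        try:
            self.dt50_ = overall_dt50(self.params_())
        except ValueError:
            self.dt50_ = np.inf
        return self

    def _curve(self, t):
        return self.c0_ * (self.g_ * np.exp(-self.k1_ * t) + (1.0 - self.g_) * np.exp(-self.k2_ * t))

    def predict(self, X):
        check_is_fitted(self, "c0_")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        return self._curve(t)

    def params_(self) -> BiphasicParams:
        check_is_fitted(self, "c0_")
        return BiphasicParams(c0=self.c0_, g=self.g_, k1=self.k1_, k2=self.k2_)


def _series_to_xy(series: ResidueTimeSeries, min_points: int):
    censored = censor_loq(series)
    pairs = censored.replicate_means()
    if len(pairs) < min_points:
        raise ValueError(
            f"{series.crop}/{series.substance}: {len(pairs)} quantifiable points "
            f"after LOQ censoring; need >= {min_points}"
        )
    t = np.array([d for d, _ in pairs])
    c = np.array([v for _, v in pairs])
    if 0.0 not in t:
        raise ValueError(f"{series.crop}/{series.substance}: no day-0 point retained")
    return t, c


def fit_sfo(series: ResidueTimeSeries, log_space: bool = False) -> KineticFit:
    """Fit an SFO decline to a residue series (replicate means, censored).

    LOQ censoring is applied first (idempotent); at least 3 retained
    points including day 0 are required.
    """
    t, c = _series_to_xy(series, min_points=3)
    est = SFODeclineModel(log_space=log_space).fit(t, c)
    return KineticFit(
        model="SFO",
        params=est.params_(),
        dt50_days=est.dt50_,
        rss=est.rss_,
        n_points=est.n_points_,
        converged=est.converged_,
    )


def fit_biphasic(series: ResidueTimeSeries, log_space: bool = False) -> KineticFit:
    """Fit a bi-phasic (DFOP) decline to a residue series.

    Requires at least 5 retained points (4 free parameters).  The
    overall DT50 (time to 50% of fitted c0) is reported.  A
    boundary-stuck g flags the fit degenerate; an SFO fit is then
    recommended.
    """
    t, c = _series_to_xy(series, min_points=5)
    est = BiphasicDeclineModel(log_space=log_space).fit(t, c)
    return KineticFit(
        model="biphasic",
        params=est.params_(),
        dt50_days=est.dt50_,
        rss=est.rss_,
        n_points=est.n_points_,
        converged=est.converged_,
        degenerate=est.degenerate_,
    )
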