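"""Normalization of ThT traces and nonlinear least-squares parameter fits.

A raw ThT fluorescence time course (arbitrary units) is mapped to the
aggregated fraction f by a two-anchor affine normalization, then (rho, k)
are estimated by bounded least squares against the closed-form sigmoid.
From the fit, k_e = k / a and k_n = rho * k, mirroring how the rate
constants are extracted from plate-reader kinetics in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import (
    CharacteristicTimes,
    KineticParameters,
    aggregated_fraction,
    characteristic_times,
)

__all__ = [
    "ThTTimeSeries",
    "FitResult",
    "FlatTraceError",
    "InsufficientCoverageError",
    "normalize_trace",
    "fit_autocatalytic",
    "fit_condition",
]

RHO_BOUNDS = (1e-10, 10.0)
K_BOUNDS = (1e-8, 1.0)  # s^-1
MAX_RESTARTS = 3
MIN_POINTS = 8


class FlatTraceError(ValueError):
    """Trace shows no aggregation signal (plateau <= baseline)."""


class InsufficientCoverageError(ValueError):
    """Too few points past half-maximum to constrain the sigmoid."""


@dataclass(frozen=True)
class ThTTimeSeries:
    """One well's fluorescence (or fraction-aggregated) time course.

    ``times`` are seconds, strictly increasing; ``values`` are raw
    fluorescence in arbitrary units unless ``is_normalized`` is set, in
    which case they are fractions (small noise excursions outside [0, 1]
    are tolerated).
    """

    times: np.ndarray
    values: np.ndarray
    replicate_id: str = "r1"
    condition: str = ""
    protein_concentration: Optional[float] = None
    is_normalized: bool = False
    normalization: Optional[tuple[float, float]] = None  # (F_base, F_plateau)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D and the same length")
        if t.size < 1:
            raise ValueError("empty series")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class FitResult:
    """Estimated kinetics for one trace or condition."""

    params: KineticParameters
    times: CharacteristicTimes
    rho_hat: float
    k_hat: float
    residual_rms: float
    converged: bool
    n_points: int
    n_replicates: int = 1

    def __post_init__(self) -> None:
        # k_n = rho*k and k_e = k/a must round-trip through params.
        assert math.isclose(self.params.k_n, self.rho_hat * self.k_hat, rel_tol=1e-12)


def normalize_trace(raw: ThTTimeSeries) -> ThTTimeSeries:
    """Map raw fluorescence to fraction aggregated.

    f = (F - F_base) / (F_plateau - F_base), with F_base the mean of the
    first 3 points and F_plateau the mean of the last 3.  The anchors are
    recorded on the returned series so reports can state the mapping.

    Raises
    ------
    FlatTraceError
        If the plateau does not exceed the baseline (no signal).
    """
    if raw.is_normalized:
        return raw
    if len(raw) < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points, got {len(raw)}")
    f_base = float(np.mean(raw.values[:3]))
    f_plateau = float(np.mean(raw.values[-3:]))
    if f_plateau <= f_base:
        raise FlatTraceError(
            f"flat trace: plateau {f_plateau:.6g} <= baseline {f_base:.6g}"
        )
    values = (raw.values - f_base) / (f_plateau - f_base)
    return replace(
        raw, values=values, is_normalized=True, normalization=(f_base, f_plateau)
    )


def _initial_guess(times: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Geometry-based starting point: k0 from the steepest finite-difference
    slope, rho0 from placing the inflection near the first half-max crossing."""
    dt = np.diff(times)
    valid = dt > 0  # pooled grids may carry duplicate times
    slopes = np.diff(f)[valid] / dt[valid]
    k0 = 4.0 * float(np.max(slopes)) if slopes.size else 1.0 / float(times[-1])
    if not math.isfinite(k0):
        k0 = 1.0 / float(times[-1])
    k0 = min(max(k0, K_BOUNDS[0] * 10), K_BOUNDS[1] / 10)
    above = np.nonzero(f >= 0.5)[0]
    if above.size:
        i = above[0]
        if i > 0 and f[i] != f[i - 1]:  # linear interpolation of the crossing
            t_half0 = times[i - 1] + (0.5 - f[i - 1]) * (times[i] - times[i - 1]) / (
                f[i] - f[i - 1]
            )
        else:
            t_half0 = times[i]
    else:
        t_half0 = times[-1]
    rho0 = math.exp(-k0 * t_half0)
    rho0 = min(max(rho0, 1e-8), 1.0)
    return rho0, k0


def _model_values(rho: float, k: float, times: np.ndarray, anchored: bool) -> np.ndarray:
    """Model prediction in the same space as the observations.

    When the data went through the two-anchor normalization, the model is
    pushed through the identical map (means of its own first/last 3 points),
    so the estimator is not biased by baseline points that already sit on
    the rising phase of the sigmoid."""
    xarg = (1.0 + rho) * k * times
    emx = np.exp(-xarg)
    f = rho * (-np.expm1(-xarg)) / (emx + rho)
    if anchored:
        b = f[:3].mean()
        p = f[-3:].mean()
        f = (f - b) / (p - b)
    return f


def _fit_once(segments, x0):
    """Bounded least squares over (rho, k); segments are
    (times, observed, anchored) triples sharing the two parameters."""

    def residuals(x):
        rho, k = x
        return np.concatenate(
            [_model_values(rho, k, t, anch) - obs for t, obs, anch in segments]
        )

    return least_squares(
        residuals,
        x0=x0,
        bounds=([RHO_BOUNDS[0], K_BOUNDS[0]], [RHO_BOUNDS[1], K_BOUNDS[1]]),
        method="trf",
        x_scale=list(x0),
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )


def fit_autocatalytic(trace: ThTTimeSeries, a: float) -> FitResult:
    """Estimate (rho, k) for one normalized trace; derive k_n, k_e.

    Unweighted least squares in fraction space, bounded trust-region
    optimizer, deterministic initialization from the curve geometry and
    up to three deterministic restarts from perturbed starting points.

    Parameters
    ----------
    trace : ThTTimeSeries
        Normalized trace (raw traces are normalized on the fly).
    a : float
        Initial monomer concentration, M.
    """
    if a <= 0:
        raise ValueError("protein concentration a must be positive")
    if len(trace) < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points, got {len(trace)}")
    trace = normalize_trace(trace)
    anchored = trace.normalization is not None
    segments = [(trace.times, trace.values, anchored)]
    return _fit_segments(segments, a, n_points=len(trace))


def _fit_segments(segments, a: float, n_points: int) -> FitResult:
    times = np.concatenate([s[0] for s in segments])
    f_obs = np.concatenate([s[1] for s in segments])
    if np.count_nonzero(f_obs > 0.5) < 3:
        raise InsufficientCoverageError(
            "insufficient sigmoid coverage: fewer than 3 points beyond half-max"
        )

    rho0, k0 = _initial_guess_pooled(times, f_obs)
    best = None
    converged = False
    # deterministic restart ladder: perturb the initial point geometrically
    for factor in (1.0, 0.3, 3.0, 0.1)[: MAX_RESTARTS + 1]:
        x0 = (
            min(max(rho0 * factor, RHO_BOUNDS[0]), RHO_BOUNDS[1]),
            min(max(k0 * factor, K_BOUNDS[0]), K_BOUNDS[1]),
        )
        sol = _fit_once(segments, x0)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost <= best.cost + 1e-30:
            converged = True
            best = sol
            break

    rho_hat, k_hat = float(best.x[0]), float(best.x[1])
    params = KineticParameters.from_rho_k(rho_hat, k_hat, a)
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return FitResult(
        params=params,
        times=characteristic_times(params),
        rho_hat=rho_hat,
        k_hat=k_hat,
        residual_rms=rms,
        converged=converged,
        n_points=n_points,
    )


def _initial_guess_pooled(times: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    order = np.argsort(times, kind="stable")
    return _initial_guess(times[order], f[order])


def fit_condition(
    replicates: Sequence[ThTTimeSeries],
    a: float,
    strategy: Literal["averaged", "pooled"] = "averaged",
) -> FitResult:
    """Fit one condition measured in replicate.

    ``averaged`` (default) fits the pointwise-mean trace, which matches
    reporting a single parameter set per condition from triplicate
    measurements; ``pooled`` stacks all points into one joint residual.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    if len(replicates) == 1:
        res = fit_autocatalytic(replicates[0], a)
        return replace(res, n_replicates=1)

    if strategy == "averaged":
        t0 = replicates[0].times
        for r in replicates[1:]:
            if len(r) != len(replicates[0]) or not np.allclose(r.times, t0):
                raise ValueError(
                    "replicates have mismatched time grids; use strategy='pooled'"
                )
        mean_vals = np.mean([r.values for r in replicates], axis=0)
        mean_trace = ThTTimeSeries(
            times=t0,
            values=mean_vals,
            replicate_id="mean",
            condition=replicates[0].condition,
            protein_concentration=replicates[0].protein_concentration,
            is_normalized=all(r.is_normalized for r in replicates),
        )
        res = fit_autocatalytic(mean_trace, a)
    elif strategy == "pooled":
        normed = [normalize_trace(r) for r in replicates]
        segments = [(r.times, r.values, r.normalization is not None) for r in normed]
        res = _fit_segments(segments, a, n_points=sum(len(r) for r in normed))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return replace(res, n_replicates=len(replicates))
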