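"""Autocatalytic nucleation–elongation kinetics of amyloid fibrillation.

The fraction of peptide in fibrillar form, f(t), follows the two-step
autocatalytic rate law

    df/dt = k * (1 - f) * (rho + f),     f(0) = 0,

where ``k = k_e * a`` lumps the elongation rate constant ``k_e``
(M^-1 s^-1) with the initial monomer concentration ``a`` (M), and
``rho = k_n / k`` is the dimensionless ratio of the nucleation rate
constant ``k_n`` (s^-1) to ``k``.  Integrating with the stated boundary
condition gives the closed-form sigmoid

    f(t) = rho * (exp((1+rho)*k*t) - 1) / (1 + rho * exp((1+rho)*k*t)).

Small ``rho`` (nucleation much slower than elongation) produces the long
lag phase characteristic of ThT aggregation time courses.

Characteristic times are extracted by the tangent construction standard
in the aggregation literature: the tangent to f(t) at its inflection
point is extrapolated to f = 0 (lag time ``t0``) and to the normalized
plateau f = 1 (end time ``t1``); the half-aggregation time ``t_half`` is
the solution of f(t) = 1/2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParameters",
    "CharacteristicTimes",
    "aggregated_fraction",
    "ode_oracle",
    "time_at_fraction",
    "characteristic_times",
    "OdeOracleError",
]

@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the autocatalytic aggregation model.

    Parameters
    ----------
    k_n : float
        Nucleation rate constant, s^-1.
    k_e : float
        Elongation rate constant, M^-1 s^-1.
    a : float
        Initial monomeric protein concentration, M.

    Derived attributes ``k = k_e * a`` (s^-1) and ``rho = k_n / k``
    (dimensionless) are computed once at construction.  ``rho >= 1``
    (nucleation as fast as elongation, no lag phase) is representable
    but flagged via :attr:`is_lagless`.
    """

    k_n: float
    k_e: float
    a: float
    k: float = field(init=False)
    rho: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("k_n", "k_e", "a"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        object.__setattr__(self, "k", self.k_e * self.a)
        object.__setattr__(self, "rho", self.k_n / self.k)

    @classmethod
    def from_rho_k(cls, rho: float, k: float, a: float) -> "KineticParameters":
        """Build from the fitted (rho, k) pair and the known concentration."""
        return cls(k_n=rho * k, k_e=k / a, a=a)

    @property
    def is_lagless(self) -> bool:
        """True when rho >= 1, i.e. the inflection point lies at t <= 0."""
        return self.rho >= 1.0


@dataclass(frozen=True)
class CharacteristicTimes:
    """Characteristic times of one sigmoidal aggregation curve (seconds).

    ``t_half`` is the time at which f = 1/2; ``t_half_tangent`` is the
    midpoint (t0 + t1)/2 of the tangent construction, which is exactly
    t_inflection + (1 - 2 f_i)/(2 v_max) and agrees with ``t_half`` to
    O(rho^3).
    """

    t0: float
    t_half: float
    t1: float
    t_inflection: float
    v_max: float
    t_half_tangent: float
    lagless: bool = False

    def __post_init__(self) -> None:
        if not self.lagless:
            assert self.t0 < self.t_inflection < self.t1


def _x(params: KineticParameters, t: np.ndarray) -> np.ndarray:
    return (1.0 + params.rho) * params.k * t


def aggregated_fraction(params: KineticParameters, t):
    """Closed-form aggregated fraction f(t) of the autocatalytic model.

    Evaluated as ``f = rho*(1 - exp(-x)) / (exp(-x) + rho)`` with
    ``x = (1+rho)*k*t``, which only ever exponentiates non-positive
    arguments and is therefore overflow-safe for arbitrarily large x.

    Parameters
    ----------
    params : KineticParameters
    t : float or array_like
        Time(s) in seconds, >= 0.

    Returns
    -------
    float or ndarray
        Fraction aggregated, in [0, 1); f(0) = 0, f -> 1 as t -> inf.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    x = _x(params, t_arr)
    emx = np.exp(-x)
    f = params.rho * (-np.expm1(-x)) / (emx + params.rho)
    return float(f) if np.isscalar(t) or t_arr.ndim == 0 else f


class OdeOracleError(RuntimeError):
    """Raised when the numerical integrator fails to converge."""


def ode_oracle(params: KineticParameters, grid) -> np.ndarray:
    """Numerically integrate df/dt = k(1-f)(rho+f) on a time grid.

    Independent of the closed form; used to cross-check
    :func:`aggregated_fraction`.  Relative tolerance 1e-12.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if np.any(grid < 0) or np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted and non-negative")
    if grid.size == 1 and grid[0] == 0.0:
        return np.zeros(1)

    k, rho = params.k, params.rho

    def rhs(_t, f):
        return k * (1.0 - f) * (rho + f)

    t0 = 0.0
    sol = solve_ivp(
        rhs,
        (t0, float(grid[-1])),
        [0.0],
        t_eval=grid,
        method="DOP853",
        rtol=1e-12,
        atol=1e-14,
        dense_output=False,
    )
    if not sol.success:
        raise OdeOracleError(f"ODE integration failed: {sol.message}")
    return sol.y[0]


def time_at_fraction(params: KineticParameters, f_target: float) -> float:
    """Closed-form inverse of the sigmoid: time at which f reaches f_target.

    t = ln((f + rho) / (rho * (1 - f))) / ((1 + rho) * k), 0 <= f_target < 1.
    """
    if not (0.0 <= f_target < 1.0):
        raise ValueError("f_target must lie in [0, 1)")
    rho, k = params.rho, params.k
    return math.log((f_target + rho) / (rho * (1.0 - f_target))) / ((1.0 + rho) * k)


def characteristic_times(params: KineticParameters) -> CharacteristicTimes:
    """Extract t0, t_half, t1 by the tangent construction.

    The inflection of the closed form sits at t_i = ln(1/rho)/((1+rho)k)
    with f_i = (1-rho)/2 and maximum slope v_max = k(1+rho)^2/4.  The
    tangent there crosses f = 0 at t0 = t_i - f_i/v_max and the
    normalized plateau f = 1 at t1 = t_i + (1-f_i)/v_max.

    For rho >= 1 the inflection lies at t <= 0 (no lag phase); the result
    is flagged ``lagless`` and t0 is clamped to 0.
    """
    rho, k = params.rho, params.k
    v_max = k * (1.0 + rho) ** 2 / 4.0
    t_half = time_at_fraction(params, 0.5)
    if rho >= 1.0:
        warnings.warn(
            f"rho = {rho:.3g} >= 1: no lag phase, tangent times degenerate",
            stacklevel=2,
        )
        t1 = t_half + 1.0 / (2.0 * v_max)
        return CharacteristicTimes(
            t0=0.0,
            t_half=t_half,
            t1=t1,
            t_inflection=0.0,
            v_max=v_max,
            t_half_tangent=t1 / 2.0,
            lagless=True,
        )
    t_i = math.log(1.0 / rho) / ((1.0 + rho) * k)
    f_i = (1.0 - rho) / 2.0
    t0 = t_i - f_i / v_max
    t1 = t_i + (1.0 - f_i) / v_max
    return CharacteristicTimes(
        t0=t0,
        t_half=t_half,
        t1=t1,
        t_inflection=t_i,
        v_max=v_max,
        t_half_tangent=0.5 * (t0 + t1),
    )
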