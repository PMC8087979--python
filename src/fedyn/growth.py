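"""Two-state growth model: cumulative food intake and saturating body weight.

The model couples cumulative food consumption ``F`` and body weight ``W``::

    dF/dt = FI
    dW/dt = FE_max * (1 - W/W_max) * FI

with three parameters: ``FI`` (food intake, g/day), ``FE_max`` (maximum feed
efficiency, a dimensionless fraction in [0, 1]) and ``W_max`` (maximum body
weight, g).  Instantaneous feed efficiency is the conversion factor in front
of ``FI``: ``FE(t) = FE_max * (1 - W(t)/W_max)`` — body-weight gain per gram
of food at the animal's current weight.  It declines monotonically toward 0
as the animal approaches its asymptotic weight.

With constant ``FI`` the weight equation is linear and has the closed form

    W(t) = W_max - (W_max - W0) * exp(-FE_max * FI * t / W_max)

which this module uses as the default evaluation path; a numerical solver is
provided for cross-validation and for future time-varying-intake extensions.

Internal units are grams and days everywhere.  Diet energy density
(kcal/g) is carried along only so that report formatters can convert
intake to kcal/day at output boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

#: Energy density of the high-fat high-cholesterol diet, kcal per gram.
DEFAULT_ENERGY_DENSITY = 5.21

__all__ = [
    "DEFAULT_ENERGY_DENSITY",
    "GrowthParams",
    "WeightTrajectory",
    "Mouse",
    "CohortData",
    "cumulative_food",
    "analytic_weight",
    "solve_growth_system",
    "instantaneous_fe",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameter vector of the growth system.

    Parameters
    ----------
    fi : float
        Food intake rate, g/day.  Must be positive.
    fe_max : float
        Maximum feed efficiency (dimensionless fraction); the conversion
        efficiency at negligible body weight.  Must lie in [0, 1].
    w_max : float
        Asymptotic (maximum) body weight, g.  Must be positive.
    energy_density : float
        Diet energy density, kcal/g; used only when formatting intake
        as kcal/day.
    """

    fi: float
    fe_max: float
    w_max: float
    energy_density: float = DEFAULT_ENERGY_DENSITY

    def __post_init__(self) -> None:
        if not (0.0 <= self.fe_max <= 1.0):
            raise ValueError(f"fe_max must be in [0, 1], got {self.fe_max}")
        if self.fi <= 0:
            raise ValueError(f"fi must be > 0, got {self.fi}")
        if self.w_max <= 0:
            raise ValueError(f"w_max must be > 0, got {self.w_max}")
        if self.energy_density <= 0:
            raise ValueError(
                f"energy_density must be > 0, got {self.energy_density}"
            )

    @property
    def fi_kcal_per_day(self) -> float:
        """Food intake expressed in kcal/day (reporting convenience)."""
        return self.fi * self.energy_density


@dataclass
class WeightTrajectory:
    """Observation series for one animal: days, body weights, cumulative food.

    ``weights`` and ``cumfood`` entries may be NaN (missing observation);
    ``days`` may not.
    """

    days: np.ndarray
    weights: np.ndarray
    cumfood: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.cumfood = np.asarray(self.cumfood, dtype=float)
        if not (len(self.days) == len(self.weights) == len(self.cumfood)):
            raise ValueError("days, weights and cumfood must have equal length")
        if len(self.days) == 0:
            raise ValueError("empty trajectory")
        if np.any(~np.isfinite(self.days)):
            raise ValueError("days must be finite")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if self.days[0] < 0:
            raise ValueError("days must be non-negative")
        observed_food = self.cumfood[~np.isnan(self.cumfood)]
        if np.any(np.diff(observed_food) < 0):
            raise ValueError("cumulative food must be non-decreasing")
        if self.days[0] == 0 and not np.isnan(self.cumfood[0]):
            if abs(self.cumfood[0]) > 1e-9:
                raise ValueError("cumulative food at day 0 must be 0")

    def __len__(self) -> int:
        return len(self.days)


@dataclass
class Mouse:
    """One animal: its id, trajectory, sacrifice day and feeding-duration group."""

    mouse_id: str
    trajectory: WeightTrajectory
    sacrifice_day: float
    group_label: str

    @property
    def w0(self) -> float:
        """Day-0 body weight (the model's initial value)."""
        if self.trajectory.days[0] != 0:
            raise ValueError(
                f"mouse {self.mouse_id}: trajectory does not start at day 0"
            )
        return float(self.trajectory.weights[0])


@dataclass
class CohortData:
    """A cohort of mice with longitudinal weight/food observations."""

    mice: list[Mouse] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.mouse_id for m in self.mice]
        if len(set(ids)) != len(ids):
            raise ValueError("mouse ids must be unique")

    def __len__(self) -> int:
        return len(self.mice)

    def __iter__(self):
        return iter(self.mice)

    def mouse(self, mouse_id: str) -> Mouse:
        for m in self.mice:
            if m.mouse_id == mouse_id:
                return m
        raise KeyError(f"unknown mouse_id {mouse_id!r}")

    @property
    def mouse_ids(self) -> list[str]:
        return [m.mouse_id for m in self.mice]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.mice:
            seen.setdefault(m.group_label, None)
        return list(seen)


def cumulative_food(fi: float, t):
    """Cumulative food consumed by time ``t`` under constant intake ``fi``.

    ``dF/dt = FI`` with ``F(0) = 0`` integrates exactly to ``FI * t``.
    """
    t = np.asarray(t, dtype=float)
    if fi < 0:
        raise ValueError(f"fi must be >= 0, got {fi}")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = fi * t
    return float(out) if out.ndim == 0 else out


def _analytic_weight_raw(fi, fe_max, w_max, w0, t):
    """Closed-form weight, vectorised over raw arrays (no validation)."""
    rate = fe_max * fi / w_max
    return w_max - (w_max - w0) * np.exp(-rate * np.asarray(t, dtype=float))


def analytic_weight(p: GrowthParams, w0: float, t):
    """Closed-form body weight at time ``t`` from initial weight ``w0``.

    Solves ``dW/dt = FE_max (1 - W/W_max) FI`` with constant intake.
    ``W(0) = w0``; as ``t`` grows, ``W`` relaxes exponentially toward
    ``W_max`` with rate ``FE_max * FI / W_max``.
    """
    t = np.asarray(t, dtype=float)
    if w0 < 0:
        raise ValueError(f"w0 must be >= 0, got {w0}")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if w0 > p.w_max:
        warnings.warn(
            f"w0={w0} exceeds w_max={p.w_max}: trajectory decays toward w_max, "
            "outside the model's intended regime",
            stacklevel=2,
        )
    out = _analytic_weight_raw(p.fi, p.fe_max, p.w_max, w0, t)
    return float(out) if out.ndim == 0 else out


def solve_growth_system(
    p: GrowthParams,
    w0: float,
    days,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> WeightTrajectory:
    """Numerically integrate both states of the growth system.

    Uses an adaptive stiff-capable solver (LSODA).  Agrees with
    :func:`analytic_weight` / :func:`cumulative_food` to well below
    measurement noise; exists as a cross-check of the closed form and as
    the extension point for time-varying intake.
    """
    days = np.asarray(days, dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if np.any(days < 0):
        raise ValueError("days must be non-negative")
    if w0 < 0:
        raise ValueError(f"w0 must be >= 0, got {w0}")

    def rhs(_t, y):
        _f, w = y
        return [p.fi, p.fe_max * (1.0 - w / p.w_max) * p.fi]

    t0 = 0.0
    t_end = float(days[-1]) if days[-1] > 0 else 1.0
    sol = solve_ivp(
        rhs,
        (t0, t_end),
        [0.0, w0],
        t_eval=days,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return WeightTrajectory(days=days, weights=sol.y[1], cumfood=sol.y[0])


def instantaneous_fe(p: GrowthParams, w: float):
    """Instantaneous feed efficiency at body weight ``w``.

    ``FE = FE_max * (1 - W/W_max)``: the fraction of ingested food mass
    converted to body-weight gain at the current weight.  Equals ``FE_max``
    at ``W = 0`` and 0 at ``W = W_max``; negative beyond ``W_max``
    (extrapolation, warned).
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("w must be >= 0")
    if np.any(w > p.w_max):
        warnings.warn(
            f"body weight exceeds w_max={p.w_max}: feed efficiency is negative "
            "(model extrapolation)",
            stacklevel=2,
        )
    out = p.fe_max * (1.0 - w / p.w_max)
    return float(out) if out.ndim == 0 else out
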