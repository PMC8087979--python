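"""Posterior-predictive simulation of body-weight trajectories.

For a new (unseen) animal with known day-0 weight, each simulation samples a
joint posterior draw, draws a fresh intake rate from the hierarchical layer
``Normal(fi_mean, fi_sd)``, evaluates the closed-form trajectory, and adds
weight observation noise.  The predictive band is the pointwise mean with
central 95% envelope; it therefore covers measured weights, not just latent
trajectories.  Day 0 is the known initial value and carries no noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import PosteriorDraws
from .growth import CohortData, _analytic_weight_raw

__all__ = ["PredictiveBand", "posterior_predictive", "coverage_report"]


@dataclass
class PredictiveBand:
    """Pointwise predictive summary for one animal."""

    days: np.ndarray
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    n_sims: int

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        for name in ("mean", "lo95", "hi95"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.lo95 > self.mean + 1e-9) or np.any(self.mean > self.hi95 + 1e-9):
            raise ValueError("band must satisfy lo95 <= mean <= hi95 pointwise")

    def to_frame(self, mouse_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"day": self.days, "mean": self.mean, "lo95": self.lo95, "hi95": self.hi95}
        )
        if mouse_id is not None:
            df.insert(0, "mouse_id", mouse_id)
        return df


def posterior_predictive(
    draws: PosteriorDraws,
    w0: float,
    days,
    n_sims: int = 1000,
    seed: int = 0,
    include_noise: bool = True,
) -> PredictiveBand:
    """Predictive band of body weight for a new animal starting at ``w0``.

    Each of the ``n_sims`` simulations uses one sampled posterior row
    (``fe_max``, ``w_max``, ``fi_mean``, ``fi_sd``, ``sigma_w`` jointly),
    draws the animal's intake from ``Normal(fi_mean, fi_sd)`` truncated to
    positive values, and evaluates the closed-form trajectory; observation
    noise is added at every post-baseline day when ``include_noise``.
    """
    days = np.asarray(days, dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if w0 <= 0:
        raise ValueError("w0 must be > 0")
    if n_sims < 100:
        warnings.warn(
            f"n_sims={n_sims} < 100: predictive bands will be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n_avail = len(draws)
    idx = rng.choice(n_avail, size=n_sims, replace=n_sims > n_avail)
    sub = draws.df.iloc[idx]
    fi_mean = sub["fi_mean"].to_numpy()
    fi_sd = sub["fi_sd"].to_numpy()
    fe_max = sub["fe_max"].to_numpy()
    w_max = sub["w_max"].to_numpy()
    sigma_w = sub["sigma_w"].to_numpy()

    fi = rng.normal(fi_mean, fi_sd)
    bad = fi <= 0
    while np.any(bad):  # truncate the intake hierarchy at 0
        fi[bad] = rng.normal(fi_mean[bad], fi_sd[bad])
        bad = fi <= 0

    w = _analytic_weight_raw(
        fi[:, None], fe_max[:, None], w_max[:, None], w0, days[None, :]
    )
    if include_noise:
        noise = rng.normal(0.0, sigma_w[:, None], w.shape)
        noise[:, days == 0] = 0.0
        w = w + noise
    lo, hi = np.percentile(w, [2.5, 97.5], axis=0)
    return PredictiveBand(
        days=days, mean=w.mean(axis=0), lo95=lo, hi95=hi, n_sims=n_sims
    )


def coverage_report(bands: dict[str, PredictiveBand], cohort: CohortData) -> pd.DataFrame:
    """Per-mouse count of observed weights falling inside the 95% band.

    Observation days must match band days exactly; points on the band
    boundary count as inside.  Returns a table with columns ``mouse_id``,
    ``n_points``, ``n_inside``, ``fraction``.
    """
    rows = []
    for mouse_id, band in bands.items():
        m = cohort.mouse(mouse_id)
        traj = m.trajectory
        obs_mask = np.isfinite(traj.weights)
        obs_days = traj.days[obs_mask]
        obs_w = traj.weights[obs_mask]
        day_to_idx = {d: i for i, d in enumerate(band.days)}
        missing = [d for d in obs_days if d not in day_to_idx]
        if missing:
            raise ValueError(
                f"mouse {mouse_id}: observation days {missing} have no exact "
                "match in the predictive band (nearest-day lookup is not done)"
            )
        idx = np.array([day_to_idx[d] for d in obs_days], dtype=int)
        inside = (band.lo95[idx] <= obs_w) & (obs_w <= band.hi95[idx])
        rows.append(
            {
                "mouse_id": mouse_id,
                "n_points": len(obs_w),
                "n_inside": int(inside.sum()),
                "fraction": float(inside.mean()) if len(obs_w) else np.nan,
            }
        )
    return pd.DataFrame(rows)
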