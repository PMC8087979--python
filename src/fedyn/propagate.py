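"""Propagation of posterior uncertainty into instantaneous feed efficiency.

Each animal's feed efficiency at its sacrifice day is recomputed once per
posterior draw — using the draw's own ``(fi_i, fe_max, w_max)`` jointly, so
parameter correlations are preserved — yielding a mice x draws matrix that
downstream association and correlation stages consume column by column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import PosteriorDraws
from .growth import CohortData, _analytic_weight_raw

__all__ = ["FeDrawMatrix", "fe_at_day", "fe_draw_matrix", "group_fe_summary"]


@dataclass
class FeDrawMatrix:
    """Mice x draws matrix of instantaneous feed efficiency (fractions).

    ``values[i, j]`` is mouse i's FE at its sacrifice day under posterior
    draw j.  ``meta`` carries one row per mouse: mouse_id, group,
    sacrifice_day.
    """

    values: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (mice x draws)")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("meta rows must match value rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FE draws must be finite (no missing entries)")
        if np.any((self.values < 0) | (self.values >= 1)):
            raise ValueError("FE draws must lie in [0, 1)")

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    @property
    def mouse_ids(self) -> list[str]:
        return list(self.meta["mouse_id"])

    def rows_for_group(self, group: str) -> "FeDrawMatrix":
        mask = (self.meta["group"] == group).to_numpy()
        return FeDrawMatrix(self.values[mask], self.meta[mask].reset_index(drop=True))

    def rows_for_mice(self, mouse_ids) -> "FeDrawMatrix":
        order = {m: i for i, m in enumerate(self.meta["mouse_id"])}
        idx = [order[m] for m in mouse_ids]
        return FeDrawMatrix(self.values[idx], self.meta.iloc[idx].reset_index(drop=True))

    def to_frame(self) -> pd.DataFrame:
        width = len(str(self.n_draws))
        cols = [f"draw_{j + 1:0{max(width, 4)}d}" for j in range(self.n_draws)]
        out = self.meta.copy()
        return pd.concat([out, pd.DataFrame(self.values, columns=cols)], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeDrawMatrix":
        draw_cols = [c for c in df.columns if c.startswith("draw_")]
        meta_cols = [c for c in df.columns if not c.startswith("draw_")]
        return cls(df[draw_cols].to_numpy(float), df[meta_cols].reset_index(drop=True))


def _select_rows(draws: PosteriorDraws, n_draws: int, seed: int) -> np.ndarray:
    n_avail = len(draws)
    rng = np.random.default_rng(seed)
    if n_draws > n_avail:
        warnings.warn(
            f"requested {n_draws} FE draws but only {n_avail} posterior rows "
            "are available; sampling with replacement",
            stacklevel=3,
        )
        return rng.choice(n_avail, size=n_draws, replace=True)
    return rng.choice(n_avail, size=n_draws, replace=False)


def fe_at_day(
    draws: PosteriorDraws,
    mouse_id: str,
    w0: float,
    day: float,
    n_draws: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Instantaneous FE of a fitted mouse at ``day``, one value per draw.

    For each sampled posterior row d:
    ``FE = fe_max_d * (1 - W_d(day) / w_max_d)`` with ``W_d`` the
    closed-form trajectory under ``(fi_i_d, fe_max_d, w_max_d)`` started at
    the mouse's observed day-0 weight ``w0``.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    fi = draws.fi_draws(mouse_id)  # KeyError for unknown mice
    idx = _select_rows(draws, n_draws, seed)
    fi = fi[idx]
    fe_max = draws.df["fe_max"].to_numpy()[idx]
    w_max = draws.df["w_max"].to_numpy()[idx]
    w = _analytic_weight_raw(fi, fe_max, w_max, w0, day)
    return fe_max * (1.0 - w / w_max)


def fe_draw_matrix(
    draws: PosteriorDraws,
    cohort: CohortData,
    n_draws: int = 1000,
    seed: int = 0,
    mouse_ids=None,
) -> FeDrawMatrix:
    """FE-at-sacrifice draw matrix for (a subset of) the fitted cohort.

    All mice share the same selection of posterior rows per column, so one
    column is one coherent posterior scenario across animals.
    """
    mouse_ids = list(mouse_ids) if mouse_ids is not None else cohort.mouse_ids
    idx = _select_rows(draws, n_draws, seed)
    fe_max = draws.df["fe_max"].to_numpy()[idx]
    w_max = draws.df["w_max"].to_numpy()[idx]
    values = np.empty((len(mouse_ids), n_draws))
    meta_rows = []
    for i, mid in enumerate(mouse_ids):
        m = cohort.mouse(mid)
        fi = draws.fi_draws(mid)[idx]
        w = _analytic_weight_raw(fi, fe_max, w_max, m.w0, m.sacrifice_day)
        values[i] = fe_max * (1.0 - w / w_max)
        meta_rows.append(
            {
                "mouse_id": mid,
                "group": m.group_label,
                "sacrifice_day": m.sacrifice_day,
            }
        )
    return FeDrawMatrix(values, pd.DataFrame(meta_rows))


def group_fe_summary(fe: FeDrawMatrix) -> pd.DataFrame:
    """Average FE per feeding-duration group with its 95% credible interval.

    Per draw, the group's FE is averaged over its mice; the summary is the
    mean and central 95% interval of that group-average across draws (the
    between-mouse spread is averaged out, the posterior uncertainty is not).
    Empty groups are omitted with a warning.
    """
    if fe.values.size == 0:
        raise ValueError("empty FE draw matrix")
    rows = []
    for group, sub in fe.meta.groupby("group", sort=False):
        vals = fe.values[sub.index.to_numpy()]
        if vals.size == 0:
            warnings.warn(f"group {group!r} has no FE draws; omitted", stacklevel=2)
            continue
        per_draw_mean = vals.mean(axis=0)
        lo, hi = np.quantile(per_draw_mean, [0.025, 0.975])
        rows.append(
            {
                "group": group,
                "n_mice": len(sub),
                "mean_fe": float(per_draw_mean.mean()),
                "lo95": float(lo),
                "hi95": float(hi),
            }
        )
    return pd.DataFrame(rows)
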