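"""Hierarchical Bayesian estimation of the growth-model parameters by MCMC.

The model shares the population parameters ``fe_max`` (maximum feed
efficiency) and ``w_max`` (maximum body weight) across animals and lets each
mouse have its own intake rate::

    fi_i    ~ Normal(fi_mean, fi_sd)
    W_ij    ~ Normal(W(t_ij; fi_i, fe_max, w_max, w0_i), sigma_w)
    F_ij    ~ Normal(fi_i * t_ij,                       sigma_f)

with ``W(t)`` the closed-form solution of the growth system and ``w0_i`` the
observed day-0 body weight.  Priors:

* ``fi_mean ~ Normal(2.5, 0.1)`` g/day (informative, from an independent
  study with the same strain and diet),
* ``w_max ~ Exponential(rate=0.02)`` per g (prior mean 50 g),
* ``fe_max ~ Beta(2, 8)`` (weakly informative on [0, 1], prior mean 0.2),
* ``fi_sd ~ HalfNormal(0.5)`` g/day,
* observation scales ``sigma_w, sigma_f ~ HalfNormal(5)`` g.

Sampling uses an affine-invariant ensemble sampler (emcee); each requested
"chain" is an independent ensemble with its own seed, and draws are retained
after discarding the warmup fraction of steps.  Split R-hat and effective
sample size are computed with arviz and enforced as hard convergence gates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from .growth import CohortData

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "ConvergenceError",
    "log_prior",
    "log_likelihood",
    "sample_posterior",
    "summarize_posterior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class ConvergenceError(RuntimeError):
    """Raised when MCMC diagnostics violate the convergence gates."""


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters for the hierarchical growth model."""

    fi_mean_loc: float = 2.5      # g/day
    fi_mean_scale: float = 0.1    # g/day
    fi_sd_scale: float = 0.5      # half-normal scale, g/day
    w_max_rate: float = 0.02      # exponential rate, 1/g
    fe_max_a: float = 2.0
    fe_max_b: float = 8.0
    sigma_w_scale: float = 5.0    # half-normal scale, g
    sigma_f_scale: float = 5.0    # half-normal scale, g

    def __post_init__(self) -> None:
        for name in (
            "fi_mean_scale",
            "fi_sd_scale",
            "w_max_rate",
            "fe_max_a",
            "fe_max_b",
            "sigma_w_scale",
            "sigma_f_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    ``n_iter`` is the number of ensemble steps per chain; the first
    ``warmup_frac`` of steps is discarded.  ``n_walkers=None`` picks an
    even number of at least ``2*ndim + 2`` walkers (minimum 32).
    """

    n_chains: int = 4
    n_iter: int = 2000
    warmup_frac: float = 0.5
    seed: int = 0
    n_walkers: int | None = None
    rhat_max: float = 1.01
    ess_min: float = 100.0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")
        if not (0.0 < self.warmup_frac < 1.0):
            raise ValueError("warmup_frac must be in (0, 1)")


# ---------------------------------------------------------------------------
# scalar log-density helpers (natural scale)
# ---------------------------------------------------------------------------

def _norm_lpdf(x, loc, scale):
    z = (x - loc) / scale
    return -0.5 * z * z - np.log(scale) - 0.5 * _LOG_2PI


def _halfnorm_lpdf(x, scale):
    out = np.where(
        x >= 0,
        np.log(2.0) - 0.5 * _LOG_2PI - np.log(scale)
        - 0.5 * (x / scale) ** 2,
        -np.inf,
    )
    return out


def _expon_lpdf(x, rate):
    return np.where(x >= 0, np.log(rate) - rate * x, -np.inf)


def _beta_lpdf(x, a, b):
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = (x > 0) & (x < 1)
        val = (a - 1.0) * np.log(np.where(inside, x, 0.5)) + (
            b - 1.0
        ) * np.log(np.where(inside, 1.0 - x, 0.5)) - betaln(a, b)
    return np.where(inside, val, -np.inf)


# ---------------------------------------------------------------------------
# public scalar-interface densities
# ---------------------------------------------------------------------------

_POP_PARAMS = ("fi_mean", "fi_sd", "fe_max", "w_max", "sigma_w", "sigma_f")


def log_prior(params: dict, priors: PriorSpec) -> float:
    """Joint log prior density of a parameter setting (natural scale).

    ``params`` maps parameter names to values; per-mouse intakes use keys
    ``"fi[<mouse_id>]"`` and are scored under the hierarchical
    ``Normal(fi_mean, fi_sd)`` layer.  Out-of-support values return ``-inf``
    rather than raising.
    """
    lp = 0.0
    lp += float(_norm_lpdf(params["fi_mean"], priors.fi_mean_loc, priors.fi_mean_scale))
    lp += float(_halfnorm_lpdf(params["fi_sd"], priors.fi_sd_scale))
    lp += float(_beta_lpdf(params["fe_max"], priors.fe_max_a, priors.fe_max_b))
    lp += float(_expon_lpdf(params["w_max"], priors.w_max_rate))
    lp += float(_halfnorm_lpdf(params["sigma_w"], priors.sigma_w_scale))
    lp += float(_halfnorm_lpdf(params["sigma_f"], priors.sigma_f_scale))
    fi_keys = [k for k in params if k.startswith("fi[")]
    if fi_keys:
        fi_sd = params["fi_sd"]
        if fi_sd <= 0:
            return -np.inf
        fis = np.array([params[k] for k in fi_keys], dtype=float)
        if np.any(fis <= 0):
            return -np.inf
        lp += float(np.sum(_norm_lpdf(fis, params["fi_mean"], fi_sd)))
    return lp


def log_likelihood(params: dict, cohort: CohortData) -> float:
    """Log likelihood of the cohort observations under ``params``.

    Sums independent normal terms over mice and post-baseline time points:
    observed weight around the closed-form trajectory and observed
    cumulative food around ``fi_i * t``.  Day-0 rows are initial conditions
    and contribute no likelihood term.  A mouse with no post-baseline
    observation contributes nothing (warned).
    """
    packed = _pack_cohort(cohort)
    theta = np.array(
        [params["fe_max"], params["w_max"], params["sigma_w"], params["sigma_f"]]
    )
    fis = np.array(
        [params[f"fi[{mid}]"] for mid in packed.mouse_ids], dtype=float
    )
    return float(
        _loglik_packed(
            packed,
            fis[None, :],
            theta[0:1],
            theta[1:2],
            theta[2:3],
            theta[3:4],
        )[0]
    )


# ---------------------------------------------------------------------------
# packed cohort representation for vectorised likelihood
# ---------------------------------------------------------------------------

@dataclass
class _PackedCohort:
    mouse_ids: list[str]
    w0: np.ndarray          # (M,)
    t: np.ndarray           # (M, L) padded post-baseline days
    w_obs: np.ndarray       # (M, L) NaN-padded
    f_obs: np.ndarray       # (M, L) NaN-padded
    w_mask: np.ndarray      # (M, L) bool
    f_mask: np.ndarray      # (M, L) bool


def _pack_cohort(cohort: CohortData) -> _PackedCohort:
    mids, w0s, ts, ws, fs = [], [], [], [], []
    for m in cohort:
        traj = m.trajectory
        post = traj.days > 0
        if post.sum() == 0:
            warnings.warn(
                f"mouse {m.mouse_id} has no post-baseline observation; "
                "it contributes only its initial condition",
                stacklevel=3,
            )
        mids.append(m.mouse_id)
        w0s.append(m.w0)
        ts.append(traj.days[post])
        ws.append(traj.weights[post])
        fs.append(traj.cumfood[post])
    n = len(mids)
    lmax = max((len(t) for t in ts), default=0)
    t = np.zeros((n, max(lmax, 1)))
    w = np.full_like(t, np.nan)
    f = np.full_like(t, np.nan)
    for i in range(n):
        k = len(ts[i])
        t[i, :k] = ts[i]
        w[i, :k] = ws[i]
        f[i, :k] = fs[i]
    return _PackedCohort(
        mouse_ids=mids,
        w0=np.asarray(w0s, dtype=float),
        t=t,
        w_obs=w,
        f_obs=f,
        w_mask=np.isfinite(w),
        f_mask=np.isfinite(f),
    )


def _loglik_packed(packed, fis, fe_max, w_max, sigma_w, sigma_f):
    """Vectorised likelihood.

    fis: (K, M); fe_max/w_max/sigma_w/sigma_f: (K,).  Returns (K,).
    """
    K = fis.shape[0]
    if len(packed.mouse_ids) == 0:
        return np.zeros(K)
    t = packed.t[None, :, :]                       # (1, M, L)
    rate = (fe_max[:, None] * fis / w_max[:, None])[:, :, None]
    wmax = w_max[:, None, None]
    w_pred = wmax - (wmax - packed.w0[None, :, None]) * np.exp(-rate * t)
    f_pred = fis[:, :, None] * t

    sw = sigma_w[:, None, None]
    sf = sigma_f[:, None, None]
    rw = np.where(packed.w_mask[None], packed.w_obs[None] - w_pred, 0.0)
    rf = np.where(packed.f_mask[None], packed.f_obs[None] - f_pred, 0.0)
    n_w = packed.w_mask.sum()
    n_f = packed.f_mask.sum()
    ll = (
        -0.5 * np.sum((rw / sw) ** 2, axis=(1, 2))
        - n_w * (np.log(sigma_w) + 0.5 * _LOG_2PI)
        - 0.5 * np.sum((rf / sf) ** 2, axis=(1, 2))
        - n_f * (np.log(sigma_f) + 0.5 * _LOG_2PI)
    )
    return ll


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

class PosteriorDraws:
    """Retained MCMC draws plus convergence diagnostics.

    ``df`` holds one row per retained draw with natural-scale parameter
    columns and a ``chain`` column; ``diagnostics`` is a per-parameter table
    with split R-hat and effective sample size.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        mouse_ids: list[str],
        diagnostics: pd.DataFrame | None = None,
    ):
        self.df = df
        self.mouse_ids = mouse_ids
        self.diagnostics = diagnostics
        self._validate()

    def _validate(self) -> None:
        if "fe_max" in self.df.columns:
            fe = self.df["fe_max"].to_numpy()
            if np.any((fe <= 0) | (fe >= 1)):
                raise ValueError("fe_max draws must lie in (0, 1)")
        for col in self.df.columns:
            if col == "chain" or col == "fi_mean":
                continue
            if col.startswith("fi[") or col in ("w_max", "fi_sd", "sigma_w", "sigma_f"):
                if np.any(self.df[col].to_numpy() < 0):
                    raise ValueError(f"negative draw in column {col}")

    @property
    def param_names(self) -> list[str]:
        return [c for c in self.df.columns if c != "chain"]

    def __len__(self) -> int:
        return len(self.df)

    def fi_draws(self, mouse_id: str) -> np.ndarray:
        col = f"fi[{mouse_id}]"
        if col not in self.df.columns:
            raise KeyError(f"no intake draws for mouse {mouse_id!r}")
        return self.df[col].to_numpy()

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PosteriorDraws":
        df = pd.read_csv(path, sep="\t")
        mids = [c[3:-1] for c in df.columns if c.startswith("fi[")]
        return cls(df, mids)


def summarize_posterior(draws: PosteriorDraws, energy_density: float | None = None) -> pd.DataFrame:
    """Posterior mean and central 95% credible interval per parameter.

    With ``energy_density`` set, appends rows expressing intake parameters in
    kcal/day (reporting convenience; internal draws stay in g/day).
    """
    if len(draws) < 100:
        raise ValueError("need at least 100 draws to summarise")
    rows = []
    for name in draws.param_names:
        x = draws.df[name].to_numpy()
        lo, hi = np.quantile(x, [0.025, 0.975])
        rows.append({"param": name, "mean": x.mean(), "lo95": lo, "hi95": hi})
    out = pd.DataFrame(rows)
    if energy_density is not None:
        intake = out["param"].str.startswith(("fi_mean", "fi["))
        extra = out[intake].copy()
        extra["param"] = extra["param"] + "_kcal_per_day"
        extra[["mean", "lo95", "hi95"]] *= energy_density
        out = pd.concat([out, extra], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

_TRANSFORMS = {
    "fi_mean": "identity",
    "fi_sd": "log",
    "fe_max": "logit",
    "w_max": "log",
    "sigma_w": "log",
    "sigma_f": "log",
}


def _to_unconstrained(name: str, x: float) -> float:
    kind = _TRANSFORMS.get(name, "identity")
    if kind == "log":
        return float(np.log(x))
    if kind == "logit":
        return float(logit(x))
    return float(x)


class _Model:
    """Posterior over free parameters on the unconstrained scale."""

    def __init__(self, cohort, priors, fixed):
        self.priors = priors
        self.packed = _pack_cohort(cohort)
        self.fixed = dict(fixed or {})
        self.tie_fi = self.fixed.get("fi_sd", None) == 0.0
        free = [p for p in _POP_PARAMS if p not in self.fixed]
        if not self.tie_fi:
            free += [
                f"fi[{mid}]"
                for mid in self.packed.mouse_ids
                if f"fi[{mid}]" not in self.fixed
            ]
        self.free_names = free
        self.ndim = len(free)
        self._fi_idx = [
            i for i, n in enumerate(free) if n.startswith("fi[")
        ]
        self._pos = {n: i for i, n in enumerate(free)}

    def _column(self, u: np.ndarray, name: str) -> np.ndarray:
        """Natural-scale values of a population parameter for walker matrix u."""
        if name in self.fixed:
            return np.full(u.shape[0], self.fixed[name])
        j = self._pos[name]
        kind = _TRANSFORMS.get(name, "identity")
        if kind == "log":
            return np.exp(u[:, j])
        if kind == "logit":
            return expit(u[:, j])
        return u[:, j]

    def _fi_matrix(self, u: np.ndarray, fi_mean: np.ndarray) -> np.ndarray:
        M = len(self.packed.mouse_ids)
        K = u.shape[0]
        if self.tie_fi:
            return np.repeat(fi_mean[:, None], M, axis=1)
        fis = np.empty((K, M))
        for m, mid in enumerate(self.packed.mouse_ids):
            key = f"fi[{mid}]"
            if key in self.fixed:
                fis[:, m] = self.fixed[key]
            else:
                fis[:, m] = u[:, self._pos[key]]
        return fis

    def log_prob(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u)
        K = u.shape[0]
        pri = self.priors
        fi_mean = self._column(u, "fi_mean")
        fi_sd = self._column(u, "fi_sd")
        fe_max = self._column(u, "fe_max")
        w_max = self._column(u, "w_max")
        sigma_w = self._column(u, "sigma_w")
        sigma_f = self._column(u, "sigma_f")

        lp = np.zeros(K)
        lp += _norm_lpdf(fi_mean, pri.fi_mean_loc, pri.fi_mean_scale)
        if not self.tie_fi:
            lp += _halfnorm_lpdf(fi_sd, pri.fi_sd_scale)
        lp += _beta_lpdf(fe_max, pri.fe_max_a, pri.fe_max_b)
        lp += _expon_lpdf(w_max, pri.w_max_rate)
        lp += _halfnorm_lpdf(sigma_w, pri.sigma_w_scale)
        lp += _halfnorm_lpdf(sigma_f, pri.sigma_f_scale)

        fis = self._fi_matrix(u, fi_mean)
        if fis.shape[1] and not self.tie_fi:
            bad = np.any(fis <= 0, axis=1) | (fi_sd <= 0)
            safe_sd = np.where(fi_sd > 0, fi_sd, 1.0)
            hier = np.sum(
                _norm_lpdf(fis, fi_mean[:, None], safe_sd[:, None]), axis=1
            )
            lp = np.where(bad, -np.inf, lp + hier)

        # Jacobians of the unconstrained transforms
        for name in ("fi_sd", "w_max", "sigma_w", "sigma_f"):
            if name in self._pos:
                lp += u[:, self._pos[name]]
        if "fe_max" in self._pos:
            lp += np.log(fe_max) + np.log1p(-fe_max)

        ok = np.isfinite(lp)
        if np.any(ok) and len(self.packed.mouse_ids):
            ll = _loglik_packed(
                self.packed,
                fis[ok],
                fe_max[ok],
                w_max[ok],
                sigma_w[ok],
                sigma_f[ok],
            )
            lp[ok] += ll
        return lp

    def _rough_estimates(self) -> dict[str, float]:
        """Cheap data-driven point estimates used to centre walker starts.

        Per-mouse intake from the least-squares slope of cumulative food
        through the origin; (fe_max, w_max) from a coarse grid search on the
        pooled weight residuals; noise scales from the residuals themselves.
        With no data, falls back to prior central values.
        """
        pk = self.packed
        pri = self.priors
        est = {
            "fi_mean": pri.fi_mean_loc,
            "fi_sd": 0.2,
            "fe_max": pri.fe_max_a / (pri.fe_max_a + pri.fe_max_b),
            "w_max": 1.0 / pri.w_max_rate,
            "sigma_w": 1.0,
            "sigma_f": 1.0,
            "fi_each": np.full(len(pk.mouse_ids), pri.fi_mean_loc),
        }
        if len(pk.mouse_ids) == 0:
            return est
        fi_hat = np.full(len(pk.mouse_ids), pri.fi_mean_loc)
        for i in range(len(pk.mouse_ids)):
            msk = pk.f_mask[i]
            if msk.sum() >= 1:
                t, f = pk.t[i][msk], pk.f_obs[i][msk]
                denom = np.sum(t * t)
                if denom > 0:
                    fi_hat[i] = max(np.sum(t * f) / denom, 0.1)
        est["fi_each"] = fi_hat
        est["fi_mean"] = float(np.mean(fi_hat))
        est["fi_sd"] = float(max(np.std(fi_hat), 0.02))
        if pk.w_mask.sum() >= 3:
            fe_grid = np.linspace(0.03, 0.6, 40)
            wm_grid = np.linspace(
                max(np.nanmax(np.where(pk.w_mask, pk.w_obs, -np.inf)) + 1.0, 35.0),
                120.0,
                40,
            )
            FE, WM = np.meshgrid(fe_grid, wm_grid, indexing="ij")
            rate = FE[..., None, None] * fi_hat[None, None, :, None] / WM[..., None, None]
            pred = WM[..., None, None] - (
                WM[..., None, None] - pk.w0[None, None, :, None]
            ) * np.exp(-rate * pk.t[None, None, :, :])
            resid = np.where(pk.w_mask[None, None], pk.w_obs[None, None] - pred, 0.0)
            sse = np.sum(resid**2, axis=(2, 3))
            i, j = np.unravel_index(np.argmin(sse), sse.shape)
            est["fe_max"] = float(fe_grid[i])
            est["w_max"] = float(wm_grid[j])
            est["sigma_w"] = float(
                max(np.sqrt(sse[i, j] / pk.w_mask.sum()), 0.1)
            )
        if pk.f_mask.sum() >= 3:
            rf = np.where(pk.f_mask, pk.f_obs - fi_hat[:, None] * pk.t, 0.0)
            est["sigma_f"] = float(
                max(np.sqrt(np.sum(rf**2) / pk.f_mask.sum()), 0.1)
            )
        return est

    def initial_walkers(self, n_walkers: int, rs: np.random.RandomState) -> np.ndarray:
        """Starting points: jittered around cheap data-driven estimates.

        With an empty cohort (prior sampling) the starts are drawn from a
        broad region of the prior instead.
        """
        pri = self.priors
        if len(self.packed.mouse_ids) == 0 and not self.tie_fi:
            nat: dict[str, np.ndarray] = {
                "fi_mean": rs.normal(pri.fi_mean_loc, pri.fi_mean_scale, n_walkers),
                "fi_sd": rs.uniform(0.05, 0.8, n_walkers),
                "fe_max": rs.uniform(0.02, 0.6, n_walkers),
                "w_max": rs.uniform(5.0, 120.0, n_walkers),
                "sigma_w": rs.uniform(0.5, 8.0, n_walkers),
                "sigma_f": rs.uniform(0.5, 8.0, n_walkers),
            }
            u0 = np.empty((n_walkers, self.ndim))
            for name, j in self._pos.items():
                kind = _TRANSFORMS.get(name, "identity")
                x = nat[name]
                u0[:, j] = (
                    np.log(x) if kind == "log" else logit(x) if kind == "logit" else x
                )
            return u0
        est = self._rough_estimates()
        u0 = np.empty((n_walkers, self.ndim))
        for name, j in self._pos.items():
            if name.startswith("fi["):
                i = self.packed.mouse_ids.index(name[3:-1])
                centre = est["fi_each"][i]
                u0[:, j] = np.maximum(rs.normal(centre, 0.1, n_walkers), 0.05)
            else:
                centre = _to_unconstrained(name, est[name])
                u0[:, j] = rs.normal(centre, 0.15, n_walkers)
        return u0

    def natural_frame(self, u: np.ndarray) -> pd.DataFrame:
        cols = {}
        for name in _POP_PARAMS:
            cols[name] = (
                np.full(u.shape[0], self.fixed[name])
                if name in self.fixed
                else self._column(u, name)
            )
        fis = self._fi_matrix(u, cols["fi_mean"])
        for m, mid in enumerate(self.packed.mouse_ids):
            cols[f"fi[{mid}]"] = fis[:, m]
        return pd.DataFrame(cols)


def sample_posterior(
    cohort: CohortData,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    fixed: dict | None = None,
) -> PosteriorDraws:
    """Draw from the joint posterior of the hierarchical growth model.

    Parameters
    ----------
    cohort : CohortData
        Observed trajectories.  An empty cohort samples the prior.
    priors, config : PriorSpec, MCMCConfig
        Hyperparameters and sampler settings (defaults used when None).
    fixed : dict, optional
        Map of parameter names to values held constant (not sampled).
        ``fixed={"fi_sd": 0.0, ...}`` ties every per-mouse intake to
        ``fi_mean`` (degenerate hierarchy), which is how reduced
        sub-models are expressed.

    Raises
    ------
    ConvergenceError
        If any split R-hat exceeds ``config.rhat_max`` or any effective
        sample size falls below ``config.ess_min``.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    model = _Model(cohort, priors, fixed)
    if model.ndim == 0:
        raise ValueError("no free parameters to sample")
    n_walkers = config.n_walkers or max(64, 4 * model.ndim)
    if n_walkers % 2:
        n_walkers += 1
    n_keep = config.n_iter - int(round(config.n_iter * config.warmup_frac))

    chains_u = []
    accept = []
    for c in range(config.n_chains):
        rs = np.random.RandomState((config.seed + 7919 * c) % (2**31))
        u0 = model.initial_walkers(n_walkers, rs)
        moves = [
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ]
        sampler = emcee.EnsembleSampler(
            n_walkers, model.ndim, model.log_prob, vectorize=True, moves=moves
        )
        state = emcee.State(u0, random_state=rs.get_state())
        sampler.run_mcmc(state, config.n_iter, progress=False)
        chain = sampler.get_chain(discard=config.n_iter - n_keep)  # (keep, nw, d)
        chains_u.append(chain)
        accept.append(float(np.mean(sampler.acceptance_fraction)))
    if np.mean(accept) < 0.05:
        warnings.warn(
            f"low mean acceptance fraction {np.mean(accept):.3f}; "
            "posterior may be poorly explored",
            stacklevel=2,
        )

    diagnostics = _diagnostics(model, chains_u)
    bad_rhat = diagnostics["rhat"] > config.rhat_max
    bad_ess = diagnostics["ess"] < config.ess_min
    if bad_rhat.any() or bad_ess.any():
        raise ConvergenceError(
            "MCMC failed convergence gates "
            f"(R-hat <= {config.rhat_max}, ESS >= {config.ess_min}):\n"
            f"{diagnostics[bad_rhat | bad_ess].to_string()}"
        )

    frames = []
    for c, chain in enumerate(chains_u):
        flat = chain.reshape(-1, model.ndim)  # step-major
        df = model.natural_frame(flat)
        df["chain"] = c
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    return PosteriorDraws(df, model.packed.mouse_ids, diagnostics)


def _diagnostics(model: _Model, chains_u: list[np.ndarray]) -> pd.DataFrame:
    """Split R-hat across ensembles (step-major) and ESS across walker chains."""
    names = model.free_names
    n_keep, n_walkers, ndim = chains_u[0].shape
    rows = []
    # (chain, draw) arrays: ensembles flattened step-major for R-hat;
    # individual walkers treated as chains for ESS.
    for j, name in enumerate(names):
        per_ens = np.stack([c[:, :, j].reshape(-1) for c in chains_u])
        rhat = float(az.rhat(az.convert_to_dataset(per_ens)).x)
        walkers = np.concatenate(
            [c[:, :, j].T for c in chains_u], axis=0
        )  # (chains*walkers, steps)
        ess = float(az.ess(az.convert_to_dataset(walkers)).x)
        rows.append({"param": name, "rhat": rhat, "ess": ess})
    return pd.DataFrame(rows).set_index("param")
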