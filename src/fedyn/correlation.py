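"""Spearman correlation between feed-efficiency draws and a phenotype.

The phenotype (e.g. hepatic triglycerides, hepatic glucose production rate)
is correlated with each posterior FE draw column in turn; the result is
summarised as the mean and median rho with its central 95% interval across
draws, together with the count of draws in which p < 0.05 — the same
stability-counting logic as the gene association stage.

Ties are handled with average ranks.  The p-value uses the t approximation
on rho with n - 2 degrees of freedom (standard at the cohort sizes this
pipeline targets); an exact permutation p-value by full enumeration is
available for n <= 8.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "spearman_rho", "repeated_correlation"]


@dataclass
class CorrelationResult:
    """Across-draw summary of a phenotype-FE Spearman analysis."""

    mean_rho: float
    median_rho: float
    lo95: float
    hi95: float
    n_significant: int
    n_draws: int
    n_pairs: int

    def to_frame(self, name: str = "phenotype") -> pd.DataFrame:
        return pd.DataFrame([{**{"phenotype": name}, **self.__dict__}])


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_rho(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    ``method="t"`` uses the t approximation with n - 2 df;
    ``method="exact"`` enumerates all n! orderings (n <= 8 only);
    ``method="auto"`` picks exact for n <= 8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if n < 6:
        warnings.warn(f"only {n} pairs: p-values are unreliable", stacklevel=2)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: Spearman rho is undefined")
    if method == "auto":
        method = "exact" if n <= 8 else "t"
    if method == "t":
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    if method == "exact":
        if n > 8:
            raise ValueError("exact enumeration supported only for n <= 8")
        rho_obs = _rank_rho(x, y)
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= abs(rho_obs) - 1e-12:
                count += 1
            total += 1
        return float(rho_obs), count / total
    raise ValueError(f"unknown method {method!r}")


def repeated_correlation(
    fe,
    phenotype,
    n_iter: int = 1000,
    alpha: float = 0.05,
    method: str = "t",
    seed: int = 0,
) -> CorrelationResult:
    """One Spearman test per FE draw column, with significance counting.

    ``fe`` is a FeDrawMatrix (rows already restricted to the phenotyped
    subgroup); ``phenotype`` aligns with its rows and may contain NaN,
    which drops the pair (the count of complete pairs is reported).
    """
    phenotype = np.asarray(phenotype, dtype=float)
    if len(phenotype) != fe.values.shape[0]:
        raise ValueError("phenotype must align 1:1 with FE matrix rows")
    complete = np.isfinite(phenotype)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} mice with missing phenotype", stacklevel=2
        )
    vals = fe.values[complete]
    pheno = phenotype[complete]
    if len(pheno) < 4:
        raise ValueError(f"only {len(pheno)} complete pairs; need at least 4")

    n_cols = vals.shape[1]
    if n_iter > n_cols:
        warnings.warn(
            f"n_iter={n_iter} exceeds {n_cols} draw columns; sampling with "
            "replacement",
            stacklevel=2,
        )
        cols = np.random.default_rng(seed).choice(n_cols, n_iter, replace=True)
    else:
        cols = np.arange(n_iter)
    rhos = np.empty(n_iter)
    n_sig = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n warning repeated per draw
        for j, c in enumerate(cols):
            rho, p = spearman_rho(vals[:, c], pheno, method=method)
            rhos[j] = rho
            n_sig += p < alpha
    lo, hi = np.quantile(rhos, [0.025, 0.975])
    return CorrelationResult(
        mean_rho=float(rhos.mean()),
        median_rho=float(np.median(rhos)),
        lo95=float(lo),
        hi95=float(hi),
        n_significant=int(n_sig),
        n_draws=n_iter,
        n_pairs=int(len(pheno)),
    )
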