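"""Synthetic study generator.

Emulates the statistical structure of a diet-induced-obesity mouse study:
four feeding-duration cohorts with longitudinal body-weight and food-intake
records, a 3'-tag RNA-seq count matrix on a sacrificed subset with batch
effects and a planted fraction of genes whose expression tracks feed
efficiency, gene-set collections enriched for the planted genes, and
phenotype vectors correlated with feed efficiency.  Every stream is driven
by one seed so a full study is reproducible byte-for-byte.

Default study conditions
------------------------
Cohorts of 20/19/20/46 mice sacrificed at days 30/60/90/180, with RNA-seq
on 9/10/8/16 of them; true intake hierarchy ``fi_i ~ N(2.5, 0.2)`` g/day,
``fe_max = 0.233``, ``w_max = 55.6`` g; baseline weight ``w0 ~ N(30, 2)`` g
(4-month-old males); weekly measurements; observation noise 0.8 g on weight
and 1.5 g on cumulative food.  Counts: 2000 genes, 5% carrying a true
association with feed efficiency, |log2 fold change| ~ U(0.5, 2) per
FE-percentage-point, NB dispersions ~ LogNormal(ln 0.15, 0.5), two 2-level
batch factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import CohortData, GrowthParams, Mouse, WeightTrajectory, _analytic_weight_raw, instantaneous_fe

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_counts",
    "simulate_gene_sets",
    "simulate_phenotype",
    "simulate_study",
]


@dataclass
class SimConfig:
    """Generative settings for a complete synthetic study."""

    # cohort structure
    n_mice_per_group: tuple = (20, 19, 20, 46)
    sacrifice_days: tuple = (30, 60, 90, 180)
    n_rnaseq_per_group: tuple = (9, 10, 8, 16)
    # growth-model truths
    fi_mean: float = 2.5          # g/day
    fi_sd: float = 0.5            # g/day, between-mouse intake spread
    fe_max: float = 0.233
    w_max: float = 55.6           # g
    w0_mean: float = 30.0         # g
    w0_sd: float = 2.0            # g
    sigma_w: float = 4.0          # g, weight residual scale (incl. model misfit)
    sigma_f: float = 5.0          # g, cumulative-food residual scale
    cadence_days: int = 7
    # count matrix
    n_genes: int = 2000
    planted_fraction: float = 0.05
    logfc_low: float = 0.5        # |log2FC| per FE-percentage-point
    logfc_high: float = 2.0
    dispersion_logmean: float = float(np.log(0.15))
    dispersion_logsd: float = 0.5
    base_logmean: float = 4.0     # natural-log baseline expression
    base_logsd: float = 1.5
    batch_effect_sd: float = 0.15  # natural-log scale, per factor level
    libsize_logsd: float = 0.2
    # gene sets
    n_sets: int = 50
    set_size_low: int = 10
    set_size_high: int = 100
    planted_set_overlap: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fe_max < 1.0):
            raise ValueError("fe_max must be in (0, 1)")
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise ValueError("planted_fraction must be in [0, 1]")
        for name in ("fi_mean", "fi_sd", "w_max", "w0_mean", "cadence_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.n_mice_per_group) != len(self.sacrifice_days):
            raise ValueError("group sizes and sacrifice days must align")
        if min(self.sacrifice_days) // self.cadence_days < 3:
            raise ValueError(
                "measurement cadence yields fewer than 3 observations "
                "before the earliest sacrifice day"
            )


@dataclass
class SimTruth:
    """Ground truth emitted alongside synthetic data."""

    mice: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: mouse_id, group, sacrifice_day, true_fi, w0, true_fe_at_sacrifice
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: gene_id, true_logfc (log2 per FE-pct, 0 if unplanted), dispersion, base_logmean
    planted_set: str | None = None
    phenotype_slope: float | None = None


def _group_labels(cfg: SimConfig) -> list[str]:
    return [f"{d}d" for d in cfg.sacrifice_days]


def simulate_cohort(cfg: SimConfig, seed: int | None = None) -> tuple[CohortData, SimTruth]:
    """Generate a cohort of noisy growth trajectories with known truth.

    Each mouse draws its intake from the population hierarchy, grows along
    the closed-form trajectory from its own baseline weight, and is
    observed every ``cadence_days`` days up to its sacrifice day with
    independent normal measurement noise on weight and cumulative food
    (day-0 rows are noise-free initial conditions).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mice: list[Mouse] = []
    rows = []
    for g, (n, sac) in enumerate(zip(cfg.n_mice_per_group, cfg.sacrifice_days)):
        label = _group_labels(cfg)[g]
        for i in range(n):
            mid = f"{label}_m{i + 1:02d}"
            fi = -1.0
            while fi <= 0:
                fi = rng.normal(cfg.fi_mean, cfg.fi_sd)
            w0 = -1.0
            while w0 <= 0:
                w0 = rng.normal(cfg.w0_mean, cfg.w0_sd)
            days = np.arange(0, sac + 1, cfg.cadence_days, dtype=float)
            w_true = _analytic_weight_raw(fi, cfg.fe_max, cfg.w_max, w0, days)
            f_true = fi * days
            w_obs = w_true + rng.normal(0.0, cfg.sigma_w, len(days))
            f_obs = f_true + rng.normal(0.0, cfg.sigma_f, len(days))
            w_obs[0], f_obs[0] = w0, 0.0
            f_obs = np.maximum.accumulate(f_obs)  # keep cumulative food monotone
            traj = WeightTrajectory(days=days, weights=w_obs, cumfood=f_obs)
            mice.append(Mouse(mid, traj, float(sac), label))
            p = GrowthParams(fi=fi, fe_max=cfg.fe_max, w_max=cfg.w_max)
            w_sac = _analytic_weight_raw(fi, cfg.fe_max, cfg.w_max, w0, sac)
            rows.append(
                {
                    "mouse_id": mid,
                    "group": label,
                    "sacrifice_day": float(sac),
                    "true_fi": fi,
                    "w0": w0,
                    "true_fe_at_sacrifice": instantaneous_fe(p, float(w_sac)),
                }
            )
    truth = SimTruth(mice=pd.DataFrame(rows))
    return CohortData(mice=mice), truth


def rnaseq_subset(cfg: SimConfig, truth: SimTruth, seed: int | None = None) -> pd.DataFrame:
    """Pick the per-group subset of mice that 'went to RNA-seq' (with metadata)."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    picked = []
    for label, k in zip(_group_labels(cfg), cfg.n_rnaseq_per_group):
        grp = truth.mice[truth.mice["group"] == label]
        k = min(k, len(grp))
        idx = rng.choice(len(grp), size=k, replace=False)
        picked.append(grp.iloc[np.sort(idx)])
    meta = pd.concat(picked, ignore_index=True).copy()
    # two 2-level technical batch factors: isolation day and reagent lot
    meta["batch_day"] = rng.integers(0, 2, len(meta)).astype(str)
    meta["batch_reagent"] = rng.integers(0, 2, len(meta)).astype(str)
    return meta


def simulate_counts(
    true_fe: np.ndarray,
    cfg: SimConfig,
    batch: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate an NB count matrix (genes x samples) linked to feed efficiency.

    Per gene g and sample j the mean is
    ``log mu = b0_g + ln2 * b1_g * FEpct_j + batch terms + log libsize_j``
    with ``b1_g`` (the planted log2 fold change per FE-percentage-point)
    nonzero only for the planted fraction; counts are negative binomial with
    per-gene dispersion.  Returns the counts and the per-gene truth.
    """
    true_fe = np.asarray(true_fe, dtype=float)
    if not np.all(np.isfinite(true_fe)):
        raise ValueError("true_fe must be finite")
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 2)
    n = len(true_fe)
    G = cfg.n_genes
    fepct = true_fe * 100.0

    n_planted = int(round(cfg.planted_fraction * G))
    b1 = np.zeros(G)
    if n_planted:
        sign = rng.choice([-1.0, 1.0], n_planted)
        b1[:n_planted] = sign * rng.uniform(cfg.logfc_low, cfg.logfc_high, n_planted)
    b0 = rng.normal(cfg.base_logmean, cfg.base_logsd, G)
    disp = rng.lognormal(cfg.dispersion_logmean, cfg.dispersion_logsd, G)
    libsize_factor = rng.lognormal(0.0, cfg.libsize_logsd, n)

    eta = b0[:, None] + np.log(2.0) * b1[:, None] * (fepct - fepct.mean())[None, :]
    if batch is not None:
        for col in batch.columns:
            levels = pd.Categorical(batch[col])
            eff = rng.normal(0.0, cfg.batch_effect_sd, (G, len(levels.categories)))
            eff -= eff.mean(axis=1, keepdims=True)
            eta += eff[:, levels.codes]
    eta += np.log(libsize_factor)[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    # NB via Poisson-gamma mixture
    shape = 1.0 / disp
    lam = mu * rng.gamma(shape[:, None], 1.0, size=mu.shape) * disp[:, None]
    counts = rng.poisson(lam)

    gene_ids = [f"gene{g + 1:05d}" for g in range(G)]
    counts_df = pd.DataFrame(counts, index=gene_ids)
    truth = SimTruth(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "true_logfc": b1,
                "dispersion": disp,
                "base_logmean": b0,
            }
        )
    )
    return counts_df, truth


def simulate_gene_sets(
    gene_ids,
    gene_truth: pd.DataFrame,
    cfg: SimConfig,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Gene-set collection with one set enriched for the planted genes.

    ``set_planted`` draws ``planted_set_overlap`` of its members from genes
    with a true association; the remaining sets are uniform random draws
    from all genes.
    """
    if cfg.n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 3)
    gene_ids = list(gene_ids)
    planted = list(gene_truth.loc[gene_truth["true_logfc"] != 0, "gene_id"])
    sets: dict[str, list[str]] = {}

    size = int(rng.integers(cfg.set_size_low, cfg.set_size_high + 1))
    n_from_planted = int(round(cfg.planted_set_overlap * size))
    if n_from_planted > len(planted):
        warnings.warn(
            f"only {len(planted)} planted genes available; shrinking the "
            f"planted set from {size} members",
            stacklevel=2,
        )
        n_from_planted = len(planted)
        size = min(size, int(np.ceil(n_from_planted / max(cfg.planted_set_overlap, 1e-9))))
    members = list(rng.choice(planted, n_from_planted, replace=False))
    others = [g for g in gene_ids if g not in set(members)]
    members += list(rng.choice(others, size - n_from_planted, replace=False))
    sets["set_planted"] = sorted(members)

    for s in range(1, cfg.n_sets):
        size = int(rng.integers(cfg.set_size_low, cfg.set_size_high + 1))
        sets[f"set_rand{s:03d}"] = sorted(rng.choice(gene_ids, size, replace=False))
    return sets


def simulate_phenotype(
    true_fe,
    slope: float,
    noise_sd: float,
    seed: int = 0,
    intercept: float = 0.0,
) -> np.ndarray:
    """Phenotype as a linear-in-FE signal plus normal noise.

    ``slope`` is in phenotype units per FE-percentage-point; ``slope=0``
    gives the independence null.
    """
    true_fe = np.asarray(true_fe, dtype=float)
    if not np.all(np.isfinite(true_fe)):
        raise ValueError("true_fe must be finite")
    rng = np.random.default_rng(seed)
    return intercept + slope * true_fe * 100.0 + rng.normal(0.0, noise_sd, len(true_fe))


@dataclass
class SyntheticStudy:
    """Bundle of all artifacts for one simulated study."""

    cohort: CohortData
    cohort_truth: SimTruth
    rnaseq_meta: pd.DataFrame
    counts: pd.DataFrame
    gene_truth: SimTruth
    gene_sets: dict[str, list[str]]


def simulate_study(cfg: SimConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Generate trajectories, RNA-seq subset, counts and gene sets in one call."""
    cfg = cfg or SimConfig()
    cohort, truth = simulate_cohort(cfg, seed=seed)
    meta = rnaseq_subset(cfg, truth, seed=seed)
    counts, gtruth = simulate_counts(
        meta["true_fe_at_sacrifice"].to_numpy(),
        cfg,
        batch=meta[["batch_day", "batch_reagent"]],
        seed=seed,
    )
    counts.columns = list(meta["mouse_id"])
    sets = simulate_gene_sets(counts.index, gtruth.genes, cfg, seed=seed)
    return SyntheticStudy(cohort, truth, meta, counts, gtruth, sets)
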