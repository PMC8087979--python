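"""Readers, writers and run configuration for the pipeline's artifacts.

All tabular artifacts are UTF-8, tab-separated with a mandatory header row;
missing values are written as ``NA``.  Gene identifiers are opaque strings.
Count matrices are supported both as genes x samples TSV and as MatrixMarket
(MTX) with separate gene/sample id files.  Gene sets use GMT (set name,
description, tab-separated members).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .fitting import MCMCConfig, PriorSpec
from .growth import CohortData, Mouse, WeightTrajectory

__all__ = [
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "read_counts",
    "write_counts",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_gmt",
    "write_gmt",
    "read_phenotypes",
    "write_phenotypes",
    "config_hash",
    "write_run_log",
]

logger = logging.getLogger("fedyn")

_NA = "NA"


@dataclass
class RunConfig:
    """Structured configuration for a pipeline run."""

    cohort_path: str | None = None
    counts_path: str | None = None
    gene_sets_path: str | None = None
    phenotype_path: str | None = None
    out_dir: str = "."
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    n_draws: int = 1000
    alpha: float = 0.05
    stability_fraction: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.stability_fraction <= 1.0):
            raise ValueError("stability_fraction must be in (0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        priors = PriorSpec(**raw.pop("priors", {}))
        mcmc = MCMCConfig(**raw.pop("mcmc", {}))
        return cls(priors=priors, mcmc=mcmc, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a run configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_run_log(out_dir, stage: str, cfg: RunConfig, extra: dict | None = None) -> Path:
    """Write a per-stage JSON log with seed, config hash and diagnostics."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "stage": stage,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        **(extra or {}),
    }
    path = out_dir / f"{stage}.log.json"
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def read_cohort(path) -> CohortData:
    """Read a longitudinal cohort table.

    Required columns: ``mouse_id``, ``day``, ``body_weight_g`` and one of
    ``cum_food_g`` (cumulative) or ``food_intake_g`` (per-interval, summed
    into cumulative food).  Optional: ``group`` and ``sacrifice_day``
    (constant per mouse; defaults: ``"all"`` and the last observed day).
    Every mouse must have a day-0 weight.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, na_values=[_NA])
    required = {"mouse_id", "day", "body_weight_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    if "cum_food_g" not in df.columns and "food_intake_g" not in df.columns:
        raise ValueError("cohort table needs cum_food_g or food_intake_g")
    if df.duplicated(subset=["mouse_id", "day"]).any():
        dup = df[df.duplicated(subset=["mouse_id", "day"], keep=False)]
        raise ValueError(
            f"duplicated (mouse_id, day) rows: {dup[['mouse_id', 'day']].to_dict('records')}"
        )
    mice = []
    for mid, sub in df.groupby("mouse_id", sort=False):
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy(dtype=float)
        if days[0] != 0 or not np.isfinite(sub["body_weight_g"].iloc[0]):
            raise ValueError(f"mouse {mid}: missing day-0 body weight")
        if "cum_food_g" in sub.columns and sub["cum_food_g"].notna().any():
            cumfood = sub["cum_food_g"].to_numpy(dtype=float)
        else:
            intake = sub["food_intake_g"].fillna(0.0).to_numpy(dtype=float)
            cumfood = np.cumsum(intake)
            if days[0] == 0:
                cumfood -= cumfood[0]
        traj = WeightTrajectory(
            days=days,
            weights=sub["body_weight_g"].to_numpy(dtype=float),
            cumfood=cumfood,
        )
        group = str(sub["group"].iloc[0]) if "group" in sub.columns else "all"
        sac = (
            float(sub["sacrifice_day"].iloc[0])
            if "sacrifice_day" in sub.columns
            else float(days[-1])
        )
        mice.append(Mouse(str(mid), traj, sac, group))
    return CohortData(mice=mice)


def write_cohort(cohort: CohortData, path) -> None:
    rows = []
    for m in cohort:
        t = m.trajectory
        for d, w, f in zip(t.days, t.weights, t.cumfood):
            rows.append(
                {
                    "mouse_id": m.mouse_id,
                    "day": d,
                    "body_weight_g": w,
                    "cum_food_g": f,
                    "group": m.group_label,
                    "sacrifice_day": m.sacrifice_day,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=_NA)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id", na_rep=_NA)


def read_counts_mtx(mtx_path, genes_path, samples_path) -> pd.DataFrame:
    """MatrixMarket counts with one-id-per-line gene and sample files."""
    mat = scipy.io.mmread(mtx_path)
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if arr.shape != (len(genes), len(samples)):
        raise ValueError(
            f"matrix shape {arr.shape} does not match {len(genes)} genes x "
            f"{len(samples)} samples"
        )
    return pd.DataFrame(arr.astype(np.int64), index=genes, columns=samples)


def write_counts_mtx(counts: pd.DataFrame, mtx_path, genes_path, samples_path) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.csr_matrix(counts.to_numpy()))
    Path(genes_path).write_text("\n".join(map(str, counts.index)) + "\n")
    Path(samples_path).write_text("\n".join(map(str, counts.columns)) + "\n")


# ---------------------------------------------------------------------------
# gene sets and phenotypes
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "fedyn") -> None:
    lines = [
        "\t".join([name, description] + list(members))
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_phenotypes(path) -> pd.DataFrame:
    """Long-format phenotype TSV: mouse_id, phenotype_name, value."""
    df = pd.read_csv(path, sep="\t", na_values=[_NA])
    required = {"mouse_id", "phenotype_name", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table is missing columns: {sorted(missing)}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)
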