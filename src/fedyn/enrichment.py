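"""Hypergeometric gene-set over-representation with draw-stability counting.

Within each FE draw, the differentially expressed genes (FDR < alpha) are
split by the sign of their fold change and each direction is tested for
over-representation in every gene set by the hypergeometric upper tail,
with BH correction across sets within the draw and direction.  Counting
the draws in which a set stays below the FDR threshold gives the same
stability semantics as the gene-level analysis.

The gene universe is the post-filter gene list (the genes actually
assessed), not the genome; set members outside the universe are dropped
(and counted) before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .association import (
    bh_fdr,
    build_design,
    estimate_dispersion,
    nb_association_one_draw,
    normalized_offsets,
    _draw_columns,
)

__all__ = [
    "GeneSetCollection",
    "hypergeom_test",
    "enrich_per_draw",
    "pathway_stability",
]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a gene universe.

    ``dropped`` records, per set, how many members fell outside the
    universe and were removed.
    """

    sets: dict[str, list[str]]
    universe: list[str]
    dropped: dict[str, int] = field(default_factory=dict)

    @classmethod
    def restrict(cls, sets: dict[str, list[str]], universe) -> "GeneSetCollection":
        universe = list(universe)
        uni = set(universe)
        restricted, dropped = {}, {}
        for name, members in sets.items():
            inside = [g for g in members if g in uni]
            dropped[name] = len(members) - len(inside)
            restricted[name] = inside
        return cls(sets=restricted, universe=universe, dropped=dropped)

    def __len__(self) -> int:
        return len(self.sets)


def hypergeom_test(overlap: int, set_size: int, n_de: int, universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    Drawing ``n_de`` genes without replacement from a universe of
    ``universe`` genes of which ``set_size`` belong to the set: the
    probability of an overlap at least as large as observed.
    """
    if not (0 <= overlap <= min(set_size, n_de)):
        raise ValueError(
            f"impossible configuration: overlap={overlap}, set={set_size}, "
            f"n_de={n_de}"
        )
    if set_size > universe or n_de > universe:
        raise ValueError("set size and DE count cannot exceed the universe")
    return float(hypergeom.sf(overlap - 1, universe, set_size, n_de))


def enrich_per_draw(
    de_up: list[str],
    de_down: list[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Directional over-representation of one draw's DE gene lists.

    Up- and down-regulated lists are tested separately against every set;
    BH correction is applied across sets within each direction.  Empty DE
    lists yield p = 1 everywhere.
    """
    N = len(collection.universe)
    uni = set(collection.universe)
    rows = []
    for direction, de in (("up", de_up), ("down", de_down)):
        de_in = set(de) & uni
        n = len(de_in)
        for name, members in collection.sets.items():
            K = len(members)
            k = len(de_in.intersection(members))
            p = 1.0 if n == 0 else hypergeom_test(k, K, n, N)
            rows.append(
                {
                    "set": name,
                    "direction": direction,
                    "overlap": k,
                    "set_size": K,
                    "n_de": n,
                    "universe": N,
                    "pvalue": p,
                }
            )
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for direction in ("up", "down"):
        mask = out["direction"] == direction
        out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "pvalue"].to_numpy())
    return out


def pathway_stability(
    counts: pd.DataFrame,
    fe,
    batches: pd.DataFrame | None,
    sets: dict[str, list[str]],
    n_iter: int = 1000,
    alpha: float = 0.05,
    stability_fraction: float = 0.95,
    dispersion_mode: str = "once",
    prior_df: float = 10.0,
    normalization: str = "tmm",
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full DE -> enrichment chain once per FE draw and count hits.

    Returns one row per (set, direction) with the number of draws in which
    the set's BH-FDR fell below ``alpha``, plus its median p-value and FDR.
    """
    sample_ids = list(counts.columns)
    if sample_ids != list(fe.mouse_ids):
        fe = fe.rows_for_mice(sample_ids)
    collection = GeneSetCollection.restrict(sets, counts.index)
    n_dropped = sum(collection.dropped.values())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} set members outside the assessed-gene universe "
            "were dropped",
            stacklevel=2,
        )
    Y = counts.to_numpy(dtype=float)
    offset = normalized_offsets(Y, normalization)
    fepct_all = fe.values * 100.0
    cols = _draw_columns(fe.n_draws, n_iter, seed)
    if dispersion_mode == "once":
        disp = estimate_dispersion(
            Y, build_design(fepct_all.mean(axis=1), batches), offset, prior_df=prior_df
        )
    elif dispersion_mode != "per-draw":
        raise ValueError("dispersion_mode must be 'once' or 'per-draw'")

    genes = np.asarray(counts.index)
    acc: dict[tuple[str, str], list] = {}
    for j, c in enumerate(cols):
        fepct = fepct_all[:, c]
        if dispersion_mode == "per-draw":
            disp = estimate_dispersion(Y, build_design(fepct, batches), offset, prior_df=prior_df)
        res = nb_association_one_draw(Y, fepct, batches, offset, disp, alpha=alpha)
        sig = (res["fdr"].to_numpy() < alpha) & res["converged"].to_numpy()
        lfc = res["logfc"].to_numpy()
        de_up = list(genes[sig & (lfc > 0)])
        de_down = list(genes[sig & (lfc < 0)])
        enr = enrich_per_draw(de_up, de_down, collection)
        for _, row in enr.iterrows():
            key = (row["set"], row["direction"])
            acc.setdefault(key, []).append((row["pvalue"], row["fdr"]))
    rows = []
    for (name, direction), vals in acc.items():
        ps = np.array([v[0] for v in vals])
        fdrs = np.array([v[1] for v in vals])
        n_sig = int(np.sum(fdrs < alpha))
        rows.append(
            {
                "set": name,
                "direction": direction,
                "n_significant": n_sig,
                "n_iter": n_iter,
                "median_pvalue": float(np.median(ps)),
                "median_FDR": float(np.median(fdrs)),
                "declared_associated": n_sig >= int(np.ceil(stability_fraction * n_iter)),
            }
        )
    return pd.DataFrame(rows)
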