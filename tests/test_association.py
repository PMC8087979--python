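"""NB GLM engine, dispersion estimation, LRT, BH-FDR, stability counting."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from fedyn.association import (
    StabilityResult,
    bh_fdr,
    build_design,
    estimate_dispersion,
    filter_genes,
    fit_nb_glm,
    logfc_to_percent,
    lrt_pvalue,
    nb_association_one_draw,
    normalized_offsets,
    stability_analysis,
    tmm_norm_factors,
    _nb_loglik,
)
from fedyn.propagate import FeDrawMatrix


class TestFilterGenes:
    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame([[0, 0, 0], [1, 2, 3]], index=["z", "g"])
        assert list(filter_genes(counts, 1).index) == ["g"]

    def test_zero_threshold_is_identity(self):
        counts = pd.DataFrame([[0, 0, 0], [1, 2, 3]], index=["z", "g"])
        assert list(filter_genes(counts, 0).index) == ["z", "g"]

    def test_matches_brute_force_scan(self, rng):
        counts = pd.DataFrame(
            (rng.random((100, 12)) > 0.4) * rng.integers(1, 50, (100, 12)),
            index=[f"g{i}" for i in range(100)],
        )
        thr = 9
        kept = filter_genes(counts, thr)
        expected = [
            g for g in counts.index
            if sum(1 for v in counts.loc[g] if v > 0) >= thr
        ]
        assert list(kept.index) == expected

    def test_default_threshold_mirrors_40_of_43(self):
        assert math.ceil(0.93 * 43) == 40  # the documented default ratio

    def test_empty_result_is_an_error(self):
        counts = pd.DataFrame([[0, 1, 0]], index=["g"])
        with pytest.raises(ValueError, match="no genes survive"):
            filter_genes(counts, 3)


class TestFitNbGlm:
    def test_poisson_intercept_closed_form(self):
        y = np.array([3, 7, 4, 9, 5, 8], dtype=float)
        off = np.full(6, 0.7)
        fit = fit_nb_glm(y, np.ones((6, 1)), off, dispersion=0.0)
        assert fit.coef[0] == pytest.approx(np.log(y.mean()) - 0.7, abs=1e-10)

    def test_constant_response_zero_slope(self):
        y = np.full(8, 20.0)
        x = np.linspace(-1, 1, 8)
        fit = fit_nb_glm(y, np.column_stack([np.ones(8), x]), None, dispersion=0.2)
        assert abs(fit.coef[1]) < 1e-8

    def test_nb_intercept_matches_scalar_likelihood_scan(self):
        """Batched IRLS agrees with direct 1-D likelihood maximisation."""
        y = np.array([5, 11, 3, 9, 14, 6], dtype=float)
        disp = 0.3

        def neg_ll(b0):
            mu = np.full(6, np.exp(b0))
            return -_nb_loglik(y[None, :], mu[None, :], np.array([disp]))[0]

        opt = minimize_scalar(neg_ll, bounds=(0.0, 5.0), method="bounded",
                              options={"xatol": 1e-10})
        fit = fit_nb_glm(y, np.ones((6, 1)), None, dispersion=disp)
        assert fit.coef[0] == pytest.approx(opt.x, abs=1e-6)

    @pytest.mark.parametrize("dispersion", [0.0, 0.4])
    def test_matches_statsmodels_glm(self, dispersion, rng):
        """Independent implementation check, Poisson and NB paths."""
        n = 16
        x = rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        off = np.log(rng.uniform(0.5, 2.0, n))
        mu = np.exp(2.0 + 0.6 * x + off)
        if dispersion == 0.0:
            y = rng.poisson(mu).astype(float)
            fam = sm.families.Poisson()
            tol = 1e-8
        else:
            y = rng.negative_binomial(1 / dispersion, 1 / (1 + dispersion * mu)).astype(float)
            fam = sm.families.NegativeBinomial(alpha=dispersion)
            tol = 1e-6
        ours = fit_nb_glm(y, X, off, dispersion)
        ref = sm.GLM(y, X, family=fam, offset=off).fit()
        assert ours.coef == pytest.approx(np.asarray(ref.params), abs=tol)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_nb_glm(np.arange(6.0), X, None, 0.0)


class TestEstimateDispersion:
    def test_poisson_counts_estimate_near_zero(self, rng):
        n, G = 20, 500
        mu = np.exp(rng.normal(4, 1, G))[:, None] * np.ones(n)
        Y = rng.poisson(mu).astype(float)
        d = estimate_dispersion(Y, np.ones((n, 1)), np.zeros(n))
        assert np.median(d) < 0.05

    def test_known_dispersion_recovered(self, rng):
        n, G, disp = 16, 2000, 0.4
        mu = np.exp(rng.normal(4, 1, G))[:, None] * np.ones(n)
        Y = rng.negative_binomial(1 / disp, 1 / (1 + disp * mu)).astype(float)
        d = estimate_dispersion(Y, np.ones((n, 1)), np.zeros(n))
        assert 0.25 <= np.median(d) <= 0.55

    def test_constant_gene_gets_zero(self):
        Y = np.vstack([np.full(10, 7.0), np.arange(10.0) + 1])
        d = estimate_dispersion(Y, np.ones((10, 1)), np.zeros(10))
        assert d[0] == 0.0


class TestLrtAndFdr:
    def test_identical_likelihoods_give_p_one(self):
        assert lrt_pvalue(-10.0, -10.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("stat,p", [(3.841, 0.05), (6.635, 0.01)])
    def test_chi_square_reference_points(self, stat, p):
        assert lrt_pvalue(stat / 2, 0.0) == pytest.approx(p, abs=5e-4)

    def test_negative_statistic_is_an_error(self):
        with pytest.raises(ValueError, match="pathology"):
            lrt_pvalue(-1.0, 0.0)

    def test_bh_equal_pvalues(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_bh_hand_worked_vectors(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_fdr([0.001, 0.5]) == pytest.approx([0.002, 0.5])

    def test_bh_nan_propagates_excluded_from_m(self):
        with pytest.warns(UserWarning, match="NaN"):
            out = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(0.02)  # m=2, rank 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_bh_matches_sort_based_oracle_and_is_order_invariant(self, pvals):
        p = np.array(pvals)
        ours = bh_fdr(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        oracle = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            oracle[i] = running
        assert ours == pytest.approx(oracle, abs=1e-12)
        perm = np.random.RandomState(0).permutation(m)
        assert bh_fdr(p[perm]) == pytest.approx(ours[perm], abs=1e-12)
        assert np.all(ours >= p - 1e-12)


class TestLogfcToPercent:
    @pytest.mark.parametrize(
        "logfc,pct",
        [(0.0, 0.0), (1.0, 100.0), (-1.0, -50.0)],
    )
    def test_reference_points(self, logfc, pct):
        assert logfc_to_percent(logfc) == pytest.approx(pct)

    def test_reported_decreases_round_to_integers(self):
        # the five internally consistent fold-change -> percent statements
        printed = {-0.441: 26, -0.475: 28, -0.578: 33, -0.706: 39, -0.856: 45}
        for logfc, pct in printed.items():
            assert round(-logfc_to_percent(logfc)) == pct

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            logfc_to_percent(np.inf)


class TestTmm:
    def test_factors_have_unit_geometric_mean(self, rng):
        Y = rng.poisson(50, (300, 8)).astype(float)
        f = tmm_norm_factors(Y)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_composition_bias_corrected(self, rng):
        """A few huge genes in one sample should not distort the offsets."""
        Y = rng.poisson(100, (400, 6)).astype(float)
        Y[:5, 0] *= 200  # 5 extreme genes dominate sample 0's column sum
        off_tmm = normalized_offsets(Y, "tmm")
        off_raw = normalized_offsets(Y, "none")
        # raw offsets inflate sample 0; TMM restores it toward the others
        assert off_raw[0] - off_raw[1:].mean() > 0.4
        assert abs(off_tmm[0] - off_tmm[1:].mean()) < 0.1


def _null_counts(rng, G=400, n=16, disp=0.3):
    mu = np.exp(rng.normal(4, 1, G))[:, None] * rng.uniform(0.8, 1.2, n)[None, :]
    return rng.negative_binomial(1 / disp, 1 / (1 + disp * mu)).astype(float)


class TestStability:
    def _fe_matrix(self, fepct, n_draws, jitter, rng):
        vals = (fepct[:, None] + rng.normal(0, jitter, (len(fepct), n_draws))) / 100.0
        vals = np.clip(vals, 1e-4, 0.5)
        meta = pd.DataFrame(
            {"mouse_id": [f"m{i}" for i in range(len(fepct))],
             "group": "g", "sacrifice_day": 30.0}
        )
        return FeDrawMatrix(vals, meta)

    def test_identical_draws_give_all_or_nothing(self):
        rng = np.random.default_rng(21)
        Y = _null_counts(rng, G=150)
        fepct = rng.normal(5, 1, 16)
        fe = self._fe_matrix(fepct, 20, jitter=0.0, rng=rng)
        counts = pd.DataFrame(Y, index=[f"g{i}" for i in range(150)],
                              columns=fe.mouse_ids)
        res = stability_analysis(counts, fe, None, n_iter=20, seed=1)
        assert set(res.table["n_significant"]).issubset({0, 20})

    def test_null_simulation_declares_nothing(self):
        rng = np.random.default_rng(22)
        Y = _null_counts(rng, G=400)
        fepct = rng.normal(5, 1, 16)
        fe = self._fe_matrix(fepct, 40, jitter=0.1, rng=rng)
        counts = pd.DataFrame(Y, index=[f"g{i}" for i in range(400)],
                              columns=fe.mouse_ids)
        res = stability_analysis(counts, fe, None, n_iter=40, seed=2)
        assert int(res.table["declared_associated"].sum()) <= 1

    def test_planted_strong_gene_is_declared(self):
        rng = np.random.default_rng(23)
        n = 16
        Y = _null_counts(rng, G=300, n=n, disp=0.2)
        fepct = rng.normal(7, 1, n)
        # plant gene 0: logFC 1.5 (log2) per FE-percentage-point, low dispersion
        mu0 = 200 * 2 ** (1.5 * (fepct - fepct.mean()))
        Y[0] = rng.negative_binomial(1 / 0.05, 1 / (1 + 0.05 * mu0))
        fe = self._fe_matrix(fepct, 40, jitter=0.1, rng=rng)
        counts = pd.DataFrame(Y, index=[f"g{i}" for i in range(300)],
                              columns=fe.mouse_ids)
        res = stability_analysis(counts, fe, None, n_iter=40, seed=3)
        row = res.table.set_index("gene_id").loc["g0"]
        assert bool(row["declared_associated"])
        assert row["median_logFC"] == pytest.approx(1.5, rel=0.2)

    def test_type_one_error_calibrated(self):
        """Under an NB null the per-draw LRT rejects ~5% of genes."""
        rng = np.random.default_rng(24)
        Y = _null_counts(rng, G=2000, n=16, disp=0.4)
        fepct = rng.normal(5, 1, 16)
        X = build_design(fepct, None)
        off = normalized_offsets(Y)
        disp = estimate_dispersion(Y, X, off)
        res = nb_association_one_draw(Y, fepct, None, off, disp)
        frac = float(np.mean(res["pvalue"].dropna() < 0.05))
        assert 0.03 <= frac <= 0.07
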