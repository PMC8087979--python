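# fedyn

Hierarchical dynamic modelling of feed efficiency in diet-fed mice, with
posterior uncertainty propagated through the downstream transcriptome and
phenotype association analyses.

## The problem

Feed efficiency (FE) — body-weight gain per gram of food eaten — declines
as an animal matures, so a single number per mouse is ill-defined: what is
needed is FE *at the moment a tissue was sampled*, with honest uncertainty.
`fedyn` addresses this for longitudinal mouse cohorts on a high-fat
high-cholesterol diet.  It couples the two observable states, cumulative
food consumption *F* and body weight *W*:

    dF/dt = FI
    dW/dt = FE_max (1 − W/W_max) FI,       FE(t) = FE_max (1 − W(t)/W_max)

with per-mouse intake rates FI_i ~ Normal(fi_mean, fi_sd) and shared
FE_max (maximum conversion fraction) and W_max (asymptotic weight, g).
The model is fitted by MCMC (ensemble sampler, hard R-hat/ESS gates);
each animal's FE at its sacrifice day is then recomputed once per
posterior draw.  Because FE is an *uncertain* covariate, every downstream
association is repeated across draws and summarised by a stability count:

* **genes** — negative-binomial GLM per gene (log link, TMM-corrected
  library-size offsets, batch adjustment), likelihood-ratio test of the FE
  coefficient, Benjamini–Hochberg FDR within each draw; a gene is declared
  associated when FDR < 0.05 in ≥ 95% of draws;
* **gene sets** — hypergeometric over-representation of each draw's up- and
  down-regulated lists, with the same counting;
* **phenotypes** — Spearman correlation per draw with p < 0.05 counting.

A first-class synthetic-data generator produces complete studies
(trajectories, counts with planted FE-linked genes and batch effects, gene
sets, phenotypes) with known ground truth, so the whole pipeline is
testable end to end without any external data.

## Worked example

```python
from fedyn.simulate import SimConfig, simulate_study
from fedyn.fitting import sample_posterior, MCMCConfig, summarize_posterior
from fedyn.propagate import fe_draw_matrix, group_fe_summary
from fedyn.growth import DEFAULT_ENERGY_DENSITY

cfg = SimConfig(n_mice_per_group=(10, 10), sacrifice_days=(30, 90),
                n_rnaseq_per_group=(6, 6), n_genes=500, seed=7)
study = simulate_study(cfg)
draws = sample_posterior(study.cohort, config=MCMCConfig(n_chains=2, n_iter=1500, seed=8))
summary = summarize_posterior(draws, energy_density=DEFAULT_ENERGY_DENSITY)
print(summary[summary.param.isin(["fe_max", "w_max", "fi_mean_kcal_per_day"])].round(3))
fe = fe_draw_matrix(draws, study.cohort, n_draws=500, seed=9)
print(group_fe_summary(fe).round(4))
```

prints

```
               param   mean   lo95   hi95
              fe_max  0.191  0.147  0.241
               w_max 62.501 53.854 75.482
fi_mean_kcal_per_day 12.948 12.405 13.481
group  n_mice  mean_fe   lo95   hi95
  30d      10   0.0779 0.0736 0.0819
  90d      10   0.0487 0.0394 0.0582
```

Reading this: the population posterior puts the maximum feed efficiency
near 0.19 (the generating truth, 0.233, sits inside the credible
interval — with data only to day 90 the FE_max/W_max pair is identified
mainly through its product, so intervals are wide), intake is
12.9 kcal/day (2.49 g/day × 5.21 kcal/g), and the group-average FE at
sacrifice falls from 7.8% at one month to 4.9% at three months: animals
convert food to mass ever less efficiently as they approach W_max.  The
`fe` matrix holds 500 posterior FE values per mouse; feeding it to
`fedyn.association.stability_analysis` with the study's counts runs the
draw-by-draw gene screen.

The same pipeline is scriptable from a shell:

```bash
fedyn simulate --seed 1 --out study/
fedyn fit      --cohort study/cohort.tsv --out study/ --seed 2
fedyn fe       --posterior study/posterior.tsv --cohort study/cohort.tsv --out study/
fedyn assoc    --counts study/counts.tsv --fe-draws study/fe_draws.tsv \
               --meta study/rnaseq_meta.tsv --out study/
fedyn correlate --fe-draws study/fe_draws.tsv --phenotypes study/phenotypes.tsv --out study/
```

Every stage writes tab-separated artifacts plus a JSON log carrying the
seed, a config hash and convergence diagnostics.

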