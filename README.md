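# panelflux

Predicting cancer proliferation rates from gene expression and turning them
into per-sample metabolic flux estimates.

Large cancer cohorts carry rich expression data but almost never direct
measurements of how fast the tumors proliferate, while cancer cell-line
panels have measured doubling times but limited clinical relevance.
`panelflux` bridges the two: it learns a proliferation-rate predictor on a
cell-line panel, transfers it to a patient cohort through a cross-platform
expression correction, and uses the predicted rates to constrain
genome-scale metabolic models — yielding per-sample flux distributions and
pathway-level statements about which metabolic processes are specific to a
cancer panel. It is aimed at computational/systems biologists who want a
tested, fully synthetic-data-verifiable implementation of this strategy.

## The method in brief

1. **Harmonization.** Cohort mean log2 expression is modeled as
   `e_cohort = α·e_ref + β`; `α` is the zero-intercept slope between matched
   dual-platform samples (`α = Σxy/Σx²`), `β` the same-platform mean
   difference between the datasets. Genes whose corrected means agree within
   1 log2 unit (a corrected 2-fold band) on both comparisons are kept.
2. **Prediction.** An L1-penalized (LASSO) regression of rates on gene
   expression selects a small gene set; a second L1 model on all pairwise
   products and squares of those genes' log2 values (for k genes,
   k(k−1)/2 + k features) captures interaction structure; coefficients at or
   below the 25% quantile of the non-zero absolute coefficients are dropped
   and the model refit. Generalization is reported by leave-one-out
   cross-validation with mse, rmse, mae, mre and R².
3. **Flux analysis.** Each sample's flux distribution is the parsimonious
   FBA solution — minimize Σᵢ vᵢ subject to S·v = 0, v ≥ 0 and the growth
   flux fixed to the predicted rate v_p = r_p — on its panel's
   reversible-split metabolic model. Samples with non-positive predicted
   rates are skipped; only fluxes non-zero in at least one sample are kept.
4. **Panel statistics.** Each flux's panel specificity is
   `s = log2 μ_in − log2 μ_out`; all (panel, flux) scores are ranked by |s|
   and a weighted running-sum enrichment score per pathway is normalized by
   100 pathway-label permutations (NES = ES / mean permuted ES) with
   positive/negative-tail empirical p-values. NES > 1 flags pathways with
   panel-specific fluxes.

All stages are exercised end-to-end on synthetic studies with known ground
truth (see `docs/methods.md` for the generative model and design choices).

## Worked example

Generate a synthetic study (57 cell lines × 500 genes; a 38-sample cohort
over three panels, each with its own toy metabolic model) and run the whole
pipeline:

```
$ panelflux simulate --out-dir demo --seed 42
$ panelflux -v run-all --config demo/config.json
INFO panelflux: harmonize: alpha=1.2495 beta=0.3986, 385/500 genes pass the 1-band filter
INFO panelflux: train: 40 genes in final model, lambda=7.22e-06
INFO panelflux: predict: 38 samples, 0 negative rates
INFO panelflux: flux: 38 samples solved, 0 skipped, 0 infeasible, 14 fluxes kept
completed stages: ['load', 'harmonize', 'train', 'predict', 'flux', 'specificity', 'enrichment']; failed: []
```

The simulation drew its platform pair as (α, β) = (1.25, 0.4); the
harmonization stage recovers (1.2495, 0.3986) from the data alone and keeps
385 of the 400 truly conserved genes (none of the 100 non-conserved genes
pass). `demo/results/metrics.csv` shows the characteristic
training/validation pattern that motivates the interaction stage —
the first-order model overfits, the second-order + cutoff model closes the
gap:

```
     mse     rmse      mae      mre  r_squared   strategy      order
0.000001 0.000783 0.000554 0.011676   0.990686      train        1st
0.000008 0.002794 0.001914 0.040387   0.881364 validation        1st
0.000000 0.000105 0.000082 0.001768   0.999833      train 2nd+cutoff
0.000000 0.000337 0.000263 0.005637   0.998271 validation 2nd+cutoff
```

(Rates are per-hour, so an rmse of 3.4 × 10⁻⁴ on rates of ~0.05
corresponds to sub-hour accuracy on doubling times.)
`demo/results/enrichment.csv` ranks pathways by NES:

```
                                  es    nes  p_pos  p_neg  n_h  n_perm
precursor_synthesis_common     0.922  1.261   0.00   1.00   12     100
precursor_synthesis_exclusive  0.879  1.184   0.08   0.92    9     100
exchange                      -0.538 -1.039   0.89   0.13    3     100
central_carbon                -0.815 -1.130   1.00   0.00   15     100
growth                        -0.692 -1.249   0.99   0.01    3     100
```

The two precursor-synthesis routes — which the simulation placed in
different panels' models — are exactly the pathways with NES > 1
(panel-specific fluxes), while pathways shared by every model score NES < 1
(homogeneous across panels).

The same steps are available as library calls
(`panelflux.run_pipeline(PipelineConfig(...))`) and as individual
subcommands (`harmonize`, `train`, `predict`, `flux`, `enrich`); models are
read from a small JSON dialect or SBML Level-3 with an FBC growth objective.

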