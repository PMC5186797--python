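# Methods

`panelflux` implements a strategy for inferring per-sample metabolic fluxes in
cancer cohorts that lack direct proliferation measurements: learn a
proliferation-rate predictor on a cell-line panel where doubling times are
known, transfer it to a patient cohort through a cross-platform expression
correction, fix each sample's growth flux to its predicted rate in a
panel-specific metabolic model, solve for the most parsimonious flux
distribution, and score pathways by how panel-specific their fluxes are.
Every stage is exercised on synthetic studies with known ground truth; this
note records the models, the tunable parameters, and the design choices that
were genuinely open.

## Cross-platform harmonization

Mean log2 expression on the cohort platform is modeled as an affine image of
the reference platform, `e_cohort = α·e_ref + β`. Rather than fitting both
parameters jointly, each is estimated from the data combination that isolates
it: `α` as the zero-intercept least-squares slope `Σxy/Σx²` between per-gene
means of samples measured on both platforms (same samples ⇒ no dataset
offset), and `β` as the mean per-gene difference between the reference
dataset and the cohort on the shared platform (same platform ⇒ slope 1).

A gene is *conserved* when its corrected mean agrees with the cohort within
`max_dist` (default 1.0 log2 unit, i.e. a maximal corrected 2-fold
difference; ties at the boundary fail) on both the same-platform comparison
(`β`-only correction) and the cross-platform comparison (full model). All
logs are base 2, enforced at I/O.

Two points deserve emphasis:

* **Composition of the correction.** Because `β` is estimated on the shared
  (array) platform, the map from reference all the way to the cohort's
  RNA-seq scale is the composition `e ↦ α·(e + β)`, i.e. the platform factor
  also scales the offset. `correct_expression` applies the literal affine map
  `α·e + β` (which is what the per-gene filter distances use);
  `run_pipeline` corrects the training matrix with the composed model
  (`PlatformModel.composed()`), which is the estimator-consistent choice and
  is exact on data generated under the two-stage model.
* **Trimmed refitting.** Genes whose cross-platform expression is
  uncorrelated — typically the low-expressed ones — bias the zero-intercept
  slope, which shifts the corrected values and rejects genuinely conserved
  genes. `fit_platform_model` therefore alternates fit → filter → refit on
  the passing genes until the passing set is stable (≤ 10 rounds). On a
  cohort where the affine model holds exactly for the conserved genes this
  converges to the exact `(α, β)` and the exact conserved set.

## The interaction-LASSO proliferation predictor

Proliferation rates are regressed on gene expression in two stages, both
L1-penalized least squares with the penalty chosen to minimize 10-fold
cross-validated MSE along an automatic path (folds are shuffled with a fixed
seed; features are standardized internally for the penalty and coefficients
reported on the original scale):

1. a **first-order** model over all genes; genes with standardized
   coefficients above `gene_tol` (default 1e-8) are retained — with `k`
   survivors this is typically a few dozen genes;
2. a **second-order** model over the `k(k−1)/2` pairwise products and `k`
   squares of those genes' log2 values (for `k = 54`, 1485 features);
3. a **coefficient cutoff**: features whose absolute standardized
   coefficient is at or below the `q = 0.25` quantile (linear interpolation)
   of the non-zero absolute coefficients are dropped and the model is
   *refit* on the survivors. A plain truncation would leave the intercept
   and remaining coefficients suboptimal. `q = 0` disables the cutoff; the
   largest-coefficient feature is always retained so the model cannot be
   emptied.

Generalization is measured by leave-one-out cross-validation with five
metrics (mse, rmse, mae, mre, R²). Two LOOCV modes exist:

* `fixed_features` (default): the selected genes, surviving features and
  regularization strength come from one full-data pass; only the
  coefficients are refit per fold. This mirrors common reporting practice
  but leaks the held-out sample into feature selection, so its R² is
  optimistic.
* `nested`: gene selection, the CV path and the cutoff are redone inside
  every fold. Honest but ~50× slower; it exists precisely because the
  default leaks.

Negative predicted rates are returned as-is but flagged; the flux stage
skips flagged samples, treating them as non-proliferating.

## Parsimonious FBA with a fixed growth flux

Every reversible reaction is split into forward and backward halves with
mirrored stoichiometry, after which each sample's flux distribution is the
solution of

    minimize Σᵢ vᵢ   subject to   S·v = 0,  v ≥ 0,  v_p = r_p

with `v_p` the proliferation (biomass) flux and `r_p` the sample's predicted
rate, encoded as an equality bound on that variable. No finite upper bounds
are needed: the objective is bounded below on the cone slice, so the LP
cannot be unbounded. The solver is HiGHS through `scipy.optimize.linprog`.

The LP is positively homogeneous in `r_p`, so `batch_pfba` solves each
panel's model once at a unit rate and scales per sample
(`method="scaled"`); a per-sample cold solve (`method="per_sample"`) is kept
and used as the oracle in tests. Scaling is exact up to solver tolerance,
and any optimal solution at one rate scales to an optimal solution at
another, so the shortcut never changes results beyond tolerance even under
degenerate alternative optima. Because pFBA minimizers may be non-unique in
general, correctness is asserted on objective values and residuals
(‖S·v‖∞ < 1e-7, |v_p − r_p| < 1e-9) unless a model is constructed to have a
unique optimum. Reactions are kept for downstream statistics only if their
flux exceeds `flux_tol = 1e-9` in at least one sample.

## Panel specificity and pathway enrichment

For panel `p` and reaction `i`, the specificity is
`s_pi = log2(μ_pi + ε) − log2(μ_oi + ε)` with `μ_pi` the mean flux inside
the panel, `μ_oi` the mean over all other samples, and a pseudocount
`ε = 1e-9` guarding zero means (`ε = 0` is available; with two equal-sized
panels and `ε = 0` the two panels' scores are exactly antisymmetric).

All (panel, reaction) entries are pooled and ranked by decreasing |s| (ties
broken lexicographically, so the ranking is order-invariant). For a pathway
with `n_h` of the `n` entries, a running sum advances by `|s|/n_r` at hits
(`n_r` = sum of |s| over the pathway's entries) and retreats by `1/(n−n_h)`
at misses; the enrichment score ES is the running-sum extreme of the largest
magnitude (max if |max| ≥ |min|, else min). The hit weights are absolute
specificity values: the list is ranked by absolute value, and signed weights
would make `n_r` ill-defined. Both extremes are computable; the
largest-magnitude convention is the default and mirrors standard GSEA
practice. At the end of the list both cumulative shares reach 1, so the
deviation closes to 0 (asserted to 1e-12 in tests).

The score is normalized by `n_perm = 100` random permutations of the
pathway-label column (the |s| values and their order stay fixed):
`NES = ES / mean(permuted ES)`, with all permutations entering the mean
regardless of sign; if the permutation mean has magnitude below 1e-12 the
NES is reported as NaN rather than divided. Empirical p-values are taken
separately from the positive tail (`p_pos`, fraction of permuted ES ≥
observed) and the negative tail (`p_neg`). Under random label assignment
the NES distribution centers near 1 and `p_pos` is approximately uniform —
the package's null-calibration test checks both (200 repeats, KS test).
NES > 1 marks pathways whose fluxes are panel-specific; NES < 1 marks
pathways homogeneous across panels.

## The synthetic-data generator

The generator emulates the *structure* of a dual-platform cancer study at
desk scale, not its biology:

* **Expression.** Gene-level log2 expression is Gaussian per gene with
  gene-specific means placed low-discrepancy over 4–12 (the RMA scale) and a
  common across-sample sd `expr_sd = 1.5`. Means are a deterministic
  function of the gene index so independently generated datasets share
  per-gene locations — the premise of cross-dataset harmonization. The sd
  was chosen so that the two-gene products are statistically identifiable:
  products of weakly varying positive variables are nearly collinear with
  the genes themselves, and below roughly one log2 unit of spread the true
  pairs cannot be distinguished from correlated substitutes by any sparse
  fit.
* **Rates.** Proliferation rates (1/hour; `rate = ln 2 / doubling time`
  helpers are provided, since either scale is plausible for a doubling-time
  panel) are `intercept + Σ c·e_a·e_b + N(0, noise_sd)` with 3 pairs,
  coefficients 2–4 × 10⁻⁴ and `noise_sd = 5 × 10⁻⁴`, giving rates of roughly
  0.01–0.09 per hour (doubling times ~8–70 h) with spread well above the
  noise.
* **Platforms.** For conserved genes, the cohort's array value is the latent
  expression plus `beta_true` and its RNA-seq value is `alpha_true` times
  the array value (plus per-gene measurement noise, `platform_noise_sd =
  0.2`); this makes the two-stage fitting recipe exact in the noise-free
  case. Non-conserved genes get RNA-seq values drawn independently at low
  expression and are pushed at least 1.5 log2 units away from the corrected
  reference mean, so the band filter has guaranteed positive and negative
  cases.
* **Metabolic models.** Small irreversible-friendly networks (~24
  reactions, ≥ 3 annotated pathways) share a core chain feeding one biomass
  precursor; a second precursor is produced through a route exclusive to
  panel 0 in the first model and through a shared route elsewhere, so one
  pathway is nonzero in exactly one panel by construction. Decoration
  pathways (reversible storage, overflow/secretion branches) carry no flux
  at the parsimonious optimum and exercise the non-zero-flux filter.
* **"Noise-free"** in tests means observation noise off (`noise_sd`,
  `platform_noise_sd`, and where needed `expr_sd` set to 0); biological
  across-sample variation stays on unless rate recovery is not at issue.

What passing tests do *not* show: the generator has no gene–gene correlation
structure, no probe-level or count-level measurement model, no mean–variance
relation, and its platform map is exactly affine. Recovery results therefore
demonstrate the correctness of the estimators under their stated model, not
robustness to real microarray/RNA-seq artifacts.

## Problem sizes and numerical choices

Synthetic studies use 500 genes × 57 cell lines for training and cohorts of
~40 samples across 3 panels — large enough for the overfitting phenomena the
predictor is designed around (p ≫ n in the first-order stage) and small
enough that the full pipeline runs in seconds. LP residue tolerances are
stated above; quantiles use linear interpolation; the first-order/second-
order LOOCV comparison uses the same folds and seed for both strategies.

## Known limitations

* `fixed_features` LOOCV is optimistic by construction (documented, not
  hidden); use `nested` for honest generalization estimates.
* The trimmed platform fit assumes conserved genes are the majority; with
  mostly non-conserved genes the first filter pass can collapse.
* NES is unstable when the permutation-mean ES is near zero; it is reported
  as NaN in that case rather than silently divided.
* pFBA flux values (as opposed to objectives and pathway sums) are only
  unique up to LP degeneracy; toy models here are built to have unique
  optima, real networks generally are not.
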