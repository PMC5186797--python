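"""Cross-platform expression harmonization.

Mean log2 expression on the cohort platform is modeled as an affine
function of the reference platform, ``e_cohort = α·e_ref + β``. The two
parameters are estimated separately from the data combinations that
isolate them:

* ``α`` — a zero-intercept least-squares slope between matched samples
  measured on both platforms (same samples, so no dataset offset),
* ``β`` — the mean per-gene difference between the reference dataset and
  the cohort on the *same* platform (same platform, so slope 1).

A gene is "conserved" when its corrected mean log expression agrees with
the cohort on both platforms within a configurable band (default 1 log2
unit, i.e. a maximal corrected 2-fold difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import LogExpressionMatrix


@dataclass(frozen=True)
class PlatformModel:
    """The scalar platform map ``e ↦ alpha·e + beta``."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError("alpha must be finite and positive")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")

    def composed(self) -> "PlatformModel":
        """Reference → cohort-RNA-seq map implied by the two-stage estimate.

        ``beta`` is estimated on the shared (array) platform, so mapping the
        reference all the way to the cohort's RNA-seq scale applies the
        platform factor to the offset as well: ``e ↦ alpha·(e + beta)``.
        """
        return PlatformModel(self.alpha, self.alpha * self.beta)


@dataclass
class GeneFilterReport:
    """Outcome of the conserved-gene filter over the gene universe."""

    passing_genes: set[str]
    per_gene_distances: pd.DataFrame  # columns: dist_array, dist_rnaseq, passed
    universe_size: int

    def to_csv(self, path) -> None:
        out = self.per_gene_distances.copy()
        out.index.name = "gene"
        out.to_csv(path)


def fit_alpha(matched_array: LogExpressionMatrix, matched_rnaseq: LogExpressionMatrix) -> float:
    """Zero-intercept slope between per-gene means of matched samples.

    Both matrices are reduced to per-gene mean log expression over the shared
    samples and gene universe; the slope is the least-squares solution
    ``α = Σxy / Σx²`` with x the array means and y the RNA-seq means.
    """
    common_samples = matched_array.sample_ids.intersection(matched_rnaseq.sample_ids)
    if len(common_samples) == 0:
        raise ValueError("matched matrices share no samples")
    common_genes = matched_array.gene_ids.intersection(matched_rnaseq.gene_ids)
    if len(common_genes) == 0:
        raise ValueError("matched matrices share no genes")
    x = matched_array.values.loc[common_genes, common_samples].mean(axis=1).to_numpy()
    y = matched_rnaseq.values.loc[common_genes, common_samples].mean(axis=1).to_numpy()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("degenerate input: sum of squared array means is zero")
    return float(np.dot(x, y) / denom)


def fit_beta(reference_means: pd.Series, cohort_means: pd.Series) -> float:
    """Mean per-gene difference cohort − reference on a shared platform."""
    common = reference_means.index.intersection(cohort_means.index)
    if len(common) == 0:
        raise ValueError("no common genes between reference and cohort means")
    diff = cohort_means.loc[common].to_numpy() - reference_means.loc[common].to_numpy()
    return float(np.mean(diff))


def correct_expression(reference_values, model: PlatformModel):
    """Apply the platform map elementwise: ``alpha·e + beta``."""
    if isinstance(reference_values, (pd.Series, pd.DataFrame)):
        return model.alpha * reference_values + model.beta
    return model.alpha * np.asarray(reference_values, dtype=float) + model.beta


def filter_conserved_genes(
    reference_array_means: pd.Series,
    cohort_array_means: pd.Series,
    cohort_rnaseq_means: pd.Series,
    model: PlatformModel,
    max_dist: float = 1.0,
) -> GeneFilterReport:
    """Keep genes whose corrected reference expression matches the cohort.

    A gene passes iff it is present in all three mean maps, the same-platform
    distance ``|reference + β − cohort_array|`` is strictly below ``max_dist``
    (slope 1 on a shared platform), and the cross-platform distance
    ``|α·reference + β − cohort_rnaseq|`` is strictly below ``max_dist``.
    Ties at exactly ``max_dist`` fail. Distances are reported for every gene
    in the union universe (NaN where a map is missing the gene).
    """
    if not (max_dist > 0):
        raise ValueError("max_dist must be positive")
    universe = reference_array_means.index.union(cohort_array_means.index).union(
        cohort_rnaseq_means.index
    )
    ref = reference_array_means.reindex(universe)
    arr = cohort_array_means.reindex(universe)
    rna = cohort_rnaseq_means.reindex(universe)
    dist_array = (ref + model.beta - arr).abs()
    dist_rnaseq = (model.alpha * ref + model.beta - rna).abs()
    passed = (dist_array < max_dist) & (dist_rnaseq < max_dist)
    passed &= ref.notna() & arr.notna() & rna.notna()
    report = pd.DataFrame(
        {"dist_array": dist_array, "dist_rnaseq": dist_rnaseq, "passed": passed}
    )
    return GeneFilterReport(
        passing_genes=set(universe[passed]),
        per_gene_distances=report,
        universe_size=len(universe),
    )


def fit_platform_model(
    reference_means: pd.Series,
    matched_array: LogExpressionMatrix,
    matched_rnaseq: LogExpressionMatrix,
    cohort_array_means: pd.Series,
    cohort_rnaseq_means: pd.Series,
    max_dist: float = 1.0,
    n_iter: int = 10,
) -> tuple[PlatformModel, GeneFilterReport]:
    """Fit (α, β) with iterative trimming of non-conserved genes.

    Genes whose cross-platform expression is uncorrelated (typically the
    low-expressed ones) bias the zero-intercept slope, which in turn shifts
    the corrected values and rejects genuinely conserved genes. A standard
    remedy is to alternate: fit on the current gene set, filter with the
    fitted model, refit on the passing genes, until the passing set stops
    changing (at most ``n_iter`` rounds). On a cohort where the affine model
    holds exactly for the conserved genes this converges to the exact (α, β)
    and the exact conserved set within a few iterations.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    model = PlatformModel(
        fit_alpha(matched_array, matched_rnaseq),
        fit_beta(reference_means, cohort_array_means),
    )
    report = filter_conserved_genes(
        reference_means, cohort_array_means, cohort_rnaseq_means, model, max_dist
    )
    for _ in range(n_iter - 1):
        genes = sorted(report.passing_genes)
        if not genes:
            break
        sub_array = matched_array.subset_genes(
            [g for g in genes if g in matched_array.gene_ids]
        )
        sub_rnaseq = matched_rnaseq.subset_genes(
            [g for g in genes if g in matched_rnaseq.gene_ids]
        )
        model = PlatformModel(
            fit_alpha(sub_array, sub_rnaseq),
            fit_beta(reference_means.loc[genes], cohort_array_means.loc[genes]),
        )
        new_report = filter_conserved_genes(
            reference_means, cohort_array_means, cohort_rnaseq_means, model, max_dist
        )
        converged = new_report.passing_genes == report.passing_genes
        report = new_report
        if converged:
            break
    return model, report


class PlatformCorrector:
    """Fit/transform wrapper around the two-stage platform model.

    ``fit`` estimates ``alpha_`` from the matched dual-platform subset and
    ``beta_`` from the same-platform mean difference; ``transform`` maps a
    reference-platform matrix onto the cohort RNA-seq scale using the
    composed model (see :meth:`PlatformModel.composed`).
    """

    def fit(
        self,
        matched_array: LogExpressionMatrix,
        matched_rnaseq: LogExpressionMatrix,
        reference_means: pd.Series,
        cohort_array_means: pd.Series,
    ) -> "PlatformCorrector":
        self.alpha_ = fit_alpha(matched_array, matched_rnaseq)
        self.beta_ = fit_beta(reference_means, cohort_array_means)
        self.model_ = PlatformModel(self.alpha_, self.beta_)
        return self

    def transform(self, matrix: LogExpressionMatrix) -> LogExpressionMatrix:
        if not hasattr(self, "model_"):
            raise ValueError("PlatformCorrector is not fitted")
        corrected = correct_expression(matrix.values, self.model_.composed())
        return LogExpressionMatrix(corrected, platform="rnaseq")

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "PlatformCorrector":
        if params:
            raise ValueError(f"unknown parameters: {sorted(params)}")
        return self
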