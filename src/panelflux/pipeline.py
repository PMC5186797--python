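"""End-to-end orchestration: harmonize → filter → train → predict → flux →
specificity → enrichment, with CSV intermediates and a JSON run manifest.

Every stage logs its headline counts (genes passing the filter, samples
skipped, fluxes kept); any stage error is re-raised with the stage name
and a ``FAILED`` marker file is left in the output directory so partial
outputs remain inspectable. Given the same config and seeds, reruns
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pfio
from .enrich import build_ranked_list, compute_specificity, normalize_enrichment
from .flux import batch_pfba, filter_informative_fluxes, to_irreversible
from .harmonize import correct_expression, fit_platform_model
from .matrix import LogExpressionMatrix
from .predictor import (
    InteractionLassoRegressor,
    loocv_evaluate,
    predict_rates,
)

logger = logging.getLogger("panelflux")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    ``model_paths`` maps panel name → JSON model file. Defaults mirror the
    analysis parameters used throughout the package: a 2-fold harmonization
    band, a 25% coefficient cutoff and 100 enrichment permutations.
    """

    reference_matrix: str
    reference_rates: str
    cohort_rnaseq: str
    cohort_array: str
    panel_labels: str
    model_paths: dict[str, str]
    out_dir: str
    max_dist: float = 1.0
    harmonize_iterations: int = 10
    cutoff_q: float = 0.25
    gene_tol: float = 1e-8
    flux_tol: float = 1e-9
    pseudocount: float = 1e-9
    n_perm: int = 100
    seed: int = 42
    loocv_mode: str = "fixed_features"
    evaluate_first_order: bool = True

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    manifest: dict = {
        "parameters": {
            "max_dist": config.max_dist,
            "harmonize_iterations": config.harmonize_iterations,
            "cutoff_q": config.cutoff_q,
            "gene_tol": config.gene_tol,
            "flux_tol": config.flux_tol,
            "pseudocount": config.pseudocount,
            "n_perm": config.n_perm,
            "seed": config.seed,
            "loocv_mode": config.loocv_mode,
        },
        "stages": [],
        "failed_stages": [],
    }
    state: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                logger.info("stage %s", name)
                fn()
                manifest["stages"].append(name)
            except Exception as exc:  # noqa: BLE001 - recorded and re-raised
                manifest["failed_stages"].append(name)
                failed_marker.write_text(f"{name}: {exc}\n")
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
                raise PipelineStageError(name, exc) from exc
            return fn

        return wrap

    @stage("load")
    def _load():
        state["reference"] = pfio.read_matrix(config.reference_matrix, platform="array")
        state["rates"] = pfio.read_rates(config.reference_rates)
        state["rnaseq"] = pfio.read_matrix(config.cohort_rnaseq, platform="rnaseq")
        state["array"] = pfio.read_matrix(config.cohort_array, platform="array")
        state["panels"] = pfio.read_panel_labels(config.panel_labels)
        state["models"] = {
            panel: to_irreversible(pfio.read_model_json(path))
            for panel, path in config.model_paths.items()
        }

    @stage("harmonize")
    def _harmonize():
        matched = state["rnaseq"].subset_samples(state["array"].sample_ids)
        model, report = fit_platform_model(
            state["reference"].gene_means(),
            state["array"],
            matched,
            state["array"].gene_means(),
            state["rnaseq"].gene_means(),
            max_dist=config.max_dist,
            n_iter=config.harmonize_iterations,
        )
        report.to_csv(out / "gene_filter.csv")
        (out / "platform_model.json").write_text(
            json.dumps({"alpha": model.alpha, "beta": model.beta}, indent=1) + "\n"
        )
        alpha, beta = model.alpha, model.beta
        state["platform_model"] = model
        state["passing_genes"] = sorted(report.passing_genes)
        logger.info(
            "harmonize: alpha=%.4f beta=%.4f, %d/%d genes pass the %.2g-band filter",
            alpha, beta, len(report.passing_genes), report.universe_size, config.max_dist,
        )
        if not report.passing_genes:
            raise ValueError("no gene passed the conserved-gene filter")

    @stage("train")
    def _train():
        genes = state["passing_genes"]
        reference = state["reference"].subset_genes(genes)
        # β is estimated on the shared platform, so the reference→RNA-seq map
        # scales the offset by α as well.
        corrected = LogExpressionMatrix(
            correct_expression(reference.values, state["platform_model"].composed()),
            platform="rnaseq",
        )
        rates = state["rates"].loc[list(corrected.sample_ids)]
        est = InteractionLassoRegressor(
            order=2, cutoff_q=config.cutoff_q, gene_tol=config.gene_tol,
            random_state=config.seed,
        )
        est.fit(corrected, rates)
        state["predictor"] = est
        state["corrected_reference"] = corrected
        pfio.write_predictor_json(est, out / "predictor.json")

        rows = []
        frame = corrected.samples_frame()
        strategies = [("2nd+cutoff", est)]
        if config.evaluate_first_order:
            strategies.insert(
                0,
                ("1st", InteractionLassoRegressor(order=1, cutoff_q=None,
                                                  random_state=config.seed)),
            )
        from .predictor import compute_fit_metrics

        for name, strat_est in strategies:
            fitted = strat_est if strat_est is est else None
            if fitted is None:
                fitted = type(strat_est)(**strat_est.get_params()).fit(frame, rates)
            train_metrics = compute_fit_metrics(fitted.predict(frame), rates)
            _, val_metrics = loocv_evaluate(
                frame, rates, mode=config.loocv_mode, seed=config.seed,
                estimator=strat_est,
            )
            for split, m in (("train", train_metrics), ("validation", val_metrics)):
                rows.append(
                    {"mse": m.mse, "rmse": m.rmse, "mae": m.mae, "mre": m.mre,
                     "r_squared": m.r_squared, "strategy": split, "order": name}
                )
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False, float_format="%.10g")
        logger.info("train: %d genes in final model, lambda=%.3g",
                    len(state["predictor"].genes_), state["predictor"].lambda_)

    @stage("predict")
    def _predict():
        est = state["predictor"]
        preds = predict_rates(est, state["rnaseq"])
        preds.index.name = "sample"
        preds.to_csv(out / "predicted_rates.csv", float_format="%.10g")
        state["predicted"] = preds
        logger.info("predict: %d samples, %d negative rates",
                    len(preds), int(preds["negative"].sum()))

    @stage("flux")
    def _flux():
        preds = state["predicted"]
        fm = batch_pfba(
            state["models"],
            preds["rate"].to_dict(),
            state["panels"].to_dict(),
        )
        fm = filter_informative_fluxes(fm, tol=config.flux_tol)
        fm.values.index.name = "sample"
        fm.values.to_csv(out / "fluxes.csv", float_format="%.10g")
        state["flux_matrix"] = fm
        logger.info("flux: %d samples solved, %d skipped, %d infeasible, %d fluxes kept",
                    len(fm.values), len(fm.skipped_samples),
                    len(fm.infeasible_samples), fm.values.shape[1])

    @stage("specificity")
    def _specificity():
        st = compute_specificity(state["flux_matrix"], pseudocount=config.pseudocount)
        st.entries.to_csv(out / "specificity.csv", index=False, float_format="%.10g")
        state["specificity"] = st

    @stage("enrichment")
    def _enrichment():
        pathway_map = {}
        for model in state["models"].values():
            pathway_map.update(model.pathway_map)
        rl = build_ranked_list(state["specificity"], pathway_map)
        rl.entries.to_csv(out / "ranked_list.csv", index=False, float_format="%.10g")
        res = normalize_enrichment(rl, n_perm=config.n_perm, seed=config.seed)
        res.table.to_csv(out / "enrichment.csv", float_format="%.10g")
        state["enrichment"] = res

    manifest["counts"] = {
        "passing_genes": len(state["passing_genes"]),
        "model_genes": len(state["predictor"].genes_),
        "model_features": len(state["predictor"].features_),
        "cohort_samples": int(len(state["predicted"])),
        "negative_rates": int(state["predicted"]["negative"].sum()),
        "skipped_samples": len(state["flux_matrix"].skipped_samples),
        "infeasible_samples": len(state["flux_matrix"].infeasible_samples),
        "informative_fluxes": int(state["flux_matrix"].values.shape[1]),
        "pathways": int(len(state["enrichment"].table)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
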