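"""Synthetic cohorts, cell-line panels and toy metabolic networks.

Everything downstream of raw data — platform harmonization, the
interaction-LASSO proliferation predictor, parsimonious FBA and the panel
enrichment statistics — is exercised on data produced here, with a known
:class:`GroundTruth` so that recovery can be asserted exactly.

The generative model
--------------------
* Gene-level log2 expression is Gaussian per gene with gene-specific means
  spanning roughly 4–12 (the scale of RMA-normalized arrays) and a common
  across-sample standard deviation (``expr_sd``). Gene means are a fixed
  low-discrepancy function of the gene index so that cell-line panels and
  patient cohorts share the same per-gene location — the premise of
  cross-dataset harmonization.
* Proliferation rates (units: 1/hour, the scale implied by doubling times of
  10–140 h) are a sparse quadratic in expression: an intercept plus a few
  two-gene products of log2 expression values, plus Gaussian noise.
* A patient cohort is measured on two platforms. For "conserved" genes the
  cohort's array-platform value is the latent reference-scale expression
  shifted by ``beta_true`` (a dataset offset on the shared platform), and the
  cohort's RNA-seq value is ``alpha_true`` times the array value (a
  zero-intercept platform factor between matched samples). Non-conserved
  genes get RNA-seq values drawn independently of the array values, at low
  expression, and are constructed to violate the 2-fold harmonization band.
* Toy metabolic networks are small irreversible-friendly stoichiometric
  models with exchange reactions, a proliferation (biomass) reaction, and
  several annotated pathways; panels differ by which synthesis route for one
  biomass precursor is present, so one pathway is exclusive to the first
  panel by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import LogExpressionMatrix

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """The latent structure a synthetic study is generated from.

    ``signal_pairs`` are the gene pairs whose log-expression products drive
    the proliferation rate; every signal gene must be conserved, otherwise
    the harmonization filter would (correctly) remove the signal.
    """

    signal_pairs: tuple[tuple[str, str], ...]
    pair_coefficients: tuple[float, ...]
    intercept: float
    noise_sd: float
    conserved_genes: frozenset[str]
    alpha_true: float
    beta_true: float

    def __post_init__(self) -> None:
        if len(self.signal_pairs) < 1:
            raise ValueError("at least one signal pair is required")
        if len(self.signal_pairs) != len(self.pair_coefficients):
            raise ValueError("one coefficient per signal pair is required")
        if not all(np.isfinite(self.pair_coefficients)):
            raise ValueError("pair coefficients must be finite")
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        if not (self.noise_sd >= 0):
            raise ValueError("noise_sd must be >= 0")
        if not (np.isfinite(self.alpha_true) and self.alpha_true > 0):
            raise ValueError("alpha_true must be finite and positive")
        if not np.isfinite(self.beta_true):
            raise ValueError("beta_true must be finite")
        for a, b in self.signal_pairs:
            for g in (a, b):
                if g not in self.conserved_genes:
                    raise ValueError(f"signal gene {g} is not in conserved_genes")

    @property
    def signal_genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a, b in self.signal_pairs:
            seen.setdefault(a)
            seen.setdefault(b)
        return tuple(sorted(seen))


@dataclass
class CohortBundle:
    """A dual-platform patient cohort with per-sample ground truth."""

    rnaseq_matrix: LogExpressionMatrix
    array_matrix: LogExpressionMatrix
    panel_labels: pd.Series  # sample id -> panel name
    true_rates: pd.Series  # sample id -> proliferation rate

    def __post_init__(self) -> None:
        if not set(self.array_matrix.sample_ids) <= set(self.rnaseq_matrix.sample_ids):
            raise ValueError("array samples must be a subset of rnaseq samples")
        if not self.rnaseq_matrix.gene_ids.equals(self.array_matrix.gene_ids):
            raise ValueError("platform matrices must share an identical gene universe")
        samples = set(self.rnaseq_matrix.sample_ids)
        if set(self.panel_labels.index) != samples or set(self.true_rates.index) != samples:
            raise ValueError("panel labels and true rates must cover every sample exactly once")


def gene_ids(n_genes: int) -> list[str]:
    """The deterministic gene universe ``G0000 … G{n-1}``."""
    return [f"G{i:04d}" for i in range(n_genes)]


def gene_mean(gene: str, low: float = 4.0, high: float = 12.0) -> float:
    """Fixed gene-specific mean log2 expression, low-discrepancy over [low, high].

    Deterministic in the gene id so that independently generated datasets share
    per-gene locations, mimicking globally conserved expression.
    """
    i = int(gene[1:])
    frac = (i * _GOLDEN) % 1.0
    return low + (high - low) * frac


def _gene_means(genes: Sequence[str], mean_range: tuple[float, float]) -> np.ndarray:
    low, high = mean_range
    return np.array([gene_mean(g, low, high) for g in genes])


def make_ground_truth(
    n_genes: int = 500,
    n_pairs: int = 3,
    conserved_fraction: float = 0.8,
    seed: int = 0,
    coef_range: tuple[float, float] = (2e-4, 4e-4),
    intercept: float = 0.005,
    noise_sd: float = 5e-4,
    alpha: float = 1.25,
    beta: float = 0.4,
) -> GroundTruth:
    """Draw a random :class:`GroundTruth` over the ``n_genes`` universe.

    Defaults give proliferation rates on the order of 0.01–0.09 per hour
    (doubling times of roughly 8–70 h) with an across-sample spread well
    above the observation noise.
    """
    rng = np.random.default_rng(seed)
    genes = gene_ids(n_genes)
    n_cons = max(int(round(conserved_fraction * n_genes)), 2 * n_pairs)
    conserved = rng.choice(n_genes, size=n_cons, replace=False)
    conserved_genes = frozenset(genes[i] for i in conserved)
    picked = rng.choice(sorted(conserved), size=2 * n_pairs, replace=False)
    pairs = tuple(
        tuple(sorted((genes[picked[2 * k]], genes[picked[2 * k + 1]])))
        for k in range(n_pairs)
    )
    coefs = tuple(rng.uniform(*coef_range, size=n_pairs))
    return GroundTruth(
        signal_pairs=pairs,
        pair_coefficients=coefs,
        intercept=intercept,
        noise_sd=noise_sd,
        conserved_genes=conserved_genes,
        alpha_true=alpha,
        beta_true=beta,
    )


def rates_from_truth(matrix: LogExpressionMatrix, truth: GroundTruth) -> pd.Series:
    """Noise-free proliferation rates implied by ``truth`` for each sample."""
    vals = matrix.values
    out = np.full(vals.shape[1], truth.intercept, dtype=float)
    for (a, b), c in zip(truth.signal_pairs, truth.pair_coefficients):
        for g in (a, b):
            if g not in vals.index:
                raise KeyError(f"signal gene {g} is not in the expression matrix")
        out = out + c * vals.loc[a].to_numpy() * vals.loc[b].to_numpy()
    return pd.Series(out, index=vals.columns, name="rate")


def proliferation_rate_from_doubling_time(doubling_time: float) -> float:
    """Convert a doubling time (hours) to an exponential growth rate ln2/t."""
    if doubling_time <= 0:
        raise ValueError("doubling time must be positive")
    return math.log(2.0) / doubling_time


def doubling_time_from_proliferation_rate(rate: float) -> float:
    if rate <= 0:
        raise ValueError("rate must be positive")
    return math.log(2.0) / rate


# ---------------------------------------------------------------------------
# cell line panel
# ---------------------------------------------------------------------------

def generate_cell_line_panel(
    n_genes: int,
    n_lines: int,
    truth: GroundTruth,
    seed: int,
    expr_mean_range: tuple[float, float] = (4.0, 12.0),
    expr_sd: float = 1.5,
) -> tuple[LogExpressionMatrix, pd.Series]:
    """A cell-line training panel: expression matrix plus measured rates.

    Rates are ``intercept + Σ coef·e_a·e_b + N(0, noise_sd)`` evaluated on the
    emitted log2 expression values, so they can be recomputed exactly from the
    matrix and the truth.
    """
    if n_lines < 10:
        raise ValueError("n_lines must be >= 10")
    genes = gene_ids(n_genes)
    universe = set(genes)
    for a, b in truth.signal_pairs:
        for g in (a, b):
            if g not in universe:
                raise ValueError(f"signal gene {g} is outside the {n_genes}-gene universe")
    rng = np.random.default_rng(seed)
    means = _gene_means(genes, expr_mean_range)
    values = means[:, None] + rng.normal(0.0, expr_sd, size=(n_genes, n_lines))
    lines = [f"CL{i:02d}" for i in range(n_lines)]
    matrix = LogExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=lines),
        platform="array",
    )
    rates = rates_from_truth(matrix, truth)
    if truth.noise_sd > 0:
        rates = rates + rng.normal(0.0, truth.noise_sd, size=n_lines)
    rates.name = "rate"
    return matrix, rates


# ---------------------------------------------------------------------------
# patient cohort
# ---------------------------------------------------------------------------

def _infer_n_genes(truth: GroundTruth) -> int:
    idx = [int(g[1:]) for g in truth.conserved_genes] + [
        int(g[1:]) for pair in truth.signal_pairs for g in pair
    ]
    return max(idx) + 1


def generate_patient_cohort(
    truth: GroundTruth,
    panels: Sequence[tuple[str, int, float]],
    dual_platform_fraction: float,
    seed: int,
    n_genes: int | None = None,
    expr_mean_range: tuple[float, float] = (4.0, 12.0),
    expr_sd: float = 1.5,
    platform_noise_sd: float = 0.2,
    nonconserved_low_range: tuple[float, float] = (1.0, 4.0),
    band_margin: float = 1.5,
) -> CohortBundle:
    """A dual-platform cohort with panel structure and known rates.

    ``panels`` is a list of ``(name, n_samples, rate_shift)``; each panel's
    true rates are shifted by ``rate_shift``. A fraction
    ``dual_platform_fraction`` of the samples (the leading ones of each panel)
    is additionally measured on the array platform.

    Conserved genes follow ``array = latent + beta_true`` and
    ``rnaseq = alpha_true·array`` (plus per-gene measurement noise), so the
    zero-intercept matched-sample fit recovers ``alpha_true`` and the
    same-platform mean difference recovers ``beta_true``. Non-conserved genes
    get uncorrelated low RNA-seq expression placed at least ``band_margin``
    log2 units away from the corrected reference mean, guaranteeing both
    positive and negative cases for the conserved-gene filter.
    """
    if not panels:
        raise ValueError("panel list must be non-empty")
    if not (0 < dual_platform_fraction <= 1):
        raise ValueError("dual_platform_fraction must be in (0, 1]")
    if n_genes is None:
        n_genes = _infer_n_genes(truth)
    genes = gene_ids(n_genes)
    rng = np.random.default_rng(seed)
    means = _gene_means(genes, expr_mean_range)
    conserved_mask = np.array([g in truth.conserved_genes for g in genes])

    sample_ids: list[str] = []
    labels: list[str] = []
    shifts: list[float] = []
    for name, n_samples, rate_shift in panels:
        for k in range(n_samples):
            sample_ids.append(f"{name}-{k:03d}")
            labels.append(name)
            shifts.append(rate_shift)
    n_total = len(sample_ids)

    latent = means[:, None] + rng.normal(0.0, expr_sd, size=(n_genes, n_total))
    array_vals = latent + truth.beta_true
    if platform_noise_sd > 0:
        array_vals = array_vals + rng.normal(0.0, platform_noise_sd, size=array_vals.shape)
    rnaseq_vals = truth.alpha_true * array_vals
    if platform_noise_sd > 0:
        rnaseq_vals = rnaseq_vals + rng.normal(0.0, platform_noise_sd, size=rnaseq_vals.shape)

    # Non-conserved genes: RNA-seq uncorrelated with the array platform, low
    # expressed, and forced outside the harmonization band.
    nc_idx = np.where(~conserved_mask)[0]
    if nc_idx.size:
        low, high = nonconserved_low_range
        nc_means = rng.uniform(low, high, size=nc_idx.size)
        corrected_ref = truth.alpha_true * means[nc_idx] + truth.beta_true
        too_close = np.abs(corrected_ref - nc_means) < band_margin
        nc_means[too_close] = corrected_ref[too_close] - band_margin
        nc_noise = rng.normal(0.0, expr_sd, size=(nc_idx.size, n_total))
        rnaseq_vals[nc_idx, :] = nc_means[:, None] + nc_noise

    latent_matrix = LogExpressionMatrix(
        pd.DataFrame(latent, index=pd.Index(genes, name="gene"), columns=sample_ids),
        platform="array",
    )
    true_rates = rates_from_truth(latent_matrix, truth) + np.asarray(shifts)
    if truth.noise_sd > 0:
        true_rates = true_rates + rng.normal(0.0, truth.noise_sd, size=n_total)
    true_rates.name = "rate"

    rnaseq = LogExpressionMatrix(
        pd.DataFrame(rnaseq_vals, index=pd.Index(genes, name="gene"), columns=sample_ids),
        platform="rnaseq",
    )
    # dual-platform subset: the leading fraction of each panel
    dual_samples: list[str] = []
    for name, n_samples, _ in panels:
        n_dual = max(1, int(round(dual_platform_fraction * n_samples)))
        dual_samples.extend(f"{name}-{k:03d}" for k in range(min(n_dual, n_samples)))
    array_matrix = LogExpressionMatrix(
        pd.DataFrame(array_vals, index=pd.Index(genes, name="gene"), columns=sample_ids)
        .loc[:, dual_samples]
        .copy(),
        platform="array",
    )
    return CohortBundle(
        rnaseq_matrix=rnaseq,
        array_matrix=array_matrix,
        panel_labels=pd.Series(labels, index=sample_ids, name="panel"),
        true_rates=true_rates,
    )


# ---------------------------------------------------------------------------
# toy metabolic models
# ---------------------------------------------------------------------------

@dataclass
class ToyNetwork:
    """A small metabolic network in the package's JSON-dialect structure."""

    metabolites: list[str]
    reactions: list[dict]  # {id, stoich: {met: coef}, reversible, pathway}
    objective: str

    def reaction_ids(self) -> list[str]:
        return [r["id"] for r in self.reactions]


def _chain(prefix: str, start: str, end: str, length: int, pathway: str) -> tuple[list[str], list[dict]]:
    """A linear chain start → x1 → … → end of ``length`` unit reactions."""
    mets = [f"{prefix}_x{i}" for i in range(1, length)]
    nodes = [start, *mets, end]
    rxns = [
        {
            "id": f"{prefix}_r{i}",
            "stoich": {nodes[i]: -1.0, nodes[i + 1]: 1.0},
            "reversible": False,
            "pathway": pathway,
        }
        for i in range(length)
    ]
    return mets, rxns


def generate_toy_model(n_panels: int, seed: int) -> list[ToyNetwork]:
    """One small metabolic model per panel, sharing a core but differing in routes.

    Every model can reach a positive proliferation flux through an
    unconstrained source exchange. The biomass reaction consumes two
    precursors: precursor A is always made through a shared central chain;
    precursor B is made through a synthesis route exclusive to panel 0
    (pathway ``"precursor_synthesis_exclusive"``) in the first model and
    through a shared route (``"precursor_synthesis_common"``) in every other
    model. Extra decorated pathways (a reversible storage shuttle and an
    overflow secretion branch) are present in all panels and carry no flux at
    the parsimonious optimum, exercising the non-zero-flux filter.
    """
    if n_panels < 1:
        raise ValueError("n_panels must be >= 1")
    rng = np.random.default_rng(seed)
    core_len = int(rng.integers(3, 6))
    excl_len = int(rng.integers(2, 5))
    common_len = int(rng.integers(2, 5))
    a_coef = float(rng.integers(1, 3))
    b_coef = float(rng.integers(1, 3))

    models: list[ToyNetwork] = []
    for p in range(n_panels):
        mets = ["src", "preA", "preB"]
        rxns: list[dict] = [
            {"id": "EX_src", "stoich": {"src": 1.0}, "reversible": False, "pathway": "exchange"},
        ]
        m, r = _chain("core", "src", "preA", core_len, "central_carbon")
        mets += m
        rxns += r
        if p == 0:
            m, r = _chain("excl", "src", "preB", excl_len, "precursor_synthesis_exclusive")
        else:
            m, r = _chain("common", "src", "preB", common_len, "precursor_synthesis_common")
        mets += m
        rxns += r
        # biomass / proliferation
        rxns.append(
            {
                "id": "proliferation",
                "stoich": {"preA": -a_coef, "preB": -b_coef},
                "reversible": False,
                "pathway": "growth",
            }
        )
        # storage shuttle: reversible, off the optimal path (dead end loop)
        mets += ["store"]
        rxns.append(
            {"id": "storage_in", "stoich": {"preA": -1.0, "store": 1.0},
             "reversible": True, "pathway": "storage"}
        )
        # overflow branch: strictly longer secretion route, zero at optimum
        m, r = _chain("ovf", "preA", "waste", 2, "overflow")
        mets += m + ["waste"]
        rxns += r
        rxns.append(
            {"id": "EX_waste", "stoich": {"waste": -1.0}, "reversible": False, "pathway": "exchange"}
        )
        # panel-shared decoration pathways: secretion branches off the source,
        # all strictly costly and therefore silent at the parsimonious optimum
        for name, length in (("fatty_acid", 3), ("redox_detox", 3), ("nucleotide_salvage", 4)):
            sink = f"{name}_end"
            m, r = _chain(name, "src", sink, length, name)
            mets += m + [sink]
            rxns += r
            rxns.append(
                {"id": f"EX_{name}", "stoich": {sink: -1.0},
                 "reversible": False, "pathway": "exchange"}
            )
        models.append(ToyNetwork(metabolites=mets, reactions=rxns, objective="proliferation"))
    return models
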