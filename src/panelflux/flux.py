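"""Proliferation-constrained parsimonious flux balance analysis.

Given an irreversible stoichiometric model and a required proliferation
rate ``r_p``, parsimonious FBA solves the linear program

    minimize    Σ_i v_i
    subject to  S·v = 0,  v_i ≥ 0,  v_p = r_p

where ``v_p`` is the flux through the proliferation (biomass) reaction.
Because minimization over the non-negative cone slice needs no finite
upper bounds, the only data required are the stoichiometry and the rate.
Reversible reactions are first split into forward and backward halves
with mirrored stoichiometry, so Σ v_i is the total absolute flux.

The LP is positively homogeneous in ``r_p``: scaling the rate scales the
feasible slice and the optimal solution set linearly. Batched solving
exploits this by solving each panel's model once at a unit rate and
scaling per sample, which reproduces per-sample solves to solver
tolerance at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog


class FluxInfeasibleError(RuntimeError):
    """The required proliferation rate is unreachable in the model."""


@dataclass
class MetabolicNetwork:
    """A stoichiometric model that may still contain reversible reactions."""

    stoichiometry: pd.DataFrame  # metabolites × reactions
    reversible: dict[str, bool]
    proliferation_reaction: str
    pathway_map: dict[str, str]

    def __post_init__(self) -> None:
        rids = list(self.stoichiometry.columns)
        if self.proliferation_reaction not in rids:
            raise ValueError(
                f"proliferation reaction {self.proliferation_reaction!r} is not in the model"
            )
        missing = [r for r in rids if r not in self.reversible]
        if missing:
            raise ValueError(f"reactions without reversibility flag: {missing[:5]}")


@dataclass
class IrreversibleModel:
    """A model in which every flux is constrained non-negative.

    ``reverse_of`` maps each backward half of a split reversible reaction to
    its forward partner (and vice versa).
    """

    stoichiometry: pd.DataFrame  # metabolites × reactions
    proliferation_reaction: str
    pathway_map: dict[str, str]
    reverse_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.proliferation_reaction not in self.stoichiometry.columns:
            raise ValueError(
                f"proliferation reaction {self.proliferation_reaction!r} is not in the model"
            )

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.stoichiometry.columns)


def to_irreversible(model: MetabolicNetwork) -> IrreversibleModel:
    """Split every reversible reaction into forward and backward halves."""
    cols: dict[str, np.ndarray] = {}
    reverse_of: dict[str, str] = {}
    pathways: dict[str, str] = {}
    S = model.stoichiometry
    for rid in S.columns:
        col = S[rid].to_numpy(dtype=float)
        cols[rid] = col
        pathways[rid] = model.pathway_map.get(rid, "unassigned")
        if model.reversible.get(rid, False):
            back = f"{rid}__rev"
            cols[back] = -col
            reverse_of[back] = rid
            reverse_of[rid] = back
            pathways[back] = pathways[rid]
    stoich = pd.DataFrame(cols, index=S.index)
    return IrreversibleModel(
        stoichiometry=stoich,
        proliferation_reaction=model.proliferation_reaction,
        pathway_map=pathways,
        reverse_of=reverse_of,
    )


@dataclass
class PfbaSolution:
    fluxes: pd.Series
    objective: float
    status: str


def pfba_fixed_growth(model: IrreversibleModel, r_p: float) -> PfbaSolution:
    """Minimize total flux subject to steady state and a fixed growth flux.

    The proliferation constraint is encoded as an equality bound
    ``lb = ub = r_p`` on that variable. Raises :class:`FluxInfeasibleError`
    when ``r_p`` is unreachable; the problem cannot be unbounded because the
    objective is bounded below by 0 on the feasible cone slice.
    """
    if not (r_p > 0):
        raise ValueError("r_p must be positive")
    S = model.stoichiometry.to_numpy(dtype=float)
    n = S.shape[1]
    p = model.reaction_ids.index(model.proliferation_reaction)
    bounds = [(0.0, None)] * n
    bounds[p] = (r_p, r_p)
    res = linprog(
        c=np.ones(n),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        raise FluxInfeasibleError(
            f"proliferation rate {r_p} is infeasible for this model"
        )
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    fluxes = pd.Series(res.x, index=model.reaction_ids, name="flux")
    return PfbaSolution(fluxes=fluxes, objective=float(res.fun), status="optimal")


@dataclass
class FluxMatrix:
    """Per-sample parsimonious flux distributions across panels."""

    values: pd.DataFrame  # samples × reactions, non-negative
    panel_labels: pd.Series  # sample -> panel (solved samples only)
    skipped_samples: list[str] = field(default_factory=list)
    infeasible_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.values.columns)


def batch_pfba(
    models: Mapping[str, IrreversibleModel],
    rates: Mapping[str, float],
    panels: Mapping[str, str],
    method: str = "scaled",
) -> FluxMatrix:
    """Parsimonious FBA for every sample with a positive rate.

    ``models`` maps panel name → irreversible model; ``panels`` maps sample →
    panel. Samples with a non-positive rate are recorded in
    ``skipped_samples`` and excluded; per-sample infeasibilities are recorded
    and the run continues. ``method="scaled"`` solves each panel once at a
    unit rate and scales by homogeneity; ``method="per_sample"`` solves every
    sample from scratch.
    """
    if method not in ("scaled", "per_sample"):
        raise ValueError(f"unknown batch method {method!r}")
    missing_panels = sorted({p for p in panels.values() if p not in models})
    if missing_panels:
        raise KeyError(f"no model for panels: {missing_panels}")

    skipped: list[str] = []
    infeasible: list[str] = []
    rows: dict[str, pd.Series] = {}
    labels: dict[str, str] = {}

    unit_solutions: dict[str, PfbaSolution | None] = {}
    all_reactions: list[str] = []
    seen = set()
    for panel, model in models.items():
        for rid in model.reaction_ids:
            if rid not in seen:
                seen.add(rid)
                all_reactions.append(rid)

    for sample, rate in rates.items():
        if sample not in panels:
            raise KeyError(f"sample {sample!r} has no panel label")
        panel = panels[sample]
        if not (rate > 0):
            skipped.append(sample)
            continue
        model = models[panel]
        try:
            if method == "scaled":
                if panel not in unit_solutions:
                    try:
                        unit_solutions[panel] = pfba_fixed_growth(model, 1.0)
                    except FluxInfeasibleError:
                        unit_solutions[panel] = None
                base = unit_solutions[panel]
                if base is None:
                    raise FluxInfeasibleError(panel)
                fluxes = base.fluxes * rate
            else:
                fluxes = pfba_fixed_growth(model, rate).fluxes
        except FluxInfeasibleError:
            infeasible.append(sample)
            continue
        rows[sample] = fluxes
        labels[sample] = panel

    values = pd.DataFrame(
        0.0, index=list(rows.keys()), columns=all_reactions, dtype=float
    )
    for sample, fluxes in rows.items():
        values.loc[sample, fluxes.index] = fluxes.to_numpy()
    return FluxMatrix(
        values=values,
        panel_labels=pd.Series(labels, dtype=object),
        skipped_samples=skipped,
        infeasible_samples=infeasible,
    )


def filter_informative_fluxes(fm: FluxMatrix, tol: float = 1e-9) -> FluxMatrix:
    """Keep reaction columns that are non-zero (> tol) in at least one sample."""
    if fm.values.empty:
        return FluxMatrix(
            values=fm.values.copy(),
            panel_labels=fm.panel_labels.copy(),
            skipped_samples=list(fm.skipped_samples),
            infeasible_samples=list(fm.infeasible_samples),
        )
    keep = fm.values.max(axis=0) > tol
    return FluxMatrix(
        values=fm.values.loc[:, keep].copy(),
        panel_labels=fm.panel_labels.copy(),
        skipped_samples=list(fm.skipped_samples),
        infeasible_samples=list(fm.infeasible_samples),
    )
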