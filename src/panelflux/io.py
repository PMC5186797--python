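"""File formats: TSV expression matrices, a JSON metabolic-model dialect,
SBML (read-only, via COBRApy), and CSV result tables.

The matrix format is tab-separated with the gene id in the first column
and a header row of sample ids; values are log2 expression. The JSON
model dialect is::

    {"metabolites": [...],
     "reactions": [{"id": ..., "stoich": {met: coef, ...},
                    "reversible": bool, "pathway": str}, ...],
     "objective": reaction_id}

Round-trips of both formats are lossless (gene/sample and reaction order
preserved).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .flux import MetabolicNetwork
from .matrix import LogExpressionMatrix
from .predictor import InteractionLassoRegressor, LinearFit
from .simulate import ToyNetwork


class ParseError(ValueError):
    """A file could not be parsed; the message locates the problem."""


# ---------------------------------------------------------------------------
# expression matrices and tables
# ---------------------------------------------------------------------------

def write_matrix(matrix: LogExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path, platform: str = "array") -> LogExpressionMatrix:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: file is empty")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise ParseError(f"{path}: non-numeric values in columns {list(bad)[:5]}")
    try:
        return LogExpressionMatrix(df, platform=platform)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_table(series_or_frame, path, index_name: str = "sample") -> None:
    out = series_or_frame.copy()
    if isinstance(out, pd.Series):
        out = out.to_frame()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_rates(path) -> pd.Series:
    df = _read_tsv(path)
    if "rate" not in df.columns:
        raise ParseError(f"{path}: expected a 'rate' column")
    return df["rate"].astype(float)


def read_panel_labels(path) -> pd.Series:
    df = _read_tsv(path)
    if "panel" not in df.columns:
        raise ParseError(f"{path}: expected a 'panel' column")
    return df["panel"].astype(str)


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: file is empty")
    try:
        return pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# metabolic models
# ---------------------------------------------------------------------------

def network_from_dialect(data: dict, source: str = "<json>") -> MetabolicNetwork:
    """Build a :class:`MetabolicNetwork` from the JSON dialect structure."""
    for key in ("metabolites", "reactions", "objective"):
        if key not in data:
            raise ParseError(f"{source}: missing key {key!r}")
    mets = list(data["metabolites"])
    met_set = set(mets)
    rids = []
    cols = {}
    reversible = {}
    pathways = {}
    for rxn in data["reactions"]:
        rid = rxn["id"]
        if rid in cols:
            raise ParseError(f"{source}: duplicate reaction id {rid!r}")
        col = np.zeros(len(mets))
        for met, coef in rxn["stoich"].items():
            if met not in met_set:
                raise ParseError(f"{source}: reaction {rid!r} references unknown metabolite {met!r}")
            col[mets.index(met)] = float(coef)
        cols[rid] = col
        rids.append(rid)
        reversible[rid] = bool(rxn.get("reversible", False))
        pathways[rid] = str(rxn.get("pathway", "unassigned"))
    if data["objective"] not in cols:
        raise ParseError(f"{source}: objective reaction {data['objective']!r} is not defined")
    stoich = pd.DataFrame(cols, index=pd.Index(mets, name="metabolite"))
    return MetabolicNetwork(
        stoichiometry=stoich,
        reversible=reversible,
        proliferation_reaction=data["objective"],
        pathway_map=pathways,
    )


def read_model_json(path) -> MetabolicNetwork:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: file is empty")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    return network_from_dialect(data, source=str(path))


def write_model_json(model: ToyNetwork | MetabolicNetwork, path) -> None:
    if isinstance(model, MetabolicNetwork):
        data = {
            "metabolites": list(model.stoichiometry.index),
            "reactions": [
                {
                    "id": rid,
                    "stoich": {
                        met: float(c)
                        for met, c in model.stoichiometry[rid].items()
                        if c != 0
                    },
                    "reversible": bool(model.reversible[rid]),
                    "pathway": model.pathway_map.get(rid, "unassigned"),
                }
                for rid in model.stoichiometry.columns
            ],
            "objective": model.proliferation_reaction,
        }
    else:
        data = {
            "metabolites": model.metabolites,
            "reactions": model.reactions,
            "objective": model.objective,
        }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=False) + "\n")


def to_cobra(model: MetabolicNetwork):
    """Convert to a COBRApy model (reversible reactions get negative lower bounds)."""
    import cobra

    cm = cobra.Model("panelflux")
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.stoichiometry.index}
    for rid in model.stoichiometry.columns:
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = -1000.0 if model.reversible[rid] else 0.0
        rxn.upper_bound = 1000.0
        rxn.subsystem = model.pathway_map.get(rid, "unassigned")
        cm.add_reactions([rxn])
        rxn.add_metabolites(
            {mets[m]: float(c) for m, c in model.stoichiometry[rid].items() if c != 0}
        )
    # pathway annotations travel as SBML groups
    by_pathway: dict[str, list] = {}
    for rid in model.stoichiometry.columns:
        by_pathway.setdefault(model.pathway_map.get(rid, "unassigned"), []).append(
            cm.reactions.get_by_id(rid)
        )
    cm.add_groups(
        [cobra.core.Group(name, name=name, members=rxns) for name, rxns in by_pathway.items()]
    )
    cm.objective = model.proliferation_reaction
    return cm


def read_model_sbml(path) -> MetabolicNetwork:
    """Read an SBML Level-3 model; the FBC objective marks the growth reaction."""
    import cobra

    cm = cobra.io.read_sbml_model(str(path))
    mets = [m.id for m in cm.metabolites]
    group_of: dict[str, str] = {}
    for group in cm.groups:
        for member in group.members:
            group_of[member.id] = group.name or group.id
    cols = {}
    reversible = {}
    pathways = {}
    for rxn in cm.reactions:
        col = np.zeros(len(mets))
        for met, coef in rxn.metabolites.items():
            col[mets.index(met.id)] = float(coef)
        cols[rxn.id] = col
        reversible[rxn.id] = rxn.lower_bound < 0
        pathways[rxn.id] = rxn.subsystem or group_of.get(rxn.id, "unassigned")
    objective_rxns = [
        r.id for r in cm.reactions if r.objective_coefficient
    ]
    if len(objective_rxns) != 1:
        raise ParseError(f"{path}: expected exactly one objective reaction, got {objective_rxns}")
    stoich = pd.DataFrame(cols, index=pd.Index(mets, name="metabolite"))
    return MetabolicNetwork(
        stoichiometry=stoich,
        reversible=reversible,
        proliferation_reaction=objective_rxns[0],
        pathway_map=pathways,
    )


# ---------------------------------------------------------------------------
# predictor serialization
# ---------------------------------------------------------------------------

def write_predictor_json(model: InteractionLassoRegressor, path) -> None:
    features = [
        list(f) if isinstance(f, tuple) else [f, f] for f in model.features_
    ]
    data = {
        "order": model.order,
        "genes": list(model.genes_),
        "features": features,
        "coefficients": [float(c) for c in model.coef_],
        "intercept": float(model.intercept_),
        "lambda": float(model.lambda_),
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def read_predictor_json(path) -> InteractionLassoRegressor:
    data = json.loads(Path(path).read_text())
    est = InteractionLassoRegressor(order=data["order"])
    est.genes_ = list(data["genes"])
    if data["order"] == 1:
        names = tuple(f[0] for f in data["features"])
    else:
        names = tuple(tuple(f) for f in data["features"])
    coefs = np.asarray(data["coefficients"], dtype=float)
    est.final_fit_ = LinearFit(
        feature_names=names,
        coefficients=coefs,
        standardized_coefficients=coefs.copy(),
        intercept=float(data["intercept"]),
        lambda_=float(data["lambda"]),
    )
    est.features_ = names
    est.coef_ = coefs
    est.intercept_ = float(data["intercept"])
    est.lambda_ = float(data["lambda"])
    return est
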