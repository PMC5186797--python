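"""Panel-specificity scores and permutation-normalized pathway enrichment.

The specificity of flux ``i`` for panel ``p`` is the log2 fold change of
its mean inside the panel against its mean in all other samples,

    s_pi = log2(μ_pi + ε) − log2(μ_oi + ε),

with a small pseudocount ``ε`` guarding zero means. All (panel, reaction)
scores are pooled and ranked by decreasing absolute value; a weighted
Kolmogorov–Smirnov-style running sum then scores each pathway: hits
advance the sum by their |s| share, misses retreat it by 1/(n − n_h), and
the enrichment score ES is the running-sum extreme of largest magnitude.
The score is normalized against random pathway-label permutations,
NES = ES / mean(permuted ES), with empirical p-values taken separately
from the positive and negative permutation tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flux import FluxMatrix


@dataclass
class SpecificityTable:
    """Per-(panel, reaction) specificity scores ``s``."""

    entries: pd.DataFrame  # columns: panel, reaction, s
    pseudocount: float

    def pivot(self) -> pd.DataFrame:
        return self.entries.pivot(index="panel", columns="reaction", values="s")


@dataclass
class RankedList:
    """All (panel, reaction) entries sorted by decreasing |s|."""

    entries: pd.DataFrame  # columns: panel, reaction, abs_s, pathway

    @property
    def n(self) -> int:
        return len(self.entries)


@dataclass
class EnrichmentResult:
    """Per-pathway ES, NES and tail p-values."""

    table: pd.DataFrame  # index: pathway; columns: es, nes, p_pos, p_neg, n_h, n_perm


def compute_specificity(fm: FluxMatrix, pseudocount: float = 1e-9) -> SpecificityTable:
    """Log2 fold change of each flux between one panel and all others."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    panels = fm.panel_labels.reindex(fm.values.index)
    unique_panels = sorted(panels.unique())
    if len(unique_panels) < 2:
        raise ValueError(
            "specificity requires at least two panels (the out-of-panel mean is "
            "undefined otherwise)"
        )
    records = []
    vals = fm.values
    for panel in unique_panels:
        inside = vals.loc[panels == panel]
        outside = vals.loc[panels != panel]
        mu_in = inside.mean(axis=0).to_numpy()
        mu_out = outside.mean(axis=0).to_numpy()
        s = np.log2(mu_in + pseudocount) - np.log2(mu_out + pseudocount)
        for rid, sval in zip(vals.columns, s):
            records.append((panel, rid, float(sval)))
    entries = pd.DataFrame(records, columns=["panel", "reaction", "s"])
    return SpecificityTable(entries=entries, pseudocount=pseudocount)


def build_ranked_list(st: SpecificityTable, pathway_map) -> RankedList:
    """Pool all panels and reactions and sort by |s| descending.

    Ties are broken by (panel, reaction) lexicographic order, so the ranking
    is deterministic and invariant to the input row order.
    """
    if st.entries.empty:
        raise ValueError("specificity table is empty")
    df = st.entries.copy()
    df["abs_s"] = df["s"].abs()
    df["pathway"] = [pathway_map.get(r, "unassigned") for r in df["reaction"]]
    df = df.sort_values(
        by=["abs_s", "panel", "reaction"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return RankedList(entries=df[["panel", "reaction", "abs_s", "pathway"]])


def _running_extreme(weights: np.ndarray, hits: np.ndarray) -> float:
    """ES for one membership vector over a ranked weight vector.

    Hits advance the running sum by weight/Σ(hit weights); misses retreat it
    by 1/(number of misses). Returns the extreme of largest magnitude
    (the maximum if |max| ≥ |min|, otherwise the minimum).
    """
    n = weights.size
    n_h = int(hits.sum())
    if n_h == 0 or n_h == n:
        raise ValueError("pathway must have at least one hit and one miss in the list")
    n_r = float(weights[hits].sum())
    if n_r == 0:
        # all-zero hit weights: hits contribute nothing, pure depletion walk
        steps = np.where(hits, 0.0, -1.0 / (n - n_h))
    else:
        steps = np.where(hits, weights / n_r, -1.0 / (n - n_h))
    dev = np.cumsum(steps)
    hi = float(dev.max())
    lo = float(dev.min())
    return hi if abs(hi) >= abs(lo) else lo


def enrichment_score(rl: RankedList, pathway: str) -> float:
    """Raw enrichment score of one pathway over the ranked list."""
    weights = rl.entries["abs_s"].to_numpy(dtype=float)
    hits = (rl.entries["pathway"] == pathway).to_numpy()
    return _running_extreme(weights, hits)


def normalize_enrichment(
    rl: RankedList,
    n_perm: int = 100,
    seed: int = 0,
) -> EnrichmentResult:
    """ES, NES and tail p-values for every pathway present in the list.

    For each permutation the pathway-label column of the ranked list is
    shuffled (the |s| values and their order stay fixed) and every pathway's
    ES is recomputed. NES = ES / mean(permuted ES); when the permutation mean
    has magnitude below 1e-12 the NES is reported as NaN rather than divided.
    ``p_pos`` is the fraction of permuted ES ≥ observed (the relevant tail
    for ES > 0), ``p_neg`` the fraction ≤ observed (for ES < 0).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    labels = rl.entries["pathway"].to_numpy()
    weights = rl.entries["abs_s"].to_numpy(dtype=float)
    pathways = sorted(pd.unique(labels))
    if len(pathways) < 2:
        raise ValueError("at least two pathway labels are required")

    observed = {p: _running_extreme(weights, labels == p) for p in pathways}
    perm_scores = {p: np.empty(n_perm) for p in pathways}
    for k in range(n_perm):
        shuffled = rng.permutation(labels)
        for p in pathways:
            perm_scores[p][k] = _running_extreme(weights, shuffled == p)

    rows = []
    for p in pathways:
        es = observed[p]
        perm = perm_scores[p]
        mean_perm = float(perm.mean())
        nes = es / mean_perm if abs(mean_perm) >= 1e-12 else float("nan")
        p_pos = float(np.mean(perm >= es))
        p_neg = float(np.mean(perm <= es))
        rows.append(
            {
                "pathway": p,
                "es": es,
                "nes": nes,
                "p_pos": p_pos,
                "p_neg": p_neg,
                "n_h": int((labels == p).sum()),
                "n_perm": n_perm,
            }
        )
    table = pd.DataFrame(rows).set_index("pathway")
    return EnrichmentResult(table=table)
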