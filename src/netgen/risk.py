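"""Risk-gene scoring: module-level evidence aggregation, seed ensembling, AUROC.

A gene's raw score is its soft-membership-weighted share of the evidence
concentration of each module:

    score(g) = sum_m P(g in m) * e(m),
    e(m)     = sum_{v in evidence} P(v in m) / sum_{all v} P(v in m)

so genes sitting in modules where QTL-regulated evidence genes concentrate
score high. Scores from independently seeded trainings are min-max scaled,
averaged, and standardized to a Z across genes; genes above a Z cutoff are
called putative risk genes. Ranking quality is evaluated as AUROC against an
external benchmark gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from netgen.interactome import InteractomeGraph
from netgen.modules import ModuleAssignment

logger = logging.getLogger(__name__)

DEFAULT_Z_CUTOFF = 1.645  # one-sided 5%


def score_genes(assignment: ModuleAssignment, evidence: Iterable[str]) -> pd.Series:
    """Per-gene raw risk score from module-level evidence concentration.

    Evidence genes absent from the graph are ignored; an empty effective
    evidence set yields all-zero scores with a warning.
    """
    nodes = assignment.nodes
    index = {g: i for i, g in enumerate(nodes)}
    ev_idx = sorted(index[g] for g in set(evidence) if g in index)
    if not ev_idx:
        logger.warning("score_genes: no evidence genes present in the graph; scores are all zero")
        return pd.Series(np.zeros(len(nodes)), index=list(nodes), name="score")
    p = assignment.soft
    module_mass = p.sum(axis=0)  # sum_v P(v in m)
    ev_mass = p[ev_idx].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        concentration = np.where(module_mass > 0, ev_mass / module_mass, 0.0)
    scores = p @ concentration
    return pd.Series(scores, index=list(nodes), name="score")


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


@dataclass
class GeneScoreTable:
    """Per-gene per-seed scores, ensemble mean, standardized Z, and rank."""

    table: pd.DataFrame  # columns: seed_<s>..., ensemble, z, rank

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def z(self) -> pd.Series:
        return self.table["z"]


def ensemble_scores(seed_tables: Sequence[pd.Series]) -> GeneScoreTable:
    """Combine per-seed scores: min-max scale each seed, average, standardize.

    All tables must cover the same gene universe. The Z standardization uses
    the population standard deviation across genes, so Z has mean 0 and
    standard deviation exactly 1.
    """
    if not seed_tables:
        raise ValueError("need at least one seed table")
    universe = set(seed_tables[0].index)
    for i, t in enumerate(seed_tables[1:], start=1):
        if set(t.index) != universe:
            diff = universe.symmetric_difference(t.index)
            raise ValueError(
                f"seed table {i} gene universe differs; symmetric difference: {sorted(diff)[:10]}"
            )
    genes = sorted(universe)
    mat = np.column_stack([_minmax(t.reindex(genes).to_numpy(float)) for t in seed_tables])
    ensemble = mat.mean(axis=1)
    sd = ensemble.std(ddof=0)
    z = (ensemble - ensemble.mean()) / sd if sd > 0 else np.zeros_like(ensemble)
    df = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                      columns=[f"seed_{i}" for i in range(mat.shape[1])])
    df["ensemble"] = ensemble
    df["z"] = z
    df["rank"] = df["z"].rank(ascending=False, method="min").astype(int)
    return GeneScoreTable(df)


def evaluate_auroc(scores: GeneScoreTable | pd.Series, benchmark: Iterable[str]) -> float:
    """AUROC of the score ranking against a benchmark positive set.

    Equals P(score(random positive) > score(random negative)) + 1/2 P(tie),
    over all positive-negative pairs. Benchmark genes outside the scored
    universe are dropped (with a logged count).
    """
    s = scores.z if isinstance(scores, GeneScoreTable) else scores
    bench = set(benchmark)
    in_universe = bench & set(s.index)
    dropped = len(bench) - len(in_universe)
    if dropped:
        logger.info("evaluate_auroc: %d benchmark genes absent from scored universe", dropped)
    if not in_universe:
        raise ValueError("benchmark has no genes in the scored universe")
    y = np.array([g in in_universe for g in s.index])
    if y.all():
        raise ValueError("all scored genes are benchmark positives; AUROC undefined")
    x = s.to_numpy(float)
    # rank-sum form of the Wilcoxon statistic, ties counted as 1/2
    order = pd.Series(x).rank(method="average").to_numpy()
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    auc = (order[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def select_pdrgs(scores: GeneScoreTable, z_cutoff: float = DEFAULT_Z_CUTOFF,
                 top_n: int | None = None) -> list[str]:
    """Genes called as putative risk genes, sorted by descending Z.

    Either all genes with Z >= ``z_cutoff``, or exactly the ``top_n``
    highest-Z genes when ``top_n`` is given.
    """
    ordered = scores.table.sort_values("z", ascending=False, kind="mergesort")
    if top_n is not None:
        return list(ordered.index[:top_n])
    return list(ordered.index[ordered["z"] >= z_cutoff])


def disease_module(g: InteractomeGraph, risk_genes: Iterable[str]) -> InteractomeGraph:
    """Subnetwork induced by risk genes, with self-loops and isolated nodes removed."""
    sub = g.subgraph([x for x in risk_genes if x in g.graph])
    gg = sub.graph
    gg.remove_edges_from(list(nx.selfloop_edges(gg)))
    isolated = [n for n, d in gg.degree() if d == 0]
    gg.remove_nodes_from(isolated)
    return InteractomeGraph(gg)
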