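"""Tissue-specificity z-scores and Fisher-exact gene-set enrichment.

Specificity of gene i in tissue t is z_it = (E_it - mean_i) / sd_i where the
mean and standard deviation are taken across all tissues for that gene;
negative values are clamped to zero ("highly expressed" means above the
gene's own cross-tissue average). Enrichment of a gene set in an annotation
is a one-sided Fisher exact test against the interactome gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class SpecificityTable:
    """Clamped and pre-clamp tissue-specificity z-scores (genes x tissues)."""

    z: pd.DataFrame           # clamped: max(z, 0)
    z_preclamp: pd.DataFrame  # raw standardized values, for diagnostics

    def specific_genes(self, tissue: str) -> list[str]:
        """Genes with strictly positive clamped specificity in ``tissue``."""
        col = self.z[tissue]
        return list(col.index[col > 0])


def tissue_specificity(expr: pd.DataFrame, ddof: int = 1) -> SpecificityTable:
    """Standardize each gene's expression across tissues, then clamp at zero.

    ``expr`` is a genes x tissues matrix of (mean) TPM. Genes constant across
    tissues (sd = 0) get z = 0 everywhere and are logged. The sd convention
    is the sample standard deviation (ddof=1) by default.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 tissues to compute specificity")
    if (expr.to_numpy() < 0).any():
        raise ValueError("TPM values must be nonnegative")
    values = expr.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.info("tissue_specificity: %d constant genes set to z=0", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (values - mean) / sd, 0.0)
    z_df = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    return SpecificityTable(z=z_df.clip(lower=0.0), z_preclamp=z_df)


@dataclass
class EnrichmentResult:
    odds_ratio: float
    pvalue: float
    overlap: int
    n_hits: int
    n_annotation: int
    n_background: int


def fisher_enrichment(
    hits: Iterable[str], annotation: Iterable[str], background: Iterable[str]
) -> EnrichmentResult:
    """One-sided (greater) Fisher exact test for over-representation.

    The 2x2 table is [[overlap, hits - overlap], [annotation - overlap,
    neither]], with the interactome gene universe as background. Hits and
    annotation are intersected with the background first.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background universe is empty")
    h = set(hits) & bg
    a = set(annotation) & bg
    overlap = len(h & a)
    table = [
        [overlap, len(h) - overlap],
        [len(a) - overlap, len(bg) - len(h) - len(a) + overlap],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(
        odds_ratio=float(odds),
        pvalue=float(p),
        overlap=overlap,
        n_hits=len(h),
        n_annotation=len(a),
        n_background=len(bg),
    )


def enrichment_qvalues(results: list[EnrichmentResult]) -> np.ndarray:
    """Benjamini-Hochberg q-values for a family of enrichment tests."""
    pvals = [r.pvalue for r in results]
    return multipletests(pvals, method="fdr_bh")[1]
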