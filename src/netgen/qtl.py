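"""GWAS-xQTL mapping: significance filtering, LD clumping, proxy SNPs, gene joins.

Five QTL resource types link trait-associated variants to genes: eQTL, pQTL
and sQTL records carry an explicit SNP->gene pair and are joined on rsID;
meQTL and haQTL records are genomic intervals (methylation / histone
acetylation peaks) assigned to the nearest protein-coding gene. The surviving
(SNP, QTL type, gene) links form the "regulatory connections" that define the
evidence-gene universe for risk scoring.

Coordinate conventions: GWAS and QTL SNP positions are 1-based; interval
inputs follow BED (0-based half-open) and are converted to 1-based inclusive
at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

SNP_LINKED_TYPES = ("eQTL", "pQTL", "sQTL")
REGION_TYPES = ("meQTL", "haQTL")

DEFAULT_P_THRESHOLD = 1e-5
DEFAULT_R2_CLUMP = 0.1
DEFAULT_CLUMP_WINDOW_BP = 1_000_000
DEFAULT_R2_PROXY = 0.8


@dataclass(frozen=True, order=True)
class VariantRecord:
    """One GWAS summary-statistic row."""

    chrom: str
    pos: int
    snp_id: str
    pvalue: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.snp_id}: p-value must be in (0, 1], got {self.pvalue}")


@dataclass(frozen=True)
class QtlRecord:
    """One molecular-QTL record; SNP-linked or interval-based depending on type."""

    qtl_type: str
    snp_id: str | None = None
    gene: str | None = None
    chrom: str | None = None
    start: int | None = None  # 1-based inclusive
    end: int | None = None    # 1-based inclusive

    def __post_init__(self) -> None:
        if self.qtl_type in SNP_LINKED_TYPES:
            if self.snp_id is None or self.gene is None:
                raise ValueError(f"{self.qtl_type} record requires snp_id and gene")
        elif self.qtl_type in REGION_TYPES:
            if self.chrom is None or self.start is None or self.end is None:
                raise ValueError(f"{self.qtl_type} record requires a chrom/start/end interval")
        else:
            raise ValueError(f"unknown QTL type {self.qtl_type!r}")


@dataclass(frozen=True)
class RegulatoryConnection:
    """One (SNP, QTL type, gene) link surviving the mapping rules."""

    snp_id: str
    qtl_type: str
    gene: str
    lead_flag: bool = False
    proxy_of: str | None = None


class LdTable:
    """Symmetric lookup of pairwise r-squared values; missing pairs read as 0."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset[str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add(a, b, r2)

    def add(self, snp_a: str, snp_b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0,1], got {r2} for ({snp_a},{snp_b})")
        if snp_a != snp_b:
            self._r2[frozenset((snp_a, snp_b))] = r2

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._r2.get(frozenset((snp_a, snp_b)), 0.0)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdTable":
        df = pd.read_csv(path, sep="\t")
        cols = {c.lower(): c for c in df.columns}
        a, b, r2 = cols.get("snp_a", df.columns[0]), cols.get("snp_b", df.columns[1]), cols.get("r2", df.columns[2])
        table = cls()
        for row in df.itertuples(index=False):
            table.add(str(getattr(row, a)), str(getattr(row, b)), float(getattr(row, r2)))
        return table


def read_gwas(path: str | Path) -> list[VariantRecord]:
    """Read GWAS summary statistics (columns: snp, chr, pos, p).

    Rows with a non-numeric or out-of-range p-value are rejected with a
    warning rather than aborting the run. Multiple studies may be
    concatenated upstream; a SNP appearing more than once keeps its minimum p.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chr": str})
    records: dict[str, VariantRecord] = {}
    n_bad = 0
    for row in df.itertuples(index=False):
        try:
            p = float(row.p)
            rec = VariantRecord(chrom=str(row.chr), pos=int(row.pos), snp_id=str(row.snp), pvalue=p)
        except (TypeError, ValueError) as exc:
            n_bad += 1
            logger.warning("read_gwas: rejected row for %s: %s", getattr(row, "snp", "?"), exc)
            continue
        prev = records.get(rec.snp_id)
        if prev is None or rec.pvalue < prev.pvalue:
            records[rec.snp_id] = rec
    if n_bad:
        logger.warning("read_gwas: %d rows rejected", n_bad)
    return sorted(records.values(), key=lambda r: (r.chrom, r.pos))


def filter_gwas_snps(
    variants: Iterable[VariantRecord], p_threshold: float = DEFAULT_P_THRESHOLD
) -> list[VariantRecord]:
    """Keep variants with p strictly below the suggestive-significance threshold."""
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError(f"p_threshold must be in (0,1], got {p_threshold}")
    kept = [v for v in variants if v.pvalue < p_threshold]
    return sorted(kept, key=lambda v: (v.chrom, v.pos))


def ld_clump(
    variants: Iterable[VariantRecord],
    ld: LdTable,
    r2_cutoff: float = DEFAULT_R2_CLUMP,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
) -> list[VariantRecord]:
    """Greedy LD clumping: return the independent lead SNPs.

    Repeatedly promote the most significant remaining SNP to lead status and
    remove every remaining SNP on the same chromosome within ``window_bp``
    base pairs whose r-squared with the lead exceeds ``r2_cutoff``. A missing
    r-squared is treated as 0 (independent).
    """
    remaining = sorted(variants, key=lambda v: (v.pvalue, v.chrom, v.pos))
    leads: list[VariantRecord] = []
    while remaining:
        lead = remaining.pop(0)
        leads.append(lead)
        remaining = [
            v
            for v in remaining
            if not (
                v.chrom == lead.chrom
                and abs(v.pos - lead.pos) <= window_bp
                and ld.r2(v.snp_id, lead.snp_id) > r2_cutoff
            )
        ]
    return sorted(leads, key=lambda v: (v.chrom, v.pos))


def find_proxy_snps(
    leads: Iterable[VariantRecord],
    candidates: Iterable[VariantRecord],
    ld: LdTable,
    r2_proxy: float = DEFAULT_R2_PROXY,
) -> dict[str, set[str]]:
    """Map each lead SNP to candidates in strong LD (r-squared strictly > cutoff).

    A candidate may proxy multiple leads; a lead never proxies itself.
    """
    out: dict[str, set[str]] = {}
    candidates = list(candidates)
    for lead in leads:
        proxies = {
            c.snp_id
            for c in candidates
            if c.snp_id != lead.snp_id and ld.r2(lead.snp_id, c.snp_id) > r2_proxy
        }
        if proxies:
            out[lead.snp_id] = proxies
    return out


def map_snp_qtl_genes(
    gwas_snps: Iterable[VariantRecord], qtls: Iterable[QtlRecord]
) -> list[RegulatoryConnection]:
    """Join SNP-linked QTLs (eQTL/pQTL/sQTL) with GWAS SNPs on rsID.

    Emits one connection per distinct (snp, qtl_type, gene) triple whose SNP
    appears in both inputs.
    """
    gwas_ids = {v.snp_id for v in gwas_snps}
    seen: set[tuple[str, str, str]] = set()
    out: list[RegulatoryConnection] = []
    for q in qtls:
        if q.qtl_type not in SNP_LINKED_TYPES:
            raise ValueError(f"map_snp_qtl_genes expects SNP-linked QTLs, got {q.qtl_type}")
        if q.snp_id in gwas_ids:
            key = (q.snp_id, q.qtl_type, q.gene)
            if key not in seen:
                seen.add(key)
                out.append(RegulatoryConnection(snp_id=q.snp_id, qtl_type=q.qtl_type, gene=q.gene))
    return out


@dataclass(frozen=True)
class GeneAnnotation:
    """Protein-coding gene bodies: symbol -> (chrom, start, end), 1-based inclusive."""

    genes: tuple[tuple[str, str, int, int], ...]  # (symbol, chrom, start, end)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneAnnotation":
        """Read a BED file (chrom, start, end, name, ...); 0-based half-open -> 1-based."""
        rows = []
        with Path(path).open() as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                rows.append((f[3].strip().upper(), f[0], int(f[1]) + 1, int(f[2])))
        return cls(genes=tuple(sorted(rows)))

    def by_chrom(self) -> dict[str, list[tuple[str, int, int]]]:
        out: dict[str, list[tuple[str, int, int]]] = {}
        for sym, chrom, start, end in self.genes:
            out.setdefault(chrom, []).append((sym, start, end))
        return out

    def symbols(self) -> set[str]:
        return {sym for sym, *_ in self.genes}


def _interval_gene_distance(start: int, end: int, g_start: int, g_end: int) -> int:
    """Gap between two 1-based inclusive intervals; 0 when they overlap."""
    if end < g_start:
        return g_start - end
    if g_end < start:
        return start - g_end
    return 0


def map_region_nearest_gene(
    regions: Iterable[QtlRecord], annotation: GeneAnnotation
) -> list[RegulatoryConnection]:
    """Assign each meQTL/haQTL interval to the nearest protein-coding gene.

    Distance is the gap between the interval and the gene body on the same
    chromosome (0 when they overlap); ties break lexicographically by gene
    symbol and both candidates are logged. Regions on chromosomes absent from
    the annotation are skipped with a warning. The connection carries the
    region's associated GWAS SNP.
    """
    genes_by_chrom = annotation.by_chrom()
    seen: set[tuple[str, str, str]] = set()
    out: list[RegulatoryConnection] = []
    for q in regions:
        if q.qtl_type not in REGION_TYPES:
            raise ValueError(f"map_region_nearest_gene expects interval QTLs, got {q.qtl_type}")
        genes = genes_by_chrom.get(q.chrom)
        if not genes:
            logger.warning(
                "map_region_nearest_gene: chromosome %s not in annotation; region skipped", q.chrom
            )
            continue
        scored = sorted(
            (( _interval_gene_distance(q.start, q.end, gs, ge), sym) for sym, gs, ge in genes)
        )
        best_dist, best_sym = scored[0]
        if len(scored) > 1 and scored[1][0] == best_dist:
            logger.info(
                "map_region_nearest_gene: tie at distance %d between %s and %s; keeping %s",
                best_dist, best_sym, scored[1][1], best_sym,
            )
        snp = q.snp_id if q.snp_id is not None else f"{q.chrom}:{q.start}-{q.end}"
        key = (snp, q.qtl_type, best_sym)
        if key not in seen:
            seen.add(key)
            out.append(RegulatoryConnection(snp_id=snp, qtl_type=q.qtl_type, gene=best_sym))
    return out


def annotate_leads(
    connections: Iterable[RegulatoryConnection],
    leads: Iterable[VariantRecord],
    proxies: Mapping[str, set[str]] | None = None,
) -> list[RegulatoryConnection]:
    """Flag connections whose SNP is a clump lead or a proxy of one."""
    lead_ids = {v.snp_id for v in leads}
    proxy_to_lead: dict[str, str] = {}
    if proxies:
        for lead, prox_set in sorted(proxies.items()):
            for p in sorted(prox_set):
                proxy_to_lead.setdefault(p, lead)
    out = []
    for c in connections:
        out.append(
            replace(
                c,
                lead_flag=c.snp_id in lead_ids,
                proxy_of=proxy_to_lead.get(c.snp_id),
            )
        )
    return out


@dataclass(frozen=True)
class RegulatorySummary:
    """Per-QTL-type connection tallies and the regulated-gene universe."""

    counts: dict[str, int]
    percentages: dict[str, float]
    gene_qtl_types: dict[str, set[str]]
    regulated_genes: set[str]

    @property
    def n_connections(self) -> int:
        return sum(self.counts.values())


def build_regulatory_table(connections: Iterable[RegulatoryConnection]) -> RegulatorySummary:
    """Summarize connections: counts and percentages per QTL type, gene universe."""
    counts: dict[str, int] = {}
    gene_types: dict[str, set[str]] = {}
    for c in connections:
        counts[c.qtl_type] = counts.get(c.qtl_type, 0) + 1
        gene_types.setdefault(c.gene, set()).add(c.qtl_type)
    total = sum(counts.values())
    pct = {t: (100.0 * n / total if total else 0.0) for t, n in counts.items()}
    return RegulatorySummary(
        counts=counts,
        percentages=pct,
        gene_qtl_types=gene_types,
        regulated_genes=set(gene_types),
    )


def restrict_to_coding(
    connections: Iterable[RegulatoryConnection], annotation: GeneAnnotation
) -> list[RegulatoryConnection]:
    """Drop connections whose gene is not in the protein-coding annotation."""
    coding = annotation.symbols()
    return [c for c in connections if c.gene in coding]
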