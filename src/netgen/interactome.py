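"""Protein-protein interactome: loading, cleaning, LCC extraction, normalization.

The interactome is an undirected, unweighted graph over gene symbols. All
downstream network computation (module learning, network proximity) runs on
its largest connected component (LCC), whose symmetrically normalized
adjacency D^(-1/2) A D^(-1/2) feeds the graph-convolutional model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class PPIFormatError(ValueError):
    """Raised for malformed or empty protein-interaction edge lists."""


@dataclass(frozen=True)
class InteractomeGraph:
    """Undirected gene-symbol graph with a deterministic (lexicographic) node order.

    Parameters
    ----------
    graph
        The underlying :class:`networkx.Graph`. Self-loops must already be
        removed; edges are unweighted.

    Notes
    -----
    Node order is fixed lexicographically so that adjacency matrices, model
    weights and scores are reproducible across runs regardless of input row
    order.
    """

    graph: nx.Graph
    nodes: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(sorted(self.graph.nodes())))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def index_of(self) -> dict[str, int]:
        """Map gene symbol -> row/column index in :meth:`adjacency`."""
        return {g: i for i, g in enumerate(self.nodes)}

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric binary adjacency in the fixed lexicographic node order."""
        return nx.to_scipy_sparse_array(self.graph, nodelist=list(self.nodes), format="csr")

    def degrees(self) -> np.ndarray:
        """Per-node edge counts, aligned with :attr:`nodes`."""
        return np.asarray([self.graph.degree(g) for g in self.nodes], dtype=np.int64)

    def subgraph(self, genes) -> "InteractomeGraph":
        return InteractomeGraph(nx.Graph(self.graph.subgraph(genes)))


@dataclass(frozen=True)
class NormalizedAdjacency:
    """A_hat = D^(-1/2) A D^(-1/2), indexed like the source graph's node order."""

    matrix: sp.csr_matrix
    nodes: tuple[str, ...]

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def _looks_like_header(fields: list[str]) -> bool:
    lowered = [f.strip().lower() for f in fields[:2]]
    header_words = {"gene", "gene1", "gene2", "gene_a", "gene_b", "protein",
                    "protein1", "protein2", "source", "target", "symbol",
                    "symbol1", "symbol2", "node1", "node2", "from", "to"}
    return any(w in header_words for w in lowered)


def load_ppi(path: str | Path, sep: str = "\t") -> InteractomeGraph:
    """Read an edge-list TSV into a cleaned :class:`InteractomeGraph`.

    The first two columns are gene symbols; extra columns (e.g. confidence
    weights) are ignored. Symbols are upper-cased and whitespace-stripped.
    Self-loops are dropped and duplicate / reversed pairs collapse to a
    single undirected edge. A header row is auto-detected by common column
    names in its first two fields.

    Raises
    ------
    PPIFormatError
        If the file is empty or any row has fewer than two fields (the
        message carries the 1-based line number).
    """
    path = Path(path)
    g = nx.Graph()
    n_self_loops = 0
    with path.open() as fh:
        first_data_line = True
        any_row = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(sep)
            if len(fields) < 2:
                raise PPIFormatError(
                    f"{path}: line {lineno}: expected >=2 tab-separated fields, got {len(fields)}"
                )
            if first_data_line and _looks_like_header(fields):
                first_data_line = False
                continue
            first_data_line = False
            a = fields[0].strip().upper()
            b = fields[1].strip().upper()
            if not a or not b:
                raise PPIFormatError(f"{path}: line {lineno}: empty gene symbol")
            any_row = True
            if a == b:
                n_self_loops += 1
                continue
            g.add_edge(a, b)
    if not any_row:
        raise PPIFormatError(f"{path}: no interaction rows found")
    if n_self_loops:
        logger.info("load_ppi: dropped %d self-loop rows", n_self_loops)
    return InteractomeGraph(g)


def extract_lcc(g: InteractomeGraph) -> InteractomeGraph:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the component containing the lexicographically
    smallest node, so the result is deterministic.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot extract LCC of an empty graph")
    components = list(nx.connected_components(g.graph))
    max_size = max(len(c) for c in components)
    tied = [c for c in components if len(c) == max_size]
    best = min(tied, key=lambda c: min(c))
    return g.subgraph(best)


def symmetric_normalize(g: InteractomeGraph) -> NormalizedAdjacency:
    """Compute A_hat = D^(-1/2) A D^(-1/2) for the graph.

    Every node must have degree >= 1; run :func:`extract_lcc` first on graphs
    that may contain isolated nodes.
    """
    deg = g.degrees().astype(float)
    if np.any(deg == 0):
        zero = [g.nodes[i] for i in np.flatnonzero(deg == 0)[:5]]
        raise ValueError(
            f"zero-degree nodes present (e.g. {zero}); extract the largest "
            "connected component before normalizing"
        )
    a = g.adjacency().astype(float)
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    a_hat = (d_inv_sqrt @ a @ d_inv_sqrt).tocsr()
    return NormalizedAdjacency(matrix=a_hat, nodes=g.nodes)
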