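"""Self-supervised functional-module detection on the interactome.

The model is a two-layer graph convolution in which each layer aggregates a
node's 0th-, 1st- and 2nd-order neighborhoods:

    H(i+1) = ReLU( sum_{j=0..2} A_hat^j H(i) W_j(i) ),   A_hat = D^-1/2 A D^-1/2

followed by a jumping-knowledge (JK) concatenation of all layer outputs,
H_bar = H(1) || ... || H(L). Second order is the highest aggregated because in
protein interaction networks higher-order neighborhoods are largely redundant
with the first two (triangle-rich structure, shared functional annotation of
2nd-order neighbors).

Module membership is a softmax head on H_bar, trained self-supervised by
gradient ascent on the soft modularity of the partition plus a weighted
adjacency-reconstruction (binary cross-entropy) term on sampled edges and
non-edges. Everything is plain numpy with hand-written backpropagation and an
Adam optimizer; training is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from netgen.interactome import InteractomeGraph, NormalizedAdjacency, symmetric_normalize

MAX_ORDER = 2  # neighborhood orders 0..2 aggregated per layer


@dataclass
class LayerWeights:
    """Weights of one propagation layer: one matrix per neighborhood order 0..2."""

    w: tuple[np.ndarray, np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.w) != MAX_ORDER + 1:
            raise ValueError(f"expected {MAX_ORDER + 1} weight matrices, got {len(self.w)}")
        shapes = {m.shape for m in self.w}
        if len(shapes) != 1:
            raise ValueError(f"order weights must share a shape, got {shapes}")


@dataclass
class ModuleAssignment:
    """Soft module memberships (rows sum to 1) plus derived hard labels."""

    soft: np.ndarray  # nodes x K
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.soft.shape[0] != len(self.nodes):
            raise ValueError("membership rows must match node count")

    @property
    def n_modules(self) -> int:
        return self.soft.shape[1]

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.soft, axis=1)

    def membership(self, gene: str) -> np.ndarray:
        return self.soft[self.nodes.index(gene)]


def _neighborhood_stack(a_hat: sp.csr_matrix, h: np.ndarray) -> list[np.ndarray]:
    """[H, A_hat H, A_hat^2 H] with powers applied by repeated multiplication."""
    out = [h]
    for _ in range(MAX_ORDER):
        out.append(a_hat @ out[-1])
    return out


def propagate_layer(
    h: np.ndarray, a_hat: NormalizedAdjacency | sp.spmatrix, weights: LayerWeights
) -> np.ndarray:
    """One propagation layer: ReLU( sum_j A_hat^j H W_j )."""
    mat = a_hat.matrix if isinstance(a_hat, NormalizedAdjacency) else a_hat
    n = mat.shape[0]
    if h.shape[0] != n:
        raise ValueError(f"feature matrix has {h.shape[0]} rows but A_hat is {n}x{n}")
    d_in = h.shape[1]
    for j, w in enumerate(weights.w):
        if w.shape[0] != d_in:
            raise ValueError(
                f"weight W_{j} has input width {w.shape[0]} but features have width {d_in}"
            )
    stack = _neighborhood_stack(sp.csr_matrix(mat), h)
    z = sum(m @ w for m, w in zip(stack, weights.w))
    return np.maximum(z, 0.0)


def jk_concat(layers: list[np.ndarray]) -> np.ndarray:
    """Jumping-knowledge representation: column-wise concatenation of layer outputs."""
    if not layers:
        raise ValueError("need at least one layer output")
    rows = {h.shape[0] for h in layers}
    if len(rows) != 1:
        raise ValueError(f"layer outputs disagree on row count: {sorted(rows)}")
    return np.concatenate(layers, axis=1)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def soft_modularity(p: np.ndarray, adj: sp.spmatrix, deg: np.ndarray) -> float:
    """Modularity of a soft partition: (1/2m)[tr(P^T A P) - ||d^T P||^2 / 2m]."""
    two_m = float(deg.sum())
    if two_m == 0:
        return 0.0
    ap = adj @ p
    dtp = deg @ p
    return (np.sum(p * ap) - dtp @ dtp / two_m) / two_m


@dataclass
class _AdamState:
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = b1 * self.m.get(k, 0.0) + (1 - b1) * g
            self.v[k] = b2 * self.v.get(k, 0.0) + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def _init_features(n: int, rng: np.random.Generator, max_onehot: int = 512,
                   proj_width: int = 128) -> np.ndarray:
    """One-hot node identity; for large graphs a Gaussian projection to proj_width."""
    if n <= max_onehot:
        return np.eye(n)
    return rng.standard_normal((n, proj_width)) / np.sqrt(proj_width)


class ModuleModel:
    """Two-layer propagation + JK + softmax assignment head + reconstruction head.

    Parameters live in a flat dict so the Adam update and finite-difference
    gradient checks can iterate over them uniformly.
    """

    def __init__(self, d_in: int, k: int, hidden: int, d_embed: int,
                 rng: np.random.Generator):
        def glorot(a: int, b: int) -> np.ndarray:
            return rng.standard_normal((a, b)) * np.sqrt(2.0 / (a + b))

        self.params: dict[str, np.ndarray] = {}
        dims = [d_in, hidden, hidden]
        for layer in range(2):
            for j in range(MAX_ORDER + 1):
                self.params[f"W{j}_{layer}"] = glorot(dims[layer], dims[layer + 1])
        d_jk = dims[1] + dims[2]
        self.params["C"] = glorot(d_jk, k)        # assignment head
        self.params["E"] = glorot(d_jk, d_embed)  # reconstruction head
        self.k = k

    def layer_weights(self, layer: int) -> LayerWeights:
        return LayerWeights(tuple(self.params[f"W{j}_{layer}"] for j in range(MAX_ORDER + 1)))

    def forward(self, a_hat: sp.csr_matrix, h0: np.ndarray) -> dict[str, np.ndarray]:
        cache: dict[str, np.ndarray] = {"H0": h0}
        h = h0
        for layer in range(2):
            stack = _neighborhood_stack(a_hat, h)
            z = sum(stack[j] @ self.params[f"W{j}_{layer}"] for j in range(MAX_ORDER + 1))
            h = np.maximum(z, 0.0)
            cache[f"stack{layer}"] = stack
            cache[f"Z{layer}"] = z
            cache[f"H{layer + 1}"] = h
        hbar = jk_concat([cache["H1"], cache["H2"]])
        cache["Hbar"] = hbar
        cache["P"] = _softmax(hbar @ self.params["C"])
        cache["Zemb"] = hbar @ self.params["E"]
        return cache

    def loss_and_grads(
        self,
        a_hat: sp.csr_matrix,
        h0: np.ndarray,
        adj: sp.csr_matrix,
        deg: np.ndarray,
        pairs: np.ndarray,
        labels: np.ndarray,
        lam: float,
    ) -> tuple[float, dict[str, np.ndarray], dict[str, np.ndarray]]:
        """Loss = -soft_modularity(P) + lam * BCE(sigmoid(z_u . z_v), A_uv) on pairs."""
        cache = self.forward(a_hat, h0)
        p, hbar, zemb = cache["P"], cache["Hbar"], cache["Zemb"]
        two_m = float(deg.sum())

        ap = adj @ p
        dtp = deg @ p
        q = (np.sum(p * ap) - dtp @ dtp / two_m) / two_m

        u, v = pairs[:, 0], pairs[:, 1]
        logits = np.sum(zemb[u] * zemb[v], axis=1)
        # stable BCE-with-logits
        bce = np.mean(np.maximum(logits, 0) - logits * labels + np.log1p(np.exp(-np.abs(logits))))
        loss = -q + lam * bce

        # --- backward ---
        # modularity -> P
        dq_dp = (2.0 * ap - 2.0 * np.outer(deg, dtp) / two_m) / two_m
        dl_dp = -dq_dp
        # softmax backward (rows independent)
        tmp = dl_dp * p
        dl_ds = tmp - p * tmp.sum(axis=1, keepdims=True)
        grads: dict[str, np.ndarray] = {}
        grads["C"] = hbar.T @ dl_ds
        d_hbar = dl_ds @ self.params["C"].T

        # reconstruction -> Zemb
        sig = 1.0 / (1.0 + np.exp(-logits))
        g_logit = lam * (sig - labels) / len(labels)
        d_zemb = np.zeros_like(zemb)
        np.add.at(d_zemb, u, g_logit[:, None] * zemb[v])
        np.add.at(d_zemb, v, g_logit[:, None] * zemb[u])
        grads["E"] = hbar.T @ d_zemb
        d_hbar += d_zemb @ self.params["E"].T

        w1 = cache["H1"].shape[1]
        d_h = {2: d_hbar[:, w1:], 1: d_hbar[:, :w1].copy()}
        for layer in (1, 0):
            dz = d_h[layer + 1] * (cache[f"Z{layer}"] > 0)
            stack = cache[f"stack{layer}"]
            back = np.zeros_like(cache["H0"] if layer == 0 else cache["H1"])
            for j in range(MAX_ORDER + 1):
                grads[f"W{j}_{layer}"] = stack[j].T @ dz
                # (A_hat^j)^T = A_hat^j by symmetry
                prop = dz
                for _ in range(j):
                    prop = a_hat @ prop
                back += prop @ self.params[f"W{j}_{layer}"].T
            if layer == 1:
                d_h[1] += back
        return loss, grads, cache


def _sample_pairs(adj: sp.csr_matrix, n_edges_sample: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample an equal number of edges and (rejection-sampled) non-edges."""
    coo = sp.triu(adj, k=1).tocoo()
    edges = np.column_stack([coo.row, coo.col])
    n = adj.shape[0]
    take = min(n_edges_sample, len(edges))
    idx = rng.choice(len(edges), size=take, replace=False)
    pos = edges[idx]
    neg = []
    adj_lil = adj.tolil()
    while len(neg) < take:
        a, b = rng.integers(0, n, size=2)
        if a != b and not adj_lil[a, b]:
            neg.append((a, b))
    pairs = np.vstack([pos, np.array(neg, dtype=np.int64)])
    labels = np.concatenate([np.ones(take), np.zeros(take)])
    return pairs, labels


def train_modules(
    g: InteractomeGraph,
    k: int,
    seed: int,
    epochs: int = 200,
    lr: float = 1e-3,
    hidden: int = 32,
    d_embed: int = 16,
    lam: float = 1.0,
    edges_per_epoch: int = 512,
) -> ModuleAssignment:
    """Train the self-supervised module model and return soft memberships.

    The graph must be connected (run LCC extraction first) and ``k`` must not
    exceed the node count. All randomness (weight init, edge sampling) comes
    from the single ``seed``, so two runs with identical arguments produce
    identical assignments.
    """
    n = g.n_nodes
    if k < 2:
        raise ValueError("need at least 2 modules")
    if k > n:
        raise ValueError(f"k={k} exceeds node count {n}")
    if not nx.is_connected(g.graph):
        raise ValueError("graph must be connected; extract the LCC first")

    rng = np.random.default_rng(seed)
    a_hat = sp.csr_matrix(symmetric_normalize(g).matrix)
    adj = sp.csr_matrix(g.adjacency().astype(float))
    deg = g.degrees().astype(float)
    h0 = _init_features(n, rng)

    model = ModuleModel(h0.shape[1], k, hidden, d_embed, rng)
    opt = _AdamState()
    for _ in range(epochs):
        pairs, labels = _sample_pairs(adj, edges_per_epoch, rng)
        _, grads, _ = model.loss_and_grads(a_hat, h0, adj, deg, pairs, labels, lam)
        opt.step(model.params, grads, lr)

    cache = model.forward(a_hat, h0)
    return ModuleAssignment(soft=cache["P"], nodes=g.nodes)
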