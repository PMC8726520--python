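"""LINE graph embedding: first- and second-order proximity by edge sampling.

First-order proximity models each undirected edge directly,

    p1(v_b | v_a) = sigmoid(u_b . u_a),        L1 = -sum_E w_ab log p1,

while second-order proximity models the neighbourhood distribution of each
vertex with a separate "context" vector per node,

    p2(v_b | v_a) = exp(c_b . u_a) / sum_k exp(c_k . u_a),
    L2 = -sum_E w_ab log p2(v_b | v_a),

against the empirical distributions p1'(a,b) = w_ab / W and
p2'(b|a) = w_ab / d_a.  Training replaces the full softmax with negative
sampling (noise proportional to degree^0.75) and draws edges in minibatches
with a linearly decaying learning rate; undirected edges are expanded to
two directed edges for the second order.  The exact objectives survive in
:func:`exact_losses` / :func:`exact_descent`, which serve as small-graph
oracles for the sampled trainer.

The final behaviour vector of a node is the concatenation
[first-order | second-order], each half of width ``dim_total / 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .man_graph import MANGraph, NodeRef

logger = logging.getLogger(__name__)

MAX_DOT = 35.0  # clamp for exp() stability


class EmbeddingError(RuntimeError):
    pass


@dataclass
class LineConfig:
    dim_total: int = 64
    negatives_k: int = 5
    initial_lr: float = 0.025
    total_samples: int | None = None  # default 100 * |E|
    batch_size: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim_total % 2:
            raise ValueError("dim_total must be even (half per order)")
        if self.negatives_k < 1:
            raise ValueError("negatives_k must be >= 1")


@dataclass
class EmbeddingResult:
    """Per-node first-order, second-order and context vectors."""

    nodes: list[NodeRef]
    index: dict[NodeRef, int]
    first: np.ndarray  # (n, d/2)
    second: np.ndarray  # (n, d/2)
    context: np.ndarray  # (n, d/2)
    loss_trace_l1: list[float] = field(default_factory=list)
    loss_trace_l2: list[float] = field(default_factory=list)

    def vector(self, node: NodeRef) -> np.ndarray:
        """Behaviour vector: first-order then second-order halves."""
        i = self.index[node]
        return np.concatenate([self.first[i], self.second[i]])

    @property
    def dim_total(self) -> int:
        return self.first.shape[1] + self.second.shape[1]


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -MAX_DOT, MAX_DOT)))


def first_order_prob(u_a: np.ndarray, u_b: np.ndarray) -> float:
    """p1 = sigmoid(u_b . u_a); symmetric in its arguments."""
    return float(_sigmoid(float(np.dot(u_a, u_b))))


def second_order_prob(a: NodeRef, b: NodeRef, emb: EmbeddingResult) -> float:
    """Full-softmax probability that b is generated as context of a."""
    ua = emb.second[emb.index[a]]
    scores = np.clip(emb.context @ ua, -MAX_DOT, MAX_DOT)
    m = scores.max()
    ex = np.exp(scores - m)
    return float(ex[emb.index[b]] / ex.sum())


def empirical_distributions(
    g: MANGraph,
) -> tuple[dict[tuple[NodeRef, NodeRef], float], dict[tuple[NodeRef, NodeRef], float]]:
    """(p1' per undirected edge, p2' per directed edge).

    p1'(a,b) = w_ab / W; p2'(b|a) = w_ab / d_a.  Raises on an isolated
    node (its p2' row would be undefined) — structurally impossible here
    because MANGraph nodes exist only through edges, but kept as a guard.
    """
    if len(g) == 0:
        raise EmbeddingError("empty graph")
    w_total = g.total_weight
    p1 = {}
    p2 = {}
    for e in g.edges:
        p1[(e.u, e.v)] = e.weight / w_total
    for n in g.nodes:
        d = g.degree(n)
        if d == 0:
            raise EmbeddingError(f"isolated node {n.id!r}: p2' undefined")
        for nbr, w in g.neighbors(n):
            p2[(n, nbr)] = w / d
    return p1, p2


# ---------------------------------------------------------------------------
# Exact objectives (small-graph oracle)
# ---------------------------------------------------------------------------

def exact_losses(g: MANGraph, emb: EmbeddingResult, guard: int = 2000) -> tuple[float, float]:
    """Exact L1 and L2.

    L1 sums each undirected edge once; L2 sums both directions of every
    edge with the full softmax over all |V| context vectors, matching the
    trainer's directed expansion.  Guarded to small graphs — the softmax
    is quadratic in |V|.
    """
    n = len(g)
    if n > guard:
        raise EmbeddingError(
            f"|V|={n} exceeds exact-loss guard ({guard}); use a sampled estimate"
        )
    idx = emb.index
    l1 = 0.0
    for e in g.edges:
        l1 -= e.weight * np.log(
            _sigmoid(float(np.dot(emb.first[idx[e.u]], emb.first[idx[e.v]])))
        )
    scores = np.clip(emb.second @ emb.context.T, -MAX_DOT, MAX_DOT)  # (n, n)
    logz = np.log(np.exp(scores - scores.max(axis=1, keepdims=True)).sum(axis=1)) + scores.max(axis=1)
    l2 = 0.0
    for e in g.edges:
        for a, b in ((idx[e.u], idx[e.v]), (idx[e.v], idx[e.u])):
            l2 -= e.weight * (scores[a, b] - logz[a])
    if not (np.isfinite(l1) and np.isfinite(l2)):
        raise EmbeddingError("non-finite exact loss")
    return float(l1), float(l2)


def exact_descent(
    g: MANGraph, emb: EmbeddingResult, order: int, lr: float = 0.05, steps: int = 1
) -> list[float]:
    """Full-gradient descent on the exact L1 (order=1) or L2 (order=2).

    Oracle mode for small graphs: returns the loss trace including the
    value before the first step.  Mutates *emb* in place.
    """
    idx = emb.index
    edges = [(idx[e.u], idx[e.v], e.weight) for e in g.edges]
    trace = [exact_losses(g, emb)[order - 1]]
    for _ in range(steps):
        if order == 1:
            grad = np.zeros_like(emb.first)
            for a, b, w in edges:
                s = _sigmoid(float(np.dot(emb.first[a], emb.first[b])))
                grad[a] -= w * (1.0 - s) * emb.first[b]
                grad[b] -= w * (1.0 - s) * emb.first[a]
            emb.first -= lr * grad
        elif order == 2:
            scores = np.clip(emb.second @ emb.context.T, -MAX_DOT, MAX_DOT)
            scores -= scores.max(axis=1, keepdims=True)
            p = np.exp(scores)
            p /= p.sum(axis=1, keepdims=True)  # p[a, k] = p2(k | a)
            g_u = np.zeros_like(emb.second)
            g_c = np.zeros_like(emb.context)
            for a, b, w in edges:
                for aa, bb in ((a, b), (b, a)):
                    g_u[aa] -= w * (emb.context[bb] - p[aa] @ emb.context)
                    g_c[bb] -= w * emb.second[aa]
                    g_c += w * np.outer(p[aa], emb.second[aa])
            emb.second -= lr * g_u
            emb.context -= lr * g_c
        else:
            raise ValueError("order must be 1 or 2")
        trace.append(exact_losses(g, emb)[order - 1])
    return trace


# ---------------------------------------------------------------------------
# Sampled trainer
# ---------------------------------------------------------------------------

def init_embedding(g: MANGraph, cfg: LineConfig) -> EmbeddingResult:
    """Seeded uniform init in (-0.5/dim, 0.5/dim) per entry."""
    nodes = g.nodes
    n, half = len(nodes), cfg.dim_total // 2
    rng = np.random.default_rng(cfg.seed)
    lim = 0.5 / half
    return EmbeddingResult(
        nodes=nodes,
        index={nd: i for i, nd in enumerate(nodes)},
        first=rng.uniform(-lim, lim, size=(n, half)),
        second=rng.uniform(-lim, lim, size=(n, half)),
        context=rng.uniform(-lim, lim, size=(n, half)),
    )


def _sample_discrete(rng: np.random.Generator, cum: np.ndarray, size) -> np.ndarray:
    """Inverse-CDF sampling from a cumulative weight vector."""
    return np.searchsorted(cum, rng.random(size) * cum[-1], side="right")


def _sgd_pass(
    emb_src: np.ndarray,
    emb_dst: np.ndarray,
    edges: np.ndarray,
    edge_cum: np.ndarray,
    noise_cum: np.ndarray,
    cfg: LineConfig,
    rng: np.random.Generator,
    total: int,
) -> list[float]:
    """Shared negative-sampling SGD over directed (src, dst) tables.

    First order passes the same matrix as src and dst (gradients flow to
    both endpoints' vertex vectors); second order passes vertex and
    context matrices.  Returns a coarse trace of the sampled objective.
    """
    k = cfg.negatives_k
    # cap the batch so a node sees ~1 accumulated update per step; larger
    # batches on small graphs compound into giant steps and diverge
    batch = min(cfg.batch_size, max(16, len(noise_cum) // 2))
    trace: list[float] = []
    done = 0
    while done < total:
        b = min(batch, total - done)
        frac = done / total
        lr = cfg.initial_lr * max(1.0 - frac, 0.01)
        eidx = _sample_discrete(rng, edge_cum, b)
        src = edges[eidx, 0]
        dst = edges[eidx, 1]
        neg = _sample_discrete(rng, noise_cum, (b, k))

        u = emb_src[src]  # (b, d)
        v = emb_dst[dst]
        vn = emb_dst[neg]  # (b, k, d)
        s_pos = _sigmoid(np.einsum("bd,bd->b", u, v))
        s_neg = _sigmoid(np.einsum("bd,bkd->bk", u, vn))
        g_pos = 1.0 - s_pos  # d/ds of log sigma
        g_neg = -s_neg

        du = g_pos[:, None] * v + np.einsum("bk,bkd->bd", g_neg, vn)
        dv = g_pos[:, None] * u
        dn = g_neg[:, :, None] * u[:, None, :]

        np.add.at(emb_src, src, lr * du)
        np.add.at(emb_dst, dst, lr * dv)
        np.add.at(emb_dst, neg.ravel(), lr * dn.reshape(-1, dn.shape[-1]))

        trace.append(float(-(np.log(s_pos + 1e-12).mean())))
        done += b
    return trace


def train_line(g: MANGraph, cfg: LineConfig | None = None) -> EmbeddingResult:
    """Train first- and second-order embeddings by edge sampling.

    Each positive edge draw is paired with ``negatives_k`` negatives drawn
    proportional to degree^0.75; the learning rate decays linearly from
    ``initial_lr`` to 1% of it.  Deterministic for a fixed seed.
    """
    cfg = cfg or LineConfig()
    if len(g) < 2:
        raise EmbeddingError("graph too small to embed")
    emb = init_embedding(g, cfg)
    idx = emb.index
    und = np.array([[idx[e.u], idx[e.v]] for e in g.edges], dtype=np.int64)
    w_und = np.array([e.weight for e in g.edges])
    total = cfg.total_samples if cfg.total_samples is not None else 100 * len(und)
    if total < len(und):
        raise ValueError("total_samples must be at least |E|")

    deg = np.zeros(len(emb.nodes))
    for e in g.edges:
        deg[idx[e.u]] += e.weight
        deg[idx[e.v]] += e.weight
    noise_cum = np.cumsum(deg**0.75)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x11E]))

    # both orders sample from the directed expansion of the undirected
    # edge set; a first-order draw of either orientation updates both
    # endpoints in the shared vertex matrix
    di = np.vstack([und, und[:, ::-1]])
    w_di = np.concatenate([w_und, w_und])
    di_cum = np.cumsum(w_di)
    emb.loss_trace_l1 = _sgd_pass(
        emb.first, emb.first, di, di_cum, noise_cum, cfg, rng, total,
    )
    emb.loss_trace_l2 = _sgd_pass(
        emb.second, emb.context, di, di_cum, noise_cum, cfg, rng, total,
    )
    for name, arr in (("first", emb.first), ("second", emb.second), ("context", emb.context)):
        if not np.all(np.isfinite(arr)):
            raise EmbeddingError(
                f"non-finite {name}-order embedding (lr={cfg.initial_lr}, samples={total})"
            )
    return emb


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def dump_embedding(emb: EmbeddingResult, path) -> None:
    """TSV: node_id, node_kind, then the concatenated behaviour vector."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write(f"#dim={emb.dim_total}\torder=first|second\n")
        for node in emb.nodes:
            vals = "\t".join(f"{v:.10g}" for v in emb.vector(node))
            fh.write(f"{node.id}\t{node.kind}\t{vals}\n")
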