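"""Stage 2 — medication-combination efficacy over multi-attribute regimen graphs.

A patient's regimen is a small undirected graph: medications are nodes, every
pair is connected, and edge weights come from a prescription co-occurrence
prior normalised to (0, 1].  Node features concatenate three attribute views:

* ``F_macro`` — pharmacology texts (meridian, property, flavours, side
  effects) embedded by a pluggable text embedder and fused by self-attention;
* ``F_micro`` — target-protein sequences embedded by a pluggable sequence
  embedder and mean-aggregated over a medication's targets;
* ``F_ppi``   — DeepWalk embeddings of the protein-protein interaction
  network, mean-aggregated over the medication's target proteins.

Two edge-aware graph-transformer layers propagate information, a VAE aligns
the node representations (closed-form KL against the standard-normal prior),
and a mean-pooled readout feeds a classifier trained with focal loss:
``L_total = L_KL + L_focal``.

The shipped embedders are deterministic, dependency-free stand-ins for the
pre-trained language models a production deployment would plug in: a seeded
hashing projection for text and a k-mer count (+ optional fixed random
projection) for amino-acid sequences.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .cohort_io import MedicationRecord, RegimenRecord, WeightedEdgeList
from .nn import Adam, Linear, Module, cross_entropy

__all__ = [
    "ATTRIBUTE_SET",
    "HashingTextEmbedder",
    "KmerEmbedder",
    "embed_text_attributes",
    "AttributeAttention",
    "fuse_attributes",
    "embed_protein_sequences",
    "deepwalk_embed",
    "random_walks",
    "WalkCorpus",
    "cooccurrence_edge_weights",
    "AttributeEmbedding",
    "RegimenGraph",
    "build_regimen_graph",
    "FeatureBuilder",
    "GraphTransformerLayer",
    "VariationalAligner",
    "focal_loss",
    "stage2_total_loss",
    "Stage2Config",
    "EfficacyModel",
    "EfficacyResults",
    "rank_pairwise_combinations",
]

ATTRIBUTE_SET = ("Meridian", "Property", "Flavours", "SideEffects")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# pluggable embedder contracts + shipped synthetic stand-ins
# ---------------------------------------------------------------------------

def _string_seed(text: str, salt: int) -> int:
    digest = hashlib.sha256(f"{salt}:{text}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


class HashingTextEmbedder:
    """Deterministic per-string Gaussian projection keyed by a SHA-256 hash.

    Synthetic stand-in for a pre-trained text language model: same string in,
    same fixed-width vector out.
    """

    def __init__(self, dim: int = 16, seed: int = 0):
        self.dim = dim
        self.seed = seed

    def embed(self, text: str) -> np.ndarray:
        if not text:
            return np.zeros(self.dim)
        rng = np.random.default_rng(_string_seed(text, self.seed))
        return rng.normal(0.0, 1.0, self.dim)


class KmerEmbedder:
    """k-mer count featurisation of amino-acid sequences.

    Synthetic stand-in for a pre-trained protein language model.  With
    ``projection_dim`` set, counts pass through a fixed seeded random
    projection; otherwise the raw count vector (20^k wide) is returned.
    """

    def __init__(self, k: int = 2, projection_dim: int | None = 16, seed: int = 0):
        self.k = k
        self.index = {}
        from itertools import product
        for i, kmer in enumerate(product(AMINO_ACIDS, repeat=k)):
            self.index["".join(kmer)] = i
        self.projection = None
        if projection_dim is not None:
            rng = np.random.default_rng(seed)
            self.projection = rng.normal(0, 1 / np.sqrt(len(self.index)),
                                         (len(self.index), projection_dim))

    @property
    def dim(self) -> int:
        return self.projection.shape[1] if self.projection is not None else len(self.index)

    def counts(self, sequence: str) -> np.ndarray:
        out = np.zeros(len(self.index))
        for i in range(len(sequence) - self.k + 1):
            kmer = sequence[i:i + self.k]
            if kmer in self.index:
                out[self.index[kmer]] += 1
        return out

    def embed(self, sequence: str) -> np.ndarray:
        c = self.counts(sequence)
        return c if self.projection is None else c @ self.projection


def embed_text_attributes(texts: dict, embedder) -> tuple[dict, list[str]]:
    """Embed each pharmacology attribute text; empty texts give zero vectors.

    Returns (attribute → vector, list of attributes flagged empty).
    """
    vectors, flagged = {}, []
    for attr in ATTRIBUTE_SET:
        text = texts.get(attr, "")
        if not text:
            flagged.append(attr)
            vectors[attr] = np.zeros(embedder.dim)
        else:
            vectors[attr] = np.asarray(embedder.embed(text), dtype=float)
    return vectors, flagged


class AttributeAttention(Module):
    """Self-attention over attribute tokens, mean-pooled to one macro vector."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dim = dim
        self.w_q = Linear(dim, dim, rng, bias=False)
        self.w_k = Linear(dim, dim, rng, bias=False)
        self.w_v = Linear(dim, dim, rng, bias=False)

    def __call__(self, tokens: Tensor) -> Tensor:
        q, k, v = self.w_q(tokens), self.w_k(tokens), self.w_v(tokens)
        scores = (q @ k.T) * (1.0 / np.sqrt(self.dim))
        return (scores.softmax(axis=-1) @ v).mean(axis=-2)


def fuse_attributes(attr_vectors: list[np.ndarray], attention: AttributeAttention) -> np.ndarray:
    """Fuse per-attribute vectors into ``F_macro`` via self-attention."""
    if not attr_vectors:
        raise ValueError("no attribute vectors to fuse")
    return attention(Tensor(np.stack(attr_vectors))).data


def embed_protein_sequences(sequences: list[str], embedder) -> tuple[np.ndarray, bool]:
    """Mean-aggregate per-target sequence embeddings into ``F_micro``.

    Returns (vector, flagged) where flagged marks a medication with no targets.
    """
    if not sequences:
        return np.zeros(embedder.dim), True
    return np.mean([embedder.embed(s) for s in sequences], axis=0), False


# ---------------------------------------------------------------------------
# DeepWalk: uniform random walks + skip-gram with negative sampling (NumPy)
# ---------------------------------------------------------------------------

@dataclass
class WalkCorpus:
    walks: list
    walks_per_node: int
    window: int
    dim: int
    seed: int


def _adjacency(network: WeightedEdgeList) -> dict:
    adj: dict = {}
    for a, b, _w in network.edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    return {k: sorted(set(v)) for k, v in adj.items()}


def random_walks(network: WeightedEdgeList, walk_length: int, walks_per_node: int,
                 rng: np.random.Generator, nodes: list | None = None) -> list:
    """Uniform-neighbor walks of ``walk_length`` nodes from every node."""
    if walk_length < 2:
        raise ValueError("walk length must be at least 2")
    adj = _adjacency(network)
    nodes = sorted(adj) if nodes is None else nodes
    walks = []
    for _ in range(walks_per_node):
        for start in nodes:
            if start not in adj:
                continue
            walk = [start]
            while len(walk) < walk_length:
                nbrs = adj[walk[-1]]
                walk.append(nbrs[rng.integers(0, len(nbrs))])
            walks.append(walk)
    return walks


def deepwalk_embed(network: WeightedEdgeList, walk_length: int = 10,
                   walks_per_node: int = 10, window: int = 4, dim: int = 16,
                   seed: int = 0, epochs: int = 2, n_negative: int = 3,
                   lr: float = 0.025, nodes: list | None = None) -> dict:
    """DeepWalk node embeddings: random walks fed to skip-gram with negative sampling.

    Nodes isolated in the network (or listed in ``nodes`` but absent from any
    edge) map to zero vectors.
    """
    rng = np.random.default_rng(seed)
    adj = _adjacency(network)
    all_nodes = sorted(set(adj) | set(nodes or []))
    connected = sorted(adj)
    if not connected:
        return {n: np.zeros(dim) for n in all_nodes}
    index = {n: i for i, n in enumerate(connected)}
    walks = random_walks(network, walk_length, walks_per_node, rng, connected)

    # unigram^0.75 negative-sampling table
    freq = np.zeros(len(connected))
    for walk in walks:
        for n in walk:
            freq[index[n]] += 1
    neg_prob = freq ** 0.75
    neg_prob /= neg_prob.sum()

    w_in = rng.normal(0, 0.5 / dim, (len(connected), dim))
    w_out = np.zeros((len(connected), dim))

    pairs = []
    for walk in walks:
        ids = [index[n] for n in walk]
        for pos, center in enumerate(ids):
            lo = max(0, pos - window)
            hi = min(len(ids), pos + window + 1)
            for ctx_pos in range(lo, hi):
                if ctx_pos != pos:
                    pairs.append((center, ids[ctx_pos]))
    pairs = np.array(pairs, dtype=int)

    for _epoch in range(epochs):
        order = rng.permutation(len(pairs))
        negatives = rng.choice(len(connected), size=(len(pairs), n_negative), p=neg_prob)
        for row, pair_idx in enumerate(order):
            center, context = pairs[pair_idx]
            targets = np.concatenate(([context], negatives[row]))
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            vin = w_in[center]
            vout = w_out[targets]
            scores = 1.0 / (1.0 + np.exp(-vout @ vin))
            err = scores - labels
            grad_in = err @ vout
            w_out[targets] -= lr * err[:, None] * vin
            w_in[center] -= lr * grad_in

    out = {n: w_in[index[n]].copy() for n in connected}
    for n in all_nodes:
        out.setdefault(n, np.zeros(dim))
    return out


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def cooccurrence_edge_weights(counts: dict) -> dict:
    """Normalise pair co-occurrence counts by the global maximum (max weight = 1)."""
    if not counts:
        return {}
    top = max(counts.values())
    return {pair: c / top for pair, c in counts.items()}


@dataclass
class AttributeEmbedding:
    f_macro: np.ndarray
    f_micro: np.ndarray
    f_ppi: np.ndarray

    @property
    def h(self) -> np.ndarray:
        """Node feature: concatenation of the three attribute views."""
        return np.concatenate([self.f_macro, self.f_micro, self.f_ppi])

    @property
    def concat_dim(self) -> int:
        return len(self.f_macro) + len(self.f_micro) + len(self.f_ppi)


@dataclass
class RegimenGraph:
    regimen_id: str
    med_ids: list
    features: np.ndarray          # (n_nodes, D_node)
    edges: list                   # (i, j, weight) with node indices
    label: int | None = None
    patient_id: str | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.med_ids)


def _pair_key(a: str, b: str) -> tuple:
    return (a, b) if a <= b else (b, a)


def build_regimen_graph(regimen: RegimenRecord, features: dict,
                        prior_weights: dict, fallback_weight: float) -> RegimenGraph:
    """Complete graph over the regimen's medications with prior edge weights.

    Pairs absent from the co-occurrence prior get ``fallback_weight``.
    """
    meds = sorted(regimen.med_ids)
    for m in meds:
        if m not in features:
            raise KeyError(f"medication {m!r} has no attribute embedding")
    h = np.stack([features[m].h for m in meds])
    edges = []
    for i in range(len(meds)):
        for j in range(i + 1, len(meds)):
            w = prior_weights.get(_pair_key(meds[i], meds[j]), fallback_weight)
            edges.append((i, j, float(w)))
    return RegimenGraph(regimen.regimen_id, meds, h, edges,
                        regimen.outcome_label, regimen.patient_id)


class FeatureBuilder:
    """Builds per-medication attribute embeddings from the three views."""

    def __init__(self, text_dim: int = 16, micro_dim: int = 16, ppi_dim: int = 16,
                 seed: int = 0, kmer_k: int = 2):
        rng = np.random.default_rng(seed)
        self.text_embedder = HashingTextEmbedder(text_dim, seed)
        self.kmer_embedder = KmerEmbedder(kmer_k, micro_dim, seed)
        self.attention = AttributeAttention(text_dim, rng)
        self.ppi_dim = ppi_dim
        self.seed = seed

    def build(self, medications: list[MedicationRecord],
              ppi: WeightedEdgeList) -> dict:
        all_proteins = sorted({p for m in medications for p in m.target_proteins})
        ppi_vectors = deepwalk_embed(ppi, dim=self.ppi_dim, seed=self.seed,
                                     nodes=all_proteins)
        out = {}
        for med in medications:
            attr_vecs, _flags = embed_text_attributes(med.attribute_texts, self.text_embedder)
            f_macro = fuse_attributes([attr_vecs[a] for a in ATTRIBUTE_SET], self.attention)
            sequences = [med.protein_sequences[p] for p in med.target_proteins
                         if p in med.protein_sequences]
            f_micro, _ = embed_protein_sequences(sequences, self.kmer_embedder)
            if med.target_proteins:
                f_ppi = np.mean([ppi_vectors.get(p, np.zeros(self.ppi_dim))
                                 for p in med.target_proteins], axis=0)
            else:
                f_ppi = np.zeros(self.ppi_dim)
            out[med.med_id] = AttributeEmbedding(f_macro, f_micro, f_ppi)
        return out


# ---------------------------------------------------------------------------
# edge-aware graph transformer + VAE + losses
# ---------------------------------------------------------------------------

NEG_INF = -1e30


class GraphTransformerLayer(Module):
    """Attention over graph neighbours with the edge weight added to the key.

    For neighbour j of node i the logit is (h_i W_Q)·(h_j W_K + w_ij)ᵀ/√d_k:
    the scalar edge weight broadcasts over the key vector.  Attention rows are
    a softmax over N(i) only; isolated nodes fall back to a self-loop.
    """

    def __init__(self, d: int, rng: np.random.Generator, activation: str = "relu"):
        self.d = d
        self.w_q = Linear(d, d, rng, bias=False)
        self.w_k = Linear(d, d, rng, bias=False)
        self.w_v = Linear(d, d, rng, bias=False)
        self.activation = activation
        self.last_alpha: np.ndarray | None = None

    def __call__(self, h: Tensor, edge_weight: np.ndarray, neighbor_mask: np.ndarray) -> Tensor:
        """h: (B, N, d); edge_weight, neighbor_mask: (B, N, N). Returns (B, N, d)."""
        mask = neighbor_mask.copy().astype(float)
        isolated = mask.sum(axis=-1) == 0                 # (B, N)
        if isolated.any():                                 # self-loop fallback, w_ii = 0
            b, i = np.nonzero(isolated)
            mask[b, i, i] = 1.0
        q = self.w_q(h)
        k = self.w_k(h)
        v = self.w_v(h)
        # q_i·(k_j + w_ij·1) = q_i·k_j + w_ij * sum(q_i)
        scores = (q @ k.T + q.sum(axis=-1, keepdims=True) * Tensor(edge_weight * mask)) \
            * (1.0 / np.sqrt(self.d))
        scores = scores + Tensor((1.0 - mask) * NEG_INF)
        alpha = scores.softmax(axis=-1)
        row_sums = alpha.data.sum(axis=-1)
        assert np.allclose(row_sums, 1.0, atol=1e-8), "attention rows must sum to 1"
        self.last_alpha = alpha.data
        out = alpha @ v
        if self.activation == "relu":
            return out.relu()
        if self.activation == "tanh":
            return out.tanh()
        return out


class VariationalAligner(Module):
    """Per-node VAE aligning node features against a standard-normal prior."""

    def __init__(self, d: int, latent: int, rng: np.random.Generator):
        self.encoder = Linear(d, 2 * latent, rng)
        # start the posterior at the prior (mu ~ 0, sigma ~ 1): otherwise the
        # initial KL gradient dwarfs the classification signal and collapses
        # the latent before it learns anything
        self.encoder.weight.data *= 0.01
        self.decoder = Linear(latent, d, rng)
        self.latent = latent

    def encode(self, h: Tensor) -> tuple[Tensor, Tensor]:
        params = self.encoder(h)
        mu = params[..., :self.latent]
        log_var = params[..., self.latent:]
        sigma = (0.5 * log_var).exp()
        assert (sigma.data > 0).all(), "sigma must be strictly positive"
        return mu, sigma

    def __call__(self, h: Tensor, eps: np.ndarray | None = None,
                 node_mask: np.ndarray | None = None):
        """Returns (z, reconstruction, L_KL averaged over valid nodes)."""
        mu, sigma = self.encode(h)
        if eps is None:
            z = mu
        else:
            z = mu + sigma * Tensor(eps)
        recon = self.decoder(z)
        kl_per_node = 0.5 * (mu ** 2 + sigma ** 2 - (sigma ** 2).log() - 1.0).sum(axis=-1)
        if node_mask is not None:
            weight = node_mask / node_mask.sum()
            l_kl = (kl_per_node * Tensor(weight)).sum()
        else:
            l_kl = kl_per_node.mean()
        return z, recon, l_kl


def kl_closed_form(mu: np.ndarray, sigma: np.ndarray) -> float:
    """½ Σ (μ² + σ² − log σ² − 1) for one node (sum over latent dims)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    return float(0.5 * np.sum(mu ** 2 + sigma ** 2 - np.log(sigma ** 2) - 1.0))


def focal_loss(p_t, alpha_t=1.0, gamma: float = 2.0):
    """−α_t (1−p_t)^γ log(p_t), averaged over the batch.

    Accepts a Tensor (training path, gradients flow) or array-like.  p_t = 0
    is clipped at 1e-12 with a warning.
    """
    if isinstance(p_t, Tensor):
        if (p_t.data <= 0).any():
            warnings.warn("focal loss: p_t <= 0 clipped at 1e-12")
            p_t = p_t + Tensor(np.where(p_t.data <= 0, 1e-12 - p_t.data, 0.0))
        alpha = alpha_t if isinstance(alpha_t, Tensor) else Tensor(np.asarray(alpha_t, dtype=float))
        return (alpha * (1.0 - p_t) ** gamma * (-p_t.log())).mean()
    p = np.asarray(p_t, dtype=float)
    if (p <= 0).any():
        warnings.warn("focal loss: p_t <= 0 clipped at 1e-12")
        p = np.clip(p, 1e-12, None)
    alpha = np.asarray(alpha_t, dtype=float)
    return float(np.mean(-alpha * (1.0 - p) ** gamma * np.log(p)))


def stage2_total_loss(l_kl, l_focal):
    """Combined stage-2 objective: KL alignment plus focal classification."""
    return l_kl + l_focal


# ---------------------------------------------------------------------------
# EfficacyModel / EfficacyResults
# ---------------------------------------------------------------------------

@dataclass
class Stage2Config:
    d: int = 32
    latent: int = 16
    lr: float = 1e-3
    epochs: int = 40
    batch_size: int = 32
    # alpha_t is a batch-constant scalar (as the focal formula prints); its only
    # effect is to rescale the classification term against L_KL, and 0.25
    # measurably starves the classifier, so the trainer default is 1.0
    alpha_t: float = 1.0
    gamma: float = 2.0
    activation: str = "relu"
    loss: str = "focal"            # "focal" | "cross_entropy"
    recon_weight: float = 0.0      # optional reconstruction term (off per the stated loss)
    n_layers: int = 2


def _pad_graphs(graphs: list[RegimenGraph]):
    """Pad a batch of small graphs to a common node count."""
    n_max = max(g.n_nodes for g in graphs)
    d = graphs[0].features.shape[1]
    feats = np.zeros((len(graphs), n_max, d))
    wmat = np.zeros((len(graphs), n_max, n_max))
    adj = np.zeros((len(graphs), n_max, n_max))
    node_mask = np.zeros((len(graphs), n_max))
    for b, g in enumerate(graphs):
        feats[b, :g.n_nodes] = g.features
        node_mask[b, :g.n_nodes] = 1.0
        for i, j, w in g.edges:
            adj[b, i, j] = adj[b, j, i] = 1.0
            wmat[b, i, j] = wmat[b, j, i] = w
    return feats, wmat, adj, node_mask


class EfficacyModel:
    """Graph-transformer classifier of regimen (medication-combination) efficacy."""

    def __init__(self, graphs: list[RegimenGraph], config: Stage2Config | None = None):
        if not graphs:
            raise ValueError("no regimen graphs")
        self.graphs = list(graphs)
        self.config = config or Stage2Config()
        labels = {g.label for g in graphs if g.label is not None}
        if len(labels) < 2:
            raise ValueError("regimen labels must contain at least two classes")
        self.n_classes = max(labels) + 1
        self.d_node = graphs[0].features.shape[1]
        self._built = False

    def _build(self, rng: np.random.Generator):
        cfg = self.config
        self.input_proj = Linear(self.d_node, cfg.d, rng)
        self.gt_layers = [GraphTransformerLayer(cfg.d, rng, cfg.activation)
                          for _ in range(cfg.n_layers)]
        self.vae = VariationalAligner(cfg.d, cfg.latent, rng)
        self.head = Linear(cfg.latent, self.n_classes, rng)
        self._built = True

    def _params(self):
        return (self.input_proj.parameters()
                + [p for layer in self.gt_layers for p in layer.parameters()]
                + self.vae.parameters() + self.head.parameters())

    def _forward(self, graphs: list[RegimenGraph], rng: np.random.Generator | None = None):
        feats, wmat, adj, node_mask = _pad_graphs(graphs)
        h = self.input_proj(Tensor(feats))
        for layer in self.gt_layers:
            h = layer(h, wmat, adj)
        eps = None
        if rng is not None:
            eps = rng.standard_normal((len(graphs), feats.shape[1], self.config.latent))
        z, recon, l_kl = self.vae(h, eps, node_mask)
        # masked mean pool over valid nodes -> regimen embedding
        weights = node_mask[:, :, None] / node_mask.sum(axis=1)[:, None, None]
        pooled = (z * Tensor(weights)).sum(axis=1)
        logits = self.head(pooled)
        recon_err = (((recon - h.detach()) ** 2).mean(axis=-1) * Tensor(node_mask)).sum() \
            * (1.0 / node_mask.sum())
        return pooled, logits, l_kl, recon_err

    def fit(self, seed: int = 0) -> "EfficacyResults":
        cfg = self.config
        rng = np.random.default_rng(seed)
        if not self._built:
            self._build(rng)
        optimizer = Adam(self._params(), lr=cfg.lr)
        labels = np.array([g.label for g in self.graphs], dtype=int)
        loss_curve = []
        n = len(self.graphs)
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = [self.graphs[i] for i in idx]
                y = labels[idx]
                _pooled, logits, l_kl, recon = self._forward(batch, rng)
                if cfg.loss == "focal":
                    probs = logits.softmax(axis=-1)
                    p_t = probs[np.arange(len(y)), y]
                    l_cls = focal_loss(p_t, cfg.alpha_t, cfg.gamma)
                else:
                    l_cls = cross_entropy(logits, y)
                total = stage2_total_loss(l_kl, l_cls)
                if cfg.recon_weight > 0:
                    total = total + cfg.recon_weight * recon
                optimizer.zero_grad()
                total.backward()
                optimizer.step()
                batch_losses.append(total.item())
            loss_curve.append(float(np.mean(batch_losses)))
        return EfficacyResults(self, loss_curve, seed)


class EfficacyResults:
    """Fitted stage-2 model: efficacy scores and pooled regimen embeddings."""

    def __init__(self, model: EfficacyModel, loss_curve: list[float], seed: int):
        self.model = model
        self.loss_curve = loss_curve
        self.seed = seed

    def predict_proba(self, graphs: list[RegimenGraph]) -> np.ndarray:
        _, logits, _, _ = self.model._forward(graphs, rng=None)  # z = mu at inference
        return logits.softmax(axis=-1).data

    def regimen_embeddings(self, graphs: list[RegimenGraph]) -> np.ndarray:
        pooled, _, _, _ = self.model._forward(graphs, rng=None)
        return pooled.data

    def summary(self) -> str:
        lines = [
            "Efficacy model (stage 2)",
            "=" * 40,
            f"regimens:   {len(self.model.graphs)}",
            f"classes:    {self.model.n_classes}",
            f"node width: {self.model.d_node} -> {self.model.config.d}",
            f"epochs:     {len(self.loss_curve)}",
            f"final loss: {self.loss_curve[-1]:.4f}",
        ]
        return "\n".join(lines)


def rank_pairwise_combinations(results: EfficacyResults, features: dict,
                               prior_weights: dict, fallback_weight: float,
                               top_fraction: float = 0.15,
                               positive_class: int | None = None) -> list:
    """Score every unordered medication pair as a 2-node regimen.

    Returns the pairs whose scores fall in the top ``top_fraction`` (ceil
    convention), sorted descending; ties break lexicographically by id pair.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    med_ids = sorted(features)
    if len(med_ids) < 2:
        raise ValueError("need at least two medications to rank pairs")
    pairs, graphs = [], []
    for i in range(len(med_ids)):
        for j in range(i + 1, len(med_ids)):
            pair = (med_ids[i], med_ids[j])
            record = RegimenRecord(f"pair:{pair[0]}+{pair[1]}", "", frozenset(pair))
            graphs.append(build_regimen_graph(record, features, prior_weights, fallback_weight))
            pairs.append(pair)
    cls = results.model.n_classes - 1 if positive_class is None else positive_class
    scores = results.predict_proba(graphs)[:, cls]
    ranked = sorted(zip(pairs, scores), key=lambda x: (-x[1], x[0]))
    keep = math.ceil(top_fraction * len(ranked))
    return ranked[:keep]
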