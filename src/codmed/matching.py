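"""Stage 3 — contrastive patient-regimen matching in a shared embedding space.

Patient embeddings (from the severity stage) and regimen embeddings (from the
efficacy stage) are projected by two-layer MLPs into one space and trained
with a hinged, bidirectional margin contrastive loss:

    L_dir = 1/(2N) Σ_i max(0, s(anchor_i, neg_i) − s(anchor_i, pos_i) + α)
    L     = ½ (L_regimen→patient + L_patient→regimen)

where s is cosine similarity and α the separation margin.  Candidate regimens
are ranked for a patient by the cosine matching confidence, and retrieval
quality is summarised by HIT@k: the fraction of patients whose true regimen
appears in their top-k list.

The as-printed (unhinged) loss variant is available via ``literal=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import Adam, Linear, Module

__all__ = [
    "MatchRanking",
    "cosine_similarity",
    "match_confidence",
    "contrastive_loss_directional",
    "bidirectional_loss",
    "rank_regimens",
    "hit_at_k",
    "export_rankings",
    "Projector",
    "Stage3Config",
    "MatchingModel",
    "MatchingResults",
]


@dataclass
class MatchRanking:
    patient_id: str
    ranked: list          # (regimen_id, confidence), confidence non-increasing
    k: int

    def top(self, k: int | None = None) -> list:
        return self.ranked[: (self.k if k is None else k)]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """a·b / (‖a‖‖b‖); defined as 0 for a zero vector (with a warning)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("cosine similarity of a zero vector is defined as 0")
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def match_confidence(patient: np.ndarray, regimen: np.ndarray) -> float:
    """Patient-regimen matching confidence: cosine similarity in [-1, 1]."""
    return cosine_similarity(patient, regimen)


def _cosine_rows(a: Tensor, b: Tensor) -> Tensor:
    """Row-wise cosine similarity of two (N, d) tensors (autodiff path)."""
    dots = (a * b).sum(axis=-1)
    na = ((a * a).sum(axis=-1) + 1e-12).sqrt()
    nb = ((b * b).sum(axis=-1) + 1e-12).sqrt()
    return dots / (na * nb)


def contrastive_loss_directional(anchors: Tensor, positives: Tensor, negatives: Tensor,
                                 margin: float = 0.2, literal: bool = False) -> Tensor:
    """Directional margin loss over N (anchor, positive, negative) triplets.

    Hinged by default; ``literal=True`` gives the unhinged printed form
    ``1/(2N) Σ [s(a, pos) − s(a, neg) + α]``.
    """
    if anchors.shape[0] == 0:
        raise ValueError("empty batch")
    s_pos = _cosine_rows(anchors, positives)
    s_neg = _cosine_rows(anchors, negatives)
    if literal:
        terms = s_pos - s_neg + margin
    else:
        terms = (s_neg - s_pos + margin).relu()
    return 0.5 * terms.mean()


def bidirectional_loss(patients: Tensor, regimens: Tensor,
                       patient_negatives: Tensor, regimen_negatives: Tensor,
                       margin: float = 0.2, literal: bool = False) -> Tensor:
    """Average of the two directional losses (regimen→patient and patient→regimen)."""
    l_p2r = contrastive_loss_directional(patients, regimens, regimen_negatives,
                                         margin, literal)
    l_r2p = contrastive_loss_directional(regimens, patients, patient_negatives,
                                         margin, literal)
    return 0.5 * (l_p2r + l_r2p)


def rank_regimens(patient_id: str, patient: np.ndarray, library: dict,
                  k: int = 5) -> MatchRanking:
    """Rank all library regimens by matching confidence, descending.

    Ties break lexicographically by regimen id so output is deterministic.
    """
    if not library:
        raise ValueError("empty regimen library")
    if k > len(library):
        raise ValueError(f"k={k} exceeds library size {len(library)}")
    scored = [(rid, match_confidence(patient, vec)) for rid, vec in library.items()]
    scored.sort(key=lambda x: (-x[1], x[0]))
    return MatchRanking(patient_id, scored, k)


def hit_at_k(rankings: list[MatchRanking], truth: dict, k: int = 10) -> float:
    """Fraction of patients whose true regimen appears in their top-k."""
    if not rankings:
        raise ValueError("no rankings")
    hits = 0
    for ranking in rankings:
        true_regimen = truth[ranking.patient_id]
        if true_regimen not in {rid for rid, _ in ranking.ranked}:
            raise KeyError(f"truth regimen {true_regimen!r} absent from library")
        hits += true_regimen in {rid for rid, _ in ranking.ranked[:k]}
    return hits / len(rankings)


def export_rankings(rankings: list[MatchRanking], tsv_path=None, json_path=None) -> None:
    """Write rankings as TSV (patient_id, rank, regimen_id, confidence) and/or JSON."""
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("patient_id\trank\tregimen_id\tconfidence\n")
            for r in rankings:
                for rank, (rid, conf) in enumerate(r.top(), start=1):
                    fh.write(f"{r.patient_id}\t{rank}\t{rid}\t{conf:.6f}\n")
    if json_path is not None:
        import json
        payload = {r.patient_id: [{"regimen_id": rid, "confidence": round(float(c), 6)}
                                  for rid, c in r.top()] for r in rankings}
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


class Projector(Module):
    """Two-layer nonlinear projection into the shared matching space."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


@dataclass
class Stage3Config:
    shared_dim: int = 32
    hidden: int = 64
    lr: float = 1e-3
    epochs: int = 60
    batch_size: int = 32
    margin: float = 0.2
    literal: bool = False
    recommend_k: int = 5
    evaluate_k: int = 10


class MatchingModel:
    """Contrastive alignment of patient and regimen embeddings.

    Parameters
    ----------
    patient_vectors : patient_id → embedding (from stage 1).
    regimen_vectors : regimen_id → embedding (from stage 2).
    truth : patient_id → matched regimen_id (positive pairs for training).
    """

    def __init__(self, patient_vectors: dict, regimen_vectors: dict, truth: dict,
                 config: Stage3Config | None = None):
        self.config = config or Stage3Config()
        missing = [p for p in truth if p not in patient_vectors] \
            + [r for r in truth.values() if r not in regimen_vectors]
        if missing:
            raise KeyError(f"truth pairs reference unknown ids: {missing[:5]}")
        self.patient_vectors = {k: np.asarray(v, dtype=float) for k, v in patient_vectors.items()}
        self.regimen_vectors = {k: np.asarray(v, dtype=float) for k, v in regimen_vectors.items()}
        self.truth = dict(truth)
        self.d_patient = len(next(iter(self.patient_vectors.values())))
        self.d_regimen = len(next(iter(self.regimen_vectors.values())))
        self._built = False

    def _build(self, rng: np.random.Generator):
        cfg = self.config
        self.project_patient = Projector(self.d_patient, cfg.hidden, cfg.shared_dim, rng)
        self.project_regimen = Projector(self.d_regimen, cfg.hidden, cfg.shared_dim, rng)
        self._built = True

    def _separation(self, p_mat: np.ndarray, r_mat: np.ndarray) -> float:
        """mean s(positive pair) − mean s(non-matching pair) in the shared space."""
        p = self.project_patient(Tensor(p_mat)).data
        r = self.project_regimen(Tensor(r_mat)).data
        p_n = p / (np.linalg.norm(p, axis=1, keepdims=True) + 1e-12)
        r_n = r / (np.linalg.norm(r, axis=1, keepdims=True) + 1e-12)
        sims = p_n @ r_n.T
        pos = np.diag(sims).mean()
        mask = ~np.eye(len(sims), dtype=bool)
        return float(pos - sims[mask].mean())

    def fit(self, seed: int = 0) -> "MatchingResults":
        cfg = self.config
        rng = np.random.default_rng(seed)
        if not self._built:
            self._build(rng)
        pids = sorted(self.truth)
        if len(pids) < 2:
            raise ValueError("need at least two matched pairs to sample in-batch negatives")
        p_mat = np.stack([self.patient_vectors[p] for p in pids])
        r_mat = np.stack([self.regimen_vectors[self.truth[p]] for p in pids])
        optimizer = Adam(self.project_patient.parameters()
                         + self.project_regimen.parameters(), lr=cfg.lr)
        separation_curve = [self._separation(p_mat, r_mat)]
        loss_curve = []
        n = len(pids)
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                if len(idx) < 2:
                    continue
                # in-batch negatives: each anchor's negative is another pair's partner
                shift = 1 + int(rng.integers(0, len(idx) - 1))
                neg_idx = idx[(np.arange(len(idx)) + shift) % len(idx)]
                p = self.project_patient(Tensor(p_mat[idx]))
                r = self.project_regimen(Tensor(r_mat[idx]))
                p_neg = self.project_patient(Tensor(p_mat[neg_idx]))
                r_neg = self.project_regimen(Tensor(r_mat[neg_idx]))
                loss = bidirectional_loss(p, r, p_neg, r_neg, cfg.margin, cfg.literal)
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_losses.append(loss.item())
            loss_curve.append(float(np.mean(epoch_losses)))
            separation_curve.append(self._separation(p_mat, r_mat))
        return MatchingResults(self, loss_curve, separation_curve, seed)


class MatchingResults:
    """Fitted stage-3 projections: ranking, recommendation and HIT@k evaluation."""

    def __init__(self, model: MatchingModel, loss_curve: list[float],
                 separation_curve: list[float], seed: int):
        self.model = model
        self.loss_curve = loss_curve
        self.separation_curve = separation_curve
        self.seed = seed

    def project_patients(self, vectors: dict) -> dict:
        ids = sorted(vectors)
        mat = self.model.project_patient(Tensor(np.stack([vectors[i] for i in ids]))).data
        return dict(zip(ids, mat))

    def project_regimens(self, vectors: dict) -> dict:
        ids = sorted(vectors)
        mat = self.model.project_regimen(Tensor(np.stack([vectors[i] for i in ids]))).data
        return dict(zip(ids, mat))

    def rank_all(self, patient_vectors: dict | None = None,
                 regimen_vectors: dict | None = None, k: int | None = None) -> list[MatchRanking]:
        k = k if k is not None else self.model.config.recommend_k
        library = self.project_regimens(regimen_vectors or self.model.regimen_vectors)
        patients = self.project_patients(patient_vectors or self.model.patient_vectors)
        return [rank_regimens(pid, vec, library, k) for pid, vec in sorted(patients.items())]

    def recommend(self, patient_id: str, k: int | None = None) -> list:
        k = k if k is not None else self.model.config.recommend_k
        library = self.project_regimens(self.model.regimen_vectors)
        patient = self.project_patients(self.model.patient_vectors)[patient_id]
        return rank_regimens(patient_id, patient, library, k).top(k)

    def evaluate_hit_at_k(self, k: int | None = None, truth: dict | None = None,
                          patient_vectors: dict | None = None,
                          regimen_vectors: dict | None = None) -> float:
        k = k if k is not None else self.model.config.evaluate_k
        truth = truth or self.model.truth
        pool = patient_vectors or self.model.patient_vectors
        rankings = self.rank_all({p: pool[p] for p in truth}, regimen_vectors, k)
        return hit_at_k(rankings, truth, k)

    def summary(self) -> str:
        lines = [
            "Matching model (stage 3)",
            "=" * 40,
            f"pairs:            {len(self.model.truth)}",
            f"shared width:     {self.model.config.shared_dim}",
            f"margin:           {self.model.config.margin}",
            f"epochs:           {len(self.loss_curve)}",
            f"final loss:       {self.loss_curve[-1]:.4f}",
            f"pos-neg gap:      {self.separation_curve[0]:.4f} -> {self.separation_curve[-1]:.4f}",
        ]
        return "\n".join(lines)
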