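"""Stage 1 — multimodal severity assessment with gradient-norm modality weighting.

A patient contributes two modalities: a table embedding ``E_Table`` from the
feature-tokenizer transformer and an image embedding ``E_Image`` (the mean of
the patient's precomputed image feature vectors, linearly projected to the
shared width).  The two are fused by cross-attention

    E_fusion = softmax((E_Table W_Q)(E_Image W_K)^T / sqrt(d)) (E_Image W_V)

with a residual connection from the query (table) path and layer
normalisation.  Auxiliary linear heads on each unimodal embedding produce
classification losses whose gradient L2 norms, taken over that modality's own
encoder+head parameters and detached, feed a three-layer projection network
(softmax output) yielding the modality weights ``w_image + w_table = 1``, and
a two-layer softplus network yielding ``w_fusion > 0``.  The composite loss is

    L = w_image·L_image + w_table·L_table + w_fusion·L_multimodal + L_gradnorm

where ``L_gradnorm = ||∇L_image||₂ + ||∇L_table||₂``.

:class:`SeverityModel` is the statsmodels-style entry point: build it from
cleaned patient records, call :meth:`SeverityModel.fit`, and read the learned
modality weights, loss curves and predictions off the returned
:class:`SeverityResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .cohort_io import PatientRecord, TabularSchema
from .nn import Adam, Linear, LayerNorm, MLP, Module, cross_entropy, gradient_norm
from .tabular_encoder import Standardizer, TabularEncoder

__all__ = [
    "ModalityEmbedding",
    "GradientStats",
    "FusionWeights",
    "embed_images",
    "CrossAttentionFusion",
    "ModalityWeightNet",
    "FusionWeightNet",
    "gradnorm_regularizer",
    "stage1_total_loss",
    "Stage1Config",
    "SeverityModel",
    "SeverityResults",
]


@dataclass(frozen=True)
class ModalityEmbedding:
    vector: np.ndarray
    modality: str  # "image" | "table" | "fusion"


@dataclass(frozen=True)
class GradientStats:
    g_image: float
    g_table: float

    def __post_init__(self):
        if self.g_image < 0 or self.g_table < 0:
            raise ValueError("gradient norms must be nonnegative")


@dataclass(frozen=True)
class FusionWeights:
    w_image: float
    w_table: float
    w_fusion: float


def embed_images(image_embeddings: list) -> ModalityEmbedding:
    """Average a patient's image feature vectors into one image embedding."""
    if not image_embeddings:
        raise ValueError("patient has no image embeddings (missing modality)")
    arr = np.asarray(image_embeddings, dtype=float)
    return ModalityEmbedding(arr.mean(axis=0), "image")


def gradnorm_regularizer(stats: GradientStats) -> float:
    """Combined gradient regularisation term: sum of the two modality norms."""
    return stats.g_image + stats.g_table


def stage1_total_loss(l_image, l_table, l_multimodal, l_gradnorm, weights: FusionWeights):
    """Weighted composite of unimodal, multimodal and gradient-norm terms."""
    return (weights.w_image * l_image + weights.w_table * l_table
            + weights.w_fusion * l_multimodal + l_gradnorm)


class CrossAttentionFusion(Module):
    """Cross-attention with table queries over image keys/values.

    With a single image token per patient the softmax over keys is 1 and the
    pre-residual output reduces to ``E_Image @ W_V``; the module still accepts
    multiple image tokens per patient for completeness.
    """

    def __init__(self, d: int, rng: np.random.Generator, layer_norm: bool = True,
                 gated: bool = True):
        self.d = d
        self.w_q = Linear(d, d, rng, bias=False)
        self.w_k = Linear(d, d, rng, bias=False)
        self.w_v = Linear(d, d, rng, bias=False)
        self.ln = LayerNorm(d, enabled=layer_norm)
        # ReZero-style scalar gate on the attention branch: fusion starts at the
        # residual (table) path and admits cross-modal content only when it
        # consistently reduces the loss — a zero-mean noise modality cannot
        # push the gate away from zero
        self.gate = Tensor(np.zeros(1), requires_grad=True) if gated else None

    def attend(self, table: Tensor, image: Tensor) -> Tensor:
        """Pre-residual attention output. table: (B, d); image: (B, T, d) or (B, d)."""
        if image.ndim == 2:
            image = image.reshape(image.shape[0], 1, self.d)
        q = self.w_q(table).reshape(table.shape[0], 1, self.d)
        k = self.w_k(image)
        v = self.w_v(image)
        scores = (q @ k.T) * (1.0 / np.sqrt(self.d))
        attended = scores.softmax(axis=-1) @ v
        return attended.reshape(table.shape[0], self.d)

    def __call__(self, table: Tensor, image: Tensor) -> Tensor:
        attended = self.attend(table, image)
        if self.gate is not None:
            attended = attended * self.gate
        return self.ln(attended + table)


class ModalityWeightNet(Module):
    """(g_image, g_table) → (w_image, w_table), a softmax pair summing to 1."""

    def __init__(self, rng: np.random.Generator, hidden: int = 8):
        self.fc1 = Linear(2, hidden, rng)
        self.fc2 = Linear(hidden, hidden, rng)
        self.fc3 = Linear(hidden, 2, rng)

    def __call__(self, stats: Tensor) -> Tensor:
        h = self.fc1(stats).relu()
        h = self.fc2(h).sigmoid()
        return self.fc3(h).softmax(axis=-1)


class FusionWeightNet(Module):
    """(w_image, w_table) → w_fusion, strictly positive via softplus."""

    def __init__(self, rng: np.random.Generator, hidden: int = 8):
        self.fc1 = Linear(2, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng)

    def __call__(self, weights: Tensor) -> Tensor:
        return self.fc2(self.fc1(weights)).softplus()


@dataclass
class Stage1Config:
    d: int = 64
    n_layers: int = 2
    n_heads: int = 4
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    image_on: bool = True
    table_on: bool = True
    gradnorm_on: bool = True
    cross_attention_on: bool = True
    impute_missing_images: bool = False


class SeverityModel:
    """Severity classifier over fused table+image patient features.

    Parameters
    ----------
    records : cleaned patient records (no missing tabular values).
    schema : the cohort's tabular schema.
    config : hyperparameters and ablation switches.
    """

    def __init__(self, records: list[PatientRecord], schema: TabularSchema,
                 config: Stage1Config | None = None):
        self.records = list(records)
        self.schema = schema
        self.config = config or Stage1Config()
        if not (self.config.image_on or self.config.table_on):
            raise ValueError("at least one modality must be enabled")
        dev = [r for r in self.records if r.split_tag == "development"]
        labels = {r.severity_label for r in dev if r.severity_label is not None}
        if len(labels) < 2:
            raise ValueError("development split must contain at least two classes")
        self.n_classes = max(labels) + 1
        self.standardizer = Standardizer(schema).fit(dev)
        self.d_image = self._image_dim()
        self._built = False

    def _image_dim(self) -> int:
        for r in self.records:
            if r.image_embeddings:
                return len(r.image_embeddings[0])
        if self.config.image_on and not self.config.impute_missing_images:
            raise ValueError("no image embeddings in cohort but image modality enabled")
        return 1

    # -- feature assembly -------------------------------------------------------
    def _arrays(self, records: list[PatientRecord]):
        encoder = self.table_encoder
        numeric = np.array([self.standardizer.transform(encoder.numeric_values(r))
                            for r in records])
        codes = np.array([encoder.categorical_codes(r) for r in records], dtype=int)
        images = []
        for r in records:
            if r.image_embeddings:
                images.append(embed_images(r.image_embeddings).vector)
            elif self.config.impute_missing_images:
                images.append(np.zeros(self.d_image))
            else:
                raise ValueError(f"patient {r.patient_id}: missing image modality")
        labels = np.array([-1 if r.severity_label is None else r.severity_label
                           for r in records], dtype=int)
        return numeric, codes, np.array(images), labels

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config
        self.table_encoder = TabularEncoder(self.schema, cfg.d, cfg.n_layers, cfg.n_heads, rng)
        self.image_encoder = Linear(self.d_image, cfg.d, rng)
        self.head_image = Linear(cfg.d, self.n_classes, rng)
        self.head_table = Linear(cfg.d, self.n_classes, rng)
        self.head_fusion = Linear(cfg.d, self.n_classes, rng)
        self.cross_attention = CrossAttentionFusion(cfg.d, rng)
        self.weight_net = ModalityWeightNet(rng)
        self.fusion_net = FusionWeightNet(rng)
        self._built = True

    def _image_params(self):
        return self.image_encoder.parameters() + self.head_image.parameters()

    def _table_params(self):
        return self.table_encoder.parameters() + self.head_table.parameters()

    def _all_params(self):
        params = []
        if self.config.image_on:
            params += self._image_params()
        if self.config.table_on:
            params += self._table_params()
        if self.config.image_on and self.config.table_on:
            params += self.head_fusion.parameters()
            if self.config.cross_attention_on:
                params += self.cross_attention.parameters()
            if self.config.gradnorm_on:
                params += self.weight_net.parameters() + self.fusion_net.parameters()
        return params

    # -- forward pieces ---------------------------------------------------------
    def _forward_embeddings(self, numeric, codes, images):
        e_table = self.table_encoder(numeric, codes) if self.config.table_on else None
        e_image = self.image_encoder(Tensor(images)) if self.config.image_on else None
        return e_table, e_image

    def _fuse(self, e_table: Tensor, e_image: Tensor) -> Tensor:
        if self.config.cross_attention_on:
            return self.cross_attention(e_table, e_image)
        return e_table + e_image  # simple-fusion ablation control

    def modality_weights(self, stats: GradientStats) -> tuple[Tensor, Tensor]:
        """Gradient stats → (softmax pair tensor, softplus fusion-weight tensor)."""
        pair = self.weight_net(Tensor([stats.g_image, stats.g_table]))
        w_fusion = self.fusion_net(pair)
        return pair, w_fusion

    # -- fitting ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "SeverityResults":
        cfg = self.config
        rng = np.random.default_rng(seed)
        if not self._built:
            self._build(rng)
        dev = [r for r in self.records if r.split_tag == "development"]
        numeric, codes, images, labels = self._arrays(dev)
        optimizer = Adam(self._all_params(), lr=cfg.lr)
        trajectory: list[FusionWeights] = []
        loss_curve: list[float] = []
        n = len(dev)
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss, epoch_weights = [], []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                loss, weights = self._batch_loss(numeric[idx], codes[idx],
                                                 images[idx], labels[idx], optimizer)
                epoch_loss.append(loss)
                epoch_weights.append(weights)
            loss_curve.append(float(np.mean(epoch_loss)))
            trajectory.append(FusionWeights(
                float(np.mean([w.w_image for w in epoch_weights])),
                float(np.mean([w.w_table for w in epoch_weights])),
                float(np.mean([w.w_fusion for w in epoch_weights])),
            ))
        return SeverityResults(self, trajectory, loss_curve, seed)

    def _batch_loss(self, numeric, codes, images, labels, optimizer: Adam):
        cfg = self.config
        e_table, e_image = self._forward_embeddings(numeric, codes, images)
        bimodal = cfg.image_on and cfg.table_on
        l_image = cross_entropy(self.head_image(e_image), labels) if cfg.image_on else None
        l_table = cross_entropy(self.head_table(e_table), labels) if cfg.table_on else None

        if not bimodal:
            loss = l_image if cfg.image_on else l_table
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            w_img = 1.0 if cfg.image_on else 0.0
            return loss.item(), FusionWeights(w_img, 1.0 - w_img, 0.0)

        if cfg.gradnorm_on:
            optimizer.zero_grad()
            l_image.backward()
            g_image = gradient_norm(self._image_params())
            optimizer.zero_grad()
            l_table.backward()
            g_table = gradient_norm(self._table_params())
            optimizer.zero_grad()
            stats = GradientStats(g_image, g_table)
            pair, w_fusion = self.modality_weights(stats)
            assert abs(float(pair.data.sum()) - 1.0) < 1e-7, "modality weights must sum to 1"
            w_image_t, w_table_t = pair[0], pair[1]
            l_gradnorm = gradnorm_regularizer(stats)
        else:
            w_image_t, w_table_t = Tensor(0.5), Tensor(0.5)
            w_fusion = Tensor(1.0)
            l_gradnorm = 0.0

        e_fusion = self._fuse(e_table, e_image)
        l_multi = cross_entropy(self.head_fusion(e_fusion), labels)
        total = (w_image_t * l_image + w_table_t * l_table
                 + w_fusion * l_multi + l_gradnorm).sum()
        optimizer.zero_grad()
        total.backward()
        optimizer.step()
        return total.item(), FusionWeights(w_image_t.data.item(), w_table_t.data.item(),
                                           w_fusion.data.item())


class SeverityResults:
    """Fitted Stage-1 model: weight trajectory, loss curve, prediction methods."""

    def __init__(self, model: SeverityModel, trajectory: list[FusionWeights],
                 loss_curve: list[float], seed: int):
        self.model = model
        self.weight_trajectory = trajectory
        self.loss_curve = loss_curve
        self.seed = seed

    @property
    def final_weights(self) -> FusionWeights:
        return self.weight_trajectory[-1] if self.weight_trajectory else FusionWeights(0.5, 0.5, 1.0)

    def predict_proba(self, records: list[PatientRecord]) -> np.ndarray:
        """Class-probability matrix (rows sum to 1) for ``records``."""
        m = self.model
        numeric, codes, images, _ = m._arrays(records)
        e_table, e_image = m._forward_embeddings(numeric, codes, images)
        if m.config.image_on and m.config.table_on:
            logits = m.head_fusion(m._fuse(e_table, e_image))
        elif m.config.table_on:
            logits = m.head_table(e_table)
        else:
            logits = m.head_image(e_image)
        return logits.softmax(axis=-1).data

    def predict(self, records: list[PatientRecord]) -> np.ndarray:
        return self.predict_proba(records).argmax(axis=1)

    def patient_embeddings(self, records: list[PatientRecord]) -> np.ndarray:
        """Fused patient embeddings E_fusion consumed by the matching stage."""
        m = self.model
        numeric, codes, images, _ = m._arrays(records)
        e_table, e_image = m._forward_embeddings(numeric, codes, images)
        if m.config.image_on and m.config.table_on:
            return m._fuse(e_table, e_image).data
        return (e_table if m.config.table_on else e_image).data

    def summary(self) -> str:
        w = self.final_weights
        lines = [
            "Severity model (stage 1)",
            "=" * 40,
            f"patients (development): {sum(r.split_tag == 'development' for r in self.model.records)}",
            f"classes:                {self.model.n_classes}",
            f"epochs:                 {len(self.loss_curve)}",
            f"final loss:             {self.loss_curve[-1]:.4f}" if self.loss_curve else "",
            f"w_image:                {w.w_image:.4f}",
            f"w_table:                {w.w_table:.4f}",
            f"w_fusion:               {w.w_fusion:.4f}",
        ]
        return "\n".join(line for line in lines if line)
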