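"""Feature-tokenizer transformer for laboratory-indicator tables.

Each numeric field j is tokenized as ``x_j * w_j + b_j`` with learned per-field
vectors; each categorical field takes a per-category learned embedding; a
learned CLS token is appended as the final row.  The token matrix (one token
per field, plus CLS, so n+m+1 rows of width d) passes through L self-attention
layers and the CLS row is returned as the table embedding ``E_Table``.

Fields are an unordered set, so no positional encodings are used; the CLS
output is therefore invariant to permuting the field tokens.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, stack
from .cohort_io import PatientRecord, TabularSchema
from .nn import LayerNorm, Linear, Module, TransformerLayer

__all__ = ["Standardizer", "TabularEncoder", "UnknownCategoryError"]


class UnknownCategoryError(KeyError):
    """A categorical value was never declared in the schema and OOV is disabled."""


class Standardizer:
    """Z-scores numeric fields using statistics from the development split."""

    def __init__(self, schema: TabularSchema):
        self.schema = schema
        self.mean: np.ndarray | None = None
        self.std: np.ndarray | None = None

    def fit(self, records: list[PatientRecord]) -> "Standardizer":
        values = np.array(
            [[r.tabular[name] for name in self.schema.numeric_names] for r in records],
            dtype=float,
        )
        self.mean = values.mean(axis=0) if len(values) else np.zeros(len(self.schema.numeric_names))
        self.std = values.std(axis=0) if len(values) else np.ones(len(self.schema.numeric_names))
        self.std = np.where(self.std < 1e-12, 1.0, self.std)
        return self

    def transform(self, numeric: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("Standardizer not fitted")
        return (numeric - self.mean) / self.std


class TabularEncoder(Module):
    """FT-style tokenizer + transformer block producing the CLS table embedding."""

    def __init__(self, schema: TabularSchema, d: int = 64, n_layers: int = 2,
                 n_heads: int = 4, rng: np.random.Generator | None = None,
                 allow_oov: bool = False):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.schema = schema
        self.d = d
        self.allow_oov = allow_oov
        n = len(schema.numeric_fields)
        scale = 1.0 / np.sqrt(d)
        self.num_weight = Tensor(rng.normal(0, scale, (n, d)), requires_grad=True)
        self.num_bias = Tensor(np.zeros((n, d)), requires_grad=True)
        # per-categorical embedding tables, with an extra OOV row at the end
        self.cat_index: list[dict[str, int]] = [
            {c: i for i, c in enumerate(cats)} for _, cats in schema.categorical_fields
        ]
        self.cat_embeddings = [
            Tensor(rng.normal(0, scale, (len(cats) + 1, d)), requires_grad=True)
            for _, cats in schema.categorical_fields
        ]
        self.cls = Tensor(rng.normal(0, scale, (d,)), requires_grad=True)
        self.layers = [TransformerLayer(d, n_heads, rng) for _ in range(n_layers)]
        self.final_ln = LayerNorm(d)

    # -- encoding of raw records into arrays -----------------------------------
    def categorical_codes(self, record: PatientRecord) -> np.ndarray:
        codes = []
        for (name, _cats), index in zip(self.schema.categorical_fields, self.cat_index):
            value = record.tabular[name]
            if value not in index:
                if not self.allow_oov:
                    raise UnknownCategoryError(f"{name}={value!r} not in schema categories")
                codes.append(len(index))  # reserved OOV row
            else:
                codes.append(index[value])
        return np.array(codes, dtype=int)

    def numeric_values(self, record: PatientRecord) -> np.ndarray:
        vals = [record.tabular[name] for name in self.schema.numeric_names]
        if any(v is None for v in vals):
            raise ValueError(f"patient {record.patient_id}: missing numeric value (clean first)")
        return np.array(vals, dtype=float)

    # -- tokenizer --------------------------------------------------------------
    def tokenize_batch(self, numeric: np.ndarray, codes: np.ndarray) -> Tensor:
        """(B, n) numerics and (B, m) category codes → (B, n+m+1, d) tokens."""
        numeric = np.atleast_2d(numeric)
        codes = np.atleast_2d(codes)
        B = numeric.shape[0]
        parts = []
        if numeric.shape[1]:
            x = Tensor(numeric[:, :, None])  # (B, n, 1)
            parts.append(x * self.num_weight + self.num_bias)  # broadcast to (B, n, d)
        for j, table in enumerate(self.cat_embeddings):
            parts.append(table[codes[:, j]].reshape(B, 1, self.d))
        cls_row = stack([self.cls] * B, axis=0).reshape(B, 1, self.d)
        parts.append(cls_row)
        return concat(parts, axis=1)

    def tokenize(self, record: PatientRecord, standardizer: Standardizer | None = None) -> Tensor:
        numeric = self.numeric_values(record)[None, :]
        if standardizer is not None:
            numeric = standardizer.transform(numeric)
        codes = self.categorical_codes(record)[None, :]
        return self.tokenize_batch(numeric, codes)[0]

    # -- transformer ------------------------------------------------------------
    def encode_table(self, tokens: Tensor) -> Tensor:
        """Token matrix → CLS embedding. Accepts (T, d) or batched (B, T, d)."""
        squeeze = tokens.ndim == 2
        if squeeze:
            tokens = tokens.reshape(1, *tokens.shape)
        for layer in self.layers:
            tokens = layer(tokens)
        tokens = self.final_ln(tokens)
        cls = tokens[:, -1, :]
        if not np.all(np.isfinite(cls.data)):
            raise FloatingPointError("non-finite activations in table encoder")
        return cls[0] if squeeze else cls

    def __call__(self, numeric: np.ndarray, codes: np.ndarray) -> Tensor:
        return self.encode_table(self.tokenize_batch(numeric, codes))

    def set_identity(self) -> None:
        """Zero all attention/FFN weights so the block is the identity (test hook)."""
        for layer in self.layers:
            for p in layer.parameters():
                p.data = np.zeros_like(p.data)
            layer.ln1.gain.data = np.ones_like(layer.ln1.gain.data)
            layer.ln2.gain.data = np.ones_like(layer.ln2.gain.data)
        self.final_ln.enabled = False
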