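"""Domain types, on-disk formats and preprocessing for patient cohorts.

File conventions
----------------
* Tabular data: CSV/TSV with a header row and a mandatory ``patient_id`` column.
* Image embeddings: TSV of ``patient_id`` plus fixed-width float columns; a
  patient may contribute several rows (several images).
* Labels/splits: 3-column TSV ``patient_id, label, split``.
* Protein sequences: FASTA.
* PPI and co-occurrence priors: 3-column TSV edge lists ``node_a, node_b, weight``.

Cleaning follows the clinical preprocessing rules used throughout the package:
out-of-physiological-range numeric values are blanked *before* median
imputation (so outliers never contaminate the median), categorical gaps take
the modal category, and network edge lists lose self-loops and duplicate
undirected pairs (keeping the maximum weight).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "TabularSchema",
    "PatientRecord",
    "MedicationRecord",
    "RegimenRecord",
    "WeightedEdgeList",
    "SchemaError",
    "IntegrityError",
    "read_cohort",
    "clean_tabular",
    "clean_network",
    "oversample_development",
    "read_fasta",
    "read_edge_list",
    "write_edge_list",
]


class SchemaError(ValueError):
    """Input columns do not match the declared schema."""


class IntegrityError(ValueError):
    """Cross-file referential integrity violated (ids, dimensions)."""


@dataclass(frozen=True)
class TabularSchema:
    """Declares the laboratory-indicator fields of a cohort.

    ``numeric_fields`` carry physiological [min, max] ranges used for outlier
    blanking; ``categorical_fields`` list their admissible categories.
    """

    numeric_fields: list[tuple[str, float, float]]
    categorical_fields: list[tuple[str, list[str]]]

    def __post_init__(self):
        names = [f[0] for f in self.numeric_fields] + [f[0] for f in self.categorical_fields]
        if len(names) != len(set(names)):
            raise SchemaError("field names must be unique across numeric and categorical lists")
        for name, lo, hi in self.numeric_fields:
            if not lo < hi:
                raise SchemaError(f"numeric field {name!r}: min must be < max")

    @property
    def numeric_names(self) -> list[str]:
        return [f[0] for f in self.numeric_fields]

    @property
    def categorical_names(self) -> list[str]:
        return [f[0] for f in self.categorical_fields]

    @property
    def field_names(self) -> list[str]:
        return self.numeric_names + self.categorical_names


@dataclass
class PatientRecord:
    patient_id: str
    tabular: dict
    image_embeddings: list = field(default_factory=list)
    severity_label: int | None = None
    split_tag: str = "development"

    def __post_init__(self):
        dims = {len(v) for v in self.image_embeddings}
        if len(dims) > 1:
            raise IntegrityError(
                f"patient {self.patient_id}: image embedding dimensions differ: {sorted(dims)}"
            )


@dataclass
class MedicationRecord:
    med_id: str
    kind: str  # "herbal" or "conventional"
    attribute_texts: dict
    target_proteins: list = field(default_factory=list)
    protein_sequences: dict = field(default_factory=dict)

    @property
    def missing_sequences(self) -> list[str]:
        return [p for p in self.target_proteins if p not in self.protein_sequences]


@dataclass
class RegimenRecord:
    regimen_id: str
    patient_id: str
    med_ids: frozenset
    outcome_label: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "med_ids", frozenset(self.med_ids))
        if len(self.med_ids) < 1:
            raise IntegrityError(f"regimen {self.regimen_id}: needs at least one medication")


@dataclass
class WeightedEdgeList:
    edges: list  # (node_a, node_b, weight)
    directed: bool = False

    def nodes(self) -> list:
        seen: dict = {}
        for a, b, _ in self.edges:
            seen.setdefault(a, None)
            seen.setdefault(b, None)
        return list(seen)


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype={"patient_id": str})


def read_cohort(tabular_path, schema: TabularSchema,
                image_embedding_path=None, labels_path=None) -> list[PatientRecord]:
    """Assemble patient records from the tabular, image-embedding and label files."""
    table = _read_table(tabular_path)
    if "patient_id" not in table.columns:
        raise SchemaError("tabular file lacks mandatory patient_id column")
    unknown = set(table.columns) - set(schema.field_names) - {"patient_id"}
    if unknown:
        raise SchemaError(f"columns not in schema: {sorted(unknown)}")
    missing = set(schema.field_names) - set(table.columns)
    if missing:
        raise SchemaError(f"schema fields absent from tabular file: {sorted(missing)}")
    if table["patient_id"].duplicated().any():
        dupes = table.loc[table["patient_id"].duplicated(), "patient_id"].tolist()
        raise IntegrityError(f"duplicate patient ids: {dupes}")

    images: dict[str, list] = {}
    if image_embedding_path is not None:
        emb = pd.read_csv(image_embedding_path, sep="\t", dtype={"patient_id": str})
        value_cols = [c for c in emb.columns if c != "patient_id"]
        for pid, group in emb.groupby("patient_id"):
            images[pid] = [row.to_numpy(dtype=float) for _, row in group[value_cols].iterrows()]

    labels: dict[str, tuple[int, str]] = {}
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", dtype={"patient_id": str})
        known = set(table["patient_id"])
        for _, row in lab.iterrows():
            if row["patient_id"] not in known:
                raise IntegrityError(
                    f"labelled patient {row['patient_id']!r} absent from tabular file"
                )
            labels[row["patient_id"]] = (int(row["label"]), str(row["split"]))

    records = []
    for _, row in table.iterrows():
        pid = row["patient_id"]
        tab = {}
        for name in schema.numeric_names:
            v = row[name]
            tab[name] = None if pd.isna(v) else float(v)
        for name in schema.categorical_names:
            v = row[name]
            tab[name] = None if pd.isna(v) else str(v)
        label, split = labels.get(pid, (None, "development"))
        records.append(PatientRecord(pid, tab, images.get(pid, []), label, split))
    return records


def clean_tabular(records: list[PatientRecord], schema: TabularSchema) -> list[PatientRecord]:
    """Blank out-of-range numerics, then impute: numeric→median, categorical→mode.

    Range filtering happens before the median is computed, so physiologically
    impossible values never contaminate the imputation statistic.  Idempotent.
    """
    records = copy.deepcopy(records)
    for name, lo, hi in schema.numeric_fields:
        for r in records:
            v = r.tabular.get(name)
            if v is not None and not lo <= v <= hi:
                r.tabular[name] = None
        observed = [r.tabular[name] for r in records if r.tabular[name] is not None]
        if not observed:
            raise IntegrityError(f"numeric field {name!r}: all values missing, cannot impute")
        median = float(np.median(observed))
        for r in records:
            if r.tabular[name] is None:
                r.tabular[name] = median
    for name, _categories in schema.categorical_fields:
        observed = [r.tabular[name] for r in records if r.tabular[name] is not None]
        if not observed:
            raise IntegrityError(f"categorical field {name!r}: all values missing, cannot impute")
        values, counts = np.unique(observed, return_counts=True)
        mode = sorted(values[counts == counts.max()])[0]
        for r in records:
            if r.tabular[name] is None:
                r.tabular[name] = mode
    return records


def clean_network(edges: WeightedEdgeList) -> WeightedEdgeList:
    """Drop self-loops; collapse duplicate (undirected) pairs keeping the max weight."""
    best: dict[tuple, float] = {}
    order: list[tuple] = []
    for a, b, w in edges.edges:
        w = float(w)
        if w < 0:
            raise ValueError(f"negative edge weight on ({a},{b}): {w}")
        if a == b:
            continue
        key = (a, b) if edges.directed else tuple(sorted((str(a), str(b))))
        if key not in best:
            best[key] = w
            order.append((a, b, key))
        else:
            best[key] = max(best[key], w)
    return WeightedEdgeList(
        edges=[(a, b, best[key]) for a, b, key in order], directed=edges.directed
    )


def oversample_development(records: list[PatientRecord], seed: int) -> list[PatientRecord]:
    """Random-oversample minority classes within the development split only.

    Whole records are duplicated (sampling with replacement) until every class
    present in development matches the majority count; the test split is
    returned untouched.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    dev = [r for r in records if r.split_tag == "development"]
    rest = [r for r in records if r.split_tag != "development"]
    by_class: dict[int, list[PatientRecord]] = {}
    for r in dev:
        if r.severity_label is None:
            raise IntegrityError(f"patient {r.patient_id}: development record lacks label")
        by_class.setdefault(r.severity_label, []).append(r)
    if not by_class:
        return list(records)
    target = max(len(v) for v in by_class.values())
    extra: list[PatientRecord] = []
    for label in sorted(by_class):
        members = by_class[label]
        if not members:
            warnings.warn(f"class {label} absent from development split; skipped")
            continue
        deficit = target - len(members)
        if deficit > 0:
            picks = rng.integers(0, len(members), size=deficit)
            extra.extend(copy.deepcopy(members[i]) for i in picks)
    return dev + extra + rest


def read_fasta(path) -> dict[str, str]:
    """Protein id (header first token) → uppercased, whitespace-free sequence."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace(" ", "").upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        sequences[rec.id] = seq
    return sequences


def read_edge_list(path, directed: bool = False) -> WeightedEdgeList:
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "w"], dtype={"a": str, "b": str})
    return WeightedEdgeList(
        edges=[(r.a, r.b, float(r.w)) for r in df.itertuples()], directed=directed
    )


def write_edge_list(edges: WeightedEdgeList, path) -> None:
    with open(path, "w") as fh:
        for a, b, w in edges.edges:
            fh.write(f"{a}\t{b}\t{w}\n")
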