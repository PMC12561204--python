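"""Orchestration of the three-stage decision chain plus metrics and ablation.

``run_chain`` trains the stages in their upstream-downstream order — severity
(stage 1) → combination efficacy (stage 2) → patient-regimen matching
(stage 3) — on a seeded synthetic cohort, evaluates each on held-out data and
writes a byte-reproducible JSON report.  Test-split severity labels live in a
:class:`LabelVault` that counts any access made before the evaluation phase,
so label leakage into training is detectable.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import (average_precision_score, f1_score, precision_score,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold

from .cohort_io import PatientRecord, clean_tabular, oversample_development
from .fusion import SeverityModel, Stage1Config
from .matching import MatchingModel, Stage3Config
from .medgraph import (EfficacyModel, FeatureBuilder, Stage2Config,
                       build_regimen_graph, cooccurrence_edge_weights)
from .synthetic import SynthConfig, SyntheticCohort, generate_cohort

__all__ = ["ChainConfig", "MetricsReport", "LabelVault", "compute_metrics",
           "stratified_folds", "crossvalidate", "prepare_regimen_graphs",
           "run_chain", "run_ablation", "ABLATION_GRID"]


class LabelVault:
    """Guards test-split labels; accesses before :meth:`unlock` are counted as leaks."""

    def __init__(self, labels: dict):
        self._labels = dict(labels)
        self.pre_unlock_accesses = 0
        self._unlocked = False

    def unlock(self) -> None:
        self._unlocked = True

    def reveal(self, key):
        if not self._unlocked:
            self.pre_unlock_accesses += 1
        return self._labels[key]

    def __len__(self):
        return len(self._labels)


@dataclass
class MetricsReport:
    auroc: float
    auprc: float
    f1: float
    precision: float
    n: int

    def as_dict(self) -> dict:
        return {k: round(float(v), 10) if isinstance(v, float) else v
                for k, v in asdict(self).items()}


def compute_metrics(scores: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """AUROC/AUPRC/F1/Precision. Binary scores are P(class 1); multiclass is macro.

    F1/Precision threshold at 0.5 for binary scores, argmax for a probability
    matrix.  Raises on single-class labels (AUROC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined for single-class labels")
    if scores.ndim == 1 or scores.shape[1] == 2:
        p1 = scores if scores.ndim == 1 else scores[:, 1]
        pred = (p1 >= 0.5).astype(int)
        return MetricsReport(
            float(roc_auc_score(labels, p1)),
            float(average_precision_score(labels, p1)),
            float(f1_score(labels, pred, zero_division=0)),
            float(precision_score(labels, pred, zero_division=0)),
            len(labels),
        )
    pred = scores.argmax(axis=1)
    return MetricsReport(
        float(roc_auc_score(labels, scores, multi_class="ovr", average="macro")),
        float(average_precision_score(labels, scores, average="macro")),
        float(f1_score(labels, pred, average="macro", zero_division=0)),
        float(precision_score(labels, pred, average="macro", zero_division=0)),
        len(labels),
    )


def stratified_folds(labels: np.ndarray, folds: int, seed: int) -> list:
    """Deterministic stratified partition: list of (train_idx, test_idx)."""
    labels = np.asarray(labels, dtype=int)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"a class has fewer members ({counts.min()}) than folds ({folds})")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(len(labels)), labels))


def crossvalidate(records: list[PatientRecord], runner, folds: int = 4,
                  seed: int = 0) -> list[MetricsReport]:
    """Stratified CV over patient records; oversampling happens inside each
    training fold only (the runner receives records already tagged by split)."""
    labels = np.array([r.severity_label for r in records], dtype=int)
    reports = []
    for fold_idx, (train_idx, test_idx) in enumerate(stratified_folds(labels, folds, seed)):
        fold_records = []
        for i in train_idx:
            r = copy.deepcopy(records[i])
            r.split_tag = "development"
            fold_records.append(r)
        for i in test_idx:
            r = copy.deepcopy(records[i])
            r.split_tag = "test"
            fold_records.append(r)
        fold_records = oversample_development(fold_records, seed=seed + fold_idx)
        reports.append(runner(fold_records, seed + fold_idx))
    return reports


@dataclass
class ChainConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    stage1: Stage1Config = field(default_factory=lambda: Stage1Config(d=32, epochs=12))
    stage2: Stage2Config = field(default_factory=lambda: Stage2Config(epochs=20))
    stage3: Stage3Config = field(default_factory=lambda: Stage3Config(epochs=40))
    feature_seed: int = 0
    regimen_test_fraction: float = 0.25
    match_test_fraction: float = 0.25

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def prepare_regimen_graphs(cohort: SyntheticCohort, feature_seed: int = 0):
    """Featurize medications and build one graph per regimen record."""
    builder = FeatureBuilder(seed=feature_seed)
    features = builder.build(cohort.medications, cohort.ppi)
    prior = cooccurrence_edge_weights(cohort.cooccurrence)
    fallback = 1.0 / max(cohort.cooccurrence.values()) if cohort.cooccurrence else 1.0
    graphs = [build_regimen_graph(r, features, prior, fallback) for r in cohort.regimens]
    return graphs, features, prior, fallback


def _strip_test_labels(records: list[PatientRecord]) -> tuple[list, LabelVault]:
    vault = LabelVault({r.patient_id: r.severity_label
                        for r in records if r.split_tag == "test"})
    stripped = []
    for r in records:
        r = copy.deepcopy(r)
        if r.split_tag == "test":
            r.severity_label = None
        stripped.append(r)
    return stripped, vault


def run_chain(config: ChainConfig, seed: int = 0, out_dir=None) -> dict:
    """Train the full chain on a synthetic cohort and report per-stage metrics."""
    synth_cfg = copy.deepcopy(config.synth)
    synth_cfg.seed = seed
    cohort = generate_cohort(synth_cfg)
    rng = np.random.default_rng(seed + 1)

    # ---- stage 1: severity ---------------------------------------------------
    records = clean_tabular(cohort.patients, cohort.schema)
    records, vault = _strip_test_labels(records)
    records = oversample_development(records, seed=seed)
    model1 = SeverityModel(records, cohort.schema, copy.deepcopy(config.stage1))
    results1 = model1.fit(seed=seed)
    test_records = [r for r in records if r.split_tag == "test"]
    scores1 = results1.predict_proba(test_records)
    leak_count = vault.pre_unlock_accesses       # must be 0: training never peeked
    vault.unlock()
    labels1 = np.array([vault.reveal(r.patient_id) for r in test_records])
    metrics1 = compute_metrics(scores1, labels1)

    # ---- stage 2: combination efficacy --------------------------------------
    graphs, features, prior, fallback = prepare_regimen_graphs(cohort, config.feature_seed)
    order = rng.permutation(len(graphs))
    n_test = int(round(config.regimen_test_fraction * len(graphs)))
    test_g = [graphs[i] for i in order[:n_test]]
    train_g = [graphs[i] for i in order[n_test:]]
    model2 = EfficacyModel(train_g, copy.deepcopy(config.stage2))
    results2 = model2.fit(seed=seed)
    scores2 = results2.predict_proba(test_g)
    labels2 = np.array([g.label for g in test_g])
    metrics2 = compute_metrics(scores2, labels2)

    # ---- stage 3: patient-regimen matching ----------------------------------
    truth = cohort.matching["truth"]
    by_id = {r.patient_id: r for r in records}
    paired_pids = sorted(p for p in truth if p in by_id)
    patient_embeddings = dict(zip(
        paired_pids,
        results1.patient_embeddings([by_id[p] for p in paired_pids])))
    graph_by_id = {g.regimen_id: g for g in graphs}
    rids = sorted(graph_by_id)
    regimen_embeddings = dict(zip(rids, results2.regimen_embeddings(
        [graph_by_id[r] for r in rids])))
    pid_order = rng.permutation(len(paired_pids))
    n_match_test = max(1, int(round(config.match_test_fraction * len(paired_pids))))
    test_pids = [paired_pids[i] for i in pid_order[:n_match_test]]
    train_pids = [paired_pids[i] for i in pid_order[n_match_test:]]
    model3 = MatchingModel(patient_embeddings, regimen_embeddings,
                           {p: truth[p] for p in train_pids},
                           copy.deepcopy(config.stage3))
    results3 = model3.fit(seed=seed)
    hit10 = results3.evaluate_hit_at_k(
        k=min(10, len(regimen_embeddings)),
        truth={p: truth[p] for p in test_pids},
        patient_vectors=patient_embeddings)

    report = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "leak_guard": {"pre_evaluation_label_accesses": leak_count,
                       "guarded_test_labels": len(vault)},
        "stage1_severity": metrics1.as_dict(),
        "stage1_weights": {"w_image": round(results1.final_weights.w_image, 10),
                           "w_table": round(results1.final_weights.w_table, 10),
                           "w_fusion": round(results1.final_weights.w_fusion, 10)},
        "stage2_efficacy": metrics2.as_dict(),
        "stage3_matching": {"hit_at_10": round(float(hit10), 10),
                            "n_test_patients": len(test_pids),
                            "library_size": len(regimen_embeddings)},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        with open(out / "regimen_embeddings.tsv", "w") as fh:
            for rid in rids:
                vec = "\t".join(repr(round(float(v), 12)) for v in regimen_embeddings[rid])
                fh.write(f"{rid}\t{vec}\n")
    return report


ABLATION_GRID = [
    # (name, image_on, table_on, gradnorm_on, cross_attention_on)
    ("MI", True, False, False, False),
    ("TD", False, True, False, False),
    ("MI+TD", True, True, False, False),
    ("MI+TD+GNW", True, True, True, False),
    ("MI+TD+GNW+CA", True, True, True, True),
]


def run_ablation(config: ChainConfig, seed: int = 0) -> list[dict]:
    """Stage-1 ablation rows: modality switches × gradient-norm weighting × cross-attention."""
    synth_cfg = copy.deepcopy(config.synth)
    synth_cfg.seed = seed
    cohort = generate_cohort(synth_cfg)
    records = clean_tabular(cohort.patients, cohort.schema)
    records = oversample_development(records, seed=seed)
    test_records = [r for r in records if r.split_tag == "test"]
    rows = []
    for name, mi, td, gnw, ca in ABLATION_GRID:
        cfg = copy.deepcopy(config.stage1)
        cfg.image_on, cfg.table_on = mi, td
        cfg.gradnorm_on, cfg.cross_attention_on = gnw, ca
        results = SeverityModel(records, cohort.schema, cfg).fit(seed=seed)
        scores = results.predict_proba(test_records)
        labels = np.array([r.severity_label for r in test_records])
        metrics = compute_metrics(scores, labels)
        rows.append({"row": name, "MI": mi, "TD": td, "GNW": gnw, "CA": ca,
                     **metrics.as_dict()})
    return rows
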