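"""Synthetic cohorts with planted, recoverable signal for all three stages.

The generator emulates the structure of a multimodal chronic-disease cohort
(patients with laboratory tables and image feature vectors, a formulary of
herbal/conventional medications with pharmacology texts, target proteins, a
protein-interaction network, a prescription co-occurrence prior, and regimen
records with outcome labels) while planting exactly the signal each stage is
supposed to recover:

* Stage 1 — severity labels are drawn first; tabular features get a
  class-conditional mean shift of size ``beta_table`` and image embeddings a
  class-aligned direction of size ``beta_image``, so either effect size can be
  zeroed to make that modality pure noise.
* Stage 2 — target proteins live in a stochastic-block-model PPI; a regimen's
  outcome adds planted pairwise synergy for same-block medication pairs on top
  of per-medication effects, so efficacy is irreducibly pairwise.
* Stage 3 — each matched patient/regimen pair shares a latent factor passed
  through fixed linear maps plus Gaussian noise.

Every generator is a pure function of (config, seed); ``truth`` in the
returned cohort is sufficient to recompute every label from features.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .cohort_io import (MedicationRecord, PatientRecord, RegimenRecord,
                        TabularSchema, WeightedEdgeList, clean_network)
from .medgraph import ATTRIBUTE_SET, AMINO_ACIDS

__all__ = ["SynthConfig", "SyntheticCohort", "generate_cohort", "generate_ppi",
           "generate_regimens_and_efficacy", "plant_matching", "make_schema"]


@dataclass
class SynthConfig:
    # patients (stage 1)
    n_patients: int = 600
    n_classes: int = 2
    n_numeric: int = 8
    n_categorical: int = 2
    d_image: int = 16
    beta_table: float = 2.0
    beta_image: float = 2.0
    missing_rate: float = 0.02
    outlier_rate: float = 0.01
    test_fraction: float = 0.25
    # medications + PPI (stage 2)
    n_medications: int = 30
    n_regimens: int = 400
    regimen_size: tuple = (2, 4)
    n_proteins: int = 60
    n_blocks: int = 2
    p_within: float = 0.3
    p_between: float = 0.02
    synergy_strength: float = 2.0
    single_effect_sd: float = 0.5
    outcome_noise_sd: float = 0.5
    outcome_quantile: float = 0.5   # label threshold; raise for class imbalance
    # matching (stage 3)
    match_factor_dim: int = 8
    match_obs_dim: int = 16
    match_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.regimen_size[1] > self.n_medications:
            raise ValueError("regimen size exceeds number of medications")
        for p in (self.p_within, self.p_between, self.missing_rate, self.outlier_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    config: SynthConfig
    schema: TabularSchema
    patients: list
    medications: list
    regimens: list
    ppi: WeightedEdgeList
    cooccurrence: dict
    matching: dict          # patient_vecs, regimen_vecs, truth pairing
    truth: dict             # every planted parameter

    # -- serialisation to the exact file set cohort_io reads --------------------
    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        num_names = self.schema.numeric_names
        cat_names = self.schema.categorical_names
        with open(out / "tabular.csv", "w") as fh:
            fh.write("patient_id," + ",".join(num_names + cat_names) + "\n")
            for p in self.patients:
                vals = [("" if p.tabular[f] is None else repr(float(p.tabular[f])))
                        for f in num_names]
                vals += [("" if p.tabular[f] is None else p.tabular[f]) for f in cat_names]
                fh.write(p.patient_id + "," + ",".join(vals) + "\n")
        with open(out / "image_embeddings.tsv", "w") as fh:
            dims = "\t".join(f"e{i}" for i in range(self.config.d_image))
            fh.write(f"patient_id\t{dims}\n")
            for p in self.patients:
                for vec in p.image_embeddings:
                    fh.write(p.patient_id + "\t"
                             + "\t".join(repr(float(v)) for v in vec) + "\n")
        with open(out / "labels.tsv", "w") as fh:
            fh.write("patient_id\tlabel\tsplit\n")
            for p in self.patients:
                fh.write(f"{p.patient_id}\t{p.severity_label}\t{p.split_tag}\n")
        with open(out / "medications.csv", "w") as fh:
            fh.write("med_id,kind," + ",".join(ATTRIBUTE_SET) + ",targets\n")
            for m in self.medications:
                texts = ",".join(m.attribute_texts.get(a, "") for a in ATTRIBUTE_SET)
                fh.write(f"{m.med_id},{m.kind},{texts},{';'.join(m.target_proteins)}\n")
        with open(out / "proteins.fasta", "w") as fh:
            seqs = {}
            for m in self.medications:
                seqs.update(m.protein_sequences)
            for pid in sorted(seqs):
                fh.write(f">{pid}\n{seqs[pid]}\n")
        with open(out / "ppi.tsv", "w") as fh:
            for a, b, w in self.ppi.edges:
                fh.write(f"{a}\t{b}\t{w}\n")
        with open(out / "cooccurrence.tsv", "w") as fh:
            for (a, b), c in sorted(self.cooccurrence.items()):
                fh.write(f"{a}\t{b}\t{c}\n")
        with open(out / "regimens.tsv", "w") as fh:
            fh.write("regimen_id\tpatient_id\tmed_ids\toutcome\n")
            for r in self.regimens:
                fh.write(f"{r.regimen_id}\t{r.patient_id}\t"
                         f"{';'.join(sorted(r.med_ids))}\t{r.outcome_label}\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(_jsonable(self.truth), fh, indent=1, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def make_schema(config: SynthConfig) -> TabularSchema:
    numeric = [(f"lab_{j}", -50.0, 50.0) for j in range(config.n_numeric)]
    categorical = [(f"cat_{j}", ["A", "B", "C"]) for j in range(config.n_categorical)]
    return TabularSchema(numeric, categorical)


# ---------------------------------------------------------------------------
# stage-1 world: patients
# ---------------------------------------------------------------------------

def _generate_patients(config: SynthConfig, rng: np.random.Generator,
                       schema: TabularSchema) -> tuple[list, dict]:
    n, k = config.n_patients, config.n_classes
    labels = rng.integers(0, k, size=n)
    # per-field class effect directions, fixed by the seed
    num_coef = rng.normal(0, 1, (k, config.n_numeric))
    num_coef = num_coef / (np.linalg.norm(num_coef, axis=1, keepdims=True) + 1e-12)
    image_dirs = rng.normal(0, 1, (k, config.d_image))
    image_dirs = image_dirs / (np.linalg.norm(image_dirs, axis=1, keepdims=True) + 1e-12)
    cat_probs = rng.dirichlet(np.ones(3) * (3.0 / max(config.beta_table, 1e-6)),
                              size=(k, config.n_categorical)) \
        if config.beta_table > 0 else np.full((k, config.n_categorical, 3), 1 / 3)

    patients = []
    for i in range(n):
        y = int(labels[i])
        numeric = config.beta_table * num_coef[y] + rng.normal(0, 1, config.n_numeric)
        tab = {}
        for j, name in enumerate(schema.numeric_names):
            if rng.random() < config.missing_rate:
                tab[name] = None
            elif rng.random() < config.outlier_rate:
                tab[name] = 999.0  # outside the physiological range, blanked by cleaning
            else:
                tab[name] = float(numeric[j])
        for j, (name, cats) in enumerate(schema.categorical_fields):
            if rng.random() < config.missing_rate:
                tab[name] = None
            else:
                tab[name] = cats[rng.choice(3, p=cat_probs[y, j])]
        n_images = int(rng.integers(1, 4))
        images = [config.beta_image * image_dirs[y] + rng.normal(0, 1, config.d_image)
                  for _ in range(n_images)]
        split = "test" if rng.random() < config.test_fraction else "development"
        patients.append(PatientRecord(f"P{i:04d}", tab, images, y, split))
    truth = {"labels": labels, "numeric_coefficients": num_coef,
             "image_directions": image_dirs, "categorical_probs": cat_probs}
    return patients, truth


# ---------------------------------------------------------------------------
# stage-2 world: PPI, medications, regimens
# ---------------------------------------------------------------------------

def generate_ppi(config: SynthConfig, seed: int | None = None) -> WeightedEdgeList:
    """Stochastic-block-model PPI network, cleaned of self-loops/duplicates."""
    seed = config.seed if seed is None else seed
    sizes = [config.n_proteins // config.n_blocks] * config.n_blocks
    sizes[-1] += config.n_proteins - sum(sizes)
    p = np.full((config.n_blocks, config.n_blocks), config.p_between)
    np.fill_diagonal(p, config.p_within)
    graph = nx.stochastic_block_model(sizes, p.tolist(), seed=seed)
    edges = [(f"PR{a:03d}", f"PR{b:03d}", 1.0) for a, b in graph.edges()]
    return clean_network(WeightedEdgeList(edges))


def _protein_block(config: SynthConfig, protein_index: int) -> int:
    per = config.n_proteins // config.n_blocks
    return min(protein_index // per, config.n_blocks - 1)


def _block_sequence(rng: np.random.Generator, block: int, length: int = 40) -> str:
    """Random amino-acid string with block-specific composition bias."""
    weights = np.ones(len(AMINO_ACIDS))
    favoured = slice(0, 5) if block % 2 == 0 else slice(5, 10)
    weights[favoured] = 6.0
    weights /= weights.sum()
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=weights))


def _generate_medications(config: SynthConfig, rng: np.random.Generator) -> tuple[list, dict]:
    per_block = config.n_proteins // config.n_blocks
    sequences = {f"PR{i:03d}": _block_sequence(rng, _protein_block(config, i))
                 for i in range(config.n_proteins)}
    medications, med_blocks = [], {}
    for m in range(config.n_medications):
        block = m % config.n_blocks
        med_id = f"M{m:03d}"
        lo = block * per_block
        hi = config.n_proteins if block == config.n_blocks - 1 else lo + per_block
        n_targets = int(rng.integers(1, 4))
        targets = sorted(f"PR{t:03d}" for t in rng.choice(np.arange(lo, hi),
                                                          size=n_targets, replace=False))
        texts = {attr: f"{attr.lower()}_block{block}_tok{rng.integers(0, 5)}_{med_id}"
                 for attr in ATTRIBUTE_SET}
        medications.append(MedicationRecord(
            med_id, "herbal" if m % 2 == 0 else "conventional", texts,
            targets, {t: sequences[t] for t in targets}))
        med_blocks[med_id] = block
    return medications, {"med_blocks": med_blocks, "sequences": sequences}


def generate_regimens_and_efficacy(config: SynthConfig, medications: list,
                                   rng: np.random.Generator | None = None,
                                   med_blocks: dict | None = None,
                                   patient_ids: list | None = None):
    """Sample regimens; outcome = Σ single effects + Σ planted pair synergies + noise.

    Synergy is ``synergy_strength`` for same-block medication pairs and 0
    otherwise, so efficacy is irreducibly pairwise.  Returns
    (regimens, co-occurrence counts, truth dict).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    med_ids = [m.med_id for m in medications]
    if med_blocks is None:
        med_blocks = {m.med_id: i % config.n_blocks for i, m in enumerate(medications)}
    single_effects = {m: float(rng.normal(0, config.single_effect_sd)) for m in med_ids}
    scores, sampled = [], []
    for r in range(config.n_regimens):
        size = int(rng.integers(config.regimen_size[0], config.regimen_size[1] + 1))
        meds = sorted(rng.choice(med_ids, size=size, replace=False))
        score = sum(single_effects[m] for m in meds)
        # symmetric pair synergy: same-block pairs synergise, cross-block pairs
        # antagonise, so the planted signal is pairwise rather than size-driven
        for a, b in itertools.combinations(meds, 2):
            sign = 1.0 if med_blocks[a] == med_blocks[b] else -1.0
            score += sign * config.synergy_strength
        score += float(rng.normal(0, config.outcome_noise_sd))
        sampled.append(meds)
        scores.append(score)
    threshold = float(np.quantile(scores, config.outcome_quantile))
    counts: dict = {}
    regimens = []
    for r, (meds, score) in enumerate(zip(sampled, scores)):
        pid = patient_ids[r % len(patient_ids)] if patient_ids else f"P{r:04d}"
        regimens.append(RegimenRecord(f"R{r:04d}", pid, frozenset(meds),
                                      int(score > threshold)))
        for a, b in itertools.combinations(meds, 2):
            key = (a, b)
            counts[key] = counts.get(key, 0) + 1
    truth = {"single_effects": single_effects, "synergy_strength": config.synergy_strength,
             "med_blocks": med_blocks, "threshold": threshold, "scores": scores}
    return regimens, counts, truth


# ---------------------------------------------------------------------------
# stage-3 world: shared-factor matching
# ---------------------------------------------------------------------------

def plant_matching(config: SynthConfig, patient_ids: list, regimen_ids: list,
                   rng: np.random.Generator | None = None) -> dict:
    """Plant a shared latent factor into matched patient/regimen observables.

    Each patient i and its true regimen share a factor f_i; both observables
    are fixed linear maps of f_i plus N(0, match_noise_sd) noise.
    """
    if config.match_factor_dim < 1:
        raise ValueError("match_factor_dim must be >= 1")
    if len(patient_ids) > len(regimen_ids):
        raise ValueError("one-to-one pairing needs at least as many regimens as patients")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    k, d = config.match_factor_dim, config.match_obs_dim
    map_patient = rng.normal(0, 1 / np.sqrt(k), (k, d))
    map_regimen = rng.normal(0, 1 / np.sqrt(k), (k, d))
    factors = rng.normal(0, 1, (len(patient_ids), k))
    truth_pairing = dict(zip(patient_ids, regimen_ids))
    patient_vecs = {}
    regimen_vecs = {}
    for i, pid in enumerate(patient_ids):
        patient_vecs[pid] = factors[i] @ map_patient + rng.normal(0, config.match_noise_sd, d)
        regimen_vecs[truth_pairing[pid]] = (factors[i] @ map_regimen
                                            + rng.normal(0, config.match_noise_sd, d))
    for rid in regimen_ids[len(patient_ids):]:
        f = rng.normal(0, 1, k)
        regimen_vecs[rid] = f @ map_regimen + rng.normal(0, config.match_noise_sd, d)
    return {"patient_vecs": patient_vecs, "regimen_vecs": regimen_vecs,
            "truth": truth_pairing, "factors": factors,
            "map_patient": map_patient, "map_regimen": map_regimen}


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Generate the complete synthetic world; pure function of (config, seed)."""
    rng = np.random.default_rng(config.seed)
    schema = make_schema(config)
    if config.n_patients == 0:
        return SyntheticCohort(config, schema, [], [], [], WeightedEdgeList([]), {},
                               {"patient_vecs": {}, "regimen_vecs": {}, "truth": {}}, {})
    patients, patient_truth = _generate_patients(config, rng, schema)
    ppi = generate_ppi(config, seed=int(rng.integers(0, 2 ** 31 - 1)))
    medications, med_truth = _generate_medications(config, rng)
    regimens, counts, regimen_truth = generate_regimens_and_efficacy(
        config, medications, rng, med_truth["med_blocks"],
        [p.patient_id for p in patients])
    n_pairs = min(config.n_patients, config.n_regimens)
    matching = plant_matching(config, [p.patient_id for p in patients][:n_pairs],
                              [r.regimen_id for r in regimens], rng)
    truth = {"patients": patient_truth, "medications": med_truth,
             "regimens": regimen_truth,
             "matching": {"truth": matching["truth"]},
             "seed": config.seed}
    return SyntheticCohort(config, schema, patients, medications, regimens,
                           ppi, counts, matching, truth)
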