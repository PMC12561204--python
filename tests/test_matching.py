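"""Stage-3 matching: cosine confidence, contrastive losses, ranking, HIT@k."""

import numpy as np
import pytest

from codmed.autodiff import Tensor
from codmed.matching import (MatchingModel, Projector, Stage3Config,
                             bidirectional_loss, contrastive_loss_directional,
                             cosine_similarity, hit_at_k, match_confidence,
                             rank_regimens)


# ---------------------------------------------------------------------------
# cosine similarity / confidence
# ---------------------------------------------------------------------------

def test_cosine_orthogonal_is_zero():
    assert cosine_similarity([1, 0], [0, 1]) == 0.0


def test_cosine_scale_invariant():
    v = np.array([0.3, -2.0, 1.1])
    assert cosine_similarity(v, 2 * v) == pytest.approx(1.0)


def test_cosine_hand_value():
    assert cosine_similarity([1, 1], [1, 0]) == pytest.approx(1 / np.sqrt(2))
    assert match_confidence([1, 1], [1, 0]) == pytest.approx(0.70711, abs=1e-5)


def test_confidence_bounds_and_collinearity(rng):
    for _ in range(20):
        a, b = rng.normal(size=4), rng.normal(size=4)
        c = match_confidence(a, b)
        assert -1.0 <= c <= 1.0
    v = rng.normal(size=4)
    assert match_confidence(v, 3.5 * v) == pytest.approx(1.0)
    assert match_confidence(v, -v) == pytest.approx(-1.0)


def test_zero_vector_confidence_is_zero_with_warning():
    with pytest.warns(UserWarning):
        assert match_confidence([0, 0], [1, 0]) == 0.0


# ---------------------------------------------------------------------------
# contrastive losses
# ---------------------------------------------------------------------------

def _triplet(s_pos_vec, s_neg_vec):
    """Build anchor/pos/neg with prescribed cosine to the anchor (2-D trick)."""
    anchors, positives, negatives = [], [], []
    for sp, sn in zip(s_pos_vec, s_neg_vec):
        anchors.append([1.0, 0.0])
        positives.append([sp, np.sqrt(max(0.0, 1 - sp ** 2))])
        negatives.append([sn, np.sqrt(max(0.0, 1 - sn ** 2))])
    return (Tensor(np.array(anchors)), Tensor(np.array(positives)),
            Tensor(np.array(negatives)))


def test_directional_loss_zero_when_margin_satisfied():
    a, p, n = _triplet([0.9], [0.1])
    assert contrastive_loss_directional(a, p, n, margin=0.2).item() == pytest.approx(0.0)


def test_directional_loss_boundary_zero_margin():
    a, p, n = _triplet([0.4], [0.4])
    assert contrastive_loss_directional(a, p, n, margin=0.0).item() == pytest.approx(0.0, abs=1e-9)


def test_directional_loss_hand_value_with_half_scaling():
    a, p, n = _triplet([0.0], [0.5])
    # per-anchor hinge max(0, 0.5 - 0.0 + 0.2) = 0.7, halved -> 0.35
    assert contrastive_loss_directional(a, p, n, margin=0.2).item() == pytest.approx(0.35, abs=1e-6)


def test_literal_unhinged_variant():
    a, p, n = _triplet([0.9], [0.1])
    val = contrastive_loss_directional(a, p, n, margin=0.2, literal=True).item()
    assert val == pytest.approx(0.5 * (0.9 - 0.1 + 0.2), abs=1e-6)


def test_directional_loss_empty_batch_is_error():
    empty = Tensor(np.zeros((0, 2)))
    with pytest.raises(ValueError):
        contrastive_loss_directional(empty, empty, empty)


def test_bidirectional_is_mean_of_directions_and_symmetric(rng):
    p = Tensor(rng.normal(size=(4, 3)))
    r = Tensor(rng.normal(size=(4, 3)))
    pn = Tensor(rng.normal(size=(4, 3)))
    rn = Tensor(rng.normal(size=(4, 3)))
    total = bidirectional_loss(p, r, pn, rn, margin=0.2).item()
    swapped = bidirectional_loss(r, p, rn, pn, margin=0.2).item()
    assert total == pytest.approx(swapped)
    l1 = contrastive_loss_directional(p, r, rn, 0.2).item()
    l2 = contrastive_loss_directional(r, p, pn, 0.2).item()
    assert total == pytest.approx(0.5 * (l1 + l2))


def test_bidirectional_symmetric_batch_equals_either_direction(rng):
    e = Tensor(rng.normal(size=(3, 4)))
    en = Tensor(rng.normal(size=(3, 4)))
    total = bidirectional_loss(e, e, en, en, margin=0.1).item()
    assert total == pytest.approx(contrastive_loss_directional(e, e, en, 0.1).item())


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def test_identity_initialized_projection_returns_input(rng):
    proj = Projector(3, 3, 3, rng)
    proj.fc1.weight.data = np.eye(3)
    proj.fc1.bias.data[:] = 0.0
    proj.fc2.weight.data = np.eye(3)
    proj.fc2.bias.data[:] = 0.0
    x = np.abs(rng.normal(size=(2, 3)))  # positive, so relu is identity
    assert np.allclose(proj(Tensor(x)).data, x)


def test_zero_weight_projection_returns_zero(rng):
    proj = Projector(3, 4, 2, rng)
    for lin in (proj.fc1, proj.fc2):
        lin.weight.data[:] = 0.0
        lin.bias.data[:] = 0.0
    assert np.allclose(proj(Tensor(rng.normal(size=(2, 3)))).data, 0.0)


def test_projection_matches_hand_composition():
    rng = np.random.default_rng(2)
    proj = Projector(2, 2, 2, rng)
    x = rng.normal(size=(1, 2))
    hidden = np.maximum(x @ proj.fc1.weight.data + proj.fc1.bias.data, 0)
    expected = hidden @ proj.fc2.weight.data + proj.fc2.bias.data
    assert np.allclose(proj(Tensor(x)).data, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# ranking + HIT@k
# ---------------------------------------------------------------------------

def test_rank_single_regimen_library():
    ranking = rank_regimens("P", np.array([1.0, 0.0]), {"R1": np.array([0.5, 0.5])}, k=1)
    assert ranking.ranked[0][0] == "R1"


def test_self_match_ranks_first(rng):
    v = rng.normal(size=4)
    library = {"Rself": v.copy(), "Rother": rng.normal(size=4)}
    ranking = rank_regimens("P", v, library, k=1)
    assert ranking.ranked[0][0] == "Rself"
    assert ranking.ranked[0][1] == pytest.approx(1.0)


def test_tie_break_is_lexicographic():
    # cosines {0.9, 0.5, 0.5, 0.1, -0.2}; the two 0.5s must appear in id order
    def vec(c):
        return np.array([c, np.sqrt(1 - c ** 2)])
    library = {"R_e": vec(0.9), "R_c": vec(0.5), "R_a": vec(0.5),
               "R_b": vec(0.1), "R_d": vec(-0.2)}
    ranking = rank_regimens("P", np.array([1.0, 0.0]), library, k=3)
    assert [rid for rid, _ in ranking.top(3)] == ["R_e", "R_a", "R_c"]


def test_rank_matches_brute_force_on_100_regimen_library(rng):
    patient = rng.normal(size=6)
    library = {f"R{i:03d}": rng.normal(size=6) for i in range(100)}
    ranking = rank_regimens("P", patient, library, k=100)
    brute = sorted(((rid, match_confidence(patient, v)) for rid, v in library.items()),
                   key=lambda x: (-x[1], x[0]))
    assert [rid for rid, _ in ranking.ranked] == [rid for rid, _ in brute]
    confs = [c for _, c in ranking.ranked]
    assert all(confs[i] >= confs[i + 1] for i in range(len(confs) - 1))


def test_rank_errors():
    with pytest.raises(ValueError):
        rank_regimens("P", np.ones(2), {}, k=1)
    with pytest.raises(ValueError):
        rank_regimens("P", np.ones(2), {"R": np.ones(2)}, k=5)


def _rankings(order_per_patient):
    out = []
    for pid, ids in order_per_patient.items():
        out.append(type("MR", (), {})())
        from codmed.matching import MatchRanking
        out[-1] = MatchRanking(pid, [(rid, 1.0 - 0.1 * i) for i, rid in enumerate(ids)], k=1)
    return out


def test_hit_at_k_counting():
    rankings = _rankings({"P1": ["R1", "R2"], "P2": ["R2", "R3", "R1"],
                          "P3": ["R1", "R3", "R2"], "P4": ["R3", "R2"]})
    truth = {"P1": "R1", "P2": "R1", "P3": "R1", "P4": "R2"}
    assert hit_at_k(rankings, truth, k=1) == 0.5
    assert hit_at_k(rankings, truth, k=2) == 0.75  # 3 of 4 within top-2


def test_hit_at_k_all_rank_one_and_exhaustive():
    rankings = _rankings({"P1": ["R1", "R2"], "P2": ["R2", "R1"]})
    truth = {"P1": "R1", "P2": "R2"}
    assert hit_at_k(rankings, truth, k=1) == 1.0
    assert hit_at_k(rankings, truth, k=2) == 1.0  # k = library size


def test_hit_at_k_nondecreasing_in_k(rng):
    library = {f"R{i}": rng.normal(size=4) for i in range(20)}
    truth = {}
    rankings = []
    for p in range(10):
        vec = rng.normal(size=4)
        truth[f"P{p}"] = f"R{p}"
        rankings.append(rank_regimens(f"P{p}", vec, library, k=20))
    values = [hit_at_k(rankings, truth, k) for k in range(1, 21)]
    assert all(a <= b for a, b in zip(values, values[1:]))
    assert values[-1] == 1.0


def test_hit_at_k_missing_truth_regimen_is_error():
    rankings = _rankings({"P1": ["R1"]})
    with pytest.raises(KeyError):
        hit_at_k(rankings, {"P1": "Rmissing"}, k=1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _paired_world(n=24, d=6, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(4, d))
    b = rng.normal(size=(4, d))
    factors = rng.normal(size=(n, 4))
    patients = {f"P{i}": factors[i] @ a + noise * rng.normal(size=d) for i in range(n)}
    regimens = {f"R{i}": factors[i] @ b + noise * rng.normal(size=d) for i in range(n)}
    truth = {f"P{i}": f"R{i}" for i in range(n)}
    return patients, regimens, truth


def test_stage3_lr_zero_unchanged():
    p, r, t = _paired_world()
    model = MatchingModel(p, r, t, Stage3Config(shared_dim=4, hidden=8, epochs=1, lr=0.0))
    model._build(np.random.default_rng(0))
    params = model.project_patient.parameters() + model.project_regimen.parameters()
    before = [q.data.copy() for q in params]
    model.fit(seed=0)
    assert all(np.array_equal(b, q.data) for b, q in zip(before, params))


def test_stage3_determinism():
    p, r, t = _paired_world()
    cfg = Stage3Config(shared_dim=4, hidden=8, epochs=4)
    h1 = MatchingModel(p, r, t, cfg).fit(seed=2).evaluate_hit_at_k(5)
    h2 = MatchingModel(p, r, t, cfg).fit(seed=2).evaluate_hit_at_k(5)
    assert h1 == h2


def test_training_increases_positive_negative_separation():
    p, r, t = _paired_world(n=40)
    res = MatchingModel(p, r, t, Stage3Config(shared_dim=8, hidden=16, epochs=25)).fit(seed=1)
    assert res.separation_curve[-1] > res.separation_curve[0]


def test_stage3_needs_two_pairs():
    p, r, t = _paired_world(n=1)
    with pytest.raises(ValueError):
        MatchingModel(p, r, t, Stage3Config()).fit(seed=0)


def test_export_rankings_tsv_and_json(tmp_path, rng):
    import json
    from codmed.matching import export_rankings
    library = {f"R{i}": rng.normal(size=3) for i in range(4)}
    rankings = [rank_regimens(f"P{j}", rng.normal(size=3), library, k=2)
                for j in range(2)]
    export_rankings(rankings, tsv_path=tmp_path / "r.tsv", json_path=tmp_path / "r.json")
    lines = (tmp_path / "r.tsv").read_text().strip().split("\n")
    assert lines[0] == "patient_id\trank\tregimen_id\tconfidence"
    assert len(lines) == 1 + 2 * 2
    payload = json.loads((tmp_path / "r.json").read_text())
    assert set(payload) == {"P0", "P1"} and len(payload["P0"]) == 2


def test_stage3_refuses_unknown_truth_ids():
    p, r, t = _paired_world(n=4)
    t["P0"] = "R_missing"
    with pytest.raises(KeyError):
        MatchingModel(p, r, t)
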