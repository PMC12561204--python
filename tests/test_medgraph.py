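"""Stage-2 medication graphs: embedders, DeepWalk, edge-aware attention, VAE, focal loss."""

import numpy as np
import pytest

from codmed.autodiff import Tensor
from codmed.cohort_io import RegimenRecord, WeightedEdgeList
from codmed.medgraph import (ATTRIBUTE_SET, AttributeAttention, AttributeEmbedding,
                             EfficacyModel, GraphTransformerLayer, HashingTextEmbedder,
                             KmerEmbedder, RegimenGraph, Stage2Config,
                             VariationalAligner, build_regimen_graph,
                             cooccurrence_edge_weights, deepwalk_embed,
                             embed_protein_sequences, embed_text_attributes,
                             focal_loss, fuse_attributes, kl_closed_form,
                             random_walks, rank_pairwise_combinations,
                             stage2_total_loss)


# ---------------------------------------------------------------------------
# embedder contracts
# ---------------------------------------------------------------------------

def test_hash_embedder_deterministic_per_string():
    emb = HashingTextEmbedder(dim=8, seed=1)
    assert np.array_equal(emb.embed("bitter"), emb.embed("bitter"))
    assert not np.array_equal(emb.embed("bitter"), emb.embed("sweet"))


def test_embed_text_attributes_covers_attribute_set():
    emb = HashingTextEmbedder(dim=8)
    vectors, flagged = embed_text_attributes(
        {a: f"text {a}" for a in ATTRIBUTE_SET}, emb)
    assert set(vectors) == set(ATTRIBUTE_SET)
    assert {len(v) for v in vectors.values()} == {8}
    assert flagged == []


def test_empty_attribute_text_gives_flagged_zero_vector():
    emb = HashingTextEmbedder(dim=8)
    vectors, flagged = embed_text_attributes({"Meridian": "lung"}, emb)
    assert flagged == ["Property", "Flavours", "SideEffects"]
    assert np.allclose(vectors["SideEffects"], 0.0)


def test_kmer_counts_hand_example():
    emb = KmerEmbedder(k=2, projection_dim=None)
    counts = emb.counts("MKV")
    assert counts.sum() == 2
    assert counts[emb.index["MK"]] == 1 and counts[emb.index["KV"]] == 1


def test_protein_embedding_mean_aggregation():
    emb = KmerEmbedder(k=2, projection_dim=4, seed=0)
    one, flagged_one = embed_protein_sequences(["MKV"], emb)
    two, _ = embed_protein_sequences(["MKV", "MKV"], emb)
    assert np.allclose(one, emb.embed("MKV")) and not flagged_one
    assert np.allclose(one, two)  # mean idempotent on duplicates


def test_no_targets_gives_flagged_zero_vector():
    emb = KmerEmbedder(k=2, projection_dim=4)
    vec, flagged = embed_protein_sequences([], emb)
    assert flagged and np.allclose(vec, 0.0)


# ---------------------------------------------------------------------------
# attribute fusion
# ---------------------------------------------------------------------------

def test_single_attribute_attention_is_value_projection(rng):
    att = AttributeAttention(4, rng)
    v = rng.normal(size=(1, 4))
    got = att(Tensor(v)).data
    assert np.allclose(got, (v @ att.w_v.weight.data)[0], atol=1e-12)


def test_identical_attribute_tokens_pool_to_single_token_output(rng):
    att = AttributeAttention(4, rng)
    v = rng.normal(size=4)
    stacked = np.stack([v, v, v])
    assert np.allclose(att(Tensor(stacked)).data, att(Tensor(v[None])).data, atol=1e-10)


def test_attribute_attention_matches_hand_oracle():
    rng = np.random.default_rng(5)
    att = AttributeAttention(3, rng)
    tokens = rng.normal(size=(2, 3))
    q = tokens @ att.w_q.weight.data
    k = tokens @ att.w_k.weight.data
    v = tokens @ att.w_v.weight.data
    scores = q @ k.T / np.sqrt(3)
    alpha = np.exp(scores - scores.max(axis=-1, keepdims=True))
    alpha /= alpha.sum(axis=-1, keepdims=True)
    expected = (alpha @ v).mean(axis=0)
    assert np.allclose(fuse_attributes(list(tokens), att), expected, atol=1e-6)


def test_fuse_attributes_empty_is_error(rng):
    with pytest.raises(ValueError):
        fuse_attributes([], AttributeAttention(4, rng))


# ---------------------------------------------------------------------------
# DeepWalk
# ---------------------------------------------------------------------------

def test_walk_on_path_graph_is_forced(rng):
    net = WeightedEdgeList([("A", "B", 1.0)])
    walks = random_walks(net, walk_length=3, walks_per_node=1, rng=rng)
    assert ["A", "B", "A"] in walks and ["B", "A", "B"] in walks


def test_walk_length_below_two_is_error(rng):
    with pytest.raises(ValueError):
        random_walks(WeightedEdgeList([("A", "B", 1.0)]), 1, 1, rng)


def test_disconnected_triangles_separate_in_embedding_space():
    edges = [("a1", "a2", 1.0), ("a2", "a3", 1.0), ("a1", "a3", 1.0),
             ("b1", "b2", 1.0), ("b2", "b3", 1.0), ("b1", "b3", 1.0)]
    emb = deepwalk_embed(WeightedEdgeList(edges), walk_length=8,
                         walks_per_node=20, dim=8, seed=0)

    def cos(u, v):
        return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))

    nodes = sorted(emb)
    within, between = [], []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            (within if a[0] == b[0] else between).append(cos(emb[a], emb[b]))
    assert np.mean(within) > np.mean(between)


def test_isolated_node_gets_zero_vector():
    net = WeightedEdgeList([("A", "B", 1.0)])
    emb = deepwalk_embed(net, dim=4, seed=0, nodes=["A", "B", "LONE"])
    assert np.allclose(emb["LONE"], 0.0)
    assert not np.allclose(emb["A"], 0.0)


def test_deepwalk_deterministic_under_seed():
    net = WeightedEdgeList([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0)])
    e1 = deepwalk_embed(net, dim=4, seed=9)
    e2 = deepwalk_embed(net, dim=4, seed=9)
    assert all(np.array_equal(e1[n], e2[n]) for n in e1)


# ---------------------------------------------------------------------------
# co-occurrence prior + graph construction
# ---------------------------------------------------------------------------

def test_cooccurrence_normalised_by_max():
    out = cooccurrence_edge_weights({("A", "B"): 4, ("A", "C"): 2})
    assert out == {("A", "B"): 1.0, ("A", "C"): 0.5}


def test_cooccurrence_single_pair_and_uniform():
    assert cooccurrence_edge_weights({("A", "B"): 7}) == {("A", "B"): 1.0}
    uniform = cooccurrence_edge_weights({("A", "B"): 3, ("B", "C"): 3})
    assert set(uniform.values()) == {1.0}
    assert cooccurrence_edge_weights({}) == {}


def _features(med_ids, dim=2):
    rng = np.random.default_rng(0)
    return {m: AttributeEmbedding(rng.normal(size=dim), rng.normal(size=dim),
                                  rng.normal(size=dim)) for m in med_ids}


def test_build_regimen_graph_triangle():
    feats = _features(["A", "B", "C"])
    prior = {("A", "B"): 0.5, ("A", "C"): 0.25, ("B", "C"): 1.0}
    reg = RegimenRecord("R1", "P1", {"A", "B", "C"}, 1)
    g = build_regimen_graph(reg, feats, prior, fallback_weight=0.1)
    assert g.n_nodes == 3 and len(g.edges) == 3
    assert g.features.shape == (3, 6)
    weights = {tuple(sorted((g.med_ids[i], g.med_ids[j]))): w for i, j, w in g.edges}
    assert weights == {("A", "B"): 0.5, ("A", "C"): 0.25, ("B", "C"): 1.0}


def test_single_medication_regimen_has_no_edges():
    g = build_regimen_graph(RegimenRecord("R1", "P1", {"A"}, 0),
                            _features(["A"]), {}, 0.1)
    assert g.n_nodes == 1 and g.edges == []


def test_missing_prior_pair_gets_fallback_weight():
    g = build_regimen_graph(RegimenRecord("R1", "P1", {"A", "B"}, 0),
                            _features(["A", "B"]), {}, fallback_weight=0.125)
    assert g.edges == [(0, 1, 0.125)]


def test_unknown_medication_is_lookup_error():
    with pytest.raises(KeyError):
        build_regimen_graph(RegimenRecord("R1", "P1", {"A", "Z"}, 0),
                            _features(["A"]), {}, 0.1)


# ---------------------------------------------------------------------------
# graph transformer layer
# ---------------------------------------------------------------------------

def _single_graph_arrays(features, edges, n):
    wmat = np.zeros((1, n, n))
    adj = np.zeros((1, n, n))
    for i, j, w in edges:
        adj[0, i, j] = adj[0, j, i] = 1.0
        wmat[0, i, j] = wmat[0, j, i] = w
    return Tensor(features[None]), wmat, adj


def test_single_neighbor_attention_is_one(rng):
    layer = GraphTransformerLayer(3, rng, activation="relu")
    h, wmat, adj = _single_graph_arrays(rng.normal(size=(2, 3)), [(0, 1, 0.7)], 2)
    out = layer(h, wmat, adj)
    assert np.allclose(layer.last_alpha[0, 0], [0.0, 1.0], atol=1e-12)
    expected = np.maximum(h.data[0, 1] @ layer.w_v.weight.data, 0.0)
    assert np.allclose(out.data[0, 0], expected, atol=1e-10)


def test_identical_neighbors_share_attention_equally(rng):
    layer = GraphTransformerLayer(3, rng)
    feats = rng.normal(size=(3, 3))
    feats[2] = feats[1]  # node 0's two neighbours identical, same edge weight
    h, wmat, adj = _single_graph_arrays(feats, [(0, 1, 0.5), (0, 2, 0.5)], 3)
    layer(h, wmat, adj)
    assert np.allclose(layer.last_alpha[0, 0, 1:], [0.5, 0.5], atol=1e-12)


def test_graph_transformer_matches_hand_oracle_and_is_equivariant():
    rng = np.random.default_rng(11)
    d = 3
    layer = GraphTransformerLayer(d, rng, activation="relu")
    feats = rng.normal(size=(3, d))
    edges = [(0, 1, 0.9), (0, 2, 0.3), (1, 2, 0.6)]
    h, wmat, adj = _single_graph_arrays(feats, edges, 3)
    got = layer(h, wmat, adj).data[0]

    # dense hand oracle: alpha_ij = softmax_j over N(i) of q_i . (k_j + w_ij) / sqrt(d)
    wq, wk, wv = (layer.w_q.weight.data, layer.w_k.weight.data, layer.w_v.weight.data)
    q, k = feats @ wq, feats @ wk
    wm = wmat[0]
    expected = np.zeros_like(feats)
    for i in range(3):
        nbrs = [j for j in range(3) if adj[0, i, j]]
        logits = np.array([q[i] @ (k[j] + wm[i, j]) / np.sqrt(d) for j in nbrs])
        alpha = np.exp(logits - logits.max())
        alpha /= alpha.sum()
        expected[i] = np.maximum(
            sum(a * (feats[j] @ wv) for a, j in zip(alpha, nbrs)), 0.0)
    assert np.allclose(got, expected, atol=1e-6)

    # permutation equivariance: relabel nodes by pi, outputs permute identically
    pi = np.array([2, 0, 1])
    perm_feats = feats[pi]
    perm_edges = [(list(pi).index(i), list(pi).index(j), w) for i, j, w in edges]
    hp, wmp, adjp = _single_graph_arrays(perm_feats, perm_edges, 3)
    got_perm = layer(hp, wmp, adjp).data[0]
    assert np.allclose(got_perm, got[pi], atol=1e-10)


def test_attention_rows_sum_to_one_with_padding(rng):
    layer = GraphTransformerLayer(4, rng)
    graphs = [RegimenGraph("r1", ["A", "B"], rng.normal(size=(2, 4)),
                           [(0, 1, 0.5)], 1),
              RegimenGraph("r2", ["A", "B", "C"], rng.normal(size=(3, 4)),
                           [(0, 1, 0.2), (0, 2, 0.4), (1, 2, 0.6)], 0)]
    from codmed.medgraph import _pad_graphs
    feats, wmat, adj, _mask = _pad_graphs(graphs)
    layer(Tensor(feats), wmat, adj)
    assert np.allclose(layer.last_alpha.sum(axis=-1), 1.0, atol=1e-8)


def test_isolated_node_self_loop_fallback(rng):
    layer = GraphTransformerLayer(3, rng, activation="identity")
    feats = rng.normal(size=(1, 3))
    h, wmat, adj = _single_graph_arrays(feats, [], 1)
    out = layer(h, wmat, adj)
    assert np.allclose(out.data[0, 0], feats[0] @ layer.w_v.weight.data, atol=1e-10)


# ---------------------------------------------------------------------------
# VAE alignment
# ---------------------------------------------------------------------------

def test_kl_zero_iff_standard_normal():
    assert kl_closed_form(np.zeros(4), np.ones(4)) == pytest.approx(0.0)
    assert kl_closed_form([1.0], [1.0]) == pytest.approx(0.5)
    # grid in both directions: zero only at (mu=0, sigma=1)
    for mu in (-1.0, -0.3, 0.0, 0.4, 2.0):
        for sigma in (0.3, 0.7, 1.0, 1.8):
            val = kl_closed_form([mu], [sigma])
            assert val >= 0.0
            if (mu, sigma) != (0.0, 1.0):
                assert val > 1e-4
            else:
                assert val == pytest.approx(0.0)


def test_vae_align_module_matches_closed_form(rng):
    vae = VariationalAligner(d=4, latent=2, rng=rng)
    h = Tensor(rng.normal(size=(1, 3, 4)))
    _z, recon, l_kl = vae(h)
    mu, sigma = vae.encode(h)
    expected = np.mean([kl_closed_form(mu.data[0, i], sigma.data[0, i])
                        for i in range(3)])
    assert l_kl.item() == pytest.approx(expected)
    assert recon.shape == (1, 3, 4)
    assert np.all(sigma.data > 0)


def test_vae_reparameterization_is_seeded(rng):
    vae = VariationalAligner(d=4, latent=2, rng=rng)
    h = Tensor(rng.normal(size=(1, 2, 4)))
    eps = np.random.default_rng(0).standard_normal((1, 2, 2))
    z1, _, _ = vae(h, eps)
    z2, _, _ = vae(h, eps)
    assert np.array_equal(z1.data, z2.data)


# ---------------------------------------------------------------------------
# focal loss + total
# ---------------------------------------------------------------------------

def test_focal_reduces_to_cross_entropy_at_gamma_zero():
    grid = np.linspace(0.01, 1.0, 50)
    for p in grid:
        assert abs(focal_loss([p], 1.0, 0.0) - (-np.log(p))) <= 1e-12


def test_focal_hand_value():
    assert focal_loss([0.5], 1.0, 2.0) == pytest.approx(-0.25 * np.log(0.5))
    assert focal_loss([0.5], 1.0, 2.0) == pytest.approx(0.17328679513998632)


def test_focal_perfect_prediction_is_zero():
    assert focal_loss([1.0], 1.0, 2.0) == 0.0


def test_focal_clips_zero_probability_with_warning():
    with pytest.warns(UserWarning):
        val = focal_loss([0.0], 1.0, 2.0)
    assert np.isfinite(val)


def test_stage2_total_loss_is_sum():
    assert stage2_total_loss(0.0, 0.0) == 0.0
    assert stage2_total_loss(0.5, 0.17329) == pytest.approx(0.67329)
    assert stage2_total_loss(1.25, 0.0) == 1.25


# ---------------------------------------------------------------------------
# training behaviour + pair ranking
# ---------------------------------------------------------------------------

def _toy_graphs(n=30, seed=0):
    rng = np.random.default_rng(seed)
    feats = _features([f"M{i}" for i in range(6)], dim=2)
    graphs = []
    for i in range(n):
        meds = sorted(rng.choice([f"M{j}" for j in range(6)], size=2, replace=False))
        reg = RegimenRecord(f"R{i}", f"P{i}", frozenset(meds), int(rng.random() < 0.5))
        graphs.append(build_regimen_graph(reg, feats, {}, 0.5))
    return graphs


def test_lr_zero_leaves_stage2_parameters_unchanged():
    graphs = _toy_graphs()
    model = EfficacyModel(graphs, Stage2Config(d=8, latent=4, epochs=1, lr=0.0))
    model._build(np.random.default_rng(0))
    before = [p.data.copy() for p in model._params()]
    model.fit(seed=0)
    assert all(np.array_equal(b, a.data) for b, a in zip(before, model._params()))


def test_stage2_same_seed_identical_curves():
    graphs = _toy_graphs()
    r1 = EfficacyModel(graphs, Stage2Config(d=8, latent=4, epochs=3)).fit(seed=4)
    r2 = EfficacyModel(graphs, Stage2Config(d=8, latent=4, epochs=3)).fit(seed=4)
    assert r1.loss_curve == r2.loss_curve


def test_stage2_single_class_labels_rejected():
    graphs = _toy_graphs()
    for g in graphs:
        g.label = 1
    with pytest.raises(ValueError):
        EfficacyModel(graphs, Stage2Config())


def test_rank_pairwise_counts_and_ceil_rule():
    graphs = _toy_graphs()
    res = EfficacyModel(graphs, Stage2Config(d=8, latent=4, epochs=2)).fit(seed=0)
    feats = _features([f"M{i}" for i in range(5)], dim=2)
    all_pairs = rank_pairwise_combinations(res, feats, {}, 0.5, top_fraction=1.0)
    assert len(all_pairs) == 10  # C(5,2)
    scores = [s for _, s in all_pairs]
    assert scores == sorted(scores, reverse=True)
    top = rank_pairwise_combinations(res, feats, {}, 0.5, top_fraction=0.15)
    assert len(top) == 2  # ceil(0.15 * 10)


def test_rank_pairwise_needs_two_medications():
    graphs = _toy_graphs()
    res = EfficacyModel(graphs, Stage2Config(d=8, latent=4, epochs=1)).fit(seed=0)
    with pytest.raises(ValueError):
        rank_pairwise_combinations(res, _features(["A"]), {}, 0.5)
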